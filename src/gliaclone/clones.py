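"""Clone decoding from combinatorial fluorescent-reporter color codes.

Cells inherit a heritable presence/absence pattern over 12 reporter
constructs (6 fluorescent proteins, each nuclear or cytoplasmic). Sibling
cells share an identical code, so the clonal partition is recovered by exact
code equality. Clone-level descriptors follow: size, the set of anatomical
regions occupied (the dispersion pattern), pattern frequencies over a
cohort, and rostro-caudal extent across serial coronal sections.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FLUOROPHORES = ("YFP", "mKO", "mCerulean", "mCherry", "mT-Sapphire", "EGFP")
LOCALIZATIONS = ("nuclear", "cytoplasmic")

#: Ordered names of the 12 reporter components.
COMPONENTS = tuple(f"{f}-{loc}" for f in FLUOROPHORES for loc in LOCALIZATIONS)

N_COMPONENTS = len(COMPONENTS)

#: The five anatomical region labels used for dispersion patterns.
REGIONS = ("St", "CC", "L-Cx", "U-Cx", "Pia")


def code_space_size() -> int:
    """Number of distinct presence/absence combinations over the 12 constructs.

    Counted by exhaustive enumeration of the component product space.
    """
    return sum(1 for _ in itertools.product((0, 1), repeat=N_COMPONENTS))


@dataclass(frozen=True)
class ColorCode:
    """Presence/absence over the 12 reporter components, in COMPONENTS order."""

    bits: tuple[bool, ...]

    def __post_init__(self):
        if len(self.bits) != N_COMPONENTS:
            raise ValueError(f"color code needs {N_COMPONENTS} components, got {len(self.bits)}")
        object.__setattr__(self, "bits", tuple(bool(b) for b in self.bits))

    @classmethod
    def from_string(cls, s: str) -> "ColorCode":
        s = s.strip()
        if len(s) != N_COMPONENTS or set(s) - {"0", "1"}:
            raise ValueError(f"code string must be {N_COMPONENTS} chars of 0/1, got {s!r}")
        return cls(tuple(c == "1" for c in s))

    @classmethod
    def from_int(cls, value: int) -> "ColorCode":
        if not 0 <= value < 2**N_COMPONENTS:
            raise ValueError(f"code integer out of range: {value}")
        return cls(tuple(bool((value >> (N_COMPONENTS - 1 - i)) & 1) for i in range(N_COMPONENTS)))

    def to_string(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)

    @property
    def is_labelled(self) -> bool:
        return any(self.bits)


@dataclass
class Clone:
    """A set of sibling cells sharing one color code."""

    clone_id: str
    code: ColorCode
    member_cell_ids: list[str]
    #: per-member region labels, aligned with member_cell_ids
    member_regions: list[str] = field(default_factory=list)
    #: per-member section indices, aligned with member_cell_ids
    member_sections: list[int] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.member_cell_ids)

    @property
    def region_pattern(self) -> frozenset[str]:
        return classify_region_pattern(self)


def _check_cells(cells: pd.DataFrame) -> None:
    required = {"cell_id", "code_bits"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cells table missing columns: {sorted(missing)}")
    dup = cells["cell_id"][cells["cell_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate cell_id values: {sorted(dup.unique().tolist())[:5]}")
    blank = cells.loc[cells["code_bits"].map(lambda s: set(str(s)) == {"0"}), "cell_id"]
    if len(blank):
        raise ValueError(
            f"all-false color code on cell(s) {sorted(blank.tolist())[:5]}; "
            "unlabelled cells must be excluded before clone assignment"
        )


def assign_clones(
    cells: pd.DataFrame, min_clone_size: int = 3
) -> tuple[list[Clone], pd.DataFrame]:
    """Partition labelled cells into clones by exact color-code equality.

    Parameters
    ----------
    cells : table with columns cell_id, code_bits (12-char 0/1 string) and
        optionally region and section.
    min_clone_size : groups smaller than this are returned as unassigned
        rather than silently dropped. Default 3, the smallest clone size
        retained in the source study; configurable down to 1.

    Returns
    -------
    (clones, unassigned) : clones sorted by descending size then code string;
    unassigned is the sub-table of cells in groups below ``min_clone_size``.
    """
    if min_clone_size < 1:
        raise ValueError("min_clone_size must be >= 1")
    _check_cells(cells)
    clones: list[Clone] = []
    unassigned_idx: list = []
    groups = cells.groupby("code_bits", sort=True)
    for code_str, grp in groups:
        if len(grp) < min_clone_size:
            unassigned_idx.extend(grp.index.tolist())
            continue
        clones.append(
            Clone(
                clone_id="",  # assigned after sorting
                code=ColorCode.from_string(str(code_str)),
                member_cell_ids=grp["cell_id"].astype(str).tolist(),
                member_regions=(
                    grp["region"].astype(str).tolist() if "region" in grp else []
                ),
                member_sections=(
                    grp["section"].astype(int).tolist() if "section" in grp else []
                ),
            )
        )
    clones.sort(key=lambda c: (-c.size, c.code.to_string()))
    for k, c in enumerate(clones):
        c.clone_id = f"clone_{k + 1:04d}"
    unassigned = cells.loc[unassigned_idx].copy()
    return clones, unassigned


def classify_region_pattern(clone: Clone) -> frozenset[str]:
    """Set of anatomical regions occupied by a clone's members."""
    if not clone.member_regions:
        raise ValueError(f"clone {clone.clone_id} has no member region labels")
    unknown = set(clone.member_regions) - set(REGIONS)
    if unknown:
        raise ValueError(f"unknown region label(s) {sorted(unknown)} in clone {clone.clone_id}")
    return frozenset(clone.member_regions)


def pattern_label(pattern: frozenset[str]) -> str:
    """Canonical label: members joined by '+' in REGIONS order."""
    return "+".join(r for r in REGIONS if r in pattern)


def pattern_frequency_table(clones: list[Clone]) -> pd.DataFrame:
    """Relative frequency of each dispersion pattern over a cohort.

    Frequencies are counts divided by the total clone number; rows sorted by
    descending frequency with lexicographic tie-break on the pattern label.
    """
    if not clones:
        raise ValueError("pattern_frequency_table requires at least one clone")
    counts: dict[str, int] = {}
    for c in clones:
        lab = pattern_label(classify_region_pattern(c))
        counts[lab] = counts.get(lab, 0) + 1
    total = len(clones)
    rows = [
        {"pattern": lab, "count": n, "frequency": n / total} for lab, n in counts.items()
    ]
    rows.sort(key=lambda r: (-r["frequency"], r["pattern"]))
    return pd.DataFrame(rows, columns=["pattern", "count", "frequency"])


def rostrocaudal_extent(clone: Clone, section_thickness: float = 50.0) -> float:
    """Clone span along the anterior-posterior axis in µm.

    Convention: (max section - min section) x thickness, so a single-section
    clone has extent 0.
    """
    if not clone.member_sections:
        raise ValueError(f"clone {clone.clone_id} has no member section indices")
    secs = clone.member_sections
    return float((max(secs) - min(secs)) * section_thickness)


def clone_summary_table(clones: list[Clone], section_thickness: float = 50.0) -> pd.DataFrame:
    """Per-clone descriptors: size, pattern, rostro-caudal extent."""
    rows = []
    for c in clones:
        rows.append(
            {
                "clone_id": c.clone_id,
                "code_bits": c.code.to_string(),
                "size": c.size,
                "pattern": pattern_label(classify_region_pattern(c)) if c.member_regions else "",
                "rc_extent_um": (
                    rostrocaudal_extent(c, section_thickness) if c.member_sections else np.nan
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=["clone_id", "code_bits", "size", "pattern", "rc_extent_um"]
    )
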