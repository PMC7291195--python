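"""Synthetic cohorts of clonally labelled glia around inflammatory lesions.

Generates per-cell records (position, serial 50 µm coronal section, region
label, 12-component color code), per-section lesion-core polygons, and
skeleton reconstructions in two morphological regimes — thin-branched
"type I"-like versus hypertrophic, thick, highly branched "type II"-like —
together with the ground truth needed to score every downstream stage.

Study conditions emulated by the defaults: clone sizes right-skewed on
[3, 80] with mean ≈ 17 cells; dispersion patterns over the five regions
{St, CC, L-Cx, U-Cx, Pia} dominated by lower-cortex clones (58%), with
corpus-callosum-only (8%) and CC+L-Cx (13%) next and no pia-only clones;
60% of clones seeded with at least one cell within 200 µm of a lesion core;
cells near the lesion biased towards the hypertrophic type.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from shapely.geometry import Point

from .clones import N_COMPONENTS, REGIONS, ColorCode
from .lesion import DEFAULT_RING_OFFSETS, INNER_THRESHOLD_UM, LesionGeometry
from .raster import rasterize_skeleton  # re-exported: part of this module's surface
from .skeleton import SOMA_TYPE, CellSkeleton

__all__ = [
    "CloneSizeDistribution",
    "LesionSpec",
    "CohortConfig",
    "SkeletonConfig",
    "Cohort",
    "generate_cohort",
    "generate_skeleton",
    "rasterize_skeleton",
]

CODE_SPACE = 2**N_COMPONENTS

#: Default dispersion-pattern weights over region subsets. The three pinned
#: frequencies (L-Cx 58%, CC 8%, CC+L-Cx 13%) are the dominant observed
#: patterns; the remainder is spread over seven further plausible patterns
#: (ten in all, none pia-only).
DEFAULT_PATTERN_WEIGHTS: dict[tuple[str, ...], float] = {
    ("L-Cx",): 0.58,
    ("CC", "L-Cx"): 0.13,
    ("CC",): 0.08,
    ("St",): 0.05,
    ("U-Cx",): 0.04,
    ("St", "CC"): 0.03,
    ("L-Cx", "U-Cx"): 0.03,
    ("St", "CC", "L-Cx"): 0.02,
    ("U-Cx", "Pia"): 0.02,
    ("St", "CC", "L-Cx", "U-Cx", "Pia"): 0.02,
}


@dataclass
class CloneSizeDistribution:
    """Discretized log-normal over integer clone sizes, truncated to a range.

    The log-scale sigma is fixed and mu is calibrated numerically so the
    truncated-discretized mean matches ``mean`` (default 17 cells on
    [3, 80]).
    """

    min_size: int = 3
    max_size: int = 80
    mean: float = 17.0
    sigma: float = 0.75

    def __post_init__(self):
        if self.min_size < 1:
            raise ValueError("min clone size must be >= 1")
        if self.max_size < self.min_size:
            raise ValueError("max_size < min_size")
        if not self.min_size <= self.mean <= self.max_size:
            raise ValueError("mean outside [min_size, max_size]")
        self._support = np.arange(self.min_size, self.max_size + 1)
        self._pmf = self._calibrated_pmf()

    def _pmf_for_mu(self, mu: float) -> np.ndarray:
        dist = stats.lognorm(s=self.sigma, scale=math.exp(mu))
        p = dist.cdf(self._support + 0.5) - dist.cdf(self._support - 0.5)
        return p / p.sum()

    def _calibrated_pmf(self) -> np.ndarray:
        def gap(mu):
            return float(self._pmf_for_mu(mu) @ self._support) - self.mean

        lo, hi = math.log(max(self.min_size, 1)) - 2.0, math.log(self.max_size) + 1.0
        mu = optimize.brentq(gap, lo, hi)
        return self._pmf_for_mu(mu)

    @property
    def expected_mean(self) -> float:
        return float(self._pmf @ self._support)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.choice(self._support, size=n, p=self._pmf)


@dataclass
class LesionSpec:
    """One lesion: a circular core of ``radius`` µm centred at ``center``.

    ``sections=None`` places the lesion on every section.
    """

    center: tuple[float, float] = (0.0, 0.0)
    radius: float = 60.0
    sections: tuple[int, ...] | None = None


@dataclass
class CohortConfig:
    """Conditions for one synthetic cohort; all randomness flows from ``seed``."""

    n_clones: int = 48
    clone_size_distribution: CloneSizeDistribution = field(default_factory=CloneSizeDistribution)
    clone_sizes: tuple[int, ...] | None = None  # explicit override of sampled sizes
    region_pattern_weights: dict[tuple[str, ...], float] = field(
        default_factory=lambda: dict(DEFAULT_PATTERN_WEIGHTS)
    )
    lesions: tuple[LesionSpec, ...] = (LesionSpec(),)
    inner_fraction_target: float = 0.6
    #: 0..1; how strongly larger clone sizes are steered to inner clones
    size_inner_coupling: float = 0.4
    section_thickness: float = 50.0
    n_sections: int = 10
    #: per-additional-cell chance of occupying one more section (drives the
    #: positive size/rostro-caudal-extent association)
    section_spread: float = 0.12
    max_rc_extent_um: float | None = None
    clone_xy_sd: float = 80.0
    #: probability that a clone reuses an already-assigned code (label collision)
    collision_rate: float = 0.0
    #: probability a cell near/far from the core is of the hypertrophic type
    p_typeII_near: float = 0.8
    p_typeII_far: float = 0.1
    typeII_distance_cutoff: float = 150.0
    seed: int = 0

    def __post_init__(self):
        if self.n_clones < 1:
            raise ValueError("n_clones must be positive")
        w = np.array(list(self.region_pattern_weights.values()), dtype=float)
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"region pattern weights sum to {w.sum()!r}, expected 1")
        if (w < 0).any():
            raise ValueError("negative pattern weight")
        for pat in self.region_pattern_weights:
            unknown = set(pat) - set(REGIONS)
            if unknown:
                raise ValueError(f"unknown region(s) {sorted(unknown)} in pattern {pat}")
        if self.section_thickness <= 0:
            raise ValueError("section_thickness must be positive")
        if not 0.0 <= self.inner_fraction_target <= 1.0:
            raise ValueError("inner_fraction_target must be in [0, 1]")
        if self.collision_rate == 0.0 and self.n_clones > CODE_SPACE:
            raise ValueError(
                f"{self.n_clones} clones requested but only {CODE_SPACE} distinct "
                "codes exist; enable collisions to exceed the code space"
            )
        if self.clone_sizes is not None and len(self.clone_sizes) != self.n_clones:
            raise ValueError("clone_sizes length must equal n_clones")


@dataclass
class Cohort:
    """A generated cohort plus its ground truth."""

    cells: pd.DataFrame
    lesions: list[LesionGeometry]
    truth: pd.DataFrame  # one row per clone
    config: CohortConfig


def _assign_codes(rng: np.random.Generator, n: int, collision_rate: float) -> list[int]:
    """Draw clone codes. Fresh codes are sampled without replacement from the
    4096-code space with the all-zero code ordered last, so it is only used
    when every other code is exhausted."""
    pool = rng.permutation(np.arange(1, CODE_SPACE)).tolist() + [0]
    codes: list[int] = []
    for _ in range(n):
        if codes and collision_rate > 0 and rng.random() < collision_rate:
            codes.append(int(codes[int(rng.integers(len(codes)))]))
        elif pool:
            codes.append(int(pool.pop(0)))
        else:  # collisions enabled and space exhausted
            codes.append(int(codes[int(rng.integers(len(codes)))]))
    return codes


def _lesion_geometries(lesions, n_sections: int) -> list[LesionGeometry]:
    geoms = []
    for spec in lesions:
        secs = spec.sections if spec.sections is not None else tuple(range(n_sections))
        poly = Point(*spec.center).buffer(spec.radius, quad_segs=64)
        for s in secs:
            geoms.append(LesionGeometry(section=int(s), core=poly))
    return geoms


def _min_core_distance(x, y, cores) -> float:
    p = Point(float(x), float(y))
    return min(float(c.distance(p)) for c in cores)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Simulate one cohort of clonally labelled cells around lesion cores."""
    rng = np.random.default_rng(config.seed)
    n = config.n_clones

    codes = _assign_codes(rng, n, config.collision_rate)
    if config.clone_sizes is not None:
        sizes = np.asarray(config.clone_sizes, dtype=int)
    else:
        sizes = config.clone_size_distribution.sample(rng, n)
    inner = rng.random(n) < config.inner_fraction_target

    # steer larger sizes preferentially to inner clones without changing the
    # marginal size distribution: rank-couple sorted sizes to a noisy score
    c = float(np.clip(config.size_inner_coupling, 0.0, 1.0))
    score = c * inner.astype(float) + (1.0 - c) * rng.random(n)
    order = np.argsort(-score, kind="stable")
    sorted_sizes = np.sort(sizes)[::-1]
    assigned = np.empty(n, dtype=int)
    assigned[order] = sorted_sizes
    sizes = assigned

    patterns = list(config.region_pattern_weights.keys())
    pweights = np.array(list(config.region_pattern_weights.values()), dtype=float)
    pattern_idx = rng.choice(len(patterns), size=n, p=pweights)

    core_polys = [Point(*l.center).buffer(l.radius, quad_segs=64) for l in config.lesions]
    centers = np.array([l.center for l in config.lesions], dtype=float)
    radii = np.array([l.radius for l in config.lesions], dtype=float)

    max_span_sections = config.n_sections - 1
    if config.max_rc_extent_um is not None:
        max_span_sections = min(
            max_span_sections, int(config.max_rc_extent_um // config.section_thickness)
        )

    rows = []
    truth_rows = []
    cell_counter = 0
    for k in range(n):
        size = int(sizes[k])
        lesion_i = int(rng.integers(len(config.lesions)))
        cx, cy = centers[lesion_i]
        R = radii[lesion_i]
        theta = rng.uniform(0, 2 * np.pi)
        if inner[k]:
            # anchor the clone so at least one cell is within the inner band
            if rng.random() < 0.25:
                d0 = 0.0  # inside the core
                rr = R * math.sqrt(rng.uniform(0, 1))
            else:
                d0 = rng.uniform(0.0, 0.9 * INNER_THRESHOLD_UM)
                rr = R + d0
            anchor = np.array([cx + rr * math.cos(theta), cy + rr * math.sin(theta)])
        else:
            rr = R + INNER_THRESHOLD_UM + rng.uniform(250.0, 700.0)
            anchor = np.array([cx + rr * math.cos(theta), cy + rr * math.sin(theta)])
        xy = anchor[None, :] + rng.normal(0.0, config.clone_xy_sd, size=(size, 2))
        xy[0] = anchor  # the seeded cell keeps its intended position
        if not inner[k]:
            # keep every member strictly beyond the inner band (50 µm margin)
            for j in range(size):
                d = _min_core_distance(xy[j, 0], xy[j, 1], core_polys)
                if d <= INNER_THRESHOLD_UM + 50.0:
                    li = int(np.argmin(np.hypot(xy[j, 0] - centers[:, 0], xy[j, 1] - centers[:, 1])))
                    v = xy[j] - centers[li]
                    nv = np.linalg.norm(v)
                    u = v / nv if nv > 1e-9 else np.array([1.0, 0.0])
                    xy[j] = centers[li] + u * (radii[li] + INNER_THRESHOLD_UM + 60.0)

        # serial-section placement: occupied span grows with clone size
        span = 1 + int(rng.binomial(max(size - 1, 0), config.section_spread))
        span = int(min(span, max_span_sections + 1, config.n_sections))
        s0 = int(rng.integers(0, config.n_sections - span + 1))
        secs = s0 + rng.integers(0, span, size=size)
        if span > 1 and size >= 2:
            secs[0], secs[1] = s0, s0 + span - 1  # realize the full span

        pat = patterns[pattern_idx[k]]
        pat_use = pat[: min(len(pat), size)]
        regions = list(pat_use) + [
            pat_use[int(rng.integers(len(pat_use)))] for _ in range(size - len(pat_use))
        ]
        regions = [regions[i] for i in rng.permutation(size)]

        dists = np.array([_min_core_distance(x, y, core_polys) for x, y in xy])
        p2 = np.where(
            dists <= config.typeII_distance_cutoff, config.p_typeII_near, config.p_typeII_far
        )
        ctype = np.where(rng.random(size) < p2, "typeII", "typeI")

        clone_id = f"t{k + 1:04d}"
        code_str = ColorCode.from_int(codes[k]).to_string()
        for j in range(size):
            rows.append(
                {
                    "cell_id": f"c{cell_counter:05d}",
                    "clone_id_truth": clone_id,
                    "x_um": float(xy[j, 0]),
                    "y_um": float(xy[j, 1]),
                    "z_um": float(secs[j]) * config.section_thickness,
                    "section": int(secs[j]),
                    "region": regions[j],
                    "code_bits": code_str,
                    "cell_type_truth": str(ctype[j]),
                }
            )
            cell_counter += 1
        truth_rows.append(
            {
                "clone_id": clone_id,
                "code_bits": code_str,
                "size": size,
                "pattern": "+".join(r for r in REGIONS if r in set(regions)),
                "inner": bool(inner[k]),
                "min_core_distance_um": float(dists.min()),
            }
        )

    cells = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return Cohort(
        cells=cells,
        lesions=_lesion_geometries(config.lesions, config.n_sections),
        truth=truth,
        config=config,
    )


# ----------------------------------------------------------------------
# skeletons
# ----------------------------------------------------------------------
@dataclass
class SkeletonConfig:
    """Growth parameters for one synthetic skeleton.

    The per-type defaults (``for_type``) make the two reactive regimes
    separable: the hypertrophic type II regime has thicker (0.8 vs 0.35 µm
    mean radius), more numerous and more frequently branching processes than
    type I, with sham below both. These are plain config values, not
    constants.
    """

    cell_type_label: str = "sham"
    n_primary_branches: tuple[int, int] = (3, 5)
    branch_radius_mean: float = 0.25
    branch_radius_sd: float = 0.05
    branching_probability_per_um: float = 0.010
    max_radial_extent: float = 40.0
    soma_radius: float = 5.0
    step_um: float = 2.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self):
        if self.branch_radius_mean <= 0 or self.soma_radius <= 0:
            raise ValueError("radii must be positive")
        if self.max_radial_extent <= 0:
            raise ValueError("max_radial_extent must be positive")
        if self.step_um <= 0:
            raise ValueError("step_um must be positive")
        lo, hi = self.n_primary_branches
        if lo < 1 or hi < lo:
            raise ValueError("invalid n_primary_branches range")

    _TYPE_DEFAULTS = {
        "sham": dict(
            n_primary_branches=(3, 5),
            branch_radius_mean=0.25,
            branching_probability_per_um=0.010,
            max_radial_extent=40.0,
        ),
        "typeI": dict(
            n_primary_branches=(4, 6),
            branch_radius_mean=0.35,
            branching_probability_per_um=0.016,
            max_radial_extent=50.0,
        ),
        "typeII": dict(
            n_primary_branches=(6, 9),
            branch_radius_mean=0.8,
            branching_probability_per_um=0.020,
            max_radial_extent=55.0,
        ),
    }

    @classmethod
    def for_type(cls, label: str, seed: int = 0, **overrides) -> "SkeletonConfig":
        if label not in cls._TYPE_DEFAULTS:
            raise ValueError(f"unknown cell type label {label!r}")
        kw = dict(cls._TYPE_DEFAULTS[label])
        kw.update(overrides)
        return cls(cell_type_label=label, seed=seed, **kw)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 1e-12 else np.array([1.0, 0.0, 0.0])


def generate_skeleton(config: SkeletonConfig, max_nodes: int = 2500) -> CellSkeleton:
    """Grow one connected rooted tree outward from a soma sphere.

    Tips advance in ~``step_um`` segments with angular jitter and a soft
    outward bias; at each step a tip may spawn a side branch with probability
    ``branching_probability_per_um * step_um``; growth stops at
    ``max_radial_extent`` from the soma.
    """
    rng = np.random.default_rng(config.seed)
    origin = np.asarray(config.origin, dtype=float)

    ids = [1]
    types = [SOMA_TYPE]
    xyz = [origin.copy()]
    radius = [config.soma_radius]
    parent = [-1]

    def add_node(p_id, pos, r):
        nid = len(ids) + 1
        ids.append(nid)
        types.append(0)
        xyz.append(pos)
        radius.append(r)
        parent.append(p_id)
        return nid

    def draw_radius():
        return max(0.08, float(rng.normal(config.branch_radius_mean, config.branch_radius_sd)))

    lo, hi = config.n_primary_branches
    n_primary = int(rng.integers(lo, hi + 1))
    tips = []  # (node_id, position, direction)
    for _ in range(n_primary):
        d = _unit(rng.normal(size=3))
        pos = origin + d * config.soma_radius
        nid = add_node(1, pos, draw_radius())
        tips.append((nid, pos, d))

    p_branch = config.branching_probability_per_um * config.step_um
    while tips and len(ids) < max_nodes:
        nid, pos, d = tips.pop(0)
        radial = np.linalg.norm(pos - origin)
        if radial >= config.max_radial_extent:
            continue
        new_d = _unit(d + 0.35 * rng.normal(size=3) + 0.15 * _unit(pos - origin))
        new_pos = pos + new_d * config.step_um
        new_id = add_node(nid, new_pos, draw_radius())
        tips.append((new_id, new_pos, new_d))
        if rng.random() < p_branch:
            side = _unit(new_d + 0.9 * rng.normal(size=3))
            side_pos = pos + side * config.step_um
            side_id = add_node(nid, side_pos, draw_radius())
            tips.append((side_id, side_pos, side))

    return CellSkeleton(
        ids=np.array(ids),
        types=np.array(types),
        xyz=np.array(xyz),
        radius=np.array(radius),
        parent=np.array(parent),
        cell_id=config.cell_type_label,
    )
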