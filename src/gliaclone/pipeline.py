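"""End-to-end pipeline: clones -> lesion distances -> morphometry -> typing.

Composes the analysis stages over either a simulated cohort or files on
disk, writing one CSV per result table plus a JSON run manifest that echoes
the full configuration and seed (sufficient to reproduce every output
byte-identically).
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, classify, clones as clones_mod, io as gio, lesion as lesion_mod
from . import morphometry as morpho_mod
from .synthetic import Cohort, CohortConfig, SkeletonConfig, generate_cohort, generate_skeleton

log = logging.getLogger("gliaclone")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end run.

    Leave the input paths unset to simulate a cohort with ``cohort``;
    otherwise supply cells CSV, lesion GeoJSON and a directory of SWC files
    named ``<cell_id>.swc``.
    """

    out_dir: str = "gliaclone_out"
    cells_path: str | None = None
    lesions_path: str | None = None
    swc_dir: str | None = None

    cohort: CohortConfig = field(default_factory=lambda: CohortConfig(n_clones=10))
    seed: int = 0

    ring_offsets: tuple[float, ...] = lesion_mod.DEFAULT_RING_OFFSETS
    inner_threshold_um: float = lesion_mod.INNER_THRESHOLD_UM
    min_clone_size: int = 3
    section_thickness: float = 50.0
    sholl_interval_um: float = morpho_mod.DEFAULT_SHOLL_INTERVAL
    radius_threshold_um: float = morpho_mod.DEFAULT_RADIUS_THRESHOLD
    type_threshold_um: float = classify.DEFAULT_TYPE_THRESHOLD_UM
    pixel_size_um: float = morpho_mod.DEFAULT_PIXEL_SIZE
    voxel_size_um: float = morpho_mod.DEFAULT_VOXEL_SIZE

    #: simulated sham cells for the three-group comparison
    n_sham: int = 6
    #: cap on skeletonized/measured cells (whole clones kept together)
    max_morphometry_cells: int = 60

    def validate(self) -> None:
        if any(o <= 0 for o in self.ring_offsets) or any(
            b <= a for a, b in zip(self.ring_offsets, self.ring_offsets[1:])
        ):
            raise ValueError("ring offsets must be positive and strictly increasing")
        for name in (
            "inner_threshold_um",
            "section_thickness",
            "sholl_interval_um",
            "type_threshold_um",
            "pixel_size_um",
            "voxel_size_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortConfig(**d["cohort"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                log.info("[%s] running", name)
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as e:
                raise PipelineError(name, e) from e

        return wrapped

    return deco


@_stage("input")
def _load_inputs(cfg: PipelineConfig):
    if cfg.cells_path is None:
        cohort_cfg = dataclasses.replace(cfg.cohort, seed=cfg.seed)
        cohort = generate_cohort(cohort_cfg)
        cells = cohort.cells
        lesions = cohort.lesions
        skeletons = _simulate_skeletons(cells, cfg)
    else:
        cells = gio.read_cells_csv(cfg.cells_path)
        if cfg.lesions_path is None:
            raise FileNotFoundError("lesion GeoJSON path not set")
        lesions = gio.read_lesions_geojson(cfg.lesions_path)
        skeletons = {}
        if cfg.swc_dir:
            for p in sorted(Path(cfg.swc_dir).glob("*.swc")):
                skeletons[p.stem] = gio.read_swc(p)
        cohort = None
    sham = _sham_skeletons(cfg)
    return cells, lesions, skeletons, sham, cohort


def _simulate_skeletons(cells: pd.DataFrame, cfg: PipelineConfig) -> dict:
    """Skeletonize whole clones (in truth order) up to the morphometry cap."""
    chosen: list[str] = []
    for _, grp in cells.groupby("clone_id_truth", sort=True):
        if len(chosen) + len(grp) > cfg.max_morphometry_cells and chosen:
            break
        chosen.extend(grp["cell_id"].tolist())
        if len(chosen) >= cfg.max_morphometry_cells:
            break
    types = dict(zip(cells["cell_id"], cells["cell_type_truth"]))
    seeds = np.random.SeedSequence(cfg.seed).generate_state(len(chosen) + 1)[1:]
    return {
        cid: generate_skeleton(
            SkeletonConfig.for_type(types[cid], seed=int(s) % 2**31)
        )
        for cid, s in zip(chosen, seeds)
    }


def _sham_skeletons(cfg: PipelineConfig) -> dict:
    seeds = np.random.SeedSequence((cfg.seed, 1)).generate_state(cfg.n_sham)
    return {
        f"sham_{k:03d}": generate_skeleton(SkeletonConfig.for_type("sham", seed=int(s) % 2**31))
        for k, s in enumerate(seeds)
    }


@_stage("clones")
def _run_clones(cells, cfg: PipelineConfig):
    cl, unassigned = clones_mod.assign_clones(cells, min_clone_size=cfg.min_clone_size)
    summary = clones_mod.clone_summary_table(cl, section_thickness=cfg.section_thickness)
    freq = clones_mod.pattern_frequency_table(cl)
    return cl, unassigned, summary, freq


@_stage("lesion")
def _run_lesion(cells, cl, lesions, cfg: PipelineConfig):
    if not lesions:
        raise FileNotFoundError("no lesion geometry available")
    dist = lesion_mod.distance_records(cells, lesions, offsets=cfg.ring_offsets)
    per_clone, stats_out = lesion_mod.radial_summary(
        cl, dist, offsets=cfg.ring_offsets, threshold_um=cfg.inner_threshold_um
    )
    return dist, per_clone, stats_out


@_stage("morphometry")
def _run_morphometry(skeletons: dict, sham: dict, cfg: PipelineConfig):
    results = []
    profiles = []
    for cid, sk in list(skeletons.items()) + list(sham.items()):
        r = morpho_mod.measure_cell(
            sk,
            cell_id=cid,
            pixel_size=cfg.pixel_size_um,
            voxel_size=cfg.voxel_size_um,
            sholl_interval=cfg.sholl_interval_um,
            radius_threshold=cfg.radius_threshold_um,
        )
        results.append(r)
        profiles.append(r.sholl.to_dataframe(cell_id=cid))
    table = morpho_mod.morphometry_table(results)
    sholl = (
        pd.concat(profiles, ignore_index=True)
        if profiles
        else pd.DataFrame(columns=["cell_id", "radius_um", "n_intersections"])
    )
    return table, sholl


@_stage("classify")
def _run_classify(cells, cl, skeletons, sham, morpho_table, dist, cfg: PipelineConfig):
    calls = {
        cid: classify.classify_cell(sk, threshold=cfg.type_threshold_um, cell_id=cid)
        for cid, sk in skeletons.items()
    }
    cell_types = pd.DataFrame(
        [
            {
                "cell_id": c.cell_id,
                "primary_branch_thickness_um": c.primary_branch_thickness,
                "call": c.call,
                "threshold_um": c.threshold_used,
            }
            for c in calls.values()
        ]
    )
    clone_calls = []
    for c in cl:
        member_calls = [calls[cid] for cid in c.member_cell_ids if cid in calls]
        if member_calls:
            clone_calls.append(classify.classify_clone(c.clone_id, member_calls))
    clone_types = pd.DataFrame(
        [{"clone_id": cc.clone_id, "composition": cc.composition} for cc in clone_calls]
    )
    groups = {cid: call.call for cid, call in calls.items()}
    groups.update({cid: "sham" for cid in sham})
    present = set(pd.Series(groups).unique())
    if {"sham", "typeI", "typeII"} <= present:
        stats_table = classify.compare_groups(morpho_table, groups)
    else:
        log.warning("group comparison skipped: need sham, typeI and typeII, have %s", present)
        stats_table = pd.DataFrame()
    c2c = pd.DataFrame(
        [
            {"cell_id": cid, "clone_id": c.clone_id}
            for c in cl
            for cid in c.member_cell_ids
            if cid in calls
        ]
    )
    if len(c2c):
        tbd = classify.type_by_distance_summary(
            clone_calls, c2c, dist, ring_order=lesion_mod.ring_labels(cfg.ring_offsets)
        )
    else:
        tbd = pd.DataFrame(columns=["ring", "composition", "n_cells"])
    return cell_types, clone_types, stats_table, tbd


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write all outputs under ``cfg.out_dir``.

    Returns the manifest dict. Any stage failure raises PipelineError
    naming the stage.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cells, lesions, skeletons, sham, cohort = _load_inputs(cfg)
    cl, unassigned, clone_summary, freq = _run_clones(cells, cfg)
    dist, per_clone_rings, radial_stats = _run_lesion(cells, cl, lesions, cfg)
    morpho_table, sholl = _run_morphometry(skeletons, sham, cfg)
    cell_types, clone_types, stats_table, tbd = _run_classify(
        cells, cl, skeletons, sham, morpho_table, dist, cfg
    )

    tables = {
        "cells.csv": cells,
        "clones.csv": clone_summary,
        "pattern_frequency.csv": freq,
        "distances.csv": dist,
        "radial_summary.csv": per_clone_rings,
        "morphometry.csv": morpho_table,
        "sholl_profiles.csv": sholl,
        "cell_types.csv": cell_types,
        "clone_types.csv": clone_types,
        "group_stats.csv": stats_table,
        "type_by_distance.csv": tbd,
    }
    for name, df in tables.items():
        df.to_csv(out / name, index=False)
    gio.write_lesions_geojson(lesions, out / "lesions.geojson")

    n_assigned = int(sum(c.size for c in cl))
    manifest = {
        "package": "gliaclone",
        "version": __version__,
        "seed": cfg.seed,
        "config": _config_dict(cfg),
        "row_counts": {k: int(len(v)) for k, v in tables.items()},
        "cells_total": int(len(cells)),
        "cells_assigned": n_assigned,
        "cells_unassigned": int(len(unassigned)),
        "radial_stats": radial_stats,
    }
    assert manifest["cells_total"] == n_assigned + len(unassigned)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)
    return manifest


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    weights = d["cohort"].get("region_pattern_weights")
    if weights:
        d["cohort"]["region_pattern_weights"] = {
            "+".join(k): v for k, v in weights.items()
        }
    return d


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
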