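"""Reactive-phenotype typing and group statistics.

Cells are split into type I (thin-branched, less reactive) and type II
(hypertrophic, thick-branched) by a threshold on primary-branch thickness;
clones roll up to type I / type II / mixed composition. Group comparisons
against sham follow one-way ANOVA with Dunnett's post hoc test (two-sided,
multivariate-t critical values), starred at 0.05 / 0.01 / 0.001.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .morphometry import PARAMETERS, primary_branch_paths
from .skeleton import CellSkeleton

log = logging.getLogger("gliaclone")

DEFAULT_TYPE_THRESHOLD_UM = 0.5


@dataclass
class CellTypeCall:
    cell_id: str
    primary_branch_thickness: float  # µm
    call: str  # "typeI" | "typeII"
    threshold_used: float


@dataclass
class CloneTypeCall:
    clone_id: str
    composition: str  # "typeI" | "typeII" | "mixed"


def primary_branch_thickness(skeleton: CellSkeleton, method: str = "mean") -> float:
    """Thickness (µm) summarized over the primary branches (children of soma).

    ``method="mean"``: mean node radius over all primary-branch nodes,
    averaged across branches; ``method="max"``: thickest primary branch.
    """
    paths = primary_branch_paths(skeleton)
    if not paths:
        raise ValueError("skeleton has no primary branches")
    per_branch = [float(np.mean(skeleton.radius[p])) for p in paths]
    if method == "mean":
        return float(np.mean(per_branch))
    if method == "max":
        return float(np.max(per_branch))
    raise ValueError(f"unknown thickness method {method!r}")


def classify_cell(
    skeleton: CellSkeleton,
    threshold: float = DEFAULT_TYPE_THRESHOLD_UM,
    cell_id: str | None = None,
    method: str = "mean",
) -> CellTypeCall:
    """Type II iff primary-branch thickness >= ``threshold`` (µm)."""
    t = primary_branch_thickness(skeleton, method=method)
    return CellTypeCall(
        cell_id=cell_id or (skeleton.cell_id or ""),
        primary_branch_thickness=t,
        call="typeII" if t >= threshold else "typeI",
        threshold_used=threshold,
    )


def classify_clone(clone_id: str, member_calls: list[CellTypeCall]) -> CloneTypeCall:
    """Homogeneous clones keep their members' type; otherwise "mixed"."""
    if not member_calls:
        raise ValueError(f"clone {clone_id} has no member type calls")
    kinds = {c.call for c in member_calls}
    comp = kinds.pop() if len(kinds) == 1 else "mixed"
    return CloneTypeCall(clone_id=clone_id, composition=comp)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(
    morpho: pd.DataFrame,
    groups: pd.Series | dict,
    control: str = "sham",
    parameters=PARAMETERS,
) -> pd.DataFrame:
    """One-way ANOVA + Dunnett post hoc against the control group, per parameter.

    Parameters
    ----------
    morpho : morphometry table with a cell_id column and parameter columns.
    groups : cell_id -> group label ("sham" / "typeI" / "typeII").

    Returns one row per parameter: F and p from the ANOVA, Dunnett-adjusted
    two-sided p for each non-control group versus control, and significance
    stars. Parameters where any group has n < 2 are skipped with a logged
    reason.
    """
    gmap = groups if isinstance(groups, dict) else dict(groups)
    df = morpho.copy()
    df["group"] = df["cell_id"].map(gmap)
    if df["group"].isna().any():
        missing = df.loc[df["group"].isna(), "cell_id"].tolist()
        raise ValueError(f"no group label for cell(s): {missing[:5]}")
    labels = sorted(df["group"].unique())
    if control not in labels:
        raise ValueError(f"control group {control!r} absent from data")
    treat_labels = [g for g in labels if g != control]
    rows = []
    for param in parameters:
        samples = {g: df.loc[df["group"] == g, param].dropna().to_numpy(float) for g in labels}
        small = [g for g in labels if len(samples[g]) < 2]
        if small:
            log.warning("parameter %s skipped: group(s) %s have n < 2", param, small)
            continue
        F, p_anova = stats.f_oneway(*[samples[g] for g in labels])
        # fixed rng: the multivariate-t integration is quasi-random and the
        # adjusted p-values must reproduce byte-identically across runs
        res = stats.dunnett(
            *[samples[g] for g in treat_labels], control=samples[control], rng=0
        )
        row = {
            "parameter": param,
            "F": float(F),
            "p_anova": float(p_anova),
        }
        for g, padj in zip(treat_labels, res.pvalue):
            row[f"p_{g}_vs_{control}"] = float(padj)
            row[f"stars_{g}"] = significance_stars(float(padj))
        rows.append(row)
    return pd.DataFrame(rows)


def type_by_distance_summary(
    clone_calls: list[CloneTypeCall],
    cell_to_clone: pd.DataFrame,
    distances: pd.DataFrame,
    ring_order: list[str] | None = None,
) -> pd.DataFrame:
    """Cell counts per lesion ring and clone composition (radial-plot data).

    Parameters
    ----------
    clone_calls : clone-level composition calls.
    cell_to_clone : table with columns cell_id, clone_id.
    distances : per-cell distance records with columns cell_id, ring.
    """
    comp = {c.clone_id: c.composition for c in clone_calls}
    merged = cell_to_clone.merge(distances[["cell_id", "ring"]], on="cell_id", how="left")
    bad = merged.loc[merged["ring"].isna(), "cell_id"].tolist()
    if bad:
        raise ValueError(f"cells without distance records: {bad[:10]}")
    merged = merged[merged["clone_id"].isin(comp)]
    if merged.empty:
        return pd.DataFrame(columns=["ring", "composition", "n_cells"])
    merged["composition"] = merged["clone_id"].map(comp)
    out = (
        merged.groupby(["ring", "composition"], sort=True)
        .size()
        .reset_index(name="n_cells")
    )
    if ring_order:
        out["ring"] = pd.Categorical(out["ring"], categories=ring_order, ordered=True)
        out = out.sort_values(["ring", "composition"]).reset_index(drop=True)
        out["ring"] = out["ring"].astype(str)
    return out
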