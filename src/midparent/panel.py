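"""Trait heterosis and expression-heterosis / trait-heterosis correlation.

Across a panel of hybrids, each feature's expression heterosis (hybrid mean /
midparent mean) is correlated (Pearson) with plant-height heterosis (hybrid
height / midparent height).  Threshold sets, top-fraction selections,
hypergeometric set enrichment, per-group correlation density curves and the
levels-versus-height negative control support the downstream interpretation.
"""
from __future__ import annotations

import logging
import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import (
    AbundanceMatrix,
    AnnotationTable,
    CrossPanel,
    SampleDesign,
    TraitTable,
)
from .heterosis import adjust_fdr, classify_hybrid

logger = logging.getLogger(__name__)

DENSITY_GRID = np.linspace(-1.05, 1.05, 512)


def trait_heterosis(traits: TraitTable, panel: CrossPanel) -> pd.Series:
    """Per-hybrid trait heterosis h_j = hybrid height / midparent height."""
    heights = traits.heights
    values = {}
    for _, row in panel.table.iterrows():
        for genotype in (row["hybrid"], row["parent_female"], row["parent_male"]):
            if genotype not in heights.index:
                raise ValueError(f"genotype '{genotype}' missing from trait table")
        mp = (heights[row["parent_female"]] + heights[row["parent_male"]]) / 2.0
        values[row["hybrid"]] = heights[row["hybrid"]] / mp
    return pd.Series(values, name="trait_heterosis").loc[panel.hybrids]


def expression_heterosis_matrix(
    records_by_hybrid: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame],
    order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Feature x hybrid matrix of MP expression-heterosis ratios.

    Accepts a mapping hybrid -> records table or a sequence of records tables
    (hybrid label taken from their ``hybrid`` column).  Cells are missing where
    a feature lacks a defined ratio in a hybrid; rows are kept if any hybrid
    defines them.  Column order follows ``order`` when given.
    """
    if not isinstance(records_by_hybrid, Mapping):
        tables: dict[str, pd.DataFrame] = {}
        for table in records_by_hybrid:
            label = str(table["hybrid"].iloc[0])
            if label in tables:
                raise ValueError(f"duplicate hybrid label '{label}'")
            tables[label] = table
        records_by_hybrid = tables
    columns = {h: t["ratio_mp"] for h, t in records_by_hybrid.items()}
    eh = pd.DataFrame(columns)
    eh = eh.sort_index()
    if order is not None:
        eh = eh[list(order)]
    eh.index.name = "feature_id"
    eh.columns.name = "hybrid"
    return eh


def _masked_pearson(X: np.ndarray, y: np.ndarray, min_n: int):
    """Row-wise Pearson r between X's rows and y over non-missing pairs.

    Returns (r, n, p, reason) where reason is '' | 'few_pairs' | 'zero_variance'.
    """
    mask = np.isfinite(X) & np.isfinite(y)[None, :]
    n = mask.sum(axis=1).astype(float)
    Xz = np.where(mask, X, 0.0)
    Yz = np.where(mask, y[None, :], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = Xz.sum(axis=1) / n
        my = Yz.sum(axis=1) / n
        # centered two-pass sums for numerical stability
        dx = np.where(mask, X - mx[:, None], 0.0)
        dy = np.where(mask, y[None, :] - my[:, None], 0.0)
        sxy = (dx * dy).sum(axis=1)
        sxx = (dx**2).sum(axis=1)
        syy = (dy**2).sum(axis=1)
        r = sxy / np.sqrt(sxx * syy)
    r = np.clip(r, -1.0, 1.0)
    # numeric round-off can leave a tiny negative variance for constant rows
    zero_var = (sxx <= 0) | (syy <= 0)
    few = n < min_n
    reason = np.where(few, "few_pairs", np.where(zero_var, "zero_variance", ""))
    ok = ~(few | zero_var)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r) == 1.0, 0.0, p)
    r = np.where(ok, r, np.nan)
    p = np.where(ok, p, np.nan)
    return r, n.astype(int), p, reason


def protein_trait_correlation(
    eh_matrix: pd.DataFrame,
    trait_h: pd.Series,
    min_hybrids: int = 5,
    annotation: AnnotationTable | None = None,
) -> pd.DataFrame:
    """Per-feature Pearson correlation of expression heterosis with trait heterosis.

    Pairs with missing expression are dropped per feature; features with fewer
    than ``min_hybrids`` pairs, or zero variance in either vector, are omitted
    (their counts are logged).  p-values come from the t transform with n - 2
    degrees of freedom.
    """
    if min_hybrids < 3:
        raise ValueError("min_hybrids must be at least 3")
    h = trait_h.reindex(eh_matrix.columns)
    if h.isna().any():
        missing = h.index[h.isna()][0]
        raise ValueError(f"hybrid '{missing}' has no trait-heterosis value")
    r, n, p, reason = _masked_pearson(
        eh_matrix.to_numpy(dtype=float), h.to_numpy(dtype=float), min_hybrids
    )
    out = pd.DataFrame({"r": r, "n": n, "p": p}, index=eh_matrix.index)
    omitted = reason != ""
    if omitted.any():
        logger.info(
            "omitted %d feature(s): %d with < %d pairs, %d with zero variance",
            int(omitted.sum()),
            int((reason == "few_pairs").sum()),
            min_hybrids,
            int((reason == "zero_variance").sum()),
        )
    out = out[~omitted].copy()
    if annotation is not None:
        out["groups"] = annotation.groups_column(out.index)
    out.index.name = "feature_id"
    return out


def correlation_threshold_set(
    correlations: pd.DataFrame, cutoff: float, side: str = "upper"
) -> list[str]:
    """Features with r > cutoff (upper) or r < cutoff (lower), deterministically
    ordered by |r| strength (descending toward the cutoff side) then feature id."""
    if side == "upper":
        sel = correlations[correlations["r"] > cutoff]
    elif side == "lower":
        sel = correlations[correlations["r"] < cutoff]
    else:
        raise ValueError("side must be 'upper' or 'lower'")
    sel = sel.reset_index().sort_values(
        ["r", "feature_id"],
        ascending=[side == "lower", True],
        kind="mergesort",
    )
    return list(sel["feature_id"])


def top_fraction(correlations: pd.DataFrame, fraction: float) -> list[str]:
    """The ceil(fraction * n) features with largest r; ties broken by feature id."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    k = math.ceil(fraction * len(correlations))
    ranked = correlations.reset_index().sort_values(
        ["r", "feature_id"], ascending=[False, True], kind="mergesort"
    )
    return list(ranked["feature_id"].iloc[:k])


def enrichment_hypergeometric(
    selected: Iterable[str],
    annotation: AnnotationTable,
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided hypergeometric (upper-tail) enrichment of annotation groups.

    For each group with at least one member in the universe, tests whether the
    overlap k between the group (size K in the universe of size N) and the
    selected set (size n) is larger than expected; BH correction across groups.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected)
    stray = selected - universe
    if stray:
        raise ValueError(f"selected feature(s) outside universe: {sorted(stray)[:5]}")
    N, n = len(universe), len(selected)
    rows = []
    for group in annotation.group_names:
        members = annotation.features_in(group) & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & selected)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"group": group, "overlap": k, "group_size": K,
                     "selected": n, "universe": N, "p": p})
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = adjust_fdr(table["p"].to_numpy())
        table = table.sort_values(["p", "group"], kind="mergesort").reset_index(drop=True)
    return table


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = x.size
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 and sd > 0 else max(sd, iqr / 1.34)
    bw = 0.9 * spread * n ** (-1 / 5)
    return max(bw, 0.01)  # floor keeps degenerate groups (all r equal) usable


def correlation_density_by_group(
    correlations: pd.DataFrame,
    annotation: AnnotationTable,
    groups: Sequence[str],
    grid: np.ndarray = DENSITY_GRID,
) -> pd.DataFrame:
    """Gaussian-kernel density of r per group on a fixed grid over [-1.05, 1.05].

    Bandwidth follows Silverman's rule per group (floored at 0.01 so that
    degenerate groups remain representable); kernels are truncated at the grid
    boundary and each curve is renormalized to integrate to 1 on the grid.
    Groups with fewer than 5 defined correlations are skipped with a warning.
    """
    frames = []
    for group in groups:
        members = annotation.features_in(group) & set(correlations.index)
        # sorted by value so identical multisets of r give bit-identical curves
        r = np.sort(correlations.loc[sorted(members), "r"].dropna().to_numpy())
        if r.size < 5:
            warnings.warn(
                f"group '{group}' has {r.size} defined correlation(s); at least 5 required, skipped",
                stacklevel=2,
            )
            continue
        bw = _silverman_bandwidth(r)
        density = stats.norm.pdf(grid[:, None], loc=r[None, :], scale=bw).mean(axis=1)
        density /= np.trapezoid(density, grid)
        frames.append(pd.DataFrame({"group": group, "r": grid, "density": density}))
    if not frames:
        return pd.DataFrame(columns=["group", "r", "density"])
    return pd.concat(frames, ignore_index=True)


def negative_control_correlation(
    levels: pd.DataFrame,
    heights: pd.Series | TraitTable,
    min_genotypes: int = 3,
) -> tuple[pd.DataFrame, dict]:
    """Correlate absolute expression levels (not heterosis ratios) with raw height.

    ``levels`` is a feature x genotype matrix of per-genotype mean expression;
    ``heights`` gives each genotype's raw trait value.  Features with constant
    levels or too few genotypes are omitted.  Returns the per-feature table and
    a distribution summary (median r, median |r|, IQR).  Under the heterosis
    model, expression heterosis — not expression level — tracks trait
    heterosis, so these correlations should be weak.
    """
    if isinstance(heights, TraitTable):
        heights = heights.heights
    h = heights.reindex(levels.columns)
    if h.isna().any():
        raise ValueError(f"genotype '{h.index[h.isna()][0]}' has no trait value")
    r, n, p, reason = _masked_pearson(
        levels.to_numpy(dtype=float), h.to_numpy(dtype=float), min_genotypes
    )
    out = pd.DataFrame({"r": r, "n": n, "p": p}, index=levels.index)
    out = out[reason == ""].copy()
    out.index.name = "feature_id"
    rv = out["r"].to_numpy()
    summary = {
        "n_features": int(len(out)),
        "median_r": float(np.median(rv)) if len(out) else float("nan"),
        "median_abs_r": float(np.median(np.abs(rv))) if len(out) else float("nan"),
        "iqr_r": float(np.subtract(*np.percentile(rv, [75, 25]))) if len(out) else float("nan"),
    }
    return out, summary


def panel_records(
    matrix: AbundanceMatrix,
    design: SampleDesign,
    panel: CrossPanel,
    tissue: str | None = None,
    alpha: float = 0.05,
    min_reps: int = 2,
) -> dict[str, pd.DataFrame]:
    """Classified heterosis records for every hybrid of a panel (one tissue)."""
    panel.check_design(design)
    records = {}
    for _, row in panel.table.iterrows():
        records[row["hybrid"]] = classify_hybrid(
            matrix,
            design,
            row["hybrid"],
            row["parent_female"],
            row["parent_male"],
            tissue=tissue,
            alpha=alpha,
            min_reps=min_reps,
        )
    return records
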