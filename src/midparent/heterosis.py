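"""Midparent/high-parent/low-parent contrasts and nonadditivity classification.

For each hybrid and feature, parental replicate summaries define the midparent
(MP = average of the two parental means), high parent (HP = larger parental
mean) and low parent (LP = smaller parental mean).  The hybrid is tested
against each reference on the log2 scale with Welch's unequal-variance t test;
the MP contrast uses per-replicate pseudo-midparent values (replicate k of one
parent averaged with replicate k of the other, pairing by replicate order and
truncating to the shorter parent) so the midparent has a sampling distribution
without assuming equal parental variances.  Benjamini-Hochberg q-values are
computed within each contrast, and each feature receives exactly one of five
categories:

    above_HP  q_HP <= alpha and hybrid mean > HP
    below_LP  q_LP <= alpha and hybrid mean < LP
    between_MP_HP  otherwise, q_MP <= alpha and hybrid mean > MP
    between_LP_MP  otherwise, q_MP <= alpha and hybrid mean < MP
    MP        otherwise (additive)

Ratios (hybrid/MP etc.) are reported on the linear scale; tests are on log2
values of anchor-normalized abundances.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import AbundanceMatrix, AnnotationTable, SampleDesign

logger = logging.getLogger(__name__)

CATEGORIES = ("above_HP", "between_MP_HP", "MP", "between_LP_MP", "below_LP")


# ---------------------------------------------------------------------------
# Replicate summaries
# ---------------------------------------------------------------------------

@dataclass
class GenotypeStats:
    """Per-feature replicate summaries for one genotype in one tissue.

    ``values`` holds the replicate-level linear-scale abundances (features x
    replicates, NaN missing); means/variances are computed over non-missing
    values, and a feature's mean is reported missing when fewer than
    ``min_reps`` replicates are present.
    """

    genotype: str
    values: pd.DataFrame
    min_reps: int = 2
    tissue: str | None = None

    n: pd.Series = field(init=False)
    mean: pd.Series = field(init=False)
    variance: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        vals = self.values.astype(float)
        self.values = vals
        self.n = vals.notna().sum(axis=1)
        mean = vals.mean(axis=1, skipna=True)
        self.mean = mean.where(self.n >= self.min_reps)
        self.variance = vals.var(axis=1, ddof=1, skipna=True)

    @property
    def log2_values(self) -> pd.DataFrame:
        with np.errstate(divide="ignore", invalid="ignore"):
            logv = np.log2(self.values.where(self.values > 0))
        return logv


def genotype_stats(
    matrix: AbundanceMatrix,
    design: SampleDesign,
    genotype: str,
    tissue: str | None = None,
    min_reps: int = 2,
) -> GenotypeStats:
    """Summarize the replicates of one genotype (optionally one tissue)."""
    rows = design.samples(genotype=genotype, tissue=tissue)
    rows = rows[rows["sample_id"].isin(matrix.data.columns)]
    if rows.empty:
        where = f" in tissue '{tissue}'" if tissue else ""
        raise ValueError(f"genotype '{genotype}' has no samples{where}")
    rows = rows.sort_values(["replicate", "sample_id"])
    values = matrix.data[list(rows["sample_id"])]
    return GenotypeStats(genotype=genotype, values=values, min_reps=min_reps, tissue=tissue)


# ---------------------------------------------------------------------------
# Welch's t test (vectorized, with degenerate-variance handling)
# ---------------------------------------------------------------------------

def welch_from_stats(m1, v1, n1, m2, v2, n2):
    """Vectorized Welch t test from group summaries; returns (t, df, p).

    When both groups have zero variance the test is degenerate: p is 1 when
    the means are equal and 0 otherwise (the noise-free limit).  Groups with
    fewer than two observations yield NaN.
    """
    m1, v1, n1, m2, v2, n2 = (np.asarray(a, dtype=float) for a in (m1, v1, n1, m2, v2, n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = v1 / n1 + v2 / n2
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    valid = (n1 >= 2) & (n2 >= 2) & np.isfinite(m1) & np.isfinite(m2)
    degenerate = valid & (se2 == 0)
    with np.errstate(invalid="ignore"):
        p = np.where(degenerate, np.where(m1 == m2, 1.0, 0.0), p)
        t = np.where(degenerate, np.where(m1 == m2, 0.0, np.inf * np.sign(m1 - m2)), t)
    p = np.where(valid, p, np.nan)
    t = np.where(valid, t, np.nan)
    df = np.where(valid, df, np.nan)
    return t, df, p


def _log2_summary(values: pd.DataFrame, min_reps: int):
    """Mean/variance/count of log2 replicate values (NaN-aware)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        logv = np.log2(values.where(values > 0)).to_numpy()
    n = np.isfinite(logv).sum(axis=1)
    with np.errstate(invalid="ignore"):
        finite = np.where(np.isfinite(logv), logv, 0.0)
        m = np.where(n > 0, finite.sum(axis=1) / np.where(n > 0, n, 1), np.nan)
        v = pd.DataFrame(logv).var(axis=1, ddof=1, skipna=True).to_numpy()
    m = np.where(n >= min_reps, m, np.nan)
    return m, v, n


# ---------------------------------------------------------------------------
# Contrasts
# ---------------------------------------------------------------------------

def pseudo_midparent_values(p1: GenotypeStats, p2: GenotypeStats) -> pd.DataFrame:
    """Per-replicate pseudo-MP values: replicate k of P1 averaged with replicate
    k of P2 (positional pairing after replicate ordering, truncated to the
    shorter parent); missing when either paired value is missing."""
    k = min(p1.values.shape[1], p2.values.shape[1])
    a = p1.values.iloc[:, :k].to_numpy()
    b = p2.values.reindex(p1.values.index).iloc[:, :k].to_numpy()
    pm = (a + b) / 2.0
    return pd.DataFrame(pm, index=p1.values.index, columns=[f"pmp{i+1}" for i in range(k)])


def heterosis_contrasts(
    hybrid: GenotypeStats,
    p1: GenotypeStats,
    p2: GenotypeStats,
    hybrid_name: str | None = None,
) -> pd.DataFrame:
    """Per-feature MP/HP/LP summaries, ratios and Welch p-values for one hybrid.

    Features where the hybrid is quantified but either parent mean is missing
    are dropped (their count is logged); categories are assigned separately by
    :func:`classify`.
    """
    features = hybrid.values.index
    p1v = p1.values.reindex(features)
    p2v = p2.values.reindex(features)
    p1s = GenotypeStats(p1.genotype, p1v, p1.min_reps, p1.tissue)
    p2s = GenotypeStats(p2.genotype, p2v, p2.min_reps, p2.tissue)

    m_h = hybrid.mean.to_numpy()
    m1 = p1s.mean.to_numpy()
    m2 = p2s.mean.to_numpy()
    mp = (m1 + m2) / 2.0
    hp = np.maximum(m1, m2)
    lp = np.minimum(m1, m2)

    valid = np.isfinite(m_h) & np.isfinite(m1) & np.isfinite(m2)
    n_dropped = int((np.isfinite(m_h) & ~(np.isfinite(m1) & np.isfinite(m2))).sum())
    if n_dropped:
        logger.info(
            "%s: dropped %d feature(s) quantified in the hybrid but missing a parent",
            hybrid.genotype,
            n_dropped,
        )

    lh_m, lh_v, lh_n = _log2_summary(hybrid.values, hybrid.min_reps)
    l1_m, l1_v, l1_n = _log2_summary(p1v, p1.min_reps)
    l2_m, l2_v, l2_n = _log2_summary(p2v, p2.min_reps)

    _, _, p_vs_p1 = welch_from_stats(lh_m, lh_v, lh_n, l1_m, l1_v, l1_n)
    _, _, p_vs_p2 = welch_from_stats(lh_m, lh_v, lh_n, l2_m, l2_v, l2_n)
    p1_is_hp = m1 >= m2
    p_hp = np.where(p1_is_hp, p_vs_p1, p_vs_p2)
    p_lp = np.where(p1_is_hp, p_vs_p2, p_vs_p1)

    pmp = pseudo_midparent_values(p1s, p2s)
    pm_m, pm_v, pm_n = _log2_summary(pmp, min(p1.min_reps, p2.min_reps))
    _, _, p_mp = welch_from_stats(lh_m, lh_v, lh_n, pm_m, pm_v, pm_n)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_mp = m_h / mp
        ratio_hp = m_h / hp
        ratio_lp = m_h / lp
        log2_mp = np.log2(ratio_mp)
        log2_hp = np.log2(ratio_hp)
        log2_lp = np.log2(ratio_lp)

    records = pd.DataFrame(
        {
            "hybrid": hybrid_name or hybrid.genotype,
            "hybrid_mean": m_h,
            "parent1_mean": m1,
            "parent2_mean": m2,
            "mp": mp,
            "hp": hp,
            "lp": lp,
            "ratio_mp": ratio_mp,
            "ratio_hp": ratio_hp,
            "ratio_lp": ratio_lp,
            "log2_ratio_mp": log2_mp,
            "log2_ratio_hp": log2_hp,
            "log2_ratio_lp": log2_lp,
            "p_mp": p_mp,
            "p_hp": p_hp,
            "p_lp": p_lp,
        },
        index=features,
    )
    records.index.name = "feature_id"
    return records.loc[valid]


# ---------------------------------------------------------------------------
# FDR and classification
# ---------------------------------------------------------------------------

def adjust_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaNs are passed through."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        bad = p[mask][(p[mask] < 0) | (p[mask] > 1)][0]
        raise ValueError(f"p-value outside [0, 1]: {bad}")
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def classify(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Attach BH q-values per contrast and the five-way nonadditivity category.

    Records with any missing q-value fall back to category ``MP`` and are
    flagged in the ``q_missing`` column.
    """
    out = records.copy()
    for contrast in ("mp", "hp", "lp"):
        out[f"q_{contrast}"] = adjust_fdr(out[f"p_{contrast}"].to_numpy())
    q_mp = out["q_mp"].to_numpy()
    q_hp = out["q_hp"].to_numpy()
    q_lp = out["q_lp"].to_numpy()
    mean = out["hybrid_mean"].to_numpy()
    hp = out["hp"].to_numpy()
    lp = out["lp"].to_numpy()
    mp = out["mp"].to_numpy()
    with np.errstate(invalid="ignore"):
        category = np.select(
            [
                (q_hp <= alpha) & (mean > hp),
                (q_lp <= alpha) & (mean < lp),
                (q_mp <= alpha) & (mean > mp),
                (q_mp <= alpha) & (mean < mp),
            ],
            ["above_HP", "below_LP", "between_MP_HP", "between_LP_MP"],
            default="MP",
        )
    out["category"] = category
    out["q_missing"] = ~(
        np.isfinite(q_mp) & np.isfinite(q_hp) & np.isfinite(q_lp)
    )
    return out


def classify_hybrid(
    matrix: AbundanceMatrix,
    design: SampleDesign,
    hybrid: str,
    parent1: str,
    parent2: str,
    tissue: str | None = None,
    alpha: float = 0.05,
    min_reps: int = 2,
) -> pd.DataFrame:
    """Convenience wrapper: replicate summaries -> contrasts -> classification."""
    h = genotype_stats(matrix, design, hybrid, tissue=tissue, min_reps=min_reps)
    p1 = genotype_stats(matrix, design, parent1, tissue=tissue, min_reps=min_reps)
    p2 = genotype_stats(matrix, design, parent2, tissue=tissue, min_reps=min_reps)
    return classify(heterosis_contrasts(h, p1, p2, hybrid_name=hybrid), alpha=alpha)


# ---------------------------------------------------------------------------
# Group-level statistics and exports
# ---------------------------------------------------------------------------

def group_mean_excess(
    records: pd.DataFrame,
    annotation: AnnotationTable,
    group: str,
    baseline: str = "HP",
) -> float:
    """Mean percent excess of a group over a baseline: 100 * (mean ratio - 1).

    A value of +19 for baseline ``HP`` means the group is expressed 19% above
    high-parent levels on average.
    """
    col = f"ratio_{baseline.lower()}"
    members = annotation.features_in(group) & set(records.index)
    ratios = records.loc[sorted(members), col].dropna()
    if ratios.empty:
        raise ValueError(f"group '{group}' has no member with a defined {baseline} ratio")
    return float(100.0 * (ratios.mean() - 1.0))


def group_shift_test(
    records: pd.DataFrame,
    annotation: AnnotationTable,
    group: str,
    baseline: str = "MP",
) -> dict:
    """Wilcoxon signed-rank test of a group's log2 ratios against zero.

    Returns the statistic, two-sided p-value, the group's median log2 ratio
    and its size.  Requires at least three members with defined ratios.
    """
    col = f"log2_ratio_{baseline.lower()}"
    members = annotation.features_in(group) & set(records.index)
    x = records.loc[sorted(members), col].dropna().to_numpy()
    if x.size < 3:
        raise ValueError(
            f"group '{group}' has {x.size} member(s) with defined ratios; at least 3 required"
        )
    nonzero = x[x != 0]
    if nonzero.size == 0:
        statistic, p = 0.0, 1.0
    else:
        res = stats.wilcoxon(nonzero, alternative="two-sided")
        statistic, p = float(res.statistic), float(res.pvalue)
    return {
        "group": group,
        "baseline": baseline,
        "n": int(x.size),
        "statistic": statistic,
        "p_value": p,
        "median_log2_ratio": float(np.median(x)),
    }


def volcano_table(
    records: pd.DataFrame,
    contrast: str = "mp",
    annotation: AnnotationTable | None = None,
    q_min: float = 1e-300,
) -> pd.DataFrame:
    """Tabular volcano export: one row per classified feature.

    Rows are sorted by q ascending, then |log2 ratio| descending, then feature
    id; q-values of zero are clamped to ``q_min`` before taking -log10.
    """
    contrast = contrast.lower()
    q = records[f"q_{contrast}"].to_numpy(dtype=float)
    log2r = records[f"log2_ratio_{contrast}"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        neg_log10_q = -np.log10(np.maximum(q, q_min))
    out = pd.DataFrame(
        {
            "feature_id": records.index,
            "log2_ratio": log2r,
            "neg_log10_q": neg_log10_q,
            "category": records["category"].to_numpy()
            if "category" in records
            else "",
            "groups": annotation.groups_column(records.index) if annotation else "",
            "_q": q,
            "_abs": np.abs(log2r),
        }
    )
    out = out.sort_values(
        ["_q", "_abs", "feature_id"], ascending=[True, False, True], kind="mergesort"
    )
    return out.drop(columns=["_q", "_abs"]).reset_index(drop=True)
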