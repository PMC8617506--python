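"""Mutant-vs-hybrid phenocopy concordance and cross-table discordance statistics.

A mutant phenocopies a hybrid's molecular phenotype when features expressed
above (below) midparent in the hybrid are elevated (repressed) in the mutant
relative to its inbred background.  The concordance table collapses the
five-way hybrid categories to above_MP / MP / below_MP and crosses them with
the mutant's up / unchanged / down calls.  Discordance statistics quantify how
well two heterosis tables (e.g. protein vs transcript for the same hybrid)
agree in sign, magnitude and category.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .data_io import AnnotationTable
from .heterosis import GenotypeStats, adjust_fdr, welch_from_stats, _log2_summary

HYBRID_LEVELS = ("above_MP", "MP", "below_MP")
MUTANT_LEVELS = ("up", "unchanged", "down")

_COLLAPSE = {
    "above_HP": "above_MP",
    "between_MP_HP": "above_MP",
    "MP": "MP",
    "between_LP_MP": "below_MP",
    "below_LP": "below_MP",
}


def mutant_contrast(
    mutant: GenotypeStats, background: GenotypeStats, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-feature mutant/background log2 ratio with Welch test, BH q and direction.

    Direction is ``up``/``down`` by the sign of the log2 ratio at q <= alpha,
    ``unchanged`` otherwise.  Both genotypes must be summarized from the same
    tissue and normalization.
    """
    features = mutant.values.index
    bg = GenotypeStats(
        background.genotype,
        background.values.reindex(features),
        background.min_reps,
        background.tissue,
    )
    lm_m, lm_v, lm_n = _log2_summary(mutant.values, mutant.min_reps)
    lb_m, lb_v, lb_n = _log2_summary(bg.values, bg.min_reps)
    _, _, p = welch_from_stats(lm_m, lm_v, lm_n, lb_m, lb_v, lb_n)
    log2_ratio = lm_m - lb_m
    out = pd.DataFrame({"log2_ratio": log2_ratio, "p": p}, index=features)
    out.index.name = "feature_id"
    out = out[np.isfinite(out["log2_ratio"])]
    out["q"] = adjust_fdr(out["p"].to_numpy())
    with np.errstate(invalid="ignore"):
        out["direction"] = np.select(
            [
                (out["q"].to_numpy() <= alpha) & (out["log2_ratio"].to_numpy() > 0),
                (out["q"].to_numpy() <= alpha) & (out["log2_ratio"].to_numpy() < 0),
            ],
            ["up", "down"],
            default="unchanged",
        )
    return out


def collapse_categories(categories: pd.Series) -> pd.Series:
    """Collapse the five-way nonadditivity categories to above_MP / MP / below_MP."""
    return categories.map(_COLLAPSE)


def phenocopy_concordance(
    mutant_table: pd.DataFrame, hybrid_records: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """3x3 contingency of hybrid MP-class versus mutant direction, plus summaries.

    Rows: hybrid above_MP / MP / below_MP (five-way categories collapsed);
    columns: mutant up / unchanged / down.  Cell counts sum to the shared
    feature universe.  The summary reports the discordant cells explicitly
    (above_MP & down = "repressed", below_MP & up = "elevated") and the
    concordance rate among features called in both directions.
    """
    shared = mutant_table.index.intersection(hybrid_records.index)
    if shared.empty:
        raise ValueError("mutant and hybrid tables share no features")
    hyb = collapse_categories(hybrid_records.loc[shared, "category"])
    mut = mutant_table.loc[shared, "direction"]
    table = pd.crosstab(hyb, mut).reindex(
        index=HYBRID_LEVELS, columns=MUTANT_LEVELS, fill_value=0
    )
    table.index.name = "hybrid"
    table.columns.name = "mutant"
    concordant = table.loc["above_MP", "up"] + table.loc["below_MP", "down"]
    discordant = table.loc["above_MP", "down"] + table.loc["below_MP", "up"]
    called = concordant + discordant
    summary = {
        "n_shared": int(len(shared)),
        "n_above_mp": int(table.loc["above_MP"].sum()),
        "n_below_mp": int(table.loc["below_MP"].sum()),
        "above_mp_repressed": int(table.loc["above_MP", "down"]),
        "below_mp_elevated": int(table.loc["below_MP", "up"]),
        "concordance": float(concordant / called) if called else float("nan"),
    }
    return table, summary


def discordance_stats(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    annotation: AnnotationTable | None = None,
    min_shared: int = 10,
) -> dict:
    """Agreement between two heterosis tables over their shared feature universe.

    Reports the fraction of features whose log2 MP-ratios agree in sign, the
    Pearson correlation between the two log2 MP-ratio vectors, and (when both
    tables are classified) the category agreement rate.  With an annotation, a
    per-group breakdown of the same metrics is included.
    """
    shared = table_a.index.intersection(table_b.index)
    a = table_a.loc[shared, "log2_ratio_mp"].to_numpy(dtype=float)
    b = table_b.loc[shared, "log2_ratio_mp"].to_numpy(dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    shared = shared[ok]
    if len(shared) < min_shared:
        raise ValueError(
            f"only {len(shared)} shared feature(s) with defined ratios; at least {min_shared} required"
        )
    a, b = a[ok], b[ok]

    def _metrics(ai, bi, idx):
        sign_agree = float(np.mean(np.sign(ai) == np.sign(bi)))
        if ai.size >= 2 and np.std(ai) > 0 and np.std(bi) > 0:
            r = float(np.corrcoef(ai, bi)[0, 1])
        else:
            r = float("nan")
        if "category" in table_a.columns and "category" in table_b.columns:
            cat = float(
                np.mean(
                    table_a.loc[idx, "category"].to_numpy()
                    == table_b.loc[idx, "category"].to_numpy()
                )
            )
        else:
            cat = float("nan")
        return {"n": int(ai.size), "sign_agreement": sign_agree, "r": r,
                "category_agreement": cat}

    result = _metrics(a, b, shared)
    if annotation is not None:
        rows = []
        for group in annotation.group_names:
            members = annotation.features_in(group) & set(shared)
            if len(members) < 2:
                continue
            pos = shared.isin(members)
            rows.append({"group": group, **_metrics(a[pos], b[pos], shared[pos])})
        result["by_group"] = pd.DataFrame(rows)
    return result
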