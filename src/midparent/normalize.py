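"""Per-run anchor normalization and counts-per-million scaling.

Anchor normalization divides every sample's value, feature by feature, by the
arithmetic mean of the anchor genotype's replicates in the same run.  This
removes multiplicative run (plex/batch) effects and puts all runs on a common
ratio-to-anchor scale.  No further between-run adjustment is applied.
"""
from __future__ import annotations

import numpy as np

from .data_io import AbundanceMatrix, SampleDesign


def normalize_to_anchor(
    matrix: AbundanceMatrix, design: SampleDesign, anchor: str
) -> AbundanceMatrix:
    """Divide each value by the per-run arithmetic mean of the anchor replicates.

    Features whose anchor mean is missing or zero in a run become missing for
    all samples of that run (no ratio is fabricated).  Every run represented in
    the matrix must contain at least one anchor-genotype sample.
    """
    design.check_matrix(matrix)
    data = matrix.data
    sample_run = dict(zip(design.table["sample_id"], design.table["run"]))
    out = data.copy()
    runs = list(dict.fromkeys(sample_run[s] for s in data.columns))
    for run in runs:
        run_cols = [s for s in data.columns if sample_run[s] == run]
        anchor_ids = set(design.samples(genotype=anchor, run=run)["sample_id"])
        anchor_cols = [s for s in run_cols if s in anchor_ids]
        if not anchor_cols:
            raise ValueError(f"run '{run}' contains no sample of anchor genotype '{anchor}'")
        anchor_mean = data[anchor_cols].mean(axis=1, skipna=True)
        anchor_mean = anchor_mean.where(anchor_mean > 0)  # zero/missing -> NaN run-wide
        out[run_cols] = data[run_cols].div(anchor_mean, axis=0)
    return AbundanceMatrix(out)


def counts_per_million(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Scale each column so its (non-missing) sum is 1,000,000.

    Input must be integer-valued nonnegative counts with positive column sums.
    """
    data = matrix.data
    vals = data.to_numpy()
    finite = np.isfinite(vals)
    if not np.all(np.mod(vals[finite], 1) == 0):
        r, c = [idx[0] for idx in np.where(finite & (np.mod(vals, 1) != 0))]
        raise ValueError(
            f"non-integer count at feature '{data.index[r]}', sample '{data.columns[c]}'"
        )
    colsums = data.sum(axis=0, skipna=True)
    zero = colsums[~(colsums > 0)]
    if len(zero):
        raise ValueError(f"zero column sum for sample '{zero.index[0]}'")
    out = data.div(colsums, axis=1) * 1_000_000
    return AbundanceMatrix(out)
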