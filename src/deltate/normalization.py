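"""Median-of-ratios size factors and count normalisation.

Library depth and composition differ between samples, so raw counts are not
comparable across columns. The median-of-ratios estimator builds a
pseudo-reference sample from the gene-wise geometric means and takes, per
sample, the median ratio of its counts to that reference over all genes with
strictly positive counts in every sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataio import CountMatrix


class NormalizationError(ValueError):
    pass


def compute_size_factors(counts) -> pd.Series:
    """Median-of-ratios size factors, one strictly positive factor per sample.

    Parameters
    ----------
    counts
        A :class:`~deltate.dataio.CountMatrix` or a genes x samples DataFrame.
        Genes containing any zero are excluded from the reference set because
        their geometric mean vanishes.

    Returns
    -------
    pandas.Series mapping sample id -> size factor.
    """
    if isinstance(counts, CountMatrix):
        frame = counts.to_frame()
    else:
        frame = pd.DataFrame(counts)
    arr = frame.to_numpy(dtype=float)
    if arr.size == 0:
        raise NormalizationError("empty count matrix")
    ref = np.all(arr > 0, axis=1)
    if not ref.any():
        raise NormalizationError(
            "no gene has positive counts in every sample; cannot form a "
            "median-of-ratios reference — consider per-assay normalization "
            "or a pseudo-reference on a filtered gene set"
        )
    logs = np.log(arr[ref])
    log_geo = logs.mean(axis=1)  # per-gene log geometric mean
    factors = np.exp(np.median(logs - log_geo[:, None], axis=0))
    if not np.all(np.isfinite(factors)) or np.any(factors <= 0):
        raise NormalizationError("non-positive or non-finite size factor")
    return pd.Series(factors, index=frame.columns, name="size_factor")


def normalize_counts(counts, sf: pd.Series) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    if isinstance(counts, CountMatrix):
        frame = counts.to_frame()
    else:
        frame = pd.DataFrame(counts)
    missing = [s for s in frame.columns if s not in sf.index]
    if missing:
        raise NormalizationError(f"no size factor for sample(s): {missing}")
    return frame / sf.reindex(frame.columns)
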