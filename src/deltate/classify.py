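"""Regulatory classification from the (ΔRPF, ΔRNA, ΔTE) significance pattern.

Each gene is placed in exactly one class by the pattern of adjusted
p-values below the threshold and, where all three are significant, by the
relative direction of the TE and RNA changes:

==================  =====  =====  ====  =============================
class               ΔRPF   ΔRNA   ΔTE   direction rule
==================  =====  =====  ====  =============================
no_change           n.s.   n.s.   n.s.
forwarded           sig    sig    n.s.  RNA change drives RPF change
exclusive           sig    n.s.   sig   translation-only regulation
intensified         sig    sig    sig   sign(ΔTE)*sign(ΔRNA) > 0
buffered            sig    sig    sig   sign(ΔTE)*sign(ΔRNA) < 0
buffered_special    n.s.   sig    sig   TE cancels the RNA change
undetermined        any other pattern with >= 1 significant call
==================  =====  =====  ====  =============================

A missing adjusted p-value counts as not significant and tags the gene so
downstream users can filter. ``buffered_special`` genes are reported in the
buffered gene list but keep a distinguishable label in memory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

CLASSES = ("forwarded", "exclusive", "intensified", "buffered",
           "buffered_special", "undetermined", "no_change")


@dataclass
class RegClassLabel:
    label: str
    is_dtg: bool
    is_dteg: bool
    has_na: bool = False


def _sig(padj, alpha, lfc=None, lfc_cutoff=0.0):
    if padj is None or not np.isfinite(padj):
        return False
    if padj >= alpha:
        return False
    if lfc_cutoff > 0.0:
        return np.isfinite(lfc) and abs(lfc) >= lfc_cutoff
    return True


def classify_gene(te, rna, rpf, alpha: float = 0.05,
                  lfc_cutoff: float = 0.0) -> RegClassLabel:
    """Classify one gene from its three test outcomes.

    ``te``, ``rna``, ``rpf`` need attributes ``padj`` and ``lfc`` (any object
    with those fields works, e.g. :class:`deltate.nbglm.TestOutcome`).
    ``lfc_cutoff`` optionally additionally requires |log2FC| >= cutoff for a
    call to count as significant (off by default).
    """
    has_na = any(x.padj is None or not np.isfinite(x.padj) for x in (te, rna, rpf))
    te_s = _sig(te.padj, alpha, te.lfc, lfc_cutoff)
    rna_s = _sig(rna.padj, alpha, rna.lfc, lfc_cutoff)
    rpf_s = _sig(rpf.padj, alpha, rpf.lfc, lfc_cutoff)

    if not (te_s or rna_s or rpf_s):
        label = "no_change"
    elif rpf_s and rna_s and not te_s:
        label = "forwarded"
    elif te_s and rpf_s and not rna_s:
        label = "exclusive"
    elif te_s and rna_s and rpf_s:
        prod = np.sign(te.lfc) * np.sign(rna.lfc)
        if prod > 0:
            label = "intensified"
        elif prod < 0:
            label = "buffered"
        else:
            warnings.warn("zero log fold change in an all-significant gene; "
                          "classifying as undetermined", UserWarning, stacklevel=2)
            label = "undetermined"
    elif te_s and rna_s and not rpf_s:
        label = "buffered_special"
    else:
        label = "undetermined"
    return RegClassLabel(label, is_dtg=rna_s, is_dteg=te_s, has_na=has_na)


def classify_table(result, alpha: float = 0.05,
                   lfc_cutoff: float = 0.0) -> tuple[pd.DataFrame, pd.Series]:
    """Vectorised classification of a full result set.

    ``result`` is a :class:`deltate.dte.DTEResult`. Returns a per-gene frame
    with columns class/is_DTG/is_DTEG/has_NA and a Series of class counts.
    """
    te, rna, rpf = result.te, result.rna, result.rpf
    genes = list(te.index)
    rows = []
    for g in genes:
        lab = classify_gene(
            _row_outcome(te.loc[g]), _row_outcome(rna.loc[g]),
            _row_outcome(rpf.loc[g]), alpha=alpha, lfc_cutoff=lfc_cutoff,
        )
        rows.append((lab.label, lab.is_dtg, lab.is_dteg, lab.has_na))
    frame = pd.DataFrame(rows, index=genes,
                         columns=["class", "is_DTG", "is_DTEG", "has_NA"])
    counts = frame["class"].value_counts().reindex(CLASSES, fill_value=0)
    return frame, counts


class _row_outcome:
    __slots__ = ("padj", "lfc")

    def __init__(self, row):
        self.padj = row["padj"]
        self.lfc = row["log2FoldChange"]
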