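"""Expression-based enrichment of prioritized genes.

Four analyses share two operations: each gene is labeled highly (or
lowly) expressed in a column — a brain dissection or a cell type — when
its value exceeds ``mean + 1.645 * SE`` (or falls below
``mean - 1.645 * SE``) of its own row, SE being the standard error of the
row mean; then, per column, a one-sided Fisher's exact test asks whether
prioritized genes are labeled more often than the remaining genes, with
Benjamini-Hochberg correction across columns within each analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from crossmeta.errors import UsageError

ALPHA_MULTIPLIER = 1.645  # one-sided normal quantile at alpha = 0.05


def _row_threshold(m: pd.DataFrame, se_of_mean: bool = True):
    values = m.to_numpy(dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise UsageError("expression matrix needs at least two columns")
    if (values < 0).any():
        raise UsageError("expression values must be nonnegative")
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    se = sd / np.sqrt(values.shape[1]) if se_of_mean else sd
    return values, mean, se


def label_high(m: pd.DataFrame, se_of_mean: bool = True) -> pd.DataFrame:
    """Boolean genes x columns matrix: value > mean + 1.645 * SE.

    A constant row has SE = 0 and no value strictly above its mean, so it
    receives no labels.  ``se_of_mean=False`` switches SE to the plain row
    standard deviation.
    """
    values, mean, se = _row_threshold(m, se_of_mean)
    return pd.DataFrame(values > mean + ALPHA_MULTIPLIER * se,
                        index=m.index, columns=m.columns)


def label_low(m: pd.DataFrame, se_of_mean: bool = True) -> pd.DataFrame:
    """Boolean genes x columns matrix: value < mean - 1.645 * SE."""
    values, mean, se = _row_threshold(m, se_of_mean)
    return pd.DataFrame(values < mean - ALPHA_MULTIPLIER * se,
                        index=m.index, columns=m.columns)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise UsageError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / (np.arange(m) + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def enrich(labels: pd.DataFrame, prioritized, direction: str = "high",
           analysis: str = "") -> pd.DataFrame:
    """Per-column Fisher's exact enrichment of prioritized genes.

    ``labels`` is a boolean genes x columns matrix from :func:`label_high`
    or :func:`label_low`; ``prioritized`` a subset of its index.  The test
    is one-sided (greater): are prioritized genes labeled more often than
    the others?  Returns the 2x2 counts, odds ratio, Fisher P and BH q per
    column.
    """
    prioritized = set(prioritized)
    if not prioritized:
        raise UsageError("prioritized gene set is empty")
    missing = prioritized - set(labels.index)
    if missing:
        raise UsageError(f"prioritized genes absent from the matrix: "
                         f"{sorted(missing)[:5]}")
    is_prio = labels.index.isin(prioritized)
    if is_prio.all():
        raise UsageError("no non-prioritized genes to compare against")
    lab = labels.to_numpy()
    a = lab[is_prio].sum(axis=0)          # prioritized, labeled
    b = is_prio.sum() - a                 # prioritized, not labeled
    c = lab[~is_prio].sum(axis=0)         # other, labeled
    d = (~is_prio).sum() - c              # other, not labeled
    rows = []
    for col, aa, bb, cc, dd in zip(labels.columns, a, b, c, d):
        odds, p = stats.fisher_exact([[aa, bb], [cc, dd]],
                                     alternative="greater")
        rows.append({"COLUMN": col, "DIRECTION": direction,
                     "ANALYSIS": analysis,
                     "PRIO_LABELED": int(aa), "PRIO_NOT": int(bb),
                     "OTHER_LABELED": int(cc), "OTHER_NOT": int(dd),
                     "ODDS_RATIO": float(odds), "P": float(p)})
    out = pd.DataFrame(rows)
    out["Q"] = bh_fdr(out["P"].to_numpy())
    return out


def run_enrichment_analyses(dissections: pd.DataFrame,
                            cell_types: pd.DataFrame,
                            prioritized) -> pd.DataFrame:
    """The four standard analyses: {dissection, cell type} x {high, low}."""
    frames = []
    for name, matrix in (("dissection", dissections),
                         ("celltype", cell_types)):
        for direction, labeler in (("high", label_high), ("low", label_low)):
            frames.append(enrich(labeler(matrix), prioritized,
                                 direction=direction,
                                 analysis=f"{name}_{direction}"))
    return pd.concat(frames, ignore_index=True)
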