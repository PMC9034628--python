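"""Subtype-specific gene selection.

For each of the six ordered CMS pairs, every gene gets a log2 fold-change,
a Welch t statistic with Welch-Satterthwaite degrees of freedom, a
two-sided p value from the t distribution, and a Benjamini-Hochberg
step-up Q value (adjusted within the pair by default).  A gene is
subtype-specific when |log2FC| > 1 and Q < 0.05 in at least one pair; the
selected genes of all pairs form the network's input gene set.

On log2-scale data the fold-change is the difference of group means,
i.e. log2 of the ratio of geometric means; a linear-scale mode computes
log2 of the ratio of arithmetic means instead.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import CMS_PAIRS, ExpressionDataset, GeneSet, pair_label

DIFFEXPR_COLUMNS = (
    "gene", "pair", "mean_a", "mean_b", "log2fc", "t", "df", "p", "q", "selected",
)


def log2_fold_change(
    group_a: np.ndarray, group_b: np.ndarray, log_scale: bool = True
) -> float:
    """log2 fold-change of group A over group B.

    ``log_scale=True`` (the default) treats inputs as log2 intensities and
    returns the difference of means; ``log_scale=False`` treats them as
    linear intensities and returns log2(mean(A)/mean(B)).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("fold-change requires non-empty groups")
    if log_scale:
        return float(a.mean() - b.mean())
    if a.mean() <= 0 or b.mean() <= 0:
        raise ValueError("linear-scale fold-change requires positive group means")
    return float(np.log2(a.mean() / b.mean()))


def welch_t(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float, float]:
    """Welch's two-sample t test.

    Returns ``(t, df, p)`` with the unpooled statistic
    ``t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b)`` (sample variances,
    n-1 denominator), Welch-Satterthwaite degrees of freedom, and a
    two-sided p value from the t distribution.  Degenerate zero-variance
    inputs: equal means give (0, ., 1); unequal means give p = 0 with a
    warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t requires at least two values per group")
    t, df, p = _welch_t_rows(a[None, :], b[None, :])
    return float(t[0]), float(df[0]), float(p[0])


def _welch_t_rows(
    A: np.ndarray, B: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Welch t over gene x sample blocks for the two groups."""
    na, nb = A.shape[1], B.shape[1]
    ma, mb = A.mean(axis=1), B.mean(axis=1)
    va, vb = A.var(axis=1, ddof=1), B.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    diff = ma - mb

    zero = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero, 0.0, diff / np.sqrt(np.where(zero, 1.0, se2)))
        df = np.where(
            zero,
            np.nan,
            se2**2
            / (
                (va / na) ** 2 / np.maximum(na - 1, 1)
                + (vb / nb) ** 2 / np.maximum(nb - 1, 1)
            ),
        )
    p = np.ones_like(t)
    ok = ~zero
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    degenerate = zero & (diff != 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) have zero variance in both groups "
            "with unequal means; p set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        p[degenerate] = 0.0
        t[degenerate] = np.where(diff[degenerate] > 0, np.inf, -np.inf)
    return t, df, p


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (Q values).

    Sort p ascending, set q_(i) = min_{j>=i} p_(j) * m / j capped at 1, and
    map back to the input order; argsort stability preserves ties.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def select_subtype_specific_genes(
    ds: ExpressionDataset,
    fc_threshold: float = 1.0,
    q_threshold: float = 0.05,
    pooled_bh: bool = False,
) -> tuple[GeneSet, pd.DataFrame]:
    """Run the six pairwise comparisons and take the union of selected genes.

    Returns the ordered :class:`GeneSet` and the full per-(gene, pair)
    table.  BH adjustment is within each pair across all genes by default;
    ``pooled_bh=True`` adjusts all six pairs' p values jointly.  Classes
    with fewer than two samples have their pairs skipped with a warning.
    """
    if ds.labels is None:
        raise ValueError("gene selection requires labelled samples")
    labels = np.asarray(ds.labels)
    present = {c: np.flatnonzero(labels == c) for c in sorted(set(ds.labels))}
    if len(present) < 2:
        raise ValueError("gene selection requires at least two CMS classes")

    records: list[pd.DataFrame] = []
    genes = np.asarray(ds.gene_ids)
    for a, b in CMS_PAIRS:
        lab = pair_label(a, b)
        if len(present.get(a, ())) < 2 or len(present.get(b, ())) < 2:
            warnings.warn(
                f"skipping pair {lab}: fewer than two samples in a class",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        A = ds.values[:, present[a]]
        B = ds.values[:, present[b]]
        t, df, p = _welch_t_rows(A, B)
        records.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "pair": lab,
                    "mean_a": A.mean(axis=1),
                    "mean_b": B.mean(axis=1),
                    "log2fc": A.mean(axis=1) - B.mean(axis=1),
                    "t": t,
                    "df": df,
                    "p": p,
                }
            )
        )
    if not records:
        raise ValueError("no pair had two classes with >=2 samples each")
    table = pd.concat(records, ignore_index=True)
    if pooled_bh:
        table["q"] = bh_adjust(table["p"].to_numpy())
    else:
        table["q"] = 0.0
        for lab in table["pair"].unique():
            mask = table["pair"] == lab
            table.loc[mask, "q"] = bh_adjust(table.loc[mask, "p"].to_numpy())
    table["selected"] = (table["log2fc"].abs() > fc_threshold) & (
        table["q"] < q_threshold
    )

    provenance = {
        lab: sorted(table.loc[(table["pair"] == lab) & table["selected"], "gene"])
        for lab in table["pair"].unique()
    }
    gene_set = GeneSet.from_provenance(provenance)
    return gene_set, table[list(DIFFEXPR_COLUMNS)]
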