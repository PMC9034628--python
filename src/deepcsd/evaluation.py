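"""Metrics, cross-validation protocols, regularizer scan, distance
correlation, and weight-based gene interpretability.

All classification metrics are one-vs-rest per CMS class and reported in
percent.  Macro averages weight classes equally; per-class ratios with a
zero denominator are excluded from the macro mean and counted, rather than
scored zero, so degenerate predictors are flagged instead of silently
rewarded.  Two accuracy conventions co-exist in the field and both are
reported: overall accuracy (fraction of correct calls) and macro per-class
one-vs-rest accuracy (mean of (TP+TN)/n over classes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.model_selection import StratifiedKFold, train_test_split

from .data_io import CMS_LABELS, ExpressionDataset, GeneSet
from .diffexpr import select_subtype_specific_genes
from .network import TrainConfig, TrainResult, build_bundle, predict, train

# ---------------------------------------------------------------------------
# Confusion counts and metrics
# ---------------------------------------------------------------------------


@dataclass
class ConfusionCounts:
    """One-vs-rest TP/TN/FP/FN per class."""

    counts: dict[str, dict[str, int]]
    n_samples: int

    def __getitem__(self, cls: str) -> dict[str, int]:
        return self.counts[cls]


def confusion(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    classes: tuple[str, ...] = CMS_LABELS,
) -> ConfusionCounts:
    t = list(true_labels)
    p = list(predicted_labels)
    if len(t) != len(p):
        raise ValueError("true and predicted label sequences differ in length")
    unknown = sorted({l for l in t + p if l not in classes})
    if unknown:
        raise ValueError(f"unknown labels: {unknown}")
    n = len(t)
    counts = {}
    for c in classes:
        tp = sum(1 for a, b in zip(t, p) if a == c and b == c)
        fn = sum(1 for a, b in zip(t, p) if a == c and b != c)
        fp = sum(1 for a, b in zip(t, p) if a != c and b == c)
        tn = n - tp - fn - fp
        counts[c] = {"TP": tp, "TN": tn, "FP": fp, "FN": fn}
    return ConfusionCounts(counts=counts, n_samples=n)


@dataclass
class MetricsReport:
    """Per-class and macro-averaged metrics, in percent.

    ``overall_accuracy`` is the plain fraction of correct predictions;
    ``macro_class_accuracy`` is the mean one-vs-rest accuracy per class.
    ``undefined`` counts (class, metric) pairs whose denominator was zero
    and which were therefore excluded from the macro mean.
    """

    per_class: dict[str, dict[str, float | None]]
    macro_sensitivity: float
    macro_specificity: float
    macro_precision: float
    macro_class_accuracy: float
    overall_accuracy: float
    undefined: list[tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class,
            "macro_sensitivity": self.macro_sensitivity,
            "macro_specificity": self.macro_specificity,
            "macro_precision": self.macro_precision,
            "macro_class_accuracy": self.macro_class_accuracy,
            "overall_accuracy": self.overall_accuracy,
            "undefined": [list(u) for u in self.undefined],
        }


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def metrics(cc: ConfusionCounts) -> MetricsReport:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP)
    and one-vs-rest accuracy (TP+TN)/n per class, macro-averaged over the
    classes where they are defined."""
    per_class: dict[str, dict[str, float | None]] = {}
    undefined: list[tuple[str, str]] = []
    for c, d in cc.counts.items():
        sens = _ratio(d["TP"], d["TP"] + d["FN"])
        spec = _ratio(d["TN"], d["TN"] + d["FP"])
        prec = _ratio(d["TP"], d["TP"] + d["FP"])
        acc = _ratio(d["TP"] + d["TN"], cc.n_samples)
        per_class[c] = {
            "sensitivity": sens,
            "specificity": spec,
            "precision": prec,
            "class_accuracy": acc,
        }
        for name, v in per_class[c].items():
            if v is None:
                undefined.append((c, name))

    def macro(name: str) -> float:
        vals = [d[name] for d in per_class.values() if d[name] is not None]
        return float(np.mean(vals)) if vals else float("nan")

    total_tp = sum(d["TP"] for d in cc.counts.values())
    return MetricsReport(
        per_class=per_class,
        macro_sensitivity=macro("sensitivity"),
        macro_specificity=macro("specificity"),
        macro_precision=macro("precision"),
        macro_class_accuracy=macro("class_accuracy"),
        overall_accuracy=100.0 * total_tp / cc.n_samples if cc.n_samples else float("nan"),
        undefined=undefined,
    )


def evaluate_predictions(
    true_labels: Sequence[str], predicted_labels: Sequence[str]
) -> MetricsReport:
    return metrics(confusion(true_labels, predicted_labels))


# ---------------------------------------------------------------------------
# Cross-validation and hold-out protocols
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    fold_reports: list[MetricsReport]
    selection_policy: str
    fold_gene_counts: list[int]

    def aggregate(self) -> dict[str, tuple[float, float]]:
        """Mean +/- sd across folds for each macro metric."""
        out = {}
        for name in (
            "macro_sensitivity",
            "macro_specificity",
            "macro_precision",
            "macro_class_accuracy",
            "overall_accuracy",
        ):
            vals = np.array([getattr(r, name) for r in self.fold_reports])
            out[name] = (float(np.nanmean(vals)), float(np.nanstd(vals)))
        return out


def _check_stratifiable(labels: Sequence[str], k: int) -> None:
    counts = pd.Series(list(labels)).value_counts()
    small = counts[counts < k]
    if not small.empty:
        raise ValueError(
            f"class(es) with fewer than k={k} samples: {dict(small)}; "
            "use a smaller k"
        )


def cross_validate(
    ds: ExpressionDataset,
    k: int = 10,
    selection_policy: str = "per_fold",
    config: TrainConfig | None = None,
    seed: int = 0,
    fc_threshold: float = 1.0,
    q_threshold: float = 0.05,
) -> CVResult:
    """Stratified k-fold cross-validation of the full pipeline.

    ``per_fold`` (default, leak-free) refits gene selection and
    standardization inside each training fold; ``global`` selects genes once
    on the full dataset before splitting.  Deterministic under ``seed``.
    """
    if ds.labels is None:
        raise ValueError("cross-validation requires labels")
    if k < 2:
        raise ValueError("k must be >= 2")
    if selection_policy not in {"per_fold", "global"}:
        raise ValueError(f"unknown selection_policy {selection_policy!r}")
    _check_stratifiable(ds.labels, k)
    config = config or TrainConfig()

    global_genes: GeneSet | None = None
    if selection_policy == "global":
        global_genes, _ = select_subtype_specific_genes(
            ds, fc_threshold=fc_threshold, q_threshold=q_threshold
        )
        if len(global_genes) == 0:
            raise ValueError("global gene selection returned no genes")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    labels = np.asarray(ds.labels)
    reports: list[MetricsReport] = []
    gene_counts: list[int] = []
    for fold_i, (train_idx, test_idx) in enumerate(
        skf.split(np.zeros(ds.n_samples), labels)
    ):
        ds_train = ds.subset_samples(train_idx)
        ds_test = ds.subset_samples(test_idx)
        if selection_policy == "per_fold":
            genes, _ = select_subtype_specific_genes(
                ds_train, fc_threshold=fc_threshold, q_threshold=q_threshold
            )
            if len(genes) == 0:
                raise ValueError(f"fold {fold_i}: gene selection returned no genes")
        else:
            genes = global_genes
        gene_counts.append(len(genes))

        fold_config = TrainConfig(**{**config.to_dict(), "seed": config.seed + fold_i})
        from .data_io import align_to_genes

        result = train(align_to_genes(ds_train, genes), fold_config)
        bundle = build_bundle(result, genes, fold_config)
        pred, _ = predict(ds_test, bundle)
        reports.append(evaluate_predictions(ds_test.labels, pred))
    return CVResult(
        fold_reports=reports,
        selection_policy=selection_policy,
        fold_gene_counts=gene_counts,
    )


def holdout_split(
    ds: ExpressionDataset, train_fraction: float = 0.9, seed: int = 0
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Stratified random train/test split (default the 9:1 protocol)."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    if ds.labels is None:
        raise ValueError("holdout_split requires labels")
    idx = np.arange(ds.n_samples)
    train_idx, test_idx = train_test_split(
        idx,
        train_size=train_fraction,
        stratify=np.asarray(ds.labels),
        random_state=seed,
    )
    return ds.subset_samples(np.sort(train_idx)), ds.subset_samples(np.sort(test_idx))


def regularizer_scan(
    ds: ExpressionDataset,
    coef_grid: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    config: TrainConfig | None = None,
    k: int = 10,
    seed: int = 0,
    selection_policy: str = "per_fold",
) -> pd.DataFrame:
    """Mean CV accuracy as a function of the shared L1/L2 coefficient.

    Reuses :func:`cross_validate` with the same fold seed at every grid
    point, so fold composition is shared across coefficients.  Returns one
    row per coefficient with mean and sd of both accuracy conventions.
    """
    if len(coef_grid) == 0:
        raise ValueError("coefficient grid is empty")
    config = config or TrainConfig()
    rows = []
    for coef in coef_grid:
        c = TrainConfig(**{**config.to_dict(), "l1_coef": float(coef), "l2_coef": float(coef)})
        cv = cross_validate(
            ds, k=k, selection_policy=selection_policy, config=c, seed=seed
        )
        agg = cv.aggregate()
        rows.append(
            {
                "coef": float(coef),
                "mean_macro_class_accuracy": agg["macro_class_accuracy"][0],
                "sd_macro_class_accuracy": agg["macro_class_accuracy"][1],
                "mean_overall_accuracy": agg["overall_accuracy"][0],
                "sd_overall_accuracy": agg["overall_accuracy"][1],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Distance correlation (Szekely-Rizzo)
# ---------------------------------------------------------------------------


def distance_correlation(X: np.ndarray, Y: np.ndarray) -> float:
    """Distance correlation between two samples of paired observations.

    Rows are observations.  Pairwise Euclidean distance matrices are doubly
    centered; dCor is the square root of dCov^2 normalized by the geometric
    mean of the distance variances.  A constant input has zero distance
    variance and yields 0 by convention.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    if Y.shape[0] == 1:
        Y = Y.T
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of observations")
    n = X.shape[0]
    if n < 2:
        raise ValueError("distance correlation requires at least two observations")

    def centered(D: np.ndarray) -> np.ndarray:
        return D - D.mean(axis=0) - D.mean(axis=1)[:, None] + D.mean()

    A = centered(squareform(pdist(X)))
    B = centered(squareform(pdist(Y)))
    dcov2 = (A * B).mean()
    dvar_x = (A * A).mean()
    dvar_y = (B * B).mean()
    if dvar_x == 0 or dvar_y == 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvar_x * dvar_y)))


def dataset_distance_correlation(
    ds1: ExpressionDataset, ds2: ExpressionDataset
) -> float:
    """Distance correlation between two cohorts of different sizes.

    The cohorts are compared over their shared genes, each reduced to its
    per-gene mean expression profile; observations are genes.
    """
    shared = sorted(set(ds1.gene_ids) & set(ds2.gene_ids))
    if len(shared) < 2:
        raise ValueError("datasets share fewer than two genes")
    i1 = {g: i for i, g in enumerate(ds1.gene_ids)}
    i2 = {g: i for i, g in enumerate(ds2.gene_ids)}
    prof1 = np.array([ds1.values[i1[g]].mean() for g in shared])
    prof2 = np.array([ds2.values[i2[g]].mean() for g in shared])
    return distance_correlation(prof1[:, None], prof2[:, None])


# ---------------------------------------------------------------------------
# Interpretability: top-weight genes per first-layer neuron
# ---------------------------------------------------------------------------


def top_weight_genes(
    params,
    gene_set: GeneSet | Sequence[str],
    neuron_indices: Sequence[int] | None = None,
    k: int = 100,
) -> dict[int, list[str]]:
    """Rank genes by |W1[neuron, gene]| for the requested first-layer
    neurons (default the first 10), ties broken by gene id; the standard
    first step toward enrichment analysis of what each neuron attends to."""
    genes = gene_set.gene_ids if isinstance(gene_set, GeneSet) else list(gene_set)
    W1 = np.asarray(params.W1, dtype=float)
    if W1.shape[1] != len(genes):
        raise ValueError("gene list length does not match W1 input width")
    if k > len(genes):
        raise ValueError(f"k={k} exceeds the {len(genes)}-gene input")
    if neuron_indices is None:
        neuron_indices = list(range(min(10, W1.shape[0])))
    out: dict[int, list[str]] = {}
    for j in neuron_indices:
        if not 0 <= j < W1.shape[0]:
            raise IndexError(f"neuron index {j} out of range for width {W1.shape[0]}")
        ranked = sorted(zip(-np.abs(W1[j]), genes))
        out[j] = [g for _, g in ranked[:k]]
    return out
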