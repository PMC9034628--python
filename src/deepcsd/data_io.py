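"""Expression-matrix and model-artifact I/O.

Conventions
-----------
Matrices are genes-in-rows, samples-in-columns (the GEO series-matrix
orientation).  Expression values are log2-scale by default; linear-scale
input is transformed with ``log2(x + 1)`` at load time.  Class labels are
the four colorectal-cancer consensus molecular subtypes CMS1-CMS4.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CMS_LABELS: tuple[str, ...] = ("CMS1", "CMS2", "CMS3", "CMS4")

#: The six ordered subtype pairs used for pairwise differential expression.
CMS_PAIRS: tuple[tuple[str, str], ...] = (
    ("CMS1", "CMS2"),
    ("CMS1", "CMS3"),
    ("CMS1", "CMS4"),
    ("CMS2", "CMS3"),
    ("CMS2", "CMS4"),
    ("CMS3", "CMS4"),
)


def pair_label(a: str, b: str) -> str:
    return f"{a}v{b}"


PAIR_LABELS: tuple[str, ...] = tuple(pair_label(a, b) for a, b in CMS_PAIRS)

MODEL_BUNDLE_VERSION = 1


class DataError(ValueError):
    """Raised for malformed expression matrices, labels or bundles."""


@dataclass
class ExpressionDataset:
    """A genes x samples expression matrix with optional CMS labels.

    Parameters
    ----------
    gene_ids : sequence of str
        Unique row identifiers (gene symbols).
    sample_ids : sequence of str
        Unique column identifiers.
    values : ndarray, shape (n_genes, n_samples)
        Expression values, log2 scale by convention.
    labels : sequence of str, optional
        Per-sample CMS label aligned to ``sample_ids``; ``None`` for
        prediction-only data.
    log_scale : bool
        Whether ``values`` are log2-transformed (always true after
        construction through :func:`read_expression`).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    labels: list[str] | None = None
    log_scale: bool = True

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if not np.all(np.isfinite(self.values)):
            raise DataError("expression matrix contains non-finite values")
        if self.labels is not None:
            self.labels = [str(l) for l in self.labels]
            if len(self.labels) != len(self.sample_ids):
                raise DataError("labels must have one entry per sample")
            bad = sorted({l for l in self.labels if l not in CMS_LABELS})
            if bad:
                raise DataError(f"unknown CMS labels: {bad}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_samples(self, indices: Sequence[int]) -> "ExpressionDataset":
        idx = list(indices)
        return ExpressionDataset(
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[:, idx].copy(),
            labels=None if self.labels is None else [self.labels[i] for i in idx],
            log_scale=self.log_scale,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GeneSet:
    """An ordered union of subtype-specific genes.

    ``provenance`` maps each pairwise comparison label (e.g. ``"CMS1vCMS2"``)
    to the genes it contributed, sorted lexicographically.  ``gene_ids`` is
    the deduplicated union taken in the fixed pair order with duplicates kept
    at first occurrence, which fixes the network input ordering.
    """

    gene_ids: list[str]
    provenance: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def from_provenance(cls, provenance: Mapping[str, Sequence[str]]) -> "GeneSet":
        prov = {
            lab: sorted(set(provenance.get(lab, ())))
            for lab in PAIR_LABELS
            if lab in provenance
        }
        seen: dict[str, None] = {}
        for lab in PAIR_LABELS:
            for g in prov.get(lab, ()):
                seen.setdefault(g, None)
        return cls(gene_ids=list(seen), provenance=prov)

    def __len__(self) -> int:
        return len(self.gene_ids)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen.add(x)
    if dups:
        raise DataError(f"duplicate {what}(s): {sorted(set(dups))}")


def read_expression(
    matrix_path: str | Path,
    label_path: str | Path | None = None,
    delimiter: str = "\t",
    log_scale: bool = True,
    transpose: bool = False,
    nonfinite: str = "error",
) -> ExpressionDataset:
    """Read a delimited expression matrix and optional label file.

    The matrix file has a header row of sample ids and gene ids in the first
    column.  The label file is two-column (sample id, CMS label) without a
    header; labels are aligned to matrix columns by sample id, never by file
    order.  ``nonfinite`` is ``"error"`` (reject the file) or ``"drop"``
    (drop offending gene rows).
    """
    df = pd.read_csv(matrix_path, sep=delimiter, index_col=0, float_precision="round_trip")
    if transpose:
        df = df.T
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    _check_unique(gene_ids, "gene id")
    _check_unique(sample_ids, "sample id")
    values = df.to_numpy(dtype=float)
    finite_rows = np.all(np.isfinite(values), axis=1)
    if not finite_rows.all():
        if nonfinite == "drop":
            values = values[finite_rows]
            gene_ids = [g for g, ok in zip(gene_ids, finite_rows) if ok]
        else:
            bad = [g for g, ok in zip(gene_ids, finite_rows) if not ok]
            raise DataError(f"non-finite values in rows: {bad[:10]}")
    if not log_scale:
        if np.any(values < 0):
            raise DataError("negative values are incompatible with log2(x+1) transform")
        values = np.log2(values + 1.0)

    labels: list[str] | None = None
    if label_path is not None:
        labels = _read_labels(label_path, sample_ids)
    return ExpressionDataset(gene_ids, sample_ids, values, labels=labels, log_scale=True)


def _read_labels(label_path: str | Path, sample_ids: Sequence[str]) -> list[str]:
    lab = pd.read_csv(label_path, sep="\t", header=None, comment="#", dtype=str)
    if lab.shape[1] < 2:
        raise DataError("label file must have two columns: sample_id<TAB>CMS label")
    mapping: dict[str, str] = {}
    for sid, cms in zip(lab.iloc[:, 0], lab.iloc[:, 1]):
        sid, cms = str(sid).strip(), str(cms).strip()
        if sid in mapping and mapping[sid] != cms:
            raise DataError(f"conflicting labels for sample {sid!r}")
        mapping[sid] = cms
    known = set(sample_ids)
    unknown = sorted(set(mapping) - known)
    if unknown:
        raise DataError(f"labels given for unknown sample id(s): {unknown}")
    missing = [s for s in sample_ids if s not in mapping]
    if missing:
        raise DataError(f"sample(s) missing a label: {missing}")
    return [mapping[s] for s in sample_ids]


def write_expression(ds: ExpressionDataset, matrix_path: str | Path, delimiter: str = "\t") -> None:
    ds.to_frame().to_csv(matrix_path, sep=delimiter, float_format="%.17g")


def write_labels(ds: ExpressionDataset, label_path: str | Path) -> None:
    if ds.labels is None:
        raise DataError("dataset has no labels to write")
    with open(label_path, "w") as fh:
        for sid, lab in zip(ds.sample_ids, ds.labels):
            fh.write(f"{sid}\t{lab}\n")


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    _check_unique(genes, "gene id")
    return genes


def write_gene_list(genes: Sequence[str] | GeneSet, path: str | Path) -> None:
    ids = genes.gene_ids if isinstance(genes, GeneSet) else list(genes)
    with open(path, "w") as fh:
        for g in ids:
            fh.write(f"{g}\n")


def align_to_genes(
    ds: ExpressionDataset,
    genes: GeneSet | Sequence[str],
    missing_policy: str = "error",
    fill_means: Mapping[str, float] | None = None,
) -> ExpressionDataset:
    """Reorder (and pad) dataset rows to exactly the gene-set order.

    ``missing_policy`` is one of ``"error"``, ``"fill_zero"`` or
    ``"fill_mean"``; the latter fills absent genes with the training-set
    per-gene mean supplied via ``fill_means``.
    """
    wanted = genes.gene_ids if isinstance(genes, GeneSet) else list(genes)
    if not wanted:
        raise DataError("gene set is empty")
    index = {g: i for i, g in enumerate(ds.gene_ids)}
    missing = [g for g in wanted if g not in index]
    if missing and missing_policy == "error":
        raise DataError(f"genes absent from dataset: {missing}")
    if missing_policy not in {"error", "fill_zero", "fill_mean"}:
        raise DataError(f"unknown missing_policy {missing_policy!r}")
    if missing_policy == "fill_mean" and missing and fill_means is None:
        raise DataError("fill_mean requires training-set per-gene means")
    out = np.empty((len(wanted), ds.n_samples), dtype=float)
    for i, g in enumerate(wanted):
        if g in index:
            out[i] = ds.values[index[g]]
        elif missing_policy == "fill_zero":
            out[i] = 0.0
        else:
            if g not in fill_means:
                raise DataError(f"no training mean available for missing gene {g!r}")
            out[i] = float(fill_means[g])
    return ExpressionDataset(
        gene_ids=list(wanted),
        sample_ids=list(ds.sample_ids),
        values=out,
        labels=None if ds.labels is None else list(ds.labels),
        log_scale=ds.log_scale,
    )


# ---------------------------------------------------------------------------
# Model bundle: a zip archive with a JSON manifest and .npy member arrays.
# ---------------------------------------------------------------------------


def save_model(bundle: "ModelBundle", path: str | Path) -> None:
    """Serialise a trained model (weights, gene set, standardisation, config)."""
    p = bundle.params
    arrays = {
        "W1": p.W1, "theta1": p.theta1,
        "W2": p.W2, "theta2": p.theta2,
        "W3": p.W3, "theta3": p.theta3,
        "feature_mean": bundle.feature_mean,
        "feature_sd": bundle.feature_sd,
    }
    manifest = {
        "format_version": MODEL_BUNDLE_VERSION,
        "gene_ids": bundle.gene_set.gene_ids,
        "provenance": bundle.gene_set.provenance,
        "classes": list(bundle.classes),
        "dropout_keep_p": p.dropout_keep_p,
        "l1_coef": p.l1_coef,
        "l2_coef": p.l2_coef,
        "train_config": bundle.train_config,
        "arrays": sorted(arrays),
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=1))
        for name, arr in arrays.items():
            buf = io.BytesIO()
            np.save(buf, np.asarray(arr, dtype=float))
            zf.writestr(f"{name}.npy", buf.getvalue())


def load_model(path: str | Path) -> "ModelBundle":
    from .network import NetworkParams

    try:
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            if manifest.get("format_version") != MODEL_BUNDLE_VERSION:
                raise DataError(
                    f"unsupported model bundle version {manifest.get('format_version')!r}"
                )
            arrays = {}
            for name in manifest["arrays"]:
                arrays[name] = np.load(io.BytesIO(zf.read(f"{name}.npy")))
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError) as exc:
        raise DataError(f"corrupted model bundle {path}: {exc}") from exc

    params = NetworkParams(
        W1=arrays["W1"], theta1=arrays["theta1"],
        W2=arrays["W2"], theta2=arrays["theta2"],
        W3=arrays["W3"], theta3=arrays["theta3"],
        dropout_keep_p=float(manifest["dropout_keep_p"]),
        l1_coef=float(manifest["l1_coef"]),
        l2_coef=float(manifest["l2_coef"]),
    )
    gene_set = GeneSet(
        gene_ids=list(manifest["gene_ids"]),
        provenance={k: list(v) for k, v in manifest["provenance"].items()},
    )
    return ModelBundle(
        params=params,
        gene_set=gene_set,
        feature_mean=arrays["feature_mean"],
        feature_sd=arrays["feature_sd"],
        classes=tuple(manifest["classes"]),
        train_config=manifest.get("train_config", {}),
    )


@dataclass
class ModelBundle:
    """Everything needed to reproduce predictions: weights, the gene set the
    model was trained on, per-gene standardisation statistics fit on the
    training data, and the training configuration."""

    params: "object"
    gene_set: GeneSet
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    classes: tuple[str, ...] = CMS_LABELS
    train_config: dict = field(default_factory=dict)

    @property
    def gene_means(self) -> dict[str, float]:
        return dict(zip(self.gene_set.gene_ids, np.asarray(self.feature_mean, dtype=float)))
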