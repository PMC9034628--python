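"""Synthetic four-class expression data with planted subtype-specific genes.

The generator emulates the structure of log-intensity microarray cohorts:
background genes are Normal(baseline_mean, noise_sd) in every class, while
each planted gene is tied to one of the six CMS pairs and has its mean
shifted by +/- effect_size in the first class of the pair relative to the
second.  An optional affine platform shift (location offset, scale factor)
emulates cross-platform intensity differences.  Generation is a pure
function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import CMS_LABELS, CMS_PAIRS, ExpressionDataset, pair_label


@dataclass
class SimulationConfig:
    """Study design of a simulated cohort.

    n_samples_per_class : per-class sample counts for CMS1..CMS4 (real CMS
        cohorts are unbalanced, so a vector rather than a single n).
    n_genes : total gene count.
    n_specific_per_pair : planted differentially expressed genes for each of
        the six ordered pairs (scalar or 6-vector).
    effect_size : mean log2 shift of a planted gene in its up-regulated
        class (log2 expression units).
    noise_sd : within-class Gaussian SD on the log2 scale.
    baseline_mean : background log2 expression level.
    platform_shift : optional (location, scale) affine transform for a
        generated test set.
    """

    n_samples_per_class: tuple[int, int, int, int] = (60, 60, 60, 60)
    n_genes: int = 2000
    n_specific_per_pair: int | tuple[int, ...] = 50
    effect_size: float = 2.0
    noise_sd: float = 0.5
    baseline_mean: float = 6.0
    platform_shift: tuple[float, float] | None = None
    seed: int = 0

    def per_pair_counts(self) -> tuple[int, ...]:
        if isinstance(self.n_specific_per_pair, int):
            return (self.n_specific_per_pair,) * len(CMS_PAIRS)
        counts = tuple(int(c) for c in self.n_specific_per_pair)
        if len(counts) != len(CMS_PAIRS):
            raise ValueError("n_specific_per_pair must be a scalar or 6-vector")
        return counts

    def validate(self) -> None:
        if len(self.n_samples_per_class) != 4 or any(
            n <= 0 for n in self.n_samples_per_class
        ):
            raise ValueError("n_samples_per_class must be four positive integers")
        counts = self.per_pair_counts()
        if any(c < 0 for c in counts):
            raise ValueError("planted gene counts must be non-negative")
        if sum(counts) > self.n_genes:
            raise ValueError(
                f"{sum(counts)} planted genes exceed n_genes={self.n_genes}"
            )
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class PlantedTruth:
    """Ground-truth record: pair label -> [(gene id, sign), ...].

    ``sign=+1`` means the gene's mean is raised by effect_size in the first
    class of the pair (relative to the second); ``-1`` lowered.  Each planted
    gene belongs to exactly one pair.
    """

    per_pair: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    def all_genes(self) -> list[str]:
        return [g for genes in self.per_pair.values() for g, _ in genes]

    def genes_for_pair(self, label: str) -> list[str]:
        return [g for g, _ in self.per_pair.get(label, [])]

    def to_json_dict(self) -> dict:
        return {lab: [[g, s] for g, s in genes] for lab, genes in self.per_pair.items()}

    @classmethod
    def from_json_dict(cls, d: dict) -> "PlantedTruth":
        return cls({lab: [(g, int(s)) for g, s in genes] for lab, genes in d.items()})


def _gene_ids(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]


def _plant(cfg: SimulationConfig, rng: np.random.Generator) -> PlantedTruth:
    # planted genes occupy the first sum(counts) rows, in pair order;
    # signs are the only random element of the structure
    counts = cfg.per_pair_counts()
    truth = PlantedTruth()
    ids = _gene_ids(cfg.n_genes)
    pos = 0
    for (a, b), c in zip(CMS_PAIRS, counts):
        signs = rng.choice([-1, 1], size=c)
        truth.per_pair[pair_label(a, b)] = [
            (ids[pos + j], int(signs[j])) for j in range(c)
        ]
        pos += c
    return truth


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[ExpressionDataset, PlantedTruth]:
    """Draw one cohort and its ground-truth planted-gene record."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    truth = _plant(cfg, rng)
    ds = _draw(cfg, truth, rng)
    return ds, truth


def simulate_from_truth(
    cfg: SimulationConfig, truth: PlantedTruth, seed: int
) -> ExpressionDataset:
    """Draw a replicate cohort sharing an existing truth record.

    Used to emulate an independent test cohort measured on the same (or,
    with ``cfg.platform_shift``, a different) platform.
    """
    cfg.validate()
    return _draw(cfg, truth, np.random.default_rng(seed))


def _draw(
    cfg: SimulationConfig, truth: PlantedTruth, rng: np.random.Generator
) -> ExpressionDataset:
    n_per_class = cfg.n_samples_per_class
    n_samples = sum(n_per_class)
    gene_ids = _gene_ids(cfg.n_genes)
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    labels: list[str] = []
    for lab, n in zip(CMS_LABELS, n_per_class):
        labels.extend([lab] * n)
    class_cols = {
        lab: np.flatnonzero(np.array(labels) == lab) for lab in CMS_LABELS
    }

    means = np.full((cfg.n_genes, n_samples), cfg.baseline_mean)
    for (a, b) in CMS_PAIRS:
        for g, sign in truth.per_pair.get(pair_label(a, b), []):
            means[gene_index[g], class_cols[a]] += sign * cfg.effect_size

    values = means + rng.normal(0.0, cfg.noise_sd, size=means.shape)
    if cfg.platform_shift is not None:
        location, scale = cfg.platform_shift
        values = values * scale + location

    sample_ids = [f"S{i:04d}" for i in range(1, n_samples + 1)]
    return ExpressionDataset(gene_ids, sample_ids, values, labels=labels)


def apply_platform_shift(
    ds: ExpressionDataset, location: float, scale: float
) -> ExpressionDataset:
    """Apply an affine cross-platform shift ``x -> x * scale + location``."""
    if scale == 0:
        raise ValueError("scale must be non-zero")
    return ExpressionDataset(
        gene_ids=list(ds.gene_ids),
        sample_ids=list(ds.sample_ids),
        values=ds.values * scale + location,
        labels=None if ds.labels is None else list(ds.labels),
        log_scale=ds.log_scale,
    )
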