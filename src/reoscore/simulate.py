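"""Synthetic cohorts with planted reversal gene pairs.

The generator emulates the statistical structure the signature cascade
assumes, so every stage is testable without any external download:

* two tissue classes whose within-sample orderings differ on a planted set
  of gene-disjoint pairs — in the normal class the first gene of a pair
  sits ``separation * noise_sd`` above its partner on a latent scale, and
  the cancer class reverses the offset;
* independent additive Gaussian noise per gene and sample on the latent
  scale, so a planted pair shows its class direction with probability
  Phi(separation / sqrt(2)) per sample;
* several "platforms", each drawing its own noise and applying its own
  strictly increasing distortion of the latent values (the minimal model
  under which rank-based analysis is exactly invariant while absolute
  values differ arbitrarily between platforms);
* non-planted genes get one base value each (shared across samples and
  classes), creating a stable global ordering that is identical in both
  classes and therefore contributes no reversal pairs;
* precancerous samples on a progression gradient: at level theta each
  planted pair is put in its cancer orientation with probability theta,
  mimicking lesions partway between normal mucosa and carcinoma.

Everything is reproducible bit-for-bit from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ValidationError
from .matrix import ExpressionMatrix
from .pairs import LESS, DirectedGenePair, ReversalSignature

_BASE_RANGE = 50.0  # latent base values ~ Uniform(0, _BASE_RANGE)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Two-class, multi-platform cohort layout.

    Defaults mirror the training structure the pipeline targets: two
    platforms, tens of samples per class per platform, a few hundred genes
    of which a planted subset of disjoint pairs reverses between classes,
    and a separation of 2 noise standard deviations (per-sample ordering
    probability Phi(2/sqrt(2)) ~ 0.92, i.e. comfortably above a 90%
    stability threshold in expectation but not degenerate).
    """

    n_genes: int = 500
    n_planted_pairs: int = 50
    n_normal: int = 40
    n_cancer: int = 40
    separation: float = 2.0
    noise_sd: float = 1.0
    platform_labels: tuple[str, ...] = ("affymetrix", "illumina")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValidationError("n_genes must be >= 10")
        if self.n_planted_pairs < 0 or 2 * self.n_planted_pairs > self.n_genes:
            raise ValidationError("need 2 * n_planted_pairs <= n_genes")
        if self.n_normal < 1 or self.n_cancer < 1:
            raise ValidationError("each class needs at least one sample")
        if self.separation <= 0:
            raise ValidationError("separation must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not self.platform_labels:
            raise ValidationError("at least one platform label required")
        if len(set(self.platform_labels)) != len(self.platform_labels):
            raise ValidationError("platform labels must be unique")

    @property
    def gap(self) -> float:
        """Latent offset between the genes of a planted pair; at zero noise
        the noise-unit parameterization degenerates, so an absolute offset
        is used there (the scale is arbitrary without noise)."""
        return self.separation * self.noise_sd if self.noise_sd > 0 else self.separation

    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def planted_keys(self) -> list[tuple[str, str]]:
        genes = self.gene_ids()
        return [(genes[2 * i], genes[2 * i + 1]) for i in range(self.n_planted_pairs)]


@dataclass(frozen=True)
class ProgressionSpec:
    """Progression-gradient cohort: ``n_samples_per_level`` samples at each
    level theta, where theta is the per-pair probability of the cancer
    orientation being planted in that sample."""

    theta_levels: tuple[float, ...]
    n_samples_per_level: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.theta_levels:
            raise ValidationError("at least one theta level required")
        for t in self.theta_levels:
            if not 0.0 <= t <= 1.0:
                raise ValidationError(f"theta must be in [0, 1], got {t}")
        if self.n_samples_per_level < 1:
            raise ValidationError("n_samples_per_level must be >= 1")


def planted_signature(spec: SyntheticCohortSpec) -> ReversalSignature:
    """Ground-truth signature: cancer direction of every planted pair.

    Pair genes are consecutive ids, so the first gene is lexicographically
    smaller; it is the high gene in normal tissue and the low gene in
    cancer, giving cancer direction ``less``."""
    entries = [DirectedGenePair(a, b, LESS) for a, b in spec.planted_keys()]
    return ReversalSignature(entries, provenance=f"planted truth seed={spec.seed}")


def cancer_direction_probability(spec: SyntheticCohortSpec) -> float:
    """Per-sample probability q that a planted pair shows its class
    direction: Phi(separation / sqrt(2)) for Gaussian noise, 1 without."""
    if spec.noise_sd == 0:
        return 1.0
    return float(norm.cdf(spec.separation / np.sqrt(2.0)))


def _base_values(spec: SyntheticCohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Latent per-gene base values.

    Non-planted genes draw one base each, shared across samples and
    classes, giving a stable global ordering that is identical in both
    classes. Each planted pair shares a base inside its own protected
    interval above the non-planted range: the swinging gene moves within
    [base, base + gap] and the intervals are separated by a margin of
    2*gap + 6*noise_sd, so no bystander ordering can reverse between
    classes — the planted pairs are exactly the ground truth (surely at
    zero noise, with overwhelming probability otherwise)."""
    base = rng.uniform(0.0, _BASE_RANGE, size=spec.n_genes)
    margin = 2.0 * spec.gap + 6.0 * spec.noise_sd
    for i in range(spec.n_planted_pairs):
        pair_base = _BASE_RANGE + margin + i * (spec.gap + margin)
        base[2 * i] = pair_base
        base[2 * i + 1] = pair_base
    return base


def _class_offsets(spec: SyntheticCohortSpec) -> tuple[np.ndarray, np.ndarray]:
    normal = np.zeros(spec.n_genes)
    cancer = np.zeros(spec.n_genes)
    for i in range(spec.n_planted_pairs):
        normal[2 * i] = spec.gap  # first gene high in normal
        cancer[2 * i + 1] = spec.gap  # partner high in cancer
    return normal, cancer


def _distortion(rng: np.random.Generator):
    """Random strictly increasing transform: scale > 0 plus a bounded-slope
    tanh warp and a shift."""
    a = rng.uniform(0.8, 1.6)
    d = rng.uniform(0.0, 3.0)
    c = rng.uniform(-5.0, 5.0)

    def f(x: np.ndarray) -> np.ndarray:
        return a * x + d * np.tanh(x / 20.0) + c

    return f


def _sample_matrix(
    base: np.ndarray,
    offsets: np.ndarray,
    n_samples: int,
    noise_sd: float,
    rng: np.random.Generator,
    distort,
) -> np.ndarray:
    latent = (base + offsets)[:, None] + rng.normal(0.0, noise_sd, size=(base.size, n_samples))
    return distort(latent)


def generate_two_class_cohorts(
    spec: SyntheticCohortSpec,
) -> tuple[dict[str, tuple[ExpressionMatrix, ExpressionMatrix]], ReversalSignature]:
    """Per-platform (normal, cancer) matrices plus the ground truth.

    Each platform draws independent noise on the latent scale and then
    applies its own strictly increasing distortion, so values differ across
    platforms while every within-sample ordering statistic is preserved in
    distribution. The ground-truth signature is identical for all
    platforms.
    """
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids()
    base = _base_values(spec, rng)
    off_normal, off_cancer = _class_offsets(spec)
    cohorts: dict[str, tuple[ExpressionMatrix, ExpressionMatrix]] = {}
    for platform in spec.platform_labels:
        distort = _distortion(rng)
        vn = _sample_matrix(base, off_normal, spec.n_normal, spec.noise_sd, rng, distort)
        vc = _sample_matrix(base, off_cancer, spec.n_cancer, spec.noise_sd, rng, distort)
        normal = ExpressionMatrix(
            pd.DataFrame(
                vn, index=genes,
                columns=[f"{platform}_normal_{i:03d}" for i in range(1, spec.n_normal + 1)],
            ),
            cohort_label=f"{platform}_normal",
        )
        cancer = ExpressionMatrix(
            pd.DataFrame(
                vc, index=genes,
                columns=[f"{platform}_cancer_{i:03d}" for i in range(1, spec.n_cancer + 1)],
            ),
            cohort_label=f"{platform}_cancer",
        )
        cohorts[platform] = (normal, cancer)
    return cohorts, planted_signature(spec)


def generate_progression_cohort(
    base_spec: SyntheticCohortSpec, prog: ProgressionSpec
) -> tuple[ExpressionMatrix, pd.Series]:
    """Cohort of precancerous samples on a theta gradient.

    A sample at level theta carries each planted pair in its cancer
    orientation independently with probability theta (then noise flips the
    observed ordering with probability 1 - q as usual), so the expected
    fraction of signature pairs in cancer orientation is
    theta * q + (1 - theta) * (1 - q). The cohort is treated as its own
    dataset: it draws its own distortion, like an evaluation dataset
    measured separately from the training platforms. Returns the matrix
    and the per-sample true theta.
    """
    rng = np.random.default_rng(prog.seed)
    base_rng = np.random.default_rng(base_spec.seed)
    genes = base_spec.gene_ids()
    base = _base_values(base_spec, base_rng)  # same latent gene order as training
    off_normal, off_cancer = _class_offsets(base_spec)
    distort = _distortion(rng)
    columns: list[str] = []
    theta_of: list[float] = []
    blocks: list[np.ndarray] = []
    for level_idx, theta in enumerate(prog.theta_levels):
        for s in range(prog.n_samples_per_level):
            cancer_state = rng.random(base_spec.n_planted_pairs) < theta
            offsets = off_normal.copy()
            for i in np.flatnonzero(cancer_state):
                offsets[2 * i] = 0.0
                offsets[2 * i + 1] = base_spec.gap
            latent = base + offsets + rng.normal(0.0, base_spec.noise_sd, size=base_spec.n_genes)
            blocks.append(distort(latent))
            columns.append(f"theta{theta:.2f}_{level_idx:02d}_{s + 1:03d}")
            theta_of.append(theta)
    data = pd.DataFrame(np.column_stack(blocks), index=genes, columns=columns)
    matrix = ExpressionMatrix(data, cohort_label="progression")
    return matrix, pd.Series(theta_of, index=columns, name="theta")
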