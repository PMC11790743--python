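"""Negative-binomial count simulator with planted gene classes.

The generator emulates a pooled-brain bulk RNA-seq study design: two sexes
(F, M) by three post-eclosion ages (3, 7, 14 days) by a small number of
replicates, with per-sample library-size factors and per-gene NB dispersion.
Genes are assigned to classes that mirror the phenomena the analysis is
built to detect:

* ``null`` — flat everywhere (the remainder after the planted fractions);
* ``sex_biased`` — a constant between-sex offset of ``effect_lfc`` log2
  units at every age (direction split between female- and male-biased);
* ``delayed_up`` — females step low -> high between days 3 and 7 and then
  plateau, males step one interval later (low, low, high): the male-delay
  signature;
* ``delayed_down`` — the mirrored decreasing pattern;
* ``female_only_change`` / ``male_only_change`` — the step occurs in one
  sex only (distractors for the delay detector);
* ``age_monotone`` — both sexes rise monotonically with age in sync.

Counts are drawn as NB(mean = sf_s * mu[g, sex(s), age(s)], dispersion
alpha_g) with variance mean + alpha * mean^2, the same parameterization the
DE core fits, so recovery tests compare like with like.  All randomness
flows through one seeded generator: a fixed seed reproduces the dataset
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import (
    DEFAULT_AGES,
    SEXES,
    ExpressionMatrix,
    GeneAnnotation,
    SampleDesign,
)
from .errors import ConfigError

GENE_CLASSES = (
    "null",
    "sex_biased",
    "delayed_up",
    "delayed_down",
    "female_only_change",
    "male_only_change",
    "age_monotone",
)


@dataclass
class SimConfig:
    """Study-design and effect-size knobs for the simulator.

    Defaults describe a desk-scale version of the emulated design: 5,000
    genes, 3 replicates per sex-age group, ages 3/7/14 days, a planted
    2-log2-unit effect, low NB dispersion (0.02-0.1, reflecting the small
    biological variability of samples pooled from ~100 brains) and a
    0.3-log-sd library-size spread.  ``x_fraction`` approximates the Drosophila X gene
    share; ``x_enrichment_in_sex_biased`` multiplies the X-linkage odds of
    sex-biased genes to emulate the X-enrichment of female-biased genes.
    """

    n_genes: int = 5000
    replicates: int = 3
    ages: tuple[int, ...] = DEFAULT_AGES
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"sex_biased": 0.10, "delayed_up": 0.04, "delayed_down": 0.01}
    )
    base_mean_log_mu: float = 4.0    # natural-log scale; median baseline ~55 counts
    base_mean_log_sigma: float = 1.0
    dispersion_range: tuple[float, float] = (0.02, 0.1)
    effect_lfc: float = 2.0
    size_factor_log_sigma: float = 0.3
    x_fraction: float = 0.17
    x_enrichment_in_sex_biased: float = 3.0
    female_biased_fraction: float = 0.5  # share of sex_biased genes that are female-biased
    sex_bias_ages: tuple[int, ...] | None = None  # None: offset at every age
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.replicates < 1:
            raise ConfigError("n_genes and replicates must be positive")
        unknown = set(self.class_fractions) - set(GENE_CLASSES)
        if unknown:
            raise ConfigError(f"unknown gene classes {sorted(unknown)}")
        if any(f < 0 for f in self.class_fractions.values()):
            raise ConfigError("class fractions must be nonnegative")
        if sum(self.class_fractions.values()) > 1.0 + 1e-12:
            raise ConfigError("class fractions sum above 1")
        lo, hi = self.dispersion_range
        if lo < 0 or hi < lo:
            raise ConfigError("dispersion_range must satisfy 0 <= low <= high")
        if self.effect_lfc <= 0:
            raise ConfigError("effect_lfc must be positive")
        if not 0 <= self.x_fraction <= 1:
            raise ConfigError("x_fraction must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated dataset.

    ``trajectories`` maps gene_id -> {(sex, age): mean} on the normalized
    (size-factor-free) scale; ``size_factors`` are the true per-sample
    multipliers; ``dispersions`` the per-gene NB alpha.
    """

    gene_class: dict[str, str]
    trajectories: dict[str, dict[tuple[str, int], float]]
    size_factors: dict[str, float]
    dispersions: dict[str, float]

    def genes_of_class(self, label: str) -> list[str]:
        return [g for g, c in self.gene_class.items() if c == label]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, c in self.gene_class.items():
            row = {"gene_id": g, "gene_class": c, "dispersion": self.dispersions[g]}
            for (sex, age), mu in self.trajectories[g].items():
                row[f"mu_{sex}{age}"] = mu
            rows.append(row)
        return pd.DataFrame(rows)


def _step_trajectory(base: float, fold: float, pattern: tuple[int, int, int]) -> list[float]:
    """Means over the three ages; pattern entries pick base (0) or base*fold (1)."""
    return [base * (fold if p else 1.0) for p in pattern]


def _assign_trajectories(
    cls: str,
    base: float,
    fold: float,
    ages: list[int],
    bias_ages: tuple[int, ...] | None = None,
) -> dict[str, list[float]]:
    """Per-sex mean trajectories over the (sorted) ages for one gene."""
    if cls == "null":
        return {"F": [base] * 3, "M": [base] * 3}
    if cls == "sex_biased":
        # direction drawn by the caller via `fold` (>1 female-biased, <1 male-biased);
        # `bias_ages` restricts the offset to a subset of ages (None = all)
        half = np.sqrt(fold)
        biased = [bias_ages is None or age in bias_ages for age in ages]
        return {
            "F": [base * half if b else base for b in biased],
            "M": [base / half if b else base for b in biased],
        }
    if cls == "delayed_up":
        return {
            "F": _step_trajectory(base, fold, (0, 1, 1)),
            "M": _step_trajectory(base, fold, (0, 0, 1)),
        }
    if cls == "delayed_down":
        return {
            "F": _step_trajectory(base, fold, (1, 0, 0)),
            "M": _step_trajectory(base, fold, (1, 1, 0)),
        }
    if cls == "female_only_change":
        return {"F": _step_trajectory(base, fold, (0, 1, 1)), "M": [base] * 3}
    if cls == "male_only_change":
        return {"F": [base] * 3, "M": _step_trajectory(base, fold, (0, 1, 1))}
    if cls == "age_monotone":
        mid = base * np.sqrt(fold)
        return {"F": [base, mid, base * fold], "M": [base, mid, base * fold]}
    raise ConfigError(f"unknown gene class {cls!r}")


def simulate_dataset(
    config: SimConfig,
) -> tuple[ExpressionMatrix, SampleDesign, GeneAnnotation, SyntheticTruth]:
    """Draw one dataset under the configured design.

    Returns the count matrix, the sample design, a gene annotation with
    planted X-linkage, and the ground truth for recovery testing.
    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    ages = sorted(config.ages)
    if len(ages) != 3:
        raise ConfigError("the planted trajectory templates require exactly 3 ages")

    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]

    # class labels: planted blocks first, remainder null, then shuffled
    labels = []
    for cls, frac in config.class_fractions.items():
        labels.extend([cls] * int(round(frac * config.n_genes)))
    labels.extend(["null"] * (config.n_genes - len(labels)))
    labels = np.array(labels[: config.n_genes])
    rng.shuffle(labels)

    base_means = np.exp(
        rng.normal(config.base_mean_log_mu, config.base_mean_log_sigma, config.n_genes)
    )
    lo, hi = config.dispersion_range
    dispersions = rng.uniform(lo, hi, config.n_genes) if hi > lo else np.full(config.n_genes, lo)
    fold = 2.0 ** config.effect_lfc

    # sample layout: F3_r1 ... M14_r3, ordered by sex, age, replicate
    sample_ids, sex_of, age_of = [], [], []
    for sex in SEXES:
        for age in ages:
            for rep in range(1, config.replicates + 1):
                sample_ids.append(f"{sex}{age}_r{rep}")
                sex_of.append(sex)
                age_of.append(age)
    design = SampleDesign(
        pd.DataFrame(
            {
                "sample": sample_ids,
                "sex": sex_of,
                "age_days": age_of,
                "replicate": [int(s.split("_r")[1]) for s in sample_ids],
            }
        )
    )
    size_factors = np.exp(rng.normal(0.0, config.size_factor_log_sigma, len(sample_ids)))
    size_factors /= np.exp(np.mean(np.log(size_factors)))  # geometric mean 1

    trajectories: dict[str, dict[tuple[str, int], float]] = {}
    mu_matrix = np.empty((config.n_genes, len(sample_ids)))
    female_biased = rng.random(config.n_genes) < config.female_biased_fraction
    for i, (g, cls) in enumerate(zip(gene_ids, labels)):
        gene_fold = fold
        if cls == "sex_biased" and not female_biased[i]:
            gene_fold = 1.0 / fold
        traj = _assign_trajectories(cls, base_means[i], gene_fold, ages, config.sex_bias_ages)
        trajectories[g] = {
            (sex, age): traj[sex][k] for sex in SEXES for k, age in enumerate(ages)
        }
        for j, s in enumerate(sample_ids):
            mu_matrix[i, j] = traj[sex_of[j]][ages.index(age_of[j])]

    mean = mu_matrix * size_factors[None, :]
    counts = np.empty_like(mean, dtype=np.int64)
    overdispersed = dispersions > 0
    if overdispersed.any():
        a = dispersions[overdispersed][:, None]
        m = mean[overdispersed]
        n_param = 1.0 / a  # NB shape; p = 1 / (1 + alpha * mean)
        counts[overdispersed] = rng.negative_binomial(n_param, n_param / (n_param + m))
    if (~overdispersed).any():
        counts[~overdispersed] = rng.poisson(mean[~overdispersed])

    matrix = ExpressionMatrix(pd.DataFrame(counts, index=gene_ids, columns=sample_ids))

    # X-linkage: sex-biased genes get boosted odds of being X-linked
    base_odds = config.x_fraction / max(1.0 - config.x_fraction, 1e-12)
    boosted = base_odds * config.x_enrichment_in_sex_biased
    p_x = np.where(
        labels == "sex_biased", boosted / (1.0 + boosted), config.x_fraction
    )
    on_x = rng.random(config.n_genes) < p_x
    annotation = GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": gene_ids,
                "chromosome": np.where(on_x, "X", "2L"),
                "detected": True,
                "annotated": True,
            }
        )
    )

    truth = SyntheticTruth(
        gene_class=dict(zip(gene_ids, labels)),
        trajectories=trajectories,
        size_factors=dict(zip(sample_ids, size_factors)),
        dispersions=dict(zip(gene_ids, dispersions)),
    )
    return matrix, design, annotation, truth


def inject_outlier(
    matrix: ExpressionMatrix, sample_id: str, severity: float, seed: int = 0
) -> ExpressionMatrix:
    """Perturb one sample by multiplying a random half of its genes by ``severity``.

    Shifts the sample in expression space (for PCA outlier-flagging tests)
    while leaving every other sample untouched.  Counts are re-rounded to
    integers.
    """
    if severity <= 0:
        raise ConfigError("severity must be positive")
    if sample_id not in matrix.counts.columns:
        raise KeyError(f"unknown sample {sample_id!r}")
    rng = np.random.default_rng(seed)
    counts = matrix.counts.copy()
    n = matrix.n_genes
    chosen = rng.choice(n, size=n // 2, replace=False)
    col = counts[sample_id].to_numpy().astype(float)
    col[chosen] = np.rint(col[chosen] * severity)
    counts[sample_id] = col.astype(np.int64)
    return ExpressionMatrix(counts)
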