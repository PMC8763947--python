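"""Synthetic cohorts with the statistical structure the analysis assumes.

Two generators replace the study's non-deposited raw data:

* :func:`generate_expression_cohort` — a bulk RNA-seq count matrix with two
  histology-driven sample clusters, a squamous marker gene elevated in one
  cluster, and a target gene set over-expressed in a therapy-resistant
  subgroup.  Counts follow a negative-binomial model (the standard bulk
  RNA-seq noise model) around log-normal gene baselines, with per-sample
  sequencing-depth factors so that size-factor normalization is exercised
  realistically.
* :func:`generate_pdx_trial` — caliper measurement tables for a xenograft
  trial: exponential per-group tumor growth or shrinkage with multiplicative
  log-normal measurement noise, decomposed into (length, width) pairs that
  reconstruct the noisy volume exactly, plus a Gaussian random-walk body
  weight to exercise the tolerability flag.

Both generators are deterministic given their config's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pdxnet.io import ExpressionMatrix

#: The nine-gene paracrine signaling set of the tumorigenic network:
#: VEGF, EGF, HGF and SDF-1alpha ligand/receptor axes plus COX2.
TARGET_SET = ["CXCL12", "CXCR4", "EGF", "EGFR", "HGF", "KDR", "MET", "PTGS2", "VEGFA"]

#: Squamous-cell-carcinoma marker gene.
MARKER_GENE = "TP63"

# Fixed width:length aspect ratio for decomposing a volume into caliper axes.
_ASPECT = 0.8


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class CohortConfig:
    """Parameters of the expression-cohort generator.

    Defaults mirror the study cohort: 19,096 HGNC genes x 38 PDX models,
    26 squamous (cluster A, marker-high) vs 12 adenocarcinoma samples, and
    12/38 of the models highly therapy-resistant.  Effect sizes are additive
    on the log2 scale of the gene's mean.
    """

    n_genes: int = 19096
    n_samples: int = 38
    marker_gene: str = MARKER_GENE
    target_set: list[str] = field(default_factory=lambda: list(TARGET_SET))
    n_cluster_a: int = 26
    resistant_fraction: float = 12 / 38
    marker_shift: float = 8.0
    marker_baseline_log2: float = 5.5
    target_shift: float = 2.0
    n_cluster_genes: int = 300
    cluster_shift: float = 2.0
    nb_dispersion: float = 0.1
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    depth_log_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_samples <= 0:
            raise ConfigError("n_genes and n_samples must be positive")
        if not 0 <= self.n_cluster_a <= self.n_samples:
            raise ConfigError("n_cluster_a must lie in [0, n_samples]")
        if not 0.0 <= self.resistant_fraction <= 1.0:
            raise ConfigError("resistant_fraction must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        for name in ("marker_shift", "target_shift", "cluster_shift"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigError(f"{name} must be finite")
        named = dict.fromkeys([self.marker_gene, *self.target_set])
        if len(named) + self.n_cluster_genes > self.n_genes:
            raise ConfigError(
                "gene universe too small for marker, target set and cluster genes"
            )


@dataclass
class TrialConfig:
    """Parameters of the caliper-trial generator.

    Defaults mirror the study design: groups of 3 mice randomized at a mean
    tumor volume of 150-200 mm^3, measured twice weekly over four 7-day
    treatment cycles.  ``growth_rate_per_day`` maps each group to an
    exponential rate (negative = shrinkage).
    """

    n_animals_per_group: int = 3
    groups: list[str] = field(default_factory=lambda: ["placebo", "combination"])
    baseline_volume_range: tuple[float, float] = (150.0, 200.0)
    growth_rate_per_day: dict[str, float] = field(
        default_factory=lambda: {"placebo": 0.08, "combination": -0.05}
    )
    measurement_cv: float = 0.05
    weight_drift_sd: float = 0.1
    weight_trend_per_day: dict[str, float] = field(default_factory=dict)
    baseline_weight_g: float = 26.0
    baseline_weight_sd: float = 1.5
    days: list[int] = field(
        default_factory=lambda: [0, 3, 7, 10, 14, 17, 21, 24, 28]
    )
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise ConfigError("at least one group required")
        if self.n_animals_per_group < 1:
            raise ConfigError("n_animals_per_group must be >= 1")
        if not self.days:
            raise ConfigError("at least one measurement day required")
        if self.days[0] != 0:
            raise ConfigError("day 0 (randomization) must be present")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ConfigError("days must be strictly increasing")
        lo, hi = self.baseline_volume_range
        if not 0 < lo <= hi:
            raise ConfigError("baseline_volume_range must be positive and ordered")
        if self.measurement_cv < 0:
            raise ConfigError("measurement_cv must be non-negative")
        missing = [g for g in self.groups if g not in self.growth_rate_per_day]
        if missing:
            raise ConfigError(f"growth_rate_per_day missing groups: {missing}")


def gene_universe(config: CohortConfig) -> list[str]:
    """Gene symbols of the cohort: marker + target set + numbered fillers."""
    named = list(dict.fromkeys([config.marker_gene, *config.target_set]))
    fillers = [f"GENE{i:05d}" for i in range(config.n_genes - len(named))]
    return named + fillers


def generate_expression_cohort(
    config: CohortConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw a raw-count cohort and its sample metadata.

    Returns the counts as an :class:`ExpressionMatrix` (``raw_counts`` scale)
    and a metadata frame indexed by sample with columns ``histology``
    (A = marker-high cluster), ``prior_best_response`` and ``resistant``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = gene_universe(config)
    named = dict.fromkeys([config.marker_gene, *config.target_set])
    samples = [f"PDX{i + 1:03d}" for i in range(config.n_samples)]
    histology = np.array(
        ["A"] * config.n_cluster_a + ["B"] * (config.n_samples - config.n_cluster_a)
    )

    n_resistant = int(round(config.resistant_fraction * config.n_samples))
    resistant = np.zeros(config.n_samples, dtype=bool)
    resistant[rng.choice(config.n_samples, size=n_resistant, replace=False)] = True

    # log2-scale gene baselines and per-sample sequencing depth; the marker's
    # baseline is pinned because the downstream cutoff is an absolute value
    base_log2 = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)
    base_log2[genes.index(config.marker_gene)] = config.marker_baseline_log2
    depth = np.exp(rng.normal(0.0, config.depth_log_sd, config.n_samples))

    shift = np.zeros((config.n_genes, config.n_samples))
    in_a = histology == "A"
    marker_idx = genes.index(config.marker_gene)
    shift[marker_idx, in_a] += config.marker_shift
    target_idx = [genes.index(g) for g in config.target_set]
    shift[np.ix_(target_idx, resistant)] += config.target_shift
    # histology-driven block: the first n_cluster_genes filler genes
    cluster_idx = np.arange(len(named), len(named) + config.n_cluster_genes)
    shift[np.ix_(cluster_idx, in_a)] += config.cluster_shift

    mu = 2.0 ** (base_log2[:, None] + shift) * depth[None, :]
    r = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=samples), scale="raw_counts"
    )
    prior = np.where(
        resistant, "PD", rng.choice(["PR", "SD"], size=config.n_samples)
    )
    metadata = pd.DataFrame(
        {"histology": histology, "prior_best_response": prior, "resistant": resistant},
        index=pd.Index(samples, name="sample"),
    )
    return matrix, metadata


def volume_to_axes(volume: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a volume into (length, width) with width = 0.8 x length.

    With V = length * width^2 / 2 and the fixed aspect ratio this gives
    V = 0.32 * length^3, so the decomposition reconstructs V exactly.
    """
    length = np.cbrt(np.asarray(volume, dtype=float) / (_ASPECT**2 / 2.0))
    return length, _ASPECT * length


def generate_pdx_trial(config: TrialConfig) -> pd.DataFrame:
    """Draw a long-format caliper trial table.

    Each animal's true volume follows ``V0 * exp(g * t)``; measurements are
    perturbed by multiplicative log-normal noise with median 1 and coefficient
    of variation ``measurement_cv``, then decomposed into caliper axes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    days = np.asarray(config.days, dtype=float)
    sigma = math.sqrt(math.log1p(config.measurement_cv**2))

    records = []
    for group in config.groups:
        g = config.growth_rate_per_day[group]
        trend = config.weight_trend_per_day.get(group, 0.0)
        for i in range(config.n_animals_per_group):
            animal = f"{group}_{i + 1:02d}"
            v0 = rng.uniform(*config.baseline_volume_range)
            noise = np.exp(rng.normal(0.0, sigma, len(days))) if sigma > 0 else np.ones(len(days))
            volume = v0 * np.exp(g * days) * noise
            length, width = volume_to_axes(volume)
            w0 = rng.normal(config.baseline_weight_g, config.baseline_weight_sd)
            dt = np.diff(days, prepend=0.0)
            steps = rng.normal(trend * dt, config.weight_drift_sd * np.sqrt(dt))
            steps[0] = 0.0  # day 0 is the baseline weight
            weight = w0 + np.cumsum(steps)
            for k, day in enumerate(config.days):
                records.append(
                    {
                        "animal_id": animal,
                        "group": group,
                        "day": day,
                        "length_mm": length[k],
                        "width_mm": width[k],
                        "body_weight_g": weight[k],
                    }
                )
    return pd.DataFrame.from_records(records)
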