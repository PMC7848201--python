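"""Shared configuration objects and canonical constants.

All stage configurations are plain dataclasses with a ``validate`` method
that raises :class:`ConfigurationError` naming the offending field.  The
canonical physiological-state order and the circannual transition graph are
defined here and used unchanged by every stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "STATES",
    "TRANSITIONS",
    "WARM_STATES",
    "COLD_STATES",
    "ConfigurationError",
    "SimulationConfig",
    "FilterRule",
    "DEConfig",
    "StateGraph",
    "ClusterConfig",
    "SpliceConfig",
    "MergeRules",
    "SymbolRules",
    "AREConfig",
]

#: Canonical ordered physiological states: summer active, interbout aroused,
#: entrance, late torpor, arousing, spring dark.
STATES: tuple[str, ...] = ("SA", "IBA", "Ent", "LT", "Ar", "SpD")

#: Circannual transition graph, ordered around the yearly cycle.
TRANSITIONS: tuple[tuple[str, str], ...] = (
    ("SpD", "SA"),
    ("SA", "IBA"),
    ("IBA", "Ent"),
    ("Ent", "LT"),
    ("LT", "Ar"),
    ("Ar", "IBA"),
    ("IBA", "SpD"),
)

#: States with euthermic (warm) body temperature, and the two cold states.
WARM_STATES: tuple[str, ...] = ("SA", "IBA", "Ent", "SpD")
COLD_STATES: tuple[str, ...] = ("LT", "Ar")


class ConfigurationError(ValueError):
    """Raised when a configuration object fails validation."""


@dataclass
class SimulationConfig:
    """Parameters for the synthetic-data generators.

    ``cluster_fractions`` maps template names to the fraction of genes
    generated from that template; the remainder are null genes with no
    state effect.  Negative-binomial variance is ``mu + dispersion * mu**2``.
    """

    seed: int = 0
    n_per_state: int = 5
    states: tuple[str, ...] = STATES
    n_genes: int = 1000
    cluster_fractions: dict[str, float] = field(default_factory=dict)
    amplitude: float = 2.0
    dispersion: float = 0.05
    baseline_logmean_range: tuple[float, float] = (6.0, 11.0)
    sex_effect_sd: float = 0.2
    libsize_factor_range: tuple[float, float] = (0.7, 1.4)
    region: str = "region1"

    def validate(self) -> None:
        if self.n_per_state < 2:
            raise ConfigurationError("n_per_state must be >= 2")
        if len(set(self.states)) != len(self.states):
            raise ConfigurationError("states must be distinct")
        if self.n_genes < 0:
            raise ConfigurationError("n_genes must be >= 0")
        total = 0.0
        for name, frac in self.cluster_fractions.items():
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(
                    f"cluster_fractions[{name!r}] must be in [0, 1]"
                )
            total += frac
        if total > 1.0 + 1e-9:
            raise ConfigurationError("cluster_fractions must sum to <= 1")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0")
        lo, hi = self.baseline_logmean_range
        if not lo <= hi:
            raise ConfigurationError("baseline_logmean_range must be ordered")
        lo, hi = self.libsize_factor_range
        if not 0 < lo <= hi:
            raise ConfigurationError("libsize_factor_range must be positive, ordered")
        if self.sex_effect_sd < 0:
            raise ConfigurationError("sex_effect_sd must be >= 0")


@dataclass
class FilterRule:
    """Detection filter: a gene is kept when, in at least one state group,
    at least ``min_pass_fraction`` of the replicates have a transformed
    value of at least ``min_transform_value`` (log2 scale)."""

    min_transform_value: float = 7.0
    min_pass_fraction: float = 4.0 / 5.0

    def validate(self) -> None:
        if not 0.0 < self.min_pass_fraction <= 1.0:
            raise ConfigurationError("min_pass_fraction must be in (0, 1]")


@dataclass
class DEConfig:
    """Differential-expression test configuration."""

    lrt_alpha: float = 0.001
    pairwise_alpha: float = 0.001
    shrinkage_sd: float = 1.0
    use_sex_covariate: bool = True

    def validate(self) -> None:
        for name in ("lrt_alpha", "pairwise_alpha"):
            a = getattr(self, name)
            if not 0.0 < a < 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1)")
        if self.shrinkage_sd <= 0:
            raise ConfigurationError("shrinkage_sd must be > 0")


@dataclass
class StateGraph:
    """Ordered transitions between physiological states."""

    transitions: tuple[tuple[str, str], ...] = TRANSITIONS

    def validate(self, states: tuple[str, ...] = STATES) -> None:
        for a, b in self.transitions:
            if a not in states or b not in states:
                raise ConfigurationError(f"transition ({a}, {b}) uses unknown state")


@dataclass
class ClusterConfig:
    """Reference-pattern assignment thresholds."""

    r_min: float = 0.8
    unassigned_label: str = "Unassigned"

    def validate(self) -> None:
        if not 0.0 < self.r_min <= 1.0:
            raise ConfigurationError("r_min must be in (0, 1]")


@dataclass
class SpliceConfig:
    """PSI/dPSI estimation and significance configuration.

    ``prob_threshold`` gates the general significance call; the weaker
    ``ir_prob_threshold`` gates the temperature-dependence scan used when
    selecting control introns.
    """

    delta: float = 0.2
    prob_threshold: float = 0.999
    ir_prob_threshold: float = 0.90
    reference_state: str = "SA"
    prior_pseudocount: float = 0.5
    mc_samples: int = 10_000
    seed: int = 0
    warm_states: tuple[str, ...] = WARM_STATES
    cold_states: tuple[str, ...] = COLD_STATES

    def validate(self) -> None:
        if not 0.0 < self.delta < 1.0:
            raise ConfigurationError("delta must be in (0, 1)")
        for name in ("prob_threshold", "ir_prob_threshold"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1)")
        if self.prior_pseudocount <= 0:
            raise ConfigurationError("prior_pseudocount must be > 0")
        if self.mc_samples < 100:
            raise ConfigurationError("mc_samples must be >= 100")


@dataclass
class MergeRules:
    """Annotation-merge thresholds."""

    short_tx_max_len: int = 1000
    reciprocal_overlap_max: float = 0.90
    min_spliced_reads: int = 1

    def validate(self) -> None:
        if not 0.0 < self.reciprocal_overlap_max <= 1.0:
            raise ConfigurationError("reciprocal_overlap_max must be in (0, 1]")
        if self.min_spliced_reads < 1:
            raise ConfigurationError("min_spliced_reads must be >= 1")
        if self.short_tx_max_len < 1:
            raise ConfigurationError("short_tx_max_len must be >= 1")


@dataclass
class SymbolRules:
    """Homology symbol assignment thresholds and suffix bands."""

    max_evalue: float = 1e-20
    like_cov_low: float = 0.50
    like_cov_high: float = 0.90

    def validate(self) -> None:
        if self.max_evalue < 0:
            raise ConfigurationError("max_evalue must be >= 0")
        if not 0.0 < self.like_cov_low < self.like_cov_high <= 1.0:
            raise ConfigurationError("need 0 < like_cov_low < like_cov_high <= 1")


@dataclass
class AREConfig:
    """AU-rich-element scoring configuration (DNA alphabet)."""

    min_utr_len: int = 200
    pentamer: str = "ATTTA"
    cluster_gap: int = 9
    cluster_bonus: float = 1.5
    high_score_min: float = 8.0

    def validate(self) -> None:
        if self.min_utr_len < len(self.pentamer):
            raise ConfigurationError("min_utr_len must be >= pentamer length")
        if self.cluster_gap < 0:
            raise ConfigurationError("cluster_gap must be >= 0")
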