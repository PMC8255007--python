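"""Configuration objects shared by the simulator and the model-fitting stages."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import hashlib
import json
from typing import Optional, Sequence, Tuple


class ConfigError(ValueError):
    """Raised when a configuration object violates its invariants."""


@dataclass
class VarianceComponents:
    """Variance components of the direct-maternal animal model.

    The model decomposes a 1/2-coded calving response into a random
    herd-year effect, a direct (calf) additive genetic effect, a maternal
    (dam) additive genetic effect with direct-maternal covariance, and a
    residual.  Defaults are the components estimated for multiple birth in
    a large Holstein population (raw scale of the 1/2 coding).
    """

    herd_year: float = 0.992e-4
    direct: float = 0.578e-4
    maternal: float = 0.130e-2
    direct_maternal: float = -0.158e-3
    residual: float = 0.036
    se: Optional[dict] = None

    def validate(self) -> "VarianceComponents":
        for name in ("herd_year", "direct", "maternal", "residual"):
            if getattr(self, name) < 0:
                raise ConfigError(f"variance component {name!r} must be >= 0")
        if self.direct_maternal**2 > self.direct * self.maternal + 1e-300:
            raise ConfigError(
                "direct-maternal covariance exceeds the Cauchy-Schwarz bound"
            )
        return self

    @property
    def phenotypic(self) -> float:
        """Phenotypic variance: sum of all components with the covariance
        counted once."""
        return (
            self.herd_year
            + self.direct
            + self.maternal
            + self.direct_maternal
            + self.residual
        )

    def genetic_covariance_matrix(self):
        import numpy as np

        return np.array(
            [
                [self.direct, self.direct_maternal],
                [self.direct_maternal, self.maternal],
            ]
        )

    def as_tuple(self) -> Tuple[float, float, float, float, float]:
        return (
            self.herd_year,
            self.direct,
            self.maternal,
            self.direct_maternal,
            self.residual,
        )


@dataclass
class QtlSpec:
    """A planted haplotype QTL acting on the dam's maternal genetic value.

    ``effect`` is the additive effect per copy of the focal haplotype on the
    maternal value, on the response scale.  ``target_frequency`` is the
    frequency the focal haplotype should reach in the simulated population.
    """

    chromosome: int = 1
    start_bp: int = 30_500_000
    end_bp: int = 31_100_000
    effect: float = -0.02
    target_frequency: float = 0.275

    def validate(self, n_chromosomes: int, chromosome_length: int) -> "QtlSpec":
        if not (1 <= self.chromosome <= n_chromosomes):
            raise ConfigError("qtl chromosome outside the simulated genome")
        if not (0 <= self.start_bp < self.end_bp <= chromosome_length):
            raise ConfigError("qtl window must lie inside one chromosome")
        if not (0.0 < self.target_frequency < 1.0):
            raise ConfigError("qtl target frequency must be in (0, 1)")
        return self


@dataclass
class SeqPanelSpec:
    """Dense sequence-variant panel around the planted QTL.

    Variants are generated as noisy copies of the planted-haplotype carrier
    indicator: a per-variant allele-flip rate yields a graded, controllable
    r-squared ladder against the haplotype.  One designated causal-proxy
    variant receives the lowest flip rate.
    """

    window_bp: int = 880_000
    n_variants: int = 200
    missing_rate: float = 0.02
    causal_proxy_flip: float = 0.02
    flip_min: float = 0.05
    flip_max: float = 0.45
    frac_independent: float = 0.3
    breeds: Tuple[str, ...] = ("Holstein", "Simmental", "BrownSwiss")
    breed_probs: Optional[Tuple[float, ...]] = None

    def validate(self) -> "SeqPanelSpec":
        if self.window_bp <= 0 or self.n_variants <= 0:
            raise ConfigError("seq panel window and variant count must be > 0")
        for nm in ("missing_rate", "causal_proxy_flip", "flip_min", "flip_max",
                   "frac_independent"):
            v = getattr(self, nm)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"seq panel rate {nm!r} must be in [0, 1]")
        if self.breed_probs is not None and len(self.breed_probs) != len(self.breeds):
            raise ConfigError("breed_probs must match breeds")
        return self


@dataclass
class FixedEffectValues:
    """True per-level fixed-effect values used when simulating phenotypes.

    Defaults follow the published solutions for a national multiple-birth
    evaluation: parity levels 1..5+ (increasing incidence with parity),
    sexed-semen no/yes, seasons spring/summer/fall/winter, plus a linear
    age-of-dam slope per month (deviation from 60 months).
    """

    parity: Tuple[float, ...] = (0.305, 0.356, 0.368, 0.374, 0.379)
    sexed_semen: Tuple[float, float] = (0.354, 0.346)  # (no, yes)
    season: Tuple[float, ...] = (0.346, 0.364, 0.354, 0.351)
    age_slope: float = -0.0002
    intercept: float = 0.33

    def validate(self) -> "FixedEffectValues":
        if len(self.parity) != 5 or len(self.season) != 4:
            raise ConfigError("expected 5 parity levels and 4 seasons")
        return self


@dataclass
class SimulationConfig:
    """Full description of one synthetic herd.

    The generator is deterministic given ``seed``; every output carries the
    seed in its provenance.  ``years`` is the inclusive calving-year range;
    generations are laid out in consecutive blocks of years, with one
    calving per dam per year of her block.
    """

    seed: int = 0
    n_founders: int = 200
    n_generations: int = 2
    n_herds: int = 10
    years: Tuple[int, int] = (2006, 2015)
    n_chromosomes: int = 1
    snps_per_chromosome: int = 300
    chromosome_length: int = 100_000_000
    qtl_spec: Optional[QtlSpec] = None
    variance_components: VarianceComponents = field(default_factory=VarianceComponents)
    fixed_effect_values: FixedEffectValues = field(default_factory=FixedEffectValues)
    phenotype_mode: str = "binary"  # {"gaussian", "binary"}
    binary_threshold: Optional[float] = None
    target_prevalence: float = 0.0356
    seq_panel_spec: SeqPanelSpec = field(default_factory=SeqPanelSpec)
    # population plumbing
    male_fraction: float = 0.5
    founder_male_fraction: float = 0.5
    n_active_sires: int = 150  # AI-sire pool size per generation
    sexed_semen_rate: float = 0.053
    embryo_transfer_rate: float = 0.0
    founder_pool_size: int = 40
    ld_block_bp: int = 500_000
    haplotypes_per_block: int = 6
    recombination_rate: float = 1e-8  # per bp per meiosis (1 cM/Mb)
    breed_labels: Tuple[str, ...] = ("Holstein", "Simmental")
    main_breed_fraction: float = 0.9

    def validate(self) -> "SimulationConfig":
        for nm in ("n_founders", "n_generations", "n_herds", "n_chromosomes",
                   "snps_per_chromosome", "chromosome_length",
                   "founder_pool_size", "haplotypes_per_block"):
            if getattr(self, nm) <= 0:
                raise ConfigError(f"count {nm!r} must be > 0")
        if self.years[1] < self.years[0]:
            raise ConfigError("years range is empty")
        if self.phenotype_mode not in ("gaussian", "binary"):
            raise ConfigError("phenotype_mode must be 'gaussian' or 'binary'")
        if not (0.0 < self.target_prevalence < 1.0):
            raise ConfigError("target prevalence must be in (0, 1)")
        self.variance_components.validate()
        self.fixed_effect_values.validate()
        self.seq_panel_spec.validate()
        if self.qtl_spec is not None:
            self.qtl_spec.validate(self.n_chromosomes, self.chromosome_length)
        return self

    @property
    def n_years(self) -> int:
        return self.years[1] - self.years[0] + 1

    @property
    def years_per_generation(self) -> int:
        return max(1, self.n_years // self.n_generations)

    def config_hash(self) -> str:
        """Stable hash of the configuration, for provenance files."""

        def default(o):
            if hasattr(o, "__dict__"):
                return o.__dict__
            return str(o)

        payload = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
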