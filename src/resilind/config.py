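"""Configuration objects for the simulator and the pipeline driver."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value is out of its admissible range."""


@dataclass
class SimConfig:
    """Parameters of the multi-breed genotype and milking-data simulator.

    Genotypes follow a Balding-Nichols-style model: per-breed allele
    frequencies are Beta-distributed around an ancestral frequency with the
    configured fixation index ``fst``, and haplotypes are drawn from a
    latent first-order autoregressive process along each chromosome so that
    LD (r^2) decays with marker distance at a rate set by
    ``ld_persistence``.

    Phenotypes emulate automatic-milking-system herds: a Wood-type gamma
    lactation curve per cow-lactation, random disturbance events with
    exponential recovery, autocorrelated daily noise, missing cow-days and
    whole-farm outage days, and daily yields decomposed into 2-3 timed
    milking events.  Two genetically controlled cow parameters drive the
    downstream indicators: log disturbance susceptibility (variance-type
    indicators) and residual AR(1) persistence (autocorrelation indicator),
    with disjoint causal loci.

    Default breed sizes and farm count mirror a three-breed German dairy
    study population (Holstein / Fleckvieh / Brown Swiss, 48 farms);
    heritability targets default to the moderate-to-low range reported for
    these indicator traits (0.05-0.15).
    """

    n_breeds: int = 3
    n_per_breed: Sequence[int] = (2300, 2330, 1073)
    n_chrom: int = 29
    n_snp_per_chrom: int = 1100
    fst: float = 0.10
    ld_persistence: float = 0.90
    maf_floor: float = 0.05
    chrom_length_bp: int = 100_000_000
    h2_target: Mapping[str, float] = field(
        default_factory=lambda: {"vd": 0.15, "vr": 0.13, "rauto": 0.05}
    )
    n_qtl: int = 2
    qtl_effect_sd: float = 0.7
    lactation_days: tuple[int, int] = (1, 305)
    disturbance_rate: float = 4.0
    disturbance_depth_sd: float = 5.0
    recovery_halflife_days: float = 7.0
    log_susceptibility_sd: float = 0.5
    persistence_mean: float = 0.35
    persistence_sd: float = 0.12
    noise_sd: float = 1.5
    missing_day_prob: float = 0.02
    farm_outage_prob: float = 0.01
    n_farms: int = 48
    n_lactations_max: int = 3
    study_start: str = "2018-01-01"
    seed: int = 1

    def __post_init__(self) -> None:
        counts = {
            "n_breeds": self.n_breeds,
            "n_chrom": self.n_chrom,
            "n_snp_per_chrom": self.n_snp_per_chrom,
            "n_farms": self.n_farms,
            "n_lactations_max": self.n_lactations_max,
        }
        for name, value in counts.items():
            if int(value) <= 0:
                raise ConfigError(f"{name} must be a positive count, got {value!r}")
        self.n_per_breed = tuple(int(n) for n in self.n_per_breed)
        if len(self.n_per_breed) != self.n_breeds:
            raise ConfigError(
                f"n_per_breed has {len(self.n_per_breed)} entries for "
                f"{self.n_breeds} breeds"
            )
        if any(n <= 0 for n in self.n_per_breed):
            raise ConfigError("all breed sizes must be positive")
        fractions = {
            "fst": self.fst,
            "ld_persistence": self.ld_persistence,
            "maf_floor": self.maf_floor,
            "missing_day_prob": self.missing_day_prob,
            "farm_outage_prob": self.farm_outage_prob,
        }
        for name, value in fractions.items():
            if not 0.0 <= float(value) <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value!r}")
        for trait, h2 in dict(self.h2_target).items():
            if not 0.0 <= float(h2) < 1.0:
                raise ConfigError(f"h2_target[{trait!r}] must lie in [0, 1), got {h2!r}")
        lo, hi = self.lactation_days
        if not (0 < lo < hi):
            raise ConfigError(f"lactation_days must be an increasing day range, got {self.lactation_days}")

    @property
    def n_individuals(self) -> int:
        return int(sum(self.n_per_breed))

    @property
    def breed_names(self) -> list[str]:
        return [f"B{k + 1}" for k in range(self.n_breeds)]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["h2_target"] = dict(self.h2_target)
        d["n_per_breed"] = list(self.n_per_breed)
        d["lactation_days"] = list(self.lactation_days)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "lactation_days" in d:
            d["lactation_days"] = tuple(d["lactation_days"])
        return cls(**d)


#: spline smoothing degrees of freedom for the lactation-curve fit
DEFAULT_SPLINE_DF = 5.0
#: selection-index weights on the (negated, log) variance indicators
SI_WEIGHT_VD = 0.65
SI_WEIGHT_VR = 0.35


@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    ``lactation_group`` selects the analysis population: ``"P"`` uses
    first-lactation records only (no permanent-environment term), ``"M"``
    adds higher lactations as repeated records (permanent-environment term
    included).
    """

    out_dir: str = "resilind_run"
    simulate: SimConfig | None = None
    milkings: str | None = None
    calvings: str | None = None
    bed_prefix: str | None = None
    breeds_file: str | None = None
    lactation_group: str = "P"
    traits: Sequence[str] = ("vd", "vr", "rauto")
    spline_df: float = DEFAULT_SPLINE_DF
    maf_min: float = 0.03
    miss_max: float = 0.01
    gwas_model: str = "auto"
    n_pcs: int = 20
    si_weights: tuple[float, float] = (SI_WEIGHT_VD, SI_WEIGHT_VR)
    make_plots: bool = False
    seed: int = 1

    def __post_init__(self) -> None:
        if self.lactation_group not in ("P", "M"):
            raise ConfigError("lactation_group must be 'P' or 'M'")
        if self.gwas_model not in ("auto", "mlma", "loco", "loco-pc"):
            raise ConfigError("gwas_model must be auto|mlma|loco|loco-pc")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = SimConfig.from_dict(sim)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        if self.simulate is not None:
            raw["simulate"] = self.simulate.to_dict()
        raw["traits"] = list(self.traits)
        raw["si_weights"] = list(self.si_weights)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)
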