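"""Configuration objects for the synthetic methylome and phenotype generators.

Defaults describe a zebrafish-like study: a GC-poor genome, triplicate
bisulfite libraries per genotype, a heavily methylated CG compartment with
sparse low-level CHG/CHH methylation, a maintenance-methylation-deficient
(dnmt1-like) hypomethylated genotype, a replication-slowed (pole1-like)
mildly hypermethylated genotype, and a double mutant in which three
quarters of the single-mutant methylation loss is restored.
"""

from __future__ import annotations

import dataclasses
from typing import Any, Mapping


@dataclasses.dataclass(frozen=True)
class ContextBaseline:
    """Wild-type methylation baseline for one cytosine context.

    p_meth
        Fraction of sites that are methylated at all.
    mu
        Mean methylation ratio of the methylated sites.
    """

    p_meth: float
    mu: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_meth <= 1.0:
            raise ValueError("p_meth must be in [0, 1]")
        if not 0.0 < self.mu < 1.0:
            raise ValueError("mu must be in (0, 1)")


def _default_baseline() -> dict[str, ContextBaseline]:
    return {
        "CG": ContextBaseline(p_meth=0.80, mu=0.80),
        "CHG": ContextBaseline(p_meth=0.05, mu=0.35),
        "CHH": ContextBaseline(p_meth=0.05, mu=0.30),
    }


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """All effect sizes, noise parameters and the seed for methylome simulation.

    The four simulated genotypes are wild type (``wt``), a hypomethylating
    single mutant (``dnmt1``), a hypermethylating single mutant (``pole1``)
    and their double mutant (``double``).  ``rho`` is the fraction of the
    hypomethylation that is restored in the double; ``conversion_failure``
    and ``overconversion`` model bisulfite chemistry errors; the SNP
    parameters plant illegitimate-base contamination at a subset of sites.
    """

    seed: int = 0
    genome_length: int = 50_000
    gc_content: float = 0.37
    n_replicates_per_genotype: int = 3
    coverage_mean: float = 20.0
    baseline_meth: dict[str, ContextBaseline] = dataclasses.field(
        default_factory=_default_baseline
    )
    hypo_factor: float = 0.5
    p_loss_CHG: float = 0.5
    p_loss_CHH: float = 0.3
    hyper_factor: float = 1.15
    p_gain_CHG: float = 0.02
    p_gain_CHH: float = 0.05
    rho: float = 0.75
    conversion_failure: float = 0.005
    overconversion: float = 0.005
    snp_site_frac: float = 0.01
    snp_allele_frac: float = 0.5
    beta_concentration: float = 20.0

    def __post_init__(self) -> None:
        probs = (
            "gc_content",
            "hypo_factor",
            "p_loss_CHG",
            "p_loss_CHH",
            "p_gain_CHG",
            "p_gain_CHH",
            "rho",
            "conversion_failure",
            "overconversion",
            "snp_site_frac",
            "snp_allele_frac",
        )
        for name in probs:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.hyper_factor < 1.0:
            raise ValueError("hyper_factor must be >= 1")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be > 0")
        if self.genome_length < 10:
            raise ValueError("genome_length must be >= 10")
        if self.n_replicates_per_genotype < 1:
            raise ValueError("need at least one replicate per genotype")
        if self.beta_concentration <= 0:
            raise ValueError("beta_concentration must be > 0")
        if set(self.baseline_meth) != {"CG", "CHG", "CHH"}:
            raise ValueError("baseline_meth must have exactly the keys CG, CHG, CHH")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "SyntheticConfig":
        return _from_mapping(cls, mapping, nested={"baseline_meth": _parse_baseline})

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["baseline_meth"] = {
            k: dataclasses.asdict(v) for k, v in self.baseline_meth.items()
        }
        return d


@dataclasses.dataclass(frozen=True)
class PhenotypeConfig:
    """Generator settings for per-fish phenotype tables.

    Genotypes are labelled ``wt``, ``x``, ``y`` and ``xy``.  The
    thymopoietic channel draws a gh (internal control) area per fish and
    multiplies it by ``index_scale`` (kappa) times the genotype's true
    fitness and lognormal measurement noise to obtain the rag1 area; the
    eye channel is built the same way around ``eye_mean``.  ``epsilon_true``
    is the true log2 interaction: the double mutant's fitness is
    ``W_x * W_y * 2**epsilon_true``.
    """

    seed: int = 0
    n_fish_per_genotype: int = 30
    gh_mean: float = 1.0
    gh_sd: float = 0.15
    index_scale: float = 2.0
    W_x: float = 0.4
    W_y: float = 0.15
    epsilon_true: float = 2.0
    noise_cv: float = 0.2
    eye_mean: float = 1.0
    eye_sd: float = 0.1
    eye_W_x: float = 1.0
    eye_W_y: float = 0.8
    eye_epsilon_true: float = 0.5

    def __post_init__(self) -> None:
        if self.n_fish_per_genotype < 2:
            raise ValueError("need at least two fish per genotype")
        for name in ("W_x", "W_y", "eye_W_x", "eye_W_y"):
            if not 0.0 < getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        for name in ("gh_mean", "gh_sd", "index_scale", "eye_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.eye_sd < 0:
            raise ValueError("eye_sd must be >= 0")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "PhenotypeConfig":
        return _from_mapping(cls, mapping)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _parse_baseline(value: Mapping[str, Any]) -> dict[str, ContextBaseline]:
    out = {}
    for ctx, pair in value.items():
        if isinstance(pair, ContextBaseline):
            out[ctx] = pair
        else:
            out[ctx] = ContextBaseline(**dict(pair))
    return out


def _from_mapping(cls, mapping, nested=None):
    nested = nested or {}
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(mapping)
    for key, parse in nested.items():
        if key in kwargs:
            kwargs[key] = parse(kwargs[key])
    return cls(**kwargs)
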