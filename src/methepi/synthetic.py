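"""Synthetic genotype-structured methylomes and phenotype tables.

The generator produces the ground truth the downstream analyses try to
recover: a random reference sequence, a latent per-site methylation ratio
for each of four genotypes, replicate-level read counts with bisulfite
conversion errors and SNP contamination, and per-fish phenotype areas with
an internal-control channel.  Latent ratios are returned alongside the
observed counts so recovery can be checked against truth.

Randomness is organised so that every (genotype, replicate) pair owns its
own RNG stream derived from the seed; adding replicates never perturbs
existing ones, and identical configs give bit-identical output.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .config import PhenotypeConfig, SyntheticConfig
from .context import enumerate_cytosines, site_frame

GENOTYPES = ("wt", "dnmt1", "pole1", "double")
PHENO_GENOTYPES = ("wt", "x", "y", "xy")

# stable stream codes so streams never collide or depend on dict order
_STREAM = {"reference": 0, "latent": 1, "phenotype": 2}
_GENOTYPE_CODE = {g: i + 10 for i, g in enumerate(GENOTYPES)}
_PHENO_CODE = {g: i + 20 for i, g in enumerate(PHENO_GENOTYPES)}


def _rng(seed: int, *codes: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, *codes)))


def generate_reference(config: SyntheticConfig) -> str:
    """Random reference sequence of the configured length and GC content."""
    if config.genome_length < 10:
        raise ValueError("genome_length must be >= 10")
    rng = _rng(config.seed, _STREAM["reference"])
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=config.genome_length, p=p)
    return bases.tobytes().decode("ascii")


def _latent_ratios(config: SyntheticConfig, sites: pd.DataFrame) -> pd.DataFrame:
    """Latent per-site true methylation ratio for each genotype.

    Wild type draws methylated/unmethylated status per context and a Beta
    ratio around the context mean for methylated sites.  The dnmt1-like
    genotype scales ratios down and stochastically zeroes methylated
    CHG/CHH sites; the pole1-like genotype scales up (capped at 1) and
    lets unmethylated non-CG sites gain methylation; the double mutant
    moves the dnmt1-like ratio a fraction ``rho`` back toward wild type
    and then applies the gain step at CHH, so doubles can overshoot wild
    type there.
    """
    rng = _rng(config.seed, _STREAM["latent"])
    n = len(sites)
    ctx = sites["context"].to_numpy()
    k = config.beta_concentration

    r_wt = np.zeros(n)
    mu_by_ctx = {c: b.mu for c, b in config.baseline_meth.items()}
    for c, base in config.baseline_meth.items():
        mask = ctx == c
        m = int(mask.sum())
        if m == 0:
            continue
        methylated = rng.random(m) < base.p_meth
        draws = rng.beta(base.mu * k, (1 - base.mu) * k, size=m)
        r_wt[mask] = np.where(methylated, np.clip(draws, 0.0, 1.0), 0.0)

    # dnmt1-like: global scaling down plus stochastic loss of non-CG sites
    r_dnmt1 = r_wt * config.hypo_factor
    for c, p_loss in (("CHG", config.p_loss_CHG), ("CHH", config.p_loss_CHH)):
        mask = (ctx == c) & (r_wt > 0)
        lost = rng.random(int(mask.sum())) < p_loss
        idx = np.flatnonzero(mask)[lost]
        r_dnmt1[idx] = 0.0

    # pole1-like: scaling up with de novo gains at unmethylated non-CG sites
    r_pole1 = np.minimum(1.0, r_wt * config.hyper_factor)
    for c, p_gain in (("CHG", config.p_gain_CHG), ("CHH", config.p_gain_CHH)):
        mask = (ctx == c) & (r_wt == 0)
        gained = rng.random(int(mask.sum())) < p_gain
        idx = np.flatnonzero(mask)[gained]
        r_pole1[idx] = np.clip(
            rng.beta(mu_by_ctx[c] * k, (1 - mu_by_ctx[c]) * k, size=idx.size), 0.0, 1.0
        )

    # double: partial restoration toward wild type, then CHH gains
    r_double = r_dnmt1 + config.rho * (r_wt - r_dnmt1)
    mask = (ctx == "CHH") & (r_double == 0)
    gained = rng.random(int(mask.sum())) < config.p_gain_CHH
    idx = np.flatnonzero(mask)[gained]
    mu_chh = mu_by_ctx["CHH"]
    r_double[idx] = np.clip(
        rng.beta(mu_chh * k, (1 - mu_chh) * k, size=idx.size), 0.0, 1.0
    )

    snp_site = rng.random(n) < config.snp_site_frac

    truth = sites[["chrom", "start", "end", "strand", "context"]].copy()
    truth["r_wt"] = r_wt
    truth["r_dnmt1"] = r_dnmt1
    truth["r_pole1"] = r_pole1
    truth["r_double"] = r_double
    truth["snp_site"] = snp_site
    return truth


def _observe(
    config: SyntheticConfig,
    truth: pd.DataFrame,
    genotype: str,
    replicate: int,
) -> pd.DataFrame:
    rng = _rng(config.seed, _GENOTYPE_CODE[genotype], replicate)
    r = truth[f"r_{genotype}"].to_numpy()
    coverage = rng.poisson(config.coverage_mean, size=len(truth))
    p_read_meth = r * (1 - config.overconversion) + (1 - r) * config.conversion_failure
    n_meth = rng.binomial(coverage, p_read_meth)
    n_ill = np.where(
        truth["snp_site"].to_numpy(),
        rng.binomial(coverage, config.snp_allele_frac),
        0,
    )
    return site_frame(
        chrom=truth["chrom"].to_numpy(),
        start=truth["start"].to_numpy(),
        strand=truth["strand"].to_numpy(),
        context=truth["context"].to_numpy(),
        n_meth=n_meth,
        n_unmeth=coverage - n_meth,
        n_illegitimate=n_ill,
    )


def simulate_methylome_set(
    config: SyntheticConfig, reference: str, chrom: str = "chr1"
) -> tuple[dict[str, list[pd.DataFrame]], pd.DataFrame]:
    """Simulate replicate methylomes for all four genotypes.

    Returns ``(methylomes, truth)``: a mapping genotype -> list of
    replicate site-record frames (all classifiable cytosines, both
    strands, including zero-coverage sites), and the latent truth table
    with one ``r_<genotype>`` column per genotype.
    """
    sites = enumerate_cytosines(reference, chrom=chrom)
    truth = _latent_ratios(config, sites)
    methylomes = {
        g: [
            _observe(config, truth, g, rep)
            for rep in range(config.n_replicates_per_genotype)
        ]
        for g in GENOTYPES
    }
    return methylomes, truth


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal draws redrawn until positive (positive areas only)."""
    out = rng.normal(mean, sd, size=n)
    while True:
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))


def true_fitness(config: PhenotypeConfig) -> dict[str, dict[str, float]]:
    """True per-genotype fitness for both phenotype channels."""
    return {
        "thymopoietic_index": {
            "wt": 1.0,
            "x": config.W_x,
            "y": config.W_y,
            "xy": config.W_x * config.W_y * 2.0**config.epsilon_true,
        },
        "eye_size": {
            "wt": 1.0,
            "x": config.eye_W_x,
            "y": config.eye_W_y,
            "xy": config.eye_W_x * config.eye_W_y * 2.0**config.eye_epsilon_true,
        },
    }


def simulate_phenotypes(config: PhenotypeConfig) -> pd.DataFrame:
    """Per-fish phenotype table: fish_id, genotype, rag1_area, gh_area, eye_size.

    gh areas are positive-truncated normal; rag1 areas multiply the fish's
    gh area by kappa, the genotype's true fitness, and lognormal
    measurement noise whose coefficient of variation is ``noise_cv``.
    The eye channel mirrors this around its own baseline.
    """
    if config.n_fish_per_genotype < 2:
        raise ValueError("need at least two fish per genotype")
    sigma = float(np.sqrt(np.log1p(config.noise_cv**2)))
    w = true_fitness(config)
    frames = []
    for genotype in PHENO_GENOTYPES:
        rng = _rng(config.seed, _STREAM["phenotype"], _PHENO_CODE[genotype])
        n = config.n_fish_per_genotype
        gh = _truncated_normal(rng, config.gh_mean, config.gh_sd, n)
        noise = rng.lognormal(0.0, sigma, size=n) if sigma > 0 else np.ones(n)
        rag1 = gh * config.index_scale * w["thymopoietic_index"][genotype] * noise
        eye_base = _truncated_normal(rng, config.eye_mean, config.eye_sd, n)
        eye_noise = rng.lognormal(0.0, sigma, size=n) if sigma > 0 else np.ones(n)
        eye = eye_base * w["eye_size"][genotype] * eye_noise
        frames.append(
            pd.DataFrame(
                {
                    "fish_id": [f"{genotype}_{i:03d}" for i in range(n)],
                    "genotype": genotype,
                    "rag1_area": rag1,
                    "gh_area": gh,
                    "eye_size": eye,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
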