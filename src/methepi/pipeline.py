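"""End-to-end pipeline: simulate -> context/filter -> summarize -> DMR -> interaction.

A single mapping (usually loaded from YAML) configures every stage; the
pipeline writes all intermediate files plus one JSON report embedding the
context summaries, DMR list, interaction results, resolved configuration,
package version and seed.  Partial failures leave a MANIFEST naming the
stages that completed.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .config import PhenotypeConfig, SyntheticConfig
from .context import CONTEXTS, FilterParams, merge_cg_strands
from .dmr import DmrParams, call_dmrs
from .interaction import METRICS, analyze_pair
from .io import split_by_context, write_bedgraph, write_fasta, write_phenotypes
from .summary import context_summaries, fraction_vs_mean, restoration_fraction
from .synthetic import generate_reference, simulate_methylome_set, simulate_phenotypes

logger = logging.getLogger("methepi")

_TOP_LEVEL_KEYS = {
    "seed",
    "stages",
    "log_level",
    "synthetic",
    "phenotypes",
    "filters",
    "dmr",
    "interaction",
}
_ALL_STAGES = ("simulate", "summarize", "dmr", "interact")


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, Mapping):
        raise ValueError(f"{path}: run config must be a mapping")
    return validate_config(cfg)


def validate_config(config: Mapping[str, Any]) -> dict[str, Any]:
    """Reject unknown keys before any computation runs; idempotent."""
    unknown = set(config) - _TOP_LEVEL_KEYS - {"dmr_groups"}
    if unknown:
        raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
    cfg = dict(config)
    seed = int(cfg.get("seed", 0))
    cfg["seed"] = seed
    stages = cfg.get("stages", list(_ALL_STAGES))
    bad = set(stages) - set(_ALL_STAGES)
    if bad:
        raise ValueError(f"unknown stages: {sorted(bad)}")
    cfg["stages"] = list(stages)
    if not isinstance(cfg.get("synthetic"), SyntheticConfig):
        syn = dict(cfg.get("synthetic", {}))
        syn.setdefault("seed", seed)
        cfg["synthetic"] = SyntheticConfig.from_mapping(syn)
    if not isinstance(cfg.get("phenotypes"), PhenotypeConfig):
        phe = dict(cfg.get("phenotypes", {}))
        phe.setdefault("seed", seed)
        cfg["phenotypes"] = PhenotypeConfig.from_mapping(phe)
    if not isinstance(cfg.get("filters"), FilterParams):
        cfg["filters"] = FilterParams(**cfg.get("filters", {}))
    if not isinstance(cfg.get("dmr"), DmrParams):
        dmr_cfg = dict(cfg.get("dmr", {}))
        cfg["dmr_groups"] = (
            dmr_cfg.pop("group_a", "dnmt1"),
            dmr_cfg.pop("group_b", "wt"),
        )
        cfg["dmr"] = DmrParams(**dmr_cfg)
    inter = dict(cfg.get("interaction", {}))
    inter.setdefault("alpha", 0.05)
    inter.setdefault("error_mode", "standard")
    inter.setdefault("metrics", list(METRICS))
    unknown_inter = set(inter) - {"alpha", "error_mode", "metrics"}
    if unknown_inter:
        raise ValueError(f"unknown interaction keys: {sorted(unknown_inter)}")
    cfg["interaction"] = inter
    return cfg


def _resolved_config(cfg: Mapping[str, Any]) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for key, value in cfg.items():
        if key == "dmr_groups":
            continue
        if hasattr(value, "to_dict"):
            out[key] = value.to_dict()
        elif dataclasses.is_dataclass(value) and not isinstance(value, type):
            out[key] = dataclasses.asdict(value)
        else:
            out[key] = value
    out["dmr"]["group_a"], out["dmr"]["group_b"] = cfg["dmr_groups"]
    return out


def run_pipeline(config: Mapping[str, Any], outdir: str | Path) -> dict[str, Any]:
    """Execute the configured stages and write the aggregated JSON report.

    Returns the report dict; raises after writing a MANIFEST if a stage
    fails.  Identical configs produce identical reports up to the
    timestamp field.
    """
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    resolved = _resolved_config(cfg)
    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=True)
    logger.info("seed = %d; stages = %s", cfg["seed"], cfg["stages"])

    report: dict[str, Any] = {
        "version": __version__,
        "seed": cfg["seed"],
        "config": resolved,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    completed: list[str] = []
    try:
        methylomes = truth = phenotypes = None
        if "simulate" in cfg["stages"]:
            methylomes, truth, phenotypes = _stage_simulate(cfg, outdir)
            completed.append("simulate")
        if "summarize" in cfg["stages"]:
            report["context_summaries"], report["restoration"] = _stage_summarize(
                cfg, methylomes, outdir
            )
            completed.append("summarize")
        if "dmr" in cfg["stages"]:
            report["dmrs"] = _stage_dmr(cfg, methylomes, outdir)
            completed.append("dmr")
        if "interact" in cfg["stages"]:
            report["interaction"] = _stage_interact(cfg, phenotypes)
            completed.append("interact")
    except Exception:
        (outdir / "MANIFEST").write_text(
            "completed stages:\n" + "".join(f"- {s}\n" for s in completed)
        )
        raise
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _stage_simulate(cfg, outdir):
    syn: SyntheticConfig = cfg["synthetic"]
    reference = generate_reference(syn)
    write_fasta({"chr1": reference}, outdir / "reference.fa")
    methylomes, truth = simulate_methylome_set(syn, reference)
    for genotype, replicates in methylomes.items():
        for i, rec in enumerate(replicates):
            for ctx, sub in split_by_context(rec).items():
                write_bedgraph(sub, outdir / f"{genotype}_rep{i}_{ctx}.bedGraph")
    truth.to_csv(outdir / "truth_latent.tsv", sep="\t", index=False, float_format="%.6g")
    phenotypes = simulate_phenotypes(cfg["phenotypes"])
    write_phenotypes(phenotypes, outdir / "phenotypes.tsv")
    return methylomes, truth, phenotypes


def _groups_by_context(methylomes):
    out: dict[str, dict[str, list[pd.DataFrame]]] = {}
    for ctx in CONTEXTS:
        out[ctx] = {}
        for genotype, replicates in methylomes.items():
            recs = []
            for rec in replicates:
                sub = rec.loc[rec["context"] == ctx]
                recs.append(merge_cg_strands(sub) if ctx == "CG" else sub)
            out[ctx][genotype] = recs
    return out


def _stage_summarize(cfg, methylomes, outdir):
    if methylomes is None:
        raise ValueError("summarize stage requires the simulate stage")
    groups = _groups_by_context(methylomes)
    summaries = context_summaries(groups, reference_condition="wt", params=cfg["filters"])
    summaries.to_csv(outdir / "context_summaries.tsv", sep="\t", index=False)
    fraction_vs_mean(summaries).to_csv(
        outdir / "fraction_vs_mean.tsv", sep="\t", index=False
    )
    restoration = {}
    for ctx in CONTEXTS:
        means = summaries.loc[summaries["context"] == ctx].set_index("genotype")[
            "mean_ratio"
        ]
        restoration[ctx] = restoration_fraction(
            means["wt"], means["dnmt1"], means["double"]
        )
    return summaries.to_dict(orient="records"), restoration


def _stage_dmr(cfg, methylomes, outdir):
    if methylomes is None:
        raise ValueError("dmr stage requires the simulate stage")
    ga, gb = cfg["dmr_groups"]
    group_a = [merge_cg_strands(r.loc[r["context"] == "CG"]) for r in methylomes[ga]]
    group_b = [merge_cg_strands(r.loc[r["context"] == "CG"]) for r in methylomes[gb]]
    dmrs = call_dmrs(group_a, group_b, cfg["dmr"])
    dmrs.to_csv(outdir / "dmrs.tsv", sep="\t", index=False, float_format="%.6g")
    return dmrs.to_dict(orient="records")


def _stage_interact(cfg, phenotypes):
    if phenotypes is None:
        raise ValueError("interact stage requires the simulate stage")
    inter = cfg["interaction"]
    results = {}
    for metric in inter["metrics"]:
        result, estimates = analyze_pair(
            phenotypes,
            metric=metric,
            alpha=inter["alpha"],
            error_mode=inter["error_mode"],
        )
        results[metric] = {
            "result": dataclasses.asdict(result),
            "fitness": [dataclasses.asdict(e) for e in estimates],
        }
    return results
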