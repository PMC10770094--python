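"""Per-genotype, per-context methylome summaries.

Site counts use the union of replicates per condition; ratio statistics
(mean, median, scaled m.a.d.) use the site matrix restricted to the
intersection of all replicates in all conditions.  The asymmetry is
deliberate: counting asks how many distinct sites carry methylation at
all, while the ratio distributions are only comparable across genotypes
on a common site set.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .context import FilterParams, apply_site_filters, intersect_sites, validate_sites

MAD_CONSISTENCY = 1.4826


def count_methylated_sites(
    groups: Mapping[str, Sequence[pd.DataFrame]],
    params: FilterParams | None = None,
) -> dict[str, int]:
    """Distinct methylated sites in the union of each condition's replicates.

    A site counts if it passes the filters (by default including the
    ratio > 0 requirement) in at least one replicate of the condition.
    """
    params = params if params is not None else FilterParams()
    counts: dict[str, int] = {}
    for condition, replicates in groups.items():
        keys: set[tuple] = set()
        for rec in replicates:
            kept = apply_site_filters(rec, params)
            keys.update(
                zip(kept["chrom"], kept["start"], kept["strand"])
            )
        counts[condition] = len(keys)
    return counts


def normalize_counts(
    counts: Mapping[str, float], reference_condition: str
) -> dict[str, float]:
    """Rescale counts so the reference condition maps to exactly 100."""
    ref = counts[reference_condition]
    if ref <= 0:
        raise ValueError("reference condition has zero site count")
    out = {c: 100.0 * v / ref for c, v in counts.items()}
    out[reference_condition] = 100.0
    return out


def summarize_ratios(
    matrix: pd.DataFrame, scale_mad: bool = True
) -> pd.DataFrame:
    """Mean, median and m.a.d. of pooled per-site ratios per condition.

    ``matrix`` is the intersection matrix from
    :func:`methepi.context.intersect_sites` (two-level columns:
    condition, replicate).  All replicate columns of a condition are
    pooled site-wise, not averaged per replicate first.  The m.a.d. is
    scaled by the 1.4826 normal-consistency constant unless
    ``scale_mad=False``; an even-length median is the mean of the two
    middle values.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("empty site matrix")
    rows = []
    for condition in matrix.columns.get_level_values(0).unique():
        pooled = matrix[condition].to_numpy().ravel()
        pooled = pooled[~np.isnan(pooled)]
        if pooled.size == 0:
            raise ValueError(f"condition {condition!r} has no ratio values")
        scale = MAD_CONSISTENCY if scale_mad else 1.0
        rows.append(
            {
                "condition": condition,
                "mean_ratio": float(np.mean(pooled)),
                "median_ratio": float(np.median(pooled)),
                "mad_ratio": float(
                    scale * np.median(np.abs(pooled - np.median(pooled)))
                ),
                "n_values": int(pooled.size),
            }
        )
    return pd.DataFrame(rows)


def restoration_fraction(
    mean_wt: float, mean_single: float, mean_double: float
) -> float:
    """Fraction of the single-mutant methylation change reversed in the double.

    rho_hat = (mean_double - mean_single) / (mean_wt - mean_single); 1 is
    full restoration, 0 none, and values above 1 indicate overshoot past
    wild type (as seen for CHH).  Invariant under affine rescaling of the
    ratio axis.
    """
    denom = mean_wt - mean_single
    if denom == 0:
        raise ValueError("wild-type and single-mutant means are equal")
    return (mean_double - mean_single) / denom


def tss_profile(
    records: pd.DataFrame,
    tss: pd.DataFrame,
    upstream: int = 3000,
    downstream: int = 3000,
    bin_size: int = 100,
) -> pd.DataFrame:
    """Mean methylation ratio in fixed bins around transcription start sites.

    ``tss`` is a BED6-style frame (chrom, start, end, name, score,
    strand); the reference point is ``start`` for + genes and ``end - 1``
    for - genes, and distances for - genes are mirrored so negative is
    always upstream of transcription.  Bins are half-open ``[a, b)`` in
    signed distance; a site exactly at the TSS falls in the first
    downstream bin.  Empty bins are reported with ``n_sites = 0`` and a
    NaN mean.
    """
    validate_sites(records)
    window = upstream + downstream
    if bin_size <= 0 or window % bin_size:
        raise ValueError("bin_size must evenly divide the upstream+downstream window")
    n_bins = window // bin_size
    bin_starts = np.arange(n_bins) * bin_size - upstream
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)

    depth = records["n_meth"] + records["n_unmeth"]
    sites = records.loc[depth > 0, ["chrom", "start"]].copy()
    sites["ratio"] = (records["n_meth"] / depth)[depth > 0]

    for _, gene in tss.iterrows():
        ref_point = int(gene["start"]) if gene["strand"] == "+" else int(gene["end"]) - 1
        here = sites.loc[sites["chrom"] == gene["chrom"]]
        dist = here["start"].to_numpy() - ref_point
        if gene["strand"] == "-":
            dist = -dist
        inside = (dist >= -upstream) & (dist < downstream)
        idx = (dist[inside] + upstream) // bin_size
        np.add.at(sums, idx, here["ratio"].to_numpy()[inside])
        np.add.at(counts, idx, 1)

    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {"bin_start": bin_starts, "mean_ratio": means, "n_sites": counts}
    )


def context_summaries(
    groups_by_context: Mapping[str, Mapping[str, Sequence[pd.DataFrame]]],
    reference_condition: str,
    params: FilterParams | None = None,
) -> pd.DataFrame:
    """Full per-genotype, per-context summary table.

    ``groups_by_context`` maps context -> condition -> replicate record
    frames.  Per context: methylated-site union counts normalized to the
    reference condition (= 100), pooled ratio statistics over the
    all-condition intersection, and the fraction of assayable sites
    (depth/variant filters only) that are methylated at all.
    """
    params = params if params is not None else FilterParams()
    depth_only = FilterParams(
        min_depth=params.min_depth,
        max_variant_frac=params.max_variant_frac,
        min_ratio_exclusive=None,
    )
    rows = []
    for context, groups in groups_by_context.items():
        counts = count_methylated_sites(groups, params)
        normalized = normalize_counts(counts, reference_condition)
        matrix = intersect_sites(groups, params)
        stats_df = summarize_ratios(matrix).set_index("condition")
        for condition, replicates in groups.items():
            assayable: set[tuple] = set()
            methylated: set[tuple] = set()
            for rec in replicates:
                covered = apply_site_filters(rec, depth_only)
                assayable.update(zip(covered["chrom"], covered["start"], covered["strand"]))
                nz = apply_site_filters(rec, params)
                methylated.update(zip(nz["chrom"], nz["start"], nz["strand"]))
            frac = len(methylated) / len(assayable) if assayable else float("nan")
            rows.append(
                {
                    "genotype": condition,
                    "context": context,
                    "n_sites_union": counts[condition],
                    "normalized_count": normalized[condition],
                    "mean_ratio": stats_df.loc[condition, "mean_ratio"],
                    "median_ratio": stats_df.loc[condition, "median_ratio"],
                    "mad_ratio": stats_df.loc[condition, "mad_ratio"],
                    "frac_sites_methylated": frac,
                }
            )
    return pd.DataFrame(rows)


def fraction_vs_mean(summaries: pd.DataFrame) -> pd.DataFrame:
    """Paired (fraction methylated, mean ratio) per genotype and context.

    The coordinates behind the correlation plot relating how many sites
    are methylated to how methylated they are; no fitting is performed.
    """
    return summaries[
        ["genotype", "context", "frac_sites_methylated", "mean_ratio"]
    ].copy()
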