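"""Cytosine context classification, CG destranding, ratios, and site filters.

Cytosines are classified by the two bases downstream on their own strand:
``CG`` (palindromic dinucleotide), ``CHG`` (partially palindromic) and
``CHH`` (non-palindromic), with H meaning A, C or T.  Coordinates are
0-based half-open throughout (bedGraph convention); a pre-merge site spans
exactly one base.

Site records are carried as :class:`pandas.DataFrame` objects with the
columns in :data:`SITE_COLUMNS`; :func:`site_frame` builds a validated
frame from column data.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SITE_COLUMNS = (
    "chrom",
    "start",
    "end",
    "strand",
    "context",
    "n_meth",
    "n_unmeth",
    "n_illegitimate",
)

CONTEXTS = ("CG", "CHG", "CHH")

_H = frozenset("ACT")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def site_frame(
    chrom,
    start,
    strand,
    context,
    n_meth,
    n_unmeth,
    n_illegitimate=0,
    end=None,
) -> pd.DataFrame:
    """Assemble a validated site-record frame.

    ``end`` defaults to ``start + 1`` (single-cytosine records).
    """
    start = np.asarray(start, dtype=np.int64)
    if end is None:
        end = start + 1
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": start,
            "end": np.asarray(end, dtype=np.int64),
            "strand": strand,
            "context": context,
            "n_meth": np.asarray(n_meth, dtype=np.int64),
            "n_unmeth": np.asarray(n_unmeth, dtype=np.int64),
            "n_illegitimate": np.broadcast_to(
                np.asarray(n_illegitimate, dtype=np.int64), start.shape
            ).copy(),
        }
    )
    validate_sites(df)
    return df


def validate_sites(records: pd.DataFrame) -> None:
    missing = [c for c in SITE_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"site frame missing columns: {missing}")
    if len(records) == 0:
        return
    for col in ("n_meth", "n_unmeth", "n_illegitimate"):
        if (records[col] < 0).any():
            raise ValueError(f"negative counts in column {col!r}")
    if (records["end"] <= records["start"]).any():
        raise ValueError("end must exceed start")
    bad = ~records["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError("strand must be '+' or '-'")


def classify_context(sequence: str, position: int, strand: str = "+") -> str | None:
    """Classify the cytosine at ``position`` on ``strand`` as CG/CHG/CHH.

    The two bases downstream of the cytosine on its own strand decide the
    context.  For the minus strand the downstream direction runs leftward
    along the forward sequence and bases are complemented.  Returns ``None``
    when fewer than two downstream bases exist or when the trinucleotide
    window contains an ambiguity base (N).

    Raises
    ------
    ValueError
        If the base at ``position`` is not a cytosine on the given strand
        (forward C for ``+``, forward G for ``-``), or the position is out
        of range.
    """
    if not 0 <= position < len(sequence):
        raise ValueError(f"position {position} outside sequence of length {len(sequence)}")
    base = sequence[position].upper()
    if strand == "+":
        if base != "C":
            raise ValueError(f"base at {position} on '+' is {base!r}, not C")
        if position + 2 >= len(sequence):
            return None
        b1 = sequence[position + 1].upper()
        b2 = sequence[position + 2].upper()
    elif strand == "-":
        if base != "G":
            raise ValueError(f"base at {position} on '-' is {base!r} (forward), not G")
        if position - 2 < 0:
            return None
        b1 = sequence[position - 1].upper().translate(_COMPLEMENT)
        b2 = sequence[position - 2].upper().translate(_COMPLEMENT)
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if "N" in (b1, b2):
        return None
    if b1 == "G":
        return "CG"
    if b1 in _H and b2 == "G":
        return "CHG"
    if b1 in _H and b2 in _H:
        return "CHH"
    return None


def enumerate_cytosines(sequence: str, chrom: str = "chr1") -> pd.DataFrame:
    """List every classifiable cytosine site on both strands.

    Returns a frame with chrom/start/end/strand/context, sorted by
    position then strand, with zeroed count columns.
    """
    seq = sequence.upper()
    rows: list[tuple[int, str, str]] = []
    for pos, base in enumerate(seq):
        if base == "C":
            ctx = classify_context(seq, pos, "+")
            if ctx is not None:
                rows.append((pos, "+", ctx))
        elif base == "G":
            ctx = classify_context(seq, pos, "-")
            if ctx is not None:
                rows.append((pos, "-", ctx))
    if not rows:
        return site_frame([], np.array([], dtype=np.int64), [], [], [], [])
    pos, strand, ctx = zip(*rows)
    return site_frame(
        chrom=[chrom] * len(pos),
        start=np.array(pos, dtype=np.int64),
        strand=list(strand),
        context=list(ctx),
        n_meth=np.zeros(len(pos), dtype=np.int64),
        n_unmeth=np.zeros(len(pos), dtype=np.int64),
    )


def compute_ratio(record) -> float:
    """Methylation ratio n_meth / (n_meth + n_unmeth) of one record.

    Accepts any mapping or object with ``n_meth``/``n_unmeth`` fields.
    Always computed from counts, never from a rounded percent column.
    """
    try:
        n_meth = record["n_meth"]
        n_unmeth = record["n_unmeth"]
    except (TypeError, KeyError, IndexError):
        n_meth = record.n_meth
        n_unmeth = record.n_unmeth
    depth = n_meth + n_unmeth
    if depth <= 0:
        raise ValueError("methylation ratio undefined at zero depth")
    return n_meth / depth


def methylation_ratios(records: pd.DataFrame) -> pd.Series:
    """Vectorized per-record ratio; NaN where depth is zero."""
    depth = records["n_meth"] + records["n_unmeth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = records["n_meth"] / depth
    return out.where(depth > 0)


def merge_cg_strands(records: pd.DataFrame) -> pd.DataFrame:
    """Destrand CG sites by summing counts over the symmetric strand pair.

    Every CG record is anchored at the forward-strand C of its dinucleotide
    (its own position on ``+``, one base left on ``-``) and reported on
    strand ``+`` spanning the two bases ``[p, p+2)``, whether or not both
    strands were covered.  CHG and CHH records pass through unchanged.
    Idempotent and count-conserving.

    Raises
    ------
    ValueError
        On duplicate records for the same (chrom, position, strand).
    """
    validate_sites(records)
    if records.duplicated(subset=["chrom", "start", "strand"]).any():
        raise ValueError("duplicate records for the same (chrom, position, strand)")
    is_cg = records["context"] == "CG"
    other = records.loc[~is_cg]
    cg = records.loc[is_cg]
    if len(cg):
        anchor = cg["start"].where(cg["strand"] == "+", cg["start"] - 1)
        merged = (
            cg.assign(start=anchor)
            .groupby(["chrom", "start"], as_index=False, sort=False)[
                ["n_meth", "n_unmeth", "n_illegitimate"]
            ]
            .sum()
        )
        merged["end"] = merged["start"] + 2
        merged["strand"] = "+"
        merged["context"] = "CG"
        merged = merged[list(SITE_COLUMNS)]
    else:
        merged = cg
    out = pd.concat([merged, other], ignore_index=True)
    return out.sort_values(["chrom", "start", "strand"], kind="stable").reset_index(
        drop=True
    )


@dataclasses.dataclass(frozen=True)
class FilterParams:
    """Site-level filters applied to each coverage file.

    min_depth
        Minimum informative reads (methylated + unmethylated); default 4.
    max_variant_frac
        Maximum tolerated fraction of illegitimate bases (reads that are
        neither C nor T evidence) out of all reads at the site; default 0.25.
        Sites at or above the threshold are removed (SNP contamination).
    min_ratio_exclusive
        Sites must have ratio strictly greater than this; the default 0
        removes fully unmethylated (ratio 0) covered sites.  ``None``
        disables the ratio filter entirely (keep covered zeros).
    high_stringency_min_ratio
        Optional extra floor: when set, sites with ratio below it are also
        removed.  Used at 0.25 to strip the fixed-value artefact band seen
        in some CHH coverage files.
    """

    min_depth: int = 4
    max_variant_frac: float = 0.25
    min_ratio_exclusive: float | None = 0.0
    high_stringency_min_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        for name in ("max_variant_frac", "min_ratio_exclusive"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.high_stringency_min_ratio is not None and not (
            0.0 <= self.high_stringency_min_ratio <= 1.0
        ):
            raise ValueError("high_stringency_min_ratio must be in [0, 1]")


def apply_site_filters(records: pd.DataFrame, params: FilterParams) -> pd.DataFrame:
    """Keep records passing depth, variant-fraction and ratio filters.

    Predicates commute and the operation is idempotent; input order is
    preserved.  An empty result is not an error.
    """
    validate_sites(records)
    if len(records) == 0:
        return records.copy()
    depth = records["n_meth"] + records["n_unmeth"]
    total = depth + records["n_illegitimate"]
    variant_frac = np.where(total > 0, records["n_illegitimate"] / total.where(total > 0, 1), 0.0)
    ratio = np.where(depth > 0, records["n_meth"] / depth.where(depth > 0, 1), np.nan)
    keep = (depth >= params.min_depth) & (variant_frac < params.max_variant_frac)
    if params.min_ratio_exclusive is not None:
        keep &= ratio > params.min_ratio_exclusive
    if params.high_stringency_min_ratio is not None:
        keep &= ratio >= params.high_stringency_min_ratio
    return records.loc[np.asarray(keep, dtype=bool)].copy()


def _keyed_ratios(records: pd.DataFrame) -> pd.Series:
    ratios = methylation_ratios(records)
    idx = pd.MultiIndex.from_frame(
        records[["chrom", "start", "strand"]], names=["chrom", "start", "strand"]
    )
    return pd.Series(ratios.to_numpy(), index=idx)


def intersect_sites(
    groups: Mapping[str, Sequence[pd.DataFrame]],
    params: FilterParams | None = None,
) -> pd.DataFrame:
    """Site x sample ratio matrix over the all-replicate, all-condition intersection.

    Only sites passing the filters in *every* replicate of *every*
    condition are retained; the returned frame is indexed by
    (chrom, start, strand) and has one ratio column per replicate, with a
    two-level column index (condition, replicate number).  An empty
    intersection yields an empty matrix.
    """
    if not groups or any(len(reps) == 0 for reps in groups.values()):
        raise ValueError("need at least one condition with at least one replicate")
    columns: dict[tuple[str, int], pd.Series] = {}
    for condition, replicates in groups.items():
        for i, rec in enumerate(replicates):
            filtered = apply_site_filters(rec, params) if params is not None else rec
            validate_sites(filtered)
            columns[(condition, i)] = _keyed_ratios(filtered)
    matrix = pd.concat(columns, axis=1, join="inner")
    matrix.columns = pd.MultiIndex.from_tuples(
        matrix.columns, names=["condition", "replicate"]
    )
    return matrix.sort_index()
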