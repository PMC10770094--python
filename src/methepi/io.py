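"""File formats: MethylDackel-style bedGraph, FASTA, BED6 TSS lists, TSV tables.

The bedGraph dialect has six tab-separated columns — chrom, start (0-based),
end (exclusive), integer percent methylation, methylated read count,
unmethylated read count — plus an optional seventh column with the
illegitimate-base read count (0 when absent).  The percent column is
written rounded for compatibility but never consumed: ratios are always
recomputed from counts.  Strand and context are not part of the format;
per-context files are conventionally named ``<sample>_<context>.bedGraph``
and :func:`annotate_sites` can recover strand/context from a reference.

All writers sort deterministically and emit bit-identical files for
identical input; all parsers reject malformed rows with the file name and
line number rather than coercing.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .context import SITE_COLUMNS, classify_context, site_frame, validate_sites

_TRACK_LINE = "track type=bedGraph"
_CONTEXT_SUFFIX = re.compile(r"_(CG|CHG|CHH)\.(bedGraph|bedgraph|bg)$")


class BedGraphError(ValueError):
    """Malformed bedGraph content; message names file and line."""


def infer_context_from_filename(path: str | Path) -> str | None:
    m = _CONTEXT_SUFFIX.search(Path(path).name)
    return m.group(1) if m else None


def read_bedgraph(
    path: str | Path,
    context: str | None = None,
    reference: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Parse one coverage file into a site-record frame.

    ``context`` defaults to the tag in the filename when present.  When
    ``reference`` (mapping chrom -> sequence) is given, strand and
    context are recovered per position; otherwise strand is reported as
    ``+`` (destranded convention) and context as provided.
    """
    path = Path(path)
    if context is None:
        context = infer_context_from_filename(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("track") or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (6, 7):
                raise BedGraphError(
                    f"{path}:{lineno}: expected 6 or 7 columns, got {len(fields)}"
                )
            try:
                start = int(fields[1])
                end = int(fields[2])
                int(fields[3])  # percent column: validated, never used
                n_meth = int(fields[4])
                n_unmeth = int(fields[5])
                n_ill = int(fields[6]) if len(fields) == 7 else 0
            except ValueError as exc:
                raise BedGraphError(f"{path}:{lineno}: non-integer field ({exc})") from None
            if start >= end:
                raise BedGraphError(f"{path}:{lineno}: start {start} >= end {end}")
            if min(n_meth, n_unmeth, n_ill) < 0:
                raise BedGraphError(f"{path}:{lineno}: negative count")
            rows.append((fields[0], start, end, n_meth, n_unmeth, n_ill))
    chrom = [r[0] for r in rows]
    start = np.array([r[1] for r in rows], dtype=np.int64)
    end = np.array([r[2] for r in rows], dtype=np.int64)
    df = site_frame(
        chrom=chrom,
        start=start,
        end=end,
        strand=["+"] * len(rows),
        context=[context or "CG"] * len(rows),
        n_meth=[r[3] for r in rows],
        n_unmeth=[r[4] for r in rows],
        n_illegitimate=[r[5] for r in rows],
    )
    if reference is not None:
        df = annotate_sites(df, reference)
    return df


def annotate_sites(records: pd.DataFrame, reference: Mapping[str, str]) -> pd.DataFrame:
    """Fill strand and context from the reference sequence.

    Single-base records are classified at their own position (forward C
    or reverse C); two-base records are taken as destranded CG
    dinucleotides on ``+``.
    """
    records = records.copy()
    strands, contexts = [], []
    for chrom, start, end in zip(records["chrom"], records["start"], records["end"]):
        seq = reference[chrom]
        if end - start == 2:
            strands.append("+")
            contexts.append("CG")
            continue
        base = seq[start].upper()
        strand = "+" if base == "C" else "-"
        strands.append(strand)
        contexts.append(classify_context(seq, start, strand))
    records["strand"] = strands
    records["context"] = contexts
    return records


def write_bedgraph(records: pd.DataFrame, path: str | Path) -> None:
    """Write records in the 7-column dialect, sorted by (chrom, start)."""
    validate_sites(records)
    if records.duplicated(subset=["chrom", "start", "end"]).any():
        raise ValueError("duplicate (chrom, start, end) records are unsortable")
    out = records.sort_values(["chrom", "start"], kind="stable")
    depth = out["n_meth"] + out["n_unmeth"]
    percent = np.where(
        depth > 0, np.round(100.0 * out["n_meth"] / depth.where(depth > 0, 1)), 0
    ).astype(int)
    with open(path, "w") as fh:
        fh.write(_TRACK_LINE + "\n")
        for row, pct in zip(out.itertuples(index=False), percent):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{pct}\t"
                f"{row.n_meth}\t{row.n_unmeth}\t{row.n_illegitimate}\n"
            )


def split_by_context(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    return {
        ctx: sub.reset_index(drop=True)
        for ctx, sub in records.groupby("context", sort=True)
    }


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


_BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_tss_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED6 TSS list; strand is required for orientation."""
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", header=None, names=_BED6_COLUMNS, comment="#", dtype={0: str}
    )
    if df["strand"].isna().any() or not df["strand"].isin(["+", "-"]).all():
        raise ValueError(f"{path}: BED6 with +/- strand required for TSS lists")
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: BED intervals must satisfy start < end")
    return df


def write_tss_bed(tss: pd.DataFrame, path: str | Path) -> None:
    tss[_BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a per-fish phenotype TSV (fish_id, genotype, areas)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"fish_id", "genotype", "rag1_area", "gh_area"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: phenotype table missing columns {sorted(missing)}")
    return df


def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_sites_tsv(records: pd.DataFrame, path: str | Path) -> None:
    """Full site-record TSV including strand and context (lossless)."""
    validate_sites(records)
    records[list(SITE_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_sites_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    validate_sites(df)
    return df
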