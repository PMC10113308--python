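"""Readers/writers for the pipeline's text formats.

Dialects: counts TSV (first column feature_id, then sample columns), sample
sheet TSV (sample_id, genotype_role, stage, replicate), Bismark-style CX
report (chrom, 1-based pos, strand, count_methylated, count_unmethylated,
context, trinucleotide), GFF3 (1-based inclusive, converted to 0-based
half-open on read), BED (0-based half-open), FASTA wrapped at 60 columns.

Writers accept ``header`` comment lines; readers skip ``#`` lines.
Malformed lines raise :class:`ParseError` naming the line number.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GeneModel, GenomicInterval, STRANDS

CONTEXTS = ("CpG", "CHG", "CHH")


class ParseError(ValueError):
    """Malformed input line; message carries path and 1-based line number."""


def _fail(path, lineno: int, msg: str):
    raise ParseError(f"{path}:{lineno}: {msg}")


def _data_lines(path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def _write_header(fh, header: Sequence[str] | None) -> None:
    for line in header or ():
        fh.write(f"# {line}\n")


# ---------------------------------------------------------------- tabular


def read_sample_sheet(path) -> pd.DataFrame:
    rows = []
    expected = ["sample_id", "genotype_role", "stage", "replicate"]
    for lineno, fields in _data_lines(path):
        if fields[: len(expected)] == expected:
            continue  # header line
        if len(fields) < 4:
            _fail(path, lineno, f"expected 4 columns, got {len(fields)}")
        if fields[1] not in {"maternal", "paternal", "hybrid"}:
            _fail(path, lineno, f"unknown genotype_role {fields[1]!r}")
        try:
            rep = int(fields[3])
        except ValueError:
            _fail(path, lineno, f"non-integer replicate {fields[3]!r}")
        rows.append((fields[0], fields[1], fields[2], rep))
    df = pd.DataFrame(rows, columns=expected)
    return df.set_index("sample_id")


def write_sample_sheet(design: pd.DataFrame, path, header: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        _write_header(fh, header)
        design.reset_index().to_csv(fh, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    """Feature x sample integer count matrix."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise ParseError(f"{path}: non-integer counts present")
        df = df.astype(np.int64)
    if (df.to_numpy() < 0).any():
        raise ParseError(f"{path}: negative counts present")
    df.index.name = "feature_id"
    return df


def write_counts(counts: pd.DataFrame, path, header: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        _write_header(fh, header)
        counts.to_csv(fh, sep="\t")


CX_COLUMNS = ["chrom", "pos", "strand", "count_methylated", "count_unmethylated", "context", "trinucleotide"]


def read_cx_report(path) -> pd.DataFrame:
    """CX report with 1-based positions kept as-is in the ``pos`` column."""
    df = pd.read_csv(
        path, sep="\t", comment="#", names=CX_COLUMNS, header=None,
        dtype={"chrom": str, "strand": str, "context": str, "trinucleotide": str},
    )
    if df["strand"].isin({"+", "-"}).all() is False or not df["strand"].isin({"+", "-"}).all():
        bad = int(np.nonzero(~df["strand"].isin({"+", "-"}).to_numpy())[0][0]) + 1
        _fail(path, bad, f"unknown strand {df['strand'].iloc[bad - 1]!r}")
    if not df["context"].isin(CONTEXTS).all():
        bad = int(np.nonzero(~df["context"].isin(CONTEXTS).to_numpy())[0][0]) + 1
        _fail(path, bad, f"unknown context {df['context'].iloc[bad - 1]!r}")
    for col in ("pos", "count_methylated", "count_unmethylated"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = int(np.nonzero(vals.isna().to_numpy())[0][0]) + 1
            _fail(path, bad, f"non-integer {col}")
        df[col] = vals.astype(np.int64)
    if (df[["count_methylated", "count_unmethylated"]].to_numpy() < 0).any():
        raise ParseError(f"{path}: negative read counts")
    return df


def write_cx_report(df: pd.DataFrame, path, header: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        _write_header(fh, header)
        df[CX_COLUMNS].to_csv(fh, sep="\t", index=False, header=False)


# ---------------------------------------------------------------- intervals


def read_bed(path) -> list[GenomicInterval]:
    """BED3+ -> half-open intervals; extra columns (name/score/strand) optional."""
    out = []
    for lineno, f in _data_lines(path):
        if len(f) < 3:
            _fail(path, lineno, f"expected >=3 BED columns, got {len(f)}")
        try:
            start, end = int(f[1]), int(f[2])
        except ValueError:
            _fail(path, lineno, "non-integer coordinates")
        strand = f[5] if len(f) >= 6 else "."
        if strand not in STRANDS:
            _fail(path, lineno, f"unknown strand {strand!r}")
        try:
            out.append(GenomicInterval(f[0], start, end, strand))
        except ValueError as e:
            _fail(path, lineno, str(e))
    return out


def read_bed_names(path) -> list[tuple[GenomicInterval, str]]:
    ivs = read_bed(path)
    names = []
    for lineno, f in _data_lines(path):
        names.append(f[3] if len(f) >= 4 else f"{f[0]}:{f[1]}-{f[2]}")
    return list(zip(ivs, names))


def write_bed(
    intervals: Iterable[GenomicInterval], path,
    names: Sequence[str] | None = None, header: Sequence[str] | None = None,
) -> None:
    ivs = list(intervals)
    with open(path, "w") as fh:
        _write_header(fh, header)
        for i, iv in enumerate(ivs):
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None:
                fields += [names[i], "0", iv.strand]
            fh.write("\t".join(fields) + "\n")


def _gff3_attrs(raw: str) -> dict[str, str]:
    out = {}
    for part in raw.split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path) -> list[GeneModel]:
    """Parse gene/exon features; 1-based inclusive -> 0-based half-open."""
    genes: dict[str, dict] = {}
    order: list[str] = []
    for lineno, f in _data_lines(path):
        if len(f) != 9:
            _fail(path, lineno, f"expected 9 GFF3 columns, got {len(f)}")
        chrom, _, ftype, start_s, end_s, _, strand, _, attrs_s = f
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError:
            _fail(path, lineno, "non-integer coordinates")
        if end1 < start1:
            _fail(path, lineno, f"coordinate inversion {start_s}>{end_s}")
        if strand not in STRANDS:
            _fail(path, lineno, f"unknown strand {strand!r}")
        iv = GenomicInterval(chrom, start1 - 1, end1, strand)
        attrs = _gff3_attrs(attrs_s)
        if ftype == "gene":
            gid = attrs.get("ID")
            if not gid:
                _fail(path, lineno, "gene feature without ID attribute")
            if gid in genes:
                _fail(path, lineno, f"duplicate gene ID {gid!r}")
            genes[gid] = {"iv": iv, "exons": []}
            order.append(gid)
        elif ftype == "exon":
            parent = attrs.get("Parent")
            if parent in genes:
                genes[parent]["exons"].append(iv)
    return [
        GeneModel(gid, genes[gid]["iv"], tuple(sorted(genes[gid]["exons"])))
        for gid in order
    ]


def write_gff3(genes: Iterable[GeneModel], path, header: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        _write_header(fh, header)
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\ttriomics\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\tID={g.gene_id}\n"
            )
            for i, ex in enumerate(g.exons, start=1):
                fh.write(
                    f"{ex.chrom}\ttriomics\texon\t{ex.start + 1}\t{ex.end}\t.\t{iv.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------- sequences


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


# ---------------------------------------------------------------- generic TSV


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_tsv(df: pd.DataFrame, path, header: Sequence[str] | None = None, index: bool = False) -> None:
    with open(path, "w") as fh:
        _write_header(fh, header)
        df.to_csv(fh, sep="\t", index=index)
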