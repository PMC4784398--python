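"""File input/output: TSV tables, wig tracks, GFF annotations, FASTA.

Internal coordinates are 0-based half-open; wig and GFF are written and
read as 1-based per their specifications.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import ChromatinTrack, CountMatrix, validate_library


def open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# tables

def read_library(path) -> pd.DataFrame:
    lib = pd.read_csv(path, sep="\t", dtype={"guide_id": str, "pool": str})
    return validate_library(lib)


def write_library(library: pd.DataFrame, path) -> None:
    library.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "pool": str})
    if df["atc"].dtype != bool:
        df["atc"] = df["atc"].map(
            {True: True, False: False, "+": True, "-": False, "True": True, "False": False}
        )
    return df


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_counts(counts_path, samples_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    samples = read_sample_sheet(samples_path)
    pools = None
    if "pool" in counts.columns:  # optional per-guide pool column
        pools = counts.pop("pool")
    return CountMatrix(counts, samples, guide_pools=pools)


def write_counts(matrix: CountMatrix, path, with_pool: bool = True) -> None:
    out = matrix.counts.copy()
    if with_pool:
        out.insert(0, "pool", matrix.guide_pools)
    out.index.name = "guide_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# wig

def write_wig(track: ChromatinTrack, path, name: str | None = None) -> None:
    """Write a track as fixedStep wig (1-based start per the wig spec)."""
    with open_text(path, "wt") as fh:
        if name:
            fh.write(f'track type=wiggle_0 name="{name}"\n')
        fh.write(
            f"fixedStep chrom={track.chrom} start={track.start + 1} "
            f"step={track.step} span={track.step}\n"
        )
        np.savetxt(fh, track.values, fmt="%.6g")


def read_wig(path, kind: str) -> ChromatinTrack:
    """Read a single-chromosome fixedStep or variableStep wig file.

    variableStep values are densified onto a per-``step`` grid; positions
    absent from the file become NaN.
    """
    chrom = None
    start = None
    step = 1
    mode = None
    fixed_vals: list[float] = []
    var_pos: list[int] = []
    var_vals: list[float] = []
    with open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            if line.startswith("fixedStep") or line.startswith("variableStep"):
                if mode is not None:
                    raise ValueError("multi-block wig files are not supported")
                fields = dict(f.split("=", 1) for f in line.split()[1:])
                chrom = fields["chrom"]
                step = int(fields.get("step", 1))
                mode = line.split()[0]
                if mode == "fixedStep":
                    start = int(fields["start"]) - 1
                continue
            if mode == "fixedStep":
                fixed_vals.append(float(line.split()[0]))
            elif mode == "variableStep":
                p, v = line.split()[:2]
                var_pos.append(int(p) - 1)
                var_vals.append(float(v))
            else:
                raise ValueError("wig data before declaration line")
    if mode == "fixedStep":
        return ChromatinTrack(chrom, start, np.array(fixed_vals), kind, step=step)
    if not var_pos:
        raise ValueError("empty wig file")
    pos = np.array(var_pos)
    start = int(pos.min())
    n = (int(pos.max()) - start) // step + 1
    values = np.full(n, np.nan)
    values[(pos - start) // step] = var_vals
    return ChromatinTrack(chrom, start, values, kind, step=step)


# ---------------------------------------------------------------------------
# genome + annotations

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(open_text(path), "fasta")}


def write_fasta(genome: dict[str, str], path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with open_text(path, "wt") as fh:
        SeqIO.write(recs, fh, "fasta")


def write_gff(annotations: pd.DataFrame, path) -> None:
    """Write gene annotations as GFF3; the TSS is carried as an attribute."""
    with open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for _, row in annotations.iterrows():
            attrs = f"ID={row['gene']};tss={row['tss'] + 1}"
            fh.write(
                f"{row['chrom']}\tcrispri_screen\tgene\t{row['start'] + 1}\t{row['end']}\t."
                f"\t{row['strand']}\t.\t{attrs}\n"
            )


def read_gff(path) -> pd.DataFrame:
    """Read gene features from GFF3 into the annotation table schema.

    Returns columns gene, chrom, strand, start, end (0-based half-open),
    orf_start (strand-aware ATG coordinate) and tss.  If no ``tss``
    attribute is present the TSS column is left as NA for downstream
    inference.
    """
    rows = []
    with open_text(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            start, end = int(f[3]) - 1, int(f[4])
            strand = f[6]
            rows.append(
                {
                    "gene": attrs.get("ID", f"gene{len(rows) + 1}"),
                    "chrom": f[0],
                    "strand": strand,
                    "start": start,
                    "end": end,
                    "orf_start": start if strand == "+" else end - 1,
                    "tss": int(attrs["tss"]) - 1 if "tss" in attrs else pd.NA,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FASTQ

def iter_fastq(path):
    """Yield (read id, sequence, quality) from FASTQ or FASTQ.gz."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open_text(path) as fh:
        yield from FastqGeneralIterator(fh)


def write_fastq(reads, path) -> None:
    """Write an iterable of (read id, sequence, quality) as FASTQ(.gz)."""
    with open_text(path, "wt") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
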