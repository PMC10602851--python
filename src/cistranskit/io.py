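"""Readers and writers for the on-disk formats the pipeline exchanges.

FASTA via Bio.SeqIO, VCF v4.2 (written as plain text, read via pysam), BED
(0-based half-open), JASPAR-format PWMs via Bio.motifs, and tab-delimited
count/metadata/result tables.  Every table writer prepends a ``#`` comment
line carrying the seed and config hash so outputs are traceable and runs are
byte-comparable.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO, motifs
from Bio.motifs import jaspar as _jaspar
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from cistranskit.genome import VariantTable


# ---------------------------------------------------------------- FASTA

def write_fasta(path: str | Path, seqs: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------- VCF

def write_vcf(path: str | Path, variants: VariantTable, contig_lengths: dict[str, int]) -> None:
    """Write a minimal VCF v4.2 (positions 1-based, one strain in the source column)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=STRAIN,Number=1,Type=String,Description="Strain carrying ALT">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt, strain in variants.df[
            ["chrom", "pos", "ref", "alt", "strain"]
        ].itertuples(index=False):
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\tSTRAIN={strain}\n")


def read_vcf(path: str | Path, strain: str | None = None) -> VariantTable:
    """Read a VCF into a VariantTable; the strain is taken from INFO/STRAIN
    unless overridden."""
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            s = strain or rec.info.get("STRAIN", "strain")
            for alt in rec.alts or ():
                rows.append((rec.chrom, rec.pos, rec.ref, alt, s))
    return VariantTable(rows)


# ---------------------------------------------------------------- BED

def write_bed(path: str | Path, features: pd.DataFrame) -> None:
    """Write ``chrom,start,end,peak_id`` columns as BED (0-based half-open)."""
    features[["chrom", "start", "end", "peak_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "peak_id"], usecols=[0, 1, 2, 3],
    )
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


# ---------------------------------------------------------------- JASPAR PWMs

def write_jaspar(path: str | Path, counts: dict[str, np.ndarray]) -> None:
    """Write PWMs (name -> 4 x width count/probability matrix, rows ACGT) in
    JASPAR bracket format."""
    mots = []
    for name, mat in counts.items():
        mat = np.asarray(mat, dtype=float)
        m = motifs.Motif(
            alphabet="ACGT",
            counts={b: list(mat[i]) for i, b in enumerate("ACGT")},
        )
        m.matrix_id = name
        m.name = name
        mots.append(m)
    with open(path, "w") as fh:
        fh.write(_jaspar.write(mots, "jaspar"))


def read_jaspar(path: str | Path) -> dict[str, np.ndarray]:
    """Read JASPAR PWMs (bracket or 4-line raw dialect) -> name -> 4 x width matrix."""
    text = Path(path).read_text()
    try:
        with _io.StringIO(text) as fh:
            parsed = motifs.parse(fh, "jaspar")
    except Exception:
        with _io.StringIO(text) as fh:
            parsed = motifs.parse(fh, "pfm-four-columns")
    out = {}
    for m in parsed:
        name = getattr(m, "matrix_id", None) or m.name or f"motif_{len(out)}"
        out[str(name)] = np.array([list(m.counts[b]) for b in "ACGT"], dtype=float)
    return out


# ---------------------------------------------------------------- tables

def write_table(path: str | Path, df: pd.DataFrame, header_comment: str | None = None,
                index: bool = False) -> None:
    """Tab-delimited table with an optional leading ``#`` provenance comment."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_counts(path: str | Path, counts: pd.DataFrame, header_comment: str | None = None) -> None:
    """Count matrix: features x samples, feature ids in the first column."""
    write_table(path, counts, header_comment=header_comment, index=True)


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)
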