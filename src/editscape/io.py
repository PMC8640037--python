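"""Readers and writers for the pipeline's plain-text interchange formats.

One TSV dialect throughout: tab-separated, UTF-8, '#'-prefixed header
comment lines.  All genomic coordinates are 1-based, fully closed
(the VCF convention), stated in every file header; BED output follows the
BED convention of 0-based half-open starts.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from editscape.recoding import TranscriptModel
from editscape.tampor import AbundanceMatrix

COORD_HEADER = "# coordinates: 1-based, fully closed"


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _write_tsv(df: pd.DataFrame, path: str | Path, header_lines: Sequence[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(line.rstrip("\n") + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_models_tsv(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """GFF3-like flat table: one row per exon/CDS interval."""
    rows = []
    for m in models:
        for s, e in m.exons:
            rows.append((m.chrom, s, e, m.strand, "exon", m.gene_id, m.transcript_id))
        for s, e in m.cds:
            rows.append((m.chrom, s, e, m.strand, "CDS", m.gene_id, m.transcript_id))
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "feature",
                       "gene_id", "transcript_id"]
    )
    _write_tsv(df, path, [COORD_HEADER, "# transcript models (GFF3-like TSV)"])


def read_models_tsv(path: str | Path) -> list[TranscriptModel]:
    df = read_tsv(path)
    models = []
    for (gene, tx), sub in df.groupby(["gene_id", "transcript_id"], sort=True):
        exons = tuple(sorted(
            (int(r.start), int(r.end)) for r in sub[sub.feature == "exon"].itertuples()
        ))
        cds = tuple(sorted(
            (int(r.start), int(r.end)) for r in sub[sub.feature == "CDS"].itertuples()
        ))
        models.append(TranscriptModel(
            gene_id=gene, transcript_id=tx, chrom=sub["chrom"].iloc[0],
            strand=sub["strand"].iloc[0], exons=exons, cds=cds,
        ))
    return models


def write_bed(positions: Iterable[tuple[str, int]], path: str | Path,
              name: str = "site") -> None:
    """BED (0-based half-open) of 1-based single positions."""
    with open(path, "w", encoding="utf-8") as fh:
        for chrom, pos in sorted(positions):
            fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{name}\n")


def read_bed_positions(path: str | Path) -> set[tuple[str, int]]:
    """1-based positions from a BED of single-base intervals."""
    out = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, _end = line.split("\t")[:3]
            out.add((chrom, int(start) + 1))
    return out


def write_calls_tsv(calls: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(calls, path, [COORD_HEADER, "# editing calls: one row per site per sample"])


def write_phenotypes_tsv(pheno: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(pheno, path, ["# phenotype table; diagnosis: 0=control, 1=MCI, 2=AD"])


def write_abundance_tsv(matrix: AbundanceMatrix, path: str | Path) -> None:
    """Matrix TSV with `batch` and `is_GIS` annotation rows above the data."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# TMT peptide abundance matrix; rows `batch` and `is_GIS` annotate samples\n")
        cols = list(matrix.values.columns)
        fh.write("peptide\t" + "\t".join(cols) + "\n")
        fh.write("batch\t" + "\t".join(str(matrix.batch[c]) for c in cols) + "\n")
        fh.write("is_GIS\t" + "\t".join(str(int(matrix.is_gis[c])) for c in cols) + "\n")
        body = matrix.values.copy()
        body.insert(0, "peptide", body.index)
        if matrix.is_edited is not None:
            body["peptide"] = [
                f"{p}|edited" if e else p
                for p, e in zip(matrix.values.index, matrix.is_edited)
            ]
        body.to_csv(fh, sep="\t", index=False, header=False)


def read_abundance_tsv(path: str | Path) -> AbundanceMatrix:
    with open(path, encoding="utf-8") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    header = lines[0].rstrip("\n").split("\t")[1:]
    batch = pd.Series(lines[1].rstrip("\n").split("\t")[1:], index=header)
    gis = pd.Series(
        [bool(int(v)) for v in lines[2].rstrip("\n").split("\t")[1:]], index=header
    )
    body = pd.read_csv(_io.StringIO("".join(lines[3:])), sep="\t", header=None,
                       names=["peptide"] + header)
    edited = body["peptide"].str.endswith("|edited")
    body["peptide"] = body["peptide"].str.removesuffix("|edited")
    values = body.set_index("peptide")
    return AbundanceMatrix(
        values=values, batch=batch, is_gis=gis,
        is_edited=pd.Series(edited.to_numpy(), index=values.index),
    )
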