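"""Amino-acid consequences of exonic A-to-I edits and edited-peptide databases.

An exonic edit is *re-coding* when substituting the edited base on the
coding strand (A>G on '+', genome T>C read as A>G on '−') changes the
encoded amino acid.  Re-coding edits on one transcript are combined into
all 2^k − 1 edited proteoforms, digested in silico with fully tryptic
specificity (Keil rule: cleave C-terminal to K/R except before P, up to a
maximum number of missed cleavages and a minimum peptide length), and the
peptides that both cover an edited residue and are absent from the digest
of the unedited proteome form the edited-peptide search database.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class TranscriptModel:
    """Strand-aware gene model with 1-based, fully closed intervals.

    ``exons`` and ``cds`` are sorted, non-overlapping genomic intervals;
    a transcript with empty ``cds`` is treated as non-coding RNA.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for ivs in (self.exons, self.cds):
            for (s, e) in ivs:
                if s > e:
                    raise ValueError(f"interval ({s}, {e}) has start > end")
            if list(ivs) != sorted(ivs) :
                raise ValueError("intervals must be sorted")
            for (a, b) in zip(ivs, ivs[1:]):
                if a[1] >= b[0]:
                    raise ValueError("intervals must be non-overlapping")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def is_coding(self) -> bool:
        return len(self.cds) > 0

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds)

    def cds_index(self, pos: int) -> int | None:
        """0-based index of a genomic position within the coding sequence.

        Indexing follows the coding strand: for '−' transcripts the first
        CDS base is the genomically last one.
        """
        if not self.in_cds(pos):
            return None
        offset = 0
        if self.strand == "+":
            for s, e in self.cds:
                if s <= pos <= e:
                    return offset + (pos - s)
                offset += e - s + 1
        else:
            for s, e in reversed(self.cds):
                if s <= pos <= e:
                    return offset + (e - pos)
                offset += e - s + 1
        return None

    def coding_sequence(self, genome: Mapping[str, str]) -> str:
        """Spliced CDS on the coding strand (reverse-complemented for '−')."""
        seq = "".join(genome[self.chrom][s - 1:e] for s, e in self.cds)
        if self.strand == "-":
            seq = "".join(COMPLEMENT[b] for b in reversed(seq))
        return seq


@dataclass(frozen=True)
class Proteoform:
    """One protein sequence produced by a specific combination of edits."""

    transcript_id: str
    sequence: str
    edit_set: frozenset[str]
    edited_residues: frozenset[int]  # 0-based residue indices carrying an edit
    truncated: bool = False


@dataclass
class PeptideRecord:
    """A tryptic peptide from an edited proteoform.

    ``sources`` lists every (transcript, edit-combination) proteoform the
    sequence arises from; ``is_edited_unique`` flags absence from the
    digest of the unedited proteome.
    """

    sequence: str
    sources: list[tuple[str, frozenset[str]]] = field(default_factory=list)
    missed_cleavages: int = 0
    is_edited_unique: bool = True

    @property
    def edit_sites(self) -> frozenset[str]:
        out: set[str] = set()
        for _, edits in self.sources:
            out |= edits
        return frozenset(out)


@dataclass(frozen=True)
class CodingEffect:
    kind: str  # "recoding" | "synonymous" | "noncoding"
    aa_ref: str | None = None
    aa_alt: str | None = None
    codon_index: int | None = None

    def __str__(self) -> str:
        if self.kind == "recoding":
            return f"recoding({self.aa_ref}->{self.aa_alt})"
        return self.kind


def _check_cds(cds_seq: str, model: TranscriptModel) -> None:
    if len(cds_seq) % 3 != 0:
        raise ValueError(
            f"model {model.transcript_id}: CDS length {len(cds_seq)} not a multiple of 3"
        )


def coding_effect(
    chrom: str,
    pos: int,
    alt: str,
    model: TranscriptModel,
    genome: Mapping[str, str],
) -> CodingEffect:
    """Classify one edit against one transcript model.

    The edited base is substituted on the coding strand and the affected
    codon translated with the standard genetic code; positions outside the
    CDS are non-coding.
    """
    if chrom != model.chrom or not model.contains(pos):
        return CodingEffect("noncoding")
    idx = model.cds_index(pos)
    if idx is None:
        return CodingEffect("noncoding")
    cds = model.coding_sequence(genome)
    _check_cds(cds, model)
    base = alt if model.strand == "+" else COMPLEMENT[alt]
    codon_i = idx // 3
    codon = cds[3 * codon_i:3 * codon_i + 3]
    new_codon = codon[: idx % 3] + base + codon[idx % 3 + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(new_codon).translate())
    if aa_ref == aa_alt:
        return CodingEffect("synonymous", aa_ref, aa_alt, codon_i)
    return CodingEffect("recoding", aa_ref, aa_alt, codon_i)


def enumerate_proteoforms(
    model: TranscriptModel,
    genome: Mapping[str, str],
    recoding_sites: Sequence[tuple[str, int, str]],
    max_sites_per_transcript: int = 16,
) -> list[Proteoform]:
    """All 2^k − 1 edited proteoforms for k re-coding sites on one transcript.

    ``recoding_sites`` holds (site_id, genomic position, alt base) triples
    that must map into the model's CDS.  The unedited form is excluded.
    An edit creating a premature stop truncates the proteoform (with a
    warning).  k above ``max_sites_per_transcript`` is refused outright as
    a combinatorial guard.
    """
    k = len(recoding_sites)
    if k > max_sites_per_transcript:
        raise ValueError(
            f"{k} re-coding sites on {model.transcript_id} exceed the "
            f"combinatorial guard of {max_sites_per_transcript}"
        )
    if k == 0:
        return []
    cds = model.coding_sequence(genome)
    _check_cds(cds, model)
    mapped = []
    for site_id, pos, alt in recoding_sites:
        idx = model.cds_index(pos)
        if idx is None:
            raise ValueError(f"site {site_id} does not map to the CDS of {model.transcript_id}")
        base = alt if model.strand == "+" else COMPLEMENT[alt]
        mapped.append((site_id, idx, base))

    out: list[Proteoform] = []
    for mask in range(1, 2 ** k):
        chosen = [mapped[i] for i in range(k) if mask >> i & 1]
        seq = list(cds)
        for _, idx, base in chosen:
            seq[idx] = base
        protein = str(Seq("".join(seq)).translate())
        full_len = len(protein)
        stop = protein.find("*")
        truncated = False
        if stop != -1:
            truncated = stop < full_len - 1
            protein = protein[:stop]
        if truncated:
            warnings.warn(
                f"edit combination on {model.transcript_id} creates a premature "
                f"stop at residue {stop}; proteoform truncated",
                stacklevel=2,
            )
        edited = frozenset(idx // 3 for _, idx, _b in chosen if idx // 3 < len(protein))
        out.append(
            Proteoform(
                transcript_id=model.transcript_id,
                sequence=protein,
                edit_set=frozenset(s for s, _, _ in chosen),
                edited_residues=edited,
                truncated=truncated,
            )
        )
    return out


def tryptic_digest(
    protein: str,
    max_missed: int = 2,
    min_length: int = 6,
) -> list[tuple[str, int, int]]:
    """Fully tryptic peptides of a protein as (sequence, start, missed) triples.

    Cleaves C-terminal to K or R except when the next residue is P, emits
    every peptide with 0..max_missed internal missed cleavages and length
    ≥ min_length, ordered N→C then by missed-cleavage count.  ``start`` is
    the 0-based residue index of the peptide in the protein.
    """
    if not protein:
        raise ValueError("empty protein sequence")
    bad = set(protein) - AA_ALPHABET
    if bad:
        raise ValueError(f"invalid residues in protein: {sorted(bad)}")
    # cut points: index i means a cut between residue i-1 and i
    cuts = [0]
    for i in range(len(protein) - 1):
        if protein[i] in "KR" and protein[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(protein))
    peptides: list[tuple[str, int, int]] = []
    for a in range(len(cuts) - 1):
        for missed in range(0, max_missed + 1):
            b = a + 1 + missed
            if b >= len(cuts):
                break
            seq = protein[cuts[a]:cuts[b]]
            if len(seq) >= min_length:
                peptides.append((seq, cuts[a], missed))
    return peptides


def build_edited_peptide_db(
    proteoforms: Iterable[Proteoform],
    unedited_proteome: Mapping[str, str],
    max_missed: int = 2,
    min_length: int = 6,
) -> list[PeptideRecord]:
    """Unique edited tryptic peptides absent from the unedited proteome.

    A peptide is retained when it covers at least one edited residue and
    its sequence does not occur in the digest of any unedited proteome
    entry under the same digestion parameters.  Records are deduplicated
    by sequence, accumulating every source proteoform.
    """
    background: set[str] = set()
    for seq in unedited_proteome.values():
        for pep, _, _ in tryptic_digest(seq, max_missed=max_missed, min_length=min_length):
            background.add(pep)

    records: dict[str, PeptideRecord] = {}
    for pf in proteoforms:
        if not pf.edit_set or not pf.sequence:
            continue
        for pep, start, missed in tryptic_digest(
            pf.sequence, max_missed=max_missed, min_length=min_length
        ):
            covered = set(range(start, start + len(pep)))
            if not covered & pf.edited_residues:
                continue
            if pep in background:
                continue
            rec = records.get(pep)
            if rec is None:
                rec = PeptideRecord(sequence=pep, missed_cleavages=missed)
                records[pep] = rec
            src = (pf.transcript_id, pf.edit_set)
            if src not in rec.sources:
                rec.sources.append(src)
    return [records[s] for s in sorted(records)]


def peptide_db_fasta(records: Iterable[PeptideRecord]) -> str:
    """FASTA of an edited-peptide database; headers encode transcript + edit set."""
    lines = []
    for rec in records:
        tags = ";".join(
            f"{tx}[{','.join(sorted(edits))}]" for tx, edits in rec.sources
        )
        lines.append(f">edited|{tags}")
        lines.append(rec.sequence)
    return "\n".join(lines) + ("\n" if lines else "")


def match_observed_peptides(
    observed: Sequence[str],
    db: Sequence[PeptideRecord],
) -> tuple[list[PeptideRecord], pd.DataFrame]:
    """Exact-match observed peptide sequences against the edited database.

    Returns the matched records and a per-site concordance table saying,
    for each re-coding site in the database, whether at least one edited
    peptide carrying it was observed ("confirmed") or not ("RNA-only").
    """
    if len(observed) == 0:
        raise ValueError("observed peptide list is empty")
    observed_set = set(observed)
    matched = [rec for rec in db if rec.sequence in observed_set]
    site_total: dict[str, int] = {}
    site_hit: dict[str, int] = {}
    for rec in db:
        hit = rec.sequence in observed_set
        for site in rec.edit_sites:
            site_total[site] = site_total.get(site, 0) + 1
            site_hit[site] = site_hit.get(site, 0) + int(hit)
    rows = [
        {
            "site_id": site,
            "n_db_peptides": site_total[site],
            "n_matched": site_hit[site],
            "status": "confirmed" if site_hit[site] > 0 else "RNA-only",
        }
        for site in sorted(site_total)
    ]
    table = pd.DataFrame(rows, columns=["site_id", "n_db_peptides", "n_matched", "status"])
    return matched, table
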