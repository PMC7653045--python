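"""Candidate-epitope library construction from HERV transcripts.

HERV loci annotated as transcriptionally active are deposited as one to four
transcript accessions per locus.  Each transcript is translated from its first
start codon to the first in-frame stop, the resulting protein is chopped into
overlapping 9-11mer peptides, and peptides predicted to bind one of the
screened HLA class I alleles (percentile rank <= 2 by default) enter the final
library.  A peptide may derive from several loci; the library keeps one record
per (peptide, allele) and annotates the union of source loci.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "HervTranscript",
    "PeptideRecord",
    "RankProvider",
    "translate_first_orf",
    "chop_peptides",
    "build_library",
    "merge_annotate",
    "read_transcript_fasta",
    "write_library_tsv",
    "read_library_tsv",
    "rank_table_provider",
]

RankProvider = Callable[[str, str], float]

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
_STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)
_ACGT = frozenset("ACGT")

PEPTIDE_LENGTHS = (9, 10, 11)
DEFAULT_RANK_THRESHOLD = 2.0


class ProviderError(RuntimeError):
    """Raised when the binding-rank provider fails for a (peptide, allele) query."""


@dataclass(frozen=True)
class HervTranscript:
    """One deposited transcript of a HERV locus."""

    locus_name: str
    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.locus_name:
            raise ValueError("locus_name must be non-empty")
        if not self.sequence:
            raise ValueError(f"transcript {self.accession!r} has empty sequence")


@dataclass
class PeptideRecord:
    """A candidate epitope: peptide bound to one HLA with its predicted rank."""

    peptide: str
    allele: str
    rank: float
    affinity: float | None = None
    source_loci: frozenset[str] = field(default_factory=frozenset)

    @property
    def occurrences(self) -> int:
        """Number of distinct source HERV loci encoding this peptide."""
        return len(self.source_loci)


def translate_first_orf(sequence: str) -> str:
    """Translate a nucleotide sequence from its first ATG to the first stop.

    The reading frame is set by the first ATG anywhere on the given strand.
    Translation stops before the first in-frame stop codon; if no stop occurs,
    the trailing incomplete codon is dropped.  Codons containing characters
    outside {A, C, G, T} translate to ``'X'``.  Returns the empty string when
    no ATG is present.
    """
    seq = sequence.upper()
    start = seq.find("ATG")
    if start < 0:
        return ""
    aa: list[str] = []
    for i in range(start, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in _STOP_CODONS:
            break
        if set(codon) <= _ACGT:
            aa.append(_CODON_TO_AA[codon])
        else:
            aa.append("X")
    return "".join(aa)


def chop_peptides(
    aa: str, lengths: Sequence[int] = PEPTIDE_LENGTHS
) -> list[tuple[str, int, int]]:
    """Enumerate all overlapping substrings of the requested lengths.

    Returns ``(peptide, start_offset, length)`` tuples ordered by length then
    start.  A protein shorter than every requested length yields nothing; this
    is the "long enough" exclusion applied to short translations.
    """
    if not lengths:
        raise ValueError("lengths must be non-empty")
    out: list[tuple[str, int, int]] = []
    for length in sorted(lengths):
        for i in range(len(aa) - length + 1):
            out.append((aa[i : i + length], i, length))
    return out


def build_library(
    transcripts: Iterable[HervTranscript],
    provider: RankProvider,
    alleles: Sequence[str],
    threshold: float = DEFAULT_RANK_THRESHOLD,
    lengths: Sequence[int] = PEPTIDE_LENGTHS,
) -> list[PeptideRecord]:
    """Build the binder library from transcripts and a rank provider.

    Peptides containing 'X' are dropped before prediction.  A peptide passing
    the threshold for several alleles yields one record per allele.  Records
    from multiple transcripts/loci are merged via :func:`merge_annotate`.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    # peptide -> set of loci encoding it
    sources: dict[str, set[str]] = {}
    for tx in transcripts:
        aa = translate_first_orf(tx.sequence)
        for pep, _, _ in chop_peptides(aa, lengths):
            if "X" in pep:
                continue
            sources.setdefault(pep, set()).add(tx.locus_name)

    raw: list[PeptideRecord] = []
    for pep in sorted(sources):
        for allele in alleles:
            try:
                rank = float(provider(pep, allele))
            except Exception as exc:  # noqa: BLE001 - abort with offending query
                raise ProviderError(
                    f"rank provider failed for peptide={pep!r} allele={allele!r}"
                ) from exc
            if rank <= threshold:
                raw.append(
                    PeptideRecord(
                        peptide=pep,
                        allele=allele,
                        rank=rank,
                        source_loci=frozenset(sources[pep]),
                    )
                )
    return merge_annotate(raw)


def merge_annotate(records: Iterable[PeptideRecord]) -> list[PeptideRecord]:
    """Deduplicate records to one per (peptide, allele).

    Source loci are unioned; transcripts of the same locus count that locus
    once.  Conflicting ranks for an identical (peptide, allele) indicate a
    non-deterministic provider and abort.
    """
    merged: dict[tuple[str, str], PeptideRecord] = {}
    for rec in records:
        key = (rec.peptide, rec.allele)
        if key not in merged:
            merged[key] = PeptideRecord(
                peptide=rec.peptide,
                allele=rec.allele,
                rank=rec.rank,
                affinity=rec.affinity,
                source_loci=frozenset(rec.source_loci),
            )
        else:
            prev = merged[key]
            if prev.rank != rec.rank:
                raise ValueError(
                    f"conflicting ranks for {key}: {prev.rank} vs {rec.rank}"
                )
            merged[key] = PeptideRecord(
                peptide=prev.peptide,
                allele=prev.allele,
                rank=prev.rank,
                affinity=prev.affinity,
                source_loci=prev.source_loci | rec.source_loci,
            )
    return list(merged.values())


# ---------------------------------------------------------------------------
# IO

def read_transcript_fasta(path: str | Path) -> list[HervTranscript]:
    """Read transcripts from FASTA with ``>locus|accession`` headers."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        locus, _, accession = rec.id.partition("|")
        out.append(
            HervTranscript(
                locus_name=locus, accession=accession or rec.id, sequence=str(rec.seq)
            )
        )
    return out


def write_library_tsv(records: Iterable[PeptideRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["peptide", "allele", "rank", "affinity", "source_loci", "occurrences"])
        for r in records:
            w.writerow(
                [
                    r.peptide,
                    r.allele,
                    r.rank,
                    "" if r.affinity is None else r.affinity,
                    ";".join(sorted(r.source_loci)),
                    r.occurrences,
                ]
            )


def read_library_tsv(path: str | Path) -> list[PeptideRecord]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                PeptideRecord(
                    peptide=row["peptide"],
                    allele=row["allele"],
                    rank=float(row["rank"]),
                    affinity=float(row["affinity"]) if row.get("affinity") else None,
                    source_loci=frozenset(
                        s for s in row["source_loci"].split(";") if s
                    ),
                )
            )
    return out


def rank_table_provider(path: str | Path) -> RankProvider:
    """Wrap a precomputed rank table (TSV: peptide, allele, rank[, affinity])
    as a provider; queries absent from the table raise (abort semantics)."""
    table: dict[tuple[str, str], float] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            table[(row["peptide"], row["allele"])] = float(row["rank"])

    def provider(peptide: str, allele: str) -> float:
        return table[(peptide, allele)]

    return provider
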