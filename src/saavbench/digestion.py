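"""Protein FASTA input and in silico tryptic digestion.

Digestion follows the search-engine convention: cleavage C-terminal to K or R,
suppressed when the next residue is proline, up to two missed cleavages, and a
6-61 residue peptide length window. Positions are 1-based and spans closed
throughout the package.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from .masses import STANDARD_AA

logger = logging.getLogger(__name__)

SPECIES = ("human", "mouse")

DEFAULT_MAX_MISSED = 2
DEFAULT_MIN_LEN = 6
DEFAULT_MAX_LEN = 61

#: Named header dialects for gene-symbol extraction; any regular expression
#: with one capture group is also accepted.
SYMBOL_DIALECTS = {
    "gn": r"GN=(\S+)",                      # UniProt-style "GN=ALB"
    "bar": r"^[^|]*\|[^|]*\|([^_\s|]+)",    # bar-delimited "sp|P02768|ALB_HUMAN"
}

_STANDARD_SET = frozenset(STANDARD_AA)


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry."""

    accession: str
    gene_symbol: str
    species: str
    sequence: str
    digestible: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.accession}")
        if self.species not in SPECIES:
            raise ValueError(f"species must be one of {SPECIES}, got {self.species!r}")


@dataclass(frozen=True)
class PeptideRecord:
    """One tryptic peptide with its provenance in the parent protein."""

    sequence: str
    start: int  # 1-based position in the parent
    missed_cleavages: int
    parent_accessions: frozenset[str] = field(default_factory=frozenset)


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(
    path: str | Path,
    species: str,
    symbol_parser: str = "gn",
) -> list[ProteinRecord]:
    """Read a protein FASTA (plain or gzip) into :class:`ProteinRecord` objects.

    ``symbol_parser`` is a named dialect (``"gn"``, ``"bar"``) or a regular
    expression with one capture group applied to the full header line. Records
    whose sequence contains letters outside the 20 standard amino acids are
    retained but flagged non-digestible. Falls back to the record id when no
    symbol matches.
    """
    if species not in SPECIES:
        raise ValueError(f"species must be one of {SPECIES}, got {species!r}")
    pattern = re.compile(SYMBOL_DIALECTS.get(symbol_parser, symbol_parser))
    records: list[ProteinRecord] = []
    with _open_maybe_gzip(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            header = rec.description
            m = pattern.search(header)
            symbol = m.group(1) if m else rec.id
            seq = str(rec.seq).upper()
            records.append(
                ProteinRecord(
                    accession=rec.id,
                    gene_symbol=symbol,
                    species=species,
                    sequence=seq,
                    digestible=set(seq) <= _STANDARD_SET,
                )
            )
    if not records:
        raise ValueError(f"no FASTA entries found in {path}")
    return records


def cleavage_boundaries(sequence: str) -> list[int]:
    """All peptide-bond boundaries: 0, the sequence end, and every position
    immediately after K or R not followed by P."""
    n = len(sequence)
    bounds = [0]
    for i, aa in enumerate(sequence):
        if aa in "KR" and i + 1 < n and sequence[i + 1] != "P":
            bounds.append(i + 1)
    bounds.append(n)
    return bounds


def digest_protein(
    sequence: str,
    max_missed: int = DEFAULT_MAX_MISSED,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    parent_accession: str | None = None,
) -> list[PeptideRecord]:
    """Fully tryptic digestion of one sequence.

    Emits every span between cleavage boundaries containing at most
    ``max_missed`` internal cleavage sites, then applies the length window —
    so missed-cleavage products are filtered against the same bounds.
    """
    for pos, aa in enumerate(sequence, start=1):
        if aa not in _STANDARD_SET:
            raise ValueError(f"non-standard residue {aa!r} at position {pos}")
    bounds = cleavage_boundaries(sequence)
    parents = frozenset([parent_accession]) if parent_accession else frozenset()
    peptides: list[PeptideRecord] = []
    for i in range(len(bounds) - 1):
        for mc in range(max_missed + 1):
            j = i + mc + 1
            if j >= len(bounds):
                break
            start, end = bounds[i], bounds[j]
            if min_len <= end - start <= max_len:
                peptides.append(
                    PeptideRecord(
                        sequence=sequence[start:end],
                        start=start + 1,
                        missed_cleavages=mc,
                        parent_accessions=parents,
                    )
                )
    return peptides


class PeptideIndex:
    """Digested-peptide index keyed by (species, gene_symbol).

    Per key, peptides are deduplicated by sequence across isoforms; each
    entry keeps the union of parent accessions and the smallest
    missed-cleavage count observed.
    """

    def __init__(self) -> None:
        self.entries: dict[tuple[str, str], dict[str, dict]] = {}
        self.n_skipped: int = 0

    def add(self, species: str, gene_symbol: str, peptide: PeptideRecord) -> None:
        bucket = self.entries.setdefault((species, gene_symbol), {})
        entry = bucket.get(peptide.sequence)
        if entry is None:
            bucket[peptide.sequence] = {
                "parents": set(peptide.parent_accessions),
                "missed_cleavages": peptide.missed_cleavages,
            }
        else:
            entry["parents"] |= peptide.parent_accessions
            entry["missed_cleavages"] = min(
                entry["missed_cleavages"], peptide.missed_cleavages
            )

    def genes(self, species: str) -> list[str]:
        return [g for (sp, g) in self.entries if sp == species]

    def peptides(self, species: str, gene_symbol: str) -> dict[str, dict]:
        return self.entries.get((species, gene_symbol), {})

    def all_peptides(self, species: str) -> Iterator[tuple[str, str]]:
        """Yield (gene_symbol, peptide) over one species."""
        for (sp, gene), bucket in self.entries.items():
            if sp == species:
                for pep in bucket:
                    yield gene, pep

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (sp, gene), bucket in sorted(self.entries.items()):
            for pep, entry in sorted(bucket.items()):
                rows.append(
                    {
                        "species": sp,
                        "gene_symbol": gene,
                        "peptide": pep,
                        "missed_cleavages": entry["missed_cleavages"],
                        "parents": ";".join(sorted(entry["parents"])),
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["species", "gene_symbol", "peptide", "missed_cleavages", "parents"],
        )


def digest_proteome(
    records: Iterable[ProteinRecord],
    max_missed: int = DEFAULT_MAX_MISSED,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> PeptideIndex:
    """Digest a proteome into a gene-keyed peptide index.

    Non-digestible records (non-standard letters) are skipped and counted.
    """
    records = list(records)
    if not records:
        raise ValueError("no protein records to digest")
    index = PeptideIndex()
    for rec in records:
        if not rec.digestible:
            index.n_skipped += 1
            continue
        for pep in digest_protein(
            rec.sequence,
            max_missed=max_missed,
            min_len=min_len,
            max_len=max_len,
            parent_accession=rec.accession,
        ):
            index.add(rec.species, rec.gene_symbol, pep)
    if index.n_skipped:
        logger.info("digest_proteome: skipped %d non-digestible records", index.n_skipped)
    return index
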