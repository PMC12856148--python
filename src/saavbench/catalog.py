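"""Cross-species SAAV catalog: cognate-peptide pairing, mass shifts, census.

A cognate pair is a human tryptic peptide and a mouse tryptic peptide from
orthologous genes, of equal length, differing at exactly one residue — the
operational definition of a peptide-embedded single amino acid variation
(SAAV). Pairs are oriented human→mouse, so the catalog's SAAVs play the role
of "translational errors" relative to the human reference.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .digestion import PeptideIndex
from .masses import IL_CLASS, MONO_MASS, residue_mass, same_category

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SaavCall:
    """An ordered amino-acid substitution with its monoisotopic mass shift.

    ``to_aa`` may be ``'X'``, the isobaric Leu/Ile class used when the
    destination is inferred from a mass shift alone.
    """

    from_aa: str
    to_aa: str
    delta_mass: float

    def __post_init__(self) -> None:
        if self.from_aa == self.to_aa:
            raise ValueError(f"identity substitution {self.from_aa}->{self.to_aa}")

    @property
    def label(self) -> str:
        return f"{self.from_aa}>{self.to_aa}"


@dataclass(frozen=True)
class CognatePair:
    """An equal-length human/mouse peptide pair differing at exactly one site."""

    gene_symbol: str
    human_peptide: str
    mouse_peptide: str
    site: int  # 1-based index within the peptide
    saav: SaavCall  # human -> mouse orientation


def compute_saav_mass_shift(
    from_aa: str, to_aa: str, table: Mapping[str, float] | None = None
) -> float:
    """Theoretical monoisotopic mass shift of substituting ``from_aa`` by
    ``to_aa`` (destination minus origin); ``'X'`` uses the shared L/I mass."""
    return residue_mass(to_aa, table) - residue_mass(from_aa, table)


def saav_call(from_aa: str, to_aa: str, table: Mapping[str, float] | None = None) -> SaavCall:
    return SaavCall(from_aa, to_aa, compute_saav_mass_shift(from_aa, to_aa, table))


def load_ortholog_map(path: str | Path) -> dict[str, str]:
    """Read a two-column tab-delimited human_symbol → mouse_symbol map.

    Duplicated human symbols keep the first mapping (warning logged).
    """
    mapping: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(f"{path}: malformed ortholog line {lineno}: {line!r}")
            human, mouse = fields[0], fields[1]
            if human in mapping:
                logger.warning(
                    "duplicate human symbol %s at line %d; keeping first", human, lineno
                )
                continue
            mapping[human] = mouse
    return mapping


def _hamming_one_site(a: str, b: str) -> int | None:
    """0-based index of the single mismatch, or None if distance != 1."""
    site = -1
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            if site >= 0:
                return None
            site = i
    return None if site < 0 else site


def find_cognate_saav_pairs(
    index: PeptideIndex,
    ortholog_map: Mapping[str, str],
    table: Mapping[str, float] | None = None,
) -> list[CognatePair]:
    """Enumerate all cognate SAAV pairs over orthologous genes.

    For each ortholog pair, every (human peptide, mouse peptide) combination
    of equal length at Hamming distance exactly 1 yields one pair; pairs are
    deduplicated on (human_peptide, mouse_peptide). Genes absent from one
    species are skipped (counted in the log).
    """
    pairs: list[CognatePair] = []
    seen: set[tuple[str, str]] = set()
    n_skipped_genes = 0
    for human_gene, mouse_gene in ortholog_map.items():
        human_peps = index.peptides("human", human_gene)
        mouse_peps = index.peptides("mouse", mouse_gene)
        if not human_peps or not mouse_peps:
            n_skipped_genes += 1
            continue
        by_len: dict[int, list[str]] = {}
        for mp in mouse_peps:
            by_len.setdefault(len(mp), []).append(mp)
        for hp in human_peps:
            for mp in by_len.get(len(hp), ()):
                if (hp, mp) in seen:
                    continue
                site0 = _hamming_one_site(hp, mp)
                if site0 is None:
                    continue
                seen.add((hp, mp))
                pairs.append(
                    CognatePair(
                        gene_symbol=human_gene,
                        human_peptide=hp,
                        mouse_peptide=mp,
                        site=site0 + 1,
                        saav=saav_call(hp[site0], mp[site0], table),
                    )
                )
    if n_skipped_genes:
        logger.info(
            "find_cognate_saav_pairs: %d ortholog genes absent from one species",
            n_skipped_genes,
        )
    return pairs


def classify_substitution(
    from_aa: str, to_aa: str, categories: Mapping[str, str] | None = None
) -> bool:
    """True iff both residues fall in the same biochemical category."""
    return same_category(from_aa, to_aa, categories)


def saav_census(
    substitutions: Iterable[SaavCall | CognatePair],
    top_n: int | None = None,
    categories: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Frequency census of ordered substitutions.

    Accepts any mixture of :class:`SaavCall` and :class:`CognatePair` (any
    substitution list is admissible, e.g. one derived from somatic-mutation
    calls). Returns a table ranked by descending count, ties broken
    lexicographically, each row carrying its same-category classification.
    """
    counts: Counter[tuple[str, str]] = Counter()
    for item in substitutions:
        call = item.saav if isinstance(item, CognatePair) else item
        counts[(call.from_aa, call.to_aa)] += 1
    rows = [
        {
            "from_aa": f,
            "to_aa": t,
            "count": c,
            "same_category": classify_substitution(f, t, categories),
        }
        for (f, t), c in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["from_aa", "to_aa", "count", "same_category"])
    if df.empty:
        return df
    df = df.sort_values(
        ["count", "from_aa", "to_aa"], ascending=[False, True, True]
    ).reset_index(drop=True)
    if top_n is not None:
        df = df.head(top_n)
    return df


def same_category_fraction(census: pd.DataFrame, weighting: str = "pair_instances") -> float:
    """Fraction of same-category substitutions in a census table.

    ``pair_instances`` weights by occurrence counts (the default, matching a
    per-peptide-pair census); ``unique_types`` counts each distinct ordered
    substitution once.
    """
    if census.empty:
        raise ValueError("empty census")
    if weighting == "pair_instances":
        return float(
            (census["count"] * census["same_category"]).sum() / census["count"].sum()
        )
    if weighting == "unique_types":
        return float(census["same_category"].mean())
    raise ValueError(f"unknown weighting {weighting!r}")


def pairs_to_frame(pairs: Iterable[CognatePair]) -> pd.DataFrame:
    """Catalog as a table (gene, peptides, site, substitution, shift, category)."""
    rows = [
        {
            "gene_symbol": p.gene_symbol,
            "human_peptide": p.human_peptide,
            "mouse_peptide": p.mouse_peptide,
            "site": p.site,
            "from_aa": p.saav.from_aa,
            "to_aa": p.saav.to_aa,
            "delta_mass": round(p.saav.delta_mass, 5),
            "same_category": classify_substitution(p.saav.from_aa, p.saav.to_aa),
        }
        for p in pairs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_symbol",
            "human_peptide",
            "mouse_peptide",
            "site",
            "from_aa",
            "to_aa",
            "delta_mass",
            "same_category",
        ],
    )


def pairs_from_frame(df: pd.DataFrame, table: Mapping[str, float] | None = None) -> list[CognatePair]:
    """Rebuild :class:`CognatePair` objects from a catalog table."""
    return [
        CognatePair(
            gene_symbol=row.gene_symbol,
            human_peptide=row.human_peptide,
            mouse_peptide=row.mouse_peptide,
            site=int(row.site),
            saav=saav_call(row.from_aa, row.to_aa, table),
        )
        for row in df.itertuples(index=False)
    ]


__all__ = [
    "SaavCall",
    "CognatePair",
    "pairs_from_frame",
    "compute_saav_mass_shift",
    "saav_call",
    "load_ortholog_map",
    "find_cognate_saav_pairs",
    "classify_substitution",
    "saav_census",
    "same_category_fraction",
    "pairs_to_frame",
    "MONO_MASS",
    "IL_CLASS",
]
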