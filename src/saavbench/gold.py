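"""Gold-standard PSM sets from closed-search results.

The gold standard is the set of closed-search PSMs (against the concatenated
human+mouse database) whose peptide is the mouse member of a cognate SAAV
pair — i.e. spectra where a "translational-error-like" peptide was confidently
observed. Two imperfect closed-search tools yield two gold sets; their
intersection (strict, for sensitivity) and union (lenient, for precision)
form the mixed gold standard.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .catalog import CognatePair

logger = logging.getLogger(__name__)

#: Normalized PSM table columns. Mandatory: sample_id, spectrum_id, tool,
#: peptide. The rest are optional and may be absent or null.
PSM_MANDATORY = ["sample_id", "spectrum_id", "peptide"]
PSM_OPTIONAL = [
    "tool",
    "charge",
    "delta_mass",
    "site",
    "site_probability",
    "retention_time",
    "score",
]

GoldKey = tuple[str, str]  # (spectrum_id, peptide)


@dataclass
class GoldStandardSet:
    """Per-sample sets of (spectrum_id, mouse_peptide) gold keys."""

    keys: dict[str, set[GoldKey]] = field(default_factory=dict)
    provenance: str = ""

    def n_total(self) -> int:
        return sum(len(s) for s in self.keys.values())

    def sample_ids(self) -> list[str]:
        return sorted(self.keys)

    def get(self, sample_id: str) -> set[GoldKey]:
        return self.keys.get(sample_id, set())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": s,
                "spectrum_id": spec,
                "peptide": pep,
                "provenance": self.provenance,
            }
            for s in sorted(self.keys)
            for spec, pep in sorted(self.keys[s])
        ]
        return pd.DataFrame(
            rows, columns=["sample_id", "spectrum_id", "peptide", "provenance"]
        )


def _dedup_best_scoring(psms: pd.DataFrame) -> pd.DataFrame:
    """One PSM per (sample, spectrum): keep the best-scoring row (chimeric
    spectra reported with several peptides collapse to their top hit)."""
    if "score" in psms.columns and psms["score"].notna().any():
        psms = psms.sort_values("score", ascending=False, kind="stable")
    return psms.drop_duplicates(subset=["sample_id", "spectrum_id"], keep="first")


def build_gold_standard(
    closed_psms: pd.DataFrame,
    pairs: Iterable[CognatePair],
    provenance: str | None = None,
) -> GoldStandardSet:
    """Gold PSMs: closed-search PSMs whose peptide is a catalog mouse peptide.

    Matching is exact string equality (the closed search assigns database
    sequences, so I and L are disambiguated).
    """
    for col in PSM_MANDATORY:
        if col not in closed_psms.columns:
            raise ValueError(f"closed PSM table lacks mandatory column {col!r}")
    mouse_peptides = {p.mouse_peptide for p in pairs}
    psms = _dedup_best_scoring(closed_psms)
    hit = psms[psms["peptide"].isin(mouse_peptides)]
    gs = GoldStandardSet(provenance=provenance or _infer_tool(closed_psms))
    for sample_id, grp in hit.groupby("sample_id", sort=True):
        gs.keys[str(sample_id)] = set(
            zip(grp["spectrum_id"].astype(str), grp["peptide"])
        )
    if gs.n_total() == 0:
        logger.warning("gold standard (%s) is empty", gs.provenance)
    return gs


def build_dependent_gold_standard(
    closed_psms: pd.DataFrame,
    pairs: Iterable[CognatePair],
    provenance: str | None = None,
) -> GoldStandardSet:
    """Gold PSMs restricted to mouse peptides whose cognate human peptide was
    also identified in the same sample — the ground truth appropriate for a
    dependent-peptide search, which can only explain a spectrum as a modified
    form of a base peptide it has already identified."""
    pairs = list(pairs)
    base = build_gold_standard(closed_psms, pairs, provenance=provenance)
    human_of: dict[str, set[str]] = {}
    for p in pairs:
        human_of.setdefault(p.mouse_peptide, set()).add(p.human_peptide)
    psms = _dedup_best_scoring(closed_psms)
    peptides_by_sample = {
        str(s): set(grp["peptide"]) for s, grp in psms.groupby("sample_id")
    }
    out = GoldStandardSet(provenance=(base.provenance + "+dependent").lstrip("+"))
    for sample_id, keys in base.keys.items():
        present = peptides_by_sample.get(sample_id, set())
        kept = {
            (spec, pep)
            for spec, pep in keys
            if human_of.get(pep, set()) & present
        }
        if kept:
            out.keys[sample_id] = kept
    return out


def mix_gold_standards(
    gs_a: GoldStandardSet, gs_b: GoldStandardSet, mode: str
) -> GoldStandardSet:
    """Per-sample intersection or union of two gold sets."""
    if mode not in ("intersection", "union"):
        raise ValueError(f"mode must be 'intersection' or 'union', got {mode!r}")
    out = GoldStandardSet(provenance=mode)
    samples = set(gs_a.keys) | set(gs_b.keys)
    for s in samples:
        a, b = gs_a.get(s), gs_b.get(s)
        merged = (a & b) if mode == "intersection" else (a | b)
        if merged:
            out.keys[s] = merged
    return out


def _infer_tool(psms: pd.DataFrame) -> str:
    if "tool" in psms.columns and psms["tool"].notna().any():
        tools = psms["tool"].dropna().unique()
        if len(tools) == 1:
            return str(tools[0])
    return "closed"


def validate_psm_frame(df: pd.DataFrame, context: str = "PSM table") -> pd.DataFrame:
    """Check mandatory columns and add any missing optional ones as nulls."""
    for col in PSM_MANDATORY:
        if col not in df.columns:
            raise ValueError(f"{context} lacks mandatory column {col!r}")
    df = df.copy()
    for col in PSM_OPTIONAL:
        if col not in df.columns:
            df[col] = pd.NA
    return df


__all__ = [
    "GoldStandardSet",
    "GoldKey",
    "PSM_MANDATORY",
    "PSM_OPTIONAL",
    "build_gold_standard",
    "build_dependent_gold_standard",
    "mix_gold_standards",
    "validate_psm_frame",
]
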