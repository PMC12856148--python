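"""Open-search PSM normalization and mass-shift → SAAV assignment.

An open (or dependent-peptide) search reports, per PSM, a base peptide, an
unexplained precursor mass shift, and a modification site. A shift is called
as a SAAV when three criteria all hold:

1. among all theoretical ordered residue substitutions, the candidate pair
   minimizes the absolute difference to the observed shift;
2. that minimal difference is below a tolerance (default 0.1 Da, strict);
3. the pair's origin residue equals the base-peptide residue at the site.

Destinations leucine and isoleucine are isobaric and collapse to a single
``'X'``-destination entry per origin, so a mass-based call can never claim to
distinguish them. Ties at the minimal difference (e.g. the +CH2 family
G→A / S→T / V→X / D→E / N→Q, all +14.01565 Da) are resolved by criterion 3;
after the I/L collapse at most one entry per origin can survive, so a
residual tie (possible only with a custom mass table) is rejected rather
than guessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .gold import PSM_MANDATORY, validate_psm_frame
from .masses import IL_CLASS, MONO_MASS, STANDARD_AA

logger = logging.getLogger(__name__)

DEFAULT_TOLERANCE = 0.1
_TIE_EPS = 1e-9  # float slack when detecting exact theoretical-shift ties

REJECT_NO_PAIR = "no_pair_within_tolerance"
REJECT_ORIGIN = "origin_mismatch"
REJECT_AMBIGUOUS = "ambiguous"

#: Column-rename maps for the shipped engine dialects. These are editable:
#: ``normalize_psm_table`` also accepts a custom mapping.
ADAPTERS: dict[str, dict[str, str]] = {
    "generic": {},
    "msfragger_open": {
        "Spectrum": "spectrum_id",
        "Peptide": "peptide",
        "Delta Mass": "delta_mass",
        "MSFragger Localization": "localization",
        "Retention": "retention_time",
        "Hyperscore": "score",
        "Charge": "charge",
    },
    "maxquant_dp": {
        "Raw file": "sample_id",
        "Scan number": "spectrum_id",
        "Sequence": "peptide",
        "DP Mass Difference": "delta_mass",
        "DP Positional Probability": "site_probability",
        "DP Probabilities": "localization",
        "Retention time": "retention_time",
        "Score": "score",
        "Charge": "charge",
    },
    "openpfind": {
        "File_Name": "spectrum_id",
        "Sequence": "peptide",
        "Mass_Shift": "delta_mass",
        "Modification": "preassigned",
        "Final_Score": "score",
        "Charge": "charge",
    },
}


@dataclass(frozen=True)
class TheoreticalSaav:
    from_aa: str
    to_aa: str  # single letter or 'X' (I/L class)
    shift: float


@dataclass(frozen=True)
class SaavAssignment:
    """Result of the three-criterion rule for one PSM."""

    accepted: bool
    from_aa: str | None = None
    to_aa: str | None = None
    theoretical_shift: float | None = None
    delta_delta_mass: float | None = None
    variant_peptide: str | None = None
    reject_reason: str | None = None


def theoretical_saav_entries(
    table: Mapping[str, float] | None = None,
) -> list[TheoreticalSaav]:
    """The ordered-substitution universe with I/L destinations collapsed.

    For each of the 20 origins, destinations are the 17 non-self, non-I/L
    residues plus one ``'X'`` entry carrying the shared L/I mass (for origins
    I and L the ``'X'`` entry has shift 0, i.e. the I↔L exchange).
    """
    table = MONO_MASS if table is None else table
    entries: list[TheoreticalSaav] = []
    for a in STANDARD_AA:
        for b in STANDARD_AA:
            if b == a or b in "IL":
                continue
            entries.append(TheoreticalSaav(a, b, table[b] - table[a]))
        entries.append(TheoreticalSaav(a, IL_CLASS, table["L"] - table[a]))
    return entries


@lru_cache(maxsize=1)
def _default_entries() -> tuple[TheoreticalSaav, ...]:
    return tuple(theoretical_saav_entries())


def _entries_for(table: Mapping[str, float] | None) -> tuple[TheoreticalSaav, ...]:
    if table is None:
        return _default_entries()
    return tuple(theoretical_saav_entries(table))


def apply_substitution(peptide: str, site: int, to_aa: str) -> str:
    """Variant peptide: destination residue substituted at the 1-based site.

    An ``'X'`` destination stays literal in the string, denoting the
    I/L-ambiguity class.
    """
    if not 1 <= site <= len(peptide):
        raise ValueError(f"site {site} outside peptide of length {len(peptide)}")
    return peptide[: site - 1] + to_aa + peptide[site:]


def assign_saav(
    peptide: str,
    delta_mass: float,
    site: int,
    table: Mapping[str, float] | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
) -> SaavAssignment:
    """Apply the three-criterion SAAV rule to one (peptide, shift, site).

    Criterion order is nearest-pair first: a nearer pair with the wrong
    origin blocks a farther correct one.
    """
    if delta_mass is None or (isinstance(delta_mass, float) and np.isnan(delta_mass)):
        raise ValueError("delta_mass is required for SAAV assignment")
    if not 1 <= site <= len(peptide):
        raise ValueError(f"site {site} outside peptide of length {len(peptide)}")
    entries = _entries_for(table)
    diffs = [abs(delta_mass - e.shift) for e in entries]
    dmin = min(diffs)
    if dmin >= tolerance:
        return SaavAssignment(accepted=False, reject_reason=REJECT_NO_PAIR)
    tie = [e for e, d in zip(entries, diffs) if d <= dmin + _TIE_EPS]
    origin = peptide[site - 1]
    matching = [e for e in tie if e.from_aa == origin]
    if not matching:
        return SaavAssignment(accepted=False, reject_reason=REJECT_ORIGIN)
    if len(matching) > 1:
        logger.warning(
            "residual tie after origin filtering at site %d of %s", site, peptide
        )
        return SaavAssignment(accepted=False, reject_reason=REJECT_AMBIGUOUS)
    e = matching[0]
    return SaavAssignment(
        accepted=True,
        from_aa=e.from_aa,
        to_aa=e.to_aa,
        theoretical_shift=e.shift,
        delta_delta_mass=dmin,
        variant_peptide=apply_substitution(peptide, site, e.to_aa),
    )


def normalize_psm_table(
    source: str | Path | pd.DataFrame,
    dialect: str | Mapping[str, str] = "generic",
    tool: str | None = None,
    sample_id: str | None = None,
) -> pd.DataFrame:
    """Read / normalize a tab-delimited PSM table into the package schema.

    ``dialect`` is a shipped adapter name or a custom native→normalized
    column map. Rows missing a mandatory field are dropped (counted in the
    log). Open-pFind rows carrying a pre-assigned substitution keep it in
    ``preassigned_from``/``preassigned_to`` with ``preassigned=True``.
    """
    if isinstance(dialect, str):
        if dialect not in ADAPTERS:
            raise ValueError(
                f"unknown dialect {dialect!r}; available: {sorted(ADAPTERS)}"
            )
        colmap = ADAPTERS[dialect]
    else:
        colmap = dict(dialect)
    if isinstance(source, (str, Path)):
        df = pd.read_csv(source, sep="\t", comment="#")
    else:
        df = source.copy()
    df = df.rename(columns=colmap)
    if tool is not None:
        df["tool"] = tool
    if sample_id is not None and "sample_id" not in df.columns:
        df["sample_id"] = sample_id
    for col in PSM_MANDATORY:
        if col not in df.columns:
            raise ValueError(f"normalized PSM table lacks mandatory column {col!r}")
    if isinstance(dialect, str) and dialect == "msfragger_open" and "localization" in df:
        df = _parse_msfragger_localization(df)
    if isinstance(dialect, str) and dialect == "openpfind" and "preassigned" in df:
        df = _parse_pfind_preassigned(df)
    n0 = len(df)
    df = df.dropna(subset=PSM_MANDATORY)
    if len(df) < n0:
        logger.info("normalize_psm_table: dropped %d incomplete rows", n0 - len(df))
    df = validate_psm_frame(df, context="normalized PSM table")
    if "preassigned" not in df.columns:
        df["preassigned"] = False
    df["spectrum_id"] = df["spectrum_id"].astype(str)
    df["sample_id"] = df["sample_id"].astype(str)
    return df.reset_index(drop=True)


def _parse_msfragger_localization(df: pd.DataFrame) -> pd.DataFrame:
    """MSFragger marks the localized residue in lowercase within the peptide
    string; a single lowercase letter is a confident single-site call."""
    sites, n_sites = [], []
    for loc in df["localization"].fillna(""):
        lowers = [i for i, c in enumerate(str(loc)) if c.islower()]
        sites.append(lowers[0] + 1 if len(lowers) == 1 else pd.NA)
        n_sites.append(len(lowers))
    df = df.copy()
    df["site"] = sites
    df["n_candidate_sites"] = n_sites
    return df


def _parse_pfind_preassigned(df: pd.DataFrame) -> pd.DataFrame:
    """Parse pFind-style '<site>,Xxx->Yyy[...]' substitution annotations."""
    import re

    three_to_one = {
        "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
        "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
        "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
        "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    }
    pat = re.compile(r"(\d+),\s*([A-Z][a-z]{2})->([A-Z][a-z]{2})")
    froms, tos, sites = [], [], []
    for ann in df["preassigned"].fillna(""):
        m = pat.search(str(ann))
        if m and m.group(2) in three_to_one and m.group(3) in three_to_one:
            sites.append(int(m.group(1)))
            froms.append(three_to_one[m.group(2)])
            tos.append(three_to_one[m.group(3)])
        else:
            sites.append(pd.NA)
            froms.append(pd.NA)
            tos.append(pd.NA)
    df = df.copy()
    parsed = pd.Series(sites, index=df.index)
    if "site" in df.columns:
        df["site"] = df["site"].where(df["site"].notna(), parsed)
    else:
        df["site"] = parsed
    df["preassigned_from"] = froms
    df["preassigned_to"] = tos
    df["preassigned"] = [f is not pd.NA for f in froms]
    return df


def filter_localized_psms(psms: pd.DataFrame, tool_policy: str = "generic") -> pd.DataFrame:
    """Localization filter applied before SAAV assignment.

    * ``maxquant_dp`` — exactly one localized site with probability
      strictly greater than 0.5;
    * ``msfragger`` — localization resolves to exactly one site;
    * ``generic`` — any non-null site.
    """
    if tool_policy not in ("generic", "msfragger", "maxquant_dp"):
        raise ValueError(f"unknown localization policy {tool_policy!r}")
    has_site = psms["site"].notna()
    if tool_policy == "generic":
        keep = has_site
    else:
        if "n_candidate_sites" in psms.columns:
            single = psms["n_candidate_sites"].fillna(1).astype(float) == 1
        else:
            single = pd.Series(True, index=psms.index)
        keep = has_site & single
        if tool_policy == "maxquant_dp":
            prob = pd.to_numeric(psms.get("site_probability"), errors="coerce")
            keep = keep & (prob > 0.5)  # strict inequality
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_localized_psms(%s): dropped %d rows", tool_policy, dropped)
    return psms[keep].reset_index(drop=True)


def assign_saav_table(
    psms: pd.DataFrame,
    table: Mapping[str, float] | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
) -> pd.DataFrame:
    """Vectorized three-criterion assignment over a normalized PSM table.

    Adds columns from_aa, to_aa, theoretical_shift, delta_delta_mass,
    variant_peptide, reject_reason (empty string when accepted). Rows with a
    pre-assigned substitution (Open-pFind) bypass the nearest-pair search but
    are still validated against the origin criterion.
    """
    psms = psms.reset_index(drop=True).copy()
    entries = _entries_for(table)
    shifts = np.array([e.shift for e in entries])
    origins = np.array([e.from_aa for e in entries])

    out = {
        "from_aa": [None] * len(psms),
        "to_aa": [None] * len(psms),
        "theoretical_shift": [np.nan] * len(psms),
        "delta_delta_mass": [np.nan] * len(psms),
        "variant_peptide": [None] * len(psms),
        "reject_reason": [""] * len(psms),
    }

    dm = pd.to_numeric(psms["delta_mass"], errors="coerce").to_numpy(dtype=float)
    sites = pd.to_numeric(psms["site"], errors="coerce").to_numpy(dtype=float)
    peptides = psms["peptide"].astype(str).to_numpy()
    preassigned = (
        psms["preassigned"].fillna(False).astype(bool).to_numpy()
        if "preassigned" in psms.columns
        else np.zeros(len(psms), dtype=bool)
    )

    # |observed - theoretical| over the whole universe at once
    diffs = np.abs(dm[:, None] - shifts[None, :])
    dmins = np.nanmin(diffs, axis=1)

    for i in range(len(psms)):
        pep, site = peptides[i], sites[i]
        if np.isnan(dm[i]):
            raise ValueError(f"row {i}: missing delta_mass")
        if np.isnan(site) or not 1 <= int(site) <= len(pep):
            raise ValueError(f"row {i}: site {site} outside peptide {pep!r}")
        site = int(site)
        if preassigned[i]:
            res = _validate_preassigned(psms.iloc[i], pep, site, table)
        else:
            dmin = dmins[i]
            if dmin >= tolerance:
                res = SaavAssignment(False, reject_reason=REJECT_NO_PAIR)
            else:
                tie_idx = np.flatnonzero(diffs[i] <= dmin + _TIE_EPS)
                matching = tie_idx[origins[tie_idx] == pep[site - 1]]
                if matching.size == 0:
                    res = SaavAssignment(False, reject_reason=REJECT_ORIGIN)
                elif matching.size > 1:
                    res = SaavAssignment(False, reject_reason=REJECT_AMBIGUOUS)
                else:
                    e = entries[int(matching[0])]
                    res = SaavAssignment(
                        True,
                        from_aa=e.from_aa,
                        to_aa=e.to_aa,
                        theoretical_shift=e.shift,
                        delta_delta_mass=float(dmin),
                        variant_peptide=apply_substitution(pep, site, e.to_aa),
                    )
        out["from_aa"][i] = res.from_aa
        out["to_aa"][i] = res.to_aa
        out["theoretical_shift"][i] = (
            res.theoretical_shift if res.theoretical_shift is not None else np.nan
        )
        out["delta_delta_mass"][i] = (
            res.delta_delta_mass if res.delta_delta_mass is not None else np.nan
        )
        out["variant_peptide"][i] = res.variant_peptide
        out["reject_reason"][i] = res.reject_reason or ""

    for col, vals in out.items():
        psms[col] = vals
    return psms


def _validate_preassigned(
    row: pd.Series, pep: str, site: int, table: Mapping[str, float] | None
) -> SaavAssignment:
    """Open-pFind pre-assigned SAAVs skip the nearest-pair search but must
    still satisfy the origin criterion; destinations I/L collapse to 'X'."""
    from .catalog import compute_saav_mass_shift

    from_aa = row.get("preassigned_from")
    to_aa = row.get("preassigned_to")
    if from_aa is None or to_aa is None or pd.isna(from_aa) or pd.isna(to_aa):
        return SaavAssignment(False, reject_reason=REJECT_NO_PAIR)
    if pep[site - 1] != from_aa:
        return SaavAssignment(False, reject_reason=REJECT_ORIGIN)
    to_reported = IL_CLASS if to_aa in "IL" else str(to_aa)
    shift = compute_saav_mass_shift(str(from_aa), to_reported, table)
    dm = row.get("delta_mass")
    ddm = abs(float(dm) - shift) if dm is not None and not pd.isna(dm) else np.nan
    return SaavAssignment(
        True,
        from_aa=str(from_aa),
        to_aa=to_reported,
        theoretical_shift=shift,
        delta_delta_mass=ddm,
        variant_peptide=apply_substitution(pep, site, to_reported),
    )


def accepted_candidates(assigned: pd.DataFrame) -> pd.DataFrame:
    """Rows that passed all three criteria (downstream candidate PSMs).

    An empty reject reason marks acceptance; it may read back from TSV as
    null, so both forms count.
    """
    ok = assigned["reject_reason"].fillna("") == ""
    return assigned[ok].reset_index(drop=True)


__all__ = [
    "DEFAULT_TOLERANCE",
    "REJECT_NO_PAIR",
    "REJECT_ORIGIN",
    "REJECT_AMBIGUOUS",
    "ADAPTERS",
    "TheoreticalSaav",
    "SaavAssignment",
    "theoretical_saav_entries",
    "apply_substitution",
    "assign_saav",
    "assign_saav_table",
    "normalize_psm_table",
    "filter_localized_psms",
    "accepted_candidates",
]
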