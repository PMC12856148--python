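"""PSM-level scoring of SAAV candidates against gold standards.

Sensitivity = TP / |gold|, precision = TP / |candidates|, F1 their harmonic
mean. A candidate is a true positive when its (sample, spectrum) key is in
the gold set and its variant peptide equals the gold mouse peptide, treating
``'X'`` at the variant site as matching either I or L. In mixed mode
sensitivity is scored against the intersection gold (strict ground truth)
and precision against the union gold (lenient), each with its own TP count.

Metrics with an empty denominator are reported as missing, never as zero,
and are excluded from median aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import CognatePair, compute_saav_mass_shift
from .gold import GoldStandardSet
from .masses import IL_CLASS


@dataclass
class MetricsResult:
    """Per-sample counts and derived metrics (fractions internally; outputs
    convert to the 0-100 scale)."""

    sample_id: str
    n_gold: int
    n_candidates: int
    n_true_positive: int  # TP against the precision gold set
    n_true_positive_sensitivity: int  # TP against the sensitivity gold set
    precision: float | None
    sensitivity: float | None
    f1: float | None
    gold_mode: str = "single"

    def to_dict(self) -> dict:
        return asdict(self)


def peptides_match(variant: str, gold_peptide: str) -> bool:
    """Equality under I/L ambiguity: ``'X'`` in the variant matches I or L;
    every other position must agree exactly."""
    if len(variant) != len(gold_peptide):
        return False
    for v, g in zip(variant, gold_peptide):
        if v == g:
            continue
        if v == IL_CLASS and g in "IL":
            continue
        return False
    return True


def canonical_variant(variant: str, site: int) -> str:
    """Key form of a variant peptide: the called residue collapses to 'X'
    when it is I, L, or already X — two tools calling V→I and V→X on the
    same spectrum agree under mass-based ambiguity."""
    c = variant[site - 1]
    if c in ("I", "L", IL_CLASS):
        return variant[: site - 1] + IL_CLASS + variant[site:]
    return variant


def match_candidates_to_gold(
    candidates: pd.DataFrame, gold: GoldStandardSet
) -> set[tuple[str, str, str]]:
    """True-positive keys (sample_id, spectrum_id, variant_peptide)."""
    tp: set[tuple[str, str, str]] = set()
    lookup: dict[str, dict[str, set[str]]] = {}
    for sample, keys in gold.keys.items():
        d = lookup.setdefault(sample, {})
        for spec, pep in keys:
            d.setdefault(spec, set()).add(pep)
    for row in candidates.itertuples(index=False):
        peps = lookup.get(str(row.sample_id), {}).get(str(row.spectrum_id))
        if not peps:
            continue
        if any(peptides_match(row.variant_peptide, g) for g in peps):
            tp.add((str(row.sample_id), str(row.spectrum_id), row.variant_peptide))
    return tp


def f1_score(precision: float, sensitivity: float) -> float:
    """Harmonic mean of precision and sensitivity; 0 when both are 0."""
    for name, v in (("precision", precision), ("sensitivity", sensitivity)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if precision + sensitivity == 0:
        return 0.0
    return 2.0 * precision * sensitivity / (precision + sensitivity)


def _dedup_candidates(candidates: pd.DataFrame) -> pd.DataFrame:
    return candidates.drop_duplicates(
        subset=["sample_id", "spectrum_id", "variant_peptide"]
    )


def compute_metrics(
    candidates: pd.DataFrame,
    gold_for_sensitivity: GoldStandardSet,
    gold_for_precision: GoldStandardSet,
    sample_id: str,
    gold_mode: str = "single",
) -> MetricsResult:
    """Score one sample's candidates.

    In single mode pass the same gold set twice; in mixed mode pass the
    intersection set for sensitivity and the union set for precision.
    """
    cand = _dedup_candidates(
        candidates[candidates["sample_id"].astype(str) == str(sample_id)]
    )
    n_candidates = len(cand)
    n_gold = len(gold_for_sensitivity.get(sample_id))
    tp_sens = {
        k for k in match_candidates_to_gold(cand, gold_for_sensitivity)
        if k[0] == str(sample_id)
    }
    tp_prec = {
        k for k in match_candidates_to_gold(cand, gold_for_precision)
        if k[0] == str(sample_id)
    }
    sensitivity = len(tp_sens) / n_gold if n_gold else None
    precision = len(tp_prec) / n_candidates if n_candidates else None
    f1 = (
        f1_score(precision, sensitivity)
        if precision is not None and sensitivity is not None
        else None
    )
    return MetricsResult(
        sample_id=str(sample_id),
        n_gold=n_gold,
        n_candidates=n_candidates,
        n_true_positive=len(tp_prec),
        n_true_positive_sensitivity=len(tp_sens),
        precision=precision,
        sensitivity=sensitivity,
        f1=f1,
        gold_mode=gold_mode,
    )


def evaluate_per_sample(
    candidates: pd.DataFrame,
    gold_for_sensitivity: GoldStandardSet,
    gold_for_precision: GoldStandardSet,
    gold_mode: str = "single",
) -> pd.DataFrame:
    """Per-sample metrics table over the union of sample universes."""
    samples = sorted(
        set(gold_for_sensitivity.keys)
        | set(gold_for_precision.keys)
        | set(candidates["sample_id"].astype(str).unique())
    )
    rows = [
        compute_metrics(
            candidates, gold_for_sensitivity, gold_for_precision, s, gold_mode
        ).to_dict()
        for s in samples
    ]
    return pd.DataFrame(rows)


def summarize_metrics(per_sample: pd.DataFrame, aggregate=np.median) -> dict:
    """Aggregate per-sample metrics (default median), skipping missing values.

    Fractions are reported on the 0-100 percent scale; F1 stays on 0-1.
    """
    out: dict[str, float | None] = {}
    for col, scale in (("precision", 100.0), ("sensitivity", 100.0), ("f1", 1.0)):
        vals = per_sample[col].dropna().astype(float)
        out[col] = float(aggregate(vals) * scale) if len(vals) else None
        out[f"{col}_min"] = float(vals.min() * scale) if len(vals) else None
        out[f"{col}_max"] = float(vals.max() * scale) if len(vals) else None
    out["n_gold_median"] = float(per_sample["n_gold"].median())
    out["n_candidates_median"] = float(per_sample["n_candidates"].median())
    return out


def _saav_label(from_aa: str, to_aa: str) -> str:
    if to_aa in "IL":
        to_aa = IL_CLASS
    return f"{from_aa}>{to_aa}"


def gold_truth_saavs(
    gold: GoldStandardSet, pairs: Iterable[CognatePair]
) -> pd.DataFrame:
    """Annotate gold keys with their true SAAV via the cognate catalog.

    A mouse peptide appearing in several pairs takes the first catalog entry
    (substitution type is almost always unique per mouse peptide).
    """
    saav_of: dict[str, tuple[str, str, int]] = {}
    for p in pairs:
        saav_of.setdefault(p.mouse_peptide, (p.saav.from_aa, p.saav.to_aa, p.site))
    rows = []
    for sample, keys in gold.keys.items():
        for spec, pep in keys:
            if pep in saav_of:
                f, t, site = saav_of[pep]
                rows.append(
                    {
                        "sample_id": sample,
                        "spectrum_id": spec,
                        "peptide": pep,
                        "from_aa": f,
                        "to_aa": t,
                        "site": site,
                        "saav": _saav_label(f, t),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "spectrum_id", "peptide", "from_aa", "to_aa", "site", "saav"],
    )


def stratify_by_saav(
    candidates: pd.DataFrame,
    gold: GoldStandardSet,
    pairs: Iterable[CognatePair],
) -> pd.DataFrame:
    """Per-SAAV precision and sensitivity (destinations I/L collapsed to X).

    Sensitivity of SAAV s is scored over gold PSMs whose true SAAV is s;
    precision of s over candidates calling s. SAAV types with neither
    candidates nor gold are omitted.
    """
    pairs = list(pairs)
    truth = gold_truth_saavs(gold, pairs)
    cand = _dedup_candidates(candidates).copy()
    cand["saav"] = [
        _saav_label(f, t) for f, t in zip(cand["from_aa"], cand["to_aa"])
    ]
    tp_keys = match_candidates_to_gold(cand, gold)
    cand["is_tp"] = [
        (str(r.sample_id), str(r.spectrum_id), r.variant_peptide) in tp_keys
        for r in cand.itertuples(index=False)
    ]
    # a gold PSM is recovered when some candidate on its spectrum matched it
    tp_spectra = {(k[0], k[1]) for k in tp_keys}
    truth["recovered"] = [
        (str(r.sample_id), str(r.spectrum_id)) in tp_spectra
        for r in truth.itertuples(index=False)
    ]
    rows = []
    for s in sorted(set(cand["saav"]) | set(truth["saav"])):
        c = cand[cand["saav"] == s]
        g = truth[truth["saav"] == s]
        if len(c) == 0 and len(g) == 0:
            continue
        rows.append(
            {
                "saav": s,
                "n_candidates": len(c),
                "n_gold": len(g),
                "n_true_positive": int(c["is_tp"].sum()),
                "n_recovered": int(g["recovered"].sum()),
                "precision": float(c["is_tp"].mean()) if len(c) else None,
                "sensitivity": float(g["recovered"].mean()) if len(g) else None,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "saav",
            "n_candidates",
            "n_gold",
            "n_true_positive",
            "n_recovered",
            "precision",
            "sensitivity",
        ],
    )


def combine_tool_candidates(
    candidate_sets: Mapping[str, pd.DataFrame], mode: str
) -> pd.DataFrame:
    """Union or intersection of per-tool candidate sets.

    Rows are keyed by (sample, spectrum, variant peptide under I/L
    equivalence); duplicates collapse to one row with a ``tools``
    provenance column.
    """
    if mode not in ("union", "intersection"):
        raise ValueError(f"mode must be 'union' or 'intersection', got {mode!r}")
    if len(candidate_sets) < 2:
        raise ValueError("need candidates from at least two tools")
    keyed: dict[tuple[str, str, str], dict] = {}
    membership: dict[tuple[str, str, str], set[str]] = {}
    for tool, df in candidate_sets.items():
        for row in _dedup_candidates(df).itertuples(index=False):
            key = (
                str(row.sample_id),
                str(row.spectrum_id),
                canonical_variant(row.variant_peptide, int(row.site)),
            )
            membership.setdefault(key, set()).add(tool)
            keyed.setdefault(key, row._asdict())
    if mode == "union":
        wanted = list(membership)
    else:
        all_tools = set(candidate_sets)
        wanted = [k for k, tools in membership.items() if tools == all_tools]
    rows = []
    for key in wanted:
        d = dict(keyed[key])
        d["tools"] = ";".join(sorted(membership[key]))
        rows.append(d)
    out = pd.DataFrame(rows)
    if out.empty:
        out = pd.DataFrame(
            columns=list(next(iter(candidate_sets.values())).columns) + ["tools"]
        )
    return out


def misassignment_census(
    false_candidates: pd.DataFrame, gold_truth: pd.DataFrame
) -> pd.DataFrame:
    """Cross-tabulate called vs true SAAV for false candidates.

    ``gold_truth`` comes from :func:`gold_truth_saavs`. Each cell carries the
    theoretical mass-shift difference between the called and the true
    substitution: a difference of ~0 with a different site diagnoses
    mislocalization (the call absorbed an isobaric true SAAV elsewhere in
    the peptide).
    """
    if false_candidates.empty:
        return pd.DataFrame(
            columns=["called_saav", "true_saav", "count", "delta_mass_shift"]
        )
    truth = gold_truth.rename(
        columns={"from_aa": "true_from", "to_aa": "true_to", "site": "true_site"}
    )[["sample_id", "spectrum_id", "true_from", "true_to", "true_site"]]
    merged = false_candidates.merge(
        truth, on=["sample_id", "spectrum_id"], how="inner"
    )
    if merged.empty:
        return pd.DataFrame(
            columns=["called_saav", "true_saav", "count", "delta_mass_shift"]
        )
    rows = []
    grouped = merged.groupby(
        ["from_aa", "to_aa", "true_from", "true_to"], sort=True
    )
    for (cf, ct, tf, tt), grp in grouped:
        delta = abs(
            compute_saav_mass_shift(cf, ct) - compute_saav_mass_shift(tf, tt)
        )
        rows.append(
            {
                "called_saav": _saav_label(cf, ct),
                "true_saav": _saav_label(tf, tt),
                "count": len(grp),
                "delta_mass_shift": round(delta, 5),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("count", ascending=False)
        .reset_index(drop=True)
    )


def rank_sum_compare(
    values_a: Iterable[float],
    values_b: Iterable[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Rank-sum comparison of two per-sample metric vectors (two-sided by
    default); returns (statistic, p-value)."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


__all__ = [
    "MetricsResult",
    "peptides_match",
    "canonical_variant",
    "match_candidates_to_gold",
    "f1_score",
    "compute_metrics",
    "evaluate_per_sample",
    "summarize_metrics",
    "gold_truth_saavs",
    "stratify_by_saav",
    "combine_tool_candidates",
    "misassignment_census",
    "rank_sum_compare",
]
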