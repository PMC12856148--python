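"""Synthetic benchmark data: ortholog proteomes with injected SAAVs, two
imperfect closed-search "tools", and open-search candidates with controlled
error modes, all with latent truth labels.

The generator emulates the statistical structure of a mixed-species
patient-derived-xenograft proteomics experiment: a configurable fraction of
closed-search PSMs map to mouse peptides, gold-eligible PSMs are shared
between two closed-search tools with a configurable overlap, and the
open-search side detects gold PSMs at a configurable rate, corrupted by
mislocalization, wrong mass shifts, and spurious background candidates on
human PSMs. Every random draw flows through one seeded generator, so a
given (config, seed) reproduces its outputs exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .catalog import (
    CognatePair,
    compute_saav_mass_shift,
    find_cognate_saav_pairs,
    pairs_to_frame,
)
from .digestion import PeptideIndex, ProteinRecord, digest_proteome
from .masses import (
    BIOCHEM_CATEGORIES,
    IL_CLASS,
    KYTE_DOOLITTLE,
    STANDARD_AA,
    same_category,
)
from .quality import Spectrum, predict_fragment_mz, rt_delta, spectral_angle

logger = logging.getLogger(__name__)

#: Residue sampling frequencies: uniform over the 18 non-K/R residues with
#: K and R enriched to 10% each, so tryptic peptides of in-range length are
#: common even for small proteomes.
_RESIDUE_FREQS = {aa: (0.10 if aa in "KR" else 0.80 / 18.0) for aa in STANDARD_AA}

_CATEGORY_MEMBERS: dict[str, list[str]] = {}
for _aa, _cat in BIOCHEM_CATEGORIES.items():
    _CATEGORY_MEMBERS.setdefault(_cat, []).append(_aa)


@dataclass
class SimConfig:
    """Parameters of one simulated benchmark experiment.

    Defaults follow the study conditions the generator emulates: ~30% of
    closed-search PSMs mouse-derived, ~67% of gold PSMs shared between the
    two closed-search tools, a same-category substitution bias of 57.5%,
    and an open-search detection rate of 0.5. ``saav_rate`` of 0.05 per
    residue approximates human-mouse proteome divergence.
    """

    n_genes: int = 200
    protein_length_mean: float = 350.0
    protein_length_sd: float = 100.0
    saav_rate: float = 0.05
    same_category_bias: float = 0.575
    mouse_psm_fraction: float = 0.30
    n_psms_per_sample: int = 5000
    n_samples: int = 4
    tool_overlap: float = 0.67
    detection_rate: float = 0.5
    misloc_rate: float = 0.2
    wrong_shift_rate: float = 0.05
    background_rate: float = 0.05
    rt_noise_sd: float = 0.5  # minutes
    rt_slope: float = 0.3  # minutes per hydropathy unit
    rt_intercept: float = 30.0  # minutes
    intensity_jitter: float = 0.2  # lognormal sigma on fragment intensities
    closed_tools: tuple[str, str] = ("toolA", "toolB")
    open_tools: tuple[str, ...] = ("open_a", "open_b")
    seed: int = 0

    def __post_init__(self) -> None:
        rates = {
            "saav_rate": self.saav_rate,
            "same_category_bias": self.same_category_bias,
            "mouse_psm_fraction": self.mouse_psm_fraction,
            "tool_overlap": self.tool_overlap,
            "detection_rate": self.detection_rate,
            "misloc_rate": self.misloc_rate,
            "wrong_shift_rate": self.wrong_shift_rate,
            "background_rate": self.background_rate,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for name in ("n_genes", "n_psms_per_sample", "n_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.protein_length_mean < 6:
            raise ValueError("protein_length_mean must be at least 6 residues")
        if len(self.closed_tools) != 2:
            raise ValueError("exactly two closed-search tools are simulated")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _substitute_residue(
    origin: str, bias: float, rng: np.random.Generator
) -> tuple[str, bool]:
    """Draw a destination residue: within the origin's biochemical category
    with probability ``bias``, otherwise uniformly among residues of the
    other categories; returns (destination, same_category flag)."""
    if rng.random() < bias:
        pool = [aa for aa in _CATEGORY_MEMBERS[BIOCHEM_CATEGORIES[origin]] if aa != origin]
        return str(rng.choice(pool)), True
    pool = [aa for aa in STANDARD_AA if BIOCHEM_CATEGORIES[aa] != BIOCHEM_CATEGORIES[origin]]
    return str(rng.choice(pool)), False


def generate_ortholog_proteomes(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[ProteinRecord], list[ProteinRecord], pd.DataFrame, dict[str, str]]:
    """Sample a human proteome and a mouse ortholog proteome.

    Mouse orthologs are copies of their human counterparts with per-residue
    substitutions at ``saav_rate``; every injected substitution is recorded
    in the returned ledger. Also returns the human→mouse gene-symbol map.
    """
    if config.protein_length_mean < 6:
        raise ValueError("degenerate config: proteins shorter than a peptide")
    rng = config.rng() if rng is None else rng
    residues = np.array(list(STANDARD_AA))
    freqs = np.array([_RESIDUE_FREQS[aa] for aa in STANDARD_AA])
    freqs = freqs / freqs.sum()

    human: list[ProteinRecord] = []
    mouse: list[ProteinRecord] = []
    ledger_rows: list[dict] = []
    ortholog_map: dict[str, str] = {}
    for g in range(1, config.n_genes + 1):
        hsym, msym = f"GENE{g}", f"Gene{g}"
        ortholog_map[hsym] = msym
        length = max(30, int(round(rng.normal(config.protein_length_mean, config.protein_length_sd))))
        hseq = "".join(rng.choice(residues, size=length, p=freqs))
        mseq = list(hseq)
        hits = np.flatnonzero(rng.random(length) < config.saav_rate)
        for pos0 in hits:
            origin = hseq[pos0]
            dest, same_cat = _substitute_residue(origin, config.same_category_bias, rng)
            mseq[pos0] = dest
            ledger_rows.append(
                {
                    "gene_symbol": hsym,
                    "position": int(pos0) + 1,
                    "from_aa": origin,
                    "to_aa": dest,
                    "same_category": same_cat,
                }
            )
        human.append(ProteinRecord(f"H{g:05d}", hsym, "human", hseq))
        mouse.append(ProteinRecord(f"M{g:05d}", msym, "mouse", "".join(mseq)))
    ledger = pd.DataFrame(
        ledger_rows,
        columns=["gene_symbol", "position", "from_aa", "to_aa", "same_category"],
    )
    return human, mouse, ledger, ortholog_map


def simulate_closed_search_psms(
    index: PeptideIndex,
    pairs: Iterable[CognatePair],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate two imperfect closed-search tools over the same spectra.

    Per sample, each spectrum is assigned a mouse peptide with probability
    ``mouse_psm_fraction``, else a human peptide. A gold-eligible PSM (mouse
    peptide present in the cognate catalog) appears in both tools with
    probability ``tool_overlap``, else in exactly one chosen uniformly;
    non-gold PSMs appear in both. Returns the combined per-tool PSM table
    and a truth table (one row per spectrum) with gold annotations.
    """
    pair_of: dict[str, CognatePair] = {}
    for p in pairs:
        pair_of.setdefault(p.mouse_peptide, p)
    if not pair_of:
        raise ValueError("cognate catalog is empty")
    rng = config.rng() if rng is None else rng

    human_pool = [pep for _, pep in index.all_peptides("human")]
    mouse_pool = [pep for _, pep in index.all_peptides("mouse")]
    if not human_pool or not mouse_pool:
        raise ValueError("peptide index lacks one of the species")

    tool_a, tool_b = config.closed_tools
    closed_rows: list[dict] = []
    truth_rows: list[dict] = []
    for s in range(1, config.n_samples + 1):
        sample_id = f"S{s}"
        n = config.n_psms_per_sample
        is_mouse = rng.random(n) < config.mouse_psm_fraction
        mouse_idx = rng.integers(0, len(mouse_pool), size=n)
        human_idx = rng.integers(0, len(human_pool), size=n)
        overlap_draw = rng.random(n)
        which_tool = rng.integers(0, 2, size=n)
        scores = rng.normal(50.0, 10.0, size=n)
        for i in range(n):
            spectrum_id = f"scan{i + 1:06d}"
            pep = mouse_pool[mouse_idx[i]] if is_mouse[i] else human_pool[human_idx[i]]
            pair = pair_of.get(pep) if is_mouse[i] else None
            is_gold = pair is not None
            if is_gold and overlap_draw[i] >= config.tool_overlap:
                tools = [tool_a if which_tool[i] == 0 else tool_b]
            else:
                tools = [tool_a, tool_b]
            for tool in tools:
                closed_rows.append(
                    {
                        "sample_id": sample_id,
                        "spectrum_id": spectrum_id,
                        "tool": tool,
                        "peptide": pep,
                        "score": round(float(scores[i]), 3),
                    }
                )
            truth_rows.append(
                {
                    "sample_id": sample_id,
                    "spectrum_id": spectrum_id,
                    "peptide": pep,
                    "species": "mouse" if is_mouse[i] else "human",
                    "is_gold": is_gold,
                    "human_cognate": pair.human_peptide if is_gold else None,
                    "site": pair.site if is_gold else None,
                    "from_aa": pair.saav.from_aa if is_gold else None,
                    "to_aa": pair.saav.to_aa if is_gold else None,
                    "tools": ";".join(tools),
                }
            )
    closed = pd.DataFrame(closed_rows)
    truth = pd.DataFrame(truth_rows)
    return closed, truth


def simulate_open_search_psms(
    truth: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    tool: str = "open_sim",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one open-search tool's candidate PSMs from the truth table.

    Each gold PSM is detected with probability ``detection_rate`` and
    emitted with the human cognate as base peptide, the true SAAV mass
    shift, and the true site — then corrupted: with ``misloc_rate`` the
    reported site moves to another position, with ``wrong_shift_rate`` the
    mass shift is offset by ±0.2-2.0 Da. Each human PSM spawns a spurious
    candidate with probability ``background_rate`` (random site, exact mass
    shift of a random substitution whose origin matches that site). Labels
    record the error mode of every emitted row; a row is ``correct`` only
    when it is an uncorrupted gold detection.
    """
    rng = config.rng() if rng is None else rng
    open_rows: list[dict] = []
    label_rows: list[dict] = []

    non_self = {
        aa: [b for b in STANDARD_AA if b != aa] for aa in STANDARD_AA
    }
    for row in truth.itertuples(index=False):
        if row.is_gold:
            if rng.random() >= config.detection_rate:
                continue
            base = row.human_cognate
            site = int(row.site)
            dm = compute_saav_mass_shift(row.from_aa, row.to_aa)
            kind = "gold_clean"
            if rng.random() < config.misloc_rate:
                others = [p for p in range(1, len(base) + 1) if p != site]
                site = int(rng.choice(others))
                kind = "mislocalized"
            if rng.random() < config.wrong_shift_rate:
                dm += float(rng.choice([-1.0, 1.0]) * rng.uniform(0.2, 2.0))
                kind = "wrong_shift" if kind == "gold_clean" else "mislocalized+wrong_shift"
            correct = kind == "gold_clean"
        elif row.species == "human":
            if rng.random() >= config.background_rate:
                continue
            base = row.peptide
            site = int(rng.integers(1, len(base) + 1))
            origin = base[site - 1]
            dest = str(rng.choice(non_self[origin]))
            dm = compute_saav_mass_shift(origin, dest)
            kind = "background"
            correct = False
        else:  # mouse PSM outside the catalog: open search cannot explain it
            continue
        open_rows.append(
            {
                "sample_id": row.sample_id,
                "spectrum_id": row.spectrum_id,
                "tool": tool,
                "peptide": base,
                "delta_mass": round(float(dm), 5),
                "site": site,
                "site_probability": round(float(rng.uniform(0.6, 1.0)), 3),
                "retention_time": np.nan,
                "score": round(float(rng.normal(30.0, 5.0)), 3),
            }
        )
        label_rows.append(
            {
                "sample_id": row.sample_id,
                "spectrum_id": row.spectrum_id,
                "tool": tool,
                "kind": kind,
                "correct": correct,
            }
        )
    columns = [
        "sample_id", "spectrum_id", "tool", "peptide", "delta_mass",
        "site", "site_probability", "retention_time", "score",
    ]
    open_df = pd.DataFrame(open_rows, columns=columns)
    labels = pd.DataFrame(
        label_rows, columns=["sample_id", "spectrum_id", "tool", "kind", "correct"]
    )
    return open_df, labels


def _hydropathy_sum(peptide: str) -> float:
    return sum(KYTE_DOOLITTLE["L" if aa == IL_CLASS else aa] for aa in peptide)


def predicted_rt(peptide: str, config: SimConfig) -> float:
    """The simulator's linear hydropathy retention-time device (minutes)."""
    return config.rt_slope * _hydropathy_sum(peptide) + config.rt_intercept


def _jittered(spec: Spectrum, sigma: float, rng: np.random.Generator) -> Spectrum:
    if sigma <= 0:
        return spec
    jitter = np.exp(rng.normal(0.0, sigma, size=len(spec)))
    return Spectrum(mz=spec.mz, intensity=spec.intensity * jitter)


def simulate_rt_and_spectra(
    candidates: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    return_spectra: bool = False,
):
    """Attach retention times and paired experimental/predicted spectra.

    The observed retention time and experimental spectrum follow the *true*
    peptide behind each spectrum (mouse peptide for gold spectra, human base
    for background rows); the predictions use the candidate's called variant
    peptide. Incorrect calls therefore separate from correct ones on both
    RT deviation and spectral angle. Requires a ``variant_peptide`` column
    (run SAAV assignment first). Adds ``retention_time``, ``rt_predicted``,
    ``rt_delta`` and ``spectral_angle`` columns.
    """
    rng = config.rng() if rng is None else rng
    # truth.peptide is the mouse peptide for gold spectra, the human base otherwise
    true_pep = {
        (r.sample_id, r.spectrum_id): r.peptide for r in truth.itertuples(index=False)
    }
    out = candidates.reset_index(drop=True).copy()
    rt_obs_col, rt_pred_col, rt_delta_col, sa_col = [], [], [], []
    spectra: dict[tuple[str, str], tuple[Spectrum, Spectrum]] = {}
    for row in out.itertuples(index=False):
        key = (row.sample_id, row.spectrum_id)
        true = true_pep.get(key)
        variant = row.variant_peptide
        if true is None or variant is None or (isinstance(variant, float) and np.isnan(variant)):
            rt_obs_col.append(np.nan)
            rt_pred_col.append(np.nan)
            rt_delta_col.append(np.nan)
            sa_col.append(np.nan)
            continue
        pred_rt = predicted_rt(variant, config)
        obs_rt = predicted_rt(true, config) + float(rng.normal(0.0, config.rt_noise_sd))
        exp_spec = _jittered(predict_fragment_mz(true), config.intensity_jitter, rng)
        pred_spec = predict_fragment_mz(variant.replace(IL_CLASS, "L"))
        rt_obs_col.append(obs_rt)
        rt_pred_col.append(pred_rt)
        rt_delta_col.append(rt_delta(obs_rt, pred_rt))
        sa_col.append(spectral_angle(exp_spec, pred_spec))
        if return_spectra:
            spectra[key] = (exp_spec, pred_spec)
    out["retention_time"] = rt_obs_col
    out["rt_predicted"] = rt_pred_col
    out["rt_delta"] = rt_delta_col
    out["spectral_angle"] = sa_col
    if return_spectra:
        return out, spectra
    return out


@dataclass
class SimulationResult:
    """Everything one simulated experiment produced."""

    config: SimConfig
    human: list[ProteinRecord]
    mouse: list[ProteinRecord]
    injected: pd.DataFrame
    ortholog_map: dict[str, str]
    index: PeptideIndex
    pairs: list[CognatePair]
    closed_psms: pd.DataFrame
    truth: pd.DataFrame
    open_psms: dict[str, pd.DataFrame] = field(default_factory=dict)
    labels: dict[str, pd.DataFrame] = field(default_factory=dict)


def simulate_benchmark(config: SimConfig) -> SimulationResult:
    """Run the full generator: proteomes → digestion → catalog → closed and
    open PSM tables for every configured tool, deterministically from
    ``config.seed``."""
    rng = config.rng()
    human, mouse, injected, ortholog_map = generate_ortholog_proteomes(config, rng)
    index = digest_proteome(human + mouse)
    pairs = find_cognate_saav_pairs(index, ortholog_map)
    closed, truth = simulate_closed_search_psms(index, pairs, config, rng)
    result = SimulationResult(
        config=config,
        human=human,
        mouse=mouse,
        injected=injected,
        ortholog_map=ortholog_map,
        index=index,
        pairs=pairs,
        closed_psms=closed,
        truth=truth,
    )
    for tool in config.open_tools:
        open_df, labels = simulate_open_search_psms(truth, config, rng, tool=tool)
        result.open_psms[tool] = open_df
        result.labels[tool] = labels
    return result


def _write_fasta(records: list[ProteinRecord], path: Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.accession} GN={rec.gene_symbol}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def simulate_to_dir(config: SimConfig, outdir: str | Path) -> SimulationResult:
    """Write a complete fixture set for the pipeline: FASTA pair, ortholog
    map, per-tool closed-search tables, open-search candidate tables, truth
    labels, and the resolved config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = simulate_benchmark(config)
    _write_fasta(result.human, outdir / "human.fasta")
    _write_fasta(result.mouse, outdir / "mouse.fasta")
    with open(outdir / "orthologs.tsv", "w") as fh:
        for h, m in result.ortholog_map.items():
            fh.write(f"{h}\t{m}\n")
    pairs_to_frame(result.pairs).to_csv(outdir / "catalog.tsv", sep="\t", index=False)
    for tool in config.closed_tools:
        df = result.closed_psms[result.closed_psms["tool"] == tool]
        df.to_csv(outdir / f"closed_{tool}.tsv", sep="\t", index=False)
    for tool, df in result.open_psms.items():
        df.to_csv(outdir / f"open_{tool}.tsv", sep="\t", index=False)
        result.labels[tool].to_csv(outdir / f"labels_{tool}.tsv", sep="\t", index=False)
    result.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    result.injected.to_csv(outdir / "injected_saavs.tsv", sep="\t", index=False)
    with open(outdir / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    return result


__all__ = [
    "SimConfig",
    "SimulationResult",
    "generate_ortholog_proteomes",
    "simulate_closed_search_psms",
    "simulate_open_search_psms",
    "simulate_rt_and_spectra",
    "simulate_benchmark",
    "simulate_to_dir",
    "predicted_rt",
]
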