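"""End-to-end benchmark orchestration.

``run_benchmark`` executes digestion → catalog → gold standards (per tool
plus mixed) → open-search parsing and SAAV assignment → evaluation (overall,
per-SAAV, tool combination) → quality metrics, and writes all stage tables
plus a machine-readable JSON summary. Inputs come either from a simulation
block (the synthetic generator) or from file paths to FASTA proteomes,
an ortholog map, and normalized PSM tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalog import (
    find_cognate_saav_pairs,
    load_ortholog_map,
    pairs_to_frame,
    saav_census,
    same_category_fraction,
)
from .digestion import digest_proteome, read_fasta
from .evaluation import (
    combine_tool_candidates,
    evaluate_per_sample,
    match_candidates_to_gold,
    stratify_by_saav,
    summarize_metrics,
)
from .gold import GoldStandardSet, build_gold_standard, mix_gold_standards
from .openparse import (
    DEFAULT_TOLERANCE,
    accepted_candidates,
    assign_saav_table,
    filter_localized_psms,
    normalize_psm_table,
)
from .quality import quality_separation
from .simulate import SimConfig, simulate_benchmark, simulate_rt_and_spectra

logger = logging.getLogger(__name__)


def config_hash(config: dict) -> str:
    """Short stable hash of a resolved configuration."""
    canon = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha1(canon.encode()).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    """Write a stage table with a provenance header comment."""
    with open(path, "w") as fh:
        fh.write(f"# saavbench {__version__} config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


class PipelineError(RuntimeError):
    """A stage failure, labeled with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _load_inputs(config: dict) -> dict:
    """File-driven mode: read proteomes, ortholog map and PSM tables."""
    inputs = config["inputs"]
    human = read_fasta(inputs["human_fasta"], "human", inputs.get("symbol_parser", "gn"))
    mouse = read_fasta(inputs["mouse_fasta"], "mouse", inputs.get("symbol_parser", "gn"))
    ortholog_map = load_ortholog_map(inputs["ortholog_map"])
    closed = {}
    for tool, path in inputs["closed_psms"].items():
        closed[tool] = normalize_psm_table(path, dialect="generic", tool=tool)
    open_specs = {}
    for tool, spec in inputs["open_psms"].items():
        if isinstance(spec, str):
            spec = {"path": spec}
        open_specs[tool] = spec
    return {
        "human": human,
        "mouse": mouse,
        "ortholog_map": ortholog_map,
        "closed": closed,
        "open_specs": open_specs,
    }


def run_benchmark(config: dict, outdir: str | Path) -> dict:
    """Run the whole benchmark; returns (and writes) the JSON summary."""
    if "simulate" not in config and "inputs" not in config:
        raise PipelineError("config", "need either a 'simulate' or an 'inputs' block")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tolerance = float(config.get("tolerance", DEFAULT_TOLERANCE))
    digestion_params = config.get("digestion", {})
    cfg_hash = config_hash(config)

    sim = None
    if "simulate" in config:
        sim_block = dict(config["simulate"])
        if "seed" in config:
            sim_block.setdefault("seed", int(config["seed"]))
        try:
            sim = simulate_benchmark(SimConfig(**sim_block))
        except (TypeError, ValueError) as exc:
            raise PipelineError("simulate", str(exc)) from exc
        pairs = sim.pairs
        closed = {
            tool: sim.closed_psms[sim.closed_psms["tool"] == tool]
            for tool in sim.config.closed_tools
        }
        open_tables = {
            tool: {"frame": df, "dialect": "generic", "policy": "generic"}
            for tool, df in sim.open_psms.items()
        }
    else:
        try:
            loaded = _load_inputs(config)
        except (OSError, KeyError, ValueError) as exc:
            raise PipelineError("inputs", str(exc)) from exc
        try:
            index = digest_proteome(loaded["human"] + loaded["mouse"], **digestion_params)
            pairs = find_cognate_saav_pairs(index, loaded["ortholog_map"])
        except ValueError as exc:
            raise PipelineError("digest", str(exc)) from exc
        closed = loaded["closed"]
        open_tables = {
            tool: {
                "frame": None,
                "path": spec["path"],
                "dialect": spec.get("dialect", "generic"),
                "policy": spec.get("policy", "generic"),
            }
            for tool, spec in loaded["open_specs"].items()
        }

    if not pairs:
        raise PipelineError("catalog", "cognate-pair catalog is empty")
    census = saav_census(pairs)
    write_tsv(pairs_to_frame(pairs), outdir / "catalog.tsv", cfg_hash)
    write_tsv(census, outdir / "saav_census.tsv", cfg_hash)

    # --- gold standards: one per closed-search tool, plus mixed ---
    gold: dict[str, GoldStandardSet] = {}
    for tool, df in closed.items():
        gold[tool] = build_gold_standard(df, pairs, provenance=tool)
    tool_names = list(gold)
    if len(tool_names) >= 2:
        a, b = tool_names[0], tool_names[1]
        gold["intersection"] = mix_gold_standards(gold[a], gold[b], "intersection")
        gold["union"] = mix_gold_standards(gold[a], gold[b], "union")
    for name, gs in gold.items():
        write_tsv(gs.to_frame(), outdir / f"gold_{name}.tsv", cfg_hash)

    # --- open-search parsing and SAAV assignment ---
    candidates: dict[str, pd.DataFrame] = {}
    for tool, spec in open_tables.items():
        try:
            frame = spec["frame"]
            if frame is None:
                psms = normalize_psm_table(spec["path"], dialect=spec["dialect"], tool=tool)
            else:
                psms = normalize_psm_table(frame, dialect=spec["dialect"], tool=tool)
            psms = filter_localized_psms(psms, spec.get("policy", "generic"))
            assigned = assign_saav_table(psms, tolerance=tolerance)
        except ValueError as exc:
            raise PipelineError(f"parse-open:{tool}", str(exc)) from exc
        write_tsv(assigned, outdir / f"candidates_{tool}.tsv", cfg_hash)
        candidates[tool] = accepted_candidates(assigned)

    # --- evaluation ---
    summary: dict[str, Any] = {
        "saavbench_version": __version__,
        "config_hash": cfg_hash,
        "n_cognate_pairs": len(pairs),
        "same_category_fraction_pct": round(100.0 * same_category_fraction(census), 2),
        "gold_counts": {name: gs.n_total() for name, gs in gold.items()},
        "tools": {},
        "combination": {},
    }
    per_sample_frames = []
    mixed = len(tool_names) >= 2
    for tool, cand in candidates.items():
        tool_summary = {}
        for gname in tool_names:
            per = evaluate_per_sample(cand, gold[gname], gold[gname], gold_mode="single")
            per.insert(0, "open_tool", tool)
            per.insert(1, "gold", gname)
            per_sample_frames.append(per)
            tool_summary[gname] = summarize_metrics(per)
        if mixed:
            per = evaluate_per_sample(
                cand, gold["intersection"], gold["union"], gold_mode="mixed"
            )
            per.insert(0, "open_tool", tool)
            per.insert(1, "gold", "mixed")
            per_sample_frames.append(per)
            tool_summary["mixed"] = summarize_metrics(per)
        summary["tools"][tool] = tool_summary

    if len(candidates) >= 2 and mixed:
        for mode in ("union", "intersection"):
            combined = combine_tool_candidates(candidates, mode)
            per = evaluate_per_sample(
                combined, gold["intersection"], gold["union"], gold_mode="mixed"
            )
            per.insert(0, "open_tool", mode)
            per.insert(1, "gold", "mixed")
            per_sample_frames.append(per)
            summary["combination"][mode] = summarize_metrics(per)

    per_sample = pd.concat(per_sample_frames, ignore_index=True)
    write_tsv(per_sample, outdir / "metrics_per_sample.tsv", cfg_hash)

    first_tool = next(iter(candidates))
    strat_gold = gold["union"] if mixed else gold[tool_names[0]]
    per_saav = stratify_by_saav(candidates[first_tool], strat_gold, pairs)
    write_tsv(per_saav, outdir / "metrics_per_saav.tsv", cfg_hash)
    summary["n_saav_types_evaluated"] = int(len(per_saav))

    # --- quality metrics (simulation supplies RT and spectra) ---
    if sim is not None:
        rng = np.random.default_rng(sim.config.seed + 1)
        cand = simulate_rt_and_spectra(candidates[first_tool], sim.truth, sim.config, rng)
        tp = match_candidates_to_gold(cand, strat_gold)
        cand["is_tp"] = [
            (str(r.sample_id), str(r.spectrum_id), r.variant_peptide) in tp
            for r in cand.itertuples(index=False)
        ]
        write_tsv(cand, outdir / f"quality_{first_tool}.tsv", cfg_hash)
        true_grp = cand[cand["is_tp"]]
        false_grp = cand[~cand["is_tp"]]
        if len(true_grp) and len(false_grp):
            _, p_rt = quality_separation(
                true_grp["rt_delta"], false_grp["rt_delta"], "smaller"
            )
            _, p_sa = quality_separation(
                true_grp["spectral_angle"], false_grp["spectral_angle"], "larger"
            )
            summary["quality"] = {
                "tool": first_tool,
                "n_true": int(len(true_grp)),
                "n_false": int(len(false_grp)),
                "rt_delta_p": p_rt,
                "spectral_angle_p": p_sa,
                "rt_delta_median_true": float(true_grp["rt_delta"].median()),
                "rt_delta_median_false": float(false_grp["rt_delta"].median()),
                "spectral_angle_median_true": float(true_grp["spectral_angle"].median()),
                "spectral_angle_median_false": float(false_grp["spectral_angle"].median()),
            }

    resolved = dict(config)
    with open(outdir / "resolved_config.yaml", "w") as fh:
        fh.write(f"# saavbench {__version__} config={cfg_hash}\n")
        yaml.safe_dump(resolved, fh, sort_keys=True)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


__all__ = ["run_benchmark", "config_hash", "write_tsv", "PipelineError"]
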