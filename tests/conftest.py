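"""Shared fixtures and independent brute-force oracles.

The oracles here re-derive the digestion and SAAV-assignment rules from
first principles (exhaustive enumeration) and are kept deliberately
independent of the package implementation they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings
from scipy import stats

from saavbench.masses import MONO_MASS, STANDARD_AA
from saavbench.simulate import SimConfig, simulate_benchmark

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


# ---------------------------------------------------------------- oracles

def brute_force_digest(
    seq: str, max_missed: int = 2, min_len: int = 6, max_len: int = 61
) -> set[tuple[str, int, int]]:
    """Enumerate every substring and keep those obeying the tryptic rules.

    Returns {(peptide, 1-based start, missed_cleavages)}.
    """
    n = len(seq)
    sites = {
        i + 1
        for i, aa in enumerate(seq)
        if aa in "KR" and i + 1 < n and seq[i + 1] != "P"
    }
    out = set()
    for start in range(n):
        if start != 0 and start not in sites:
            continue
        for end in range(start + 1, n + 1):
            if end != n and end not in sites:
                continue
            internal = sum(1 for s in sites if start < s < end)
            if internal > max_missed:
                continue
            if min_len <= end - start <= max_len:
                out.add((seq[start:end], start + 1, internal))
    return out


def brute_force_assign(
    pep: str, delta_mass: float, site: int, tolerance: float = 0.1
):
    """Exhaustive scorer over all ordered residue pairs (I/L destinations
    merged). Returns ("accept", from, to) or ("reject", reason)."""
    entries: dict[tuple[str, str], float] = {}
    for a in STANDARD_AA:
        for b in STANDARD_AA:
            if a == b:
                continue
            key = (a, "X" if b in "IL" else b)
            entries[key] = MONO_MASS[b] - MONO_MASS[a]
    best = min(abs(delta_mass - s) for s in entries.values())
    if best >= tolerance:
        return ("reject", "no_pair_within_tolerance")
    ties = [k for k, s in entries.items() if abs(delta_mass - s) <= best + 1e-9]
    matching = [k for k in ties if k[0] == pep[site - 1]]
    if not matching:
        return ("reject", "origin_mismatch")
    if len(matching) > 1:
        return ("reject", "ambiguous")
    return ("accept", matching[0][0], matching[0][1])


def binomial_count_interval(n: int, p: float, level: float = 0.95):
    """Central acceptance region [lo, hi] for a Binomial(n, p) count."""
    alpha = 1.0 - level
    lo = int(stats.binom.ppf(alpha / 2, n, p))
    hi = int(stats.binom.ppf(1 - alpha / 2, n, p))
    return lo, hi


# ---------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated experiment shared across read-only tests."""
    cfg = SimConfig(
        n_genes=80,
        protein_length_mean=250.0,
        protein_length_sd=60.0,
        n_psms_per_sample=2500,
        n_samples=2,
        seed=11,
    )
    return simulate_benchmark(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
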