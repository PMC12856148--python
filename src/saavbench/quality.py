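"""Orthogonal PSM quality metrics: retention-time deviation and normalized
spectral angle, plus a minimal theoretical b/y fragment generator.

The normalized spectral angle between an experimental and a predicted
spectrum is SA = 1 - 2*arccos(<s1_hat, s2_hat>)/pi, where the hats denote
unit (L2) normalization of intensity vectors over matched peaks; unmatched
peaks contribute zero intensity to the counterpart. SA is 1 for identical
normalized spectra and 0 for spectra sharing no peaks. Higher SA and smaller
RT deviation both indicate higher PSM quality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .masses import PROTON, WATER, residue_mass

DEFAULT_PEAK_TOLERANCE = 0.02  # Da


@dataclass(frozen=True)
class Spectrum:
    """A stick spectrum: strictly increasing m/z with nonnegative intensity."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if len(mz) == 0:
            raise ValueError("empty spectrum")
        if np.any(np.diff(mz) <= 0):
            raise ValueError("mz must be strictly increasing")
        if np.any(mz <= 0) or np.any(inten < 0):
            raise ValueError("mz must be positive and intensities nonnegative")
        if not np.any(inten > 0):
            raise ValueError("spectrum needs at least one positive intensity")

    def __len__(self) -> int:
        return len(self.mz)


def rt_delta(rt_observed: float, rt_predicted: float) -> float:
    """Absolute observed-minus-predicted retention-time deviation (minutes)."""
    if not (math.isfinite(rt_observed) and math.isfinite(rt_predicted)):
        raise ValueError("retention times must be finite")
    return abs(rt_observed - rt_predicted)


def match_peaks(
    s1: Spectrum, s2: Spectrum, tolerance: float = DEFAULT_PEAK_TOLERANCE
) -> list[tuple[int, int]]:
    """Greedy nearest-m/z peak matching within +-tolerance; each peak is
    matched at most once; closest absolute m/z differences claimed first."""
    cands = [
        (abs(m1 - m2), i, j)
        for i, m1 in enumerate(s1.mz)
        for j, m2 in enumerate(s2.mz)
        if abs(m1 - m2) <= tolerance
    ]
    cands.sort()
    used1: set[int] = set()
    used2: set[int] = set()
    matches: list[tuple[int, int]] = []
    for _, i, j in cands:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        matches.append((i, j))
    return matches


def spectral_angle(
    s1: Spectrum, s2: Spectrum, tolerance: float = DEFAULT_PEAK_TOLERANCE
) -> float:
    """Normalized spectral angle between two spectra in [0, 1]."""
    matches = match_peaks(s1, s2, tolerance)
    m1 = {i for i, _ in matches}
    m2 = {j for _, j in matches}
    v1 = [s1.intensity[i] for i, _ in matches]
    v2 = [s2.intensity[j] for _, j in matches]
    # unmatched peaks contribute zero to the counterpart
    for i in range(len(s1)):
        if i not in m1:
            v1.append(s1.intensity[i])
            v2.append(0.0)
    for j in range(len(s2)):
        if j not in m2:
            v1.append(0.0)
            v2.append(s2.intensity[j])
    a = np.asarray(v1)
    b = np.asarray(v2)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("all-zero intensity vector after peak matching")
    cos = float(np.clip(np.dot(a / na, b / nb), 0.0, 1.0))
    return 1.0 - 2.0 * math.acos(cos) / math.pi


def predict_fragment_mz(
    peptide: str, table: Mapping[str, float] | None = None
) -> Spectrum:
    """Singly charged b- and y-ion stick spectrum with unit intensities.

    b_i = sum(residues 1..i) + proton; y_i = sum(last i residues) + water +
    proton, for i = 1..len-1. ``'X'`` residues use the shared Leu/Ile mass.
    Coinciding b/y m/z values merge into one peak with summed intensity.
    """
    n = len(peptide)
    if n < 2:
        raise ValueError("peptide must have at least 2 residues to fragment")
    masses = [residue_mass(aa, table) for aa in peptide]
    prefix = np.cumsum(masses)
    peaks: dict[float, float] = {}
    for i in range(1, n):
        b = prefix[i - 1] + PROTON
        y = (prefix[-1] - prefix[n - i - 1]) + WATER + PROTON
        for mz in (round(b, 5), round(y, 5)):
            peaks[mz] = peaks.get(mz, 0.0) + 1.0
    mz = np.array(sorted(peaks))
    return Spectrum(mz=mz, intensity=np.array([peaks[m] for m in mz]))


def quality_separation(
    true_values: Iterable[float],
    false_values: Iterable[float],
    direction: str = "smaller",
) -> tuple[float, float]:
    """One-sided rank-sum test that TRUE PSMs score better than FALSE ones.

    ``direction='smaller'`` tests that TRUE values are stochastically smaller
    (RT deviation); ``'larger'`` that they are larger (spectral angle).
    Returns (statistic, p-value); exact enumeration for small tie-free
    samples via scipy.
    """
    t = np.asarray(list(true_values), dtype=float)
    f = np.asarray(list(false_values), dtype=float)
    if len(t) == 0 or len(f) == 0:
        raise ValueError("both groups must be non-empty")
    if direction not in ("smaller", "larger"):
        raise ValueError(f"direction must be 'smaller' or 'larger', got {direction!r}")
    alternative = "less" if direction == "smaller" else "greater"
    res = stats.mannwhitneyu(t, f, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


__all__ = [
    "Spectrum",
    "rt_delta",
    "match_peaks",
    "spectral_angle",
    "predict_fragment_mz",
    "quality_separation",
    "DEFAULT_PEAK_TOLERANCE",
]
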