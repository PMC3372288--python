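"""Spacing histogram, normalisation and the normalised periodicity spectrum.

The pipeline transforms a nucleotide sequence into a periodicity plot:

1. locate all A-tract occurrences (``tracts`` module);
2. count ``N(s)``, the number of occurrence pairs at start-to-start
   distance ``s``;
3. divide by the expected pair count ``E(s)`` for uniformly placed starts,
   smooth with a 3-bp centred moving average (removes the codon-driven 3-bp
   signal) and subtract a least-squares parabola in ``s`` (removes slow
   trends from compositional heterogeneity);
4. evaluate the Fourier amplitude of the residual on a dense period grid
   and scale it to average 1 over periods 5–20 bp.

The scaled spectrum ``Q*(P)`` measures periodic-signal intensity as a
function of the period ``P``; its dominant peak gives the summary indices
``MaxQ`` (height) and ``PMaxQ`` (period).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TextIO

import numpy as np

from .tracts import TractMethod, TractOccurrenceSet, build_method, find_tracts

__all__ = [
    "DEFAULT_S_MIN",
    "DEFAULT_S_MAX",
    "NORM_RANGE",
    "DegenerateInput",
    "SpacingHistogram",
    "ProcessedSpacing",
    "SpacingSpectrum",
    "count_pair_spacings",
    "normalize_and_detrend",
    "power_spectrum",
    "perplot",
    "write_spectrum_tsv",
]

DEFAULT_S_MIN = 30
DEFAULT_S_MAX = 100

#: Period range (bp) over which the spectrum is scaled to unit mean and over
#: which MaxQ/PMaxQ are searched.
NORM_RANGE = (5.0, 20.0)

DEFAULT_P_LO = 2.0
DEFAULT_P_HI = 20.0
DEFAULT_DP = 0.05


class DegenerateInput(ValueError):
    """Raised when a spectrum cannot be formed (e.g. fewer than two tracts)."""


@dataclass
class SpacingHistogram:
    """Pair-spacing counts ``N(s)`` for ``s`` = 1..``s_hist_max``.

    ``counts[i]`` holds ``N(i + 1)``.  ``m`` is the number of tract
    occurrences and ``L`` the sequence length in bp.
    """

    counts: np.ndarray
    m: int
    L: int
    method: TractMethod

    @property
    def s_hist_max(self) -> int:
        return int(self.counts.size)

    def n_of(self, s: int) -> int:
        """``N(s)`` for 1 <= s <= s_hist_max."""
        if not 1 <= s <= self.s_hist_max:
            raise IndexError(f"spacing {s} outside 1..{self.s_hist_max}")
        return int(self.counts[s - 1])


@dataclass
class ProcessedSpacing:
    """Normalised, smoothed and detrended spacing function on [s_min, s_max]."""

    y: np.ndarray
    s_min: int
    s_max: int

    @property
    def s(self) -> np.ndarray:
        return np.arange(self.s_min, self.s_max + 1)


@dataclass
class SpacingSpectrum:
    """Normalised periodicity spectrum ``Q*(P)`` with its summary indices.

    A degenerate result (too few tracts, zero-variance spacing function)
    carries ``degenerate=True`` and empty arrays instead of NaNs.
    """

    periods: np.ndarray = field(repr=False)
    q: np.ndarray = field(repr=False)
    max_q: float | None
    p_max_q: float | None
    method: TractMethod | None = None
    s_min: int = DEFAULT_S_MIN
    s_max: int = DEFAULT_S_MAX
    degenerate: bool = False
    note: str = ""

    @classmethod
    def flagged(cls, method, s_min, s_max, note: str) -> "SpacingSpectrum":
        return cls(
            periods=np.empty(0),
            q=np.empty(0),
            max_q=None,
            p_max_q=None,
            method=method,
            s_min=s_min,
            s_max=s_max,
            degenerate=True,
            note=note,
        )


def count_pair_spacings(occ: TractOccurrenceSet, s_hist_max: int) -> SpacingHistogram:
    """Count occurrence pairs at every start-to-start distance up to s_hist_max.

    The count at distance ``s`` equals the lag-``s`` autocorrelation of the
    0/1 occurrence indicator, computed exactly with integer-valued dot
    products; this is O(L * s_hist_max) regardless of occurrence density.
    """
    if s_hist_max < 1:
        raise ValueError("s_hist_max must be >= 1")
    L = occ.seq_length
    counts = np.zeros(s_hist_max, dtype=np.int64)
    m = len(occ)
    if m >= 2:
        x = np.zeros(L, dtype=np.float64)
        x[occ.positions] = 1.0
        for s in range(1, min(s_hist_max, L - 1) + 1):
            counts[s - 1] = int(round(float(x[:-s] @ x[s:])))
    return SpacingHistogram(counts=counts, m=m, L=L, method=occ.method)


def expected_pair_counts(m: int, L: int, s: np.ndarray) -> np.ndarray:
    """Expected pairs at distance ``s`` for ``m`` uniformly placed starts.

    ``E(s) = m (m - 1) (L - s) / L^2``.  Any smooth low-order deviation of
    the true expectation from this form is absorbed downstream by the
    parabolic detrend and the unit-mean spectrum scaling.
    """
    return m * (m - 1) * (L - np.asarray(s, dtype=np.float64)) / float(L) ** 2


def normalize_and_detrend(
    hist: SpacingHistogram, s_min: int = DEFAULT_S_MIN, s_max: int = DEFAULT_S_MAX
) -> ProcessedSpacing:
    """Normalise ``N(s)`` by expected counts, smooth and detrend.

    The 3-point moving average is computed on the extended range
    [s_min - 1, s_max + 1] so every interior point uses true neighbours;
    the least-squares quadratic is fitted and subtracted on [s_min, s_max].
    """
    if not 1 < s_min < s_max:
        raise ValueError("require 1 < s_min < s_max")
    if s_max > hist.s_hist_max - 1:
        raise ValueError("s_max must leave one bp of histogram margin for smoothing")
    if hist.L <= s_max:
        raise ValueError("sequence shorter than s_max")
    if hist.m < 2:
        raise DegenerateInput("fewer than two tract occurrences")

    s_ext = np.arange(s_min - 1, s_max + 2)
    n_ext = hist.counts[s_min - 2 : s_max + 1] / expected_pair_counts(
        hist.m, hist.L, s_ext
    )
    smoothed = (n_ext[:-2] + n_ext[1:-1] + n_ext[2:]) / 3.0
    s = np.arange(s_min, s_max + 1)
    coeffs = np.polyfit(s, smoothed, 2)
    y = smoothed - np.polyval(coeffs, s)
    return ProcessedSpacing(y=y, s_min=s_min, s_max=s_max)


def power_spectrum(
    ps: ProcessedSpacing,
    p_lo: float = DEFAULT_P_LO,
    p_hi: float = DEFAULT_P_HI,
    dp: float = DEFAULT_DP,
    method: TractMethod | None = None,
) -> SpacingSpectrum:
    """Fourier amplitude spectrum of the processed spacing function.

    The spectrum is evaluated directly on a dense period grid (default
    [2, 20] bp at 0.05 bp) rather than on DFT bins, giving sub-bp period
    resolution.  The signal intensity is the modulus of the Fourier sum,

        Q(P) = | sum_s y(s) exp(2 pi i s / P) |,

    scaled so that the mean of Q over periods 5-20 bp equals 1; this
    amplitude-scale normalisation is the one under which the packaged null
    percentiles (significance module) are calibrated.  MaxQ/PMaxQ are the
    height and period of the highest point of Q* over 5-20 bp, with ties
    broken toward the smaller period.
    """
    if p_lo < 2:
        raise ValueError("p_lo must be >= 2 bp")
    lo, hi = NORM_RANGE
    if p_lo > lo or p_hi < hi:
        raise ValueError(f"period grid must cover the normalisation range {NORM_RANGE}")
    periods = np.round(np.arange(p_lo, p_hi + dp / 2, dp), 9)
    phases = np.exp(2j * np.pi * np.outer(ps.s, 1.0 / periods))
    amp = np.abs(ps.y @ phases)
    norm_mask = (periods >= lo - 1e-12) & (periods <= hi + 1e-12)
    mean_amp = amp[norm_mask].mean()
    if mean_amp == 0.0:
        raise DegenerateInput("zero-variance spacing function (flat spectrum)")
    q = amp / mean_amp
    search = np.flatnonzero(norm_mask)
    i_best = search[np.argmax(q[search])]  # first index on ties -> smaller period
    return SpacingSpectrum(
        periods=periods,
        q=q,
        max_q=float(q[i_best]),
        p_max_q=float(periods[i_best]),
        method=method,
        s_min=ps.s_min,
        s_max=ps.s_max,
    )


def perplot(
    sequence,
    method: TractMethod | str = "A2T2",
    s_min: int = DEFAULT_S_MIN,
    s_max: int = DEFAULT_S_MAX,
    p_lo: float = DEFAULT_P_LO,
    p_hi: float = DEFAULT_P_HI,
    dp: float = DEFAULT_DP,
) -> SpacingSpectrum:
    """Full periodicity-plot pipeline for one sequence.

    Composes :func:`~perioscan.tracts.find_tracts`,
    :func:`count_pair_spacings`, :func:`normalize_and_detrend` and
    :func:`power_spectrum`.  Sequences with fewer than two tract
    occurrences (or a degenerate flat spacing function) yield a flagged
    empty spectrum rather than an exception.
    """
    if isinstance(method, str):
        method = build_method(method)
    occ = find_tracts(sequence, method)
    if occ.seq_length <= s_max:
        raise ValueError(
            f"sequence length {occ.seq_length} must exceed s_max={s_max}"
        )
    try:
        hist = count_pair_spacings(occ, s_hist_max=s_max + 1)
        ps = normalize_and_detrend(hist, s_min=s_min, s_max=s_max)
        return power_spectrum(ps, p_lo=p_lo, p_hi=p_hi, dp=dp, method=method)
    except DegenerateInput as exc:
        return SpacingSpectrum.flagged(method, s_min, s_max, note=str(exc))


def write_spectrum_tsv(spec: SpacingSpectrum, handle: TextIO) -> None:
    """Write the spectrum as tab-delimited text with a parameter header."""
    code = spec.method.code if spec.method is not None else "NA"
    handle.write(f"# method\t{code}\n")
    handle.write(f"# s_min\t{spec.s_min}\n")
    handle.write(f"# s_max\t{spec.s_max}\n")
    if spec.degenerate:
        handle.write(f"# degenerate\t{spec.note}\n")
        handle.write("period\tQ\n")
        return
    handle.write(f"# MaxQ\t{spec.max_q:.6g}\n")
    handle.write(f"# PMaxQ\t{spec.p_max_q:.6g}\n")
    handle.write("period\tQ\n")
    for p, q in zip(spec.periods, spec.q):
        handle.write(f"{p:.2f}\t{q:.6g}\n")
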