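"""Sliding-window periodicity scan of a chromosome.

A periodicity spectrum summarises a whole sequence; it says nothing about
whether the signal is uniform or concentrated in a few regions.  The scan
applies the full spectrum pipeline in a sliding window (default 10 kb
moved in 5 kb steps), producing

* a heat-map matrix of Q*(P) per window, grey-mapped linearly between
  Q* = 1.8 (white) and 4.0 (black);
* persistency curves: the fraction of windows whose spectrum maximum lies
  within +/- 0.2 bp of each period, and the fraction of windows with
  Q*(P) >= t for t in {2.0, 2.5, 3.0, 4.0, 6.0};
* six indices: MaxMax/PMaxMax (peak of the argmax-fraction curve),
  Max2/PMax2 (peak of the t = 2.0 exceedance curve) and Max3/PMax3
  (t = 3.0), measuring how persistent the dominant periodicity is along
  the chromosome.

Windows with fewer than two tract occurrences or more than 10% non-ACGT
content are skipped and excluded from all fraction denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TextIO

import numpy as np

from .spectrum import DEFAULT_S_MAX, DEFAULT_S_MIN, NORM_RANGE, perplot
from .tracts import TractMethod, build_method, sequence_codes

__all__ = [
    "DEFAULT_WINDOW",
    "DEFAULT_STEP",
    "EXCEED_THRESHOLDS",
    "ScanResult",
    "PersistencyCurves",
    "ScanIndices",
    "perscan",
    "persistency",
    "scan_indices",
    "heatmap_matrix",
    "write_scan_tsv",
    "read_scan_tsv",
    "write_indices_tsv",
]

DEFAULT_WINDOW = 10_000
DEFAULT_STEP = 5_000

#: Q* thresholds of the exceedance-fraction curves (heat-map colour key).
EXCEED_THRESHOLDS = (2.0, 2.5, 3.0, 4.0, 6.0)

MAX_NON_ACGT_FRACTION = 0.10

_ACGT = frozenset(b"ACGT")


@dataclass
class ScanResult:
    """Per-window spectra over a chromosome.

    ``spectra`` holds one row of Q*(P) per retained window over the shared
    period grid ``periods``; ``windows`` are the matching half-open
    [start, end) intervals in ascending order.  ``skipped`` records the
    (start, end, reason) of excluded windows.
    """

    windows: list[tuple[int, int]]
    periods: np.ndarray = field(repr=False)
    spectra: np.ndarray = field(repr=False)
    max_q: np.ndarray = field(repr=False)
    p_max_q: np.ndarray = field(repr=False)
    window_length: int
    step: int
    method: TractMethod
    s_min: int
    s_max: int
    skipped: list[tuple[int, int, str]] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return len(self.windows)

    @property
    def midpoints(self) -> np.ndarray:
        return np.asarray([(a + b) / 2.0 for a, b in self.windows])


def perscan(
    sequence,
    method: TractMethod | str = "A2T2",
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    s_min: int = DEFAULT_S_MIN,
    s_max: int = DEFAULT_S_MAX,
) -> ScanResult:
    """Run the spectrum pipeline in a sliding window along ``sequence``.

    Trailing partial windows (shorter than ``window``) are dropped: a
    shorter window would have a different null MaxQ distribution and
    corrupt the persistency fractions.
    """
    if isinstance(method, str):
        method = build_method(method)
    if window <= s_max:
        raise ValueError(f"window ({window}) must exceed s_max ({s_max})")
    if step < 1:
        raise ValueError("step must be >= 1")
    codes = sequence_codes(sequence)
    L = codes.size
    if L < window:
        raise ValueError(
            f"sequence length {L} is shorter than the window {window}; "
            "reduce the window or use a plain periodicity plot"
        )
    acgt = np.isin(codes, np.frombuffer(b"ACGT", dtype=np.uint8))

    windows: list[tuple[int, int]] = []
    skipped: list[tuple[int, int, str]] = []
    rows: list[np.ndarray] = []
    max_qs: list[float] = []
    p_max_qs: list[float] = []
    periods: np.ndarray | None = None
    for start in range(0, L - window + 1, step):
        end = start + window
        sub = codes[start:end]
        non_acgt = 1.0 - acgt[start:end].mean()
        if non_acgt > MAX_NON_ACGT_FRACTION:
            skipped.append((start, end, f"non-ACGT fraction {non_acgt:.2f} > 0.10"))
            continue
        sp = perplot(sub, method=method, s_min=s_min, s_max=s_max)
        if sp.degenerate:
            skipped.append((start, end, sp.note))
            continue
        periods = sp.periods
        windows.append((start, end))
        rows.append(sp.q)
        max_qs.append(sp.max_q)
        p_max_qs.append(sp.p_max_q)
    if periods is None:
        periods = np.empty(0)
    spectra = np.vstack(rows) if rows else np.empty((0, periods.size))
    return ScanResult(
        windows=windows,
        periods=periods,
        spectra=spectra,
        max_q=np.asarray(max_qs),
        p_max_q=np.asarray(p_max_qs),
        window_length=window,
        step=step,
        method=method,
        s_min=s_min,
        s_max=s_max,
        skipped=skipped,
    )


@dataclass
class PersistencyCurves:
    """Fraction-of-windows curves over the shared period grid."""

    periods: np.ndarray = field(repr=False)
    argmax_fraction: np.ndarray = field(repr=False)
    exceed_fraction: dict[float, np.ndarray] = field(repr=False)
    halfwidth: float = 0.2
    n_windows: int = 0


def persistency(
    scan: ScanResult,
    thresholds: tuple[float, ...] = EXCEED_THRESHOLDS,
    halfwidth: float = 0.2,
) -> PersistencyCurves:
    """Persistency curves of the periodic signal across scan windows.

    ``argmax_fraction(P)`` counts windows whose spectrum maximum (over the
    5-20 bp search range, regardless of its height) falls within
    ``P +/- halfwidth``; ``exceed_fraction[t](P)`` counts windows with
    ``Q*(P) >= t``.  Denominators are the retained windows only.
    """
    n = scan.n_retained
    if n == 0:
        raise ValueError("scan has no retained windows")
    P = scan.periods
    diffs = np.abs(scan.p_max_q[:, None] - P[None, :])
    argmax_fraction = (diffs <= halfwidth + 1e-12).mean(axis=0)
    exceed = {
        float(t): (scan.spectra >= t).mean(axis=0) for t in sorted(thresholds)
    }
    return PersistencyCurves(
        periods=P,
        argmax_fraction=argmax_fraction,
        exceed_fraction=exceed,
        halfwidth=halfwidth,
        n_windows=n,
    )


@dataclass(frozen=True)
class ScanIndices:
    """Peak height and period of the persistency curves.

    ``p_*`` is ``None`` when the corresponding curve is identically zero
    over the search range.
    """

    max_max: float
    p_max_max: float | None
    max2: float
    p_max2: float | None
    max3: float
    p_max3: float | None


def _curve_peak(periods, curve, search_range) -> tuple[float, float | None]:
    lo, hi = search_range
    mask = (periods >= lo - 1e-12) & (periods <= hi + 1e-12)
    idx = np.flatnonzero(mask)
    best = idx[np.argmax(curve[idx])]  # first index on ties -> smaller period
    height = float(curve[best])
    return height, (float(periods[best]) if height > 0 else None)


def scan_indices(
    curves: PersistencyCurves, search_range: tuple[float, float] = NORM_RANGE
) -> ScanIndices:
    """Six persistency indices from the curves, searched over 5-20 bp."""
    max_max, p_max_max = _curve_peak(
        curves.periods, curves.argmax_fraction, search_range
    )
    max2, p_max2 = _curve_peak(curves.periods, curves.exceed_fraction[2.0], search_range)
    max3, p_max3 = _curve_peak(curves.periods, curves.exceed_fraction[3.0], search_range)
    return ScanIndices(max_max, p_max_max, max2, p_max2, max3, p_max3)


def heatmap_matrix(scan: ScanResult, lo: float = 1.8, hi: float = 4.0) -> np.ndarray:
    """Grey levels in [0, 1] for the periodicity-scan heat map.

    0 = white at Q* <= ``lo``, 1 = black at Q* >= ``hi``, linear in
    between.  Rows are periods (vertical axis), columns are windows in
    chromosome order (horizontal axis at window midpoints).
    """
    if not lo < hi:
        raise ValueError("require lo < hi")
    return np.clip((scan.spectra.T - lo) / (hi - lo), 0.0, 1.0)


# ---------------------------------------------------------------------------
# Tab-delimited persistence: scans are written once and post-processed many
# times without recomputation.

def write_scan_tsv(scan: ScanResult, handle: TextIO) -> None:
    """Long-format scan table: one row per (window, period)."""
    handle.write(f"# window\t{scan.window_length}\n")
    handle.write(f"# step\t{scan.step}\n")
    handle.write(f"# method\t{scan.method.code}\n")
    handle.write(f"# s_min\t{scan.s_min}\n")
    handle.write(f"# s_max\t{scan.s_max}\n")
    for start, end, reason in scan.skipped:
        handle.write(f"# skipped\t{start}\t{end}\t{reason}\n")
    handle.write("window_start\twindow_end\tperiod\tQ\n")
    for (start, end), row in zip(scan.windows, scan.spectra):
        for p, q in zip(scan.periods, row):
            handle.write(f"{start}\t{end}\t{p:.2f}\t{q:.8g}\n")


def read_scan_tsv(handle: TextIO) -> ScanResult:
    """Reconstruct a :class:`ScanResult` written by :func:`write_scan_tsv`."""
    meta: dict[str, str] = {}
    skipped: list[tuple[int, int, str]] = []
    windows: list[tuple[int, int]] = []
    periods: list[float] = []
    rows: list[list[float]] = []
    first_window = True
    for line in handle:
        line = line.rstrip("\n")
        if line.startswith("#"):
            parts = line[1:].strip().split("\t")
            if parts[0] == "skipped":
                skipped.append((int(parts[1]), int(parts[2]), parts[3]))
            else:
                meta[parts[0]] = parts[1]
            continue
        if line.startswith("window_start") or not line:
            continue
        s, e, p, q = line.split("\t")
        win = (int(s), int(e))
        if not windows or windows[-1] != win:
            windows.append(win)
            rows.append([])
            first_window = len(windows) == 1
        if first_window:
            periods.append(float(p))
        rows[-1].append(float(q))
    periods_arr = np.asarray(periods)
    spectra = (
        np.asarray(rows) if rows else np.empty((0, periods_arr.size))
    )
    lo, hi = NORM_RANGE
    mask = (periods_arr >= lo - 1e-12) & (periods_arr <= hi + 1e-12)
    idx = np.flatnonzero(mask)
    if spectra.shape[0]:
        best = idx[np.argmax(spectra[:, idx], axis=1)]
        max_q = spectra[np.arange(spectra.shape[0]), best]
        p_max_q = periods_arr[best]
    else:
        max_q = np.empty(0)
        p_max_q = np.empty(0)
    return ScanResult(
        windows=windows,
        periods=periods_arr,
        spectra=spectra,
        max_q=max_q,
        p_max_q=p_max_q,
        window_length=int(meta["window"]),
        step=int(meta["step"]),
        method=build_method(meta["method"]),
        s_min=int(meta["s_min"]),
        s_max=int(meta["s_max"]),
        skipped=skipped,
    )


def write_indices_tsv(
    curves: PersistencyCurves, indices: ScanIndices, handle: TextIO
) -> None:
    """Small companion table with the six persistency indices."""
    handle.write("index\tvalue\n")
    handle.write(f"MaxMax\t{indices.max_max:.6g}\n")
    handle.write(f"PMaxMax\t{'' if indices.p_max_max is None else f'{indices.p_max_max:.6g}'}\n")
    handle.write(f"Max2\t{indices.max2:.6g}\n")
    handle.write(f"PMax2\t{'' if indices.p_max2 is None else f'{indices.p_max2:.6g}'}\n")
    handle.write(f"Max3\t{indices.max3:.6g}\n")
    handle.write(f"PMax3\t{'' if indices.p_max3 is None else f'{indices.p_max3:.6g}'}\n")
    handle.write(f"n_windows\t{curves.n_windows}\n")
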