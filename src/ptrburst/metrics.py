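"""Spectral and temporal characterisation of burst states.

State power spectra are estimated with the multitaper method (DPSS tapers,
time-bandwidth 4) over the data samples where a state is "on": on-segments
of at least 3 samples are chopped into pieces of at most 2 s, each piece's
tapered periodograms are evaluated on a common 0.5 Hz grid (zero-padded
FFT), and pieces are averaged with segment-length weights.  A
covariance-derived spectrum (Blackman-Tukey transform of the state's
autocovariance extracted from its lag-space covariance matrix) is provided
as a cross-check on the same grid.

Band powers are areas under the PSD within the canonical theta (4-8 Hz),
alpha (8-13 Hz) and beta (13-30 Hz) bands.  Time-frequency responses are
reconstructed as the outer product of a state's PSD with its trial-averaged
probability evolution, summed over states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import dpss

from .hmm import TdeHmmModel

__all__ = [
    "DEFAULT_FREQS",
    "BANDS",
    "StateSpectrum",
    "BandPower",
    "RegionBurstSummary",
    "ReconstructedTFR",
    "multitaper_psd",
    "multitaper_spectrogram",
    "state_psd",
    "state_psd_from_model",
    "band_power",
    "summarize_region",
    "reconstruct_tfr",
    "burst_coincidence",
]

DEFAULT_FREQS = np.round(np.arange(1.0, 45.0 + 1e-9, 0.5), 3)
BANDS = {"theta": (4.0, 8.0), "alpha": (8.0, 13.0), "beta": (13.0, 30.0)}
PEAK_RANGE = (3.0, 45.0)


@dataclass
class StateSpectrum:
    """PSD of one (region, state) on a fixed 1-45 Hz grid."""

    freqs: np.ndarray
    psd: np.ndarray
    peak_freq: float
    region: str = ""
    state: int = -1


@dataclass(frozen=True)
class BandPower:
    theta: float
    alpha: float
    beta: float


@dataclass
class RegionBurstSummary:
    region_name: str
    mean_duration: float
    se_duration: float
    peak_freq: float
    cycles_per_burst: float
    burst_rate: dict[str, float] = field(default_factory=dict)
    n_bursts: int = 0


@dataclass
class ReconstructedTFR:
    """Per-state TFR(f, t) = psd_state(f) x probability_state(t), plus sum."""

    freqs: np.ndarray
    times: np.ndarray
    per_state: np.ndarray
    total: np.ndarray


def _taper_bank(n: int, nw: float = 4.0) -> np.ndarray:
    """DPSS tapers for a segment of n samples; adapts NW for very short
    segments so at least one valid taper always exists."""
    nw_eff = min(nw, (n - 1) / 2.0)
    n_tapers = max(1, min(int(2 * nw_eff - 1), n - 1))
    tapers = dpss(n, nw_eff, Kmax=n_tapers)
    return np.atleast_2d(tapers)


def multitaper_psd(
    x: np.ndarray,
    fs: float,
    nw: float = 4.0,
    freqs: np.ndarray = DEFAULT_FREQS,
) -> np.ndarray:
    """Multitaper PSD of one segment, interpolated onto ``freqs``.

    The FFT is zero-padded to a 0.5 Hz native resolution so segments of
    different lengths land on a common grid.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("segment too short for a PSD (need >= 3 samples)")
    nfft = max(int(round(2 * fs)), n)
    tapers = _taper_bank(n, nw)
    spec = rfft(tapers * x[None, :], n=nfft, axis=1)
    pxx = (np.abs(spec) ** 2).mean(axis=0) / fs
    grid = rfftfreq(nfft, d=1.0 / fs)
    # one-sided scaling (DC and Nyquist are not doubled)
    pxx[1:] *= 2.0
    if nfft % 2 == 0:
        pxx[-1] /= 2.0
    return np.interp(freqs, grid, pxx)


def _on_segments(onoff_row: np.ndarray, min_samples: int = 3) -> list[tuple[int, int]]:
    padded = np.concatenate(([0], np.asarray(onoff_row).astype(np.int8), [0]))
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return [(a, b) for a, b in zip(starts, stops) if b - a >= min_samples]


def state_psd(
    series: np.ndarray,
    onoff_row: np.ndarray,
    fs: float,
    region: str = "",
    state: int = -1,
    nw: float = 4.0,
    max_segment_s: float = 2.0,
    min_total_s: float = 2.0,
    freqs: np.ndarray = DEFAULT_FREQS,
) -> StateSpectrum | None:
    """Multitaper PSD over the samples where a state is on.

    Returns None (flagged missing) when the state's total on-time is below
    ``min_total_s``; such states are excluded from summaries.
    """
    series = np.asarray(series, dtype=float)
    segs = _on_segments(onoff_row)
    total = sum(b - a for a, b in segs)
    if total / fs < min_total_s:
        return None
    max_len = int(round(max_segment_s * fs))
    pieces: list[np.ndarray] = []
    for a, b in segs:
        for lo in range(a, b, max_len):
            piece = series[lo: min(lo + max_len, b)]
            if piece.shape[0] >= 3:
                pieces.append(piece)
    weights = np.array([p.shape[0] for p in pieces], dtype=float)
    # nw is the time-bandwidth of a full-length (max_segment_s) piece;
    # shorter pieces keep the same spectral half-bandwidth nw/max_segment_s
    # instead of inheriting a bandwidth inversely proportional to their
    # length, which would smear sub-second bursts over tens of Hz
    psds = np.stack(
        [
            multitaper_psd(p, fs, max(1.0, nw * p.shape[0] / max_len), freqs)
            for p in pieces
        ]
    )
    psd = (psds * weights[:, None]).sum(axis=0) / weights.sum()
    return StateSpectrum(
        freqs=freqs, psd=psd, peak_freq=_peak(freqs, psd), region=region, state=state
    )


def _peak(freqs: np.ndarray, psd: np.ndarray) -> float:
    sel = (freqs >= PEAK_RANGE[0]) & (freqs <= PEAK_RANGE[1])
    return float(freqs[sel][np.argmax(psd[sel])])


def state_psd_from_model(
    model: TdeHmmModel,
    state: int,
    fs: float,
    freqs: np.ndarray = DEFAULT_FREQS,
) -> StateSpectrum:
    """Blackman-Tukey spectrum of a state's autocovariance.

    The state autocovariance at lag d is the mean of the d-th diagonal of
    the state's lag-space covariance matrix; a Hann lag window controls
    leakage and the result is clipped at zero.
    """
    cov = model.covariances[state]
    d = cov.shape[0]
    acov = np.array([np.diagonal(cov, offset=k).mean() for k in range(d)])
    lag_win = np.hanning(2 * d - 1)[d - 1:]
    acov = acov * lag_win
    lags = np.arange(d) / fs
    psd = np.array(
        [
            (acov[0] + 2.0 * (acov[1:] * np.cos(2 * np.pi * f * lags[1:])).sum()) / fs
            for f in freqs
        ]
    )
    psd = np.clip(psd, 0.0, None)
    return StateSpectrum(freqs=freqs, psd=psd, peak_freq=_peak(freqs, psd), state=state)


def band_power(spec: StateSpectrum, bands: dict[str, tuple[float, float]] = BANDS) -> BandPower:
    """Area under the PSD within each canonical band (trapezoidal rule).

    Bands are integrated over the closed interval [low, high]; a grid point
    shared by two adjacent bands contributes half its trapezoid to each, so
    no power is double counted.
    """
    vals = {}
    for name, (lo, hi) in bands.items():
        sel = (spec.freqs >= lo) & (spec.freqs <= hi)
        pts = spec.freqs[sel]
        if pts.size < 2 or pts[0] > lo or pts[-1] < hi:
            raise ValueError(f"frequency grid does not cover band {name} [{lo}, {hi}]")
        if np.any(np.diff(pts) > 1.0 + 1e-9):
            raise ValueError(f"frequency grid has gaps inside band {name}")
        vals[name] = float(np.trapezoid(spec.psd[sel], pts))
    return BandPower(**vals)


def summarize_region(
    bursts: pd.DataFrame,
    spec: StateSpectrum,
    window_durations: dict[str, float] | None = None,
    window_of_burst: pd.Series | None = None,
) -> RegionBurstSummary | None:
    """Regional burst summary for the PTR state.

    ``bursts`` is a BurstTable restricted to one region's PTR state.  The
    mean duration is the mean of per-participant means, with the standard
    error across participants (across bursts when only one participant is
    present).  ``cycles_per_burst`` is mean_duration x peak_freq.  Burst
    rates per window type are counts (of bursts assigned to each window by
    ``window_of_burst``) divided by the window's total duration.
    """
    if bursts.empty:
        return None
    per_participant = bursts.groupby("participant")["duration_s"].mean()
    mean_dur = float(per_participant.mean())
    if len(per_participant) > 1:
        se = float(per_participant.std(ddof=1) / np.sqrt(len(per_participant)))
    elif len(bursts) > 1:
        se = float(bursts["duration_s"].std(ddof=1) / np.sqrt(len(bursts)))
    else:
        se = 0.0
    rates: dict[str, float] = {}
    if window_durations:
        counts = (
            window_of_burst.value_counts()
            if window_of_burst is not None
            else pd.Series(dtype=int)
        )
        for wtype, total_s in window_durations.items():
            if total_s > 0:
                rates[wtype] = float(counts.get(wtype, 0)) / total_s
    return RegionBurstSummary(
        region_name=str(bursts["region"].iloc[0]),
        mean_duration=mean_dur,
        se_duration=se,
        peak_freq=spec.peak_freq,
        cycles_per_burst=mean_dur * spec.peak_freq,
        burst_rate=rates,
        n_bursts=int(len(bursts)),
    )


def reconstruct_tfr(
    evolutions: np.ndarray,
    spectra: list[StateSpectrum],
    fs: float,
) -> ReconstructedTFR:
    """TFR reconstruction: per-state outer product psd(f) x probability(t).

    ``evolutions`` is (K, block_samples); ``spectra`` one StateSpectrum per
    state (states with a missing spectrum contribute zero).
    """
    K, L = evolutions.shape
    if len(spectra) != K:
        raise ValueError("need one spectrum (or None) per state")
    freqs = next(s.freqs for s in spectra if s is not None)
    per_state = np.zeros((K, freqs.size, L))
    for k, spec in enumerate(spectra):
        if spec is None:
            continue
        if spec.freqs.shape != freqs.shape or not np.allclose(spec.freqs, freqs):
            raise ValueError("spectra must share one frequency grid")
        per_state[k] = np.outer(spec.psd, evolutions[k])
    return ReconstructedTFR(
        freqs=freqs,
        times=np.arange(L) / fs,
        per_state=per_state,
        total=per_state.sum(axis=0),
    )


def multitaper_spectrogram(
    x: np.ndarray,
    fs: float,
    window_s: float = 0.5,
    step_s: float = 0.1,
    nw: float = 2.0,
    freqs: np.ndarray = DEFAULT_FREQS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sliding-window multitaper spectrogram (freqs x frame centres)."""
    x = np.asarray(x, dtype=float)
    win = int(round(window_s * fs))
    step = max(1, int(round(step_s * fs)))
    if win > x.shape[0]:
        raise ValueError("window longer than series")
    starts = np.arange(0, x.shape[0] - win + 1, step)
    S = np.stack([multitaper_psd(x[s: s + win], fs, nw, freqs) for s in starts], axis=1)
    times = (starts + win / 2.0) / fs
    return freqs, times, S


def tfr_fidelity(
    series: np.ndarray,
    evolutions: np.ndarray,
    spectra: list[StateSpectrum | None],
    design,
    fs: float,
    band: tuple[float, float] = (8.0, 13.0),
    state: int | None = None,
    window_s: float = 0.5,
    step_s: float = 0.1,
) -> float:
    """Pearson correlation between a reconstructed TFR and a direct
    trial-averaged multitaper spectrogram, restricted to ``band``.

    ``state`` selects one state's reconstruction (e.g. the PTR state);
    None uses the all-state sum.  Both estimates target the same induced
    power modulation, so high correlation validates the probability x PSD
    factorisation.
    """
    from scipy.stats import pearsonr

    from .preprocess import epoch_blocks

    tfr = reconstruct_tfr(evolutions, spectra, fs)
    blocks = epoch_blocks(np.asarray(series, dtype=float), design, fs)
    S = None
    for b in blocks:
        _, times, s = multitaper_spectrogram(b, fs, window_s=window_s, step_s=step_s)
        S = s if S is None else S + s
    S /= blocks.shape[0]
    sel = (tfr.freqs >= band[0]) & (tfr.freqs < band[1])
    rec = tfr.total[sel] if state is None else tfr.per_state[state][sel]
    rec_on_frames = np.stack([np.interp(times, tfr.times, row) for row in rec])
    r, _ = pearsonr(rec_on_frames.ravel(), S[sel].ravel())
    return float(r)


def burst_coincidence(
    row_a: np.ndarray, row_b: np.ndarray, window: slice | None = None
) -> float:
    """Jaccard index of on-samples of two regions within a window.

    Returns 0.0 when neither region is ever on in the window.
    """
    a = np.asarray(row_a).astype(bool)
    b = np.asarray(row_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("rows must have equal length")
    if window is not None:
        a, b = a[window], b[window]
    if a.size == 0:
        raise ValueError("empty coincidence window")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)
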