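"""Filtering, downsampling, cross-participant concatenation and epoching.

The pipeline's front end: broadband (1-150 Hz) zero-phase bandpass at the
acquisition rate, polyphase downsampling (600 -> 100 Hz by default), then
per-region concatenation of all participants followed by a single z-scoring
of the concatenated series.  Concatenation boundaries are recorded so that
downstream state lifetimes never span two participants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from .synthetic import BlockDesign, SyntheticDataset

__all__ = [
    "PreprocConfig",
    "ConcatenatedSeries",
    "bandpass",
    "downsample",
    "concat_zscore",
    "epoch_blocks",
    "preprocess_datasets",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocConfig:
    band: tuple[float, float] = (1.0, 150.0)
    target_fs: float = 100.0
    filter_order: int = 4


def bandpass(x: np.ndarray, fs: float, config: PreprocConfig = PreprocConfig()) -> np.ndarray:
    """Zero-phase Butterworth bandpass along the last axis; removes DC.

    Forward-backward (``sosfiltfilt``) application preserves burst timing,
    which downstream lifetime estimates depend on.
    """
    low, high = config.band
    if not (0 < low < high < fs / 2):
        raise ValueError(f"band {config.band} outside (0, Nyquist={fs / 2})")
    x = np.asarray(x, dtype=float)
    x = x - x.mean(axis=-1, keepdims=True)
    sos = signal.butter(config.filter_order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def downsample(x: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    """Polyphase resampling with internal anti-alias filtering (last axis)."""
    if target_fs > fs:
        raise ValueError("target_fs must not exceed fs")
    if target_fs == fs:
        return np.asarray(x, dtype=float)
    from math import gcd

    up, down = int(round(target_fs)), int(round(fs))
    g = gcd(up, down)
    return signal.resample_poly(np.asarray(x, dtype=float), up // g, down // g, axis=-1)


@dataclass
class ConcatenatedSeries:
    """Per-region concatenation of all participants, z-scored once.

    ``values`` is (n_regions, total_samples); ``boundaries`` are the sample
    indices where consecutive participant segments abut (excluding 0 and
    the end); ``segment_labels`` names the participant of each segment.
    """

    values: np.ndarray
    region_names: list[str]
    fs: float
    boundaries: list[int] = field(default_factory=list)
    segment_labels: list[str] = field(default_factory=list)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def segment_of(self, sample: int) -> int:
        """Index of the participant segment containing ``sample``."""
        return int(np.searchsorted(np.asarray(self.boundaries), sample, side="right"))


def concat_zscore(
    segments: Sequence[np.ndarray],
    region_names: Sequence[str],
    fs: float,
    segment_labels: Sequence[str] | None = None,
) -> ConcatenatedSeries:
    """Concatenate per-participant (regions x time) arrays and z-score.

    Z-scoring is applied once, per region, on the concatenation (not per
    segment), reducing between-participant variance while preserving the
    relative scale of each participant's activity.
    """
    if len(segments) == 0:
        raise ValueError("need at least one segment")
    segments = [np.atleast_2d(np.asarray(s, dtype=float)) for s in segments]
    n_regions = segments[0].shape[0]
    if any(s.shape[0] != n_regions for s in segments):
        raise ValueError("all segments must share the region count")
    if segment_labels is None:
        segment_labels = [f"p{i:02d}" for i in range(len(segments))]
    values = np.concatenate(segments, axis=1)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance region cannot be z-scored")
    values = (values - mean) / sd
    boundaries = list(np.cumsum([s.shape[1] for s in segments])[:-1].astype(int))
    return ConcatenatedSeries(
        values=values,
        region_names=list(region_names),
        fs=float(fs),
        boundaries=boundaries,
        segment_labels=list(segment_labels),
    )


def epoch_blocks(x: np.ndarray, design: BlockDesign, fs: float) -> np.ndarray:
    """Reshape a 1-D series (signal, probability or binary state) into
    (n_blocks, block_samples).  Trailing partial blocks are dropped, never
    zero-padded, with a logged warning."""
    x = np.asarray(x)
    if x.ndim != 1:
        raise ValueError("epoch_blocks expects a 1-D series")
    block_len = int(round(design.block_dur * fs))
    n_full = x.shape[0] // block_len
    if n_full < 1:
        raise ValueError("series shorter than one block")
    if x.shape[0] % block_len:
        logger.warning(
            "dropping %d trailing samples (partial block)", x.shape[0] % block_len
        )
    return x[: n_full * block_len].reshape(n_full, block_len)


def preprocess_datasets(
    datasets: Sequence[SyntheticDataset],
    config: PreprocConfig = PreprocConfig(),
) -> ConcatenatedSeries:
    """Bandpass, downsample and concatenate a cohort of datasets.

    All datasets must share sampling rate and region names; the output is
    at ``config.target_fs``.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    fs = datasets[0].fs
    names = datasets[0].region_names
    if any(ds.fs != fs or ds.region_names != names for ds in datasets):
        raise ValueError("datasets must share fs and region names")
    processed = []
    for ds in datasets:
        x = bandpass(ds.data, fs, config) if config.band else ds.data
        processed.append(downsample(x, fs, config.target_fs))
    return concat_zscore(
        processed, names, config.target_fs,
        segment_labels=[ds.participant_id for ds in datasets],
    )
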