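"""Between-task comparisons and behaviour correlations.

Regional burst metrics (band powers, durations, cycles per burst) are
compared between two tasks by ordinary least-squares simple regression
(reported as R^2); per-participant PTR-state probability contrasts between
two task conditions are correlated with reaction-time contrasts using
Pearson correlation with Bonferroni correction over the family of tested
regions/networks (4 by default: frontal, left parietal, left lateral
visual, dorsal attention network).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .grouping import PtrWindow, _window_slice
from .synthetic import BlockDesign

__all__ = [
    "RegionMetricVector",
    "OlsFit",
    "between_task_r2",
    "ptr_contrast",
    "behaviour_table",
    "rt_correlation",
]


@dataclass
class RegionMetricVector:
    """One scalar metric per region for one task, in a fixed region order."""

    values: pd.Series
    task: str = ""
    metric: str = ""


@dataclass(frozen=True)
class OlsFit:
    r2: float
    slope: float
    intercept: float


def _as_series(v) -> pd.Series:
    if isinstance(v, RegionMetricVector):
        return v.values
    if isinstance(v, pd.Series):
        return v
    return pd.Series(np.asarray(v, dtype=float))


def between_task_r2(a, b) -> OlsFit:
    """OLS simple regression of task-b regional metrics on task-a metrics.

    Accepts RegionMetricVector, pandas Series (indices must match) or plain
    arrays of equal length >= 3.
    """
    sa, sb = _as_series(a), _as_series(b)
    if isinstance(sa.index, pd.Index) and isinstance(sb.index, pd.Index):
        if not sa.index.equals(sb.index):
            raise ValueError("region orders differ between tasks")
    if len(sa) != len(sb) or len(sa) < 3:
        raise ValueError("need matched vectors of length >= 3")
    x, y = sa.to_numpy(float), sb.to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor vector")
    res = sps.linregress(x, y)
    return OlsFit(r2=float(res.rvalue**2), slope=float(res.slope),
                  intercept=float(res.intercept))


def ptr_contrast(
    evolutions: Mapping[str, Mapping[str, np.ndarray]],
    design: BlockDesign,
    fs: float,
    conditions: tuple[str, str],
    ptr: PtrWindow | None = None,
) -> pd.Series:
    """Per-participant PTR-window probability contrast, condition A - B.

    ``evolutions[participant][condition]`` is a trial-averaged PTR-state
    probability evolution over one block.  Participants missing either
    condition are dropped with a warning.
    """
    if ptr is None:
        ptr = PtrWindow(*design.ptr_window)
    sl = _window_slice(design, fs, ptr.start, ptr.end)
    cond_a, cond_b = conditions
    out = {}
    for participant, by_cond in evolutions.items():
        if cond_a not in by_cond or cond_b not in by_cond:
            warnings.warn(
                f"participant {participant} missing a condition; dropped",
                stacklevel=2,
            )
            continue
        out[participant] = float(
            np.mean(by_cond[cond_a][sl]) - np.mean(by_cond[cond_b][sl])
        )
    return pd.Series(out, name="ptr_contrast", dtype=float)


def behaviour_table(
    state_contrast: pd.Series, rt_contrast: pd.Series
) -> pd.DataFrame:
    """Align per-participant state and reaction-time contrasts."""
    table = pd.concat(
        {"ptr_contrast": state_contrast, "rt_contrast": rt_contrast}, axis=1
    ).dropna()
    if not np.isfinite(table.to_numpy()).all():
        raise ValueError("contrasts must be finite")
    return table


def rt_correlation(
    table: pd.DataFrame, m_comparisons: int = 4
) -> tuple[float, float, float]:
    """Pearson correlation of PTR-state and RT contrasts with Bonferroni.

    Returns (r, p_raw, p_bonferroni) where p_bonferroni = min(1, m * p).
    """
    if len(table) < 4:
        raise ValueError("need at least 4 participants")
    x = table["ptr_contrast"].to_numpy(float)
    y = table["rt_contrast"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance contrast")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), float(min(1.0, m_comparisons * p))
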