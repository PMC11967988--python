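"""Phase classification from closeness centrality, and transition tracking.

In ~800-molecule surfactant systems at a 0.7 nm contact cutoff, the three
mesophase architectures occupy distinct closeness-centrality ranges: values
below 0.03 are characteristic of the micellar phase, values between 0.03 and
0.055 of the hexagonal phase, and values above 0.055 of the lamellar phase
(whose inter-lamellar contacts merge the graph into one well-connected
component).  The thresholds are system-size dependent — closeness decreases
as the graph grows — so they are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .centrality_descriptors import (
    MetricDistribution,
    NodeMetricTable,
    closeness_centrality,
    running_average,
)
from .graph_construction import build_contact_graph
from .particles import DEFAULT_CUTOFF, DEFAULT_SELECTION, ConfigurationError

__all__ = [
    "PhaseThresholds",
    "PHASES",
    "classify_nodes",
    "phase_fractions",
    "coexistence_flag",
    "transition_scan",
    "TransitionScanResult",
]

PHASES = ("micellar", "hexagonal", "lamellar")


@dataclass(frozen=True)
class PhaseThresholds:
    """Closeness-centrality boundaries between the three phases.

    Values exactly equal to a boundary are assigned to the middle
    (hexagonal) class.
    """

    micellar_max: float = 0.03
    lamellar_min: float = 0.055

    def __post_init__(self):
        if not (0.0 < self.micellar_max < self.lamellar_min < 1.0):
            raise ConfigurationError(
                "thresholds must satisfy 0 < micellar_max < lamellar_min < 1"
            )


DEFAULT_THRESHOLDS = PhaseThresholds()


def classify_nodes(
    closeness: NodeMetricTable | pd.Series,
    thresholds: PhaseThresholds = DEFAULT_THRESHOLDS,
) -> pd.Series:
    """Per-node phase labels from closeness-centrality values."""
    values = closeness.values if isinstance(closeness, NodeMetricTable) else \
        pd.Series(closeness, dtype=float)
    arr = values.to_numpy(dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ConfigurationError("closeness values must lie in [0, 1]")
    labels = np.where(
        arr < thresholds.micellar_max, "micellar",
        np.where(arr <= thresholds.lamellar_min, "hexagonal", "lamellar"),
    )
    return pd.Series(labels, index=values.index, name="phase")


def _fractions(labels: pd.Series) -> dict:
    counts = labels.value_counts()
    n = len(labels)
    return {phase: counts.get(phase, 0) / n for phase in PHASES}


def phase_fractions(
    trajectory,
    selection=DEFAULT_SELECTION,
    cutoff: float = DEFAULT_CUTOFF,
    thresholds: PhaseThresholds = DEFAULT_THRESHOLDS,
    smoothing_window: int = 25,
) -> pd.DataFrame:
    """Per-frame molar fractions of each phase, plus running averages.

    ``trajectory`` is a :class:`~phasegraph.trajectory_io.Trajectory` or any
    iterable of configurations.  The smoothed columns use a centered
    ``smoothing_window``-point running average (window clamped to the series
    length for short trajectories).
    """
    frames = list(trajectory)
    if not frames:
        raise ConfigurationError("trajectory has no frames")
    rows = []
    for k, config in enumerate(frames):
        graph = build_contact_graph(config, selection, cutoff)
        labels = classify_nodes(closeness_centrality(graph), thresholds)
        row = {"time": config.time if config.time is not None else float(k)}
        row.update(_fractions(labels))
        rows.append(row)
    df = pd.DataFrame(rows)
    window = min(smoothing_window, len(df))
    if window % 2 == 0:
        window -= 1
    window = max(window, 1)
    for phase in PHASES:
        df[f"{phase}_smooth"] = running_average(df[phase].to_numpy(), window)
    return df


def coexistence_flag(distribution: MetricDistribution) -> str:
    """"bimodal" when two local maxima are separated by a deep valley.

    The documented heuristic: the histogram is bimodal iff some pair of
    local maxima is separated by a valley whose height is below 50% of the
    lower of the two peaks; otherwise "unimodal".  Requires >= 10 bins.
    """
    p = np.asarray(distribution.probability, dtype=float)
    if len(p) < 10:
        raise ConfigurationError("coexistence_flag needs >= 10 bins")
    peaks = [i for i in range(len(p))
             if p[i] > 0
             and (i == 0 or p[i] > p[i - 1])
             and (i == len(p) - 1 or p[i] >= p[i + 1])]
    for a in range(len(peaks)):
        for b in range(a + 1, len(peaks)):
            i, j = peaks[a], peaks[b]
            valley = p[i + 1:j].min() if j > i + 1 else min(p[i], p[j])
            if valley < 0.5 * min(p[i], p[j]):
                return "bimodal"
    return "unimodal"


@dataclass
class TransitionScanResult:
    """Location of the steepest change of a mean metric vs a control parameter."""

    metric: str
    location: float | None  # None: no localized transition
    gradient: np.ndarray

    @property
    def localized(self) -> bool:
        return self.location is not None


def transition_scan(
    control,
    means,
    metric: str = "metric",
    smoothing_window: int = 1,
    flatness_tolerance: float = 0.1,
) -> TransitionScanResult:
    """Control value maximizing |d<metric>/d control| of the smoothed curve.

    ``control`` must be sorted ascending with >= 5 points.  When the
    absolute gradient is uniform within ``flatness_tolerance`` (relative
    spread), no localized transition is reported (e.g. a linear ramp).
    """
    x = np.asarray(control, dtype=float)
    y = np.asarray(means, dtype=float)
    if len(x) < 5 or len(x) != len(y):
        raise ConfigurationError("need >= 5 sorted control points with means")
    if np.any(np.diff(x) <= 0):
        raise ConfigurationError("control values must be strictly increasing")
    if smoothing_window > 1:
        y = running_average(y, smoothing_window)
    grad = np.abs(np.gradient(y, x))
    gmax = grad.max()
    if gmax == 0 or (gmax - grad.min()) / gmax < flatness_tolerance:
        return TransitionScanResult(metric=metric, location=None, gradient=grad)
    return TransitionScanResult(
        metric=metric, location=float(x[int(np.argmax(grad))]), gradient=grad
    )
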