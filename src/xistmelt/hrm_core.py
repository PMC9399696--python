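"""Core high-resolution melt (HRM) transforms.

Turns raw melt traces into the three standard HRM constructions:

1. the negative-derivative trace −dF/dT, whose local maxima are amplicon
   melting temperatures (Tm);
2. the normalized melt curve — fluorescence rescaled between a fitted
   pre-melt baseline (≈1) and post-melt baseline (≈0) over an analysis
   window;
3. the difference curve — each normalized curve minus a "typical"
   reference curve, chosen automatically as the plate medoid.

A female duplex well shows two transitions (XIST ~84 °C, ACTB ~85.5 °C) and
a pronounced negative excursion in its difference curve against a male
reference near the XIST Tm; a male well shows a single smooth transition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .plate_io import MeltCurve

__all__ = [
    "NormalizedCurve",
    "DifferenceCurve",
    "MeltPeaks",
    "DegenerateBaselineError",
    "negative_derivative",
    "estimate_tms",
    "normalize_curve",
    "normalized_full_grid",
    "baseline_fits",
    "melt_amplitude",
    "select_reference",
    "difference_curve",
    "curve_distance",
]

DEFAULT_PRE_WINDOW = (80.0, 82.5)
DEFAULT_POST_WINDOW = (88.0, 92.0)


class DegenerateBaselineError(ValueError):
    """Pre- and post-melt baselines do not bracket a positive melt amplitude
    (flat or non-amplified well)."""


@dataclass(frozen=True)
class NormalizedCurve:
    """A melt curve rescaled to [0, 1] on the analysis window."""

    well_id: str
    temperatures: np.ndarray
    values: np.ndarray
    pre_window: tuple[float, float]
    post_window: tuple[float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "temperatures", np.asarray(self.temperatures, float))
        object.__setattr__(self, "values", np.asarray(self.values, float))


@dataclass(frozen=True)
class DifferenceCurve:
    """Pointwise difference of a normalized curve against the reference."""

    well_id: str
    reference_well_id: str
    temperatures: np.ndarray
    values: np.ndarray


@dataclass(frozen=True)
class MeltPeaks:
    """Derivative-peak melting temperatures for one well.

    ``peaks`` is a tuple of (tm °C, prominence) sorted by temperature.
    """

    well_id: str
    peaks: tuple[tuple[float, float], ...]

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def primary_tm(self) -> float | None:
        """Tm of the highest-prominence peak, or None if no peaks."""
        if not self.peaks:
            return None
        return max(self.peaks, key=lambda p: p[1])[0]


def negative_derivative(
    curve: MeltCurve, window: int = 5, polyorder: int = 3
) -> np.ndarray:
    """−dF/dT via a Savitzky–Golay local-polynomial first derivative.

    Window of 5 points with a cubic local fit is the lightest smoothing
    that still resolves the two duplex transitions (1.5 °C apart, ~0.25 °C
    wide) on a 0.5 °C grid — a quadratic over the same window blurs them
    into one shoulder. Output length matches the temperature grid.
    """
    if len(curve) < window:
        raise ValueError(
            f"well {curve.well_id!r}: curve shorter than smoothing window ({window})"
        )
    dfdt = savgol_filter(curve.rfu, window, polyorder, deriv=1, delta=curve.step)
    return -dfdt


def estimate_tms(
    temperatures: np.ndarray,
    derivative: np.ndarray,
    min_prominence: float,
    min_separation: float = 1.0,
    well_id: str = "",
) -> MeltPeaks:
    """Locate melt transitions as prominent maxima of a −dF/dT trace.

    ``min_prominence`` is an absolute prominence floor (the pipeline passes
    a fraction — default 10% — of the run-wide derivative maximum, so flat
    wells and noise wiggles yield no peaks).
    Peaks closer than ``min_separation`` °C collapse to the stronger one.
    Each retained peak is refined by quadratic interpolation through its
    three nearest grid points. An empty peak list signals a flat or
    non-amplified well.
    """
    temperatures = np.asarray(temperatures, float)
    derivative = np.asarray(derivative, float)
    if temperatures.size != derivative.size:
        raise ValueError("temperature grid and derivative trace differ in length")
    step = float(temperatures[1] - temperatures[0])
    distance = max(1, int(round(min_separation / step)))
    idx, props = find_peaks(derivative, prominence=min_prominence, distance=distance)
    peaks = []
    for i, prom in zip(idx, props["prominences"]):
        tm = float(temperatures[i])
        if 0 < i < temperatures.size - 1:
            y0, y1, y2 = derivative[i - 1 : i + 2]
            denom = y0 - 2.0 * y1 + y2
            if denom < 0:  # concave — vertex of the fitted parabola
                tm += 0.5 * step * (y0 - y2) / denom
        peaks.append((tm, float(prom)))
    peaks.sort(key=lambda p: p[0])
    return MeltPeaks(well_id=well_id, peaks=tuple(peaks))


def _window_mask(grid: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    low, high = window
    if low >= high:
        raise ValueError(f"window {window} must satisfy low < high")
    return (grid >= low - 1e-9) & (grid <= high + 1e-9)


def baseline_fits(
    curve: MeltCurve,
    pre_window: tuple[float, float] = DEFAULT_PRE_WINDOW,
    post_window: tuple[float, float] = DEFAULT_POST_WINDOW,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit linear pre-melt (upper) and post-melt (lower) baselines.

    Returns (U, L) evaluated on the curve's full grid.
    """
    grid = curve.temperatures
    pre_mask = _window_mask(grid, pre_window)
    post_mask = _window_mask(grid, post_window)
    for name, mask in (("pre", pre_mask), ("post", post_mask)):
        if mask.sum() < 3:
            raise ValueError(
                f"well {curve.well_id!r}: {name}-melt window covers "
                f"{int(mask.sum())} grid points; at least 3 required"
            )
    if pre_window[1] > post_window[0]:
        raise ValueError("pre-melt window must lie below the post-melt window")
    upper = np.polyval(np.polyfit(grid[pre_mask], curve.rfu[pre_mask], 1), grid)
    lower = np.polyval(np.polyfit(grid[post_mask], curve.rfu[post_mask], 1), grid)
    return upper, lower


def melt_amplitude(
    curve: MeltCurve,
    pre_window: tuple[float, float] = DEFAULT_PRE_WINDOW,
    post_window: tuple[float, float] = DEFAULT_POST_WINDOW,
) -> float:
    """Relative melt amplitude: mean(U − L) / mean(U) on the analysis window.

    Near zero for flat (non-amplified) wells, order 0.5–1 for wells whose
    products actually melt between the windows.
    """
    upper, lower = baseline_fits(curve, pre_window, post_window)
    mask = _window_mask(curve.temperatures, (pre_window[1], post_window[0]))
    u = float(np.mean(upper[mask]))
    if u == 0:
        return 0.0
    return float(np.mean(upper[mask] - lower[mask]) / abs(u))


def normalized_full_grid(
    curve: MeltCurve,
    pre_window: tuple[float, float] = DEFAULT_PRE_WINDOW,
    post_window: tuple[float, float] = DEFAULT_POST_WINDOW,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized fluorescence on the curve's full grid (clipped to [0, 1]).

    value(T) = (RFU(T) − L(T)) / (U(T) − L(T)) with U/L the fitted pre- and
    post-melt baselines. Raises :class:`DegenerateBaselineError` when the
    baselines fail to enclose a positive amplitude anywhere on the analysis
    window.
    """
    upper, lower = baseline_fits(curve, pre_window, post_window)
    denom = upper - lower
    mask = _window_mask(curve.temperatures, (pre_window[1], post_window[0]))
    if np.any(denom[mask] <= 0):
        raise DegenerateBaselineError(
            f"well {curve.well_id!r}: pre/post baselines cross inside the "
            f"analysis window (flat or non-amplified well)"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(denom != 0, (curve.rfu - lower) / denom, 0.0)
    return curve.temperatures, np.clip(values, 0.0, 1.0)


def normalize_curve(
    curve: MeltCurve,
    pre_window: tuple[float, float] = DEFAULT_PRE_WINDOW,
    post_window: tuple[float, float] = DEFAULT_POST_WINDOW,
) -> NormalizedCurve:
    """Normalize a melt curve between fitted baselines on the analysis window.

    The analysis window spans [pre_window high, post_window low]; values are
    clipped to [0, 1].
    """
    grid, values = normalized_full_grid(curve, pre_window, post_window)
    mask = _window_mask(grid, (pre_window[1], post_window[0]))
    return NormalizedCurve(
        well_id=curve.well_id,
        temperatures=grid[mask],
        values=values[mask],
        pre_window=(float(pre_window[0]), float(pre_window[1])),
        post_window=(float(post_window[0]), float(post_window[1])),
    )


def curve_distance(a: NormalizedCurve, b: NormalizedCurve) -> float:
    """Maximum absolute pointwise difference between two normalized curves.

    This is the shape metric driving both reference selection and
    clustering; it is 0 for identical curves and bounded by 1.
    """
    if a.temperatures.size != b.temperatures.size or not np.allclose(
        a.temperatures, b.temperatures, atol=1e-9
    ):
        raise ValueError(
            f"wells {a.well_id!r} and {b.well_id!r} are on different analysis grids"
        )
    return float(np.max(np.abs(a.values - b.values)))


def select_reference(curves: Sequence[NormalizedCurve]) -> str:
    """Automatically pick the "typical" curve: the shape medoid.

    Returns the well id minimizing summed shape distance to all other
    curves; ties break lexicographically on well id. With a majority of
    male-like wells on a plate the medoid lands in the male group, matching
    the instrument software's automatic reference choice.
    """
    if not curves:
        raise ValueError("cannot select a reference from an empty set of curves")
    ordered = sorted(curves, key=lambda c: c.well_id)
    n = len(ordered)
    totals = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            d = curve_distance(ordered[i], ordered[j])
            totals[i] += d
            totals[j] += d
    return ordered[int(np.argmin(totals))].well_id


def difference_curve(
    normalized: NormalizedCurve, reference: NormalizedCurve
) -> DifferenceCurve:
    """Subtract the reference curve from a well's normalized curve."""
    if normalized.temperatures.size != reference.temperatures.size or not np.allclose(
        normalized.temperatures, reference.temperatures, atol=1e-9
    ):
        raise ValueError(
            f"well {normalized.well_id!r} and reference "
            f"{reference.well_id!r} are on different analysis grids"
        )
    return DifferenceCurve(
        well_id=normalized.well_id,
        reference_well_id=reference.well_id,
        temperatures=normalized.temperatures.copy(),
        values=normalized.values - reference.values,
    )
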