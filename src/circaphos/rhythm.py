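"""Free-running circadian period estimation from luminescence traces.

The estimator is a Fourier-component fit: after removing a linear baseline by
least squares, a damped cosine (optionally with higher harmonics) is fitted
by nonlinear least squares, with the period initialized on a grid across the
search window and the best fit selected by residual RMS. Rhythmicity is
scored by the relative amplitude error (RAE), the standard error of the
fitted amplitude divided by the amplitude; traces whose RAE exceeds the
threshold are flagged non-rhythmic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class LuminescenceTrace:
    times: np.ndarray  # hours, strictly increasing
    values: np.ndarray
    well_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if len(self.times) < 4:
            raise ValueError("trace too short")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def span_h(self) -> float:
        return float(self.times[-1] - self.times[0])


def traces_from_frame(df: pd.DataFrame, metadata: Mapping[str, str] | None = None) -> list[LuminescenceTrace]:
    """Split a plate table (column ``time_h`` + one column per well) into traces."""
    if "time_h" not in df.columns:
        raise ValueError("trace table needs a time_h column")
    t = df["time_h"].to_numpy(dtype=float)
    metadata = metadata or {}
    return [
        LuminescenceTrace(t, df[c].to_numpy(dtype=float), well_id=c, condition=metadata.get(c, ""))
        for c in df.columns
        if c != "time_h"
    ]


@dataclass(frozen=True)
class PeriodEstimate:
    period_h: float
    amplitude: float
    phase_h: float
    damping_rate: float
    rae: float
    rhythmic: bool
    residual_rms: float
    well_id: str = ""
    condition: str = ""


def _damped_cosine(t, amplitude, period, phase, damping):
    return amplitude * np.exp(-damping * t) * np.cos(2 * np.pi * (t - phase) / period)


def _model(t, baseline, slope, amplitude, period, phase, damping):
    """Linear baseline plus damped cosine, fitted jointly.

    The baseline is estimated simultaneously with the oscillation: on a
    finite sampling grid a cosine is not orthogonal to a linear trend, so
    detrending first and fitting afterwards leaves a small period bias even
    on noiseless data.
    """
    return baseline + slope * t + _damped_cosine(t, amplitude, period, phase, damping)


def fit_period(
    trace: LuminescenceTrace,
    search_window: tuple[float, float] = (18.0, 34.0),
    n_harmonics: int = 1,
    rae_threshold: float = 0.6,
    grid_step_h: float = 0.5,
) -> PeriodEstimate:
    """Estimate the free-running period of one trace.

    The search window must be positive and within the data span (at least
    two full cycles of the longest candidate period are required by the
    generator contract; the fit itself only requires the window to fit once).
    """
    lo, hi = search_window
    if not 0 < lo < hi:
        raise ValueError("search window must satisfy 0 < low < high")
    if trace.span_h < hi:
        raise ValueError(
            f"data span {trace.span_h:.1f} h shorter than the search window upper bound {hi} h"
        )

    t = trace.times - trace.times[0]
    yv = trace.values
    slope0, intercept0 = np.polyfit(t, yv, 1)
    y0 = yv - (intercept0 + slope0 * t)

    amp0 = float(np.std(y0) * math.sqrt(2.0))
    if amp0 == 0.0:
        amp0 = 1e-12
    bounds = (
        [-np.inf, -np.inf, 0.0, lo, -np.inf, 0.0],
        [np.inf, np.inf, np.inf, hi, np.inf, 1.0],
    )

    best = None
    for tau0 in np.arange(lo, hi + 1e-9, grid_step_h):
        # phase initialization from the cosine/sine correlation at tau0
        w = 2 * np.pi / tau0
        c = float(np.dot(y0, np.cos(w * t)))
        s = float(np.dot(y0, np.sin(w * t)))
        phase0 = math.atan2(s, c) / w
        try:
            popt, pcov = optimize.curve_fit(
                _model,
                t,
                yv,
                p0=[intercept0, slope0, amp0, tau0, phase0, 0.001],
                bounds=bounds,
                maxfev=2000,
            )
        except RuntimeError:
            continue
        resid = yv - _model(t, *popt)
        rms = float(np.sqrt(np.mean(resid**2)))
        if best is None or rms < best[0]:
            best = (rms, popt, pcov)

    if best is None:
        return PeriodEstimate(
            math.nan, math.nan, math.nan, math.nan, math.inf, False, math.nan,
            trace.well_id, trace.condition,
        )

    rms, popt, pcov = best
    _, _, amplitude, period, phase, damping = (float(v) for v in popt)

    if n_harmonics > 1:
        # add harmonic cos/sin components linearly at the fitted fundamental
        resid = yv - _model(t, *popt)
        cols = []
        for k in range(2, n_harmonics + 1):
            wk = 2 * np.pi * k / period
            env = np.exp(-damping * t)
            cols.extend([env * np.cos(wk * t), env * np.sin(wk * t)])
        X = np.column_stack(cols)
        coef, *_ = np.linalg.lstsq(X, resid, rcond=None)
        resid = resid - X @ coef
        rms = float(np.sqrt(np.mean(resid**2)))

    amp_se = float(np.sqrt(max(pcov[2, 2], 0.0))) if np.all(np.isfinite(pcov)) else math.inf
    rae = amp_se / amplitude if amplitude > 0 else math.inf
    phase = float(phase % period)
    return PeriodEstimate(
        period_h=period,
        amplitude=amplitude,
        phase_h=phase,
        damping_rate=damping,
        rae=rae,
        rhythmic=bool(rae <= rae_threshold),
        residual_rms=rms,
        well_id=trace.well_id,
        condition=trace.condition,
    )


def fit_periods(traces: Sequence[LuminescenceTrace], **kwargs) -> list[PeriodEstimate]:
    return [fit_period(tr, **kwargs) for tr in traces]


def compare_periods(
    periods_parent: Sequence[float | PeriodEstimate],
    periods_line: Sequence[float | PeriodEstimate],
) -> tuple[float, float]:
    """Mean period difference (line - parent) and two-tailed t-test p-value."""

    def _vals(xs):
        return np.array(
            [x.period_h if isinstance(x, PeriodEstimate) else float(x) for x in xs]
        )

    a, b = _vals(periods_parent), _vals(periods_line)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 period estimates per group")
    delta = float(b.mean() - a.mean())
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    else:
        p = float(stats.ttest_ind(b, a, equal_var=True).pvalue)
    return delta, p


@dataclass(frozen=True)
class DoseResponsePoint:
    dose: float
    mean_delta_period_h: float
    sd: float
    n: int


def dose_response_curve(
    periods_by_dose: Mapping[float, Sequence[float | PeriodEstimate]],
    vehicle: Sequence[float | PeriodEstimate],
) -> list[DoseResponsePoint]:
    """Period lengthening per inhibitor dose relative to the matched vehicle.

    Each trace's period is differenced against the vehicle mean; the vehicle
    itself appears as the dose-0 point with zero mean shift by construction.
    No parametric dose-response curve is fitted.
    """

    def _vals(xs):
        return np.array(
            [x.period_h if isinstance(x, PeriodEstimate) else float(x) for x in xs]
        )

    veh = _vals(vehicle)
    if len(veh) < 1:
        raise ValueError("vehicle group must be non-empty")
    veh_mean = float(veh.mean())
    points = [
        DoseResponsePoint(
            0.0,
            0.0,
            float(veh.std(ddof=1)) if len(veh) > 1 else 0.0,
            len(veh),
        )
    ]
    for dose in sorted(periods_by_dose):
        if dose == 0.0:
            continue
        vals = _vals(periods_by_dose[dose]) - veh_mean
        points.append(
            DoseResponsePoint(
                float(dose),
                float(vals.mean()),
                float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                len(vals),
            )
        )
    return points


def periods_to_tsv(estimates: Sequence[PeriodEstimate], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "well_id": e.well_id,
                "condition": e.condition,
                "period_h": e.period_h,
                "amplitude": e.amplitude,
                "phase_h": e.phase_h,
                "damping_rate": e.damping_rate,
                "rae": e.rae,
                "rhythmic": e.rhythmic,
                "residual_rms": e.residual_rms,
            }
            for e in estimates
        ]
    ).to_csv(path, sep="\t", index=False)
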