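"""Shared signal primitives for current and fluorescence traces.

Uniformly sampled time series, zero-phase smoothing filters specified by
their -3 dB corner frequency, exponential/affine kinetic fits, per-event
amplitude/charge/width measures and robust baseline-noise estimation.

Conventions: internal time unit is seconds; currents are stored signed
(inward currents negative), summary magnitudes are reported positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, signal


class Units(str, Enum):
    AMPERE = "ampere"
    DFF = "dff"
    ARBITRARY = "arbitrary"


@dataclass
class TimeSeries:
    """A uniformly sampled signal.

    Parameters
    ----------
    t0 : float
        Time of the first sample, seconds.
    dt : float
        Sampling interval, seconds.
    values : np.ndarray
        Ordered samples; amperes for current, dimensionless for dF/F.
    label : str
        Free-text description.
    units : Units
        Physical units of ``values``.
    """

    t0: float
    dt: float
    values: np.ndarray
    label: str = ""
    units: Units = Units.ARBITRARY

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("values must be a 1-D array of length >= 2")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must all be finite")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.dt

    @property
    def t_end(self) -> float:
        return self.t0 + (self.n - 1) * self.dt

    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    def index_at(self, t: float) -> int:
        """Nearest sample index for time ``t`` (clipped to the trace)."""
        return int(np.clip(round((t - self.t0) / self.dt), 0, self.n - 1))

    def slice(self, t_start: float, t_end: float) -> "TimeSeries":
        i0 = self.index_at(t_start)
        i1 = self.index_at(t_end)
        if i1 <= i0:
            raise ValueError("empty slice window")
        return TimeSeries(
            t0=self.t0 + i0 * self.dt,
            dt=self.dt,
            values=self.values[i0 : i1 + 1].copy(),
            label=self.label,
            units=self.units,
        )

    def copy_with(self, values: np.ndarray, label: Optional[str] = None) -> "TimeSeries":
        return TimeSeries(
            t0=self.t0,
            dt=self.dt,
            values=np.asarray(values, dtype=float),
            label=self.label if label is None else label,
            units=self.units,
        )


@dataclass
class ExpFit:
    """Single-exponential decay fit A*exp(-(t - t_start)/tau) + offset."""

    amplitude: float
    tau: float
    offset: float
    rmse: float
    window: Tuple[float, float]
    converged: bool = True
    message: str = ""
    upper_bound: bool = False  # tau from a train decay only bounds the true value

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.amplitude * np.exp(-(t - self.window[0]) / self.tau) + self.offset


@dataclass
class AffineFit:
    """Straight-line fit over a time window (used for event rising phases)."""

    slope: float
    intercept: float
    window: Tuple[float, float]


@dataclass
class EventMeasures:
    amplitude: float
    charge: float
    fwhm: float
    rise_slope: float


# --------------------------------------------------------------------------
# filters
# --------------------------------------------------------------------------

def gaussian_sigma_from_corner(f_c: float) -> float:
    """Time-domain sigma of a Gaussian whose amplitude response is -3 dB at f_c.

    |H(f)| = exp(-2 pi^2 sigma^2 f^2) = 1/sqrt(2) at f = f_c
    => sigma = sqrt(ln 2) / (2 pi f_c).
    """
    return math.sqrt(math.log(2.0)) / (2.0 * math.pi * f_c)


def _check_corner(ts: TimeSeries, f_c: float) -> None:
    nyquist = 0.5 / ts.dt
    if not (0 < f_c < nyquist):
        raise ValueError(
            f"corner frequency {f_c:g} Hz outside (0, Nyquist = {nyquist:g} Hz)"
        )


def gaussian_filter_corner(ts: TimeSeries, f_c: float) -> TimeSeries:
    """Zero-phase Gaussian smoothing with -3 dB amplitude at ``f_c``.

    Reflective edge handling; length preserved.
    """
    _check_corner(ts, f_c)
    sigma_samples = gaussian_sigma_from_corner(f_c) / ts.dt
    out = ndimage.gaussian_filter1d(ts.values, sigma_samples, mode="reflect")
    return ts.copy_with(out)


def binomial_pass_count(f_c: float, dt: float) -> int:
    """Number of [1,2,1]/4 passes with combined -3 dB response at f_c.

    One pass has amplitude response cos^2(pi f dt); n passes reach 1/sqrt(2)
    at f_c when n = ln(2^-1/2) / (2 ln cos(pi f_c dt)); at least one pass.
    """
    c = math.cos(math.pi * f_c * dt)
    if c <= 0:
        return 1
    n = math.log(2 ** (-0.5)) / (2.0 * math.log(c))
    return max(1, round(n))


def binomial_filter_corner(ts: TimeSeries, f_c: float) -> TimeSeries:
    """Iterated [1,2,1]/4 smoothing with -3 dB corner at ``f_c``."""
    _check_corner(ts, f_c)
    n_pass = binomial_pass_count(f_c, ts.dt)
    kernel = np.array([0.25, 0.5, 0.25])
    out = ts.values
    for _ in range(n_pass):
        out = np.convolve(np.pad(out, 1, mode="reflect"), kernel, mode="valid")
    return ts.copy_with(out)


# --------------------------------------------------------------------------
# fits
# --------------------------------------------------------------------------

def _window_slice(ts: TimeSeries, window: Tuple[float, float]) -> slice:
    i0 = ts.index_at(window[0])
    i1 = ts.index_at(window[1])
    return slice(i0, i1 + 1)


def fit_exp_decay(
    ts: TimeSeries,
    window: Tuple[float, float],
    max_iter: int = 200,
    tol: float = 1e-8,
) -> ExpFit:
    """Least-squares fit of A*exp(-(t-t_start)/tau) + offset over ``window``.

    Log-linear initialization followed by nonlinear least squares. A failed
    fit is returned flagged (``converged=False``), never as silent NaN.
    """
    sl = _window_slice(ts, window)
    y = ts.values[sl]
    if y.size < 5:
        raise ValueError("decay window must contain at least 5 samples")
    t = np.arange(y.size) * ts.dt

    offset0 = float(y[-1])
    amp0 = float(y[0] - offset0)
    if amp0 == 0.0:
        amp0 = float(np.ptp(y)) or 1.0
    # log-linear init on the offset-subtracted magnitude
    z = (y - offset0) / amp0
    pos = z > 1e-12
    if pos.sum() >= 2:
        slope, _ = np.polyfit(t[pos], np.log(z[pos]), 1)
        tau0 = -1.0 / slope if slope < 0 else (t[-1] - t[0]) / 2 or ts.dt
    else:
        tau0 = (t[-1] - t[0]) / 2 or ts.dt
    tau0 = float(np.clip(tau0, ts.dt * 0.5, 100 * (t[-1] + ts.dt)))

    def model(p: np.ndarray) -> np.ndarray:
        a, log_tau, c = p
        return a * np.exp(-t / np.exp(log_tau)) + c

    def resid(p: np.ndarray) -> np.ndarray:
        return model(p) - y

    p0 = np.array([amp0, math.log(tau0), offset0])
    try:
        res = optimize.least_squares(
            resid, p0, method="lm", xtol=tol, ftol=tol, max_nfev=max_iter * 4
        )
        a, log_tau, c = res.x
        tau = float(np.exp(log_tau))
        rmse = float(np.sqrt(np.mean(res.fun**2)))
        converged = bool(res.success) and np.isfinite(rmse)
        message = "" if converged else f"least_squares: {res.message}"
    except Exception as exc:  # pragma: no cover - defensive
        a, tau, c, rmse = amp0, tau0, offset0, float("inf")
        converged, message = False, str(exc)

    t_start = ts.t0 + sl.start * ts.dt
    t_stop = ts.t0 + (sl.stop - 1) * ts.dt
    return ExpFit(
        amplitude=float(a),
        tau=tau,
        offset=float(c),
        rmse=rmse,
        window=(t_start, t_stop),
        converged=converged,
        message=message,
    )


def fit_affine(ts: TimeSeries, window: Tuple[float, float]) -> AffineFit:
    """Ordinary least-squares line over ``window`` (absolute time axis)."""
    sl = _window_slice(ts, window)
    y = ts.values[sl]
    if y.size < 2:
        raise ValueError("affine window must contain at least 2 samples")
    t = ts.t0 + ts.dt * np.arange(sl.start, sl.stop)
    slope, intercept = np.polyfit(t, y, 1)
    return AffineFit(
        slope=float(slope),
        intercept=float(intercept),
        window=(float(t[0]), float(t[-1])),
    )


# --------------------------------------------------------------------------
# event measures and noise
# --------------------------------------------------------------------------

def event_measures(
    ts: TimeSeries,
    onset: float,
    end: float,
    baseline: Optional[float] = None,
) -> EventMeasures:
    """Amplitude, charge, FWHM and rise slope of one event window.

    Amplitude is the maximum absolute deviation from the local baseline
    (the sample at onset unless ``baseline`` is given); charge is the
    time-integral of the baseline-subtracted signal over [onset, end];
    FWHM is the total time the deviation exceeds half its maximum. All
    three are reported as positive magnitudes regardless of polarity.

    Quantal events rise faster than one sample at 40 kHz; when the sample
    before the peak is still below half-maximum the rise is treated as a
    jump at the peak sample (no interpolated ramp), which removes the
    half-sample bias a trapezoid across the jump would add to both the
    charge and the width.
    """
    if not (ts.t0 <= onset < end <= ts.t_end + ts.dt / 2):
        raise ValueError("event window must lie within the trace")
    i0 = ts.index_at(onset)
    i1 = ts.index_at(end)
    if i1 - i0 < 2:
        raise ValueError("event window shorter than 3 samples")
    seg = ts.values[i0 : i1 + 1]
    base = float(seg[0]) if baseline is None else float(baseline)
    dev = seg - base
    ipk = int(np.argmax(np.abs(dev)))
    amplitude = float(abs(dev[ipk]))
    if amplitude == 0.0:
        return EventMeasures(0.0, 0.0, 0.0, 0.0)
    mag = np.abs(dev)
    half = amplitude / 2.0

    signed_charge = float(np.trapezoid(dev, dx=ts.dt))
    jump_rise = ipk >= 1 and mag[ipk - 1] < half
    if jump_rise:
        # rise within one sample: the pre-peak interval sat at baseline
        signed_charge += 0.5 * (dev[ipk - 1] - dev[ipk]) * ts.dt
    charge = float(abs(signed_charge))

    # FWHM: total dwell time above half-maximal deviation, with linear
    # interpolation at the crossings of each suprathreshold run.
    above = mag >= half
    fwhm = 0.0
    runs = np.flatnonzero(np.diff(above.astype(int)))
    edges = np.concatenate(([0], runs + 1, [above.size]))
    for a, b in zip(edges[:-1], edges[1:]):
        if not above[a]:
            continue
        width = (b - a) * ts.dt
        # refine both run edges by interpolating the half crossing
        if a == ipk and jump_rise:
            width -= ts.dt  # crossing coincides with the jump at the peak sample
        elif a > 0:
            frac = (mag[a] - half) / (mag[a] - mag[a - 1])
            width += frac * ts.dt - ts.dt
        if b < above.size:
            frac = (mag[b - 1] - half) / (mag[b - 1] - mag[b])
            width += frac * ts.dt
        fwhm += max(width, 0.0)

    # 10-90% rise slope on the rising limb, signed like the raw deflection
    rise_slope = 0.0
    lo, hi = 0.1 * amplitude, 0.9 * amplitude
    limb = mag[: ipk + 1]
    idx = np.flatnonzero((limb >= lo) & (limb <= hi))
    if idx.size >= 2:
        tt = idx * ts.dt
        rise_slope = float(np.polyfit(tt, dev[idx], 1)[0])
    elif ipk >= 1:
        rise_slope = float(dev[ipk] / (ipk * ts.dt))
    return EventMeasures(amplitude, charge, float(fwhm), rise_slope)


def rms_noise(ts: TimeSeries, window: Optional[Tuple[float, float]] = None) -> float:
    """Robust baseline noise sigma: 1.4826 x MAD of the detrended window.

    The MAD estimator is used instead of the raw rms because analysis
    windows may contain events; it is consistent for Gaussian noise.
    """
    if window is None:
        y = ts.values
    else:
        sl = _window_slice(ts, window)
        y = ts.values[sl]
    if y.size < 10:
        raise ValueError("noise window must contain at least 10 samples")
    detrended = signal.detrend(y, type="linear")
    mad = float(np.median(np.abs(detrended - np.median(detrended))))
    return 1.4826 * mad


# --------------------------------------------------------------------------
# trace CSV dialect
# --------------------------------------------------------------------------

_UNIFORMITY_PPM = 1e-6


def read_trace_csv(path, units: Units = Units.ARBITRARY, label: str = "") -> TimeSeries:
    """Read a two-column ``time_s,value`` CSV and validate uniform sampling.

    Sampling is accepted as uniform when every interval agrees with the
    mean interval to 1 ppm.
    """
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["time_s", "value"]:
        raise ValueError("trace CSV must have columns 'time_s,value'")
    t = df["time_s"].to_numpy(dtype=float)
    v = df["value"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("trace must contain at least 2 samples")
    dts = np.diff(t)
    dt = float(np.mean(dts))
    if np.any(np.abs(dts - dt) > _UNIFORMITY_PPM * dt):
        raise ValueError("non-uniform sampling (tolerance 1 ppm)")
    return TimeSeries(t0=float(t[0]), dt=dt, values=v, label=label or str(path), units=units)


def write_trace_csv(ts: TimeSeries, path) -> None:
    df = pd.DataFrame({"time_s": ts.times(), "value": ts.values})
    df.to_csv(path, index=False)
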