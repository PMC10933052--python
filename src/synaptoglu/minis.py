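"""Detection and kinetic characterization of miniature EPSCs.

Candidate quantal events are found by a dual criterion on a smoothed
current trace and its smoothed derivative, both thresholded at a multiple
of the robust baseline noise; each accepted event is then characterized by
an affine fit to its rising phase, a single-exponential fit to its decay,
and amplitude/charge/width measures. Acceptance rules replace the manual
inspection step of bench practice with explicit, reproducible criteria.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .core import (
    TimeSeries,
    Units,
    binomial_filter_corner,
    event_measures,
    fit_exp_decay,
    gaussian_filter_corner,
    rms_noise,
)

EVENT_COLUMNS = [
    "onset", "peak_time", "amplitude", "charge",
    "tau_decay", "fwhm", "rise_slope", "accepted", "fit_failed",
]

# detection geometry (seconds)
COINCIDENCE_WINDOW = 0.5e-3   # trace and derivative criteria must co-occur
MERGE_DISTANCE = 1.0e-3       # candidates closer than this are one event
DECAY_FIT_SPAN = 1.5e-3       # decay-fit window after the peak
CHARGE_TAU_CAP = 5.0          # integrate charge to onset + cap * tau


def empty_event_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=float) for c in EVENT_COLUMNS}).astype(
        {"accepted": bool, "fit_failed": bool}
    )


def _jump_peak_attenuation(tau: float, dt: float, n_pass: int) -> float:
    """Measured-over-true peak ratio for an unresolved (sub-sample) rise.

    A quantal current rising faster than one sample at 40 kHz appears in
    the binomially smoothed trace with its peak attenuated twice: by the
    smoothing kernel acting on the jump and by the random sub-sample
    phase of the onset (half a sample in the median). The ratio is
    computed numerically by smoothing a half-sample-phase template.
    """
    k = np.arange(64)
    template = np.concatenate([np.zeros(4), np.exp(-(k + 0.5) * dt / tau)])
    kernel = np.array([0.25, 0.5, 0.25])
    for _ in range(n_pass):
        template = np.convolve(np.pad(template, 1, mode="edge"), kernel, mode="valid")
    return float(template.max())


def detect_minis(
    ts: TimeSeries,
    threshold_sigma: float = 5.0,
    amplitude_correction: bool = True,
) -> pd.DataFrame:
    """Detect spontaneous quantal currents in a voltage-clamp trace.

    Pipeline: binomial smoothing (8 kHz corner); candidate peaks where the
    2 kHz Gaussian-filtered trace deviates by at least ``threshold_sigma``
    times its robust noise AND the 4 kHz Gaussian-filtered derivative does
    so within +-0.5 ms; candidates closer than 1 ms merged keeping the
    larger. Each surviving candidate is kinetically characterized and
    flagged accepted unless its rise-slope sign is inconsistent with an
    inward current or its width is below two samples.

    ``amplitude_correction`` (default on) divides each amplitude by the
    closed-form peak attenuation the smoothing filter and sub-sample
    onset phase impose on an event whose rise is unresolved at the
    sampling rate, as holds for quantal currents at 40 kHz; disable it
    for events with resolved rising phases.
    """
    if ts.units != Units.AMPERE:
        raise ValueError("mEPSC detection expects a current trace in amperes")
    smooth = binomial_filter_corner(ts, 8_000.0)
    trace_f = gaussian_filter_corner(smooth, 2_000.0)
    deriv = np.gradient(trace_f.values, ts.dt)
    deriv_f = gaussian_filter_corner(trace_f.copy_with(deriv), 4_000.0)

    sigma_trace = rms_noise(trace_f)
    sigma_deriv = rms_noise(deriv_f)
    if sigma_trace == 0.0:
        # noiseless traces: fall back to a floor well below one quantum
        sigma_trace = max(np.max(np.abs(trace_f.values)) * 1e-3, 1e-15)
        sigma_deriv = max(np.max(np.abs(deriv_f.values)) * 1e-3, 1e-12)

    min_dist = max(1, int(round(MERGE_DISTANCE / ts.dt)))
    peaks, _ = _signal.find_peaks(
        -trace_f.values, height=threshold_sigma * sigma_trace, distance=min_dist
    )
    win = max(1, int(round(COINCIDENCE_WINDOW / ts.dt)))
    dmag = np.abs(deriv_f.values)
    keep = []
    for p in peaks:
        lo, hi = max(0, p - win), min(ts.n, p + win + 1)
        if np.max(dmag[lo:hi]) >= threshold_sigma * sigma_deriv:
            keep.append(p)

    rows = []
    for j, p in enumerate(keep):
        next_peak = keep[j + 1] if j + 1 < len(keep) else ts.n
        row = _characterize_event(smooth, trace_f, p, next_peak, sigma_trace,
                                  amplitude_correction=amplitude_correction)
        if row is not None:
            rows.append(row)
    if not rows:
        return empty_event_table()
    table = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return table.sort_values("onset", ignore_index=True)


def _find_onset(values: np.ndarray, peak: int, dt: float, sigma: float) -> int:
    """Walk back from the peak to the start of the deflection."""
    amp = abs(values[peak])
    floor = max(0.1 * amp, 2.0 * sigma)
    limit = max(0, peak - int(round(2e-3 / dt)))
    i = peak
    while i > limit and abs(values[i - 1]) > floor and abs(values[i - 1]) < abs(values[i]) + 3 * sigma:
        i -= 1
    return i


def _characterize_event(
    smooth: TimeSeries,
    trace_f: TimeSeries,
    peak: int,
    next_peak: int,
    sigma: float,
    amplitude_correction: bool = True,
) -> Optional[dict]:
    dt = smooth.dt
    onset_idx = _find_onset(trace_f.values, peak, dt, sigma)
    onset = smooth.t0 + onset_idx * dt
    peak_time = smooth.t0 + peak * dt

    fit_failed = False
    tau = float("nan")
    fit_end_idx = min(int(peak + round(DECAY_FIT_SPAN / dt)), next_peak - 1, smooth.n - 1)
    if fit_end_idx - peak >= 4:
        fit = fit_exp_decay(smooth, (peak_time, smooth.t0 + fit_end_idx * dt))
        if fit.converged and fit.tau > 0:
            tau = fit.tau
        else:
            fit_failed = True
    else:
        fit_failed = True

    span = CHARGE_TAU_CAP * tau if np.isfinite(tau) else DECAY_FIT_SPAN
    span = min(span, 20e-3)  # guard against runaway decay fits
    end_idx = min(int(peak + round(span / dt)), next_peak - 1, smooth.n - 1)
    if end_idx - onset_idx < 2:
        return None
    base_lo = max(0, onset_idx - int(round(0.5e-3 / dt)))
    baseline = float(np.mean(smooth.values[base_lo : onset_idx + 1]))
    meas = event_measures(
        smooth, onset, smooth.t0 + end_idx * dt, baseline=baseline
    )
    amplitude = meas.amplitude
    if amplitude_correction and np.isfinite(tau) and tau > 0.5 * dt:
        from .core import binomial_pass_count

        n_pass = binomial_pass_count(8_000.0, dt)
        attenuation = _jump_peak_attenuation(tau, dt, n_pass)
        if attenuation > 0.1:  # implausible fits leave the raw measure
            amplitude /= attenuation

    accepted = (
        not fit_failed
        and meas.rise_slope < 0          # inward current grows negative
        and meas.fwhm >= 2 * dt
        and meas.amplitude > 0
    )
    return {
        "onset": onset,
        "peak_time": peak_time,
        "amplitude": amplitude,
        "charge": meas.charge,
        "tau_decay": tau,
        "fwhm": meas.fwhm,
        "rise_slope": meas.rise_slope,
        "accepted": bool(accepted),
        "fit_failed": bool(fit_failed),
    }


def fit_event_kinetics(ts: TimeSeries, row: pd.Series) -> pd.Series:
    """Re-fit one event's kinetics on an arbitrary trace.

    Affine fit over the 10-90% rising limb gives the rise slope; a
    single-exponential fit from the peak gives tau; amplitude, charge and
    width come from the event-measure primitives. A failed fit keeps the
    row and sets ``fit_failed`` rather than raising.
    """
    row = row.copy()
    dt = ts.dt
    peak_idx = ts.index_at(row["peak_time"])
    fit_end = min(peak_idx + int(round(DECAY_FIT_SPAN / dt)), ts.n - 1)
    try:
        if fit_end - peak_idx < 4:
            raise ValueError("event truncated at trace end")
        fit = fit_exp_decay(ts, (row["peak_time"], ts.t0 + fit_end * dt))
        if not fit.converged:
            raise ValueError(fit.message or "decay fit did not converge")
        row["tau_decay"] = fit.tau
        end = min(row["peak_time"] + CHARGE_TAU_CAP * fit.tau, ts.t_end)
        meas = event_measures(ts, row["onset"], end)
        row["amplitude"] = meas.amplitude
        row["charge"] = meas.charge
        row["fwhm"] = meas.fwhm
        row["rise_slope"] = meas.rise_slope
        row["fit_failed"] = False
    except (ValueError, RuntimeError):
        row["fit_failed"] = True
    return row


@dataclass
class CellSummary:
    frequency: float
    median_amplitude: float
    median_charge: float
    median_tau: float
    median_fwhm: float
    mean_waveform: Optional[TimeSeries]
    n_accepted: int
    valid: bool


def summarize_cell(events: pd.DataFrame, ts: TimeSeries,
                   waveform_halfwidth: float = 2e-3) -> CellSummary:
    """Per-cell medians, event frequency and the peak-aligned mean waveform.

    The mean waveform averages all accepted events over a fixed window of
    +-``waveform_halfwidth`` around each peak; events too close to the trace
    edges are skipped for the average but still counted.
    """
    acc = events[events["accepted"]] if len(events) else events
    duration = (ts.n - 1) * ts.dt
    if len(acc) == 0:
        return CellSummary(0.0, float("nan"), float("nan"), float("nan"),
                           float("nan"), None, 0, valid=False)
    freq = len(acc) / duration
    half = int(round(waveform_halfwidth / ts.dt))
    snippets = []
    for t_peak in acc["peak_time"]:
        p = ts.index_at(t_peak)
        if p - half >= 0 and p + half < ts.n:
            snippets.append(ts.values[p - half : p + half + 1])
    wave = None
    if snippets:
        wave = TimeSeries(
            t0=-half * ts.dt, dt=ts.dt,
            values=np.mean(snippets, axis=0),
            label="mean peak-aligned mEPSC", units=ts.units,
        )
    return CellSummary(
        frequency=float(freq),
        median_amplitude=float(acc["amplitude"].median()),
        median_charge=float(acc["charge"].median()),
        median_tau=float(acc["tau_decay"].median()),
        median_fwhm=float(acc["fwhm"].median()),
        mean_waveform=wave,
        n_accepted=int(len(acc)),
        valid=True,
    )
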