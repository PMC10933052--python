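"""Forward model of vesicular glutamate release and its two readouts.

Generates ground-truthed data with the statistical structure the analysis
pipeline assumes: binomial release from a depleting, replenishing vesicle
pool; postsynaptic currents as sums of instant-rise exponential quantal
currents sampled at 40 kHz; reporter fluorescence as the convolution of
the release impulses with a monoexponential indicator kernel, integrated
over 100 Hz camera frames; Poisson spontaneous quantal events; and an
image mode painting a cup-shaped terminal ROI over a noisy background.

Every stochastic routine takes an explicit numpy Generator so that a
fixed seed reproduces outputs bitwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .core import TimeSeries, Units

# Indicator decay constants measured for single stimuli (seconds)
TAU_IGLUSNFR_2MM = 0.03843
TAU_IGLUSNFR_4MM = 0.06866


@dataclass
class StimulusProtocol:
    """Ordered stimulus times defining a train."""

    times: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValueError("protocol needs at least one stimulus time")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("stimulus times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def isi(self) -> float:
        """Inter-stimulus interval of a constant-rate train."""
        if self.n < 2:
            raise ValueError("ISI undefined for a single stimulus")
        d = np.diff(self.times)
        if np.any(np.abs(d - d[0]) > 1e-9 * d[0]):
            raise ValueError("protocol is not a constant-rate train")
        return float(d[0])

    @classmethod
    def regular(cls, n: int, freq_hz: float, start: float = 0.0) -> "StimulusProtocol":
        return cls(
            times=start + np.arange(n) / freq_hz,
            label=f"{n}@{freq_hz:g}Hz",
        )


@dataclass
class PoolModel:
    """Depleting/replenishing readily-releasable pool with binomial release.

    n_rrp      pool capacity, vesicles
    p_r        release probability per vesicle per stimulus
    refill_rate  replenishment, vesicles per second (clipped at capacity)
    quantal_amp  postsynaptic current per vesicle, amperes (magnitude)
    quantal_tau  decay time constant of the quantal current, seconds
    """

    n_rrp: float = 100.0
    p_r: float = 0.3
    refill_rate: float = 400.0
    quantal_amp: float = 127e-12
    quantal_tau: float = 0.33e-3

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_r <= 1.0):
            raise ValueError("p_r must be in [0, 1]")
        if self.n_rrp < 0 or self.refill_rate < 0:
            raise ValueError("pool sizes and rates must be nonnegative")


@dataclass
class KernelModel:
    """Monoexponential glutamate-reporter kernel.

    tau   indicator decay constant, seconds
    s0    dF/F contributed by one released vesicle (n binding sites times
          unitary response g0; both optional metadata)
    rise  rise time, seconds (0 = instant, the default)
    """

    tau: float = TAU_IGLUSNFR_2MM
    s0: float = 0.025
    rise: float = 0.0
    n_sites: Optional[float] = None
    g0: Optional[float] = None

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.s0 <= 0:
            raise ValueError("tau and s0 must be positive")


@dataclass
class SynthConfig:
    """Complete description of one synthetic experiment."""

    seed: int = 0
    pool: PoolModel = field(default_factory=PoolModel)
    kernel: KernelModel = field(default_factory=KernelModel)
    ephys_fs: float = 40_000.0
    frame_rate: float = 100.0
    baseline_f0: float = 1000.0
    noise_ephys: float = 5e-12
    noise_frames: float = 5.0
    mini_rate: float = 7.0
    mini_amp_cv: float = 0.25
    syn_delay: float = 0.9e-3
    ca_condition: str = "2mM"

    def __post_init__(self) -> None:
        if self.frame_rate >= self.ephys_fs:
            raise ValueError("frame_rate must be below the ephys sampling rate")
        if self.ca_condition not in ("2mM", "4mM"):
            raise ValueError("ca_condition must be '2mM' or '4mM'")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    @classmethod
    def for_condition(cls, ca: str, **kwargs) -> "SynthConfig":
        tau = TAU_IGLUSNFR_2MM if ca == "2mM" else TAU_IGLUSNFR_4MM
        kernel = kwargs.pop("kernel", KernelModel(tau=tau))
        return cls(kernel=kernel, ca_condition=ca, **kwargs)


# --------------------------------------------------------------------------
# vesicle pool
# --------------------------------------------------------------------------

@dataclass
class PoolTrainResult:
    released: np.ndarray        # quanta per stimulus
    pool_before: np.ndarray     # occupancy just before each stimulus
    refilled: np.ndarray        # vesicles restocked after each stimulus


def simulate_pool_train(
    protocol: StimulusProtocol,
    pool: PoolModel,
    rng: Optional[np.random.Generator] = None,
    deterministic: bool = False,
) -> PoolTrainResult:
    """Release per stimulus from a binomially releasing, refilling pool.

    Stochastic mode draws released_i ~ Binomial(N_i, p_r) and restocks with
    Poisson(refill_rate * ISI) vesicles clipped at capacity. Deterministic
    mode replaces both draws by their means, which makes the train the
    geometric-depletion sequence the cumulative (SMN) analysis assumes.
    """
    if rng is None and not deterministic:
        raise ValueError("stochastic mode requires an rng")
    n = protocol.n
    released = np.zeros(n)
    pool_before = np.zeros(n)
    refilled = np.zeros(n)
    level = float(pool.n_rrp)
    for i in range(n):
        pool_before[i] = level
        if deterministic:
            rel = level * pool.p_r
        else:
            rel = float(rng.binomial(int(round(level)), pool.p_r))
        released[i] = rel
        level -= rel
        if i < n - 1:
            isi = protocol.times[i + 1] - protocol.times[i]
            capacity_gap = pool.n_rrp - level
            if deterministic:
                restock = min(capacity_gap, pool.refill_rate * isi)
            else:
                restock = min(capacity_gap, float(rng.poisson(pool.refill_rate * isi)))
            refilled[i] = restock
            level += restock
    return PoolTrainResult(released=released, pool_before=pool_before, refilled=refilled)


# --------------------------------------------------------------------------
# electrophysiological readout
# --------------------------------------------------------------------------

def _add_exp_event(
    values: np.ndarray, dt: float, t0_trace: float, t_event: float, amp: float, tau: float
) -> None:
    """Add an instant-rise exponential (inward, negative) in place."""
    i0 = int(math.ceil((t_event - t0_trace) / dt - 1e-9))
    if i0 >= values.size:
        return
    i0 = max(i0, 0)
    k = np.arange(values.size - i0)
    t_rel = (t0_trace + (i0 + k) * dt) - t_event
    values[i0:] += -amp * np.exp(-t_rel / tau)


def render_epsc(
    quanta: np.ndarray,
    protocol: StimulusProtocol,
    cfg: SynthConfig,
    rng: Optional[np.random.Generator] = None,
    pre_time: float = 0.02,
    tail_time: float = 0.05,
) -> Tuple[TimeSeries, np.ndarray]:
    """Render a 40 kHz current trace from per-stimulus quanta counts.

    Each stimulus contributes quanta * quantal_amp as an instant-rise
    exponential at the stimulus time plus the synaptic delay. Inward
    currents are negative. Returns the trace and the ground-truth
    amplitude magnitudes (quanta * quantal_amp).
    """
    quanta = np.asarray(quanta, dtype=float)
    if quanta.size != protocol.n:
        raise ValueError("one quanta count per stimulus required")
    dt = 1.0 / cfg.ephys_fs
    t0 = protocol.times[0] - pre_time
    t_end = protocol.times[-1] + cfg.syn_delay + tail_time
    n = int(round((t_end - t0) / dt)) + 1
    values = np.zeros(n)
    for q, t_stim in zip(quanta, protocol.times):
        if q > 0:
            _add_exp_event(
                values, dt, t0, t_stim + cfg.syn_delay,
                q * cfg.pool.quantal_amp, cfg.pool.quantal_tau,
            )
    if rng is not None and cfg.noise_ephys > 0:
        values += rng.normal(0.0, cfg.noise_ephys, size=n)
    ts = TimeSeries(t0=t0, dt=dt, values=values, label="synthetic eEPSC", units=Units.AMPERE)
    return ts, quanta * cfg.pool.quantal_amp


# --------------------------------------------------------------------------
# fluorescence readout
# --------------------------------------------------------------------------

def frame_averaged_exponential(
    frame_starts: np.ndarray,
    frame_dt: float,
    t_onset: float,
    tau: float,
) -> np.ndarray:
    """Exposure-window average of a unit instant-rise exponential.

    Closed-form mean of exp(-(t - t_onset)/tau) over each frame's exposure
    interval [start, start + frame_dt); zero before the onset.
    """
    a = np.asarray(frame_starts, dtype=float)
    b = a + frame_dt
    lo = np.maximum(a, t_onset)
    out = np.zeros_like(a)
    ov = b > t_onset
    out[ov] = tau * (
        np.exp(-(lo[ov] - t_onset) / tau) - np.exp(-(b[ov] - t_onset) / tau)
    ) / frame_dt
    return out


def _frame_averaged_dff(
    quanta: np.ndarray,
    stim_times: np.ndarray,
    kernel: KernelModel,
    frame_starts: np.ndarray,
    frame_dt: float,
) -> np.ndarray:
    """Exact exposure-window average of s(t) = s0 * sum_i q_i exp(-(t-t_i)/tau).

    The indicator decay (~38 ms) is comparable to the 10 ms frame, so each
    frame reports the time-average of s(t) over its exposure, not a point
    sample; the average is computed in closed form per stimulus.
    """
    out = np.zeros(np.asarray(frame_starts).size)
    for q, ti in zip(quanta, stim_times):
        if q <= 0:
            continue
        out += kernel.s0 * q * frame_averaged_exponential(
            frame_starts, frame_dt, ti, kernel.tau
        )
    return out


@dataclass
class FluorescenceResult:
    dff: TimeSeries                 # noisy frame-averaged dF/F
    truth_dff: TimeSeries           # noiseless frame-averaged dF/F
    stack: Optional[np.ndarray]     # H x W x T counts, image mode only
    mask: Optional[np.ndarray]      # ground-truth ROI booleans
    pre_frames: int


def cup_mask(
    shape: Tuple[int, int] = (48, 48),
    center: Optional[Tuple[float, float]] = None,
    inner_radius: float = 8.0,
    width: float = 4.0,
    arc_deg: float = 240.0,
) -> np.ndarray:
    """Cup-shaped ROI: a 240-degree arc of an annulus, opening upward."""
    h, w = shape
    cy, cx = center if center is not None else ((h - 1) / 2.0, (w - 1) / 2.0)
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - cy, xx - cx)
    theta = np.degrees(np.arctan2(yy - cy, xx - cx))  # 0 deg = +x, 90 = down
    in_ring = (r >= inner_radius) & (r <= inner_radius + width)
    half = arc_deg / 2.0
    # keep the arc centred on the downward direction (+90 deg), gap on top
    delta = (theta - 90.0 + 180.0) % 360.0 - 180.0
    return in_ring & (np.abs(delta) <= half)


def render_fluorescence(
    quanta: np.ndarray,
    protocol: StimulusProtocol,
    cfg: SynthConfig,
    rng: Optional[np.random.Generator] = None,
    pre_time: float = 0.1,
    tail_time: Optional[float] = None,
    image: bool = False,
    image_shape: Tuple[int, int] = (48, 48),
    background_f: float = 200.0,
) -> FluorescenceResult:
    """Render the reporter dF/F readout of a release train at the frame rate.

    The continuous signal is the release-impulse train convolved with the
    monoexponential indicator kernel; each frame reports the exposure
    average of F0 * (1 + s(t)) plus Gaussian frame noise. In image mode a
    multi-page stack is produced with the per-frame intensity painted into
    a cup-shaped ROI over a dimmer noisy background; the ground-truth mask
    is returned alongside.
    """
    quanta = np.asarray(quanta, dtype=float)
    if quanta.size != protocol.n:
        raise ValueError("one quanta count per stimulus required")
    frame_dt = 1.0 / cfg.frame_rate
    if tail_time is None:
        tail_time = 5.0 * cfg.kernel.tau
    t0 = protocol.times[0] - pre_time
    t_end = protocol.times[-1] + tail_time
    n_frames = int(round((t_end - t0) / frame_dt)) + 1
    frame_starts = t0 + frame_dt * np.arange(n_frames)
    pre_frames = max(1, int(math.floor(pre_time / frame_dt)))

    s = _frame_averaged_dff(quanta, protocol.times, cfg.kernel, frame_starts, frame_dt)
    truth = TimeSeries(t0=t0, dt=frame_dt, values=s.copy(),
                       label="ground-truth dF/F", units=Units.DFF)

    noise_dff = cfg.noise_frames / cfg.baseline_f0
    noisy = s.copy()
    if rng is not None and cfg.noise_frames > 0:
        noisy = noisy + rng.normal(0.0, noise_dff, size=n_frames)
    dff = TimeSeries(t0=t0, dt=frame_dt, values=noisy,
                     label="synthetic dF/F", units=Units.DFF)

    stack = None
    mask = None
    if image:
        mask = cup_mask(image_shape)
        h, w = image_shape
        stack = np.empty((h, w, n_frames))
        base = np.full((h, w), background_f, dtype=float)
        base[mask] = cfg.baseline_f0
        stack[:] = base[:, :, None]
        stack[mask, :] = cfg.baseline_f0 * (1.0 + s)[None, :]
        if rng is not None and cfg.noise_frames > 0:
            stack += rng.normal(0.0, cfg.noise_frames, size=stack.shape)
        stack = np.clip(stack, 0.0, None)
    return FluorescenceResult(dff=dff, truth_dff=truth, stack=stack,
                              mask=mask, pre_frames=pre_frames)


def apply_saturation(quanta: np.ndarray, k: float) -> np.ndarray:
    """Hill-type reporter saturation with unit small-signal gain.

    q -> q / (1 + q/k); the limit k -> inf restores linearity, so the
    saturated and linear readouts share the same single-quantum calibration.
    """
    quanta = np.asarray(quanta, dtype=float)
    if k <= 0:
        raise ValueError("saturation constant must be positive")
    return quanta / (1.0 + quanta / k)


# --------------------------------------------------------------------------
# spontaneous quantal events
# --------------------------------------------------------------------------

def simulate_minis(
    duration: float,
    cfg: SynthConfig,
    rng: np.random.Generator,
) -> Tuple[TimeSeries, pd.DataFrame]:
    """Poisson spontaneous quantal events in a noisy 40 kHz current trace.

    Event times are homogeneous Poisson at ``cfg.mini_rate``; amplitudes are
    log-normal around ``cfg.pool.quantal_amp`` with coefficient of variation
    ``cfg.mini_amp_cv``; each event is an instant-rise exponential with the
    quantal decay constant. Returns the trace and the ground-truth table.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    dt = 1.0 / cfg.ephys_fs
    n = int(round(duration / dt))
    values = np.zeros(n)
    n_events = rng.poisson(cfg.mini_rate * duration)
    onsets = np.sort(rng.uniform(0.0, duration, size=n_events))
    if cfg.mini_amp_cv > 0:
        sigma_log = math.sqrt(math.log(1.0 + cfg.mini_amp_cv**2))
        mu_log = math.log(cfg.pool.quantal_amp) - sigma_log**2 / 2.0
        amps = rng.lognormal(mu_log, sigma_log, size=n_events)
    else:
        amps = np.full(n_events, cfg.pool.quantal_amp)
    for t_ev, amp in zip(onsets, amps):
        _add_exp_event(values, dt, 0.0, t_ev, amp, cfg.pool.quantal_tau)
    if cfg.noise_ephys > 0:
        values += rng.normal(0.0, cfg.noise_ephys, size=n)
    ts = TimeSeries(t0=0.0, dt=dt, values=values,
                    label="synthetic minis", units=Units.AMPERE)
    truth = pd.DataFrame({
        "onset": onsets,
        "amplitude": amps,
        "tau_decay": np.full(n_events, cfg.pool.quantal_tau),
    })
    return ts, truth
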