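"""dF/F computation, dF-image ROI segmentation and per-pulse quantification.

A fluorescence stack is reduced to a single response image (mean response
frames minus mean baseline frames), segmented into a terminal ROI by
histogram-based thresholding of the blurred image, and collapsed to a
dF/F0 time series over the ROI. Per-pulse responses in a train are
quantified as tail-corrected areas under the curve, since consecutive
reporter responses overlap when the indicator decay is comparable to the
inter-stimulus interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import tifffile
from scipy import ndimage
from skimage import filters, measure

from .core import TimeSeries, Units, fit_exp_decay
from .synth import StimulusProtocol, frame_averaged_exponential


@dataclass
class ImageStack:
    """H x W x T stack of nonnegative intensities with a frame clock."""

    frames: np.ndarray
    frame_dt: float
    pre_frames: int
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be H x W x T")
        if self.frame_dt <= 0:
            raise ValueError("frame_dt must be positive")
        if self.pre_frames < 1:
            raise ValueError("need at least one baseline frame")
        if self.pre_frames >= self.frames.shape[2]:
            raise ValueError("baseline window exceeds the stack")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[2]

    @classmethod
    def from_tiff(cls, path, frame_dt: float, pre_frames: int, t0: float = 0.0) -> "ImageStack":
        pages = tifffile.imread(path)          # T x H x W
        if pages.ndim == 2:
            pages = pages[None]
        return cls(frames=np.moveaxis(pages, 0, -1), frame_dt=frame_dt,
                   pre_frames=pre_frames, t0=t0)

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, np.moveaxis(self.frames, -1, 0).astype(np.float32))


@dataclass
class ROIMask:
    """Segmented region of interest with its provenance."""

    mask: np.ndarray
    area: int
    provenance: dict
    valid: bool = True
    note: str = ""


def delta_f_image(stack: ImageStack, response_window: Tuple[int, int]) -> np.ndarray:
    """Pixelwise mean(response frames) minus mean(baseline frames).

    ``response_window`` is a half-open frame-index range; it must not
    overlap the baseline frames.
    """
    lo, hi = response_window
    if not (0 <= lo < hi <= stack.n_frames):
        raise ValueError("response window outside the stack")
    if lo < stack.pre_frames:
        raise ValueError("response window overlaps the baseline frames")
    baseline = stack.frames[:, :, : stack.pre_frames].mean(axis=2)
    response = stack.frames[:, :, lo:hi].mean(axis=2)
    return response - baseline


def segment_roi(
    dF: np.ndarray,
    sigma_px: float = 3.0,
    seed_point: Optional[Tuple[int, int]] = None,
    method: str = "otsu",
    percentile: float = 99.0,
) -> ROIMask:
    """Histogram-threshold segmentation of a dF image into one ROI.

    The image is blurred with a 2-D Gaussian (sigma ``sigma_px``) and
    thresholded globally, by Otsu's criterion or at a percentile of the
    blurred histogram. The connected component containing ``seed_point``
    (else the largest) is kept and its holes filled. The result is an
    outer bound for the responding terminal, as liberal blurring dilates
    the true footprint.
    """
    dF = np.asarray(dF, dtype=float)
    if dF.ndim != 2 or min(dF.shape) < 16:
        raise ValueError("dF image must be 2-D and at least 16 x 16 px")
    blurred = filters.gaussian(dF, sigma=sigma_px, preserve_range=True)
    if method == "otsu":
        thr = filters.threshold_otsu(blurred)
    elif method == "percentile":
        thr = float(np.percentile(blurred, percentile))
    else:
        raise ValueError("method must be 'otsu' or 'percentile'")
    fg = blurred > thr
    provenance = {"filter_sigma": sigma_px, "threshold": float(thr),
                  "method": method, "seed_point": seed_point}
    if not fg.any() or fg.all():
        return ROIMask(mask=np.zeros_like(fg), area=0, provenance=provenance,
                       valid=False, note="empty or degenerate foreground")
    labels = measure.label(fg, connectivity=2)
    if seed_point is not None:
        lab = labels[seed_point[0], seed_point[1]]
        if lab == 0:
            return ROIMask(mask=np.zeros_like(fg), area=0, provenance=provenance,
                           valid=False, note="seed point not in foreground")
    else:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        lab = int(np.argmax(counts))
    mask = ndimage.binary_fill_holes(labels == lab)
    return ROIMask(mask=mask, area=int(mask.sum()), provenance=provenance)


def extract_trace(stack: ImageStack, mask: np.ndarray) -> TimeSeries:
    """ROI-mean dF/F0 time series; F0 is the pre-stimulus ROI mean."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.frames.shape[:2]:
        raise ValueError("mask shape does not match the stack")
    if not mask.any():
        raise ValueError("mask is empty")
    roi_mean = stack.frames[mask, :].mean(axis=0)
    f0 = float(roi_mean[: stack.pre_frames].mean())
    if f0 <= 0:
        raise ValueError("nonpositive baseline fluorescence F0")
    return TimeSeries(t0=stack.t0, dt=stack.frame_dt,
                      values=(roi_mean - f0) / f0,
                      label="ROI dF/F0", units=Units.DFF)


# --------------------------------------------------------------------------
# per-pulse quantification
# --------------------------------------------------------------------------

def per_pulse_auc(
    dff: TimeSeries,
    protocol: StimulusProtocol,
    tau: Optional[float] = None,
    normalize: bool = False,
) -> np.ndarray:
    """Tail-corrected area under the dF/F curve for each stimulus.

    Each pulse's response is integrated over its own inter-stimulus
    window after subtracting the exponential continuation of all
    preceding responses; the continuation uses an amplitude fitted per
    pulse and a shared decay constant (estimated from the final decay
    when not supplied). Because camera frames report exposure averages,
    the left Riemann sum of the frame values is the exact time integral
    over the window (a trapezoid would half-weight the onset frame). The
    last window is capped at one inter-stimulus interval so all pulses
    are integrated over equal spans. With ``normalize`` the sequence is
    divided by its first element.
    """
    if protocol.n >= 2 and protocol.isi < 2 * dff.dt:
        raise ValueError("ISI under two frames: use the deconvolution path")
    if tau is None:
        tau = _estimate_tail_tau(dff, protocol)
    frame_starts = dff.times()
    work = dff.values.astype(float).copy()
    aucs = np.zeros(protocol.n)
    for i, t_stim in enumerate(protocol.times):
        i0 = dff.index_at(t_stim)
        if i + 1 < protocol.n:
            t_next = protocol.times[i + 1]
        elif protocol.n >= 2:
            t_next = t_stim + float(np.median(np.diff(protocol.times)))
        else:
            t_next = dff.t0 + dff.n * dff.dt
        i1 = int(np.clip(round((t_next - dff.t0) / dff.dt), i0 + 1, dff.n))
        shape = frame_averaged_exponential(frame_starts, dff.dt, t_stim, tau)
        seg_shape = shape[i0:i1]
        denom = float(seg_shape @ seg_shape)
        amp = float(work[i0:i1] @ seg_shape) / denom if denom > 0 else 0.0
        aucs[i] = float(np.sum(work[i0:i1]) * dff.dt)
        if i1 < dff.n:
            work[i1:] -= amp * shape[i1:]
    if normalize:
        if aucs[0] == 0:
            raise ValueError("cannot normalize: first-pulse AUC is zero")
        aucs = aucs / aucs[0]
    return aucs


def _estimate_tail_tau(dff: TimeSeries, protocol: StimulusProtocol) -> float:
    """Decay constant from the post-train tail (fallback: first window)."""
    t_last = protocol.times[-1]
    i_last = dff.index_at(t_last)
    tail = dff.values[i_last:]
    if tail.size >= 6:
        ipk = int(np.argmax(tail))
        if dff.n - (i_last + ipk) >= 5:
            fit = fit_exp_decay(dff, (dff.t0 + (i_last + ipk) * dff.dt, dff.t_end))
            if fit.converged and fit.tau > 0:
                return fit.tau
    # fallback: decay inside the first inter-stimulus window
    i0 = dff.index_at(protocol.times[0])
    i1 = dff.index_at(protocol.times[1]) if protocol.n > 1 else dff.n - 1
    seg = dff.values[i0 : i1 + 1]
    ipk = int(np.argmax(seg))
    fit = fit_exp_decay(dff, (dff.t0 + (i0 + ipk) * dff.dt, dff.t0 + i1 * dff.dt))
    if not (fit.converged and fit.tau > 0):
        raise ValueError("could not estimate the reporter decay constant")
    return fit.tau
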