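"""Stimulus-locked IOS processing chain.

The stages follow the standard widefield reflectance workflow: cut the
recording into stimulus-locked trials, convert to fractional change dI/I0
against the per-pixel trial mean, detrend, average across trials, re-zero on
the prestimulus baseline, reduce to ROI traces, smooth, bin into activity
maps, and extract the triphasic response features (initial dip, overshoot,
undershoot).

Invalid pixels (non-positive mean intensity) are carried as NaN and excluded
from every reduction; they never enter a mean as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    ActivityMapSet,
    FrameStack,
    ResponseFeatures,
    RoiSpec,
    StimulusSchedule,
    TrialTensor,
)

__all__ = [
    "segment_trials",
    "fractional_change",
    "detrend",
    "trial_average",
    "normalize_to_baseline",
    "roi_trace",
    "propose_rois",
    "smooth_moving_average",
    "activity_maps",
    "contrast_sd",
    "extract_response_features",
    "analyze_session",
    "SessionResult",
]

DETREND_METHODS = ("first_difference", "linear", "none")


# ---------------------------------------------------------------------------
# segmentation and normalisation
# ---------------------------------------------------------------------------

def segment_trials(stack: FrameStack, schedule: StimulusSchedule,
                   n_pre: int = 400, n_post: int = 2600) -> np.ndarray:
    """Cut a recording into stimulus-locked trial windows.

    Each trial spans ``n_pre`` frames before the onset and ``n_post`` frames
    from the onset onwards, so the onset frame sits at index ``n_pre`` within
    the window.  Onsets whose window overruns the recording are dropped with
    a warning; zero usable trials is an error.

    Returns a ``(n_trials, H, W, n_pre + n_post)`` array of raw intensities.
    """
    if n_pre < 0 or n_post < 1:
        raise ValueError("need n_pre >= 0 and n_post >= 1")
    T = stack.n_frames
    trials = []
    for onset in schedule.onset_frames:
        if onset - n_pre < 0 or onset + n_post > T:
            warnings.warn(
                f"trial at onset frame {onset} overruns the recording "
                f"({T} frames); dropped", stacklevel=2)
            continue
        trials.append(stack.data[:, :, onset - n_pre:onset + n_post])
    if not trials:
        raise ValueError("no stimulus onset leaves a complete trial window")
    return np.stack(trials, axis=0).astype(float)


def fractional_change(trials: np.ndarray, n_pre: int,
                      frame_rate_fps: float) -> TrialTensor:
    """Fractional intensity change dI/I0 per trial.

    I0 is the per-pixel mean over the full trial window, so each pixel's
    dI/I0 series has exactly zero temporal mean.  Pixels with a
    non-positive or non-finite mean cannot be normalised and become NaN.
    """
    trials = np.asarray(trials, dtype=float)
    if trials.ndim != 4:
        raise ValueError("trials must be (n_trials, H, W, T)")
    i0 = trials.mean(axis=3, keepdims=True)
    bad = ~np.isfinite(i0) | (i0 <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dii = trials / i0 - 1.0
    dii = np.where(np.broadcast_to(bad, dii.shape), np.nan, dii)
    n_bad = int(bad.sum())
    if n_bad:
        warnings.warn(f"{n_bad} pixel-trials with non-positive mean marked "
                      "invalid (NaN)", stacklevel=2)
    return TrialTensor(data=dii, n_pre=n_pre, frame_rate_fps=frame_rate_fps,
                       provenance={"normalisation": "per-pixel trial mean"})


def detrend(tensor: TrialTensor, method: str = "first_difference") -> TrialTensor:
    """Remove slow per-pixel trends within each trial.

    ``first_difference`` replaces each series by its first difference
    (length preserved, y[0] = 0); ``linear`` subtracts the least-squares
    line; ``none`` is the identity.  The method is recorded in provenance.
    """
    if method not in DETREND_METHODS:
        raise ValueError(f"unknown detrend method {method!r}; "
                         f"choose from {DETREND_METHODS}")
    x = tensor.data
    if x.shape[3] < 2:
        raise ValueError("detrending needs at least two frames per trial")
    if method == "first_difference":
        y = np.diff(x, axis=3, prepend=x[..., :1])
    elif method == "linear":
        t = np.arange(x.shape[3], dtype=float)
        tc = t - t.mean()
        denom = float((tc ** 2).sum())
        xm = x.mean(axis=3, keepdims=True)
        slope = ((x - xm) * tc).sum(axis=3, keepdims=True) / denom
        y = x - xm - slope * tc
    else:
        y = x.copy()
    prov = dict(tensor.provenance)
    prov["detrend"] = method
    return TrialTensor(data=y, n_pre=tensor.n_pre,
                       frame_rate_fps=tensor.frame_rate_fps, provenance=prov)


def trial_average(tensor: TrialTensor) -> np.ndarray:
    """Arithmetic mean across trials -> ``(H, W, T)``.

    NaN pixels are excluded trial-wise; a pixel invalid in every trial
    stays NaN.
    """
    if tensor.n_trials < 1:
        raise ValueError("trial average needs at least one trial")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        return np.nanmean(tensor.data, axis=0)


def normalize_to_baseline(avg: np.ndarray, n_pre: int, frame_rate_fps: float,
                          baseline_s: float = 2.0) -> np.ndarray:
    """Re-zero each pixel on its prestimulus baseline.

    Subtracts the per-pixel mean over the final ``baseline_s`` seconds
    before the onset frame ``n_pre``, so the baseline mean of the output
    is zero.
    """
    n_base = int(round(baseline_s * frame_rate_fps))
    if n_base < 1 or n_base > n_pre:
        raise ValueError(
            f"baseline window of {n_base} frames does not fit in the "
            f"{n_pre}-frame prestimulus segment")
    base = np.nanmean(avg[..., n_pre - n_base:n_pre], axis=-1, keepdims=True)
    return avg - base


# ---------------------------------------------------------------------------
# ROI traces and smoothing
# ---------------------------------------------------------------------------

def roi_trace(avg: np.ndarray, roi: RoiSpec) -> np.ndarray:
    """Spatial mean over a rectangular ROI per frame -> 1-D trace.

    Invalid (NaN) pixels are excluded from the mean.  An ROI that lies
    entirely outside the frame, or whose pixels are all invalid, is an
    error; a partially out-of-bounds ROI is clipped with a warning.
    """
    if roi.kind != "rect":
        raise ValueError("roi_trace expects a rectangular ROI; "
                         "use kymograph.sample_line for polylines")
    H, W = avg.shape[:2]
    r, c, h, w = roi.rect
    r0, c0 = max(r, 0), max(c, 0)
    r1, c1 = min(r + h, H), min(c + w, W)
    if r1 <= r0 or c1 <= c0:
        raise ValueError(f"ROI {roi.rect} lies outside the {H}x{W} frame")
    if (r0, c0, r1, c1) != (r, c, r + h, c + w):
        warnings.warn(f"ROI {roi.rect} clipped to frame bounds", stacklevel=2)
    block = avg[r0:r1, c0:c1]
    if np.all(np.isnan(block)):
        raise ValueError("ROI contains no valid pixels")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(block, axis=(0, 1))


def propose_rois(parenchyma_mask: np.ndarray, n_rois: int = 5,
                 size: int = 20) -> list[RoiSpec]:
    """Suggest parenchymal ROIs, farthest-from-vessel first.

    Greedily places ``size`` x ``size`` rectangles centred on maxima of the
    distance transform of the mask (True = usable tissue), suppressing a
    placed ROI's footprint before picking the next.  ROIs are explicit
    analysis inputs; this helper only proposes reproducible candidates for
    data where nobody has drawn them yet.
    """
    from scipy.ndimage import distance_transform_edt

    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    H, W = parenchyma_mask.shape
    if size > min(H, W):
        raise ValueError(f"ROI size {size} exceeds frame {H}x{W}")
    score = distance_transform_edt(parenchyma_mask)
    rois = []
    half = size // 2
    for i in range(n_rois):
        if score.max() <= 0:
            break
        r, c = np.unravel_index(int(np.argmax(score)), (H, W))
        r0 = int(np.clip(r - half, 0, H - size))
        c0 = int(np.clip(c - half, 0, W - size))
        rois.append(RoiSpec.rectangle(r0, c0, size, size, label=f"roi{i}"))
        score[max(0, r0 - half):r0 + size + half,
              max(0, c0 - half):c0 + size + half] = 0.0
    return rois


def smooth_moving_average(trace: np.ndarray, window: int = 20) -> np.ndarray:
    """Centered moving average; edges use a shrinking window.

    Length-preserving and phase-free (for even ``window`` the support is
    offset by half a frame).  NaN samples are excluded from each window.
    """
    trace = np.asarray(trace, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > trace.size:
        raise ValueError(f"window {window} exceeds trace length {trace.size}")
    valid = np.isfinite(trace)
    filled = np.where(valid, trace, 0.0)
    kern = np.ones(window)
    num = np.convolve(filled, kern, mode="same")
    den = np.convolve(valid.astype(float), kern, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


# ---------------------------------------------------------------------------
# activity maps and contrast
# ---------------------------------------------------------------------------

def activity_maps(avg: np.ndarray, bin_frames: int = 200,
                  lut_range: tuple[float, float] = (-2.3e-3, 1.5e-3),
                  frame_rate_fps: float | None = None) -> ActivityMapSet:
    """Average consecutive ``bin_frames``-frame bins into spatial maps.

    Bins are disjoint, consecutive, and exhaustive up to an incomplete tail
    bin, which is dropped.  ``bin_frames`` larger than the series is an
    error.
    """
    if bin_frames < 1:
        raise ValueError("bin_frames must be >= 1")
    T = avg.shape[-1]
    n_maps = T // bin_frames
    if n_maps == 0:
        raise ValueError(f"bin_frames {bin_frames} exceeds series length {T}")
    used = avg[..., :n_maps * bin_frames]
    binned = used.reshape(avg.shape[0], avg.shape[1], n_maps, bin_frames)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        maps = np.nanmean(binned, axis=3)
    maps = np.moveaxis(maps, 2, 0)
    dur = bin_frames / frame_rate_fps if frame_rate_fps else None
    return ActivityMapSet(maps=maps, bin_frames=bin_frames,
                          lut_range=tuple(lut_range), bin_duration_s=dur)


def contrast_sd(maps: ActivityMapSet) -> float:
    """Grayscale-histogram contrast metric of a map set.

    Each map is clipped to the LUT range, rescaled to 8-bit gray levels
    (0..255), and the population standard deviation of all pooled pixels is
    returned.  Higher values mean stronger dark/bright separation across
    the maps.
    """
    lo, hi = maps.lut_range
    if not lo < hi:
        raise ValueError(f"degenerate LUT range {maps.lut_range}")
    if maps.n_maps < 1:
        raise ValueError("contrast_sd needs at least one map")
    pooled = maps.maps[np.isfinite(maps.maps)]
    if pooled.size == 0:
        raise ValueError("maps contain no valid pixels")
    gray = np.rint(np.clip((pooled - lo) / (hi - lo), 0.0, 1.0) * 255.0)
    return float(gray.std(ddof=0))


# ---------------------------------------------------------------------------
# response features
# ---------------------------------------------------------------------------

def extract_response_features(trace: np.ndarray, frame_rate_fps: float,
                              onset_frame: int, sd_threshold: float = 0.5,
                              dip_search_s: float = 5.0) -> ResponseFeatures:
    """Locate the triphasic extrema of an ROI trace.

    The initial dip is the global minimum within ``(0, dip_search_s]`` after
    onset, the overshoot peak the global maximum after the dip, and the
    undershoot the minimum after the peak.  Amplitudes are measured from the
    prestimulus mean; the response is significant when the dip magnitude
    exceeds ``sd_threshold`` prestimulus standard deviations.  If no
    consistent dip < peak < undershoot ordering exists the features are
    reported absent and ``significant`` is False.
    """
    trace = np.asarray(trace, dtype=float)
    t = (np.arange(trace.size) - onset_frame) / frame_rate_fps
    pre = trace[(t < 0) & np.isfinite(trace)]
    if pre.size < 2:
        raise ValueError("trace must include a prestimulus segment")
    m0 = float(pre.mean())
    sd = float(pre.std(ddof=0))

    def _extremum(mask: np.ndarray, sign: float):
        idx = np.flatnonzero(mask & np.isfinite(trace))
        if idx.size == 0:
            return None, None
        k = idx[np.argmin(sign * trace[idx])]
        return float(t[k]), float(trace[k] - m0)

    dip_t, dip_a = _extremum((t > 0) & (t <= dip_search_s), sign=+1.0)
    if dip_t is None:
        return ResponseFeatures(prestim_sd=sd)
    peak_t, peak_a = _extremum(t > dip_t, sign=-1.0)
    if peak_t is None:
        return ResponseFeatures(prestim_sd=sd)
    under_t, under_a = _extremum(t > peak_t, sign=+1.0)
    if under_t is None or not dip_t < peak_t < under_t:
        return ResponseFeatures(prestim_sd=sd)
    significant = bool(sd > 0 and abs(dip_a) > sd_threshold * sd)
    return ResponseFeatures(dip_time_s=dip_t, dip_amp=dip_a,
                            peak_time_s=peak_t, peak_amp=peak_a,
                            undershoot_time_s=under_t, undershoot_amp=under_a,
                            significant=significant, prestim_sd=sd)


# ---------------------------------------------------------------------------
# one-call session analysis
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class SessionResult:
    """Products of a full stimulus-locked analysis run."""

    average: np.ndarray            # (H, W, T) trial-averaged dI/I0
    n_pre: int
    frame_rate_fps: float
    traces: pd.DataFrame           # time_s, roi, dI_over_I0 (smoothed)
    features: dict[str, ResponseFeatures]
    maps: ActivityMapSet
    contrast: float
    provenance: dict = field(default_factory=dict)


def analyze_session(stack: FrameStack, schedule: StimulusSchedule,
                    rois: list[RoiSpec], n_pre: int = 400, n_post: int = 2600,
                    detrend_method: str = "linear", baseline_s: float = 2.0,
                    smooth_window: int = 20, bin_frames: int = 200,
                    lut_range: tuple[float, float] = (-2.3e-3, 1.5e-3),
                    sd_threshold: float = 0.5,
                    dip_search_s: float = 5.0) -> SessionResult:
    """Run the full chain: segment -> dI/I0 -> detrend -> average ->
    baseline-normalize -> ROI traces -> smooth -> maps/contrast/features.

    Detrending is applied per trial before averaging so trial-specific
    drifts cancel; the stage order and parameters are recorded in
    provenance.
    """
    raw = segment_trials(stack, schedule, n_pre=n_pre, n_post=n_post)
    tensor = fractional_change(raw, n_pre=n_pre,
                               frame_rate_fps=stack.frame_rate_fps)
    tensor = detrend(tensor, method=detrend_method)
    avg = trial_average(tensor)
    avg = normalize_to_baseline(avg, n_pre=n_pre,
                                frame_rate_fps=stack.frame_rate_fps,
                                baseline_s=baseline_s)
    fps = stack.frame_rate_fps
    time_s = (np.arange(avg.shape[-1]) - n_pre) / fps

    rows = []
    features: dict[str, ResponseFeatures] = {}
    for i, roi in enumerate(rois):
        label = roi.label or f"roi{i}"
        smoothed = smooth_moving_average(roi_trace(avg, roi), smooth_window)
        features[label] = extract_response_features(
            smoothed, fps, n_pre, sd_threshold=sd_threshold,
            dip_search_s=dip_search_s)
        rows.append(pd.DataFrame({"time_s": time_s, "roi": label,
                                  "dI_over_I0": smoothed}))
    traces = (pd.concat(rows, ignore_index=True) if rows
              else pd.DataFrame(columns=["time_s", "roi", "dI_over_I0"]))

    maps = activity_maps(avg, bin_frames=bin_frames, lut_range=lut_range,
                         frame_rate_fps=fps)
    prov = {"order": ["segment", "fractional_change", f"detrend:{detrend_method}",
                      "trial_average", f"baseline_normalize:{baseline_s}s",
                      "roi_trace", f"smooth:{smooth_window}",
                      f"activity_maps:{bin_frames}"],
            "n_pre": n_pre, "n_post": n_post,
            "n_trials_used": int(raw.shape[0]),
            "lut_range": list(lut_range)}
    return SessionResult(average=avg, n_pre=n_pre, frame_rate_fps=fps,
                         traces=traces, features=features, maps=maps,
                         contrast=contrast_sd(maps), provenance=prov)
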