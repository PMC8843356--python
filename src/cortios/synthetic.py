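"""Synthetic cortical-imaging data with known ground truth.

Everything the analysis modules consume can be generated here: a static
vessel scene, stimulus schedules, stimulus-locked IOS movies with
physiological artifacts, and vessel movies with erythrocyte bands advected
at a known speed.  All randomness flows through a single integer seed, so
identical inputs give bit-identical outputs.

The forward model for an IOS movie is

    frame(t) = baseline * (1 + response(t) * kernel + artifacts(t)) + noise

with ``response`` a triphasic template summed over stimulus onsets,
``kernel`` a 2-D Gaussian activation patch centred in parenchyma,
``artifacts`` global heartbeat/respiration sinusoids plus a linear drift,
and ``noise`` a signal-scaled Gaussian approximation of shot noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import splev, splprep
from scipy.ndimage import binary_dilation, distance_transform_edt, gaussian_filter
from scipy.spatial import cKDTree
from skimage.morphology import disk

from .errors import ScheduleError
from .types import (
    AcquisitionConfig,
    ArtifactModel,
    FlowGroundTruth,
    FrameStack,
    HemodynamicTemplate,
    StimulusSchedule,
    VesselScene,
)

__all__ = [
    "make_vessel_scene",
    "hemodynamic_trace",
    "random_schedule",
    "render_ios_stack",
    "render_flow_movie",
    "simulate_ios_session",
    "IosSimulation",
    "trigger_log_frame",
]

#: mean parenchymal intensity of generated scenes, in sensor counts
BASELINE_LEVEL = 20000.0
#: multiplicative attenuation at a vessel centerline relative to parenchyma
VESSEL_ATTENUATION = 0.35


# ---------------------------------------------------------------------------
# vessel scene
# ---------------------------------------------------------------------------

def _vessel_path(rng: np.random.Generator, height: int, width: int) -> np.ndarray:
    """A smooth curve crossing the field of view, sampled every ~0.5 px."""
    # endpoints on opposite borders, interior control points jittered
    if rng.random() < 0.5:  # left-right crossing
        p0 = np.array([rng.uniform(0.15, 0.85) * height, 0.0])
        p1 = np.array([rng.uniform(0.15, 0.85) * height, width - 1.0])
    else:  # top-bottom crossing
        p0 = np.array([0.0, rng.uniform(0.15, 0.85) * width])
        p1 = np.array([height - 1.0, rng.uniform(0.15, 0.85) * width])
    mids = []
    for frac in (0.33, 0.66):
        mid = p0 + frac * (p1 - p0)
        mid += rng.normal(0.0, 0.08 * min(height, width), size=2)
        mids.append(mid)
    ctrl = np.stack([p0, *mids, p1])
    tck, _ = splprep(ctrl.T, s=0.0, k=3)
    # dense evaluation, then resample by chord length to ~0.5 px spacing
    u = np.linspace(0.0, 1.0, 50 * max(height, width) // 10)
    dense = np.stack(splev(u, tck), axis=1)
    dense[:, 0] = np.clip(dense[:, 0], 0.0, height - 1.0)
    dense[:, 1] = np.clip(dense[:, 1], 0.0, width - 1.0)
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(int(arc[-1] / 0.5), 2)
    s = np.linspace(0.0, arc[-1], n)
    return np.stack([np.interp(s, arc, dense[:, 0]),
                     np.interp(s, arc, dense[:, 1])], axis=1)


def make_vessel_scene(config: AcquisitionConfig, n_vessels: int = 3,
                      seed: int | None = None,
                      vessel_radius_px: tuple[float, float] = (2.5, 4.5),
                      baseline_level: float = BASELINE_LEVEL) -> VesselScene:
    """Generate a static scene: dark curved vessels over bright parenchyma.

    The baseline image combines a smooth illumination field (+-10 %) with a
    parabolic absorbance profile across each vessel lumen.  Each vessel
    pixel is tagged with the arclength of its nearest centerline sample so
    that flow movies can advect band patterns along the vessel axis.

    Deterministic for a fixed ``seed`` (defaults to ``config.seed``).
    """
    if n_vessels < 0:
        raise ValueError("n_vessels must be non-negative")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    H, W = config.shape

    # smooth illumination field: heavily low-passed white noise
    illum = gaussian_filter(rng.normal(0.0, 1.0, (H, W)), sigma=min(H, W) / 4.0)
    if illum.std() > 0:
        illum = illum / (illum.std() * 10.0)  # +-~10 %
    baseline = baseline_level * (1.0 + illum)

    vessel_mask = np.zeros((H, W), dtype=bool)
    vessel_id = np.full((H, W), -1, dtype=np.int32)
    arclength = np.full((H, W), np.nan)
    attenuation = np.zeros((H, W))
    centerlines: list[np.ndarray] = []

    rows, cols = np.mgrid[0:H, 0:W]
    pixels = np.stack([rows.ravel(), cols.ravel()], axis=1).astype(float)

    for j in range(n_vessels):
        path = _vessel_path(rng, H, W)
        radius = rng.uniform(*vessel_radius_px)
        tree = cKDTree(path)
        dist, idx = tree.query(pixels)
        dist = dist.reshape(H, W)
        idx = idx.reshape(H, W)
        inside = dist < radius
        seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        # later vessels overwrite earlier ones where they cross
        vessel_mask |= inside
        vessel_id[inside] = j
        arclength[inside] = arc[idx[inside]]
        prof = VESSEL_ATTENUATION * np.clip(1.0 - (dist / radius) ** 2, 0.0, 1.0)
        attenuation = np.where(inside, np.maximum(attenuation, prof), attenuation)
        centerlines.append(path)

    baseline = baseline * (1.0 - attenuation)
    parenchyma = ~binary_dilation(vessel_mask, structure=disk(2)) \
        if n_vessels else np.ones((H, W), dtype=bool)

    return VesselScene(
        vessel_mask=vessel_mask,
        centerlines=centerlines,
        parenchyma_mask=parenchyma,
        baseline_image=baseline,
        arclength_px=arclength,
        vessel_id=vessel_id,
    )


def default_activation_center(scene: VesselScene) -> tuple[int, int]:
    """Pick the parenchymal pixel farthest from vessels and borders."""
    free = distance_transform_edt(~scene.vessel_mask)
    H, W = scene.shape
    rows, cols = np.mgrid[0:H, 0:W]
    border = np.minimum(np.minimum(rows, H - 1 - rows),
                        np.minimum(cols, W - 1 - cols))
    score = np.minimum(free, border.astype(float))
    r, c = np.unravel_index(int(np.argmax(score)), (H, W))
    return int(r), int(c)


# ---------------------------------------------------------------------------
# hemodynamic response
# ---------------------------------------------------------------------------

def hemodynamic_trace(template: HemodynamicTemplate, t: np.ndarray) -> np.ndarray:
    """Evaluate the triphasic template at times ``t`` (s from onset).

    Sum of three Gaussian lobes; exactly zero for ``t < 0``.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    out = np.zeros_like(t)
    lobes = (
        (template.dip_time_s, template.dip_amp, template.lobe_widths_s[0]),
        (template.peak_time_s, template.peak_amp, template.lobe_widths_s[1]),
        (template.undershoot_time_s, template.undershoot_amp,
         template.lobe_widths_s[2]),
    )
    for mu, amp, sigma in lobes:
        out += amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2)
    out[t < 0] = 0.0
    return out


# ---------------------------------------------------------------------------
# schedules and trigger logs
# ---------------------------------------------------------------------------

def random_schedule(config: AcquisitionConfig, n_trials: int = 20,
                    isi_range_s: tuple[float, float] = (90.0, 240.0),
                    start_s: float = 30.0, duration_s: float = 1.5,
                    seed: int | None = None) -> StimulusSchedule:
    """Stimulus onsets with a random interstimulus interval.

    The first onset follows an initial quiescent recording of ``start_s``;
    subsequent onsets are spaced by intervals drawn uniformly from
    ``isi_range_s``.  Onset times are rounded to the nearest frame.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    isi = rng.uniform(*isi_range_s, size=max(n_trials - 1, 0))
    times = start_s + np.concatenate([[0.0], np.cumsum(isi)])
    frames = np.rint(times * config.frame_rate_fps).astype(int)
    return StimulusSchedule(onset_frames=tuple(frames), duration_s=duration_s,
                            isi_range_s=isi_range_s)


def trigger_log_frame(schedule: StimulusSchedule,
                      frame_rate_fps: float) -> pd.DataFrame:
    """Trigger log as a DataFrame (trial_index, onset_frame, onset_time_s, duration_s)."""
    onsets = np.asarray(schedule.onset_frames, dtype=int)
    return pd.DataFrame({
        "trial_index": np.arange(len(onsets)),
        "onset_frame": onsets,
        "onset_time_s": onsets / frame_rate_fps,
        "duration_s": schedule.duration_s,
    })


# ---------------------------------------------------------------------------
# IOS movie rendering
# ---------------------------------------------------------------------------

def render_ios_stack(scene: VesselScene, template: HemodynamicTemplate | None,
                     artifacts: ArtifactModel, schedule: StimulusSchedule,
                     config: AcquisitionConfig, duration_s: float | None = None,
                     activation_center: tuple[int, int] | None = None,
                     kernel_sigma_px: float = 8.0,
                     response_tail_s: float = 22.0
                     ) -> tuple[FrameStack, pd.DataFrame]:
    """Render a stimulus-locked IOS movie plus its trigger log.

    ``duration_s`` defaults to the last onset plus ``response_tail_s`` so the
    final response fits.  ``template=None`` (or an all-zero response) leaves
    only baseline, artifacts and noise.  Raises :class:`ScheduleError` when
    an onset falls outside the rendered stack.
    """
    artifacts.validate_for_rate(config.frame_rate_fps)
    F = config.frame_rate_fps
    onset_times = schedule.onset_times_s(F)
    if duration_s is None:
        duration_s = float(onset_times[-1]) + response_tail_s
    n_frames = int(round(duration_s * F))
    if schedule.onset_frames[0] < 0 or schedule.onset_frames[-1] >= n_frames:
        raise ScheduleError(
            f"onset frames {schedule.onset_frames[0]}..{schedule.onset_frames[-1]} "
            f"do not fit in a {n_frames}-frame stack")
    t = np.arange(n_frames) / F

    response = np.zeros(n_frames)
    if template is not None:
        for onset in onset_times:
            response += hemodynamic_trace(template, t - onset)

    if activation_center is None:
        activation_center = default_activation_center(scene)
    r0, c0 = activation_center
    rows, cols = np.mgrid[0:scene.shape[0], 0:scene.shape[1]]
    kernel = np.exp(-((rows - r0) ** 2 + (cols - c0) ** 2)
                    / (2.0 * kernel_sigma_px ** 2))

    rng = np.random.default_rng(config.seed)
    phase_hb, phase_rs = rng.uniform(0.0, 2.0 * np.pi, size=2)
    artifact_ts = (
        artifacts.heartbeat_amp * np.sin(2 * np.pi * artifacts.heartbeat_hz * t + phase_hb)
        + artifacts.respiration_amp * np.sin(2 * np.pi * artifacts.respiration_hz * t + phase_rs)
        + artifacts.drift_slope * t
    )

    clean = scene.baseline_image[:, :, None] * (
        1.0 + kernel[:, :, None] * response[None, None, :]
        + artifact_ts[None, None, :]
    )
    if artifacts.shot_noise_scale > 0:
        clean += (artifacts.shot_noise_scale * np.sqrt(np.maximum(clean, 0.0))
                  * rng.standard_normal(clean.shape))

    meta = {
        "kind": "ios",
        "seed": config.seed,
        "activation_center": [int(r0), int(c0)],
        "kernel_sigma_px": float(kernel_sigma_px),
        "artifact_phases": [float(phase_hb), float(phase_rs)],
    }
    stack = FrameStack(data=clean, frame_rate_fps=F,
                       pixel_pitch_um=config.pixel_pitch_um,
                       bit_depth=config.bit_depth, meta=meta)
    return stack, trigger_log_frame(schedule, F)


# ---------------------------------------------------------------------------
# flow movie rendering
# ---------------------------------------------------------------------------

def render_flow_movie(scene: VesselScene, truth: FlowGroundTruth,
                      config: AcquisitionConfig, duration_s: float,
                      noise_scale: float = 1.0,
                      seed: int | None = None) -> FrameStack:
    """Render a movie with dark erythrocyte bands advected along each vessel.

    Within vessel ``j``, pixel values are modulated by a sinusoidal
    absorbance pattern that is a pure function of the advected phase
    ``xi = s - u * k`` (arclength minus pixels-per-frame times frame index),
    so the band pattern between frames ``k`` and ``k + n`` is an exact shift
    by ``u * n`` pixels of arclength.  A smooth Poisson-derived envelope
    riding on ``xi`` perturbs the band contrast without breaking that shift.
    Parenchyma stays static apart from optional shot noise.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    F = config.frame_rate_fps
    n_frames = max(int(round(duration_s * F)), 1)
    lam_px = truth.band_spacing_um / config.pixel_pitch_um

    data = np.repeat(scene.baseline_image[:, :, None], n_frames, axis=2)
    k = np.arange(n_frames)

    for j, path in enumerate(scene.centerlines):
        in_vessel = scene.vessel_id == j
        if not np.any(in_vessel):
            continue
        s = scene.arclength_px[in_vessel]  # (P,)
        u = truth.speed_for(j) * 1e3 / (config.pixel_pitch_um * F)  # px/frame
        xi = s[:, None] - u * k[None, :]  # (P, T)

        # contrast envelope: Poisson counts on a coarse grid of the phase
        # variable, linearly interpolated -> advects rigidly with the bands
        xi_lo, xi_hi = float(xi.min()) - lam_px, float(xi.max()) + lam_px
        grid = np.arange(xi_lo, xi_hi + 2 * lam_px, lam_px)
        counts = rng.poisson(25.0, size=grid.size) / 25.0
        envelope = np.interp(xi, grid, counts)

        bands = 0.5 * (1.0 + np.sin(2 * np.pi * xi / lam_px))
        modulation = 1.0 - truth.band_contrast * envelope * bands
        data[in_vessel, :] = scene.baseline_image[in_vessel, None] * modulation

    if noise_scale > 0:
        data = data + (noise_scale * np.sqrt(np.maximum(data, 0.0))
                       * rng.standard_normal(data.shape))

    meta = {"kind": "flow", "seed": config.seed if seed is None else seed,
            "speed_mm_s": truth.speed_mm_s,
            "band_spacing_um": truth.band_spacing_um,
            "band_contrast": truth.band_contrast}
    return FrameStack(data=data, frame_rate_fps=F,
                      pixel_pitch_um=config.pixel_pitch_um,
                      bit_depth=config.bit_depth, meta=meta)


# ---------------------------------------------------------------------------
# one-call session
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class IosSimulation:
    """A rendered IOS session bundled with its ground truth."""

    stack: FrameStack
    schedule: StimulusSchedule
    trigger_log: pd.DataFrame
    scene: VesselScene
    template: HemodynamicTemplate
    activation_center: tuple[int, int]
    config: AcquisitionConfig = field(repr=False, default=None)


def simulate_ios_session(config: AcquisitionConfig,
                         template: HemodynamicTemplate,
                         artifacts: ArtifactModel | None = None,
                         n_trials: int = 20,
                         isi_range_s: tuple[float, float] = (90.0, 240.0),
                         start_s: float = 30.0,
                         stimulus_duration_s: float = 1.5,
                         n_vessels: int = 2,
                         kernel_sigma_px: float = 8.0,
                         response_tail_s: float = 22.0) -> IosSimulation:
    """Scene + schedule + movie in one deterministic call (seed from config)."""
    if artifacts is None:
        artifacts = ArtifactModel()
    scene = make_vessel_scene(config, n_vessels=n_vessels)
    schedule = random_schedule(config, n_trials=n_trials, isi_range_s=isi_range_s,
                               start_s=start_s, duration_s=stimulus_duration_s)
    center = default_activation_center(scene)
    stack, log = render_ios_stack(scene, template, artifacts, schedule, config,
                                  activation_center=center,
                                  kernel_sigma_px=kernel_sigma_px,
                                  response_tail_s=response_tail_s)
    return IosSimulation(stack=stack, schedule=schedule, trigger_log=log,
                         scene=scene, template=template,
                         activation_center=center, config=config)
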