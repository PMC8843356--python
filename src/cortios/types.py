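"""Core domain containers for cortical reflectance imaging analysis.

The containers mirror the stages of a stimulus-locked intrinsic-optical-signal
(IOS) experiment: acquisition geometry, the stereotyped hemodynamic response
shape, physiological artifact levels, the simulated vessel scene, frame
stacks, trial tensors, ROI specifications, binned activity maps, extracted
response features, and kymograph/flow-estimate records.

Array axis conventions (0-based everywhere):

* frame stacks are ``(H, W, T)`` with time last,
* trial tensors are ``(n_trials, H, W, T)``,
* image coordinates are ``(row, col)``,
* the onset frame of a trial is the first stimulated frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


# ---------------------------------------------------------------------------
# acquisition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionConfig:
    """Sensor and acquisition geometry.

    Defaults describe a lens-free contact imager: a 124 x 268 pixel CMOS
    array with 7.5 um pixel pitch read out at ~132.82 frames per second.
    ``array_height_um``/``array_width_um`` hold the active-array dimensions
    of the sensor die (900 x 1920 um), which define the imaged area.
    """

    height_px: int = 124
    width_px: int = 268
    frame_rate_fps: float = 132.82
    pixel_pitch_um: float = 7.5
    bit_depth: int = 16
    seed: int = 0
    array_height_um: float = 900.0
    array_width_um: float = 1920.0

    def __post_init__(self) -> None:
        if self.height_px <= 0 or self.width_px <= 0:
            raise ValueError("pixel dimensions must be positive")
        if self.frame_rate_fps <= 0:
            raise ValueError("frame_rate_fps must be positive")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        if not 1 <= self.bit_depth <= 32:
            raise ValueError("bit_depth must be in [1, 32]")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height_px, self.width_px)

    @property
    def frame_period_s(self) -> float:
        return 1.0 / self.frame_rate_fps

    @property
    def imaged_area_mm2(self) -> float:
        """Area of the active pixel array in square millimetres."""
        return self.array_height_um * self.array_width_um * 1e-6


# ---------------------------------------------------------------------------
# hemodynamic response template
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HemodynamicTemplate:
    """Triphasic stimulus-locked reflectance response.

    The response is modelled as a sum of three Gaussian lobes - an initial
    dip (reflectance decrease), an overshoot, and a late undershoot - so the
    extrema fall exactly at the lobe centres.  Amplitudes are fractional
    reflectance changes (dI/I0, dimensionless); times are seconds from
    stimulus onset.  The template is causal: it evaluates to 0 for t < 0.

    The ``green`` preset follows the volume-weighted response seen near the
    hemoglobin isosbestic point (trough ~2.5 s, peak ~7 s, undershoot ~13 s);
    the ``red`` preset follows the faster oximetric response (trough ~1 s,
    peak 3.5 s, undershoot ~7 s) with smaller amplitudes.
    """

    dip_time_s: float
    peak_time_s: float
    undershoot_time_s: float
    dip_amp: float
    peak_amp: float
    undershoot_amp: float
    lobe_widths_s: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not (self.dip_time_s < self.peak_time_s < self.undershoot_time_s):
            raise ValueError("lobe times must satisfy dip < peak < undershoot")
        if not (self.dip_amp < 0 < self.peak_amp) or self.undershoot_amp > 0:
            raise ValueError("amplitudes must satisfy dip < 0 < peak, undershoot <= 0")
        if min(self.dip_time_s, *self.lobe_widths_s) <= 0:
            raise ValueError("times and lobe widths must be positive")

    @classmethod
    def green(cls) -> "HemodynamicTemplate":
        return cls(
            dip_time_s=2.5,
            peak_time_s=7.0,
            undershoot_time_s=13.0,
            dip_amp=-2.0e-3,
            peak_amp=1.2e-3,
            undershoot_amp=-0.5e-3,
            lobe_widths_s=(1.0, 1.6, 0.7),
        )

    @classmethod
    def red(cls) -> "HemodynamicTemplate":
        return cls(
            dip_time_s=1.0,
            peak_time_s=3.5,
            undershoot_time_s=7.0,
            dip_amp=-0.4e-3,
            peak_amp=0.35e-3,
            undershoot_amp=-0.25e-3,
            lobe_widths_s=(0.4, 0.9, 0.9),
        )

    @classmethod
    def preset(cls, name: str) -> "HemodynamicTemplate":
        try:
            return {"green": cls.green, "red": cls.red}[name]()
        except KeyError:
            raise ValueError(f"unknown template preset {name!r}") from None


@dataclass(frozen=True)
class ArtifactModel:
    """Physiological and sensor artifact levels for the generator.

    Frequencies are in Hz and must stay below the Nyquist limit of the frame
    rate they are rendered at.  Amplitudes are fractional (multiplicative on
    the baseline image).  ``shot_noise_scale`` multiplies a Gaussian noise
    term with standard deviation ``scale * sqrt(intensity)``, the Gaussian
    approximation of photon shot noise; 1.0 is Poisson-equivalent.
    ``drift_slope`` is a slow linear illumination drift per second.

    Default frequencies approximate an anesthetized mouse (~10 Hz heartbeat,
    ~2 Hz respiration).  Default amplitudes are calibrated, not raw-sensor
    values: they are set so that the stimulus-locked trace noise after ROI
    averaging, trial averaging, and temporal smoothing stays well below the
    curvature scale of the triphasic extrema, the regime in which the
    response timing the generator encodes is recoverable (the property this
    generator exists to verify).  An argmax over a lobe of amplitude ``A``
    and width ``w`` wanders by about ``sqrt(4*sigma*w^2/A)`` under trace
    noise ``sigma``, so the flattest lobe (the red overshoot, A ~ 3.5e-4,
    w ~ 0.9 s) bounds the budget.  Raise the amplitudes to stress-test the
    pipeline under raw-photon-noise conditions.
    """

    heartbeat_hz: float = 10.0
    respiration_hz: float = 2.0
    heartbeat_amp: float = 5.0e-5
    respiration_amp: float = 2.5e-5
    shot_noise_scale: float = 0.1
    drift_slope: float = 2.0e-5

    def __post_init__(self) -> None:
        if min(self.heartbeat_amp, self.respiration_amp, self.shot_noise_scale) < 0:
            raise ValueError("artifact amplitudes must be non-negative")
        if self.heartbeat_hz <= 0 or self.respiration_hz <= 0:
            raise ValueError("artifact frequencies must be positive")

    def validate_for_rate(self, frame_rate_fps: float) -> None:
        nyquist = frame_rate_fps / 2.0
        if self.heartbeat_hz >= nyquist or self.respiration_hz >= nyquist:
            raise ValueError(
                f"artifact frequencies must be below the Nyquist rate {nyquist} Hz"
            )

    @classmethod
    def none(cls) -> "ArtifactModel":
        return cls(heartbeat_amp=0.0, respiration_amp=0.0,
                   shot_noise_scale=0.0, drift_slope=0.0)


# ---------------------------------------------------------------------------
# synthetic scene / flow ground truth
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class VesselScene:
    """A static cortical-surface scene with superficial vessels.

    ``vessel_mask`` marks pixels inside vessels; ``parenchyma_mask`` is the
    complement of the dilated vessel mask (tissue clear of large vessels).
    ``centerlines`` are ordered (row, col) polylines, one per vessel,
    resampled at sub-pixel spacing.  ``baseline_image`` is the mean sensor
    intensity in counts.  ``arclength_px`` assigns each vessel pixel the
    arclength (in pixels) of its nearest centerline sample and is NaN
    elsewhere; ``vessel_id`` is -1 outside vessels.
    """

    vessel_mask: np.ndarray
    centerlines: list[np.ndarray]
    parenchyma_mask: np.ndarray
    baseline_image: np.ndarray
    arclength_px: np.ndarray
    vessel_id: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.baseline_image.shape


@dataclass(frozen=True)
class FlowGroundTruth:
    """Known erythrocyte-band kinematics for a simulated vessel movie.

    ``speed_mm_s`` may be a scalar (applied to all vessels) or one value per
    centerline.  ``band_spacing_um`` is the spatial period of the absorbance
    bands along the vessel axis, ``band_contrast`` their peak fractional
    darkening in (0, 1].
    """

    speed_mm_s: float | tuple[float, ...] = 0.7
    band_spacing_um: float = 60.0
    band_contrast: float = 0.3

    def __post_init__(self) -> None:
        speeds = np.atleast_1d(np.asarray(self.speed_mm_s, dtype=float))
        if np.any(speeds < 0):
            raise ValueError("speed_mm_s must be non-negative")
        if self.band_spacing_um <= 0:
            raise ValueError("band_spacing_um must be positive")
        if not 0 < self.band_contrast <= 1:
            raise ValueError("band_contrast must be in (0, 1]")

    def speed_for(self, vessel_index: int) -> float:
        speeds = np.atleast_1d(np.asarray(self.speed_mm_s, dtype=float))
        if speeds.size == 1:
            return float(speeds[0])
        return float(speeds[vessel_index])


# ---------------------------------------------------------------------------
# stacks, schedules, trials
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class FrameStack:
    """A grayscale movie with acquisition metadata, shaped ``(H, W, T)``."""

    data: np.ndarray
    frame_rate_fps: float = 132.82
    pixel_pitch_um: float = 7.5
    bit_depth: int = 16
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("FrameStack data must be (H, W, T)")
        if self.frame_rate_fps <= 0 or self.pixel_pitch_um <= 0:
            raise ValueError("frame rate and pixel pitch must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_fps

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_fps


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered stimulus onsets (frame indices) and the stimulus duration."""

    onset_frames: tuple[int, ...]
    duration_s: float = 1.5
    isi_range_s: tuple[float, float] = (90.0, 240.0)

    def __post_init__(self) -> None:
        onsets = tuple(int(f) for f in self.onset_frames)
        object.__setattr__(self, "onset_frames", onsets)
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("onset frames must be strictly increasing")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")

    @property
    def n_trials(self) -> int:
        return len(self.onset_frames)

    def onset_times_s(self, frame_rate_fps: float) -> np.ndarray:
        return np.asarray(self.onset_frames, dtype=float) / frame_rate_fps


@dataclass(eq=False)
class TrialTensor:
    """Per-trial fractional-change data, ``(n_trials, H, W, T)``.

    ``data`` holds dI/I0 relative to the per-pixel mean over each trial
    window, so each pixel's temporal mean is zero by construction.  The
    stimulus onset sits at frame index ``n_pre`` within every trial.
    Pixels that could not be normalised (non-positive mean intensity) are
    NaN and are excluded, never zero-filled, by downstream reductions.
    """

    data: np.ndarray
    n_pre: int
    frame_rate_fps: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("TrialTensor data must be (n_trials, H, W, T)")
        if not 0 <= self.n_pre <= self.data.shape[3]:
            raise ValueError("n_pre must lie within the trial window")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def t0_frame(self) -> int:
        return self.n_pre


# ---------------------------------------------------------------------------
# ROIs, maps, features
# ---------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class RoiSpec:
    """A rectangular ROI or a vessel polyline.

    Rectangles are ``(row, col, height, width)`` with the 20 x 20 px default
    used for parenchymal IOS traces; polylines are ordered (row, col) vertex
    arrays traced along a vessel lumen.
    """

    kind: str
    rect: tuple[int, int, int, int] | None = None
    points: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind == "rect":
            if self.rect is None:
                raise ValueError("rect ROI requires a (row, col, height, width) tuple")
            r, c, h, w = self.rect
            if h <= 0 or w <= 0:
                raise ValueError("ROI height and width must be positive")
        elif self.kind == "polyline":
            pts = np.asarray(self.points, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
                raise ValueError("polyline ROI requires >= 2 (row, col) points")
            object.__setattr__(self, "points", pts)
        else:
            raise ValueError(f"unknown ROI kind {self.kind!r}")

    @classmethod
    def rectangle(cls, row: int, col: int, height: int = 20, width: int = 20,
                  label: str = "") -> "RoiSpec":
        return cls(kind="rect", rect=(row, col, height, width), label=label)

    @classmethod
    def line(cls, points: Sequence[Sequence[float]], label: str = "") -> "RoiSpec":
        return cls(kind="polyline", points=np.asarray(points, dtype=float),
                   label=label)


@dataclass(eq=False)
class ActivityMapSet:
    """Time-binned mean dI/I0 maps with the display LUT range.

    ``maps`` is ``(n_maps, H, W)``; every map averages ``bin_frames``
    consecutive frames, and an incomplete tail bin is dropped.
    """

    maps: np.ndarray
    bin_frames: int
    lut_range: tuple[float, float]
    bin_duration_s: float | None = None

    @property
    def n_maps(self) -> int:
        return self.maps.shape[0]


#: Display LUT ranges (dI/I0) used for activity maps under each illumination.
LUT_GREEN: tuple[float, float] = (-2.3e-3, 1.5e-3)
LUT_RED: tuple[float, float] = (-0.5e-3, 0.5e-3)


@dataclass(frozen=True)
class ResponseFeatures:
    """Extrema of a triphasic IOS trace, measured from stimulus onset.

    Times are seconds, amplitudes dI/I0 relative to the prestimulus mean.
    ``significant`` applies the rule that the initial dip must exceed
    ``sd_threshold`` prestimulus standard deviations.  Fields are None when
    the trace admits no consistent dip < peak < undershoot ordering.
    """

    dip_time_s: float | None = None
    dip_amp: float | None = None
    peak_time_s: float | None = None
    peak_amp: float | None = None
    undershoot_time_s: float | None = None
    undershoot_amp: float | None = None
    significant: bool = False
    prestim_sd: float | None = None


# ---------------------------------------------------------------------------
# kymographs and flow estimates
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class Kymograph:
    """Position x time intensity matrix sampled along a vessel polyline.

    Rows index arclength (one resampled pixel step, physically
    ``arclength_step_um``), columns index frames.  Moving erythrocyte bands
    appear as diagonal striations whose slope (pixels/frame) equals
    tan(theta) in the flow-speed relation v = F * dP * tan(theta).
    """

    matrix: np.ndarray
    arclength_step_um: float
    frame_rate_fps: float
    polyline: RoiSpec | None = None

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2:
            raise ValueError("kymograph matrix must be 2-D (arclength x time)")
        if self.arclength_step_um <= 0:
            raise ValueError("arclength_step_um must be positive")


@dataclass(frozen=True)
class OrientationEstimate:
    """Result of striation-angle estimation on a kymograph.

    ``theta_rad`` is None when no dominant orientation was found (the
    isotropy score fell below the decision threshold); this is a
    no-estimate outcome, not an error.
    """

    theta_rad: float | None
    isotropy_score: float
    method: str

    @property
    def ok(self) -> bool:
        return self.theta_rad is not None


@dataclass(frozen=True)
class FlowEstimate:
    """A striation angle and the speed it implies via v = F * dP * tan|theta|."""

    theta_rad: float
    F_fps: float
    pitch_um: float
    speed_mm_s: float

    @classmethod
    def from_theta(cls, theta_rad: float, F_fps: float,
                   pitch_um: float) -> "FlowEstimate":
        speed = F_fps * pitch_um * math.tan(abs(theta_rad)) * 1e-3
        return cls(theta_rad=float(theta_rad), F_fps=float(F_fps),
                   pitch_um=float(pitch_um), speed_mm_s=speed)
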