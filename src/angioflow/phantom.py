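"""Synthetic flow-phantom simulator with known ground-truth flow.

Emulates a benchtop silicone-tube phantom imaged with a C-arm: a peristaltic
carrier flow, a power-injected contrast bolus (default 10/3 mL/s for 3 s
after a 1 s delay — 10 mL total), and an 8 s acquisition in subtracted (DSA,
low-noise) or unsubtracted (fluoroscopy, high-noise) mode at 3–10 samples/s.

Transport model: plug flow. The injection waveform is a rectangular pulse
diluted by the carrier to an inlet concentration ``Qi / (Qi + Q)`` and
advected along the tube at the mean velocity ``v = Q / A``, with Gaussian
longitudinal dispersion of variance ``2 D t`` (superposed step responses of
the 1-D advection–dispersion equation). The default dispersion coefficient
(15 cm^2/s) is sized from the shear-induced spreading of a plug in a 0.6 cm
tube at patent-access velocities (sigma_s ~ v t / sqrt(12) over sub-second
transits), which is what smears real first-pass time-density curves into
smooth right-skewed humps. Projection model: each pixel's
noise-free intensity is the chord length of the circular tube at the pixel's
perpendicular distance from the centerline, times the local concentration —
i.e. path-length-proportional attenuation in arbitrary detector units.

Tube configurations: STRAIGHT (vertical segment), ANGULAR (two straight legs
meeting at a stated interior angle), LOOP (segment + circular arc bulge +
segment). All paths keep the image row monotone along the flow so that
row-wise geometry extraction is well posed.
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np
from scipy import special
from scipy.spatial import cKDTree

from .imaging import ImageSequence, Modality, ROI

__all__ = [
    "TubeShape",
    "PhantomConfig",
    "ParametricPath",
    "GroundTruth",
    "make_path",
    "bolus_concentration",
    "render_sequence",
]

DSA_NOISE_FRAC = 0.05
FLUORO_NOISE_FRAC = 0.15  # 3x the DSA default: unsubtracted, low-dose beam


class TubeShape(str, enum.Enum):
    STRAIGHT = "STRAIGHT"
    ANGULAR = "ANGULAR"
    LOOP = "LOOP"


@dataclasses.dataclass(frozen=True)
class PhantomConfig:
    """Phantom and protocol parameters; the defaults are the study protocol.

    ``noise_sigma_frac`` is the per-pixel frame-noise SD as a fraction of the
    peak vessel signal; ``None`` selects the modality default (0.05 DSA,
    0.15 fluoroscopy). ``seed`` fixes all randomness.
    """

    tube_shape: TubeShape = TubeShape.STRAIGHT
    diameter_cm: float = 0.6
    true_flow_ml_min: float = 600.0
    injection_rate_ml_s: float = 10.0 / 3.0
    injection_duration_s: float = 3.0
    injection_delay_s: float = 1.0
    total_duration_s: float = 8.0
    sampling_rate_per_s: float = 6.0
    modality: Modality = Modality.DSA
    noise_sigma_frac: float | None = None
    dispersion_coeff_cm2_s: float = 15.0
    pixel_spacing_cm: float = 0.05
    image_shape: tuple = (512, 256)
    seed: int = 0
    recirculation_frac: float = 0.0  # optional delayed second pass, off by default
    recirculation_delay_s: float = 8.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "tube_shape", TubeShape(self.tube_shape))
        object.__setattr__(self, "modality", Modality(self.modality))
        positives = {
            "diameter_cm": self.diameter_cm,
            "true_flow_ml_min": self.true_flow_ml_min,
            "injection_rate_ml_s": self.injection_rate_ml_s,
            "injection_duration_s": self.injection_duration_s,
            "total_duration_s": self.total_duration_s,
            "sampling_rate_per_s": self.sampling_rate_per_s,
            "pixel_spacing_cm": self.pixel_spacing_cm,
        }
        for name, value in positives.items():
            if not value > 0:
                raise ValueError(f"{name} must be positive; got {value}")
        if self.injection_delay_s < 0 or self.dispersion_coeff_cm2_s < 0:
            raise ValueError("delay and dispersion coefficient must be non-negative")
        if self.injection_delay_s + self.injection_duration_s > self.total_duration_s:
            raise ValueError("injection delay + duration must fit inside the acquisition")
        if not (0.0 <= self.recirculation_frac < 1.0):
            raise ValueError("recirculation_frac must be in [0, 1)")

    @property
    def injected_volume_ml(self) -> float:
        return self.injection_rate_ml_s * self.injection_duration_s

    @property
    def n_frames(self) -> int:
        return int(round(self.total_duration_s * self.sampling_rate_per_s))

    @property
    def frame_interval_s(self) -> float:
        return 1.0 / self.sampling_rate_per_s

    @property
    def cross_section_cm2(self) -> float:
        return np.pi * (self.diameter_cm / 2.0) ** 2

    @property
    def mean_velocity_cm_s(self) -> float:
        """Plug-flow mean velocity: flow / (60 x cross-section area)."""
        return self.true_flow_ml_min / 60.0 / self.cross_section_cm2

    @property
    def inlet_concentration(self) -> float:
        """Relative iodine concentration after dilution by the carrier."""
        carrier_ml_s = self.true_flow_ml_min / 60.0
        return self.injection_rate_ml_s / (self.injection_rate_ml_s + carrier_ml_s)

    @property
    def noise_sigma(self) -> float:
        if self.noise_sigma_frac is not None:
            return float(self.noise_sigma_frac)
        return FLUORO_NOISE_FRAC if self.modality is Modality.FLUORO else DSA_NOISE_FRAC


@dataclasses.dataclass(frozen=True)
class ParametricPath:
    """Arc-length parameterized centerline, densely sampled in pixels."""

    points_px: np.ndarray  # (n, 2) of (row, col)
    pixel_spacing_cm: float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points_px, dtype=np.float64)
        seg = np.hypot(*np.diff(pts, axis=0).T)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        object.__setattr__(self, "points_px", pts)
        object.__setattr__(self, "_arc_px", arc)

    @property
    def arc_px(self) -> np.ndarray:
        return self._arc_px

    @property
    def arc_cm(self) -> np.ndarray:
        return self._arc_px * self.pixel_spacing_cm

    @property
    def arc_length_cm(self) -> float:
        return float(self._arc_px[-1] * self.pixel_spacing_cm)

    def point_at_s(self, s_cm: float) -> np.ndarray:
        """Interpolated (row, col) at arc position ``s_cm``."""
        s_px = np.asarray(s_cm, dtype=np.float64) / self.pixel_spacing_cm
        row = np.interp(s_px, self._arc_px, self.points_px[:, 0])
        col = np.interp(s_px, self._arc_px, self.points_px[:, 1])
        return np.stack([row, col], axis=-1)

    def s_at_row(self, row: float) -> float:
        """Arc position (cm) where the path crosses an image row (rows are
        monotone along every supported shape)."""
        rows = self.points_px[:, 0]
        if rows[0] > rows[-1]:
            return float(np.interp(row, rows[::-1], self.arc_cm[::-1]))
        return float(np.interp(row, rows, self.arc_cm))


_DENSE_STEP_PX = 0.25


def _segment(p0, p1):
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    n = max(2, int(np.ceil(np.hypot(*(p1 - p0)) / _DENSE_STEP_PX)) + 1)
    frac = np.linspace(0.0, 1.0, n)[:, None]
    return p0[None, :] + frac * (p1 - p0)[None, :]


def make_path(
    shape: TubeShape | str,
    image_shape: tuple,
    pixel_spacing_cm: float,
    margin_px: float = 16.0,
    bend_angle_deg: float = 120.0,
    loop_radius_px: float | None = None,
    loop_sweep_deg: float = 120.0,
) -> ParametricPath:
    """Centerline for a tube configuration, top-to-bottom through the image.

    STRAIGHT: one vertical segment. ANGULAR: two equal legs meeting at the
    interior angle ``bend_angle_deg`` (rows stay monotone for interior
    angles > 90 deg). LOOP: vertical segment, circular-arc bulge of sweep
    ``loop_sweep_deg`` and radius ``loop_radius_px``, vertical segment.
    Raises if the path (plus ``margin_px``) exceeds the image bounds.
    """
    shape = TubeShape(shape)
    rows_n, cols_n = image_shape
    top, bottom = margin_px, rows_n - 1 - margin_px
    mid_col = (cols_n - 1) / 2.0
    if bottom <= top:
        raise ValueError("image too small for the requested margin")

    if shape is TubeShape.STRAIGHT:
        pts = _segment((top, mid_col), (bottom, mid_col))
    elif shape is TubeShape.ANGULAR:
        if not 90.0 < bend_angle_deg < 180.0:
            raise ValueError("interior bend angle must be in (90, 180) deg to keep rows monotone")
        dev = np.deg2rad((180.0 - bend_angle_deg) / 2.0)
        mid_row = (top + bottom) / 2.0
        half_extent = (mid_row - top) * np.tan(dev)
        start = (top, mid_col - half_extent / 2.0)
        bend = (mid_row, mid_col + half_extent / 2.0)
        end = (bottom, mid_col - half_extent / 2.0)
        pts = np.vstack([_segment(start, bend), _segment(bend, end)[1:]])
    else:  # LOOP
        half_sweep = np.deg2rad(loop_sweep_deg) / 2.0
        if not 0 < half_sweep < np.pi / 2.0:
            raise ValueError("loop sweep must be in (0, 180) deg to keep rows monotone")
        mid_row = (top + bottom) / 2.0
        if loop_radius_px is not None:
            r = float(loop_radius_px)
        else:
            # arc occupies ~70% of the vertical span, capped by the lateral room
            r_vert = 0.35 * (bottom - top) / np.sin(half_sweep)
            r_horiz = 0.9 * (cols_n - 1 - 2 * margin_px) / (1.0 - np.cos(half_sweep))
            r = min(r_vert, r_horiz)
        span = r * (1.0 - np.cos(half_sweep))  # lateral bulge of the arc
        seg_col = mid_col - span / 2.0
        col_center = seg_col - r * np.cos(half_sweep)
        arc_top_row = mid_row - r * np.sin(half_sweep)
        arc_bot_row = mid_row + r * np.sin(half_sweep)
        if arc_top_row <= top or arc_bot_row >= bottom:
            raise ValueError("loop arc does not fit between the vertical segments")
        psi = np.linspace(-half_sweep, half_sweep, max(16, int(2 * half_sweep * r / _DENSE_STEP_PX)))
        arc = np.column_stack([mid_row + r * np.sin(psi), col_center + r * np.cos(psi)])
        pts = np.vstack(
            [
                _segment((top, seg_col), (arc_top_row, seg_col)),
                arc[1:],
                _segment((arc_bot_row, seg_col), (bottom, seg_col))[1:],
            ]
        )

    if (
        pts[:, 0].min() < margin_px - 1e-9
        or pts[:, 0].max() > rows_n - 1 - margin_px + 1e-9
        or pts[:, 1].min() < margin_px - 1e-9
        or pts[:, 1].max() > cols_n - 1 - margin_px + 1e-9
    ):
        raise ValueError("path exceeds the image bounds for the given margin")
    return ParametricPath(points_px=pts, pixel_spacing_cm=pixel_spacing_cm)


def _step_response(cfg: PhantomConfig, s_cm: np.ndarray, elapsed_s: np.ndarray) -> np.ndarray:
    """Concentration step response of the 1-D advection-dispersion transport:
    inlet held at unit concentration since ``elapsed`` seconds ago."""
    v = cfg.mean_velocity_cm_s
    d_coeff = cfg.dispersion_coeff_cm2_s
    s_cm, elapsed_s = np.broadcast_arrays(s_cm, elapsed_s)
    out = np.zeros(s_cm.shape, dtype=np.float64)
    active = elapsed_s > 0
    if not np.any(active):
        return out
    s_a, e_a = s_cm[active], elapsed_s[active]
    if d_coeff == 0.0:
        out[active] = np.where(s_a < v * e_a, 1.0, np.where(s_a == v * e_a, 0.5, 0.0))
    else:
        out[active] = 0.5 * special.erfc((s_a - v * e_a) / (2.0 * np.sqrt(d_coeff * e_a)))
    return out


def bolus_concentration(cfg: PhantomConfig, s_cm, t_s) -> np.ndarray:
    """Relative iodine concentration at path position ``s`` and time ``t``.

    Rectangular injection pulse over ``[delay, delay + duration]``, diluted
    to ``Qi / (Qi + Q)`` at the inlet, advected at the plug-flow mean
    velocity with Gaussian longitudinal dispersion (variance ``2 D t``).
    Non-negative everywhere; exactly zero before the injection delay.
    """
    s_cm = np.asarray(s_cm, dtype=np.float64)
    t_s = np.asarray(t_s, dtype=np.float64)
    t1 = cfg.injection_delay_s
    t2 = cfg.injection_delay_s + cfg.injection_duration_s
    conc = cfg.inlet_concentration * (
        _step_response(cfg, s_cm, t_s - t1) - _step_response(cfg, s_cm, t_s - t2)
    )
    if cfg.recirculation_frac > 0.0:
        lag = cfg.recirculation_delay_s
        conc = conc + cfg.recirculation_frac * cfg.inlet_concentration * (
            _step_response(cfg, s_cm, t_s - t1 - lag) - _step_response(cfg, s_cm, t_s - t2 - lag)
        )
    return np.maximum(conc, 0.0)


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """Everything the in-line flow sensor and the bench drawings would give:
    the true flow, the rendered tube mask, the centerline and its arc
    length, and analytic arrival times at any path position."""

    true_flow_ml_min: float
    tube_mask: np.ndarray
    path: ParametricPath
    mean_velocity_cm_s: float
    injection_delay_s: float
    roi1: ROI
    roi2: ROI
    s_roi1_cm: float
    s_roi2_cm: float

    @property
    def centerline_points(self) -> np.ndarray:
        return self.path.points_px

    @property
    def arc_length_cm(self) -> float:
        return self.path.arc_length_cm

    def arrival_time_s(self, s_cm) -> np.ndarray:
        """Bolus-front arrival time at arc position ``s`` (monotone in s)."""
        return self.injection_delay_s + np.asarray(s_cm, dtype=np.float64) / self.mean_velocity_cm_s

    def transit_time_s(self, s_from_cm: float, s_to_cm: float) -> float:
        """Ground-truth transit time between two path positions."""
        return (s_to_cm - s_from_cm) / self.mean_velocity_cm_s

    @property
    def roi_transit_time_s(self) -> float:
        return self.transit_time_s(self.s_roi1_cm, self.s_roi2_cm)


def _default_rois(path: ParametricPath, radius_px: float, image_shape: tuple):
    """ROIs centered on the path at 20% and 80% of the arc length."""
    half = int(np.ceil(radius_px)) + 2
    rois = []
    length = path.arc_length_cm
    for frac, label in ((0.2, "ROI1"), (0.8, "ROI2")):
        s = frac * length
        row, col = path.point_at_s(s)
        r0 = int(round(row)) - half
        c0 = int(round(col)) - half
        rois.append(
            (
                ROI(
                    row_start=max(r0, 0),
                    row_end=min(r0 + 2 * half + 1, image_shape[0]),
                    col_start=max(c0, 0),
                    col_end=min(c0 + 2 * half + 1, image_shape[1]),
                    label=label,
                ),
                s,
            )
        )
    return rois


def render_sequence(cfg: PhantomConfig) -> tuple[ImageSequence, GroundTruth]:
    """Render the phantom into an :class:`ImageSequence` plus ground truth.

    Same seed + config gives a bit-identical sequence. DSA frames have zero
    baseline and additive Gaussian noise; fluoroscopic frames put the
    darkened vessel on a bright constant background with 3x noisier frames
    (both polarity and noise level mirror the clinical ordering of the two
    modes).
    """
    radius_px = cfg.diameter_cm / 2.0 / cfg.pixel_spacing_cm
    margin = max(16.0, radius_px + 6.0)
    path = make_path(cfg.tube_shape, cfg.image_shape, cfg.pixel_spacing_cm, margin_px=margin)

    rows_n, cols_n = cfg.image_shape
    r_lo = max(0, int(np.floor(path.points_px[:, 0].min() - radius_px - 2)))
    r_hi = min(rows_n, int(np.ceil(path.points_px[:, 0].max() + radius_px + 3)))
    c_lo = max(0, int(np.floor(path.points_px[:, 1].min() - radius_px - 2)))
    c_hi = min(cols_n, int(np.ceil(path.points_px[:, 1].max() + radius_px + 3)))
    rr, cc = np.meshgrid(np.arange(r_lo, r_hi), np.arange(c_lo, c_hi), indexing="ij")
    pix = np.column_stack([rr.ravel(), cc.ravel()]).astype(np.float64)

    tree = cKDTree(path.points_px)
    dist_px, nearest_idx = tree.query(pix, k=1)
    inside = dist_px < radius_px
    pix_r = pix[inside, 0].astype(int)
    pix_c = pix[inside, 1].astype(int)
    chord_px = 2.0 * np.sqrt(radius_px**2 - dist_px[inside] ** 2)
    s_idx = nearest_idx[inside]

    mask = np.zeros(cfg.image_shape, dtype=bool)
    mask[pix_r, pix_c] = True

    times = np.arange(cfg.n_frames) * cfg.frame_interval_s
    arc_cm = path.arc_cm
    signal = np.zeros((cfg.n_frames,) + tuple(cfg.image_shape), dtype=np.float64)
    for k, t in enumerate(times):
        conc_on_path = bolus_concentration(cfg, arc_cm, t)
        signal[k, pix_r, pix_c] = chord_px * conc_on_path[s_idx]

    peak_signal = float(signal.max())
    rng = np.random.default_rng(cfg.seed)
    sigma = cfg.noise_sigma * peak_signal
    if cfg.modality is Modality.DSA:
        frames = signal
        if sigma > 0:
            frames = frames + rng.normal(0.0, sigma, signal.shape)
    else:
        background = 2.0 * max(peak_signal, 1.0)
        frames = background - signal
        if sigma > 0:
            frames = frames + rng.normal(0.0, sigma, signal.shape)

    seq = ImageSequence(
        frames=frames,
        frame_interval_s=cfg.frame_interval_s,
        pixel_spacing_cm=cfg.pixel_spacing_cm,
        modality=cfg.modality,
    )
    (roi1, s1), (roi2, s2) = _default_rois(path, radius_px, cfg.image_shape)
    truth = GroundTruth(
        true_flow_ml_min=cfg.true_flow_ml_min,
        tube_mask=mask,
        path=path,
        mean_velocity_cm_s=cfg.mean_velocity_cm_s,
        injection_delay_s=cfg.injection_delay_s,
        roi1=roi1,
        roi2=roi2,
        s_roi1_cm=s1,
        s_roi2_cm=s2,
    )
    return seq, truth
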