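"""Time-density curves: the sampled indicator-dilution signal at a ROI.

A time-density curve (TDC) is the spatial-mean contrast intensity inside a
rectangular ROI, one sample per frame. For fluoroscopy the sign is inverted
at extraction time (contrast attenuates the beam, darkening the vessel), so
that bolus passage is contrast-positive under a single convention for every
downstream fit and transit algorithm. Baseline correction subtracts the mean
of the designated pre-contrast samples; the default window is the number of
samples inside the injector's initial delay (1 s).
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path

import numpy as np

from .imaging import ImageSequence, Modality, ROI

__all__ = [
    "TimeDensityCurve",
    "extract_tdc",
    "baseline_correct",
    "default_pre_contrast_samples",
    "tdc_to_csv",
]


@dataclasses.dataclass(frozen=True)
class TimeDensityCurve:
    """Contrast intensity versus time at one ROI.

    ``times_s`` must be strictly increasing with constant spacing
    ``delta_t_s``; ``values`` are finite, in arbitrary (linear) units.
    """

    times_s: np.ndarray
    values: np.ndarray
    delta_t_s: float
    roi_label: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times_s, dtype=np.float64)
        values = np.asarray(self.values, dtype=np.float64)
        if times.ndim != 1 or values.shape != times.shape:
            raise ValueError("times_s and values must be 1-D arrays of equal length")
        if times.size < 2:
            raise ValueError("a time-density curve needs at least 2 samples")
        if not np.all(np.isfinite(values)):
            raise ValueError("TDC values contain non-finite entries")
        steps = np.diff(times)
        if np.any(steps <= 0):
            raise ValueError("TDC times must be strictly increasing")
        if not np.allclose(steps, self.delta_t_s, rtol=1e-6, atol=1e-12):
            raise ValueError("TDC times must be uniformly spaced by delta_t_s")
        object.__setattr__(self, "times_s", times)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "delta_t_s", float(self.delta_t_s))

    def __len__(self) -> int:
        return self.times_s.size

    def with_values(self, values: np.ndarray) -> "TimeDensityCurve":
        return TimeDensityCurve(self.times_s, values, self.delta_t_s, self.roi_label)


def extract_tdc(seq: ImageSequence, roi: ROI) -> TimeDensityCurve:
    """Average the ROI of every frame into a raw (uncorrected) TDC.

    The aggregate is the unweighted spatial mean, which makes the TDC
    amplitude invariant to ROI size — transit estimation depends on timing,
    not on absolute level. Fluoroscopic sequences are negated so that
    contrast arrival increases the value; no baseline correction is applied
    here.
    """
    roi.validate_within(seq.frame_shape)
    rs, cs = roi.slices
    values = seq.frames[:, rs, cs].mean(axis=(1, 2))
    if seq.modality is Modality.FLUORO:
        values = -values
    return TimeDensityCurve(
        times_s=seq.times_s,
        values=values,
        delta_t_s=seq.frame_interval_s,
        roi_label=roi.label,
    )


def default_pre_contrast_samples(delta_t_s: float, injection_delay_s: float = 1.0) -> int:
    """Number of samples inside the injection delay: ``floor(delay / Δt)``, at least 1."""
    return max(1, int(np.floor(injection_delay_s / delta_t_s)))


def baseline_correct(tdc: TimeDensityCurve, n_pre: int | None = None) -> TimeDensityCurve:
    """Subtract the mean of the first ``n_pre`` (pre-contrast) samples.

    ``n_pre`` defaults to the samples within the 1 s injection delay.
    Requires ``1 <= n_pre < len(tdc)``.
    """
    if n_pre is None:
        n_pre = default_pre_contrast_samples(tdc.delta_t_s)
    n_pre = int(n_pre)
    if not 1 <= n_pre < len(tdc):
        raise ValueError(f"n_pre must be in [1, {len(tdc) - 1}]; got {n_pre}")
    baseline = tdc.values[:n_pre].mean()
    return tdc.with_values(tdc.values - baseline)


def tdc_to_csv(tdc: TimeDensityCurve, path: str | os.PathLike) -> None:
    """Export as two-column CSV (time_s, value)."""
    header = "time_s,value"
    data = np.column_stack([tdc.times_s, tdc.values])
    np.savetxt(Path(path), data, delimiter=",", header=header, comments="")
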