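"""End-to-end flow measurement: TDC -> fit -> transit, geometry -> flow.

Volumetric flow is computed from the plug-flow indicator-transport relation

    Q [mL/min] = mean_area [cm^2] * path_length [cm] / tau [s] * 60

i.e. the mean velocity implied by the bolus transit between the two ROIs
times the mean circular cross-section, converted from mL/s with the factor
60. No parabolic-profile correction factor is applied.
"""

from __future__ import annotations

import dataclasses
import json
import os
from pathlib import Path

from .curvefit import FitModel, fit
from .errors import DegenerateMeasurementError, StageError
from .geometry import (
    DEFAULT_SPACING_PX,
    DEFAULT_THRESHOLD_FRAC,
    build_geometry,
    max_opacification_image,
)
from .imaging import ImageSequence, Modality, ROI
from .tdc import baseline_correct, default_pre_contrast_samples, extract_tdc
from .transit import DEFAULT_UPSAMPLE, TransitAlgorithm, transit_time_cc, transit_time_pp

__all__ = ["FlowResult", "compute_flow", "measure_flow", "measure_flow_multi", "MeasureConfig"]


@dataclasses.dataclass(frozen=True)
class MeasureConfig:
    """Tunable measurement settings with the study defaults."""

    threshold_frac: float = DEFAULT_THRESHOLD_FRAC
    spacing_px: int = DEFAULT_SPACING_PX
    upsample: int = DEFAULT_UPSAMPLE
    n_pre: int | None = None  # None -> samples within the 1 s injection delay
    median_size_px: int = 3

    @classmethod
    def from_dict(cls, config: dict | None) -> "MeasureConfig":
        if config is None:
            return cls()
        if isinstance(config, MeasureConfig):
            return config
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in config.items() if k in known})


@dataclasses.dataclass(frozen=True)
class FlowResult:
    """A flow measurement with full provenance of the method choices."""

    flow_ml_min: float
    tau_s: float
    path_length_cm: float
    mean_area_cm2: float
    algorithm: TransitAlgorithm
    fit_model: FitModel
    sampling_rate_per_s: float
    modality: Modality
    provenance: dict

    def to_json(self, path: str | os.PathLike | None = None) -> dict:
        record = dataclasses.asdict(self)
        record["algorithm"] = self.algorithm.value
        record["fit_model"] = self.fit_model.value
        record["modality"] = self.modality.value
        if path is not None:
            Path(path).write_text(json.dumps(record, indent=2))
        return record

    @classmethod
    def from_json(cls, record: dict | str | os.PathLike) -> "FlowResult":
        if not isinstance(record, dict):
            record = json.loads(Path(record).read_text())
        return cls(
            flow_ml_min=record["flow_ml_min"],
            tau_s=record["tau_s"],
            path_length_cm=record["path_length_cm"],
            mean_area_cm2=record["mean_area_cm2"],
            algorithm=TransitAlgorithm(record["algorithm"]),
            fit_model=FitModel(record["fit_model"]),
            sampling_rate_per_s=record["sampling_rate_per_s"],
            modality=Modality(record["modality"]),
            provenance=dict(record["provenance"]),
        )


def compute_flow(mean_area_cm2: float, path_length_cm: float, tau_s: float) -> float:
    """``Q = area * distance / tau * 60`` (cm^3/s -> mL/min). All inputs must
    be positive; zero transit time signals a degenerate measurement."""
    if tau_s <= 0:
        raise DegenerateMeasurementError(f"non-positive transit time tau = {tau_s} s")
    if mean_area_cm2 <= 0 or path_length_cm <= 0:
        raise DegenerateMeasurementError(
            f"non-positive geometry (area {mean_area_cm2} cm^2, length {path_length_cm} cm)"
        )
    return mean_area_cm2 * path_length_cm / tau_s * 60.0


def _stage(name: str):
    class _StageContext:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, exc) from exc
            return False

    return _StageContext()


def measure_flow_multi(
    seq: ImageSequence,
    roi1: ROI,
    roi2: ROI,
    combos: list,
    config: MeasureConfig | dict | None = None,
    collect_errors: bool = False,
) -> dict:
    """Measure flow for several (algorithm, fit model) combinations while
    sharing the TDC extraction, curve fits and geometry across them.

    ``combos`` is a list of ``(TransitAlgorithm, FitModel)`` pairs (string
    values accepted). Returns ``{(algorithm, fit_model): FlowResult}``.
    With ``collect_errors=True`` a failing combination maps to its
    :class:`StageError` instead of aborting the whole call (shared-stage
    failures still abort, since no combination can proceed without them).
    """
    cfg = MeasureConfig.from_dict(config)
    combos = [(TransitAlgorithm(a), FitModel(m)) for a, m in combos]
    n_pre = cfg.n_pre if cfg.n_pre is not None else default_pre_contrast_samples(
        seq.frame_interval_s
    )

    with _stage("tdc"):
        tdc1 = baseline_correct(extract_tdc(seq, roi1), n_pre)
        tdc2 = baseline_correct(extract_tdc(seq, roi2), n_pre)

    fits = {}
    for _, model in combos:
        if model in fits:
            continue
        try:
            with _stage("curvefit"):
                fits[model] = (fit(tdc1, model), fit(tdc2, model))
        except StageError as err:
            if collect_errors:
                fits[model] = err
            else:
                raise

    # transit before geometry: a zero transit time (identical/overlapping
    # ROIs) is reported as the degenerate measurement it is, not as a
    # geometry failure
    transits = {}
    for algorithm, model in combos:
        if isinstance(fits[model], StageError):
            transits[(algorithm, model)] = fits[model]
            continue
        c1, c2 = fits[model]
        try:
            with _stage("transit"):
                if algorithm is TransitAlgorithm.PP:
                    transit = transit_time_pp(c1, c2, cfg.upsample)
                else:
                    transit = transit_time_cc(c1, c2, cfg.upsample)
                if transit.tau_s == 0.0:
                    raise DegenerateMeasurementError(
                        "zero transit time between the ROIs (identical or overlapping ROIs?)"
                    )
        except StageError as err:
            if collect_errors:
                transits[(algorithm, model)] = err
                continue
            raise
        transits[(algorithm, model)] = transit

    with _stage("geometry"):
        opac = max_opacification_image(seq, n_pre)
        geom = build_geometry(
            opac,
            roi1,
            roi2,
            pixel_spacing_cm=seq.pixel_spacing_cm,
            spacing_px=cfg.spacing_px,
            threshold_frac=cfg.threshold_frac,
            median_size_px=cfg.median_size_px,
        )

    results = {}
    for algorithm, model in combos:
        transit = transits[(algorithm, model)]
        if isinstance(transit, StageError):
            results[(algorithm, model)] = transit
            continue
        c1, c2 = fits[model]
        try:
            with _stage("flow"):
                flow = compute_flow(geom.mean_area_cm2, geom.path_length_cm, transit.tau_s)
        except StageError as err:
            if collect_errors:
                results[(algorithm, model)] = err
                continue
            raise
        results[(algorithm, model)] = FlowResult(
            flow_ml_min=flow,
            tau_s=transit.tau_s,
            path_length_cm=geom.path_length_cm,
            mean_area_cm2=geom.mean_area_cm2,
            algorithm=algorithm,
            fit_model=model,
            sampling_rate_per_s=1.0 / seq.frame_interval_s,
            modality=seq.modality,
            provenance={
                "threshold_frac": cfg.threshold_frac,
                "spacing_px": cfg.spacing_px,
                "upsample": cfg.upsample,
                "n_pre": n_pre,
                "median_size_px": cfg.median_size_px,
                "effective_dt_s": transit.effective_dt_s,
                "roi1": dataclasses.asdict(roi1),
                "roi2": dataclasses.asdict(roi2),
                "fit_rmse_roi1": c1.rmse,
                "fit_rmse_roi2": c2.rmse,
            },
        )
    return results


def measure_flow(
    seq: ImageSequence,
    roi1: ROI,
    roi2: ROI,
    algorithm: TransitAlgorithm | str = TransitAlgorithm.CC,
    fit_model: FitModel | str = FitModel.GAMMA_VARIATE,
    config: MeasureConfig | dict | None = None,
) -> FlowResult:
    """Run the full measurement for one algorithm / fit-model choice.

    Stage failures propagate as :class:`StageError` labeled ``tdc``,
    ``curvefit``, ``transit``, ``geometry`` or ``flow``.
    """
    algorithm = TransitAlgorithm(algorithm)
    fit_model = FitModel(fit_model)
    results = measure_flow_multi(seq, roi1, roi2, [(algorithm, fit_model)], config)
    return results[(algorithm, fit_model)]
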