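"""Evaluation statistics and the simulation benchmark harness.

Accuracy is quantified as the absolute percent quantification error against
the ground-truth flow; agreement as Bland–Altman bias and limits of
agreement (bias ± 1.96 × SD of the paired differences) plus the Pearson
correlation of measured versus reference flow; and algorithm comparisons as
a two-sided paired Student t test on per-case errors. 95% confidence
intervals use the normal 1.96 multiplier throughout, consistent with the
limits-of-agreement convention.
"""

from __future__ import annotations

import dataclasses
import math
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .curvefit import FitModel
from .imaging import Modality
from .phantom import PhantomConfig, TubeShape, render_sequence
from .pipeline import MeasureConfig, measure_flow_multi
from .transit import TransitAlgorithm

__all__ = [
    "AgreementStats",
    "absolute_percent_error",
    "summarize_errors",
    "bland_altman",
    "paired_t_test",
    "run_benchmark",
]


@dataclasses.dataclass(frozen=True)
class AgreementStats:
    bias_ml_min: float
    loa_low_ml_min: float
    loa_high_ml_min: float
    pearson_r: float
    mqe_mean_pct: float
    mqe_sem_pct: float
    mqe_ci_low_pct: float
    mqe_ci_high_pct: float
    n: int


def absolute_percent_error(measured, reference):
    """``100 * |measured - reference| / reference`` (reference must be > 0)."""
    measured = np.asarray(measured, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if np.any(reference <= 0):
        raise ValueError("reference flow must be positive")
    out = 100.0 * np.abs(measured - reference) / reference
    return float(out) if out.ndim == 0 else out


class ErrorSummary(NamedTuple):
    mean: float
    sem: float
    ci_low: float
    ci_high: float


def summarize_errors(errors) -> ErrorSummary:
    """Mean, SEM (sample SD / sqrt(n)) and normal 95% CI of an error list."""
    errors = np.asarray(errors, dtype=np.float64)
    if errors.size < 2:
        raise ValueError("need at least 2 error values")
    mean = float(errors.mean())
    sem = float(errors.std(ddof=1) / math.sqrt(errors.size))
    return ErrorSummary(mean, sem, mean - 1.96 * sem, mean + 1.96 * sem)


def bland_altman(measured, reference) -> AgreementStats:
    """Bland–Altman bias and limits of agreement of measured vs reference,
    plus Pearson r and the mean-quantification-error summary."""
    measured = np.asarray(measured, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if measured.shape != reference.shape or measured.ndim != 1:
        raise ValueError("measured and reference must be 1-D arrays of equal length")
    n = measured.size
    if n < 2:
        raise ValueError("need at least 2 paired measurements")
    diffs = measured - reference
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if measured.std() == 0.0 or reference.std() == 0.0:
        r = float("nan")  # correlation undefined for a constant series
    else:
        r = float(sps.pearsonr(measured, reference).statistic)
    mqe = summarize_errors(absolute_percent_error(measured, reference))
    return AgreementStats(
        bias_ml_min=bias,
        loa_low_ml_min=bias - 1.96 * sd,
        loa_high_ml_min=bias + 1.96 * sd,
        pearson_r=r,
        mqe_mean_pct=mqe.mean,
        mqe_sem_pct=mqe.sem,
        mqe_ci_low_pct=mqe.ci_low,
        mqe_ci_high_pct=mqe.ci_high,
        n=n,
    )


class TTestResult(NamedTuple):
    t_statistic: float
    p_value: float
    degenerate: bool = False


def paired_t_test(errors_a, errors_b) -> TTestResult:
    """Two-sided paired Student t test on per-case error differences.

    Zero within-pair variance is degenerate: identical lists give
    ``(t=0, p=1)``, a constant nonzero difference gives ``(±inf, p=0)``,
    both flagged.
    """
    a = np.asarray(errors_a, dtype=np.float64)
    b = np.asarray(errors_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired test needs equal-length 1-D error lists on the same cases")
    if a.size < 2:
        raise ValueError("need at least 2 paired cases")
    diffs = a - b
    if float(diffs.std(ddof=1)) == 0.0:
        if float(diffs.mean()) == 0.0:
            return TTestResult(0.0, 1.0, degenerate=True)
        return TTestResult(math.copysign(math.inf, float(diffs.mean())), 0.0, degenerate=True)
    res = sps.ttest_rel(a, b)
    return TTestResult(float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------------------
# Benchmark harness


def _scenario_key(sc: dict):
    return (
        sc.get("tube_shape", TubeShape.STRAIGHT),
        sc.get("modality", Modality.DSA),
        sc.get("sampling_rate_per_s", 6.0),
        sc.get("noise_sigma_frac"),
        sc.get("diameter_cm", 0.6),
        sc.get("true_flow_ml_min"),
    )


def run_benchmark(
    scenarios: list,
    n_reps: int,
    seed: int,
    flow_range_ml_min: tuple = (300.0, 1000.0),
    measure_config: MeasureConfig | dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate and measure a grid of scenarios with paired phantoms.

    Each scenario is a dict with any of ``tube_shape``, ``modality``,
    ``sampling_rate_per_s``, ``noise_sigma_frac``, ``diameter_cm``,
    ``true_flow_ml_min`` (fixed flow; otherwise drawn uniformly from
    ``flow_range_ml_min`` per rep), plus ``algorithm`` and ``fit_model``.
    Scenarios sharing imaging settings are measured on the *same* rendered
    phantoms (same seeds, same drawn flows), so method comparisons are
    paired, as in a bench experiment where every algorithm sees the same
    acquisition. A fixed master ``seed`` makes the whole run reproducible
    row for row.

    Returns ``(summary, detail)``: per-scenario :class:`AgreementStats` rows
    (with a failure count — failed measurements are excluded, never
    imputed), and the per-rep measurements.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    scenarios = [dict(sc) for sc in scenarios]
    rng = np.random.default_rng(seed)
    drawn_flows = rng.uniform(*flow_range_ml_min, size=n_reps)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_reps)

    groups: dict = {}
    for idx, sc in enumerate(scenarios):
        groups.setdefault(_scenario_key(sc), []).append(idx)

    detail_rows = []
    for rep in range(n_reps):
        for key, members in groups.items():
            shape, modality, rate, noise, diameter, fixed_flow = key
            flow = float(fixed_flow) if fixed_flow is not None else float(drawn_flows[rep])
            cfg = PhantomConfig(
                tube_shape=shape,
                modality=modality,
                sampling_rate_per_s=rate,
                noise_sigma_frac=noise,
                diameter_cm=diameter,
                true_flow_ml_min=flow,
                seed=int(rep_seeds[rep]),
            )
            seq, truth = render_sequence(cfg)
            combos = [
                (scenarios[i].get("algorithm", TransitAlgorithm.CC),
                 scenarios[i].get("fit_model", FitModel.GAMMA_VARIATE))
                for i in members
            ]
            results = measure_flow_multi(
                seq, truth.roi1, truth.roi2, combos, measure_config, collect_errors=True
            )
            for i, combo in zip(members, combos):
                combo = (TransitAlgorithm(combo[0]), FitModel(combo[1]))
                res = results[combo]
                row = {
                    "scenario": i,
                    "rep": rep,
                    "true_flow_ml_min": flow,
                    "algorithm": combo[0].value,
                    "fit_model": combo[1].value,
                    "modality": Modality(modality).value,
                    "sampling_rate_per_s": rate,
                }
                if isinstance(res, Exception):
                    row["measured_flow_ml_min"] = np.nan
                    row["error"] = str(res)
                else:
                    row["measured_flow_ml_min"] = res.flow_ml_min
                    row["error"] = ""
                detail_rows.append(row)

    detail = pd.DataFrame(detail_rows)
    summary_rows = []
    for i, sc in enumerate(scenarios):
        sub = detail[detail["scenario"] == i]
        ok = sub[sub["error"] == ""]
        row = {
            "scenario": i,
            "algorithm": TransitAlgorithm(sc.get("algorithm", TransitAlgorithm.CC)).value,
            "fit_model": FitModel(sc.get("fit_model", FitModel.GAMMA_VARIATE)).value,
            "modality": Modality(sc.get("modality", Modality.DSA)).value,
            "sampling_rate_per_s": sc.get("sampling_rate_per_s", 6.0),
            "n_failed": int(len(sub) - len(ok)),
        }
        if len(ok) >= 2:
            ag = bland_altman(
                ok["measured_flow_ml_min"].to_numpy(), ok["true_flow_ml_min"].to_numpy()
            )
            row.update(dataclasses.asdict(ag))
        elif len(ok) == 1:
            row.update({"n": 1, "mqe_mean_pct": float(absolute_percent_error(
                ok["measured_flow_ml_min"].iloc[0], ok["true_flow_ml_min"].iloc[0]
            ))})
        else:
            row.update({"n": 0})
        summary_rows.append(row)
    return pd.DataFrame(summary_rows), detail
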