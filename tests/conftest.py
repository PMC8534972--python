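"""Shared fixtures: seeded phantom ensembles reused across test modules.

The ensembles simulate the bench protocol (straight silicone tube, flows
drawn uniformly from the patent-access range 300-1000 mL/min, default
modality noise) and measure every phantom with several algorithm/fit
combinations on the *same* rendered acquisition, so method comparisons are
paired. They are session-scoped because rendering 50 phantoms is the
expensive part of the suite.
"""

from __future__ import annotations

import numpy as np
import pytest

import angioflow as af
from angioflow import FitModel as FM
from angioflow import TransitAlgorithm as TA

ENSEMBLE_N = 50
_MASTER_SEED = 12345

CC_GV = (TA.CC, FM.GAMMA_VARIATE)
PP_GV = (TA.PP, FM.GAMMA_VARIATE)
CC_RAW = (TA.CC, FM.NONE)
PP_RAW = (TA.PP, FM.NONE)


def run_ensemble(modality, rate, combos, n=ENSEMBLE_N, master_seed=_MASTER_SEED):
    """Render-and-measure an ensemble; same master seed -> same flows and
    phantom seeds, so ensembles at different rates/modalities are paired."""
    rng = np.random.default_rng(master_seed)
    flows = rng.uniform(300.0, 1000.0, n)
    seeds = rng.integers(0, 2**31 - 1, n)
    records = []
    for i in range(n):
        cfg = af.PhantomConfig(
            true_flow_ml_min=float(flows[i]),
            modality=modality,
            sampling_rate_per_s=rate,
            seed=int(seeds[i]),
        )
        seq, truth = af.render_sequence(cfg)
        results = af.measure_flow_multi(
            seq, truth.roi1, truth.roi2, combos, collect_errors=True
        )
        records.append(
            {
                "true_flow": float(flows[i]),
                "tau_true": truth.roi_transit_time_s,
                "results": results,
            }
        )
    return records


def collect_apes(records, combo):
    """Absolute percent errors for one combo; failures excluded."""
    apes = []
    for rec in records:
        res = rec["results"][combo]
        if not isinstance(res, Exception):
            apes.append(af.absolute_percent_error(res.flow_ml_min, rec["true_flow"]))
    return np.asarray(apes)


def count_failures(records, combo):
    return sum(1 for rec in records if isinstance(rec["results"][combo], Exception))


def collect_tau_errors(records, combo):
    """|tau_measured - tau_true| per rep; a degenerate (tau = 0) failure
    counts as an error of tau_true."""
    errs = []
    for rec in records:
        res = rec["results"][combo]
        if isinstance(res, Exception):
            errs.append(rec["tau_true"])
        else:
            errs.append(abs(res.tau_s - rec["tau_true"]))
    return np.asarray(errs)


@pytest.fixture(scope="session")
def dsa6_ensemble():
    """50 straight-tube DSA phantoms at 6 F/s, measured with CC/PP x GV/raw."""
    return run_ensemble(af.Modality.DSA, 6.0, [CC_GV, PP_GV, CC_RAW, PP_RAW])


@pytest.fixture(scope="session")
def dsa3_ensemble():
    """Same flows and seeds at 3 F/s (paired with dsa6_ensemble), CC + GV."""
    return run_ensemble(af.Modality.DSA, 3.0, [CC_GV])


@pytest.fixture(scope="session")
def fluoro10_ensemble():
    """50 straight-tube fluoroscopic phantoms at 10 P/s, CC + GV."""
    return run_ensemble(af.Modality.FLUORO, 10.0, [CC_GV])


@pytest.fixture(scope="session")
def quiet_phantom():
    """One noise-free straight-tube DSA phantom at the protocol defaults."""
    cfg = af.PhantomConfig(true_flow_ml_min=600.0, noise_sigma_frac=0.0, seed=11)
    seq, truth = af.render_sequence(cfg)
    return cfg, seq, truth
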