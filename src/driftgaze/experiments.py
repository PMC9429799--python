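"""Replication experiments: recovery and calibration studies run end to end.

These drivers generate synthetic experiments with the study's design,
push them through the fitting or time-course machinery, and score the
outcome against the generating truth. They are what the acceptance
checks and the power/calibration tests call; problem sizes default to
desk-scale settings chosen to finish on one CPU in minutes (documented
in docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import FitOptions, fit_all_variants, fit_variant, information_weights
from .params import CONDITIONS, VariantSpec, all_variants
from .smart import SmartConfig, cluster_permutation_test, smooth_participant
from .synth import SyntheticConfig, generate_session

#: lean fitting options for batch experiments (accuracy/runtime trade-off
#: validated by the parameter-recovery study itself)
LEAN_FIT = dict(restarts=1, rounds=2, maxfev_per_dim=30, n_grid=128, n_sz=5, n_st0=5)
#: stronger options for single-variant recovery fits
RECOVERY_FIT = dict(restarts=2, rounds=2, maxfev_per_dim=50, n_grid=160, n_sz=5, n_st0=5)


@dataclass
class RecoveryResult:
    """Parameter-recovery study outcome."""

    errors: pd.DataFrame  # participant x condition v / t0 errors
    v_mae: float
    t0_mae_ms: float
    v_bias: float
    t0_bias_ms: float
    n_participants: int


def parameter_recovery_experiment(
    n_participants: int = 12,
    seed: int = 0,
    trials_per_condition: int = 256,
    options: FitOptions | None = None,
) -> RecoveryResult:
    """Simulate from the default truth and refit the generating variant.

    Group-mean absolute errors of the drift rate and non-decision time
    estimates (across participants and conditions) quantify recovery.
    """
    cfg = SyntheticConfig(
        n_participants=n_participants,
        trials_per_condition=trials_per_condition,
        seed=seed,
    )
    sess = generate_session(cfg)
    opts = options or FitOptions(seed=seed, **RECOVERY_FIT)
    variant = VariantSpec(frozenset({"v", "t0"}))
    rows = []
    for pid in sess.participants:
        fit = fit_variant(sess.for_participant(pid), variant, opts)
        truth = sess.metadata["true_params"][pid]
        for c in CONDITIONS:
            est = fit.params_by_condition[c]
            rows.append(
                {"participant_id": pid, "condition": c,
                 "v_err": est.v - truth[c]["v"],
                 "t0_err_ms": 1000 * (est.t0 - truth[c]["t0"])}
            )
    err = pd.DataFrame(rows)
    return RecoveryResult(
        errors=err,
        v_mae=float(err["v_err"].abs().mean()),
        t0_mae_ms=float(err["t0_err_ms"].abs().mean()),
        v_bias=float(err["v_err"].mean()),
        t0_bias_ms=float(err["t0_err_ms"].mean()),
        n_participants=n_participants,
    )


@dataclass
class SelectionResult:
    """Model-selection recovery over seeded replicate experiments."""

    replicate_winners: list
    win_rate: float  # fraction of replicates whose mean weight peaks at {v, t0}
    mean_weights: pd.DataFrame  # replicate x variant mean information weights
    n_participants: int


def model_selection_experiment(
    n_replicates: int = 20,
    n_participants: int = 6,
    seed: int = 0,
    options: FitOptions | None = None,
) -> SelectionResult:
    """Replicate the eight-variant comparison on data generated under {v, t0}.

    Each replicate simulates a fresh cohort, fits all eight variants per
    participant, and records which variant attains the highest mean BIC
    information weight.
    """
    names = [v.name for v in all_variants()]
    winners, rows = [], []
    for rep in range(n_replicates):
        rep_seed = seed + 7919 * rep  # fixed stride keeps replicates disjoint
        sess = generate_session(
            SyntheticConfig(n_participants=n_participants, seed=rep_seed)
        )
        opts = options or FitOptions(seed=rep_seed % 2**31, **LEAN_FIT)
        W = []
        for pid in sess.participants:
            fits = fit_all_variants(sess.for_participant(pid), opts)
            W.append(information_weights([fits[n].bic for n in names]))
        mean_w = np.asarray(W).mean(axis=0)
        winners.append(names[int(np.argmax(mean_w))])
        rows.append(dict(zip(names, mean_w)))
    return SelectionResult(
        replicate_winners=winners,
        win_rate=float(np.mean([w == "v+t0" for w in winners])),
        mean_weights=pd.DataFrame(rows),
        n_participants=n_participants,
    )


@dataclass
class SmartCalibrationResult:
    false_positive_rate: float
    n_simulations: int
    detection_rate: float  # injected-effect runs with an overlapping cluster
    n_injection_runs: int


def _null_curves(n_participants, trials_per_participant, grid_cfg, rng):
    curves_a, wa, curves_b, wb = [], [], [], []
    for _ in range(n_participants):
        half = trials_per_participant // 2
        for curves, ws in [(curves_a, wa), (curves_b, wb)]:
            rt = rng.uniform(grid_cfg.t_min + 20, grid_cfg.t_max - 50, half)
            y = rng.integers(0, 2, half).astype(float)
            c, w = smooth_participant(rt, y, grid_cfg)
            curves.append(c)
            ws.append(w)
    return curves_a, wa, curves_b, wb


def smart_calibration_experiment(
    n_simulations: int = 500,
    n_participants: int = 12,
    trials_per_participant: int = 200,
    n_permutations: int = 200,
    n_injection_runs: int = 20,
    effect: float = 0.3,
    effect_window=(400.0, 600.0),
    seed: int = 0,
) -> SmartCalibrationResult:
    """Type-I error and sensitivity of the cluster permutation test.

    Null simulations draw outcome labels independent of response time and
    count experiments with any significant cluster; injection runs add a
    step effect on a known window to one condition and count runs whose
    strongest significant cluster overlaps that window.
    """
    rng = np.random.default_rng(seed)
    false_pos = 0
    for i in range(n_simulations):
        cfg = SmartConfig(n_permutations=n_permutations, seed=int(rng.integers(2**31)))
        A, wa, B, wb = _null_curves(n_participants, trials_per_participant, cfg, rng)
        res = cluster_permutation_test(A, wa, B, wb, cfg)
        false_pos += any(c.p < cfg.alpha for c in res.clusters)

    detected = 0
    for i in range(n_injection_runs):
        cfg = SmartConfig(n_permutations=n_permutations, seed=int(rng.integers(2**31)))
        curves_a, wa, curves_b, wb = [], [], [], []
        half = trials_per_participant // 2
        lo, hi = effect_window
        for _ in range(n_participants):
            rt_a = rng.uniform(cfg.t_min + 20, cfg.t_max - 50, half)
            in_win = (rt_a >= lo) & (rt_a <= hi)
            p_a = np.where(in_win, 0.5 + effect, 0.5)
            y_a = (rng.uniform(size=half) < p_a).astype(float)
            c, w = smooth_participant(rt_a, y_a, cfg)
            curves_a.append(c)
            wa.append(w)
            rt_b = rng.uniform(cfg.t_min + 20, cfg.t_max - 50, half)
            y_b = rng.integers(0, 2, half).astype(float)
            c, w = smooth_participant(rt_b, y_b, cfg)
            curves_b.append(c)
            wb.append(w)
        res = cluster_permutation_test(curves_a, wa, curves_b, wb, cfg)
        sig = [c for c in res.clusters if c.p < cfg.alpha]
        detected += any(c.start_ms <= hi and c.end_ms >= lo for c in sig)

    return SmartCalibrationResult(
        false_positive_rate=false_pos / n_simulations,
        n_simulations=n_simulations,
        detection_rate=detected / n_injection_runs,
        n_injection_runs=n_injection_runs,
    )
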