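"""Per-participant diffusion-model fitting by the Kolmogorov–Smirnov criterion.

Eight model variants are fitted per participant: drift rate, boundary
separation and non-decision time — or any combination of the three — may
take condition-specific values, while the starting point and the three
variability components are always shared across conditions. Each variant
is optimised by minimising the trial-count-weighted sum of per-condition
KS distances between the empirical and predicted signed-RT distributions
(``+RT`` for face choices, ``-RT`` for noise choices). Model comparison
uses BIC information weights, with the log-likelihood evaluated at the
KS-fitted parameters.

The KS objective is non-smooth, so optimisation uses a Nelder–Mead simplex
on an unconstrained reparameterisation (log for scale parameters, logistic
for bounded ones) with seeded jittered restarts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .params import CONDITIONS, DDMParams, VariantSpec, all_variants
from .wiener import SignedRTPrediction, batch_signed_predictions

logger = logging.getLogger(__name__)

_MARGIN = 0.98  # keeps zr +- sz/2 and t0 +- st0/2 strictly inside their ranges


@dataclass
class FitOptions:
    """Knobs of the KS fit; defaults trade accuracy against runtime."""

    restarts: int = 3  # optimiser starts per variant (first may be a warm start)
    rounds: int = 2  # chained simplex runs per start (rebuilds a stale simplex)
    seed: int = 0  # start-point jitter stream; fixes the fit completely
    jitter: float = 0.25  # SD of the start-point jitter (transformed scale)
    simplex_step: float = 0.25  # initial simplex edge (transformed scale)
    maxfev_per_dim: int = 50  # simplex budget per free dimension and round
    xatol: float = 2e-3
    fatol: float = 1e-4
    trial_floor: int = 40  # minimal trials per condition to attempt a fit
    n_grid: int = 256  # CDF tabulation points
    n_sz: int = 7  # Gauss-Legendre nodes for starting-point variability
    n_st0: int = 7  # Gauss-Legendre nodes for non-decision-time variability
    density_floor: float = 1e-10  # likelihood floor per trial for BIC
    criterion: str = "ks"  # "ks" or "ml"


@dataclass
class VariantFit:
    """One fitted variant for one participant."""

    variant: VariantSpec
    params_by_condition: dict
    objective: float
    ks_by_condition: dict
    log_likelihood: float
    bic: float
    n_trials: int
    converged: bool
    restart_objectives: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.variant.k


def signed_rt_seconds(trials: pd.DataFrame) -> np.ndarray:
    """Signed response variable in seconds: +RT face, -RT noise choices."""
    rt = trials["fixation_duration_ms"].to_numpy(float) / 1000.0
    sign = np.where(trials["choice"].to_numpy() == "face", 1.0, -1.0)
    return sign * rt


def ks_statistic(trials, params: DDMParams, **pred_kw) -> float:
    """Sup-distance between the empirical and predicted signed-RT CDFs.

    ``trials`` is a DataFrame with ``choice`` and ``fixation_duration_ms``
    columns, or a 1-d array of signed RTs in seconds. The predicted CDF is
    evaluated on both sides of every empirical jump.
    """
    if isinstance(trials, pd.DataFrame):
        x = signed_rt_seconds(trials)
    else:
        x = np.asarray(trials, float)
    if x.size == 0:
        raise ValueError("KS statistic needs at least one trial")
    pred = SignedRTPrediction(params, **pred_kw)
    return _ks_sorted(np.sort(x), pred)


def _ks_sorted(xs: np.ndarray, pred: SignedRTPrediction) -> float:
    n = xs.size
    F = pred.cdf(xs)
    i = np.arange(1, n + 1)
    return float(max(np.abs(F - i / n).max(), np.abs(F - (i - 1) / n).max()))


# ---------------------------------------------------------------------------
# parameter vector <-> condition parameter sets
# ---------------------------------------------------------------------------

def _layout(variant: VariantSpec):
    """(name, n_slots) pairs in packing order."""
    return [
        ("a", 4 if "a" in variant.free else 1),
        ("zr", 1),
        ("v", 4 if "v" in variant.free else 1),
        ("t0", 4 if "t0" in variant.free else 1),
        ("sv", 1),
        ("sz", 1),
        ("st0", 1),
    ]


def n_free(variant: VariantSpec) -> int:
    return sum(n for _, n in _layout(variant))


def _unpack(x: np.ndarray, variant: VariantSpec) -> dict:
    """Unconstrained vector -> legal per-condition parameter sets."""
    vals, i = {}, 0
    for name, n in _layout(variant):
        vals[name] = x[i : i + n]
        i += n
    a = np.exp(vals["a"])
    zr = float(expit(vals["zr"][0]))
    v = vals["v"]
    t0 = np.exp(vals["t0"])
    sv = float(np.exp(vals["sv"][0]))
    sz = float(expit(vals["sz"][0])) * 2 * min(zr, 1 - zr) * _MARGIN
    st0 = float(expit(vals["st0"][0])) * 2 * float(t0.min()) * _MARGIN
    out = {}
    for ci, cond in enumerate(CONDITIONS):
        out[cond] = DDMParams(
            a=float(a[ci % len(a)]),
            zr=zr,
            v=float(v[ci % len(v)]),
            t0=float(t0[ci % len(t0)]),
            sv=sv,
            sz=sz,
            st0=st0,
        )
    return out


def _pack(guess: dict, variant: VariantSpec) -> np.ndarray:
    """Per-condition parameter guess -> unconstrained start vector."""

    def _logit(p):
        return float(logit(np.clip(p, 1e-4, 1 - 1e-4)))

    first = guess[CONDITIONS[0]]
    zr = first.zr
    t0_min = min(guess[c].t0 for c in CONDITIONS)
    x = []
    for name, n in _layout(variant):
        if name == "a":
            x += [np.log(guess[c].a) for c in CONDITIONS[:n]]
        elif name == "zr":
            x.append(_logit(zr))
        elif name == "v":
            x += [guess[c].v for c in CONDITIONS[:n]]
        elif name == "t0":
            x += [np.log(max(guess[c].t0, 1e-3)) for c in CONDITIONS[:n]]
        elif name == "sv":
            x.append(np.log(max(first.sv, 1e-3)))
        elif name == "sz":
            x.append(_logit(first.sz / (2 * min(zr, 1 - zr) * _MARGIN)))
        elif name == "st0":
            x.append(_logit(first.st0 / (2 * max(t0_min, 1e-3) * _MARGIN)))
    return np.asarray(x, float)


def _heuristic_start(data: dict) -> dict:
    """Method-of-moments style start from per-condition choice and RT."""
    guess = {}
    for cond in CONDITIONS:
        x = data[cond]
        n = x.size
        pf = np.clip((x > 0).mean(), 1 / (n + 2), 1 - 1 / (n + 2))
        v0 = float(np.log(pf / (1 - pf)))  # inverts the a=1, zr=.5 choice rule
        rt = np.abs(x)
        t0_0 = float(0.85 * np.quantile(rt, 0.02))
        guess[cond] = DDMParams(
            a=1.0, zr=0.5, v=v0, t0=t0_0, sv=0.3, sz=0.1, st0=min(0.08, t0_0)
        )
    return guess


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _prepare_data(trials: pd.DataFrame, floor: int) -> dict:
    data = {}
    for cond in CONDITIONS:
        sub = trials[trials["condition"] == cond]
        if len(sub) < floor:
            raise ValueError(
                f"condition {cond} has {len(sub)} trials; "
                f"at least {floor} are required (see FitOptions.trial_floor)"
            )
        data[cond] = np.sort(signed_rt_seconds(sub))
    return data


def _objective_factory(data: dict, variant: VariantSpec, opts: FitOptions):
    n_by_cond = {c: data[c].size for c in CONDITIONS}
    n_total = sum(n_by_cond.values())

    def objective(x):
        params = _unpack(x, variant)
        unique = list({params[c] for c in CONDITIONS})
        try:
            built = batch_signed_predictions(
                unique, n_grid=opts.n_grid, n_sz=opts.n_sz, n_st0=opts.n_st0
            )
        except (ValueError, FloatingPointError):
            return 2.0  # illegal corner of the transformed space
        preds = dict(zip(unique, built))
        total = 0.0
        for cond in CONDITIONS:
            pred = preds[params[cond]]
            if opts.criterion == "ml":
                ll = pred.log_density(
                    np.abs(data[cond]), data[cond] > 0, floor=opts.density_floor
                ).sum()
                total += -ll / n_total
            else:
                total += n_by_cond[cond] / n_total * _ks_sorted(data[cond], pred)
        return total

    return objective


def log_likelihood(
    trials: pd.DataFrame, params_by_condition: dict, floor: float = 0.0, **pred_kw
) -> float:
    """Total log first-passage density of all trials at the given parameters."""
    total = 0.0
    for cond in CONDITIONS:
        sub = trials[trials["condition"] == cond]
        if not len(sub):
            continue
        x = signed_rt_seconds(sub)
        pred = SignedRTPrediction(params_by_condition[cond], **pred_kw)
        total += float(pred.log_density(np.abs(x), x > 0, floor=floor).sum())
    return total


def ml_objective(trials: pd.DataFrame, params_by_condition: dict, **pred_kw) -> float:
    """Negative log-likelihood; +inf (with the trials logged) on zero density.

    The maximum-likelihood criterion is exposed as a non-default fitting
    option for robustness comparisons; unlike the KS distance it diverges
    on any response faster than the minimal non-decision time.
    """
    nll = 0.0
    for cond in CONDITIONS:
        sub = trials[trials["condition"] == cond]
        if not len(sub):
            continue
        x = signed_rt_seconds(sub)
        pred = SignedRTPrediction(params_by_condition[cond], **pred_kw)
        lp = pred.log_density(np.abs(x), x > 0, floor=0.0)
        if np.any(np.isneginf(lp)):
            bad = sub.index[np.isneginf(lp)].tolist()
            logger.warning(
                "zero first-passage density in condition %s at trials %s",
                cond,
                bad[:10],
            )
            return float("inf")
        nll -= float(lp.sum())
    return nll


def fit_variant(
    trials: pd.DataFrame,
    variant: VariantSpec,
    options: FitOptions | None = None,
    x0: np.ndarray | None = None,
) -> VariantFit:
    """Fit one variant to one participant's trials.

    ``x0`` optionally warm-starts the first restart (used when fitting the
    whole family, where richer variants start from the nested fit).
    Deterministic for fixed ``options.seed``.
    """
    opts = options or FitOptions()
    data = _prepare_data(trials, opts.trial_floor)
    objective = _objective_factory(data, variant, opts)
    ndim = n_free(variant)
    rng = np.random.default_rng(opts.seed)

    base = _pack(_heuristic_start(data), variant)
    starts = []
    if x0 is not None:
        starts.append(np.asarray(x0, float))
    starts.append(base)
    while len(starts) < opts.restarts:
        starts.append(base + opts.jitter * rng.standard_normal(ndim))
    starts = starts[: max(opts.restarts, 1)]

    best, best_x, restart_objs, any_conv = np.inf, None, [], False
    for s in starts:
        x_cur, f_cur, conv = s, np.inf, False
        step = opts.simplex_step
        for _ in range(max(opts.rounds, 1)):
            # explicit simplex: a fixed edge per coordinate, halved each
            # chained round (the default pct-based simplex degenerates for
            # coordinates starting at zero)
            simplex = np.vstack([x_cur, x_cur + step * np.eye(ndim)])
            res = minimize(
                objective,
                x_cur,
                method="Nelder-Mead",
                options=dict(
                    maxfev=opts.maxfev_per_dim * ndim,
                    xatol=opts.xatol,
                    fatol=opts.fatol,
                    initial_simplex=simplex,
                ),
            )
            step /= 2
            x_cur, conv = res.x, bool(res.success)
            if res.fun >= f_cur - opts.fatol:  # chained round stalled
                f_cur = min(f_cur, float(res.fun))
                break
            f_cur = float(res.fun)
        restart_objs.append(f_cur)
        any_conv = any_conv or conv
        if f_cur < best:
            best, best_x = f_cur, x_cur

    params = _unpack(best_x, variant)
    slot_names = [name for name, n in _layout(variant) for _ in range(n)]
    warnings = sorted(
        {
            f"{name} near transform bound"
            for name, xv in zip(slot_names, best_x)
            if name != "v" and abs(xv) > 8
        }
    )
    if not any_conv:
        warnings.append("no restart reached the simplex convergence tolerance")
    pred_kw = dict(n_grid=max(opts.n_grid, 384), n_sz=opts.n_sz, n_st0=opts.n_st0)
    ks_by_cond = {
        c: _ks_sorted(data[c], SignedRTPrediction(params[c], **pred_kw))
        for c in CONDITIONS
    }
    ll = log_likelihood(trials, params, floor=opts.density_floor, **pred_kw)
    n = sum(len(data[c]) for c in CONDITIONS)
    bic = -2.0 * ll + variant.k * np.log(n)
    return VariantFit(
        variant=variant,
        params_by_condition=params,
        objective=best,
        ks_by_condition=ks_by_cond,
        log_likelihood=ll,
        bic=float(bic),
        n_trials=n,
        converged=any_conv,
        restart_objectives=restart_objs,
        warnings=warnings,
    )


def _expand_warm_start(fit: VariantFit, variant: VariantSpec) -> np.ndarray:
    """Start vector for ``variant`` from a fitted nested variant."""
    return _pack(fit.params_by_condition, variant)


def _project_params(fit: VariantFit, variant: VariantSpec) -> dict:
    """Project a richer fit onto a nested variant by pooling freed values."""
    pooled = {}
    for name in ("a", "v", "t0"):
        if name not in variant.free:
            pooled[name] = float(
                np.mean([getattr(fit.params_by_condition[c], name) for c in CONDITIONS])
            )
    src = fit.params_by_condition
    first = src[CONDITIONS[0]]
    st0_cap = 2 * min(pooled.get("t0", min(src[c].t0 for c in CONDITIONS)), *(src[c].t0 for c in CONDITIONS))
    out = {}
    for c in CONDITIONS:
        out[c] = DDMParams(
            a=pooled.get("a", src[c].a),
            zr=first.zr,
            v=pooled.get("v", src[c].v),
            t0=pooled.get("t0", src[c].t0),
            sv=first.sv,
            sz=first.sz,
            st0=min(first.st0, st0_cap * _MARGIN),
        )
    return out


def fit_all_variants(
    trials: pd.DataFrame, options: FitOptions | None = None
) -> dict[str, VariantFit]:
    """Fit the full eight-variant family for one participant.

    Variants are fitted in order of increasing parameter count, each
    warm-started from the best already-fitted variant it nests. A repair
    pass then re-fits any variant whose objective exceeds that of a richer
    variant nesting it (which a converged fit cannot), warm-started from
    the richer fit projected onto the nested parameter space.
    """
    opts = options or FitOptions()
    fits: dict[str, VariantFit] = {}
    for variant in all_variants():
        x0 = None
        nested = [
            f
            for f in fits.values()
            if variant.nests(f.variant) and f.variant != variant
        ]
        if nested:
            donor = min(nested, key=lambda f: f.objective)
            x0 = _expand_warm_start(donor, variant)
        fits[variant.name] = fit_variant(trials, variant, opts, x0=x0)

    # repair pass: a richer variant can never truly fit worse than one it
    # nests, and a nested variant should beat the richer fit's projection
    # onto its own space; either failure marks a stalled simplex.
    data = _prepare_data(trials, opts.trial_floor)
    repair_opts = FitOptions(**{**vars(opts), "restarts": 1, "rounds": max(opts.rounds, 2)})
    tol = 2 * opts.fatol
    for _ in range(2):
        repaired = False
        for rich_var in sorted(all_variants(), key=lambda v: -v.k):
            rich = fits[rich_var.name]
            for poor_var in all_variants():
                if poor_var == rich_var or not rich_var.nests(poor_var):
                    continue
                poor = fits[poor_var.name]
                if rich.objective > poor.objective + tol:
                    x0 = _expand_warm_start(poor, rich_var)
                    refit = fit_variant(trials, rich_var, repair_opts, x0=x0)
                    if refit.objective < rich.objective:
                        fits[rich_var.name] = rich = refit
                        repaired = True
                    continue
                x0 = _pack(_project_params(rich, poor_var), poor_var)
                probe = _objective_factory(data, poor_var, opts)(x0)
                if probe < poor.objective - tol:
                    refit = fit_variant(trials, poor_var, repair_opts, x0=x0)
                    if refit.objective < poor.objective:
                        fits[poor_var.name] = refit
                        repaired = True
        if not repaired:
            break
    return fits


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def information_weights(bics) -> np.ndarray:
    """BIC information weights: exp(-dBIC/2) normalised over the model set.

    Weights lie in [0, 1], sum to 1 and are invariant to adding a constant
    to every BIC; higher means better support for that model.
    """
    bics = np.asarray(bics, float)
    if not np.all(np.isfinite(bics)):
        raise ValueError("information weights require finite BIC values")
    delta = bics - bics.min()
    w = np.exp(-delta / 2)
    return w / w.sum()


def select_model(weights: pd.DataFrame):
    """Pick the variant with the highest across-participant mean weight.

    ``weights`` is participants x variant-name. Returns ``(VariantSpec,
    mean_weights: Series)``; exact ties break toward the smaller parameter
    count (and are logged).
    """
    if weights.empty:
        raise ValueError("need at least one participant")
    mean_w = weights.mean(axis=0)
    by_name = {v.name: v for v in all_variants()}
    top = mean_w.max()
    tied = [name for name in mean_w.index if mean_w[name] == top]
    if len(tied) > 1:
        tied.sort(key=lambda name: (by_name[name].k, name))
        logger.info("mean-weight tie between %s; selecting smallest k", tied)
    return by_name[tied[0]], mean_w


def trim_outliers(trials: pd.DataFrame, fraction: float = 0.05):
    """Symmetric per-tail RT trimming within participant x condition.

    Removes ``floor(fraction/2 * n)`` trials from each RT tail of every
    participant x condition cell. Returns ``(trimmed, removal_log)``.
    """
    if not 0 <= fraction < 0.5:
        raise ValueError("fraction must be in [0, 0.5)")
    drop = []
    for (pid, cond), sub in trials.groupby(["participant_id", "condition"], observed=True):
        k = int(np.floor(fraction / 2 * len(sub)))
        if k == 0:
            continue
        order = sub["fixation_duration_ms"].sort_values()
        drop += list(order.index[:k]) + list(order.index[-k:])
    log = trials.loc[drop, ["participant_id", "condition", "fixation_duration_ms"]]
    return trials.drop(index=drop), log.reset_index(names="trial_row")
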