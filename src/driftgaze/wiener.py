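"""First-passage-time machinery for the two-boundary Wiener diffusion.

The defective first-passage density toward the lower boundary of a Wiener
process with drift ``v``, boundary separation ``a`` and relative start ``w``
factorises as::

    f_lower(t) = a**-2 * exp(-v*a*w - v**2 * t / 2) * f0(t / a**2, w)

where ``f0`` is the zero-drift standardized density on unit boundaries.
``f0`` has two classical series representations — one converging fast for
small times (image/reflection sum) and one for large times (spectral sine
series) — and we switch between them per evaluation point using the
term-count criterion of Navarro & Fuss (2009) at a target truncation error
of 1e-7.

Across-trial drift variability (normal with SD ``sv``) enters only through
the exponential prefactor, whose Gaussian mixture has a closed form; it is
therefore marginalised exactly rather than by quadrature::

    E_v[exp(-v*a*w - v**2 t/2)]
        = (1 + sv**2 t)**-1/2
          * exp((sv**2 a**2 w**2 - 2 v a w - v**2 t) / (2 (1 + sv**2 t)))

Starting-point (uniform, width ``sz``) and non-decision-time (uniform,
width ``st0``) variability are marginalised by Gauss–Legendre quadrature
(7 nodes each by default).

The upper boundary is the lower boundary of the mirrored process
(``v -> -v``, ``w -> 1 - w``).
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy.special import expm1

from .params import DDMParams

__all__ = [
    "choice_probability",
    "fpt_density",
    "predicted_joint_cdf",
    "SignedRTPrediction",
    "simulate_trials",
]

_TRUNC_EPS = 1e-7  # per-evaluation truncation target for the series


# ---------------------------------------------------------------------------
# series for the standardized (zero-drift, unit-boundary) density
# ---------------------------------------------------------------------------

def _term_counts(tau, eps):
    """Series lengths each representation needs for error <= eps."""
    sq = np.sqrt(2 * np.pi * tau)
    ks = np.where(
        2 * sq * eps < 1,
        2 + np.sqrt(np.maximum(-2 * tau * np.log(2 * eps * sq), 0.0)),
        2.0,
    )
    ks = np.maximum(ks, np.sqrt(tau) + 1)
    kl = np.where(
        np.pi * tau * eps < 1,
        np.sqrt(np.maximum(-2 * np.log(np.pi * tau * eps), 0.0) / (np.pi**2 * tau)),
        0.0,
    )
    kl = np.maximum(kl, 1 / (np.pi * np.sqrt(tau)))
    return ks, kl


try:  # numba accelerates the innermost series loop; numpy path is equivalent
    import numba

    @numba.njit(cache=False, fastmath=True)
    def _f0_kernel(tau, w, eps):  # pragma: no cover - exercised via _f0
        out = np.empty(tau.shape)
        for i in range(tau.shape[0]):
            for j in range(tau.shape[1]):
                t = max(tau[i, j], 1e-12)
                ww = w[i, j]
                sq = np.sqrt(2 * np.pi * t)
                if 2 * sq * eps < 1:
                    ks = 2 + np.sqrt(max(-2 * t * np.log(2 * eps * sq), 0.0))
                else:
                    ks = 2.0
                ks = max(ks, np.sqrt(t) + 1)
                if np.pi * t * eps < 1:
                    kl = np.sqrt(max(-2 * np.log(np.pi * t * eps), 0.0) / (np.pi**2 * t))
                else:
                    kl = 0.0
                kl = max(kl, 1 / (np.pi * np.sqrt(t)))
                acc = 0.0
                if ks < kl:
                    K = int(np.ceil(ks))
                    lo = -((K - 1) // 2)
                    hi = (K - 1) // 2 + (K - 1) % 2
                    for k in range(lo, hi + 1):
                        arg = ww + 2 * k
                        acc += arg * np.exp(-(arg * arg) / (2 * t))
                    acc /= np.sqrt(2 * np.pi * t**3)
                else:
                    K = int(np.ceil(kl))
                    for k in range(1, K + 1):
                        acc += (
                            k
                            * np.exp(-(k * k) * np.pi**2 * t / 2)
                            * np.sin(k * np.pi * ww)
                        )
                    acc *= np.pi
                out[i, j] = max(acc, 0.0)
        return out

except ImportError:  # pragma: no cover
    _f0_kernel = None


def _f0(tau, w, eps=_TRUNC_EPS):
    """Zero-drift density at the lower unit boundary; tau, w broadcast."""
    tau = np.maximum(np.asarray(tau, float), 1e-12)
    w = np.asarray(w, float)
    if _f0_kernel is not None:
        shape = np.broadcast_shapes(tau.shape, w.shape)
        tau2 = np.broadcast_to(tau, shape).reshape(-1, shape[-1] if shape else 1)
        w2 = np.broadcast_to(w, shape).reshape(tau2.shape)
        return _f0_kernel(np.ascontiguousarray(tau2), np.ascontiguousarray(w2), eps).reshape(shape)
    # the switch rule depends on tau alone; evaluate it before broadcasting
    ks, kl = _term_counts(tau, eps)
    shape = np.broadcast_shapes(tau.shape, w.shape)
    tau_b = np.broadcast_to(tau, shape)
    w_b = np.broadcast_to(w, shape)
    use_small = np.broadcast_to(ks < kl, shape)
    out = np.zeros(shape)

    if np.any(use_small):
        t_s, w_s = tau_b[use_small], w_b[use_small]
        K = int(math.ceil(ks[ks < kl].max()))
        lo, hi = -((K - 1) // 2), (K - 1) // 2 + (K - 1) % 2
        k = np.arange(lo, hi + 1)
        arg = w_s[..., None] + 2 * k
        terms = arg * np.exp(-(arg**2) / (2 * t_s[..., None]))
        out[use_small] = terms.sum(-1) / np.sqrt(2 * np.pi * t_s**3)

    if np.any(~use_small):
        t_l, w_l = tau_b[~use_small], w_b[~use_small]
        K = int(math.ceil(kl[ks >= kl].max()))
        k = np.arange(1, K + 1)
        terms = (
            k
            * np.exp(-(k**2) * np.pi**2 * t_l[..., None] / 2)
            * np.sin(k * np.pi * w_l[..., None])
        )
        out[~use_small] = np.pi * terms.sum(-1)

    return np.maximum(out, 0.0)


def _drift_factor(t, a, w, v, sv):
    """Drift-dependent prefactor, exactly marginalised over v ~ N(v, sv)."""
    if sv == 0.0:
        return np.exp(-v * a * w - v**2 * t / 2)
    s2t = 1 + sv**2 * t
    num = sv**2 * a**2 * w**2 - 2 * v * a * w - v**2 * t
    return np.exp(num / (2 * s2t)) / np.sqrt(s2t)


def _density_lower(t, a, w, v, sv=0.0):
    """Defective density at the lower boundary; t and w broadcast."""
    t = np.asarray(t, float)
    tau = t / a**2
    return _drift_factor(t, a, w, v, sv) * _f0(tau, w) / a**2


# ---------------------------------------------------------------------------
# public pointwise API
# ---------------------------------------------------------------------------

def choice_probability(params: DDMParams) -> float:
    """Probability of absorption at the upper (face) boundary.

    Closed form for a Wiener process without across-trial variability in
    drift or starting point (``sv = sz = 0``); ``st0`` is irrelevant here.
    For ``v != 0``: ``(1 - exp(-2 v z)) / (1 - exp(-2 v a))``; for ``v = 0``
    the limit is ``zr``.
    """
    params.validate()
    if params.sv != 0 or params.sz != 0:
        raise ValueError("closed-form choice probability requires sv = sz = 0")
    if params.v == 0:
        return float(params.zr)
    # expm1 keeps the ratio accurate for |v| near 0
    num = -expm1(-2 * params.v * params.z)
    den = -expm1(-2 * params.v * params.a)
    return float(num / den)


def fpt_density(t, boundary: str, params: DDMParams):
    """Defective first-passage density at ``boundary`` ("upper" or "lower").

    Requires ``sz = st0 = 0`` (no starting-point or non-decision-time
    variability); drift variability ``sv`` is marginalised in closed form.
    ``t`` is decision time in seconds (no non-decision time added).
    """
    params.validate()
    if params.sz != 0 or params.st0 != 0:
        raise ValueError("fpt_density expects sz = st0 = 0; use SignedRTPrediction")
    t = np.asarray(t, float)
    if np.any(t <= 0):
        raise ValueError("first-passage times must be strictly positive")
    if boundary == "lower":
        out = _density_lower(t, params.a, params.zr, params.v, params.sv)
    elif boundary == "upper":
        out = _density_lower(t, params.a, 1 - params.zr, -params.v, params.sv)
    else:
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# signed-RT prediction (CDF / density with all variability components)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _leggauss(n: int):
    return np.polynomial.legendre.leggauss(n)


def _gauss_legendre(n: int, center: float, width: float):
    """Nodes/weights of an n-point GL rule on ``center +- width/2``.

    Degenerate width collapses to a single node at ``center``.
    """
    if width == 0.0 or n == 1:
        return np.array([center]), np.array([1.0])
    x, wgt = _leggauss(n)
    return center + x * width / 2, wgt / 2


def _density_lower_vec(t, a, w, v, sv):
    """Vectorised defective lower-boundary density; all arguments broadcast.

    The drift prefactor is written in its sv-marginalised form, which
    reduces to the fixed-drift exponential when ``sv = 0``.
    """
    s2t = 1 + sv**2 * t
    num = sv**2 * a**2 * w**2 - 2 * v * a * w - v**2 * t
    M = np.exp(num / (2 * s2t)) / np.sqrt(s2t)
    return M * _f0(t / a**2, w) / a**2


class SignedRTPrediction:
    """Predicted distribution of the signed response variable.

    The signed variable is ``+RT`` for upper-boundary (face) responses and
    ``-RT`` for lower-boundary (noise) responses, so its CDF runs from 0 to
    1 with the lower-boundary probability as its value just below zero —
    the mirrored representation used throughout the fitting stage.

    The defective decision-time CDFs are tabulated once on a quadratically
    spaced grid (dense near zero where the density peaks) by cumulative
    trapezoidal integration, then evaluated by linear interpolation with the
    non-decision-time mixture applied at lookup time.
    """

    def __init__(self, params: DDMParams, n_grid: int = 384, n_sz: int = 7, n_st0: int = 7):
        built = batch_signed_predictions([params], n_grid=n_grid, n_sz=n_sz, n_st0=n_st0)
        self.__dict__.update(built[0].__dict__)

    @classmethod
    def _blank(cls):
        return cls.__new__(cls)

    def _decision_cdf(self, F, t):
        """Interpolated defective decision-time CDF at RT ``t`` (seconds)."""
        t = np.asarray(t, float)
        tau = t[..., None] - self._tnd_nodes  # subtract non-decision time
        vals = np.interp(tau, self._tgrid, F, left=0.0, right=F[-1])
        return vals @ self._tnd_wgt

    def cdf(self, x):
        """CDF of the signed RT at signed seconds ``x`` (array ok)."""
        x = np.asarray(x, float)
        pos = self._decision_cdf(self._F_upper, np.maximum(x, 0.0)) + self.p_lower
        neg = self.p_lower - self._decision_cdf(self._F_lower, np.maximum(-x, 0.0))
        out = np.where(x >= 0, pos, neg)
        return out if out.shape else float(out)

    def log_density(self, rt, upper, floor=0.0):
        """Log defective density of observed RTs (seconds).

        ``upper`` is a boolean array marking face (upper-boundary)
        responses. ``floor`` clips the density from below before the log,
        which keeps downstream likelihood sums finite for stray responses
        faster than the fitted minimal non-decision time.
        """
        rt = np.asarray(rt, float)
        upper = np.asarray(upper, bool)
        f = np.where(upper[..., None], self._f_upper, self._f_lower)
        tau = rt[..., None] - self._tnd_nodes
        # interpolate each trial's density at its st0 quadrature nodes
        dens = np.empty(tau.shape)
        for j in range(tau.shape[-1]):
            lo = np.interp(tau[..., j], self._tgrid, self._f_lower, left=0.0, right=0.0)
            up = np.interp(tau[..., j], self._tgrid, self._f_upper, left=0.0, right=0.0)
            dens[..., j] = np.where(upper, up, lo)
        mixed = dens @ self._tnd_wgt / self.total_mass
        with np.errstate(divide="ignore"):  # -inf is the honest answer at 0
            return np.log(np.maximum(mixed, floor))


def batch_signed_predictions(
    params_list, n_grid: int = 384, n_sz: int = 7, n_st0: int = 7
) -> list[SignedRTPrediction]:
    """Tabulate :class:`SignedRTPrediction` objects for several parameter sets.

    All conditions' density tables are computed in one vectorised pass (one
    series evaluation for every condition, boundary and starting-point
    node), which is what makes the multi-condition fitting objective cheap.
    """
    C = len(params_list)
    for p in params_list:
        p.validate()
    a = np.array([p.a for p in params_list])[:, None, None]
    v = np.array([p.v for p in params_list])[:, None, None]
    sv = np.array([p.sv for p in params_list])[:, None, None]
    # per-condition grid long enough for the slowest decay mode to vanish
    tau_max = np.minimum(np.maximum(1.0, 3.6 * a[:, 0, 0] ** 2) + 2.0 * a[:, 0, 0] ** 2, 30.0)
    u = np.linspace(0.0, 1.0, n_grid) ** 2
    tgrid = tau_max[:, None] * u  # (C, G)
    t = tgrid[:, None, 1:]  # (C, 1, G-1)

    w_nodes = np.empty((C, n_sz))
    w_wgt = np.empty((C, n_sz))
    for i, p in enumerate(params_list):
        w_nodes[i], w_wgt[i] = _gauss_legendre(n_sz, p.zr, p.sz)
    wc = w_nodes[:, :, None]  # (C, W, 1)

    f_lo = _density_lower_vec(t, a, wc, v, sv)
    f_up = _density_lower_vec(t, a, 1 - wc, -v, sv)
    f_lower = np.concatenate(
        [np.zeros((C, 1)), np.einsum("cw,cwg->cg", w_wgt, f_lo)], axis=1
    )
    f_upper = np.concatenate(
        [np.zeros((C, 1)), np.einsum("cw,cwg->cg", w_wgt, f_up)], axis=1
    )
    dt = np.diff(tgrid, axis=1)
    F_lower = np.concatenate(
        [np.zeros((C, 1)), np.cumsum(dt * (f_lower[:, 1:] + f_lower[:, :-1]) / 2, axis=1)],
        axis=1,
    )
    F_upper = np.concatenate(
        [np.zeros((C, 1)), np.cumsum(dt * (f_upper[:, 1:] + f_upper[:, :-1]) / 2, axis=1)],
        axis=1,
    )
    out = []
    for i, p in enumerate(params_list):
        pred = SignedRTPrediction._blank()
        pred.params = p
        pred.n_grid, pred.n_sz, pred.n_st0 = n_grid, n_sz, n_st0
        pred._tgrid = tgrid[i]
        total = float(F_lower[i, -1] + F_upper[i, -1])
        pred.total_mass = total
        pred._f_lower, pred._f_upper = f_lower[i], f_upper[i]
        # renormalise so the signed CDF reaches exactly 1
        pred._F_lower, pred._F_upper = F_lower[i] / total, F_upper[i] / total
        pred.p_lower = float(pred._F_lower[-1])
        pred.p_upper = float(pred._F_upper[-1])
        pred._tnd_nodes, pred._tnd_wgt = _gauss_legendre(n_st0, p.t0, p.st0)
        out.append(pred)
    return out


def predicted_joint_cdf(params: DDMParams, t_grid, n_sz: int = 7, n_st0: int = 7):
    """CDF of the signed RT (``+RT`` face / ``-RT`` noise) on ``t_grid``.

    ``t_grid`` is a monotone grid of signed seconds. All three variability
    components are marginalised: drift in closed form, starting point and
    non-decision time by ``n_sz``- and ``n_st0``-node Gauss–Legendre rules.
    """
    t_grid = np.asarray(t_grid, float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) < 0):
        raise ValueError("t_grid must be a nondecreasing 1-d grid")
    pred = SignedRTPrediction(params, n_sz=n_sz, n_st0=n_st0)
    return pred.cdf(t_grid)


# ---------------------------------------------------------------------------
# trial-level simulation
# ---------------------------------------------------------------------------

def simulate_trials(
    params: DDMParams,
    n: int,
    rng: np.random.Generator,
    dt: float = 5e-4,
    t_max: float = 30.0,
):
    """Simulate ``n`` trials by Euler–Maruyama integration of the diffusion.

    Per trial, drift is drawn from ``N(v, sv)``, the relative start from
    ``U(zr +- sz/2)`` and the non-decision time from ``U(t0 +- st0/2)``.
    The path is advanced in steps of ``dt`` seconds (default 0.5 ms; halving
    it is the standard convergence check) until absorption.

    Returns ``(upper, rt)``: a boolean array marking upper-boundary (face)
    responses and the total response time in seconds (decision time plus
    non-decision time).
    """
    p = params.validate()
    drift = rng.normal(p.v, p.sv, n) if p.sv > 0 else np.full(n, p.v)
    start = np.full(n, p.zr) + (rng.uniform(-0.5, 0.5, n) * p.sz if p.sz > 0 else 0.0)
    x = start * p.a
    tnd = p.t0 + (rng.uniform(-0.5, 0.5, n) * p.st0 if p.st0 > 0 else 0.0)

    sqdt = math.sqrt(dt)
    upper = np.zeros(n, bool)
    steps = np.zeros(n, np.int64)
    active = np.arange(n)
    max_steps = int(t_max / dt)
    k = 0
    while active.size and k < max_steps:
        k += 1
        x_old = x[active]
        xa = x_old + drift[active] * dt + sqdt * rng.standard_normal(active.size)
        x[active] = xa
        hit_up = xa >= p.a
        hit_lo = xa <= 0.0
        # Brownian-bridge correction: the path may have grazed a boundary
        # inside the step even when both endpoints lie strictly within.
        inside = ~(hit_up | hit_lo)
        if np.any(inside):
            xo, xn = x_old[inside], xa[inside]
            u = rng.uniform(size=2 * inside.sum()).reshape(2, -1)
            cross_up = u[0] < np.exp(-2 * (p.a - xo) * (p.a - xn) / dt)
            cross_lo = ~cross_up & (u[1] < np.exp(-2 * xo * xn / dt))
            hit_up[inside] |= cross_up
            hit_lo[inside] |= cross_lo
        done = hit_up | hit_lo
        if np.any(done):
            hit = active[done]
            upper[hit] = hit_up[done]
            steps[hit] = k
            active = active[~done]
    if active.size:  # censored stragglers: resolve by current position
        upper[active] = x[active] >= p.a / 2
        steps[active] = max_steps
    return upper, steps * dt + tnd
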