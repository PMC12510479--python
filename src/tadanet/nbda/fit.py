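"""Maximum-likelihood fitting, model-set fitting and profile-likelihood CIs."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from tadanet.networks import LAYERS
from tadanet.nbda.data import DiffusionData
from tadanet.nbda.likelihood import TadaParams, _expand, tada_log_likelihood
from tadanet.nbda.modelset import TadaModelSpec, aicc as _aicc, akaike_weights

logger = logging.getLogger(__name__)

S_STARTS = (0.1, 1.0, 10.0)
LOG_KAPPA_BOUNDS = (np.log(0.05), np.log(20.0))


class FitError(RuntimeError):
    """All optimisation starts failed."""


def param_names(spec: TadaModelSpec, n_ilvs: int, ilv_names=None) -> list[str]:
    """Names of the free-parameter vector entries, in packing order."""
    if ilv_names is None:
        ilv_names = [f"ilv{i}" for i in range(n_ilvs)]
    names = [f"s_{l}" for l in LAYERS if l in spec.networks]
    for i, place in enumerate(spec.ilv_placement):
        if place in ("asocial_only", "both"):
            names.append(f"betaA_{ilv_names[i]}")
    for i, place in enumerate(spec.ilv_placement):
        if place in ("social_only", "both"):
            names.append(f"betaS_{ilv_names[i]}")
    names.append("log_theta")
    if spec.baseline == "weibull":
        names.append("log_kappa")
    return names


def _bounds(spec: TadaModelSpec, n_ilvs: int) -> list[tuple]:
    bounds = [(0.0, None)] * len(spec.networks)
    bounds += [(-15.0, 15.0)] * (spec.n_asocial_ilv + spec.n_social_ilv)
    bounds.append((-25.0, 25.0))  # log theta
    if spec.baseline == "weibull":
        bounds.append(LOG_KAPPA_BOUNDS)
    return bounds


def _asocial_theta_init(data: DiffusionData) -> float:
    """Exponential-MLE scale ignoring networks: total exposure / events."""
    exposure = 0.0
    for site in data.sites:
        dlam = np.diff(site.boundaries)
        active = site.naive & site.present
        exposure += float(np.sum(dlam[:, None] * active))
    return max(exposure / max(data.n_events, 1), 1e-3)


@dataclass
class TadaFit:
    """A fitted TADA model."""

    spec: TadaModelSpec
    params: TadaParams
    free: np.ndarray
    loglik: float
    aicc: float
    n_events: int
    converged: bool
    n_starts_ok: int
    akaike_weight: float = field(default=np.nan)

    def param_dict(self, ilv_names=None) -> dict[str, float]:
        names = param_names(self.spec, len(self.params.beta_asocial), ilv_names)
        out = dict(zip(names, self.free))
        out["theta"] = self.params.theta
        out["kappa"] = self.params.kappa
        return out


def fit_tada(
    data: DiffusionData,
    spec: TadaModelSpec,
    n_starts: int = 5,
    seed: int = 0,
) -> TadaFit:
    """Maximise the TADA likelihood from multiple seeded starts.

    Social rates are box-constrained at 0; the baseline scale and Weibull
    shape are optimised on the log scale.  Deterministic starts place the
    social rates at 0.1, 1 and 10; remaining starts jitter the best
    deterministic start with a seeded RNG.
    """
    if data.n_events < 1:
        raise FitError("no acquisition events")
    n_ilvs = data.n_ilvs
    theta0 = _asocial_theta_init(data)
    m = len(spec.networks)
    n_beta = spec.n_asocial_ilv + spec.n_social_ilv
    base = [np.log(theta0)] + ([0.0] if spec.baseline == "weibull" else [])
    starts = [
        np.array([s0] * m + [0.0] * n_beta + base) for s0 in S_STARTS[: max(1, n_starts)]
    ]
    rng = np.random.default_rng(seed)
    while len(starts) < n_starts:
        jit = starts[1 % len(starts)].copy()
        jit[:m] = np.abs(jit[:m] * np.exp(rng.normal(0, 1, m)))
        jit[m:] += rng.normal(0, 0.5, len(jit) - m)
        starts.append(jit)
    bounds = _bounds(spec, n_ilvs)

    def nll(v):
        try:
            return -tada_log_likelihood(data, v, spec)
        except (ValueError, FloatingPointError, OverflowError):
            return 1e12

    best = None
    n_ok = 0
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if np.isfinite(res.fun) and res.fun < 1e11:
            n_ok += 1
            if best is None or res.fun < best.fun - 1e-12:
                best = res
    if best is None:
        raise FitError(f"all {len(starts)} starts failed for {spec.label()}")
    params = _expand(best.x, spec, n_ilvs)
    loglik = -float(best.fun)
    return TadaFit(
        spec=spec,
        params=params,
        free=np.asarray(best.x, dtype=float),
        loglik=loglik,
        aicc=_aicc(loglik, spec.n_params, data.n_events),
        n_events=data.n_events,
        converged=bool(best.success),
        n_starts_ok=n_ok,
    )


def fit_model_set(
    data: DiffusionData,
    specs: list[TadaModelSpec],
    n_starts: int = 3,
    seed: int = 0,
) -> tuple[list[TadaFit], pd.DataFrame]:
    """Fit every spec, attach Akaike weights, and tabulate the model set."""
    fits = []
    for i, spec in enumerate(specs):
        fits.append(fit_tada(data, spec, n_starts=n_starts, seed=seed + i))
    a = np.array([f.aicc for f in fits])
    w = akaike_weights(a)
    for f, wi in zip(fits, w):
        f.akaike_weight = float(wi)
    finite = a[np.isfinite(a)]
    dmin = finite.min() if finite.size else np.nan
    table = pd.DataFrame(
        {
            "model": [f.spec.label() for f in fits],
            "networks": ["+".join(f.spec.networks) or "asocial" for f in fits],
            "baseline": [f.spec.baseline for f in fits],
            "K": [f.spec.n_params for f in fits],
            "loglik": [f.loglik for f in fits],
            "AICc": a,
            "delta_AICc": a - dmin,
            "weight": w,
        }
    ).sort_values("AICc", kind="mergesort").reset_index(drop=True)
    return fits, table


@dataclass
class ProfileCI:
    lower: float
    upper: float
    lower_open: bool = False
    upper_open: bool = False

    def __iter__(self):
        return iter((self.lower, self.upper))


def profile_interval(
    profile_loglik,
    mle: float,
    lmax: float,
    level: float = 0.95,
    lower_bound: float | None = None,
    expand_limit: float | None = None,
) -> ProfileCI:
    """Invert a 1-D profile log-likelihood into a confidence interval.

    The interval is ``{v : 2 (lmax - l_profile(v)) <= chi2_{1, level}}``.
    ``lower_bound`` marks a hard box constraint (e.g. 0 for a social rate):
    if the profile at the bound is within the threshold, the interval is
    closed there.  A side on which the deviance never crosses the threshold
    before ``expand_limit`` is reported open.
    """
    thresh = stats.chi2.ppf(level, df=1)

    def dev(v):
        return 2.0 * (lmax - profile_loglik(v))

    def cross(lo, hi):
        return float(optimize.brentq(lambda v: dev(v) - thresh, lo, hi, xtol=1e-6, rtol=1e-8))

    scale = max(abs(mle), 1.0)
    if expand_limit is None:
        expand_limit = 1e3 * scale
    # lower side
    lower_open = False
    if lower_bound is not None and mle - lower_bound < 1e-12:
        lower = lower_bound
    else:
        lo = mle
        step = 0.5 * scale
        lower = None
        for _ in range(60):
            cand = lo - step
            if lower_bound is not None and cand <= lower_bound:
                if dev(lower_bound) <= thresh:
                    lower = lower_bound
                else:
                    lower = cross(lower_bound, lo)
                break
            if dev(cand) > thresh:
                lower = cross(cand, lo)
                break
            lo = cand
            step *= 1.6
        if lower is None:
            lower = lo
            lower_open = True
    # upper side
    hi = mle
    step = 0.5 * scale
    upper = None
    upper_open = False
    for _ in range(200):
        cand = hi + step
        if cand > expand_limit:
            break
        if dev(cand) > thresh:
            upper = cross(hi, cand)
            break
        hi = cand
        step *= 1.6
    if upper is None:
        upper = np.inf
        upper_open = True
    return ProfileCI(lower, upper, lower_open, upper_open)


def profile_ci(
    data: DiffusionData,
    spec: TadaModelSpec,
    best_fit: TadaFit,
    param: str,
    level: float = 0.95,
    ilv_names=None,
) -> ProfileCI:
    """Profile-likelihood CI for one parameter of a fitted model.

    ``param`` is a free-parameter name (see :func:`param_names`) or the
    natural-scale aliases ``theta`` / ``kappa``.  Each profile point
    re-optimises all remaining parameters, warm-started at the MLE; a point
    that fails to converge is flagged and skipped by the expansion search.
    """
    n_ilvs = data.n_ilvs
    names = param_names(spec, n_ilvs, ilv_names)
    natural_log = False
    if param in ("theta", "kappa"):
        natural_log = True
        param = f"log_{param}"
    if param not in names:
        raise ValueError(f"{param!r} not a parameter of {spec.label()}")
    idx = names.index(param)
    bounds = _bounds(spec, n_ilvs)
    free_idx = [i for i in range(len(names)) if i != idx]
    sub_bounds = [bounds[i] for i in free_idx]
    x_mle = best_fit.free

    def profile_loglik(v_natural: float) -> float:
        v = np.log(v_natural) if natural_log else v_natural
        if not free_idx:
            full = np.array([v])
            return tada_log_likelihood(data, full, spec)

        def nll(sub):
            full = np.empty(len(names))
            full[idx] = v
            full[free_idx] = sub
            try:
                return -tada_log_likelihood(data, full, spec)
            except (ValueError, FloatingPointError, OverflowError):
                return 1e12
        x0 = x_mle[free_idx]
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=sub_bounds)
        if not np.isfinite(res.fun) or res.fun >= 1e11:
            logger.warning("profile point %s=%g failed to converge", param, v_natural)
            return -1e12
        return -float(res.fun)

    if natural_log:
        mle = float(np.exp(x_mle[idx]))
        lower_bound = 1e-10
    else:
        mle = float(x_mle[idx])
        lower_bound = bounds[idx][0]
    return profile_interval(
        profile_loglik, mle, best_fit.loglik, level=level, lower_bound=lower_bound
    )
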