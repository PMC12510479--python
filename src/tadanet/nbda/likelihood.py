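"""TADA hazard and log-likelihood.

The baseline hazard is either constant, ``lambda0(t) = 1/theta``, or
Weibull, ``lambda0(t) = (kappa/theta) (t/theta)^(kappa-1)`` with integrated
baseline ``Lambda0(t) = (t/theta)^kappa`` (``kappa = 1`` recovers the
constant family).  On top of the baseline, individual i's rate multiplier
during interval m is

    R_i(m) = exp(beta_A . x_i(m)) + exp(beta_S . x_i(m)) * sum_k s_k S_ik(m)

with ``S_ik`` the precomputed weighted knowledgeable-neighbour sum of layer
k.  The log-likelihood is the standard event-history form: a log-hazard
term for each acquisition event plus the negative integrated hazard over
every interval in which an individual is naive and present; individuals who
never learn are censored at the site's end time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from tadanet.networks import LAYERS
from tadanet.nbda.data import DiffusionData, SiteDiffusion
from tadanet.nbda.modelset import TadaModelSpec


@dataclass
class TadaParams:
    """Unpacked parameters on their natural scale."""

    s: np.ndarray  # (len(LAYERS),) with zeros for excluded layers
    beta_asocial: np.ndarray  # (n_ilv,) zeros where not placed
    beta_social: np.ndarray  # (n_ilv,)
    theta: float
    kappa: float = 1.0

    def __post_init__(self) -> None:
        if np.any(self.s < 0):
            raise ValueError("social transmission rates must be >= 0")
        if self.theta <= 0 or self.kappa <= 0:
            raise ValueError("baseline scale and shape must be > 0")


def baseline_hazard(t, theta: float, kappa: float = 1.0):
    t = np.asarray(t, dtype=float)
    if kappa == 1.0:
        return np.full_like(t, 1.0 / theta)
    return (kappa / theta) * (t / theta) ** (kappa - 1.0)


def integrated_baseline(t, theta: float, kappa: float = 1.0):
    t = np.asarray(t, dtype=float)
    return (t / theta) ** kappa


def rate_multipliers(site: SiteDiffusion, params: TadaParams) -> np.ndarray:
    """R_i(m) for every interval and individual, shape (E+1, n)."""
    xa = np.clip(site.ilv @ params.beta_asocial, -300.0, 300.0)
    xs = np.clip(site.ilv @ params.beta_social, -300.0, 300.0)
    social = site.social @ params.s
    return np.exp(xa) + np.exp(xs) * social


def social_components(site: SiteDiffusion, params: TadaParams) -> np.ndarray:
    """Per-layer social hazard components, shape (E+1, n, len(LAYERS))."""
    xs = np.clip(site.ilv @ params.beta_social, -300.0, 300.0)
    return np.exp(xs)[..., None] * site.social * params.s[None, None, :]


def hazard(
    site: SiteDiffusion, individual: int, interval: int, t: float, params: TadaParams
) -> float:
    """lambda_i(t) during one interval; 0 if absent; error if not naive."""
    if not site.naive[interval, individual]:
        raise ValueError("hazard requested for a knowledgeable individual")
    if not site.present[interval, individual]:
        return 0.0
    r = rate_multipliers(site, params)[interval, individual]
    return float(baseline_hazard(t, params.theta, params.kappa) * r)


def site_log_likelihood(site: SiteDiffusion, params: TadaParams) -> float:
    tau = site.boundaries
    r = rate_multipliers(site, params)  # (E+1, n)
    active = site.naive & site.present
    lam = integrated_baseline(tau, params.theta, params.kappa)
    dlam = np.diff(lam)  # (E+1,)
    integral = float(np.sum(dlam[:, None] * (r * active)))
    e_idx = np.arange(site.n_events)
    learners = site.event_learner
    if not np.all(active[e_idx, learners]):
        raise ValueError("acquisition event by an individual not at risk")
    r_events = r[e_idx, learners]
    log_lam0 = np.log(baseline_hazard(site.event_times, params.theta, params.kappa))
    return float(np.sum(log_lam0 + np.log(r_events)) - integral)


def _expand(params_free: np.ndarray, spec: TadaModelSpec, n_ilvs: int) -> TadaParams:
    """Unpack a free-parameter vector for ``spec`` into :class:`TadaParams`.

    Layout: s per included network (layer order), beta_A for ILVs placed
    asocially, beta_S for ILVs placed socially, log(theta), then log(kappa)
    for the Weibull family.
    """
    v = np.asarray(params_free, dtype=float)
    pos = 0
    s = np.zeros(len(LAYERS))
    for k, layer in enumerate(LAYERS):
        if layer in spec.networks:
            s[k] = v[pos]
            pos += 1
    ba = np.zeros(n_ilvs)
    bs = np.zeros(n_ilvs)
    for i, place in enumerate(spec.ilv_placement):
        if place in ("asocial_only", "both"):
            ba[i] = v[pos]
            pos += 1
    for i, place in enumerate(spec.ilv_placement):
        if place in ("social_only", "both"):
            bs[i] = v[pos]
            pos += 1
    theta = float(np.exp(v[pos]))
    pos += 1
    kappa = 1.0
    if spec.baseline == "weibull":
        kappa = float(np.exp(v[pos]))
        pos += 1
    if pos != v.size:
        raise ValueError(f"parameter vector length {v.size}, expected {pos}")
    return TadaParams(s=s, beta_asocial=ba, beta_social=bs, theta=theta, kappa=kappa)


def tada_log_likelihood(
    data: DiffusionData, params: TadaParams | np.ndarray, spec: TadaModelSpec | None = None
) -> float:
    """Multi-diffusion log-likelihood (sum over sites, shared parameters).

    ``params`` is either an unpacked :class:`TadaParams` or, together with
    ``spec``, the free-parameter vector used by the optimiser.
    """
    if not isinstance(params, TadaParams):
        if spec is None:
            raise ValueError("spec required when passing a packed vector")
        params = _expand(params, spec, data.n_ilvs)
    return sum(site_log_likelihood(site, params) for site in data.sites)
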