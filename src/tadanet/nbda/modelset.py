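"""Model specifications, enumeration, AICc and Akaike-weight support."""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from tadanet.networks import LAYERS

ILV_PLACEMENTS = ("absent", "asocial_only", "social_only", "both")
BASELINES = ("constant", "weibull")


@dataclass(frozen=True)
class TadaModelSpec:
    """Which networks, ILV placements and baseline family a model uses.

    ``networks`` is an ordered subset of the pathway layers (the empty
    tuple is the purely asocial model).  ``ilv_placement`` gives, for each
    ILV in data order, where it acts: on the asocial rate, the social rate,
    both, or nowhere.  ``baseline`` selects a constant or Weibull baseline
    hazard.
    """

    networks: tuple[str, ...] = ()
    ilv_placement: tuple[str, ...] = ()
    baseline: str = "constant"

    def __post_init__(self) -> None:
        if self.baseline not in BASELINES:
            raise ValueError(f"unknown baseline {self.baseline!r}")
        bad = set(self.networks) - set(LAYERS)
        if bad:
            raise ValueError(f"unknown networks {sorted(bad)}")
        if len(set(self.networks)) != len(self.networks):
            raise ValueError("duplicate networks")
        bad = set(self.ilv_placement) - set(ILV_PLACEMENTS)
        if bad:
            raise ValueError(f"unknown ILV placements {sorted(bad)}")
        # canonical layer order
        object.__setattr__(
            self,
            "networks",
            tuple(l for l in LAYERS if l in self.networks),
        )

    @property
    def n_asocial_ilv(self) -> int:
        return sum(p in ("asocial_only", "both") for p in self.ilv_placement)

    @property
    def n_social_ilv(self) -> int:
        return sum(p in ("social_only", "both") for p in self.ilv_placement)

    @property
    def n_baseline_params(self) -> int:
        return 1 if self.baseline == "constant" else 2

    @property
    def n_params(self) -> int:
        return (
            len(self.networks)
            + self.n_asocial_ilv
            + self.n_social_ilv
            + self.n_baseline_params
        )

    def label(self) -> str:
        nets = "+".join(self.networks) if self.networks else "asocial"
        ilvs = ",".join(self.ilv_placement) if self.ilv_placement else "-"
        return f"{nets}|{ilvs}|{self.baseline}"


def enumerate_model_set(
    networks: tuple[str, ...] = LAYERS,
    n_ilvs: int = 2,
    baseline: str = "constant",
) -> list[TadaModelSpec]:
    """All network subsets × ILV placements for one baseline family.

    With 4 candidate networks and 2 unconstrained ILVs this yields
    2^4 × 4^2 = 256 specifications per baseline; the empty network subset
    is the no-social-transmission model.
    """
    specs = []
    for r in range(len(networks) + 1):
        for subset in itertools.combinations(networks, r):
            for placement in itertools.product(ILV_PLACEMENTS, repeat=n_ilvs):
                specs.append(TadaModelSpec(subset, placement, baseline))
    return specs


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC; ``n`` is the number of acquisition events.

    Undefined (returns ``nan`` with a warning) when n <= k + 1.
    """
    if n <= k + 1:
        warnings.warn(
            f"AICc undefined for n={n}, K={k} (n <= K+1); model should be dropped",
            stacklevel=2,
        )
        return np.nan
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights w_m = exp(-Delta_m/2) / sum exp(-Delta/2).

    ``nan`` AICc values (dropped models) get weight 0.
    """
    a = np.asarray(aicc_values, dtype=float)
    ok = np.isfinite(a)
    w = np.zeros_like(a)
    if ok.any():
        d = a[ok] - np.nanmin(a[ok])
        e = np.exp(-d / 2.0)
        w[ok] = e / e.sum()
    return w


def summed_support(
    specs: list[TadaModelSpec], weights, component: str, ilv_index: int | None = None
) -> float:
    """Summed Akaike weight of models containing a network or an ILV.

    ``component`` is a layer name, or ``"ilv_asocial"`` / ``"ilv_social"`` /
    ``"ilv_any"`` together with ``ilv_index``.
    """
    w = np.asarray(weights, dtype=float)
    total = 0.0
    for spec, wm in zip(specs, w):
        if component in LAYERS:
            has = component in spec.networks
        elif component == "ilv_asocial":
            has = spec.ilv_placement[ilv_index] in ("asocial_only", "both")
        elif component == "ilv_social":
            has = spec.ilv_placement[ilv_index] in ("social_only", "both")
        elif component == "ilv_any":
            has = spec.ilv_placement[ilv_index] != "absent"
        elif component == "social":
            has = len(spec.networks) > 0
        else:
            raise ValueError(f"unknown component {component!r}")
        if has:
            total += wm
    return float(total)


def weighted_median(values, weights) -> float:
    """Median of ``values`` under normalised ``weights``."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        return np.nan
    order = np.argsort(v)
    v, w = v[order], w[order]
    cw = np.cumsum(w) / w.sum()
    return float(v[np.searchsorted(cw, 0.5)])


def model_averaged_median(
    specs: list[TadaModelSpec], weights, values_by_model, component: str
) -> float:
    """Akaike-weight-weighted median of a parameter across models holding it.

    ``values_by_model`` maps model index -> parameter value (``None`` if the
    model does not contain the component); weights are renormalised over the
    models that do.  This is one reading of a model-averaged median effect
    size; medians over bootstrap replicates are a different quantity and are
    not computed here.
    """
    vals, ws = [], []
    for m, spec in enumerate(specs):
        v = values_by_model.get(m)
        if v is not None:
            vals.append(v)
            ws.append(weights[m])
    if not vals:
        return np.nan
    return weighted_median(vals, ws)
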