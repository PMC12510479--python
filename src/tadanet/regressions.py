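"""Decision-strategy and exposure covariates, with logistic fit contracts.

Three analyses sit on top of the event streams:

* exposure — did a juvenile become knowledgeable, as a function of
  log10-counts of parental solves and parental scrounges between fledging
  and its own acquisition (non-learners: a 15-day post-fledge window, the
  mean latency to first solving);
* first-day side choices — whether side choice on a bird's first solving
  day follows the parental strategy during dependence, or the side
  majority among other birds' solves in the preceding 5 minutes;
* all-days side choices — social (others' right-proportion, 5 min) versus
  personal (own right-proportion, 1 h) information, each interacting with
  cumulative experience (per 100 solves).

The fits are a standard estimator behind a contract: penalized-likelihood
(MAP) logistic regression under weakly regularising normal priors
(sd 10 intercept, sd 5 slopes), with Laplace or cluster-robust 95%
intervals; any engine delivering posterior means and 95% intervals under
the same priors is interchangeable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special
from statsmodels.tools.numdiff import approx_hess1

from tadanet import events as ev
from tadanet.events import BirdRegistry
from tadanet.networks import DAY_S

SOCIAL_WINDOW_S = 300.0
PERSONAL_WINDOW_S = 3600.0
DEPENDENCE_DAYS = 15.0
PARENTAL_STRATEGY_CUTOFF = 0.9
PRIOR_SD_INTERCEPT = 10.0
PRIOR_SD_SLOPE = 5.0

Z95 = 1.959963984540054


def log_count(n) -> float:
    """log10(count + 1): a unit step is a tenfold ("per magnitude") increase."""
    return float(np.log10(np.asarray(n, dtype=float) + 1.0))


def classify_parental_strategy(
    n_right: int, n_left: int, cutoff: float = PARENTAL_STRATEGY_CUTOFF
) -> str:
    """Parental side strategy from solve counts during dependence."""
    total = n_right + n_left
    if total == 0:
        return "none"
    prop = n_right / total
    if prop > cutoff:
        return "nonconflicting_right"
    if prop < 1.0 - cutoff:
        return "nonconflicting_left"
    return "conflicting"


def _parental_solve_counts(
    puzzle_events: pd.DataFrame, registry: BirdRegistry, juvenile: str,
    start: float, end: float,
) -> tuple[int, int]:
    """(right, left) solves by the juvenile's parents in [start, end]."""
    parents = registry.parents(juvenile)
    m = (
        puzzle_events["bird_id"].isin(parents)
        & puzzle_events["action"].isin(ev.SOLVE_ACTIONS)
        & (puzzle_events["timestamp"] >= start)
        & (puzzle_events["timestamp"] <= end)
    )
    acts = puzzle_events.loc[m, "action"]
    return int((acts == "solve_right").sum()), int((acts == "solve_left").sum())


def build_exposure_records(
    puzzle_events: pd.DataFrame,
    registry: BirdRegistry,
    knowledge: pd.DataFrame,
    dependence_days: float = DEPENDENCE_DAYS,
) -> pd.DataFrame:
    """One record per juvenile: learned or not, plus parental exposure counts."""
    scrounges = ev.derive_scrounges(puzzle_events)
    kn = {r.bird_id: r for r in knowledge.itertuples(index=False)}
    rows = []
    for j in registry.juveniles:
        r = kn[j]
        fledge = registry.fledge_date(j)
        end = (
            r.acquisition_time
            if r.knowledgeable
            else fledge + dependence_days * DAY_S
        )
        n_right, n_left = _parental_solve_counts(puzzle_events, registry, j, fledge, end)
        parents = registry.parents(j)
        if scrounges.empty:
            n_scr = 0
        else:
            n_scr = int(
                (
                    scrounges["bird_id"].isin(parents)
                    & (scrounges["timestamp"] >= fledge)
                    & (scrounges["timestamp"] <= end)
                ).sum()
            )
        rows.append(
            {
                "juvenile_id": j,
                "learned": bool(r.knowledgeable),
                "parental_solves": n_right + n_left,
                "parental_scrounges": n_scr,
                "log_parental_solves": log_count(n_right + n_left),
                "log_parental_scrounges": log_count(n_scr),
                "parental_strategy": classify_parental_strategy(n_right, n_left),
            }
        )
    return pd.DataFrame(rows)


def build_side_choice_records(
    puzzle_events: pd.DataFrame,
    registry: BirdRegistry,
    social_window_s: float = SOCIAL_WINDOW_S,
    personal_window_s: float = PERSONAL_WINDOW_S,
) -> pd.DataFrame:
    """One record per juvenile solve with its social/personal context.

    ``social_prop_right``/``social_count`` summarise *other* birds' solves
    at the same site in the prior 5 minutes; ``personal_prop_right``/
    ``personal_count`` the focal bird's own solves in the prior hour
    (NaN-proportion when the window is empty).  ``cumulative_solves``
    counts the bird's prior solves; ``first_day`` flags the bird's first
    solving calendar day.  Availability filters are applied downstream.
    """
    solves = (
        puzzle_events[puzzle_events["action"].isin(ev.SOLVE_ACTIONS)]
        .sort_values("timestamp", kind="mergesort")
        .reset_index(drop=True)
    )
    rows = []
    for site, grp in solves.groupby("site_id", sort=False):
        t = grp["timestamp"].to_numpy()
        birds = grp["bird_id"].to_numpy()
        right = (grp["action"] == "solve_right").to_numpy().astype(int)
        is_juv = np.array([b in registry and registry.is_juvenile(b) for b in birds])
        first_day = {}
        for b in set(birds[is_juv]):
            first_day[b] = int(t[birds == b].min() // DAY_S)
        for i in np.flatnonzero(is_juv):
            b = birds[i]
            lo_s = np.searchsorted(t, t[i] - social_window_s, side="right")
            win = slice(lo_s, i)
            others = birds[win] != b
            n_soc = int(others.sum())
            soc_r = int(right[win][others].sum())
            lo_p = np.searchsorted(t, t[i] - personal_window_s, side="right")
            own_mask = birds[lo_p:i] == b
            n_per = int(own_mask.sum())
            per_r = int(right[lo_p:i][own_mask].sum())
            prior = int((birds[:i] == b).sum())
            rows.append(
                {
                    "juvenile_id": b,
                    "site_id": site,
                    "solve_time": float(t[i]),
                    "choice": "right" if right[i] else "left",
                    "social_count": n_soc,
                    "social_prop_right": soc_r / n_soc if n_soc else np.nan,
                    "personal_count": n_per,
                    "personal_prop_right": per_r / n_per if n_per else np.nan,
                    "cumulative_solves": prior,
                    "first_day": int(t[i] // DAY_S) == first_day[b],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# penalized logistic estimator
# ---------------------------------------------------------------------------

@dataclass
class LogitFit:
    terms: list[str]
    coef: np.ndarray
    se: np.ndarray

    def summary(self) -> pd.DataFrame:
        lo = self.coef - Z95 * self.se
        hi = self.coef + Z95 * self.se
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.coef,
                "se": self.se,
                "odds_ratio": np.exp(self.coef),
                "or_lower": np.exp(lo),
                "or_upper": np.exp(hi),
            }
        )


def penalized_logit(
    x: np.ndarray,
    y: np.ndarray,
    terms: list[str],
    groups: np.ndarray | None = None,
    prior_sd: np.ndarray | None = None,
) -> LogitFit:
    """MAP logistic regression with normal priors and robust intervals.

    The first column of ``x`` is the intercept (prior sd 10; slopes sd 5).
    With ``groups`` (≥ 2 clusters) the covariance is the cluster-robust
    sandwich, absorbing within-bird correlation; otherwise — including the
    degenerate single-cluster case, which warns — the Laplace (inverse
    Hessian) covariance is used.  Complete separation is tamed by the
    priors and reported via a warning when any |coefficient| is extreme.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = x.shape
    if prior_sd is None:
        prior_sd = np.r_[PRIOR_SD_INTERCEPT, np.full(p - 1, PRIOR_SD_SLOPE)]

    def neg_post(beta):
        eta = x @ beta
        ll = np.sum(y * eta - np.logaddexp(0.0, eta))
        return -(ll - 0.5 * np.sum((beta / prior_sd) ** 2))

    def grad(beta):
        mu = special.expit(x @ beta)
        return -(x.T @ (y - mu) - beta / prior_sd**2)

    res = optimize.minimize(neg_post, np.zeros(p), jac=grad, method="BFGS")
    beta = res.x
    h = approx_hess1(beta, neg_post)
    cov = np.linalg.pinv(h)
    if groups is not None:
        uniq = np.unique(groups)
        if len(uniq) < 2:
            warnings.warn(
                "single group: random-intercept structure degenerate, "
                "falling back to fixed-effects intervals",
                stacklevel=2,
            )
        else:
            mu = special.expit(x @ beta)
            resid = (y - mu)[:, None] * x
            meat = np.zeros((p, p))
            for g in uniq:
                sg = resid[groups == g].sum(axis=0)
                meat += np.outer(sg, sg)
            cov = cov @ meat @ cov
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    if np.any(np.abs(beta) > 15):
        warnings.warn("extreme coefficients: possible complete separation", stacklevel=2)
    return LogitFit(terms, beta, se)


def fit_exposure_model(records: pd.DataFrame) -> pd.DataFrame:
    """Odds of learning per magnitude of parental solves and scrounges.

    Returns the term table plus a ``baseline_probability`` row: the
    intercept-implied probability of learning for a juvenile whose parents
    produced no solves and no scrounges.
    """
    if len(records) < 10 or records["learned"].nunique() < 2:
        raise ValueError("need >= 10 records with both outcomes represented")
    x = np.column_stack(
        [
            np.ones(len(records)),
            records["log_parental_solves"].to_numpy(),
            records["log_parental_scrounges"].to_numpy(),
        ]
    )
    y = records["learned"].to_numpy(dtype=float)
    fit = penalized_logit(
        x, y, ["intercept", "log_parental_solves", "log_parental_scrounges"]
    )
    out = fit.summary()
    b0, s0 = fit.coef[0], fit.se[0]
    base = pd.DataFrame(
        {
            "term": ["baseline_probability"],
            "estimate": [special.expit(b0)],
            "se": [np.nan],
            "odds_ratio": [np.nan],
            "or_lower": [special.expit(b0 - Z95 * s0)],
            "or_upper": [special.expit(b0 + Z95 * s0)],
        }
    )
    return pd.concat([out, base], ignore_index=True)


SIDE_CHOICE_MODELS = ("first_day_parental", "first_day_social", "all_days")


def fit_side_choice_models(
    records: pd.DataFrame, model: str, exposure: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Fit one of the three side-choice analyses.

    ``first_day_parental`` regresses each bird's first-day right-proportion
    on the parental strategy category (linear; estimates are proportion
    differences from the "none" category, not odds ratios).
    ``first_day_social`` and ``all_days`` are logistic models of each solve
    with bird-clustered intervals; experience enters per 100 solves.
    """
    if model not in SIDE_CHOICE_MODELS:
        raise ValueError(f"unknown model {model!r}")
    if model == "first_day_parental":
        if exposure is None:
            raise ValueError("parental model needs exposure records for strategies")
        first = records[records["first_day"]]
        prop = (
            first.assign(right=(first["choice"] == "right").astype(float))
            .groupby("juvenile_id")["right"]
            .mean()
        )
        strat = exposure.set_index("juvenile_id")["parental_strategy"]
        df = pd.DataFrame({"prop_right": prop}).join(strat, how="left").fillna(
            {"parental_strategy": "none"}
        )
        import statsmodels.formula.api as smf

        ols = smf.ols(
            "prop_right ~ C(parental_strategy, Treatment('none'))", data=df
        ).fit()
        ci = ols.conf_int()
        return pd.DataFrame(
            {
                "term": ols.params.index,
                "estimate": ols.params.to_numpy(),
                "se": ols.bse.to_numpy(),
                "odds_ratio": np.nan,
                "or_lower": ci[0].to_numpy(),
                "or_upper": ci[1].to_numpy(),
            }
        )
    if model == "first_day_social":
        d = records[records["first_day"] & (records["social_count"] >= 1)].copy()
        x = np.column_stack(
            [
                np.ones(len(d)),
                d["social_prop_right"].to_numpy(),
                d["social_count"].to_numpy(),
                d["social_prop_right"].to_numpy() * d["social_count"].to_numpy(),
            ]
        )
        terms = ["intercept", "social_prop_right", "social_count",
                 "social_prop_right:social_count"]
    else:
        d = records[
            (records["social_count"] >= 1) & (records["personal_count"] >= 1)
        ].copy()
        c100 = d["cumulative_solves"].to_numpy() / 100.0
        x = np.column_stack(
            [
                np.ones(len(d)),
                d["social_prop_right"].to_numpy(),
                d["personal_prop_right"].to_numpy(),
                c100,
                d["social_prop_right"].to_numpy() * c100,
                d["personal_prop_right"].to_numpy() * c100,
            ]
        )
        terms = [
            "intercept",
            "social_prop_right",
            "personal_prop_right",
            "cumulative_per100",
            "social_prop_right:cumulative_per100",
            "personal_prop_right:cumulative_per100",
        ]
    y = (d["choice"] == "right").to_numpy(dtype=float)
    fit = penalized_logit(x, y, terms, groups=d["juvenile_id"].to_numpy())
    return fit.summary()
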