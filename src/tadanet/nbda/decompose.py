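"""Per-event learning-pathway decomposition and %ST summaries.

At the moment individual i acquires the behaviour its hazard is a sum of
one asocial and four social components; the probability that the event
travelled through layer k is that layer's share of the total rate
multiplier:

    p_k(e) = s_k exp(beta_S . x_i) S_ik / R_i,    p_asocial(e) = exp(beta_A . x_i) / R_i.

Events are additionally classed by whether the learner was the first of
its sibling cohort to acquire (no same-brood bird knowledgeable at the
event time) or a subsequent learner — the split that separates "who seeds
a family" from "who spreads it within the family".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from tadanet.networks import LAYERS
from tadanet.nbda.data import DiffusionData
from tadanet.nbda.fit import TadaFit
from tadanet.nbda.likelihood import rate_multipliers, social_components

PATHWAY_COLUMNS = [f"p_{l}" for l in LAYERS] + ["p_asocial"]


def pathway_decomposition(data: DiffusionData, fit: TadaFit) -> pd.DataFrame:
    """PathwayTable: one row per acquisition event, probabilities sum to 1.

    Columns: ``site_id, event, learner_id, time_days``, one probability per
    pathway layer plus asocial, and ``learner_class`` in
    ``{first_in_cohort, subsequent}`` (first iff no same-brood bird was
    knowledgeable at the event time; learners without brood information are
    classed first).
    """
    params = fit.params
    # global acquisition order for the sibling-cohort split
    acq_global: list[tuple[float, str]] = []
    for site in data.sites:
        for e in range(site.n_events):
            acq_global.append((site.event_times[e], site.ids[site.event_learner[e]]))
    rows = []
    for site in data.sites:
        r = rate_multipliers(site, params)
        sc = social_components(site, params)
        xa = site.ilv @ params.beta_asocial
        for e in range(site.n_events):
            i = site.event_learner[e]
            t_e = site.event_times[e]
            learner = site.ids[i]
            denom = r[e, i]
            if denom <= 0:
                raise ValueError("zero total rate at an acquisition event")
            probs = {f"p_{l}": sc[e, i, k] / denom for k, l in enumerate(LAYERS)}
            probs["p_asocial"] = np.exp(xa[e, i]) / denom
            brood = (data.broods or {}).get(learner)
            first = True
            if brood is not None:
                for t_other, other in acq_global:
                    if (
                        other != learner
                        and t_other < t_e
                        and (data.broods or {}).get(other) == brood
                    ):
                        first = False
                        break
            rows.append(
                {
                    "site_id": site.site_id,
                    "event": e,
                    "learner_id": learner,
                    "time_days": t_e,
                    **probs,
                    "learner_class": "first_in_cohort" if first else "subsequent",
                }
            )
    return pd.DataFrame(rows)


def percent_st(pathway_table: pd.DataFrame) -> pd.Series:
    """%ST per pathway: mean per-event probability × 100 (sums to 100)."""
    return pathway_table[PATHWAY_COLUMNS].mean(axis=0) * 100.0


def pathway_class_summary(pathway_table: pd.DataFrame) -> pd.DataFrame:
    """Mean and median pathway probabilities per learner class (as %)."""
    out = []
    for cls, grp in pathway_table.groupby("learner_class"):
        for stat, agg in (("mean", grp[PATHWAY_COLUMNS].mean()),
                          ("median", grp[PATHWAY_COLUMNS].median())):
            row = {"learner_class": cls, "statistic": stat, "n_events": len(grp)}
            row.update((c, v * 100.0) for c, v in agg.items())
            out.append(row)
    return pd.DataFrame(out)
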