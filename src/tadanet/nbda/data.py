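"""Diffusion-data containers and assembly from event streams.

A :class:`SiteDiffusion` holds one site's acquisition history on a time
axis of days since diffusion start, discretised into the ``E + 1``
inter-event intervals over which networks, transmission weights, presence
and ILVs are piecewise constant: interval ``m`` spans
``[tau_m, tau_{m+1}]`` with ``tau_0 = 0``, ``tau_m`` the m-th acquisition
time and ``tau_{E+1}`` the censoring time.  Acquisition event ``e``
(0-based) closes interval ``e``, so the hazard leading to an event is
evaluated with that interval's arrays.

``social[m, i, k]`` is individual i's weighted knowledgeable-neighbour sum
in layer k during interval m — the product ``a_ij w_j z_j pi_j`` already
summed over transmitters j — so the likelihood never needs to touch raw
networks again.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tadanet import events as ev
from tadanet import networks as nw
from tadanet.networks import DAY_S, LAYERS

ILV_NAMES = ("parental_solves", "scrounges")
TIE_SEPARATION_S = 1.0
MIN_SITE_EVENTS = 3


@dataclass
class SiteDiffusion:
    """One site's discretised diffusion history (times in days)."""

    site_id: str
    ids: list[str]
    event_times: np.ndarray  # (E,) strictly increasing, > 0
    event_learner: np.ndarray  # (E,) int index into ids
    end_time: float
    social: np.ndarray  # (E+1, n, len(LAYERS))
    ilv: np.ndarray  # (E+1, n, n_ilv)
    present: np.ndarray  # (E+1, n) bool
    naive: np.ndarray = field(init=False)  # (E+1, n) bool

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times, dtype=float)
        if np.any(np.diff(t) <= 0) or (t.size and t[0] <= 0):
            raise ValueError("event times must be strictly increasing and > 0")
        if t.size and self.end_time < t[-1]:
            raise ValueError("end_time precedes last event")
        e, n = len(t), len(self.ids)
        for name, arr, shape in (
            ("social", self.social, (e + 1, n, len(LAYERS))),
            ("ilv", self.ilv, None),
            ("present", self.present, (e + 1, n)),
        ):
            if shape is not None and arr.shape != shape:
                raise ValueError(f"{name}: shape {arr.shape} != {shape}")
        if self.ilv.shape[:2] != (e + 1, n):
            raise ValueError("ilv: wrong leading shape")
        if not np.all(np.isfinite(self.ilv)):
            raise ValueError("ILVs must be finite")
        if self.social.min() < 0:
            raise ValueError("social sums must be non-negative")
        naive = np.ones((e + 1, n), dtype=bool)
        for m, learner in enumerate(self.event_learner):
            naive[m + 1 :, learner] = False
        self.naive = naive

    @property
    def n_events(self) -> int:
        return len(self.event_times)

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def boundaries(self) -> np.ndarray:
        """Interval boundaries ``tau_0..tau_{E+1}`` (length E + 2)."""
        return np.concatenate(([0.0], self.event_times, [self.end_time]))


@dataclass
class DiffusionData:
    """Validated multi-site diffusion data with shared ILV definitions."""

    sites: list[SiteDiffusion]
    ilv_names: tuple[str, ...] = ILV_NAMES
    broods: dict[str, str] | None = None  # learner id -> brood id

    @property
    def n_events(self) -> int:
        return sum(s.n_events for s in self.sites)

    @property
    def n_ilvs(self) -> int:
        return len(self.ilv_names)


def acquisition_events(
    knowledge: pd.DataFrame, puzzle_events: pd.DataFrame, diffusion_start: float
) -> pd.DataFrame:
    """Juvenile acquisition events (learner, absolute time, site), time-sorted.

    The site of an acquisition is the site of the bird's third solve.  Ties
    are broken by separating identical times by 1 s in recorded order.
    """
    rows = []
    for r in knowledge.itertuples(index=False):
        if not r.knowledgeable or r.demonstrator or r.filtered:
            continue
        t3 = r.acquisition_time
        if t3 < diffusion_start:
            continue
        m = (
            (puzzle_events["bird_id"] == r.bird_id)
            & puzzle_events["action"].isin(ev.SOLVE_ACTIONS)
            & (puzzle_events["timestamp"] == t3)
        )
        site = puzzle_events.loc[m, "site_id"].iloc[0]
        rows.append({"learner_id": r.bird_id, "timestamp": float(t3), "site_id": site})
    out = pd.DataFrame(rows, columns=["learner_id", "timestamp", "site_id"])
    out = out.sort_values("timestamp", kind="mergesort").reset_index(drop=True)
    # separate exact ties in recorded order so event times are strict
    t = out["timestamp"].to_numpy().copy()
    for i in range(1, len(t)):
        if t[i] <= t[i - 1]:
            t[i] = t[i - 1] + TIE_SEPARATION_S
    out["timestamp"] = t
    return out


def transmission_weight(
    puzzle_events: pd.DataFrame, bird_id: str, acquisition_time: float, now: float
) -> float:
    """Solves per day since acquisition, cumulative to ``now`` (days >= 1)."""
    if now <= acquisition_time:
        return 0.0
    ts = ev.solve_times(puzzle_events, bird_id)
    n = int(np.sum((ts >= acquisition_time) & (ts <= now)))
    days = max((now - acquisition_time) / DAY_S, 1.0)
    return n / days


def build_diffusion_data(
    detections: pd.DataFrame,
    puzzle_events: pd.DataFrame,
    registry: ev.BirdRegistry,
    diffusion_start: float,
    study_end: float | None = None,
    window_days: float = 7.0,
    min_registrations: int = 10,
    k_max: int = 10,
    min_site_events: int = MIN_SITE_EVENTS,
    seed: int = 0,
) -> DiffusionData:
    """Assemble multi-site diffusion data from raw streams.

    Per acquisition event this recomputes the four-layer association
    network in the ±``window_days`` window, the presence matrix over the
    preceding week, transmission weights for every knowledgeable bird, and
    the two time-varying ILVs (parental solves since fledging; own
    scrounges to date), centred across the learner pool within each
    interval.  Sites with fewer than ``min_site_events`` acquisitions are
    dropped.
    """
    knowledge = ev.knowledge_states(puzzle_events, registry, diffusion_start)
    if study_end is None:
        study_end = float(
            max(puzzle_events["timestamp"].max(), detections["timestamp"].max())
        )
    acq = acquisition_events(knowledge, puzzle_events, diffusion_start)
    scrounges = ev.derive_scrounges(puzzle_events)
    kn = {r.bird_id: r for r in knowledge.itertuples(index=False)}
    juveniles = registry.juveniles
    # caches shared across sites and intervals
    solves = puzzle_events[puzzle_events["action"].isin(ev.SOLVE_ACTIONS)]
    solve_t_by_bird = {
        b: np.unique(g["timestamp"].to_numpy()) for b, g in solves.groupby("bird_id")
    }
    scrounge_t_by_bird = (
        {b: np.sort(g["timestamp"].to_numpy()) for b, g in scrounges.groupby("bird_id")}
        if not scrounges.empty
        else {}
    )
    feeders = detections[detections["source"] == "network_feeder"]
    counts = feeders["bird_id"].value_counts()
    included = set(b for b in registry.bird_ids if counts.get(b, 0) >= min_registrations)
    all_gatherings = nw.gathering_events_in_window(
        feeders[feeders["bird_id"].isin(included)],
        float(feeders["timestamp"].min()) if not feeders.empty else 0.0,
        float(feeders["timestamp"].max()) if not feeders.empty else 0.0,
        k_max=k_max,
        seed=seed,
    )

    def solves_up_to(bird: str, t0: float, t1: float) -> int:
        ts = solve_t_by_bird.get(bird)
        if ts is None:
            return 0
        return int(np.searchsorted(ts, t1, side="right") - np.searchsorted(ts, t0))

    # transmitters: demonstrators from start; filtered adults and juvenile
    # learners from their own acquisition time
    acq_time = {
        r.bird_id: r.acquisition_time
        for r in knowledge.itertuples(index=False)
        if r.knowledgeable
    }
    sites_out: list[SiteDiffusion] = []
    broods: dict[str, str] = {}
    for site in sorted(acq["site_id"].unique()):
        sev = acq[acq["site_id"] == site].reset_index(drop=True)
        if len(sev) < min_site_events:
            continue
        ids = list(juveniles)
        index = {b: i for i, b in enumerate(ids)}
        e = len(sev)
        n = len(ids)
        social = np.zeros((e + 1, n, len(LAYERS)))
        ilv = np.zeros((e + 1, n, len(ILV_NAMES)))
        present = np.zeros((e + 1, n), dtype=bool)
        pres = nw.presence_matrix(
            detections, puzzle_events, sev, registry, lookback_days=window_days
        )
        times_abs = sev["timestamp"].to_numpy()
        for m in range(e + 1):
            # interval m closes at event m; the final censoring interval
            # reuses the state of the last event
            ref = min(m, e - 1)
            t_ref = times_abs[ref]
            net = nw.dynamic_network(
                detections,
                registry,
                t_ref,
                window_days=window_days,
                min_registrations=min_registrations,
                k_max=k_max,
                seed=seed,
                gatherings=all_gatherings,
            )
            nidx = {b: i for i, b in enumerate(net.node_ids)}
            rows = np.array([nidx.get(b, -1) for b in ids])
            present[m] = pres[ref].reindex(ids).to_numpy(dtype=bool)
            # transmitters active at the start of interval m
            t_start_abs = diffusion_start if m == 0 else times_abs[m - 1]
            for j, t_acq in acq_time.items():
                r = kn[j]
                if registry.is_adult(j):
                    active = r.demonstrator or (r.filtered and t_acq <= t_start_abs)
                else:
                    active = t_acq <= t_start_abs and m > 0
                if not active or j not in nidx:
                    continue
                pi_j = pres.loc[j, ref] if j in pres.index else 0
                if not pi_j:
                    continue
                n_perf = solves_up_to(j, t_acq, t_ref)
                days = max((t_ref - t_acq) / DAY_S, 1.0)
                w_j = n_perf / days
                if w_j <= 0:
                    continue
                jj = nidx[j]
                ok = rows >= 0
                for k, layer in enumerate(LAYERS):
                    col = net.matrices[layer][:, jj]
                    social[m, ok, k] += col[rows[ok]] * w_j
            # ILVs at the start of interval m
            for b, i in index.items():
                fledge = registry.fledge_date(b)
                ilv[m, i, 0] = sum(
                    solves_up_to(p, fledge, t_ref) for p in registry.parents(b)
                )
                sc = scrounge_t_by_bird.get(b)
                if sc is not None:
                    ilv[m, i, 1] = int(np.searchsorted(sc, t_ref, side="right"))
        # centre ILVs across the learner pool within each interval and put
        # them on unit scale so exp(beta . x) stays well conditioned
        ilv -= ilv.mean(axis=1, keepdims=True)
        sd = ilv.reshape(-1, ilv.shape[-1]).std(axis=0)
        ilv /= np.where(sd > 0, sd, 1.0)
        learner_idx = np.array([index[b] for b in sev["learner_id"]], dtype=int)
        event_times = (times_abs - diffusion_start) / DAY_S
        sites_out.append(
            SiteDiffusion(
                site_id=site,
                ids=ids,
                event_times=event_times,
                event_learner=learner_idx,
                end_time=max((study_end - diffusion_start) / DAY_S, event_times[-1]),
                social=social,
                ilv=ilv,
                present=present,
            )
        )
        for b in sev["learner_id"]:
            br = registry.brood(b)
            if br is not None:
                broods[b] = br
    for b in juveniles:
        br = registry.brood(b)
        if br is not None:
            broods.setdefault(b, br)
    return DiffusionData(sites=sites_out, broods=broods)
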