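"""Multi-layer association networks from feeder co-visiting.

Feeder detections are clustered per site and day into *gathering events*
with 1-D Gaussian mixtures over timestamps (the number of components chosen
by BIC).  Under the gambit of the group, all members of a gathering are
taken to associate, and dyadic association strength is the simple-ratio
index

    SRI(a, b) = n_ab / (n_ab + n_a + n_b)

where n_ab counts gatherings containing both birds and n_a, n_b gatherings
containing only one of them.  Each dyad's weight is routed to exactly one
of four pathway layers by pedigree:

* vertical — a juvenile and one of its own parents,
* oblique  — a juvenile and a non-parental adult,
* sibling  — two juveniles of the same brood,
* peer     — two juveniles of different broods;

adult–adult dyads carry no layer (adults are transmitters, not learners).
Networks are recalculated in a sliding window around each acquisition event
so that associations can change over the season.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from tadanet.events import BirdRegistry

logger = logging.getLogger(__name__)

DAY_S = 86400.0
LAYERS = ("vertical", "oblique", "sibling", "peer")


@dataclass(frozen=True)
class GatheringEvent:
    """Birds assigned to one mixture component at one site on one day."""

    site_id: str
    day: int
    member_ids: frozenset
    time_span: tuple[float, float]


@dataclass
class NetworkLayerSet:
    """Four masked symmetric association matrices over a common node order."""

    node_ids: list[str]
    matrices: dict[str, np.ndarray]
    window: tuple[float, float]

    def __post_init__(self) -> None:
        n = len(self.node_ids)
        for layer in LAYERS:
            a = self.matrices[layer]
            if a.shape != (n, n):
                raise ValueError(f"layer {layer}: shape {a.shape} != ({n},{n})")
            if not np.allclose(a, a.T):
                raise ValueError(f"layer {layer}: not symmetric")
            if np.any(np.diag(a) != 0):
                raise ValueError(f"layer {layer}: nonzero diagonal")
            if a.min() < 0 or a.max() > 1:
                raise ValueError(f"layer {layer}: weights outside [0,1]")

    def index_of(self, bird_id: str) -> int:
        return self.node_ids.index(bird_id)

    def to_edgelist(self) -> pd.DataFrame:
        """Long-format ``layer,bird_a,bird_b,weight,window_start,window_end``."""
        rows = []
        for layer in LAYERS:
            a = self.matrices[layer]
            ii, jj = np.nonzero(np.triu(a, k=1))
            for i, j in zip(ii, jj):
                rows.append(
                    {
                        "layer": layer,
                        "bird_a": self.node_ids[i],
                        "bird_b": self.node_ids[j],
                        "weight": a[i, j],
                        "window_start": self.window[0],
                        "window_end": self.window[1],
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["layer", "bird_a", "bird_b", "weight", "window_start", "window_end"],
        )


def detect_gathering_events(
    detections: pd.DataFrame, k_max: int = 10, seed: int = 0
) -> list[GatheringEvent]:
    """Cluster one site-day of detections into gathering events.

    Fits 1-D Gaussian mixtures with K = 1..min(k_max, n) components to the
    timestamps, picks K by BIC, and assigns each detection to its
    maximum-responsibility component.  Component variances are floored at
    (30 s)^2 so that sub-minute visit bursts are never split into
    near-singular clusters.  Degenerate inputs (a single detection, or all
    timestamps identical) give one event.
    """
    if detections.empty:
        return []
    site = detections["site_id"].iloc[0]
    t = detections["timestamp"].to_numpy(dtype=float)
    day = int(t.min() // DAY_S)
    birds = detections["bird_id"].to_numpy()
    if len(t) == 1 or np.ptp(t) == 0.0:
        return [
            GatheringEvent(site, day, frozenset(birds), (float(t.min()), float(t.max())))
        ]
    x = t.reshape(-1, 1)
    best = None
    best_bic = np.inf
    for k in range(1, min(k_max, len(t)) + 1):
        gm = GaussianMixture(
            n_components=k, n_init=3, reg_covar=900.0, random_state=seed
        ).fit(x)
        bic = gm.bic(x)
        if bic < best_bic - 1e-9:
            best_bic = bic
            best = gm
    labels = best.predict(x)
    out = []
    for lab in np.unique(labels):
        sel = labels == lab
        out.append(
            GatheringEvent(
                site,
                day,
                frozenset(birds[sel]),
                (float(t[sel].min()), float(t[sel].max())),
            )
        )
    out.sort(key=lambda g: g.time_span[0])
    return out


def simple_ratio_index(
    gathering_events: list[GatheringEvent], bird_a: str, bird_b: str
) -> float:
    """SRI = joint sightings / sightings of a, b or both; 0 if never seen."""
    both = either = 0
    for g in gathering_events:
        a = bird_a in g.member_ids
        b = bird_b in g.member_ids
        if a and b:
            both += 1
        if a or b:
            either += 1
    return both / either if either else 0.0


def dyad_layer(registry: BirdRegistry, bird_a: str, bird_b: str) -> str | None:
    """Pathway layer of a dyad, or None for adult–adult pairs."""
    a_juv = registry.is_juvenile(bird_a)
    b_juv = registry.is_juvenile(bird_b)
    if a_juv and b_juv:
        return "sibling" if registry.brood(bird_a) == registry.brood(bird_b) else "peer"
    if not a_juv and not b_juv:
        return None
    juv, adult = (bird_a, bird_b) if a_juv else (bird_b, bird_a)
    return "vertical" if adult in registry.parents(juv) else "oblique"


def layer_masks(registry: BirdRegistry) -> dict[tuple[str, str], str]:
    """Layer assignment for every admissible (sorted) dyad in the registry."""
    ids = registry.bird_ids
    out = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            layer = dyad_layer(registry, a, b)
            if layer is not None:
                out[tuple(sorted((a, b)))] = layer
    return out


def gathering_events_in_window(
    feeder_detections: pd.DataFrame,
    start: float,
    end: float,
    k_max: int = 10,
    seed: int = 0,
) -> list[GatheringEvent]:
    """Gathering events for all site-days whose detections fall in [start, end]."""
    m = (feeder_detections["timestamp"] >= start) & (
        feeder_detections["timestamp"] <= end
    )
    window = feeder_detections.loc[m].copy()
    if window.empty:
        return []
    window["_day"] = (window["timestamp"] // DAY_S).astype(int)
    events: list[GatheringEvent] = []
    for (site, day), grp in window.groupby(["site_id", "_day"], sort=True):
        events.extend(detect_gathering_events(grp, k_max=k_max, seed=seed))
    return events


def dynamic_network(
    detections: pd.DataFrame,
    registry: BirdRegistry,
    event_time: float,
    window_days: float = 7.0,
    min_registrations: int = 10,
    k_max: int = 10,
    seed: int = 0,
    gatherings: list[GatheringEvent] | None = None,
) -> NetworkLayerSet:
    """Four-layer association network in ±``window_days`` around an event.

    Only feeder detections enter the associations.  Birds with fewer than
    ``min_registrations`` feeder detections over the *whole* study are
    excluded as transients.  Dyads never co-observed get weight 0.
    Precomputed study-wide ``gatherings`` may be supplied (events whose
    midpoint falls in the window are used); otherwise mixtures are fitted
    on the windowed detections.
    """
    feeders = detections[detections["source"] == "network_feeder"]
    counts = feeders["bird_id"].value_counts()
    node_ids = sorted(
        b
        for b in registry.bird_ids
        if counts.get(b, 0) >= min_registrations
    )
    window = (event_time - window_days * DAY_S, event_time + window_days * DAY_S)
    if gatherings is None:
        keep = feeders[feeders["bird_id"].isin(node_ids)]
        gatherings = gathering_events_in_window(keep, window[0], window[1], k_max, seed)
    else:
        gatherings = [
            g
            for g in gatherings
            if window[0] <= 0.5 * (g.time_span[0] + g.time_span[1]) <= window[1]
        ]
    n = len(node_ids)
    mats = {layer: np.zeros((n, n)) for layer in LAYERS}
    if not gatherings:
        logger.info("no detections in window %s; network is empty", window)
    masks = layer_masks(registry)
    # membership indicator per gathering for vectorised SRI counting
    idx = {b: i for i, b in enumerate(node_ids)}
    member = np.zeros((len(gatherings), n), dtype=bool)
    for g_i, g in enumerate(gatherings):
        for b in g.member_ids:
            if b in idx:
                member[g_i, idx[b]] = True
    both = member.astype(int).T @ member.astype(int)
    seen = member.sum(axis=0)
    either = seen[:, None] + seen[None, :] - both
    with np.errstate(invalid="ignore", divide="ignore"):
        sri = np.where(either > 0, both / np.maximum(either, 1), 0.0)
    np.fill_diagonal(sri, 0.0)
    for (a, b), layer in masks.items():
        if a in idx and b in idx:
            i, j = idx[a], idx[b]
            mats[layer][i, j] = mats[layer][j, i] = sri[i, j]
    return NetworkLayerSet(node_ids, mats, window)


def presence_matrix(
    detections: pd.DataFrame,
    puzzle_events: pd.DataFrame,
    acquisition_events: pd.DataFrame,
    registry: BirdRegistry,
    lookback_days: float = 7.0,
) -> pd.DataFrame:
    """Binary bird × acquisition-event availability indicators.

    π(i, e) = 1 iff bird i was registered — on a feeder or on the puzzle —
    at event e's site within ``(t_e − lookback, t_e]``.  Rows are all birds
    in the registry; columns follow ``acquisition_events`` row order.
    """
    streams = [detections[["bird_id", "timestamp", "site_id"]]]
    if not puzzle_events.empty:
        streams.append(puzzle_events[["bird_id", "timestamp", "site_id"]])
    allev = pd.concat(streams, ignore_index=True)
    birds = registry.bird_ids
    out = np.zeros((len(birds), len(acquisition_events)), dtype=int)
    for e_i, ev in enumerate(acquisition_events.itertuples(index=False)):
        t, site = ev.timestamp, ev.site_id
        m = (
            (allev["site_id"] == site)
            & (allev["timestamp"] > t - lookback_days * DAY_S)
            & (allev["timestamp"] <= t)
        )
        present = set(allev.loc[m, "bird_id"])
        for b_i, b in enumerate(birds):
            if b in present:
                out[b_i, e_i] = 1
    return pd.DataFrame(out, index=birds, columns=range(len(acquisition_events)))


def plot_network(layers: NetworkLayerSet, ax=None):
    """Quick-look spring-layout plot with one colour per layer."""
    import matplotlib.pyplot as plt
    import networkx as nx

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    g = nx.Graph()
    g.add_nodes_from(layers.node_ids)
    colours = {"vertical": "tab:red", "oblique": "tab:orange",
               "sibling": "tab:blue", "peer": "tab:green"}
    for layer in LAYERS:
        a = layers.matrices[layer]
        ii, jj = np.nonzero(np.triu(a, k=1))
        for i, j in zip(ii, jj):
            g.add_edge(layers.node_ids[i], layers.node_ids[j],
                       weight=a[i, j], colour=colours[layer])
    pos = nx.spring_layout(g, seed=0)
    edge_colours = [d["colour"] for _, _, d in g.edges(data=True)]
    widths = [3 * d["weight"] for _, _, d in g.edges(data=True)]
    nx.draw_networkx(g, pos, ax=ax, node_size=60, with_labels=False,
                     edge_color=edge_colours, width=widths)
    ax.set_axis_off()
    return ax
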