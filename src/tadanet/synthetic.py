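"""Synthetic breeding populations, feeder streams and diffusions.

The generator emulates the study system end to end with known ground
truth: breeding pairs fledge broods at several sites; families forage
together so that sibling associations are strongest, parent–offspring next,
and other dyads weakest; knowledge of a two-option puzzle spreads from
adult demonstrators through the configured transmission pathways; and
knowledgeable birds emit solve streams whose side choices follow a
conformity-versus-personal-information rule, with scrounge visits inserted
inside the 2-second door-open window.

Scale defaults mirror the study system: four sites, twelve breeding pairs
per site with mean clutch five (≈ 240 fledglings, of which a quarter or so
learn), a two-week demonstrator seeding period, ten weeks of tracking with
four puzzle days and two feeder days per week, and solve rates of a few
solves per experimental day.

The diffusion itself is simulated by exact event-driven (Gillespie)
sampling — competing exponentials over the individual hazards within each
piecewise-constant interval, with time rescaling through the integrated
baseline for the Weibull family — so the simulator is a quadrature-free
oracle for the TADA likelihood, and each acquisition carries a ground-truth
pathway label drawn proportional to its hazard components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tadanet.events import BirdRegistry
from tadanet.networks import DAY_S, LAYERS, NetworkLayerSet
from tadanet.nbda.data import DiffusionData, SiteDiffusion

PUZZLE_WEEKDAYS = (0, 1, 2, 3)
FEEDER_WEEKDAYS = (4, 5)


def _default_assoc():
    return {"vertical": 0.35, "oblique": 0.10, "sibling": 0.55, "peer": 0.05}


def _default_s():
    return {"vertical": 1.0, "oblique": 2.0, "sibling": 5.0, "peer": 0.0}


@dataclass
class ScenarioConfig:
    """All knobs of the generator; every default is a study-scale choice."""

    seed: int = 0
    n_sites: int = 4
    pairs_per_site: int = 12
    clutch_mean: float = 5.0  # Poisson, truncated at 1
    fledge_spread_days: float = 10.0
    study_days: float = 70.0
    warmup_days: float = 14.0  # demonstrator solving before diffusion start
    # family-biased gathering attendance at feeders: each gathering is a
    # small flock of whole families drawn with heterogeneous propensities
    families_per_gathering: int = 3
    sibling_attend: float = 0.9
    parent_attend: float = 0.6
    other_attend: float = 0.02
    gatherings_per_day: int = 8
    visits_per_attendance: int = 2
    gathering_sd_s: float = 90.0
    # block association strengths per layer (used for ground-truth networks)
    assoc_strength: dict = field(default_factory=_default_assoc)
    # true transmission parameters
    s_true: dict = field(default_factory=_default_s)
    baseline: str = "constant"
    theta_days: float = 5000.0
    kappa: float = 1.0
    beta_asocial: tuple = (0.0, 0.0)
    beta_social: tuple = (0.0, 0.0)
    ilv_sd: tuple = (0.0, 0.0)  # spread of the per-bird ILV values
    demonstrators_per_site: int = 12  # paired adults, in whole pairs (half the pairs)
    solve_rate_mean: float = 6.0  # solves per experimental day
    solve_rate_sigma: float = 0.5  # lognormal sigma of individual rates
    # side-choice decision rule (odds ratios on the fitted scale)
    or_social: float = 4.15
    or_personal: float = 7.30
    or_social_per100: float = 0.76
    or_personal_per100: float = 1.22
    social_window_s: float = 300.0
    personal_window_s: float = 3600.0
    scrounge_prob: float = 0.15


def recovery_scenario(seed: int = 0) -> ScenarioConfig:
    """Sibling-only transmission (s_sibling = 5) with rare asocial seeding."""
    return ScenarioConfig(
        seed=seed,
        s_true={"vertical": 0.0, "oblique": 0.0, "sibling": 5.0, "peer": 0.0},
        theta_days=1000.0,
        demonstrators_per_site=2,
    )


def null_scenario(seed: int = 0) -> ScenarioConfig:
    """No social transmission; acquisitions are i.i.d. baseline draws."""
    return ScenarioConfig(
        seed=seed,
        s_true={l: 0.0 for l in LAYERS},
        theta_days=300.0,
        demonstrators_per_site=2,
    )


@dataclass
class Population:
    """Generated registry plus the site/brood bookkeeping the field crew knows."""

    registry: BirdRegistry
    site_of: dict[str, str]
    sites: list[str]
    demonstrators: dict[str, str]  # bird -> restricted side ("left"/"right")

    def birds_at(self, site: str) -> list[str]:
        return [b for b, s in self.site_of.items() if s == site]

    def juveniles_at(self, site: str) -> list[str]:
        return [b for b in self.birds_at(site) if self.registry.is_juvenile(b)]


def generate_population(config: ScenarioConfig) -> Population:
    """Breeding pairs, broods and demonstrator assignments, seed-determined.

    Demonstrator pairs alternate between same-side and opposite-side
    restriction, mirroring an experimental design that manipulates whether
    parents hold non-conflicting or conflicting knowledge.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    site_of = {}
    demonstrators: dict[str, str] = {}
    sites = [f"S{k + 1}" for k in range(config.n_sites)]
    demo_pairs = config.demonstrators_per_site // 2
    for site in sites:
        for p in range(config.pairs_per_site):
            mother = f"{site}-P{p:02d}-F"
            father = f"{site}-P{p:02d}-M"
            brood = f"{site}-B{p:02d}"
            for b in (mother, father):
                rows.append(
                    {
                        "bird_id": b,
                        "age_class": "adult",
                        "mother_id": "",
                        "father_id": "",
                        "brood_id": "",
                        "fledge_date": "",
                    }
                )
                site_of[b] = site
            clutch = max(1, rng.poisson(config.clutch_mean))
            fledge = float(rng.uniform(0.0, config.fledge_spread_days)) * DAY_S
            for c in range(clutch):
                j = f"{site}-P{p:02d}-J{c}"
                rows.append(
                    {
                        "bird_id": j,
                        "age_class": "juvenile",
                        "mother_id": mother,
                        "father_id": father,
                        "brood_id": brood,
                        "fledge_date": fledge,
                    }
                )
                site_of[j] = site
            if p < demo_pairs:
                if p % 2 == 0:
                    side = "right" if (p // 2) % 2 == 0 else "left"
                    demonstrators[mother] = side
                    demonstrators[father] = side
                else:
                    demonstrators[mother] = "right"
                    demonstrators[father] = "left"
    registry = BirdRegistry(pd.DataFrame(rows))
    return Population(registry, site_of, sites, demonstrators)


# ---------------------------------------------------------------------------
# feeder associations
# ---------------------------------------------------------------------------

def feeder_days(config: ScenarioConfig) -> list[int]:
    return [
        d
        for d in range(int(config.study_days))
        if d % 7 in FEEDER_WEEKDAYS
    ]


def puzzle_days(config: ScenarioConfig) -> list[int]:
    lo = -int(config.warmup_days)
    return [d for d in range(lo, int(config.study_days)) if d % 7 in PUZZLE_WEEKDAYS]


def simulate_associations(pop: Population, config: ScenarioConfig) -> pd.DataFrame:
    """Feeder detection stream with family-biased gathering membership.

    Per site and feeder day, a few gatherings form.  Each gathering is a
    small flock: ``families_per_gathering`` whole families drawn without
    replacement with heterogeneous (gamma-weighted) propensities — some
    families are feeder regulars, others rare visitors, as in real tit
    flocks — whose siblings attend with high probability and parents
    somewhat lower, plus rare unrelated drop-ins.  The result is sibling >
    vertical > oblique/peer association strength, with sparse,
    strongly contrasting cross-family associations (the contrast is what
    lets a diffusion analysis separate oblique transmission from baseline
    learning).  Timestamps are normal around the gathering centre.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rows = []
    for site in pop.sites:
        broods: dict[str, list[str]] = {}
        adults_of: dict[str, list[str]] = {}
        for b in pop.juveniles_at(site):
            br = pop.registry.brood(b)
            broods.setdefault(br, []).append(b)
            adults_of.setdefault(br, sorted(pop.registry.parents(b)))
        fam_ids = sorted(broods)
        weights = rng.gamma(1.0, 1.0, len(fam_ids))
        p_fam = weights / weights.sum()
        all_birds = pop.birds_at(site)
        k_fam = min(config.families_per_gathering, len(fam_ids))
        for day in feeder_days(config):
            centres = day * DAY_S + np.sort(
                rng.uniform(8 * 3600, 17 * 3600, config.gatherings_per_day)
            )
            for centre in centres:
                members = set()
                if k_fam > 0:
                    chosen = rng.choice(len(fam_ids), size=k_fam, replace=False, p=p_fam)
                    for f in chosen:
                        br = fam_ids[f]
                        for j in broods[br]:
                            if rng.random() < config.sibling_attend:
                                members.add(j)
                        for a in adults_of[br]:
                            if rng.random() < config.parent_attend:
                                members.add(a)
                for b in all_birds:
                    if b not in members and rng.random() < config.other_attend:
                        members.add(b)
                for b in sorted(members):
                    for _ in range(rng.poisson(config.visits_per_attendance) + 1):
                        rows.append(
                            {
                                "bird_id": b,
                                "timestamp": float(
                                    centre + rng.normal(0, config.gathering_sd_s)
                                ),
                                "site_id": site,
                                "source": "network_feeder",
                            }
                        )
    return (
        pd.DataFrame(rows, columns=["bird_id", "timestamp", "site_id", "source"])
        .sort_values("timestamp", kind="mergesort")
        .reset_index(drop=True)
    )


def block_networks(pop: Population, config: ScenarioConfig) -> dict[str, NetworkLayerSet]:
    """Ground-truth association networks with per-dyad heterogeneity.

    Each admissible dyad's weight is the layer mean from
    ``assoc_strength`` times a seeded Gamma(2, 1/2) multiplier (mean 1),
    clipped to [0, 1].  The spread matters: a perfectly uniform layer is
    indistinguishable from the asocial baseline, whereas real association
    matrices are strongly heterogeneous.
    """
    from tadanet.networks import dyad_layer

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    out = {}
    for site in pop.sites:
        ids = sorted(pop.birds_at(site))
        n = len(ids)
        mats = {l: np.zeros((n, n)) for l in LAYERS}
        for i in range(n):
            for j in range(i + 1, n):
                layer = dyad_layer(pop.registry, ids[i], ids[j])
                if layer is None:
                    continue
                w = min(config.assoc_strength[layer] * rng.gamma(2.0, 0.5), 1.0)
                mats[layer][i, j] = mats[layer][j, i] = w
        out[site] = NetworkLayerSet(ids, mats, (0.0, config.study_days * DAY_S))
    return out


# ---------------------------------------------------------------------------
# diffusion simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDiffusion:
    """Acquisition schedule with full ground truth."""

    config: ScenarioConfig
    population: Population
    networks: dict[str, NetworkLayerSet]
    events: pd.DataFrame  # site_id, learner_id, time_days, pathway
    w_rates: dict[str, float]  # solves per experimental day, every knowledgeable bird
    ilv: dict[str, np.ndarray]  # per-bird ILV vector (centred)

    def learners(self) -> list[str]:
        return list(self.events["learner_id"])


def _draw_ilvs(pop: Population, config: ScenarioConfig, rng) -> dict[str, np.ndarray]:
    juv = pop.registry.juveniles
    sd = np.asarray(config.ilv_sd, dtype=float)
    x = rng.normal(0.0, 1.0, size=(len(juv), sd.size)) * sd
    x -= x.mean(axis=0)
    return {b: x[i] for i, b in enumerate(juv)}


def _social_sums(
    net: NetworkLayerSet, ids: list[str], knowledgeable: dict[str, float]
) -> np.ndarray:
    """S[i, k] = sum_j a_ij^(k) w_j over currently knowledgeable j.

    Individuals absent from the network (e.g. filtered out as transients)
    contribute and receive nothing.
    """
    s = np.zeros((len(ids), len(LAYERS)))
    idx = {b: i for i, b in enumerate(net.node_ids)}
    known = np.array([b in idx for b in ids])
    rows = np.array([idx[b] for b, k in zip(ids, known) if k], dtype=int)
    for j, w in knowledgeable.items():
        if j not in idx:
            continue
        jj = idx[j]
        for k, layer in enumerate(LAYERS):
            s[known, k] += net.matrices[layer][rows, jj] * w
    return s


def _rate_components(
    s_sums: np.ndarray, x: np.ndarray, config: ScenarioConfig
) -> np.ndarray:
    """Per-individual hazard components: column 0 asocial, then one per layer."""
    s_vec = np.array([config.s_true[l] for l in LAYERS])
    ba = np.asarray(config.beta_asocial)
    bs = np.asarray(config.beta_social)
    comps = np.empty((s_sums.shape[0], 1 + len(LAYERS)))
    comps[:, 0] = np.exp(x @ ba)
    comps[:, 1:] = np.exp(x @ bs)[:, None] * s_sums * s_vec[None, :]
    return comps


def simulate_diffusion(
    pop: Population,
    networks: dict[str, NetworkLayerSet],
    config: ScenarioConfig,
    seed: int | None = None,
) -> SimulatedDiffusion:
    """Exact event-driven simulation of the acquisition diffusion.

    Within each interval the individual hazards are constant multiples of
    the baseline, so the next acquisition is drawn by competing
    exponentials in integrated-baseline time (time rescaling makes this
    exact for the Weibull family too).  Each event's pathway label is drawn
    proportional to the learner's hazard components.  Demonstrators are
    knowledgeable from the start and never appear as learners.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 2])
    )
    ilv = _draw_ilvs(pop, config, rng)
    theta, kappa = config.theta_days, config.kappa
    rows = []
    w_rates: dict[str, float] = {}

    def draw_rate() -> float:
        return float(
            np.exp(rng.normal(np.log(config.solve_rate_mean), config.solve_rate_sigma))
        )

    for b in pop.demonstrators:
        w_rates[b] = draw_rate()
    for site in pop.sites:
        net = networks[site]
        juv = sorted(pop.juveniles_at(site))
        naive = list(juv)
        knowledgeable = {
            b: w_rates[b] for b in pop.demonstrators if pop.site_of[b] == site
        }
        t = 0.0
        while naive and t < config.study_days:
            s_sums = _social_sums(net, naive, knowledgeable)
            x = np.stack([ilv[b] for b in naive])
            comps = _rate_components(s_sums, x, config)
            r = comps.sum(axis=1)
            # competing exponentials in integrated-baseline time
            u_wait = rng.exponential(1.0, size=len(naive)) / np.maximum(r, 1e-300)
            winner = int(np.argmin(u_wait))
            u_now = (t / theta) ** kappa
            u_next = u_now + u_wait[winner]
            t_next = theta * u_next ** (1.0 / kappa)
            if t_next >= config.study_days:
                break
            t = t_next
            learner = naive.pop(winner)
            p = comps[winner] / comps[winner].sum()
            path = rng.choice(["asocial", *LAYERS], p=p)
            rows.append(
                {
                    "site_id": site,
                    "learner_id": learner,
                    "time_days": t,
                    "pathway": path,
                }
            )
            w_rates[learner] = draw_rate()
            knowledgeable[learner] = w_rates[learner]
    events = pd.DataFrame(
        rows, columns=["site_id", "learner_id", "time_days", "pathway"]
    ).sort_values("time_days", kind="mergesort").reset_index(drop=True)
    return SimulatedDiffusion(config, pop, networks, events, w_rates, ilv)


def to_diffusion_data(sim: SimulatedDiffusion, min_site_events: int = 1) -> DiffusionData:
    """Exact :class:`DiffusionData` replayed from the simulator's own state.

    Because the simulator holds networks, weights and ILVs piecewise
    constant between events, the arrays built here reproduce its hazards
    exactly — no re-estimation from streams is involved.
    """
    config = sim.config
    pop = sim.population
    sites_out = []
    broods = {}
    for site in pop.sites:
        sev = sim.events[sim.events["site_id"] == site].reset_index(drop=True)
        if len(sev) < min_site_events:
            continue
        ids = sorted(pop.juveniles_at(site))
        index = {b: i for i, b in enumerate(ids)}
        e, n = len(sev), len(ids)
        social = np.zeros((e + 1, n, len(LAYERS)))
        ilv = np.stack([sim.ilv[b] for b in ids])
        net = sim.networks[site]
        knowledgeable = {
            b: sim.w_rates[b] for b in pop.demonstrators if pop.site_of[b] == site
        }
        for m in range(e + 1):
            social[m] = _social_sums(net, ids, knowledgeable)
            if m < e:
                learner = sev.loc[m, "learner_id"]
                knowledgeable[learner] = sim.w_rates[learner]
        sites_out.append(
            SiteDiffusion(
                site_id=site,
                ids=ids,
                event_times=sev["time_days"].to_numpy(dtype=float),
                event_learner=np.array([index[b] for b in sev["learner_id"]]),
                end_time=config.study_days,
                social=social,
                ilv=np.repeat(ilv[None, :, :], e + 1, axis=0),
                present=np.ones((e + 1, n), dtype=bool),
            )
        )
    for b in pop.registry.juveniles:
        br = pop.registry.brood(b)
        if br is not None:
            broods[b] = br
    return DiffusionData(sites=sites_out, broods=broods)


# ---------------------------------------------------------------------------
# puzzle stream with side choices and scrounges
# ---------------------------------------------------------------------------

def _side_logit(
    p_social: float | None, p_personal: float | None, cum: int, config: ScenarioConfig
) -> float:
    """Log-odds of a right solve under the conformity/personal rule.

    Proportions are centred at 0.5 so that absent information is neutral;
    the experience interactions act per 100 cumulative solves.
    """
    z = 0.0
    c = cum / 100.0
    if p_social is not None:
        z += (np.log(config.or_social) + c * np.log(config.or_social_per100)) * (
            p_social - 0.5
        )
    if p_personal is not None:
        z += (np.log(config.or_personal) + c * np.log(config.or_personal_per100)) * (
            p_personal - 0.5
        )
    return z


def simulate_puzzle_stream(
    sim: SimulatedDiffusion, seed: int | None = None
) -> pd.DataFrame:
    """Solve/visit stream realising the acquisition schedule.

    Each learner's first two solves fall minutes before its scheduled
    acquisition and the third exactly at it, so knowledge-state derivation
    recovers the schedule; afterwards birds solve at their individual rate
    on puzzle-deployment days.  Demonstrators solve only their restricted
    side; juveniles choose sides by the configured conformity/personal
    rule.  After each solve a scrounge visit by another local bird is
    inserted within the 2-s door-open window with configured probability.
    """
    config = sim.config
    pop = sim.population
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 3])
    )
    acq_abs = {
        r.learner_id: r.time_days * DAY_S for r in sim.events.itertuples(index=False)
    }
    rows = []
    for site in pop.sites:
        site_birds = sorted(pop.birds_at(site))
        plan: list[tuple[float, str]] = []  # (timestamp, bird)
        for b, w in sim.w_rates.items():
            if pop.site_of[b] != site:
                continue
            is_demo = b in pop.demonstrators
            if is_demo:
                start_day = -config.warmup_days
            else:
                if b not in acq_abs:
                    continue
                t0 = acq_abs[b]
                plan.extend([(t0 - 180.0, b), (t0 - 90.0, b), (t0, b)])
                start_day = t0 / DAY_S
            for day in puzzle_days(config):
                if day + 1 <= start_day:
                    continue
                lo = max(day * DAY_S + 6 * 3600, acq_abs.get(b, -np.inf))
                hi = day * DAY_S + 18 * 3600
                if hi <= lo:
                    continue
                k = rng.poisson(w * (hi - lo) / (12 * 3600))
                if is_demo and day < 0:
                    k = max(k, 2)  # guarantees demonstrator status by start
                for t in np.sort(rng.uniform(lo, hi, k)):
                    plan.append((float(t), b))
        plan.sort()
        # walk chronologically, assigning sides with window bookkeeping
        hist_t: list[float] = []
        hist_bird: list[str] = []
        hist_right: list[int] = []
        cum: dict[str, int] = {}
        for t, b in plan:
            if b in pop.demonstrators:
                side = pop.demonstrators[b]
            else:
                lo_s = t - config.social_window_s
                lo_p = t - config.personal_window_s
                oth_r = oth_n = own_r = own_n = 0
                for tt, bb, rr in zip(
                    reversed(hist_t), reversed(hist_bird), reversed(hist_right)
                ):
                    if tt < t - max(config.social_window_s, config.personal_window_s):
                        break
                    if bb == b:
                        if tt >= lo_p:
                            own_n += 1
                            own_r += rr
                    elif tt >= lo_s and tt < t:
                        oth_n += 1
                        oth_r += rr
                p_soc = oth_r / oth_n if oth_n else None
                p_per = own_r / own_n if own_n else None
                z = _side_logit(p_soc, p_per, cum.get(b, 0), config)
                side = "right" if rng.random() < 1.0 / (1.0 + np.exp(-z)) else "left"
            rows.append(
                {
                    "bird_id": b,
                    "timestamp": t,
                    "site_id": site,
                    "action": f"solve_{side}",
                }
            )
            hist_t.append(t)
            hist_bird.append(b)
            hist_right.append(1 if side == "right" else 0)
            cum[b] = cum.get(b, 0) + 1
            if rng.random() < config.scrounge_prob:
                others = [o for o in site_birds if o != b]
                scrounger = others[rng.integers(len(others))]
                rows.append(
                    {
                        "bird_id": scrounger,
                        "timestamp": t + float(rng.uniform(0.5, 2.0)),
                        "site_id": site,
                        "action": "visit",
                    }
                )
    return (
        pd.DataFrame(rows, columns=["bird_id", "timestamp", "site_id", "action"])
        .sort_values("timestamp", kind="mergesort")
        .reset_index(drop=True)
    )


def association_networks(
    pop: Population, detections: pd.DataFrame, config: ScenarioConfig
) -> dict[str, NetworkLayerSet]:
    """Whole-study four-layer SRI networks from a simulated feeder stream.

    Used as the generating networks of the end-to-end scenario, so that
    the co-feeding record and the learning opportunities share one social
    structure — the same structure the pipeline later re-estimates in
    sliding windows.
    """
    from tadanet import networks as nw

    net = nw.dynamic_network(
        detections,
        pop.registry,
        event_time=config.study_days * DAY_S / 2.0,
        window_days=config.study_days,
        seed=config.seed,
    )
    return {site: net for site in pop.sites}


def generate_scenario(config: ScenarioConfig):
    """Population, feeder stream, diffusion and puzzle stream in one call.

    Returns ``(population, detections, sim, puzzle_events)``.  The
    diffusion runs on the whole-study association networks implied by the
    simulated feeder stream (family-structured by construction), so the
    generating social structure is the one the analysis can re-estimate.
    """
    pop = generate_population(config)
    detections = simulate_associations(pop, config)
    networks = association_networks(pop, detections, config)
    sim = simulate_diffusion(pop, networks, config)
    puzzle = simulate_puzzle_stream(sim)
    return pop, detections, sim, puzzle


def write_scenario_csvs(pop, detections, puzzle, outdir) -> dict[str, str]:
    """Write pedigree/detections/puzzle CSVs in the schemas the loaders read."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "pedigree": os.path.join(outdir, "pedigree.csv"),
        "detections": os.path.join(outdir, "detections.csv"),
        "puzzle": os.path.join(outdir, "puzzle_events.csv"),
    }
    pop.registry.table.to_csv(paths["pedigree"], index=False)
    detections.to_csv(paths["detections"], index=False)
    puzzle.to_csv(paths["puzzle"], index=False)
    return paths
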