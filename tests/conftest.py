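import numpy as np
import pandas as pd
import pytest

from tadanet.events import BirdRegistry

DAY = 86400.0


@pytest.fixture()
def toy_registry() -> BirdRegistry:
    """Two families plus an unrelated adult: 4 adults, 5 juveniles."""
    rows = [
        ("A-F", "adult", "", "", "", ""),
        ("A-M", "adult", "", "", "", ""),
        ("B-F", "adult", "", "", "", ""),
        ("B-M", "adult", "", "", "", ""),
        ("J1", "juvenile", "A-F", "A-M", "BA", 0.0),
        ("J2", "juvenile", "A-F", "A-M", "BA", 0.0),
        ("J3", "juvenile", "B-F", "B-M", "BB", DAY),
        ("J4", "juvenile", "B-F", "B-M", "BB", DAY),
        ("J5", "juvenile", "B-F", "B-M", "BB", DAY),
    ]
    return BirdRegistry(
        pd.DataFrame(
            rows,
            columns=[
                "bird_id",
                "age_class",
                "mother_id",
                "father_id",
                "brood_id",
                "fledge_date",
            ],
        )
    )


def puzzle_frame(rows):
    return pd.DataFrame(rows, columns=["bird_id", "timestamp", "site_id", "action"])


def detection_frame(rows):
    return pd.DataFrame(rows, columns=["bird_id", "timestamp", "site_id", "source"])


@pytest.fixture(scope="session")
def recovery_run():
    """One sibling-only diffusion with its exact diffusion data (shared)."""
    from tadanet import synthetic as syn

    cfg = syn.recovery_scenario(seed=7)
    pop = syn.generate_population(cfg)
    nets = syn.block_networks(pop, cfg)
    sim = syn.simulate_diffusion(pop, nets, cfg)
    data = syn.to_diffusion_data(sim, min_site_events=3)
    return cfg, pop, sim, data


@pytest.fixture(scope="session")
def random_site():
    """A small hand-sized random SiteDiffusion for likelihood checks."""
    from tadanet.nbda.data import DiffusionData, SiteDiffusion

    rng = np.random.default_rng(42)
    n, e = 10, 6
    times = np.sort(rng.uniform(1.0, 40.0, e))
    learners = rng.choice(n, e, replace=False)
    social = rng.uniform(0.0, 3.0, (e + 1, n, 4))
    ilv = rng.normal(0.0, 0.5, (e + 1, n, 2))
    present = rng.random((e + 1, n)) < 0.9
    present[np.arange(e), learners] = True
    site = SiteDiffusion(
        "s1", [f"b{i}" for i in range(n)], times, learners, 50.0, social, ilv, present
    )
    return DiffusionData([site])
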