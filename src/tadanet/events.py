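"""Event streams, pedigree registry, and knowledge-state derivation.

Three delimited-text inputs drive the pipeline:

* detections  — ``bird_id,timestamp,site_id,source`` with
  ``source in {network_feeder, puzzle}``; one row per antenna registration.
* puzzle events — ``bird_id,timestamp,site_id,action`` with
  ``action in {solve_left, solve_right, visit}``.
* pedigree — ``bird_id,age_class,mother_id,father_id,brood_id,fledge_date``.

Timestamps are seconds (floats).  ``fledge_date`` may be given either as
seconds or as an ISO ``YYYY-MM-DD`` date (parsed to midnight UTC).

From the puzzle stream the module derives scrounge events (a visit by a
different bird within 2 s of a solve at the same site, while the sliding
door is still open) and per-bird knowledge states: a bird is
*knowledgeable* once it has produced at least 10 solves over the study, and
its *acquisition time* is the time of its 3rd solve — the higher
knowledgeable threshold guards against RFID misreads when several birds
perch simultaneously, while the earlier 3rd solve marks when the behaviour
was actually acquired.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCROUNGE_WINDOW_S = 2.0
KNOWLEDGEABLE_SOLVES = 10
ACQUISITION_SOLVE = 3

DETECTION_COLUMNS = ["bird_id", "timestamp", "site_id", "source"]
PUZZLE_COLUMNS = ["bird_id", "timestamp", "site_id", "action"]
PEDIGREE_COLUMNS = [
    "bird_id",
    "age_class",
    "mother_id",
    "father_id",
    "brood_id",
    "fledge_date",
]

SOLVE_ACTIONS = ("solve_left", "solve_right")
PUZZLE_ACTIONS = ("solve_left", "solve_right", "visit")


class SchemaError(ValueError):
    """A required column is missing or a table fails basic validation."""


class ReferentialError(ValueError):
    """A record references a bird or site not present in the registry."""


def _parse_date(value) -> float:
    """Parse a fledge date given as seconds or as an ISO date string."""
    if value is None or value == "" or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    try:
        return float(value)
    except (TypeError, ValueError):
        pass
    d = _dt.date.fromisoformat(str(value).strip())
    return _dt.datetime(d.year, d.month, d.day, tzinfo=_dt.timezone.utc).timestamp()


@dataclass
class BirdRegistry:
    """Pedigree table with id-indexed lookups.

    Invariants enforced at construction: every juvenile carries a brood id
    and a fledge date, referenced parents exist, and no bird is its own
    parent.
    """

    table: pd.DataFrame
    _by_id: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = set(PEDIGREE_COLUMNS) - set(t.columns)
        if missing:
            raise SchemaError(f"pedigree missing columns: {sorted(missing)}")
        if t["bird_id"].duplicated().any():
            dups = t.loc[t["bird_id"].duplicated(), "bird_id"].tolist()
            raise SchemaError(f"duplicate bird ids in pedigree: {dups}")
        t = t.copy()
        t["fledge_date"] = [_parse_date(v) for v in t["fledge_date"]]
        bad_cls = set(t["age_class"]) - {"adult", "juvenile"}
        if bad_cls:
            raise SchemaError(f"unknown age_class values: {sorted(bad_cls)}")
        ids = set(t["bird_id"])
        for _, row in t.iterrows():
            for p in ("mother_id", "father_id"):
                pid = row[p]
                if pd.isna(pid) or pid == "":
                    continue
                if pid == row["bird_id"]:
                    raise SchemaError(f"bird {pid} is its own parent")
                if pid not in ids:
                    raise ReferentialError(
                        f"{p}={pid!r} of {row['bird_id']!r} not in registry"
                    )
            if row["age_class"] == "juvenile":
                if pd.isna(row["brood_id"]) or row["brood_id"] == "":
                    raise SchemaError(f"juvenile {row['bird_id']} lacks brood_id")
                if np.isnan(row["fledge_date"]):
                    raise SchemaError(f"juvenile {row['bird_id']} lacks fledge_date")
        self.table = t.reset_index(drop=True)
        self._by_id = {r.bird_id: r for r in self.table.itertuples(index=False)}

    # -- lookups ---------------------------------------------------------
    @property
    def bird_ids(self) -> list[str]:
        return list(self.table["bird_id"])

    def __contains__(self, bird_id: str) -> bool:
        return bird_id in self._by_id

    def age_class(self, bird_id: str) -> str:
        return self._by_id[bird_id].age_class

    def is_juvenile(self, bird_id: str) -> bool:
        return self._by_id[bird_id].age_class == "juvenile"

    def is_adult(self, bird_id: str) -> bool:
        return self._by_id[bird_id].age_class == "adult"

    def parents(self, bird_id: str) -> set[str]:
        r = self._by_id[bird_id]
        out = set()
        for p in (r.mother_id, r.father_id):
            if not (pd.isna(p) or p == ""):
                out.add(p)
        return out

    def brood(self, bird_id: str) -> str | None:
        b = self._by_id[bird_id].brood_id
        return None if (pd.isna(b) or b == "") else b

    def fledge_date(self, bird_id: str) -> float:
        return self._by_id[bird_id].fledge_date

    @property
    def juveniles(self) -> list[str]:
        return [b for b in self.bird_ids if self.is_juvenile(b)]

    @property
    def adults(self) -> list[str]:
        return [b for b in self.bird_ids if self.is_adult(b)]

    def siblings(self, bird_id: str) -> set[str]:
        """Same-brood juveniles other than the bird itself."""
        b = self.brood(bird_id)
        if b is None:
            return set()
        t = self.table
        same = t.loc[(t["brood_id"] == b) & (t["bird_id"] != bird_id), "bird_id"]
        return set(same)


def _load_stream(
    path, required: list[str], categorical: dict[str, tuple] | None = None
) -> pd.DataFrame:
    """Read a delimited event table, dropping and reporting unparseable rows.

    Rejected rows (with 1-based data line numbers and a reason) are stored in
    ``df.attrs["rejections"]``.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(required) - set(raw.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    rejections: list[tuple[int, str]] = []
    ts = pd.to_numeric(raw["timestamp"], errors="coerce")
    keep = np.isfinite(ts.to_numpy(dtype=float, na_value=np.nan))
    for i in np.flatnonzero(~keep):
        rejections.append((int(i) + 1, f"bad timestamp {raw['timestamp'].iloc[i]!r}"))
    if categorical:
        for col, allowed in categorical.items():
            ok = raw[col].isin(allowed).to_numpy()
            for i in np.flatnonzero(keep & ~ok):
                rejections.append((int(i) + 1, f"bad {col} {raw[col].iloc[i]!r}"))
            keep &= ok
    df = raw.loc[keep, required].copy()
    df["timestamp"] = ts[keep].astype(float)
    df = df.sort_values("timestamp", kind="mergesort").reset_index(drop=True)
    df.attrs["rejections"] = rejections
    for line, reason in rejections:
        logger.warning("%s line %d rejected: %s", path, line, reason)
    return df


def load_event_tables(
    paths: dict[str, str],
) -> tuple[BirdRegistry, pd.DataFrame, pd.DataFrame]:
    """Load ``{"pedigree": ..., "detections": ..., "puzzle": ...}`` CSVs.

    Returns the validated registry plus time-sorted detection and puzzle
    streams; each stream reports rejected rows in ``.attrs["rejections"]``.
    Exact duplicate puzzle rows (RFID double-reads) are dropped.
    """
    registry = BirdRegistry(pd.read_csv(paths["pedigree"], dtype=str, keep_default_na=False))
    detections = _load_stream(
        paths["detections"],
        DETECTION_COLUMNS,
        {"source": ("network_feeder", "puzzle")},
    )
    puzzle = _load_stream(paths["puzzle"], PUZZLE_COLUMNS, {"action": PUZZLE_ACTIONS})
    rej = puzzle.attrs["rejections"]
    puzzle = puzzle.drop_duplicates(
        subset=["bird_id", "timestamp", "site_id", "action"], keep="first"
    ).reset_index(drop=True)
    puzzle.attrs["rejections"] = rej
    return registry, detections, puzzle


def derive_scrounges(
    puzzle_events: pd.DataFrame, window_s: float = SCROUNGE_WINDOW_S
) -> pd.DataFrame:
    """Scrounges: visits within 2 s of another bird's solve at the same site.

    A visit by bird B at time t scrounges if some solve by a different bird
    at the same site happened in ``(t - 2 s, t)``; the scrounge is attached
    to the most recent such solve.  Returns columns ``bird_id, timestamp,
    site_id, solver_id, solve_timestamp``.
    """
    ev = puzzle_events.sort_values("timestamp", kind="mergesort")
    out = []
    for site, grp in ev.groupby("site_id", sort=False):
        solves = grp[grp["action"].isin(SOLVE_ACTIONS)]
        visits = grp[grp["action"] == "visit"]
        if solves.empty or visits.empty:
            continue
        st = solves["timestamp"].to_numpy()
        sb = solves["bird_id"].to_numpy()
        for _, v in visits.iterrows():
            # scan back through solves in (t-2, t), most recent first
            hi = np.searchsorted(st, v["timestamp"], side="left")
            j = hi - 1
            while j >= 0 and v["timestamp"] - st[j] <= window_s:
                if st[j] < v["timestamp"] and sb[j] != v["bird_id"]:
                    out.append(
                        {
                            "bird_id": v["bird_id"],
                            "timestamp": v["timestamp"],
                            "site_id": site,
                            "solver_id": sb[j],
                            "solve_timestamp": st[j],
                        }
                    )
                    break
                j -= 1
    cols = ["bird_id", "timestamp", "site_id", "solver_id", "solve_timestamp"]
    if not out:
        return pd.DataFrame(columns=cols)
    return (
        pd.DataFrame(out, columns=cols)
        .sort_values("timestamp", kind="mergesort")
        .reset_index(drop=True)
    )


def solve_times(puzzle_events: pd.DataFrame, bird_id: str) -> np.ndarray:
    """Sorted, de-duplicated solve timestamps of one bird."""
    m = (puzzle_events["bird_id"] == bird_id) & puzzle_events["action"].isin(
        SOLVE_ACTIONS
    )
    return np.unique(puzzle_events.loc[m, "timestamp"].to_numpy())


def knowledge_states(
    puzzle_events: pd.DataFrame,
    registry: BirdRegistry,
    diffusion_start: float,
    knowledgeable_solves: int = KNOWLEDGEABLE_SOLVES,
    acquisition_solve: int = ACQUISITION_SOLVE,
) -> pd.DataFrame:
    """Per-bird knowledge-state table.

    knowledgeable ⇔ total solves ≥ 10; acquisition_time = time of the 3rd
    solve (NaN for non-knowledgeable birds).  Adults acquiring before
    ``diffusion_start`` are demonstrators; adults acquiring during the
    diffusion are "filtered" (excluded as learners but still able to
    transmit).  Juveniles are never demonstrators or filtered.
    """
    solves = puzzle_events[puzzle_events["action"].isin(SOLVE_ACTIONS)]
    unknown = set(solves["bird_id"]) - set(registry.bird_ids)
    if unknown:
        raise ReferentialError(f"solving birds absent from registry: {sorted(unknown)}")
    rows = []
    for bird in registry.bird_ids:
        ts = solve_times(puzzle_events, bird)
        n = len(ts)
        knowledgeable = n >= knowledgeable_solves
        acq = float(ts[acquisition_solve - 1]) if knowledgeable else np.nan
        adult = registry.is_adult(bird)
        demonstrator = bool(adult and knowledgeable and acq < diffusion_start)
        filtered = bool(adult and knowledgeable and acq >= diffusion_start)
        rows.append(
            {
                "bird_id": bird,
                "n_solves": n,
                "knowledgeable": knowledgeable,
                "acquisition_time": acq,
                "demonstrator": demonstrator,
                "filtered": filtered,
            }
        )
    return pd.DataFrame(rows)
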