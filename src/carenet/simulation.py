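"""Agent-based patient-displacement engine and the two stress scenarios.

Physicians of one specialty hold patients up to an estimated maximum capacity.
When a physician is removed, their patients start *searching*: in every
displacement round each searching patient, in uniformly random order, picks a
candidate physician — with probability ``alpha`` uniformly at random from all
still-available physicians, otherwise proportional to the patient-sharing
weight between their most recent physician and its available neighbours.  A
candidate farther than ``d`` km from the patient's home municipality triggers
a redraw (after ten failed redraws the last candidate is kept regardless of
distance).  A candidate with free capacity accepts the patient; otherwise the
patient's rejection counter increases, and after ``s`` rejections the patient
is *lost* and leaves the simulation.  Successful placement resets the
counter, so ``s`` bounds one search episode, not a patient's lifetime moves.

Two stress scenarios are provided:

* scenario (i), :func:`run_iterative_removal` — remove one uniformly random
  available physician per step, let displacement run to quiescence, repeat
  until a single physician remains (slow-onset shocks such as retirement
  waves);
* scenario (ii), :func:`run_shock` — remove a fixed fraction of physicians
  at once, then run exactly ``s`` displacement rounds (fast-onset shocks
  such as mass quarantine).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .network import haversine_km

PLACED, SEARCHING, LOST = 0, 1, 2


@dataclasses.dataclass
class SimulationParams:
    """Model parameters with the baseline setting as defaults.

    s : maximum rejections before a patient is lost (10)
    c : capacity percentile used upstream by the capacity estimate (10)
    d : maximum distance patients travel to a new physician, km (100)
    p : minimum shared patients for a network edge, used upstream (2)
    alpha : probability of picking a physician at random instead of via the
        sharing network (0; at 1 the network plays no role)
    max_distance_retries : redraws allowed for the distance rule (10)
    seed : base seed; replicate ``k`` of an ensemble uses ``seed + k``
    ensemble_size : default number of replicates
    """

    s: int = 10
    c: float = 10.0
    d: float = 100.0
    p: int = 2
    alpha: float = 0.0
    max_distance_retries: int = 10
    seed: int = 0
    ensemble_size: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigurationError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.s < 1:
            raise ConfigurationError(f"s must be >= 1, got {self.s}")
        if self.d <= 0:
            raise ConfigurationError(f"d must be positive, got {self.d}")
        if self.p < 1:
            raise ConfigurationError(f"p must be >= 1, got {self.p}")
        if self.ensemble_size < 1:
            raise ConfigurationError("ensemble_size must be >= 1")


@dataclasses.dataclass
class System:
    """Compiled, immutable description of one specialty's care system."""

    node_ids: np.ndarray          # physician IDs, defines the index
    C: np.ndarray                 # maximum capacities
    N: np.ndarray                 # initial patient counts
    muni_of_phys: np.ndarray      # municipality index per physician
    muni_ids: np.ndarray          # municipality IDs, defines muni index
    muni_dist: np.ndarray         # pairwise municipality distances, km
    state_labels: list[str]       # federal-state labels (leading ID digit)
    state_of_phys: np.ndarray     # state index per physician
    neighbors: list[np.ndarray]   # adjacency lists (physician indices)
    nbr_weights: list[np.ndarray]  # matching shared-patient weights

    @property
    def n_physicians(self) -> int:
        return self.node_ids.size

    @property
    def total_patients(self) -> int:
        return int(self.N.sum())


def compile_system(
    net: nx.Graph,
    profiles: pd.DataFrame,
    municipalities: pd.DataFrame,
) -> System:
    """Bind a (layered, thresholded) network to capacities and geography.

    ``profiles`` must carry ``physician_id``, ``N`` and ``C`` for every node
    of ``net``; ``municipalities`` supplies coordinates.  The federal state
    of a physician is the leading digit of their municipality ID.
    """
    node_ids = np.array(sorted(net.nodes, key=str))
    prof = profiles.set_index("physician_id")
    missing = [n for n in node_ids if n not in prof.index]
    if missing:
        raise ValidationError(f"profiles missing for physicians: {missing[:5]}")
    C = prof.loc[node_ids, "C"].to_numpy(dtype=np.int64)
    N = prof.loc[node_ids, "N"].to_numpy(dtype=np.int64)

    muni_ids = municipalities["municipality_id"].astype(str).to_numpy()
    muni_pos = {m: k for k, m in enumerate(muni_ids)}
    lat = municipalities["lat"].to_numpy()
    lon = municipalities["lon"].to_numpy()
    muni_dist = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])

    node_muni = []
    for n in node_ids:
        m = str(net.nodes[n]["municipality"])
        if m not in muni_pos:
            raise ValidationError(f"municipality {m!r} of {n!r} not in gazetteer")
        node_muni.append(muni_pos[m])
    muni_of_phys = np.array(node_muni, dtype=np.int64)

    state_labels = sorted({m[0] for m in muni_ids})
    state_pos = {s: k for k, s in enumerate(state_labels)}
    state_of_phys = np.array(
        [state_pos[muni_ids[m][0]] for m in muni_of_phys], dtype=np.int64)

    index = {n: k for k, n in enumerate(node_ids)}
    neighbors, nbr_weights = [], []
    for n in node_ids:
        nbrs = sorted(net.adj[n], key=str) if n in net.adj else []
        neighbors.append(np.array([index[u] for u in nbrs], dtype=np.int64))
        nbr_weights.append(np.array(
            [float(net.adj[n][u].get("weight", 1)) for u in nbrs]))
    return System(node_ids=node_ids, C=C, N=N, muni_of_phys=muni_of_phys,
                  muni_ids=muni_ids, muni_dist=muni_dist,
                  state_labels=state_labels, state_of_phys=state_of_phys,
                  neighbors=neighbors, nbr_weights=nbr_weights)


class SystemState:
    """Mutable state of one simulation run: physicians and patient agents."""

    def __init__(self, system: System):
        if system.n_physicians == 0:
            raise ValidationError("cannot initialise an empty network")
        if np.any(system.N > system.C):
            bad = system.node_ids[system.N > system.C]
            raise ValidationError(
                f"initial load exceeds capacity for {list(bad[:5])}")
        self.system = system
        n = system.n_physicians
        self.available = np.ones(n, dtype=bool)
        self.count = system.N.copy()
        m = system.total_patients
        self.pat_phys = np.repeat(np.arange(n), system.N)
        self.pat_home_muni = system.muni_of_phys[self.pat_phys]
        self.pat_home_state = system.state_of_phys[self.pat_phys]
        self.pat_status = np.full(m, PLACED, dtype=np.int8)
        self.pat_rejections = np.zeros(m, dtype=np.int64)
        self.pat_distance = np.zeros(m, dtype=float)
        self.n_removed = 0
        # caches valid within one removal epoch: the weighted draw depends
        # on availability only, which changes solely at removals
        self._avail_list = np.arange(n)
        self._wcache: dict[int, tuple[np.ndarray, float]] = {}

    def _masked_weights(self, recent: int) -> tuple[np.ndarray, float]:
        cached = self._wcache.get(recent)
        if cached is None:
            nb = self.system.neighbors[recent]
            w = self.system.nbr_weights[recent] * self.available[nb]
            cw = np.cumsum(w)
            cached = (cw, float(cw[-1]) if cw.size else 0.0)
            self._wcache[recent] = cached
        return cached

    # -- bookkeeping ------------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.system.state_labels)

    def n_searching(self) -> int:
        return int(np.count_nonzero(self.pat_status == SEARCHING))

    def n_located(self) -> int:
        return int(np.count_nonzero(self.pat_status == PLACED))

    def n_lost(self) -> int:
        return int(np.count_nonzero(self.pat_status == LOST))

    def free_capacity_by_state(self) -> np.ndarray:
        free = np.where(self.available, self.system.C - self.count, 0)
        return np.bincount(self.system.state_of_phys, weights=free,
                           minlength=self.n_states).astype(np.int64)

    def _patients_by_state(self, status: int) -> np.ndarray:
        mask = self.pat_status == status
        return np.bincount(self.pat_home_state[mask],
                           minlength=self.n_states).astype(np.int64)

    def located_by_state(self) -> np.ndarray:
        return self._patients_by_state(PLACED)

    def lost_by_state(self) -> np.ndarray:
        return self._patients_by_state(LOST)


def initialize(system: System) -> SystemState:
    """Create the initial state: every patient placed, none searching/lost."""
    return SystemState(system)


def pick_new_physician(
    state: SystemState,
    patient: int,
    params: SimulationParams,
    rng: np.random.Generator,
) -> int:
    """Draw a candidate physician for one searching patient.

    Returns the physician index, or -1 when no candidate exists (counted as
    a rejection by the caller).  The distance rule redraws candidates whose
    municipality lies farther than ``d`` km from the patient's *home*
    municipality; after ``max_distance_retries`` failed draws the last
    candidate is kept regardless of distance.
    """
    sys_ = state.system
    home = state.pat_home_muni[patient]
    recent = state.pat_phys[patient]
    last = -1
    for _ in range(params.max_distance_retries):
        if params.alpha > 0.0 and rng.random() < params.alpha:
            avail = state._avail_list
            if avail.size == 0:
                return -1
            cand = int(avail[rng.integers(avail.size)])
        else:
            cw, total = state._masked_weights(recent)
            if total == 0.0:
                if last >= 0:
                    continue
                return -1
            cand = int(sys_.neighbors[recent][
                np.searchsorted(cw, rng.random() * total, side="right")])
        last = cand
        if sys_.muni_dist[home, sys_.muni_of_phys[cand]] <= params.d:
            return cand
    return last


def displacement_round(
    state: SystemState,
    params: SimulationParams,
    rng: np.random.Generator,
) -> SystemState:
    """One displacement round: every searching patient attempts one placement.

    Patients act in uniformly random order.  Acceptance requires the
    candidate to have free capacity; rejection (including the no-candidate
    case) increments the patient's counter, and at ``s`` rejections the
    patient is lost.  Mutates and returns ``state``.
    """
    searching = np.flatnonzero(state.pat_status == SEARCHING)
    if searching.size == 0:
        return state
    sys_ = state.system
    for pt in rng.permutation(searching):
        cand = pick_new_physician(state, int(pt), params, rng)
        if cand >= 0 and state.available[cand] and \
                state.count[cand] < sys_.C[cand]:
            state.count[cand] += 1
            state.pat_distance[pt] += sys_.muni_dist[
                sys_.muni_of_phys[state.pat_phys[pt]],
                sys_.muni_of_phys[cand]]
            state.pat_phys[pt] = cand
            state.pat_status[pt] = PLACED
            state.pat_rejections[pt] = 0
        else:
            state.pat_rejections[pt] += 1
            if state.pat_rejections[pt] >= params.s:
                state.pat_status[pt] = LOST
    return state


def run_to_quiescence(
    state: SystemState,
    params: SimulationParams,
    rng: np.random.Generator,
) -> SystemState:
    """Run displacement rounds until no patient is searching.

    Terminates after at most ``s`` rounds: each round every searching
    patient is either placed or one rejection closer to being lost.
    """
    while state.n_searching() > 0:
        displacement_round(state, params, rng)
    return state


def remove_physician(state: SystemState, physician: int) -> SystemState:
    """Flag a physician unavailable and set their patients searching."""
    if not state.available[physician]:
        raise ValidationError(
            f"physician {state.system.node_ids[physician]!r} already removed")
    state.available[physician] = False
    mine = (state.pat_phys == physician) & (state.pat_status == PLACED)
    state.pat_status[mine] = SEARCHING
    state.pat_rejections[mine] = 0
    state.count[physician] = 0
    state.n_removed += 1
    state._avail_list = np.flatnonzero(state.available)
    state._wcache.clear()
    return state


# ---------------------------------------------------------------------------
# scenario (i): iterative removal

@dataclasses.dataclass
class RemovalTrajectory:
    """Per-removal-step observables of one scenario-(i) run.

    Row 0 is the intact system; row ``k`` the state after ``k`` removals and
    the subsequent displacement quiescence.  State-level patient counts are
    attributed to the patient's home state, free capacity to the physician's
    state.
    """

    state_labels: list[str]
    frac_removed: np.ndarray        # (steps,)
    free_capacity: np.ndarray       # (steps, n_states)
    located: np.ndarray             # (steps, n_states)
    lost: np.ndarray                # (steps, n_states) cumulative
    removed_ids: list[str]
    n_physicians: int
    total_patients: int

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (step, frac_removed, state, observable, value)."""
        rows = []
        for name, arr in (("free_capacity", self.free_capacity),
                          ("located", self.located), ("lost", self.lost)):
            for step in range(arr.shape[0]):
                for j, st in enumerate(self.state_labels):
                    rows.append((step, self.frac_removed[step], st, name,
                                 int(arr[step, j])))
        return pd.DataFrame(
            rows, columns=["step", "frac_removed", "state", "observable",
                           "value"])


def run_iterative_removal(
    system: System,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
    remove_all: bool = False,
) -> RemovalTrajectory:
    """Scenario (i): remove one random physician per step, country-wide.

    After each removal, displacement runs to quiescence before the next
    removal.  Stops when a single physician remains, or after complete
    removal when ``remove_all`` is set (at which point every patient is
    lost).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    state = initialize(system)
    n = system.n_physicians
    n_steps = n if remove_all else n - 1

    frac = np.zeros(n_steps + 1)
    fc = np.zeros((n_steps + 1, state.n_states), dtype=np.int64)
    loc = np.zeros_like(fc)
    lost = np.zeros_like(fc)
    removed: list[str] = []
    fc[0], loc[0], lost[0] = (state.free_capacity_by_state(),
                              state.located_by_state(), state.lost_by_state())
    for step in range(1, n_steps + 1):
        avail = np.flatnonzero(state.available)
        victim = int(avail[rng.integers(avail.size)])
        remove_physician(state, victim)
        run_to_quiescence(state, params, rng)
        removed.append(str(system.node_ids[victim]))
        frac[step] = step / n
        fc[step], loc[step], lost[step] = (
            state.free_capacity_by_state(), state.located_by_state(),
            state.lost_by_state())
    return RemovalTrajectory(
        state_labels=list(system.state_labels), frac_removed=frac,
        free_capacity=fc, located=loc, lost=lost, removed_ids=removed,
        n_physicians=n, total_patients=system.total_patients)


def run_removal_ensemble(
    system: System,
    params: SimulationParams,
    n_replicates: int | None = None,
    remove_all: bool = False,
) -> list[RemovalTrajectory]:
    """Run an ensemble of scenario-(i) replicates, replicate ``k`` seeded
    with ``params.seed + k``."""
    n_rep = params.ensemble_size if n_replicates is None else n_replicates
    return [
        run_iterative_removal(system, params,
                              rng=np.random.default_rng(params.seed + k),
                              remove_all=remove_all)
        for k in range(n_rep)
    ]


# ---------------------------------------------------------------------------
# scenario (ii): single large shock

@dataclasses.dataclass
class ShockResult:
    """Observables of one scenario-(ii) run, indexed by displacement round.

    Index 0 is immediately after the shock (before any displacement); the
    main observable is ``located`` — patients who currently have an active
    physician.  Patients still searching after round ``s`` are lost.
    """

    located: np.ndarray
    searching: np.ndarray
    lost: np.ndarray
    n_removed: int
    n_physicians: int
    total_patients: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "round": np.arange(self.located.size),
            "located": self.located,
            "searching": self.searching,
            "lost": self.lost,
        })


def run_shock(
    system: System,
    params: SimulationParams,
    shock_fraction: float,
    rng: np.random.Generator | None = None,
) -> ShockResult:
    """Scenario (ii): remove ``floor(shock_fraction% * n)`` physicians at
    once, then run exactly ``s`` displacement rounds."""
    if not 0.0 <= shock_fraction < 100.0:
        raise ConfigurationError(
            f"shock_fraction is a percentage in [0, 100), got {shock_fraction}")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    state = initialize(system)
    n = system.n_physicians
    k = int(np.floor(shock_fraction / 100.0 * n))
    victims = rng.choice(n, size=k, replace=False)
    for v in victims:
        remove_physician(state, int(v))

    located = np.zeros(params.s + 1, dtype=np.int64)
    searching = np.zeros_like(located)
    lost = np.zeros_like(located)
    located[0], searching[0], lost[0] = (
        state.n_located(), state.n_searching(), state.n_lost())
    for t in range(1, params.s + 1):
        displacement_round(state, params, rng)
        located[t], searching[t], lost[t] = (
            state.n_located(), state.n_searching(), state.n_lost())
    still = state.pat_status == SEARCHING
    state.pat_status[still] = LOST
    lost[-1] = state.n_lost()
    searching[-1] = 0
    return ShockResult(located=located, searching=searching, lost=lost,
                       n_removed=k, n_physicians=n,
                       total_patients=system.total_patients)


def run_shock_ensemble(
    system: System,
    params: SimulationParams,
    shock_fraction: float,
    n_replicates: int | None = None,
) -> list[ShockResult]:
    n_rep = params.ensemble_size if n_replicates is None else n_replicates
    return [
        run_shock(system, params, shock_fraction,
                  rng=np.random.default_rng(params.seed + k))
        for k in range(n_rep)
    ]
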