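"""In-silico stimulation protocol and brain-state transition analytics.

A model fitted to an *initial* state receives additive periodic forcing at
one homotopic pair of regions, and the resulting simulated FC is compared
to the *target* state's empirical FC. The normalized score

    dGoF = (GoF(FC_sim_target, FC_emp_target) - GoF(FC_sim_forced, FC_emp_target))
           / (GoF(FC_sim_target, FC_emp_target) - GoF(FC_sim_initial, FC_emp_target))

is 1 when the forcing leaves the model at its initial state and 0 when the
forced model fits the target as well as the target's own fitted model; it
may go negative when the forcing fits the target even better. Sweeping all
homotopic pairs and a grid of amplitudes yields a dGoF grid whose global
minimum is the perturbational distance between the two states. Thresholding
the distance matrix gives a directed transition graph; a state's out-degree
is its instability index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.stats import rankdata

from .core import FCMatrix, Parcellation, StructuralConnectome
from .errors import ConfigurationError, DegenerateTransitionError
from .fitting import FitResult
from .io import enumerate_homotopic_pairs
from .observables import BandSpec, gof
from .simulate import (
    DEFAULT_BETA,
    DEFAULT_DT,
    DEFAULT_G,
    ForcingSpec,
    HopfModelSpec,
    _integrate,
    _series_batch_to_group_fcs,
)

#: Default forcing amplitude grid: 0 to 2 in steps of 0.1.
DEFAULT_AMPLITUDES = tuple(np.round(np.arange(0.0, 2.0 + 1e-9, 0.1), 10))

#: Default transition threshold on dGoF.
DGOF_THRESHOLD = 0.3


def delta_gof(gof_target_fit: float, gof_initial: float, gof_perturbed: float,
              tol: float = 1e-6) -> float:
    """Normalized perturbational score (see module docstring).

    Raises :class:`DegenerateTransitionError` when the initial state already
    fits the target as well as the target's own fit (denominator ~ 0); such
    state pairs must be excluded from the sweep.
    """
    denom = gof_target_fit - gof_initial
    if abs(denom) <= tol:
        raise DegenerateTransitionError(
            "initial-state fit quality equals the target's own fit "
            f"({gof_initial:.6f} vs {gof_target_fit:.6f}); exclude this state pair"
        )
    return (gof_target_fit - gof_perturbed) / denom


@dataclass
class SweepConfig:
    """Amplitude-sweep settings: the forcing grid, the number of independent
    simulated-FC realizations averaged per grid point, and the simulated
    cohort geometry (matching the fitted cohorts)."""

    amplitudes: tuple = DEFAULT_AMPLITUDES
    n_reps: int = 100
    n_samples: int = 200
    tr: float = 2.0
    band: BandSpec = field(default_factory=BandSpec)
    G: float = DEFAULT_G
    beta: float = DEFAULT_BETA
    dt: float = DEFAULT_DT
    target_forcing: ForcingSpec | None = None  # for targets defined by forcing
    degenerate_tol: float = 1e-6

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes, dtype=float)
        if amps.size == 0 or amps[0] != 0.0 or (np.diff(amps) <= 0).any():
            raise ConfigurationError(
                "amplitudes must be strictly increasing and start at 0"
            )


@dataclass
class SweepResult:
    """dGoF grid over homotopic pairs x forcing amplitudes for one ordered
    state pair."""

    initial_state: str
    target_state: str
    pairs: list[tuple[int, int]]
    amplitudes: np.ndarray
    delta_gof: np.ndarray  # (P, A)
    gof_target_fit: float
    gof_initial: float

    @property
    def best_per_pair(self) -> np.ndarray:
        """Minimum dGoF per pair across amplitudes."""
        return self.delta_gof.min(axis=1)

    @property
    def best_amplitude_per_pair(self) -> np.ndarray:
        return self.amplitudes[self.delta_gof.argmin(axis=1)]

    @property
    def global_best(self) -> float:
        return float(self.delta_gof.min())

    @property
    def best_pair_index(self) -> int:
        return int(np.unravel_index(self.delta_gof.argmin(), self.delta_gof.shape)[0])

    @property
    def best_pair(self) -> tuple[int, int]:
        return self.pairs[self.best_pair_index]


def _group_fc_for(spec: HopfModelSpec, cfg: SweepConfig, seed: int,
                  forcing: ForcingSpec | None = None) -> FCMatrix:
    kwargs = {}
    if forcing is not None:
        kwargs = dict(
            forcing_pair=tuple(forcing.pair),
            forcing_amplitudes=np.array([forcing.amplitude]),
            force_both_components=forcing.force_both_components,
        )
    out = _integrate(
        spec.a[None, :], spec, cfg.n_samples, cfg.tr,
        np.random.default_rng(seed), n_subjects=cfg.n_reps, **kwargs,
    )
    return _series_batch_to_group_fcs(out, cfg.tr, cfg.band)[0]


def amplitude_sweep(
    fit_initial: FitResult,
    fit_target: FitResult,
    emp_fc_target: FCMatrix,
    parcellation: Parcellation,
    connectome: StructuralConnectome,
    omega: np.ndarray,
    config: SweepConfig | None = None,
    master_seed: int = 0,
) -> SweepResult:
    """Sweep periodic forcing over every homotopic pair and amplitude.

    For each grid point, ``n_reps`` independent simulations of the
    initial-state model with forcing are run and their FCs Fisher-z
    averaged (the same pipeline as the empirical group FC) before a single
    GoF against the target state's empirical FC. The unforced baseline FC
    is computed once with the same rep count and reused, which makes the
    amplitude-0 column exactly 1. Deterministic for a fixed master seed.
    """
    cfg = config or SweepConfig()
    pairs = enumerate_homotopic_pairs(parcellation)
    if not pairs:
        raise ConfigurationError("parcellation has no homotopic pairs")
    amps = np.asarray(cfg.amplitudes, dtype=float)

    spec_init = HopfModelSpec(
        a=fit_initial.a_best, omega=omega, connectome=connectome,
        G=cfg.G, beta=cfg.beta, dt=cfg.dt,
    )
    spec_target = HopfModelSpec(
        a=fit_target.a_best, omega=omega, connectome=connectome,
        G=cfg.G, beta=cfg.beta, dt=cfg.dt,
    )

    rng = np.random.default_rng(np.random.SeedSequence(master_seed))
    seed_target, seed_init = (int(s) for s in rng.integers(2**31, size=2))
    pair_seeds = rng.integers(2**31, size=len(pairs))

    gof_target_fit = gof(
        _group_fc_for(spec_target, cfg, seed_target, cfg.target_forcing), emp_fc_target
    )
    gof_initial = gof(_group_fc_for(spec_init, cfg, seed_init), emp_fc_target)
    denom = gof_target_fit - gof_initial
    if abs(denom) <= cfg.degenerate_tol:
        raise DegenerateTransitionError(
            f"degenerate state pair {fit_initial.state_name!r} -> "
            f"{fit_target.state_name!r}: GoF {gof_initial:.6f} vs {gof_target_fit:.6f}"
        )

    grid = np.ones((len(pairs), len(amps)))
    for p, pair in enumerate(pairs):
        # all non-zero amplitudes of this pair share one noise realization
        out = _integrate(
            np.tile(spec_init.a, (len(amps) - 1, 1)),
            spec_init, cfg.n_samples, cfg.tr,
            np.random.default_rng(int(pair_seeds[p])),
            n_subjects=cfg.n_reps,
            forcing_pair=pair,
            forcing_amplitudes=amps[1:],
        )
        for ai, fc in enumerate(_series_batch_to_group_fcs(out, cfg.tr, cfg.band)):
            grid[p, ai + 1] = (gof_target_fit - gof(fc, emp_fc_target)) / denom
    return SweepResult(
        initial_state=fit_initial.state_name or "initial",
        target_state=fit_target.state_name or "target",
        pairs=pairs,
        amplitudes=amps,
        delta_gof=grid,
        gof_target_fit=float(gof_target_fit),
        gof_initial=float(gof_initial),
    )


def perturbational_distance(sweep: SweepResult) -> float:
    """Minimum dGoF over all pairs and amplitudes (the state-to-state
    perturbational distance)."""
    if sweep.delta_gof.size == 0:
        raise ConfigurationError("empty sweep grid")
    return sweep.global_best


@dataclass
class TransitionGraph:
    """Directed graph of externally inducible transitions between states."""

    states: list[str]
    graph: nx.DiGraph
    threshold: float

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges())


def build_transition_graph(
    distances: np.ndarray,
    states: list[str],
    threshold: float = DGOF_THRESHOLD,
) -> TransitionGraph:
    """Edge i -> j iff distance(i, j) <= threshold (inclusive), i != j.

    Rows index the initial state, columns the target state. Diagonal
    entries are ignored.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(states):
        raise ConfigurationError("distance matrix must be square over the states")
    g = nx.DiGraph()
    g.add_nodes_from(states)
    for i, si in enumerate(states):
        for j, sj in enumerate(states):
            if i != j and d[i, j] <= threshold:
                g.add_edge(si, sj, weight=float(d[i, j]))
    return TransitionGraph(states=list(states), graph=g, threshold=threshold)


def instability_index(graph: TransitionGraph) -> dict[str, int]:
    """Out-degree per state: how many other states it can be pushed into."""
    return {s: int(graph.graph.out_degree(s)) for s in graph.states}


def rank_perturbation_targets(
    sweeps: list[SweepResult],
    grouping: dict[tuple[str, str], str],
    top_fraction: float = 0.5,
) -> dict[str, dict]:
    """Average per-pair rankings of optimal dGoF across transition groups.

    Within each sweep, homotopic pairs are ranked by their best (minimum)
    dGoF (rank 1 = best; ties get average ranks). Ranks are then averaged
    across all transitions assigned to the same group (e.g. "increase" /
    "decrease" level of consciousness). Returns, per group, the pair list,
    the average ranks, and the top ``top_fraction`` pairs (lowest average
    rank; ties broken by pair index).
    """
    if not sweeps:
        raise ConfigurationError("no sweeps given")
    pair_list = sweeps[0].pairs
    for s in sweeps:
        if s.pairs != pair_list:
            raise ConfigurationError(
                f"sweep {s.initial_state}->{s.target_state} has a different pair list"
            )
    groups: dict[str, list[np.ndarray]] = {}
    for s in sweeps:
        key = (s.initial_state, s.target_state)
        if key not in grouping:
            raise ConfigurationError(f"transition {key} missing from grouping")
        groups.setdefault(grouping[key], []).append(rankdata(s.best_per_pair))
    results: dict[str, dict] = {}
    n_top = int(np.floor(top_fraction * len(pair_list)))
    for name, ranks in groups.items():
        avg = np.mean(ranks, axis=0)
        order = sorted(range(len(pair_list)), key=lambda i: (avg[i], i))
        results[name] = {
            "pairs": pair_list,
            "average_rank": avg,
            "top_pairs": [pair_list[i] for i in order[:n_top]],
        }
    return results


@dataclass
class StateDiagramPoint:
    """One state's coordinates in the level/stability diagram: model-parameter
    distance to its wakefulness baseline (level) and out-degree in the
    transition graph (instability)."""

    state: str
    level: float
    instability: int


def state_diagram(
    fits: dict[str, FitResult],
    graph: TransitionGraph,
    wake_map: dict[str, str],
) -> list[StateDiagramPoint]:
    """Place every state by its distance-to-wakefulness and its instability."""
    out_deg = instability_index(graph)
    points = []
    for state in graph.states:
        if state not in fits:
            raise ConfigurationError(f"no fit for state {state!r}")
        wake = wake_map.get(state, state)
        if wake not in fits:
            raise ConfigurationError(f"state {state!r}: missing baseline fit {wake!r}")
        level = float(np.linalg.norm(fits[state].a_best - fits[wake].a_best))
        points.append(StateDiagramPoint(state=state, level=level,
                                        instability=out_deg.get(state, 0)))
    return points
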