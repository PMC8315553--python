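"""RSN-constrained fitting of regional bifurcation parameters.

Rather than optimizing one bifurcation parameter per region, regions are
grouped by resting-state-network (RSN) membership: the local parameter of
region j is the linear combination a_j = sum_k M[j, k] * g_k of the K
network contributions g. With the six canonical RSNs this embeds the
90-dimensional regional parameter space into a 6-dimensional search space.
The contributions g are optimized with a real-coded genetic algorithm that
minimizes 1 - GoF, where GoF is the SSIM between the simulated group FC
and the empirical group FC of the target state.

Every candidate within one GA run is evaluated against the same noise
realization (common random numbers), so each run optimizes a deterministic
objective surface; independent runs restart from fresh populations and
fresh noise, and the best solution across runs is returned.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core import FCMatrix, StructuralConnectome
from .errors import ConfigurationError, HopfbrainError
from .observables import BandSpec, DEFAULT_BAND, gof
from .simulate import (
    DEFAULT_BETA,
    DEFAULT_DT,
    DEFAULT_G,
    HopfModelSpec,
    _integrate,
    _series_batch_to_group_fcs,
    simulated_group_fc,
)

logger = logging.getLogger(__name__)


def expand_parameters(membership: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Expand K network contributions into N regional bifurcation parameters:
    a_j = sum_k M[j, k] * g_k. Regions in no network receive a_j = 0 (with a
    logged warning)."""
    m = np.asarray(membership)
    g = np.asarray(g, dtype=float)
    if m.ndim != 2 or g.ndim != 1 or m.shape[1] != g.shape[0]:
        raise ConfigurationError(
            f"membership {m.shape} incompatible with g of length {g.shape}"
        )
    empty = ~m.any(axis=1)
    if empty.any():
        logger.warning(
            "%d region(s) belong to no RSN; their bifurcation parameter is 0",
            int(empty.sum()),
        )
    return m @ g


@dataclass
class SimSettings:
    """Size of the simulated cohort used when evaluating a candidate: it
    mirrors the empirical cohort (same number of subjects, same number of
    samples per subject, same TR)."""

    n_subjects: int = 20
    n_samples: int = 200
    tr: float = 2.0
    band: BandSpec = field(default_factory=BandSpec)
    penalty: float = 2.0  # objective value substituted on simulation blow-up


@dataclass
class GAConfig:
    """Real-coded genetic algorithm settings.

    Defaults follow the study protocol (population 10, 200 generations,
    100 independent runs); the operators are tournament selection (size 2),
    uniform crossover, Gaussian mutation and single-individual elitism,
    with gene bounds bracketing the near-bifurcation regime.
    """

    population: int = 10
    generations: int = 200
    n_runs: int = 100
    bounds: tuple[float, float] = (-0.3, 0.3)
    tournament_size: int = 2
    crossover_rate: float = 0.5
    mutation_sigma: float = 0.02
    mutation_rate: float = 0.2
    elitism: int = 1
    sim: SimSettings = field(default_factory=SimSettings)

    def __post_init__(self) -> None:
        if not self.bounds[0] < self.bounds[1]:
            raise ConfigurationError("infeasible gene bounds (lower >= upper)")
        if self.population < 2 or self.elitism < 0 or self.elitism >= self.population:
            raise ConfigurationError("need population >= 2 and 0 <= elitism < population")


@dataclass
class FitResult:
    """Outcome of fitting one brain state."""

    g_best: np.ndarray
    a_best: np.ndarray
    gof_best: float
    run_history: list[list[float]]
    config: dict
    state_name: str | None = None

    def to_json(self, path) -> None:
        payload = {
            "state_name": self.state_name,
            "g_best": list(map(float, self.g_best)),
            "a_best": list(map(float, self.a_best)),
            "gof_best": self.gof_best,
            "run_history": self.run_history,
            "config": self.config,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "FitResult":
        d = json.loads(Path(path).read_text())
        return cls(
            g_best=np.asarray(d["g_best"]),
            a_best=np.asarray(d["a_best"]),
            gof_best=d["gof_best"],
            run_history=d["run_history"],
            config=d["config"],
            state_name=d.get("state_name"),
        )


def objective(
    g: np.ndarray,
    target_fc: FCMatrix,
    template: HopfModelSpec,
    membership: np.ndarray,
    sim: SimSettings,
    seed: int,
) -> float:
    """1 - GoF of the candidate's simulated group FC against the target FC.

    Deterministic for a fixed seed. A simulation blow-up yields the
    configured penalty value (with a warning) so an optimizer can continue.
    """
    spec = template.with_a(expand_parameters(membership, g))
    try:
        sim_fc = simulated_group_fc(
            spec, sim.n_subjects, sim.n_samples, sim.tr, seed=seed, band=sim.band
        )
    except HopfbrainError as exc:
        logger.warning("candidate %s failed to simulate (%s); penalized", g, exc)
        return sim.penalty
    return 1.0 - gof(sim_fc, target_fc)


def _evaluate_population(
    pop: np.ndarray,
    target: np.ndarray,
    template: HopfModelSpec,
    membership: np.ndarray,
    sim: SimSettings,
    seed: int,
) -> np.ndarray:
    """Objective for every candidate, all sharing one noise realization."""
    a_pop = pop @ membership.T
    try:
        out = _integrate(
            a_pop, template, sim.n_samples, sim.tr,
            np.random.default_rng(seed), n_subjects=sim.n_subjects,
        )
        fcs = _series_batch_to_group_fcs(out, sim.tr, sim.band)
        return np.array([1.0 - gof(fc, target) for fc in fcs])
    except HopfbrainError as exc:
        logger.warning("population batch failed (%s); evaluating individually", exc)
        return np.array(
            [objective(g, FCMatrix(target, kind="fisher_avg"), template, membership, sim, seed) for g in pop]
        )


def fit_state(
    target_fc: FCMatrix,
    connectome: StructuralConnectome,
    membership: np.ndarray,
    omega: np.ndarray,
    ga: GAConfig | None = None,
    master_seed: int = 0,
    G: float = DEFAULT_G,
    beta: float = DEFAULT_BETA,
    dt: float = DEFAULT_DT,
    state_name: str | None = None,
) -> FitResult:
    """Fit the network contributions g to one state's empirical group FC.

    Runs ``ga.n_runs`` independent GA optimizations (each with its own
    population initialization and simulation noise seed) and returns the
    solution with the lowest objective 1 - GoF, i.e. the highest SSIM,
    across runs. Deterministic for a fixed ``master_seed``.
    """
    ga = ga or GAConfig()
    membership = np.asarray(membership)
    if target_fc.n_regions != connectome.n_regions:
        raise ConfigurationError(
            f"target FC is {target_fc.n_regions}x{target_fc.n_regions} but the "
            f"connectome has {connectome.n_regions} regions"
        )
    if membership.shape[0] != connectome.n_regions:
        raise ConfigurationError("membership rows must match connectome size")
    template = HopfModelSpec(
        a=np.zeros(connectome.n_regions), omega=omega, connectome=connectome,
        G=G, beta=beta, dt=dt,
    )
    lo, hi = ga.bounds
    K = membership.shape[1]
    target = target_fc.values

    best_g = None
    best_obj = np.inf
    best_run = -1
    run_history: list[list[float]] = []
    sim_seeds: list[int] = []
    children = np.random.SeedSequence(master_seed).spawn(ga.n_runs)
    for run, child in enumerate(children):
        rng = np.random.default_rng(child)
        sim_seed = int(rng.integers(2**31))
        sim_seeds.append(sim_seed)
        pop = rng.uniform(lo, hi, size=(ga.population, K))
        fitness = _evaluate_population(pop, target, template, membership, ga.sim, sim_seed)
        trace = [float(fitness.min())]
        for gen in range(ga.generations):
            order = np.argsort(fitness, kind="stable")
            new_pop = [pop[i].copy() for i in order[: ga.elitism]]
            while len(new_pop) < ga.population:
                parents = []
                for _ in range(2):
                    contenders = rng.integers(ga.population, size=ga.tournament_size)
                    parents.append(pop[contenders[np.argmin(fitness[contenders])]])
                mask = rng.random(K) < ga.crossover_rate
                child_g = np.where(mask, parents[0], parents[1])
                mut = rng.random(K) < ga.mutation_rate
                child_g = child_g + mut * rng.normal(0.0, ga.mutation_sigma, K)
                new_pop.append(np.clip(child_g, lo, hi))
            pop = np.asarray(new_pop)
            fitness = _evaluate_population(pop, target, template, membership, ga.sim, sim_seed)
            trace.append(float(fitness.min()))
            logger.debug("run %d gen %d best %.5f", run, gen, trace[-1])
        run_history.append(trace)
        i_best = int(np.argmin(fitness))
        if fitness[i_best] < best_obj:
            best_obj = float(fitness[i_best])
            best_g = pop[i_best].copy()
            best_run = run
        logger.info("GA run %d/%d best objective %.5f", run + 1, ga.n_runs, trace[-1])

    config = {
        "ga": {
            "population": ga.population,
            "generations": ga.generations,
            "n_runs": ga.n_runs,
            "bounds": list(ga.bounds),
            "tournament_size": ga.tournament_size,
            "crossover_rate": ga.crossover_rate,
            "mutation_sigma": ga.mutation_sigma,
            "mutation_rate": ga.mutation_rate,
            "elitism": ga.elitism,
        },
        "sim": asdict(ga.sim),
        "model": {"G": G, "beta": beta, "dt": dt},
        "master_seed": master_seed,
        "sim_seeds": sim_seeds,
        "best_run": best_run,
        "best_sim_seed": sim_seeds[best_run],
    }
    return FitResult(
        g_best=best_g,
        a_best=expand_parameters(membership, best_g),
        gof_best=1.0 - best_obj,
        run_history=run_history,
        config=config,
        state_name=state_name,
    )
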