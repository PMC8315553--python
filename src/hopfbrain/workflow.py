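"""End-to-end study orchestration.

``run_full_study`` reproduces the whole analysis on any cohort collection:
per-state model fits, amplitude sweeps for every ordered state pair, the
four distance matrices (connectivity correlation, classification, model
parameter, perturbational), the thresholded transition graph, the
level/stability diagram, the increase/decrease regional ranking tables and
the cross-metric Spearman table. Every stage writes its outputs under the
run directory and is skipped on re-runs when its file already exists and
was produced under the same configuration (checksum match), making long
studies resumable.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .core import Parcellation, StateDataset, StructuralConnectome
from .errors import ConfigurationError, DegenerateTransitionError
from .fitting import FitResult, GAConfig, fit_state
from .metrics import (
    DistanceMatrix,
    RandomForestConfig,
    classification_distance,
    connectivity_correlation_distance,
    model_parameter_distance,
    top_fraction_graph,
    zscore_distance_matrix,
)
from .observables import BandSpec, fc_pipeline, group_fc, natural_frequencies
from .core import FCMatrix
from .perturbation import (
    DGOF_THRESHOLD,
    SweepConfig,
    SweepResult,
    amplitude_sweep,
    build_transition_graph,
    instability_index,
    perturbational_distance,
    rank_perturbation_targets,
    state_diagram,
)

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    """Analysis thresholds: transition threshold on dGoF, extreme-edge and
    top-similarity fractions, regional-ranking fraction, and the Eq-style
    correlation/significance cutoffs."""

    delta_gof: float = DGOF_THRESHOLD
    extreme_fraction: float = 0.05
    top_fraction: float = 0.25
    rank_fraction: float = 0.5
    r_threshold: float = 0.5
    alpha: float = 0.05


@dataclass
class RunConfig:
    """Resolved configuration of one study run (written alongside outputs)."""

    outdir: str
    band: BandSpec = field(default_factory=BandSpec)
    ga: GAConfig = field(default_factory=GAConfig)
    sweep: SweepConfig = field(default_factory=SweepConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    rf: RandomForestConfig = field(default_factory=RandomForestConfig)
    n_permutations: int = 0
    n_transfer_repeats: int = 10
    master_seed: int = 0
    include_wake_in_data_metrics: bool = False

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def grouping_from_levels(
    state_meta: dict[str, dict],
    transitions: list[tuple[str, str]],
) -> dict[tuple[str, str], str]:
    """Label each ordered transition as increasing or decreasing the level
    of consciousness.

    A transition is *increase* when the target is a wakefulness state or a
    shallower state on the same route; *decrease* for the reverse
    (wakefulness to anything, or deeper on the same route). Cross-route
    transitions between non-wake states are excluded (absent from the map).
    Wake states are identified by depth 0.
    """
    for name, meta in state_meta.items():
        if "depth" not in meta or "route" not in meta:
            raise ConfigurationError(f"state {name!r} lacks depth/route annotation")
    grouping: dict[tuple[str, str], str] = {}
    for init, target in transitions:
        mi, mt = state_meta[init], state_meta[target]
        if mt["depth"] == 0 and mi["depth"] > 0:
            grouping[(init, target)] = "increase"
        elif mi["depth"] == 0 and mt["depth"] > 0:
            grouping[(init, target)] = "decrease"
        elif mi["route"] == mt["route"] and mi["depth"] != mt["depth"]:
            grouping[(init, target)] = (
                "increase" if mt["depth"] < mi["depth"] else "decrease"
            )
        # cross-route non-wake (or equal-depth same-route): excluded
    return grouping


class _StageCache:
    """Skip-completed-stages bookkeeping: a stage output is reused iff its
    file exists and was written under the same configuration digest."""

    def __init__(self, outdir: Path, digest: str):
        self.outdir = outdir
        self.digest = digest
        self.meta_path = outdir / "stage_digests.json"
        self.meta = (
            json.loads(self.meta_path.read_text()) if self.meta_path.exists() else {}
        )

    def fresh(self, name: str, path: Path) -> bool:
        return path.exists() and self.meta.get(name) == self.digest

    def mark(self, name: str) -> None:
        self.meta[name] = self.digest
        self.meta_path.write_text(json.dumps(self.meta, indent=1, sort_keys=True))


def _write_distance_matrix(path: Path, dm: DistanceMatrix) -> None:
    pd.DataFrame(dm.values, index=dm.states, columns=dm.states).to_csv(path, sep="\t")


def _read_distance_matrix(path: Path, metric: str, symmetric: bool) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(states=list(df.index), values=df.to_numpy(),
                          metric=metric, symmetric=symmetric)


def _sweep_to_frame(sweep: SweepResult) -> pd.DataFrame:
    rows = []
    for p, pair in enumerate(sweep.pairs):
        for a, amp in enumerate(sweep.amplitudes):
            rows.append(
                {"pair_low": pair[0], "pair_high": pair[1], "amplitude": amp,
                 "delta_gof": sweep.delta_gof[p, a]}
            )
    return pd.DataFrame(rows)


def run_full_study(
    cohorts: dict[str, StateDataset],
    state_meta: dict[str, dict],
    connectome: StructuralConnectome,
    parcellation: Parcellation,
    membership: np.ndarray,
    config: RunConfig,
) -> dict:
    """Run the complete analysis; returns the in-memory report bundle.

    ``state_meta`` carries per-state ``route``, ``depth`` (0 = wakefulness)
    and ``wake_baseline`` annotations. Deterministic for a fixed master
    seed; completed stages are skipped on re-runs (see module docstring).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    (outdir / "run_config.json").write_text(
        json.dumps(asdict(config), indent=1, default=str)
    )
    cache = _StageCache(outdir, digest)
    states = sorted(cohorts)
    wake_map = {
        s: (state_meta[s].get("wake_baseline") or s) for s in states
    }
    non_wake = [s for s in states if state_meta[s]["depth"] > 0]
    data_states = states if config.include_wake_in_data_metrics else non_wake

    # --- group FCs and intrinsic frequencies -------------------------------
    group_fcs: dict[str, FCMatrix] = {}
    omegas: dict[str, np.ndarray] = {}
    for s in states:
        ds = cohorts[s]
        if ds.has_series():
            group_fcs[s] = fc_pipeline(ds.subjects, config.band)
            omegas[s] = natural_frequencies(ds, config.band)
        else:
            group_fcs[s] = group_fc(ds.subjects)
    if not omegas:
        raise ConfigurationError("at least one cohort must hold raw BOLD series")

    # --- per-state fits ----------------------------------------------------
    fits: dict[str, FitResult] = {}
    for i, s in enumerate(states):
        path = outdir / f"fit_{s}.json"
        if cache.fresh(f"fit_{s}", path):
            fits[s] = FitResult.from_json(path)
            logger.info("fit %s: reused cached result", s)
            continue
        fits[s] = fit_state(
            group_fcs[s], connectome, membership, omegas.get(s, next(iter(omegas.values()))),
            config.ga, master_seed=config.master_seed + 1000 + i, state_name=s,
            G=config.sweep.G, beta=config.sweep.beta, dt=config.sweep.dt,
        )
        fits[s].to_json(path)
        cache.mark(f"fit_{s}")

    # --- amplitude sweeps for all ordered pairs ----------------------------
    sweeps: dict[tuple[str, str], SweepResult] = {}
    pert_vals = np.full((len(states), len(states)), np.nan)
    for (i, si), (j, sj) in itertools.permutations(enumerate(states), 2):
        path = outdir / f"sweep_{si}_to_{sj}.csv"
        stage = f"sweep_{si}_{sj}"
        try:
            if cache.fresh(stage, path):
                df = pd.read_csv(path)
                pairs = sorted({(int(a), int(b)) for a, b in zip(df.pair_low, df.pair_high)})
                amps = np.sort(df.amplitude.unique())
                grid = (
                    df.pivot_table(index=["pair_low", "pair_high"],
                                   columns="amplitude", values="delta_gof")
                    .loc[pairs, amps].to_numpy()
                )
                meta = json.loads((outdir / f"sweep_{si}_to_{sj}.json").read_text())
                sweeps[(si, sj)] = SweepResult(
                    initial_state=si, target_state=sj, pairs=pairs,
                    amplitudes=amps, delta_gof=grid,
                    gof_target_fit=meta["gof_target_fit"],
                    gof_initial=meta["gof_initial"],
                )
                logger.info("sweep %s->%s: reused cached result", si, sj)
            else:
                sweep = amplitude_sweep(
                    fits[si], fits[sj], group_fcs[sj], parcellation, connectome,
                    omegas.get(si, next(iter(omegas.values()))), config.sweep,
                    master_seed=config.master_seed + 5000 + 131 * i + j,
                )
                sweeps[(si, sj)] = sweep
                _sweep_to_frame(sweep).to_csv(path, index=False)
                (outdir / f"sweep_{si}_to_{sj}.json").write_text(json.dumps({
                    "gof_target_fit": sweep.gof_target_fit,
                    "gof_initial": sweep.gof_initial,
                    "global_best": sweep.global_best,
                    "best_pair": list(sweep.best_pair),
                }))
                cache.mark(stage)
            pert_vals[i, j] = perturbational_distance(sweeps[(si, sj)])
        except DegenerateTransitionError as exc:
            logger.warning("sweep %s->%s skipped: %s", si, sj, exc)
    dm_pert = DistanceMatrix(states=states, values=pert_vals,
                             metric="perturbational", symmetric=False)

    # --- descriptive distance matrices -------------------------------------
    n_d = len(data_states)
    corr_vals = np.zeros((n_d, n_d))
    for a in range(n_d):
        for b in range(a + 1, n_d):
            s1, s2 = data_states[a], data_states[b]
            d, *_ = connectivity_correlation_distance(
                group_fcs[s1], group_fcs[wake_map[s1]],
                group_fcs[s2], group_fcs[wake_map[s2]],
                r_threshold=config.thresholds.r_threshold,
                alpha=config.thresholds.alpha,
            )
            corr_vals[a, b] = corr_vals[b, a] = d
    dm_corr = DistanceMatrix(states=data_states, values=corr_vals,
                             metric="correlation", symmetric=True)

    cls_vals = np.zeros((n_d, n_d))
    for a, s1 in enumerate(data_states):
        for b, s2 in enumerate(data_states):
            rep = classification_distance(
                cohorts[s1], None if a == b else cohorts[s2],
                rf_config=config.rf, n_permutations=config.n_permutations,
                seed=config.master_seed + 9000 + 17 * a + b,
                n_repeats=config.n_transfer_repeats, band=config.band,
            )
            cls_vals[a, b] = rep.distance
    dm_cls = DistanceMatrix(states=data_states, values=cls_vals,
                            metric="classification", symmetric=False)

    mp_vals = np.zeros((len(states), len(states)))
    for a in range(len(states)):
        for b in range(len(states)):
            mp_vals[a, b] = model_parameter_distance(
                fits[states[a]].a_best, fits[states[b]].a_best
            )
    dm_mp = DistanceMatrix(states=states, values=mp_vals,
                           metric="model_parameter", symmetric=True)

    matrices = {
        "correlation": dm_corr,
        "classification": dm_cls,
        "model_parameter": dm_mp,
        "perturbational": dm_pert,
    }
    for name, dm in matrices.items():
        _write_distance_matrix(outdir / f"distance_{name}.tsv", dm)
        try:
            _write_distance_matrix(outdir / f"distance_{name}_z.tsv",
                                   zscore_distance_matrix(dm))
        except ConfigurationError as exc:
            logger.warning("z-scoring %s matrix skipped: %s", name, exc)
        edges = top_fraction_graph(dm, config.thresholds.top_fraction)
        pd.DataFrame(edges, columns=["state_a", "state_b"]).to_csv(
            outdir / f"top_{name}.csv", index=False
        )

    # --- transition graph, diagram, rankings -------------------------------
    graph = build_transition_graph(pert_vals, states, config.thresholds.delta_gof)
    instability = instability_index(graph)
    pd.DataFrame(
        {"state": list(instability), "out_degree": list(instability.values())}
    ).to_csv(outdir / "instability.csv", index=False)
    pd.DataFrame(graph.edges, columns=["initial", "target"]).to_csv(
        outdir / "transition_edges.csv", index=False
    )
    diagram = state_diagram(fits, graph, wake_map)
    pd.DataFrame([asdict(p) for p in diagram]).to_csv(
        outdir / "state_diagram.csv", index=False
    )

    grouping = grouping_from_levels(state_meta, list(sweeps))
    rankings = None
    grouped_sweeps = [s for k, s in sweeps.items() if k in grouping]
    if grouped_sweeps:
        rankings = rank_perturbation_targets(
            grouped_sweeps, grouping, top_fraction=config.thresholds.rank_fraction
        )
        for gname, table in rankings.items():
            pd.DataFrame({
                "pair_low": [p[0] for p in table["pairs"]],
                "pair_high": [p[1] for p in table["pairs"]],
                "average_rank": table["average_rank"],
            }).to_csv(outdir / f"ranking_{gname}.csv", index=False)

    # --- cross-metric rank correlations over shared state pairs ------------
    cross = _cross_metric_spearman(matrices, data_states)
    cross.to_csv(outdir / "metric_spearman.csv", index=False)

    return {
        "states": states,
        "group_fcs": group_fcs,
        "fits": fits,
        "sweeps": sweeps,
        "distance_matrices": matrices,
        "transition_graph": graph,
        "instability": instability,
        "state_diagram": diagram,
        "rankings": rankings,
        "metric_spearman": cross,
    }


def _cross_metric_spearman(matrices: dict[str, DistanceMatrix],
                           shared_states: list[str]) -> pd.DataFrame:
    """Spearman rank correlation between every pair of distance metrics,
    computed over unique unordered state pairs shared by all matrices
    (asymmetric metrics contribute the mean of the two directions)."""
    def pair_values(dm: DistanceMatrix) -> np.ndarray:
        idx = [dm.states.index(s) for s in shared_states]
        v = dm.values[np.ix_(idx, idx)]
        vals = []
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                vals.append(0.5 * (v[a, b] + v[b, a]))
        return np.asarray(vals)

    rows = []
    names = list(matrices)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            va, vb = pair_values(matrices[names[a]]), pair_values(matrices[names[b]])
            ok = np.isfinite(va) & np.isfinite(vb)
            if ok.sum() >= 3:
                res = spearmanr(va[ok], vb[ok])
                rows.append({"metric_a": names[a], "metric_b": names[b],
                             "spearman_rho": float(res.statistic),
                             "p_value": float(res.pvalue), "n_pairs": int(ok.sum())})
    return pd.DataFrame(rows)
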