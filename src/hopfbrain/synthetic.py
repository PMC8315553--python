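"""Synthetic fixtures with known ground truth.

The clinical recordings the framework was designed for (sleep, propofol
anesthesia, disorders of consciousness) are not publicly deposited, so this
module generates everything needed to exercise and validate the pipeline:
a homotopically symmetric modular connectome, a hemisphere-symmetric
network partition, and multi-subject, multi-state cohorts of band-limited
regional signals produced by the forward model itself from known
state-specific network contributions g. Every artifact is exactly
reproducible from its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .core import BoldSeries, Parcellation, StateDataset, StructuralConnectome
from .errors import ConfigurationError, SimulationError
from .fitting import expand_parameters
from .io import scale_connectome
from .simulate import (
    DEFAULT_BETA,
    DEFAULT_DT,
    DEFAULT_G,
    ForcingSpec,
    HopfModelSpec,
    _integrate,
)


def make_aal_style_parcellation(n_regions: int = 90, membership: np.ndarray | None = None) -> Parcellation:
    """An AAL-style parcellation: regions listed left/right interleaved so
    that (2k, 2k+1) are homotopic partners; 90 regions give the standard 45
    pairs."""
    if n_regions % 2:
        raise ConfigurationError("n_regions must be even")
    labels = []
    hemi = []
    partner = np.empty(n_regions, dtype=int)
    for k in range(n_regions // 2):
        labels += [f"Region{k:02d}_L", f"Region{k:02d}_R"]
        hemi += ["L", "R"]
        partner[2 * k] = 2 * k + 1
        partner[2 * k + 1] = 2 * k
    return Parcellation(
        region_labels=labels,
        hemisphere=np.array(hemi),
        homotopic_partner=partner,
        rsn_membership=membership,
    )


def make_connectome(
    n_regions: int = 20,
    n_modules: int = 2,
    density: float = 0.3,
    seed: int | None = None,
    homotopic_weight: float = 1.0,
    within_weight: float = 0.6,
    between_weight: float = 0.15,
    cross_hemisphere_factor: float = 0.5,
    max_attempts: int = 100,
) -> tuple[StructuralConnectome, Parcellation]:
    """A modular random weighted connectome with mirrored hemispheres.

    Homotopic pairs (2k, 2k+1) are strongly connected; within-module edges
    are denser and heavier than between-module edges; the matrix is exactly
    invariant under the hemisphere-swap permutation and is scaled so the
    maximum weight equals the weak-coupling ceiling 0.2. Retries up to
    ``max_attempts`` random draws to obtain a connected graph.
    """
    if n_regions % 2:
        raise ConfigurationError("n_regions must be even")
    if not 0 < density <= 1:
        raise ConfigurationError("density must be in (0, 1]")
    n_pairs = n_regions // 2
    if n_modules > n_pairs:
        raise ConfigurationError("more modules than homotopic pairs")
    rng = np.random.default_rng(seed)
    module_of_pair = np.concatenate(
        [np.full(len(chunk), m) for m, chunk in
         enumerate(np.array_split(np.arange(n_pairs), n_modules))]
    )
    p_within = min(1.0, 2.0 * density)
    p_between = 0.5 * density
    for _ in range(max_attempts):
        w = np.zeros((n_regions, n_regions))
        for p in range(n_pairs):
            w[2 * p, 2 * p + 1] = w[2 * p + 1, 2 * p] = homotopic_weight * rng.uniform(0.8, 1.2)
            for q in range(p + 1, n_pairs):
                same = module_of_pair[p] == module_of_pair[q]
                if rng.random() >= (p_within if same else p_between):
                    continue
                base = within_weight if same else between_weight
                wpq = base * rng.uniform(0.5, 1.5)
                # same-hemisphere edges mirrored exactly; weaker cross edges
                w[2 * p, 2 * q] = w[2 * q, 2 * p] = wpq
                w[2 * p + 1, 2 * q + 1] = w[2 * q + 1, 2 * p + 1] = wpq
                wx = cross_hemisphere_factor * wpq
                w[2 * p, 2 * q + 1] = w[2 * q + 1, 2 * p] = wx
                w[2 * p + 1, 2 * q] = w[2 * q, 2 * p + 1] = wx
        if nx.is_connected(nx.from_numpy_array(w)):
            conn = scale_connectome(StructuralConnectome(w))
            return conn, make_aal_style_parcellation(n_regions)
    raise ConfigurationError(
        f"could not draw a connected connectome in {max_attempts} attempts "
        f"(density {density})"
    )


def make_rsn_partition(
    n_regions: int,
    k_networks: int,
    seed: int | None = None,
    overlap_fraction: float = 0.0,
) -> np.ndarray:
    """A hemisphere-symmetric binary membership matrix M (N x K).

    Every region belongs to at least one network; homotopic partners share
    identical rows; ``overlap_fraction`` of the regions (in whole homotopic
    pairs) belong to two networks.
    """
    if n_regions % 2:
        raise ConfigurationError("n_regions must be even")
    n_pairs = n_regions // 2
    if k_networks > n_pairs:
        raise ConfigurationError("more networks than homotopic pairs")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_pairs)
    m = np.zeros((n_regions, k_networks), dtype=int)
    primary = np.empty(n_pairs, dtype=int)
    for rank, p in enumerate(order):
        primary[p] = rank % k_networks  # round-robin: every network non-empty
    n_overlap_pairs = int(round(overlap_fraction * n_regions)) // 2
    overlap_pairs = rng.choice(n_pairs, size=n_overlap_pairs, replace=False)
    for p in range(n_pairs):
        nets = {primary[p]}
        if p in overlap_pairs:
            others = [k for k in range(k_networks) if k != primary[p]]
            nets.add(int(rng.choice(others)))
        for k in nets:
            m[2 * p, k] = m[2 * p + 1, k] = 1
    return m


@dataclass
class StateSpec:
    """Ground-truth definition of one synthetic brain state: its network
    contributions g, an optional forcing that derives it from its baseline's
    dynamics, and its nominal position on a route towards unconsciousness."""

    g: np.ndarray
    forcing: ForcingSpec | None = None
    route: str = "synthetic"
    depth: int = 0
    wake: str | None = "W"


@dataclass
class GroundTruth:
    """Everything needed to regenerate a synthetic multi-state study."""

    connectome: StructuralConnectome
    parcellation: Parcellation
    membership: np.ndarray
    omega: np.ndarray
    states: dict[str, StateSpec]
    n_subjects: int = 20
    n_samples: int = 200
    tr: float = 2.0
    G: float = DEFAULT_G
    beta: float = DEFAULT_BETA
    dt: float = DEFAULT_DT
    seed: int = 0

    def a_for(self, state: str) -> np.ndarray:
        return expand_parameters(self.membership, self.states[state].g)

    def spec_for(self, state: str) -> HopfModelSpec:
        return HopfModelSpec(
            a=self.a_for(state), omega=self.omega, connectome=self.connectome,
            G=self.G, beta=self.beta, dt=self.dt,
        )


#: Graded state family: one wakefulness baseline plus states whose network
#: contributions move towards negative values, mimicking the loss of
#: self-sustained oscillations in deeper states.
DEFAULT_STATE_TABLE = {
    "W": dict(g=(0.06, 0.05, 0.07), depth=0, wake=None),
    "N1": dict(g=(0.03, 0.00, 0.02), depth=1),
    "N2": dict(g=(-0.03, -0.07, -0.01), depth=2),
    "N3": dict(g=(-0.13, -0.09, -0.16), depth=3),
    "S": dict(g=(0.00, -0.14, 0.05), depth=2),
}


def default_ground_truth(
    seed: int = 0,
    n_regions: int = 20,
    k_networks: int = 3,
    n_subjects: int = 20,
    n_samples: int = 200,
    tr: float = 2.0,
    state_table: dict | None = None,
) -> GroundTruth:
    """The desk-scale study: a 20-region, 3-network connectome and five
    graded states, sized so the full pipeline (including a scaled-down GA)
    runs in minutes."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2023]))
    conn, parc = make_connectome(n_regions, n_modules=min(2, k_networks), density=0.3,
                                 seed=int(rng.integers(2**31)))
    membership = make_rsn_partition(n_regions, k_networks, seed=int(rng.integers(2**31)))
    parc.rsn_membership = membership
    # each homotopic pair shares one intrinsic frequency inside the band
    f_pairs = rng.uniform(0.04, 0.07, n_regions // 2)
    omega = 2 * np.pi * np.repeat(f_pairs, 2)
    table = state_table if state_table is not None else DEFAULT_STATE_TABLE
    states = {}
    for name, entry in table.items():
        g = np.asarray(entry["g"], dtype=float)
        if g.shape != (k_networks,):
            raise ConfigurationError(f"state {name!r}: g must have length {k_networks}")
        states[name] = StateSpec(
            g=g,
            forcing=entry.get("forcing"),
            route=entry.get("route", "synthetic"),
            depth=entry.get("depth", 0),
            wake=entry.get("wake", "W"),
        )
    return GroundTruth(
        connectome=conn, parcellation=parc, membership=membership, omega=omega,
        states=states, n_subjects=n_subjects, n_samples=n_samples, tr=tr, seed=seed,
    )


def make_multistate_cohort(gt: GroundTruth) -> dict[str, StateDataset]:
    """Simulate every state's cohort (independent subjects, optional
    forcing for states derived from their baseline) and link wakefulness
    baselines. Bit-for-bit reproducible from (config, seed)."""
    datasets: dict[str, StateDataset] = {}
    for idx, (name, spec) in enumerate(sorted(gt.states.items())):
        model = gt.spec_for(name)
        rng = np.random.default_rng(np.random.SeedSequence([gt.seed, 101, idx]))
        kwargs = {}
        if spec.forcing is not None:
            kwargs = dict(
                forcing_pair=tuple(spec.forcing.pair),
                forcing_amplitudes=np.array([spec.forcing.amplitude]),
                force_both_components=spec.forcing.force_both_components,
            )
        try:
            out = _integrate(
                model.a[None, :], model, gt.n_samples, gt.tr, rng,
                n_subjects=gt.n_subjects, **kwargs,
            )
        except SimulationError as exc:
            raise SimulationError(f"state {name!r}: {exc}") from exc
        subjects = [BoldSeries(out[0, s], tr_seconds=gt.tr) for s in range(gt.n_subjects)]
        datasets[name] = StateDataset(state_name=name, subjects=subjects)
    for name, spec in gt.states.items():
        if spec.wake is not None:
            if spec.wake not in datasets:
                raise ConfigurationError(f"state {name!r}: unknown baseline {spec.wake!r}")
            datasets[name].wake_baseline = datasets[spec.wake]
    return datasets


def state_metadata(gt: GroundTruth) -> dict[str, dict]:
    """Route/depth/baseline annotations in the form the workflow consumes."""
    return {
        name: {"route": s.route, "depth": s.depth, "wake_baseline": s.wake}
        for name, s in gt.states.items()
    }
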