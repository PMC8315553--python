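"""Core data containers.

The toolkit operates strictly at the parcellated-time-series level: a
parcellation (region labels, hemispheres, homotopic pairing and
resting-state-network membership), a structural connectome (non-negative
coupling matrix), per-subject regional BOLD series, and functional
connectivity (FC) matrices. All containers validate their scientific
invariants on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

#: Maximum structural coupling weight after scaling ("weak coupling" ceiling).
SC_CEILING = 0.2

VALID_HEMISPHERES = ("L", "R", "M")


@dataclass
class Parcellation:
    """A brain parcellation with homotopic pairing and network membership.

    Parameters
    ----------
    region_labels : list of str
        Ordered region names; the order defines all matrix/vector indexing.
    hemisphere : array of {"L", "R", "M"}
        Hemisphere tag per region ("M" for midline/unpaired regions).
    homotopic_partner : int array
        Index of the mirror-symmetric contralateral region, or -1 for none.
        Must be an involution with no self-pairs; partners must carry
        opposite hemisphere tags.
    rsn_membership : (N, K) binary array, optional
        Region-by-network membership matrix M: M[j, k] = 1 if region j
        belongs to network k. Rows may overlap or be all-zero.
    """

    region_labels: list[str]
    hemisphere: np.ndarray
    homotopic_partner: np.ndarray
    rsn_membership: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.hemisphere = np.asarray(self.hemisphere, dtype="U1")
        self.homotopic_partner = np.asarray(self.homotopic_partner, dtype=int)
        n = len(self.region_labels)
        if self.hemisphere.shape != (n,) or self.homotopic_partner.shape != (n,):
            raise ConfigurationError(
                "hemisphere and homotopic_partner must have one entry per region"
            )
        bad = set(self.hemisphere) - set(VALID_HEMISPHERES)
        if bad:
            raise ConfigurationError(f"invalid hemisphere tags: {sorted(bad)}")
        for j, p in enumerate(self.homotopic_partner):
            if p < 0:
                continue
            if p >= n or p == j:
                raise ConfigurationError(
                    f"region {self.region_labels[j]!r}: invalid partner index {p}"
                )
            if self.homotopic_partner[p] != j:
                raise ConfigurationError(
                    f"homotopic pairing is not an involution at region "
                    f"{self.region_labels[j]!r}"
                )
            tags = {self.hemisphere[j], self.hemisphere[p]}
            if tags != {"L", "R"}:
                raise ConfigurationError(
                    f"homotopic partners {self.region_labels[j]!r}/"
                    f"{self.region_labels[p]!r} must lie in opposite hemispheres"
                )
        if self.rsn_membership is not None:
            m = np.asarray(self.rsn_membership)
            if m.ndim != 2 or m.shape[0] != n:
                raise ConfigurationError("rsn_membership must be N x K")
            if not np.isin(m, (0, 1)).all():
                raise ConfigurationError("rsn_membership entries must be 0 or 1")
            self.rsn_membership = m.astype(int)

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    @property
    def n_networks(self) -> int:
        if self.rsn_membership is None:
            raise ConfigurationError("parcellation has no RSN membership matrix")
        return self.rsn_membership.shape[1]


@dataclass
class StructuralConnectome:
    """Symmetric non-negative coupling matrix C with zero diagonal.

    ``scaled`` records whether the matrix has been rescaled so that its
    maximum entry equals the weak-coupling ceiling (0.2).
    """

    weights: np.ndarray
    scaled: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ConfigurationError("connectome weights must be square")
        if (w < 0).any():
            raise ConfigurationError("connectome weights must be non-negative")
        if np.diag(w).any():
            raise ConfigurationError("connectome diagonal must be zero")
        if self.scaled and not np.isclose(w.max(), SC_CEILING):
            raise ConfigurationError(
                f"scaled connectome must have max weight {SC_CEILING}"
            )
        self.weights = w

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass
class BoldSeries:
    """A T x N matrix of regional BOLD samples at a fixed sampling interval."""

    samples: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2:
            raise ConfigurationError("BOLD samples must be a T x N matrix")
        if s.shape[0] < 2:
            raise ConfigurationError("BOLD series needs at least 2 samples")
        if not np.isfinite(s).all():
            raise ConfigurationError("BOLD series contains missing/non-finite values")
        if not self.tr_seconds > 0:
            raise ConfigurationError("tr_seconds must be positive")
        self.samples = s

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_regions(self) -> int:
        return self.samples.shape[1]


FC_KINDS = ("pearson", "fisher_avg", "difference")


@dataclass
class FCMatrix:
    """A symmetric functional-connectivity matrix.

    ``kind`` distinguishes per-subject Pearson matrices, Fisher-z group
    averages, and state-minus-baseline difference matrices (whose entries
    may span [-2, 2]).
    """

    values: np.ndarray
    kind: str = "pearson"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ConfigurationError("FC matrix must be square")
        if self.kind not in FC_KINDS:
            raise ConfigurationError(f"unknown FC kind {self.kind!r}")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ConfigurationError("FC matrix must be symmetric")
        if self.kind in ("pearson", "fisher_avg"):
            if v.min() < -1 - 1e-9 or v.max() > 1 + 1e-9:
                raise ConfigurationError("correlation entries must lie in [-1, 1]")
            if self.kind == "pearson" and not np.allclose(np.diag(v), 1.0):
                raise ConfigurationError("pearson FC must have unit diagonal")
        elif self.kind == "difference":
            if v.min() < -2 - 1e-9 or v.max() > 2 + 1e-9:
                raise ConfigurationError("difference entries must lie in [-2, 2]")
        self.values = v

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class StateDataset:
    """A named cohort of per-subject recordings (or FC matrices) for one
    brain state, with a reference to its site-matched wakefulness baseline."""

    state_name: str
    subjects: list = field(default_factory=list)
    wake_baseline: "StateDataset | None" = None

    def __post_init__(self) -> None:
        ns = {s.n_regions for s in self.subjects}
        if len(ns) > 1:
            raise ConfigurationError(
                f"state {self.state_name!r}: subjects disagree on region count {ns}"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_regions(self) -> int:
        if not self.subjects:
            raise ConfigurationError(f"state {self.state_name!r} has no subjects")
        return self.subjects[0].n_regions

    def has_series(self) -> bool:
        """True when subjects are raw BOLD series (not precomputed FC)."""
        return bool(self.subjects) and isinstance(self.subjects[0], BoldSeries)
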