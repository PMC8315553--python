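"""Data-driven distance metrics between brain states.

Three descriptive distances complement the perturbational one:

* **Connectivity correlation distance** — for each region, the profile of
  FC changes relative to wakefulness is correlated between two states; the
  distance is the fraction of regions *without* a strong, significant
  correlation: d = 1 - (1/N) * sum_j I(j), with I(j) = 1 iff |R| exceeds a
  threshold (default 0.5) and the correlation is significant at alpha after
  Bonferroni correction over the N regions.
* **Classification distance** — 1 - <AUC> of a random-forest classifier
  separating a state from its wakefulness baseline, evaluated either by
  stratified 5-fold cross-validation (self-distance) or by transfer to a
  second state-vs-wake cohort; significance via label-permutation.
* **Model parameter distance** — Euclidean distance between the fitted
  regional bifurcation-parameter vectors of two states.

Plus FC-difference analytics (extreme-edge lists), distance-matrix
z-scoring and top-fraction similarity graphs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .core import BoldSeries, FCMatrix, StateDataset
from .errors import ConfigurationError
from .observables import BandSpec, DEFAULT_BAND, bandpass, compute_fc, zscore

logger = logging.getLogger(__name__)


def _upper_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def fc_difference(
    state_fc: FCMatrix,
    wake_fc: FCMatrix,
    extreme_fraction: float = 0.05,
) -> tuple[FCMatrix, list[tuple[int, int]], list[tuple[int, int]]]:
    """State-minus-wake FC difference plus its extreme edges.

    Returns the difference matrix and the upper-triangle edges in the top
    and bottom ``extreme_fraction`` by signed value (the largest increases
    and decreases relative to wakefulness). Ties are broken by (i, j) index
    order, deterministically.
    """
    if state_fc.n_regions != wake_fc.n_regions:
        raise ConfigurationError("FC matrices must share the parcellation")
    diff = FCMatrix(state_fc.values - wake_fc.values, kind="difference")
    iu, ju = _upper_indices(diff.n_regions)
    vals = diff.values[iu, ju]
    n_extreme = int(np.floor(extreme_fraction * vals.size))
    top_order = sorted(range(vals.size), key=lambda e: (-vals[e], iu[e], ju[e]))
    bot_order = sorted(range(vals.size), key=lambda e: (vals[e], iu[e], ju[e]))
    top = [(int(iu[e]), int(ju[e])) for e in top_order[:n_extreme]]
    bottom = [(int(iu[e]), int(ju[e])) for e in bot_order[:n_extreme]]
    return diff, top, bottom


def difference_correlation(diff_a: FCMatrix, diff_b: FCMatrix) -> float:
    """Pearson correlation between the upper triangles of two FC-difference
    matrices (the similarity of two states' FC-change patterns)."""
    if diff_a.n_regions != diff_b.n_regions:
        raise ConfigurationError("difference matrices must share the parcellation")
    iu, ju = _upper_indices(diff_a.n_regions)
    va, vb = diff_a.values[iu, ju], diff_b.values[iu, ju]
    if va.std() == 0 or vb.std() == 0:
        raise ConfigurationError("zero-variance difference matrix")
    return float(stats.pearsonr(va, vb)[0])


def connectivity_correlation_distance(
    fc_1: FCMatrix,
    wake_1: FCMatrix,
    fc_2: FCMatrix,
    wake_2: FCMatrix,
    r_threshold: float = 0.5,
    alpha: float = 0.05,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Connectivity correlation distance between two states.

    For each region j, the j-th row (i != j) of each state's
    FC-minus-wake-baseline matrix is correlated between the states. The
    indicator I(j) is 1 iff |R| > r_threshold and the correlation p-value
    is below alpha after Bonferroni correction over the N regions. Returns
    (distance, indicators, signed R per region, raw p per region).
    """
    n = fc_1.n_regions
    if any(m.n_regions != n for m in (wake_1, fc_2, wake_2)):
        raise ConfigurationError("all four FC matrices must share the parcellation")
    if n < 3:
        raise ConfigurationError("need at least 3 regions")
    d1 = fc_1.values - wake_1.values
    d2 = fc_2.values - wake_2.values
    indicator = np.zeros(n, dtype=int)
    r_signed = np.zeros(n)
    p_raw = np.ones(n)
    for j in range(n):
        mask = np.arange(n) != j
        a, b = d1[j, mask], d2[j, mask]
        if a.std() == 0 or b.std() == 0:
            logger.warning("region %d has a zero-variance FC-change profile", j)
            continue
        r, p = stats.pearsonr(a, b)
        r_signed[j], p_raw[j] = r, p
        if abs(r) > r_threshold and p * n < alpha:
            indicator[j] = 1
    distance = 1.0 - indicator.mean()
    return float(distance), indicator, r_signed, p_raw


@dataclass
class RandomForestConfig:
    """Random-forest hyperparameters: 1000 trees, sqrt(features) candidate
    features per split, Gini impurity, trees grown until pure."""

    n_estimators: int = 1000
    max_features: str = "sqrt"
    criterion: str = "gini"

    def build(self, seed) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            criterion=self.criterion,
            random_state=seed,
        )


@dataclass
class ClassifierReport:
    """Transfer/self classification outcome for one ordered state pair."""

    train_state: str
    eval_state: str
    auc_mean: float
    auc_sd: float
    p_value: float | None
    n_permutations: int
    null_aucs: np.ndarray | None = None

    @property
    def distance(self) -> float:
        return 1.0 - self.auc_mean


def _cohort_features(cohort: StateDataset, band: BandSpec | None) -> np.ndarray:
    """Vectorized upper-triangle FC per subject (raw series are passed
    through the band-pass/z-score/Pearson pipeline first)."""
    feats = []
    for s in cohort.subjects:
        if isinstance(s, BoldSeries):
            fc = compute_fc(zscore(bandpass(s, band) if band else s))
        else:
            fc = s
        iu, ju = _upper_indices(fc.n_regions)
        feats.append(fc.values[iu, ju])
    return np.asarray(feats)


def _cohort_xy(cohort: StateDataset, band: BandSpec | None) -> tuple[np.ndarray, np.ndarray]:
    if cohort.wake_baseline is None:
        raise ConfigurationError(
            f"state {cohort.state_name!r} has no wakefulness baseline cohort"
        )
    x_state = _cohort_features(cohort, band)
    x_wake = _cohort_features(cohort.wake_baseline, band)
    if min(len(x_state), len(x_wake)) < 5:
        raise ConfigurationError("need at least 5 subjects per class")
    x = np.vstack([x_wake, x_state])
    y = np.concatenate([np.zeros(len(x_wake), dtype=int), np.ones(len(x_state), dtype=int)])
    return x, y


def _cv_auc(x, y, rf: RandomForestConfig, seed) -> tuple[float, float]:
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    aucs = []
    for k, (tr, te) in enumerate(skf.split(x, y)):
        clf = rf.build(seed + k + 1).fit(x[tr], y[tr])
        aucs.append(roc_auc_score(y[te], clf.predict_proba(x[te])[:, 1]))
    return float(np.mean(aucs)), float(np.std(aucs))


def _transfer_auc(x_tr, y_tr, x_ev, y_ev, rf: RandomForestConfig, seed, n_repeats) -> tuple[float, float]:
    aucs = []
    for r in range(n_repeats):
        clf = rf.build(seed + r).fit(x_tr, y_tr)
        aucs.append(roc_auc_score(y_ev, clf.predict_proba(x_ev)[:, 1]))
    return float(np.mean(aucs)), float(np.std(aucs))


def classification_distance(
    cohort_train: StateDataset,
    cohort_eval: StateDataset | None = None,
    rf_config: RandomForestConfig | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
    n_repeats: int = 10,
    band: BandSpec | None = DEFAULT_BAND,
) -> ClassifierReport:
    """Classification distance 1 - <AUC> for a state-vs-wake classifier.

    Self-distance (``cohort_eval`` omitted or equal to ``cohort_train``)
    uses stratified 5-fold cross-validation; transfer distance trains on
    the full training cohort and evaluates the AUC on the second cohort's
    state-vs-wake task, repeated ``n_repeats`` times with different forest
    seeds for a mean +/- sd. The permutation p-value retrains the
    classifier ``n_permutations`` times with shuffled training labels and
    counts null AUCs reaching the observed one. Deterministic for a fixed
    seed.
    """
    rf = rf_config or RandomForestConfig()
    x_tr, y_tr = _cohort_xy(cohort_train, band)
    self_mode = cohort_eval is None or cohort_eval is cohort_train
    if self_mode:
        auc_mean, auc_sd = _cv_auc(x_tr, y_tr, rf, seed)
        eval_name = cohort_train.state_name
    else:
        x_ev, y_ev = _cohort_xy(cohort_eval, band)
        if x_ev.shape[1] != x_tr.shape[1]:
            raise ConfigurationError("cohorts must share the parcellation")
        auc_mean, auc_sd = _transfer_auc(x_tr, y_tr, x_ev, y_ev, rf, seed, n_repeats)
        eval_name = cohort_eval.state_name

    p_value = None
    null_aucs = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed + 7)
        null = []
        for i in range(n_permutations):
            y_perm = rng.permutation(y_tr)
            if self_mode:
                null.append(_cv_auc(x_tr, y_perm, rf, seed + 1000 + i)[0])
            else:
                clf = rf.build(seed + 1000 + i).fit(x_tr, y_perm)
                null.append(roc_auc_score(y_ev, clf.predict_proba(x_ev)[:, 1]))
        null_aucs = np.asarray(null)
        p_value = float((1 + (null_aucs >= auc_mean).sum()) / (1 + n_permutations))
    return ClassifierReport(
        train_state=cohort_train.state_name,
        eval_state=eval_name,
        auc_mean=auc_mean,
        auc_sd=auc_sd,
        p_value=p_value,
        n_permutations=n_permutations,
        null_aucs=null_aucs,
    )


def model_parameter_distance(a_1: np.ndarray, a_2: np.ndarray) -> float:
    """Euclidean distance between two regional bifurcation-parameter vectors."""
    a_1, a_2 = np.asarray(a_1, dtype=float), np.asarray(a_2, dtype=float)
    if a_1.shape != a_2.shape:
        raise ConfigurationError(f"length mismatch: {a_1.shape} vs {a_2.shape}")
    return float(np.linalg.norm(a_1 - a_2))


@dataclass
class DistanceMatrix:
    """States x states distance values for one metric. Correlation and
    model-parameter matrices are symmetric with zero diagonal; classification
    and perturbational matrices may be asymmetric."""

    states: list[str]
    values: np.ndarray
    metric: str
    symmetric: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.states):
            raise ConfigurationError("distance matrix must be square over the states")
        if self.symmetric and not np.allclose(v, v.T, equal_nan=True):
            raise ConfigurationError("symmetric distance matrix is not symmetric")
        self.values = v

    def informative_entries(self) -> tuple[np.ndarray, np.ndarray]:
        n = len(self.states)
        if self.symmetric:
            return np.triu_indices(n, k=1)
        off = ~np.eye(n, dtype=bool)
        return np.nonzero(off)


def zscore_distance_matrix(dm: DistanceMatrix) -> DistanceMatrix:
    """Z-score a distance matrix over its informative entries (off-diagonal;
    unique pairs when symmetric), leaving the diagonal untouched."""
    idx = dm.informative_entries()
    vals = dm.values[idx]
    vals = vals[np.isfinite(vals)]
    if vals.size < 3:
        raise ConfigurationError("need at least 3 informative entries")
    sd = vals.std()
    if sd == 0:
        raise ConfigurationError("zero variance across distance entries")
    z = (dm.values - vals.mean()) / sd
    np.fill_diagonal(z, np.diag(dm.values))
    if dm.symmetric:
        z = np.where(np.isfinite(z), z, z.T)
    return DistanceMatrix(states=list(dm.states), values=z,
                          metric=dm.metric + "_z", symmetric=dm.symmetric)


def top_fraction_graph(
    dm: DistanceMatrix, fraction: float = 0.25
) -> list[tuple[str, str]]:
    """The ``fraction`` of state pairs with the smallest distances (the
    strongest similarities), as an edge list; ties broken by index order."""
    if not 0 < fraction <= 1:
        raise ConfigurationError("fraction must be in (0, 1]")
    idx = dm.informative_entries()
    entries = [
        (dm.values[i, j], i, j)
        for i, j in zip(*idx)
        if np.isfinite(dm.values[i, j])
    ]
    entries.sort(key=lambda t: (t[0], t[1], t[2]))
    n_keep = int(np.floor(fraction * len(entries)))
    return [(dm.states[i], dm.states[j]) for _, i, j in entries[:n_keep]]
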