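"""Coupled stochastic Hopf (Stuart–Landau) oscillator network.

Each brain region j carries the normal form of a Hopf bifurcation with
complex state z_j = x_j + i*y_j, bifurcation parameter a_j and intrinsic
angular frequency omega_j. For a_j < 0 the node has a single stable fixed
point at z_j = 0 (noise-driven fluctuations); for a_j > 0 a stable limit
cycle of radius sqrt(a_j) produces self-sustained oscillation at
omega_j / (2*pi) Hz; near a_j ~ 0 additive noise drives switching across
the bifurcation. Nodes are diffusively coupled through the structural
connectome C scaled by a global factor G:

    dx_j/dt = (a_j - x_j^2 - y_j^2) x_j - omega_j y_j
              + G * sum_i C_ij (x_i - x_j) + beta eta_j(t)  [+ F_j(t)]
    dy_j/dt = (a_j - x_j^2 - y_j^2) y_j + omega_j x_j
              + G * sum_i C_ij (y_i - y_j) + beta eta_j(t)

integrated with the Euler–Maruyama scheme at step dt, with independent
unit Gaussian noise per node and per equation. The real part x_j is the
BOLD proxy, recorded once per repetition time after a discarded transient.
An optional external perturbation adds a periodic forcing term
F_j(t) = F0 * cos(omega_j t) to the real-part equation of both members of
one homotopic pair.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numba
import numpy as np

from .core import BoldSeries, FCMatrix, StructuralConnectome
from .errors import ConfigurationError, SimulationError
from .observables import BandSpec, DEFAULT_BAND, _bandpass_array, _zscore_array

#: Defaults from the whole-brain model: global coupling, noise amplitude,
#: integration step (seconds), discarded transient (seconds) and the
#: standard deviation of the random initial state.
DEFAULT_G = 0.5
DEFAULT_BETA = 0.04
DEFAULT_DT = 0.1
TRANSIENT_SECONDS = 100.0
INIT_SD = 0.1


@dataclass
class HopfModelSpec:
    """Full parameterization of the coupled-oscillator model."""

    a: np.ndarray
    omega: np.ndarray
    connectome: StructuralConnectome
    G: float = DEFAULT_G
    beta: float = DEFAULT_BETA
    dt: float = DEFAULT_DT

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        n = self.connectome.n_regions
        if self.a.shape != (n,) or self.omega.shape != (n,):
            raise ConfigurationError(
                f"a and omega must have length {n} (connectome size)"
            )
        if not self.dt > 0:
            raise ConfigurationError("dt must be positive")
        if self.beta < 0:
            raise ConfigurationError("beta must be non-negative")

    @property
    def n_regions(self) -> int:
        return self.connectome.n_regions

    def with_a(self, a: np.ndarray) -> "HopfModelSpec":
        return replace(self, a=np.asarray(a, dtype=float))


@dataclass(frozen=True)
class ForcingSpec:
    """Periodic forcing of one homotopic pair: F0 * cos(omega_j t) added to
    the real-part equation of both nodes, each at its own intrinsic
    frequency. ``force_both_components`` additionally forces the imaginary
    part."""

    pair: tuple[int, int]
    amplitude: float
    force_both_components: bool = False

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ConfigurationError("forcing amplitude must be non-negative")
        if len(self.pair) != 2 or self.pair[0] == self.pair[1]:
            raise ConfigurationError("forcing pair must be two distinct region indices")


def _steps_per_sample(tr: float, dt: float) -> int:
    k = tr / dt
    if abs(k - round(k)) > 1e-9:
        raise ConfigurationError(f"tr = {tr} must be an integer multiple of dt = {dt}")
    return int(round(k))


@numba.njit(cache=False)
def _em_kernel(x, y, a, omega, C, wsum, G, dt, eta, out, rec_start, sps, step0, j0, j1, famp, force_y):
    """Euler–Maruyama steps for one chunk of the integration.

    State arrays x, y are (R, N) with R = P * S rows (population member p,
    subject s at row p * S + s); ``eta`` holds the pre-scaled noise
    increments for this chunk, shape (L, 2, S, N), shared across the
    population; ``famp`` is the per-row forcing amplitude (0 disables).
    Samples are recorded into ``out`` (R, T, N) before each update.
    """
    L = eta.shape[0]
    R, N = x.shape
    S = eta.shape[2]
    for l in range(L):
        step = step0 + l
        if step >= rec_start and (step - rec_start) % sps == 0:
            k = (step - rec_start) // sps
            if k < out.shape[1]:
                for r in range(R):
                    for n in range(N):
                        out[r, k, n] = x[r, n]
        cx = x @ C
        cy = y @ C
        t = step * dt
        for r in range(R):
            s = r % S
            fa = famp[r]
            for n in range(N):
                xr = x[r, n]
                yr = y[r, n]
                ar = a[r, n] - xr * xr - yr * yr
                dx = ar * xr - omega[n] * yr + G * (cx[r, n] - xr * wsum[n])
                dy = ar * yr + omega[n] * xr + G * (cy[r, n] - yr * wsum[n])
                if fa != 0.0 and (n == j0 or n == j1):
                    f = fa * np.cos(omega[n] * t)
                    dx += f
                    if force_y:
                        dy += f
                x[r, n] = xr + dt * dx + eta[l, 0, s, n]
                y[r, n] = yr + dt * dy + eta[l, 1, s, n]


#: Steps integrated per noise chunk (bounds the noise buffer memory).
_CHUNK_STEPS = 512


def _integrate(
    a_pop: np.ndarray,
    spec: HopfModelSpec,
    n_samples: int,
    tr: float,
    rng: np.random.Generator,
    n_subjects: int,
    forcing_pair: tuple[int, int] | None = None,
    forcing_amplitudes: np.ndarray | None = None,
    force_both_components: bool = False,
    transient: float = TRANSIENT_SECONDS,
) -> np.ndarray:
    """Integrate a batch of models sharing everything but ``a`` (and the
    forcing amplitude), with one common noise realization per subject.

    ``a_pop`` has shape (P, N): P parameter candidates integrated against
    the same n_subjects noise streams. The shared noise makes the map from
    parameters to simulated FC deterministic given the seed (common random
    numbers), so optimizers see a noiseless objective surface. Returns an
    array of shape (P, n_subjects, n_samples, N) of the recorded real parts.
    """
    if n_samples < 2:
        raise ConfigurationError("need at least 2 samples")
    a_pop = np.atleast_2d(np.asarray(a_pop, dtype=float))
    P, N = a_pop.shape
    if N != spec.n_regions:
        raise ConfigurationError("a vectors must match connectome size")
    sps = _steps_per_sample(tr, spec.dt)
    transient_steps = int(round(transient / spec.dt))
    total_steps = transient_steps + (n_samples - 1) * sps + 1

    C = np.ascontiguousarray(spec.connectome.weights)
    wsum = C.sum(axis=0)
    dt = spec.dt
    noise_scale = spec.beta * np.sqrt(dt)

    init = rng.normal(0.0, INIT_SD, size=(2, n_subjects, N))
    x = np.ascontiguousarray(np.repeat(init[0][None], P, axis=0).reshape(P * n_subjects, N))
    y = np.ascontiguousarray(np.repeat(init[1][None], P, axis=0).reshape(P * n_subjects, N))
    a_rows = np.ascontiguousarray(np.repeat(a_pop, n_subjects, axis=0))

    j0 = j1 = -1
    famp_rows = np.zeros(P * n_subjects)
    if forcing_pair is not None and forcing_amplitudes is not None:
        fa = np.asarray(forcing_amplitudes, dtype=float).reshape(-1)
        if fa.shape[0] == 1:
            fa = np.repeat(fa, P)
        if fa.shape[0] != P:
            raise ConfigurationError("one forcing amplitude per population member")
        famp_rows = np.repeat(fa, n_subjects)
        j0, j1 = int(forcing_pair[0]), int(forcing_pair[1])

    out = np.empty((P * n_subjects, n_samples, N))
    for start in range(0, total_steps, _CHUNK_STEPS):
        chunk = min(_CHUNK_STEPS, total_steps - start)
        if noise_scale > 0:
            eta = noise_scale * rng.standard_normal(size=(chunk, 2, n_subjects, N))
        else:
            eta = np.zeros((chunk, 2, n_subjects, N))
        _em_kernel(
            x, y, a_rows, spec.omega, C, wsum, spec.G, dt, eta, out,
            transient_steps, sps, start, j0, j1, famp_rows,
            force_both_components,
        )
        if not np.isfinite(x).all():
            raise SimulationError(
                f"non-finite oscillator state by step {start + chunk}"
            )
    if not np.isfinite(out).all():
        raise SimulationError("non-finite oscillator state in recorded samples")
    return out.reshape(P, n_subjects, n_samples, N)


def simulate(
    spec: HopfModelSpec,
    n_samples: int,
    tr: float = 2.0,
    seed: int | None = None,
    forcing: ForcingSpec | None = None,
    transient: float = TRANSIENT_SECONDS,
) -> BoldSeries:
    """Integrate one realization and record the real parts as a BOLD proxy.

    Deterministic for a fixed seed; a forcing amplitude of 0 reproduces the
    unforced trajectory exactly.
    """
    rng = np.random.default_rng(seed)
    kwargs = {}
    if forcing is not None:
        kwargs = dict(
            forcing_pair=tuple(forcing.pair),
            forcing_amplitudes=np.array([forcing.amplitude]),
            force_both_components=forcing.force_both_components,
        )
    out = _integrate(
        spec.a[None, :], spec, n_samples, tr, rng, n_subjects=1,
        transient=transient, **kwargs,
    )
    return BoldSeries(out[0, 0], tr_seconds=tr)


def _series_batch_to_group_fcs(
    out: np.ndarray, tr: float, band: BandSpec
) -> list[FCMatrix]:
    """Apply the observation pipeline (band-pass, z-score, Pearson,
    Fisher-z average across subjects) to an integration batch of shape
    (P, S, T, N); returns one group FC per population member."""
    P, S, T, N = out.shape
    flat = out.reshape(P * S, T, N)
    filt = _bandpass_array(flat, tr, band, axis=1)
    z = _zscore_array(filt, axis=1)
    # z-scored columns: Pearson correlation reduces to z^T z / T
    fcs = np.clip(z.transpose(0, 2, 1) @ z / T, -1.0, 1.0)
    zf = np.arctanh(np.clip(fcs, -1 + 1e-6, 1 - 1e-6))
    avg = np.tanh(zf.reshape(P, S, N, N).mean(axis=1))
    results = []
    for p in range(P):
        m = 0.5 * (avg[p] + avg[p].T)
        np.fill_diagonal(m, 1.0)
        results.append(FCMatrix(m, kind="fisher_avg"))
    return results


def simulated_group_fc(
    spec: HopfModelSpec,
    n_subjects: int,
    n_samples: int,
    tr: float = 2.0,
    seed: int | None = None,
    forcing: ForcingSpec | None = None,
    band: BandSpec = DEFAULT_BAND,
    transient: float = TRANSIENT_SECONDS,
) -> FCMatrix:
    """Simulate ``n_subjects`` independent runs and compute the group FC
    with the identical pipeline used for empirical data.

    Deterministic for a fixed master seed (subject noise streams are drawn
    from one generator in a fixed order).
    """
    rng = np.random.default_rng(seed)
    kwargs = {}
    if forcing is not None:
        kwargs = dict(
            forcing_pair=tuple(forcing.pair),
            forcing_amplitudes=np.array([forcing.amplitude]),
            force_both_components=forcing.force_both_components,
        )
    out = _integrate(
        spec.a[None, :], spec, n_samples, tr, rng, n_subjects=n_subjects,
        transient=transient, **kwargs,
    )
    return _series_batch_to_group_fcs(out, tr, band)[0]
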