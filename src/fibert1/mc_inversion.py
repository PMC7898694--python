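"""Quasi-genetic Monte Carlo inversion of diffusion-T1 signals.

The per-voxel signal is inverted into a discrete distribution of
weighted diffusion-relaxation components by iterating non-negative
least-squares (NNLS) fits over randomly sampled candidate components:

1. an initial pool of ``n_initial`` random candidates is fitted and
   pruned to its positive-weight survivors;
2. ``n_proliferation`` rounds inject fresh random candidates next to the
   survivors and refit (the optimal residual can only decrease when
   columns are added);
3. ``n_mutation`` rounds add locally perturbed copies of the survivors
   (log-normal scaling of diffusivities and R1, small orientation
   tilts) that compete against their parents in the refit; components
   driven to zero weight go extinct;
4. the ``n_output`` highest-weight components are refitted once more.

Because the inverse Laplace problem is ill-conditioned, no single
solution is trusted: the inversion is repeated over ``n_bootstrap``
with-replacement resamplings of the measurements, and all downstream
statistics are medians across these bootstrap solutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .tensor_model import (
    AcquisitionScheme,
    ComponentSet,
    cartesian_to_spherical,
    design_matrix,
)

__all__ = [
    "InversionConfig",
    "BootstrapSolution",
    "VoxelEnsemble",
    "sample_components",
    "fit_weights",
    "quasi_genetic_fit",
    "bootstrap_invert",
]


@dataclass(frozen=True)
class InversionConfig:
    """Settings of the quasi-genetic Monte Carlo inversion.

    Defaults follow the reference protocol: 200 initial components, 30
    proliferation and 30 mutation/extinction steps, 50 output components
    and 96 bootstrap solutions.  Scale parameters (diffusivities, R1)
    are sampled log-uniformly over their ranges; orientations uniformly
    over the hemisphere (cos(theta) in [0, 1), phi in [0, 2*pi)).
    """

    n_initial: int = 200
    n_proliferation: int = 30
    n_mutation: int = 30
    n_output: int = 50
    n_bootstrap: int = 96
    d_par_range: tuple = (5e-3, 5.0)
    d_perp_range: tuple = (5e-3, 5.0)
    r1_range: tuple = (0.1, 2.0)
    mutation_scale: float = 0.2  # sigma of log-normal parameter kicks
    mutation_tilt_deg: float = 10.0  # max orientation tilt per mutation
    rng_seed: int | None = None

    def __post_init__(self):
        for name in ("n_initial", "n_proliferation", "n_mutation",
                     "n_output", "n_bootstrap"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("d_par_range", "d_perp_range", "r1_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ValueError(f"{name} must be a positive, non-empty range")


@dataclass
class BootstrapSolution:
    """One inversion result: <= n_output weighted components and its fit."""

    components: ComponentSet
    residual: float
    bootstrap_index: int = 0
    residual_history: list = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return len(self.components) == 0

    @property
    def s0(self) -> float:
        """Total weight, an estimate of the unweighted signal S0."""
        return float(np.sum(self.components.w))


@dataclass
class VoxelEnsemble:
    """The n_bootstrap solutions obtained for a single voxel."""

    solutions: list
    scheme: AcquisitionScheme | None = None

    def __len__(self) -> int:
        return len(self.solutions)

    def __iter__(self):
        return iter(self.solutions)


def sample_components(n: int, config: InversionConfig, rng) -> ComponentSet:
    """Draw ``n`` random candidate components (weights left at zero).

    D_par, D_perp and R1 are log-uniform over their configured ranges;
    cos(theta) is uniform on [0, 1) and phi uniform on [0, 2*pi).
    """
    if n < 1:
        raise ValueError("need n >= 1")

    def loguniform(lo, hi, size):
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size))

    d_par = loguniform(*config.d_par_range, n)
    d_perp = loguniform(*config.d_perp_range, n)
    theta = np.arccos(rng.uniform(0.0, 1.0, n))
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    r1 = loguniform(*config.r1_range, n)
    return ComponentSet(d_par, d_perp, theta, phi, r1)


def fit_weights(signal, scheme: AcquisitionScheme, components):
    """Non-negative least-squares weights for a candidate component set.

    Solves min ||K w - S||_2 subject to w >= 0, where K is the forward
    design matrix.  Returns ``(weights, residual_norm)``.
    """
    signal = np.asarray(signal, dtype=float)
    if len(signal) != len(scheme):
        raise ValueError("signal length must match the acquisition scheme")
    if not isinstance(components, ComponentSet):
        components = ComponentSet.from_components(components)
    if len(components) == 0:
        raise ValueError("need at least one candidate component")
    kernel = design_matrix(scheme, components)
    w, residual = nnls(kernel, signal)
    return w, float(residual)


def _mutate(components: ComponentSet, config: InversionConfig, rng) -> ComponentSet:
    """Local perturbation: log-normal kicks on scale parameters, a random
    tilt (<= mutation_tilt_deg) of each orientation; clipped to ranges."""
    n = len(components)
    out = components.copy()
    for name, rng_range in (
        ("d_par", config.d_par_range),
        ("d_perp", config.d_perp_range),
        ("r1", config.r1_range),
    ):
        vals = getattr(out, name) * np.exp(
            rng.normal(0.0, config.mutation_scale, n)
        )
        setattr(out, name, np.clip(vals, *rng_range))

    # tilt each axis by a random angle about a random perpendicular
    u = out.orientations
    tilt = np.deg2rad(config.mutation_tilt_deg) * rng.uniform(0.0, 1.0, n)
    raw = rng.normal(size=(n, 3))
    perp = raw - (np.sum(raw * u, axis=1, keepdims=True)) * u
    norm = np.linalg.norm(perp, axis=1, keepdims=True)
    norm[norm < 1e-12] = 1.0
    perp /= norm
    tilted = np.cos(tilt)[:, None] * u + np.sin(tilt)[:, None] * perp
    tilted /= np.linalg.norm(tilted, axis=1, keepdims=True)
    out.theta, out.phi = cartesian_to_spherical(tilted)
    return out


def _prune(components: ComponentSet, w: np.ndarray):
    keep = w > 0
    pruned = components[keep]
    pruned.w = w[keep]
    return pruned


def quasi_genetic_fit(
    signal, scheme: AcquisitionScheme, config: InversionConfig, rng,
    bootstrap_index: int = 0,
) -> BootstrapSolution:
    """Invert one signal vector into a single bootstrap solution."""
    signal = np.asarray(signal, dtype=float)
    history = []

    # (i) initial random pool
    pool = sample_components(config.n_initial, config, rng)
    w, residual = fit_weights(signal, scheme, pool)
    survivors = _prune(pool, w)
    history.append(residual)
    if len(survivors) == 0:
        return BootstrapSolution(
            ComponentSet.empty(), np.inf, bootstrap_index, history
        )

    # (ii) proliferation: inject fresh candidates, refit, prune
    for _ in range(config.n_proliferation):
        n_fresh = max(config.n_initial - len(survivors), config.n_initial // 4)
        pool = survivors.concat(sample_components(n_fresh, config, rng))
        w, residual = fit_weights(signal, scheme, pool)
        survivors = _prune(pool, w)
        history.append(residual)

    # (iii) mutation/extinction: perturbed copies of the survivors
    # compete against their parents in the refit; components driven to
    # zero weight go extinct.  The feasible set only grows before each
    # refit, so the residual is non-increasing by construction.
    for _ in range(config.n_mutation):
        pool = survivors.concat(_mutate(survivors, config, rng))
        w, residual = fit_weights(signal, scheme, pool)
        survivors = _prune(pool, w)
        history.append(residual)

    # (iv) keep the n_output heaviest components, refit once
    order = np.argsort(survivors.w)[::-1][: config.n_output]
    final = survivors[np.sort(order)]
    w, residual = fit_weights(signal, scheme, final)
    final = _prune(final, w)
    return BootstrapSolution(final, residual, bootstrap_index, history)


def bootstrap_invert(
    signal, scheme: AcquisitionScheme, config: InversionConfig,
    rng=None, resample: bool = True,
) -> VoxelEnsemble:
    """Ensemble of ``n_bootstrap`` inversions of one voxel's signal.

    Each bootstrap solves the inversion on a with-replacement resampling
    of the measurement indices (signal entries and kernel rows resampled
    jointly).  ``resample=False`` disables the resampling, in which case
    every bootstrap fits the full data (they still differ through the
    random candidate pools).  Each bootstrap has its own child RNG
    spawned from the seed, so results do not depend on execution order.
    """
    signal = np.asarray(signal, dtype=float)
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    children = rng.spawn(config.n_bootstrap)

    m = len(scheme)
    solutions = []
    for nb, child in enumerate(children):
        if resample:
            idx = child.integers(0, m, size=m)
        else:
            idx = np.arange(m)
        sol = quasi_genetic_fit(
            signal[idx], scheme.resample(idx), config, child,
            bootstrap_index=nb,
        )
        solutions.append(sol)
    return VoxelEnsemble(solutions, scheme)
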