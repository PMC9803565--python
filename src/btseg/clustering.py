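"""Fuzzy c-means, guaranteed-convergence PSO, and their hybrid.

Fuzzy c-means (FCM) minimizes

    J_m = sum_i sum_j u_ij^m ||x_i - c_j||^2,   m > 1,

by alternating the membership update u_ij = 1 / sum_k (d_ij/d_ik)^(2/(m-1))
and the weighted-mean center update.  FCM descends J_m monotonically but
is a local method; the hybrid wraps it in a guaranteed-convergence
particle swarm (GCPSO), where each particle encodes a full center set,
fitness is J_m with memberships recomputed at the particle's centers,
and particles are periodically refined by a few FCM inner iterations
(Lamarckian: refined centers replace the particle when they improve
fitness).

GCPSO differs from plain PSO in the update of the globally best
particle: instead of the two-term attraction rule it samples a box of
diameter rho(t) around the global best,

    v <- -x + gbest + w*v + rho(t)*(1 - 2r),   r ~ U(0,1)^dim,

so its next position is gbest + w*v + rho*(1-2r).  The diameter rho
adapts to consecutive successes/failures of the global best: more than
``sc`` consecutive successes double rho, more than ``fc`` consecutive
failures halve it (sc = 15, fc = 5).

All operations accept per-point ``sample_weight``; clustering an 8-bit
image by intensity then reduces to a weighted problem over at most 256
unique values, identical in objective and centers to the per-pixel
problem but orders of magnitude cheaper.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "FuzzyPartition",
    "SwarmState",
    "GCPSOFCMConfig",
    "fcm_distances",
    "fcm_memberships",
    "fcm_centers",
    "fcm_objective",
    "fcm_run",
    "init_swarm",
    "gcpso_velocity_update",
    "rho_update",
    "hybrid_gcpso_fcm",
    "segment_image",
    "tumour_mask",
    "FuzzyCMeans",
    "GCPSOFCM",
]


@dataclass
class FuzzyPartition:
    """Result of a fuzzy clustering: memberships U (n x c), centers, J_m."""

    U: np.ndarray
    centers: np.ndarray
    m: float
    objective: float
    n_iter: int = 0
    converged: bool = False


# ---------------------------------------------------------------- FCM core


def fcm_distances(points: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix d_ij = ||x_i - c_j||, shape (n, c)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if points.shape[1] != centers.shape[1]:
        raise ValueError(
            f"feature dimensionality mismatch: points {points.shape[1]}, "
            f"centers {centers.shape[1]}"
        )
    diff = points[:, None, :] - centers[None, :, :]
    return np.sqrt(np.sum(diff**2, axis=2))


def fcm_memberships(D: np.ndarray, m: float) -> np.ndarray:
    """Membership update u_ij = 1 / sum_k (d_ij / d_ik)^(2/(m-1)).

    Rows sum to 1.  A point at zero distance from one or more centers
    gets its mass split equally among those centers.
    """
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    D = np.asarray(D, dtype=float)
    p = 2.0 / (m - 1.0)
    zero = D <= 1e-300
    any_zero = zero.any(axis=1)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        W = np.where(zero, np.inf, D) ** (-p)
        U = W / W.sum(axis=1, keepdims=True)
    if any_zero.any():
        rows = np.nonzero(any_zero)[0]
        U[rows] = zero[rows] / zero[rows].sum(axis=1, keepdims=True)
    return U


def fcm_centers(
    points: np.ndarray,
    U: np.ndarray,
    m: float,
    sample_weight: np.ndarray | None = None,
) -> np.ndarray:
    """Center update c_j = sum_i u_ij^m x_i / sum_i u_ij^m (weighted)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    U = np.asarray(U, dtype=float)
    um = U**m
    if sample_weight is not None:
        um = um * np.asarray(sample_weight, dtype=float)[:, None]
    denom = um.sum(axis=0)
    if np.any(denom <= 0):
        bad = int(np.argmin(denom))
        raise ValueError(
            f"cluster {bad} has zero total membership; cannot update its center"
        )
    return (um.T @ points) / denom[:, None]


def fcm_objective(
    points: np.ndarray,
    U: np.ndarray,
    centers: np.ndarray,
    m: float,
    sample_weight: np.ndarray | None = None,
) -> float:
    """J_m = sum_i sum_j u_ij^m ||x_i - c_j||^2 (>= 0)."""
    D2 = fcm_distances(points, centers) ** 2
    um = np.asarray(U, dtype=float) ** m
    if sample_weight is not None:
        um = um * np.asarray(sample_weight, dtype=float)[:, None]
    return float(np.sum(um * D2))


def _fitness(points, centers, m, sample_weight=None) -> float:
    """J_m at the optimal memberships for the given centers."""
    D = fcm_distances(points, centers)
    U = fcm_memberships(D, m)
    um = U**m
    if sample_weight is not None:
        um = um * np.asarray(sample_weight, dtype=float)[:, None]
    return float(np.sum(um * D**2))


def fcm_run(
    points: np.ndarray,
    c: int,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int | None = 0,
    sample_weight: np.ndarray | None = None,
    init_centers: np.ndarray | None = None,
) -> FuzzyPartition:
    """Alternate membership/center updates to a local minimum of J_m.

    Stops when max |U_new - U_old| < tol or after ``max_iter`` rounds.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    if c < 2:
        raise ValueError("need at least 2 clusters")
    if n < c:
        raise ValueError("need at least as many points as clusters")
    uniq = np.unique(points, axis=0)
    if uniq.shape[0] < 2:
        raise ValueError(
            "degenerate data: all points identical; a single cluster suffices"
        )
    if init_centers is None:
        rng = np.random.default_rng(seed)
        k = min(c, uniq.shape[0])
        idx = rng.choice(uniq.shape[0], size=k, replace=False)
        centers = uniq[idx]
        if k < c:  # duplicate-free seeding impossible; jitter the extras
            extra = uniq[rng.choice(uniq.shape[0], size=c - k)]
            extra = extra + rng.normal(0, 1e-3, size=extra.shape)
            centers = np.vstack([centers, extra])
    else:
        centers = np.array(init_centers, dtype=float)
    U = fcm_memberships(fcm_distances(points, centers), m)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        centers = fcm_centers(points, U, m, sample_weight)
        U_new = fcm_memberships(fcm_distances(points, centers), m)
        delta = float(np.max(np.abs(U_new - U)))
        U = U_new
        if delta < tol:
            converged = True
            break
    obj = fcm_objective(points, U, centers, m, sample_weight)
    return FuzzyPartition(
        U=U, centers=centers, m=m, objective=obj, n_iter=it, converged=converged
    )


# ------------------------------------------------------------------ GCPSO


@dataclass
class SwarmState:
    """Positions, velocities, personal/global bests and GCPSO counters."""

    positions: np.ndarray  # (P, dim)
    velocities: np.ndarray
    pbest_pos: np.ndarray
    pbest_fit: np.ndarray
    gbest_pos: np.ndarray
    gbest_fit: float
    best_index: int
    omega: float = 0.72
    c1: float = 1.49
    c2: float = 1.49
    rho: float = 1.0
    success_count: int = 0
    failure_count: int = 0
    sc: int = 15
    fc: int = 5
    rho_max: float = np.inf


def init_swarm(
    positions: np.ndarray,
    fitness: np.ndarray,
    omega: float = 0.72,
    c1: float = 1.49,
    c2: float = 1.49,
    rho: float = 1.0,
    rho_max: float = np.inf,
) -> SwarmState:
    positions = np.asarray(positions, dtype=float)
    fitness = np.asarray(fitness, dtype=float)
    if positions.shape[0] < 2:
        raise ValueError("population must contain at least 2 particles")
    best = int(np.argmin(fitness))
    return SwarmState(
        positions=positions.copy(),
        velocities=np.zeros_like(positions),
        pbest_pos=positions.copy(),
        pbest_fit=fitness.copy(),
        gbest_pos=positions[best].copy(),
        gbest_fit=float(fitness[best]),
        best_index=best,
        omega=omega,
        c1=c1,
        c2=c2,
        rho=rho,
        rho_max=rho_max,
    )


def gcpso_velocity_update(
    state: SwarmState,
    idx: int,
    rng: np.random.Generator | None = None,
    draws=None,
) -> np.ndarray:
    """New velocity for particle ``idx``.

    The globally best particle uses the guaranteed-convergence rule
    v' = -x + gbest + w*v + rho*(1-2r) — its next position samples the
    box gbest + w*v +/- rho uniformly — while every other particle uses
    the canonical two-term attraction rule.  ``draws`` may supply the
    uniform variates explicitly (r for the best particle, (r1, r2)
    otherwise); by default they come from ``rng``.
    """
    x = state.positions[idx]
    v = state.velocities[idx]
    if idx == state.best_index:
        r = rng.uniform(size=x.shape) if draws is None else np.asarray(draws, dtype=float)
        return -x + state.gbest_pos + state.omega * v + state.rho * (1.0 - 2.0 * r)
    if draws is None:
        r1 = rng.uniform(size=x.shape)
        r2 = rng.uniform(size=x.shape)
    else:
        r1, r2 = (np.asarray(d, dtype=float) for d in draws)
    return (
        state.omega * v
        + state.c1 * r1 * (state.pbest_pos[idx] - x)
        + state.c2 * r2 * (state.gbest_pos - x)
    )


def rho_update(state: SwarmState, improved_gbest: bool) -> None:
    """Adapt the search diameter from consecutive success/failure runs.

    A success resets the failure counter and vice versa.  More than
    ``sc`` consecutive successes double rho; more than ``fc``
    consecutive failures halve it; the triggering counter resets.
    """
    if improved_gbest:
        state.failure_count = 0
        state.success_count += 1
        if state.success_count > state.sc:
            state.rho *= 2.0
            state.success_count = 0
    else:
        state.success_count = 0
        state.failure_count += 1
        if state.failure_count > state.fc:
            state.rho *= 0.5
            state.failure_count = 0
    state.rho = float(np.clip(state.rho, 1e-10, state.rho_max))


@dataclass(frozen=True)
class GCPSOFCMConfig:
    """Hyperparameters of the hybrid optimizer (all exposed)."""

    population: int = 20
    omega: float = 0.72
    c1: float = 1.49
    c2: float = 1.49
    rho0: float = 1.0
    max_generations: int = 100
    stagnation: int = 20
    refine_every: int = 1
    inner_fcm_iters: int = 2
    m: float = 2.0
    tol: float = 1e-5
    seed: int = 0


def _fcm_refine(points, centers, m, iters, sample_weight=None) -> np.ndarray:
    """A few FCM alternations starting from the given centers."""
    for _ in range(iters):
        U = fcm_memberships(fcm_distances(points, centers), m)
        try:
            centers = fcm_centers(points, U, m, sample_weight)
        except ValueError:
            break  # dead cluster: keep previous centers
    return centers


def hybrid_gcpso_fcm(
    points: np.ndarray,
    c: int,
    config: GCPSOFCMConfig | None = None,
    sample_weight: np.ndarray | None = None,
) -> tuple[FuzzyPartition, SwarmState]:
    """GCPSO over center sets with Lamarckian FCM refinement.

    Each particle encodes c centers (flattened); fitness is J_m with
    memberships recomputed at the particle's centers.  Every
    ``refine_every`` generations each particle is polished by
    ``inner_fcm_iters`` FCM alternations and keeps the refined centers
    when they improve fitness.  Terminates on gbest stagnation or after
    ``max_generations``; the returned partition is the gbest polished
    to FCM convergence.
    """
    cfg = config or GCPSOFCMConfig()
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n, dim = points.shape
    if c < 2:
        raise ValueError("need at least 2 clusters")
    if cfg.population < 2:
        raise ValueError("population must contain at least 2 particles")
    rng = np.random.default_rng(cfg.seed)
    uniq = np.unique(points, axis=0)
    if uniq.shape[0] < 2:
        raise ValueError("degenerate data: all points identical")

    lo = points.min(axis=0)
    hi = points.max(axis=0)
    span = float(np.max(hi - lo))

    def sample_centers() -> np.ndarray:
        k = min(c, uniq.shape[0])
        idx = rng.choice(uniq.shape[0], size=k, replace=False)
        cen = uniq[idx]
        if k < c:
            cen = np.vstack([cen, uniq[rng.choice(uniq.shape[0], size=c - k)]])
            cen = cen + rng.normal(0, 1e-3, size=cen.shape)
        return cen

    positions = np.stack(
        [sample_centers().ravel() for _ in range(cfg.population)]
    )
    fits = np.array(
        [_fitness(points, p.reshape(c, dim), cfg.m, sample_weight) for p in positions]
    )
    state = init_swarm(
        positions,
        fits,
        omega=cfg.omega,
        c1=cfg.c1,
        c2=cfg.c2,
        rho=cfg.rho0,
        rho_max=max(span, 1.0),
    )
    since_improvement = 0
    for gen in range(cfg.max_generations):
        for i in range(cfg.population):
            state.velocities[i] = gcpso_velocity_update(state, i, rng)
        state.positions += state.velocities
        np.clip(
            state.positions,
            np.tile(lo, c),
            np.tile(hi, c),
            out=state.positions,
        )
        fits = np.array(
            [
                _fitness(points, p.reshape(c, dim), cfg.m, sample_weight)
                for p in state.positions
            ]
        )
        if cfg.refine_every > 0 and gen % cfg.refine_every == 0:
            for i in range(cfg.population):
                refined = _fcm_refine(
                    points,
                    state.positions[i].reshape(c, dim),
                    cfg.m,
                    cfg.inner_fcm_iters,
                    sample_weight,
                ).ravel()
                f = _fitness(points, refined.reshape(c, dim), cfg.m, sample_weight)
                if f < fits[i]:  # Lamarckian replacement
                    state.positions[i] = refined
                    fits[i] = f
        better = fits < state.pbest_fit
        state.pbest_pos[better] = state.positions[better]
        state.pbest_fit[better] = fits[better]
        best = int(np.argmin(state.pbest_fit))
        improved = state.pbest_fit[best] < state.gbest_fit - 1e-12
        if improved:
            state.gbest_fit = float(state.pbest_fit[best])
            state.gbest_pos = state.pbest_pos[best].copy()
            state.best_index = best
            since_improvement = 0
        else:
            since_improvement += 1
        rho_update(state, improved)
        if since_improvement >= cfg.stagnation:
            break

    centers = _fcm_refine(
        points, state.gbest_pos.reshape(c, dim), cfg.m, 200, sample_weight
    )
    part = fcm_run(
        points,
        c,
        m=cfg.m,
        tol=cfg.tol,
        max_iter=200,
        sample_weight=sample_weight,
        init_centers=centers,
    )
    if part.objective <= state.gbest_fit + 1e-9:
        state.gbest_fit = min(state.gbest_fit, part.objective)
        return part, state
    # polishing never worsens in practice; fall back to raw gbest if it did
    U = fcm_memberships(fcm_distances(points, state.gbest_pos.reshape(c, dim)), cfg.m)
    part = FuzzyPartition(
        U=U,
        centers=state.gbest_pos.reshape(c, dim),
        m=cfg.m,
        objective=state.gbest_fit,
    )
    return part, state


# ------------------------------------------------------- image wrappers


def segment_image(
    img: np.ndarray, c: int = 3, config: GCPSOFCMConfig | None = None
) -> np.ndarray:
    """Cluster pixel intensities with the hybrid; return an int label map.

    Labels are ordered by ascending cluster center intensity, so label
    c-1 is always the brightest class.  Internally the unique intensity
    values are clustered with their pixel counts as sample weights —
    identical objective and centers to per-pixel clustering of a 1-D
    intensity feature, at a fraction of the cost.  Max-membership ties
    go to the lowest cluster index.
    """
    img = np.asarray(img, dtype=float)
    quant = np.round(img)  # 8-bit imagery: at most 256 distinct values
    values, counts = np.unique(quant.ravel(), return_counts=True)
    if values.size < c:
        raise ValueError(
            f"image has {values.size} distinct intensities; cannot form {c} clusters"
        )
    part, _ = hybrid_gcpso_fcm(
        values[:, None], c, config, sample_weight=counts.astype(float)
    )
    order = np.argsort(part.centers[:, 0])
    # per-value label, ties to the lowest index via argmax on reordered U
    labels_by_value = np.argmax(part.U[:, order], axis=1)
    idx = np.searchsorted(values, quant.ravel())
    return labels_by_value[idx].reshape(img.shape)


def tumour_mask(
    labels: np.ndarray, keep_largest: bool = True, n_labels: int | None = None
) -> np.ndarray:
    """Binary mask of the brightest cluster.

    ``n_labels`` names the label count of the map (labels 0..n_labels-1);
    when the brightest label is absent the mask is empty, without error.
    With ``keep_largest`` only the largest 8-connected component is kept
    (the tumour is assumed compact).
    """
    labels = np.asarray(labels)
    brightest = (n_labels - 1) if n_labels is not None else labels.max()
    mask = labels == brightest
    if not mask.any():
        return mask
    if keep_largest:
        structure = ndimage.generate_binary_structure(2, 2)
        comp, ncomp = ndimage.label(mask, structure=structure)
        if ncomp > 1:
            sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, ncomp + 1))
            mask = comp == (1 + int(np.argmax(sizes)))
    return mask


# ------------------------------------------------------ sklearn wrappers


class FuzzyCMeans(BaseEstimator, ClusterMixin):
    """Fuzzy c-means clusterer with the sklearn estimator interface.

    Attributes after fit: ``cluster_centers_``, ``membership_`` (U),
    ``labels_``, ``objective_`` (J_m), ``n_iter_``.
    """

    def __init__(self, n_clusters=3, m=2.0, tol=1e-5, max_iter=300, random_state=0):
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None, sample_weight=None):
        part = fcm_run(
            X,
            self.n_clusters,
            m=self.m,
            tol=self.tol,
            max_iter=self.max_iter,
            seed=self.random_state,
            sample_weight=sample_weight,
        )
        self.cluster_centers_ = part.centers
        self.membership_ = part.U
        self.labels_ = np.argmax(part.U, axis=1)
        self.objective_ = part.objective
        self.n_iter_ = part.n_iter
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        D = fcm_distances(X, self.cluster_centers_)
        return np.argmax(fcm_memberships(D, self.m), axis=1)


class GCPSOFCM(BaseEstimator, ClusterMixin):
    """Hybrid GCPSO-FCM clusterer with the sklearn estimator interface."""

    def __init__(
        self,
        n_clusters=3,
        m=2.0,
        population=20,
        omega=0.72,
        c1=1.49,
        c2=1.49,
        rho0=1.0,
        max_generations=100,
        stagnation=20,
        refine_every=1,
        inner_fcm_iters=2,
        tol=1e-5,
        random_state=0,
    ):
        self.n_clusters = n_clusters
        self.m = m
        self.population = population
        self.omega = omega
        self.c1 = c1
        self.c2 = c2
        self.rho0 = rho0
        self.max_generations = max_generations
        self.stagnation = stagnation
        self.refine_every = refine_every
        self.inner_fcm_iters = inner_fcm_iters
        self.tol = tol
        self.random_state = random_state

    def _config(self) -> GCPSOFCMConfig:
        return GCPSOFCMConfig(
            population=self.population,
            omega=self.omega,
            c1=self.c1,
            c2=self.c2,
            rho0=self.rho0,
            max_generations=self.max_generations,
            stagnation=self.stagnation,
            refine_every=self.refine_every,
            inner_fcm_iters=self.inner_fcm_iters,
            m=self.m,
            tol=self.tol,
            seed=self.random_state,
        )

    def fit(self, X, y=None, sample_weight=None):
        part, state = hybrid_gcpso_fcm(
            X, self.n_clusters, self._config(), sample_weight=sample_weight
        )
        self.cluster_centers_ = part.centers
        self.membership_ = part.U
        self.labels_ = np.argmax(part.U, axis=1)
        self.objective_ = part.objective
        self.swarm_state_ = state
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        D = fcm_distances(X, self.cluster_centers_)
        return np.argmax(fcm_memberships(D, self.m), axis=1)
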