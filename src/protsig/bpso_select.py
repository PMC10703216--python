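"""Binary particle swarm optimization over protein-subset masks.

Each particle is a bit vector marking a candidate feature subset.  The
velocity update is the classical PSO rule

    v(t+1) = w*v(t) + c1*R1*(pbest - x(t)) + c2*R2*(gbest - x(t))

with fresh uniform R1, R2 per particle per coordinate and clamping to
[-v_clamp, +v_clamp].  Positions are then *resampled* bit-wise: a bit is 1
with probability S(v) = 1/(1+exp(-v)), the sigmoid transfer of the velocity.
Fitness is a classifier wrapper: stratified cross-validated accuracy of a
simple base learner restricted to the masked features, minus a small
size penalty so equally accurate masks prefer fewer proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.linear_model import LogisticRegression

from .io_preprocess import InputError, ProteinMatrix

__all__ = [
    "BPSOParams",
    "FitnessSpec",
    "SwarmState",
    "SelectionResult",
    "FitnessEvaluator",
    "sigmoid_transfer",
    "update_velocity",
    "update_position",
    "evaluate_fitness",
    "run_bpso",
]


@dataclass
class BPSOParams:
    """Swarm hyper-parameters.

    Defaults follow the reference workflow: 500 particles, 50 iterations,
    inertia w=0.5, cognitive c1=1, social c2=2.  ``v_clamp`` bounds the
    velocity magnitude at 6 (sigmoid(6) ~ 0.9975, keeping bit flips
    possible); ``seed`` governs every stochastic draw.
    """

    n_particles: int = 500
    n_iterations: int = 50
    w: float = 0.5
    c1: float = 1.0
    c2: float = 2.0
    v_clamp: float = 6.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_particles < 1 or self.n_iterations < 1:
            raise InputError("n_particles and n_iterations must be >= 1")
        if min(self.w, self.c1, self.c2) < 0 or self.v_clamp <= 0:
            raise InputError("w, c1, c2 must be >= 0 and v_clamp > 0")


@dataclass
class FitnessSpec:
    """Wrapper-fitness contract: CV accuracy of a base learner minus
    ``size_penalty * (selected count / total features)``; empty mask -> 0."""

    base_learner: str = "knn"
    cv_folds: int = 5
    size_penalty: float = 0.01
    knn_neighbors: int = 5

    def make_classifier(self):
        if self.base_learner == "knn":
            return KNeighborsClassifier(n_neighbors=self.knn_neighbors)
        if self.base_learner == "logreg":
            return LogisticRegression(max_iter=1000)
        raise InputError(f"unknown base_learner {self.base_learner!r}")


@dataclass
class SwarmState:
    """Positions, velocities and best-so-far bookkeeping of the swarm."""

    x: np.ndarray          # (n_particles, m) in {0,1}
    v: np.ndarray          # (n_particles, m) real
    pbest_x: np.ndarray
    pbest_f: np.ndarray    # (n_particles,)
    gbest_x: np.ndarray    # (m,)
    gbest_f: float
    t: int = 0


@dataclass
class SelectionResult:
    """Outcome of a BPSO run: best mask, its fitness, the per-iteration
    gbest trace, and the names of the selected proteins."""

    mask: np.ndarray
    fitness: float
    trace: list[float]
    selected: list[str]
    n_evaluations: int = 0


def sigmoid_transfer(v):
    """Velocity-to-probability transfer S(v) = 1/(1+exp(-v))."""
    return expit(v)


def update_velocity(state: SwarmState, params: BPSOParams, rng: np.random.Generator) -> None:
    """Apply the PSO velocity rule in place, then clamp to +/- v_clamp."""
    shape = state.x.shape
    r1 = rng.uniform(size=shape)
    r2 = rng.uniform(size=shape)
    state.v = (
        params.w * state.v
        + params.c1 * r1 * (state.pbest_x - state.x)
        + params.c2 * r2 * (state.gbest_x[None, :] - state.x)
    )
    np.clip(state.v, -params.v_clamp, params.v_clamp, out=state.v)


def update_position(state: SwarmState, rng: np.random.Generator) -> None:
    """Resample every bit: 1 with probability S(v), using fresh uniforms."""
    u = rng.uniform(size=state.x.shape)
    state.x = (u < sigmoid_transfer(state.v)).astype(np.int8)


class FitnessEvaluator:
    """Cached wrapper fitness over a fixed dataset and fold assignment.

    The stratified fold assignment is drawn once from the seed, so repeated
    evaluations of the same mask are identical and cacheable; the cache is
    keyed by the mask bytes.  Per-fold feature standardization (training
    statistics only) is precomputed, so evaluating a mask reduces to a
    column selection plus one classifier fit per fold.
    """

    def __init__(self, data: ProteinMatrix, spec: FitnessSpec, seed: int | None = None):
        if data.n_proteins < 1:
            raise InputError("no features to select from")
        y = data.class_labels.to_numpy()
        if len(np.unique(y)) < 2:
            raise InputError("both classes must be present")
        X = data.values.to_numpy(dtype=float)
        self.y = y
        self.spec = spec
        self.m = data.n_proteins
        cv = StratifiedKFold(
            n_splits=spec.cv_folds,
            shuffle=True,
            random_state=None if seed is None else seed % (2**31),
        )
        # freeze folds; standardize each fold's train+test by train statistics
        self._folds = []
        for train, test in cv.split(X, y):
            mu = X[train].mean(axis=0)
            sd = X[train].std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            self._folds.append(
                ((X[train] - mu) / sd, y[train], (X[test] - mu) / sd, y[test])
            )
        self._cache: dict[bytes, float] = {}
        self.n_evaluations = 0

    def __call__(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=np.int8)
        if mask.shape != (self.m,):
            raise RuntimeError(f"mask length {mask.shape} != feature count {self.m}")
        key = mask.tobytes()
        if key in self._cache:
            return self._cache[key]
        k = int(mask.sum())
        if k == 0:
            fit = 0.0
        else:
            cols = mask.astype(bool)
            correct = total = 0
            for Xtr, ytr, Xte, yte in self._folds:
                clf = self.spec.make_classifier()
                clf.fit(Xtr[:, cols], ytr)
                correct += int((clf.predict(Xte[:, cols]) == yte).sum())
                total += len(yte)
            fit = float(correct / total - self.spec.size_penalty * k / self.m)
        self._cache[key] = fit
        self.n_evaluations += 1
        return fit


def evaluate_fitness(
    mask: np.ndarray, data: ProteinMatrix, spec: FitnessSpec, seed: int | None = None
) -> float:
    """One-off wrapper fitness of a mask (see :class:`FitnessEvaluator`)."""
    return FitnessEvaluator(data, spec, seed)(np.asarray(mask))


def run_bpso(
    data: ProteinMatrix,
    params: BPSOParams | None = None,
    spec: FitnessSpec | None = None,
    evaluator: FitnessEvaluator | None = None,
) -> SelectionResult:
    """Search protein subsets with binary PSO and return the best mask found.

    Positions start as independent Bernoulli(0.5) bits, velocities at zero.
    Each iteration evaluates all particles, updates personal and global
    bests (strict improvement, so ties keep the first achiever), then moves
    the swarm.  Fully reproducible given ``params.seed``.
    """
    params = params or BPSOParams()
    spec = spec or FitnessSpec()
    if data.n_proteins < 2:
        raise InputError("need >= 2 features for subset search")
    rng = np.random.default_rng(params.seed)
    if evaluator is None:
        cv_seed = None if params.seed is None else int(rng.integers(2**31))
        evaluator = FitnessEvaluator(data, spec, cv_seed)
    n, m = params.n_particles, data.n_proteins

    state = SwarmState(
        x=(rng.uniform(size=(n, m)) < 0.5).astype(np.int8),
        v=np.zeros((n, m)),
        pbest_x=np.zeros((n, m), dtype=np.int8),
        pbest_f=np.full(n, -np.inf),
        gbest_x=np.zeros(m, dtype=np.int8),
        gbest_f=-np.inf,
    )
    trace: list[float] = []
    for t in range(params.n_iterations):
        state.t = t
        f = np.array([evaluator(state.x[i]) for i in range(n)])
        improved = f > state.pbest_f
        state.pbest_f[improved] = f[improved]
        state.pbest_x[improved] = state.x[improved]
        best = int(np.argmax(state.pbest_f))
        if state.pbest_f[best] > state.gbest_f:
            state.gbest_f = float(state.pbest_f[best])
            state.gbest_x = state.pbest_x[best].copy()
        trace.append(state.gbest_f)
        update_velocity(state, params, rng)
        update_position(state, rng)

    mask = state.gbest_x.astype(np.int8)
    selected = [p for p, b in zip(data.protein_ids, mask) if b]
    return SelectionResult(
        mask=mask,
        fitness=state.gbest_f,
        trace=trace,
        selected=selected,
        n_evaluations=evaluator.n_evaluations,
    )
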