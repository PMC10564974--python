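"""Random normal-form maps and the labelled training library.

Training data for the bifurcation classifier comes from stochastic
difference equations built from the normal form of each local,
codimension-one, discrete-time bifurcation (period-doubling,
Neimark-Sacker, fold, transcritical, pitchfork), plus random
higher-order polynomial terms up to degree 10 and additive Gaussian
white noise.  The bifurcation occurs at ``mu = 0`` in every family.

A *forced* simulation ramps ``mu`` linearly from ``mu0`` to 0; a *null*
simulation holds ``mu`` at ``mu0``.  ``mu0`` is drawn so the linearised
eigenvalue satisfies ``|lambda| < 0.8``, i.e. the run starts a variable
distance from the bifurcation but never so close that noise-induced
transitions dominate.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "BifurcationClass",
    "NormalFormModel",
    "Trajectory",
    "TrainingLibrary",
    "rotation_matrix",
    "sample_mu0",
    "sample_model",
    "step_normal_form",
    "equilibrium",
    "detect_transition",
    "simulate",
    "build_library",
    "SimulationDiverged",
]

#: number of burn-in iterations discarded before recording
BURN_IN = 100
#: number of recorded iterations per simulation
N_RECORDED = 600
#: maximum stored trajectory length
MAX_LEN = 500
#: absolute deviation floor used by the transition rule when sigma == 0
NOISE_FREE_FLOOR = 1e-3
#: default training range for the noise amplitude sigma
SIGMA_RANGE = (0.005, 0.015)


class BifurcationClass(enum.IntEnum):
    """The six classifier targets: no bifurcation plus the five local
    codimension-one discrete-time bifurcations.  The integer codes are
    the classifier's class labels and are fixed."""

    NULL = 0
    PERIOD_DOUBLING = 1
    NEIMARK_SACKER = 2
    FOLD = 3
    TRANSCRITICAL = 4
    PITCHFORK = 5


# polynomial degrees of the random higher-order terms for each family
_DEGREES = {
    BifurcationClass.PERIOD_DOUBLING: np.arange(4, 11),
    BifurcationClass.FOLD: np.arange(3, 11),
    BifurcationClass.TRANSCRITICAL: np.arange(3, 11),
    BifurcationClass.PITCHFORK: np.arange(4, 11),
}

# Neimark-Sacker mixed monomials x^(i-j) y^j for i = 4..10, j = 0..i
_NS_EXP_X = np.array([i - j for i in range(4, 11) for j in range(i + 1)])
_NS_EXP_Y = np.array([j for i in range(4, 11) for j in range(i + 1)])
N_NS_TERMS = len(_NS_EXP_X)  # 56

# mu0 sampling intervals corresponding to |lambda| < 0.8
_MU0_RANGE = {
    BifurcationClass.PERIOD_DOUBLING: (-1.8, -0.2),
    BifurcationClass.NEIMARK_SACKER: (-1.8, -0.2),
    BifurcationClass.FOLD: (-0.9, -0.1),
    BifurcationClass.TRANSCRITICAL: (-1.8, -0.2),
    BifurcationClass.PITCHFORK: (-1.8, -0.2),
}


class SimulationDiverged(RuntimeError):
    """Raised when a simulation reaches non-finite values (typically
    overflow driven by the degree-10 terms)."""


def rotation_matrix(theta: float) -> np.ndarray:
    """2x2 rotation matrix through angle ``theta`` (radians)."""
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


@dataclass(frozen=True)
class NormalFormModel:
    """One randomly generated training model.

    Attributes
    ----------
    bif_class:
        The (non-null) bifurcation family.
    alpha:
        Coefficients of the higher-order terms.  For the 1-D families
        this is indexed by polynomial degree (see ``degrees``); for
        Neimark-Sacker it holds the x-component coefficients of the 56
        mixed monomials ``x^(i-j) y^j``, ``i = 4..10``, ``j = 0..i``.
    beta:
        y-component coefficients of the mixed monomials
        (Neimark-Sacker only).
    theta:
        Angular frequency at the bifurcation, radians in [0, pi]
        (Neimark-Sacker only).
    cubic_sign:
        Sign of the cubic normal-form term (period-doubling,
        Neimark-Sacker, pitchfork); +-1.
    sigma:
        Additive noise amplitude, >= 0.
    mu0:
        Initial bifurcation parameter, < 0.
    seed:
        Seed of the noise stream used by :func:`simulate`.
    """

    bif_class: BifurcationClass
    alpha: np.ndarray
    sigma: float
    mu0: float
    seed: int
    beta: Optional[np.ndarray] = None
    theta: Optional[float] = None
    cubic_sign: Optional[int] = None

    def __post_init__(self) -> None:
        if self.bif_class == BifurcationClass.NULL:
            raise ValueError("a normal-form model must have a non-null class")
        is_ns = self.bif_class == BifurcationClass.NEIMARK_SACKER
        if is_ns:
            if self.theta is None or self.beta is None:
                raise ValueError("Neimark-Sacker requires theta and beta")
            if len(self.alpha) != N_NS_TERMS or len(self.beta) != N_NS_TERMS:
                raise ValueError("Neimark-Sacker expects 56 mixed-term coefficients")
        else:
            if self.theta is not None or self.beta is not None:
                raise ValueError("theta/beta are defined only for Neimark-Sacker")
            if len(self.alpha) != len(_DEGREES[self.bif_class]):
                raise ValueError("coefficient count does not match the family's degrees")
        lo, hi = _MU0_RANGE[self.bif_class]
        if not (lo <= self.mu0 <= hi):
            raise ValueError(f"mu0={self.mu0} outside the sampling interval [{lo}, {hi}]")

    @property
    def degrees(self) -> np.ndarray:
        """Polynomial degrees matching ``alpha`` (1-D families only)."""
        return _DEGREES[self.bif_class]

    @property
    def ndim(self) -> int:
        return 2 if self.bif_class == BifurcationClass.NEIMARK_SACKER else 1


@dataclass
class Trajectory:
    """A stored simulation: the scalar observable, the per-step value of
    the bifurcation parameter, and bookkeeping on forcing/transition."""

    observable: np.ndarray
    mu_schedule: np.ndarray
    forced: bool
    source_class: BifurcationClass
    transition_index: Optional[int] = None  # index within the recorded run

    def __post_init__(self) -> None:
        if len(self.observable) > MAX_LEN:
            raise ValueError("stored trajectories are at most 500 points long")
        if len(self.observable) != len(self.mu_schedule):
            raise ValueError("observable and mu_schedule must align")


def sample_mu0(bif_class: BifurcationClass, rng_seed=None) -> float:
    """Draw the initial bifurcation parameter uniformly over the values
    with linearised eigenvalue modulus below 0.8: U[-1.8, -0.2] for all
    families except the fold, which uses U[-0.9, -0.1]."""
    if bif_class == BifurcationClass.NULL:
        raise ValueError("mu0 is defined only for bifurcation classes")
    rng = np.random.default_rng(rng_seed)
    lo, hi = _MU0_RANGE[bif_class]
    return float(rng.uniform(lo, hi))


def sample_model(
    bif_class: BifurcationClass,
    rng_seed=None,
    sigma_range: Sequence[float] = SIGMA_RANGE,
) -> NormalFormModel:
    """Draw one random training model of the given family.

    Higher-order coefficients are standard normal, ``theta`` is uniform
    on [0, pi] (Neimark-Sacker only), the cubic sign is +-1 with equal
    probability where the family has one, ``sigma`` is uniform on
    ``sigma_range`` and ``mu0`` comes from :func:`sample_mu0`.
    """
    if bif_class == BifurcationClass.NULL:
        raise ValueError("cannot sample a normal-form model for the null class")
    rng = np.random.default_rng(rng_seed)
    theta = beta = None
    cubic_sign = None
    if bif_class == BifurcationClass.NEIMARK_SACKER:
        alpha = rng.standard_normal(N_NS_TERMS)
        beta = rng.standard_normal(N_NS_TERMS)
        theta = float(rng.uniform(0.0, math.pi))
        cubic_sign = int(rng.choice([-1, 1]))
    else:
        alpha = rng.standard_normal(len(_DEGREES[bif_class]))
        if bif_class in (BifurcationClass.PERIOD_DOUBLING, BifurcationClass.PITCHFORK):
            cubic_sign = int(rng.choice([-1, 1]))
    sigma = float(rng.uniform(*sigma_range))
    lo, hi = _MU0_RANGE[bif_class]
    mu0 = float(rng.uniform(lo, hi))
    seed = int(rng.integers(0, 2**31 - 1))
    return NormalFormModel(
        bif_class=bif_class,
        alpha=np.asarray(alpha, dtype=float),
        beta=None if beta is None else np.asarray(beta, dtype=float),
        theta=theta,
        cubic_sign=cubic_sign,
        sigma=sigma,
        mu0=mu0,
        seed=seed,
    )


def equilibrium(model: NormalFormModel, mu: float) -> np.ndarray:
    """Deterministic equilibrium tracked during forcing: 0 for every
    family except the fold, whose stable branch sits at sqrt(-mu)."""
    if model.bif_class == BifurcationClass.FOLD:
        return np.array([math.sqrt(-mu)])
    return np.zeros(model.ndim)


def step_normal_form(
    model: NormalFormModel,
    state: np.ndarray,
    mu: float,
    noise_draw: np.ndarray,
) -> np.ndarray:
    """One iteration of the model's update rule at parameter ``mu``.

    ``state`` and ``noise_draw`` are 1-vectors (2-vectors for
    Neimark-Sacker).  The higher-order terms of the fold family are
    powers of the displacement from the moving equilibrium,
    ``x - sqrt(-mu)``.
    """
    if mu > 0:
        raise ValueError("the training maps are defined for mu <= 0")
    state = np.atleast_1d(np.asarray(state, dtype=float))
    noise_draw = np.atleast_1d(np.asarray(noise_draw, dtype=float))
    cls = model.bif_class
    if cls == BifurcationClass.NEIMARK_SACKER:
        if state.shape != (2,):
            raise ValueError("Neimark-Sacker state must be a 2-vector")
        x, y = state
        rot = rotation_matrix(model.theta)
        r2 = x * x + y * y
        linear = (1.0 + mu) * (rot @ state)
        cubic = model.cubic_sign * r2 * (rot @ state)
        px = np.power(x, _NS_EXP_X)
        py = np.power(y, _NS_EXP_Y)
        mono = px * py
        higher = np.array([model.alpha @ mono, model.beta @ mono])
        return linear + cubic + higher + model.sigma * noise_draw
    if state.shape != (1,):
        raise ValueError("1-D families take a 1-vector state")
    x = float(state[0])
    degs = _DEGREES[cls]
    if cls == BifurcationClass.PERIOD_DOUBLING:
        core = -(1.0 + mu) * x + model.cubic_sign * x**3
        higher = float(model.alpha @ np.power(x, degs))
    elif cls == BifurcationClass.FOLD:
        core = -mu + x - x * x
        u = x - math.sqrt(-mu)
        higher = float(model.alpha @ np.power(u, degs))
    elif cls == BifurcationClass.TRANSCRITICAL:
        core = (1.0 + mu) * x - x * x
        higher = float(model.alpha @ np.power(x, degs))
    elif cls == BifurcationClass.PITCHFORK:
        core = (1.0 + mu) * x + model.cubic_sign * x**3
        higher = float(model.alpha @ np.power(x, degs))
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(cls)
    return np.array([core + higher + model.sigma * float(noise_draw[0])])


def detect_transition(
    values: np.ndarray,
    equilibrium_path: np.ndarray,
    sigma: float,
) -> Optional[int]:
    """First index at which the deviation from the (moving) equilibrium
    exceeds ten times the noise amplitude, or ``None``.

    For 2-D states the deviation is the component-wise maximum.  With
    ``sigma == 0`` the 10-sigma rule degenerates; an absolute floor of
    ``NOISE_FREE_FLOOR`` is used instead.
    """
    values = np.asarray(values, dtype=float)
    eq = np.asarray(equilibrium_path, dtype=float)
    dev = np.abs(values - eq)
    if dev.ndim == 2:
        dev = dev.max(axis=1)
    threshold = 10.0 * sigma if sigma > 0 else NOISE_FREE_FLOOR
    hits = np.nonzero(dev > threshold)[0]
    return int(hits[0]) if hits.size else None


def simulate(model: NormalFormModel, forced: bool) -> Trajectory:
    """Run one simulation of ``model``.

    100 burn-in iterations at ``mu0`` (noise on, discarded) start from
    the deterministic equilibrium; 600 further iterations are recorded
    with ``mu`` either ramped linearly to reach 0 at the final step
    (forced) or held at ``mu0`` (null).  The stored observable is the
    last 500 recorded points, or the 500 points immediately preceding a
    detected transition.  For the 2-D Neimark-Sacker map only the x
    component is recorded.

    Raises
    ------
    SimulationDiverged
        If the state becomes non-finite (callers typically resample the
        model).
    """
    rng = np.random.default_rng([model.seed, int(forced)])
    ndim = model.ndim
    eps = rng.standard_normal((BURN_IN + N_RECORDED, ndim))
    mu0 = model.mu0
    state = equilibrium(model, mu0).copy()

    for t in range(BURN_IN):
        state = step_normal_form(model, state, mu0, eps[t])
        if not np.all(np.isfinite(state)):
            raise SimulationDiverged("non-finite state during burn-in")

    if forced:
        # mu reaches exactly 0 at the last recorded step
        mu_sched = mu0 * (1.0 - np.arange(1, N_RECORDED + 1) / N_RECORDED)
    else:
        mu_sched = np.full(N_RECORDED, mu0)

    states = np.empty((N_RECORDED, ndim))
    eq_path = np.empty((N_RECORDED, ndim))
    for t in range(N_RECORDED):
        mu = float(mu_sched[t])
        state = step_normal_form(model, state, mu, eps[BURN_IN + t])
        if not np.all(np.isfinite(state)) or np.any(np.abs(state) > 1e12):
            raise SimulationDiverged("non-finite state during recording")
        states[t] = state
        eq_path[t] = equilibrium(model, mu)

    trans = detect_transition(states, eq_path, model.sigma)
    if trans is None:
        lo, hi = N_RECORDED - MAX_LEN, N_RECORDED
    else:
        lo, hi = max(0, trans - MAX_LEN), trans
    return Trajectory(
        observable=states[lo:hi, 0].copy(),
        mu_schedule=mu_sched[lo:hi].copy(),
        forced=forced,
        source_class=model.bif_class,
        transition_index=trans,
    )


@dataclass
class TrainingLibrary:
    """Labelled training set: raw (un-normalised) trajectories with
    class codes, plus a manifest of every model's parameters."""

    series: list[np.ndarray]
    labels: np.ndarray
    manifest: list[dict] = field(default_factory=list)
    n_resampled: int = 0

    def __len__(self) -> int:
        return len(self.series)

    def class_counts(self) -> dict[int, int]:
        codes, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(codes.tolist(), counts.tolist()))


def _model_record(model: NormalFormModel) -> dict:
    return {
        "bif_class": model.bif_class.name,
        "alpha": model.alpha.tolist(),
        "beta": None if model.beta is None else model.beta.tolist(),
        "theta": model.theta,
        "cubic_sign": model.cubic_sign,
        "sigma": model.sigma,
        "mu0": model.mu0,
        "seed": model.seed,
    }


def build_library(
    n_models_per_class: int,
    n_null_kept: int,
    rng_seed=None,
    sigma_range: Sequence[float] = SIGMA_RANGE,
) -> TrainingLibrary:
    """Generate the labelled library: one forced and one null run per
    model, all forced runs kept with their class label, and exactly
    ``n_null_kept`` null runs retained at random with label 0.

    Models whose simulations diverge (overflow from the degree-10
    terms) are resampled with a fresh seed so class counts are exact;
    the number of resamples is recorded on the returned library.
    """
    if n_null_kept > 5 * n_models_per_class:
        raise ValueError("cannot keep more nulls than were simulated")
    rng = np.random.default_rng(rng_seed)
    forced_series: list[np.ndarray] = []
    forced_labels: list[int] = []
    null_series: list[np.ndarray] = []
    manifest: list[dict] = []
    n_resampled = 0

    classes = [c for c in BifurcationClass if c != BifurcationClass.NULL]
    for cls in classes:
        for _ in range(n_models_per_class):
            while True:
                model = sample_model(cls, int(rng.integers(0, 2**31 - 1)), sigma_range)
                try:
                    tf = simulate(model, forced=True)
                    tn = simulate(model, forced=False)
                except SimulationDiverged:
                    n_resampled += 1
                    continue
                break
            forced_series.append(tf.observable)
            forced_labels.append(int(cls))
            null_series.append(tn.observable)
            manifest.append(_model_record(model))

    keep = rng.choice(len(null_series), size=n_null_kept, replace=False)
    series = forced_series + [null_series[i] for i in sorted(keep)]
    labels = np.array(forced_labels + [int(BifurcationClass.NULL)] * n_null_kept)
    return TrainingLibrary(
        series=series, labels=labels, manifest=manifest, n_resampled=n_resampled
    )
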