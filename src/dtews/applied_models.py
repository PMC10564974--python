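"""Five applied discrete-time models used to benchmark the detectors.

Each model is a noisy map with one control parameter that is either
ramped linearly through a known local bifurcation (*forced* runs) or
held fixed far from it (*null* runs):

* ``fox`` — cardiac alternans (action-potential-duration restitution
  with memory); period-doubling as the stimulation period T decreases,
  near T = 200.
* ``westerhoff`` — business cycles from consumer sentiment;
  Neimark-Sacker at autonomous expenditure a = 24.
* ``ricker`` — Ricker population map with sigmoidal harvesting; fold at
  harvesting rate F ~ 2.36.
* ``lotka_volterra`` — discrete predator-prey; transcritical at
  foraging efficiency c = 1 (EWS on the prey).
* ``lorenz`` — reduced discrete Lorenz system; pitchfork at a = 0
  (EWS on x).

``locate_bifurcation`` finds the bifurcation numerically from the
deterministic fixed point's Jacobian eigenvalues, never from the
printed value.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.optimize import brentq, fsolve

from .normal_forms import BifurcationClass, Trajectory

__all__ = [
    "FoxParams",
    "WesterhoffParams",
    "RickerParams",
    "LotkaVolterraParams",
    "LorenzParams",
    "BenchmarkGrid",
    "MODELS",
    "step_test_model",
    "fixed_point",
    "jacobian",
    "locate_bifurcation",
    "make_forced_run",
    "make_null_run",
]

BURN_IN = 100


@dataclass(frozen=True)
class FoxParams:
    """Restitution-with-memory map for cardiac alternans.  State is
    (D action-potential duration, M memory); rest interval I = T - D."""

    A: float = 88.0
    B: float = 122.0
    C: float = 40.0
    D: float = 28.0
    tau: float = 180.0
    alpha: float = 0.2


@dataclass(frozen=True)
class WesterhoffParams:
    """Sentiment-driven national-income map, treated as a 2-D system in
    (Y_{t-2}, Y_{t-1})."""

    b: float = 0.45
    c: float = 0.1
    d: float = 0.2


@dataclass(frozen=True)
class RickerParams:
    """Ricker growth with sigmoidal harvesting; transition threshold on
    the population itself."""

    r: float = 0.75
    k: float = 10.0
    h: float = 0.75
    transition_threshold: float = 0.45


@dataclass(frozen=True)
class LotkaVolterraParams:
    """Discrete predator-prey map; state (prey x, predator y)."""

    r: float = 0.5


@dataclass(frozen=True)
class LorenzParams:
    """Reduced discrete Lorenz map; state (x, y)."""

    h: float = 0.5


@dataclass(frozen=True)
class BenchmarkGrid:
    """Noise-amplitude x series-length grid for one model."""

    noise_amplitudes: tuple[float, ...]
    series_lengths: tuple[int, ...] = (100, 200, 300, 400, 500)
    n_reps: int = 100

    @classmethod
    def for_model(cls, name: str, n_reps: int = 100) -> "BenchmarkGrid":
        base = MODELS[name].base_noise
        return cls(
            noise_amplitudes=tuple(base * 2.0**-k for k in range(5)),
            n_reps=n_reps,
        )


# ---------------------------------------------------------------------------
# single-step maps (noise added to the stated components only)
# ---------------------------------------------------------------------------


def _step_fox(p: FoxParams, state, T, eps):
    D_n, M_n = state
    I_n = T - D_n
    M_next = math.exp(-I_n / p.tau) * (1.0 + (M_n - 1.0) * math.exp(-D_n / p.tau))
    D_next = (1.0 - p.alpha * M_next) * (
        p.A + p.B / (1.0 + math.exp(-(I_n - p.C) / p.D))
    ) + eps[0]
    return np.array([D_next, M_next])


def _step_westerhoff(p: WesterhoffParams, state, a, eps):
    y2, y1 = state  # (Y_{t-2}, Y_{t-1})
    s = 1.0 / (1.0 + math.exp(-(y1 - y2)))
    y = a + (p.b - p.d) * y1 + p.d * y2 + p.c * y1 * s + eps[0]
    return np.array([y1, y])


def _step_ricker(p: RickerParams, state, F, eps):
    x = state[0]
    x_next = x * math.exp(p.r * (1.0 - x / p.k)) - F * x * x / (x * x + p.h * p.h) + eps[0]
    return np.array([x_next])


def _step_lv(p: LotkaVolterraParams, state, c, eps):
    x, y = state
    return np.array(
        [(p.r + 1.0) * x - p.r * x * x - c * x * y + eps[0], c * x * y + eps[1]]
    )


def _step_lorenz(p: LorenzParams, state, a, eps):
    x, y = state
    return np.array(
        [(1.0 + a * p.h) * x - p.h * x * y + eps[0], (1.0 - p.h) * y + p.h * x * x + eps[1]]
    )


@dataclass(frozen=True)
class ModelSpec:
    name: str
    step: Callable
    default_params: object
    bif_class: BifurcationClass
    control_interval: tuple[float, float]  # forced ramp (start, end)
    null_value: float
    base_noise: float
    noise_dims: tuple[int, ...]  # state components receiving noise
    observable: int  # index of the recorded component
    bracket: tuple[float, float]  # control bracket for locate_bifurcation
    init_state: Callable  # params -> initial state at the null control


def _fox_init(p: FoxParams) -> np.ndarray:
    return fixed_point("fox", 300.0, p)


def _westerhoff_init(p: WesterhoffParams, a: float = 10.0) -> np.ndarray:
    ystar = a / (1.0 - p.b - p.c / 2.0)
    return np.array([ystar, ystar])


MODELS: dict[str, ModelSpec] = {
    "fox": ModelSpec(
        name="fox",
        step=_step_fox,
        default_params=FoxParams(),
        bif_class=BifurcationClass.PERIOD_DOUBLING,
        control_interval=(300.0, 150.0),
        null_value=300.0,
        base_noise=0.1,
        noise_dims=(0,),
        observable=0,
        bracket=(160.0, 290.0),
        init_state=_fox_init,
    ),
    "westerhoff": ModelSpec(
        name="westerhoff",
        step=_step_westerhoff,
        default_params=WesterhoffParams(),
        bif_class=BifurcationClass.NEIMARK_SACKER,
        control_interval=(10.0, 27.0),
        null_value=10.0,
        base_noise=0.1,
        noise_dims=(0,),
        observable=1,  # Y_{t-1} slot holds the newest income value
        bracket=(10.0, 27.0),
        init_state=_westerhoff_init,
    ),
    "ricker": ModelSpec(
        name="ricker",
        step=_step_ricker,
        default_params=RickerParams(),
        bif_class=BifurcationClass.FOLD,
        control_interval=(0.0, 3.54),
        null_value=0.0,
        base_noise=0.2,
        noise_dims=(0,),
        observable=0,
        bracket=(0.5, 3.5),
        init_state=lambda p: np.array([p.k]),
    ),
    "lotka_volterra": ModelSpec(
        name="lotka_volterra",
        step=_step_lv,
        default_params=LotkaVolterraParams(),
        bif_class=BifurcationClass.TRANSCRITICAL,
        control_interval=(0.5, 1.25),
        null_value=0.5,
        base_noise=0.01,
        noise_dims=(0, 1),
        observable=0,
        bracket=(0.6, 1.2),
        init_state=lambda p: np.array([1.0, 0.05]),
    ),
    "lorenz": ModelSpec(
        name="lorenz",
        step=_step_lorenz,
        default_params=LorenzParams(),
        bif_class=BifurcationClass.PITCHFORK,
        control_interval=(-1.0, 0.25),
        null_value=-1.0,
        base_noise=0.01,
        noise_dims=(0, 1),
        observable=0,
        bracket=(-0.9, 0.2),
        init_state=lambda p: np.array([0.01, 0.0]),
    ),
}


def step_test_model(model_name: str, params, state, control_value: float, noise_draw):
    """One deterministic-plus-noise iteration of the named model.
    ``noise_draw`` is already scaled by sigma and applies only to the
    components that receive noise."""
    spec = MODELS[model_name]
    eps = np.zeros(max(len(np.atleast_1d(state)), 2))
    nd = np.atleast_1d(noise_draw)
    for i, dim in enumerate(spec.noise_dims):
        eps[dim] = nd[i] if i < len(nd) else 0.0
    nxt = spec.step(params, np.atleast_1d(np.asarray(state, dtype=float)), control_value, eps)
    if not np.all(np.isfinite(nxt)):
        raise FloatingPointError(f"{model_name} produced a non-finite state")
    return nxt


# ---------------------------------------------------------------------------
# deterministic analysis: fixed points, Jacobians, bifurcation location
# ---------------------------------------------------------------------------


def fixed_point(model_name: str, control_value: float, params=None, guess=None) -> np.ndarray:
    """Deterministic fixed point of the map at a given control value."""
    spec = MODELS[model_name]
    params = params or spec.default_params
    if model_name == "lotka_volterra":
        return np.array([1.0, 0.0])  # predator-free equilibrium
    if model_name == "lorenz":
        return np.array([0.0, 0.0])
    if model_name == "westerhoff":
        ystar = control_value / (1.0 - params.b - params.c / 2.0)
        return np.array([ystar, ystar])

    def resid(s):
        return step_test_model(model_name, params, s, control_value, np.zeros(2)) - s

    if guess is None:
        if model_name == "fox":
            guess = np.array([0.7 * control_value, 0.5])
        else:  # ricker upper branch
            guess = np.array([params.k * 0.8])
    sol, info, ier, msg = fsolve(resid, guess, full_output=True)
    if ier != 1 or np.max(np.abs(resid(sol))) > 1e-8:
        raise RuntimeError(f"fixed point not found for {model_name}: {msg}")
    return sol


def jacobian(model_name: str, params, state, control_value: float, h: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian of the deterministic map."""
    state = np.atleast_1d(np.asarray(state, dtype=float))
    n = len(state)
    J = np.empty((n, n))
    for j in range(n):
        dp = state.copy()
        dm = state.copy()
        dp[j] += h
        dm[j] -= h
        fp = step_test_model(model_name, params, dp, control_value, np.zeros(2))
        fm = step_test_model(model_name, params, dm, control_value, np.zeros(2))
        J[:, j] = (fp - fm) / (2.0 * h)
    return J


def _eig_condition(model_name: str, params, control: float, guess=None) -> float:
    """Signed distance of the critical eigenvalue from the unit circle,
    per bifurcation type: crosses zero at the bifurcation."""
    spec = MODELS[model_name]
    fp = fixed_point(model_name, control, params, guess=guess)
    eig = np.linalg.eigvals(jacobian(model_name, params, fp, control))
    cls = spec.bif_class
    if cls == BifurcationClass.PERIOD_DOUBLING:
        real = eig[np.abs(eig.imag) < 1e-8].real
        return float(real.min() + 1.0)  # eigenvalue crossing -1
    if cls == BifurcationClass.NEIMARK_SACKER:
        return float(np.max(np.abs(eig)) - 1.0)  # complex pair modulus 1
    # transcritical / pitchfork: eigenvalue crossing +1
    return float(np.max(eig.real) - 1.0)


_BIF_CACHE: dict[tuple, float] = {}


def locate_bifurcation(model_name: str, params=None, tol: float = 1e-6) -> float:
    """Control value where the bifurcation condition holds.

    Period-doubling: a real Jacobian eigenvalue of the fixed point
    crosses -1.  Neimark-Sacker: the complex pair's modulus crosses 1.
    Transcritical/pitchfork: an eigenvalue crosses +1.  Fold: tangency,
    solved as f(x) = x together with f'(x) = 1.
    """
    spec = MODELS[model_name]
    params = params or spec.default_params
    key = (model_name, params, tol)
    if key in _BIF_CACHE:
        return _BIF_CACHE[key]
    if spec.bif_class == BifurcationClass.FOLD:
        value = _locate_fold(model_name, params)
        _BIF_CACHE[key] = value
        return value

    lo, hi = spec.bracket
    if model_name == "fox":
        # continuation from the high-T side keeps fsolve on the branch
        guesses = {}
        guess = None
        for T in np.linspace(hi, lo, 60):
            guess = fixed_point("fox", T, params, guess=guess)
            guesses[round(float(T), 6)] = guess

        def cond(T):
            near = min(guesses, key=lambda g: abs(g - T))
            return _eig_condition("fox", params, T, guess=guesses[near])

    else:
        def cond(ctrl):
            return _eig_condition(model_name, params, ctrl)

    f_lo, f_hi = cond(lo), cond(hi)
    if f_lo * f_hi > 0:
        raise RuntimeError(
            f"no eigenvalue-condition sign change for {model_name} in {spec.bracket}"
        )
    value = float(brentq(cond, lo, hi, xtol=tol))
    _BIF_CACHE[key] = value
    return value


def _locate_fold(model_name: str, params) -> float:
    spec = MODELS[model_name]

    def system(v):
        x, F = v
        fp = step_test_model(model_name, params, [x], F, np.zeros(2))[0] - x
        J = jacobian(model_name, params, [x], F)[0, 0] - 1.0
        return [fp, J]

    (x0,) = fixed_point(model_name, spec.control_interval[0], params)
    sol, info, ier, msg = fsolve(system, [x0 * 0.5, np.mean(spec.bracket)], full_output=True)
    if ier != 1:
        raise RuntimeError(f"fold tangency not found for {model_name}: {msg}")
    return float(sol[1])


# ---------------------------------------------------------------------------
# forced / null runs
# ---------------------------------------------------------------------------


def _ramp(model_name: str, series_length: int, params) -> tuple[np.ndarray, int]:
    """Control schedule spanning the printed interval, with the step
    increment chosen so the pre-bifurcation segment has approximately
    ``series_length`` points.  Returns (schedule, expected transition
    step index)."""
    spec = MODELS[model_name]
    start, end = spec.control_interval
    bif = locate_bifurcation(model_name, params)
    frac = (bif - start) / (end - start)
    total = int(math.ceil(series_length / frac))
    sched = start + (end - start) * np.arange(1, total + 1) / total
    return sched, series_length


def make_forced_run(
    model_name: str,
    noise_amplitude: float,
    series_length: int,
    rng_seed=None,
    params=None,
) -> Trajectory:
    """One forced run of a grid cell: 100-step burn-in at the ramp's
    start value, then the control ramps linearly over its printed
    interval at a rate giving ~``series_length`` pre-transition points.
    The stored observable is truncated to pre-transition data (control
    crossing the bifurcation, or the population threshold for the
    Ricker model)."""
    spec = MODELS[model_name]
    params = params or spec.default_params
    rng = np.random.default_rng(rng_seed)
    sched, _ = _ramp(model_name, series_length, params)
    bif = locate_bifurcation(model_name, params)
    start = spec.control_interval[0]
    increasing = spec.control_interval[1] > start

    state = np.asarray(spec.init_state(params), dtype=float)
    for _ in range(BURN_IN):
        state = step_test_model(
            model_name, params, state, start,
            noise_amplitude * rng.standard_normal(len(spec.noise_dims)),
        )

    obs = np.empty(len(sched))
    trans: Optional[int] = None
    for t, ctrl in enumerate(sched):
        state = step_test_model(
            model_name, params, state, float(ctrl),
            noise_amplitude * rng.standard_normal(len(spec.noise_dims)),
        )
        obs[t] = state[spec.observable]
        if model_name == "ricker":
            # state-based transition rule; control crossing is a fallback
            if state[0] < params.transition_threshold:
                trans = t
                break
        else:
            crossed = ctrl >= bif if increasing else ctrl <= bif
            if crossed:
                trans = t
                break
    if trans is None:
        crossed = sched >= bif if increasing else sched <= bif
        hits = np.nonzero(crossed)[0]
        trans = int(hits[0]) if hits.size else len(sched)
    lo = max(0, trans - 500)
    return Trajectory(
        observable=obs[lo:trans].copy(),
        mu_schedule=np.asarray(sched[lo:trans], dtype=float),
        forced=True,
        source_class=spec.bif_class,
        transition_index=trans,
    )


def make_null_run(
    model_name: str,
    noise_amplitude: float,
    series_length: int,
    rng_seed=None,
    params=None,
) -> Trajectory:
    """Null run at the model's fixed far-from-bifurcation control value,
    with the same length as the cell's forced runs."""
    spec = MODELS[model_name]
    params = params or spec.default_params
    rng = np.random.default_rng(rng_seed)
    ctrl = spec.null_value
    state = np.asarray(spec.init_state(params), dtype=float)
    for _ in range(BURN_IN):
        state = step_test_model(
            model_name, params, state, ctrl,
            noise_amplitude * rng.standard_normal(len(spec.noise_dims)),
        )
    obs = np.empty(series_length)
    for t in range(series_length):
        state = step_test_model(
            model_name, params, state, ctrl,
            noise_amplitude * rng.standard_normal(len(spec.noise_dims)),
        )
        obs[t] = state[spec.observable]
    return Trajectory(
        observable=obs,
        mu_schedule=np.full(series_length, ctrl),
        forced=False,
        source_class=BifurcationClass.NULL,
        transition_index=None,
    )
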