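"""The two-member CNN-LSTM ensemble: training, prediction, persistence.

Member 1 is trained on *middle*-censored windows and provides an
earlier but less specific warning; member 2 is trained on *end*-censored
windows and is more specific close to the bifurcation.  Reported
predictions are the arithmetic mean of the two members' probability
vectors.

At inference on applied-model or empirical records the ensemble
consumes detrended residuals (the training series, being normal-form
simulations around a known equilibrium, need no detrending).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from .ews import DetrendSpec, detrend
from .nn import CNNLSTM, NetworkConfig
from .normal_forms import BifurcationClass, TrainingLibrary
from .preprocess import CensorScheme, normalize_pad, prepare_training_inputs

__all__ = [
    "ProbabilityVector",
    "TrainedMember",
    "TrainedEnsemble",
    "train_classifier",
    "train_ensemble",
    "predict_along_series",
]


@dataclass
class ProbabilityVector:
    """Six class probabilities indexed by ``BifurcationClass`` code."""

    p: np.ndarray
    flagged_degenerate: bool = False

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (6,):
            raise ValueError("expected 6 class probabilities")
        if np.any(self.p < -1e-9) or abs(self.p.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must be non-negative and sum to 1")

    @property
    def bif_sum(self) -> float:
        """Total probability of any bifurcation (1 - p[null])."""
        return float(1.0 - self.p[int(BifurcationClass.NULL)])

    @property
    def argmax_class(self) -> BifurcationClass:
        return BifurcationClass(int(self.p.argmax()))


@dataclass
class TrainedMember:
    """One trained classifier member plus its censoring scheme."""

    net: CNNLSTM
    scheme: CensorScheme
    metrics: dict

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(X)


@dataclass
class TrainedEnsemble:
    """Average of the middle-censored and end-censored members."""

    member_1: TrainedMember
    member_2: TrainedMember
    manifest: dict

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Mean of the two members' probability vectors; rows sum to 1."""
        return 0.5 * (self.member_1.predict_proba(X) + self.member_2.predict_proba(X))

    # -- persistence --------------------------------------------------
    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, member in [("member_1", self.member_1), ("member_2", self.member_2)]:
            np.savez(outdir / f"{name}.npz", **member.net.parameters())
        manifest = dict(self.manifest)
        manifest["schemes"] = {
            "member_1": self.member_1.scheme.value,
            "member_2": self.member_2.scheme.value,
        }
        manifest["metrics"] = {
            "member_1": _jsonable(self.member_1.metrics),
            "member_2": _jsonable(self.member_2.metrics),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, outdir) -> "TrainedEnsemble":
        outdir = Path(outdir)
        manifest = json.loads((outdir / "manifest.json").read_text())
        cfg = NetworkConfig(**manifest["network_config"])
        members = {}
        for name in ("member_1", "member_2"):
            net = CNNLSTM(cfg, input_len=500)
            with np.load(outdir / f"{name}.npz") as data:
                net.set_parameters({k: data[k] for k in data.files})
            members[name] = TrainedMember(
                net=net,
                scheme=CensorScheme(manifest["schemes"][name]),
                metrics=manifest["metrics"][name],
            )
        return cls(member_1=members["member_1"], member_2=members["member_2"], manifest=manifest)


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            out[k] = v.tolist()
        elif isinstance(v, (np.floating, np.integer)):
            out[k] = v.item()
        else:
            out[k] = v
    return out


def _stratified_split(X, y, split, rng_seed):
    f_train, f_val, f_test = split
    idx = np.arange(len(y))
    train_idx, rest_idx = train_test_split(
        idx, train_size=f_train, stratify=y, random_state=rng_seed
    )
    rel_test = f_test / (f_val + f_test)
    val_idx, test_idx = train_test_split(
        rest_idx, test_size=rel_test, stratify=y[rest_idx], random_state=rng_seed
    )
    return train_idx, val_idx, test_idx


def train_classifier(
    library: TrainingLibrary,
    scheme: CensorScheme,
    config: Optional[NetworkConfig] = None,
    rng_seed=None,
    split_indices: Optional[tuple] = None,
    verbose: bool = False,
) -> TrainedMember:
    """Train one censoring-scheme member on a labelled library.

    The library is censored/normalised once, split into stratified
    train/validation/test partitions per ``config.split``, and trained
    with Adam on sparse categorical cross-entropy.  Held-out metrics
    (accuracy, macro F1, binary F1, per-class recall) are attached to
    the returned member.
    """
    config = config or NetworkConfig()
    rng = np.random.default_rng(rng_seed)
    X, y = prepare_training_inputs(library, scheme, rng_seed=int(rng.integers(2**31)))
    present = np.unique(y)
    if len(present) < 2:
        raise ValueError("library must contain at least two classes")
    if split_indices is None:
        split_indices = _stratified_split(X, y, config.split, int(rng.integers(2**31)))
    tr, va, te = split_indices
    if len(np.unique(y[tr])) < len(present):
        raise ValueError("a class is missing from the training split")

    net = CNNLSTM(config, input_len=X.shape[1], rng_seed=int(rng.integers(2**31)))
    net.fit(
        X[tr],
        y[tr],
        rng_seed=int(rng.integers(2**31)),
        validation=(X[va], y[va]) if len(va) else None,
        verbose=verbose,
    )

    from .evaluation import multiclass_metrics  # local import: avoid cycle

    pred = net.predict_proba(X[te]).argmax(axis=1)
    metrics = multiclass_metrics(pred, y[te])
    metrics["final_train_loss"] = net.history["loss"][-1]
    return TrainedMember(net=net, scheme=CensorScheme(scheme), metrics=metrics)


def train_ensemble(
    library: TrainingLibrary,
    config: Optional[NetworkConfig] = None,
    rng_seed=None,
    verbose: bool = False,
) -> TrainedEnsemble:
    """Train both members on the same stratified split (different
    censoring draws) and return their averaging ensemble."""
    config = config or NetworkConfig()
    rng = np.random.default_rng(rng_seed)
    X0, y = prepare_training_inputs(library, CensorScheme.END, rng_seed=0)
    split = _stratified_split(X0, y, config.split, int(rng.integers(2**31)))
    m1 = train_classifier(
        library, CensorScheme.MIDDLE, config,
        rng_seed=int(rng.integers(2**31)), split_indices=split, verbose=verbose,
    )
    m2 = train_classifier(
        library, CensorScheme.END, config,
        rng_seed=int(rng.integers(2**31)), split_indices=split, verbose=verbose,
    )
    manifest = {
        "network_config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "library_size": len(library),
        "rng_seed": rng_seed if isinstance(rng_seed, int) else None,
    }
    return TrainedEnsemble(member_1=m1, member_2=m2, manifest=manifest)


def predict_along_series(
    ensemble,
    series: np.ndarray,
    eval_fractions: Sequence[float],
    detrend_spec: Optional[DetrendSpec] = None,
    detrend_mode: str = "full",
) -> list[ProbabilityVector]:
    """Ensemble predictions at several points along a (pre-transition)
    record.

    At each fraction ``f`` the first ``floor(f * len)`` points of the
    detrended record are taken (the residuals are what the classifier
    sees on applied/empirical data), normalised by mean absolute value,
    zero-padded to 500 points and classified.

    With ``detrend_mode="full"`` (the reference protocol) the whole
    record is detrended once and prefixes are sliced from its
    residuals; later points influence a prediction only through the
    smooth trend estimate.  ``detrend_mode="prefix"`` re-detrends each
    prefix independently, which is strictly causal but leaves smoother
    edge artefacts at the evaluation point.

    Fractions giving fewer than 2 points are skipped with a warning.  A
    residual segment that is identically zero carries no information
    and yields a flagged null-dominant vector.
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    if detrend_mode not in ("full", "prefix"):
        raise ValueError("detrend_mode must be 'full' or 'prefix'")
    full_resid = None
    if detrend_spec is not None and detrend_mode == "full":
        _, full_resid = detrend(series, detrend_spec)
    out: list[ProbabilityVector] = []
    for f in eval_fractions:
        if not 0 < f <= 1:
            raise ValueError("evaluation fractions must lie in (0, 1]")
        m = int(np.floor(f * n))
        if m < 2:
            warnings.warn(f"fraction {f} gives fewer than 2 points; skipped")
            continue
        if detrend_spec is None:
            seg = series[:m]
        elif full_resid is not None:
            seg = full_resid[:m]
        else:
            _, seg = detrend(series[:m], detrend_spec)
        if np.all(seg == 0):
            p = np.zeros(6)
            p[int(BifurcationClass.NULL)] = 1.0
            out.append(ProbabilityVector(p=p, flagged_degenerate=True))
            continue
        x = normalize_pad(seg).values
        probs = ensemble.predict_proba(x[None, :])[0]
        out.append(ProbabilityVector(p=probs))
    return out
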