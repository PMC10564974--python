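"""Censoring, normalisation and zero-padding of classifier inputs.

Each classifier member sees fixed-length (500-point) inputs.  Training
series are censored so the network learns from records of varying
length and position relative to the bifurcation: the *middle* scheme
(Classifier 1) cuts a random window anywhere in the series, while the
*end* scheme (Classifier 2) always keeps the final points.  Censored
series are normalised by their mean absolute value and prepended with
zeros to 500 points.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

INPUT_LEN = 500
MIN_CENSOR_LEN = 50


class CensorScheme(str, enum.Enum):
    """Which part of a training series the classifier member sees."""

    MIDDLE = "middle"  # Classifier 1: random interior window
    END = "end"        # Classifier 2: window anchored at the series end


@dataclass
class ClassifierInput:
    """A normalised, zero-padded 500-point network input."""

    values: np.ndarray
    n_pad: int
    label: int | None = None

    def __post_init__(self) -> None:
        if len(self.values) != INPUT_LEN:
            raise ValueError("classifier inputs are exactly 500 points")


def censor(series: np.ndarray, scheme: CensorScheme, rng_seed=None) -> np.ndarray:
    """Random censoring window of a (<=500 point) series.

    The window length L is uniform on [50, min(500, len(series))].  For
    the middle scheme the start t0 is uniform on [0, len - L]; for the
    end scheme t0 = len - L.
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    if n < MIN_CENSOR_LEN:
        raise ValueError(f"series shorter than {MIN_CENSOR_LEN} cannot be censored")
    rng = np.random.default_rng(rng_seed)
    length = int(rng.integers(MIN_CENSOR_LEN, min(INPUT_LEN, n) + 1))
    if CensorScheme(scheme) == CensorScheme.MIDDLE:
        t0 = int(rng.integers(0, n - length + 1))
    else:
        t0 = n - length
    return series[t0 : t0 + length]


def normalize_pad(sub_series: np.ndarray, label: int | None = None) -> ClassifierInput:
    """Divide by the mean absolute value and left-pad with zeros to 500.

    Inputs longer than 500 points keep only their most recent 500.
    All-zero input has no defined scale and is rejected.
    """
    x = np.asarray(sub_series, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a univariate series")
    if len(x) > INPUT_LEN:
        x = x[-INPUT_LEN:]
    scale = np.mean(np.abs(x))
    if scale == 0:
        raise ValueError("all-zero series has no mean-absolute-value scale")
    normed = x / scale
    n_pad = INPUT_LEN - len(normed)
    return ClassifierInput(
        values=np.concatenate([np.zeros(n_pad), normed]),
        n_pad=n_pad,
        label=label,
    )


def prepare_training_inputs(
    library,
    scheme: CensorScheme,
    rng_seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Censor + normalise + pad every library entry once.

    Returns ``(X, y)`` with ``X`` of shape ``(n, 500)`` and integer
    labels ``y``.  Each series is censored a single time, fixed at
    library-build time.
    """
    rng = np.random.default_rng(rng_seed)
    xs = []
    for s in library.series:
        sub = censor(s, scheme, rng_seed=int(rng.integers(0, 2**31 - 1)))
        xs.append(normalize_pad(sub).values)
    return np.asarray(xs), np.asarray(library.labels, dtype=int)
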