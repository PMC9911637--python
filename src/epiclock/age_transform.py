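"""Piecewise log-linear age transformation (Horvath's transform).

Chronological age is a poor direct regression target when methylation
changes fast in childhood and slows in adulthood. The canonical remedy maps
age through a function that is logarithmic up to an "adult age" knot and
linear above it:

    F(age) = log((age + 1) / (adult_age + 1))        for age <= adult_age
    F(age) = (age - adult_age) / (adult_age + 1)     for age  > adult_age

F is continuous and strictly increasing, with F(adult_age) = 0. Clocks are
fitted on F(age) and predictions are mapped back to years through the exact
inverse. The transform is optional (``enabled=False`` makes both maps the
identity) because for a narrow adolescent age span the fit is nearly
indifferent to it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TransformSpec", "transform_age", "inverse_transform_age"]


@dataclass(frozen=True)
class TransformSpec:
    adult_age: float = 20.0
    enabled: bool = True

    def __post_init__(self):
        if self.adult_age <= 0:
            raise ValueError("adult_age must be positive")


def transform_age(age, spec: TransformSpec = TransformSpec()):
    """Map age in years to the transformed scale. Accepts scalars or arrays."""
    arr = np.asarray(age, dtype=float)
    if np.any(arr <= -1):
        raise ValueError("age must be > -1 year")
    if not spec.enabled:
        return arr if arr.ndim else float(arr)
    a = spec.adult_age
    out = np.where(
        arr <= a,
        np.log((arr + 1.0) / (a + 1.0)),
        (arr - a) / (a + 1.0),
    )
    return out if out.ndim else float(out)


def inverse_transform_age(t, spec: TransformSpec = TransformSpec()):
    """Exact inverse of :func:`transform_age`."""
    arr = np.asarray(t, dtype=float)
    if not spec.enabled:
        return arr if arr.ndim else float(arr)
    a = spec.adult_age
    out = np.where(
        arr <= 0,
        (a + 1.0) * np.exp(arr) - 1.0,
        a + arr * (a + 1.0),
    )
    return out if out.ndim else float(out)
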