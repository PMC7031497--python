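"""Data normalizations applied to trait vectors before CV estimation.

Four transforms are supported, addressed by the CLI/config names
``raw``, ``log``, ``cuberoot`` and ``minmax``:

* identity (``raw``)
* natural log with an add-1 shift rule: if any value of the vector is
  below 1, 1 is added to *all* values of that vector first (``log``)
* elementwise cube root (``cuberoot``)
* min-max scaling ``(x - x_min) / x_max`` (``minmax``) — note the
  denominator is ``x_max``, not the range; the conventional
  ``(x - x_min)/(x_max - x_min)`` is available behind ``conventional=True``.

Fitting a transform freezes its parameters (shift flag, reference min/max)
into a :class:`TransformSpec` so that the same scaling can be re-applied to
subsamples without re-deriving parameters per draw.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "TransformSpec",
    "TransformError",
    "identity_transform",
    "log_shift_transform",
    "cube_root_transform",
    "min_max_transform",
    "fit_transform",
    "apply_spec",
    "TRANSFORM_NAMES",
]

TRANSFORM_NAMES = ("raw", "log", "cuberoot", "minmax")


class TransformError(ValueError):
    """Raised when a transform is applied outside its domain."""


@dataclass(frozen=True)
class TransformSpec:
    """Frozen parameters of a fitted transform.

    ``shift_applied`` is meaningful for the log transform only;
    ``reference_min``/``reference_max`` for min-max only (taken from the
    vector the transform was fitted on).
    """

    kind: str
    shift_applied: bool = False
    reference_min: Optional[float] = None
    reference_max: Optional[float] = None
    conventional: bool = False


def _asarray(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise TransformError("trait values must be finite")
    return arr


def identity_transform(values) -> tuple[np.ndarray, TransformSpec]:
    """Return the values unchanged with an identity spec."""
    return _asarray(values).copy(), TransformSpec(kind="raw")


def log_shift_transform(values) -> tuple[np.ndarray, TransformSpec]:
    """Natural log with the add-1 shift rule.

    If the minimum of the vector is below 1, 1 is added to all values of
    the vector before taking logs; ``shift_applied`` records this.

    Raises
    ------
    TransformError
        If any value would be non-positive at the point the log is taken.
    """
    arr = _asarray(values)
    shift = bool(arr.size and arr.min() < 1.0)
    shifted = arr + 1.0 if shift else arr
    if np.any(shifted <= 0.0):
        raise TransformError("log domain: non-positive value after shift rule")
    return np.log(shifted), TransformSpec(kind="log", shift_applied=shift)


def cube_root_transform(values) -> tuple[np.ndarray, TransformSpec]:
    """Elementwise cube root (trait domain is non-negative)."""
    arr = _asarray(values)
    return np.cbrt(arr), TransformSpec(kind="cuberoot")


def min_max_transform(
    values, conventional: bool = False
) -> tuple[np.ndarray, TransformSpec]:
    """Min-max scaling ``(x - x_min) / x_max``.

    The default denominator is ``x_max`` (not the range).  Set
    ``conventional=True`` for ``(x - x_min)/(x_max - x_min)``.
    """
    arr = _asarray(values)
    x_min = float(arr.min())
    x_max = float(arr.max())
    denom = (x_max - x_min) if conventional else x_max
    if denom <= 0.0:
        raise TransformError("min-max undefined: denominator <= 0")
    spec = TransformSpec(
        kind="minmax",
        reference_min=x_min,
        reference_max=x_max,
        conventional=conventional,
    )
    return (arr - x_min) / denom, spec


_FITTERS = {
    "raw": identity_transform,
    "log": log_shift_transform,
    "cuberoot": cube_root_transform,
    "minmax": min_max_transform,
}


def fit_transform(name: str, values) -> tuple[np.ndarray, TransformSpec]:
    """Fit and apply the named transform to a vector.

    ``name`` is one of ``raw``, ``log``, ``cuberoot``, ``minmax``.
    """
    try:
        fitter = _FITTERS[name]
    except KeyError:
        raise TransformError(
            f"unknown transform {name!r}; expected one of {TRANSFORM_NAMES}"
        ) from None
    return fitter(values)


def apply_spec(values, spec: TransformSpec) -> np.ndarray:
    """Apply an already-fitted transform without re-deriving parameters."""
    arr = _asarray(values)
    if spec.kind == "raw":
        return arr.copy()
    if spec.kind == "log":
        shifted = arr + 1.0 if spec.shift_applied else arr
        if np.any(shifted <= 0.0):
            raise TransformError("log domain: non-positive value under spec")
        return np.log(shifted)
    if spec.kind == "cuberoot":
        return np.cbrt(arr)
    if spec.kind == "minmax":
        denom = (
            spec.reference_max - spec.reference_min
            if spec.conventional
            else spec.reference_max
        )
        if denom is None or denom <= 0.0:
            raise TransformError("min-max undefined: denominator <= 0")
        return (arr - spec.reference_min) / denom
    raise TransformError(f"unknown transform kind {spec.kind!r}")
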