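"""Sample moments and the eight coefficient-of-variation estimators.

The plug-in estimator ``CV1 = s / x̄`` underestimates the population CV at
small sample sizes.  This module implements CV1 together with seven
bias-reduced alternatives:

``CV2``
    normal-theory correction, ``CV1 * (1 + 1/(4n))``.
``CV3``
    skewness-aware correction,
    ``CV1 / (1 - (CV1/n) * (3*CV1 - 2*g1))`` with ``g1 = m3 / s**3``.
``CV4``
    skewness- and kurtosis-aware correction,
    ``CV1 - CV1**3/n + CV1/(4n) + CV1**2*G1/(2n) + CV1*G2/(8n)`` with the
    Fisher-adjusted sample skewness ``G1`` and excess kurtosis ``G2``.
``CV5``–``CV8``
    arithmetic/geometric composites: ``CV5 = (CV3+CV4)/2``,
    ``CV6 = (CV2+CV4)/2``, ``CV7 = sqrt(CV3*CV4)``, ``CV8 = sqrt(CV2*CV4)``.

Moment conventions
------------------
``sd`` always uses the n-1 (sample) denominator; the corrections in the
source literature are derived for the sample sd.  The shape-moment
conventions inside CV3 and CV4 were fixed operationally by a Monte-Carlo
bias-reduction oracle on gamma populations (shape in {1, 4, 9},
n in {10, 20}; see ``tests/test_acceptance.py``), which also resolved the
algebraic form of both corrections:

* CV3 divides by the bracket (the multiplicative reading makes its bias
  strictly worse than CV1's) and uses ``g1 = m3 / s**3`` — plug-in third
  central moment over the cubed sample sd.  Other skewness conventions
  fail the oracle at shape 4 or 9 with n = 20.
* CV4 subtracts the cubic term and uses the Fisher-adjusted (bias
  corrected) sample skewness and EXCESS kurtosis — the conventions of
  ``pandas.Series.skew()``/``.kurt()`` and R's ``e1071 (type = 2)``.
  Under normality both adjusted γ-terms vanish in expectation, leaving a
  pure CV1/n correction; with raw kurtosis CV4 would overshoot every
  distribution by ``3*CV1/(8n)`` asymptotically, and with unadjusted
  plug-in moments it fails the oracle at shape 1, n 10.

Degenerate samples (sd == 0) yield 0 for every estimator, flagged rather
than raised, so batch pipelines do not abort on constant traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "TraitSample",
    "MomentSet",
    "CVEstimateSet",
    "EstimationError",
    "InsufficientSampleError",
    "NonPositiveMeanError",
    "CorrectionDomainError",
    "compute_moments",
    "cv1",
    "cv2",
    "cv3",
    "cv4",
    "cv_composites",
    "estimate_all",
    "ESTIMATOR_NAMES",
]

ESTIMATOR_NAMES = ("cv1", "cv2", "cv3", "cv4", "cv5", "cv6", "cv7", "cv8")


class EstimationError(ValueError):
    """Base class for CV-estimation domain errors."""


class InsufficientSampleError(EstimationError):
    """Raised when the sample is too small for the requested estimator."""


class NonPositiveMeanError(EstimationError):
    """Raised when the sample mean is not strictly positive."""


class CorrectionDomainError(EstimationError):
    """Raised when a correction factor falls outside its valid domain."""


@dataclass(frozen=True)
class TraitSample:
    """A vector of trait measurements for one species x trait.

    Parameters
    ----------
    values
        Trait measurements.  Must be finite; at least two are required
        for any CV estimation.
    """

    values: np.ndarray

    def __init__(self, values) -> None:
        arr = np.asarray(values, dtype=float).ravel()
        if arr.size < 2:
            raise InsufficientSampleError(
                f"insufficient sample: n={arr.size} < 2"
            )
        if not np.all(np.isfinite(arr)):
            raise EstimationError("trait values must be finite")
        object.__setattr__(self, "values", arr)

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class MomentSet:
    """Mean, sample sd, skewness and excess kurtosis of a trait sample.

    ``skewness`` and ``kurtosis`` are the Fisher-adjusted sample statistics
    (``pandas.Series.skew()``/``.kurt()`` conventions); ``kurtosis`` is on
    the excess scale (normal -> 0) and is NaN for n < 4.  For a degenerate
    (constant) sample both shape moments are reported as 0 and
    ``degenerate`` is set.
    """

    mean: float
    sd: float
    skewness: float
    kurtosis: float
    n: int
    degenerate: bool = False

    @property
    def raw_kurtosis(self) -> float:
        """Kurtosis on the raw Pearson scale (normal -> 3)."""
        return self.kurtosis + 3.0


@dataclass(frozen=True)
class CVEstimateSet:
    """All eight CV estimates plus the moments they were computed from."""

    cv1: float
    cv2: float
    cv3: float
    cv4: float
    cv5: float
    cv6: float
    cv7: float
    cv8: float
    moments: MomentSet
    n: int

    def as_dict(self) -> dict:
        d = {name: getattr(self, name) for name in ESTIMATOR_NAMES}
        d.update(
            n=self.n,
            mean=self.moments.mean,
            sd=self.moments.sd,
            skewness=self.moments.skewness,
            kurtosis=self.moments.kurtosis,
            degenerate=self.moments.degenerate,
        )
        return d


SampleLike = Union[TraitSample, np.ndarray, list, tuple]


def _as_sample(sample: SampleLike) -> TraitSample:
    if isinstance(sample, TraitSample):
        return sample
    return TraitSample(sample)


# ---------------------------------------------------------------------------
# vectorised moment/estimator kernels, shared by the scalar API and the
# resampling engine (which feeds (replicates, k) matrices)
# ---------------------------------------------------------------------------

class _Parts:
    """Row-wise moment quantities along the last axis of ``x``."""

    __slots__ = ("n", "mean", "sd", "g1_ratio", "G1", "G2", "degenerate")

    def __init__(self, x: np.ndarray):
        n = x.shape[-1]
        mean = x.mean(axis=-1)
        d = x - mean[..., None]
        m2 = np.mean(d * d, axis=-1)
        m3 = np.mean(d * d * d, axis=-1)
        m4 = np.mean(d * d * d * d, axis=-1)
        sd = np.sqrt(m2 * n / (n - 1))
        degenerate = sd == 0.0
        safe_sd = np.where(degenerate, 1.0, sd)
        safe_m2 = np.where(degenerate, 1.0, m2)
        with np.errstate(divide="ignore", invalid="ignore"):
            # cv3's convention: plug-in m3 over sample sd cubed
            g1_ratio = np.where(degenerate, 0.0, m3 / safe_sd**3)
            # Fisher-adjusted sample skewness / excess kurtosis
            b1 = m3 / safe_m2**1.5
            if n > 2:
                G1 = np.where(degenerate, 0.0,
                              b1 * np.sqrt(n * (n - 1.0)) / (n - 2))
            else:
                # two points are symmetric about their mean: m3 is 0
                G1 = np.zeros(np.shape(m3))
            if n > 3:
                b2 = m4 / safe_m2**2
                G2 = np.where(
                    degenerate, 0.0,
                    (n - 1.0) / ((n - 2) * (n - 3)) * ((n + 1) * (b2 - 3) + 6),
                )
            else:
                G2 = np.where(degenerate, 0.0, np.full(np.shape(m4), np.nan))
        self.n = n
        self.mean = mean
        self.sd = sd
        self.g1_ratio = g1_ratio
        self.G1 = G1
        self.G2 = G2
        self.degenerate = degenerate


def _cv3_bracket(n, cv1, g1_ratio):
    return 1.0 - (cv1 / n) * (3.0 * cv1 - 2.0 * g1_ratio)


def _cv4_parts(n, cv1, g1, g2):
    """CV4 from pre-computed parts; negative results clamped to 0."""
    out = (
        cv1
        - cv1**3 / n
        + cv1 / (4.0 * n)
        + cv1**2 * g1 / (2.0 * n)
        + cv1 * g2 / (8.0 * n)
    )
    return np.maximum(out, 0.0)


def _base_estimates(p: _Parts, cv1_arr, needed):
    n = p.n
    base = {}
    if "cv1" in needed:
        base["cv1"] = cv1_arr
    if "cv2" in needed:
        base["cv2"] = cv1_arr * (1.0 + 1.0 / (4.0 * n))
    if "cv3" in needed:
        br = _cv3_bracket(n, cv1_arr, p.g1_ratio)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv3_arr = np.where(br > 0.0, cv1_arr / np.where(br > 0, br, 1.0),
                               np.nan)
        base["cv3"] = cv3_arr
    if "cv4" in needed:
        base["cv4"] = _cv4_parts(n, cv1_arr, p.G1, p.G2)
    for name in base:
        base[name] = np.where(p.degenerate, 0.0, base[name])
    return base


_PARENTS = {"cv5": ("cv3", "cv4"), "cv6": ("cv2", "cv4"),
            "cv7": ("cv3", "cv4"), "cv8": ("cv2", "cv4")}


def batch_estimates(x: np.ndarray, estimators=ESTIMATOR_NAMES) -> dict:
    """Compute CV estimators row-wise over a (replicates, k) matrix.

    Degenerate rows (sd == 0) contribute 0 for every estimator.  Rows whose
    mean is non-positive, or where a correction leaves its domain, are NaN;
    callers count and report them.

    Returns a dict mapping estimator name to a 1-D array of estimates.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n < 2:
        raise InsufficientSampleError(f"insufficient sample: n={n} < 2")
    unknown = set(estimators) - set(ESTIMATOR_NAMES)
    if unknown:
        raise KeyError(f"unknown estimator(s): {sorted(unknown)}")
    p = _Parts(x)
    bad_mean = p.mean <= 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        cv1_arr = np.where(bad_mean, np.nan,
                           p.sd / np.where(bad_mean, 1.0, p.mean))
    cv1_arr = np.where(p.degenerate, 0.0, cv1_arr)

    needed = set(estimators)
    for name in estimators:
        if name in _PARENTS:
            needed.update(_PARENTS[name])
    base = _base_estimates(p, cv1_arr, needed)

    out = {}
    for name in estimators:
        if name in base:
            out[name] = base[name]
        elif name in ("cv5", "cv6"):
            a, b = (base[par] for par in _PARENTS[name])
            out[name] = 0.5 * (a + b)
        else:  # cv7, cv8
            a, b = (base[par] for par in _PARENTS[name])
            prod = a * b
            with np.errstate(invalid="ignore"):
                gm = np.sqrt(np.where(prod >= 0.0, prod, np.nan))
            out[name] = np.where(p.degenerate, 0.0, gm)
    return out


# ---------------------------------------------------------------------------
# scalar API
# ---------------------------------------------------------------------------

def compute_moments(sample: SampleLike) -> MomentSet:
    """Compute mean, sample sd, skewness and excess kurtosis of a sample.

    Parameters
    ----------
    sample
        Trait measurements, n >= 2 (n >= 4 recommended for kurtosis,
        which is NaN below that).

    Returns
    -------
    MomentSet
        ``sd`` uses the n-1 denominator; ``skewness``/``kurtosis`` are the
        Fisher-adjusted sample statistics (excess convention).  A constant
        sample gets skewness = kurtosis = 0 and the ``degenerate`` flag.
    """
    s = _as_sample(sample)
    p = _Parts(s.values)
    return MomentSet(
        mean=float(p.mean),
        sd=float(p.sd),
        skewness=float(p.G1),
        kurtosis=float(p.G2),
        n=s.n,
        degenerate=bool(p.degenerate),
    )


def _scalar_parts(sample: SampleLike) -> tuple[TraitSample, _Parts, float]:
    s = _as_sample(sample)
    p = _Parts(s.values)
    if p.degenerate:
        return s, p, 0.0
    if p.mean <= 0.0:
        raise NonPositiveMeanError(
            f"CV undefined for non-positive mean (mean={float(p.mean):g})"
        )
    return s, p, float(p.sd / p.mean)


def cv1(sample: SampleLike) -> float:
    """Plug-in estimator: sample sd over sample mean."""
    _, _, c1 = _scalar_parts(sample)
    return c1


def cv2(sample: SampleLike) -> float:
    """Normal-theory corrected estimator ``cv1 * (1 + 1/(4n))``."""
    s, _, c1 = _scalar_parts(sample)
    return c1 + c1 / (4.0 * s.n)


def cv3(sample: SampleLike) -> float:
    """Skewness-corrected estimator (division form, see module docstring).

    Raises
    ------
    CorrectionDomainError
        If the correction bracket ``1 - (cv1/n)(3 cv1 - 2 g1)`` is <= 0.
    """
    s, p, c1 = _scalar_parts(sample)
    if s.n < 3:
        raise InsufficientSampleError("cv3 requires n >= 3 (skewness)")
    if c1 == 0.0:
        return 0.0
    br = float(_cv3_bracket(s.n, c1, p.g1_ratio))
    if br <= 0.0:
        raise CorrectionDomainError(
            f"correction out of domain: cv3 bracket = {br:g} <= 0"
        )
    return c1 / br


def cv4(sample: SampleLike) -> float:
    """Skewness- and kurtosis-corrected estimator.

    A negative corrected value (possible at tiny n with extreme moments)
    is clamped to 0 with a warning: a CV is non-negative by definition.
    """
    s, p, c1 = _scalar_parts(sample)
    if s.n < 4:
        raise InsufficientSampleError("cv4 requires n >= 4 (kurtosis)")
    if c1 == 0.0:
        return 0.0
    raw = (
        c1
        - c1**3 / s.n
        + c1 / (4.0 * s.n)
        + c1**2 * float(p.G1) / (2.0 * s.n)
        + c1 * float(p.G2) / (8.0 * s.n)
    )
    if raw < 0.0:
        warnings.warn(
            f"cv4 correction produced {raw:g} < 0; clamped to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return raw


def cv_composites(sample: SampleLike) -> tuple[float, float, float, float]:
    """Return (cv5, cv6, cv7, cv8), the arithmetic and geometric composites.

    cv5 = (cv3 + cv4)/2, cv6 = (cv2 + cv4)/2, cv7 = sqrt(cv3*cv4),
    cv8 = sqrt(cv2*cv4).
    """
    c2, c3, c4 = cv2(sample), cv3(sample), cv4(sample)
    if min(c2, c3, c4) < 0.0:
        raise CorrectionDomainError(
            "geometric mean undefined for negative parent"
        )
    return (
        0.5 * (c3 + c4),
        0.5 * (c2 + c4),
        float(np.sqrt(c3 * c4)),
        float(np.sqrt(c2 * c4)),
    )


def estimate_all(sample: SampleLike) -> CVEstimateSet:
    """Compute moments and all eight estimators in one pass.

    Requires n >= 4 (cv4 needs a kurtosis).  Per-estimator domain errors
    propagate with the failing estimator named in the message.
    """
    s = _as_sample(sample)
    if s.n < 4:
        raise InsufficientSampleError(
            f"estimate_all requires n >= 4: cv4 (kurtosis) fails at n={s.n}"
        )
    m = compute_moments(s)
    results = {}
    for name, fn in (("cv1", cv1), ("cv2", cv2), ("cv3", cv3), ("cv4", cv4)):
        try:
            results[name] = fn(s)
        except EstimationError as exc:
            raise type(exc)(f"{name}: {exc}") from exc
    c5, c6, c7, c8 = cv_composites(s)
    return CVEstimateSet(
        cv1=results["cv1"],
        cv2=results["cv2"],
        cv3=results["cv3"],
        cv4=results["cv4"],
        cv5=c5,
        cv6=c6,
        cv7=c7,
        cv8=c8,
        moments=m,
        n=s.n,
    )
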