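"""Contaminated-gamma trait pool simulator.

Each simulated pool mimics the structure of large empirical trait datasets:
a gamma-distributed bulk (strictly positive, right-skewed) plus a small
fraction of extreme large values.  Defaults: 9,520 gamma draws with shape
~ U(1, 10) and scale ~ U(5, 30), plus 480 extremes placed a truncated
exponential (rate 1) above ``mean + 3*sd`` of the base draws, i.e. a 4.8%
contamination fraction in a pool of 10,000.

The pool's reference CV (``cv_true``) is always computed empirically from
the full contaminated pool with the plug-in estimator, because the
contamination changes the population CV away from the analytic gamma value
``1/sqrt(shape)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

from .transforms import TransformSpec, fit_transform

__all__ = [
    "PoolConfig",
    "TraitPool",
    "draw_pool_config",
    "generate_base_pool",
    "add_extremes",
    "generate_pool",
    "generate_pools",
    "pool_true_cv",
    "transform_pool",
]

#: default counts: 9,520 base draws + 480 extremes = 10,000 values (4.8%)
DEFAULT_N_BASE = 9_520
DEFAULT_N_EXTREME = 480

SHAPE_RANGE = (1.0, 10.0)
SCALE_RANGE = (5.0, 30.0)


@dataclass(frozen=True)
class PoolConfig:
    """Parameters of one simulated trait pool.

    Attributes
    ----------
    shape, scale
        Gamma parameters of the base pool.
    n_base, n_extreme
        Counts of gamma draws and appended extreme values.
    rate
        Rate (lambda) of the exponential excess of extreme values over the
        ``mean + 3*sd`` threshold, on the raw trait scale (mean excess
        ``1/rate`` trait units).
    threshold_on
        ``"base"`` (default): the extreme-value threshold is
        ``mean + 3*sd`` of the base draws — the extremes do not exist yet
        when the threshold is formed.  ``"pool"``: post-hoc reading; after
        a provisional placement the threshold is recomputed on the
        contaminated pool and the extremes are re-placed above it (one
        refinement step, same exponential excess draws).
    """

    shape: float
    scale: float
    n_base: int = DEFAULT_N_BASE
    n_extreme: int = DEFAULT_N_EXTREME
    rate: float = 1.0
    threshold_on: str = "base"
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n_base < 2 or self.n_extreme < 0:
            raise ValueError("need n_base >= 2 and n_extreme >= 0")
        if self.shape <= 0 or self.scale <= 0 or self.rate <= 0:
            raise ValueError("shape, scale and rate must be positive")
        if self.threshold_on not in ("base", "pool"):
            raise ValueError("threshold_on must be 'base' or 'pool'")


@dataclass(frozen=True)
class TraitPool:
    """A full population of trait values with its reference CV."""

    values: np.ndarray
    cv_true: float
    config: Union[PoolConfig, str]
    transform: TransformSpec = field(default_factory=lambda: TransformSpec("raw"))

    @property
    def size(self) -> int:
        return int(self.values.size)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def draw_pool_config(rng, **overrides) -> PoolConfig:
    """Draw gamma parameters: shape ~ U(1, 10), scale ~ U(5, 30).

    Keyword overrides are forwarded to :class:`PoolConfig` (e.g. smaller
    ``n_base`` for quick tests).
    """
    rng = _as_rng(rng)
    shape = rng.uniform(*SHAPE_RANGE)
    scale = rng.uniform(*SCALE_RANGE)
    return PoolConfig(shape=shape, scale=scale, **overrides)


def generate_base_pool(config: PoolConfig, rng) -> np.ndarray:
    """Draw ``n_base`` independent gamma(shape, scale) trait values."""
    rng = _as_rng(rng)
    return rng.gamma(config.shape, config.scale, size=config.n_base)


def pool_true_cv(values) -> float:
    """Reference CV of a full pool: plug-in cv1 over all values."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("pool needs at least 2 values")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(arr.std(ddof=1) / mean)


def add_extremes(base: np.ndarray, config: PoolConfig, rng) -> TraitPool:
    """Append extreme large values and assemble the pool.

    The threshold is ``mean(base) + 3*sd(base)``; each extreme equals the
    threshold plus an Exp(rate) draw, so every appended value exceeds the
    threshold and the mean excess is ``1/rate``.  The pool is shuffled so
    positional sampling cannot be biased, and ``cv_true`` is recomputed on
    the full contaminated pool.
    """
    rng = _as_rng(rng)
    base = np.asarray(base, dtype=float)
    if config.n_extreme > 0:
        sd = base.std(ddof=1)
        if sd == 0.0:
            raise ValueError("cannot place extremes on a degenerate base pool")
        threshold = base.mean() + 3.0 * sd
        excess = rng.exponential(1.0 / config.rate, size=config.n_extreme)
        values = np.concatenate([base, threshold + excess])
        if config.threshold_on == "pool":
            threshold = values.mean() + 3.0 * values.std(ddof=1)
            values = np.concatenate([base, threshold + excess])
    else:
        values = base.copy()
    rng.shuffle(values)
    return TraitPool(values=values, cv_true=pool_true_cv(values), config=config)


def generate_pool(config: Optional[PoolConfig] = None, rng=None,
                  **overrides) -> TraitPool:
    """Generate one contaminated pool (config drawn if not given)."""
    rng = _as_rng(rng)
    if config is None:
        config = draw_pool_config(rng, **overrides)
    base = generate_base_pool(config, rng)
    return add_extremes(base, config, rng)


def generate_pools(n_pools: int, rng=None, **overrides) -> list[TraitPool]:
    """Generate ``n_pools`` pools, each with freshly drawn gamma parameters."""
    rng = _as_rng(rng)
    return [generate_pool(rng=rng, **overrides) for _ in range(n_pools)]


def transform_pool(pool: TraitPool, name: str) -> TraitPool:
    """Apply a named normalization to the whole pool.

    The transform is fitted on the entire pool (pool-wide shift / min-max
    parameters frozen into the spec) and ``cv_true`` is recomputed on the
    transformed scale, so resampled estimates and the reference CV live on
    the same scale.
    """
    values, spec = fit_transform(name, pool.values)
    return replace(pool, values=values, cv_true=pool_true_cv(values),
                   transform=spec)
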