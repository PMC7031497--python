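"""Resampling engine for estimator bias and minimum-sample-size search.

For a pool with known reference CV (``cv_true``), ``replicates`` samples of
size ``k`` are drawn with replacement and an estimator is applied to each.
Bias is summarised per estimator and sample size as

* ``B(i, k)  = mean_cv(i, k) - cv_true``
* ``PB(i, k) = B(i, k) / cv_true``  (proportional bias)
* ``TPB(i)   = sum_k |PB(i, k)|``   (headline total; ``sum_k |B(i, k)|``
  is emitted alongside as ``tpb_b``)

and the minimum sample size ``k_min(i)`` is the smallest grid ``k`` at
which ``|PB|`` enters — and by default stays inside — a ±5% accuracy band.

Draws are shared across estimators within a profile (paired comparison),
which removes most Monte-Carlo noise from estimator differences.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .estimators import ESTIMATOR_NAMES, batch_estimates
from .simulation import TraitPool, pool_true_cv, transform_pool

__all__ = [
    "default_grid",
    "coarse_grid",
    "resample_mean_cv",
    "bias_profile",
    "total_bias",
    "min_sample_size",
    "evaluate_matrix",
    "EvaluationResult",
]

logger = logging.getLogger(__name__)

#: default estimator set reported by the sweep (cv7/cv8 behave almost
#: identically to cv5/cv6 and are opt-in)
DEFAULT_ESTIMATORS = ("cv1", "cv2", "cv3", "cv4", "cv5", "cv6")

DEFAULT_REPLICATES = 9_999
DEFAULT_ACCURACY = 0.05

EstimatorSpec = Union[str, Callable[[np.ndarray], np.ndarray]]


def default_grid() -> np.ndarray:
    """Sample sizes 10, 15, 20, ..., 400."""
    return np.arange(10, 401, 5)


def coarse_grid() -> np.ndarray:
    """Sample sizes 10, 20, 30, ..., 1000."""
    return np.arange(10, 1001, 10)


def _pool_values(pool) -> np.ndarray:
    if isinstance(pool, TraitPool):
        return pool.values
    return np.asarray(pool, dtype=float)


def _draw_indices(rng, pool_size, k, replicates, replace):
    if replace:
        return rng.integers(0, pool_size, size=(replicates, k))
    if k > pool_size:
        raise ValueError(f"k={k} exceeds pool size {pool_size} "
                         "for without-replacement sampling")
    keys = rng.random((replicates, pool_size))
    return np.argsort(keys, axis=1)[:, :k]


def _apply_estimators(x, estimators: Sequence[EstimatorSpec]) -> dict:
    names = [e for e in estimators if isinstance(e, str)]
    out = dict(batch_estimates(x, names)) if names else {}
    for e in estimators:
        if not isinstance(e, str):
            out[getattr(e, "__name__", repr(e))] = np.asarray(e(x), dtype=float)
    return out


def _estimator_label(e: EstimatorSpec) -> str:
    return e if isinstance(e, str) else getattr(e, "__name__", repr(e))


def resample_mean_cv(pool, estimator: EstimatorSpec, k: int,
                     replicates: int, rng, replace: bool = True):
    """Mean and standard error of one estimator over resampled draws.

    Parameters
    ----------
    pool
        :class:`~traitcv.simulation.TraitPool` or plain array of values.
    estimator
        Estimator name (``"cv1"`` .. ``"cv8"``) or a callable mapping a
        ``(replicates, k)`` matrix to a vector of estimates.
    replace
        Sample with replacement (default).  With ``replace=False`` and
        ``k`` equal to the pool size every draw is the full pool.

    Returns
    -------
    (mean_cv, se)
    """
    values = _pool_values(pool)
    if replicates < 2:
        raise ValueError("need replicates >= 2")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    idx = _draw_indices(rng, values.size, k, replicates, replace)
    est = _apply_estimators(values[idx], [estimator])[
        _estimator_label(estimator)]
    ok = np.isfinite(est)
    n_err = int((~ok).sum())
    if n_err:
        _check_error_rate(n_err, replicates, _estimator_label(estimator), k)
    good = est[ok]
    return float(good.mean()), float(good.std(ddof=1) / np.sqrt(good.size))


def _check_error_rate(n_err, replicates, label, k):
    if n_err / replicates >= 0.01:
        raise RuntimeError(
            f"estimator {label} failed on {n_err}/{replicates} replicates "
            f"at k={k} (>= 1%); aborting"
        )
    logger.warning("estimator %s: %d/%d domain errors at k=%d (ignored)",
                   label, n_err, replicates, k)


def bias_profile(pool, estimators: Sequence[EstimatorSpec] = DEFAULT_ESTIMATORS,
                 grid=None, replicates: int = DEFAULT_REPLICATES,
                 rng=None, replace: bool = True) -> pd.DataFrame:
    """Bias of each estimator across the sample-size grid for one pool.

    The pool's transform must already be applied (``cv_true`` is read from
    the pool on its current scale).  For each grid ``k`` one index matrix
    is drawn and reused by every estimator, so estimator comparisons are
    paired.

    Returns
    -------
    pandas.DataFrame
        Tidy rows: estimator, k, mean_cv, se, bias, pb, n_errors,
        n_degenerate, replicates, cv_true.
    """
    if isinstance(pool, TraitPool):
        values, cv_true = pool.values, pool.cv_true
    else:
        values = np.asarray(pool, dtype=float)
        cv_true = pool_true_cv(values)
    if cv_true == 0.0:
        raise ValueError("PB undefined: cv_true = 0")
    if replicates < 2:
        raise ValueError("need replicates >= 2")
    grid = default_grid() if grid is None else np.asarray(list(grid), dtype=int)
    if not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    if grid[0] < 4:
        raise ValueError("grid minimum must be >= 4 (cv4 needs a kurtosis)")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng

    rows = []
    for k in grid:
        idx = _draw_indices(rng, values.size, int(k), replicates, replace)
        x = values[idx]
        n_degenerate = int((x.max(axis=1) == x.min(axis=1)).sum())
        ests = _apply_estimators(x, estimators)
        for e in estimators:
            label = _estimator_label(e)
            est = ests[label]
            ok = np.isfinite(est)
            n_err = int((~ok).sum())
            if n_err:
                _check_error_rate(n_err, replicates, label, int(k))
            good = est[ok]
            mean_cv = good.mean()
            se = good.std(ddof=1) / np.sqrt(good.size)
            rows.append({
                "estimator": label,
                "k": int(k),
                "mean_cv": mean_cv,
                "se": se,
                "bias": mean_cv - cv_true,
                "pb": (mean_cv - cv_true) / cv_true,
                "n_errors": n_err,
                "n_degenerate": n_degenerate,
                "replicates": replicates,
                "cv_true": cv_true,
            })
    return pd.DataFrame(rows)


def total_bias(profile: pd.DataFrame) -> pd.DataFrame:
    """Total absolute bias per estimator.

    ``tpb`` sums |PB| across grid sizes (headline, comparable across
    pools); ``tpb_b`` sums |B| on the raw CV scale.
    """
    g = profile.groupby("estimator", sort=False)
    out = g.agg(tpb=("pb", lambda s: s.abs().sum()),
                tpb_b=("bias", lambda s: s.abs().sum()))
    return out.reset_index()


def min_sample_size(profile: pd.DataFrame, accuracy: float = DEFAULT_ACCURACY,
                    rule: str = "sustained") -> pd.DataFrame:
    """Minimum grid sample size reaching the ±``accuracy`` PB band.

    rule
        ``"sustained"`` (default): smallest k with ``|PB| <= accuracy`` at
        k and at every larger tested k.  ``"first"``: first crossing only.

    Rows where the band is never (sustainably) reached get ``k_min = NaN``
    and ``reached = False``.
    """
    if profile.empty:
        raise ValueError("empty bias profile")
    if rule not in ("sustained", "first"):
        raise ValueError("rule must be 'sustained' or 'first'")
    rows = []
    for est, sub in profile.groupby("estimator", sort=False):
        sub = sub.sort_values("k")
        ks = sub["k"].to_numpy()
        ok = np.abs(sub["pb"].to_numpy()) <= accuracy
        if rule == "sustained":
            sustained = np.logical_and.accumulate(ok[::-1])[::-1]
            hit = np.flatnonzero(sustained)
        else:
            hit = np.flatnonzero(ok)
        reached = hit.size > 0
        rows.append({
            "estimator": est,
            "k_min": float(ks[hit[0]]) if reached else np.nan,
            "reached": reached,
            "accuracy": accuracy,
            "grid_max": int(ks[-1]),
        })
    return pd.DataFrame(rows)


@dataclass
class EvaluationResult:
    """Tidy outputs of a full factorial sweep."""

    profiles: pd.DataFrame
    tpb: pd.DataFrame
    kmin: pd.DataFrame


def _group_seed(base_seed, *labels) -> np.random.Generator:
    # stable per-group stream: results do not depend on processing order
    tags = [zlib.crc32(str(lbl).encode()) for lbl in labels]
    return np.random.default_rng([int(base_seed), *tags])


def _iter_pools(source) -> Iterable[tuple[str, str, TraitPool]]:
    if isinstance(source, pd.DataFrame):
        for (species, trait), sub in source.groupby(["species", "trait"]):
            values = np.sort(sub["value"].to_numpy(dtype=float))
            if values.size < 2:
                logger.warning("skipping %s/%s: only %d value(s)",
                               species, trait, values.size)
                continue
            pool = TraitPool(values=values, cv_true=pool_true_cv(values),
                             config="empirical")
            yield str(species), str(trait), pool
    else:
        for i, pool in enumerate(source):
            yield f"pool{i}", "simulated", pool


def evaluate_matrix(source, estimators: Sequence[EstimatorSpec] = DEFAULT_ESTIMATORS,
                    transforms: Sequence[str] = ("raw",),
                    grid=None, replicates: int = DEFAULT_REPLICATES,
                    seed: int = 0, accuracy: float = DEFAULT_ACCURACY,
                    rule: str = "sustained",
                    replace: bool = True) -> EvaluationResult:
    """Full factorial sweep: pools x transforms x estimators x grid.

    Parameters
    ----------
    source
        Either a list of :class:`~traitcv.simulation.TraitPool` or a tidy
        trait table (DataFrame with columns species, trait, value); each
        species x trait group is treated as an empirical pool, its values
        sorted so results are invariant to input row order.
    seed
        Base seed; every (pool, transform) combination gets its own
        deterministic stream derived from it.

    Groups smaller than the smallest grid size are skipped with a logged
    warning; for larger groups the grid is truncated to the group size.
    """
    grid = default_grid() if grid is None else np.asarray(list(grid), dtype=int)
    profiles, tpbs, kmins = [], [], []
    for species, trait, pool in _iter_pools(source):
        for tname in transforms:
            tpool = transform_pool(pool, tname)
            sub_grid = grid[grid <= tpool.size]
            if sub_grid.size == 0:
                logger.warning(
                    "skipping %s/%s (%s): %d values < smallest grid size %d",
                    species, trait, tname, tpool.size, int(grid[0]))
                continue
            rng = _group_seed(seed, species, trait, tname)
            prof = bias_profile(tpool, estimators, sub_grid, replicates,
                                rng, replace=replace)
            meta = {"pool": species, "trait": trait, "transform": tname}
            prof = prof.assign(**meta)
            profiles.append(prof)
            tpbs.append(total_bias(prof).assign(**meta))
            kmins.append(min_sample_size(prof, accuracy, rule).assign(**meta))
    if not profiles:
        raise ValueError("no group was large enough to evaluate")
    lead = ["pool", "trait", "transform"]
    return EvaluationResult(
        profiles=_front(pd.concat(profiles, ignore_index=True), lead),
        tpb=_front(pd.concat(tpbs, ignore_index=True), lead),
        kmin=_front(pd.concat(kmins, ignore_index=True), lead),
    )


def _front(df: pd.DataFrame, lead: list) -> pd.DataFrame:
    return df[lead + [c for c in df.columns if c not in lead]]
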