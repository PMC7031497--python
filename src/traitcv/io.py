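"""Readers, writers and run configuration for the command-line surface.

Trait tables are tidy/long: one row per measured individual with columns
``species``, ``trait``, ``value`` (order-free, case-insensitive header).
Unequal group sizes are expected.  Outputs are plain CSV at full double
precision plus a YAML echo of the resolved run configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

__all__ = ["read_trait_table", "read_pool_csv", "RunConfig",
           "write_reports", "write_pools"]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("species", "trait", "value")


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_trait_table(path) -> pd.DataFrame:
    """Read a tidy trait table (CSV or TSV).

    Header must contain ``species``, ``trait`` and ``value`` in any order
    and case; extra columns are dropped.  Malformed numeric values are
    reported with their 1-based file line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    rename = {c: c.strip().lower() for c in df.columns}
    df = df.rename(columns=rename)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing column: {col}")
    df = df[list(REQUIRED_COLUMNS)].copy()
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = values.isna() & df["value"].notna() | df["value"].isna()
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad][:10]]  # +2: header + 1-based
        raise ValueError(f"non-numeric value(s) at line(s) {lines}")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite trait values")
    df["value"] = values.astype(float)
    sizes = df.groupby(["species", "trait"]).size()
    logger.info("read %d rows, %d species x trait groups (n: %d-%d)",
                len(df), len(sizes), sizes.min(), sizes.max())
    return df


def read_pool_csv(path) -> dict[str, np.ndarray]:
    """Read simulated pools written by ``write_pools`` (pool_id, value)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    df = df.rename(columns={c: c.strip().lower() for c in df.columns})
    for col in ("pool_id", "value"):
        if col not in df.columns:
            raise ValueError(f"missing column: {col}")
    return {str(pid): sub["value"].to_numpy(dtype=float)
            for pid, sub in df.groupby("pool_id")}


@dataclass
class RunConfig:
    """Resolved parameters of one CLI run; round-trips through YAML."""

    command: str
    seed: int = 0
    estimators: list = field(default_factory=lambda: ["cv1", "cv2", "cv3",
                                                      "cv4", "cv5", "cv6"])
    transforms: list = field(default_factory=lambda: ["raw"])
    grid: Optional[list] = None
    replicates: int = 9_999
    accuracy: float = 0.05
    input: Optional[str] = None
    output: Optional[str] = None
    extra: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def write_pools(pools, out: Path, configs=None) -> None:
    """Write pools as tidy CSV (pool_id, value) plus a YAML config echo."""
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    frames = [pd.DataFrame({"pool_id": f"pool{i}", "value": p.values})
              for i, p in enumerate(pools)]
    pd.concat(frames, ignore_index=True).to_csv(out, index=False)
    echo = []
    for i, p in enumerate(pools):
        cfg = p.config
        entry = {"pool_id": f"pool{i}", "cv_true": float(p.cv_true)}
        if not isinstance(cfg, str):
            entry.update(shape=float(cfg.shape), scale=float(cfg.scale),
                         n_base=int(cfg.n_base), n_extreme=int(cfg.n_extreme),
                         rate=float(cfg.rate))
        echo.append(entry)
    with open(out.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(echo, fh, sort_keys=False)


def write_reports(results: dict, out_prefix, config: Optional[RunConfig] = None,
                  round_digits: Optional[int] = None) -> list[Path]:
    """Write a dict of DataFrames as ``<prefix>_<name>.csv`` + JSON summary.

    Numeric formatting is full double precision unless ``round_digits`` is
    given.  Parent directories are created as needed.
    """
    if not results:
        raise ValueError("no results to write")
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    summary = {}
    for name, df in results.items():
        target = prefix.parent / f"{prefix.name}_{name}.csv"
        out_df = df.round(round_digits) if round_digits is not None else df
        out_df.to_csv(target, index=False, float_format="%.17g")
        written.append(target)
        summary[name] = {"path": target.name, "rows": int(len(df))}
    summary_path = prefix.parent / f"{prefix.name}_summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2)
    written.append(summary_path)
    if config is not None:
        cfg_path = prefix.parent / f"{prefix.name}_config.yaml"
        config.to_yaml(cfg_path)
        written.append(cfg_path)
    return written
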