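"""Measurement arithmetic for the field and lab variables.

These are the small, exact computations that turn raw field measurements into
the quantities the hierarchical model consumes: in-vitro digestibility indices,
depth-averaged soil element concentrations, leaf-to-tree herbivory aggregation,
and column standardization with an invertible scaling record.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DigestionPair",
    "n_digestibility",
    "dm_digestibility",
    "depth_average",
    "tree_damage",
    "standardize",
    "ScalingRecord",
    "DAMAGE_EPS",
]

#: Open-interval clamp for proportions entering a beta likelihood.
DAMAGE_EPS = 1e-6


@dataclass(frozen=True)
class DigestionPair:
    """Paired pre-/post-digestion measurements of one foliage sample.

    Parameters
    ----------
    n0, n1 : float
        Nitrogen concentration (fraction of dry matter) before and after the
        in-vitro digestion.
    dm0, dm1 : float
        Dry-matter mass (g) before and after digestion.
    """

    n0: float
    dm0: float
    n1: float
    dm1: float

    def __post_init__(self) -> None:
        if not (self.dm0 > 0):
            raise ValueError("pre-digestion dry matter dm0 must be positive")
        if not (self.n0 > 0):
            raise ValueError("pre-digestion nitrogen n0 must be positive")
        if self.n1 < 0 or self.dm1 < 0:
            raise ValueError("post-digestion quantities must be non-negative")
        if self.dm1 > self.dm0:
            raise ValueError("post-digestion dry matter cannot exceed pre-digestion")


def n_digestibility(pair: DigestionPair) -> float:
    """Nitrogen digestibility index: (N0*DM0 - N1*DM1) / (N0*DM0).

    A high index means a high fraction of the total foliar nitrogen is
    available after digestion (low tannin binding).  Values below zero are
    possible with measurement noise; they are returned as-is with a warning
    rather than silently clipped.
    """
    total = pair.n0 * pair.dm0
    if total == 0:
        raise ZeroDivisionError("undefined digestibility: N0 * DM0 is zero")
    value = (total - pair.n1 * pair.dm1) / total
    if value < 0:
        warnings.warn(
            f"negative N digestibility ({value:.4g}); post-digestion N exceeds "
            "pre-digestion N, check the assay pair",
            stacklevel=2,
        )
    return value


def dm_digestibility(dm0: float, dm1: float) -> float:
    """Dry-matter digestibility: (DM0 - DM1) / DM0."""
    if not (dm0 > 0):
        raise ValueError("dm0 must be positive")
    if dm1 < 0 or dm1 > dm0:
        raise ValueError("dm1 must lie in [0, dm0]")
    return (dm0 - dm1) / dm0


def depth_average(values) -> tuple[float, int]:
    """Mean element concentration across soil sampling depths.

    Parameters
    ----------
    values : sequence of float or NaN
        Concentrations at the sampled depths (e.g. 0-10, 20-30, 50-60 cm);
        missing depths are NaN/None.

    Returns
    -------
    (mean, n_depths)
        Arithmetic mean over the non-missing depths and how many contributed.
    """
    arr = np.asarray(
        [np.nan if v is None else float(v) for v in values], dtype=float
    )
    ok = ~np.isnan(arr)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("all depth values missing; cannot average soil core set")
    return float(arr[ok].mean()), n


def tree_damage(
    leaf_proportions, *, eps: float = DAMAGE_EPS, min_leaves: int = 10
) -> float:
    """Aggregate per-leaf damage proportions to one tree-level value.

    The tree-level herbivory response is the arithmetic mean of its leaves'
    proportional area loss, clamped into the open interval (eps, 1-eps) so a
    beta likelihood stays finite.  A warning is emitted when fewer than
    ``min_leaves`` leaves are available (the field protocol collects 20).
    """
    arr = np.asarray(list(leaf_proportions), dtype=float)
    if arr.size == 0:
        raise ValueError("tree_damage requires at least one leaf")
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("leaf damage proportions must lie in [0, 1]")
    if arr.size < min_leaves:
        warnings.warn(
            f"only {arr.size} leaves for this tree (< {min_leaves}); "
            "tree-level damage estimate may be noisy",
            stacklevel=2,
        )
    return float(np.clip(arr.mean(), eps, 1.0 - eps))


@dataclass
class ScalingRecord:
    """Centering/scaling used to standardize columns; supports exact inversion."""

    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    def transform(self, name: str, values):
        return (np.asarray(values, dtype=float) - self.means[name]) / self.sds[name]

    def inverse(self, name: str, z):
        return np.asarray(z, dtype=float) * self.sds[name] + self.means[name]


def standardize(
    table: pd.DataFrame, columns, *, quadratic: tuple[str, ...] = ()
) -> tuple[pd.DataFrame, ScalingRecord]:
    """Center and scale columns to unit sd; optionally append squared terms.

    Returns a copy of ``table`` with ``z_<col>`` columns appended and, for each
    column listed in ``quadratic``, a ``z_<col>2`` column equal to the square of
    the standardized linear column (squares are taken *after* standardization,
    so quadratic slopes live on a comparable scale).
    """
    out = table.copy()
    rec = ScalingRecord()
    for col in columns:
        vals = np.asarray(out[col], dtype=float)
        sd = float(np.std(vals, ddof=1))
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {col!r} has zero variance; cannot standardize")
        rec.means[col] = float(np.mean(vals))
        rec.sds[col] = sd
        out[f"z_{col}"] = (vals - rec.means[col]) / sd
        if col in quadratic:
            out[f"z_{col}2"] = out[f"z_{col}"] ** 2
    return out, rec
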