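"""Deterministic asymmetry indices for bilateral tract metrics.

The two central quantities are the lateralisation index

    LI = (right - left) / (right + left)

computed per participant on a single bilateral measurement (negative =
left-lateralised, positive = right-lateralised, bounded in [-1, 1]), and the
variability index

    VI = (MAD_right - MAD_left) / (MAD_right + MAD_left)

computed across participants per tract x metric, where MAD is the raw median
absolute deviation from the sample median (no 1.4826 consistency factor; any
common factor cancels in the ratio).  A negative VI means the left hemisphere
is more dispersed across individuals; VI is likewise bounded in [-1, 1].

Cohort data are long-format pandas DataFrames with columns
``participant_id, tract, metric, hemisphere, value`` (``NaN`` value = failed
reconstruction of that tract in that hemisphere; all three metrics of a
failed tract/hemisphere are missing together).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

TRACTS = ("AFl", "AFa", "AFp", "IFOF", "UF", "ILF", "FAT")
METRICS = ("HMOA", "TC", "VC")
HEMISPHERES = ("L", "R")

#: (tract, metric) feature order used everywhere a flat feature axis is needed.
FEATURES = tuple((t, m) for t in TRACTS for m in METRICS)

#: Test family for multiple-comparison correction: 21 tract-level VI tests
#: plus 3 hemisphere-averaged (global) left-vs-right comparisons.
FAMILY_SIZE = 24

COHORT_COLUMNS = ("participant_id", "tract", "metric", "hemisphere", "value")


class UndefinedIndexError(ValueError):
    """Raised when an index has a zero denominator (degenerate input)."""


class SchemaError(ValueError):
    """Raised when a cohort table violates the long-format schema."""


@dataclass(frozen=True)
class ViObservation:
    """Observed variability asymmetry for one tract x metric.

    ``vi = (mad_right - mad_left) / (mad_right + mad_left)`` over the
    participants with both hemispheres present (``n_pairs`` of them).
    """

    tract: str | None
    metric: str | None
    mad_left: float
    mad_right: float
    vi: float
    n_pairs: int


# ---------------------------------------------------------------------------
# Elementary indices
# ---------------------------------------------------------------------------

def compute_li(left: float, right: float) -> float:
    """Lateralisation index of one bilateral pair.

    Antisymmetric under hemisphere swap and invariant to common positive
    scaling.  Raises :class:`UndefinedIndexError` when ``left + right == 0``
    (caller should record the pair as missing).
    """
    if left < 0 or right < 0:
        raise ValueError(f"bilateral values must be non-negative, got ({left}, {right})")
    denom = left + right
    if denom == 0:
        raise UndefinedIndexError("LI undefined: left + right == 0")
    return (right - left) / denom


def compute_mad(values) -> float:
    """Raw median absolute deviation: median(|x_i - median(x)|).

    Even-length medians are the mean of the two central order statistics.
    No consistency constant is applied.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("compute_mad requires at least one value")
    if np.isnan(x).any():
        raise ValueError("compute_mad input contains missing values")
    return float(np.median(np.abs(x - np.median(x))))


def compute_vi(left_values, right_values, *, tract: str | None = None,
               metric: str | None = None) -> ViObservation:
    """Variability index between the two hemispheres' per-participant values.

    Inputs are the paired per-participant values for one tract x metric,
    restricted to participants with both hemispheres present.  Swapping the
    two inputs flips the sign of ``vi`` exactly.
    """
    left = np.asarray(left_values, dtype=float)
    right = np.asarray(right_values, dtype=float)
    if left.size == 0 or right.size == 0:
        raise ValueError("compute_vi requires non-empty hemisphere samples")
    if left.size != right.size:
        raise ValueError("left and right samples must be paired (equal length)")
    mad_l = compute_mad(left)
    mad_r = compute_mad(right)
    denom = mad_l + mad_r
    if denom == 0:
        raise UndefinedIndexError("VI undefined: both hemispheres constant (MAD sum 0)")
    return ViObservation(tract=tract, metric=metric, mad_left=mad_l,
                         mad_right=mad_r, vi=(mad_r - mad_l) / denom,
                         n_pairs=int(left.size))


def success_percentage(n_success: int, n_participants: int) -> float:
    """Percentage of successful tract reconstructions, 100 * k / n."""
    if n_participants <= 0:
        raise ValueError("n_participants must be positive")
    if not 0 <= n_success <= n_participants:
        raise ValueError("n_success must lie in [0, n_participants]")
    return 100.0 * n_success / n_participants


def bonferroni_alpha(family_alpha: float, n_tests: int) -> float:
    """Bonferroni-corrected per-test alpha, family_alpha / n_tests.

    With the default family of 24 tests (21 tract-level + 3 global) and
    family alpha 0.05 this is 0.0020833..., conventionally reported as 0.0021.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < family_alpha <= 1:
        raise ValueError("family_alpha must lie in (0, 1]")
    return family_alpha / n_tests


# ---------------------------------------------------------------------------
# Cohort-level assembly
# ---------------------------------------------------------------------------

def _bilateral_wide(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """participant x tract table of (L, R) value pairs for one metric."""
    sub = table[table["metric"] == metric]
    return sub.pivot_table(index="participant_id", columns=["tract", "hemisphere"],
                           values="value", aggfunc="first", dropna=False)


def hemisphere_average(table: pd.DataFrame, metric: str):
    """Per-participant mean of the 7 tract values in each hemisphere.

    Only participants with all 7 tracts present bilaterally contribute (the
    global left-vs-right variability comparison is computed on these means).
    Returns ``(left, right, participant_ids)`` as aligned arrays.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    wide = _bilateral_wide(table, metric)
    present = [t for t in TRACTS if (t, "L") in wide.columns and (t, "R") in wide.columns]
    cols_l = [(t, "L") for t in present]
    cols_r = [(t, "R") for t in present]
    complete = wide[cols_l + cols_r].notna().all(axis=1)
    wide = wide.loc[complete]
    if wide.empty:
        raise ValueError(f"no participants with complete bilateral data for {metric}")
    left = wide[cols_l].mean(axis=1).to_numpy()
    right = wide[cols_r].mean(axis=1).to_numpy()
    return left, right, list(wide.index)


def assemble_li_matrix(table: pd.DataFrame, exclusion_policy: str = "listwise") -> pd.DataFrame:
    """Participants x (tract, metric) matrix of lateralisation indices.

    One LI is computed per participant x tract x metric where both
    hemispheres are present.  Under the default ``"listwise"`` policy,
    participants with any missing feature are dropped entirely (mirroring a
    whole-participant exclusion for failed reconstructions); under
    ``"per_feature"`` they are retained with missing cells.

    Returns a DataFrame indexed by participant_id with a (tract, metric)
    MultiIndex on the columns, values in [-1, 1] or NaN.
    """
    if exclusion_policy not in ("listwise", "per_feature"):
        raise ValueError(f"unknown exclusion policy {exclusion_policy!r}")
    blocks = {}
    for metric in METRICS:
        wide = _bilateral_wide(table, metric)
        for tract in TRACTS:
            if (tract, "L") not in wide.columns or (tract, "R") not in wide.columns:
                continue
            left = wide[(tract, "L")]
            right = wide[(tract, "R")]
            denom = left + right
            zero_denom = denom.eq(0) & left.notna() & right.notna()
            if zero_denom.any():
                warnings.warn(
                    f"{int(zero_denom.sum())} zero-denominator LI pair(s) for "
                    f"{tract}/{metric} recorded as missing", RuntimeWarning)
            with np.errstate(invalid="ignore", divide="ignore"):
                li = (right - left) / denom
            li[zero_denom] = np.nan
            blocks[(tract, metric)] = li
    mat = pd.DataFrame(blocks)
    mat.columns = pd.MultiIndex.from_tuples(mat.columns, names=["tract", "metric"])
    mat = mat[[f for f in FEATURES if f in mat.columns]]
    mat.index.name = "participant_id"
    if exclusion_policy == "listwise":
        mat = mat.dropna(axis=0, how="any")
    if mat.empty:
        raise ValueError("all participants excluded while assembling the LI matrix")
    return mat


def li_matrix_to_long(li_matrix: pd.DataFrame) -> pd.DataFrame:
    """Tidy long form of an LI matrix: participant_id, tract, metric, li."""
    long = li_matrix.stack(["tract", "metric"], future_stack=True).rename("li").reset_index()
    return long.dropna(subset=["li"]).reset_index(drop=True)


def paired_values(table: pd.DataFrame, tract: str, metric: str):
    """Aligned (left, right) per-participant arrays for one tract x metric.

    Restricted to participants with both hemispheres present.
    """
    wide = _bilateral_wide(table, metric)
    if (tract, "L") not in wide.columns or (tract, "R") not in wide.columns:
        return np.empty(0), np.empty(0)
    sub = wide[[(tract, "L"), (tract, "R")]].dropna()
    return sub[(tract, "L")].to_numpy(), sub[(tract, "R")].to_numpy()
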