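"""Hemisphere-swap permutation inference for the variability index.

The null hypothesis of equal interindividual variability in the two
hemispheres is exchangeability of the (left, right) pair within each
participant.  The null distribution of VI is generated by independently
swapping each participant's left and right values with probability 0.5
(pairing is never broken across participants), recomputing VI for each of
``n_perm`` permutations, and the two-sided p-value is the proportion of
permuted |VI| values greater than or equal to the observed |VI|.

A zero count is reported as p = 1/n_perm with ``p_is_floor=True`` rather
than p = 0; a conservative smoothed estimator (count+1)/(n_perm+1) is
available via ``estimator="smoothed"``.  An exact enumerator over all 2^n
swap patterns serves as the small-n oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .indices import (FAMILY_SIZE, METRICS, TRACTS, UndefinedIndexError,
                      ViObservation, bonferroni_alpha, compute_vi,
                      hemisphere_average, paired_values)

#: Fixed substream index for each test in the 24-test family, keyed by
#: (tract, metric) with tract "ALL" for the hemisphere-averaged comparisons.
#: Derived RNG streams use SeedSequence([master_seed, index]) so results are
#: order-independent and reproducible test by test.
FAMILY_STREAMS = {**{(t, m): i for i, (t, m) in
                     enumerate((t, m) for t in TRACTS for m in METRICS)},
                  **{("ALL", m): 21 + j for j, m in enumerate(METRICS)}}

_CHUNK = 20_000  # permutations per vectorised block (memory bound)


@dataclass(frozen=True)
class ViResult:
    """Permutation-test result for one tract x metric (or global) VI."""

    observation: ViObservation
    n_perm: int
    p_value: float
    p_is_floor: bool
    null_quantiles: dict
    seed: int | None
    alpha: float | None = None
    significant_bonferroni: bool | None = None
    missing: bool = False
    note: str = ""


def _mad_rows(x: np.ndarray) -> np.ndarray:
    """Row-wise raw MAD of a 2-D array."""
    med = np.median(x, axis=1, keepdims=True)
    return np.median(np.abs(x - med), axis=1)


def _vi_rows(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Row-wise VI; degenerate rows (MAD sum 0) are returned as +inf so that
    they count as maximally extreme (conservative)."""
    mad_l = _mad_rows(left)
    mad_r = _mad_rows(right)
    denom = mad_l + mad_r
    with np.errstate(invalid="ignore", divide="ignore"):
        vi = (mad_r - mad_l) / denom
    vi[denom == 0] = np.inf
    return vi


def _swapped(left, right, swap):
    l = np.where(swap, right, left)
    r = np.where(swap, left, right)
    return l, r


def permute_vi_once(paired, rng) -> float:
    """VI of one random hemisphere-swap permutation of ``paired`` (n x 2)."""
    pairs = np.asarray(paired, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("paired must be an (n, 2) array of (left, right) values")
    if pairs.shape[0] < 2:
        raise ValueError("need at least 2 pairs to permute")
    swap = rng.random(pairs.shape[0]) < 0.5
    l, r = _swapped(pairs[:, 0], pairs[:, 1], swap)
    return compute_vi(l, r).vi


def _null_vi(left, right, n_perm, rng):
    out = np.empty(n_perm)
    for start in range(0, n_perm, _CHUNK):
        stop = min(start + _CHUNK, n_perm)
        swap = rng.random((stop - start, left.size)) < 0.5
        l = np.where(swap, right, left)
        r = np.where(swap, left, right)
        out[start:stop] = _vi_rows(l, r)
    return out


def permutation_test_vi(paired, n_perm: int = 100_000, seed: int | None = None,
                        *, rng=None, alpha: float | None = None,
                        estimator: str = "raw", tract: str | None = None,
                        metric: str | None = None) -> ViResult:
    """Monte-Carlo hemisphere-swap permutation test of VI = 0.

    ``paired`` is an (n, 2) array of per-participant (left, right) values.
    The p-value is two-sided on |VI| with ties counted as extreme.  Identical
    ``(paired, seed, n_perm)`` give bit-identical results.
    """
    pairs = np.asarray(paired, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("paired must be an (n, 2) array of (left, right) values")
    if pairs.shape[0] < 2:
        raise ValueError("need at least 2 pairs")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if estimator not in ("raw", "smoothed"):
        raise ValueError(f"unknown estimator {estimator!r}")
    obs = compute_vi(pairs[:, 0], pairs[:, 1], tract=tract, metric=metric)
    if rng is None:
        rng = np.random.default_rng(seed)
    null = _null_vi(pairs[:, 0], pairs[:, 1], n_perm, rng)
    count = int(np.count_nonzero(np.abs(null) >= abs(obs.vi)))
    if estimator == "smoothed":
        p, floor = (count + 1) / (n_perm + 1), False
    elif count == 0:
        p, floor = 1.0 / n_perm, True
    else:
        p, floor = count / n_perm, False
    finite = null[np.isfinite(null)]
    qs = (0.025, 0.25, 0.5, 0.75, 0.975)
    quantiles = {f"q{int(q * 1000):03d}": float(v)
                 for q, v in zip(qs, np.quantile(finite, qs) if finite.size else [np.nan] * 5)}
    return ViResult(observation=obs, n_perm=n_perm, p_value=p, p_is_floor=floor,
                    null_quantiles=quantiles, seed=seed, alpha=alpha,
                    significant_bonferroni=None if alpha is None else bool(p < alpha))


def exact_permutation_vi(paired) -> float:
    """Exact two-sided p-value over all 2^n swap patterns (n <= 16)."""
    pairs = np.asarray(paired, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("paired must be an (n, 2) array of (left, right) values")
    n = pairs.shape[0]
    if n < 1:
        raise ValueError("need at least 1 pair")
    if n > 16:
        raise ValueError("exact enumeration refused for n_pairs > 16")
    try:
        obs = compute_vi(pairs[:, 0], pairs[:, 1]).vi
    except UndefinedIndexError:
        # degenerate observation (e.g. a single pair): every swap pattern is
        # equally degenerate, so the enumeration is all ties and p = 1
        obs = np.inf
    patterns = np.arange(2 ** n)[:, None]
    swap = (patterns >> np.arange(n)[None, :]) & 1 == 1
    l = np.where(swap, pairs[:, 1], pairs[:, 0])
    r = np.where(swap, pairs[:, 0], pairs[:, 1])
    null = _vi_rows(l, r)
    return float(np.count_nonzero(np.abs(null) >= abs(obs)) / 2 ** n)


def vi_family_analysis(table: pd.DataFrame, n_perm: int = 100_000,
                       seed: int = 0, family_alpha: float = 0.05,
                       estimator: str = "raw") -> list[ViResult]:
    """The full 24-test family: 7 tracts x 3 metrics plus 3 global tests.

    The global tests compare hemisphere-averaged (across all 7 tracts)
    per-participant means, one per metric, labelled tract="ALL".  The
    per-test alpha is ``bonferroni_alpha(family_alpha, 24)`` regardless of
    how many tests could actually be run.  Each test draws from its own RNG
    substream SeedSequence([seed, stream_index]) (see FAMILY_STREAMS).
    """
    alpha = bonferroni_alpha(family_alpha, FAMILY_SIZE)
    results = []
    for (tract, metric), stream in FAMILY_STREAMS.items():
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), stream]))
        try:
            if tract == "ALL":
                left, right, _ = hemisphere_average(table, metric)
            else:
                left, right = paired_values(table, tract, metric)
            if left.size < 2:
                raise ValueError(f"fewer than 2 complete pairs for {tract}/{metric}")
            res = permutation_test_vi(np.column_stack([left, right]), n_perm=n_perm,
                                      rng=rng, seed=seed, alpha=alpha,
                                      estimator=estimator, tract=tract, metric=metric)
        except ValueError as exc:
            res = ViResult(observation=ViObservation(tract, metric, np.nan, np.nan,
                                                     np.nan, 0),
                           n_perm=n_perm, p_value=np.nan, p_is_floor=False,
                           null_quantiles={}, seed=seed, alpha=alpha,
                           significant_bonferroni=None, missing=True, note=str(exc))
        results.append(res)
    return results


def vi_results_frame(results: list[ViResult]) -> pd.DataFrame:
    """Tidy table of family-analysis results."""
    rows = []
    for r in results:
        o = r.observation
        rows.append({"tract": o.tract, "metric": o.metric, "mad_left": o.mad_left,
                     "mad_right": o.mad_right, "vi": o.vi, "n_pairs": o.n_pairs,
                     "p_value": r.p_value, "p_is_floor": r.p_is_floor,
                     "n_perm": r.n_perm, "significant_bonferroni": r.significant_bonferroni,
                     "missing": r.missing})
    return pd.DataFrame(rows)
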