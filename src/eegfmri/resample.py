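"""Sensitivity of group consistency to sample size and scan duration.

The t-test significance of EEG-fMRI correlations depends on the number of
subjects, and the correlation estimates themselves on the number of
retained epochs.  Two resampling analyses quantify this: drawing random
subject subsets (without replacement) before recomputing the group
t-statistics, and drawing random windows of consecutive minutes before
recomputing the correlations.  Curves report, per grid point, the mean and
standard error over iterations and over the HRF delay grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["ResamplingCurve", "subsample_subjects", "subsample_duration"]

DEFAULT_ITERATIONS = 5000
FAST_ITERATIONS = 500


@dataclass
class ResamplingCurve:
    """Resampling result: one row per (x, rsn, band) with mean/SE of p and r."""

    table: pd.DataFrame     # x, rsn, band, mean_p, se_p, mean_r, se_r
    x_name: str             # "n_subjects" | "minutes"
    iterations: int
    seed: int


def _aggregate(records: pd.DataFrame, x_name: str, iterations: int,
               seed: int) -> ResamplingCurve:
    """Aggregate per (x, rsn, band): delay-mean within each iteration, then
    mean and standard error over iterations.

    Averaging over the delay grid first makes the SE purely a resampling
    spread: when every draw is the full sample it is exactly zero.
    """
    def se(v):
        v = v.dropna()
        return float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0

    per_iter = (records.groupby([x_name, "rsn", "band", "iteration"])
                .agg(p=("p", "mean"), r=("r", "mean")).reset_index())
    agg = (per_iter.groupby([x_name, "rsn", "band"])
           .agg(mean_p=("p", "mean"), se_p=("p", se),
                mean_r=("r", "mean"), se_r=("r", se))
           .reset_index()
           .sort_values([x_name, "rsn", "band"], ignore_index=True))
    return ResamplingCurve(table=agg, x_name=x_name, iterations=iterations,
                           seed=seed)


def subsample_subjects(avg_correlations: pd.DataFrame, n_grid,
                       iterations: int = DEFAULT_ITERATIONS,
                       seed: int = 0) -> ResamplingCurve:
    """Group statistics under random subject subsets of increasing size.

    For each ``n`` in ``n_grid`` and each iteration, ``n`` subjects are
    drawn without replacement and the one-sample t-test against zero is
    recomputed per (rsn, band, delay) cell on their spatially averaged
    correlations.  ``n = 1`` yields no t-statistic and is reported with
    missing p.  At ``n = N`` every draw is the full set, so each iteration
    reproduces the full-sample statistic exactly.
    """
    subjects = sorted(avg_correlations["subject"].unique())
    n_total = len(subjects)
    n_grid = sorted(set(int(n) for n in n_grid))
    if any(n < 1 or n > n_total for n in n_grid):
        raise ValueError(f"subject grid must lie in [1, {n_total}]")
    rng = np.random.default_rng(seed)

    # Wide matrix: rows = subjects, columns = (rsn, band, delay) cells.
    wide = avg_correlations.pivot_table(
        index="subject", columns=["rsn", "band", "delay"], values="r",
        aggfunc="first")
    cells = wide.columns
    mat = wide.to_numpy(dtype=float)

    records = []
    for n in n_grid:
        for it in range(iterations):
            idx = rng.choice(n_total, size=n, replace=False)
            sub = mat[idx]
            means = np.nanmean(sub, axis=0)
            if n >= 2:
                sd = np.nanstd(sub, axis=0, ddof=1)
                with np.errstate(invalid="ignore", divide="ignore"):
                    t = means / (sd / np.sqrt(n))
                p = 2.0 * sps.t.sf(np.abs(t), n - 1)
            else:
                p = np.full(len(cells), np.nan)
            for c, (rsn, band, delay) in enumerate(cells):
                records.append((n, rsn, band, delay, it, p[c], means[c]))
    rec = pd.DataFrame(records, columns=["n_subjects", "rsn", "band", "delay",
                                         "iteration", "p", "r"])
    return _aggregate(rec, "n_subjects", iterations, seed)


def subsample_duration(subject_bundles: list, minutes_grid,
                       iterations: int = DEFAULT_ITERATIONS,
                       seed: int = 0, tr: float = 2.0) -> ResamplingCurve:
    """Group statistics on random windows of consecutive minutes.

    ``subject_bundles`` holds per-subject dicts with keys ``features``
    (``[n_cell, n_epoch]`` spatially averaged regressors, one row per
    (rsn, band, delay) cell), ``targets`` (``[n_cell, n_epoch]`` matching
    RSN series), ``retain`` (epoch mask) and ``cells`` (the (rsn, band,
    delay) index).  For each duration and iteration a uniformly random
    start is chosen so the window fits, correlations are recomputed on
    retained epochs inside the window, and the group t-test follows.  The
    full-recording window reproduces the full analysis exactly.
    """
    minutes_grid = sorted(set(float(m) for m in minutes_grid))
    n_epoch = min(b["features"].shape[1] for b in subject_bundles)
    max_minutes = n_epoch * tr / 60.0
    if any(m <= 0 or m > max_minutes + 1e-9 for m in minutes_grid):
        raise ValueError(f"window must lie in (0, {max_minutes:.1f}] minutes")
    rng = np.random.default_rng(seed)
    cells = subject_bundles[0]["cells"]

    records = []
    for minutes in minutes_grid:
        w = int(round(minutes * 60.0 / tr))
        for it in range(iterations):
            rs = np.empty((len(subject_bundles), len(cells)))
            for s, b in enumerate(subject_bundles):
                start = int(rng.integers(0, n_epoch - w + 1))
                sl = slice(start, start + w)
                m = b["retain"][sl]
                if m.sum() < 3:
                    rs[s] = np.nan
                    continue
                f = b["features"][:, sl][:, m]
                g = b["targets"][:, sl][:, m]
                # cell-wise correlation between matched rows
                fc = f - f.mean(axis=1, keepdims=True)
                gc = g - g.mean(axis=1, keepdims=True)
                den = np.sqrt((fc**2).sum(axis=1) * (gc**2).sum(axis=1))
                with np.errstate(invalid="ignore", divide="ignore"):
                    rs[s] = (fc * gc).sum(axis=1) / den
            n_eff = np.isfinite(rs).sum(axis=0)
            means = np.nanmean(rs, axis=0)
            sd = np.nanstd(rs, axis=0, ddof=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                t = means / (sd / np.sqrt(n_eff))
            p = 2.0 * sps.t.sf(np.abs(t), np.maximum(n_eff - 1, 1))
            p[n_eff < 2] = np.nan
            for c, (rsn, band, delay) in enumerate(cells):
                records.append((minutes, rsn, band, delay, it, p[c], means[c]))
    rec = pd.DataFrame(records, columns=["minutes", "rsn", "band", "delay",
                                         "iteration", "p", "r"])
    return _aggregate(rec, "minutes", iterations, seed)


def duration_bundle(avg_features: np.ndarray, rsn_ts: np.ndarray,
                    retain: np.ndarray, cells: list) -> dict:
    """Package one subject for :func:`subsample_duration`.

    ``avg_features[c]`` must already be the spatially averaged band-power
    regressor for cell ``c`` and ``rsn_ts[c]`` the matching RSN series.
    """
    if avg_features.shape != rsn_ts.shape:
        raise ValueError("features and targets must share shape [n_cell, n_epoch]")
    return {"features": np.asarray(avg_features, dtype=float),
            "targets": np.asarray(rsn_ts, dtype=float),
            "retain": np.asarray(retain, dtype=bool), "cells": list(cells)}
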