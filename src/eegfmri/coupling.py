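"""Delay-resolved Pearson correlation between RSN BOLD and EEG band power.

For each subject, EEG space, spatial unit (channel or region), RSN,
frequency band, and HRF delay, the Pearson correlation is computed between
the HRF-convolved relative band-power series and the RSN time series over
the retained (unscrubbed, wavelet-valid) epochs.  Reductions follow:
spatial averaging over units, subject averaging per dataset and grand
averaging over all subjects (restricted to the channel-label intersection
in scalp space), pooling of the two EEG spaces, and best-delay selection by
maximum absolute spatially averaged correlation.

The long-format table (subject, space, unit, rsn, band, delay, r, n) is the
pipeline's central exchange format; missing values stay missing (NaN)
through every reduction — they are never zero-filled, which would bias the
averages toward the null.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .features import BandPowerSeries

__all__ = [
    "pearson",
    "row_correlations",
    "correlation_maps",
    "spatial_average",
    "group_average",
    "pool_spaces",
    "best_delay",
]

log = logging.getLogger(__name__)

TENSOR_COLUMNS = ["subject", "space", "unit", "rsn", "band", "delay", "r", "n"]


def pearson(x: np.ndarray, y: np.ndarray,
            retain_mask: np.ndarray | None = None) -> float:
    """Sample Pearson correlation over retained samples.

    Requires at least 3 retained samples and non-constant retained vectors;
    a constant vector makes the correlation undefined and returns NaN
    (reported missing, never coerced to 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must have the same length")
    if retain_mask is not None:
        m = np.asarray(retain_mask, dtype=bool)
        x, y = x[m], y[m]
    if len(x) < 3:
        raise ValueError("need >= 3 retained samples")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.clip((xc * yc).sum() / (sx * sy), -1.0, 1.0))


def row_correlations(features: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """All-pairs Pearson correlations between rows of two matrices.

    ``features`` is ``[m, t]``, ``targets`` ``[k, t]``; returns ``[m, k]``.
    Rows with zero variance produce NaN in their pairs.
    """
    f = np.asarray(features, dtype=float)
    g = np.asarray(targets, dtype=float)
    fc = f - f.mean(axis=1, keepdims=True)
    gc = g - g.mean(axis=1, keepdims=True)
    fn = np.sqrt((fc**2).sum(axis=1))
    gn = np.sqrt((gc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (fc @ gc.T) / np.outer(fn, gn)
    r[~np.isfinite(r)] = np.nan
    return np.clip(r, -1.0, 1.0)


def correlation_maps(subject_features: dict, rsn_ts: np.ndarray,
                     retain: np.ndarray, rsn_labels, subject: str = "sub-01",
                     ) -> pd.DataFrame:
    """Correlation tensor of one subject as a long-format DataFrame.

    ``subject_features`` is the :func:`eegfmri.features.extract_features`
    output ``{space: {delay: BandPowerSeries}}``; ``rsn_ts`` is
    ``[n_rsn, n_vol]`` on the same volume grid; ``retain`` is the joint
    scrub mask over epochs.  Feature-validity flags and the scrub mask are
    combined into a single retention mask applied pairwise-complete to every
    correlation.  Subjects with fewer than 3 retained epochs are rejected.
    """
    retain = np.asarray(retain, dtype=bool)
    rows = []
    for space, per_delay in subject_features.items():
        for delay, bp in per_delay.items():
            n_epoch = min(bp.n_epoch, rsn_ts.shape[1], len(retain))
            mask = retain[:n_epoch] & bp.valid[:n_epoch]
            n_ret = int(mask.sum())
            if n_ret < 3:
                raise ValueError(
                    f"subject {subject}: only {n_ret} retained epochs; skipped")
            vals = bp.values[:n_epoch][mask]            # [n_ret, unit, band]
            flat = vals.reshape(n_ret, -1).T            # [unit*band, n_ret]
            r = row_correlations(flat, rsn_ts[:, :n_epoch][:, mask])
            r = r.reshape(len(bp.unit_labels), len(bp.band_names), -1)
            for u, unit in enumerate(bp.unit_labels):
                for b, band in enumerate(bp.band_names):
                    for k, rsn in enumerate(rsn_labels):
                        rows.append((subject, space, unit, rsn, band,
                                     float(delay), r[u, b, k], n_ret))
    return pd.DataFrame(rows, columns=TENSOR_COLUMNS)


def spatial_average(tensor: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean of r over units per (subject, space, rsn, band, delay).

    Missing units are excluded from the mean; a cell with no non-missing
    unit stays missing.
    """
    grouped = (tensor.groupby(["subject", "space", "rsn", "band", "delay"],
                              sort=False)
               .agg(r=("r", "mean"), n=("n", "min"))
               .reset_index())
    return grouped


def group_average(avg: pd.DataFrame, dataset_of: dict | None = None,
                  tensor: pd.DataFrame | None = None,
                  ) -> dict[str, pd.DataFrame]:
    """Per-dataset and grand-average reductions over subjects.

    ``avg`` is a spatially averaged table (one row per subject x space x
    rsn x band x delay); ``dataset_of`` maps subject id to dataset name.
    If the unit-level ``tensor`` is supplied, unit-level averaged maps are
    also produced, with scalp maps restricted to the channel labels common
    to all datasets (the label intersection is computed and reported).
    Subjects are weighted equally regardless of dataset size.
    """
    if dataset_of is None:
        dataset_of = {s: "all" for s in avg["subject"].unique()}
    out: dict[str, pd.DataFrame] = {}
    keys = ["space", "rsn", "band", "delay"]
    with_ds = avg.assign(dataset=avg["subject"].map(dataset_of))
    per_ds = (with_ds.groupby(["dataset"] + keys, sort=False)["r"]
              .mean().reset_index())
    out["per_dataset"] = per_ds
    out["grand"] = avg.groupby(keys, sort=False)["r"].mean().reset_index()
    if tensor is not None:
        t = tensor.assign(dataset=tensor["subject"].map(dataset_of))
        scalp = t[t["space"] == "scalp"]
        if len(scalp):
            label_sets = [set(g["unit"]) for _, g in scalp.groupby("dataset")]
            common = set.intersection(*label_sets)
            if not common:
                raise ValueError("empty channel-label intersection across datasets")
            log.info("scalp grand average over %d common channels", len(common))
            t = t[(t["space"] != "scalp") | t["unit"].isin(common)]
            out["common_channels"] = sorted(common)
        out["grand_maps"] = (t.groupby(["space", "unit", "rsn", "band", "delay"],
                                       sort=False)["r"].mean().reset_index())
    return out


def pool_spaces(avg: pd.DataFrame) -> pd.DataFrame:
    """Average the scalp and source spatially averaged values per cell.

    A cell missing either space yields a missing pooled value (never a
    silent single-space value).  Output rows carry ``space == "pooled"``.
    """
    pivot = avg.pivot_table(index=["subject", "rsn", "band", "delay"],
                            columns="space", values="r", aggfunc="first",
                            dropna=False)
    for needed in ("scalp", "source"):
        if needed not in pivot.columns:
            pivot[needed] = np.nan
    pooled = (pivot["scalp"] + pivot["source"]) / 2.0
    out = pooled.reset_index().rename(columns={0: "r"})
    out.columns = ["subject", "rsn", "band", "delay", "r"]
    out.insert(1, "space", "pooled")
    return out


def best_delay(avg: pd.DataFrame, rsn: str, band: str,
               space: str | None = None) -> float:
    """Delay maximizing the absolute spatially averaged correlation.

    Ties go to the smallest delay (logged).  Returns NaN when every delay is
    missing for the requested cell.
    """
    sel = avg[(avg["rsn"] == rsn) & (avg["band"] == band)]
    if space is not None:
        sel = sel[sel["space"] == space]
    sel = sel.groupby("delay")["r"].mean().dropna()
    if sel.empty:
        return float("nan")
    mags = sel.abs()
    best = mags.max()
    winners = sorted(mags[mags == best].index)
    if len(winners) > 1:
        log.info("best-delay tie for (%s, %s): %s -> %s", rsn, band,
                 winners, winners[0])
    return float(winners[0])
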