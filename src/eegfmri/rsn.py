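"""RSN identification: Dice template matching and stage-1 spatial regression.

Group independent-component (IC) maps are matched to canonical resting-state
network templates by thresholding the IC statistical maps at Z = 3,
binarizing, and assigning each template the IC with the highest Dice
overlap.  Subject RSN time series are then obtained by regressing the group
spatial maps into each volume of the subject's data (the first stage of
dual regression).  Group ICA itself is consumed, not computed.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

__all__ = ["dice", "match_ics_to_templates", "extract_rsn_timeseries"]

log = logging.getLogger(__name__)

#: Z threshold applied to IC statistical maps before binarizing.
IC_Z_THRESHOLD = 3.0


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice coefficient ``2|A∩B| / (|A| + |B|)`` of two binary masks.

    Defined as 0 when both masks are empty.
    """
    a = np.asarray(mask_a, dtype=bool).ravel()
    b = np.asarray(mask_b, dtype=bool).ravel()
    if a.shape != b.shape:
        raise ValueError(f"mask length mismatch: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * (a & b).sum() / denom)


def match_ics_to_templates(ic_maps: np.ndarray, templates: np.ndarray,
                           z_thresh: float = IC_Z_THRESHOLD) -> list[dict]:
    """Assign each RSN template the argmax-Dice IC.

    ``ic_maps`` is ``[n_ic, n_vox]`` of z-scored statistics, thresholded at
    ``z_thresh`` and binarized; ``templates`` is ``[n_template, n_vox]`` of
    binary masks.  ICs may serve several templates (per-template argmax).
    Ties are broken by the lowest IC index and logged.  Returns one dict per
    template: ``{"template", "ic", "dice"}``.
    """
    ics = np.atleast_2d(np.asarray(ic_maps, dtype=float))
    tmpl = np.atleast_2d(np.asarray(templates)).astype(bool)
    if ics.shape[1] != tmpl.shape[1]:
        raise ValueError("IC maps and templates must share the voxel grid")
    bin_ics = ics > z_thresh
    if not bin_ics.any():
        warnings.warn("all IC maps empty after thresholding; zero Dice scores")
    out = []
    for t in range(tmpl.shape[0]):
        scores = np.array([dice(bin_ics[i], tmpl[t]) for i in range(ics.shape[0])])
        best = int(np.argmax(scores))  # argmax returns the first (lowest) index
        if (scores == scores[best]).sum() > 1:
            log.info("template %d: Dice tie broken toward IC %d", t, best)
        out.append({"template": t, "ic": best, "dice": float(scores[best])})
    return out


def extract_rsn_timeseries(data: np.ndarray, group_maps: np.ndarray) -> np.ndarray:
    """Stage-1 dual regression: per-volume OLS of voxel data on spatial maps.

    ``data`` is ``[n_vox, n_vol]``; ``group_maps`` is ``[n_vox, K]``.  Each
    volume's voxel vector is regressed on the K maps plus an intercept; the
    K map coefficients form the subject's RSN time series ``[K, n_vol]``.
    Maps are not demeaned (the intercept column absorbs the mean).
    """
    data = np.asarray(data, dtype=float)
    maps = np.asarray(group_maps, dtype=float)
    if maps.ndim != 2 or data.shape[0] != maps.shape[0]:
        raise ValueError("data and maps must share the voxel dimension")
    n_vox, k = maps.shape
    if k >= n_vox:
        raise ValueError("need more voxels than maps")
    design = np.column_stack([np.ones(n_vox), maps])
    rank = np.linalg.matrix_rank(design)
    if rank < k + 1:
        # identify offending maps by leave-one-out rank
        bad = [j for j in range(k)
               if np.linalg.matrix_rank(np.delete(design, j + 1, axis=1)) == rank]
        raise ValueError(f"rank-deficient spatial maps (collinear): columns {bad}")
    coef, *_ = np.linalg.lstsq(design, data, rcond=None)
    return coef[1:]
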