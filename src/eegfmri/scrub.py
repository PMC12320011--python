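"""Joint motion scrubbing of EEG epochs and fMRI volumes.

Motion-contaminated segments are flagged independently in each modality —
fMRI volumes by DVARS outliers, EEG epochs by a 4-standard-deviation
amplitude rule — and their union is excluded just before the EEG features
are correlated with the fMRI network time series.  Band-power estimation
and HRF convolution always run on the continuous recordings first, so the
time-frequency analysis never sees artificial discontinuities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScrubMask",
    "dvars",
    "flag_dvars_outliers",
    "flag_eeg_epochs",
    "joint_mask",
]

#: EEG amplitude rule: flag epochs exceeding the channel mean by this many SD.
EEG_SD_THRESHOLD = 4.0
#: DVARS rule: flag transitions above Q3 + this multiple of the IQR.
DVARS_IQR_FACTOR = 1.5


@dataclass
class ScrubMask:
    """Per-TR-epoch retention mask with per-modality provenance."""

    retain: np.ndarray
    eeg_flags: np.ndarray
    fmri_flags: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def n_discarded(self) -> int:
        return int((~self.retain).sum())

    def summary(self) -> dict:
        """Discarded-epoch accounting: total and per modality."""
        return {
            "n_epochs": int(len(self.retain)),
            "discarded_total": self.n_discarded,
            "discarded_eeg": int(self.eeg_flags.sum()),
            "discarded_fmri": int(self.fmri_flags.sum()),
        }


def dvars(voxel_matrix: np.ndarray) -> np.ndarray:
    """DVARS of a voxels-by-volumes matrix.

    Entry ``i`` is the root-mean-square over voxels of the intensity
    difference between volumes ``i+1`` and ``i``, normalized by the median
    of all intensities and multiplied by 1000.  For synthetic data without
    voxel volumes, the RSN-by-time matrix serves as the voxel proxy.
    """
    v = np.asarray(voxel_matrix, dtype=float)
    if v.ndim != 2 or v.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least two volumes")
    med = np.median(v)
    if med == 0:
        raise ValueError("median intensity is zero; DVARS undefined")
    diff = np.diff(v, axis=1)
    return np.sqrt((diff**2).mean(axis=0)) / med * 1000.0


def flag_dvars_outliers(dvars_vector: np.ndarray) -> np.ndarray:
    """Flag fMRI volumes whose incoming transition exceeds Q3 + 1.5 IQR.

    Quartiles use linear interpolation (numpy's default, R type 7).  The
    flagged volume is volume ``i+1`` of the offending transition; the first
    volume is never flagged by this rule.  Returns a boolean vector of
    length ``n_vol = len(dvars_vector) + 1``.
    """
    d = np.asarray(dvars_vector, dtype=float)
    if len(d) < 3:
        raise ValueError("need at least 4 volumes (3 transitions)")
    q1, q3 = np.percentile(d, [25, 75])
    thresh = q3 + DVARS_IQR_FACTOR * (q3 - q1)
    flags = np.zeros(len(d) + 1, dtype=bool)
    flags[1:] = d > thresh
    return flags


def flag_eeg_epochs(eeg: np.ndarray, fs: float, tr: float,
                    sd_threshold: float = EEG_SD_THRESHOLD) -> np.ndarray:
    """Flag TR epochs where any channel strays >= ``sd_threshold`` SD from its mean.

    Channel mean and SD are computed over the whole recording.  Zero-variance
    channels are excluded from the rule with a warning.  This automatic rule
    replaces interactive visual confirmation of the pre-selected epochs.
    """
    eeg = np.atleast_2d(np.asarray(eeg, dtype=float))
    spe = int(round(tr * fs))
    n_epoch = eeg.shape[1] // spe
    if n_epoch < 1:
        raise ValueError("recording shorter than one TR epoch")
    mean = eeg.mean(axis=1, keepdims=True)
    sd = eeg.std(axis=1, ddof=0, keepdims=True)
    ok = sd[:, 0] > 0
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} zero-variance channel(s) excluded "
                      "from the EEG amplitude rule")
    z = np.zeros_like(eeg)
    z[ok] = np.abs(eeg[ok] - mean[ok]) / sd[ok]
    flags = np.zeros(n_epoch, dtype=bool)
    for e in range(n_epoch):
        flags[e] = bool((z[:, e * spe:(e + 1) * spe] >= sd_threshold).any())
    return flags


def joint_mask(eeg_flags: np.ndarray, fmri_flags: np.ndarray,
               provenance: dict | None = None) -> ScrubMask:
    """Union of the per-modality flags; retained = neither flagged."""
    eeg_flags = np.asarray(eeg_flags, dtype=bool)
    fmri_flags = np.asarray(fmri_flags, dtype=bool)
    if eeg_flags.shape != fmri_flags.shape:
        raise ValueError(
            f"flag length mismatch: EEG {eeg_flags.shape} vs fMRI {fmri_flags.shape}")
    prov = {"eeg_rule": f">= {EEG_SD_THRESHOLD} SD from channel mean",
            "fmri_rule": f"DVARS > Q3 + {DVARS_IQR_FACTOR} IQR"}
    if provenance:
        prov.update(provenance)
    return ScrubMask(retain=~(eeg_flags | fmri_flags),
                     eeg_flags=eeg_flags, fmri_flags=fmri_flags,
                     provenance=prov)


def subject_mask(eeg: np.ndarray, fmri_matrix: np.ndarray, fs: float,
                 tr: float) -> ScrubMask:
    """Full scrubbing stage for one subject, aligned on the common epoch grid."""
    eeg_flags = flag_eeg_epochs(eeg, fs, tr)
    fmri_flags = flag_dvars_outliers(dvars(fmri_matrix))
    n = min(len(eeg_flags), len(fmri_flags))
    return joint_mask(eeg_flags[:n], fmri_flags[:n])
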