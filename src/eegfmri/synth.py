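"""Synthetic coupled EEG-fMRI groups with known ground-truth coupling.

The generator emulates the minimal structure the correlation analysis
assumes: slow network-level neural fluctuations drive (a) the BOLD signal
of each resting-state network (RSN) through a delayed hemodynamic response
and (b) the band-limited EEG amplitude of the cortical regions belonging to
that network, with a signed coupling coefficient per (RSN, band) pair.
Scalp channels are linear mixtures of the source regions.  Motion is
injected as additive high-amplitude epochs in either modality.  Everything
is deterministic given the seed, so downstream stages can be validated by
recovering the planted coupling signs, the true hemodynamic delay, and the
injected motion epochs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .features import BandDef, DEFAULT_BANDS
from .hrf import HRFKernel, HRFParams, hrf_kernel, scaled_params

__all__ = [
    "GroundTruth",
    "SyntheticSubject",
    "GroupConfig",
    "simulate_neural_rsn",
    "simulate_eeg",
    "simulate_bold",
    "inject_motion",
    "simulate_subject",
    "generate_group",
]

#: Internal sampling step of the neural drivers, seconds.
NEURAL_DT_S = 0.1

#: Names of the seven canonical RSNs used for labeling.
RSN_NAMES = ("VN", "SMN", "DAN", "VAN", "LN", "FPN", "DMN")


@dataclass
class GroundTruth:
    """Planted generative parameters of one synthetic subject or group."""

    coupling: np.ndarray            # [n_rsn, n_band], signed, |.| <= 1
    true_delay: float               # HRF overshoot delay, s
    region_assignment: dict         # region label -> RSN index
    eeg_noise_sd: float
    bold_noise_sd: float
    seed: int
    motion_epochs: list = field(default_factory=list)  # (modality, epoch)

    def __post_init__(self) -> None:
        self.coupling = np.asarray(self.coupling, dtype=float)
        if np.any(np.abs(self.coupling) > 1):
            raise ValueError("coupling magnitudes must be <= 1")
        if self.true_delay < 0:
            raise ValueError("true_delay must be >= 0")


@dataclass
class SyntheticSubject:
    """One simulated subject: scalp + source EEG and RSN BOLD series."""

    eeg_scalp: np.ndarray           # [n_chan, n_samp] at fs
    eeg_source: np.ndarray          # [n_region, n_samp] at fs
    rsn_bold: np.ndarray            # [n_rsn, n_vol] at TR
    chan_labels: list
    region_labels: list
    rsn_labels: list
    fs: float
    tr: float
    truth: GroundTruth

    def __post_init__(self) -> None:
        for labels in (self.chan_labels, self.region_labels, self.rsn_labels):
            if len(set(labels)) != len(labels):
                raise ValueError("labels must be unique")
        n_samp = self.eeg_scalp.shape[1]
        if abs(n_samp / self.fs - self.rsn_bold.shape[1] * self.tr) > self.tr:
            raise ValueError("EEG and fMRI durations disagree by more than one TR")
        for arr in (self.eeg_scalp, self.eeg_source, self.rsn_bold):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite values in synthetic signals")


def simulate_neural_rsn(n_rsn: int, duration_s: float, dt_s: float = NEURAL_DT_S,
                        band_lo_hz: float = 0.01, band_hi_hz: float = 0.1,
                        seed: int = 0) -> np.ndarray:
    """Band-limited Gaussian neural drivers, one row per RSN.

    White Gaussian noise is restricted to ``[band_lo, band_hi]`` in the
    Fourier domain (the typical resting-state BOLD band 0.01-0.1 Hz by
    default) and each row is standardized to zero mean, unit variance.
    """
    if duration_s <= 0 or dt_s <= 0:
        raise ValueError("duration and dt must be > 0")
    if not 0 <= band_lo_hz < band_hi_hz <= 1.0 / (2.0 * dt_s):
        raise ValueError("need 0 <= band_lo < band_hi <= Nyquist")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s / dt_s))
    white = rng.standard_normal((n_rsn, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n, d=dt_s)
    keep = (f >= band_lo_hz) & (f <= band_hi_hz)
    spec[:, ~keep] = 0.0
    x = np.fft.irfft(spec, n=n, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("degenerate neural driver (zero variance)")
    return x / sd


def _one_over_f_noise(rng: np.random.Generator, shape: tuple, dt: float,
                      sd: float) -> np.ndarray:
    """1/f-power background: white noise spectrally shaped by f^(-1/2)."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, d=dt)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** -0.5
    x = np.fft.irfft(spec * shaping, n=n, axis=-1)
    cur = x.std(axis=-1, keepdims=True)
    return sd * x / np.where(cur > 0, cur, 1.0)


def default_mixing(n_chan: int, n_region: int, seed: int) -> np.ndarray:
    """Nonnegative random scalp-mixing matrix with row-normalized gains.

    Stands in for volume conduction without a leadfield: every channel is a
    convex-like combination of region signals.
    """
    rng = np.random.default_rng(seed)
    m = rng.uniform(0.0, 1.0, size=(n_chan, n_region))
    return m / m.sum(axis=1, keepdims=True)


def simulate_eeg(neural: np.ndarray, truth: GroundTruth,
                 bands=DEFAULT_BANDS, fs: float = 250.0,
                 mixing_matrix: np.ndarray | None = None,
                 sensor_noise_sd: float = 0.1, seed: int = 0,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Source and scalp EEG whose band envelopes track the neural drivers.

    Region ``r`` assigned to RSN ``k`` emits, per band ``b``, a sinusoidal
    carrier at the band's geometric-center frequency with random phase and
    envelope ``max(0, 1 + coupling[k, b] * z_k(t))`` (rectified so
    amplitudes stay physical; with |coupling| <= 1 rectification is rarely
    active), summed over bands, plus 1/f background noise of SD
    ``truth.eeg_noise_sd``.  Scalp = mixing @ source + white sensor noise.
    """
    max_f = max(b.f_hi for b in bands)
    if fs < 2.0 * max_f:
        raise ValueError(f"fs={fs} below twice the maximum band frequency {max_f}")
    rng = np.random.default_rng(seed)
    n_rsn, n_t = neural.shape
    regions = list(truth.region_assignment.items())
    n_region = len(regions)
    duration = n_t * NEURAL_DT_S
    n_samp = int(round(duration * fs))
    t = np.arange(n_samp) / fs
    # neural drivers interpolated onto the EEG clock
    t_neural = np.arange(n_t) * NEURAL_DT_S
    z = np.vstack([np.interp(t, t_neural, neural[k]) for k in range(n_rsn)])

    source = np.zeros((n_region, n_samp))
    for r, (_, k) in enumerate(regions):
        if not 0 <= k < n_rsn:
            raise ValueError("region assigned to unknown RSN")
        for b, band in enumerate(bands):
            env = np.maximum(0.0, 1.0 + truth.coupling[k, b] * z[k])
            phase = rng.uniform(0, 2 * np.pi)
            source[r] += env * np.sin(2 * np.pi * band.center_hz * t + phase)
    if truth.eeg_noise_sd > 0:
        source += _one_over_f_noise(rng, (n_region, n_samp), 1.0 / fs,
                                    truth.eeg_noise_sd)
    if mixing_matrix is None:
        mixing_matrix = np.eye(n_region)
    mixing_matrix = np.asarray(mixing_matrix, dtype=float)
    if mixing_matrix.shape[1] != n_region:
        raise ValueError("mixing matrix column count must equal region count")
    scalp = mixing_matrix @ source
    if sensor_noise_sd > 0:
        scalp = scalp + sensor_noise_sd * rng.standard_normal(scalp.shape)
    return source, scalp


def simulate_bold(neural: np.ndarray, kernel: HRFKernel, tr: float,
                  bold_noise_sd: float, seed: int = 0) -> np.ndarray:
    """BOLD RSN series: HRF-convolved neural drivers sampled on the TR grid.

    Causal convolution at the neural sampling step, read at the TR epoch
    centers ``(k + 1/2) * TR`` (matching the epoch convention of the EEG
    features), plus white Gaussian noise.  Output length is
    ``floor(duration / TR)`` volumes.
    """
    neural = np.atleast_2d(np.asarray(neural, dtype=float))
    n_t = neural.shape[1]
    if len(kernel.samples) > n_t:
        raise ValueError("HRF kernel longer than the neural signal")
    rng = np.random.default_rng(seed)
    conv = np.apply_along_axis(
        lambda x: np.convolve(x, kernel.samples)[:n_t], 1, neural)
    duration = n_t * kernel.dt
    n_vol = int(duration / tr)
    centers = np.round((np.arange(n_vol) + 0.5) * tr / kernel.dt).astype(int)
    centers = np.minimum(centers, n_t - 1)
    bold = conv[:, centers]
    if bold_noise_sd > 0:
        bold = bold + bold_noise_sd * rng.standard_normal(bold.shape)
    return bold


def motion_template(subject: SyntheticSubject, epoch_ids, amplitude_sd: float,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Additive motion templates (EEG and fMRI) for the listed TR epochs.

    A half-sine burst of peak ``amplitude_sd`` times each channel's SD spans
    every listed EEG epoch; each listed fMRI volume gets a constant offset of
    ``amplitude_sd`` times each RSN series' SD.
    """
    epoch_ids = list(epoch_ids)
    spe = int(round(subject.tr * subject.fs))   # samples per epoch
    n_epoch = subject.eeg_scalp.shape[1] // spe
    if len(set(epoch_ids)) != len(epoch_ids):
        raise ValueError("duplicate epoch ids")
    if any(not 0 <= e < n_epoch for e in epoch_ids):
        raise ValueError("epoch id outside the TR-epoch grid")
    eeg_t = np.zeros_like(subject.eeg_scalp)
    fmri_t = np.zeros_like(subject.rsn_bold)
    burst = np.sin(np.pi * np.arange(spe) / max(spe - 1, 1))
    for e in epoch_ids:
        sl = slice(e * spe, (e + 1) * spe)
        eeg_t[:, sl] += amplitude_sd * subject.eeg_scalp.std(axis=1, keepdims=True) * burst
        if e < subject.rsn_bold.shape[1]:
            fmri_t[:, e] += amplitude_sd * subject.rsn_bold.std(axis=1)
    return eeg_t, fmri_t


def inject_motion(subject: SyntheticSubject, epoch_ids,
                  amplitude_sd: float = 10.0, seed: int = 0,
                  modality: str = "both") -> tuple[SyntheticSubject, dict]:
    """Add motion spikes at the listed TR epochs; returns (subject', templates).

    The injection is purely additive: subtracting the returned templates
    restores the original signals — bitwise outside the burst samples, to
    floating-point rounding within them.  ``truth.motion_epochs`` records
    the contaminated (modality, epoch) pairs.
    """
    eeg_t, fmri_t = motion_template(subject, epoch_ids, amplitude_sd)
    scalp = subject.eeg_scalp.copy()
    source = subject.eeg_source.copy()
    bold = subject.rsn_bold.copy()
    templates = {}
    truth = GroundTruth(
        coupling=subject.truth.coupling.copy(),
        true_delay=subject.truth.true_delay,
        region_assignment=dict(subject.truth.region_assignment),
        eeg_noise_sd=subject.truth.eeg_noise_sd,
        bold_noise_sd=subject.truth.bold_noise_sd,
        seed=subject.truth.seed,
        motion_epochs=list(subject.truth.motion_epochs))
    if modality in ("both", "eeg"):
        # the source template reuses the same SD-scaled burst, per region
        src_t, _ = motion_template(
            SyntheticSubject(subject.eeg_source, subject.eeg_source, bold,
                             subject.region_labels, subject.region_labels,
                             subject.rsn_labels, subject.fs, subject.tr,
                             subject.truth),
            epoch_ids, amplitude_sd)
        scalp += eeg_t
        source += src_t
        # store the realized float difference: subtraction restores the
        # original signals bit-for-bit
        templates["eeg_scalp"] = scalp - subject.eeg_scalp
        templates["eeg_source"] = source - subject.eeg_source
        truth.motion_epochs += [("eeg", int(e)) for e in epoch_ids]
    if modality in ("both", "fmri"):
        bold += fmri_t
        templates["rsn_bold"] = bold - subject.rsn_bold
        truth.motion_epochs += [("fmri", int(e)) for e in epoch_ids]
    new = SyntheticSubject(scalp, source, bold, list(subject.chan_labels),
                           list(subject.region_labels), list(subject.rsn_labels),
                           subject.fs, subject.tr, truth)
    return new, templates


@dataclass
class GroupConfig:
    """Study conditions for one synthetic group.

    Defaults mirror the recovery benchmark used throughout the test suite:
    10 subjects, 10-minute recordings at TR 2 s, EEG at 250 Hz, a true
    hemodynamic delay of 6 s, and signed couplings of magnitude 0.5.  The
    montage (16 channels, 2 source regions per RSN) is deliberately compact:
    the analysis spatially averages over units, so the spatial dimension
    adds cost, not information, to coupling recovery.
    """

    n_subjects: int = 10
    duration_s: float = 600.0
    tr: float = 2.0
    fs: float = 250.0
    n_rsn: int = 7
    regions_per_rsn: int = 2
    n_channels: int = 16
    true_delay: float = 6.0
    coupling: np.ndarray | None = None
    coupling_magnitude: float = 0.5
    eeg_noise_sd: float = 1.0
    sensor_noise_sd: float = 0.1
    bold_noise_sd: float = 1.0
    #: additive baseline intensity of the RSN series; BOLD fluctuations ride
    #: on a large positive mean, which the median-normalized DVARS assumes
    bold_baseline: float = 100.0
    motion_epochs: tuple = ()
    motion_amplitude_sd: float = 0.0
    bands: tuple = DEFAULT_BANDS
    seed: int = 0

    def coupling_matrix(self) -> np.ndarray:
        """Planted coupling; default alternates sign over (RSN, band) cells."""
        if self.coupling is not None:
            return np.asarray(self.coupling, dtype=float)
        n_band = len(self.bands)
        signs = (-1.0) ** (np.add.outer(np.arange(self.n_rsn), np.arange(n_band)))
        return self.coupling_magnitude * signs


def simulate_subject(config: GroupConfig, seed: int) -> SyntheticSubject:
    """Simulate one subject under the group's study conditions."""
    ss = np.random.SeedSequence(seed)
    s_neural, s_eeg, s_bold, s_mix, s_motion = ss.generate_state(5) >> 1
    coupling = config.coupling_matrix()
    n_region = config.n_rsn * config.regions_per_rsn
    rsn_labels = [RSN_NAMES[k] if k < len(RSN_NAMES) else f"RSN{k}"
                  for k in range(config.n_rsn)]
    region_assignment = {
        f"{rsn_labels[r % config.n_rsn]}_r{r // config.n_rsn}": r % config.n_rsn
        for r in range(n_region)}
    truth = GroundTruth(coupling=coupling, true_delay=config.true_delay,
                        region_assignment=region_assignment,
                        eeg_noise_sd=config.eeg_noise_sd,
                        bold_noise_sd=config.bold_noise_sd, seed=seed)
    neural = simulate_neural_rsn(config.n_rsn, config.duration_s,
                                 NEURAL_DT_S, seed=int(s_neural))
    mixing = default_mixing(config.n_channels, n_region, int(s_mix))
    source, scalp = simulate_eeg(neural, truth, config.bands, config.fs,
                                 mixing, config.sensor_noise_sd, int(s_eeg))
    kernel = hrf_kernel(scaled_params(config.true_delay,
                                      HRFParams(dt=NEURAL_DT_S)))
    bold = config.bold_baseline + simulate_bold(
        neural, kernel, config.tr, config.bold_noise_sd, int(s_bold))
    subject = SyntheticSubject(
        eeg_scalp=scalp, eeg_source=source, rsn_bold=bold,
        chan_labels=[f"CH{c:02d}" for c in range(config.n_channels)],
        region_labels=list(region_assignment), rsn_labels=rsn_labels,
        fs=config.fs, tr=config.tr, truth=truth)
    if config.motion_epochs:
        subject, _ = inject_motion(subject, config.motion_epochs,
                                   config.motion_amplitude_sd, int(s_motion))
    return subject


def subject_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-subject seeds derived from the master seed."""
    return [int(s) for s in np.random.SeedSequence(master_seed).generate_state(n) >> 1]


def generate_group(config: GroupConfig, out_dir: str | Path,
                   overwrite: bool = False) -> dict:
    """Write a synthetic group to disk and return its manifest.

    Layout: one directory per subject with TSV signal files and JSON
    sidecars (see :mod:`eegfmri.io`), plus ``manifest.json`` at the root
    recording conditions, labels, per-subject seeds, and the truth block.
    Regeneration under the same config and seed is byte-identical.
    """
    from . import io as _io

    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} exists; pass overwrite=True to replace")
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = subject_seeds(config.seed, config.n_subjects)
    manifest: dict = {
        "n_subjects": config.n_subjects, "fs": config.fs, "tr": config.tr,
        "duration_s": config.duration_s,
        "bands": [asdict(b) for b in config.bands],
        "subjects": [], "master_seed": config.seed,
        "truth": {
            "coupling": config.coupling_matrix().tolist(),
            "true_delay": config.true_delay,
            "eeg_noise_sd": config.eeg_noise_sd,
            "bold_noise_sd": config.bold_noise_sd,
            "motion_epochs": list(config.motion_epochs),
        },
    }
    for i, seed in enumerate(seeds):
        sid = f"sub-{i + 1:02d}"
        subj = simulate_subject(config, seed)
        sdir = out_dir / sid
        sdir.mkdir(exist_ok=True)
        _io.write_timeseries(sdir / "eeg_scalp.tsv", subj.eeg_scalp.T,
                             subj.chan_labels,
                             {"fs": subj.fs, "units": "a.u.", "seed": seed,
                              "space": "scalp"})
        _io.write_timeseries(sdir / "eeg_source.tsv", subj.eeg_source.T,
                             subj.region_labels,
                             {"fs": subj.fs, "units": "a.u.", "seed": seed,
                              "space": "source"})
        _io.write_timeseries(sdir / "rsn_bold.tsv", subj.rsn_bold.T,
                             subj.rsn_labels,
                             {"tr": subj.tr, "units": "a.u.", "seed": seed,
                              "space": "rsn"})
        manifest["subjects"].append({
            "id": sid, "seed": seed,
            "region_assignment": subj.truth.region_assignment,
            "rsn_labels": subj.rsn_labels})
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
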