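"""End-to-end orchestration: features -> scrub -> correlate -> stats -> resample.

Each stage reads the previous stage's persisted outputs and writes its own
under ``<out_dir>/<stage>/`` together with a small ``stage.json`` marker
recording the configuration hash; a stage whose marker matches the current
configuration is skipped on rerun, so deleting one stage's directory
recomputes only that stage and the ones downstream.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import coupling, groupstats, io, resample, scrub
from .features import DEFAULT_BANDS, BandDef, extract_features
from .hrf import DEFAULT_DELAYS, HRFParams, delay_family
from .synth import GroupConfig, generate_group

log = logging.getLogger(__name__)

STAGES = ("features", "scrub", "correlate", "stats", "resample")


@dataclass
class PipelineConfig:
    """Resolved configuration of one analysis run.

    Scrub thresholds (4 SD for EEG amplitude, Q3 + 1.5 IQR for DVARS) and
    the wavelet constant (3-s FWHM at 1 Hz) live in their modules and are
    recorded here for the audit trail only.
    """

    data_dir: str = "group"
    delays: tuple = DEFAULT_DELAYS
    bands: tuple = tuple((b.name, b.f_lo, b.f_hi) for b in DEFAULT_BANDS)
    canonical_hrf: dict = field(default_factory=lambda: asdict(HRFParams()))
    fdr_q: float = 0.05
    resample_iterations: int = resample.DEFAULT_ITERATIONS
    resample_minutes: tuple = ()
    seed: int = 0

    def validate(self) -> None:
        if not self.delays or len(set(self.delays)) != len(self.delays):
            raise ValueError("delays must be nonempty and unique")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must lie in (0, 1)")
        if self.resample_iterations < 1:
            raise ValueError("resample_iterations must be positive")
        for name, lo, hi in self.bands:
            BandDef(name, lo, hi)

    def band_defs(self) -> tuple[BandDef, ...]:
        return tuple(BandDef(*b) for b in self.bands)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("delays", "resample_minutes"):
            if key in known:
                known[key] = tuple(known[key])
        if "bands" in known:
            known["bands"] = tuple(tuple(b) for b in known["bands"])
        cfg = cls(**known)
        cfg.validate()
        return cfg


def _stage_dir(out_dir: Path, stage: str) -> Path:
    d = out_dir / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def _marker(stage_dir: Path) -> Path:
    return stage_dir / "stage.json"


def _stage_fresh(stage_dir: Path, digest: str) -> bool:
    m = _marker(stage_dir)
    if not m.exists():
        return False
    try:
        return json.loads(m.read_text()).get("config_digest") == digest
    except json.JSONDecodeError:
        return False


def _write_marker(stage_dir: Path, digest: str, info: dict) -> None:
    payload = {"config_digest": digest, **info}
    _marker(stage_dir).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _load_group(data_dir: Path) -> dict:
    with open(data_dir / "manifest.json") as fh:
        return json.load(fh)


def stage_features(config: PipelineConfig, data_dir: Path, out_dir: Path) -> None:
    manifest = _load_group(data_dir)
    tr = manifest["tr"]
    family = delay_family(config.delays,
                          HRFParams(**{**config.canonical_hrf, "dt": tr}))
    sdir = _stage_dir(out_dir, "features")
    for sub in manifest["subjects"]:
        sid = sub["id"]
        signals = {}
        for space, fname in (("scalp", "eeg_scalp.tsv"), ("source", "eeg_source.tsv")):
            p = data_dir / sid / fname
            if p.exists():
                vals, labels, meta = io.read_timeseries(p, require_keys=("fs",))
                signals[space] = (vals.T, labels)
        feats = extract_features(signals, manifest["fs"], tr, family,
                                 config.band_defs())
        for space, per_delay in feats.items():
            for delay, bp in per_delay.items():
                cols = [f"{u}.{b}" for u in bp.unit_labels for b in bp.band_names]
                mat = bp.values.reshape(bp.n_epoch, -1)
                io.write_timeseries(
                    sdir / f"{sid}_{space}_delay{delay:g}.tsv", mat, cols,
                    {"tr": tr, "space": space, "delay": delay,
                     "units": "relative power",
                     "valid": bp.valid.astype(int).tolist(),
                     "unit_labels": bp.unit_labels,
                     "band_names": bp.band_names})


def stage_scrub(config: PipelineConfig, data_dir: Path, out_dir: Path) -> None:
    manifest = _load_group(data_dir)
    sdir = _stage_dir(out_dir, "scrub")
    for sub in manifest["subjects"]:
        sid = sub["id"]
        eeg, _, _ = io.read_timeseries(data_dir / sid / "eeg_scalp.tsv",
                                       require_keys=("fs",))
        bold, _, _ = io.read_timeseries(data_dir / sid / "rsn_bold.tsv",
                                        require_keys=("tr",))
        mask = scrub.subject_mask(eeg.T, bold.T, manifest["fs"], manifest["tr"])
        tab = pd.DataFrame({
            "epoch": np.arange(len(mask.retain)),
            "eeg_flag": mask.eeg_flags.astype(int),
            "fmri_flag": mask.fmri_flags.astype(int),
            "retain": mask.retain.astype(int)})
        tab.to_csv(sdir / f"{sid}_mask.tsv", sep="\t", index=False)
        log.info("%s scrubbing: %s", sid, mask.summary())


def stage_correlate(config: PipelineConfig, data_dir: Path, out_dir: Path) -> None:
    manifest = _load_group(data_dir)
    sdir = _stage_dir(out_dir, "correlate")
    fdir = out_dir / "features"
    tensors, avgs = [], []
    for sub in manifest["subjects"]:
        sid = sub["id"]
        mask_tab = pd.read_csv(out_dir / "scrub" / f"{sid}_mask.tsv", sep="\t")
        retain = mask_tab["retain"].to_numpy(dtype=bool)
        bold, rsn_labels, _ = io.read_timeseries(
            data_dir / sid / "rsn_bold.tsv", require_keys=("tr",))
        feats: dict = {}
        for f in sorted(fdir.glob(f"{sid}_*_delay*.tsv")):
            vals, cols, meta = io.read_timeseries(f)
            from .features import BandPowerSeries
            bp = BandPowerSeries(
                values=vals.reshape(vals.shape[0], len(meta["unit_labels"]),
                                    len(meta["band_names"])),
                unit_labels=meta["unit_labels"], band_names=meta["band_names"],
                tr=meta["tr"], space=meta["space"],
                valid=np.asarray(meta["valid"], dtype=bool))
            feats.setdefault(meta["space"], {})[meta["delay"]] = bp
        tensor = coupling.correlation_maps(feats, bold.T, retain, rsn_labels,
                                           subject=sid)
        tensors.append(tensor)
        avgs.append(coupling.spatial_average(tensor))
    tensor = pd.concat(tensors, ignore_index=True)
    avg = pd.concat(avgs, ignore_index=True)
    pooled = coupling.pool_spaces(avg)
    tensor.to_csv(sdir / "tensor.tsv", sep="\t", index=False)
    pd.concat([avg, pooled], ignore_index=True).to_csv(
        sdir / "averaged.tsv", sep="\t", index=False)


def stage_stats(config: PipelineConfig, data_dir: Path, out_dir: Path) -> None:
    sdir = _stage_dir(out_dir, "stats")
    avg = pd.read_csv(out_dir / "correlate" / "averaged.tsv", sep="\t")
    report = groupstats.consistency_report(avg, q=config.fdr_q)
    report.to_csv(sdir / "consistency.tsv", sep="\t", index=False)
    pooled = avg[avg["space"] == "pooled"].copy()
    if pooled["subject"].nunique() >= 2 and pooled["r"].notna().all():
        anova = groupstats.rm_anova(pooled, dv="r",
                                    within=["rsn", "band", "delay"])
        anova.to_csv(sdir / "anova.tsv", sep="\t", index=False)


def stage_resample(config: PipelineConfig, data_dir: Path, out_dir: Path) -> None:
    sdir = _stage_dir(out_dir, "resample")
    avg = pd.read_csv(out_dir / "correlate" / "averaged.tsv", sep="\t")
    pooled = avg[avg["space"] == "pooled"]
    n_total = pooled["subject"].nunique()
    curve = resample.subsample_subjects(
        pooled, n_grid=range(2, n_total + 1),
        iterations=config.resample_iterations, seed=config.seed)
    curve.table.to_csv(sdir / "subjects_curve.tsv", sep="\t", index=False)
    meta = {"iterations": curve.iterations, "seed": curve.seed,
            "x": curve.x_name}
    (sdir / "subjects_curve.json").write_text(json.dumps(meta, indent=1))


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 simulate: GroupConfig | None = None) -> Path:
    """Run all stages, reusing any stage whose cached outputs are current.

    When ``simulate`` is given and the data directory does not exist yet,
    a synthetic group is generated there first.  Returns the results
    directory; the resolved configuration is written next to the outputs.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data_dir = Path(config.data_dir)
    if not data_dir.is_absolute():
        data_dir = out_dir / data_dir
    if simulate is not None and not (data_dir / "manifest.json").exists():
        generate_group(simulate, data_dir, overwrite=True)
    if not (data_dir / "manifest.json").exists():
        raise FileNotFoundError(f"no group manifest under {data_dir}")
    (out_dir / "config.json").write_text(
        json.dumps(asdict(config), indent=1, sort_keys=True, default=str))
    digest = config.digest()
    runners = {"features": stage_features, "scrub": stage_scrub,
               "correlate": stage_correlate, "stats": stage_stats,
               "resample": stage_resample}
    upstream_ran = False
    for stage in STAGES:
        sdir = out_dir / stage
        if not upstream_ran and _stage_fresh(sdir, digest):
            log.info("stage %s: cached, skipped", stage)
            continue
        upstream_ran = True
        t0 = time.time()
        try:
            runners[stage](config, data_dir, out_dir)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage name
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        _write_marker(_stage_dir(out_dir, stage), digest,
                      {"elapsed_s": round(time.time() - t0, 3)})
        log.info("stage %s: %.1f s", stage, time.time() - t0)
    return out_dir
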