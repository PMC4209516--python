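"""Top-level study orchestration, configuration and provenance.

``run_study`` executes the whole chain on a synthetic study: phantom
generation -> R1 mapping -> blood-curve extraction -> v_b mapping ->
region summaries -> ventricular permeability -> Monte Carlo uncertainty,
writing maps, tables and a provenance manifest to the output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from . import csf as csfmod
from . import exchange, masks, phantom, pipeline, stats
from .mprage import make_r1_map
from .phantom import LABELS, DEFAULT_SCHEDULE, PhantomSpec
from .volumes import VolumeMap

__all__ = ["StudyConfig", "StudyResult", "run_study", "ConfigError"]

log = logging.getLogger("relaxovb")


class ConfigError(ValueError):
    """Invalid study configuration."""


@dataclass
class StudyConfig:
    """Configuration of one synthetic study run.

    Attributes map one-to-one onto YAML keys; ``from_yaml``/``to_yaml``
    round-trip the configuration unchanged.
    """

    out_dir: str = "study_out"
    seed: int = 0
    snr: float | None = 100.0
    schedule_min: tuple = DEFAULT_SCHEDULE
    # exchange / CR constants
    tau_b_s: float = exchange.TAU_B_DEFAULT
    f_w: float = exchange.F_W_DEFAULT
    relaxivity_r1: float = exchange.RELAXIVITY_R1_DEFAULT
    hematocrit: float = exchange.HEMATOCRIT_DEFAULT
    r1b0: float = exchange.R1B0_DEFAULT
    # NAWM band geometry
    nawm_band_distance_mm: float = 15.0
    nawm_band_tolerance_mm: float = 3.0
    # CSF ROI
    csf_roi_volume_ul: float = 16.0
    csf_roi_side: str = "left"
    # Monte Carlo
    mc_replicates: int = 1000
    # phantom overrides (merged into PhantomSpec defaults)
    phantom: dict = field(default_factory=dict)
    write_nifti: bool = True

    def validate(self) -> None:
        sched = tuple(float(t) for t in self.schedule_min)
        if sum(t < 0 for t in sched) != 1:
            raise ConfigError("schedule_min must contain exactly one pre-CR "
                              "(negative) timepoint")
        if sum(t >= 0 for t in sched) < 2:
            raise ConfigError("schedule_min must contain >= 2 post-CR timepoints")
        if self.snr is not None and self.snr <= 0:
            raise ConfigError("snr must be positive or null")
        if self.mc_replicates < 100:
            raise ConfigError("mc_replicates must be >= 100")
        if self.csf_roi_side not in ("left", "right"):
            raise ConfigError("csf_roi_side must be 'left' or 'right'")

    def phantom_spec(self) -> PhantomSpec:
        kw = dict(self.phantom)
        kw.setdefault("snr", self.snr)
        kw.setdefault("seed", self.seed)
        kw.setdefault("tau_b_s", self.tau_b_s)
        kw.setdefault("f_w", self.f_w)
        kw.setdefault("relaxivity_r1", self.relaxivity_r1)
        kw.setdefault("hematocrit", self.hematocrit)
        kw.setdefault("r1b0", self.r1b0)
        return PhantomSpec(**kw)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return plain(dataclasses.asdict(self))

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class StudyResult:
    """Bundle of study outputs (in memory; files listed in the manifest)."""

    config: StudyConfig
    truth: "phantom.PhantomTruth"
    r1_maps: list
    blood_curve: exchange.BloodInputCurve
    vb_map: VolumeMap
    region_summaries: dict  # region -> RegionVbSummary
    permeability: csfmod.PermeabilityEstimate
    mc_r1: stats.MonteCarloReport
    mc_vb: stats.MonteCarloReport
    manifest: dict


def _sinus_roi(labels: VolumeMap) -> np.ndarray:
    """Voxels strictly inside the sagittal-sinus label (eroded by one)."""
    blood = labels.values == LABELS["blood"]
    core = ndimage.binary_erosion(blood, ndimage.generate_binary_structure(3, 1))
    if not core.any():
        core = blood
    return np.argwhere(core)


def run_study(config: StudyConfig) -> StudyResult:
    """Run the full synthetic study defined by ``config``.

    Writes maps, tables and a provenance manifest under ``config.out_dir``;
    partial outputs are removed if a stage fails.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    try:
        return _run_study_inner(config, out, written)
    except Exception:
        for name in written:
            (out / name).unlink(missing_ok=True)
        raise


def _run_study_inner(config: StudyConfig, out: Path,
                     written: list) -> StudyResult:
    def _write_map(vol: VolumeMap, name: str):
        if config.write_nifti:
            vol.to_nifti(out / name)
            written.append(name)

    spec = config.phantom_spec()
    log.info("generating phantom (grid %s, SNR %s, seed %d)",
             spec.shape, spec.snr, spec.seed)
    datasets, truth = phantom.generate_study(spec, config.schedule_min)
    labels = truth.labels
    _write_map(labels, "labels.nii.gz")
    _write_map(truth.vb_map, "vb_truth.nii.gz")

    # masks from the study's segmentation products
    wm = VolumeMap(np.isin(labels.values,
                           [LABELS["nawm"], LABELS["dwmh"], LABELS["pwmh"]]),
                   labels.voxel_size_mm)
    dwmh = masks.persistence_filter(
        VolumeMap(labels.values == LABELS["dwmh"], labels.voxel_size_mm))
    pwmh = masks.persistence_filter(
        VolumeMap(labels.values == LABELS["pwmh"], labels.voxel_size_mm))
    vent = VolumeMap(labels.values == LABELS["ventricle"], labels.voxel_size_mm)
    wmh_all = VolumeMap(dwmh.values | pwmh.values, labels.voxel_size_mm)
    nawm_band = masks.nawm_band_mask(
        VolumeMap(labels.values == LABELS["nawm"], labels.voxel_size_mm),
        vent, config.nawm_band_distance_mm, config.nawm_band_tolerance_mm,
        wmh_mask=wmh_all)

    analysis_mask = VolumeMap(labels.values > 0, labels.voxel_size_mm)
    log.info("fitting R1 maps (%d timepoints, %d voxels)",
             len(datasets), int(np.count_nonzero(analysis_mask.values)))
    r1_maps = [make_r1_map(ds, analysis_mask) for ds in datasets]
    for i, m in enumerate(r1_maps):
        _write_map(m, f"r1map_tp{i:02d}.nii.gz")

    sinus = _sinus_roi(labels)
    curve = pipeline.extract_blood_curve(
        r1_maps, sinus, relaxivity_r1=config.relaxivity_r1,
        hematocrit_h=config.hematocrit, labels=labels,
        blood_label=LABELS["blood"])

    log.info("fitting v_b map")
    vb_map = pipeline.map_vb(r1_maps, curve, wm, tau_b=config.tau_b_s,
                             f_w=config.f_w)
    _write_map(vb_map, "vb_map.nii.gz")

    summaries = {}
    for region, region_mask in (("dWMH", dwmh), ("pWMH", pwmh),
                                ("NAWM", nawm_band)):
        vals = 100.0 * vb_map.values[np.asarray(region_mask.values, bool)]
        summaries[region] = pipeline.region_mean_vb(vals, region=region)
    pd.DataFrame([dataclasses.asdict(s) for s in summaries.values()]).to_csv(
        out / "region_vb.csv", index=False)
    written.append("region_vb.csv")

    # ventricular permeability from the posterior-horn CSF ROI
    roi = masks.csf_roi(vent, truth.ventricle_pve, side=config.csf_roi_side,
                        target_volume_ul=config.csf_roi_volume_ul)
    ix = tuple(roi.T)
    times, means, nvox = [], [], []
    for m in r1_maps:
        t = float(m.meta["acquisition_midpoint_min"])
        if t < 0:
            continue
        vals = m.values[ix]
        vals = vals[np.isfinite(vals)]
        times.append(t)
        means.append(vals.mean())
        nvox.append(vals.size)
    perm = csfmod.permeability_from_series(times, means,
                                           relaxivity_r1=config.relaxivity_r1)
    pd.DataFrame({"time_min": times, "mean_r1": means, "n_voxels": nvox,
                  "rate_uM_per_hr": perm.rate_uM_per_hr}).to_csv(
        out / "csf_permeability.csv", index=False)
    written.append("csf_permeability.csv")

    # Monte Carlo uncertainty at a representative deep-lesion voxel
    prot = spec.protocol
    from .mprage import mprage_signal
    r1_wmh = spec.r1_baseline("dwmh")
    sig = np.array([abs(mprage_signal(r1_wmh, spec.m0["dwmh"], prot, ti))
                    for ti in prot.ti_list])
    snr_mc = spec.snr if spec.snr is not None else 1e6
    mc_r1 = stats.monte_carlo_r1(sig, prot, snr_mc, n=config.mc_replicates,
                                 seed=config.seed)
    r1_sd = mc_r1.sd
    truth_curve = truth.blood_curve
    r1e = exchange.r1e_no_exchange(r1_wmh, truth_curve.r1b0,
                                   spec.v_b["dwmh"], spec.f_w)
    series = exchange.VoxelRelaxationSeries(
        r1_wmh, exchange.r1t_two_site(truth_curve.r1b_values, r1e,
                                      spec.v_b["dwmh"], spec.tau_b_s, spec.f_w))
    mc_vb = stats.monte_carlo_vb(series, truth_curve, r1_sd,
                                 n=config.mc_replicates, seed=config.seed,
                                 tau_b=config.tau_b_s, f_w=config.f_w)
    with open(out / "monte_carlo.json", "w") as fh:
        json.dump({"r1": dataclasses.asdict(mc_r1),
                   "v_b": dataclasses.asdict(mc_vb)}, fh, indent=2)
    written.append("monte_carlo.json")

    import nibabel
    import scipy

    from . import __version__

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {"relaxovb": __version__, "numpy": np.__version__,
                     "scipy": scipy.__version__, "nibabel": nibabel.__version__},
        "outputs": written + ["manifest.json"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return StudyResult(
        config=config, truth=truth, r1_maps=r1_maps, blood_curve=curve,
        vb_map=vb_map, region_summaries=summaries, permeability=perm,
        mc_r1=mc_r1, mc_vb=mc_vb, manifest=manifest,
    )
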