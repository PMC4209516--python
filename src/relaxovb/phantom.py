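"""Digital brain phantom for relaxographic blood-volume studies.

The phantom is not anatomically realistic; it reproduces the statistical and
kinetic structure the analysis assumes: disjoint tissue compartments with
known baseline T1 and fractional blood volume v_b, a sagittal-sinus blood
pool following a decaying plasma contrast-reagent (CR) curve, ventricular
CSF with slow linear CR accumulation, periventricular lesion rims adjacent
to the ventricle surface and deep lesion blobs away from it, all sampled as
variable-TI MPRAGE signal volumes with Gaussian image noise at a configured
signal-background SNR.

Default tissue constants are the study conditions: baseline T1 of 1454 ms
(NAWM), 1608 ms (deep WMH), 1861 ms (periventricular WMH), CSF R1 of
0.239 s^-1; v_b of 0.024 (NAWM and pWMH) and 0.018 (dWMH); a CSF CR
accumulation rate of 3.4 uM/hr; image SNR 100; acquisition schedule of one
pre-CR dataset plus four post-CR datasets over a ~55-minute washout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import exchange
from .exchange import BloodInputCurve, r1e_no_exchange, r1t_two_site
from .mprage import MprageProtocol, VariableTiDataset, mprage_signal
from .volumes import VolumeMap

__all__ = [
    "LABELS",
    "PhantomSpec",
    "PhantomTruth",
    "DEFAULT_SCHEDULE",
    "plasma_curve",
    "tissue_r1_timecourse",
    "build_labels",
    "generate_study",
    "flair_like",
    "save_study",
]

#: Compartment label codes used throughout the package.
LABELS = {
    "background": 0,
    "nawm": 1,
    "dwmh": 2,
    "pwmh": 3,
    "ventricle": 4,
    "blood": 5,
}
_PARENCHYMA = ("nawm", "dwmh", "pwmh")

#: Acquisition midpoints in minutes relative to CR injection; negative = pre-CR.
DEFAULT_SCHEDULE = (-20.0, 15.0, 30.0, 45.0, 55.0)


@dataclass
class PhantomSpec:
    """Geometry, tissue constants and kinetics of the synthetic study."""

    shape: tuple[int, int, int] = (96, 96, 48)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 2.0)

    # geometry (mm unless noted)
    brain_semiaxes_mm: tuple[float, float, float] = (44.0, 44.0, 40.0)
    ventricle_semiaxes_mm: tuple[float, float, float] = (7.0, 22.0, 11.0)
    ventricle_offset_mm: float = 11.0  # lateral offset of each ventricle centre
    pwmh_rim_mm: float = 3.0
    n_dwmh: int = 6
    dwmh_radius_mm: float = 3.5
    dwmh_clearance_mm: float = 8.0  # minimum distance from the ventricle surface
    sinus_radius_mm: float = 2.5
    sinus_z_mm: float = 78.0  # height of the sinus tube axis

    # baseline T1 (ms) per compartment
    t1_ms: dict = field(default_factory=lambda: {
        "nawm": 1454.0, "dwmh": 1608.0, "pwmh": 1861.0,
        "ventricle": 1e3 / 0.239, "blood": 1e3 / exchange.R1B0_DEFAULT,
    })
    # proton-density / gain factor per compartment (arbitrary units)
    m0: dict = field(default_factory=lambda: {
        "nawm": 700.0, "dwmh": 760.0, "pwmh": 800.0,
        "ventricle": 1000.0, "blood": 850.0,
    })
    # ground-truth fractional blood volume per parenchymal compartment
    v_b: dict = field(default_factory=lambda: {
        "nawm": 0.024, "dwmh": 0.018, "pwmh": 0.024,
    })

    # exchange and CR constants
    tau_b_s: float = exchange.TAU_B_DEFAULT
    f_w: float = exchange.F_W_DEFAULT
    relaxivity_r1: float = exchange.RELAXIVITY_R1_DEFAULT
    hematocrit: float = exchange.HEMATOCRIT_DEFAULT
    r1b0: float = exchange.R1B0_DEFAULT

    # plasma CR curve: c0 * exp(-ln2 * t / half-life)
    plasma_c0_mM: float = 1.2
    plasma_half_life_min: float = 96.0

    #: CR accumulation rate in ventricular CSF, uM per hour
    csf_permeability_uM_per_hr: float = 3.4

    snr: float | None = 100.0  # None disables noise
    seed: int = 0

    protocol: MprageProtocol = field(default_factory=MprageProtocol)

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        self.brain_semiaxes_mm = tuple(float(v) for v in self.brain_semiaxes_mm)
        self.ventricle_semiaxes_mm = tuple(
            float(v) for v in self.ventricle_semiaxes_mm)
        for k, v in self.t1_ms.items():
            if v <= 0:
                raise ValueError(f"baseline T1 of {k} must be positive")
        for k, v in self.v_b.items():
            if not (0 <= v <= 0.1):
                raise ValueError(f"v_b of {k} must lie in [0, 0.1], got {v}")

    def r1_baseline(self, label_name: str) -> float:
        return 1e3 / self.t1_ms[label_name]


@dataclass
class PhantomTruth:
    """Ground truth aligned voxel-for-voxel with the generated datasets."""

    labels: VolumeMap
    vb_map: VolumeMap
    r1_maps: list  # list[VolumeMap], one per schedule entry
    blood_curve: BloodInputCurve
    csf_r1_series: np.ndarray  # true CSF R1 at each schedule entry
    schedule_min: tuple
    ventricle_pve: VolumeMap
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def plasma_curve(spec: PhantomSpec, t_min, pre_cr: bool = False):
    """Plasma CR concentration (mM) at ``t_min`` minutes after injection."""
    if pre_cr:
        return 0.0
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("post-CR time must be nonnegative")
    out = spec.plasma_c0_mM * np.exp(-np.log(2.0) * t / spec.plasma_half_life_min)
    return float(out) if out.ndim == 0 else out


def _blood_r1(spec: PhantomSpec, t_min, pre_cr: bool = False):
    if pre_cr:
        return spec.r1b0
    cp = plasma_curve(spec, t_min)
    return spec.r1b0 + spec.relaxivity_r1 * (1.0 - spec.hematocrit) * cp


def tissue_r1_timecourse(label_name: str, spec: PhantomSpec, t_min,
                         pre_cr: bool = False):
    """True R1 (s^-1) of a compartment at ``t_min`` minutes post-injection.

    Parenchymal labels follow the two-site exchange model driven by the
    blood curve; the ventricle label accumulates CR linearly
    (R1csf(t) = R1csf(0) + r1 * permeability * t); the blood label follows
    the plasma relation directly.
    """
    if label_name in _PARENCHYMA:
        base = spec.r1_baseline(label_name)
        if pre_cr:
            return base
        vb = spec.v_b[label_name]
        r1e = r1e_no_exchange(base, spec.r1b0, vb, spec.f_w)
        return r1t_two_site(_blood_r1(spec, t_min), r1e, vb, spec.tau_b_s, spec.f_w)
    if label_name == "ventricle":
        base = spec.r1_baseline("ventricle")
        if pre_cr:
            return base
        t_hr = np.asarray(t_min, dtype=float) / 60.0
        rate_mM_per_hr = spec.csf_permeability_uM_per_hr / 1e3
        out = base + spec.relaxivity_r1 * rate_mM_per_hr * t_hr
        return float(out) if out.ndim == 0 else out
    if label_name == "blood":
        return _blood_r1(spec, t_min, pre_cr)
    raise ValueError(f"unknown compartment label {label_name!r}")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _coord_grids_mm(spec: PhantomSpec):
    vx, vy, vz = spec.voxel_size_mm
    nx, ny, nz = spec.shape
    x = (np.arange(nx) + 0.5) * vx
    y = (np.arange(ny) + 0.5) * vy
    z = (np.arange(nz) + 0.5) * vz
    return np.meshgrid(x, y, z, indexing="ij")


def _ellipsoid(xg, yg, zg, center_mm, semiaxes_mm):
    cx, cy, cz = center_mm
    ax, ay, az = semiaxes_mm
    return ((xg - cx) / ax) ** 2 + ((yg - cy) / ay) ** 2 + ((zg - cz) / az) ** 2 <= 1.0


def build_labels(spec: PhantomSpec, rng: np.random.Generator | None = None):
    """Construct the compartment label volume and the ventricle PVE map.

    Deep lesion centres are drawn reproducibly from ``spec.seed`` within a
    deep-WM band (at least ``dwmh_clearance_mm`` from the ventricle surface);
    the periventricular rim hugs the ventricle surface by construction, and
    lesion radii guarantee the three-consecutive-slice persistence rule.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    xg, yg, zg = _coord_grids_mm(spec)
    vx, vy, vz = spec.voxel_size_mm
    center = tuple(0.5 * n * v for n, v in zip(spec.shape, spec.voxel_size_mm))

    brain = _ellipsoid(xg, yg, zg, center, spec.brain_semiaxes_mm)
    vent = np.zeros_like(brain)
    for sgn in (-1.0, 1.0):
        c = (center[0] + sgn * spec.ventricle_offset_mm, center[1], center[2])
        vent |= _ellipsoid(xg, yg, zg, c, spec.ventricle_semiaxes_mm)
    vent &= brain

    # distance (mm) from the ventricle compartment
    sampling = (vx, vy, vz)
    dist_vent = ndimage.distance_transform_edt(~vent, sampling=sampling)

    pwmh = brain & ~vent & (dist_vent <= spec.pwmh_rim_mm)

    # sagittal-sinus tube along y at the posterior midline
    r2 = (xg - center[0]) ** 2 + (zg - spec.sinus_z_mm) ** 2
    sinus = brain & (r2 <= spec.sinus_radius_mm ** 2)

    # deep lesions: rejection-sample centres in the deep WM band
    dwmh = np.zeros_like(brain)
    margin = spec.dwmh_radius_mm + 2.0
    inner = _ellipsoid(
        xg, yg, zg, center,
        tuple(a - margin for a in spec.brain_semiaxes_mm),
    )
    eligible = inner & ~vent & (dist_vent >= spec.dwmh_clearance_mm) & ~sinus
    # a blob is valid if it stays inside the deep WM: within the margin
    # ellipsoid, clear of the rim (non-adjacent to the ventricle surface),
    # and off the sinus
    allowed = inner & ~vent & ~sinus & (dist_vent > spec.pwmh_rim_mm)
    placed = []
    idx_eligible = np.argwhere(eligible)
    if len(idx_eligible) == 0:
        raise RuntimeError("no eligible voxels for deep lesion centres")
    tries = 0
    while len(placed) < spec.n_dwmh and tries < 20000:
        tries += 1
        i, j, k = idx_eligible[rng.integers(len(idx_eligible))]
        c = ((i + 0.5) * vx, (j + 0.5) * vy, (k + 0.5) * vz)
        if any(np.hypot(np.hypot(c[0] - p[0], c[1] - p[1]), c[2] - p[2])
               < 2.5 * spec.dwmh_radius_mm for p in placed):
            continue
        blob = ((xg - c[0]) ** 2 + (yg - c[1]) ** 2 + (zg - c[2]) ** 2
                <= spec.dwmh_radius_mm ** 2)
        if not (blob & ~allowed).any():
            dwmh |= blob
            placed.append(c)
    if len(placed) < spec.n_dwmh:
        raise RuntimeError("could not place the requested number of deep lesions")

    labels = np.zeros(spec.shape, dtype=np.int16)
    labels[brain] = LABELS["nawm"]
    labels[pwmh] = LABELS["pwmh"]
    labels[dwmh] = LABELS["dwmh"]
    labels[vent] = LABELS["ventricle"]
    labels[sinus] = LABELS["blood"]

    # partial-volume estimate of ventricular CSF: 1 in the interior, 0.5 on
    # the compartment surface (face-connected neighbourhood)
    interior = ndimage.binary_erosion(vent, structure=ndimage.generate_binary_structure(3, 1))
    pve = np.where(interior, 1.0, np.where(vent, 0.5, 0.0))

    return (VolumeMap(labels, spec.voxel_size_mm, {"kind": "labels"}),
            VolumeMap(pve, spec.voxel_size_mm, {"kind": "csf_pve"}))


# ---------------------------------------------------------------------------
# study generation
# ---------------------------------------------------------------------------

def _true_r1_volume(spec: PhantomSpec, labels: np.ndarray, t_min: float,
                    pre_cr: bool) -> np.ndarray:
    out = np.full(labels.shape, np.nan)
    for name, code in LABELS.items():
        if name == "background":
            continue
        out[labels == code] = tissue_r1_timecourse(name, spec, t_min, pre_cr)
    return out


def generate_study(spec: PhantomSpec, schedule=DEFAULT_SCHEDULE):
    """Generate the full synthetic study.

    Parameters
    ----------
    spec : PhantomSpec
    schedule : sequence of float
        Acquisition midpoints in minutes; negative entries are pre-CR.
        Exactly one pre-CR entry is required.

    Returns
    -------
    (datasets, truth) : (list of VariableTiDataset, PhantomTruth)
    """
    schedule = tuple(float(t) for t in schedule)
    n_pre = sum(t < 0 for t in schedule)
    if n_pre != 1:
        raise ValueError("schedule must contain exactly one pre-CR (negative) entry")
    rng = np.random.default_rng(spec.seed)
    labels_map, pve_map = build_labels(spec, rng)
    labels = labels_map.values
    prot = spec.protocol

    vb = np.full(spec.shape, np.nan)
    for name in _PARENCHYMA:
        vb[labels == LABELS[name]] = spec.v_b[name]
    vb_map = VolumeMap(vb, spec.voxel_size_mm, {"kind": "vb_truth"})

    m0 = np.zeros(spec.shape)
    for name, code in LABELS.items():
        if name == "background":
            continue
        m0[labels == code] = spec.m0[name]
    fg = labels > 0

    post_times = [t for t in schedule if t >= 0]
    blood_curve = BloodInputCurve(
        np.asarray(post_times) * 60.0,
        np.asarray([_blood_r1(spec, t) for t in post_times]),
        r1b0=spec.r1b0, relaxivity_r1=spec.relaxivity_r1,
        hematocrit_h=spec.hematocrit,
    )
    csf_series = np.array([
        tissue_r1_timecourse("ventricle", spec, max(t, 0.0), pre_cr=t < 0)
        for t in schedule
    ])

    datasets, r1_maps = [], []
    for t in schedule:
        pre = t < 0
        r1_true = _true_r1_volume(spec, labels, max(t, 0.0), pre)
        r1_maps.append(VolumeMap(r1_true, spec.voxel_size_mm,
                                 {"kind": "r1_truth",
                                  "acquisition_midpoint_min": t}))
        vols = []
        for ti in prot.ti_list:
            sig = np.zeros(spec.shape)
            # the signal is piecewise constant over labels at fixed time
            for name, code in LABELS.items():
                if name == "background":
                    continue
                sel = labels == code
                r1c = tissue_r1_timecourse(name, spec, max(t, 0.0), pre)
                sig[sel] = abs(mprage_signal(r1c, spec.m0[name], prot, ti))
            if spec.snr is not None and np.isfinite(spec.snr):
                sigma = sig[fg].mean() / spec.snr
                sig = sig + rng.normal(0.0, sigma, size=sig.shape)
            vols.append(VolumeMap(sig, spec.voxel_size_mm,
                                  {"ti_ms": ti, "acquisition_midpoint_min": t}))
        datasets.append(VariableTiDataset(vols, t, prot))

    truth = PhantomTruth(
        labels=labels_map, vb_map=vb_map, r1_maps=r1_maps,
        blood_curve=blood_curve, csf_r1_series=csf_series,
        schedule_min=schedule, ventricle_pve=pve_map, spec=spec,
    )
    return datasets, truth


def flair_like(spec: PhantomSpec, truth: PhantomTruth,
               rng: np.random.Generator | None = None) -> VolumeMap:
    """FLAIR-like intensity volume: lesions bright, CSF nulled, plus noise."""
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    levels = {"background": 0.0, "nawm": 0.55, "dwmh": 0.92, "pwmh": 0.97,
              "ventricle": 0.06, "blood": 0.30}
    labels = truth.labels.values
    img = np.zeros(spec.shape)
    for name, code in LABELS.items():
        img[labels == code] = levels[name]
    if spec.snr is not None and np.isfinite(spec.snr):
        sigma = img[labels > 0].mean() / spec.snr
        img = img + rng.normal(0.0, sigma, size=img.shape)
    return VolumeMap(img, spec.voxel_size_mm, {"kind": "flair_like"})


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_study(outdir, datasets, truth: PhantomTruth) -> dict:
    """Write NIfTI volumes, per-dataset JSON sidecars, truth CSVs and a YAML
    manifest; returns the manifest."""
    import json

    import pandas as pd
    import yaml
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []

    def _write(vol: VolumeMap, name: str):
        path = outdir / name
        vol.to_nifti(path)
        files.append(name)

    _write(truth.labels, "labels.nii.gz")
    _write(truth.vb_map, "vb_truth.nii.gz")
    _write(truth.ventricle_pve, "csf_pve.nii.gz")
    for i, ds in enumerate(datasets):
        for j, vol in enumerate(ds.volumes):
            ti = ds.protocol.ti_list[j]
            tag = "noinv" if ti is None else f"ti{int(ti)}"
            _write(vol, f"tp{i:02d}_{tag}.nii.gz")
        # JSON sidecar: protocol fields + acquisition midpoint
        sidecar = dataclasses.asdict(ds.protocol)
        sidecar["ti_list"] = [t if t is None else float(t)
                              for t in ds.protocol.ti_list]
        sidecar["acquisition_midpoint_min"] = float(ds.acquisition_midpoint_min)
        with open(outdir / f"tp{i:02d}.json", "w") as fh:
            json.dump(_plain(sidecar), fh, indent=2)
        files.append(f"tp{i:02d}.json")
    pd.DataFrame({
        "time_s": truth.blood_curve.times_s,
        "r1b": truth.blood_curve.r1b_values,
    }).to_csv(outdir / "blood_curve.csv", index=False)
    pd.DataFrame({
        "time_min": truth.schedule_min,
        "csf_r1": truth.csf_r1_series,
    }).to_csv(outdir / "csf_r1_truth.csv", index=False)
    files += ["blood_curve.csv", "csf_r1_truth.csv"]

    spec_dict = dataclasses.asdict(truth.spec)
    spec_dict["protocol"] = dataclasses.asdict(truth.spec.protocol)
    spec_dict["protocol"]["ti_list"] = [
        t if t is None else float(t) for t in truth.spec.protocol.ti_list
    ]
    manifest = {
        "spec": _plain(spec_dict),
        "schedule_min": list(truth.schedule_min),
        "files": files,
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    return manifest


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
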