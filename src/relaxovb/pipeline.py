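"""Study-level v_b pipeline: blood curve, voxelwise mapping, region summaries.

The voxelwise product is a fractional-blood-volume map obtained by fitting
each voxel's R1 washout course to the two-site exchange model with the
blood input curve taken from a sagittal-sinus ROI.  Nonphysiological voxels
(v_b < 0 or > 20 mL/100 g) are excluded afterwards, and per-region mean
v_b is reported from a fitted distribution: Gaussian if the voxel values
are normal (directly or after a log or square-root transform), otherwise
the better of maximum-likelihood gamma and Weibull fits by AIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from . import exchange
from .exchange import BloodInputCurve, fit_vb_many
from .volumes import VolumeMap

__all__ = [
    "RegionVbSummary",
    "VB_PHYSIOLOGICAL_RANGE",
    "extract_blood_curve",
    "map_vb",
    "exclude_nonphysiological",
    "region_mean_vb",
]

#: Physiological range of v_b in mL/100 g; values outside are excluded.
VB_PHYSIOLOGICAL_RANGE = (0.0, 20.0)


@dataclass
class RegionVbSummary:
    """Per-region-class v_b summary after exclusion and distribution fitting."""

    region: str
    n_before: int
    n_after: int
    excluded_fraction_pct: float
    family: str  # 'gaussian', 'gaussian(log)', 'gaussian(sqrt)', 'gamma', 'weibull', 'degenerate', 'low-n'
    mean_vb_ml_per_100g: float
    dispersion: float  # SD of the fitted distribution, mL/100 g

    def summary(self) -> str:
        lines = [
            f"Region {self.region}",
            f"  voxels (kept/total)   {self.n_after}/{self.n_before}",
            f"  excluded              {self.excluded_fraction_pct:.1f}%",
            f"  distribution          {self.family}",
            f"  mean v_b              {self.mean_vb_ml_per_100g:.2f} mL/100 g",
            f"  dispersion (SD)       {self.dispersion:.2f} mL/100 g",
        ]
        return "\n".join(lines)


def extract_blood_curve(r1_maps, sinus_roi, r1b0: float | None = None,
                        relaxivity_r1: float = exchange.RELAXIVITY_R1_DEFAULT,
                        hematocrit_h: float = exchange.HEMATOCRIT_DEFAULT,
                        labels: VolumeMap | None = None,
                        blood_label: int | None = None) -> BloodInputCurve:
    """Blood input curve from a sagittal-sinus ROI across R1 maps.

    Parameters
    ----------
    r1_maps : list of VolumeMap
        Per-timepoint R1 maps carrying ``acquisition_midpoint_min`` metadata;
        the pre-CR map (negative midpoint) provides R1b(0) unless ``r1b0``
        is given explicitly.
    sinus_roi : (n, 3) integer voxel indices
        ROI contained entirely within the sagittal sinus.
    labels, blood_label : optional
        If provided, warn when the ROI touches non-blood labels.
    """
    roi = np.asarray(sinus_roi, dtype=int)
    if roi.size == 0:
        raise ValueError("sinus ROI is empty")
    ix = tuple(roi.T)
    if labels is not None and blood_label is not None:
        if np.any(labels.values[ix] != blood_label):
            warnings.warn("sinus ROI touches non-blood voxels")
    times, means = [], []
    pre_means = []
    for vol in r1_maps:
        t = float(vol.meta.get("acquisition_midpoint_min"))
        vals = np.asarray(vol.values, dtype=float)[ix]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"sinus ROI has no fitted voxels at t={t} min")
        if t < 0:
            pre_means.append(vals.mean())
        else:
            times.append(t * 60.0)
            means.append(vals.mean())
    if r1b0 is None:
        if not pre_means:
            raise ValueError("no pre-CR map to measure R1b(0) from")
        r1b0 = float(np.mean(pre_means))
    order = np.argsort(times)
    return BloodInputCurve(
        np.asarray(times)[order], np.asarray(means)[order], r1b0=r1b0,
        relaxivity_r1=relaxivity_r1, hematocrit_h=hematocrit_h,
    )


def map_vb(r1_maps, curve: BloodInputCurve, mask: VolumeMap,
           tau_b: float = exchange.TAU_B_DEFAULT,
           f_w: float = exchange.F_W_DEFAULT) -> VolumeMap:
    """Voxelwise v_b map (dimensionless fraction) inside ``mask``.

    Requires the pre-CR R1 map plus >= 2 post-CR maps; out-of-range
    estimates are retained (exclusion happens downstream).  Voxels with any
    non-finite R1 are left as NaN.
    """
    pre = [v for v in r1_maps if float(v.meta.get("acquisition_midpoint_min")) < 0]
    post = sorted(
        (v for v in r1_maps if float(v.meta.get("acquisition_midpoint_min")) >= 0),
        key=lambda v: float(v.meta["acquisition_midpoint_min"]),
    )
    if len(pre) != 1:
        raise ValueError("exactly one pre-CR R1 map is required")
    if len(post) < 2:
        raise ValueError("need >= 2 post-CR R1 maps")
    if len(post) != curve.n_post:
        raise ValueError("number of post-CR maps must match the blood curve")
    ref = pre[0]
    ref.require_same_grid(mask, "mask")
    for v in post:
        ref.require_same_grid(v, "R1 map")
    m = np.asarray(mask.values, dtype=bool)
    out = np.full(ref.shape, np.nan)
    if m.any():
        r1t0 = np.asarray(ref.values, dtype=float)[m]
        r1t = np.stack([np.asarray(v.values, dtype=float)[m] for v in post], axis=1)
        good = np.isfinite(r1t0) & np.all(np.isfinite(r1t), axis=1)
        vb = np.full(r1t0.size, np.nan)
        if good.any():
            vb[good] = fit_vb_many(r1t0[good], r1t[good], curve,
                                   tau_b=tau_b, f_w=f_w)
        out[m] = vb
    return VolumeMap(out, ref.voxel_size_mm, {"kind": "vb"})


def exclude_nonphysiological(vb_values_ml_per_100g):
    """Apply the physiological v_b filter (keep 0 <= v_b <= 20 mL/100 g).

    Returns ``(kept_values, excluded_fraction_pct)``.  NaN values (non-fit
    voxels) are dropped before the rule is applied and do not count as
    excluded.
    """
    vals = np.asarray(vb_values_ml_per_100g, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return vals, 0.0
    lo, hi = VB_PHYSIOLOGICAL_RANGE
    keep = (vals >= lo) & (vals <= hi)
    return vals[keep], float(100.0 * np.count_nonzero(~keep) / vals.size)


def _shapiro_normal(vals: np.ndarray, alpha: float, rng_cap: int = 5000) -> bool:
    v = vals if vals.size <= rng_cap else np.random.default_rng(0).choice(
        vals, rng_cap, replace=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sps.shapiro(v).pvalue > alpha


def region_mean_vb(vb_values_ml_per_100g, region: str = "",
                   alpha: float = 0.05) -> RegionVbSummary:
    """Mean v_b of a region class by distribution fitting.

    The kept voxel values are tested for normality (Shapiro-Wilk at
    ``alpha``, subsampled to 5000 voxels); if normal -- directly or after a
    log or square-root transform -- the Gaussian mean is reported
    (back-transformed where applicable).  Otherwise gamma and Weibull
    distributions are fitted by maximum likelihood and the lower-AIC
    family's mean is reported.
    """
    raw = np.asarray(vb_values_ml_per_100g, dtype=float)
    kept, excl = exclude_nonphysiological(raw)
    n_before = int(np.isfinite(raw).sum())
    n = kept.size

    def make(family, mean, sd):
        return RegionVbSummary(region, n_before, n, excl, family,
                               float(mean), float(sd))

    if n < 20:
        return make("low-n", kept.mean() if n else np.nan,
                    kept.std() if n else np.nan)
    if np.ptp(kept) == 0:
        return make("degenerate", kept[0], 0.0)

    if _shapiro_normal(kept, alpha):
        return make("gaussian", *sps.norm.fit(kept))
    positive = kept[kept > 0]
    if positive.size == n and _shapiro_normal(np.log(positive), alpha):
        mu, sd = sps.norm.fit(np.log(positive))
        return make("gaussian(log)", np.exp(mu + 0.5 * sd ** 2),
                    np.sqrt((np.exp(sd ** 2) - 1) * np.exp(2 * mu + sd ** 2)))
    if np.all(kept >= 0) and _shapiro_normal(np.sqrt(kept), alpha):
        mu, sd = sps.norm.fit(np.sqrt(kept))
        mean = mu ** 2 + sd ** 2
        var = 2 * sd ** 4 + 4 * mu ** 2 * sd ** 2
        return make("gaussian(sqrt)", mean, np.sqrt(var))

    # bounded, non-negative families by maximum likelihood
    fits = {}
    data = positive if positive.size else np.maximum(kept, 1e-12)
    for family, dist in (("gamma", sps.gamma), ("weibull", sps.weibull_min)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            params = dist.fit(data, floc=0)
            ll = np.sum(dist.logpdf(data, *params))
        fits[family] = (params, 2 * 2 - 2 * ll, dist)
    family = min(fits, key=lambda f: fits[f][1])
    params, _, dist = fits[family]
    return make(family, dist.mean(*params), dist.std(*params))
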