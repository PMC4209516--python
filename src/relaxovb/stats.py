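"""Monte Carlo error propagation, SNR estimation, and group statistics.

Monte Carlo conventions follow the acquisition-noise recipe: zero-mean
Gaussian noise with standard deviation = signal/SNR added to each TI signal
for R1 uncertainty, and R1(t) perturbation (uniform within +/-1 SD by
default, Gaussian optional) for v_b uncertainty.  "Relative variance" is
reported as the variance divided by the squared mean, in percent (the
squared coefficient of variation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exchange import BloodInputCurve, VoxelRelaxationSeries, fit_vb_many
from .mprage import MprageProtocol, fit_r1_many
from .volumes import VolumeMap

__all__ = [
    "MonteCarloReport",
    "estimate_snr",
    "monte_carlo_r1",
    "monte_carlo_vb",
    "within_subject_anova",
    "paired_tests_modified_bonferroni",
    "regression_r2",
    "outlier_flags",
    "water_fraction_ratio",
]


@dataclass
class MonteCarloReport:
    """Summary of one Monte Carlo uncertainty run."""

    n_replicates: int
    snr_used: float | None
    relative_variance_pct: float  # 100 * var / mean^2
    mean: float
    sd: float
    seed: int
    quantity: str  # 'r1' or 'v_b'

    def __post_init__(self) -> None:
        if self.n_replicates < 100:
            raise ValueError("Monte Carlo runs require >= 100 replicates")


def relative_variance_pct(samples: np.ndarray) -> float:
    """100 * var / mean^2 (squared coefficient of variation, %)."""
    samples = np.asarray(samples, dtype=float)
    m = samples.mean()
    return float(100.0 * samples.var() / m ** 2)


# ---------------------------------------------------------------------------
# SNR and Monte Carlo propagation
# ---------------------------------------------------------------------------

def estimate_snr(volume: VolumeMap, foreground_mask: VolumeMap,
                 background_mask: VolumeMap, method: str = "mean") -> float:
    """Signal-background SNR of an image volume.

    The noise scale is estimated from background voxels outside the object.
    With ``method='mean'`` (default) the Gaussian noise SD is recovered from
    the mean absolute background value via the half-normal correction
    sigma = mean(|bg|) * sqrt(pi/2); ``method='std'`` uses the raw background
    standard deviation.  SNR = mean(foreground) / sigma.
    """
    volume.require_same_grid(foreground_mask, "foreground mask")
    volume.require_same_grid(background_mask, "background mask")
    fg = np.asarray(foreground_mask.values, dtype=bool)
    bg = np.asarray(background_mask.values, dtype=bool)
    if np.count_nonzero(bg) < 100:
        raise ValueError("background mask must contain >= 100 voxels")
    vals = np.asarray(volume.values, dtype=float)
    if method == "mean":
        sigma = np.abs(vals[bg]).mean() * np.sqrt(np.pi / 2.0)
    elif method == "std":
        sigma = vals[bg].std()
    else:
        raise ValueError(f"unknown method {method!r}")
    if sigma == 0:
        raise ValueError("zero background noise: SNR undefined")
    return float(vals[fg].mean() / sigma)


def monte_carlo_r1(signals, protocol: MprageProtocol, snr: float,
                   n: int = 1000, seed: int = 0) -> MonteCarloReport:
    """R1 uncertainty by refitting noise-perturbed variable-TI signals.

    Per replicate, each TI signal s_i receives zero-mean Gaussian noise with
    SD = s_i / SNR; R1 is refit and the relative variance of the fitted R1
    across replicates is reported.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    signals = np.asarray(signals, dtype=float)
    rng = np.random.default_rng(seed)
    noisy = np.abs(signals[None, :]
                   + rng.normal(0.0, np.abs(signals) / snr, size=(n, signals.size)))
    r1 = fit_r1_many(noisy, protocol)
    return MonteCarloReport(
        n_replicates=n, snr_used=snr,
        relative_variance_pct=relative_variance_pct(r1),
        mean=float(r1.mean()), sd=float(r1.std()), seed=seed, quantity="r1",
    )


def monte_carlo_vb(series: VoxelRelaxationSeries, curve: BloodInputCurve,
                   r1_sd, n: int = 1000, seed: int = 0,
                   tau_b: float | None = None, f_w: float | None = None,
                   distribution: str = "uniform") -> MonteCarloReport:
    """v_b uncertainty by refitting perturbed R1(t) series.

    Each post-CR R1(t) value is perturbed within +/-1 SD (uniform by
    default, matching the sampling description; ``distribution='gaussian'``
    uses Gaussian draws with that SD) and v_b is refit.
    """
    from . import exchange

    tau_b = exchange.TAU_B_DEFAULT if tau_b is None else tau_b
    f_w = exchange.F_W_DEFAULT if f_w is None else f_w
    r1_sd = np.broadcast_to(np.asarray(r1_sd, dtype=float),
                            series.r1t_values.shape)
    rng = np.random.default_rng(seed)
    if distribution == "uniform":
        delta = rng.uniform(-1.0, 1.0, size=(n, r1_sd.size)) * r1_sd
    elif distribution == "gaussian":
        delta = rng.normal(0.0, 1.0, size=(n, r1_sd.size)) * r1_sd
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    perturbed = series.r1t_values[None, :] + delta
    vb = fit_vb_many(np.full(n, series.r1t0), perturbed, curve,
                     tau_b=tau_b, f_w=f_w)
    return MonteCarloReport(
        n_replicates=n, snr_used=None,
        relative_variance_pct=relative_variance_pct(vb),
        mean=float(vb.mean()), sd=float(vb.std()), seed=seed, quantity="v_b",
    )


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def within_subject_anova(values: np.ndarray):
    """One-way within-subject (repeated measures) ANOVA.

    Parameters
    ----------
    values : (n_subjects, k_conditions) array
        Complete cases only (every subject measured in every condition).

    Returns
    -------
    (F, (df1, df2), p)
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 2:
        raise ValueError("values must be a subjects x conditions table")
    n, k = y.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if np.any(~np.isfinite(y)):
        raise ValueError("complete cases only: table contains missing values")
    grand = y.mean()
    ss_cond = n * np.sum((y.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((y.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err == 0:
        f = 0.0 if ms_cond == 0 else np.inf
    else:
        f = ms_cond / ms_err
    p = float(sps.f.sf(f, df1, df2))
    return float(f), (df1, df2), p


def paired_tests_modified_bonferroni(pairs, alpha: float = 0.05,
                                     method: str = "hochberg"):
    """Post-hoc paired t-tests with step-up multiple-comparison adjustment.

    ``pairs`` is a sequence of (name, a, b) or (a, b) paired samples.  The
    sequentially rejective ("modified Bonferroni") adjustment is Hochberg's
    step-up procedure by default; Holm's step-down is available.

    Returns a list of dicts with t, raw p, adjusted p and the decision at
    familywise level ``alpha``.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 paired comparisons")
    names, stats_, pvals = [], [], []
    for i, pair in enumerate(pairs):
        if len(pair) == 3:
            name, a, b = pair
        else:
            a, b = pair
            name = f"pair{i}"
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ValueError(f"{name}: paired samples must have equal length")
        if np.allclose(a, b):
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(a, b)
        names.append(name)
        stats_.append(float(t))
        pvals.append(float(p))
    mt_method = {"hochberg": "simes-hochberg", "holm": "holm"}[method]
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method=mt_method)
    return [
        {"name": nm, "t": t, "p_raw": p, "p_adjusted": float(pa),
         "significant": bool(r)}
        for nm, t, p, pa, r in zip(names, stats_, pvals, p_adj, reject)
    ]


def regression_r2(x, y):
    """Ordinary least-squares regression: (slope, r^2, p) with a two-sided
    test of the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: slope undefined")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.rvalue ** 2), float(res.pvalue)


def outlier_flags(data: np.ndarray, response_col: int | None = None,
                  chi2_q: float = 0.975):
    """Distributional outliers by Mahalanobis and Cook's distance.

    Mahalanobis distance of each row against the column mean/covariance is
    compared with the chi-square(p) quantile ``chi2_q``; Cook's distance
    from an OLS fit of ``response_col`` (default: last column) on the
    remaining columns is compared with 4/n.  The union is flagged.

    Returns a dict with boolean arrays 'mahalanobis', 'cooks' and 'flagged'.
    """
    import statsmodels.api as sm

    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be a 2-D table")
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need n > p + 1 observations")
    cov = np.cov(X, rowvar=False)
    if np.linalg.matrix_rank(np.atleast_2d(cov)) < p:
        raise ValueError("singular covariance matrix")
    delta = X - X.mean(axis=0)
    d2 = np.einsum("ij,jk,ik->i", delta, np.linalg.inv(np.atleast_2d(cov)), delta)
    maha = d2 > sps.chi2.ppf(chi2_q, df=p)

    if response_col is None:
        response_col = p - 1
    ycol = X[:, response_col]
    Xcols = np.delete(X, response_col, axis=1)
    model = sm.OLS(ycol, sm.add_constant(Xcols)).fit()
    cooks = model.get_influence().cooks_distance[0] > 4.0 / n
    return {"mahalanobis": maha, "cooks": cooks, "flagged": maha | cooks}


def water_fraction_ratio(t1_a_ms: float, t1_b_ms: float) -> float:
    """Percent water-fraction difference implied by two T1 values.

    Under a linear dependence of R1 on tissue water fraction (and T1
    differences attributed solely to water content), the water fraction is
    proportional to T1, so the percent difference is 100 * (T1_a/T1_b - 1).
    """
    if t1_a_ms <= 0 or t1_b_ms <= 0:
        raise ValueError("T1 values must be positive")
    return 100.0 * (t1_a_ms / t1_b_ms - 1.0)
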