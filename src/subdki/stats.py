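"""Evaluation statistics: goodness of fit, dispersion, contrast, reproducibility.

* ``r_squared`` — coefficient of determination of fitted against true
  (simulated) kurtosis, with the total sum of squares taken about the mean
  of the *true* values.  Negative values are possible (and meaningful) for
  badly chosen sampling schemes.
* ``pooled_region_stats`` — voxel-count-weighted mean and within-subject
  pooled SD over subjects, with CV reported in percent.
* ``tissue_contrast`` — ``|mu_WM - mu_GM| / sqrt(sd_WM^2 + sd_GM^2)``.
* ``icc_voxelwise`` — scan-rescan intraclass correlation per voxel,
  ``ICC = s_inter^2 / (s_intra^2 + s_inter^2)``, with the intra-subject
  variance taken as the mean half squared deviation of scan and rescan about
  the subject mean and the inter-subject variance as the variance of subject
  means across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = [
    "RegionStats",
    "ICCResult",
    "r_squared",
    "pooled_region_stats",
    "tissue_contrast",
    "icc_voxelwise",
    "welch_ttest",
]


@dataclass(frozen=True)
class RegionStats:
    """Pooled summary of one region across subjects."""

    region_id: object
    n_vox: int
    mean: float
    sd: float

    @property
    def cv(self) -> float:
        """Coefficient of variation, percent."""
        return 100.0 * self.sd / self.mean


@dataclass
class ICCResult:
    """Voxelwise scan-rescan reproducibility summary."""

    icc: np.ndarray          # per-voxel ICC map (NaN outside mask)
    mu: float                # mean ICC over the mask
    sigma: float             # SD of ICC over the mask
    s2_intra: np.ndarray
    s2_inter: np.ndarray


def r_squared(true_values, fitted_values) -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot``.

    ``SS_tot`` is taken about the mean of the true values.  Errors on
    degenerate input (fewer than two points, or zero variance in the truth,
    where the ratio is undefined).
    """
    t = np.asarray(true_values, dtype=float).ravel()
    f = np.asarray(fitted_values, dtype=float).ravel()
    if t.size != f.size:
        raise ValueError("true and fitted vectors must have equal length")
    if t.size < 2:
        raise ValueError("need at least 2 points")
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("true values have zero variance; R^2 undefined")
    ss_res = float(np.sum((t - f) ** 2))
    return 1.0 - ss_res / ss_tot


def pooled_region_stats(values_by_subject, region_id=None) -> RegionStats:
    """Voxel-count-weighted mean and pooled within-subject SD over subjects.

    ``values_by_subject`` is a sequence of 1-D arrays of voxel values, one
    per subject.  The mean is weighted by each subject's voxel count; the SD
    pools within-subject variances with weights ``n_i - 1`` (so subjects
    contributing a single voxel add no variance information).
    """
    arrs = [np.asarray(v, dtype=float).ravel() for v in values_by_subject]
    if not arrs or any(a.size == 0 for a in arrs):
        raise ValueError("every subject must contribute at least one voxel")
    n = np.array([a.size for a in arrs])
    means = np.array([a.mean() for a in arrs])
    mean = float(np.sum(n * means) / np.sum(n))
    dof = np.sum(n - 1)
    if dof > 0:
        variances = np.array([a.var(ddof=1) if a.size > 1 else 0.0
                              for a in arrs])
        sd = float(np.sqrt(np.sum((n - 1) * variances) / dof))
    else:
        sd = 0.0
    return RegionStats(region_id=region_id, n_vox=int(np.sum(n)),
                       mean=mean, sd=sd)


def tissue_contrast(mu_wm: float, sd_wm: float, mu_gm: float,
                    sd_gm: float) -> float:
    """Tissue contrast ``|mu_WM - mu_GM| / sqrt(sd_WM^2 + sd_GM^2)``."""
    denom = np.sqrt(sd_wm ** 2 + sd_gm ** 2)
    if denom == 0:
        raise ValueError("both SDs are zero; contrast undefined")
    return float(abs(mu_wm - mu_gm) / denom)


def icc_voxelwise(scan_maps, rescan_maps, mask=None,
                  inter_ddof: int = 0) -> ICCResult:
    """Scan-rescan intraclass correlation per voxel across subjects.

    ``scan_maps`` and ``rescan_maps`` are arrays of shape
    ``(n_subjects, ...)`` holding co-registered metric maps (alignment is
    assumed; registration is out of scope).  Per voxel:

        m_bar_i  = (scan_i + rescan_i) / 2
        s_intra^2 = mean_i [ ((scan_i - m_bar_i)^2 + (rescan_i - m_bar_i)^2) / 2 ]
        s_inter^2 = var_i (m_bar_i)
        ICC      = s_inter^2 / (s_intra^2 + s_inter^2)

    ``inter_ddof`` selects population (0, default) or sample (1) variance
    for the inter-subject term.  Voxels where both variance components
    vanish get ICC = NaN.
    """
    scan = np.asarray(scan_maps, dtype=float)
    rescan = np.asarray(rescan_maps, dtype=float)
    if scan.shape != rescan.shape:
        raise ValueError("scan and rescan stacks must have identical shape")
    if scan.ndim < 2 or scan.shape[0] < 2:
        raise ValueError("need at least 2 subjects along the first axis")
    m_bar = 0.5 * (scan + rescan)
    s2_intra = np.mean(0.5 * ((scan - m_bar) ** 2 + (rescan - m_bar) ** 2),
                       axis=0)
    s2_inter = np.var(m_bar, axis=0, ddof=inter_ddof)
    denom = s2_intra + s2_inter
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = np.where(denom > 0, s2_inter / denom, np.nan)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != icc.shape:
            raise ValueError("mask shape must match the voxel grid")
        icc = np.where(mask, icc, np.nan)
    valid = icc[np.isfinite(icc)]
    mu = float(valid.mean()) if valid.size else float("nan")
    sigma = float(valid.std()) if valid.size else float("nan")
    return ICCResult(icc=icc, mu=mu, sigma=sigma,
                     s2_intra=s2_intra, s2_inter=s2_inter)


def welch_ttest(a, b):
    """Two-sample Welch t-test (thin wrapper; returns (statistic, p-value))."""
    res = _sps.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                         equal_var=False)
    return float(res.statistic), float(res.pvalue)
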