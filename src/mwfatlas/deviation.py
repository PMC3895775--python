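"""Deviation of individuals and groups from the normative MWF atlas.

An individual's MWF volume is compared voxel-wise against the age-matched
atlas prediction by the Z-statistic

    Z_i = (x_i - u_i) / s_i,

where x_i is the subject's MWF, u_i the model-derived mean MWF and s_i the
model-derived dMWF at the same voxel.  |Z| >= 1.96 flags two-sided p < 0.05
deviation.  Statistics are restricted to a white-matter mask: voxels whose
mean MWF reaches 0.02 (the boundary is in-mask).

Note that a denominator built purely from parameter uncertainty (dMWF)
shrinks as the normative cohort grows and will inflate Z for any fixed
individual scatter; callers who want Z calibrated against individual
variability should pass a prediction-scale SD map, sqrt(dMWF^2 +
sigma_resid^2), as ``sd_map`` instead.  Both are accepted.

Group-level comparison is a paired test on voxel-wise differences between
in-vivo and model-derived volumes, with the null built by random sign flips
of the paired differences (the standard one-sample permutation scheme for
paired data); an uncorrected two-sided p-value per voxel is returned,
alongside the parametric paired-t p-value for reference.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .atlas import VolumeImage, _check_common_grid

logger = logging.getLogger(__name__)

__all__ = ["ZMap", "wm_mask", "z_map", "group_paired_test", "PairedTestResult"]

#: two-sided p = 0.05 normal critical value used for Z-map flagging
Z_CRITICAL_95 = float(stats.norm.ppf(1.0 - 0.05 / 2.0))


@dataclasses.dataclass
class ZMap:
    """Voxel-wise standardized deviation of one subject from the atlas."""

    z_values: np.ndarray
    mask: np.ndarray
    subject_id: str
    age_days: Optional[float]
    threshold: float
    n_significant: int
    frac_significant: float

    def summary(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "age_days": self.age_days,
            "threshold": self.threshold,
            "n_in_mask": int(self.mask.sum()),
            "n_significant": self.n_significant,
            "frac_significant": self.frac_significant,
        }


def wm_mask(mean_img: VolumeImage, threshold: float = 0.02) -> np.ndarray:
    """White-matter mask: voxels whose mean MWF reaches the threshold.

    Values *below* the threshold are excluded; the boundary value itself is
    kept in-mask.  NaN (no-data) voxels are excluded.
    """
    with np.errstate(invalid="ignore"):
        return np.asarray(mean_img.voxels >= threshold)


def z_map(
    subject: VolumeImage,
    mean_map: VolumeImage,
    sd_map: VolumeImage,
    mask: Optional[np.ndarray] = None,
    threshold: float = Z_CRITICAL_95,
) -> ZMap:
    """Z-statistic map of one subject against atlas mean and SD maps.

    Voxels where the SD map is zero or non-finite cannot be standardized
    and are dropped from the mask with a logged count.  Out-of-mask voxels
    carry NaN.
    """
    _check_common_grid([subject, mean_map, sd_map])
    if mask is None:
        mask = wm_mask(subject)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != subject.shape:
        raise ValueError("mask grid does not match the image grid")

    with np.errstate(invalid="ignore"):
        finite = (
            np.isfinite(subject.voxels)
            & np.isfinite(mean_map.voxels)
            & np.isfinite(sd_map.voxels)
            & (sd_map.voxels > 0)
        )
    dropped = int(np.sum(mask & ~finite))
    if dropped:
        logger.info(
            "z_map: dropped %d voxel(s) with zero/non-finite SD from the mask",
            dropped,
        )
    mask = mask & finite

    z = np.full(subject.shape, np.nan)
    z[mask] = (subject.voxels[mask] - mean_map.voxels[mask]) / sd_map.voxels[mask]
    n_in_mask = int(mask.sum())
    n_sig = int(np.sum(np.abs(z[mask]) >= threshold))
    return ZMap(
        z_values=z,
        mask=mask,
        subject_id=subject.subject_id or "",
        age_days=subject.age_days,
        threshold=float(threshold),
        n_significant=n_sig,
        frac_significant=n_sig / n_in_mask if n_in_mask else float("nan"),
    )


@dataclasses.dataclass
class PairedTestResult:
    """Voxel-wise paired-comparison output (uncorrected)."""

    p_values: np.ndarray  # sign-flip permutation, two-sided
    t_values: np.ndarray  # observed paired-t statistic
    p_parametric: np.ndarray  # Student-t reference p-values
    mask: np.ndarray
    n_pairs: int
    n_permutations: int
    seed: int


def group_paired_test(
    group: Sequence[VolumeImage],
    model_maps: Sequence[VolumeImage],
    mask: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
) -> PairedTestResult:
    """Sign-flip permutation paired test of in-vivo vs model-derived volumes.

    Per voxel, paired differences d_j = in_vivo_j - model_j give the
    statistic t = mean(d) / SE(d).  The null distribution is built from
    ``n_permutations`` random sign-flip vectors applied to the d_j, and the
    two-sided p-value is (1 + #{|t*| >= |t|}) / (1 + n_permutations).
    Zero-variance voxels get p = 1 with a logged count.
    """
    group, model_maps = list(group), list(model_maps)
    if len(group) != len(model_maps):
        raise ValueError("group and model_maps must have equal length")
    n = len(group)
    if n < 3:
        raise ValueError("paired test needs at least 3 pairs")
    _check_common_grid(group + model_maps)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != group[0].shape:
        raise ValueError("mask grid does not match the image grid")

    d = np.stack(
        [g.voxels[mask] - m.voxels[mask] for g, m in zip(group, model_maps)]
    )  # (n, V)
    sumsq = np.sum(d * d, axis=0)

    def t_stat(signed_mean: np.ndarray) -> np.ndarray:
        # Sign flips leave sum(d^2) invariant; only the mean changes.
        var = (sumsq - n * signed_mean**2) / (n - 1)
        se = np.sqrt(np.maximum(var, 0.0) / n)
        with np.errstate(invalid="ignore", divide="ignore"):
            return signed_mean / se

    mean_obs = d.mean(axis=0)
    t_obs = t_stat(mean_obs)

    rng = np.random.default_rng(seed)
    abs_t_obs = np.abs(t_obs)
    exceed = np.zeros(d.shape[1], dtype=np.int64)
    for _ in range(n_permutations):
        signs = rng.integers(0, 2, size=n) * 2 - 1
        t_perm = t_stat(signs @ d / n)
        with np.errstate(invalid="ignore"):
            exceed += np.abs(t_perm) >= abs_t_obs
    p = (1.0 + exceed) / (1.0 + n_permutations)

    # A zero-variance difference leaves the t statistic undefined; those
    # voxels are conservatively assigned p = 1 and flagged.
    degenerate = sumsq - n * mean_obs**2 <= 0
    if degenerate.any():
        logger.info(
            "group_paired_test: %d zero-variance voxel(s) set to p=1",
            int(degenerate.sum()),
        )
    p[degenerate] = 1.0
    t_obs = np.where(degenerate, 0.0, t_obs)

    with np.errstate(invalid="ignore"):
        p_param = 2.0 * stats.t.sf(np.abs(t_obs), df=n - 1)
    p_param = np.where(degenerate, 1.0, p_param)

    out_p = np.full(mask.shape, np.nan)
    out_t = np.full(mask.shape, np.nan)
    out_pp = np.full(mask.shape, np.nan)
    out_p[mask] = p
    out_t[mask] = t_obs
    out_pp[mask] = p_param
    return PairedTestResult(
        p_values=out_p,
        t_values=out_t,
        p_parametric=out_pp,
        mask=mask,
        n_pairs=n,
        n_permutations=n_permutations,
        seed=seed,
    )
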