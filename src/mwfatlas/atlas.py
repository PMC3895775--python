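"""Continuous age-queryable MWF atlas from voxel-wise growth-model fits.

Given a stack of spatially aligned MWF volumes with per-subject ages, each
voxel's (age, MWF) trajectory is fit independently with the selected growth
model and wild-bootstrapped, yielding 3-D fields of mean parameters and
parameter uncertainties.  Those fields constitute a 4-D atlas: evaluating
the model at any age produces a representative mean MWF volume, and
delta-method propagation of the per-voxel parameter SDs produces the
matching dMWF (uncertainty) volume.  Input volumes are smoothed with a 3 mm
FWHM Gaussian kernel before fitting, mirroring standard practice.

Voxels are eligible for fitting when their across-age maximum MWF reaches
``min_mwf`` (default 0.02, the white-matter threshold); background and
failed-fit voxels are excluded by ``fit_mask`` and flagged NaN in all
output maps.  Per-voxel bootstrap seeds are derived reproducibly from the
master seed and the voxel's linear index, so results do not depend on
traversal or parallelization order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from typing import Dict, List, Optional, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .growth_models import GrowthModel, get_model
from .model_fitting import FitOptions, TrajectoryData, fit_model
from .uncertainty import wild_bootstrap

logger = logging.getLogger(__name__)

__all__ = [
    "VolumeImage",
    "ParameterAtlas",
    "smooth_volume",
    "fit_voxelwise",
    "predict_mwf_map",
    "predict_uncertainty_map",
    "extract_regional_means",
    "load_volume",
    "save_volume",
    "load_stack",
    "save_atlas",
    "load_atlas",
]

#: FWHM-to-sigma conversion for a Gaussian kernel
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclasses.dataclass
class VolumeImage:
    """A 3-D MWF volume with voxel geometry and optional subject metadata.

    Voxel values are MWF fractions; values outside [0, 1] are clipped on
    construction with a logged count (NaN no-data flags pass through).
    """

    voxels: np.ndarray
    voxel_size_mm: np.ndarray = dataclasses.field(
        default_factory=lambda: np.ones(3)
    )
    age_days: Optional[float] = None
    subject_id: Optional[str] = None
    #: set False for volumes whose values are not MWF fractions (e.g. dMWF
    #: uncertainty maps), which must not be clipped
    clip: bool = True

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array")
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=float)
        if self.voxel_size_mm.shape != (3,) or np.any(self.voxel_size_mm <= 0):
            raise ValueError("voxel_size_mm must be a positive 3-vector")
        if self.clip:
            out_of_range = np.nansum((self.voxels < 0) | (self.voxels > 1))
            if out_of_range:
                logger.info("clipped %d voxel(s) outside [0, 1]", int(out_of_range))
                self.voxels = np.clip(self.voxels, 0.0, 1.0)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.voxels.shape


@dataclasses.dataclass
class ParameterAtlas:
    """Per-voxel growth-model parameter and uncertainty fields.

    ``param_fields`` and ``param_sd_fields`` have shape (n_params, X, Y, Z);
    both are NaN where ``fit_mask`` is False.  ``age_validity`` records the
    age span of the training stack; queries outside it warn (extrapolation).
    """

    model: GrowthModel
    param_fields: np.ndarray
    param_sd_fields: np.ndarray
    fit_mask: np.ndarray
    n_resamples: int
    age_validity: Tuple[float, float]
    voxel_size_mm: np.ndarray = dataclasses.field(
        default_factory=lambda: np.ones(3)
    )
    seed: int = 0

    def __post_init__(self):
        k = self.model.n_params
        if self.param_fields.shape[0] != k or self.param_sd_fields.shape[0] != k:
            raise ValueError("parameter field count does not match the model")
        if self.param_fields.shape[1:] != self.fit_mask.shape:
            raise ValueError("parameter fields and mask must share one grid")

    @property
    def grid_shape(self) -> Tuple[int, int, int]:
        return self.fit_mask.shape


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------


def smooth_volume(img: VolumeImage, fwhm_mm: float = 3.0) -> VolumeImage:
    """Gaussian-smooth a volume with a kernel of the given FWHM in mm.

    Sigma per axis is fwhm * (2*sqrt(2*ln 2))^-1 converted to voxel units.
    Reflective boundary handling conserves total intensity.  A FWHM below
    half a voxel (per axis) is treated as the identity on that axis.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    sigma_vox = np.where(
        fwhm_mm < 0.5 * img.voxel_size_mm,
        0.0,
        fwhm_mm * _FWHM_TO_SIGMA / img.voxel_size_mm,
    )
    if np.all(sigma_vox == 0.0):
        smoothed = img.voxels.copy()
    else:
        smoothed = ndimage.gaussian_filter(img.voxels, sigma=sigma_vox, mode="reflect")
    return VolumeImage(
        voxels=smoothed,
        voxel_size_mm=img.voxel_size_mm.copy(),
        age_days=img.age_days,
        subject_id=img.subject_id,
    )


# ---------------------------------------------------------------------------
# Voxel-wise fitting
# ---------------------------------------------------------------------------


def _voxel_seed(master_seed: int, flat_index: int) -> int:
    """Reproducible per-voxel seed, independent of traversal order."""
    ss = np.random.SeedSequence([int(master_seed), int(flat_index)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _check_common_grid(stack: Sequence[VolumeImage]) -> None:
    shapes = {v.shape for v in stack}
    sizes = {tuple(v.voxel_size_mm) for v in stack}
    if len(shapes) != 1 or len(sizes) != 1:
        raise ValueError("all volumes must share one grid and voxel size")


def fit_voxelwise(
    stack: Sequence[VolumeImage],
    model: GrowthModel,
    n_resamples: int = 5000,
    min_mwf: float = 0.02,
    seed: int = 0,
    fit_options: Optional[FitOptions] = None,
    weight_law: str = "rademacher",
) -> ParameterAtlas:
    """Fit the growth model at every eligible voxel and bootstrap each fit.

    Eligibility: the voxel's across-age maximum MWF must reach ``min_mwf``.
    ``n_resamples=0`` skips the bootstrap and reports zero parameter SDs
    (useful for noiseless round-trip checks); otherwise each voxel gets its
    own wild bootstrap with a seed derived from ``seed`` and the voxel's
    linear index.
    """
    stack = list(stack)
    if not stack:
        raise ValueError("empty volume stack")
    _check_common_grid(stack)
    ages = np.array([v.age_days for v in stack], dtype=float)
    if np.any(~np.isfinite(ages)):
        raise ValueError("every volume in the stack needs an age_days")
    if len(stack) < model.n_params + 2:
        raise ValueError(
            f"need at least n_params + 2 = {model.n_params + 2} subjects"
        )
    fit_options = fit_options or FitOptions(n_starts=3)

    shape = stack[0].shape
    data4d = np.stack([v.voxels for v in stack])  # (n_subj, X, Y, Z)
    eligible = np.nanmax(data4d, axis=0) >= min_mwf
    if not eligible.any():
        raise ValueError("no voxel reaches min_mwf; empty fit mask")

    k = model.n_params
    param_fields = np.full((k,) + shape, np.nan)
    sd_fields = np.full((k,) + shape, np.nan)
    fit_mask = np.zeros(shape, dtype=bool)

    flat_idx = np.flatnonzero(eligible.ravel())
    n_failed = 0
    for idx in flat_idx:
        ijk = np.unravel_index(idx, shape)
        # contiguous copy: strided views can differ at the ulp level in
        # vectorized transcendentals, which ill-conditioned refits amplify
        values = np.ascontiguousarray(data4d[(slice(None),) + ijk])
        vseed = _voxel_seed(seed, idx)
        try:
            data = TrajectoryData(ages=ages, values=values, region_label=str(ijk))
            opts = dataclasses.replace(fit_options, seed=vseed)
            fit = fit_model(model, data, options=opts)
            if n_resamples:
                draws = wild_bootstrap(
                    model, data, fit, n_resamples=n_resamples, seed=vseed,
                    weight_law=weight_law,
                )
                params, sds = draws.param_means, draws.param_sds
            else:
                params, sds = fit.params, np.zeros(k)
        except (ValueError, RuntimeError, FloatingPointError):
            n_failed += 1
            continue
        param_fields[(slice(None),) + ijk] = params
        sd_fields[(slice(None),) + ijk] = sds
        fit_mask[ijk] = True
    if n_failed:
        logger.info("voxel-wise fitting: %d voxel(s) failed and were masked out", n_failed)
    if not fit_mask.any():
        raise RuntimeError("all voxel fits failed")

    return ParameterAtlas(
        model=model,
        param_fields=param_fields,
        param_sd_fields=sd_fields,
        fit_mask=fit_mask,
        n_resamples=n_resamples,
        age_validity=(float(ages.min()), float(ages.max())),
        voxel_size_mm=stack[0].voxel_size_mm.copy(),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Age-queried maps
# ---------------------------------------------------------------------------


def _warn_if_extrapolating(atlas: ParameterAtlas, age_days: float) -> None:
    lo, hi = atlas.age_validity
    if not lo <= age_days <= hi:
        logger.warning(
            "age %.0f days is outside the atlas validity range [%.0f, %.0f]; "
            "extrapolating", age_days, lo, hi,
        )


def _masked_params(atlas: ParameterAtlas) -> np.ndarray:
    """In-mask parameter fields as a (n_params, V) array."""
    return atlas.param_fields[:, atlas.fit_mask]


def predict_mwf_map(atlas: ParameterAtlas, age_days: float) -> VolumeImage:
    """Representative mean MWF volume at an arbitrary age.

    Background (mask-false) voxels carry NaN as the no-data flag.
    """
    _warn_if_extrapolating(atlas, age_days)
    p = _masked_params(atlas)
    x = np.full(p.shape[1], float(age_days))
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        values = atlas.model._func(p, x)
    bad = ~np.isfinite(values)
    if bad.any():
        logger.warning(
            "%d in-mask voxel(s) evaluated non-finite at age %.0f (pathological "
            "fit); flagged NaN", int(bad.sum()), age_days,
        )
        values = np.where(bad, np.nan, values)
    out = np.full(atlas.grid_shape, np.nan)
    out[atlas.fit_mask] = values
    return VolumeImage(out, atlas.voxel_size_mm.copy(), age_days=float(age_days))


def predict_uncertainty_map(atlas: ParameterAtlas, age_days: float) -> VolumeImage:
    """dMWF (delta-method uncertainty) volume at an arbitrary age.

    Per voxel this equals ``propagate_uncertainty`` applied to that voxel's
    parameter means and SDs.
    """
    _warn_if_extrapolating(atlas, age_days)
    model = atlas.model
    p = _masked_params(atlas)
    sds = atlas.param_sd_fields[:, atlas.fit_mask]
    x = np.full(p.shape[1], float(age_days))
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        if model.has_analytic_gradient:
            G = model._grad(p, x)  # (V, n_params)
        else:
            G = np.empty((p.shape[1], model.n_params))
            for i in range(model.n_params):
                h = 1e-6 * np.maximum(np.abs(p[i]), 1e-3)
                pp, pm = p.copy(), p.copy()
                pp[i] = p[i] + h
                pm[i] = p[i] - h
                G[:, i] = (model._func(pp, x) - model._func(pm, x)) / (2.0 * h)
        dmwf = np.sqrt(np.sum((G * sds.T) ** 2, axis=1))
    bad = ~np.isfinite(dmwf)
    if bad.any():
        logger.warning(
            "%d in-mask voxel(s) produced non-finite dMWF at age %.0f; flagged NaN",
            int(bad.sum()), age_days,
        )
        dmwf = np.where(bad, np.nan, dmwf)
    out = np.full(atlas.grid_shape, np.nan)
    out[atlas.fit_mask] = dmwf
    return VolumeImage(
        out, atlas.voxel_size_mm.copy(), age_days=float(age_days), clip=False
    )


def extract_regional_means(img: VolumeImage, labels: np.ndarray) -> pd.DataFrame:
    """Mean MWF per nonzero integer label.

    Returns a DataFrame with columns label, mean_mwf, n_voxels; an empty
    label yields NaN with n_voxels 0.
    """
    labels = np.asarray(labels)
    if labels.shape != img.shape:
        raise ValueError("label volume grid does not match the image grid")
    rows = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        sel = labels == lab
        vals = img.voxels[sel]
        vals = vals[np.isfinite(vals)]
        rows.append(
            {
                "label": int(lab),
                "mean_mwf": float(vals.mean()) if vals.size else np.nan,
                "n_voxels": int(vals.size),
            }
        )
    return pd.DataFrame(rows, columns=["label", "mean_mwf", "n_voxels"])


# ---------------------------------------------------------------------------
# NIfTI / manifest I/O
# ---------------------------------------------------------------------------


def _affine(voxel_size_mm: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def save_volume(img: VolumeImage, path) -> None:
    nib.save(nib.Nifti1Image(img.voxels.astype(np.float64), _affine(img.voxel_size_mm)), str(path))


def load_volume(
    path,
    age_days: Optional[float] = None,
    subject_id: Optional[str] = None,
    clip: bool = True,
) -> VolumeImage:
    nii = nib.load(str(path))
    voxel_size = np.asarray(nii.header.get_zooms()[:3], dtype=float)
    return VolumeImage(
        voxels=np.asarray(nii.dataobj, dtype=float),
        voxel_size_mm=voxel_size,
        age_days=age_days,
        subject_id=subject_id,
        clip=clip,
    )


def load_stack(manifest_csv, base_dir=None) -> List[VolumeImage]:
    """Load a cohort from a CSV manifest with columns path, subject_id, age_days."""
    df = pd.read_csv(manifest_csv)
    base = pathlib.Path(base_dir) if base_dir else pathlib.Path(manifest_csv).parent
    stack = []
    for _, row in df.iterrows():
        p = pathlib.Path(row["path"])
        if not p.is_absolute():
            p = base / p
        stack.append(load_volume(p, age_days=float(row["age_days"]), subject_id=str(row["subject_id"])))
    return stack


def save_atlas(atlas: ParameterAtlas, out_dir) -> None:
    """Persist an atlas as NIfTI parameter/SD maps, mask, and JSON metadata."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(atlas.voxel_size_mm)
    for i, sym in enumerate(atlas.model.param_symbols):
        nib.save(nib.Nifti1Image(atlas.param_fields[i], aff), str(out / f"param_{sym}.nii.gz"))
        nib.save(nib.Nifti1Image(atlas.param_sd_fields[i], aff), str(out / f"sd_{sym}.nii.gz"))
    nib.save(nib.Nifti1Image(atlas.fit_mask.astype(np.uint8), aff), str(out / "fit_mask.nii.gz"))
    meta = {
        "model": atlas.model.name,
        "seed": atlas.seed,
        "n_resamples": atlas.n_resamples,
        "age_validity": list(atlas.age_validity),
        "voxel_size_mm": atlas.voxel_size_mm.tolist(),
    }
    (out / "atlas.json").write_text(json.dumps(meta, indent=2))


def load_atlas(in_dir) -> ParameterAtlas:
    src = pathlib.Path(in_dir)
    meta = json.loads((src / "atlas.json").read_text())
    model = get_model(meta["model"])
    params, sds = [], []
    for sym in model.param_symbols:
        params.append(np.asarray(nib.load(str(src / f"param_{sym}.nii.gz")).dataobj, dtype=float))
        sds.append(np.asarray(nib.load(str(src / f"sd_{sym}.nii.gz")).dataobj, dtype=float))
    mask = np.asarray(nib.load(str(src / "fit_mask.nii.gz")).dataobj) > 0
    return ParameterAtlas(
        model=model,
        param_fields=np.stack(params),
        param_sd_fields=np.stack(sds),
        fit_mask=mask,
        n_resamples=int(meta["n_resamples"]),
        age_validity=tuple(meta["age_validity"]),
        voxel_size_mm=np.asarray(meta["voxel_size_mm"], dtype=float),
        seed=int(meta["seed"]),
    )
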