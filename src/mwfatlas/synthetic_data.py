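"""Synthetic cohorts, regional trajectories, and voxel-grid MWF volumes.

Every stage of the pipeline can be exercised without any acquired data by
simulating inputs with the statistical structure the analysis assumes:

* a cohort age structure matching the study design — 122 subjects spanning
  70–1809 days (gestation-corrected) in 14 age groups;
* regional mean-MWF trajectories following modified-Gompertz ground truth
  with additive Gaussian noise (plateaus ~0.05–0.25, scatter ~0.012 MWF);
* small voxel grids ("phantoms") whose per-voxel trajectories follow smooth
  modified-Gompertz parameter fields inside an ellipsoidal parenchyma,
  partitioned into contiguous labeled regions, with exact-zero background.

The noise model is additive homoscedastic Gaussian by default, with a
heteroscedastic option (SD proportional to the mean curve); the wild
bootstrap downstream is valid under both.  Ground-truth parameter ranges
are plausibility choices calibrated to the observed scale of infant MWF
data (plateaus below ~0.3), not measured constants.

Everything is driven by explicit integer seeds: one master seed fixes the
ages, the phantom, every noise draw, and therefore every downstream atlas
and Z-map bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .atlas import VolumeImage, save_volume
from .growth_models import get_model
from .model_fitting import TrajectoryData

logger = logging.getLogger(__name__)

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "REFERENCE_COHORT",
    "DEFAULT_TRUTH_PARAMS",
    "DEFAULT_REGIONAL_PARAMS",
    "DEFAULT_NOISE_SD",
    "sample_ages",
    "uniform_ages",
    "generate_regional_trajectories",
    "generate_cohort_volumes",
    "make_phantom",
    "write_dataset",
]

_MODIFIED_GOMPERTZ = get_model("modified_gompertz")

#: default regional ground truth (modified Gompertz alpha, beta, gamma, delta)
DEFAULT_TRUTH_PARAMS: Tuple[float, float, float, float] = (0.2, 1.5, 0.008, 1e-5)

#: additive Gaussian noise SD in MWF units, matching the scatter of regional
#: mean-MWF measurements about their fitted trajectories
DEFAULT_NOISE_SD: float = 0.012

#: plausibility ranges for phantom parameter draws
PARAM_RANGES = {
    "alpha": (0.05, 0.3),
    "beta": (0.5, 3.0),
    "gamma": (0.003, 0.02),
    "delta": (0.0, 5e-5),
}

#: per-region ground-truth parameters for the nine-region trajectory set
DEFAULT_REGIONAL_PARAMS: Dict[str, Tuple[float, float, float, float]] = {
    "genu_cc": (0.20, 1.6, 0.009, 1.2e-5),
    "body_cc": (0.22, 1.5, 0.008, 1.0e-5),
    "splenium_cc": (0.25, 1.4, 0.0085, 1.0e-5),
    "frontal_wm": (0.15, 1.8, 0.007, 1.5e-5),
    "parietal_wm": (0.16, 1.7, 0.0075, 1.2e-5),
    "occipital_wm": (0.17, 1.3, 0.009, 1.0e-5),
    "temporal_wm": (0.14, 1.9, 0.0065, 1.5e-5),
    "cingulum": (0.18, 1.6, 0.008, 1.0e-5),
    "cerebellar_wm": (0.12, 1.2, 0.010, 0.8e-5),
}


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Cohort age structure: labeled age groups with ranges and sizes."""

    groups: Tuple[Tuple[str, float, float, int], ...]

    def __post_init__(self):
        if not self.groups:
            raise ValueError("cohort spec has no groups")
        prev_min = -np.inf
        for label, lo, hi, n in self.groups:
            if not (0 < lo <= hi) or n < 1:
                raise ValueError(f"invalid group {label!r}: [{lo}, {hi}], n={n}")
            if lo <= prev_min:
                raise ValueError("group age ranges must start in increasing order")
            prev_min = lo
        for (l1, lo1, hi1, _), (l2, lo2, hi2, _) in zip(self.groups, self.groups[1:]):
            if hi1 > lo2:
                logger.warning(
                    "age ranges of groups %r (%g-%g) and %r (%g-%g) overlap",
                    l1, lo1, hi1, l2, lo2, hi2,
                )

    @property
    def total_n(self) -> int:
        return sum(n for _, _, _, n in self.groups)

    @property
    def age_span(self) -> Tuple[float, float]:
        return (
            min(lo for _, lo, _, _ in self.groups),
            max(hi for _, _, hi, _ in self.groups),
        )


#: the study's 14-group, 122-subject cohort (age ranges in gestation-
#: corrected days; the 36-month group's tabulated range overlaps later
#: groups and is kept as-is — the validator warns)
REFERENCE_COHORT = CohortSpec(
    groups=(
        ("3mo", 70, 124, 21),
        ("6mo", 140, 211, 15),
        ("9mo", 240, 313, 11),
        ("12mo", 316, 383, 6),
        ("15mo", 413, 487, 5),
        ("18mo", 497, 573, 5),
        ("21mo", 593, 677, 6),
        ("24mo", 720, 724, 2),
        ("30mo", 772, 987, 15),
        ("36mo", 1030, 1728, 9),
        ("42mo", 1205, 1328, 7),
        ("48mo", 1368, 1526, 9),
        ("54mo", 1541, 1683, 6),
        ("60mo", 1728, 1809, 5),
    )
)

#: tabulated per-group mean ages, used by the match_means option
REFERENCE_GROUP_MEANS = (
    101.67, 178.53, 271.91, 346.17, 466.4, 522.6, 634.0,
    722.0, 887.87, 1158.56, 1284.71, 1430.22, 1620.67, 1758.0,
)


@dataclasses.dataclass
class GroundTruth:
    """Generating model for a synthetic study.

    ``regional_params`` drives regional trajectory generation;
    ``param_fields`` (shape (4, X, Y, Z)) and ``label_volume`` drive volume
    generation.  ``noise_sd`` is the additive Gaussian SD in MWF units.
    """

    regional_params: Dict[str, Tuple[float, float, float, float]]
    noise_sd: float = DEFAULT_NOISE_SD
    param_fields: Optional[np.ndarray] = None
    label_volume: Optional[np.ndarray] = None
    voxel_size_mm: np.ndarray = dataclasses.field(default_factory=lambda: np.ones(3))
    heteroscedastic: bool = False

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for region, p in self.regional_params.items():
            a, b, g, d = p
            if not (0 < a < 0.35 and g > 0 and d >= 0):
                raise ValueError(
                    f"implausible parameters for region {region!r}: {p} "
                    "(need 0 < alpha < 0.35, gamma > 0, delta >= 0)"
                )
        if (self.param_fields is None) != (self.label_volume is None):
            raise ValueError("param_fields and label_volume go together")
        if self.param_fields is not None:
            if self.param_fields.shape != (4,) + self.label_volume.shape:
                raise ValueError("param_fields must be (4,) + label_volume.shape")


# ---------------------------------------------------------------------------
# Ages
# ---------------------------------------------------------------------------


def sample_ages(
    spec: CohortSpec = REFERENCE_COHORT,
    seed: int = 0,
    match_means: bool = False,
    group_means: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """Draw one age (days) per subject, uniform within each group's range.

    With ``match_means``, draws are iteratively nudged (shift-and-clip)
    toward the tabulated group mean ages for fixture realism.
    """
    rng = np.random.default_rng(seed)
    if match_means and group_means is None:
        if spec is not REFERENCE_COHORT:
            raise ValueError("match_means requires group_means for custom cohorts")
        group_means = REFERENCE_GROUP_MEANS
    ages = []
    for gi, (_, lo, hi, n) in enumerate(spec.groups):
        a = rng.uniform(lo, hi, size=n)
        if match_means:
            target = group_means[gi]
            for _ in range(8):
                a = np.clip(a + (target - a.mean()), lo, hi)
        ages.append(a)
    return np.concatenate(ages)


def uniform_ages(
    n: int, age_min: float = 70.0, age_max: float = 1809.0, seed: int = 0
) -> np.ndarray:
    """n ages uniform over the study span (no group structure)."""
    return np.random.default_rng(seed).uniform(age_min, age_max, size=n)


# ---------------------------------------------------------------------------
# Regional trajectories
# ---------------------------------------------------------------------------


def generate_regional_trajectories(
    truth: GroundTruth, ages: np.ndarray, seed: int = 0
) -> Dict[str, TrajectoryData]:
    """Noisy regional mean-MWF trajectories from the ground-truth curves."""
    ages = np.asarray(ages, dtype=float)
    rng = np.random.default_rng(seed)
    out = {}
    n_clipped = 0
    for region in sorted(truth.regional_params):
        p = truth.regional_params[region]
        curve = _MODIFIED_GOMPERTZ._func(np.asarray(p, float), ages)
        sd = truth.noise_sd * (curve / np.mean(curve) if truth.heteroscedastic else 1.0)
        values = curve + rng.normal(0.0, 1.0, ages.size) * sd
        n_clipped += int(np.sum((values < 0) | (values > 1)))
        values = np.clip(values, 0.0, 1.0)
        out[region] = TrajectoryData(
            ages=ages, values=values, region_label=region,
            subject_ids=[f"sub-{i:03d}" for i in range(ages.size)],
        )
    if n_clipped:
        logger.info("clipped %d simulated value(s) to [0, 1]", n_clipped)
    return out


# ---------------------------------------------------------------------------
# Phantom volumes
# ---------------------------------------------------------------------------


def make_phantom(
    grid_shape: Tuple[int, int, int] = (12, 12, 6),
    n_regions: int = 9,
    seed: int = 0,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> GroundTruth:
    """Build a labeled ellipsoidal parenchyma with smooth parameter fields.

    A central ellipsoid (semi-axes 40% of the grid) is partitioned into
    ``n_regions`` contiguous regions by nearest-seed-point assignment.  Each
    region receives modified-Gompertz parameters drawn from the documented
    plausibility ranges, with smooth ±5% within-region variation; background
    voxels are zero-labeled with NaN parameter fields.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if len(grid_shape) != 3 or min(grid_shape) < 4:
        raise ValueError("grid must be 3-D with every side >= 4 voxels")
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    rng = np.random.default_rng(seed)

    center = (np.asarray(grid_shape) - 1) / 2.0
    semi = 0.4 * np.asarray(grid_shape)
    ii, jj, kk = np.indices(grid_shape)
    r2 = (
        ((ii - center[0]) / semi[0]) ** 2
        + ((jj - center[1]) / semi[1]) ** 2
        + ((kk - center[2]) / semi[2]) ** 2
    )
    parenchyma = r2 <= 1.0
    coords = np.argwhere(parenchyma)
    if coords.shape[0] < n_regions:
        raise ValueError("grid too small for the requested region count")

    # contiguous regions: Voronoi cells of seed points inside the parenchyma
    seed_pts = coords[rng.choice(coords.shape[0], size=n_regions, replace=False)]
    d2 = np.sum(
        (coords[:, None, :] - seed_pts[None, :, :]) ** 2, axis=2
    )  # (n_vox, n_regions)
    assignment = np.argmin(d2, axis=1)
    labels = np.zeros(grid_shape, dtype=np.int32)
    labels[tuple(coords.T)] = assignment + 1

    regional_params = {}
    fields = np.full((4,) + grid_shape, np.nan)
    for r in range(1, n_regions + 1):
        p = np.array(
            [rng.uniform(*PARAM_RANGES[k]) for k in ("alpha", "beta", "gamma", "delta")]
        )
        regional_params[f"region_{r}"] = tuple(p)
        fields[:, labels == r] = p[:, None]
    # smooth within-region variation (±5% multiplicative), re-clipped to ranges
    for i, key in enumerate(("alpha", "beta", "gamma", "delta")):
        noise = ndimage.gaussian_filter(rng.standard_normal(grid_shape), sigma=1.5)
        noise = noise / max(np.abs(noise).max(), 1e-12)
        fields[i] = fields[i] * (1.0 + 0.05 * noise)
        lo, hi = PARAM_RANGES[key]
        fields[i] = np.clip(fields[i], lo, hi)
    fields[:, ~parenchyma] = np.nan

    return GroundTruth(
        regional_params=regional_params,
        noise_sd=noise_sd,
        param_fields=fields,
        label_volume=labels,
    )


def generate_cohort_volumes(
    truth: GroundTruth, ages: np.ndarray, seed: int = 0
) -> List[VolumeImage]:
    """One MWF volume per age from the phantom's parameter fields.

    In-parenchyma voxels follow their modified-Gompertz curves plus i.i.d.
    Gaussian noise (clipped to [0, 1]); background voxels are exactly 0.
    """
    if truth.param_fields is None:
        raise ValueError("ground truth has no param_fields; build a phantom first")
    ages = np.asarray(ages, dtype=float)
    rng = np.random.default_rng(seed)
    mask = truth.label_volume > 0
    p = truth.param_fields[:, mask]  # (4, V)
    volumes = []
    for i, age in enumerate(ages):
        curve = _MODIFIED_GOMPERTZ._func(p, np.full(p.shape[1], age))
        values = np.clip(curve + rng.normal(0.0, truth.noise_sd, curve.size), 0.0, 1.0)
        vol = np.zeros(truth.label_volume.shape)
        vol[mask] = values
        volumes.append(
            VolumeImage(
                voxels=vol,
                voxel_size_mm=truth.voxel_size_mm.copy(),
                age_days=float(age),
                subject_id=f"sub-{i:03d}",
            )
        )
    return volumes


# ---------------------------------------------------------------------------
# Dataset writer
# ---------------------------------------------------------------------------


def write_dataset(
    out_dir,
    grid_shape: Tuple[int, int, int] = (12, 12, 6),
    n_regions: int = 9,
    noise_sd: float = DEFAULT_NOISE_SD,
    cohort: CohortSpec = REFERENCE_COHORT,
    seed: int = 0,
) -> pathlib.Path:
    """Write a complete synthetic study: volumes, manifest, trajectories, truth.

    Layout: ``volumes/sub-XXX.nii.gz``, ``manifest.csv`` (path, subject_id,
    age_days), ``trajectories.csv`` (subject_id, age_days, region, mwf), and
    ``ground_truth.json`` (seeds, parameters, noise).
    """
    out = pathlib.Path(out_dir)
    (out / "volumes").mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_ages, s_phantom, s_vols, s_traj = (
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(4)
    )

    ages = sample_ages(cohort, seed=s_ages)
    phantom = make_phantom(grid_shape, n_regions, seed=s_phantom, noise_sd=noise_sd)
    volumes = generate_cohort_volumes(phantom, ages, seed=s_vols)

    rows = []
    for vol in volumes:
        fname = f"volumes/{vol.subject_id}.nii.gz"
        save_volume(vol, out / fname)
        rows.append({"path": fname, "subject_id": vol.subject_id, "age_days": vol.age_days})
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)

    truth_regional = GroundTruth(
        regional_params=dict(DEFAULT_REGIONAL_PARAMS), noise_sd=noise_sd
    )
    trajectories = generate_regional_trajectories(truth_regional, ages, seed=s_traj)
    traj_rows = []
    for region, data in trajectories.items():
        for sid, age, mwf in zip(data.subject_ids, data.ages, data.values):
            traj_rows.append(
                {"subject_id": sid, "age_days": age, "region": region, "mwf": mwf}
            )
    pd.DataFrame(traj_rows).to_csv(out / "trajectories.csv", index=False)

    import nibabel as nib  # labels saved alongside for regional extraction

    nib.save(
        nib.Nifti1Image(phantom.label_volume.astype(np.int16), np.eye(4)),
        str(out / "labels.nii.gz"),
    )
    meta = {
        "seed": seed,
        "noise_sd": noise_sd,
        "grid_shape": list(grid_shape),
        "n_regions": n_regions,
        "regional_params": {k: list(v) for k, v in truth_regional.regional_params.items()},
        "phantom_regional_params": {
            k: list(v) for k, v in phantom.regional_params.items()
        },
        "cohort_groups": [list(g) for g in cohort.groups],
    }
    (out / "ground_truth.json").write_text(json.dumps(meta, indent=2))
    return out
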