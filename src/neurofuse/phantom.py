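"""Synthetic lesion-phantom cohorts.

Real post-intervention stroke MRI collections are restricted-access, so every
stage of this package is exercised on generated stand-ins: brain-like
ellipsoidal volumes with a focal hyperintense lesion, correlated tabular
covariates (age, an NIHSS-like admission severity score, sex, thrombus
location), and binary outcomes drawn from a logistic model on lesion volume
plus covariates, with the intercept calibrated to a target prevalence.
Continuous outcome values (length of stay in days, 90-day mRS on the 0-6
ordinal scale) are then sampled consistently with the binary label so the
dichotomization stage is exercised end to end.

The generator mimics cohort *structure*, not MRI physics: no partial-volume
effects, no scanner variation, single-focus lesions only.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


class SizingError(ValueError):
    """Grid too small to host a phantom brain."""


class PlacementError(ValueError):
    """Requested lesion center falls outside the brain mask."""


class SchemaError(KeyError):
    """A named predictor is absent from the cohort table."""


class CalibrationError(RuntimeError):
    """Intercept calibration failed to converge."""


@dataclass
class Covariate:
    """One tabular feature distribution.

    kind 'continuous': params mean, sd, optional lower truncation bound.
    kind 'binary': params p.
    kind 'categorical': params levels, probs.
    """

    name: str
    kind: str
    params: dict


def default_covariates() -> list[Covariate]:
    # marginals chosen to resemble a typical ischemic-stroke admission cohort
    return [
        Covariate("age", "continuous", {"mean": 62.0, "sd": 14.0}),
        Covariate("nihss", "continuous", {"mean": 6.1, "sd": 6.6, "lower": 0.0}),
        Covariate("male", "binary", {"p": 0.53}),
        Covariate("thrombus_location", "categorical",
                  {"levels": ["Bilateral", "Left", "Right", "Missing"],
                   "probs": [0.14, 0.40, 0.37, 0.09]}),
    ]


def default_coefficients() -> dict[str, dict[str, float]]:
    """Logistic-link weights per outcome; lesion volume in cm^3 carries the
    dominant image signal, severity and age add correlated clinical signal."""
    return {
        "los": {"lesion_volume_cm3": 2.0, "nihss": 0.10, "age": 0.015},
        "mrs": {"lesion_volume_cm3": 1.6, "nihss": 0.12, "age": 0.02},
    }


@dataclass
class PhantomConfig:
    n_subjects: int = 200
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_volume: float = 8.0  # mm^3 per voxel (2 mm isotropic)
    lesion_axis_range: tuple[float, float] = (2.0, 6.0)  # semi-axes, voxels
    base_intensity: float = 1.0
    background_noise_sd: float = 0.05
    lesion_contrast: float = 1.0
    covariate_spec: list[Covariate] = field(default_factory=default_covariates)
    outcome_coefficients: dict[str, dict[str, float]] = field(
        default_factory=default_coefficients)
    target_prevalence: dict[str, float] = field(
        default_factory=lambda: {"los": 0.1891, "mrs": 0.3850})
    # how strongly the NIHSS-like score tracks lesion volume (per cm^3)
    severity_lesion_coupling: float = 0.8
    missing_rate: float = 0.05
    seed: int = 0

    def validate(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if any(g < 8 for g in self.grid_shape):
            raise SizingError("grid_shape must be at least 8 voxels per axis")
        if self.voxel_volume <= 0:
            raise ValueError("voxel_volume must be positive")
        lo, hi = self.lesion_axis_range
        if lo <= 0 or hi < lo:
            raise ValueError("lesion_axis_range must be positive and ordered")
        for name, p in self.target_prevalence.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"target_prevalence[{name}] must be in (0,1)")
        if not 0.0 <= self.missing_rate < 0.2:
            raise ValueError("missing_rate must be below 0.2")
        return self


@dataclass
class VolumeSample:
    """One subject's image, brain mask and lesion mask on a shared grid."""

    image: np.ndarray
    brain_mask: np.ndarray
    lesion_mask: np.ndarray
    subject_id: str
    voxel_volume: float

    def validate(self):
        if not (self.image.shape == self.brain_mask.shape == self.lesion_mask.shape):
            raise ValueError("image and masks must share one grid")
        for m in (self.brain_mask, self.lesion_mask):
            if not np.isin(m, (0, 1)).all():
                raise ValueError("masks must be strictly binary")
        if (self.lesion_mask & ~self.brain_mask.astype(bool)).any():
            raise ValueError("lesion mask must lie inside the brain mask")
        return self

    @property
    def lesion_volume_cm3(self) -> float:
        return float(self.lesion_mask.sum()) * self.voxel_volume / 1000.0


@dataclass
class SyntheticCohort:
    volumes: list[VolumeSample]
    table: pd.DataFrame
    generating_truth: dict

    def validate(self):
        if len(self.volumes) != len(self.table):
            raise ValueError("one table row per volume required")
        return self


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    grids = np.indices(shape, dtype=float)
    q = np.zeros(shape)
    for g, c, a in zip(grids, center, semi_axes):
        q += ((g - c) / a) ** 2
    return q <= 1.0


def generate_brain_volume(config: PhantomConfig, rng: np.random.Generator,
                          subject_id: str = "sub-000") -> VolumeSample:
    """A centered ellipsoidal 'brain' covering 30-60% of the grid, constant
    base intensity plus Gaussian noise inside, exactly zero outside."""
    if any(g < 8 for g in config.grid_shape):
        raise SizingError("grid_shape must be at least 8 voxels per axis")
    shape = tuple(config.grid_shape)
    center = [(d - 1) / 2.0 for d in shape]
    r = rng.uniform(0.90, 0.99)
    semi_axes = [r * (d - 1) / 2.0 for d in shape]
    brain = _ellipsoid_mask(shape, center, semi_axes)
    image = np.zeros(shape)
    image[brain] = config.base_intensity
    if config.background_noise_sd > 0:
        noise = rng.normal(0.0, config.background_noise_sd, size=shape)
        image[brain] += noise[brain]
    return VolumeSample(image=image, brain_mask=brain.astype(np.uint8),
                        lesion_mask=np.zeros(shape, dtype=np.uint8),
                        subject_id=subject_id,
                        voxel_volume=config.voxel_volume)


def implant_lesion(vol: VolumeSample, center, semi_axes,
                   contrast: float) -> VolumeSample:
    """Add an ellipsoidal hyperintense lesion clipped to the brain mask."""
    center = tuple(int(c) for c in center)
    if not vol.brain_mask[center]:
        raise PlacementError(f"lesion center {center} outside brain mask")
    ell = _ellipsoid_mask(vol.image.shape, center, semi_axes)
    lesion = (ell & vol.brain_mask.astype(bool)).astype(np.uint8)
    image = vol.image + contrast * lesion
    return VolumeSample(image=image, brain_mask=vol.brain_mask,
                        lesion_mask=lesion, subject_id=vol.subject_id,
                        voxel_volume=vol.voxel_volume)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _linear_predictor(table: pd.DataFrame, coefficients: dict[str, float]):
    lin = np.zeros(len(table))
    for name, coef in coefficients.items():
        if name not in table.columns:
            raise SchemaError(name)
        lin += coef * table[name].to_numpy(dtype=float)
    return lin


def generate_outcomes(table: pd.DataFrame, coefficients: dict[str, float],
                      intercept: float, rng: np.random.Generator):
    """Bernoulli labels from a logistic link on named table columns.

    Returns (labels, probabilities); probabilities expose the generating
    truth for oracle checks.
    """
    lin = _linear_predictor(table, coefficients)
    probs = _logistic(intercept + lin)
    labels = (rng.random(len(table)) < probs).astype(int)
    return labels, probs


def calibrate_intercept(table: pd.DataFrame, coefficients: dict[str, float],
                        target_prevalence: float, tol: float = 1e-4,
                        max_iter: int = 200) -> float:
    """Bisect the intercept until the mean predicted probability matches the
    target prevalence within ``tol``."""
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target_prevalence must be in (0,1)")
    lin = _linear_predictor(table, coefficients)
    lo, hi = -60.0, 60.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        mean_p = float(_logistic(mid + lin).mean())
        if abs(mean_p - target_prevalence) < tol:
            return mid
        if mean_p < target_prevalence:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"no intercept reached prevalence {target_prevalence} in {max_iter} steps")


def _sample_covariates(config: PhantomConfig, n: int,
                       rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for cov in config.covariate_spec:
        if cov.kind == "continuous":
            x = rng.normal(cov.params["mean"], cov.params["sd"], size=n)
            if "lower" in cov.params:
                lo = cov.params["lower"]
                # truncate by resampling the offending tail
                bad = x < lo
                while bad.any():
                    x[bad] = rng.normal(cov.params["mean"], cov.params["sd"],
                                        size=int(bad.sum()))
                    bad = x < lo
            cols[cov.name] = x
        elif cov.kind == "binary":
            cols[cov.name] = (rng.random(n) < cov.params["p"]).astype(int)
        elif cov.kind == "categorical":
            cols[cov.name] = rng.choice(cov.params["levels"], size=n,
                                        p=cov.params["probs"])
        else:
            raise ValueError(f"unknown covariate kind {cov.kind!r}")
    return pd.DataFrame(cols)


def _sample_lesion_center(brain_mask: np.ndarray, rng: np.random.Generator):
    """A voxel well inside the brain (interior 60% of the ellipsoid radius)."""
    shape = brain_mask.shape
    center = [(d - 1) / 2.0 for d in shape]
    grids = np.indices(shape, dtype=float)
    q = np.zeros(shape)
    for g, c, d in zip(grids, center, shape):
        q += ((g - c) / (d / 2.0 - 1.0)) ** 2
    interior = np.argwhere((q <= 0.36) & brain_mask.astype(bool))
    return tuple(interior[rng.integers(len(interior))])


def generate_cohort(config: PhantomConfig) -> SyntheticCohort:
    """The full synthetic study: volumes, tabular features, outcomes, truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    table = _sample_covariates(config, n, rng)
    table.insert(0, "subject_id", [f"sub-{i:04d}" for i in range(n)])

    volumes: list[VolumeSample] = []
    lesion_vols = np.zeros(n)
    lo, hi = config.lesion_axis_range
    for i in range(n):
        vol = generate_brain_volume(config, rng, subject_id=table.subject_id[i])
        center = _sample_lesion_center(vol.brain_mask, rng)
        semi_axes = rng.uniform(lo, hi, size=3)
        vol = implant_lesion(vol, center, semi_axes, config.lesion_contrast)
        volumes.append(vol)
        lesion_vols[i] = vol.lesion_volume_cm3
    table["lesion_volume_cm3"] = lesion_vols
    if "nihss" in table.columns and config.severity_lesion_coupling:
        bump = config.severity_lesion_coupling * (lesion_vols - lesion_vols.mean())
        table["nihss"] = np.maximum(0.0, table["nihss"] + bump)

    truth = {"seed": config.seed, "outcomes": {}}
    for outcome, coefs in config.outcome_coefficients.items():
        target = config.target_prevalence[outcome]
        intercept = calibrate_intercept(table, coefs, target)
        labels, probs = generate_outcomes(table, coefs, intercept, rng)
        truth["outcomes"][outcome] = {
            "coefficients": coefs, "intercept": intercept,
            "target_prevalence": target,
            "linear_predictor": np.log(probs / (1 - probs)).tolist(),
            "probabilities": probs.tolist(),
            "labels": labels.tolist(),
        }
        if outcome == "los":
            los = np.where(labels == 1, 9 + rng.poisson(5.0, size=n),
                           rng.integers(2, 9, size=n))
            table["los_days"] = los.astype(float)
        elif outcome == "mrs":
            mrs = np.where(labels == 1, rng.integers(3, 7, size=n),
                           rng.integers(0, 3, size=n))
            table["mrs_90day"] = mrs.astype(float)

    # MCAR missingness on continuous clinical covariates only
    if config.missing_rate > 0:
        for cov in config.covariate_spec:
            if cov.kind == "continuous":
                mask = rng.random(n) < config.missing_rate
                table.loc[mask, cov.name] = np.nan

    return SyntheticCohort(volumes=volumes, table=table,
                           generating_truth=truth).validate()


# ---------------------------------------------------------------------------
# on-disk form

def _write_nifti(path: Path, data: np.ndarray, voxel_volume: float):
    spacing = voxel_volume ** (1.0 / 3.0)
    affine = np.diag([spacing, spacing, spacing, 1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    raw = img.to_bytes()
    if str(path).endswith(".gz"):
        # fixed mtime so identical configs give byte-identical files
        path.write_bytes(gzip.compress(raw, mtime=0))
    else:
        path.write_bytes(raw)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path,
                 compress: bool = True) -> Path:
    """Write per-subject NIfTI triplets, cohort.csv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = ".nii.gz" if compress else ".nii"
    for vol in cohort.volumes:
        _write_nifti(outdir / f"{vol.subject_id}_image{ext}",
                     vol.image.astype(np.float32), vol.voxel_volume)
        _write_nifti(outdir / f"{vol.subject_id}_brainmask{ext}",
                     vol.brain_mask.astype(np.uint8), vol.voxel_volume)
        _write_nifti(outdir / f"{vol.subject_id}_lesionmask{ext}",
                     vol.lesion_mask.astype(np.uint8), vol.voxel_volume)
    cohort.table.to_csv(outdir / "cohort.csv", index=False)
    (outdir / "truth.json").write_text(
        json.dumps(cohort.generating_truth, indent=1, sort_keys=True))
    return outdir


def config_from_dict(d: dict) -> PhantomConfig:
    d = dict(d)
    if "covariate_spec" in d:
        d["covariate_spec"] = [Covariate(**c) for c in d["covariate_spec"]]
    for key in ("grid_shape", "lesion_axis_range"):
        if key in d:
            d[key] = tuple(d[key])
    return PhantomConfig(**d).validate()


def config_to_dict(config: PhantomConfig) -> dict:
    return asdict(config)
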