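"""Cohort construction and tabular preprocessing.

Outcomes are dichotomized with strict thresholds (length of stay > 8 days,
90-day mRS > 2 define the poor-outcome positive class).  Each outcome's
cohort contains only the subjects with that outcome recorded.  Subjects are
split once into an 80/20 stratified hold-out, and the remaining 80% is
shuffled into three stratified 80/20 train/validation folds that every
experiment reuses; the plan serializes to JSON so reuse is verifiable.

Preprocessing is fit on training rows only: continuous features are
mean-imputed and standardized with statistics from the training fold,
categorical features are one-hot encoded against schema-declared levels
(unseen categories encode to all zeros — "assumed false if absent"), and
binary indicators pass through with missing treated as 0.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedShuffleSplit, train_test_split

LOS_THRESHOLD_DAYS = 8.0
MRS_THRESHOLD = 2.0


class StratificationError(ValueError):
    """Too few members of a class to stratify as requested."""


class LeakageError(RuntimeError):
    """A preprocessing or training step would see non-training rows."""


@dataclass
class FeatureDef:
    name: str
    kind: str  # continuous | binary | categorical
    levels: list[str] | None = None

    def encoded_width(self) -> int:
        return len(self.levels) if self.kind == "categorical" else 1


@dataclass
class FeatureSchema:
    """Declares the clinical block, the image-derived block and the outcomes.

    The real study's clinical block encodes to 40 columns; the schema is
    config-driven so any cohort (synthetic or real) declares its own list.
    """

    clinical_features: list[FeatureDef]
    idf_features: list[FeatureDef]
    outcome_columns: dict[str, str] = field(
        default_factory=lambda: {"los": "los_days", "mrs": "mrs_90day"})

    def __post_init__(self):
        names = [f.name for f in self.clinical_features + self.idf_features]
        if len(names) != len(set(names)):
            raise ValueError("feature names must be unique")

    @property
    def clinical_width(self) -> int:
        return sum(f.encoded_width() for f in self.clinical_features)

    @property
    def idf_width(self) -> int:
        return sum(f.encoded_width() for f in self.idf_features)


def phantom_schema() -> FeatureSchema:
    """Schema matching the synthetic cohort produced by ``phantom``."""
    return FeatureSchema(
        clinical_features=[
            FeatureDef("age", "continuous"),
            FeatureDef("nihss", "continuous"),
            FeatureDef("male", "binary"),
        ],
        idf_features=[
            FeatureDef("lesion_volume_cm3", "continuous"),
            FeatureDef("thrombus_location", "categorical",
                       ["Bilateral", "Left", "Right", "Missing"]),
        ],
    )


def dichotomize(values, outcome: str) -> np.ndarray:
    """Binary poor-outcome labels; NaN stays NaN (outcome unavailable)."""
    values = np.asarray(values, dtype=float)
    present = ~np.isnan(values)
    if outcome == "los":
        if (values[present] < 0).any():
            raise ValueError("negative length of stay")
        threshold = LOS_THRESHOLD_DAYS
    elif outcome == "mrs":
        v = values[present]
        if ((v < 0) | (v > 6)).any():
            raise ValueError("mRS values must lie in 0..6")
        threshold = MRS_THRESHOLD
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    labels = np.full(values.shape, np.nan)
    labels[present] = (values[present] > threshold).astype(float)
    return labels


@dataclass
class SplitPlan:
    """Hold-out test indices plus three stratified train/validation folds."""

    outcome: str
    test_indices: list[int]
    folds: list[dict[str, list[int]]]  # [{"train": [...], "val": [...]}, ...]
    seed: int
    labels_hash: str

    def validate(self):
        test = set(self.test_indices)
        for fold in self.folds:
            tr, va = set(fold["train"]), set(fold["val"])
            if tr & va:
                raise ValueError("train/validation overlap within a fold")
            if (tr | va) & test:
                raise ValueError("fold indices leak into the hold-out test set")
        return self

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SplitPlan":
        return cls(**json.loads(text)).validate()

    @property
    def plan_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _labels_hash(labels: np.ndarray) -> str:
    return hashlib.sha256(np.asarray(labels, dtype=np.int64).tobytes()).hexdigest()[:16]


def make_split_plan(labels, outcome: str = "los", test_fraction: float = 0.2,
                    n_folds: int = 3, fold_val_fraction: float = 0.2,
                    seed: int = 0) -> SplitPlan:
    labels = np.asarray(labels).astype(int)
    counts = np.bincount(labels, minlength=2)
    if (counts < max(2, n_folds)).any():
        raise StratificationError(
            f"each class needs at least {max(2, n_folds)} members, got {counts.tolist()}")
    idx = np.arange(len(labels))
    rest, test = train_test_split(idx, test_size=test_fraction,
                                  stratify=labels, random_state=seed)
    rest = np.sort(rest)
    sss = StratifiedShuffleSplit(n_splits=n_folds, test_size=fold_val_fraction,
                                 random_state=seed)
    folds = []
    for tr, va in sss.split(rest.reshape(-1, 1), labels[rest]):
        folds.append({"train": sorted(int(i) for i in rest[tr]),
                      "val": sorted(int(i) for i in rest[va])})
    return SplitPlan(outcome=outcome,
                     test_indices=sorted(int(i) for i in test),
                     folds=folds, seed=seed,
                     labels_hash=_labels_hash(labels)).validate()


class Preprocessor:
    """Column pipeline fit on training rows only.

    continuous -> mean-impute (training mean), standardize (training mean/SD,
    SD 1 with a warning for zero-variance columns); binary -> missing as 0;
    categorical -> one-hot against declared levels, unknown levels all-zero.
    """

    def __init__(self, schema: FeatureSchema, include_idf: bool = True,
                 include_clinical: bool = True):
        self.schema = schema
        feats: list[FeatureDef] = []
        if include_clinical:
            feats += schema.clinical_features
        if include_idf:
            feats += schema.idf_features
        if not feats:
            raise ValueError("preprocessor needs at least one feature block")
        self.features = feats
        self.stats_: dict[str, tuple[float, float]] = {}
        self.fitted = False

    @property
    def column_names(self) -> list[str]:
        names = []
        for f in self.features:
            if f.kind == "categorical":
                names += [f"{f.name}={lv}" for lv in f.levels]
            else:
                names.append(f.name)
        return names

    @property
    def width(self) -> int:
        return sum(f.encoded_width() for f in self.features)

    def fit(self, train_rows: pd.DataFrame) -> "Preprocessor":
        for f in self.features:
            if f.kind == "continuous":
                col = train_rows[f.name].to_numpy(dtype=float)
                mean = float(np.nanmean(col))
                sd = float(np.nanstd(np.where(np.isnan(col), mean, col), ddof=0))
                if sd == 0.0:
                    warnings.warn(f"zero-variance feature {f.name!r}; SD set to 1")
                    sd = 1.0
                self.stats_[f.name] = (mean, sd)
        self.fitted = True
        return self

    def transform(self, rows: pd.DataFrame) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("preprocessor must be fit before transform")
        blocks = []
        for f in self.features:
            if f.kind == "continuous":
                mean, sd = self.stats_[f.name]
                col = rows[f.name].to_numpy(dtype=float)
                col = np.where(np.isnan(col), mean, col)
                blocks.append(((col - mean) / sd)[:, None])
            elif f.kind == "binary":
                col = rows[f.name].to_numpy(dtype=float)
                blocks.append(np.where(np.isnan(col), 0.0, col)[:, None])
            else:
                raw = rows[f.name].astype(object).to_numpy()
                raw = np.where(pd.isna(raw),
                               "Missing" if "Missing" in f.levels else "__absent__",
                               raw)
                onehot = np.zeros((len(rows), len(f.levels)))
                known = set(f.levels)
                unseen = {v for v in raw if v not in known}
                if unseen - {"__absent__"}:
                    warnings.warn(f"unseen categories {sorted(unseen - {'__absent__'})} "
                                  f"for {f.name!r} encoded as all-zero")
                for j, lv in enumerate(f.levels):
                    onehot[:, j] = raw == lv
                blocks.append(onehot)
        return np.hstack(blocks)


def fit_preprocessor(train_rows: pd.DataFrame, schema: FeatureSchema,
                     include_idf: bool = True,
                     include_clinical: bool = True) -> Preprocessor:
    return Preprocessor(schema, include_idf=include_idf,
                        include_clinical=include_clinical).fit(train_rows)


def apply_preprocessor(fitted: Preprocessor, rows: pd.DataFrame) -> np.ndarray:
    return fitted.transform(rows)


def outcome_cohort(table: pd.DataFrame, schema: FeatureSchema,
                   outcome: str) -> tuple[pd.DataFrame, np.ndarray]:
    """Rows with the outcome available, plus their binary labels."""
    col = schema.outcome_columns[outcome]
    labels = dichotomize(table[col].to_numpy(dtype=float), outcome)
    keep = ~np.isnan(labels)
    return table.loc[keep].reset_index(drop=True), labels[keep].astype(int)


def permutation_test(group_a, group_b, kind: str = "continuous",
                     n_perm: int = 1000, seed: int = 0) -> float:
    """Two-sided permutation p-value for a group difference.

    continuous: |mean(a) - mean(b)|; categorical: total variation distance
    between level proportions.  p = (1 + #{|perm| >= |obs|}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    a = np.asarray(group_a)
    b = np.asarray(group_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")

    if kind == "continuous":
        def stat(x, y):
            return abs(float(np.mean(x)) - float(np.mean(y)))
        pooled = np.concatenate([a.astype(float), b.astype(float)])
    elif kind == "categorical":
        levels = np.unique(np.concatenate([a.astype(str), b.astype(str)]))

        def stat(x, y):
            pa = np.array([(x == lv).mean() for lv in levels])
            pb = np.array([(y == lv).mean() for lv in levels])
            return 0.5 * float(np.abs(pa - pb).sum())
        pooled = np.concatenate([a.astype(str), b.astype(str)])
    else:
        raise ValueError(f"unknown kind {kind!r}")

    observed = stat(a, b)
    rng = np.random.default_rng(seed)
    na = a.size
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if stat(perm[:na], perm[na:]) >= observed - 1e-15:
            exceed += 1
    return (1 + exceed) / (n_perm + 1)
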