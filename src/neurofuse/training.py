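"""Experiment harness: clinical / image / combined arms, each with and
without image-derived features (IDF); transfer-learning, fine-tuning and
from-scratch regimes for the ResNet branch; autoencoder pretraining and
embedding extraction; AUPRC-based model and epoch selection; frozen-backbone
classifier retraining for the combined arms.

Learning-rate defaults follow the study conditions: classifier-only training
uses a constant 0.01; fine-tuning starts at 0.001 and from-scratch at 0.1,
both with a reduce-on-plateau scheduler on validation loss.  Checkpoints are
selected by best validation AUPRC; hold-out test metrics are computed once,
from the selected checkpoint, on subjects no training step ever saw.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import metrics as M
from . import nn
from .networks import (Autoencoder, AutoencoderSpec, ClassifierSpec,
                       DaftClassifier, DaftSpec, LinearClassifier,
                       ResNetClassifier, ResNetSpec, build, encode)
from .nn import Adam, ReduceLROnPlateau, bce_with_logits, mse_loss
from .nn.functional import trilinear_resize
from .tabular import (Preprocessor, SplitPlan, dichotomize, make_split_plan)

ARMS = ("clinical", "image", "combined")
REGIME_ORDER = ("TL", "FT", "FT+SE", "scratch", "scratch+SE")
DEFAULT_CLASSIFIER_LR = 0.01
DEFAULT_REGIME_LR = {"TL": 0.01, "FT": 0.001, "scratch": 0.1}


class TrainingError(RuntimeError):
    """Raised on degenerate training inputs or divergence."""


@dataclass
class ExperimentSpec:
    """One experiment arm's declarative settings."""

    arm: str
    outcome: str = "los"
    branch: str | None = None  # resnet | autoencoder | daft
    regime: str | None = None  # TL | FT | scratch (resnet only)
    use_ehr: bool = True
    use_idf: bool = False
    optimizer: str = "adam"
    lr: float | None = None
    scheduler: bool | None = None
    epochs: int = 100
    batch_size: int = 64
    patience: int = 15
    weight_decay: float = 0.0
    pos_class_weight: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.arm == "clinical" and self.branch is not None:
            raise ValueError("clinical arm takes no image branch")
        if self.arm != "clinical" and self.branch is None:
            raise ValueError(f"{self.arm} arm requires an image branch")
        if self.regime is not None and self.branch != "resnet":
            raise ValueError("training regimes apply to the resnet branch only")

    @property
    def resolved_lr(self) -> float:
        if self.lr is not None:
            return self.lr
        if self.regime in ("FT", "scratch"):
            return DEFAULT_REGIME_LR[self.regime]
        return DEFAULT_CLASSIFIER_LR

    @property
    def resolved_scheduler(self) -> bool:
        if self.scheduler is not None:
            return self.scheduler
        return self.regime in ("FT", "scratch")


@dataclass
class RunRecord:
    """Everything one fold's training run produced."""

    spec: ExperimentSpec
    fold_id: int
    train_losses: list[float]
    val_auprc: list[float]
    best_epoch: int
    val_metrics: dict[str, float]
    test_metrics: dict[str, float] | None
    split_hash: str
    train_indices: list[int]
    val_indices: list[int]
    lr_trace: list[float] = field(default_factory=list)


def _minibatches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def _check_two_classes(y):
    if len(np.unique(y)) < 2:
        raise TrainingError("training fold contains a single class")


def _pos_weight(y) -> float:
    pos = int(np.sum(y == 1))
    return (len(y) - pos) / pos if pos else 1.0


# ---------------------------------------------------------------------------
# autoencoder pretraining

def train_autoencoder(volumes: np.ndarray, spec: AutoencoderSpec,
                      epochs: int = 30, batch_size: int = 8,
                      lr: float = 1e-3, seed: int = 0):
    """Fit the autoencoder with each volume as both input and target.

    Returns (model, history) where history['train_loss'] holds per-epoch
    mean reconstruction MSE.
    """
    model: Autoencoder = build(spec, seed=seed)
    rng = np.random.default_rng(seed + 1)
    opt = Adam(model.parameters(), lr=lr)
    history = {"train_loss": []}
    best = (np.inf, None)
    for _epoch in range(epochs):
        losses = []
        for idx in _minibatches(len(volumes), batch_size, rng):
            x = volumes[idx]
            recon = model.forward(x, train=True)
            loss, dr = mse_loss(recon, x)
            if not np.isfinite(loss):
                raise TrainingError("autoencoder diverged (non-finite loss)")
            opt.zero_grad()
            model.backward(dr)
            opt.step()
            losses.append(loss)
        epoch_loss = float(np.mean(losses))
        history["train_loss"].append(epoch_loss)
        if epoch_loss < best[0]:
            best = (epoch_loss, copy.deepcopy(nn.state_arrays(model)))
    if best[1] is not None:
        nn.load_state(model, best[1])
    history["best_epoch"] = int(np.argmin(history["train_loss"])) if history["train_loss"] else 0
    return model, history


# ---------------------------------------------------------------------------
# classifier training on fixed feature matrices

def train_linear_head(X_tr, y_tr, X_va, y_va, spec: ExperimentSpec):
    """Single-layer classifier on precomputed features; checkpoint selected
    by best validation AUPRC with early stopping."""
    _check_two_classes(y_tr)
    width = X_tr.shape[1]
    model: LinearClassifier = build(ClassifierSpec({"input": width}),
                                    seed=spec.seed)
    rng = np.random.default_rng(spec.seed + 1)
    opt = Adam(model.parameters(), lr=spec.resolved_lr,
               weight_decay=spec.weight_decay)
    sched = ReduceLROnPlateau(opt) if spec.resolved_scheduler else None
    pw = _pos_weight(y_tr) if spec.pos_class_weight else None
    history = {"train_loss": [], "val_auprc": [], "lr": []}
    best = (-np.inf, 0, None)
    since_best = 0
    for epoch in range(spec.epochs):
        losses = []
        for idx in _minibatches(len(y_tr), spec.batch_size, rng):
            logits = model.forward(X_tr[idx], train=True)
            loss, dz = bce_with_logits(logits, y_tr[idx], pos_weight=pw)
            if not np.isfinite(loss):
                raise TrainingError("classifier diverged (non-finite loss)")
            opt.zero_grad()
            model.backward(dz)
            opt.step()
            losses.append(loss)
        val_probs = model.predict_proba(X_va)
        val_ap = M.auprc(val_probs, y_va)
        val_loss, _ = bce_with_logits(model.forward(X_va), y_va, pos_weight=pw)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_auprc"].append(val_ap)
        history["lr"].append(opt.lr)
        if sched is not None:
            sched.step(val_loss)
        if val_ap > best[0]:
            best = (val_ap, epoch, copy.deepcopy(nn.state_arrays(model)))
            since_best = 0
        else:
            since_best += 1
            if since_best > spec.patience:
                break
    nn.load_state(model, best[2])
    history["best_epoch"] = best[1]
    return model, history


# ---------------------------------------------------------------------------
# end-to-end image models

def _image_forward_probs(model, vols, tabs=None, batch_size: int = 16):
    probs = []
    for start in range(0, len(vols), batch_size):
        sl = slice(start, start + batch_size)
        t = tabs[sl] if tabs is not None else None
        if isinstance(model, (DaftClassifier,)):
            logit = model.forward(vols[sl], tab=t, train=False)
        else:
            logit = model.forward(vols[sl], tab=t, train=False)
        probs.append(1.0 / (1.0 + np.exp(-logit.ravel())))
    return np.concatenate(probs)


def backbone_features(model: ResNetClassifier, vols, batch_size: int = 16):
    """Pooled backbone features in inference mode (used for frozen-backbone
    classifier retraining in the combined arms)."""
    feats = []
    for start in range(0, len(vols), batch_size):
        feats.append(model.backbone.forward(vols[start:start + batch_size],
                                            train=False))
    return np.vstack(feats)


def train_image_model(vols_tr, y_tr, vols_va, y_va, rspec: ResNetSpec,
                      xspec: ExperimentSpec, pretrained_state=None,
                      tabs_tr=None, tabs_va=None, dspec: DaftSpec | None = None):
    """Train a CNN branch end to end (resnet regimes or the DAFT baseline)."""
    _check_two_classes(y_tr)
    if dspec is not None:
        model = build(dspec, seed=xspec.seed)
    else:
        model = build(rspec, seed=xspec.seed, tab_dim=0)
        if pretrained_state is not None:
            nn.load_state(model.backbone, pretrained_state)
        if xspec.regime == "TL":
            model.backbone.freeze()
    rng = np.random.default_rng(xspec.seed + 1)
    opt = Adam(model.parameters(), lr=xspec.resolved_lr,
               weight_decay=xspec.weight_decay)
    sched = ReduceLROnPlateau(opt) if xspec.resolved_scheduler else None
    pw = _pos_weight(y_tr) if xspec.pos_class_weight else None
    history = {"train_loss": [], "val_auprc": [], "lr": []}
    best = (-np.inf, 0, None)
    since_best = 0
    for epoch in range(xspec.epochs):
        losses = []
        for idx in _minibatches(len(y_tr), xspec.batch_size, rng):
            t = tabs_tr[idx] if tabs_tr is not None else None
            logits = model.forward(vols_tr[idx], tab=t, train=True)
            loss, dz = bce_with_logits(logits, y_tr[idx], pos_weight=pw)
            if not np.isfinite(loss):
                raise TrainingError("image model diverged (non-finite loss)")
            opt.zero_grad()
            model.backward(dz)
            opt.step()
            losses.append(loss)
        val_probs = _image_forward_probs(model, vols_va, tabs_va)
        val_ap = M.auprc(val_probs, y_va)
        vlogit = np.log(np.clip(val_probs, 1e-12, 1 - 1e-12)
                        / np.clip(1 - val_probs, 1e-12, 1))
        val_loss, _ = bce_with_logits(vlogit, y_va, pos_weight=pw)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_auprc"].append(val_ap)
        history["lr"].append(opt.lr)
        if sched is not None:
            sched.step(val_loss)
        if val_ap > best[0]:
            best = (val_ap, epoch, copy.deepcopy(nn.state_arrays(model)))
            since_best = 0
        else:
            since_best += 1
            if since_best > xspec.patience:
                break
    nn.load_state(model, best[2])
    history["best_epoch"] = best[1]
    return model, history


def make_surrogate_backbone(vols_tr, rspec: ResNetSpec, seed: int = 0,
                            epochs: int = 5, batch_size: int = 8,
                            lr: float = 1e-3):
    """SYNTHETIC surrogate for an externally pretrained backbone.

    When no pretrained checkpoint is supplied, the transfer-learning regime
    needs *some* non-task-specific backbone.  This fits the backbone with a
    self-supervised regression head that reproduces an 8x8x8 trilinear
    thumbnail of the masked input volume (an autoencoding-style task), then
    discards the head.  Returns the backbone state dict.
    """
    from .nn import Dense, Module

    class _Surrogate(Module):
        def __init__(self, rng):
            super().__init__()
            self.backbone = build(rspec, seed=seed, tab_dim=0).backbone
            self.head = Dense(rspec.feature_width, 8 ** 3, rng)

        def forward(self, x, train=False):
            return self.head.forward(self.backbone.forward(x, train=train),
                                     train=train)

        def backward(self, g):
            self.backbone.backward(self.head.backward(g))

    rng = np.random.default_rng(seed + 2)
    model = _Surrogate(rng)
    targets = np.stack([trilinear_resize(v[0], (8, 8, 8)).ravel()
                        for v in vols_tr])
    opt = Adam(model.parameters(), lr=lr)
    for _ in range(epochs):
        for idx in _minibatches(len(vols_tr), batch_size, rng):
            pred = model.forward(vols_tr[idx], train=True)
            loss, dp = mse_loss(pred, targets[idx])
            if not np.isfinite(loss):
                raise TrainingError("surrogate pretraining diverged")
            opt.zero_grad()
            model.backward(dp)
            opt.step()
    return nn.state_arrays(model.backbone)


def select_best_image_model(candidates: list[dict]) -> dict:
    """Pick the image-branch candidate with the highest mean validation
    AUPRC across folds; ties break on lower SD, then on fixed regime order.

    Each candidate dict needs keys 'label', 'regime', 'val_auprc' (one value
    per fold); all candidates must cover identical fold counts.
    """
    if not candidates:
        raise ValueError("no candidates to select from")
    nfolds = {len(c["val_auprc"]) for c in candidates}
    if len(nfolds) != 1:
        raise ValueError("candidates ran on different fold sets")

    def key(c):
        vals = np.asarray(c["val_auprc"], dtype=float)
        order = (REGIME_ORDER.index(c["regime"])
                 if c["regime"] in REGIME_ORDER else len(REGIME_ORDER))
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        return (-float(np.mean(vals)), sd, order)

    return min(candidates, key=key)


# ---------------------------------------------------------------------------
# the full suite

@dataclass
class SuiteConfig:
    """Scaled-down defaults sized for desk hardware; every knob is explicit."""

    outcomes: tuple = ("los", "mrs")
    arms: tuple = ("clinical", "image", "combined")
    branches: tuple = ("resnet", "autoencoder", "daft")
    regimes: tuple = ("scratch",)  # candidates for the resnet image branch
    se_variants: bool = False      # add FT+SE / scratch+SE candidates
    resnet_widths: tuple = (8, 16, 32, 64)
    ae_channels: tuple = (8, 16, 32)
    latent_dim: int = 64
    epochs_ae: int = 20
    epochs_image: int = 8
    epochs_clf: int = 60
    batch_volumes: int = 8
    batch_tabular: int = 64
    lr_image: float | None = 1e-3  # None -> paper default per regime
    lr_ae: float = 1e-3
    patience_clf: int = 15
    patience_image: int = 4
    test_fraction: float = 0.2
    n_folds: int = 3
    threshold: float = 0.5
    seed: int = 0
    pretrained_backbone: str | None = None


@dataclass
class SuiteResult:
    reports: dict  # outcome -> {row label -> MetricReport}
    records: list[RunRecord]
    plans: dict    # outcome -> SplitPlan
    config: SuiteConfig


def _fold_spec(config: SuiteConfig, arm: str, outcome: str, branch=None,
               regime=None, use_ehr=True, use_idf=False, lr=None,
               epochs=None, batch=None, patience=None) -> ExperimentSpec:
    return ExperimentSpec(
        arm=arm, outcome=outcome, branch=branch, regime=regime,
        use_ehr=use_ehr, use_idf=use_idf, lr=lr,
        epochs=epochs if epochs is not None else config.epochs_clf,
        batch_size=batch if batch is not None else config.batch_tabular,
        patience=patience if patience is not None else config.patience_clf,
        seed=config.seed)


def run_suite(table: pd.DataFrame, volumes: np.ndarray, schema,
              config: SuiteConfig) -> SuiteResult:
    """Run every requested arm x branch x (+/- IDF) cell on three folds and
    aggregate test metrics as mean (SD), one results row per cell.

    ``volumes`` is the stacked (N, 1, D, H, W) array aligned row-for-row
    with ``table``.
    """
    reports: dict = {}
    records: list[RunRecord] = []
    plans: dict = {}
    for outcome in config.outcomes:
        col = schema.outcome_columns[outcome]
        labels_full = dichotomize(table[col].to_numpy(dtype=float), outcome)
        keep = np.flatnonzero(~np.isnan(labels_full))
        rows = table.iloc[keep].reset_index(drop=True)
        vols = volumes[keep]
        y = labels_full[keep].astype(int)
        plan = make_split_plan(y, outcome=outcome,
                               test_fraction=config.test_fraction,
                               n_folds=config.n_folds, seed=config.seed)
        plans[outcome] = plan
        reports[outcome] = _run_outcome(rows, vols, y, plan, schema, config,
                                        outcome, records)
    return SuiteResult(reports=reports, records=records, plans=plans,
                       config=config)


def _run_outcome(rows, vols, y, plan: SplitPlan, schema, config: SuiteConfig,
                 outcome: str, records: list[RunRecord]) -> dict:
    test = np.asarray(plan.test_indices)
    y_test = y[test]
    out: dict = {}

    fold_blocks = []  # per fold: dict of encoded feature blocks for all rows
    for f, fold in enumerate(plan.folds):
        tr = np.asarray(fold["train"])
        ehr_pre = Preprocessor(schema, include_clinical=True,
                               include_idf=False).fit(rows.iloc[tr])
        idf_pre = Preprocessor(schema, include_clinical=False,
                               include_idf=True).fit(rows.iloc[tr])
        fold_blocks.append({"ehr": ehr_pre.transform(rows),
                            "idf": idf_pre.transform(rows)})

    def tab_block(f, use_ehr, use_idf):
        parts = []
        if use_ehr:
            parts.append(fold_blocks[f]["ehr"])
        if use_idf:
            parts.append(fold_blocks[f]["idf"])
        return np.hstack(parts) if parts else None

    def run_feature_row(label, feature_fn, spec_proto):
        """feature_fn(f) -> all-row feature matrix for fold f."""
        fold_metrics = []
        for f, fold in enumerate(plan.folds):
            tr, va = np.asarray(fold["train"]), np.asarray(fold["val"])
            X = feature_fn(f)
            spec = replace(spec_proto, seed=config.seed + f)
            model, hist = train_linear_head(X[tr], y[tr], X[va], y[va], spec)
            test_m = M.evaluate(model.predict_proba(X[test]), y_test,
                                config.threshold)
            fold_metrics.append(test_m)
            records.append(RunRecord(
                spec=spec, fold_id=f, train_losses=hist["train_loss"],
                val_auprc=hist["val_auprc"], best_epoch=hist["best_epoch"],
                val_metrics={"auprc": max(hist["val_auprc"])},
                test_metrics=test_m, split_hash=plan.plan_hash,
                train_indices=tr.tolist(), val_indices=va.tolist(),
                lr_trace=hist["lr"]))
        out[label] = M.aggregate(fold_metrics, threshold=config.threshold,
                                 n_pos=int(y_test.sum()),
                                 n_neg=int(len(y_test) - y_test.sum()),
                                 label=label)

    # ----- clinical arm -------------------------------------------------
    if "clinical" in config.arms:
        for label, use_ehr, use_idf in (("Clinical/EHR", True, False),
                                        ("Clinical/EHR w/IDF", True, True),
                                        ("Clinical/IDF", False, True)):
            run_feature_row(label, lambda f, e=use_ehr, i=use_idf: tab_block(f, e, i),
                            _fold_spec(config, "clinical", outcome,
                                       use_ehr=use_ehr, use_idf=use_idf))

    image_on = "image" in config.arms
    combined_on = "combined" in config.arms

    # ----- autoencoder branch ------------------------------------------
    if (image_on or combined_on) and "autoencoder" in config.branches:
        ae_spec = AutoencoderSpec(grid_shape=vols.shape[2:],
                                  channels=config.ae_channels,
                                  latent_dim=config.latent_dim)
        embeddings = []
        for f, fold in enumerate(plan.folds):
            tr = np.asarray(fold["train"])
            ae, _ = train_autoencoder(vols[tr], ae_spec,
                                      epochs=config.epochs_ae,
                                      batch_size=config.batch_volumes,
                                      lr=config.lr_ae, seed=config.seed + f)
            embeddings.append(encode(vols, ae))
        if image_on:
            run_feature_row("Image/AE", lambda f: embeddings[f],
                            _fold_spec(config, "image", outcome,
                                       branch="autoencoder", use_ehr=False))
            run_feature_row("Image/AE w/IDF",
                            lambda f: np.hstack([embeddings[f],
                                                 fold_blocks[f]["idf"]]),
                            _fold_spec(config, "image", outcome,
                                       branch="autoencoder", use_ehr=False,
                                       use_idf=True))
        if combined_on:
            run_feature_row("Combined/AE",
                            lambda f: np.hstack([embeddings[f],
                                                 fold_blocks[f]["ehr"]]),
                            _fold_spec(config, "combined", outcome,
                                       branch="autoencoder"))
            run_feature_row("Combined/AE w/IDF",
                            lambda f: np.hstack([embeddings[f],
                                                 tab_block(f, True, True)]),
                            _fold_spec(config, "combined", outcome,
                                       branch="autoencoder", use_idf=True))

    # ----- resnet branch ------------------------------------------------
    if (image_on or combined_on) and "resnet" in config.branches:
        candidates = []
        regs = []
        for regime in config.regimes:
            regs.append((regime, False))
            if config.se_variants and regime in ("FT", "scratch"):
                regs.append((regime, True))
        pretrained = None
        for regime, se in regs:
            rspec = ResNetSpec(widths=config.resnet_widths, se_enabled=se)
            if regime in ("TL", "FT") and pretrained is None:
                if config.pretrained_backbone:
                    base = build(rspec, seed=config.seed, tab_dim=0)
                    from .networks import load_checkpoint
                    load_checkpoint(base.backbone, config.pretrained_backbone)
                    pretrained = nn.state_arrays(base.backbone)
                else:
                    tr0 = np.asarray(plan.folds[0]["train"])
                    pretrained = make_surrogate_backbone(
                        vols[tr0], ResNetSpec(widths=config.resnet_widths),
                        seed=config.seed)
            label = regime + ("+SE" if se else "")
            fold_models, fold_val = [], []
            for f, fold in enumerate(plan.folds):
                tr, va = np.asarray(fold["train"]), np.asarray(fold["val"])
                xspec = ExperimentSpec(
                    arm="image", outcome=outcome, branch="resnet",
                    regime=regime, use_ehr=False, lr=config.lr_image,
                    epochs=config.epochs_image,
                    batch_size=config.batch_volumes,
                    patience=config.patience_image, seed=config.seed + f)
                pstate = pretrained if regime in ("TL", "FT") else None
                model, hist = train_image_model(vols[tr], y[tr], vols[va],
                                                y[va], rspec, xspec,
                                                pretrained_state=pstate)
                fold_models.append(model)
                fold_val.append(max(hist["val_auprc"]))
                records.append(RunRecord(
                    spec=xspec, fold_id=f, train_losses=hist["train_loss"],
                    val_auprc=hist["val_auprc"], best_epoch=hist["best_epoch"],
                    val_metrics={"auprc": max(hist["val_auprc"])},
                    test_metrics=None, split_hash=plan.plan_hash,
                    train_indices=tr.tolist(), val_indices=va.tolist(),
                    lr_trace=hist["lr"]))
            candidates.append({"label": label, "regime": regime,
                               "val_auprc": fold_val, "models": fold_models})
        chosen = select_best_image_model(candidates)
        feats = [backbone_features(m, vols) for m in chosen["models"]]
        if image_on:
            fold_metrics = []
            for f, m in enumerate(chosen["models"]):
                probs = _image_forward_probs(m, vols[test])
                fold_metrics.append(M.evaluate(probs, y_test, config.threshold))
            out["Image/Resnet"] = M.aggregate(
                fold_metrics, threshold=config.threshold,
                n_pos=int(y_test.sum()),
                n_neg=int(len(y_test) - y_test.sum()), label="Image/Resnet")
            out["Image/Resnet"].extras["selected"] = chosen["label"]
            run_feature_row("Image/Resnet w/IDF",
                            lambda f: np.hstack([feats[f],
                                                 fold_blocks[f]["idf"]]),
                            _fold_spec(config, "image", outcome,
                                       branch="resnet", use_ehr=False,
                                       use_idf=True))
        if combined_on:
            run_feature_row("Combined/Resnet",
                            lambda f: np.hstack([feats[f],
                                                 fold_blocks[f]["ehr"]]),
                            _fold_spec(config, "combined", outcome,
                                       branch="resnet"))
            run_feature_row("Combined/Resnet w/IDF",
                            lambda f: np.hstack([feats[f],
                                                 tab_block(f, True, True)]),
                            _fold_spec(config, "combined", outcome,
                                       branch="resnet", use_idf=True))

    # ----- DAFT baseline ------------------------------------------------
    if combined_on and "daft" in config.branches:
        for label, use_idf in (("Combined/DAFT", False),
                               ("Combined/DAFT w/IDF", True)):
            fold_metrics = []
            for f, fold in enumerate(plan.folds):
                tr, va = np.asarray(fold["train"]), np.asarray(fold["val"])
                tabs = tab_block(f, True, use_idf)
                rspec = ResNetSpec(widths=config.resnet_widths)
                dspec = DaftSpec(resnet=rspec, tab_dim=tabs.shape[1])
                xspec = ExperimentSpec(
                    arm="combined", outcome=outcome, branch="daft",
                    use_idf=use_idf, lr=config.lr_image or 1e-3,
                    epochs=config.epochs_image,
                    batch_size=config.batch_volumes,
                    patience=config.patience_image, seed=config.seed + f)
                model, hist = train_image_model(
                    vols[tr], y[tr], vols[va], y[va], rspec, xspec,
                    tabs_tr=tabs[tr], tabs_va=tabs[va], dspec=dspec)
                probs = _image_forward_probs(model, vols[test], tabs[test])
                test_m = M.evaluate(probs, y_test, config.threshold)
                fold_metrics.append(test_m)
                records.append(RunRecord(
                    spec=xspec, fold_id=f, train_losses=hist["train_loss"],
                    val_auprc=hist["val_auprc"], best_epoch=hist["best_epoch"],
                    val_metrics={"auprc": max(hist["val_auprc"])},
                    test_metrics=test_m, split_hash=plan.plan_hash,
                    train_indices=tr.tolist(), val_indices=va.tolist(),
                    lr_trace=hist["lr"]))
            out[label] = M.aggregate(fold_metrics, threshold=config.threshold,
                                     n_pos=int(y_test.sum()),
                                     n_neg=int(len(y_test) - y_test.sum()),
                                     label=label)
    return out


ROW_ORDER = ("Clinical/EHR", "Clinical/EHR w/IDF", "Clinical/IDF",
             "Image/Resnet", "Image/Resnet w/IDF", "Image/AE",
             "Image/AE w/IDF", "Combined/DAFT", "Combined/DAFT w/IDF",
             "Combined/Resnet", "Combined/Resnet w/IDF", "Combined/AE",
             "Combined/AE w/IDF")


def results_table(result: SuiteResult, outcome: str) -> pd.DataFrame:
    """Results rows in the canonical arm order, metrics as 'mean (SD)'."""
    rows = result.reports[outcome]
    data = []
    for label in ROW_ORDER:
        if label in rows:
            rep = rows[label]
            data.append({"Experiment": label,
                         "AUC": rep.row()["auc"],
                         "AUPRC": rep.row()["auprc"],
                         "Recall": rep.row()["recall"],
                         "Specificity": rep.row()["specificity"],
                         "F1-Score": rep.row()["f1"]})
    return pd.DataFrame(data)


def check_no_leakage(result: SuiteResult) -> bool:
    """Hold-out indices must never appear in any training or validation log."""
    for outcome, plan in result.plans.items():
        test = set(plan.test_indices)
        for rec in result.records:
            if rec.split_hash != plan.plan_hash:
                continue
            if test & set(rec.train_indices) or test & set(rec.val_indices):
                raise TrainingError(
                    f"hold-out subjects leaked into fold {rec.fold_id}")
    return True
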