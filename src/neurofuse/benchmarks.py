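"""Canned phantom studies exercising the full pipeline at desk scale.

These are the package's built-in validation experiments: each plants a known
signal with the phantom generator, runs the same code paths a real cohort
would take, and measures whether the pipeline recovers the signal.  They are
deliberately small (200 subjects, 32-cubed grids, narrow network widths) so
a full run fits on a laptop CPU in minutes; the methods note discusses what
these scales do and do not demonstrate.
"""

from __future__ import annotations

import numpy as np

from . import metrics as M
from . import phantom, tabular, training, volumes
from .interpret import chance_fraction, gradcam, localization_score
from .networks import AutoencoderSpec, ResNetSpec, encode
from .tabular import Preprocessor, make_split_plan, phantom_schema
from .training import ExperimentSpec, train_autoencoder, train_image_model, train_linear_head

#: narrow desk-scale widths for the ResNet-10 (the full-width default is
#: (64, 128, 256, 512); at 32^3 on one CPU that is out of scope for tests)
DESK_WIDTHS = (8, 16, 32, 64)
AE_EPOCHS = 30


def lesion_signal_config(seed: int, n_subjects: int = 200) -> phantom.PhantomConfig:
    """Phantom whose outcome depends ONLY on lesion volume (coefficient
    2.5 per cm^3, generating-truth AUC ~0.93), with the severity-volume
    coupling switched off, so the tabular clinical block carries no outcome
    signal at all.  Recovering performance then requires the image branch."""
    return phantom.PhantomConfig(
        n_subjects=n_subjects, seed=seed,
        outcome_coefficients={"los": {"lesion_volume_cm3": 2.5}},
        severity_lesion_coupling=0.0)


def _cohort_arrays(config: phantom.PhantomConfig):
    cohort = phantom.generate_cohort(config)
    batch = volumes.stack_volumes(cohort.volumes)
    y = np.asarray(cohort.generating_truth["outcomes"]["los"]["labels"])
    return cohort, batch.data, y


def planted_signal_study(seed: int, n_subjects: int = 200,
                         ae_epochs: int = AE_EPOCHS) -> dict:
    """Combined (embedding + EHR) vs clinical (EHR only) arms on a phantom
    whose outcome is driven by lesion volume excluded from the tabular block.

    One autoencoder is fit per seed on the first fold's training subjects
    (hold-out untouched); the classifier arms run on all three folds.
    Also returns the held-out linear-probe R^2 from latent vectors to true
    lesion volume, sharing the same autoencoder.
    """
    cohort, vols, y = _cohort_arrays(lesion_signal_config(seed, n_subjects))
    schema = phantom_schema()
    plan = make_split_plan(y, "los", seed=seed)
    test = np.asarray(plan.test_indices)
    tr0 = np.asarray(plan.folds[0]["train"])

    ae, _ = train_autoencoder(vols[tr0], AutoencoderSpec(
        grid_shape=vols.shape[2:], latent_dim=64),
        epochs=ae_epochs, batch_size=8, seed=seed)
    emb = encode(vols, ae)

    auc_clinical, auc_combined = [], []
    for f, fold in enumerate(plan.folds):
        tr, va = np.asarray(fold["train"]), np.asarray(fold["val"])
        pre = Preprocessor(schema, include_idf=False).fit(cohort.table.iloc[tr])
        X_ehr = pre.transform(cohort.table)
        # embeddings are continuous features to the combined classifier, so
        # they get the same treatment as other continuous features:
        # standardized with training-fold statistics
        mu = emb[tr].mean(axis=0)
        sd = emb[tr].std(axis=0) + 1e-12
        X_comb = np.hstack([(emb - mu) / sd, X_ehr])
        m_cl, _ = train_linear_head(
            X_ehr[tr], y[tr], X_ehr[va], y[va],
            ExperimentSpec(arm="clinical", epochs=300, patience=60,
                           weight_decay=1e-2, seed=seed + f))
        m_co, _ = train_linear_head(
            X_comb[tr], y[tr], X_comb[va], y[va],
            ExperimentSpec(arm="combined", branch="autoencoder", epochs=300,
                           patience=60, weight_decay=1e-2, seed=seed + f))
        auc_clinical.append(M.auc(m_cl.predict_proba(X_ehr[test]), y[test]))
        auc_combined.append(M.auc(m_co.predict_proba(X_comb[test]), y[test]))

    # linear probe with shrinkage chosen on the training rows only: with
    # ~130 training rows and 64 latent features an unregularized readout
    # memorizes the training set
    from sklearn.linear_model import RidgeCV

    lv = cohort.table.lesion_volume_cm3.to_numpy()
    muz = emb[tr0].mean(axis=0)
    sdz = emb[tr0].std(axis=0) + 1e-12
    embz = (emb - muz) / sdz
    probe = RidgeCV(alphas=np.logspace(-2, 3, 13), cv=5).fit(embz[tr0], lv[tr0])
    r2 = float(probe.score(embz[test], lv[test]))
    return {"auc_clinical": float(np.mean(auc_clinical)),
            "auc_combined": float(np.mean(auc_combined)),
            "probe_r2": r2}


def null_calibration_study(seed: int, n_subjects: int = 400) -> dict:
    """Labels permuted independently of every input: test AUPRC should sit
    near prevalence and AUC near one half (averaged over the three folds).

    Uses a larger cohort than the signal studies: at small n, chance
    cohort-wide feature-label associations survive the train/test split and
    masquerade as signal."""
    cohort, _, y = _cohort_arrays(lesion_signal_config(seed, n_subjects))
    rng = np.random.default_rng(seed + 1000)
    y_null = rng.permutation(y)
    schema = phantom_schema()
    plan = make_split_plan(y_null, "los", seed=seed)
    test = np.asarray(plan.test_indices)
    aucs, auprcs = [], []
    for f, fold in enumerate(plan.folds):
        tr, va = np.asarray(fold["train"]), np.asarray(fold["val"])
        pre = Preprocessor(schema).fit(cohort.table.iloc[tr])
        X = pre.transform(cohort.table)
        model, _ = train_linear_head(
            X[tr], y_null[tr], X[va], y_null[va],
            ExperimentSpec(arm="clinical", use_idf=True, epochs=60,
                           seed=seed + f))
        probs = model.predict_proba(X[test])
        aucs.append(M.auc(probs, y_null[test]))
        auprcs.append(M.auprc(probs, y_null[test]))
    return {"auc": float(np.mean(aucs)),
            "auprc": float(np.mean(auprcs)),
            "prevalence": float(y_null[test].mean())}


def gradcam_localization_study(seed: int, n_subjects: int = 200,
                               epochs: int = 15,
                               target_layer: str = "stage1") -> dict:
    """Train a lesion-driven CNN from scratch and measure how much Grad-CAM
    heat falls inside the lesion, against the lesion's share of the brain.

    Two desk-scale choices, both documented in the methods note: the
    saliency map is taken at ``stage1`` (8^3 on a 32^3 grid) because the
    last residual stage pools to a single cell at this input size, which
    after upsampling is spatially uniform and cannot localize anything; and
    the heat is restricted to the brain mask before scoring, since saliency
    outside a zero-masked input reflects convolution boundary offsets, not
    evidence, while the chance reference is the lesion's share of the brain.
    """
    cohort, vols, y = _cohort_arrays(lesion_signal_config(seed, n_subjects))
    plan = make_split_plan(y, "los", seed=seed)
    fold = plan.folds[0]
    tr, va = np.asarray(fold["train"]), np.asarray(fold["val"])
    test = np.asarray(plan.test_indices)
    rspec = ResNetSpec(widths=DESK_WIDTHS)
    xspec = ExperimentSpec(arm="image", branch="resnet", regime="scratch",
                           use_ehr=False, lr=3e-3, epochs=epochs,
                           batch_size=8, patience=epochs, seed=seed)
    model, _ = train_image_model(vols[tr], y[tr], vols[va], y[va],
                                 rspec, xspec)
    scores, chances = [], []
    for i in test[:10]:
        sal = gradcam(model, vols[i:i + 1], target_layer=target_layer)
        brain = cohort.volumes[i].brain_mask
        scores.append(localization_score(sal.heat * brain,
                                         cohort.volumes[i].lesion_mask))
        chances.append(chance_fraction(cohort.volumes[i].lesion_mask, brain))
    return {"heat_in_lesion": float(np.mean(scores)),
            "chance_fraction": float(np.mean(chances))}


def prevalence_calibration_study(seeds=(0, 1, 2), n_subjects: int = 2000) -> dict:
    """Empirical label prevalence vs the calibration targets, per outcome.

    Uses a coarse grid so the volumetric part stays cheap at n = 2000."""
    out = {"los": [], "mrs": []}
    for seed in seeds:
        cfg = phantom.PhantomConfig(
            n_subjects=n_subjects, seed=seed, grid_shape=(16, 16, 16),
            voxel_volume=64.0, lesion_axis_range=(1.0, 3.0))
        cohort = phantom.generate_cohort(cfg)
        for outcome in ("los", "mrs"):
            labels = np.asarray(
                cohort.generating_truth["outcomes"][outcome]["labels"])
            out[outcome].append(float(labels.mean()))
    return {k: v for k, v in out.items()}


def suite_determinism_study(seed: int = 0, n_subjects: int = 60) -> dict:
    """Run a miniature full suite twice with identical seeds; the two runs
    must emit identical results tables (bit-identical determinism)."""
    cfg = phantom.PhantomConfig(n_subjects=n_subjects, grid_shape=(16, 16, 16),
                                voxel_volume=64.0,
                                lesion_axis_range=(1.0, 3.0), seed=seed)
    cohort = phantom.generate_cohort(cfg)
    batch = volumes.stack_volumes(cohort.volumes)
    sconf = training.SuiteConfig(
        outcomes=("los",), epochs_ae=4, epochs_image=2, epochs_clf=15,
        resnet_widths=(4, 8, 8, 8), latent_dim=16, seed=seed)
    results = []
    for _ in range(2):
        res = training.run_suite(cohort.table, batch.data, phantom_schema(),
                                 sconf)
        training.check_no_leakage(res)
        results.append(training.results_table(res, "los"))
    return {"identical": bool(results[0].equals(results[1])),
            "n_rows": int(len(results[0])),
            "tables": results}
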