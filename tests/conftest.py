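"""Shared fixtures: the phantom cohort, its preprocessed dataset, and the
end-to-end phantom training study reused by several tests."""

from __future__ import annotations

import numpy as np
import pytest

from noduleclip.inference import (ensemble, fit_beta_calibrator, patient_scores,
                                  zero_shot_infer)
from noduleclip.metrics import auroc, expected_calibration_error
from noduleclip.model import build_model
from noduleclip.phantoms import PhantomConfig, generate_cases
from noduleclip.semantics import build_prompts, default_schema
from noduleclip.training import (NoduleDataset, TrainConfig, make_splits,
                                 predict_probs, train_fold)

PHANTOM_SEED = 7
PHANTOM_N = 400
PHANTOM_VOLUME = 32  # voxels; desk-scale study volumes
TINY_IMAGE_SIZE = 56


@pytest.fixture(scope="session")
def phantom_config() -> PhantomConfig:
    return PhantomConfig(n_cases=PHANTOM_N, volume_size=PHANTOM_VOLUME,
                         seed=PHANTOM_SEED)


@pytest.fixture(scope="session")
def phantom_cohort(phantom_config):
    return generate_cases(phantom_config)


@pytest.fixture(scope="session")
def phantom_dataset(phantom_cohort) -> NoduleDataset:
    return NoduleDataset.from_cases(phantom_cohort, image_size=TINY_IMAGE_SIZE)


def run_phantom_study(dataset: NoduleDataset, seed: int, n_folds: int = 2,
                      epochs: int = 50):
    """The end-to-end phantom protocol: patient-level splits, per-fold tiny
    from-scratch training with the full objective, Beta calibration on each
    fold's validation split, fold ensembling, and held-out patient scoring.

    The run seed drives the whole stochastic path (split, fold seeds,
    training); training runs the full epoch budget from random
    initialization at the from-scratch learning rate with view-level flip
    augmentation. Returns a dict with the held-out patient AUROC, the
    trained fold models, calibration diagnostics and the calibrated test
    probabilities.
    """
    plan = make_splits(dataset.patient_ids, seed=seed)
    test_idx = dataset.indices_for_patients(plan.test_patients)
    cfg = TrainConfig(seed=seed, epochs=epochs, patience=epochs,
                      tuning="full", lr=1e-3, view_aug="flip")
    fold_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                  for s in np.random.SeedSequence(seed).spawn(n_folds)]
    models, fold_results, calibrated, ece_pairs = [], [], [], []
    for k in range(n_folds):
        tr = dataset.indices_for_patients(plan.folds[k]["train"])
        va = dataset.indices_for_patients(plan.folds[k]["val"])
        res = train_fold(dataset, tr, va, cfg, seed=fold_seeds[k])
        model = build_model("tiny", seed=fold_seeds[k], tau_init=cfg.tau_init)
        model.load_state_dict(res.state)
        val_probs = predict_probs(model, dataset.view_stacks[va])
        cal = fit_beta_calibrator(val_probs, dataset.labels[va])
        ece_pairs.append((
            expected_calibration_error(val_probs, dataset.labels[va]),
            expected_calibration_error(cal(val_probs), dataset.labels[va])))
        test_probs = predict_probs(model, dataset.view_stacks[test_idx])
        calibrated.append(cal(test_probs))
        models.append(model)
        fold_results.append(res)
    ens = ensemble(calibrated, expected=n_folds)
    test_pids = [dataset.patient_ids[i] for i in test_idx]
    pat = patient_scores(ens, test_pids)
    pat_label = {p: int(l) for p, l in zip(test_pids, dataset.labels[test_idx])}
    pids = sorted(pat)
    return {
        "plan": plan,
        "test_idx": test_idx,
        "models": models,
        "fold_results": fold_results,
        "calibrated_test": calibrated,
        "patient_auroc": auroc([pat[p] for p in pids], [pat_label[p] for p in pids]),
        "ece_before_after": ece_pairs,
    }


def zero_shot_consistency_auroc(model, dataset: NoduleDataset,
                                test_idx: np.ndarray) -> float:
    """Zero-shot solid vs pure-ground-glass discrimination on held-out
    phantoms whose consistency is one of the two classes."""
    bank = build_prompts(default_schema())
    scores, labels = [], []
    for i in test_idx:
        cons = dataset.records[i].get("consistency")
        if cons not in ("solid", "pure ground glass"):
            continue
        res = zero_shot_infer(model, dataset.view_stacks[i], bank)
        p = res.categorical["consistency"]
        denom = p["solid"] + p["pure ground glass"]
        scores.append(p["solid"] / denom if denom > 0 else 0.5)
        labels.append(int(cons == "solid"))
    return auroc(np.asarray(scores), np.asarray(labels))


@pytest.fixture(scope="session")
def phantom_study_runs(phantom_dataset):
    """Five independent repetitions of the end-to-end study (different master
    seeds), each with its zero-shot consistency score."""
    runs = []
    for seed in range(5):
        run = run_phantom_study(phantom_dataset, seed=seed)
        run["zero_shot_auroc"] = zero_shot_consistency_auroc(
            run["models"][0], phantom_dataset, run["test_idx"])
        # the models are large-ish; keep only what downstream tests use
        run.pop("models")
        runs.append(run)
    return runs
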