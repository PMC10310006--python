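"""Reproducible experiment driver: replicate loops, comparisons, ablations.

Each replicate regenerates the simulated cohort (new weight mask, new
split) from a seed derived deterministically from the master seed, trains
the ROI-wise CNN once (it serves every naive aggregation arm and, after
front-freezing, initialises the aggregation network), and records held-out
patient-level c-indices.  Summaries report mean +/- SD per method across
replicates.

Hyperparameter profiles
-----------------------
``sim_digit``   — the simulated-digit design at full scale: lr 5e-5,
                  weight decay 1e-3, 100 epochs, batch 32, LR decay 0.995.
``histology``   — full-size histology ROIs: lr 1e-6, weight decay 1e-2,
                  batch 32, 50 epochs (stage 1: lr 1e-5, wd 1e-6, batch 64,
                  30 epochs).
``desk``        — a scaled-down profile for CPU-only runs: the small CNN
                  backbone trained from scratch, lr 1e-3, 30 epochs,
                  5 replicates.  Clearly labelled; used by default for the
                  simulated designs in this package.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .baselines import AGGREGATION_RULES, evaluate_baseline, train_roi_cnn
from .encoder import EncoderConfig, TrainConfig, build_encoder, freeze_front
from .model import DalanConfig, DalanModel, predict_bags, train_dalan
from .simulator import SimulationConfig, build_simulation, oracle_patient_risk
from .survival import (concordance_index, kaplan_meier,
                       logrank_test, normalize_risks, stratify_by_risk,
                       RISK_GROUPS, RiskPrediction)

__all__ = [
    "ExperimentProfile", "PROFILES", "ABLATION_VARIANTS", "replicate_seed",
    "run_replicate", "run_comparison", "run_ablation", "risk_group_report",
    "summarize",
]

DIGIT_AUGMENT = ("hflip", "vflip", "rot90")
HISTOLOGY_AUGMENT = ("hflip", "vflip", "brightness", "contrast")


@dataclass
class ExperimentProfile:
    """Bundled stage-1 + bag-level training settings for one context."""

    name: str
    stage1: TrainConfig
    bag: TrainConfig
    n_repeats: int = 20
    augment: tuple[str, ...] = DIGIT_AUGMENT


PROFILES = {
    "sim_digit": ExperimentProfile(
        name="sim_digit",
        stage1=TrainConfig(lr=1e-5, weight_decay=1e-6, epochs=30, batch_size=64,
                           augment=DIGIT_AUGMENT),
        bag=TrainConfig(lr=5e-5, weight_decay=1e-3, epochs=100, batch_size=32,
                        lr_gamma=0.995, augment=DIGIT_AUGMENT),
        n_repeats=20, augment=DIGIT_AUGMENT),
    "histology": ExperimentProfile(
        name="histology",
        stage1=TrainConfig(lr=1e-5, weight_decay=1e-6, epochs=30, batch_size=64,
                           augment=HISTOLOGY_AUGMENT),
        bag=TrainConfig(lr=1e-6, weight_decay=1e-2, epochs=50, batch_size=32,
                        augment=HISTOLOGY_AUGMENT),
        n_repeats=20, augment=HISTOLOGY_AUGMENT),
    # scaled-down CPU profile: small CNN trained from scratch
    "desk": ExperimentProfile(
        name="desk",
        stage1=TrainConfig(lr=1e-3, weight_decay=1e-6, epochs=30, batch_size=64,
                           augment=DIGIT_AUGMENT),
        bag=TrainConfig(lr=1e-3, weight_decay=1e-3, epochs=30, batch_size=32,
                        lr_gamma=0.995, augment=DIGIT_AUGMENT),
        n_repeats=5, augment=DIGIT_AUGMENT),
}

ABLATION_VARIANTS = ("full", "no_finetuned_weights", "no_frozen_cnn",
                     "no_lstm", "no_attention", "no_augmentation")


def config_hash(*configs) -> str:
    """Short stable digest of dataclass configs, for result provenance."""
    blob = repr([dataclasses.asdict(c) if dataclasses.is_dataclass(c) else c
                 for c in configs]).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def replicate_seed(master_seed: int, replicate: int, stream: int = 0) -> int:
    """Deterministic per-replicate seed: one child generator per (replicate, stream)."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(replicate, stream))
    return int(ss.generate_state(1)[0] % (2 ** 31 - 1))


# ------------------------------------------------------------------ replicate
def _train_dalan_arm(dataset, profile: ExperimentProfile, dalan_cfg: DalanConfig,
                     seed: int, roi_encoder=None, augment: bool = True,
                     freeze_fraction: float | None = None):
    model = DalanModel(dalan_cfg, seed=seed, encoder=roi_encoder)
    if freeze_fraction is not None:
        freeze_front(model.encoder, freeze_fraction)
    bag_cfg = replace(profile.bag, seed=seed, augment=profile.augment)
    train_dalan(model, dataset.train_bags, bag_cfg, augment=augment)
    return model


def _clone_trunk(roi_model, enc_cfg: EncoderConfig, seed: int):
    """Fresh encoder carrying a copy of the stage-1 weights.

    Bag-level training updates its encoder in place; cloning keeps the
    ROI-wise model (and hence every naive baseline) untouched.
    """
    enc = build_encoder(enc_cfg, seed=seed)
    enc.load_state_dict(roi_model.encoder.state_dict())
    return enc


def run_replicate(sim_cfg: SimulationConfig, profile: ExperimentProfile,
                  methods, replicate: int, master_seed: int,
                  dalan_cfg: DalanConfig | None = None,
                  variant: str = "full") -> list[dict]:
    """Train and evaluate every requested method on one fresh cohort."""
    seed = replicate_seed(master_seed, replicate)
    dataset = build_simulation(replace(sim_cfg, seed=seed))
    enc_cfg = (dalan_cfg.encoder if dalan_cfg is not None
               else EncoderConfig(in_channels=sim_cfg.image_shape[2],
                                  input_size=sim_cfg.image_shape[:2]))
    if dalan_cfg is None:
        dalan_cfg = DalanConfig(encoder=enc_cfg)
    test_records = [b.record for b in dataset.test_bags]
    chash = config_hash(sim_cfg, profile, dalan_cfg)
    rows = []

    needs_roi = any(m in AGGREGATION_RULES for m in methods) or (
        "dalan" in methods and variant != "no_finetuned_weights")
    roi_model = None
    if needs_roi:
        stage1 = replace(profile.stage1, seed=replicate_seed(master_seed, replicate, 1),
                         augment=profile.augment)
        roi_model = train_roi_cnn(dataset.train_bags, enc_cfg, stage1)

    for method in methods:
        if method in AGGREGATION_RULES:
            ci = evaluate_baseline(roi_model, dataset.test_bags, method)
        elif method == "oracle":
            risks = [oracle_patient_risk(b, dataset.mask) for b in dataset.test_bags]
            ci = concordance_index(risks, test_records, ties="half")
        elif method == "dalan":
            dseed = replicate_seed(master_seed, replicate, 2)
            cfg = dalan_cfg
            augment = True
            freeze = cfg.encoder.frozen_fraction
            encoder = None
            if variant == "full":
                encoder = _clone_trunk(roi_model, enc_cfg, dseed)
            elif variant == "no_finetuned_weights":
                encoder = None                      # fresh weights, no stage 1
            elif variant == "no_frozen_cnn":
                encoder, freeze = _clone_trunk(roi_model, enc_cfg, dseed), 0.0
            elif variant == "no_lstm":
                encoder = _clone_trunk(roi_model, enc_cfg, dseed)
                cfg = replace(cfg, use_lstm=False)
            elif variant == "no_attention":
                encoder = _clone_trunk(roi_model, enc_cfg, dseed)
                cfg = replace(cfg, use_attention=False)
            elif variant == "no_augmentation":
                encoder, augment = _clone_trunk(roi_model, enc_cfg, dseed), False
            else:
                raise ValueError(f"unknown ablation variant {variant!r}")
            model = _train_dalan_arm(dataset, profile, cfg, dseed, roi_encoder=encoder,
                                     augment=augment, freeze_fraction=freeze)
            preds = predict_bags(model, dataset.test_bags,
                                 seed=replicate_seed(master_seed, replicate, 3))
            ci = concordance_index([p.log_hazard for p in preds], test_records,
                                   ties="half")
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append({"method": method if variant == "full" or method != "dalan"
                     else f"dalan:{variant}",
                     "replicate": replicate, "cindex": float(ci), "seed": seed,
                     "config_hash": chash})
    return rows


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Per-method mean +/- SD of the replicate c-indices."""
    g = results.groupby("method")["cindex"]
    return pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1), "n": g.count()})


def run_comparison(sim_cfg: SimulationConfig, methods, n_repeats: int,
                   master_seed: int, profile: ExperimentProfile | str = "desk",
                   dalan_cfg: DalanConfig | None = None,
                   on_error: str = "record") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate loop over methods; returns (per-replicate rows, summary)."""
    if isinstance(profile, str):
        profile = PROFILES[profile]
    rows, failures = [], []
    for rep in range(n_repeats):
        try:
            rows.extend(run_replicate(sim_cfg, profile, methods, rep, master_seed,
                                      dalan_cfg=dalan_cfg))
        except Exception as exc:        # noqa: BLE001 — keep the loop alive
            if on_error == "raise":
                raise
            failures.append({"replicate": rep, "error": repr(exc)})
    results = pd.DataFrame(rows)
    if failures:
        results.attrs["failures"] = failures
    return results, summarize(results) if len(results) else pd.DataFrame()


def run_ablation(sim_cfg: SimulationConfig, variants, n_repeats: int,
                 master_seed: int, profile: ExperimentProfile | str = "desk",
                 dalan_cfg: DalanConfig | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Component-removal study: each variant trains with one config delta."""
    if isinstance(profile, str):
        profile = PROFILES[profile]
    for v in variants:
        if v not in ABLATION_VARIANTS:
            raise ValueError(f"unknown ablation variant {v!r}")
    rows = []
    for rep in range(n_repeats):
        for variant in variants:
            rows.extend(run_replicate(sim_cfg, profile, ["dalan"], rep, master_seed,
                                      dalan_cfg=dalan_cfg, variant=variant))
    results = pd.DataFrame(rows)
    return results, summarize(results)


# ------------------------------------------------------------- group analysis
def risk_group_report(predictions, records, clinical_covariates: pd.DataFrame | None = None):
    """Tertile risk-group analysis: KM per group, log-rank, covariate rank tests.

    ``predictions`` are cohort log-hazards (array or RiskPrediction list);
    ``clinical_covariates`` (optional) holds one categorical column per
    clinical parameter; each is tested for a shift in normalised risk with
    the two-group Wilcoxon rank-sum or the k-group Kruskal–Wallis test.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 patients")
    if isinstance(predictions[0], RiskPrediction):
        raw = np.array([p.log_hazard for p in predictions])
    else:
        raw = np.asarray(predictions, dtype=np.float64)
    norm = normalize_risks(raw)
    labels = stratify_by_risk(raw)
    groups = {name: [r for r, lab in zip(records, labels) if lab == name]
              for name in RISK_GROUPS}
    km = {name: kaplan_meier(g) for name, g in groups.items() if g}
    lr = logrank_test([g for g in groups.values() if g])
    report = {
        "groups": labels,
        "km": km,
        "median_survival": {name: est.median for name, est in km.items()},
        "logrank": lr,
        "covariate_tests": {},
    }
    if clinical_covariates is not None:
        for col in clinical_covariates.columns:
            values = clinical_covariates[col].to_numpy()
            levels = pd.unique(values[pd.notna(values)])
            if len(levels) < 2:
                import warnings
                warnings.warn(f"covariate {col!r} has a single level; skipped",
                              stacklevel=2)
                continue
            samples = [norm[values == lv] for lv in levels]
            if len(levels) == 2:
                stat, p = stats.ranksums(samples[0], samples[1])
                test = "wilcoxon_rank_sum"
            else:
                stat, p = stats.kruskal(*samples)
                test = "kruskal_wallis"
            report["covariate_tests"][col] = {
                "test": test, "statistic": float(stat), "p_value": float(p),
                "level_means": {str(lv): float(s.mean()) for lv, s in zip(levels, samples)},
            }
    return report
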