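"""Naive patient-level aggregation baselines over ROI-wise Cox predictions.

The comparison arms: a single CNN Cox model is trained at ROI level (every
ROI inherits its patient's time and event), each test patient's ROIs are all
scored, and the per-ROI log-hazards are collapsed to one patient value by a
fixed order statistic — average, minimum, maximum, or median.  The encoder
architecture and training budget match the aggregation model's stage 1, so
any performance difference isolates the aggregation step.
"""

from __future__ import annotations

import numpy as np

from .encoder import EncoderConfig, RoiCoxModel, TrainConfig, build_encoder, train_roi_cox_model
from .survival import concordance_index

__all__ = ["AGGREGATION_RULES", "train_roi_cnn", "aggregate_patient_risk",
           "evaluate_baseline", "roi_dataset_from_bags"]

AGGREGATION_RULES = ("average", "min", "max", "median")


def roi_dataset_from_bags(bags) -> list:
    """Flatten patient bags into (image, record) pairs, label inherited per ROI."""
    return [(roi, bag.record) for bag in bags for roi in bag.rois]


def train_roi_cnn(bags, config: EncoderConfig, train_cfg: TrainConfig,
                  encoder=None) -> RoiCoxModel:
    """Train the ROI-wise CNN Cox model used by every naive aggregation arm."""
    enc = encoder if encoder is not None else build_encoder(config, seed=train_cfg.seed)
    model = RoiCoxModel(enc, config, seed=train_cfg.seed)
    train_roi_cox_model(model, roi_dataset_from_bags(bags), train_cfg)
    return model


def aggregate_patient_risk(roi_risks, rule: str) -> float:
    """Collapse ROI-level log-hazards to one patient value by the named rule."""
    risks = np.asarray(roi_risks, dtype=np.float64)
    if risks.size == 0:
        raise ValueError("empty ROI risk list")
    if rule == "average":
        return float(risks.mean())
    if rule == "min":
        return float(risks.min())
    if rule == "max":
        return float(risks.max())
    if rule == "median":
        return float(np.median(risks))
    raise ValueError(f"unknown aggregation rule {rule!r}; expected one of {AGGREGATION_RULES}")


def predict_patient_risks(model: RoiCoxModel, bags, rule: str) -> np.ndarray:
    """Score every ROI in each bag (no sampling) and aggregate per patient."""
    out = []
    for bag in bags:
        roi_risks = model.predict_risks(bag.rois)
        out.append(aggregate_patient_risk(roi_risks, rule))
    return np.asarray(out)


def evaluate_baseline(model: RoiCoxModel, test_bags, rule: str,
                      ties: str = "half") -> float:
    """Patient-level c-index of a naive aggregation arm on held-out bags."""
    risks = predict_patient_risks(model, test_bags, rule)
    return concordance_index(risks, [b.record for b in test_bags], ties=ties)
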