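"""File formats: manifests, dataset export, checkpoints, plots.

* Survival manifests are CSV with header ``patient_id,time,event``;
  ROI-level manifests add ``roi_path`` (and the simulator writes
  ``true_time,replicate,split`` for diagnostics).
* Predictions are CSV ``patient_id,log_hazard,normalized_risk,risk_group``.
* Datasets export as one PNG per ROI plus the manifest.
* Model checkpoints are ``.npz`` weight archives with a JSON config sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .simulator import PatientBag, ROIImage, SimulatedDataset
from .survival import RiskPrediction, SurvivalRecord

__all__ = [
    "read_manifest", "write_predictions", "read_predictions",
    "export_dataset", "load_bags", "save_checkpoint", "load_checkpoint",
    "write_history", "plot_km_groups",
]


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"patient_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks required columns: {sorted(missing)}")
    return df


def write_predictions(predictions: list[RiskPrediction], path) -> None:
    pd.DataFrame([{"patient_id": p.patient_id, "log_hazard": p.log_hazard,
                   "normalized_risk": p.normalized_risk, "risk_group": p.risk_group}
                  for p in predictions]).to_csv(path, index=False)


def read_predictions(path) -> list[RiskPrediction]:
    df = pd.read_csv(path)
    return [RiskPrediction(patient_id=str(r.patient_id), log_hazard=float(r.log_hazard),
                           normalized_risk=None if pd.isna(r.normalized_risk)
                           else float(r.normalized_risk),
                           risk_group=None if pd.isna(r.risk_group) else str(r.risk_group))
            for r in df.itertuples()]


def export_dataset(dataset: SimulatedDataset, out_dir, replicate: int = 0) -> Path:
    """Write PNGs plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for split, bags in (("train", dataset.train_bags), ("test", dataset.test_bags)):
        for bag in bags:
            for k, roi in enumerate(bag.rois):
                rel = f"images/{bag.patient_id}_roi{k}.png"
                arr = np.rint(np.clip(roi.pixels, 0, 1) * 255).astype(np.uint8)
                iio.imwrite(out_dir / rel, arr.squeeze())
                rows.append({"patient_id": bag.patient_id, "roi_path": rel,
                             "time": bag.record.time, "event": bag.record.event,
                             "true_time": bag.true_time, "replicate": replicate,
                             "split": split})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    np.save(out_dir / "weight_mask.npy", dataset.mask.weights)
    return manifest


def load_bags(manifest_path) -> dict[str, list[PatientBag]]:
    """Read an exported dataset back into per-split patient bags."""
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    root = manifest_path.parent
    out: dict[str, list[PatientBag]] = {}
    split_col = df["split"] if "split" in df.columns else pd.Series(["all"] * len(df))
    for (split, pid), grp in df.groupby([split_col, "patient_id"], sort=False):
        rois = []
        for rel in grp["roi_path"]:
            arr = np.asarray(iio.imread(root / rel), dtype=np.float64) / 255.0
            if arr.ndim == 2:
                arr = arr[:, :, None]
            rois.append(ROIImage(pixels=arr))
        rec = SurvivalRecord(time=float(grp["time"].iloc[0]),
                             event=int(grp["event"].iloc[0]))
        true_time = float(grp["true_time"].iloc[0]) if "true_time" in grp else rec.time
        out.setdefault(str(split), []).append(
            PatientBag(patient_id=str(pid), rois=rois, record=rec, true_time=true_time))
    return out


def _config_to_jsonable(cfg):
    if dataclasses.is_dataclass(cfg):
        return {k: _config_to_jsonable(v) for k, v in dataclasses.asdict(cfg).items()}
    if isinstance(cfg, dict):
        return {k: _config_to_jsonable(v) for k, v in cfg.items()}
    if isinstance(cfg, (list, tuple)):
        return [_config_to_jsonable(v) for v in cfg]
    if isinstance(cfg, (np.integer, np.floating)):
        return cfg.item()
    return cfg


def save_checkpoint(model, path, config=None) -> None:
    """Weights to ``<path>.npz``; config sidecar to ``<path>.json``."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    if config is not None:
        path.with_suffix(".json").write_text(
            json.dumps(_config_to_jsonable(config), indent=2))


def load_checkpoint(model, path) -> None:
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as state:
        model.load_state_dict(dict(state))


def write_history(history: list[dict], path) -> None:
    pd.DataFrame(history).to_csv(path, index=False)


def plot_km_groups(km_by_group: dict, path, title: str = "Risk-group survival") -> None:
    """Step-plot Kaplan–Meier curves per risk group to SVG/PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, est in km_by_group.items():
        ax.step(est.times, est.survival, where="post", label=f"{name} (n={est.n})")
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability S(t)")
    ax.set_ylim(0, 1.02)
    ax.legend()
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
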