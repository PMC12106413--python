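"""Model and dataset archives.

Models are stored as a single JSON document (architecture tag, shapes,
weights, pooling/activation settings and optionally the standardization
statistics needed at inference time).  Preprocessed datasets are stored as
NumPy ``.npz`` archives holding the window tensor, targets, split bounds,
standardization statistics and the filled raw target series used by the
mechanistic forecaster.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .attention import AttentionModel, AttentionParams
from .dnn import LayerParams, MLPModel
from .preprocess import DataSplit, StandardizationStats, WindowedDataset

__all__ = ["save_model", "load_model", "save_dataset", "load_dataset"]

PathLike = Union[str, Path]


def save_model(
    model: Union[MLPModel, AttentionModel],
    path: PathLike,
    stats: Optional[StandardizationStats] = None,
    extra: Optional[dict] = None,
) -> None:
    if isinstance(model, MLPModel):
        doc = {
            "architecture": "mlp",
            "layers": [
                {
                    "W": layer.W.tolist(),
                    "b": layer.b.tolist(),
                    "activation": layer.activation,
                }
                for layer in model.layers
            ],
        }
    elif isinstance(model, AttentionModel):
        p = model.params
        doc = {
            "architecture": "attention",
            "h": p.h,
            "d_k": p.d_k,
            "pooling": p.pooling,
            "use_positional": p.use_positional,
            "Wq": p.Wq.tolist(),
            "Wk": p.Wk.tolist(),
            "Wv": p.Wv.tolist(),
            "Wo": p.Wo.tolist(),
            "w_out": p.w_out.tolist(),
            "b_out": p.b_out.tolist(),
        }
    else:
        raise TypeError(f"cannot serialize model of type {type(model).__name__}")
    if stats is not None:
        doc["standardization"] = {"mean": stats.mean, "sd": stats.sd}
    if extra:
        doc["extra"] = extra
    Path(path).write_text(json.dumps(doc))


def load_model(
    path: PathLike,
) -> tuple[Union[MLPModel, AttentionModel], Optional[StandardizationStats]]:
    doc = json.loads(Path(path).read_text())
    arch = doc.get("architecture")
    if arch == "mlp":
        model: Union[MLPModel, AttentionModel] = MLPModel(
            layers=[
                LayerParams(
                    W=np.array(l["W"]), b=np.array(l["b"]), activation=l["activation"]
                )
                for l in doc["layers"]
            ]
        )
    elif arch == "attention":
        model = AttentionModel(
            AttentionParams(
                Wq=np.array(doc["Wq"]),
                Wk=np.array(doc["Wk"]),
                Wv=np.array(doc["Wv"]),
                Wo=np.array(doc["Wo"]),
                w_out=np.array(doc["w_out"]),
                b_out=np.array(doc["b_out"]),
                pooling=doc["pooling"],
                use_positional=doc["use_positional"],
            )
        )
    else:
        raise ValueError(f"unknown architecture tag {arch!r}")
    stats = None
    if "standardization" in doc:
        stats = StandardizationStats(
            mean=doc["standardization"]["mean"], sd=doc["standardization"]["sd"]
        )
    return model, stats


def save_dataset(
    path: PathLike,
    ds: WindowedDataset,
    split: DataSplit,
    stats: StandardizationStats,
    raw_target: np.ndarray,
    dt_hours: float,
) -> None:
    np.savez(
        path,
        X=ds.X,
        y=ds.y,
        feature_names=np.array(ds.feature_names),
        target_col=np.array(ds.target_col),
        T=ds.T,
        stride=ds.stride,
        split_bounds=np.array(
            [split.train.stop, split.validation.stop, split.test.stop]
        ),
        stats_mean=np.array([stats.mean[c] for c in ds.feature_names]),
        stats_sd=np.array([stats.sd[c] for c in ds.feature_names]),
        raw_target=np.asarray(raw_target, dtype=float),
        dt_hours=dt_hours,
    )


def load_dataset(
    path: PathLike,
) -> tuple[WindowedDataset, DataSplit, StandardizationStats, np.ndarray, float]:
    with np.load(path, allow_pickle=False) as z:
        feature_names = [str(c) for c in z["feature_names"]]
        ds = WindowedDataset(
            X=z["X"],
            y=z["y"],
            feature_names=feature_names,
            target_col=str(z["target_col"]),
            T=int(z["T"]),
            stride=int(z["stride"]),
        )
        b = z["split_bounds"]
        split = DataSplit(
            train=slice(0, int(b[0])),
            validation=slice(int(b[0]), int(b[1])),
            test=slice(int(b[1]), int(b[2])),
        )
        stats = StandardizationStats(
            mean={c: float(m) for c, m in zip(feature_names, z["stats_mean"])},
            sd={c: float(s) for c, s in zip(feature_names, z["stats_sd"])},
        )
        raw_target = z["raw_target"]
        dt_hours = float(z["dt_hours"])
    return ds, split, stats, raw_target, dt_hours
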