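"""CSV/JSON plumbing: study readers and fit-document serialization.

Studies travel as plain CSV with a header row (one column is the
response, named by the caller; every other column is a predictor, in file
order).  Fits serialize to JSON documents that round-trip all numeric
fields at full double precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .losses import LossFunction
from .solvers import RidgeFit, StudyData
from .transfer import AdaptiveFit, TransferFit

__all__ = [
    "read_study_csv",
    "write_study_csv",
    "fit_document",
    "write_fit_json",
    "read_fit_json",
]


def read_study_csv(path, response: str = "y") -> StudyData:
    frame = pd.read_csv(path, float_precision="round_trip")
    if response not in frame.columns:
        raise ValueError(f"response column {response!r} not found in {path}")
    y = frame[response].to_numpy(dtype=float)
    X = frame.drop(columns=[response]).to_numpy(dtype=float)
    return StudyData(X, y)


def write_study_csv(path, data: StudyData, response: str = "y") -> None:
    frame = pd.DataFrame(
        data.X, columns=[f"x{j + 1}" for j in range(data.p)]
    )
    frame[response] = data.y
    frame.to_csv(path, index=False, float_format="%.17g")


def fit_document(fit, loss: LossFunction | None = None, **extra) -> dict:
    """JSON-ready document for a ridge, transfer, or adaptive fit."""
    if isinstance(fit, (RidgeFit, TransferFit, AdaptiveFit)):
        doc = {"kind": type(fit).__name__, **fit.to_dict()}
    else:
        raise TypeError(f"unsupported fit type {type(fit).__name__}")
    if loss is not None:
        doc["loss"] = {"name": loss.name, "delta": loss.delta, "eta": loss.eta}
    doc.update(extra)
    return doc


def write_fit_json(path, fit, loss: LossFunction | None = None, **extra) -> None:
    Path(path).write_text(json.dumps(fit_document(fit, loss, **extra), indent=1))


def read_fit_json(path) -> dict:
    doc = json.loads(Path(path).read_text())
    for key in ("coef", "w_hat", "delta_hat", "beta_hat", "beta_ada"):
        if key in doc:
            doc[key] = np.asarray(doc[key], dtype=float)
    return doc
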