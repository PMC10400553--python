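"""Call-level quality control: rule-based pre-filter and linear-SVM classifier.

Screening pipelines first drop calls failing hard evidence minima (alternate
read fraction >= 16%, depth >= 20x, both inclusive), then separate remaining
true calls from sequencing/alignment artifacts with a linear support vector
machine trained on labeled call features.  A sample-level gate removes whole
exomes with insufficient breadth of coverage (< 85% of target at >= 20x).

The SVM operates on a small numeric feature vector per call — depth,
alternate read fraction, and optional quality proxies such as strand
balance and mean base quality.  Features are z-score standardized before
training; the fitted model (weights, bias, standardization constants) is
serializable to JSON and reloads with bit-identical decisions.  Ties on
the decision boundary classify as true calls: at the QC stage a screening
test favors sensitivity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .model import AnnotatedCall, SampleMetrics, Thresholds

PathLike = Union[str, Path]

TRUE_CALL = "TRUE_CALL"
FALSE_CALL = "FALSE_CALL"

#: Exclusion reasons emitted by the rule-based pre-filter.
REASON_ALT_FRACTION = "ALT_FRACTION"
REASON_DEPTH = "DEPTH"
REASON_BLACKLIST = "BLACKLIST"


class SchemaError(ValueError):
    """Feature schema of the scored table does not match the trained model."""


class TrainingError(ValueError):
    """Training set unusable (e.g. a single class)."""


def sample_quality_gate(metrics: SampleMetrics, thr: Thresholds = Thresholds()) -> str:
    """Gate a whole sample on exome coverage breadth.

    Returns ``"PASS"`` unless strictly less than ``exome_cov_fraction_min``
    of the exome reaches ``exome_cov_depth`` (default: < 85% at >= 20x
    fails).  A sample at exactly the threshold passes.
    """
    return "FAIL" if metrics.fraction_exome_at_depth < thr.exome_cov_fraction_min else "PASS"


def preprocess_filter(
    calls: Sequence[AnnotatedCall],
    thr: Thresholds = Thresholds(),
    blacklist: Iterable[str] = (),
) -> tuple[list[AnnotatedCall], list[tuple[AnnotatedCall, str]]]:
    """Rule-based pre-filter; returns ``(retained, excluded_with_reason)``.

    A call is excluded iff its alternate read fraction or depth falls
    strictly below the configured minima (cut-offs themselves are
    retained), or its variant key appears on the optional blacklist of
    known calling artifacts.  Counts are conserved:
    ``len(retained) + len(excluded) == len(calls)``.
    """
    black = set(blacklist)
    retained: list[AnnotatedCall] = []
    excluded: list[tuple[AnnotatedCall, str]] = []
    for call in calls:
        if call.variant_key in black:
            excluded.append((call, REASON_BLACKLIST))
        elif call.alt_fraction < thr.alt_fraction_min:
            excluded.append((call, REASON_ALT_FRACTION))
        elif call.depth < thr.depth_min:
            excluded.append((call, REASON_DEPTH))
        else:
            retained.append(call)
    return retained, excluded


def read_blacklist(path: PathLike) -> list[str]:
    """One variant key per line; blank lines and ``#`` comments ignored."""
    keys = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                keys.append(line)
    return keys


@dataclass
class CallQualityModel:
    """A fitted linear max-margin call classifier.

    ``weights`` and ``bias`` act on z-score standardized features:
    decision value ``w . (x - mean) / scale + b``; calls with decision
    value >= 0 are true calls.
    """

    feature_names: tuple[str, ...]
    weights: np.ndarray
    bias: float
    C: float
    seed: int
    standardize_mean: np.ndarray = field(default_factory=lambda: np.zeros(0))
    standardize_scale: np.ndarray = field(default_factory=lambda: np.ones(0))

    def decision_values(self, X: pd.DataFrame) -> np.ndarray:
        if tuple(X.columns) != self.feature_names:
            raise SchemaError(
                f"expected features {self.feature_names}, got {tuple(X.columns)}"
            )
        Z = (X.to_numpy(dtype=float) - self.standardize_mean) / self.standardize_scale
        return Z @ self.weights + self.bias

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Label per row; boundary ties resolve to TRUE_CALL."""
        d = self.decision_values(X)
        return np.where(d >= 0.0, TRUE_CALL, FALSE_CALL)

    def to_json(self, path: PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "feature_names": list(self.feature_names),
                    "weights": self.weights.tolist(),
                    "bias": self.bias,
                    "C": self.C,
                    "seed": self.seed,
                    "standardize_mean": self.standardize_mean.tolist(),
                    "standardize_scale": self.standardize_scale.tolist(),
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: PathLike) -> "CallQualityModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            feature_names=tuple(d["feature_names"]),
            weights=np.asarray(d["weights"], dtype=float),
            bias=float(d["bias"]),
            C=float(d["C"]),
            seed=int(d["seed"]),
            standardize_mean=np.asarray(d["standardize_mean"], dtype=float),
            standardize_scale=np.asarray(d["standardize_scale"], dtype=float),
        )


def train_call_classifier(
    features: pd.DataFrame,
    labels: Sequence[str],
    C: float = 1.0,
    seed: int = 0,
) -> CallQualityModel:
    """Fit the linear SVM on a labeled feature table.

    Labels must contain both :data:`TRUE_CALL` and :data:`FALSE_CALL`.
    The fit (libsvm linear kernel, hinge loss, L2 penalty of strength
    1/C) is deterministic for a fixed seed and row order.
    """
    labels = np.asarray(labels)
    classes = set(labels.tolist())
    if classes != {TRUE_CALL, FALSE_CALL}:
        raise TrainingError(
            f"training set must contain both classes, got {sorted(classes)}"
        )
    X = features.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise TrainingError("features must be finite")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0.0] = 1.0
    Z = (X - mean) / scale
    y = (labels == TRUE_CALL).astype(int)
    svm = SVC(kernel="linear", C=C, random_state=seed)
    svm.fit(Z, y)
    # libsvm orders classes [0, 1]; positive decision = class 1 = TRUE_CALL
    return CallQualityModel(
        feature_names=tuple(features.columns),
        weights=svm.coef_.ravel().copy(),
        bias=float(svm.intercept_[0]),
        C=C,
        seed=seed,
        standardize_mean=mean,
        standardize_scale=scale,
    )


def score_calls(
    model: CallQualityModel, table: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a call table into (high_confidence, rejected).

    ``table`` must contain the model's feature columns; any extra columns
    (identifiers, truth labels) ride along.  Row counts are conserved.
    """
    X = table[list(model.feature_names)]
    pred = model.predict(X)
    keep = pred == TRUE_CALL
    return table[keep].copy(), table[~keep].copy()


def call_features(calls: Sequence[AnnotatedCall]) -> pd.DataFrame:
    """Minimal per-call feature frame (depth, alt_fraction) from annotations."""
    return pd.DataFrame(
        {
            "depth": [c.depth for c in calls],
            "alt_fraction": [c.alt_fraction for c in calls],
        }
    )
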