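"""Visual-acuity estimation from OCTA biomarkers.

Feature vectors combine the SCP FAZ area with the five zonal vessel
densities of each scan; an epsilon-SVR (after z-score standardization fit
on the training data only) regresses decimal VA, evaluated with seeded
k-fold cross-validation.  Two feature sets are supported: ``scp_only``
(11 features) and ``scp_dcp`` (21 features, adding the deep plexus).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .errors import (
    InsufficientDataError,
    UndefinedCorrelationError,
    ValidationError,
)
from .image_io import DCP, SCP

ZONES = ("foveal", "upper", "nasal", "temporal", "lower")

SCP_ONLY = "scp_only"
SCP_DCP = "scp_dcp"
EXPERIMENTS = (SCP_ONLY, SCP_DCP)


def _vd_names(plexus: str, extent: int) -> list:
    return [f"vd_{plexus.lower()}{extent}_{z}" for z in ZONES]


#: stable feature order per experiment
FEATURE_NAMES = {
    SCP_ONLY: ["faz_area_scp3_mm2"] + _vd_names(SCP, 3) + _vd_names(SCP, 6),
    SCP_DCP: (
        ["faz_area_scp3_mm2"]
        + _vd_names(SCP, 3)
        + _vd_names(SCP, 6)
        + _vd_names(DCP, 3)
        + _vd_names(DCP, 6)
    ),
}


@dataclass(frozen=True)
class VisitRecord:
    """Per-visit biomarkers paired with the real decimal VA."""

    visit_id: str
    faz_area_scp3_mm2: float
    vd: Mapping  # (plexus, extent int, zone) -> density in [0, 1]
    real_va_decimal: float = float("nan")
    laterality: str = "OD"
    extras: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.faz_area_scp3_mm2 < 0:
            raise ValidationError(
                f"visit {self.visit_id!r}: negative FAZ area {self.faz_area_scp3_mm2}"
            )
        for key, v in self.vd.items():
            if not 0.0 <= v <= 1.0:
                raise ValidationError(
                    f"visit {self.visit_id!r}: density {key} = {v} outside [0, 1]"
                )
        if not math.isnan(self.real_va_decimal) and not 0.0 <= self.real_va_decimal <= 1.0:
            raise ValidationError(
                f"visit {self.visit_id!r}: real VA {self.real_va_decimal} outside [0, 1]"
            )

    def get_vd(self, plexus: str, extent: int, zone: str) -> float:
        return self.vd[(plexus, extent, zone)]


def assemble_features(record: VisitRecord, experiment: str) -> np.ndarray:
    """Order the record's biomarkers into the experiment's feature vector."""
    if experiment not in EXPERIMENTS:
        raise ValidationError(f"experiment must be one of {EXPERIMENTS}")
    plexuses = (SCP,) if experiment == SCP_ONLY else (SCP, DCP)
    values = [record.faz_area_scp3_mm2]
    for plexus in plexuses:
        for extent in (3, 6):
            for zone in ZONES:
                key = (plexus, extent, zone)
                if key not in record.vd:
                    raise ValidationError(
                        f"visit {record.visit_id!r}: missing density {key} "
                        f"for experiment {experiment}"
                    )
                values.append(record.vd[key])
    out = np.asarray(values, dtype=np.float64)
    if not np.isfinite(out).all():
        raise ValidationError(f"visit {record.visit_id!r}: non-finite biomarker value")
    return out


@dataclass(frozen=True)
class SVRConfig:
    kernel: str = "linear"
    C: float = 1.0
    epsilon: float = 0.05  # half a decimal-VA line


DEFAULT_SVR_CONFIG = SVRConfig()


class VAModel:
    """Standardization + epsilon-SVR; predictions clipped to decimal [0, 1]."""

    def __init__(self, pipeline: Pipeline):
        self._pipeline = pipeline

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.clip(self._pipeline.predict(np.asarray(X, dtype=np.float64)), 0.0, 1.0)


def fit_svr(
    X: Sequence, y: Sequence, config: SVRConfig = DEFAULT_SVR_CONFIG
) -> VAModel:
    """Fit the VA regressor on assembled feature vectors."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.shape[0] != y.shape[0]:
        raise ValidationError("X and y must have the same number of samples")
    if X.shape[0] < 10:
        raise InsufficientDataError(f"need >= 10 samples, got {X.shape[0]}")
    if ((y < 0) | (y > 1)).any():
        raise ValidationError("decimal VA targets must lie in [0, 1]")
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svr", SVR(kernel=config.kernel, C=config.C, epsilon=config.epsilon)),
        ]
    )
    pipe.fit(X, y)
    return VAModel(pipe)


def mse(est: Sequence, real: Sequence) -> float:
    """Mean squared error on the decimal VA scale."""
    est = np.asarray(est, dtype=np.float64)
    real = np.asarray(real, dtype=np.float64)
    if est.shape != real.shape or est.size == 0:
        raise ValidationError("estimate and reference must be equal-length, non-empty")
    return float(np.mean((est - real) ** 2))


def pearson_r(a: Sequence, b: Sequence) -> tuple:
    """Product-moment correlation with the two-sided t-transform p-value."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.size < 3:
        raise ValidationError("need two equal-length vectors of length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def decimal_to_logmar(va: float) -> float:
    """logMAR = -log10(decimal VA); defined for va > 0."""
    if not va > 0:
        raise ValidationError(f"decimal VA must be > 0 for logMAR, got {va}")
    return -math.log10(va)


@dataclass(frozen=True)
class CVResult:
    """Pooled out-of-fold predictions and the derived metrics."""

    fold_of_record: np.ndarray  # fold index per record, in input order
    predictions: np.ndarray  # out-of-fold prediction per record, in input order
    real: np.ndarray
    pearson_r: float
    p_value: float
    mse_decimal: float
    fold_mse: tuple
    train_mse: float  # all-data refit, evaluated on the training data itself
    train_predictions: np.ndarray


def _make_folds(n: int, k: int, seed: int, groups: Sequence | None) -> np.ndarray:
    """Seeded shuffle into k near-equal folds; optional group-keeping variant."""
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    if groups is None:
        order = rng.permutation(n)
        for fold, idx in enumerate(np.array_split(order, k)):
            fold_of[idx] = fold
    else:
        groups = np.asarray(groups)
        unique = list(dict.fromkeys(groups.tolist()))  # first-appearance order
        perm = rng.permutation(len(unique))
        # greedy balance: next group joins the currently smallest fold
        sizes = [0] * k
        for gi in perm:
            members = np.nonzero(groups == unique[gi])[0]
            fold = int(np.argmin(sizes))
            fold_of[members] = fold
            sizes[fold] += len(members)
    return fold_of


def cross_validate(
    records: Sequence[VisitRecord],
    experiment: str,
    k: int = 5,
    seed: int = 0,
    config: SVRConfig = DEFAULT_SVR_CONFIG,
    group_by_patient: Sequence | None = None,
) -> CVResult:
    """Seeded k-fold cross-validation of the VA estimator.

    Standardization is fit on the training folds only.  The pooled
    out-of-fold predictions give the test-phase metrics; an all-data refit
    gives ``train_mse`` for the whole-sample analysis.
    ``group_by_patient`` optionally supplies one label per record so all
    visits of a patient share a fold.
    """
    n = len(records)
    if n < k * 3:
        raise InsufficientDataError(f"need >= {k * 3} records for {k}-fold CV, got {n}")
    X = np.stack([assemble_features(r, experiment) for r in records])
    y = np.array([r.real_va_decimal for r in records], dtype=np.float64)
    if not np.isfinite(y).all():
        raise ValidationError("every record needs a real decimal VA for CV")

    fold_of = _make_folds(n, k, seed, group_by_patient)
    pred = np.empty(n, dtype=np.float64)
    fold_mse = []
    for fold in range(k):
        test = fold_of == fold
        model = fit_svr(X[~test], y[~test], config)
        pred[test] = model.predict(X[test])
        fold_mse.append(mse(pred[test], y[test]))
    r, p = pearson_r(pred, y)
    full_model = fit_svr(X, y, config)
    train_pred = full_model.predict(X)
    return CVResult(
        fold_of_record=fold_of,
        predictions=pred,
        real=y,
        pearson_r=r,
        p_value=p,
        mse_decimal=mse(pred, y),
        fold_mse=tuple(fold_mse),
        train_mse=mse(train_pred, y),
        train_predictions=train_pred,
    )
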