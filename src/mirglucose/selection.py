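"""Validation designs, preprocessing x LV grid search, and the metric suite.

Three validation designs are implemented:

* ``RandomSubsetCV`` — repeated k-fold: per iteration the samples are
  shuffled with an iteration-derived seed and partitioned into near-equal
  folds; each fold is held out once, held-out predictions are pooled into a
  per-iteration MAPE, and the mean over iterations is reported (the pooled
  MAPE over all iterations is also carried along for reference).
* ``LOOCV`` — n deterministic single-sample folds.
* ``GroupedHoldout`` — a single fit on all samples of the training
  individuals, evaluated on samples of disjoint validation individuals.

Every fold refits the preprocessing centering statistics and the PLS model
on the in-fold training rows only; the row-wise operators are
training-independent, so they are computed once per candidate and shared
across folds without any leakage.

The primary accuracy metric is MAPE (also known as MARD in glucose
monitoring): ``100/n * sum |y_t - yhat_t| / y_t``.  RMSE, the bias-corrected
standard error of prediction (SEP) and R^2 are reported for completeness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import pls
from .preprocess import PreprocessSpec, fit_apply, row_transform
from .spectra import SpectraSet

__all__ = [
    "mape",
    "rmse",
    "sep",
    "r2",
    "RandomSubsetCV",
    "LOOCV",
    "GroupedHoldout",
    "EvaluationReport",
    "CVResult",
    "GridSearchResult",
    "random_subset_cv",
    "loocv",
    "grouped_holdout",
    "grid_search",
]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def _check_pair(y_true, y_pred) -> Tuple[np.ndarray, np.ndarray]:
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape or yt.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D and the same length")
    return yt, yp


def mape(y_true, y_pred) -> float:
    """Mean absolute percentage error, in percent.

    Scale-invariant; undefined (and rejected) when any reference value is
    nonpositive.
    """
    yt, yp = _check_pair(y_true, y_pred)
    if np.any(yt <= 0):
        raise ValueError("MAPE needs strictly positive reference values")
    return float(100.0 * np.mean(np.abs(yt - yp) / yt))


def rmse(y_true, y_pred) -> float:
    """Root-mean-square error, in the units of y (mg/dL here)."""
    yt, yp = _check_pair(y_true, y_pred)
    return float(np.sqrt(np.mean((yt - yp) ** 2)))


def sep(y_true, y_pred) -> float:
    """Standard error of prediction: bias-corrected residual SD,
    sqrt(sum((e - mean(e))^2) / (n - 1))."""
    yt, yp = _check_pair(y_true, y_pred)
    if yt.size < 2:
        raise ValueError("SEP needs at least 2 samples")
    e = yt - yp
    return float(np.sqrt(np.sum((e - e.mean()) ** 2) / (e.size - 1)))


def r2(y_true, y_pred) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    yt, yp = _check_pair(y_true, y_pred)
    ss_tot = float(np.sum((yt - yt.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 is undefined for constant reference values")
    return float(1.0 - np.sum((yt - yp) ** 2) / ss_tot)


# ---------------------------------------------------------------------------
# Validation schemes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RandomSubsetCV:
    """Repeated random-subset k-fold CV (defaults: 10 splits, 20 iterations)."""

    splits: int = 10
    iterations: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.splits < 2:
            raise ValueError("splits must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")

    def describe(self) -> dict:
        return {
            "kind": "random_subset",
            "splits": self.splits,
            "iterations": self.iterations,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class LOOCV:
    """Leave-one-out cross-validation (deterministic)."""

    def describe(self) -> dict:
        return {"kind": "loocv"}


@dataclass(frozen=True)
class GroupedHoldout:
    """Single split by individual: disjoint train / validation groups."""

    train_groups: Tuple[str, ...]
    val_groups: Tuple[str, ...]

    def __post_init__(self):
        tg, vg = set(self.train_groups), set(self.val_groups)
        if not tg or not vg:
            raise ValueError("train and validation groups must be non-empty")
        if tg & vg:
            raise ValueError(
                f"individuals shared across the split: {sorted(tg & vg)}"
            )

    def describe(self) -> dict:
        return {
            "kind": "grouped_holdout",
            "train_groups": list(self.train_groups),
            "val_groups": list(self.val_groups),
        }


CVScheme = Union[RandomSubsetCV, LOOCV, GroupedHoldout]


def _near_equal_folds(perm: np.ndarray, splits: int) -> List[np.ndarray]:
    """Partition a permutation into near-equal folds; remainder samples go to
    the first folds."""
    n = perm.size
    base, extra = divmod(n, splits)
    sizes = [base + (1 if i < extra else 0) for i in range(splits)]
    if base < 1:
        raise ValueError(f"cannot split {n} samples into {splits} folds")
    folds, start = [], 0
    for s in sizes:
        folds.append(perm[start : start + s])
        start += s
    return folds


def make_folds(scheme: CVScheme, n: int) -> List[List[np.ndarray]]:
    """Held-out index folds per iteration for a CV scheme (grouped holdout is
    not fold-based and handled separately)."""
    if isinstance(scheme, LOOCV):
        if n < 3:
            raise ValueError("LOOCV needs at least 3 samples")
        return [[np.array([i]) for i in range(n)]]
    if isinstance(scheme, RandomSubsetCV):
        if scheme.splits > n:
            raise ValueError("more folds than samples")
        iterations = []
        for it in range(scheme.iterations):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(scheme.seed), it])
            )
            iterations.append(_near_equal_folds(rng.permutation(n), scheme.splits))
        return iterations
    raise TypeError(f"no fold generation for scheme {type(scheme).__name__}")


def _fold_predict(
    T: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    lv_list: Sequence[int],
) -> Dict[int, np.ndarray]:
    """Refit centering + PLS on the training rows of a pre-transformed
    matrix and predict the held-out rows for every LV count at once.

    PLS1 components are nested, so a single NIPALS run at max(lv_list)
    serves every smaller LV count.
    """
    mu = T[train_idx].mean(axis=0)
    ym = float(y[train_idx].mean())
    model = pls.fit(T[train_idx] - mu, y[train_idx] - ym, max(lv_list))
    Xv = T[test_idx] - mu
    out = {}
    for k in lv_list:
        kk = min(k, model.n_components)
        out[k] = Xv @ pls.regression_vector(model, kk) + ym
    return out


def _cv_mape_table(
    sset: SpectraSet,
    spec: PreprocessSpec,
    lv_list: Sequence[int],
    folds_per_iteration: List[List[np.ndarray]],
) -> Dict[int, dict]:
    """CV MAPE per LV count over shared fold partitions.

    Returns per LV: mean of per-iteration pooled MAPEs (primary), the pooled
    MAPE over all held-out predictions, and the pooled predictions of the
    first iteration (used by LOOCV reports).
    """
    T = row_transform(spec, sset.matrix, sset.grid.spacing)
    y = sset.glucose
    if np.any(~np.isfinite(y)):
        raise ValueError("cross-validation needs reference glucose for all samples")
    n = sset.n_samples
    all_idx = np.arange(n)
    per_iter: Dict[int, List[float]] = {k: [] for k in lv_list}
    pooled_t: Dict[int, List[np.ndarray]] = {k: [] for k in lv_list}
    pooled_p: Dict[int, List[np.ndarray]] = {k: [] for k in lv_list}
    first_iter_pred: Dict[int, np.ndarray] = {}
    for it, folds in enumerate(folds_per_iteration):
        preds = {k: np.empty(n) for k in lv_list}
        held = np.zeros(n, dtype=int)
        for test_idx in folds:
            train_idx = np.setdiff1d(all_idx, test_idx, assume_unique=False)
            fold_pred = _fold_predict(T, y, train_idx, test_idx, lv_list)
            for k in lv_list:
                preds[k][test_idx] = fold_pred[k]
            held[test_idx] += 1
        if not np.all(held == 1):
            raise AssertionError("folds do not partition the sample set")
        for k in lv_list:
            per_iter[k].append(mape(y, preds[k]))
            pooled_t[k].append(y)
            pooled_p[k].append(preds[k])
            if it == 0:
                first_iter_pred[k] = preds[k]
    out = {}
    for k in lv_list:
        out[k] = {
            "cv_mape": float(np.mean(per_iter[k])),
            "cv_mape_pooled": mape(
                np.concatenate(pooled_t[k]), np.concatenate(pooled_p[k])
            ),
            "per_iteration": per_iter[k],
            "first_iteration_pred": first_iter_pred[k],
        }
    return out


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvaluationReport:
    """Per-sample predictions plus the metric suite for one evaluation."""

    sample_ids: np.ndarray
    groups: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    mape: float
    rmse: float
    sep: float
    r2: float
    spec: PreprocessSpec
    n_lv: int
    scheme: dict

    @classmethod
    def from_predictions(
        cls, sset: SpectraSet, index, y_pred, spec, n_lv, scheme
    ) -> "EvaluationReport":
        idx = np.asarray(index)
        yt = sset.glucose[idx]
        yp = np.asarray(y_pred, dtype=float)
        return cls(
            sample_ids=sset.sample_ids[idx],
            groups=sset.groups[idx],
            y_true=yt,
            y_pred=yp,
            mape=mape(yt, yp),
            rmse=rmse(yt, yp),
            sep=sep(yt, yp),
            r2=r2(yt, yp),
            spec=spec,
            n_lv=int(n_lv),
            scheme=dict(scheme),
        )

    def metrics(self) -> dict:
        return {
            "mape_percent": self.mape,
            "rmse_mgdl": self.rmse,
            "sep_mgdl": self.sep,
            "r2": self.r2,
        }

    def to_json_dict(self) -> dict:
        return {
            "metrics": self.metrics(),
            "model": {"preprocess": self.spec.to_dict(), "n_lv": self.n_lv},
            "scheme": self.scheme,
            "n_predictions": int(self.y_true.size),
        }

    def predictions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "individual_id": self.groups,
                "y_true_mgdl": self.y_true,
                "y_pred_mgdl": self.y_pred,
            }
        )


@dataclass(frozen=True)
class CVResult:
    """Random-subset CV summary for one (preprocessing, n_lv) candidate."""

    cv_mape: float  # mean of per-iteration pooled MAPEs (primary)
    cv_mape_pooled: float  # MAPE pooled over all iterations (reference)
    per_iteration: Tuple[float, ...]


def random_subset_cv(
    sset: SpectraSet,
    spec: PreprocessSpec,
    n_lv: int,
    scheme: RandomSubsetCV,
) -> CVResult:
    """Repeated random-subset CV MAPE of one candidate."""
    folds = make_folds(scheme, sset.n_samples)
    table = _cv_mape_table(sset, spec, [n_lv], folds)[n_lv]
    return CVResult(
        cv_mape=table["cv_mape"],
        cv_mape_pooled=table["cv_mape_pooled"],
        per_iteration=tuple(table["per_iteration"]),
    )


def loocv(sset: SpectraSet, spec: PreprocessSpec, n_lv: int) -> EvaluationReport:
    """Leave-one-out CV: n fits, each predicting one held-out sample."""
    folds = make_folds(LOOCV(), sset.n_samples)
    table = _cv_mape_table(sset, spec, [n_lv], folds)[n_lv]
    return EvaluationReport.from_predictions(
        sset,
        np.arange(sset.n_samples),
        table["first_iteration_pred"],
        spec,
        n_lv,
        LOOCV().describe(),
    )


def grouped_holdout(
    sset: SpectraSet,
    spec: PreprocessSpec,
    n_lv: int,
    train_groups: Iterable[str],
    val_groups: Iterable[str],
) -> EvaluationReport:
    """Fit once on the training individuals, evaluate on the validation
    individuals; the split never shares an individual."""
    scheme = GroupedHoldout(tuple(train_groups), tuple(val_groups))
    groups = sset.groups
    train_mask = np.isin(groups, list(scheme.train_groups))
    val_mask = np.isin(groups, list(scheme.val_groups))
    if not train_mask.any() or not val_mask.any():
        raise ValueError("a split side has no samples")
    cal = pls.calibrate(sset.subset(train_mask), spec, n_lv)
    preds = pls.predict_set(cal, sset.subset(val_mask))
    return EvaluationReport.from_predictions(
        sset, np.where(val_mask)[0], preds, spec, n_lv, scheme.describe()
    )


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSearchResult:
    """Every (preprocessing, n_lv) candidate's CV MAPE plus the winner."""

    table: pd.DataFrame
    best_spec: PreprocessSpec
    best_n_lv: int
    best_mape: float
    scheme: dict

    def to_json_dict(self) -> dict:
        return {
            "best": {
                "preprocess": self.best_spec.to_dict(),
                "n_lv": self.best_n_lv,
                "cv_mape_percent": self.best_mape,
            },
            "scheme": self.scheme,
            "n_candidates": int(len(self.table)),
        }


def grid_search(
    train: SpectraSet,
    specs: Sequence[PreprocessSpec],
    lv_range: Sequence[int] = range(3, 13),
    scheme: CVScheme = None,
) -> GridSearchResult:
    """Exhaustive CV over every preprocessing pipeline and LV count.

    All candidates are scored on identical fold partitions (one shared seed),
    and ties are broken by fewer LVs, then fewer active preprocessing steps,
    then enumeration order.
    """
    if len(specs) == 0:
        raise ValueError("empty preprocessing grid")
    lv_list = sorted(set(int(k) for k in lv_range))
    if not lv_list or lv_list[0] < 1:
        raise ValueError("lv_range must contain positive LV counts")
    scheme = RandomSubsetCV() if scheme is None else scheme
    folds = make_folds(scheme, train.n_samples)
    rows = []
    for si, spec in enumerate(specs):
        per_lv = _cv_mape_table(train, spec, lv_list, folds)
        for k in lv_list:
            rows.append(
                {
                    "spec_index": si,
                    "pipeline": spec.label,
                    "n_lv": k,
                    "cv_mape": per_lv[k]["cv_mape"],
                    "cv_mape_pooled": per_lv[k]["cv_mape_pooled"],
                    "n_active_steps": spec.n_active_steps,
                }
            )
    table = pd.DataFrame(rows)
    order = table.sort_values(
        ["cv_mape", "n_lv", "n_active_steps", "spec_index"],
        kind="mergesort",
    )
    best = order.iloc[0]
    return GridSearchResult(
        table=table,
        best_spec=specs[int(best["spec_index"])],
        best_n_lv=int(best["n_lv"]),
        best_mape=float(best["cv_mape"]),
        scheme=scheme.describe(),
    )
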