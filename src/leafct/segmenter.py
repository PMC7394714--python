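"""Per-scan random-forest pixel classifier: training and full-stack prediction.

The classifier is an sklearn-style estimator (`LeafSegmenter`) so it composes
with sklearn model selection; `train`/`predict_stack` are the pipeline-level
wrappers that carry tissue-class and feature-column metadata.  A fresh forest
is always fitted per scan — models do not transfer between scans.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .featgen import FeatureConfig, FeatureTable, build_features
from .stack_io import ClassMap, LabelStack

logger = logging.getLogger(__name__)


class LeafSegmenter(ClassifierMixin, BaseEstimator):
    """Random-forest pixel classifier over engineered feature layers.

    Parameters
    ----------
    n_estimators : int, default=50
        Trees in the ensemble.
    oob_score : bool, default=False
        Estimate generalization accuracy from out-of-bag samples.
    warm_start : bool, default=False
        Reuse the previous fit and add estimators on subsequent calls.
    class_weight : None or "balanced", default=None
        Optional reweighting for class imbalance; off by default so the raw
        sensitivity pattern (rare tissues are harder) is reproduced.
    random_state : int or None
        Seed for bootstrap sampling and per-node feature subsampling.

    Attributes
    ----------
    forest_ : fitted RandomForestClassifier
    classes_ : sorted class codes seen at fit time
    feature_names_in_ : column names when fitted from a FeatureTable
    oob_score_ : out-of-bag accuracy (only when ``oob_score=True``)
    """

    def __init__(
        self,
        n_estimators: int = 50,
        oob_score: bool = False,
        warm_start: bool = False,
        class_weight=None,
        random_state=None,
        n_jobs: int = 1,
    ):
        self.n_estimators = n_estimators
        self.oob_score = oob_score
        self.warm_start = warm_start
        self.class_weight = class_weight
        self.random_state = random_state
        self.n_jobs = n_jobs

    @staticmethod
    def _unpack(X):
        if isinstance(X, FeatureTable):
            return X.values, X.columns
        return np.asarray(X), None

    def fit(self, X, y=None):
        """Fit the forest on a FeatureTable (with targets) or an (X, y) pair."""
        X, columns = self._unpack(X)
        if y is None:
            raise ValueError("fit requires targets: pass y or a FeatureTable with .target")
        y = np.asarray(y)
        if X.shape[0] == 0:
            raise ValueError("empty training table")
        if np.unique(y).size < 2:
            raise ValueError(
                "single-class training table; pass allow_degenerate=True via train() to override"
            )
        warm_continue = self.warm_start and hasattr(self, "forest_")
        if not warm_continue:
            self.forest_ = RandomForestClassifier(
                n_estimators=self.n_estimators,
                oob_score=self.oob_score,
                warm_start=self.warm_start,
                class_weight=self.class_weight,
                random_state=self.random_state,
                n_jobs=self.n_jobs,
            )
        else:
            self.forest_.set_params(n_estimators=self.n_estimators)
        self.forest_.fit(X, y)
        self.classes_ = self.forest_.classes_
        if columns is not None:
            self.feature_names_in_ = np.asarray(columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        if self.oob_score:
            self.oob_score_ = float(self.forest_.oob_score_)
        return self

    def _check_columns(self, columns) -> None:
        if columns is not None and hasattr(self, "feature_names_in_"):
            if list(columns) != list(self.feature_names_in_):
                raise ValueError(
                    "feature columns differ from training columns:\n"
                    f"  got      {list(columns)}\n  expected {list(self.feature_names_in_)}"
                )

    def predict(self, X):
        check_is_fitted(self, "forest_")
        X, columns = self._unpack(X)
        self._check_columns(columns)
        # argmax over averaged votes; sklearn breaks ties toward the first
        # entry of classes_, i.e. the lowest class code — deterministic.
        return self.forest_.predict(X)

    def predict_proba(self, X):
        check_is_fitted(self, "forest_")
        X, columns = self._unpack(X)
        self._check_columns(columns)
        return self.forest_.predict_proba(X)


@dataclass
class SegmenterModel:
    """A fitted LeafSegmenter plus everything needed to reproduce it."""

    classifier: LeafSegmenter
    feature_columns: list[str]
    class_map: ClassMap
    feature_config: FeatureConfig
    metadata: dict = field(default_factory=dict)


def select_training_slices(labeled_indices, n: int, seed: int) -> list[int]:
    """Draw n distinct labeled-slice indices uniformly without replacement."""
    labeled_indices = list(labeled_indices)
    if not 1 <= n <= len(labeled_indices):
        raise ValueError(f"n must be within [1, {len(labeled_indices)}], got {n}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(labeled_indices), size=n, replace=False)
    return sorted(int(labeled_indices[i]) for i in chosen)


def train(
    table: FeatureTable,
    class_map: ClassMap,
    feature_config: FeatureConfig,
    n_estimators: int = 50,
    use_oob: bool = False,
    warm_start: bool = False,
    seed: int | None = 0,
    slice_indices=None,
    allow_degenerate: bool = False,
    class_weight=None,
) -> SegmenterModel:
    """Fit a fresh forest on a training FeatureTable and record metadata."""
    if table.target is None:
        raise ValueError("training table carries no targets")
    clf = LeafSegmenter(
        n_estimators=n_estimators,
        oob_score=use_oob,
        warm_start=warm_start,
        class_weight=class_weight,
        random_state=seed,
    )
    if allow_degenerate and np.unique(table.target).size < 2:
        logger.warning("fitting on a degenerate single-class table")
        clf.forest_ = RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed, n_jobs=1
        ).fit(table.values, table.target)
        clf.classes_ = clf.forest_.classes_
        clf.feature_names_in_ = np.asarray(table.columns, dtype=object)
        clf.n_features_in_ = table.values.shape[1]
    else:
        clf.fit(table, table.target)
    meta = {
        "n_estimators": int(n_estimators),
        "use_oob": bool(use_oob),
        "warm_start": bool(warm_start),
        "seed": seed,
        "slice_indices": list(map(int, slice_indices)) if slice_indices is not None else None,
        "n_training_rows": int(table.n_rows),
        "max_features": clf.forest_.max_features,  # library default, recorded
    }
    if use_oob:
        meta["oob_score"] = clf.oob_score_
    return SegmenterModel(clf, list(table.columns), class_map, feature_config, meta)


def add_estimators(model: SegmenterModel, table: FeatureTable, n_more: int) -> SegmenterModel:
    """Grow a warm-started model by ``n_more`` trees on the same table."""
    clf = model.classifier
    if not clf.warm_start:
        raise ValueError("model was not trained with warm_start")
    clf.n_estimators = len(clf.forest_.estimators_) + int(n_more)
    clf.fit(table, table.target)
    model.metadata["n_estimators"] = clf.n_estimators
    return model


def predict_slices(model: SegmenterModel, gridrec, phase, lt_map, slice_indices) -> np.ndarray:
    """Predict class codes for the given slices; shape (len(indices), y, x)."""
    cfg = model.feature_config
    out = np.empty((len(slice_indices),) + gridrec.shape[1:], dtype=np.int64)
    for i, z in enumerate(slice_indices):
        lt_slice = lt_map.voxels[z] if cfg.include_local_thickness else None
        tab = build_features(gridrec.voxels[z], phase.voxels[z], lt_slice, cfg)
        if tab.columns != model.feature_columns:
            raise ValueError("feature-column mismatch between model and prediction input")
        out[i] = model.classifier.predict(tab.values).reshape(gridrec.shape[1:])
    return out


def predict_stack(model: SegmenterModel, gridrec, phase, lt_map) -> LabelStack:
    """Predict every slice of the scan, streaming slice by slice.

    Peak memory is one slice of feature layers; every voxel receives a class
    code from the training classes (the unlabeled sentinel can never appear).
    """
    if gridrec.shape != phase.shape:
        raise ValueError("gridrec/phase shape mismatch")
    nz = gridrec.shape[0]
    vox = np.empty(gridrec.shape, dtype=np.uint8)
    for z in range(nz):
        vox[z] = predict_slices(model, gridrec, phase, lt_map, [z])[0]
        if z % 50 == 0:
            logger.info("predicted slice %d/%d", z, nz)
    return LabelStack(vox, model.class_map, gridrec.spacing)


def save_model(model: SegmenterModel, path: str | Path) -> None:
    """Persist the fitted model with a plain-text metadata sidecar."""
    path = Path(path)
    joblib.dump(model, path)
    sidecar = {
        "feature_columns": model.feature_columns,
        "class_map": dict(model.class_map.codes),
        **model.metadata,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> SegmenterModel:
    return joblib.load(Path(path))
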