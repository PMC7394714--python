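"""Cross-validation of the segmenter: precision/recall vs training-slice count.

Reproduces the standard testing design for per-scan trainable segmentation:
for each number of training slices n, repeatedly (i) draw n hand-labeled
slices at random, (ii) fit a fresh forest, (iii) predict the *held-out*
hand-labeled slices, and (iv) tabulate per-class precision and recall from
the confusion matrix.  Raw predictions are evaluated — no anatomy-aware
corrections are applied here.  A separate routine pushes full-stack
predictions through correction + trait analysis to study trait stability
versus n.

Per-class rows are emitted both for the split adaxial/abaxial epidermis codes
and for a merged "epidermis" class, and likewise for vein/bundle sheath and
their merged "vein_bundle_sheath" class, since the merged views are the ones
usually reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .featgen import FeatureConfig, assemble_training_table
from .segmenter import predict_slices, predict_stack, select_training_slices, train
from .stack_io import ClassMap, LabelStack
from .postprocess import apply_corrections
from .traits import compile_report

logger = logging.getLogger(__name__)

MERGED_GROUPS = {
    "epidermis": ("epidermis_adaxial", "epidermis_abaxial"),
    "vein_bundle_sheath": ("vein", "bundle_sheath"),
}


@dataclass
class ConfusionMatrix:
    """K x K pixel counts; rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError("confusion matrix shape inconsistent with class names")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())


def confusion(
    true: np.ndarray, pred: np.ndarray, class_map: ClassMap, exclude_sentinel: bool = True
) -> ConfusionMatrix:
    """Confusion matrix over labeled pixels (sentinel-coded pixels excluded)."""
    true = np.asarray(true)
    pred = np.asarray(pred)
    if true.shape != pred.shape:
        raise ValueError(f"geometry mismatch: true {true.shape} vs pred {pred.shape}")
    t, p = true.ravel(), pred.ravel()
    if exclude_sentinel:
        keep = t != class_map.sentinel
        t, p = t[keep], p[keep]
    names = class_map.names
    codes = np.array([class_map.code(n) for n in names])
    k = len(codes)
    code_to_idx = np.full(int(max(codes.max(), class_map.sentinel)) + 1, -1)
    code_to_idx[codes] = np.arange(k)
    ti, pi = code_to_idx[t], code_to_idx[p]
    valid = (ti >= 0) & (pi >= 0)
    counts = np.bincount(ti[valid] * k + pi[valid], minlength=k * k).reshape(k, k)
    return ConfusionMatrix(counts, names)


def precision_recall(matrix: ConfusionMatrix) -> pd.DataFrame:
    """Per-class recall (sensitivity) and precision (positive predictive value).

    ``recall_k = M[k,k] / sum_j M[k,j]``; ``precision_k = M[k,k] / sum_i M[i,k]``.
    Zero denominators yield NaN (undefined), never zero.
    """
    m = matrix.counts.astype(np.float64)
    diag = np.diag(m)
    row_sums, col_sums = m.sum(axis=1), m.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(row_sums > 0, diag / row_sums, np.nan)
        precision = np.where(col_sums > 0, diag / col_sums, np.nan)
    return pd.DataFrame(
        {
            "class_name": matrix.class_names,
            "recall": recall,
            "precision": precision,
            "n_true": row_sums.astype(np.int64),
            "n_pred": col_sums.astype(np.int64),
        }
    )


def merge_codes(arr: np.ndarray, class_map: ClassMap, group: tuple[str, ...]) -> np.ndarray:
    """Remap every code of ``group`` onto the group's first code."""
    target = class_map.code(group[0])
    out = arr.copy()
    for name in group[1:]:
        out[out == class_map.code(name)] = target
    return out


def _spawn_seed(base_seed: int, n: int, rep: int) -> int:
    """Deterministic per-(n, rep) child seed; any cell re-runnable alone."""
    ss = np.random.SeedSequence(entropy=int(base_seed), spawn_key=(int(n), int(rep)))
    return int(ss.generate_state(1)[0] % (2**31))


def _pr_records(true_slices, pred_slices, class_map) -> list[dict]:
    """Precision/recall rows for split classes plus each merged group."""
    rows = []
    pr = precision_recall(confusion(true_slices, pred_slices, class_map))
    for rec in pr.to_dict("records"):
        rec["merged"] = False
        rows.append(rec)
    for merged_name, group in MERGED_GROUPS.items():
        t = merge_codes(true_slices, class_map, group)
        p = merge_codes(pred_slices, class_map, group)
        pr = precision_recall(confusion(t, p, class_map))
        rec = pr[pr.class_name == group[0]].iloc[0].to_dict()
        rec["class_name"] = merged_name
        rec["merged"] = True
        rows.append(rec)
    return rows


def cross_validate(
    gridrec,
    phase,
    lt_map,
    labels: LabelStack,
    cfg: FeatureConfig,
    n_range=range(1, 13),
    reps: int = 30,
    base_seed: int = 0,
    n_estimators: int = 50,
) -> pd.DataFrame:
    """Precision/recall experiment over (n_train, repetition) cells.

    Returns a tidy table with one row per (n_train, rep, class); held-out
    hand-labeled slices form the test set of every cell.  Raw predictions
    only — no post-prediction correction.
    """
    labeled = list(labels.labeled_slice_indices or range(labels.shape[0]))
    n_range = list(n_range)
    if max(n_range) >= len(labeled):
        raise ValueError(
            f"n_range max {max(n_range)} leaves no held-out slices out of {len(labeled)}"
        )
    rows = []
    for n, rep in product(n_range, range(reps)):
        seed = _spawn_seed(base_seed, n, rep)
        train_idx = select_training_slices(labeled, n, seed)
        test_idx = [z for z in labeled if z not in train_idx]
        table = assemble_training_table(gridrec, phase, lt_map, labels, train_idx, cfg)
        model = train(
            table, labels.class_map, cfg, n_estimators=n_estimators, seed=seed,
            slice_indices=train_idx, allow_degenerate=True,
        )
        pred = predict_slices(model, gridrec, phase, lt_map, test_idx)
        true = labels.voxels[test_idx]
        for rec in _pr_records(true, pred, labels.class_map):
            rec.update(n_train=n, rep=rep, seed=seed, n_test_slices=len(test_idx))
            rows.append(rec)
        logger.info("cross_validate: n=%d rep=%d done", n, rep)
    return pd.DataFrame(rows)


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Median and quartiles of precision/recall per (n_train, class)."""
    def q(s, p):
        return s.dropna().quantile(p) if s.notna().any() else np.nan

    g = records.groupby(["n_train", "class_name"], sort=True)
    out = g.apply(
        lambda d: pd.Series(
            {
                "recall_median": q(d.recall, 0.5),
                "recall_q25": q(d.recall, 0.25),
                "recall_q75": q(d.recall, 0.75),
                "precision_median": q(d.precision, 0.5),
                "precision_q25": q(d.precision, 0.25),
                "precision_q75": q(d.precision, 0.75),
                "n_reps": len(d),
            }
        ),
        include_groups=False,
    )
    return out.reset_index()


def trait_stability(
    gridrec,
    phase,
    lt_map,
    labels: LabelStack,
    cfg: FeatureConfig,
    n_values=(1, 2, 3, 4, 5),
    reps_per_n: int = 5,
    base_seed: int = 0,
    n_estimators: int = 50,
    similarity_ratio: float = 5.0,
    min_voxels: int = 27,
) -> pd.DataFrame:
    """Full-stack prediction + correction + trait report per (n, rep).

    Unlike :func:`cross_validate` this applies the post-prediction
    corrections, since traits require a corrected stack.  Stacks whose
    epidermes cannot be told apart keep NaN side-specific thicknesses and
    carry the flag in the ``flags`` column.
    """
    labeled = list(labels.labeled_slice_indices or range(labels.shape[0]))
    rows = []
    for n, rep in product(n_values, range(reps_per_n)):
        seed = _spawn_seed(base_seed, n, rep)
        train_idx = select_training_slices(labeled, n, seed)
        table = assemble_training_table(gridrec, phase, lt_map, labels, train_idx, cfg)
        model = train(
            table, labels.class_map, cfg, n_estimators=n_estimators, seed=seed,
            slice_indices=train_idx, allow_degenerate=True,
        )
        pred = predict_stack(model, gridrec, phase, lt_map)
        corrected = apply_corrections(pred, similarity_ratio, min_voxels)
        report = compile_report(corrected)
        row = report.to_frame().iloc[0].to_dict()
        row.update(n_train=n, rep=rep, seed=seed)
        rows.append(row)
        logger.info("trait_stability: n=%d rep=%d done (flags=%s)", n, rep, report.flags)
    return pd.DataFrame(rows)


def plot_precision_recall(records: pd.DataFrame, path) -> None:
    """Median curves with 25th-75th quantile bands, one panel per metric."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = summarize(records)
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, metric in zip(axes, ("recall", "precision")):
        for name, d in summary.groupby("class_name"):
            ax.plot(d.n_train, d[f"{metric}_median"], marker="o", label=name)
            ax.fill_between(d.n_train, d[f"{metric}_q25"], d[f"{metric}_q75"], alpha=0.2)
        ax.set_xlabel("training slices")
        ax.set_title(metric)
    axes[0].set_ylabel("score")
    axes[1].legend(fontsize=7, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
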