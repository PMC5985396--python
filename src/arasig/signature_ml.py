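"""TSS epigenetic feature encoding, random-forest discrimination and the
label-shuffle Gini-importance null.

The classifier is a Gini-criterion random forest grown with warm start across
a tree-count grid, scored out-of-bag and by stratified 5-fold cross
validation. Feature significance is assessed per feature against the 95th
percentile of importances obtained by retraining on shuffled labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .genome_intervals import (
    NeighborPair,
    ReadTrack,
    TranscriptModel,
    count_in_window,
    tss_window,
)

__all__ = [
    "FeatureMatrix",
    "ModelReport",
    "ImportanceReport",
    "encode_features",
    "train_classifier",
    "importance_null",
    "significant_features",
]

LABELS = ("ARA", "NonA")


@dataclass
class FeatureMatrix:
    """Rows: labeled lincRNAs with a neighbor; columns: per-mark normalized
    TSS-window read counts at the lincRNA ("<mark>@linc") and at the neighbor
    ("<mark>@pc")."""

    row_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    labels: list[str]
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.feature_names)):
            raise ValueError("feature matrix shape mismatch")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels {bad}")

    @property
    def y(self) -> np.ndarray:
        return np.asarray([1 if l == "ARA" else 0 for l in self.labels])

    def subset(self, ids: Sequence[str]) -> "FeatureMatrix":
        wanted = set(ids)
        keep = [i for i, r in enumerate(self.row_ids) if r in wanted]
        return FeatureMatrix(
            row_ids=[self.row_ids[i] for i in keep],
            feature_names=list(self.feature_names),
            values=self.values[keep],
            labels=[self.labels[i] for i in keep],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.row_ids, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        df.index.name = "lincrna_id"
        return df


@dataclass
class ModelReport:
    tree_grid: list[int]
    chosen_trees: int
    cv_accuracy: float
    cv_accuracy_by_size: dict[int, float]
    oob_score_by_size: dict[int, float]
    oob_score: float
    importances: np.ndarray = field(repr=False)
    feature_names: list[str] = field(default_factory=list)


@dataclass
class ImportanceReport:
    table: pd.DataFrame  # feature, gini, null_cutoff, significant, direction, rank

    def significant(self) -> list[str]:
        t = self.table
        return list(t.index[t["significant"]])


def encode_features(
    pairs: Sequence[NeighborPair],
    tracks: Sequence[ReadTrack],
    labels: Mapping[str, str],
    models: Mapping[str, TranscriptModel],
    flank: int = 500,
) -> FeatureMatrix:
    """Build the per-lincRNA feature matrix from TSS-window read counts.

    ``labels`` maps lincRNA gene ids to ARA/NonA; lincRNAs without a pair are
    omitted (counted in ``n_skipped``). ``models`` must resolve both the
    lincRNA and neighbor gene ids of every retained pair.
    """
    if not tracks:
        raise ValueError("no tracks supplied")
    pair_of = {p.lincrna_id: p for p in pairs}
    feature_names = [f"{t.mark}@linc" for t in tracks] + [f"{t.mark}@pc" for t in tracks]
    rows, row_ids, row_labels = [], [], []
    n_skipped = 0
    for linc_id in labels:
        pair = pair_of.get(linc_id)
        if pair is None:
            n_skipped += 1
            continue
        linc_win = tss_window(models[linc_id], flank)
        pc_win = tss_window(models[pair.pc_id], flank)
        rows.append(
            [count_in_window(t, linc_win) for t in tracks]
            + [count_in_window(t, pc_win) for t in tracks]
        )
        row_ids.append(linc_id)
        row_labels.append(labels[linc_id])
    if n_skipped:
        warnings.warn(f"{n_skipped} labeled lincRNAs had no neighbor pair; rows omitted")
    return FeatureMatrix(
        row_ids=row_ids,
        feature_names=feature_names,
        values=np.asarray(rows, dtype=float) if rows else np.empty((0, len(feature_names))),
        labels=row_labels,
        n_skipped=n_skipped,
    )


def _forest(trees: int, seed: int, oob: bool = False) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=trees,
        criterion="gini",
        warm_start=True,
        oob_score=oob,
        random_state=seed,
        n_jobs=1,
    )


def train_classifier(
    fm: FeatureMatrix,
    tree_grid: Sequence[int] = (100, 500, 1000, 10000),
    folds: int = 5,
    seed: int = 0,
) -> ModelReport:
    """Grow a warm-started forest across the tree grid, pick the grid size
    with the best stratified CV accuracy, and report the importances of that
    model refit on all rows."""
    X, y = fm.values, fm.y
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both labels must be present to train")
    if counts.min() < folds:
        raise ValueError(f"need >= {folds} rows per label, got {counts.min()}")
    grid = sorted(int(t) for t in tree_grid)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    cv_acc = {n: [] for n in grid}
    for k, (tr, te) in enumerate(skf.split(X, y)):
        rf = _forest(grid[0], seed + k)
        for n in grid:
            rf.n_estimators = n
            rf.fit(X[tr], y[tr])
            cv_acc[n].append(float(rf.score(X[te], y[te])))
    cv_mean = {n: float(np.mean(v)) for n, v in cv_acc.items()}

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # OOB warning on tiny forests
        full = _forest(grid[0], seed, oob=True)
        oob_by_size = {}
        for n in grid:
            full.n_estimators = n
            full.fit(X, y)
            oob_by_size[n] = float(full.oob_score_)

    chosen = max(grid, key=lambda n: (cv_mean[n], -n))
    final = RandomForestClassifier(
        n_estimators=chosen, criterion="gini", random_state=seed, n_jobs=1
    ).fit(X, y)

    return ModelReport(
        tree_grid=grid,
        chosen_trees=chosen,
        cv_accuracy=cv_mean[chosen],
        cv_accuracy_by_size=cv_mean,
        oob_score_by_size=oob_by_size,
        oob_score=oob_by_size[chosen],
        importances=final.feature_importances_,
        feature_names=list(fm.feature_names),
    )


def importance_null(
    fm: FeatureMatrix,
    n_shuffles: int = 1000,
    trees: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Gini importances from forests retrained on label-shuffled data.

    Returns an (n_shuffles, n_features) matrix; each forest is trained fresh
    at the chosen tree count.
    """
    if n_shuffles < 100:
        warnings.warn("fewer than 100 shuffles makes the null cutoff unstable")
    X, y = fm.values, fm.y
    rng = np.random.default_rng(seed)
    out = np.empty((n_shuffles, X.shape[1]))
    for i in range(n_shuffles):
        y_perm = rng.permutation(y)
        rf = RandomForestClassifier(
            n_estimators=trees,
            criterion="gini",
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        ).fit(X, y_perm)
        out[i] = rf.feature_importances_
    return out


def significant_features(
    report: ModelReport,
    null: np.ndarray,
    fm: FeatureMatrix,
    ci: float = 95.0,
) -> ImportanceReport:
    """Per-feature significance against the ci-th percentile of its shuffled
    null, with enrichment direction from the ARA-minus-NonA mean difference."""
    null = np.asarray(null)
    if null.shape[1] != len(report.feature_names):
        raise ValueError("null matrix does not cover every feature")
    cutoffs = np.percentile(null, ci, axis=0)
    gini = report.importances
    y = fm.y
    mean_diff = fm.values[y == 1].mean(axis=0) - fm.values[y == 0].mean(axis=0)
    table = pd.DataFrame(
        {
            "gini": gini,
            "null_cutoff": cutoffs,
            "significant": gini > cutoffs,
            "direction": np.where(mean_diff >= 0, "up", "down"),
        },
        index=pd.Index(report.feature_names, name="feature"),
    )
    table["rank"] = table["gini"].rank(ascending=False, method="first").astype(int)
    return ImportanceReport(table=table.sort_values("rank"))
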