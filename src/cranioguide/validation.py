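"""Cross-validation and error statistics for the landmark pipeline.

Summaries follow the median/IQR convention (landmark errors are heavy-
tailed; means would be dominated by the occasional bad head).  Every
report keeps its raw per-item errors so any summary can be recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .errors import InvalidInputError
from .mapping import (REGRESSED_TARGETS, FacialLandmarks, LinearHeadMap,
                      SubsetSpec, fit_linear_headmap, predict_cranial,
                      training_rows_from_records)
from .registration import fit_registration, transform_layout
from .synthetic import render_views
from .tentwenty import TenTwentyLayout
from .tracking import AtlasBundle, Stabilizer


@dataclass
class ErrorReport:
    """Raw per-item Euclidean errors plus grouping keys.

    ``table`` has an ``error`` column and arbitrary grouping columns
    (landmark, label, view, subject, fold, region, ...).
    """

    table: pd.DataFrame

    def __post_init__(self):
        if "error" not in self.table.columns:
            raise InvalidInputError("an ErrorReport table needs an 'error' column")
        if (self.table["error"] < 0).any():
            raise InvalidInputError("errors must be non-negative")

    def median(self, by=None):
        if by is None:
            return float(self.table["error"].median())
        return self.table.groupby(by, observed=True)["error"].median()

    def iqr(self, by=None):
        def _iqr(x):
            q1, q3 = np.percentile(x, [25, 75])
            return q3 - q1
        if by is None:
            return float(_iqr(self.table["error"]))
        return self.table.groupby(by, observed=True)["error"].apply(_iqr)

    def summary(self, by) -> pd.DataFrame:
        g = self.table.groupby(by, observed=True)["error"]
        return pd.DataFrame({"median": g.median(),
                             "iqr": g.apply(lambda x: np.subtract(*np.percentile(x, [75, 25]))),
                             "n": g.size()})


def kfold_split(subject_ids, k: int = 5, seed: int = 0):
    """Disjoint test folds over *subjects* (never over views).

    Returns ``k`` pairs ``(train_ids, test_ids)``; each subject is tested
    exactly once.
    """
    ids = list(subject_ids)
    if k > len(ids):
        raise InvalidInputError(f"k={k} exceeds the {len(ids)} available subjects")
    if k < 2:
        raise InvalidInputError("k must be >= 2")
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    out = []
    for train_idx, test_idx in splitter.split(ids):
        out.append(([ids[i] for i in train_idx], [ids[i] for i in test_idx]))
    return out


def evaluate_cranial(hmap: LinearHeadMap, records, fold: int | None = None) -> ErrorReport:
    """Per-landmark prediction errors of one fitted map on test records."""
    rows = []
    for rec in records:
        if "targets" not in rec:
            raise InvalidInputError("test record is missing ground-truth targets")
        f = FacialLandmarks(np.asarray(rec["facial"], dtype=float),
                            convention=rec.get("convention", hmap.subset.convention))
        pred = predict_cranial(hmap, f)
        pred_pts = {"Iz": pred.iz, "LPA": pred.lpa, "RPA": pred.rpa, "Cz": pred.cz}
        for c in REGRESSED_TARGETS:
            err = float(np.linalg.norm(pred_pts[c] - np.asarray(rec["targets"][c])))
            rows.append({"subject": rec.get("subject"), "view": rec.get("view"),
                         "landmark": c, "fold": fold, "error": err})
    return ErrorReport(pd.DataFrame(rows))


def cross_validate_cranial(records, subset: SubsetSpec, k: int = 5, seed: int = 0,
                           ridge: float = 0.0) -> ErrorReport:
    """Subject-wise k-fold CV of the linear head map, errors pooled over folds."""
    records = list(records)
    subjects = sorted({rec["subject"] for rec in records})
    tables = []
    for fold, (train_ids, test_ids) in enumerate(kfold_split(subjects, k=k, seed=seed)):
        train = [r for r in records if r["subject"] in set(train_ids)]
        test = [r for r in records if r["subject"] in set(test_ids)]
        hmap = fit_linear_headmap(training_rows_from_records(train, subset),
                                  subset, ridge=ridge)
        tables.append(evaluate_cranial(hmap, test, fold=fold).table)
    return ErrorReport(pd.concat(tables, ignore_index=True))


def evaluate_layout(predicted: TenTwentyLayout, truth: TenTwentyLayout) -> ErrorReport:
    """Per-label errors between two layouts, tagged by head region.

    The label intersection is used; an empty intersection raises.  Labels
    on the coronal medial line carry the ``both`` tag and are counted in
    both the anterior and the posterior summaries.
    """
    shared = [l for l in predicted.entries if l in truth.entries]
    if not shared:
        raise InvalidInputError("predicted and truth layouts share no labels")
    rows = []
    for label in shared:
        err = float(np.linalg.norm(predicted.entries[label] - truth.entries[label]))
        region = truth.region.get(label) or predicted.region.get(label) or "unknown"
        rows.append({"label": label, "region": region, "error": err})
    return ErrorReport(pd.DataFrame(rows))


def region_medians(report: ErrorReport) -> dict[str, float]:
    """Overall/anterior/posterior medians; ``both`` labels count in both."""
    t = report.table
    out = {"overall": float(t["error"].median())}
    for region in ("anterior", "posterior"):
        sel = t[t["region"].isin([region, "both"])]
        out[region] = float(sel["error"].median()) if len(sel) else float("nan")
    return out


def noise_uncertainty_experiment(hmap: LinearHeadMap, atlas: AtlasBundle,
                                 subject, view, jitter_sigma: float,
                                 n_repeats: int = 100,
                                 windows=(1, 3, 5, 8, 10), seed: int = 0,
                                 density: str = "10-20",
                                 mode: str = "three-point") -> pd.DataFrame:
    """Landmark-jitter analogue of an image-noise stability experiment.

    A single subject/view is rendered once; ``n_repeats`` facial frames
    with i.i.d. Gaussian jitter form a stream, and for each moving-average
    window the per-label standard deviation of the predicted 10-20
    positions is computed over the steady-state frames (the first
    ``w − 1`` warm-up frames are dropped).  Returns a tidy frame with
    columns window/label/std.
    """
    if n_repeats < 2:
        raise InvalidInputError("n_repeats must be >= 2")
    base = render_views(subject, [view], jitter_sigma=0.0)[0]
    rng = np.random.default_rng(seed)
    frames = [FacialLandmarks(
        base.facial.points + rng.normal(0.0, jitter_sigma, size=base.facial.points.shape),
        convention=base.facial.convention, frame="normalized-camera")
        for _ in range(n_repeats)]
    base_layout = atlas.layout(density)
    rows = []
    for w in windows:
        stab = Stabilizer(int(w))
        positions = []
        for frame in frames:
            smoothed = stab.update(frame)
            predicted = predict_cranial(hmap, smoothed)
            T = fit_registration(predicted, atlas.cranial, mode=mode)
            layout = transform_layout(base_layout, T)
            positions.append(layout.as_array(base_layout.labels))
        steady = np.stack(positions[int(w) - 1:])
        stds = np.sqrt(steady.var(axis=0, ddof=1).sum(axis=1))
        for label, std in zip(base_layout.labels, stds):
            rows.append({"window": int(w), "label": label, "std": float(std)})
    return pd.DataFrame(rows)
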