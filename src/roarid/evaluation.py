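"""Grouped leave-one-out fold designs, accuracy, and Equal Error Rate.

Four fold schemes are supported, mirroring the study's cross-validation
designs: ``day`` (hold out one (individual, day) recording group — 20
folds for the 5-individuals x 4-day-groups shape), ``bout`` (hold out one
roar bout of 1-3 samples, ~74 folds at field scale), and their one-vs-many
counterparts ``eer_day`` / ``eer_bout``, where one individual is the
target ("class 1"), everyone else is "class 2", and each fold tests one
genuine and one impostor sample.

A "day" here is an (individual_id, day_id) pair, not a calendar date
shared across individuals: each animal's logger ran on its own 4-10 day
window, and only the per-individual reading yields the 20 groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .classify import (BackboneSpec, ImageClassifier, ScoreMatrix, TrainConfig,
                       build_classifier, fold_seed)
from .errors import AlignmentError, DegenerateFoldError
from .synthetic_roars import RoarDataset

logger = logging.getLogger(__name__)

__all__ = [
    "FoldPlan",
    "EvalResult",
    "EERResult",
    "make_day_folds",
    "make_bout_folds",
    "make_sample_folds",
    "make_eer_folds",
    "relabel_one_vs_many",
    "accuracy",
    "accuracy_fraction",
    "compute_eer",
    "eer_from_binary_scores",
    "cross_validate",
    "evaluate_eer",
]

GENUINE, IMPOSTOR = "1", "2"  # one-vs-many binary labels


@dataclass
class FoldPlan:
    """Ordered train/test partitions for one scheme."""

    scheme: str
    folds: list[tuple[list[str], list[str]]]
    target_individual: str | None = None

    def validate_disjoint(self) -> None:
        for train, test in self.folds:
            if set(train) & set(test):
                raise ValueError("train and test overlap within a fold")


@dataclass
class EvalResult:
    scheme: str
    per_fold: list[tuple[int, int, int]]  # (fold index, n_test, n_correct)
    overall_accuracy: float


@dataclass
class EERResult:
    target_individual: str
    eer_percent: float
    threshold_at_eer: float
    n_genuine: int
    n_impostor: int


# ---------------------------------------------------------------------------
# fold construction
# ---------------------------------------------------------------------------

def _leave_one_group_out(dataset: RoarDataset, groups: dict, scheme: str,
                         group_kind: str) -> FoldPlan:
    if len(groups) < 2:
        raise ValueError(f"need at least 2 {group_kind} groups")
    owner = {s.sample_id: s.individual_id for s in dataset.samples}
    all_ids = dataset.sample_ids()
    # every class must survive removal of any single group
    groups_per_class: dict[str, set] = {}
    for key, ids in groups.items():
        for sid in ids:
            groups_per_class.setdefault(owner[sid], set()).add(key)
    for cls, keys in groups_per_class.items():
        if len(keys) < 2:
            raise DegenerateFoldError(
                f"class {cls!r} occurs in a single {group_kind} group; "
                "removing it would leave the class untrainable"
            )
    folds = []
    for key in sorted(groups, key=str):
        test = list(groups[key])
        test_set = set(test)
        folds.append(([sid for sid in all_ids if sid not in test_set], test))
    return FoldPlan(scheme, folds)


def make_day_folds(dataset: RoarDataset) -> FoldPlan:
    """One fold per (individual_id, day_id) recording group."""
    return _leave_one_group_out(dataset, dataset.day_groups(), "day", "day")


def make_bout_folds(dataset: RoarDataset) -> FoldPlan:
    """One fold per bout; test sets have 1-3 samples."""
    return _leave_one_group_out(dataset, dataset.bout_groups(), "bout", "bout")


def make_sample_folds(dataset: RoarDataset) -> FoldPlan:
    """Naive per-sample LOOCV (no grouping).

    Not one of the study's designs — it exists to demonstrate the
    intra-bout leakage that the grouped designs prevent.
    """
    all_ids = dataset.sample_ids()
    folds = [([x for x in all_ids if x != sid], [sid]) for sid in all_ids]
    return FoldPlan("sample", folds)


def relabel_one_vs_many(dataset: RoarDataset, target: str) -> dict[str, str]:
    """Map sample_id -> "1" (target's roars) or "2" (all other individuals).

    Grouping metadata lives on the dataset and is untouched; applying the
    relabelling twice is idempotent by construction.
    """
    if target not in dataset.class_labels:
        raise ValueError(f"unknown target individual {target!r}")
    return {s.sample_id: (GENUINE if s.individual_id == target else IMPOSTOR)
            for s in dataset.samples}


def make_eer_folds(dataset: RoarDataset, target: str,
                   base_scheme: str = "day") -> FoldPlan:
    """One-vs-many folds: each fold tests one genuine and one impostor sample.

    One fold per base-scheme group: the held-out group supplies the test
    sample for the binary class it contains; the other class's test
    sample rotates round-robin over that class's groups, and its whole
    group is excluded from training so no group ever spans train and
    test.  A fold whose held-out group contains neither class is skipped
    with a log entry.
    """
    if base_scheme == "day":
        groups = dataset.day_groups()
    elif base_scheme == "bout":
        groups = dataset.bout_groups()
    else:
        raise ValueError("base_scheme must be 'day' or 'bout'")
    binary = relabel_one_vs_many(dataset, target)
    all_ids = dataset.sample_ids()
    keys = sorted(groups, key=str)
    by_class = {
        GENUINE: [k for k in keys if binary[groups[k][0]] == GENUINE],
        IMPOSTOR: [k for k in keys if binary[groups[k][0]] == IMPOSTOR],
    }
    folds = []
    rotation = {GENUINE: 0, IMPOSTOR: 0}
    for key in keys:
        ids = groups[key]
        cls = binary[ids[0]]
        other = IMPOSTOR if cls == GENUINE else GENUINE
        if not by_class[other]:
            logger.info("eer fold %s skipped: no %s-class group available",
                        key, other)
            continue
        other_key = by_class[other][rotation[other] % len(by_class[other])]
        rotation[other] += 1
        test = [ids[0], groups[other_key][0]]
        excluded = set(ids) | set(groups[other_key])
        train = [sid for sid in all_ids if sid not in excluded]
        folds.append((train, test))
    return FoldPlan(f"eer_{base_scheme}", folds, target_individual=target)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def accuracy_fraction(scores: ScoreMatrix, true_labels) -> float:
    """Fraction of rows whose argmax class matches the true label."""
    true_labels = list(true_labels)
    if len(true_labels) != len(scores.sample_ids):
        raise AlignmentError("true_labels length does not match score rows")
    preds = scores.predictions()
    return float(np.mean([p == t for p, t in zip(preds, true_labels)]))


def accuracy(scores: ScoreMatrix, true_labels) -> tuple[int, int, float]:
    """(n_correct, n_test, accuracy) with argmax prediction; ties break
    toward the lowest class index."""
    frac = accuracy_fraction(scores, true_labels)
    n = len(scores.sample_ids)
    return int(round(frac * n)), n, frac


def compute_eer(genuine_scores, impostor_scores) -> EERResult:
    """Equal Error Rate of target-posterior scores, in percent.

    FAR(t) = fraction of impostor scores >= t; FRR(t) = fraction of
    genuine scores < t.  Thresholds sweep the midpoints of adjacent
    sorted distinct scores plus -inf/+inf sentinels; when no threshold
    gives exact FAR = FRR the crossing is linearly interpolated between
    the bracketing thresholds.
    """
    genuine = np.asarray(list(genuine_scores), dtype=float)
    impostor = np.asarray(list(impostor_scores), dtype=float)
    if genuine.size == 0 or impostor.size == 0:
        raise ValueError("need at least one genuine and one impostor score")
    distinct = np.unique(np.concatenate([genuine, impostor]))
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[distinct[0] - 1.0], mids, [distinct[-1] + 1.0]])
    imp_sorted = np.sort(impostor)
    gen_sorted = np.sort(genuine)
    far = (impostor.size - np.searchsorted(imp_sorted, thresholds, "left")) / impostor.size
    frr = np.searchsorted(gen_sorted, thresholds, "left") / genuine.size
    diff = far - frr  # monotone nonincreasing in t; starts >= 0, ends <= 0
    exact = np.nonzero(diff == 0)[0]
    if exact.size:
        i = int(exact[0])
        eer, thr = far[i], thresholds[i]
    else:
        i = int(np.nonzero(diff < 0)[0][0])
        a = diff[i - 1] / (diff[i - 1] - diff[i])
        eer = far[i - 1] + a * (far[i] - far[i - 1])
        thr = thresholds[i - 1] + a * (thresholds[i] - thresholds[i - 1])
    return EERResult("", float(100.0 * eer), float(thr),
                     int(genuine.size), int(impostor.size))


def eer_from_binary_scores(scores: ScoreMatrix, target_label: str) -> EERResult:
    """EER of a binary ScoreMatrix using the target-class posterior column."""
    if scores.true_labels is None:
        raise ValueError("EER needs true_labels")
    col = scores.class_labels.index(target_label)
    vals = scores.values[:, col]
    genuine = [v for v, t in zip(vals, scores.true_labels) if t == target_label]
    impostor = [v for v, t in zip(vals, scores.true_labels) if t != target_label]
    res = compute_eer(genuine, impostor)
    res.target_individual = target_label
    return res


# ---------------------------------------------------------------------------
# cross-validated pipeline runs
# ---------------------------------------------------------------------------

def cross_validate(images: dict[str, np.ndarray], labels: dict[str, str],
                   plan: FoldPlan, spec: BackboneSpec, cfg: TrainConfig,
                   ) -> tuple[EvalResult, ScoreMatrix]:
    """Train per fold, score the fold's test set, and pool results.

    ``images`` maps sample_id to a network-ready (H, W, 3) array.  The
    backbone's features are extracted once for all samples and reused
    across folds (the fixed backbone never trains); each fold fits a
    fresh head seeded by ``fold_seed(cfg.seed, fold_index)``, so no state
    leaks between folds.
    """
    class_labels = sorted(set(labels.values()))
    clf = build_classifier(spec, len(class_labels))
    order = list(images)
    feats = clf.feature_map(np.stack([images[sid] for sid in order]))
    feat_of = {sid: feats[i] for i, sid in enumerate(order)}

    per_fold = []
    pooled_ids: list[str] = []
    pooled_rows: list[np.ndarray] = []
    pooled_true: list[str] = []
    for f, (train_ids, test_ids) in enumerate(plan.folds):
        fold_clf = build_classifier(spec, len(class_labels))
        fold_cfg = TrainConfig(cfg.epochs, cfg.batch_size, cfg.learning_rate,
                               cfg.optimizer, cfg.momentum, fold_seed(cfg.seed, f))
        fold_clf.fit_head(np.stack([feat_of[s] for s in train_ids]),
                          [labels[s] for s in train_ids], fold_cfg)
        probs = fold_clf.head.predict_proba(
            np.stack([feat_of[s] for s in test_ids]))
        sm = ScoreMatrix(probs, test_ids, fold_clf.class_labels)
        n_correct, n_test, _ = accuracy(sm, [labels[s] for s in test_ids])
        per_fold.append((f, n_test, n_correct))
        pooled_ids.extend(test_ids)
        pooled_rows.append(probs)
        pooled_true.extend(labels[s] for s in test_ids)

    overall = sum(c for _, _, c in per_fold) / sum(n for _, n, _ in per_fold)
    pooled = ScoreMatrix(np.vstack(pooled_rows), pooled_ids,
                         sorted(set(labels.values())), pooled_true)
    return EvalResult(plan.scheme, per_fold, float(overall)), pooled


def evaluate_eer(dataset: RoarDataset, images: dict[str, np.ndarray],
                 spec: BackboneSpec, cfg: TrainConfig,
                 base_scheme: str = "day", targets=None,
                 ) -> tuple[list[EERResult], float]:
    """One-vs-many EER per target individual, pooled across folds.

    For each target, genuine/impostor posteriors are pooled over all that
    target's folds and a single EER computed; the mean over targets is
    returned alongside the per-target results.
    """
    targets = list(targets) if targets is not None else list(dataset.class_labels)
    clf = build_classifier(spec, 2)
    order = list(images)
    feats = clf.feature_map(np.stack([images[sid] for sid in order]))
    feat_of = {sid: feats[i] for i, sid in enumerate(order)}

    results = []
    for target in targets:
        plan = make_eer_folds(dataset, target, base_scheme)
        binary = relabel_one_vs_many(dataset, target)
        genuine, impostor = [], []
        for f, (train_ids, test_ids) in enumerate(plan.folds):
            fold_clf = build_classifier(spec, 2)
            fold_cfg = TrainConfig(cfg.epochs, cfg.batch_size, cfg.learning_rate,
                                   cfg.optimizer, cfg.momentum,
                                   fold_seed(cfg.seed, f))
            fold_clf.fit_head(np.stack([feat_of[s] for s in train_ids]),
                              [binary[s] for s in train_ids], fold_cfg)
            probs = fold_clf.head.predict_proba(
                np.stack([feat_of[s] for s in test_ids]))
            col = fold_clf.class_labels.index(GENUINE)
            for sid, row in zip(test_ids, probs):
                (genuine if binary[sid] == GENUINE else impostor).append(row[col])
        res = compute_eer(genuine, impostor)
        res.target_individual = target
        results.append(res)
    mean_eer = float(np.mean([r.eer_percent for r in results]))
    return results, mean_eer
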