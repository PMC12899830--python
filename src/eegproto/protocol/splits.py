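"""Session-level and subject-grouped dataset partitioning."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..records import ConfigurationError, SessionRecord


@dataclass(frozen=True)
class SplitPlan:
    train: frozenset[str]
    val: frozenset[str]
    test: frozenset[str]

    def subset_of(self, session_id: str) -> str:
        if session_id in self.train:
            return "train"
        if session_id in self.val:
            return "val"
        if session_id in self.test:
            return "test"
        raise KeyError(session_id)


@dataclass
class Fold:
    test_subjects: frozenset[str]
    train_subjects: frozenset[str]


@dataclass
class FoldPlan:
    folds: list[Fold]
    val_fraction: float = 0.1


def osw_split(
    sessions: list[SessionRecord],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitPlan:
    """Label-stratified train/val/test split over session ids.

    The test set takes ceil(n * r_test) sessions and the validation set
    round(n * r_val); for 54 balanced sessions at 80/10/10 this yields the
    43/5/6 partition. Deterministic for a given seed.
    """
    if len(sessions) < 10:
        raise ConfigurationError("need at least 10 sessions for an 80/10/10 split")
    if not math.isclose(sum(ratios), 1.0, abs_tol=1e-9):
        raise ConfigurationError("ratios must sum to 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    by_label: dict[int, list[str]] = {0: [], 1: []}
    for rec in sessions:
        by_label[rec.label].append(rec.session_id)
    for ids in by_label.values():
        perm = rng.permutation(len(ids))
        ids[:] = [ids[i] for i in perm]

    n = len(sessions)
    n_labels = sum(1 for ids in by_label.values() if ids)
    # val and test must each see both labels so ROC-based calibration is
    # well-defined even on tiny datasets
    n_test = max(n_labels, math.ceil(n * ratios[2]))
    n_val = max(n_labels, round(n * ratios[1]))
    if n_test + n_val >= n:
        raise ConfigurationError("split leaves no training sessions")

    def take(count: int, offset_parity: int) -> set[str]:
        # Largest-remainder allocation across labels (min 1 per label),
        # alternating the tie side between calls.
        taken: set[str] = set()
        labels = sorted((lab for lab in by_label if by_label[lab]),
                        reverse=bool(offset_parity % 2))
        base = {lab: count * len(by_label[lab]) // n_total for lab in labels}
        assigned = sum(base.values())
        for lab in labels:
            extra = 1 if assigned < count else 0
            base[lab] += extra
            assigned += extra
        if count >= len(labels):
            for lab in labels:
                if base[lab] == 0:
                    base[lab] = 1
                    donor = max(labels, key=lambda l: base[l])
                    base[donor] -= 1
        for lab in labels:
            pool = [s for s in by_label[lab] if s not in used]
            taken.update(pool[: base[lab]])
        return taken

    used: set[str] = set()
    n_total = n
    test = take(n_test, 0)
    used |= test
    val = take(n_val, 1)
    used |= val
    train = {rec.session_id for rec in sessions} - used
    if not train or not val or not test:
        raise ConfigurationError("a split subset would be empty")
    return SplitPlan(frozenset(train), frozenset(val), frozenset(test))


def grouped_folds(subject_ids: list[str], k: int = 5, seed: int = 0,
                  val_fraction: float = 0.1) -> FoldPlan:
    """Partition subjects into K folds (sizes differing by at most one).

    Each subject is a test subject in exactly one fold; the remaining
    subjects form that fold's training pool. Window-level inner validation
    (``val_fraction`` of the non-test windows) is drawn later by the driver.
    """
    subjects = sorted(set(subject_ids))
    if k > len(subjects):
        raise ConfigurationError(f"K={k} exceeds the {len(subjects)} available subjects")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    sizes = [len(subjects) // k + (1 if i < len(subjects) % k else 0) for i in range(k)]
    folds, pos = [], 0
    for size in sizes:
        test = frozenset(order[pos : pos + size])
        folds.append(Fold(test_subjects=test, train_subjects=frozenset(subjects) - test))
        pos += size
    return FoldPlan(folds=folds, val_fraction=val_fraction)


def inner_validation_indices(n_windows: int, val_fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Seeded random subset of window indices used for inner validation."""
    n_val = max(1, round(n_windows * val_fraction))
    return rng.permutation(n_windows)[:n_val]
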