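"""Subject-wise cross-validation fold assignment.

Every participant lands in exactly one test fold, so no subject contributes
to both the training and test side of any split — the leakage guard required
when many rows (steps) share a subject.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np


def grouped_cv_split(
    subject_ids: Sequence[str],
    k: int = 5,
    seed: int = 0,
    group_labels: Optional[Mapping[str, str]] = None,
) -> dict[str, int]:
    """Assign each subject to one of ``k`` test folds.

    Fold sizes differ by at most one subject.  When ``group_labels`` maps
    subjects to cohort groups, assignment is stratified: subjects are dealt
    round-robin within shuffled group strata, so each fold sees every group.
    Deterministic given ``seed``.
    """
    subjects = list(dict.fromkeys(subject_ids))  # unique, order-preserving
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(subjects):
        raise ValueError(f"k={k} exceeds the number of subjects ({len(subjects)})")
    rng = np.random.default_rng(seed)

    if group_labels:
        strata: dict[str, list[str]] = {}
        for s in subjects:
            strata.setdefault(str(group_labels.get(s, "")), []).append(s)
        ordered: list[str] = []
        for label in sorted(strata):
            members = strata[label]
            ordered.extend(np.array(members)[rng.permutation(len(members))].tolist())
    else:
        ordered = np.array(subjects)[rng.permutation(len(subjects))].tolist()

    start = int(rng.integers(k))  # rotate so fold 0 is not always the largest
    return {s: (start + i) % k for i, s in enumerate(ordered)}


def check_no_leakage(train_subjects: set, test_subjects: set) -> None:
    """Raise if any subject appears on both sides of a split."""
    overlap = set(train_subjects) & set(test_subjects)
    if overlap:
        raise AssertionError(f"subject leakage across folds: {sorted(overlap)}")
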