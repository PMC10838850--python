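"""Labeled sinus records, instance tables and patient-level CV splits.

Labels are per sinus (anomalous = positive class); every instance sampled
from a sinus inherits its label, so instance counts scale exactly with the
sample size N.  Splits are made at patient level — both sinuses and all N
instances of a patient land in one partition — which prevents leakage while
stratifying on the sinus-level positive fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .phantom import PhantomTruth
from .sampling import SIDES, Side, SinusInstance

PARTITIONS = ("train", "val", "test")

# Default partition proportions, matching the study's 327/37/41 sinus split.
DEFAULT_VAL_FRAC = 37 / 405
DEFAULT_TEST_FRAC = 41 / 405


@dataclass(frozen=True)
class LabeledSinus:
    patient_id: str
    side: Side
    label: int   # 0 normal, 1 anomalous (positive class)

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


def labels_from_truths(truths: Iterable[PhantomTruth]) -> list[LabeledSinus]:
    return [LabeledSinus(t.patient_id, side, t.sides[side].label)
            for t in truths for side in SIDES]


def labels_from_table(df: pd.DataFrame) -> list[LabeledSinus]:
    return [LabeledSinus(str(r.patient_id), r.side, int(r.label))
            for r in df.itertuples()]


@dataclass
class FoldSplit:
    """One cross-validation fold: patient id -> partition."""

    fold_index: int
    assignment: dict[str, str]

    def __post_init__(self) -> None:
        bad = set(self.assignment.values()) - set(PARTITIONS)
        if bad:
            raise ValueError(f"unknown partitions: {sorted(bad)}")

    def patients(self, partition: str) -> list[str]:
        return [p for p, part in self.assignment.items() if part == partition]

    def partition_of(self, patient_id: str) -> str:
        return self.assignment[patient_id]


def build_labeled_instances(instances: Sequence[SinusInstance],
                            labels: Sequence[LabeledSinus]) -> pd.DataFrame:
    """Join instances with their sinus labels.

    Returns a table with one row per instance (columns: patient_id, side,
    instance_index, label, instance); every instance of a sinus inherits
    that sinus's label.  Instances whose (patient, side) has no label raise
    a ValueError listing the offenders.
    """
    label_map = {(l.patient_id, l.side): l.label for l in labels}
    rows, missing = [], set()
    for inst in instances:
        key = (inst.patient_id, inst.side)
        if key not in label_map:
            missing.add(key)
            continue
        rows.append({"patient_id": inst.patient_id, "side": inst.side,
                     "instance_index": inst.instance_index,
                     "label": label_map[key], "instance": inst})
    if missing:
        raise ValueError(f"unlabeled sinuses: {sorted(missing)}")
    return pd.DataFrame(rows, columns=["patient_id", "side", "instance_index",
                                       "label", "instance"])


def _largest_remainder(total: int, fracs: np.ndarray) -> np.ndarray:
    raw = fracs * total
    counts = np.floor(raw).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return counts


def make_folds(labels: Sequence[LabeledSinus], k: int = 3,
               val_frac: float = DEFAULT_VAL_FRAC,
               test_frac: float = DEFAULT_TEST_FRAC,
               positive_frac_target: float | None = None,
               tolerance: float = 0.03, seed: int = 0,
               max_swaps: int = 2000) -> list[FoldSplit]:
    """Build k patient-level stratified train/val/test splits.

    Patients are stratified by how many of their sinuses are anomalous
    (0, 1 or 2) and dealt to partitions proportionally, so the sinus-level
    positive fraction of each partition tracks ``positive_frac_target``
    (default: the cohort's realized fraction).  A swap-based repair then
    enforces the tolerance; infeasible targets raise RuntimeError.  Each
    fold is an independent stratified split seeded from (seed, fold).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if val_frac < 0 or test_frac < 0 or val_frac + test_frac >= 1:
        raise ValueError("val/test fractions must be >= 0 and sum to < 1")
    # per-patient stratum: (number of labeled sinuses, number anomalous)
    n_sin: dict[str, int] = {}
    n_pos: dict[str, int] = {}
    for l in labels:
        n_sin[l.patient_id] = n_sin.get(l.patient_id, 0) + 1
        n_pos[l.patient_id] = n_pos.get(l.patient_id, 0) + l.label
    patients = sorted(n_sin)
    if not patients:
        raise ValueError("no labeled patients")
    target = positive_frac_target
    if target is None:
        target = sum(n_pos.values()) / sum(n_sin.values())
    fracs = np.array([1.0 - val_frac - test_frac, val_frac, test_frac])
    strata_keys = sorted({(n_sin[p], n_pos[p]) for p in patients})
    stratum_of = {p: strata_keys.index((n_sin[p], n_pos[p])) for p in patients}
    sin_per = np.array([ks[0] for ks in strata_keys])
    pos_per = np.array([ks[1] for ks in strata_keys])
    n_strata = len(strata_keys)

    def violation(cmat: np.ndarray) -> float:
        devs = []
        for part in range(3):
            tot = int(cmat[:, part] @ sin_per)
            if tot > 0:
                devs.append(abs(cmat[:, part] @ pos_per / tot - target))
        return max(devs) if devs else 0.0

    folds = []
    for fold in range(1, k + 1):
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, fold]))
        assign: dict[str, int] = {}   # patient -> partition index
        counts = np.zeros((n_strata, 3), dtype=int)   # [stratum, partition]
        for s in range(n_strata):
            plist = [p for p in patients if stratum_of[p] == s]
            rng.shuffle(plist)
            alloc = _largest_remainder(len(plist), fracs)
            pos = 0
            for part, c in enumerate(alloc):
                for p in plist[pos:pos + c]:
                    assign[p] = part
                counts[s, part] = c
                pos += c

        # per-stratum rounding can leave column totals off the cohort-level
        # allocation (and may empty a small partition entirely); move
        # patients from over-full to under-full partitions to correct it
        desired = _largest_remainder(len(patients), fracs)
        while True:
            totals = counts.sum(axis=0)
            over = np.flatnonzero(totals > desired)
            under = np.flatnonzero(totals < desired)
            if over.size == 0:
                break
            p_from, p_to = int(over[0]), int(under[0])
            movable = np.flatnonzero(counts[:, p_from] > 0)
            s = int(movable[rng.integers(movable.size)])
            cand = [p for p, part in assign.items()
                    if part == p_from and stratum_of[p] == s]
            assign[cand[int(rng.integers(len(cand)))]] = p_to
            counts[s, p_from] -= 1
            counts[s, p_to] += 1

        # repair: swap patients of different strata between partitions
        # (keeps partition sizes fixed, moves positive counts)
        for _ in range(max_swaps):
            if violation(counts) <= tolerance:
                break
            s_a, s_b = rng.choice(n_strata, size=2, replace=False) \
                if n_strata > 1 else (0, 0)
            p_a, p_b = rng.choice(3, size=2, replace=False)
            if counts[s_a, p_a] == 0 or counts[s_b, p_b] == 0:
                continue
            trial = counts.copy()
            trial[s_a, p_a] -= 1; trial[s_a, p_b] += 1
            trial[s_b, p_b] -= 1; trial[s_b, p_a] += 1
            if violation(trial) < violation(counts):
                cand_a = [p for p, part in assign.items()
                          if part == p_a and stratum_of[p] == s_a]
                cand_b = [p for p, part in assign.items()
                          if part == p_b and stratum_of[p] == s_b]
                assign[cand_a[rng.integers(len(cand_a))]] = p_b
                assign[cand_b[rng.integers(len(cand_b))]] = p_a
                counts = trial
        if violation(counts) > tolerance:
            raise RuntimeError(
                f"fold {fold}: cannot stratify partitions to within "
                f"{tolerance:.3f} of positive fraction {target:.3f}")
        folds.append(FoldSplit(fold_index=fold,
                               assignment={p: PARTITIONS[i]
                                           for p, i in assign.items()}))
    return folds


def check_no_leakage(folds: Sequence[FoldSplit]) -> None:
    """Assert that within each fold the partitions' patient sets are disjoint."""
    for f in folds:
        sets = [set(f.patients(p)) for p in PARTITIONS]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise AssertionError(
                        f"fold {f.fold_index}: patients in both "
                        f"{PARTITIONS[i]} and {PARTITIONS[j]}")


def partition_positive_fraction(fold: FoldSplit,
                                labels: Sequence[LabeledSinus],
                                partition: str) -> float:
    pats = set(fold.patients(partition))
    ls = [l.label for l in labels if l.patient_id in pats]
    if not ls:
        raise ValueError(f"partition {partition!r} is empty")
    return float(np.mean(ls))


def write_folds(folds: Sequence[FoldSplit], path) -> None:
    rows = [{"fold": f.fold_index, "patient_id": p, "partition": part}
            for f in folds for p, part in sorted(f.assignment.items())]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_folds(path) -> list[FoldSplit]:
    df = pd.read_csv(path, sep="\t")
    folds = []
    for fold_index, grp in df.groupby("fold"):
        folds.append(FoldSplit(
            fold_index=int(fold_index),
            assignment={str(r.patient_id): r.partition for r in grp.itertuples()}))
    return folds
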