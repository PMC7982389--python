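"""Train/test division strategies of increasing difficulty.

Four splitting schemes are supported, crossing two axes: the unit that is
assigned (individual compounds vs whole analog series) and the scope of the
assignment (independently per target vs globally across all targets).

- ``CPD_TARGET``: compounds randomly split per target; a compound may train
  for one target and test for another.
- ``CPD_GLOBAL``: one global compound split; a compound and all its
  annotations are exclusively train or test across every target.
- ``AS_TARGET``: complete analog series assigned to train or test per target,
  so close analogs never straddle a target's train/test boundary.
- ``AS_GLOBAL``: whole series assigned globally — the hardest setting.

For multi-target models the training-label mask is derived from the split:
a (compound, target) annotation enters the training loss only when the
compound is in that target's training set, so test annotations are masked
even when the same compound trains for other targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd

from .curation import PotencyMatrix

__all__ = [
    "Strategy",
    "SplitSpec",
    "SplitAssignment",
    "make_split",
    "derive_training_mask",
    "leakage_audit",
    "assignment_table",
]


class Strategy(str, Enum):
    CPD_TARGET = "cpd_target"
    CPD_GLOBAL = "cpd_global"
    AS_TARGET = "as_target"
    AS_GLOBAL = "as_global"


@dataclass(frozen=True)
class SplitSpec:
    """One seeded split request.

    ``test_fraction`` must be strictly between 0 and 1 (no value is implied
    by the benchmark protocol itself, so it is always explicit in outputs).
    Trials are realized as seed offsets: trial i uses entropy (seed, i).
    """

    strategy: Strategy
    test_fraction: float = 0.2
    seed: int = 0
    trial_index: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")


@dataclass
class SplitAssignment:
    """Per-target train/test compound sets produced by one strategy."""

    spec: SplitSpec
    train: dict[str, set[str]]
    test: dict[str, set[str]]
    skipped_targets: list[tuple[str, str]] = field(default_factory=list)

    def targets(self) -> list[str]:
        return sorted(self.train)


def _rng(spec: SplitSpec) -> np.random.Generator:
    return np.random.default_rng([spec.seed, spec.trial_index])


def _split_units(
    units: list[str],
    sizes: Mapping[str, int],
    test_fraction: float,
    rng: np.random.Generator,
) -> set[str]:
    """Assign whole units to the test side until the compound-count test
    fraction is first met or exceeded, keeping >= 1 unit on each side."""
    total = sum(sizes[u] for u in units)
    order = [units[i] for i in rng.permutation(len(units))]
    test_units: set[str] = set()
    covered = 0
    for u in order:
        if covered >= test_fraction * total:
            break
        if len(test_units) == len(units) - 1:
            break  # keep at least one unit in training
        test_units.add(u)
        covered += sizes[u]
    return test_units


def make_split(
    matrix: PotencyMatrix,
    partition: Mapping[str, str],
    spec: SplitSpec,
) -> SplitAssignment:
    """Divide each target's annotated compounds into train and test sets.

    Deterministic for a fixed spec.  Under the AS strategies a target whose
    annotated compounds all belong to one series cannot have non-empty train
    and test sets and is skipped with a warning record; under the global
    strategies a target whose annotations happen to fall entirely on one side
    of the global split is likewise skipped.
    """
    missing = [c for c in matrix.compounds if c not in partition]
    if missing:
        raise ValueError(f"partition does not cover compounds: {missing[:5]}...")
    rng = _rng(spec)
    frac = spec.test_fraction
    train: dict[str, set[str]] = {}
    test: dict[str, set[str]] = {}
    skipped: list[tuple[str, str]] = []

    targets = sorted(matrix.targets)
    per_target = {t: sorted(matrix.compounds_for_target(t)) for t in targets}

    if spec.strategy is Strategy.CPD_TARGET:
        for t in targets:
            cids = per_target[t]
            if len(cids) < 2:
                skipped.append((t, "fewer than 2 annotated compounds"))
                continue
            n_test = min(max(1, round(frac * len(cids))), len(cids) - 1)
            perm = [cids[i] for i in rng.permutation(len(cids))]
            test[t] = set(perm[:n_test])
            train[t] = set(perm[n_test:])

    elif spec.strategy is Strategy.CPD_GLOBAL:
        cids = sorted(matrix.compounds)
        n_test = min(max(1, round(frac * len(cids))), len(cids) - 1)
        perm = [cids[i] for i in rng.permutation(len(cids))]
        global_test = set(perm[:n_test])
        for t in targets:
            te = {c for c in per_target[t] if c in global_test}
            tr = {c for c in per_target[t] if c not in global_test}
            if not te or not tr:
                skipped.append((t, "global compound split left train or test empty"))
                continue
            train[t], test[t] = tr, te

    elif spec.strategy is Strategy.AS_TARGET:
        for t in targets:
            cids = per_target[t]
            series_members: dict[str, list[str]] = {}
            for c in cids:
                series_members.setdefault(partition[c], []).append(c)
            if len(series_members) < 2:
                skipped.append((t, "single analog series: AS split impossible"))
                continue
            sizes = {s: len(m) for s, m in series_members.items()}
            test_series = _split_units(sorted(series_members), sizes, frac, rng)
            test[t] = {c for s in test_series for c in series_members[s]}
            train[t] = set(cids) - test[t]

    elif spec.strategy is Strategy.AS_GLOBAL:
        series_members: dict[str, list[str]] = {}
        for c in sorted(matrix.compounds):
            series_members.setdefault(partition[c], []).append(c)
        if len(series_members) < 2:
            raise ValueError("AS_GLOBAL needs at least two analog series")
        sizes = {s: len(m) for s, m in series_members.items()}
        test_series = _split_units(sorted(series_members), sizes, frac, rng)
        global_test = {c for s in test_series for c in series_members[s]}
        for t in targets:
            te = {c for c in per_target[t] if c in global_test}
            tr = {c for c in per_target[t] if c not in global_test}
            if not te or not tr:
                skipped.append((t, "global series split left train or test empty"))
                continue
            train[t], test[t] = tr, te
    else:  # pragma: no cover
        raise ValueError(f"unknown strategy {spec.strategy}")

    return SplitAssignment(spec=spec, train=train, test=test, skipped_targets=skipped)


def derive_training_mask(
    matrix: PotencyMatrix, assignment: SplitAssignment
) -> frozenset[tuple[str, str]]:
    """(compound, target) pairs usable in the training loss.

    A pair is trainable iff the annotation exists and the compound is in that
    target's training set; every test annotation is excluded even when the
    compound trains for other targets.
    """
    mask = set()
    for t, tr in assignment.train.items():
        for c in tr:
            if (c, t) in matrix.entries:
                mask.add((c, t))
    return frozenset(mask)


def leakage_audit(
    matrix: PotencyMatrix,
    partition: Mapping[str, str],
    assignment: SplitAssignment,
    mask: frozenset[tuple[str, str]] | None = None,
) -> list[str]:
    """Check every strategy invariant; returns a list of violation messages.

    Checks (as applicable to the strategy): per-target train/test disjointness
    and exhaustiveness; no series straddling train/test (AS, per target; AS
    global across targets); no compound training for one target while testing
    for another (global strategies); and that the training mask excludes every
    test annotation.
    """
    if mask is None:
        mask = derive_training_mask(matrix, assignment)
    spec = assignment.spec
    bad: list[str] = []
    for t in assignment.train:
        tr, te = assignment.train[t], assignment.test[t]
        if tr & te:
            bad.append(f"{t}: train/test overlap")
        if tr | te != matrix.compounds_for_target(t):
            bad.append(f"{t}: train+test do not cover annotated compounds")
        if not tr or not te:
            bad.append(f"{t}: empty train or test set")
    if spec.strategy in (Strategy.AS_TARGET, Strategy.AS_GLOBAL):
        for t in assignment.train:
            s_tr = {partition[c] for c in assignment.train[t]}
            s_te = {partition[c] for c in assignment.test[t]}
            if s_tr & s_te:
                bad.append(f"{t}: analog series split across train and test")
    if spec.strategy in (Strategy.CPD_GLOBAL, Strategy.AS_GLOBAL):
        all_train = set().union(*assignment.train.values()) if assignment.train else set()
        all_test = set().union(*assignment.test.values()) if assignment.test else set()
        for c in all_train & all_test:
            bad.append(f"compound {c} trains for one target and tests for another")
    if spec.strategy is Strategy.AS_GLOBAL:
        all_train = set().union(*assignment.train.values()) if assignment.train else set()
        all_test = set().union(*assignment.test.values()) if assignment.test else set()
        s_tr = {partition[c] for c in all_train}
        s_te = {partition[c] for c in all_test}
        for s in s_tr & s_te:
            bad.append(f"series {s} spans train and test across targets")
    for t, te in assignment.test.items():
        for c in te:
            if (c, t) in mask:
                bad.append(f"test annotation ({c}, {t}) present in training mask")
    return bad


def assignment_table(assignment: SplitAssignment) -> pd.DataFrame:
    """Long-format table: (trial, strategy, test_fraction, target, compound, role)."""
    rows = []
    spec = assignment.spec
    for t in sorted(assignment.train):
        for c in sorted(assignment.train[t]):
            rows.append((spec.trial_index, spec.strategy.value, spec.test_fraction, t, c, "train"))
        for c in sorted(assignment.test[t]):
            rows.append((spec.trial_index, spec.strategy.value, spec.test_fraction, t, c, "test"))
    return pd.DataFrame(
        rows,
        columns=["trial", "strategy", "test_fraction", "target_id", "compound_id", "role"],
    )
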