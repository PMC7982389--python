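"""Curation of compound-target potency tables into sparse pKi matrices.

Replicate Ki measurements for a (compound, target) pair are aggregated to a
single pKi label by geometric mean, subject to two exclusion rules that drop
borderline or inconsistent annotations: all replicates must fall within one
order of magnitude of each other, and the aggregated pKi must exceed a potency
floor (default 5, i.e. Ki below 10 uM). Activity classes (targets) are then
filtered to a minimum compound count and a minimum number of distinct analog
series, and the surviving annotations are assembled into a sparse
compound x target matrix with an explicit density.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CurationConfig",
    "PotencyAnnotation",
    "PotencyMatrix",
    "aggregate_potency",
    "curate_table",
    "build_potency_matrix",
    "filter_activity_classes",
    "read_potency_table",
    "write_matrix",
    "read_matrix",
]

#: Conversion factors from supported input concentration units to molar.
_UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9, "pM": 1e-12}


@dataclass(frozen=True)
class CurationConfig:
    """Tunable curation rules.

    max_ki_ratio
        Largest allowed max/min ratio among replicate Ki values ("same order
        of magnitude"); inclusive boundary.
    min_pki
        Potency floor; aggregated pKi must be strictly greater.
    units
        Concentration units of the input Ki column.
    rejection_scope
        ``"annotation"`` drops only the rejected (compound, target)
        annotation; ``"compound"`` drops every annotation of a compound that
        has at least one rejected annotation.
    """

    max_ki_ratio: float = 10.0
    min_pki: float = 5.0
    units: str = "nM"
    rejection_scope: str = "annotation"

    def __post_init__(self) -> None:
        if self.units not in _UNIT_TO_MOLAR:
            raise ValueError(f"unsupported units {self.units!r}")
        if self.rejection_scope not in ("annotation", "compound"):
            raise ValueError("rejection_scope must be 'annotation' or 'compound'")


@dataclass(frozen=True)
class PotencyAnnotation:
    """An accepted, aggregated potency label for one (compound, target) pair."""

    compound_id: str
    target_id: str
    pki: float


def aggregate_potency(
    ki_values: Sequence[float],
    *,
    max_ki_ratio: float = 10.0,
    min_pki: float = 5.0,
    units: str = "nM",
) -> float | None:
    """Aggregate replicate Ki values into a single pKi label.

    The geometric mean of the replicates is converted to molar and negated in
    log10: ``pKi = -log10(geomean(Ki) in M)``.  Returns the pKi when all
    replicates fall within ``max_ki_ratio`` of each other (inclusive) and the
    aggregated pKi is strictly greater than ``min_pki``; returns ``None``
    (rejected, borderline-active or inconsistent) otherwise.

    Raises ``ValueError`` on an empty list or any non-positive value.
    """
    if len(ki_values) == 0:
        raise ValueError("ki_values is empty")
    if any(not (k > 0) for k in ki_values):
        raise ValueError("all Ki values must be positive")
    if max(ki_values) / min(ki_values) > max_ki_ratio:
        return None
    to_molar = _UNIT_TO_MOLAR[units]
    # geometric mean in log space: pKi = -mean(log10(ki * to_molar))
    pki = -sum(math.log10(k * to_molar) for k in ki_values) / len(ki_values)
    if not pki > min_pki:
        return None
    return pki


@dataclass
class PotencyMatrix:
    """Sparse compound x target pKi label matrix.

    ``entries`` maps (compound_id, target_id) to an aggregated pKi value.
    Compounds and targets are kept as explicit ordered indexes so that the
    density denominator is well defined even when rows/columns are empty.
    """

    compounds: list[str]
    targets: list[str]
    entries: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cset, tset = set(self.compounds), set(self.targets)
        if len(cset) != len(self.compounds) or len(tset) != len(self.targets):
            raise ValueError("duplicate ids in compound or target index")
        for c, t in self.entries:
            if c not in cset or t not in tset:
                raise ValueError(f"entry ({c!r}, {t!r}) outside the matrix index")

    @property
    def density(self) -> float:
        """Fraction of (compound, target) cells with an annotation, in [0, 1]."""
        cells = len(self.compounds) * len(self.targets)
        return len(self.entries) / cells if cells else 0.0

    @property
    def n_entries(self) -> int:
        return len(self.entries)

    def compounds_for_target(self, target_id: str) -> set[str]:
        return {c for (c, t) in self.entries if t == target_id}

    def targets_for_compound(self, compound_id: str) -> set[str]:
        return {t for (c, t) in self.entries if c == compound_id}

    def labels_for_target(self, target_id: str) -> dict[str, float]:
        return {c: v for (c, t), v in self.entries.items() if t == target_id}

    def to_frame(self) -> pd.DataFrame:
        """Triplet representation: one row per annotation, sorted."""
        rows = sorted((c, t, v) for (c, t), v in self.entries.items())
        return pd.DataFrame(rows, columns=["compound_id", "target_id", "pki"])

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        compounds: Iterable[str] | None = None,
        targets: Iterable[str] | None = None,
    ) -> "PotencyMatrix":
        entries = {
            (str(r.compound_id), str(r.target_id)): float(r.pki)
            for r in frame.itertuples()
        }
        if compounds is None:
            compounds = sorted({c for c, _ in entries})
        if targets is None:
            targets = sorted({t for _, t in entries})
        return cls(list(compounds), list(targets), entries)


def build_potency_matrix(annotations: Iterable[PotencyAnnotation]) -> PotencyMatrix:
    """Assemble accepted annotations into a sparse matrix.

    Duplicate (compound, target) pairs with differing pKi raise ``ValueError``
    — curation should already have aggregated replicates.
    """
    entries: dict[tuple[str, str], float] = {}
    for ann in annotations:
        key = (ann.compound_id, ann.target_id)
        if key in entries and entries[key] != ann.pki:
            raise ValueError(f"conflicting duplicate annotation for {key}")
        entries[key] = ann.pki
    compounds = sorted({c for c, _ in entries})
    targets = sorted({t for _, t in entries})
    return PotencyMatrix(compounds, targets, entries)


def curate_table(
    table: pd.DataFrame, config: CurationConfig = CurationConfig()
) -> PotencyMatrix:
    """Curate a raw potency table into a PotencyMatrix.

    ``table`` has columns ``compound_id``, ``target_id``, ``ki_<units>`` (or
    ``ki_nM``); multiple rows per (compound, target) are replicates.  A
    ``smiles`` column, if present, is ignored here (structures are handled by
    the fingerprint and analog-series modules).
    """
    ki_col = next(
        (c for c in table.columns if c.lower() in (f"ki_{config.units}".lower(), "ki_nm", "ki")),
        None,
    )
    if ki_col is None:
        raise ValueError("no Ki column found (expected e.g. 'ki_nM')")
    accepted: list[PotencyAnnotation] = []
    rejected_compounds: set[str] = set()
    for (cid, tid), grp in table.groupby(["compound_id", "target_id"], sort=True):
        pki = aggregate_potency(
            list(grp[ki_col]),
            max_ki_ratio=config.max_ki_ratio,
            min_pki=config.min_pki,
            units=config.units,
        )
        if pki is None:
            rejected_compounds.add(str(cid))
        else:
            accepted.append(PotencyAnnotation(str(cid), str(tid), pki))
    if config.rejection_scope == "compound":
        accepted = [a for a in accepted if a.compound_id not in rejected_compounds]
    return build_potency_matrix(accepted)


def filter_activity_classes(
    matrix: PotencyMatrix,
    partition: Mapping[str, str],
    min_compounds: int = 50,
    min_series: int = 2,
) -> PotencyMatrix:
    """Drop activity classes that are too small or lack analog diversity.

    A target survives iff it has at least ``min_compounds`` annotated
    compounds and those compounds span at least ``min_series`` distinct analog
    series.  ``partition`` maps compound_id -> series_id and must cover every
    compound in the matrix.  Compounds left without any annotation are dropped
    from the compound index.  Idempotent.
    """
    missing = [c for c in matrix.compounds if c not in partition]
    if missing:
        raise ValueError(f"partition does not cover compounds: {missing[:5]}...")
    keep_targets = []
    for t in matrix.targets:
        members = matrix.compounds_for_target(t)
        series = {partition[c] for c in members}
        if len(members) >= min_compounds and len(series) >= min_series:
            keep_targets.append(t)
    keep_tset = set(keep_targets)
    entries = {(c, t): v for (c, t), v in matrix.entries.items() if t in keep_tset}
    keep_compounds = [c for c in matrix.compounds if any((c, t) in entries for t in keep_targets)]
    return PotencyMatrix(keep_compounds, keep_targets, entries)


# ---------------------------------------------------------------------------
# I/O

def read_potency_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, dtype={"compound_id": str, "target_id": str})


def write_matrix(matrix: PotencyMatrix, out_dir: str | Path, sep: str = "\t") -> None:
    """Write the sparse triplet table plus a metadata sidecar (counts, density)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix.to_frame().to_csv(out / "matrix.tsv", sep=sep, index=False)
    meta = {
        "n_compounds": len(matrix.compounds),
        "n_targets": len(matrix.targets),
        "n_annotations": matrix.n_entries,
        "density": matrix.density,
        "compounds": matrix.compounds,
        "targets": matrix.targets,
    }
    (out / "matrix.meta.json").write_text(json.dumps(meta, indent=1))


def read_matrix(in_dir: str | Path, sep: str = "\t") -> PotencyMatrix:
    out = Path(in_dir)
    frame = pd.read_csv(out / "matrix.tsv", sep=sep, dtype={"compound_id": str, "target_id": str})
    meta = json.loads((out / "matrix.meta.json").read_text())
    return PotencyMatrix.from_frame(frame, meta["compounds"], meta["targets"])
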