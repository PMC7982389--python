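"""Synthetic compound libraries and sparse potency matrices with known truth.

The generator emulates the structure of curated public potency data:
compounds organized into analog series (one scaffold per series, varying
substituents), sparsely annotated against multiple targets, with
log-normally distributed Ki (i.e. roughly Gaussian pKi).  Every generated
data set carries its ground truth — series membership and the noise-free
mean pKi per (compound, target) — so that series extraction, splitting and
model behaviour can be verified exactly.

The potency model is additive and analyzable:

    true_pKi(c, t) = target_offset(t) + series_effect(series(c), t)
                     + substituent_effect(c)

Series effects are drawn with a tunable inter-target correlation rho, which
controls how much one target's labels can inform another's — the lever
behind multi-task learning synergy.  Observed labels add Gaussian noise and
are clipped to a plausible pKi range; matrix cells are retained
independently with probability ``density``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .analog_series import fragment_single_cut
from .curation import PotencyMatrix

__all__ = [
    "DEFAULT_SCAFFOLDS",
    "DEFAULT_SUBSTITUENTS",
    "FixtureSpec",
    "FixtureTruth",
    "generate_library",
    "generate_potency_matrix",
    "to_ki_table",
]

#: Scaffold cores with one open attachment point, pairwise structurally
#: distinct so that ground-truth series stay disjoint under MMP clustering.
DEFAULT_SCAFFOLDS: tuple[str, ...] = (
    "[*:1]c1ccccc1",          # benzene
    "[*:1]c1ccncc1",          # pyridin-4-yl
    "[*:1]C1CCCCC1",          # cyclohexane
    "[*:1]c1ccc2ccccc2c1",    # naphthalen-2-yl
    "[*:1]c1ccco1",           # furan-2-yl
    "[*:1]c1cccs1",           # thiophen-2-yl
    "[*:1]c1cncnc1",          # pyrimidin-5-yl
    "[*:1]C1CCNCC1",          # piperidin-4-yl
    "[*:1]c1cnccn1",          # pyrazin-2-yl
    "[*:1]C1CCCC1",           # cyclopentane
    "[*:1]C1CCOCC1",          # oxan-4-yl
    "[*:1]C1CCOC1",           # oxolan-3-yl
    "[*:1]c1cccnc1",          # pyridin-3-yl
    "[*:1]C1CCSCC1",          # thian-4-yl
    "[*:1]c1ccoc1",           # furan-3-yl
    "[*:1]c1ccsc1",           # thiophen-3-yl
)

#: R-groups (<= 4 heavy atoms, below every scaffold's size so the scaffold is
#: always the MMP core).
DEFAULT_SUBSTITUENTS: tuple[str, ...] = (
    "[*:1]C", "[*:1]CC", "[*:1]CCC", "[*:1]C(C)C", "[*:1]CCCC",
    "[*:1]CC(C)C", "[*:1]OC", "[*:1]OCC", "[*:1]CO", "[*:1]CCO",
    "[*:1]N", "[*:1]CN", "[*:1]CCN", "[*:1]F", "[*:1]Cl",
    "[*:1]Br", "[*:1]C(F)(F)F", "[*:1]C=C", "[*:1]CC=C", "[*:1]C#N",
    "[*:1]CC#N", "[*:1]C(=O)C", "[*:1]C(=O)OC", "[*:1]CCF",
    "[*:1]CCCl", "[*:1]CCCO", "[*:1]OC(C)C", "[*:1]CC(=O)C",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Generation parameters; defaults give a small, sparse, correlated
    multi-target data set with clearly separated analog series."""

    n_series: int = 8
    series_size_range: tuple[int, int] = (5, 12)
    n_targets: int = 10
    density: float = 0.2
    target_offset_range: tuple[float, float] = (6.0, 9.0)
    series_effect_sd: float = 0.8
    substituent_effect_sd: float = 0.4
    noise_sd: float = 0.3
    rho: float = 0.5
    seed: int = 0
    scaffold_templates: tuple[str, ...] = DEFAULT_SCAFFOLDS
    substituent_pool: tuple[str, ...] = DEFAULT_SUBSTITUENTS
    pki_range: tuple[float, float] = (5.01, 11.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.density <= 1.0:
            raise ValueError("density must be in (0, 1]")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        if self.series_size_range[0] < 1 or self.series_size_range[0] > self.series_size_range[1]:
            raise ValueError("invalid series_size_range")


@dataclass
class FixtureTruth:
    """Ground truth of a generated data set."""

    series_of: dict[str, str] = field(default_factory=dict)
    substituent_of: dict[str, str] = field(default_factory=dict)
    true_pki: dict[tuple[str, str], float] = field(default_factory=dict)


def _assemble(core_smiles: str, sub_smiles: str) -> str:
    core = Chem.MolFromSmiles(core_smiles)
    sub = Chem.MolFromSmiles(sub_smiles)
    if core is None or sub is None:
        raise ValueError(f"invalid template or substituent: {core_smiles!r} + {sub_smiles!r}")
    return Chem.MolToSmiles(Chem.molzip(core, sub))


def generate_library(
    spec: FixtureSpec, validate: bool = True
) -> tuple[list[tuple[str, str]], FixtureTruth]:
    """Generate (compound_id, smiles) records organized into analog series.

    Each series combines one scaffold template with distinct substituents
    drawn without replacement from the pool.  Deterministic per seed.
    Raises when the template or substituent pool cannot realize the request,
    or (with ``validate=True``) when two series share an MMP core — which
    would merge ground-truth series.
    """
    if spec.n_series > len(spec.scaffold_templates):
        raise ValueError(
            f"need {spec.n_series} scaffold templates, only "
            f"{len(spec.scaffold_templates)} available"
        )
    if spec.series_size_range[1] > len(spec.substituent_pool):
        raise ValueError(
            f"series size up to {spec.series_size_range[1]} requested but the "
            f"substituent pool has only {len(spec.substituent_pool)} entries"
        )
    rng = np.random.default_rng([spec.seed, 1])
    records: list[tuple[str, str]] = []
    truth = FixtureTruth()
    lo, hi = spec.series_size_range
    core_owner: dict[str, str] = {}
    for s in range(spec.n_series):
        scaffold = spec.scaffold_templates[s]
        size = int(rng.integers(lo, hi + 1))
        sub_idx = rng.choice(len(spec.substituent_pool), size=size, replace=False)
        sid = f"S{s:03d}"
        for j, si in enumerate(sub_idx):
            cid = f"CPD{s:03d}_{j:03d}"
            smi = _assemble(scaffold, spec.substituent_pool[si])
            records.append((cid, smi))
            truth.series_of[cid] = sid
            truth.substituent_of[cid] = spec.substituent_pool[si]
    smiles_seen: dict[str, str] = {}
    for cid, smi in records:
        if smi in smiles_seen:
            raise ValueError(f"duplicate structure {smi!r} ({smiles_seen[smi]}, {cid})")
        smiles_seen[smi] = cid
    if validate:
        for cid, smi in records:
            for frag in fragment_single_cut(smi):
                owner = core_owner.setdefault(frag.core, truth.series_of[cid])
                if owner != truth.series_of[cid]:
                    raise ValueError(
                        f"scaffold templates not disjoint: core {frag.core!r} "
                        f"shared by series {owner} and {truth.series_of[cid]}"
                    )
    return records, truth


def generate_potency_matrix(
    library: list[tuple[str, str]],
    truth: FixtureTruth,
    spec: FixtureSpec,
) -> tuple[PotencyMatrix, FixtureTruth]:
    """Sample a sparse observed pKi matrix over the library's compounds.

    Series effects across targets share a latent component weighted by
    sqrt(rho), giving inter-target correlation rho.  Substituent effects are
    keyed to the substituent structure (the same R-group contributes the same
    increment in every series and for every target), so with zero noise the
    labels are fully structure-determined and the best achievable prediction
    error equals the noise sd.  Observed labels add Gaussian noise
    and are clipped into ``pki_range``.  Cells are kept independently with
    probability ``density``; a target left with zero labels has its column
    resampled once and a warning is issued if it is still empty.
    """
    if not library:
        raise ValueError("empty library")
    rng = np.random.default_rng([spec.seed, 2])
    compounds = [cid for cid, _ in library]
    targets = [f"T{t:03d}" for t in range(spec.n_targets)]
    series_ids = sorted({truth.series_of[c] for c in compounds})
    s_index = {s: i for i, s in enumerate(series_ids)}

    offsets = rng.uniform(*spec.target_offset_range, size=spec.n_targets)
    shared = rng.normal(size=len(series_ids))  # latent per-series component
    local = rng.normal(size=(len(series_ids), spec.n_targets))
    series_eff = spec.series_effect_sd * (
        np.sqrt(spec.rho) * shared[:, None] + np.sqrt(1.0 - spec.rho) * local
    )
    sub_structures = sorted({truth.substituent_of[c] for c in compounds})
    sub_eff = {
        s: e
        for s, e in zip(
            sub_structures,
            rng.normal(0.0, spec.substituent_effect_sd, size=len(sub_structures)),
        )
    }

    true_pki: dict[tuple[str, str], float] = {}
    observed = np.empty((len(compounds), spec.n_targets))
    for i, c in enumerate(compounds):
        si = s_index[truth.series_of[c]]
        for j in range(spec.n_targets):
            mu = offsets[j] + series_eff[si, j] + sub_eff[truth.substituent_of[c]]
            true_pki[(c, targets[j])] = float(mu)
    noise = rng.normal(0.0, spec.noise_sd, size=observed.shape)
    for i, c in enumerate(compounds):
        for j in range(spec.n_targets):
            observed[i, j] = true_pki[(c, targets[j])] + noise[i, j]
    observed = np.clip(observed, *spec.pki_range)

    keep = rng.random(observed.shape) < spec.density
    for j in range(spec.n_targets):
        if not keep[:, j].any():
            keep[:, j] = rng.random(len(compounds)) < spec.density
            if not keep[:, j].any():
                import warnings

                warnings.warn(f"target {targets[j]} has no labels at density {spec.density}")

    entries = {
        (compounds[i], targets[j]): float(observed[i, j])
        for i in range(len(compounds))
        for j in range(spec.n_targets)
        if keep[i, j]
    }
    matrix = PotencyMatrix(list(compounds), list(targets), entries)
    full_truth = FixtureTruth(
        series_of=dict(truth.series_of),
        substituent_of=dict(truth.substituent_of),
        true_pki=true_pki,
    )
    return matrix, full_truth


def to_ki_table(matrix: PotencyMatrix, library: list[tuple[str, str]]) -> pd.DataFrame:
    """Back-convert the matrix to the raw input format consumed by curation:
    one row per annotation with Ki in nM (Ki_nM = 10**(9 - pKi))."""
    smiles_of = dict(library)
    rows = [
        (c, smiles_of[c], t, 10.0 ** (9.0 - pki))
        for (c, t), pki in sorted(matrix.entries.items())
    ]
    return pd.DataFrame(rows, columns=["compound_id", "smiles", "target_id", "ki_nM"])
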