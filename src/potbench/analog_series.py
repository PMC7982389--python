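"""Analog-series extraction via matched-molecular-pair (MMP) fragmentation.

Each molecule is fragmented at every eligible bond (acyclic single bond
between two heavy atoms) into a core and a substituent, both carrying one
attachment point.  Two compounds form an MMP when they share an identical
core, i.e. they differ only by a substituent exchange.  The compound network
with MMP edges decomposes into connected components; each disjoint component
is one analog series (compounds sharing a core structure with varying
R-groups), and every compound belongs to exactly one series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
from rdkit import Chem

from .fingerprints import SmilesParseError

__all__ = [
    "Fragmentation",
    "AnalogSeriesPartition",
    "fragment_single_cut",
    "build_mmp_network",
    "extract_analog_series",
    "assign_series",
]


@dataclass(frozen=True)
class Fragmentation:
    """One single-cut fragmentation: core (larger half) + substituent.

    Both halves are canonical SMILES with exactly one attachment point
    (``[1*]``).  When the two halves have equal heavy-atom counts the
    fragmentation is emitted in both orientations by
    :func:`fragment_single_cut`, so core >= substituent always holds.
    """

    core: str
    substituent: str


def _n_heavy(frag: Chem.Mol) -> int:
    """Heavy atoms excluding the dummy attachment atom."""
    return sum(1 for a in frag.GetAtoms() if a.GetAtomicNum() > 1)


def fragment_single_cut(
    smiles: str, max_substituent_atoms: int = 13
) -> set[Fragmentation]:
    """Enumerate all single-cut fragmentations of a molecule.

    Eligible cut bonds are acyclic single bonds between two heavy atoms.  For
    each cut the larger fragment is the core and the smaller the substituent;
    equal-sized halves yield both orientations.  Fragmentations whose
    substituent exceeds ``max_substituent_atoms`` heavy atoms are discarded
    (standard MMP size convention).  Molecules with no eligible bond (e.g.
    simple rings) return the empty set.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    out: set[Fragmentation] = set()
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a1, a2 = bond.GetBeginAtom(), bond.GetEndAtom()
        if a1.GetAtomicNum() <= 1 or a2.GetAtomicNum() <= 1:
            continue
        cut = Chem.FragmentOnBonds(mol, [bond.GetIdx()], addDummies=True, dummyLabels=[(1, 1)])
        frags = Chem.GetMolFrags(cut, asMols=True, sanitizeFrags=True)
        if len(frags) != 2:  # pragma: no cover - single acyclic cut always splits in two
            continue
        n0, n1 = _n_heavy(frags[0]), _n_heavy(frags[1])
        s0, s1 = Chem.MolToSmiles(frags[0]), Chem.MolToSmiles(frags[1])
        pairs: list[tuple[str, str, int]]
        if n0 > n1:
            pairs = [(s0, s1, n1)]
        elif n1 > n0:
            pairs = [(s1, s0, n0)]
        else:  # equal halves: both orientations are valid MMP cores
            pairs = [(s0, s1, n1), (s1, s0, n0)]
        for core, sub, n_sub in pairs:
            if n_sub <= max_substituent_atoms:
                out.add(Fragmentation(core=core, substituent=sub))
    return out


def build_mmp_network(
    fragmentations: Mapping[str, set[Fragmentation]]
) -> nx.Graph:
    """Compound network with an edge between compounds sharing >= 1 core.

    ``fragmentations`` maps compound_id to its set of single-cut
    fragmentations (cores canonicalized consistently).  Every compound is a
    node even when it has no fragmentation; edges carry the shared core(s).
    """
    graph = nx.Graph()
    graph.add_nodes_from(fragmentations)
    by_core: dict[str, list[str]] = {}
    for cid, frags in fragmentations.items():
        for frag in frags:
            by_core.setdefault(frag.core, []).append(cid)
    for core, cids in by_core.items():
        cids = sorted(set(cids))
        for i, ci in enumerate(cids):
            for cj in cids[i + 1 :]:
                if graph.has_edge(ci, cj):
                    graph[ci][cj]["cores"].add(core)
                else:
                    graph.add_edge(ci, cj, cores={core})
    return graph


@dataclass
class AnalogSeriesPartition:
    """Assignment of every compound to exactly one analog series."""

    series_of: dict[str, str]
    series: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        covered = set()
        for sid, members in self.series.items():
            if covered & members:
                raise ValueError("series overlap: not a partition")
            covered |= members
        if covered != set(self.series_of):
            raise ValueError("series_of and series are inconsistent")

    @property
    def n_series(self) -> int:
        return len(self.series)

    def __getitem__(self, compound_id: str) -> str:
        return self.series_of[compound_id]

    def keys(self):  # Mapping-compatible for filter_activity_classes
        return self.series_of.keys()

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self.series_of


def extract_analog_series(network: nx.Graph) -> AnalogSeriesPartition:
    """Connected components of the MMP network, one series per component.

    Isolated nodes form singleton series.  Series ids are deterministic: the
    lexicographically smallest member compound_id.
    """
    series: dict[str, frozenset[str]] = {}
    series_of: dict[str, str] = {}
    for comp in nx.connected_components(network):
        sid = min(comp)
        series[sid] = frozenset(comp)
        for cid in comp:
            series_of[cid] = sid
    return AnalogSeriesPartition(series_of=series_of, series=series)


def assign_series(
    records: Iterable[tuple[str, str]], max_substituent_atoms: int = 13
) -> AnalogSeriesPartition:
    """Full pipeline: fragment (compound_id, smiles) pairs, build the MMP
    network, and return the connected-component series partition."""
    frags = {cid: fragment_single_cut(smi, max_substituent_atoms) for cid, smi in records}
    return extract_analog_series(build_mmp_network(frags))
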