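"""Dataset-level characterization.

* summary statistics (entry/rule/example/data-point counts, cross-reference
  coverage percentages, optional taxon roll-up from user-supplied lineages),
* differential reaction fingerprints and a k-nearest-neighbour reaction map,
* sequence similarity networks (SSN) with orphan counting.

The differential reaction fingerprint encodes *what a reaction changes*:
circular substructure identifiers (SMILES shingles up to a radius) are
enumerated on the reactant side and the product side, the symmetric
difference of the two identifier multisets is taken, and each surviving
identifier is hashed with a seeded hash into a fixed-length bit vector.
An identity reaction therefore maps to the zero vector. The defaults
(2048 bits, radius 3) are package configuration; no bit-compatibility with
any other implementation is claimed.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional

import networkx as nx
import numpy as np
from rdkit import Chem

from . import align, chem, model
from .model import Dataset

DEFAULT_FP_LENGTH = 2048
DEFAULT_FP_RADIUS = 3
DEFAULT_FP_SEED = 42


@dataclass(frozen=True)
class DatasetStats:
    n_active: int
    n_retired: int
    n_rules: int
    n_examples: int
    n_datapoints: int
    pct_mibig: Optional[int]
    pct_rhea: Optional[int]
    pct_neither: Optional[int]
    taxon_rollup: Optional[dict[str, int]] = None

    def to_tsv(self) -> str:
        rows = [("n_active", self.n_active), ("n_retired", self.n_retired),
                ("n_rules", self.n_rules), ("n_examples", self.n_examples),
                ("n_datapoints", self.n_datapoints),
                ("pct_mibig", _na(self.pct_mibig)),
                ("pct_rhea", _na(self.pct_rhea)),
                ("pct_neither", _na(self.pct_neither))]
        if self.taxon_rollup is not None:
            rows.extend((f"taxon:{k}", v) for k, v in sorted(self.taxon_rollup.items()))
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


def _na(v):
    return "NA" if v is None else v


def _pct(count: int, total: int) -> int:
    """Percentage rounded half-up to integer."""
    return int((Decimal(100 * count) / Decimal(total))
               .quantize(Decimal(1), rounding=ROUND_HALF_UP))


def compute_stats(dataset: Dataset,
                  lineages: Optional[dict[str, str]] = None) -> DatasetStats:
    """Counts and coverage percentages over the *active* entries.

    Coverage: an entry counts for MIBiG if its enzyme has a MIBiG id, for
    Rhea if any of its reactions has a Rhea id, and for "neither" if it has
    neither. A data point is a leaf key-value pair excluding bookkeeping
    metadata (status, changelog). Percentages are reported as None (rendered
    ``NA``) for an empty dataset.
    """
    active = dataset.active()
    n_active = len(active)
    n_retired = len(dataset) - n_active
    n_rules = sum(len(e.reactions) for e in active)
    n_examples = sum(len(r.examples) for e in active for r in e.reactions)
    n_datapoints = sum(model.count_data_points(e) for e in active)
    if n_active == 0:
        pct_mibig = pct_rhea = pct_neither = None
    else:
        n_mibig = sum(1 for e in active if e.enzyme.mibig_id)
        n_rhea = sum(1 for e in active if any(r.rhea_id for r in e.reactions))
        n_neither = sum(1 for e in active
                        if not e.enzyme.mibig_id and not any(r.rhea_id for r in e.reactions))
        pct_mibig = _pct(n_mibig, n_active)
        pct_rhea = _pct(n_rhea, n_active)
        pct_neither = _pct(n_neither, n_active)
    rollup = None
    if lineages is not None:
        rollup = {}
        for e in active:
            lineage = lineages.get(e.accession, "unknown")
            rollup[lineage] = rollup.get(lineage, 0) + 1
    return DatasetStats(n_active, n_retired, n_rules, n_examples, n_datapoints,
                        pct_mibig, pct_rhea, pct_neither, rollup)


@dataclass(frozen=True)
class FingerprintParams:
    radius: int = DEFAULT_FP_RADIUS
    length: int = DEFAULT_FP_LENGTH
    seed: int = DEFAULT_FP_SEED


@dataclass(frozen=True)
class ReactionFingerprint:
    bits: np.ndarray  # bool array of shape (length,)
    params: FingerprintParams

    def __post_init__(self):
        self.bits.setflags(write=False)

    @property
    def on_bits(self) -> frozenset[int]:
        return frozenset(int(i) for i in np.flatnonzero(self.bits))

    def jaccard_distance(self, other: "ReactionFingerprint") -> float:
        a, b = self.bits, other.bits
        union = int(np.logical_or(a, b).sum())
        if union == 0:
            return 0.0
        inter = int(np.logical_and(a, b).sum())
        return 1.0 - inter / union


def _shingles(smiles: str, radius: int) -> Counter:
    """Multiset of circular substructure identifiers up to *radius* bonds."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise chem.ChemistryError(f"unparsable SMILES for fingerprinting: {smiles!r}")
    out: Counter = Counter()
    for idx in range(mol.GetNumAtoms()):
        atom = mol.GetAtomWithIdx(idx)
        out[f"{atom.GetSymbol()};D{atom.GetDegree()};H{atom.GetTotalNumHs()}"] += 1
        for r in range(1, radius + 1):
            bonds = Chem.FindAtomEnvironmentOfRadiusN(mol, r, idx, useHs=False)
            if not bonds:
                break
            atoms = {idx}
            for b in bonds:
                bond = mol.GetBondWithIdx(b)
                atoms.add(bond.GetBeginAtomIdx())
                atoms.add(bond.GetEndAtomIdx())
            out[Chem.MolFragmentToSmiles(mol, atomsToUse=sorted(atoms),
                                         bondsToUse=list(bonds),
                                         canonical=True)] += 1
    return out


def _hash_identifier(identifier: str, seed: int, length: int) -> int:
    digest = hashlib.blake2b(identifier.encode("utf-8"),
                             digest_size=8,
                             key=str(seed).encode("utf-8")).digest()
    return int.from_bytes(digest, "big") % length


def reaction_symmetric_difference(substrate: str, products: list[str],
                                  radius: int = DEFAULT_FP_RADIUS) -> Counter:
    """The raw identifier multiset surviving the reactant/product symmetric
    difference — what the fingerprint bits encode, before hashing."""
    left = _shingles(substrate, radius)
    right: Counter = Counter()
    for p in products:
        right += _shingles(p, radius)
    diff = Counter()
    for key in set(left) | set(right):
        d = abs(left.get(key, 0) - right.get(key, 0))
        if d:
            diff[key] = d
    return diff


def reaction_fingerprint(substrate: str, products: list[str],
                         params: FingerprintParams = FingerprintParams()
                         ) -> ReactionFingerprint:
    """Differential fingerprint of one reaction (deterministic for fixed
    reaction and params; identity reactions give the zero vector)."""
    diff = reaction_symmetric_difference(substrate, products, params.radius)
    bits = np.zeros(params.length, dtype=bool)
    for identifier in diff:
        bits[_hash_identifier(identifier, params.seed, params.length)] = True
    return ReactionFingerprint(bits=bits, params=params)


@dataclass
class SimilarityGraph:
    """Undirected, self-loop-free graph over entry accessions."""

    graph: nx.Graph
    orphan_fraction: float
    node_labels: dict[str, str] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return sorted((min(u, v), max(u, v), d["weight"])
                      for u, v, d in self.graph.edges(data=True))

    def to_edge_tsv(self) -> str:
        lines = ["source\ttarget\tweight"]
        lines.extend(f"{u}\t{v}\t{w:g}" for u, v, w in self.edges)
        return "\n".join(lines) + "\n"

    def write_graphml(self, path) -> None:
        g = self.graph.copy()
        for node, label in self.node_labels.items():
            if node in g:
                g.nodes[node]["label"] = label
        nx.write_graphml(g, path)


def _make_graph(names: list[str], edges: set[tuple[int, int]],
                weights: dict[tuple[int, int], float],
                labels: Optional[dict[str, str]]) -> SimilarityGraph:
    g = nx.Graph()
    g.add_nodes_from(names)
    for i, j in edges:
        g.add_edge(names[i], names[j], weight=weights[(i, j)])
    orphans = sum(1 for n in g.nodes if g.degree(n) == 0)
    frac = orphans / g.number_of_nodes() if g.number_of_nodes() else 0.0
    return SimilarityGraph(graph=g, orphan_fraction=frac,
                           node_labels=labels or {})


def knn_reaction_map(fingerprints: list[ReactionFingerprint], k: int,
                     names: Optional[list[str]] = None,
                     labels: Optional[dict[str, str]] = None) -> SimilarityGraph:
    """k-nearest-neighbour graph under Jaccard distance.

    Each node is connected to its *k* nearest neighbours; mutual edges are
    deduplicated and exact distance ties are broken by node (accession)
    order. With fewer than 2 fingerprints the graph has no edges.
    """
    n = len(fingerprints)
    if names is None:
        names = [f"fp{i:04d}" for i in range(n)]
    if n >= 2 and not (1 <= k < n):
        raise ValueError(f"k must satisfy 1 <= k < n (k={k}, n={n})")
    edges: set[tuple[int, int]] = set()
    weights: dict[tuple[int, int], float] = {}
    if n >= 2:
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = fingerprints[i].jaccard_distance(fingerprints[j])
                dist[i, j] = dist[j, i] = d
        order = np.argsort(names)  # tie-break key
        rank = np.empty(n, dtype=int)
        rank[order] = np.arange(n)
        for i in range(n):
            neighbours = sorted((dist[i, j], rank[j], j) for j in range(n) if j != i)
            for d, _, j in neighbours[:k]:
                e = (min(i, j), max(i, j))
                edges.add(e)
                weights[e] = dist[i, j]
    return _make_graph(names, edges, weights, labels)


def sequence_similarity_network(sequences: dict[str, str],
                                identity_threshold: float,
                                labels: Optional[dict[str, str]] = None
                                ) -> SimilarityGraph:
    """All-pairs local-alignment SSN.

    An edge connects two entries iff the identity of their best local
    alignment (BLOSUM62, gap open 11 / extend 1; identity over alignment
    columns, gaps counted) reaches the threshold. Nodes with no edges are
    orphans; ``orphan_fraction`` is their share of all nodes.
    """
    if len(sequences) < 2:
        raise ValueError("an SSN needs at least 2 sequences")
    names = sorted(sequences)
    edges: set[tuple[int, int]] = set()
    weights: dict[tuple[int, int], float] = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            identity, _ = align.local_identity(sequences[names[i]], sequences[names[j]])
            if identity >= identity_threshold:
                edges.add((i, j))
                weights[(i, j)] = round(identity, 6)
    return _make_graph(names, edges, weights, labels)


def sample_entry_fingerprints(dataset: Dataset,
                              params: FingerprintParams = FingerprintParams()
                              ) -> tuple[list[ReactionFingerprint], list[str]]:
    """One fingerprint per active entry, from its first rule's first example."""
    fps, names = [], []
    for entry in dataset.active():
        ex = entry.reactions[0].examples[0]
        fps.append(reaction_fingerprint(ex.substrate, list(ex.products), params))
        names.append(entry.accession)
    return fps, names
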