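"""In-silico biosynthesis: consecutive rule application and pathway search.

A cascade applies the reaction rules of a sequence of entries to a precursor,
one step at a time, recording for every step the substrate, the chosen
product, the full product tuple and the atoms modified by the transformation
(the atoms of the product outside its maximum common substructure with the
substrate — the "area of modification").

When a rule produces several product tuples (regio-ambiguity), the branch
policy decides: ``first-canonical`` deterministically takes the
lexicographically smallest tuple; ``all-branches`` explores every tuple. When
the chosen tuple contains several molecules (e.g. proteolytic cleavage), the
*largest* fragment (heavy-atom count, ties by canonical SMILES) is carried
forward as the next intermediate; the full tuple stays on record in the step.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import rdFMCS

from . import chem
from .errors import CascadeError
from .model import Entry

# MCS is NP-hard; above this many combined heavy atoms (or on MCS failure)
# we fall back to a canonical atom-environment multiset diff.
MCS_ATOM_CAP = 160
MCS_TIMEOUT_S = 10


@dataclass(frozen=True)
class Step:
    entry_accession: str
    rule_index: int
    substrate: str
    product: str
    product_tuple: tuple[str, ...]
    modified_atoms: frozenset[int]

    def to_dict(self) -> dict:
        return {
            "entry_accession": self.entry_accession,
            "rule_index": self.rule_index,
            "substrate": self.substrate,
            "product": self.product,
            "product_tuple": list(self.product_tuple),
            "modified_atoms": sorted(self.modified_atoms),
        }


@dataclass
class Trajectory:
    precursor: str
    steps: list[Step] = field(default_factory=list)

    @property
    def final_product(self) -> str:
        return self.steps[-1].product if self.steps else self.precursor

    @property
    def accession_sequence(self) -> tuple[str, ...]:
        return tuple(s.entry_accession for s in self.steps)

    def serialize(self) -> str:
        return json.dumps(
            {"precursor": self.precursor,
             "steps": [s.to_dict() for s in self.steps],
             "final_product": self.final_product},
            indent=2, ensure_ascii=False) + "\n"


def _env_hash(mol: Chem.Mol, idx: int, radius: int = 2) -> str:
    """Canonical identifier of an atom's neighbourhood up to *radius* bonds."""
    if radius == 0 or mol.GetNumAtoms() == 1:
        a = mol.GetAtomWithIdx(idx)
        return f"{a.GetSymbol()}|{a.GetDegree()}|{a.GetTotalNumHs()}"
    bonds = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, idx, useHs=False)
    if not bonds:
        return _env_hash(mol, idx, 0)
    atoms = {idx}
    for b in bonds:
        bond = mol.GetBondWithIdx(b)
        atoms.add(bond.GetBeginAtomIdx())
        atoms.add(bond.GetEndAtomIdx())
    return Chem.MolFragmentToSmiles(mol, atomsToUse=sorted(atoms),
                                    bondsToUse=list(bonds), canonical=True,
                                    rootedAtAtom=idx)


def _env_diff(before: Chem.Mol, after: Chem.Mol) -> frozenset[int]:
    """Fallback modified-atom set: atoms of *after* whose radius-2 environment
    occurs more often in *after* than in *before*."""
    from collections import Counter
    before_envs = Counter(_env_hash(before, i) for i in range(before.GetNumAtoms()))
    budget = dict(before_envs)
    changed = set()
    for i in range(after.GetNumAtoms()):
        h = _env_hash(after, i)
        if budget.get(h, 0) > 0:
            budget[h] -= 1
        else:
            changed.add(i)
    return frozenset(changed)


def _stereo_diff(before: Chem.Mol, after: Chem.Mol) -> frozenset[int] | None:
    """For pure stereo changes: the stereocenters of *after* whose parity
    differs from the matched atom of *before*; None if no atom map is found.

    Both molecules are matched onto their shared flat (stereo-stripped)
    skeleton; chiral tags are then compared atom by atom through that map.
    """
    flat = Chem.MolFromSmiles(chem.strip_stereo(Chem.MolToSmiles(before)))
    map_b = before.GetSubstructMatch(flat, useChirality=False)
    map_a = after.GetSubstructMatch(flat, useChirality=False)
    if len(map_b) != before.GetNumAtoms() or len(map_a) != after.GetNumAtoms():
        return None
    changed = set()
    for k in range(flat.GetNumAtoms()):
        tag_b = before.GetAtomWithIdx(map_b[k]).GetChiralTag()
        tag_a = after.GetAtomWithIdx(map_a[k]).GetChiralTag()
        if tag_b != tag_a:
            changed.add(map_a[k])
    return frozenset(changed)


def atom_diff(before: str, after: str) -> frozenset[int]:
    """Atom indices of *after* outside the maximum common substructure with
    *before*; for a pure stereo change, the stereocenters whose parity changed.
    """
    b = Chem.MolFromSmiles(before)
    a = Chem.MolFromSmiles(after)
    if b is None or a is None:
        raise chem.ChemistryError("atom_diff requires two parsable SMILES")
    if Chem.MolToSmiles(a) == Chem.MolToSmiles(b):
        return frozenset()
    if chem.strip_stereo(before) == chem.strip_stereo(after):
        stereo = _stereo_diff(b, a)
        if stereo is not None:
            return stereo
    if b.GetNumAtoms() + a.GetNumAtoms() <= MCS_ATOM_CAP:
        try:
            res = rdFMCS.FindMCS([b, a], timeout=MCS_TIMEOUT_S)
            if not res.canceled and res.numAtoms > 0:
                q = Chem.MolFromSmarts(res.smartsString)
                hit_a = a.GetSubstructMatch(q)
                hit_b = b.GetSubstructMatch(q)
                if hit_a and hit_b:
                    changed = set(range(a.GetNumAtoms())) - set(hit_a)
                    # attachment points: matched atoms whose H count or charge
                    # changed are part of the modified area
                    for k in range(q.GetNumAtoms()):
                        atom_a = a.GetAtomWithIdx(hit_a[k])
                        atom_b = b.GetAtomWithIdx(hit_b[k])
                        if (atom_a.GetTotalNumHs() != atom_b.GetTotalNumHs()
                                or atom_a.GetFormalCharge() != atom_b.GetFormalCharge()):
                            changed.add(hit_a[k])
                    return frozenset(changed)
        except Exception:  # pragma: no cover - MCS robustness guard
            pass
    return _env_diff(b, a)


RuleRef = tuple[Entry, int]


def _carry_forward(tup: tuple[str, ...]) -> str:
    """The intermediate carried into the next step: largest fragment."""
    return max(tup, key=lambda s: (Chem.MolFromSmiles(s).GetNumHeavyAtoms(), s))


def _apply(entry: Entry, rule_index: int, substrate: str) -> chem.ProductSet:
    rule = chem.standardize_rule(entry.reactions[rule_index].smarts)
    return chem.apply_rule(rule, substrate)


def run_cascade(precursor: str, rules: list[RuleRef],
                selection: str = "first-canonical",
                compute_diffs: bool = True) -> Trajectory | list[Trajectory]:
    """Apply entry rules consecutively to a precursor.

    With ``selection='first-canonical'`` returns one :class:`Trajectory`;
    with ``'all-branches'`` returns the list of trajectories over every
    product-tuple choice at every step. A rule that does not recognize its
    intermediate raises :class:`CascadeError` naming the failing step, the
    intermediate and the rule's reactant template.
    """
    if selection not in {"first-canonical", "all-branches"}:
        raise ValueError(f"unknown branch policy {selection!r}")
    start = chem.canonicalize(precursor)

    def extend(traj: Trajectory, depth: int) -> list[Trajectory]:
        if depth == len(rules):
            return [traj]
        entry, ridx = rules[depth]
        current = traj.final_product
        products = _apply(entry, ridx, current)
        if not products:
            raise CascadeError(
                f"step {depth + 1} ({entry.accession} rule {ridx}) does not recognize "
                f"intermediate {current}",
                step_index=depth, intermediate=current,
                template=entry.reactions[ridx].smarts.split(">>")[0])
        tuples = sorted(products.tuples)
        if selection == "first-canonical":
            tuples = tuples[:1]
        out = []
        for tup in tuples:
            product = _carry_forward(tup)
            diff = atom_diff(current, product) if compute_diffs else frozenset()
            step = Step(entry.accession, ridx, current, product, tup, diff)
            out.extend(extend(Trajectory(start, traj.steps + [step]), depth + 1))
        return out

    results = extend(Trajectory(start), 0)
    return results[0] if selection == "first-canonical" else results


def search_pathway(precursor: str, rule_pool: list[RuleRef], target: str,
                   max_depth: int, limit: int | None = None,
                   max_expansions: int = 200_000) -> list[Trajectory]:
    """Breadth-first search for rule orderings that reach *target*.

    Each pool rule is usable at most once, unless its :class:`ReactionRule`
    is flagged ``iterative``. States are deduplicated by (canonical SMILES,
    used-rule multiset); stereo differences are distinct states. Returns all
    minimal-length trajectories reaching the target's canonical form, sorted
    lexicographically by accession sequence (optionally truncated to *limit*).
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    start = chem.canonicalize(precursor)
    goal = chem.canonicalize(target)
    if start == goal:
        return [Trajectory(start)]

    State = tuple[str, frozenset[int]]
    start_node: State = (start, frozenset())
    depth_of: dict[State, int] = {start_node: 0}
    # shortest-path DAG: child -> [(parent, accession, rule_index, tuple)]
    parents: dict[State, list[tuple[State, str, int, tuple[str, ...]]]] = {}
    apply_cache: dict[tuple[int, str], chem.ProductSet] = {}
    standardized = [chem.standardize_rule(e.reactions[r].smarts)
                    for e, r in rule_pool]

    frontier: list[State] = [start_node]
    goal_nodes: list[State] = []
    expansions = 0
    for depth in range(1, max_depth + 1):
        next_frontier: list[State] = []
        for node in frontier:
            state, used = node
            for pool_idx, (entry, ridx) in enumerate(rule_pool):
                iterative = entry.reactions[ridx].iterative
                if pool_idx in used and not iterative:
                    continue
                key = (pool_idx, state)
                if key not in apply_cache:
                    expansions += 1
                    if expansions > max_expansions:
                        raise CascadeError(
                            f"pathway search exceeded {max_expansions} rule applications")
                    apply_cache[key] = chem.apply_rule(standardized[pool_idx], state)
                for tup in sorted(apply_cache[key].tuples):
                    product = _carry_forward(tup)
                    new_used = used if iterative else used | {pool_idx}
                    child: State = (product, new_used)
                    prev = depth_of.get(child)
                    if prev is not None and prev < depth:
                        continue  # already reachable by a shorter route
                    if prev is None:
                        depth_of[child] = depth
                        if product == goal:
                            goal_nodes.append(child)
                        else:
                            next_frontier.append(child)
                    parents.setdefault(child, []).append(
                        (node, entry.accession, ridx, tup))
        if goal_nodes:
            break
        frontier = next_frontier
        if not frontier:
            break
    if not goal_nodes:
        return []

    # mark every node lying on a shortest path to a goal, then enumerate the
    # trajectories forward in lexicographic order of accession sequences
    on_path: set[State] = set(goal_nodes)
    stack = list(goal_nodes)
    while stack:
        node = stack.pop()
        for parent, *_ in parents.get(node, []):
            if parent not in on_path:
                on_path.add(parent)
                stack.append(parent)
    children: dict[State, list[tuple[str, int, tuple[str, ...], State]]] = {}
    for child, links in parents.items():
        if child not in on_path:
            continue
        for parent, accession, ridx, tup in links:
            if parent in on_path and depth_of[child] == depth_of[parent] + 1:
                children.setdefault(parent, []).append((accession, ridx, tup, child))
    for lst in children.values():
        lst.sort()

    hits: list[Trajectory] = []

    def walk(node: State, steps: list[Step]) -> bool:
        if node[0] == goal and len(steps) == depth_of[node]:
            hits.append(Trajectory(start, list(steps)))
            return limit is not None and len(hits) >= limit
        for accession, ridx, tup, child in children.get(node, []):
            step = Step(accession, ridx, node[0], child[0], tup, frozenset())
            if walk(child, steps + [step]):
                return True
        return False

    walk(start_node, [])
    hits.sort(key=lambda t: t.accession_sequence)
    return hits[:limit] if limit is not None else hits
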