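"""Fragmentation of molecules into scaffold / variable-part splits.

A matched molecular pair is two molecules that share a scaffold and differ
only in a small "variable" fragment.  This module enumerates the candidate
splits: every way of cutting 1-3 acyclic single bonds such that the variable
part is a single connected fragment carrying all attachment points, is small
(at most ``max_variable_atoms`` heavy atoms, default 10), and is strictly
smaller than the unaffected scaffold.  Hydrogen positions are treated as
zero-atom variable fragments, so hydrogen-to-group replacements are first
class transformations.

Fragment notation is SMILES with atom-map-labelled wildcard attachment
points (``[*:1]``, ``[*:2]``, ``[*:3]``); labels are assigned from the
canonical atom ranking of the scaffold so that the same chemical split
always yields byte-identical keys.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations, permutations

from rdkit import Chem

from .chem import ChemError, MoleculeRecord, standardize

__all__ = [
    "FragmentKey",
    "FragmentationRecord",
    "breakable_bonds",
    "enumerate_fragmentations",
    "canonical_fragment",
    "canonical_pair",
    "reassemble",
    "MAX_VARIABLE_ATOMS",
    "MAX_BREAKABLE_BONDS",
]

logger = logging.getLogger(__name__)

MAX_VARIABLE_ATOMS = 10
MAX_BREAKABLE_BONDS = 40

HYDROGEN_FRAGMENT = "[H][*:1]"  # canonical notation of the explicit-H variable part


@dataclass(frozen=True)
class FragmentKey:
    """Canonical key of a molecular fragment with labelled attachment points."""

    notation: str
    attachment_count: int
    atom_count: int  # heavy atoms, excluding wildcard attachment atoms


@dataclass(frozen=True)
class FragmentationRecord:
    """One scaffold/variable split of one molecule."""

    molecule_id: str
    scaffold: FragmentKey
    variable: FragmentKey
    n_cuts: int


def _heavy_count(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def _fragment_key(mol: Chem.Mol) -> FragmentKey:
    n_att = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 0)
    return FragmentKey(
        notation=Chem.MolToSmiles(mol),
        attachment_count=n_att,
        atom_count=_heavy_count(mol),
    )


def breakable_bonds(mol: MoleculeRecord | Chem.Mol) -> list[int]:
    """Indices of all acyclic single bonds between two heavy atoms.

    Ring bonds and multiple-order bonds are never cut.
    """
    rdmol = mol.mol() if isinstance(mol, MoleculeRecord) else mol
    out = []
    for bond in rdmol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        if bond.GetBeginAtom().GetAtomicNum() <= 1 or bond.GetEndAtom().GetAtomicNum() <= 1:
            continue
        out.append(bond.GetIdx())
    return out


def _label_by_scaffold_ranks(scaffold: Chem.RWMol, variable: Chem.RWMol) -> None:
    """Assign attachment labels 1..k from the canonical atom ranking of the
    scaffold; the variable fragment inherits the matching labels through the
    cut-bond pairing (stored as dummy-atom isotopes, cleared here)."""
    pair_id = {}
    for atom in scaffold.GetAtoms():
        if atom.GetAtomicNum() == 0:
            pair_id[atom.GetIdx()] = atom.GetIsotope()
            atom.SetIsotope(0)
    var_dummy = {}
    for atom in variable.GetAtoms():
        if atom.GetAtomicNum() == 0:
            var_dummy[atom.GetIsotope()] = atom.GetIdx()
            atom.SetIsotope(0)
    ranks = list(Chem.CanonicalRankAtoms(scaffold, breakTies=True))
    for label, s_idx in enumerate(sorted(pair_id, key=lambda i: ranks[i]), start=1):
        scaffold.GetAtomWithIdx(s_idx).SetAtomMapNum(label)
        variable.GetAtomWithIdx(var_dummy[pair_id[s_idx]]).SetAtomMapNum(label)


def _split_on_bonds(rdmol: Chem.Mol, bond_ids: tuple[int, ...]) -> tuple[Chem.Mol, Chem.Mol] | None:
    """Cut the given bonds and return (scaffold, variable) RDKit mols with
    labelled attachment points, or None if the cut-set is not a valid split.

    Cutting k acyclic bonds yields k+1 connected components.  A valid split
    has exactly one component touching all k cuts (the variable part); the
    scaffold is everything else, kept as one possibly multi-component
    fragment for k >= 2.
    """
    k = len(bond_ids)
    frag = Chem.FragmentOnBonds(
        rdmol, list(bond_ids), addDummies=True, dummyLabels=[(i + 1, i + 1) for i in range(k)]
    )
    pieces = Chem.GetMolFrags(frag)
    # locate the component holding all k attachment points; for a single cut
    # both components qualify and the smaller one is the variable part
    candidates = []
    for piece in pieces:
        n_dummies = sum(1 for i in piece if frag.GetAtomWithIdx(i).GetAtomicNum() == 0)
        if n_dummies == k:
            candidates.append(piece)
    if not candidates:
        return None
    def piece_heavy(piece):
        return sum(1 for i in piece if frag.GetAtomWithIdx(i).GetAtomicNum() > 1)
    variable_piece = set(min(candidates, key=piece_heavy))
    var = Chem.RWMol(frag)
    scaf = Chem.RWMol(frag)
    for idx in sorted(range(frag.GetNumAtoms()), reverse=True):
        if idx in variable_piece:
            scaf.RemoveAtom(idx)
        else:
            var.RemoveAtom(idx)
    try:
        Chem.SanitizeMol(scaf)
        Chem.SanitizeMol(var)
    except Exception:  # pragma: no cover - defensive; cuts of sane mols sanitize
        return None
    _label_by_scaffold_ranks(scaf, var)
    return scaf.GetMol(), var.GetMol()


def _hydrogen_records(rdmol: Chem.Mol, molecule_id: str) -> list[FragmentationRecord]:
    """One single-cut record per symmetry-distinct hydrogen position, with the
    explicit hydrogen as the (zero-atom) variable fragment."""
    ranks = list(Chem.CanonicalRankAtoms(rdmol, breakTies=False))
    seen: set[int] = set()
    total_heavy = _heavy_count(rdmol)
    records = []
    for atom in rdmol.GetAtoms():
        if atom.GetTotalNumHs() == 0 or ranks[atom.GetIdx()] in seen:
            continue
        seen.add(ranks[atom.GetIdx()])
        molh = Chem.AddHs(rdmol)
        for nbr in molh.GetAtomWithIdx(atom.GetIdx()).GetNeighbors():
            if nbr.GetAtomicNum() == 1:
                nbr.SetAtomicNum(0)
                nbr.SetAtomMapNum(1)
                break
        scaf = Chem.RemoveHs(molh)
        Chem.SanitizeMol(scaf)
        records.append(
            FragmentationRecord(
                molecule_id=molecule_id,
                scaffold=_fragment_key(scaf),
                variable=FragmentKey(HYDROGEN_FRAGMENT, 1, 0),
                n_cuts=1,
            )
        )
    return records


def enumerate_fragmentations(
    mol: MoleculeRecord,
    max_cuts: int = 3,
    max_variable_atoms: int = MAX_VARIABLE_ATOMS,
    max_breakable_bonds: int = MAX_BREAKABLE_BONDS,
    include_hydrogen: bool = True,
) -> list[FragmentationRecord]:
    """Enumerate all valid scaffold/variable splits of a molecule.

    A split is valid when the variable part is connected, carries all
    attachment points, has at most ``max_variable_atoms`` heavy atoms, and
    has strictly fewer heavy atoms than the scaffold.  Molecules with more
    than ``max_breakable_bonds`` breakable bonds are skipped entirely (with a
    logged warning) to bound the combinatorial cost.  Records are
    deduplicated on (scaffold, variable) notation.
    """
    if not 1 <= max_cuts <= 3:
        raise ChemError("max_cuts must be between 1 and 3")
    rdmol = mol.mol()
    bonds = breakable_bonds(rdmol)
    if len(bonds) > max_breakable_bonds:
        logger.warning(
            "skipping %s: %d breakable bonds exceeds the limit of %d",
            mol.id, len(bonds), max_breakable_bonds,
        )
        return []
    records: dict[tuple[str, str], FragmentationRecord] = {}
    for k in range(1, max_cuts + 1):
        for bond_ids in combinations(bonds, k):
            split = _split_on_bonds(rdmol, bond_ids)
            if split is None:
                continue
            scaf, var = split
            var_atoms = _heavy_count(var)
            scaf_atoms = _heavy_count(scaf)
            if var_atoms > max_variable_atoms or var_atoms >= scaf_atoms:
                continue
            rec = FragmentationRecord(
                molecule_id=mol.id,
                scaffold=_fragment_key(scaf),
                variable=_fragment_key(var),
                n_cuts=k,
            )
            records.setdefault((rec.scaffold.notation, rec.variable.notation), rec)
    if include_hydrogen:
        for rec in _hydrogen_records(rdmol, mol.id):
            records.setdefault((rec.scaffold.notation, rec.variable.notation), rec)
    return list(records.values())


def _parse_fragment(notation: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(notation, sanitize=False)
    if mol is None:
        raise ChemError(f"cannot parse fragment {notation!r}")
    Chem.SanitizeMol(mol)
    return mol


def _relabel(mol: Chem.Mol, mapping: dict[int, int]) -> Chem.Mol:
    out = Chem.RWMol(mol)
    for atom in out.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomMapNum(mapping[atom.GetAtomMapNum()])
    return out.GetMol()


def _label_permutations(k: int):
    for perm in permutations(range(1, k + 1)):
        yield {i + 1: perm[i] for i in range(k)}


def canonical_fragment(raw_fragment: str) -> FragmentKey:
    """Canonical key of a standalone fragment with 1-3 attachment wildcards.

    Attachment labels are renumbered to the permutation giving the
    lexicographically smallest canonical SMILES, so chemically identical
    fragments entered with different labellings collapse to one notation.
    """
    mol = _parse_fragment(raw_fragment)
    labels = sorted(
        a.GetAtomMapNum() for a in mol.GetAtoms() if a.GetAtomicNum() == 0
    )
    k = len(labels)
    if not 1 <= k <= 3:
        raise ChemError(f"fragment must have 1-3 attachment points, got {k}")
    if labels != list(range(1, k + 1)):
        # normalize arbitrary incoming labels to 1..k first
        remap = {old: i + 1 for i, old in enumerate(labels)}
        mol = _relabel(mol, remap)
    best = min(
        Chem.MolToSmiles(_relabel(mol, m)) for m in _label_permutations(k)
    )
    canon = _parse_fragment(best)
    return _fragment_key(canon)


def canonical_pair(frag_a: str, frag_b: str) -> tuple[FragmentKey, FragmentKey, int]:
    """Jointly canonicalize the two variable fragments of a matched pair.

    The two fragments share attachment labels (both bind the same scaffold
    positions), so they must be relabelled with the *same* permutation.  The
    result is ordered so ``left.notation <= right.notation``; the returned
    sign is +1 when (frag_a, frag_b) maps to (left, right) and -1 when the
    orientation was swapped.
    """
    ma, mb = _parse_fragment(frag_a), _parse_fragment(frag_b)
    k = sum(1 for a in ma.GetAtoms() if a.GetAtomicNum() == 0)
    kb = sum(1 for a in mb.GetAtoms() if a.GetAtomicNum() == 0)
    if k != kb:
        raise ChemError("paired fragments must have the same attachment count")
    best = None
    for mapping in _label_permutations(k):
        sa = Chem.MolToSmiles(_relabel(ma, mapping))
        sb = Chem.MolToSmiles(_relabel(mb, mapping))
        if sa <= sb:
            cand = (sa, sb, 1)
        else:
            cand = (sb, sa, -1)
        if best is None or cand[:2] < best[:2]:
            best = cand
    left, right, sign = best
    lk = _fragment_key(_parse_fragment(left))
    rk = _fragment_key(_parse_fragment(right))
    return lk, rk, sign


def reassemble(scaffold: str | FragmentKey, variable: str | FragmentKey) -> MoleculeRecord:
    """Rejoin a scaffold and a variable fragment at matching attachment labels
    and standardize the result."""
    s = scaffold.notation if isinstance(scaffold, FragmentKey) else scaffold
    v = variable.notation if isinstance(variable, FragmentKey) else variable
    combined = Chem.CombineMols(_parse_fragment(s), _parse_fragment(v))
    try:
        joined = Chem.molzip(combined)
        joined = Chem.RemoveHs(joined)
        Chem.SanitizeMol(joined)
    except Exception as exc:
        raise ChemError(f"cannot reassemble {s!r} + {v!r}: {exc}") from exc
    return standardize(Chem.MolToSmiles(joined))
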