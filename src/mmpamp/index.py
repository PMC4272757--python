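"""Scaffold-keyed index, matched-pair identification and transformation
extraction.

The index maps each scaffold key to the molecules that produce it together
with their variable fragments.  Two molecules sharing a scaffold entry with
distinct variable fragments form a matched molecular pair; pairs realizing
the same fragment replacement (after joint canonical relabelling and
orientation) aggregate into a transformation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

from .chem import EndpointData, MoleculeRecord, fingerprint, tanimoto
from .config import AnalysisConfig
from .fragment import FragmentKey, canonical_pair, enumerate_fragmentations

__all__ = [
    "PairEndpointData",
    "PairDelta",
    "MatchedPair",
    "Transformation",
    "PairIndex",
    "build_index",
    "find_matched_pairs",
    "extract_transformations",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairDelta:
    """Effect of one pair on one endpoint, in the pair's (a -> b) direction.

    For continuous endpoints ``delta = value_b - value_a`` (log units); for
    binary endpoints the values are the activity labels before/after.  The
    provenance is experimental only when both sides are experimental; the
    uncertainty combines both sides (quadrature for continuous values,
    per-side flip probabilities for labels).
    """

    kind: str
    value_a: float | str
    value_b: float | str
    provenance: str
    uncertainty_a: float = 0.0
    uncertainty_b: float = 0.0

    @property
    def delta(self) -> float:
        if self.kind != "continuous":
            raise TypeError("delta is defined for continuous endpoints only")
        return self.value_b - self.value_a

    @property
    def uncertainty(self) -> float:
        return (self.uncertainty_a**2 + self.uncertainty_b**2) ** 0.5


@dataclass
class PairEndpointData:
    """Per-side endpoint values of a pair, from which experimental-only,
    predicted-only and effective (experimental-preferred) deltas derive."""

    a: EndpointData
    b: EndpointData

    def _make(self, va, vb) -> PairDelta | None:
        if va is None or vb is None:
            return None
        prov = (
            "experimental"
            if va.source == "experimental" and vb.source == "experimental"
            else "predicted"
        )
        return PairDelta(
            kind=va.kind,
            value_a=va.value,
            value_b=vb.value,
            provenance=prov,
            uncertainty_a=va.uncertainty,
            uncertainty_b=vb.uncertainty,
        )

    def effective(self, include_out_of_domain: bool = False) -> PairDelta | None:
        return self._make(
            self.a.effective(include_out_of_domain), self.b.effective(include_out_of_domain)
        )

    def experimental(self) -> PairDelta | None:
        return self._make(self.a.experimental, self.b.experimental)

    def predicted(self) -> PairDelta | None:
        return self._make(self.a.predicted, self.b.predicted)


@dataclass
class MatchedPair:
    """Two molecules sharing a scaffold, differing in the variable fragment.

    Stored once per (molecule pair, scaffold) with a deterministic
    orientation: ``frag_a.notation < frag_b.notation``.  ``pair_group``
    identifies the unordered molecule pair, so one molecule pair matched via
    several (nested) scaffolds can be deduplicated downstream.
    """

    mol_a: str
    mol_b: str
    scaffold: FragmentKey
    frag_a: FragmentKey
    frag_b: FragmentKey
    n_cuts: int
    similarity: float
    pair_group: tuple[str, str]
    deltas: dict[str, PairEndpointData] = field(default_factory=dict)


@dataclass
class Transformation:
    """A canonical directed fragment replacement aggregating matched pairs.

    ``left.notation <= right.notation``; each member pair carries the sign
    of its own direction relative to left -> right.
    """

    id: str
    left: FragmentKey
    right: FragmentKey
    n_cuts: int
    pairs: list[tuple[MatchedPair, int]] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def smirks(self) -> str:
        return f"{self.left.notation}>>{self.right.notation}"


@dataclass
class PairIndex:
    """Mapping scaffold notation -> [(molecule id, variable fragment, n_cuts)]."""

    molecules: dict[str, MoleculeRecord]
    entries: dict[str, list[tuple[str, FragmentKey, int]]]
    aliases: dict[str, str]  # duplicate-structure id -> indexed id
    config: AnalysisConfig


def build_index(mols: list[MoleculeRecord], config: AnalysisConfig | None = None) -> PairIndex:
    """Fragment every unique molecule and build the scaffold-keyed index.

    Duplicate ids raise; duplicate structures (same InChI key) are indexed
    once with the extra ids recorded as aliases.
    """
    config = config or AnalysisConfig()
    molecules: dict[str, MoleculeRecord] = {}
    by_key: dict[str, str] = {}
    aliases: dict[str, str] = {}
    for mol in mols:
        if mol.id in molecules or mol.id in aliases:
            raise ValueError(f"duplicate molecule id {mol.id!r}")
        if mol.unique_key in by_key:
            aliases[mol.id] = by_key[mol.unique_key]
            continue
        by_key[mol.unique_key] = mol.id
        molecules[mol.id] = mol
    entries: dict[str, list[tuple[str, FragmentKey, int]]] = {}
    for mol_id in sorted(molecules):
        mol = molecules[mol_id]
        records = enumerate_fragmentations(
            mol,
            max_cuts=config.max_cuts,
            max_variable_atoms=config.max_variable_atoms,
            max_breakable_bonds=config.max_breakable_bonds,
        )
        for rec in records:
            entries.setdefault(rec.scaffold.notation, []).append(
                (mol_id, rec.variable, rec.n_cuts)
            )
    return PairIndex(molecules=molecules, entries=entries, aliases=aliases, config=config)


def find_matched_pairs(index: PairIndex, min_similarity: float | None = None) -> list[MatchedPair]:
    """All unordered molecule pairs sharing a scaffold with distinct variable
    fragments and whole-molecule Tanimoto similarity >= ``min_similarity``.

    One pair record is emitted per shared scaffold; records for the same
    molecule pair share a ``pair_group`` id.  Output is sorted, hence
    independent of input molecule order.
    """
    cfg = index.config
    if min_similarity is None:
        min_similarity = cfg.min_similarity
    if not 0 <= min_similarity <= 1:
        raise ValueError("min_similarity must lie in [0, 1]")
    fps = {
        mid: fingerprint(m, radius=cfg.fp_radius, n_bits=cfg.fp_bits)
        for mid, m in index.molecules.items()
    }
    pairs: list[MatchedPair] = []
    for scaffold_notation in sorted(index.entries):
        entries = index.entries[scaffold_notation]
        if len(entries) < 2:
            continue
        for (id_a, frag_a, cuts_a), (id_b, frag_b, cuts_b) in combinations(entries, 2):
            if id_a == id_b or frag_a.notation == frag_b.notation:
                continue
            sim = tanimoto(fps[id_a], fps[id_b])
            if sim < min_similarity:
                continue
            # deterministic orientation within the pair record
            if (frag_b.notation, id_b) < (frag_a.notation, id_a):
                id_a, id_b = id_b, id_a
                frag_a, frag_b = frag_b, frag_a
            mol_a, mol_b = index.molecules[id_a], index.molecules[id_b]
            deltas = {}
            for endpoint in set(mol_a.endpoint_values) & set(mol_b.endpoint_values):
                deltas[endpoint] = PairEndpointData(
                    a=mol_a.endpoint_values[endpoint], b=mol_b.endpoint_values[endpoint]
                )
            scaffold_key = FragmentKey(
                notation=scaffold_notation,
                attachment_count=frag_a.attachment_count,
                atom_count=max(
                    index.molecules[id_a].heavy_atom_count - frag_a.atom_count,
                    0,
                ),
            )
            pairs.append(
                MatchedPair(
                    mol_a=id_a,
                    mol_b=id_b,
                    scaffold=scaffold_key,
                    frag_a=frag_a,
                    frag_b=frag_b,
                    n_cuts=cuts_a,
                    similarity=sim,
                    pair_group=tuple(sorted((id_a, id_b))),
                    deltas=deltas,
                )
            )
    return pairs


def extract_transformations(pairs: list[MatchedPair]) -> list[Transformation]:
    """Group pairs by their canonically oriented fragment replacement.

    Pair multiplicity is conserved: every input pair appears in exactly one
    transformation, with sign +1 if its (a -> b) direction matches the
    canonical left -> right direction and -1 otherwise.
    """
    grouped: dict[tuple[str, str, int], Transformation] = {}
    for pair in pairs:
        left, right, sign = canonical_pair(pair.frag_a.notation, pair.frag_b.notation)
        key = (left.notation, right.notation, pair.n_cuts)
        t = grouped.get(key)
        if t is None:
            t = Transformation(
                id=f"{left.notation}>>{right.notation}",
                left=left,
                right=right,
                n_cuts=pair.n_cuts,
            )
            grouped[key] = t
        t.pairs.append((pair, sign))
    return [grouped[k] for k in sorted(grouped)]
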