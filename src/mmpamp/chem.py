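"""Structure standardization, uniqueness keys, fingerprints and similarity.

Every molecule entering the matched-pair machinery passes through
:func:`standardize`, which canonicalizes the SMILES, derives an InChI hash
key for uniqueness tracking, and rejects inputs the pair semantics cannot
handle (unparseable strings, salts/mixtures).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Literal

from rdkit import Chem, RDLogger, rdBase
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "ChemError",
    "ParseError",
    "EndpointValue",
    "EndpointData",
    "MoleculeRecord",
    "Fingerprint",
    "standardize",
    "fingerprint",
    "tanimoto",
]

logger = logging.getLogger(__name__)

# RDKit is chatty on stderr; warnings (e.g. InChI normalization notes) are
# demoted, errors are captured explicitly where we need their text.
RDLogger.DisableLog("rdApp.warning")
RDLogger.DisableLog("rdApp.info")


class ChemError(ValueError):
    """Base class for chemistry-layer failures."""


class ParseError(ChemError):
    """Raised when a structure string cannot be parsed."""


@dataclass(frozen=True)
class EndpointValue:
    """One endpoint measurement or prediction for one molecule.

    ``value`` is a float (log units) for continuous endpoints or one of the
    labels ``"active"``/``"inactive"`` for binary endpoints.  ``uncertainty``
    is the estimated standard error of a continuous prediction, or the
    estimated misclassification probability (in [0, 0.5]) of a binary one.
    Experimental values carry uncertainty 0 and are always in-domain.
    """

    kind: Literal["continuous", "binary"]
    value: float | str
    source: Literal["experimental", "predicted"] = "experimental"
    uncertainty: float = 0.0
    in_domain: bool = True

    def __post_init__(self) -> None:
        if self.kind == "binary" and self.value not in ("active", "inactive"):
            raise ChemError(f"binary endpoint value must be active/inactive, got {self.value!r}")
        if self.uncertainty < 0:
            raise ChemError("uncertainty must be nonnegative")
        if self.source == "experimental" and (self.uncertainty != 0 or not self.in_domain):
            raise ChemError("experimental values must have uncertainty 0 and be in-domain")


@dataclass
class EndpointData:
    """Experimental and/or predicted value of one endpoint on one molecule."""

    experimental: EndpointValue | None = None
    predicted: EndpointValue | None = None

    def effective(self, include_out_of_domain: bool = False) -> EndpointValue | None:
        """The value used for pair statistics: experimental wins; a predicted
        value fills the gap unless it is out of domain (configurable)."""
        if self.experimental is not None:
            return self.experimental
        if self.predicted is not None and (self.predicted.in_domain or include_out_of_domain):
            return self.predicted
        return None

    @property
    def kind(self) -> str | None:
        v = self.experimental or self.predicted
        return v.kind if v is not None else None


@dataclass
class MoleculeRecord:
    """A standardized compound: canonical SMILES, InChI-key uniqueness key,
    and per-endpoint values."""

    id: str
    structure: str
    unique_key: str
    heavy_atom_count: int
    endpoint_values: dict[str, EndpointData] = field(default_factory=dict)

    def set_value(self, endpoint: str, value: EndpointValue) -> None:
        data = self.endpoint_values.setdefault(endpoint, EndpointData())
        if value.source == "experimental":
            data.experimental = value
        else:
            data.predicted = value

    def get_value(
        self, endpoint: str, include_out_of_domain: bool = False
    ) -> EndpointValue | None:
        data = self.endpoint_values.get(endpoint)
        return None if data is None else data.effective(include_out_of_domain)

    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.structure)


@dataclass(frozen=True)
class Fingerprint:
    """A binary structural fingerprint as a set of on-bits."""

    bits: frozenset[int]
    n_bits: int
    radius: int

    def __post_init__(self) -> None:
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.n_bits):
            raise ChemError("fingerprint bits out of range")


def _parse_smiles_capturing(raw: str) -> Chem.Mol | None:
    """Parse SMILES while capturing RDKit's error text (which names the
    offending token position when the syntax is at fault)."""
    sio = io.StringIO()
    rdBase.LogToPythonStderr()
    import sys

    old = sys.stderr
    sys.stderr = sio
    try:
        mol = Chem.MolFromSmiles(raw)
    finally:
        sys.stderr = old
        rdBase.LogToCppStreams()
    if mol is None:
        detail = sio.getvalue().strip().replace("\n", "; ")
        raise ParseError(f"cannot parse structure {raw!r}: {detail or 'invalid SMILES'}")
    return mol


def standardize(
    raw_structure: str, mol_id: str | None = None, *, use_stereo: bool = True
) -> MoleculeRecord:
    """Canonicalize a structure and derive its uniqueness key.

    Parameters
    ----------
    raw_structure:
        A SMILES string describing a single covalently connected molecule.
    mol_id:
        Identifier for the record; defaults to the canonical SMILES.
    use_stereo:
        Whether stereochemistry is retained in the canonical structure and
        the uniqueness key.  Stereo is retained by default.

    Raises
    ------
    ParseError
        If the input cannot be parsed.
    ChemError
        If the input is disconnected (salts and mixtures are rejected rather
        than stripped, keeping pair semantics unambiguous).
    """
    mol = _parse_smiles_capturing(raw_structure)
    if len(Chem.GetMolFrags(mol)) > 1:
        raise ChemError(
            f"multi-component structure {raw_structure!r}: salts/mixtures are not supported"
        )
    if not use_stereo:
        Chem.RemoveStereochemistry(mol)
    structure = Chem.MolToSmiles(mol)
    unique_key = Chem.MolToInchiKey(mol)
    if not unique_key:
        raise ChemError(f"could not derive InChI key for {raw_structure!r}")
    return MoleculeRecord(
        id=mol_id if mol_id is not None else structure,
        structure=structure,
        unique_key=unique_key,
        heavy_atom_count=mol.GetNumHeavyAtoms(),
    )


def fingerprint(mol: MoleculeRecord | str, radius: int = 2, n_bits: int = 2048) -> Fingerprint:
    """Morgan/ECFP fingerprint of a molecule (default ECFP4, 2048 bits)."""
    if radius < 1:
        raise ChemError("radius must be >= 1")
    if n_bits < 1 or (n_bits & (n_bits - 1)) != 0:
        raise ChemError("n_bits must be a power of two")
    smiles = mol.structure if isinstance(mol, MoleculeRecord) else mol
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise ParseError(f"cannot parse structure {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bits = frozenset(gen.GetFingerprint(rdmol).GetOnBits())
    return Fingerprint(bits=bits, n_bits=n_bits, radius=radius)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |a & b| / |a | b|.

    Two empty fingerprints are defined as identical (similarity 1.0).
    """
    if a.n_bits != b.n_bits:
        raise ChemError(f"fingerprint length mismatch: {a.n_bits} != {b.n_bits}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 1.0
    return len(a.bits & b.bits) / union
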