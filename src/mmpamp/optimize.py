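"""Transformation-driven molecular optimization.

Given a target molecule and a set of significant transformations, generate
every product reachable by replacing an embedded source fragment with the
transformation's target fragment, filter the products by Tanimoto
similarity to the original, and score each kept product with a predictor.
The accounting mirrors lead-optimization practice: ``generated`` products,
``kept`` after the similarity filter, ``hits`` whose predicted endpoint
moved in the desired direction, and ``effectiveness = hits / kept``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from rdkit import Chem

from .chem import ChemError, MoleculeRecord, fingerprint, tanimoto
from .fragment import (
    FragmentKey,
    _label_permutations,
    _parse_fragment,
    _relabel,
    enumerate_fragmentations,
    reassemble,
)
from .index import Transformation
from .stats import TransformationStats

__all__ = [
    "OptimizationConfig",
    "ProductRow",
    "OptimizationResult",
    "apply_transformation",
    "select_applicable",
    "optimize",
]

logger = logging.getLogger(__name__)


@dataclass
class OptimizationConfig:
    """Direction and filters for an optimization run.

    ``direction`` is ``increase``/``decrease`` for continuous endpoints and
    ``activate``/``deactivate`` for binary ones.  ``practical_threshold``
    gates which transformations are applied at all: the minimum |mean delta|
    (default 1.0 log unit) or minimum deactivation/activation ratio (default
    0.55).  ``min_similarity`` filters the generated products.
    """

    direction: str = "decrease"
    min_similarity: float = 0.5
    practical_threshold: float | None = None
    max_products_per_transformation: int | None = None
    fp_radius: int = 2
    fp_bits: int = 2048

    def __post_init__(self) -> None:
        if self.direction not in ("increase", "decrease", "activate", "deactivate"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not 0 <= self.min_similarity <= 1:
            raise ValueError("min_similarity must lie in [0, 1]")

    @property
    def is_binary(self) -> bool:
        return self.direction in ("activate", "deactivate")

    @property
    def effective_threshold(self) -> float:
        if self.practical_threshold is not None:
            return self.practical_threshold
        return 0.55 if self.is_binary else 1.0


@dataclass
class ProductRow:
    transformation_id: str
    product: MoleculeRecord
    similarity: float
    kept: bool
    value_before: float | str | None = None
    value_after: float | str | None = None
    is_hit: bool = False


@dataclass
class OptimizationResult:
    molecule_id: str
    rows: list[ProductRow] = field(default_factory=list)

    @property
    def generated(self) -> int:
        return len(self.rows)

    @property
    def kept(self) -> int:
        return sum(1 for r in self.rows if r.kept)

    @property
    def hits(self) -> int:
        return sum(1 for r in self.rows if r.is_hit)

    @property
    def effectiveness(self) -> float | None:
        """Hits-to-kept ratio; undefined (None) when nothing was kept."""
        return None if self.kept == 0 else self.hits / self.kept

    def per_transformation(self) -> dict[str, dict[str, float | int | None]]:
        """Generated / kept / hits / effectiveness broken down by
        transformation, mirroring per-transformation optimization tables."""
        out: dict[str, dict[str, float | int | None]] = {}
        for row in self.rows:
            d = out.setdefault(
                row.transformation_id,
                {"generated": 0, "kept": 0, "hits": 0, "effectiveness": None},
            )
            d["generated"] += 1
            d["kept"] += row.kept
            d["hits"] += row.is_hit
        for d in out.values():
            if d["kept"]:
                d["effectiveness"] = d["hits"] / d["kept"]
        return out


def _matching_permutations(variable: FragmentKey, source: FragmentKey):
    """Label permutations mapping a fragmentation record's variable part onto
    the transformation's source fragment notation."""
    if variable.attachment_count != source.attachment_count:
        return
    mol = _parse_fragment(variable.notation)
    for mapping in _label_permutations(variable.attachment_count):
        if Chem.MolToSmiles(_relabel(mol, mapping)) == source.notation:
            yield mapping


def apply_transformation(
    mol: MoleculeRecord,
    t: Transformation,
    direction_sign: int = 1,
    max_variable_atoms: int = 10,
    max_breakable_bonds: int = 40,
) -> list[MoleculeRecord]:
    """All distinct products of replacing the source fragment by the target.

    ``direction_sign`` +1 applies left -> right, -1 right -> left.  Every
    scaffold/variable split of the molecule whose variable part equals the
    source fragment (up to attachment relabelling) is an application site;
    the target fragment is attached with the corresponding label
    correspondence.  Products are standardized and deduplicated on the
    uniqueness key; chemically invalid products are discarded.  No embedding
    yields an empty list.
    """
    source, target = (t.left, t.right) if direction_sign >= 0 else (t.right, t.left)
    records = enumerate_fragmentations(
        mol,
        max_cuts=t.n_cuts,
        max_variable_atoms=max_variable_atoms,
        max_breakable_bonds=max_breakable_bonds,
    )
    target_mol = _parse_fragment(target.notation)
    products: dict[str, MoleculeRecord] = {}
    for rec in records:
        if rec.n_cuts != t.n_cuts:
            continue
        for mapping in _matching_permutations(rec.variable, source):
            inverse = {new: old for old, new in mapping.items()}
            relabelled = Chem.MolToSmiles(_relabel(target_mol, inverse))
            try:
                product = reassemble(rec.scaffold.notation, relabelled)
            except ChemError as exc:
                logger.debug("discarding invalid product at %s: %s", rec.scaffold.notation, exc)
                continue
            products.setdefault(product.unique_key, product)
    return [products[k] for k in sorted(products)]


def select_applicable(
    stats: list[TransformationStats],
    transformations: list[Transformation],
    config: OptimizationConfig,
) -> list[tuple[Transformation, int]]:
    """Pick the Holm-significant transformations whose effect matches the
    configured direction and clears the practical threshold; returns each
    with the sign in which it should be applied."""
    by_id = {t.id: t for t in transformations}
    picked: list[tuple[Transformation, int]] = []
    for s in stats:
        if not s.holm_significant or s.transformation_id not in by_id:
            continue
        t = by_id[s.transformation_id]
        if config.is_binary:
            if s.n_activated is None or s.n_deactivated is None:
                continue
            want_deactivate = config.direction == "deactivate"
            # orientation whose transitions move labels the desired way
            if want_deactivate:
                forward = s.n_pos > 0 and s.n_deactivated / s.n_pos >= config.effective_threshold
                backward = (
                    s.after_neg is not None
                    and s.after_pos > 0
                    and s.n_activated / max(s.after_pos, 1) >= config.effective_threshold
                )
            else:
                forward = s.n_neg > 0 and s.n_activated / s.n_neg >= config.effective_threshold
                backward = (
                    s.after_neg is not None
                    and s.after_neg > 0
                    and s.n_deactivated / max(s.after_neg, 1) >= config.effective_threshold
                )
            if forward:
                picked.append((t, 1))
            elif backward:
                picked.append((t, -1))
        else:
            if s.mean_delta is None or abs(s.mean_delta) < config.effective_threshold:
                continue
            improves_forward = (s.mean_delta > 0) == (config.direction == "increase")
            picked.append((t, 1 if improves_forward else -1))
    return picked


def _improved(before, after, config: OptimizationConfig) -> bool:
    if config.is_binary:
        desired = "active" if config.direction == "activate" else "inactive"
        return after == desired
    if config.direction == "increase":
        return after > before
    return after < before


def optimize(
    mol: MoleculeRecord,
    selected: list[tuple[Transformation, int]],
    predictor,
    config: OptimizationConfig,
) -> OptimizationResult:
    """Apply the selected transformations to one molecule and account for
    generated / kept / hit products.

    ``selected`` is the output of :func:`select_applicable` (significant
    transformations with their application signs).  Products passing the
    similarity filter are scored with the predictor; a hit is any kept
    product whose predicted value moves in the configured direction
    (continuous) or flips to the desired class (binary).
    """
    result = OptimizationResult(molecule_id=mol.id)
    ref_fp = fingerprint(mol, radius=config.fp_radius, n_bits=config.fp_bits)
    base_value = predictor([mol])[0]
    if base_value is None:
        raise RuntimeError(f"predictor failed on the target molecule {mol.id}")
    for t, sign in selected:
        products = apply_transformation(mol, t, sign)
        if config.max_products_per_transformation is not None:
            products = products[: config.max_products_per_transformation]
        for product in products:
            sim = tanimoto(
                ref_fp, fingerprint(product, radius=config.fp_radius, n_bits=config.fp_bits)
            )
            row = ProductRow(
                transformation_id=t.id,
                product=product,
                similarity=sim,
                kept=sim >= config.min_similarity,
            )
            if row.kept:
                predicted = predictor([product])[0]
                if predicted is None:
                    logger.warning("predictor failed on product %s; excluded", product.id)
                    row.kept = False
                else:
                    row.value_before = base_value.value
                    row.value_after = predicted.value
                    row.is_hit = _improved(base_value.value, predicted.value, config)
            result.rows.append(row)
    return result
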