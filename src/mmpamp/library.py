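"""Deterministic synthetic compound libraries with planted transformation
effects.

The generator decorates a set of drug-like scaffold cores with a small
substituent vocabulary and assigns each molecule an endpoint value

    value = base(scaffold) + sum of fragment contributions + Gaussian noise,

where the fragment contributions are solved from a list of planted
left -> right effects (e.g. "replacing methyl by hydroxyl adds +1.0 log
units").  Because the score uses the same additive single-cut fragment rule
as :class:`~mmpamp.amplify.AdditivePredictor`, a zero-noise predictor built
from the same contributions reproduces every planted pair delta exactly,
making the whole pipeline verifiable by arithmetic.

Everything is a pure function of the seed: two runs with the same seed
produce byte-identical endpoint tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .amplify import AdditivePredictor
from .chem import ChemError, EndpointValue, MoleculeRecord
from .fragment import HYDROGEN_FRAGMENT, canonical_fragment, enumerate_fragmentations, reassemble

__all__ = [
    "PlantedEffect",
    "LibraryBundle",
    "DEFAULT_SCAFFOLD_CORES",
    "DEFAULT_VOCABULARY",
    "DEFAULT_EFFECTS",
    "solve_contributions",
    "generate_library",
]

logger = logging.getLogger(__name__)

# Drug-like cores (14-20 heavy atoms) with one marked substitution site.
# Sized so that any two same-core library members stay above the 50% ECFP4
# Tanimoto similarity filter.
DEFAULT_SCAFFOLD_CORES: tuple[str, ...] = (
    "[*:1]c1ccc(CN2CCN(c3ccccc3)CC2)cc1",
    "[*:1]c1ccc(C(=O)Nc2ccc(OC)cc2)cc1",
    "[*:1]c1ccc(S(=O)(=O)N2CCOCC2)cc1",
    "[*:1]c1ccc(Oc2ccc(Cl)cc2)cc1",
    "[*:1]c1ccc(CCNC(=O)c2ccco2)cc1",
    "[*:1]c1ccc2nc(NC3CCCCC3)ncc2c1",
    "[*:1]c1ccc(-c2nc3ccccc3[nH]2)cc1",
    "[*:1]c1ccc(CN2CCc3ccccc3C2)cc1",
    "[*:1]c1ccc(NC(=O)C2CCN(C)CC2)cc1",
    "[*:1]c1ccc(COc2ccccn2)cc1",
    "[*:1]c1ccc(N2CCN(S(C)(=O)=O)CC2)cc1",
    "[*:1]c1cc2ccccc2cc1NC(=O)C1CC1",
)

# Small common groups mirroring classic medicinal-chemistry replacements
# (hydrogen, methyl, hydroxyl, chloro, bromo, amino, carboxyl).
DEFAULT_VOCABULARY: tuple[str, ...] = (
    "[*:1][H]",
    "[*:1]C",
    "[*:1]O",
    "[*:1]Cl",
    "[*:1]Br",
    "[*:1]N",
    "[*:1]C(=O)O",
)


@dataclass(frozen=True)
class PlantedEffect:
    """Endpoint shift (log units) when ``right`` replaces ``left``."""

    left: str
    right: str
    effect: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.effect):
            raise ValueError("planted effect must be finite")


DEFAULT_EFFECTS: tuple[PlantedEffect, ...] = (
    PlantedEffect("[*:1]C", "[*:1]O", +1.0),       # the headline planted effect
    PlantedEffect("[*:1][H]", "[*:1]C(=O)O", -1.0),  # carboxylation reduces the endpoint
    PlantedEffect("[*:1][H]", "[*:1]Cl", +0.5),
    PlantedEffect("[*:1]Cl", "[*:1]Br", 0.0),      # null control
    PlantedEffect("[*:1][H]", "[*:1]N", -0.4),
    PlantedEffect("[*:1][H]", "[*:1]C", +0.3),
)


def _fragment_count_delta(core: str, sub: str, vocab: set[str]) -> dict[str, int]:
    """Per-fragment count increase of core+sub over the bare core, restricted
    to the vocabulary (multiplicity matters: a substituent may bring another
    vocabulary fragment along, e.g. carboxyl contains hydroxyl)."""

    def counts(mol) -> dict[str, int]:
        out: dict[str, int] = {}
        for rec in enumerate_fragmentations(mol, max_cuts=1):
            out[rec.variable.notation] = out.get(rec.variable.notation, 0) + 1
        return out

    decorated = counts(reassemble(core, sub))
    bare = counts(reassemble(core, HYDROGEN_FRAGMENT))
    return {
        f: decorated.get(f, 0) - bare.get(f, 0)
        for f in vocab
        if decorated.get(f, 0) != bare.get(f, 0)
    }


def solve_contributions(
    vocabulary: list[str],
    effects: list[PlantedEffect],
    reference_core: str = DEFAULT_SCAFFOLD_CORES[0],
) -> tuple[dict[str, float], dict[str, float]]:
    """Solve per-fragment contributions realizing the planted effects.

    Returns ``(contributions, substituent_scores)`` keyed by canonical
    fragment notation.  Substituent scores S are propagated from the effect
    constraints (the first vocabulary entry anchors S = 0); contributions c
    then unfold the containment closure so that the *additive fragment
    score* of a decorated molecule shifts by exactly S(right) - S(left)
    under each planted replacement (a substituent such as carboxyl contains
    the hydroxyl fragment, whose contribution must be discounted).
    Contradictory effect cycles raise.
    """
    vocab = [canonical_fragment(v).notation for v in vocabulary]
    if len(set(vocab)) != len(vocab):
        raise ValueError("duplicate vocabulary fragments")
    edges = [
        (canonical_fragment(e.left).notation, canonical_fragment(e.right).notation, e.effect)
        for e in effects
    ]
    for left, right, _ in edges:
        for frag in (left, right):
            if frag not in vocab:
                raise ValueError(f"planted effect references {frag!r} outside the vocabulary")
    # propagate substituent scores along effect constraints; every connected
    # component is anchored at 0 (the first vocabulary entry first)
    scores: dict[str, float] = {}
    for anchor in vocab:
        if anchor in scores:
            continue
        scores[anchor] = 0.0
        changed = True
        while changed:
            changed = False
            for left, right, effect in edges:
                if left in scores and right not in scores:
                    scores[right] = scores[left] + effect
                    changed = True
                elif right in scores and left not in scores:
                    scores[left] = scores[right] - effect
                    changed = True
    for left, right, effect in edges:
        if abs(scores[right] - scores[left] - effect) > 1e-9:
            raise ValueError(f"inconsistent planted effects around {left} -> {right}")
    # unfold containment: c(s) = S(s) - contributions of the other vocabulary
    # fragments s brings along (with multiplicity)
    vocab_set = set(vocab)
    closures: dict[str, dict[str, int]] = {}
    for frag in vocab:
        if frag == HYDROGEN_FRAGMENT:
            closures[frag] = {}
            continue
        delta = _fragment_count_delta(reference_core, frag, vocab_set)
        delta.pop(HYDROGEN_FRAGMENT, None)
        closures[frag] = delta
    contributions: dict[str, float] = {HYDROGEN_FRAGMENT: 0.0}
    for frag in sorted(vocab, key=lambda f: canonical_fragment(f).atom_count):
        if frag == HYDROGEN_FRAGMENT:
            continue
        others = {f: n for f, n in closures[frag].items() if f != frag}
        unresolved = [o for o in others if o not in contributions]
        if unresolved:
            raise ValueError(f"cannot resolve containment of {frag!r}: {unresolved}")
        contributions[frag] = scores[frag] - sum(
            n * contributions[o] for o, n in others.items()
        )
    return contributions, scores


@dataclass
class LibraryBundle:
    """A generated library with its ground truth."""

    molecules: list[MoleculeRecord]
    endpoint_table: pd.DataFrame
    contributions: dict[str, float]
    substituent_scores: dict[str, float]
    bases: dict[str, float]
    scaffold_cores: list[str]
    vocabulary: list[str]
    endpoint: str
    binary_endpoint: str | None
    noise_sd: float
    seed: int
    skipped: list[tuple[str, str, str]] = field(default_factory=list)

    def predictor(self, noise_sd: float = 0.0, seed: int | None = None,
                  uncertainty: float | None = None, kind: str = "continuous",
                  threshold: float = 0.0) -> AdditivePredictor:
        """A predictor sharing the library's planted contributions.

        With ``noise_sd=0`` it reproduces every planted pair delta exactly.
        """
        return AdditivePredictor(
            endpoint=self.endpoint,
            contributions=dict(self.contributions),
            intercept=float(np.mean(list(self.bases.values()))),
            noise_sd=noise_sd,
            seed=self.seed if seed is None else seed,
            kind=kind,
            threshold=threshold,
            uncertainty=uncertainty,
        )


def generate_library(
    seed: int,
    n_scaffolds: int = 10,
    substituent_vocabulary: list[str] | None = None,
    effects: list[PlantedEffect] | None = None,
    noise_sd: float = 0.1,
    endpoint: str = "activity",
    experimental_fraction: float = 1.0,
    prediction_sd: float | None = None,
    binary_threshold: float | None = None,
    binary_endpoint: str = "activity_class",
    scaffold_cores: list[str] | None = None,
) -> LibraryBundle:
    """Build a scaffold x substituent combinatorial library with planted
    effects.

    Each molecule receives a continuous endpoint value (and, when
    ``binary_threshold`` is given, an active/inactive label from
    thresholding the same score).  A fraction ``experimental_fraction`` of
    molecules carries experimental-source values; the remainder carries
    predicted-source values with uncertainty ``prediction_sd`` (default: the
    generator noise).  Chemically impossible core/substituent combinations
    are skipped and reported in ``bundle.skipped``.
    """
    cores = list(scaffold_cores or DEFAULT_SCAFFOLD_CORES)
    if n_scaffolds > len(cores):
        raise ValueError(
            f"n_scaffolds={n_scaffolds} exceeds the {len(cores)} available cores"
        )
    cores = cores[:n_scaffolds]
    vocabulary = [
        canonical_fragment(v).notation
        for v in (substituent_vocabulary or DEFAULT_VOCABULARY)
    ]
    effects = list(effects if effects is not None else DEFAULT_EFFECTS)
    contributions, scores = solve_contributions(vocabulary, effects, cores[0])
    rng = np.random.default_rng(seed)
    bases = {core: float(b) for core, b in zip(cores, rng.uniform(0.0, 2.0, len(cores)))}
    if prediction_sd is None:
        prediction_sd = noise_sd

    molecules: list[MoleculeRecord] = []
    rows: list[dict] = []
    skipped: list[tuple[str, str, str]] = []
    scorer = AdditivePredictor(endpoint=endpoint, contributions=contributions)
    for si, core in enumerate(cores):
        for vi, sub in enumerate(vocabulary):
            mol_id = f"S{si:02d}_V{vi:02d}"
            try:
                mol = reassemble(core, sub)
            except ChemError as exc:
                skipped.append((core, sub, str(exc)))
                logger.warning("skipping %s + %s: %s", core, sub, exc)
                continue
            mol.id = mol_id
            value = bases[core] + scorer.score(mol) + float(rng.normal(0.0, noise_sd))
            experimental = bool(rng.random() < experimental_fraction)
            source = "experimental" if experimental else "predicted"
            uncertainty = 0.0 if experimental else prediction_sd
            ev = EndpointValue(
                kind="continuous",
                value=value,
                source=source,
                uncertainty=uncertainty,
                in_domain=True,
            )
            mol.set_value(endpoint, ev)
            rows.append(
                {
                    "id": mol_id,
                    "endpoint": endpoint,
                    "kind": "continuous",
                    "value": value,
                    "source": source,
                    "uncertainty": uncertainty,
                    "in_domain": True,
                }
            )
            if binary_threshold is not None:
                label = "active" if value > binary_threshold else "inactive"
                bev = EndpointValue(
                    kind="binary",
                    value=label,
                    source=source,
                    uncertainty=uncertainty if source == "predicted" else 0.0,
                    in_domain=True,
                )
                mol.set_value(binary_endpoint, bev)
                rows.append(
                    {
                        "id": mol_id,
                        "endpoint": binary_endpoint,
                        "kind": "binary",
                        "value": label,
                        "source": source,
                        "uncertainty": bev.uncertainty,
                        "in_domain": True,
                    }
                )
            molecules.append(mol)
    table = pd.DataFrame(
        rows, columns=["id", "endpoint", "kind", "value", "source", "uncertainty", "in_domain"]
    )
    return LibraryBundle(
        molecules=molecules,
        endpoint_table=table,
        contributions=contributions,
        substituent_scores=scores,
        bases=bases,
        scaffold_cores=cores,
        vocabulary=vocabulary,
        endpoint=endpoint,
        binary_endpoint=binary_endpoint if binary_threshold is not None else None,
        noise_sd=noise_sd,
        seed=seed,
        skipped=skipped,
    )
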