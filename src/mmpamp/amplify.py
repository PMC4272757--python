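"""Prediction-driven evidence: predictor contract, annotation and
amplification classes.

The central idea is to let a QSAR model vote alongside the bench: matched
pairs built from predicted values join the experimentally measured pairs in
the significance tests.  A transformation is

* ``experimental`` when its experimental pairs alone reach significance,
* ``amplified`` when experimental evidence exists but is insufficient and
  the combined evidence is significant,
* ``predicted`` when significance rests on predicted pairs only.
"""

from __future__ import annotations

import logging
import subprocess
import zlib
from dataclasses import dataclass, field
from typing import Literal, Protocol, runtime_checkable

import numpy as np

from .chem import EndpointValue, MoleculeRecord
from .fragment import canonical_fragment, enumerate_fragmentations

__all__ = [
    "Predictor",
    "AdditivePredictor",
    "SubprocessPredictor",
    "toy_additive_predictor",
    "annotate_predictions",
    "classify_provenance",
    "EvidenceSummary",
]

logger = logging.getLogger(__name__)


@runtime_checkable
class Predictor(Protocol):
    """The predictor contract: a batch callable with endpoint metadata.

    Calling with a list of molecules returns one predicted
    :class:`EndpointValue` per input, in order, deterministically for a
    fixed model state.
    """

    endpoint: str
    kind: Literal["continuous", "binary"]

    def __call__(self, mols: list[MoleculeRecord]) -> list[EndpointValue | None]: ...


@dataclass
class AdditivePredictor:
    """Additive group-contribution predictor over single-cut fragments.

    Score = intercept + sum of contributions of the single-cut variable
    fragments present in the molecule (one term per distinct
    scaffold/variable split, so repeated occurrences count with
    multiplicity), plus seeded Gaussian noise of standard deviation
    ``noise_sd``.  The noise is a pure function of
    (seed, molecule key), so repeated calls and input reordering give
    identical outputs.  The binary variant labels molecules ``active`` when
    the continuous score exceeds ``threshold``.

    This is a deliberately transparent stand-in for a trained QSAR model:
    with ``noise_sd=0`` its pair deltas equal the planted fragment
    contribution differences exactly, which makes every downstream claim
    checkable by arithmetic.
    """

    endpoint: str
    contributions: dict[str, float]
    intercept: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    kind: Literal["continuous", "binary"] = "continuous"
    threshold: float = 0.0
    uncertainty: float | None = None
    in_domain_keys: set[str] | None = None
    _canon: dict[str, float] = field(init=False, repr=False)
    _warned: set[str] = field(init=False, repr=False, default_factory=set)

    def __post_init__(self) -> None:
        self._canon = {
            canonical_fragment(k).notation: v for k, v in self.contributions.items()
        }

    def fragment_counts(self, mol: MoleculeRecord) -> dict[str, int]:
        """Occurrences of each single-cut variable fragment, one per distinct
        scaffold/variable split (symmetry-equivalent splits collapse)."""
        counts: dict[str, int] = {}
        for rec in enumerate_fragmentations(mol, max_cuts=1):
            counts[rec.variable.notation] = counts.get(rec.variable.notation, 0) + 1
        return counts

    def score(self, mol: MoleculeRecord) -> float:
        total = self.intercept
        for notation, count in sorted(self.fragment_counts(mol).items()):
            if notation in self._canon:
                total += count * self._canon[notation]
            elif notation not in self._warned:
                self._warned.add(notation)
                logger.debug("fragment %s has no contribution; counted as 0", notation)
        if self.noise_sd > 0:
            rng = np.random.default_rng(
                np.random.SeedSequence([self.seed, zlib.crc32(mol.unique_key.encode())])
            )
            total += rng.normal(0.0, self.noise_sd)
        return total

    def __call__(self, mols: list[MoleculeRecord]) -> list[EndpointValue | None]:
        out: list[EndpointValue | None] = []
        unc = self.noise_sd if self.uncertainty is None else self.uncertainty
        for mol in mols:
            try:
                score = self.score(mol)
            except Exception as exc:
                logger.warning("prediction failed for %s: %s", mol.id, exc)
                out.append(None)
                continue
            in_dom = True
            if self.in_domain_keys is not None:
                in_dom = mol.unique_key in self.in_domain_keys
            if self.kind == "binary":
                value = "active" if score > self.threshold else "inactive"
            else:
                value = score
            out.append(
                EndpointValue(
                    kind=self.kind,
                    value=value,
                    source="predicted",
                    uncertainty=unc,
                    in_domain=in_dom,
                )
            )
        return out


def toy_additive_predictor(
    contributions: dict[str, float],
    intercept: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    endpoint: str = "activity",
    kind: Literal["continuous", "binary"] = "continuous",
    threshold: float = 0.0,
) -> AdditivePredictor:
    """Convenience constructor for :class:`AdditivePredictor`."""
    return AdditivePredictor(
        endpoint=endpoint,
        contributions=contributions,
        intercept=intercept,
        noise_sd=noise_sd,
        seed=seed,
        kind=kind,
        threshold=threshold,
    )


@dataclass
class SubprocessPredictor:
    """Out-of-process predictor plug-in.

    The command receives SMILES lines on stdin and must print one
    tab-separated ``value<TAB>uncertainty<TAB>in_domain`` line per input.
    """

    command: list[str]
    endpoint: str
    kind: Literal["continuous", "binary"] = "continuous"

    def __call__(self, mols: list[MoleculeRecord]) -> list[EndpointValue | None]:
        payload = "\n".join(m.structure for m in mols) + "\n"
        proc = subprocess.run(
            self.command, input=payload, capture_output=True, text=True, check=True
        )
        out: list[EndpointValue | None] = []
        lines = proc.stdout.strip().splitlines()
        if len(lines) != len(mols):
            raise RuntimeError(
                f"predictor returned {len(lines)} lines for {len(mols)} molecules"
            )
        for line in lines:
            value, unc, in_dom = line.rstrip("\n").split("\t")
            out.append(
                EndpointValue(
                    kind=self.kind,
                    value=value if self.kind == "binary" else float(value),
                    source="predicted",
                    uncertainty=float(unc),
                    in_domain=in_dom.strip().lower() in ("1", "true", "yes"),
                )
            )
        return out


def annotate_predictions(
    mols: list[MoleculeRecord], predictor: Predictor
) -> list[MoleculeRecord]:
    """Attach a predicted endpoint value to every molecule (in place).

    Experimental values already present are retained alongside; molecules
    the predictor fails on keep no predicted value and are therefore
    excluded from predicted pairs downstream.
    """
    values = predictor(mols)
    if len(values) != len(mols):
        raise RuntimeError("predictor must return one value per input molecule")
    for mol, value in zip(mols, values):
        if value is None:
            continue
        mol.set_value(predictor.endpoint, value)
    return mols


def classify_provenance(
    p_experimental: float | None,
    p_combined: float | None,
    n_exp_pairs: int,
    n_pred_pairs: int,
    alpha: float = 0.05,
    experimental_significant: bool | None = None,
    combined_significant: bool | None = None,
) -> str:
    """Evidence class of a transformation: experimental | amplified |
    predicted | none.

    ``experimental``: significant on experimental pairs alone.  ``amplified``:
    not significant (or untestable) on experimental pairs alone, at least one
    experimental pair, and significant on the combined evidence.
    ``predicted``: significant on combined evidence with no experimental
    pairs.  ``none``: not significant on any evidence.  Corrected decisions
    may be passed explicitly; otherwise plain alpha thresholds apply.
    """
    if experimental_significant is None:
        experimental_significant = p_experimental is not None and p_experimental <= alpha
    if combined_significant is None:
        combined_significant = p_combined is not None and p_combined <= alpha
    if experimental_significant:
        return "experimental"
    if combined_significant:
        if n_exp_pairs >= 1:
            return "amplified"
        if n_pred_pairs >= 1:
            return "predicted"
    return "none"


@dataclass(frozen=True)
class EvidenceSummary:
    """Condensed provenance view of one transformation x endpoint."""

    transformation_id: str
    endpoint: str
    n_experimental_pairs: int
    n_predicted_pairs: int
    p_experimental: float | None
    p_combined: float | None
    provenance_class: str

    @classmethod
    def from_stats(cls, stats) -> "EvidenceSummary":
        return cls(
            transformation_id=stats.transformation_id,
            endpoint=stats.endpoint,
            n_experimental_pairs=stats.n_experimental_pairs,
            n_predicted_pairs=stats.n_predicted_pairs,
            p_experimental=stats.p_experimental,
            p_combined=stats.p_value,
            provenance_class=stats.provenance_class,
        )
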