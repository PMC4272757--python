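"""Model/Results interface to the matched-pair analysis.

:class:`MMPAnalysis` bundles a compound set, an endpoint and the analysis
configuration; :meth:`MMPAnalysis.fit` runs indexing, pair identification,
transformation extraction and significance testing, returning an
:class:`MMPResults` carrying the per-transformation statistics with a
``summary()`` table.  Optimization, the transformation graph and the
delta-pair chart hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .amplify import Predictor, annotate_predictions
from .chem import MoleculeRecord
from .config import AnalysisConfig
from .index import (
    MatchedPair,
    PairIndex,
    Transformation,
    build_index,
    extract_transformations,
    find_matched_pairs,
)
from .io import apply_endpoint_table, stats_frame
from .optimize import OptimizationConfig, OptimizationResult, optimize, select_applicable
from .stats import TransformationStats, significant_transformations

__all__ = ["MMPAnalysis", "MMPResults"]


class MMPAnalysis:
    """Matched-molecular-pair significance analysis of one endpoint.

    Parameters
    ----------
    molecules:
        Standardized molecule records (see :func:`mmpamp.chem.standardize`
        and the readers in :mod:`mmpamp.io`).
    endpoint:
        Name of the endpoint to analyse; values must already be attached to
        the molecules or supplied via ``endpoint_table``.
    endpoint_table:
        Optional long-format table (columns ``id, endpoint, kind, value,
        source, uncertainty, in_domain``) applied to the molecules.
    predictor:
        Optional predictor honouring the :class:`~mmpamp.amplify.Predictor`
        contract; its predictions are attached before fitting so that
        predicted pairs can amplify the experimental evidence.
    config:
        :class:`~mmpamp.config.AnalysisConfig` with the analysis defaults
        (50% similarity filter, alpha 0.05, 1,000 bootstrap replicas).
    """

    def __init__(
        self,
        molecules: list[MoleculeRecord],
        endpoint: str,
        endpoint_table: pd.DataFrame | None = None,
        predictor: Predictor | None = None,
        config: AnalysisConfig | None = None,
    ) -> None:
        if not molecules:
            raise ValueError("no molecules supplied")
        self.molecules = molecules
        self.endpoint = endpoint
        self.config = config or AnalysisConfig()
        if endpoint_table is not None:
            apply_endpoint_table(molecules, endpoint_table)
        if predictor is not None:
            annotate_predictions(molecules, predictor)

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        endpoint: str,
        smiles_column: str = "smiles",
        id_column: str = "id",
        value_column: str = "value",
        kind: str = "continuous",
        source_column: str | None = None,
        config: AnalysisConfig | None = None,
        predictor: Predictor | None = None,
    ) -> "MMPAnalysis":
        """Build an analysis from a wide table of SMILES and endpoint values."""
        from .chem import EndpointValue, standardize

        config = config or AnalysisConfig()
        molecules = []
        for row in frame.itertuples(index=False):
            rec = standardize(
                getattr(row, smiles_column),
                str(getattr(row, id_column)),
                use_stereo=config.use_stereo,
            )
            raw = getattr(row, value_column)
            source = getattr(row, source_column) if source_column else "experimental"
            rec.set_value(
                endpoint,
                EndpointValue(
                    kind=kind,
                    value=str(raw) if kind == "binary" else float(raw),
                    source=source,
                ),
            )
            molecules.append(rec)
        return cls(molecules, endpoint, config=config, predictor=predictor)

    def fit(self) -> "MMPResults":
        index = build_index(self.molecules, self.config)
        pairs = find_matched_pairs(index)
        transformations = extract_transformations(pairs) if pairs else []
        stats = significant_transformations(transformations, self.endpoint, self.config)
        return MMPResults(
            model=self,
            index=index,
            pairs=pairs,
            transformations=transformations,
            stats=stats,
        )


@dataclass
class MMPResults:
    """Fitted matched-pair analysis: pairs, transformations and their stats."""

    model: MMPAnalysis
    index: PairIndex
    pairs: list[MatchedPair]
    transformations: list[Transformation]
    stats: list[TransformationStats]
    _by_id: dict[str, Transformation] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {t.id: t for t in self.transformations}

    @property
    def endpoint(self) -> str:
        return self.model.endpoint

    @property
    def significant(self) -> list[TransformationStats]:
        return [s for s in self.stats if s.holm_significant]

    def frame(self) -> pd.DataFrame:
        """Per-transformation statistics as a DataFrame."""
        return stats_frame(self.stats)

    def summary(self, max_rows: int = 20) -> str:
        """Human-readable summary of the fitted analysis."""
        n_tested = sum(1 for s in self.stats if s.tested)
        lines = [
            "Matched Molecular Pair Analysis",
            "=" * 72,
            f"Endpoint:                 {self.endpoint}",
            f"Molecules (unique):       {len(self.index.molecules)}"
            + (f"  (+{len(self.index.aliases)} duplicates)" if self.index.aliases else ""),
            f"Matched pairs:            {len(self.pairs)}",
            f"Transformations:          {len(self.transformations)}"
            f"  (tested: {n_tested}, min pairs {self.model.config.min_pairs})",
            f"Holm-significant:         {len(self.significant)}"
            f"  (alpha {self.model.config.alpha})",
            "-" * 72,
            f"{'transformation':<38s} {'N':>4s} {'mean_d':>7s} {'siglev':>7s} {'class':>12s}",
        ]
        shown = sorted(
            (s for s in self.stats if s.tested),
            key=lambda s: (not s.holm_significant, s.p_value or 1.0),
        )[:max_rows]
        for s in shown:
            md = f"{s.mean_delta:+.2f}" if s.mean_delta is not None else "--"
            sl = f"{s.sig_level:.2f}" if s.sig_level is not None else "--"
            mark = "*" if s.holm_significant else " "
            name = s.transformation_id
            if len(name) > 37:
                name = name[:34] + "..."
            lines.append(f"{name:<38s} {s.N:>4d} {md:>7s} {sl:>7s} {s.provenance_class:>11s}{mark}")
        lines.append("-" * 72)
        lines.append("* Holm-significant (after bootstrap exclusion where applicable)")
        return "\n".join(lines)

    def transformation(self, transformation_id: str) -> Transformation:
        return self._by_id[transformation_id]

    def graph(self):
        """Directed fragment graph of the significant transformations."""
        from .viz import build_graph

        return build_graph(self.significant)

    def delta_pair_frame(self, cliff_threshold: float = 1.0) -> pd.DataFrame:
        """Experimental-vs-predicted delta table for pairs carrying both."""
        from .viz import delta_pair_table

        return delta_pair_table(self.pairs, self.endpoint, cliff_threshold)

    def optimize(
        self,
        target: MoleculeRecord,
        predictor: Predictor,
        config: OptimizationConfig | None = None,
    ) -> OptimizationResult:
        """Apply the significant transformations to a target molecule."""
        config = config or OptimizationConfig()
        selected = select_applicable(self.stats, self.transformations, config)
        return optimize(target, selected, predictor, config)
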