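"""End-to-end pipeline with file artifacts and a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

from . import __version__
from .chem import ChemError
from .config import AnalysisConfig
from .io import (
    pairs_frame,
    read_endpoint_table,
    read_sdf,
    read_smiles,
    stats_frame,
    transformations_frame,
    write_transformations,
)
from .model import MMPAnalysis

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    molecules_path: str | Path,
    endpoint_table_path: str | Path,
    endpoint: str,
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
) -> Path:
    """Run index -> pairs -> significance and write all stage artifacts.

    Outputs (CSV unless noted): ``pairs.csv``, ``transformations.csv``,
    ``transformations.smirks`` (one left>>right per line), ``stats.csv`` and
    ``manifest.json`` (input hashes, full config echo, seed, version).
    Reruns with identical inputs and config reproduce identical tables.
    """
    config = config or AnalysisConfig()
    molecules_path = Path(molecules_path)
    endpoint_table_path = Path(endpoint_table_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failure_marker = out / "FAILED"
    try:
        if not molecules_path.exists():
            raise FileNotFoundError(f"molecule input not found: {molecules_path}")
        if not endpoint_table_path.exists():
            raise FileNotFoundError(f"endpoint table not found: {endpoint_table_path}")
        if molecules_path.suffix.lower() in (".sdf", ".sd"):
            molecules = read_sdf(molecules_path, use_stereo=config.use_stereo)
        else:
            molecules = read_smiles(molecules_path, use_stereo=config.use_stereo)
        if not molecules:
            raise ChemError(f"no molecules read from {molecules_path}")
        table = read_endpoint_table(endpoint_table_path)
        results = MMPAnalysis(
            molecules, endpoint, endpoint_table=table, config=config
        ).fit()
        pairs_frame(results.pairs, endpoint).to_csv(out / "pairs.csv", index=False)
        transformations_frame(results.transformations).to_csv(
            out / "transformations.csv", index=False
        )
        write_transformations(results.transformations, out / "transformations.smirks")
        stats_frame(results.stats).to_csv(out / "stats.csv", index=False)
        (out / "summary.txt").write_text(results.summary() + "\n")
        manifest = {
            "version": __version__,
            "inputs": {
                "molecules": {"path": str(molecules_path), "sha256": _sha256(molecules_path)},
                "endpoint_table": {
                    "path": str(endpoint_table_path),
                    "sha256": _sha256(endpoint_table_path),
                },
            },
            "endpoint": endpoint,
            "config": config.to_dict(),
            "seed": config.seed,
            "n_molecules": len(molecules),
            "n_pairs": len(results.pairs),
            "n_transformations": len(results.transformations),
            "n_significant": len(results.significant),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        if failure_marker.exists():
            failure_marker.unlink()
        return out
    except Exception as exc:
        failure_marker.write_text(f"{type(exc).__name__}: {exc}\n")
        raise
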