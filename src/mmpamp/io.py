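"""Readers and writers for the package's plain-text formats.

Molecules come in as SMILES lists (one per line, optional tab-separated id)
or V2000 SDF; endpoint data as a delimited table with columns
``id, endpoint, kind, value, source, uncertainty, in_domain``.  All exports
are CSV with documented headers.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from rdkit import Chem

from .chem import ChemError, EndpointValue, MoleculeRecord, standardize
from .index import MatchedPair, Transformation
from .stats import TransformationStats

__all__ = [
    "read_smiles",
    "read_sdf",
    "write_smiles",
    "read_endpoint_table",
    "apply_endpoint_table",
    "pairs_frame",
    "transformations_frame",
    "stats_frame",
    "write_transformations",
]

ENDPOINT_COLUMNS = ["id", "endpoint", "kind", "value", "source", "uncertainty", "in_domain"]


def read_smiles(path: str | Path, use_stereo: bool = True) -> list[MoleculeRecord]:
    """Read a SMILES file: one molecule per line, optional tab-separated id."""
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        smiles = parts[0].strip()
        mol_id = parts[1].strip() if len(parts) > 1 and parts[1].strip() else None
        try:
            records.append(standardize(smiles, mol_id, use_stereo=use_stereo))
        except ChemError as exc:
            raise ChemError(f"{path}:{lineno}: {exc}") from exc
    return records


def read_sdf(path: str | Path, use_stereo: bool = True) -> list[MoleculeRecord]:
    """Read a V2000 SDF file; the molecule title (or _Name) becomes the id."""
    records = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ChemError(f"{path}: entry {i + 1} failed to parse")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        records.append(standardize(Chem.MolToSmiles(mol), name or None, use_stereo=use_stereo))
    return records


def write_smiles(records: list[MoleculeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.structure}\t{rec.id}\n")


def read_endpoint_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    frame = pd.read_csv(path, sep=sep)
    missing = set(ENDPOINT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"endpoint table missing columns: {sorted(missing)}")
    return frame


def apply_endpoint_table(records: list[MoleculeRecord], frame: pd.DataFrame) -> None:
    """Attach endpoint values from a table to molecule records (by id)."""
    by_id = {rec.id: rec for rec in records}
    for row in frame.itertuples(index=False):
        rec = by_id.get(str(row.id))
        if rec is None:
            continue
        kind = str(row.kind)
        value = str(row.value) if kind == "binary" else float(row.value)
        uncertainty = float(row.uncertainty) if pd.notna(row.uncertainty) else 0.0
        rec.set_value(
            str(row.endpoint),
            EndpointValue(
                kind=kind,
                value=value,
                source=str(row.source),
                uncertainty=uncertainty,
                in_domain=bool(row.in_domain),
            ),
        )


def pairs_frame(pairs: list[MatchedPair], endpoint: str | None = None) -> pd.DataFrame:
    """Tabular pair export; one row per pair (x endpoint when present)."""
    rows = []
    for p in pairs:
        base = {
            "mol_a": p.mol_a,
            "mol_b": p.mol_b,
            "scaffold": p.scaffold.notation,
            "frag_a": p.frag_a.notation,
            "frag_b": p.frag_b.notation,
            "n_cuts": p.n_cuts,
            "similarity": p.similarity,
        }
        endpoints = [endpoint] if endpoint else sorted(p.deltas)
        if not endpoints:
            rows.append(base)
            continue
        for ep in endpoints:
            data = p.deltas.get(ep)
            delta = data.effective() if data is not None else None
            row = dict(base)
            row["endpoint"] = ep
            if delta is not None:
                row["value_a"] = delta.value_a
                row["value_b"] = delta.value_b
                row["provenance"] = delta.provenance
                if delta.kind == "continuous":
                    row["delta"] = delta.delta
            rows.append(row)
    return pd.DataFrame(rows)


def transformations_frame(transformations: list[Transformation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": t.id,
                "left": t.left.notation,
                "right": t.right.notation,
                "n_cuts": t.n_cuts,
                "n_pairs": t.n_pairs,
            }
            for t in transformations
        ]
    )


def write_transformations(transformations: list[Transformation], path: str | Path) -> None:
    """SMIRKS-like left>>right strings, one per line."""
    with open(path, "w") as fh:
        for t in transformations:
            fh.write(t.smirks() + "\n")


def stats_frame(stats: list[TransformationStats]) -> pd.DataFrame:
    rows = []
    for s in stats:
        rows.append(
            {
                "transformation": s.transformation_id,
                "endpoint": s.endpoint,
                "kind": s.kind,
                "N": s.N,
                "n_pos": s.n_pos,
                "n_neg": s.n_neg,
                "n_zero": s.n_zero,
                "after_pos": s.after_pos,
                "after_neg": s.after_neg,
                "mean_delta": s.mean_delta,
                "p_value": s.p_value,
                "significance_level": s.sig_level,
                "tested": s.tested,
                "holm_significant": s.holm_significant,
                "bootstrap_p": s.bootstrap_p,
                "bootstrap_excluded": s.bootstrap_excluded,
                "n_experimental_pairs": s.n_experimental_pairs,
                "n_predicted_pairs": s.n_predicted_pairs,
                "p_experimental": s.p_experimental,
                "provenance_class": s.provenance_class,
            }
        )
    return pd.DataFrame(rows)
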