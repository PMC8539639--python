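"""Compound collection curation: reading, standardization, deduplication and
Bemis–Murcko scaffold clustering.

The modeling and evaluation sets for the QEPPI index are built from compound
collections (SMILES/SDF/CSV exports, e.g. from iPPI-DB) by a fixed pipeline:
standardize each structure, drop duplicates by standard InChI, cluster by
Bemis–Murcko atomic framework, and keep the most potent member of each
cluster. Every step is deterministic so a curated set is reproducible.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

logger = logging.getLogger(__name__)

#: Scaffold key assigned to acyclic molecules (empty Murcko framework).
ACYCLIC_SCAFFOLD = ""


@dataclass
class CompoundRecord:
    """One molecule in a curated collection.

    ``activity`` is on a higher-is-better scale (e.g. pActivity); convert
    concentrations (Kd, IC50) to their negative log before loading.
    """

    id: str
    smiles: str
    inchi: str = ""
    activity: float | None = None
    tags: set[str] = field(default_factory=set)


@dataclass
class CompoundSet:
    """An ordered collection of compound records."""

    records: list[CompoundRecord]
    name: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class ScaffoldCluster:
    """Records sharing one Bemis–Murcko framework, plus a representative."""

    scaffold: str
    members: list[CompoundRecord]
    representative: CompoundRecord | None = None


def _mol_from_smiles(smiles: str) -> Chem.Mol | None:
    return Chem.MolFromSmiles(smiles)


def standardize(record: CompoundRecord) -> CompoundRecord:
    """Standardize one record: keep the largest covalent fragment, sanitize,
    and recompute canonical SMILES and standard InChI.

    Fragment choice (salt/counter-ion stripping) is by heavy-atom count, ties
    broken by molecular weight, then canonical SMILES — deterministic so that
    descriptors are reproducible. Idempotent on its own output.

    Raises
    ------
    ValueError
        If the structure cannot be parsed or sanitized.
    """
    mol = _mol_from_smiles(record.smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES for {record.id!r}: {record.smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if not frags:
        raise ValueError(f"no fragments in {record.id!r}")

    def frag_key(m: Chem.Mol) -> tuple:
        from rdkit.Chem import Descriptors

        return (m.GetNumHeavyAtoms(), Descriptors.MolWt(m), Chem.MolToSmiles(m))

    best = max(frags, key=frag_key)
    canonical = Chem.MolToSmiles(best)
    inchi = Chem.MolToInchi(best)
    if not inchi:
        raise ValueError(f"InChI generation failed for {record.id!r}")
    return replace(record, smiles=canonical, inchi=inchi)


def standardize_set(cset: CompoundSet) -> CompoundSet:
    """Standardize every record; unparseable records are logged and dropped."""
    kept: list[CompoundRecord] = []
    skipped = 0
    for rec in cset.records:
        try:
            kept.append(standardize(rec))
        except ValueError as exc:
            skipped += 1
            logger.warning("skipping %s: %s", rec.id, exc)
    if skipped:
        logger.info("standardize: kept %d records, skipped %d", len(kept), skipped)
    return CompoundSet(records=kept, name=cset.name)


def read_compounds(
    path: str | Path,
    format: str | None = None,
    smiles_column: str | None = None,
    id_column: str | None = None,
    activity_column: str | None = None,
) -> CompoundSet:
    """Read a compound collection from a SMILES table, SDF or CSV/TSV file.

    ``format`` is one of ``smiles-table``, ``sdf``, ``csv``; inferred from
    the file suffix when omitted. Unparseable records are counted and logged,
    never fatal; an input yielding zero parseable records is an error.

    Records are returned raw (not standardized); pass the set through
    :func:`standardize_set` before deduplication or descriptor work.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {
            ".smi": "smiles-table",
            ".smiles": "smiles-table",
            ".sdf": "sdf",
            ".csv": "csv",
            ".tsv": "csv",
        }.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer format from suffix {suffix!r}")

    records: list[CompoundRecord] = []
    skipped = 0

    if format == "smiles-table":
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smi = parts[0]
            rid = parts[1] if len(parts) > 1 else f"mol{i}"
            if _mol_from_smiles(smi) is None:
                skipped += 1
                logger.warning("line %d: unparseable SMILES %r", i + 1, smi)
                continue
            records.append(CompoundRecord(id=rid, smiles=smi))
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path))
        for i, mol in enumerate(supplier):
            if mol is None:
                skipped += 1
                logger.warning("SDF record %d unparseable", i)
                continue
            rid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i}"
            activity = None
            if activity_column and mol.HasProp(activity_column):
                try:
                    activity = float(mol.GetProp(activity_column))
                except ValueError:
                    pass
            records.append(
                CompoundRecord(id=rid, smiles=Chem.MolToSmiles(mol), activity=activity)
            )
    elif format == "csv":
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        df = pd.read_csv(path, sep=sep)
        smi_col = smiles_column or _find_column(df, ("smiles", "canonical_smiles"))
        idc = id_column or _find_column(df, ("id", "name", "compound_id"), required=False)
        act = activity_column or _find_column(df, ("activity", "pactivity"), required=False)
        for i, row in df.iterrows():
            smi = str(row[smi_col])
            if _mol_from_smiles(smi) is None:
                skipped += 1
                logger.warning("row %d: unparseable SMILES %r", i, smi)
                continue
            rid = str(row[idc]) if idc is not None else f"mol{i}"
            activity = None
            if act is not None and pd.notna(row[act]):
                activity = float(row[act])
            records.append(CompoundRecord(id=rid, smiles=smi, activity=activity))
    else:
        raise ValueError(f"unsupported format {format!r}")

    if not records:
        raise ValueError(f"no parseable records in {path}")
    if skipped:
        logger.info("read_compounds: %d records, %d skipped", len(records), skipped)
    return CompoundSet(records=records, name=path.stem)


def _find_column(df: pd.DataFrame, candidates: Sequence[str], required: bool = True) -> str | None:
    lower = {c.lower(): c for c in df.columns}
    for cand in candidates:
        if cand in lower:
            return lower[cand]
    if required:
        raise ValueError(f"none of the columns {candidates} found in {list(df.columns)}")
    return None


def dedupe_by_inchi(cset: CompoundSet) -> CompoundSet:
    """Drop duplicate structures, keeping the first occurrence per standard
    InChI; input order otherwise preserved. Idempotent."""
    seen: set[str] = set()
    kept = []
    for rec in cset.records:
        if not rec.inchi:
            raise ValueError(f"record {rec.id!r} has no InChI; standardize first")
        if rec.inchi in seen:
            continue
        seen.add(rec.inchi)
        kept.append(rec)
    return CompoundSet(records=kept, name=cset.name)


def murcko_scaffold(smiles: str) -> str:
    """Canonical SMILES of the Bemis–Murcko framework ('' for acyclic)."""
    mol = _mol_from_smiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return MurckoScaffold.MurckoScaffoldSmiles(mol=mol)


def cluster_by_scaffold(cset: CompoundSet) -> list[ScaffoldCluster]:
    """Partition records by Bemis–Murcko framework.

    Acyclic molecules (empty framework) form a single shared cluster.
    Cluster order follows first appearance in the input; every input record
    lands in exactly one cluster.
    """
    clusters: dict[str, ScaffoldCluster] = {}
    for rec in cset.records:
        key = murcko_scaffold(rec.smiles)
        if key not in clusters:
            clusters[key] = ScaffoldCluster(scaffold=key, members=[])
        clusters[key].members.append(rec)
    return list(clusters.values())


def select_representatives(clusters: list[ScaffoldCluster]) -> CompoundSet:
    """One record per cluster: the member with the highest activity.

    Missing activity counts as -infinity; ties (including the all-missing
    case) are broken by lexicographically smallest id, so the selection is
    reproducible.
    """
    if not clusters:
        raise ValueError("no clusters to select from")
    reps = []
    for cluster in clusters:
        if not cluster.members:
            raise ValueError(f"empty cluster {cluster.scaffold!r}")
        best = min(
            cluster.members,
            key=lambda r: (-(r.activity if r.activity is not None else float("-inf")), r.id),
        )
        cluster.representative = best
        reps.append(best)
    return CompoundSet(records=reps, name="representatives")


def curate(cset: CompoundSet) -> tuple[CompoundSet, list[ScaffoldCluster]]:
    """Full curation pipeline: standardize -> dedupe -> cluster -> representatives."""
    std = standardize_set(cset)
    unique = dedupe_by_inchi(std)
    clusters = cluster_by_scaffold(unique)
    reps = select_representatives(clusters)
    logger.info(
        "curate: %d in, %d standardized, %d unique, %d clusters",
        len(cset), len(std), len(unique), len(clusters),
    )
    return reps, clusters


def write_compounds_csv(cset: CompoundSet, path: str | Path, scaffolds: dict[str, str] | None = None) -> None:
    """Write a curated set as CSV (id, SMILES, InChI, activity[, scaffold])."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        header = ["id", "smiles", "inchi", "activity"]
        if scaffolds is not None:
            header.append("scaffold")
        writer.writerow(header)
        for rec in cset.records:
            row = [rec.id, rec.smiles, rec.inchi, "" if rec.activity is None else rec.activity]
            if scaffolds is not None:
                row.append(scaffolds.get(rec.id, ""))
            writer.writerow(row)
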