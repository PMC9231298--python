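"""Molecule/activity table IO, curation and 3D embedding.

The entry point of every analysis here is a table of molecules (SMILES)
with measured IC50 values.  Activities are modelled on the pIC50 scale,
the negative decadic logarithm of the molar IC50; for an IC50 given in
nanomolar this is ``pIC50 = 9 - log10(IC50_nM)``.

Curation removes records a regression model cannot use: unparseable
SMILES, multi-fragment inputs (salts, mixtures), organometallics, and
records whose activity is missing or ambiguous.  Duplicate structures
with consistent activity are collapsed to a single record; duplicates
whose reported activities disagree are discarded as ambiguous.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

RDLogger.DisableLog("rdApp.*")

# Elements tolerated in an "organic" drug-like record; anything outside
# this set (metals, metalloids beyond Si/B, lanthanides ...) marks the
# record as organometallic/inorganic and curation removes it.
ORGANIC_ELEMENTS = frozenset(
    [1, 5, 6, 7, 8, 9, 14, 15, 16, 17, 34, 35, 53]
)  # H B C N O F Si P S Cl Se Br I

#: Activity values qualified with a comparator ("<", ">", "~") are
#: treated as ambiguous, not coerced to numbers.
_QUALIFIED_RE = re.compile(r"^\s*[<>~]")


class CurationError(ValueError):
    """Raised for unusable configuration or input tables."""


@dataclass
class MoleculeRecord:
    """One curated molecule with optional activity and 3D geometry.

    ``mol`` is the hydrogen-suppressed RDKit molecule (aromaticity
    perceived by RDKit's default model); ``mol3d`` additionally carries
    explicit hydrogens and a single conformer when coordinates exist.
    """

    id: str
    smiles_input: str
    mol: Optional[Chem.Mol] = None
    mol3d: Optional[Chem.Mol] = None
    ic50_nM: Optional[float] = None
    pic50: Optional[float] = None
    geometry_source: Optional[str] = None  # "sdf" | "embedded" | None
    error: Optional[str] = None  # "unparseable" | "embed_failed" | ...

    @property
    def canonical_smiles(self) -> Optional[str]:
        if self.mol is None:
            return None
        return Chem.MolToSmiles(self.mol)

    @property
    def has_coords(self) -> bool:
        return self.mol3d is not None and self.mol3d.GetNumConformers() > 0


@dataclass
class CurationLog:
    n_input: int = 0
    n_removed_duplicates: int = 0
    n_removed_unparseable: int = 0
    n_removed_salts_organometallics: int = 0
    n_removed_ambiguous_activity: int = 0
    n_output: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)

    def check(self) -> None:
        removed = (
            self.n_removed_duplicates
            + self.n_removed_unparseable
            + self.n_removed_salts_organometallics
            + self.n_removed_ambiguous_activity
        )
        assert self.n_output == self.n_input - removed, "curation ledger imbalance"


def to_pic50(ic50_nM: float) -> float:
    """Convert an IC50 in nM to pIC50 (molar -log10 scale).

    ``pIC50 = -log10(IC50 [M]) = 9 - log10(IC50 [nM])``.
    """
    if not ic50_nM > 0:
        raise ValueError(f"IC50 must be positive, got {ic50_nM!r}")
    return 9.0 - math.log10(ic50_nM)


def from_pic50(pic50: float) -> float:
    """Inverse of :func:`to_pic50`: pIC50 back to IC50 in nM."""
    return 10.0 ** (9.0 - pic50)


def _parse_activity(raw: object) -> Optional[float]:
    """Parse an activity cell; qualified/non-numeric values give None."""
    if raw is None:
        return None
    text = str(raw).strip().replace(",", "")
    if not text or _QUALIFIED_RE.match(text):
        return None
    try:
        value = float(text)
    except ValueError:
        return None
    return value if math.isfinite(value) else None


def read_activity_table(
    path: str | Path,
    activity_column: str = "IC50",
    activity_unit: str = "nM",
    smiles_column: str = "SMILES",
    id_column: str = "id",
) -> list[MoleculeRecord]:
    """Read a CSV of molecules and activities into records.

    Rows with unparseable SMILES are kept but flagged (``error ==
    "unparseable"``) so curation can count them; rows with missing or
    qualified activities get ``pic50 = None``.
    """
    if activity_unit not in {"nM", "pIC50"}:
        raise CurationError(f"unknown activity unit {activity_unit!r}")
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CurationError(f"{path}: empty file")
        fieldnames = [f.strip() for f in reader.fieldnames]
        for col in (id_column, smiles_column, activity_column):
            if col not in fieldnames:
                raise CurationError(
                    f"{path}: missing column {col!r} (have {fieldnames})"
                )
        records = []
        for row in reader:
            row = {(k or "").strip(): v for k, v in row.items()}
            rid = (row.get(id_column) or "").strip()
            smiles = (row.get(smiles_column) or "").strip()
            mol = Chem.MolFromSmiles(smiles) if smiles else None
            activity = _parse_activity(row.get(activity_column))
            ic50 = pic50 = None
            if activity is not None:
                if activity_unit == "nM":
                    if activity > 0:
                        ic50 = activity
                        pic50 = to_pic50(activity)
                else:
                    pic50 = activity
                    ic50 = from_pic50(activity)
            records.append(
                MoleculeRecord(
                    id=rid,
                    smiles_input=smiles,
                    mol=mol,
                    ic50_nM=ic50,
                    pic50=pic50,
                    error=None if mol is not None else "unparseable",
                )
            )
    if not records:
        raise CurationError(f"{path}: no data rows")
    return records


def write_activity_table(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    """Write curated records as CSV (id, canonical SMILES, IC50, pIC50)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "SMILES", "IC50", "pIC50"])
        for rec in records:
            writer.writerow(
                [
                    rec.id,
                    rec.canonical_smiles or rec.smiles_input,
                    "" if rec.ic50_nM is None else repr(rec.ic50_nM),
                    "" if rec.pic50 is None else repr(rec.pic50),
                ]
            )


def _contains_metal(mol: Chem.Mol) -> bool:
    return any(a.GetAtomicNum() not in ORGANIC_ELEMENTS for a in mol.GetAtoms())


def curate(records: Sequence[MoleculeRecord]) -> tuple[list[MoleculeRecord], CurationLog]:
    """Apply the curation rules and return kept records plus a ledger.

    Order of application: unparseable SMILES; multi-fragment inputs and
    organometallics; missing/ambiguous activity; duplicates by canonical
    (stereo-aware) SMILES.  Duplicate groups whose activities agree keep
    the first record; groups with conflicting activities are removed
    entirely and counted as ambiguous.
    """
    log = CurationLog(n_input=len(records))
    stage: list[MoleculeRecord] = []
    for rec in records:
        if rec.mol is None or rec.mol.GetNumHeavyAtoms() < 1:
            log.n_removed_unparseable += 1
            continue
        if len(Chem.GetMolFrags(rec.mol)) > 1 or _contains_metal(rec.mol):
            log.n_removed_salts_organometallics += 1
            continue
        if rec.pic50 is None:
            log.n_removed_ambiguous_activity += 1
            continue
        stage.append(rec)

    by_smiles: dict[str, list[MoleculeRecord]] = {}
    for rec in stage:
        by_smiles.setdefault(rec.canonical_smiles, []).append(rec)

    kept: list[MoleculeRecord] = []
    for rec in stage:  # preserve input order
        group = by_smiles.get(rec.canonical_smiles)
        if group is None or group[0] is not rec:
            continue
        pic50s = [r.pic50 for r in group]
        if max(pic50s) - min(pic50s) < 1e-6:
            kept.append(rec)
            log.n_removed_duplicates += len(group) - 1
        else:
            log.n_removed_ambiguous_activity += len(group)
    log.n_output = len(kept)
    log.check()
    return kept, log


def embed3d(record: MoleculeRecord, seed: int = 42) -> MoleculeRecord:
    """Attach 3D coordinates by seeded distance-geometry embedding.

    Explicit hydrogens are added, a conformer is generated with the
    ETKDGv3 torsion-aware distance-geometry method and relaxed with the
    MMFF94 force field (UFF fallback).  The result is deterministic for
    a fixed seed.  Records already carrying coordinates (e.g. from an
    SDF) are returned unchanged.
    """
    if record.has_coords:
        return record
    if record.mol is None:
        return replace(record, error="unparseable")
    mol3d = Chem.AddHs(Chem.Mol(record.mol))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    conf_id = AllChem.EmbedMolecule(mol3d, params)
    if conf_id < 0:
        return replace(record, error="embed_failed")
    try:
        if AllChem.MMFFHasAllMoleculeParams(mol3d):
            AllChem.MMFFOptimizeMolecule(mol3d)
        else:
            AllChem.UFFOptimizeMolecule(mol3d)
    except Exception:
        pass  # unrefined DG geometry is still usable
    return replace(record, mol3d=mol3d, geometry_source="embedded")


def read_sdf_coords(path: str | Path, records: Sequence[MoleculeRecord]) -> int:
    """Attach conformers from an SDF (V2000) to matching records.

    Molecules are matched by SDF title or an ``id`` property against
    record ids.  Returns the number of records that received
    coordinates.
    """
    by_id = {rec.id: rec for rec in records}
    n_attached = 0
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    for mol in supplier:
        if mol is None or mol.GetNumConformers() == 0:
            continue
        key = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        if not key and mol.HasProp("id"):
            key = mol.GetProp("id")
        rec = by_id.get(key.strip())
        if rec is None:
            continue
        rec.mol3d = mol
        rec.geometry_source = "sdf"
        n_attached += 1
    return n_attached
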