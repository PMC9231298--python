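"""Typed-atom perception and molecular descriptor computation.

Three descriptor families are implemented:

``f<source><target><k>B`` — typed atom-pair frequencies at exact bond
distance.  The value counts *target* atoms whose nearest *source* atom
(topological bond distance over the hydrogen-suppressed graph, the atom
itself excluded from its own source set) lies at exactly ``k`` bonds.
A target atom with any source atom closer than ``k`` is excluded, and a
target atom with no source within ``k`` bonds does not count.  This
"nearest source at exactly k" reading is what makes descriptors such as
``fsp3CringC2B`` (ring carbons whose nearest sp3 carbon sits at two
bonds) well defined.

``com_<element>_<r>A`` — number of atoms of an element within ``r``
angstroms of the molecular center of mass (mass-weighted over all atoms
including explicit hydrogens); requires 3D coordinates.

``Saturated_Carbo_Rings`` — number of SSSR rings that are all-carbon,
non-aromatic and contain only single bonds.

Atom typing uses conventional medicinal-chemistry rules (lipophilic
atoms, H-bond donors/acceptors, planar nitrogens); the exact rules are
documented per type below because descriptor values depend on them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .curation import MoleculeRecord

__all__ = [
    "TYPE_NAMES",
    "MODEL_A_DESCRIPTORS",
    "AtomTyping",
    "DescriptorMatrix",
    "perceive_types",
    "bond_distances",
    "pairfreq",
    "com_shell_count",
    "saturated_carbo_rings",
    "model_a_descriptors",
    "generate_pool",
]

#: Recognised atom-type flags, in a fixed order.
TYPE_NAMES = (
    "sp3C", "ringC", "aroC", "aroN", "plaN", "N",
    "sp3O", "sulfonS", "lipo", "acc", "don",
)

#: The seven descriptors of the published BRD-4 model, with their
#: family definitions (pair-frequency source/target/k, center-of-mass
#: shell, or ring count).
MODEL_A_DESCRIPTORS: dict[str, tuple] = {
    "fsp3CringC2B": ("pairfreq", "sp3C", "ringC", 2),
    "com_C_4A": ("com_shell", "C", 4.0),
    "Saturated_Carbo_Rings": ("ring_count",),
    "fsulfonSaroC8B": ("pairfreq", "sulfonS", "aroC", 8),
    "flipoacc3B": ("pairfreq", "lipo", "acc", 3),
    "fsp3OaroN6B": ("pairfreq", "sp3O", "aroN", 6),
    "fplaNN4B": ("pairfreq", "plaN", "N", 4),
}


class DescriptorError(ValueError):
    """Raised for unusable descriptor requests (unknown type, no 3D)."""


@dataclass
class AtomTyping:
    """Per-atom boolean type flags on the hydrogen-suppressed graph.

    ``sets[name]`` is the set of heavy-atom indices carrying the flag.
    """

    n_heavy: int
    sets: dict[str, frozenset[int]]

    def __getitem__(self, name: str) -> frozenset[int]:
        try:
            return self.sets[name]
        except KeyError:
            raise DescriptorError(
                f"unknown atom type {name!r}; known: {sorted(self.sets)}"
            ) from None


def _is_amide_nitrogen(atom: Chem.Atom) -> bool:
    """Nitrogen single-bonded to a carbonyl (or thiocarbonyl) carbon."""
    for nbr in atom.GetNeighbors():
        if nbr.GetAtomicNum() != 6:
            continue
        for bond in nbr.GetBonds():
            other = bond.GetOtherAtom(nbr)
            if (
                bond.GetBondType() == Chem.BondType.DOUBLE
                and other.GetAtomicNum() in (8, 16)
            ):
                return True
    return False


def perceive_types(record: MoleculeRecord | Chem.Mol) -> AtomTyping:
    """Assign every heavy atom its type flags.

    Rules (heavy neighbours only; hydrogens implicit):

    - ``sp3C``: carbon, non-aromatic, all bonds single.
    - ``ringC``: carbon in at least one ring; ``aroC``: aromatic carbon.
    - ``N`` any nitrogen; ``aroN`` aromatic nitrogen.
    - ``plaN`` (planar nitrogen): aromatic, or carrying a double bond,
      or conjugated — directly bonded to an aromatic atom or to a
      carbonyl carbon.
    - ``sp3O``: oxygen, non-aromatic, all bonds single.
    - ``sulfonS``: sulfur with exactly two double bonds to oxygen and
      two further single bonds (the -SO2- sulfone/sulfonamide sulfur).
    - ``lipo``: carbon whose heavy neighbours are all carbons, or a
      Cl/Br/I halogen.
    - ``acc`` (H-bond acceptor): N or O, excluding positively charged
      atoms, amide/thioamide nitrogens and pyrrole-type aromatic N-H.
    - ``don`` (H-bond donor): N or O bearing at least one hydrogen.
    """
    mol = record.mol if isinstance(record, MoleculeRecord) else record
    if mol is None:
        raise DescriptorError("record has no parsed structure")
    mol = Chem.RemoveHs(mol)
    sets: dict[str, set[int]] = {name: set() for name in TYPE_NAMES}
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        z = atom.GetAtomicNum()
        bonds = atom.GetBonds()
        all_single = all(b.GetBondType() == Chem.BondType.SINGLE for b in bonds)
        has_double = any(b.GetBondType() == Chem.BondType.DOUBLE for b in bonds)
        heavy_nbrs = [n for n in atom.GetNeighbors() if n.GetAtomicNum() > 1]
        if z == 6:
            # bonds required: an isolated carbon carries no hybridisation
            if bonds and not atom.GetIsAromatic() and all_single:
                sets["sp3C"].add(i)
            if atom.IsInRing():
                sets["ringC"].add(i)
            if atom.GetIsAromatic():
                sets["aroC"].add(i)
            if all(n.GetAtomicNum() == 6 for n in heavy_nbrs):
                sets["lipo"].add(i)
        elif z in (17, 35, 53):
            sets["lipo"].add(i)
        elif z == 7:
            sets["N"].add(i)
            aromatic = atom.GetIsAromatic()
            if aromatic:
                sets["aroN"].add(i)
            conjugated = any(
                n.GetIsAromatic() for n in heavy_nbrs
            ) or _is_amide_nitrogen(atom)
            if aromatic or has_double or conjugated:
                sets["plaN"].add(i)
            if atom.GetFormalCharge() <= 0 and not _is_amide_nitrogen(atom):
                if not (aromatic and atom.GetTotalNumHs() > 0):
                    sets["acc"].add(i)
            if atom.GetTotalNumHs() > 0:
                sets["don"].add(i)
        elif z == 8:
            if not atom.GetIsAromatic() and all_single:
                sets["sp3O"].add(i)
            if atom.GetFormalCharge() <= 0:
                sets["acc"].add(i)
            if atom.GetTotalNumHs() > 0:
                sets["don"].add(i)
        elif z == 16:
            dbl_o = sum(
                1
                for b in bonds
                if b.GetBondType() == Chem.BondType.DOUBLE
                and b.GetOtherAtom(atom).GetAtomicNum() == 8
            )
            single = sum(1 for b in bonds if b.GetBondType() == Chem.BondType.SINGLE)
            if dbl_o == 2 and single == 2:
                sets["sulfonS"].add(i)
    return AtomTyping(
        n_heavy=mol.GetNumHeavyAtoms(),
        sets={name: frozenset(v) for name, v in sets.items()},
    )


def bond_distances(record: MoleculeRecord | Chem.Mol) -> np.ndarray:
    """Shortest-path bond counts between heavy atoms.

    Returns a symmetric matrix of minimum bond counts on the
    hydrogen-suppressed graph, with ``inf`` across disconnected
    fragments.
    """
    mol = record.mol if isinstance(record, MoleculeRecord) else record
    if mol is None:
        raise DescriptorError("record has no parsed structure")
    mol = Chem.RemoveHs(mol)
    dist = np.array(Chem.GetDistanceMatrix(mol), dtype=float)
    n = mol.GetNumAtoms()
    dist[dist > n] = np.inf  # RDKit marks unreachable pairs with 1e8
    return dist


def pairfreq(
    typing: AtomTyping,
    dist: np.ndarray,
    source: str,
    target: str,
    k: int,
) -> int:
    """Count target atoms whose nearest source atom is exactly k bonds away.

    The target atom itself is excluded from its own source set.  Target
    atoms with a source atom nearer than ``k`` are excluded; target
    atoms with no source atom within ``k`` bonds are not counted.
    """
    if k < 1:
        raise DescriptorError(f"k must be >= 1, got {k}")
    src = typing[source]
    tgt = typing[target]
    if not src or not tgt:
        return 0
    count = 0
    for t in tgt:
        nearest = min((dist[t, s] for s in src if s != t), default=np.inf)
        if nearest == k:
            count += 1
    return count


def com_shell_count(
    record: MoleculeRecord, element: str, radius: float
) -> int:
    """Atoms of ``element`` within ``radius`` angstroms of the center of mass.

    The center of mass is mass-weighted over *all* atoms of the 3D
    structure, explicit hydrogens included; the shell is closed
    (distance <= radius).
    """
    if not record.has_coords:
        raise DescriptorError(
            f"molecule {record.id!r}: 3D coordinates required for com shell counts"
        )
    mol = record.mol3d
    conf = mol.GetConformer()
    coords = np.asarray(conf.GetPositions(), dtype=float)
    masses = np.array([a.GetMass() for a in mol.GetAtoms()])
    com = (coords * masses[:, None]).sum(axis=0) / masses.sum()
    count = 0
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != element:
            continue
        if np.linalg.norm(coords[atom.GetIdx()] - com) <= radius:
            count += 1
    return count


def saturated_carbo_rings(record: MoleculeRecord | Chem.Mol) -> int:
    """Number of SSSR rings that are saturated and all-carbon.

    A ring counts iff every ring atom is a non-aromatic carbon and
    every ring bond is a single bond (so cyclohexene and piperidine
    rings do not count, decalin contributes two).
    """
    mol = record.mol if isinstance(record, MoleculeRecord) else record
    if mol is None:
        raise DescriptorError("record has no parsed structure")
    mol = Chem.RemoveHs(mol)
    ring_info = mol.GetRingInfo()
    count = 0
    for atom_ring, bond_ring in zip(ring_info.AtomRings(), ring_info.BondRings()):
        atoms_ok = all(
            mol.GetAtomWithIdx(i).GetAtomicNum() == 6
            and not mol.GetAtomWithIdx(i).GetIsAromatic()
            for i in atom_ring
        )
        bonds_ok = all(
            mol.GetBondWithIdx(b).GetBondType() == Chem.BondType.SINGLE
            for b in bond_ring
        )
        if atoms_ok and bonds_ok:
            count += 1
    return count


def parse_descriptor_name(name: str) -> tuple:
    """Resolve a descriptor name to its definition tuple.

    Understands ``f<source><target><k>B`` (type names matched greedily
    against the known vocabulary), ``com_<element>_<r>A`` and
    ``Saturated_Carbo_Rings``.
    """
    if name == "Saturated_Carbo_Rings":
        return ("ring_count",)
    m = re.fullmatch(r"com_([A-Z][a-z]?)_([0-9.]+)A", name)
    if m:
        return ("com_shell", m.group(1), float(m.group(2)))
    m = re.fullmatch(r"f(\w+?)(\d+)B", name)
    if m:
        body, k = m.group(1), int(m.group(2))
        for source in TYPE_NAMES:
            if body.startswith(source) and body[len(source):] in TYPE_NAMES:
                return ("pairfreq", source, body[len(source):], k)
    raise DescriptorError(f"cannot parse descriptor name {name!r}")


def compute_descriptor(record: MoleculeRecord, definition: tuple) -> float:
    """Evaluate one descriptor definition tuple on a record."""
    family = definition[0]
    if family == "pairfreq":
        _, source, target, k = definition
        typing = perceive_types(record)
        dist = bond_distances(record)
        return float(pairfreq(typing, dist, source, target, k))
    if family == "com_shell":
        _, element, radius = definition
        return float(com_shell_count(record, element, radius))
    if family == "ring_count":
        return float(saturated_carbo_rings(record))
    raise DescriptorError(f"unknown descriptor family {definition!r}")


def model_a_descriptors(record: MoleculeRecord) -> dict[str, float]:
    """Compute the seven descriptors of the published model.

    Requires 3D coordinates for ``com_C_4A``; raises naming that
    descriptor if they are absent.
    """
    values: dict[str, float] = {}
    typing = perceive_types(record)
    dist = bond_distances(record)
    for name, definition in MODEL_A_DESCRIPTORS.items():
        if definition[0] == "pairfreq":
            _, source, target, k = definition
            values[name] = float(pairfreq(typing, dist, source, target, k))
        elif definition[0] == "com_shell":
            values[name] = float(com_shell_count(record, *definition[1:]))
        else:
            values[name] = float(saturated_carbo_rings(record))
    return values


def _format_radius(radius: float) -> str:
    return str(int(radius)) if float(radius).is_integer() else str(radius)


@dataclass
class DescriptorMatrix:
    """Molecules x named descriptors, with each column's definition."""

    data: pd.DataFrame  # index: molecule ids; columns: descriptor names
    definitions: dict[str, tuple] = field(default_factory=dict)

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)

    def select(self, names: Sequence[str]) -> "DescriptorMatrix":
        return DescriptorMatrix(
            data=self.data[list(names)].copy(),
            definitions={n: self.definitions.get(n, ()) for n in names},
        )

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="id")


def generate_pool(
    records: Sequence[MoleculeRecord],
    sources: Iterable[str] = ("sp3C",),
    targets: Iterable[str] = ("ringC",),
    k_range: Iterable[int] = (1, 2, 3),
    com_elements: Iterable[str] = (),
    com_radii: Iterable[float] = (),
    include_ring_count: bool = False,
    extra: Optional[Mapping[str, tuple]] = None,
) -> DescriptorMatrix:
    """Compute the Cartesian product of requested descriptor families.

    Pair-frequency names follow ``f<source><target><k>B``; shell counts
    ``com_<element>_<r>A``.  ``extra`` adds arbitrary named definition
    tuples (e.g. the published model's exact descriptor set).
    """
    definitions: dict[str, tuple] = {}
    for source in sources:
        for target in targets:
            for k in k_range:
                definitions[f"f{source}{target}{k}B"] = (
                    "pairfreq", source, target, int(k),
                )
    for element in com_elements:
        for radius in com_radii:
            definitions[f"com_{element}_{_format_radius(radius)}A"] = (
                "com_shell", element, float(radius),
            )
    if include_ring_count:
        definitions["Saturated_Carbo_Rings"] = ("ring_count",)
    if extra:
        definitions.update({k: tuple(v) for k, v in extra.items()})

    rows = []
    for rec in records:
        typing = perceive_types(rec)
        dist = bond_distances(rec)
        row = {}
        for name, definition in definitions.items():
            if definition[0] == "pairfreq":
                _, source, target, k = definition
                row[name] = float(pairfreq(typing, dist, source, target, k))
            else:
                row[name] = compute_descriptor(rec, definition)
        rows.append(row)
    data = pd.DataFrame(rows, index=[rec.id for rec in records], columns=list(definitions))
    return DescriptorMatrix(data=data, definitions=definitions)
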