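"""Synthetic molecule sets with a planted structure-activity relationship.

The generator assembles drug-like molecules from a versioned fragment
library (aromatic and saturated scaffolds decorated with sulfone arms,
alkoxy groups, N-heterocycles, amines, carbocycles ...) and assigns
each molecule a pIC50 from a known linear model over descriptors the
package itself computes, plus Gaussian noise:

    pIC50_i = intercept + sum_j coeff_j * descriptor_j(mol_i) + eps_i

Because the planted model is known exactly, every downstream stage —
pruning, GA subset selection, breaking-point size choice, coefficient
estimation, validation statistics — can be tested for parameter
recovery.  Defaults plant three descriptors with model-scale
coefficients and noise_sd = 0.1 on a 200-molecule set.

``make_decoy_pool`` stresses pruning and selection by appending
duplicate, near-constant and pure-noise columns to a real descriptor
matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .curation import MoleculeRecord, from_pic50
from .descriptors import (
    DescriptorMatrix,
    compute_descriptor,
    generate_pool,
    parse_descriptor_name,
)


class SyntheticError(ValueError):
    pass


def load_fragment_library() -> dict:
    """Load the packaged scaffold/substituent library."""
    with resources.files("brd4qsar.assets").joinpath("fragments.json").open() as fh:
        return json.load(fh)


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults: 200 molecules, three planted descriptors with
    coefficients on the scale of the packaged model, noise_sd 0.1.
    ``clip_range`` optionally clips activities into a pIC50 window
    (e.g. (4.82, 9.0), the span of IC50 15 uM .. 1 nM).
    """

    n_molecules: int = 200
    planted_descriptors: tuple[str, ...] = (
        "fsp3CringC2B",
        "flipoacc3B",
        "fplaNN4B",
    )
    planted_coefficients: tuple[float, ...] = (0.40, 0.62, -0.37)
    planted_intercept: float = 4.27
    noise_sd: float = 0.1
    seed: int = 0
    clip_range: Optional[tuple[float, float]] = None
    fragment_library: Optional[dict] = None
    max_slots: int = 2

    def __post_init__(self) -> None:
        if len(self.planted_descriptors) != len(self.planted_coefficients):
            raise SyntheticError("planted descriptors and coefficients differ in length")
        if self.noise_sd < 0:
            raise SyntheticError("noise_sd must be >= 0")


@dataclass
class TruthRecord:
    """The exact planted model behind a generated dataset."""

    planted_descriptors: list[str]
    planted_coefficients: list[float]
    planted_intercept: float
    noise_sd: float
    seed: int
    descriptor_values: pd.DataFrame  # molecules x planted descriptors
    pic50_noiseless: np.ndarray
    decoy_labels: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "planted_descriptors": self.planted_descriptors,
            "planted_coefficients": self.planted_coefficients,
            "planted_intercept": self.planted_intercept,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "pic50_noiseless": self.pic50_noiseless.tolist(),
            "decoy_labels": self.decoy_labels,
        }


def _assemble(template: str, substituents: Sequence[str]) -> str:
    out = template
    for i, sub in enumerate(substituents):
        slot = "{%d}" % i
        if sub == "":
            out = out.replace(f"({slot})", "").replace(slot, "")
        else:
            out = out.replace(slot, sub)
    return out


def _validate_library(library: dict) -> None:
    scaffolds = library.get("scaffolds") or []
    substituents = library.get("substituents")
    if not scaffolds or substituents is None:
        raise SyntheticError("fragment library needs 'scaffolds' and 'substituents'")
    probe = next(s for s in substituents if s) if any(substituents) else "C"
    for tpl in scaffolds:
        n_slots = sum(("{%d}" % i) in tpl for i in range(10))
        smi = _assemble(tpl, [probe] * n_slots)
        if Chem.MolFromSmiles(smi) is None:
            raise SyntheticError(f"invalid scaffold template {tpl!r}")
    for sub in substituents:
        if sub and Chem.MolFromSmiles(_assemble("C({0})", [sub])) is None:
            raise SyntheticError(f"invalid substituent {sub!r}")


def generate(spec: SyntheticSpec) -> tuple[list[MoleculeRecord], TruthRecord]:
    """Generate a deduplicated molecule set with planted activities.

    Molecules are assembled by seeded random scaffold-substituent
    combination until ``n_molecules`` unique canonical structures
    exist; the activity of each is the planted linear model evaluated
    on its computed descriptors plus Gaussian noise.  Byte-identical
    across runs for a fixed spec.
    """
    library = spec.fragment_library or load_fragment_library()
    _validate_library(library)
    scaffolds: list[str] = list(library["scaffolds"])
    substituents: list[str] = list(library["substituents"])
    definitions = [parse_descriptor_name(n) for n in spec.planted_descriptors]

    rng = np.random.default_rng(spec.seed)
    seen: dict[str, Chem.Mol] = {}
    attempts = 0
    max_attempts = max(2000, 100 * spec.n_molecules)
    while len(seen) < spec.n_molecules and attempts < max_attempts:
        attempts += 1
        tpl = scaffolds[rng.integers(len(scaffolds))]
        n_slots = sum(("{%d}" % i) in tpl for i in range(10))
        chosen = [substituents[rng.integers(len(substituents))] for _ in range(n_slots)]
        mol = Chem.MolFromSmiles(_assemble(tpl, chosen))
        if mol is None:
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical not in seen:
            seen[canonical] = mol
    if len(seen) < spec.n_molecules:
        raise SyntheticError(
            f"fragment library exhausted: {len(seen)} unique molecules "
            f"after {attempts} attempts (requested {spec.n_molecules})"
        )

    records: list[MoleculeRecord] = []
    width = len(str(spec.n_molecules))
    desc_rows = []
    for i, (canonical, mol) in enumerate(seen.items(), start=1):
        rec = MoleculeRecord(id=f"S{i:0{width}d}", smiles_input=canonical, mol=mol)
        desc_rows.append(
            {
                name: compute_descriptor(rec, definition)
                for name, definition in zip(spec.planted_descriptors, definitions)
            }
        )
        records.append(rec)
    desc = pd.DataFrame(desc_rows, index=[r.id for r in records])

    coeffs = np.asarray(spec.planted_coefficients, dtype=float)
    noiseless = spec.planted_intercept + desc.to_numpy(dtype=float) @ coeffs
    noise = rng.normal(0.0, spec.noise_sd, size=len(records)) if spec.noise_sd > 0 \
        else np.zeros(len(records))
    pic50 = noiseless + noise
    if spec.clip_range is not None:
        pic50 = np.clip(pic50, *spec.clip_range)
    for rec, value in zip(records, pic50):
        rec.pic50 = float(value)
        rec.ic50_nM = from_pic50(float(value))

    truth = TruthRecord(
        planted_descriptors=list(spec.planted_descriptors),
        planted_coefficients=coeffs.tolist(),
        planted_intercept=spec.planted_intercept,
        noise_sd=spec.noise_sd,
        seed=spec.seed,
        descriptor_values=desc,
        pic50_noiseless=noiseless,
    )
    return records, truth


#: Pool used throughout the parameter-recovery studies: 27 typed
#: pair-frequency columns plus the ring count and two published-model
#: descriptors = 30 candidate descriptors containing the planted three.
DEFAULT_POOL_SPEC = dict(
    sources=("sp3C", "lipo", "plaN"),
    targets=("ringC", "acc", "N"),
    k_range=(2, 3, 4),
    include_ring_count=True,
    extra={
        "fsp3OaroN6B": ("pairfreq", "sp3O", "aroN", 6),
        "fsulfonSaroC8B": ("pairfreq", "sulfonS", "aroC", 8),
    },
)


def default_pool(records: Sequence[MoleculeRecord]) -> DescriptorMatrix:
    """The 30-descriptor candidate pool used in the recovery studies."""
    return generate_pool(records, **DEFAULT_POOL_SPEC)


def make_decoy_pool(
    records: Sequence[MoleculeRecord],
    n_decoys: int = 9,
    seed: int = 0,
    base: Optional[DescriptorMatrix] = None,
) -> tuple[DescriptorMatrix, dict[str, str]]:
    """Append decoy columns to a real descriptor matrix.

    Decoys cycle through three kinds: exact duplicates of real columns
    (trip the |R| > 0.95 pruning), near-constant columns (one value in
    more than 98% of molecules) and pure-noise columns scaled to the
    real columns' spread.  Returns the augmented matrix and a map
    decoy name -> kind.
    """
    matrix = base if base is not None else default_pool(records)
    df = matrix.data.copy()
    rng = np.random.default_rng(seed)
    n = len(df)
    real = [c for c in df.columns if df[c].std() > 0]
    typical_sd = float(np.median([df[c].std() for c in real])) if real else 1.0
    labels: dict[str, str] = {}
    definitions = dict(matrix.definitions)
    for i in range(n_decoys):
        kind = ("duplicate", "constant", "noise")[i % 3]
        # the 'z' prefix makes an exact duplicate (which ties with its
        # source on |corr to y|) lose the lexicographic tie-break
        name = f"zdecoy_{kind}_{i}"
        if kind == "duplicate" and real:
            src = real[rng.integers(len(real))]
            col = df[src].to_numpy(dtype=float).copy()
        elif kind == "constant":
            col = np.zeros(n)
            n_hot = max(1, int(np.ceil(0.005 * n)))  # 99.5% one value
            col[rng.choice(n, size=n_hot, replace=False)] = 1.0
        else:
            col = rng.normal(0.0, typical_sd, size=n)
        df[name] = col
        labels[name] = kind
        definitions[name] = ("decoy", kind)
    return DescriptorMatrix(data=df, definitions=definitions), labels
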