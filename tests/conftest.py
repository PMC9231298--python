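"""Shared fixtures: reference molecules and independent oracles.

The pair-frequency oracle here deliberately avoids the package's
distance machinery: it does its own breadth-first search over the bond
graph, so descriptor tests compare two independent routes.
"""

from __future__ import annotations

from collections import deque

import pytest
from rdkit import Chem, RDLogger

from brd4qsar.curation import MoleculeRecord

RDLogger.DisableLog("rdApp.*")

# The ten reference BRD-4 inhibitors (five most / five least active)
# shipped with the published model: id -> (SMILES, IC50 nM, pIC50).
REFERENCE_MOLECULES = {
    "207": ("Cn1cc2-c3cc(CS(C)(=O)=O)ccc3N(Cc3c[nH]c(=O)c1c23)c1ccccn1", 1.0, 9.0),
    "692": ("Cn1cc2-c3cc(CS(C)(=O)=O)ccc3N(Cc3c[nH]c(c23)c1=O)c1ccc(F)cc1", 1.5, 8.824),
    "158": ("CCS(=O)(=O)c1ccc2Oc3ccc(F)cc3CCCCOc3cc(=O)n(C)cc3-c2c1", 2.0, 8.699),
    "570": ("COc1cc2c(cc1-c1c(C)noc1C)[nH]c1nc(C)nc(Nc3cc(nn3C)C3CC3)c21", 2.0, 8.699),
    "688": ("Cn1cc2CN(c3ccc(F)cc3)c3ccc(CS(C)(=O)=O)cc3-c3c[nH]c(=O)c1c23", 2.5, 8.602),
    "633": ("CC(=O)N1CCc2c(C1)c(nn2C1CCOCC1)-c1cccc2c(Cl)cncc12", 14000.0, 4.854),
    "242": ("CC(=O)N1CCc2c(C1)c(Nc1cccc(C)c1)nn2C1CC1", 15000.0, 4.824),
    "385": ("Cc1noc(C)c1-c1ccc(C)c(c1)S(=O)(=O)NC1CCNCC1", 15000.0, 4.824),
    "634": ("CCc1cncc2c(cccc12)-c1nn(C2CCOCC2)c2CCN(Cc12)C(C)=O", 15000.0, 4.824),
    "721": ("CNC(=O)c1cn(C)c(=O)c2ccccc12", 15000.0, 4.824),
}


def record_from_smiles(smiles: str, mol_id: str = "m") -> MoleculeRecord:
    mol = Chem.MolFromSmiles(smiles)
    assert mol is not None, f"fixture SMILES failed to parse: {smiles}"
    return MoleculeRecord(id=mol_id, smiles_input=smiles, mol=mol)


@pytest.fixture
def make_record():
    return record_from_smiles


@pytest.fixture(scope="session")
def reference_records() -> list[MoleculeRecord]:
    return [
        record_from_smiles(smiles, mol_id)
        for mol_id, (smiles, _, _) in REFERENCE_MOLECULES.items()
    ]


def bfs_distances(mol: Chem.Mol, start: int) -> dict[int, int]:
    """Plain BFS over the heavy-atom bond graph (oracle path)."""
    mol = Chem.RemoveHs(mol)
    adjacency: dict[int, list[int]] = {a.GetIdx(): [] for a in mol.GetAtoms()}
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adjacency[i].append(j)
        adjacency[j].append(i)
    dist = {start: 0}
    queue = deque([start])
    while queue:
        u = queue.popleft()
        for v in adjacency[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def pairfreq_oracle(mol: Chem.Mol, sources: set[int], targets: set[int], k: int) -> int:
    """All-pairs brute force: target atoms whose nearest source is at k."""
    count = 0
    for t in targets:
        dist = bfs_distances(mol, t)
        nearest = min(
            (dist[s] for s in sources if s != t and s in dist), default=None
        )
        if nearest == k:
            count += 1
    return count
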