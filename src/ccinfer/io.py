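"""Readers and writers: SDF (V2000), SMILES, property CSV, adjacency dumps.

Molecule parsing goes through RDKit.  Inputs are kekulized on load
(explicit 1/2/3 bond orders) and hydrogens are made explicit; records
that cannot be kekulized are skipped with a logged reason rather than
guessed at, since every descriptor depends on concrete bond
multiplicities.  Per-record parse errors are collected, not fatal.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import rdDepictor

from .chemgraph import ChemicalGraph
from .elements import ElementTable, default_element_table

log = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

_BOND_TYPES = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}


def from_rdkit(mol: "Chem.Mol", table: ElementTable | None = None) -> ChemicalGraph:
    """Convert an RDKit molecule to an explicit-hydrogen chemical graph."""
    table = table or default_element_table()
    mol = Chem.Mol(mol)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    mol = Chem.AddHs(mol)
    g = ChemicalGraph()
    orders: dict[int, int] = {}
    for bond in mol.GetBonds():
        o = bond.GetBondTypeAsDouble()
        if o not in (1.0, 2.0, 3.0):
            raise ValueError(f"unsupported bond order {o}")
        orders[bond.GetIdx()] = int(o)
    valence = {a.GetIdx(): 0 for a in mol.GetAtoms()}
    for bond in mol.GetBonds():
        m = orders[bond.GetIdx()]
        valence[bond.GetBeginAtomIdx()] += m
        valence[bond.GetEndAtomIdx()] += m
    for atom in mol.GetAtoms():
        if atom.GetFormalCharge() != 0:
            raise ValueError("charged atoms are not supported")
        code = table.code_for(atom.GetSymbol(), valence[atom.GetIdx()])
        g.add_atom(atom.GetIdx(), code)
    for bond in mol.GetBonds():
        g.add_bond(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), orders[bond.GetIdx()])
    return g


def to_rdkit(graph: ChemicalGraph) -> "Chem.Mol":
    """Convert a chemical graph back to an RDKit molecule (explicit H kept)."""
    rw = Chem.RWMol()
    index: dict = {}
    for v in graph.atoms():
        atom = Chem.Atom(ElementTable.symbol(graph.element(v)))
        atom.SetNoImplicit(True)
        index[v] = rw.AddAtom(atom)
    for (u, v) in graph.bonds():
        rw.AddBond(index[u], index[v], _BOND_TYPES[graph.order(u, v)])
    mol = rw.GetMol()
    Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_ADJUSTHS)
    return mol


def read_molecules(path: str | Path, fmt: str | None = None,
                   table: ElementTable | None = None):
    """Read molecules from an SDF or SMILES file.

    Returns ``(mols, ids, errors)``: explicit-hydrogen chemical graphs,
    their record identifiers, and a list of skipped-record messages.
    """
    path = Path(path)
    if fmt is None:
        fmt = "smiles" if path.suffix.lower() in (".smi", ".smiles", ".txt") else "sdf"
    table = table or default_element_table()
    mols, ids, errors = [], [], []
    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        for i, mol in enumerate(supplier):
            name = f"mol{i}"
            if mol is not None and mol.HasProp("_Name") and mol.GetProp("_Name"):
                name = mol.GetProp("_Name")
            if mol is None:
                errors.append(f"record {i}: RDKit failed to parse")
                continue
            try:
                mols.append(from_rdkit(mol, table))
                ids.append(name)
            except Exception as exc:  # kekulization, charges, odd valences
                errors.append(f"record {i} ({name}): {exc}")
    elif fmt == "smiles":
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles, name = parts[0], (parts[1] if len(parts) > 1 else f"mol{i}")
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                errors.append(f"line {i + 1}: unparsable SMILES {smiles!r}")
                continue
            try:
                mols.append(from_rdkit(mol, table))
                ids.append(name)
            except Exception as exc:
                errors.append(f"line {i + 1} ({smiles}): {exc}")
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'sdf' or 'smiles'")
    for msg in errors:
        log.warning("skipped %s", msg)
    if not mols:
        log.warning("no molecules read from %s", path)
    return mols, ids, errors


def write_sdf(mols, ids, path: str | Path) -> None:
    """Write chemical graphs to an SDF file (V2000, kekulized)."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    try:
        for mol_id, g in zip(ids, mols):
            mol = to_rdkit(g)
            mol.SetProp("_Name", str(mol_id))
            rdDepictor.Compute2DCoords(mol)
            writer.write(mol)
    finally:
        writer.close()


def write_adjacency(graph: ChemicalGraph, path: str | Path) -> None:
    """Plain-text dump: one atom line (id element) then one bond line per edge."""
    lines = [f"atoms {graph.n_atoms()}"]
    for v in sorted(graph.atoms(), key=repr):
        lines.append(f"{v} {graph.element(v)}")
    lines.append(f"bonds {len(graph.bonds())}")
    for u, v in sorted(graph.bonds(), key=repr):
        lines.append(f"{u} {v} {graph.order(u, v)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_properties(path: str | Path) -> pd.Series:
    """Property table CSV: first column molecule id, second the value."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("property CSV needs at least two columns (id, value)")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str))
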