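"""File I/O: receptors from PDB, ligands and poses from/to SD files.

PDB parsing goes through Biopython; SD files (V2000, multi-record conformer
convention) go through rdkit with sanitization disabled, so that synthetic
pseudo-molecules with unusual valences survive a round trip.  Scores travel
as SD data fields ``<grid_score>``, ``<fa_score>``, ``<rmsd>``.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

from .model import Molecule, Pose, Receptor, detect_rotatable_bonds

__all__ = ["read_pdb", "write_pdb", "read_sdf", "write_sdf"]

BACKBONE_ATOM_NAMES = {"N", "CA", "C", "O"}
_WATER_RES = {"HOH", "WAT", "DOD"}


class PDBParseError(ValueError):
    pass


def read_pdb(path, exclude_waters: bool = True, exclude_hydrogens: bool = True) -> Receptor:
    """Read ATOM/HETATM records into a :class:`Receptor`.

    Waters and hydrogens are excluded by default.  The backbone mask is set
    from atom names N/CA/C/O of standard (ATOM-record) residues.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    path = Path(path)
    parser = PDBParser(QUIET=True, PERMISSIVE=False)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure("receptor", str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise PDBParseError(f"malformed PDB record in {path}: {exc}") from exc

    elements, coords, backbone, names, resnames, resids, chains = (
        [], [], [], [], [], [], [])
    for model in structure:
        for chain in model:
            for residue in chain:
                resname = residue.get_resname().strip()
                if exclude_waters and resname in _WATER_RES:
                    continue
                het_flag = residue.id[0].strip()
                for atom in residue:
                    element = (atom.element or atom.get_name()[0]).capitalize()
                    if exclude_hydrogens and element == "H":
                        continue
                    elements.append(element)
                    coords.append(atom.get_coord().astype(float))
                    names.append(atom.get_name())
                    backbone.append(
                        het_flag == "" and atom.get_name() in BACKBONE_ATOM_NAMES
                    )
                    resnames.append(resname)
                    resids.append(residue.id[1])
                    chains.append(chain.id)
        break  # first model only

    if not elements:
        raise PDBParseError(f"no ATOM/HETATM records found in {path}")
    return Receptor(
        elements=elements,
        coords=np.array(coords),
        backbone_mask=np.array(backbone, dtype=bool),
        atom_names=names,
        res_names=resnames,
        res_ids=resids,
        chain_ids=chains,
    )


def write_pdb(receptor: Receptor, path) -> None:
    """Write a receptor as plain ATOM records (deterministic byte output)."""
    lines = []
    for i in range(receptor.n_atoms):
        name = receptor.atom_names[i] if receptor.atom_names else receptor.elements[i]
        resname = receptor.res_names[i] if receptor.res_names else "GLY"
        resid = receptor.res_ids[i] if receptor.res_ids else 1
        chain = receptor.chain_ids[i] if receptor.chain_ids else "A"
        x, y, z = receptor.coords[i]
        pad_name = f" {name:<3s}" if len(name) < 4 else name
        lines.append(
            f"ATOM  {i + 1:5d} {pad_name}{'':1s}{resname:>3s} {chain}{resid:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{receptor.elements[i].upper():>2s}\n"
        )
    lines.append("END\n")
    Path(path).write_text("".join(lines))


def _mol_from_rdkit(rdmols) -> Molecule:
    first = rdmols[0]
    elements = [a.GetSymbol() for a in first.GetAtoms()]
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), int(b.GetBondTypeAsDouble()))
        for b in first.GetBonds()
    ]
    conformers = []
    for m in rdmols:
        if [a.GetSymbol() for a in m.GetAtoms()] != elements:
            raise ValueError("SD records have differing element sequences")
        conf = m.GetConformer()
        conformers.append(
            np.array([list(conf.GetAtomPosition(i)) for i in range(m.GetNumAtoms())])
        )
    mol = Molecule(
        elements=elements,
        conformers=conformers,
        bonds=bonds,
        name=first.GetProp("_Name") if first.HasProp("_Name") else "LIG",
    )
    if not mol.heavy_mask.any():
        raise ValueError("molecule has zero heavy atoms")
    mol.rotatable_bonds = detect_rotatable_bonds(elements, bonds)
    return mol


def read_sdf(path) -> Molecule:
    """Read an SD file; multiple records of one molecule become conformers.

    Record 1 is conformer 0.  Rotatable bonds are detected as acyclic single
    bonds between heavy atoms, each bearing at least one other heavy neighbor.
    """
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    rdmols = [m for m in supplier if m is not None]
    if not rdmols:
        raise ValueError(f"no parseable SD records in {path}")
    return _mol_from_rdkit(rdmols)


_BOND_TYPES = None


def _to_rdkit(molecule: Molecule, coords: np.ndarray):
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    global _BOND_TYPES
    if _BOND_TYPES is None:
        _BOND_TYPES = {
            1: Chem.BondType.SINGLE,
            2: Chem.BondType.DOUBLE,
            3: Chem.BondType.TRIPLE,
        }
    rw = Chem.RWMol()
    for el in molecule.elements:
        atom = Chem.Atom(el)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    for i, j, order in molecule.bonds:
        rw.AddBond(int(i), int(j), _BOND_TYPES.get(order, Chem.BondType.SINGLE))
    m = rw.GetMol()
    conf = Chem.Conformer(molecule.n_atoms)
    for i, (x, y, z) in enumerate(coords):
        conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
    m.AddConformer(conf)
    m.SetProp("_Name", molecule.name)
    return m


def write_sdf(poses: Sequence[Pose], path) -> None:
    """Write poses as a multi-record SD file, one record per pose.

    Scores are emitted as SD data fields; coordinates survive a round trip
    to the V2000 format precision (1e-4 A).
    """
    from rdkit import Chem

    path = Path(path)
    if len(poses) == 0:
        warnings.warn("writing an empty SD file: no poses given")
        path.write_text("")
        return
    mols = {id(p.molecule) for p in poses}
    if len(mols) > 1:
        raise ValueError("all poses must share one molecule")

    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for k, pose in enumerate(poses):
            m = _to_rdkit(pose.molecule, pose.coords)
            m.SetProp("_Name", f"{pose.molecule.name}_{k}")
            if np.isfinite(pose.grid_score):
                m.SetProp("grid_score", f"{pose.grid_score:.6f}")
            if np.isfinite(pose.fa_score):
                m.SetProp("fa_score", f"{pose.fa_score:.6f}")
            if pose.rmsd_to_native is not None:
                m.SetProp("rmsd", f"{pose.rmsd_to_native:.6f}")
            writer.write(m)
    finally:
        writer.close()


def write_molecule_sdf(molecule: Molecule, path) -> None:
    """Write all conformers of a molecule as consecutive SD records."""
    from rdkit import Chem

    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for coords in molecule.conformers:
            writer.write(_to_rdkit(molecule, coords))
    finally:
        writer.close()
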