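"""Structure standardization and minimum-energy 3D conformer generation.

Input structures (SMILES or SDF) are standardized — largest organic
fragment kept, charges neutralized where chemically valid, explicit
hydrogens added — and embedded in 3D.  The default path embeds up to
200 random-coordinate candidate conformers, minimizes each with the
MMFF94 force field and keeps the lowest-energy one.  If that path
exceeds a per-molecule wall-clock budget (60 s by default), a single
knowledge-based ETKDG embedding is minimized instead and tagged as the
fallback.  Molecules without MMFF parameters keep the unminimized
ETKDG geometry, with their own tag.
"""

from __future__ import annotations

import time
import warnings
import zlib
from dataclasses import dataclass
from pathlib import Path

from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem.MolStandardize import rdMolStandardize

__all__ = [
    "StandardizedMolecule",
    "Conformer3D",
    "InvalidStructureError",
    "ConformerFailureError",
    "METHOD_RANDOM",
    "METHOD_FALLBACK",
    "METHOD_FALLBACK_UNMINIMIZED",
    "standardize_structure",
    "generate_conformer",
    "write_sdf",
    "read_sdf",
    "read_smiles_file",
    "molecule_seed",
]

METHOD_RANDOM = "random-candidate"
METHOD_FALLBACK = "fallback"
METHOD_FALLBACK_UNMINIMIZED = "fallback-unminimized"

ENERGY_FIELD = "ENERGY_KCAL_MOL"
METHOD_FIELD = "CONF_METHOD"


class InvalidStructureError(ValueError):
    """Input string does not parse as a molecule."""


class ConformerFailureError(RuntimeError):
    """3D embedding failed on both the candidate and fallback paths."""


@dataclass
class StandardizedMolecule:
    """A cleaned single-fragment molecule with explicit hydrogens."""

    mol: Chem.Mol
    smiles: str  # canonical, without explicit H
    source: str  # original input string
    mol_id: str = ""


@dataclass
class Conformer3D:
    """One 3D geometry per compound with its MMFF94 energy."""

    mol: Chem.Mol  # carries exactly one conformer, explicit H
    energy: float  # kcal/mol; NaN only for the unminimized tag
    method: str  # METHOD_RANDOM | METHOD_FALLBACK | METHOD_FALLBACK_UNMINIMIZED
    seed: int
    mol_id: str = ""
    candidate_energies: tuple[float, ...] = ()


def standardize_structure(s: str, mol_id: str = "") -> StandardizedMolecule:
    """Standardize a SMILES string.

    Keeps the largest organic fragment (salts/counterions dropped),
    neutralizes formal charges where chemically valid, and adds
    explicit hydrogens.  Unparseable input raises
    :class:`InvalidStructureError`; batch callers record the ID and
    skip the compound.
    """
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise InvalidStructureError(f"cannot parse structure {s!r}")
    mol = rdMolStandardize.Cleanup(mol)
    mol = rdMolStandardize.LargestFragmentChooser().choose(mol)
    mol = rdMolStandardize.Uncharger().uncharge(mol)
    smiles = Chem.MolToSmiles(mol)
    return StandardizedMolecule(
        mol=Chem.AddHs(mol), smiles=smiles, source=s, mol_id=mol_id
    )


def molecule_seed(global_seed: int, canonical_smiles: str) -> int:
    """Per-molecule embedding seed, independent of batch order."""
    return (int(global_seed) + zlib.crc32(canonical_smiles.encode())) % (2**31 - 1)


def _minimize_all(mol: Chem.Mol, deadline: float | None) -> list[float] | None:
    """MMFF-minimize every conformer; None if the deadline passes."""
    props = AllChem.MMFFGetMoleculeProperties(mol)
    energies = []
    for conf in mol.GetConformers():
        ff = AllChem.MMFFGetMoleculeForceField(mol, props, confId=conf.GetId())
        ff.Minimize(maxIts=200)
        energies.append(ff.CalcEnergy())
        if deadline is not None and time.monotonic() > deadline:
            return None
    return energies


def _single_conformer(mol: Chem.Mol, conf_id: int) -> Chem.Mol:
    out = Chem.Mol(mol)
    out.RemoveAllConformers()
    out.AddConformer(mol.GetConformer(conf_id), assignId=True)
    return out


def generate_conformer(
    m: StandardizedMolecule,
    n_candidates: int = 200,
    time_budget: float = 60.0,
    seed: int = 0,
) -> Conformer3D:
    """Produce the minimum-energy 3D conformer for a standardized molecule.

    Embeds up to ``n_candidates`` (capped at 200) random-coordinate
    conformers, MMFF94-minimizes them and returns the lowest-energy one
    (ties broken toward the lowest candidate index).  If the wall clock
    exceeds ``time_budget`` seconds, a single ETKDG embedding is
    minimized instead (``time_budget=0`` forces this path, which makes
    the budget rule directly testable).  The embedding seed is derived
    from ``seed`` and the canonical SMILES so batch order is irrelevant.
    """
    n_candidates = min(int(n_candidates), 200)
    mol_seed = molecule_seed(seed, m.smiles)
    start = time.monotonic()
    deadline = start + time_budget

    has_mmff = AllChem.MMFFHasAllMoleculeParams(m.mol)
    if time_budget > 0 and has_mmff:
        work = Chem.Mol(m.mol)
        cids = AllChem.EmbedMultipleConfs(
            work,
            numConfs=n_candidates,
            useRandomCoords=True,
            randomSeed=mol_seed,
        )
        if len(cids) and time.monotonic() <= deadline:
            energies = _minimize_all(work, deadline)
            if energies is not None:
                best = int(min(range(len(energies)), key=energies.__getitem__))
                return Conformer3D(
                    mol=_single_conformer(work, list(cids)[best]),
                    energy=float(energies[best]),
                    method=METHOD_RANDOM,
                    seed=mol_seed,
                    mol_id=m.mol_id,
                    candidate_energies=tuple(energies),
                )

    # fallback: one knowledge-based embedding
    work = Chem.Mol(m.mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = mol_seed
    if AllChem.EmbedMolecule(work, params) != 0:
        raise ConformerFailureError(
            f"3D embedding failed for {m.mol_id or m.smiles!r}"
        )
    if has_mmff:
        energies = _minimize_all(work, deadline=None)
        return Conformer3D(
            mol=work,
            energy=float(energies[0]),
            method=METHOD_FALLBACK,
            seed=mol_seed,
            mol_id=m.mol_id,
        )
    warnings.warn(
        f"MMFF94 parameters unavailable for {m.mol_id or m.smiles!r}; "
        "keeping unminimized ETKDG geometry",
        stacklevel=2,
    )
    return Conformer3D(
        mol=work,
        energy=float("nan"),
        method=METHOD_FALLBACK_UNMINIMIZED,
        seed=mol_seed,
        mol_id=m.mol_id,
    )


def write_sdf(cs: list[Conformer3D], path: str | Path) -> None:
    """Write conformers to a V2000 SDF, one record per compound.

    Energy and method are stored as data fields so a later read-back
    can recover them alongside the coordinates.
    """
    if not cs:
        warnings.warn(f"writing empty SDF to {path}", stacklevel=2)
    writer = Chem.SDWriter(str(path))
    try:
        for c in cs:
            mol = Chem.Mol(c.mol)
            if c.mol_id:
                mol.SetProp("_Name", c.mol_id)
            mol.SetProp(ENERGY_FIELD, repr(c.energy))
            mol.SetProp(METHOD_FIELD, c.method)
            writer.write(mol)
    finally:
        writer.close()


def read_sdf(path: str | Path) -> list[Conformer3D]:
    """Read a conformer SDF written by :func:`write_sdf` (or any 3D SDF)."""
    out: list[Conformer3D] = []
    if Path(path).stat().st_size == 0:  # the supplier rejects empty files
        return out
    for mol in Chem.SDMolSupplier(str(path), removeHs=False):
        if mol is None:
            continue
        energy = float(mol.GetProp(ENERGY_FIELD)) if mol.HasProp(ENERGY_FIELD) else float("nan")
        method = mol.GetProp(METHOD_FIELD) if mol.HasProp(METHOD_FIELD) else ""
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        out.append(
            Conformer3D(mol=mol, energy=energy, method=method, seed=-1, mol_id=mol_id)
        )
    return out


def read_smiles_file(path: str | Path) -> list[tuple[str, str]]:
    """Read a SMILES file: one molecule per line, optional tab-separated ID.

    Returns (mol_id, smiles) pairs; IDs default to MOL<line number>.
    """
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) >= 2:
            smiles, mol_id = parts[0].strip(), parts[1].strip()
        else:
            smiles, mol_id = parts[0].strip(), f"MOL{i}"
        out.append((mol_id, smiles))
    return out
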