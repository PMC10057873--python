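"""Synthetic data generators for exercising every pipeline stage offline.

Two generators are provided, both seed-deterministic:

* random proteins with a controlled residue composition — used to test the
  digestion engine against brute-force oracles and the fragment-count
  statistics of i.i.d. sequences (a storage-protein-like, glutamine-rich
  preset is included);
* ligand–receptor coordinate sets with hydrogen bonds planted at exact
  geometry — used to test hydrogen-bond detection by exact recovery rather
  than statistically.  Decoy heteroatoms are kept beyond twice the
  detection cutoff so a correct detector must find exactly the planted
  bonds and nothing else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .dockprep import AtomRecord, write_pdb
from .sequences import CANONICAL_RESIDUES, ProteinRecord
from . import sequences

__all__ = [
    "RESIDUE_ORDER",
    "CompositionSpec",
    "uniform_composition",
    "storage_protein_composition",
    "random_protein",
    "PlantedGeometry",
    "make_planted_geometry",
    "write_geometry",
]

#: Fixed residue ordering used by probability vectors.
RESIDUE_ORDER = tuple(sorted(CANONICAL_RESIDUES))


@dataclass(frozen=True)
class CompositionSpec:
    """Residue-composition model for random protein generation.

    ``probabilities`` maps each canonical residue to its i.i.d. draw
    probability (must sum to 1 within 1e-9).
    """

    probabilities: Mapping[str, float]
    length: int
    seed: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        probs = {r: float(p) for r, p in self.probabilities.items()}
        unknown = set(probs) - CANONICAL_RESIDUES
        if unknown:
            raise ValueError(f"non-canonical residues in composition: {sorted(unknown)}")
        if any(p < 0 for p in probs.values()):
            raise ValueError("probabilities must be non-negative")
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total!r}, not 1")
        object.__setattr__(self, "probabilities", probs)

    def vector(self) -> np.ndarray:
        return np.array([self.probabilities.get(r, 0.0) for r in RESIDUE_ORDER])


def uniform_composition(length: int, seed: int) -> CompositionSpec:
    """All 20 residues equiprobable."""
    return CompositionSpec(
        probabilities={r: 1.0 / 20.0 for r in RESIDUE_ORDER}, length=length, seed=seed
    )


def storage_protein_composition(length: int, seed: int, *, gln: float = 0.18) -> CompositionSpec:
    """Glutamine-rich composition emulating cereal storage proteins
    (prolamins/glutelins are dominated by Gln); the remaining mass is spread
    uniformly over the other 19 residues."""
    rest = (1.0 - gln) / 19.0
    probs = {r: rest for r in RESIDUE_ORDER}
    probs["Q"] = gln
    return CompositionSpec(probabilities=probs, length=length, seed=seed)


def random_protein(spec: CompositionSpec, *, id: str | None = None) -> ProteinRecord:
    """Draw an i.i.d. random protein under *spec*; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    letters = rng.choice(list(RESIDUE_ORDER), size=spec.length, p=spec.vector())
    return ProteinRecord(
        id=id or f"synthetic-{spec.seed}",
        sequence="".join(letters),
        name="synthetic random protein",
        source=f"synthdata.random_protein(seed={spec.seed}, length={spec.length})",
    )


@dataclass(frozen=True)
class PlantedGeometry:
    """A ligand/receptor coordinate pair with known hydrogen-bond geometry.

    ``planted`` lists (donor serial, acceptor serial, distance Å, angle °)
    for each intended bond; realized geometry matches the targets to
    numerical precision.
    """

    ligand: tuple[AtomRecord, ...]
    receptor: tuple[AtomRecord, ...]
    planted: tuple[tuple[int, int, float, float], ...]
    seed: int


# Receptor residues cycled through when planting bonds; all are members of
# the antiadipogenic hotspot set so contact reports are easy to assert on.
_PLANT_RESIDUES = (("CYS", 285), ("SER", 289), ("ARG", 288), ("HIS", 449))


def _donor_hydrogen(donor: np.ndarray, acceptor: np.ndarray, angle_deg: float) -> np.ndarray:
    """Place H at 1.0 Å from the donor so that ∠(D–H···A) equals *angle_deg*.

    Triangle D-H-A with |DH| = 1 and the planted |DA|: the law of sines
    gives the angle at D, hence H's direction in the D→A frame.
    """
    d_ha = math.radians(angle_deg)
    dda = float(np.linalg.norm(acceptor - donor))
    sin_at_a = math.sin(d_ha) * 1.0 / dda
    at_a = math.asin(max(-1.0, min(1.0, sin_at_a)))
    at_d = math.pi - d_ha - at_a
    axis = (acceptor - donor) / dda
    # any perpendicular to the D→A axis
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-8:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    return donor + math.cos(at_d) * axis + math.sin(at_d) * perp


def make_planted_geometry(
    n_bonds: int,
    seed: int,
    distance: float = 2.9,
    angle: float = 160.0,
    *,
    cutoff: float = 3.5,
) -> PlantedGeometry:
    """Build a ligand/receptor pair with exactly *n_bonds* hydrogen bonds.

    Each bond is a ligand amine nitrogen (explicit hydrogen) donating to a
    receptor backbone carbonyl oxygen at the target distance and D–H···A
    angle.  Bond sites are spaced far apart and decoy atoms kept beyond
    ``2 × cutoff`` of the partner molecule, so detection at the default
    criteria must recover exactly the planted set.  The whole scene is
    rigidly rotated and translated at random (seed-deterministic), which
    leaves the planted geometry intact to numerical precision.
    """
    if n_bonds < 0:
        raise ValueError("n_bonds must be >= 0")
    site_pitch = max(4.0 * cutoff, 25.0)
    if n_bonds > 2000:
        raise ValueError("infeasible packing: too many planted bonds requested")

    ligand: list[AtomRecord] = []
    receptor: list[AtomRecord] = []
    planted: list[tuple[int, int, float, float]] = []
    lig_serial = rec_serial = 0

    def lig_atom(name: str, element: str, pos: np.ndarray) -> AtomRecord:
        nonlocal lig_serial
        lig_serial += 1
        return AtomRecord(
            serial=lig_serial, atom_name=name, residue_name="LIG", chain="L",
            residue_number=1, x=float(pos[0]), y=float(pos[1]), z=float(pos[2]),
            element=element, hetatm=True,
        )

    def rec_atom(name: str, element: str, resname: str, resnum: int, pos: np.ndarray) -> AtomRecord:
        nonlocal rec_serial
        rec_serial += 1
        return AtomRecord(
            serial=rec_serial, atom_name=name, residue_name=resname, chain="A",
            residue_number=resnum, x=float(pos[0]), y=float(pos[1]), z=float(pos[2]),
            element=element,
        )

    for i in range(n_bonds):
        off = np.array([site_pitch * i, 0.0, 0.0])
        resname, resnum = _PLANT_RESIDUES[i % len(_PLANT_RESIDUES)]
        resnum += 1000 * (i // len(_PLANT_RESIDUES))  # keep residue keys unique
        acc_pos = off
        don_pos = off + np.array([distance, 0.0, 0.0])
        h_pos = _donor_hydrogen(don_pos, acc_pos, angle)
        acc = rec_atom("O", "O", resname, resnum, acc_pos)       # backbone carbonyl: pure acceptor
        receptor.append(acc)
        receptor.append(rec_atom("CA", "C", resname, resnum, off + np.array([0.0, -1.5, 0.0])))
        don = lig_atom(f"N{i + 1}", "N", don_pos)
        ligand.append(don)
        ligand.append(lig_atom(f"H{i + 1}", "H", h_pos))
        ligand.append(lig_atom(f"C{i + 1}", "C", don_pos + np.array([1.4, 0.5, 0.0])))
        planted.append((don.serial, acc.serial, distance, angle))

    # Decoy heteroatoms, each beyond 2×cutoff from every partner heteroatom.
    far = np.array([0.0, 4.0 * cutoff, 0.0])
    base = np.array([site_pitch * max(n_bonds, 1), 0.0, 0.0])
    ligand.append(lig_atom("O99", "O", base + far))
    receptor.append(rec_atom("N", "N", "GLY", 999, base - far))
    if not any(a.element == "H" for a in receptor):
        # no receptor hydrogens → receptor-side donors are judged on
        # distance alone; the decoys above are well out of range.
        pass

    rng = np.random.default_rng(seed)
    rot = _random_rotation(rng)
    shift = rng.uniform(-20.0, 20.0, size=3)

    def moved(a: AtomRecord) -> AtomRecord:
        p = rot @ a.coords + shift
        return AtomRecord(
            serial=a.serial, atom_name=a.atom_name, residue_name=a.residue_name,
            chain=a.chain, residue_number=a.residue_number,
            x=float(p[0]), y=float(p[1]), z=float(p[2]),
            element=a.element, insertion_code=a.insertion_code, hetatm=a.hetatm,
        )

    return PlantedGeometry(
        ligand=tuple(moved(a) for a in ligand),
        receptor=tuple(moved(a) for a in receptor),
        planted=tuple(planted),
        seed=seed,
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def write_geometry(
    geom: PlantedGeometry, ligand_path: str | Path, receptor_path: str | Path
) -> None:
    """Emit the geometry as two PDB files with provenance remarks."""
    prov = [
        f"synthetic planted-geometry fixture, seed={geom.seed}",
        f"planted bonds: {len(geom.planted)}",
    ]
    write_pdb(geom.ligand, ligand_path, remarks=prov)
    write_pdb(geom.receptor, receptor_path, remarks=prov)


def write_protein_fasta(record: ProteinRecord, path: str | Path) -> None:
    """Emit a generated protein as FASTA plus a sidecar provenance file."""
    sequences.write_fasta([record], path)
    Path(str(path) + ".provenance.txt").write_text(record.source + "\n")
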