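"""Docking-adjacent utilities: PDB coordinates, grid-box configuration,
docking-log parsing, and geometric hydrogen-bond / hotspot contact analysis.

The docking search and scoring themselves are out of scope — energies are
parsed from tool output, never computed.  What this module owns is the
geometry around docking: defining the search box over the receptor's
antiadipogenic region, and asking, for a docked pose, which receptor
residues the ligand hydrogen-bonds to and whether those residues belong to
the antagonist hotspot set.

Hydrogen-bond criterion (configurable): donor–acceptor heavy-atom distance
≤ 3.5 Å, and donor angle D–H···A ≥ 120° whenever the donor carries explicit
hydrogens; structures without hydrogens are judged on distance alone.
Donor/acceptor typing uses a residue template table for protein residues
and an element heuristic (N/O polar) for ligands and unknown residues.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "GridBox",
    "HotspotSet",
    "HBond",
    "ContactReport",
    "ANTIADIPOGENIC_HOTSPOTS",
    "DEFAULT_GRIDBOX",
    "parse_pdb",
    "write_pdb",
    "make_gridbox_config",
    "parse_gridbox_config",
    "parse_docking_log",
    "detect_hbonds",
    "contact_residues",
]


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM/HETATM record with fixed-column PDB provenance."""

    serial: int
    atom_name: str
    residue_name: str
    chain: str
    residue_number: int
    x: float
    y: float
    z: float
    element: str
    insertion_code: str = ""
    hetatm: bool = False

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.x, self.y, self.z))):
            raise ValueError(f"atom {self.serial}: non-finite coordinates")
        if not self.element:
            raise ValueError(f"atom {self.serial}: empty element")

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.residue_name, self.residue_number)


@dataclass(frozen=True)
class GridBox:
    """Docking search box: center (Å), grid dimensions (points), spacing (Å).

    The physical edge lengths are ``points × spacing`` Å (AutoDock-style
    semantics).  Tools that take sizes directly in Å receive the computed
    products.
    """

    center_x: float
    center_y: float
    center_z: float
    size_x: int
    size_y: int
    size_z: int
    spacing: float

    def __post_init__(self) -> None:
        if min(self.size_x, self.size_y, self.size_z) <= 0 or self.spacing <= 0:
            raise ValueError("grid sizes and spacing must be positive")

    @property
    def extent_angstrom(self) -> tuple[float, float, float]:
        return (
            self.size_x * self.spacing,
            self.size_y * self.spacing,
            self.size_z * self.spacing,
        )


#: Search box over the receptor's antiadipogenic region (center in Å,
#: 70×40×40 points at 0.375 Å spacing).
DEFAULT_GRIDBOX = GridBox(
    center_x=7.745, center_y=50.606, center_z=57.552,
    size_x=70, size_y=40, size_z=40, spacing=0.375,
)


@dataclass(frozen=True)
class HotspotSet:
    """Receptor residues whose contact marks antagonist-like binding."""

    residues: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("hotspot set must be non-empty")
        clean = tuple((name.upper(), int(num)) for name, num in self.residues)
        if any(num <= 0 for _, num in clean):
            raise ValueError("residue numbers must be positive")
        object.__setattr__(self, "residues", clean)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return (key[0].upper(), key[1]) in self.residues


#: The PPARγ antiadipogenic pocket residues targeted by the screening study.
ANTIADIPOGENIC_HOTSPOTS = HotspotSet(
    residues=(
        ("PHE", 264), ("HIS", 266), ("ILE", 281), ("CYS", 285),
        ("ARG", 288), ("SER", 289), ("MET", 348), ("HIS", 449),
    )
)


@dataclass(frozen=True)
class HBond:
    """One detected hydrogen bond between a ligand and a receptor atom.

    ``angle`` is the D–H···A angle in degrees, or ``None`` when the donor
    has no explicit hydrogens and the bond was accepted on distance alone.
    """

    donor: AtomRecord
    acceptor: AtomRecord
    distance: float
    angle: float | None
    donor_is_ligand: bool

    @property
    def receptor_atom(self) -> AtomRecord:
        return self.acceptor if self.donor_is_ligand else self.donor

    @property
    def receptor_residue(self) -> tuple[str, int]:
        return self.receptor_atom.residue_key


@dataclass(frozen=True)
class ContactReport:
    """Hydrogen-bond contacts of one pose against a hotspot residue set."""

    hbonds: tuple[HBond, ...]
    contacted: tuple[tuple[str, int], ...]
    hotspot_contacts: tuple[tuple[str, int], ...]
    non_hotspot_contacts: tuple[tuple[str, int], ...]


# ---------------------------------------------------------------------------
# PDB fixed-column I/O

_COORD_SLICES = {"x": slice(30, 38), "y": slice(38, 46), "z": slice(46, 54)}


def _infer_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return ""
    # PDB convention: element is the first character for C/N/O/S/H-led names.
    if name[0].isdigit():          # e.g. 1HB
        return "H"
    if len(name) >= 2 and name[:2].capitalize() in ("Cl", "Br", "Fe", "Zn", "Mg", "Na"):
        return name[:2].capitalize()
    return name[0].upper()


def parse_pdb(path: str | Path) -> list[AtomRecord]:
    """Parse ATOM/HETATM records from a fixed-column PDB file.

    Only the first MODEL is read; additional models trigger a logged
    warning.  Malformed fixed-width fields raise with the line number.
    Insertion codes are preserved.
    """
    path = Path(path)
    atoms: list[AtomRecord] = []
    n_models = 0
    in_first_model = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                n_models += 1
                in_first_model = n_models == 1
                continue
            if rec == "ENDMDL":
                continue
            if rec not in ("ATOM", "HETATM") or not in_first_model:
                continue
            try:
                element = line[76:78].strip() or _infer_element(line[12:16])
                atoms.append(
                    AtomRecord(
                        serial=int(line[6:11]),
                        atom_name=line[12:16].strip(),
                        residue_name=line[17:20].strip(),
                        chain=line[21].strip() or " ",
                        residue_number=int(line[22:26]),
                        insertion_code=line[26].strip(),
                        x=float(line[_COORD_SLICES["x"]]),
                        y=float(line[_COORD_SLICES["y"]]),
                        z=float(line[_COORD_SLICES["z"]]),
                        element=element.capitalize(),
                        hetatm=rec == "HETATM",
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed PDB record: {exc}") from exc
    if n_models > 1:
        logger.warning("%s: %d MODELs present; only the first was read", path, n_models)
    if not atoms:
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    return atoms


def write_pdb(atoms: Sequence[AtomRecord], path: str | Path, *, remarks: Iterable[str] = ()) -> None:
    """Write atoms in fixed-column PDB format (coordinates to 3 decimals)."""
    lines = [f"REMARK   1 {r}" for r in remarks]
    for a in atoms:
        rec = "HETATM" if a.hetatm else "ATOM"
        name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3s}"
        lines.append(
            f"{rec:<6s}{a.serial:>5d} {name:<4s}{'':1s}{a.residue_name:>3s} "
            f"{a.chain:1s}{a.residue_number:>4d}{a.insertion_code:1s}   "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{a.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Grid box configuration

def make_gridbox_config(box: GridBox = DEFAULT_GRIDBOX) -> str:
    """Emit docking-tool config text for *box*.

    Centers are in Å; ``size_*`` lines give the physical edge lengths
    (points × spacing); the grid dimensions and spacing are also emitted so
    the text round-trips through :func:`parse_gridbox_config`.
    """
    ex, ey, ez = box.extent_angstrom
    return (
        f"center_x = {box.center_x:g}\n"
        f"center_y = {box.center_y:g}\n"
        f"center_z = {box.center_z:g}\n"
        f"size_x = {ex:g}\n"
        f"size_y = {ey:g}\n"
        f"size_z = {ez:g}\n"
        f"npts_x = {box.size_x:d}\n"
        f"npts_y = {box.size_y:d}\n"
        f"npts_z = {box.size_z:d}\n"
        f"spacing = {box.spacing:g}\n"
    )


def parse_gridbox_config(text: str) -> GridBox:
    """Recover a :class:`GridBox` from config text emitted by
    :func:`make_gridbox_config`."""
    kv: dict[str, float] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        m = re.fullmatch(r"(\w+)\s*=\s*([-+0-9.eE]+)", line)
        if not m:
            raise ValueError(f"cannot parse config line: {line!r}")
        kv[m.group(1)] = float(m.group(2))
    needed = {"center_x", "center_y", "center_z", "npts_x", "npts_y", "npts_z", "spacing"}
    missing = needed - set(kv)
    if missing:
        raise ValueError(f"config missing keys: {sorted(missing)}")
    return GridBox(
        center_x=kv["center_x"], center_y=kv["center_y"], center_z=kv["center_z"],
        size_x=int(kv["npts_x"]), size_y=int(kv["npts_y"]), size_z=int(kv["npts_z"]),
        spacing=kv["spacing"],
    )


# ---------------------------------------------------------------------------
# Docking log parsing

_MODE_LINE = re.compile(r"^\s*(\d+)\s+(-?\d+(?:\.\d+)?)(?:\s+-?\d|\s*$)")


def parse_docking_log(text: str) -> list[tuple[int, float]]:
    """Extract (mode rank, affinity kcal/mol) pairs from a docking result log.

    Expects the standard tabular result block (``mode | affinity | ...``
    header followed by numbered rows); the best pose comes first.
    """
    pairs: list[tuple[int, float]] = []
    in_block = False
    for line in text.splitlines():
        if re.match(r"^\s*mode\s*\|", line) or re.match(r"^-+\+", line.strip()):
            in_block = True
            continue
        if in_block:
            m = _MODE_LINE.match(line)
            if m:
                pairs.append((int(m.group(1)), float(m.group(2))))
            elif pairs:
                break
    if not pairs:
        raise ValueError("no docking result block found in log text")
    return pairs


# ---------------------------------------------------------------------------
# Hydrogen-bond detection

# Donor / acceptor heavy-atom names per protein residue (neutral templates).
# Backbone: N donates (except proline), O accepts, OXT accepts.
_SIDECHAIN_DONORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "ASN": {"ND2"},
    "GLN": {"NE2"}, "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"},
    "HIS": {"ND1", "NE2"}, "TRP": {"NE1"}, "CYS": set(), "MET": set(),
}
_SIDECHAIN_ACCEPTORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"},
}
_PROTEIN_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

_H_COVALENT_MAX = 1.25  # Å, H considered bonded to its nearest heavy atom


def _is_donor(atom: AtomRecord) -> bool:
    if atom.residue_name in _PROTEIN_RESIDUES:
        if atom.atom_name == "N":
            return atom.residue_name != "PRO"
        return atom.atom_name in _SIDECHAIN_DONORS.get(atom.residue_name, set())
    return atom.element in ("N", "O")  # ligand heuristic


def _is_acceptor(atom: AtomRecord) -> bool:
    if atom.residue_name in _PROTEIN_RESIDUES:
        if atom.atom_name in ("O", "OXT"):
            return True
        return atom.atom_name in _SIDECHAIN_ACCEPTORS.get(atom.residue_name, set())
    return atom.element in ("N", "O")


def _attached_hydrogens(heavy: AtomRecord, hydrogens: Sequence[AtomRecord]) -> list[AtomRecord]:
    c = heavy.coords
    return [h for h in hydrogens if float(np.linalg.norm(h.coords - c)) <= _H_COVALENT_MAX]


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    u, v = a - vertex, b - vertex
    cosang = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def _directional_bonds(
    donor_side: Sequence[AtomRecord],
    acceptor_side: Sequence[AtomRecord],
    donor_is_ligand: bool,
    d_max: float,
    angle_min: float,
) -> list[HBond]:
    hydrogens = [a for a in donor_side if a.element == "H"]
    has_h = bool(hydrogens)
    bonds = []
    for d in donor_side:
        if d.element == "H" or not _is_donor(d):
            continue
        attached = _attached_hydrogens(d, hydrogens) if has_h else []
        if has_h and not attached:
            continue  # explicit-H structure, but this N/O carries none
        for a in acceptor_side:
            if a.element == "H" or not _is_acceptor(a):
                continue
            dist = float(np.linalg.norm(d.coords - a.coords))
            if dist > d_max:
                continue
            angle: float | None = None
            if attached:
                angle = max(_angle_deg(d.coords, h.coords, a.coords) for h in attached)
                if angle < angle_min:
                    continue
            bonds.append(HBond(donor=d, acceptor=a, distance=dist, angle=angle,
                               donor_is_ligand=donor_is_ligand))
    return bonds


def detect_hbonds(
    ligand: Sequence[AtomRecord],
    receptor: Sequence[AtomRecord],
    d_max: float = 3.5,
    angle_min: float = 120.0,
) -> list[HBond]:
    """Geometric hydrogen bonds between a docked ligand pose and the receptor.

    Both directions are scanned (ligand donor → receptor acceptor and
    receptor donor → ligand acceptor).  Donor–acceptor heavy-atom distance
    must be ≤ *d_max*; when the donor molecule carries explicit hydrogens
    the best D–H···A angle must reach *angle_min*.  Results are sorted by
    distance; an empty list is a valid outcome.
    """
    if not ligand or not receptor:
        raise ValueError("both atom lists must be non-empty")
    bonds = _directional_bonds(ligand, receptor, True, d_max, angle_min)
    bonds += _directional_bonds(receptor, ligand, False, d_max, angle_min)
    # serial tie-break keeps the order stable when distances are equal
    return sorted(bonds, key=lambda b: (round(b.distance, 6), b.donor.serial, b.acceptor.serial))


def contact_residues(
    bonds: Sequence[HBond],
    hotspots: HotspotSet = ANTIADIPOGENIC_HOTSPOTS,
) -> ContactReport:
    """Summarise which receptor residues a pose hydrogen-bonds to.

    Contacts outside the hotspot set are flagged (reported separately),
    never dropped — published interaction tables list such residues too.
    """
    seen: dict[tuple[str, int], None] = {}
    for b in bonds:
        seen.setdefault(b.receptor_residue, None)
    contacted = tuple(seen)
    return ContactReport(
        hbonds=tuple(bonds),
        contacted=contacted,
        hotspot_contacts=tuple(r for r in contacted if r in hotspots),
        non_hotspot_contacts=tuple(r for r in contacted if r not in hotspots),
    )
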