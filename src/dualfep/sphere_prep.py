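"""Spherical-boundary system preparation.

A finite droplet of water around the region of interest replaces periodic
boundary conditions: atoms inside the sphere move freely, a thin boundary
shell is restrained, and everything outside is tightly constrained and
excluded from nonbonded interactions.  This module places the sphere,
classifies atoms against it, strips waters clashing with the ligand pair,
neutralizes ionizable residues that would sit (partially) charged in the
restrained region, and fills the sphere with grid water.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .ligand_io import LigandTopology

__all__ = [
    "AtomRecord",
    "Residue",
    "Structure",
    "SimulationSphere",
    "ChangeRecord",
    "sphere_center",
    "classify_atoms",
    "remove_overlapping_waters",
    "neutralize_outside",
    "solvate_sphere",
    "read_structure_pdb",
    "write_structure_pdb",
]

WATER_NAMES = {"HOH", "WAT", "SPC", "T3P", "TIP3", "SOL"}

#: charged (ionized) residue name -> neutral library variant
NEUTRAL_VARIANT = {
    "ASP": "ASH",
    "GLU": "GLH",
    "LYS": "LYN",
    "ARG": "ARN",
    "HIP": "HID",
}

#: atoms whose centroid locates the charged group of an ionizable residue
CHARGED_GROUP_ATOMS = {
    "ASP": {"CG", "OD1", "OD2"},
    "GLU": {"CD", "OE1", "OE2"},
    "LYS": {"NZ"},
    "ARG": {"NE", "CZ", "NH1", "NH2"},
    "HIP": {"ND1", "NE2"},
}

STANDARD_RESIDUES = WATER_NAMES | set(NEUTRAL_VARIANT) | set(NEUTRAL_VARIANT.values()) | {
    "ALA", "GLY", "SER", "THR", "CYS", "VAL", "LEU", "ILE", "MET", "PRO",
    "PHE", "TYR", "TRP", "ASN", "GLN", "HIS", "HID", "HIE",
    "NA", "CL", "K", "MG", "CA", "ZN",
}

# TIP3P geometry: O-H 0.9572 Å, H-O-H 104.52 deg; fixed orientation.
_TIP3P_OH = 0.9572
_TIP3P_HOH = math.radians(104.52)
_TIP3P_H1 = (_TIP3P_OH * math.sin(_TIP3P_HOH / 2), _TIP3P_OH * math.cos(_TIP3P_HOH / 2), 0.0)
_TIP3P_H2 = (-_TIP3P_OH * math.sin(_TIP3P_HOH / 2), _TIP3P_OH * math.cos(_TIP3P_HOH / 2), 0.0)


@dataclass
class AtomRecord:
    """One structure atom; ``region`` is set by :func:`classify_atoms`."""

    name: str
    element: str
    xyz: tuple[float, float, float]
    region: str | None = None  # "inside" | "shell" | "outside"


@dataclass
class Residue:
    name: str
    resid: int
    atoms: list[AtomRecord] = field(default_factory=list)

    def centroid(self, atom_names: set[str] | None = None) -> np.ndarray:
        sel = [a for a in self.atoms if atom_names is None or a.name in atom_names]
        if not sel:
            sel = self.atoms
        return np.mean([a.xyz for a in sel], axis=0)


@dataclass
class Structure:
    """Ordered residues (protein, ligands, waters) with per-atom region flags."""

    residues: list[Residue] = field(default_factory=list)

    def all_atoms(self) -> list[AtomRecord]:
        return [a for r in self.residues for a in r.atoms]

    def coordinates(self) -> np.ndarray:
        atoms = self.all_atoms()
        if not atoms:
            return np.zeros((0, 3))
        return np.asarray([a.xyz for a in atoms], dtype=float)

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def region_counts(self) -> dict[str, int]:
        counts = {"inside": 0, "shell": 0, "outside": 0}
        for a in self.all_atoms():
            if a.region in counts:
                counts[a.region] += 1
        return counts


@dataclass(frozen=True)
class SimulationSphere:
    """Simulation droplet: ``center`` Å triple, ``radius`` Å (> 0)."""

    center: tuple[float, float, float]
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError(f"sphere radius must be positive, got {self.radius}")

    def distance(self, xyz) -> float:
        return float(np.linalg.norm(np.asarray(xyz, dtype=float) - np.asarray(self.center)))


@dataclass(frozen=True)
class ChangeRecord:
    """One neutralization event for the change-log."""

    resid: int
    old_name: str
    new_name: str
    reason: str

    def as_row(self) -> str:
        return f"{self.resid:6d}  {self.old_name:<4s} -> {self.new_name:<4s}  {self.reason}"


# ---------------------------------------------------------------------------
# Sphere placement and classification
# ---------------------------------------------------------------------------

def sphere_center(mode: str, *, ligands: tuple[LigandTopology, LigandTopology] | None = None,
                  xyz=None, structure: Structure | None = None, resid: int | None = None,
                  ligand: LigandTopology | None = None, atom_name: str | None = None,
                  ) -> tuple[float, float, float]:
    """Locate the sphere center.

    ``cog_two_ligands`` (the automated default) takes the unweighted mean of
    all atom coordinates of both ligands of the perturbation pair, so the
    droplet encloses both end states.  ``cartesian`` passes coordinates
    through; ``residue`` uses a residue centroid; ``ligand_atom`` a named
    ligand atom.
    """
    if mode == "cog_two_ligands":
        if not ligands:
            raise ValueError("cog_two_ligands mode requires ligands=(A, B)")
        coords = [a.xyz for lig in ligands for a in lig.atoms]
        if not coords:
            raise ValueError("empty ligand selection")
        return tuple(np.mean(coords, axis=0))
    if mode == "cartesian":
        if xyz is None:
            raise ValueError("cartesian mode requires xyz")
        return tuple(float(v) for v in xyz)
    if mode == "residue":
        if structure is None or resid is None:
            raise ValueError("residue mode requires structure and resid")
        for r in structure.residues:
            if r.resid == resid:
                if not r.atoms:
                    raise ValueError(f"residue {resid} has no atoms")
                return tuple(r.centroid())
        raise ValueError(f"no residue with id {resid}")
    if mode == "ligand_atom":
        if ligand is None or atom_name is None:
            raise ValueError("ligand_atom mode requires ligand and atom_name")
        return tuple(map(float, ligand.atoms[ligand.atom_index(atom_name)].xyz))
    raise ValueError(f"unknown sphere_center mode {mode!r}")


def classify_atoms(structure: Structure, sphere: SimulationSphere,
                   shell_width: float = 3.0) -> Structure:
    """Partition atoms into inside / boundary-shell / outside regions.

    The boundary is closed: distance == radius counts as inside.  The shell
    is the sub-region ``radius - shell_width < d <= radius`` used for
    restraint and neutralization bookkeeping.  Returns a classified copy.
    """
    if shell_width < 0:
        raise ValueError("shell_width must be non-negative")
    out = copy.deepcopy(structure)
    center = np.asarray(sphere.center)
    for res in out.residues:
        for a in res.atoms:
            d = float(np.linalg.norm(np.asarray(a.xyz) - center))
            if d > sphere.radius:
                a.region = "outside"
            elif d > sphere.radius - shell_width:
                a.region = "shell"
            else:
                a.region = "inside"
    return out


# ---------------------------------------------------------------------------
# Water handling
# ---------------------------------------------------------------------------

def remove_overlapping_waters(waters: Structure, lig_a: LigandTopology,
                              lig_b: LigandTopology, cutoff: float = 2.4) -> Structure:
    """Drop whole water residues clashing with either ligand.

    A water is removed iff any of its atoms lies within *cutoff* Å of any
    heavy atom of either ligand (both dual-topology end states displace the
    same solvent).  Non-water residues pass through untouched.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    heavy = [lig.atoms[i].xyz for lig in (lig_a, lig_b)
             for i in lig.heavy_atom_indices()]
    out = Structure()
    if not heavy:
        out.residues = copy.deepcopy(waters.residues)
        return out
    tree = cKDTree(np.asarray(heavy, dtype=float))
    for res in waters.residues:
        if res.name.upper() in WATER_NAMES and res.atoms:
            dmin = min(tree.query(np.asarray(a.xyz, dtype=float))[0] for a in res.atoms)
            if dmin <= cutoff:
                continue
        out.residues.append(copy.deepcopy(res))
    return out


# ---------------------------------------------------------------------------
# Neutralization
# ---------------------------------------------------------------------------

def neutralize_outside(structure: Structure, sphere: SimulationSphere,
                       shell_width: float = 3.0,
                       ) -> tuple[Structure, list[ChangeRecord]]:
    """Neutralize ionizable residues in the restrained region.

    A residue charged at simulation pH whose charged-group centroid lies
    outside the sphere or within the restrained boundary shell would leave an
    unscreened monopole in frozen territory; it is renamed to its neutral
    library variant (protonation state is inferred from the residue name:
    ASP->ASH, GLU->GLH, LYS->LYN, ARG->ARN, HIP->HID).  Coordinates and atom
    counts are untouched; proton bookkeeping is deferred to the library
    builder and noted in the change-log.  Unknown residue names trigger a
    warning and are left unchanged.
    """
    out = copy.deepcopy(structure)
    log: list[ChangeRecord] = []
    cutoff = sphere.radius - shell_width
    for res in out.residues:
        name = res.name.upper()
        if name in NEUTRAL_VARIANT:
            centroid = res.centroid(CHARGED_GROUP_ATOMS.get(name))
            d = sphere.distance(centroid)
            if d > cutoff:
                where = "outside sphere" if d > sphere.radius else "boundary shell"
                new = NEUTRAL_VARIANT[name]
                log.append(ChangeRecord(res.resid, res.name, new,
                                        f"charged-group centroid {d:.2f} Å from center ({where})"))
                res.name = new
        elif name not in STANDARD_RESIDUES:
            warnings.warn(f"unknown residue name {res.name!r} (id {res.resid}); "
                          "left unchanged", stacklevel=2)
    return out, log


def format_change_log(log: list[ChangeRecord]) -> str:
    header = " resid  change        reason\n"
    return header + "\n".join(rec.as_row() for rec in log) + ("\n" if log else "")


# ---------------------------------------------------------------------------
# Solvation
# ---------------------------------------------------------------------------

def solvate_sphere(sphere: SimulationSphere, existing: Structure,
                   grid_spacing: float = 3.1, clash_cutoff: float = 2.4,
                   first_resid: int | None = None,
                   grid_origin=None) -> Structure:
    """Fill the sphere with TIP3P waters on a cubic grid.

    Grid nodes are laid out on a cube around *grid_origin* (default: the
    sphere center) at *grid_spacing* Å pitch; a water (oxygen on the node,
    fixed-orientation TIP3P hydrogens) is kept iff the oxygen is within the
    sphere and no existing atom lies within *clash_cutoff* Å of it.
    Deterministic for fixed inputs; solvating an already-solvated system
    adds nothing because every node clashes with the water placed there
    before.
    """
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be positive")
    center = np.asarray(sphere.center, dtype=float)
    origin = center if grid_origin is None else np.asarray(grid_origin, dtype=float)
    m = int(math.floor((sphere.radius + float(np.linalg.norm(origin - center)))
                       / grid_spacing)) + 1
    offsets = np.arange(-m, m + 1) * grid_spacing
    coords = existing.coordinates()
    tree = cKDTree(coords) if len(coords) else None
    out = Structure(residues=copy.deepcopy(existing.residues))
    resid = first_resid if first_resid is not None else (
        max((r.resid for r in existing.residues), default=0) + 1)
    for dx in offsets:
        for dy in offsets:
            for dz in offsets:
                node = origin + (dx, dy, dz)
                if np.linalg.norm(node - center) > sphere.radius:
                    continue
                if tree is not None and tree.query(node)[0] <= clash_cutoff:
                    continue
                o = tuple(node)
                h1 = tuple(node + _TIP3P_H1)
                h2 = tuple(node + _TIP3P_H2)
                out.residues.append(Residue(name="HOH", resid=resid, atoms=[
                    AtomRecord("O", "O", o),
                    AtomRecord("H1", "H", h1),
                    AtomRecord("H2", "H", h2),
                ]))
                resid += 1
    return out


# ---------------------------------------------------------------------------
# PDB I/O for structures
# ---------------------------------------------------------------------------

def read_structure_pdb(path) -> Structure:
    """Read a protein/water structure from PDB ATOM/HETATM records."""
    from .ligand_io import LigandParseError, _infer_element

    structure = Structure()
    current: Residue | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            try:
                name = line[12:16].strip()
                resn = line[17:21].strip()
                resid = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                element = line[76:78].strip() if len(line) >= 78 else ""
            except (ValueError, IndexError):
                raise LigandParseError(
                    f"{path}: malformed record at line {lineno}") from None
            if current is None or current.resid != resid or current.name != resn:
                current = Residue(name=resn, resid=resid)
                structure.residues.append(current)
            current.atoms.append(AtomRecord(
                name=name, element=(element or _infer_element(name)).capitalize(),
                xyz=(x, y, z)))
    return structure


def write_structure_pdb(structure: Structure, path) -> None:
    serial = 1
    with open(path, "w") as fh:
        for res in structure.residues:
            for a in res.atoms:
                x, y, z = a.xyz
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                fh.write(
                    f"ATOM  {serial:5d} {name:<4.4s} {res.name:<4.4s} {res.resid:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                    f"{a.element.upper():>2.2s}\n")
                serial += 1
        fh.write("END\n")
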