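"""Ligand coordinate and force-field file handling.

Reads ligand coordinates from PDB, reads/writes topologies in a Q-style
library (``.lib``) text dialect and parameters in a ``.prm`` dialect, and
reads/writes a YAML "ligand interchange" document that carries a complete
ligand (atoms, charges, types, bonded lists) together with its parameter
tables.  The interchange format decouples the workflow from external
parameterization programs: any converter or a careful human can produce it.

The ``.lib`` dialect::

    {RES}
    [atoms]
        1 C1   c3   -0.060
        2 H1   hc    0.020
    [bonds]
        C1 H1
    [charge_groups]
        C1 H1

The ``.prm`` dialect holds ``[atom_types]`` (type, LJ well depth eps
kcal/mol, LJ radius rmin Å, mass amu), ``[bonds]`` (type pair, force
constant, equilibrium length), ``[angles]``, ``[torsions]`` and
``[impropers]`` tables, whitespace separated, ``#``/``!`` comments allowed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import yaml

__all__ = [
    "Atom",
    "LigandTopology",
    "ParameterSet",
    "ValidationReport",
    "LigandParseError",
    "IntegrityError",
    "ParameterConflictError",
    "MissingParameterError",
    "read_ligand_pdb",
    "write_ligand_pdb",
    "read_q_library",
    "write_q_library",
    "read_q_parameters",
    "write_q_parameters",
    "read_interchange",
    "write_interchange",
    "merge_parameter_sets",
    "validate_ligand",
    "derive_angles",
    "derive_torsions",
]


class LigandParseError(ValueError):
    """Raised when a ligand file cannot be parsed; message names the line."""


class IntegrityError(ValueError):
    """Raised when a file is syntactically valid but internally inconsistent."""


class ParameterConflictError(ValueError):
    """Raised when merged parameter sets disagree on a key."""


class MissingParameterError(KeyError):
    """Raised when a topology references parameters that cannot be resolved."""


@dataclass(frozen=True)
class Atom:
    """One ligand atom.

    ``partial_charge`` is in elementary charges, ``xyz`` in Å.  ``type_code``
    is the force-field atom type; ``element`` is the chemical element symbol.
    """

    name: str
    element: str
    type_code: str
    partial_charge: float
    xyz: tuple[float, float, float]


@dataclass
class LigandTopology:
    """A single ligand: atoms plus bonded structure.

    Bonded terms are tuples of 0-based atom indices.  ``charge_groups``
    partitions the atom indices; a ligand read from PDB alone has one
    default group containing all atoms and empty bonded lists until a
    library/interchange file supplies them.
    """

    residue_name: str
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[tuple[int, int]] = field(default_factory=list)
    angles: list[tuple[int, int, int]] = field(default_factory=list)
    torsions: list[tuple[int, int, int, int]] = field(default_factory=list)
    impropers: list[tuple[int, int, int, int]] = field(default_factory=list)
    charge_groups: list[list[int]] = field(default_factory=list)

    @property
    def net_charge(self) -> float:
        return float(sum(a.partial_charge for a in self.atoms))

    def atom_index(self, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.name == name:
                return i
        raise KeyError(f"no atom named {name!r} in ligand {self.residue_name}")

    def heavy_atom_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.element.upper() != "H"]

    def check(self) -> None:
        """Raise :class:`IntegrityError` on violated structural invariants."""
        names = [a.name for a in self.atoms]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise IntegrityError(f"duplicate atom names: {dupes}")
        n = len(self.atoms)
        for kind, terms in (
            ("bond", self.bonds),
            ("angle", self.angles),
            ("torsion", self.torsions),
            ("improper", self.impropers),
        ):
            for t in terms:
                if any(i < 0 or i >= n for i in t):
                    raise IntegrityError(f"{kind} {t} references invalid atom index")
        if self.charge_groups:
            flat = sorted(i for g in self.charge_groups for i in g)
            if flat != list(range(n)):
                raise IntegrityError("charge_groups do not partition the atom set")


@dataclass
class ParameterSet:
    """Force-field parameter tables keyed by atom-type codes.

    ``vdw`` maps type_code -> (epsilon kcal/mol, rmin Å); ``masses`` maps
    type_code -> amu.  Bonded tables are keyed by type tuples; key direction
    is canonicalized (a bond A-B equals B-A).
    """

    vdw: dict[str, tuple[float, float]] = field(default_factory=dict)
    masses: dict[str, float] = field(default_factory=dict)
    bond_params: dict[tuple[str, str], tuple[float, ...]] = field(default_factory=dict)
    angle_params: dict[tuple[str, str, str], tuple[float, ...]] = field(default_factory=dict)
    torsion_params: dict[tuple[str, str, str, str], tuple[float, ...]] = field(default_factory=dict)
    improper_params: dict[tuple[str, str, str, str], tuple[float, ...]] = field(default_factory=dict)

    @staticmethod
    def canon(key: tuple[str, ...]) -> tuple[str, ...]:
        rev = tuple(reversed(key))
        return min(key, rev)

    def n_entries(self) -> int:
        return (
            len(self.vdw)
            + len(self.masses)
            + len(self.bond_params)
            + len(self.angle_params)
            + len(self.torsion_params)
            + len(self.improper_params)
        )

    def resolves(self, topology: LigandTopology) -> list[str]:
        """Return the type codes referenced by *topology* that are missing."""
        missing = sorted(
            {a.type_code for a in topology.atoms if a.type_code not in self.vdw}
        )
        return missing


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

_ELEMENTS2 = {"CL", "BR", "NA", "MG", "ZN", "FE", "CA", "SE", "SI", "LI", "AL", "MN", "CU"}


def _infer_element(atom_name: str) -> str:
    stripped = "".join(c for c in atom_name if c.isalpha())
    if stripped[:2].upper() in _ELEMENTS2:
        return stripped[:2].capitalize()
    return stripped[:1].upper()


def read_ligand_pdb(path) -> LigandTopology:
    """Read ligand coordinates from ATOM/HETATM records of a PDB file.

    Atoms are returned in file order.  Parsing is by fixed PDB columns with a
    whitespace-split fallback for malformed column layouts.  No protonation,
    tautomer or connectivity inference is performed: bonded lists are empty
    and all atoms form one charge group.
    """
    atoms: list[Atom] = []
    residue_name = "LIG"
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            try:
                name = line[12:16].strip()
                resn = line[17:21].strip()
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                element = line[76:78].strip() if len(line) >= 78 else ""
            except (ValueError, IndexError):
                # fallback: record, serial, atom name, residue name,
                # [chain], [resid], then three consecutive coordinate floats
                fields = line.split()
                try:
                    name = fields[2]
                    resn = fields[3]
                    rest = fields[4:]
                    if rest and len(rest[0]) == 1 and rest[0].isalpha():
                        rest = rest[1:]  # chain id
                    if rest and rest[0].lstrip("-").isdigit():
                        rest = rest[1:]  # residue number
                    if len(rest) < 3 or not all(_is_float(v) for v in rest[:3]):
                        raise ValueError
                    x, y, z = (float(v) for v in rest[:3])
                    element = ""
                except (IndexError, ValueError):
                    raise LigandParseError(
                        f"{path}: malformed coordinate record at line {lineno}: {line.rstrip()!r}"
                    ) from None
            if not name:
                raise LigandParseError(f"{path}: empty atom name at line {lineno}")
            if resn:
                residue_name = resn
            if not element:
                element = _infer_element(name)
            atoms.append(Atom(name=name, element=element.capitalize(),
                              type_code="", partial_charge=0.0, xyz=(x, y, z)))
    if not atoms:
        raise LigandParseError(f"{path}: no ATOM/HETATM records found")
    top = LigandTopology(residue_name=residue_name, atoms=atoms,
                         charge_groups=[list(range(len(atoms)))])
    return top


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_ligand_pdb(topology: LigandTopology, path) -> None:
    """Write ligand atoms as HETATM records (Å, 1-based serials)."""
    with open(path, "w") as fh:
        for i, a in enumerate(topology.atoms, start=1):
            x, y, z = a.xyz
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            fh.write(
                f"HETATM{i:5d} {name:<4.4s} {topology.residue_name:<4.4s} {1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{a.element.upper():>2.2s}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Q library dialect
# ---------------------------------------------------------------------------

def _iter_sections(path):
    """Yield (section_name, lines) from a bracket-sectioned text file."""
    section = None
    lines: list[tuple[int, str]] = []
    header = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("!")[0].split("#")[0].strip()
            if not line:
                continue
            if line.startswith("{") and line.endswith("}"):
                header = line[1:-1].strip()
                continue
            if line.startswith("[") and line.endswith("]"):
                if section is not None:
                    yield section, lines
                section = line[1:-1].strip().lower()
                lines = []
                continue
            lines.append((lineno, line))
    if section is not None:
        yield section, lines
    if header is not None:
        yield "__header__", [(0, header)]


def read_q_library(path) -> LigandTopology:
    """Read a topology (sans coordinates) from the ``.lib`` dialect.

    Angles, torsions and impropers are derived deterministically from the
    bond graph, so ``write_q_library`` → ``read_q_library`` round-trips to
    an equal structure.  Unknown sections are skipped with a warning; a bond
    that names an absent atom raises :class:`IntegrityError`.
    """
    residue_name = "LIG"
    atoms: list[Atom] = []
    bond_names: list[tuple[str, str]] = []
    groups: list[list[str]] = []
    for section, lines in _iter_sections(path):
        if section == "__header__":
            residue_name = lines[0][1]
        elif section == "atoms":
            for lineno, line in lines:
                parts = line.split()
                if len(parts) < 4:
                    raise LigandParseError(f"{path}:{lineno}: expected 'index name type charge'")
                _, name, type_code, charge = parts[:4]
                element = parts[4] if len(parts) > 4 else _infer_element(name)
                try:
                    q = float(charge)
                except ValueError:
                    raise LigandParseError(f"{path}:{lineno}: bad charge {charge!r}") from None
                atoms.append(Atom(name=name, element=element.capitalize(),
                                  type_code=type_code, partial_charge=q,
                                  xyz=(0.0, 0.0, 0.0)))
        elif section == "bonds":
            for lineno, line in lines:
                parts = line.split()
                if len(parts) != 2:
                    raise LigandParseError(f"{path}:{lineno}: expected two atom names")
                bond_names.append((parts[0], parts[1]))
        elif section == "charge_groups":
            for _, line in lines:
                groups.append(line.split())
        else:
            warnings.warn(f"{path}: skipping unknown section [{section}]", stacklevel=2)

    name_to_idx = {a.name: i for i, a in enumerate(atoms)}
    bonds = []
    for a, b in bond_names:
        if a not in name_to_idx or b not in name_to_idx:
            missing = a if a not in name_to_idx else b
            raise IntegrityError(f"{path}: bond references absent atom {missing!r}")
        bonds.append((name_to_idx[a], name_to_idx[b]))
    charge_groups = []
    for g in groups:
        idx = []
        for nm in g:
            if nm not in name_to_idx:
                raise IntegrityError(f"{path}: charge group references absent atom {nm!r}")
            idx.append(name_to_idx[nm])
        charge_groups.append(idx)
    if not charge_groups and atoms:
        charge_groups = [list(range(len(atoms)))]
    top = LigandTopology(residue_name=residue_name, atoms=atoms, bonds=bonds,
                         charge_groups=charge_groups)
    top.angles = derive_angles(bonds)
    top.torsions = derive_torsions(bonds)
    top.check()
    return top


def write_q_library(topology: LigandTopology, path) -> None:
    """Write the topology in the ``.lib`` dialect (coordinates not stored)."""
    topology.check()
    with open(path, "w") as fh:
        fh.write(f"{{{topology.residue_name}}}\n")
        fh.write("[atoms]\n")
        for i, a in enumerate(topology.atoms, start=1):
            fh.write(f"    {i:4d} {a.name:<5s} {a.type_code or '??':<8s} "
                     f"{a.partial_charge: .4f}  {a.element}\n")
        fh.write("[bonds]\n")
        for i, j in topology.bonds:
            fh.write(f"    {topology.atoms[i].name} {topology.atoms[j].name}\n")
        fh.write("[charge_groups]\n")
        for group in topology.charge_groups:
            fh.write("    " + " ".join(topology.atoms[i].name for i in group) + "\n")


def derive_angles(bonds: list[tuple[int, int]]) -> list[tuple[int, int, int]]:
    """Enumerate i-j-k angles from the bond graph, deterministically ordered."""
    nbrs: dict[int, set[int]] = {}
    for i, j in bonds:
        nbrs.setdefault(i, set()).add(j)
        nbrs.setdefault(j, set()).add(i)
    angles = []
    for j in sorted(nbrs):
        adj = sorted(nbrs[j])
        for a in range(len(adj)):
            for b in range(a + 1, len(adj)):
                angles.append((adj[a], j, adj[b]))
    return angles


def derive_torsions(bonds: list[tuple[int, int]]) -> list[tuple[int, int, int, int]]:
    """Enumerate proper torsions i-j-k-l around every central bond j-k."""
    nbrs: dict[int, set[int]] = {}
    for i, j in bonds:
        nbrs.setdefault(i, set()).add(j)
        nbrs.setdefault(j, set()).add(i)
    torsions = []
    for j, k in sorted(tuple(sorted(b)) for b in bonds):
        for i in sorted(nbrs.get(j, ()) - {k}):
            for l in sorted(nbrs.get(k, ()) - {j, i}):
                torsions.append((i, j, k, l))
    return torsions


# ---------------------------------------------------------------------------
# Q parameter dialect
# ---------------------------------------------------------------------------

def write_q_parameters(params: ParameterSet, path,
                       required_by: LigandTopology | None = None) -> None:
    """Write parameter tables in the ``.prm`` dialect.

    If *required_by* is given, every atom type it references must resolve in
    *params*; otherwise :class:`MissingParameterError` lists the codes.
    """
    if required_by is not None:
        missing = params.resolves(required_by)
        if missing:
            raise MissingParameterError(
                f"unresolvable atom types for {required_by.residue_name}: {missing}"
            )
    with open(path, "w") as fh:
        fh.write("[atom_types]\n")
        for code in sorted(params.vdw):
            eps, rmin = params.vdw[code]
            mass = params.masses.get(code, 0.0)
            fh.write(f"    {code:<8s} {eps:10.4f} {rmin:10.4f} {mass:10.4f}\n")
        for title, table in (("bonds", params.bond_params),
                             ("angles", params.angle_params),
                             ("torsions", params.torsion_params),
                             ("impropers", params.improper_params)):
            fh.write(f"[{title}]\n")
            for key in sorted(table):
                vals = " ".join(f"{v:10.4f}" for v in table[key])
                fh.write("    " + " ".join(f"{c:<8s}" for c in key) + vals + "\n")


def read_q_parameters(path) -> ParameterSet:
    """Read the ``.prm`` dialect back into a :class:`ParameterSet`."""
    params = ParameterSet()
    arity = {"bonds": 2, "angles": 3, "torsions": 4, "impropers": 4}
    tables = {"bonds": params.bond_params, "angles": params.angle_params,
              "torsions": params.torsion_params, "impropers": params.improper_params}
    for section, lines in _iter_sections(path):
        if section == "atom_types":
            for lineno, line in lines:
                parts = line.split()
                if len(parts) < 3:
                    raise LigandParseError(f"{path}:{lineno}: expected 'type eps rmin [mass]'")
                code = parts[0]
                try:
                    eps, rmin = float(parts[1]), float(parts[2])
                    mass = float(parts[3]) if len(parts) > 3 else 0.0
                except ValueError:
                    raise LigandParseError(f"{path}:{lineno}: non-numeric parameter") from None
                params.vdw[code] = (eps, rmin)
                if mass:
                    params.masses[code] = mass
        elif section in arity:
            k = arity[section]
            for lineno, line in lines:
                parts = line.split()
                if len(parts) < k + 1:
                    raise LigandParseError(f"{path}:{lineno}: too few fields in [{section}]")
                key = ParameterSet.canon(tuple(parts[:k]))
                try:
                    vals = tuple(float(v) for v in parts[k:])
                except ValueError:
                    raise LigandParseError(f"{path}:{lineno}: non-numeric parameter") from None
                tables[section][key] = vals  # type: ignore[index]
        elif section != "__header__":
            warnings.warn(f"{path}: skipping unknown section [{section}]", stacklevel=2)
    return params


# ---------------------------------------------------------------------------
# Interchange format (YAML)
# ---------------------------------------------------------------------------

def write_interchange(topology: LigandTopology, params: ParameterSet, path) -> None:
    """Write a complete ligand (topology + coordinates + parameters) as YAML."""
    doc = {
        "ligand": {
            "residue_name": topology.residue_name,
            "atoms": [
                {"name": a.name, "element": a.element, "type": a.type_code,
                 "charge": a.partial_charge, "xyz": list(a.xyz)}
                for a in topology.atoms
            ],
            "bonds": [list(b) for b in topology.bonds],
            "impropers": [list(t) for t in topology.impropers],
            "charge_groups": [list(g) for g in topology.charge_groups],
        },
        "parameters": {
            "atom_types": {
                code: {"epsilon": eps, "rmin": rmin,
                       "mass": params.masses.get(code, 0.0)}
                for code, (eps, rmin) in params.vdw.items()
            },
            "bonds": {"|".join(k): list(v) for k, v in params.bond_params.items()},
            "angles": {"|".join(k): list(v) for k, v in params.angle_params.items()},
            "torsions": {"|".join(k): list(v) for k, v in params.torsion_params.items()},
            "impropers": {"|".join(k): list(v) for k, v in params.improper_params.items()},
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_interchange(path) -> tuple[LigandTopology, ParameterSet]:
    """Read a ligand interchange YAML document."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "ligand" not in doc:
        raise LigandParseError(f"{path}: not a ligand interchange document")
    lig = doc["ligand"]
    atoms = [
        Atom(name=a["name"], element=a["element"], type_code=a.get("type", ""),
             partial_charge=float(a.get("charge", 0.0)),
             xyz=tuple(float(v) for v in a.get("xyz", (0.0, 0.0, 0.0))))
        for a in lig.get("atoms", [])
    ]
    bonds = [tuple(b) for b in lig.get("bonds", [])]
    top = LigandTopology(
        residue_name=lig.get("residue_name", "LIG"),
        atoms=atoms,
        bonds=bonds,
        impropers=[tuple(t) for t in lig.get("impropers", [])],
        charge_groups=[list(g) for g in lig.get("charge_groups", [])]
        or [list(range(len(atoms)))],
    )
    top.angles = derive_angles(top.bonds)
    top.torsions = derive_torsions(top.bonds)
    top.check()
    params = ParameterSet()
    p = doc.get("parameters", {})
    for code, entry in p.get("atom_types", {}).items():
        params.vdw[code] = (float(entry["epsilon"]), float(entry["rmin"]))
        if entry.get("mass"):
            params.masses[code] = float(entry["mass"])
    tables = {"bonds": params.bond_params, "angles": params.angle_params,
              "torsions": params.torsion_params, "impropers": params.improper_params}
    for name, table in tables.items():
        for key, vals in p.get(name, {}).items():
            table[ParameterSet.canon(tuple(key.split("|")))] = tuple(float(v) for v in vals)  # type: ignore[index]
    return top, params


# ---------------------------------------------------------------------------
# Merging and validation
# ---------------------------------------------------------------------------

def merge_parameter_sets(*sets: ParameterSet) -> ParameterSet:
    """Union of parameter sets; identical duplicates deduplicate.

    Ligand-specific sets are merged with the general force-field set the same
    way.  A key present in two inputs with different values raises
    :class:`ParameterConflictError` naming the key and both values.
    """
    if not sets:
        raise ValueError("merge_parameter_sets requires at least one input set")
    out = ParameterSet()
    for ps in sets:
        for table_name in ("vdw", "masses", "bond_params", "angle_params",
                           "torsion_params", "improper_params"):
            src = getattr(ps, table_name)
            dst = getattr(out, table_name)
            for key, val in src.items():
                if key in dst and dst[key] != val:
                    raise ParameterConflictError(
                        f"conflicting {table_name} entry for {key!r}: "
                        f"{dst[key]!r} vs {val!r}"
                    )
                dst[key] = val
    return out


@dataclass
class ValidationReport:
    """Report-only ligand check: never raises."""

    net_charge: float
    integer_charge: bool
    missing_parameters: list[str]
    disconnected_atoms: list[str]

    @property
    def clean(self) -> bool:
        return self.integer_charge and not self.missing_parameters and not self.disconnected_atoms


def validate_ligand(topology: LigandTopology, params: ParameterSet,
                    charge_tol: float = 1e-3) -> ValidationReport:
    """Check net charge integrality, parameter coverage and connectivity.

    The net-charge tolerance (default 1e-3 e) absorbs rounding in published
    charge sets.  Atoms not reached from atom 0 through the bond graph are
    reported as disconnected (a ligand with no bonds reports none: there is
    no graph to contradict).
    """
    q = topology.net_charge
    integer = abs(q - round(q)) <= charge_tol
    missing = params.resolves(topology)
    disconnected: list[str] = []
    if topology.bonds and topology.atoms:
        seen = {0}
        stack = [0]
        nbrs: dict[int, list[int]] = {}
        for i, j in topology.bonds:
            nbrs.setdefault(i, []).append(j)
            nbrs.setdefault(j, []).append(i)
        while stack:
            cur = stack.pop()
            for nxt in nbrs.get(cur, []):
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        disconnected = [topology.atoms[i].name
                        for i in range(len(topology.atoms)) if i not in seen]
    return ValidationReport(net_charge=q, integer_charge=integer,
                            missing_parameters=missing,
                            disconnected_atoms=disconnected)


def with_coordinates(topology: LigandTopology,
                     coords: LigandTopology) -> LigandTopology:
    """Return *topology* with coordinates taken from *coords* by atom name."""
    by_name = {a.name: a.xyz for a in coords.atoms}
    new_atoms = []
    for a in topology.atoms:
        if a.name not in by_name:
            raise IntegrityError(f"coordinate set lacks atom {a.name!r}")
        new_atoms.append(replace(a, xyz=by_name[a.name]))
    out = replace(topology)
    out.atoms = new_atoms
    return out
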