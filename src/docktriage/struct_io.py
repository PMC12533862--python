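"""Readers, writers and internal containers for structures, poses and RMSD series.

All coordinates and distances are carried in Ångström internally; GROMACS-style
nm series are converted at the read boundary. Residue identity is the authored
PDB tuple (chain, residue number, insertion code, residue name) — no
renumbering is ever applied, so key-residue lists written against the deposited
receptor numbering match directly.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import gemmi
import numpy as np
from rdkit import Chem, RDLogger
from scipy.spatial.distance import cdist

from .errors import FormatError, UnknownElementError

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "ResidueKey",
    "AtomRecord",
    "ReceptorStructure",
    "MolecularGraph",
    "RmsdSeries",
    "read_receptor",
    "write_receptor",
    "read_ligand",
    "write_mol2",
    "perceive_bonds",
    "read_rmsd_series",
    "COVALENT_RADII",
]


class ResidueKey(NamedTuple):
    """Authored residue identity: (chain id, residue number, insertion code, name)."""

    chain: str
    number: int
    icode: str
    name: str

    def label(self) -> str:
        ic = self.icode.strip()
        return f"{self.chain}/{self.name}{self.number}{ic}"


@dataclass(frozen=True)
class AtomRecord:
    """One atom: element, author name, position (Å) and hydrogen flag.

    ``residue_key`` is set for receptor atoms and ``None`` for free-ligand atoms.
    """

    element: str
    name: str
    coords: np.ndarray
    is_hydrogen: bool
    residue_key: ResidueKey | None = None

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.name!r}: coordinates must be a finite 3-vector")
        object.__setattr__(self, "coords", coords)
        if self.is_hydrogen != (self.element == "H"):
            raise ValueError(f"atom {self.name!r}: is_hydrogen inconsistent with element {self.element!r}")


@dataclass
class ReceptorStructure:
    """Receptor atoms indexed by residue, plus any HETATM groups found alongside.

    ``residue_index`` maps each :class:`ResidueKey` to the indices of its atoms
    in ``atoms``; ``het_groups`` holds HETATM records (ligand/cofactor
    candidates) keyed the same way, kept separate from the polymer.
    """

    atoms: list[AtomRecord]
    residue_index: dict[ResidueKey, list[int]] = field(default_factory=dict)
    het_groups: dict[ResidueKey, list[AtomRecord]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.residue_index:
            index: dict[ResidueKey, list[int]] = {}
            for i, atom in enumerate(self.atoms):
                if atom.residue_key is None:
                    raise ValueError("receptor atoms must carry a residue key")
                index.setdefault(atom.residue_key, []).append(i)
            self.residue_index = index

    @property
    def residues(self) -> list[ResidueKey]:
        return list(self.residue_index)

    def residue_atoms(self, key: ResidueKey) -> list[AtomRecord]:
        return [self.atoms[i] for i in self.residue_index[key]]

    def residue_heavy_coords(self, key: ResidueKey) -> np.ndarray:
        atoms = [a for a in self.residue_atoms(key) if not a.is_hydrogen]
        return np.array([a.coords for a in atoms], dtype=float).reshape(-1, 3)


@dataclass
class MolecularGraph:
    """A small molecule as an explicit graph: atoms, bonds and 3-D coordinates.

    Bonds are unordered index pairs stored as sorted tuples; bond orders are
    not recorded (docking outputs frequently disagree on order assignment, so
    pose comparison uses connectivity + element only).
    """

    atoms: list[AtomRecord]
    bonds: set[tuple[int, int]]
    provenance: str = ""

    def __post_init__(self):
        n = len(self.atoms)
        norm = set()
        for i, j in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on atom index {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) references a missing atom")
            norm.add((min(i, j), max(i, j)))
        self.bonds = norm

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if not a.is_hydrogen]

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    def heavy_coords(self) -> np.ndarray:
        return np.array([self.atoms[i].coords for i in self.heavy_indices], dtype=float).reshape(-1, 3)

    def adjacency(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {i: set() for i in range(self.n_atoms)}
        for i, j in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def heavy_connected(self) -> bool:
        """True when the heavy-atom subgraph forms a single connected component."""
        heavy = set(self.heavy_indices)
        if not heavy:
            return False
        adj = self.adjacency()
        seen = set()
        stack = [next(iter(heavy))]
        while stack:
            i = stack.pop()
            if i in seen:
                continue
            seen.add(i)
            stack.extend(j for j in adj[i] if j in heavy and j not in seen)
        return seen == heavy


@dataclass
class RmsdSeries:
    """A per-replicate ligand-RMSD time series: times in ns, values in Å.

    ``censored_from`` is the index of the first frame replaced by the censor
    value after an early-stop crossing; ``None`` while uncensored.
    """

    replicate_id: str
    times: np.ndarray
    values: np.ndarray
    censored_from: int | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("RMSD values must be non-negative")
        if self.censored_from is not None and not (0 <= self.censored_from < len(self.times)):
            raise ValueError("censored_from must index into the series")

    def __len__(self) -> int:
        return len(self.times)


# Covalent radii (Å), single-bond values; the common organic/biological set.
COVALENT_RADII: Mapping[str, float] = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "Na": 1.66, "Mg": 1.41, "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02,
    "K": 2.03, "Ca": 1.76, "Fe": 1.32, "Zn": 1.22, "Se": 1.20, "Br": 1.20,
    "I": 1.39,
}

_BOND_TOLERANCE = 0.45  # Å added to the radii sum
_BOND_MIN = 0.4  # Å; closer pairs are treated as clashes, not bonds


def _validate_coordinate_fields(text: str) -> None:
    """Raise FormatError with a line number for unparseable PDB coordinates.

    gemmi silently zero-fills malformed numeric fields, so the coordinate
    columns are checked up front.
    """
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise FormatError(f"line {lineno}: ATOM/HETATM record too short for coordinates")
        for lo, hi in ((30, 38), (38, 46), (46, 54)):
            try:
                float(line[lo:hi])
            except ValueError:
                raise FormatError(
                    f"line {lineno}: unparseable coordinate field {line[lo:hi]!r}"
                ) from None


def _pick_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Resolve alternate locations: keep highest occupancy, tie broken toward 'A'."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for atom in residue:
        by_name.setdefault(atom.name, []).append(atom)
    chosen = []
    for name, group in by_name.items():
        if len(group) > 1:
            group.sort(key=lambda a: (-a.occ, a.altloc or "A"))
        chosen.append(group[0])
    return chosen


def read_receptor(pdb_text: str) -> ReceptorStructure:
    """Parse PDB text into a :class:`ReceptorStructure`.

    ATOM records populate the polymer; HETATM records are returned separately
    in ``het_groups`` as ligand/cofactor candidates. Alternate locations keep
    the highest-occupancy conformer (ties resolved toward altloc 'A').
    """
    _validate_coordinate_fields(pdb_text)
    if not any(l.startswith(("ATOM", "HETATM")) for l in pdb_text.splitlines()):
        raise FormatError("no ATOM/HETATM records found")
    structure = gemmi.read_pdb_string(pdb_text)
    if len(structure) == 0:
        raise FormatError("no models parsed from PDB text")
    model = structure[0]

    atoms: list[AtomRecord] = []
    het: dict[ResidueKey, list[AtomRecord]] = {}
    for chain in model:
        for residue in chain:
            key = ResidueKey(chain.name, residue.seqid.num, residue.seqid.icode.strip(), residue.name)
            for atom in _pick_altlocs(residue):
                element = atom.element.name
                rec = AtomRecord(
                    element=element,
                    name=atom.name,
                    coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    is_hydrogen=element == "H",
                    residue_key=key,
                )
                if residue.het_flag == "H":
                    het.setdefault(key, []).append(rec)
                else:
                    atoms.append(rec)
    return ReceptorStructure(atoms=atoms, het_groups=het)


def _format_pdb_line(record: str, serial: int, atom: AtomRecord) -> str:
    key = atom.residue_key
    assert key is not None
    name = atom.name
    # Standard placement: 1-char element symbols are indented one column.
    if len(name) < 4 and len(atom.element) == 1:
        name = f" {name}"
    return (
        f"{record:<6}{serial:>5} {name:<4} {key.name:>3} {key.chain:>1}"
        f"{key.number:>4}{key.icode or ' ':1}   "
        f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2}"
    )


def write_receptor(structure: ReceptorStructure) -> str:
    """Serialize a ReceptorStructure back to PDB text (3-decimal coordinates)."""
    lines = []
    serial = 0
    for atom in structure.atoms:
        serial += 1
        lines.append(_format_pdb_line("ATOM", serial, atom))
    for key, group in structure.het_groups.items():
        for atom in group:
            serial += 1
            lines.append(_format_pdb_line("HETATM", serial, atom))
    lines.append("END")
    return "\n".join(lines) + "\n"


def _graph_from_rdkit(mol: Chem.Mol, provenance: str) -> MolecularGraph:
    if mol.GetNumAtoms() == 0:
        raise FormatError("molecule record contains no atoms")
    if mol.GetNumConformers() == 0:
        raise FormatError("molecule record carries no 3-D coordinates")
    conf = mol.GetConformer()
    pos = conf.GetPositions()
    atoms = []
    for i, a in enumerate(mol.GetAtoms()):
        symbol = a.GetSymbol()
        atoms.append(
            AtomRecord(
                element=symbol,
                name=f"{symbol}{i + 1}",
                coords=pos[i],
                is_hydrogen=symbol == "H",
            )
        )
    bonds = {(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()}
    graph = MolecularGraph(atoms=atoms, bonds=bonds, provenance=provenance)
    if not graph.bonds and graph.n_atoms > 1:
        warnings.warn("record has no bond block; perceiving bonds from geometry")
        graph.bonds = perceive_bonds(graph.atoms)
    return graph


def read_ligand(text: str, fmt: str | None = None) -> MolecularGraph:
    """Parse one molecule from MOL2 or SDF text into a :class:`MolecularGraph`.

    The format is sniffed (``@<TRIPOS>`` marks MOL2) unless ``fmt`` is given.
    Multi-record inputs take the first molecule with a warning. Records
    without a bond block fall back to distance-based bond perception.
    """
    stripped = text.lstrip()
    if not stripped:
        raise FormatError("empty molecule text")
    if fmt is None:
        fmt = "mol2" if "@<TRIPOS>" in text else "sdf"
    fmt = fmt.lower()
    if fmt == "mol2":
        n_records = text.count("@<TRIPOS>MOLECULE")
        if n_records > 1:
            warnings.warn(f"MOL2 input has {n_records} molecules; taking the first")
            idx = text.index("@<TRIPOS>MOLECULE", text.index("@<TRIPOS>MOLECULE") + 1)
            text = text[:idx]
        mol = Chem.MolFromMol2Block(text, sanitize=False, removeHs=False)
    elif fmt in ("sdf", "sd", "mol"):
        records = [r for r in text.split("$$$$") if r.strip()]
        if len(records) > 1:
            warnings.warn(f"SDF input has {len(records)} molecules; taking the first")
        mol = Chem.MolFromMolBlock(records[0], sanitize=False, removeHs=False)
    else:
        raise FormatError(f"unsupported ligand format: {fmt!r}")
    if mol is None:
        raise FormatError(f"could not parse {fmt.upper()} molecule record")
    return _graph_from_rdkit(mol, provenance=fmt)


_SYBYL_TYPES = {"C": "C.3", "N": "N.3", "O": "O.3", "S": "S.3", "P": "P.3", "H": "H"}


def write_mol2(graph: MolecularGraph, name: str = "LIG") -> str:
    """Serialize a MolecularGraph to SYBYL MOL2 text (all bonds written as single)."""
    lines = [
        "@<TRIPOS>MOLECULE",
        name,
        f" {graph.n_atoms} {len(graph.bonds)} 0 0 0",
        "SMALL",
        "NO_CHARGES",
        "",
        "@<TRIPOS>ATOM",
    ]
    for i, atom in enumerate(graph.atoms, start=1):
        sybyl = _SYBYL_TYPES.get(atom.element, atom.element)
        x, y, z = atom.coords
        lines.append(
            f"{i:>7} {atom.name:<8}{x:>10.4f}{y:>10.4f}{z:>10.4f} {sybyl:<8}1  LIG1{0.0:>12.4f}"
        )
    lines.append("@<TRIPOS>BOND")
    for k, (i, j) in enumerate(sorted(graph.bonds), start=1):
        lines.append(f"{k:>6} {i + 1:>4} {j + 1:>4} 1")
    return "\n".join(lines) + "\n"


def perceive_bonds(atoms: Sequence[AtomRecord]) -> set[tuple[int, int]]:
    """Infer covalent bonds from geometry.

    Atoms i, j are bonded when their distance lies in
    [0.4 Å, r_cov(i) + r_cov(j) + 0.45 Å].
    """
    if len(atoms) == 0:
        raise ValueError("need at least one atom")
    radii = []
    for a in atoms:
        if a.element not in COVALENT_RADII:
            raise UnknownElementError(a.element)
        radii.append(COVALENT_RADII[a.element])
    radii = np.array(radii)
    coords = np.array([a.coords for a in atoms], dtype=float).reshape(-1, 3)
    dists = cdist(coords, coords)
    cut = radii[:, None] + radii[None, :] + _BOND_TOLERANCE
    bonds = set()
    ii, jj = np.nonzero((dists <= cut) & (dists >= _BOND_MIN))
    for i, j in zip(ii.tolist(), jj.tolist()):
        if i < j:
            bonds.add((i, j))
    return bonds


def read_rmsd_series(text: str, unit: str = "nm", replicate_id: str = "rep1") -> RmsdSeries:
    """Parse a two-column RMSD series from GROMACS XVG or CSV text.

    Lines starting with ``#`` or ``@`` (XVG metadata) are skipped, as is a
    single non-numeric CSV header line. Times are taken as ns; values are
    converted from nm to Å (×10) when ``unit="nm"``, or used as-is for
    ``unit="A"``/``"Å"``/``"angstrom"``.
    """
    unit_l = unit.lower()
    if unit_l == "nm":
        scale = 10.0
    elif unit_l in ("a", "å", "angstrom", "ang"):
        scale = 1.0
    else:
        raise ValueError(f"unit must be 'nm' or 'Å', got {unit!r}")

    rows = []
    header_skipped = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "@")):
            continue
        fields = line.split(",") if "," in line else line.split()
        if len(fields) < 2:
            raise FormatError(f"line {lineno}: expected two columns, got {len(fields)}")
        try:
            t, v = float(fields[0]), float(fields[1])
        except ValueError:
            if not rows and not header_skipped:
                header_skipped = True  # tolerate a single CSV header line
                continue
            raise FormatError(f"line {lineno}: non-numeric data {line!r}") from None
        rows.append((t, v))

    if len(rows) < 2:
        raise FormatError(f"need at least 2 data points, found {len(rows)}")
    arr = np.array(rows, dtype=float)
    if not np.all(np.diff(arr[:, 0]) > 0):
        raise FormatError("time column is not strictly increasing")
    return RmsdSeries(replicate_id=replicate_id, times=arr[:, 0], values=arr[:, 1] * scale)
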