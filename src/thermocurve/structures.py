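"""Protein structures and the geometric descriptors scored by the potentials.

A protein enters the pipeline as an ordered list of residues, each reduced to
a coarse-grained representation: the backbone atoms N, CA, C and the
geometric center of the heavy side-chain atoms.  Two kinds of descriptors are
computed from this representation:

* residue-pair descriptors -- the unordered amino-acid pair of two residues
  together with the binned spatial distance between their side-chain centers
  (27 bins: one below 3.0 A, 25 bins of 0.2 A between 3.0 and 8.0 A, one at
  or above 8.0 A);
* torsion descriptors -- the amino-acid type of a residue together with the
  discrete domain of the Ramachandran plane its backbone (phi, psi) angles
  fall in.

Glycine, which has no heavy side-chain atom, is represented by its CA
position so that it still contributes to the distance statistics.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser

__all__ = [
    "AA_THREE_TO_ONE",
    "AA_ONE_LETTER",
    "Residue",
    "ProteinStructure",
    "PairDescriptor",
    "TorsionDescriptor",
    "parse_pdb",
    "side_chain_center",
    "residue_distance",
    "distance_bin",
    "backbone_torsions",
    "assign_torsion_domain",
    "dihedral_angle",
    "N_DISTANCE_BINS",
    "DEFAULT_TORSION_DOMAINS",
    "UNDEFINED_DOMAIN",
]

AA_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_ONE_TO_THREE = {v: k for k, v in AA_THREE_TO_ONE.items()}
AA_ONE_LETTER = sorted(AA_THREE_TO_ONE.values())

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

#: number of distance bins: 1 underflow + 25 interior + 1 overflow
N_DISTANCE_BINS = 27
DISTANCE_LOW = 3.0
DISTANCE_HIGH = 8.0
DISTANCE_STEP = 0.2

UNDEFINED_DOMAIN = "undefined"

#: Rectangular partition of the Ramachandran plane into 7 domains.  Each row
#: is (label, phi_lo, phi_hi, psi_lo, psi_hi) with half-open [lo, hi)
#: rectangles checked in order; the first match wins and anything left maps
#: to the catch-all "O".  Angles are normalised to [-180, 180).  The table is
#: a package default and can be overridden through the configuration.
DEFAULT_TORSION_DOMAINS = [
    ("A", -110.0, -40.0, -80.0, -5.0),    # right-handed alpha helix
    ("C", -180.0, -40.0, -5.0, 60.0),     # helical-adjacent core
    ("B", -180.0, -90.0, 90.0, 180.0),    # extended / beta strand
    ("P", -90.0, -40.0, 90.0, 180.0),     # polyproline-like
    ("G", 30.0, 110.0, -20.0, 80.0),      # left-handed helix
    ("E", 30.0, 180.0, 130.0, 180.0),     # epsilon
    # catch-all "O" for everything else
]


@dataclass
class Residue:
    """One amino-acid residue in the coarse-grained representation.

    ``center`` is the arithmetic mean of the heavy side-chain atom
    coordinates, or the CA position for residues without side-chain atoms
    (glycine, incomplete residues).  A residue lacking both is unusable for
    distance statistics and has ``center is None``.
    """

    index: int
    aa_type: str
    backbone_coords: dict[str, np.ndarray] = field(default_factory=dict)
    side_chain_coords: np.ndarray | None = None
    center: np.ndarray | None = field(default=None, init=False)

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"residue index must be >= 1, got {self.index}")
        if self.aa_type not in AA_ONE_TO_THREE:
            raise ValueError(f"unknown amino acid code {self.aa_type!r}")
        self.center = side_chain_center(self)

    @property
    def usable(self) -> bool:
        return self.center is not None


@dataclass
class ProteinStructure:
    """A single-chain protein with optional thermal metadata.

    ``tm_exp`` and ``t_env`` are in degrees Celsius; ``dcp_exp`` is the
    experimental heat-capacity change reported as an unfolding-convention
    magnitude (kcal/mol/K); ``dg25_exp`` is the folding free energy at 25 C
    (kcal/mol, negative for a stable protein).
    """

    id: str
    chain: str
    residues: list[Residue]
    family: str | None = None
    tm_exp: float | None = None
    t_env: float | None = None
    dcp_exp: float | None = None
    dg25_exp: float | None = None

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"{self.id}: structure has no residues")
        indices = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValueError(f"{self.id}: residues not strictly ordered by index")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa_type for r in self.residues)


@dataclass(frozen=True)
class PairDescriptor:
    """Unordered amino-acid pair plus distance-bin index."""

    aa_pair: tuple[str, str]
    bin: int

    def __post_init__(self) -> None:
        if tuple(sorted(self.aa_pair)) != self.aa_pair:
            raise ValueError("aa_pair must be lexicographically ordered")
        if not 0 <= self.bin < N_DISTANCE_BINS:
            raise ValueError(f"bin {self.bin} out of range")


@dataclass(frozen=True)
class TorsionDescriptor:
    """Amino-acid type plus backbone torsion domain label."""

    aa: str
    domain: str


def side_chain_center(residue: Residue) -> np.ndarray | None:
    """Geometric center of the heavy side-chain atoms.

    Falls back to the CA position when the residue has no side-chain heavy
    atoms; returns ``None`` when neither is available (the residue is then
    excluded from pair counting).
    """
    sc = residue.side_chain_coords
    if sc is not None and len(sc) > 0:
        return np.asarray(sc, dtype=float).mean(axis=0)
    ca = residue.backbone_coords.get("CA")
    if ca is not None:
        return np.asarray(ca, dtype=float)
    return None


def residue_distance(p: ProteinStructure, i: int, j: int) -> float:
    """Euclidean distance (A) between the side-chain centers of residues i, j.

    ``i`` and ``j`` are 1-based residue indices as stored on the residues.
    """
    if i == j:
        raise ValueError("residue_distance requires two distinct residues")
    by_index = {r.index: r for r in p.residues}
    try:
        ri, rj = by_index[i], by_index[j]
    except KeyError as exc:
        raise KeyError(f"{p.id}: no residue with index {exc.args[0]}") from None
    if not (ri.usable and rj.usable):
        raise ValueError(f"{p.id}: pair ({i},{j}) skipped, unusable residue")
    return float(np.linalg.norm(ri.center - rj.center))


def distance_bin(d: float) -> int:
    """Map a distance (A) to one of the 27 bins.

    Bin 0 collects d < 3.0 A, bins 1..25 cover [3.0, 8.0) in half-open
    0.2 A steps, and bin 26 collects d >= 8.0 A.
    """
    if d < 0:
        raise ValueError(f"invalid distance {d}")
    if d < DISTANCE_LOW:
        return 0
    if d >= DISTANCE_HIGH:
        return N_DISTANCE_BINS - 1
    k = 1 + int(math.floor((d - DISTANCE_LOW) / DISTANCE_STEP))
    return min(k, N_DISTANCE_BINS - 2)


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
                   p3: np.ndarray) -> float:
    """Signed dihedral angle (degrees, in (-180, 180]) of four points."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.linalg.norm(b1)
    if nb1 == 0:
        raise ValueError("degenerate dihedral: coincident central atoms")
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang == -180.0 else ang


def backbone_torsions(p: ProteinStructure) -> list[tuple[float | None, float | None]]:
    """Backbone (phi, psi) angles in degrees for every residue.

    phi is undefined at the first residue and psi at the last; angles
    involving a missing backbone atom are also undefined and returned as
    ``None``.  Residues are treated as sequential neighbours in storage
    order.
    """
    out: list[tuple[float | None, float | None]] = []
    res = p.residues
    for k, r in enumerate(res):
        phi: float | None = None
        psi: float | None = None
        n, ca, c = (r.backbone_coords.get(a) for a in ("N", "CA", "C"))
        complete = n is not None and ca is not None and c is not None
        if k > 0 and complete:
            c_prev = res[k - 1].backbone_coords.get("C")
            if c_prev is not None:
                phi = dihedral_angle(c_prev, n, ca, c)
        if k < len(res) - 1 and complete:
            n_next = res[k + 1].backbone_coords.get("N")
            if n_next is not None:
                psi = dihedral_angle(n, ca, c, n_next)
        out.append((phi, psi))
    return out


def _norm_angle(a: float) -> float:
    """Normalise to [-180, 180)."""
    a = math.fmod(a + 180.0, 360.0)
    if a < 0:
        a += 360.0
    return a - 180.0


def assign_torsion_domain(
    phi: float | None,
    psi: float | None,
    table: list[tuple[str, float, float, float, float]] | None = None,
) -> str:
    """Assign a torsion-domain label to a (phi, psi) pair.

    Rectangles of ``table`` are checked in order (half-open in both angles,
    first match wins); anything unmatched maps to the catch-all label "O".
    A missing angle yields the distinguished "undefined" label, excluded
    from torsion counting.
    """
    if phi is None or psi is None:
        return UNDEFINED_DOMAIN
    if table is None:
        table = DEFAULT_TORSION_DOMAINS
    phi = _norm_angle(phi)
    psi = _norm_angle(psi)
    for label, plo, phi_hi, slo, shi in table:
        if plo <= phi < phi_hi and slo <= psi < shi:
            return label
    return "O"


def _pick_altloc(atoms: list) -> "object":
    """altLoc rule: highest occupancy wins; ties prefer altloc 'A'/blank."""
    def key(atom):
        occ = atom.get_occupancy()
        occ = 0.0 if occ is None else occ
        alt = atom.get_altloc()
        # blank or 'A' preferred on ties, then lexicographic
        pref = 0 if alt in (" ", "", "A") else 1
        return (-occ, pref, alt)

    return sorted(atoms, key=key)[0]


def parse_pdb(pdb_text: str, chain: str, structure_id: str = "protein",
              **metadata) -> ProteinStructure:
    """Parse PDB-format text into a :class:`ProteinStructure`.

    Keeps standard amino-acid ATOM records of the requested chain, ordered
    by (resSeq, iCode); waters, HETATM records and non-standard residues are
    skipped.  Hydrogens and backbone O/OXT atoms never enter the side-chain
    center.  Alternate locations keep the highest-occupancy copy (ties go
    to altloc 'A').
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(structure_id, io.StringIO(pdb_text))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise ValueError(f"{structure_id}: empty chain {chain!r}") from None
    if chain not in [c.id for c in model]:
        raise ValueError(f"{structure_id}: empty chain {chain!r}")

    residues: list[Residue] = []
    raw = [r for r in model[chain] if r.id[0] == " "]
    raw.sort(key=lambda r: (r.id[1], r.id[2]))
    for res in raw:
        name = res.get_resname().strip()
        if name not in AA_THREE_TO_ONE:
            continue
        # group atoms by name, resolving altlocs explicitly
        groups: dict[str, list] = {}
        for atom in res.get_unpacked_list():
            if atom.element == "H" or atom.get_name().startswith("H"):
                continue
            groups.setdefault(atom.get_name(), []).append(atom)
        backbone: dict[str, np.ndarray] = {}
        side: list[np.ndarray] = []
        for atom_name, atoms in groups.items():
            atom = _pick_altloc(atoms)
            coord = np.asarray(atom.get_coord(), dtype=float)
            if atom_name in BACKBONE_ATOMS:
                if atom_name in ("N", "CA", "C"):
                    backbone[atom_name] = coord
            else:
                side.append(coord)
        try:
            residues.append(
                Residue(
                    index=len(residues) + 1,
                    aa_type=AA_THREE_TO_ONE[name],
                    backbone_coords=backbone,
                    side_chain_coords=np.array(side) if side else None,
                )
            )
        except ValueError as exc:  # pragma: no cover - defensive
            warnings.warn(f"{structure_id}: skipping residue {res.id}: {exc}")
    if not residues:
        raise ValueError(f"{structure_id}: no standard residues in chain {chain!r}")
    return ProteinStructure(id=structure_id, chain=chain, residues=residues,
                            **metadata)
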