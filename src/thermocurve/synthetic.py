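"""Synthetic study generators: toy structures and homologous families.

Two generators provide everything needed to exercise the pipeline without
experimental data:

* :func:`generate_toy_structures` builds mesostable and thermostable sets
  of ideal-geometry helical chains in which one amino-acid pair's contact
  association is enriched in the thermostable set by a prescribed odds
  factor rho.  The backbone is a poly-helix built from ideal internal
  coordinates; every residue carries a CB side-chain atom (glycine is kept
  out of the alphabet so all side-chain centers share one geometry), and
  the contact bin is the distance bin of the (i, i+4) CB pairs.  Planting
  replaces the sequence at disjoint (i, i+4) slots with the enriched pair
  at set-specific rates chosen so the expected association ratio
  F(s,c)/(F(s)F(c)) differs between the sets by exactly rho.
* :func:`generate_family` draws homologous-family members with true
  Gibbs-Helmholtz parameters and observes their folding free energy at
  three temperatures with independent Gaussian noise, so full-pipeline
  parameter recovery can be scored against known truth.

All generators are pure functions of their spec (seed included), and toy
structures round-trip through the PDB writer/parser at the precision the
pipeline consumes (coordinates are rounded to PDB's three decimals at
construction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .curvefit import CELSIUS_TO_KELVIN, StabilityCurve
from .free_energy import FreeEnergyTriple
from .structures import (
    AA_ONE_LETTER,
    AA_ONE_TO_THREE,
    ProteinStructure,
    Residue,
    distance_bin,
)

__all__ = [
    "PlantedContactSpec",
    "SyntheticFamilySpec",
    "FamilyMember",
    "build_backbone",
    "place_atom",
    "generate_toy_structures",
    "generate_family",
    "structure_to_pdb",
    "write_study",
    "IDEAL_HELIX_PHI_PSI",
]

# ideal backbone internal coordinates (A, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_CA_CB = 1.530
ANG_N_CA_C = 111.2
ANG_CA_C_N = 116.2
ANG_C_N_CA = 121.7
ANG_N_CA_CB = 110.5
TORSION_N_C_CA_CB = 122.5

IDEAL_HELIX_PHI_PSI = (-57.0, -47.0)

#: alphabet without glycine so that every residue has a CB side-chain center
ALPHABET = tuple(a for a in AA_ONE_LETTER if a != "G")


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D from reference atoms A-B-C and internal coordinates.

    ``bond`` is |C-D|, ``angle_deg`` the B-C-D angle and ``torsion_deg``
    the A-B-C-D dihedral (natural extension reference frame).
    """
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * math.cos(ang),
                  bond * math.sin(ang) * math.cos(tor),
                  bond * math.sin(ang) * math.sin(tor)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(
    phis: list[float],
    psis: list[float],
    omega: float = 180.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Backbone N, CA, C coordinates from torsion angles, ideal geometry.

    ``phis[0]`` and ``psis[-1]`` are unused (undefined at the termini).
    Returns three (L, 3) arrays.
    """
    L = len(phis)
    if len(psis) != L or L < 1:
        raise ValueError("phis and psis must have equal positive length")
    n_atoms = [np.array([0.0, 0.0, 0.0])]
    ca_atoms = [np.array([BOND_N_CA, 0.0, 0.0])]
    ang = math.radians(ANG_N_CA_C)
    c_atoms = [ca_atoms[0] + BOND_CA_C * np.array([-math.cos(ang),
                                                   math.sin(ang), 0.0])]
    for i in range(1, L):
        n_atoms.append(place_atom(n_atoms[i - 1], ca_atoms[i - 1],
                                  c_atoms[i - 1], BOND_C_N, ANG_CA_C_N,
                                  psis[i - 1]))
        ca_atoms.append(place_atom(ca_atoms[i - 1], c_atoms[i - 1],
                                   n_atoms[i], BOND_N_CA, ANG_C_N_CA, omega))
        c_atoms.append(place_atom(c_atoms[i - 1], n_atoms[i], ca_atoms[i],
                                  BOND_CA_C, ANG_N_CA_C, phis[i]))
    return np.array(n_atoms), np.array(ca_atoms), np.array(c_atoms)


def _cb_positions(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    return np.array([
        place_atom(n[i], c[i], ca[i], BOND_CA_CB, ANG_N_CA_CB,
                   TORSION_N_C_CA_CB)
        for i in range(len(ca))
    ])


@dataclass(frozen=True)
class PlantedContactSpec:
    """Design of the planted-contact toy structure sets.

    ``odds_factor`` is the target ratio of the enriched cell's association
    ratio F(s,c)/(F(s)F(c)) between the thermostable and mesostable sets.
    ``baseline_rate`` is the per-chain planting probability in the
    mesostable set.  Every chain carries exactly two copies of each
    enriched amino acid regardless of planting, so the pair-type marginal
    F(s) is planting-invariant and the enrichment is a pure
    sequence-structure association.
    """

    enriched_pair: tuple[str, str] = ("I", "L")
    odds_factor: float = 4.0
    n_structures: int = 200
    chain_length: int = 30
    baseline_rate: float = 0.02
    min_separation: int = 2
    tm_intercept: float = 45.0
    tm_slope: float = 30.0
    tm_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.odds_factor <= 0:
            raise ValueError("odds factor must be positive")
        if self.chain_length < 10:
            raise ValueError("chain_length must be at least 10")
        a, b = self.enriched_pair
        if a not in ALPHABET or b not in ALPHABET or a == b:
            raise ValueError("enriched pair must be two distinct non-glycine "
                             "amino acids")


def _slot_positions(chain_length: int) -> list[tuple[int, int]]:
    """Disjoint (i, i+4) contact slots (0-based positions)."""
    return [(i, i + 4) for i in range(0, chain_length - 4, 5)]


#: copies of each enriched amino acid carried by every chain
N_COPIES = 2


def _planting_geometry(spec: PlantedContactSpec):
    """Template geometry quantities entering the planting-rate algebra."""
    L = spec.chain_length
    phis = [IDEAL_HELIX_PHI_PSI[0]] * L
    psis = [IDEAL_HELIX_PHI_PSI[1]] * L
    n, ca, c = build_backbone(phis, psis)
    cb = np.round(_cb_positions(n, ca, c), 3)
    slots = _slot_positions(L)
    target_bin = distance_bin(float(np.linalg.norm(cb[slots[0][0]] -
                                                   cb[slots[0][1]])))
    n_pairs = 0      # qualifying pairs (|i-j| >= min_separation)
    k_cell = 0       # qualifying pairs in the enriched cell's bin
    for i in range(L):
        for j in range(i + spec.min_separation, L):
            n_pairs += 1
            if distance_bin(float(np.linalg.norm(cb[i] - cb[j]))) == target_bin:
                k_cell += 1
    return (n, ca, c, cb), slots, target_bin, n_pairs, k_cell


def _association_ratio(r: float, n_pairs: int, k_cell: int, L: int) -> float:
    """Expected F(s,c)/(F(s)F(c)) of the enriched cell at planting rate r.

    With a fixed composition of two copies of each enriched amino acid,
    every chain contains exactly four enriched position pairs; with
    probability r one of them sits in a contact slot (hence in the cell's
    bin) and the rest fall on uniformly random positions.
    """
    n_pos_pairs = L * (L - 1) // 2
    p_cell = k_cell / n_pos_pairs       # random pair lands in the cell
    p_qual = n_pairs / n_pos_pairs      # random pair qualifies at all
    n_sp = N_COPIES * N_COPIES          # enriched position pairs per chain
    f_sc = r * (1.0 + (n_sp - 1) * p_cell) + (1.0 - r) * n_sp * p_cell
    f_s = r * (1.0 + (n_sp - 1) * p_qual) + (1.0 - r) * n_sp * p_qual
    return (f_sc * n_pairs) / (f_s * k_cell)


def _solve_planting_rates(spec: PlantedContactSpec, n_pairs: int,
                          k_cell: int) -> tuple[float, float]:
    L = spec.chain_length
    ratio = lambda r: _association_ratio(r, n_pairs, k_cell, L)
    r_m = spec.baseline_rate
    if spec.odds_factor == 1.0:
        return r_m, r_m
    if spec.odds_factor > 1.0:
        target = spec.odds_factor * ratio(r_m)
        if ratio(1.0) < target:
            raise ValueError(
                f"odds factor {spec.odds_factor} infeasible for chain "
                f"length {spec.chain_length}: maximum association ratio is "
                f"{ratio(1.0):.2f}")
        return r_m, brentq(lambda r: ratio(r) - target, r_m, 1.0, xtol=1e-12)
    # odds factor below 1: enrich the mesostable set instead
    target = ratio(r_m) / spec.odds_factor
    if ratio(1.0) < target:
        raise ValueError(
            f"odds factor {spec.odds_factor} infeasible for chain length "
            f"{spec.chain_length}")
    return brentq(lambda r: ratio(r) - target, r_m, 1.0, xtol=1e-12), r_m


def _make_structure(
    sid: str, coords, sequence: str, tm: float, family: str | None = None,
) -> ProteinStructure:
    n, ca, c, cb = coords
    residues = []
    for i, aa in enumerate(sequence):
        residues.append(Residue(
            index=i + 1,
            aa_type=aa,
            backbone_coords={"N": n[i], "CA": ca[i], "C": c[i]},
            side_chain_coords=cb[i:i + 1].copy(),
        ))
    return ProteinStructure(id=sid, chain="A", residues=residues,
                            family=family, tm_exp=round(float(tm), 2))


def _sample_set(rng: np.random.Generator, spec: PlantedContactSpec,
                coords, slots, rate: float, prefix: str,
                n_structures: int) -> list[ProteinStructure]:
    out = []
    L = spec.chain_length
    a_star, b_star = spec.enriched_pair
    background = np.array([a for a in ALPHABET if a not in (a_star, b_star)])
    for k in range(n_structures):
        seq = rng.choice(background, size=L)
        planted = bool(rng.random() < rate)
        used: list[int] = []
        copies = [a_star] * N_COPIES + [b_star] * N_COPIES
        if planted:
            i, j = slots[rng.integers(len(slots))]
            if rng.random() < 0.5:
                seq[i], seq[j] = a_star, b_star
            else:
                seq[i], seq[j] = b_star, a_star
            used = [i, j]
            copies.remove(a_star)
            copies.remove(b_star)
        free = np.array([p for p in range(L) if p not in used])
        pos = rng.choice(free, size=len(copies), replace=False)
        for p_, aa in zip(pos, copies):
            seq[p_] = aa
        tm = (spec.tm_intercept + spec.tm_slope * int(planted)
              + rng.normal(0.0, spec.tm_noise_sd))
        out.append(_make_structure(f"{prefix}_{k:04d}", coords,
                                   "".join(seq), tm))
    return out


def generate_toy_structures(
    spec: PlantedContactSpec,
) -> tuple[list[ProteinStructure], list[ProteinStructure], list[ProteinStructure]]:
    """Mesostable, thermostable and union sets with a planted contact signal.

    All chains share one ideal-helix template geometry; the thermostable
    planting rate is solved so the enriched cell's expected association
    ratio exceeds the mesostable one by the spec's odds factor.  The
    per-structure melting temperature is affine in the planted-contact
    content plus Gaussian noise.  Deterministic given the spec.
    """
    coords, slots, target_bin, n_pairs, k_cell = _planting_geometry(spec)
    r_m, r_t = _solve_planting_rates(spec, n_pairs, k_cell)
    rng = np.random.default_rng(spec.seed)
    meso = _sample_set(rng, spec, coords, slots, r_m, "meso",
                       spec.n_structures)
    thermo = _sample_set(rng, spec, coords, slots, r_t, "thermo",
                         spec.n_structures)
    return meso, thermo, meso + thermo


def enriched_cell(spec: PlantedContactSpec) -> tuple[tuple[str, str], int]:
    """The (aa pair, distance bin) cell the generator enriches."""
    _, _, target_bin, _, _ = _planting_geometry(spec)
    return tuple(sorted(spec.enriched_pair)), target_bin


@dataclass(frozen=True)
class SyntheticFamilySpec:
    """Design of one synthetic homologous family.

    A family-center parameter set is drawn uniformly from the given ranges
    (folding convention: dHm and dCp negative); members jitter around the
    center -- melting temperatures by up to ``member_tm_spread`` degrees,
    enthalpy and heat capacity by up to ``member_scale_spread`` relative --
    mirroring the fact that homologous proteins share size and overall
    energetics while their thermal resistance varies.  The folding free
    energy of each member is observed at ``obs_temps_c`` with independent
    Gaussian noise of standard deviation ``noise_sd`` (same units as dG,
    kcal/mol).
    """

    n_members: int = 4
    tm_range: tuple[float, float] = (40.0, 100.0)   # Celsius
    dHm_range: tuple[float, float] = (-150.0, -60.0)  # kcal/mol
    dCp_range: tuple[float, float] = (-3.0, -0.8)   # kcal/mol/K
    member_tm_spread: float = 15.0       # Celsius, within-family
    member_scale_spread: float = 0.15    # relative, within-family
    noise_sd: float = 0.5
    obs_temps_c: tuple[float, float, float] = (45.0, 65.0, 85.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for lo, hi in (self.tm_range, self.dHm_range, self.dCp_range):
            if hi < lo:
                raise ValueError("ranges must satisfy lo <= hi")


@dataclass
class FamilyMember:
    """One synthetic family member with full ground truth."""

    id: str
    true_curve: StabilityCurve
    triple: FreeEnergyTriple
    tm_true: float      # Celsius
    dcp_true: float     # folding convention, kcal/mol/K
    dg25_true: float    # kcal/mol
    family: str = "fam"


def generate_family(spec: SyntheticFamilySpec) -> list[FamilyMember]:
    """Draw one homologous family with noisy three-point dG observations."""
    rng = np.random.default_rng(spec.seed)
    tm_center = rng.uniform(*spec.tm_range)
    dhm_center = rng.uniform(*spec.dHm_range)
    dcp_center = rng.uniform(*spec.dCp_range)
    out = []
    for k in range(spec.n_members):
        tm_c = tm_center + rng.uniform(-spec.member_tm_spread,
                                       spec.member_tm_spread)
        dhm = dhm_center * (1.0 + rng.uniform(-spec.member_scale_spread,
                                              spec.member_scale_spread))
        dcp = dcp_center * (1.0 + rng.uniform(-spec.member_scale_spread,
                                              spec.member_scale_spread))
        curve = StabilityCurve.from_params(dhm, tm_c + CELSIUS_TO_KELVIN, dcp)
        points = []
        for t_c in spec.obs_temps_c:
            t_k = t_c + CELSIUS_TO_KELVIN
            dg = curve.evaluate(t_k) + rng.normal(0.0, spec.noise_sd)
            points.append((t_k, float(dg)))
        out.append(FamilyMember(
            id=f"member_{k:02d}",
            true_curve=curve,
            triple=FreeEnergyTriple(points=points),
            tm_true=tm_c,
            dcp_true=dcp,
            dg25_true=float(curve.evaluate(298.15)),
        ))
    return out


def structure_to_pdb(p: ProteinStructure) -> str:
    """Serialise a structure as minimal PDB-format ATOM records."""
    lines = []
    serial = 1
    for r in p.residues:
        resname = AA_ONE_TO_THREE[r.aa_type]
        atoms = [(name, r.backbone_coords[name])
                 for name in ("N", "CA", "C") if name in r.backbone_coords]
        if r.side_chain_coords is not None:
            for k, coord in enumerate(r.side_chain_coords):
                atoms.append((f"CB" if k == 0 else f"C{k+1}G", coord))
        for name, coord in atoms:
            x, y, z = (float(v) for v in coord)
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s}{resname:>4s} {p.chain}"
                f"{r.index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                f"          {name[0]:>2s}")
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_study(
    out_dir: str | Path,
    spec: PlantedContactSpec,
) -> Path:
    """Emit a complete synthetic study: PDB files, metadata TSV, truth TSV.

    The metadata table has the columns the pipeline's readers expect
    (id, pdb_path, chain, family, tm_exp_c, t_env_c, dcp_exp, dg25_exp);
    families are assigned round-robin within each thermal set so the
    leave-one-family-out machinery can be exercised.
    """
    out_dir = Path(out_dir)
    pdb_dir = out_dir / "pdb"
    pdb_dir.mkdir(parents=True, exist_ok=True)
    meso, thermo, everything = generate_toy_structures(spec)
    n_families = max(2, min(6, len(everything) // 4))
    meta_rows = ["id\tpdb_path\tchain\tfamily\ttm_exp_c\tt_env_c\tdcp_exp\tdg25_exp"]
    truth_rows = ["id\tset\ttm_true_c"]
    for k, p in enumerate(everything):
        fam = f"fam{k % n_families}"
        p.family = fam
        pdb_path = pdb_dir / f"{p.id}.pdb"
        pdb_path.write_text(structure_to_pdb(p))
        meta_rows.append(
            f"{p.id}\t{pdb_path.relative_to(out_dir)}\t{p.chain}\t{fam}\t"
            f"{p.tm_exp}\t\t\t")
        which = "meso" if p in meso else "thermo"
        truth_rows.append(f"{p.id}\t{which}\t{p.tm_exp}")
    (out_dir / "metadata.tsv").write_text("\n".join(meta_rows) + "\n")
    (out_dir / "truth.tsv").write_text("\n".join(truth_rows) + "\n")
    return out_dir
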