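"""Folding free energies at the three dataset temperatures.

Scoring a protein with the potential pair (distance + torsion) derived from
one thermal dataset yields its folding free energy at that dataset's mean
melting temperature.  The two potential types are mixed with non-negative
coefficients alpha:

    dG_D = ( sum_nu alpha_nu E_nu(D) ) / N,   N = sum_nu alpha_nu

so dG is invariant under a common rescaling of the alphas.  The alphas are
calibrated so that the difference between thermo- and meso-scored energies
anticorrelates as strongly as possible with the experimental melting
temperature; the fit is an ordinary least squares of Tm on the per-type
energy differences (normalised per pair/residue so proteins of different
length are comparable), with negative-direction slopes retained and
wrong-sign slopes clipped to zero.  Calibration always excludes the
homologous family of the protein being predicted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .potentials import PotentialSet
from .structures import ProteinStructure, assign_torsion_domain, backbone_torsions
from .potentials import _structure_pair_cells

__all__ = [
    "EnergyProfile",
    "AlphaCoefficients",
    "FreeEnergyTriple",
    "score_protein",
    "folding_free_energy",
    "free_energy_triple",
    "calibrate_alphas",
    "CalibrationProtein",
    "POTENTIAL_TYPES",
]

POTENTIAL_TYPES = ("distance", "torsion")

CELSIUS_TO_KELVIN = 273.15


@dataclass
class EnergyProfile:
    """Raw per-type energies of one protein under one dataset's potentials."""

    per_type_energy: dict[str, float]
    n_pairs: int
    n_residues: int
    dataset_tag: str

    def normalized(self, kind: str) -> float:
        """Energy per scored term (pair or residue) for one potential type."""
        n = self.n_pairs if kind == "distance" else self.n_residues
        return self.per_type_energy[kind] / n if n else 0.0


@dataclass
class AlphaCoefficients:
    """Non-negative mixing coefficients for the potential types."""

    alpha: dict[str, float]
    excluded_family: str | None = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.alpha.values()):
            raise ValueError("alpha coefficients must be non-negative")
        if self.normalization <= 0:
            raise ValueError("at least one alpha must be positive")

    @property
    def normalization(self) -> float:
        return float(sum(self.alpha.values()))


@dataclass
class FreeEnergyTriple:
    """Three (temperature K, dG) points, one per thermal dataset."""

    points: list[tuple[float, float]]

    def __post_init__(self) -> None:
        temps = [t for t, _ in self.points]
        if len(temps) != 3 or any(b <= a for a, b in zip(temps, temps[1:])):
            raise ValueError("need three points with strictly increasing "
                             "temperatures (meso < all < thermo)")


def score_protein(
    p: ProteinStructure,
    pots: dict[str, PotentialSet],
    min_separation: int = 2,
    torsion_table=None,
) -> EnergyProfile:
    """Sum potential energies over all qualifying descriptors of a protein.

    ``pots`` maps potential kind to the PotentialSet of one thermal dataset.
    Cells absent from a potential contribute zero.
    """
    tags = {ps.dataset_tag for ps in pots.values()}
    if len(tags) != 1:
        raise ValueError(f"potentials from mixed datasets: {sorted(tags)}")
    for kind, ps in pots.items():
        if ps.kind != kind:
            raise ValueError(f"potential kind mismatch: {kind} vs {ps.kind}")
    e_dist = 0.0
    n_pairs = 0
    if "distance" in pots:
        ps = pots["distance"]
        for pair, b in _structure_pair_cells(p, min_separation):
            e_dist += ps.energy(pair, b)
            n_pairs += 1
    e_tors = 0.0
    n_res = 0
    if "torsion" in pots:
        ps = pots["torsion"]
        for r, (phi, psi) in zip(p.residues, backbone_torsions(p)):
            dom = assign_torsion_domain(phi, psi, table=torsion_table)
            if dom == "undefined":
                continue
            e_tors += ps.energy(r.aa_type, dom)
            n_res += 1
    return EnergyProfile(
        per_type_energy={"distance": e_dist, "torsion": e_tors},
        n_pairs=n_pairs, n_residues=n_res,
        dataset_tag=next(iter(tags)),
    )


def folding_free_energy(profile: EnergyProfile, alphas: AlphaCoefficients) -> float:
    """Alpha-weighted mean of the per-type energies (kT units)."""
    num = sum(alphas.alpha.get(k, 0.0) * e
              for k, e in profile.per_type_energy.items())
    return num / alphas.normalization


def free_energy_triple(
    p: ProteinStructure,
    pots_by_tag: dict[str, dict[str, PotentialSet]],
    alphas: AlphaCoefficients,
    min_separation: int = 2,
    torsion_table=None,
    profiles: dict[str, EnergyProfile] | None = None,
) -> FreeEnergyTriple:
    """dG at the three dataset temperatures (meso, all, thermo).

    Each dataset's mean melting temperature (taken from its potentials,
    converted to Kelvin) is paired with the protein's score under that
    dataset's potentials.  Precomputed ``profiles`` may be passed to avoid
    re-scoring.
    """
    points = []
    for tag in ("meso", "all", "thermo"):
        pots = pots_by_tag[tag]
        temps = {ps.dataset_mean_tm for ps in pots.values()}
        if len(temps) != 1:
            raise ValueError(f"inconsistent mean Tm inside dataset {tag!r}")
        t_k = next(iter(temps)) + CELSIUS_TO_KELVIN
        if profiles is not None and tag in profiles:
            profile = profiles[tag]
        else:
            profile = score_protein(p, pots, min_separation=min_separation,
                                    torsion_table=torsion_table)
        points.append((t_k, folding_free_energy(profile, alphas)))
    if len({t for t, _ in points}) != 3:
        raise ValueError("dataset mean temperatures are not distinct")
    return FreeEnergyTriple(points=points)


@dataclass
class CalibrationProtein:
    """Training record for the alpha calibration."""

    id: str
    family: str | None
    tm_exp: float
    profiles: dict[str, EnergyProfile]  # dataset tag -> profile


def calibrate_alphas(
    training: list[CalibrationProtein],
    excluded_family: str | None = None,
) -> AlphaCoefficients:
    """Fit the potential-type mixing coefficients by leave-family-out OLS.

    Per-protein features are the thermo-minus-meso energy differences of
    each potential type, normalised by the number of scored terms.  An OLS
    regression of experimental Tm on these features yields slopes beta; the
    anticorrelation convention retains ``alpha_nu = max(-beta_nu, 0)``.
    When every slope clips to zero the calibration falls back to equal
    weights with a warning.
    """
    rows = [t for t in training
            if excluded_family is None or t.family != excluded_family]
    if len(rows) < 3:
        raise ValueError(
            f"need at least 3 training proteins outside family "
            f"{excluded_family!r}, got {len(rows)}")
    X = np.array([
        [t.profiles["thermo"].normalized(k) - t.profiles["meso"].normalized(k)
         for k in POTENTIAL_TYPES]
        for t in rows
    ])
    y = np.array([t.tm_exp for t in rows], dtype=float)
    design = np.column_stack([np.ones(len(rows)), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    alpha = {k: max(-float(b), 0.0)
             for k, b in zip(POTENTIAL_TYPES, beta[1:])}
    if all(v == 0.0 for v in alpha.values()):
        warnings.warn("all calibrated alphas clipped to zero; "
                      "falling back to equal weights")
        alpha = {k: 1.0 for k in POTENTIAL_TYPES}
    return AlphaCoefficients(alpha=alpha, excluded_family=excluded_family)
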