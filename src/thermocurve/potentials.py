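"""Thermally-labelled datasets and melting-temperature-dependent potentials.

Statistical (mean-force) potentials convert observed sequence/structure
association frequencies into effective energies through the inverse
Boltzmann law:

    dW(s, c) = -ln [ F(s, c) / (F(s) F(c)) ]        (kT = 1 internal unit)

where ``s`` is a sequence element (an amino acid or an unordered amino-acid
pair) and ``c`` a structure element (a torsion domain or a distance bin).
Deriving the same potentials from three structure sets with different mean
melting temperatures -- mesostable, thermostable, and their union -- yields
three potentials that encode amino-acid interactions at three effective
temperatures.

Two smallness corrections are applied before taking the logarithm:

* sparse-data correction: the frequency ratio r is replaced by
  ``(sigma + n r) / (sigma + n)`` where ``n`` is the cell count, so cells
  with few observations are pulled toward independence (dW -> 0 as n -> 0);
* distance-bin smoothing: counts in neighbouring bins contribute with
  decreasing weight (default kernel 1, 1/2, 1/4 two bins each side,
  normalised), conserving the total count.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .structures import (
    N_DISTANCE_BINS,
    ProteinStructure,
    assign_torsion_domain,
    backbone_torsions,
    distance_bin,
)

__all__ = [
    "ThermalDatasets",
    "FrequencyTable",
    "PotentialSet",
    "sequence_identity",
    "build_thermal_datasets",
    "count_descriptors",
    "smooth_bins",
    "corrected_ratio",
    "potential_from_counts",
    "default_kernel",
    "write_potentials",
    "read_potentials",
    "DEFAULT_SIGMA",
]

#: sparse-data correction parameter per potential kind
DEFAULT_SIGMA = {"distance": 10.0, "torsion": 20.0}

DATASET_TAGS = ("meso", "all", "thermo")


def default_kernel(half: tuple[float, ...] = (1.0, 0.5, 0.25)) -> np.ndarray:
    """Symmetric normalised smoothing kernel from its decreasing half."""
    half = tuple(float(h) for h in half)
    full = np.array(tuple(reversed(half[1:])) + half, dtype=float)
    s = full.sum()
    if s <= 0:
        raise ValueError("kernel weights must have positive sum")
    return full / s


@dataclass
class ThermalDatasets:
    """The three training sets with their mean melting temperatures (C)."""

    meso: list[ProteinStructure]
    thermo: list[ProteinStructure]
    all: list[ProteinStructure]
    tm_cutoff: float
    identity_cap: float
    tm_values: dict[str, float] = field(default_factory=dict)
    estimated_ids: frozenset[str] = frozenset()

    def members(self, tag: str) -> list[ProteinStructure]:
        return {"meso": self.meso, "all": self.all, "thermo": self.thermo}[tag]

    def mean_tm(self, tag: str) -> float:
        """Mean melting temperature (C) of the retained members of a set."""
        vals = [self.tm_values[p.id] for p in self.members(tag)]
        return float(np.mean(vals))


@dataclass
class FrequencyTable:
    """Joint counts n(s, c) with marginals for one descriptor kind.

    ``counts`` maps (s, c) to a non-negative real; marginals and the total
    are derived on construction and kept consistent.
    """

    kind: str
    counts: dict[tuple, float]
    dataset_tag: str = "all"
    seq_marginals: dict = field(init=False)
    struct_marginals: dict = field(init=False)
    total: float = field(init=False)

    def __post_init__(self) -> None:
        if self.kind not in ("distance", "torsion"):
            raise ValueError(f"unknown table kind {self.kind!r}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be non-negative")
        self.seq_marginals = {}
        self.struct_marginals = {}
        total = 0.0
        for (s, c), v in self.counts.items():
            self.seq_marginals[s] = self.seq_marginals.get(s, 0.0) + v
            self.struct_marginals[c] = self.struct_marginals.get(c, 0.0) + v
            total += v
        self.total = total

    def smoothed(self, weights: np.ndarray) -> "FrequencyTable":
        """Smooth interior distance bins (1..25) of each sequence row."""
        if self.kind != "distance":
            raise ValueError("bin smoothing applies to distance tables only")
        new_counts: dict[tuple, float] = {}
        for s in self.seq_marginals:
            row = np.zeros(N_DISTANCE_BINS)
            for c in range(N_DISTANCE_BINS):
                row[c] = self.counts.get((s, c), 0.0)
            row[1:N_DISTANCE_BINS - 1] = smooth_bins(
                row[1:N_DISTANCE_BINS - 1], weights)
            for c in range(N_DISTANCE_BINS):
                if row[c] != 0.0:
                    new_counts[(s, c)] = float(row[c])
        return FrequencyTable(kind=self.kind, counts=new_counts,
                              dataset_tag=self.dataset_tag)


@dataclass
class PotentialSet:
    """dW(s, c) values derived from one thermal dataset.

    ``dataset_mean_tm`` is the mean melting temperature (C) of the source
    dataset; it becomes the effective temperature at which scores computed
    from this potential are interpreted.
    """

    kind: str
    values: dict[tuple, float]
    sigma: float
    dataset_mean_tm: float
    dataset_tag: str = "all"
    smoothing_weights: np.ndarray | None = None

    def energy(self, s, c) -> float:
        """dW for a cell; unobserved cells carry zero energy."""
        return self.values.get((s, c), 0.0)


def sequence_identity(a: str, b: str) -> float:
    """Percent identity from a global alignment.

    Match +1, mismatch 0, linear gap penalty; identity is the number of
    identical aligned positions divided by the alignment length.
    """
    if not a or not b:
        raise ValueError("sequence_identity requires non-empty sequences")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -0.5
    aligner.extend_gap_score = -0.5
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length


def _greedy_identity_filter(
    proteins: list[ProteinStructure],
    identity_cap: float,
    estimated: set[str],
) -> list[ProteinStructure]:
    """Drop members until all pairwise identities are below the cap.

    Greedy: repeatedly remove the member with the most violations; ties are
    broken by dropping estimated-Tm members before experimental ones, then
    the later entry.
    """
    keep = list(proteins)
    while True:
        n = len(keep)
        viol = np.zeros(n, dtype=int)
        pairs = {}
        for i in range(n):
            for j in range(i + 1, n):
                ident = sequence_identity(keep[i].sequence, keep[j].sequence)
                pairs[(i, j)] = ident
                if ident >= identity_cap:
                    viol[i] += 1
                    viol[j] += 1
        if viol.max(initial=0) == 0:
            return keep
        worst = viol.max()
        cand = [i for i in range(n) if viol[i] == worst]
        cand.sort(key=lambda i: (keep[i].id not in estimated, -i))
        keep.pop(cand[0])


def build_thermal_datasets(
    proteins: list[ProteinStructure],
    tm_cutoff: float = 70.0,
    identity_cap: float = 25.0,
    tenv_to_tm=None,
) -> ThermalDatasets:
    """Split proteins into mesostable / thermostable / union training sets.

    Members with experimental Tm below the cutoff (C) are mesostable, the
    rest thermostable.  When ``tenv_to_tm`` is given, members lacking an
    experimental Tm but carrying an environmental temperature are included
    with the estimated Tm ``tenv_to_tm(t_env)`` and flagged as estimated.
    The union set is redundancy-filtered so every pairwise identity is below
    the cap, and the meso/thermo sets are its Tm-split (hence equally
    filtered).  Mean Tm's are recomputed from the retained members.
    """
    tm_map: dict[str, float] = {}
    estimated: set[str] = set()
    usable: list[ProteinStructure] = []
    for p in proteins:
        if p.tm_exp is not None:
            tm_map[p.id] = float(p.tm_exp)
        elif tenv_to_tm is not None and p.t_env is not None:
            tm_map[p.id] = float(tenv_to_tm(p.t_env))
            estimated.add(p.id)
        else:
            raise ValueError(
                f"{p.id}: no experimental Tm and no usable environmental "
                "temperature")
        usable.append(p)

    retained = _greedy_identity_filter(usable, identity_cap, estimated)
    meso = [p for p in retained if tm_map[p.id] < tm_cutoff]
    thermo = [p for p in retained if tm_map[p.id] >= tm_cutoff]
    if not meso or not thermo:
        raise ValueError("unbalanced datasets: need both mesostable and "
                         "thermostable members")
    return ThermalDatasets(
        meso=meso, thermo=thermo, all=retained,
        tm_cutoff=tm_cutoff, identity_cap=identity_cap,
        tm_values=tm_map, estimated_ids=frozenset(estimated),
    )


def _structure_pair_cells(p: ProteinStructure, min_separation: int):
    """Yield ((aa_i, aa_j) sorted, bin) for qualifying residue pairs."""
    usable = [r for r in p.residues if r.usable]
    n = len(usable)
    if n < 2:
        return
    centers = np.array([r.center for r in usable])
    idx = np.array([r.index for r in usable])
    aas = [r.aa_type for r in usable]
    diff = centers[:, None, :] - centers[None, :, :]
    dmat = np.sqrt((diff ** 2).sum(axis=-1))
    for i in range(n):
        for j in range(i + 1, n):
            if idx[j] - idx[i] < min_separation:
                continue
            pair = (aas[i], aas[j]) if aas[i] <= aas[j] else (aas[j], aas[i])
            yield pair, distance_bin(dmat[i, j])


def count_descriptors(
    dataset: list[ProteinStructure],
    kind: str,
    min_separation: int = 2,
    dataset_tag: str = "all",
    torsion_table=None,
) -> FrequencyTable:
    """Tally descriptor occurrences over a structure set.

    distance: one count per unordered residue pair with sequence separation
    ``|i - j| >= min_separation``; torsion: one count per residue whose
    (phi, psi) domain is defined.
    """
    if not dataset:
        raise ValueError("empty dataset")
    counts: dict[tuple, float] = {}
    if kind == "distance":
        if min_separation < 1:
            raise ValueError("min_separation must be >= 1")
        for p in dataset:
            for cell in _structure_pair_cells(p, min_separation):
                counts[cell] = counts.get(cell, 0.0) + 1.0
    elif kind == "torsion":
        for p in dataset:
            torsions = backbone_torsions(p)
            for r, (phi, psi) in zip(p.residues, torsions):
                dom = assign_torsion_domain(phi, psi, table=torsion_table)
                if dom == "undefined":
                    continue
                cell = (r.aa_type, dom)
                counts[cell] = counts.get(cell, 0.0) + 1.0
    else:
        raise ValueError(f"unknown descriptor kind {kind!r}")
    return FrequencyTable(kind=kind, counts=counts, dataset_tag=dataset_tag)


def smooth_bins(counts_over_bins: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Convolve a count vector with a normalised symmetric kernel.

    Each source bin scatters its mass over the kernel window; where the
    window is truncated by an edge the remaining weights are renormalised so
    the mass of every source bin -- and hence the vector total -- is
    conserved exactly.
    """
    m = np.asarray(counts_over_bins, dtype=float)
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or len(w) % 2 == 0:
        raise ValueError("kernel must be a 1-D vector of odd length")
    if np.any(w <= 0):
        raise ValueError("kernel weights must be positive")
    if not np.allclose(w, w[::-1]):
        raise ValueError("kernel must be symmetric")
    half = len(w) // 2
    if np.any(np.diff(w[half:]) > 0):
        raise ValueError("kernel must be non-increasing from its center")
    s = w.sum()
    if not math.isfinite(s) or s <= 0:
        raise ValueError("kernel weights are not normalizable")
    w = w / s
    n = len(m)
    out = np.zeros(n)
    for j in range(n):
        if m[j] == 0.0:
            continue
        lo = max(0, j - half)
        hi = min(n - 1, j + half)
        window = w[lo - j + half: hi - j + half + 1]
        out[lo:hi + 1] += m[j] * window / window.sum()
    return out


def corrected_ratio(n_sc: float, ratio_obs: float | None, sigma: float) -> float:
    """Sparse-data corrected frequency ratio.

    Mixture of the independence reference (ratio 1) and the observed ratio,
    weighted by sigma and the cell count: ``(sigma + n r) / (sigma + n)``.
    Equals 1 when the cell is unobserved and tends to the observed ratio as
    the count grows.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if n_sc < 0:
        raise ValueError("count must be non-negative")
    if n_sc == 0:
        return 1.0
    if ratio_obs is None or ratio_obs < 0:
        raise ValueError("observed ratio must be non-negative for n > 0")
    return (sigma + n_sc * ratio_obs) / (sigma + n_sc)


def potential_from_counts(
    table: FrequencyTable,
    sigma: float | None = None,
    weights: np.ndarray | None = None,
    dataset_mean_tm: float = 0.0,
) -> PotentialSet:
    """Derive an inverse-Boltzmann potential from a frequency table.

    Distance tables are bin-smoothed first; then for every cell
    ``dW = -ln corrected_ratio(n(s,c), F(s,c)/(F(s)F(c)), sigma)`` in kT
    units.  Cells with a vanishing marginal get dW = 0.
    """
    if table.total <= 0:
        raise ValueError("cannot derive a potential from an empty table")
    if sigma is None:
        sigma = DEFAULT_SIGMA[table.kind]
    if table.kind == "distance":
        if weights is None:
            weights = default_kernel()
        table = table.smoothed(weights)
        struct_keys = list(range(N_DISTANCE_BINS))
    else:
        struct_keys = sorted(table.struct_marginals)
    values: dict[tuple, float] = {}
    total = table.total
    for s, n_s in table.seq_marginals.items():
        for c in struct_keys:
            n_c = table.struct_marginals.get(c, 0.0)
            n_sc = table.counts.get((s, c), 0.0)
            if n_s <= 0 or n_c <= 0 or n_sc == 0:
                continue
            robs = (n_sc * total) / (n_s * n_c)
            values[(s, c)] = -math.log(corrected_ratio(n_sc, robs, sigma))
    return PotentialSet(kind=table.kind, values=values, sigma=sigma,
                        dataset_mean_tm=dataset_mean_tm,
                        dataset_tag=table.dataset_tag,
                        smoothing_weights=weights)


def write_potentials(pots: PotentialSet, path) -> None:
    """Write a potential as a JSON header line plus (kind, s, c, dW) TSV."""
    header = {
        "kind": pots.kind,
        "sigma": pots.sigma,
        "dataset_tag": pots.dataset_tag,
        "dataset_mean_tm": pots.dataset_mean_tm,
        "kernel": (list(np.asarray(pots.smoothing_weights, dtype=float))
                   if pots.smoothing_weights is not None else None),
    }
    with open(path, "w") as fh:
        fh.write("#" + json.dumps(header) + "\n")
        fh.write("kind\ts\tc\tdW\n")
        for (s, c), v in sorted(pots.values.items(), key=lambda kv: repr(kv[0])):
            s_txt = s if isinstance(s, str) else "".join(s)
            fh.write(f"{pots.kind}\t{s_txt}\t{c}\t{v:.12g}\n")


def read_potentials(path) -> PotentialSet:
    """Read a potential written by :func:`write_potentials`."""
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError(f"{path}: missing JSON header line")
        header = json.loads(first[1:])
        fh.readline()  # column header
        values: dict[tuple, float] = {}
        for line in fh:
            if not line.strip():
                continue
            _, s_txt, c_txt, v = line.rstrip("\n").split("\t")
            if header["kind"] == "distance":
                s = (s_txt[0], s_txt[1])
                c: object = int(c_txt)
            else:
                s = s_txt
                c = c_txt
            values[(s, c)] = float(v)
    kernel = header.get("kernel")
    return PotentialSet(
        kind=header["kind"], values=values, sigma=header["sigma"],
        dataset_mean_tm=header["dataset_mean_tm"],
        dataset_tag=header["dataset_tag"],
        smoothing_weights=np.array(kernel) if kernel is not None else None,
    )
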