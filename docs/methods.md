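# Methods

## Model

The pipeline predicts the folding free-energy curve ΔG(T) of a protein
under three assumptions: constant pressure, a two-state folding
transition, and a temperature-independent heat-capacity change ΔCp.
Under these the Gibbs–Helmholtz equation referenced at the melting
temperature reads

    ΔG(T) = ΔHm (1 − T/Tm) + ΔCp (T − Tm − T ln(T/Tm)),

an inverse bell with its zero at Tm and minimum at
Ts = Tm·exp(−ΔHm/(Tm·ΔCp)).  All internal computation uses the folding
convention (ΔHm, ΔCp, ΔG negative for a stable protein) and Kelvin;
user-facing outputs are Celsius, and ΔCp is reported as a positive
unfolding-convention magnitude to match how experimental tables quote it.

The equation is linear in the basis {1, T, T·ln T} with the exact
bijection a = ΔHm − ΔCp·Tm, b = −ΔHm/Tm + ΔCp(1 + ln Tm), c = −ΔCp, so
curve fitting is ordinary least squares and ΔCp can be read off the
T·ln T coefficient.  The fit is solved in the centered basis
{1, T − T₀, T·ln(T/T₀) − (T − T₀)} (T₀ = mean observation temperature)
purely for numerical conditioning — the raw columns T and T·ln T are
nearly collinear over a 40 K window — and mapped back exactly.  With
three distinct temperatures the fit interpolates; duplicate temperatures
are rejected as a degenerate design.

Tm of a fitted curve is its zero crossing above the stability maximum,
searched on (0, 1000] K; a curve with no such crossing — including any
curve whose fitted curvature has the wrong sign, which has a stability
maximum instead of a minimum — is flagged as having no melting transition
and reports NaN temperatures rather than a number without meaning.

## Temperature-dependent statistical potentials

Potentials are derived from three thermally labelled structure sets:
mesostable (experimental Tm below `tm_cutoff_c`), thermostable (above),
and their union.  Proteins without an experimental Tm can be included
with a Tm estimated from the environmental temperature of their host
organism via a user-supplied mapping; such members are flagged.  The
union is redundancy-filtered by greedy removal until every pairwise
global-alignment identity (match +1, mismatch 0, linear gap −0.5) is
below `identity_cap_pct`; the meso/thermo sets are the Tm-split of the
filtered union, which keeps all three sets filtered and nested.  Each
set's mean Tm is recomputed from the retained members and becomes the
effective temperature of its potentials.

Two descriptor families are counted per set:

* distance: unordered amino-acid pair × binned side-chain-center distance
  (bin 0: < 3 Å; bins 1–25: half-open 0.2 Å steps over [3, 8) Å;
  bin 26: ≥ 8 Å), over residue pairs with sequence separation
  ≥ `min_separation` (default 2 — adjacent pairs are dominated by
  covalent geometry and their signal belongs to the torsion potentials);
* torsion: amino-acid type × Ramachandran domain of (φ, ψ), using a
  7-label rectangular partition (first-match rectangles plus a catch-all)
  shipped in the configuration.  The partition is a package default
  chosen to cover the classical helical, extended, polyproline,
  left-handed and ε regions; the literature definition it stands in for
  is not printed anywhere accessible, so the table is deliberately
  config-overridable.  Undefined angles (termini, missing atoms) are
  excluded from counting.

The inverse Boltzmann law converts counts to energies in kT units
(kT ≡ 1; the absolute energy scale is deliberately deferred to the
curve-level factor k below):

    ΔW(s, c) = −ln [ corrected( n(s,c), F(s,c)/(F(s)F(c)) ) ].

Two corrections are applied:

* sparse data: the frequency ratio r is replaced by the mixture
  (σ + n·r)/(σ + n), σ = 10 (distance) / 20 (torsion).  This form is a
  behaviour-equivalent substitute for the original correction, which is
  not legible in the available source; it reproduces both of its stated
  limits (ratio → 1, hence ΔW → 0, for unobserved cells; ratio → r for
  well-observed ones) and never increases |ΔW|.
* bin smoothing (distance only; domains are categorical): each interior
  bin's counts are spread over its neighbours with decreasing weights
  (default 1, 1/2, 1/4 two bins each side, normalised).  Smoothing uses
  a scatter formulation — each source bin's truncated kernel is
  renormalised — so the total count is conserved exactly; the price is
  that a uniform vector is perturbed within four bins of the edges.
  Conservation was kept as the binding contract because the marginals
  derived from smoothed counts must stay consistent.

## Free energies at three temperatures

Scoring a protein with one set's potentials sums ΔW over all qualifying
pairs (distance) and residues with defined domains (torsion); unobserved
cells contribute zero.  The two energies are mixed as
ΔG = Σ_ν α_ν E_ν / Σ_ν α_ν with non-negative α, making ΔG invariant
under rescaling of α.  The α are calibrated by OLS of experimental Tm on
the per-type thermo-minus-meso energy differences, each normalised by its
term count (pairs or residues) so proteins of different length are
comparable; anticorrelation fixes the sign convention α_ν = max(−β_ν, 0),
and if every slope clips to zero the calibration falls back to equal
weights with a warning.  Calibration always excludes the homologous
family of the protein being predicted.  The same α vector serves all
three temperatures.

Pairing each score with its set's mean Tm (in Kelvin) gives the three
points of the curve fit.

## Family-context curve corrections

All three corrections are computed from the target's family **excluding
the target**, so every reported number is cross-validated:

* **0 K anchor.**  Every family member is first fitted unanchored.  A
  member is re-fitted once with the basis constant a — the T→0 limit of
  the curve — fixed to the mean of the other members' a values when its
  own curve is upside-down (fitted ΔCp > 0) or when its a deviates from
  that mean by more than one standard deviation (sample SD, at least two
  references required).  The anchor is imposed as an exact constraint on
  a rather than as a data point at T = 0, which lies outside the model's
  domain of validity.  One corrective pass, no iteration.
* **Amplitude k.**  k = Σ|ΔCp_exp| / Σ|ΔCp_pred| over the other family
  members with experimental ΔCp (magnitudes, so sign conventions cancel);
  without such members, the mean of the other families' k values with the
  single largest and smallest removed (plain mean when two or fewer
  remain), and k = 1 with a warning when no information exists at all.
* **Temperature factor ω.**  ω minimises Σ_Q (T0_Q/ω − Tm_exp,Q)² over
  the other members Q, where T0_Q is the zero crossing of Q's fitted
  curve; solved in closed form via u = 1/ω.  ω = 1 when no references
  exist.

The corrected curve is ΔG_final(T) = k·ΔG_fit(ω·T): k rescales energies
without moving any temperature; ω divides every temperature-valued output
by ω.  Outputs per protein: Tm (zero above the minimum, bracketed root
finding to |ΔG| < 10⁻⁹), Ts (= Ts_fit/ω), ΔCp (= k·|ΔCp_fit|), ΔG(25 °C),
ΔHm (= −Tm · dΔG_final/dT at Tm) and ΔSm (= ΔHm/Tm).

## Evaluation statistics

Prediction-error summaries report σ as the root mean square of
(pred − exp) residuals — the quantity of interest is error against
experiment, not residual spread — and the Pearson correlation with a
two-tailed t-based P-value.  The optional worst-prediction exclusion
drops the ceil(fraction·N) pairs with the largest absolute residual
(fraction 0.1 by default, which maps 45→40, 17→15 and 16→14).  Strategy
correlations relate predicted ΔG(25 °C), Ts and ΔCp to predicted Tm,
optionally excluding named (e.g. worst-predicted) families.

## Synthetic data

The package is developed and tested entirely against two generators,
both pure functions of their seed.

**Planted-contact structure sets** emulate the premise that some
interactions stabilise specifically at high temperature.  All chains
share one ideal-geometry α-helical template (φ, ψ = −57°, −47°; NeRF
construction from ideal bond lengths/angles; a CB side-chain atom per
residue, glycine excluded so every residue has the same center type;
coordinates rounded to PDB's three decimals so serialisation is
lossless).  The template's (i, i+4) CB pairs fall in one 0.2 Å bin,
cleanly separated (≥ 4 bins) from the other distance clusters so kernel
smoothing cannot mix them.  Every chain carries exactly two copies of
each enriched amino acid; "planting" moves one copy pair into a randomly
chosen disjoint (i, i+4) slot with a set-specific probability.  Because
the composition is fixed, the pair-type marginal F(s) is
planting-invariant and the enrichment is a pure sequence–structure
association; the thermostable planting rate is solved (Brent's method on
the expected-frequency model) so the ratio of the enriched cell's
association ratios F(s,c)/(F(s)F(c)) between the sets equals the
requested odds factor, with an explicit infeasibility error when the
geometry cannot support it.  Per-chain melting temperatures are affine in
the planted-contact content plus Gaussian noise (defaults 45 °C + 30 °C
per planted contact, SD 2 °C), separating the set means by roughly 25 °C.

**Synthetic homologous families** draw a family-center parameter set
uniformly (Tm ∈ [40, 100] °C, ΔHm ∈ [−150, −60] kcal/mol,
ΔCp ∈ [−3, −0.8] kcal/mol/K) and jitter members around it (±15 °C on Tm,
±15 % relative on ΔHm and ΔCp).  The within-family similarity is part of
the model being tested: the family-mean anchor and the k/ω transfer
presuppose that homologous proteins share size and overall energetics,
and fully independent members would violate that premise rather than
stress the method.  Each member's ΔG is observed at 45/65/85 °C
(mirroring plausible dataset mean melting temperatures) with independent
Gaussian noise, default SD 0.5 kcal/mol.

What the generators do **not** emulate — and hence what passing tests do
not show about real data: real side-chain geometry and packing, sequence
conservation within families (family members here are geometrically
identical up to sequence), correlated experimental errors between
laboratories, ligand contributions to stability, any mismatch between a
structure set's mean Tm and the physical temperature beyond the single
multiplicative factor ω, and cold denaturation data.

## Numerical choices and degenerate inputs

* Root finding: sign-change scan on a 0.25 K grid over (0, 1000] K
  refined by Brent's method (xtol 10⁻¹²); tangential double roots closer
  than the grid step would be missed, but do not arise for curves with
  ΔG(Ts) meaningfully below zero.
* Half-open distance bins with d = 8.0 Å in the overflow bin;
  deterministic edge behaviour.
* altLoc resolution keeps the highest-occupancy copy, ties prefer
  altloc 'A'/blank; residues are ordered by (resSeq, iCode).
* The identity filter drops the member with the most cap violations,
  ties dropping estimated-Tm members before experimental ones.
* Alpha calibration requires ≥ 3 training proteins outside the excluded
  family; fewer is an error, not a silent fallback.
* An empty mesostable or thermostable set is an "unbalanced datasets"
  error.

## Known limitations

* The absolute energy scale rests entirely on k, i.e. on experimental
  ΔCp values inside the family (or the trimmed cross-family mean); ΔG and
  ΔCp predictions inherit that uncertainty directly, while Tm and Ts are
  insensitive to it.
* Proteins whose three scored points all lie in the unfolded regime can
  defeat the anchor correction; such members are flagged rather than
  forced to a number.
* Torsion-domain boundaries are a documented package default, not the
  original literature table.
* No solvent-accessibility or combined multi-descriptor potentials, no
  temperature-dependent ΔCp, no multi-state transitions, no ligand
  effects, no mmCIF input.
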