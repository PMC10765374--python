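# Methods

## The partitioning model

A single membrane compartment holds three classes of reactant, measured in
moles: cholesterol (total `C_T`), one or more phospholipid species (totals
`P_T,i`) and at most one protein ligand (total `L_T`). Chemical activities
are ideal and expressed as mole fractions over the compartment size
`α = C_T + Σ P_T,i + L_T`, computed from *total* amounts; `α` is held fixed
within a single solve and changes across a sweep as `C_T` changes. All
association constants are therefore dimensionless.

Each phospholipid species forms stoichiometric sterol complexes
`C + r P ⇌ CP_r` with constant `K_P`; the protein oligomer binds `n`
sterols in one concerted, all-or-none step `nC + L ⇌ C_nL` with constant
`K_Ln = K_L1^n`. Concerted binding is the maximally cooperative scheme for
a given `n`; sequential (site-by-site) schemes, non-integer `n`, activity
coefficients, and kinetics are deliberately out of scope — the model
describes equilibrium partitioning only.

### Solving the speciation

At fixed free cholesterol `c`, every other species is available in closed
form: the ligand balance gives `L_f = L_T / (1 + K_Ln (c/α)^n)` directly,
and the per-species lipid balance
`P_f + r·K_P·c·P_f^r/α^r = P_T` is linear for r = 1 and quadratic for
r = 2 (evaluated in the cancellation-free form
`P_f = 2 P_T / (1 + √(1 + 8 K_P c P_T/α²))`); for r > 2 — not used by any
preset but supported so the contract does not silently break — a bracketed
Brent solve on [0, P_T] is used. The total bound sterol
`b(c) = Σ (P_T,i − P_f,i)/r_i + n (L_T − L_f)` is strictly increasing, so
`g(c) = c + b(c) − C_T` has exactly one root in [0, C_T]. It is found by
Brent's method with an effectively machine-precision tolerance and an
iteration cap of 200; robustness was preferred over elegance since each
solve costs tens of microseconds. `C_T = 0` short-circuits to the all-free
state, and the free-cholesterol fraction `C_f/C_T` is defined as 0 there to
avoid 0/0. After every solve the three mass balances are re-verified at a
relative tolerance of 1e-12 and a violation raises rather than returns.

### Sweeps and derived scalars

Membrane cholesterol is quoted as mol % = `100·C_T/(C_T + Σ P_T)` (the
protein is excluded from the denominator). The default sweep is 0–60 mol %
in 121 uniform points — the physiological range at a resolution fine
enough to localise thresholds — with `P_T` normalised to 1 and trace
protein (`L_T` = 1e-3 for cell membranes and vesicles, 1e-5 for planar
bilayers; occupancy differs by well under 1 % of full scale between the
two, which the tests verify).

Derived quantities:

- equivalence point `100·E/(E + Σ P_T)`, `E = Σ P_T,i/r_i` — the sterol
  load that exactly saturates the lipid complexes;
- half-saturation law: occupancy is 1/2 exactly where the free mole
  fraction `C_f/α` equals `1/K_L1`, independent of `n`. In *total*
  cholesterol space the different-`n` isotherms for one `K_L1` therefore
  intersect at essentially one `C_T`; the residual spread, and the
  deviation of occupancy from 1/2 at the pairwise crossing of two curves,
  are O(`L_T`) finite-protein effects (≈1e-5 at `L_T` = 1e-5), which is why
  the exactness assertions in the tests are made at each curve's own
  half-saturation point and in free-mole-fraction space;
- `ΔG° = −RT ln K_L1` at 298 K with R = 8.314 J mol⁻¹ K⁻¹, reported in
  kJ/mol per subunit. Scalars are rounded only at presentation (one
  decimal for ΔG°, nearest integer for equivalence mol %).

Weight-percent sterol inputs convert by
`100·(w/387) / (w/387 + (100−w)/740)` using molecular weights 387
(cholesterol) and 740 (mean phospholipid). Note a known source
inconsistency: the BK literature curve's midpoint of 8.3 wt % is quoted as
12.7 mol % in its original presentation, whereas these molecular weights
give 14.8 mol %; the formula is implemented as stated and the discrepancy
is simply documented.

## Fitting

The historical analysis matched simulated isotherms to published activity
points by eye on dual axes. `sterolbind` replaces that with an explicit,
deterministic estimator, so fitted constants may differ somewhat from
eyeballed ones. Measured activity is modelled as
`baseline + amplitude·occ` (or `… + amplitude·(1 − occ)` for proteins
inhibited by cholesterol). At each candidate `K_Ln` the model occupancy at
the observed mol % values comes from the full speciation solve and the two
affine nuisance parameters are profiled out by linear least squares;
the profiled sum of squared errors is minimised over `log10 K_Ln` on
[−2, 16] by a 0.1-step grid followed by bounded scalar refinement to 1e-4
in `log10 K`. The SSE profile is unimodal in practice; the grid stage
makes the search robust to any local structure. Residuals are unweighted
(no uncertainties accompany such data), no points are excluded by default,
and the baseline may optionally be pinned at zero. R² is
`1 − SS_res/SS_tot` about the observed mean; it is invariant to affine
rescaling of the activity column because the nuisance parameters absorb
it. A stoichiometry scan refits `n = 1…5` and ranks by R², ties broken
toward smaller `n`. Occupancy profiles are memoised on
(composition, n, L_T, abscissae, K) — a pure function — which makes
replicated refits cheap.

Fitted `K_Ln` values inherit the uncertainty of the assumed lipid
constants: `sensitivity_to_lipid_affinity` refits under scaled `K_P` and
reports the spread; the free-energy spread is compressed by the logarithm.

## Synthetic data

No machine-readable experimental isotherms exist for the six characterised
transporters (the historical points were digitised from earlier figures),
so the package ships a generator instead of fixtures.
`generate_activity_data` evaluates the exact model isotherm for a given
protein/bilayer pair at 12 uniformly spaced points over 0–60 mol %
(defaults), maps occupancy through the affine activity scale
(baseline 0, amplitude 1), and perturbs with seeded multiplicative
Gaussian noise of relative sd 2 % floored at zero activity — a magnitude
chosen to mimic the scatter of single-channel and transport assays. The
generator records its ground truth in the dataset provenance and is
bit-reproducible for a fixed seed.

What this does and does not demonstrate: parameter-recovery tests show the
estimator is consistent and well-conditioned *under the model's own noise
process*. Real assay data add systematic effects the generator does not
emulate — response nonlinearity, composition drift, digitisation error,
non-Gaussian single-channel statistics — so recovery tolerances here say
nothing about accuracy against such distortions, and fitted constants for
real proteins remain conditional on the assumed lipid `K_P` and `r`.
The weakest-conditioned preset is the cholesterol-inhibited inward
rectifier on the avid plasma-membrane composition, where occupancy only
moves near the equivalence point and a handful of points carry all the
information; its Monte-Carlo recovery spread is accordingly the widest.

## Presets

Bilayer presets (name: species as (K_P, r, amount)): `gat_liposome`
(200, 1, 0.5) + (200, 2, 0.5); `planar_pops_pope` (210, 2, 0.5) +
(130, 1, 0.5); `plasma_membrane` (5000, 1, 0.5) + (2500, 2, 0.5);
`achr_vesicle` (930, 2, 0.75) + (200, 2, 0.25); `endomembrane`
(21, 1, 0.3) + (10, 2, 0.7). Protein presets (K_L1, n, direction): GAT
(100, 1, ↑), Kir3.4* (35, 1, ↑), Kir2 (100, 1, ↓), BK (563, 4, ↓),
Kir3.4*_M182I (700, 4, ↓), AChR (950, 2, ↑). The liposome preset pins the
best-match lipid affinity 200; `gat_lipid_affinity_sweep` exposes the
alternative values {1e-6, 100, 200, 400, 1000} explored around it.

## Numerical and testing choices

Randomised property tests draw `K_P` from [1e-6, 1e4], `K_L1` from
[1, 1e4], r from {1, 2}, n from 1–5 and cholesterol mole fractions up to
0.6. The solver is cross-checked against a vectorised brute-force grid
oracle (1e6 points over [0, C_T]) on 20 random systems, and against
hand-derived closed forms (the single-lipid quadratic, the lipid-free
concerted isotherm). Monte-Carlo recovery uses 100 replicates per protein
preset with seeds 0–99; problem sizes throughout (12-point datasets,
121-point sweeps, 1e6-point oracle grids) keep the whole suite around ten
seconds on one core while leaving every check well resolved.

## Known limitations

- Binding is strictly concerted; proteins with sequential or mixed
  cooperativity will be summarised by an effective (K_L1, n).
- Constants are assumed composition- and temperature-independent
  (temperature enters only through ΔG°).
- The affine activity map assumes the assay responds linearly to
  occupancy.
- Fitted protein constants are identifiable only jointly with the assumed
  lipid constants; report them with the composition used.
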