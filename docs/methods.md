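# Methods

## Assembly model

The model describes the "vertical" growth pathway of IgG oligomers on an
antigenic membrane: a solution IgG binds a surface epitope with one Fab
(`y1`), closes the bivalent ring (`y1b`), and the anchored seed then
alternates between recruiting a solution IgG via an Fc–Fc contact and
capturing an epitope with that IgG's free Fab, up to the epitope-engaged
hexamer (`y11b`). Fourteen state variables evolve under mass action: the
twelve surface species, the surface-compartment IgG concentration, and the
available epitope density. Lateral (diffusion-driven) oligomerization and
the all-monovalent branch of the pathway are outside the model's scope: at
the antigen densities it targets, bivalent anchoring re-forms quickly after
single-Fab release, and those routes contribute negligibly. The lower
branch's rate constants remain connected to the model through
detailed-balance constraints, which `check_reversibility_constraints`
verifies in log space for any future extension; the lower-branch and
hexamer-closure rates themselves (`k5…k7`, `k1b,i`) are deliberately not
simulated or fitted.

Statistical factors on the Fc–Fc association: the first recruitment onto a
bivalent monomer can form 4 equivalent interface pairings (both partners
expose two interfaces), later additions onto the open oligomer end 2. The
backward rate of the bivalent state is `2 k−1` (either Fab may release).

### Units

Concentrations M, surface densities µm⁻², time s, geometry nm. Surface
capture rates (`k1b`, `k3`, `k4`) carry s⁻¹ µm², so rate × epitope density
is a first-order rate. The compartment conversion
`α = 1/(6.022×10⁸)` M per µm⁻² corresponds to a 1-µm, instantaneously
mixed solution column above the membrane.

### Epitope screening

A bound species hides epitopes beneath its footprint: monomer disc of
diameter 8.8 nm, bivalent disc scaled by 1.6, hexamer disc of 23 nm;
oligomers of 2–5 IgGs screen the corresponding fraction of the hexamer
disc plus a rim-overlap strip (23 nm × 2.9 nm). The weights
`w_i = A_i × ρ_epi` use the **total** (constant) epitope density — a
mean-field choice; the alternative, scaling with the instantaneous free
density, is available as `ScreeningGeometry(screening="free")`. Screening
enters the epitope balance as `−Σ w_i × d(paired states)/dt`, and the
integrator clamps the screening term if the free-epitope density would
cross zero (a warning is logged; the bookkeeping error tolerance is
10⁻⁶ × ρ_epi).

### Condition resolution

Per-surface Fab kinetics are tabulated by DNP mole fraction
(kon 3.1/2.8/0.6 ×10⁴ M⁻¹s⁻¹ and koff 0.13/0.21/0.21 s⁻¹ for
0.85/2.5/5%); the whole-IgG association rate is 1.7× the Fab value. The
capture rates are multiplied by the surface prefactor (2.0 / 1.5 / 1) and,
for E430G variants, `k3`/`k4` additionally by ν (1.9 for IgG1; 1.2/1.4 for
IgG3/IgG4). The epitope density is linear in the DNP mole fraction through
the measured anchor 0.5% → 8.1×10³ µm⁻². Reference parameter sets for
IgG1, IgG3 and IgG4 ship as `IGG1_PARAMS` etc.; IgG2 is not supported
(its membrane-disrupting behaviour is outside the model).

### SpA competition

SpA-B occupancy of Fc–Fc interfaces follows 1:1 kinetics
(kC = 1.9×10⁵ M⁻¹s⁻¹, k−C = 3.2×10⁻³ s⁻¹). Because the relaxation time is
~1 s against minutes-long incubations, simulations use the pre-equilibrated
free fraction `φ = K/(K+[SpA])` and scale every Fc–Fc association by `φ²`
(both partners' interfaces must be free). SpA concentration is treated as
an un-depletable reservoir. IgG3 interfaces are not bound by SpA-B; the
module returns φ = 1 for that subclass. The φ² coupling and the 1:1 site
stoichiometry are modelling choices of this package.

### Protocol and integration

Simulations mimic the assay: incubation at constant bulk concentration,
a 3-min wash (bulk held by default; `wash_bulk="zero"` zeroes it at the
wash start), then bulk set to zero and a 60-min observation window whose
trapezoidal time average (201 dense points) is the reported distribution.
Sizes pair an Fc-attached state with its epitope-engaged successor
(dimers = y2b+y3b, … hexamers = y10b+y11b). Integration uses LSODA with
relative tolerance 10⁻⁸ (10⁻⁵–10⁻⁶ inside fitting loops, where the
integration error is orders of magnitude below counting noise) and
per-component absolute tolerances (10⁻⁸ µm⁻² for densities, 10⁻¹⁸ M for
the surface concentration). The transport identity
`α·(bound IgG)′ + y_surf′ = kT(C_bulk − y_surf)` holds exactly in the
right-hand side and is verified numerically to 10⁻⁸ relative accuracy.

## Parameter determination analyses

**Force spectroscopy.** The most probable rupture force is
`F* = (kBT/x_β) ln(r x_β / (k_off kBT))`, clamped at zero below the
threshold rate. Binned spectra are fit by weighted least squares (inverse
squared standard errors). Bin *mean* forces lie below the most probable
force by the Gumbel mean–mode offset `γ kBT/x_β` (γ the Euler–Mascheroni
constant); ignoring this biases `k_off` upward by ≈ e^γ ≈ 1.8×, so the
default `statistic="mean"` applies the offset and `statistic="mode"` fits
peak forces directly. The event simulator samples the Bell–Evans
first-passage density by inverse transform. Binding-probability series are
fit to `p_b = p_max(1 − e^{−t/τ})`; when the number of curves per point is
known, the fit minimizes the binomial deviance and intervals use the
likelihood-ratio threshold (the unweighted least-squares intervals
undercover slightly at the assay's 6-point design). The on-rate conversion
uses a half-sphere effective volume of radius `r_eff` and 4 equivalent
Fc–Fc pairings: `c_eff = 4 p_max/(N_A V_eff)`, `k_on = 1/(τ c_eff)`.
`x_β` defaults to 0.5 nm in simulators and is always configurable.

**Biosensor kinetics.** Plain 1:1 Langmuir (no mass-transport term — the
two-compartment treatment belongs to the membrane system): association
`R = R_eq(1−e^{−(kon C+koff)t})`, `R_eq = Rmax C/(C+KD)`, exponential
dissociation. The global fit shares (kon, koff, Rmax) across a
concentration series, optimizing log parameters with a bounded
trust-region least-squares solver; with no user initialization a coarse
4×4 grid of starts guards against local minima. Wald intervals come from
the Jacobian; an Rmax uninformed by the data (all C ≪ KD) is flagged.
Association/dissociation default to 2.5/25 min, and generated traces
always sample the phase boundary so the phase structure survives CSV
round trips.

## Global fitting and confidence intervals

Fitting minimizes, in log10-parameter space, one of three objectives:
least squares on fractional abundances with equal condition weights (the
default), a multinomial count likelihood, or a Poisson count deviance
against model density × scanned area. The Poisson objective exists because
fractions alone do not identify the absolute scale of `{k1b, k3, k4}`: a
joint rescaling moves time-averaged fractions by less than counting noise
while changing total densities severalfold (the capture equilibria are
saturated; only retention times shift). Particle counting over a known
area measures exactly that missing total-density information, so count
data with areas is the recommended route for absolute-rate inference.

Optimization is Nelder-Mead with seeded multi-starts; the function
tolerance scales with the starting objective and parameter precision is
set by the simplex tolerance (10⁻³ log10 units ≈ 0.2%). Local curvature
(finite-difference Hessian) supplies quick Wald intervals; the reported
intervals use profile likelihood: the target parameter is scanned on a log
grid, the others re-optimized, and the boundary interpolated where the
objective crosses `f_best (1 + F_{0.95}(1, n−p)/(n−p))` (for deviance
objectives, `f_best + χ²_{0.95}(1)`). Bounds that never cross within the
scan are reported open and flagged — expected behaviour for weakly
identified directions such as the Fc–Fc association rate's upper bound.

## Thermodynamics

`ΔG = RT ln K_D` (natural log, T = 300 K, R = 8.3145×10⁻³ kJ mol⁻¹ K⁻¹,
unity activities). Surface reactions have `K_D` in µm⁻²; it is divided by
6.022×10¹¹ µm⁻² per M before the logarithm. That divisor is a reporting
convention validated against the package's reference free-energy columns;
it deliberately differs from the transport equation's compartment factor
(1 µm column ↔ 6.022×10⁸), i.e. the free-energy table's implied standard
state is **not** the simulation compartment — the two conventions are kept
in separate configuration fields on purpose. Entropy differences assume
equal enthalpies across Fab–epitope steps, `ΔΔS = −ΔΔG/T`, computed from
unrounded rate constants. They are divisor-independent only between two
surface reactions; mixed rows (e.g. bivalent vs monovalent anchoring)
inherit the convention.

## Lysis simulation

Oligomerization on the vesicle runs on the planar-surface model with the
vesicle's DNP density (curvature ignored). C1 loading is reduced to
independent 1:1 occupancy per activating size (4, 5, 6) with configurable
rates — the bundled `examples/c1_example.yaml` values are synthetic
placeholders — and every bound C1 is assumed to yield at least one
membrane pore (vesicles carry no complement-regulatory defences). Pores
are Poisson over vesicles (diameter 200 nm); a vesicle lyses at
≥ `lysis_threshold` pores (default 1, giving `1 − e^{−λ}`). EC50 is
extracted by monotone piecewise-linear interpolation in log concentration
and reported as not-reached when the curve never attains 50%.

## Synthetic data

The fixture generator forward-simulates conditions and samples particle
counts: multinomial at fixed total (fractions only), or Poisson over a
scanned area sized for an expected 300 particles/condition — a plausible
single-particle-imaging scale; the truth record stores generating
parameters and exact model fractions. The default 35-condition design
(3 concentrations × 3 surfaces for wild type and E430G, incubation-time
series for both, and an SpA titration) is a reconstruction of the
calibration experiment's structure, not a published design matrix. Force
and biosensor generators delegate to the corresponding simulators with
seeded Gaussian/binomial noise. Synthetic data shares the model's own
statistical structure; passing recovery tests therefore demonstrates
correctness and identifiability of the inference machinery, not robustness
to real-data pathologies (drift, misclassification of oligomer sizes,
surface heterogeneity).

## Validation strategy and problem sizes

An independent exact stochastic simulation (direct-method SSA over integer
molecule counts on a 1 µm² patch, transport as a birth–death process on
the solution column) reproduces the deterministic fractions within three
standard errors over 500 replicates; the test condition (16.5 nM, 5%
surface, 90 s) keeps the event count tractable. Parameter-recovery checks
use 9 conditions at ~300 particles each; the coverage studies use 100
seeds. These sizes are the package's chosen test scales — larger designs
only sharpen the same comparisons.

## Known limitations

* Lateral oligomerization and monovalent-branch dynamics are absent, so
  predictions for fluid membranes and low antigen densities underestimate
  assembly — visible as steeper-than-observed lysis transitions.
* Hexamer abundance is not monotone across the *measured* surfaces at
  fixed bulk concentration: the per-surface Fab chemistry (kon, koff, α)
  co-varies with density and can outweigh the density effect (the 0.85%
  surface binds Fabs faster and releases them slower than 2.5%).
  Monotonicity in antigen density holds with surface chemistry held fixed.
* C1 binding kinetics are consumed as configuration; no multivalent C1
  model is included.
* The SpA coupling (φ², 1:1 sites) and the fit objectives' weighting are
  package choices where the underlying mechanism or procedure is not
  uniquely determined by the available evidence.
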