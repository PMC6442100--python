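# Methods

`cubiphase` models the computational workflow around drug-loaded glyceryl
monooleate (GMO) lyotropic liquid-crystal formulations: a mesoscale
simulation screen that ranks candidate compositions, and the scalar
analyses applied to the corresponding laboratory measurements (SAXS
indexing, Franz-cell permeation, xenograft efficacy). This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic-data tests do and do not demonstrate.

## Coarse-grained model and χ parameters

Each GMO molecule is split into two bonded beads: a hydrophilic head **A**
(glycerol + carboxyl, 118.1 g/mol) and a hydrophobic tail **B** (oleyl
chain, 238.4 g/mol). Water, ethanol and metformin hydrochloride (MET) are
single-bead species; one water bead represents three water molecules (the
conventional DPD coarse-graining degree, and the mapping under which the
composition arithmetic in our fixtures is self-consistent).

Pairwise energetics enter as Flory–Huggins parameters. Three values are
measured properties of this system and shipped as authoritative defaults:

| pair        | χ    |
|-------------|------|
| B / water   | 5.1  |
| B / ethanol | 0.5  |
| water / A   | −1.1 |

The remaining seven pairs have no measured values; the shipped defaults
(water/ethanol −0.3, ethanol/MET −0.5, water/MET −0.5, A/ethanol −0.2,
A/MET −0.3, A/B 2.0, B/MET 4.0) encode the qualitative miscibility picture
(ethanol and MET freely miscible with water and the head group; the tail
strongly hydrophobic) and are flagged `default` in the matrix provenance so
they can never be confused with measured values. All are overridable via
`default_chi_matrix(overrides=...)` or a χ file. A single
composition-independent χ per pair is used per run; the known concentration
dependence of χ for head/ethanol and MET/ethanol pairs is a documented
limitation. An auxiliary regular-solution route
χ = v_ref (δ_i − δ_j)² / (RT) is provided for users with Hildebrand
solubility parameters; it cannot produce negative χ and warns accordingly.

χ maps linearly onto DPD repulsion amplitudes, a_ij = a_ii + 3.27 χ_ij at
bead density ρ = 3 (the Groot–Warren calibration; any other density
requires an explicit coefficient).

## DPD engine

Standard Groot–Warren DPD in reduced units (r_c = k_BT = m = 1):
soft conservative repulsion F_C = a_ij (1 − r) r̂ for r < 1, dissipative
F_D = −γ w² (r̂·v_ij) r̂ and random F_R = σ w θ_ij r̂ / √dt with
w = 1 − r and σ² = 2γk_BT enforced at construction; harmonic A–B bonds
(k = 100, r_0 = 0.7; no angle potentials — the minimal two-fragment
amphiphile). Integration is the modified velocity-Verlet scheme with
λ = 0.65 and dt = 0.04; the defaults ρ = 3, a_ii = 25, γ = 4.5, σ = 3 are
the standard well-characterized parameterization consistent with the 3.27
χ-mapping.

Numerical specifics worth knowing:

* **Pair noise is counter-based**: θ_ij is a splitmix64 hash of
  (seed, step, pair) mapped to a zero-mean unit-variance uniform variate
  (uniform noise is sufficient for the DPD thermostat). This makes θ
  exactly symmetric in (i, j) — momentum conservation is exact, not
  statistical — and trajectories bit-reproducible for a fixed seed,
  independent of neighbor-list iteration order. The same stream is exposed
  to tests so a brute-force all-pairs oracle can reproduce the full force
  vector to 1e-12.
* **Neighbor search** is a cell list (edge ≥ r_c) with half-neighbor
  enumeration; boxes smaller than 3 r_c degenerate to an all-pairs loop.
  Cell indices are clamped so that a non-finite coordinate cannot corrupt
  the sort; the integrator instead aborts naming the step.
* **Pressure tensor**: per-frame diagonal components are block means over
  the sampling interval, with kinetic part plus the virial of conservative
  and bond forces only — the dissipative/random contributions average to
  zero and would only inflate the variance of the interfacial-tension
  estimator.
* **Unwrapped coordinates** are tracked alongside wrapped ones for MSD
  computation, and round-trip through the extended-XYZ writer.

Default production scale is a 10×10×10 r_c box (3000 beads) with 3,000
equilibration and 15,000 production steps, sampled every 300 steps. This is
a deliberate desk-scale choice: large enough that the microphase morphology
coarsens and the water-diffusivity measurement converges (seed-to-seed
scatter of D well below the compositional trend), small enough that the
full six-formulation, three-seed screen runs in minutes on one CPU.
Publication-grade cubic-phase simulations use substantially larger boxes
and longer runs; all phase-classification conclusions at this scale are
qualitative.

## Structure analysis

**Density field.** Water beads are binned on a periodic grid (default 16³)
and averaged over frames; the integral is checked against the water count
to 1%.

**Phase classification** works from the mean-subtracted field's 3-D power
spectrum plus percolation of the two level sets (threshold at the mean,
periodic-boundary-aware 6-connectivity, a component "spans" an axis when it
occupies every layer):

1. constant field → `disordered`;
2. one wavevector axis family carrying ≥ 60% of off-origin power →
   `lamellar`;
3. flat shell-averaged spectrum → `disordered`. Flatness means: among
   shells with ≥ 12 Fourier modes (sparser shells have statistically
   incomparable means — a 6-mode white-noise shell exceeds 3× the median
   in ~10% of seeds), no shell mean exceeds 3× the median shell mean, and
   those shells carry ≥ 50% of the off-origin power (a spectrum
   concentrated in sparse shells is structured, e.g. an ideal nodal-surface
   field);
4. both level sets percolate along all three axes → `bicontinuous_cubic`;
5. otherwise `intermediate` (which is where stalk-intermediate and
   partially ordered morphologies land — no attempt is made to detect
   stalks as such).

All thresholds are keyword arguments and every intermediate quantity is
returned in the diagnostics, so a label is re-derivable from its record.
The thresholds were set on constructed reference fields (Schwarz-D nodal
surface, single cosine, white noise), where classification is 100% correct
noiseless and at 10% relative noise.

**Water diffusivity** uses the Einstein relation on unwrapped water
coordinates: MSD over multiple time origins (origin stride = lag/2, i.e.
50% overlap), D = slope/6 over the last half of the curve. Lags are capped
at 10% of the trajectory length: longer lags have so few independent
origins that including them leaves ~8–10% estimator noise on reference
random walks, versus < 2.5% with the cap (the 5% recovery tolerance on
constructed walks with D ∈ {0.05, 0.25, 1.0} is met comfortably).

**Interfacial tension** is the pressure-tensor anisotropy
γ = (L/2)⟨P_N − P_T⟩ assuming two interfaces (planar slab geometry); for
non-planar phases the same number is reported flagged as an effective
value. On a homogeneous fluid at the default run length |γ| < 0.05
k_BT/r_c²; a strongly demixed two-species slab gives γ ≈ 3.8.

## Screening loop

`run_screen` simulates every formulation once per replicate seed
(default 3), classifies the water microstructure, and measures D and γ.
"Proper fluidity" is operationalized as maximal mean water diffusivity —
the fluidity indicator the screen is built around — restricted to
candidates whose majority label is `bicontinuous_cubic`; ties break toward
higher ethanol fraction. The rule is a pure function over the per-candidate
records, unit-tested against brute-force enumeration.

At desk scale, the reference six-composition series (64/x/30/5 for
x = 0…10 mass parts ethanol) behaves as follows under the shipped χ set:
all compositions relax to sponge-like bicontinuous morphologies; water
diffusivity rises monotonically with ethanol content (the fluidity trend
the screen exploits); but the ethanol-richest composition does **not**
spontaneously order into a lamellar stack. That transition is driven in
reality by ethanol swelling the lipid tail region; with the shipped χ set
ethanol partitions into the aqueous phase, so the minimal model lacks the
negative-curvature drive regardless of run length. Consequently the screen
at desk scale selects the most ethanol-rich candidate rather than the
laboratory optimum — a known, documented limitation of the two-bead model
rather than of the selection rule (which is tested separately under
reference phase labels).

## SAXS indexing

Peaks are matched in order to a contiguous window of each candidate
symmetry's allowed √(h²+k²+l²) sequence (Pn3m √2,√3,√4,√6,√8…;
Im3m √2,√4,√6,√8…; Ia3d √6,√8,√14,√16…; lamellar 1,2,3…; hexagonal
1,√3,√4,√7…), with window start offsets up to 3, and the lattice constant
is fitted by zero-intercept least squares on q = 2π√N/a (slope standard
error propagated to a). Minimal RMS relative residual wins; assignments
with residual above 2% (configurable) raise instead of guessing.

Short peak lists need conventions, because a two-peak pattern with ratio
√8/√6 is *exactly* degenerate: it fits Pn3m at (211),(220), Pn3m at
(111),(200) with a lattice constant smaller by √2, Im3m, Ia3d and even a
hexagonal (10),(11) pair. Ties are therefore broken by (i) candidate
priority — Pn3m first, the symmetry GMO/water cubic phases adopt — and
(ii) a preferred-window convention assigning two-peak cubic patterns to the
strong 211/220 reflections, both explicit, configurable arguments. A
ratio-only reporting mode (`spacing_ratio_string`) exists for patterns
whose observed ratios (e.g. 4:5, 3:4) should be recorded without forcing a
physical indexing.

## Permeation analysis

The Franz-cell cumulative amount corrects for sampling:
Q_n = [C_n·V + V_0·Σ_{i<n} C_i]/A with defaults V = 10 ml, V_0 = 1 ml,
A = 0.785 cm², schedule 0.5–5 h. The implementation is tested against an
independent mass-balance bookkeeping simulation (track receptor mass,
withdraw, replace with blank) to 1e-9. The "linear portion" for the
J_ss/T_lag fit defaults to t ≥ 1 h (drops only the first sample of the
standard schedule); the window used is always reported, and a negative
fitted lag is clamped to zero with a flag. The enhancement ratio is the
5-h cumulative amount of the test formulation over the reference solution.

The synthetic generator inverts the Q_n equation exactly (concentrations
solved in time order from a target flux profile Q = max(0, J_ss(t − T_lag)))
rather than simulating membrane diffusion — it tests the pipeline's own
bookkeeping, not extra physics. At the reference flux (1259.6 µg·cm⁻²·h⁻¹)
with 1% concentration noise, J_ss is recovered within 5% in 100/100 seeds.

## Efficacy analysis

Tumor volume is the caliper ellipsoid 0.5·L·W² (L ≥ W enforced); the
inhibitory rate is (W_blank − W_test)/W_blank × 100% on mean terminal
weights, reported half-up to 2 decimals (the printed-rate convention; full
precision is kept internally). Group comparison is a two-sample t-test for
two groups, one-way ANOVA for more, followed — only when the omnibus test
rejects — by the Student–Newman–Keuls stepwise multiple-range procedure.
SNK critical values come from `scipy.stats.studentized_range`, not table
lookup; unequal group sizes use the harmonic mean; non-significant ranges
protect all nested sub-ranges. The procedure is tested against an
independently coded studentized-range oracle.

The tumor-study generator produces per-mouse exponential growth
V(t) = V_0 e^{r(1−i_g)t} with mean-one lognormal measurement noise, and
terminal weights with group means control_mean × (1 − i_g) — the contract
that makes the zero-noise round trip exact (growth-rate scaling alone would
recover 1 − e^{−r·i·T} ≠ i). Defaults: 4 groups × 6 mice, r = 0.25/day,
10 days, V_0 = 75 mm³, control mean weight 1.73 g, aspect ratio L/W = 1.2.

## What the synthetic data do and do not show

Every generator is deterministic under a fixed seed and returns the truth
it generated from, so each analyzer is tested as a recovery problem with
known answers. The noise models (multiplicative Gaussian on q and
concentrations, lognormal on volumes/weights) are positivity-preserving
conventions, not fitted error models; passing the recovery suites shows the
estimators are correct and adequately powered under those models, not that
real SAXS optics, HPLC assay error or caliper technique behave this way.
Likewise the DPD screen demonstrates the pipeline's logic end to end at
desk scale; it does not reproduce publication-scale microstructures, and
the lamellar end of the composition series is outside what the minimal
two-bead amphiphile can express (see above).

## Known limitations

* Single composition-independent χ per pair; no concentration dependence.
* Two-bead GMO with no angle potential cannot encode spontaneous-curvature
  changes, hence no cubic→lamellar transition along the ethanol series.
* No automated cubic space-group discrimination (Pn3m vs Im3m vs Ia3d)
  from simulated density fields; SAXS indexing handles that for measured
  patterns.
* The tension estimator assumes planar interfaces; for non-planar phases
  it is an effective anisotropy measure only.
* Electrostatics, many-bead lipid models and parallel execution are out of
  scope.
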