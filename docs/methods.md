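# Methods

## The scaffold and the randomization scheme

The library scaffold is a single 321-nt gene encoding a 107-residue
head-to-tail dimeric affibody: two identical 46-residue subunits (each an
N-terminally truncated three-helix domain carrying one fixed cysteine at
subunit position 17), an Ala + (S₄G)₂ linker (11 residues), a 3-residue
RAS segment encoded between linker and second subunit, and a C-terminal
lysine.  The packaged gene fixture carries the fixed codons verbatim,
including the deliberately different synonymous codons the two subunits use
for the same residues (e.g. `GAAGATGAT` vs `GAGGATGAC` for E-D-D); the 22
randomized codons appear as `NNN`.

Eleven positions per subunit are diversified, with identical distributions
in both subunits.  Nine of them are *spiked*: the wildtype codon at
fraction 0.61 mixed with mutation codons carrying the remaining 0.39,
uniformly spread over a class alphabet —

| class            | alphabet                | size |
|------------------|-------------------------|------|
| hydrophobic-core | A V I L M F W           | 7    |
| beta-strand      | all residues except C   | 19   |
| spiked (surface) | all except P, G, C      | 17   |

— and two are *binary*, toggling 50:50 between the wildtype and one
alternative residue.  Per subunit the packaged default assigns 3
beta-strand, 4 surface, 2 hydrophobic-core and 2 binary positions.

**Reconstruction caveat.**  The per-position class membership, the wildtype
residues at randomized positions, and the binary alternatives in
`data/sequestrin_design.yaml` are a synthetic reconstruction: they are
class-compatible choices, not transcribed measurements.  The class-count
split is the unique assignment of the textual class rules whose diversity,
(19³ · 17⁴ · 7² · 2²)² ≈ 1.26 × 10²², is within 1% of the design-level
headline; every quantity that depends only on class structure (diversity,
mutation load, spiking fractions) is faithful, while residue-identity
details (which residue is wildtype where) are placeholders.  Users with the
real per-position table can supply their own YAML config.

## Combinatorics

*Theoretical diversity* is the exact big-integer product of per-position
alternative counts; values exceed 10²², so no floating-point shortcut is
taken.  The *mutation-load distribution* is the exact Poisson-binomial PMF
over the count of positions drawing a non-wildtype residue, computed by
dynamic-programming convolution (22 terms is cheap; no normal
approximation).  By default only the eighteen 61/39 spiked positions count:
their mean is 18 × 0.39 = 7.02 — "about seven mutations per scaffold".
The four binary positions are design *toggles*, not mutations: counting
them would add a constant 2.0 to every clone's expectation and break the
correspondence with the designed mutation load, so classification reports
them separately (`design_toggles` on a clone record), as it does
substitutions outside designed positions (`off_design`, sequencing-error
candidates).

## Oligo assembly and splitting

`assemble_gene(o1, o2, L)` concatenates two oligos whose terminal/initial
`L` bases agree literally (N pairs only with N), counting the shared region
once.  `split_gene(gene, junction, L)` is its exact inverse: the shared
`L`-base region is centred on the junction, so
`assemble_gene(*split_gene(g, j, L), L) == g` for every valid `(j, L)` —
this round-trip identity is property-tested on random degenerate genes.
BamHI/SalI flanks are modelled as optional export decorations because the
assembled gene itself carries none.

## Clone classification

Length-based, mirroring a PCR screen: after stripping restriction flanks a
read is a *sequestrin* if it has the exact full gene length and a stop-free
frame-0 reading; a *monomer* if its length falls in a configurable
single-subunit window (default 127–190 nt) with a stop-free frame-0
reading; a *dummy* otherwise (premature stops, frameshifts, unrelated
inserts); *invalid* if empty or containing non-nucleotide symbols.  The
dummy class is defined purely by exclusion.

## Panning simulator

Each round applies, per clone, capture probability
`eff · C/(C + K_D)` (equilibrium occupancy times bead-capture efficiency;
non-binders with `K_D = inf` see only a configurable background), wash
survival `exp(−k_d · Σ wash seconds)` with no rebinding and no avidity,
complete elution, then per-class growth-bias amplification and
renormalization.  These are the simplest defensible kinetic assumptions and
are stated as such; bead capacity, temperature dependence across rounds and
phage infection kinetics are deliberately out of scope.  Stochastic mode
replaces the expectation update by per-clone binomial draws from one seeded
generator and converges to the deterministic trajectory at large pool sizes
(verified at 10⁶ virtual phage, <2% relative deviation).  The reference
five-round scenario uses 50/40/20/10/1 nM target and the escalating wash
schedule ending in 4 × 6 min + 2 h + 6 min (9000 s).  Reported per-round
recovery fractions are scenario illustrations — they depend entirely on the
assumed pool composition.

## SPR kinetics

The 1:1 Langmuir model in closed form: during injection
`R(t) = R_max · C/(C+K_D) · (1 − e^−(k_a·C+k_d)·t)`, afterwards exponential
decay at `k_d`.  `fit_kinetics` is a global unweighted least-squares fit
sharing `k_a`, `k_d`, `R_max` across all cycles (single-surface
assumption), parameterized in log₁₀ for the rates, started from a 3 × 3
grid over log k_a ∈ {3, 4.5, 6} and log k_d ∈ {−5, −3.5, −2} with
ftol = xtol = 10⁻¹², best converged start wins.  `K_D = k_d/k_a` is an
identity of the parameterization (machine precision).  Mass-transport
limitation and bulk refractive-index jumps are not modelled.  Sets with no
measurable signal, or where no start converges, return a flagged failure
rather than numbers.  On noiseless synthetic data the fit recovers the
generating rates to better than 0.1% relative for all tabulated rate pairs;
with 1 RU Gaussian noise recovery is within 5%.

The affinity helper `kd_over_ka` reports nM at 3 significant figures, the
print precision of the reference table.  Note that for several published
rate pairs the printed K_D differs from the ratio of the printed (rounded)
rates; only ratio-consistent rows are used as checks here.

## Thermal melting

Two-state folded/unfolded equilibrium with linear baselines:
`θ(T) = (a_f + b_f·T)(1−f_u) + (a_u + b_u·T)·f_u` with
`f_u = 1/(1 + e^−lnK)`, `lnK = (ΔH_vH/R)(1/T_m − 1/T)` in Kelvin.  T_m is
the fitted midpoint (°C), ΔH_vH a free van't Hoff enthalpy (default start
300 kJ/mol, bounds 10–3000).  Initialization is affine-equivariant
(steepest smoothed slope for T_m, edge fits for baselines), so the
estimator is invariant to affine transforms of the signal axis.  A fit
whose baseline separation at T_m is below 10% of the signal range (or a
signal with no variation) raises a no-transition error instead of
reporting a meaningless midpoint.

## CD spectra and refolding

`cd_difference` is the plain spectral arithmetic Δθ(λ) = θ_complex − Σ
θ_free on a shared 195–260 nm grid; a nonzero difference indicates
structural rearrangement upon binding.  The synthetic spectra are linear
combinations of three fixed Gaussian-band basis curves (helix: positive
~193 nm band and the double minimum at 208/222 nm; sheet: single minimum
near 218 nm; coil: deep minimum below 200 nm).  This basis — and the
companion non-negative least-squares unmixer — is an explicit stand-in
chosen for testability, not a published deconvolution basis; it reproduces
the qualitative signatures only.  Refolding is scored as
`1 − RMS(after−before)/RMS(before)` clipped to [0, 1], mapped to
Yes (≥0.9) / Partly (≥0.5) / No — the thresholds are configurable because
the reference labels are qualitative.

## Aggregation inhibition

Sequestrins bind monomeric peptide 1:1 and tightly, so free
aggregation-competent peptide is `max(0, total − n · inhibitor)`: 20 µM
peptide gives 0, 16 and 18 µM free at 1:1, 1:5 and 1:10 inhibitor ratios.
The synthetic ThT traces are logistic (lag midpoint 15 h, rate 0.5 h⁻¹ on
the 999 × 325 s acquisition grid) with plateau = coefficient × free
peptide; the logistic shape is a stand-in — no aggregation mechanism
(nucleation–elongation) is fitted or implied.  Endpoint prediction from a
concentration standard uses piecewise-linear interpolation, clipping below
the lowest standard to background, with an isotonic repair (and a warning)
for non-monotone standards.

## Synthetic data: what it does and does not emulate

Generators draw from independent per-generator streams spawned from one
top-level seed, so outputs are byte-identical under a fixed seed and adding
a generator never perturbs another's fixtures.  Reads carry truth labels in
their headers; substitution errors only (no indels) at a default 10⁻³ per
base, Sanger-grade.  The default class mixture (72% sequestrin / 24%
monomer / 4% dummy), analyte series (1:1.5 dilutions 342→30 nM plus a blank
cycle, in duplicate, 200 s association / 600 s dissociation), melting grid
(20–90 °C at 1 °C) and ThT design are the study conditions of the campaign
the package models.  Passing tests therefore demonstrate internal
consistency — each pipeline stage recovers the generator's ground truth
under the stated noise — not instrument realism: real sensorgrams carry
drift, bulk jumps and mass-transport effects; real chromatograms carry
indels and quality gradients; real CD spectra are not three Gaussian bands.

## Problem sizes and numerical tolerances used in the tests

Sampling-based checks use 10⁵ clones for per-position frequency recovery
(TV < 0.01), 10⁴ reads for class-mixture recovery (±2%), 10⁶ virtual phage
for stochastic-vs-deterministic panning (<2%), 50 replicates for the noisy
melting study (median within 1 °C), and 2 s sampling on sensorgram grids
where full 1 s resolution adds nothing.  Exact arithmetic (diversity, PMF,
capture/wash closed forms) is asserted at 10⁻¹² absolute or machine
precision.

## Known limitations

* Per-position residue identities are reconstructed, not transcribed (see
  above); analyses that depend on *which* residue is wildtype at a given
  randomized position are placeholders until a real config is supplied.
* The monomer length window and the dummy class are heuristics of a
  length-based screen.
* The panning simulator has no bead-capacity saturation, negative-selection
  kinetics, or round-temperature effects.
* The CD basis/unmixer and ThT logistic are stand-ins (documented above).
* The kinetic fit assumes a single surface (shared R_max) and unweighted
  residuals; replicate-specific surface densities are not modelled.
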