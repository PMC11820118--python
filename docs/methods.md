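# Methods

This note documents the models implemented in `pldscale`, the defaults
and why they were chosen, what the synthetic-data generators do and do
not emulate, and the numerical choices that matter. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Scaling laws for critical-temperature shifts

A mutation class is one source→target substitution type (Y→F, R→K, ...;
"X" denotes composition-biased replacement by weakly interacting
residues). For a variant with N substitutions of one class in a chain of
length L, three candidate ansätze relate the critical-temperature shift
ΔTc = Tc(variant) − Tc(wild type) to (N, L):

- **count**: ΔTc = S·N — the effect is per substitution, independent of
  chain length. Appropriate when the mutation preserves the number of
  associative contacts and only retunes their strength (aromatic
  identity swaps).
- **fraction**: ΔTc = S·N/L — longer chains buffer the perturbation in
  proportion to their valency (charge-altering mutations).
- **sqrt**: ΔTc = S·N/√L — intermediate buffering; the effective number
  of strongly interacting residues grows more slowly than L because a
  fraction of the chain is spacers (aromatic deletions).

Fits are **through the origin**: zero mutations force ΔTc = 0 exactly,
so a free intercept would only absorb noise. With x the ansatz variable,
S = Σxy/Σx², its standard error uses the residual variance with n−1
degrees of freedom, and R² = 1 − SSres/Σy² (the raw-sum-of-squares
baseline is the correct one for a no-intercept model; the conventional
mean-centred R² would be misleading here). By the sign convention,
reversing a pair flips S (S(A→B) = −S(B→A)); observations flagged as
multi-type (substitutions spanning more than one class) are refused by
the fitters.

Ansatz selection fits all three forms and flags the R² maximizer. When
every observation shares one L the three design vectors are exactly
proportional and the data cannot distinguish the ansätze; the selection
reports `indistinguishable` instead of declaring a winner.

The constants fitted on the published 140-variant direct-coexistence
dataset ship as versioned package data
(`data/published_scaling_laws.json`) and are never silently refit:
count laws for Y→F (−0.40 ± 0.04), F/Y→W (4.3 ± 0.1), S→T (−0.09 ±
0.03), G→T (−0.08 ± 0.02), A→S (0.16 ± 0.05); fraction laws for R→K
(−1300 ± 100), R→X (−640 ± 50), N→Q (50 ± 5); the sqrt law for F/Y→X
(−56 ± 5). G→S is acknowledged in that dataset with no fitted constant
(only a very minor decrease was reported); it is represented and
predictions refuse it explicitly rather than guessing. Laws are
cumulative across classes: predictions add, errors combine in
quadrature — valid as long as the combined mutations stay within PLD
composition and patterning biases.

Predictions report S·x ± |x|·S_err. The prediction grid ("table1")
evaluates every class at N = 1 over a set of chain lengths; note the
published grid's aromatic-deletion cell at L = 200 prints −3.9 while
the constant gives −56/√200 = −3.96 ≈ −4.0 — the package reports the
computed value and tests compare within one unit of the last printed
digit.

## Binodal extraction and the critical point

**Interface extraction.** A direct-coexistence slab profile is fitted to
a symmetric double hyperbolic tangent

ρ(z) = ρ_low + (ρ_high − ρ_low)/2 · [tanh((z−z1)/w) − tanh((z−z2)/w)]

("a suitable fitting" in slab-geometry practice; the double-tanh is the
standard, robust, deterministic choice). Because the box is periodic the
profile is first circularly re-centred so the dense slab is contiguous
at mid-box (circular mean of the density used as the shift). Initial
guesses are the 10th/90th density percentiles for the plateaus and the
half-maximum crossings for the interfaces; at least 20 bins are
required. The no-coexistence flag is raised when the fitted plateaus
differ by less than 3× their joint standard error. Per-bin errors, when
present, weight the fit.

**Critical point.** Coexistence points (T, ρ_low, ρ_high ± err) are
fitted simultaneously to

(ρ_high − ρ_low)^3.06 = d(1 − T/Tc)   and   (ρ_high + ρ_low)/2 = ρc + A(T − Tc)

by weighted nonlinear least squares over (Tc, ρc, d, A). The 3.06
exponent is the dimensionless empirical factor from 3D-Ising
simulations and is a fixed constant, never a free parameter. Initial
guesses come from two linear fits ((gap)^3.06 vs T gives Tc and d; the
diameter vs T gives ρc and A), making the optimisation deterministic.
Tc is bounded below by the highest fitted temperature. The parameter
covariance is s²(JᵀJ)⁻¹ with the usual residual-variance scaling; the
reported Tc error is its square root ("the uncertainty of the fit").
Per-point errors weight the residuals when all are positive, else the
fit is unweighted; uniform rescaling of all weights leaves the
noise-free fit unchanged. No temperature-window truncation is applied
by default; `tmax_frac` exists for sensitivity checks. ΔTc between two
fits propagates errors in quadrature.

## Aromatic patterning order parameter

σaro splits the sequence into consecutive windows of length l (5 and 6
by convention, reported separately; a convenience mean exists but is
never substituted), scores each window by the squared deviation of its
aromatic asymmetry from the whole-chain value, normalises by the same
statistic for a reference sequence with all aromatics in one contiguous
N-terminal block, sums the ratios, and multiplies by N_stickers/L
(stickers = charged ∪ aromatic; histidine counts as charged by default,
configurable). The final partial window enters with its true length,
since the per-segment statistic is written in terms of l_i. Windows
where the reference statistic vanishes contribute zero (both numerator
and reference vanish in aromatic-free regimes; 0/0 → 0).

Two documented conventions: the reference block is anchored at the
N-terminus (the definition only requires the aromatics "concentrated in
part of the chain"; start-anchoring is deterministic), and which window
length a given comparison should use is left to the caller.

**Limitation (ordering).** "Clustered scores at least as high as
dispersed" is guaranteed when the chain's aromatic fraction is in the
PLD range (so the global asymmetry σ_T < 0.5) *and* the reference block
fills whole windows: every dispersed window then deviates from σ_T by at
most the empty-window deviation that normalises it, so each ratio is
≤ 1 while the clustered arrangement scores 1 per window. Outside that
domain the normalisation can degenerate — the reference's partial
transition window may itself sit near the global fraction, making its
σ_max tiny and inflating a dispersed ratio — and the ordering can
invert (e.g. 3 aromatics in 53 residues). The ordering tests sample the
guaranteed domain; σaro values outside the PLD compositional regime
should be interpreted with care.

## Mpipi energy terms

One bead per residue; E = E_bond + E_elec + E_pair with fixed
package-wide units (Å, K, kcal/mol, elementary charges, g/cm³).

- Bonds: harmonic, ½k(r − r0)², defaults k = 19.1 kcal mol⁻¹ Å⁻²,
  r0 = 3.81 Å.
- Electrostatics: Debye–Hückel screened Coulomb,
  (C·q_iq_j)/(ε_r·r)·exp(−κr) with C = e²/(4πε₀) = 332.0637
  kcal mol⁻¹ Å e⁻² (CODATA-derived, documented to full precision);
  defaults ε_r = 80 and κ = 0.126 Å⁻¹ (150 mM monovalent salt near
  300 K — `debye_kappa` recomputes κ from ionic strength via scipy's
  physical constants).
- Short-range pairs: the published Wang–Frenkel form
  φ(r) = ε·α·[(σ/r)^2μ − 1]·[(r_c/r)^2μ − 1]^2ν with
  α = 2ν(r_c/σ)^2μ·[(1+2ν)/(2ν((r_c/σ)^2μ − 1))]^(2ν+1), which makes
  φ(σ) = 0, φ(r_c) = 0 identically (no discontinuity at the cutoff)
  and the minimum depth exactly −ε. Default r_c = 3σ when a table omits
  it.

Totals use standard 1–2 exclusion (directly bonded pairs are omitted
from the non-bonded sums). Per-pair (ε, σ, μ, ν) values are consumed
from user-supplied YAML tables — they belong to the force-field release,
not to this package — with symmetric completion of single-order listings
and rejection of conflicting duplicates. The shipped
`mpipi_synthetic_params.yaml` fixture carries invented-but-plausible
pair values for six residues so the module is exercisable; only its
four global constants are the standard ones. No forces, no sampling, no
trajectory I/O: energies only.

## Synthetic-data generators

Each generator is a pure function of a truth dataclass that includes
its seed, and each truth serialises to JSON beside its output, so every
synthetic dataset is self-describing and bit-reproducible.

- **Profiles**: the double-tanh slab shape plus i.i.d. Gaussian noise,
  defaults (plateaus 0.05/0.60 g/cm³, 1000 Å box, 200 bins, 300 Å slab,
  20 Å interfaces) shaped like a 64-chain slab box.
- **Binodal point sets**: closed-form inversion of the two coexistence
  laws at a temperature grid below Tc, plus Gaussian density noise with
  the noise sd recorded as the per-point error. Default truth
  (Tc = 400 K, ρc = 0.30 g/cm³, d = 0.77, A = −0.001 g cm⁻³ K⁻¹) is an
  arbitrary fixture resembling typical PLD binodal axes, not a measured
  value.
- **Variant families**: ΔTc = S_truth·x(ansatz) + Gaussian noise, with
  per-observation (N, L) cycling through configurable lists; the default
  study condition for recovery tests is n = 20 observations, L spanning
  100–300, noise sd 2 K (the scale of the Tc estimation error of
  coarse-grained direct-coexistence, ~3 K).
- **Sequences**: class counts by largest-remainder rounding of target
  fractions (defaults: aromatic 0.30, positive 0.03, negative 0.01,
  Asn/Gln 0.25, Gly 0.20, other neutral 0.21 — inside the wild-type PLD
  ranges of aromatic fraction 0.19–0.43 and total charge 0.02–0.10),
  letters uniform within class, arrangement a seeded permutation.

What passing recovery tests on these inputs shows: the estimators are
correct and well-calibrated for data that actually follows the models
with independent Gaussian errors. What they do not show: robustness to
correlated MD noise, equilibration artefacts, finite-size effects, or
interfacial fluctuations — none of which the generators emulate.

## Variant design rules

In-silico mutagenesis mirrors how PLD variant families are constructed:
one amino-acid type at a time (multi-type substitution sets are
representable but flagged, and all fitters refuse them), substitutions
spread homogeneously, and deletions replaced composition-preservingly.
Two under-specified steps needed concrete conventions:

- **"Distributed homogeneously"**: the chosen positions are the evenly
  spaced quantiles of the source-residue occurrence list — occurrence
  indices round(j(M−1)/(N−1)) for j = 0..N−1 of the M occurrences, the
  middle occurrence for a single mutation. Deterministic and order-free;
  the exact placement used for the published variant sequences is not
  recoverable from the text, so this is a documented stand-in.
- **Composition-biased replacement ("X" targets)**: replacement letters
  are Ser/Thr/Gly/Ala with multiplicities proportional to their
  wild-type counts, rounded by largest remainder with ties broken in
  the fixed order S<T<G<A; the seed only shuffles which chosen position
  receives which letter. If the wild type contains none of the four,
  the pool is uniform over them.

Histidine carries zero formal charge in the default charge model (its
compositional grouping with the positives does not assign it an
electrostatic charge at neutral pH); `ChargeModel.default(histidine_charge=...)`
overrides. Positions are 1-based at every interface.

## Pipeline and problem sizes

The `run` pipeline chains: FASTA + variant table + per-variant
coexistence CSVs → critical fits → ΔTc vs wild type → per-class fits
under all three ansätze → σaro table → prediction grid → JSON/CSV
report with stage timings. It is a pure function of (inputs, config)
for deterministic stages; stochastic stages record their seeds.
`generate_synthetic_study` writes a complete input set whose binodals
are shifted by the published laws, so the end-to-end run has a known
answer.

Default problem sizes throughout (200-bin profiles, ~10-temperature
binodals, 20-observation families, 100-seed selection studies, 1000
random sequences for the patterning oracle) were chosen as the smallest
sizes at which the statistical checks are sharp; the full suite runs in
a few seconds on one core.

## Known limitations

- The binodal fitter assumes the 3.06-exponent coexistence law holds
  over the whole fitted temperature range; very-near-critical data with
  crossover behavior would need a different form.
- Per-point error protocols (independent replicas vs trajectory
  chunking) are consumed as given; the package does not reconstruct
  either from trajectories, and does not read trajectory formats at all.
- Scaling-law predictions extrapolate only within PLD-like composition;
  other protein families (transcription factors, nucleoporins) likely
  obey different constants and possibly different ansätze.
- The σaro ordering guarantee is domain-restricted (see above).
- Insertions, deletions, and post-translational modifications are out of
  scope; variants are substitution-only and assumed not to change
  secondary structure.
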