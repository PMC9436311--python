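# Methods

This note documents the model, its parameterization, the numerical
choices, what the synthetic inputs do and do not emulate, and the known
limitations.  Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Tissue automaton

The epidermis is a hybrid cellular automaton: discrete keratinocytes on a
3D lattice coupled to a continuous growth-factor (GF) field.  One voxel is
one cell (default `cell_size_um = 15`), so a biopsy of area *B* mm² maps
to `Lx = Ly = floor(sqrt(B)/0.015)` columns; the actual simulated area
(`SimConfig.area_mm2`) is used everywhere densities are reported, so the
integer rounding never biases per-area quantities.  The default height
`lz = 30` leaves head-room above the target mean column height of ~27
cells (120,000 cells/mm² ÷ 66.7² basal columns/mm²).

**Growth factor.**  The field obeys a diffusion–consumption–decay balance,
`D ∇²u = (λ_d + c·1_occupied) u`, with `u = s0` clamped on the basal plane
(the dermal source), periodic lateral faces, and a no-flux top.  Only the
ratio (λ_d + c)/D matters for the quasi-steady shape; the defaults
(`D = 1`, `c = 0.2`, `λ_d = 0.05`, per voxel²/day) give a decay length of
2 cell layers in occupied tissue, so division is basal-concentrated and
death is confined to the upper layers.  The field is relaxed to
quasi-steady state by Jacobi iteration before every cell step
(`gf_every = 1`), warm-started from the previous step's field; the
stopping rule is max update < `gf_tol·s0` (default 1e-5), with a
RuntimeError carrying the residual if `gf_max_sweeps` is exhausted.  A
no-flux top was chosen over an absorbing one because the stratum corneum
neither consumes nor drains the dermal signal; at the default decay
length the two differ by ~1e-8·s0 in the tissue.  Lateral faces are
periodic for both cells and field: a mixed boundary would reintroduce
edge artifacts in the GF that the periodic occupancy boundary exists to
remove.

**Cell events.**  Each day every cell draws, against the pre-step field,
first a death check `p_die(u) = d_max·K_die/(u+K_die)` and otherwise a
division check `p_div(u) = p_max·u/(u+K_div)` (monotone saturating
responses — the minimal family consistent with a niche-driven tissue).
Deaths are applied, then divisions execute in a fresh random permutation
(removing sweep-direction bias).  A cell displaced before its turn
forfeits that division (<1% of attempts at homeostasis; absorbed by
calibration).  The daughter goes to one of 4 lateral neighbors or
directly above, uniformly by default (`placement_weights` is
configurable); an occupied target shifts its occupant and the cells above
it, up to the first gap in the column, one position upward; a cell
shifted past `z = lz−1` is shed.  A daughter directed "above" from the
top layer is born directly into the shedding boundary (counted as birth
and shed).  The ledger births − deaths − sheddings = ΔN is exact every
step and is asserted in the tests.

**Calibration.**  Two measured anchors parameterize the neutral tissue: a
basal progenitor loss/replacement rate of 0.51/week and a density of
≈120,000 cells/mm².  Basal loss is dominated by lateral displacement
(basal death is negligible at the default `K_die`), giving the analytic
pin `0.8·p_div(s0) ≈ 0.51/7 per day`, refined by pilot runs; density is
set by the height at which GF starvation kills, i.e. by `K_die`.  The
frozen defaults (`p_max = 0.1425`, `K_div = 0.5`, `d_max = 0.6`,
`K_die = 5e-7`) measure ~121,000 cells/mm² and ~0.51/week on pilot
domains (`driver.calibrate` re-verifies this and performs a local grid
search when given different targets).

**Problem sizes.**  Library defaults favor desk-scale experiments:
0.04–0.25 mm² domains and 1–5 simulated years, with per-area quantities
extrapolated linearly by area (density is per-column and the lateral
boundary is periodic, so the extrapolation is exact in expectation;
`tests/test_tissue.py` checks half-life domain-invariance directly).
Patient-scale runs (1–3.14 mm², 58 years) use the same code path and are
simply longer.

## In silico genomes

Each cell's genome is the gene panel: per gene a length, base
composition, rate μ_g, and driver class.  Per division, gene g draws
X_g ~ Poisson(μ_g·L_g) substitutions; the engine draws the per-gene count
matrix for all of a step's divisions at once (distributionally identical
by Poisson superposition) and materializes events only for the rare
nonzero draws.  Reference-base weights are {C: 1/2, A,G,T: 1/6 each},
renormalized per gene over the base classes present (the UV signature is
a genome-level property; a gene with no cytosines cannot supply C
events).  The alternate base for a C reference is T with probability 0.9
(C>T transitions dominate UV mutagenesis), otherwise uniform; non-C
references mutate uniformly.  Positions are uniform among same-base sites;
within a lineage a previously hit position is redrawn (infinite sites per
lineage), keeping every mutation id usable as a fate marker.  Genotypes
are persistent tree nodes (own events + parent pointer), so a daughter
with no de novo events shares its parent's node and memory stays
proportional to the number of mutational events, not cells.

The default panel is synthetic: 72 genes, lengths log-uniform on
[2 kb, 120 kb] (the NOTCH1-like and TP53-like genes fixed at 51 kb and
19 kb, typical of those loci), GC fraction 0.41, per-gene rates
log-normal (σ = 0.5) normalized to a length-weighted mean of
3.2×10⁻⁹ bp⁻¹division⁻¹.  Base *positions* are a seeded arrangement
consistent with the stored composition — a stand-in for real sequence
that guarantees a position always reports the same reference base.  Real
panels load from TSV (`gene chrom start end nA nC nG nT mu_g
driver_class`, 0-based half-open coordinates).

## Selection mechanisms

Neither driver touches division rates.  NOTCH1: when a division targets a
site whose occupant carries a NOTCH1-class mutation, the occupant vetoes
with probability f₀; the divider retries among its remaining candidates
and aborts (no birth) only if all five are vetoed.  Redirect-then-abort
was chosen over abort-on-first-veto because it keeps the neutral limit
exact (f₀ = 0 consumes no randomness and is bitwise identical to the
neutral engine) while still producing the persistence phenotype; at full
blocking the interior of a NOTCH1 clone aborts entirely (veto⁵ = 1) and
homeostasis degrades, which is the mechanism's intended cost.  TP53: on
each sun day (day-of-year set *S*, repeated yearly; even spacing or a
consecutive "vacation" block), every non-TP53-mutant cell dies with
probability θ_s, drawn from a dedicated UV RNG stream.  The kill applies
to all layers by default (`uv_basal_only` restricts it), the simplest
reading of UV damage reaching the whole epidermis.

dH = ln(mean squared population difference) between a trajectory and a
homeostatic reference, floored at ln(1) = 0 so identical trajectories
score zero while a constant offset Δ scores exactly ln(Δ²).

## ODE surrogate

Between sun days the population follows the exact logistic closed form
segment by segment (no integrator error); each sun day multiplies N by
(1−θ_s) at the start of that day, so same-day pulses compose
multiplicatively.  Defaults r = 0.05/day and K = 120,000 match the
automaton's wound-recovery timescale and 1 mm² equilibrium.  The
surrogate is single-compartment — it answers only whether a UV regime
keeps density near K (flagging minima below 0.8·K), not what the clones
do; a two-compartment (TP53/non-TP53) extension would be straightforward
but is not needed for regime screening.

## Virtual sequencing and clone statistics

VAF_t = n/(2N) (diploid heterozygous; copy number is not modeled).  Depth
D_i ~ Gamma(k_p, θ_p) rounded to the nearest integer with floor 1 — a
binomial needs an integer trial count, and the floor keeps VAF_s defined;
reads f_i ~ Binomial(D_i, VAF_t); VAF_s = f_i/D_i.  The gamma fit is a
true MLE (scipy, location fixed at 0) started from moment matching;
constant samples raise rather than silently degenerate.  Depths are drawn
independently per variant.  The filter keeps VAF_s ≥ 0.005 (the cutoff
value itself is observable).  Clone area = 2·VAF·B, clamped at B because
noise can push VAF past 0.5.  For μ₁ and KS, areas are discretized in
units of one cell footprint (0.015² mm²), matching the discrete n of the
neutral theory P_n(t) = exp(−n/(r_λ t))/(n ln(r_λ t)).  KS comparisons
run on the clone-size samples underlying the μ₁ curves (the two-sample
statistic and its critical value D_α = c(α)√((m+n)/(mn)), c(0.05) ≈
1.358, are defined on samples); comparing μ₁-transformed values is
exposed as an option.

## What the synthetic inputs do and do not emulate

The synthetic panel reproduces panel-scale structure (length spread, GC
content, one gene per driver class, heterogeneous normalized rates) but
not the identity of real genes, real sequence context, trinucleotide
signatures, or per-gene empirical rates.  Distribution-level tests
(clone-size shapes, KS self-consistency, signature fractions) transfer to
real panels; gene-level conclusions do not.  Tests that need many
observable clones on desk-scale domains raise the mean mutation rate
(e.g. 100×) — this rescales clone *counts*, not the drift dynamics that
determine clone *sizes*, though at very high rates clonal interference is
stronger than in real tissue.  Passing tests therefore demonstrate the
mechanisms and the pipeline, not patient-level realism of any particular
gene.

## Numerical and degenerate-input choices

Random streams: one per concern (tissue events, mutations, UV kills,
sequencing), all spawned from the master seed, so re-drawing sequencing
noise never perturbs the tissue trajectory; runs are bitwise reproducible
from (config, seed).  Degenerate cases are defined, not special-cased
away: an empty wound region is a no-op; a gene missing a base class
renormalizes its signature weights; a lineage that saturates a tiny gene
raises after a bounded number of redraws; survival fits with no decay
report an infinite half-life.  Lineage half-lives come from a nonlinear
least-squares fit of exp(−kt) to weekly survival fractions (CI from the
fit covariance) — chosen over a log-linear fit because the early, well-
populated part of the curve should dominate.

## Known limitations

Basal lineage survival under critical drift has a heavier-than-
exponential tail: with turnover pinned at 0.51/week, the measured
half-life is ~3.5 weeks but ~87% (not ≥95%) of lineages are lost by four
months — a single exponential cannot fit both ends of the measured
survival curve, and the model reports what it measures.  Melanocytes,
fibroblasts, dermis, mechanics, indels and copy-number changes are out of
scope; transient amplifying cells exist only implicitly (suprabasal
divisions); UV exposure repeats identically every year.
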