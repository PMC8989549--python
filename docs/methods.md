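# Methods

This note documents the models behind `ribodrop`, the defaults and why
they were chosen, and what the simulator does and does not capture.

## Library model

A library is a pair of constant DNA flanks around a fully degenerate
window whose length may take several values; the design space is
`Σ_L 4^L`. Variants are identified by their variable-region sequence
(unique across length classes because the string length differs), and
sequences are stored as DNA throughout — RNA is a display concern. The
shipped preset designs (histamine ON: lengths {4,5,6}, 5376 variants;
histamine OFF: {3,4,5,6}, 5440; ciprofloxacin: {6}, 4096) use synthetic
stand-in flank sequences; they carry the structural roles of a tag + T7
promoter and an aptamer + RBS + reporter context but are not any
published sequence. Initial pools are multinomial draws with optional
Gamma-distributed per-variant synthesis weights (`skew`, default 0 =
uniform; library synthesis bias is not part of the modeled protocol, so
the default assumes none, and all length classes are uniform over
sequences so longer classes dominate). Enumeration refuses design
spaces above 10⁷ variants to stay desk-scale.

Consensus calling returns, per position, the minimal IUPAC code covering
every observed base (IUPAC codes in the input are expanded first).

## Encapsulation

Bead counts per droplet are Poisson(λ). Closed forms used throughout:
occupancy `1 − e^{−λ}`, its inverse `λ = −ln(1 − target)`, and
monoclonality `λe^{−λ}/(1 − e^{−λ})`. The protocol operates at 10–30%
occupancy; the 30% ceiling leaves ≥70% of droplets empty while 83% of
occupied droplets are monoclonal. The same arithmetic applies to
template-per-bead loading during clonal amplification, so no separate
implementation exists for it.

Magnetic beads aggregate; no quantitative measurement of aggregation is
available, so it is modeled with the simplest mean-preserving
overdispersion mechanism: droplets receive Poisson(λ(1−p)) clumps of
Geometric(p) beads each (`clump_p`, default 0; the mock-sorting preset
uses 0.3). The bead-count probability generating function
`E[s^K] = exp(μ(g(s)−1))` is exposed because thinning it answers "how
often does a droplet contain at least one bead of a species at fraction
f" in closed form.

## Phenotypes and optics

Ground-truth dose responses are Hill curves (default Hill coefficient 1;
the screen's readouts are empirical EC50s and ratios, and a Hill
parameterization is the simulator's modeling choice). Expression is in
units of the no-riboswitch control construct. Default class structure of
a library built around an inhibitory stem-loop:

- planted switches (default 1%): OFF leak uniform in 0.02–0.15,
  ON/OFF ratio uniform in 5–20 (covering the strongest observed
  responses near 19.7×), EC50 lognormal around 1.6 mM;
- constitutive/leaky variants (10% of the remainder): level 0.6–1.4;
- repressed ("dead") variants: leak 0.02–0.15. The repressed leak range
  deliberately equals the switch OFF range — both are set by the same
  inhibitory stem — so OFF-sorting cannot spuriously separate them.

Optics: ROX is a bead-presence indicator (the beacon reports
transcription generally; mRNA-level variation folds into the noise
term), GFP is baseline + scale × min(Σ expression, cap) with the cap at
1.2 control units representing the fixed detector-fragment budget of the
split-GFP system. Multi-bead droplets sum expression and share one
sorting fate — this is the mechanism that dilutes template-level
enrichment in the mock experiment. All signals carry mean-1 lognormal
noise (default CV 0.25). Whether droplet expression saturates at the
same ceiling as bulk assays is unknown; a single shared cap is assumed.

## Gate construction

The ROX floor is the 99.9% quantile of the dominant low-ROX cluster,
identified as values within 4× the population median (valid whenever
empties are the majority, as the protocol guarantees); a population is
declared all-empty if the remaining "positives" are not well separated
(median of positives < 2× the floor). The GFP bound is the exact order
statistic of GFP among ROX-positive droplets such that the gate holds at
most `cap_fraction` of all droplets (default 3%, hard ceiling 10%). Ties
at the boundary push the bound outward so the cap is never exceeded;
ties have measure zero for noisy signals and only matter for constructed
noise-free populations. This quantile rule was chosen over mixture
fitting for simplicity and testability.

## Sorting rounds and campaigns

A round encapsulates the pool, measures, gates, sorts (in-gate droplets
kept with probability 1−miss, out-of-gate leak through at `false_sort`),
and regenerates the pool: every bead in a sorted droplet contributes one
template lineage, weighted by optional lognormal PCR bias, normalized to
sum to 1. An empty recovery halts the campaign and is recorded. Each
stochastic operation takes an explicit seed; a campaign derives per-round
seeds from its seed by a fixed stride so single rounds are reproducible
in isolation.

Sorter error rates are not separately measurable from the published
composite efficiency/purity numbers, so they are calibration choices:
`miss = 0.02` and `false_sort = 0.003`, the latter chosen so that mock
ON-sorting purity lands near 85% (the observed range is ~80–89%) given
that nearly all out-of-gate droplets are empty. With these defaults the
mock ON-sort yields ≈48× droplet-level and ≈9× template-level
enrichment at clump_p = 0.3. OFF-direction mock purity comes out lower
(~55–60%) because the false-sort floor is proportionally larger against
the smaller OFF gate; a single false-sort rate cannot reproduce both
directions' purities exactly, and the ON direction was chosen as the
calibration anchor.

The default round size is 5×10⁵ droplets at 30% occupancy: ≈90 droplets
per variant for a ~5000-variant library, comparable to the 10–40×
coverage the protocol targets. Coverage matters — at 10× fewer droplets
per round the regenerated pools pass through ~3000-bead bottlenecks,
genetic drift concentrates surviving non-switch variants, and their
spuriously steep late trajectories contaminate the top ranks. Each round
runs in well under a second, so the larger default costs little.

The mock experiment sets its gate cap just inside the expected
minor-droplet cluster (85% of its closed-form population fraction, from
the loading PGF), mirroring how an operator draws the gate around the
visible minor cluster; screening rounds use the fixed 3% default because
there the target cluster is not identifiable a priori.

## Sequencing and read processing

Reads are `barcode + upstream + variable + downstream` truncated to
150 nt (single-end; the modeled protocol pre-merges paired ends), with
i.i.d. substitution errors and uniform base qualities consistent with
the error rate. Processing is deterministic and alignment-free:

- demultiplexing is exact-prefix barcode matching (no error
  correction — with 6–8 nt ad-hoc barcodes any correction policy would
  be arbitrary); unassigned reads are tallied, not errors;
- filtering discards reads with any base below Phred 20 (the published
  threshold is unstated; Q20 is the conventional floor), constant
  regions that do not match the design exactly, or a variable-region
  length outside the design. The variable region is located by fixed
  offsets from the constant flanks, so indels surface as
  constant-region mismatches;
- counting pre-registers all design-space variants as rows (dense) for
  spaces up to 10⁵ variants, else only observed variants (sparse);
- abundances are `100 × count / cycle total`, failing loudly on
  zero-read cycles.

Conservation holds at every stage: input = assigned + unassigned =
passed + discarded per cycle.

## Ranking

The enrichment trend is the OLS slope of percentage abundance against
cycle index 0…C (cycle 0 = unsorted library, which the protocol also
sequences); undetected cycles contribute exactly 0 (no pseudocounts — a
slope, unlike a log fold change, tolerates zeros). Percentage vs
fractional abundance and the inclusion of cycle 0 only rescale/shift all
slopes jointly, so ranks are unaffected; the defaults above are declared
choices. Ties break by final-cycle abundance, then variant id. OFF
screens use the same descending order: enrichment of the desired
behavior is still "up".

One property one might expect — that nearly all planted switches end
high in the *final-abundance* ranking — does not hold under
extreme-quantile gating with a final OFF round: weak switches are
statistically exchangeable with repressed variants in an OFF round, so
their final abundances interleave. The slope ranking, which integrates
the ON-round gains, is the statistic that separates them, and it is what
the recovery tests assert (≥15 planted switches in the top 20 at default
settings with 1% planted and ratios ≥8×).

## Dose-response fitting

`fit_dose_response` fits the 4-parameter Hill model (two asymptotes,
EC50, Hill coefficient) by bounded least squares, with starting values
taken from the extreme-dose means and the median positive dose. It
requires ≥4 distinct concentrations including 0, rejects constant
responses as degenerate, and enforces the declared direction
(activation/repression) against the data. Nonspecific ligand effects on
the control construct are removed before fitting as a ratio of ratios at
each concentration — the only reading consistent with a per-
concentration correction. Both raw and corrected ratios are available,
since published ratio figures mix the two conventions.

## Sorting metrics

Efficiency is `100 × sorted desired / droplets detected in the gate` —
deliberately gate-conditional, exactly as a droplet sorter reports it,
not a global recall. Purity is desired among sorted. Droplet-level
enrichment compares desired-droplet fractions over *all* droplets
(empties included) before vs after; template-level enrichment compares
pool fractions. These two folds have different denominators (≈1.7% of
droplets vs 5% of templates in the standard mock), so they are not equal
even for a perfect monoclonal sort; what coincides in that limit is the
*after* composition (template purity ≈ droplet purity), and that is the
invariant the tests check. Restriction-digest composition is pure
band-intensity arithmetic; background subtraction and image analysis are
the caller's responsibility.

## What the simulator does not capture

Droplet physics (volume, coalescence, chip geometry), real cytometer
file formats, secondary-structure prediction and folding energetics,
PCR chemistry artifacts such as heteroduplex formation, paired-end
merging and adapter trimming, and aptamer affinity (K_d) measurements
are all out of scope. Passing tests therefore demonstrate the
statistical machinery of the screen — Poisson loading, quantile gating,
selection dynamics, counting and ranking — not the biochemistry of any
particular riboswitch; absolute enrichment folds from real experiments
will differ from simulated ones wherever these unmodeled effects
matter.

## Problem sizes

Defaults were sized for interactive use: screening rounds simulate
5×10⁵ droplets (~0.2 s each), the mock experiment 10⁵, sequencing
benchmarks 10⁶ reads (~10 s through the full pipeline), and Monte-Carlo
checks of the Poisson closed forms use 10⁶ droplets with 4σ binomial
tolerances.
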