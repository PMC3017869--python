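# Methods

## Scope and model

`cghkit` analyses two-colour CGH data in which a query strain's genomic
DNA competes with reference DNA on a dense tiling array of 60-mer
probes. The analysis assumes (i) most of the query genome is identical
to the reference, so the summarized log-ratio distribution has a
dominant component centred near 0; (ii) probes lose signal sharply with
target divergence — by design the arrays are validated so that three
mismatches abolish binding — so absent or diverged targets form a
well-separated negative component; (iii) replicates are dye-swapped, so
fluorophore-specific bias cancels under orientation-aware averaging.

Coordinates are 1-based inclusive everywhere inside the library
(EMBL-style annotation convention); BED writers/readers convert to and
from 0-based half-open and say so in their docstrings.

## Synthetic data generator

The generator is first-class, tested code: it defines the study
conditions the rest of the package is validated under.

Reference genomes are i.i.d. with a G+C bias (default 0.72, the
high-GC actinomycete regime). Genes (default 200, lengths 300–900 bp,
codon multiples) are placed non-overlapping with random intergenic
gaps; strands are random. Probes are 60-mers tiled every 30 bp; a
configurable fraction (default 0.15) of fully intergenic probes also
gets a minus-strand complement, to exercise complementary-probe
averaging.

The query genome differs by: deletion islands (default 4 islands of
3–6 consecutive genes; the whole block span including intergenic DNA is
removed), isolated gene deletions (default 6), and divergent genes
(default 6) mutated at a per-bp substitution rate of 0.15 — the level
of substantially diverged, recently acquired material, which is what
fails hybridization in practice; selections are separated by at least
one intact gene so islands remain maximal runs. Genes destined
absent/divergent are (optionally, default on) composed at 55% G+C so the
composition contrast of acquired material is present in the simulation.

Probe truth: a probe's mismatch count is the number of its bases deleted
from the query plus the Hamming distance of the surviving part at its
deletion-shifted coordinates; `binds` is mismatches < 3. Signals: per
array, binding probes draw M ~ N(0, 0.25), non-binding probes
M ~ N(−4, 0.5) (≈ 8 present-component SDs of separation, as seen on
strongly absent targets), A ~ N(10, 1); channel intensities are
back-computed from (M, A) under the array's dye orientation. Each
replicate contributes a dye-balanced array pair (default 2 pairs = 4
arrays). A `flag_rate` fraction (default 0.01) of features per array
receives a both-channel outlier flag pair (these are the features the QC
rule excludes) and the same rate again a single-channel flag (retained,
exercising the "both channels" requirement). An optional `dye_bias`
slope injects a linear M ~ A trend for loess testing; default 0.

All randomness flows from one `numpy` generator seeded by `seed`
(signal simulation uses `seed + 1` so genome and signal streams are
independent); sampling order is fixed, so outputs are byte-identical
across runs.

What the generator does *not* emulate: hybridization thermodynamics and
sequence-dependent probe affinity, cross-hybridization between
paralogues, spatial array artifacts, and partial/graded signal loss at
1–2 mismatches. Passing end-to-end tests therefore demonstrates the
statistical machinery recovers truth under the stated mixture model,
not that it would overcome probe-chemistry pathologies absent from the
model.

## Signal processing

Fixed stage order: QC flag filtering → orientation/log transform →
within-array loess → between-array scaling → replicate selection →
per-probe medians → complementary-probe averaging.

- **QC rule**: a feature is excluded iff for at least one of the four
  outlier variables *both* the green and red channel flags are set.
- **Zero intensities** are floored at 0.5 before log2 (prevents −∞; the
  choice of floor is inconsequential for well-measured features).
- **Loess**: span 0.3, degree 1, 3 robustness iterations
  (`statsmodels` lowess). Standard two-colour practice; the span is a
  package default, configurable.
- **Scale normalization**: each array's M divided by its MAD and
  multiplied by the geometric mean of all arrays' MADs, leaving every
  array with the same MAD. All arrays of all strain comparisons are
  normalized together, which keeps comparisons on one scale since the
  reference DNA is common to every array.
- **Replicate selection**: a probe is retained iff it has at least one
  good value in each dye orientation; the over-represented orientation
  is down-sampled at random (pipeline seed; e.g. of three good values,
  one of the two same-dye values is dropped) so the median is taken over
  a dye-balanced set.
- **Complementary averaging** is applied after replicate medians (the
  ordering is not dictated by the method; averaging medians keeps the
  per-locus value robust even when one strand member lost replicates).
  If one member of a strand pair was dropped entirely, the survivor
  passes through unaveraged.

## Dynamic-cutoff classification

Density estimation uses a Gaussian KDE (Silverman bandwidth) on a
512-point grid padded by three bandwidths. The mode is located on a
2×-oversmoothed pilot density — the raw KDE's argmax wobbles by O(h)
under resampling, and the mirror construction needs a stable centre —
with ties broken toward smaller M (conservative: fewer absents).
EPP(x) = min(1, f_pres(x)/f_obs(x)), exactly 1 at and right of the
mode; where f_obs vanishes, EPP extrapolates to 1 right of the mode and
0 left of it. The binary threshold is EPP ≥ 0.5 (configurable); the
graded output of the original tool is intentionally not reproduced.
Classification is per strain-comparison track, not per array. Adding a
constant to all ratios shifts the mode equally and leaves calls
unchanged, so the global shift introduced by loess-centring a mixture
is immaterial.

## Region calling

Runs are maximal stretches of call = 0 over *retained* probes in
coordinate order; gaps left by QC-dropped probes do not break runs.
Length 1 and 2 runs are reported as single/double absences and never
contribute to gene calls; runs of ≥ 3 probes are regions of difference
with span [start of first probe, end of last probe] (endpoint-inclusive
membership). A gene is absent iff its strand-aware translational start
(low coordinate on +, high on −, per CDS semantics) lies in a region
span; genes outside probe coverage are called present with a warning
flag. This rule is deliberately conservative — 3′-truncated genes stay
present — and has a known failure mode in the opposite direction: an
upstream absent run reaching just past a gene's start codon calls an
otherwise intact gene absent. Both behaviours are asserted in tests.

## Reciprocal-search validation

Presence requires, in *each* direction, some hit with alignment length
strictly > 60, identity strictly > 60 % and E-value < 0.01; any
qualifying hit suffices (the criterion speaks of *a* match, not the
best). Confusion-matrix orientation treats the sequence-based calls as
the reference. Percentages are rounded half-up for reporting, exact
values retained. One published inconsistency is handled explicitly: the
stated gene-level cells TP = 7047, TN = 498, FN = 120, FP = 159 give
specificity 498/657 = 75.8 %, while the accompanying text prints 78 %;
the package implements the formula and reports 75.8 % (rounded 76).

The bundled fixture aligner (exact 12-mer seeds, ungapped X-drop
extension, one extension per diagonal stripe, ungapped Karlin–Altschul
E-values with blastn +1/−2 parameters) exists to produce outfmt-6 hit
tables for synthetic genomes without an external dependency; tests
cross-check its presence calls against blastn where available. It is a
test fixture, not a general-purpose aligner.

## Sequence statistics

%G+C rejects ambiguity codes rather than guessing. Codon usage is
aggregated over all CDS (genome-frequency background, not a
highly-expressed reference set); within-family relative adaptiveness is
w_c = f_c / max f_c′. Zero-count codons receive the floor w = 0.01 so a
single unobserved codon cannot zero a gene's CAI; a wholly unobserved
family is uninformative and gets w = 1 throughout. Single-codon families
(Met, Trp) have w = 1 and thus no effect on the geometric mean. Stop
codons are tallied but excluded from CAI. The standard genetic code is
used with no special treatment of start codons.

## Flux balance analysis

The reaction-table dialect is `coef? MET (+ coef? MET)* (= | ->) ...`
("=" reversible with bounds [−1000, 1000], "->" irreversible with
[0, 1000]); a one-sided formula is an exchange reaction. Gene-based
removal requires *all* listed genes absent — a surviving isozyme keeps
its reaction (the malate-synthase isoform SCO6243 is the motivating
case) — and gene-less reactions are never removed; the ten
removable reactions shipped in `cghkit.models` are single-gene, so the
nine-gene absent set removes them exactly. Media set exchange lower
bounds to −uptake (positive flux = export). LPs are solved with
scipy's HiGHS; optima below 1e-9 are reported as exactly 0, and the
grow/no-grow threshold for phenotype screens is 1e-6.

The shipped toy network (22 reactions + optional ethylmalonyl module)
contains lumped glycolysis, pyruvate carboxylase anaplerosis, lumped
β-oxidation of palmitate, the TCA cycle, the glyoxylate shunt (R386,
R388, gene-tagged), lumped oxidative phosphorylation, a
transhydrogenase, and a biomass drain on OAA + 4 ATP + 2 NADPH. It is
constructed so that on palmitate carbon enters solely as acetyl-CoA:
without the glyoxylate shunt (or the lumped ethylmalonyl-CoA reaction
2 AcCoA + 2 NADPH → SUCC + 2 CoA + 2 NADP) no net C4 synthesis — and
hence no biomass — is possible, while glucose growth is unaffected.
Deleting isocitrate lyase (R386) alone already abolishes palmitate
growth, since malate synthase has no glyoxylate source without it. The
lumped module trades elemental fidelity for clarity; the full
genome-scale model is supported through the same reaction-table format
but is not shipped.

## Problem sizes and tolerances

Default synthetic studies use a 240 kb genome, 200 genes, ~8,600 probes
and 4 arrays — large enough for stable density estimation (KDE on ~8,000
summarized ratios) and tight binomial bounds on recovery rates, small
enough that the full pipeline runs in well under a minute. Statistical
test sizes (n = 10,000 mixture draws for the Bayes comparison, 1,000
random tracks for the run-caller oracle, 4,000 points for loess bias
removal) follow the same reasoning. Numerical comparisons: CAI against
its log-sum oracle at 1e-12; LP mass balance at 1e-8; loess residual
bound 0.05 on the injected-bias design.

## Known limitations

- The mixture model gives probes a binary bind/no-bind truth; real
  arrays show graded intermediate signal for 1–2 mismatch targets.
- The mode-mirroring EPP is a ratio of density estimates and is only as
  stable as the KDE in sparse tails; with < 500 summarized ratios the
  fit is accepted but warnings about interpretation apply (< 50 is an
  error).
- The fixture aligner has no gapped extension; highly fragmented
  homology can fall below the reciprocal thresholds that a full
  Smith–Waterman would pass.
- The toy metabolic network is a teaching-scale surrogate; its flux
  values (e.g. 12.31 biomass on 10 glucose) are properties of the toy
  stoichiometry, not predictions for the organism. Only the qualitative
  grow/no-grow contrasts carry over.
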