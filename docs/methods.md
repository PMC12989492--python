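# Methods

This note documents the models, statistics and numerical choices behind
`lentiflux`, in the order the pipeline applies them.

## Expression processing

Counts are converted to transcripts per million from recorded gene lengths:
`TPM_gs = (c_gs / L_g) / Σ_g' (c_g's / L_g') × 10⁶`, so every sample sums to
10⁶.  Group contrast per gene is `log2((mean_lesion + pc)/(mean_control + pc))`
with pseudocount `pc = 1` TPM — large enough to avoid ±∞ on zero means,
negligible against typical TPM magnitudes.  Per-gene significance comes from
a two-sided Wilcoxon rank-sum test: exact (full permutation null) when both
groups have ≤ 10 samples and the pooled values are tie-free, otherwise the
mid-rank normal approximation; a gene constant across all samples gets
p = 1.  Multiplicity is controlled by the Benjamini–Hochberg step-up,
implemented directly (sorted p·n/rank, reverse cumulative minimum, clipped
to [0, 1]) and cross-checked in the test suite against a brute-force oracle
on every short vector.  The significance filter is strict on both sides:
FDR < 0.05 **and** |log2FC| > 0.01.  The log2FC threshold is unusually
permissive by design — with fluxes, not transcripts, as the endpoint, the
filter's job is only to drop exactly-boundary cases.  The rank test is an
intentionally simple, assumption-light stand-in for a parametric
count-model fit; it is unpaired by default so the differential-expression
and differential-flux arms make the same two-sample comparison.

## Metabolic model and toy model

Models are stoichiometric: metabolite × reaction matrix `S`, per-reaction
bounds, subsystem labels, and GPR boolean trees parsed from BiGG-style rule
strings (`and` binds tighter than `or`; an empty rule is a distinct
"no gene association" sentinel).  BiGG-JSON is the primary dialect (reader,
writer, round-trip exact); SBML Level 3 + FBC is read best-effort through
COBRApy when installed.  Files omitting bounds get the COBRA convention:
reversible −1000/1000, irreversible 0/1000.

The built-in toy model (16 metabolites, 26 reactions, 16 genes) has a
glucose → acetyl-CoA → NADH → ATP backbone with CoA turnover and
fatty-acid synthesis/oxidation cycles, covering all nine energy-associated
subsystems, plus six single-gene-gated branch reactions reusing BiGG ids of
lipid-metabolic reactions (`PSDm_hs`, `PETOHMr_hs`, `DHCRD2`, `DESAT18_3`,
`FAEL183`, `SQLEr`).  Each branch is modelled as a single energy-yielding
conversion (substrate → ATP) so that branch throughput enters the
maintenance objective and the gating gene's expression is the binding
bottleneck — a deliberate simplification that makes planted effects
identifiable, not a claim about lipid biochemistry.  The builder verifies
by LP that the energy objective admits a strictly positive optimum and can
optionally add ungated branches or a dead-end branch (whose maximum flux is
provably zero) for testing.

## Expression-constrained flux simulation

Per sample, each reaction's activity is its GPR evaluated on the TPM
vector: AND → min over present children, OR → sum, genes missing from the
expression table are skipped, and a rule with no present gene leaves the
reaction unconstrained.  Activities are normalized by the sample's 95th
percentile of constrained activities and clipped to [0, 1]; upper bounds
(and the negative lower bounds of reversible reactions) are multiplied by
the normalized score.  The percentile normalization makes the constraint
scale-free — multiplying a sample's TPM column by any λ > 0 leaves its flux
vector unchanged — and bounds the influence of outlier transcripts.  One
consequence worth knowing: lowering a gene that itself contributes to the
percentile lowers the normalizer, so *other* reactions' effective bounds
can rise.  Raw activities are monotone in every gene (min/sum algebra), and
a branch's own bound is monotone in its gating gene whenever the normalizer
is anchored by higher-expressed enzymes, which is the regime the synthetic
cohorts emulate (see below).

The objective places coefficient +1 on every reaction (both halves after
splitting reversibles) whose subsystem matches one of the nine energy
subsystems, case-insensitively with "/" read as "and" plus a configurable
synonym table.  A single composite equal-weight objective is used rather
than lexicographic per-pathway optimization: with no stated ordering among
the nine pathways, symmetry is the neutral reading, and the weights are
config-exposed.  Stage 1 maximizes `c·v` subject to `S·v = 0` and the
effective bounds, with reversible reactions split into non-negative
forward/backward halves.  Stage 2 holds `c·v` at the stage-1 optimum as an
equality (the parsimonious-FBA convention; an inequality with 1e-9 relative
slack is the fallback if the equality is reported infeasible) and minimizes
the sum of all split variables; reported flux is forward − backward.
Without the second stage, alternate optimal vertices would make per-sample
fluxes incomparable and the downstream rank test would be comparing solver
arbitrariness.  Equivalent parallel pathways remain a known degeneracy: the
parsimonious total flux is unique, the split across the paths is not.

LPs are solved with HiGHS via `scipy.optimize.linprog`.  Returned vectors
satisfy `|S·v| ≤ 1e-6` (observed ≈ 1e-14 on the toy model) and their bounds
to solver tolerance.  Simulation is per sample (one flux vector per sample,
two conditions × n pairs), not per condition-mean; the per-sample choice is
what gives the downstream test its replicates.

## Van der Waerden differential flux testing

For each reaction, pooled fluxes across the two groups receive mid-ranks
`R_i` and normal scores `A_i = Φ⁻¹(R_i/(N+1))`; the statistic is the
lesion-group score sum `T` (the groups' statistics are exact negatives of
each other since scores sum to zero).  Two modes:

- **exact** — `p` is the fraction of all C(N, n₁) group assignments with
  `|T*| ≥ |T|` (tie tolerance 1e-12).  At the 7-vs-7 design this is 3432
  assignments, enumerated with a cached index matrix; exact mode is used
  automatically whenever C(N, n₁) ≤ 200 000.
- **normal** — `T` standardized by its permutation variance
  `Var(T) = n₁n₂ ΣA² / (N(N−1))`, two-sided normal p.  Against exact mode
  at n = 5 vs 5 the agreement is ≤ 0.014 for p ≤ 0.1; deviations up to
  ~0.06 occur only at large p where the discrete exact null has coarse
  atoms, so the approximation is reliable exactly where decisions are made.

The test is two-sided (both flux increases and decreases are of interest);
direction is the sign of `T`.  Reactions with degenerate (constant) pooled
flux are reported untested with p = 1, and single-metabolite boundary stubs
(exchanges/demands) are excluded from testing by default: a branch's
exchange flux is stoichiometrically the mirror of the branch reaction
itself, so testing it would double-count every effect.  Both exclusions are
config-exposed, and the BH-FDR runs over tested reactions only so
structurally blocked reactions do not dilute the correction.  Significance
is FDR < 0.05, strict.  No paired/stratified variant is implemented.

## Synthetic cohorts and the answer key

`SyntheticDesign` draws gene × sample counts from a negative binomial with
`var = μ + φμ²` (Poisson in the φ → 0 limit), means per gene times a shared
per-patient lognormal depth factor (applied to both samples of a pair — a
sequencing-depth-like effect that TPM normalization removes, keeping the
unpaired tests exactly calibrated under the null), and planted
multiplicative fold changes on chosen genes in the lesion group.  Gene
lengths are log-uniform on [500, 5000] nt and recorded for TPM conversion.
All randomness flows from one seed through deterministically spawned
sub-streams; identical designs give identical matrices.

The demo conditions are 7 pairs, 200 genes, baseline mean 100, dispersion
0.05, depth sd 0.2.  Two backbone enzymes (`GAPDH_toy`, `NDUFA_toy`) get
housekeeping-level means of 5000: they anchor the 95th-percentile
normalizer of the flux bounds, emulating the real situation where the most
abundant metabolic transcripts — not the perturbed ones — set the
expression scale.  Planted effects are 0.25× on the genes gating `DHCRD2`
and `FAEL183` and 4× on the gene gating `PSDm_hs`.  The answer key derives
expected flux directions deterministically: a reaction whose sole gating
gene is knocked down is expected "down", upregulated "up", others "none".

What the generator does *not* emulate: isoform structure, GC/length biases
beyond a fixed per-gene length, batch effects beyond the depth factor,
correlated gene programs in the null genes, or any transcript–flux coupling
other than the GPR bounds themselves.  Passing recovery tests therefore
demonstrates that the pipeline recovers effects that propagate through
expression-scaled bounds — not that real lesions behave like the toy model.

For clustering benchmarks, `make_cluster_profiles` plants k clusters of
log2FC-like profiles whose centers are distinct sign patterns across
features scaled to `separation` noise-SD units per feature.  Pattern
centers (shared response *shapes*) rather than constant offsets are used
because the consensus procedure median-centers each gene first, which
removes any constant offset exactly.

## Consensus clustering and networks

Profiles are median-centered per gene, then for each k in the range
(default 2–10) and each of 30 repetitions, 80% of genes are subsampled
without replacement and clustered by k-means (Euclidean, k-means++ init,
10 restarts, ≤ 100 iterations, per-repetition sub-seeds).  The consensus
matrix entry is co-clustering count over co-sampling count; pairs never
co-sampled get 0 and a flag.  Final assignments cut an average-linkage tree
of 1 − M.  The number of clusters maximizes the relative gain in area under
the consensus CDF among k above the smallest candidate — the smallest k has
no gain of its own, so it is chosen instead when its consensus is crisper
(lower proportion of entries in (0.1, 0.9), a PAC-style ambiguity measure)
than the winner's.  This guard matters in both directions: the CDF area
grows mechanically with k, so raw-area scoring of the smallest k would win
near-ties even against a perfectly crisp larger k, while dropping the
smallest k entirely would never let a true two-cluster structure be chosen.

Co-expression networks connect gene pairs whose consensus at the chosen k
meets a threshold (default 0.5; the consensus value is the edge weight).
STRING-style edge lists are read offline: scores above 1 are taken to be on
STRING's 0–1000 scale and rescaled, self-loops dropped, duplicate pairs
collapsed to their maximum score, and a minimum-score filter applied
(default 0.4, STRING's "medium confidence").  Topology summaries are
degrees, connected components and density.

Over-representation of a gene selection against GMT sets is the upper-tail
hypergeometric probability `P(X ≥ overlap)` with universe N, set size K and
selection size n (all intersected with the universe; the universe defaults
to the expression matrix's genes), BH-corrected across sets.

## Pipeline and determinism

The pipeline runs model → expression → flux simulation → differential flux,
plus the clustering/ORA arm, from one YAML config.  Every output TSV starts
with a comment line carrying the run id (a hash of config and seed — never
a timestamp), so identical config + seed reproduce byte-identical outputs;
the JSON report records input hashes and per-stage counts.  A stage failure
writes a `FAILED_<stage>` marker and aborts with the stage name.

## Problem sizes used in the shipped checks

Exactness checks run against brute-force enumeration oracles (all 70
assignments at 4 vs 4 for the VdW test, all C(N, n) draws for N ≤ 12 for
the hypergeometric test, all step-up paths for BH on vectors of length
≤ 8).  Calibration uses 2000 effect-free genes at the 7-vs-7 design;
parameter recovery uses 50 independently seeded planted cohorts; consensus
recovery uses 50 seeds of 60-gene three-cluster profiles with the full
k = 2–10 sweep at 30 repetitions.  These sizes give binomial standard
errors comfortably below the asserted margins while keeping the whole suite
at a few minutes on one CPU.

## Known limitations

- The GPR → bound mapping is the whole transcript–flux coupling; no
  thermodynamics, metabolomics or enzyme kinetics.
- Flux-variability analysis, flux sampling and gap-filling are out of
  scope; alternate-optima structure beyond the parsimonious total is not
  reported.
- The VdW test has no paired variant here, and the percentile normalizer
  couples reactions through a shared scale (see above).
- Which exchange constraints a curated genome-scale model (e.g. Recon1)
  should open is model-specific and left to the user's bounds/config; the
  toy model sidesteps the question by construction.
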