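# Methods

This note documents the models and procedures implemented in `tcrkit`, the
defaults and why they were chosen, the numerical decisions, and the known
limits of what the synthetic-cohort tests demonstrate.

## Data model

A *clonotype* is the set of T cells sharing one CDR3β amino-acid sequence;
its abundance is counted in rearranged DNA templates (one template ≈ one
T cell). Rearrangement rows with identical CDR3β amino-acid sequence are
collapsed into one clonotype — nucleotide-level variants converging on the
same amino-acid sequence are merged, since all downstream analyses (unique
clones, networks, sharing) operate at the amino-acid level. Rows that are
out of frame, contain a stop, or contain any character outside the
20-letter amino-acid alphabet are marked nonproductive; they are retained
in storage but excluded from every analysis by default, so all reported
totals are productive templates. The default column dialect follows
immunoSEQ v2 rearrangement exports (`amino_acid`, `templates`,
`seq_reads`, `frame_type`, `v_resolved`, `j_resolved`) and can be
overridden per file; unknown extra columns are ignored.

## T-cell fraction and coverage

T-cell fraction = total productive templates / genomes, with genomes =
input DNA (ng) × 1000 / 6.6 pg per diploid cell. Fractions above 1 are
physically implausible and produce a warning rather than an error, since
they can arise from DNA quantification noise. Sequencing coverage is
defined as total reads / total templates per sample — the natural depth
notion for template-barcoded multiplex-PCR data — and samples below
coverage 5 (configurable) are excluded from clonality, network and overlap
analyses to avoid bias from unreliable low-frequency clones. When a
patient contributes several datasets, the fraction analysis keeps one per
patient, chosen as the replicate with the highest coverage (deterministic,
QC-aligned; ties broken by sample id).

## Hill diversity, evenness, clonality

D(q) = (Σ pᵢ^q)^(1/(1−q)) on the grid q = 0(0.2)10, with the Shannon limit
exp(−Σ pᵢ ln pᵢ) at q = 1 (any q within 1e−12 of 1 is treated as 1);
evaluation is in log space so very small frequencies at large q do not
underflow. Frequencies are template proportions of productive clonotypes —
templates, not reads, are the T-cell proxy — and no
subsampling/rarefaction is applied: the evenness normalisation
E(q) = D(q)/SR is the cross-sample comparison surface. The clonality index
is 10 − AUC(E) with the AUC computed by composite Simpson's rule on the
even q-grid (matching the numerical-integration convention of the R
tooling this analysis style comes from; a trapezoid variant would differ
only in the 4th decimal on these smooth profiles).

Degenerate limit: a strictly monoclonal repertoire (SR = 1) has E ≡ 1 and
clonality 0 — indistinguishable from a perfectly even repertoire under the
richness normalisation. The implementation warns on SR < 2 rather than
inventing a convention.

## LD=1 convergence networks

The unit-cost Levenshtein distance is implemented with the standard
two-row dynamic program. Networks connect unique CDR3β sequences at
distance exactly 1. The production edge finder avoids the quadratic
all-pairs scan: two equal-length sequences are at distance 1 iff they
share a (length, position, masked-sequence) key, and a length-L and a
length-(L−1) sequence are at distance 1 iff the shorter equals one of the
longer's deletion variants. Both constructions guarantee distance exactly
1, and the test suite proves the edge set equal to the all-pairs DP oracle
(and to `edlib`, an independent implementation) on randomized inputs.

The connectivity fraction is edges/nodes, counting isolated nodes.
Degree-0 nodes are, however, excluded from the power-law fit sample: the
discrete power law has support k ≥ 1.

### Discrete power-law goodness of fit

The degree-distribution diagnostic follows the standard recipe for
discrete power laws: maximum-likelihood α for P(k) ∝ k^−α above a cutoff
x-min, x-min chosen to minimise the Kolmogorov–Smirnov distance between
the fitted model and the empirical tail, and a semiparametric bootstrap
(synthetic samples drawn from the fitted tail model and resampled from the
data below x-min, each refitted from scratch) giving the goodness-of-fit
p-value; p > 0.1 is flagged "plausibly power law". Numerical choices: the
α search is bracketed around the closed-form continuous approximation
1 + n/Σln(x/(x-min−½)) and solved to 1e−4; the x-min scan is capped at 30
quantile-spaced unique values (applied identically to observed and
bootstrap fits, so the test statistic and its null distribution use the
same procedure); both CDFs are right-continuous step functions with jumps
at the same atoms, so the KS supremum is evaluated at observed values; the
inverse-CDF sampling table is truncated where the residual tail mass falls
below 1e−9 and cached. 1,000 bootstrap replicates give p-value resolution
0.001; 200 are adequate for screening and are the default in the
acceptance script. A fit requires at least 50 positive degrees; constant
degree vectors are rejected as degenerate. The bootstrap p-values are
conservative (they concentrate away from 0 under the fitted null), which
is the known behavior of this test, so the 0.1 plausibility threshold errs
toward keeping the null.

### Public/private stratification

Sharing level is the number of *patients* (not samples) in which a clone
is detected; public means ≥ 2 patients. Public-vs-private connectivity is
compared per repertoire on equal-size uniform subsamples (default 1,000
clones per class, the whole class when smaller — flagged), with the
subsampling RNG seeded from a master seed plus the sample id so results
are reproducible and order-independent. The comparison is clone-level
(unweighted); abundance enters only as a node attribute in network
exports. For pathology annotation, the "highest connectivity and/or
sharing" set is the union of the top decile by degree and the top decile
by sharing level (ties broken lexicographically by sequence), compared
against the top decile by template count; matching is exact sequence
identity against the human TCRβ subset of a McPAS-like CSV.

## Morisita–Horn overlap

MHI = 2Σxᵢyᵢ / [(Σxᵢ²/X² + Σyᵢ²/Y²)·X·Y] on the union clone axis,
computed for all pairs via one sparse cross-product. The index is
abundance-weighted, scale-invariant in each vector, 1 exactly for
proportional frequencies and 0 exactly for disjoint support. Pairs are
labelled by manifest metadata as between-patient, within-patient
between-lesion, or within-lesion replicate, and summarised per class.
Overlap (like clonality and networks) is computed after the coverage
exclusion by default; a flag recomputes it on all samples.

## Comparison statistics

Welch t-tests (two-sided, Welch–Satterthwaite df), means with t-based 95%
CIs, and closed-form OLS with coefficient CIs. Significance is the usual
0.05 convention with no multiplicity correction — a reporting convention
only, not enforced in code.

## Synthetic cohort: what it emulates

The generator realises a three-group cohort — 35 no-NACT, 35
short-interval, 15 long-interval patients — plus 3 technical aliquot
replicates and 4 second-lesion datasets (92 datasets from 85 patients).
Defaults, with rationale:

* **T-cell fractions**: log-normal per group with means 6.3% / 10.6% /
  6.2% and σ_log = 0.6 (matching the wide spread reported for such
  cohorts). Input DNA mass is set by inverting the fraction formula, so
  quantification recovers each sample's planted fraction exactly.
* **Clone abundances**: template counts are i.i.d. discrete power-law
  draws; the exponent is the one-dimensional evenness knob, frozen at
  4.35 (no-NACT) and 3.85 (NACT groups) from a one-off exponent→clonality
  calibration so the group mean clonality lands near 5.0 and 5.8. Counts
  are then multiplied by 5 (`template_scale`), which matches the observed
  templates-per-clone ratio of deep repertoire data (~5), leaves clonality
  untouched (scale invariance), and gives replicate resampling its
  realistic near-complete overlap.
* **Richness**: uniform 1,500–20,000 unique clones per sample — the lower
  end of the reported clone-richness range, keeping desk-scale runtimes.
* **Sequences**: CDR3β-like strings (C…F, lengths ~N(15,2) truncated to
  8–25). Private clones are globally unique random strings; public clones
  come from a planted pool of 6,800 motif clusters (a seed plus 9
  single-substitution mutants, an LD=1 star), sampled at 20% of each
  sample's clone set. With these rates ~6% of distinct cohort clones end
  up public (detected in ≥2 patients), inside the emulated <10% band, and
  the planted pool is *exactly* the set of possibly-public clones — a
  clean oracle for the sharing analysis.
* **Replicates**: aliquot replicates are multinomial template resamples of
  the parent's clone distribution at full depth (MHI ≈ 0.93); second
  lesions share half of the parent's clones with their abundances
  (intermediate MHI with wide spread, ≈ 0.5).
* **Depth**: per-sample reads-per-template is log-normal (mean 10,
  σ_log = 0.45), which puts the expected number of coverage<5 exclusions
  at ~8 of 92 datasets.

What the synthetic cohort does **not** emulate: V(D)J recombination
statistics and generation-probability biases (real repertoires show far
more sequence convergence — real connectivity fractions run ~20% against
<1% here, so absolute network densities are not comparable to real data);
nucleotide-level clonotypes; antigen-driven co-expansion of public clones
(planted public clones follow the same abundance law as private ones, so
between-patient MHI is a few 1e−3 rather than 1e−4); and cross-sample
contamination or PCR artefacts. Passing the end-to-end tests therefore
shows that the pipeline *recovers planted structure through every stage*,
not that real data will show effects of the same absolute size.

## Problem sizes and determinism

Default desk-scale runs use the full 92-dataset cohort (~1M cohort
clones); the unit-test fixture scales to 10 patients with hundreds of
clones per sample. All randomness flows from explicit seeds (a master seed
plus stable per-sample hashes), and identical configuration + seed
reproduce byte-identical outputs.
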