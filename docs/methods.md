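# Methods

This note documents the statistical procedures, conventions and design
choices implemented in `bloodmeal`, and what the synthetic-data tests do and
do not demonstrate about real surveys.

## Data model

The unit of observation is one engorged mosquito with an identified host.
Host species map to the three host groups (bird, non-human mammal, human)
through an explicit `HostTaxonomy`; unknown species raise an error rather
than defaulting, because a silent mis-grouping would bias every downstream
fraction. Records with unidentified hosts may be stored but are excluded
from all tabulations (exclusions are logged). Dates are ISO-8601; only the
month is used analytically, via the early (months 1–6) / late (7–12)
season split. Land use around a site is the dominant class among aggregated
land-cover proportions (urban = class codes 111–142, rural = 211–244,
natural = 311–423); an exact tie raises unless the caller supplies an
explicit precedence order — the CLI default order is urban > rural >
natural behind that explicit flag.

Percentages are stored at full precision; a display column rounds half-up
to one decimal, matching printed-table style (so 46.84 % prints as 46.8).

## Packaged fixtures and the survey reconstruction

The package ships the aggregate tables of a nationwide German blood-meal
survey: per-taxon host-group counts (775 specimens, 20 named species plus
4 aggregate taxa), per-host-species counts (32 species) and the early/late
split for the three dominant taxa. The specimen-level pairing of mosquito
taxon and host species was never published. `data/host_allocation.csv` is a
*synthetic reconstruction*: one feasible solution of the implied
transportation problem, chosen by hand so that it simultaneously reproduces
(i) every per-taxon host-group count, (ii) every per-taxon count of
distinct host species, (iii) every per-host-species total, and (iv) the
published host-range breadths over the 20 named species (humans 90 %, roe
deer 65 %, cattle 60 %, wild boar 50 %). `tables.reconstruct_survey()`
expands it deterministically into 775 records; sites, dates within a
period, and trap methods are synthetic plumbing constrained only by the
period table, so analyses that depend on the *site* axis (per-taxon
between-site null models) or on trap composition are illustrative rather
than reproductions.

Aggregate taxa (e.g. "Culex pipiens (s.l.)/torrentium") are kept as rows in
tabulations but excluded from "percentage of species" denominators, which
the named-species list fixes at 20.

## Chi-square and Kruskal-Wallis conventions

Rows or columns with a zero marginal total are dropped before testing and
the degrees of freedom reflect the reduced table; Yates' continuity
correction applies exactly when the reduced table is 2×2. Both conventions
are forced by the reference results: the published statistic for the taxon
with no bird feeds (0.0033981, df 1) equals the Yates-corrected value of
the reduced 2×2 table, while the df = 2 statistics equal uncorrected
Pearson values. Expected counts below 5 set a warning flag but never abort
— the published analysis itself reports a statistic for a table with an
expected bird cell below 1, and this implementation warns and proceeds.

Kruskal-Wallis uses the tie-corrected H with the chi-square approximation
regardless of sample size (groups below 5 get a warning); when every
observation is identical the tie-correction denominator vanishes and the
statistic is reported as 0 with a warning instead of an error. Pairwise
trap-method tests compare the 2×2 bird/mammal table for every pair of trap
methods; p-values are adjusted over the family of pairs by
Benjamini-Hochberg by default (Holm and Bonferroni selectable) — the
adjustment procedure is a free choice here, as only "adjusted P-values"
is specified upstream.

## C-score null model

The C-score of a binary matrix is the mean checkerboard-unit count over
unordered row pairs, (r_i − S_ij)(r_j − S_ij), with r the row totals and
S_ij the shared-column count. Matrix orientation matters (the statistic is
not symmetric): rows are host species and columns mosquito taxa for the
survey-wide analysis, or trapping sites for per-taxon analyses, following
the feeding-pattern framework this analysis descends from. All-zero rows
and columns are dropped (logged) before testing; a matrix below 2×2 is an
error, never a silent pass.

The null distribution is fixed-equiprobable: each row's total is preserved
and its presences are re-placed uniformly over all columns, rows
independent. Tail probabilities use the add-one convention,
p_low = (#{null ≤ observed} + 1)/(n + 1) and symmetrically for p_high, so
p ∈ (0, 1] and with the default n = 5000 the smallest reportable p is
≈ 0.0002. Ties between null and observed count toward both tails,
conservatively. The verdict is aggregated if p_low < 0.05, segregated if
p_high < 0.05, random otherwise. The engine is vectorized (uniform subsets
drawn via per-row order statistics, overlaps via batched matrix products)
and is fully reproducible from the mandatory seed; `exact_null_tails`
enumerates the whole outcome space for small matrices as an internal
cross-check, and the test suite additionally carries an independent
brute-force oracle.

"Mean ± Variance" in the one-line report is labelled exactly as in the
reference table it mirrors; the stored quantity is the variance of the
simulated null ensemble.

## Feeding groups

Each taxon's profile is the binary triple over host groups (any count ≥ 1
sets the bit — "normalized presence-absence"; no abundance weighting).
Jaccard dissimilarity on these triples is a metric, so UPGMA (average
linkage) heights are monotone. Ties between equally close cluster pairs
merge the lexicographically smallest pair of cluster labels (a cluster is
labelled by its smallest leaf), making the dendrogram deterministic.
Feeding groups are the zero-height clusters, i.e. the equivalence classes
of identical profiles; the implementation reports the combinations actually
present rather than forcing a fixed number of groups. On the packaged
survey that yields 5 groups among the 20 named species and 7 when
aggregate taxa are included (two aggregate-taxon profiles — birds only,
birds and humans — plus the birds-and-mammals profile of one named species
fall outside the two large groups).

## Transmission risk

Ap is a fraction in [0, 1]; percentage inputs are divided by 100 at the
boundary and both forms appear in outputs. The two channels are exact
products Ap·Fa·Fh and Ap·Fm·Fh with no vector-competence factor: the index
measures ecological contact, not physiological transmission ability, so a
high value flags a *candidate* vector only. Abundance tables that pool
sibling taxa (the Culex pipiens complex) propagate the pooled Ap unchanged
to each member, and the sharing is recorded in the output. Because the
surveillance abundance table behind the original analysis is unpublished,
Ap is a required user input; examples use the survey's own specimen shares.

## In-silico host identification

Primer search is IUPAC-aware (a degenerate code matches any base in its
set; N matches everything), scans the primer and its reverse complement on
the top strand, and reports 0-based half-open coordinates; default
tolerance is 2 mismatches per primer. Reverse primers are stored as
synthesized and reverse-complemented internally. The amplicon spans primer
footprint to primer footprint inclusive — a 200-nt insert between the
22-nt and 22-nt footprints of the primary pair gives the expected ~244 bp
product — and the shortest feasible product wins, as in PCR.

Assignment scoring is fixed: global alignment, match +1, mismatch 0,
linear gap −1; identity = identical columns / aligned columns, which for
equal-length ungapped pairs reduces to 1 − Hamming/length. The default
thresholds (identity ≥ 0.95, margin to second-best ≥ 0.02; ties are
ambiguous) were chosen to separate the ≥ 10 %-divergent synthetic panel
and are explicit parameters — the thresholds of the original
database-comparison workflow are unknown, and real reference databases
with close congeners may need stricter settings. Identification is
two-tier: only queries unassigned against the primary pair's panel fall
through to the fallback pair's panel, and the tier is recorded per call.

## Synthetic generators

The survey generator draws, per record: taxon (relative abundance), site
(site weights), month (seasonal weights), trap (trap weights), then host
from preference ⊙ availability ⊙ trap-bias, renormalized — operationalizing
the hypothesis that feeding patterns are driven by host availability at
least as much as by host choice (uniform preferences isolate pure
availability). Trap bias is a per-host-group multiplicative factor,
default 1. A taxon whose effective host distribution is all-zero at some
site/trap is a configuration error naming both. `n_per_taxon` draws a
stratified survey for parameter-recovery studies; otherwise taxa are
multinomial. Every generator is a pure function of its config including
the seed.

Scenario matrices calibrate the null model: *aggregated* plants a universal
host column plus one noise presence per row; *segregated* partitions the
columns into disjoint blocks; *random* is the fixed-equiprobable null
itself. Default geometry is 8 hosts × 6 columns with sparse rows — the
scale of a per-taxon host-by-site analysis, where most hosts appear at a
couple of sites. This choice is deliberate: on sparse small matrices the
C-score support is coarse, ties are common, and the tie-inclusive add-one
tails make the verdict conservative on truly random matrices (measured
false-positive rate ≈ 8 % over 1000 replicates at 5000 iterations, versus
the ≈ 10 % nominal two-tail bound), while a universal shared host is still
detected essentially always (measured power 100 % for both structured
kinds). Segregation requires at least as many columns as rows; the usual
segregated benchmark is 4 hosts over 8 columns.

The amplicon generator mutates panel sequences with i.i.d. substitutions
(a substitution always changes the base), rate ≤ 0.2. The synthetic
reference panel covers 12 host species (6 mammals including humans, 6
birds) whose species-specific inserts are ≥ 10 % divergent and which carry
both primer pairs' binding sites.

**What the synthetic tests do not show.** Generated surveys have clean
taxonomy, no unidentified hosts, no spatial autocorrelation, no
digestion-dependent detection failure, and independent records; the panel
has no within-species haplotype variation and divergences far above those
of congeneric cytochrome-*b* sequences. Passing calibration and recovery
tests therefore demonstrates correctness of the estimators under the
stated model, not robustness to the messiness of field data.

## Problem sizes

Default problem sizes were chosen so the whole suite runs comfortably on a
single CPU: null-model verification enumerates all 216 3×3 matrices with
row sums ≤ 2 against 20 000-iteration Monte Carlo runs; calibration uses
100 replicates × 5000 iterations per scenario kind; parameter recovery uses
1000 records per taxon; host-identification accuracy uses 240 mutated
queries and the primer-search cross-check 1000 random templates.
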