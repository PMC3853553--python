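# Methods

This note documents the models, defaults and numerical choices behind
`trnldiet`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Reference database and discrimination rates

The taxonomy is a strict three-level tree (species → genus → family) under
an implicit root; every species carries an origin flag
(native/introduced/both). The P6 insert is defined as the subsequence
strictly between the 3′ end of the forward-primer site (primer g) and the
5′ end of the reverse-primer site (primer h matched as its reverse
complement), with primers excluded: because query reads are trimmed the
same way, reference and query coordinates agree. Primer matching allows
substitutions only (no indels in primer sites); `N` never matches
anything, here or in any identity computation. Several non-overlapping
forward-site matches raise an explicit "ambiguous primer site" error
rather than guessing. Extracted inserts outside a plausible length window
(default 50–200 bp; the marker's observed range in island floras is
66–148 bp) are logged and dropped.

Haplotype groups partition references by *exact* sequence identity
(case-insensitive). The database is assumed Sanger-derived, so no
alignment-based merging is attempted. Multi-species groups are labelled
`Gr. <taxon><k>` with `<taxon>` the lowest-rank taxon containing every
member and `k` counting groups per taxon in order of first appearance.

Discrimination rates follow the distinct-haplotype reading of "unique
sequence": Rs divides distinct haplotypes by species; Rf does the same
within a family (a haplotype shared across families counts once in each);
Rg counts genera owning at least one haplotype found in no other genus.
An alternative reading of Rg (species-diagnostic sequences) exists; the
genus-exclusive reading is implemented because it is the only one under
which "genera with one or more unique sequences" is well-defined for
multi-species haplotypes. All rates round half-up to integer percent;
frequency tables round half-up to two decimals. Duplicate species ids are
a hard error, never a silent dedup.

## Read processing

MID tags must be prefix-unique; a read is routed to the unique tag
matching its prefix within `max_mid_mismatch` substitutions (default 0 —
the matching stringency of the original MID protocol is not documented,
so exact matching is the conservative default) and the tag is stripped.
Ambiguous or unmatched reads go to an explicit unassigned bin, so reads
are conserved across the demultiplexing boundary.

Pre-clustering, reads shorter than the forward primer or with > 10%
ambiguous bases are rejected (identity would be undefined), then
primer-trimmed with the same contract as reference extraction (a
pass-through mode exists for reads trimmed upstream).

Clustering is greedy centroid clustering per sample, replacing contig
assembly of the original 454 workflow: for 66–148 bp single-locus
amplicons, 98%-identity clustering is the functional equivalent and is
fully specifiable. Dereplicated sequences are scanned in decreasing-count
(then lexicographic) order; each joins the first centroid at
global-alignment identity ≥ 0.98, else founds a cluster, so the centroid
is always the most abundant member and the outcome is invariant to input
shuffles within count ties. Identity is matches / alignment columns (end
gaps count) under unit match score, mismatch −1, gap open −2, gap extend
−1 (all configurable). Two exact shortcuts keep this fast without
changing results: equal-length pairs whose ungapped identity already
clears the threshold are accepted (the ungapped alignment is itself a
global alignment), and pairs whose edit distance bounds identity below
the threshold (identity ≤ Lmin/(Lmin + ed) for any global alignment) are
rejected without a full alignment.

Filtering retains clusters with centroid ≥ 40 bp AND ≥ 4 reads — the
boundary values are kept, matching the strict reading of "less than
40 bp" / "fewer than four reads" exclusion rules — and logs a reason for
every discarded cluster.

Quality strings are read and ignored: the upstream 454 workflow did not
use them, and no quality model is assumed.

## Taxonomic assignment

Scoring is global alignment with free end gaps on the query (reference
overhang costs nothing), so a read that is a sub-fragment of a reference
aligns cleanly; identity is computed over columns excluding the free
overhang. The original workflow's BLAST e-value cutoff (< 1e−25) is
replaced by identity ≥ 0.95 over ≥ 40 aligned columns: e-values depend on
database size and Karlin–Altschul parameters that are not reproducible
here, while identity and length are, and 40 bp is already the pipeline's
length floor. Ties are exact integer score equality (unit costs make this
well-defined); tied groups are lifted to their lowest common taxon, and a
tie spanning two families is reported unassigned. Assignment targets
haplotype groups, never individual species within a group. Under unit
costs the maximal attainable score is the query length, reached exactly
by references containing the query as a substring — this gives an exact
shortcut that also collects all substring ties.

## Diet metrics

F_R uses assigned reads only as its denominator, which is what reproduces
published diet tables from their own read columns. F_P takes an explicit
denominator because different detection methods may cover different
sample subsets of one collection (e.g. 48 samples barcoded but 47
examined microscopically). Richness SD is the sample SD (n−1); the method
comparison uses Welch's unequal-variance t-test. Months are ISO
year-months, so the same calendar month of different years stays
distinct. Microhistological results enter as an externally supplied
presence table; the microscopy itself is out of scope.

## Community statistics

The Chao abundance-based Jaccard estimator is implemented from its
defining formula: with n = Σx, m = Σy and S the shared species,
U = Σ_{S} x_i/n + ((m−1)/m)·(f₊₁/(2 f₊₂))·Σ_{S, y_i=1} x_i/n (f₊₂
replaced by 1 when zero), V symmetrically, both clipped to ≤ 1;
similarity = UV/(U+V−UV). Presence/absence mode computes classic Jaccard
directly instead of pushing 0/1 vectors through the estimator: the
unseen-species correction is built on shared singletons/doubletons, which
are meaningless for binary data, and Jaccard is the standard binary
counterpart.

NMDS minimises Kruskal stress-1 by alternating the secondary (tie-mean)
isotonic regression of configuration distances on input-dissimilarity
ranks with Guttman-transform updates; 20 random starts, ≤ 200 iterations,
stopping when the stress improvement falls below 1e−6 or an update would
increase stress (updates are never accepted uphill, so the per-start
stress trace is non-increasing by construction). k = 2 by default; the
best start's configuration is returned centred at the origin, and runs
are bit-reproducible given a seed. ANOSIM rank-transforms the
dissimilarities with mean ranks for ties and uses the add-one permutation
estimator p = (1 + #{R* ≥ R}) / (1 + n_perm), which cannot return p = 0.
Pearson chi-square drops zero-margin rows/columns with a warning; both
read-count and presence pooled tables are supported because the original
table construction is not documented.

## Synthetic data

The generator's defaults are the study conditions it emulates: 222
species / 175 genera / 76 families collapsing to exactly 167 distinct
haplotypes of 66–148 bp; 2 islands × 24 samples spanning a
September–May season; per-sample depth truncated-normal 743 ± 338
(minimum 50); per-base substitution error 0.01 (a typical
pyrosequencing-era figure; an indel knob exists but defaults to 0);
island taxon pools of 20 groups with 30% island-exclusive taxa;
per-sample richness ≈ N(6.7, 2.7); Dirichlet(0.3) proportions with one
shared dominant taxon forced to ≥ 0.35 of reads, mimicking the extreme
read-share skew of real fecal amplicon data. Optional per-taxon
multiplicative efficiency bias emulates differential PCR amplification.

Haplotype collapse merges a species onto another member of its family
(within its genus with probability 0.5 when possible) until the distinct
count hits the target, so Rs is pinned by construction while Rg emerges
from the merge pattern; because most synthetic genera are monotypic, the
realized Rg (≈ 66–69%) is lower than in real island floras. A separate
constructor builds databases with an exact per-family
(species, haplotype) layout for table-level verification.

What passing tests show — and do not. Error-free reads recover simulated
read counts exactly, 1%-error reads are ≥ 95% correctly assigned, and
presence-based ANOSIM detects the built-in island contrast at the study's
sample sizes. The generator has no chimeras, no homopolymer or
length-dependent errors, no contamination, and uniformly random reference
sequences (real P6 haplotypes are phylogenetically autocorrelated, which
makes real discrimination harder at a given haplotype count); passing
these tests therefore validates the pipeline's bookkeeping and statistics,
not the field error profile of any particular sequencing platform. In
simulated data the count-based (Chao) island contrast is usually also
significant, slightly weaker than the presence-based one; the real-data
phenomenon of a count-based test losing significance under extreme
single-taxon dominance is reproduced only qualitatively (presence R ≥
count R), not forced.

## Problem sizes

Tests run the full pipeline once at the default study shape (48 samples,
~35k reads) and use 2–6-sample studies at depths 100–1500 for
stage-level checks; the acceptance script builds the 222-species database
once. These sizes were chosen as the smallest that exercise every code
path at the study's own parameter values.

## Known limitations

- Exact-identity reference grouping cannot absorb Sanger sequencing
  errors in the reference set itself.
- Greedy clustering is order-dependent by design (the deterministic
  abundance order); it is not a global optimum partition.
- The NMDS stress surface is multimodal; 20 starts is a heuristic, and
  stress values for binary Jaccard matrices of ~50 samples are typically
  ≈ 0.3, which is normal for such data but far from "good" by Kruskal's
  benchmarks.
- e-value-based hit filtering is deliberately not implemented; users
  porting thresholds from BLAST workflows must translate them into
  identity/length terms.
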