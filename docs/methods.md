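# Methods

## Selection model

For one individual, let `a` be the read count of a CDR3β amino-acid
sequence in the activated compartment (total `A`) and `r` its count in
the resting compartment (total `R`). The selection statistic is the G
test of independence on the 2×2 table (this clone vs all other reads) ×
(activated vs resting): `G = 2 Σ Oᵢ ln(Oᵢ/Eᵢ)` with expected counts from
the marginals. Cells with `Oᵢ = 0` contribute 0; no continuity or
Williams correction is applied, so results are reproducible bit for bit
against the plain likelihood-ratio definition (the unit tests verify
equality with a direct multinomial likelihood-ratio evaluation and with
scipy's log-likelihood chi-square to < 1e-9). p values come from the
χ²(1) upper tail; a clone with `a = 0` is outside the tested universe and
raises an error rather than returning a value.

The tested universe is every unique amino-acid sequence in the activated
compartment (nucleotide-level testing is available via
`SelectionConfig(level="nt")`). Benjamini–Hochberg adjustment is applied
per individual over exactly that universe. Three filters define a
ps-CDR3: q < `alpha` (default 0.05), activated count ≥ `min_count`
(default 2, removing singletons), and activated proportion strictly
greater than resting proportion. Counts are used as exported by the
sequencer — no depth normalization — because the statistic models raw
read counts.

Ties are broken deterministically: output is sorted by (q, −G, sequence).

## Distances

Minimum Hamming distance is defined only against equal-length partners; a
sequence with no equal-length partner has an undefined Hamming minimum
and is excluded from the histogram denominator (the only self-consistent
way to report percentages). Levenshtein distances use edlib's banded
alignment with an adaptive cutoff; length differences lower-bound the
edit distance, which prunes most pairs. Profiles accept pooled
multi-individual lists with repetition — a sequence contributed by two
individuals has minimum distance 0, which is what produces the
distance-0 bins of a pooled analysis. Baselines draw, per resample and
without replacement, per-individual strata matching each individual's
ps-CDR3 count from the activated or resting unique-sequence pools
(unstratified pooled sampling is a flag); the median percentage per
distance over 100 resamples is the reference, and observed vs baseline
counts at or below the cutoff (Hamming 2, Levenshtein 1) enter a
two-sided Fisher exact test.

## Diversity

Hill number of order q, with the q → 1 limit taken analytically
(exponential Shannon). The pooled-sample weighting `W_j` is exposed but
defaults to the single-sample case. Curves are estimated by uniform
resampling: `n_boot` (default 200) multinomial draws of `resample_size`
reads from the count distribution; the point estimate is the bootstrap
mean, the band the 2.5/97.5 percentiles. The resample size convention is
the common minimum of total reads across the sets being compared (the
rule is not dictated by the resampling idea itself, so it is fixed here
and logged). Two curves built with the same `n_boot`/`resample_size` are
compared per q through the paired bootstrap delta:
`p = 2·min(P(δ≤0), P(δ≥0))`, floored at `1/n_boot`, capped at 1 — so
`n_boot = 200` resolves p ≥ 0.005. Cohort-level fold-change contrasts use
the Wilcoxon matched-pairs signed-rank test over individuals, restricted
to individuals with more than 30 ps-CDR3s (configurable).

## Publicity, convergence, insertions

Publicity is the number of distinct individuals whose selections contain
the amino-acid sequence (set semantics; public ⇔ ≥ 2). Convergence
counts unique nucleotide variants pooled across all individuals'
selections; variants are keyed by nucleotide sequence alone by default
(adding the V call to the key is a flag, relevant when vendors trim
differently). Insertion contrasts use one record per unique nucleotide
variant — insertions are properties of rearrangements, not of amino-acid
sequences — with two-sided Mann–Whitney U tests for total, V-D and D-J
insertions. Encoding-probability matrices tabulate, per amino-acid
position, the empirical codon frequencies (and V-gene frequencies)
across a sequence's variants; rows normalize to 1 exactly, and variants
whose nucleotide length is not 3× the amino-acid length are skipped with
a warning.

## Motifs

Sequences are trimmed by dropping the first two residues (the conserved
cysteine and its neighbor) and the last residue (the conserved
phenylalanine), leaving the central antigen-contact region; the offsets
are configurable because CDR3 reporting conventions differ. Patterns are
all continuous 3/4/5-mers plus 4-mers with one internal wildcard and
5-mers with one or two internal wildcards — wildcards never sit on a
pattern edge (an edge gap would alias a shorter motif), and every
pattern keeps ≥ 3 conserved residues. 5-mers with a single wildcard are
included by default (four conserved residues still satisfies the
≥ 3-conserved rule) and excludable by flag. A read "contains" a pattern
if it matches the trimmed sequence at any offset, counted once per read.
Enrichment is read-weighted — (ps reads with pattern / total ps reads) ÷
(resting reads with pattern / total resting reads) — so scaling all
counts leaves folds unchanged; patterns absent from resting get fold
+∞. Dominance: fold ≥ 10, ≥ 3 unique ps-CDR3s, ≥ 3 individuals.

## Network

Nodes are unique ps-CDR3 amino-acid sequences. Pair edges join sequences
at Levenshtein distance 1 (equal length + Hamming 1, or length ± 1 with
a deletion match — found by length-bucketed hashing, verified against an
all-pairs oracle in the tests) or sharing a dominant motif; a pair
satisfying both carries type `both` and counts once. Each additional
nucleotide variant contributes one self-edge, and a node's degree counts
pair edges plus self-edges once each (a self-edge represents one extra
rearrangement, not the graph-theoretic 2). Nodes whose only edge is a
self-edge count as "in the graph" (excludable by flag). Edge baselines
resample equal-sized sets from the activated or resting pools and count
edges the same way; by default dominant motifs are re-derived within
each resample against the resting reference (`motif_mode="recompute"`,
symmetric with the ps analysis; `"fixed"` reuses the ps-derived motifs),
and the observed total is compared by a two-sided Z test (undefined when
the baseline standard deviation is 0, reported as such). GML export
materializes self-edges as loop edges; import restores the object
losslessly.

## Subset probing

Bulk Th-subset repertoires are probed for autologous ps-CDR3s by exact
amino-acid match; fractions are read-weighted. Clonal expansion is a
logistic regression of per-sequence ps membership on read count (raw by
default, log1p by flag), pooled per subset; complete or quasi-complete
separation is flagged in the result rather than silently reported.
Jaccard matrices are computed overall and restricted to public or
private sequences; cells whose union is empty are undefined (NaN).

## Simulator

Each individual's resting compartment is a multinomial draw over a
discrete power-law (Zipf) background — heavy tails are what give the
count and proportion filters something to do — and the activated
compartment is a draw over the same background with the spiked clones'
proportions multiplied by the enrichment factor and renormalized.
Renormalization means non-spiked clones are slightly depleted in the
activated compartment, so abundant bystanders can reach significance in
the depletion direction and are removed by the proportion filter — the
same structure the selection procedure assumes in real data. Defaults
are the benchmark study conditions: 27 individuals, 2000 clones,
exponent 1.5, 100 spiked clones at 10-fold, 10⁵ reads per compartment.
Public spiked clones come from a cohort-shared pool (10 clones, each
included per individual with probability 0.3), carry 3 codon-degenerate
nucleotide variants (Dirichlet-split within a clone), Poisson insertions
with mean 1.5 per junction against 3.5 for private clones (matching
median total insertions of ~3 vs ~7), and a planted amino-acid motif.
Amino-acid stems exclude cysteine so trimming anchors stay unambiguous;
nucleotide sequences are exact codon-degenerate reverse translations, so
translation consistency holds by construction. All randomness flows from
one seed through spawned streams (stream 0: public pool; stream 1+i:
individual i), making `simulate_individual` independently reproducible
and byte-identical across reruns.

Ground truth records, per spiked clone, its analytic expected activated
count `depth · p·f/Z` and whether it was actually emitted; truth sets
are therefore always subsets of observed sequences.

### What the simulator does not emulate

No VDJ recombination model (gene-segment usage, junctional trimming or
realistic insertion sequences), no PCR/sequencing error, no shared
low-level sequence similarity between unrelated clones beyond chance.
Passing tests show the statistical machinery behaves as intended under
the assumed abundance structure; they do not certify performance on real
repertoires, where clone-abundance laws, repertoire sizes and bystander
structure differ.

### Abundance-law choice for qualitative contrasts

With exponent 1.5 over 2000 clones, the single top background clone
carries ~36–39% of the reads of *both* compartments (inverse Simpson
≈ 6). That concentration is far beyond real memory repertoires (top
clones of a few percent) and inverts the expected diversity contrast at
orders q ≥ 1: the selected pool, spread over ~50 enriched clones, is
then *more* even than its source. The exponent-1.5 default is retained
for the selection/FDR benchmarks, where the heavy tail is the point; the
qualitative direction checks (selected pool less diverse than activated
and resting at orders 0–2) use exponent 1.0 (top clone ~14%, inverse
Simpson ≈ 30), which restores repertoire-like evenness. This is a
deliberate design choice documented here, not a tuning of the benchmark
conditions.

## Benchmarks and known limits

The acceptance benchmark reports the mean realized false-discovery
proportion of the full selection procedure over 50 study-scale cohorts;
it sits near 0.01, comfortably below the q < 0.05 target — the BH
adjustment plus the count and proportion filters are conservative in
combination.

Spike-in sensitivity is monotone in enrichment factor and depth, but at
10-fold enrichment it is ~0.65 among spiked clones with expected
activated count ≥ 5 (≈ 0.87 at ≥ 10, ≈ 0.97 at ≥ 20). This is a
property of the statistics, not of the implementation: with ~1400 tests
and ~60 discoveries per individual, the effective BH threshold is
p ≈ 0.002, while a clone with expected activated count 5 against a
resting expectation of 0.5 reaches p < 0.002 only ~15% of the time
(exact Poisson enumeration). Detecting marginal clones at such depths
requires either more reads or a less stringent error target.

Problem sizes used in the test suite (6–8 individual cohorts of 300–800
clones at 2–4 × 10⁴ reads for characterization stages; full 27 × 2000 ×
10⁵ cohorts for the selection benchmarks) were chosen so each check
exercises the regime it is about while the whole suite stays quick.
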