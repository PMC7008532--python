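# Methods

## Problem

Input is a k × n haplotype matrix over a constant-size alphabet of small
integers — for phased biallelic SNP data, k = 2 × samples rows of {0, 1}
with 0 the REF/ancestral and 1 the ALT/derived allele. The target objects
are all maximal perfect haplotype blocks (K, i, j): row sets |K| ≥ 2
identical on the column range [i, j] and maximal in all three directions
(left, right, rows). Block size is (j − i + 1)·|K|. Nothing in the method
requires a binary alphabet; all routes accept any digits 0–9.

## Production path: streamed positional BWT

For each column l the state is the colexicographic permutation a_l of row
prefixes and the divergence array d_l (d_l[1] = l + 1; otherwise one plus
the last column where the prefix of a_l[r] mismatches that of a_l[r−1]).
The state is advanced in O(k·|Σ|) per column by a stable bucket pass, one
bucket per symbol, with a per-symbol running maximum of divergence values
initialised to l + 2: this generalises the classical binary two-bucket
update to any constant-size alphabet and reduces to it when |Σ| = 2.

**Duplicate rows.** The textbook presentation assumes distinct rows. We
define the divergence of two identical prefixes via max ∅ := 0, giving
d = 1. No other change is needed: a set of fully identical rows then
surfaces as the block (K, 1, n), and all exhaustive tests include
duplicated rows.

**Candidates per column.** A candidate ("available") block ending at j is
a colex range [x, y] with d_j ≤ i inside (x, y], the value i attained, and
strictly larger divergence just outside. These are exactly the LCP
intervals of LCP_j[r] = j − d_j[r] + 1 with positive value; the stack
algorithm emits each interval once, at its rightmost end, with i recovered
from the interval depth (i = j − v + 1). At most k − 1 intervals exist per
column (branching trie nodes). One boundary subtlety is worth stating:
the LCP entry at sorted position r compares entries r − 1 and r, so an
interval freshly opened at r extends back to r − 1.

**Right-maximality.** A candidate at column j < n is a real block iff its
rows do not all agree at column j + 1. A bit vector over the colex order
(1 where adjacent sorted rows disagree at j + 1) is prefix-summed once per
column, making each test an O(1) subtraction; at j = n the condition holds
trivially. The finder therefore looks one column ahead: state for column j
is enumerated when column j + 1 arrives, and the last column is flushed
after the stream ends. Only two adjacent columns of state exist at a time.

**Reporting.** Blocks stream out grouped by end column j ascending, then
by colex start x — a deterministic order. `expand_rows=True` materialises
K from the live a_j (O(output) extra); `False` keeps the compact
(i, j; x, y) form and O(k) working memory. Reported coordinates are
1-based inclusive everywhere; the single conversion from internal 0-based
arrays happens at block construction.

## Cross-check path: decorated-string maximal repeats

Each row is interleaved with shared per-column index characters α_0…α_n
and terminated by a row-unique separator; the concatenation's maximal
repeats that start and end with an index character and span ℓ ≥ 1 sites
are in bijection with the blocks ((K, p+1, p+ℓ) for a repeat starting at
α_p, with |K| = occurrence count). The index characters force occurrences
to align by column; unique separators stop repeats crossing rows. Integer
encoding: alphabet ranks in [0, |Σ|), α_p = |Σ| + p, separators above
those. Maximal repeats come from a suffix array (prefix doubling, O(m log
m)) with Kasai LCP: every positive-depth LCP interval is right-maximal by
construction and is kept iff left-diverse. This route holds the whole
O(kn) string in memory and exists for cross-validation, not speed.

## Ground truth

A brute-force enumeration of the definition: for every column pair (i, j)
partition rows by their [i, j] substring; maximal equality classes of
size ≥ 2 make row-maximality structural, leaving only the two boundary
checks. O(n²·kn̄) time, used on small inputs only; the CLI refuses it
above k·n = 10⁶.

## Synthetic data

Two seeded generators (one `numpy` generator per matrix; the seed is kept
in the matrix metadata):

* **uniform** — i.i.d. symbols; a noise floor with only small chance
  blocks.
* **founder-copy** — f founder haplotypes drawn uniformly; each row copies
  one founder, re-drawing the founder with probability ρ per site and
  flipping the copied symbol with probability μ per site. Low μ, ρ create
  the long shared segments (large, size-filterable blocks) that selection
  scans target. Defaults model a small resequencing panel: k = 50,
  n = 200, f = 5, μ = ρ = 0.01 per site — at these settings the mean block
  size is roughly an order of magnitude above the uniform panel's.

The founder-copy model is deliberately not a coalescent simulation: no
genealogy, recombination map or allele-frequency spectrum. Passing tests
on it show the finder's combinatorics are exact on structured input, not
that any population-genetic quantity is well calibrated; exactness on real
data follows from the definition-level equivalence, not from the
generator's realism.

## VCF ingestion

Only biallelic SNP records (single-base REF, exactly one single-base ALT)
become columns; others are dropped and counted. Sites with a missing
allele are dropped whole by default (a block has no missing-data
semantics) or can raise. Heterozygous unphased genotypes raise unless
explicitly allowed, since their haplotype assignment is arbitrary;
homozygous genotypes are accepted with either separator because their
phase is immaterial. Samples contribute rows in header order, haplotype 1
before haplotype 2, fixing row indices deterministically.

## Validation strategy and problem sizes

* Exhaustive: every binary matrix of shapes (2,3), (2,4), (3,3), (3,4),
  (4,3) — 9024 matrices — through all three routes, compared as sets.
* Randomised: 500 seeded matrices, k ≤ 12, n ≤ 40, alphabet sizes 2–4,
  duplicate rows injected in ~30% of draws.
* pBWT arrays are checked column by column against an independent
  from-scratch colexicographic sort with the mismatch-formula divergence.
* The block count is asserted ≤ (k−1)·n on every tested input.
* Linearity is checked as a trend: best-of-several timing at k = 100 for
  n ∈ {1000, 2000, 4000}; the doubling ratio lands near 2 and the test
  only rejects ratios approaching quadratic behaviour. These sizes keep
  the whole validation suite in the tens of seconds while being large
  enough that a quadratic implementation would fail clearly.

## Known limitations

* The quadratic oracle and the repeat route materialise the whole matrix;
  only the pBWT route streams.
* No downstream selection-coefficient likelihood is computed; the output
  is the block table that such a scan would consume.
* Multi-chromosome VCFs are treated as one concatenated column stream;
  split by chromosome upstream if cross-chromosome blocks are unwanted.
* The per-column bucket pass is pure Python/numpy; it is linear but not
  tuned for million-site chromosomes.
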