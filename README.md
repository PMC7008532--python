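# hapblocks

Linear-time detection of **maximal perfect haplotype blocks** in phased
haplotype data.

Haplotype-based selection scans look for genomic regions where many
haplotypes are unusually similar — the footprint of a recent selective
sweep. The combinatorial core of such scans is the *maximal perfect
haplotype block*: given a k × n haplotype matrix S (k haplotypes, n
variant sites), a block is a triple (K, i, j) with |K| ≥ 2 and
1 ≤ i ≤ j ≤ n such that

* all rows in K are identical on columns [i, j] (*equality*),
* i = 1 or some pair in K disagrees at column i−1 (*left-maximality*),
* j = n or some pair in K disagrees at column j+1 (*right-maximality*),
* no proper superset of K satisfies equality on [i, j] (*row-maximality*).

Its **size** is (j − i + 1)·|K|, the usual filtering criterion. There are
O(kn) such blocks, and `hapblocks` finds all of them in O(kn) time.

## How it works

The production path streams the matrix column by column while maintaining
the **positional Burrows–Wheeler Transform**: for each column l, the
colexicographic order a_l of the row prefixes and the divergence array
d_l, with d_l[1] = l+1 and d_l[r] = 1 + max{ j ≤ l : S[a_l[r]][j] ≠
S[a_l[r−1]][j] }. Candidate blocks ending at column j are exactly the LCP
intervals of LCP_j[r] = j − d_j[r] + 1 with positive value (each interval
[x, y] at depth v gives the candidate (i, j; x, y) with i = j − v + 1),
enumerated in O(k) per column by a stack pass; right-maximality is a
single O(1) prefix-sum lookup over the next column. Only two adjacent
columns of state are held, so compact reporting runs in O(k) memory.

Two independent routes validate the result: a decorated-string reduction
to maximal-repeat detection on a suffix array (rows interleaved with
per-column index characters, so repeat occurrences align by column), and
a brute-force enumeration of the definition itself.

## Worked example

```python
from hapblocks import HaplotypeMatrix, find_blocks

matrix = HaplotypeMatrix.from_strings(["010", "011", "110"])
for b in find_blocks(matrix):
    print(sorted(b.rows), b.i, b.j, b.size)
```

prints

```
[1, 2] 1 2 4
[1, 2, 3] 2 2 3
[1, 3] 2 3 4
```

— rows 1 and 2 share `01` on columns 1–2, all three rows share `1` on
column 2, and rows 1 and 3 share `10` on columns 2–3; none of these can
be grown in any direction. With `min_size=4` the single-column block
(size 3) is filtered out and 2 blocks remain. The same set is returned
by `blocks_from_repeats` (suffix-array route) and `brute_force_blocks`
(definition route); see `examples/` for this script, a VCF-to-blocks
pipeline and a synthetic-panel demonstration.

## Command line

```
hapblocks findblocks panel.vcf --min-size 1000 -o blocks.tsv
hapblocks vcf2bm panel.vcf -o matrix.txt
hapblocks synth --model founder-copy --k 50 --n 200 --seed 7 -o synth.txt
```

`findblocks` accepts phased VCF (biallelic SNPs become binary columns,
each diploid sample contributes two rows) or the package's plain-text
matrix dialects, and writes a TSV of `start  end  n_rows  size` (plus row
labels with `--expand-rows`). VCF input is streamed one record at a time.

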