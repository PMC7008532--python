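"""VCF to blocks: the preprocessing a selection scan starts from.

Writes a tiny phased 2-sample VCF, streams its biallelic SNP records as
binary columns (REF -> 0, ALT -> 1; each diploid sample contributes two
haplotype rows) and reports the maximal perfect haplotype blocks. The
multiallelic record is dropped by the biallelic-SNP filter.
"""

import tempfile
from pathlib import Path

from hapblocks import find_blocks, read_vcf, write_blocks

VCF = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample1\tsample2
1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t0|1\t1|0
1\t200\t.\tG\tT\t.\tPASS\t.\tGT\t0|0\t1|1
1\t300\t.\tT\tA\t.\tPASS\t.\tGT\t1|1\t0|1
1\t400\t.\tC\tA,T\t.\tPASS\t.\tGT\t0|1\t0|2
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "panel.vcf"
    path.write_text(VCF)
    matrix = read_vcf(str(path))

print(f"retained {matrix.n} biallelic SNP columns for {matrix.k} haplotypes "
      f"(dropped {matrix.meta['dropped_non_snp']} non-biallelic record)")
for rid, r in zip(matrix.row_ids, range(1, matrix.k + 1)):
    print(f"  {rid}: {matrix.row_string(r)}")

print("\nblock table (start/end are 1-based SNP columns):")
import sys
write_blocks(find_blocks(matrix), sys.stdout, expand_rows=True, row_ids=matrix.row_ids)
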