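"""Reading and writing haplotype matrices and block tables.

Two plain-text matrix dialects are defined (this package's own fixture
convention):

* ``row-major``    -- one haplotype per line, single-digit symbols;
* ``column-major`` -- one variant site per line (a length-k string),
  suited to column streaming.

Lines starting with ``#`` are comments in both dialects. Both represent
the same abstract matrix and round-trip exactly.

VCF ingestion follows the usual haplotype-matrix preprocessing: only
biallelic SNP records (single-base REF, exactly one single-base ALT)
become columns, REF -> 0 and ALT -> 1, and each diploid sample contributes
two rows (haplotype 1 then haplotype 2, samples in header order). Records
failing the biallelic-SNP test are skipped silently with a logged count.
Sites with a missing allele are dropped whole (``skip-site``, the default)
or raise (``error``): a block has no semantics for missing symbols.
Heterozygous unphased genotypes are an error unless ``allow_unphased`` is
set; homozygous genotypes are accepted with either separator since their
phase is immaterial.
"""

from __future__ import annotations

import logging
from typing import Iterable, Iterator, Optional, Sequence, TextIO, Union

import numpy as np

from .blocks import PerfectBlock
from .matrix import ColumnStream, HaplotypeMatrix

logger = logging.getLogger("hapblocks")

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_vcf",
    "stream_vcf",
    "VcfColumnStream",
    "write_blocks",
    "DIALECTS",
]

DIALECTS = ("row-major", "column-major")
_DIGITS = set("0123456789")


def _parse_lines(path: str) -> list[str]:
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            bad = set(line) - _DIGITS
            if bad:
                raise ValueError(
                    f"{path}:{lineno}: symbol(s) {sorted(bad)} outside the digit alphabet 0-9"
                )
            rows.append((lineno, line))
    if rows:
        width = len(rows[0][1])
        for lineno, line in rows:
            if len(line) != width:
                raise ValueError(
                    f"{path}:{lineno}: ragged line of length {len(line)}, expected {width}"
                )
    return [line for _, line in rows]


def read_matrix(
    path: str,
    dialect: str = "row-major",
    alphabet: Optional[Sequence[int]] = None,
) -> HaplotypeMatrix:
    """Read a plain-text haplotype matrix in either dialect."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    lines = _parse_lines(path)
    grid = np.asarray([[int(c) for c in line] for line in lines], dtype=np.int16)
    if grid.size == 0:
        grid = grid.reshape(0, 0)
    if dialect == "column-major":
        grid = grid.T
    return HaplotypeMatrix(grid, alphabet=alphabet)


def write_matrix(matrix: HaplotypeMatrix, path: str, dialect: str = "row-major") -> None:
    """Write a matrix in the given dialect (symbols must be single digits)."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    if matrix.alphabet and (min(matrix.alphabet) < 0 or max(matrix.alphabet) > 9):
        raise ValueError("plain-text dialects require symbols in 0-9")
    grid = matrix.data if dialect == "row-major" else matrix.data.T
    with open(path, "w") as fh:
        for line in grid:
            fh.write("".join(str(int(s)) for s in line) + "\n")


# -- VCF ingestion -------------------------------------------------------


class VcfColumnStream(ColumnStream):
    """Streams one binary column per retained biallelic SNP record.

    ``row_ids`` are known from the header ("<sample>.hap1"/".hap2");
    ``site_ids`` ("chrom:pos") and the drop counters accumulate as the
    stream is consumed.
    """

    def __init__(self, path: str, allow_unphased: bool = False, missing_policy: str = "skip-site"):
        import cyvcf2

        if missing_policy not in ("skip-site", "error"):
            raise ValueError(f"missing_policy must be 'skip-site' or 'error', got {missing_policy!r}")
        self._vcf = cyvcf2.VCF(path)
        samples = list(self._vcf.samples)
        if not samples:
            raise ValueError(f"{path}: VCF has no samples")
        row_ids = [f"{s}.hap{h}" for s in samples for h in (1, 2)]
        super().__init__(k=2 * len(samples), columns=(), alphabet=(0, 1), row_ids=row_ids)
        self.path = path
        self.allow_unphased = allow_unphased
        self.missing_policy = missing_policy
        self.site_ids: list[str] = []
        self.n_retained = 0
        self.n_dropped_non_snp = 0
        self.n_dropped_missing = 0

    @staticmethod
    def _is_biallelic_snp(variant) -> bool:
        ref, alts = variant.REF, variant.ALT
        if len(alts) != 1:
            return False
        alt = alts[0]
        return (
            len(ref) == 1 and ref in "ACGTacgt" and len(alt) == 1 and alt in "ACGTacgt"
        )

    def __iter__(self) -> Iterator[np.ndarray]:
        for variant in self._vcf:
            if not self._is_biallelic_snp(variant):
                self.n_dropped_non_snp += 1
                continue
            col = np.empty(self.k, dtype=np.int16)
            missing = False
            for s, gt in enumerate(variant.genotypes):
                *alleles, phased = gt
                if len(alleles) != 2:
                    raise ValueError(
                        f"{self.path}: non-diploid genotype for sample "
                        f"{self._vcf.samples[s]} at {variant.CHROM}:{variant.POS}"
                    )
                if alleles[0] < 0 or alleles[1] < 0:
                    missing = True
                    continue
                if not phased and alleles[0] != alleles[1] and not self.allow_unphased:
                    raise ValueError(
                        f"{self.path}: unphased heterozygous genotype at "
                        f"{variant.CHROM}:{variant.POS} (sample {self._vcf.samples[s]}); "
                        "pass allow_unphased to accept"
                    )
                col[2 * s] = alleles[0]
                col[2 * s + 1] = alleles[1]
            if missing:
                if self.missing_policy == "error":
                    raise ValueError(
                        f"{self.path}: missing allele at {variant.CHROM}:{variant.POS}"
                    )
                self.n_dropped_missing += 1
                continue
            self.site_ids.append(f"{variant.CHROM}:{variant.POS}")
            self.n_retained += 1
            yield col
        self.n = self.n_retained
        if self.n_dropped_non_snp or self.n_dropped_missing:
            logger.info(
                "%s: dropped %d non-biallelic-SNP and %d missing-data record(s)",
                self.path,
                self.n_dropped_non_snp,
                self.n_dropped_missing,
            )


def stream_vcf(
    path: str, allow_unphased: bool = False, missing_policy: str = "skip-site"
) -> VcfColumnStream:
    """Open a VCF as a column stream (one retained record = one column)."""
    return VcfColumnStream(path, allow_unphased=allow_unphased, missing_policy=missing_policy)


def read_vcf(
    path: str, allow_unphased: bool = False, missing_policy: str = "skip-site"
) -> HaplotypeMatrix:
    """Materialise a VCF into a binary haplotype matrix (k = 2 x samples)."""
    stream = stream_vcf(path, allow_unphased=allow_unphased, missing_policy=missing_policy)
    cols = list(stream)
    data = (
        np.stack(cols, axis=1)
        if cols
        else np.empty((stream.k, 0), dtype=np.int16)
    )
    return HaplotypeMatrix(
        data,
        alphabet=(0, 1),
        row_ids=stream.row_ids,
        site_ids=stream.site_ids,
        meta={
            "source": path,
            "dropped_non_snp": stream.n_dropped_non_snp,
            "dropped_missing": stream.n_dropped_missing,
        },
    )


# -- block table output --------------------------------------------------


def _first_row(block: PerfectBlock) -> int:
    if block.rows is not None:
        return min(block.rows)
    return block.x if block.x is not None else 0


def write_blocks(
    blocks: Iterable[PerfectBlock],
    out: Union[str, TextIO],
    expand_rows: bool = False,
    row_ids: Optional[Sequence[str]] = None,
) -> None:
    """Write blocks as a TSV with header; deterministic (j, i, first-row) order.

    Columns: start and end (1-based inclusive), n_rows (|K|), size
    ((j-i+1)*|K|) and, when ``expand_rows``, the comma-separated row labels
    (``row_ids`` or the 1-based indices themselves).
    """
    ordered = sorted(blocks, key=lambda b: (b.j, b.i, _first_row(b)))
    close = False
    if isinstance(out, str):
        out = open(out, "w")
        close = True
    try:
        header = "start\tend\tn_rows\tsize"
        if expand_rows:
            header += "\trows"
        out.write(header + "\n")
        for b in ordered:
            line = f"{b.i}\t{b.j}\t{b.n_rows}\t{b.size}"
            if expand_rows:
                if b.rows is None:
                    raise ValueError("expand_rows requested but block carries no row set")
                labels = (
                    [row_ids[r - 1] for r in sorted(b.rows)]
                    if row_ids is not None
                    else [str(r) for r in sorted(b.rows)]
                )
                line += "\t" + ",".join(labels)
            out.write(line + "\n")
    finally:
        if close:
            out.close()
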