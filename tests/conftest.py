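"""Shared fixtures and the independent brute-force binomial oracle.

The oracle computes binomial masses and tails in exact rational
arithmetic (``fractions.Fraction`` over ``math.comb``), entirely
independently of the package's log-gamma / incomplete-beta route, and is
the reference every tail computation is checked against.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import pytest


def oracle_pmf(k: int, n: int, p: float | Fraction) -> Fraction:
    """Exact P(X = k) as a rational number (p taken at its exact
    binary-float value, so both routes see the same parameter)."""
    pf = Fraction(p)
    return comb(n, k) * pf**k * (1 - pf) ** (n - k)


def oracle_cdf(k: int, n: int, p: float | Fraction) -> Fraction:
    """Exact P(X <= k) by term-by-term summation."""
    return sum(oracle_pmf(j, n, p) for j in range(0, k + 1))


def oracle_sf(k: int, n: int, p: float | Fraction) -> Fraction:
    """Exact P(X >= k) by term-by-term summation."""
    return sum(oracle_pmf(j, n, p) for j in range(k, n + 1))


def oracle_min_k(n: int, error: float, alpha: float) -> int:
    """Smallest k with P(X >= k | n, error) <= alpha, by linear scan."""
    af = Fraction(alpha)
    for k in range(0, n + 2):
        if oracle_sf(k, n, error) <= af:
            return k
    raise AssertionError("unreachable: tail at k=n+1 is zero")


@pytest.fixture
def depth_tsv(tmp_path):
    """samtools-depth style table: 10 positions, half at 2000x."""
    rows = [("chr17", 7579470 + i, 2000 if i < 5 else 1000) for i in range(10)]
    path = tmp_path / "depth.tsv"
    path.write_text("".join(f"{c}\t{p}\t{d}\n" for c, p, d in rows))
    return path


VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr17,length=83257441>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample1
"""


@pytest.fixture
def variants_vcf(tmp_path):
    """Small VCF: a biallelic record with AD and a multiallelic one."""
    body = (
        "chr17\t7579472\t.\tG\tA\t.\tPASS\t.\tGT:AD:DP\t0/1:95,5:100\n"
        "chr17\t7578406\t.\tC\tT,G\t.\tPASS\t.\tGT:AD:DP\t0/1:90,6,4:100\n"
    )
    path = tmp_path / "variants.vcf"
    path.write_text(VCF_HEADER + body)
    return path


@pytest.fixture
def variants_tsv(tmp_path):
    path = tmp_path / "variants.tsv"
    path.write_text(
        "chrom\tpos\tref\talt\tdepth\tvariant_reads\n"
        "chr17\t7578406\tC\tT\t5000\t160\n"
        "chr17\t7579472\tG\tA\t100\t0\n"
    )
    return path
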