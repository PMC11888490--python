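"""Shared fixtures and in-memory record builders for the test suite."""

from __future__ import annotations

import textwrap
from pathlib import Path

import pytest

from denovoduo import GenotypeCall, VariantRecord

VCF_HEADER = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1,length=100000000>
    ##contig=<ID=chr2,length=100000000>
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
    ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
    ##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">
    """
)


def write_vcf_text(path: Path, body_lines: list[str], samples: list[str]) -> Path:
    """Write a small VCF from tab-joined body lines (CHROM..sample columns)."""
    header = VCF_HEADER + "#" + "\t".join(
        ["CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT", *samples]
    ) + "\n"
    path.write_text(header + "".join(line + "\n" for line in body_lines))
    return path


def mk_call(gt: str = "0|1", gq: int | None = 50, dp: int | None = 30,
            ps: int | None = 1) -> GenotypeCall:
    """Build a GenotypeCall from a GT string like '0|1', '0/0' or '.'."""
    if gt == ".":
        return GenotypeCall(None, None, False, gq=gq, dp=dp, ps=None)
    phased = "|" in gt
    sep = "|" if phased else "/"
    parts = gt.split(sep)
    a = None if parts[0] == "." else int(parts[0])
    b = None if len(parts) < 2 or parts[1] == "." else int(parts[1])
    return GenotypeCall(a, b, phased, gq=gq, dp=dp, ps=ps if phased else None)


def mk_rec(pos: int, pro: GenotypeCall, par: GenotypeCall, chrom: str = "chr1",
           ref: str = "A", alt="G", extra_samples: dict | None = None) -> VariantRecord:
    """Two-sample (proband 'P', parent 'F') record; ``alt`` may be a tuple."""
    alts = (alt,) if isinstance(alt, str) else tuple(alt)
    calls = {"P": pro, "F": par}
    if extra_samples:
        calls.update(extra_samples)
    return VariantRecord(chrom=chrom, pos=pos, ref_allele=ref, alt_alleles=alts,
                         calls=calls)


@pytest.fixture(scope="session")
def tiny_family(tmp_path_factory):
    """Small noise-free family shared by unit tests (fast to classify)."""
    from denovoduo import SimulationParams, simulate_family

    params = SimulationParams(
        seed=17, n_sites=8_000, region_length=800_000,
        n_de_novo_paternal=4, n_de_novo_maternal=2,
    )
    return simulate_family(params, tmp_path_factory.mktemp("tiny_family"))
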