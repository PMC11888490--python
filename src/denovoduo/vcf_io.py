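"""Read phased multi-sample VCFs and BED interval files; write classification results.

The input contract is the joint-calling + read-backed-phasing dialect
(DeepVariant/GLnexus-style multi-sample VCF post-processed by a phaser such
as HiPhase): per-sample FORMAT fields GT (with ``|`` marking phased calls),
GQ, DP and PS, where PS identifies the phase set a phased genotype belongs
to. Coordinates stay 1-based (VCF convention) everywhere except inside
:class:`RegionSet`, which converts to 0-based half-open at query time.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import pysam
from intervaltree import IntervalTree

__all__ = [
    "GenotypeCall",
    "VariantRecord",
    "RegionSet",
    "read_joint_vcf",
    "read_bed",
    "write_classifications",
    "read_classifications",
    "VcfFormatError",
]

#: INFO key used when annotating an output VCF with classification labels.
CLASS_INFO_KEY = "DENOVO_CLASS"

#: TSV column order for classification output.
TSV_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "orientation",
    "allele_kind",
    "label",
    "d_c_p1",
    "d_c_p2",
    "d_o_p1",
    "d_o_p2",
    "n_sites",
    "block_id",
    "span_start",
    "span_end",
    "fail_reasons",
]


class VcfFormatError(ValueError):
    """Raised on malformed or contract-violating VCF/BED input."""


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call at one site.

    ``allele_a``/``allele_b`` are VCF allele indices (0 = REF, >=1 = ALT),
    ``None`` when missing ("." or haploid second allele). ``phased`` mirrors
    the GT separator; a phased GT without a PS value is demoted to unphased
    at parse time because phase-set identity is what block construction
    consumes. ``gq``/``dp`` stay ``None`` when absent — a missing value fails
    every threshold test, it is never imputed.
    """

    allele_a: Optional[int]
    allele_b: Optional[int]
    phased: bool
    gq: Optional[int] = None
    dp: Optional[int] = None
    ps: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.phased and self.ps is not None:
            object.__setattr__(self, "ps", None)

    @property
    def is_diploid(self) -> bool:
        return self.allele_a is not None and self.allele_b is not None

    @property
    def is_het(self) -> bool:
        return self.is_diploid and self.allele_a != self.allele_b

    @property
    def is_hom(self) -> bool:
        return self.is_diploid and self.allele_a == self.allele_b

    def is_hom_allele(self, allele: int) -> bool:
        return self.is_hom and self.allele_a == allele

    @property
    def is_phased_het(self) -> bool:
        return self.is_het and self.phased and self.ps is not None


@dataclass
class VariantRecord:
    """One VCF row with per-sample calls, 1-based position."""

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    calls: Mapping[str, GenotypeCall]
    info_af: Optional[float] = None

    @property
    def is_biallelic(self) -> bool:
        return len(self.alt_alleles) == 1

    @property
    def is_indel(self) -> bool:
        return self.is_biallelic and len(self.ref_allele) != len(self.alt_alleles[0])


class RegionSet:
    """Normalized per-contig set of 0-based half-open intervals (BED convention).

    Membership of a 1-based variant position ``p`` means ``p - 1`` falls in
    some interval, i.e. ``start < p <= end`` for a BED line ``start end``.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()) -> None:
        self._trees: dict[str, IntervalTree] = collections.defaultdict(IntervalTree)
        for chrom, start, end in intervals:
            if start > end:
                raise VcfFormatError(f"interval start {start} > end {end} on {chrom}")
            if start < end:  # zero-length intervals contain nothing
                self._trees[chrom].addi(start, end)
        for tree in self._trees.values():
            tree.merge_overlaps(strict=False)

    def contains(self, chrom: str, pos: int) -> bool:
        """True iff 1-based position ``pos`` lies inside an interval."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos - 1))

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self._trees):
            for iv in sorted(self._trees[chrom]):
                out.append((chrom, iv.begin, iv.end))
        return out

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())


def _parse_int(value) -> Optional[int]:
    if value is None:
        return None
    if isinstance(value, tuple):  # pysam wraps Number=1 values sometimes
        value = value[0] if value else None
        if value is None:
            return None
    try:
        return int(value)
    except (TypeError, ValueError):
        return None


def _parse_sample(sample: "pysam.libcbcf.VariantRecordSample") -> GenotypeCall:
    gt = sample.get("GT") or (None, None)
    allele_a = gt[0] if len(gt) >= 1 else None
    allele_b = gt[1] if len(gt) >= 2 else None
    phased = bool(sample.phased)
    gq = _parse_int(sample.get("GQ"))
    dp = _parse_int(sample.get("DP"))
    ps = _parse_int(sample.get("PS"))
    if ps is None:
        phased = False
    return GenotypeCall(allele_a, allele_b, phased, gq=gq, dp=dp, ps=ps)


def read_joint_vcf(path, sample_ids: Sequence[str]) -> list[VariantRecord]:
    """Read a jointly-called phased VCF into :class:`VariantRecord` objects.

    Parameters
    ----------
    path
        Plain or bgzipped VCF; no index required (single linear scan).
    sample_ids
        The 2 (duo) or 3 (trio) sample names to extract, e.g.
        ``[proband, parent]``. All must be present in the header.

    Records must be sorted by contig then position; multi-allelic rows are
    retained but carry ``is_biallelic == False`` and are excluded from
    candidacy downstream.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        header_samples = list(vcf.header.samples)
        for sid in sample_ids:
            if sid not in header_samples:
                raise VcfFormatError(
                    f"sample {sid!r} not found in VCF {path} "
                    f"(samples: {', '.join(header_samples)})"
                )
        has_af = "AF" in vcf.header.info
        seen_contigs: list[str] = []
        last_pos: Optional[int] = None
        for line_no, rec in enumerate(vcf.fetch(), start=1):
            if not seen_contigs or rec.chrom != seen_contigs[-1]:
                if rec.chrom in seen_contigs:
                    raise VcfFormatError(
                        f"unsorted VCF: contig {rec.chrom} revisited at position {rec.pos}"
                    )
                seen_contigs.append(rec.chrom)
                last_pos = None
            if last_pos is not None and rec.pos < last_pos:
                raise VcfFormatError(
                    f"unsorted VCF: {rec.chrom}:{rec.pos} follows {last_pos}"
                )
            last_pos = rec.pos
            try:
                calls = {sid: _parse_sample(rec.samples[sid]) for sid in sample_ids}
            except (ValueError, TypeError) as exc:  # malformed GT etc.
                raise VcfFormatError(
                    f"malformed genotype at record {line_no} ({rec.chrom}:{rec.pos}): {exc}"
                ) from exc
            af = rec.info.get("AF") if has_af else None
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_alleles=tuple(rec.alts or ()),
                    calls=calls,
                    info_af=float(af[0]) if isinstance(af, tuple) and af else
                    (float(af) if af is not None else None),
                )
            )
    return records


def read_bed(path) -> RegionSet:
    """Read a 3+ column BED file (0-based half-open) into a RegionSet."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise VcfFormatError(f"{path}:{line_no}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise VcfFormatError(f"{path}:{line_no}: non-integer coordinates") from exc
            if start > end:
                raise VcfFormatError(f"{path}:{line_no}: start {start} > end {end}")
            intervals.append((chrom, start, end))
    return RegionSet(intervals)


def _fmt(value) -> str:
    return "." if value is None else str(value)


def write_classifications(classified, tsv_path, vcf_in=None, vcf_out=None) -> None:
    """Write classification records as TSV and, optionally, an annotated VCF.

    The TSV carries one row per candidate; re-reading it with
    :func:`read_classifications` reproduces labels exactly. When both
    ``vcf_in`` and ``vcf_out`` are given, the input VCF is copied with an
    added ``DENOVO_CLASS`` INFO key on rows matching a classified candidate.
    """
    rows = []
    for cr in classified:
        h = cr.hamming
        rows.append(
            {
                "chrom": cr.chrom,
                "pos": cr.pos,
                "ref": cr.ref,
                "alt": cr.alt,
                "orientation": cr.candidate.orientation,
                "allele_kind": cr.candidate.allele_kind,
                "label": cr.label,
                "d_c_p1": _fmt(h.d_c_p1 if h else None),
                "d_c_p2": _fmt(h.d_c_p2 if h else None),
                "d_o_p1": _fmt(h.d_o_p1 if h else None),
                "d_o_p2": _fmt(h.d_o_p2 if h else None),
                "n_sites": _fmt(h.n_sites if h else None),
                "block_id": _fmt(cr.candidate.block_id),
                "span_start": _fmt(cr.span_start),
                "span_end": _fmt(cr.span_end),
                "fail_reasons": ",".join(cr.fail_reasons) if cr.fail_reasons else ".",
            }
        )
    df = pd.DataFrame(rows, columns=TSV_COLUMNS)
    df.to_csv(tsv_path, sep="\t", index=False)

    if vcf_in is not None and vcf_out is not None:
        labels = {(cr.chrom, cr.pos): cr.label for cr in classified}
        with pysam.VariantFile(str(vcf_in)) as src:
            header = src.header.copy()
            if CLASS_INFO_KEY not in header.info:
                header.info.add(
                    CLASS_INFO_KEY, 1, "String", "Duo-based de novo classification label"
                )
            with pysam.VariantFile(str(vcf_out), "w", header=header) as dst:
                for rec in src.fetch():
                    label = labels.get((rec.chrom, rec.pos))
                    out = rec.copy()
                    out.translate(header)
                    if label is not None:
                        out.info[CLASS_INFO_KEY] = label
                    dst.write(out)


def read_classifications(tsv_path) -> pd.DataFrame:
    """Round-trip reader for the classification TSV ('.' becomes NA)."""
    return pd.read_csv(tsv_path, sep="\t", na_values=["."], dtype={"chrom": str})
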