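"""Candidate selection and per-site QC gates.

A candidate is a site where the proband carries a phased heterozygous call
and the sequenced parent is homozygous for the other allele: for the
standard (alternative-allele) candidate class the proband is 0|1 or 1|0 and
the parent 0/0; the reference-allele class (proband 0|1 or 1|0, parent 1/1)
is a negative control with a very low prior probability of being de novo.
Both samples must pass depth and genotype-quality gates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .blocks import HaplotypeBlock, block_span_bp
from .vcf_io import VariantRecord

__all__ = [
    "DuoParams",
    "Candidate",
    "HAP1",
    "HAP2",
    "ALT_KIND",
    "REF_KIND",
    "site_passes_qc",
    "select_candidates",
    "attach_blocks",
    "positional_filter",
]

HAP1 = "HAP1"  # left of the "|" in the phased GT
HAP2 = "HAP2"
ALT_KIND = "alternative"
REF_KIND = "reference"


@dataclass(frozen=True)
class DuoParams:
    """Tunable thresholds of the duo classification pipeline.

    Defaults are the operating point used throughout: sites need depth >= 20
    and GQ >= 30 in both samples to enter the analysis at all; classified
    candidates additionally need GQ >= 40 in both samples; haplotype blocks
    under 10 kb, and candidates within 2 kb of a block edge, are discarded;
    a proband haplotype counts as dissimilar from a parental haplotype when
    their Hamming distance exceeds 40.
    """

    min_depth: int = 20
    gq_input_min: int = 30
    gq_final_min: int = 40
    min_block_span: int = 10_000
    boundary_margin: int = 2_000
    hd_dissimilarity_threshold: int = 40
    candidate_allele_kind: str = ALT_KIND

    def __post_init__(self) -> None:
        for name in (
            "min_depth",
            "gq_input_min",
            "gq_final_min",
            "min_block_span",
            "boundary_margin",
            "hd_dissimilarity_threshold",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.gq_final_min < self.gq_input_min:
            raise ValueError("gq_final_min must be >= gq_input_min")
        if self.candidate_allele_kind not in (ALT_KIND, REF_KIND):
            raise ValueError("candidate_allele_kind must be 'alternative' or 'reference'")


@dataclass
class Candidate:
    """A proband-het / parent-homozygous site under test.

    ``orientation`` names the proband haplotype carrying the tested allele
    (ALT for the alternative kind, REF for the reference kind); HAP1 is the
    allele left of the ``|`` separator.
    """

    record_index: int
    orientation: str
    allele_kind: str
    block_id: Optional[int] = None


def _call_passes_gates(call, params: DuoParams) -> bool:
    # missing GQ/DP conservatively fails the gate
    return (
        call is not None
        and call.dp is not None
        and call.dp >= params.min_depth
        and call.gq is not None
        and call.gq >= params.gq_input_min
    )


def site_passes_qc(
    rec: VariantRecord, params: DuoParams, sample_ids: Sequence[str]
) -> bool:
    """Site-level retention gate: DP and GQ thresholds in every sample."""
    return all(_call_passes_gates(rec.calls.get(s), params) for s in sample_ids)


def select_candidates(
    records: Sequence[VariantRecord],
    params: DuoParams,
    proband_id: str,
    parent_id: str,
) -> list[Candidate]:
    """Return every record satisfying the candidate definition.

    Requires: biallelic site; proband phased heterozygous 0|1 or 1|0 with a
    phase set; parent homozygous 0/0 (alternative kind) or 1/1 (reference
    kind); DP and GQ gates passed in both samples. Haploid or missing
    genotypes are never candidates.
    """
    kind = params.candidate_allele_kind
    parent_allele = 0 if kind == ALT_KIND else 1
    tested_allele = 1 if kind == ALT_KIND else 0
    out: list[Candidate] = []
    for idx, rec in enumerate(records):
        if not rec.is_biallelic:
            continue
        pro = rec.calls.get(proband_id)
        par = rec.calls.get(parent_id)
        if pro is None or par is None:
            continue
        if not (pro.is_phased_het and {pro.allele_a, pro.allele_b} == {0, 1}):
            continue
        if not par.is_hom_allele(parent_allele):
            continue
        if not (_call_passes_gates(pro, params) and _call_passes_gates(par, params)):
            continue
        orientation = HAP1 if pro.allele_a == tested_allele else HAP2
        out.append(Candidate(record_index=idx, orientation=orientation, allele_kind=kind))
    return out


def attach_blocks(
    candidates: Sequence[Candidate], blocks: Sequence[HaplotypeBlock]
) -> list[Candidate]:
    """Set each candidate's ``block_id`` to its containing block (in place)."""
    index_to_block: dict[int, int] = {}
    for blk in blocks:
        for idx in blk.member_indices:
            index_to_block[idx] = blk.block_id
    for cand in candidates:
        cand.block_id = index_to_block.get(cand.record_index)
    return list(candidates)


def positional_filter(
    candidate: Candidate,
    block: HaplotypeBlock,
    records: Sequence[VariantRecord],
    params: DuoParams,
) -> Optional[str]:
    """Block-geometry gate; returns a failure reason or None on pass.

    Candidates in blocks spanning less than ``min_block_span`` bp fail with
    ``"small_block"``; candidates closer than ``boundary_margin`` bp to
    either end of the block span fail with ``"boundary"`` (a candidate
    exactly at span_start + margin passes — ties resolve permissively).
    """
    if block_span_bp(block) < params.min_block_span:
        return "small_block"
    pos = records[candidate.record_index].pos
    if pos < block.span_start + params.boundary_margin:
        return "boundary"
    if pos > block.span_end - params.boundary_margin:
        return "boundary"
    return None
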