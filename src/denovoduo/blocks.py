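"""Joint proband-parent haplotype blocks from phase-set (PS) assignments.

A haplotype block is a maximal run of consecutive variants on one contig in
which every proband-phased member carries one proband PS value and every
parent-phased member carries one parent PS value. Within such a run the
allele order of every phased GT is consistent, so the four haplotype
sequences (proband hap1/hap2, parent hap1/hap2) are well defined across the
whole block — the prerequisite for the identity-by-descent comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .vcf_io import VariantRecord

__all__ = ["HaplotypeBlock", "build_blocks", "block_span_bp"]


@dataclass
class HaplotypeBlock:
    block_id: int
    chrom: str
    proband_ps: Optional[int]
    parent_ps: Optional[int]
    member_indices: list[int]
    span_start: int
    span_end: int


def build_blocks(
    records: Sequence[VariantRecord], proband_id: str, parent_id: str
) -> list[HaplotypeBlock]:
    """Partition sorted records into maximal joint phase-set runs.

    A record phased in neither sample joins the enclosing run but never
    delimits one; a change in either sample's PS value, or a contig change,
    starts a new block. The block span is the inclusive range of member
    positions. Every record belongs to exactly one block.
    """
    blocks: list[HaplotypeBlock] = []
    cur: Optional[HaplotypeBlock] = None

    for idx, rec in enumerate(records):
        pro = rec.calls.get(proband_id)
        par = rec.calls.get(parent_id)
        pro_ps = pro.ps if pro is not None and pro.phased else None
        par_ps = par.ps if par is not None and par.phased else None

        boundary = cur is None or rec.chrom != cur.chrom
        if not boundary and pro_ps is not None and cur.proband_ps is not None:
            boundary = pro_ps != cur.proband_ps
        if not boundary and par_ps is not None and cur.parent_ps is not None:
            boundary = par_ps != cur.parent_ps

        if boundary:
            cur = HaplotypeBlock(
                block_id=len(blocks),
                chrom=rec.chrom,
                proband_ps=pro_ps,
                parent_ps=par_ps,
                member_indices=[idx],
                span_start=rec.pos,
                span_end=rec.pos,
            )
            blocks.append(cur)
        else:
            cur.member_indices.append(idx)
            cur.span_end = rec.pos
            if cur.proband_ps is None:
                cur.proband_ps = pro_ps
            if cur.parent_ps is None:
                cur.parent_ps = par_ps
    return blocks


def block_span_bp(block: HaplotypeBlock) -> int:
    """Inclusive genomic span of a block's member positions, in bp."""
    return block.span_end - block.span_start + 1
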