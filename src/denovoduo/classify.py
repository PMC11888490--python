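"""Haplotype encoding, Hamming comparison and the duo decision rule.

The idea: within a joint haplotype block, compare each of the proband's two
haplotypes against each of the sequenced parent's two haplotypes as binary
strings (0 = REF allele, 1 = ALT allele). A Hamming distance of exactly 0
marks a proband-parent haplotype pair as identical by descent. A candidate
variant (proband het, parent homozygous for the other allele) sitting on a
haplotype that is IBD with exactly one parental haplotype — while the other
proband haplotype is dissimilar (distance above a threshold) to both — must
have arisen de novo on the transmitted haplotype. Conversely, if it is the
*other* proband haplotype that is IBD with one parental haplotype, the
candidate-bearing haplotype came from the non-sequenced parent and its
variant is labeled inherited-from-non-sequenced. Anything else stays
uncertain.

Three position classes make the distance informative: proband-het /
parent-hom sites directly reveal which proband haplotype was transmitted;
both-het phased sites and proband-hom / parent-het sites act as phasing
quality controls — any switch or genotyping error in the region breaks the
exact distance-0 requirement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .blocks import HaplotypeBlock, build_blocks
from .candidates import (
    ALT_KIND,
    HAP1,
    HAP2,
    Candidate,
    DuoParams,
    attach_blocks,
    positional_filter,
    select_candidates,
    site_passes_qc,
)
from .vcf_io import RegionSet, VariantRecord

__all__ = [
    "LABEL_DE_NOVO",
    "LABEL_INHERITED",
    "LABEL_UNCERTAIN",
    "LABEL_FAILED_QC",
    "HammingResult",
    "ClassificationRecord",
    "encode_block_haplotypes",
    "hamming",
    "classify_candidate",
    "apply_post_filters",
    "classify_duo",
]

LABEL_DE_NOVO = "de_novo"
LABEL_INHERITED = "inherited_from_non_sequenced"
LABEL_UNCERTAIN = "uncertain"
LABEL_FAILED_QC = "failed_qc"


@dataclass(frozen=True)
class HammingResult:
    """Four haplotype-pair distances for one candidate's block.

    ``d_c_*``: candidate-bearing proband haplotype vs parent haplotype 1/2;
    ``d_o_*``: the other proband haplotype vs parent haplotype 1/2;
    ``n_sites``: informative positions entering the comparison.
    """

    d_c_p1: int
    d_c_p2: int
    d_o_p1: int
    d_o_p2: int
    n_sites: int


@dataclass
class ClassificationRecord:
    candidate: Candidate
    label: str
    chrom: str
    pos: int
    ref: str
    alt: str
    hamming: Optional[HammingResult] = None
    fail_reasons: list[str] = field(default_factory=list)
    span_start: Optional[int] = None
    span_end: Optional[int] = None


def encode_block_haplotypes(
    block: HaplotypeBlock,
    records: Sequence[VariantRecord],
    candidates_same_orientation: set[int],
    proband_id: str,
    parent_id: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Binary haplotype vectors (proband h1, h2; parent h1, h2) for a block.

    A block member enters the vectors iff it is biallelic and, in each
    sample, either phased heterozygous (alleles taken in GT order) or
    homozygous (both haplotypes carry the same allele). Unphased-het or
    missing calls in either sample exclude the position, as do the record
    indices in ``candidates_same_orientation`` (candidate variants sharing
    the evaluated candidate's phasing orientation must not contribute to
    the distances they are judged by).
    """
    pro_h1: list[int] = []
    pro_h2: list[int] = []
    par_h1: list[int] = []
    par_h2: list[int] = []
    for idx in block.member_indices:
        if idx in candidates_same_orientation:
            continue
        rec = records[idx]
        if not rec.is_biallelic:
            continue
        pair = []
        ok = True
        for sid in (proband_id, parent_id):
            call = rec.calls.get(sid)
            if call is None or not call.is_diploid:
                ok = False
                break
            if call.is_hom:
                pair.append((call.allele_a, call.allele_a))
            elif call.is_phased_het:
                pair.append((call.allele_a, call.allele_b))
            else:
                ok = False
                break
        if not ok:
            continue
        (pa, pb), (qa, qb) = pair
        if {pa, pb, qa, qb} - {0, 1}:
            continue
        pro_h1.append(pa)
        pro_h2.append(pb)
        par_h1.append(qa)
        par_h2.append(qb)
    to_arr = lambda xs: np.asarray(xs, dtype=np.int8)
    return to_arr(pro_h1), to_arr(pro_h2), to_arr(par_h1), to_arr(par_h2)


def hamming(u: np.ndarray, v: np.ndarray) -> int:
    """Number of positions at which two equal-length binary vectors differ."""
    u = np.asarray(u)
    v = np.asarray(v)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    return int(np.count_nonzero(u != v))


def classify_candidate(h: HammingResult, params: DuoParams) -> str:
    """Apply the IBD decision rule to one candidate's four distances.

    With dissimilarity threshold T: de novo iff the candidate-bearing
    haplotype has distance 0 to exactly one parental haplotype while the
    other proband haplotype has distance > T to both; inherited-from-
    non-sequenced iff the mirror-image pattern holds; otherwise uncertain.
    """
    t = params.hd_dissimilarity_threshold
    c_zero = (h.d_c_p1 == 0) + (h.d_c_p2 == 0)
    o_zero = (h.d_o_p1 == 0) + (h.d_o_p2 == 0)
    if c_zero == 1 and h.d_o_p1 > t and h.d_o_p2 > t:
        return LABEL_DE_NOVO
    if o_zero == 1 and h.d_c_p1 > t and h.d_c_p2 > t:
        return LABEL_INHERITED
    return LABEL_UNCERTAIN


def apply_post_filters(
    classified: Sequence[ClassificationRecord],
    records: Sequence[VariantRecord],
    blocks: Sequence[HaplotypeBlock],
    problematic: Optional[RegionSet],
    params: DuoParams,
    proband_id: str,
    parent_id: str,
) -> list[ClassificationRecord]:
    """Post-classification filters, applied in order.

    1. Candidates inside a problematic region fail QC outright.
    2. Candidates with GQ below ``gq_final_min`` in either sample are
       demoted to uncertain (genotyping-error guard on the call itself).
    3. If two or more surviving de novo labels share one haplotype block,
       all of them fail QC — clustered de novo calls in a single block are
       overwhelmingly artifacts.
    """
    for cr in classified:
        if problematic is not None and problematic.contains(cr.chrom, cr.pos):
            cr.label = LABEL_FAILED_QC
            cr.fail_reasons.append("problematic_region")
    for cr in classified:
        if cr.label == LABEL_FAILED_QC:
            continue
        rec = records[cr.candidate.record_index]
        pro, par = rec.calls.get(proband_id), rec.calls.get(parent_id)
        low = any(
            c is None or c.gq is None or c.gq < params.gq_final_min for c in (pro, par)
        )
        if low:
            cr.label = LABEL_UNCERTAIN
            cr.fail_reasons.append("low_gq_final")
    by_block: dict[int, list[ClassificationRecord]] = {}
    for cr in classified:
        if cr.label == LABEL_DE_NOVO and cr.candidate.block_id is not None:
            by_block.setdefault(cr.candidate.block_id, []).append(cr)
    for group in by_block.values():
        if len(group) >= 2:
            for cr in group:
                cr.label = LABEL_FAILED_QC
                cr.fail_reasons.append("clustered_in_block")
    return list(classified)


def classify_duo(
    records: Sequence[VariantRecord],
    params: DuoParams,
    proband_id: str,
    parent_id: str,
    problematic: Optional[RegionSet] = None,
) -> list[ClassificationRecord]:
    """Full duo pipeline: QC -> blocks -> candidates -> IBD rule -> filters.

    Sites failing the depth/GQ retention gate in either sample are dropped
    before block construction, so they neither delimit blocks nor enter the
    haplotype encodings. Every surviving candidate receives exactly one
    label. Classification is fully deterministic.
    """
    kept = [r for r in records if site_passes_qc(r, params, (proband_id, parent_id))]
    blocks = build_blocks(kept, proband_id, parent_id)
    cands = select_candidates(kept, params, proband_id, parent_id)
    attach_blocks(cands, blocks)
    block_by_id = {b.block_id: b for b in blocks}

    out: list[ClassificationRecord] = []
    pending: dict[tuple[int, str], list[ClassificationRecord]] = {}
    cand_indices_by_block_orient: dict[tuple[int, str], set[int]] = {}
    for cand in cands:
        key = (cand.block_id, cand.orientation)
        cand_indices_by_block_orient.setdefault(key, set()).add(cand.record_index)

    for cand in cands:
        rec = kept[cand.record_index]
        cr = ClassificationRecord(
            candidate=cand,
            label=LABEL_UNCERTAIN,
            chrom=rec.chrom,
            pos=rec.pos,
            ref=rec.ref_allele,
            alt=rec.alt_alleles[0],
        )
        out.append(cr)
        if cand.block_id is None:
            cr.label = LABEL_FAILED_QC
            cr.fail_reasons.append("no_block")
            continue
        block = block_by_id[cand.block_id]
        cr.span_start, cr.span_end = block.span_start, block.span_end
        reason = positional_filter(cand, block, kept, params)
        if reason is not None:
            cr.label = LABEL_FAILED_QC
            cr.fail_reasons.append(reason)
            continue
        pending.setdefault((cand.block_id, cand.orientation), []).append(cr)

    # one encoding + distance computation per (block, orientation) group;
    # identical by contract to per-candidate recomputation
    for (block_id, orientation), group in pending.items():
        block = block_by_id[block_id]
        excluded = cand_indices_by_block_orient[(block_id, orientation)]
        ph1, ph2, qh1, qh2 = encode_block_haplotypes(
            block, kept, excluded, proband_id, parent_id
        )
        c_hap, o_hap = (ph1, ph2) if orientation == HAP1 else (ph2, ph1)
        h = HammingResult(
            d_c_p1=hamming(c_hap, qh1),
            d_c_p2=hamming(c_hap, qh2),
            d_o_p1=hamming(o_hap, qh1),
            d_o_p2=hamming(o_hap, qh2),
            n_sites=len(ph1),
        )
        label = classify_candidate(h, params)
        for cr in group:
            cr.hamming = h
            cr.label = label

    apply_post_filters(out, kept, blocks, problematic, params, proband_id, parent_id)
    return out
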