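"""Trio-based evaluation of duo classifications.

Given classifications produced from a duo and the full trio VCF, this module
checks de novo calls against the genotype of the parent that was masked in
the duo, derives a ground-truth de novo set from the full trio, and computes
the summary metrics (PPV, NPV vs the naive all-non-de-novo baseline, FPR
over candidates known to be transmitted from the non-sequenced parent,
sensitivity over the trio truth set), plus a substitution-spectrum tally
and a parameter sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dataclass_fields
from typing import Iterable, Optional, Sequence

import pandas as pd

from .candidates import ALT_KIND, DuoParams
from .classify import (
    LABEL_DE_NOVO,
    LABEL_FAILED_QC,
    LABEL_INHERITED,
    LABEL_UNCERTAIN,
    classify_duo,
)
from .vcf_io import RegionSet, VariantRecord

__all__ = [
    "TruthAssessment",
    "EvaluationSummary",
    "assess_against_nonsequenced_parent",
    "trio_de_novo_truth",
    "compute_metrics",
    "swapped_duo_control",
    "mutation_spectrum",
    "parameter_sweep",
    "SPECTRUM_CLASSES",
]

CORRECT_DN = "correct_de_novo"
INCORRECT_DN = "incorrect_de_novo"
CORRECT_NON_DN = "correct_non_de_novo"
INCORRECT_NON_DN = "incorrect_non_de_novo"
UNEVALUABLE = "unevaluable"

SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G", "indel")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class TruthAssessment:
    """Per-candidate verdict against the non-sequenced parent's genotype.

    ``parent_has_allele`` records whether that parent carries >=1 copy of
    the tested allele (None when the call is missing or below the GQ gate);
    it is kept for every candidate so the naive baseline and the false
    positive rate can be computed over the full candidate set.
    """

    chrom: str
    pos: int
    label: str
    verdict: str
    parent_has_allele: Optional[bool] = None


@dataclass
class EvaluationSummary:
    n_candidates: int
    n_de_novo_called: int
    n_inherited_called: int
    n_uncertain: int
    n_failed_qc: int
    ppv: Optional[float]
    npv: Optional[float]
    naive_npv: Optional[float]
    fpr: Optional[float]
    sensitivity: Optional[float]
    truth_breakdown: dict


def _allele_strings(rec: VariantRecord) -> list[str]:
    return [rec.ref_allele, *rec.alt_alleles]


def assess_against_nonsequenced_parent(
    classified: Sequence,
    trio_records: Sequence[VariantRecord],
    nonseq_parent_id: str,
    min_gq: int = 40,
) -> list[TruthAssessment]:
    """Judge each classification using the masked parent's trio genotype.

    A de novo call is correct iff the non-sequenced parent (at GQ >=
    ``min_gq``) carries zero copies of the tested allele; an
    inherited-from-non-sequenced call is correct iff that parent carries at
    least one copy. This is conservative for de novo calls: a variant can be
    genuinely de novo yet present in the other parent at a recurrently
    mutated site. Positions missing from the trio or failing the GQ gate
    are unevaluable and never enter metric denominators.
    """
    by_pos = {(r.chrom, r.pos): r for r in trio_records}
    out: list[TruthAssessment] = []
    for cr in classified:
        ta = TruthAssessment(chrom=cr.chrom, pos=cr.pos, label=cr.label, verdict=UNEVALUABLE)
        out.append(ta)
        rec = by_pos.get((cr.chrom, cr.pos))
        if rec is None:
            continue
        call = rec.calls.get(nonseq_parent_id)
        if call is None or not call.is_diploid or call.gq is None or call.gq < min_gq:
            continue
        tested = cr.alt if cr.candidate.allele_kind == ALT_KIND else cr.ref
        alleles = _allele_strings(rec)
        copies = sum(
            1
            for a in (call.allele_a, call.allele_b)
            if a is not None and a < len(alleles) and alleles[a] == tested
        )
        ta.parent_has_allele = copies >= 1
        if cr.label == LABEL_DE_NOVO:
            ta.verdict = INCORRECT_DN if ta.parent_has_allele else CORRECT_DN
        elif cr.label == LABEL_INHERITED:
            ta.verdict = CORRECT_NON_DN if ta.parent_has_allele else INCORRECT_NON_DN
    return out


def trio_de_novo_truth(
    trio_records: Sequence[VariantRecord],
    params: DuoParams,
    proband_id: str,
    father_id: str,
    mother_id: str,
) -> set[tuple[str, int]]:
    """Ground-truth de novo positions from the full trio.

    A position qualifies iff it is biallelic, the proband is heterozygous
    0/1, both parents are homozygous reference, and every sample passes
    GQ >= ``gq_final_min`` and DP >= ``min_depth``. Qualifying variants that
    share one proband phase set are then all removed (clustered de novo
    calls in one block are treated as likely artifacts).
    """
    qualifying: list[VariantRecord] = []
    for rec in trio_records:
        if not rec.is_biallelic:
            continue
        pro = rec.calls.get(proband_id)
        fa = rec.calls.get(father_id)
        mo = rec.calls.get(mother_id)
        if pro is None or fa is None or mo is None:
            continue
        if not (pro.is_het and {pro.allele_a, pro.allele_b} == {0, 1}):
            continue
        if not (fa.is_hom_allele(0) and mo.is_hom_allele(0)):
            continue
        if any(
            c.gq is None or c.gq < params.gq_final_min or c.dp is None or c.dp < params.min_depth
            for c in (pro, fa, mo)
        ):
            continue
        qualifying.append(rec)

    ps_counts: dict[tuple[str, int], int] = {}
    for rec in qualifying:
        pro = rec.calls[proband_id]
        if pro.phased and pro.ps is not None:
            key = (rec.chrom, pro.ps)
            ps_counts[key] = ps_counts.get(key, 0) + 1
    out = set()
    for rec in qualifying:
        pro = rec.calls[proband_id]
        if pro.phased and pro.ps is not None and ps_counts[(rec.chrom, pro.ps)] >= 2:
            continue
        out.add((rec.chrom, rec.pos))
    return out


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def compute_metrics(
    assessments: Sequence[TruthAssessment],
    truth_set: set[tuple[str, int]],
    classified: Sequence,
) -> EvaluationSummary:
    """Summary metrics; empty denominators report None, never 0."""
    labels = [cr.label for cr in classified]
    verdicts = [a.verdict for a in assessments]
    cd = verdicts.count(CORRECT_DN)
    icd = verdicts.count(INCORRECT_DN)
    cn = verdicts.count(CORRECT_NON_DN)
    icn = verdicts.count(INCORRECT_NON_DN)

    evaluable = [a for a in assessments if a.parent_has_allele is not None]
    transmitted = [a for a in evaluable if a.parent_has_allele]
    fp = sum(1 for a in transmitted if a.label == LABEL_DE_NOVO)

    dn_positions = {(cr.chrom, cr.pos) for cr in classified if cr.label == LABEL_DE_NOVO}
    label_by_pos = {(cr.chrom, cr.pos): cr.label for cr in classified}
    breakdown = {LABEL_DE_NOVO: 0, LABEL_INHERITED: 0, LABEL_UNCERTAIN: 0,
                 LABEL_FAILED_QC: 0, "not_candidate": 0}
    for key in truth_set:
        breakdown[label_by_pos.get(key, "not_candidate")] += 1
    n_truth = len(truth_set)
    breakdown_frac = (
        {k: v / n_truth for k, v in breakdown.items()} if n_truth else {}
    )

    return EvaluationSummary(
        n_candidates=len(classified),
        n_de_novo_called=labels.count(LABEL_DE_NOVO),
        n_inherited_called=labels.count(LABEL_INHERITED),
        n_uncertain=labels.count(LABEL_UNCERTAIN),
        n_failed_qc=labels.count(LABEL_FAILED_QC),
        ppv=_ratio(cd, cd + icd),
        npv=_ratio(cn, cn + icn),
        # naive baseline: label every candidate non-de-novo; such a label is
        # correct whenever the non-sequenced parent carries the allele
        naive_npv=_ratio(len(transmitted), len(evaluable)),
        fpr=_ratio(fp, len(transmitted)),
        sensitivity=_ratio(len(truth_set & dn_positions), n_truth),
        truth_breakdown=breakdown_frac,
    )


def swapped_duo_control(
    records: Sequence[VariantRecord],
    params: DuoParams,
    proband_id: str,
    parent_id: str,
    problematic: Optional[RegionSet] = None,
) -> Optional[float]:
    """Fraction of evaluated candidates receiving an IBD-based label.

    Runs the duo pipeline on an arbitrary two-sample pairing (e.g. the two
    parents of a trio, as a negative control) and returns the fraction of
    QC-passing candidates labeled de novo or inherited-from-non-sequenced.
    Both labels require an identical-by-descent block, so unrelated pairs
    should score near zero while true parent-child pairs score high.
    Returns None when no candidate survives QC.
    """
    classified = classify_duo(records, params, proband_id, parent_id, problematic)
    evaluated = [cr for cr in classified if cr.label != LABEL_FAILED_QC]
    if not evaluated:
        return None
    hit = sum(1 for cr in evaluated if cr.label in (LABEL_DE_NOVO, LABEL_INHERITED))
    return hit / len(evaluated)


def mutation_spectrum(ref_alt_pairs: Iterable[tuple[str, str]]) -> dict[str, int]:
    """Tally substitutions into the six pyrimidine-reference classes + indel.

    SNVs with a purine reference are collapsed by reverse complement
    (G>A counts as C>T); any length-changing allele counts as ``indel``.
    """
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    for ref, alt in ref_alt_pairs:
        if len(ref) != 1 or len(alt) != 1:
            counts["indel"] += 1
            continue
        ref_u, alt_u = ref.upper(), alt.upper()
        if ref_u in ("G", "A"):
            ref_u, alt_u = _COMPLEMENT[ref_u], _COMPLEMENT[alt_u]
        key = f"{ref_u}>{alt_u}"
        if key in counts:
            counts[key] += 1
    return counts


def parameter_sweep(
    records: Sequence[VariantRecord],
    grid: Iterable[DuoParams],
    proband_id: str,
    parent_id: str,
    problematic: Optional[RegionSet] = None,
) -> pd.DataFrame:
    """One full duo classification per parameter setting.

    Returns a table with one row per setting (sorted by the parameter
    values) carrying the label counts; fully deterministic.
    """
    param_names = [f.name for f in dataclass_fields(DuoParams)]
    rows = []
    for params in grid:
        classified = classify_duo(records, params, proband_id, parent_id, problematic)
        labels = [cr.label for cr in classified]
        row = {name: getattr(params, name) for name in param_names}
        row.update(
            n_candidates=len(classified),
            n_de_novo=labels.count(LABEL_DE_NOVO),
            n_inherited=labels.count(LABEL_INHERITED),
            n_uncertain=labels.count(LABEL_UNCERTAIN),
            n_failed_qc=labels.count(LABEL_FAILED_QC),
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(param_names).reset_index(drop=True)
    return df
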