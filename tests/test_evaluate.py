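"""Trio-based assessment, metrics, spectrum, parameter sweep."""

from __future__ import annotations

import dataclasses

import pytest

from denovoduo import (
    Candidate,
    ClassificationRecord,
    DuoParams,
    LABEL_DE_NOVO,
    LABEL_INHERITED,
    LABEL_UNCERTAIN,
    assess_against_nonsequenced_parent,
    classify_duo,
    compute_metrics,
    mutation_spectrum,
    parameter_sweep,
    read_joint_vcf,
    swapped_duo_control,
    trio_de_novo_truth,
)
from denovoduo.evaluate import (
    CORRECT_DN,
    CORRECT_NON_DN,
    INCORRECT_DN,
    INCORRECT_NON_DN,
    UNEVALUABLE,
)
from conftest import mk_call, mk_rec

P = DuoParams()


def _classified(pos, label, ref="A", alt="G", kind="alternative"):
    return ClassificationRecord(
        candidate=Candidate(record_index=0, orientation="HAP1", allele_kind=kind),
        label=label, chrom="chr1", pos=pos, ref=ref, alt=alt,
    )


def _trio_rec(pos, pro, fa, mo, ref="A", alt="G"):
    return mk_rec(pos, pro, fa, ref=ref, alt=alt, extra_samples={"M": mo})


class TestAssessment:
    def _trio(self, mother_call):
        return [_trio_rec(1000, mk_call("0|1", ps=1), mk_call("0/0"), mother_call)]

    @pytest.mark.parametrize(
        "label,mother,verdict",
        [
            (LABEL_DE_NOVO, mk_call("0/0", gq=50), CORRECT_DN),
            (LABEL_DE_NOVO, mk_call("0/1", gq=50), INCORRECT_DN),
            (LABEL_DE_NOVO, mk_call("0/0", gq=35), UNEVALUABLE),
            (LABEL_INHERITED, mk_call("0/1", gq=50), CORRECT_NON_DN),
            (LABEL_INHERITED, mk_call("0/0", gq=50), INCORRECT_NON_DN),
            (LABEL_UNCERTAIN, mk_call("0/0", gq=50), UNEVALUABLE),
        ],
    )
    def test_verdicts(self, label, mother, verdict):
        (ta,) = assess_against_nonsequenced_parent(
            [_classified(1000, label)], self._trio(mother), "M")
        assert ta.verdict == verdict

    def test_position_absent_from_trio_is_unevaluable(self):
        (ta,) = assess_against_nonsequenced_parent(
            [_classified(99_999, LABEL_DE_NOVO)], self._trio(mk_call("0/0")), "M")
        assert ta.verdict == UNEVALUABLE and ta.parent_has_allele is None

    def test_reference_kind_tests_ref_allele(self):
        trio = [_trio_rec(1000, mk_call("0|1", ps=1), mk_call("1/1"), mk_call("1/1", gq=50))]
        (ta,) = assess_against_nonsequenced_parent(
            [_classified(1000, LABEL_DE_NOVO, kind="reference")], trio, "M")
        # mother 1/1 carries zero REF copies -> de novo REF call is correct
        assert ta.verdict == CORRECT_DN and ta.parent_has_allele is False


class TestTrioTruth:
    def _rec(self, pos, pro=None, fa=None, mo=None, alt="G", ps=None):
        pro = pro or mk_call("0|1" if ps else "0/1", gq=50, dp=25, ps=ps)
        fa = fa or mk_call("0/0", gq=45, dp=22)
        mo = mo or mk_call("0/0", gq=48, dp=30)
        return _trio_rec(pos, pro, fa, mo, alt=alt)

    def test_qualifying_position_included(self):
        assert trio_de_novo_truth([self._rec(1000)], P, "P", "F", "M") == {("chr1", 1000)}

    def test_low_parent_gq_excluded(self):
        rec = self._rec(1000, fa=mk_call("0/0", gq=35, dp=22))
        assert trio_de_novo_truth([rec], P, "P", "F", "M") == set()

    def test_low_depth_excluded(self):
        rec = self._rec(1000, pro=mk_call("0/1", gq=50, dp=15))
        assert trio_de_novo_truth([rec], P, "P", "F", "M") == set()

    def test_multiallelic_excluded(self):
        rec = self._rec(1000, alt=("G", "T"))
        assert trio_de_novo_truth([rec], P, "P", "F", "M") == set()

    def test_parent_carrier_excluded(self):
        rec = self._rec(1000, mo=mk_call("0/1", gq=48, dp=30))
        assert trio_de_novo_truth([rec], P, "P", "F", "M") == set()

    def test_clustered_in_proband_phase_set_all_excluded(self):
        recs = [self._rec(1000, ps=7), self._rec(2000, ps=7), self._rec(9000, ps=8)]
        assert trio_de_novo_truth(recs, P, "P", "F", "M") == {("chr1", 9000)}


class TestComputeMetrics:
    def test_ppv_arithmetic(self):
        assessments = (
            [dataclasses.replace(a) for a in []]
            + [self._ta(i, LABEL_DE_NOVO, CORRECT_DN, False) for i in range(49)]
            + [self._ta(100, LABEL_DE_NOVO, INCORRECT_DN, True)]
        )
        classified = [_classified(a.pos, a.label) for a in assessments]
        s = compute_metrics(assessments, set(), classified)
        assert s.ppv == pytest.approx(0.98)

    @staticmethod
    def _ta(pos, label, verdict, has):
        from denovoduo import TruthAssessment

        return TruthAssessment(chrom="chr1", pos=pos, label=label, verdict=verdict,
                               parent_has_allele=has)

    def test_empty_denominators_are_missing_not_zero(self):
        s = compute_metrics([], set(), [])
        assert s.ppv is None and s.npv is None and s.fpr is None and s.sensitivity is None

    def test_zero_false_positives_give_fpr_zero(self):
        assessments = [self._ta(i, LABEL_INHERITED, CORRECT_NON_DN, True) for i in range(100)]
        classified = [_classified(a.pos, a.label) for a in assessments]
        assert compute_metrics(assessments, set(), classified).fpr == 0.0

    def test_metrics_equal_brute_force_confusion_matrix(self, tiny_family):
        fam = tiny_family
        duo = read_joint_vcf(fam.father_duo_vcf, ["proband", "father"])
        trio = read_joint_vcf(fam.trio_vcf, ["proband", "father", "mother"])
        classified = classify_duo(duo, P, "proband", "father")
        assessments = assess_against_nonsequenced_parent(classified, trio, "mother")
        truth = trio_de_novo_truth(trio, P, "proband", "father", "mother")
        s = compute_metrics(assessments, truth, classified)

        verdicts = [a.verdict for a in assessments]
        cd, icd = verdicts.count(CORRECT_DN), verdicts.count(INCORRECT_DN)
        cn, icn = verdicts.count(CORRECT_NON_DN), verdicts.count(INCORRECT_NON_DN)
        if cd + icd:
            assert s.ppv == cd / (cd + icd)
        if cn + icn:
            assert s.npv == cn / (cn + icn)
        trans = [a for a in assessments if a.parent_has_allele]
        assert s.fpr == sum(1 for a in trans if a.label == LABEL_DE_NOVO) / len(trans)
        dn = {(c.chrom, c.pos) for c in classified if c.label == LABEL_DE_NOVO}
        assert s.sensitivity == len(truth & dn) / len(truth)

    def test_truth_breakdown_partition_sums_to_one(self, tiny_family):
        fam = tiny_family
        duo = read_joint_vcf(fam.father_duo_vcf, ["proband", "father"])
        trio = read_joint_vcf(fam.trio_vcf, ["proband", "father", "mother"])
        classified = classify_duo(duo, P, "proband", "father")
        assessments = assess_against_nonsequenced_parent(classified, trio, "mother")
        truth = trio_de_novo_truth(trio, P, "proband", "father", "mother")
        s = compute_metrics(assessments, truth, classified)
        assert sum(s.truth_breakdown.values()) == pytest.approx(1.0)

    def test_error_free_family_has_no_misclassified_truth(self, tiny_family):
        """On clean data no trio-truth de novo is called non-de-novo by BOTH duos.

        (A maternal de novo is correctly "inherited from the non-sequenced
        parent" in the father duo, and vice versa — only a variant labeled
        inherited from both duos would be genuinely misclassified.)
        """
        fam = tiny_family
        trio = read_joint_vcf(fam.trio_vcf, ["proband", "father", "mother"])
        truth = trio_de_novo_truth(trio, P, "proband", "father", "mother")
        labels = {}
        for vcf, parent in ((fam.father_duo_vcf, "father"), (fam.mother_duo_vcf, "mother")):
            duo = read_joint_vcf(vcf, ["proband", parent])
            classified = classify_duo(duo, P, "proband", parent)
            labels[parent] = {(c.chrom, c.pos): c.label for c in classified}
        for key in truth:
            assert not (labels["father"].get(key) == LABEL_INHERITED
                        and labels["mother"].get(key) == LABEL_INHERITED)


class TestMutationSpectrum:
    def test_classes(self):
        counts = mutation_spectrum(
            [("C", "T"), ("G", "A"), ("T", "G"), ("A", "C"), ("AT", "A"), ("A", "AG")])
        assert counts["C>T"] == 2      # G>A collapses by reverse complement
        assert counts["T>G"] == 2      # T>G itself plus A>C collapsed
        assert counts["T>C"] == 0
        assert counts["indel"] == 2
        assert sum(counts.values()) == 6


class TestParameterSweep:
    def test_singleton_grid_matches_classify_duo(self, tiny_family):
        fam = tiny_family
        duo = read_joint_vcf(fam.father_duo_vcf, ["proband", "father"])
        table = parameter_sweep(duo, [P], "proband", "father")
        classified = classify_duo(duo, P, "proband", "father")
        assert len(table) == 1
        row = table.iloc[0]
        assert row["n_candidates"] == len(classified)
        assert row["n_de_novo"] == sum(c.label == LABEL_DE_NOVO for c in classified)

    def test_threshold_and_margin_directions(self, tiny_family):
        fam = tiny_family
        duo = read_joint_vcf(fam.father_duo_vcf, ["proband", "father"])
        grid = [
            P,
            dataclasses.replace(P, hd_dissimilarity_threshold=0),
            dataclasses.replace(P, boundary_margin=0),
        ]
        table = parameter_sweep(duo, grid, "proband", "father")
        by_t = table.set_index("hd_dissimilarity_threshold")
        t0 = table[table.hd_dissimilarity_threshold == 0].iloc[0]
        t40 = table[(table.hd_dissimilarity_threshold == 40)
                    & (table.boundary_margin == 2000)].iloc[0]
        m0 = table[table.boundary_margin == 0].iloc[0]
        assert t0["n_de_novo"] >= t40["n_de_novo"]
        # relaxing the boundary margin can only add classified candidates
        assert m0["n_de_novo"] + m0["n_inherited"] >= t40["n_de_novo"] + t40["n_inherited"]


class TestSwappedDuoControl:
    def test_empty_candidate_set_returns_missing(self):
        assert swapped_duo_control([], P, "P", "F") is None
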