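"""Trio integration: presence, inheritance rules, compound-het pairing."""

import pytest

from prenataldx import synthdata as sd
from prenataldx import trio as tr
from prenataldx.cnv_lowpass import CnvCall
from prenataldx.trio import Candidate, InheritanceLabel, Trio
from prenataldx.wes_filter import MemberCall, VariantRecord, filter_variant_records

TRIO = Trio("T1", "F1", "M1", "C1", "male")


def variant(chrom="1", pos=100, father="0/0", mother="0/0", fetus="0/1",
            gene="G1", csq="missense", af=1e-4):
    return VariantRecord(
        chrom=chrom, pos=pos, ref="A", alt="T", gene_id=gene, consequence=csq,
        population_af=af,
        father=MemberCall(father, 99, 50, 0.01),
        mother=MemberCall(mother, 99, 50, 0.01),
        fetus=MemberCall(fetus, 99, 50, 0.01),
    )


def cnv(sample, chrom="1", start=1_000_000, end=2_000_000, state="loss", cn=1):
    return CnvCall(sample_id=sample, chrom=chrom, start=start, end=end,
                   mean_ratio=cn / 2, copy_number=cn, state=state, n_bins=50)


def candidate(payload, kind, presence, gene_ids=("G1",)):
    return Candidate(trio_id="T1", kind=kind, payload=payload,
                     gene_ids=gene_ids, presence=presence)


class TestIntegration:
    def test_fetal_variant_with_noncarrier_parents(self):
        cands = tr.integrate_trio_candidates([variant()], {}, TRIO)
        assert len(cands) == 1
        assert cands[0].presence == {"father": "0/0", "mother": "0/0", "fetus": "0/1"}

    def test_noncarrier_fetus_not_a_candidate(self):
        cands = tr.integrate_trio_candidates([variant(fetus="0/0")], {}, TRIO)
        assert cands == []

    def test_reciprocal_overlap_marks_parental_cnv_presence(self):
        cnvs = {
            "C1": [cnv("C1", start=1_000_000, end=2_000_000)],
            "F1": [cnv("F1", start=1_100_000, end=2_100_000)],
        }
        cands = tr.integrate_trio_candidates([], cnvs, TRIO)
        assert cands[0].presence == {"father": True, "mother": False, "fetus": True}

    def test_low_overlap_or_opposite_state_not_matched(self):
        cnvs = {
            "C1": [cnv("C1")],
            "F1": [cnv("F1", start=1_800_000, end=2_800_000)],  # 20% reciprocal
            "M1": [cnv("M1", state="gain", cn=3)],
        }
        cands = tr.integrate_trio_candidates([], cnvs, TRIO)
        assert cands[0].presence == {"father": False, "mother": False, "fetus": True}

    def test_empty_inputs_give_empty_candidates(self):
        assert tr.integrate_trio_candidates([], {}, TRIO) == []

    def test_unknown_sample_id_rejected(self):
        with pytest.raises(ValueError, match="not members"):
            tr.integrate_trio_candidates([], {"stranger": []}, TRIO)


class TestInheritanceRules:
    def _label(self, rec, trio=TRIO):
        cand = tr.integrate_trio_candidates([rec], {}, trio)[0]
        return tr.classify_inheritance(cand, trio)

    def test_de_novo(self):
        assert self._label(variant()) == InheritanceLabel.DE_NOVO

    def test_x_linked_maternal_male_fetus(self):
        rec = variant(chrom="X", father="0", mother="0/1", fetus="1")
        assert self._label(rec) == InheritanceLabel.X_LINKED_MATERNAL

    def test_x_het_in_female_fetus_is_maternal_not_xl(self):
        female = Trio("T2", "F1", "M1", "C1", "female")
        rec = variant(chrom="X", father="0", mother="0/1", fetus="0/1")
        assert self._label(rec, female) == InheritanceLabel.MATERNAL

    def test_biparental_homozygous(self):
        rec = variant(father="0/1", mother="0/1", fetus="1/1")
        assert self._label(rec) == InheritanceLabel.BIPARENTAL_HOMOZYGOUS

    def test_single_parent_carrier(self):
        assert self._label(variant(father="0/1")) == InheritanceLabel.PATERNAL
        assert self._label(variant(mother="0/1")) == InheritanceLabel.MATERNAL

    def test_both_parents_het_fetus_het_unclassified(self):
        rec = variant(father="0/1", mother="0/1", fetus="0/1")
        assert self._label(rec) == InheritanceLabel.UNCLASSIFIED

    def test_cnv_in_neither_parent_is_de_novo(self):
        cands = tr.integrate_trio_candidates([], {"C1": [cnv("C1")]}, TRIO)
        assert tr.classify_inheritance(cands[0], TRIO) == InheritanceLabel.DE_NOVO


class TestCompoundHet:
    def _pair(self, records, cnvs=None):
        cands = tr.integrate_trio_candidates(records, cnvs or {}, TRIO, genes=())
        tr.classify_all(cands, TRIO)
        return cands, tr.detect_compound_het(cands, TRIO)

    def test_paternal_cnv_plus_maternal_variant_pairs_certain(self):
        gene = type("G", (), {"gene_id": "G1", "chrom": "1",
                              "start": 900_000, "end": 2_100_000})()
        cnvs = {"C1": [cnv("C1")], "F1": [cnv("F1")]}
        records = [variant(pos=1_500_000, mother="0/1")]
        cands = tr.integrate_trio_candidates(records, cnvs, TRIO, genes=[gene])
        tr.classify_all(cands, TRIO)
        pairs = tr.detect_compound_het(cands, TRIO)
        assert len(pairs) == 1
        assert all(c.phase_confidence == "certain" for c in pairs[0])
        assert all(
            c.inheritance == InheritanceLabel.COMPOUND_HETEROZYGOUS for c in pairs[0]
        )

    def test_same_origin_pair_rejected_as_cis(self):
        records = [
            variant(pos=100, mother="0/1"),
            variant(pos=200, mother="0/1"),
        ]
        _, pairs = self._pair(records)
        assert pairs == []

    def test_de_novo_plus_inherited_pairs_possible(self):
        records = [
            variant(pos=100),
            variant(pos=200, father="0/1"),
        ]
        cands, pairs = self._pair(records)
        assert len(pairs) == 1
        assert pairs[0][0].phase_confidence == "possible"

    def test_common_polymorphisms_do_not_pair(self):
        records = [
            variant(pos=100, father="0/1", af=0.2),
            variant(pos=200, mother="0/1", af=0.3),
        ]
        _, pairs = self._pair(records)
        assert pairs == []

    def test_pairing_is_order_invariant(self):
        records = [
            variant(pos=100, father="0/1"),
            variant(pos=200, mother="0/1"),
        ]
        _, fwd = self._pair(records)
        _, rev = self._pair(list(reversed(records)))
        assert len(fwd) == len(rev) == 1
        assert fwd[0][0].payload.pos == rev[0][0].payload.pos


class TestDiagnosis:
    def test_cnv_plus_variant_is_double_diagnosis(self):
        v = candidate(variant(), "variant", {"father": "0/0"})
        c = candidate(cnv("C1"), "cnv", {"father": False})
        v.tier, c.tier = "P", "P"
        diag = tr.summarize_diagnosis([v, c], TRIO)
        assert diag.double_diagnosis

    def test_single_kind_is_not_double(self):
        c = candidate(cnv("C1"), "cnv", {"father": False})
        c.tier = "P"
        assert not tr.summarize_diagnosis([c], TRIO).double_diagnosis

    def test_empty_report_is_undiagnosed(self):
        diag = tr.summarize_diagnosis([], TRIO)
        assert not diag.diagnosed and not diag.double_diagnosis


class TestCohortRecovery:
    def test_mendelian_only_cohort_yields_no_de_novo_labels(self, default_model):
        rates = sd.CohortRates(denovo_rate=0.0, causal_fraction=0.0)
        cohort = sd.simulate_trio_cohort(default_model, n_trios=25, rates=rates, seed=61)
        for trio in cohort.trios:
            passed, _ = filter_variant_records(cohort.records[trio.trio_id], "fetus")
            cands = tr.integrate_trio_candidates(passed, {}, trio)
            tr.classify_all(cands, trio)
            assert all(c.inheritance != InheritanceLabel.DE_NOVO for c in cands)

    def test_planted_mechanisms_recovered_exactly(self, default_model, small_cohort):
        expected = {
            "ad_denovo_cnv": InheritanceLabel.DE_NOVO,
            "ad_denovo_snv": InheritanceLabel.DE_NOVO,
            "xl_maternal": InheritanceLabel.X_LINKED_MATERNAL,
            "ar_homozygous": InheritanceLabel.BIPARENTAL_HOMOZYGOUS,
            "ar_comphet_snv": InheritanceLabel.COMPOUND_HETEROZYGOUS,
            "ar_comphet_cnv_snv": InheritanceLabel.COMPOUND_HETEROZYGOUS,
        }

        def truth_call(c):
            return CnvCall(
                sample_id=c.sample_id, chrom=c.chrom, start=c.start, end=c.end,
                mean_ratio=c.copies / 2, copy_number=c.copies,
                state="loss" if c.copies < 2 else "gain",
                n_bins=max((c.end - c.start) // default_model.bin_size, 3),
                origin=c.channel,
            )

        checked = 0
        for trio, finding in zip(small_cohort.trios, small_cohort.truth.causal_findings):
            if finding.mechanism == "none":
                continue
            passed, _ = filter_variant_records(small_cohort.records[trio.trio_id], "fetus")
            cnvs = {
                m: [truth_call(c) for c in small_cohort.truth.cnvs_for(m)]
                for m in trio.member_ids
            }
            cands = tr.integrate_trio_candidates(passed, cnvs, trio, genes=default_model.genes)
            tr.classify_all(cands, trio)
            tr.detect_compound_het(cands, trio)
            want = expected[finding.mechanism]
            assert any(
                finding.gene_id in c.gene_ids and c.inheritance == want for c in cands
            ), (trio.trio_id, finding.mechanism)
            checked += 1
        assert checked > 0


class TestMendelianErrorRate:
    def test_clean_trio_has_zero_rate(self):
        records = [variant(father="0/1", mother="0/0", fetus="0/1", pos=p)
                   for p in range(1, 30)]
        assert tr.mendelian_error_rate(records, TRIO) == 0.0

    def test_contaminated_trio_flagged(self, caplog):
        records = [variant(father="0/0", mother="0/0", fetus="1/1", pos=p)
                   for p in range(1, 30)]
        rate = tr.mendelian_error_rate(records, TRIO)
        assert rate == 1.0
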