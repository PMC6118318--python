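"""Trio genetics: Mendelian classification, gamete-logic phasing against
simulator truth, de novo detection filters, the Poisson de novo burden
test and the Model-1/Model-2 carrier encodings."""

import numpy as np
import pandas as pd
import pytest

import triovar as tv
from triovar.cohort import MISSING, Status
from triovar.trio import MendelStatus, PhaseConfiguration

from conftest import panel_from_cohort


class TestCheckMendelian:
    @pytest.mark.parametrize("child,mother,father,expected", [
        (2, 0, 1, MendelStatus.INCONSISTENT),   # mother cannot transmit alt
        (1, 0, 0, MendelStatus.INCONSISTENT),   # candidate de novo
        (1, 1, 1, MendelStatus.CONSISTENT),
        (0, 2, 0, MendelStatus.INCONSISTENT),   # mother must transmit alt
        (2, 2, 2, MendelStatus.CONSISTENT),
        (1, MISSING, 0, MendelStatus.UNKNOWN),
        (MISSING, 0, 0, MendelStatus.UNKNOWN),
    ])
    def test_classification(self, child, mother, father, expected):
        assert tv.check_mendelian(child, mother, father) is expected

    def test_exhaustive_against_gamete_enumeration(self):
        for c in (0, 1, 2):
            for m in (0, 1, 2):
                for f in (0, 1, 2):
                    gametes = {0: (0,), 1: (0, 1), 2: (1,)}
                    ok = any(gm + gf == c for gm in gametes[m] for gf in gametes[f])
                    expected = MendelStatus.CONSISTENT if ok else MendelStatus.INCONSISTENT
                    assert tv.check_mendelian(c, m, f) is expected


class TestPhasePair:
    @pytest.mark.parametrize("mother,father,expected", [
        ((1, 0), (0, 1), PhaseConfiguration.TRANS),   # each parent gives one alt
        ((1, 1), (0, 0), PhaseConfiguration.CIS),     # both alts maternal
        ((1, 1), (1, 1), PhaseConfiguration.AMBIGUOUS),
        ((2, 0), (0, 2), PhaseConfiguration.TRANS),
        ((2, 2), (0, 0), PhaseConfiguration.CIS),
        ((MISSING, MISSING), (MISSING, MISSING), PhaseConfiguration.UNPHASABLE),
    ])
    def test_configurations(self, mother, father, expected):
        assert tv.phase_pair((1, 1), mother, father).configuration is expected

    def test_mendelian_inconsistency_flagged_without_phase(self):
        call = tv.phase_pair((1, 1), (0, 0), (0, 1))
        assert call.mendelian_error and call.configuration is None

    def test_requires_double_heterozygote(self):
        with pytest.raises(ValueError):
            tv.phase_pair((1, 2), (1, 1), (0, 1))

    def test_matches_simulator_truth_on_double_heterozygotes(self):
        """Non-ambiguous cis/trans calls agree with the generating haplotypes
        on >= 10,000 simulated double-heterozygous children, zero errors."""
        config = tv.SimulationConfig(
            n_trios=60_000, n_case_only=0, n_controls=0, missing_rate=0.0,
            variants=[tv.PanelVariant(0.3, 1.0, variant_id="a"),
                      tv.PanelVariant(0.3, 1.0, variant_id="b")],
            prevalence=0.5, de_novo_rate_snv=0, de_novo_rate_indel=0, seed=23)
        cohort = tv.simulate_cohort(config)
        gm, ped, truth = cohort.genotypes, cohort.pedigree, cohort.truth
        double_hets = called = errors = 0
        for child, mother, father in ped.complete_trios(gm.individuals):
            ci = gm.individual_index(child)
            if tuple(gm.calls[ci, :2]) != (1, 1):
                continue
            double_hets += 1
            mo = tuple(gm.calls[gm.individual_index(mother), :2])
            fa = tuple(gm.calls[gm.individual_index(father), :2])
            call = tv.phase_pair((1, 1), mo, fa)
            assert not call.mendelian_error
            if call.configuration in (PhaseConfiguration.CIS, PhaseConfiguration.TRANS):
                hap = truth.diplotypes[child]
                true_cis = hap[0, 0] == hap[0, 1]  # both alts on one gamete
                want = PhaseConfiguration.CIS if true_cis else PhaseConfiguration.TRANS
                errors += call.configuration is not want
                called += 1
        assert double_hets >= 10_000
        assert called > 0.5 * double_hets  # phase is usually resolvable
        assert errors == 0


def _ref_table(rows):
    counts = {}
    for key, pop, ac, an in rows:
        counts.setdefault(key, {})[pop] = (ac, an)
    return tv.ReferenceCountTable(counts)


class TestDetectDeNovo:
    def build(self, child_call, mother_call, father_call, extra_carrier=0):
        inds = ["kid", "mom", "dad", "ctl"]
        calls = np.array([[child_call], [mother_call], [father_call],
                          [extra_carrier]], dtype=np.int8)
        gm = tv.GenotypeMatrix(inds, [tv.VariantRecord("16", 100, "A", "G",
                                                       gene="G1")], calls)
        ped = tv.PedigreeTable(pd.DataFrame(
            [("F", "kid", "dad", "mom", "1", Status.CASE),
             ("F", "mom", "0", "0", "2", Status.PARENT),
             ("F", "dad", "0", "0", "1", Status.PARENT),
             ("C", "ctl", "0", "0", "1", Status.CONTROL)],
            columns=["family", "individual", "father", "mother", "sex", "status"]))
        return gm, ped

    def test_unique_candidate_retained(self):
        gm, ped = self.build(1, 0, 0)
        calls = tv.detect_de_novo(gm, ped, None)
        assert len(calls) == 1 and calls[0].trio_id == "kid"
        assert calls[0].cohort_occurrence == 1

    def test_reference_maf_above_half_percent_excluded(self):
        gm, ped = self.build(1, 0, 0)
        ref = _ref_table([((("16", 100, "A", "G")), "AFR", 60, 10000),   # 0.6%
                          ((("16", 100, "A", "G")), "NFE", 10, 10000)])
        assert tv.detect_de_novo(gm, ped, ref) == []
        # exactly 0.5% passes: the filter removes strictly greater
        ref_ok = _ref_table([((("16", 100, "A", "G")), "AFR", 50, 10000)])
        assert len(tv.detect_de_novo(gm, ped, ref_ok)) == 1

    def test_recurrent_carrier_excluded(self):
        gm, ped = self.build(1, 0, 0, extra_carrier=1)
        assert tv.detect_de_novo(gm, ped, None) == []

    def test_missing_parent_call_suppresses_candidate(self):
        gm, ped = self.build(1, MISSING, 0)
        assert tv.detect_de_novo(gm, ped, None) == []

    def test_full_recall_on_injected_events(self):
        config = tv.SimulationConfig(
            n_trios=120, n_case_only=0, n_controls=120, missing_rate=0.0,
            de_novo_rate_snv=5e-6, de_novo_rate_indel=1e-6, seed=31)
        cohort = tv.simulate_cohort(config)
        calls = tv.detect_de_novo(cohort.genotypes, cohort.pedigree, None)
        found = {(c.trio_id, c.variant.key) for c in calls}
        injected = {(cid, v.key) for cid, v in cohort.truth.de_novo_events}
        assert injected, "simulation produced no de novo events"
        assert injected <= found
        # every extra call must sit at a site with a masked/missing origin;
        # with missing_rate 0 there are none
        assert found == injected


class TestDeNovoBurden:
    def test_zero_observed_gives_one(self):
        assert tv.de_novo_burden_test(0, 3040, 179) == 1.0

    def test_single_event_closed_form(self):
        lam = 2 * 179 * 3040 * (1.2e-8 + 4e-10)
        p = tv.de_novo_burden_test(1, 3040, 179)
        assert p == pytest.approx(1 - np.exp(-lam), rel=1e-12)
        assert p == pytest.approx(0.0134, abs=5e-4)

    def test_zero_rate_degenerate(self):
        assert tv.de_novo_burden_test(1, 3040, 179, rate_snv=0, rate_indel=0) == 0.0

    def test_monotone_in_observed_and_rate(self):
        ps = [tv.de_novo_burden_test(k, 3040, 179) for k in range(5)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        p_small = tv.de_novo_burden_test(1, 3040, 179, rate_snv=1e-9)
        p_large = tv.de_novo_burden_test(1, 3040, 179, rate_snv=1e-7)
        assert p_small < p_large < 1


class TestCarrierEncoding:
    def build_cohort(self, genotypes, parent_genotypes=None):
        """genotypes: {individual: (g_common1, g_common2, g_rare)}; optional
        parent genotypes make individuals phasable."""
        variants = [tv.VariantRecord("16", 100, "A", "G", gene="G1", variant_id="c1"),
                    tv.VariantRecord("16", 200, "A", "G", gene="G1", variant_id="c2"),
                    tv.VariantRecord("16", 300, "A", "G", gene="G1", variant_id="r1")]
        inds, calls, rows = [], [], []
        parent_genotypes = parent_genotypes or {}
        for ind, g in genotypes.items():
            inds.append(ind)
            calls.append(g)
            status = Status.CASE if ind.startswith("case") else Status.CONTROL
            if ind in parent_genotypes:
                mo, fa = f"{ind}_mo", f"{ind}_fa"
                rows.append((ind, ind, fa, mo, "1", status))
            else:
                rows.append((ind, ind, "0", "0", "1", status))
        for ind, (gmo, gfa) in parent_genotypes.items():
            for pid, g, sex in ((f"{ind}_mo", gmo, "2"), (f"{ind}_fa", gfa, "1")):
                inds.append(pid)
                calls.append(g)
                rows.append((ind, pid, "0", "0", sex, Status.PARENT))
        gm = tv.GenotypeMatrix(inds, variants, np.array(calls, dtype=np.int8))
        ped = tv.PedigreeTable(pd.DataFrame(
            rows, columns=["family", "individual", "father", "mother", "sex", "status"]))
        panel = tv.Panel(common=(variants[0].key, variants[1].key),
                         rare=(variants[2].key,),
                         labels=tuple((v.key, v.variant_id) for v in variants))
        return gm, ped, panel

    def test_single_common_het_flagged_in_both_models(self):
        gm, ped, panel = self.build_cohort({"case1": (1, 0, 0), "ctrl1": (0, 0, 0)})
        enc = tv.build_carrier_encoding(gm, ped, panel)
        assert enc.model1.loc["case1", "het_c1"] == 1
        assert enc.model2.loc["case1", "het_c1"] == 1
        assert enc.model2.loc["case1", "compound_heterozygote"] == 0

    def test_trans_double_het_is_compound_only_in_model2(self):
        gm, ped, panel = self.build_cohort(
            {"case1": (1, 1, 0), "ctrl1": (0, 0, 0)},
            parent_genotypes={"case1": ((1, 0, 0), (0, 1, 0))})
        enc = tv.build_carrier_encoding(gm, ped, panel)
        # model 1 ignores phase: both het flags set
        assert enc.model1.loc["case1", ["het_c1", "het_c2"]].tolist() == [1, 1]
        # model 2: compound only, removed from het rows
        assert enc.model2.loc["case1", "compound_heterozygote"] == 1
        assert enc.model2.loc["case1", ["het_c1", "het_c2"]].tolist() == [0, 0]

    def test_ambiguous_double_het_not_compound(self):
        gm, ped, panel = self.build_cohort(
            {"case1": (1, 1, 0), "ctrl1": (0, 0, 0)},
            parent_genotypes={"case1": ((1, 1, 0), (1, 1, 0))})
        enc = tv.build_carrier_encoding(gm, ped, panel)
        assert enc.model2.loc["case1", "compound_heterozygote"] == 0
        assert enc.model2.loc["case1", ["het_c1", "het_c2"]].tolist() == [1, 1]

    def test_unphasable_double_het_not_compound(self):
        gm, ped, panel = self.build_cohort({"case1": (1, 1, 0), "ctrl1": (0, 0, 0)})
        enc = tv.build_carrier_encoding(gm, ped, panel)
        assert enc.model2.loc["case1", "compound_heterozygote"] == 0

    def test_homozygote_dominates_both_models(self):
        gm, ped, panel = self.build_cohort({"case1": (2, 0, 0), "ctrl1": (0, 0, 0)})
        enc = tv.build_carrier_encoding(gm, ped, panel)
        assert enc.model1.loc["case1", "any_homozygote"] == 1
        assert enc.model2.loc["case1", "common_homozygote"] == 1
        assert enc.model2.loc["case1", ["het_c1", "het_c2",
                                        "compound_heterozygote",
                                        "rare_heterozygote"]].sum() == 0

    def test_rare_het_only_without_common_carrier(self):
        gm, ped, panel = self.build_cohort({"case1": (0, 0, 1), "ctrl1": (0, 0, 0)})
        enc = tv.build_carrier_encoding(gm, ped, panel)
        assert enc.model2.loc["case1", "rare_heterozygote"] == 1

    def test_common_rare_trans_pair_is_compound(self):
        gm, ped, panel = self.build_cohort(
            {"case1": (1, 0, 1), "ctrl1": (0, 0, 0)},
            parent_genotypes={"case1": ((1, 0, 0), (0, 0, 1))})
        enc = tv.build_carrier_encoding(gm, ped, panel)
        assert enc.model2.loc["case1", "compound_heterozygote"] == 1
        assert enc.model2.loc["case1", "rare_heterozygote"] == 0

    def test_panel_variant_missing_from_matrix_rejected(self):
        gm, ped, panel = self.build_cohort({"case1": (0, 0, 0), "ctrl1": (0, 0, 0)})
        bad = tv.Panel(common=(("16", 999, "A", "G"),), rare=())
        with pytest.raises(tv.ConfigurationError):
            tv.build_carrier_encoding(gm, ped, bad)

    def test_model2_categories_partition_cohort(self, study_sized_cohort,
                                                study_encoding):
        """Every case/control lands in exactly one Model-2 category
        (counting the multi-het note as its het category)."""
        enc = study_encoding
        ped = study_sized_cohort.pedigree
        n_subjects = len(ped.cases) + len(ped.controls)
        assert len(enc.model2) == n_subjects
        exclusive = enc.model2[["common_homozygote", "compound_heterozygote",
                                "rare_heterozygote"]]
        assert (exclusive.sum(axis=1) <= 1).all()
        # het flags never co-occur with an exclusive category
        het_cols = [c for c in enc.model2.columns if c.startswith("het_")]
        overlap = (enc.model2[het_cols].sum(axis=1) > 0) & \
                  (exclusive.sum(axis=1) > 0)
        assert not overlap.any()
        # category notes cover the whole cohort
        counts = enc.provenance["category"].str.split(":").str[0].value_counts()
        assert counts.sum() == n_subjects

    def test_compound_carriers_reduce_model2_het_counts(self, study_encoding):
        """Mirrors the het-row shrinkage between the two published models."""
        het_cols = [c for c in study_encoding.model1.columns if c.startswith("het_")]
        m1 = study_encoding.model1[het_cols].sum().sum()
        m2 = study_encoding.model2[het_cols].sum().sum()
        n_compound = study_encoding.model2["compound_heterozygote"].sum()
        assert n_compound > 0
        assert m2 < m1
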