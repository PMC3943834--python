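import pytest

from paneldx.panel_io import VariantRecord
from paneldx.synthetic_fixtures import SimConfig, gen_variant_cohort
from paneldx.variant_triage import (
    TIERS,
    CohortRecord,
    TriageConfig,
    VariantSummary,
    classify,
    filter_candidates,
    gene_shares,
    summarize_cohort,
    summarize_variants,
    triage,
)


def snv(consequence="missense", quality=50.0, gene="GCK", pos=100, db_afs=None,
        predictor_calls=None, conserved=False, known_id=None, ref="A", alt="G",
        zygosity="het"):
    return VariantRecord(
        chrom="chr7", pos=pos, ref=ref, alt=alt, consequence=consequence,
        call_quality=quality, gene=gene, db_afs=db_afs or {},
        predictor_calls=predictor_calls or {}, conserved=conserved,
        known_pathogenic_id=known_id, depth=100, alt_fraction=0.5,
        zygosity=zygosity,
    )


class TestFilterCandidates:
    def test_clean_missense_kept(self):
        assert filter_candidates([snv(quality=35.0)]) == [snv(quality=35.0)]

    def test_synonymous_removed_regardless_of_quality(self):
        assert filter_candidates([snv("synonymous", quality=99.0)]) == []

    def test_common_variant_removed(self):
        v = snv(db_afs={"thousand_genomes": 0.05})
        assert filter_candidates([v]) == []

    def test_rare_in_every_database_kept(self):
        v = snv(db_afs={"thousand_genomes": 0.005, "esp": 0.002})
        assert filter_candidates([v]) == [v]

    def test_rare_in_one_common_in_other_removed(self):
        v = snv(db_afs={"thousand_genomes": 0.005, "esp": 0.2})
        assert filter_candidates([v]) == []

    def test_absent_from_all_databases_passes(self):
        assert filter_candidates([snv()]) == [snv()]

    def test_low_quality_removed(self):
        assert filter_candidates([snv(quality=19.9)]) == []

    def test_frameshift_indel_kept(self):
        v = VariantRecord(chrom="chr7", pos=5, ref="AT", alt="A",
                          consequence="frameshift", call_quality=50.0, gene="GCK")
        assert filter_candidates([v]) == [v]

    def test_intronic_indel_removed(self):
        v = VariantRecord(chrom="chr7", pos=5, ref="AT", alt="A",
                          consequence="intron", call_quality=50.0)
        assert filter_candidates([v]) == []

    def test_gene_restriction(self):
        cfg = TriageConfig(restrict_genes=frozenset({"HNF1A"}))
        assert filter_candidates([snv(gene="GCK")], cfg) == []
        assert filter_candidates([snv(gene="HNF1A")], cfg) == [snv(gene="HNF1A")]

    def test_unannotated_consequence_treated_as_nonfunctional(self):
        assert filter_candidates([snv(consequence="")]) == []

    def test_enumerated_fixture_matches_independent_oracle(self):
        """200 constructed variants, exactly 7 passing; filter output equals
        an independently coded predicate evaluation."""
        variants = []
        # 7 passers: functional, high quality, rare
        for i in range(7):
            variants.append(snv(pos=1000 + i, quality=40.0))
        # failures along each predicate axis
        for i in range(60):
            variants.append(snv("synonymous", pos=2000 + i))
        for i in range(60):
            variants.append(snv(pos=3000 + i, db_afs={"kg": 0.05}))
        for i in range(60):
            variants.append(snv(pos=4000 + i, quality=5.0))
        for i in range(13):
            variants.append(snv("intron", pos=5000 + i))
        assert len(variants) == 200

        def oracle(v):
            functional = (
                v.consequence in {"nonsense", "splice_site", "missense"}
                if v.vtype == "SNV"
                else v.consequence in {"frameshift", "inframe_indel", "splice_site"}
            )
            rare = all(af < 0.01 for af in v.db_afs.values())
            return functional and rare and v.call_quality >= 20.0

        expected = [v for v in variants if oracle(v)]
        got = filter_candidates(variants)
        assert got == expected
        assert len(got) == 7

    def test_idempotent_and_order_independent(self):
        variants = [snv(pos=p, quality=q) for p, q in
                    [(1, 50.0), (2, 10.0), (3, 99.0)]]
        once = filter_candidates(variants)
        assert filter_candidates(once) == once
        reversed_kept = filter_candidates(list(reversed(variants)))
        assert sorted(v.pos for v in reversed_kept) == sorted(v.pos for v in once)


KNOWN = {("chr7", 100, "A", "G"): {"gene": "GCK", "citation_id": "KP0001"}}


class TestClassify:
    def test_novel_nonsense_is_pathogenic(self):
        c = classify(snv("nonsense", pos=500), {})
        assert c.tier == "pathogenic" and "lof_stop_frameshift" in c.evidence

    def test_frameshift_is_pathogenic(self):
        v = VariantRecord(chrom="chr7", pos=5, ref="AT", alt="A",
                          consequence="frameshift", call_quality=50.0)
        assert classify(v, {}).tier == "pathogenic"

    def test_known_match_is_pathogenic(self):
        c = classify(snv(pos=100), KNOWN)
        assert c.tier == "pathogenic" and "known_pathogenic" in c.evidence

    def test_conserved_missense_is_suspected(self):
        c = classify(
            snv(pos=500, conserved=True, predictor_calls={"sift": "damaging"}), {}
        )
        assert c.tier == "suspected_pathogenic"
        assert "conserved_missense" in c.evidence

    def test_predictor_consensus_is_suspected(self):
        c = classify(
            snv(pos=500, predictor_calls={"sift": "damaging", "polyphen2": "damaging"}),
            {},
        )
        assert c.tier == "suspected_pathogenic"

    def test_single_damaging_verdict_is_not_enough(self):
        c = classify(
            snv(pos=500, predictor_calls={"sift": "damaging", "polyphen2": "benign",
                                          "mutationtaster": "benign", "bdgp": "benign"}),
            {},
        )
        assert c.tier == "unknown_significance"

    def test_min_damaging_predictors_configurable(self):
        v = snv(pos=500, predictor_calls={"sift": "damaging", "polyphen2": "damaging"})
        cfg = TriageConfig(min_damaging_predictors=3)
        assert classify(v, {}, cfg).tier == "unknown_significance"

    def test_control_database_hit_is_polymorphism(self):
        control = frozenset({("chr7", 500, "A", "G")})
        c = classify(snv(pos=500), {}, control_db=control)
        assert c.tier == "polymorphism" and "control_database" in c.evidence

    def test_splice_site_gt_at_with_panel(self, small_panel):
        inside = snv("splice_site", pos=201)  # within GCK splice_site 200-202
        outside = snv("splice_site", pos=150)  # inside the exon body
        assert classify(inside, {}, panel=small_panel).tier == "suspected_pathogenic"
        assert classify(outside, {}, panel=small_panel).tier == "unknown_significance"

    def test_every_variant_gets_exactly_one_tier_with_evidence(self):
        cohort = gen_variant_cohort(SimConfig(seed=2, n_samples=4))
        for sample, records in cohort.variants.items():
            for c in triage(records, cohort.knowledge, panel=cohort.panel):
                assert c.tier in TIERS
                assert c.evidence

    def test_adding_damaging_verdict_never_lowers_tier(self):
        rank = {t: i for i, t in enumerate(reversed(TIERS))}
        bases = [
            snv(pos=500),
            snv(pos=500, conserved=True),
            snv("nonsense", pos=500),
            snv(pos=500, predictor_calls={"sift": "damaging"}),
            snv(pos=500, predictor_calls={"sift": "damaging", "polyphen2": "damaging"}),
        ]
        for base in bases:
            before = classify(base, KNOWN).tier
            more = dict(base.predictor_calls)
            more[f"extra{len(more)}"] = "damaging"
            upgraded = snv(
                base.consequence, pos=base.pos, conserved=base.conserved,
                predictor_calls=more,
            )
            after = classify(upgraded, KNOWN).tier
            assert rank[after] >= rank[before]


class TestSummaries:
    def test_tally_by_class_and_zygosity(self):
        variants = [
            snv(pos=1), snv(pos=2, zygosity="hom"), snv("synonymous", pos=3),
            VariantRecord(chrom="c", pos=4, ref="AT", alt="A",
                          consequence="frameshift", zygosity="het"),
        ]
        s = summarize_variants(variants)
        assert s.snv_by_class == {"missense": 2, "synonymous": 1}
        assert s.snv_zygosity == {"het": 2, "hom": 1}
        assert s.indel_zygosity == {"het": 1}
        assert s.snv_zygosity_percents()["het"] == pytest.approx(66.67)

    def test_empty_input(self):
        s = summarize_variants([])
        assert s.total_snvs == 0 and s.snv_zygosity_percents() == {}

    def test_published_average_zygosity_ratios(self):
        s = VariantSummary.from_counts(
            snv_zygosity={"het": 9795.97, "hom": 4012.28},
            indel_zygosity={"het": 1927.41, "hom": 139.14},
        )
        assert s.snv_zygosity_percents() == {"het": 70.94, "hom": 29.06}
        assert s.indel_zygosity_percents() == {"het": 93.27, "hom": 6.73}


class TestCohortTable:
    def test_gene_share_rounding(self):
        records = [
            CohortRecord(sample_id=f"s{i}", pathogenic_gene="GCK" if i < 26 else "other")
            for i in range(70)
        ]
        assert gene_shares(records)["GCK"] == 37

    def test_single_record_degenerate_stats(self):
        r = CohortRecord(sample_id="s1", pathogenic_gene="GCK", sex="F",
                         age_at_examination=23.0, hba1c=6.5, treatment="diet")
        table = summarize_cohort([r])
        cell = table.loc["GCK", "age_at_examination"]
        assert cell == "23.00 (23-23) [0]"
        assert table.loc["Total", "n"] == 1

    def test_field_missing_everywhere_reported_na(self):
        records = [CohortRecord(sample_id=f"s{i}", pathogenic_gene="GCK")
                   for i in range(3)]
        table = summarize_cohort(records)
        assert table.loc["GCK", "hba1c"] == "NA [3]"

    def test_missing_values_excluded_from_mean(self):
        records = [
            CohortRecord(sample_id="a", pathogenic_gene="GCK", hba1c=6.0),
            CohortRecord(sample_id="b", pathogenic_gene="GCK", hba1c=8.0),
            CohortRecord(sample_id="c", pathogenic_gene="GCK"),
        ]
        assert summarize_cohort(records).loc["GCK", "hba1c"] == "7.00 (6-8) [1]"

    def test_inconsistent_bmi_rejected(self):
        with pytest.raises(ValueError, match="bmi"):
            CohortRecord(sample_id="x", height=170.0, weight=70.0, bmi=30.0)


class TestCandidateBand:
    def test_default_cohort_candidates_in_3_to_10_band(self):
        cohort = gen_variant_cohort(SimConfig(seed=4, n_samples=8))
        for sample, records in cohort.variants.items():
            n = len(filter_candidates(records))
            assert 3 <= n <= 10
            assert n == cohort.expected_candidates[sample]
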