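"""Generator contracts: determinism, model invariants, planted-signal means."""

import json
import math

import numpy as np
import pytest

from prenataldx import synthdata as sd


class TestGenomeModel:
    def test_bin_layout_forced_by_lengths(self):
        cfg = sd.SimulationConfig(
            chromosomes=(("1", 10_000_000), ("2", 10_000_000), ("X", 5_000_000))
        )
        model = sd.build_genome_model(cfg, seed=1)
        assert [model.n_bins(c) for c in ("1", "2", "X")] == [500, 500, 250]
        assert model.total_bins == 1250

    def test_same_seed_gives_byte_identical_model(self):
        cfg = sd.SimulationConfig()
        a = sd.build_genome_model(cfg, seed=7)
        b = sd.build_genome_model(cfg, seed=7)
        assert a.to_json() == b.to_json()

    def test_different_seed_changes_layout(self):
        cfg = sd.SimulationConfig()
        a = sd.build_genome_model(cfg, seed=7)
        b = sd.build_genome_model(cfg, seed=8)
        assert a.to_json() != b.to_json()

    def test_three_level_branching_three_ontology_has_13_terms(self):
        onto = sd.build_toy_ontology(levels=3, branching=3, gene_ids=["g1", "g2"])
        assert len(onto.terms) == 1 + 3 + 9
        for term in onto.terms:
            assert onto.root in onto.ancestors_or_self(term)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            sd.build_genome_model(sd.SimulationConfig(bin_size=0), seed=1)
        with pytest.raises(ValueError):
            sd.build_genome_model(sd.SimulationConfig(chromosomes=()), seed=1)
        with pytest.raises(ValueError):
            sd.build_genome_model(
                sd.SimulationConfig(chromosomes=(("1", 1_000_000),)), seed=1
            )

    def test_exons_sorted_nonoverlapping_and_genes_annotated(self, default_model):
        for gene in default_model.genes:
            exons = default_model.gene_exons(gene.gene_id)
            assert exons, gene.gene_id
            for a, b in zip(exons, exons[1:]):
                assert a.end <= b.start
            assert gene.hpo_terms

    def test_every_term_reachable_from_an_annotated_gene(self, default_model):
        onto = default_model.ontology
        covered = set()
        for gene in onto.gene_annotations:
            covered |= onto.gene_closure(gene)
        assert covered == onto.terms


class TestLowpassCounts:
    def test_mean_bin_count_matches_poisson_expectation(self):
        cfg = sd.SimulationConfig(
            chromosomes=(("1", 25_000_000), ("2", 25_000_000), ("X", 10_000_000))
        )
        model = sd.build_genome_model(cfg, seed=1)
        assert model.total_bins == 3000
        counts, _ = sd.simulate_lowpass_counts(
            model,
            sd.TruthSet(),
            ["s1"],
            depth=5_000_000,
            seed=2,
            noise=sd.LowpassNoise(bias_sigma=0.0, batch_sigma=0.0),
        )
        expected = 5_000_000 * 20_000 / 60_000_000  # 1666.7
        assert counts["s1"].mean() == pytest.approx(expected, rel=0.01)

    def test_het_deletion_bins_run_at_half_depth(self, default_model):
        truth = sd.TruthSet(
            planted_cnvs=[sd.PlantedCnv("s1", "1", 2_000_000, 4_000_000, 1, "denovo")]
        )
        counts, truth2 = sd.simulate_lowpass_counts(
            default_model,
            truth,
            ["s1"],
            depth=5_000_000,
            seed=3,
            noise=sd.LowpassNoise(bias_sigma=0.0, batch_sigma=0.0),
        )
        on_1 = counts[counts["chrom"] == "1"]
        inside = on_1[(on_1["start"] >= 2_000_000) & (on_1["start"] < 4_000_000)]["s1"]
        outside = on_1[(on_1["start"] < 2_000_000) | (on_1["start"] >= 4_000_000)]["s1"]
        assert inside.mean() == pytest.approx(0.5 * outside.mean(), rel=0.05)

    def test_planted_ratio_within_monte_carlo_error(self, default_model):
        # empirical mean ratio of event bins vs copies/2, 3 MC standard errors
        copies = 3
        truth = sd.TruthSet(
            planted_cnvs=[sd.PlantedCnv("s1", "2", 1_000_000, 3_000_000, copies, "denovo")]
        )
        counts, _ = sd.simulate_lowpass_counts(
            default_model,
            truth,
            ["s1"],
            depth=2_500_000,  # >= 1000 expected reads/bin on 25 Mb / 1250 bins
            seed=4,
            noise=sd.LowpassNoise(bias_sigma=0.0, batch_sigma=0.0),
        )
        per_bin = 2_500_000 * 20_000 / default_model.genome_size
        on_2 = counts[counts["chrom"] == "2"]
        inside = on_2[(on_2["start"] >= 1_000_000) & (on_2["start"] < 3_000_000)]["s1"]
        ratio = inside.mean() / per_bin
        se = math.sqrt(copies / 2 * per_bin) / per_bin / math.sqrt(len(inside))
        assert abs(ratio - copies / 2) <= 3 * se

    def test_zero_depth_gives_all_zero_matrix(self, default_model):
        counts, _ = sd.simulate_lowpass_counts(
            default_model, sd.TruthSet(), ["s1", "s2"], depth=0, seed=5
        )
        assert (counts[["s1", "s2"]].to_numpy() == 0).all()

    def test_cnv_outside_bounds_rejected(self, default_model):
        truth = sd.TruthSet(
            planted_cnvs=[sd.PlantedCnv("s1", "X", 0, 99_000_000, 1, "denovo")]
        )
        with pytest.raises(ValueError, match="outside chromosome bounds"):
            sd.simulate_lowpass_counts(default_model, truth, ["s1"], seed=1)

    def test_truth_coordinates_snap_to_bin_boundaries(self, default_model):
        truth = sd.TruthSet(
            planted_cnvs=[sd.PlantedCnv("s1", "1", 2_010_123, 3_999_999, 1, "denovo")]
        )
        _, truth2 = sd.simulate_lowpass_counts(default_model, truth, ["s1"], seed=1)
        cnv = truth2.planted_cnvs[0]
        assert cnv.start == 2_000_000 and cnv.end == 4_000_000

    def test_deterministic_for_fixed_seed(self, default_model):
        a, _ = sd.simulate_lowpass_counts(default_model, sd.TruthSet(), ["s1"], seed=9)
        b, _ = sd.simulate_lowpass_counts(default_model, sd.TruthSet(), ["s1"], seed=9)
        assert a.equals(b)


class TestExonDepths:
    def test_noise_free_matrix_is_rank_one(self, default_model):
        depths, _ = sd.simulate_exon_depths(
            default_model,
            sd.TruthSet(),
            [f"s{i}" for i in range(12)],
            seed=1,
            noise=sd.ExonNoise(noise_sigma=0.0, n_latent=0),
        )
        s = np.linalg.svd(depths.to_numpy(), compute_uv=False)
        assert s[1] / s[0] < 1e-12

    def test_homozygous_deletion_zeroes_its_exons(self, default_model):
        gene = default_model.genes[0]
        exs = default_model.gene_exons(gene.gene_id)
        truth = sd.TruthSet(
            planted_cnvs=[
                sd.PlantedCnv(
                    "s0", gene.chrom, exs[0].start, exs[2].end, 0, "denovo",
                    channel="exonic",
                )
            ]
        )
        depths, exons = sd.simulate_exon_depths(
            default_model, truth, [f"s{i}" for i in range(12)], seed=2
        )
        inside = (
            (exons["chrom"] == gene.chrom)
            & (exons["start"] >= exs[0].start)
            & (exons["start"] < exs[2].end)
        )
        assert (depths.loc["s0"].to_numpy()[inside.to_numpy()] == 0).all()

    def test_het_deletion_runs_at_half_cohort_depth(self, default_model):
        gene = default_model.genes[5]
        exs = default_model.gene_exons(gene.gene_id)
        truth = sd.TruthSet(
            planted_cnvs=[
                sd.PlantedCnv(
                    "s0", gene.chrom, exs[0].start, exs[4].end, 1, "pat",
                    channel="exonic",
                )
            ]
        )
        samples = [f"s{i}" for i in range(50)]
        depths, exons = sd.simulate_exon_depths(default_model, truth, samples, seed=3)
        inside = (
            (exons["chrom"] == gene.chrom)
            & (exons["start"] >= exs[0].start)
            & (exons["start"] < exs[4].end)
        ).to_numpy()
        # normalize out per-sample library size before comparing dosage
        mat = depths.to_numpy()
        lib = mat[:, ~inside].mean(axis=1)
        rel = mat / lib[:, None]
        carrier = rel[0, inside].mean()
        cohort = rel[1:, inside].mean()
        assert carrier == pytest.approx(0.5 * cohort, rel=0.10)

    def test_small_cohort_rejected(self, default_model):
        with pytest.raises(ValueError, match=">= 10 samples"):
            sd.simulate_exon_depths(default_model, sd.TruthSet(), ["s1"], seed=1)


class TestTrioCohort:
    def test_mendelian_only_cohort_has_no_transmission_violations(self, default_model):
        rates = sd.CohortRates(denovo_rate=0.0, causal_fraction=0.0)
        cohort = sd.simulate_trio_cohort(default_model, n_trios=30, rates=rates, seed=21)
        for trio in cohort.trios:
            for rec in cohort.records[trio.trio_id]:
                f, m, k = rec.father, rec.mother, rec.fetus
                if rec.chrom == "X" and trio.fetal_sex == "male":
                    assert k.genotype in set(m.genotype.split("/"))
                else:
                    pat = set(f.genotype.split("/"))
                    mat = set(m.genotype.split("/"))
                    a, b = k.genotype.split("/")
                    assert (a in pat and b in mat) or (a in mat and b in pat)

    def test_xl_mechanism_structure(self, default_model):
        rates = sd.CohortRates(causal_fraction=1.0, ad_fraction=0.0, xl_fraction=1.0,
                               ar_hom_fraction=0.0, ar_comphet_snv_fraction=0.0,
                               ar_comphet_cnv_snv_fraction=0.0)
        cohort = sd.simulate_trio_cohort(default_model, n_trios=10, rates=rates, seed=22)
        for trio, finding in zip(cohort.trios, cohort.truth.causal_findings):
            assert finding.mechanism == "xl_maternal"
            assert trio.fetal_sex == "male"
            var = finding.variants[0]
            rec = next(
                r
                for r in cohort.records[trio.trio_id]
                if (r.chrom, r.pos) == (var.chrom, var.pos)
            )
            assert rec.fetus.genotype == "1"
            assert rec.mother.genotype == "0/1"
            assert rec.father.genotype == "0"

    def test_comphet_cnv_snv_truth_has_opposite_origins(self, default_model):
        rates = sd.CohortRates(causal_fraction=1.0, ad_fraction=0.0, xl_fraction=0.0,
                               ar_hom_fraction=0.0, ar_comphet_snv_fraction=0.0,
                               ar_comphet_cnv_snv_fraction=1.0)
        cohort = sd.simulate_trio_cohort(default_model, n_trios=10, rates=rates, seed=23)
        for trio, finding in zip(cohort.trios, cohort.truth.causal_findings):
            assert finding.mechanism == "ar_comphet_cnv_snv"
            assert finding.cnv is not None and len(finding.variants) == 1
            assert {finding.cnv.parental_origin, finding.variants[0].origin} == {"pat", "mat"}
            assert finding.cnv.gene_id == finding.variants[0].gene_id
            # carrier parent holds the same event
            carrier = (
                trio.father_id if finding.cnv.parental_origin == "pat" else trio.mother_id
            )
            assert any(
                c.sample_id == carrier and c.start == finding.cnv.start
                for c in cohort.truth.planted_cnvs
            )

    def test_invalid_rates_rejected(self, default_model):
        with pytest.raises(ValueError):
            sd.simulate_trio_cohort(
                default_model, 5, rates=sd.CohortRates(denovo_rate=1.5), seed=1
            )

    def test_deterministic_for_fixed_seed(self, default_model):
        a = sd.simulate_trio_cohort(default_model, n_trios=5, seed=31)
        b = sd.simulate_trio_cohort(default_model, n_trios=5, seed=31)
        assert a.truth.to_dict() == b.truth.to_dict()
        assert a.phenotypes == b.phenotypes
        assert all(a.records[t.trio_id] == b.records[t.trio_id] for t in a.trios)


class TestFixtureRoundTrip:
    def test_write_then_read_reproduces_objects(self, default_model, tmp_path):
        cohort = sd.simulate_trio_cohort(default_model, n_trios=8, seed=41)
        counts, cohort.truth = sd.simulate_lowpass_counts(
            default_model, cohort.truth, [t.fetus_id for t in cohort.trios], seed=42
        )
        depths, exons = sd.simulate_exon_depths(
            default_model, cohort.truth, [m for t in cohort.trios for m in t.member_ids],
            seed=43,
        )
        sd.write_fixtures(tmp_path, default_model, cohort, counts, depths, exons)
        model2, cohort2 = sd.read_fixtures(tmp_path)
        assert model2.to_json() == default_model.to_json()
        assert cohort2.truth.to_dict() == cohort.truth.to_dict()
        assert cohort2.phenotypes == cohort.phenotypes
        assert cohort2.trios == cohort.trios
        for t in cohort.trios:
            assert cohort2.records[t.trio_id] == cohort.records[t.trio_id]

    def test_truth_serialization_is_lossless(self, default_model):
        cohort = sd.simulate_trio_cohort(default_model, n_trios=15, seed=44)
        round_tripped = sd.TruthSet.from_dict(
            json.loads(json.dumps(cohort.truth.to_dict()))
        )
        assert round_tripped.to_dict() == cohort.truth.to_dict()

    def test_vcf_is_standard_and_bed_is_half_open(self, default_model, tmp_path):
        import pysam

        cohort = sd.simulate_trio_cohort(default_model, n_trios=4, seed=45)
        paths = sd.write_fixtures(tmp_path, default_model, cohort)
        with pysam.VariantFile(str(paths["vcf"])) as vcf:
            assert "GT" in vcf.header.formats
            assert "GQ" in vcf.header.formats
            assert "DP" in vcf.header.formats
            n = sum(1 for _ in vcf)
        assert n > 0
        for line in paths["truth_cnv"].read_text().splitlines():
            chrom, start, end, name = line.split("\t")
            matches = [
                c
                for c in cohort.truth.planted_cnvs
                if (c.chrom, c.start, c.end) == (chrom, int(start), int(end))
            ]
            assert matches, line
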