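"""Simulator behaviour: segregation ratios, map function, calibration, I/O."""

import math

import numpy as np
import pandas as pd
import pytest

from bulkscan.simulate import (
    SimConfig,
    SimulationError,
    marker_table,
    simulate_dataset,
    simulate_f2,
    simulate_phenotypes,
    simulate_pool_reads,
)
from bulkscan.variant_io import variant_table


def _dosage_matrix(genotypes):
    return np.stack([g.dosage for g in genotypes])


class TestMeiosis:
    def test_no_crossover_limit_gives_constant_haplotypes(self):
        # infinite bp/cM -> zero map length -> each gamete is one parent chromosome
        cfg = SimConfig(
            n_f2=30,
            bulk_size=5,
            chrom_lengths={"chr1": 1_000_000},
            snp_density=50,
            qtl=(),
            bp_per_cm=float("inf"),
            seed=3,
        )
        dosage = _dosage_matrix(simulate_f2(cfg))
        assert (dosage == dosage[:, [0]]).all(), "dosage must be constant along the chromosome"

    def test_f2_segregation_is_1_2_1(self):
        cfg = SimConfig(
            n_f2=10_000,
            bulk_size=50,
            chrom_lengths={"chr1": 500_000},
            snp_density=10,
            qtl=(),
            seed=5,
        )
        dosage = _dosage_matrix(simulate_f2(cfg))[:, 0]
        n = len(dosage)
        for k, p in ((0, 0.25), (1, 0.5), (2, 0.25)):
            se = math.sqrt(p * (1 - p) / n)
            assert abs((dosage == k).mean() - p) < 3 * se

    def test_recombinant_fraction_matches_haldane(self):
        # two loci 1 cM apart: r = (1 - exp(-0.02)) / 2
        cfg = SimConfig(
            n_f2=8_000,
            bulk_size=50,
            chrom_lengths={"chr1": 20_000_000},
            snp_density=0,
            qtl=(
                ("chr1", 10_000_000, 0.0, 0.0),
                ("chr1", 10_250_000, 0.0, 0.0),
            ),
            seed=7,
        )
        markers = marker_table(cfg)
        assert len(markers) == 2
        dosage = _dosage_matrix(simulate_f2(cfg, markers))
        # gametes are not directly observable from dosage; use double heterozygote
        # avoidance: count plants discordant at the two loci
        expected_r = (1 - math.exp(-0.02)) / 2
        # P(discordant dosage) for two independent meioses each recombinant w.p. r:
        # dosage differs unless both gametes agree at the loci; to leading order
        # P(d1 != d2) ~ 2r for small r
        observed = (dosage[:, 0] != dosage[:, 1]).mean()
        se = math.sqrt(2 * expected_r * (1 - 2 * expected_r) / cfg.n_f2)
        assert abs(observed - 2 * expected_r) < 4 * se

    def test_qtl_on_unknown_chromosome_rejected(self):
        with pytest.raises(SimulationError, match="chromosome"):
            SimConfig(chrom_lengths={"chr1": 1_000_000}, qtl=(("chr9", 10, 0.1, 0.0),))


class TestPhenotypes:
    def test_no_effect_no_noise_is_constant_baseline(self):
        cfg = SimConfig(
            n_f2=20,
            bulk_size=5,
            chrom_lengths={"chr1": 1_000_000},
            qtl=(),
            resid_sd=0.0,
            seed=1,
        )
        pheno = simulate_phenotypes(simulate_f2(cfg), cfg)
        assert np.allclose(pheno["fertility"], cfg.baseline_mu)

    def test_homozygous_qtl_shifts_by_additive_effect(self):
        cfg = SimConfig(
            n_f2=200,
            bulk_size=20,
            chrom_lengths={"chr1": 1_000_000},
            snp_density=2,
            qtl=(("chr1", 500_000, 0.2, 0.0),),
            resid_sd=0.0,
            f3_family_size=1,  # phenotype the F2 plant itself: exact formula
            seed=9,
        )
        markers = marker_table(cfg)
        genotypes = simulate_f2(cfg, markers)
        pheno = simulate_phenotypes(genotypes, cfg, markers)
        (j,) = markers.index[markers["is_qtl"]].to_numpy()
        dosage = np.array([g.dosage[j] for g in genotypes])
        hom = dosage == 2
        assert hom.any()
        assert np.allclose(pheno.loc[hom, "fertility"], cfg.baseline_mu + 0.2)

    def test_default_design_fertility_sd_envelope(self):
        # study-scale design: total SD near 0.1847 across seeds
        sds = []
        for seed in range(20):
            cfg = SimConfig(
                chrom_lengths={"chr8": 10_000_000},
                qtl=(("chr8", 4_000_000, 0.18, 0.0),),
                snp_density=2,
                seed=seed,
            )
            pheno = simulate_phenotypes(simulate_f2(cfg), cfg)
            sds.append(pheno["fertility"].std(ddof=1))
        assert all(0.13 <= sd <= 0.24 for sd in sds)
        assert abs(np.mean(sds) - 0.1847) < 0.02

    def test_grain_counts_sum_to_panicle_and_track_fertility(self, small_config):
        pheno = simulate_phenotypes(simulate_f2(small_config), small_config)
        total = pheno[["N_FG", "N_PG", "N_EG"]].sum(axis=1)
        assert (total == small_config.panicle_grains).all()
        observed = (pheno["N_FG"] + pheno["N_PG"]) / total
        assert np.corrcoef(observed, pheno["fertility"])[0, 1] > 0.95


class TestPoolReads:
    def _fixed_bulks(self, cfg):
        genotypes = simulate_f2(cfg)
        ids = [g.plant_id for g in genotypes]
        k = cfg.bulk_size
        return genotypes, {"T": ids[:k], "S": ids[k : 2 * k]}

    def test_fixed_pool_without_error_supports_only_hhz(self):
        cfg = SimConfig(
            n_f2=10,
            bulk_size=5,
            chrom_lengths={"chr1": 1_000_000},
            snp_density=30,
            qtl=(),
            seq_error=0.0,
            bp_per_cm=float("inf"),
            seed=2,
        )
        genotypes = simulate_f2(cfg)
        # force every pooled plant to be dosage 2 at all sites
        hhz_plants = [g for g in genotypes if (g.dosage == 2).all()]
        assert hhz_plants, "seeded draw must contain at least one doubled-HHZ plant"
        bulks = {"T": [hhz_plants[0].plant_id], "S": [genotypes[0].plant_id]}
        sites = simulate_pool_reads(genotypes, bulks, cfg)
        assert (sites["t_hhz"] == sites["t_depth"]).all()

    def test_balanced_pool_mean_ratio_is_half(self):
        cfg = SimConfig(
            n_f2=4,
            bulk_size=2,
            chrom_lengths={"chr1": 50_000_000},
            snp_density=200,  # ~10,000 sites
            qtl=(),
            seq_error=0.0,
            bp_per_cm=float("inf"),
            seed=4,
        )
        genotypes = simulate_f2(cfg)
        het_like = [g.plant_id for g in genotypes]
        # pool all plants: E[f] = 0.5 marginally over meiosis
        sites = simulate_pool_reads(genotypes, {"T": het_like, "S": het_like[:2]}, cfg)
        ratio = sites["t_hhz"].sum() / sites["t_depth"].sum()
        se = 0.5 / math.sqrt(sites["t_depth"].sum())
        # gametes are shared across sites (no recomb), so allow genotype noise too
        geno_se = 0.5 / math.sqrt(2 * len(het_like))
        assert abs(ratio - 0.5) < 3 * (se + geno_se)

    def test_expected_snp_index_includes_error_term(self):
        # E[index] = (1-2e)f + e, checked at f=1 where it is 1-e
        eps = 0.05
        cfg = SimConfig(
            n_f2=10,
            bulk_size=5,
            chrom_lengths={"chr1": 50_000_000},
            snp_density=200,
            qtl=(),
            seq_error=eps,
            bp_per_cm=float("inf"),
            seed=6,
        )
        genotypes = simulate_f2(cfg)
        hhz_plants = [g.plant_id for g in genotypes if (g.dosage == 2).all()]
        assert hhz_plants
        sites = simulate_pool_reads(genotypes, {"T": hhz_plants[:1], "S": [0]}, cfg)
        expected = (1 - 2 * eps) * 1.0 + eps
        total = sites["t_depth"].sum()
        observed = sites["t_hhz"].sum() / total
        se = math.sqrt(expected * (1 - expected) / total)
        assert abs(observed - expected) < 3 * se

    def test_half_error_rate_rejected(self):
        with pytest.raises(SimulationError, match="seq_error"):
            SimConfig(seq_error=0.5)

    def test_empty_bulk_rejected(self, small_config):
        genotypes = simulate_f2(small_config)
        with pytest.raises(SimulationError, match="empty"):
            simulate_pool_reads(genotypes, {"T": []}, small_config)


class TestBulkSignal:
    def test_tolerant_bulk_carries_more_hhz_at_qtl(self):
        # planted a >= 0.15, resid_sd <= 0.12: tail bulks must separate at the QTL
        from bulkscan.phenotyping import select_bulks

        wins = 0
        for seed in range(20):
            cfg = SimConfig(
                n_f2=120,
                bulk_size=25,
                chrom_lengths={"chr1": 5_000_000},
                snp_density=5,
                qtl=(("chr1", 2_000_000, 0.15, 0.0),),
                resid_sd=0.12,
                seed=seed,
            )
            markers = marker_table(cfg)
            genotypes = simulate_f2(cfg, markers)
            pheno = simulate_phenotypes(genotypes, cfg, markers)
            design = select_bulks(pheno.set_index("plant_id")["fertility"], cfg.bulk_size)
            (j,) = markers.index[markers["is_qtl"]].to_numpy()
            dos = {g.plant_id: g.dosage[j] for g in genotypes}
            mean_t = np.mean([dos[i] for i in design.tolerant_ids])
            mean_s = np.mean([dos[i] for i in design.sensitive_ids])
            wins += mean_t > mean_s
        assert wins == 20


class TestDatasetIO:
    def test_vcf_round_trip_preserves_sites_and_depths(self, small_dataset):
        config, paths = small_dataset
        table, report = variant_table(paths["vcf"])
        markers = marker_table(config)
        assert report["input"] == len(markers)
        assert report["kept"] == len(markers)
        assert list(table["pos"]) == list(markers["pos"])
        # depth round trip against the in-memory generator output
        genotypes = simulate_f2(config, markers)
        from bulkscan.phenotyping import select_bulks

        pheno = simulate_phenotypes(genotypes, config, markers)
        design = select_bulks(pheno.set_index("plant_id")["fertility"] * 100, config.bulk_size)
        sites = simulate_pool_reads(
            genotypes, {"T": design.tolerant_ids, "S": design.sensitive_ids}, config, markers
        )
        assert (table["t_ref"] + table["t_alt"]).tolist() == sites["t_depth"].tolist()
        assert (table["s_ref"] + table["s_alt"]).tolist() == sites["s_depth"].tolist()

    def test_positions_strictly_increasing_per_chromosome(self, small_dataset):
        _, paths = small_dataset
        table, _ = variant_table(paths["vcf"])
        for _, sub in table.groupby("chrom"):
            assert (np.diff(sub["pos"]) > 0).all()

    def test_dataset_is_byte_identical_across_runs(self, small_config, tmp_path):
        a = simulate_dataset(small_config, tmp_path / "a")
        b = simulate_dataset(small_config, tmp_path / "b")
        for key in ("vcf", "phenotypes", "bulks", "gff3", "truth"):
            assert a[key].read_bytes() == b[key].read_bytes(), key

    def test_truth_file_names_disjoint_full_bulks(self, small_dataset):
        import json

        config, paths = small_dataset
        truth = json.loads(paths["truth"].read_text())
        tol, sen = set(truth["tolerant_ids"]), set(truth["sensitive_ids"])
        assert len(tol) == len(sen) == config.bulk_size
        assert not (tol & sen)
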