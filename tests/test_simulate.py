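"""Determinism, planted-signal, and calibration checks for the simulators."""

import numpy as np
import pytest

from bagwas.assoc import AlleleTable2x2, allelic_test, association_scan
from bagwas.mapping import map_snps_to_genes
from bagwas.molecular import eqtl_correlation
from bagwas.network import assemble_network, first_neighbors, hypergeom_enrich
from bagwas.phenotypes import ttest_unpaired
from bagwas.simulate import (
    NetworkSimSpec,
    PhenotypeGroupSpec,
    SimulationConfig,
    simulate_expression,
    simulate_gene_annotation,
    simulate_genotypes,
    simulate_network,
    simulate_phenotype_table,
)


class TestSimulateGenotypes:
    def test_identical_seed_identical_output(self):
        cfg = SimulationConfig(seed=4, n_cases=20, n_controls=50, n_null_snps=100,
                               missing_rate=0.05)
        a = simulate_genotypes(cfg)
        b = simulate_genotypes(cfg)
        assert a.matrix == b.matrix
        assert a.risk_snp_ids == b.risk_snp_ids

    def test_zero_missing_rate(self):
        cfg = SimulationConfig(seed=2, n_cases=10, n_controls=20, n_null_snps=50)
        panel = simulate_genotypes(cfg)
        assert not np.isnan(panel.matrix.dosage).any()

    def test_planted_frequency_within_binomial_error(self):
        cfg = SimulationConfig(seed=1, fst=0.0, n_cases=1000, n_controls=1000,
                               n_null_snps=10, risk_maf_case=0.2, risk_maf_control=0.2)
        panel = simulate_genotypes(cfg)
        m = panel.matrix
        f = m.allele_frequency()[m.snp_index("risk_a")]
        se = np.sqrt(0.2 * 0.8 / (2 * 2000))
        assert abs(f - 0.2) < 4 * se

    def test_planted_or_matches_study_conditions(self):
        """Monte-Carlo check against the odds ratio implied by the planted MAFs."""
        cfg = SimulationConfig(seed=7, n_cases=630, n_controls=19070, n_null_snps=2,
                               risk_maf_case=0.2857, risk_maf_control=0.1308)
        panel = simulate_genotypes(cfg)
        df = association_scan(panel.matrix).set_index("snp_id")
        assert 2.0 <= df.loc["risk_a", "odds_ratio"] <= 3.5

    def test_risk_pair_in_perfect_ld(self):
        cfg = SimulationConfig(seed=3, n_cases=100, n_controls=200, n_null_snps=10)
        m = simulate_genotypes(cfg).matrix
        a = m.dosage[:, m.snp_index("risk_a")]
        b = m.dosage[:, m.snp_index("risk_b")]
        assert np.array_equal(a, b)

    def test_planted_mafs_recovered(self):
        cfg = SimulationConfig(seed=9, n_cases=500, n_controls=2000, n_null_snps=5)
        m = simulate_genotypes(cfg).matrix
        case = m.case_mask
        j = m.snp_index("risk_a")
        for mask, target, n in ((case, 0.2857, 500), (~case, 0.1308, 2000)):
            f = np.nanmean(m.dosage[mask, j]) / 2
            se = np.sqrt(target * (1 - target) / (2 * n))
            assert abs(f - target) < 3 * se

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(risk_maf_case=0.6)
        with pytest.raises(ValueError):
            SimulationConfig(n_cases=0)
        with pytest.raises(ValueError):
            SimulationConfig(pop_fractions=(0.5, 0.4))
        with pytest.raises(ValueError):
            SimulationConfig(fst=1.0)


class TestGeneAnnotation:
    def test_deterministic_valid_intervals(self):
        cfg = SimulationConfig(seed=5, chrom_length_bp=60_000_000)
        genes = simulate_gene_annotation(cfg, n_genes=10)
        again = simulate_gene_annotation(cfg, n_genes=10)
        assert genes == again and len(genes) == 10
        for g in genes:
            assert 0 <= g.start < g.end <= cfg.chrom_length_bp

    def test_planted_gene_distance(self):
        """The planted gene boundary sits exactly 8763 bp from the risk SNP."""
        cfg = SimulationConfig(seed=5)
        genes = simulate_gene_annotation(cfg, n_genes=3)
        import pandas as pd

        snps = pd.DataFrame(
            {"snp_id": ["risk_a"], "chrom": [cfg.chrom], "pos_bp": [cfg.risk_pos_bp]}
        )
        hits, _ = map_snps_to_genes(snps, genes, window_bp=20_000)
        arf = hits[hits["gene_id"] == "ARF6"]
        assert list(arf["distance_bp"]) == [8763]

    def test_zero_genes(self):
        import pandas as pd

        cfg = SimulationConfig(seed=5)
        genes = simulate_gene_annotation(cfg, n_genes=0)
        assert genes == []
        snps = pd.DataFrame({"snp_id": ["x"], "chrom": ["14"], "pos_bp": [100]})
        hits, unique = map_snps_to_genes(snps, genes)
        assert hits.empty and unique == []


class TestSimulateNetwork:
    def test_no_background_only_module_edges(self):
        spec = NetworkSimSpec(n_genes=50, background_edge_prob=0.0, planted_module_size=8)
        net = simulate_network(spec, seed=1)
        planted = set(net.planted_genes)
        assert net.edges  # module wiring present
        for e in net.edges:
            assert e.gene_a in planted and e.gene_b in planted

    def test_determinism(self):
        spec = NetworkSimSpec()
        a = simulate_network(spec, seed=3)
        b = simulate_network(spec, seed=3)
        assert a.edges == b.edges and a.planted_genes == b.planted_genes

    def test_planted_module_recovered_by_enrichment(self):
        spec = NetworkSimSpec(n_genes=200, planted_module_size=20)
        sim = simulate_network(spec, seed=3)
        net = assemble_network(sim.edges)
        _, neighbors = first_neighbors(net, sim.seed_genes)
        universe = sorted(set(net.nodes) | set(neighbors))
        res = hypergeom_enrich(neighbors, sim.planted_genes, universe)
        assert res.p < 0.01

    def test_module_size_validation(self):
        with pytest.raises(ValueError):
            NetworkSimSpec(n_genes=10, planted_module_size=11)


class TestSimulatePhenotypes:
    def test_degenerate_class_probs_all_singles(self):
        spec = PhenotypeGroupSpec(name="g", n_larvae=5, class_probs=(1.0, 0, 0, 0))
        table = simulate_phenotype_table([spec], seed=0)
        for sizes in table["cluster_sizes"]:
            assert all(s == 1 for s in sizes)

    def test_separated_groups_detected_by_ttest(self):
        specs = [
            PhenotypeGroupSpec(name="a", n_larvae=30, length_mean_um=10.0, length_sd_um=1.0,
                               lengths_per_larva=1),
            PhenotypeGroupSpec(name="b", n_larvae=30, length_mean_um=6.0, length_sd_um=1.0,
                               lengths_per_larva=1),
        ]
        table = simulate_phenotype_table(specs, seed=8)
        a = np.concatenate(list(table.loc[table["group"] == "a", "lengths_um"]))
        b = np.concatenate(list(table.loc[table["group"] == "b", "lengths_um"]))
        _, _, p, sig = ttest_unpaired(a, b)
        assert p < 0.001 and sig

    def test_null_effect_pvalues_calibrated(self, rng):
        """beta = 0: type-I error of the eQTL test near nominal 5%."""
        hits = 0
        reps = 200
        for i in range(reps):
            dosage = rng.binomial(2, 0.3, size=80).astype(float)
            if np.ptp(dosage) == 0:
                continue
            expr = simulate_expression(dosage, beta=0.0, seed=10_000 + i)
            if eqtl_correlation(dosage, expr).p < 0.05:
                hits += 1
        assert 0.01 <= hits / reps <= 0.10
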