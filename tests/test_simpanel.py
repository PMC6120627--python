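"""Generator contracts: determinism, divergence rates, truth consistency."""

import filecmp
from dataclasses import replace

import numpy as np
import pytest

from polymethkit.io_formats import write_panel
from polymethkit.simpanel import (
    ConfigError,
    SimConfig,
    simulate_expression,
    simulate_genome,
    simulate_panel,
)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"conversion_rate": 1.2},
            {"epiallele_rate": -0.1},
            {"deamination_fold": 0.5},
            {"subgenome_length": 500},
            {"n_populations": 30, "n_accessions": 5},
            {"mean_coverage": 0.0},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimConfig(**kwargs).validate()

    def test_defaults_valid(self):
        SimConfig().validate()


class TestSimulateGenome:
    def test_zero_divergence_identical_subgenomes(self):
        cfg = SimConfig(
            subgenome_length=2000, ancestor_divergence=0.0, indel_rate=0.0, seed=4
        )
        g = simulate_genome(cfg)
        assert g.sequences["A"] == g.sequences["B"] == g.sequences["D"]
        for p in (1, 1000, 2000):
            assert g.homoeolog_map.translate(p, "A", "B") == p
            assert g.homoeolog_map.translate(p, "A", "D") == p

    def test_substitution_count_binomial(self):
        """Observed divergence stays within 3 binomial SDs of the target."""
        cfg = SimConfig(
            subgenome_length=10_000, ancestor_divergence=0.02, indel_rate=0.0, seed=5
        )
        g = simulate_genome(cfg)
        n, p = 10_000, 0.02
        # A and the derived subgenome each substitute independently at rate
        # p, so the observable pairwise divergence follows pairwise_rate(p)
        q = pairwise_rate(p)
        for sub in ("B", "D"):
            diff = sum(a != b for a, b in zip(g.sequences["A"], g.sequences[sub]))
            assert abs(diff - n * q) < 4 * np.sqrt(n * q * (1 - q))

    def test_indel_round_trip_in_blocks(self):
        cfg = SimConfig(subgenome_length=5000, indel_rate=0.002, seed=6)
        g = simulate_genome(cfg)
        m = g.homoeolog_map
        for p in range(1, len(g.sequences["A"]) + 1, 13):
            q = m.translate(p, "A", "D")
            if q is not None:
                assert m.translate(q, "D", "A") == p


def pairwise_rate(p):
    """Expected A-vs-derived divergence when both lineages substitute at p.

    A site differs unless both lineages kept the ancestral base or both hit
    the same substitute (substitutes uniform over the 3 alternatives).
    """
    return 2 * p * (1 - p) + p * p * (2 / 3)


class TestSimulatePanel:
    def test_seed_fixes_outputs_byte_for_byte(self, tmp_path):
        cfg = SimConfig(subgenome_length=3000, n_accessions=5, seed=9)
        for d in ("p1", "p2"):
            genome = simulate_genome(cfg)
            panel = simulate_panel(cfg, genome)
            expr = simulate_expression(cfg, panel.truth)
            write_panel(panel, tmp_path / d, expression=expr)
        cmp = filecmp.dircmp(tmp_path / "p1", tmp_path / "p2")
        assert not cmp.diff_files and not cmp.left_only and not cmp.right_only

    def test_chloroplast_only_conversion_failures(self, small_cfg, small_panel):
        pooled_m = pooled_u = 0
        for acc in small_panel.accessions:
            rep = small_panel.reports[acc]
            cp = rep[rep["chrom"] == "chloroplast"]
            pooled_m += cp["n_meth"].sum()
            pooled_u += cp["n_unmeth"].sum()
        rate = pooled_m / (pooled_m + pooled_u)
        expect = 1 - small_cfg.conversion_rate
        se = np.sqrt(expect * (1 - expect) / (pooled_m + pooled_u))
        assert abs(rate - expect) < 3 * se + 1e-9

    def test_marginal_context_levels_match_configuration(self, small_cfg, small_panel):
        """Pooled per-context methylation approaches fraction*level plus the
        conversion-failure floor."""
        acc = small_panel.accessions[0]
        rep = small_panel.reports[acc]
        rep = rep[rep["chrom"] == "chr1A"]
        params = {
            "CpG": (small_cfg.cpg_meth_fraction, small_cfg.cpg_meth_high),
            "CHG": (small_cfg.chg_meth_fraction, small_cfg.chg_meth_mean),
            "CHH": (small_cfg.chh_meth_fraction, small_cfg.chh_meth_mean),
        }
        states = small_panel.truth.methylation_state["A"]
        sites = small_panel.truth.sites["A"]
        for ctx, (frac, lvl) in params.items():
            sub = rep[rep["context"] == ctx]
            got = sub["n_meth"].sum() / (sub["n_meth"] + sub["n_unmeth"]).sum()
            # expectation uses the realised state fraction, not the nominal one
            mask = (sites["context"] == ctx).to_numpy()
            real_frac = states[mask, 0].mean()
            expect = real_frac * lvl + (1 - real_frac * lvl) * (
                1 - small_cfg.conversion_rate
            )
            n = (sub["n_meth"] + sub["n_unmeth"]).sum()
            se = np.sqrt(expect * (1 - expect) / n)
            assert abs(got - expect) < 4 * se + 0.01

    def test_truth_consistency_deaminated_sites_absent(self, small_panel):
        """A homozygous substitution at a cytosine removes it from that
        accession's callable set but not from others'."""
        acc = small_panel.accessions[0]
        vcf = small_panel.vcfs[acc]
        d_cyt = small_panel.truth.sites["D"]
        cyt_pos = set(d_cyt["pos"])
        hits = vcf[(vcf["chrom"] == "chr1D") & (vcf["gt"] == "1/1")
                   & vcf["pos"].isin(cyt_pos)]
        assert len(hits) > 0
        rep_pos = set(
            small_panel.reports[acc].query("chrom == 'chr1D'")["pos"]
        )
        assert not (set(hits["pos"]) & rep_pos)

    def test_population_labels_and_regions_cover_panel(self, small_cfg, small_panel):
        t = small_panel.truth
        assert set(t.population_labels.index) == set(small_panel.accessions)
        assert t.population_labels.nunique() == small_cfg.n_populations
        assert t.regions.notna().all()


class TestSimulateExpression:
    def test_noise_free_balanced_triads_exact_thirds(self):
        cfg = SimConfig(expr_noise_sd=0.0, n_triads=9, seed=13)
        data = simulate_expression(cfg)
        tri = data.triads[data.triads["meth_class"] == "tri"]
        for _, grp in tri.groupby("triad"):
            shares = 100 * grp["expression"] / grp["expression"].sum()
            assert np.allclose(shares, 100 / 3)

    def test_noise_free_uni_triads_exact_configured_shares(self):
        cfg = SimConfig(expr_noise_sd=0.0, n_triads=9, seed=13)
        data = simulate_expression(cfg)
        uni = data.triads[data.triads["meth_class"] == "uni"]
        for _, grp in uni.groupby("triad"):
            shares = (100 * grp["expression"] / grp["expression"].sum()).round(6)
            target = grp["methylated_genome"].iloc[0]
            m = grp["subgenome"] == target
            assert shares[m].iloc[0] == pytest.approx(28.82)
            assert np.allclose(shares[~m], 35.59)

    def test_planted_de_recovered_at_large_effect(self):
        from polymethkit.expression import de_test

        cfg = SimConfig(de_log2_fold=1.0, expr_noise_sd=0.1, seed=14)
        data = simulate_expression(cfg)
        out = de_test(data.expr_matrix, data.groups["accA"], data.groups["accB"])
        recovered = out.loc[sorted(data.true_de_genes), "is_de"].mean()
        assert recovered >= 0.9
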