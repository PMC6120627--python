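"""SMP identification, conservation profiling, and gene-level aggregation."""

import numpy as np
import pandas as pd
import pytest

from polymethkit.methcall import call_sites
from polymethkit.smp import (
    SmpError,
    SmpMatrix,
    accession_smps,
    conservation_profile,
    family_methylation_profile,
    gene_methylation_groups,
    identify_smps,
)


def make_calls(status_by_site: dict, accessions):
    """Build per-accession called tables from {site -> [status per accession]}."""
    out = {}
    for a, acc in enumerate(accessions):
        rows = []
        for (chrom, pos, strand, context), statuses in status_by_site.items():
            rows.append((chrom, pos, strand, context, 30, statuses[a]))
        out[acc] = pd.DataFrame(
            rows, columns=["chrom", "pos", "strand", "context", "coverage", "status"]
        )
    return out


ACCS = [f"a{i}" for i in range(6)]


class TestIdentifySmps:
    def test_requires_two_per_class(self):
        calls = make_calls(
            {
                # only one methylated accession: not an SMP
                ("c", 10, "+", "CpG"): ["methylated"] + ["unmethylated"] * 5,
                # 3 methylated / 3 unmethylated: SMP
                ("c", 20, "+", "CpG"): ["methylated"] * 3 + ["unmethylated"] * 3,
                # 2/2 with intermediates: still an SMP
                ("c", 30, "+", "CHH"): ["methylated"] * 2 + ["unmethylated"] * 2
                + ["intermediate"] * 2,
            },
            ACCS,
        )
        m = identify_smps(calls)
        assert set(m.sites["pos"]) == {20, 30}
        assert m.codes.loc[m.sites["pos"].tolist().index(30)].tolist() == [
            100, 100, 0, 0, 50, 50,
        ]

    def test_uncovered_anywhere_excludes_site(self):
        calls = make_calls(
            {("c", 10, "+", "CpG"): ["methylated"] * 3 + ["unmethylated"] * 2 + ["uncovered"]},
            ACCS,
        )
        assert len(identify_smps(calls)) == 0

    def test_site_missing_from_one_report_excluded(self):
        calls = make_calls(
            {("c", 10, "+", "CpG"): ["methylated"] * 3 + ["unmethylated"] * 3},
            ACCS,
        )
        calls[ACCS[0]] = calls[ACCS[0]].iloc[0:0]  # cytosine abolished by a SNP
        assert len(identify_smps(calls)) == 0

    def test_context_filter(self):
        calls = make_calls(
            {
                ("c", 10, "+", "CpG"): ["methylated"] * 3 + ["unmethylated"] * 3,
                ("c", 50, "+", "CpG"): ["methylated"] * 3 + ["unmethylated"] * 3,
            },
            ACCS,
        )
        intact = pd.DataFrame({"chrom": ["c"], "pos": [50], "strand": ["+"]})
        m = identify_smps(calls, context_intact=intact)
        assert m.sites["pos"].tolist() == [50]

    def test_fewer_than_four_accessions_rejected(self):
        calls = make_calls({("c", 10, "+", "CpG"): ["methylated"] * 3}, ACCS[:3])
        with pytest.raises(SmpError, match="4 accessions"):
            identify_smps(calls)

    def test_accession_order_invariance(self, small_panel):
        calls = {
            acc: call_sites(r[r["chrom"] != "chloroplast"])
            for acc, r in small_panel.reports.items()
        }
        m1 = identify_smps(calls)
        reversed_calls = dict(reversed(list(calls.items())))
        m2 = identify_smps(reversed_calls)
        pd.testing.assert_frame_equal(m1.sites, m2.sites)
        pd.testing.assert_frame_equal(m1.codes, m2.codes[m1.codes.columns])

    def test_round_trip(self, tmp_path):
        calls = make_calls(
            {("c", 20, "+", "CpG"): ["methylated"] * 3 + ["unmethylated"] * 3}, ACCS
        )
        m = identify_smps(calls)
        m.write(tmp_path / "m.tsv")
        back = SmpMatrix.read(tmp_path / "m.tsv")
        pd.testing.assert_frame_equal(back.sites, m.sites)
        pd.testing.assert_frame_equal(back.codes, m.codes)


class TestAccessionSmps:
    @pytest.fixture()
    def matrix(self):
        sites = pd.DataFrame(
            {"chrom": "c", "pos": [1, 2, 3, 4], "strand": "+", "context": "CpG"}
        )
        codes = pd.DataFrame(
            {"a0": [100, 0, 50, 100], "a1": [0, 100, 100, 0],
             "a2": [0, 0, 0, 100], "a3": [100, 100, 100, 0]}
        )
        return SmpMatrix(sites=sites, codes=codes)

    def test_counts(self, matrix):
        assert accession_smps(matrix, "a0")["pos"].tolist() == [1, 4]
        assert accession_smps(matrix, "a2")["pos"].tolist() == [4]

    def test_all_zero_column_empty(self, matrix):
        matrix.codes["a2"] = 0
        assert len(accession_smps(matrix, "a2")) == 0

    def test_sum_over_accessions_is_total_100_codes(self, matrix):
        total = sum(len(accession_smps(matrix, a)) for a in matrix.accessions)
        assert total == int((matrix.codes == 100).sum().sum())

    def test_unknown_accession(self, matrix):
        with pytest.raises(SmpError):
            accession_smps(matrix, "nope")


class TestConservation:
    def test_fraction_value(self):
        codes = pd.DataFrame([[100] * 21 + [0] * 84], columns=[f"a{i}" for i in range(105)])
        sites = pd.DataFrame({"chrom": ["c"], "pos": [1], "strand": ["+"], "context": ["CpG"]})
        prof = conservation_profile(SmpMatrix(sites=sites, codes=codes))
        assert prof["profile"]["pct_methylated"].iloc[0] == 20.0

    def test_planted_high_frequency_sites_in_high_bin(self):
        n = 40
        rows = [[100] * 38 + [0] * 2, [100] * 2 + [0] * 38]
        codes = pd.DataFrame(rows, columns=[f"a{i}" for i in range(n)])
        sites = pd.DataFrame(
            {"chrom": "c", "pos": [1, 2], "strand": "+", "context": "CpG"}
        )
        prof = conservation_profile(SmpMatrix(sites=sites, codes=codes))
        assert prof["profile"]["pct_methylated"].tolist() == [95.0, 5.0]
        assert prof["bins"]["all"]["pct_high_conserved"] == 50.0
        assert prof["bins"]["all"]["pct_rare"] == 50.0

    def test_empty_matrix_rejected(self):
        m = SmpMatrix(sites=pd.DataFrame(), codes=pd.DataFrame())
        with pytest.raises(SmpError):
            conservation_profile(m)


class TestGeneGroups:
    def test_boundaries_at_reference_panel_size(self):
        presence = pd.DataFrame(
            False, index=["g_high", "g_low", "g_med", "g_zero"],
            columns=[f"a{i}" for i in range(105)],
        )
        presence.loc["g_high", presence.columns[:95]] = True
        presence.loc["g_low", presence.columns[:39]] = True
        presence.loc["g_med", presence.columns[:40]] = True
        groups = gene_methylation_groups(presence)
        assert "g_high" in groups["high"]
        assert "g_low" in groups["low"]
        assert "g_med" in groups["medium"]
        assert "g_zero" not in groups["high"] | groups["medium"] | groups["low"]

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        presence = pd.DataFrame(
            rng.random((30, 20)) < 0.5,
            index=[f"g{i}" for i in range(30)],
            columns=[f"a{i}" for i in range(20)],
        )
        groups = gene_methylation_groups(presence)
        with_presence = set(presence.index[presence.sum(axis=1) >= 1])
        parts = [groups["high"], groups["medium"], groups["low"]]
        assert set().union(*parts) == with_presence
        assert sum(len(p) for p in parts) == len(with_presence)

    def test_thresholds_scale_with_panel(self):
        # 21 accessions: high cutoff scales to 90*21/105 = 18
        presence = pd.DataFrame(
            False, index=["g"], columns=[f"a{i}" for i in range(21)]
        )
        presence.loc["g", presence.columns[:18]] = True
        assert "g" in gene_methylation_groups(presence)["high"]


class TestFamilyProfile:
    def test_boundary_quarter_flagged(self):
        presence = pd.DataFrame(
            {"acc": [True, False, False, False]}, index=["g1", "g2", "g3", "g4"]
        )
        prof = family_methylation_profile({"fam": ["g1", "g2", "g3", "g4"]}, presence)
        assert prof.loc["fam", "mean_fraction"] == 0.25
        assert bool(prof.loc["fam", "flagged"])

    def test_no_methylation_not_flagged(self):
        presence = pd.DataFrame({"acc": [False, False]}, index=["g1", "g2"])
        prof = family_methylation_profile({"fam": ["g1", "g2"]}, presence)
        assert prof.loc["fam", "mean_fraction"] == 0.0 and not prof.loc["fam", "flagged"]

    def test_single_gene_families_binary(self):
        presence = pd.DataFrame({"acc": [True, False]}, index=["g1", "g2"])
        prof = family_methylation_profile({"f1": ["g1"], "f2": ["g2"]}, presence)
        assert sorted(prof["acc"].tolist()) == [0.0, 1.0]

    def test_empty_family_rejected(self):
        with pytest.raises(SmpError):
            family_methylation_profile({"fam": []}, pd.DataFrame({"acc": []}))


def test_monomorphic_sites_never_smps(small_cfg, small_genome):
    """With perfect conversion and deep coverage, only truly polymorphic
    sites can satisfy the two-methylated/two-unmethylated rule."""
    from dataclasses import replace

    from polymethkit.simpanel import simulate_panel

    cfg = replace(small_cfg, conversion_rate=1.0, mean_coverage=30.0)
    panel = simulate_panel(cfg, small_genome)
    calls = {
        acc: call_sites(r[r["chrom"] == "chr1A"]) for acc, r in panel.reports.items()
    }
    m = identify_smps(calls)
    truth_sites = panel.truth.sites["A"]
    poly = panel.truth.site_polymorphic["A"]
    poly_keys = set(
        zip(truth_sites["pos"][poly], truth_sites["strand"][poly])
    )
    for pos, strand in zip(m.sites["pos"], m.sites["strand"]):
        assert (pos, strand) in poly_keys
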