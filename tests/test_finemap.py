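"""Segregation χ², recombinant counting, flanking-interval delimitation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import bsamap as bm
from bsamap.finemap import scan_markers
from bsamap.simulate import finemap_marker_indices

from _oracles import oracle_chi2, oracle_overlap, oracle_recombinants


class TestSegregationTest:
    def test_f2_ratio_3_to_1(self):
        res = bm.segregation_test((948, 321), (3, 1))
        assert res.chi2 == pytest.approx(oracle_chi2((948, 321), (3, 1)), abs=1e-12)
        assert res.chi2 == pytest.approx(0.0591, abs=5e-4)
        assert res.p_value == pytest.approx(0.81, abs=0.01)
        assert res.df == 1

    def test_testcross_ratio_1_to_1(self):
        res = bm.segregation_test((103, 104), (1, 1))
        assert res.chi2 == pytest.approx(oracle_chi2((103, 104), (1, 1)), abs=1e-12)
        assert res.chi2 == pytest.approx(0.00483, abs=5e-5)

    def test_exact_fit_gives_zero(self):
        assert bm.segregation_test((75, 25), (3, 1)).chi2 == 0.0

    @pytest.mark.parametrize(
        "observed,ratio",
        [((120, 45), (3, 1)), ((52, 99, 49), (1, 2, 1)), ((7, 9, 2), (4, 3, 2))],
    )
    def test_matches_hand_formula(self, observed, ratio):
        res = bm.segregation_test(observed, ratio)
        assert res.chi2 == pytest.approx(oracle_chi2(observed, ratio), abs=1e-12)
        assert res.df == len(observed) - 1
        assert res.p_value == pytest.approx(sps.chi2.sf(res.chi2, res.df))

    def test_zero_total_rejected(self):
        with pytest.raises(bm.FineMapError):
            bm.segregation_test((0, 0), (3, 1))


class TestMarkerIds:
    def test_parse_kasp_style_id(self):
        m = bm.parse_marker_id("T785241C")
        assert (m.pos, m.allele_P2, m.allele_P1) == (785241, "T", "C")

    def test_bad_id_rejected(self):
        with pytest.raises(bm.FineMapError):
            bm.parse_marker_id("marker7")


def _table(phenos, genos, marker="T100C"):
    return pd.DataFrame(
        {
            "plant_id": [f"p{i}" for i in range(len(phenos))],
            "phenotype": phenos,
            marker: genos,
        }
    )


class TestCountRecombinants:
    def test_complete_linkage_gives_zero(self):
        t = _table(["sterile", "sterile", "fertile", "fertile"],
                   ["AA", "AA", "AB", "BB"])
        assert bm.count_recombinants(t, "T100C").n_recombinants == 0

    def test_constructed_sterile_het_plants(self):
        phenos = ["sterile"] * 600 + ["fertile"] * 100
        genos = ["AB", "AB"] + ["AA"] * 598 + ["AB"] * 100
        rc = bm.count_recombinants(_table(phenos, genos), "T100C")
        assert rc.n_recombinants == 2

    def test_missing_genotypes_skipped_and_counted(self):
        t = _table(["sterile", "fertile", "fertile"], ["--", "AA", "BB"])
        rc = bm.count_recombinants(t, "T100C")
        assert (rc.n_recombinants, rc.n_missing, rc.n_plants) == (1, 1, 2)

    def test_unknown_code_is_error(self):
        t = _table(["sterile"], ["A?"])
        with pytest.raises(bm.FineMapError):
            bm.count_recombinants(t, "T100C")

    def test_unlinked_marker_matches_multinomial_expectation(self, rng):
        n = 2_553
        phenos = np.where(rng.random(n) < 0.25, "sterile", "fertile")
        genos = rng.choice(["AA", "AB", "BB"], size=n, p=[0.25, 0.5, 0.25])
        t = _table(list(phenos), list(genos))
        rc = bm.count_recombinants(t, "T100C")
        n_sterile = (phenos == "sterile").sum()
        n_fertile = n - n_sterile
        expect = 0.75 * n_sterile + 0.25 * n_fertile
        sd = np.sqrt(n_sterile * 0.75 * 0.25 + n_fertile * 0.25 * 0.75)
        assert abs(rc.n_recombinants - expect) < 4 * sd

    def test_agrees_with_bookkeeping_oracle_on_simulated_f2(self):
        config = bm.SimConfig(seed=31, n_f2=800, n_snps=500)
        pop = bm.simulate_f2(config)
        idx = finemap_marker_indices(pop)
        table = pop.to_f2_table(idx)
        for marker in table.columns[2:]:
            rc = bm.count_recombinants(table, marker)
            assert rc.n_recombinants == oracle_recombinants(
                table["phenotype"], table[marker]
            )


def _markers(pos_counts, chrom="chr3"):
    markers = [
        bm.MarkerDef(f"M{i}", chrom, pos, "C", "T")
        for i, (pos, _) in enumerate(pos_counts)
    ]
    return markers, [c for _, c in pos_counts]


class TestFlankingInterval:
    def test_kasp_style_flanks_span_76_kb(self):
        markers, counts = _markers([(701_466, 9), (785_241, 2), (806_246, 0),
                                    (861_262, 4), (1_101_289, 8)])
        iv = bm.flanking_interval(markers, counts)
        assert (iv.start, iv.end) == (785_241, 861_262)
        assert iv.span_bp == 76_021
        assert iv.span_kb == 76

    def test_region_boundary_span(self):
        markers, counts = _markers([(166_710, 3), (300_000, 0), (564_531, 5)])
        iv = bm.flanking_interval(markers, counts)
        assert iv.span_bp == 397_821

    def test_identical_positions_span_zero(self):
        markers, counts = _markers([(600, 2), (600, 0), (600, 3)])
        iv = bm.flanking_interval(markers, counts)
        assert iv.span_bp == 0

    def test_one_sided_coverage_is_error(self):
        markers, counts = _markers([(100, 0), (200, 0), (300, 4)])
        with pytest.raises(bm.FineMapError, match="left"):
            bm.flanking_interval(markers, counts)

    def test_recombinants_increase_with_distance(self):
        config = bm.SimConfig(seed=32, n_f2=2_000, n_snps=1_000)
        pop = bm.simulate_f2(config)
        # 20 markers fanning out from the causal locus
        causal = pop.causal_index
        idx = [causal + k for k in range(2, 402, 20)]
        table = pop.to_f2_table(idx)
        _, counts = scan_markers(table, chrom=config.chrom)
        dist = counts["pos"] - config.causal_pos
        rho = sps.spearmanr(dist, counts["n_recombinants"]).statistic
        assert rho > 0.9


class TestIntervalGenes:
    def _models(self, triples):
        return [
            bm.GeneModel(g, c, "+", ((s, e),), ()) for g, c, s, e in triples
        ]

    def test_overlap_and_edge_touching(self):
        models = self._models(
            [("g1", "c", 100, 200), ("g2", "c", 500, 600), ("g3", "c", 900, 950)]
        )
        hits = bm.interval_genes("c", 200, 520, models)
        assert hits == ["g1", "g2"]  # g1 touches the edge by 1 bp

    def test_matches_brute_force_on_random_intervals(self, rng):
        triples = [
            ("g%d" % i, "c", int(s), int(s + rng.integers(1, 5_000)))
            for i, s in enumerate(rng.integers(1, 100_000, size=30))
        ]
        models = self._models(triples)
        for _ in range(1_000):
            a, b = sorted(rng.integers(1, 105_000, size=2))
            assert bm.interval_genes("c", a, b, models) == oracle_overlap(
                ("c", a, b), triples
            )


def test_flanking_interval_contains_causal_on_simulated_f2():
    config = bm.SimConfig(seed=33, n_f2=2_553)
    pop = bm.simulate_f2(config)
    table = pop.to_f2_table(finemap_marker_indices(pop))
    markers, counts = scan_markers(table, chrom=config.chrom)
    iv = bm.flanking_interval(markers, list(counts["n_recombinants"]))
    assert iv.start <= config.causal_pos <= iv.end
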