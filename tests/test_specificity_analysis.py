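"""DE classification, TPS binning, Fisher enrichment, RACE tallies."""

import math

import numpy as np
import pandas as pd
import pytest

from amirnaforge import (
    bin_by_tps,
    classify_de,
    enrichment_test,
    find_sites,
    min_tps_per_gene,
    predict_cleavage,
    race_tally,
)
from amirnaforge.fixtures import simulate_de, simulate_transcriptome
from amirnaforge._seq import revcomp_rna
from tests.conftest import random_rna


def de_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "baseMean", "log2FoldChange", "padj"])


class TestClassifyDE:
    @pytest.mark.parametrize(
        "log2fc,q,expected",
        [
            (-2.0, 0.001, "UNDER"),
            (-2.0, 0.02, "NS"),     # above the 1% FDR threshold
            (2.0, 0.001, "OVER"),
            (0.0, 0.001, "NS"),     # significant but no direction
            (-2.0, None, "NS"),     # missing q
        ],
    )
    def test_status_rules(self, log2fc, q, expected):
        df = classify_de(de_frame([("g", 10.0, log2fc, q)]))
        assert df.loc[0, "status"] == expected

    def test_zero_count_prefilter(self):
        table = de_frame(
            [("kept", 10.0, -2.0, 0.001), ("dropped", 0.5, -2.0, 0.001)]
        )
        df = classify_de(table, zero_counts={"dropped": 6, "kept": 1})
        assert list(df["gene_id"]) == ["kept"]

    def test_duplicate_gene_rejected(self):
        table = de_frame([("g", 1, -1, 0.1), ("g", 2, 1, 0.2)])
        with pytest.raises(ValueError, match="duplicate"):
            classify_de(table)

    def test_threshold_monotonicity(self, rng):
        """UNDER/OVER sets shrink as the q threshold decreases."""
        n = 200
        table = de_frame(
            [
                (f"g{i}", 10.0, float(rng.normal()), float(rng.uniform()))
                for i in range(n)
            ]
        )
        prev_under, prev_over = None, None
        for q in (0.2, 0.1, 0.05, 0.01, 0.001):
            df = classify_de(table, q_threshold=q)
            under = set(df.loc[df.status == "UNDER", "gene_id"])
            over = set(df.loc[df.status == "OVER", "gene_id"])
            if prev_under is not None:
                assert under <= prev_under
                assert over <= prev_over
            prev_under, prev_over = under, over


class TestBinByTPS:
    def test_single_under_gene_in_its_bin(self):
        records = classify_de(de_frame([("g", 10.0, -2.0, 0.001)]))
        report = bin_by_tps(records, {"g": 3.5})
        row = report.bins.loc[report.bins.tps_bin == 3.5].iloc[0]
        assert row.n_under == 1 and row.n_total == 1

    def test_no_site_stratum(self):
        records = classify_de(de_frame([("g", 10.0, -2.0, 0.001)]))
        report = bin_by_tps(records, {})
        assert report.no_site == {
            "n_total": 1, "n_under": 1, "n_over": 0, "n_ns": 0,
        }

    def test_interval_bounds_are_closed(self):
        records = classify_de(
            de_frame(
                [
                    ("a", 1, -1, 0.001),  # tps 4.0 -> in
                    ("b", 1, -1, 0.001),  # tps 11.0 -> in
                    ("c", 1, -1, 0.001),  # tps 3.5 -> out
                ]
            )
        )
        report = bin_by_tps(records, {"a": 4.0, "b": 11.0, "c": 3.5})
        assert report.interval_counts["n_total"] == 2
        assert report.interval_counts["n_under"] == 2

    def test_order_invariance(self, rng):
        rows = [
            (f"g{i}", 1.0, float(rng.normal()), float(rng.uniform(0, 0.05)))
            for i in range(40)
        ]
        tps = {f"g{i}": float(rng.integers(0, 23)) / 2 for i in range(30)}
        a = bin_by_tps(classify_de(de_frame(rows)), tps)
        b = bin_by_tps(classify_de(de_frame(rows[::-1])), tps)
        pd.testing.assert_frame_equal(
            a.bins, b.bins.reset_index(drop=True)
        )
        assert a.no_site == b.no_site

    def test_orphan_tps_gene_warns_and_skips(self):
        records = classify_de(de_frame([("g", 1, -1, 0.001)]))
        with pytest.warns(UserWarning, match="skipped"):
            report = bin_by_tps(records, {"g": 1.0, "ghost": 2.0})
        assert report.bins.n_total.sum() == 1

    def test_generator_bookkeeping_round_trip(self):
        """simulate_de -> classify_de -> bin_by_tps reproduces the planted
        composition exactly."""
        genes = [f"g{i:03d}" for i in range(120)]
        planted = {"g005", "g017", "g101"}
        table = simulate_de(genes, planted, seed=4)
        records = classify_de(table)
        assert set(records.loc[records.status == "UNDER", "gene_id"]) == planted
        tps_map = {"g005": 4.0, "g017": 6.5, "g101": 2.0, "g050": 9.0}
        report = bin_by_tps(records, tps_map)
        assert report.bins.loc[report.bins.tps_bin == 4.0, "n_under"].item() == 1
        assert report.bins.loc[report.bins.tps_bin == 6.5, "n_under"].item() == 1
        assert report.bins.loc[report.bins.tps_bin == 2.0, "n_under"].item() == 1
        assert report.bins.loc[report.bins.tps_bin == 9.0, "n_ns"].item() == 1
        assert report.no_site["n_total"] == 116
        assert report.interval_counts == {
            "n_total": 3, "n_under": 2, "n_over": 0, "n_ns": 1,
        }


def fisher_two_sided_enumeration(a, b, c, d):
    """Oracle: enumerate the full hypergeometric support at fixed margins and
    sum the probabilities of all tables no more likely than the observed."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_fact(k):
        return math.lgamma(k + 1)

    def log_p(x):
        # P(X = x) for the 2x2 table with first cell x
        return (
            log_fact(r1) + log_fact(r2) + log_fact(c1) + log_fact(n - c1)
            - log_fact(n)
            - log_fact(x) - log_fact(r1 - x)
            - log_fact(c1 - x) - log_fact(r2 - c1 + x)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    obs = log_p(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = log_p(x)
        if lp <= obs + 1e-9:
            total += math.exp(lp)
    return min(total, 1.0)


class TestEnrichmentTest:
    def test_identical_proportions_give_p_one(self):
        res = enrichment_test([[5, 95], [5, 95]])
        assert res.p_value == pytest.approx(1.0)

    def test_extreme_association(self):
        res = enrichment_test([[0, 10], [10, 0]])
        assert res.p_value < 0.001

    def test_matches_enumeration_oracle_on_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 11, 4))
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            res = enrichment_test([[a, b], [c, d]])
            oracle = fisher_two_sided_enumeration(a, b, c, d)
            assert res.p_value == pytest.approx(oracle, rel=1e-9, abs=1e-12)

    def test_exhaustive_small_margins(self):
        """All 2x2 tables with total n <= 14 agree with the enumeration."""
        for n in range(1, 15):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                            continue
                        res = enrichment_test([[a, b], [c, d]])
                        oracle = fisher_two_sided_enumeration(a, b, c, d)
                        assert res.p_value == pytest.approx(
                            oracle, rel=1e-9, abs=1e-12
                        ), (a, b, c, d)

    def test_degenerate_margin(self):
        res = enrichment_test([[0, 0], [3, 7]])
        assert res.p_value == 1.0
        assert "degenerate" in res.note

    def test_negative_or_misshaped_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test([[1, 2, 3], [4, 5, 6]])


class TestRaceTally:
    def _hit(self, amirna, rng):
        transcript = (
            random_rna(rng, 60) + revcomp_rna(amirna) + random_rna(rng, 60)
        )
        return find_sites(amirna, transcript)[0]

    def test_eight_of_ten_canonical(self, amirna, rng):
        hit = self._hit(amirna, rng)
        canonical = predict_cleavage(hit)
        tally = race_tally([canonical] * 8 + [canonical + 5] * 2, hit)
        assert tally.canonical_fraction == pytest.approx(0.8)
        assert tally.canonical_position == canonical

    def test_all_off_site(self, amirna, rng):
        hit = self._hit(amirna, rng)
        tally = race_tally([predict_cleavage(hit) + 3] * 5, hit)
        assert tally.canonical_fraction == 0.0

    def test_empty_clone_list_is_undefined(self, amirna, rng):
        tally = race_tally([], self._hit(amirna, rng))
        assert tally.canonical_fraction is None
        assert tally.total_clones == 0

    def test_eligibility_cap_enforced(self, amirna, rng):
        records = simulate_transcriptome(amirna, [8.0], background_n=0, seed=3)
        hit = next(
            h
            for h in find_sites(amirna, records[0][1])
            if h.tps == 8.0 and h.alignment.gap_count == 0
        )
        with pytest.raises(ValueError, match="cap"):
            race_tally([1, 2], hit)
        # lifting the preset tallies regardless of score
        assert race_tally([1, 2], hit, max_tps=None).total_clones == 2

    def test_binomial_recovery(self, amirna):
        rng = np.random.default_rng(77)
        hit = self._hit(amirna, rng)
        canonical = predict_cleavage(hit)
        n, p = 500, 0.9
        draws = rng.random(n) < p
        positions = [canonical if x else canonical - 4 for x in draws]
        tally = race_tally(positions, hit)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(tally.canonical_fraction - p) <= 3 * se


class TestMinTPSPerGene:
    def test_minimum_over_sites(self, amirna):
        records = simulate_transcriptome(
            amirna, [2.0, 5.0], background_n=1, seed=21
        )
        hits = []
        for tid, seq in records:
            hits.extend(find_sites(amirna, seq, transcript_id=tid))
        per_gene = min_tps_per_gene(hits)
        planted = {tid for tid, _ in records if tid.startswith("planted")}
        assert {per_gene[t] for t in planted} == {2.0, 5.0}
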