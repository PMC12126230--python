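"""Differential APA: ΔPDUI, per-gene tests, BH-FDR, classification, summaries."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from apakit.diffapa import (
    APACallConfig,
    bh_fdr,
    classify,
    delta_pdui,
    direction_percent,
    summarize_direction,
)
from apakit.diffapa import test_gene as group_test  # alias: not a pytest test


def make_table(ref, alt, gene_id="g"):
    rows = []
    for i, v in enumerate(ref):
        rows.append({"gene_id": gene_id, "sample_id": f"c{i}",
                     "group": "control", "pdui": v})
    for i, v in enumerate(alt):
        rows.append({"gene_id": gene_id, "sample_id": f"k{i}",
                     "group": "knockdown", "pdui": v})
    return pd.DataFrame(rows)


class TestDeltaPdui:
    def test_group_means_and_delta(self):
        # a lengthening shift of the magnitude seen for strong APA hits
        table = make_table([0.300, 0.300], [0.663, 0.663])
        (row,) = delta_pdui(table, "control", "knockdown").to_dict("records")
        assert row["delta_pdui"] == pytest.approx(0.363)
        assert row["mean_pdui_ref"] == pytest.approx(0.300)

    def test_null_case(self):
        table = make_table([0.4, 0.5], [0.4, 0.5])
        (row,) = delta_pdui(table, "control", "knockdown").to_dict("records")
        assert row["delta_pdui"] == pytest.approx(0.0)

    def test_antisymmetry(self):
        table = make_table([0.2, 0.3, 0.25], [0.6, 0.7])
        fwd = delta_pdui(table, "control", "knockdown")["delta_pdui"][0]
        rev = delta_pdui(table, "knockdown", "control")["delta_pdui"][0]
        assert fwd == pytest.approx(-rev)

    def test_one_group_gene_dropped(self):
        table = pd.concat([
            make_table([0.4], [0.6], "both"),
            make_table([0.4], [], "ref_only"),
        ])
        out = delta_pdui(table, "control", "knockdown")
        assert list(out["gene_id"]) == ["both"]


def welch_p(x, y):
    """Textbook Welch t with Welch–Satterthwaite df (independent oracle)."""
    from scipy.stats import t as tdist

    x, y = np.asarray(x), np.asarray(y)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t = (x.mean() - y.mean()) / math.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    return 2 * tdist.sf(abs(t), df)


def fisher_two_sided(table):
    """Exhaustive hypergeometric enumeration of the two-sided Fisher p."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(k):
        return (
            Fraction(math.comb(col1, k))
            * math.comb(n - col1, row1 - k)
            / math.comb(n, row1)
        )

    observed = prob(a)
    total = Fraction(0)
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        if prob(k) <= observed:
            total += prob(k)
    return float(total)


class TestTestGene:
    def test_zero_variance_identical_groups(self):
        assert group_test([0.5, 0.5], [0.5, 0.5]) == 1.0

    def test_welch_matches_closed_form(self):
        ref, alt = [0.10, 0.12, 0.11], [0.60, 0.58, 0.63]
        p = group_test(ref, alt)
        assert p < 0.001
        assert p == pytest.approx(welch_p(ref, alt), rel=1e-9)

    def test_single_replicate_fisher_matches_enumeration(self):
        # long/short read mass (90,10) vs (50,50)
        p = group_test([0.9], [0.5], mass_ref=(90, 10), mass_alt=(50, 50))
        assert p == pytest.approx(
            fisher_two_sided([[90, 10], [50, 50]]), rel=1e-9
        )

    def test_single_replicate_without_mass_raises(self):
        with pytest.raises(ValueError, match="read mass"):
            group_test([0.9], [0.5])


class TestBhFdr:
    def test_hand_step_up(self):
        assert bh_fdr([0.04]) == pytest.approx([0.04])
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_input_order_preserved(self):
        p = [0.03, 0.001, 0.5, 0.02]
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.argsort(q[order]) == np.arange(4)).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.5])

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_statsmodels_reference(self, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.random(int(rng.integers(1, 60)))
        ours = bh_fdr(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert ours == pytest.approx(theirs, rel=1e-12)


class TestClassify:
    @pytest.mark.parametrize(
        "q,delta,expect_sig,expect_dir",
        [
            (0.03, +0.15, True, "lengthened"),
            (0.20, +0.50, False, "lengthened"),  # fails alpha
            (0.01, +0.05, False, "none"),        # fails delta threshold
            (0.03, -0.15, True, "shortened"),
            (0.03, +0.10, True, "lengthened"),   # inclusive delta boundary
        ],
    )
    def test_dual_threshold(self, q, delta, expect_sig, expect_dir):
        # single-gene frame: raw p equals q after BH with m=1
        df = pd.DataFrame([{"gene_id": "g", "delta_pdui": delta, "p_value": q}])
        out = classify(df, APACallConfig())
        assert bool(out["significant"][0]) is expect_sig
        assert out["direction"][0] == expect_dir

    def test_raw_p_mode(self):
        df = pd.DataFrame([
            {"gene_id": f"g{i}", "delta_pdui": 0.2, "p_value": p}
            for i, p in enumerate([0.03, 0.04, 0.04, 0.04])
        ])
        raw = classify(df, APACallConfig(p_mode="raw"))
        assert raw["significant"].all()
        # at alpha=0.035 only the raw regime keeps g0: its BH q is 0.04
        strict = classify(df, APACallConfig(alpha=0.035, p_mode="fdr"))
        raw_strict = classify(df, APACallConfig(alpha=0.035, p_mode="raw"))
        assert raw_strict["significant"].sum() == 1
        assert strict["significant"].sum() == 0

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(200)],
            "delta_pdui": rng.uniform(-0.5, 0.5, 200),
            "p_value": rng.random(200),
        })
        base = classify(df, APACallConfig(alpha=0.2, delta_threshold=0.1))
        tighter_alpha = classify(df, APACallConfig(alpha=0.05, delta_threshold=0.1))
        tighter_delta = classify(df, APACallConfig(alpha=0.2, delta_threshold=0.3))
        base_set = set(base.loc[base["significant"], "gene_id"])
        assert set(tighter_alpha.loc[tighter_alpha["significant"], "gene_id"]) <= base_set
        assert set(tighter_delta.loc[tighter_delta["significant"], "gene_id"]) <= base_set


def test_power_at_moderate_effect():
    """>= 80% of genes with true ΔPDUI 0.3 at 100x depth are detected."""
    from apakit.breakpoint import pdui_table
    from apakit.diffapa import run_differential
    from apakit.simulate import SimConfig, simulate_coverage_tables

    cfg = SimConfig(n_genes=60, frac_null=0.0, frac_lengthened=1.0,
                    frac_shortened=0.0, seed=43)
    utrs, samples, covmaps, _ = simulate_coverage_tables(cfg)
    table, fits = pdui_table(utrs, samples, coverage_maps=covmaps)
    results = run_differential(table, "control", "knockdown", fits=fits)
    assert results["significant"].mean() >= 0.8


class TestSummarizeDirection:
    def make_results(self, n_len, n_short):
        rows = [
            {"gene_id": f"L{i}", "direction": "lengthened", "significant": True}
            for i in range(n_len)
        ] + [
            {"gene_id": f"S{i}", "direction": "shortened", "significant": True}
            for i in range(n_short)
        ]
        return pd.DataFrame(rows)

    @pytest.mark.parametrize(
        "n_len,n_total,expected",
        [
            (460, 658, 69.9),
            (429, 720, 59.6),
            (250, 320, 78.1),
            (59, 82, 72.0),
            (0, 10, 0.0),
        ],
    )
    def test_printed_percentages(self, n_len, n_total, expected):
        s = summarize_direction(self.make_results(n_len, n_total - n_len))
        assert s["pct_lengthened"] == expected
        assert s["pct_lengthened"] + s["pct_shortened"] == pytest.approx(100.0)

    def test_half_away_from_zero_rounding(self):
        assert direction_percent(164, 320) == 51.3  # 51.25 rounds up
        assert direction_percent(52, 320) == 16.3   # 16.25 rounds up

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            summarize_direction(pd.DataFrame({"significant": [False]}))
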