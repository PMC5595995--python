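"""Gene-body methylation, metagene mapping, expression correlation, overlap, screen."""

import numpy as np
import pandas as pd
import pytest

from mchscape import genes as gm
from tests.conftest import toy_methylome


def gene_table(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss", "tts"])
    df["length"] = (df["tts"] - df["tss"]).abs()
    return df


class TestGeneBodyMethylation:
    def test_uniform_body_mean(self):
        rows = [("c", p, "+", "CpH", "CAG", 0.04) for p in range(2000, 4000, 200)]
        genes = gene_table([("g1", "c", "+", 2000, 4000)])
        out = gm.gene_body_methylation(toy_methylome(rows), genes)
        assert out.iloc[0]["mean_level"] == pytest.approx(0.04)

    def test_cag_filter(self):
        rows = [("c", p, "+", "CpH", "CAG", 0.08) for p in range(2000, 3000, 100)]
        rows += [("c", p, "+", "CpH", "CAC", 0.01) for p in range(3000, 4000, 100)]
        genes = gene_table([("g1", "c", "+", 2000, 4000)])
        out = gm.gene_body_methylation(toy_methylome(rows), genes, context_filter="CAG")
        assert out.iloc[0]["mean_level"] == pytest.approx(0.08)

    def test_short_genes_excluded(self):
        rows = [("c", p, "+", "CpH", "CAG", 0.1) for p in range(0, 900, 50)]
        genes = gene_table([("short", "c", "+", 0, 900)])
        assert gm.gene_body_methylation(toy_methylome(rows), genes).empty

    def test_matches_brute_force_interval_scan(self):
        rng = np.random.default_rng(7)
        rows = [("c", int(p), "+", "CpH", "CAG", float(rng.random()))
                for p in sorted(rng.choice(100_000, 2000, replace=False))]
        m = toy_methylome(rows)
        genes = gene_table([
            (f"g{i}", "c", "+", int(s), int(s + rng.integers(1100, 4000)))
            for i, s in enumerate(rng.choice(90_000, 50, replace=False))
        ])
        out = gm.gene_body_methylation(m, genes).set_index("gene_id")
        for _, g in genes.iterrows():
            sub = m[(m["pos"] >= g["tss"]) & (m["pos"] < g["tts"])]
            if len(sub) == 0:
                assert g["gene_id"] not in out.index
            else:
                assert out.loc[g["gene_id"], "mean_level"] == pytest.approx(
                    sub["level"].mean()
                )


class TestMetagene:
    def test_tss_tts_bin_constants(self):
        assert gm.tss_tts_bins() == (142, 857)
        assert gm.tss_tts_bins(nbins=1000, flank=0.2) == (142, 857)

    def test_uniform_methylome_flat_profile(self):
        rows = [("c", p, "+", "CpH", "CAG", 0.05) for p in range(0, 30_000, 25)]
        genes = gene_table([("g1", "c", "+", 5000, 15_000), ("g2", "c", "+", 18_000, 24_000)])
        prof = gm.metagene_profile(toy_methylome(rows), genes, smooth_window=1)
        filled = prof["mean"].dropna()
        np.testing.assert_allclose(filled, 0.05)

    def test_strand_reversal_flips_profile(self):
        rng = np.random.default_rng(8)
        rows = [("c", int(p), "+", "CpH", "CAG", float(rng.random()))
                for p in sorted(rng.choice(20_000, 3000, replace=False))]
        m = toy_methylome(rows)
        fwd = gene_table([("g1", "c", "+", 5000, 15_000)])
        rev = gene_table([("g1", "c", "-", 15_000, 5000)])
        pf = gm.metagene_profile(m, fwd, smooth_window=1)["mean"].to_numpy()
        pr = gm.metagene_profile(m, rev, smooth_window=1)["mean"].to_numpy()
        np.testing.assert_allclose(pf, pr[::-1], equal_nan=True)

    def test_empty_group_rejected(self):
        rows = [("c", p, "+", "CpH", "CAG", 0.05) for p in range(0, 9000, 100)]
        genes = gene_table([("g1", "c", "+", 2000, 8000)])
        expr = pd.DataFrame({"gene_id": ["other"], "fpkm": [5.0]})
        with pytest.raises(ValueError, match="no genes in group"):
            gm.metagene_profile(toy_methylome(rows), genes, expr, group="high20")

    def test_expression_group_direction(self, esc_dataset, esc_methylome):
        hi = gm.metagene_profile(esc_methylome, esc_dataset.genes, esc_dataset.expression,
                                 group="high20")
        lo = gm.metagene_profile(esc_methylome, esc_dataset.genes, esc_dataset.expression,
                                 group="low20")
        tss, tts = gm.tss_tts_bins()
        body = slice(tss, tts)
        assert np.nanmean(hi["mean"].to_numpy()[body]) > np.nanmean(lo["mean"].to_numpy()[body])


class TestExpressionCorrelation:
    def test_monotone_relation_gives_one(self):
        s = pd.DataFrame({"mean_level": np.arange(20) * 0.01, "fpkm": np.exp(np.arange(20))})
        assert gm.expression_correlation(s) == pytest.approx(1.0)

    def test_requires_ten_genes(self):
        s = pd.DataFrame({"mean_level": [0.1] * 5, "fpkm": [1.0] * 5})
        with pytest.raises(ValueError):
            gm.expression_correlation(s)

    def test_constant_vector_nan(self):
        s = pd.DataFrame({"mean_level": [0.1] * 12, "fpkm": np.arange(12.0)})
        with pytest.warns(UserWarning):
            assert np.isnan(gm.expression_correlation(s))


class TestHistoneOverlap:
    def test_half_covered_gene(self):
        genes = gene_table([("g1", "c", "+", 1000, 2000)])
        peaks = pd.DataFrame({"chrom": ["c"], "start": [1200], "end": [1700]})
        out = gm.histone_overlap_rate(genes, peaks)
        assert out.iloc[0]["overlap_rate"] == pytest.approx(0.5)

    def test_overlapping_peaks_counted_once(self):
        genes = gene_table([("g1", "c", "+", 0, 1000)])
        peaks = pd.DataFrame({"chrom": ["c", "c"], "start": [100, 200], "end": [400, 500]})
        out = gm.histone_overlap_rate(genes, peaks)
        assert out.iloc[0]["overlap_rate"] == pytest.approx(0.4)

    def test_matches_bitmap_oracle(self):
        rng = np.random.default_rng(9)
        genes = gene_table([
            (f"g{i}", "c", "+", int(s), int(s) + 2000)
            for i, s in enumerate(rng.choice(50_000, 20, replace=False))
        ])
        starts = rng.choice(60_000, 40, replace=False)
        peaks = pd.DataFrame({"chrom": "c", "start": starts,
                              "end": starts + rng.integers(50, 3000, 40)})
        out = gm.histone_overlap_rate(genes, peaks).set_index("gene_id")
        bitmap = np.zeros(70_000, dtype=bool)
        for _, p in peaks.iterrows():
            bitmap[p["start"]:p["end"]] = True
        for _, g in genes.iterrows():
            expected = bitmap[g["tss"]:g["tts"]].sum() / (g["tts"] - g["tss"])
            assert out.loc[g["gene_id"], "overlap_rate"] == pytest.approx(expected)

    def test_monotone_under_adding_peaks(self):
        genes = gene_table([("g1", "c", "+", 0, 1000)])
        p1 = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [300]})
        p2 = pd.concat([p1, pd.DataFrame({"chrom": ["c"], "start": [500], "end": [600]})])
        r1 = gm.histone_overlap_rate(genes, p1).iloc[0]["overlap_rate"]
        r2 = gm.histone_overlap_rate(genes, p2).iloc[0]["overlap_rate"]
        assert r2 >= r1


class TestScreen:
    def _summaries(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "mean_mcag", "overlap_rate", "length"])

    def test_placeholder_symbols_excluded(self):
        s = self._summaries([
            ("LOC12345", 0.2, 0.9, 5000),
            ("2410002F23Rik", 0.2, 0.9, 5000),
            ("USP22", 0.2, 0.9, 5000),
        ])
        selected, _ = gm.screen_genes(s, excluded_prefixes=("LOC", "2410002F23Rik"))
        assert list(selected["gene_id"]) == ["USP22"]

    def test_all_below_cuts_empty(self):
        s = self._summaries([("a", 0.01, 0.2, 5000), ("b", 0.04, 0.9, 5000)])
        selected, quantile = gm.screen_genes(s)
        assert selected.empty and quantile == 1.0

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(10)
        s = self._summaries([
            (f"g{i}", float(rng.random() * 0.1), float(rng.random()),
             int(rng.integers(500, 8000)))
            for i in range(100)
        ])
        selected, _ = gm.screen_genes(s)
        expected = {
            r["gene_id"]
            for _, r in s.iterrows()
            if r["mean_mcag"] > 0.05 and r["overlap_rate"] > 0.5 and r["length"] > 1000
        }
        assert set(selected["gene_id"]) == expected

    def test_quantile_reported(self):
        s = self._summaries([(f"g{i}", v, 0.9, 5000) for i, v in
                             enumerate([0.01, 0.02, 0.04, 0.06, 0.08])])
        selected, quantile = gm.screen_genes(s)
        assert len(selected) == 2
        assert quantile == pytest.approx(0.6)
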