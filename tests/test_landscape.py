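"""Genome blocks, distance profiles, periodicity, hemi-methylation, clustering."""

import numpy as np
import pandas as pd
import pytest

from mchscape import landscape as lsc
from tests.conftest import make_dataset, run_calling, toy_methylome


class TestBinGenome:
    def test_single_block_means(self):
        m = toy_methylome([
            ("c", 10, "+", "CpG", "CGT", 0.9),
            ("c", 20, "+", "CpH", "CAG", 0.1),
        ])
        blocks = lsc.bin_genome(m)
        assert len(blocks) == 1
        b = blocks.iloc[0]
        assert b["mean_mcpg"] == pytest.approx(0.9)
        assert b["mean_mcph"] == pytest.approx(0.1)
        assert (b["n_cpg"], b["n_cph"]) == (1, 1)

    def test_block_boundaries_half_open(self):
        m = toy_methylome([
            ("c", 999, "+", "CpH", "CAG", 0.2),
            ("c", 1000, "+", "CpH", "CAG", 0.4),
        ])
        blocks = lsc.bin_genome(m)
        assert list(blocks["start"]) == [0, 1000]

    def test_matches_naive_recount(self, small_esc_methylome):
        blocks = lsc.bin_genome(small_esc_methylome)
        m = small_esc_methylome
        sub = m[(m["chrom"].astype(str) == "chr1") & (m["pos"] // 1000 == 7)]
        b = blocks[(blocks["chrom"].astype(str) == "chr1") & (blocks["start"] == 7000)].iloc[0]
        for cls, col in [("CpG", "mean_mcpg"), ("CpH", "mean_mcph")]:
            naive = sub[sub["cclass"] == cls]["level"].mean()
            assert b[col] == pytest.approx(naive, nan_ok=True)


class TestBlockCorrelation:
    def _blocks(self, mcpg, mcph, n=20):
        return pd.DataFrame({
            "mean_mcpg": mcpg, "mean_mcph": mcph,
            "n_cpg": n, "n_cph": n,
        })

    def test_perfect_linear_relation(self):
        x = np.linspace(0.1, 0.9, 12)
        assert lsc.block_correlation(self._blocks(x, 0.1 * x)) == pytest.approx(1.0)

    def test_constant_vector_degenerate(self):
        x = np.linspace(0.1, 0.9, 12)
        with pytest.warns(UserWarning):
            assert np.isnan(lsc.block_correlation(self._blocks(x, np.full(12, 0.3))))

    def test_insufficient_blocks(self):
        with pytest.raises(ValueError, match="insufficient"):
            lsc.block_correlation(self._blocks(np.array([0.1]), np.array([0.2])))

    def test_positive_coupling_recovered(self, esc_methylome):
        blocks = lsc.bin_genome(esc_methylome)
        assert lsc.block_correlation(blocks) > 0


class TestHemiStrand:
    def test_cis_assignment(self):
        blocks = pd.DataFrame({
            "mean_mcpg_fwd": [0.9], "mean_mcpg_rev": [0.1],
            "mean_mcph_fwd": [0.12], "mean_mcph_rev": [0.03],
        })
        res = lsc.hemi_strand_analysis(blocks)
        assert res["cis_mean"] == pytest.approx(0.12)
        assert res["trans_mean"] == pytest.approx(0.03)

    def test_no_qualifying_blocks(self):
        blocks = pd.DataFrame({
            "mean_mcpg_fwd": [0.5], "mean_mcpg_rev": [0.4],
            "mean_mcph_fwd": [0.1], "mean_mcph_rev": [0.1],
        })
        with pytest.raises(ValueError):
            lsc.hemi_strand_analysis(blocks)

    def test_strand_coupled_data_cis_exceeds_trans(self, esc_methylome):
        res = lsc.hemi_strand_analysis(lsc.bin_genome(esc_methylome))
        assert res["cis_mean"] > res["trans_mean"]
        assert res["pvalue"] < 0.05

    def test_strand_symmetric_null(self):
        ds = make_dataset("esc", seed=21, genome_length=250_000, n_genes=25,
                          gene_length_range=(1000, 4000), trans_factor=1.0)
        res = lsc.hemi_strand_analysis(lsc.bin_genome(run_calling(ds)))
        assert res["cis_mean"] == pytest.approx(res["trans_mean"], abs=0.05)
        assert res["pvalue"] >= 0.05


class TestProbabilityProfile:
    def test_no_called_mcph_gives_zero(self, small_esc_methylome):
        m = small_esc_methylome.copy()
        m["called"] = False
        prof = lsc.distance_probability_profile(m, radius=200, binwidth=10)
        assert (prof.values == 0).all()

    def test_matches_brute_force_window_scan(self):
        rng = np.random.default_rng(3)
        rows = []
        for p in sorted(rng.choice(20_000, size=900, replace=False)):
            if rng.random() < 0.25:
                rows.append(("c", int(p), rng.choice(["+", "-"]), "CpG", "CGA",
                             float(rng.choice([0.05, 0.95]))))
            else:
                rows.append(("c", int(p), rng.choice(["+", "-"]), "CpH", "CAG",
                             float(rng.random() * 0.4)))
        m = toy_methylome(rows)
        m["called"] = (m["cclass"] == "CpH") & (rng.random(len(m)) < 0.3)
        radius, binwidth = 200, 10
        prof = lsc.distance_probability_profile(m, radius=radius, binwidth=binwidth)

        anchors = m[(m["cclass"] == "CpG") & (m["level"] >= 0.8)]
        mpos = m[m["called"]]["pos"].to_numpy()
        nbins = 2 * radius // binwidth + 1
        hits = np.zeros(nbins)
        for _, a in anchors.iterrows():
            off = mpos - a["pos"]
            if str(a["strand"]) == "-":
                off = -off
            off = off[np.abs(off) <= radius]
            for b in np.unique((off + radius) // binwidth):
                hits[b] += 1
        np.testing.assert_allclose(prof.table["n"].to_numpy(), hits)
        np.testing.assert_allclose(prof.values, hits / len(anchors))

    def test_methylated_anchor_probability_higher_centrally(self, esc_methylome):
        pm = lsc.distance_probability_profile(esc_methylome, 500, 10, "methylated")
        pu = lsc.distance_probability_profile(esc_methylome, 500, 10, "unmethylated")
        central = slice(45, 56)
        assert pm.values[central].mean() > pu.values[central].mean()


class TestLevelProfile:
    def test_uniform_levels_flat_profile(self):
        rows = [("c", p, "+", "CpH", "CAG", 0.02) for p in range(0, 400, 7)]
        rows += [("c", p, "+", "CpG", "CGA", 0.9) for p in (100, 300)]
        prof = lsc.distance_level_profile(toy_methylome(rows), radius=50)
        vals = prof.values[np.isfinite(prof.values)]
        np.testing.assert_allclose(vals, 0.02)

    def test_esc_peak_at_minus_four(self, esc_methylome):
        prof = lsc.distance_level_profile(esc_methylome, radius=100)
        assert prof.offsets[np.nanargmax(prof.values)] == -4

    def test_neuron_periodicity(self, neuron_methylome):
        prof = lsc.distance_level_profile(neuron_methylome, radius=100)
        res = lsc.periodicity_score(prof.values, (5, 15))
        assert res["best_lag"] in (8, 9, 10)


class TestSlidingWindow:
    def _profile(self, values):
        table = pd.DataFrame({"offset": np.arange(len(values)), "value": values, "n": 1})
        return lsc.DistanceProfile("methylated", "level", len(values) // 2, 1, table)

    def test_constant_unchanged(self):
        prof = lsc.sliding_window_profile(self._profile(np.full(50, 0.3)), 10)
        np.testing.assert_allclose(prof.values, 0.3)

    def test_central_impulse_mass_conserved(self):
        x = np.zeros(101)
        x[50] = 1.0
        sm = lsc.sliding_window_profile(self._profile(x), 11)
        assert sm.values.sum() == pytest.approx(1.0)
        assert sm.values.max() == pytest.approx(1 / 11)

    def test_window_too_large(self):
        with pytest.raises(ValueError):
            lsc.sliding_window_profile(self._profile(np.zeros(5)), 99)


class TestPeriodicity:
    def test_pure_cosine_recovered(self):
        x = np.cos(2 * np.pi * np.arange(200) / 9.0)
        assert lsc.periodicity_score(x, (5, 15))["best_lag"] == 9

    def test_white_noise_below_permutation_null(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=300)
        res = lsc.periodicity_score(x, (5, 15), n_permutations=200, seed=1)
        assert res["score"] <= res["null_95"]

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            lsc.periodicity_score(np.zeros(10), (5, 15))

    def test_nucleosome_scale_in_d1ko_mode(self):
        ds = make_dataset("d1ko", seed=22, genome_length=400_000, n_genes=30,
                          gene_length_range=(1000, 5000))
        prof = lsc.distance_level_profile(run_calling(ds), radius=500)
        res = lsc.periodicity_score(prof.values, (100, 300))
        assert 160 <= res["best_lag"] <= 200


class TestPatternClustering:
    def test_duplicate_sample_perfect_correlation(self, small_esc_methylome):
        samples = {"a": small_esc_methylome, "b": small_esc_methylome,
                   "c": small_esc_methylome.assign(level=lambda d: 1 - d["level"])}
        res = lsc.proximal_pattern_matrix(samples, radius=60)
        assert res.pcc.loc["a", "b"] == pytest.approx(1.0)
        assert res.order.index("a") + 1 == res.order.index("b") or \
               res.order.index("b") + 1 == res.order.index("a")

    def test_matrix_symmetric_unit_diagonal(self, small_esc_methylome):
        samples = {"a": small_esc_methylome, "b": small_esc_methylome}
        res = lsc.proximal_pattern_matrix(samples, radius=60)
        np.testing.assert_allclose(res.pcc.to_numpy(), res.pcc.to_numpy().T)
        np.testing.assert_allclose(np.diag(res.pcc.to_numpy()), 1.0)

    def test_requires_two_samples(self, small_esc_methylome):
        with pytest.raises(ValueError):
            lsc.proximal_pattern_matrix({"a": small_esc_methylome})

    def test_newick_contains_all_samples(self, small_esc_methylome):
        samples = {"s1": small_esc_methylome, "s2": small_esc_methylome,
                   "s3": small_esc_methylome.assign(level=lambda d: d["level"] ** 2)}
        res = lsc.proximal_pattern_matrix(samples, radius=60)
        for sid in samples:
            assert sid in res.newick


def test_profiles_invariant_under_chromosome_relabeling(small_esc_methylome):
    m = small_esc_methylome
    renamed = m.copy()
    renamed["chrom"] = renamed["chrom"].astype(str).map(
        {"chr1": "chrZ", "chrCtrl": "chrA"}
    )
    renamed["chrom"] = pd.Categorical(renamed["chrom"])
    p1 = lsc.distance_level_profile(m, radius=80)
    p2 = lsc.distance_level_profile(renamed, radius=80)
    np.testing.assert_allclose(p1.values, p2.values, equal_nan=True)


def test_kernel_width_recovery_within_tolerance(esc_methylome):
    corr = lsc.distance_correlation_profile(esc_methylome, radius=300, pairing="nearest")
    width = lsc.kernel_width_estimate(corr)
    assert 80 <= width <= 120


def test_nearest_pcc_concentrated_within_coupling_range(esc_methylome):
    corr = lsc.distance_correlation_profile(esc_methylome, radius=300, pairing="nearest")
    prof = corr.set_index("offset")["pcc"]
    near = prof.loc[-100:100].mean()
    far = (prof.loc[200:300].mean() + prof.loc[-300:-200].mean()) / 2
    assert near > far
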