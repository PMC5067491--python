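"""Colocalization, saturation, dropout rate, CV series and library filters."""

import itertools

import numpy as np
import pandas as pd
import pytest

import spotseq as ss
from spotseq.array_model import ConfigurationError
from spotseq.demux_count import dedup_umis


class TestColocalize:
    def test_centroid_at_spot_centre(self, small_layout):
        layout, _ = small_layout
        spot = layout.barcode_spots.iloc[5]
        cent = pd.DataFrame(
            {"cell_id": ["c1"], "x_um": [spot["x_um"]], "y_um": [spot["y_um"]]}
        )
        annotation, assignment = ss.colocalize(cent, layout, radius_um=50)
        assert assignment["c1"] == spot["spot_id"]
        row = annotation.set_index("spot_id").loc[spot["spot_id"]]
        assert row["n_cells"] == 1 and row["group"] == "single"

    def test_distant_centroid_unassigned(self, small_layout):
        layout, _ = small_layout
        spot = layout.barcode_spots.iloc[0]
        cent = pd.DataFrame(
            {"cell_id": ["c1"], "x_um": [spot["x_um"] + 60], "y_um": [spot["y_um"]]}
        )
        _, assignment = ss.colocalize(cent, layout, radius_um=50)
        assert assignment["c1"] is None

    def test_radius_beyond_half_pitch_rejected(self, small_layout):
        layout, _ = small_layout
        cent = pd.DataFrame({"cell_id": ["c1"], "x_um": [0.0], "y_um": [0.0]})
        with pytest.raises(ConfigurationError):
            ss.colocalize(cent, layout, radius_um=150)

    def test_recovers_simulated_occupancy(self, clean_experiment):
        truth = clean_experiment["truth"]
        layout = clean_experiment["layout"]
        annotation, _ = ss.colocalize(
            truth.cells[["cell_id", "x_um", "y_um"]], layout, radius_um=50
        )
        merged = annotation.set_index("spot_id")["group"]
        expected = truth.spots.set_index("spot_id")["group"]
        assert merged.loc[expected.index].equals(expected)


@pytest.fixture(scope="module")
def reads():
    rng = np.random.default_rng(7)
    pool = ss.UmiPattern().sample(rng, 40)
    return pd.DataFrame(
        {
            "barcode_id": rng.choice(["b1", "b2"], size=200),
            "gene_id": rng.choice(["g1", "g2", "g3"], size=200),
            "umi": [pool[i] for i in rng.integers(0, 40, 200)],
        }
    )


class TestSaturation:
    def test_endpoints(self, reads):
        full = sum(
            dedup_umis(list(u))
            for _, u in reads.groupby(["gene_id", "barcode_id"])["umi"]
        )
        sat = ss.saturation_curve(reads, [0, len(reads)], repeats=3, seed=0)
        assert sat["mean_unique_molecules"].iloc[0] == 0
        assert sat["mean_unique_molecules"].iloc[-1] == full

    def test_monotone_in_depth(self, reads):
        sat = ss.saturation_curve(reads, [0, 50, 100, 200], repeats=20, seed=1)
        assert sat["mean_unique_molecules"].is_monotonic_increasing
        assert sat["mean_unique_genes"].is_monotonic_increasing

    def test_subsample_mean_matches_exhaustive_toy(self):
        """10-read toy: mean unique molecules at depth 5 vs full enumeration."""
        rng = np.random.default_rng(3)
        umis = ss.UmiPattern().sample(rng, 6)
        toy = pd.DataFrame(
            {
                "barcode_id": ["b"] * 10,
                "gene_id": ["g"] * 10,
                "umi": [umis[i] for i in [0, 0, 1, 1, 2, 2, 3, 3, 4, 5]],
            }
        )
        exact = np.mean([
            sum(
                dedup_umis([toy["umi"].iloc[i] for i in combo])
                for _ in [0]
            )
            for combo in itertools.combinations(range(10), 5)
        ])
        B = 200
        sat = ss.saturation_curve(toy, [5], repeats=B, seed=4)
        observed = sat["mean_unique_molecules"].iloc[0]
        # molecule count at depth 5 is bounded by 5; allow 3 SE of the MC mean
        per_draw_sd = 1.5
        assert abs(observed - exact) <= 3 * per_draw_sd / np.sqrt(B)

    def test_excess_depth_truncated_with_warning(self, reads):
        with pytest.warns(UserWarning):
            sat = ss.saturation_curve(reads, [10**6], repeats=2, seed=0)
        assert sat["depth"].iloc[0] == len(reads)


class TestDropoutRate:
    def test_identical_profiles_zero(self):
        assert ss.dropout_rate({"g1", "g2"}, {"g1", "g2"}) == 0.0

    def test_denominator_is_reference_profile(self):
        assert ss.dropout_rate({"g1", "g2", "g3"}, {"g1", "g2", "g3", "g4"}) == 25.0

    def test_asymmetry(self):
        a, b = {"g1"}, {"g1", "g2", "g3"}
        assert ss.dropout_rate(a, b) != ss.dropout_rate(b, a)

    def test_empty_reference_undefined(self):
        with pytest.raises(ValueError):
            ss.dropout_rate({"g1"}, set())

    def test_bounded_in_0_100(self):
        assert 0 <= ss.dropout_rate(set(), {"g1", "g2"}) <= 100


class TestCvVsRank:
    def test_constant_gene_has_zero_cv(self):
        mat = pd.DataFrame(
            {"c1": [5.0, 1.0], "c2": [5.0, 3.0]}, index=["flat", "varying"]
        )
        out = ss.cv_vs_rank(mat, window=1)
        assert out.set_index("gene_id").loc["flat", "cv"] == 0.0

    def test_window_one_returns_raw_cv_in_rank_order(self):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(rng.poisson(10, (20, 8)).astype(float),
                           index=[f"g{i}" for i in range(20)])
        out = ss.cv_vs_rank(mat, window=1)
        assert (out["cv"] == out["mean_cv"]).all()
        assert out["mean_expression"].is_monotonic_decreasing

    def test_nb_matrix_cv_decreases_with_mean(self):
        """Fixed dispersion: smoothed CV falls with expression rank."""
        from spotseq.simulate import _nb_counts

        rng = np.random.default_rng(5)
        mus = np.logspace(0.5, 3, 60)
        mat = pd.DataFrame(
            np.stack([_nb_counts(rng, np.full(200, m), 2.0, 0.0) for m in mus]),
            index=[f"g{i}" for i in range(60)],
        ).astype(float)
        out = ss.cv_vs_rank(mat, window=15)
        third = len(out) // 3
        assert out["mean_cv"].iloc[:third].mean() < out["mean_cv"].iloc[-third:].mean()


class TestBackgroundGeneFilter:
    def test_housekeeping_exempt_top_two(self, clean_experiment):
        cm = clean_experiment["cm"]
        truth = clean_experiment["truth"]
        bg = truth.spots.loc[truth.spots["group"] == "background", "barcode_id"]
        totals = cm.counts[list(bg)].sum(axis=1)
        hk = {totals.idxmax()}  # exempt the top gene
        picked = ss.background_gene_filter(cm, bg, housekeeping=hk, top_n=2)
        assert len(picked) == 2 and totals.idxmax() not in picked
        remaining = totals.drop(index=list(hk)).sort_values(ascending=False)
        assert set(picked) == set(remaining.index[:2])

    def test_all_housekeeping_empty_list(self, clean_experiment):
        cm = clean_experiment["cm"]
        truth = clean_experiment["truth"]
        bg = truth.spots.loc[truth.spots["group"] == "background", "barcode_id"]
        picked = ss.background_gene_filter(cm, bg, housekeeping=set(cm.genes))
        assert picked == []


class TestLibraryMeanFilter:
    def test_strict_threshold(self):
        kept = ss.filter_libraries_by_mean(
            pd.Series([10, 20, 30], index=["a", "b", "c"])
        )
        assert kept == ["c"]

    def test_all_equal_keeps_none_strict(self):
        kept = ss.filter_libraries_by_mean(pd.Series([5, 5, 5], index=list("abc")))
        assert kept == []

    def test_inclusive_switch(self):
        kept = ss.filter_libraries_by_mean(
            pd.Series([5, 5], index=["a", "b"]), inclusive=True
        )
        assert kept == ["a", "b"]

    def test_single_library_warns(self):
        with pytest.warns(UserWarning):
            kept = ss.filter_libraries_by_mean(pd.Series([7], index=["a"]))
        assert kept == []


class TestBackgroundReadFraction:
    def test_simulated_fraction_recovered(self, clean_experiment):
        cm = clean_experiment["cm"]
        truth = clean_experiment["truth"]
        f = clean_experiment["config"].background_fraction
        frac = ss.background_read_fraction(cm, truth.spots)
        n = int(cm.raw_reads.sum())
        assert abs(frac - f) <= 4 * np.sqrt(f * (1 - f) / n) + 0.01

    def test_no_background_barcodes_zero(self, clean_experiment):
        cm = clean_experiment["cm"]
        truth = clean_experiment["truth"]
        forced = truth.spots.assign(group="single")
        assert ss.background_read_fraction(cm, forced) == 0.0
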