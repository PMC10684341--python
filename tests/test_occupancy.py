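import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beebrains.occupancy import (
    HABITATS,
    HabitatGrid,
    apply_min_records,
    assign_habitat,
    build_matrix,
    classify_occupancy,
    filter_records,
    occupancy_percentiles,
    patefield_sample,
)

from conftest import FILTER_TOY_KEPT


class TestFilterRecords:
    @pytest.mark.parametrize(
        "year,lat,lon,kept",
        [
            (1989, "40.123", "-75.10", False),  # year below window
            (2000, "40.1", "-75.123", False),   # lat has one decimal
            (1990, "40.10", "-75.10", True),    # inclusive bounds
        ],
    )
    def test_boundary_cases(self, year, lat, lon, kept):
        df = pd.DataFrame(
            {
                "species": ["x"],
                "year": [year],
                "lat": [float(lat)],
                "lon": [float(lon)],
                "lat_text": [lat],
                "lon_text": [lon],
            }
        )
        assert len(filter_records(df)) == (1 if kept else 0)

    def test_toy_ledger_matches_hand_enumeration(self, filter_toy_records):
        kept = filter_records(filter_toy_records)
        assert list(kept.index) == FILTER_TOY_KEPT

    def test_numeric_fallback_counts_shortest_roundtrip(self):
        df = pd.DataFrame(
            {
                "species": ["x", "y"],
                "year": [2000, 2000],
                "lat": [40.12, 40.12],
                "lon": [-75.3, -75.34],
            }
        )
        kept = filter_records(df)
        assert list(kept["species"]) == ["y"]

    def test_does_not_mutate_input(self, filter_toy_records):
        before = filter_toy_records.copy()
        filter_records(filter_toy_records)
        pd.testing.assert_frame_equal(before, filter_toy_records)


@pytest.fixture
def small_grid():
    # 2x2 grid over lat [0, 2), lon [0, 2); codes 0/1 natural, 2/3 agricultural,
    # 4/5 urban
    codes = np.array([[0, 4], [2, 0]])
    return HabitatGrid(
        codes=codes,
        lat_min=0.0,
        lat_max=2.0,
        lon_min=0.0,
        lon_max=2.0,
        reclass={0: "natural", 1: "natural", 2: "agricultural", 3: "agricultural", 4: "urban", 5: "urban"},
    )


class TestAssignHabitat:
    def test_cell_centre(self, small_grid):
        df = pd.DataFrame(
            {"species": ["x"], "lat": [0.5], "lon": [1.5], "year": [2000]}
        )
        labelled, report = assign_habitat(df, small_grid)
        assert labelled["habitat"].iloc[0] == "urban"
        assert report["n_outside"] == 0

    def test_shared_edge_goes_to_closed_lower_edge(self, small_grid):
        # the point (1.0, 0.5) sits on the edge between rows 0 and 1: the
        # half-open convention assigns it to row 1 (lat interval [1, 2))
        df = pd.DataFrame(
            {"species": ["x"] * 3, "lat": [1.0] * 3, "lon": [0.5] * 3, "year": [2000] * 3}
        )
        for _ in range(3):
            labelled, _ = assign_habitat(df, small_grid)
            assert (labelled["habitat"] == "agricultural").all()

    def test_outside_dropped_and_counted(self, small_grid):
        df = pd.DataFrame(
            {"species": ["x", "y"], "lat": [0.5, 5.0], "lon": [0.5, 0.5], "year": [2000, 2000]}
        )
        labelled, report = assign_habitat(df, small_grid)
        assert len(labelled) == 1
        assert report["n_outside"] == 1
        with pytest.raises(ValueError, match="outside"):
            assign_habitat(df, small_grid, strict=True)

    def test_all_natural_grid(self):
        grid = HabitatGrid(
            codes=np.zeros((3, 3), dtype=int),
            lat_min=0, lat_max=3, lon_min=0, lon_max=3,
            reclass={0: "natural"},
        )
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "species": ["x"] * 20,
                "lat": rng.uniform(0, 3, 20),
                "lon": rng.uniform(0, 3, 20),
                "year": [2000] * 20,
            }
        )
        labelled, _ = assign_habitat(df, grid)
        assert (labelled["habitat"] == "natural").all()

    def test_unmapped_code_rejected(self):
        with pytest.raises(ValueError, match="reclassification"):
            HabitatGrid(
                codes=np.array([[0, 7]]), lat_min=0, lat_max=1,
                lon_min=0, lon_max=2, reclass={0: "natural"},
            )


class TestBuildMatrix:
    def test_counts_and_columns(self):
        labelled = pd.DataFrame(
            {"species": ["A", "A", "A"], "habitat": ["urban"] * 3}
        )
        mat = build_matrix(labelled)
        assert list(mat.columns) == list(HABITATS)
        assert mat.loc["A"].tolist() == [0, 0, 3]

    def test_record_order_irrelevant(self):
        rng = np.random.default_rng(2)
        labelled = pd.DataFrame(
            {
                "species": rng.choice(["A", "B"], 50),
                "habitat": rng.choice(list(HABITATS), 50),
            }
        )
        a = build_matrix(labelled)
        b = build_matrix(labelled.iloc[rng.permutation(50)].reset_index(drop=True))
        pd.testing.assert_frame_equal(a, b)


class TestApplyMinRecords:
    def test_boundary_at_fifty(self):
        mat = pd.DataFrame(
            {"natural": [49, 50], "agricultural": [0, 0], "urban": [0, 0]},
            index=["under", "at"],
        )
        out = apply_min_records(mat, 50)
        assert list(out.index) == ["at"]

    def test_all_below_raises(self):
        mat = pd.DataFrame(
            {"natural": [5], "agricultural": [3], "urban": [1]}, index=["A"]
        )
        with pytest.raises(ValueError, match="no species"):
            apply_min_records(mat, 50)


class TestPatefieldSample:
    def test_degenerate_single_row(self):
        for seed in range(5):
            t = patefield_sample([3], [1, 2], seed)
            np.testing.assert_array_equal(t, [[1, 2]])

    def test_margins_always_preserved(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            shape = (int(rng.integers(2, 6)), int(rng.integers(2, 5)))
            cells = rng.integers(0, 15, size=shape)
            r = cells.sum(axis=1)
            c = cells.sum(axis=0)
            if r.sum() == 0:
                continue
            for _ in range(20):
                t = patefield_sample(r, c, rng)
                np.testing.assert_array_equal(t.sum(axis=1), r)
                np.testing.assert_array_equal(t.sum(axis=0), c)
                assert (t >= 0).all()

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        cells=st.lists(
            st.lists(st.integers(0, 12), min_size=3, max_size=3),
            min_size=2,
            max_size=6,
        ),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_margins_preserved_property(self, cells, seed):
        obs = np.array(cells)
        r = obs.sum(axis=1)
        c = obs.sum(axis=0)
        if r.sum() == 0:
            return
        t = patefield_sample(r, c, seed)
        assert (t >= 0).all()
        np.testing.assert_array_equal(t.sum(axis=1), r)
        np.testing.assert_array_equal(t.sum(axis=0), c)

    def test_margin_mismatch_rejected(self):
        with pytest.raises(ValueError, match="margin sums differ"):
            patefield_sample([3, 2], [4, 4], 0)

    def test_matches_random_pairing_oracle(self):
        """Sequential hypergeometric filling equals label-pairing sampling.

        The oracle pairs N shuffled row labels with N fixed column labels
        and tabulates -- an independent construction of the same
        conditional-on-margins distribution.
        """
        r = np.array([4, 3])
        c = np.array([2, 5])
        rng = np.random.default_rng(11)
        n_draws = 30_000
        counts_impl = np.zeros(5)
        counts_oracle = np.zeros(5)
        row_labels = np.repeat(np.arange(2), r)
        col_labels = np.repeat(np.arange(2), c)
        for _ in range(n_draws):
            t = patefield_sample(r, c, rng)
            counts_impl[t[0, 0]] += 1
            shuffled = rng.permutation(row_labels)
            k = int(np.sum((shuffled == 0) & (col_labels == 0)))
            counts_oracle[k] += 1
        # compare the two empirical pmfs of cell (0,0)
        from scipy.stats import chisquare

        mask = (counts_impl + counts_oracle) > 0
        expected = counts_oracle[mask] + 0.5
        observed = counts_impl[mask] + 0.5
        stat, p = chisquare(observed, expected * observed.sum() / expected.sum())
        assert p > 0.001


class TestOccupancyPercentiles:
    def test_single_species_degenerate_null(self):
        mat = pd.DataFrame(
            {"natural": [10], "agricultural": [5], "urban": [2]}, index=["A"]
        )
        res = occupancy_percentiles(mat, n_sim=200, seed=1)
        assert (res.table["percentile"] == 0).all()
        assert (res.table["klass"] == "low").all()

    def test_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(
            rng.integers(0, 60, size=(8, 3)),
            columns=list(HABITATS),
            index=[f"sp{i}" for i in range(8)],
        )
        a = occupancy_percentiles(mat, n_sim=300, seed=42)
        b = occupancy_percentiles(mat, n_sim=300, seed=42)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        mat = pd.DataFrame(
            rng.integers(0, 40, size=(6, 3)),
            columns=list(HABITATS),
            index=[f"sp{i}" for i in range(6)],
        )
        perm = ["urban", "natural", "agricultural"]
        permuted = mat[perm]
        a = occupancy_percentiles(mat, n_sim=400, seed=9)
        b = occupancy_percentiles(permuted, n_sim=400, seed=9)
        pa = a.matrix("percentile")
        pb = b.table.pivot(index="species", columns="habitat", values="percentile")
        for hab in HABITATS:
            np.testing.assert_allclose(pa[hab], pb[hab])

    def test_percentiles_bounded(self):
        rng = np.random.default_rng(6)
        mat = pd.DataFrame(
            rng.integers(0, 30, size=(5, 3)),
            columns=list(HABITATS),
            index=[f"sp{i}" for i in range(5)],
        )
        res = occupancy_percentiles(mat, n_sim=100, seed=2)
        assert res.table["percentile"].between(0, 100).all()
        # exactly one class per cell
        assert res.table["klass"].isin(["low", "intermediate", "high"]).all()
        assert len(res.table) == 15

    def test_half_tie_policy_not_below_strict(self):
        mat = pd.DataFrame(
            {"natural": [10, 3], "agricultural": [5, 5], "urban": [2, 9]},
            index=["A", "B"],
        )
        strict = occupancy_percentiles(mat, n_sim=500, seed=4, ties="strict")
        half = occupancy_percentiles(mat, n_sim=500, seed=4, ties="half")
        assert (half.table["percentile"] >= strict.table["percentile"]).all()


class TestClassifyOccupancy:
    @pytest.mark.parametrize(
        "value,expected",
        [(85.0, "high"), (20.0, "intermediate"), (80.0, "intermediate"), (19.9, "low")],
    )
    def test_strict_thresholds(self, value, expected):
        assert classify_occupancy(np.array([value]))[0] == expected

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            classify_occupancy(np.array([50.0]), high=20, low=80)
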