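"""Interval algebra: normalization, mask building, hotspot rules, quantiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linkedsel.intervals import (
    GenomeLayout,
    IntervalTrack,
    MaskSet,
    bin_membership,
    build_neutral_mask,
    disjoint_bins,
    hotspot_exclusion,
    normalize_track,
    quantile_thresholds,
    track_intersect,
    track_subtract,
    track_union,
)


def covered_positions(track, contig, upto):
    """Per-base membership oracle: pure-python interval walk."""
    out = set()
    for iv in track.to_list():
        if iv[0] == contig:
            out |= set(range(iv[1], min(iv[2], upto)))
    return out


class TestNormalize:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ([("c1", 10, 20), ("c1", 15, 30)], [("c1", 10, 30)]),
            ([], []),
            ([("c1", 5, 6), ("c1", 6, 7)], [("c1", 5, 7)]),
            ([("c1", 0, 3), ("c2", 0, 3)], [("c1", 0, 3), ("c2", 0, 3)]),
        ],
    )
    def test_merges_overlap_and_adjacency(self, raw, expected):
        assert normalize_track(IntervalTrack(raw)).to_list() == expected

    def test_rejects_interval_beyond_contig_end(self):
        layout = GenomeLayout({"c1": 50})
        with pytest.raises(ValueError, match="c1"):
            normalize_track(IntervalTrack([("c1", 40, 60)]), layout)

    def test_rejects_empty_interval(self):
        with pytest.raises(ValueError):
            IntervalTrack([("c1", 10, 10)])

    def test_value_tracks_are_not_merged(self):
        t = IntervalTrack([("c1", 0, 5, 0.1), ("c1", 5, 10, 0.9)])
        assert len(normalize_track(t).to_list()) == 2


class TestNeutralMask:
    def test_include_minus_exclude(self):
        layout = GenomeLayout({"c1": 100})
        masks = MaskSet(
            include={"accessible": IntervalTrack([("c1", 0, 100)])},
            exclude={"repeats": IntervalTrack([("c1", 40, 60)])},
        )
        assert build_neutral_mask(masks, layout).to_list() == [
            ("c1", 0, 40), ("c1", 60, 100),
        ]

    def test_empty_include_set_means_whole_layout(self):
        layout = GenomeLayout({"c1": 70, "c2": 30})
        got = build_neutral_mask(MaskSet(), layout)
        assert got.total_bp == 100

    def test_exclude_covering_everything_gives_empty(self):
        layout = GenomeLayout({"c1": 50})
        masks = MaskSet(
            include={"a": IntervalTrack([("c1", 10, 30)])},
            exclude={"b": IntervalTrack([("c1", 0, 50)])},
        )
        assert build_neutral_mask(masks, layout).to_list() == []

    @settings(max_examples=50, deadline=None)
    @given(st.data())
    def test_matches_per_base_set_arithmetic(self, data):
        n_inc = data.draw(st.integers(1, 3))
        n_exc = data.draw(st.integers(0, 3))
        layout = GenomeLayout({"c1": 2000})

        def draw_track():
            ivs = data.draw(
                st.lists(
                    st.tuples(st.integers(0, 1990), st.integers(1, 200)),
                    min_size=1, max_size=6,
                )
            )
            return IntervalTrack(
                [("c1", s, min(s + l, 2000)) for s, l in ivs]
            )

        inc = {f"i{k}": draw_track() for k in range(n_inc)}
        exc = {f"e{k}": draw_track() for k in range(n_exc)}
        got = build_neutral_mask(MaskSet(include=inc, exclude=exc), layout)
        expect = set.intersection(
            *[covered_positions(t, "c1", 2000) for t in inc.values()]
        )
        for t in exc.values():
            expect -= covered_positions(t, "c1", 2000)
        assert covered_positions(got, "c1", 2000) == expect


class TestSetOps:
    def test_against_pyranges(self):
        """Independent cross-check of subtract/intersect via pyranges."""
        pytest.importorskip("pyranges")
        import pandas as pd
        import pyranges as pr

        rng = np.random.default_rng(5)
        a_iv = [("c1", int(s), int(s) + int(l)) for s, l in
                zip(rng.integers(0, 5000, 20), rng.integers(1, 400, 20))]
        b_iv = [("c1", int(s), int(s) + int(l)) for s, l in
                zip(rng.integers(0, 5000, 20), rng.integers(1, 400, 20))]
        a, b = IntervalTrack(a_iv), IntervalTrack(b_iv)

        def to_pr(ivs):
            df = pd.DataFrame(ivs, columns=["Chromosome", "Start", "End"])
            return pr.PyRanges(df)

        got = track_subtract(a, b)
        want = to_pr(a_iv).subtract(to_pr(b_iv)).merge()
        want_set = set()
        for _, row in want.df.iterrows():
            want_set |= set(range(row.Start, row.End))
        assert covered_positions(got, "c1", 6000) == want_set

        got_i = track_intersect([a, b])
        want_i = to_pr(a_iv).intersect(to_pr(b_iv)).merge()
        want_set_i = set()
        for _, row in want_i.df.iterrows():
            want_set_i |= set(range(row.Start, row.End))
        assert covered_positions(got_i, "c1", 6000) == want_set_i


class TestHotspotExclusion:
    def test_rate_site_flanked(self):
        rates = IntervalTrack([("c1", 5000, 5001, 10.5)])
        got = hotspot_exclusion(rates, None)
        assert got.to_list() == [("c1", 3500, 6501)]

    def test_rate_below_threshold_ignored(self):
        rates = IntervalTrack([("c1", 5000, 5001, 9.9)])
        assert hotspot_exclusion(rates, None).to_list() == []

    def test_hotspot_centered_window(self):
        hs = IntervalTrack([("c1", 9500, 10500)])
        assert hotspot_exclusion(None, hs).to_list() == [("c1", 8500, 11500)]

    def test_long_hotspot_kept_as_is(self):
        hs = IntervalTrack([("c1", 8000, 12000)])
        assert hotspot_exclusion(None, hs).to_list() == [("c1", 8000, 12000)]

    def test_idempotent_under_renormalization(self):
        rates = IntervalTrack(
            [("c1", 1000, 1200, 12.0), ("c1", 1500, 1600, 15.0), ("c1", 9000, 9100, 3.0)]
        )
        hs = IntervalTrack([("c1", 2000, 2500), ("c1", 30000, 34500)])
        got = hotspot_exclusion(rates, hs)
        again = normalize_track(got)
        assert got.to_list() == again.to_list()

    def test_midpoint_mode(self):
        rates = IntervalTrack([("c1", 4000, 6000, 11.0)])
        got = hotspot_exclusion(rates, None, rate_mode="midpoint")
        assert got.to_list() == [("c1", 3500, 6500)]


class TestQuantiles:
    def test_equal_length_intervals(self):
        bm = IntervalTrack([("c1", 0, 10, 0.1), ("c1", 10, 20, 0.5), ("c1", 20, 30, 0.9)])
        assert quantile_thresholds(bm, 0.01)[0] == pytest.approx(0.1)

    def test_constant_map(self):
        bm = IntervalTrack([("c1", 0, 10, 0.7), ("c1", 10, 50, 0.7)])
        for q in (0.01, 0.25, 0.5, 0.99):
            assert quantile_thresholds(bm, q)[0] == pytest.approx(0.7)

    def test_empty_map_errors(self):
        with pytest.raises(ValueError):
            quantile_thresholds(IntervalTrack([]), 0.1)

    def test_monotone_and_matches_per_base_oracle(self, rng):
        starts = np.arange(0, 5000, 50)
        vals = rng.uniform(0, 1, len(starts))
        lens = rng.integers(10, 50, len(starts))
        bm = IntervalTrack(
            [("c1", int(s), int(s + l), float(v)) for s, l, v in zip(starts, lens, vals)]
        )
        qs = np.linspace(0.05, 0.95, 19)
        got = quantile_thresholds(bm, qs)
        assert (np.diff(got) >= 0).all()
        # per-base enumeration oracle (length-weighted)
        per_base = np.concatenate([np.full(l, v) for l, v in zip(lens, vals)])
        per_base.sort()
        for q, g in zip(qs, got):
            idx = int(np.ceil(q * len(per_base))) - 1
            assert g == pytest.approx(per_base[max(idx, 0)])


class TestBinMembership:
    def test_lowest_bin_is_low_value_interval(self):
        bm = IntervalTrack([("c1", 0, 10, 0.1), ("c1", 10, 20, 0.5), ("c1", 20, 30, 0.9)])
        bins = bin_membership(bm)
        assert bins["lowest_1pct"].to_list() == [("c1", 0, 10)]
        assert bins["highest_1pct"].to_list() == [("c1", 20, 30)]

    def test_nested_low_bins(self, rng):
        vals = rng.uniform(0, 1, 200)
        bm = IntervalTrack(
            [("c1", 10 * i, 10 * i + 10, float(v)) for i, v in enumerate(vals)]
        )
        bins = bin_membership(bm)
        low1 = covered_positions(bins["lowest_1pct"], "c1", 2000)
        low25 = covered_positions(bins["lowest_25pct"], "c1", 2000)
        assert low1 <= low25

    def test_disjoint_two_percent_bins_partition_the_map(self, rng):
        vals = rng.uniform(0, 1, 300)
        bm = IntervalTrack(
            [("c1", 10 * i, 10 * i + 10, float(v)) for i, v in enumerate(vals)]
        )
        tracks, bounds = disjoint_bins(bm, 50)
        total = sum(t.total_bp for t in tracks)
        assert total == 3000
        sets = [covered_positions(t, "c1", 3000) for t in tracks]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert not (sets[i] & sets[j])

    def test_constant_map_occupies_single_bin(self):
        bm = IntervalTrack([("c1", 0, 100, 0.7)])
        tracks, _ = disjoint_bins(bm, 50)
        occupied = [t for t in tracks if t.total_bp > 0]
        assert len(occupied) == 1 and occupied[0].total_bp == 100


def test_union_subtract_roundtrip(rng):
    a = IntervalTrack([("c1", 0, 50), ("c1", 80, 120)])
    b = IntervalTrack([("c1", 40, 90)])
    u = track_union([a, b])
    assert u.to_list() == [("c1", 0, 120)]
    assert track_subtract(u, b).to_list() == [("c1", 0, 40), ("c1", 90, 120)]
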