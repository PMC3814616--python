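"""Pointwise transformed-Hill Kd estimation and panel handling."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from offkin.binding import (
    AffinityEstimate,
    ConcentrationSeries,
    PanelParseError,
    PercentControlProfile,
    classify_affinity,
    estimate_kd,
    parse_panel_table,
    pointwise_kd,
    round_half_up,
    selectivity_table,
)

SERIES = ConcentrationSeries((50, 200, 1000, 10000))


def profile(pc, name="K1", drug="PLX4720"):
    return PercentControlProfile(
        kinase_name=name, gene_symbol=name, drug=drug, pc=tuple(pc)
    )


class TestPointwise:
    @pytest.mark.parametrize(
        "conc, pc, expected",
        [
            (100.0, 50.0, 100.0),      # half-displacement: Kd equals conc
            (10000.0, 0.0, 0.0),       # complete displacement
            (50.0, 20.0, 12.5),        # direct evaluation of c*PC/(100-PC)
        ],
    )
    def test_transform(self, conc, pc, expected):
        assert pointwise_kd(conc, pc) == pytest.approx(expected)

    @pytest.mark.parametrize("pc", [100.0, 101.0, 350.0])
    def test_no_displacement_point_is_excluded(self, pc):
        assert pointwise_kd(1000.0, pc) is None

    @pytest.mark.parametrize("conc, pc", [(-1.0, 50.0), (0.0, 50.0), (100.0, -2.0)])
    def test_invalid_inputs_rejected(self, conc, pc):
        with pytest.raises(ValueError):
            pointwise_kd(conc, pc)

    @given(
        st.floats(min_value=0.0, max_value=99.0),
        st.floats(min_value=0.1, max_value=99.9),
    )
    @settings(max_examples=100, deadline=None)
    def test_strictly_increasing_in_pc(self, lo, delta):
        hi = lo + delta * (99.9 - lo) / 100.0
        if hi <= lo:
            return
        assert pointwise_kd(500.0, hi) > pointwise_kd(500.0, lo)


class TestEstimate:
    @pytest.mark.parametrize(
        "pc, expected, n_used",
        [
            ((20, 4, 0.7, 0.1), 9.47, 4),            # all points used
            ((96, 100, 63, 8), 1257.42, 3),          # interior pc=100 dropped
            ((89, 98, 97, 100), 14179.29, 3),        # top-concentration pc=100 dropped
            ((1.9, 0.55, 0.05, 0), 0.64, 4),         # pc=0 contributes 0 to the mean
            ((38, 19, 3.9, 0.1), 32.04, 4),
        ],
    )
    def test_reported_two_decimal_values(self, pc, expected, n_used):
        est = estimate_kd(profile(pc), SERIES)
        assert est.n_used == n_used
        assert round_half_up(est.kd_nM, 2) == pytest.approx(expected, abs=0.011)

    def test_full_censoring(self):
        est = estimate_kd(profile((100, 100, 100, 100)), SERIES)
        assert est.censored
        assert est.kd_nM is None
        assert est.n_used == 0
        assert est.censor_bound_nM == 10000
        assert est.render() == ">10,000"

    def test_censored_iff_every_point_at_or_above_threshold(self):
        for pc in [(100, 100, 99.9, 100), (100, 100, 100, 0.1)]:
            assert not estimate_kd(profile(pc), SERIES).censored
        assert estimate_kd(profile((100, 101, 100.5, 100)), SERIES).censored

    def test_misaligned_profile_rejected(self):
        with pytest.raises(ValueError, match="readings"):
            estimate_kd(profile((50, 50)), SERIES)

    def test_estimate_invariants_enforced(self):
        with pytest.raises(ValueError):
            AffinityEstimate(
                kinase_name="x", gene_symbol="x", drug="d",
                kd_nM=1.0, pointwise_nM=(1.0,), n_used=0, censored=True,
            )

    @given(st.floats(min_value=1.0, max_value=5000.0))
    @settings(max_examples=80, deadline=None)
    def test_noiseless_single_site_profile_recovers_kd(self, kd):
        # PC(c) = 100/(1 + c/Kd) makes every pointwise estimate equal Kd
        pc = tuple(100.0 / (1.0 + c / kd) for c in SERIES)
        est = estimate_kd(profile(pc), SERIES)
        assert est.kd_nM == pytest.approx(kd, rel=1e-9)

    @given(
        st.floats(min_value=1.0, max_value=5000.0),
        st.floats(min_value=0.01, max_value=100.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_scale_equivariance(self, kd, lam):
        pc = tuple(100.0 / (1.0 + c / kd) for c in SERIES)
        scaled = ConcentrationSeries(tuple(c * lam for c in SERIES))
        base = estimate_kd(profile(pc), SERIES).kd_nM
        assert estimate_kd(profile(pc), scaled).kd_nM == pytest.approx(
            lam * base, rel=1e-9
        )


class TestClassification:
    def test_categories(self):
        high = estimate_kd(profile((20, 4, 0.7, 0.1)), SERIES)
        assert classify_affinity(high) == "high_affinity"          # Kd 9.47
        censored = estimate_kd(profile((100,) * 4), SERIES)
        assert classify_affinity(censored) == "above_range"
        weak = estimate_kd(profile((96, 100, 63, 8)), SERIES)
        assert classify_affinity(weak) == "weak"                   # Kd 1257

    def test_boundary_is_strict(self):
        est = AffinityEstimate(
            kinase_name="x", gene_symbol="x", drug="d",
            kd_nM=50.0, pointwise_nM=(50.0,), n_used=1, censored=False,
        )
        assert classify_affinity(est, threshold_nM=50.0) == "intermediate"

    def test_bad_threshold(self):
        est = estimate_kd(profile((20, 4, 0.7, 0.1)), SERIES)
        with pytest.raises(ValueError):
            classify_affinity(est, threshold_nM=-5.0)


class TestSelectivity:
    def make_panel(self):
        return [
            estimate_kd(profile((20, 4, 0.7, 0.1), name="ZAK"), SERIES),
            estimate_kd(profile((38, 19, 3.9, 0.1), name="BRAF(V600E)"), SERIES),
            estimate_kd(profile((100,) * 4, name="MLK1"), SERIES),
        ]

    def test_ratio_to_reference(self):
        records = selectivity_table(self.make_panel(), "BRAF(V600E)")
        by_name = {r.kinase_name: r for r in records}
        assert by_name["ZAK"].ratio == pytest.approx(9.47 / 32.04, rel=1e-2)
        assert by_name["BRAF(V600E)"].ratio == pytest.approx(1.0)
        assert by_name["MLK1"].category == "above_range"
        assert by_name["MLK1"].ratio is None
        # sorted ascending by Kd, censored appended last
        assert [r.kinase_name for r in records] == ["ZAK", "BRAF(V600E)", "MLK1"]

    def test_missing_or_censored_reference_rejected(self):
        panel = self.make_panel()
        with pytest.raises(ValueError, match="not in panel"):
            selectivity_table(panel, "NOPE")
        with pytest.raises(ValueError, match="censored"):
            selectivity_table(panel, "MLK1")


class TestParser:
    def test_packaged_panels_parse_fully(self, plx_profiles, vem_profiles):
        for series, profiles in (plx_profiles, vem_profiles):
            assert len(profiles) == 38
            assert len(series) == 4

    def test_header_only_file(self, tmp_path):
        f = tmp_path / "empty.tsv"
        f.write_text("kinase_name\tgene_symbol\tpc_50\tpc_200\tpc_1000\tpc_10000\n")
        assert parse_panel_table(f, drug="d") == []

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        f = tmp_path / "bad.tsv"
        f.write_text(
            "kinase_name\tgene_symbol\tpc_50\tpc_200\tpc_1000\tpc_10000\n"
            "K1\tK1\t50\tNA\t10\t1\n"
        )
        with pytest.raises(PanelParseError, match=r"row 1.*pc_200"):
            parse_panel_table(f, drug="d")

    def test_missing_cell_rejected(self, tmp_path):
        f = tmp_path / "short.tsv"
        f.write_text(
            "kinase_name\tgene_symbol\tpc_50\tpc_200\tpc_1000\tpc_10000\n"
            "K1\tK1\t50\t20\t10\n"
        )
        with pytest.raises(PanelParseError, match="missing value"):
            parse_panel_table(f, drug="d")


def test_series_validation():
    with pytest.raises(ValueError):
        ConcentrationSeries(())
    with pytest.raises(ValueError):
        ConcentrationSeries((50, 50, 100))
    with pytest.raises(ValueError):
        ConcentrationSeries((-1, 10))


def test_profile_flags_noisy_values_above_100():
    p = profile((105, 50, 10, 1))
    assert p.flagged_points == (0,)
    assert not math.isnan(estimate_kd(p, SERIES).kd_nM)
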