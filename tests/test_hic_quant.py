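"""HIC peak integration, DAR arithmetic, replicate stats, heart-cuts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cysadc.hic_quant import (
    Chromatogram,
    dar_from_areas,
    detect_peaks,
    extract_heart_cut,
    group_areas,
    replicate_stats,
)

TABLE2 = {
    "low": {0: 16.73, 2: 40.71, 4: 28.56, 6: 12.54, 8: 1.50},
    "medium": {0: 2.80, 2: 18.85, 4: 41.69, 6: 26.87, 8: 9.79},
    "high": {0: 0.37, 2: 3.42, 4: 30.67, 6: 28.60, 8: 36.90},
}


def _gaussian_chrom(apexes, sigmas, areas, t_max=10.0, hz=20.0):
    t = np.arange(0.0, t_max, 1.0 / (hz * 60.0))
    y = np.zeros_like(t)
    for apex, sigma, area in zip(apexes, sigmas, areas):
        y += area / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((t - apex) / sigma) ** 2)
    return Chromatogram(time=t, intensity=y)


class TestDetectPeaks:
    def test_single_gaussian_area_matches_analytic(self):
        chrom = _gaussian_chrom([5.0], [0.1], [2.5])
        table = detect_peaks(chrom)
        assert len(table.peaks) == 1
        assert table.peaks[0].area == pytest.approx(2.5, rel=0.005)
        assert table.peaks[0].apex_time == pytest.approx(5.0, abs=0.01)

    def test_two_resolved_equal_gaussians_split_fifty_fifty(self):
        chrom = _gaussian_chrom([3.0, 7.0], [0.1, 0.1], [1.0, 1.0])
        table = detect_peaks(chrom)
        rel = table.relative_areas()
        assert sorted(rel) == ["A", "B"]
        assert rel["A"] == pytest.approx(50.0, abs=0.05)
        assert rel["B"] == pytest.approx(50.0, abs=0.05)

    def test_fixture_profile_yields_eight_labeled_peaks(self):
        from cysadc.synthetic_data import batch_config, make_hic_chromatogram

        cfg = batch_config("high", seed=0)
        chrom, _ = make_hic_chromatogram(cfg, 0)
        table = detect_peaks(chrom)
        assert [p.label for p in table.peaks] == list("ABCDEFGH")
        apexes = [p.apex_time for p in table.peaks]
        assert apexes == sorted(apexes)

    def test_relative_areas_sum_to_hundred(self):
        chrom = _gaussian_chrom([2, 4, 6, 8], [0.1] * 4, [1, 2, 3, 4])
        rel = detect_peaks(chrom).relative_areas()
        assert sum(rel.values()) == pytest.approx(100.0, abs=0.01)

    def test_non_monotone_time_grid_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            Chromatogram(time=np.array([0.0, 1.0, 0.5]), intensity=np.zeros(3))


class TestGroupingAndDar:
    def test_grouping_sums_member_peaks(self):
        chrom = _gaussian_chrom([2, 4, 6], [0.08] * 3, [1.0, 1.0, 2.0])
        table = detect_peaks(chrom)
        grouped = group_areas(table, {"A": 0, "B": 4, "C": 4})
        assert grouped[0] == pytest.approx(25.0, abs=0.1)
        assert grouped[4] == pytest.approx(75.0, abs=0.1)

    def test_unassigned_peak_raises_with_label(self):
        chrom = _gaussian_chrom([2, 6], [0.08] * 2, [1.0, 1.0])
        table = detect_peaks(chrom)
        with pytest.raises(ValueError, match="B"):
            group_areas(table, {"A": 0})

    @pytest.mark.parametrize(
        "batch, expected_dar, expected_contribs",
        [
            ("low", 2.83, {0: 0.00, 2: 0.81, 4: 1.14, 6: 0.75, 8: 0.12}),
            ("medium", 4.44, {0: 0.00, 2: 0.38, 4: 1.67, 6: 1.61, 8: 0.78}),
            ("high", 5.96, {0: 0.00, 2: 0.07, 4: 1.23, 6: 1.72, 8: 2.95}),
        ],
    )
    def test_dar_from_printed_batch_areas(self, batch, expected_dar, expected_contribs):
        report = dar_from_areas(TABLE2[batch]).rounded()
        assert report.total_dar == pytest.approx(expected_dar, abs=0.01)
        for load, contrib in expected_contribs.items():
            assert report.dar_contribution[load] == pytest.approx(contrib, abs=0.01)

    def test_single_load_extremes(self):
        assert dar_from_areas({0: 100.0}).total_dar == 0.0
        assert dar_from_areas({8: 100.0}).total_dar == 8.0

    def test_negative_percent_rejected(self):
        with pytest.raises(ValueError):
            dar_from_areas({0: -1.0, 2: 101.0})

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=100.0), min_size=5, max_size=5),
        st.floats(min_value=0.1, max_value=10.0),
    )
    def test_scaling_invariance_and_bounds(self, raw, scale):
        total = sum(raw) or 1.0
        percents = {load: 100.0 * v / total for load, v in zip((0, 2, 4, 6, 8), raw)}
        base = dar_from_areas(percents).total_dar
        scaled = dar_from_areas({k: v * scale for k, v in percents.items()}).total_dar / scale
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)
        assert 0.0 <= base <= 8.0


class TestReplicateStats:
    def _report(self, percents):
        return dar_from_areas(percents)

    def test_identical_replicates_have_zero_rsd(self):
        reports = [self._report(TABLE2["low"])] * 3
        summary = replicate_stats(reports)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in summary.rsd_area_percent.values())
        assert summary.rsd_total_dar == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_total_dar_rsd(self):
        # totals 2.82 / 2.83 / 2.84: mean 2.83, sample sd 0.01, RSD 0.3534%
        reports = []
        for shift in (-1.0, 0.0, 1.0):  # shift 1% of area from load 0 to load 2
            pct = dict(TABLE2["low"])
            pct[0] -= 0.5 * shift
            pct[2] += 0.5 * shift
            reports.append(self._report(pct))
        summary = replicate_stats(reports)
        assert summary.mean_total_dar == pytest.approx(2.83, abs=0.005)
        assert summary.rsd_total_dar == pytest.approx(100 * 0.01 / 2.83, rel=0.01)

    def test_single_replicate_flags_undefined_rsd(self):
        summary = replicate_stats([self._report(TABLE2["low"])])
        assert not summary.rsd_defined
        assert summary.rsd_total_dar is None

    def test_mismatched_groupings_rejected(self):
        with pytest.raises(ValueError):
            replicate_stats([self._report({0: 100.0}), self._report({0: 50.0, 2: 50.0})])


class TestHeartCut:
    def test_programmed_window_volume(self):
        chrom = _gaussian_chrom([5.0], [0.1], [1.0])
        cut = extract_heart_cut(chrom, 4.9, 5.1, flow_rate=0.500)
        assert cut.volume == pytest.approx(0.100, abs=1e-12)

    def test_zero_width_window_is_empty(self):
        chrom = _gaussian_chrom([5.0], [0.1], [1.0])
        cut = extract_heart_cut(chrom, 5.0, 5.0, flow_rate=0.500)
        assert cut.volume == 0.0
        assert cut.composition == {}

    def test_window_outside_run_rejected(self):
        chrom = _gaussian_chrom([5.0], [0.1], [1.0])
        with pytest.raises(ValueError, match="outside"):
            extract_heart_cut(chrom, 9.5, 10.5, flow_rate=0.5)

    def test_post_apex_cut_enriches_later_species(self):
        t = np.arange(0.0, 10.0, 1 / 1200)
        early = np.exp(-0.5 * ((t - 5.0) / 0.15) ** 2)
        late = np.exp(-0.5 * ((t - 5.3) / 0.15) ** 2)
        chrom = Chromatogram(time=t, intensity=early + late)
        profiles = {"early": early, "late": late}
        centered = extract_heart_cut(chrom, 4.9, 5.1, 0.5, species_profiles=profiles)
        post_apex = extract_heart_cut(chrom, 5.1, 5.3, 0.5, species_profiles=profiles)
        assert post_apex.composition["late"] > centered.composition["late"]

    def test_purge_delay_trims_composition_window(self):
        t = np.arange(0.0, 10.0, 1 / 1200)
        early = np.exp(-0.5 * ((t - 5.0) / 0.1) ** 2)
        late = np.exp(-0.5 * ((t - 5.4) / 0.1) ** 2)
        chrom = Chromatogram(time=t, intensity=early + late)
        profiles = {"early": early, "late": late}
        full = extract_heart_cut(chrom, 5.0, 5.4, 0.5, species_profiles=profiles)
        trimmed = extract_heart_cut(chrom, 5.0, 5.4, 0.5, purge_delay=0.05, species_profiles=profiles)
        # volume reflects the valve window, not the trimmed analyte window
        assert trimmed.volume == full.volume
        assert trimmed.composition != full.composition
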