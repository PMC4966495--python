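"""Peak picking, charge-comb deconvolution, ppm errors, mass-delta lookup."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cysadc.ms_tools import (
    PROTON_MASS,
    MassSpectrum,
    Modification,
    ModificationTable,
    deconvolve,
    explain_mass_delta,
    pick_peaks,
    ppm_error,
)


def _envelope_spectrum(mass, charges, sigma_mz=0.15, grid_step=0.02, pad=10.0):
    """Test-local envelope builder, independent of the package generator."""
    mzs = [(mass + z * PROTON_MASS) / z for z in charges]
    grid = np.arange(min(mzs) - pad, max(mzs) + pad, grid_step)
    y = np.zeros_like(grid)
    for mz in mzs:
        y += np.exp(-0.5 * ((grid - mz) / sigma_mz) ** 2)
    return MassSpectrum(mz=grid, intensity=y)


class TestPickPeaks:
    def test_single_gaussian_centroid(self):
        grid = np.arange(990.0, 1010.0, 0.01)
        y = np.exp(-0.5 * ((grid - 1000.0) / 0.2) ** 2)
        centroids = pick_peaks(MassSpectrum(mz=grid, intensity=y))
        assert len(centroids) == 1
        assert centroids[0][0] == pytest.approx(1000.0, abs=0.01)

    def test_flat_zero_spectrum_is_empty(self):
        grid = np.arange(500.0, 600.0, 0.1)
        assert pick_peaks(MassSpectrum(mz=grid, intensity=np.zeros_like(grid))) == []

    def test_fixture_envelope_has_one_centroid_per_charge(self):
        spec = _envelope_spectrum(23580.0, range(15, 26))
        centroids = pick_peaks(spec)
        assert len(centroids) == 11

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError):
            MassSpectrum(mz=np.array([]), intensity=np.array([]))


class TestDeconvolve:
    def test_single_species_round_trip(self):
        spec = _envelope_spectrum(23580.0, range(15, 26))
        results = deconvolve(spec, (23000, 24100), (15, 25), grid_step=0.1)
        assert results
        assert results[0].neutral_average_mass == pytest.approx(23580.0, abs=0.5)
        assert len(results[0].supporting_charges) >= 2

    def test_two_species_recovered_in_intensity_order(self):
        s1 = _envelope_spectrum(23580.0, range(15, 26))
        s2 = _envelope_spectrum(51630.6, range(30, 46))
        grid = np.arange(900.0, 2000.0, 0.02)
        y = 2.0 * np.interp(grid, s1.mz, s1.intensity, left=0, right=0)
        y += np.interp(grid, s2.mz, s2.intensity, left=0, right=0)
        spec = MassSpectrum(mz=grid, intensity=y)
        light = deconvolve(spec, (23000, 24100), (15, 25), grid_step=0.1)
        heavy = deconvolve(spec, (51000, 52300), (30, 45), grid_step=0.1)
        assert light[0].neutral_average_mass == pytest.approx(23580.0, abs=1.0)
        assert heavy[0].neutral_average_mass == pytest.approx(51630.6, abs=1.0)
        assert light[0].score > heavy[0].score

    def test_single_charge_state_is_ambiguous(self):
        spec = _envelope_spectrum(23580.0, [20])
        results = deconvolve(spec, (23000, 24100), (15, 25), grid_step=0.1)
        assert results == []

    def test_doubling_intensities_doubles_scores_not_masses(self):
        spec = _envelope_spectrum(23580.0, range(15, 26))
        doubled = MassSpectrum(mz=spec.mz, intensity=2 * spec.intensity)
        r1 = deconvolve(spec, (23300, 23900), (15, 25), grid_step=0.1)
        r2 = deconvolve(doubled, (23300, 23900), (15, 25), grid_step=0.1)
        assert r2[0].score == pytest.approx(2 * r1[0].score, rel=1e-9)
        assert r2[0].neutral_average_mass == pytest.approx(r1[0].neutral_average_mass, abs=1e-9)

    def test_invalid_windows_rejected(self):
        spec = _envelope_spectrum(23580.0, range(15, 26))
        with pytest.raises(ValueError):
            deconvolve(spec, (24000, 23000), (15, 25))
        with pytest.raises(ValueError):
            deconvolve(spec, (23000, 24000), (15, 25), grid_step=0.0)
        with pytest.raises(ValueError):
            deconvolve(spec, (23000, 24000), (0, 25))

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        mass=st.floats(min_value=20_000.0, max_value=160_000.0),
        z_lo_frac=st.floats(min_value=0.0, max_value=1.0),
        n_charges=st.integers(min_value=3, max_value=12),
    )
    def test_round_trip_recovers_any_mass_within_grid_step(self, mass, z_lo_frac, n_charges):
        # contiguous charge set whose m/z stay inside 500-4000
        z_min_allowed = int(np.ceil(mass / 3800.0))
        z_max_allowed = max(int(mass / 600.0), z_min_allowed + n_charges)
        z_lo = z_min_allowed + int(z_lo_frac * (z_max_allowed - z_min_allowed - n_charges))
        charges = range(z_lo, z_lo + n_charges)
        spec = _envelope_spectrum(mass, charges)
        results = deconvolve(
            spec, (mass - 300, mass + 300), (z_lo, z_lo + n_charges - 1), grid_step=0.1
        )
        assert results
        assert abs(results[0].neutral_average_mass - mass) <= 0.1


class TestPpmError:
    @pytest.mark.parametrize(
        "observed, predicted, expected",
        [
            (23580.0, 23580.0, 0.0),
            (100001.0, 100000.0, 10.0),
            (23580.0, 23580.2, -8.48),
        ],
    )
    def test_values(self, observed, predicted, expected):
        assert ppm_error(observed, predicted) == pytest.approx(expected, abs=0.005)

    def test_nonpositive_predicted_rejected(self):
        with pytest.raises(ValueError):
            ppm_error(100.0, 0.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        a=st.floats(min_value=1000.0, max_value=200_000.0),
        rel=st.floats(min_value=-1e-4, max_value=1e-4),
    )
    def test_antisymmetry_to_first_order(self, a, rel):
        b = a * (1 + rel)
        assert ppm_error(a, b) == pytest.approx(-ppm_error(b, a), abs=0.01)
        assert ppm_error(a, a) == 0.0


class TestExplainMassDelta:
    @pytest.mark.parametrize(
        "delta, expected",
        [
            (-17.4, "dehydration"),  # the ~17 Da water-loss satellite
            (+162.1, "hexose"),  # G1F vs G0F spacing
            (0.0, None),
            (-40.0, None),
        ],
    )
    def test_lookup(self, delta, expected):
        mod = explain_mass_delta(delta)
        assert (mod.name if mod else None) == expected

    def test_overlapping_table_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            ModificationTable(
                entries=(Modification("a", 10.0, 2.0), Modification("b", 12.0, 2.0))
            )
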