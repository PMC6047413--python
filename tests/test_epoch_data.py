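import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somno.epoch_data import (
    BLOCK_SAMPLES,
    EpochSeries,
    EpochTableError,
    N_BINS,
    epoch_band_power,
    full_band_energy,
    load_epoch_table,
    normalize_swa,
    phase_from_index,
    spectral_bins,
    swa_from_spectra,
    write_epoch_table,
)
from conftest import build_series


def _write_table(path, rows, header="epoch_index\tstate\tartifact\tphase\tswa_frontal"):
    path.write_text("\n".join([header] + rows) + "\n")


class TestLoadEpochTable:
    def test_four_row_table(self, tmp_path):
        p = tmp_path / "t.tsv"
        _write_table(p, [f"{i}\tN\t0\tL\t100.0" for i in range(4)])
        s = load_epoch_table(p)
        assert s.n_ts == 4
        assert list(s.state) == ["N"] * 4
        assert s.derivations == ("frontal",)

    def test_unknown_state_cites_row(self, tmp_path):
        p = tmp_path / "t.tsv"
        rows = [f"{i}\tN\t0\tL\t100.0" for i in range(10)]
        rows[7] = "7\tX\t0\tL\t100.0"
        _write_table(p, rows)
        with pytest.raises(EpochTableError, match="row 7"):
            load_epoch_table(p)

    def test_missing_column(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("epoch_index\tstate\tartifact\n0\tN\t0\n")
        with pytest.raises(EpochTableError, match="phase"):
            load_epoch_table(p)

    def test_noncontiguous_index(self, tmp_path):
        p = tmp_path / "t.tsv"
        _write_table(p, ["0\tN\t0\tL\t1.0", "2\tN\t0\tL\t1.0"])
        with pytest.raises(EpochTableError, match="contiguous"):
            load_epoch_table(p)

    def test_ba_run_too_long(self, tmp_path):
        p = tmp_path / "t.tsv"
        _write_table(p, [f"{i}\tBA\t0\tL\t1.0" for i in range(6)])
        with pytest.raises(EpochTableError, match="brief-awakening"):
            load_epoch_table(p)

    def test_round_trip_bytewise(self, tmp_path):
        rng = np.random.default_rng(42)
        s = build_series(
            rng.choice(["W", "N", "R"], size=100),
            swa=rng.uniform(0, 300, 100),
            artifact=rng.random(100) < 0.05,
        )
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_epoch_table(s, p1)
        write_epoch_table(load_epoch_table(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_load_write_identity(self, tmp_path):
        s = build_series(["N", "W", "N", "R"], swa=[1.5, 2.25, 3.0, 0.125])
        p = tmp_path / "t.tsv"
        write_epoch_table(s, p)
        s2 = load_epoch_table(p)
        assert np.array_equal(s.state, s2.state)
        assert np.array_equal(s.swa["frontal"], s2.swa["frontal"])


class TestPhaseGrid:
    def test_alternates_starting_light(self):
        ph = phase_from_index(4 * 10_800)
        assert ph[0] == "L"
        assert ph[10_799] == "L"
        assert ph[10_800] == "D"
        assert ph[21_600] == "L"
        assert ph[32_400] == "D"

    def test_strict_phase_validation(self):
        s = build_series(["N"] * 4, phase=["L", "L", "D", "L"])
        with pytest.raises(EpochTableError, match="12:12"):
            s.validate(strict_phase=True)


class TestBandPower:
    def test_zero_signal(self):
        spec = epoch_band_power(np.zeros((3, BLOCK_SAMPLES)))
        assert np.all(spec.power == 0)

    def test_bin_grid(self):
        spec = epoch_band_power(np.zeros((1, BLOCK_SAMPLES)))
        assert spec.power.shape[1] == N_BINS == 81
        assert np.allclose(spec.bins, np.arange(81) * 0.25)
        assert spec.bins[0] == 0.0 and spec.bins[-1] == 20.0

    def test_sine_concentrates_at_its_bin(self):
        t = np.arange(BLOCK_SAMPLES) / 256.0
        x = np.sin(2 * np.pi * 2.0 * t)
        spec = epoch_band_power(x[None, :])
        k = int(np.argmax(spec.power[0]))
        assert spec.bins[k] == 2.0
        # oracle: naive DFT of the Hann-windowed signal at bin 8 (2 Hz)
        w = np.hanning(BLOCK_SAMPLES)
        n = np.arange(BLOCK_SAMPLES)
        X = np.sum(w * x * np.exp(-2j * np.pi * 8 * n / BLOCK_SAMPLES))
        expected = 2.0 * abs(X) ** 2 / BLOCK_SAMPLES
        assert spec.power[0, 8] == pytest.approx(expected, rel=1e-9)

    def test_parseval_against_time_domain(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(100, BLOCK_SAMPLES))
        total = full_band_energy(x)
        w = np.hanning(BLOCK_SAMPLES)
        energy = np.sum((x * w) ** 2, axis=1)
        assert np.allclose(total, energy, rtol=1e-6)

    def test_wrong_block_length(self):
        with pytest.raises(ValueError, match="1024"):
            epoch_band_power(np.zeros((1, 512)))

    def test_nan_flags_artifact(self):
        x = np.zeros((2, BLOCK_SAMPLES))
        x[1, 5] = np.nan
        spec = epoch_band_power(x)
        assert not spec.artifact[0] and spec.artifact[1]
        assert np.all(np.isnan(spec.power[1]))


class TestSwaFromSpectra:
    def test_all_ones_gives_15(self):
        spec = epoch_band_power(np.zeros((1, BLOCK_SAMPLES)))
        spec.power[:] = 1.0
        assert swa_from_spectra(spec)[0] == 15.0

    def test_zero_spectrum(self):
        spec = epoch_band_power(np.zeros((1, BLOCK_SAMPLES)))
        assert swa_from_spectra(spec)[0] == 0.0

    def test_out_of_band_power_ignored(self):
        spec = epoch_band_power(np.zeros((1, BLOCK_SAMPLES)))
        spec.power[0, np.flatnonzero(spec.bins == 10.0)[0]] = 50.0
        assert swa_from_spectra(spec)[0] == 0.0

    def test_band_off_grid_rejected(self):
        spec = epoch_band_power(np.zeros((1, BLOCK_SAMPLES)))
        with pytest.raises(ValueError):
            swa_from_spectra(spec, band=(0.3, 4.0))
        with pytest.raises(ValueError):
            swa_from_spectra(spec, band=(0.5, 30.0))


class TestNormalizeSwa:
    def test_constant_all_n(self):
        s = build_series(["N"] * 8, swa=np.full(8, 5.0))
        out = normalize_swa(s)
        assert np.allclose(out.swa["frontal"], 100.0)

    def test_non_n_excluded_from_denominator(self):
        s = build_series(["N", "N", "W"], swa=[2.0, 4.0, 1000.0])
        out = normalize_swa(s)
        assert out.swa["frontal"][0] == pytest.approx(200 / 3)
        assert out.swa["frontal"][1] == pytest.approx(400 / 3)

    def test_no_baseline_nrem_errors(self):
        s = build_series(["W", "W"], swa=[1.0, 2.0])
        with pytest.raises(ValueError, match="NREMS"):
            normalize_swa(s)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_normalization_identity(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        states = rng.choice(["W", "N", "R"], size=n, p=[0.3, 0.6, 0.1])
        states[0] = "N"  # guarantee a usable baseline epoch
        art = rng.random(n) < 0.1
        art[0] = False
        s = build_series(states, swa=rng.uniform(0.1, 50, n), artifact=art)
        out = normalize_swa(s)
        usable = (out.state == "N") & ~out.artifact
        assert out.swa["frontal"][usable].mean() == pytest.approx(100.0, abs=1e-9)
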