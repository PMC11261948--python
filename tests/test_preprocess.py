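"""Montage arithmetic, notch/resample behavior, channel selection."""

import numpy as np
import pandas as pd
import pytest

from hfomorph.io import Recording
from hfomorph.preprocess import (
    PreprocConfig,
    apply_montage,
    notch_response,
    select_channels,
    standardize,
)


def _meta(names, types=None, bad=None):
    return pd.DataFrame(
        {
            "name": names,
            "type": types or ["grid"] * len(names),
            "soz": False,
            "resected": False,
            "bad": bad or [False] * len(names),
        }
    )


class TestMontage:
    def test_car_removes_mean(self):
        data = np.array([[1.0], [2.0], [3.0]]) * np.ones((3, 100))
        rec = Recording(data=data, fs=1000.0, ch_names=["G1", "G2", "G3"])
        out = apply_montage(rec, _meta(["G1", "G2", "G3"]))
        np.testing.assert_allclose(out.data[:, 0], [-1.0, 0.0, 1.0])
        assert out.montage == "CAR"

    def test_bipolar_difference(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal((2, 500))
        rec = Recording(data=np.stack([x, y]), fs=1000.0, ch_names=["A1", "A2"])
        out = apply_montage(rec, _meta(["A1", "A2"], types=["depth", "depth"]))
        assert out.ch_names == ["A1-A2"]
        np.testing.assert_allclose(out.data[0], x - y)

    def test_common_mode_line_noise_cancels(self):
        t = np.arange(2000) / 1000.0
        common = 50 * np.sin(2 * np.pi * 60 * t)
        rec = Recording(data=np.tile(common, (3, 1)), fs=1000.0,
                        ch_names=["G1", "G2", "G3"])
        out = apply_montage(rec, _meta(["G1", "G2", "G3"]))
        assert np.sqrt((out.data**2).mean()) < 1e-9 * np.sqrt((common**2).mean())

    def test_single_contact_shaft_dropped(self):
        rec = Recording(
            data=np.random.default_rng(1).standard_normal((3, 100)),
            fs=1000.0, ch_names=["A1", "A2", "B1"],
        )
        with pytest.warns(UserWarning, match="single contact"):
            out = apply_montage(rec, _meta(["A1", "A2", "B1"], types=["depth"] * 3))
        assert out.ch_names == ["A1-A2"]

    def test_bad_channel_excluded_from_reference(self):
        data = np.stack([np.ones(100), np.full(100, 3.0), np.full(100, 1000.0)])
        rec = Recording(data=data, fs=1000.0, ch_names=["G1", "G2", "G3"])
        out = apply_montage(rec, _meta(["G1", "G2", "G3"], bad=[False, False, True]))
        # reference is mean of G1, G2 only
        np.testing.assert_allclose(out.data[0], -1.0)
        np.testing.assert_allclose(out.data[1], 1.0)


class TestStandardize:
    def test_60hz_attenuated(self):
        t = np.arange(10000) / 1000.0
        x = np.sin(2 * np.pi * 60 * t)
        rec = Recording(data=x[np.newaxis], fs=1000.0)
        out = standardize(rec)
        steady = out.data[0, 1000:-1000]  # past the filter's ring-in
        assert np.sqrt((steady**2).mean()) <= 0.01 * np.sqrt((x**2).mean())

    def test_100hz_passes(self):
        t = np.arange(10000) / 1000.0
        x = np.sin(2 * np.pi * 100 * t)
        out = standardize(Recording(data=x[np.newaxis], fs=1000.0))
        steady = out.data[0, 1000:-1000]
        assert abs(np.sqrt((steady**2).mean()) - np.sqrt((x**2).mean())) < 0.1 * np.sqrt((x**2).mean())

    def test_2000hz_downsampled(self):
        rec = Recording(data=np.random.default_rng(2).standard_normal((2, 4000)), fs=2000.0)
        out = standardize(rec)
        assert out.fs == 1000.0
        assert out.n_samples == 2000

    def test_low_rate_rejected(self):
        rec = Recording(data=np.zeros((1, 500)), fs=500.0)
        with pytest.raises(ValueError, match="unsupported rate"):
            standardize(rec)

    def test_notch_attenuation_at_harmonics(self):
        """Filter-response oracle: >=40 dB notch depth at 60/120/180 Hz."""
        resp = notch_response(1000.0, np.array([60.0, 120.0, 180.0]))
        assert (20 * np.log10(resp) <= -40.0).all()
        passband = notch_response(1000.0, np.array([30.0, 100.0, 250.0]))
        assert (20 * np.log10(passband) >= -1.0).all()

    def test_idempotent_at_1khz_passband(self):
        """A second standardize pass leaves passband content untouched
        (idempotence up to filter transients and stopband edges)."""
        t = np.arange(10000) / 1000.0
        x = sum(np.sin(2 * np.pi * f * t) for f in (30.0, 100.0, 250.0))
        once = standardize(Recording(data=x[np.newaxis], fs=1000.0))
        twice = standardize(once)
        mid = slice(2000, -2000)  # ignore filter ring-in
        resid = twice.data[:, mid] - once.data[:, mid]
        assert np.sqrt((resid**2).mean()) < 1e-3 * np.sqrt((once.data[:, mid] ** 2).mean())

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((4, 3000))
        names = ["G1", "G2", "G3", "G4"]
        meta = _meta(names)
        out = standardize(apply_montage(Recording(data=data, fs=1000.0, ch_names=names), meta))
        perm = [2, 0, 3, 1]
        rec_p = Recording(data=data[perm], fs=1000.0, ch_names=[names[i] for i in perm])
        out_p = standardize(apply_montage(rec_p, meta))
        for i, name in enumerate(out_p.ch_names):
            np.testing.assert_allclose(out_p.data[i], out.data[out.ch_names.index(name)])


class TestSelectChannels:
    def test_drop_bad(self):
        rec = Recording(data=np.zeros((10, 100)), fs=1000.0,
                        ch_names=[f"G{i}" for i in range(10)])
        bad = [False] * 10
        bad[2] = bad[7] = True
        out = select_channels(rec, _meta(rec.ch_names, bad=bad))
        assert out.n_channels == 8
        assert "G2" not in out.ch_names

    def test_identity_when_clean(self):
        rec = Recording(data=np.zeros((3, 100)), fs=1000.0)
        out = select_channels(rec, _meta(rec.ch_names))
        assert out.ch_names == rec.ch_names

    def test_missing_flag_column(self):
        rec = Recording(data=np.zeros((2, 100)), fs=1000.0)
        with pytest.raises(ValueError, match="bad"):
            select_channels(rec, pd.DataFrame({"name": rec.ch_names}))

    def test_all_dropped(self):
        rec = Recording(data=np.zeros((2, 100)), fs=1000.0)
        with pytest.raises(ValueError, match="empty"):
            select_channels(rec, _meta(rec.ch_names, bad=[True, True]))
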