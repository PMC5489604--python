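"""Containers, portable round-trip, EDF reading, filtering, windowing, splits."""

import struct

import numpy as np
import pytest

import sccsp
from sccsp import preprocess_io as pio
from sccsp.errors import ConfigError, FormatError, ValidationError


def make_epochs(n_trials=4, n_channels=6, n_samples=100, fs=250.0, labels=True,
                positions=True, seed=0):
    rng = np.random.default_rng(seed)
    return sccsp.EpochSet(
        data=rng.standard_normal((n_trials, n_channels, n_samples)),
        fs=fs,
        channel_names=tuple(f"ch{i}" for i in range(n_channels)),
        channel_positions=(
            np.column_stack([np.linspace(-1, 1, n_channels), np.zeros(n_channels)])
            if positions else None
        ),
        labels=np.array(([1, 2] * n_trials)[:n_trials]) if labels else None,
    )


class TestEpochSet:
    def test_validates_label_count(self):
        with pytest.raises(ValidationError, match="2 classes"):
            sccsp.EpochSet(data=np.zeros((2, 2, 10)), fs=250, labels=np.array([1, 1]))

    def test_shape_accessors(self):
        ep = make_epochs(3, 5, 70)
        assert (ep.n_trials, ep.n_channels, ep.n_samples) == (3, 5, 70)

    def test_class_indices(self):
        ep = make_epochs(6)
        idx = ep.class_indices()
        assert set(idx) == {1, 2}
        assert len(idx[1]) == len(idx[2]) == 3


class TestPortableRoundTrip:
    def test_bit_exact_round_trip(self, tmp_path):
        ep = make_epochs()
        path = pio.write_epochs(ep, tmp_path / "epochs")
        back = pio.read_epochs(path)
        assert np.array_equal(back.data, ep.data)
        assert back.fs == ep.fs
        assert back.channel_names == ep.channel_names
        assert np.array_equal(back.labels, ep.labels)

    def test_unlabeled_round_trip_preserves_absence(self, tmp_path):
        ep = make_epochs(labels=False)
        path = pio.write_epochs(ep, tmp_path / "u.npz")
        assert pio.read_epochs(path).labels is None

    def test_empty_set_refused(self, tmp_path):
        ep = sccsp.EpochSet(data=np.zeros((0, 2, 10)), fs=250)
        with pytest.raises(ValidationError, match="0 trials"):
            pio.write_epochs(ep, tmp_path / "e.npz")

    def test_missing_sidecar_raises(self, tmp_path):
        ep = make_epochs()
        path = pio.write_epochs(ep, tmp_path / "x.npz")
        path.with_suffix(".json").unlink()
        with pytest.raises(FormatError, match="sidecar"):
            pio.read_epochs(path)

    def test_unknown_format_raises(self, tmp_path):
        with pytest.raises(ConfigError):
            pio.read_epochs(tmp_path / "y", format="fif")


# ---------------------------------------------------------------------------
# minimal EDF+ writer (synthetic fixture; only what the reader test needs)
# ---------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    return text.encode("ascii").ljust(width)[:width]


def write_minimal_edf(path, n_channels=22, fs=250, n_records=8,
                      events=((1.0, "769"), (3.0, "770"), (5.0, "769"))):
    """Write a tiny EDF+C file with an annotation channel carrying cue events."""
    ns = n_channels + 1  # + EDF Annotations
    spr = fs  # 1-second records
    ann_bytes = 64
    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad("synthetic patient", 80))
        fh.write(_pad("synthetic recording", 80))
        fh.write(_pad("01.01.20", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(256 * (ns + 1)), 8))
        fh.write(_pad("EDF+C", 44))
        fh.write(_pad(str(n_records), 8))
        fh.write(_pad("1", 8))
        fh.write(_pad(str(ns), 4))
        labels = [f"EEG {i:03d}" for i in range(n_channels)] + ["EDF Annotations"]
        for lab in labels:
            fh.write(_pad(lab, 16))
        for _ in range(ns):
            fh.write(_pad("", 80))  # transducer
        for i in range(ns):
            fh.write(_pad("uV" if i < n_channels else "", 8))
        for i in range(ns):
            fh.write(_pad("-250" if i < n_channels else "-1", 8))  # phys min
        for i in range(ns):
            fh.write(_pad("250" if i < n_channels else "1", 8))  # phys max
        for _ in range(ns):
            fh.write(_pad("-32768", 8))
        for _ in range(ns):
            fh.write(_pad("32767", 8))
        for _ in range(ns):
            fh.write(_pad("", 80))  # prefilter
        for i in range(ns):
            fh.write(_pad(str(spr if i < n_channels else ann_bytes // 2), 8))
        for _ in range(ns):
            fh.write(_pad("", 32))
        t = np.arange(spr) / fs
        for rec in range(n_records):
            wave = np.sin(2 * np.pi * 10.0 * (t + rec))
            digital = (wave * 1000).astype("<i2")
            for _ in range(n_channels):
                fh.write(digital.tobytes())
            tal = f"+{rec}\x14\x14\x00".encode()
            for onset, desc in events:
                if rec <= onset < rec + 1:
                    tal += f"+{onset:g}\x14{desc}\x14\x00".encode()
            fh.write(tal.ljust(ann_bytes, b"\x00"))


class TestEdfReading:
    def test_reads_channels_fs_and_events(self, tmp_path):
        pytest.importorskip("mne")
        path = tmp_path / "rec.edf"
        write_minimal_edf(path, n_channels=22, fs=250)
        ep = pio.read_epochs(path, format="edf", tmax=1.0)
        assert ep.fs == 250.0
        assert ep.n_channels == 22
        assert ep.n_trials == 3
        assert list(ep.labels) == [1, 2, 1]
        assert ep.n_samples == 250  # half-open [0, 1) s window

    def test_missing_events_raise_format_error(self, tmp_path):
        pytest.importorskip("mne")
        path = tmp_path / "plain.edf"
        write_minimal_edf(path, n_channels=4, events=())
        with pytest.raises(FormatError, match="events"):
            pio.read_epochs(path, format="edf", tmax=1.0)


class TestBandpass:
    def test_dc_removed(self):
        ep = sccsp.EpochSet(data=np.ones((1, 2, 1000)), fs=250.0)
        out = pio.bandpass_filter(ep)
        core = out.data[:, :, 125:-125]  # discard 0.5 s edge transient
        assert np.abs(core).max() < 1e-6

    @pytest.mark.parametrize(
        "freq,lo,hi",
        [(10.0, 0.95, 1.05), (45.0, 0.0, 0.2)],
    )
    def test_tone_attenuation_matches_response_oracle(self, freq, lo, hi):
        fs, n = 250.0, 4000
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * freq * t)
        ep = sccsp.EpochSet(data=x[None, None, :], fs=fs)
        y = pio.bandpass_filter(ep).data[0, 0, 500:-500]
        ratio = np.sqrt(np.mean(y**2)) / np.sqrt(0.5)
        # forward-backward filtering applies |H|^2
        from scipy import signal as sps

        sos = sps.butter(4, [5, 30], btype="bandpass", fs=fs, output="sos")
        _, h = sps.sosfreqz(sos, worN=[freq], fs=fs)
        expected = np.abs(h[0]) ** 2
        assert lo <= ratio <= hi
        assert abs(ratio - expected) < 0.02

    def test_linearity(self, rng):
        a = rng.standard_normal((2, 3, 500))
        b = rng.standard_normal((2, 3, 500))
        ep = lambda d: sccsp.EpochSet(data=d, fs=250.0)
        lhs = pio.bandpass_filter(ep(2.0 * a + 3.0 * b)).data
        rhs = 2.0 * pio.bandpass_filter(ep(a)).data + 3.0 * pio.bandpass_filter(ep(b)).data
        assert np.abs(lhs - rhs).max() < 1e-9 * np.abs(lhs).max()

    def test_nyquist_violation_raises(self):
        ep = make_epochs(fs=50.0)
        with pytest.raises(ConfigError, match="Nyquist"):
            pio.bandpass_filter(ep, 5, 30)

    def test_input_unmodified(self):
        ep = make_epochs()
        before = ep.data.copy()
        pio.bandpass_filter(ep)
        assert np.array_equal(ep.data, before)


class TestExtractWindow:
    def test_imagery_window_sample_counts(self):
        ep = sccsp.EpochSet(data=np.zeros((2, 3, int(7.5 * 250))), fs=250.0)
        assert pio.extract_window(ep, 3.0, 6.0).n_samples == 750
        assert pio.extract_window(ep, 3.0, 7.0).n_samples == 1000

    def test_full_window_is_identity(self):
        ep = make_epochs(n_samples=200)
        out = pio.extract_window(ep, 0.0, 200 / 250.0)
        assert np.array_equal(out.data, ep.data)

    def test_out_of_bounds_raises(self):
        ep = make_epochs(n_samples=100)
        with pytest.raises(ConfigError):
            pio.extract_window(ep, 0.0, 10.0)


class TestSplitHemispheres:
    def test_auto_by_x_coordinate(self):
        # C3 (left), C4 (right), Cz (midline) style montage
        ep = sccsp.EpochSet(
            data=np.zeros((1, 5, 10)),
            fs=250.0,
            channel_names=("C3", "C5", "C4", "C6", "Cz"),
            channel_positions=np.array(
                [[-0.3, 0.0], [-0.5, 0.0], [0.3, 0.0], [0.5, 0.0], [0.0, 0.0]]
            ),
        )
        left, right = pio.split_hemispheres(ep, "auto")
        assert left.channel_names == ("C3", "C5")
        assert right.channel_names == ("C4", "C6")

    def test_explicit_split_reproduces_indices(self):
        ep = make_epochs(n_channels=6, positions=False)
        split = pio.HemisphereSplit(left_idx=(0, 1, 2), right_idx=(3, 4, 5))
        left, right = pio.split_hemispheres(ep, split)
        assert left.n_channels == 3 and right.n_channels == 3
        assert np.array_equal(left.data, ep.data[:, :3])
        assert np.array_equal(right.data, ep.data[:, 3:])

    def test_partition_is_exact(self):
        ep = make_epochs(n_channels=7)
        left, right = pio.split_hemispheres(ep, "auto")
        # channel 3 of 7 sits at x = 0 -> excluded
        assert left.n_channels + right.n_channels == 6

    def test_auto_without_positions_raises(self):
        ep = make_epochs(positions=False)
        with pytest.raises(ConfigError, match="positions"):
            pio.split_hemispheres(ep, "auto")

    def test_tiny_hemisphere_raises(self):
        ep = make_epochs(n_channels=4, positions=False)
        split = pio.HemisphereSplit(left_idx=(0,), right_idx=(1, 2, 3))
        with pytest.raises(ConfigError, match="fewer than 2"):
            pio.split_hemispheres(ep, split)

    def test_overlapping_split_rejected(self):
        with pytest.raises(ConfigError, match="disjoint"):
            pio.HemisphereSplit(left_idx=(0, 1), right_idx=(1, 2))
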