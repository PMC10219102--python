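"""FCS reading/writing and baseline+activation appending."""

import numpy as np
import pandas as pd
import pytest

from fluxkin.fcs_io import (
    EventStream,
    FCSFormatError,
    append_recordings,
    read_fcs,
    write_fcs,
)
from fluxkin import synthetic


def _handmade_fcs(path, values, channels, timestep="0.01", version=b"FCS3.1"):
    """Independent minimal FCS writer (float32, little-endian) used as the
    oracle for the package's reader."""
    arr = np.asarray(values, dtype="<f4")
    n_tot, n_par = arr.shape
    kv = {
        "$DATATYPE": "F", "$MODE": "L", "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par), "$TOT": str(n_tot), "$NEXTDATA": "0",
        "$TIMESTEP": timestep,
    }
    for i, ch in enumerate(channels, 1):
        kv[f"$P{i}N"] = ch
        kv[f"$P{i}B"] = "32"
        kv[f"$P{i}E"] = "0,0"
        kv[f"$P{i}R"] = "262144"
    kv["$BEGINDATA"] = "0" * 10
    kv["$ENDDATA"] = "0" * 10

    def render(d):
        return ("/" + "".join(f"{k}/{v}/" for k, v in d.items())).encode()

    text = render(kv)
    ts, te = 58, 58 + len(text) - 1
    ds = te + 1
    de = ds + arr.nbytes - 1
    kv["$BEGINDATA"] = str(ds).rjust(10, "0")
    kv["$ENDDATA"] = str(de).rjust(10, "0")
    text = render(kv)
    header = version + b"    " + b"".join(
        str(v).rjust(8).encode() for v in (ts, te, ds, de, 0, 0)
    )
    path.write_bytes(header + text + arr.tobytes())
    return path


class TestRead:
    def test_timestep_converts_ticks_to_seconds(self, tmp_path):
        p = _handmade_fcs(
            tmp_path / "t.fcs",
            [[0, 5.0], [100, 6.0], [200, 7.0]],
            ["Time", "Fluo4"],
            timestep="0.01",
        )
        s = read_fcs(p)
        np.testing.assert_allclose(s.times(), [0.0, 1.0, 2.0], atol=1e-9)
        np.testing.assert_allclose(s.events["Fluo4"], [5, 6, 7])
        assert s.metadata["$TIMESTEP"] == "0.01"

    def test_integer_list_mode_fcs30(self, tmp_path):
        arr = np.array([[0, 50], [100, 60], [200, 70]], dtype="<u2")
        kv = {"$DATATYPE": "I", "$MODE": "L", "$BYTEORD": "1,2,3,4",
              "$PAR": "2", "$TOT": "3", "$NEXTDATA": "0", "$TIMESTEP": "0.01"}
        for i, ch in enumerate(["Time", "Fluo4"], 1):
            kv.update({f"$P{i}N": ch, f"$P{i}B": "16", f"$P{i}E": "0,0",
                       f"$P{i}R": "65536"})
        kv["$BEGINDATA"] = kv["$ENDDATA"] = "0" * 10

        def render(d):
            return ("/" + "".join(f"{k}/{v}/" for k, v in d.items())).encode()

        text = render(kv)
        ts, te = 58, 58 + len(text) - 1
        ds, de = te + 1, te + arr.nbytes
        kv["$BEGINDATA"] = str(ds).rjust(10, "0")
        kv["$ENDDATA"] = str(de).rjust(10, "0")
        p = tmp_path / "int.fcs"
        p.write_bytes(b"FCS3.0    " + b"".join(
            str(v).rjust(8).encode() for v in (ts, te, ds, de, 0, 0))
            + render(kv) + arr.tobytes())
        s = read_fcs(p)
        np.testing.assert_allclose(s.times(), [0.0, 1.0, 2.0])
        np.testing.assert_allclose(s.events["Fluo4"], [50, 60, 70])

    def test_unsupported_version_rejected(self, tmp_path):
        p = _handmade_fcs(tmp_path / "v.fcs", [[0, 1]], ["Time", "X"],
                          version=b"FCS2.0")
        with pytest.raises(FCSFormatError, match="version"):
            read_fcs(p)

    def test_missing_time_channel_is_fatal(self, tmp_path):
        p = _handmade_fcs(tmp_path / "n.fcs", [[1.0, 2.0]], ["FSC-A", "SSC-A"])
        with pytest.raises(FCSFormatError, match="[Tt]ime"):
            read_fcs(p)

    def test_simulated_file_event_count_and_panel(self, tmp_path, small_spec):
        stream = synthetic.generate_fmo(small_spec, "CD19", duration=100.0)
        p = write_fcs(stream, tmp_path / "s.fcs")
        back = read_fcs(p, "fmo")
        assert back.n_events == stream.n_events
        assert back.channel_names == list(small_spec.panel)


class TestWriteRoundTrip:
    def test_empty_stream_five_channels(self, tmp_path):
        chans = ["Time", "A", "B", "C", "D"]
        s = EventStream(pd.DataFrame({c: [] for c in chans}), chans)
        back = read_fcs(write_fcs(s, tmp_path / "e.fcs"))
        assert back.n_events == 0
        assert back.channel_names == chans

    def test_empty_channel_list_rejected(self, tmp_path):
        s = EventStream(pd.DataFrame(), [])
        with pytest.raises(ValueError, match="empty channel"):
            write_fcs(s, tmp_path / "x.fcs")

    def test_round_trip_synthetic_stream(self, tmp_path, small_spec):
        baseline, _, _ = synthetic.generate_recording(small_spec, "NA")
        back = read_fcs(write_fcs(baseline, tmp_path / "rt.fcs"))
        a = baseline.events.to_numpy()
        b = back.events[baseline.channel_names].to_numpy()
        scale = np.abs(a).max(axis=0) + 1.0
        assert np.max(np.abs(a - b) / scale) < 1e-5
        # event order preserved
        assert np.all(np.diff(back.times()) >= 0)

    def test_timestep_keyword_preserved(self, tmp_path):
        chans = ["Time", "X"]
        s = EventStream(
            pd.DataFrame({"Time": [0.0, 1.0], "X": [3.0, 4.0]}),
            chans, metadata={"$TIMESTEP": "0.01"},
        )
        back = read_fcs(write_fcs(s, tmp_path / "ts.fcs"))
        assert float(back.metadata["$TIMESTEP"]) == 0.01
        np.testing.assert_allclose(back.times(), [0.0, 1.0], atol=1e-6)


def _uniform_stream(duration, n, channels=("Time", "Fluo4"), role="baseline"):
    t = np.linspace(0, duration, n)
    df = pd.DataFrame({"Time": t, "Fluo4": np.full(n, 100.0)})
    return EventStream(df, list(channels), role)


class TestAppend:
    def test_standard_protocol_ends_at_780(self):
        rec = append_recordings(
            _uniform_stream(60, 600), _uniform_stream(720, 7200, role="activation"),
            gap_seconds=0.0,
        )
        assert rec.t_act == pytest.approx(60.0)
        assert rec.t_end == 780.0
        assert rec.times().max() <= 780.0

    def test_gap_offsets_and_truncates(self):
        base = _uniform_stream(60, 600)
        act = _uniform_stream(720, 7200, role="activation")
        rec = append_recordings(base, act, gap_seconds=10.0)
        assert rec.t_act == pytest.approx(70.0)
        # brute-force oracle: activation events past 710 s are beyond 780 s
        act_t = act.times()
        expect_drop = int(np.sum(act_t + 70.0 > 780.0))
        assert rec.n_dropped == expect_drop
        assert rec.n_events == base.n_events + act.n_events - expect_drop
        shifted = rec.times()[base.n_events:]
        np.testing.assert_allclose(shifted, act_t[act_t + 70 <= 780] + 70.0)

    def test_event_conservation_brute_force(self, small_spec):
        b, a, _ = synthetic.generate_recording(small_spec, "IgG+M")
        rec = append_recordings(b, a, gap_seconds=5.0)
        t_all = np.concatenate([b.times(), a.times() + rec.t_act])
        assert rec.n_events == int(np.sum(t_all <= rec.t_end))
        assert rec.n_dropped == int(np.sum(t_all > rec.t_end))

    def test_t_act_increases_with_gap(self):
        base = _uniform_stream(60, 600)
        act = _uniform_stream(700, 700, role="activation")
        t_acts = [append_recordings(base, act, g).t_act for g in (0, 5, 12)]
        assert t_acts == sorted(t_acts) and len(set(t_acts)) == 3

    def test_empty_activation_warns(self, caplog):
        base = _uniform_stream(60, 600)
        empty = _uniform_stream(720, 0, role="activation")
        with caplog.at_level("WARNING"):
            rec = append_recordings(base, empty, 0.0)
        assert rec.n_events == base.n_events
        assert any("empty" in m for m in caplog.messages)

    def test_channel_mismatch_lists_channels(self):
        base = _uniform_stream(60, 100)
        other = EventStream(
            pd.DataFrame({"Time": [0.0], "CD19": [1.0]}), ["Time", "CD19"],
            "activation",
        )
        with pytest.raises(ValueError, match="CD19"):
            append_recordings(base, other, 0.0)

    def test_zero_length_baseline_rejected(self):
        zero = EventStream(
            pd.DataFrame({"Time": [0.0, 0.0], "Fluo4": [1.0, 1.0]}),
            ["Time", "Fluo4"],
        )
        with pytest.raises(ValueError, match="baseline"):
            append_recordings(zero, _uniform_stream(720, 10, role="activation"), 0.0)
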