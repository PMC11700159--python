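import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from clampkit import CellRecording, StepProtocol, Sweep, read_recording, write_recording
from clampkit.trace_model import (
    CURRENT_CLAMP,
    VOLTAGE_CLAMP,
    FormatError,
    IntegrityError,
    SpikeEvent,
    UnitError,
    VClampFeatures,
)


def _make_recording(protocol, rng, cell_id="cell_a"):
    sr = 10_000.0
    n = int(round(protocol.total_duration * sr))
    sweeps = []
    for rep in range(protocol.repetitions):
        for amp in protocol.amplitudes:
            sweeps.append(
                Sweep(
                    samples=rng.normal(-60.0, 5.0, size=n),
                    sampling_rate=sr,
                    command_level=amp,
                    step_onset=protocol.step_onset,
                    step_offset=protocol.step_offset,
                    holding_level=protocol.holding_level,
                    mode=protocol.mode,
                    repetition_index=rep,
                )
            )
    return CellRecording(
        cell_id=cell_id,
        genotype="WT",
        treatment="vehicle",
        condition="from_rest" if protocol.mode == CURRENT_CLAMP else "held_minus60",
        resting_potential=-65.0,
        sweeps={"proto": sweeps},
        protocols={"proto": protocol},
    )


@st.composite
def protocols(draw):
    mode = draw(st.sampled_from([CURRENT_CLAMP, VOLTAGE_CLAMP]))
    n_amps = draw(st.integers(1, 4))
    start = draw(st.integers(-100, 0))
    step = draw(st.integers(1, 50))
    amps = tuple(float(start + i * step) for i in range(n_amps))
    reps = draw(st.integers(1, 3))
    return StepProtocol(
        mode=mode,
        holding_level=0.0 if mode == CURRENT_CLAMP else -60.0,
        pre_duration=draw(st.sampled_from([0.01, 0.02])),
        step_duration=draw(st.sampled_from([0.02, 0.05])),
        post_duration=0.01,
        amplitudes=amps,
        repetitions=reps,
    )


@pytest.mark.parametrize("fmt", ["csv", "npy"])
@settings(max_examples=15, deadline=None, derandomize=True,
          suppress_health_check=[HealthCheck.function_scoped_fixture])
@given(proto=protocols(), seed=st.integers(0, 2**16))
def test_container_round_trip_is_identity(tmp_path_factory, proto, seed, fmt):
    """read(write(x)) reproduces every field and every sample bit-exactly."""
    rng = np.random.default_rng(seed)
    rec = _make_recording(proto, rng)
    out = tmp_path_factory.mktemp("containers")
    path = write_recording(rec, out, fmt=fmt)
    back = read_recording(path)
    assert back == rec
    # bit-exact sample values
    for a, b in zip(rec.sweeps["proto"], back.sweeps["proto"]):
        assert np.array_equal(a.samples, b.samples)


def test_round_trip_of_large_protocol_groups_all_sweeps(tmp_path):
    proto = StepProtocol(
        mode=CURRENT_CLAMP, holding_level=0.0, pre_duration=0.005,
        step_duration=0.01, post_duration=0.005,
        amplitudes=tuple(float(a) for a in range(-100, 481, 20)), repetitions=5,
    )
    rec = _make_recording(proto, np.random.default_rng(0))
    back = read_recording(write_recording(rec, tmp_path))
    assert len(back.sweeps["proto"]) == 150
    assert back == rec


def test_two_cells_share_a_directory_without_collision(tmp_path):
    proto = StepProtocol(
        mode=CURRENT_CLAMP, holding_level=0.0, pre_duration=0.005,
        step_duration=0.01, post_duration=0.005, amplitudes=(20.0,),
    )
    rng = np.random.default_rng(1)
    a = _make_recording(proto, rng, "cell_a")
    b = _make_recording(proto, rng, "cell_b")
    write_recording(a, tmp_path)
    write_recording(b, tmp_path)
    dirs = sorted(p.name for p in tmp_path.iterdir() if p.is_dir())
    assert dirs == ["cell_a", "cell_b"]
    assert read_recording(tmp_path / "cell_a").cell_id == "cell_a"
    assert read_recording(tmp_path / "cell_b").cell_id == "cell_b"


def test_missing_sampling_rate_is_a_format_error(tmp_path):
    proto = StepProtocol(
        mode=CURRENT_CLAMP, holding_level=0.0, pre_duration=0.005,
        step_duration=0.01, post_duration=0.005, amplitudes=(20.0,),
    )
    rec = _make_recording(proto, np.random.default_rng(2))
    path = write_recording(rec, tmp_path)
    meta = (path / "meta.json").read_text().replace('"sampling_rate"', '"sampling_rat"')
    (path / "meta.json").write_text(meta)
    with pytest.raises(FormatError):
        read_recording(path)


def test_sweep_length_mismatch_is_an_integrity_error(tmp_path):
    proto = StepProtocol(
        mode=CURRENT_CLAMP, holding_level=0.0, pre_duration=0.005,
        step_duration=0.01, post_duration=0.005, amplitudes=(20.0,),
    )
    rec = _make_recording(proto, np.random.default_rng(3))
    path = write_recording(rec, tmp_path, fmt="npy")
    arr = np.load(path / "sweeps_proto.npy")
    np.save(path / "sweeps_proto.npy", arr[:, :-7])
    with pytest.raises(IntegrityError):
        read_recording(path)


def test_sweep_validation_rejects_bad_inputs():
    good = dict(
        samples=np.zeros(100), sampling_rate=10_000.0, command_level=20.0,
        step_onset=0.002, step_offset=0.008, holding_level=0.0,
        mode=CURRENT_CLAMP,
    )
    Sweep(**good)
    with pytest.raises(ValueError):
        Sweep(**{**good, "samples": np.array([1.0, np.nan])})
    with pytest.raises(ValueError):
        Sweep(**{**good, "sampling_rate": 0.0})
    with pytest.raises(ValueError):
        Sweep(**{**good, "step_onset": 0.009})  # onset after offset
    with pytest.raises(UnitError):
        Sweep(**{**good, "mode": "dynamic_clamp"})
    with pytest.raises(UnitError):
        Sweep(**{**good, "response_units": "pA"})  # pA response in current clamp


def test_protocol_validation():
    with pytest.raises(ValueError):
        StepProtocol(
            mode=CURRENT_CLAMP, holding_level=0.0, pre_duration=0.01,
            step_duration=0.01, post_duration=0.01,
            amplitudes=(20.0, 20.0),  # not unique
        )
    with pytest.raises(ValueError):
        StepProtocol(
            mode=CURRENT_CLAMP, holding_level=0.0, pre_duration=0.01,
            step_duration=0.01, post_duration=0.01,
            amplitudes=(40.0, 20.0),  # not increasing
        )


def test_spike_event_invariants():
    with pytest.raises(ValueError):
        SpikeEvent(upcross_time=0.1, peak_time=0.1, peak_voltage=10.0,
                   threshold_time=0.2, threshold_voltage=-40.0)
    with pytest.raises(ValueError):  # width defined without end_time
        SpikeEvent(upcross_time=0.1, peak_time=0.101, peak_voltage=10.0,
                   width=1.0)


def test_vclamp_features_sign_contract():
    with pytest.raises(ValueError):
        VClampFeatures(
            injections=np.array([0.0, 10.0]),
            early_max_inward=np.array([5.0, -1.0]),  # positive inward
            early_max_outward=np.array([1.0, 1.0]),
            late_mean=np.array([0.0, 0.0]),
        )
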