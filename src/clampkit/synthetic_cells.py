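"""Synthetic whole-cell recordings with exact ground truth.

The generator exists to test the analysis, not to model membrane
biophysics.  Subthreshold dynamics are a leaky RC membrane,

    dV/dt = (v_rest - V) / (r_input * c_m) + I / c_m,

integrated by forward Euler at the 10 kHz acquisition grid (0.1 ms).  When
the voltage crosses ``spike_threshold`` outside refractoriness, a
stereotyped triangular spike template is spliced into the trace and its
exact onset sample, threshold, amplitude and half-width are logged as
ground truth.  The template is constructed to satisfy the detection
criteria used downstream (rise >= 100 mV/ms, fall steeper than -15 mV/ms,
peak above 0 mV when the parameters put it there), so at zero noise every
inserted spike is recoverable by construction.  A per-spike adaptation
current (incremented at each spike, decaying exponentially) produces
realistic firing-rate saturation.  Gaussian observation noise is added
last, after ground truth is recorded.

Voltage-clamp sweeps are the sum of closed-form components: ohmic leak and
a series-resistance capacitive transient (both linear in the step, hence
removable by -10 mV leak scaling), a transient inward conductance and a
delayed outward conductance (Boltzmann activation in voltage, exponential
time course), and a persistent current proportional to depolarizing
injections.  The noiseless leak-free sum is logged per step.

Phenotype presets encode effect *directions* only — tangle-bearing (Tau)
neurons: higher input resistance, lower capacitance, depolarized rest,
higher threshold, stronger adaptation, smaller voltage-gated currents;
AdipoRon-treated Tau cells are drawn from the wild-type distribution.  The
magnitudes are package choices (see docs/methods.md); no group means are
published for these cultures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .trace_model import (
    CURRENT_CLAMP,
    VOLTAGE_CLAMP,
    MEMBRANE_TEST,
    CellRecording,
    ClampKitError,
    StepProtocol,
    Sweep,
)
from .protocols import (
    LEAK_INJECTION_MV,
    current_clamp_protocol,
    test_pulse_protocol,
    voltage_clamp_protocol,
)

__all__ = [
    "SyntheticCellParams",
    "CurrentClampTruth",
    "VClampTruth",
    "CellTruth",
    "GroupSpec",
    "simulate_current_clamp",
    "simulate_voltage_clamp",
    "simulate_membrane_test",
    "simulate_cell",
    "make_cohort",
    "wt_params",
    "tau_params",
    "default_design",
]


class SimulationError(ClampKitError):
    pass


@dataclass(frozen=True)
class SyntheticCellParams:
    """Generative ground truth for one synthetic neuron.

    Resistances in MOhm, capacitance in pF, potentials in mV, currents in
    pA, times in ms.  ``vg_inward`` and ``vg_outward`` peak currents are
    referenced to a 0 mV absolute command.
    """

    v_rest: float = -65.0
    r_input: float = 150.0
    r_series: float = 12.0
    c_m: float = 90.0
    spike_threshold: float = -45.0
    spike_amplitude: float = 85.0  # threshold to peak, mV
    spike_width: float = 1.5  # full width at half amplitude, ms
    ahp: float = 12.0  # afterhyperpolarization below threshold, mV
    refractory_ms: float = 4.0
    adaptation_increment_pA: float = 30.0
    adaptation_tau_ms: float = 300.0
    latency_jitter_ms: float = 0.0
    vg_inward_peak_pA: float = 1800.0  # magnitude of transient inward at 0 mV
    vg_inward_vhalf: float = -30.0
    vg_inward_slope: float = 6.0
    vg_inward_decay_ms: float = 3.0
    vg_outward_peak_pA: float = 1600.0
    vg_outward_vhalf: float = -15.0
    vg_outward_slope: float = 6.0
    vg_outward_rise_ms: float = 5.0
    persistent_pA_per_mV: float = 1.5
    noise_sd_mV: float = 0.3
    noise_sd_pA: float = 4.0

    def __post_init__(self) -> None:
        if not (self.r_input > 0 and self.c_m > 0 and self.r_series > 0):
            raise ValueError("r_input, r_series and c_m must be positive")
        if not (self.spike_amplitude > 0):
            raise ValueError("spike template amplitude must be positive")
        if self.noise_sd_mV < 0 or self.noise_sd_pA < 0:
            raise ValueError("noise sd must be non-negative")

    @property
    def membrane_tau_ms(self) -> float:
        # MOhm * pF = microseconds
        return self.r_input * self.c_m / 1000.0


@dataclass
class CurrentClampTruth:
    """Exact inserted-spike bookkeeping for one current-clamp run."""

    spike_times: List[np.ndarray]  # seconds, one array per sweep
    threshold: float  # mV
    amplitude: float  # mV
    width_ms: float  # half-amplitude width of the template


@dataclass
class VClampTruth:
    """Noiseless, leak-free voltage-gated component per injection."""

    injections: np.ndarray  # mV
    early_max_inward: np.ndarray  # pA over the first 10 ms of the step
    early_max_outward: np.ndarray
    late_mean: np.ndarray  # pA over the last third of the step
    leak_free: List[np.ndarray]  # full noiseless component traces


@dataclass
class CellTruth:
    params: SyntheticCellParams
    current_clamp: Dict[str, CurrentClampTruth] = field(default_factory=dict)
    voltage_clamp: Optional[VClampTruth] = None


# ---------------------------------------------------------------------------
# spike template
# ---------------------------------------------------------------------------

def _spike_template(params: SyntheticCellParams, dt_ms: float) -> Tuple[np.ndarray, float]:
    """Triangular spike sampled on the acquisition grid.

    Rise at ~200 mV/ms, linear fall back to threshold; rise and fall times
    are snapped to grid multiples so the apex lies exactly on a sample and
    the analytic half-width ``(t_rise + t_fall) / 2`` is exact under linear
    interpolation.  Returns (absolute voltage samples, half-width in ms).
    """
    amp = params.spike_amplitude
    theta = params.spike_threshold
    t_rise = max(dt_ms, round((amp / 200.0) / dt_ms) * dt_ms)
    t_fall = max(dt_ms, round((2.0 * params.spike_width - t_rise) / dt_ms) * dt_ms)
    n_r = int(round(t_rise / dt_ms))
    n_f = int(round(t_fall / dt_ms))
    if amp / t_fall <= 15.0:
        raise SimulationError(
            "spike template fall slope does not satisfy the -15 mV/ms "
            "detection criterion; reduce spike_width or raise amplitude"
        )
    up = theta + amp * np.arange(n_r + 1) / n_r
    down = theta + amp * (1.0 - np.arange(1, n_f + 1) / n_f)
    tmpl = np.concatenate([up, down])
    width_ms = (t_rise + t_fall) / 2.0
    return tmpl, width_ms


def _integrate_cc_sweep(
    i_cmd: np.ndarray,
    dt_ms: float,
    v0: float,
    v_rest: float,
    tau_ms: float,
    c_m: float,
    theta: float,
    tmpl: np.ndarray,
    v_reset: float,
    refr_n: int,
    adapt_inc: float,
    adapt_decay: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """Forward-Euler RC integration with template insertion.

    Returns the noiseless voltage trace and the sample indices at which
    spikes were initiated (voltage equals ``theta`` exactly there).
    """
    n = i_cmd.shape[0]
    v = np.empty(n, dtype=np.float64)
    max_spk = n // (tmpl.shape[0] + refr_n) + 1
    spikes = np.empty(max_spk, dtype=np.int64)
    nspk = 0
    vcur = v0
    adapt = 0.0
    m = tmpl.shape[0]
    k = 0
    while k < n:
        if vcur >= theta:
            spikes[nspk] = k
            nspk += 1
            j = 0
            while j < m and k + j < n:
                v[k + j] = tmpl[j]
                j += 1
            k += j
            r = 0
            while r < refr_n and k < n:
                v[k] = v_reset
                k += 1
                r += 1
            vcur = v_reset
            adapt = adapt * adapt_decay ** (j + r) + adapt_inc
            continue
        v[k] = vcur
        i_eff = i_cmd[k] - adapt
        vcur = vcur + ((v_rest - vcur) / tau_ms + i_eff / c_m) * dt_ms
        adapt *= adapt_decay
        k += 1
    return v, spikes[:nspk].copy()


try:  # numba speeds the inner loop up ~100x when available
    from numba import njit as _njit

    _integrate_cc_sweep = _njit(cache=False)(_integrate_cc_sweep)  # type: ignore
except Exception:  # pragma: no cover - numba is normally installed
    pass


def simulate_current_clamp(
    params: SyntheticCellParams,
    protocol: StepProtocol,
    seed,
    v_start: Optional[float] = None,
    holding_pA: Optional[float] = None,
) -> Tuple[List[Sweep], CurrentClampTruth]:
    """Simulate one current-clamp run of a protocol.

    ``v_start`` / ``holding_pA`` default to the cell's resting state; pass
    the steady state at -60 mV to emulate the held condition (see
    :func:`holding_current_for`).
    """
    if protocol.mode != CURRENT_CLAMP:
        raise SimulationError("protocol mode must be current_clamp")
    sr = 10_000.0
    dt_ms = 1000.0 / sr
    tau_ms = params.membrane_tau_ms
    if tau_ms < 4 * dt_ms:
        raise SimulationError(
            f"membrane tau {tau_ms:.2f} ms too short for stable integration "
            f"at dt {dt_ms} ms"
        )
    if holding_pA is None:
        holding_pA = 0.0
    if v_start is None:
        v_start = params.v_rest + holding_pA * params.r_input / 1000.0

    tmpl, width_ms = _spike_template(params, dt_ms)
    if params.spike_threshold + params.spike_amplitude <= 0:
        import warnings

        warnings.warn(
            "spike template peak does not exceed 0 mV; inserted spikes will "
            "fail the downstream peak criterion",
            stacklevel=2,
        )
    v_reset = params.spike_threshold - params.ahp
    refr_n = int(round(params.refractory_ms / dt_ms))
    adapt_decay = math.exp(-dt_ms / params.adaptation_tau_ms)

    n_total = int(round(protocol.total_duration * sr))
    onset_i = int(round(protocol.step_onset * sr))
    offset_i = int(round(protocol.step_offset * sr))

    rng = np.random.default_rng(seed)
    sweeps: List[Sweep] = []
    spike_times: List[np.ndarray] = []
    for rep in range(protocol.repetitions):
        for amp in protocol.amplitudes:
            jitter_n = 0
            if params.latency_jitter_ms > 0:
                jitter_n = int(rng.integers(0, int(params.latency_jitter_ms / dt_ms) + 1))
            i_cmd = np.full(n_total, holding_pA, dtype=np.float64)
            i_cmd[onset_i + jitter_n : offset_i] += amp
            v, spk = _integrate_cc_sweep(
                i_cmd,
                dt_ms,
                v_start,
                params.v_rest,
                tau_ms,
                params.c_m,
                params.spike_threshold,
                tmpl,
                v_reset,
                refr_n,
                params.adaptation_increment_pA,
                adapt_decay,
            )
            if params.noise_sd_mV > 0:
                v = v + rng.normal(0.0, params.noise_sd_mV, size=n_total)
            sweeps.append(
                Sweep(
                    samples=v,
                    sampling_rate=sr,
                    command_level=float(amp),
                    step_onset=protocol.step_onset,
                    step_offset=protocol.step_offset,
                    holding_level=float(holding_pA),
                    mode=CURRENT_CLAMP,
                    repetition_index=rep,
                )
            )
            spike_times.append(spk.astype(np.float64) / sr)
    truth = CurrentClampTruth(
        spike_times=spike_times,
        threshold=params.spike_threshold,
        amplitude=params.spike_amplitude,
        width_ms=width_ms,
    )
    return sweeps, truth


def holding_current_for(params: SyntheticCellParams, v_hold: float) -> float:
    """DC current (pA) that holds the model cell at ``v_hold``."""
    return 1000.0 * (v_hold - params.v_rest) / params.r_input


# ---------------------------------------------------------------------------
# voltage clamp
# ---------------------------------------------------------------------------

def _boltzmann(v: float, vhalf: float, slope: float) -> float:
    return 1.0 / (1.0 + math.exp(-(v - vhalf) / slope))


def _vc_components(
    params: SyntheticCellParams,
    protocol: StepProtocol,
    injection: float,
    t: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray]:
    """(linear leak+capacitive trace, voltage-gated leak-free trace) in pA."""
    rs, rin, cm = params.r_series, params.r_input, params.c_m
    rtot = rs + rin
    tau_s = (rs * rin / rtot) * cm * 1e-6  # MOhm*pF = microseconds
    on, off = protocol.step_onset, protocol.step_offset
    in_step = (t >= on) & (t < off)
    after = t >= off

    i_hold = 1000.0 * (protocol.holding_level - params.v_rest) / rtot
    linear = np.full(t.size, i_hold, dtype=np.float64)
    dI_ss = 1000.0 * injection / rtot
    dI_peak = 1000.0 * injection / rs
    linear[in_step] += dI_ss + (dI_peak - dI_ss) * np.exp(-(t[in_step] - on) / tau_s)
    linear[after] += -(dI_peak - dI_ss) * np.exp(-(t[after] - off) / tau_s)

    v_abs = protocol.holding_level + injection
    gated = np.zeros(t.size, dtype=np.float64)
    ts = t[in_step] - on
    if params.vg_inward_peak_pA > 0:
        act = _boltzmann(v_abs, params.vg_inward_vhalf, params.vg_inward_slope)
        norm = _boltzmann(0.0, params.vg_inward_vhalf, params.vg_inward_slope)
        gated[in_step] += (
            -params.vg_inward_peak_pA
            * (act / norm)
            * np.exp(-ts / (params.vg_inward_decay_ms * 1e-3))
        )
    if params.vg_outward_peak_pA > 0:
        act = _boltzmann(v_abs, params.vg_outward_vhalf, params.vg_outward_slope)
        norm = _boltzmann(0.0, params.vg_outward_vhalf, params.vg_outward_slope)
        gated[in_step] += (
            params.vg_outward_peak_pA
            * (act / norm)
            * (1.0 - np.exp(-ts / (params.vg_outward_rise_ms * 1e-3)))
        )
    if params.persistent_pA_per_mV != 0 and injection > 0:
        gated[in_step] += params.persistent_pA_per_mV * injection
    return linear, gated


def simulate_voltage_clamp(
    params: SyntheticCellParams,
    protocol: StepProtocol,
    seed,
    early_s: float = 0.010,
    late_fraction: float = 1.0 / 3.0,
    require_leak_step: bool = True,
) -> Tuple[List[Sweep], VClampTruth]:
    """Simulate one voltage-clamp run and log the leak-free ground truth."""
    if protocol.mode != VOLTAGE_CLAMP:
        raise SimulationError("protocol mode must be voltage_clamp")
    if require_leak_step and LEAK_INJECTION_MV not in protocol.amplitudes:
        raise SimulationError("voltage-clamp protocol must include the -10 mV step")
    sr = 10_000.0
    n_total = int(round(protocol.total_duration * sr))
    t = np.arange(n_total) / sr
    rng = np.random.default_rng(seed)

    on_i = int(round(protocol.step_onset * sr))
    off_i = int(round(protocol.step_offset * sr))
    early_sl = slice(on_i, on_i + int(round(early_s * sr)))
    n_step = off_i - on_i
    late_sl = slice(off_i - int(round(n_step * late_fraction)), off_i)

    sweeps: List[Sweep] = []
    injections, e_in, e_out, l_mean, leak_free = [], [], [], [], []
    for rep in range(protocol.repetitions):
        for inj in protocol.amplitudes:
            linear, gated = _vc_components(params, protocol, inj, t)
            i = linear + gated
            if params.noise_sd_pA > 0:
                i = i + rng.normal(0.0, params.noise_sd_pA, size=n_total)
            sweeps.append(
                Sweep(
                    samples=i,
                    sampling_rate=sr,
                    command_level=float(inj),
                    step_onset=protocol.step_onset,
                    step_offset=protocol.step_offset,
                    holding_level=protocol.holding_level,
                    mode=VOLTAGE_CLAMP,
                    repetition_index=rep,
                )
            )
            if rep == 0:
                injections.append(inj)
                e_in.append(min(0.0, float(gated[early_sl].min())))
                e_out.append(max(0.0, float(gated[early_sl].max())))
                l_mean.append(float(gated[late_sl].mean()))
                leak_free.append(gated)
    truth = VClampTruth(
        injections=np.asarray(injections),
        early_max_inward=np.asarray(e_in),
        early_max_outward=np.asarray(e_out),
        late_mean=np.asarray(l_mean),
        leak_free=leak_free,
    )
    return sweeps, truth


def simulate_membrane_test(
    params: SyntheticCellParams, protocol: StepProtocol, seed
) -> List[Sweep]:
    """Simulate -5 mV membrane-test pulses (no voltage-gated currents: the
    pulse is small and hyperpolarizing)."""
    quiet = replace(
        params,
        vg_inward_peak_pA=0.0,
        vg_outward_peak_pA=0.0,
        persistent_pA_per_mV=0.0,
    )
    sweeps, _ = simulate_voltage_clamp(quiet, protocol, seed, require_leak_step=False)
    return sweeps


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """One experimental group: size, genotype/treatment labels, parameter
    means and between-cell dispersions (normal, clipped to valid ranges)."""

    n_cells: int
    genotype: str
    treatment: str
    params: SyntheticCellParams
    dispersion: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


_POSITIVE_FIELDS = {
    "r_input",
    "r_series",
    "c_m",
    "spike_amplitude",
    "spike_width",
    "vg_inward_peak_pA",
    "vg_outward_peak_pA",
}

#: default between-cell dispersion (sd) applied to every group
DEFAULT_DISPERSION = {
    "v_rest": 2.0,
    "r_input": 25.0,
    "c_m": 12.0,
    "spike_threshold": 1.5,
    "spike_amplitude": 5.0,
    "vg_inward_peak_pA": 250.0,
    "vg_outward_peak_pA": 220.0,
}


def wt_params() -> SyntheticCellParams:
    return SyntheticCellParams()


def tau_params() -> SyntheticCellParams:
    """Tangle-bearing phenotype: directions follow the reported group
    contrasts (higher input resistance, lower capacitance, depolarized
    rest, fewer spikes, smaller voltage-gated currents); magnitudes are
    package choices."""
    return SyntheticCellParams(
        v_rest=-58.0,
        r_input=250.0,
        c_m=55.0,
        spike_threshold=-38.0,
        spike_amplitude=72.0,
        spike_width=1.6,
        ahp=10.0,
        adaptation_increment_pA=140.0,
        adaptation_tau_ms=400.0,
        vg_inward_peak_pA=850.0,
        vg_outward_peak_pA=700.0,
        persistent_pA_per_mV=0.8,
    )


def default_design(scale: float = 1.0) -> Dict[str, GroupSpec]:
    """Study design: 64 WT, 13 WT+AR, 40 Tau, 31 Tau+AR neurons.

    ``scale`` shrinks every group proportionally (minimum 3 cells) for
    quick runs.  AdipoRon-treated Tau cells are drawn from the wild-type
    parameter distribution (treatment restores the phenotype); treated
    wild-type cells are wild-type.
    """

    def n(x: int) -> int:
        return max(3, int(round(x * scale)))

    wt = wt_params()
    return {
        "WT": GroupSpec(n(64), "WT", "vehicle", wt, dict(DEFAULT_DISPERSION)),
        "WT+AR": GroupSpec(n(13), "WT", "AR", wt, dict(DEFAULT_DISPERSION)),
        "Tau": GroupSpec(n(40), "Tau", "vehicle", tau_params(), dict(DEFAULT_DISPERSION)),
        "Tau+AR": GroupSpec(n(31), "Tau", "AR", wt, dict(DEFAULT_DISPERSION)),
    }


def _draw_params(
    spec: GroupSpec, rng: np.random.Generator
) -> SyntheticCellParams:
    updates = {}
    for name, sd in spec.dispersion.items():
        mean = getattr(spec.params, name)
        val = rng.normal(mean, sd)
        if name in _POSITIVE_FIELDS:
            val = max(val, 0.1 * mean)
        updates[name] = float(val)
    return replace(spec.params, **updates)


def simulate_cell(
    params: SyntheticCellParams,
    cell_id: str,
    genotype: str,
    treatment: str,
    seed,
    cc_protocol: Optional[StepProtocol] = None,
    vc_protocol: Optional[StepProtocol] = None,
    tp_protocol: Optional[StepProtocol] = None,
) -> Tuple[List[CellRecording], CellTruth]:
    """Simulate the full study battery for one cell.

    Emits two recordings: the from-rest condition (current clamp only) and
    the held -60 mV condition (current clamp plus voltage clamp plus the
    membrane test, all run from -60 mV as in the acquisition design).
    """
    cc_protocol = cc_protocol or current_clamp_protocol()
    vc_protocol = vc_protocol or voltage_clamp_protocol()
    tp_protocol = tp_protocol or test_pulse_protocol()
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    ss = seed.spawn(4)

    truth = CellTruth(params=params)

    rest_sweeps, rest_truth = simulate_current_clamp(params, cc_protocol, ss[0])
    truth.current_clamp["from_rest"] = rest_truth
    rec_rest = CellRecording(
        cell_id=cell_id,
        genotype=genotype,
        treatment=treatment,
        condition="from_rest",
        resting_potential=params.v_rest,
        sweeps={"current_steps": rest_sweeps},
        protocols={"current_steps": cc_protocol},
    )

    hold_pA = holding_current_for(params, -60.0)
    held_sweeps, held_truth = simulate_current_clamp(
        params, cc_protocol, ss[1], v_start=-60.0, holding_pA=hold_pA
    )
    truth.current_clamp["held_minus60"] = held_truth
    vc_sweeps, vc_truth = simulate_voltage_clamp(params, vc_protocol, ss[2])
    truth.voltage_clamp = vc_truth
    tp_sweeps = simulate_membrane_test(params, tp_protocol, ss[3])
    rec_held = CellRecording(
        cell_id=cell_id,
        genotype=genotype,
        treatment=treatment,
        condition="held_minus60",
        resting_potential=params.v_rest,
        sweeps={
            "current_steps": held_sweeps,
            "voltage_steps": vc_sweeps,
            MEMBRANE_TEST: tp_sweeps,
        },
        protocols={
            "current_steps": cc_protocol,
            "voltage_steps": vc_protocol,
            MEMBRANE_TEST: tp_protocol,
        },
    )
    return [rec_rest, rec_held], truth


def make_cohort(
    design: Dict[str, GroupSpec],
    seed,
    cc_protocol: Optional[StepProtocol] = None,
    vc_protocol: Optional[StepProtocol] = None,
    tp_protocol: Optional[StepProtocol] = None,
) -> Tuple[List[CellRecording], Dict[str, CellTruth]]:
    """Simulate every cell of a study design.

    Per-cell parameters are drawn independently from each group's
    distribution; both recording conditions are emitted per cell.  The
    pseudo-random stream is split hierarchically per cell so the cohort is
    reproducible bit-exactly from ``seed``.
    """
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    n_cells_total = sum(spec.n_cells for spec in design.values())
    children = root.spawn(n_cells_total)
    recordings: List[CellRecording] = []
    truths: Dict[str, CellTruth] = {}
    idx = 0
    for label, spec in design.items():
        for j in range(spec.n_cells):
            child = children[idx]
            idx += 1
            rng = np.random.default_rng(child)
            params = _draw_params(spec, rng)
            cell_id = f"{label.replace('+', '_')}_{j:03d}"
            recs, truth = simulate_cell(
                params,
                cell_id,
                spec.genotype,
                spec.treatment,
                child.spawn(1)[0],
                cc_protocol=cc_protocol,
                vc_protocol=vc_protocol,
                tp_protocol=tp_protocol,
            )
            recordings.extend(recs)
            truths[cell_id] = truth
    return recordings, truths
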