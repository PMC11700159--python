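"""Voltage-clamp analysis: leak subtraction, baseline zeroing, early
extrema and late steady-state currents, and per-cell IV summaries.

Leak subtraction scales the response to the smallest negative step
(-10 mV) — the best measure of passive current through leak channels and
capacitance — linearly with the applied voltage and subtracts it:

    subtracted(t) = I(t) - (dV / -10) * I_leak(t)

Repetitions of the -10 mV step are averaged before scaling.  After
subtraction, traces are zeroed by the mean current of the pre-step epoch.
Early maxima (inward = most negative, outward = most positive) come from
the first 10 ms after voltage application; the steady-state (late) current
is the mean over the last third of the step.  Capacitive transients are not
blanked from the early window by default; pass ``blank_ms`` to exclude the
first fraction of a millisecond when desired.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .trace_model import (
    VOLTAGE_CLAMP,
    ClampKitError,
    Sweep,
    VClampFeatures,
)
from .protocols import LEAK_INJECTION_MV

__all__ = [
    "VClampError",
    "leak_subtract",
    "zero_baseline",
    "vclamp_features",
    "cell_vclamp_summary",
]

EARLY_WINDOW_S = 0.010
LATE_FRACTION = 1.0 / 3.0
MIN_PRESTEP_S = 0.010


class VClampError(ClampKitError):
    pass


def _check_vc(sweeps: Sequence[Sweep]) -> None:
    if not sweeps:
        raise VClampError("no sweeps")
    for s in sweeps:
        if s.mode != VOLTAGE_CLAMP:
            raise VClampError("leak subtraction requires voltage-clamp sweeps")


def leak_subtract(
    sweeps: Sequence[Sweep], leak_injection: float = LEAK_INJECTION_MV
) -> List[Sweep]:
    """Subtract the linearly scaled leak-step response from every sweep.

    The leak trace is the mean across repetitions of the ``leak_injection``
    (-10 mV) sweeps.  The leak sweep subtracted against itself is
    identically zero up to repetition-averaging noise (exactly zero for a
    single repetition).
    """
    _check_vc(sweeps)
    leak_sweeps = [s for s in sweeps if s.command_level == leak_injection]
    if not leak_sweeps:
        raise VClampError(
            f"no {leak_injection} mV sweep present: leak subtraction impossible"
        )
    leak = np.mean([s.samples for s in leak_sweeps], axis=0)
    out = []
    for s in sweeps:
        scale = s.command_level / leak_injection
        out.append(
            Sweep(
                samples=s.samples - scale * leak,
                sampling_rate=s.sampling_rate,
                command_level=s.command_level,
                step_onset=s.step_onset,
                step_offset=s.step_offset,
                holding_level=s.holding_level,
                mode=s.mode,
                repetition_index=s.repetition_index,
            )
        )
    return out


def zero_baseline(sweep: Sweep) -> Sweep:
    """Subtract the mean pre-step current from the whole trace."""
    sr = sweep.sampling_rate
    on_i = int(round(sweep.step_onset * sr))
    if on_i < int(round(MIN_PRESTEP_S * sr)):
        raise VClampError(
            f"pre-step epoch shorter than {MIN_PRESTEP_S * 1000:.0f} ms; "
            "cannot estimate the baseline"
        )
    baseline = float(sweep.samples[:on_i].mean())
    return Sweep(
        samples=sweep.samples - baseline,
        sampling_rate=sr,
        command_level=sweep.command_level,
        step_onset=sweep.step_onset,
        step_offset=sweep.step_offset,
        holding_level=sweep.holding_level,
        mode=sweep.mode,
        repetition_index=sweep.repetition_index,
    )


def vclamp_features(
    sweeps: Sequence[Sweep],
    early_s: float = EARLY_WINDOW_S,
    late_fraction: float = LATE_FRACTION,
    blank_ms: float = 0.0,
    leak_injection: float = LEAK_INJECTION_MV,
    apply_leak_subtraction: bool = True,
) -> VClampFeatures:
    """Leak-subtract, zero and measure every injection of a voltage-clamp run.

    Per injection (repetitions averaged): ``early_max_inward`` is the
    minimum (clipped at 0 from above) and ``early_max_outward`` the maximum
    (clipped at 0 from below) over the first ``early_s`` of the step;
    ``late_mean`` is the signed mean over the final third.  Results are
    ordered by ascending injection.
    """
    _check_vc(sweeps)
    processed = leak_subtract(sweeps, leak_injection) if apply_leak_subtraction else list(sweeps)
    processed = [zero_baseline(s) for s in processed]

    first = processed[0]
    sr = first.sampling_rate
    on_i = int(round(first.step_onset * sr))
    off_i = int(round(first.step_offset * sr))
    n_step = off_i - on_i
    early_n = int(round(early_s * sr))
    if n_step < early_n:
        raise VClampError(
            f"step of {n_step / sr * 1000:.1f} ms is shorter than the "
            f"{early_s * 1000:.0f} ms early window"
        )
    blank_n = int(round(blank_ms * sr / 1000.0))
    early_sl = slice(on_i + blank_n, on_i + early_n)
    late_sl = slice(off_i - int(round(n_step * late_fraction)), off_i)

    by_inj: Dict[float, List[np.ndarray]] = {}
    for s in processed:
        by_inj.setdefault(s.command_level, []).append(s.samples)

    injections = np.asarray(sorted(by_inj))
    e_in, e_out, late = [], [], []
    for inj in injections:
        trace = np.mean(by_inj[float(inj)], axis=0)
        e_in.append(min(0.0, float(trace[early_sl].min())))
        e_out.append(max(0.0, float(trace[early_sl].max())))
        late.append(float(trace[late_sl].mean()))
    return VClampFeatures(
        injections=injections,
        early_max_inward=np.asarray(e_in),
        early_max_outward=np.asarray(e_out),
        late_mean=np.asarray(late),
        leak_subtracted=apply_leak_subtraction,
        zeroed=True,
    )


def cell_vclamp_summary(features: VClampFeatures) -> Tuple[float, float]:
    """(maximum inward, maximum outward) early current across injections.

    Maximum inward is the most negative ``early_max_inward``; maximum
    outward the largest ``early_max_outward``.  These are the per-cell
    quantities entering the group statistics.
    """
    return (
        float(features.early_max_inward.min()),
        float(features.early_max_outward.max()),
    )
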