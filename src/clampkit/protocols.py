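"""Stimulus protocols, constructed as data.

The study protocols: a current-clamp family of 20 pA steps from -100 to
480 pA repeated five times; a voltage-clamp family of 10 mV injections from
a -60 mV holding potential that must include the -10 mV leak step; and a
single -5 mV membrane-test pulse.  Step timing is a package choice (the
acquisition timing is metadata, not a constant): 100/500/400 ms
pre/step/post for current clamp and 50/300/150 ms for voltage clamp.

The step window is half-open, ``[onset, offset)``: the sample at the offset
time belongs to the post-step epoch.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .trace_model import CURRENT_CLAMP, VOLTAGE_CLAMP, ClampKitError, StepProtocol

__all__ = [
    "ProtocolError",
    "current_clamp_protocol",
    "voltage_clamp_protocol",
    "test_pulse_protocol",
    "DEFAULT_VC_INJECTIONS",
]

#: leak step plus 0..100 mV in 10 mV increments, relative to holding
DEFAULT_VC_INJECTIONS = tuple(float(v) for v in range(-10, 101, 10))

LEAK_INJECTION_MV = -10.0


class ProtocolError(ClampKitError):
    """Invalid protocol parameters."""


def current_clamp_protocol(
    start_pA: float = -100.0,
    stop_pA: float = 480.0,
    increment_pA: float = 20.0,
    repetitions: int = 5,
    pre_s: float = 0.100,
    step_s: float = 0.500,
    post_s: float = 0.400,
    holding_pA: float = 0.0,
) -> StepProtocol:
    """Square current steps on an arithmetic grid (defaults: 30 amplitudes,
    -100 to 480 pA by 20 pA, five repetitions)."""
    if repetitions < 1:
        raise ProtocolError("repetitions must be >= 1")
    if start_pA == stop_pA:
        amps = (float(start_pA),)
    else:
        if increment_pA <= 0:
            raise ProtocolError("increment must be positive")
        span = stop_pA - start_pA
        n_steps = span / increment_pA
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ProtocolError(
                f"increment {increment_pA} pA does not divide the range "
                f"{start_pA}..{stop_pA} pA"
            )
        n = int(round(n_steps)) + 1
        amps = tuple(float(start_pA + i * increment_pA) for i in range(n))
    return StepProtocol(
        mode=CURRENT_CLAMP,
        holding_level=holding_pA,
        pre_duration=pre_s,
        step_duration=step_s,
        post_duration=post_s,
        amplitudes=amps,
        repetitions=repetitions,
    )


def voltage_clamp_protocol(
    injections_mV: Sequence[float] = DEFAULT_VC_INJECTIONS,
    holding_mV: float = -60.0,
    repetitions: int = 1,
    pre_s: float = 0.050,
    step_s: float = 0.300,
    post_s: float = 0.150,
) -> StepProtocol:
    """Voltage steps relative to holding.  The -10 mV injection is required:
    it is the leak-subtraction reference downstream."""
    inj = tuple(sorted(float(v) for v in injections_mV))
    if LEAK_INJECTION_MV not in inj:
        raise ProtocolError(
            "voltage-clamp protocol must include the -10 mV leak step; "
            "leak subtraction is impossible without it"
        )
    return StepProtocol(
        mode=VOLTAGE_CLAMP,
        holding_level=holding_mV,
        pre_duration=pre_s,
        step_duration=step_s,
        post_duration=post_s,
        amplitudes=inj,
        repetitions=repetitions,
    )


def test_pulse_protocol(
    delta_mV: float = -5.0,
    holding_mV: float = -60.0,
    repetitions: int = 3,
    pre_s: float = 0.050,
    step_s: float = 0.100,
    post_s: float = 0.050,
) -> StepProtocol:
    """Single small membrane-test pulse (default -5 mV from -60 mV) used to
    estimate input resistance, series resistance and capacitance."""
    if delta_mV == 0:
        raise ProtocolError("test pulse amplitude must be nonzero")
    return StepProtocol(
        mode=VOLTAGE_CLAMP,
        holding_level=holding_mV,
        pre_duration=pre_s,
        step_duration=step_s,
        post_duration=post_s,
        amplitudes=(float(delta_mV),),
        repetitions=repetitions,
    )


def absolute_levels(protocol: StepProtocol) -> np.ndarray:
    """Absolute command levels (holding + amplitude) of a protocol."""
    return protocol.holding_level + np.asarray(protocol.amplitudes)
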