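"""Current-clamp spike analysis.

Detection uses slope-pair criteria applied directly to the recorded trace:
an action potential is an up-slope crossing of 30 mV/ms followed within
10 ms by a down-slope crossing of -15 mV/ms, whose voltage maximum between
the two crossings exceeds 0 mV.  Slopes are first-order finite differences
in mV/ms with no additional smoothing.  Candidate pairs are resolved
greedily left-to-right: an up-cross consumed by an event cannot seed
another.

Spikes whose up-cross lies outside a depolarizing step window are
spontaneous (before onset) or rebound (at/after offset, or during a
non-depolarizing step) and are omitted from all downstream counts.

At rheobase — the minimum current step that elicits at least one evoked
spike in any repetition — the first spike gets the full feature set:

* threshold: voltage at the maximum of the second finite difference in the
  window from 3 ms before the up-cross to the up-cross (earliest tie wins)
* latency: step onset to threshold time, ms
* amplitude: threshold to peak, mV
* width: full width at half amplitude (threshold + amplitude/2), linearly
  interpolated between samples, ms
* spike end: first sample after the peak back below threshold; when the
  trace never re-crosses below threshold before the sweep ends, width and
  end are undefined and the spike is excluded from those statistics.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .trace_model import (
    CURRENT_CLAMP,
    CellRecording,
    ClampKitError,
    FICurve,
    RheobaseFeatures,
    SpikeEvent,
    Sweep,
)

__all__ = [
    "DetectionError",
    "detect_spikes",
    "classify_spikes",
    "evoked_spikes",
    "fi_curve",
    "rheobase_features",
    "UP_SLOPE_MV_PER_MS",
    "DOWN_SLOPE_MV_PER_MS",
    "PAIR_WINDOW_MS",
    "MIN_PEAK_MV",
]

UP_SLOPE_MV_PER_MS = 30.0
DOWN_SLOPE_MV_PER_MS = -15.0
PAIR_WINDOW_MS = 10.0
MIN_PEAK_MV = 0.0
THRESHOLD_LOOKBACK_MS = 3.0

CC_PROTOCOL_NAME = "current_steps"


class DetectionError(ClampKitError):
    pass


def detect_spikes(
    sweep: Sweep,
    up_slope: float = UP_SLOPE_MV_PER_MS,
    down_slope: float = DOWN_SLOPE_MV_PER_MS,
    pair_window_ms: float = PAIR_WINDOW_MS,
    min_peak: float = MIN_PEAK_MV,
) -> List[SpikeEvent]:
    """Detect action potentials in one current-clamp sweep.

    Returns events (up-cross, peak time/voltage filled) in time order.
    """
    if sweep.mode != CURRENT_CLAMP:
        raise DetectionError("spike detection requires a current-clamp sweep")
    v = sweep.samples
    sr = sweep.sampling_rate
    window_n = int(round(pair_window_ms * sr / 1000.0))
    if v.size <= window_n:
        raise DetectionError(
            f"sweep of {v.size} samples is shorter than the {pair_window_ms} ms "
            "pairing window"
        )
    slope = np.diff(v) * (sr / 1000.0)  # mV/ms, slope[i] spans samples i..i+1

    up_hit = slope >= up_slope
    down_hit = slope <= down_slope
    up_cross = np.flatnonzero(up_hit & ~np.concatenate(([False], up_hit[:-1])))
    down_cross = np.flatnonzero(down_hit & ~np.concatenate(([False], down_hit[:-1])))

    events: List[SpikeEvent] = []
    di = 0
    min_next = -1  # up-crosses at/before this index are consumed
    for ui in up_cross:
        if ui <= min_next:
            continue
        while di < down_cross.size and down_cross[di] <= ui:
            di += 1
        if di >= down_cross.size:
            break
        dj = down_cross[di]
        min_next = ui  # the up-cross is consumed whether or not it pairs
        if dj - ui > window_n:
            continue
        seg = v[ui : dj + 2]  # both crossings' sample spans
        peak_rel = int(np.argmax(seg))
        peak_idx = ui + peak_rel
        if seg[peak_rel] <= min_peak:
            min_next = dj
            continue
        events.append(
            SpikeEvent(
                upcross_time=ui / sr,
                peak_time=peak_idx / sr,
                peak_voltage=float(seg[peak_rel]),
            )
        )
        min_next = dj
    return events


def classify_spikes(events: Sequence[SpikeEvent], sweep: Sweep) -> List[SpikeEvent]:
    """Label each event evoked / spontaneous / rebound.

    Evoked means the up-cross falls inside the half-open depolarizing step
    window ``[onset, offset)`` of a positive current step; everything else
    is omitted from downstream counts.
    """
    out = []
    depolarizing = sweep.command_level > 0
    for ev in events:
        if ev.upcross_time < sweep.step_onset:
            label = "spontaneous"
        elif (
            depolarizing
            and sweep.step_onset <= ev.upcross_time < sweep.step_offset
        ):
            label = "evoked"
        else:
            label = "rebound"
        out.append(replace(ev, classification=label))
    return out


def evoked_spikes(sweep: Sweep, **detect_kwargs) -> List[SpikeEvent]:
    """Detect and classify, returning evoked events only."""
    events = classify_spikes(detect_spikes(sweep, **detect_kwargs), sweep)
    return [e for e in events if e.classification == "evoked"]


def _cc_sweeps(recording: CellRecording, protocol_name: str) -> List[Sweep]:
    if protocol_name not in recording.sweeps:
        raise DetectionError(f"recording has no protocol {protocol_name!r}")
    sweeps = recording.sweeps[protocol_name]
    if any(s.mode != CURRENT_CLAMP for s in sweeps):
        raise DetectionError(f"protocol {protocol_name!r} is not current clamp")
    return sweeps


def fi_curve(
    recording: CellRecording, protocol_name: str = CC_PROTOCOL_NAME
) -> FICurve:
    """Mean evoked spike count and firing proportions per step amplitude.

    Counts are averaged across repetitions; the one-or-more and exactly-one
    flags are computed per repetition then averaged to proportions.
    """
    import warnings

    sweeps = _cc_sweeps(recording, protocol_name)
    proto = recording.protocols[protocol_name]
    by_amp: Dict[float, List[int]] = defaultdict(list)
    for s in sweeps:
        by_amp[s.command_level].append(len(evoked_spikes(s)))

    amps = np.asarray(proto.amplitudes)
    counts, p_any, p_one = [], [], []
    for a in amps:
        c = by_amp.get(float(a), [])
        if len(c) < proto.repetitions:
            warnings.warn(
                f"amplitude {a} pA has {len(c)}/{proto.repetitions} repetitions; "
                "averaging available sweeps",
                stacklevel=2,
            )
        if not c:
            counts.append(0.0), p_any.append(0.0), p_one.append(0.0)
            continue
        arr = np.asarray(c, dtype=float)
        counts.append(float(arr.mean()))
        p_any.append(float(np.mean(arr >= 1)))
        p_one.append(float(np.mean(arr == 1)))
    return FICurve(
        amplitudes=amps,
        spike_count=np.asarray(counts),
        p_one_or_more=np.asarray(p_any),
        p_exactly_one=np.asarray(p_one),
    )


def _first_spike_features(sweep: Sweep, first: SpikeEvent) -> SpikeEvent:
    """Fill threshold, latency, amplitude, width of the rheobase spike."""
    v = sweep.samples
    sr = sweep.sampling_rate
    ui = int(round(first.upcross_time * sr))
    peak_idx = int(round(first.peak_time * sr))

    lookback = int(round(THRESHOLD_LOOKBACK_MS * sr / 1000.0))
    lo = max(1, ui - lookback)
    hi = min(ui, v.size - 2)
    d2 = (v[lo + 1 : hi + 2] - 2.0 * v[lo : hi + 1] + v[lo - 1 : hi]) * (sr / 1000.0) ** 2
    thr_idx = lo + int(np.argmax(d2))  # earliest tie wins
    thr_v = float(v[thr_idx])
    amplitude = float(first.peak_voltage - thr_v)
    latency = (thr_idx / sr - sweep.step_onset) * 1000.0

    # spike end: first sample after the peak back below threshold
    after = v[peak_idx + 1 :]
    below = np.flatnonzero(after < thr_v)
    if below.size == 0:
        end_time = None
        width = None
    else:
        end_idx = peak_idx + 1 + int(below[0])
        end_time = end_idx / sr
        half = thr_v + amplitude / 2.0
        width = _half_width(v, sr, peak_idx, half)
    return replace(
        first,
        threshold_time=thr_idx / sr,
        threshold_voltage=thr_v,
        latency=latency,
        amplitude=amplitude,
        end_time=end_time,
        width=width,
    )


def _half_width(v: np.ndarray, sr: float, peak_idx: int, half: float) -> Optional[float]:
    """Half-amplitude chord around the peak, sub-sample interpolated."""
    k = peak_idx
    while k > 0 and v[k - 1] >= half:
        k -= 1
    if k == 0:
        return None
    t_up = (k - 1 + (half - v[k - 1]) / (v[k] - v[k - 1])) / sr
    k = peak_idx
    n = v.size
    while k + 1 < n and v[k + 1] >= half:
        k += 1
    if k + 1 >= n:
        return None
    t_down = (k + (half - v[k]) / (v[k + 1] - v[k])) / sr
    return (t_down - t_up) * 1000.0


def rheobase_features(
    recording: CellRecording, protocol_name: str = CC_PROTOCOL_NAME
) -> Optional[RheobaseFeatures]:
    """Rheobase current and fully featured first spike, or ``None`` when the
    cell never fires an evoked spike (the cell is then excluded from the
    rheobase statistics)."""
    sweeps = _cc_sweeps(recording, protocol_name)
    by_amp: Dict[float, List[Sweep]] = defaultdict(list)
    for s in sweeps:
        if s.command_level > 0:
            by_amp[s.command_level].append(s)

    for amp in sorted(by_amp):
        reps = sorted(by_amp[amp], key=lambda s: s.repetition_index)
        for s in reps:
            ev = evoked_spikes(s)
            if ev:
                first = min(ev, key=lambda e: e.upcross_time)
                return RheobaseFeatures(
                    rheobase_current=float(amp),
                    first_spike=_first_spike_features(s, first),
                )
    return None
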