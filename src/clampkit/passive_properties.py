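"""Passive membrane properties from the -5 mV membrane test.

The whole-cell test-pulse current is modelled as a single exponential,

    I(t) = I_ss + (I_peak - I_ss) * exp(-t / tau),

measured relative to the pre-step baseline.  The two-compartment
identities then give

    R_s  = dV / (I_peak - I_baseline)
    R_in = dV / (I_ss  - I_baseline) - R_s
    C_m  = tau * (R_in + R_s) / (R_in * R_s)

with dV the pulse amplitude.  Repetitions are averaged before fitting; the
fit window starts one sample after the step edge (the edge sample carries
the command discontinuity) and the fitted curve is extrapolated back to
the edge to recover the true transient peak.  The steady-state window is
the last third of the step.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .trace_model import (
    VOLTAGE_CLAMP,
    ClampKitError,
    PassiveProperties,
    Sweep,
)

__all__ = ["EstimationError", "estimate_passive"]


class EstimationError(ClampKitError):
    """Membrane-test fit failed or is degenerate."""


def _exp_decay(t, i_ss, a, tau):
    return i_ss + a * np.exp(-t / tau)


def estimate_passive(
    test_sweeps: Sequence[Sweep],
    resting_potential: float = np.nan,
) -> PassiveProperties:
    """Estimate R_in, R_s and C_m from membrane-test sweeps.

    All sweeps must be voltage clamp at a single nonzero pulse amplitude.
    ``resting_potential`` is metadata passed through to the result.
    """
    if len(test_sweeps) == 0:
        raise EstimationError("no membrane-test sweeps provided")
    first = test_sweeps[0]
    if first.mode != VOLTAGE_CLAMP:
        raise EstimationError("membrane test must be recorded in voltage clamp")
    delta_mV = first.command_level
    if delta_mV == 0:
        raise EstimationError("test pulse amplitude is zero")
    for s in test_sweeps[1:]:
        if s.command_level != delta_mV or s.sampling_rate != first.sampling_rate:
            raise EstimationError("membrane-test sweeps must share one pulse")

    sr = first.sampling_rate
    mean_trace = np.mean([s.samples for s in test_sweeps], axis=0)
    on_i = int(round(first.step_onset * sr))
    off_i = int(round(first.step_offset * sr))
    baseline = float(mean_trace[:on_i].mean())

    n_step = off_i - on_i
    tail = mean_trace[off_i - n_step // 3 : off_i]
    i_ss_obs = float(tail.mean())
    if abs(i_ss_obs - baseline) < 1e-12:
        raise EstimationError("steady-state current equals baseline: infinite resistance")

    # fit from one sample after the edge; t = 0 at the edge itself
    fit = mean_trace[on_i + 1 : off_i]
    t = (np.arange(1, fit.size + 1)) / sr
    a0 = float(fit[0] - i_ss_obs)
    tau0 = max(2.0 / sr, 0.2 * n_step / sr)
    c_m_reliable = True

    if abs(a0) <= 0.05 * abs(i_ss_obs - baseline):
        # The transient has fully decayed within one sample: tau is not
        # identifiable from the sampled trace.  Take the peak from the raw
        # edge sample, bound tau by the sampling interval, and flag the
        # capacitance as unreliable rather than fitting an exponential to
        # what is effectively a flat line.
        i_peak_raw = float(mean_trace[on_i])
        warnings.warn(
            "membrane-test transient shorter than one sample; capacitance "
            "estimate flagged unreliable",
            stacklevel=2,
        )
        return _from_levels(
            delta_mV=delta_mV,
            baseline=baseline,
            i_peak=i_peak_raw,
            i_ss=i_ss_obs,
            tau=1.0 / sr,
            rss=float(np.sum((fit - i_ss_obs) ** 2)),
            resting_potential=resting_potential,
            capacitance_reliable=False,
        )

    try:
        with np.errstate(over="ignore"):
            popt, _ = curve_fit(
                _exp_decay,
                t,
                fit,
                p0=(i_ss_obs, a0, tau0),
                maxfev=10_000,
            )
        i_ss, a, tau = float(popt[0]), float(popt[1]), float(popt[2])
        rss = float(np.sum((fit - _exp_decay(t, *popt)) ** 2))
    except RuntimeError as exc:
        raise EstimationError(f"membrane-test transient fit failed: {exc}") from exc
    if tau <= 0 or a * (i_ss_obs - baseline) < 0:
        raise EstimationError(
            "membrane-test transient is non-decaying or of inconsistent sign "
            f"(tau={tau:.3g} s, amplitude={a:.3g} pA)"
        )
    if tau < 1.5 / sr:
        # transient shorter than ~one sample: essentially a pure resistor;
        # R_in from steady state remains valid but C_m cannot be trusted
        c_m_reliable = False
        warnings.warn(
            "membrane-test transient shorter than one sample; capacitance "
            "estimate flagged unreliable",
            stacklevel=2,
        )
    i_peak = i_ss + a  # extrapolated to the step edge
    return _from_levels(
        delta_mV=delta_mV,
        baseline=baseline,
        i_peak=i_peak,
        i_ss=i_ss,
        tau=tau,
        rss=rss,
        resting_potential=resting_potential,
        capacitance_reliable=c_m_reliable,
    )


def _from_levels(
    *,
    delta_mV: float,
    baseline: float,
    i_peak: float,
    i_ss: float,
    tau: float,
    rss: float,
    resting_potential: float,
    capacitance_reliable: bool,
) -> PassiveProperties:
    # mV / pA = GOhm -> MOhm
    r_s = 1000.0 * delta_mV / (i_peak - baseline)
    r_chord = 1000.0 * delta_mV / (i_ss - baseline)
    r_in = r_chord - r_s
    if r_s <= 0 or r_in <= 0:
        raise EstimationError(
            f"non-physical resistances from fit (R_s={r_s:.3g}, R_in={r_in:.3g} MOhm)"
        )
    tau_us = tau * 1e6
    c_m = tau_us * (r_in + r_s) / (r_in * r_s)  # us / MOhm = pF
    return PassiveProperties(
        input_resistance=r_in,
        series_resistance=r_s,
        capacitance=c_m,
        resting_potential=resting_potential,
        fit_rss=rss,
        capacitance_reliable=capacitance_reliable,
    )
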