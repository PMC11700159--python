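"""Cohort pipeline: simulate -> analyze -> stats -> report.

Each stage is a plain function over files so stages can be re-run in
isolation: simulation writes one container directory per cell recording
plus a ground-truth table; analysis reads containers and writes the
feature table (one row per cell x condition); statistics consumes the
feature table and writes a tidy results CSV and a human-readable report;
reporting draws the group panels (per-cell scatter with median/IQR, mean
+/- SEM spike count vs current, current-voltage curves).

Outputs are deterministic given the seed; ``provenance.json`` records the
package version, seed and a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .trace_model import (
    CellRecording,
    ClampKitError,
    read_recording,
    write_recording,
)
from .passive_properties import EstimationError, estimate_passive
from .spike_pipeline import CC_PROTOCOL_NAME, fi_curve, rheobase_features
from .vclamp_pipeline import cell_vclamp_summary, vclamp_features
from .group_stats import (
    GroupSample,
    kruskal_dunn,
    line_f_test,
    mann_whitney,
    one_phase_f_test,
    rm_anova_gg,
    rout_outliers,
    tukey_posthoc,
)
from .synthetic_cells import default_design, make_cohort

logger = logging.getLogger("clampkit")

VC_PROTOCOL_NAME = "voltage_steps"

PASSIVE_ENDPOINTS = ["r_input_MOhm", "c_m_pF", "v_rest_mV"]
RHEOBASE_ENDPOINTS = ["rheobase_pA", "latency_ms", "amplitude_mV", "width_ms"]


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "clampkit_out"
    design_scale: float = 1.0
    stages: Tuple[str, ...] = ("simulate", "analyze", "stats", "report")
    container_dir: Optional[str] = None  # analyze an existing cohort instead

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# per-cell analysis
# ---------------------------------------------------------------------------

def analyze_recording(recording: CellRecording) -> Dict:
    """Extract every feature the recording's protocols support."""
    row: Dict = {
        "cell_id": recording.cell_id,
        "group": recording.group,
        "genotype": recording.genotype,
        "treatment": recording.treatment,
        "condition": recording.condition,
    }
    tp = recording.test_pulse_sweeps
    if tp:
        try:
            pp = estimate_passive(tp, resting_potential=recording.resting_potential)
            row.update(
                r_input_MOhm=pp.input_resistance,
                r_series_MOhm=pp.series_resistance,
                c_m_pF=pp.capacitance,
                v_rest_mV=pp.resting_potential,
                passive_fit_rss=pp.fit_rss,
            )
        except EstimationError as exc:
            logger.warning("cell %s: passive fit failed: %s", recording.cell_id, exc)

    if CC_PROTOCOL_NAME in recording.sweeps:
        fi = fi_curve(recording)
        for a, c, pa, pe in zip(
            fi.amplitudes, fi.spike_count, fi.p_one_or_more, fi.p_exactly_one
        ):
            key = f"{int(a)}"
            row[f"count_{key}"] = c
            row[f"p_any_{key}"] = pa
            row[f"p_one_{key}"] = pe
        rb = rheobase_features(recording)
        if rb is not None:
            row["rheobase_pA"] = rb.rheobase_current
            row["latency_ms"] = rb.first_spike.latency
            row["threshold_mV"] = rb.first_spike.threshold_voltage
            row["amplitude_mV"] = rb.first_spike.amplitude
            row["width_ms"] = rb.first_spike.width

    if VC_PROTOCOL_NAME in recording.sweeps:
        feats = vclamp_features(recording.sweeps[VC_PROTOCOL_NAME])
        max_in, max_out = cell_vclamp_summary(feats)
        row["max_in_pA"] = max_in
        row["max_out_pA"] = max_out
        for inj, ei, eo, lm in zip(
            feats.injections,
            feats.early_max_inward,
            feats.early_max_outward,
            feats.late_mean,
        ):
            key = f"{int(inj)}"
            row[f"early_in_{key}"] = ei
            row[f"early_out_{key}"] = eo
            row[f"late_{key}"] = lm
    return row


def feature_table(recordings: Sequence[CellRecording]) -> pd.DataFrame:
    """One row per cell x condition, sorted for byte-stable output."""
    rows = [analyze_recording(r) for r in recordings]
    df = pd.DataFrame(rows)
    return df.sort_values(["group", "cell_id", "condition"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# statistics stage
# ---------------------------------------------------------------------------

def _groups_for(df: pd.DataFrame, endpoint: str, apply_rout: bool = True):
    out = []
    removed_total = 0
    for label, sub in df.groupby("group", observed=True):
        vals = sub[endpoint].dropna().to_numpy()
        if vals.size == 0:
            continue
        if apply_rout and vals.size >= 4:
            vals, removed = rout_outliers(vals)
            removed_total += removed.size
        out.append(GroupSample(label=label, values=vals))
    return out, removed_total


def _wide_to_long(df: pd.DataFrame, prefix: str) -> pd.DataFrame:
    cols = [c for c in df.columns if c.startswith(prefix)]
    long = df.melt(
        id_vars=["cell_id", "group"],
        value_vars=cols,
        var_name="level",
        value_name="value",
    ).dropna(subset=["value"])
    long["level"] = long["level"].str.removeprefix(prefix).astype(float)
    return long.rename(columns={"cell_id": "subject"})


def run_group_stats(features: pd.DataFrame) -> Tuple[pd.DataFrame, str]:
    """The study's statistical battery over a feature table.

    Scalar endpoints (passive properties, rheobase spike features, per-cell
    current maxima) get per-group ROUT outlier removal then Kruskal-Wallis
    with Dunn post-hocs (Mann-Whitney when only two groups are present).
    Spike counts across current steps and currents across voltage steps get
    the mixed-design ANOVA with Greenhouse-Geisser correction and Tukey
    post-hocs.  Firing-proportion curves get the origin-constrained
    one-phase (one-or-more spikes) and straight-line (exactly-one spike)
    F-tests.
    """
    rows: List[Dict] = []
    report: List[str] = []

    def emit(**kw):
        rows.append(kw)

    for condition, cond_df in features.groupby("condition", observed=True):
        scalar_endpoints = [
            e
            for e in PASSIVE_ENDPOINTS + RHEOBASE_ENDPOINTS + ["max_in_pA", "max_out_pA"]
            if e in cond_df.columns and cond_df[e].notna().sum() > 0
        ]
        for endpoint in scalar_endpoints:
            groups, n_removed = _groups_for(cond_df, endpoint)
            if groups and min(g.values.size for g in groups) < 3:
                logger.warning(
                    "[%s] %s: a group has fewer than 3 cells; skipped",
                    condition, endpoint,
                )
                continue
            if len(groups) >= 3:
                res = kruskal_dunn(groups)
                emit(
                    condition=condition, endpoint=endpoint, test="kruskal_wallis",
                    statistic=res["H"], p=res["p"], comparison="omnibus",
                    n_outliers_removed=n_removed,
                )
                for _, pr in res["pairwise"].iterrows():
                    emit(
                        condition=condition, endpoint=endpoint, test="dunn",
                        statistic=pr["z"], p=pr["p_raw"], adjusted_p=pr["p_adj"],
                        comparison=f"{pr['group_a']} vs {pr['group_b']}",
                    )
                report.append(
                    f"[{condition}] {endpoint}: Kruskal-Wallis H={res['H']:.3f}, "
                    f"p={res['p']:.4g} ({n_removed} outliers removed)"
                )
            elif len(groups) == 2:
                u, p = mann_whitney(groups[0].values, groups[1].values)
                emit(
                    condition=condition, endpoint=endpoint, test="mann_whitney",
                    statistic=u, p=p,
                    comparison=f"{groups[0].label} vs {groups[1].label}",
                    n_outliers_removed=n_removed,
                )
                report.append(
                    f"[{condition}] {endpoint}: Mann-Whitney U={u:.1f}, p={p:.4g}"
                )

        # repeated-measures endpoints
        rm_specs = [("count_", "spike_count")]
        if condition == "held_minus60":
            rm_specs += [
                ("early_in_", "early_inward"),
                ("early_out_", "early_outward"),
                ("late_", "late_current"),
            ]
        for prefix, name in rm_specs:
            long = _wide_to_long(cond_df, prefix)
            if long.empty or long["group"].nunique() < 2:
                continue
            res = rm_anova_gg(long)
            for _, er in res.table.iterrows():
                emit(
                    condition=condition, endpoint=name, test="rm_anova",
                    effect=er["effect"], statistic=er["F"], p=er["p"],
                    p_gg=er["p_gg"], epsilon=res.epsilon,
                    df=f"{er['df1']:.0f},{er['df2']:.0f}",
                )
            tk = tukey_posthoc(long)
            for _, pr in tk.iterrows():
                emit(
                    condition=condition, endpoint=name, test="tukey",
                    statistic=pr["meandiff"], adjusted_p=float(pr["p_adj"]),
                    comparison=f"{pr['group_a']} vs {pr['group_b']}",
                )
            wrow = res.table[res.table.effect == "within"].iloc[0]
            report.append(
                f"[{condition}] {name}: RM-ANOVA within F={wrow['F']:.2f}, "
                f"GG eps={res.epsilon:.3f}, p_GG={wrow['p_gg']:.4g}"
            )

        # firing-proportion curve comparisons (depolarizing steps only)
        for prefix, name, fitter in [
            ("p_any_", "one_or_more", one_phase_f_test),
            ("p_one_", "exactly_one", line_f_test),
        ]:
            long = _wide_to_long(cond_df, prefix)
            long = long[long["level"] >= 0]
            if long.empty or long["group"].nunique() < 2:
                continue
            try:
                res = fitter(
                    long["level"].to_numpy(),
                    long["value"].to_numpy(),
                    long["group"].to_numpy(),
                )
            except ClampKitError as exc:
                logger.warning("%s curve comparison failed: %s", name, exc)
                continue
            emit(
                condition=condition, endpoint=name, test=f"{fitter.__name__}",
                statistic=res["F"], p=res["p"],
                comparison="shared vs per-group parameters",
            )
            report.append(
                f"[{condition}] {name}: extra-sum-of-squares F={res['F']:.2f}, "
                f"p={res['p']:.4g}"
            )

    stats_df = pd.DataFrame(rows)
    return stats_df, "\n".join(report) + "\n"


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------

def make_figures(features: pd.DataFrame, out_dir: Path) -> List[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    order = sorted(features["group"].unique())

    held = features[features.condition == "held_minus60"]
    panels = [e for e in PASSIVE_ENDPOINTS + ["max_in_pA", "max_out_pA"] if e in held]
    if panels:
        fig, axes = plt.subplots(1, len(panels), figsize=(3 * len(panels), 3.2))
        axes = np.atleast_1d(axes)
        for ax, ep in zip(axes, panels):
            for i, gl in enumerate(order):
                vals = held.loc[held.group == gl, ep].dropna()
                ax.scatter(np.full(vals.size, i), vals, s=10, alpha=0.6)
                if vals.size:
                    q1, med, q3 = np.percentile(vals, [25, 50, 75])
                    ax.hlines(med, i - 0.25, i + 0.25, color="k")
                    ax.vlines(i, q1, q3, color="k", lw=1)
            ax.set_xticks(range(len(order)), order, rotation=45, fontsize=7)
            ax.set_title(ep, fontsize=9)
        fig.tight_layout()
        p = out_dir / "passive_panels.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)

    for condition, cond_df in features.groupby("condition", observed=True):
        long = _wide_to_long(cond_df, "count_")
        if long.empty:
            continue
        fig, ax = plt.subplots(figsize=(4.5, 3.2))
        for gl in order:
            sub = long[long.group == gl]
            agg = sub.groupby("level")["value"].agg(["mean", "sem"])
            ax.errorbar(agg.index, agg["mean"], yerr=agg["sem"], label=gl, capsize=2)
        ax.set_xlabel("current step (pA)")
        ax.set_ylabel("mean spike count")
        ax.set_title(f"F-I, {condition}")
        ax.legend(fontsize=7)
        fig.tight_layout()
        p = out_dir / f"fi_curve_{condition}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)

    long = _wide_to_long(held, "late_")
    if not long.empty:
        fig, ax = plt.subplots(figsize=(4.5, 3.2))
        for gl in order:
            sub = long[long.group == gl]
            agg = sub.groupby("level")["value"].agg(["mean", "sem"])
            ax.errorbar(agg.index, agg["mean"], yerr=agg["sem"], label=gl, capsize=2)
        ax.set_xlabel("voltage injection (mV)")
        ax.set_ylabel("late current (pA)")
        ax.set_title("IV curve (leak subtracted)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        p = out_dir / "iv_curve.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, out: Path) -> Path:
    cohort_dir = out / "cohort"
    cohort_dir.mkdir(parents=True, exist_ok=True)
    design = default_design(scale=config.design_scale)
    recordings, truths = make_cohort(design, seed=config.seed)
    gt_rows = []
    for rec in recordings:
        write_recording(rec, cohort_dir / rec.condition, fmt="npy")
        truth = truths[rec.cell_id]
        gt_rows.append(
            {
                "cell_id": rec.cell_id,
                "condition": rec.condition,
                "v_rest": truth.params.v_rest,
                "r_input": truth.params.r_input,
                "c_m": truth.params.c_m,
                "spike_threshold": truth.params.spike_threshold,
                "spike_amplitude": truth.params.spike_amplitude,
            }
        )
    pd.DataFrame(gt_rows).to_csv(out / "ground_truth.csv", index=False)
    logger.info("simulated %d recordings into %s", len(recordings), cohort_dir)
    return cohort_dir


def load_cohort(cohort_dir: Path) -> List[CellRecording]:
    recs = []
    for cond_dir in sorted(Path(cohort_dir).iterdir()):
        if not cond_dir.is_dir():
            continue
        for cell_dir in sorted(cond_dir.iterdir()):
            if (cell_dir / "meta.json").exists():
                recs.append(read_recording(cell_dir))
    if not recs:
        raise ClampKitError(f"no containers found under {cohort_dir}")
    return recs


def stage_analyze(cohort_dir: Path, out: Path) -> Path:
    recordings = load_cohort(cohort_dir)
    df = feature_table(recordings)
    path = out / "features.csv"
    df.to_csv(path, index=False)
    logger.info("analyzed %d recordings -> %s", len(recordings), path)
    return path


def stage_stats(features_path: Path, out: Path) -> Path:
    features = pd.read_csv(features_path)
    stats_df, report = run_group_stats(features)
    path = out / "stats.csv"
    stats_df.to_csv(path, index=False)
    (out / "report.txt").write_text(report)
    logger.info("wrote %d statistical results -> %s", len(stats_df), path)
    return path


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the configured stages; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        cohort_dir = Path(config.container_dir) if config.container_dir else out / "cohort"
        if "simulate" in config.stages:
            cohort_dir = stage_simulate(config, out)
        if "analyze" in config.stages:
            stage_analyze(cohort_dir, out)
        if "stats" in config.stages:
            if not (out / "features.csv").exists():
                raise ClampKitError("stats stage requires features.csv; run analyze")
            stage_stats(out / "features.csv", out)
        if "report" in config.stages:
            if not (out / "features.csv").exists():
                raise ClampKitError("report stage requires features.csv; run analyze")
            make_figures(pd.read_csv(out / "features.csv"), out / "figures")
        provenance = {
            "package": "clampkit",
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "config": asdict(config),
        }
        (out / "provenance.json").write_text(json.dumps(provenance, indent=1))
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out
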