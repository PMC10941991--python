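"""Seeded reference fixtures and the end-to-end report pipeline.

``generate_fixtures`` writes deterministic session-log CSVs for a named
observer scenario plus a manifest with configs, seeds and SHA-256
checksums, so tests and documentation can pin byte-identical inputs.
``end_to_end_report`` chains simulate -> analyze -> classify -> plot
into a single markdown report with figure analogues for the training
curves, per-contrast performance, latency comparison and psychometric
fit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import analysis, classify
from .engine import (
    ConfigError,
    SessionConfig,
    SessionLog,
    run_sessions,
    write_session_csv,
)
from .observer import ObserverParams, preset, preset_names

__all__ = ["FixtureSpec", "generate_fixtures", "end_to_end_report"]

SCENARIOS = ("perfect", "good_cs", "weak_cs", "biased", "learner", "random")


@dataclass(frozen=True)
class FixtureSpec:
    """A named simulation scenario: observer preset + session count + seed."""

    scenario: str
    sessions: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigError(
                f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}"
            )
        if self.sessions < 1:
            raise ConfigError("sessions must be positive")


def _spawn_seeds(seed: int, n: int) -> list[int]:
    # stable sub-seed derivation, kept below 2**31
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _scenario_config(scenario: str, seed: int) -> SessionConfig:
    if scenario == "learner":
        return SessionConfig(
            phase="self_run_training",
            contrast_levels=[1.0],
            reps_per_contrast=100,
            max_trials=100,
            seed=seed,
        )
    return SessionConfig(phase="experiment", seed=seed)


def simulate_scenario(spec: FixtureSpec) -> tuple[list[SessionLog], SessionConfig,
                                                  ObserverParams]:
    """Run the scenario's sessions in memory (no files written)."""
    cfg_seed, obs_seed = _spawn_seeds(spec.seed, 2)
    config = _scenario_config(spec.scenario, cfg_seed)
    observer = dataclasses.replace(preset(spec.scenario), seed=obs_seed)
    logs = run_sessions(config, observer, spec.sessions,
                        animal_id=spec.scenario)
    return logs, config, observer


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def generate_fixtures(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Write the scenario's session CSVs and a checksum manifest.

    Deterministic per (scenario, sessions, seed): repeated calls
    produce byte-identical files and checksums.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logs, config, observer = simulate_scenario(spec)
    entries = []
    for i, log in enumerate(logs, start=1):
        path = out_dir / f"{spec.scenario}_s{i:02d}.csv"
        write_session_csv(log, path)
        entries.append({
            "file": path.name,
            "session_date": log.session_date,
            "n_trials": len(log.trials),
            "sha256": _sha256(path),
        })
    manifest = {
        "scenario": spec.scenario,
        "sessions": spec.sessions,
        "seed": spec.seed,
        "config": {**dataclasses.asdict(config),
                   "contrast_levels": list(config.contrast_levels)},
        "observer": dataclasses.asdict(observer),
        "files": entries,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


# --- report pipeline --------------------------------------------------------


def _write_tables(out_dir: Path, logs: list[SessionLog]) -> dict:
    points = analysis.per_contrast_performance(logs)
    pd.DataFrame([dataclasses.asdict(p) for p in points]).to_csv(
        out_dir / "per_contrast.csv", index=False
    )
    summaries = [analysis.session_summary(log) for log in logs]
    pd.DataFrame([dataclasses.asdict(s) for s in summaries]).to_csv(
        out_dir / "sessions.csv", index=False
    )
    lat = analysis.latency_summary(logs)
    pd.DataFrame([dataclasses.asdict(lat)]).to_csv(
        out_dir / "latency.csv", index=False
    )
    try:
        fit = analysis.fit_psychometric(points)
        with open(out_dir / "fit.json", "w") as fh:
            json.dump(dataclasses.asdict(fit), fh, indent=2)
            fh.write("\n")
    except analysis.AnalysisError:
        fit = None
    bands = classify.band_summary(
        [(p.contrast, p.percent_correct) for p in points]
    )
    rows = [{"contrast": p.contrast, "percent_correct": p.percent_correct,
             "area": classify.classify_point(p.contrast, p.percent_correct).label}
            for p in points]
    pd.DataFrame(rows).to_csv(out_dir / "bands.csv", index=False)
    return {"points": points, "summaries": summaries, "latency": lat,
            "fit": fit, "bands": bands}


def _plot_all(out_dir: Path, results: dict) -> list[Path]:
    paths = []
    summaries, points, fit = (results["summaries"], results["points"],
                              results["fit"])

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    idx = np.arange(1, len(summaries) + 1)
    axes[0].plot(idx, [s.percent_correct_overall for s in summaries], "o-")
    axes[0].axhline(75, ls="--", c="gray")
    axes[0].set(xlabel="session", ylabel="% correct", ylim=(0, 100),
                title="Training trajectory")
    axes[1].plot(idx, [s.side1_touch_percent for s in summaries], "o-")
    for y in (25, 50, 75):
        axes[1].axhline(y, ls="--", c="gray", lw=0.5)
    axes[1].set(xlabel="session", ylabel="% touches side 1", ylim=(0, 100),
                title="Side bias")
    fig.tight_layout()
    paths.append(out_dir / "training.png")
    fig.savefig(paths[-1], dpi=100)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    c = [p.contrast * 100 for p in points]
    pc = [p.percent_correct for p in points]
    ax.bar(c, pc, width=6, color=["tab:blue" if p.p_value_vs_chance < 0.05
                                  else "lightgray" for p in points])
    ax.axhline(50, ls="--", c="k", lw=0.8)
    ax.set(xlabel="contrast (%)", ylabel="% correct", ylim=(0, 100),
           title="Per-contrast performance (blue: p < 0.05 vs chance)")
    if fit is not None:
        grid = np.linspace(0.01, 1.0, 200)
        ax.plot(grid * 100, fit.predict_percent_correct(grid), "r-", lw=1.5)
        if fit.threshold_corrected is not None:
            ax.axvline(fit.threshold_corrected * 100, c="r", ls=":")
    fig.tight_layout()
    paths.append(out_dir / "per_contrast.png")
    fig.savefig(paths[-1], dpi=100)
    plt.close(fig)

    lat = results["latency"]
    if lat.mean_latency_correct_s is not None:
        fig, ax = plt.subplots(figsize=(3.5, 3.5))
        vals = [lat.mean_latency_correct_s, lat.mean_latency_incorrect_s or 0]
        ax.bar(["correct", "incorrect"], vals, color=["tab:green", "tab:red"])
        ax.set(ylabel="mean latency (s)", title="Response latency")
        fig.tight_layout()
        paths.append(out_dir / "latency.png")
        fig.savefig(paths[-1], dpi=100)
        plt.close(fig)
    return paths


def end_to_end_report(
    config: SessionConfig,
    observer: ObserverParams,
    out_dir: str | Path,
    n_sessions: int = 4,
    animal_id: str = "sim",
) -> Path:
    """Simulate, analyze, classify and plot; returns the report path.

    Writes session CSVs, tidy result tables (``per_contrast.csv``,
    ``sessions.csv``, ``latency.csv``, ``fit.json``, ``bands.csv``),
    PNG figure analogues and a single ``report.md`` tying them
    together.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logs = run_sessions(config, observer, n_sessions, animal_id=animal_id)
    for i, log in enumerate(logs, start=1):
        write_session_csv(log, out_dir / f"{animal_id}_s{i:02d}.csv")
    return report_from_logs(logs, out_dir)


def report_from_logs(logs: list[SessionLog], out_dir: str | Path) -> Path:
    """Analysis-and-report stage usable on real (converted) logs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results = _write_tables(out_dir, logs)
    plots = _plot_all(out_dir, results)
    lat, fit, bands = results["latency"], results["fit"], results["bands"]
    pct1, biased = analysis.side_bias(logs)
    lines = [
        f"# Contrast-sensitivity report: {logs[0].animal_id}",
        "",
        f"Sessions analyzed: {len(logs)}; completed trials: "
        f"{sum(log.n_completed for log in logs)}.",
        "",
        "## Side bias",
        f"- Touches on side 1: {pct1:.1f}%"
        + (" — **significant side bias**" if biased else " (no significant bias)"),
        "",
        "## Per-contrast performance",
        "",
        "| contrast | n | correct | % correct | p vs chance |",
        "|---|---|---|---|---|",
    ]
    for p in results["points"]:
        lines.append(
            f"| {p.contrast:.1f} | {p.n} | {p.k} | {p.percent_correct:.1f} "
            f"| {p.p_value_vs_chance:.4g} |"
        )
    lines += ["", "## Latency"]
    if lat.mean_latency_correct_s is not None:
        lines.append(f"- Mean latency, correct: {lat.mean_latency_correct_s:.2f} s "
                     f"(n={lat.n_correct})")
    if lat.mean_latency_incorrect_s is not None:
        lines.append(f"- Mean latency, incorrect: "
                     f"{lat.mean_latency_incorrect_s:.2f} s (n={lat.n_incorrect})")
    if lat.ratio_incorrect_over_correct is not None:
        lines.append(f"- Ratio incorrect/correct: "
                     f"{lat.ratio_incorrect_over_correct:.2f} "
                     f"(Mann-Whitney p = {lat.test_p_value:.4g})")
    lines += ["", "## Psychometric fit"]
    if fit is not None:
        thr = ("not measurable" if fit.threshold_corrected is None
               else f"{fit.threshold_corrected * 100:.1f}% contrast")
        lines += [
            f"- alpha = {fit.alpha_hat:.3f}, beta = {fit.beta_hat:.1f}, "
            f"lapse = {fit.lambda_hat:.3f} (converged: {fit.converged})",
            f"- Threshold (75% correct, guessing-corrected): {thr}",
        ]
        if fit.note:
            lines.append(f"- Note: {fit.note}")
    else:
        lines.append("- Not fitted (fewer than 3 contrast levels).")
    lines += [
        "",
        "## CS-function bands",
        f"- good/moderate CS (A1+A2): {bands['bands']['good_moderate']} "
        f"of {bands['n']} points",
        f"- weak CS (A3+A4): {bands['bands']['weak_cs']}",
        f"- weak training / random (A5+A6): {bands['bands']['weak_training']}",
        "",
        "## Figures",
    ]
    lines += [f"![{p.stem}]({p.name})" for p in plots]
    report = out_dir / "report.md"
    report.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return report
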