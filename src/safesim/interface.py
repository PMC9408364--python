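"""Configuration files, tabular outputs, and the command-line interface.

All file formats are plain text: YAML configs, RFC-4180 CSV tables, and a
JSON metadata sidecar recording full configuration and seed schedules for
provenance. The CLI is a thin layer over the library; all randomness flows
from the ``--seed`` flag.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path
from typing import Mapping, Sequence

import click
import pandas as pd
import yaml

from . import __version__
from .experiments import (
    ScenarioSpec,
    calibrate_gain,
    multi_variable_specs,
    run_scenario,
    single_variable_specs,
)
from .metrics import RunResult, ScenarioSummary
from .model_core import ConfigError, ModelConfig, validate_config

__all__ = ["load_config", "write_tables", "main"]

logger = logging.getLogger("safesim")

_SUMMARY_COLUMNS = [
    "scenario",
    "replicates",
    "onset_median",
    "onset_iqr",
    "plateau_tick_median",
    "plateau_level_mean",
    "plateau_fraction",
    "n_no_onset",
]
_TIMESERIES_COLUMNS = [
    "scenario",
    "replicate",
    "seed",
    "tick",
    "exhibiting_count",
    "willing_count",
]


def load_config(path: str | Path) -> ModelConfig:
    """Parse and validate a YAML config file; an empty file means all defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f"{path}:{mark.line + 1}" if mark is not None else str(path)
        raise ConfigError(f"malformed YAML in {where}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"config file {path} must contain a key-value mapping")
    return validate_config(raw)


def write_tables(
    results: Mapping[str, Sequence[RunResult]],
    summaries: Sequence[ScenarioSummary],
    out_dir: str | Path,
    metadata: Mapping | None = None,
) -> dict[str, Path]:
    """Write timeseries.csv, summary.csv and metadata.json under ``out_dir``.

    Row order is deterministic — (scenario, replicate, tick) — so reruns
    with identical inputs produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for scenario in sorted(results):
        for rep, res in enumerate(results[scenario]):
            for t in range(len(res.exhibiting_count)):
                rows.append(
                    (
                        scenario,
                        rep,
                        res.seed,
                        t,
                        int(res.exhibiting_count[t]),
                        int(res.willing_count[t]),
                    )
                )
    ts = pd.DataFrame(rows, columns=_TIMESERIES_COLUMNS)

    summary = pd.DataFrame(
        [
            (
                s.scenario_name,
                s.replicates,
                s.onset_median,
                s.onset_iqr,
                s.plateau_tick_median,
                s.plateau_level_mean,
                s.plateau_fraction,
                s.n_no_onset,
            )
            for s in sorted(summaries, key=lambda s: s.scenario_name)
        ],
        columns=_SUMMARY_COLUMNS,
    )

    paths = {
        "timeseries": out_dir / "timeseries.csv",
        "summary": out_dir / "summary.csv",
        "metadata": out_dir / "metadata.json",
    }
    ts.to_csv(paths["timeseries"], index=False, lineterminator="\n")
    summary.to_csv(paths["summary"], index=False, lineterminator="\n")

    meta = {
        "package_version": __version__,
        "scenarios": {
            name: {
                "replicates": len(res),
                "seeds": [r.seed for r in res],
                "config_digest": res[0].config_digest if res else None,
            }
            for name, res in sorted(results.items())
        },
    }
    if metadata:
        meta.update(metadata)
    paths["metadata"].write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    logger.info("wrote %s", ", ".join(str(p) for p in paths.values()))
    return paths


def _base_config(config_path: str | None, **flag_overrides) -> ModelConfig:
    base = load_config(config_path) if config_path else validate_config({})
    overrides = {k: v for k, v in flag_overrides.items() if v is not None}
    return base.with_overrides(**overrides) if overrides else base


@click.group()
@click.option("--verbose", is_flag=True, help="Log progress to stderr.")
def main(verbose: bool) -> None:
    """Simulate safety-behavior adoption among workers on a construction site."""
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(levelname)s %(name)s: %(message)s",
    )


def _run_and_write(specs, base, out):
    results, summaries = {}, []
    for spec in specs:
        res, summary = run_scenario(spec, base)
        results[spec.name] = res
        summaries.append(summary)
        logger.info(
            "scenario %s: median onset %s, plateau level %.1f",
            spec.name,
            summary.onset_median,
            summary.plateau_level_mean,
        )
    paths = write_tables(
        results, summaries, out, metadata={"base_config": base.to_dict()}
    )
    click.echo(f"wrote {paths['summary']} ({len(summaries)} scenario(s))")


@main.command("run")
@click.option("--igii", type=float, default=None, help="Site-mean IGII (0-10).")
@click.option("--gks", type=float, default=None, help="Site-mean GKS (0-10).")
@click.option("--gi", type=float, default=None, help="Site-mean GI (0-10).")
@click.option("--workers", type=int, default=None, help="Worker count (0-100).")
@click.option("--ticks", type=int, default=None, help="Ticks per run.")
@click.option("--replicates", type=int, default=1, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--config", "config_path", type=click.Path(), default=None)
@click.option("--out", type=click.Path(), default="safesim_out", show_default=True)
def cli_run(igii, gks, gi, workers, ticks, replicates, seed, config_path, out):
    """Run one scenario and write its tables."""
    try:
        base = _base_config(
            config_path,
            initial_igii=igii,
            initial_gks=gks,
            initial_gi=gi,
            initial_workers_count=workers,
            ticks=ticks,
        )
        spec = ScenarioSpec(
            name="run", overrides={}, replicates=replicates, base_seed=seed
        )
        _run_and_write([spec], base, out)
    except (ConfigError, ValueError, OSError) as exc:
        raise click.ClickException(str(exc))


@main.command("suite")
@click.option(
    "--which",
    type=click.Choice(["single", "multi", "both"]),
    default="both",
    show_default=True,
)
@click.option("--replicates", type=int, default=100, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--config", "config_path", type=click.Path(), default=None)
@click.option("--out", type=click.Path(), default="safesim_out", show_default=True)
def cli_suite(which, replicates, seed, config_path, out):
    """Run the single- and/or multi-variable scenario suites."""
    try:
        base = _base_config(config_path)
        specs = []
        if which in ("single", "both"):
            specs += single_variable_specs(replicates, seed)
        if which in ("multi", "both"):
            specs += multi_variable_specs(replicates, seed)
        _run_and_write(specs, base, out)
    except (ConfigError, ValueError, OSError) as exc:
        raise click.ClickException(str(exc))


@main.command("calibrate")
@click.option("--target-onset", type=float, default=15, show_default=True)
@click.option("--replicates", type=int, default=100, show_default=True)
@click.option(
    "--bounds", type=(float, float), default=(0.05, 5.0), show_default=True
)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--config", "config_path", type=click.Path(), default=None)
def cli_calibrate(target_onset, replicates, bounds, seed, config_path):
    """Calibrate the cultivation gain to a target baseline median onset."""
    try:
        base = _base_config(config_path)
        gain = calibrate_gain(
            base, target_onset, replicates=replicates, bounds=bounds, base_seed=seed
        )
        click.echo(json.dumps({"cultivation_gain": gain}))
    except Exception as exc:
        raise click.ClickException(str(exc))


@main.command("plot")
@click.option(
    "--timeseries",
    type=click.Path(exists=True),
    required=True,
    help="timeseries.csv from a previous run/suite invocation.",
)
@click.option("--out", type=click.Path(), default="safesim_out", show_default=True)
@click.option(
    "--format", "fmt", type=click.Choice(["png", "svg"]), default="png",
    show_default=True,
)
def cli_plot(timeseries, out, fmt):
    """Plot adoption curves (exhibiting count vs t), one figure per scenario."""
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        ts = pd.read_csv(timeseries)
        out_dir = Path(out)
        out_dir.mkdir(parents=True, exist_ok=True)
        for scenario, df in ts.groupby("scenario"):
            fig, ax = plt.subplots(figsize=(6, 4))
            for _, rep_df in df.groupby("replicate"):
                ax.plot(
                    rep_df["tick"], rep_df["exhibiting_count"],
                    color="steelblue", alpha=0.15, lw=0.8,
                )
            mean_curve = df.groupby("tick")["exhibiting_count"].mean()
            ax.plot(mean_curve.index, mean_curve.values, color="crimson", lw=2,
                    label="replicate mean")
            ax.set_xlabel("t (ticks)")
            ax.set_ylabel("workers exhibiting safety behavior")
            ax.set_title(scenario)
            ax.legend(frameon=False)
            fig.tight_layout()
            path = out_dir / f"{scenario}.{fmt}"
            fig.savefig(path, dpi=150)
            plt.close(fig)
            click.echo(f"wrote {path}")
    except (ConfigError, ValueError, OSError, KeyError) as exc:
        raise click.ClickException(str(exc))


if __name__ == "__main__":  # pragma: no cover
    main()
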