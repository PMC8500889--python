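"""Command-line interface and file-level glue.

Subcommands: ``simulate`` (generate a synthetic judgment dataset),
``fit`` (fit one model to a dataset CSV and print a summary), ``recover``
(run the recovery grid) and ``report`` (re-render tables from saved cell
summaries).  Options can also come from a YAML/JSON config file; explicit
command-line flags win over the file, which wins over the documented
defaults.  Exit codes: 0 ok, 1 validation error, 2 runtime failure.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from pathlib import Path
from typing import Optional

import click
import numpy as np
import yaml

from . import bayes_fit, datagen, recovery
from .bayes_fit import FitConfig
from .datagen import JudgmentDataset

logger = logging.getLogger("exemplarmix")

EXIT_OK, EXIT_VALIDATION, EXIT_RUNTIME = 0, 1, 2


def read_dataset(path: str | Path) -> JudgmentDataset:
    """Read and validate a judgment dataset CSV.

    Dialect: ``cue_1..cue_D,response,is_trained,learned_criterion`` with an
    empty last field on untrained rows.  Errors name the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise ValueError(f"dataset file not found: {path}")
    return JudgmentDataset.read_csv(path)


def _load_config_file(path: Optional[str], allowed: set[str]) -> dict:
    if path is None:
        return {}
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
    return data


def _resolve(cli_value, file_cfg: dict, key: str, default):
    """Precedence: explicit CLI flag > config file > default."""
    if cli_value is not None:
        return cli_value
    if key in file_cfg and file_cfg[key] is not None:
        return file_cfg[key]
    return default


def _fit_config(file_cfg: dict, seed: Optional[int], desk: bool) -> FitConfig:
    base = FitConfig.desk(seed=seed) if desk else FitConfig(seed=seed)
    overrides = {
        k: file_cfg[k]
        for k in ("chains", "draws_per_chain", "burn_in", "adaptation", "thin",
                  "density_method")
        if k in file_cfg
    }
    return dataclasses.replace(base, **overrides) if overrides else base


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Log progress to stderr.")
def cli(verbose: bool) -> None:
    """Exemplar-model judgment simulation, fitting and recovery studies."""
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        stream=sys.stderr,
    )


@cli.command()
@click.option("--d", "n_cues", type=int, default=None, help="Number of binary cues (default 5).")
@click.option("--s", "s_true", type=float, default=None, help="True similarity parameter.")
@click.option("--pr", type=float, default=None, help="Recall probability P_r.")
@click.option("--noise-sd", type=float, default=None, help="Response noise SD (default 0).")
@click.option("--n-exemplars", type=int, default=None, help="Trained exemplars (default 12).")
@click.option("--seed", type=int, default=None, help="RNG seed.")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--out", type=click.Path(), required=True, help="Output dataset CSV.")
def simulate(n_cues, s_true, pr, noise_sd, n_exemplars, seed, config_path, out):
    """Generate one synthetic judgment dataset and its design sidecar JSON."""
    allowed = {"n_cues", "s_true", "pr", "noise_sd", "n_exemplars", "seed"}
    file_cfg = _load_config_file(config_path, allowed)
    n_cues = int(_resolve(n_cues, file_cfg, "n_cues", datagen.DEFAULT_N_CUES))
    s_true = float(_resolve(s_true, file_cfg, "s_true", 0.3))
    pr = float(_resolve(pr, file_cfg, "pr", 0.5))
    noise_sd = float(_resolve(noise_sd, file_cfg, "noise_sd", 0.0))
    n_exemplars = int(_resolve(n_exemplars, file_cfg, "n_exemplars", datagen.DEFAULT_N_EXEMPLARS))
    seed = _resolve(seed, file_cfg, "seed", 0)

    rng = np.random.default_rng(seed)
    design = datagen.sample_design(rng, n_cues=n_cues, n_exemplars=n_exemplars)
    regime = datagen.GenerationRegime(s_true=s_true, recall_prob=pr, noise_sd=noise_sd, seed=seed)
    dataset = datagen.generate_judgments(design, regime, rng)
    dataset.write_csv(out)
    design.to_json(Path(out).with_suffix(".design.json"), seed=seed)
    logger.info("wrote %d trials to %s (seed=%s)", len(dataset), out, seed)
    click.echo(f"wrote {len(dataset)} trials to {out}")


@cli.command()
@click.argument("dataset_path", type=click.Path(exists=True))
@click.option("--model", type=click.Choice(["orig", "split", "mixture"]), default="mixture")
@click.option("--tol", type=float, default=None, help="Exact-recall tolerance for --model split.")
@click.option("--seed", type=int, default=None)
@click.option("--full-mcmc", is_flag=True, help="Use the heavyweight MCMC schedule.")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--out", type=click.Path(), default=None, help="Summary JSON path.")
def fit(dataset_path, model, tol, seed, full_mcmc, config_path, out):
    """Fit one model to a dataset CSV and print the posterior summary."""
    allowed = {"seed", "tol", "chains", "draws_per_chain", "burn_in", "adaptation",
               "thin", "density_method"}
    file_cfg = _load_config_file(config_path, allowed)
    seed = _resolve(seed, file_cfg, "seed", 0)
    tol = float(_resolve(tol, file_cfg, "tol", 1e-9))
    cfg = _fit_config(file_cfg, seed=seed, desk=not full_mcmc)

    data = read_dataset(dataset_path)
    extras = {"seed": seed, "dataset": str(dataset_path)}
    if model == "orig":
        post = bayes_fit.fit_original(data, cfg)
    elif model == "split":
        post = bayes_fit.fit_split(data, cfg, tol=tol)
        extras["split_tol"] = tol
    else:
        post = bayes_fit.fit_mixture(data, cfg)
        extras["log_bf_10"] = bayes_fit.savage_dickey_log_bf(post)
        extras["density_method"] = cfg.density_method
    extras["rmse"] = bayes_fit.posterior_predictive_rmse(post, data)
    summary = post.summary()
    summary.update(extras)
    logger.info("fit %s: R-hat %s", post.model, post.rhats)
    click.echo(json.dumps(summary, indent=1, default=float))
    if out:
        bayes_fit.write_summary(out, post, extras=extras)


@cli.command()
@click.option("--s-grid", default=None, help="Comma-separated true s values.")
@click.option("--pr-grid", default=None, help="Comma-separated recall probabilities.")
@click.option("--reps", type=int, default=None, help="Replications per cell (default 30).")
@click.option("--seed", type=int, default=None, help="Master seed (default 0).")
@click.option("--full-mcmc", is_flag=True, help="Use the heavyweight MCMC schedule.")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--out", type=click.Path(), required=True, help="Output directory.")
def recover(s_grid, pr_grid, reps, seed, full_mcmc, config_path, out):
    """Run the parameter-recovery grid and write table2/3/4 + cells.json."""
    allowed = {"s_grid", "pr_grid", "reps", "seed", "chains", "draws_per_chain",
               "burn_in", "adaptation", "thin", "density_method"}
    file_cfg = _load_config_file(config_path, allowed)
    seed = int(_resolve(seed, file_cfg, "seed", 0))
    reps = int(_resolve(reps, file_cfg, "reps", 30))
    s_values = _resolve(s_grid, file_cfg, "s_grid", recovery.DEFAULT_S_GRID)
    pr_values = _resolve(pr_grid, file_cfg, "pr_grid", recovery.DEFAULT_PR_GRID)
    if isinstance(s_values, str):
        s_values = tuple(float(v) for v in s_values.split(","))
    if isinstance(pr_values, str):
        pr_values = tuple(float(v) for v in pr_values.split(","))

    cfg = recovery.GridConfig(
        s_grid=tuple(s_values),
        pr_grid=tuple(pr_values),
        replications=reps,
        master_seed=seed,
        fit_config=_fit_config(file_cfg, seed=None, desk=not full_mcmc),
    )
    summaries = recovery.run_grid(cfg)
    paths = recovery.write_tables(summaries, out, config=cfg)
    click.echo(f"wrote {len(summaries)} cells to {paths['cells']}")


@cli.command()
@click.argument("cells_json", type=click.Path(exists=True))
@click.option("--out", type=click.Path(), required=True, help="Output directory.")
def report(cells_json, out):
    """Re-render the recovery tables from a saved cells.json."""
    payload = json.loads(Path(cells_json).read_text())
    summaries = []
    for c in payload["cells"]:
        c = {k: (np.nan if v is None else v) for k, v in c.items()}
        c.setdefault("draws", {})
        summaries.append(recovery.RecoveryCellSummary(**c))
    paths = recovery.write_tables(summaries, out)
    click.echo(f"wrote tables for {len(summaries)} cells to {out}")


def main(argv: Optional[list[str]] = None) -> int:
    """Entry point with the documented exit-code contract."""
    try:
        cli.main(args=argv, standalone_mode=False)
        return EXIT_OK
    except click.exceptions.Exit as exc:
        return int(exc.exit_code)
    except click.exceptions.UsageError as exc:
        click.echo(f"usage error: {exc.format_message()}", err=True)
        click.echo(cli.get_help(click.Context(cli)), err=True)
        return EXIT_VALIDATION
    except click.exceptions.Abort:
        return EXIT_RUNTIME
    except ValueError as exc:
        click.echo(f"validation error: {exc}", err=True)
        return EXIT_VALIDATION
    except Exception as exc:  # pragma: no cover - defensive
        click.echo(f"runtime failure: {exc}", err=True)
        return EXIT_RUNTIME


if __name__ == "__main__":
    sys.exit(main())
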