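"""Config-driven orchestration of end-to-end runs.

A single :class:`RunConfig` (built directly or loaded from YAML) names a
stage chain and its parameters; :func:`run` executes it and writes CSV
outputs plus a YAML manifest (config echo, package version, derived
per-stage seeds) beside them, so any run can be reproduced exactly from
its manifest.  Stages:

* ``synth``    — generate a synthetic meta-dataset (estimates + metadata);
* ``compute``  — read records, compute per group-and-sex skew estimates;
* ``meta``     — fit a group-comparison model to estimates + metadata;
* ``sweep``    — run a mating-market parameter sweep;
* ``run_all``  — synth, then meta on the synthesized tables.

The global seed is expanded into independent per-stage seeds through
``numpy.random.SeedSequence(seed, spawn_key=(stage_index,))``, with stage
indices fixed by :data:`STAGE_INDEX`; rerunning one stage in isolation
with the same config therefore reproduces its output bit for bit.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .mating import MatingMarketConfig, sweep as run_sweep
from .meta import MetaSpec, SamplerSettings, contrast, fit_group_model
from .records import read_metadata, read_records
from .skew import NullModelSpec, skew_table
from .synth import SyntheticSpec, default_study_spec, gen_meta_dataset

logger = logging.getLogger("repskew")

__all__ = ["RunConfig", "run", "stage_seed", "load_config"]

STAGE_INDEX = {"synth": 0, "compute": 1, "meta": 2, "sweep": 3}


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed (< 2^31)."""
    ss = np.random.SeedSequence(base_seed, spawn_key=(STAGE_INDEX[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclasses.dataclass
class RunConfig:
    """One pipeline run: which stages, where the inputs/outputs live, seeds.

    Stage-specific blocks are plain dicts passed through to the stage
    implementations (null-model replicates, sweep grid, sampler settings,
    subset filters); anything omitted takes the package default.
    """

    command: str
    out_dir: str
    seed: int = 0
    records_path: str | None = None
    metadata_path: str | None = None
    estimates_path: str | None = None
    skew: dict[str, Any] = dataclasses.field(default_factory=dict)
    meta: dict[str, Any] = dataclasses.field(default_factory=dict)
    sweep: dict[str, Any] = dataclasses.field(default_factory=dict)
    synth: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        allowed = set(STAGE_INDEX) | {"run_all"}
        if self.command not in allowed:
            raise ValueError(f"unknown command {self.command!r}; allowed: {sorted(allowed)}")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig(**raw)


def _require_path(path: str | None, what: str) -> Path:
    if path is None:
        raise ValueError(f"config is missing the {what} path")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} path does not exist: {p}")
    return p


def _stage_synth(config: RunConfig, out: Path) -> dict[str, str]:
    seed = stage_seed(config.seed, "synth")
    opts = dict(config.synth)
    if opts.pop("study_default", True):
        spec = default_study_spec(seed=seed, mode=opts.pop("mode", "direct"))
    else:
        spec = SyntheticSpec(seed=seed, **opts)
    estimates, metadata, truths = gen_meta_dataset(spec)
    estimates.to_csv(out / "skew_estimates.csv", index=False)
    metadata.to_csv(out / "metadata.csv", index=False)
    with open(out / "truths.yaml", "w") as fh:
        yaml.safe_dump(truths, fh)
    return {"estimates": "skew_estimates.csv", "metadata": "metadata.csv",
            "truths": "truths.yaml"}


def _stage_compute(config: RunConfig, out: Path) -> dict[str, str]:
    records = read_records(_require_path(config.records_path, "records"))
    opts = dict(config.skew)
    null = NullModelSpec(
        replicates=opts.get("null_reps", 2000), seed=stage_seed(config.seed, "compute")
    )
    table = skew_table(records, null, method=opts.get("method", "mc"),
                       bootstrap_reps=opts.get("bootstrap_reps", 0))
    table.to_csv(out / "skew_estimates.csv", index=False)
    return {"estimates": "skew_estimates.csv"}


def _stage_meta(config: RunConfig, out: Path,
                estimates: pd.DataFrame | None = None,
                metadata: pd.DataFrame | None = None) -> dict[str, str]:
    if estimates is None:
        estimates = pd.read_csv(_require_path(config.estimates_path, "estimates"),
                                dtype={"group_id": str})
    if metadata is None:
        metadata = read_metadata(_require_path(config.metadata_path, "metadata"))
    opts = dict(config.meta)
    sampler = SamplerSettings(seed=stage_seed(config.seed, "meta"),
                              **opts.get("sampler", {}))
    spec = MetaSpec(
        outcome=opts.get("outcome", "M_star_male"),
        grouping=opts.get("grouping", "taxon"),
        use_measurement_error=opts.get("use_measurement_error", False),
        sampler=sampler,
    )
    fit = fit_group_model(estimates, metadata, spec)
    frames = [fit.to_frame()]
    pair = opts.get("contrast")
    if pair is None and len(fit.class_labels) == 2:
        pair = fit.class_labels
    if pair:
        c = contrast(fit, pair[0], pair[1])
        frames.append(pd.DataFrame([{
            "parameter": c.label, "mean": c.mean, "ci89_low": c.ci89_low,
            "ci89_high": c.ci89_high, "rhat": c.rhat, "ess_bulk": c.ess_bulk,
        }]))
    pd.concat(frames, ignore_index=True).to_csv(out / "posterior_summaries.csv", index=False)
    np.savez(out / "posterior_draws.npz",
             **{s.label: s.draws for s in fit.summaries.values()})
    return {"summaries": "posterior_summaries.csv", "draws": "posterior_draws.npz"}


def _stage_sweep(config: RunConfig, out: Path) -> dict[str, str]:
    opts = dict(config.sweep)
    grid_r = np.linspace(*opts.get("gini_r", (0.12, 0.64)), opts.get("steps_r", 25))
    grid_mu = np.linspace(*opts.get("mu", (0.15, 0.95)), opts.get("steps_mu", 25))
    cfg = MatingMarketConfig(
        n_males=opts.get("n", 200), replicates=opts.get("reps", 20),
        seed=stage_seed(config.seed, "sweep"),
    )
    rules = opts.get("rules", ("ideal_free", "imposed_monogamy"))
    table = run_sweep(grid_r, grid_mu, rules=rules, config=cfg)
    table.to_csv(out / "sweep.csv", index=False)
    return {"sweep": "sweep.csv"}


def run(config: RunConfig) -> dict[str, str]:
    """Execute a configured stage chain; returns the output-file map.

    Outputs are pure functions of the config (inputs + seeds); a manifest
    echoing the config, package version and derived per-stage seeds is
    written beside them.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    try:
        if config.command == "synth":
            outputs = _stage_synth(config, out)
        elif config.command == "compute":
            outputs = _stage_compute(config, out)
        elif config.command == "meta":
            outputs = _stage_meta(config, out)
        elif config.command == "sweep":
            outputs = _stage_sweep(config, out)
        elif config.command == "run_all":
            outputs = _stage_synth(config, out)
            estimates = pd.read_csv(out / outputs["estimates"], dtype={"group_id": str})
            metadata = read_metadata(out / outputs["metadata"])
            outputs |= _stage_meta(config, out, estimates, metadata)
    except Exception as exc:
        raise type(exc)(f"stage {config.command!r}: {exc}") from exc
    manifest = {
        "config": dataclasses.asdict(config),
        "package_version": __version__,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGE_INDEX},
        "outputs": outputs,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    logger.info("run %s complete: %s", config.command, sorted(outputs.values()))
    return outputs
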