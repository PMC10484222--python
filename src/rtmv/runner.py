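"""Experiment orchestration: configs, dispatch, trial-table I/O.

``ExperimentConfig`` carries every generator / design / analysis parameter
with the standard defaults, round-trips through JSON or YAML, and
``run_experiment`` dispatches to the matching simulation engine:

* simulation 1 - power vs contamination proportion (raw and/or a randomly
  chosen single treatment per repetition)
* simulation 2 - false-alarm rate vs number of methods tried
* simulation 3 - minimal CI width and maximal |Cohen's d| under selection
* simulation 4 - Bayesian per-family and cumulative HDI-exclusion rates

Every run writes a tidy long-format CSV (one estimate per row) and a JSON
sidecar echoing the fully resolved configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bayes import SamplerConfig, BayesModelSpec, bayes_rate_study
from .datagen import TRIAL_COLUMNS
from .multiverse import power_curve, run_multiverse
from .specs import ContaminationSpec, DesignSpec, ExGaussianSpec
from .treatments import select_methods, standard_table1_menu

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A trial CSV does not match the expected schema."""


def read_trial_csv(path) -> pd.DataFrame:
    """Read a long-format trial table.

    Requires columns subject, condition, trial, rt; a missing
    ``contaminated`` column defaults to False.  Conditions must be labeled
    1 and 2.
    """
    table = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("subject", "condition", "trial", "rt") if c not in table.columns]
    if missing:
        raise SchemaError(f"trial CSV missing column(s): {', '.join(missing)}")
    if not pd.api.types.is_numeric_dtype(table["rt"]):
        raise SchemaError("column 'rt' must be numeric")
    conditions = set(pd.unique(table["condition"]))
    if not conditions <= {1, 2}:
        raise SchemaError(f"unknown condition label(s): {sorted(conditions - {1, 2})}")
    if "contaminated" not in table.columns:
        table["contaminated"] = False
    table["contaminated"] = table["contaminated"].astype(bool)
    counts = table.groupby(["subject", "condition"]).size()
    if counts.nunique() > 1:
        logger.info("trial table is unbalanced (cell sizes %d..%d)", counts.min(), counts.max())
    return table[TRIAL_COLUMNS]


def write_trial_csv(table: pd.DataFrame, path) -> None:
    """Write a trial table with full float precision (lossless round-trip)."""
    table.to_csv(path, index=False, float_format="%.17g")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one simulation end to end."""

    simulation: int = 2
    # generative model
    mu: float = 400.0
    sigma: float = 40.0
    tau: float = 200.0
    p: float = 0.1
    a: float = 0.0
    b: float = 2000.0
    n_subjects: int = 30
    n_obs: int = 10
    mu_diff: float = 0.0
    # analysis
    alpha: float = 0.05
    methods: tuple[int, ...] | None = None  # menu method ids; None = all 20
    subset_sizes: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 8, 10, 12, 16, 20)
    cont_grid: tuple[float, ...] = (0.0, 0.05, 0.1, 0.15, 0.2)
    power_modes: tuple[str, ...] = ("raw", "random_single_method")
    effect_size: str = "dz"
    include_untreated: bool = False
    # Bayesian settings (simulation 4)
    families: tuple[str, ...] = ("normal", "t", "lognormal", "gamma")
    chains: int = 16
    warmup: int = 500
    draws: int = 250
    # execution
    reps: int = 10_000
    seed: int = 0
    out: str | None = None

    def __post_init__(self) -> None:
        if self.simulation not in (1, 2, 3, 4):
            raise ValueError(f"unknown simulation id {self.simulation}")
        if self.simulation == 4 and self.reps == 10_000:
            self.reps = 1000  # the Bayesian study's standard repetition count

    # -- sub-spec views ----------------------------------------------------
    @property
    def design(self) -> DesignSpec:
        return DesignSpec(self.n_subjects, self.n_obs, self.mu_diff)

    @property
    def exgaussian(self) -> ExGaussianSpec:
        return ExGaussianSpec(self.mu, self.sigma, self.tau)

    @property
    def contamination(self) -> ContaminationSpec:
        return ContaminationSpec(self.p, self.a, self.b)

    def menu(self):
        full = standard_table1_menu()
        if self.methods is None:
            return full
        return select_methods(full, self.methods)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        d = dict(d)
        for key in ("methods", "subset_sizes", "cont_grid", "power_modes", "families"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        return cls.from_dict(data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Run one simulation end to end and return its tidy results table.

    Deterministic under a fixed config (identical seed => byte-identical
    CSV).  If ``config.out`` is set, writes the CSV and a ``<out>.config.json``
    sidecar with the resolved configuration.
    """
    logger.info(
        "simulation %d: seed=%d reps=%d config=%s",
        config.simulation, config.seed, config.reps, config.config_hash(),
    )
    sim = config.simulation
    if sim == 1:
        frames = []
        design = DesignSpec(config.n_subjects, config.n_obs, config.mu_diff or 50.0)
        for mode in config.power_modes:
            curve = power_curve(
                design,
                config.exgaussian,
                cont_grid=config.cont_grid,
                mode=mode,
                alpha=config.alpha,
                n_reps=config.reps,
                rng=np.random.SeedSequence(config.seed),
                menu=config.menu(),
                cont_bounds=(config.a, config.b),
            )
            frames.append(curve)
        results = pd.concat(frames, ignore_index=True)
        results.insert(0, "simulation", 1)
        results.insert(1, "criterion", "power")
    elif sim in (2, 3):
        criteria = ["false_alarm"] if sim == 2 else ["min_ci_width", "max_abs_d"]
        rows = []
        for criterion in criteria:
            for k in config.subset_sizes:
                est = run_multiverse(
                    config.design,
                    config.exgaussian,
                    config.contamination,
                    menu=config.menu(),
                    subset_size_k=k,
                    criterion=criterion,
                    alpha=config.alpha,
                    n_reps=config.reps,
                    rng=np.random.SeedSequence(config.seed),
                    effect_size=config.effect_size,
                    include_untreated=config.include_untreated,
                )
                rows.append(
                    {
                        "simulation": sim,
                        "criterion": criterion,
                        "k": k,
                        "p_outlier": config.p,
                        "estimate": est.estimate,
                        "mc_se": est.mc_se,
                        "n_reps": est.n_reps,
                        "seed": config.seed,
                    }
                )
        results = pd.DataFrame(rows)
    else:  # simulation 4
        sampler = SamplerConfig(
            chains=config.chains, warmup=config.warmup, draws=config.draws
        )
        specs = tuple(BayesModelSpec(f, sampler_config=sampler) for f in config.families)
        results = bayes_rate_study(
            config.design,
            config.exgaussian,
            config.contamination,
            specs=specs,
            mu_diff=config.mu_diff,
            n_reps=config.reps,
            rng=np.random.SeedSequence(config.seed),
        )
        results.insert(0, "simulation", 4)
        results.insert(1, "criterion", "hdi_excludes_zero")
        results["p_outlier"] = config.p
        results["seed"] = config.seed
    if config.out:
        out = Path(config.out)
        out.parent.mkdir(parents=True, exist_ok=True)
        results.to_csv(out, index=False)
        sidecar = out.with_suffix(out.suffix + ".config.json")
        sidecar.write_text(config.to_json())
        logger.info("wrote %s (+ %s)", out, sidecar.name)
    return results
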