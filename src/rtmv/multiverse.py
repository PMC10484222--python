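"""Monte-Carlo engines for selection across outlier-treatment methods.

The hazardous practice being quantified: analyze the same experiment with a
subset of k treatment methods and report the most favorable outcome.  Three
criteria are supported:

* ``power`` / ``false_alarm`` - a repetition scores 1 if ANY method in the
  subset yields p < alpha (with mu_diff > 0 this is power; with mu_diff = 0
  it is the selection-inflated type-I error rate)
* ``min_ci_width`` - the minimal CI width among the subset's *significant*
  methods (repetitions with no significant method contribute nothing)
* ``max_abs_d`` - the maximal |Cohen's d| over the subset

Subsets are drawn uniformly without replacement, fresh per repetition, as the
first k entries of a per-repetition permutation of the menu; for a fixed seed
this makes the subsets nested across k, so false-alarm estimates are exactly
non-decreasing in k on the shared datasets.  ``include_untreated=True``
forces the untreated analysis (method 1) into every subset, emulating the
workflow in which the raw analysis is always run first and k-1 alternative
treatments are explored afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._masked import apply_treatment_masked, subject_values
from .datagen import RngLike, sample_trial_arrays, spawn_rngs
from .specs import ContaminationSpec, DesignSpec, ExGaussianSpec
from .treatments import TreatmentSpec, standard_table1_menu

logger = logging.getLogger(__name__)

CRITERIA = ("power", "false_alarm", "min_ci_width", "max_abs_d")


@dataclass
class MultiverseEstimate:
    """Monte-Carlo estimate of one selection criterion at subset size k."""

    criterion: str
    subset_size_k: int
    n_reps: int
    estimate: float
    mc_se: float
    alpha: float
    n_degenerate: int = 0
    n_contributing: int | None = None


def _method_stats(
    rt: np.ndarray, specs: Sequence[TreatmentSpec], alpha: float, effect_size: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """p-value, CI width and |d| for each treatment applied to one dataset.

    Returns arrays aligned with ``specs``.  A method that leaves fewer than
    two complete subjects (or zero variance) gets p=1, width/|d|=NaN.
    """
    n_specs = len(specs)
    pvals = np.ones(n_specs)
    widths = np.full(n_specs, np.nan)
    absd = np.full(n_specs, np.nan)
    for j, spec in enumerate(specs):
        treated = apply_treatment_masked(rt, spec)
        v = subject_values(treated, spec.aggregation)
        ok = ~np.isnan(v).any(axis=1)
        v = v[ok]
        n = v.shape[0]
        if n < 2:
            continue
        d = v[:, 1] - v[:, 0]
        sd = d.std(ddof=1)
        if sd == 0:
            continue
        se = sd / np.sqrt(n)
        t_stat = d.mean() / se
        pvals[j] = 2.0 * stats.t.sf(abs(t_stat), n - 1)
        t_crit = stats.t.ppf(1.0 - alpha / 2.0, n - 1)
        widths[j] = 2.0 * t_crit * se
        if effect_size == "dz":
            absd[j] = abs(d.mean() / sd)
        else:
            pooled = np.sqrt((v[:, 0].var(ddof=1) + v[:, 1].var(ddof=1)) / 2.0)
            absd[j] = abs(v[:, 1].mean() - v[:, 0].mean()) / pooled if pooled else np.nan
    return pvals, widths, absd


def _rate_se(rate: float, n: int) -> float:
    return float(np.sqrt(rate * (1.0 - rate) / n))


def run_multiverse(
    design: DesignSpec,
    exg: ExGaussianSpec = ExGaussianSpec(),
    cont: ContaminationSpec = ContaminationSpec(),
    menu: Sequence[TreatmentSpec] | None = None,
    subset_size_k: int = 1,
    criterion: str = "false_alarm",
    alpha: float = 0.05,
    n_reps: int = 10_000,
    rng: RngLike | None = None,
    effect_size: str = "dz",
    include_untreated: bool = False,
) -> MultiverseEstimate:
    """Monte-Carlo estimate of one selection criterion.

    Per repetition: simulate a fresh experiment, draw a random subset of
    ``subset_size_k`` methods from ``menu`` (shared dataset across the
    subset's methods - that is the point), apply each, aggregate, test,
    and score the repetition per ``criterion``.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}")
    menu = tuple(menu) if menu is not None else standard_table1_menu()
    if not 1 <= subset_size_k <= len(menu):
        raise ValueError(f"subset_size_k must be in 1..{len(menu)}")
    scores: list[float] = []
    hits = 0
    n_degenerate = 0
    rep_seeds = spawn_rngs(rng, n_reps)
    for i, rep_ss in enumerate(rep_seeds):
        data_ss, choice_ss = rep_ss.spawn(2)
        choice_rng = np.random.default_rng(choice_ss)
        # regenerate on the (practically unreachable) fully degenerate draw
        usable = False
        for attempt_ss in [data_ss, *data_ss.spawn(4)]:
            rt, _ = sample_trial_arrays(
                design, exg, cont, np.random.default_rng(attempt_ss)
            )
            perm = choice_rng.permutation(len(menu))
            if include_untreated:
                perm = np.concatenate(([0], perm[perm != 0]))
            subset = [menu[j] for j in perm[:subset_size_k]]
            pvals, widths, absd = _method_stats(rt, subset, alpha, effect_size)
            if np.isnan(absd).all():
                n_degenerate += 1
                continue
            usable = True
            break
        if not usable:
            continue
        sig = pvals < alpha
        if criterion in ("power", "false_alarm"):
            hits += bool(sig.any())
        elif criterion == "min_ci_width":
            if sig.any():
                scores.append(float(np.nanmin(widths[sig])))
        else:  # max_abs_d
            scores.append(float(np.nanmax(absd)))
        if (i + 1) % 100 == 0:
            logger.debug(
                "multiverse %s k=%d: %d/%d reps (%d degenerate)",
                criterion, subset_size_k, i + 1, n_reps, n_degenerate,
            )
    if criterion in ("power", "false_alarm"):
        est = hits / n_reps
        return MultiverseEstimate(
            criterion, subset_size_k, n_reps, est, _rate_se(est, n_reps),
            alpha, n_degenerate,
        )
    arr = np.asarray(scores, dtype=float)
    est = float(arr.mean()) if arr.size else float("nan")
    se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else float("nan")
    return MultiverseEstimate(
        criterion, subset_size_k, n_reps, est, se, alpha, n_degenerate,
        n_contributing=int(arr.size),
    )


def power_curve(
    design: DesignSpec,
    exg: ExGaussianSpec = ExGaussianSpec(),
    cont_grid: Sequence[float] = (0.0, 0.05, 0.1, 0.15, 0.2),
    mode: str = "raw",
    alpha: float = 0.05,
    n_reps: int = 10_000,
    rng: RngLike | None = None,
    menu: Sequence[TreatmentSpec] | None = None,
    cont_bounds: tuple[float, float] = (0.0, 2000.0),
) -> pd.DataFrame:
    """Rejection rate as a function of the contamination proportion.

    mode='raw' analyzes the untreated data (method 1 only);
    mode='random_single_method' applies one method drawn uniformly from the
    menu in each repetition.  With mu_diff = 0 the "power" estimate is the
    plain type-I error rate.
    """
    if mode not in ("raw", "random_single_method"):
        raise ValueError("mode must be 'raw' or 'random_single_method'")
    menu = tuple(menu) if menu is not None else standard_table1_menu()
    rows = []
    grid_seeds = spawn_rngs(rng, len(cont_grid))
    for p, grid_ss in zip(cont_grid, grid_seeds):
        cont = ContaminationSpec(p=p, a=cont_bounds[0], b=cont_bounds[1])
        hits = 0
        for rep_ss in grid_ss.spawn(n_reps):
            data_ss, choice_ss = rep_ss.spawn(2)
            rt, _ = sample_trial_arrays(
                design, exg, cont, np.random.default_rng(data_ss)
            )
            if mode == "raw":
                subset = [menu[0]]
            else:
                j = int(np.random.default_rng(choice_ss).integers(len(menu)))
                subset = [menu[j]]
            pvals, _, _ = _method_stats(rt, subset, alpha, "dz")
            hits += bool((pvals < alpha).any())
        est = hits / n_reps
        rows.append(
            {
                "p_outlier": p,
                "mode": mode,
                "power": est,
                "mc_se": _rate_se(est, n_reps),
                "n_reps": n_reps,
            }
        )
    return pd.DataFrame(rows)
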