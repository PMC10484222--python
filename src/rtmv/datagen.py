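"""Synthetic within-subject RT experiments from the contaminated ex-Gaussian model.

Public surface
--------------
``sample_exgaussian``    draw i.i.d. ex-Gaussian values
``sample_trial_arrays``  the (n_subjects, 2, n_obs) array form used by the
                         simulation engines
``generate_dataset``     the long-format trial table (pandas DataFrame)
``spawn_rngs``           per-repetition independent substreams from one seed

Seeding contract: every stochastic entry point accepts either an integer
seed, a ``numpy.random.SeedSequence`` or a ``numpy.random.Generator``.
Identical seed + configuration gives a bit-identical trial table.
"""

from __future__ import annotations

from typing import Sequence, Union

import numpy as np
import pandas as pd

from .specs import ContaminationSpec, DesignSpec, ExGaussianSpec

RngLike = Union[int, np.random.SeedSequence, np.random.Generator]

TRIAL_COLUMNS = ["subject", "condition", "trial", "rt", "contaminated"]


def as_rng(rng: RngLike | None) -> np.random.Generator:
    """Coerce an int / SeedSequence / Generator into a Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def spawn_rngs(seed: RngLike | None, n: int) -> list[np.random.SeedSequence]:
    """Spawn ``n`` independent child seed sequences from one root seed.

    Repetition ``i`` of a Monte-Carlo study always receives child ``i``, so
    results are invariant to execution order (and to parallel scheduling).
    """
    if isinstance(seed, np.random.SeedSequence):
        root = seed
    elif isinstance(seed, np.random.Generator):
        # derive a fresh entropy value from the generator
        root = np.random.SeedSequence(int(seed.integers(0, 2**63)))
    else:
        root = np.random.SeedSequence(seed)
    return root.spawn(n)


def sample_exgaussian(
    spec: ExGaussianSpec, n: int, rng: RngLike | None = None
) -> np.ndarray:
    """Draw ``n`` i.i.d. ex-Gaussian response times (ms).

    Each value is N(mu, sigma) + Exp(mean=tau); the expectation is
    mu + tau and the variance sigma^2 + tau^2.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    g = as_rng(rng)
    return g.normal(spec.mu, spec.sigma, n) + g.exponential(spec.tau, n)


def sample_trial_arrays(
    design: DesignSpec,
    exg: ExGaussianSpec = ExGaussianSpec(),
    cont: ContaminationSpec = ContaminationSpec(),
    rng: RngLike | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one experiment as arrays of shape (n_subjects, 2, n_obs).

    Returns ``(rt, contaminated)``.  Axis 1 indexes the two conditions;
    condition 2 (index 1) has ``mu_diff`` added to its normal mean.  Each
    trial is independently contaminated with probability ``p`` by adding one
    U(a, b) draw; the boolean array flags exactly those trials.
    """
    g = as_rng(rng)
    shape = (design.n_subjects, 2, design.n_obs)
    rt = g.normal(exg.mu, exg.sigma, shape) + g.exponential(exg.tau, shape)
    rt[:, 1, :] += design.mu_diff
    flagged = g.random(shape) < cont.p
    noise = g.uniform(cont.a, cont.b, shape)
    rt = rt + flagged * noise
    return rt, flagged


def arrays_to_table(rt: np.ndarray, contaminated: np.ndarray) -> pd.DataFrame:
    """Convert (n_subjects, 2, n_obs) arrays to the long trial table."""
    n_subj, _, n_obs = rt.shape
    subject = np.repeat(np.arange(1, n_subj + 1), 2 * n_obs)
    condition = np.tile(np.repeat([1, 2], n_obs), n_subj)
    trial = np.tile(np.arange(1, n_obs + 1), 2 * n_subj)
    return pd.DataFrame(
        {
            "subject": subject,
            "condition": condition,
            "trial": trial,
            "rt": rt.ravel(),
            "contaminated": contaminated.ravel(),
        }
    )


def generate_dataset(
    design: DesignSpec,
    exg: ExGaussianSpec = ExGaussianSpec(),
    cont: ContaminationSpec = ContaminationSpec(),
    rng: RngLike | None = None,
) -> pd.DataFrame:
    """Simulate one balanced two-condition experiment as a long trial table.

    Columns: subject (1..n_subjects), condition (1 or 2), trial
    (1..n_obs), rt (ms), contaminated (bool).  The table has exactly
    n_subjects * 2 * n_obs rows.
    """
    rt, flagged = sample_trial_arrays(design, exg, cont, rng)
    return arrays_to_table(rt, flagged)


def expected_grand_mean(
    exg: ExGaussianSpec, cont: ContaminationSpec, mu_diff: float = 0.0
) -> float:
    """Analytic grand mean: mu + tau + p*(a+b)/2 (+ mu_diff/2 across conditions)."""
    return exg.mean + cont.mean_shift + mu_diff / 2.0


def two_group_arrays(
    design: DesignSpec,
    exg: ExGaussianSpec = ExGaussianSpec(),
    cont: ContaminationSpec = ContaminationSpec(),
    rng: RngLike | None = None,
    subject_aggregated: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one experiment and return (condition-2, condition-1) samples.

    By default the two groups are the raw trial RTs pooled across subjects
    (n_subjects * n_obs values each), which is the input expected by the
    two-group Bayesian models.  With ``subject_aggregated=True`` the groups
    are the per-subject condition means instead.
    """
    rt, _ = sample_trial_arrays(design, exg, cont, rng)
    if subject_aggregated:
        means = rt.mean(axis=2)
        return means[:, 1], means[:, 0]
    return rt[:, 1, :].ravel(), rt[:, 0, :].ravel()
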