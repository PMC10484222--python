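"""Subject-level aggregation, the paired t-test, and effect sizes.

This is the frequentist analysis pipeline applied to every simulated (or
user-supplied) experiment: aggregate each subject's retained trials per
condition (mean, or median when the treatment says so), then run a two-sided
paired Student's t-test on the per-subject condition differences, with a
(1 - alpha) confidence interval for the mean difference and Cohen's d.

``PairedRTModel`` wraps the pipeline in a model/results pair: build the model
from a trial table, ``fit()`` it (optionally through an outlier treatment)
and read the estimates off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .treatments import TreatmentResult, TreatmentSpec, apply_treatment


class DegenerateDesignError(ValueError):
    """Fewer than two subjects survive treatment; the analysis is undefined."""


class DegenerateStatisticsError(ValueError):
    """A required variance is zero (identical differences or summaries)."""


@dataclass
class FreqResult:
    """Outcome of one paired t-test, with data-loss bookkeeping."""

    t_stat: float
    df: int
    p_value: float
    ci_low: float
    ci_high: float
    cohens_d: float
    n_subjects_used: int
    prop_removed: float = 0.0
    alpha: float = 0.05
    mean_diff: float = 0.0

    @property
    def ci_width(self) -> float:
        return self.ci_high - self.ci_low

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def aggregate_by_subject(
    result: TreatmentResult | pd.DataFrame, aggregation: str | None = None
) -> pd.DataFrame:
    """Per-subject condition aggregates of a (treated) trial table.

    Returns a DataFrame with columns subject, value_c1, value_c2, diff
    (diff = value_c2 - value_c1).  Subjects left without any retained trial
    in one of the conditions are dropped.
    """
    if isinstance(result, TreatmentResult):
        table = result.table
        aggregation = aggregation or result.aggregation
    else:
        table = result
        aggregation = aggregation or "mean"
    agg_fn = "median" if aggregation == "median" else "mean"
    wide = (
        table.groupby(["subject", "condition"], sort=True)["rt"]
        .agg(agg_fn)
        .unstack("condition")
    )
    for cond in (1, 2):
        if cond not in wide.columns:
            wide[cond] = np.nan
    wide = wide.dropna(subset=[1, 2])
    out = pd.DataFrame(
        {
            "subject": wide.index.to_numpy(),
            "value_c1": wide[1].to_numpy(dtype=float),
            "value_c2": wide[2].to_numpy(dtype=float),
        }
    )
    out["diff"] = out["value_c2"] - out["value_c1"]
    if len(out) < 2:
        raise DegenerateDesignError(
            f"only {len(out)} subject(s) have data in both conditions"
        )
    return out


def paired_t_from_diffs(diffs: np.ndarray, alpha: float = 0.05) -> tuple:
    """Closed-form one-sample t-test on the condition differences.

    Returns (t, df, p, ci_low, ci_high, mean_diff).
    """
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.size
    if n < 2:
        raise DegenerateDesignError("need at least 2 paired differences")
    mean = diffs.mean()
    sd = diffs.std(ddof=1)
    if sd == 0:
        raise DegenerateStatisticsError("zero variance of paired differences")
    se = sd / np.sqrt(n)
    t_stat = mean / se
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t_stat), df)
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return t_stat, df, p, mean - t_crit * se, mean + t_crit * se, mean


def cohens_d(summaries: pd.DataFrame, kind: str = "pooled") -> float:
    """Standardized mean difference between the two conditions.

    kind='pooled': (mean_c2 - mean_c1) / pooled sample SD of the two sets of
    subject aggregates (classic two-group Cohen's d).
    kind='dz': mean of the paired differences divided by their SD (the paired
    form; equals t / sqrt(n)).
    """
    if len(summaries) < 2:
        raise DegenerateDesignError("need at least 2 subjects for an effect size")
    c1 = summaries["value_c1"].to_numpy(dtype=float)
    c2 = summaries["value_c2"].to_numpy(dtype=float)
    if kind == "dz":
        d = c2 - c1
        sd = d.std(ddof=1)
        if sd == 0:
            raise DegenerateStatisticsError("zero variance of paired differences")
        return float(d.mean() / sd)
    if kind != "pooled":
        raise ValueError("kind must be 'pooled' or 'dz'")
    pooled = np.sqrt((c1.var(ddof=1) + c2.var(ddof=1)) / 2.0)
    if pooled == 0:
        raise DegenerateStatisticsError("zero pooled SD of subject aggregates")
    return float((c2.mean() - c1.mean()) / pooled)


def paired_t(
    summaries: pd.DataFrame,
    alpha: float = 0.05,
    prop_removed: float = 0.0,
    effect_size: str = "pooled",
) -> FreqResult:
    """Two-sided paired Student's t-test on subject summaries."""
    t_stat, df, p, lo, hi, mean = paired_t_from_diffs(
        summaries["diff"].to_numpy(dtype=float), alpha=alpha
    )
    return FreqResult(
        t_stat=float(t_stat),
        df=int(df),
        p_value=float(p),
        ci_low=float(lo),
        ci_high=float(hi),
        cohens_d=cohens_d(summaries, kind=effect_size),
        n_subjects_used=len(summaries),
        prop_removed=prop_removed,
        alpha=alpha,
        mean_diff=float(mean),
    )


class PairedRTModel:
    """Paired two-condition RT analysis on a long trial table.

    Parameters
    ----------
    table
        Long-format trials with columns subject, condition (1/2), trial, rt.
    alpha
        Two-sided significance level (default 0.05).
    effect_size
        'pooled' (classic Cohen's d on the two sets of subject aggregates)
        or 'dz' (paired standardized difference).
    """

    def __init__(
        self, table: pd.DataFrame, alpha: float = 0.05, effect_size: str = "pooled"
    ):
        missing = {"subject", "condition", "rt"} - set(table.columns)
        if missing:
            raise ValueError(f"trial table missing columns: {sorted(missing)}")
        self.table = table
        self.alpha = alpha
        self.effect_size = effect_size

    @classmethod
    def from_csv(cls, path, **kwargs) -> "PairedRTModel":
        from .runner import read_trial_csv

        return cls(read_trial_csv(path), **kwargs)

    def fit(self, treatment: TreatmentSpec | None = None) -> "PairedRTResults":
        """Run the pipeline, optionally through an outlier treatment."""
        if treatment is None:
            treated = TreatmentResult(
                table=self.table, n_removed=0, prop_removed=0.0, aggregation="mean"
            )
        else:
            treated = apply_treatment(self.table, treatment)
        summaries = aggregate_by_subject(treated)
        res = paired_t(
            summaries,
            alpha=self.alpha,
            prop_removed=treated.prop_removed,
            effect_size=self.effect_size,
        )
        flipped = treatment is not None and treatment.transform_fn == "inverse"
        return PairedRTResults(
            model=self,
            treatment=treatment,
            summaries=summaries,
            result=res,
            direction_flipped=flipped,
        )


@dataclass
class PairedRTResults:
    """Fitted paired analysis: estimates, uncertainty and bookkeeping.

    ``direction_flipped`` is True when the treatment was the inverse
    transform (1/rt), which reverses the order of the conditions: the
    reported sign of t / d then refers to the transformed scale.
    """

    model: PairedRTModel
    treatment: TreatmentSpec | None
    summaries: pd.DataFrame
    result: FreqResult
    direction_flipped: bool = False

    def __getattr__(self, name):
        # delegate estimate fields to the FreqResult
        try:
            return getattr(self.__dict__["result"], name)
        except KeyError:  # pragma: no cover - during unpickling
            raise AttributeError(name)

    def summary(self) -> str:
        r = self.result
        label = self.treatment.label if self.treatment is not None else "raw data"
        lines = [
            "Paired RT analysis",
            "==================",
            f"treatment:        {label}",
            f"subjects used:    {r.n_subjects_used}",
            f"trials removed:   {r.prop_removed:.2%}",
            f"mean difference:  {r.mean_diff:.3f} ms",
            f"t({r.df}) = {r.t_stat:.4f}, two-sided p = {r.p_value:.4g}",
            f"{100 * (1 - r.alpha):.0f}% CI: [{r.ci_low:.3f}, {r.ci_high:.3f}]"
            f" (width {r.ci_width:.3f})",
            f"Cohen's d ({self.model.effect_size}): {r.cohens_d:.4f}",
        ]
        if self.direction_flipped:
            lines.append(
                "note: inverse transform reverses condition order; the sign of"
                " t and d is on the 1/rt scale"
            )
        return "\n".join(lines)
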