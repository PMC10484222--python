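"""The 20-method outlier-treatment menu and its application to trial tables.

Four families:

* ``ignore``    leave the data as they are (analysis on subject means)
* ``median``    leave the data as they are, aggregate subjects by median
* ``transform`` replace rt elementwise by log(rt) or 1/rt
* ``truncate``  drop trials outside a window, either mean +/- k*SD within a
  scope (whole experiment / one subject / one subject-condition cell) or a
  fixed [low, high] cutoff pair

Truncation conventions (fixed for reproducibility): thresholds use the sample
standard deviation (n-1 denominator) of the untreated values in the stated
scope, computed once (no iterative re-trimming); boundary values are kept
(a trial is removed iff rt < center - k*SD or rt > center + k*SD, strictly).

The ``condition`` scope computes the mean and SD within each subject-by-
condition cell.  A pooled-across-subjects per-condition variant is available
as scope ``condition_pooled``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

FAMILIES = ("ignore", "median", "transform", "truncate")
TRANSFORMS = ("log", "inverse")
SCOPES = ("experiment", "subject", "condition", "condition_pooled")


class TreatmentDomainError(ValueError):
    """Raised when a transform is applied to non-positive response times."""


@dataclass(frozen=True)
class TreatmentSpec:
    """One fully parameterized outlier-treatment method.

    Exactly the fields required by the family are set; the rest are None.
    ``aggregation`` tells the downstream subject-level step whether to use
    the mean or the median of each subject's retained trials.
    """

    id: int
    family: str
    transform_fn: str | None = None
    sd_multiplier: float | None = None
    scope: str | None = None
    low_cutoff: float | None = None
    high_cutoff: float | None = None
    aggregation: str = "mean"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "transform" and self.transform_fn not in TRANSFORMS:
            raise ValueError(f"transform_fn must be one of {TRANSFORMS}")
        if self.family == "truncate":
            sd_based = self.sd_multiplier is not None
            fixed = self.low_cutoff is not None or self.high_cutoff is not None
            if sd_based == fixed:
                raise ValueError(
                    "truncate family needs either sd_multiplier+scope "
                    "or low_cutoff+high_cutoff, not both"
                )
            if sd_based and self.scope not in SCOPES:
                raise ValueError(f"scope must be one of {SCOPES}")
        if self.aggregation not in ("mean", "median"):
            raise ValueError("aggregation must be 'mean' or 'median'")

    @property
    def label(self) -> str:
        if self.family == "ignore":
            return "raw data"
        if self.family == "median":
            return "median aggregation"
        if self.family == "transform":
            return f"{self.transform_fn} transform"
        if self.sd_multiplier is not None:
            return f"{self.scope} mean +/- {self.sd_multiplier} SD"
        return f"keep [{self.low_cutoff:g}, {self.high_cutoff:g}] ms"


@dataclass
class TreatmentResult:
    """A treated trial table plus data-loss bookkeeping."""

    table: pd.DataFrame
    n_removed: int
    prop_removed: float
    aggregation: str
    spec: TreatmentSpec | None = None


def standard_table1_menu() -> tuple[TreatmentSpec, ...]:
    """The canonical 20-method menu, in order.

    1 ignore; 2 median aggregation; 3 log transform; 4 inverse transform;
    5-7 experiment-scope SD truncation (k = 2, 2.5, 3); 8-11 subject-scope
    (k = 1.5, 2, 2.5, 3); 12-14 condition-scope (k = 2, 2.5, 3); 15-20 fixed
    cutoffs, keep 100 <= rt <= high for high in
    {800, 1000, 1200, 1500, 1750, 2000}.
    """
    menu: list[TreatmentSpec] = [
        TreatmentSpec(1, "ignore"),
        TreatmentSpec(2, "median", aggregation="median"),
        TreatmentSpec(3, "transform", transform_fn="log"),
        TreatmentSpec(4, "transform", transform_fn="inverse"),
    ]
    next_id = 5
    for k in (2.0, 2.5, 3.0):
        menu.append(TreatmentSpec(next_id, "truncate", sd_multiplier=k, scope="experiment"))
        next_id += 1
    for k in (1.5, 2.0, 2.5, 3.0):
        menu.append(TreatmentSpec(next_id, "truncate", sd_multiplier=k, scope="subject"))
        next_id += 1
    for k in (2.0, 2.5, 3.0):
        menu.append(TreatmentSpec(next_id, "truncate", sd_multiplier=k, scope="condition"))
        next_id += 1
    for high in (800.0, 1000.0, 1200.0, 1500.0, 1750.0, 2000.0):
        menu.append(
            TreatmentSpec(next_id, "truncate", low_cutoff=100.0, high_cutoff=high)
        )
        next_id += 1
    return tuple(menu)


def _truncation_keep_mask(table: pd.DataFrame, spec: TreatmentSpec) -> np.ndarray:
    rt = table["rt"].to_numpy(dtype=float)
    if spec.sd_multiplier is None:
        return (rt >= spec.low_cutoff) & (rt <= spec.high_cutoff)
    k = spec.sd_multiplier
    if spec.scope == "experiment":
        center = rt.mean()
        spread = rt.std(ddof=1)
        lo, hi = center - k * spread, center + k * spread
        return (rt >= lo) & (rt <= hi)
    if spec.scope == "subject":
        grouper = [table["subject"]]
    elif spec.scope == "condition":
        grouper = [table["subject"], table["condition"]]
    else:  # condition_pooled
        grouper = [table["condition"]]
    g = table.groupby(grouper, sort=False)["rt"]
    center = g.transform("mean").to_numpy()
    spread = g.transform("std").to_numpy()  # ddof=1
    # a scope with a single trial has undefined SD; keep the trial
    spread = np.where(np.isnan(spread), np.inf, spread)
    return (rt >= center - k * spread) & (rt <= center + k * spread)


def apply_treatment(table: pd.DataFrame, spec: TreatmentSpec) -> TreatmentResult:
    """Apply one treatment to a long trial table.

    ignore/median return the table unchanged (they differ only in the
    aggregation directive); transform replaces rt elementwise and preserves
    the row count; truncate drops rows outside the window.
    """
    if len(table) == 0:
        raise ValueError("cannot treat an empty trial table")
    n_in = len(table)
    if spec.family in ("ignore", "median"):
        out = table.copy()
        n_removed = 0
    elif spec.family == "transform":
        rt = table["rt"].to_numpy(dtype=float)
        if np.any(rt <= 0):
            raise TreatmentDomainError(
                f"{spec.transform_fn} transform requires rt > 0"
            )
        out = table.copy()
        out["rt"] = np.log(rt) if spec.transform_fn == "log" else 1.0 / rt
        n_removed = 0
    else:
        keep = _truncation_keep_mask(table, spec)
        out = table.loc[keep].copy()
        n_removed = int(n_in - len(out))
    return TreatmentResult(
        table=out,
        n_removed=n_removed,
        prop_removed=n_removed / n_in,
        aggregation=spec.aggregation,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# menu (de)serialization and id selection


def menu_to_json(menu: Iterable[TreatmentSpec]) -> str:
    return json.dumps([asdict(s) for s in menu], indent=2)


def menu_from_json(text: str) -> tuple[TreatmentSpec, ...]:
    return tuple(TreatmentSpec(**d) for d in json.loads(text))


def parse_method_selection(expr: str) -> tuple[int, ...]:
    """Parse a method-id selection like ``"1,3,5-20"`` into sorted unique ids."""
    ids: set[int] = set()
    for part in expr.split(","):
        part = part.strip()
        if not part:
            continue
        if "-" in part:
            lo, hi = part.split("-", 1)
            ids.update(range(int(lo), int(hi) + 1))
        else:
            ids.add(int(part))
    return tuple(sorted(ids))


def select_methods(
    menu: Sequence[TreatmentSpec], ids: Iterable[int]
) -> tuple[TreatmentSpec, ...]:
    by_id = {s.id: s for s in menu}
    try:
        return tuple(by_id[i] for i in ids)
    except KeyError as err:
        raise KeyError(f"method id {err.args[0]} not in menu") from None
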