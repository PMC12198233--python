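"""Cohort preprocessing: complete cases, 1–5 rescaling, grouping, balancing.

The outcome grouping follows the three-band convention used throughout the
analysis: children scoring at or below mean − 0.5·SD of the wave-2
conduct-problems score are *low*, at or above mean + 0.5·SD *high*, and
*medium* in between.  The cuts are computed once on the analysis sample
(after complete-case filtering) and then frozen, so that the same bands
classify model predictions later.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GROUP_ORDER",
    "FilterReport",
    "RescaleMap",
    "GroupLabeling",
    "PreprocessError",
    "filter_complete_cases",
    "rescale_variable",
    "assign_outcome_groups",
    "balance_training_set",
]

GROUP_ORDER = ("low", "medium", "high")


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class FilterReport:
    n_in: int
    n_retained: int
    n_discarded: int


def filter_complete_cases(
    table: pd.DataFrame, required: list[str]
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop rows missing any required variable; row order is preserved."""
    unknown = [c for c in required if c not in table.columns]
    if unknown:
        raise PreprocessError(f"unknown variable(s) in required list: {unknown}")
    kept = table.dropna(subset=list(required))
    report = FilterReport(
        n_in=len(table), n_retained=len(kept), n_discarded=len(table) - len(kept)
    )
    return kept.copy(), report


@dataclass(frozen=True)
class RescaleMap:
    """Affine map from an instrument's native range onto the common [1, 5] scale."""

    source_min: float
    source_max: float

    def __post_init__(self):
        if not self.source_min < self.source_max:
            raise PreprocessError(
                f"source_min must be below source_max, got "
                f"[{self.source_min}, {self.source_max}]"
            )

    def apply(self, values) -> np.ndarray:
        x = np.asarray(values, dtype=float)
        return 1.0 + 4.0 * (x - self.source_min) / (self.source_max - self.source_min)

    def invert(self, values) -> np.ndarray:
        y = np.asarray(values, dtype=float)
        return self.source_min + (y - 1.0) * (self.source_max - self.source_min) / 4.0


def rescale_variable(values, rmap: RescaleMap) -> np.ndarray:
    """Map values onto [1, 5]; being affine, it leaves correlations untouched."""
    x = np.asarray(values, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (x < rmap.source_min) | (x > rmap.source_max)
    if bad.any():
        idx = np.nonzero(bad)[0][:10]
        raise PreprocessError(
            f"values outside [{rmap.source_min}, {rmap.source_max}] "
            f"at rows {idx.tolist()}"
        )
    return rmap.apply(x)


@dataclass(frozen=True)
class GroupLabeling:
    """A frozen low/medium/high partition of an outcome distribution.

    ``labels`` covers the sample the cuts were derived from; ``classify``
    applies the same cuts (low: x ≤ mean − 0.5·SD, high: x ≥ mean + 0.5·SD)
    to any score vector, e.g. model predictions.
    """

    mean: float
    sd: float
    low_cut: float
    high_cut: float
    labels: tuple[str, ...]

    def classify(self, scores) -> np.ndarray:
        # boundary values are inclusive; the epsilon keeps scores stated at
        # printed precision (e.g. mean + 0.5*sd typed as 1.565) on the
        # inclusive side of a float-accumulated cut
        eps = 1e-9 * max(1.0, abs(self.low_cut), abs(self.high_cut))
        x = np.asarray(scores, dtype=float)
        out = np.full(x.shape, "medium", dtype=object)
        out[x <= self.low_cut + eps] = "low"
        out[x >= self.high_cut - eps] = "high"
        return out.astype(str)

    def counts(self) -> dict[str, int]:
        lab = np.asarray(self.labels)
        return {g: int((lab == g).sum()) for g in GROUP_ORDER}


def assign_outcome_groups(outcome_values) -> GroupLabeling:
    """Derive the ±0.5 SD three-group labeling from an outcome sample."""
    x = np.asarray(outcome_values, dtype=float)
    if np.isnan(x).any():
        raise PreprocessError("outcome contains missing values; filter first")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0 or len(np.unique(x)) < 2:
        raise PreprocessError("degenerate outcome distribution (zero SD)")
    low_cut = mean - 0.5 * sd
    high_cut = mean + 0.5 * sd
    labeling = GroupLabeling(
        mean=mean, sd=sd, low_cut=low_cut, high_cut=high_cut, labels=()
    )
    labels = tuple(labeling.classify(x))
    return GroupLabeling(
        mean=mean, sd=sd, low_cut=low_cut, high_cut=high_cut, labels=labels
    )


def balance_training_set(
    table: pd.DataFrame, labels, seed: int
) -> pd.DataFrame:
    """Undersample the two larger outcome groups to the minority-group size.

    ``labels`` is positionally aligned with ``table`` (a GroupLabeling's
    ``labels`` or any sequence of low/medium/high strings).  Sampling is
    without replacement, deterministic given the seed, and never fabricates
    rows; already-balanced inputs pass through with the same row multiset.
    """
    if isinstance(labels, GroupLabeling):
        labels = labels.labels
    lab = np.asarray(labels, dtype=str)
    if len(lab) != len(table):
        raise PreprocessError("labels and table lengths differ")
    sizes = {g: int((lab == g).sum()) for g in GROUP_ORDER}
    empty = [g for g, c in sizes.items() if c == 0]
    if empty:
        raise PreprocessError(f"cannot balance: empty group(s) {empty}")
    m = min(sizes.values())
    rng = np.random.default_rng(seed)
    take: list[int] = []
    for g in GROUP_ORDER:
        pos = np.nonzero(lab == g)[0]
        if len(pos) > m:
            pos = np.sort(rng.choice(pos, size=m, replace=False))
        take.extend(pos.tolist())
    take = sorted(take)
    return table.iloc[take].copy()
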