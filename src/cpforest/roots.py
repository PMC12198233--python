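"""Path-prefix ("root") mining and harmonic-mean quality ranking.

A *root* is the ordered prefix of the first N steps of a high-outcome
decision path.  Merging paths by their root collapses the forest's many
high paths into prototypical predictor combinations.  Roots are ranked by
the quality score

    P = precision / max(precision over qualifying roots)
    C = count / max(count over qualifying roots)
    M = 2·P·C / (P + C)

i.e. the harmonic mean of max-normalized precision and support, after two
qualification filters: a root must reach at least ``min_count`` path
occurrences and a precision no lower than the model's global precision for
the same case.  M = 1 identifies a root that is simultaneously the most
precise and the most frequent of its case.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .forest import CanonicalPath, PathStep, signature_of

__all__ = [
    "RootRecord",
    "QualificationRule",
    "NormalizationContext",
    "RootAnalysisError",
    "extract_roots",
    "select_root_length",
    "qualify_roots",
    "compute_m",
    "rank_best_roots",
    "solve_normalization_maxima",
    "derive_normalization",
    "root_table",
    "round_half_up",
]


class RootAnalysisError(ValueError):
    pass


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal rounding with ties away from zero, as printed reports use."""
    scale = 10.0 ** ndigits
    return float(np.floor(abs(x) * scale + 0.5) / scale * np.sign(x))


@dataclass(frozen=True)
class RootRecord:
    """An N-step path prefix with the statistics of its member paths."""

    steps: tuple[PathStep, ...]  # averaged thresholds
    count: int  # summed path occurrences
    avg_length: float
    avg_leaf_samples: float
    precision: float | None  # in [0, 1]
    m_score: float | None = None

    @property
    def signature(self):
        return signature_of(self.steps)

    @property
    def n_nodes(self) -> int:
        return len(self.steps)


def extract_roots(
    paths: list[CanonicalPath], n_nodes: int, weighted: bool = True
) -> tuple[list[RootRecord], int]:
    """Group canonical paths by their first-N (variable, direction) signature.

    Per group, ``count`` sums the member paths' occurrence counts, and the
    averages (length, leaf samples, precision, per-step thresholds) are
    occurrence-weighted means by default (``weighted=False`` gives plain
    means over member paths).  Paths shorter than N are excluded; their
    number is returned alongside.  Output sorted by count descending, ties
    by signature.
    """
    if not (1 <= n_nodes <= 6):
        raise RootAnalysisError(f"root length must lie in 1..6, got {n_nodes}")
    groups: dict[tuple, list[CanonicalPath]] = {}
    n_excluded = 0
    for p in paths:
        if p.length < n_nodes:
            n_excluded += 1
            continue
        groups.setdefault(signature_of(p.steps[:n_nodes]), []).append(p)
    records = []
    for sig, members in groups.items():
        w = np.array(
            [m.occurrence_count if weighted else 1 for m in members], dtype=float
        )
        thr = np.array([[s.threshold for s in m.steps[:n_nodes]] for m in members])
        avg_thr = (w[:, None] * thr).sum(axis=0) / w.sum()
        steps = tuple(
            PathStep(variable=v, direction=d, threshold=float(t))
            for (v, d), t in zip(sig, avg_thr)
        )
        prec_pairs = [
            (m.precision_high, wi)
            for m, wi in zip(members, w)
            if m.precision_high is not None
        ]
        if prec_pairs:
            pv = np.array([p_ for p_, _ in prec_pairs])
            pw = np.array([w_ for _, w_ in prec_pairs])
            precision = float((pv * pw).sum() / pw.sum())
        else:
            precision = None
        records.append(
            RootRecord(
                steps=steps,
                count=int(sum(m.occurrence_count for m in members)),
                avg_length=float(
                    (w * np.array([m.length for m in members])).sum() / w.sum()
                ),
                avg_leaf_samples=float(
                    (w * np.array([m.avg_leaf_samples for m in members])).sum() / w.sum()
                ),
                precision=precision,
            )
        )
    records.sort(key=lambda r: (-r.count, r.signature))
    return records, n_excluded


def select_root_length(
    paths: list[CanonicalPath],
    min_count: int = 10,
    min_roots: int = 5,
    max_n: int = 6,
) -> tuple[int, dict[int, int]]:
    """Largest N in 1..max_n yielding at least ``min_roots`` roots with
    count >= ``min_count``; falls back to N=1 when no N qualifies.

    Also returns the qualifying-root-count profile over every candidate N.
    """
    if not paths:
        raise RootAnalysisError("no paths supplied")
    profile: dict[int, int] = {}
    chosen = None
    for n in range(1, max_n + 1):
        roots, _ = extract_roots(paths, n)
        n_ok = sum(1 for r in roots if r.count >= min_count)
        profile[n] = n_ok
        if n_ok >= min_roots:
            chosen = n
    if chosen is None:
        chosen = 1
    return chosen, profile


@dataclass(frozen=True)
class QualificationRule:
    """Conjunctive eligibility filters for the M ranking."""

    min_count: int = 10
    min_precision: float = 0.0  # the model's global precision for the case


def qualify_roots(
    roots: list[RootRecord], rule: QualificationRule
) -> tuple[list[RootRecord], list[RootRecord]]:
    """Split roots into (qualifying, near-misses).

    Qualifying: count >= min_count AND precision >= min_precision (both
    boundaries inclusive).  Near-misses fail exactly one rule — surfaced so
    borderline roots are never silently lost.
    """
    qualifying, near = [], []
    for r in roots:
        if r.precision is None:
            continue
        ok_count = r.count >= rule.min_count
        ok_prec = r.precision >= rule.min_precision
        if ok_count and ok_prec:
            qualifying.append(r)
        elif ok_count or ok_prec:
            near.append(r)
    return qualifying, near


@dataclass(frozen=True)
class NormalizationContext:
    """Maxima of the qualifying set, the denominators of P and C."""

    max_precision: float
    max_count: int

    def __post_init__(self):
        if not (self.max_precision > 0 and self.max_count > 0):
            raise RootAnalysisError("normalization maxima must be positive")

    @classmethod
    def from_roots(cls, qualifying: list[RootRecord]) -> "NormalizationContext":
        if not qualifying:
            raise RootAnalysisError("empty qualifying set")
        return cls(
            max_precision=max(r.precision for r in qualifying),
            max_count=max(r.count for r in qualifying),
        )


def compute_m(precision: float, count: float, ctx: NormalizationContext) -> float:
    """Harmonic mean of max-normalized precision and count."""
    p = precision / ctx.max_precision
    c = count / ctx.max_count
    if p <= 0 or c <= 0:
        raise RootAnalysisError("M undefined for non-positive precision or count")
    return 2.0 * p * c / (p + c)


def rank_best_roots(
    roots: list[RootRecord],
    rule: QualificationRule,
    top_k: int = 5,
) -> list[RootRecord]:
    """Qualify, normalize, score and rank; returns the top_k roots with M.

    Sorted by M descending, ties by count descending then precision
    descending.  An empty qualifying set yields an empty ranking.
    """
    qualifying, _ = qualify_roots(roots, rule)
    if not qualifying:
        return []
    ctx = NormalizationContext.from_roots(qualifying)
    scored = [
        replace(r, m_score=compute_m(r.precision, r.count, ctx)) for r in qualifying
    ]
    scored.sort(key=lambda r: (-r.m_score, -r.count, -r.precision))
    return scored[:top_k]


def solve_normalization_maxima(
    rows: list[tuple[float, int, float]],
    max_count_cap: int = 250,
    precision_step: float = 0.01,
) -> list[tuple[float, int]]:
    """Brute-force solve for (max_precision, max_count) from printed rows.

    ``rows`` are (precision in percent, count, M rounded to 2 d.p.) triples.
    A candidate pair is admissible when recomputing M for every row with
    that normalization reproduces every printed M after 2-d.p. rounding.
    Candidates scan counts from the largest printed count up to the cap and
    precisions from the largest printed precision up to 100%.
    """
    if not rows:
        raise RootAnalysisError("no rows supplied")
    pmax_seen = max(r[0] for r in rows)
    cmax_seen = max(r[1] for r in rows)
    admissible = []
    prec_grid = np.arange(pmax_seen, 100.0 + precision_step / 2, precision_step)
    for max_c in range(cmax_seen, max_count_cap + 1):
        for max_p in prec_grid:
            ctx = NormalizationContext(max_precision=float(max_p), max_count=max_c)
            if all(
                abs(round_half_up(compute_m(p, c, ctx)) - m) < 1e-9
                for p, c, m in rows
            ):
                admissible.append((float(round(max_p, 6)), max_c))
    return admissible


def derive_normalization(
    rows: list[tuple[float, int, float]], **kwargs
) -> NormalizationContext:
    """Canonical pick among admissible pairs: smallest max_count, then the
    largest max_precision (a 100%-precision root is the natural ceiling)."""
    admissible = solve_normalization_maxima(rows, **kwargs)
    if not admissible:
        raise RootAnalysisError("no admissible normalization maxima found")
    best = min(admissible, key=lambda pc: (pc[1], -pc[0]))
    return NormalizationContext(max_precision=best[0], max_count=best[1])


def root_table(roots: list[RootRecord], n_nodes: int | None = None) -> pd.DataFrame:
    """Report table in the study layout: node columns (case-rendered name,
    rounded threshold), then Avg. length / Count / Avg. leaf samples /
    Precision (percent) and M when scored."""
    if n_nodes is None:
        n_nodes = max((r.n_nodes for r in roots), default=0)
    rows = []
    for r in roots:
        row: dict[str, object] = {}
        for j in range(n_nodes):
            if j < r.n_nodes:
                row[f"Node {j}"] = r.steps[j].render()
                row[f"Thr {j}"] = round_half_up(r.steps[j].threshold)
            else:
                row[f"Node {j}"] = ""
                row[f"Thr {j}"] = ""
        row["Avg. length"] = round_half_up(r.avg_length)
        row["Count"] = r.count
        row["Avg. leaf samples"] = round_half_up(r.avg_leaf_samples)
        row["Precision"] = (
            f"{round_half_up(100 * r.precision):.2f}%" if r.precision is not None else "n/a"
        )
        if r.m_score is not None:
            row["M"] = round_half_up(r.m_score)
        rows.append(row)
    return pd.DataFrame(rows)
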