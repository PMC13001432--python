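"""Endpoint-relevance ranking of bioassays by Bayesian-smoothed active rates.

For each assay i with Active_i actives and Inactive_i inactives among the
profiled chemicals, the raw active rate is Active_i / (Active_i + Inactive_i).
Raw rates on small denominators are unstable, so each is shrunk toward the
pooled rate mu = sum(Active_i) / sum(Active_i + Inactive_i) via

    adjusted_score_i = (Active_i + k * mu) / (Active_i + Inactive_i + k)

with smoothing weight k = 100 by default: the score behaves like a posterior
mean under a pseudo-count prior of k observations at rate mu, approaching the
raw rate as evidence accumulates and mu in its absence. Assays are ranked by
adjusted score and the top entries (default 500) reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .store import AssayOutcomeCounts

__all__ = [
    "SmoothingConfig",
    "RelevanceTable",
    "active_rate",
    "global_mean_rate",
    "adjusted_score",
    "rank_relevant_assays",
    "counts_from_bioprofile",
]

DEFAULT_K = 100.0
DEFAULT_TOP = 500


@dataclass(frozen=True)
class SmoothingConfig:
    """Bayesian smoothing weight (pseudo-count mass pulled toward mu)."""

    k: float = DEFAULT_K

    def __post_init__(self):
        if not self.k > 0:
            raise ValueError("smoothing parameter k must be positive")


@dataclass
class RelevanceTable:
    """Ranked assay relevance scores with the pooled rate they shrink toward."""

    scores: pd.DataFrame  # columns: aid, active, inactive, inconclusive, active_rate, adjusted_score, rank
    mu: float
    n_assays: int

    def to_csv(self, path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.scores.to_csv(fh, index=False)


def active_rate(c: AssayOutcomeCounts) -> float | None:
    """Raw per-assay active rate; None (undefined) when no active/inactive calls exist."""
    denom = c.active + c.inactive
    if denom == 0:
        return None
    return c.active / denom


def global_mean_rate(counts: Sequence[AssayOutcomeCounts]) -> float:
    """Pooled active rate mu: ratio of summed actives to summed (active+inactive).

    Assays with no active/inactive calls contribute nothing to either sum.
    """
    num = sum(c.active for c in counts)
    den = sum(c.active + c.inactive for c in counts)
    if den == 0:
        raise ValueError("mu undefined: no assay has any active or inactive calls")
    return num / den


def adjusted_score(
    c: AssayOutcomeCounts, mu: float, cfg: SmoothingConfig = SmoothingConfig()
) -> float:
    """Bayesian adjusted score (Active + k*mu) / (Active + Inactive + k)."""
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must lie in [0, 1]")
    return (c.active + cfg.k * mu) / (c.active + c.inactive + cfg.k)


def rank_relevant_assays(
    counts: Sequence[AssayOutcomeCounts],
    cfg: SmoothingConfig = SmoothingConfig(),
    top: int = DEFAULT_TOP,
) -> RelevanceTable:
    """Rank assays by adjusted score, descending; ties broken by ascending aid.

    The table is truncated to ``top`` rows. Inconclusive counts are carried
    for transparency but enter no formula.
    """
    if not counts:
        warnings.warn("empty counts: returning an empty relevance table")
        empty = pd.DataFrame(
            columns=["aid", "active", "inactive", "inconclusive",
                     "active_rate", "adjusted_score", "rank"]
        )
        return RelevanceTable(empty, mu=math.nan, n_assays=0)
    mu = global_mean_rate(counts)
    rows = []
    for c in counts:
        rate = active_rate(c)
        rows.append(
            {
                "aid": c.aid,
                "active": c.active,
                "inactive": c.inactive,
                "inconclusive": c.inconclusive,
                "active_rate": math.nan if rate is None else rate,
                "adjusted_score": adjusted_score(c, mu, cfg),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["adjusted_score", "aid"], ascending=[False, True], kind="mergesort"
    )
    df = df.head(top).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return RelevanceTable(df, mu=mu, n_assays=len(counts))


def counts_from_bioprofile(profile) -> list[AssayOutcomeCounts]:
    """Tally per-assay outcome counts from a bioprofile's 1/-1/0 columns."""
    out = []
    for j, aid in enumerate(profile.assays):
        col = profile.matrix[:, j]
        out.append(
            AssayOutcomeCounts(
                aid=aid,
                active=int((col == 1).sum()),
                inactive=int((col == -1).sum()),
                inconclusive=int((col == 0).sum()),
            )
        )
    return out
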