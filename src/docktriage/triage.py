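"""Ranked-library triage: top-fraction selection, enrichment factors, gating.

A virtual screen produces one docking score per compound. Ranking them,
taking the best fraction f, and comparing the rate of known actives inside
that bin against the library-wide rate gives the enrichment factor

    EF_f = (n_a / N_top) / (N_actives / N),

the standard early-recognition summary for a repurposing screen. Candidate
selection for molecular dynamics then applies three gates in order: docking
score, key-residue overlap, and a user-supplied clinical-inclusion flag
(route of administration and prescription frequency are judged by the
analyst, not computed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import TriageError

__all__ = [
    "TriageThresholds",
    "EnrichmentResult",
    "rank_compounds",
    "top_fraction",
    "enrichment_factor",
    "select_candidates",
]


@dataclass(frozen=True)
class TriageThresholds:
    """Gates of the candidate-selection flowchart.

    ``score_threshold`` is compared in the ranking direction (a lower-is-better
    screen passes scores ≤ threshold). ``overlap_threshold`` is the minimum
    key-residue overlap. ``require_clinical_inclusion`` demands a truthy
    ``include`` column.
    """

    score_threshold: float | None = None
    overlap_threshold: float | None = None
    require_clinical_inclusion: bool = False

    def __post_init__(self):
        if self.overlap_threshold is not None and not (0 <= self.overlap_threshold <= 1):
            raise ValueError("overlap threshold must lie in [0, 1]")


@dataclass(frozen=True)
class EnrichmentResult:
    """Enrichment factor at fraction f plus the counts behind it."""

    fraction: float
    n_top: int
    n_actives_in_bin: int
    n_total: int
    n_actives: int
    ef: float


def rank_compounds(table: pd.DataFrame, lower_is_better: bool = True) -> pd.DataFrame:
    """Sort a compound table by score and attach 1-based ranks.

    Requires columns ``id`` and ``score``. Ties are broken lexicographically
    by compound id, so the ranking is deterministic regardless of input order.
    """
    if len(table) == 0:
        raise TriageError("screen table is empty")
    for col in ("id", "score"):
        if col not in table.columns:
            raise TriageError(f"screen table is missing required column {col!r}")
    if table["id"].duplicated().any():
        dups = table.loc[table["id"].duplicated(), "id"].tolist()
        raise TriageError(f"duplicate compound ids: {dups[:5]}")
    if not np.all(np.isfinite(table["score"].astype(float))):
        raise TriageError("scores must be finite")
    ranked = table.sort_values(
        ["score", "id"], ascending=[lower_is_better, True], kind="mergesort"
    ).reset_index(drop=True)
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    return ranked


def bin_size(n: int, fraction: float) -> int:
    """Top-bin size: round-half-up of fraction × n, at least 1."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    return max(1, int(math.floor(fraction * n + 0.5)))


def top_fraction(ranked: pd.DataFrame, fraction: float) -> pd.DataFrame:
    """First round-half-up(f·N) rows (minimum 1) of a ranked table."""
    if "rank" not in ranked.columns:
        raise TriageError("table must be ranked first (missing 'rank' column)")
    return ranked.head(bin_size(len(ranked), fraction))


def enrichment_factor(
    ranked: pd.DataFrame, fraction: float, active_col: str = "active"
) -> EnrichmentResult:
    """Enrichment factor of labeled actives in the top fraction of a ranking."""
    if active_col not in ranked.columns:
        raise TriageError(f"missing active-label column {active_col!r}")
    active = ranked[active_col].astype(bool)
    n, n_actives = len(ranked), int(active.sum())
    if n_actives == 0:
        raise TriageError("no labeled actives; enrichment factor is undefined")
    n_top = bin_size(n, fraction)
    n_a = int(active.iloc[:n_top].sum())
    ef = (n_a / n_top) / (n_actives / n)
    return EnrichmentResult(
        fraction=fraction, n_top=n_top, n_actives_in_bin=n_a,
        n_total=n, n_actives=n_actives, ef=ef,
    )


def select_candidates(
    table: pd.DataFrame,
    thresholds: TriageThresholds,
    lower_is_better: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the score / overlap / clinical-inclusion gates to a compound table.

    Returns (candidates, decision trail). The trail has one row per compound
    with the verdict and, for rejected compounds, the first gate that failed
    ("score", "overlap" or "clinical"). Both outputs are sorted by compound id
    so the result is independent of input row order.
    """
    if thresholds.overlap_threshold is not None and "overlap" not in table.columns:
        raise TriageError("overlap threshold set but table has no 'overlap' column")
    if thresholds.require_clinical_inclusion and "include" not in table.columns:
        raise TriageError("clinical inclusion required but table has no 'include' column")

    work = table.sort_values("id", kind="mergesort").reset_index(drop=True)
    reasons = []
    for row in work.itertuples():
        reason = "pass"
        if thresholds.score_threshold is not None:
            ok = row.score <= thresholds.score_threshold if lower_is_better else row.score >= thresholds.score_threshold
            if not ok:
                reason = "score"
        if reason == "pass" and thresholds.overlap_threshold is not None:
            if not (row.overlap >= thresholds.overlap_threshold):
                reason = "overlap"
        if reason == "pass" and thresholds.require_clinical_inclusion:
            if not bool(row.include):
                reason = "clinical"
        reasons.append(reason)
    trail = work[["id"]].copy()
    trail["decision"] = ["selected" if r == "pass" else "rejected" for r in reasons]
    trail["reason"] = reasons
    candidates = work[[r == "pass" for r in reasons]].reset_index(drop=True)
    return candidates, trail
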