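"""Post-docking MD stability statistic: censored replicate-median ligand RMSD.

A docked pose is validated by short molecular-dynamics replicates (three
10 ns runs per compound here). A ligand whose RMSD from its starting pose
exceeds 5.5 Å is considered to have left the site; from the first such frame
the replicate is censored to a fixed 10 Å so that escape events dominate any
later re-entry when medians are formed. The per-compound statistic is the
median across replicates taken pointwise in time, summarized by the median
over the final-nanosecond window (9–10 ns), which ranks compounds and
classifies them as bound (window median strictly below 5.5 Å) or unbound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import StabilityError
from .struct_io import RmsdSeries

__all__ = [
    "StabilityConfig",
    "StabilityResult",
    "apply_early_stop",
    "median_across_replicates",
    "window_median",
    "classify_binding",
    "compound_stability",
    "rank_ligands",
]


@dataclass(frozen=True)
class StabilityConfig:
    """Thresholds of the stability pipeline (distances Å, times ns).

    ``early_stop_threshold`` triggers censoring; ``censor_value`` replaces all
    frames from the first crossing (or the whole replicate when
    ``censor_whole_replicate`` is set). The ranking statistic is the median
    over the closed ``window``. ``binding_threshold`` separates bound from
    unbound, bound requiring a window median strictly below it.
    """

    early_stop_threshold: float = 5.5
    censor_value: float = 10.0
    expected_replicates: int = 3
    window: tuple[float, float] = (9.0, 10.0)
    binding_threshold: float = 5.5
    censor_whole_replicate: bool = False

    def __post_init__(self):
        if self.censor_value <= self.early_stop_threshold:
            raise ValueError("censor value must exceed the early-stop threshold")
        if not self.window[0] < self.window[1]:
            raise ValueError("window start must precede window end")


@dataclass
class StabilityResult:
    """Per-compound stability summary."""

    compound_id: str
    median_series: RmsdSeries
    window_median: float
    bound: bool
    rank: int | None = None


def apply_early_stop(series: RmsdSeries, cfg: StabilityConfig | None = None) -> RmsdSeries:
    """Censor a replicate from its first early-stop crossing onward.

    Frames from the first value strictly above the threshold are replaced by
    the censor value; an uncrossed series is returned unchanged (new object).
    Idempotent: the censor value itself re-censors to the same series.
    """
    cfg = cfg or StabilityConfig()
    above = series.values > cfg.early_stop_threshold
    if not above.any():
        return replace(series, times=series.times.copy(), values=series.values.copy())
    t_star = int(np.argmax(above))
    values = series.values.copy()
    if cfg.censor_whole_replicate:
        values[:] = cfg.censor_value
        t_star = 0
    else:
        values[t_star:] = cfg.censor_value
    return replace(series, times=series.times.copy(), values=values, censored_from=t_star)


def median_across_replicates(replicates: list[RmsdSeries]) -> RmsdSeries:
    """Pointwise median series across replicates sharing a time grid.

    Replicates on slightly different grids (same length) are used as-is with
    a warning after checking the grids agree to within one frame step; even
    replicate counts take the mean of the central pair (NumPy convention).
    """
    if not replicates:
        raise StabilityError("no replicates supplied")
    ref = replicates[0]
    n = len(ref)
    step = float(np.min(np.diff(ref.times))) if n > 1 else 0.0
    for rep in replicates[1:]:
        if len(rep) != n:
            raise StabilityError(
                f"replicate {rep.replicate_id!r} has {len(rep)} frames, expected {n}"
            )
        if not np.allclose(rep.times, ref.times):
            if np.max(np.abs(rep.times - ref.times)) > step:
                raise StabilityError(
                    f"replicate {rep.replicate_id!r} time grid differs by more than one frame step"
                )
            warnings.warn(
                f"replicate {rep.replicate_id!r} grid differs slightly; matching frames by index"
            )
    stacked = np.vstack([rep.values for rep in replicates])
    return RmsdSeries(
        replicate_id="median",
        times=ref.times.copy(),
        values=np.median(stacked, axis=0),
    )


def window_median(series: RmsdSeries, cfg: StabilityConfig | None = None) -> float:
    """Median RMSD over frames inside the closed ranking window."""
    cfg = cfg or StabilityConfig()
    lo, hi = cfg.window
    mask = (series.times >= lo) & (series.times <= hi)
    if not mask.any():
        raise StabilityError(
            f"no frames in the [{lo}, {hi}] ns window (series spans "
            f"{series.times[0]:g}–{series.times[-1]:g} ns)"
        )
    return float(np.median(series.values[mask]))


def classify_binding(value: float, cfg: StabilityConfig | None = None) -> bool:
    """Bound iff the window median lies strictly below the binding threshold."""
    cfg = cfg or StabilityConfig()
    return value < cfg.binding_threshold


def compound_stability(
    compound_id: str,
    replicates: list[RmsdSeries],
    cfg: StabilityConfig | None = None,
) -> StabilityResult:
    """Full per-compound pipeline: censor replicates → median → window → classify."""
    cfg = cfg or StabilityConfig()
    if len(replicates) != cfg.expected_replicates:
        warnings.warn(
            f"{compound_id}: {len(replicates)} replicates supplied, "
            f"expected {cfg.expected_replicates}"
        )
    censored = [apply_early_stop(r, cfg) for r in replicates]
    med = median_across_replicates(censored)
    wm = window_median(med, cfg)
    return StabilityResult(
        compound_id=compound_id,
        median_series=med,
        window_median=wm,
        bound=classify_binding(wm, cfg),
    )


def rank_ligands(results: list[StabilityResult]) -> pd.DataFrame:
    """Rank compounds ascending by window median (ties id-lexicographic).

    Returns a table (compound, window_median, bound, rank) and writes the
    1-based rank back onto each result.
    """
    if not results:
        raise StabilityError("no stability results to rank")
    ordered = sorted(results, key=lambda r: (r.window_median, r.compound_id))
    rows = []
    for rank, res in enumerate(ordered, start=1):
        res.rank = rank
        rows.append(
            {
                "compound": res.compound_id,
                "window_median": res.window_median,
                "bound": res.bound,
                "rank": rank,
            }
        )
    return pd.DataFrame(rows)
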