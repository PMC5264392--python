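"""Incremental removal of the most varied sites with a correlation-based
stopping rule.

The alignment is sorted fastest-first by observed variability (OV).  At
each step ``k`` (multiples of the increment, default 250) the matrix is
split into the retained partition A (columns ``k..end``) and the removed
partition B (columns ``0..k``); the step records two Pearson correlations
over taxon pairs: between ML distances of A and B, and between ML and
uncorrected p distances of B.  While the removed partition consists of
saturated noise these correlations sit low; once genuinely informative
sites start entering B both jump — the recommended stopping point is the
end of that sharp increase.  The jump detector used here flags a step as
a sharp increase when its delta exceeds ``jump_factor`` times the median
absolute delta of all earlier steps, in both series, and returns the k at
the end of the maximal run of consecutive flagged steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import Alignment
from .saturation import ml_distance_matrix, p_distance_matrix
from .sites import SiteRateTable, ov_scores, rank_sites


@dataclass
class RemovalStep:
    k: int
    position: int          # remaining width
    r_AB: float | None     # Pearson r, ML(A) vs ML(B)
    r_MLp: float | None    # Pearson r, ML(B) vs p(B)


@dataclass
class RemovalTrace:
    steps: list[RemovalStep] = field(default_factory=list)
    increment: int = 250
    original_width: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.steps])


def ov_sort(aln: Alignment):
    """Reorder columns fastest-first by OV; returns (alignment, rank map).

    ``rank_map[new_position] = original_column``, so the inverse
    permutation restores the original order.
    """
    ov, _ = ov_scores(aln)
    table = SiteRateTable(ov=ov)
    perm = rank_sites(table, by="ov", order="fastest-first")
    return aln.take_columns(perm), perm


def _pair_correlation(A: pd.DataFrame, B: pd.DataFrame) -> float | None:
    a = A.to_numpy()
    b = B.to_numpy()
    iu = np.triu_indices(a.shape[0], k=1)
    x, y = a[iu], b[iu]
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        return None
    return float(stats.pearsonr(x[ok], y[ok]).statistic)


def removal_series(aln_sorted: Alignment, increment: int = 250,
                   max_removed: int | None = None,
                   model: str = "GTR") -> RemovalTrace:
    """Correlation trace over successive removals from an OV-sorted matrix.

    ``model`` is the ML distance model applied to both partitions at
    every step (one model, fit-free closed forms by default, reused
    throughout).
    """
    width = aln_sorted.n_columns
    if max_removed is None:
        max_removed = width - increment
    if max_removed >= width:
        raise ValueError("max_removed must be below the alignment width")
    trace = RemovalTrace(increment=increment, original_width=width)
    for k in range(increment, max_removed + 1, increment):
        A = aln_sorted.take_columns(np.arange(k, width))
        B = aln_sorted.take_columns(np.arange(0, k))
        ml_A = ml_distance_matrix(A, model=model)
        ml_B = ml_distance_matrix(B, model=model)
        p_B = p_distance_matrix(B)
        trace.steps.append(RemovalStep(
            k=k, position=width - k,
            r_AB=_pair_correlation(ml_A, ml_B),
            r_MLp=_pair_correlation(ml_B, p_B)))
    return trace


def detect_stopping_point(trace: RemovalTrace, jump_factor: float = 3.0):
    """Locate the end of the sharp correlation increase.

    Returns a dict with ``k_star`` (None when no sharp increase exists),
    the extent of the detected run, and both per-step delta series.
    """
    if len(trace.steps) < 4:
        raise ValueError("need at least 4 steps")
    ks = [s.k for s in trace.steps]
    series = {}
    for name in ("r_AB", "r_MLp"):
        vals = np.array([np.nan if getattr(s, name) is None
                         else getattr(s, name) for s in trace.steps])
        series[name] = np.diff(vals)
    n_deltas = len(ks) - 1
    sharp = np.zeros(n_deltas, dtype=bool)
    for s in range(1, n_deltas):
        flags = []
        for name in ("r_AB", "r_MLp"):
            deltas = series[name]
            prior = np.abs(deltas[:s])
            prior = prior[np.isfinite(prior)]
            if len(prior) == 0 or not np.isfinite(deltas[s]):
                flags.append(False)
                continue
            med = np.median(prior)
            flags.append(deltas[s] > jump_factor * max(med, 1e-12))
        sharp[s] = all(flags)
    diagnostics = {
        "delta_r_AB": series["r_AB"].tolist(),
        "delta_r_MLp": series["r_MLp"].tolist(),
        "sharp_steps": [ks[i + 1] for i in np.flatnonzero(sharp)],
    }
    if not sharp.any():
        return {"k_star": None, "run": [], **diagnostics,
                "note": "no-stopping-point"}
    # maximal run of consecutive sharp steps; first such run if tied
    runs, cur = [], []
    for i in range(n_deltas):
        if sharp[i]:
            cur.append(i)
        elif cur:
            runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)
    best = max(runs, key=len)
    run_ks = [ks[i + 1] for i in best]
    return {"k_star": run_ks[-1], "run": run_ks, **diagnostics}


def apply_removal(aln_sorted: Alignment, k: int,
                  rank_map: np.ndarray | None = None) -> Alignment:
    """Drop the first ``k`` (fastest) columns of an OV-sorted alignment.

    With the ``rank_map`` from :func:`ov_sort` the surviving columns are
    restored to their original relative order.
    """
    if k > aln_sorted.n_columns or k < 0:
        raise ValueError(f"k={k} out of range for width "
                         f"{aln_sorted.n_columns}")
    keep = np.arange(k, aln_sorted.n_columns)
    if rank_map is not None:
        orig = np.asarray(rank_map)[keep]
        keep = keep[np.argsort(orig, kind="stable")]
    return aln_sorted.take_columns(keep)
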