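"""Tree-independent per-column rate metrics and site classification.

Two rate proxies are provided:

* **OV (observed variability)** — for each column, the fraction of
  unordered taxon pairs whose states differ, over pairs where both
  characters are unambiguous.  Gap/ambiguous characters are excluded from
  both numerator and denominator.
* **TIGER** — each column induces a set partition of the taxa by state;
  the rate of a column is one minus its mean *partition agreement* with
  every other column, where the agreement of partition ``P_j`` with
  ``P_i`` is the fraction of blocks of ``P_j`` nested inside some block
  of ``P_i``.  Conserved columns agree with everything (rate near 0),
  randomised columns with nothing (rate near 1).

Sites are classified as constant (at most one unambiguous state),
parsimony-informative (>= 2 states each carried by >= 2 taxa), or variable
but parsimony-uninformative.  The tertile partitioner splits the
parsimony-informative sites into three equal rate groups and pads each
with the shared uninformative variable sites, mirroring the accounting of
rate-partitioned supermatrix subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment

CONSTANT = "constant"
VARIABLE = "variable-uninformative"
PIS = "parsimony-informative"


@dataclass
class SiteRateTable:
    """Per-column classes, OV scores, TIGER rates and rank order."""

    classes: np.ndarray | None = None     # object array of class labels
    ov: np.ndarray | None = None
    tiger: np.ndarray | None = None
    rank: np.ndarray | None = None
    low_coverage: np.ndarray | None = None  # columns with <2 unambiguous chars
    summary: dict = field(default_factory=dict)

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({
            "column": np.arange(len(self.classes)),
            "class": self.classes,
            "ov": self.ov,
            "tiger": self.tiger,
            "rank": self.rank,
        })


def _state_counts(aln: Alignment) -> np.ndarray:
    """(n_states, n_columns) counts of unambiguous states per column."""
    codes = aln.state_codes()
    n_states = int(codes.max(initial=-1)) + 1
    n_states = max(n_states, 1)
    counts = np.zeros((n_states, aln.n_columns), dtype=np.int64)
    for s in range(n_states):
        counts[s] = (codes == s).sum(axis=0)
    return counts


def classify_sites(aln: Alignment) -> SiteRateTable:
    """Fill site classes; empty columns are constant by convention."""
    if aln.n_columns == 0 or aln.n_taxa == 0:
        raise ValueError("empty alignment")
    counts = _state_counts(aln)
    n_states_present = (counts > 0).sum(axis=0)
    n_states_ge2 = (counts >= 2).sum(axis=0)
    classes = np.full(aln.n_columns, VARIABLE, dtype=object)
    classes[n_states_present <= 1] = CONSTANT
    classes[n_states_ge2 >= 2] = PIS
    table = SiteRateTable(classes=classes)
    n_pis = int((classes == PIS).sum())
    n_const = int((classes == CONSTANT).sum())
    table.summary = {
        "total": aln.n_columns,
        "constant": n_const,
        "variable": aln.n_columns - n_const,
        "parsimony_informative": n_pis,
    }
    return table


def ov_scores(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Observed variability per column, plus a low-coverage flag array.

    Columns with fewer than two unambiguous characters score 0 and are
    flagged.
    """
    if aln.n_taxa < 2:
        raise ValueError("OV needs at least 2 taxa")
    counts = _state_counts(aln)
    m = counts.sum(axis=0)
    total_pairs = m * (m - 1) // 2
    same_pairs = (counts * (counts - 1) // 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ov = np.where(total_pairs > 0,
                      (total_pairs - same_pairs) / np.maximum(total_pairs, 1),
                      0.0)
    return ov.astype(float), m < 2


def _column_partitions(aln: Alignment) -> list[list[np.ndarray]]:
    """Set partition of taxa induced by each column (missing taxa dropped)."""
    codes = aln.state_codes()
    parts = []
    for j in range(aln.n_columns):
        col = codes[:, j]
        blocks = [np.flatnonzero(col == s)
                  for s in np.unique(col[col >= 0])]
        parts.append(blocks)
    return parts


def tiger_rates(aln: Alignment) -> np.ndarray:
    """Exact TIGER rates, O(L^2 * taxa).

    ``pa(P_i, P_j)`` = fraction of blocks of ``P_j`` contained in a single
    block of ``P_i``; a column's agreement is the mean of ``pa(P_i, P_j)``
    over all other columns ``j``, and its rate is one minus that.
    Columns inducing an empty partition (all missing) get agreement 1
    against everything (vacuously nested), hence rate 0.
    """
    if aln.n_taxa < 3:
        raise ValueError("TIGER needs at least 3 taxa")
    if aln.n_columns < 2:
        raise ValueError("TIGER needs at least 2 columns")
    codes = aln.state_codes()
    parts = _column_partitions(aln)
    L = aln.n_columns
    pa = np.ones((L, L))  # pa[i, j] = agreement of P_j's blocks within P_i
    for j in range(L):
        blocks = parts[j]
        if not blocks:
            pa[:, j] = 1.0
            continue
        nested = np.zeros(L, dtype=np.int64)
        for b in blocks:
            sub = codes[b, :]            # states of the block's taxa, all cols
            ok = (sub >= 0).all(axis=0) & (sub == sub[0]).all(axis=0)
            nested += ok
        pa[:, j] = nested / len(blocks)
    np.fill_diagonal(pa, 0.0)
    agreement = pa.sum(axis=1) / (L - 1)
    return 1.0 - agreement


def rank_sites(table: SiteRateTable, by: str = "ov",
               order: str = "fastest-first") -> np.ndarray:
    """Stable permutation of column indices by rate; ties keep column order."""
    scores = table.ov if by == "ov" else table.tiger
    if scores is None:
        raise ValueError(f"{by} scores not computed")
    if order == "fastest-first":
        perm = np.argsort(-np.asarray(scores), kind="stable")
    elif order == "slowest-first":
        perm = np.argsort(np.asarray(scores), kind="stable")
    else:
        raise ValueError(f"unknown order {order!r}")
    return perm


def compute_site_rate_table(aln: Alignment, tiger: bool = False,
                            rank_by: str = "ov") -> SiteRateTable:
    """Convenience: classes + OV (+ optional TIGER) + fastest-first rank."""
    table = classify_sites(aln)
    table.ov, table.low_coverage = ov_scores(aln)
    if tiger:
        table.tiger = tiger_rates(aln)
    table.rank = rank_sites(table, by=rank_by)
    return table


def tertile_partition(aln: Alignment, table: SiteRateTable,
                      method: str = "ov", include_constant: bool = False):
    """Split parsimony-informative sites into slow/medium/fast rate tertiles.

    Each returned partition holds its tertile of parsimony-informative
    columns plus *all* variable parsimony-uninformative columns (and,
    with ``include_constant``, the constant columns too), in original
    column order.  When the informative count is not divisible by 3 the
    remainder goes to the slow, then the medium group.

    Returns ``(slow, medium, fast, report)`` where the report carries
    per-partition column and informative-site counts.
    """
    scores = table.ov if method == "ov" else table.tiger
    if scores is None or table.classes is None:
        raise ValueError("classification and rates must be computed first")
    pis_idx = np.flatnonzero(table.classes == PIS)
    if len(pis_idx) < 3:
        raise ValueError(
            f"need >=3 parsimony-informative columns, got {len(pis_idx)}")
    # slowest first, stable in original column order
    order = pis_idx[np.argsort(np.asarray(scores)[pis_idx], kind="stable")]
    n = len(order)
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    bounds = np.cumsum([0] + sizes)
    tertiles = [np.sort(order[bounds[i]:bounds[i + 1]]) for i in range(3)]

    shared = np.flatnonzero(table.classes == VARIABLE)
    if include_constant:
        shared = np.concatenate(
            [shared, np.flatnonzero(table.classes == CONSTANT)])
    outputs, rows = [], []
    for name, tert in zip(("slow", "medium", "fast"), tertiles):
        cols = np.sort(np.concatenate([tert, shared]))
        outputs.append(aln.take_columns(cols))
        rows.append({"partition": name, "n_columns": int(len(cols)),
                     "n_pis": int(len(tert))})
    report = {"partitions": rows, "n_pis_total": n,
              "n_shared": int(len(shared)), "method": method,
              "include_constant": include_constant}
    return outputs[0], outputs[1], outputs[2], report
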