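"""Substitution-saturation diagnostics.

Three complementary views of saturation are provided:

* **Pairwise distances** — uncorrected p-distances and model-corrected ML
  distances (JC69/K80 closed forms; GTR via the reversible log-det ML
  estimator; GTR+G by 1-D likelihood optimisation per pair).  Saturated
  pairs whose divergence matrix has lost full rank are capped at ``d_max``.
* **Entropy index (Iss)** — mean per-site entropy over the expected
  entropy at full randomisation; a gene whose Iss approaches or exceeds
  the critical value Iss.c (the Iss at which distance-based tree building
  stops recovering the true 4-taxon topology 95% of the time) has lost
  most of its phylogenetic signal.  Iss.c is estimated by Monte-Carlo
  simulation across a grid of tree depths, for a symmetric and an
  asymmetric (Felsenstein-zone-shaped) quartet.
* **Patristic-vs-p regression** — ordinary least squares of p-distance on
  patristic distance over taxon pairs.  Saturation flattens this curve, so
  genes in the left shoulder of the per-gene slope (or R-squared) density
  are flagged, either at the deepest density antimode left of the mode or
  at a fixed percentile.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .alignment import Alignment
from .models import ModelError, SubstitutionModel, empirical_base_freqs

_PAIR_IDX = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


class DistanceError(ValueError):
    pass


@dataclass
class SaturationStats:
    """Entropy-based saturation test results for one alignment."""

    H: float
    H_FSS: float
    Iss: float
    n_taxa: int
    n_sites: int
    degenerate: bool = False
    Iss_c_sym: float | None = None
    Iss_c_asym: float | None = None
    p_sym: float | None = None
    p_asym: float | None = None
    se_Iss: float | None = None
    saturated: bool | None = None


@dataclass
class RegressionStats:
    """Slope and fit of p-distance regressed on patristic distance."""

    slope: float
    intercept: float
    R2: float
    n_pairs: int


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _pair_counts(ci: np.ndarray, cj: np.ndarray) -> np.ndarray:
    """4x4 site-pattern counts over sites where both rows are unambiguous."""
    valid = (ci >= 0) & (cj >= 0)
    if not valid.any():
        return np.zeros((4, 4))
    flat = ci[valid].astype(np.int64) * 4 + cj[valid]
    return np.bincount(flat, minlength=16).reshape(4, 4).astype(float)


def p_distance_matrix(aln: Alignment) -> pd.DataFrame:
    """Uncorrected p-distances; NaN where a pair shares no comparable site."""
    if aln.n_taxa < 2:
        raise DistanceError("need >= 2 taxa")
    codes = aln.state_codes()
    n = aln.n_taxa
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = (codes[i] >= 0) & (codes[j] >= 0)
            m = valid.sum()
            if m == 0:
                D[i, j] = D[j, i] = np.nan
            else:
                d = (codes[i][valid] != codes[j][valid]).sum() / m
                D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=aln.taxa, columns=aln.taxa)


def _jc69_distance(p: float, d_max: float) -> float:
    if p >= 0.75:
        return d_max
    return min(-0.75 * np.log1p(-4.0 * p / 3.0), d_max)


def _k80_distance(P: float, Q: float, d_max: float) -> float:
    a, b = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if a <= 0 or b <= 0:
        return d_max
    return min(-0.5 * np.log(a) - 0.25 * np.log(b), d_max)


def _gtr_logdet_distance(F: np.ndarray, d_max: float) -> float:
    """Reversible ML distance d = -sum_i pi_i [log(Pi^-1 F)]_ii."""
    n = F.sum()
    if n == 0:
        return np.nan
    Fs = (F + F.T) / (2.0 * n)
    pi = np.maximum(Fs.sum(axis=1), 1e-10)
    isq = 1.0 / np.sqrt(pi)
    M = isq[:, None] * Fs * isq[None, :]
    w, U = np.linalg.eigh((M + M.T) / 2)
    if (w <= 0).any():
        return d_max
    d = -float((pi[:, None] * U ** 2 * np.log(w)[None, :]).sum())
    if not np.isfinite(d) or d < 0:
        return d_max if d > 0 else 0.0
    return min(d, d_max)


def _mixture_pair_loglik(F: np.ndarray, model: SubstitutionModel,
                         d: float) -> float:
    Ps = model.mixture_transition(d).mean(axis=0)
    J = np.maximum(model.freqs[:, None] * Ps, 1e-300)
    return float((F * np.log(J)).sum())


def _optimised_distance(F: np.ndarray, model: SubstitutionModel,
                        d_max: float) -> float:
    if F.sum() == 0:
        return np.nan
    off = F.sum() - np.trace(F)
    if off == 0:
        return 0.0
    res = optimize.minimize_scalar(
        lambda d: -_mixture_pair_loglik(F, model, d),
        bounds=(1e-9, d_max), method="bounded",
        options={"xatol": 1e-8})
    return float(res.x)


def ml_distance_matrix(aln: Alignment, model: str = "GTR",
                       fitted: SubstitutionModel | None = None,
                       d_max: float = 5.0) -> pd.DataFrame:
    """Pairwise ML distances under JC69, K80, GTR or GTR+G.

    ``GTR`` uses the closed-form reversible estimator per pair; ``GTR+G``
    requires (or fits) a shared :class:`SubstitutionModel` and optimises
    each pair's distance numerically.  Distances of pairs beyond the model
    ceiling are capped at ``d_max``.
    """
    if aln.n_taxa < 2:
        raise DistanceError("need >= 2 taxa")
    if aln.molecule != "nt":
        raise DistanceError("ML distances are nucleotide-only")
    if model == "GTR+G" and fitted is None:
        fitted, _ = fit_substitution_model(aln, candidates=("GTR+G",))
    codes = aln.encoded()
    n = aln.n_taxa
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            F = _pair_counts(codes[i], codes[j])
            m = F.sum()
            if m == 0:
                D[i, j] = D[j, i] = np.nan
                continue
            p = (m - np.trace(F)) / m
            if model == "JC69":
                d = _jc69_distance(p, d_max)
            elif model == "K80":
                P = (F[0, 2] + F[2, 0] + F[1, 3] + F[3, 1]) / m
                d = _k80_distance(P, p - P, d_max)
            elif model == "GTR":
                d = _gtr_logdet_distance(F, d_max)
            elif model == "GTR+G":
                d = _optimised_distance(F, fitted, d_max)
            else:
                raise ValueError(f"unknown model {model!r}")
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=aln.taxa, columns=aln.taxa)


def _pooled_divergence(aln: Alignment) -> np.ndarray:
    codes = aln.encoded()
    F = np.zeros((4, 4))
    for i in range(aln.n_taxa):
        for j in range(i + 1, aln.n_taxa):
            F += _pair_counts(codes[i], codes[j])
    return F


def _gtr_rates_from_pooled(F: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Exchangeabilities from the matrix log of the pooled divergence."""
    n = F.sum()
    Fs = (F + F.T) / (2.0 * n)
    isq = 1.0 / np.sqrt(np.maximum(freqs, 1e-10))
    M = isq[:, None] * Fs * isq[None, :]
    w, U = np.linalg.eigh((M + M.T) / 2)
    w = np.maximum(w, 1e-8)
    logM = (U * np.log(w)) @ U.T
    Qhat = np.sqrt(freqs)[:, None] * logM / np.sqrt(freqs)[None, :]
    rates = np.array([max(Qhat[i, j] / freqs[j], 1e-4)
                      for i, j in _PAIR_IDX])
    return rates / rates[-1]


def fit_substitution_model(aln: Alignment,
                           candidates=("JC69", "K80", "GTR", "GTR+G"),
                           d_max: float = 5.0):
    """Fit candidate models to the whole matrix, select by BIC.

    The fit maximises the sum of independent pairwise log-likelihoods
    (composite likelihood) with shared model parameters and per-pair
    distances.  Returns ``(model, report)`` with per-candidate BIC.
    """
    codes = aln.encoded()
    pooled = _pooled_divergence(aln)
    n_total = pooled.sum()
    if n_total == 0:
        raise ModelError("no comparable sites")
    freqs = empirical_base_freqs(codes)
    gtr_rates = _gtr_rates_from_pooled(pooled, freqs)
    P_ts = (pooled[0, 2] + pooled[2, 0] + pooled[1, 3] + pooled[3, 1])
    Q_tv = n_total - np.trace(pooled) - P_ts
    kappa = max(2.0 * P_ts / max(Q_tv, 1.0), 0.05)

    pair_F = []
    for i in range(aln.n_taxa):
        for j in range(i + 1, aln.n_taxa):
            F = _pair_counts(codes[i], codes[j])
            if F.sum() > 0:
                pair_F.append(F)

    def total_loglik(model: SubstitutionModel) -> float:
        tot = 0.0
        for F in pair_F:
            d = _optimised_distance(F, model, d_max)
            if np.isnan(d):
                continue
            tot += _mixture_pair_loglik(F, model, d)
        return tot

    def build(name: str, alpha: float | None = None) -> SubstitutionModel:
        if name == "JC69":
            return SubstitutionModel.jc69(alpha=alpha)
        if name == "K80":
            return SubstitutionModel.k80(kappa=kappa, alpha=alpha)
        return SubstitutionModel(freqs=freqs, rates=gtr_rates, alpha=alpha,
                                 name=name)

    report, best, best_bic = {}, None, np.inf
    n_free = {"JC69": 0, "K80": 1, "GTR": 8, "GTR+G": 9}
    for name in candidates:
        if name == "GTR+G":
            res = optimize.minimize_scalar(
                lambda la: -total_loglik(build(name, alpha=np.exp(la))),
                bounds=(np.log(0.05), np.log(20.0)), method="bounded",
                options={"xatol": 1e-2})
            model = build(name, alpha=float(np.exp(res.x)))
            ll = -res.fun
        else:
            model = build(name)
            ll = total_loglik(model)
        bic = -2.0 * ll + n_free[name] * np.log(n_total)
        report[name] = {"loglik": ll, "bic": bic,
                        "alpha": getattr(model, "alpha", None)}
        if bic < best_bic:
            best, best_bic = model, bic
    return best, report


# ---------------------------------------------------------------------------
# patristic distances and regression
# ---------------------------------------------------------------------------

def patristic_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Path-length distances between all leaf pairs."""
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree has edges without branch lengths")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = [t.label for t in tree.taxon_namespace]
    n = len(taxa)
    D = np.zeros((n, n))
    for i, ti in enumerate(tree.taxon_namespace):
        for j, tj in enumerate(tree.taxon_namespace):
            if i < j:
                D[i, j] = D[j, i] = pdm.patristic_distance(ti, tj)
    return pd.DataFrame(D, index=taxa, columns=taxa)


def _flatten_pairs(A: pd.DataFrame, B: pd.DataFrame):
    taxa = [t for t in A.index if t in set(B.index)]
    if len(taxa) < 3:
        raise ValueError("need >= 3 shared taxa")
    a = A.loc[taxa, taxa].to_numpy()
    b = B.loc[taxa, taxa].to_numpy()
    iu = np.triu_indices(len(taxa), k=1)
    x, y = a[iu], b[iu]
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def saturation_regression(patristic: pd.DataFrame,
                          p: pd.DataFrame) -> RegressionStats:
    """OLS of p-distance (response) on patristic distance (predictor)."""
    x, y = _flatten_pairs(patristic, p)
    if np.var(x) == 0:
        raise ValueError("degenerate regression: predictor has zero variance")
    res = stats.linregress(x, y)
    return RegressionStats(slope=float(res.slope),
                           intercept=float(res.intercept),
                           R2=float(res.rvalue ** 2), n_pairs=len(x))


# ---------------------------------------------------------------------------
# entropy saturation index
# ---------------------------------------------------------------------------

def expected_full_saturation_entropy(q: np.ndarray, n: int) -> float:
    """Expected per-site entropy (bits) of ``n`` independent draws from
    base frequencies ``q`` — the full-substitution-saturation reference.

    Computed exactly by enumerating state-count compositions for modest
    ``n``; for large ``n`` the asymptotic value ``-sum q log2 q`` is used
    (the plug-in entropy bias vanishes as 1/n).
    """
    q = np.asarray(q, dtype=float)
    q = q[q > 0]
    if n <= 0:
        return 0.0
    if n > 200:
        return float(-(q * np.log2(q)).sum())
    from scipy.special import gammaln

    def compositions(total: int, parts: int):
        if parts == 1:
            yield (total,)
            return
        for head in range(total + 1):
            for rest in compositions(total - head, parts - 1):
                yield (head, *rest)

    logq = np.log(q)
    expected = 0.0
    for counts in compositions(n, len(q)):
        c = np.array(counts, dtype=float)
        logp = (gammaln(n + 1) - gammaln(c + 1).sum() + (c * logq).sum())
        p = np.exp(logp)
        f = c[c > 0] / n
        expected += p * float(-(f * np.log2(f)).sum())
    return expected


def iss_index(aln: Alignment) -> SaturationStats:
    """Entropy saturation index Iss = H / H_FSS.

    ``H`` is the mean per-site entropy (bits) of unambiguous state
    frequencies; ``H_FSS`` the expected per-site entropy at full
    randomisation — the mean entropy of ``n_taxa`` independent draws from
    the alignment-wide base frequencies — so Iss tends to 1 on fully
    randomised data at any taxon count.
    """
    codes = aln.encoded()
    counts = np.stack([(codes == s).sum(axis=0) for s in range(4)])
    m = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(m > 0, counts / np.maximum(m, 1), 0.0)
        logf = np.where(f > 0, np.log2(np.where(f > 0, f, 1.0)), 0.0)
    H_sites = -(f * logf).sum(axis=0)
    H = float(H_sites.mean()) if len(H_sites) else 0.0
    total = counts.sum(axis=1).astype(float)
    if total.sum() == 0 or (total > 0).sum() <= 1:
        return SaturationStats(H=H, H_FSS=0.0, Iss=0.0, n_taxa=aln.n_taxa,
                               n_sites=aln.n_columns, degenerate=True)
    q = total / total.sum()
    H_FSS = expected_full_saturation_entropy(q, aln.n_taxa)
    iss = H / H_FSS if H_FSS > 0 else 0.0
    return SaturationStats(H=H, H_FSS=H_FSS, Iss=iss, n_taxa=aln.n_taxa,
                           n_sites=aln.n_columns,
                           degenerate=H_FSS == 0)


def _quartet_topology_from_distances(D: np.ndarray) -> int:
    """0: AB|CD, 1: AC|BD, 2: AD|BC by the four-point criterion."""
    sums = [D[0, 1] + D[2, 3], D[0, 2] + D[1, 3], D[0, 3] + D[1, 2]]
    return int(np.argmin(sums))


def _simulate_quartet_iss(kind: str, depth: float, length: int,
                          freqs: np.ndarray, rng: np.random.Generator):
    """One simulated quartet at the given depth: (Iss, recovered?)."""
    from .simulate import simulate_alignment
    from .io import parse_tree
    model = SubstitutionModel(freqs=freqs, name="GTR")
    if kind == "sym":
        t = depth
        nwk = f"((A:{t},B:{t}):{t},(C:{t},D:{t}):{0.0});"
    else:  # asymmetric, Felsenstein-zone shaped: long A and C branches
        nwk = (f"((A:{2 * depth},B:{depth / 4}):{depth / 4},"
               f"C:{2 * depth},D:{depth / 4});")
    tree = parse_tree(nwk)
    aln = simulate_alignment(tree, model, length,
                             seed=int(rng.integers(2 ** 31)))
    order = {t: i for i, t in enumerate(aln.taxa)}
    sub = aln.matrix[[order[x] for x in "ABCD"]]
    sub_aln = Alignment(list("ABCD"), sub)
    codes = sub_aln.encoded()
    D = np.zeros((4, 4))
    for i, j in _PAIR_IDX:
        valid = (codes[i] >= 0) & (codes[j] >= 0)
        p = ((codes[i][valid] != codes[j][valid]).sum()
             / max(valid.sum(), 1))
        D[i, j] = D[j, i] = _jc69_distance(p, 5.0)
    recovered = _quartet_topology_from_distances(D) == 0
    return iss_index(sub_aln).Iss, recovered


def _estimate_iss_c(kind: str, length: int, freqs: np.ndarray,
                    reps: int, rng: np.random.Generator,
                    recovery_target: float = 0.95) -> float:
    """Iss at which NJ recovery of the true quartet drops below 95%."""
    depths = np.geomspace(0.02, 4.0, 10)
    per_depth = max(reps // len(depths), 10)
    mean_iss, recovery = [], []
    for depth in depths:
        vals, hits = [], 0
        for _ in range(per_depth):
            iss, rec = _simulate_quartet_iss(kind, depth, length, freqs, rng)
            vals.append(iss)
            hits += rec
        mean_iss.append(float(np.mean(vals)))
        recovery.append(hits / per_depth)
    for k in range(len(depths)):
        if recovery[k] < recovery_target:
            if k == 0:
                return mean_iss[0]
            # linear interpolation of Iss at the recovery crossing
            r0, r1 = recovery[k - 1], recovery[k]
            w = (r0 - recovery_target) / max(r0 - r1, 1e-12)
            return float(mean_iss[k - 1] + w * (mean_iss[k] - mean_iss[k - 1]))
    return mean_iss[-1]


def iss_test(aln: Alignment, reps: int = 200, seed: int = 0,
             n_subsamples: int = 8, alpha_level: float = 0.05,
             n_bootstrap: int = 100) -> SaturationStats:
    """Monte-Carlo saturation test of Iss against simulated Iss.c.

    With more than four taxa the observed Iss is the average over random
    4-taxon subsamples.  The observed index is compared to the critical
    value by a z-test using a site-bootstrap standard error; the gene is
    flagged saturated when Iss is significantly *above* Iss.c for the
    symmetric quartet at the given level.
    """
    if aln.n_taxa < 4:
        raise ValueError("Iss test needs >= 4 taxa")
    if reps < 100:
        import logging
        logging.getLogger(__name__).warning(
            "reps=%d < 100: Iss.c estimate may be unstable", reps)
    rng = np.random.default_rng(seed)

    def subsample_sets():
        if aln.n_taxa == 4:
            return [np.arange(4)]
        return [rng.choice(aln.n_taxa, 4, replace=False)
                for _ in range(n_subsamples)]

    subsets = subsample_sets()

    def observed_iss(matrix: np.ndarray) -> float:
        vals = []
        for rows in subsets:
            sub = Alignment([aln.taxa[r] for r in rows], matrix[rows])
            vals.append(iss_index(sub).Iss)
        return float(np.mean(vals))

    iss_obs = observed_iss(aln.matrix)
    base = iss_index(aln)

    boots = []
    for _ in range(n_bootstrap):
        cols = rng.integers(0, aln.n_columns, aln.n_columns)
        boots.append(observed_iss(aln.matrix[:, cols]))
    se = float(np.std(boots, ddof=1)) if len(boots) > 1 else np.nan

    freqs = empirical_base_freqs(aln.encoded())
    issc_sym = _estimate_iss_c("sym", aln.n_columns, freqs, reps, rng)
    issc_asym = _estimate_iss_c("asym", aln.n_columns, freqs, reps, rng)

    def pval(issc: float) -> float:
        if not np.isfinite(se) or se == 0:
            return 0.0 if iss_obs > issc else 1.0
        z = (iss_obs - issc) / se
        return float(stats.norm.sf(z))

    p_sym, p_asym = pval(issc_sym), pval(issc_asym)
    return SaturationStats(
        H=base.H, H_FSS=base.H_FSS, Iss=iss_obs, n_taxa=aln.n_taxa,
        n_sites=aln.n_columns, degenerate=base.degenerate,
        Iss_c_sym=issc_sym, Iss_c_asym=issc_asym,
        p_sym=p_sym, p_asym=p_asym, se_Iss=se,
        saturated=bool(p_sym < alpha_level))


# ---------------------------------------------------------------------------
# left-shoulder gene flagging
# ---------------------------------------------------------------------------

def flag_saturated_genes(values: dict[str, float] | pd.Series,
                         method: str = "valley",
                         param: float = 15.0):
    """Flag low-value genes (left shoulder of the slope/R2 density).

    ``valley``: Gaussian KDE (Silverman bandwidth); genes below the
    deepest density minimum left of the global mode are flagged.  Falls
    back to the percentile method when no antimode exists.
    ``percentile``: flag genes below the ``param``-th percentile.

    Returns ``(flagged_gene_set, cut_value)``.
    """
    series = pd.Series(values, dtype=float)
    if len(series) < 5:
        raise ValueError("need >= 5 genes")
    vals = series.to_numpy()
    if method == "percentile":
        cut = float(np.percentile(vals, param))
        return set(series.index[vals < cut]), cut
    if method != "valley":
        raise ValueError(f"unknown method {method!r}")
    if np.ptp(vals) == 0:
        return flag_saturated_genes(series, "percentile", param)
    kde = stats.gaussian_kde(vals, bw_method="silverman")
    grid = np.linspace(vals.min() - np.ptp(vals) * 0.05,
                       vals.max() + np.ptp(vals) * 0.05, 512)
    dens = kde(grid)
    mode_idx = int(np.argmax(dens))
    interior = np.flatnonzero(
        (dens[1:-1] <= dens[:-2]) & (dens[1:-1] <= dens[2:])) + 1
    minima = [i for i in interior if i < mode_idx]
    if not minima:
        import logging
        logging.getLogger(__name__).info(
            "no antimode left of the mode; falling back to percentile")
        return flag_saturated_genes(series, "percentile", param)
    cut_idx = min(minima, key=lambda i: dens[i])
    cut = float(grid[cut_idx])
    return set(series.index[vals < cut]), cut
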