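"""GTR family substitution models with discrete-Gamma rate heterogeneity.

One :class:`SubstitutionModel` object is shared by the sequence simulator,
the pruning likelihood, and the pairwise ML distances.  The rate matrix is
the general time-reversible (GTR) parameterisation
``Q[i,j] = s[i,j] * pi[j]`` (i != j), normalised so the expected rate at
stationarity is one substitution per site per unit branch length.  JC69
and K80 are the usual special cases.  Among-site rate variation uses the
mean-per-category discretisation of a mean-one Gamma(alpha, alpha) into
``ncat`` equal-probability classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

# exchangeability order: AC, AG, AT, CG, CT, GT
_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


class ModelError(ValueError):
    """Invalid substitution-model parameters."""


def gamma_category_rates(alpha: float, ncat: int = 4) -> np.ndarray:
    """Mean rate of each of ``ncat`` equal-probability Gamma categories.

    The underlying density is Gamma(alpha, rate=alpha), i.e. mean 1.
    """
    if alpha <= 0:
        raise ModelError("gamma shape must be positive")
    cuts = gamma_dist.ppf(np.linspace(0, 1, ncat + 1), a=alpha,
                          scale=1.0 / alpha)
    upper = gammainc(alpha + 1, alpha * cuts[1:])
    lower = gammainc(alpha + 1, alpha * cuts[:-1])
    rates = ncat * (upper - lower)
    return rates / rates.mean()


@dataclass
class SubstitutionModel:
    """Time-reversible nucleotide model (GTR with JC69/K80 special cases).

    Parameters
    ----------
    freqs
        Stationary base frequencies (A, C, G, T), summing to one.
    rates
        Six exchangeabilities in the order AC, AG, AT, CG, CT, GT.
    alpha
        Gamma shape for among-site rate variation; ``None`` = equal rates.
    ncat
        Number of discrete Gamma categories.
    """

    freqs: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    rates: np.ndarray = field(default_factory=lambda: np.ones(6))
    alpha: float | None = None
    ncat: int = 4
    name: str = "GTR"

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.freqs.shape != (4,) or self.rates.shape != (6,):
            raise ModelError("need 4 frequencies and 6 exchangeabilities")
        if (self.freqs <= 0).any() or not np.isclose(self.freqs.sum(), 1.0):
            raise ModelError("frequencies must be positive and sum to 1")
        if (self.rates < 0).any() or self.rates.sum() == 0:
            raise ModelError("exchangeabilities must be nonnegative")
        self._build()

    # -- construction helpers --------------------------------------------
    @classmethod
    def jc69(cls, alpha: float | None = None, ncat: int = 4):
        return cls(alpha=alpha, ncat=ncat, name="JC69")

    @classmethod
    def k80(cls, kappa: float = 2.0, alpha: float | None = None,
            ncat: int = 4):
        rates = np.ones(6)
        rates[1] = rates[4] = kappa  # AG, CT transitions
        return cls(rates=rates, alpha=alpha, ncat=ncat, name="K80")

    def _build(self) -> None:
        Q = np.zeros((4, 4))
        for r, (i, j) in zip(self.rates, _PAIRS):
            Q[i, j] = r * self.freqs[j]
            Q[j, i] = r * self.freqs[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(self.freqs * np.diag(Q)).sum()
        if mu <= 0:
            raise ModelError("degenerate rate matrix")
        Q /= mu
        self.Q = Q
        # reversible: symmetrise with pi^1/2 and eigendecompose
        sq = np.sqrt(self.freqs)
        S = (sq[:, None] * Q) / sq[None, :]
        w, V = np.linalg.eigh((S + S.T) / 2)
        self._eval = w
        self._right = V / sq[:, None] * 1.0
        self._left = (V * sq[:, None]).T

    # -- transition probabilities ----------------------------------------
    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to one."""
        if t < 0:
            raise ModelError("negative branch length")
        P = (self._right * np.exp(self._eval * t)) @ self._left
        return np.clip(P, 0.0, None)

    def category_rates(self) -> np.ndarray:
        if self.alpha is None:
            return np.ones(1)
        return gamma_category_rates(self.alpha, self.ncat)

    def mixture_transition(self, t: float) -> np.ndarray:
        """Gamma-mixture transition probabilities, shape (ncat, 4, 4)."""
        return np.stack([self.transition_matrix(t * r)
                         for r in self.category_rates()])


def empirical_base_freqs(codes: np.ndarray) -> np.ndarray:
    """Base frequencies from integer-coded sequences (-1 = missing)."""
    counts = np.array([(codes == s).sum() for s in range(4)], dtype=float)
    if counts.sum() == 0:
        raise ModelError("no unambiguous characters")
    counts = np.maximum(counts, 0.5)  # avoid zero frequencies
    return counts / counts.sum()
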