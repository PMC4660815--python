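"""Closed-form marginal likelihoods for column groups and the joint partition
likelihood.

The model: columns of a :class:`~bhit.data.MixedDataset` are partitioned into
groups; columns in different groups are independent, columns within a group
are dependent.  The likelihood of a partition factorizes over groups:

* a group of discrete columns is scored by the Dirichlet-multinomial marginal
  of its joint combination counts (the multinomial parameter integrated out
  against a Dirichlet prior);
* a continuous column grouped with discrete columns is clustered by the
  group's joint discrete combinations, and each cluster is scored by the
  Normal-Inverse-chi-squared marginal (Gaussian mean and variance integrated
  out); multiple continuous members are conditionally independent given the
  cluster;
* a lone continuous column is a single Normal-Inv-chi^2 marginal;
* a group of two or more continuous columns (no discrete member) is scored by
  the multivariate Normal-Inverse-Wishart marginal with hyperparameters
  matched to the 1-D priors, so the d=1 case coincides with Normal-Inv-chi^2.

Everything is computed in log-gamma space and is finite for sample sizes up
to at least 1e6.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln, multigammaln

from .data import MixedDataset
from .partition import Partition
from .priors import NormalInvChisqPrior, PriorConfig

__all__ = [
    "PosteriorParams",
    "count_combinations",
    "dirichlet_multinomial_log_marginal",
    "normal_invchisq_posterior",
    "normal_invchisq_log_marginal",
    "normal_inverse_wishart_log_marginal",
    "group_log_marginal",
    "joint_log_likelihood",
    "LikelihoodEvaluator",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

# full count tables are materialized only up to this many joint combinations;
# beyond it the sparse (observed-combinations) path is used internally
_DENSE_COMBO_LIMIT = 3 ** 12


def count_combinations(
    dataset: MixedDataset, group_columns: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Tally joint combination values of a set of discrete columns.

    Returns ``(counts, cluster_ids)``: ``counts[j]`` is the number of samples
    taking the j-th joint value (zeros included, length = product of member
    cardinalities, first column most significant in the mixed-radix code) and
    ``cluster_ids[i]`` is the combination index of sample i.
    """
    if len(group_columns) == 0:
        raise ValueError("group_columns must be non-empty")
    cols = [dataset.columns[i] for i in group_columns]
    for c in cols:
        if not c.is_discrete:
            raise ValueError(f"column {c.label!r} is continuous; counts need discrete columns")
    code = cols[0].values.astype(np.int64)
    c_h = cols[0].cardinality
    for c in cols[1:]:
        code = code * c.cardinality + c.values
        c_h *= c.cardinality
    if c_h > _DENSE_COMBO_LIMIT:
        raise ValueError(f"joint combination space too large to tabulate densely ({c_h})")
    counts = np.bincount(code, minlength=c_h)
    return counts, code


def dirichlet_multinomial_log_marginal(counts: np.ndarray, alphas: np.ndarray) -> float:
    """Log marginal probability of categorical counts under a Dirichlet prior.

    log [ prod_j Gamma(n_j + a_j)/Gamma(a_j) * Gamma(sum a)/Gamma(sum n + sum a) ].
    """
    counts = np.asarray(counts, dtype=np.float64)
    alphas = np.asarray(alphas, dtype=np.float64)
    if counts.shape != alphas.shape:
        raise ValueError(f"counts and alphas length mismatch: {counts.shape} vs {alphas.shape}")
    if np.any(alphas <= 0):
        raise ValueError("all Dirichlet pseudo-counts must be positive")
    if np.any(counts < 0):
        raise ValueError("negative counts")
    a_sum = alphas.sum()
    n = counts.sum()
    return float(
        np.sum(gammaln(counts + alphas) - gammaln(alphas))
        + gammaln(a_sum)
        - gammaln(n + a_sum)
    )


@dataclass(frozen=True)
class PosteriorParams:
    """Normal-Inv-chi^2 posterior hyperparameters plus the sufficient stats."""

    mu_n: float
    kappa_n: float
    nu_n: float
    sigma_n_sq: float
    ybar: float
    s_sq: float
    n: int


def normal_invchisq_posterior(
    values: np.ndarray, prior: NormalInvChisqPrior
) -> PosteriorParams:
    """Conjugate update of the Normal-Inv-chi^2 prior on observing ``values``.

    mu_n = (kappa0 mu0 + n ybar) / kappa_n,  kappa_n = kappa0 + n,
    nu_n = nu0 + n,
    sigma_n^2 = [nu0 sigma0^2 + (n-1) s^2 + kappa0 n (ybar - mu0)^2 / kappa_n] / nu_n,
    with the (n-1) s^2 term taken as 0 for n <= 1.
    """
    values = np.asarray(values, dtype=np.float64)
    n = int(values.size)
    if n == 0:
        return PosteriorParams(
            prior.mu0, prior.kappa0, prior.nu0, prior.sigma0_sq, np.nan, 0.0, 0
        )
    ybar = float(values.mean())
    ss = float(np.sum((values - ybar) ** 2))  # (n-1) s^2; zero when n == 1
    s_sq = ss / (n - 1) if n > 1 else 0.0
    kappa_n = prior.kappa0 + n
    nu_n = prior.nu0 + n
    mu_n = (prior.kappa0 * prior.mu0 + n * ybar) / kappa_n
    sigma_n_sq = (
        prior.nu0 * prior.sigma0_sq
        + ss
        + prior.kappa0 * n / kappa_n * (ybar - prior.mu0) ** 2
    ) / nu_n
    return PosteriorParams(mu_n, kappa_n, nu_n, sigma_n_sq, ybar, s_sq, n)


def _nix_log_marginal_from_stats(
    n: np.ndarray, total: np.ndarray, total_sq: np.ndarray, prior: NormalInvChisqPrior
) -> np.ndarray:
    """Vectorized Normal-Inv-chi^2 log marginal from per-cluster (n, sum, sum of squares)."""
    n = np.asarray(n, dtype=np.float64)
    out = np.zeros_like(n)
    pos = n > 0
    if not np.any(pos):
        return out
    npos = n[pos]
    ybar = total[pos] / npos
    ss = np.maximum(total_sq[pos] - npos * ybar**2, 0.0)
    kn = prior.kappa0 + npos
    vn = prior.nu0 + npos
    lam0 = prior.nu0 * prior.sigma0_sq
    lam_n = lam0 + ss + prior.kappa0 * npos / kn * (ybar - prior.mu0) ** 2
    out[pos] = (
        -0.5 * npos * _LOG_2PI
        + 0.5 * (np.log(prior.kappa0) - np.log(kn))
        + gammaln(vn / 2.0)
        - gammaln(prior.nu0 / 2.0)
        + prior.nu0 / 2.0 * np.log(lam0 / 2.0)
        - vn / 2.0 * np.log(lam_n / 2.0)
    )
    return out


def normal_invchisq_log_marginal(values: np.ndarray, prior: NormalInvChisqPrior) -> float:
    """Log marginal density of a data vector under the Normal-Inv-chi^2 model.

    Equals the joint density of the data with the Gaussian mean and variance
    integrated out: a multivariate Student-t; zero (probability one) for an
    empty vector.
    """
    values = np.asarray(values, dtype=np.float64)
    n = values.size
    if n == 0:
        return 0.0
    stats_n = np.array([float(n)])
    total = np.array([float(values.sum())])
    total_sq = np.array([float(np.sum(values**2))])
    return float(_nix_log_marginal_from_stats(stats_n, total, total_sq, prior)[0])


def normal_inverse_wishart_log_marginal(
    Y: np.ndarray,
    mu0: np.ndarray,
    kappa0: float,
    nu0: float,
    lambda0: np.ndarray,
) -> float:
    """Log marginal of an n x d data matrix under the Normal-Inverse-Wishart model.

    ``nu0`` must satisfy nu0 > d - 1; ``lambda0`` is the d x d prior scale
    matrix.  For d = 1 with lambda0 = nu0_1d * sigma0_sq this reduces to the
    Normal-Inv-chi^2 marginal.
    """
    Y = np.asarray(Y, dtype=np.float64)
    n, d = Y.shape
    if n == 0:
        return 0.0
    mu0 = np.asarray(mu0, dtype=np.float64)
    lambda0 = np.atleast_2d(np.asarray(lambda0, dtype=np.float64))
    ybar = Y.mean(axis=0)
    dev = Y - ybar
    S = dev.T @ dev
    kn = kappa0 + n
    vn = nu0 + n
    diff = ybar - mu0
    lam_n = lambda0 + S + (kappa0 * n / kn) * np.outer(diff, diff)
    sign0, logdet0 = np.linalg.slogdet(lambda0)
    sign_n, logdet_n = np.linalg.slogdet(lam_n)
    if sign0 <= 0 or sign_n <= 0:
        raise ValueError("prior/posterior scale matrix not positive definite")
    return float(
        -0.5 * n * d * np.log(np.pi)
        + 0.5 * d * (np.log(kappa0) - np.log(kn))
        + multigammaln(vn / 2.0, d)
        - multigammaln(nu0 / 2.0, d)
        + nu0 / 2.0 * logdet0
        - vn / 2.0 * logdet_n
    )


def group_log_marginal(
    dataset: MixedDataset, group_columns: Sequence[int], priors: PriorConfig
) -> float:
    """Marginal log likelihood of one column group (see module docstring)."""
    return LikelihoodEvaluator(dataset, priors).group_log_marginal(frozenset(group_columns))


def joint_log_likelihood(
    dataset: MixedDataset, partition: Partition, priors: PriorConfig
) -> float:
    """Joint log likelihood of the dataset under a partition: sum of group marginals."""
    if partition.n_columns != dataset.n_columns:
        raise ValueError(
            f"partition over {partition.n_columns} columns but dataset has {dataset.n_columns}"
        )
    ev = LikelihoodEvaluator(dataset, priors)
    return ev.joint_log_likelihood(partition)


class LikelihoodEvaluator:
    """Caching evaluator of group marginals for one (dataset, priors) pair.

    Group marginals depend only on the member-column set, so they are cached
    by frozenset; the Metropolis-Hastings sampler touches at most two groups
    per move and revisits the same groups constantly, making this cache the
    workhorse of the sampler's incremental evaluation.
    """

    def __init__(self, dataset: MixedDataset, priors: PriorConfig):
        self.dataset = dataset
        self.priors = priors
        self._cache: dict[frozenset[int], float] = {}
        self._codes = [
            c.values.astype(np.int64) if c.is_discrete else None for c in dataset.columns
        ]
        self._cards = [c.cardinality for c in dataset.columns]
        self._cont = [
            None if c.is_discrete else c.values.astype(np.float64) for c in dataset.columns
        ]
        self._cont_sq = [None if v is None else v * v for v in self._cont]
        self._cont_priors = [
            None if c.is_discrete else priors.for_column(dataset, i)
            for i, c in enumerate(dataset.columns)
        ]

    # -- internals -----------------------------------------------------

    def _joint_code(self, disc: list[int]) -> tuple[np.ndarray, int]:
        code = self._codes[disc[0]]
        c_h = self._cards[disc[0]]
        for i in disc[1:]:
            code = code * self._cards[i] + self._codes[i]
            c_h *= self._cards[i]
        return code, c_h

    def _discrete_and_clusters(
        self, disc: list[int], need_clusters: bool
    ) -> tuple[float, np.ndarray | None, int]:
        """Dirichlet-multinomial log marginal of the joint combinations, plus
        per-sample cluster ids over the observed combinations."""
        code, c_h = self._joint_code(disc)
        dirichlet = self.priors.dirichlet
        if c_h <= _DENSE_COMBO_LIMIT:
            counts = np.bincount(code, minlength=c_h)
            alphas = dirichlet.resolve(self.dataset, disc)
            logml = dirichlet_multinomial_log_marginal(counts, alphas)
            if need_clusters:
                return logml, code, c_h
            return logml, None, c_h
        # sparse path: unobserved combinations contribute zero to the product
        uniq, inv, counts = np.unique(code, return_inverse=True, return_counts=True)
        if dirichlet.scheme == "symmetric":
            a0 = dirichlet.alpha0
            a_sum = a0 * float(c_h)
            logml = float(
                np.sum(gammaln(counts + a0)) - counts.size * gammaln(a0)
                + gammaln(a_sum) - gammaln(a_sum + counts.sum())
            )
        else:
            alphas_obs = self._decode_alphas(uniq, disc)
            a_sum = dirichlet.alpha0  # maf_informed pseudo-counts sum to alpha0
            logml = float(
                np.sum(gammaln(counts + alphas_obs) - gammaln(alphas_obs))
                + gammaln(a_sum) - gammaln(a_sum + counts.sum())
            )
        return logml, (inv if need_clusters else None), int(uniq.size)

    def _decode_alphas(self, uniq_codes: np.ndarray, disc: list[int]) -> np.ndarray:
        """MAF-informed pseudo-counts for the observed joint codes only."""
        from .priors import hwe_genotype_probs

        probs = np.ones_like(uniq_codes, dtype=np.float64)
        rem = uniq_codes.copy()
        for i in reversed(disc):
            card = self._cards[i]
            digit = rem % card
            rem = rem // card
            col = self.dataset.columns[i]
            if col.role == "genotype" and card == 3:
                p = hwe_genotype_probs(self.priors.dirichlet.maf)
            else:
                p = np.full(card, 1.0 / card)
            probs *= p[digit]
        return self.priors.dirichlet.alpha0 * probs

    def _clustered_continuous(self, cont_idx: int, clusters: np.ndarray, m: int) -> float:
        y = self._cont[cont_idx]
        ysq = self._cont_sq[cont_idx]
        n = np.bincount(clusters, minlength=m)
        tot = np.bincount(clusters, weights=y, minlength=m)
        tot_sq = np.bincount(clusters, weights=ysq, minlength=m)
        return float(
            np.sum(_nix_log_marginal_from_stats(n, tot, tot_sq, self._cont_priors[cont_idx]))
        )

    def _compute(self, group: frozenset[int]) -> float:
        disc = sorted(i for i in group if self._codes[i] is not None)
        cont = sorted(i for i in group if self._codes[i] is None)
        if disc and not cont:
            logml, _, _ = self._discrete_and_clusters(disc, need_clusters=False)
            return logml
        if disc and cont:
            logml, clusters, m = self._discrete_and_clusters(disc, need_clusters=True)
            for ci in cont:
                logml += self._clustered_continuous(ci, clusters, m)
            return logml
        if len(cont) == 1:
            ci = cont[0]
            p = self._cont_priors[ci]
            return float(
                _nix_log_marginal_from_stats(
                    np.array([float(len(self._cont[ci]))]),
                    np.array([float(self._cont[ci].sum())]),
                    np.array([float(self._cont_sq[ci].sum())]),
                    p,
                )[0]
            )
        # continuous-only group of size >= 2: Normal-Inverse-Wishart with
        # hyperparameters matched to the per-column 1-D priors
        d = len(cont)
        ps = [self._cont_priors[i] for i in cont]
        mu0 = np.array([p.mu0 for p in ps])
        kappa0 = ps[0].kappa0
        nu0_1d = ps[0].nu0
        nu0 = nu0_1d + d - 1  # reduces to the 1-D nu0 when d == 1
        lambda0 = np.diag([nu0_1d * p.sigma0_sq for p in ps])
        Y = np.column_stack([self._cont[i] for i in cont])
        return normal_inverse_wishart_log_marginal(Y, mu0, kappa0, nu0, lambda0)

    # -- public --------------------------------------------------------

    def group_log_marginal(self, group: frozenset[int]) -> float:
        if not group:
            raise ValueError("empty group")
        try:
            return self._cache[group]
        except KeyError:
            val = self._compute(group)
            self._cache[group] = val
            return val

    def joint_log_likelihood(self, partition: Partition) -> float:
        return sum(self.group_log_marginal(frozenset(g)) for g in partition.groups())
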