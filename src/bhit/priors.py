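"""Conjugate prior configuration for the partition model.

Discrete column groups carry a Dirichlet prior over the joint-combination
probabilities; continuous columns carry a Normal-Inverse-chi-squared prior on
(mean, variance).  Groups of two or more dependent continuous columns use a
Normal-Inverse-Wishart prior whose hyperparameters are matched to the 1-D
prior so that the d=1 special case reduces exactly to Normal-Inv-chi^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .data import MixedDataset

__all__ = ["DirichletPrior", "NormalInvChisqPrior", "PriorConfig"]

# genotype codes under Hardy-Weinberg equilibrium: (1-p)^2, 2p(1-p), p^2
def hwe_genotype_probs(maf: float) -> np.ndarray:
    if not 0.0 < maf <= 0.5:
        raise ValueError(f"MAF must be in (0, 0.5], got {maf}")
    q = 1.0 - maf
    return np.array([q * q, 2.0 * q * maf, maf * maf])


@dataclass(frozen=True)
class DirichletPrior:
    """Pseudo-count scheme for the combination-value probabilities of a group.

    ``symmetric``: every joint combination cell gets pseudo-count ``alpha0``
    (default 1, a flat Dirichlet).  ``maf_informed``: each genotype column's
    cell probability follows Hardy-Weinberg expectations at the user-supplied
    minor allele frequency; the combination pseudo-count is ``alpha0`` times
    the product of per-column cell probabilities (non-genotype discrete
    columns contribute a uniform factor).
    """

    scheme: Literal["symmetric", "maf_informed"] = "symmetric"
    alpha0: float = 1.0
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.alpha0 <= 0:
            raise ValueError("alpha0 must be positive")
        if self.scheme == "maf_informed":
            if self.maf is None:
                raise ValueError("maf_informed scheme requires a MAF")
            hwe_genotype_probs(self.maf)  # validates range
        elif self.scheme != "symmetric":
            raise ValueError(f"unknown alpha scheme {self.scheme!r}")

    def resolve(self, dataset: MixedDataset, group_columns: list[int]) -> np.ndarray:
        """Per-combination pseudo-count vector over the c_h joint values.

        Combination index is the mixed-radix code of the member columns in
        the given order (first column is the most significant digit).
        """
        cards = [dataset.columns[i].cardinality for i in group_columns]
        if any(c is None for c in cards):
            raise ValueError("Dirichlet prior applies to discrete columns only")
        if self.scheme == "symmetric":
            c_h = int(np.prod(cards))
            return np.full(c_h, self.alpha0)
        probs = np.ones(1)
        for i, card in zip(group_columns, cards):
            col = dataset.columns[i]
            if col.role == "genotype" and card == 3:
                p = hwe_genotype_probs(self.maf)
            else:
                p = np.full(card, 1.0 / card)
            probs = np.kron(probs, p)
        return self.alpha0 * probs


@dataclass(frozen=True)
class NormalInvChisqPrior:
    """Normal-Inverse-chi-squared prior on a Gaussian's (mean, variance).

    mu | sigma^2 ~ N(mu0, sigma^2 / kappa0), sigma^2 ~ Inv-chi^2(nu0, sigma0_sq).
    """

    mu0: float
    kappa0: float = 1.0
    nu0: float = 1.0
    sigma0_sq: float = 1.0

    def __post_init__(self) -> None:
        if self.kappa0 <= 0 or self.nu0 <= 0 or self.sigma0_sq <= 0:
            raise ValueError("kappa0, nu0 and sigma0_sq must all be positive")


@dataclass
class PriorConfig:
    """Bundle of priors for all columns of a dataset.

    Continuous-column hyperparameters default to empirical Bayes: mu0 equals
    the column sample mean and sigma0_sq the column sample variance, with
    kappa0 = nu0 = 1 (one pseudo-observation's worth of shrinkage).
    """

    dirichlet: DirichletPrior = field(default_factory=DirichletPrior)
    continuous: dict[str, NormalInvChisqPrior] = field(default_factory=dict)

    @classmethod
    def empirical(
        cls,
        dataset: MixedDataset,
        dirichlet: DirichletPrior | None = None,
        kappa0: float = 1.0,
        nu0: float = 1.0,
    ) -> "PriorConfig":
        cont: dict[str, NormalInvChisqPrior] = {}
        for col in dataset.columns:
            if col.is_discrete:
                continue
            v = col.values
            var = float(np.var(v, ddof=1)) if len(v) > 1 else 1.0
            if var <= 0:
                var = 1.0
            cont[col.label] = NormalInvChisqPrior(
                mu0=float(np.mean(v)), kappa0=kappa0, nu0=nu0, sigma0_sq=var
            )
        return cls(dirichlet=dirichlet or DirichletPrior(), continuous=cont)

    def for_column(self, dataset: MixedDataset, index: int) -> NormalInvChisqPrior:
        col = dataset.columns[index]
        if col.is_discrete:
            raise ValueError(f"column {col.label!r} is discrete")
        try:
            return self.continuous[col.label]
        except KeyError:
            raise KeyError(f"no continuous prior configured for column {col.label!r}")
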