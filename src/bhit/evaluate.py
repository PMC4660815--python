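"""Statistical power and type-I-error harness over the simulation models.

Power is the fraction of simulated datasets on which the sampler's reported
structure matches the generating ground truth:

* epistasis models -- the group containing the trait must equal exactly the
  causal loci plus the trait (a superset is a miss);
* dependency models -- the thresholded co-occurrence grouping must equal the
  generating partition exactly, singletons included;
* null models -- a dataset counts as a false association when any extracted
  group contains both a phenotype and a genotype column
  (genotype-genotype and phenotype-phenotype groupings are allowed under
  the null); power is the fraction of datasets without one.

With k runs per dataset, a dataset is a hit if any single run's grouping
matches (epistasis/dependency), so multi-run power is non-decreasing in k.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .data import MixedDataset
from .likelihood import LikelihoodEvaluator
from .priors import PriorConfig
from .sampler import (
    ChainConfig,
    ChainResult,
    extract_interactions,
    pairwise_cooccurrence,
    run_chain,
)
from .simulate import (
    DependencySpec,
    EpistasisSpec,
    GroundTruth,
    NullSpec,
    simulate_dependency,
    simulate_epistasis,
    simulate_null,
)

__all__ = [
    "PowerReport",
    "recovered_partition",
    "epistasis_hit",
    "dependency_hit",
    "null_hit",
    "power_experiment",
    "genotype_class_ttest",
]


def recovered_partition(
    result: ChainResult, dataset: MixedDataset, threshold: float = 0.5
) -> frozenset[frozenset[str]]:
    """One chain's thresholded co-occurrence grouping, as label sets."""
    cooc = pairwise_cooccurrence(result)
    groups = extract_interactions(cooc, threshold=threshold)
    labels = dataset.labels
    return frozenset(frozenset(labels[i] for i in g) for g in groups)


def _as_list(results) -> list[ChainResult]:
    return [results] if isinstance(results, ChainResult) else list(results)


def epistasis_hit(
    results: ChainResult | Sequence[ChainResult],
    dataset: MixedDataset,
    truth: GroundTruth,
    threshold: float = 0.5,
) -> bool:
    """Hit if any run's group containing the trait equals exactly the causal
    loci plus the trait.  Supersets and subsets are misses."""
    if truth.phenotype_group is None:
        raise ValueError("ground truth has no phenotype-associated group")
    pheno_labels = {dataset.columns[i].label for i in dataset.phenotype_indices()}
    for r in _as_list(results):
        parts = recovered_partition(r, dataset, threshold)
        for g in parts:
            if g & pheno_labels and g == truth.phenotype_group:
                return True
    return False


def dependency_hit(
    results: ChainResult | Sequence[ChainResult],
    dataset: MixedDataset,
    truth: GroundTruth,
    threshold: float = 0.5,
) -> bool:
    """Hit if any run's thresholded grouping equals the generating partition
    exactly (label-set comparison; singletons included)."""
    target = truth.as_sets()
    return any(
        recovered_partition(r, dataset, threshold) == target for r in _as_list(results)
    )


def null_hit(
    results: ChainResult | Sequence[ChainResult],
    dataset: MixedDataset,
    truth: GroundTruth,
    threshold: float = 0.5,
) -> bool:
    """Hit (correct null call) if no extracted group mixes a phenotype with a
    genotype column in any run."""
    pheno = {dataset.columns[i].label for i in dataset.phenotype_indices()}
    geno = {dataset.columns[i].label for i in dataset.genotype_indices()}
    for r in _as_list(results):
        parts = recovered_partition(r, dataset, threshold)
        for g in parts:
            if g & pheno and g & geno:
                return False
    return True


_SIMULATORS = {
    EpistasisSpec: (simulate_epistasis, epistasis_hit),
    DependencySpec: (simulate_dependency, dependency_hit),
    NullSpec: (simulate_null, null_hit),
}


@dataclass
class PowerReport:
    """Power estimate over replicate simulated datasets."""

    model: str
    setting: dict
    n_datasets: int
    n_runs_per_dataset: int
    power: float
    ci95: tuple[float, float]
    hits: list[bool]
    run_hits: list[list[bool]]  # per dataset, per run

    def power_at(self, k: int) -> float:
        """Power when only the first k runs per dataset are considered."""
        if not 1 <= k <= self.n_runs_per_dataset:
            raise ValueError(f"k must be in [1, {self.n_runs_per_dataset}]")
        return float(np.mean([any(rh[:k]) for rh in self.run_hits]))


def power_experiment(
    spec: EpistasisSpec | DependencySpec | NullSpec,
    n_datasets: int,
    chain_config: ChainConfig,
    seed: int = 0,
    n_runs: int = 1,
    threshold: float = 0.5,
    priors_factory=None,
) -> PowerReport:
    """Simulate-run-score loop: power and Wilson 95% CI over replicates.

    Each replicate gets an independent simulation seed and chain seeds
    derived from ``seed``; the whole experiment is reproducible from it.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    simulate, hit_fn = None, None
    for klass, (sim, hf) in _SIMULATORS.items():
        if isinstance(spec, klass):
            simulate, hit_fn = sim, hf
    if simulate is None:
        raise TypeError(f"unsupported spec type {type(spec)!r}")

    master = np.random.default_rng(seed)
    run_hits: list[list[bool]] = []
    for _ in range(n_datasets):
        ds_seed = int(master.integers(2**31 - 1))
        chain_seed = int(master.integers(2**31 - 1 - n_runs))
        dataset, truth = simulate(replace(spec, seed=ds_seed))
        priors = (
            priors_factory(dataset) if priors_factory else PriorConfig.empirical(dataset)
        )
        evaluator = LikelihoodEvaluator(dataset, priors)
        hits_k = []
        for r in range(n_runs):
            cfg = replace(chain_config, seed=chain_seed + r, n_runs=1)
            result = run_chain(dataset, priors, cfg, evaluator=evaluator)
            hits_k.append(bool(hit_fn(result, dataset, truth, threshold)))
        run_hits.append(hits_k)
    hits = [any(rh) for rh in run_hits]
    power = float(np.mean(hits))
    lo, hi = proportion_confint(sum(hits), n_datasets, alpha=0.05, method="wilson")
    return PowerReport(
        model=type(spec).__name__ + str(spec.model_id),
        setting={
            k: v
            for k, v in vars(spec).items()
            if k not in ("seed",) and v is not None
        },
        n_datasets=n_datasets,
        n_runs_per_dataset=n_runs,
        power=power,
        ci95=(float(lo), float(hi)),
        hits=hits,
        run_hits=run_hits,
    )


def genotype_class_ttest(
    dataset: MixedDataset,
    loci: Sequence[str],
    combo_a: Sequence[int],
    combo_b: Sequence[int],
    phenotype: str | None = None,
) -> tuple[float, float]:
    """Welch two-sample t-test of a quantitative phenotype between samples
    carrying joint genotype ``combo_a`` vs ``combo_b`` at the given loci.

    Both classes need at least two samples.  Two identical constant classes
    return (0.0, 1.0) by convention.
    """
    from scipy.stats import ttest_ind

    idx = [dataset.column_index(l) for l in loci]
    geno = np.column_stack([dataset.columns[i].values for i in idx])
    if phenotype is None:
        cont = [
            i for i in dataset.phenotype_indices() if not dataset.columns[i].is_discrete
        ]
        if not cont:
            raise ValueError("no continuous phenotype column")
        y = dataset.columns[cont[0]].values
    else:
        y = dataset.columns[dataset.column_index(phenotype)].values
    mask_a = np.all(geno == np.asarray(combo_a), axis=1)
    mask_b = np.all(geno == np.asarray(combo_b), axis=1)
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError(
            f"genotype class too small: {int(mask_a.sum())} vs {int(mask_b.sum())} samples"
        )
    ya, yb = y[mask_a], y[mask_b]
    if ya.std() == 0 and yb.std() == 0 and ya.mean() == yb.mean():
        return 0.0, 1.0
    t, p = ttest_ind(ya, yb, equal_var=False)
    return float(t), float(p)
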