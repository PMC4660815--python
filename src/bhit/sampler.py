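"""Metropolis-Hastings sampling over column partitions.

The chain starts from the all-singletons partition (every column its own
group), proposes single-column reassignments, and accepts with probability
min(1, posterior ratio x Hastings correction).  The partition prior is
uniform over canonical partitions, so the posterior ratio equals the joint
marginal-likelihood ratio.  Post-burn-in samples are summarized by the
pairwise co-occurrence matrix: entry (i, j) is the fraction of retained
samples placing columns i and j in the same group.  Interactions are read
off by transitive closure over pairs whose co-occurrence exceeds a threshold
(default 0.5).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .data import MixedDataset
from .likelihood import LikelihoodEvaluator
from .partition import Partition, canonicalize
from .priors import PriorConfig

__all__ = [
    "ChainConfig",
    "ChainResult",
    "CooccurrenceMatrix",
    "propose_move",
    "mh_step",
    "run_chain",
    "run_chains",
    "pairwise_cooccurrence",
    "extract_interactions",
    "phenotype_associated_groups",
]


_P_SPLIT = 0.75  # proposal mass on split (fresh-group) moves
_P_MERGE = 1.0 - _P_SPLIT


@dataclass(frozen=True)
class ChainConfig:
    """MCMC budget: ``max_iterations`` total iterations T, of which the first
    ``burn_in`` B are discarded (B < T).  One iteration is a sweep of R
    single-column update attempts (R = number of columns), so every column
    gets on average one reassignment opportunity per iteration regardless of
    problem width."""

    max_iterations: int = 2000
    burn_in: int = 1000
    seed: int = 0
    n_runs: int = 1
    checkpoint_every: int | None = None
    checkpoint_path: str | Path | None = None

    def __post_init__(self) -> None:
        if self.burn_in >= self.max_iterations:
            raise ValueError("burn_in must be smaller than max_iterations")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass
class ChainResult:
    """Output of one chain: retained samples, trace and summary state."""

    samples: list[tuple[int, ...]]
    loglik_trace: np.ndarray
    acceptance_rate: float
    final_partition: Partition
    map_partition: Partition
    map_loglik: float
    seed: int

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Posterior pairwise grouping probabilities over columns."""

    matrix: np.ndarray
    labels: tuple[str, ...] | None = None


def propose_move(
    partition: Partition, rng: np.random.Generator
) -> tuple[Partition, float]:
    """Single-column reassignment proposal.

    Picks a column uniformly; with probability ``_P_SPLIT`` it moves to a
    fresh group (a split), otherwise it joins the group of a second uniformly
    chosen column (a merge whose rate scales with the target group's size, so
    large dependent groups assemble quickly).  Choosing a second column from
    the moving column's own group, or a fresh group for a singleton,
    re-proposes the current state.  Weighting splits above merges lets
    wrongly fused groups dissolve before they are reinforced.  Returns
    ``(candidate, log_correction)`` with
    ``log_correction = log q(old|new) - log q(new|old)`` for the exact
    Metropolis-Hastings acceptance ratio.
    """
    ind = partition.indicators
    R = len(ind)
    col = int(rng.integers(R))
    source_size = len(partition.group_of(col))
    if rng.random() < _P_SPLIT:
        candidate = partition.move(col, 0)  # fresh group
        if candidate.indicators == partition.indicators:
            return candidate, 0.0
        q_fwd = _P_SPLIT
        # reverse: merge back into the remaining source members
        q_rev = _P_MERGE * (source_size - 1) / (R - 1)
    else:
        if R == 1:
            return partition, 0.0
        j = int(rng.integers(R - 1))
        if j >= col:
            j += 1
        target_gid = ind[j]
        if target_gid == ind[col]:
            return partition, 0.0
        target_size = len(partition.group_of(j))
        candidate = partition.move(col, target_gid)
        q_fwd = _P_MERGE * target_size / (R - 1)
        if source_size == 1:
            q_rev = _P_SPLIT  # reverse is a split to a fresh group
        else:
            q_rev = _P_MERGE * (source_size - 1) / (R - 1)
    return candidate, float(np.log(q_rev) - np.log(q_fwd))


def mh_step(
    state: tuple[Partition, float],
    evaluator: LikelihoodEvaluator,
    rng: np.random.Generator,
) -> tuple[Partition, float, bool]:
    """One Metropolis-Hastings transition from ``(partition, loglik)``.

    Accepts with probability min(1, exp(delta loglik + Hastings correction));
    on reject the state is unchanged.  Returns (partition, loglik, accepted).
    """
    current, current_ll = state
    candidate, log_corr = propose_move(current, rng)
    if candidate.indicators == current.indicators:
        return current, current_ll, True
    cand_ll = evaluator.joint_log_likelihood(candidate)
    log_alpha = cand_ll - current_ll + log_corr
    if log_alpha >= 0 or rng.random() < np.exp(log_alpha):
        return candidate, cand_ll, True
    return current, current_ll, False


class _ChainState:
    """Mutable partition state with incremental likelihood bookkeeping.

    Group labels are internal (arbitrary, increasing); canonical partitions
    are materialized only when a sample is stored.  Only the one or two
    groups touched by a move are (re)evaluated, through the evaluator's
    group-marginal cache.
    """

    def __init__(self, R: int, evaluator: LikelihoodEvaluator):
        self.ev = evaluator
        self.ind = list(range(R))
        self.groups: dict[int, frozenset[int]] = {
            g: frozenset([g]) for g in range(R)
        }
        self.next_gid = R
        self.loglik = sum(self.ev.group_log_marginal(s) for s in self.groups.values())

    @classmethod
    def from_indicators(cls, ind: Sequence[int], evaluator: LikelihoodEvaluator):
        obj = cls.__new__(cls)
        obj.ev = evaluator
        obj.ind = list(ind)
        members: dict[int, set[int]] = {}
        for i, g in enumerate(obj.ind):
            members.setdefault(g, set()).add(i)
        obj.groups = {g: frozenset(m) for g, m in members.items()}
        obj.next_gid = max(obj.groups) + 1
        obj.loglik = sum(obj.ev.group_log_marginal(s) for s in obj.groups.values())
        return obj

    def step(self, rng: np.random.Generator) -> bool:
        R = len(self.ind)
        col = int(rng.integers(R))
        g_old = self.ind[col]
        source = self.groups[g_old]
        source_new = source - {col}

        if rng.random() < _P_SPLIT:
            # split: move the column to a fresh group
            if not source_new:  # already a singleton: identity move
                return True
            target = -1
            q_fwd = _P_SPLIT
            q_rev = _P_MERGE * len(source_new) / (R - 1)
            dest_new = frozenset([col])
            delta = (
                self.ev.group_log_marginal(source_new)
                + self.ev.group_log_marginal(dest_new)
                - self.ev.group_log_marginal(source)
            )
        else:
            # merge: join the group of a second uniformly chosen column
            if R == 1:
                return True
            j = int(rng.integers(R - 1))
            if j >= col:
                j += 1
            target = self.ind[j]
            if target == g_old:  # same group: identity move
                return True
            dest = self.groups[target]
            dest_new = dest | {col}
            q_fwd = _P_MERGE * len(dest) / (R - 1)
            q_rev = _P_SPLIT if not source_new else _P_MERGE * len(source_new) / (R - 1)
            delta = (
                self.ev.group_log_marginal(dest_new)
                - self.ev.group_log_marginal(dest)
                - self.ev.group_log_marginal(source)
            )
            if source_new:
                delta += self.ev.group_log_marginal(source_new)

        log_alpha = delta + np.log(q_rev) - np.log(q_fwd)
        if log_alpha >= 0 or rng.random() < np.exp(log_alpha):
            if target == -1:
                gid = self.next_gid
                self.next_gid += 1
            else:
                gid = target
            self.groups[gid] = dest_new
            if source_new:
                self.groups[g_old] = source_new
            else:
                del self.groups[g_old]
            self.ind[col] = gid
            self.loglik += delta
            return True
        return False

    def canonical(self) -> tuple[int, ...]:
        return canonicalize(self.ind)


def run_chain(
    dataset: MixedDataset,
    priors: PriorConfig,
    config: ChainConfig,
    evaluator: LikelihoodEvaluator | None = None,
    resume_from: str | Path | None = None,
) -> ChainResult:
    """Run one Metropolis-Hastings chain over partitions of the dataset columns.

    Starts from all singletons, runs T iterations, stores canonical
    partitions for iterations past the burn-in, and records the per-iteration
    log-likelihood trace and acceptance rate.  Deterministic given
    ``config.seed``.  Passing a shared ``evaluator`` lets multiple chains
    over the same dataset reuse cached group marginals.
    """
    if evaluator is None:
        evaluator = LikelihoodEvaluator(dataset, priors)
    R = dataset.n_columns

    if resume_from is not None:
        ck = json.loads(Path(resume_from).read_text())
        if ck.get("format") != "bhit-checkpoint-v1":
            raise ValueError("unrecognized checkpoint format")
        state = _ChainState.from_indicators(ck["partition"], evaluator)
        rng = np.random.Generator(np.random.PCG64())
        rng_state = ck["rng_state"]
        rng_state["state"] = {k: int(v) for k, v in rng_state["state"].items()}
        rng.bit_generator.state = rng_state
        start_iter = int(ck["iteration"])
        samples = [tuple(s) for s in ck["samples"]]
        trace = [float(x) for x in ck["trace"]]
        n_accept = int(ck["n_accept"])
    else:
        state = _ChainState(R, evaluator)
        rng = np.random.default_rng(config.seed)
        start_iter = 0
        samples = []
        trace = []
        n_accept = 0

    T, B = config.max_iterations, config.burn_in
    for t in range(start_iter, T):
        for _ in range(R):
            if state.step(rng):
                n_accept += 1
        trace.append(state.loglik)
        if t >= B:
            samples.append(state.canonical())
        if (
            config.checkpoint_every
            and config.checkpoint_path
            and (t + 1) % config.checkpoint_every == 0
        ):
            _write_checkpoint(config.checkpoint_path, t + 1, state, rng, samples, trace, n_accept)

    trace_arr = np.asarray(trace)
    sample_lls = trace_arr[B:]
    best = int(np.argmax(sample_lls))
    return ChainResult(
        samples=samples,
        loglik_trace=trace_arr,
        acceptance_rate=n_accept / max(T * R, 1),
        final_partition=Partition(tuple(state.canonical())),
        map_partition=Partition(samples[best]),
        map_loglik=float(sample_lls[best]),
        seed=config.seed,
    )


def _write_checkpoint(path, iteration, state: _ChainState, rng, samples, trace, n_accept):
    st = rng.bit_generator.state
    rng_state = dict(st)
    rng_state["state"] = {k: int(v) for k, v in st["state"].items()}
    payload = {
        "format": "bhit-checkpoint-v1",
        "iteration": iteration,
        "partition": list(state.ind),
        "rng_state": rng_state,
        "loglik": state.loglik,
        "samples": [list(s) for s in samples],
        "trace": [float(x) for x in trace],
        "n_accept": n_accept,
    }
    Path(path).write_text(json.dumps(payload))


def run_chains(
    dataset: MixedDataset,
    priors: PriorConfig,
    config: ChainConfig,
    share_cache: bool = True,
) -> list[ChainResult]:
    """Run ``config.n_runs`` independent chains (seeds = seed + run index)."""
    evaluator = LikelihoodEvaluator(dataset, priors) if share_cache else None
    results = []
    for r in range(config.n_runs):
        cfg = ChainConfig(
            max_iterations=config.max_iterations,
            burn_in=config.burn_in,
            seed=config.seed + r,
            n_runs=1,
        )
        results.append(run_chain(dataset, priors, cfg, evaluator=evaluator))
    return results


def pairwise_cooccurrence(
    results: ChainResult | Sequence[ChainResult],
    labels: Sequence[str] | None = None,
) -> CooccurrenceMatrix:
    """Fraction of pooled post-burn-in samples placing each column pair together."""
    if isinstance(results, ChainResult):
        results = [results]
    all_samples = [s for r in results for s in r.samples]
    if not all_samples:
        raise ValueError("no post-burn-in samples to summarize")
    arr = np.asarray(all_samples)  # n_samples x n_columns
    n, R = arr.shape
    counts = np.zeros((R, R), dtype=np.int64)
    # identical consecutive samples are common; collapse runs before the O(R^2) work
    uniq, run_counts = _collapse_runs(arr)
    for row, w in zip(uniq, run_counts):
        counts += w * (row[:, None] == row[None, :])
    mat = counts / float(n)
    return CooccurrenceMatrix(mat, tuple(labels) if labels is not None else None)


def _collapse_runs(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if arr.shape[0] == 1:
        return arr, np.array([1])
    change = np.any(arr[1:] != arr[:-1], axis=1)
    starts = np.concatenate([[0], np.nonzero(change)[0] + 1])
    lengths = np.diff(np.concatenate([starts, [arr.shape[0]]]))
    return arr[starts], lengths


def extract_interactions(
    matrix: CooccurrenceMatrix | np.ndarray,
    threshold: float = 0.5,
) -> list[tuple[int, ...]]:
    """Column groups from transitive closure of co-occurrence strictly above
    ``threshold`` (a pair exactly at the threshold is NOT linked).

    Groups are ordered by decreasing size, ties broken by first column index;
    singletons included, so the result is a partition of all columns.
    """
    mat = matrix.matrix if isinstance(matrix, CooccurrenceMatrix) else np.asarray(matrix)
    R = mat.shape[0]
    parent = list(range(R))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    ii, jj = np.nonzero(np.triu(mat > threshold, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    groups: dict[int, list[int]] = {}
    for i in range(R):
        groups.setdefault(find(i), []).append(i)
    out = [tuple(sorted(g)) for g in groups.values()]
    out.sort(key=lambda g: (-len(g), g[0]))
    return out


def phenotype_associated_groups(
    groups: Sequence[tuple[int, ...]], dataset: MixedDataset
) -> list[tuple[int, ...]]:
    """Groups containing at least one phenotype and one genotype column."""
    pheno = set(dataset.phenotype_indices())
    geno = set(dataset.genotype_indices())
    return [g for g in groups if (set(g) & pheno) and (set(g) & geno)]
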