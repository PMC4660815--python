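"""PLINK text-format I/O, preprocessing, and the genome-scale run strategies.

Preprocessing follows the standard GWAS intake path: parse .ped/.map, recode
genotypes additively against the minor allele (0 = homozygous major, 1 =
heterozygous, 2 = homozygous minor), drop SNPs with minor allele frequency
below a threshold (default 0.05, strict <), and optionally check quantitative
traits for normality with a Kolmogorov-Smirnov test.  Genotypes and
phenotypes are then assembled into a :class:`~bhit.data.MixedDataset` (and a
tab-separated on-disk "bhit" format) for the sampler.

Three strategies make genome-scale inputs tractable:

* **A** -- prefilter SNPs with an L1-penalized regression of the phenotype on
  the additive codes (pluggable hook), then sample on the surviving SNPs;
* **B** -- one independent sampling run per chromosome, phenotypes included
  in every block;
* **C** -- restrict to SNPs inside user-supplied regions (BED-like, 0-based
  half-open; .map positions are 1-based).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import Column, MixedDataset
from .priors import PriorConfig
from .sampler import (
    ChainConfig,
    extract_interactions,
    pairwise_cooccurrence,
    phenotype_associated_groups,
    run_chains,
)

__all__ = [
    "MapRecord",
    "PedMapPair",
    "PipelineConfig",
    "read_ped_map",
    "write_ped_map",
    "recode_additive",
    "maf_filter",
    "ks_normality_check",
    "assemble_bhit_input",
    "write_bhit",
    "read_bhit",
    "read_regions",
    "lasso_prefilter",
    "run_strategy",
]

_VALID_ALLELES = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class MapRecord:
    chromosome: str
    snp_id: str
    genetic_distance: float
    position: int  # 1-based bp position


@dataclass
class PedMapPair:
    """Parsed .ped/.map file pair: per-SNP metadata plus per-sample allele pairs."""

    map_records: list[MapRecord]
    sample_ids: list[str]  # "family_individual"
    ped_meta: list[tuple[str, str, str, str, str, str]]  # fid iid father mother sex pheno
    alleles: np.ndarray  # samples x SNPs x 2, single characters

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.map_records)


def read_ped_map(ped_path: str | Path, map_path: str | Path) -> PedMapPair:
    """Parse a whitespace-delimited PLINK .ped/.map pair.

    Missing alleles ('0') are rejected with an error naming the offending
    SNP and sample: imputation belongs upstream of this pipeline.
    """
    map_records: list[MapRecord] = []
    for ln, line in enumerate(Path(map_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"{map_path}:{ln}: expected 4 fields, got {len(parts)}")
        map_records.append(
            MapRecord(parts[0], parts[1], float(parts[2]), int(parts[3]))
        )
    n_snps = len(map_records)

    sample_ids: list[str] = []
    meta: list[tuple[str, str, str, str, str, str]] = []
    allele_rows: list[list[str]] = []
    for ln, line in enumerate(Path(ped_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_snps:
            raise ValueError(
                f"{ped_path}:{ln}: expected {6 + 2 * n_snps} fields for "
                f"{n_snps} map SNPs, got {len(parts)}"
            )
        fid, iid = parts[0], parts[1]
        sample = f"{fid}_{iid}"
        for j in range(n_snps):
            a1, a2 = parts[6 + 2 * j], parts[7 + 2 * j]
            for a in (a1, a2):
                if a == "0":
                    raise ValueError(
                        f"missing allele at SNP {map_records[j].snp_id!r} "
                        f"for sample {sample!r}; impute upstream"
                    )
                if a not in _VALID_ALLELES:
                    raise ValueError(
                        f"invalid allele {a!r} at SNP {map_records[j].snp_id!r} "
                        f"for sample {sample!r}"
                    )
        sample_ids.append(sample)
        meta.append(tuple(parts[:6]))
        allele_rows.append(parts[6:])
    alleles = np.array(allele_rows, dtype="U1").reshape(len(sample_ids), n_snps, 2)
    return PedMapPair(map_records, sample_ids, meta, alleles)


def write_ped_map(pair: PedMapPair, ped_path: str | Path, map_path: str | Path) -> None:
    with open(map_path, "w") as fh:
        for m in pair.map_records:
            gd = int(m.genetic_distance) if m.genetic_distance == int(m.genetic_distance) else m.genetic_distance
            fh.write(f"{m.chromosome}\t{m.snp_id}\t{gd}\t{m.position}\n")
    with open(ped_path, "w") as fh:
        for i, meta in enumerate(pair.ped_meta):
            fields = list(meta)
            for j in range(pair.n_snps):
                fields.extend(pair.alleles[i, j])
            fh.write("\t".join(fields) + "\n")


def recode_additive(pair: PedMapPair) -> tuple[np.ndarray, list[str]]:
    """Additive recoding: per SNP, count minor alleles per sample.

    The minor allele is the less frequent of the two observed alleles; an
    exact 50/50 tie treats the alphabetically first allele as major.
    Monomorphic SNPs recode to all zeros (and fall to the MAF filter).
    """
    n, m = pair.n_samples, pair.n_snps
    codes = np.zeros((n, m), dtype=np.int64)
    snp_ids = [r.snp_id for r in pair.map_records]
    for j in range(m):
        snp_alleles = pair.alleles[:, j, :]
        uniq, counts = np.unique(snp_alleles, return_counts=True)
        if len(uniq) > 2:
            raise ValueError(
                f"SNP {snp_ids[j]!r} has {len(uniq)} alleles; only biallelic SNPs supported"
            )
        if len(uniq) == 1:
            continue
        order = np.argsort(uniq)  # alphabetical
        a, b = uniq[order[0]], uniq[order[1]]
        ca, cb = counts[order[0]], counts[order[1]]
        minor = b if cb <= ca else a  # tie -> alphabetically first is major
        codes[:, j] = (snp_alleles == minor).sum(axis=1)
    return codes, snp_ids


def maf_filter(
    matrix: np.ndarray,
    threshold: float = 0.05,
    snp_ids: Sequence[str] | None = None,
) -> tuple[np.ndarray, list[int | str]]:
    """Drop SNPs with minor allele frequency strictly below ``threshold``.

    MAF of an additively coded SNP over G samples is (2 n2 + n1) / (2 G).
    Returns the filtered matrix and the removed SNP ids (indices when no ids
    are given).  A SNP with MAF exactly at the threshold is kept.
    """
    matrix = np.asarray(matrix)
    G = matrix.shape[0]
    maf = matrix.sum(axis=0) / (2.0 * G)
    keep = maf >= threshold
    removed_idx = np.nonzero(~keep)[0]
    removed = (
        [snp_ids[i] for i in removed_idx] if snp_ids is not None else removed_idx.tolist()
    )
    return matrix[:, keep], removed


def ks_normality_check(
    values: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """One-sample Kolmogorov-Smirnov test against N(sample mean, sample SD).

    Returns (statistic, p-value, pass flag at ``alpha``).  Because the
    reference distribution's parameters are estimated from the same data,
    the nominal p-value is anti-conservative for small samples (the
    Lilliefors caveat); a warning records this.  Failing the check is a
    warning for the caller, not a hard stop.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 8:
        raise ValueError(f"need at least 8 observations, got {values.size}")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("constant vector: normality test undefined (zero SD)")
    warnings.warn(
        "KS test uses parameters estimated from the data; p-values are "
        "anti-conservative for small samples (Lilliefors)",
        UserWarning,
        stacklevel=2,
    )
    stat, p = stats.kstest(values, "norm", args=(values.mean(), sd))
    return float(stat), float(p), bool(p >= alpha)


# ---------------------------------------------------------------------------
# dataset assembly and the on-disk bhit format


def assemble_bhit_input(
    genotypes: pd.DataFrame,
    phenotypes: pd.DataFrame,
    phenotype_kinds: dict[str, str] | None = None,
) -> MixedDataset:
    """Column-align additive genotype codes with a phenotype table by sample id.

    Both frames must be indexed by sample id; a phenotype row missing for any
    genotyped sample is an error naming the sample.
    """
    missing = [s for s in genotypes.index if s not in phenotypes.index]
    if missing:
        raise ValueError(f"phenotype table missing sample ids: {missing}")
    phenotypes = phenotypes.loc[genotypes.index]
    cols = [
        Column(str(c), "discrete", "genotype", genotypes[c].to_numpy(), 3)
        for c in genotypes.columns
    ]
    kinds = phenotype_kinds or {}
    for c in phenotypes.columns:
        vals = phenotypes[c].to_numpy()
        kind = kinds.get(str(c))
        if kind is None:
            kind = "discrete" if np.issubdtype(vals.dtype, np.integer) else "continuous"
        if kind == "discrete":
            cols.append(
                Column(str(c), "discrete", "phenotype", vals, int(np.max(vals)) + 1)
            )
        else:
            cols.append(Column(str(c), "continuous", "phenotype", vals))
    return MixedDataset(cols)


def write_bhit(dataset: MixedDataset, path: str | Path) -> None:
    """Write the tab-separated bhit format: a version line, one descriptor
    line ``label|kind|role|cardinality`` per column, then one row per sample."""
    with open(path, "w") as fh:
        fh.write("#bhit-v1\n")
        fh.write(
            "\t".join(
                f"{c.label}|{c.kind}|{c.role}|{c.cardinality if c.cardinality is not None else '-'}"
                for c in dataset.columns
            )
            + "\n"
        )
        for i in range(dataset.n_samples):
            row = [
                str(int(c.values[i])) if c.is_discrete else repr(float(c.values[i]))
                for c in dataset.columns
            ]
            fh.write("\t".join(row) + "\n")


def read_bhit(path: str | Path) -> MixedDataset:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != "#bhit-v1":
        raise ValueError("not a bhit-v1 file")
    descriptors = lines[1].split("\t")
    rows = [ln.split("\t") for ln in lines[2:] if ln.strip()]
    data = list(zip(*rows))
    cols = []
    for desc, vals in zip(descriptors, data):
        label, kind, role, card = desc.split("|")
        if kind == "discrete":
            cols.append(Column(label, kind, role, np.array([int(v) for v in vals]), int(card)))
        else:
            cols.append(Column(label, kind, role, np.array([float(v) for v in vals])))
    return MixedDataset(cols)


def read_regions(path: str | Path) -> list[tuple[str, int, int]]:
    """BED-like region file: chromosome, start, end (0-based half-open)."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


# ---------------------------------------------------------------------------
# strategies


@dataclass
class PipelineConfig:
    """Settings for preprocessing and a strategy run."""

    strategy: str = "B"
    maf_threshold: float = 0.05
    ks_alpha: float = 0.05
    threshold: float = 0.5  # posterior co-occurrence cut for reporting
    regions: list[tuple[str, int, int]] | None = None  # strategy C
    prefilter: Callable[[MixedDataset], list[str]] | None = None  # strategy A hook
    chain: ChainConfig = field(default_factory=ChainConfig)

    def __post_init__(self) -> None:
        if self.strategy not in ("A", "B", "C"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not 0.0 < self.maf_threshold < 1.0 or not 0.0 < self.ks_alpha < 1.0:
            raise ValueError("thresholds must lie in (0, 1)")


def lasso_prefilter(dataset: MixedDataset, cv: int = 5, random_state: int = 0) -> list[str]:
    """Default strategy-A prefilter: L1-penalized regression of the first
    continuous phenotype on the additive genotype codes, penalty chosen by
    cross-validation; returns labels of SNPs with non-zero coefficients."""
    from sklearn.linear_model import LassoCV

    cont_phenos = [
        i for i in dataset.phenotype_indices() if not dataset.columns[i].is_discrete
    ]
    if not cont_phenos:
        raise ValueError("strategy A prefilter needs a continuous phenotype")
    y = dataset.columns[cont_phenos[0]].values
    geno_idx = dataset.genotype_indices()
    X = np.column_stack([dataset.columns[i].values for i in geno_idx]).astype(float)
    model = LassoCV(cv=cv, random_state=random_state).fit(X, y)
    return [
        dataset.columns[geno_idx[j]].label
        for j in np.nonzero(model.coef_ != 0.0)[0]
    ]


def _run_block(
    dataset: MixedDataset, config: PipelineConfig, priors: PriorConfig | None
) -> dict:
    priors = priors or PriorConfig.empirical(dataset)
    results = run_chains(dataset, priors, config.chain)
    cooc = pairwise_cooccurrence(results, labels=dataset.labels)
    groups = extract_interactions(cooc, threshold=config.threshold)
    assoc = phenotype_associated_groups(groups, dataset)
    to_labels = lambda gs: [[dataset.columns[i].label for i in g] for g in gs]
    return {
        "labels": dataset.labels,
        "groups": to_labels(groups),
        "phenotype_associated": to_labels(assoc),
        "cooccurrence": cooc.matrix.tolist(),
        "acceptance_rates": [r.acceptance_rate for r in results],
    }


def run_strategy(
    dataset: MixedDataset,
    config: PipelineConfig,
    map_records: Sequence[MapRecord] | None = None,
    priors: PriorConfig | None = None,
) -> dict:
    """Run one of the three genome-scale strategies and merge the reports.

    Strategy A prefilters SNPs (default: L1 regression hook), B blocks by
    .map chromosome (phenotypes included in every block), C restricts to
    SNPs whose position falls in ``config.regions``.  Every block run ends
    with pooled co-occurrence and thresholded interaction extraction.
    """
    pheno_idx = dataset.phenotype_indices()

    if config.strategy == "A":
        prefilter = config.prefilter or lasso_prefilter
        kept = set(prefilter(dataset))
        snp_idx = [i for i in dataset.genotype_indices() if dataset.columns[i].label in kept]
        blocks = [dataset.subset_columns(snp_idx + pheno_idx)] if snp_idx else []
        block_names = ["prefiltered"] if snp_idx else []
    elif config.strategy == "B":
        if map_records is None:
            raise ValueError("strategy B needs map records for chromosome assignment")
        by_chrom: dict[str, list[int]] = {}
        chrom_of = {m.snp_id: m.chromosome for m in map_records}
        for i in dataset.genotype_indices():
            by_chrom.setdefault(chrom_of[dataset.columns[i].label], []).append(i)
        block_names = sorted(by_chrom)
        blocks = [dataset.subset_columns(by_chrom[c] + pheno_idx) for c in block_names]
    else:  # strategy C
        if config.regions is None:
            raise ValueError("strategy C needs a region list")
        if map_records is None:
            raise ValueError("strategy C needs map records for SNP positions")
        pos_of = {m.snp_id: (m.chromosome, m.position) for m in map_records}
        snp_idx = []
        for i in dataset.genotype_indices():
            chrom, pos = pos_of[dataset.columns[i].label]
            # .map positions are 1-based; regions are 0-based half-open
            if any(c == chrom and start <= pos - 1 < end for c, start, end in config.regions):
                snp_idx.append(i)
        if not snp_idx:
            warnings.warn("strategy C: no SNPs fall inside the given regions", UserWarning)
            blocks, block_names = [], []
        else:
            blocks = [dataset.subset_columns(snp_idx + pheno_idx)]
            block_names = ["regions"]

    reports = [_run_block(b, config, priors) for b in blocks]
    merged = {
        "strategy": config.strategy,
        "threshold": config.threshold,
        "blocks": dict(zip(block_names, reports)),
        "interactions": [g for r in reports for g in r["phenotype_associated"]],
    }
    return merged
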