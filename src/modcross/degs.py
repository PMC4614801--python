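"""SAM-style differential expression calling and cross-dataset integration.

Per-dataset calls use the relative-difference statistic

    d_i = (mean_disease - mean_normal) / (s_i + s0)

where ``s_i`` is the pooled standard error of the gene and ``s0`` a small
"fudge" constant that stabilises genes with near-zero variance.  Significance
is assessed by permuting group labels: a symmetric cutoff on ``|d|`` is chosen
so that the permutation-estimated false discovery rate (median permuted
exceedance count over the number of called genes) stays at or below the
requested target.

Calls from several datasets of one disease context are integrated under two
rules: a gene must be called in at least two datasets, and every call must
agree in direction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DISEASE = "disease"
NORMAL = "normal"
UP = "up"
DOWN = "down"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """One study's log-scale expression matrix with two-group sample labels."""

    dataset_id: str
    genes: list[str]
    samples: list[str]
    values: np.ndarray  # genes x samples
    group_labels: dict[str, str]  # sample -> disease|normal

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"{self.dataset_id}: duplicate gene ids")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"{self.dataset_id}: matrix shape {self.values.shape} does not "
                f"match {len(self.genes)} genes x {len(self.samples)} samples"
            )
        missing = [s for s in self.samples if s not in self.group_labels]
        if missing:
            raise ValueError(f"{self.dataset_id}: unlabeled samples {missing[:5]}")
        bad = {g for g in self.group_labels.values()} - {DISEASE, NORMAL}
        if bad:
            raise ValueError(f"{self.dataset_id}: unknown group labels {bad}")
        for grp in (DISEASE, NORMAL):
            if int(self.group_mask(grp).sum()) < 2:
                raise ValueError(
                    f"{self.dataset_id}: group '{grp}' has fewer than 2 samples"
                )

    def group_mask(self, group: str) -> np.ndarray:
        return np.array([self.group_labels[s] == group for s in self.samples])


@dataclass(frozen=True)
class DEGRecord:
    """A single differential-expression call within one dataset."""

    gene: str
    d_stat: float
    direction: str  # up|down, disease relative to normal
    q_value: float

    def __post_init__(self) -> None:
        if self.direction not in (UP, DOWN):
            raise ValueError(f"bad direction {self.direction!r}")
        if (self.d_stat > 0) != (self.direction == UP):
            raise ValueError(f"{self.gene}: direction inconsistent with d sign")
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError(f"{self.gene}: q={self.q_value} outside [0,1]")


@dataclass
class IntegratedDEGSet:
    """Direction-consistent DEGs supported by at least two datasets."""

    context: str
    members: dict[str, str] = field(default_factory=dict)  # gene -> up|down
    support: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, direction in self.members.items():
            if direction not in (UP, DOWN):
                raise ValueError(f"{gene}: bad direction {direction!r}")
            if gene not in self.support or not self.support[gene]:
                raise ValueError(f"{gene}: member without support")

    def genes(self) -> set[str]:
        return set(self.members)

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# statistic
# ---------------------------------------------------------------------------

def pooled_standard_errors(dataset: ExpressionDataset) -> np.ndarray:
    """Gene-wise pooled standard error s_i of the two-group mean difference."""
    dz = dataset.group_mask(DISEASE)
    nz = dataset.group_mask(NORMAL)
    return _pooled_se(dataset.values, dz, nz)


def _pooled_se(x: np.ndarray, dz: np.ndarray, nz: np.ndarray) -> np.ndarray:
    n1, n2 = int(dz.sum()), int(nz.sum())
    ss1 = ((x[:, dz] - x[:, dz].mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss2 = ((x[:, nz] - x[:, nz].mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    pooled_var = (ss1 + ss2) / (n1 + n2 - 2)
    return np.sqrt((1.0 / n1 + 1.0 / n2) * pooled_var)


def sam_statistic(
    dataset: ExpressionDataset,
    s0: float | None = None,
    on_zero_variance: str = "error",
) -> pd.Series:
    """Relative difference d per gene, disease minus normal.

    ``s0=None`` uses the median of the gene-wise pooled standard errors.
    With ``s0=0`` a zero-variance gene makes the denominator vanish;
    ``on_zero_variance`` selects between raising and returning +/-inf.
    """
    dz = dataset.group_mask(DISEASE)
    nz = dataset.group_mask(NORMAL)
    se = _pooled_se(dataset.values, dz, nz)
    if s0 is None:
        s0 = float(np.median(se))
    if s0 < 0:
        raise ValueError("s0 must be nonnegative")
    num = dataset.values[:, dz].mean(axis=1) - dataset.values[:, nz].mean(axis=1)
    denom = se + s0
    if np.any(denom == 0):
        if on_zero_variance == "error":
            bad = [g for g, dn in zip(dataset.genes, denom) if dn == 0]
            raise ZeroDivisionError(
                f"{dataset.dataset_id}: zero pooled SE with s0=0 for {bad[:5]}"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(denom == 0, np.sign(num) * np.inf, num / np.maximum(denom, 1e-300))
            d = np.where((denom == 0) & (num == 0), 0.0, d)
    else:
        d = num / denom
    return pd.Series(d, index=dataset.genes, name="d")


# ---------------------------------------------------------------------------
# permutation FDR calling
# ---------------------------------------------------------------------------

def _permutation_masks(
    n_samples: int, n_disease: int, n_permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean masks (perm x sample), disease positions per permutation.

    All distinct label assignments are enumerated when there are no more of
    them than ``n_permutations``; otherwise that many are drawn at random.
    """
    total = math.comb(n_samples, n_disease)
    if total <= n_permutations:
        masks = np.zeros((total, n_samples), dtype=bool)
        for i, idx in enumerate(combinations(range(n_samples), n_disease)):
            masks[i, list(idx)] = True
        return masks
    masks = np.zeros((n_permutations, n_samples), dtype=bool)
    for i in range(n_permutations):
        masks[i, rng.choice(n_samples, size=n_disease, replace=False)] = True
    return masks


def call_degs(
    dataset: ExpressionDataset,
    fdr_target: float = 0.01,
    n_permutations: int = 100,
    rng_seed: int = 0,
    s0: float | None = None,
) -> list[DEGRecord]:
    """Call DEGs at a symmetric |d| cutoff with permutation-estimated FDR.

    The cutoff is the smallest observed |d| whose estimated FDR (median count
    of permuted |d| values above the cutoff, divided by the number of genes
    called at it) stays at or below ``fdr_target``.  Returns an empty list,
    with a log message, when no cutoff achieves the target.
    """
    if not 0.0 < fdr_target < 1.0:
        raise ValueError("fdr_target must be in (0,1)")
    rng = np.random.default_rng(rng_seed)
    d_obs = sam_statistic(dataset, s0=s0).to_numpy()
    abs_obs = np.abs(d_obs)

    dz = dataset.group_mask(DISEASE)
    n_dis = int(dz.sum())
    masks = _permutation_masks(len(dataset.samples), n_dis, n_permutations, rng)

    se = pooled_standard_errors(dataset)
    s0_val = float(np.median(se)) if s0 is None else float(s0)

    x = dataset.values
    abs_perm_sorted = np.empty((masks.shape[0], x.shape[0]))
    for i, mz in enumerate(masks):
        nzp = ~mz
        sep = _pooled_se(x, mz, nzp)
        dp = (x[:, mz].mean(axis=1) - x[:, nzp].mean(axis=1)) / (sep + s0_val)
        abs_perm_sorted[i] = np.sort(np.abs(dp))

    # candidate cutoffs = observed |d| in descending order; R(t) = rank
    order = np.argsort(-abs_obs, kind="stable")
    thresholds = abs_obs[order]
    n_called = np.arange(1, len(thresholds) + 1, dtype=float)
    # permuted exceedance counts at every cutoff, per permutation
    exceed = np.empty((masks.shape[0], len(thresholds)))
    for i in range(masks.shape[0]):
        exceed[i] = x.shape[0] - np.searchsorted(
            abs_perm_sorted[i], thresholds, side="left"
        )
    fdr_at = np.median(exceed, axis=0) / n_called
    # gene-wise q: FDR at the gene's own cutoff, made monotone in |d|
    q_sorted = np.minimum(np.minimum.accumulate(fdr_at[::-1])[::-1], 1.0)

    ok = np.nonzero(fdr_at <= fdr_target)[0]
    if ok.size == 0:
        logger.info(
            "%s: no |d| cutoff achieves FDR <= %g; no genes called",
            dataset.dataset_id, fdr_target,
        )
        return []
    k = int(ok[-1])  # smallest qualifying cutoff -> most genes called
    records = []
    for rank in range(k + 1):
        g = int(order[rank])
        d = float(d_obs[g])
        if d == 0.0:
            continue
        records.append(
            DEGRecord(
                gene=dataset.genes[g],
                d_stat=d,
                direction=UP if d > 0 else DOWN,
                q_value=float(q_sorted[rank]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# integration across datasets
# ---------------------------------------------------------------------------

def integrate_degs(
    tables: Sequence[tuple[str, Sequence[DEGRecord]]],
    context: str = "inflammation",
    min_datasets: int = 2,
) -> IntegratedDEGSet:
    """Keep genes called in >= ``min_datasets`` datasets with one direction."""
    if not tables:
        raise ValueError("no DEG tables supplied")
    ids = [t[0] for t in tables]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate dataset ids in {ids}")
    calls: dict[str, list[tuple[str, str]]] = {}
    for dataset_id, records in tables:
        for rec in records:
            calls.setdefault(rec.gene, []).append((dataset_id, rec.direction))
    members: dict[str, str] = {}
    support: dict[str, list[str]] = {}
    for gene, entries in calls.items():
        if len(entries) < min_datasets:
            continue
        directions = {direction for _, direction in entries}
        if len(directions) != 1:
            continue
        members[gene] = entries[0][1]
        support[gene] = sorted(ds for ds, _ in entries)
    return IntegratedDEGSet(context=context, members=members, support=support)


def set_overlap(
    a: IntegratedDEGSet, b: IntegratedDEGSet
) -> tuple[set[str], set[str], set[str]]:
    """(shared, a-only, b-only) partition of the two member universes."""
    ga, gb = a.genes(), b.genes()
    return ga & gb, ga - gb, gb - ga


# ---------------------------------------------------------------------------
# TSV round-trips (generator's expression format; stage outputs)
# ---------------------------------------------------------------------------

def read_expression(
    matrix_path: str | Path, labels_path: str | Path, dataset_id: str | None = None
) -> ExpressionDataset:
    """Read a genes-x-samples TSV plus a two-column sample->group label file."""
    matrix_path = Path(matrix_path)
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    labels = pd.read_csv(labels_path, sep="\t", index_col=0, header=None).iloc[:, 0]
    return ExpressionDataset(
        dataset_id=dataset_id or matrix_path.stem,
        genes=[str(g) for g in df.index],
        samples=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
        group_labels={str(k): str(v) for k, v in labels.items()},
    )


def write_expression(dataset: ExpressionDataset, matrix_path, labels_path) -> None:
    df = pd.DataFrame(dataset.values, index=dataset.genes, columns=dataset.samples)
    df.index.name = "gene"
    df.to_csv(matrix_path, sep="\t", float_format="%.6g")
    with open(labels_path, "w") as fh:
        for s in dataset.samples:
            fh.write(f"{s}\t{dataset.group_labels[s]}\n")


def write_deg_table(path, dataset_id: str, records: Iterable[DEGRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("gene\td\tdirection\tq\tdataset\n")
        for r in records:
            fh.write(f"{r.gene}\t{r.d_stat:.6g}\t{r.direction}\t{r.q_value:.6g}\t{dataset_id}\n")


def read_deg_table(path) -> tuple[str, list[DEGRecord]]:
    df = pd.read_csv(path, sep="\t")
    ids = df["dataset"].unique()
    if len(ids) != 1:
        raise ValueError(f"{path}: expected one dataset id, found {list(ids)}")
    records = [
        DEGRecord(gene=str(r.gene), d_stat=float(r.d), direction=str(r.direction),
                  q_value=float(r.q))
        for r in df.itertuples()
    ]
    return str(ids[0]), records


def write_integrated_set(path, integrated: IntegratedDEGSet) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tdirection\tsupport\tcontext\n")
        for gene in sorted(integrated.members):
            fh.write(
                f"{gene}\t{integrated.members[gene]}\t"
                f"{','.join(integrated.support[gene])}\t{integrated.context}\n"
            )


def read_integrated_set(path) -> IntegratedDEGSet:
    df = pd.read_csv(path, sep="\t")
    if len(df) == 0:
        return IntegratedDEGSet(context="unknown")
    context = str(df["context"].iloc[0])
    members = {str(r.gene): str(r.direction) for r in df.itertuples()}
    support = {str(r.gene): str(r.support).split(",") for r in df.itertuples()}
    return IntegratedDEGSet(context=context, members=members, support=support)
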