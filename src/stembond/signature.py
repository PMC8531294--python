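"""Stiffness-signature expression statistics.

These statistics summarise a per-gene differential-expression table
(log2 fold change soft-over-stiff, adjusted p-value, gene-cluster label)
without re-estimating differential expression itself:

* cumulative log2fc of a gene cluster (genes with |log2fc| above a floor),
  whose endpoint measures the systematic direction of a cluster's response
  to substrate softening;
* up/down direction fractions among significantly changed genes of a
  cluster (e.g. pre-implantation genes mostly up on soft, post-implantation
  genes mostly down);
* concordance of ERK-target regulation with substrate softening (activated
  targets down, suppressed targets up on soft substrates);
* a permutation test for whether a selection of genes responds
  systematically, comparing its mean log2fc with that of random gene sets
  of the same size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CLUSTER_LABELS",
    "CumulativeResult",
    "DirectionSummary",
    "ErkConcordance",
    "PermutationResult",
    "validate_expression_table",
    "cumulative_log2fc",
    "direction_fractions",
    "erk_concordance",
    "permutation_systematic",
]

CLUSTER_LABELS = (
    "pre_implantation",
    "post_implantation",
    "naive",
    "formative",
    "general",
    "erk_activated",
    "erk_suppressed",
    "none",
)

REQUIRED_COLUMNS = ("gene_id", "log2fc", "padj", "cluster")


def validate_expression_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the per-gene table contract and return it unchanged.

    Required columns: gene_id, log2fc, padj, cluster (an optional
    ``condition`` column labels the medium/timepoint).  padj must lie in
    [0, 1], gene ids must be unique within a condition, and cluster labels
    must come from the fixed vocabulary.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"expression table is missing columns: {missing}")
    if ((table["padj"] < 0) | (table["padj"] > 1)).any():
        raise ValueError("padj values must lie in [0, 1]")
    bad = set(table["cluster"].unique()) - set(CLUSTER_LABELS)
    if bad:
        raise ValueError(f"unknown cluster labels: {sorted(bad)}")
    group = ["condition", "gene_id"] if "condition" in table.columns else ["gene_id"]
    if table.duplicated(subset=group).any():
        raise ValueError("gene ids must be unique within a condition")
    return table


@dataclass(frozen=True)
class CumulativeResult:
    condition: str
    cluster: str
    included_genes: int
    series: np.ndarray  # running cumulative sums over the documented order
    endpoint: float  # sum of included log2fc; independent of gene ordering


@dataclass(frozen=True)
class DirectionSummary:
    cluster: str
    pct_up: float | None  # % of direction-called significant genes with log2fc > 0
    pct_down: float | None
    n_significant: int

    @property
    def defined(self) -> bool:
        return self.pct_up is not None


@dataclass(frozen=True)
class ErkConcordance:
    activated: DirectionSummary
    suppressed: DirectionSummary
    mean_abs_log2fc_erk: float
    mean_abs_log2fc_nontarget: float | None  # None when the table has no background genes


@dataclass(frozen=True)
class PermutationResult:
    observed_statistic: float
    null_distribution: np.ndarray
    p_value: float
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError("p_value must lie in (0, 1]")


def _cluster_rows(table: pd.DataFrame, cluster: str) -> pd.DataFrame:
    if cluster not in CLUSTER_LABELS:
        raise ValueError(f"unknown cluster label {cluster!r}")
    if cluster not in set(table["cluster"]):
        raise ValueError(f"cluster {cluster!r} not present in the table")
    return table[table["cluster"] == cluster]


def cumulative_log2fc(
    table: pd.DataFrame, cluster: str, min_abs: float = 0.2, condition: str = ""
) -> CumulativeResult:
    """Cumulative sum of log2fc over a cluster's genes with |log2fc| > min_abs.

    Genes are ordered by descending |log2fc| (ties broken by gene id) so the
    running series is deterministic; the endpoint is the plain sum and does
    not depend on the ordering.
    """
    rows = _cluster_rows(table, cluster)
    rows = rows[rows["log2fc"].abs() > min_abs]
    rows = rows.assign(_absfc=rows["log2fc"].abs()).sort_values(
        ["_absfc", "gene_id"], ascending=[False, True]
    )
    series = rows["log2fc"].to_numpy(dtype=float).cumsum()
    endpoint = float(series[-1]) if series.size else 0.0
    return CumulativeResult(
        condition=condition,
        cluster=cluster,
        included_genes=int(series.size),
        series=series,
        endpoint=endpoint,
    )


def direction_fractions(
    table: pd.DataFrame, cluster: str, padj_threshold: float = 0.05
) -> DirectionSummary:
    """Percentages of significantly up/down-regulated genes in a cluster.

    Considers genes with padj < padj_threshold; genes with log2fc exactly 0
    carry no direction and are excluded from the denominator.  With no
    direction-called significant genes the percentages are undefined
    (``None``), flagged rather than raised.
    """
    rows = _cluster_rows(table, cluster)
    sig = rows[rows["padj"] < padj_threshold]
    called = sig[sig["log2fc"] != 0]
    n = len(called)
    if n == 0:
        return DirectionSummary(cluster=cluster, pct_up=None, pct_down=None, n_significant=0)
    n_up = int((called["log2fc"] > 0).sum())
    return DirectionSummary(
        cluster=cluster,
        pct_up=100.0 * n_up / n,
        pct_down=100.0 * (n - n_up) / n,
        n_significant=n,
    )


def erk_concordance(table: pd.DataFrame, padj_threshold: float = 0.05) -> ErkConcordance:
    """Direction fractions for ERK-activated and ERK-suppressed target genes,
    plus the mean |log2fc| of ERK targets versus non-target genes."""
    activated = direction_fractions(table, "erk_activated", padj_threshold)
    suppressed = direction_fractions(table, "erk_suppressed", padj_threshold)
    erk = table[table["cluster"].isin(["erk_activated", "erk_suppressed"])]
    background = table[table["cluster"] == "none"]
    mean_nontarget = (
        float(background["log2fc"].abs().mean()) if len(background) else None
    )
    return ErkConcordance(
        activated=activated,
        suppressed=suppressed,
        mean_abs_log2fc_erk=float(erk["log2fc"].abs().mean()),
        mean_abs_log2fc_nontarget=mean_nontarget,
    )


def permutation_systematic(
    table: pd.DataFrame,
    gene_set: list[str],
    n_permutations: int = 999,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test for a systematic soft-vs-stiff shift of a gene set.

    The observed statistic is the mean log2fc of ``gene_set``.  The null
    draws random gene sets of identical size without replacement from the
    whole table and recomputes the statistic.  The two-sided p-value uses
    the add-one correction

        p = (1 + #{|null| >= |observed|}) / (n_permutations + 1)

    and is therefore never exactly zero.  Fully reproducible given ``seed``.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    gene_set = list(gene_set)
    genes = table["gene_id"].to_numpy()
    log2fc = table["log2fc"].to_numpy(dtype=float)
    if len(gene_set) > len(genes):
        raise ValueError("gene_set is larger than the table")
    idx = pd.Index(genes)
    positions = idx.get_indexer(gene_set)
    if (positions < 0).any():
        missing = [g for g, p in zip(gene_set, positions) if p < 0]
        raise ValueError(f"gene_set members not in the table: {missing[:5]}")
    observed = float(np.mean(log2fc[positions]))

    rng = np.random.default_rng(seed)
    k = len(gene_set)
    n = len(genes)
    if k == n:
        null = np.full(n_permutations, observed)
    else:
        # vectorised sampling without replacement: the k smallest of n
        # uniforms per permutation index a uniform random k-subset
        u = rng.random((n_permutations, n))
        subset = np.argpartition(u, k - 1, axis=1)[:, :k]
        null = log2fc[subset].mean(axis=1)
    p = (1.0 + np.count_nonzero(np.abs(null) >= abs(observed))) / (n_permutations + 1.0)
    return PermutationResult(
        observed_statistic=observed,
        null_distribution=null,
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
    )
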