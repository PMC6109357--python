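"""Single-cell QC, pairwise differential expression, consensus markers, enrichment.

The marker-calling contract: cells below a minimum library size are dropped,
then sparsely detected genes; differential expression is computed for every
ordered pair of clusters (built-in seeded permutation test on median-library
normalized means, or an external table ingested verbatim); a gene is a
cluster marker when it is significantly upregulated (q <= 0.05) in at least
k of that cluster's pairwise comparisons (default k = n_pairs - 1).
Term enrichment is an upper-tail hypergeometric test with mode-specific
inclusion rules (pathway mode: p < 0.05; ontology mode: additionally more
upregulated than downregulated members and at least two upregulated).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import CountTable


@dataclass(frozen=True)
class QCParams:
    min_library: int = 500
    min_gene_reads: int = 10
    min_cells_detected: int = 5

    def __post_init__(self) -> None:
        if min(self.min_library, self.min_gene_reads, self.min_cells_detected) < 1:
            raise ValueError("QC parameters must be >= 1")


@dataclass(frozen=True)
class PairwiseDE:
    gene: str
    cluster_a: str
    cluster_b: str
    log2fc: float  # a over b
    p: float
    q: float


@dataclass(frozen=True)
class MarkerCall:
    gene: str
    cluster: str
    n_pairs_up_significant: int
    n_pairs_total: int
    is_marker: bool


@dataclass(frozen=True)
class FractionRatioMarker:
    gene: str
    cluster: str
    fraction_expressing: float
    expression_ratio: float
    is_marker: bool


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    N: int
    K: int
    n: int
    k: int
    p: float
    enriched: bool
    k_up: int
    k_down: int


# ---------------------------------------------------------------------------
# QC


def qc_filter(
    counts: CountTable,
    labels: Mapping[str, str],
    params: QCParams | None = None,
) -> tuple[CountTable, dict[str, str]]:
    """Drop low-depth cells, then sparsely detected genes (order fixed)."""
    params = params or QCParams()
    missing = [c for c in counts.col_ids if c not in labels]
    if missing:
        raise ValueError(f"cells without cluster labels: {missing[:5]}")
    lib = counts.counts.sum(axis=0)
    keep_cells = lib >= params.min_library
    if not keep_cells.any():
        raise ValueError("QC removed every cell")
    sub = counts.counts[:, keep_cells]
    col_ids = [c for c, k in zip(counts.col_ids, keep_cells) if k]
    total = sub.sum(axis=1)
    detected = (sub > 0).sum(axis=1)
    keep_genes = (total >= params.min_gene_reads) & (
        detected >= params.min_cells_detected
    )
    table = CountTable(
        [r for r, k in zip(counts.row_ids, keep_genes) if k],
        col_ids,
        sub[keep_genes],
    )
    return table, {c: labels[c] for c in col_ids}


# ---------------------------------------------------------------------------
# Normalization and pairwise DE


def median_library_normalize(counts: np.ndarray) -> np.ndarray:
    """Scale each cell (column) to the median library size."""
    lib = counts.sum(axis=0).astype(float)
    if np.any(lib == 0):
        raise ValueError("cell with zero library size")
    return counts * (np.median(lib) / lib)[None, :]


def _cluster_cells(labels: Mapping[str, str], col_ids: Sequence[str]) -> dict[str, np.ndarray]:
    clusters: dict[str, list[int]] = {}
    for j, c in enumerate(col_ids):
        clusters.setdefault(labels[c], []).append(j)
    return {k: np.asarray(v) for k, v in sorted(clusters.items())}


def pairwise_de(
    counts: CountTable,
    labels: Mapping[str, str],
    n_perm: int = 1000,
    seed: int = 0,
) -> list[PairwiseDE]:
    """Built-in engine: seeded permutation test on the absolute log2 fold change
    of add-one shifted cluster means, BH-adjusted within each cluster pair.

    Emits both ordered directions for every cluster pair (log2fc antisymmetric,
    p and q shared).
    """
    clusters = _cluster_cells(labels, counts.col_ids)
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    small = [c for c, idx in clusters.items() if len(idx) < 3]
    if small:
        raise ValueError(f"clusters with < 3 cells: {small}")
    norm = median_library_normalize(counts.counts)
    genes = counts.row_ids
    rng = np.random.default_rng(seed)
    out: list[PairwiseDE] = []
    for a, b in itertools.combinations(sorted(clusters), 2):
        ia, ib = clusters[a], clusters[b]
        X = norm[:, np.concatenate([ia, ib])]
        n_a, n_cells = len(ia), len(ia) + len(ib)
        mean_a = X[:, :n_a].mean(axis=1)
        mean_b = X[:, n_a:].mean(axis=1)
        obs = np.log2((mean_a + 1.0) / (mean_b + 1.0))
        # permutation null on |log2fc|
        order = np.argsort(rng.random((n_perm, n_cells)), axis=1)
        mask = np.zeros((n_perm, n_cells))
        np.put_along_axis(mask, order[:, :n_a], 1.0, axis=1)
        sums = X @ mask.T  # genes x n_perm: sum over permuted group A
        tot = X.sum(axis=1, keepdims=True)
        ma = sums / n_a
        mb = (tot - sums) / (n_cells - n_a)
        null = np.log2((ma + 1.0) / (mb + 1.0))
        exceed = (np.abs(null) >= np.abs(obs)[:, None]).sum(axis=1)
        p = (exceed + 1.0) / (n_perm + 1.0)
        q = multipletests(p, method="fdr_bh")[1]
        for g, lfc, pv, qv in zip(genes, obs, p, q):
            out.append(PairwiseDE(g, a, b, float(lfc), float(pv), float(qv)))
            out.append(PairwiseDE(g, b, a, float(-lfc), float(pv), float(qv)))
    return out


def read_pairwise_de(path) -> list[PairwiseDE]:
    """Ingest an external DE table (TSV: gene, cluster_a, cluster_b, log2fc, p, q)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "cluster_a", "cluster_b", "log2fc", "p", "q"}
    if not required <= set(df.columns):
        raise ValueError(f"DE table missing columns {sorted(required - set(df.columns))}")
    return [
        PairwiseDE(str(r.gene), str(r.cluster_a), str(r.cluster_b),
                   float(r.log2fc), float(r.p), float(r.q))
        for r in df.itertuples()
    ]


def write_pairwise_de(de: Sequence[PairwiseDE], path) -> None:
    pd.DataFrame(
        [(d.gene, d.cluster_a, d.cluster_b, d.log2fc, d.p, d.q) for d in de],
        columns=["gene", "cluster_a", "cluster_b", "log2fc", "p", "q"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Consensus markers


def consensus_markers(
    de: Sequence[PairwiseDE],
    q_max: float = 0.05,
    k_required: int | None = None,
) -> list[MarkerCall]:
    """A gene marks cluster c when up-significant (q <= q_max, log2fc > 0) in at
    least ``k_required`` of c's pairwise comparisons (default n_pairs - 1)."""
    clusters = sorted({d.cluster_a for d in de} | {d.cluster_b for d in de})
    genes = sorted({d.gene for d in de})
    by_key: dict[tuple[str, str, str], PairwiseDE] = {}
    for d in de:
        by_key[(d.gene, d.cluster_a, d.cluster_b)] = d
    n_pairs = len(clusters) - 1
    k_req = n_pairs - 1 if k_required is None else k_required
    out: list[MarkerCall] = []
    for g in genes:
        for c in clusters:
            n_up = 0
            for b in clusters:
                if b == c:
                    continue
                d = by_key.get((g, c, b))
                if d is None:
                    rev = by_key.get((g, b, c))
                    if rev is None:
                        raise ValueError(f"missing DE pair ({c}, {b}) for gene {g!r}")
                    d = PairwiseDE(g, c, b, -rev.log2fc, rev.p, rev.q)
                if d.q <= q_max and d.log2fc > 0:
                    n_up += 1
            out.append(MarkerCall(g, c, n_up, n_pairs, n_up >= k_req))
    return out


def fraction_ratio_markers(
    counts: CountTable,
    labels: Mapping[str, str],
    min_frac: float = 0.25,
    min_ratio: float = 1.25,
) -> list[FractionRatioMarker]:
    """Detection-fraction and mean-expression-ratio marker criteria (no test):
    expressed in >= 25% of the cluster's cells and mean normalized expression
    >= 1.25x the mean over all other cells (both inclusive)."""
    clusters = _cluster_cells(labels, counts.col_ids)
    norm = median_library_normalize(counts.counts)
    raw = counts.counts
    out: list[FractionRatioMarker] = []
    all_idx = np.arange(len(counts.col_ids))
    for c, idx in clusters.items():
        rest = np.setdiff1d(all_idx, idx)
        frac = (raw[:, idx] > 0).mean(axis=1)
        mean_c = norm[:, idx].mean(axis=1)
        mean_rest = norm[:, rest].mean(axis=1) if len(rest) else np.zeros(len(counts.row_ids))
        for i, g in enumerate(counts.row_ids):
            if mean_rest[i] > 0:
                ratio = mean_c[i] / mean_rest[i]
            else:
                ratio = float("inf") if mean_c[i] > 0 else 0.0
            ok = frac[i] >= min_frac and mean_c[i] >= min_ratio * mean_rest[i] and mean_c[i] > 0
            out.append(FractionRatioMarker(g, c, float(frac[i]), float(ratio), bool(ok)))
    return out


# ---------------------------------------------------------------------------
# Hypergeometric enrichment


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P[X >= k] for drawing n from a
    population of N containing K successes."""
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N} K={K} n={n} k={k}")
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def enrich(
    term_sets: Mapping[str, Iterable[str]],
    de_for_one_comparison: Sequence[PairwiseDE],
    mode: str,
    log2fc_up: float = 1.0,
    log2fc_down: float = -1.0,
    alpha: float = 0.05,
    q_max: float = 0.05,
    direction: str = "up",
) -> list[EnrichmentResult]:
    """Term over-representation for one cluster comparison.

    Population = genes tested in the comparison carrying >= 1 annotation.
    Up set = significant (q <= q_max) genes with log2fc > ``log2fc_up``;
    the down set is symmetric.  ``kegg`` mode: enriched iff p < alpha.
    ``go`` mode: enriched iff p < alpha AND k_up > k_down AND k_up >= 2.
    """
    if mode not in {"kegg", "go"}:
        raise ValueError(f"unknown enrichment mode {mode!r}")
    if direction not in {"up", "down"}:
        raise ValueError(f"unknown direction {direction!r}")
    annotated = {g for gs in term_sets.values() for g in gs}
    tested = {d.gene for d in de_for_one_comparison}
    population = tested & annotated
    if not population:
        raise ValueError("empty enrichment population (no tested gene is annotated)")
    best: dict[str, PairwiseDE] = {}
    for d in de_for_one_comparison:
        best[d.gene] = d
    up = {g for g, d in best.items()
          if g in population and d.q <= q_max and d.log2fc > log2fc_up}
    down = {g for g, d in best.items()
            if g in population and d.q <= q_max and d.log2fc < log2fc_down}
    sig = up if direction == "up" else down
    out: list[EnrichmentResult] = []
    for term, gs in sorted(term_sets.items()):
        members = set(gs) & population
        if not members:
            continue
        N, K, n = len(population), len(members), len(sig)
        k = len(members & sig)
        p = hypergeom_upper(N, K, n, k)
        k_up = len(members & up)
        k_down = len(members & down)
        if mode == "kegg":
            enriched = p < alpha
        else:
            enriched = p < alpha and k_up > k_down and k_up >= 2
        out.append(EnrichmentResult(term, N, K, n, k, p, enriched, k_up, k_down))
    return out
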