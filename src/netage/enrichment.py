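"""Pre-ranked gene set enrichment on differential-targeting statistics.

Genes are ranked by a signed statistic (here: the t-statistic of the age
coefficient from the differential-targeting model). For each gene set a
weighted Kolmogorov-Smirnov-like running sum walks the ranked list, rising
by ``|stat| / sum(|stat| over hits)`` at member genes and falling by
``1 / (N - N_hit)`` elsewhere; the enrichment score (ES) is the extremum of
largest magnitude, signed. Significance comes from a null of random gene
sets of matching size drawn from the ranked universe (exact enumeration of
all same-size sets when that space is small); the normalized enrichment
score (NES) divides ES by the mean magnitude of same-sign null scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "enrichment_score",
    "preranked_gsea",
    "bh_adjust",
]

#: above this many same-size subsets the null switches from exhaustive
#: enumeration to random sampling.
ENUMERATION_LIMIT = 100_000


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets (GMT-style)."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} is empty")
        if len(self.sets) != len(set(self.sets)):
            raise ValueError("duplicate gene set names")

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


def _ranked_order(ranked: pd.Series) -> pd.Series:
    """Sort descending by statistic, ties broken by stable gene-id order."""
    if ranked.index.duplicated().any():
        raise ValueError("duplicate genes in ranking")
    if not np.isfinite(ranked.to_numpy(dtype=float)).all():
        raise ValueError("ranking statistics must be finite")
    df = ranked.rename("stat").rename_axis("gene").reset_index()
    df = df.sort_values(["stat", "gene"], ascending=[False, True], kind="stable")
    return pd.Series(df["stat"].to_numpy(), index=df["gene"])


def enrichment_score(ranked: pd.Series, gene_set: list[str]) -> float:
    """Signed weighted-KS enrichment score of one set against a ranking."""
    ordered = _ranked_order(ranked)
    hit = ordered.index.isin(set(gene_set))
    return _es_from_hits(ordered.to_numpy(dtype=float), np.nonzero(hit)[0])


def _es_from_hits(stats_sorted: np.ndarray, hit_pos: np.ndarray) -> float:
    """ES given sorted |stat| positions of the set members (0-based).

    The running sum is piecewise linear between hits, so its extrema occur
    immediately before or after a hit; only those 2k points are evaluated.
    """
    n = stats_sorted.size
    k = hit_pos.size
    if k == 0 or k == n:
        return 0.0
    w = np.abs(stats_sorted[hit_pos])
    total = w.sum()
    if total == 0:
        w = np.ones(k)
        total = float(k)
    cum = np.cumsum(w) / total
    miss = 1.0 / (n - k)
    # after hit i: cum[i] - (misses so far) * miss ; before hit i: cum[i-1] - ...
    misses_before = hit_pos - np.arange(k)
    after = cum - misses_before * miss
    before = np.concatenate([[0.0], cum[:-1]]) - misses_before * miss
    hi = after.max()
    lo = min(before.min(), 0.0)
    return float(hi if hi >= -lo else lo)


def _null_scores(
    stats_sorted: np.ndarray,
    k: int,
    n_perm: int,
    rng: np.random.Generator,
    perm_pool: np.ndarray | None = None,
) -> np.ndarray:
    """Null ES distribution for random same-size sets.

    Exhaustive over all C(n, k) position subsets when that count is within
    ``ENUMERATION_LIMIT``; otherwise ``n_perm`` random draws (reusing a
    shared permutation pool when given).
    """
    n = stats_sorted.size
    if comb(n, k) <= ENUMERATION_LIMIT:
        return np.array(
            [
                _es_from_hits(stats_sorted, np.asarray(c))
                for c in combinations(range(n), k)
            ]
        )
    if perm_pool is not None:
        picks = np.sort(perm_pool[:n_perm, :k], axis=1)
    else:
        picks = np.sort(
            np.array([rng.choice(n, size=k, replace=False) for _ in range(n_perm)]),
            axis=1,
        )
    return np.array([_es_from_hits(stats_sorted, row) for row in picks])


@dataclass
class EnrichmentResult:
    """Per-set ES/NES/p/FDR table plus the sets excluded by size bounds."""

    table: pd.DataFrame  # index: set name; columns: size, es, nes, p, fdr
    excluded: dict[str, int]

    def significant(self, fdr: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["fdr"] < fdr]


def preranked_gsea(
    ranked: pd.Series,
    sets: GeneSetCollection,
    min_size: int = 15,
    max_size: int = 500,
    n_perm: int = 10_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Pre-ranked GSEA over a gene set collection.

    Set sizes are counted after intersection with the ranked universe, and
    the bounds are strict: only sets with ``min_size < size < max_size``
    are tested. The nominal p-value is the same-sign permutation tail
    ``(1 + #{null with |null ES| >= |ES|, same sign}) / (1 + #same-sign)``,
    and FDR is Benjamini-Hochberg across retained sets.
    """
    ordered = _ranked_order(ranked)
    stats_sorted = ordered.to_numpy(dtype=float)
    pos = {g: i for i, g in enumerate(ordered.index)}
    n = len(pos)
    rng = np.random.default_rng(seed)

    # one shared pool of random index permutations serves every set size
    need_pool = any(
        comb(n, len({g for g in members if g in pos})) > ENUMERATION_LIMIT
        for members in sets.sets.values()
    )
    perm_pool = None
    if need_pool:
        perm_pool = np.argsort(rng.random((n_perm, n)), axis=1)

    rows = []
    excluded: dict[str, int] = {}
    for name, members in sets.items():
        hit_pos = np.sort(np.array([pos[g] for g in set(members) if g in pos], int))
        k = hit_pos.size
        if not (min_size < k < max_size):
            excluded[name] = k
            continue
        es = _es_from_hits(stats_sorted, hit_pos)
        null = _null_scores(stats_sorted, k, n_perm, rng, perm_pool)
        same = null[null >= 0] if es >= 0 else null[null < 0]
        if same.size == 0:
            p = 1.0 / (1.0 + null.size)
            nes = np.nan
        else:
            p = (1.0 + (np.abs(same) >= abs(es)).sum()) / (1.0 + same.size)
            denom = np.abs(same).mean()
            nes = es / denom if denom > 0 else np.nan
        rows.append({"set": name, "size": k, "es": es, "nes": nes, "p": p})
    table = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["size", "es", "nes", "p", "fdr"]
    )
    if len(table):
        table["fdr"] = bh_adjust(table["p"].to_numpy())
        table = table.sort_values("p", kind="stable")
    return EnrichmentResult(table=table, excluded=excluded)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-aligned to input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
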