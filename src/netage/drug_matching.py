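"""Drug-repurposing by regulatory-signature reversal matching.

Given the genes increasingly (``up``) and decreasingly (``down``) targeted
with age, each drug in a library of regulatory signatures (its own up/down
gene sets) is scored for *reversal*: a drug that down-targets the genes
aging up-targets, and vice versa, is a candidate geroprotector. The score
is a normalized four-cell overlap contrast,

    score = (|up n sig.down| + |down n sig.up|
             - |up n sig.up| - |down n sig.down|) / (|up| + |down|),

so +1 is perfect reversal and -1 perfect mimicry, and swapping a drug's
up/down sets negates its score exactly. Significance is empirical: the
same drug is scored against random input lists drawn from the gene
universe with sizes matched to the query (optionally jittered +/-20%, the
"varying lengths" null), and p = (1 + #{null >= observed}) / (1 + n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DrugSignature", "MatchResult", "reversal_score", "match_drugs"]


@dataclass
class DrugSignature:
    """A drug's regulatory signature: disjoint up/down gene sets."""

    drug_id: str
    up: set
    down: set

    def __post_init__(self) -> None:
        self.up = set(self.up)
        self.down = set(self.down)
        if self.up & self.down:
            raise ValueError(
                f"drug {self.drug_id!r}: up and down sets overlap"
            )


@dataclass
class MatchResult:
    """Per-drug reversal score with empirical p and the four overlap cells."""

    drug_id: str
    score: float
    p: float
    overlap: dict = field(default_factory=dict)


def reversal_score(
    up: list[str], down: list[str], sig: DrugSignature, universe: list[str] | None = None
) -> float:
    """Normalized overlap contrast between a query and one drug signature."""
    up_s, down_s = set(up), set(down)
    if not up_s and not down_s:
        raise ValueError("up and down query lists are both empty")
    if up_s & down_s:
        raise ValueError("query up and down lists overlap")
    if universe is not None:
        uni = set(universe)
        stray = (up_s | down_s | sig.up | sig.down) - uni
        if stray:
            raise ValueError(f"genes outside the universe, e.g. {next(iter(stray))!r}")
    good = len(up_s & sig.down) + len(down_s & sig.up)
    bad = len(up_s & sig.up) + len(down_s & sig.down)
    return (good - bad) / (len(up_s) + len(down_s))


def match_drugs(
    up: list[str],
    down: list[str],
    library: list[DrugSignature],
    universe: list[str],
    n_resamples: int = 10_000,
    seed: int = 0,
    vary_lengths: bool = False,
) -> list[MatchResult]:
    """Score every library drug against a query and attach resampling p-values.

    The null redraws the query: ``n_resamples`` random disjoint up/down
    lists sampled without replacement from ``universe`` with the query's
    sizes (``vary_lengths=True`` jitters each size uniformly by +/-20%),
    scored against the same drug. Results are sorted by score descending
    (p ascending on ties). Scoring is vectorized over membership masks.
    """
    if n_resamples < 100:
        raise ValueError("n_resamples must be >= 100")
    up_s, down_s = set(up), set(down)
    if not up_s or not down_s:
        raise ValueError("up and down query lists must be non-empty")
    n_up, n_down = len(up_s), len(down_s)
    genes = list(universe)
    g = len(genes)
    if g < n_up + n_down:
        raise ValueError("universe smaller than the combined query size")
    gi = {gene: i for i, gene in enumerate(genes)}

    rng = np.random.default_rng(seed)
    # drug membership masks (n_drugs x genes)
    d_up = np.zeros((len(library), g), dtype=np.float32)
    d_down = np.zeros((len(library), g), dtype=np.float32)
    for k, sig in enumerate(library):
        d_up[k, [gi[x] for x in sig.up if x in gi]] = 1.0
        d_down[k, [gi[x] for x in sig.down if x in gi]] = 1.0

    q_up = np.zeros(g, dtype=np.float32)
    q_down = np.zeros(g, dtype=np.float32)
    q_up[[gi[x] for x in up_s if x in gi]] = 1.0
    q_down[[gi[x] for x in down_s if x in gi]] = 1.0
    obs_good = d_down @ q_up + d_up @ q_down
    obs_bad = d_up @ q_up + d_down @ q_down
    obs = (obs_good - obs_bad) / (n_up + n_down)

    if vary_lengths:
        ups = rng.integers(
            max(1, int(0.8 * n_up)), int(np.ceil(1.2 * n_up)) + 1, n_resamples
        )
        downs = rng.integers(
            max(1, int(0.8 * n_down)), int(np.ceil(1.2 * n_down)) + 1, n_resamples
        )
    else:
        ups = np.full(n_resamples, n_up)
        downs = np.full(n_resamples, n_down)

    r_up = np.zeros((n_resamples, g), dtype=np.float32)
    r_down = np.zeros((n_resamples, g), dtype=np.float32)
    for i in range(n_resamples):
        pick = rng.choice(g, size=ups[i] + downs[i], replace=False)
        r_up[i, pick[: ups[i]]] = 1.0
        r_down[i, pick[ups[i] :]] = 1.0
    sizes = (ups + downs).astype(np.float32)
    null_good = r_down @ d_up.T + r_up @ d_down.T  # (resamples, drugs)
    null_bad = r_up @ d_up.T + r_down @ d_down.T
    null = (null_good - null_bad) / sizes[:, None]

    p = (1.0 + (null >= obs[None, :]).sum(axis=0)) / (1.0 + n_resamples)
    results = [
        MatchResult(
            drug_id=sig.drug_id,
            score=float(obs[k]),
            p=float(p[k]),
            overlap={
                "up_vs_down": int(len(up_s & sig.down)),
                "down_vs_up": int(len(down_s & sig.up)),
                "up_vs_up": int(len(up_s & sig.up)),
                "down_vs_down": int(len(down_s & sig.down)),
            },
        )
        for k, sig in enumerate(library)
    ]
    results.sort(key=lambda r: (-r.score, r.p))
    return results
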