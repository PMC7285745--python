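"""S-value ranking and hypergeometric validation of candidate lists.

Predictions are ranked by the signed confidence score

    S = 2 * (argmax(p) - 0.5) * max(p)

where p is the 2-class softmax output.  S lies in [-1, 1]; positive S means
the protein is predicted saliva-secretory, and |S| is the winning-class
probability.  At the exact tie p = (0.5, 0.5) the argmax resolves to index 0
(giving S = -0.5) and the score is flagged.

A ranked list is validated against a set of K known marker proteins inside a
population of N proteins by counting the overlap k within the top n and
scoring it under the hypergeometric distribution

    P(X = k) = C(K, k) * C(N-K, n-k) / C(N, n).

Both the point probability P(X = k) and the upper tail P(X >= k) are
available; published significance tables for this ranking protocol print the
point probability, so that is the default reported by
:func:`enrichment_table`, with the tail selectable (it is the standard
enrichment p-value and is the more conservative choice for new analyses).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

DEFAULT_TOPS = (1000, 2000, 3000, 4000)


@dataclass(frozen=True)
class PredictionScore:
    """A per-protein prediction: softmax pair, S-value, and tie flag."""

    id: str
    p: tuple[float, float]
    S: float
    tie_flagged: bool = False


@dataclass(frozen=True)
class EnrichmentQuery:
    """(N, K, n, k): population, marker-set size, top-list size, overlap."""

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self) -> None:
        if not (0 <= self.K <= self.N):
            raise ValueError("need 0 <= K <= N")
        if not (0 <= self.n <= self.N):
            raise ValueError("need 0 <= n <= N")
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValueError("need 0 <= k <= min(K, n)")


def s_value(p: Sequence[float]) -> float:
    """Signed confidence S = 2*(argmax(p) - 0.5)*max(p) of a softmax pair.

    At the tie p = (0.5, 0.5), argmax resolves to index 0 and S = -0.5.
    """
    p = np.asarray(p, dtype=np.float64)
    if p.shape != (2,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("p must be a nonnegative probability pair summing to 1")
    return float(2.0 * (np.argmax(p) - 0.5) * np.max(p))


def score_predictions(
    ids: Sequence[str], probs: np.ndarray
) -> list[PredictionScore]:
    """Build :class:`PredictionScore` objects from softmax outputs."""
    probs = np.asarray(probs, dtype=np.float64)
    if len(ids) != len(probs):
        raise ValueError("ids and probs must have equal lengths")
    out = []
    for pid, p in zip(ids, probs):
        out.append(
            PredictionScore(
                id=pid,
                p=(float(p[0]), float(p[1])),
                S=s_value(p),
                tie_flagged=bool(np.isclose(p[0], p[1])),
            )
        )
    return out


def rank_candidates(scores: Iterable[PredictionScore]) -> list[PredictionScore]:
    """Sort descending by S; ties break by id lexicographically."""
    scores = list(scores)
    ids = [s.id for s in scores]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids in ranking input")
    return sorted(scores, key=lambda s: (-s.S, s.id))


def hypergeom_point(q: EnrichmentQuery) -> float:
    """Point probability P(X = k) of the hypergeometric distribution."""
    return float(hypergeom.pmf(q.k, q.N, q.K, q.n))


def hypergeom_tail(q: EnrichmentQuery) -> float:
    """Upper-tail probability P(X >= k); equals 1 at k = 0."""
    return float(hypergeom.sf(q.k - 1, q.N, q.K, q.n))


def overlap_at_top(
    ranked_ids: Sequence[str],
    markers: Iterable[str],
    n: int,
) -> EnrichmentQuery:
    """Count marker overlap in the top n of a full-population ranking.

    ``ranked_ids`` must be the complete ranked population (N = its length).
    Markers absent from the population are excluded with a warning.
    """
    ranked_ids = list(ranked_ids)
    population = set(ranked_ids)
    if len(population) != len(ranked_ids):
        raise ValueError("ranked_ids contains duplicates")
    markers = set(markers)
    missing = markers - population
    if missing:
        warnings.warn(
            f"{len(missing)} marker id(s) absent from the ranked population "
            f"and excluded: {sorted(missing)[:5]}...",
            stacklevel=2,
        )
        markers = markers & population
    top = set(ranked_ids[:n])
    return EnrichmentQuery(
        N=len(ranked_ids), K=len(markers), n=n, k=len(top & markers)
    )


def enrichment_table(
    ranked_ids: Sequence[str],
    markers: Iterable[str],
    tops: Sequence[int] = DEFAULT_TOPS,
    statistic: str = "point",
) -> pd.DataFrame:
    """Overlap counts and hypergeometric probabilities at several list depths.

    ``statistic`` selects 'point' (P(X = k), the convention of published
    ranking-validation tables) or 'tail' (P(X >= k)).
    """
    if statistic not in ("point", "tail"):
        raise ValueError("statistic must be 'point' or 'tail'")
    fn = hypergeom_point if statistic == "point" else hypergeom_tail
    rows = []
    for n in tops:
        q = overlap_at_top(ranked_ids, markers, n)
        rows.append(
            {"top_n": n, "K": q.K, "k": q.k, "p_value": fn(q)}
        )
    return pd.DataFrame(rows)
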