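"""Template-based GO-term scoring, gain/loss comparison and enrichment.

Four evidence channels score each GO term: sequence homology hits
(identity-weighted bitscores), structure hits (additionally TM-score
weighted), PPI partners (STRING-score weighted) and domain matches
(logistic model over Pfam-family indicators with externally supplied
weights). Channel scores are combined by a pluggable consensus combiner
(default: weighted mean); terms above a confidence threshold form each
isoform's predicted-function set, and gains/losses between reference and
isoform sets are assessed with an upper-tail hypergeometric test.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "cscore_sequence",
    "cscore_structure",
    "cscore_ppi",
    "cscore_pfam",
    "combine_scores",
    "confident_terms",
    "gain_loss",
    "enrichment_pmf",
    "enrichment_test",
    "heatmap_filter",
]


def _weighted_term_score(hits: pd.DataFrame, term: str, weight_cols: list[str]) -> float:
    for col in weight_cols + ["go_terms"]:
        if col not in hits.columns:
            raise ValueError(f"hit table lacks required column {col!r}")
    if len(hits) == 0:
        raise ValueError("empty hit table")
    w = np.ones(len(hits))
    for col in weight_cols:
        w = w * hits[col].to_numpy(dtype=float)
    denom = w.sum()
    if denom <= 0:
        raise ValueError("hit weights sum to zero")
    has = hits["go_terms"].map(lambda s: term in s).to_numpy(dtype=bool)
    return float(w[has].sum() / denom)


def cscore_sequence(hits: pd.DataFrame, term: str) -> float:
    """Identity·bitscore-weighted fraction of sequence hits carrying ``term``."""
    return _weighted_term_score(hits, term, ["identity", "bitscore"])


def cscore_structure(hits: pd.DataFrame, term: str) -> float:
    """Identity·TM·bitscore-weighted fraction of structure hits with ``term``."""
    return _weighted_term_score(hits, term, ["identity", "tm", "bitscore"])


def cscore_ppi(partners: pd.DataFrame, term: str) -> float:
    """STRING-score-weighted fraction of PPI partners annotated with ``term``."""
    return _weighted_term_score(partners, term, ["string_score"])


def cscore_pfam(match_vector: Iterable[float], weights: Iterable[float], w0: float = 0.0) -> float:
    """Logistic score over Pfam-family match indicators with supplied weights."""
    x = np.asarray(list(match_vector), dtype=float)
    w = np.asarray(list(weights), dtype=float)
    if x.shape != w.shape:
        raise ValueError(f"match vector ({x.shape}) and weights ({w.shape}) differ in length")
    z = w0 + float(w @ x)
    return 1.0 / (1.0 + math.exp(-z))


def combine_scores(
    channel_scores: Mapping[str, float],
    weights: Mapping[str, float] | None = None,
    combiner: Callable[[Mapping[str, float]], float] | None = None,
) -> float:
    """Consensus probability from the available channel scores.

    Default combiner is a weighted mean over the channels present (uniform
    weights unless given); a trained model can be plugged in via ``combiner``.
    """
    if not channel_scores:
        raise ValueError("no channel scores to combine")
    if combiner is not None:
        return float(combiner(channel_scores))
    if weights is None:
        weights = {k: 1.0 for k in channel_scores}
    num = sum(weights.get(k, 0.0) * v for k, v in channel_scores.items())
    den = sum(weights.get(k, 0.0) for k in channel_scores)
    if den <= 0:
        raise ValueError("combiner weights sum to zero")
    return num / den


def confident_terms(table: Mapping[str, float], threshold: float = 0.6) -> set[str]:
    """Terms with consensus probability strictly above the threshold."""
    return {term for term, score in table.items() if score > threshold}


def gain_loss(ref_terms: set[str], iso_terms: set[str]) -> tuple[set[str], set[str]]:
    """(gained, lost) term sets for an isoform relative to its reference."""
    return (set(iso_terms) - set(ref_terms), set(ref_terms) - set(iso_terms))


def _check_counts(k: int, M: int, n: int, N: int) -> None:
    if not (0 <= n <= M and 0 <= N <= M):
        raise ValueError(f"infeasible counts: n={n}, N={N} must lie in [0, M={M}]")
    if not 0 <= k <= min(n, N):
        raise ValueError(f"infeasible count k={k}: must lie in [0, min(n={n}, N={N})]")


def enrichment_pmf(k: int, M: int, n: int, N: int) -> float:
    """Hypergeometric point probability of exactly ``k`` annotated isoforms.

    ``M`` isoforms in total, ``n`` gaining/losing the term, ``N`` with the
    splicing type, ``k`` in the intersection.
    """
    _check_counts(k, M, n, N)
    return float(stats.hypergeom.pmf(k, M, n, N))


def enrichment_test(k: int, M: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric enrichment p-value, p = P(X >= k)."""
    _check_counts(k, M, n, N)
    return float(stats.hypergeom.sf(k - 1, M, n, N))


def heatmap_filter(
    term_stats: pd.DataFrame,
    min_gained: int = 5,
    min_lost: int = 15,
    max_predictions: int = 5000,
) -> dict[str, set[str]]:
    """Terms retained for the gain and loss panels of the enrichment heatmap.

    ``term_stats`` needs columns term, n_gained, n_lost, n_predictions.
    Overly general terms (more than ``max_predictions`` predictions) are
    dropped from both panels.
    """
    for col in ("term", "n_gained", "n_lost", "n_predictions"):
        if col not in term_stats.columns:
            raise ValueError(f"term_stats lacks required column {col!r}")
    ok = term_stats["n_predictions"] <= max_predictions
    gain = set(term_stats.loc[ok & (term_stats["n_gained"] >= min_gained), "term"])
    loss = set(term_stats.loc[ok & (term_stats["n_lost"] >= min_lost), "term"])
    return {"gain": gain, "loss": loss}
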