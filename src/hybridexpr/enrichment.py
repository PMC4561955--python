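"""Hypergeometric over-representation testing with BH-FDR.

For a study set of ``n`` genes drawn from a background of ``M`` genes of
which ``K`` carry a term, the enrichment p-value is the upper tail
``P(X >= k)`` of Hypergeometric(M, K, n).  Observed and expected
percentages mirror the study's bar-plot convention: ``100*k/n`` in the
study set versus ``100*K/M`` in the background.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from hybridexpr.core import GeneMeta
from hybridexpr.diffexpr import bh_adjust


def hypergeom_upper_tail(k: int, K: int, n: int, M: int) -> float:
    """``P(X >= k)`` for X ~ Hypergeometric(M, K, n)."""
    if not (0 <= k <= n <= M):
        raise ValueError(f"require 0 <= k <= n <= M, got k={k}, n={n}, M={M}")
    if not (k <= K <= M):
        raise ValueError(f"require k <= K <= M, got k={k}, K={K}, M={M}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, M, K, n))


def enrich(
    study_set: Iterable[str],
    meta: Mapping[str, GeneMeta],
    background: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One enrichment row per term annotated in the background.

    The study set must be a subset of the background.  Terms absent
    from the background (K = 0) are not reported — they cannot be
    enriched and would only inflate the BH family.  ``significant`` is
    the strict rule ``q < alpha``.
    """
    study = set(study_set)
    bg = set(background)
    if not study:
        raise ValueError("study set is empty")
    if not bg:
        raise ValueError("background set is empty")
    if not study <= bg:
        extra = sorted(study - bg)[:5]
        raise ValueError(f"study set is not a subset of the background: {extra}")
    term_bg: dict = {}
    term_study: dict = {}
    for gid in bg:
        gm = meta.get(gid)
        if gm is None:
            continue
        for term in gm.go_terms:
            term_bg[term] = term_bg.get(term, 0) + 1
            if gid in study:
                term_study[term] = term_study.get(term, 0) + 1
    n = len(study)
    M = len(bg)
    records = []
    for term in sorted(term_bg):
        K = term_bg[term]
        k = term_study.get(term, 0)
        records.append(
            {
                "term_id": term,
                "k": k,
                "n": n,
                "K": K,
                "M": M,
                "observed_pct": 100.0 * k / n,
                "expected_pct": 100.0 * K / M,
                "p": hypergeom_upper_tail(k, K, n, M),
            }
        )
    df = pd.DataFrame(
        records,
        columns=["term_id", "k", "n", "K", "M", "observed_pct", "expected_pct", "p"],
    )
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
        df["significant"] = df["q"] < alpha
    else:
        df["q"] = []
        df["significant"] = []
    return df
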