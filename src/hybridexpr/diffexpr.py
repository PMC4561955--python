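"""Exact two-library differential expression without replicates.

The per-gene significance computation is the Audic-Claverie conditional
test: given ``x`` fragments for a gene in a library of size ``n1``, the
count ``y'`` in a second library of size ``n2`` follows, under the null
of equal relative abundance, the conditional distribution

    p(y' | x) = (n2/n1)^y' * G(x+y'+1) / (G(x+1) G(y'+1) (1+n2/n1)^(x+y'+1))

which is the negative binomial with ``x+1`` successes and success
probability ``n1/(n1+n2)``.  Two-sided p-values double the smaller tail
and clip at 1.  The decision rule gates BH-adjusted q-values at the FDR
threshold and log2 fold change strictly above ``log2(fc_threshold)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from hybridexpr.core import CountTable, require_samples

UP = "UP"
DOWN = "DOWN"
NS = "NS"


def exact_count_test(x, n1, y, n2):
    """Two-sided Audic-Claverie p-value(s) for counts x@n1 vs y@n2.

    Accepts scalars or arrays (broadcast).  Returns values in (0, 1];
    symmetric under swapping ``(x, n1) <-> (y, n2)``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n1 = np.asarray(n1, dtype=np.float64)
    n2 = np.asarray(n2, dtype=np.float64)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))
            and np.all(np.isfinite(n1)) and np.all(np.isfinite(n2))):
        raise ValueError("exact_count_test requires finite inputs")
    if np.any(n1 <= 0) or np.any(n2 <= 0):
        raise ValueError("library sizes must be positive")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    prob = n1 / (n1 + n2)
    # y' | x ~ NegBinom(x+1, n1/(n1+n2)); scipy evaluates the CDF via the
    # regularized incomplete beta, stable for large counts.
    p_low = stats.nbinom.cdf(y, x + 1.0, prob)
    p_high = stats.nbinom.sf(y - 1.0, x + 1.0, prob)
    two_sided = np.minimum(1.0, 2.0 * np.minimum(p_low, p_high))
    if two_sided.ndim == 0:
        return float(two_sided)
    return two_sided


def ac_conditional_pmf(y_prime, x, n1, n2):
    """log-space Audic-Claverie conditional pmf p(y'|x); testing aid."""
    from scipy.special import gammaln

    y_prime = np.asarray(y_prime, dtype=np.float64)
    r = n2 / n1
    return np.exp(
        y_prime * np.log(r)
        + gammaln(x + y_prime + 1.0)
        - gammaln(x + 1.0)
        - gammaln(y_prime + 1.0)
        - (x + y_prime + 1.0) * np.log1p(r)
    )


def bh_adjust(p_values):
    """Benjamini-Hochberg step-up q-values.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` on the sorted p-values,
    clipped to 1 and mapped back to the input order.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.ndim != 1:
        raise ValueError("p_values must be a 1-D vector")
    if p.size == 0:
        return np.array([], dtype=np.float64)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def log2_fold_change(a_norm, b_norm, pseudocount=1.0):
    """``log2((a + pseudocount) / (b + pseudocount))`` on normalized counts."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    a = np.asarray(a_norm, dtype=np.float64)
    b = np.asarray(b_norm, dtype=np.float64)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("normalized counts must be non-negative")
    out = np.log2((a + pseudocount) / (b + pseudocount))
    if out.ndim == 0:
        return float(out)
    return out


def call_directions(log2fc, q, alpha, fc_threshold, strict_alpha=False):
    """Vectorized UP/DOWN/NS decision.

    Significant means ``q < alpha`` when ``strict_alpha`` (the miRNA
    layer's printed rule) else ``q <= alpha``; the fold gate is always
    strict, so a fold change of exactly ``fc_threshold`` stays NS.
    """
    log2fc = np.asarray(log2fc, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    gate = np.log2(fc_threshold)
    sig = (q < alpha) if strict_alpha else (q <= alpha)
    direction = np.full(log2fc.shape, NS, dtype=object)
    direction[sig & (log2fc > gate)] = UP
    direction[sig & (log2fc < -gate)] = DOWN
    return direction


def call_de(
    counts: CountTable,
    pair,
    alpha: float,
    fc_threshold: float,
    size_factors: pd.Series | None = None,
    pseudocount: float = 1.0,
    strict_alpha: bool = False,
) -> pd.DataFrame:
    """Per-gene differential-expression calls for one ordered sample pair.

    ``pair`` is (numerator, denominator).  The p-value comes from the
    exact test on raw counts at raw library sizes; the fold change from
    size-factor-normalized counts with a pseudocount; BH is applied
    across all genes of this pair.
    """
    num, den = pair
    require_samples(counts, (num, den))
    x = counts.column(num).astype(np.float64)
    y = counts.column(den).astype(np.float64)
    n1 = float(counts.library_size(num))
    n2 = float(counts.library_size(den))
    if size_factors is not None:
        sf_num = float(size_factors[num])
        sf_den = float(size_factors[den])
    else:
        sf_num = sf_den = 1.0
    if counts.n_genes == 0:
        return pd.DataFrame(
            columns=["gene_id", "x", "y", "log2fc", "p", "q", "direction"]
        )
    p = exact_count_test(x, n1, y, n2)
    p = np.atleast_1d(p)
    q = bh_adjust(p)
    lfc = log2_fold_change(x / sf_num, y / sf_den, pseudocount)
    direction = call_directions(lfc, q, alpha, fc_threshold, strict_alpha)
    return pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "x": x.astype(np.int64),
            "y": y.astype(np.int64),
            "log2fc": lfc,
            "p": p,
            "q": q,
            "direction": direction,
        }
    )
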