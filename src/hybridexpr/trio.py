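"""Mid-parent additivity testing and the twelve-bin dominance classifier.

A gene's state in one hybrid generation is a triple of pairwise
relations — parent1 vs parent2, hybrid vs parent1, hybrid vs parent2 —
each in {GT, LT, NS} where GT means the first member is significantly
greater.  Fourteen of the 27 triples are interpretable (twelve numbered
bins plus the all-NS conserved state); the remaining thirteen are
internally contradictory and are reported AMBIGUOUS rather than forced
into a bin.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from hybridexpr.core import AnalysisConfig, CountTable, require_samples
from hybridexpr.diffexpr import (
    DOWN,
    NS,
    UP,
    bh_adjust,
    call_de,
    exact_count_test,
    log2_fold_change,
)
from hybridexpr.normalization import FpkmTable, size_factors_median_ratio

GT = "GT"
LT = "LT"
# NS shared with diffexpr

ADDITIVE = "ADDITIVE"
NONADDITIVE_UP = "NONADDITIVE_UP"
NONADDITIVE_DOWN = "NONADDITIVE_DOWN"

GROUP_ADDITIVITY = "ADDITIVITY"
GROUP_ELD_P1 = "ELD_P1"
GROUP_ELD_P2 = "ELD_P2"
GROUP_TRANS_UP = "TRANSGRESSIVE_UP"
GROUP_TRANS_DOWN = "TRANSGRESSIVE_DOWN"
GROUP_CONSERVED = "CONSERVED"
GROUP_AMBIGUOUS = "AMBIGUOUS"

GROUPS = (
    GROUP_ADDITIVITY,
    GROUP_ELD_P1,
    GROUP_ELD_P2,
    GROUP_TRANS_UP,
    GROUP_TRANS_DOWN,
    GROUP_CONSERVED,
    GROUP_AMBIGUOUS,
)

#: (rel_P1P2, rel_HP1, rel_HP2) -> (bin, group) for the 14 coherent triples.
BIN_TABLE = {
    (LT, GT, LT): ("I", GROUP_ADDITIVITY),
    (GT, LT, GT): ("XII", GROUP_ADDITIVITY),
    (LT, NS, LT): ("II", GROUP_ELD_P1),
    (GT, NS, GT): ("XI", GROUP_ELD_P1),
    (LT, GT, NS): ("IV", GROUP_ELD_P2),
    (GT, LT, NS): ("IX", GROUP_ELD_P2),
    (LT, GT, GT): ("V", GROUP_TRANS_UP),
    (NS, GT, GT): ("VI", GROUP_TRANS_UP),
    (GT, GT, GT): ("VIII", GROUP_TRANS_UP),
    (LT, LT, LT): ("III", GROUP_TRANS_DOWN),
    (NS, LT, LT): ("VII", GROUP_TRANS_DOWN),
    (GT, LT, LT): ("X", GROUP_TRANS_DOWN),
    (NS, NS, NS): ("NO_CHANGE", GROUP_CONSERVED),
}

GROUP_BINS = {
    GROUP_ADDITIVITY: frozenset({"I", "XII"}),
    GROUP_ELD_P1: frozenset({"II", "XI"}),
    GROUP_ELD_P2: frozenset({"IV", "IX"}),
    GROUP_TRANS_UP: frozenset({"V", "VI", "VIII"}),
    GROUP_TRANS_DOWN: frozenset({"III", "VII", "X"}),
    GROUP_CONSERVED: frozenset({"NO_CHANGE"}),
}

_RELATIONS = frozenset({GT, LT, NS})


def classify_trio(rel_p1p2: str, rel_hp1: str, rel_hp2: str):
    """Map a relation triple to its (bin, group).

    Total on the 3^3 alphabet: the 13 triples outside the table return
    ``("AMBIGUOUS", "AMBIGUOUS")``.
    """
    triple = (rel_p1p2, rel_hp1, rel_hp2)
    for rel in triple:
        if rel not in _RELATIONS:
            raise ValueError(f"relation must be GT, LT or NS, got {rel!r}")
    return BIN_TABLE.get(triple, (GROUP_AMBIGUOUS, GROUP_AMBIGUOUS))


def direction_to_relation(direction: str) -> str:
    """ComparisonCall direction (first vs second member) to a relation."""
    return {UP: GT, DOWN: LT, NS: NS}[direction]


def mpv_test(
    counts: CountTable,
    generation: str,
    size_factors: pd.Series,
    alpha: float,
    pseudocount: float = 1.0,
    strict_alpha: bool = False,
) -> pd.DataFrame:
    """Test each gene's hybrid expression against the mid-parent value.

    The MPV on the normalized-count scale is the mean of the two
    parents' size-factor-normalized counts.  It is materialized as a
    pseudo-library (round-half-even counts, pseudo-size = rounded mean
    of the parents' normalized library sizes) so the exact count test
    applies; BH runs across all genes.
    """
    if generation not in ("F1", "F2"):
        raise ValueError(f"generation must be 'F1' or 'F2', got {generation!r}")
    require_samples(counts, ("P1", "P2", generation))
    sf_p1 = float(size_factors["P1"])
    sf_p2 = float(size_factors["P2"])
    sf_h = float(size_factors[generation])
    p1 = counts.column("P1").astype(np.float64)
    p2 = counts.column("P2").astype(np.float64)
    h = counts.column(generation).astype(np.float64)
    n_p1 = counts.library_size("P1") / sf_p1
    n_p2 = counts.library_size("P2") / sf_p2
    n_h = counts.library_size(generation) / sf_h

    mpv_norm = (p1 / sf_p1 + p2 / sf_p2) / 2.0
    h_norm = h / sf_h
    if counts.n_genes == 0:
        return pd.DataFrame(
            columns=[
                "gene_id", "generation", "mpv_norm", "hybrid_norm",
                "log2fc_vs_mpv", "p", "q", "status",
            ]
        )
    mpv_pseudo = np.rint(mpv_norm)  # round half to even, deterministic
    pseudo_size = float(np.rint((n_p1 + n_p2) / 2.0))
    p = np.atleast_1d(exact_count_test(h, n_h, mpv_pseudo, pseudo_size))
    q = bh_adjust(p)
    lfc = log2_fold_change(h_norm, mpv_norm, pseudocount)
    sig = (q < alpha) if strict_alpha else (q <= alpha)
    status = np.full(counts.n_genes, ADDITIVE, dtype=object)
    status[sig & (h_norm > mpv_norm)] = NONADDITIVE_UP
    status[sig & (h_norm <= mpv_norm)] = NONADDITIVE_DOWN
    return pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "generation": generation,
            "mpv_norm": mpv_norm,
            "hybrid_norm": h_norm,
            "log2fc_vs_mpv": lfc,
            "p": p,
            "q": q,
            "status": status,
        }
    )


def classify_generation(
    counts: CountTable,
    generation: str,
    config: AnalysisConfig,
    size_factors: pd.Series | None = None,
    alpha: float | None = None,
    strict_alpha: bool = False,
):
    """Full trio classification of one hybrid generation.

    Builds the three pairwise comparisons (P1 vs P2, hybrid vs P1,
    hybrid vs P2) with :func:`call_de`, maps directions to relations,
    assigns each gene a bin and group, and joins the MPV additivity
    test.  Returns ``(trio_calls, mpv_results)``; the same code path
    serves genes and miRNAs (only ``alpha``/``strict_alpha`` differ).
    """
    require_samples(counts, ("P1", "P2", generation))
    if size_factors is None:
        size_factors = size_factors_median_ratio(counts)
    if alpha is None:
        alpha = config.fdr_gene
    kwargs = dict(
        alpha=alpha,
        fc_threshold=config.fc_threshold,
        size_factors=size_factors,
        pseudocount=config.pseudocount,
        strict_alpha=strict_alpha,
    )
    de_p1p2 = call_de(counts, ("P1", "P2"), **kwargs)
    de_hp1 = call_de(counts, (generation, "P1"), **kwargs)
    de_hp2 = call_de(counts, (generation, "P2"), **kwargs)
    mpv = mpv_test(
        counts, generation, size_factors, alpha,
        pseudocount=config.pseudocount, strict_alpha=strict_alpha,
    )
    rel_p1p2 = [direction_to_relation(d) for d in de_p1p2["direction"]]
    rel_hp1 = [direction_to_relation(d) for d in de_hp1["direction"]]
    rel_hp2 = [direction_to_relation(d) for d in de_hp2["direction"]]
    bins, groups = [], []
    for triple in zip(rel_p1p2, rel_hp1, rel_hp2):
        b, g = classify_trio(*triple)
        bins.append(b)
        groups.append(g)
    trio = pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "generation": generation,
            "rel_P1P2": rel_p1p2,
            "rel_HP1": rel_hp1,
            "rel_HP2": rel_hp2,
            "bin": bins,
            "group": groups,
            "mpv_status": mpv["status"].to_numpy(),
            "log2fc_vs_mpv": mpv["log2fc_vs_mpv"].to_numpy(),
            "p_mpv": mpv["p"].to_numpy(),
            "q_mpv": mpv["q"].to_numpy(),
        }
    )
    return trio, mpv


def expressed_sets(fpkm: FpkmTable, min_fpkm: float = 1.0) -> dict:
    """Presence calls: per-sample expressed, co-expressed, and specific sets.

    A gene is expressed in a sample when its FPKM is at least
    ``min_fpkm``; co-expressed genes are expressed in every sample;
    a sample's specific set is its expressed genes minus the
    co-expressed set.
    """
    if min_fpkm < 0:
        raise ValueError("min_fpkm must be >= 0")
    gene_ids = np.asarray(fpkm.gene_ids, dtype=object)
    expressed = {}
    mask_all = np.ones(len(gene_ids), dtype=bool)
    for j, label in enumerate(fpkm.sample_labels):
        mask = fpkm.values[:, j] >= min_fpkm
        expressed[label] = set(gene_ids[mask])
        mask_all &= mask
    co_expressed = set(gene_ids[mask_all])
    specific = {
        label: expressed[label] - co_expressed for label in fpkm.sample_labels
    }
    return {
        "expressed": expressed,
        "co_expressed": co_expressed,
        "specific": specific,
    }
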