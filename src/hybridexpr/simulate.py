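"""Synthetic hybrid-trio count data with planted truth labels.

Generates four unreplicated libraries (P1, P2, F1, F2) of negative
binomial counts over log-normal baseline abundances, with genes planted
in configurable proportions of conserved, additive, dominance (toward
either parent), transgressive, and sample-specific categories, plus a
miRNA layer whose target genes' hybrid log2 fold changes are negatively
coupled to the miRNA fold changes.

Each gene's truth record carries both the *planted* recipe category and
the *expected* classifier group: the group an infinitely deep,
noise-free run of the trio classifier would assign given the true means
and the fold-change gate.  The two differ systematically — e.g. a gene
whose hybrid mean sits exactly mid-way between parents eight-fold apart
can never clear the two-fold gate against the high parent, so its
expected group is a dominance call, not additivity.  Recovery is always
measured against the expected group.

All randomness flows from one root seed; submodules draw from fixed
spawned streams so a partial re-run reproduces the same data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Mapping

import numpy as np
import pandas as pd

from hybridexpr.core import CountTable, GeneMeta, MiRNATargetMap, SAMPLES
from hybridexpr.trio import (
    GROUP_ADDITIVITY,
    GROUP_CONSERVED,
    GROUP_ELD_P1,
    GROUP_ELD_P2,
    GROUP_TRANS_DOWN,
    GROUP_TRANS_UP,
    GT,
    LT,
    classify_trio,
)
from hybridexpr.diffexpr import NS

SPECIFIC_P1 = "SPECIFIC_P1"
SPECIFIC_P2 = "SPECIFIC_P2"
SPECIFIC_F1 = "SPECIFIC_F1"
SPECIFIC_F2 = "SPECIFIC_F2"

PLANT_CATEGORIES = (
    GROUP_CONSERVED,
    GROUP_ADDITIVITY,
    GROUP_ELD_P1,
    GROUP_ELD_P2,
    GROUP_TRANS_UP,
    GROUP_TRANS_DOWN,
    SPECIFIC_P1,
    SPECIFIC_P2,
    SPECIFIC_F1,
    SPECIFIC_F2,
)

#: Categories whose recipe touches only the hybrid mean; used when a
#: gene's F2 category is re-drawn (parent means are shared with F1).
_HYBRID_CATEGORIES = (
    GROUP_CONSERVED,
    GROUP_ADDITIVITY,
    GROUP_ELD_P1,
    GROUP_ELD_P2,
    GROUP_TRANS_UP,
    GROUP_TRANS_DOWN,
)


def _default_proportions() -> dict:
    return {
        GROUP_CONSERVED: 0.45,
        GROUP_ADDITIVITY: 0.05,
        GROUP_ELD_P1: 0.10,
        GROUP_ELD_P2: 0.10,
        GROUP_TRANS_UP: 0.10,
        GROUP_TRANS_DOWN: 0.10,
        SPECIFIC_P1: 0.025,
        SPECIFIC_P2: 0.025,
        SPECIFIC_F1: 0.025,
        SPECIFIC_F2: 0.025,
    }


@dataclass
class SimParams:
    """Knobs for the synthetic hybrid-trio generator."""

    n_genes: int = 2000
    n_mirnas: int = 200
    category_proportions: dict = field(default_factory=_default_proportions)
    fold_effect: float = 8.0
    baseline_logmean: float = 4.5
    baseline_logsd: float = 0.8
    nb_dispersion: float = 0.05
    library_sizes: tuple = (10_000_000, 10_000_000, 10_000_000, 10_000_000)
    f2_inherit_prob: float = 0.9
    mirna_coupling_beta: float = 1.0
    mirna_noise_sd: float = 0.1
    mirna_coupled_fraction: float = 0.5
    targets_per_mirna: int = 3
    mirna_log2fc_sd: float = 1.5
    gene_length_range: tuple = (500, 5000)
    n_go_terms: int = 25
    mean_go_per_gene: float = 2.0
    fc_threshold: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.category_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category proportions must sum to 1, got {total}")
        unknown = set(self.category_proportions) - set(PLANT_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")
        if any(v < 0 for v in self.category_proportions.values()):
            raise ValueError("category proportions must be non-negative")
        for name in ("fold_effect", "baseline_logsd", "mirna_log2fc_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.mirna_noise_sd < 0:
            raise ValueError("mirna_noise_sd must be >= 0")
        if not 0.0 <= self.f2_inherit_prob <= 1.0:
            raise ValueError("f2_inherit_prob must be in [0, 1]")
        if not 0.0 <= self.mirna_coupled_fraction <= 1.0:
            raise ValueError("mirna_coupled_fraction must be in [0, 1]")
        if len(self.library_sizes) != 4 or any(s <= 0 for s in self.library_sizes):
            raise ValueError("library_sizes must be four positive integers")
        lo, hi = self.gene_length_range
        if lo < 1 or hi < lo:
            raise ValueError("gene_length_range must be a valid positive interval")
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must be > 1")

    def to_dict(self) -> dict:
        d = {}
        for f in fields(self):
            v = getattr(self, f.name)
            d[f.name] = list(v) if isinstance(v, tuple) else v
        return d


@dataclass
class SyntheticTruth:
    """Planted categories, true means, and miRNA coupling per entity.

    ``genes`` columns: gene_id, planted_F1, planted_F2, expected_F1,
    expected_F2, mu_P1, mu_P2, mu_F1, mu_F2, mirna_target.
    ``mirnas``/``pairs`` are filled by :func:`simulate_mirna_layer`.
    """

    genes: pd.DataFrame
    mirnas: pd.DataFrame | None = None
    pairs: pd.DataFrame | None = None
    beta: float | None = None


def _streams(seed: int):
    """Fixed derived RNG streams: gene structure, gene counts, miRNA
    structure, miRNA counts, target-patch counts."""
    children = np.random.SeedSequence(seed).spawn(5)
    return [np.random.default_rng(c) for c in children]


def _ideal_relation(a: float, b: float, fc: float) -> str:
    """Relation an infinitely deep run would call: significance detects
    any true mean difference, the fold gate is strict."""
    if a > b and a > fc * b:
        return GT
    if b > a and b > fc * a:
        return LT
    return NS


def expected_group(mu_p1: float, mu_p2: float, mu_h: float, fc: float) -> str:
    """Classifier group implied by the true means under the fold gate."""
    return classify_trio(
        _ideal_relation(mu_p1, mu_p2, fc),
        _ideal_relation(mu_h, mu_p1, fc),
        _ideal_relation(mu_h, mu_p2, fc),
    )[1]


def _hybrid_mean(category: str, mu_p1: float, mu_p2: float, lam: float,
                 delta: float, generation: str) -> float:
    if category == GROUP_CONSERVED:
        # hybrid indistinguishable from the parents: their common value,
        # or the midpoint when the parents were split by another recipe
        return (mu_p1 + mu_p2) / 2.0
    if category == GROUP_ADDITIVITY:
        return (mu_p1 + mu_p2) / 2.0
    if category == GROUP_ELD_P1:
        return mu_p1
    if category == GROUP_ELD_P2:
        return mu_p2
    if category == GROUP_TRANS_UP:
        return delta * max(mu_p1, mu_p2)
    if category == GROUP_TRANS_DOWN:
        return min(mu_p1, mu_p2) / delta
    if category in (SPECIFIC_P1, SPECIFIC_P2):
        return 0.0
    if category == SPECIFIC_F1:
        return lam if generation == "F1" else 0.0
    if category == SPECIFIC_F2:
        return lam if generation == "F2" else 0.0
    raise ValueError(f"unknown category {category!r}")


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean, dispersion phi) draws; variance = mean + phi*mean^2.
    phi = 0 degrades to Poisson; a zero mean always yields zero."""
    mean = np.asarray(mean, dtype=np.float64)
    if phi == 0.0:
        return rng.poisson(mean).astype(np.int64)
    size_param = 1.0 / phi
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p).astype(np.int64)


def simulate_trio(params: SimParams):
    """Generate the gene-layer trio: counts, metadata, and truth.

    Returns ``(CountTable, meta dict, SyntheticTruth)``.  Per gene a
    baseline abundance is drawn log-normally, per-sample means follow
    the planted category's recipe (parent polarity random, effect size
    ``fold_effect``), the F2 recipe repeats F1 with probability
    ``f2_inherit_prob`` (else the hybrid category is re-drawn), and
    counts are negative binomial at depth ``library_sizes``.
    """
    gene_rng, count_rng = _streams(params.seed)[:2]
    n = params.n_genes
    cats = list(params.category_proportions.keys())
    probs = np.array([params.category_proportions[c] for c in cats], dtype=float)
    planted_f1 = gene_rng.choice(cats, size=n, p=probs)
    lam = gene_rng.lognormal(params.baseline_logmean, params.baseline_logsd, size=n)
    polarity = gene_rng.random(n) < 0.5  # True: P1 is the low parent
    parents_differ = gene_rng.random(n) < 0.5  # transgressive parents split
    inherit = gene_rng.random(n) < params.f2_inherit_prob
    hybrid_cats = [c for c in _HYBRID_CATEGORIES if params.category_proportions.get(c, 0) > 0]
    if hybrid_cats:
        hprobs = np.array([params.category_proportions[c] for c in hybrid_cats], dtype=float)
    else:
        hybrid_cats = [GROUP_CONSERVED]
        hprobs = np.array([1.0])
    hprobs = hprobs / hprobs.sum()
    redraws = gene_rng.choice(hybrid_cats, size=n, p=hprobs)

    delta = params.fold_effect
    mu = np.zeros((n, 4), dtype=np.float64)  # P1, P2, F1, F2
    planted_f2 = np.empty(n, dtype=object)
    for i in range(n):
        cat = planted_f1[i]
        l = lam[i]
        if cat in (GROUP_CONSERVED, SPECIFIC_F1, SPECIFIC_F2):
            mu_p1 = mu_p2 = l if cat == GROUP_CONSERVED else 0.0
        elif cat == SPECIFIC_P1:
            mu_p1, mu_p2 = l, 0.0
        elif cat == SPECIFIC_P2:
            mu_p1, mu_p2 = 0.0, l
        elif cat == GROUP_TRANS_UP or cat == GROUP_TRANS_DOWN:
            if parents_differ[i]:
                mu_p1, mu_p2 = (l, delta * l) if polarity[i] else (delta * l, l)
            else:
                mu_p1 = mu_p2 = l
        else:  # ADDITIVITY, ELD_P1, ELD_P2: parents split by delta
            mu_p1, mu_p2 = (l, delta * l) if polarity[i] else (delta * l, l)
        mu_f1 = _hybrid_mean(cat, mu_p1, mu_p2, l, delta, "F1")
        if inherit[i]:
            cat_f2 = cat
            mu_f2 = _hybrid_mean(cat, mu_p1, mu_p2, l, delta, "F2")
        else:
            cat_f2 = redraws[i]
            mu_f2 = _hybrid_mean(cat_f2, mu_p1, mu_p2, l, delta, "F2")
        planted_f2[i] = cat_f2
        mu[i] = (mu_p1, mu_p2, mu_f1, mu_f2)

    fc = params.fc_threshold
    exp_f1 = [expected_group(mu[i, 0], mu[i, 1], mu[i, 2], fc) for i in range(n)]
    exp_f2 = [expected_group(mu[i, 0], mu[i, 1], mu[i, 3], fc) for i in range(n)]

    scale = np.asarray(params.library_sizes, dtype=np.float64) / 1e6
    counts = _draw_counts(count_rng, mu * scale[None, :], params.nb_dispersion)
    gene_ids = [f"g{i + 1:05d}" for i in range(n)]
    # nominal depth is the mapped-fragment total; it can never undercut
    # the table itself, so clamp when a heavy tail overshoots it
    lib_sizes = np.maximum(
        np.asarray(params.library_sizes, dtype=np.int64), counts.sum(axis=0)
    )
    table = CountTable(gene_ids, counts, list(SAMPLES), lib_sizes)

    lo, hi = params.gene_length_range
    lengths = gene_rng.integers(lo, hi + 1, size=n)
    term_pool = [f"GO:{i + 1:07d}" for i in range(params.n_go_terms)]
    n_terms = gene_rng.poisson(params.mean_go_per_gene, size=n)
    meta = {}
    for i, gid in enumerate(gene_ids):
        k = min(int(n_terms[i]), len(term_pool))
        terms = gene_rng.choice(term_pool, size=k, replace=False) if k else []
        meta[gid] = GeneMeta(gid, int(lengths[i]), frozenset(terms))

    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "planted_F1": planted_f1,
            "planted_F2": planted_f2,
            "expected_F1": exp_f1,
            "expected_F2": exp_f2,
            "mu_P1": mu[:, 0],
            "mu_P2": mu[:, 1],
            "mu_F1": mu[:, 2],
            "mu_F2": mu[:, 3],
            "mirna_target": False,
        }
    )
    return table, meta, SyntheticTruth(genes=genes)


def simulate_mirna_layer(params: SimParams, truth: SyntheticTruth,
                         gene_counts: CountTable):
    """Add the miRNA layer on top of a simulated gene layer.

    A fraction of miRNAs are "coupled": each gets a true hybrid
    log2 fold change vs its mid-parent value, ``m ~ N(0, sd)``, and each
    of its target genes has its hybrid means re-set so that the target's
    log2 fold change vs MPV equals ``-beta * m + N(0, noise_sd)``
    (independent noise per generation).  Target genes' hybrid counts are
    re-drawn; parents and non-target genes are untouched.  One gene is
    targeted by at most one miRNA, while a miRNA targets
    ``targets_per_mirna`` genes.

    Returns ``(mirna CountTable, MiRNATargetMap, SyntheticTruth, updated
    gene CountTable)``.
    """
    streams = _streams(params.seed)
    mirna_rng, mirna_count_rng, patch_rng = streams[2], streams[3], streams[4]
    n_mi = params.n_mirnas
    n_coupled = int(round(params.mirna_coupled_fraction * n_mi))
    genes = truth.genes.copy()
    eligible = genes.index[
        (genes["mu_P1"] + genes["mu_P2"] > 0) & ~genes["mirna_target"]
    ].to_numpy()
    needed = n_coupled * params.targets_per_mirna
    if needed > len(eligible):
        raise ValueError(
            f"need {needed} target genes but only {len(eligible)} are eligible"
        )

    lam = mirna_rng.lognormal(params.baseline_logmean, params.baseline_logsd, n_mi)
    coupled = np.zeros(n_mi, dtype=bool)
    coupled[:n_coupled] = True
    m_true = np.zeros(n_mi, dtype=np.float64)
    m_true[coupled] = mirna_rng.normal(0.0, params.mirna_log2fc_sd, n_coupled)
    mu_mi = np.empty((n_mi, 4), dtype=np.float64)
    mu_mi[:, 0] = lam
    mu_mi[:, 1] = lam
    mu_mi[:, 2] = lam * np.exp2(m_true)
    mu_mi[:, 3] = lam * np.exp2(m_true)

    mirna_ids = [f"mir{i + 1:04d}" for i in range(n_mi)]
    scale = np.asarray(params.library_sizes, dtype=np.float64) / 1e6
    mi_counts = _draw_counts(mirna_count_rng, mu_mi * scale[None, :],
                             params.nb_dispersion)
    mirna_counts = CountTable(
        mirna_ids,
        mi_counts,
        list(SAMPLES),
        np.maximum(np.asarray(params.library_sizes, dtype=np.int64),
                   mi_counts.sum(axis=0)),
    )

    target_idx = mirna_rng.choice(eligible, size=needed, replace=False)
    beta = params.mirna_coupling_beta
    links = []
    pair_rows = []
    new_counts = gene_counts.counts.copy()
    f1_col = gene_counts.sample_index("F1")
    f2_col = gene_counts.sample_index("F2")
    for j in range(n_coupled):
        mi = mirna_ids[j]
        block = target_idx[j * params.targets_per_mirna:(j + 1) * params.targets_per_mirna]
        for gi in block:
            gid = genes.at[gi, "gene_id"]
            mpv = (genes.at[gi, "mu_P1"] + genes.at[gi, "mu_P2"]) / 2.0
            eps = patch_rng.normal(0.0, params.mirna_noise_sd, size=2)
            t_f1 = -beta * m_true[j] + eps[0]
            t_f2 = -beta * m_true[j] + eps[1]
            genes.at[gi, "mu_F1"] = mpv * 2.0 ** t_f1
            genes.at[gi, "mu_F2"] = mpv * 2.0 ** t_f2
            genes.at[gi, "mirna_target"] = True
            genes.at[gi, "expected_F1"] = expected_group(
                genes.at[gi, "mu_P1"], genes.at[gi, "mu_P2"],
                genes.at[gi, "mu_F1"], params.fc_threshold,
            )
            genes.at[gi, "expected_F2"] = expected_group(
                genes.at[gi, "mu_P1"], genes.at[gi, "mu_P2"],
                genes.at[gi, "mu_F2"], params.fc_threshold,
            )
            row_means = np.array([genes.at[gi, "mu_F1"], genes.at[gi, "mu_F2"]])
            drawn = _draw_counts(
                patch_rng,
                row_means * scale[[f1_col, f2_col]],
                params.nb_dispersion,
            )
            new_counts[gi, f1_col] = drawn[0]
            new_counts[gi, f2_col] = drawn[1]
            links.append((mi, gid))
            pair_rows.append((mi, gid, m_true[j], t_f1, t_f2))

    updated = CountTable(
        list(gene_counts.gene_ids), new_counts, list(gene_counts.sample_labels),
        np.maximum(np.asarray(params.library_sizes, dtype=np.int64),
                   new_counts.sum(axis=0)),
    )
    mirnas = pd.DataFrame(
        {
            "mirna_id": mirna_ids,
            "coupled": coupled,
            "true_log2fc_mpv": m_true,
            "mu_P1": mu_mi[:, 0],
            "mu_P2": mu_mi[:, 1],
            "mu_F1": mu_mi[:, 2],
            "mu_F2": mu_mi[:, 3],
        }
    )
    pairs = pd.DataFrame(
        pair_rows,
        columns=["mirna_id", "gene_id", "mirna_log2fc", "target_log2fc_F1",
                 "target_log2fc_F2"],
    )
    new_truth = SyntheticTruth(genes=genes, mirnas=mirnas, pairs=pairs, beta=beta)
    return mirna_counts, MiRNATargetMap(frozenset(links)), new_truth, updated


def simulate_dataset(params: SimParams):
    """Gene layer plus miRNA layer in one call.

    Returns a dict with keys ``gene_counts``, ``gene_meta``,
    ``mirna_counts``, ``target_map``, ``truth``.
    """
    gene_counts, meta, truth = simulate_trio(params)
    mirna_counts, target_map, truth, gene_counts = simulate_mirna_layer(
        params, truth, gene_counts
    )
    return {
        "gene_counts": gene_counts,
        "gene_meta": meta,
        "mirna_counts": mirna_counts,
        "target_map": target_map,
        "truth": truth,
    }
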