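"""miRNA layer: classification and miRNA-target fold-change correlation.

miRNAs run through exactly the same machinery as genes (median-of-ratios
size factors, exact test, BH, twelve-bin classification); only the FDR
threshold differs and its comparison is strict (< alpha).  A
nonadditively expressed miRNA above its mid-parent value is "activated",
below it "repressed".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from hybridexpr.core import (
    AnalysisConfig,
    CountTable,
    DegenerateDataError,
    MiRNATargetMap,
)
from hybridexpr.trio import ADDITIVE, classify_generation


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n_pairs: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("Pearson r must lie in [-1, 1]")
        if self.n_pairs < 3:
            raise ValueError("a p-value requires at least 3 pairs")

    def to_dict(self) -> dict:
        return {"r": self.r, "p": self.p, "n_pairs": self.n_pairs}


def classify_mirna(
    mirna_counts: CountTable,
    generation: str,
    config: AnalysisConfig,
    size_factors: pd.Series | None = None,
):
    """Trio-classify miRNAs; identical code path to the gene layer with
    ``alpha = fdr_mirna`` applied strictly."""
    trio, mpv = classify_generation(
        mirna_counts,
        generation,
        config,
        size_factors=size_factors,
        alpha=config.fdr_mirna,
        strict_alpha=True,
    )
    trio = trio.rename(columns={"gene_id": "mirna_id"})
    mpv = mpv.rename(columns={"gene_id": "mirna_id"})
    return trio, mpv


def mirna_target_correlation(
    mirna_log2fc,
    gene_log2fc,
    target_map: MiRNATargetMap,
    mirna_selected=None,
    gene_selected=None,
    restrict_both_de: bool = False,
):
    """Pearson correlation between miRNA and target-gene log2 fold changes.

    Each (miRNA, gene) link contributes one pair, so a miRNA targeting
    many genes appears once per target.  ``mirna_log2fc`` and
    ``gene_log2fc`` are mappings (or Series) id -> log2 fold change
    (vs-MPV by convention).  With ``restrict_both_de`` set, only pairs
    where both members appear in ``mirna_selected``/``gene_selected``
    (e.g. the nonadditive/DE sets) are kept.

    Returns ``(CorrelationResult, pair_table)``.
    """
    mirna_fc = dict(mirna_log2fc)
    gene_fc = dict(gene_log2fc)
    rows = []
    for mirna_id, gene_id in target_map:
        if mirna_id not in mirna_fc or gene_id not in gene_fc:
            continue
        if restrict_both_de:
            if mirna_selected is None or gene_selected is None:
                raise ValueError(
                    "restrict_both_de requires mirna_selected and gene_selected"
                )
            if mirna_id not in mirna_selected or gene_id not in gene_selected:
                continue
        rows.append(
            (mirna_id, gene_id, float(mirna_fc[mirna_id]), float(gene_fc[gene_id]))
        )
    pairs = pd.DataFrame(
        rows, columns=["mirna_id", "gene_id", "mirna_log2fc", "target_log2fc"]
    )
    n = len(pairs)
    if n < 3:
        raise DegenerateDataError(
            f"need at least 3 miRNA-target pairs for a correlation, got {n}"
        )
    x = pairs["mirna_log2fc"].to_numpy()
    y = pairs["target_log2fc"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("correlation undefined: zero variance in one axis")
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), n), pairs
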