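"""Cross-generation inheritance of expression categories and reporting."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from hybridexpr.core import AnalysisConfig
from hybridexpr.trio import ADDITIVE, GROUPS, NONADDITIVE_DOWN, NONADDITIVE_UP


@dataclass(frozen=True)
class InheritanceSummary:
    """Counts of one category in F1, in F2, and heritable in both."""

    category: str
    n_f1: int
    n_f2: int
    n_both: int

    def __post_init__(self) -> None:
        if self.n_both > min(self.n_f1, self.n_f2):
            raise ValueError("n_both cannot exceed min(n_f1, n_f2)")


def intersect_category(
    f1_calls: pd.DataFrame,
    f2_calls: pd.DataFrame,
    category: str,
    label_column: str = "group",
    id_column: str = "gene_id",
) -> InheritanceSummary:
    """Count genes carrying ``category`` in F1, F2, and both generations.

    Membership is by ``id_column`` equality (``mirna_id`` for the miRNA
    layer); ``label_column`` selects which label is intersected
    (``group`` or ``mpv_status``).
    """
    f1_set = set(f1_calls.loc[f1_calls[label_column] == category, id_column])
    f2_set = set(f2_calls.loc[f2_calls[label_column] == category, id_column])
    return InheritanceSummary(
        category=category,
        n_f1=len(f1_set),
        n_f2=len(f2_set),
        n_both=len(f1_set & f2_set),
    )


def percent_of(n: int, denominator: int) -> float:
    """``100 * n / denominator`` rounded half away from zero to 2 decimals."""
    if denominator == 0:
        raise ValueError("denominator must be nonzero")
    if n < 0:
        raise ValueError("n must be non-negative")
    value = Decimal(100 * n) / Decimal(denominator)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _category_counts(calls: pd.DataFrame, label_column: str = "group") -> dict:
    counts = calls[label_column].value_counts().to_dict()
    return {g: int(counts.get(g, 0)) for g in GROUPS}


def summarize_run(
    trio_f1: pd.DataFrame,
    trio_f2: pd.DataFrame,
    de_calls: dict,
    sets: dict,
    config: AnalysisConfig,
    mirna_trio_f1: pd.DataFrame | None = None,
    mirna_trio_f2: pd.DataFrame | None = None,
):
    """Named run statistics: DE counts/percentages, nonadditive counts,
    per-group classification counts, and cross-generation inheritance.

    ``de_calls`` maps a pair name like ``"P1_vs_P2"`` to its call table;
    ``sets`` is the output of :func:`hybridexpr.trio.expressed_sets`.
    Percentages use the co-expressed gene count as denominator.
    Returns ``(tidy_frame, stats_dict)``; keys are stable across runs.
    """
    stats: dict = {}
    denom = len(sets["co_expressed"])
    stats["n_co_expressed"] = denom
    for label, specific in sorted(sets["specific"].items()):
        stats[f"n_specific_{label}"] = len(specific)

    for pair_name in sorted(de_calls):
        calls = de_calls[pair_name]
        n_de = int((calls["direction"] != "NS").sum())
        n_up = int((calls["direction"] == "UP").sum())
        n_down = int((calls["direction"] == "DOWN").sum())
        stats[f"de_{pair_name}_n"] = n_de
        stats[f"de_{pair_name}_up"] = n_up
        stats[f"de_{pair_name}_down"] = n_down
        if denom > 0:
            stats[f"de_{pair_name}_pct"] = percent_of(n_de, denom)

    for gen, trio in (("F1", trio_f1), ("F2", trio_f2)):
        for group, count in _category_counts(trio).items():
            stats[f"class_{gen}_{group}"] = count
        n_nonadd = int((trio["mpv_status"] != ADDITIVE).sum())
        stats[f"nonadditive_{gen}_n"] = n_nonadd
        stats[f"nonadditive_{gen}_up"] = int((trio["mpv_status"] == NONADDITIVE_UP).sum())
        stats[f"nonadditive_{gen}_down"] = int(
            (trio["mpv_status"] == NONADDITIVE_DOWN).sum()
        )
        if denom > 0:
            stats[f"nonadditive_{gen}_pct"] = percent_of(n_nonadd, denom)

    for group in GROUPS:
        summary = intersect_category(trio_f1, trio_f2, group)
        stats[f"inherit_{group}_f1"] = summary.n_f1
        stats[f"inherit_{group}_f2"] = summary.n_f2
        stats[f"inherit_{group}_both"] = summary.n_both
    for status in (ADDITIVE, NONADDITIVE_UP, NONADDITIVE_DOWN):
        summary = intersect_category(trio_f1, trio_f2, status, "mpv_status")
        stats[f"inherit_mpv_{status}_both"] = summary.n_both

    if mirna_trio_f1 is not None and mirna_trio_f2 is not None:
        for gen, trio in (("F1", mirna_trio_f1), ("F2", mirna_trio_f2)):
            stats[f"mirna_nonadditive_{gen}_n"] = int(
                (trio["mpv_status"] != ADDITIVE).sum()
            )
            stats[f"mirna_activated_{gen}_n"] = int(
                (trio["mpv_status"] == NONADDITIVE_UP).sum()
            )
            stats[f"mirna_repressed_{gen}_n"] = int(
                (trio["mpv_status"] == NONADDITIVE_DOWN).sum()
            )
        for status, name in (
            (NONADDITIVE_UP, "activated"),
            (NONADDITIVE_DOWN, "repressed"),
        ):
            summary = intersect_category(
                mirna_trio_f1, mirna_trio_f2, status, "mpv_status",
                id_column="mirna_id",
            )
            stats[f"mirna_{name}_inherited_both"] = summary.n_both

    tidy = pd.DataFrame(
        {"statistic": list(stats.keys()), "value": list(stats.values())}
    )
    return tidy, stats
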