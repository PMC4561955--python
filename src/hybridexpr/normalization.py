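"""FPKM computation and between-library median-of-ratios scaling."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from hybridexpr.core import (
    ConfigError,
    CountTable,
    DegenerateDataError,
    GeneMeta,
)


@dataclass
class FpkmTable:
    """Fragments per kilobase of transcript per million mapped fragments.

    Same shape and labelling as the :class:`CountTable` it was derived
    from; a value is zero exactly when the underlying count is zero.
    """

    gene_ids: list
    values: np.ndarray
    sample_labels: list

    def sample_index(self, label: str) -> int:
        try:
            return self.sample_labels.index(label)
        except ValueError:
            raise ConfigError(f"sample {label!r} not present in FPKM table") from None

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.sample_index(label)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.sample_labels)
        df.insert(0, "gene_id", self.gene_ids)
        return df


def compute_fpkm(counts: CountTable, meta: Mapping[str, GeneMeta]) -> FpkmTable:
    """Elementwise ``10^9 * C / (N * L)``.

    ``C`` is the fragment count, ``N`` the library's mapped-fragment
    total and ``L`` the transcript length in bp.  Every gene in the
    table must have a length in ``meta``.
    """
    lengths = np.empty(counts.n_genes, dtype=np.float64)
    for i, gid in enumerate(counts.gene_ids):
        m = meta.get(gid)
        if m is None:
            raise ConfigError(f"gene {gid!r} has no length in metadata")
        lengths[i] = m.length_bp
    if np.any(counts.library_sizes <= 0):
        raise DegenerateDataError("library sizes must be positive for FPKM")
    n = counts.library_sizes.astype(np.float64)
    values = 1e9 * counts.counts / (n[None, :] * lengths[:, None])
    return FpkmTable(list(counts.gene_ids), values, list(counts.sample_labels))


def size_factors_median_ratio(counts: CountTable) -> pd.Series:
    """Median-of-ratios size factors, renormalized to geometric mean 1.

    Only genes with strictly positive counts in every sample enter the
    median (the per-gene geometric mean is undefined at zero).  The raw
    factor for sample ``j`` is the median over those genes of
    ``count_gj / geometric_mean_g``; factors are then divided by their
    own geometric mean.
    """
    c = counts.counts.astype(np.float64)
    positive = np.all(c > 0, axis=1)
    if not np.any(positive):
        raise DegenerateDataError(
            "no gene has positive counts in all samples; size factors undefined"
        )
    logc = np.log(c[positive])
    log_gm = logc.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logc - log_gm, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=list(counts.sample_labels), name="size_factor")
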