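"""Shared domain types, configuration, and errors.

Sample roles are fixed by label, not column position: ``P1`` is the
maternal parent, ``P2`` the paternal parent, ``F1`` and ``F2`` the two
hybrid generations.  All downstream polarity (which parent an
expression-level-dominance call points at) derives from these labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping

import numpy as np
import yaml

#: Canonical sample labels in canonical order.
SAMPLES = ("P1", "P2", "F1", "F2")

#: Labels naming a hybrid generation.
GENERATIONS = ("F1", "F2")


class FormatError(ValueError):
    """Malformed input data (bad cell values, duplicate identifiers...)."""


class ConfigError(ValueError):
    """Invalid configuration or a missing required column/sample/length."""


class DegenerateDataError(ValueError):
    """Input is structurally valid but statistically degenerate."""


@dataclass
class CountTable:
    """Integer fragment counts for a set of genes across named libraries.

    Parameters
    ----------
    gene_ids : list of str
        Row identifiers, in input order. Must be unique.
    counts : ndarray of int, shape (n_genes, n_samples)
        Non-negative fragment counts.
    sample_labels : list of str
        Column labels; must be unique.
    library_sizes : ndarray of int, optional
        Per-library mapped-fragment totals.  Defaults to column sums.
        When given explicitly each total must be at least the column sum
        (a mapped-fragment total can exceed, never undercut, the counted
        fragments).
    """

    gene_ids: list
    counts: np.ndarray
    sample_labels: list
    library_sizes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_labels = list(self.sample_labels)
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise FormatError("counts must be a 2-D genes x samples matrix")
        if counts.shape != (len(self.gene_ids), len(self.sample_labels)):
            raise FormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_labels)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise FormatError("counts must be integers")
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise FormatError("counts must be non-negative")
        self.counts = counts.astype(np.int64, copy=False)
        if len(set(self.sample_labels)) != len(self.sample_labels):
            raise FormatError("duplicate sample labels")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            seen, dup = set(), None
            for g in self.gene_ids:
                if g in seen:
                    dup = g
                    break
                seen.add(g)
            raise FormatError(f"duplicate gene_id: {dup!r}")
        colsums = self.counts.sum(axis=0) if self.counts.size else np.zeros(
            len(self.sample_labels), dtype=np.int64
        )
        if self.library_sizes is None:
            self.library_sizes = colsums.astype(np.int64)
        else:
            ls = np.asarray(self.library_sizes, dtype=np.int64)
            if ls.shape != (len(self.sample_labels),):
                raise FormatError("library_sizes must have one entry per sample")
            if np.any(ls <= 0):
                raise FormatError("library_sizes must be positive")
            if np.any(ls < colsums):
                raise FormatError(
                    "explicit library_sizes must be >= column sums "
                    "(mapped totals cannot undercount the table)"
                )
            self.library_sizes = ls

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_labels)

    def sample_index(self, label: str) -> int:
        try:
            return self.sample_labels.index(label)
        except ValueError:
            raise ConfigError(f"sample {label!r} not present in table") from None

    def column(self, label: str) -> np.ndarray:
        """Counts for one sample, in gene order."""
        return self.counts[:, self.sample_index(label)]

    def library_size(self, label: str) -> int:
        return int(self.library_sizes[self.sample_index(label)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_labels == other.sample_labels
            and np.array_equal(self.counts, other.counts)
            and np.array_equal(self.library_sizes, other.library_sizes)
        )


@dataclass(frozen=True)
class GeneMeta:
    """Per-gene metadata: transcript length and annotation terms."""

    gene_id: str
    length_bp: int
    go_terms: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise FormatError(
                f"gene {self.gene_id!r}: length_bp must be >= 1, got {self.length_bp}"
            )
        object.__setattr__(self, "go_terms", frozenset(self.go_terms))


@dataclass(frozen=True)
class MiRNATargetMap:
    """Many-to-many miRNA -> target-gene links."""

    links: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        links = list(self.links)
        if len(links) != len(set(links)):
            raise FormatError("duplicate (mirna_id, gene_id) links")
        for link in links:
            if len(link) != 2:
                raise FormatError(f"link must be a (mirna_id, gene_id) pair: {link!r}")
        object.__setattr__(self, "links", frozenset(tuple(l) for l in links))

    @property
    def mirna_ids(self) -> set:
        return {m for m, _ in self.links}

    @property
    def gene_ids(self) -> set:
        return {g for _, g in self.links}

    def targets_of(self, mirna_id: str) -> set:
        return {g for m, g in self.links if m == mirna_id}

    def __len__(self) -> int:
        return len(self.links)

    def __iter__(self):
        return iter(sorted(self.links))


@dataclass
class AnalysisConfig:
    """Thresholds and knobs shared across the pipeline.

    ``fdr_gene`` gates gene-layer calls at ``q <= fdr_gene`` while
    ``fdr_mirna`` gates the miRNA layer at the strict ``q < fdr_mirna``,
    mirroring the inequality directions of the two decision rules.
    """

    fdr_gene: float = 0.001
    fdr_mirna: float = 0.05
    fc_threshold: float = 2.0
    min_fpkm_expressed: float = 1.0
    pseudocount: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fdr_gene", "fdr_mirna", "fc_threshold", "min_fpkm_expressed",
                     "pseudocount"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.fc_threshold <= 1:
            raise ConfigError("fc_threshold must be > 1")
        self.seed = int(self.seed)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config YAML must map keys to values")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def require_samples(table: CountTable, labels: Iterable[str]) -> None:
    """Raise :class:`ConfigError` naming the first missing sample label."""
    for label in labels:
        if label not in table.sample_labels:
            raise ConfigError(f"required sample {label!r} missing from table")
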