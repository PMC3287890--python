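"""Replicate-frequency filter for spuriously associated genes.

Long-distance correlation between a non-risk gene's genotypes and a causal
gene makes the non-risk gene significant far more often than chance across
phenotype replicates. The filter flags any non-risk gene significant
(p < alpha, strict) in at least ``min_hits`` of R replicates. The classic
rule is 16 of 200 at alpha = 0.05; :func:`default_min_hits` generalizes it
as the smallest k whose binomial tail P(Bin(R, alpha) >= k) drops to a
target probability (0.05 by default, which reproduces k = 16 at R = 200).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import GeneMap, GeneSet, GeneSetCollection
from .enrichment import GeneScorePanel

__all__ = [
    "ReplicatePValueMatrix",
    "identify_spurious",
    "default_min_hits",
    "exclude_genes",
]


@dataclass
class ReplicatePValueMatrix:
    """Replicate x gene matrix of gene-level p-values for one test."""

    pvalues: np.ndarray  # (R, G), entries in (0, 1]
    gene_ids: list[str]
    risk_genes: Sequence[str] = ()

    def __post_init__(self) -> None:
        self.pvalues = np.asarray(self.pvalues, dtype=float)
        self.gene_ids = list(self.gene_ids)
        if self.pvalues.ndim != 2 or self.pvalues.shape[1] != len(self.gene_ids):
            raise ValueError("pvalues must be (R, G) matching gene_ids")
        if (self.pvalues <= 0).any() or (self.pvalues > 1).any():
            raise ValueError("p-values must lie in (0, 1]")
        unknown = set(self.risk_genes) - set(self.gene_ids)
        if unknown:
            raise ValueError(f"risk genes absent from gene list: {sorted(unknown)[:5]}")

    @property
    def n_replicates(self) -> int:
        return self.pvalues.shape[0]

    @classmethod
    def from_table(cls, path, risk_genes: Sequence[str] = ()) -> "ReplicatePValueMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(dtype=float), [str(c) for c in df.columns], risk_genes)

    def write(self, path) -> None:
        df = pd.DataFrame(self.pvalues, columns=self.gene_ids)
        df.index.name = "replicate"
        df.to_csv(path, sep="\t")


def default_min_hits(R: int, alpha: float = 0.05, tail: float = 0.05) -> int:
    """Smallest k with P(Bin(R, alpha) >= k) <= tail, clamped to >= 1.

    With R = 200, alpha = 0.05, tail = 0.05 this returns 16 (implied tail
    probability 0.0444), matching the 16-of-200 convention.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    # sf(k-1) = P(X >= k); scan for the smallest qualifying k
    for k in range(1, R + 1):
        if stats.binom.sf(k - 1, R, alpha) <= tail:
            return k
    return R


def identify_spurious(
    m: ReplicatePValueMatrix, alpha: float = 0.05, min_hits: int | None = None
) -> list[str]:
    """Non-risk genes with p < alpha (strict) in at least min_hits replicates.

    Risk genes are never returned. ``min_hits`` defaults to
    :func:`default_min_hits` for the matrix's replicate count.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    R = m.n_replicates
    if min_hits is None:
        min_hits = default_min_hits(R, alpha)
    if not 1 <= min_hits <= R:
        raise ValueError(f"min_hits must be in [1, {R}]")
    hits = np.sum(m.pvalues < alpha, axis=0)
    risk = set(m.risk_genes)
    return [
        g for g, h in zip(m.gene_ids, hits) if h >= min_hits and g not in risk
    ]


def exclude_genes(obj, genes: Sequence[str]):
    """Remove the listed genes from a gene-indexed structure.

    Supports GeneScorePanel, GeneMap, GeneSet, GeneSetCollection and
    ReplicatePValueMatrix; unknown genes warn rather than raise. Returns a
    new object of the same kind (a GeneSet emptied of all its members
    returns None).
    """
    drop = set(genes)
    if isinstance(obj, GeneScorePanel):
        return obj.exclude(genes)
    if isinstance(obj, GeneMap):
        unknown = drop - set(obj.genes)
        if unknown:
            warnings.warn(f"genes not in map: {sorted(unknown)[:5]}", stacklevel=2)
        return obj.without_genes(genes)
    if isinstance(obj, GeneSet):
        kept = tuple(g for g in obj.genes if g not in drop)
        if not kept:
            warnings.warn(f"gene set {obj.name!r} emptied by exclusion", stacklevel=2)
            return None
        return GeneSet(obj.name, kept, obj.description)
    if isinstance(obj, GeneSetCollection):
        out = GeneSetCollection()
        for s in obj.values():
            fs = exclude_genes(s, genes)
            if fs is not None:
                out.add(fs)
        return out
    if isinstance(obj, ReplicatePValueMatrix):
        unknown = drop - set(obj.gene_ids)
        if unknown:
            warnings.warn(f"genes not in matrix: {sorted(unknown)[:5]}", stacklevel=2)
        keep = [i for i, g in enumerate(obj.gene_ids) if g not in drop]
        return ReplicatePValueMatrix(
            obj.pvalues[:, keep],
            [obj.gene_ids[i] for i in keep],
            [g for g in obj.risk_genes if g not in drop],
        )
    raise TypeError(f"cannot exclude genes from {type(obj).__name__}")
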