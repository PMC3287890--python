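"""Gene-set enrichment on gene-level association scores.

Two set-level tests operate on a :class:`GeneScorePanel` — the per-gene
observed scores together with the same scores recomputed under B shared
phenotype permutations:

* **GSEA** applies the running-sum enrichment statistic directly to the raw
  gene scores: genes are ranked by decreasing score; walking down the ranked
  list, the running sum gains |score|^exponent / N_R at member genes (N_R
  normalizes member weights to 1) and loses 1/(N - m) at non-members. The
  enrichment score ES is the signed maximum-magnitude deviation. With
  exponent 0 this is the classical two-sample Kolmogorov–Smirnov statistic
  between member and non-member rank distributions.

* **VSEA** first standardizes each gene's score against that gene's own
  permutation distribution — adjusted = (score - mu_g) / sigma_g with mu_g,
  sigma_g the mean and SD of the gene's B permutation scores — and then runs
  the identical enrichment statistic on the adjusted panel. Genes differ in
  size and allele-frequency composition, hence in the null spread and
  discreteness of their scores; without this normalization, large genes with
  smooth, heavy-tailed score nulls dominate the top of the ranking and drown
  the signal carried by small rare-variant genes.

Significance uses the shared phenotype-permutation null by default (ES
recomputed on each permutation row; one-sided, enrichment only), which
preserves gene–gene correlation. A gene-resampling null (random member sets
of the same size) is available as an alternative.

Gene scores are -log10(p) of the gene-level test, applied identically to
observed and permuted p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "GeneScorePanel",
    "EnrichmentResult",
    "scores_from_pvalues",
    "enrichment_score",
    "gsea_test",
    "vsea_adjust",
    "vsea_test",
    "enrichment_table",
]


def scores_from_pvalues(p: np.ndarray, floor: float | None = None) -> np.ndarray:
    """Transform p-values to gene scores, score = -log10(p).

    ``floor`` (e.g. the permutation floor 1/(B+1)) replaces any p = 0 with a
    warning; p outside (0, 1] otherwise raises.
    """
    p = np.asarray(p, dtype=float)
    if (p == 0).any():
        if floor is None:
            raise ValueError("p = 0 encountered and no floor given")
        warnings.warn("clipping p = 0 to the permutation floor", stacklevel=2)
        p = np.maximum(p, floor)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return -np.log10(p)


@dataclass
class GeneScorePanel:
    """Observed gene scores plus the B x G matrix of the same scores under
    shared phenotype permutations.

    ``adjusted`` marks a panel already standardized per gene by
    :func:`vsea_adjust` (scores are then z-like, not -log10 p).
    """

    gene_ids: list[str]
    scores: np.ndarray  # (G,)
    perm_scores: np.ndarray  # (B, G)
    test: str = ""
    seed: int | None = None
    flags: np.ndarray | None = None  # per-gene degeneracy
    adjusted: bool = False

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.scores = np.asarray(self.scores, dtype=float)
        self.perm_scores = np.asarray(self.perm_scores, dtype=float)
        G = len(self.gene_ids)
        if self.scores.shape != (G,):
            raise ValueError("scores length must match gene_ids")
        if self.perm_scores.ndim != 2 or self.perm_scores.shape[1] != G:
            raise ValueError("perm_scores must be (B, G)")
        if self.flags is None:
            self.flags = np.zeros(G, dtype=bool)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_permutations(self) -> int:
        return self.perm_scores.shape[0]

    @classmethod
    def from_pvalues(
        cls,
        gene_ids: Sequence[str],
        obs_p: np.ndarray,
        perm_p: np.ndarray,
        test: str = "",
        seed: int | None = None,
        flags: np.ndarray | None = None,
    ) -> "GeneScorePanel":
        B = np.asarray(perm_p).shape[0]
        floor = 1.0 / (B + 1.0)
        return cls(
            list(gene_ids),
            scores_from_pvalues(obs_p, floor),
            scores_from_pvalues(perm_p, floor),
            test=test,
            seed=seed,
            flags=flags,
        )

    def exclude(self, genes: Sequence[str]) -> "GeneScorePanel":
        """Panel with the listed genes' columns removed (unknown genes warn)."""
        drop = set(genes)
        unknown = drop - set(self.gene_ids)
        if unknown:
            warnings.warn(f"genes not in panel: {sorted(unknown)[:5]}", stacklevel=2)
        keep = np.array([g not in drop for g in self.gene_ids])
        return GeneScorePanel(
            [g for g, k in zip(self.gene_ids, keep) if k],
            self.scores[keep],
            self.perm_scores[:, keep],
            test=self.test,
            seed=self.seed,
            flags=self.flags[keep],
            adjusted=self.adjusted,
        )


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    p: float
    method: str
    set_size: int
    n_permutations: int


def _ranking_order(score_rows: np.ndarray, id_rank: np.ndarray) -> np.ndarray:
    """Column order of each row sorted by decreasing score, ties broken by
    stable gene-id order (deterministic across reruns)."""
    by_id = np.argsort(id_rank, kind="stable")
    ordered = score_rows[:, by_id]
    o = np.argsort(-ordered, axis=1, kind="stable")
    return by_id[o]


def _running_sum_es(
    score_rows: np.ndarray,
    member_mask: np.ndarray,
    exponent: float,
    order: np.ndarray | None = None,
    id_rank: np.ndarray | None = None,
) -> np.ndarray:
    """Signed max-magnitude running-sum deviation, one ES per row."""
    R, G = score_rows.shape
    m = int(member_mask.sum())
    if order is None:
        order = _ranking_order(score_rows, id_rank)
    ordered_scores = np.take_along_axis(score_rows, order, axis=1)
    ordered_member = member_mask[order]
    w = np.abs(ordered_scores) ** exponent * ordered_member
    nr = w.sum(axis=1, keepdims=True)
    # all member weights zero: fall back to unweighted (KS) hit increments
    flat = (nr[:, 0] == 0)
    if flat.any():
        w[flat] = ordered_member[flat].astype(float)
        nr = w.sum(axis=1, keepdims=True)
    hits = np.cumsum(w, axis=1) / nr
    misses = np.cumsum(~ordered_member, axis=1) / (G - m)
    run = hits - misses
    idx = np.argmax(np.abs(run), axis=1)
    return run[np.arange(R), idx]


def _resolve_members(panel: GeneScorePanel, genes: Sequence[str]) -> np.ndarray:
    pos = {g: i for i, g in enumerate(panel.gene_ids)}
    unresolved = [g for g in genes if g not in pos]
    if unresolved:
        raise KeyError(f"gene set members absent from panel: {unresolved}")
    mask = np.zeros(panel.n_genes, dtype=bool)
    mask[[pos[g] for g in genes]] = True
    if mask.all() or not mask.any():
        raise ValueError("gene set must be a proper non-empty subset of the panel")
    return mask


def enrichment_score(
    scores: np.ndarray,
    members: Sequence[str] | np.ndarray,
    gene_ids: Sequence[str] | None = None,
    exponent: float = 1.0,
) -> float:
    """Running-sum enrichment score of one gene subset in one score vector.

    ``members`` may be a boolean mask aligned with ``scores`` or a list of
    gene ids resolved against ``gene_ids``.
    """
    scores = np.asarray(scores, dtype=float)
    if isinstance(members, np.ndarray) and members.dtype == bool:
        mask = members
    else:
        if gene_ids is None:
            raise ValueError("gene_ids required to resolve member names")
        pos = {g: i for i, g in enumerate(gene_ids)}
        unresolved = [g for g in members if g not in pos]
        if unresolved:
            raise KeyError(f"unresolvable gene ids: {unresolved}")
        mask = np.zeros(len(scores), dtype=bool)
        mask[[pos[g] for g in members]] = True
    if mask.all() or not mask.any():
        raise ValueError("members must be a proper non-empty subset")
    id_rank = _id_rank(gene_ids if gene_ids is not None else [str(i) for i in range(len(scores))])
    return float(_running_sum_es(scores[None, :], mask, exponent, id_rank=id_rank)[0])


def _id_rank(gene_ids: Sequence[str]) -> np.ndarray:
    order = np.argsort(np.asarray(gene_ids, dtype=object))
    rank = np.empty(len(gene_ids), dtype=np.intp)
    rank[order] = np.arange(len(gene_ids))
    return rank


class _RankedPanel:
    """Cached rankings of a panel's observed + permutation rows, so many gene
    sets can be tested against the same panel without re-sorting."""

    def __init__(self, panel: GeneScorePanel):
        self.panel = panel
        self.id_rank = _id_rank(panel.gene_ids)
        rows = np.vstack([panel.scores[None, :], panel.perm_scores])
        self.rows = rows
        self.order = _ranking_order(rows, self.id_rank)

    def test(self, members: Sequence[str], exponent: float, method: str, set_name: str) -> EnrichmentResult:
        mask = _resolve_members(self.panel, members)
        es = _running_sum_es(self.rows, mask, exponent, order=self.order)
        es_obs, es_null = es[0], es[1:]
        B = len(es_null)
        p = (1.0 + np.sum(es_null >= es_obs)) / (B + 1.0)
        return EnrichmentResult(set_name, float(es_obs), float(p), method, int(mask.sum()), B)


def gsea_test(
    panel: GeneScorePanel,
    gene_set,
    exponent: float = 1.0,
    null: str = "permutation",
    n_random: int = 1000,
    rng: np.random.Generator | None = None,
    method: str = "GSEA",
) -> EnrichmentResult:
    """Enrichment test of one gene set against the panel.

    ``null='permutation'`` (default) recomputes ES on every shared phenotype
    permutation row; ``null='geneset'`` instead compares against ES of
    ``n_random`` random member sets of the same size drawn from the panel's
    genes (observed scores only). One-sided: enrichment, ES_null >= ES_obs.
    """
    name, genes = _set_name_genes(gene_set)
    if null == "permutation":
        return _RankedPanel(panel).test(genes, exponent, method, name)
    if null != "geneset":
        raise ValueError(f"unknown null {null!r}")
    mask = _resolve_members(panel, genes)
    id_rank = _id_rank(panel.gene_ids)
    row = panel.scores[None, :]
    order = _ranking_order(row, id_rank)
    es_obs = float(_running_sum_es(row, mask, exponent, order=order)[0])
    if rng is None:
        rng = np.random.default_rng(panel.seed)
    m = int(mask.sum())
    es_null = np.empty(n_random)
    for i in range(n_random):
        rmask = np.zeros(panel.n_genes, dtype=bool)
        rmask[rng.choice(panel.n_genes, size=m, replace=False)] = True
        es_null[i] = _running_sum_es(row, rmask, exponent, order=order)[0]
    p = (1.0 + np.sum(es_null >= es_obs)) / (n_random + 1.0)
    return EnrichmentResult(name, es_obs, float(p), method, m, n_random)


def vsea_adjust(panel: GeneScorePanel) -> GeneScorePanel:
    """Standardize every gene's score by its own permutation distribution.

    Adjusted observed score = (score - mu_g)/sigma_g; each permutation row is
    adjusted identically, so the panel invariant (observed and null rows
    produced by one procedure) is preserved. Requires B >= 10; genes whose
    permutation scores are constant (sigma = 0) get adjusted scores 0 and a
    degeneracy flag. Idempotent: adjusting an adjusted panel is a no-op.
    """
    B = panel.n_permutations
    if B < 10:
        raise ValueError(f"B = {B} < 10 permutations: adjustment would be unstable")
    mu = panel.perm_scores.mean(axis=0)
    sigma = panel.perm_scores.std(axis=0, ddof=1)
    # a numerically constant permutation column has sd at round-off scale
    degenerate = sigma <= 1e-12 * np.maximum(1.0, np.abs(mu))
    safe = np.where(degenerate, 1.0, sigma)
    scores = np.where(degenerate, 0.0, (panel.scores - mu) / safe)
    perm = np.where(degenerate[None, :], 0.0, (panel.perm_scores - mu[None, :]) / safe[None, :])
    return GeneScorePanel(
        panel.gene_ids,
        scores,
        perm,
        test=panel.test,
        seed=panel.seed,
        flags=panel.flags | degenerate,
        adjusted=True,
    )


def vsea_test(panel: GeneScorePanel, gene_set, exponent: float = 1.0, **kwargs) -> EnrichmentResult:
    """GSEA on the permutation-standardized panel; method label VSEA."""
    if not panel.adjusted:
        panel = vsea_adjust(panel)
    return gsea_test(panel, gene_set, exponent=exponent, method="VSEA", **kwargs)


def _set_name_genes(gene_set) -> tuple[str, Sequence[str]]:
    if hasattr(gene_set, "genes"):
        return gene_set.name, list(gene_set.genes)
    return "set", list(gene_set)


def enrichment_table(
    panel: GeneScorePanel,
    sets,
    methods: Sequence[str] = ("GSEA", "VSEA"),
    exponent: float = 1.0,
):
    """Test many gene sets against one panel, sharing the sort work.

    ``sets`` is an iterable of GeneSet (or a GeneSetCollection). Returns a
    pandas DataFrame: set, method, gene_test, ES, p, set_size, B, seed.
    """
    import pandas as pd

    if hasattr(sets, "values"):
        sets = list(sets.values())
    ranked = {}
    if "GSEA" in methods:
        ranked["GSEA"] = _RankedPanel(panel)
    if "VSEA" in methods:
        ranked["VSEA"] = _RankedPanel(panel if panel.adjusted else vsea_adjust(panel))
    rows = []
    for s in sets:
        name, genes = _set_name_genes(s)
        for method, rp in ranked.items():
            r = rp.test(genes, exponent, method, name)
            rows.append(
                {
                    "set": r.set_name,
                    "method": r.method,
                    "gene_test": panel.test,
                    "ES": r.es,
                    "p": r.p,
                    "set_size": r.set_size,
                    "B": r.n_permutations,
                    "seed": panel.seed,
                }
            )
    return pd.DataFrame(rows)
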