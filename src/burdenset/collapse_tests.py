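"""Gene-level collapsing association tests for a quantitative trait.

Rare variants are individually almost untestable at population sample sizes,
so a gene's rare variants (MAF <= 0.01 by default) are aggregated into a
single collapsed variable before testing. Four tests are provided:

``CMC-1``
    Combined multivariate and collapsing with a 0/1 carrier indicator: the
    collapsed variable is 1 iff the individual carries at least one minor
    allele at any rare variant. The indicator is entered into an ordinary
    least-squares regression of the trait together with the gene's common
    variants, and the gene p-value is the joint F-test of all genetic
    coefficients against the intercept-only model.
``CMC-count``
    As CMC-1, but the collapsed variable is the total count of rare-allele
    copies.
``WeightSum1``
    Weighted-sum collapse of *all* the gene's variants (each variant's dosage
    divided by a weight that grows with its allele frequency, so rare alleles
    dominate), tested by a phenotype-permutation test of the centered cross
    product between the collapsed score and the trait.
``WeightSum2``
    The same weighted-sum score, tested by simple linear regression of the
    trait on the score (two-sided slope t-test).

Variant weights follow the inverse-standard-deviation form: for variant j
with m_j minor-allele copies among n_j genotyped individuals,

    q_j = (m_j + 1) / (2 n_j + 2),      w_j = sqrt(n_j q_j (1 - q_j)),

and an individual's score is sum_j dosage_ij / w_j. The pseudo-count keeps
every weight strictly positive. The weighted-sum method was originally posed
for case-control data with frequencies estimated in unaffected individuals;
for a quantitative trait there is no such split, so q_j uses the whole
sample.

A shared :class:`PermutationPlan` drives every permutation computation: the
same permuted phenotype vector is applied to *all* genes within one
permutation, which preserves inter-gene correlation — exactly what the
downstream set-enrichment null requires. :class:`Step1Engine` precomputes
per-gene design bases once (genotypes are fixed across phenotype replicates)
and evaluates all genes x all permutations with a handful of matrix
products, which is what makes 2,000-permutation sweeps over hundreds of
genes cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import GeneMap, GenotypeMatrix, Phenotype, partition_variants
from .enrichment import GeneScorePanel

__all__ = [
    "TESTS",
    "F_TESTS",
    "PermutationPlan",
    "CollapsedVariable",
    "GeneTestResult",
    "Step1Engine",
    "Step1Result",
    "cmc_collapse",
    "weighted_sum_collapse",
    "cmc_test",
    "weightsum1_test",
    "weightsum2_test",
    "run_step1",
]

TESTS = ("CMC-1", "CMC-count", "WeightSum1", "WeightSum2")
#: tests whose statistic is an OLS F (analytic p available)
F_TESTS = ("CMC-1", "CMC-count", "WeightSum2")

_P_FLOOR = 1e-300  # analytic p of a numerically perfect fit


@dataclass(frozen=True)
class PermutationPlan:
    """An ordered list of sample-index permutations shared across genes.

    ``exhaustive`` marks a plan enumerating all n! permutations (identity
    included), in which case permutation p-values are exact enumeration
    p-values r/B rather than the add-one estimator (r+1)/(B+1).
    """

    indices: np.ndarray  # (B, n) int
    seed: int | None = None
    exhaustive: bool = False

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.intp)
        if idx.ndim != 2:
            raise ValueError("permutation indices must be a (B, n) matrix")
        expect = np.arange(idx.shape[1])
        if not np.all(np.sort(idx, axis=1) == expect):
            raise ValueError("every permutation row must be a bijection of 0..n-1")
        object.__setattr__(self, "indices", idx)

    @property
    def n_permutations(self) -> int:
        return self.indices.shape[0]

    @property
    def n_samples(self) -> int:
        return self.indices.shape[1]

    @classmethod
    def random(cls, n_samples: int, n_permutations: int, seed: int) -> "PermutationPlan":
        """B independent uniform permutations from a seeded generator."""
        rng = np.random.default_rng(seed)
        idx = np.array([rng.permutation(n_samples) for _ in range(n_permutations)])
        return cls(idx, seed=seed)

    @classmethod
    def exhaustive_plan(cls, n_samples: int) -> "PermutationPlan":
        """All n! permutations in lexicographic order (n <= 8)."""
        if n_samples > 8:
            raise ValueError("exhaustive enumeration limited to n <= 8")
        from itertools import permutations

        idx = np.array(list(permutations(range(n_samples))), dtype=np.intp)
        return cls(idx, seed=None, exhaustive=True)

    def phenotype_columns(self, y: np.ndarray) -> np.ndarray:
        """Matrix (n, B+1): observed y in column 0, permuted copies after."""
        y = np.asarray(y, dtype=float)
        out = np.empty((len(y), self.n_permutations + 1))
        out[:, 0] = y
        out[:, 1:] = y[self.indices.T]
        return out


@dataclass
class CollapsedVariable:
    """A per-individual collapsed genotype summary for one gene."""

    values: np.ndarray
    mode: str  # indicator | count | weighted_sum
    variant_indices: np.ndarray
    weights: np.ndarray | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.variant_indices = np.asarray(self.variant_indices, dtype=np.intp)
        if self.mode == "indicator" and not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("indicator values must be 0/1")
        if self.mode == "count" and (self.values < 0).any():
            raise ValueError("count values must be non-negative")


@dataclass
class GeneTestResult:
    gene: str
    test: str
    statistic: float
    p_analytic: float | None
    p_permutation: float | None = None
    dfn: int = 0
    dfd: int = 0
    degenerate: bool = False


def cmc_collapse(g: GenotypeMatrix, rare: Sequence[int], mode: str = "indicator") -> CollapsedVariable:
    """Collapse a gene's rare variants into one variable.

    ``indicator``: 1 iff the individual carries any rare minor allele;
    ``count``: the number of rare-allele copies (missing mean-imputed).
    An empty rare index set yields an all-zero degenerate variable.
    """
    rare = np.asarray(rare, dtype=np.intp)
    if mode not in ("indicator", "count"):
        raise ValueError(f"unknown collapse mode {mode!r}")
    if rare.size == 0:
        return CollapsedVariable(
            np.zeros(g.n_samples), mode, rare, degenerate=True
        )
    if mode == "indicator":
        carrier = np.nan_to_num(g.dosages[:, rare], nan=0.0) > 0
        values = carrier.any(axis=1).astype(float)
    else:
        values = g.imputed()[:, rare].sum(axis=1)
    return CollapsedVariable(values, mode, rare)


def weighted_sum_collapse(g: GenotypeMatrix, variants: Sequence[int]) -> CollapsedVariable:
    """Frequency-weighted sum of all the gene's variant dosages.

    Weights are strictly positive thanks to the pseudo-count, so the score is
    always defined; rarer variants receive larger 1/w multipliers.
    """
    variants = np.asarray(variants, dtype=np.intp)
    if variants.size == 0:
        return CollapsedVariable(
            np.zeros(g.n_samples), "weighted_sum", variants, degenerate=True
        )
    dos = g.dosages[:, variants]
    n_called = np.sum(~np.isnan(dos), axis=0)
    m = np.nansum(dos, axis=0)
    q = (m + 1.0) / (2.0 * n_called + 2.0)
    w = np.sqrt(n_called * q * (1.0 - q))
    values = g.imputed()[:, variants] @ (1.0 / w)
    return CollapsedVariable(values, "weighted_sum", variants, weights=w)


def _orthonormal_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of the *centered* design.

    Rank-deficient designs (duplicate or constant columns) reduce cleanly;
    the returned basis may have fewer columns than X.
    """
    Xc = X - X.mean(axis=0)
    if Xc.size == 0:
        return Xc
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        return U[:, :0]
    keep = s > s[0] * max(Xc.shape) * np.finfo(float).eps
    return U[:, keep]


def _f_pvalues(Q: np.ndarray, Yc: np.ndarray, tss: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Joint F statistic and p for each centered phenotype column of Yc,
    given an orthonormal basis Q of the centered genetic design."""
    n = Yc.shape[0]
    dfn = Q.shape[1]
    dfd = n - 1 - dfn
    ess = np.einsum("ij,ik->jk", Q, Yc) ** 2  # (dfn, K)
    ess = ess.sum(axis=0)
    rss = np.maximum(tss - ess, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ess / dfn) / (rss / dfd)
    F = np.where(rss > 0, F, np.inf)
    p = np.clip(stats.f.sf(F, dfn, dfd), _P_FLOOR, 1.0)
    return F, p


def cmc_test(
    y: Phenotype | np.ndarray,
    collapsed: CollapsedVariable,
    common: Sequence[int],
    g: GenotypeMatrix,
    joint: bool = True,
) -> GeneTestResult:
    """OLS test of the trait on [collapsed variable, common variants].

    ``joint=True`` (default) reports the F-test of *all* genetic coefficients
    against the intercept-only model; ``joint=False`` reports the partial
    F-test of the collapsed variable conditional on the common variants.
    Constant designs or a constant trait give p = 1 with a degenerate flag.
    """
    yv = y.values if isinstance(y, Phenotype) else np.asarray(y, dtype=float)
    common = np.asarray(common, dtype=np.intp)
    X = np.column_stack([collapsed.values, g.imputed()[:, common]])
    keep = X.std(axis=0) > 0
    X = X[:, keep]
    gene = "?"
    if X.shape[1] == 0 or np.std(yv) == 0:
        return GeneTestResult(gene, "CMC", 0.0, 1.0, dfn=0, dfd=0, degenerate=True)
    n = len(yv)
    if n < X.shape[1] + 2:
        raise ValueError(f"n={n} too small for {X.shape[1]} genetic predictors")
    yc = (yv - yv.mean())[:, None]
    tss = float((yc**2).sum())
    Q = _orthonormal_basis(X)
    if Q.shape[1] == 0:
        return GeneTestResult(gene, "CMC", 0.0, 1.0, dfn=0, dfd=0, degenerate=True)
    if joint:
        F, p = _f_pvalues(Q, yc, np.array([tss]))
        return GeneTestResult(
            gene, "CMC", float(F[0]), float(p[0]), dfn=Q.shape[1], dfd=n - 1 - Q.shape[1]
        )
    # partial F: extra explained SS of the full model over the common-only model
    Qr = _orthonormal_basis(g.imputed()[:, common]) if common.size else np.empty((n, 0))
    ess_full = float(((Q.T @ yc) ** 2).sum())
    ess_red = float(((Qr.T @ yc) ** 2).sum()) if Qr.size else 0.0
    df_extra = Q.shape[1] - (Qr.shape[1] if Qr.size else 0)
    if df_extra <= 0:
        return GeneTestResult(gene, "CMC", 0.0, 1.0, degenerate=True)
    dfd = n - 1 - Q.shape[1]
    rss_full = max(tss - ess_full, 0.0)
    F = ((ess_full - ess_red) / df_extra) / (rss_full / dfd) if rss_full > 0 else np.inf
    p = float(np.clip(stats.f.sf(F, df_extra, dfd), _P_FLOOR, 1.0))
    return GeneTestResult(gene, "CMC", float(F), p, dfn=df_extra, dfd=dfd)


def weightsum1_test(
    y: Phenotype | np.ndarray, s: CollapsedVariable, plan: PermutationPlan
) -> GeneTestResult:
    """Permutation test of T = |sum_i (s_i - s̄)(y_i - ȳ)|.

    p = (r+1)/(B+1) for random plans; for an exhaustive plan the exact
    enumeration p = r/B (the identity permutation is one of the B rows, so
    r >= 1 and the p-value cannot be zero).
    """
    yv = y.values if isinstance(y, Phenotype) else np.asarray(y, dtype=float)
    sv = s.values
    if np.std(sv) == 0 or np.std(yv) == 0:
        return GeneTestResult("?", "WeightSum1", 0.0, None, 1.0, degenerate=True)
    sc = sv - sv.mean()
    yc = yv - yv.mean()
    if plan.n_permutations < 1:
        raise ValueError("plan must contain at least one permutation")
    t_obs = abs(float(sc @ yc))
    t_perm = np.abs(sc @ yc[plan.indices.T])
    # count ties up to floating round-off (the identity permutation's
    # statistic must tie the observed one exactly)
    r = int(np.sum(t_perm >= t_obs * (1.0 - 1e-12)))
    if plan.exhaustive:
        p = r / plan.n_permutations
    else:
        p = (1 + r) / (plan.n_permutations + 1)
    return GeneTestResult("?", "WeightSum1", t_obs, None, p)


def weightsum2_test(y: Phenotype | np.ndarray, s: CollapsedVariable) -> GeneTestResult:
    """Simple linear regression of the trait on the weighted-sum score;
    two-sided t-test for the slope."""
    yv = y.values if isinstance(y, Phenotype) else np.asarray(y, dtype=float)
    if np.std(s.values) == 0 or np.std(yv) == 0:
        return GeneTestResult("?", "WeightSum2", 0.0, 1.0, degenerate=True)
    fit = stats.linregress(s.values, yv)
    t = fit.slope / fit.stderr if fit.stderr > 0 else np.inf
    p = float(np.clip(fit.pvalue, _P_FLOOR, 1.0))
    return GeneTestResult("?", "WeightSum2", float(t), p, dfn=1, dfd=len(yv) - 2)


# ---------------------------------------------------------------------------
# batched engine


@dataclass
class _StackedDesigns:
    """Per-test stacked orthonormal designs for all genes."""

    Q: np.ndarray  # (n, total_rank) concatenated bases of non-degenerate genes
    starts: np.ndarray  # reduceat offsets into Q's columns, one per active gene
    active: np.ndarray  # indices of non-degenerate genes
    dfn: np.ndarray  # rank per active gene


class Step1Engine:
    """Precomputed gene designs for fast phenotype sweeps.

    Genotypes are fixed across phenotype replicates and permutations, so each
    gene's design basis is computed once; evaluating a new (possibly
    permuted) phenotype column is then a single matrix product per test.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        gene_map: GeneMap,
        tests: Sequence[str] = TESTS,
        maf_threshold: float = 0.01,
    ):
        unknown = set(tests) - set(TESTS)
        if unknown:
            raise ValueError(f"unknown tests: {sorted(unknown)}")
        self.genotypes = genotypes
        self.gene_map = gene_map
        self.tests = tuple(tests)
        self.maf_threshold = maf_threshold
        self.genes = gene_map.genes
        n, G = genotypes.n_samples, len(self.genes)

        want_f = [t for t in self.tests if t in F_TESTS]
        blocks: dict[str, list[np.ndarray]] = {t: [] for t in want_f}
        active: dict[str, list[int]] = {t: [] for t in want_f}
        dfn: dict[str, list[int]] = {t: [] for t in want_f}
        ws_cols = np.zeros((n, G))
        self.degenerate: dict[str, np.ndarray] = {
            t: np.ones(G, dtype=bool) for t in self.tests
        }

        X = genotypes.imputed()
        for gi, gene in enumerate(self.genes):
            part = partition_variants(genotypes, gene_map, gene, maf_threshold)
            poly = np.concatenate([part.rare, part.common])
            designs: dict[str, np.ndarray | None] = {}
            if "CMC-1" in self.tests or "CMC-count" in self.tests:
                commons = X[:, part.common]
                if "CMC-1" in self.tests:
                    ind = cmc_collapse(genotypes, part.rare, "indicator")
                    designs["CMC-1"] = np.column_stack([ind.values, commons])
                if "CMC-count" in self.tests:
                    cnt = cmc_collapse(genotypes, part.rare, "count")
                    designs["CMC-count"] = np.column_stack([cnt.values, commons])
            if "WeightSum1" in self.tests or "WeightSum2" in self.tests:
                ws = weighted_sum_collapse(genotypes, poly)
                if np.std(ws.values) > 0:
                    if "WeightSum1" in self.tests:
                        ws_cols[:, gi] = ws.values - ws.values.mean()
                        self.degenerate["WeightSum1"][gi] = False
                    if "WeightSum2" in self.tests:
                        designs["WeightSum2"] = ws.values[:, None]
            for t in want_f:
                Xg = designs.get(t)
                if Xg is None:
                    continue
                Q = _orthonormal_basis(Xg)
                if Q.shape[1] == 0 or n - 1 - Q.shape[1] < 1:
                    continue
                blocks[t].append(Q)
                active[t].append(gi)
                dfn[t].append(Q.shape[1])
                self.degenerate[t][gi] = False

        self._stacked: dict[str, _StackedDesigns] = {}
        for t in want_f:
            if blocks[t]:
                ranks = np.asarray(dfn[t], dtype=np.intp)
                starts = np.concatenate([[0], np.cumsum(ranks)[:-1]])
                self._stacked[t] = _StackedDesigns(
                    np.concatenate(blocks[t], axis=1),
                    starts,
                    np.asarray(active[t], dtype=np.intp),
                    ranks,
                )
            else:
                self._stacked[t] = _StackedDesigns(
                    np.empty((n, 0)), np.empty(0, np.intp), np.empty(0, np.intp), np.empty(0, np.intp)
                )
        self._ws_cols = ws_cols if "WeightSum1" in self.tests else None

    def pvalue_matrices(self, Y: np.ndarray) -> dict[str, dict[str, np.ndarray]]:
        """Analytic/rank p-values and statistics for phenotype columns Y.

        Y has shape (n, K); column 0 is conventionally the observed trait and
        the rest permutations of it, but any columns work. Returns, per test,
        ``p`` and ``stat`` arrays of shape (G, K). Degenerate genes carry
        p = 1 and stat 0. WeightSum1 p-values are pooled-rank p-values
        (each column's statistic ranked against all K columns), identical in
        construction for observed and permuted columns.
        """
        Y = np.asarray(Y, dtype=float)
        n, K = Y.shape
        G = len(self.genes)
        Yc = Y - Y.mean(axis=0)
        tss = (Yc**2).sum(axis=0)
        out: dict[str, dict[str, np.ndarray]] = {}
        for t in self.tests:
            if t in F_TESTS:
                p = np.ones((G, K))
                stat = np.zeros((G, K))
                sd = self._stacked[t]
                if sd.active.size:
                    C2 = (sd.Q.T @ Yc) ** 2  # (total_rank, K)
                    ess = np.add.reduceat(C2, sd.starts, axis=0)
                    rss = np.maximum(tss[None, :] - ess, 0.0)
                    dfn = sd.dfn[:, None].astype(float)
                    dfd = (n - 1 - sd.dfn)[:, None].astype(float)
                    with np.errstate(divide="ignore", invalid="ignore"):
                        F = (ess / dfn) / (rss / dfd)
                    F = np.where(rss > 0, F, np.inf)
                    pa = np.clip(stats.f.sf(F, dfn, dfd), _P_FLOOR, 1.0)
                    # a constant phenotype column is degenerate: p = 1
                    null_col = tss <= 0
                    pa[:, null_col] = 1.0
                    F[:, null_col] = 0.0
                    p[sd.active] = pa
                    stat[sd.active] = np.where(np.isfinite(F), F, np.inf)
                out[t] = {"p": p, "stat": stat}
            else:  # WeightSum1
                T = np.abs(self._ws_cols.T @ Yc)  # (G, K)
                # pooled rank of each column's statistic among all K columns
                ge = stats.rankdata(-T, method="max", axis=1)
                p = ge / K
                dg = self.degenerate[t]
                p[dg] = 1.0
                T[dg] = 0.0
                out[t] = {"p": p, "stat": T}
        return out

    def run(self, y: Phenotype | np.ndarray, plan: PermutationPlan) -> "Step1Result":
        """Observed + permuted statistics for every gene and selected test."""
        yv = y.aligned_to(self.genotypes).values if isinstance(y, Phenotype) else np.asarray(y, float)
        if plan.n_samples != len(yv):
            raise ValueError("plan sample count does not match phenotype length")
        Y = plan.phenotype_columns(yv)
        mats = self.pvalue_matrices(Y)
        B = plan.n_permutations
        panels: dict[str, GeneScorePanel] = {}
        rows = []
        for t in self.tests:
            p = mats[t]["p"]
            stat = mats[t]["stat"]
            obs_p, perm_p = p[:, 0], p[:, 1:].T  # (G,), (B, G)
            if t in F_TESTS:
                # permutation p of the observed statistic: rank among permutations
                r = np.sum(perm_p <= obs_p[None, :], axis=0)
                pp = (1.0 + r) / (B + 1.0)
            else:
                pp = obs_p  # already a pooled-rank permutation p
            pp = np.where(self.degenerate[t], 1.0, pp)
            panels[t] = GeneScorePanel.from_pvalues(
                self.genes, obs_p, perm_p, test=t, seed=plan.seed,
                flags=self.degenerate[t].copy(),
            )
            for gi, gene in enumerate(self.genes):
                rows.append(
                    {
                        "gene": gene,
                        "test": t,
                        "statistic": stat[gi, 0],
                        "p_analytic": obs_p[gi] if t in F_TESTS else np.nan,
                        "p_permutation": pp[gi],
                        "degenerate": bool(self.degenerate[t][gi]),
                    }
                )
        results = pd.DataFrame(rows)
        return Step1Result(panels=panels, results=results, plan=plan)


@dataclass
class Step1Result:
    """Per-gene observed/permuted scores (one panel per test) and a tidy
    result table with analytic and permutation p-values."""

    panels: dict[str, GeneScorePanel]
    results: pd.DataFrame
    plan: PermutationPlan

    def permutation_pvalues(self, test: str) -> pd.Series:
        sub = self.results[self.results["test"] == test]
        return sub.set_index("gene")["p_permutation"]

    def write(self, path) -> None:
        self.results.to_csv(path, sep="\t", index=False)


def run_step1(
    g: GenotypeMatrix,
    gene_map: GeneMap,
    y: Phenotype | np.ndarray,
    tests: Sequence[str] = TESTS,
    plan: PermutationPlan | None = None,
    maf_threshold: float = 0.01,
    n_permutations: int = 2000,
    seed: int = 0,
) -> Step1Result:
    """Run the selected gene-level tests for every gene, with one shared
    permutation plan applied identically to all genes.

    Convenience wrapper over :class:`Step1Engine`; build the engine directly
    when sweeping many phenotype replicates over fixed genotypes.
    """
    if plan is None:
        plan = PermutationPlan.random(g.n_samples, n_permutations, seed)
    return Step1Engine(g, gene_map, tests, maf_threshold).run(y, plan)
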