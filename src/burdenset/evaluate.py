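"""Experiment harness: gene-set designs, FPR/power estimation, full runs.

The harness reproduces the canonical evaluation design for the two-step
pipeline: a base risk gene set; perturbed variants of it with random noise
genes added (5/10/15/20 by default) or risk genes removed (5/10); a
reference null set of genes causal only for an independent second trait;
and a batch of random null sets (200 of size 3–64 by default) for the
set-level false-positive rate. Rates are averaged over phenotype
replicates, before and after excluding spurious genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .collapse_tests import PermutationPlan, Step1Engine
from .data_model import GeneSet, GeneSetCollection
from .enrichment import GeneScorePanel, _RankedPanel, vsea_adjust
from .simulate import SimulatedStudy, SimulationConfig, simulate_study
from .spurious_filter import ReplicatePValueMatrix, identify_spurious

__all__ = [
    "GeneSetDesign",
    "EvaluationReport",
    "perturb_gene_set",
    "make_random_sets",
    "estimate_rates",
    "run_experiment",
]


def perturb_gene_set(
    base: GeneSet,
    add_n: int,
    remove_n: int,
    universe: Sequence[str],
    seed: int | np.random.Generator = 0,
) -> GeneSet:
    """Remove ``remove_n`` uniformly chosen members, then add ``add_n``
    uniformly chosen non-members from the universe."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if add_n < 0 or not 0 <= remove_n < len(base):
        raise ValueError("need add_n >= 0 and 0 <= remove_n < |base|")
    pool = [g for g in universe if g not in set(base.genes)]
    if add_n > len(pool):
        raise ValueError(f"universe has only {len(pool)} non-base genes, need {add_n}")
    genes = list(base.genes)
    if remove_n:
        keep = rng.choice(len(genes), size=len(genes) - remove_n, replace=False)
        genes = [genes[i] for i in sorted(keep)]
    if add_n:
        genes += [pool[i] for i in rng.choice(len(pool), size=add_n, replace=False)]
    name = base.name
    if add_n:
        name += f"+{add_n}"
    if remove_n:
        name += f"-{remove_n}"
    return GeneSet(name, tuple(genes), f"perturbed from {base.name}")


def make_random_sets(
    universe: Sequence[str],
    exclude: Sequence[str],
    n_sets: int,
    size_range: tuple[int, int] = (3, 64),
    seed: int | np.random.Generator = 0,
) -> GeneSetCollection:
    """Random null sets of sizes uniform on [lo, hi], drawn without
    replacement from the universe minus the excluded (risk) genes."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = size_range
    pool = [g for g in universe if g not in set(exclude)]
    if not 1 <= lo <= hi <= len(pool):
        raise ValueError(f"sizes [{lo}, {hi}] infeasible for a pool of {len(pool)} genes")
    out = GeneSetCollection()
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(pool), size=size, replace=False)
        out.add(GeneSet(f"null{i + 1:03d}", tuple(pool[j] for j in sorted(members)), "random null"))
    return out


def estimate_rates(
    pvalues: np.ndarray | pd.DataFrame, alpha: float = 0.05, strict: bool = True
) -> dict:
    """Empirical rejection rate from a replicate x unit p-value table.

    Rate = mean over replicates of the fraction of unit p-values below alpha
    (strictly, by default). The Monte-Carlo SE treats the replicate as the
    sampling unit: sqrt(rate (1 - rate) / R).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim == 1:
        p = p[:, None]
    if p.shape[0] < 1:
        raise ValueError("need at least one replicate")
    hit = p < alpha if strict else p <= alpha
    per_rep = hit.mean(axis=1)
    rate = float(per_rep.mean())
    R = p.shape[0]
    return {"rate": rate, "se": float(np.sqrt(rate * (1 - rate) / R)), "n_replicates": R}


@dataclass
class GeneSetDesign:
    """The family of gene sets evaluated against one study."""

    base_set: GeneSet
    add_levels: tuple[int, ...] = (5, 10, 15, 20)
    remove_levels: tuple[int, ...] = (5, 10)
    reference_set: GeneSet | None = None
    n_random_sets: int = 200
    random_size_range: tuple[int, int] = (3, 64)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r >= len(self.base_set) for r in self.remove_levels):
            raise ValueError("remove levels must be smaller than the base set")


@dataclass
class EvaluationReport:
    """Tidy rate table plus the power-by-perturbation summary."""

    table: pd.DataFrame  # test, method, condition, spurious_excluded, kind, rate, se, R
    spurious_genes: dict[str, list[str]]
    alpha: float

    def power_by_perturbation(self) -> pd.DataFrame:
        sub = self.table[self.table["kind"] == "power"]
        return sub.pivot_table(
            index="condition",
            columns=["test", "method", "spurious_excluded"],
            values="rate",
            sort=False,
        )

    def write(self, prefix) -> None:
        self.table.to_csv(f"{prefix}_rates.tsv", sep="\t", index=False)
        self.power_by_perturbation().to_csv(f"{prefix}_power_by_perturbation.tsv", sep="\t")


def _condition_sets(
    design: GeneSetDesign, universe: Sequence[str], rng: np.random.Generator
) -> list[tuple[str, GeneSet, str]]:
    """(condition label, set, kind) triples for one replicate.

    Noise genes are drawn nested: one pool of max(add_levels) genes per
    replicate, each level using a prefix of it, so power comparisons across
    noise levels are paired within a replicate.
    """
    out: list[tuple[str, GeneSet, str]] = [("base", design.base_set, "power")]
    if design.add_levels:
        top = max(design.add_levels)
        pool = [g for g in universe if g not in set(design.base_set.genes)]
        picked = [pool[i] for i in rng.choice(len(pool), size=top, replace=False)]
        for a in design.add_levels:
            out.append(
                (
                    f"add{a}",
                    GeneSet(f"{design.base_set.name}+{a}", tuple(design.base_set.genes) + tuple(picked[:a])),
                    "power",
                )
            )
    for r in design.remove_levels:
        out.append((f"remove{r}", perturb_gene_set(design.base_set, 0, r, universe, rng), "power"))
    if design.reference_set is not None:
        out.append(("reference", design.reference_set, "fpr"))
    return out


def run_experiment(
    cfg: SimulationConfig,
    design: GeneSetDesign,
    tests: Sequence[str] = ("CMC-1", "CMC-count"),
    n_permutations: int = 500,
    alpha: float = 0.05,
    exponent: float = 1.0,
    maf_threshold: float = 0.01,
    spurious_alpha: float = 0.05,
    spurious_min_hits: int | None = None,
    study: SimulatedStudy | None = None,
) -> EvaluationReport:
    """Simulate a study and cross-tabulate FPR and power of GSEA and VSEA
    over the designed gene sets, with and without spurious-gene exclusion.

    Per replicate: step-1 panels for every test (one shared permutation plan
    per replicate), set-level p-values for every condition. Spurious genes
    are identified from the per-gene permutation p-values across replicates
    and the whole set-level analysis repeated on the filtered panels.
    """
    if study is None:
        study = simulate_study(cfg)
    geno, gmap = study.genotypes, study.gene_map
    universe = gmap.genes
    risk = set(study.causal_genes) | (
        set(design.reference_set.genes) if design.reference_set else set()
    )
    engine = Step1Engine(geno, gmap, tests, maf_threshold)
    master = np.random.default_rng(cfg.seed + 1)
    R = len(study.phenotypes)

    random_sets = make_random_sets(
        universe, sorted(risk), design.n_random_sets, design.random_size_range,
        np.random.default_rng(design.seed),
    )
    gene_pp: dict[str, np.ndarray] = {t: np.empty((R, len(universe))) for t in tests}
    panels_by_rep: list[dict[str, GeneScorePanel]] = []
    cond_rng = np.random.default_rng(design.seed + 1)
    conditions_by_rep = []
    for rep, y in enumerate(study.phenotypes):
        plan = PermutationPlan.random(
            geno.n_samples, n_permutations, int(master.integers(2**31 - 1))
        )
        step1 = engine.run(y, plan)
        for t in tests:
            gene_pp[t][rep] = step1.permutation_pvalues(t).loc[universe].to_numpy()
        panels_by_rep.append(step1.panels)
        conditions_by_rep.append(_condition_sets(design, universe, cond_rng))

    spurious = {
        t: identify_spurious(
            ReplicatePValueMatrix(gene_pp[t], universe, sorted(risk)),
            spurious_alpha,
            spurious_min_hits,
        )
        for t in tests
    }

    rows = []
    for t in tests:
        for excluded in (False, True):
            cond_p: dict[str, dict[str, list[float]]] = {}
            rand_p = {m: np.empty((R, len(random_sets))) for m in ("GSEA", "VSEA")}
            for rep in range(R):
                panel = panels_by_rep[rep][t]
                if excluded:
                    panel = panel.exclude(spurious[t])
                ranked = {"GSEA": _RankedPanel(panel), "VSEA": _RankedPanel(vsea_adjust(panel))}
                present = set(panel.gene_ids)
                for m, rp in ranked.items():
                    for label, gs, kind in conditions_by_rep[rep]:
                        members = [g for g in gs.genes if g in present]
                        # a set emptied by the spurious filter cannot reject
                        p = rp.test(members, exponent, m, gs.name).p if members else 1.0
                        cond_p.setdefault(label, {}).setdefault(m, []).append(p)
                    for si, gs in enumerate(random_sets.values()):
                        members = [g for g in gs.genes if g in present]
                        rand_p[m][rep, si] = (
                            rp.test(members, exponent, m, gs.name).p if members else 1.0
                        )
            for m in ("GSEA", "VSEA"):
                for label, _, kind in conditions_by_rep[0]:
                    est = estimate_rates(np.asarray(cond_p[label][m])[:, None], alpha)
                    rows.append(
                        dict(
                            test=t, method=m, condition=label, spurious_excluded=excluded,
                            kind=kind, **est,
                        )
                    )
                est = estimate_rates(rand_p[m], alpha)
                rows.append(
                    dict(
                        test=t, method=m, condition="random", spurious_excluded=excluded,
                        kind="fpr", **est,
                    )
                )
    return EvaluationReport(pd.DataFrame(rows), spurious, alpha)
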