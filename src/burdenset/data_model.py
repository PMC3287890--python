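"""Core data containers and text-format I/O.

The central object is a :class:`GenotypeMatrix` of minor-allele dosages
(individuals x variants, values 0/1/2 with missing allowed), accompanied by a
:class:`GeneMap` assigning variant columns to genes, a quantitative
:class:`Phenotype`, and named gene lists in a :class:`GeneSetCollection`.

Dosages are always coded on the *minor* allele, i.e. the allele whose sample
frequency is <= 0.5 (ties broken toward the alternate allele when reading
VCF). Collapsing burden tests are defined on minor-allele counts, so readers
re-orient columns from the sample itself rather than trusting REF/ALT.

Supported text formats:

* VCF v4.x (diploid GT field, biallelic sites) via cyvcf2.
* A TSV genotype dialect: header row of variant ids, first column the sample
  id, cells in {0, 1, 2, NA}.
* Gene map TSV (columns ``gene``, ``variant_id``), phenotype TSV
  (``sample_id``, ``value``), and standard GMT gene-set files.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GeneLookupError",
    "GenotypeMatrix",
    "GeneMap",
    "Phenotype",
    "GeneSet",
    "GeneSetCollection",
    "Partition",
    "compute_maf",
    "partition_variants",
    "read_genotypes",
    "write_genotypes",
    "read_gene_map",
    "read_phenotype",
    "write_phenotype",
    "read_gene_sets",
    "write_gene_sets",
]


class FormatError(ValueError):
    """An input file does not conform to its declared format."""


class GeneLookupError(KeyError):
    """A requested gene is absent from the gene map."""


def _allele_frequency(dosages: np.ndarray) -> np.ndarray:
    """Frequency of the coded allele per column, over non-missing calls."""
    n_called = np.sum(~np.isnan(dosages), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.nansum(dosages, axis=0) / (2.0 * n_called)
    return np.where(n_called > 0, freq, np.nan)


def compute_maf(g: "GenotypeMatrix | np.ndarray") -> np.ndarray:
    """Per-variant minor allele frequency, min(f, 1-f) over non-missing calls.

    Variants with no non-missing genotypes get MAF NaN with a warning.
    """
    dosages = g.dosages if isinstance(g, GenotypeMatrix) else np.asarray(g, dtype=float)
    freq = _allele_frequency(dosages)
    if np.isnan(freq).any():
        warnings.warn(
            f"{int(np.isnan(freq).sum())} variant(s) have no non-missing "
            "genotypes; MAF undefined (NaN)",
            stacklevel=2,
        )
    return np.minimum(freq, 1.0 - freq)


@dataclass
class GenotypeMatrix:
    """Individuals x variants minor-allele dosage matrix with metadata.

    Parameters
    ----------
    dosages
        Float array of shape (n_samples, n_variants); entries 0, 1, 2 or NaN
        for missing.
    sample_ids, variant_ids
        Ordered identifiers matching the rows / columns.
    variant_maf
        Per-variant minor allele frequency. Recomputed from ``dosages`` when
        not supplied.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    variant_ids: list[str]
    variant_maf: np.ndarray | None = None
    _imputed: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        self.sample_ids = list(self.sample_ids)
        self.variant_ids = list(self.variant_ids)
        n, m = self.dosages.shape
        if n != len(self.sample_ids):
            raise ValueError(f"{n} dosage rows but {len(self.sample_ids)} sample ids")
        if m != len(self.variant_ids):
            raise ValueError(f"{m} dosage columns but {len(self.variant_ids)} variant ids")
        finite = self.dosages[~np.isnan(self.dosages)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must be 0, 1 or 2")
        if self.variant_maf is None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self.variant_maf = compute_maf(self.dosages)
        else:
            self.variant_maf = np.asarray(self.variant_maf, dtype=float)
            if self.variant_maf.shape != (m,):
                raise ValueError("variant_maf length must equal the variant count")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def imputed(self) -> np.ndarray:
        """Dosages with missing entries mean-imputed per variant (cached).

        Keeps regression design matrices full rank without dropping
        individuals; all-missing columns impute to 0.
        """
        if self._imputed is None:
            x = self.dosages.copy()
            missing = np.isnan(x)
            if missing.any():
                warnings.warn(
                    f"mean-imputing {int(missing.sum())} missing dosage(s)",
                    stacklevel=2,
                )
                col_mean = np.where(
                    np.all(missing, axis=0), 0.0, np.nanmean(np.where(missing, np.nan, x), axis=0)
                )
                x[missing] = np.broadcast_to(col_mean, x.shape)[missing]
            self._imputed = x
        return self._imputed


class GeneMap(Mapping):
    """Mapping from gene identifier to ordered variant column indices."""

    def __init__(self, mapping: Mapping[str, Sequence[int]], n_variants: int | None = None):
        self._map: dict[str, np.ndarray] = {}
        for gene, idx in mapping.items():
            arr = np.asarray(idx, dtype=np.intp)
            if arr.ndim != 1:
                raise ValueError(f"gene {gene!r}: indices must be one-dimensional")
            if len(np.unique(arr)) != len(arr):
                raise ValueError(f"gene {gene!r}: duplicate variant indices")
            if n_variants is not None and arr.size and (arr.min() < 0 or arr.max() >= n_variants):
                raise ValueError(f"gene {gene!r}: index out of range for {n_variants} variants")
            self._map[str(gene)] = arr

    def __getitem__(self, gene: str) -> np.ndarray:
        try:
            return self._map[gene]
        except KeyError:
            raise GeneLookupError(gene) from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._map)

    def __len__(self) -> int:
        return len(self._map)

    @property
    def genes(self) -> list[str]:
        return list(self._map)

    def without_genes(self, genes: Sequence[str]) -> "GeneMap":
        drop = set(genes)
        return GeneMap({g: v for g, v in self._map.items() if g not in drop})

    @classmethod
    def from_table(cls, path, variant_ids: Sequence[str]) -> "GeneMap":
        """Read a two-column TSV (gene, variant_id) against known variant ids."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"gene", "variant_id"}.issubset(df.columns):
            raise FormatError("gene map must have columns 'gene' and 'variant_id'")
        col_of = {v: i for i, v in enumerate(variant_ids)}
        unknown = sorted(set(df["variant_id"]) - col_of.keys())
        if unknown:
            raise FormatError(f"gene map names unknown variants: {unknown[:5]}")
        mapping: dict[str, list[int]] = {}
        for gene, vid in zip(df["gene"], df["variant_id"]):
            mapping.setdefault(gene, []).append(col_of[vid])
        return cls(mapping, n_variants=len(variant_ids))

    def write(self, path, variant_ids: Sequence[str]) -> None:
        rows = [(g, variant_ids[i]) for g in self.genes for i in self[g]]
        pd.DataFrame(rows, columns=["gene", "variant_id"]).to_csv(path, sep="\t", index=False)


def read_gene_map(path, variant_ids: Sequence[str]) -> GeneMap:
    return GeneMap.from_table(path, variant_ids)


@dataclass
class Phenotype:
    """A quantitative trait: ordered sample ids and real values."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.sample_ids):
            raise ValueError("values must be 1-D and match sample_ids in length")

    def aligned_to(self, g: GenotypeMatrix) -> "Phenotype":
        """Reorder to the genotype matrix's sample order; error on mismatch."""
        if self.sample_ids == g.sample_ids:
            return self
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in g.sample_ids if s not in pos]
        if missing or len(self.sample_ids) != len(g.sample_ids):
            raise ValueError(f"phenotype/genotype sample mismatch (missing: {missing[:5]})")
        order = [pos[s] for s in g.sample_ids]
        return Phenotype(list(g.sample_ids), self.values[order])


class Partition(NamedTuple):
    rare: np.ndarray
    common: np.ndarray
    monomorphic: np.ndarray


def partition_variants(
    g: GenotypeMatrix, gene_map: GeneMap, gene: str, maf_threshold: float = 0.01
) -> Partition:
    """Split a gene's variants into rare (MAF <= threshold, inclusive) and
    common, excluding monomorphic variants (MAF == 0) from both.

    Returns column indices into the genotype matrix. Monomorphic variants
    carry no information for association and are reported separately.
    """
    if not 0.0 < maf_threshold <= 0.5:
        raise ValueError("maf_threshold must be in (0, 0.5]")
    idx = gene_map[gene]
    maf = g.variant_maf[idx]
    mono = (maf == 0) | np.isnan(maf)
    rare = (~mono) & (maf <= maf_threshold)
    common = (~mono) & (maf > maf_threshold)
    return Partition(idx[rare], idx[common], idx[mono])


# ---------------------------------------------------------------------------
# genotype I/O


def read_genotypes(path, format: str = "table") -> GenotypeMatrix:
    """Read genotypes from a VCF or the TSV dosage dialect.

    Dosages are re-coded onto the minor allele (sample frequency <= 0.5,
    ties toward ALT / toward the coded allele for tables).
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "table":
        return _read_table(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad files
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    columns: list[np.ndarray] = []
    ids: list[str] = []
    for v in vcf:
        if len(v.ALT) != 1:
            raise FormatError(
                f"{path}: site {v.CHROM}:{v.POS} is not biallelic (ALT={v.ALT})"
            )
        col = np.full(len(samples), np.nan)
        for i, gt in enumerate(v.genotypes):
            alleles = gt[:-1]
            if len(alleles) != 2:
                raise FormatError(
                    f"{path}: non-diploid GT for sample {samples[i]} at {v.CHROM}:{v.POS}"
                )
            if -1 in alleles:
                continue
            col[i] = float(sum(alleles))
        columns.append(col)
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
    dosages = np.column_stack(columns) if columns else np.empty((len(samples), 0))
    # orient onto the minor allele; ties at 0.5 stay on ALT
    freq = _allele_frequency(dosages)
    flip = freq > 0.5
    dosages[:, flip] = 2.0 - dosages[:, flip]
    return GenotypeMatrix(dosages, samples, ids)


def _read_table(path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    except Exception as exc:
        raise FormatError(f"cannot parse genotype table {path}: {exc}") from exc
    values = df.to_numpy(dtype=float)
    bad_rows = np.where(
        ~np.all(np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0)), axis=1)
    )[0]
    if bad_rows.size:
        # +2: one for the header line, one for 1-based numbering
        raise FormatError(f"{path}: invalid dosage on line {bad_rows[0] + 2}")
    freq = _allele_frequency(values)
    flip = freq > 0.5
    values[:, flip] = 2.0 - values[:, flip]
    return GenotypeMatrix(values, [str(s) for s in df.index], [str(c) for c in df.columns])


def write_genotypes(g: GenotypeMatrix, path) -> None:
    """Write the TSV dosage dialect (exact round trip for integer dosages)."""
    df = pd.DataFrame(g.dosages, index=g.sample_ids, columns=g.variant_ids)
    df.index.name = "sample_id"
    with np.errstate(invalid="ignore"):
        out = df.astype("Int64")
    out.to_csv(path, sep="\t", na_rep="NA")


def read_phenotype(path) -> Phenotype:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError("phenotype table needs columns sample_id, value")
    return Phenotype(df.iloc[:, 0].tolist(), df.iloc[:, 1].to_numpy(dtype=float))


def write_phenotype(y: Phenotype, path) -> None:
    pd.DataFrame({"sample_id": y.sample_ids, "value": y.values}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# gene sets


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) < 1:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.genes)


class GeneSetCollection(Mapping):
    """Named gene sets, preserving file order."""

    def __init__(self, sets: Sequence[GeneSet] = ()):
        self._sets = {s.name: s for s in sets}

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def add(self, s: GeneSet) -> None:
        self._sets[s.name] = s


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, tab-separated name, description,
    members. Duplicate members within a line are dropped with a warning."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: GMT needs >= 3 fields")
            name, desc, *members = fields
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                warnings.warn(
                    f"{path}: line {lineno}: dropped {len(members) - len(unique)} "
                    f"duplicate member(s) in set {name!r}",
                    stacklevel=2,
                )
            sets.append(GeneSet(name, tuple(unique), desc))
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection.values():
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")
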