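"""Genotype data model for single-gene rare-variant analysis.

Genotypes are additively coded minor-allele counts (0/1/2, ``NaN`` for
missing) for one gene or region across ``n`` individuals.  The module
provides minor-allele-frequency computation with automatic re-orientation
to the minor allele, Hardy-Weinberg imputation of missing calls,
monomorphic filtering, construction of the variable-threshold pooled
predictor set, and readers/writers for VCF and plain delimited matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "AugmentedDesign",
    "compute_maf",
    "impute_missing",
    "filter_monomorphic",
    "build_pooled_variables",
    "load_genotypes",
    "load_phenotype",
    "write_genotype_matrix",
    "align_phenotype",
]

#: Default upper rarity bound for pooled predictors (5%).
DEFAULT_POOL_TMAX = 0.05


@dataclass
class GenotypeMatrix:
    """Additively coded genotypes for one region.

    Attributes
    ----------
    values : (n, p) float ndarray
        Minor-allele counts in {0, 1, 2}; missing entries are NaN.
        Columns are oriented so that the counted allele is the minor one.
    variant_ids : list of str
        One label per variant column.
    maf : (p,) float ndarray
        Sample minor allele frequency per variant, in [0, 0.5], computed
        from non-missing entries.
    sample_ids : list of str or None
        Optional individual identifiers (used to align with phenotypes).
    """

    values: np.ndarray
    variant_ids: list[str]
    maf: np.ndarray
    sample_ids: list[str] | None = None

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_values(
        cls,
        values: np.ndarray,
        variant_ids: list[str] | None = None,
        sample_ids: list[str] | None = None,
    ) -> "GenotypeMatrix":
        """Build a matrix, orienting each column to its minor allele."""
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("genotype values must be a 2-D array")
        n, p = values.shape
        if n < 2 or p < 1:
            raise ValueError(f"need n >= 2 individuals and p >= 1 variants, got {n}x{p}")
        ok = np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.unique(values[~ok])
            raise ValueError(f"genotype entries must be 0/1/2 or missing; found {bad}")
        if variant_ids is None:
            variant_ids = [f"v{j + 1}" for j in range(p)]
        if len(variant_ids) != p:
            raise ValueError("variant_ids length does not match number of columns")
        oriented, maf = compute_maf(values, variant_ids)
        return cls(oriented, list(variant_ids), maf, sample_ids)


def compute_maf(
    values: np.ndarray, variant_ids: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant allele frequency with minor-allele re-orientation.

    The frequency of the counted allele is the sum of non-missing allele
    counts over twice the number of non-missing genotypes.  Columns whose
    frequency exceeds 0.5 are recoded ``g -> 2 - g`` and the frequency is
    replaced by its complement, so every returned MAF lies in [0, 0.5].

    Returns the (possibly recoded) value matrix and the MAF vector.
    Raises if any variant has no non-missing genotype.
    """
    values = np.asarray(values, dtype=float)
    observed = ~np.isnan(values)
    n_obs = observed.sum(axis=0)
    if np.any(n_obs == 0):
        j = int(np.argmax(n_obs == 0))
        name = variant_ids[j] if variant_ids is not None else f"column {j}"
        raise ValueError(f"variant {name!r} has no non-missing genotypes")
    freq = np.nansum(values, axis=0) / (2.0 * n_obs)
    flip = freq > 0.5
    out = values.copy()
    if flip.any():
        out[:, flip] = 2.0 - out[:, flip]
        # recompute on the flipped columns so a second pass is a no-op bit-for-bit
        freq = np.nansum(out, axis=0) / (2.0 * n_obs)
    return out, freq


def impute_missing(G: GenotypeMatrix, rng: np.random.Generator) -> GenotypeMatrix:
    """Fill missing genotypes from Hardy-Weinberg proportions.

    Each missing entry at a variant with MAF ``q`` is drawn independently
    from {0, 1, 2} with probabilities {(1-q)^2, 2q(1-q), q^2}; observed
    entries are untouched.  MAFs are recomputed on the completed matrix.
    """
    values = G.values.copy()
    for j in range(G.n_variants):
        miss = np.isnan(values[:, j])
        if not miss.any():
            continue
        q = G.maf[j]
        probs = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
        values[miss, j] = rng.choice(3, size=int(miss.sum()), p=probs)
    return GenotypeMatrix.from_values(values, G.variant_ids, G.sample_ids)


def filter_monomorphic(G: GenotypeMatrix) -> GenotypeMatrix:
    """Drop variants with MAF exactly zero, preserving column order."""
    keep = G.maf > 0.0
    if not keep.any():
        raise ValueError("all variants are monomorphic: no testable region")
    if keep.all():
        return G
    ids = [v for v, k in zip(G.variant_ids, keep) if k]
    return GenotypeMatrix(G.values[:, keep], ids, G.maf[keep], G.sample_ids)


@dataclass
class AugmentedDesign:
    """Genotype design augmented with variable-threshold pooled counts.

    ``matrix`` holds the p original genotype columns followed by m pooled
    columns; pooled column for threshold t is the per-individual sum of
    minor-allele counts over all variants with MAF <= t.  Duplicate pooled
    columns and pooled columns identical to a single original column are
    removed.
    """

    matrix: np.ndarray
    pooled_thresholds: np.ndarray
    pooled_members: list[np.ndarray]
    origin: list[str] = field(default_factory=list)  # 'original' | 'pooled'

    @property
    def n_original(self) -> int:
        return sum(o == "original" for o in self.origin)

    @property
    def n_pooled(self) -> int:
        return len(self.pooled_members)

    def column_labels(self, variant_ids: list[str]) -> list[str]:
        labels = list(variant_ids)
        labels += [f"pool(maf<={t:g})" for t in self.pooled_thresholds]
        return labels


def build_pooled_variables(
    G: GenotypeMatrix, t_max: float = DEFAULT_POOL_TMAX
) -> AugmentedDesign:
    """Augment the design with pooled rare-allele counts.

    The threshold lattice is ``{t_max}`` plus every observed MAF strictly
    below ``t_max``; the pooled variable for threshold t counts minor
    alleles across all variants with MAF <= t.  Exactly duplicated pooled
    columns collapse to the largest threshold's column, and pooled columns
    equal to a single original column are dropped (they would be perfectly
    collinear with it).  Original columns are always retained.
    """
    if not (0.0 < t_max <= 0.5):
        raise ValueError(f"t_max must be in (0, 0.5], got {t_max}")
    if np.isnan(G.values).any():
        raise ValueError("impute missing genotypes before building pooled variables")
    maf = G.maf
    observed = np.unique(maf[(maf > 0) & (maf < t_max)])
    thresholds = np.concatenate(([t_max], observed[::-1]))  # descending

    kept_t: list[float] = []
    kept_members: list[np.ndarray] = []
    kept_cols: list[np.ndarray] = []
    for t in thresholds:
        members = np.flatnonzero(maf <= t)
        if members.size == 0:
            continue
        col = G.values[:, members].sum(axis=1)
        if any(np.array_equal(col, c) for c in kept_cols):
            continue  # duplicate of a larger-threshold column
        if any(np.array_equal(col, G.values[:, j]) for j in range(G.n_variants)):
            continue  # identical to an original predictor
        kept_t.append(float(t))
        kept_members.append(members)
        kept_cols.append(col)

    if kept_cols:
        matrix = np.column_stack([G.values] + kept_cols)
    else:
        matrix = G.values.copy()
    origin = ["original"] * G.n_variants + ["pooled"] * len(kept_cols)
    return AugmentedDesign(matrix, np.array(kept_t), kept_members, origin)


# ---------------------------------------------------------------------------
# File I/O


def load_genotypes(
    path: str, format: str = "matrix", on_multiallelic: str = "error"
) -> GenotypeMatrix:
    """Read genotypes from a delimited matrix or a VCF.

    Matrix format: delimited text, first column ``id`` (individual
    identifiers), remaining columns one per variant with entries 0/1/2 or
    NA.  VCF: biallelic records consumed via the GT field; ``./.`` is
    missing.  Multiallelic records raise unless ``on_multiallelic='split'``,
    in which case each alternate allele becomes its own variant column.
    """
    if format == "matrix":
        return _load_matrix(path)
    if format == "vcf":
        return _load_vcf(path, on_multiallelic)
    raise ValueError(f"unknown genotype format {format!r}")


def _load_matrix(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=None, engine="python", dtype={0: str})
    if df.shape[1] < 2 or df.columns[0] != "id":
        raise ValueError("matrix file must have an 'id' column followed by variant columns")
    ids = df["id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicated individual ids: {dupes}")
    values = df.drop(columns="id").to_numpy(dtype=float)
    return GenotypeMatrix.from_values(values, list(df.columns[1:]), ids)


def _load_vcf(path: str, on_multiallelic: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    ids: list[str] = []
    for var in vcf:
        alts = var.ALT
        if len(alts) == 0:
            continue
        if len(alts) > 1 and on_multiallelic != "split":
            raise ValueError(
                f"multiallelic record at {var.CHROM}:{var.POS}; "
                "pass on_multiallelic='split' to expand it"
            )
        gts = var.genotypes  # [[a1, a2, phased], ...]
        for k in range(1, len(alts) + 1):
            counts = np.full(len(samples), np.nan)
            for i, g in enumerate(gts):
                alleles = [a for a in g[:-1] if a is not None and a >= 0]
                if len(alleles) < 2:
                    continue  # ./., treated as missing
                counts[i] = sum(a == k for a in alleles)
            name = var.ID or f"{var.CHROM}:{var.POS}"
            if len(alts) > 1:
                name = f"{name}_{alts[k - 1]}"
            cols.append(counts)
            ids.append(name)
    if not cols:
        raise ValueError(f"no usable variant records in {path}")
    return GenotypeMatrix.from_values(np.column_stack(cols), ids, samples)


def write_genotype_matrix(G: GenotypeMatrix, path: str) -> None:
    """Write a matrix-format genotype file (round-trips with the reader)."""
    ids = G.sample_ids or [f"s{i + 1}" for i in range(G.n_individuals)]
    df = pd.DataFrame(G.values, columns=G.variant_ids)
    df.insert(0, "id", ids)
    with np.errstate(invalid="ignore"):
        for c in G.variant_ids:
            df[c] = df[c].map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    df.to_csv(path, sep="\t", index=False)


def load_phenotype(path: str) -> pd.Series:
    """Read a phenotype table with columns ``id`` and ``value``."""
    df = pd.read_csv(path, sep=None, engine="python", dtype={"id": str})
    if not {"id", "value"}.issubset(df.columns):
        raise ValueError("phenotype file must have columns 'id' and 'value'")
    if df["id"].duplicated().any():
        dupes = sorted(df.loc[df["id"].duplicated(), "id"].unique())
        raise ValueError(f"duplicated phenotype ids: {dupes}")
    values = pd.to_numeric(df["value"], errors="coerce")
    if values.isna().any():
        bad = df.loc[values.isna(), "id"].tolist()
        raise ValueError(f"non-numeric phenotype values for ids: {bad}")
    return pd.Series(values.to_numpy(float), index=df["id"].astype(str), name="value")


def align_phenotype(G: GenotypeMatrix, pheno: pd.Series) -> np.ndarray:
    """Return phenotype values ordered to the genotype samples.

    Every genotyped individual must appear in the phenotype table;
    otherwise the missing ids are listed in the error.
    """
    if G.sample_ids is None:
        if len(pheno) != G.n_individuals:
            raise ValueError(
                f"phenotype length {len(pheno)} does not match {G.n_individuals} individuals"
            )
        return pheno.to_numpy(float)
    missing = [s for s in G.sample_ids if s not in pheno.index]
    if missing:
        raise ValueError(f"phenotype missing for ids: {missing}")
    extra = [s for s in pheno.index if s not in set(G.sample_ids)]
    if extra:
        warnings.warn(f"phenotype ids not in genotype data ignored: {extra}")
    return pheno.loc[G.sample_ids].to_numpy(float)
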