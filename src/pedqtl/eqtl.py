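"""Expression preprocessing and cis-eQTL scanning.

Counts are filtered on mean reads per animal, variance-stabilised with a
closed-form negative-binomial transform (arcsinh family, common
dispersion), screened for outlier samples by PCA, and then mapped with
the same GLS engine used for the organismal traits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import VarianceModel, gls_scan
from .core_io import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Gene x sample read-count matrix with an optional transformed view."""

    counts: pd.DataFrame  # genes x samples, non-negative integers
    transformed: pd.DataFrame | None = None
    size_factors: pd.Series | None = None
    dispersion: float | None = None

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("expression counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("expression counts must be integral")

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.counts.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.counts.columns]

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            counts=self.counts[sample_ids],
            transformed=None if self.transformed is None else self.transformed[sample_ids],
            size_factors=None if self.size_factors is None else self.size_factors[sample_ids],
            dispersion=self.dispersion,
        )


def read_counts(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(counts=df)


def write_counts(e: ExpressionMatrix, path) -> None:
    out = e.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def filter_expressed_genes(
    e: ExpressionMatrix, min_mean_reads: float = 8.0
) -> ExpressionMatrix:
    """Keep genes with mean count per animal strictly greater than the cut."""
    keep = e.counts.mean(axis=1) > min_mean_reads
    logger.info("expression filter: kept %d/%d genes", int(keep.sum()), len(keep))
    return ExpressionMatrix(
        counts=e.counts.loc[keep],
        transformed=None if e.transformed is None else e.transformed.loc[keep],
        size_factors=e.size_factors,
        dispersion=e.dispersion,
    )


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-sample size factors by the median-of-ratios method.

    The reference is the per-gene geometric mean across samples, computed
    only over genes with no zero count; each sample's factor is the median
    ratio of its counts to that reference.
    """
    vals = counts.to_numpy(dtype=float)
    nonzero = (vals > 0).all(axis=1)
    if not nonzero.any():
        logger.warning("no all-nonzero genes for size factors; using 1.0")
        return pd.Series(1.0, index=counts.columns)
    logref = np.log(vals[nonzero]).mean(axis=1)
    sf = np.exp(np.median(np.log(vals[nonzero]) - logref[:, None], axis=0))
    return pd.Series(sf, index=counts.columns)


def estimate_dispersion(counts: pd.DataFrame, size_factors: pd.Series) -> float:
    """Common NB dispersion by method of moments on normalised counts.

    Per gene, alpha_g = (var - mean) / mean^2; the pooled estimate is the
    median over genes with positive alpha_g.
    """
    norm = counts.to_numpy(dtype=float) / size_factors.to_numpy()[None, :]
    mu = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_g = (var - mu) / mu**2
    alpha_g = alpha_g[np.isfinite(alpha_g) & (alpha_g > 0)]
    if alpha_g.size == 0:
        raise ValueError("cannot estimate dispersion: no overdispersed genes")
    return float(np.median(alpha_g))


def vst_transform(
    e: ExpressionMatrix, dispersion: float | str = "estimate"
) -> ExpressionMatrix:
    """Variance-stabilising transform for NB counts with common dispersion.

    Each count is divided by its sample's median-of-ratios size factor,
    then mapped through y = (2 / sqrt(alpha)) * asinh(sqrt(alpha * x)),
    which has approximately constant variance when counts are
    NB(mean mu, variance mu + alpha mu^2). Strictly increasing in the
    count for a fixed size factor.
    """
    sf = median_of_ratios_size_factors(e.counts)
    if dispersion == "estimate":
        alpha = estimate_dispersion(e.counts, sf)
    else:
        alpha = float(dispersion)
    if not alpha > 0:
        raise ValueError(f"dispersion must be positive, got {alpha}")
    norm = e.counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    t = (2.0 / np.sqrt(alpha)) * np.arcsinh(np.sqrt(alpha * norm))
    transformed = pd.DataFrame(t, index=e.counts.index, columns=e.counts.columns)
    return ExpressionMatrix(
        counts=e.counts, transformed=transformed, size_factors=sf, dispersion=alpha
    )


@dataclass
class OutlierRecord:
    sample_id: str
    component: int  # 1-based
    score: float
    sd_units: float


def pca_outlier_filter(
    e: ExpressionMatrix, n_components: int = 6, sd_limit: float = 3.0
) -> tuple[ExpressionMatrix, list[OutlierRecord]]:
    """Drop samples whose PCA score exceeds ``sd_limit`` SDs on any of the
    first ``n_components`` components (single pass, no iteration).

    PCA runs on the transformed expression (samples as observations) if
    available, else on raw counts. Uses min(n_components, available).
    """
    mat = e.transformed if e.transformed is not None else e.counts.astype(float)
    X = mat.to_numpy(dtype=float).T  # samples x genes
    n_samples = X.shape[0]
    if n_samples < 3:
        raise ValueError("PCA outlier filtering needs at least 3 samples")
    Xc = X - X.mean(axis=0)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, len(S), n_samples - 1)
    scores = U[:, :k] * S[:k]
    sd = scores.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    outliers: list[OutlierRecord] = []
    drop = np.zeros(n_samples, dtype=bool)
    for j in range(k):
        over = np.abs(scores[:, j]) > sd_limit * sd[j]
        for i in np.flatnonzero(over):
            outliers.append(
                OutlierRecord(
                    sample_id=str(mat.columns[i]),
                    component=j + 1,
                    score=float(scores[i, j]),
                    sd_units=float(abs(scores[i, j]) / sd[j]),
                )
            )
        drop |= over
    keep = [str(s) for s, d in zip(mat.columns, drop) if not d]
    for rec in outliers:
        logger.info(
            "PCA outlier: sample %s, component %d, %.1f SD",
            rec.sample_id, rec.component, rec.sd_units,
        )
    return e.subset_samples(keep), outliers


@dataclass(frozen=True)
class GenomicWindow:
    chrom: str
    start: int  # half-open [start, end), 1-based positions
    end: int


@dataclass
class EqtlResult:
    gene_id: str
    window: GenomicWindow
    assoc: pd.DataFrame  # association-table columns
    animal_ids: list[str] = field(default_factory=list)


def cis_eqtl_scan(
    g: GenotypeMatrix,
    e: ExpressionMatrix,
    gene: str,
    window: GenomicWindow,
    vm: VarianceModel,
) -> EqtlResult:
    """Scan every variant in ``window`` against a gene's transformed
    expression with the GLS engine.

    Animals are intersected across genotypes, expression samples and the
    variance model; the model's phenotypic variance is replaced by the
    sample variance of the gene's transformed values. A gene with
    constant transformed values yields all-missing statistics.
    """
    if e.transformed is None:
        raise ValueError("expression matrix has no transformed view; run vst_transform")
    if gene not in e.transformed.index:
        raise KeyError(f"gene {gene!r} absent from expression matrix")
    samples = set(e.sample_ids)
    vm_ids = set(vm.animal_ids)
    animals = [a for a in g.animal_ids if a in samples and a in vm_ids]
    if not animals:
        raise ValueError("no animals shared by genotypes, expression and pedigree")
    gw = g.subset_animals(animals).window(window.chrom, window.start, window.end)
    y = e.transformed.loc[gene, animals].to_numpy(dtype=float)
    sub = vm.relationship.subset(animals)
    var_y = float(np.var(y, ddof=1)) if len(y) > 1 else 0.0
    if len(y) < 2 or np.all(y == y[0]):
        assoc = gw.variants[["variant_id", "chrom", "pos"]].copy()
        assoc[["beta", "se", "chi2", "p"]] = np.nan
        assoc["n_used"] = 0
        return EqtlResult(gene_id=gene, window=window, assoc=assoc, animal_ids=animals)
    vm_gene = VarianceModel(vm.h2, var_y, sub)
    assoc = gls_scan(gw, y, vm_gene)
    return EqtlResult(gene_id=gene, window=window, assoc=assoc, animal_ids=animals)
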