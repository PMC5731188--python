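"""Single-marker generalised least-squares association scan and its
significance machinery.

The model regresses a phenotype vector on an intercept plus one centred
dosage column at a time, with error covariance

    W = sigma2_P * (h2 * A + (1 - h2) * I),

where A is the pedigree numerator relationship matrix. beta_hat =
(X' W^-1 X)^-1 X' W^-1 y, s.e. = sqrt(diag (X' W^-1 X)^-1), and the
per-variant statistic (beta_hat / s.e.)^2 is chi-square with 1 df under
the null. W is factorised once per trait (symmetric eigendecomposition)
and every variant is fitted in the whitened coordinates; results are
identical to explicit inversion to 1e-10.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ASSOC_COLUMNS, GenotypeMatrix
from .relationship import RelationshipMatrix

logger = logging.getLogger(__name__)

#: median of the chi-square distribution with 1 df, to 5 decimal places —
#: the denominator of the genomic inflation factor
CHI2_1DF_MEDIAN = round(float(stats.chi2.ppf(0.5, df=1)), 5)


@dataclass
class VarianceModel:
    """Phenotypic covariance structure W = sigma2_P (h2 A + (1-h2) I).

    The eigendecomposition of (h2 A + (1-h2) I) is computed lazily and
    cached, so one VarianceModel can be reused across many scans of the
    same cohort (e.g. per-gene expression traits).
    """

    h2: float
    sigma2_P: float
    relationship: RelationshipMatrix
    _whitener: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError(f"h2 must be in [0, 1], got {self.h2}")
        if not self.sigma2_P > 0:
            raise ValueError(f"sigma2_P must be positive, got {self.sigma2_P}")

    @property
    def animal_ids(self) -> list[str]:
        return self.relationship.animal_ids

    def covariance(self) -> np.ndarray:
        A = self.relationship.A
        n = len(A)
        return self.sigma2_P * (self.h2 * A + (1.0 - self.h2) * np.eye(n))

    def whitener(self) -> np.ndarray:
        """Matrix T with T' T = (h2 A + (1-h2) I)^-1 (up to sigma2_P)."""
        if self._whitener is None:
            A = self.relationship.A
            n = len(A)
            K = self.h2 * A + (1.0 - self.h2) * np.eye(n)
            evals, evecs = np.linalg.eigh(K)
            if evals.min() <= 1e-10:
                raise np.linalg.LinAlgError(
                    "h2*A + (1-h2)*I is numerically singular; "
                    f"min eigenvalue {evals.min():g}"
                )
            self._whitener = (evecs / np.sqrt(evals)).T
        return self._whitener

    def replace_sigma2(self, sigma2_P: float) -> "VarianceModel":
        """Same covariance structure, new phenotypic variance; shares the
        cached factorization."""
        vm = VarianceModel(self.h2, sigma2_P, self.relationship)
        vm._whitener = self._whitener if self._whitener is not None else self.whitener()
        return vm


def gls_scan(g: GenotypeMatrix, y: np.ndarray, vm: VarianceModel) -> pd.DataFrame:
    """GLS single-marker scan of every variant in ``g`` against ``y``.

    ``y`` must be aligned with ``g.animal_ids`` (which must equal the
    variance model's animal order). Missing dosages are mean-imputed per
    variant inside the engine only. Monomorphic variants get NaN
    statistics. Returns a DataFrame with columns
    variant_id, chrom, pos, beta, se, chi2, p, n_used.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (g.n_animals,):
        raise ValueError(f"phenotype length {y.shape} != {g.n_animals} animals")
    if not np.isfinite(y).all():
        raise ValueError("phenotype vector contains non-finite values")
    if g.animal_ids != vm.animal_ids:
        raise ValueError("genotype and variance-model animal orders differ")

    D = g.dosages
    n, m = D.shape
    called = np.isfinite(D)
    n_used = called.sum(axis=0)
    D0 = np.where(called, D, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        col_mean = np.where(n_used > 0, D0.sum(axis=0) / n_used, 0.0)
        col_var = np.where(
            n_used > 0, (D0**2).sum(axis=0) / np.maximum(n_used, 1) - col_mean**2, 0.0
        )
    X = np.where(called, D, col_mean) - col_mean  # centred, imputed
    mono = (col_var <= 0) | (n_used == 0)

    T = vm.whitener()
    yt = T @ y
    ones_t = T @ np.ones(n)
    Xt = T @ X

    # closed-form 2x2 GLS for [intercept, snp] per variant
    a11 = float(ones_t @ ones_t)
    a12 = ones_t @ Xt  # (m,)
    a22 = np.einsum("ij,ij->j", Xt, Xt)
    b1 = float(ones_t @ yt)
    b2 = Xt.T @ yt
    det = a11 * a22 - a12**2
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (a11 * b2 - a12 * b1) / det
        # diag of (X' W^-1 X)^-1 for the snp coefficient, incl. sigma2_P
        se = np.sqrt(vm.sigma2_P * a11 / det)
        chi2 = (beta / se) ** 2
    bad = mono | ~np.isfinite(det) | (det <= 0)
    for arr in (beta, se, chi2):
        arr[bad] = np.nan
    if bad.any():
        logger.info("gls_scan: %d monomorphic/degenerate variants skipped", bad.sum())
    p = np.where(np.isfinite(chi2), stats.chi2.sf(chi2, df=1), np.nan)
    out = g.variants[["variant_id", "chrom", "pos"]].copy()
    out["beta"] = beta
    out["se"] = se
    out["chi2"] = chi2
    out["p"] = p
    out["n_used"] = n_used
    return out[ASSOC_COLUMNS]


def gls_scan_dense(g: GenotypeMatrix, y: np.ndarray, vm: VarianceModel) -> pd.DataFrame:
    """Reference implementation by explicit per-variant matrix inversion.

    O(n^3) per variant; for validation on small cohorts only.
    """
    y = np.asarray(y, dtype=float)
    W = vm.covariance()
    Winv = np.linalg.inv(W)
    rows = []
    D = g.dosages
    for j in range(g.n_variants):
        d = D[:, j]
        called = np.isfinite(d)
        x = np.where(called, d, np.nanmean(d)) - np.nanmean(d)
        if np.nanstd(d) == 0 or not called.any():
            rows.append((np.nan, np.nan, np.nan, np.nan, int(called.sum())))
            continue
        X = np.column_stack([np.ones_like(y), x])
        XtWiX_inv = np.linalg.inv(X.T @ Winv @ X)
        b = XtWiX_inv @ X.T @ Winv @ y
        se = np.sqrt(np.diag(XtWiX_inv))
        chi2 = (b[1] / se[1]) ** 2
        rows.append((b[1], se[1], chi2, stats.chi2.sf(chi2, df=1), int(called.sum())))
    out = g.variants[["variant_id", "chrom", "pos"]].copy()
    out[["beta", "se", "chi2", "p", "n_used"]] = pd.DataFrame(rows, index=out.index)
    return out[ASSOC_COLUMNS]


def maf(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-variant alt frequency, MAF, and whether the minor allele is REF.

    Frequencies are over called dosages only; an all-missing variant
    yields NaN. ``minor_is_ref`` is True when alt frequency > 0.5 (the
    reference allele is the minor one).
    """
    freq = g.alt_freq()
    with np.errstate(invalid="ignore"):
        m = np.minimum(freq, 1.0 - freq)
        minor_is_ref = freq > 0.5
    return pd.DataFrame(
        {
            "variant_id": g.variant_ids,
            "alt_freq": freq,
            "maf": m,
            "minor_is_ref": minor_is_ref,
        }
    )


def inflation_factor(chi2: np.ndarray) -> float:
    """Genomic inflation factor: median observed chi2 / median of chi2(1df).

    NaN entries (e.g. monomorphic variants) are dropped first.
    """
    chi2 = np.asarray(chi2, dtype=float)
    chi2 = chi2[np.isfinite(chi2)]
    if chi2.size == 0:
        raise ValueError("no finite association statistics supplied")
    return float(np.median(chi2)) / CHI2_1DF_MEDIAN


@dataclass(frozen=True)
class SignificanceReport:
    n_tests: int
    alpha: float
    bonferroni_p: float
    lam: float
    adjusted_p: float
    priority_p: float

    def to_dict(self) -> dict:
        return {
            "n_tests": self.n_tests,
            "alpha": self.alpha,
            "bonferroni_p": self.bonferroni_p,
            "lambda": self.lam,
            "adjusted_p": self.adjusted_p,
            "priority_p": self.priority_p,
        }


def significance_thresholds(
    n_tests: int, alpha: float = 0.05, lam: float = 1.0
) -> SignificanceReport:
    """Bonferroni, inflation-adjusted, and locus-prioritisation thresholds.

    The inflation-adjusted threshold takes the chi2(1) quantile whose
    upper tail equals the Bonferroni p-value, multiplies it by lambda,
    and converts back to an upper-tail probability. The prioritisation
    threshold scales the Bonferroni threshold's -log10 by 1.5.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    bonferroni_p = alpha / n_tests
    q = stats.chi2.isf(bonferroni_p, df=1)
    adjusted_p = float(stats.chi2.sf(lam * q, df=1))
    priority_p = 10.0 ** (-1.5 * -np.log10(bonferroni_p))
    return SignificanceReport(
        n_tests=n_tests,
        alpha=alpha,
        bonferroni_p=bonferroni_p,
        lam=lam,
        adjusted_p=adjusted_p,
        priority_p=float(priority_p),
    )


def _chrom_key(chrom) -> tuple:
    s = str(chrom)
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


@dataclass(frozen=True)
class Locus:
    trait: str
    chrom: str
    tag_variant: str
    tag_pos: int
    tag_p: float
    window: tuple[int, int]  # half-open [start, end) in bp
    member_variants: tuple[str, ...]


def define_loci(
    result: pd.DataFrame,
    threshold_p: float,
    window_bp: int = 1_000_000,
    trait: str = "",
) -> list[Locus]:
    """Greedy peak selection into non-overlapping tag windows.

    Repeatedly takes the most significant remaining variant with
    p < ``threshold_p`` as a tag (ties broken by smallest chromosome then
    position), assigns a ``window_bp`` window centred on it, and removes
    all variants inside. Loci are returned in genomic order.
    """
    df = result.dropna(subset=["p"]).copy()
    df["_ckey"] = df["chrom"].map(_chrom_key)
    df = df.sort_values(["p", "_ckey", "pos"], kind="mergesort")
    remaining = df[df["p"] < threshold_p]
    loci: list[Locus] = []
    half = window_bp // 2
    while not remaining.empty:
        tag = remaining.iloc[0]
        start, end = int(tag["pos"]) - half, int(tag["pos"]) + half
        in_window = (
            (df["chrom"] == tag["chrom"]) & (df["pos"] >= start) & (df["pos"] < end)
        )
        members = df.loc[in_window]
        loci.append(
            Locus(
                trait=trait,
                chrom=str(tag["chrom"]),
                tag_variant=str(tag["variant_id"]),
                tag_pos=int(tag["pos"]),
                tag_p=float(tag["p"]),
                window=(start, end),
                member_variants=tuple(members["variant_id"].astype(str)),
            )
        )
        df = df.loc[~in_window]
        remaining = df[df["p"] < threshold_p]
    loci.sort(key=lambda l: (_chrom_key(l.chrom), l.tag_pos))
    return loci


def variance_explained(beta: float, alt_freq: float, sigma2_P: float) -> float:
    """Fraction of phenotypic variance: 2 p (1-p) beta^2 / sigma2_P.

    Cumulative summaries for a set of tag variants sum the per-variant
    values (ignores LD between tags).
    """
    if not sigma2_P > 0:
        raise ValueError("sigma2_P must be positive")
    if not 0.0 < alt_freq < 1.0:
        warnings.warn(
            f"allele frequency {alt_freq} at boundary; variance explained is 0",
            stacklevel=2,
        )
        return 0.0
    return 2.0 * alt_freq * (1.0 - alt_freq) * beta**2 / sigma2_P
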