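"""QTL x eQTL co-segregation analysis and candidate-gene triage.

Two scans over the same window that tag a shared causal element should
produce similar per-variant association statistics. This module scores
each (locus, gene) pair by the Pearson and Spearman correlation of the
paired chi-square vectors, the genotype LD between the two top variants,
and applies the rule-based candidate triage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import Locus, _chrom_key
from .core_io import AnnotationTable, GenotypeMatrix
from .eqtl import EqtlResult


def ld_r2(g: GenotypeMatrix, v1: str, v2: str) -> float:
    """Composite LD: squared Pearson correlation of the two dosage vectors,
    over animals called at both variants. Invariant to allele relabelling."""
    d1 = g.dosage_of(v1)
    d2 = g.dosage_of(v2)
    both = np.isfinite(d1) & np.isfinite(d2)
    d1, d2 = d1[both], d2[both]
    if d1.std() == 0 or d2.std() == 0:
        raise ValueError(
            f"cannot compute LD: monomorphic dosage vector ({v1!r} vs {v2!r})"
        )
    r = np.corrcoef(d1, d2)[0, 1]
    return float(r * r)


def top_variant(result: pd.DataFrame) -> str:
    """Variant with minimum p; ties broken by smallest (chromosome, position)."""
    df = result.dropna(subset=["p"])
    if df.empty:
        raise ValueError("no variant with a non-missing p-value")
    best = min(
        df.itertuples(), key=lambda r: (r.p, _chrom_key(r.chrom), r.pos)
    )
    return str(best.variant_id)


def chi2_correlation(
    qtl: pd.DataFrame, eqtl: pd.DataFrame
) -> tuple[float, float, int]:
    """(Pearson r, Spearman rho, n) of the paired chi2 vectors over the
    variants shared by both scans; pairs with a missing statistic in
    either scan are dropped. Requires >= 3 shared variants."""
    merged = qtl[["variant_id", "chi2"]].merge(
        eqtl[["variant_id", "chi2"]], on="variant_id", suffixes=("_qtl", "_eqtl")
    ).dropna()
    n = len(merged)
    if n < 3:
        raise ValueError(f"only {n} shared variants with finite statistics (need >= 3)")
    a = merged["chi2_qtl"].to_numpy()
    b = merged["chi2_eqtl"].to_numpy()
    pearson = float(stats.pearsonr(a, b).statistic)
    spearman = float(stats.spearmanr(a, b).statistic)
    return pearson, spearman, n


@dataclass(frozen=True)
class ColocScore:
    locus_id: str
    gene_id: str
    pearson_r: float
    spearman_rho: float
    n_shared: int
    top_ld_r2: float
    eqtl_top_variant: str
    eqtl_top_p: float
    qtl_tag_p_in_eqtl: float


@dataclass(frozen=True)
class TriageThresholds:
    coding_ld: float = 0.9
    corr: float = 0.7
    top_ld: float = 0.9
    eqtl_alpha: float = 2.53e-7


@dataclass
class Candidate:
    gene_id: str
    reasons: list[str]
    score: ColocScore | None = None


@dataclass
class CandidateReport:
    locus_id: str
    candidates: list[Candidate] = field(default_factory=list)

    def genes(self) -> list[str]:
        return [c.gene_id for c in self.candidates]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.candidates:
            s = c.score
            rows.append(
                {
                    "locus_id": self.locus_id,
                    "gene_id": c.gene_id,
                    "reasons": ";".join(c.reasons),
                    "pearson_r": np.nan if s is None else s.pearson_r,
                    "spearman_rho": np.nan if s is None else s.spearman_rho,
                    "top_ld_r2": np.nan if s is None else s.top_ld_r2,
                    "eqtl_top_p": np.nan if s is None else s.eqtl_top_p,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["locus_id", "gene_id", "reasons", "pearson_r",
                     "spearman_rho", "top_ld_r2", "eqtl_top_p"],
        )


def coloc_score(
    locus: Locus, qtl: pd.DataFrame, eqtl: EqtlResult, g: GenotypeMatrix
) -> ColocScore:
    """Score one locus/gene pair: chi2 correlations, top-variant LD and
    headline p-values."""
    pearson, spearman, n = chi2_correlation(qtl, eqtl.assoc)
    e_top = top_variant(eqtl.assoc)
    try:
        ld = ld_r2(g, locus.tag_variant, e_top)
    except ValueError:
        ld = np.nan
    e_by_id = eqtl.assoc.set_index("variant_id")
    tag_in_eqtl = (
        float(e_by_id.loc[locus.tag_variant, "p"])
        if locus.tag_variant in e_by_id.index
        else np.nan
    )
    return ColocScore(
        locus_id=f"{locus.trait}:{locus.chrom}:{locus.tag_pos}",
        gene_id=eqtl.gene_id,
        pearson_r=pearson,
        spearman_rho=spearman,
        n_shared=n,
        top_ld_r2=ld,
        eqtl_top_variant=e_top,
        eqtl_top_p=float(np.nanmin(e_by_id["p"])) if len(e_by_id) else np.nan,
        qtl_tag_p_in_eqtl=tag_in_eqtl,
    )


def scores_to_frame(scores: list[ColocScore]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in scores])


def triage_candidates(
    locus: Locus,
    qtl: pd.DataFrame,
    eqtls: list[EqtlResult],
    ann: AnnotationTable | None,
    g: GenotypeMatrix,
    thresholds: TriageThresholds = TriageThresholds(),
) -> CandidateReport:
    """Nominate candidate genes at a locus. A gene qualifies when any rule
    fires; all firing reasons are recorded:

    - ``coding_LD``: an annotated protein-altering variant in the gene is
      in LD r^2 > ``coding_ld`` with the QTL top variant;
    - ``eqtl_correlation``: the gene's eQTL passes ``eqtl_alpha`` and the
      Pearson or Spearman chi2 correlation exceeds ``corr``;
    - ``shared_top_variant``: the eQTL passes ``eqtl_alpha`` and the LD
      r^2 between the eQTL and QTL top variants exceeds ``top_ld``.
    """
    locus_id = f"{locus.trait}:{locus.chrom}:{locus.tag_pos}"
    by_gene: dict[str, Candidate] = {}

    def add(gene: str, reason: str, score: ColocScore | None = None) -> None:
        c = by_gene.setdefault(gene, Candidate(gene_id=gene, reasons=[]))
        if reason not in c.reasons:
            c.reasons.append(reason)
        if score is not None:
            c.score = score

    if ann is not None:
        for gene in ann.gene_ids:
            for vid in ann.protein_altering_variants(gene):
                try:
                    if ld_r2(g, vid, locus.tag_variant) > thresholds.coding_ld:
                        add(gene, "coding_LD")
                        break
                except (KeyError, ValueError):
                    continue

    for eq in eqtls:
        try:
            score = coloc_score(locus, qtl, eq, g)
        except ValueError:
            continue
        passes_alpha = (
            np.isfinite(score.eqtl_top_p) and score.eqtl_top_p < thresholds.eqtl_alpha
        )
        if passes_alpha and (
            score.pearson_r > thresholds.corr or score.spearman_rho > thresholds.corr
        ):
            add(eq.gene_id, "eqtl_correlation", score)
        if passes_alpha and np.isfinite(score.top_ld_r2) and (
            score.top_ld_r2 > thresholds.top_ld
        ):
            add(eq.gene_id, "shared_top_variant", score)
        if eq.gene_id in by_gene and by_gene[eq.gene_id].score is None:
            by_gene[eq.gene_id].score = score

    return CandidateReport(
        locus_id=locus_id, candidates=sorted(by_gene.values(), key=lambda c: c.gene_id)
    )
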