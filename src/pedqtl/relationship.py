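"""Pedigree-expected additive relationships and pedigree/genotype checks.

The numerator relationship matrix A is built densely with the tabular
(recursive) method over a topologically sorted pedigree. Also here:
founder-breed ancestry fractions with a configurable purebred threshold,
and the opposite-homozygote Mendelian concordance check used to flag
animals whose genotypes conflict with a recorded parent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GenotypeMatrix, Pedigree

#: an animal counts as purebred at >= 15/16 recorded ancestry of one breed
PUREBRED_THRESHOLD = 15.0 / 16.0


@dataclass
class RelationshipMatrix:
    """Dense symmetric numerator relationship matrix with its animal order."""

    animal_ids: list[str]
    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        n = len(self.animal_ids)
        if self.A.shape != (n, n):
            raise ValueError(f"A shape {self.A.shape} != ({n}, {n})")

    def __len__(self) -> int:
        return len(self.animal_ids)

    def inbreeding(self) -> np.ndarray:
        return np.diag(self.A) - 1.0

    def subset(self, animal_ids: list[str]) -> "RelationshipMatrix":
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        idx = np.array([pos[a] for a in animal_ids])
        return RelationshipMatrix(list(animal_ids), self.A[np.ix_(idx, idx)])

    def write(self, path) -> None:
        df = pd.DataFrame(self.A, index=self.animal_ids, columns=self.animal_ids)
        df.index.name = "animal_id"
        df.to_csv(path, sep="\t", float_format="%.17g")


def build_numerator_relationship(p: Pedigree) -> RelationshipMatrix:
    """Tabular method: A_ii = 1 + 0.5 A(sire, dam); A_ij = mean of A(j, parents).

    A missing parent contributes 0 (treated as an unrelated, non-inbred
    founder). Requires the pedigree's topological ordering, which
    :class:`~pedqtl.core_io.Pedigree` guarantees.
    """
    n = len(p)
    A = np.zeros((n, n))
    idx = {r.animal_id: i for i, r in enumerate(p.records)}
    for i, rec in enumerate(p.records):
        s = idx[rec.sire_id] if rec.sire_id is not None else -1
        d = idx[rec.dam_id] if rec.dam_id is not None else -1
        row = np.zeros(i)
        if s >= 0:
            row += A[s, :i]
        if d >= 0:
            row += A[d, :i]
        row *= 0.5
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(p.animal_ids, A)


@dataclass
class AncestryReport:
    """Per-animal founder-breed fractions plus purebred flags."""

    fractions: pd.DataFrame  # index animal_id, one column per breed
    purebred: pd.DataFrame  # same shape, boolean
    threshold: float = PUREBRED_THRESHOLD


def breed_fractions(
    p: Pedigree, threshold: float = PUREBRED_THRESHOLD
) -> AncestryReport:
    """Breed fraction of each animal = average of its parents' fractions.

    Unlabelled founders contribute to an ``unknown`` breed column; a
    missing parent contributes as an unknown-breed founder.
    """
    breeds = sorted({r.breed for r in p.founders if r.breed is not None})
    labels = breeds + ["unknown"]
    col = {b: j for j, b in enumerate(labels)}
    n = len(p)
    frac = np.zeros((n, len(labels)))
    unknown_founder = np.zeros(len(labels))
    unknown_founder[col["unknown"]] = 1.0
    for i, rec in enumerate(p.records):
        if rec.is_founder:
            frac[i, col[rec.breed if rec.breed is not None else "unknown"]] = 1.0
        else:
            for pid in (rec.sire_id, rec.dam_id):
                contrib = frac[p.index_of(pid)] if pid is not None else unknown_founder
                frac[i] += 0.5 * contrib
    fractions = pd.DataFrame(frac, index=p.animal_ids, columns=labels)
    purebred = fractions.ge(threshold) & (fractions.columns.to_numpy() != "unknown")
    return AncestryReport(fractions=fractions, purebred=purebred, threshold=threshold)


def purebred_animals(report: AncestryReport, breed: str) -> list[str]:
    return [str(a) for a in report.purebred.index[report.purebred[breed]]]


@dataclass
class ConcordanceReport:
    """Opposite-homozygote conflict counts per (animal, parent) pair."""

    pairs: pd.DataFrame  # animal_id, parent_id, relation, n_tested, n_conflicts, rate, excluded
    max_conflict_rate: float

    @property
    def excluded_animals(self) -> list[str]:
        return sorted(self.pairs.loc[self.pairs["excluded"], "animal_id"].unique())


def mendel_concordance(
    p: Pedigree, g: GenotypeMatrix, max_conflict_rate: float = 0.02
) -> ConcordanceReport:
    """Count opposite-homozygote conflicts for every genotyped parent pair.

    A conflict is parent dosage 0 with child dosage 2 or vice versa,
    counted only at variants where both members are called. Animals whose
    conflict rate with either recorded parent exceeds ``max_conflict_rate``
    are flagged for exclusion.
    """
    if g.n_variants == 0:
        raise ValueError("no variants available for concordance checking")
    gpos = {a: i for i, a in enumerate(g.animal_ids)}
    D = g.dosages
    rows = []
    for rec in p.records:
        ci = gpos.get(rec.animal_id)
        if ci is None:
            continue
        for relation, pid in (("sire", rec.sire_id), ("dam", rec.dam_id)):
            if pid is None or pid not in gpos:
                continue
            pi = gpos[pid]
            both = np.isfinite(D[ci]) & np.isfinite(D[pi])
            n_tested = int(both.sum())
            conflicts = both & (
                ((D[ci] == 0) & (D[pi] == 2)) | ((D[ci] == 2) & (D[pi] == 0))
            )
            n_conf = int(conflicts.sum())
            rate = n_conf / n_tested if n_tested else np.nan
            rows.append(
                (rec.animal_id, pid, relation, n_tested, n_conf, rate,
                 bool(n_tested and rate > max_conflict_rate))
            )
    pairs = pd.DataFrame(
        rows,
        columns=["animal_id", "parent_id", "relation", "n_tested",
                 "n_conflicts", "rate", "excluded"],
    )
    return ConcordanceReport(pairs=pairs, max_conflict_rate=max_conflict_rate)
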