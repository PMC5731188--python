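"""Readers and writers for the tabular inputs and outputs of the pipeline.

Pedigrees, genotype matrices (VCF or TSV dosage), phenotype tables,
annotation tables, and the association result table all live here, together
with variant-level quality-control filtering.

Coordinate convention: variant positions are 1-based (as in VCF). Window
arithmetic elsewhere in the package uses half-open ``[start, end)``
intervals on those 1-based positions.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_PARENT_TOKENS = {"", "0", "NA", "na", ".", None}

#: consequence classes understood by the triage rules
CONSEQUENCE_CLASSES = ("missense", "splice_region", "splice_donor", "other")
PROTEIN_ALTERING = frozenset({"missense", "splice_region", "splice_donor"})


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, dangling parents)."""


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PedigreeRecord:
    animal_id: str
    sire_id: str | None
    dam_id: str | None
    breed: str | None = None

    @property
    def is_founder(self) -> bool:
        return self.sire_id is None and self.dam_id is None


@dataclass
class Pedigree:
    """A topologically sorted pedigree (parents always precede offspring)."""

    records: list[PedigreeRecord]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {r.animal_id: i for i, r in enumerate(self.records)}
        if len(self._index) != len(self.records):
            seen: set[str] = set()
            for r in self.records:
                if r.animal_id in seen:
                    raise PedigreeError(f"duplicate animal id {r.animal_id!r}")
                seen.add(r.animal_id)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, animal_id: str) -> bool:
        return animal_id in self._index

    def index_of(self, animal_id: str) -> int:
        return self._index[animal_id]

    @property
    def animal_ids(self) -> list[str]:
        return [r.animal_id for r in self.records]

    @property
    def founders(self) -> list[PedigreeRecord]:
        return [r for r in self.records if r.is_founder]

    def record(self, animal_id: str) -> PedigreeRecord:
        return self.records[self._index[animal_id]]

    @classmethod
    def from_records(
        cls,
        records: Iterable[PedigreeRecord],
        allow_implicit_founders: bool = True,
    ) -> "Pedigree":
        """Validate, add implicit founders if allowed, and topologically sort.

        Raises :class:`PedigreeError` on cycles, naming one member of the
        cycle, or when a parent is referenced but never defined and implicit
        founders are disallowed.
        """
        recs = list(records)
        by_id = {r.animal_id: r for r in recs}
        if len(by_id) != len(recs):
            raise PedigreeError("duplicate animal ids in pedigree input")
        referenced: list[str] = []
        for r in recs:
            for pid in (r.sire_id, r.dam_id):
                if pid is not None and pid not in by_id:
                    referenced.append(pid)
        if referenced:
            if not allow_implicit_founders:
                raise PedigreeError(
                    f"parent {referenced[0]!r} referenced but never defined"
                )
            for pid in dict.fromkeys(referenced):
                by_id[pid] = PedigreeRecord(pid, None, None, None)
            recs = list(by_id.values())

        # Kahn's algorithm; deterministic order (input order within a level).
        n_parents = {
            r.animal_id: sum(p is not None for p in (r.sire_id, r.dam_id))
            for r in recs
        }
        children: dict[str, list[str]] = {r.animal_id: [] for r in recs}
        for r in recs:
            for pid in (r.sire_id, r.dam_id):
                if pid is not None:
                    children[pid].append(r.animal_id)
        order: list[PedigreeRecord] = []
        ready = [r.animal_id for r in recs if n_parents[r.animal_id] == 0]
        while ready:
            aid = ready.pop(0)
            order.append(by_id[aid])
            for c in children[aid]:
                n_parents[c] -= 1
                if n_parents[c] == 0:
                    ready.append(c)
        if len(order) != len(recs):
            stuck = sorted(a for a, k in n_parents.items() if k > 0)
            raise PedigreeError(f"pedigree contains a cycle involving {stuck[0]!r}")
        return cls(order)


def _parse_parent(token: str) -> str | None:
    token = token.strip()
    return None if token in MISSING_PARENT_TOKENS else token


def read_pedigree(path: str | Path, allow_implicit_founders: bool = True) -> Pedigree:
    """Read a delimited pedigree file with header ``id, sire, dam[, breed]``.

    ``0`` or an empty field denotes a missing parent. Output is
    topologically sorted regardless of input row order.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    cols = {c.lower(): c for c in df.columns}
    for required in ("id", "sire", "dam"):
        if required not in cols:
            raise PedigreeError(f"pedigree file missing column {required!r}")
    breed_col = cols.get("breed")
    records = []
    for _, row in df.iterrows():
        breed = row[breed_col].strip() if breed_col is not None else ""
        records.append(
            PedigreeRecord(
                animal_id=row[cols["id"]].strip(),
                sire_id=_parse_parent(row[cols["sire"]]),
                dam_id=_parse_parent(row[cols["dam"]]),
                breed=breed or None,
            )
        )
    return Pedigree.from_records(records, allow_implicit_founders=allow_implicit_founders)


def write_pedigree(p: Pedigree, path: str | Path) -> None:
    rows = [
        (r.animal_id, r.sire_id or "0", r.dam_id or "0", r.breed or "")
        for r in p.records
    ]
    pd.DataFrame(rows, columns=["id", "sire", "dam", "breed"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt"]


class GenotypeParseError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Animals x variants alt-allele dosage matrix.

    ``dosages`` is float with values in {0, 1, 2} and NaN for missing calls.
    ``variants`` is a DataFrame with columns variant_id, chrom, pos (1-based),
    ref, alt; positions are strictly increasing within each chromosome.
    """

    animal_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.animal_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.animal_ids)} animals x {len(self.variants)} variants"
            )
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValueError(
                f"dosage value {self.dosages[tuple(bad)]!r} at animal "
                f"{self.animal_ids[bad[0]]!r} is not in {{0,1,2,missing}}"
            )
        self.variants = self.variants.reset_index(drop=True)
        # non-decreasing, not strict: split multi-allelic records share a
        # coordinate
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not (np.diff(pos) >= 0).all():
                raise ValueError(f"positions not sorted on {chrom}")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return self.variants["variant_id"].tolist()

    def variant_index(self, variant_id: str) -> int:
        idx = self.variants.index[self.variants["variant_id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"variant {variant_id!r} not in matrix")
        return int(idx[0])

    def dosage_of(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.variant_index(variant_id)]

    def subset_animals(self, animal_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        idx = [pos[a] for a in animal_ids]
        return GenotypeMatrix(list(animal_ids), self.variants.copy(), self.dosages[idx])

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeMatrix(
            list(self.animal_ids),
            self.variants.iloc[idx].reset_index(drop=True),
            self.dosages[:, idx],
        )

    def window(self, chrom: str, start: int, end: int) -> "GenotypeMatrix":
        """Variants with ``start <= pos < end`` on ``chrom`` (half-open)."""
        mask = (
            (self.variants["chrom"].astype(str) == str(chrom))
            & (self.variants["pos"] >= start)
            & (self.variants["pos"] < end)
        ).to_numpy()
        return self.subset_variants(mask)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def alt_freq(self) -> np.ndarray:
        """Alt-allele frequency over called dosages; NaN if all missing."""
        called = np.isfinite(self.dosages)
        n_called = called.sum(axis=0)
        total = np.where(called, self.dosages, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, total / (2.0 * n_called), np.nan)


def _vcf_dosages_biallelic(gt_types: np.ndarray) -> np.ndarray:
    # cyvcf2 gts012 coding: 0=hom ref, 1=het, 2=hom alt, 3=unknown
    d = gt_types.astype(float)
    d[d == 3] = np.nan
    return d


def read_genotypes(
    path: str | Path,
    dialect: str = "vcf",
    multiallelic: str = "reject",
) -> GenotypeMatrix:
    """Read genotypes from a VCF (GT field) or a TSV dosage matrix.

    The TSV dialect has animals as rows; the first column is ``animal_id``
    and each remaining column header is ``variant_id:chrom:pos:ref:alt``
    (or a bare variant id, in which case synthetic coordinates are
    assigned). ``multiallelic`` is ``"reject"`` (error) or ``"split"``
    (one row per alt allele).
    """
    path = Path(path)
    if dialect == "vcf":
        return _read_vcf(path, multiallelic)
    if dialect == "tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_vcf(path: Path, multiallelic: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    if multiallelic not in ("reject", "split"):
        raise ValueError(f"unknown multiallelic policy {multiallelic!r}")
    vcf = VCF(str(path), gts012=True)
    animal_ids = list(vcf.samples)
    rows = []
    cols = []
    for v in vcf:
        coord = f"{v.CHROM}:{v.POS}"
        if len(v.ALT) == 0:
            continue
        if len(v.ALT) > 1:
            if multiallelic == "reject":
                raise GenotypeParseError(
                    f"multi-allelic record at {coord} under 'reject' policy"
                )
            # split: count each alt allele separately from the raw genotypes
            alleles = np.array([g[:2] for g in v.genotypes])
            if alleles.shape[1] != 2:
                raise GenotypeParseError(f"malformed GT at {coord}")
            for k, alt in enumerate(v.ALT, start=1):
                called = (alleles >= 0).all(axis=1)
                d = (alleles == k).sum(axis=1).astype(float)
                d[~called] = np.nan
                vid = v.ID or f"{v.CHROM}:{v.POS}:{v.REF}:{alt}"
                rows.append((f"{vid}_alt{k}" if v.ID else vid, v.CHROM, v.POS, v.REF, alt))
                cols.append(d)
            continue
        gt = v.gt_types
        if gt is None or len(gt) != len(animal_ids):
            raise GenotypeParseError(f"malformed GT at {coord}")
        vid = v.ID or f"{v.CHROM}:{v.POS}:{v.REF}:{v.ALT[0]}"
        rows.append((vid, v.CHROM, v.POS, v.REF, v.ALT[0]))
        cols.append(_vcf_dosages_biallelic(gt))
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosages = (
        np.column_stack(cols) if cols else np.empty((len(animal_ids), 0))
    )
    return GenotypeMatrix(animal_ids, variants, dosages)


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df = df.set_index(df.columns[0])
    rows = []
    for j, label in enumerate(df.columns):
        parts = str(label).split(":")
        if len(parts) == 5:
            vid, chrom, pos, ref, alt = parts
            rows.append((vid, chrom, int(pos), ref, alt))
        else:
            rows.append((str(label), "0", j + 1, "N", "N"))
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    return GenotypeMatrix(
        [str(a) for a in df.index], variants, df.to_numpy(dtype=float)
    )


def write_genotypes_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    """Write the TSV dosage dialect (lossless against ``read_genotypes``)."""
    labels = [
        f"{r.variant_id}:{r.chrom}:{r.pos}:{r.ref}:{r.alt}"
        for r in g.variants.itertuples()
    ]
    df = pd.DataFrame(g.dosages, index=g.animal_ids, columns=labels)
    df.index.name = "animal_id"
    df.to_csv(path, sep="\t", float_format="%g")


def write_genotypes_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with unphased GT fields."""
    gtmap = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(g.variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.animal_ids)
            + "\n"
        )
        for j, r in enumerate(g.variants.itertuples()):
            calls = [
                gtmap.get(d, "./.") if np.isfinite(d) else "./."
                for d in g.dosages[:, j]
            ]
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.variant_id}\t{r.ref}\t{r.alt}"
                f"\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------------------
# Variant QC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QCReport:
    n_input: int
    n_removed_maf: int
    n_removed_call_rate: int
    n_kept: int


def qc_filter_variants(
    g: GenotypeMatrix, min_maf: float = 0.025, min_call_rate: float = 0.9
) -> tuple[GenotypeMatrix, QCReport]:
    """Keep variants with MAF >= ``min_maf`` and call rate >= ``min_call_rate``.

    MAF is computed over called alleles only. Idempotent by construction.
    """
    if not (0 <= min_maf <= 1 and 0 <= min_call_rate <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    freq = g.alt_freq()
    with np.errstate(invalid="ignore"):
        maf_ = np.minimum(freq, 1.0 - freq)
    cr = g.call_rate()
    pass_maf = maf_ >= min_maf  # NaN freq (all missing) fails
    pass_cr = cr >= min_call_rate
    keep = pass_maf & pass_cr
    report = QCReport(
        n_input=g.n_variants,
        n_removed_maf=int((~pass_maf).sum()),
        n_removed_call_rate=int((~pass_cr).sum()),
        n_kept=int(keep.sum()),
    )
    logger.info(
        "QC: kept %d/%d variants (maf<%g removed %d, call rate<%g removed %d)",
        report.n_kept, report.n_input, min_maf, report.n_removed_maf,
        min_call_rate, report.n_removed_call_rate,
    )
    return g.subset_variants(keep), report


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    """Per-animal trait values, one column per trait."""

    values: pd.DataFrame  # index: animal_id

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate animal id {dup!r} in phenotype table")

    @property
    def animal_ids(self) -> list[str]:
        return [str(a) for a in self.values.index]

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)

    def vector(self, trait: str, animal_ids: Sequence[str]) -> np.ndarray:
        return self.values.loc[list(animal_ids), trait].to_numpy(dtype=float)

    def variance(self, trait: str) -> float:
        v = float(self.values[trait].var(ddof=1))
        if not v > 0:
            raise ValueError(f"phenotypic variance of {trait!r} is not positive")
        return v


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={0: str}).set_index("animal_id")
    return PhenotypeTable(df.astype(float))


def write_phenotypes(t: PhenotypeTable, path: str | Path) -> None:
    out = t.values.copy()
    out.index.name = "animal_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

@dataclass
class AnnotationTable:
    rows: pd.DataFrame  # variant_id, gene_id, consequence_class[, deleterious]

    def __post_init__(self) -> None:
        bad = set(self.rows["consequence_class"]) - set(CONSEQUENCE_CLASSES)
        if bad:
            raise ValueError(f"unknown consequence class(es): {sorted(bad)}")

    def protein_altering_variants(self, gene_id: str) -> list[str]:
        sel = (self.rows["gene_id"] == gene_id) & self.rows[
            "consequence_class"
        ].isin(PROTEIN_ALTERING)
        return self.rows.loc[sel, "variant_id"].tolist()

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.rows["gene_id"].unique())


def read_annotations(path: str | Path) -> AnnotationTable:
    return AnnotationTable(pd.read_csv(path, sep="\t", dtype=str))


# ---------------------------------------------------------------------------
# Association tables
# ---------------------------------------------------------------------------

ASSOC_COLUMNS = ["variant_id", "chrom", "pos", "beta", "se", "chi2", "p", "n_used"]


def write_association_table(results: pd.DataFrame, path: str | Path) -> None:
    """Write an association result table as TSV.

    Effects and standard errors are written at full double precision;
    p-values in scientific notation (17 significant digits, so the
    round trip is lossless well past 3 significant figures).
    """
    out = results.copy()
    for col in ("beta", "se", "chi2"):
        out[col] = [("" if not np.isfinite(v) else f"{v:.17g}") for v in out[col]]
    out["p"] = [("" if not np.isfinite(v) else f"{v:.16e}") for v in out["p"]]
    out.to_csv(path, sep="\t", index=False, columns=ASSOC_COLUMNS)


def read_association_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "chrom": str})
    for col in ("beta", "se", "chi2", "p"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def file_digest(path: str | Path) -> str:
    """SHA-256 of a file, for run provenance logs."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
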