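import numpy as np
import pandas as pd
import pytest

from pedqtl import (
    ChromosomeSpec,
    ExpressionSpec,
    GeneSpec,
    GenomicWindow,
    GenotypeMatrix,
    Pedigree,
    PedigreeRecord,
    SimConfig,
    TraitSpec,
    simulate,
)


def make_genotypes(dosages, animal_ids=None, chrom="1", positions=None,
                   variant_ids=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a dosage array (NaN = missing)."""
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    animal_ids = animal_ids or [f"a{i}" for i in range(n)]
    positions = positions if positions is not None else [100 * (j + 1) for j in range(m)]
    variant_ids = variant_ids or [f"v{j}" for j in range(m)]
    variants = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chrom": [chrom] * m,
            "pos": positions,
            "ref": ["A"] * m,
            "alt": ["B"] * m,
        }
    )
    return GenotypeMatrix(list(animal_ids), variants, d)


@pytest.fixture
def trio_pedigree() -> Pedigree:
    return Pedigree.from_records(
        [
            PedigreeRecord("sire", None, None, "HF"),
            PedigreeRecord("dam", None, None, "JE"),
            PedigreeRecord("kid", "sire", "dam", None),
        ]
    )


@pytest.fixture
def halfsib_pedigree() -> Pedigree:
    """Four founders, two half-sib offspring sharing founder f1 as sire."""
    return Pedigree.from_records(
        [
            PedigreeRecord("f1", None, None, "HF"),
            PedigreeRecord("f2", None, None, "HF"),
            PedigreeRecord("f3", None, None, "JE"),
            PedigreeRecord("f4", None, None, "JE"),
            PedigreeRecord("c1", "f1", "f2", None),
            PedigreeRecord("c2", "f1", "f3", None),
        ]
    )


def small_sim_config(seed=0, **kwargs) -> SimConfig:
    defaults = dict(
        seed=seed,
        n_founders_per_breed=20,
        n_generations=2,
        matings_per_generation=60,
        chromosomes=(ChromosomeSpec("1", 10_000_000, 1.0, 300),),
        trait=TraitSpec(h2=0.5, sigma2_P=2.0),
    )
    defaults.update(kwargs)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_sim():
    """A modest reusable cohort: 160 animals, 300 variants, 10 genes."""
    genes = tuple(
        GeneSpec(
            f"g{i}",
            GenomicWindow("1", 1, 10_000_001),
            causal_variant=None,
            log_fold=0.0,
            base_log_mean=3.0 + 0.4 * i,
        )
        for i in range(10)
    )
    cfg = small_sim_config(
        seed=11, expression=ExpressionSpec(genes=genes, n_samples=80)
    )
    return simulate(cfg)


def dense_gls_oracle(A, y, dosage, h2, sigma2_P):
    """Literal evaluation of the GLS equations by explicit inversion:
    beta = (X' W^-1 X)^-1 X' W^-1 y with W = sigma2_P (h2 A + (1-h2) I),
    X = [1, centred dosage]; se = sqrt(diag (X' W^-1 X)^-1)."""
    n = len(y)
    W = sigma2_P * (h2 * np.asarray(A) + (1 - h2) * np.eye(n))
    Wi = np.linalg.inv(W)
    x = np.asarray(dosage, float)
    x = np.where(np.isfinite(x), x, np.nanmean(x)) - np.nanmean(x)
    X = np.column_stack([np.ones(n), x])
    C = np.linalg.inv(X.T @ Wi @ X)
    b = C @ X.T @ Wi @ y
    se = np.sqrt(np.diag(C))
    chi2 = (b[1] / se[1]) ** 2
    return b[1], se[1], chi2


def kinship_oracle(ped: Pedigree):
    """Brute-force recursive kinship; A = 2 * kinship."""
    parents = {
        r.animal_id: (r.sire_id, r.dam_id) for r in ped.records
    }
    order = {r.animal_id: i for i, r in enumerate(ped.records)}
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def phi(a, b):
        if a is None or b is None:
            return 0.0
        # ensure a is not younger than b for the recursion
        if order[a] < order[b]:
            a, b = b, a
        sa, da = parents[a]
        if a == b:
            return 0.5 * (1.0 + phi(sa, da))
        return 0.5 * (phi(sa, b) + phi(da, b))

    ids = ped.animal_ids
    n = len(ids)
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1):
            A[i, j] = A[j, i] = 2.0 * phi(ids[i], ids[j])
    return A
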