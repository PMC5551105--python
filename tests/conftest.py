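import numpy as np
import pandas as pd
import pytest

from locustload.popgen import GenotypeTable


def make_table(pops: dict, loci=None) -> GenotypeTable:
    """Build a GenotypeTable from nested lists.

    ``pops`` maps population name -> list of individuals, each a list of
    (allele, allele) pairs per locus; ``None`` marks a missing genotype.
    """
    n_loci = len(next(iter(pops.values()))[0])
    loci = loci or [f"L{j + 1}" for j in range(n_loci)]
    arrays = {}
    for name, inds in pops.items():
        arr = np.zeros((len(inds), n_loci, 2), dtype=np.int64)
        for i, ind in enumerate(inds):
            for j, g in enumerate(ind):
                if g is not None:
                    arr[i, j] = g
        arrays[name] = arr
    return GenotypeTable(loci=list(loci), populations=arrays)


def make_pods(rows) -> pd.DataFrame:
    """Pod table from (population, treatment, rank, eggs, hatched[, surv])."""
    recs = []
    for i, row in enumerate(rows):
        pop, treatment, rank, eggs, hatched = row[:5]
        surv = row[5] if len(row) > 5 else hatched
        recs.append(
            {
                "population": pop,
                "family": f"{pop}_fam1",
                "female_id": f"{pop}_f{i}",
                "treatment": treatment,
                "pod_rank": rank,
                "n_eggs": eggs,
                "n_hatched": hatched,
                "n_survived_24h": surv,
            }
        )
    return pd.DataFrame(recs)


@pytest.fixture
def simple_pods():
    """One population: outbred 200/150 hatched, parthenogenetic 200/50."""
    return make_pods(
        [
            ("P", "outbred", 1, 100, 75),
            ("P", "outbred", 2, 100, 75),
            ("P", "parthenogenetic", 1, 120, 30),
            ("P", "parthenogenetic", 2, 80, 20),
            ("P", "inbred_fullsib", 1, 100, 75),
            ("P", "inbred_fullsib", 2, 100, 60),
        ]
    )
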