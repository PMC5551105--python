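"""Microsatellite summary statistics.

Implements the descriptive statistics routinely reported for diploid
multilocus genotype samples: unbiased expected heterozygosity (gene
diversity), observed heterozygosity, the within-population inbreeding
coefficient F_IS, allelic richness rarefied by hypergeometric sampling,
and the Weir & Cockerham (1984) theta estimator of pairwise F_ST.

Genotypes are held in a :class:`GenotypeTable`: per population an
integer array of shape ``(n_individuals, n_loci, 2)`` with allele code
``0`` marking missing data.  Individuals missing at a locus are
excluded locus-wise, never list-wise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeTable",
    "PopGenSummary",
    "allele_counts",
    "expected_heterozygosity",
    "observed_heterozygosity",
    "inbreeding_coefficient",
    "fis_per_locus",
    "allelic_richness",
    "pairwise_fst",
    "summarize",
]

MISSING = 0  # allele code for missing data; real codes are positive ints


@dataclass
class GenotypeTable:
    """Diploid multilocus genotypes for one or more populations.

    Attributes
    ----------
    loci : list of str
        Locus labels.
    populations : dict
        Maps population label -> int array ``(n_individuals, n_loci, 2)``.
        Allele codes are positive integers; 0 means missing.  A locus is
        either fully typed or fully missing per individual (a half-typed
        genotype is treated as missing).
    individual_names : dict, optional
        Maps population label -> list of individual labels.
    """

    loci: list
    populations: dict
    individual_names: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.loci) < 1:
            raise ValueError("need at least one locus")
        if len(self.populations) < 1:
            raise ValueError("need at least one population")
        L = len(self.loci)
        for pop, arr in self.populations.items():
            arr = np.asarray(arr, dtype=np.int64)
            if arr.ndim != 3 or arr.shape[1] != L or arr.shape[2] != 2:
                raise ValueError(
                    f"population {pop!r}: expected genotype array of shape "
                    f"(n, {L}, 2), got {arr.shape}"
                )
            if (arr < 0).any():
                raise ValueError(f"population {pop!r}: negative allele codes")
            # half-missing genotypes collapse to fully missing
            half = (arr == MISSING).any(axis=2)
            arr[half] = MISSING
            self.populations[pop] = arr

    @property
    def population_names(self) -> list:
        return list(self.populations)

    def genotypes(self, pop: str, locus: str) -> np.ndarray:
        """(n, 2) allele array at one locus, missing rows included."""
        j = self.loci.index(locus)
        return self.populations[pop][:, j, :]


def allele_counts(genotypes: np.ndarray) -> dict:
    """Counts of each allele among non-missing gene copies at one locus."""
    g = np.asarray(genotypes).reshape(-1)
    g = g[g != MISSING]
    alleles, counts = np.unique(g, return_counts=True)
    return dict(zip(alleles.tolist(), counts.tolist()))


def expected_heterozygosity(counts: Mapping[int, int]) -> float:
    """Unbiased gene diversity ``(2n/(2n-1)) * (1 - sum p_i^2)``.

    ``counts`` maps allele code -> number of gene copies; ``2n`` is the
    total number of copies.  Returns NaN when fewer than two copies.
    """
    total = sum(counts.values())
    if total < 2:
        return math.nan
    p = np.array(list(counts.values()), dtype=float) / total
    return total / (total - 1) * (1.0 - float(np.sum(p * p)))


def observed_heterozygosity(genotypes: np.ndarray) -> float:
    """Fraction of non-missing individuals carrying two distinct alleles."""
    g = np.asarray(genotypes)
    ok = (g != MISSING).all(axis=1)
    if not ok.any():
        return math.nan
    return float(np.mean(g[ok, 0] != g[ok, 1]))


def fis_per_locus(h_obs: float, h_exp: float) -> float:
    """Single-locus inbreeding coefficient ``1 - H_O / H_E``."""
    if not (h_exp > 0) or math.isnan(h_obs):
        return math.nan
    return 1.0 - h_obs / h_exp


def inbreeding_coefficient(
    h_obs: Sequence[float], h_exp: Sequence[float]
) -> float:
    """Multilocus F_IS by ratio of sums, ``1 - sum(H_O) / sum(H_E)``.

    Loci with ``H_E == 0`` (monomorphic) or missing values are excluded;
    all loci monomorphic -> NaN.  Ratio-of-sums is preferred to the mean
    of per-locus ratios because loci with tiny H_E make the latter wild.
    """
    ho = np.asarray(h_obs, dtype=float)
    he = np.asarray(h_exp, dtype=float)
    keep = (he > 0) & ~np.isnan(ho)
    if not keep.any():
        return math.nan
    return 1.0 - float(ho[keep].sum()) / float(he[keep].sum())


def allelic_richness(counts: Mapping[int, int], g: int) -> float:
    """Expected allele count in a rarefied sample of ``g`` gene copies.

    Hypergeometric rarefaction: ``A_R = sum_i [1 - C(N - N_i, g) / C(N, g)]``
    with ``N`` total copies and ``N_i`` copies of allele ``i``.
    """
    N = sum(counts.values())
    if g < 2:
        raise ValueError("rarefaction size g must be >= 2 gene copies")
    if g > N:
        raise ValueError(f"rarefaction size g={g} exceeds sample of {N} gene copies")
    denom = comb(N, g)
    return float(sum(1.0 - comb(N - ni, g) / denom for ni in counts.values()))


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) theta
# ---------------------------------------------------------------------------


def _wc_components(table: GenotypeTable, pops: Sequence[str], locus: str):
    """Per-allele variance components (a, b, c) at one locus.

    Follows the estimator's standard variance-components form for r
    sampled populations; here r = len(pops).  Returns (sum_a, sum_abc)
    over alleles, or (0, 0) when the locus carries no information.
    """
    r = len(pops)
    geno = [table.genotypes(p, locus) for p in pops]
    geno = [g[(g != MISSING).all(axis=1)] for g in geno]
    n = np.array([len(g) for g in geno], dtype=float)
    if (n < 1).any() or n.sum() < 2:
        return 0.0, 0.0

    alleles = sorted(set(np.concatenate(geno).reshape(-1).tolist()))
    nbar = n.mean()
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    if nbar <= 1 or nc <= 0:
        return 0.0, 0.0

    sum_a = 0.0
    sum_abc = 0.0
    for allele in alleles:
        p_i = np.array([np.mean(g == allele) for g in geno])  # freq per pop
        h_i = np.array(
            [np.mean((g == allele).sum(axis=1) == 1) for g in geno]
        )  # heterozygote frequency for this allele
        pbar = (n * p_i).sum() / (r * nbar)
        s2 = (n * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n * h_i).sum() / (r * nbar)

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        sum_a += a
        sum_abc += a + b + c
    return sum_a, sum_abc


def pairwise_fst(table: GenotypeTable, pop_a: str, pop_b: str) -> float:
    """Weir & Cockerham theta between two populations.

    Multilocus ratio of sums of the variance components over loci and
    alleles.  Negative estimates are reported as computed.  Returns NaN
    when no locus is informative (e.g. both samples monomorphic for the
    same allele everywhere).
    """
    num = 0.0
    den = 0.0
    for locus in table.loci:
        a, abc = _wc_components(table, (pop_a, pop_b), locus)
        num += a
        den += abc
    if den == 0.0:
        return math.nan
    return num / den


# ---------------------------------------------------------------------------
# summary report
# ---------------------------------------------------------------------------


@dataclass
class PopGenSummary:
    """Per-population summary statistics and a pairwise F_ST matrix."""

    per_locus: pd.DataFrame  # columns: population, locus, n, H_E, H_O, F_IS, A_R
    per_population: pd.DataFrame  # columns: population, n, A_R, H_E, H_O, F_IS
    fst: pd.DataFrame  # square matrix, NaN diagonal
    rarefaction_g: dict  # locus -> gene copies used for A_R

    def to_csv(self, per_population_path, per_locus_path=None, fst_path=None) -> None:
        self.per_population.to_csv(per_population_path, index=False)
        if per_locus_path is not None:
            self.per_locus.to_csv(per_locus_path, index=False)
        if fst_path is not None:
            self.fst.to_csv(fst_path)

    def to_text(self) -> str:
        lines = ["Population genetic summary (means over loci)", ""]
        lines.append(f"{'Population':<16}{'N':>5}{'A_R':>8}{'H_E':>8}{'H_O':>8}{'F_IS':>8}")
        for _, row in self.per_population.iterrows():
            lines.append(
                f"{row['population']:<16}{int(row['n']):>5}"
                f"{row['A_R']:>8.2f}{row['H_E']:>8.3f}{row['H_O']:>8.3f}{row['F_IS']:>8.3f}"
            )
        if len(self.fst.columns) > 1:
            lines += ["", "Pairwise F_ST (Weir & Cockerham theta):", self.fst.round(4).to_string()]
        return "\n".join(lines) + "\n"


def _min_copies_per_locus(table: GenotypeTable) -> dict:
    out = {}
    for locus in table.loci:
        mins = []
        for pop in table.population_names:
            g = table.genotypes(pop, locus)
            mins.append(int((g != MISSING).all(axis=1).sum()) * 2)
        out[locus] = min(mins)
    return out


def summarize(table: GenotypeTable, rarefaction_g: "int | None" = None) -> PopGenSummary:
    """All per-locus and mean statistics plus the pairwise theta matrix.

    ``rarefaction_g`` fixes the rarefied sample size in gene copies; by
    default each locus is rarefied to the smallest per-population
    non-missing copy count at that locus (standard richness reporting).
    """
    g_by_locus = {}
    min_copies = _min_copies_per_locus(table)
    for locus in table.loci:
        g = rarefaction_g if rarefaction_g is not None else min_copies[locus]
        if g > min_copies[locus]:
            small = min(
                table.population_names,
                key=lambda p: ((table.genotypes(p, locus) != MISSING).all(axis=1)).sum(),
            )
            raise ValueError(
                f"rarefaction size g={g} exceeds the {min_copies[locus]} gene "
                f"copies available at locus {locus!r} in population {small!r}"
            )
        g_by_locus[locus] = g

    rows = []
    for pop in table.population_names:
        for locus in table.loci:
            geno = table.genotypes(pop, locus)
            counts = allele_counts(geno)
            n = int((geno != MISSING).all(axis=1).sum())
            he = expected_heterozygosity(counts) if counts else math.nan
            ho = observed_heterozygosity(geno)
            ar = (
                allelic_richness(counts, g_by_locus[locus])
                if counts and g_by_locus[locus] >= 2
                else math.nan
            )
            rows.append(
                {
                    "population": pop,
                    "locus": locus,
                    "n": n,
                    "H_E": he,
                    "H_O": ho,
                    "F_IS": fis_per_locus(ho, he),
                    "A_R": ar,
                }
            )
    per_locus = pd.DataFrame(rows)

    pop_rows = []
    for pop, sub in per_locus.groupby("population", sort=False):
        pop_rows.append(
            {
                "population": pop,
                "n": int(sub["n"].max()),
                "A_R": float(sub["A_R"].mean()),
                "H_E": float(sub["H_E"].mean()),
                "H_O": float(sub["H_O"].mean()),
                "F_IS": inbreeding_coefficient(sub["H_O"], sub["H_E"]),
            }
        )
    per_population = pd.DataFrame(pop_rows)

    pops = table.population_names
    fst = pd.DataFrame(np.nan, index=pops, columns=pops)
    for i, pa in enumerate(pops):
        for pb in pops[i + 1 :]:
            theta = pairwise_fst(table, pa, pb)
            fst.loc[pa, pb] = theta
            fst.loc[pb, pa] = theta

    return PopGenSummary(
        per_locus=per_locus,
        per_population=per_population,
        fst=fst,
        rarefaction_g=g_by_locus,
    )
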