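"""Seeded generators for breeding-experiment and genotype tables.

Emulates a three-treatment locust breeding design: for each population,
full-sib families supply females that are assigned to an outbred,
full-sib inbred, or parthenogenetic (no mate) treatment.  A female lays
with a treatment-specific probability; each of her (up to two) egg pods
draws a rank-dependent Poisson egg number (first pods are larger);
every egg passes a baseline viability Bernoulli and then a mechanistic
genetic-load filter: the egg draws ``k ~ Poisson(B)`` maternal lethal
equivalents, each is expressed (made homozygous) independently with
probability ``F`` of the treatment, and the egg hatches only if no
lethal is expressed.  This per-egg draw — rather than a single
Bernoulli with the closed-form probability ``exp(-B*F)`` — makes the
simulator an independent mechanistic oracle for the analytical load
model instead of a restatement of it.

Hatchlings survive 24 h with a treatment-specific probability; up to a
per-pod cap of survivors become offspring records with Gaussian traits
(development time in days, adult femur length in mm) shifted by
treatment.  Genotype tables are generated separately with a target
within-population inbreeding coefficient F_IS.

Each population consumes its own RNG stream, split deterministically
from the master seed and the population name, so adding or reordering
populations never perturbs the draws of the others.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .load_model import TREATMENT_F
from .popgen import GenotypeTable

__all__ = [
    "PopulationSimConfig",
    "GenotypeSimConfig",
    "ExperimentTables",
    "simulate_experiment",
    "simulate_genotypes",
    "simulate_egg_hatching",
    "merge_genotype_tables",
    "default_experiment_configs",
    "default_genotype_configs",
    "POD_COLUMNS",
    "OFFSPRING_COLUMNS",
    "FEMALE_COLUMNS",
]

POD_COLUMNS = [
    "population",
    "family",
    "female_id",
    "treatment",
    "pod_rank",
    "n_eggs",
    "n_hatched",
    "n_survived_24h",
]
OFFSPRING_COLUMNS = [
    "population",
    "family",
    "treatment",
    "offspring_id",
    "sex",
    "extra_molt",
    "development_time",
    "femur_length",
    "survival_days",
    "event",
]
FEMALE_COLUMNS = ["population", "family", "female_id", "treatment", "laid"]


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be a probability in [0, 1], got {value}")


def _check_prob_map(name: str, mapping: dict) -> None:
    missing = set(TREATMENT_F) - set(mapping)
    if missing:
        raise ValueError(f"{name} missing treatments: {sorted(missing)}")
    for k, v in mapping.items():
        _check_prob(f"{name}[{k!r}]", v)


@dataclass
class PopulationSimConfig:
    """Study conditions for one simulated population.

    Probabilities the design does not pin down numerically reflect the
    qualitative pattern of the experiment: mated females nearly always
    lay while virgin females lay far less often, and first-day survival
    of parthenogenetic hatchlings is strongly reduced.
    """

    name: str
    B: float  # lethal equivalents per haploid genome; may be math.inf
    baseline_hatch: float = 0.75  # outbred hatching probability
    laying_prob: dict = field(
        default_factory=lambda: {
            "outbred": 0.9,
            "inbred_fullsib": 0.9,
            "parthenogenetic": 0.45,
        }
    )
    n_families: int = 8
    females_per_family_per_treatment: int = 4
    pods_per_female: int = 2
    egg_mean_rank1: float = 65.0
    egg_mean_rank2: float = 50.0
    survival24h_prob: dict = field(
        default_factory=lambda: {
            "outbred": 0.92,
            "inbred_fullsib": 0.92,
            "parthenogenetic": 0.5,
        }
    )
    # additive treatment shifts for (development_time days, femur_length mm)
    trait_effects: dict = field(
        default_factory=lambda: {
            "outbred": (0.0, 0.0),
            "inbred_fullsib": (0.5, -0.1),
            "parthenogenetic": (2.0, -0.5),
        }
    )
    dev_time_mean: float = 32.0
    dev_time_sd: float = 3.0
    femur_mean: float = 22.0
    femur_sd: float = 1.0
    female_femur_bonus: float = 2.0  # adult females are the larger sex
    extra_molt_prob: float = 0.15
    extra_molt_dev_delay: float = 5.0
    larval_survival_prob: float = 0.85
    max_offspring_per_pod: int = 15
    egg_distribution: str = "poisson"  # or "negative_binomial"
    nb_dispersion: float = 10.0  # negative-binomial size parameter

    def validate(self) -> None:
        if not (self.B >= 0.0):
            raise ValueError(f"B must be >= 0, got {self.B}")
        _check_prob("baseline_hatch", self.baseline_hatch)
        _check_prob_map("laying_prob", self.laying_prob)
        _check_prob_map("survival24h_prob", self.survival24h_prob)
        _check_prob("extra_molt_prob", self.extra_molt_prob)
        _check_prob("larval_survival_prob", self.larval_survival_prob)
        if not (self.egg_mean_rank1 >= self.egg_mean_rank2 > 0):
            raise ValueError(
                "egg means must satisfy egg_mean_rank1 >= egg_mean_rank2 > 0, "
                f"got {self.egg_mean_rank1}, {self.egg_mean_rank2}"
            )
        for n, v in [
            ("n_families", self.n_families),
            ("females_per_family_per_treatment", self.females_per_family_per_treatment),
            ("pods_per_female", self.pods_per_female),
            ("max_offspring_per_pod", self.max_offspring_per_pod),
        ]:
            if v < 1:
                raise ValueError(f"{n} must be >= 1, got {v}")
        if self.egg_distribution not in ("poisson", "negative_binomial"):
            raise ValueError(
                f"egg_distribution must be 'poisson' or 'negative_binomial', "
                f"got {self.egg_distribution!r}"
            )
        if self.egg_distribution == "negative_binomial" and self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")


@dataclass
class GenotypeSimConfig:
    """Conditions for one population's microsatellite genotype sample."""

    name: str
    n_individuals: int = 30
    n_loci: int = 6
    alleles_per_locus: int = 6
    allele_freqs: "list | None" = None  # per-locus frequency vectors
    F_is: float = 0.0
    missing_rate: float = 0.0

    def resolved_freqs(self) -> list:
        if self.allele_freqs is None:
            k = self.alleles_per_locus
            return [np.full(k, 1.0 / k) for _ in range(self.n_loci)]
        return [np.asarray(f, dtype=float) for f in self.allele_freqs]

    def validate(self) -> None:
        if self.n_individuals < 1 or self.n_loci < 1 or self.alleles_per_locus < 1:
            raise ValueError("n_individuals, n_loci, alleles_per_locus must be >= 1")
        if not (-1.0 < self.F_is < 1.0):
            raise ValueError(f"F_is must lie in (-1, 1), got {self.F_is}")
        _check_prob("missing_rate", self.missing_rate)
        freqs = self.resolved_freqs()
        if len(freqs) != self.n_loci:
            raise ValueError(
                f"allele_freqs has {len(freqs)} loci, expected {self.n_loci}"
            )
        for j, f in enumerate(freqs):
            if (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
                raise ValueError(f"locus {j}: frequencies must be >= 0 and sum to 1")
            if self.F_is < 0.0:
                p_min = f[f > 0].min()
                bound = -p_min / (1.0 - p_min) if p_min < 1.0 else 0.0
                if self.F_is < bound:
                    raise ValueError(
                        f"locus {j}: F_is={self.F_is} below the feasibility bound "
                        f"{bound:.4f} set by the rarest allele (p={p_min:.4f})"
                    )


class ExperimentTables(NamedTuple):
    """Tidy outputs of one simulated experiment."""

    pods: pd.DataFrame
    offspring: pd.DataFrame
    females: pd.DataFrame


def _population_rng(seed: int, name: str) -> np.random.Generator:
    # stable stream per population: master seed + CRC32 of the name
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode("utf-8"))])
    )


def simulate_egg_hatching(
    B: float,
    F: float,
    n_eggs: int,
    rng: np.random.Generator,
    baseline_hatch: float = 1.0,
) -> np.ndarray:
    """Mechanistic per-egg hatching draw; returns a boolean array.

    Each egg draws its lethal count ``k ~ Poisson(B)``; each lethal is
    expressed independently with probability ``F``; the egg hatches iff
    the baseline-viability Bernoulli succeeds and no lethal is
    expressed.
    """
    if n_eggs == 0:
        return np.zeros(0, dtype=bool)
    baseline_ok = rng.random(n_eggs) < baseline_hatch
    if F == 0.0:
        return baseline_ok
    if math.isinf(B):
        return np.zeros(n_eggs, dtype=bool)
    k = rng.poisson(B, size=n_eggs)
    expressed = rng.binomial(k, F)
    return baseline_ok & (expressed == 0)


def _draw_eggs(cfg: PopulationSimConfig, mean: float, rng: np.random.Generator) -> int:
    if cfg.egg_distribution == "poisson":
        return int(rng.poisson(mean))
    size = cfg.nb_dispersion
    return int(rng.negative_binomial(size, size / (size + mean)))


def _offspring_traits(
    cfg: PopulationSimConfig,
    population: str,
    family: str,
    treatment: str,
    n: int,
    id_start: int,
    rng: np.random.Generator,
) -> list:
    dev_shift, femur_shift = cfg.trait_effects[treatment]
    rows = []
    for i in range(n):
        sex = "F" if rng.random() < 0.5 else "M"
        extra = bool(rng.random() < cfg.extra_molt_prob)
        molted = rng.random() < cfg.larval_survival_prob
        if molted:
            dev = (
                cfg.dev_time_mean
                + dev_shift
                + (cfg.extra_molt_dev_delay if extra else 0.0)
                + rng.normal(0.0, cfg.dev_time_sd)
            )
            dev = max(10.0, dev)
            femur = (
                cfg.femur_mean
                + femur_shift
                + (cfg.female_femur_bonus if sex == "F" else 0.0)
                + rng.normal(0.0, cfg.femur_sd)
            )
            rows.append(
                {
                    "population": population,
                    "family": family,
                    "treatment": treatment,
                    "offspring_id": f"{population}_{id_start + i}",
                    "sex": sex,
                    "extra_molt": extra,
                    "development_time": round(dev, 1),
                    "femur_length": round(femur, 2),
                    "survival_days": round(dev, 1),
                    "event": "molted",
                }
            )
        else:
            died_at = float(rng.integers(2, max(3, int(cfg.dev_time_mean))))
            rows.append(
                {
                    "population": population,
                    "family": family,
                    "treatment": treatment,
                    "offspring_id": f"{population}_{id_start + i}",
                    "sex": sex,
                    "extra_molt": extra,
                    "development_time": np.nan,
                    "femur_length": np.nan,
                    "survival_days": died_at,
                    "event": "died",
                }
            )
    return rows


def simulate_experiment(
    configs: Iterable[PopulationSimConfig],
    seed: int,
    include_parthenogenetic_offspring: bool = False,
) -> ExperimentTables:
    """Simulate the full three-treatment breeding experiment.

    Returns tidy pod, offspring, and female tables.  Offspring records
    are produced for the outbred and inbred treatments (the rearing
    design's restriction); set ``include_parthenogenetic_offspring`` to
    also rear parthenogenetic survivors.  Output is fully reproducible
    for a fixed seed and invariant to the order of ``configs``.
    """
    configs = list(configs)
    for cfg in configs:
        cfg.validate()
    names = [c.name for c in configs]
    if len(set(names)) != len(names):
        raise ValueError("population names must be unique")

    pod_rows: list = []
    off_rows: list = []
    female_rows: list = []
    for cfg in configs:
        rng = _population_rng(seed, cfg.name)
        egg_means = [
            cfg.egg_mean_rank1
            if r == 0
            else cfg.egg_mean_rank2
            for r in range(cfg.pods_per_female)
        ]
        n_offspring = 0
        for fam_i in range(cfg.n_families):
            family = f"{cfg.name}_fam{fam_i + 1}"
            for treatment in ("outbred", "inbred_fullsib", "parthenogenetic"):
                F = TREATMENT_F[treatment]
                for fem_i in range(cfg.females_per_family_per_treatment):
                    female_id = f"{family}_{treatment}_f{fem_i + 1}"
                    laid = bool(rng.random() < cfg.laying_prob[treatment])
                    female_rows.append(
                        {
                            "population": cfg.name,
                            "family": family,
                            "female_id": female_id,
                            "treatment": treatment,
                            "laid": laid,
                        }
                    )
                    if not laid:
                        continue
                    for rank, mean in enumerate(egg_means, start=1):
                        n_eggs = _draw_eggs(cfg, mean, rng)
                        hatched = simulate_egg_hatching(
                            cfg.B, F, n_eggs, rng, cfg.baseline_hatch
                        )
                        n_hatched = int(hatched.sum())
                        n_surv = int(
                            rng.binomial(n_hatched, cfg.survival24h_prob[treatment])
                        )
                        pod_rows.append(
                            {
                                "population": cfg.name,
                                "family": family,
                                "female_id": female_id,
                                "treatment": treatment,
                                "pod_rank": rank,
                                "n_eggs": n_eggs,
                                "n_hatched": n_hatched,
                                "n_survived_24h": n_surv,
                            }
                        )
                        rear = treatment in ("outbred", "inbred_fullsib") or (
                            include_parthenogenetic_offspring
                        )
                        if rear and n_surv > 0:
                            n_rear = min(n_surv, cfg.max_offspring_per_pod)
                            off_rows.extend(
                                _offspring_traits(
                                    cfg,
                                    cfg.name,
                                    family,
                                    treatment,
                                    n_rear,
                                    n_offspring + 1,
                                    rng,
                                )
                            )
                            n_offspring += n_rear

    pods = pd.DataFrame(pod_rows, columns=POD_COLUMNS)
    offspring = pd.DataFrame(off_rows, columns=OFFSPRING_COLUMNS)
    females = pd.DataFrame(female_rows, columns=FEMALE_COLUMNS)
    return ExperimentTables(pods=pods, offspring=offspring, females=females)


def simulate_genotypes(config: GenotypeSimConfig, seed: int) -> GenotypeTable:
    """Draw one population's multilocus genotypes at target F_IS.

    For ``F_is >= 0`` each genotype is identical-by-descent (one allele
    drawn and duplicated) with probability ``F_is`` and two independent
    draws otherwise, giving ``E[H_O] = (1 - F_is) * H_E``.  For
    ``F_is < 0`` exact rejection sampling against the target genotype
    distribution ``P(A_iA_i) = p_i^2 + F p_i(1-p_i)``,
    ``P(A_iA_j) = 2 p_i p_j (1-F)`` is used: propose a random-union
    pair, always accept heterozygotes, accept a homozygote for allele i
    with probability ``(1 + F(1-p_i)/p_i) / (1-F)``.
    """
    config.validate()
    rng = _population_rng(seed, config.name)
    n, L = config.n_individuals, config.n_loci
    freqs = config.resolved_freqs()
    F = config.F_is

    arr = np.zeros((n, L, 2), dtype=np.int64)
    for j, p in enumerate(freqs):
        codes = np.arange(1, len(p) + 1)
        if F >= 0.0:
            a1 = rng.choice(codes, size=n, p=p)
            a2 = rng.choice(codes, size=n, p=p)
            ibd = rng.random(n) < F
            a2 = np.where(ibd, a1, a2)
        else:
            accept_hom = np.ones(len(p))
            nz = p > 0
            accept_hom[nz] = (1.0 + F * (1.0 - p[nz]) / p[nz]) / (1.0 - F)
            a1 = np.empty(n, dtype=np.int64)
            a2 = np.empty(n, dtype=np.int64)
            todo = np.arange(n)
            while todo.size:
                c1 = rng.choice(codes, size=todo.size, p=p)
                c2 = rng.choice(codes, size=todo.size, p=p)
                het = c1 != c2
                ok = het | (rng.random(todo.size) < accept_hom[c1 - 1])
                a1[todo[ok]] = c1[ok]
                a2[todo[ok]] = c2[ok]
                todo = todo[~ok]
        arr[:, j, 0] = a1
        arr[:, j, 1] = a2

    if config.missing_rate > 0.0:
        miss = rng.random((n, L)) < config.missing_rate
        arr[miss] = 0

    return GenotypeTable(loci=[f"L{j + 1}" for j in range(L)], populations={config.name: arr})


def merge_genotype_tables(tables: Iterable[GenotypeTable]) -> GenotypeTable:
    """Combine single-population tables sharing one locus set."""
    tables = list(tables)
    loci = tables[0].loci
    pops: dict = {}
    names: dict = {}
    for t in tables:
        if t.loci != loci:
            raise ValueError("all tables must share the same loci")
        for p, arr in t.populations.items():
            if p in pops:
                raise ValueError(f"duplicate population {p!r}")
            pops[p] = arr
            if p in t.individual_names:
                names[p] = t.individual_names[p]
    return GenotypeTable(loci=loci, populations=pops, individual_names=names)


def default_experiment_configs() -> list:
    """Four-population design mirroring the study layout: two old
    colonies with low diversity and low-to-moderate load, one recent
    colony and one field-derived population with high load.  The
    field-derived population's parthenogenetic females essentially
    never produce scorable pods."""
    return [
        replace(PopulationSimConfig(name="England", B=1.1), n_families=8),
        replace(PopulationSimConfig(name="Belgium", B=3.8), n_families=8),
        replace(PopulationSimConfig(name="France", B=3.9), n_families=7),
        replace(
            PopulationSimConfig(name="Mauritania", B=3.9),
            n_families=6,
            laying_prob={
                "outbred": 0.75,
                "inbred_fullsib": 0.75,
                "parthenogenetic": 0.02,
            },
        ),
    ]


def default_genotype_configs() -> list:
    """Genotype samples echoing the study contrast: diverse field and
    recent populations, depauperate old colonies."""
    rich = [  # skewed 8-allele loci, H_E ~ 0.8
        np.array([0.25, 0.2, 0.15, 0.12, 0.1, 0.08, 0.06, 0.04])
    ] * 6
    poor = [np.array([0.55, 0.25, 0.12, 0.08])] * 6  # H_E ~ 0.6
    return [
        GenotypeSimConfig(name="Mauritania", n_individuals=21, n_loci=6,
                          alleles_per_locus=8, allele_freqs=rich, F_is=-0.04),
        GenotypeSimConfig(name="France", n_individuals=22, n_loci=6,
                          alleles_per_locus=8, allele_freqs=rich, F_is=0.07),
        GenotypeSimConfig(name="Belgium", n_individuals=30, n_loci=6,
                          alleles_per_locus=4, allele_freqs=poor, F_is=0.0),
        GenotypeSimConfig(name="England", n_individuals=30, n_loci=6,
                          alleles_per_locus=4, allele_freqs=poor, F_is=0.02),
    ]
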