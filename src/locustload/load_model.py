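"""Poisson lethal-equivalents model of hatching under inbreeding.

The model treats hatching failure as the expression of fully recessive
lethal alleles.  Let ``B`` be the expected number of lethal equivalents
per haploid genome, assumed Poisson-distributed, and let ``F`` be the
inbreeding coefficient of an offspring (the probability that the two
alleles at a locus are identical by descent).  Each lethal carried by
the mother is exposed as a homozygote with probability ``F``, so the
number of expressed lethals is Poisson with mean ``B*F`` and the
probability that an egg carries zero expressed lethals is::

    h(B, F) = exp(-B * F)

``h`` is the hatching rate *relative* to outbred (F = 0) eggs: shared
non-genetic causes of egg death cancel in the ratio.  Fully homozygous
automictic parthenogens have F = 1, full-sib progeny F = 1/4, outbred
progeny F = 0.  Inverting the map at an observed relative hatching rate
gives the classic load estimate ``B = -ln(rel) / F``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TREATMENT_F",
    "ReproductionTreatment",
    "LethalLoadModel",
    "BootstrapResult",
    "expected_relative_hatching",
    "estimate_lethal_equivalents",
    "predict_inbred_relative_hatching",
    "pooled_hatch_rate",
    "pooled_relative_hatching",
    "bootstrap_load_ci",
]

#: Offspring inbreeding coefficient of each reproduction treatment.
#: Automictic (endomitotic) parthenogenesis yields fully homozygous
#: offspring, hence F = 1; full-sib matings give F = 1/4.
TREATMENT_F: Mapping[str, float] = {
    "outbred": 0.0,
    "inbred_fullsib": 0.25,
    "parthenogenetic": 1.0,
}


@dataclass(frozen=True)
class ReproductionTreatment:
    """A named reproduction treatment and the inbreeding coefficient F
    of the offspring it produces."""

    name: str
    F: float

    def __post_init__(self) -> None:
        if self.name not in TREATMENT_F:
            raise ValueError(
                f"unknown treatment {self.name!r}; valid treatments: "
                f"{sorted(TREATMENT_F)}"
            )
        if not math.isclose(self.F, TREATMENT_F[self.name]):
            raise ValueError(
                f"treatment {self.name!r} implies F={TREATMENT_F[self.name]}, "
                f"got F={self.F}"
            )

    @classmethod
    def from_name(cls, name: str) -> "ReproductionTreatment":
        if name not in TREATMENT_F:
            raise ValueError(
                f"unknown treatment {name!r}; valid treatments: "
                f"{sorted(TREATMENT_F)}"
            )
        return cls(name, TREATMENT_F[name])


def _check_F(F: float, *, allow_zero: bool = True) -> None:
    if not (0.0 <= F <= 1.0):
        raise ValueError(f"inbreeding coefficient F must lie in [0, 1], got {F}")
    if not allow_zero and F == 0.0:
        raise ValueError(
            "F = 0: genetic load is not identifiable from non-inbred offspring"
        )


def expected_relative_hatching(B: float, F: float) -> float:
    """Hatching rate relative to outbred eggs, ``exp(-B * F)``.

    Parameters
    ----------
    B : float
        Lethal equivalents per haploid genome, >= 0.  ``math.inf`` is a
        valid load (no inbred egg ever hatches).
    F : float
        Inbreeding coefficient of the offspring, in [0, 1].
    """
    if not (B >= 0.0):  # catches negatives and NaN
        raise ValueError(f"lethal equivalents B must be >= 0, got {B}")
    _check_F(F)
    if F == 0.0:
        return 1.0
    if math.isinf(B):
        return 0.0
    return math.exp(-B * F)


@dataclass(frozen=True)
class LethalLoadModel:
    """Estimated genetic load of a population.

    Attributes
    ----------
    B : float
        Lethal equivalents per haploid genome (>= 0, possibly ``inf``).
    clamped : bool
        True when the observed relative hatching exceeded 1 (sampling
        noise) and the estimate was clamped to B = 0.
    """

    B: float
    clamped: bool = False

    def __post_init__(self) -> None:
        if not (self.B >= 0.0):
            raise ValueError(f"lethal equivalents B must be >= 0, got {self.B}")

    def relative_hatching(self, F: float) -> float:
        return expected_relative_hatching(self.B, F)


def estimate_lethal_equivalents(rel: float, F: float) -> LethalLoadModel:
    """Invert the hatching map: ``B = -ln(rel) / F``.

    ``rel`` is the hatching rate of offspring with inbreeding
    coefficient ``F`` relative to outbred offspring.  ``rel == 0``
    yields infinite load; ``rel >= 1`` (possible through sampling
    noise) is clamped to B = 0 and flagged.
    """
    _check_F(F, allow_zero=False)
    if not (rel >= 0.0):
        raise ValueError(f"relative hatching must be >= 0, got {rel}")
    if rel == 0.0:
        return LethalLoadModel(math.inf)
    if rel >= 1.0:
        return LethalLoadModel(0.0, clamped=rel > 1.0)
    return LethalLoadModel(-math.log(rel) / F)


def predict_inbred_relative_hatching(model: "LethalLoadModel | float") -> float:
    """Predicted hatching of full-sib inbred offspring relative to
    outbred offspring, ``exp(-B / 4)``."""
    B = model.B if isinstance(model, LethalLoadModel) else float(model)
    return expected_relative_hatching(B, TREATMENT_F["inbred_fullsib"])


# ---------------------------------------------------------------------------
# observed rates and bootstrap uncertainty
# ---------------------------------------------------------------------------


def _treatment_counts(
    pods: pd.DataFrame, treatment: str
) -> tuple[np.ndarray, np.ndarray]:
    sub = pods.loc[pods["treatment"] == treatment]
    return (
        sub["n_eggs"].to_numpy(dtype=np.int64),
        sub["n_hatched"].to_numpy(dtype=np.int64),
    )


def pooled_hatch_rate(eggs: np.ndarray, hatched: np.ndarray) -> float:
    """Total hatched over total eggs (egg-weighted pooling over pods)."""
    total = int(np.sum(eggs))
    if total == 0:
        return math.nan
    return float(np.sum(hatched)) / total


def pooled_relative_hatching(
    pods: pd.DataFrame,
    treatment: str = "parthenogenetic",
    reference: str = "outbred",
) -> float:
    """Pooled hatch rate of ``treatment`` divided by that of ``reference``.

    ``pods`` holds one population's pod records with columns
    ``treatment``, ``n_eggs``, ``n_hatched``.
    """
    fe, fh = _treatment_counts(pods, treatment)
    re_, rh = _treatment_counts(pods, reference)
    rf = pooled_hatch_rate(fe, fh)
    rr = pooled_hatch_rate(re_, rh)
    if math.isnan(rf) or math.isnan(rr) or rr == 0.0:
        return math.nan
    return rf / rr


@dataclass(frozen=True)
class BootstrapResult:
    """Point estimate and percentile bootstrap interval for the load B."""

    b_point: float
    ci_low: float
    ci_high: float
    rel_point: float
    n_boot: int
    n_discarded: int

    @property
    def interval(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)


def _rel_to_B(rel: np.ndarray, F: float) -> np.ndarray:
    B = np.full(rel.shape, np.inf)
    pos = rel > 0.0
    with np.errstate(divide="ignore"):
        B[pos] = -np.log(rel[pos]) / F
    np.clip(B, 0.0, None, out=B)  # rel >= 1 clamps to 0
    return B


def bootstrap_load_ci(
    pods: pd.DataFrame,
    treatment_pair: tuple[str, str] = ("parthenogenetic", "outbred"),
    n_boot: int = 1000,
    seed: "int | None" = None,
    F: "float | None" = None,
) -> BootstrapResult:
    """Percentile bootstrap (2.5%, 97.5%) for the load estimate.

    Pods are resampled with replacement *within* each treatment of
    ``treatment_pair = (focal, reference)``; each replicate recomputes
    the pooled relative hatching and B = -ln(rel)/F.  Replicates with
    zero reference hatchlings (or no eggs in either treatment) are
    discarded and counted; more than 50% discarded raises.

    ``F`` defaults to the focal treatment's inbreeding coefficient.
    """
    focal, reference = treatment_pair
    if F is None:
        F = TREATMENT_F.get(focal)
        if F is None:
            raise ValueError(
                f"unknown treatment {focal!r}: pass F explicitly or use one of "
                f"{sorted(TREATMENT_F)}"
            )
    _check_F(F, allow_zero=False)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")

    fe, fh = _treatment_counts(pods, focal)
    re_, rh = _treatment_counts(pods, reference)
    if fe.sum() == 0 or re_.sum() == 0:
        raise ValueError(
            f"need at least one pod with eggs in both {focal!r} and {reference!r}"
        )

    rel_point = pooled_relative_hatching(pods, focal, reference)
    b_point = estimate_lethal_equivalents(rel_point, F).B if rel_point == rel_point else math.nan

    rng = np.random.default_rng(seed)
    idx_f = rng.integers(0, len(fe), size=(n_boot, len(fe)))
    idx_r = rng.integers(0, len(re_), size=(n_boot, len(re_)))
    eggs_f = fe[idx_f].sum(axis=1).astype(float)
    hatch_f = fh[idx_f].sum(axis=1).astype(float)
    eggs_r = re_[idx_r].sum(axis=1).astype(float)
    hatch_r = rh[idx_r].sum(axis=1).astype(float)

    valid = (eggs_f > 0) & (eggs_r > 0) & (hatch_r > 0)
    n_discarded = int(n_boot - valid.sum())
    if n_discarded > n_boot / 2:
        raise RuntimeError(
            f"{n_discarded}/{n_boot} bootstrap replicates discarded "
            f"(zero {reference!r} hatchlings); data too sparse for a bootstrap CI"
        )

    rel = (hatch_f[valid] / eggs_f[valid]) / (hatch_r[valid] / eggs_r[valid])
    B = _rel_to_B(rel, F)
    if np.isinf(B).any():
        # interpolation is undefined across +inf; take the nearest order stat
        lo, hi = np.percentile(B, [2.5, 97.5], method="nearest")
    else:
        lo, hi = np.percentile(B, [2.5, 97.5])
    return BootstrapResult(
        b_point=b_point,
        ci_low=float(lo),
        ci_high=float(hi),
        rel_point=rel_point,
        n_boot=n_boot,
        n_discarded=n_discarded,
    )
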