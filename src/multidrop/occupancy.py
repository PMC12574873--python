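"""Poisson occupancy model for droplet encapsulation with sample multiplexing.

Cell loading into micro-fluidic droplets is modelled as a Poisson process with
occupancy parameter ``lam`` (mean cells per droplet, empties included).  With
``D`` hashed samples pooled in equal proportions, only multiplets whose member
cells span two or more samples are visible to cell hashing, so the observed
inter-sample multiplet rate ``f_obs`` underestimates the true multiplet rate
``f_mult``.  The model links the two through the theoretical inter-sample
multiplet fraction ``f_diff``:

    f_obs = f_mult(lam) * f_diff(lam, D)

Solving this for ``lam`` given a measured ``f_obs`` yields an effective
occupancy, from which the true multiplet rate among non-empty droplets follows
as ``f_mult = f_obs / f_diff``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "OccupancySolution",
    "ChemistryHeuristic",
    "occupancy_pmf",
    "true_multiplet_rate",
    "intersample_fraction",
    "observed_rate",
    "solve_lambda",
    "estimate_true_rate",
    "heuristic_rate",
    "observed_intersample_rate",
]

# Below this occupancy the closed form for f_diff suffers catastrophic
# cancellation (both numerator and denominator are O(lam^2)); a direct term
# sum of the series is exact there and converges in a handful of terms.
_SERIES_SWITCH = 1e-3


@dataclass(frozen=True)
class OccupancySolution:
    """Fitted occupancy model for one dataset.

    Attributes
    ----------
    lambda_hat
        Effective mean cells per droplet (empties included).
    D
        Number of equally represented hashed samples.
    f_obs
        Observed inter-sample multiplet rate (fraction of non-empty droplets).
    f_diff
        Theoretical fraction of multiplets that span >= 2 samples.
    f_mult
        Estimated true multiplet rate among non-empty droplets.
    """

    lambda_hat: float
    D: int
    f_obs: float
    f_diff: float
    f_mult: float

    def __post_init__(self) -> None:
        if abs(self.f_mult * self.f_diff - self.f_obs) > 1e-8:
            raise ValidationError(
                "inconsistent solution: f_mult * f_diff != f_obs "
                f"({self.f_mult} * {self.f_diff} != {self.f_obs})"
            )
        if self.f_mult < self.f_obs - 1e-12:
            raise ValidationError("f_mult must be >= f_obs (f_diff <= 1)")


@dataclass(frozen=True)
class ChemistryHeuristic:
    """Vendor rule of thumb: multiplet percentage added per 1,000 non-empty droplets.

    The default coefficient of 0.8 (percent per 1,000 droplets) is shared by
    the common 10X chemistries; it is configurable because the vendor tables
    differ slightly between chemistry versions.
    """

    chemistry: str = "3p_v3"
    rate_per_1000: float = 0.8

    def __post_init__(self) -> None:
        if not self.rate_per_1000 > 0:
            raise ValidationError("rate_per_1000 must be positive")


def _check_lambda(lam: float) -> float:
    lam = float(lam)
    if not math.isfinite(lam) or lam <= 0:
        raise ValidationError(f"occupancy parameter must be positive, got {lam!r}")
    return lam


def occupancy_pmf(k: int, lam: float) -> float:
    """P(droplet contains exactly ``k`` cells) = exp(-lam) lam^k / k!."""
    lam = _check_lambda(lam)
    if k < 0 or k != int(k):
        raise ValidationError(f"cell count k must be a nonnegative integer, got {k!r}")
    k = int(k)
    return math.exp(-lam + k * math.log(lam) - math.lgamma(k + 1))


def true_multiplet_rate(lam: float) -> float:
    """Fraction of non-empty droplets holding >= 2 cells: 1 - lam e^-lam / (1 - e^-lam)."""
    lam = _check_lambda(lam)
    # 1 - e^-lam == -expm1(-lam), stable for small lam
    return 1.0 - lam * math.exp(-lam) / (-math.expm1(-lam))


def _multiplet_series(lam: float, D: float) -> tuple[float, float]:
    """Return (sum_{k>=2} P(k) D^{-(k-1)}, sum_{k>=2} P(k)) by direct term summation."""
    num = 0.0
    den = 0.0
    term = math.exp(-lam) * lam * lam / 2.0  # P(2)
    ratio = lam / D
    num_term = term / D
    k = 2
    while (term > 1e-18 * max(den, 1e-300) or k < 4) and k < 500:
        den += term
        num += num_term
        k += 1
        term *= lam / k
        num_term *= ratio / k
    return num, den


def intersample_fraction(lam: float, D: int) -> float:
    """Theoretical fraction of multiplets containing cells from >= 2 samples.

    Equal sample proportions are assumed: a k-cell droplet is single-sample
    with probability D^-(k-1), so

        f_diff = sum_{k>=2} P(k) (1 - D^-(k-1)) / sum_{k>=2} P(k),

    which has the closed form
    1 - D e^-lam (e^{lam/D} - 1 - lam/D) / (1 - e^-lam - lam e^-lam).
    """
    lam = _check_lambda(lam)
    if D < 1 or D != int(D):
        raise ValidationError(f"sample count D must be an integer >= 1, got {D!r}")
    D = int(D)
    if D == 1:
        return 0.0
    if lam < _SERIES_SWITCH:
        num, den = _multiplet_series(lam, D)
        return 1.0 - num / den
    den = 1.0 - math.exp(-lam) - lam * math.exp(-lam)
    num = D * math.exp(-lam) * (math.exp(lam / D) - 1.0 - lam / D)
    return 1.0 - num / den


def observed_rate(lam: float, D: int) -> float:
    """Expected inter-sample multiplet rate f_obs = f_mult(lam) * f_diff(lam, D)."""
    return true_multiplet_rate(lam) * intersample_fraction(lam, D)


def solve_lambda(f_obs: float, D: int, tol: float = 1e-10) -> float:
    """Numerically invert f_obs = f_mult(lam) f_diff(lam, D) for lam.

    Bracketed bisection: the upper bracket is doubled from 1 until the model
    rate exceeds ``f_obs`` (the rate is strictly increasing in lam for D >= 2),
    then bisected until the residual |observed_rate(lam) - f_obs| <= ``tol``.
    """
    f_obs = float(f_obs)
    if not 0.0 < f_obs < 1.0:
        raise ValidationError(f"f_obs must lie in (0, 1), got {f_obs!r}")
    if D < 2 or D != int(D):
        raise ValidationError(
            f"D must be an integer >= 2 (a single sample makes f_obs uninformative), got {D!r}"
        )
    D = int(D)
    lo = 1e-8
    hi = 1.0
    while observed_rate(hi, D) < f_obs:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - f_obs < 1 guarantees a bracket
            raise ValidationError(f"no bracket found for f_obs={f_obs}")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        resid = observed_rate(mid, D) - f_obs
        if abs(resid) <= tol:
            return mid
        if resid < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def estimate_true_rate(f_obs: float, D: int) -> OccupancySolution:
    """Estimate the true multiplet rate from the observed inter-sample rate.

    Solves for the effective occupancy ``lambda_hat``, evaluates the
    inter-sample multiplet fraction at that occupancy, and reports
    ``f_mult = f_obs / f_diff``.
    """
    lam = solve_lambda(f_obs, D)
    f_diff = intersample_fraction(lam, D)
    return OccupancySolution(
        lambda_hat=lam, D=int(D), f_obs=float(f_obs), f_diff=f_diff, f_mult=float(f_obs) / f_diff
    )


def heuristic_rate(
    n_nonempty_droplets: int, chem: ChemistryHeuristic | None = None
) -> float:
    """Vendor heuristic multiplet rate: linear in the number of non-empty droplets.

    Returns ``(n / 1000) * rate_per_1000 / 100`` as a fraction, clipped to [0, 1].
    """
    if chem is None:
        chem = ChemistryHeuristic()
    if n_nonempty_droplets < 0:
        raise ValidationError("droplet count must be nonnegative")
    rate = (n_nonempty_droplets / 1000.0) * chem.rate_per_1000 / 100.0
    return min(max(rate, 0.0), 1.0)


def observed_intersample_rate(droplets: Union["DropletTable", Iterable]) -> float:
    """Fraction of non-empty droplets labelled multiplet by cell hashing.

    Accepts a :class:`~multidrop.simulate.DropletTable` or any boolean label
    vector (True = hashing multiplet).
    """
    from .simulate import DropletTable, hashing_labels  # cycle-free at call time

    if isinstance(droplets, DropletTable):
        labels = hashing_labels(droplets)
    else:
        labels = pd.Series(list(droplets))
        if labels.dtype == object:
            labels = labels.map({"multiplet": True, "singlet": False, True: True, False: False})
            if labels.isna().any():
                raise ValidationError("labels must be boolean or 'multiplet'/'singlet'")
        labels = labels.astype(bool)
    n = len(labels)
    if n == 0:
        raise ValidationError("need at least one droplet")
    return float(np.count_nonzero(labels)) / n
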