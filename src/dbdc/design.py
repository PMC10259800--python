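"""Survey design arithmetic.

Finite-population sample size (Krejcie & Morgan 1970), proportional
allocation of the sample across strata by largest-remainder (Hamilton)
apportionment, the defensive doubling applied before fieldwork, and the
fixed-rate MYR -> USD conversion used in reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

__all__ = [
    "SampleDesign",
    "krejcie_morgan",
    "allocate_proportional",
    "double_sample",
    "myr_to_usd",
    "plan_sample",
    "SELANGOR_DISTRICTS",
]

#: District populations (thousands) of Selangor used as allocation strata.
SELANGOR_DISTRICTS: tuple[tuple[str, float], ...] = (
    ("sabak bernam", 126.1),
    ("kuala selangor", 251.2),
    ("klang", 1025.1),
    ("kuala langat", 270.1),
    ("petaling", 2157.0),
    ("sepang", 256.9),
    ("ulu langat", 1370.2),
    ("gombak", 815.2),
    ("ulu selangor", 237.6),
)


def _round_half_up(x: float, digits: int = 0) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def krejcie_morgan(N: int, p: float = 0.5, e: float = 0.05, z: float = 1.96) -> int:
    """Required sample size s = [z^2 p(1-p)/e^2] / [1 + z^2 p(1-p)/(e^2 N)].

    Rounded half-up to the nearest integer and capped at the population size.
    With N = 6,509,400, p = 0.5, e = 0.05, z = 1.96 this gives 384.
    """
    if N < 1:
        raise ValueError("population size must be >= 1")
    if not 0 < p < 1:
        raise ValueError("proportion p must lie in (0, 1)")
    if not 0 < e < 1:
        raise ValueError("margin of error e must lie in (0, 1)")
    if z <= 0:
        raise ValueError("z-score must be positive")
    core = z * z * p * (1 - p) / (e * e)
    s = core / (1 + core / N)
    return min(int(_round_half_up(s)), int(N))


def allocate_proportional(populations: Sequence[float], total_n: int) -> list[int]:
    """Largest-remainder apportionment of ``total_n`` by population share.

    Each stratum receives the floor of its exact quota; leftover units go to
    the strata with the largest fractional remainders (ties broken toward the
    larger population, then the earlier stratum).  The result always sums
    exactly to ``total_n`` and is invariant to rescaling the populations.
    """
    pops = [float(v) for v in populations]
    if not pops:
        raise ValueError("empty strata list")
    if any(v <= 0 for v in pops):
        raise ValueError("populations must be positive")
    if total_n < 0:
        raise ValueError("total_n must be non-negative")
    total = sum(pops)
    quotas = [total_n * v / total for v in pops]
    alloc = [int(q) for q in quotas]
    leftover = total_n - sum(alloc)
    order = sorted(
        range(len(pops)),
        key=lambda i: (-(quotas[i] - alloc[i]), -pops[i], i),
    )
    for i in order[:leftover]:
        alloc[i] += 1
    return alloc


def double_sample(n: int) -> int:
    """Double the planned sample to absorb incomplete responses."""
    if n < 0:
        raise ValueError("sample size must be non-negative")
    return 2 * n


def myr_to_usd(amount: float, rate: float = 11.10 / 50) -> float:
    """Convert MYR to USD at a fixed rate, rounded half-up to 2 decimals.

    The default rate 11.10/50 = 0.222 is the November 2022 rate under which
    MYR 50 equals US$ 11.10.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if amount < 0:
        raise ValueError("negative amount")
    return float(
        (Decimal(repr(amount)) * Decimal(repr(rate))).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


@dataclass(frozen=True)
class SampleDesign:
    """A stratified sampling plan: strata, total size, per-stratum allocation."""

    strata: tuple[tuple[str, float], ...]
    total_n: int
    allocations: tuple[int, ...]

    def __post_init__(self) -> None:
        if sum(self.allocations) != self.total_n:
            raise ValueError("allocations must sum to total_n")
        if any(a < 0 for a in self.allocations):
            raise ValueError("allocations must be non-negative")

    @property
    def doubled_n(self) -> int:
        return double_sample(self.total_n)

    @property
    def doubled_allocations(self) -> tuple[int, ...]:
        return tuple(double_sample(a) for a in self.allocations)


def plan_sample(
    strata: Sequence[tuple[str, float]] = SELANGOR_DISTRICTS,
    population: float | None = None,
    p: float = 0.5,
    e: float = 0.05,
    z: float = 1.96,
) -> SampleDesign:
    """Size the sample for the summed stratum population and allocate it.

    ``population`` overrides the population total used in the size formula
    (the stratum figures may be in thousands, as for the Selangor defaults).
    """
    pops = [v for _, v in strata]
    N = population if population is not None else sum(pops)
    n = krejcie_morgan(int(round(N)), p=p, e=e, z=z)
    return SampleDesign(tuple(strata), n, tuple(allocate_proportional(pops, n)))
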