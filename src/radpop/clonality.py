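"""Detection of asexually propagated (grafted) plants via conserved heterozygosity.

Two individuals propagated from the same tree share a genotype, so sites
heterozygous in one are heterozygous in the other except where genotyping
error or allelic dropout intervenes.  The pair statistic is the fraction of
conserved heterozygous sites: among sites called in both individuals where
at least one is heterozygous, the fraction where both are.  Grafted pairs
sit roughly at 50% and above with de novo RAD genotyping; unrelated pairs
stay below (the fraction is bounded by 1/3 in expectation for independent
Hardy–Weinberg individuals).  Pairs at or above a threshold are linked;
connected components of that graph are clonal groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, pairwise_shared_sites

#: Inclusive decision threshold, anchored at the lowest confirmed graft pair (48.5%).
DEFAULT_THRESHOLD = 0.485


class UndefinedFractionError(ValueError):
    """No qualifying site for the pair: conserved-het fraction undefined."""


def round_percent(fraction: float, decimals: int = 1) -> float:
    """Percentage rounded half-up (62.85 -> 62.9, not banker's 62.8)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(fraction * 100)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PairHetConservation:
    """Conserved-heterozygosity counts for one pair of individuals."""

    sample_a: str
    sample_b: str
    n_denominator: int
    n_conserved_het: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_conserved_het <= self.n_denominator:
            raise ValueError("conserved count exceeds denominator")

    @property
    def fraction(self) -> float:
        if self.n_denominator == 0:
            raise UndefinedFractionError(
                f"no qualifying sites for pair ({self.sample_a}, {self.sample_b})"
            )
        return self.n_conserved_het / self.n_denominator

    @property
    def percent(self) -> float:
        return round_percent(self.fraction)


@dataclass(frozen=True)
class ClonalityCall:
    pair: tuple[str, str]
    fraction: float
    threshold: float
    verdict: str  # "clonal" | "non-clonal"


def conserved_het(
    gm: GenotypeMatrix, a: str, b: str, denominator: str = "either_het"
) -> PairHetConservation:
    """Conserved-heterozygosity statistic for a pair.

    Restricts first to sites called in both individuals.  With the default
    ``denominator="either_het"`` the denominator is the number of those
    sites where at least one of the pair is heterozygous and the numerator
    the number where both are; ``denominator="co_called"`` divides by all
    co-called sites instead (sensitivity-analysis reading).
    """
    sub = pairwise_shared_sites(gm, a, b)
    ga, gb = sub.calls[0], sub.calls[1]
    both_het = int(((ga == 1) & (gb == 1)).sum())
    if denominator == "either_het":
        denom = int(((ga == 1) | (gb == 1)).sum())
    elif denominator == "co_called":
        denom = sub.n_sites
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    return PairHetConservation(
        sample_a=a, sample_b=b, n_denominator=denom, n_conserved_het=both_het
    )


def classify_pair(
    phc: PairHetConservation, threshold: float = DEFAULT_THRESHOLD
) -> ClonalityCall:
    """Clonal iff fraction >= threshold (inclusive boundary)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    frac = phc.fraction  # raises UndefinedFractionError when denominator is 0
    verdict = "clonal" if frac >= threshold else "non-clonal"
    return ClonalityCall(
        pair=(phc.sample_a, phc.sample_b),
        fraction=frac,
        threshold=threshold,
        verdict=verdict,
    )


def _pairwise_counts(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised numerators / denominators for every sample pair."""
    het = (gm.calls == 1).astype(np.int64)
    called = (gm.calls != MISSING).astype(np.int64)
    nonhet_called = called - het
    both_het = het @ het.T
    co_called = called @ called.T
    neither_het = nonhet_called @ nonhet_called.T
    return both_het, co_called - neither_het


def pairwise_table(
    gm: GenotypeMatrix,
    samples: list[str] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Long-format conserved-heterozygosity table for all pairs.

    Columns: sample_a, sample_b, n_denominator, n_conserved_het, percent,
    verdict.  Pairs with an undefined fraction get verdict "undefined".
    """
    sub = gm if samples is None else gm.take_samples(list(samples))
    num, den = _pairwise_counts(sub)
    rows = []
    for i in range(sub.n_samples):
        for j in range(i + 1, sub.n_samples):
            d, n = int(den[i, j]), int(num[i, j])
            if d == 0:
                verdict, pct = "undefined", float("nan")
            else:
                pct = round_percent(n / d)
                verdict = "clonal" if n / d >= threshold else "non-clonal"
            rows.append(
                {
                    "sample_a": sub.samples[i],
                    "sample_b": sub.samples[j],
                    "n_denominator": d,
                    "n_conserved_het": n,
                    "percent": pct,
                    "verdict": verdict,
                }
            )
    return pd.DataFrame(rows)


def clonal_clusters(
    gm: GenotypeMatrix,
    samples: list[str] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[list[str]]:
    """Partition samples into clonal groups by transitive closure.

    Every pair at or above the threshold contributes an edge; connected
    components are clonal groups (singletons = non-clonal individuals).
    Components are listed sorted by first member id.  Pairs with undefined
    fractions are skipped with a warning.
    """
    sub = gm if samples is None else gm.take_samples(list(samples))
    if sub.n_samples < 2:
        raise ValueError("need at least 2 samples")
    num, den = _pairwise_counts(sub)
    n = sub.n_samples
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    n_undefined = 0
    for i in range(n):
        for j in range(i + 1, n):
            if den[i, j] == 0:
                n_undefined += 1
                continue
            if num[i, j] / den[i, j] >= threshold:
                parent[find(i)] = find(j)
    if n_undefined:
        warnings.warn(
            f"{n_undefined} pair(s) had no qualifying sites; edges skipped",
            stacklevel=2,
        )
    comps: dict[int, list[str]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(sub.samples[i])
    return sorted((sorted(c) for c in comps.values()), key=lambda c: c[0])
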