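"""Population statistics: heterozygosity/Fis, Weir–Cockerham Fst, f3/f4.

Fst is the Weir & Cockerham (1984) theta: per-site variance components
a (between populations), b (between individuals within populations) and
c (within individuals), combined genome-wide as a ratio of sums,
sum(a) / sum(a + b + c).  Negative estimates are reported as-is.

f3(A; B, C) = E[(a - b)(a - c)] and f4(A, B; C, D) = E[(a - b)(c - d)]
over site allele frequencies, following the Patterson/Reich definitions.
f3 subtracts the finite-sample bias term hhat_A / n_A per site, with
hhat_A the unbiased estimate of p(1-p) in the target and n_A its allele
count — without it small target samples push f3 upward and mask
admixture.  Standard errors come from a weighted delete-one-block
jackknife over consecutive SNP blocks (default 500 SNPs), which absorbs
local correlation along the genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

DEFAULT_BLOCK_SIZE = 500


class PopulationMap(dict):
    """Mapping sample id -> population label, with simple helpers."""

    def populations(self) -> list[str]:
        seen: list[str] = []
        for pop in self.values():
            if pop not in seen:
                seen.append(pop)
        return seen

    def members(self, pop: str) -> list[str]:
        return [s for s, p in self.items() if p == pop]

    @classmethod
    def from_table(cls, path: str) -> "PopulationMap":
        df = pd.read_csv(path, sep=None, engine="python")
        return cls(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


@dataclass
class PopFreqs:
    """Per-population allele frequencies and call counts, per site."""

    pops: list[str]
    freq: np.ndarray  # n_pops x n_sites alt-allele frequency (nan if no calls)
    n_called: np.ndarray  # n_pops x n_sites called individuals
    n_het: np.ndarray  # n_pops x n_sites heterozygous individuals

    def index(self, pop: str) -> int:
        try:
            return self.pops.index(pop)
        except ValueError:
            raise KeyError(f"unknown population {pop!r}") from None


@dataclass(frozen=True)
class FStatResult:
    kind: str  # "f3" | "f4"
    pops: tuple[str, ...]
    estimate: float
    se: float  # nan when fewer than 2 blocks
    z: float  # estimate / se
    block_size: int
    n_blocks: int
    n_sites: int


def pop_allele_freqs(gm: GenotypeMatrix, pm: PopulationMap) -> PopFreqs:
    """Alternate-allele frequency and call counts per population per site.

    Frequency = alt-allele count / (2 x non-missing individuals); sites with
    zero calls in a population carry nan and are excluded from any pairwise
    statistic involving that population.
    """
    pops = pm.populations()
    sample_set = set(gm.samples)
    for pop in pops:
        members = [s for s in pm.members(pop) if s in sample_set]
        if not members:
            raise ValueError(f"population {pop!r} has no samples in the matrix")
    freq = np.full((len(pops), gm.n_sites), np.nan)
    n_called = np.zeros((len(pops), gm.n_sites), dtype=np.int64)
    n_het = np.zeros((len(pops), gm.n_sites), dtype=np.int64)
    for k, pop in enumerate(pops):
        rows = [gm.sample_index(s) for s in pm.members(pop) if s in sample_set]
        calls = gm.calls[rows]
        called = calls != MISSING
        nc = called.sum(axis=0)
        alt = np.where(called, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[k] = np.where(nc > 0, alt / (2.0 * np.maximum(nc, 1)), np.nan)
        n_called[k] = nc
        n_het[k] = (calls == 1).sum(axis=0)
    return PopFreqs(pops=pops, freq=freq, n_called=n_called, n_het=n_het)


def heterozygosity_fis(gm: GenotypeMatrix, pm: PopulationMap) -> pd.DataFrame:
    """Per-population observed/expected heterozygosity and Fis.

    Per polymorphic site: Ho = heterozygote fraction among called
    individuals, He = 2p(1-p) * 2n/(2n-1) (small-sample unbiased).
    Fis = 1 - mean(Ho)/mean(He) over sites polymorphic in the population
    (ratio of means).  A population with no polymorphic site gets nan.
    """
    pf = pop_allele_freqs(gm, pm)
    rows = []
    for k, pop in enumerate(pf.pops):
        n = pf.n_called[k].astype(float)
        p = pf.freq[k]
        ok = (n >= 2) & np.isfinite(p) & (p > 0) & (p < 1)
        if not ok.any():
            rows.append({"population": pop, "n": len(pm.members(pop)),
                         "Ho": np.nan, "He": np.nan, "Fis": np.nan})
            continue
        ho = pf.n_het[k][ok] / n[ok]
        he = 2.0 * p[ok] * (1.0 - p[ok]) * (2.0 * n[ok] / (2.0 * n[ok] - 1.0))
        mean_ho, mean_he = float(ho.mean()), float(he.mean())
        rows.append(
            {
                "population": pop,
                "n": len(pm.members(pop)),
                "Ho": mean_ho,
                "He": mean_he,
                "Fis": 1.0 - mean_ho / mean_he,
            }
        )
    return pd.DataFrame(rows).set_index("population")


def _wc_components(
    pf: PopFreqs, i: int, j: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir–Cockerham (1984) a, b, c for one population pair.

    Sites need at least one called individual in each population and a
    mean sample size above one; others return nan components.
    """
    n1, n2 = pf.n_called[i].astype(float), pf.n_called[j].astype(float)
    p1, p2 = pf.freq[i], pf.freq[j]
    h1 = np.divide(pf.n_het[i], n1, out=np.zeros_like(n1), where=n1 > 0)
    h2 = np.divide(pf.n_het[j], n2, out=np.zeros_like(n2), where=n2 > 0)
    r = 2.0
    usable = (n1 >= 1) & (n2 >= 1) & ((n1 + n2) / 2.0 > 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (n1 + n2) - (n1**2 + n2**2) / (n1 + n2)  # (r*nbar - sum n^2/(r nbar))/(r-1)
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - s2 * (r - 1.0) / r
            - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
    for arr in (a, b, c):
        arr[~usable] = np.nan
    return a, b, c


def wc_fst(pf: PopFreqs, pop1: str, pop2: str) -> float:
    """Genome-wide Weir–Cockerham theta for one pair: sum(a)/sum(a+b+c)."""
    i, j = pf.index(pop1), pf.index(pop2)
    a, b, c = _wc_components(pf, i, j)
    ok = np.isfinite(a)
    denom = np.nansum(a[ok] + b[ok] + c[ok])
    if not ok.any() or denom == 0:
        return float("nan")
    return float(np.nansum(a[ok]) / denom)


def pairwise_fst(gm: GenotypeMatrix, pm: PopulationMap) -> pd.DataFrame:
    """Symmetric matrix of pairwise Weir–Cockerham Fst estimates."""
    pf = pop_allele_freqs(gm, pm)
    pops = pf.pops
    out = pd.DataFrame(np.nan, index=pops, columns=pops, dtype=float)
    for i, p1 in enumerate(pops):
        for p2 in pops[i + 1 :]:
            theta = wc_fst(pf, p1, p2)
            out.loc[p1, p2] = out.loc[p2, p1] = theta
    return out


def _block_jackknife(
    values: np.ndarray, block_size: int
) -> tuple[float, float, int, int]:
    """Weighted delete-one-block jackknife of a mean over sites.

    ``values`` holds per-site contributions with nan for unusable sites;
    blocks are consecutive runs of ``block_size`` entries in site order
    (trailing partial block kept), weighted by their usable-site counts.
    Returns (estimate, se, n_blocks, n_usable_sites); se is nan with fewer
    than 2 non-empty blocks.
    """
    if block_size < 1:
        raise ValueError("block size must be >= 1")
    usable = np.isfinite(values)
    n_tot = int(usable.sum())
    if n_tot == 0:
        return float("nan"), float("nan"), 0, 0
    est = float(np.nanmean(values))
    starts = range(0, len(values), block_size)
    loo, weights = [], []
    total = np.nansum(values)
    for s in starts:
        blk = values[s : s + block_size]
        m_j = int(np.isfinite(blk).sum())
        if m_j == 0:
            continue
        loo.append((total - np.nansum(blk)) / (n_tot - m_j) if n_tot > m_j else np.nan)
        weights.append(m_j)
    g = len(loo)
    if g < 2 or not np.isfinite(loo).all():
        return est, float("nan"), g, n_tot
    loo = np.asarray(loo)
    h = n_tot / np.asarray(weights, dtype=float)  # inverse relative block weight
    tau = h * est - (h - 1.0) * loo
    theta_j = float(g * est - np.sum((1.0 - 1.0 / h) * loo))
    var = float(np.sum((tau - theta_j) ** 2 / (h - 1.0)) / g)
    return est, float(np.sqrt(var)), g, n_tot


def _fstat_result(
    kind: str, pops: tuple[str, ...], values: np.ndarray, block_size: int
) -> FStatResult:
    est, se, g, n_sites = _block_jackknife(values, block_size)
    z = est / se if np.isfinite(se) and se > 0 else float("nan")
    return FStatResult(
        kind=kind, pops=pops, estimate=est, se=se, z=z,
        block_size=block_size, n_blocks=g, n_sites=n_sites,
    )


def f3(
    pf: PopFreqs,
    target: str,
    source1: str,
    source2: str,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> FStatResult:
    """Patterson f3(target; source1, source2) with jackknife SE.

    Significantly negative f3 indicates the target is admixed between
    populations related to the two sources.
    """
    if target in (source1, source2):
        raise ValueError("f3 target must differ from both sources")
    ia, ib, ic = pf.index(target), pf.index(source1), pf.index(source2)
    a, b, c = pf.freq[ia], pf.freq[ib], pf.freq[ic]
    n_alleles = 2.0 * pf.n_called[ia]
    with np.errstate(invalid="ignore", divide="ignore"):
        # unbiased p(1-p) in the target, divided by its allele count
        correction = a * (1.0 - a) / np.maximum(n_alleles - 1.0, 1.0)
        vals = (a - b) * (a - c) - correction
    vals[(n_alleles < 2) | ~np.isfinite(a) | ~np.isfinite(b) | ~np.isfinite(c)] = np.nan
    return _fstat_result("f3", (target, source1, source2), vals, block_size)


def f4(
    pf: PopFreqs,
    a_pop: str,
    b_pop: str,
    c_pop: str,
    d_pop: str,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> FStatResult:
    """Patterson f4(A, B; C, D) = mean (a-b)(c-d) with jackknife SE."""
    idx = [pf.index(p) for p in (a_pop, b_pop, c_pop, d_pop)]
    a, b, c, d = (pf.freq[i] for i in idx)
    vals = (a - b) * (c - d)
    vals[~(np.isfinite(a) & np.isfinite(b) & np.isfinite(c) & np.isfinite(d))] = np.nan
    return _fstat_result("f4", (a_pop, b_pop, c_pop, d_pop), vals, block_size)


def fstat_table(results: list[FStatResult]) -> pd.DataFrame:
    """Long-format table of f-statistic results."""
    return pd.DataFrame(
        [
            {
                "kind": r.kind,
                "pops": ":".join(r.pops),
                "estimate": r.estimate,
                "se": r.se,
                "z": r.z,
                "block_size": r.block_size,
                "n_blocks": r.n_blocks,
                "n_sites": r.n_sites,
            }
            for r in results
        ]
    )
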