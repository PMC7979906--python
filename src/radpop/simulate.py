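"""Truth-tracked synthetic genotype datasets with structure, admixture and clones.

Population allele frequencies follow the Balding–Nichols model: each
population's frequency at a site is Beta-distributed around an ancestral
frequency with spread controlled by a per-population drift parameter F
(larger F, more divergence; the expected pairwise Fst between two
populations rises with their F values).  Individuals are Hardy–Weinberg
draws from their (possibly admixed) ancestry-weighted frequencies.  Clonal
individuals copy a source genotype and are then perturbed by allelic
dropout (heterozygote -> random homozygote, the dominant genotyping
artifact in reduced-representation data), a symmetric genotype error, and
per-call missingness.

The default preset emulates a partly clonal, eight-population orchard-and-
wild sample set: 90 individuals, 4,000 SNP sites assigned to loci in pairs,
one ten-member graft-propagated cluster and five independent clone pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, SITE_COLUMNS, GenotypeMatrix


@dataclass(frozen=True)
class ClonePairSpec:
    """A clone to be copied from ``source`` with its own error/dropout rates."""

    source: str
    clone: str
    error_rate: float = 0.0
    dropout_rate: float = 0.0


@dataclass
class SimConfig:
    """Parameters of one synthetic dataset.

    Parameters
    ----------
    pop_sizes : dict
        Population label -> number of independently drawn individuals.
    divergence_F : dict
        Population label -> Balding–Nichols drift parameter in [0, 1).
    n_sites : int
        Number of biallelic SNP sites (independent; no linkage).
    ancestral_maf_range : (float, float)
        Ancestral minor-allele frequencies are uniform on this interval;
        the major/minor orientation is randomised per site.
    admixed : dict
        Sample id -> ancestry proportion vector over populations
        (dict label -> weight, summing to 1).  These individuals are added
        on top of ``pop_sizes`` and labelled ``"admixed"`` in the truth.
    clone_pairs : list of ClonePairSpec
        Clones copied from already-simulated individuals.
    missing_rate : float
        Per-call missingness applied to every individual.
    seed : int
        Mandatory; all randomness flows from it.
    """

    pop_sizes: dict[str, int]
    divergence_F: dict[str, float]
    n_sites: int
    seed: int
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    admixed: dict[str, dict[str, float]] = field(default_factory=dict)
    clone_pairs: list[ClonePairSpec] = field(default_factory=list)
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if set(self.pop_sizes) != set(self.divergence_F):
            raise ValueError("pop_sizes and divergence_F must cover the same pops")
        if any(n < 1 for n in self.pop_sizes.values()):
            raise ValueError("pop_sizes must be >= 1")
        for k, f in self.divergence_F.items():
            if not 0.0 <= f < 1.0:
                raise ValueError(f"divergence_F[{k!r}] must be in [0, 1)")
        lo, hi = self.ancestral_maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("ancestral_maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        for sid, q in self.admixed.items():
            if abs(sum(q.values()) - 1.0) > 1e-9:
                raise ValueError(f"ancestry proportions of {sid!r} must sum to 1")
            unknown = set(q) - set(self.pop_sizes)
            if unknown:
                raise ValueError(f"admixed sample {sid!r} references pops {unknown}")

    @property
    def pops(self) -> list[str]:
        return list(self.pop_sizes)


@dataclass
class SimTruth:
    """Generator ground truth: labels, ancestry, clones, frequencies."""

    labels: dict[str, str]
    q_matrix: pd.DataFrame  # samples x pops ancestry proportions
    clone_pairs: list[tuple[str, str]]  # symmetric registry, (source, clone)
    pop_frequencies: pd.DataFrame  # pops x sites realized frequencies
    config: SimConfig

    def clone_groups(self) -> list[list[str]]:
        """Connected components of the clone registry (sorted, deterministic)."""
        parent: dict[str, str] = {}

        def find(x: str) -> str:
            parent.setdefault(x, x)
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in self.clone_pairs:
            parent[find(a)] = find(b)
        groups: dict[str, list[str]] = {}
        for s in parent:
            groups.setdefault(find(s), []).append(s)
        return sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])


def draw_population_frequencies(cfg: SimConfig) -> pd.DataFrame:
    """Per-population per-site allele frequencies under Balding–Nichols.

    The ancestral frequency p is uniform on the configured minor-allele
    range, mirrored to the upper half at random so the alternate allele is
    not systematically minor.  Population k draws
    Beta(p (1-F_k)/F_k, (1-p)(1-F_k)/F_k); F_k = 0 returns p unchanged.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.ancestral_maf_range
    p = rng.uniform(lo, hi, size=cfg.n_sites)
    flip = rng.random(cfg.n_sites) < 0.5
    p = np.where(flip, 1.0 - p, p)
    rows = {}
    for pop in cfg.pops:
        f = cfg.divergence_F[pop]
        if f == 0.0:
            rows[pop] = p.copy()
        else:
            scale = (1.0 - f) / f
            rows[pop] = rng.beta(p * scale, (1.0 - p) * scale)
    out = pd.DataFrame(rows).T
    out.columns = [f"site{j}" for j in range(cfg.n_sites)]
    return out


def _perturb_clone(
    source_row: np.ndarray, spec: ClonePairSpec, rng: np.random.Generator
) -> np.ndarray:
    g = source_row.copy()
    # allelic dropout: het -> random homozygote
    het = g == 1
    drop = het & (rng.random(g.shape) < spec.dropout_rate)
    g[drop] = rng.choice([0, 2], size=int(drop.sum()))
    # symmetric error: replace with a uniform different code
    err = rng.random(g.shape) < spec.error_rate
    if err.any():
        offs = rng.integers(1, 3, size=int(err.sum()))
        g[err] = (g[err] + offs) % 3
    return g


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate a genotype matrix and its ground truth.

    Sample ids are ``<pop>_<i>`` for population members, the configured ids
    for admixed individuals, and the configured ids for clones.  Sites are
    assigned synthetic locus ids in pairs (two SNPs per locus) so that
    one-SNP-per-locus filtering is exercised downstream.
    """
    freqs = draw_population_frequencies(cfg)
    rng = np.random.default_rng(np.random.default_rng(cfg.seed).integers(2**31))

    samples: list[str] = []
    labels: dict[str, str] = {}
    q_rows: dict[str, np.ndarray] = {}
    pops = cfg.pops
    rows: list[np.ndarray] = []

    def draw_individual(q: np.ndarray) -> np.ndarray:
        p_ind = q @ freqs.to_numpy()
        return rng.binomial(2, p_ind).astype(np.int8)

    for k, pop in enumerate(pops):
        onehot = np.zeros(len(pops))
        onehot[k] = 1.0
        for i in range(cfg.pop_sizes[pop]):
            sid = f"{pop}_{i + 1}"
            samples.append(sid)
            labels[sid] = pop
            q_rows[sid] = onehot
            rows.append(draw_individual(onehot))

    for sid, qdict in cfg.admixed.items():
        q = np.array([qdict.get(pop, 0.0) for pop in pops])
        samples.append(sid)
        labels[sid] = "admixed"
        q_rows[sid] = q
        rows.append(draw_individual(q))

    registry: list[tuple[str, str]] = []
    for spec in cfg.clone_pairs:
        if spec.source not in samples:
            raise ValueError(f"clone source {spec.source!r} not simulated")
        if spec.clone in samples:
            raise ValueError(f"clone id {spec.clone!r} already in use")
        src_idx = samples.index(spec.source)
        samples.append(spec.clone)
        labels[spec.clone] = labels[spec.source]
        q_rows[spec.clone] = q_rows[spec.source]
        rows.append(_perturb_clone(rows[src_idx], spec, rng))
        registry.append((spec.source, spec.clone))

    calls = np.vstack(rows)
    if cfg.missing_rate > 0:
        calls[rng.random(calls.shape) < cfg.missing_rate] = MISSING

    n_loci = (cfg.n_sites + 1) // 2
    bases = np.array(list("ACGT"))
    ref = rng.integers(0, 4, size=cfg.n_sites)
    alt = (ref + rng.integers(1, 4, size=cfg.n_sites)) % 4
    sites = pd.DataFrame(
        {
            "chrom": [f"L{j // 2 + 1}" for j in range(cfg.n_sites)],
            "pos": [10 * (j % 2) + 10 for j in range(cfg.n_sites)],
            "ref": bases[ref],
            "alt": bases[alt],
            "locus_id": [f"L{j // 2 + 1}" for j in range(cfg.n_sites)],
        },
        columns=SITE_COLUMNS,
    )
    gm = GenotypeMatrix(samples=samples, sites=sites, calls=calls)
    truth = SimTruth(
        labels=labels,
        q_matrix=pd.DataFrame(q_rows, index=pops).T.loc[samples],
        clone_pairs=registry,
        pop_frequencies=freqs,
        config=cfg,
    )
    return gm, truth


def default_preset(seed: int = 20210319, n_sites: int = 4000) -> SimConfig:
    """The desk-scale study-shaped preset.

    Eight populations (A1, A2, B, C, D, E, F, H) totalling 90 individuals,
    one ten-member clonal cluster inside A2 (a graft lineage: one founder,
    nine clones), five independent clone pairs, three A1 individuals with
    50/50 A1/D ancestry, genotyping error 0.01, allelic dropout 0.10,
    missingness 0.10.
    """
    pop_sizes = {"A1": 8, "A2": 1, "B": 9, "C": 9, "D": 14, "E": 13, "F": 9, "H": 10}
    divergence_F = {
        "A1": 0.08,
        "A2": 0.25,
        "B": 0.20,
        "C": 0.10,
        "D": 0.06,
        "E": 0.12,
        "F": 0.08,
        "H": 0.30,
    }
    e, d = 0.01, 0.10
    clone_pairs = [
        ClonePairSpec("A2_1", f"A2_c{i}", error_rate=e, dropout_rate=d)
        for i in range(1, 10)
    ] + [
        ClonePairSpec("F_1", "F_c1", error_rate=e, dropout_rate=d),
        ClonePairSpec("C_1", "C_c1", error_rate=e, dropout_rate=d),
        ClonePairSpec("B_1", "B_c1", error_rate=e, dropout_rate=d),
        ClonePairSpec("A1_1", "A1_c1", error_rate=e, dropout_rate=d),
        ClonePairSpec("A1_2", "A1_c2", error_rate=e, dropout_rate=d),
    ]
    admixed = {
        f"A1_adm{i}": {"A1": 0.5, "D": 0.5} for i in range(1, 4)
    }
    return SimConfig(
        pop_sizes=pop_sizes,
        divergence_F=divergence_F,
        n_sites=n_sites,
        seed=seed,
        admixed=admixed,
        clone_pairs=clone_pairs,
        missing_rate=0.10,
    )
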