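"""Biallelic SNP genotype matrices: VCF I/O and site filtering.

Genotypes are stored as alternate-allele counts (0, 1, 2) with ``MISSING``
(= -1) for uncalled or half-called genotypes.  Three site filters mirror a
standard reduced-representation (RAD-seq) export pipeline: a per-site call
rate threshold, one-SNP-per-locus deduplication, and a minor-allele-frequency
floor.  Filters are applied in that fixed order so reported removal counts
are reproducible.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "locus_id"]


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed into a genotype matrix."""


class EmptyMatrixError(ValueError):
    """Raised when filtering removes every site."""


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic-SNP-sites genotype matrix.

    Parameters
    ----------
    samples : list of str
        Ordered, unique sample identifiers (rows of ``calls``).
    sites : pandas.DataFrame
        One row per site with columns ``chrom, pos, ref, alt, locus_id``;
        (chrom, pos) pairs are unique, positions 1-based as in VCF.
    calls : numpy.ndarray
        ``(n_samples, n_sites)`` int8 array of alternate-allele counts in
        {0, 1, 2} or ``MISSING`` (-1).
    """

    samples: list[str]
    sites: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids are not unique")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid genotype codes: {np.unique(self.calls[bad])}")
        missing_cols = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing_cols:
            raise ValueError(f"site table lacks columns {missing_cols}")
        keys = self.sites[["chrom", "pos"]].apply(tuple, axis=1)
        if keys.duplicated().any():
            raise ValueError("duplicate (chrom, pos) site keys")
        if (self.sites["ref"] == self.sites["alt"]).any():
            raise ValueError("site with ref == alt (not biallelic)")
        self.sites = self.sites.reset_index(drop=True).astype(
            {"chrom": str, "pos": "int64", "ref": str, "alt": str, "locus_id": str}
        )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id!r}") from None

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        """Matrix restricted to the given site indices (order preserved)."""
        idx = np.asarray(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.iloc[idx].reset_index(drop=True),
            calls=self.calls[:, idx].copy(),
        )

    def take_samples(self, ids: list[str]) -> "GenotypeMatrix":
        rows = [self.sample_index(s) for s in ids]
        return GenotypeMatrix(
            samples=list(ids),
            sites=self.sites.copy(),
            calls=self.calls[rows, :].copy(),
        )

    def call_rate(self) -> np.ndarray:
        """Per-site fraction of non-missing calls."""
        return (self.calls != MISSING).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Per-site minor allele frequency over non-missing calls.

        Sites with zero calls get MAF 0 (they are removed by any call-rate
        filter first anyway).
        """
        called = self.calls != MISSING
        n_alleles = 2 * called.sum(axis=0)
        alt = np.where(called, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), 0.0)
        return np.minimum(p, 1.0 - p)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and np.array_equal(self.calls, other.calls)
            and self.sites[SITE_COLUMNS].equals(other.sites[SITE_COLUMNS])
        )


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the three site filters.

    ``min_call_rate`` keeps sites called in at least that fraction of samples
    (the export pipeline's -R option); ``one_snp_per_locus`` keeps only the
    first SNP per RAD locus; ``min_maf`` is an inclusive minor-allele-frequency
    floor computed over non-missing calls.
    """

    min_call_rate: float = 0.5
    one_snp_per_locus: bool = True
    min_maf: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_call_rate <= 1.0:
            raise ValueError("min_call_rate must be in [0, 1]")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")


@dataclass(frozen=True)
class FilterReport:
    n_sites_input: int
    n_removed_call_rate: int
    n_removed_locus_dedup: int
    n_removed_maf: int
    n_sites_output: int

    def __post_init__(self) -> None:
        removed = (
            self.n_removed_call_rate + self.n_removed_locus_dedup + self.n_removed_maf
        )
        if self.n_sites_output != self.n_sites_input - removed:
            raise ValueError("filter report counts do not reconcile")
        if min(
            self.n_sites_input,
            self.n_removed_call_rate,
            self.n_removed_locus_dedup,
            self.n_removed_maf,
            self.n_sites_output,
        ) < 0:
            raise ValueError("negative count in filter report")

    def to_dict(self) -> dict[str, int]:
        return {
            "n_sites_input": self.n_sites_input,
            "n_removed_call_rate": self.n_removed_call_rate,
            "n_removed_locus_dedup": self.n_removed_locus_dedup,
            "n_removed_maf": self.n_removed_maf,
            "n_sites_output": self.n_sites_output,
        }


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF with GT fields into a :class:`GenotypeMatrix`.

    Biallelic SNP records only: indels and multiallelic records are skipped
    (with a summary warning).  ``./.`` and half-missing calls map to
    ``MISSING``; phased and unphased separators are both accepted.  Sample
    order follows the VCF header.  The ID column, when present, is used as
    the RAD locus identifier; otherwise the chromosome/locus name is.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib raises plain OSError/Exception
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    rows: list[dict] = []
    codes: list[np.ndarray] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        gt = np.array([g[:2] for g in var.genotypes], dtype=np.int16)
        site_codes = gt.sum(axis=1).astype(np.int8)
        site_codes[(gt < 0).any(axis=1)] = MISSING
        codes.append(site_codes)
        rows.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0],
                "locus_id": var.ID if var.ID not in (None, ".") else var.CHROM,
            }
        )
    vcf.close()
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} non-biallelic-SNP record(s)", stacklevel=2)
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    calls = (
        np.array(codes, dtype=np.int8).T
        if codes
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples=samples, sites=sites, calls=calls)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a GT-only VCF 4.2 file; ``read_vcf(write_vcf(gm)) == gm``."""
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write("##source=radpop\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    for chrom in pd.unique(gm.sites["chrom"]):
        buf.write(f"##contig=<ID={chrom}>\n")
    buf.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.samples)
        + "\n"
    )
    for j, site in enumerate(gm.sites.itertuples(index=False)):
        gts = "\t".join(_GT_STRINGS[int(c)] for c in gm.calls[:, j])
        buf.write(
            f"{site.chrom}\t{site.pos}\t{site.locus_id}\t{site.ref}\t{site.alt}"
            f"\t.\t.\t.\tGT\t{gts}\n"
        )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def apply_filters(
    gm: GenotypeMatrix, cfg: FilterConfig
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the three site filters in order: call rate, locus dedup, MAF.

    The first SNP per locus is the one with the smallest position (ties broken
    by input order).  The MAF boundary is inclusive: a site at exactly
    ``min_maf`` is retained.  Raises :class:`EmptyMatrixError` if nothing
    survives.
    """
    if gm.n_sites == 0:
        raise EmptyMatrixError("input matrix has no sites")
    n_input = gm.n_sites

    keep = gm.call_rate() >= cfg.min_call_rate
    n_cr = int((~keep).sum())
    gm = gm.take_sites(np.flatnonzero(keep))

    n_dedup = 0
    if cfg.one_snp_per_locus and gm.n_sites:
        order = gm.sites.sort_values("pos", kind="stable").index
        first = set(
            gm.sites.loc[order].groupby("locus_id", sort=False).head(1).index
        )
        keep_idx = np.array([i in first for i in range(gm.n_sites)])
        n_dedup = int((~keep_idx).sum())
        gm = gm.take_sites(np.flatnonzero(keep_idx))

    keep = gm.maf() >= cfg.min_maf if gm.n_sites else np.zeros(0, dtype=bool)
    n_maf = int((~keep).sum())
    gm = gm.take_sites(np.flatnonzero(keep))

    if gm.n_sites == 0:
        raise EmptyMatrixError("all sites removed by filtering")
    report = FilterReport(
        n_sites_input=n_input,
        n_removed_call_rate=n_cr,
        n_removed_locus_dedup=n_dedup,
        n_removed_maf=n_maf,
        n_sites_output=gm.n_sites,
    )
    return gm, report


def pairwise_shared_sites(gm: GenotypeMatrix, a: str, b: str) -> GenotypeMatrix:
    """Two-sample matrix restricted to sites called in BOTH individuals.

    This reproduces, on a fixed genotype matrix, a per-pair export with the
    call-rate requirement set to one.
    """
    if a == b:
        raise ValueError("pair must be two distinct samples")
    ia, ib = gm.sample_index(a), gm.sample_index(b)
    shared = (gm.calls[ia] != MISSING) & (gm.calls[ib] != MISSING)
    sub = gm.take_samples([a, b])
    return sub.take_sites(np.flatnonzero(shared))
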