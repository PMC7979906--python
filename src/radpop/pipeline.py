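"""End-to-end orchestration: simulate/load -> filter -> structure -> clonality -> popgen.

Every stage writes its artifacts into the output directory as plain-text
tables, and a final ``report.json`` summarises filter counts, dendrogram
groups at the requested cut, clonal groups, the Fst matrix and any
requested f-statistics.  Runs are deterministic: all randomness flows from
the single seed in :class:`RunConfig`, and every output carries the config
hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clonality, genotype_io, popgen, simulate, structure
from .genotype_io import FilterConfig, GenotypeMatrix
from .popgen import PopulationMap

log = logging.getLogger("radpop")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``vcf`` (with ``metadata``) or ``use_sim_preset`` must be
    active.  ``fstats`` lists f-statistics to compute, each as
    ``("f3", target, src1, src2)`` or ``("f4", a, b, c, d)``.
    """

    out_dir: str
    seed: int = 0
    vcf: str | None = None
    metadata: str | None = None
    use_sim_preset: bool = False
    n_sites: int = 4000
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    clonality_threshold: float = clonality.DEFAULT_THRESHOLD
    block_size: int = popgen.DEFAULT_BLOCK_SIZE
    dendrogram_cut_k: int = 8
    fstats: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        if bool(self.vcf) == self.use_sim_preset:
            raise ValueError("exactly one of vcf input or simulation preset required")

    def config_hash(self) -> str:
        # out_dir excluded: the same analysis into two directories is the
        # same run and must stamp (and produce) identical tables
        fields = {k: v for k, v in dataclasses.asdict(self).items() if k != "out_dir"}
        payload = json.dumps(fields, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


class StageError(RuntimeError):
    """A pipeline stage failed; message names the stage."""


def _stamp(cfg: RunConfig) -> str:
    return f"# radpop config_hash={cfg.config_hash()} seed={cfg.seed}\n"


def _write_table(df: pd.DataFrame, path: Path, cfg: RunConfig, index=True) -> None:
    with open(path, "w") as fh:
        fh.write(_stamp(cfg))
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages in order and return the summary report dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    try:
        gm, pop_map, truth = _stage_input(cfg, out)
        report["n_samples"] = gm.n_samples
        gm, filt = _stage_filter(cfg, out, gm)
        report["filter"] = filt.to_dict()
        report["structure"] = _stage_structure(cfg, out, gm)
        report["clonality"] = _stage_clonality(cfg, out, gm)
        report["popgen"] = _stage_popgen(cfg, out, gm, pop_map)
        if truth is not None:
            report["truth_clone_groups"] = truth.clone_groups()
    except Exception:
        (out / "FAILED").write_text("pipeline failed; partial outputs retained\n")
        raise
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


def _stage_input(cfg, out):
    try:
        if cfg.use_sim_preset:
            sim_cfg = simulate.default_preset(seed=cfg.seed, n_sites=cfg.n_sites)
            gm, truth = simulate.simulate_genotypes(sim_cfg)
            genotype_io.write_vcf(gm, str(out / "simulated.vcf"))
            pop_map = PopulationMap(
                {s: truth.labels[s] for s in gm.samples}
            )
            meta = pd.DataFrame(
                {"sample_id": gm.samples,
                 "population": [truth.labels[s] for s in gm.samples]}
            )
            _write_table(meta, out / "metadata.tsv", cfg, index=False)
            _write_table(
                truth.q_matrix, out / "truth_q_matrix.tsv", cfg
            )
            pd.DataFrame(truth.clone_pairs, columns=["source", "clone"]).to_csv(
                out / "truth_clones.tsv", sep="\t", index=False
            )
        else:
            gm = genotype_io.read_vcf(cfg.vcf)
            pop_map = PopulationMap.from_table(cfg.metadata)
            truth = None
        log.info("input: %d samples x %d sites", gm.n_samples, gm.n_sites)
        return gm, pop_map, truth
    except Exception as exc:
        raise StageError(f"input stage failed: {exc}") from exc


def _stage_filter(cfg, out, gm):
    try:
        gm, rep = genotype_io.apply_filters(gm, cfg.filter_config)
        genotype_io.write_vcf(gm, str(out / "filtered.vcf"))
        with open(out / "filter_report.json", "w") as fh:
            json.dump(rep.to_dict(), fh, indent=2)
        log.info("filter: %s", rep.to_dict())
        return gm, rep
    except Exception as exc:
        raise StageError(f"filter stage failed: {exc}") from exc


def _stage_structure(cfg, out, gm):
    try:
        dm = structure.ibs_distance(gm)
        _write_table(dm.to_frame(), out / "ibs_distance.tsv", cfg)
        dend = structure.upgma_cluster(dm)
        (out / "dendrogram.nwk").write_text(dend.to_newick() + "\n")
        groups = dend.cut(cfg.dendrogram_cut_k)
        _write_table(
            pd.DataFrame(
                {"sample_id": list(groups), "group": list(groups.values())}
            ),
            out / "dendrogram_groups.tsv",
            cfg,
            index=False,
        )
        pca = structure.genotype_pca(gm, n_axes=10)
        _write_table(pca.scores_frame(), out / "pca_scores.tsv", cfg)
        _write_table(
            pd.DataFrame(
                {
                    "eigenvalue": pca.eigenvalues,
                    "contribution_ratio": pca.contribution_ratios[
                        : len(pca.eigenvalues)
                    ],
                },
                index=[f"PC{k+1}" for k in range(len(pca.eigenvalues))],
            ),
            out / "pca_eigen.tsv",
            cfg,
        )
        sizes = pd.Series(list(groups.values())).value_counts().to_dict()
        return {"group_sizes_at_cut": {str(k): int(v) for k, v in sizes.items()}}
    except Exception as exc:
        raise StageError(f"structure stage failed: {exc}") from exc


def _stage_clonality(cfg, out, gm):
    try:
        table = clonality.pairwise_table(gm, threshold=cfg.clonality_threshold)
        _write_table(table, out / "clonality_pairs.tsv", cfg, index=False)
        groups = clonality.clonal_clusters(gm, threshold=cfg.clonality_threshold)
        multi = [g for g in groups if len(g) > 1]
        membership = pd.DataFrame(
            [(f"CG{gi+1}", s) for gi, g in enumerate(multi) for s in g],
            columns=["clonal_group", "sample_id"],
        )
        _write_table(membership, out / "clonal_groups.tsv", cfg, index=False)
        return {"clonal_groups": multi}
    except Exception as exc:
        raise StageError(f"clonality stage failed: {exc}") from exc


def _stage_popgen(cfg, out, gm, pop_map):
    try:
        pm = PopulationMap({s: pop_map[s] for s in gm.samples if s in pop_map})
        summary = popgen.heterozygosity_fis(gm, pm)
        _write_table(summary, out / "pop_summary.tsv", cfg)
        fst = popgen.pairwise_fst(gm, pm)
        _write_table(fst, out / "fst_matrix.tsv", cfg)
        results = []
        pf = popgen.pop_allele_freqs(gm, pm)
        for spec in cfg.fstats:
            kind, *pops = spec
            if kind == "f3":
                results.append(popgen.f3(pf, *pops, block_size=cfg.block_size))
            elif kind == "f4":
                results.append(popgen.f4(pf, *pops, block_size=cfg.block_size))
            else:
                raise ValueError(f"unknown f-statistic kind {kind!r}")
        if results:
            _write_table(
                popgen.fstat_table(results), out / "fstats.tsv", cfg, index=False
            )
        return {
            "fis": {p: (None if pd.isna(v) else float(v))
                    for p, v in summary["Fis"].items()},
            "fst": json.loads(fst.to_json()),
            "fstats": [dataclasses.asdict(r) for r in results],
        }
    except Exception as exc:
        raise StageError(f"popgen stage failed: {exc}") from exc
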