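"""Population statistics: Ho/He/Fis, pairwise Fst, f3/f4 with jackknife.

The clonal population (A2) should show the most negative Fis and inflated
Fst against every other group; f3 with the admixed individuals as target
should be negative.
"""

from pathlib import Path

import pandas as pd

from radpop.genotype_io import read_vcf
from radpop.popgen import (
    PopulationMap,
    f3,
    f4,
    fstat_table,
    heterozygosity_fis,
    pairwise_fst,
    pop_allele_freqs,
)

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    gm = read_vcf(str(BASE / "sim" / "filtered.vcf"))
    meta = pd.read_csv(BASE / "sim" / "metadata.tsv", sep="\t")
    pm = PopulationMap(zip(meta.sample_id, meta.population))
    out = BASE / "popgen"
    out.mkdir(parents=True, exist_ok=True)

    summary = heterozygosity_fis(gm, pm)
    summary.to_csv(out / "pop_summary.tsv", sep="\t")
    fis = summary["Fis"].dropna().sort_values()
    print(f"most negative Fis: {fis.index[0]} ({fis.iloc[0]:.3f}); "
          f"all others within [{fis.iloc[1]:.3f}, {fis.iloc[-1]:.3f}]")

    fst = pairwise_fst(gm, pm)
    fst.to_csv(out / "fst_matrix.tsv", sep="\t")
    others = [p for p in fst.index if p not in ("A2", "admixed")]
    print(f"Fst A2 vs others: {fst.loc['A2', others].min():.3f}-"
          f"{fst.loc['A2', others].max():.3f}; "
          f"A1 vs D: {fst.loc['A1', 'D']:.3f} (closest pair, as for an "
          f"admixture source)")

    pf = pop_allele_freqs(gm, pm)
    results = [
        f3(pf, "admixed", "A1", "D"),
        f3(pf, "admixed", "A1", "A2"),
        f3(pf, "B", "A1", "D"),
        f4(pf, "A1", "D", "B", "C"),
        f4(pf, "A1", "admixed", "B", "C"),
    ]
    tbl = fstat_table(results)
    tbl.to_csv(out / "fstats.tsv", sep="\t", index=False)
    for r in results:
        print(f"{r.kind}({':'.join(r.pops)}) = {r.estimate:+.5f} "
              f"SE {r.se:.5f} Z {r.z:+.2f}")


if __name__ == "__main__":
    main()
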