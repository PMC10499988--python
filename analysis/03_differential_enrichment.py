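#!/usr/bin/env python
"""Call differential-enrichment hits for the HSA selection.

Tests HSA counts against the naive library and both control selections
(exact conditional binomial, p < 0.05 and fold > 3, intersection across the
three comparisons), writes per-comparison DE and volcano tables and the
final ranked hit list, and reports whether the planted binders were
recovered.
"""

from pathlib import Path

from cycloscreen import DEConfig, de_table, nominate_hits, volcano_table
from cycloscreen.reads import CountTable

ROOT = Path(__file__).resolve().parents[1]
CONTROLS = ("naive", "T4", "ConA")
PLANTED = ("SICRFFC", "SFCPMFC", "SLCKREC")


def main() -> None:
    counts_path = ROOT / "results" / "counts.tsv"
    if not counts_path.exists():
        raise SystemExit("run analysis/02_process_reads.py first")
    table = CountTable.from_tsv(counts_path)
    counts = table.to_dataframe().set_index("peptide")
    cfg = DEConfig()  # p < 0.05, fold > 3, raw p, intersection

    results = {}
    outdir = ROOT / "results"
    for ctrl in CONTROLS:
        df = de_table(counts, "HSA", ctrl, depths=table.depth, config=cfg)
        results[ctrl] = df
        df.to_csv(outdir / f"de_HSA_vs_{ctrl}.tsv", sep="\t")
        volcano_table(df).to_csv(outdir / f"volcano_HSA_vs_{ctrl}.tsv",
                                 sep="\t", index=False)
        print(f"HSA vs {ctrl}: {int(df.hit.sum())} per-comparison hits")

    per_comp, final = nominate_hits(results, cfg)
    final.to_csv(outdir / "hits.tsv", sep="\t", index=False)
    recovered = [p for p in PLANTED if p in set(final.peptide)]
    print(f"final hits (intersection of {len(CONTROLS)} comparisons): {len(final)}")
    print(f"planted binders recovered: {len(recovered)}/{len(PLANTED)} "
          f"({', '.join(recovered)})")
    print(f"hit list: {outdir / 'hits.tsv'}")


if __name__ == "__main__":
    main()
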