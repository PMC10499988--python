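#!/usr/bin/env python
"""Motif analysis of the nominated hits.

Builds the position-frequency heat-map matrix of the top 25 hits, the
20x20 dipeptide enrichment matrix over all hits, and Hamming-distance
families (radius 2) with per-family consensus sequences.
"""

from pathlib import Path

import pandas as pd

from cycloscreen.motifs import (
    cluster_families,
    consensus_from_family,
    dipeptide_enrichment,
    position_frequency_matrix,
    top_hits,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    hits_path = ROOT / "results" / "hits.tsv"
    if not hits_path.exists():
        raise SystemExit("run analysis/03_differential_enrichment.py first")
    hits_df = pd.read_csv(hits_path, sep="\t")
    hits = hits_df["peptide"].tolist()
    if not hits:
        raise SystemExit("no hits to analyse")
    outdir = ROOT / "results"

    top = top_hits(hits_df, k=25)
    pfm = position_frequency_matrix(top)
    pfm.to_csv(outdir / "pfm_top25.tsv", sep="\t")
    print(f"position-frequency matrix over top {len(top)} hits "
          f"-> {outdir / 'pfm_top25.tsv'}")

    dip = dipeptide_enrichment(hits)
    dip.counts.to_csv(outdir / "dipeptide_observed.tsv", sep="\t")
    dip.expected.to_csv(outdir / "dipeptide_expected.tsv", sep="\t")
    dip.enrichment.to_csv(outdir / "dipeptide_enrichment.tsv", sep="\t")
    stacked = dip.enrichment.stack()
    pair, value = stacked.idxmax(), stacked.max()
    print(f"dipeptides: {dip.total_pairs} pairs from {len(hits)} hits; "
          f"strongest enrichment {pair[0]}{pair[1]} at {value:.2f}x")

    families = cluster_families(hits, max_hamming=2)
    rows = []
    for i, fam in enumerate(families, start=1):
        cons = consensus_from_family(fam)
        rows.append({"family": i, "size": len(fam),
                     "consensus": cons.sequence,
                     "ties_at": ",".join(map(str, cons.tie_positions)),
                     "members": ",".join(fam)})
    pd.DataFrame(rows).to_csv(outdir / "families.tsv", sep="\t", index=False)
    print(f"{len(families)} Hamming families (radius 2); largest: "
          f"{rows[0]['size']} members, consensus {rows[0]['consensus']}")


if __name__ == "__main__":
    main()
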