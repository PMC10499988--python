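#!/usr/bin/env python
"""Simulate the single-round albumin-selection campaign.

Builds a naive n=3 macrocycle library (10^4 variants, log-normal
abundances), plants three albumin binders (SICRFFC, SFCPMFC, SLCKREC) plus
the non-binding control STCQGEC, runs one selection round for the test
target (HSA) and two irrelevant-target controls (T4, ConA), and renders the
four experiments as a multiplexed paired-end FASTQ run with realistic
substitution errors.  FASTQ goes to scratch/ (large); the ground-truth
manifest to results/.
"""

from pathlib import Path

from cycloscreen import (
    LibraryDesign,
    SimulationConfig,
    generate_naive_population,
    render_fastq_run,
    simulate_selection_round,
)

ROOT = Path(__file__).resolve().parents[1]
SEED = 0

BARCODES = {"naive": "ACGTACGT", "HSA": "TGCATGCA",
            "T4": "CCAATTGG", "ConA": "GGTTAACC"}
# enrichment factors for the planted binders; STCQGEC rides along at λ=1
PLANTED = (("SICRFFC", 10.0), ("SFCPMFC", 8.0), ("SLCKREC", 6.0),
           ("STCQGEC", 1.0))


def main() -> None:
    design = LibraryDesign(cycle_sizes=(3,))
    cfg = SimulationConfig(n_variants=10_000, reads_per_experiment=100_000,
                           error_rate=1e-3, seed=SEED, planted=PLANTED,
                           planted_naive_freq=1e-3,
                           barcode_assignment=BARCODES)
    null_cfg = SimulationConfig(n_variants=10_000, reads_per_experiment=100_000,
                                error_rate=1e-3, seed=SEED, planted=(),
                                barcode_assignment=BARCODES)
    naive = generate_naive_population(design, cfg)
    pops = [naive,
            simulate_selection_round(naive, cfg, label="HSA"),
            simulate_selection_round(naive, null_cfg, label="T4"),
            simulate_selection_round(naive, null_cfg, label="ConA")]

    outdir = ROOT / "scratch" / "screen"
    manifest = render_fastq_run(pops, design, cfg, outdir)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    manifest["truth"].to_csv(results / "screen_truth.tsv", sep="\t", index=False)

    n_reads = int(manifest["truth"].true_count.sum())
    print(f"rendered {n_reads} read pairs across {len(pops)} experiments")
    print(f"FASTQ: {manifest['r1']} / {manifest['r2']}")
    print(f"ground truth: {results / 'screen_truth.tsv'}")


if __name__ == "__main__":
    main()
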