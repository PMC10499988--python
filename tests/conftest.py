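import pytest

from cycloscreen import (
    LibraryDesign,
    SimulationConfig,
    generate_naive_population,
    render_fastq_run,
    simulate_selection_round,
)

BARCODES = {"naive": "ACGTACGT", "HSA": "TGCATGCA", "ConA": "GGTTAACC"}


@pytest.fixture(scope="session")
def design_n3() -> LibraryDesign:
    return LibraryDesign(name="SXCX3C", cycle_sizes=(3,))


@pytest.fixture(scope="session")
def design_full() -> LibraryDesign:
    return LibraryDesign()


@pytest.fixture(scope="session")
def small_campaign(design_n3, tmp_path_factory):
    """A small error-free three-experiment campaign with one planted binder."""
    cfg = SimulationConfig(
        n_variants=500,
        reads_per_experiment=5_000,
        error_rate=0.0,
        seed=11,
        planted=(("SICRFFC", 10.0),),
        planted_naive_freq=2e-3,
        barcode_assignment=BARCODES,
    )
    null_cfg = SimulationConfig(
        n_variants=500, reads_per_experiment=5_000, error_rate=0.0, seed=11,
        planted=(), barcode_assignment=BARCODES)
    naive = generate_naive_population(design_n3, cfg)
    hsa = simulate_selection_round(naive, cfg, label="HSA")
    cona = simulate_selection_round(naive, null_cfg, label="ConA")
    outdir = tmp_path_factory.mktemp("campaign")
    manifest = render_fastq_run([naive, hsa, cona], design_n3, cfg, outdir)
    barcode_map = {bc: exp for exp, bc in BARCODES.items()}
    return {"config": cfg, "design": design_n3, "populations": [naive, hsa, cona],
            "manifest": manifest, "barcode_map": barcode_map}
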