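"""Read deconvolution: quality, demultiplex, priming, F/R merge, counting."""

from collections import Counter

import numpy as np
import pytest

from cycloscreen.library import reverse_translate
from cycloscreen.reads import (
    UNASSIGNED,
    ConfigError,
    CountTable,
    ReadPair,
    demultiplex,
    match_constant_region,
    merge_pair_extract,
    process_run,
    quality_filter,
)
from cycloscreen.simulate import (
    SimulationConfig,
    generate_naive_population,
    render_fastq_run,
    revcomp,
)

Q37 = chr(33 + 37)
Q2 = chr(33 + 2)


def make_pair(design, peptide="SICRFFC", barcode="ACGTACGT", read_length=75,
              fwd_mut=None, rev_mut=None, qual_override=None):
    """Construct a synthetic read pair the way the simulator renders one."""
    insert = reverse_translate(peptide)
    construct = barcode + design.constant_5p + insert + design.constant_3p
    fwd = list(construct[:read_length])
    rev = list(revcomp(construct)[:read_length])
    for pos, base in (fwd_mut or {}).items():
        fwd[pos] = base
    for pos, base in (rev_mut or {}).items():
        rev[pos] = base
    qual = qual_override or Q37 * read_length
    return ReadPair(id="t", fwd_seq="".join(fwd), rev_seq="".join(rev),
                    fwd_qual=qual, rev_qual=Q37 * read_length)


class TestQualityFilter:
    def test_all_high_quality_passes(self, design_n3):
        assert quality_filter(make_pair(design_n3), min_q=20)

    def test_single_low_base_fails(self, design_n3):
        qual = Q37 * 40 + Q2 + Q37 * 34
        assert not quality_filter(make_pair(design_n3, qual_override=qual), min_q=20)

    def test_zero_threshold_vacuous(self, design_n3):
        qual = Q2 * 75
        assert quality_filter(make_pair(design_n3, qual_override=qual), min_q=0)


class TestDemultiplex:
    BM = {"ACGTACGT": "naive", "TGCATGCA": "HSA"}

    def test_exact_match(self, design_n3):
        assert demultiplex(make_pair(design_n3), self.BM) == "naive"

    def test_one_substitution_is_unassigned(self, design_n3):
        pair = make_pair(design_n3, fwd_mut={0: "T"})
        assert demultiplex(pair, self.BM) == UNASSIGNED

    def test_empty_map_rejected(self, design_n3):
        with pytest.raises(ConfigError):
            demultiplex(make_pair(design_n3), {})


class TestMatchConstantRegion:
    def test_substitution_budget(self):
        assert match_constant_region("AAACGTACGT", "CGTACGT", 3) == (True, 0)
        assert match_constant_region("AAACGTACTT", "CGTACGT", 3) == (True, 1)
        matched, subs = match_constant_region("AAACGAACTT", "CGTACGT", 3)
        assert not matched and subs == 2

    def test_span_past_read_end_fails(self):
        matched, subs = match_constant_region("ACGT", "ACGTACGT", 0)
        assert not matched and subs is None


class TestMergePairExtract:
    def test_identical_windows_return_insert(self, design_n3):
        pair = make_pair(design_n3)
        assert merge_pair_extract(pair, design_n3, 3) == reverse_translate("SICRFFC")

    def test_single_base_disagreement_fails(self, design_n3):
        # mutate one insert base on the forward mate only
        pos = design_n3.barcode_length + len(design_n3.constant_5p) + 5
        pair = make_pair(design_n3, fwd_mut={pos: "A"})
        assert merge_pair_extract(pair, design_n3, 3) is None

    def test_reverse_mate_needs_reverse_complement(self, design_n3):
        pair = make_pair(design_n3)
        # the raw reverse mate differs from the forward window; only its
        # reverse complement matches, which extraction must handle
        assert pair.rev_seq[:10] != pair.fwd_seq[:10]
        assert merge_pair_extract(pair, design_n3, 3) is not None


class TestProcessRun:
    def test_roundtrip_counts_match_manifest(self, small_campaign):
        man = small_campaign["manifest"]
        table = process_run(man["r1"], man["r2"], small_campaign["design"],
                            small_campaign["barcode_map"])
        truth = man["truth"].pivot_table(index="peptide", columns="experiment",
                                         values="true_count", fill_value=0)
        obs = table.to_dataframe().set_index("peptide")
        for exp in table.experiments:
            expected = truth[exp][truth[exp] > 0]
            assert expected.sum() == table.depth[exp]
            for pep, c in expected.items():
                assert obs.at[pep, exp] == c

    def test_audit_conserves_reads(self, design_n3, tmp_path):
        cfg = SimulationConfig(
            n_variants=300, reads_per_experiment=3_000, error_rate=0.005,
            low_quality_fraction=0.05, seed=13, planted=(),
            barcode_assignment={"naive": "ACGTACGT"})
        pop = generate_naive_population(design_n3, cfg)
        man = render_fastq_run([pop], design_n3, cfg, tmp_path)
        table = process_run(man["r1"], man["r2"], design_n3,
                            {"ACGTACGT": "naive"})
        assert sum(table.audit.values()) == 3_000
        statuses = {s for (_, s) in table.audit}
        assert "FAIL_QUALITY" in statuses  # the Q2 injection is caught

    def test_raising_min_q_never_increases_depth(self, design_n3, tmp_path):
        cfg = SimulationConfig(
            n_variants=100, reads_per_experiment=1_000, error_rate=0.0,
            low_quality_fraction=0.2, seed=17, planted=(),
            barcode_assignment={"naive": "ACGTACGT"})
        pop = generate_naive_population(design_n3, cfg)
        man = render_fastq_run([pop], design_n3, cfg, tmp_path)
        depths = []
        for q in (0, 10, 20, 40):
            t = process_run(man["r1"], man["r2"], design_n3,
                            {"ACGTACGT": "naive"}, min_q=q)
            depths.append(t.depth["naive"])
        assert depths == sorted(depths, reverse=True)

    def test_error_tolerance_sanity_band(self, design_n3, tmp_path):
        cfg = SimulationConfig(
            n_variants=500, reads_per_experiment=20_000, error_rate=0.001,
            seed=19, planted=(), barcode_assignment={"naive": "ACGTACGT"})
        pop = generate_naive_population(design_n3, cfg)
        man = render_fastq_run([pop], design_n3, cfg, tmp_path)
        table = process_run(man["r1"], man["r2"], design_n3,
                            {"ACGTACGT": "naive"})
        assert table.depth["naive"] / 20_000 >= 0.85

    def test_brute_force_oracle_small_run(self, design_n3, tmp_path):
        """Exhaustive string comparison rebuilds the counts of an error-free run."""
        barcodes = {"naive": "ACGTACGT", "HSA": "TGCATGCA"}
        cfg = SimulationConfig(n_variants=40, reads_per_experiment=400,
                               error_rate=0.0, seed=23, planted=(),
                               barcode_assignment=barcodes)
        pop = generate_naive_population(design_n3, cfg)
        man = render_fastq_run([pop, type(pop)(records=pop.records, label="HSA")],
                               design_n3, cfg, tmp_path)
        # oracle: match every read against every (barcode, variant) construct
        oracle = Counter()
        reads = man["r1"].read_text().splitlines()[1::4]
        constructs = {}
        for exp, bc in barcodes.items():
            for rec, _ in pop.records:
                full = bc + design_n3.constant_5p + rec.dna + design_n3.constant_3p
                constructs[full[:75]] = (rec.peptide, exp)
        for read in reads:
            assert read in constructs
            oracle[constructs[read]] += 1
        table = process_run(man["r1"], man["r2"], design_n3,
                            {bc: exp for exp, bc in barcodes.items()})
        assert table.counts == dict(oracle)

    def test_stop_codon_inserts_fail(self, design_n3, tmp_path):
        # hand-write a run whose single insert carries a stop codon
        insert = "TCT" + "TAA" + "TGT" + "GCT" * 3 + "TGT"
        construct = "ACGTACGT" + design_n3.constant_5p + insert + design_n3.constant_3p
        fwd, rev = construct[:75], revcomp(construct)[:75]
        (tmp_path / "r1.fq").write_text(f"@r/1\n{fwd}\n+\n{'F' * 75}\n")
        (tmp_path / "r2.fq").write_text(f"@r/2\n{rev}\n+\n{'F' * 75}\n")
        table = process_run(tmp_path / "r1.fq", tmp_path / "r2.fq", design_n3,
                            {"ACGTACGT": "naive"})
        assert table.depth["naive"] == 0
        assert table.audit == {("naive", "FAIL_STOP"): 1}

    def test_empty_fastq(self, design_n3, tmp_path):
        (tmp_path / "r1.fq").write_text("")
        (tmp_path / "r2.fq").write_text("")
        table = process_run(tmp_path / "r1.fq", tmp_path / "r2.fq", design_n3,
                            {"ACGTACGT": "naive"})
        assert table.counts == {} and table.depth["naive"] == 0

    def test_off_design_deletion_kept_and_flagged(self, design_full, tmp_path):
        # an n3-sized insert whose peptide violates the pattern (A at pos 1)
        insert = reverse_translate("AICRFFC")
        construct = "ACGTACGT" + design_full.constant_5p + insert + design_full.constant_3p
        fwd, rev = construct[:75], revcomp(construct)[:75]
        (tmp_path / "r1.fq").write_text(f"@r/1\n{fwd}\n+\n{'F' * 75}\n")
        (tmp_path / "r2.fq").write_text(f"@r/2\n{rev}\n+\n{'F' * 75}\n")
        table = process_run(tmp_path / "r1.fq", tmp_path / "r2.fq", design_full,
                            {"ACGTACGT": "naive"})
        assert table.counts == {("AICRFFC", "naive"): 1}
        assert table.audit == {("naive", "OFF_DESIGN_KEPT"): 1}
        assert table.architecture["AICRFFC"] == "off_design"


class TestCountTableIO:
    def test_tsv_roundtrip(self, small_campaign, tmp_path):
        man = small_campaign["manifest"]
        table = process_run(man["r1"], man["r2"], small_campaign["design"],
                            small_campaign["barcode_map"])
        path = tmp_path / "counts.tsv"
        table.to_tsv(path)
        loaded = CountTable.from_tsv(path)
        assert loaded.depth == table.depth
        assert loaded.counts == table.counts
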