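"""Synthetic selection campaigns with known ground truth.

Generates a long-tailed naive phage population, applies one round of
selection as per-sequence frequency reweighting (planted binders carry an
enrichment factor λ; everything else λ = 1), and renders the populations as
multiplexed paired-end FASTQ with barcodes, constant priming regions and
substitution sequencing errors.  The rendered reads emulate a 2×75-cycle
paired-end run over the construct

    barcode + constant_5p + variable insert + constant_3p

so the read-deconvolution pipeline can be exercised end-to-end against the
manifest of true counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .library import (
    LibraryDesign,
    PeptideRecord,
    classify_architecture,
    reverse_translate,
    theoretical_diversity,
)

__all__ = [
    "SimulationConfig",
    "Population",
    "CapacityError",
    "DegenerateSelectionError",
    "generate_naive_population",
    "simulate_selection_round",
    "render_fastq_run",
    "sample_counts",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: default per-base quality for correct bases (Phred 37 -> 'F')
_HIGH_Q = chr(33 + 37)
_LOW_Q = chr(33 + 2)


class CapacityError(ValueError):
    """Requested more distinct variants than the library can hold."""


class DegenerateSelectionError(ValueError):
    """Selection reweighting annihilated the whole population."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic campaign.

    Defaults mirror a single-round solution-panning campaign read out on a
    2×75 paired-end run: 10^4 distinct n=3 variants with log-normal naive
    abundances (σ = 1.5, a long-tailed naive pool), 10^5 read pairs per
    experiment, substitution errors at 10⁻³/base, and planted binders at
    naive frequency 10⁻³ with enrichment factor λ.
    """

    n_variants: int = 10_000
    cycle_size: int = 3
    abundance_model: str = "log_normal"   # or "uniform"
    log_normal_mu: float = 0.0
    log_normal_sigma: float = 1.5
    planted: tuple[tuple[str, float], ...] = ()
    planted_naive_freq: float | None = 1e-3
    reads_per_experiment: int = 100_000
    error_rate: float = 1e-3
    read_length: int = 75
    low_quality_fraction: float = 0.0
    seed: int = 0
    barcode_assignment: Mapping[str, str] = field(
        default_factory=lambda: {"naive": "ACGTACGT"})

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")
        if self.reads_per_experiment < 0:
            raise ValueError("reads_per_experiment must be nonnegative")
        lengths = {len(b) for b in self.barcode_assignment.values()}
        if len(self.barcode_assignment) and len(lengths) != 1:
            raise ValueError("all barcodes must share one length")
        barcodes = list(self.barcode_assignment.values())
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("barcodes must be distinct")


@dataclass
class Population:
    """A weighted peptide population (frequencies sum to 1)."""

    records: list[tuple[PeptideRecord, float]]
    label: str = ""

    def __post_init__(self) -> None:
        freqs = np.array([f for _, f in self.records], dtype=float)
        if len(freqs) and (freqs < 0).any():
            raise ValueError("negative frequency")
        if len(freqs) and abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {freqs.sum()}, expected 1")

    @property
    def peptides(self) -> list[str]:
        return [rec.peptide for rec, _ in self.records]

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([f for _, f in self.records], dtype=float)


def _decode_variant(index: int, design: LibraryDesign, n: int) -> str:
    """Map an integer in [0, a^(n+1)) to an in-design peptide."""
    alphabet = design.variable_alphabet
    a = len(alphabet)
    slots = design.n_variable_positions(n)
    letters = []
    for _ in range(slots):
        index, r = divmod(index, a)
        letters.append(alphabet[r])
    x = letters[::-1]
    return "S" + x[0] + "C" + "".join(x[1:]) + "C"


def generate_naive_population(design: LibraryDesign,
                              config: SimulationConfig) -> Population:
    """Draw a naive library: distinct in-design variants with model abundances.

    Planted peptides are always included; when ``planted_naive_freq`` is set
    they are pinned at that frequency and the remaining mass is shared by the
    background variants according to the abundance model.
    """
    n = config.cycle_size
    capacity = theoretical_diversity(design, n, len(design.variable_alphabet))
    if config.n_variants > capacity:
        raise CapacityError(
            f"{config.n_variants} variants requested but design holds {capacity}")

    planted_peps = [p for p, _ in config.planted]
    for pep in planted_peps:
        if classify_architecture(pep, design) != f"n{n}":
            raise ValueError(f"planted peptide {pep} is not an n{n} design")

    rng = np.random.default_rng(config.seed)
    n_background = config.n_variants - len(planted_peps)
    if n_background < 0:
        raise CapacityError("more planted peptides than n_variants")

    taken = set(planted_peps)
    background: list[str] = []
    if n_background == 0:
        pass
    elif capacity <= 2_000_000:
        order = rng.permutation(capacity)
        for idx in order:
            pep = _decode_variant(int(idx), design, n)
            if pep not in taken:
                background.append(pep)
                taken.add(pep)
                if len(background) == n_background:
                    break
    else:  # rejection sampling for huge spaces
        while len(background) < n_background:
            pep = _decode_variant(int(rng.integers(capacity)), design, n)
            if pep not in taken:
                background.append(pep)
                taken.add(pep)

    peptides = planted_peps + background
    if config.abundance_model == "uniform":
        weights = np.ones(len(peptides))
    elif config.abundance_model == "log_normal":
        weights = rng.lognormal(config.log_normal_mu, config.log_normal_sigma,
                                size=len(peptides))
    else:
        raise ValueError(f"unknown abundance model {config.abundance_model!r}")

    freqs = weights / weights.sum()
    if config.planted_naive_freq is not None and planted_peps:
        k = len(planted_peps)
        pinned = config.planted_naive_freq
        if pinned * k >= 1.0:
            raise ValueError("planted frequencies exceed unit mass")
        freqs[k:] *= (1.0 - pinned * k) / freqs[k:].sum()
        freqs[:k] = pinned

    records = [(PeptideRecord(peptide=p, dna=reverse_translate(p),
                              architecture_class=f"n{n}"), float(f))
               for p, f in zip(peptides, freqs)]
    return Population(records=records, label="naive")


def simulate_selection_round(naive: Population,
                             config: SimulationConfig,
                             label: str = "selected") -> Population:
    """One selection round as frequency reweighting: f_i -> λ_i f_i / Σ λ_j f_j."""
    lam = {pep: lam_i for pep, lam_i in config.planted}
    missing = set(lam) - set(naive.peptides)
    if missing:
        raise ValueError(f"planted peptides absent from naive pool: {missing}")
    weights = np.array([lam.get(rec.peptide, 1.0) * f
                        for rec, f in naive.records])
    total = weights.sum()
    if total <= 0:
        raise DegenerateSelectionError("all λ·f products are zero")
    freqs = weights / total
    records = [(rec, float(f)) for (rec, _), f in zip(naive.records, freqs)]
    return Population(records=records, label=label)


def sample_counts(population: Population, n_reads: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Multinomial read counts over the population's variants."""
    if n_reads == 0:
        return np.zeros(len(population.records), dtype=np.int64)
    return rng.multinomial(n_reads, population.frequencies)


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BYTE_TO_IDX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BYTE_TO_IDX[_b] = _i


def _apply_substitutions(reads: np.ndarray, error_rate: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Independent per-base substitutions on a (n_reads, read_len) byte matrix."""
    if error_rate == 0.0 or reads.size == 0:
        return reads
    mask = rng.random(reads.shape) < error_rate
    n_err = int(mask.sum())
    if n_err == 0:
        return reads
    orig_idx = _BYTE_TO_IDX[reads[mask]]
    shift = rng.integers(1, 4, size=n_err)
    reads[mask] = _BASE_BYTES[(orig_idx + shift) % 4]
    return reads


def render_fastq_run(populations: Sequence[Population],
                     design: LibraryDesign,
                     config: SimulationConfig,
                     outdir: str | Path) -> dict:
    """Render populations as one multiplexed paired-end FASTQ run.

    Forward read: barcode + constant_5p + insert + constant_3p prefix,
    truncated to ``read_length``.  Reverse read: reverse complement of the
    construct's 3' end, same length.  Substitution errors are applied
    independently per base; qualities are Q37 except for an optional
    fraction of read pairs demoted to Q2 to exercise the quality filter.

    Returns a manifest dict with FASTQ paths and a ground-truth count table
    (``manifest["truth"]``: peptide × experiment true counts).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    bl = config.read_length

    r1_path = outdir / "run_R1.fastq"
    r2_path = outdir / "run_R2.fastq"
    truth_rows = []
    r1_chunks: list[str] = []
    r2_chunks: list[str] = []
    serial = 0

    for pop in populations:
        if pop.label not in config.barcode_assignment:
            raise ValueError(f"no barcode assigned to experiment {pop.label!r}")
        barcode = config.barcode_assignment[pop.label]
        counts = sample_counts(pop, config.reads_per_experiment, rng)

        fwd_templates = []
        rev_templates = []
        for rec, _ in pop.records:
            construct = barcode + design.constant_5p + rec.dna + design.constant_3p
            fwd_templates.append(construct[:bl].ljust(bl, "A"))
            rev_templates.append(revcomp(construct)[:bl].ljust(bl, "A"))

        for (rec, freq), c in zip(pop.records, counts):
            truth_rows.append((rec.peptide, rec.dna, pop.label, int(c), freq))

        nonzero = np.flatnonzero(counts)
        if len(nonzero) == 0:
            continue
        fwd_mat = np.frombuffer(
            "".join(fwd_templates[i] for i in nonzero).encode(), dtype=np.uint8
        ).reshape(len(nonzero), bl).copy()
        rev_mat = np.frombuffer(
            "".join(rev_templates[i] for i in nonzero).encode(), dtype=np.uint8
        ).reshape(len(nonzero), bl).copy()
        reps = counts[nonzero]
        fwd_mat = np.repeat(fwd_mat, reps, axis=0)
        rev_mat = np.repeat(rev_mat, reps, axis=0)

        fwd_mat = _apply_substitutions(fwd_mat, config.error_rate, rng)
        rev_mat = _apply_substitutions(rev_mat, config.error_rate, rng)

        n_reads = fwd_mat.shape[0]
        high_qual = _HIGH_Q * bl
        low_qual = _LOW_Q * bl
        low_mask = (rng.random(n_reads) < config.low_quality_fraction
                    if config.low_quality_fraction > 0
                    else np.zeros(n_reads, dtype=bool))

        for i in range(n_reads):
            rid = f"@sim_{pop.label}_{serial}"
            serial += 1
            qual = low_qual if low_mask[i] else high_qual
            r1_chunks.append(
                f"{rid}/1\n{fwd_mat[i].tobytes().decode()}\n+\n{qual}\n")
            r2_chunks.append(
                f"{rid}/2\n{rev_mat[i].tobytes().decode()}\n+\n{qual}\n")

    r1_path.write_text("".join(r1_chunks))
    r2_path.write_text("".join(r2_chunks))

    truth = pd.DataFrame(
        truth_rows,
        columns=["peptide", "dna", "experiment", "true_count", "frequency"])
    manifest_path = outdir / "manifest.tsv"
    truth.to_csv(manifest_path, sep="\t", index=False)
    return {
        "r1": r1_path,
        "r2": r2_path,
        "manifest": manifest_path,
        "truth": truth,
        "barcodes": dict(config.barcode_assignment),
    }
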