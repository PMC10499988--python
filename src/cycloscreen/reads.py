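"""Deconvolution of paired-end display-library reads into peptide counts.

The pipeline follows the published processing order: per-base quality
discard, exact barcode demultiplexing, priming-region matching at fixed
offsets allowing at most one base substitution per region, strict
forward–reverse agreement (zero mismatches) over the variable-region window,
then translation and architecture classification.  Coordinates are 0-based
half-open; the reverse mate is reverse-complemented before any comparison;
no indel-aware alignment is attempted anywhere (substitution-only error
model).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .library import LibraryDesign, translate_variable_region
from .simulate import revcomp

__all__ = [
    "ReadPair",
    "ProcessedRecord",
    "CountTable",
    "ConfigError",
    "UNASSIGNED",
    "quality_filter",
    "demultiplex",
    "match_constant_region",
    "merge_pair_extract",
    "process_run",
]

UNASSIGNED = "UNASSIGNED"

STATUSES = ("OK", "FAIL_QUALITY", "FAIL_BARCODE", "FAIL_PRIMER_F",
            "FAIL_PRIMER_R", "FAIL_FR_MISMATCH", "FAIL_STOP",
            "OFF_DESIGN_KEPT")


class ConfigError(ValueError):
    """Invalid processing configuration (e.g. duplicate barcodes)."""


@dataclass(frozen=True)
class ReadPair:
    id: str
    fwd_seq: str
    rev_seq: str
    fwd_qual: str  # Phred+33 ASCII
    rev_qual: str

    def __post_init__(self) -> None:
        if len(self.fwd_seq) != len(self.fwd_qual) or len(self.rev_seq) != len(self.rev_qual):
            raise ValueError(f"sequence/quality length mismatch in read {self.id}")


@dataclass
class ProcessedRecord:
    read_id: str
    barcode_id: str = UNASSIGNED
    status: str = "FAIL_QUALITY"
    dna_insert: str = ""
    peptide: str = ""
    architecture_class: str = ""


@dataclass
class CountTable:
    """Peptide × experiment counts with per-experiment depth and audit."""

    experiments: list[str]
    counts: dict = field(default_factory=dict)       # (peptide, experiment) -> int
    depth: dict = field(default_factory=dict)        # experiment -> kept reads
    audit: dict = field(default_factory=dict)        # (experiment|UNASSIGNED, status) -> int
    dna: dict = field(default_factory=dict)          # peptide -> representative insert
    architecture: dict = field(default_factory=dict)  # peptide -> class

    def to_dataframe(self) -> pd.DataFrame:
        peptides = sorted({p for p, _ in self.counts})
        data = {"peptide": peptides,
                "dna": [self.dna.get(p, "") for p in peptides],
                "architecture": [self.architecture.get(p, "") for p in peptides]}
        for exp in self.experiments:
            data[exp] = [self.counts.get((p, exp), 0) for p in peptides]
        return pd.DataFrame(data)

    def audit_dataframe(self) -> pd.DataFrame:
        rows = [(exp, status, n) for (exp, status), n in sorted(self.audit.items())]
        return pd.DataFrame(rows, columns=["experiment", "status", "reads"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        """Read a count TSV (this package's format, or any table whose first
        column is the peptide and remaining numeric columns are experiments —
        the documented route for externally exported count tables)."""
        df = pd.read_csv(path, sep="\t")
        meta = [c for c in ("peptide", "dna", "architecture") if c in df.columns]
        if "peptide" not in meta:
            df = df.rename(columns={df.columns[0]: "peptide"})
            meta = ["peptide"] + [c for c in ("dna", "architecture") if c in df.columns]
        experiments = [c for c in df.columns if c not in meta]
        table = cls(experiments=experiments)
        for row in df.itertuples(index=False):
            pep = getattr(row, "peptide")
            table.dna[pep] = getattr(row, "dna", "")
            table.architecture[pep] = getattr(row, "architecture", "")
            for exp in experiments:
                c = int(getattr(row, exp))
                if c:
                    table.counts[(pep, exp)] = c
        for exp in experiments:
            table.depth[exp] = int(df[exp].sum())
        return table


def _min_phred(qual: str) -> int:
    return min(qual.encode()) - 33


def quality_filter(pair: ReadPair, min_q: int) -> bool:
    """True iff every base on both mates reaches ``min_q`` (Phred+33).

    At 2×75 over barcode + priming regions + insert the reads are
    interrogated span end to end, so the whole read is checked.
    """
    if min_q <= 0:
        return True
    return _min_phred(pair.fwd_qual) >= min_q and _min_phred(pair.rev_qual) >= min_q


def _validate_barcodes(barcode_map: Mapping[str, str]) -> int:
    if not barcode_map:
        raise ConfigError("empty barcode map")
    lengths = {len(b) for b in barcode_map}
    if len(lengths) != 1:
        raise ConfigError("barcodes must share one length")
    return lengths.pop()


def demultiplex(pair: ReadPair, barcode_map: Mapping[str, str]) -> str:
    """Exact-match the leading barcode of the forward read; no partial credit.

    ``barcode_map`` maps barcode DNA -> experiment name.
    """
    bl = _validate_barcodes(barcode_map)
    return barcode_map.get(pair.fwd_seq[:bl], UNASSIGNED)


def match_constant_region(seq: str, expected: str, offset: int,
                          max_sub: int = 1) -> tuple[bool, int | None]:
    """Hamming-compare ``expected`` against ``seq`` at a fixed offset.

    Returns (matched, substitution count); a span running past the read end
    is a fail (reported upstream as a primer fail).  No indel search.
    """
    end = offset + len(expected)
    if offset < 0 or end > len(seq):
        return False, None
    window = seq[offset:end]
    if window == expected:
        return True, 0
    subs = sum(a != b for a, b in zip(window, expected))
    return subs <= max_sub, subs


def merge_pair_extract(pair: ReadPair, design: LibraryDesign,
                       cycle_size: int) -> str | None:
    """Extract the variable-region insert, requiring exact F/R agreement.

    The forward window sits at ``barcode_length + |constant_5p|``; the
    reverse-complemented reverse mate covers the construct's 3' end, so its
    window ends ``|constant_3p|`` bases before the read end.  Any mismatch
    between the two windows returns None (FAIL_FR_MISMATCH upstream).
    """
    ins_len = design.insert_length(cycle_size)
    f_start = design.barcode_length + len(design.constant_5p)
    insert_f = pair.fwd_seq[f_start:f_start + ins_len]
    if len(insert_f) < ins_len:
        return None
    rc_rev = revcomp(pair.rev_seq)
    r_end = len(rc_rev) - len(design.constant_3p)
    insert_r = rc_rev[r_end - ins_len:r_end]
    if len(insert_r) != ins_len:
        return None
    return insert_f if insert_f == insert_r else None


def _resolve_insert(pair: ReadPair, design: LibraryDesign) -> str | None:
    """Find the cycle size whose 3' anchor and F/R windows agree.

    Cycle sizes are tried in ascending order; a size is accepted when the
    forward read carries the constant_3p prefix at the expected offset
    (≤1 substitution over the overlapping span) and the F and R variable
    windows agree exactly.
    """
    f_start = design.barcode_length + len(design.constant_5p)
    for n in sorted(design.cycle_sizes):
        anchor_off = f_start + design.insert_length(n)
        span = min(len(design.constant_3p), len(pair.fwd_seq) - anchor_off)
        if span < 6:
            continue
        ok, _ = match_constant_region(pair.fwd_seq,
                                      design.constant_3p[:span], anchor_off)
        if not ok:
            continue
        insert = merge_pair_extract(pair, design, n)
        if insert is not None:
            return insert
    return None


def parse_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[ReadPair]:
    with open(r1_path) as fh1, open(r2_path) as fh2:
        for (id1, seq1, q1), (id2, seq2, q2) in zip(
                FastqGeneralIterator(fh1), FastqGeneralIterator(fh2), strict=True):
            yield ReadPair(id=id1.split("/")[0].split()[0],
                           fwd_seq=seq1, rev_seq=seq2, fwd_qual=q1, rev_qual=q2)


def process_pair(pair: ReadPair, design: LibraryDesign,
                 barcode_map: Mapping[str, str], min_q: int = 20,
                 _translation_cache: dict | None = None) -> ProcessedRecord:
    """Run one read pair through the full deconvolution cascade."""
    rec = ProcessedRecord(read_id=pair.id)
    if not quality_filter(pair, min_q):
        rec.status = "FAIL_QUALITY"
        return rec
    experiment = demultiplex(pair, barcode_map)
    rec.barcode_id = experiment
    if experiment == UNASSIGNED:
        rec.status = "FAIL_BARCODE"
        return rec

    ok_f, _ = match_constant_region(pair.fwd_seq, design.constant_5p,
                                    design.barcode_length)
    if not ok_f:
        rec.status = "FAIL_PRIMER_F"
        return rec
    ok_r, _ = match_constant_region(pair.rev_seq, revcomp(design.constant_3p), 0)
    if not ok_r:
        rec.status = "FAIL_PRIMER_R"
        return rec

    insert = _resolve_insert(pair, design)
    if insert is None:
        rec.status = "FAIL_FR_MISMATCH"
        return rec
    rec.dna_insert = insert

    cache = _translation_cache if _translation_cache is not None else {}
    if insert in cache:
        peptide, contains_stop, arch = cache[insert]
    else:
        prec = translate_variable_region(insert)
        peptide, contains_stop = prec.peptide, prec.contains_stop
        arch = prec.architecture_class
        cache[insert] = (peptide, contains_stop, arch)

    if contains_stop:
        rec.status = "FAIL_STOP"
        return rec
    rec.peptide = peptide
    rec.architecture_class = arch
    rec.status = "OK" if arch != "off_design" else "OFF_DESIGN_KEPT"
    return rec


def process_run(r1_path: str | Path, r2_path: str | Path,
                design: LibraryDesign, barcode_map: Mapping[str, str],
                min_q: int = 20,
                keep_records: bool = False,
                ) -> CountTable | tuple[CountTable, list[ProcessedRecord]]:
    """Deconvolute a multiplexed paired-end run into a peptide count table.

    Both OK and OFF_DESIGN_KEPT records contribute counts (off-design
    peptides — e.g. deletion products — are kept but flagged); audit tallies
    conserve the total number of input read pairs.
    """
    _validate_barcodes(barcode_map)
    experiments = list(dict.fromkeys(barcode_map.values()))
    table = CountTable(experiments=experiments)
    audit: Counter = Counter()
    counts: Counter = Counter()
    records: list[ProcessedRecord] = []
    cache: dict = {}

    for pair in parse_fastq_pairs(r1_path, r2_path):
        rec = process_pair(pair, design, barcode_map, min_q=min_q,
                           _translation_cache=cache)
        exp = rec.barcode_id if rec.barcode_id != UNASSIGNED else UNASSIGNED
        audit[(exp, rec.status)] += 1
        if rec.status in ("OK", "OFF_DESIGN_KEPT"):
            counts[(rec.peptide, exp)] += 1
            if rec.peptide not in table.dna:
                table.dna[rec.peptide] = rec.dna_insert
                table.architecture[rec.peptide] = rec.architecture_class
        if keep_records:
            records.append(rec)

    table.counts = dict(counts)
    table.audit = dict(audit)
    for exp in experiments:
        table.depth[exp] = sum(c for (p, e), c in counts.items() if e == exp)
    return (table, records) if keep_records else table
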