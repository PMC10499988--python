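"""Motif analysis of hit peptides: position frequencies, dipeptide
enrichment, and Hamming-distance family clustering with consensus calling."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .library import AMINO_ACIDS

__all__ = [
    "HeterogeneityError",
    "position_frequency_matrix",
    "DipeptideMatrix",
    "dipeptide_enrichment",
    "cluster_families",
    "Consensus",
    "consensus_from_family",
    "top_hits",
]


class HeterogeneityError(ValueError):
    """Hit set mixes architectures / lengths where one is required."""


def _require_equal_lengths(hits: list[str]) -> int:
    if not hits:
        raise HeterogeneityError("empty hit list")
    lengths = {len(h) for h in hits}
    if len(lengths) != 1:
        raise HeterogeneityError(f"mixed peptide lengths: {sorted(lengths)}")
    return lengths.pop()


def position_frequency_matrix(hits: list[str]) -> pd.DataFrame:
    """Column-normalised amino-acid frequencies per position (1-based index).

    Rows are positions, columns the 20 canonical amino acids; each row sums
    to 1.  All hits must share one architecture (equal length).
    """
    length = _require_equal_lengths(hits)
    mat = np.zeros((length, len(AMINO_ACIDS)))
    aa_index = {aa: j for j, aa in enumerate(AMINO_ACIDS)}
    for pep in hits:
        for i, aa in enumerate(pep):
            mat[i, aa_index[aa]] += 1
    mat /= len(hits)
    return pd.DataFrame(mat, index=pd.RangeIndex(1, length + 1, name="position"),
                        columns=list(AMINO_ACIDS))


@dataclass
class DipeptideMatrix:
    """Observed vs expected ordered adjacent residue pairs (20 × 20)."""

    counts: pd.DataFrame
    expected: pd.DataFrame
    enrichment: pd.DataFrame
    total_pairs: int


def dipeptide_enrichment(hits: list[str],
                         background: str = "positional_independence",
                         pseudocount: float = 1.0,
                         naive_frequencies: dict[str, float] | None = None,
                         ) -> DipeptideMatrix:
    """Ordered adjacent residue-pair counts and their enrichment over a null.

    Pairs are taken over the full displayed peptide (fixed S/C positions
    included).  Backgrounds:

    ``positional_independence``
        expected(a,b) = Σ_i n·f_i(a)·f_{i+1}(b): adjacent positions made
        independent while each position keeps its observed composition
        (requires equal-length hits).
    ``naive_frequencies``
        expected(a,b) = total_pairs·p(a)·p(b) with p from a supplied naive
        residue-frequency table.

    enrichment = (observed + pseudocount) / (expected + pseudocount).
    """
    if not hits:
        raise HeterogeneityError("empty hit list")
    aas = list(AMINO_ACIDS)
    counts = pd.DataFrame(0, index=aas, columns=aas, dtype=float)
    total_pairs = 0
    for pep in hits:
        for a, b in zip(pep, pep[1:]):
            counts.loc[a, b] += 1
            total_pairs += 1

    if background == "positional_independence":
        length = _require_equal_lengths(hits)
        pfm = position_frequency_matrix(hits).to_numpy()  # length × 20
        expected_mat = np.zeros((len(aas), len(aas)))
        for i in range(length - 1):
            expected_mat += np.outer(pfm[i], pfm[i + 1])
        expected = pd.DataFrame(expected_mat * len(hits), index=aas, columns=aas)
    elif background == "naive_frequencies":
        if naive_frequencies is None:
            raise ValueError("naive_frequencies background requires a frequency table")
        p = np.array([naive_frequencies.get(aa, 0.0) for aa in aas])
        p = p / p.sum()
        expected = pd.DataFrame(total_pairs * np.outer(p, p), index=aas, columns=aas)
    else:
        raise ValueError(f"unknown background {background!r}")

    enrichment = (counts + pseudocount) / (expected + pseudocount)
    return DipeptideMatrix(counts=counts, expected=expected,
                           enrichment=enrichment, total_pairs=total_pairs)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise HeterogeneityError("unequal lengths in Hamming comparison")
    return sum(x != y for x, y in zip(a, b))


def cluster_families(hits: list[str], max_hamming: int = 2) -> list[list[str]]:
    """Single-linkage families: connected components of the Hamming graph.

    Two peptides are linked when their Hamming distance is ≤ ``max_hamming``;
    families are the connected components, ordered by size (descending) then
    by lexicographically smallest member; members sorted within each family.
    The families partition the input set.
    """
    _require_equal_lengths(hits)
    unique = sorted(set(hits))
    g = nx.Graph()
    g.add_nodes_from(unique)
    for i, a in enumerate(unique):
        for b in unique[i + 1:]:
            if hamming(a, b) <= max_hamming:
                g.add_edge(a, b)
    families = [sorted(c) for c in nx.connected_components(g)]
    families.sort(key=lambda fam: (-len(fam), fam[0]))
    return families


@dataclass(frozen=True)
class Consensus:
    sequence: str
    tie_positions: tuple[int, ...] = ()  # 1-based positions with modal ties

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.sequence


def consensus_from_family(family: list[str]) -> Consensus:
    """Per-position modal residue; ties resolved alphabetically and flagged."""
    length = _require_equal_lengths(family)
    letters = []
    ties = []
    for i in range(length):
        tally = Counter(pep[i] for pep in family)
        best = max(tally.values())
        modal = sorted(aa for aa, c in tally.items() if c == best)
        letters.append(modal[0])
        if len(modal) > 1:
            ties.append(i + 1)
    return Consensus(sequence="".join(letters), tie_positions=tuple(ties))


def top_hits(results: pd.DataFrame, k: int = 25) -> list[str]:
    """Top-k peptides by differential-enrichment evidence.

    Ranks by ascending p_raw, ties by descending fold, then peptide, and
    returns the first ``k`` — the ordering used for hit heat maps.
    """
    df = results.reset_index() if "peptide" not in results.columns else results.copy()
    df = df.sort_values(["p_raw", "fold", "peptide"],
                        ascending=[True, False, True])
    return df["peptide"].head(k).tolist()
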