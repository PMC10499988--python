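"""Differential-enrichment statistics for single-round selection counts.

For each peptide, the test conditions on the total number of times the
peptide was seen across the test and control experiments: under the null of
no differential enrichment, c_test | (c_test + c_ctrl = k) is
Binomial(k, π₀) with π₀ = N_test / (N_test + N_ctrl).  The two-sided p-value
sums the probabilities of all outcomes no more likely than the observed one
(minimum-likelihood method).  This exact conditional test needs no replicate
dispersion estimate, which suits one-round panning where each experiment is
sequenced once.

Fold change is a pseudocount-regularised ratio of depth-normalised
frequencies; the pseudocount touches the fold only, never the exact test.
Hits require p_raw < 0.05 and fold > 3 (strict), intersected across control
comparisons by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .reads import CountTable

__all__ = [
    "DEConfig",
    "EnrichmentResult",
    "normalize_cpm",
    "exact_conditional_p",
    "de_test",
    "de_table",
    "adjust_bh",
    "nominate_hits",
    "volcano_table",
]

#: relative tolerance when deciding pmf ties in the minimum-likelihood sum
_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class DEConfig:
    pseudocount: float = 1.0
    p_threshold: float = 0.05
    fold_threshold: float = 3.0
    adjust: str = "none"              # or "benjamini_hochberg"
    nomination_rule: str = "intersection"  # or "any"

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")
        if self.p_threshold <= 0 or self.fold_threshold <= 0:
            raise ValueError("thresholds must be strictly positive")
        if self.adjust not in ("none", "benjamini_hochberg"):
            raise ValueError(f"unknown adjust mode {self.adjust!r}")
        if self.nomination_rule not in ("intersection", "any"):
            raise ValueError(f"unknown nomination rule {self.nomination_rule!r}")


@dataclass
class EnrichmentResult:
    peptide: str
    c_test: int
    c_ctrl: int
    n_test: int
    n_ctrl: int
    freq_test: float  # counts per million
    freq_ctrl: float
    fold: float
    p_raw: float
    p_adj: float
    comparison: tuple[str, str]
    hit: bool = False


def normalize_cpm(table: CountTable) -> pd.DataFrame:
    """Counts-per-million per experiment (columns sum to 10⁶)."""
    df = table.to_dataframe().set_index("peptide")
    out = {}
    for exp in table.experiments:
        depth = table.depth.get(exp, 0)
        if depth <= 0:
            raise ValueError(f"experiment {exp!r} has zero depth")
        out[exp] = 1e6 * df[exp] / depth
    return pd.DataFrame(out, index=df.index)


def exact_conditional_p(c_test: int, k: int, pi0: float) -> float:
    """Two-sided exact binomial p by minimum-likelihood summation.

    Sums Binomial(k, π₀) probabilities over every outcome whose probability
    does not exceed the observed outcome's (to relative tolerance 1e-12).
    """
    if k == 0:
        return 1.0
    outcomes = np.arange(k + 1)
    pmf = stats.binom.pmf(outcomes, k, pi0)
    p_obs = pmf[c_test]
    p = pmf[pmf <= p_obs * (1.0 + _TIE_RTOL)].sum()
    return float(min(p, 1.0))


def de_test(c_test: int, n_test: int, c_ctrl: int, n_ctrl: int,
            config: DEConfig = DEConfig(),
            peptide: str = "", comparison: tuple[str, str] = ("test", "ctrl"),
            ) -> EnrichmentResult:
    """Exact conditional differential-enrichment test for one peptide."""
    if c_test > n_test or c_ctrl > n_ctrl:
        raise ValueError("count exceeds experiment depth")
    if n_test <= 0 or n_ctrl <= 0:
        raise ValueError("depths must be positive")
    a = config.pseudocount
    fold = ((c_test + a) / n_test) / ((c_ctrl + a) / n_ctrl)
    pi0 = n_test / (n_test + n_ctrl)
    p_raw = exact_conditional_p(c_test, c_test + c_ctrl, pi0)
    return EnrichmentResult(
        peptide=peptide, c_test=c_test, c_ctrl=c_ctrl,
        n_test=n_test, n_ctrl=n_ctrl,
        freq_test=1e6 * c_test / n_test, freq_ctrl=1e6 * c_ctrl / n_ctrl,
        fold=fold, p_raw=p_raw, p_adj=p_raw, comparison=comparison)


def _batch_exact_p(c_test: np.ndarray, k: np.ndarray, pi0: float) -> np.ndarray:
    """Vectorised minimum-likelihood p-values, grouped by total count k."""
    p = np.ones(len(k), dtype=float)
    for kv in np.unique(k):
        if kv == 0:
            continue
        idx = np.flatnonzero(k == kv)
        pmf = stats.binom.pmf(np.arange(kv + 1), int(kv), pi0)
        order = np.argsort(pmf, kind="stable")
        sorted_pmf = pmf[order]
        csum = np.cumsum(sorted_pmf)
        # rank of the largest sorted pmf still <= observed * (1 + rtol)
        obs = pmf[c_test[idx]]
        pos = np.searchsorted(sorted_pmf, obs * (1.0 + _TIE_RTOL), side="right")
        p[idx] = np.minimum(csum[pos - 1], 1.0)
    return p


def de_table(counts: pd.DataFrame, test: str, control: str,
             depths: dict[str, int] | None = None,
             config: DEConfig = DEConfig()) -> pd.DataFrame:
    """Differential enrichment for every peptide of a count table.

    ``counts`` is a peptide-indexed DataFrame with integer count columns;
    depths default to column sums.
    """
    c_t = counts[test].to_numpy(dtype=np.int64)
    c_c = counts[control].to_numpy(dtype=np.int64)
    n_t = int(depths[test]) if depths else int(c_t.sum())
    n_c = int(depths[control]) if depths else int(c_c.sum())
    if n_t <= 0 or n_c <= 0:
        raise ValueError("depths must be positive")
    a = config.pseudocount
    fold = ((c_t + a) / n_t) / ((c_c + a) / n_c)
    p_raw = _batch_exact_p(c_t, c_t + c_c, n_t / (n_t + n_c))
    df = pd.DataFrame({
        "peptide": counts.index,
        "c_test": c_t, "c_ctrl": c_c,
        "n_test": n_t, "n_ctrl": n_c,
        "freq_test": 1e6 * c_t / n_t, "freq_ctrl": 1e6 * c_c / n_c,
        "fold": fold, "p_raw": p_raw,
    }).set_index("peptide")
    df["p_adj"] = (adjust_bh(df["p_raw"].to_numpy())
                   if config.adjust == "benjamini_hochberg"
                   else df["p_raw"])
    p_col = "p_adj" if config.adjust == "benjamini_hochberg" else "p_raw"
    df["hit"] = (df[p_col] < config.p_threshold) & (df["fold"] > config.fold_threshold)
    df.attrs["comparison"] = (test, control)
    return df


def adjust_bh(p_raw: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p_raw, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def nominate_hits(results: dict[str, pd.DataFrame],
                  config: DEConfig = DEConfig(),
                  ) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Per-comparison hit sets and the ranked final hit list.

    A peptide is a per-comparison hit iff p < p_threshold AND
    fold > fold_threshold (both strict).  The final list keeps peptides that
    are hits in every comparison (``intersection``) or in at least one
    (``any``), ranked by ascending worst-case p, ties by descending
    worst-case fold, then peptide.
    """
    if not results:
        raise ValueError("no comparisons supplied")
    per_comp: dict[str, set[str]] = {
        name: set(df.index[df["hit"]]) for name, df in results.items()}
    sets = list(per_comp.values())
    final = (set.intersection(*sets) if config.nomination_rule == "intersection"
             else set.union(*sets))
    rows = []
    for pep in final:
        worst_p = max(df.loc[pep, "p_raw"] for df in results.values())
        worst_fold = min(df.loc[pep, "fold"] for df in results.values())
        rows.append((pep, worst_p, worst_fold))
    ranked = sorted(rows, key=lambda r: (r[1], -r[2], r[0]))
    final_df = pd.DataFrame(ranked, columns=["peptide", "p_raw", "fold"])
    return per_comp, final_df


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """Volcano-plot coordinates: log2 fold vs −log10 p, sorted by evidence."""
    if (results["fold"] <= 0).any():
        raise ValueError("fold must be positive for log transform")
    out = pd.DataFrame({
        "peptide": results.index,
        "log2_fold": np.log2(results["fold"].to_numpy()),
        "neg_log10_p": -np.log10(results["p_raw"].to_numpy()),
        "hit": results["hit"].to_numpy(),
    })
    return out.sort_values("neg_log10_p", ascending=False).reset_index(drop=True)
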