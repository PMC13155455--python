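"""Enrichment statistic, paired effect sizes, and rank-level aggregation.

The enrichment of a real genome over its dinucleotide-preserving shuffled
control is FE = (O − E)/(O + E) ∈ [−1, 1], defined as 0 when O = E. Effect
sizes across paired genome/control densities are the small-sample-corrected
Hedges' g on paired differences, g = J(N−1)·mean(d)/sd(d) with
J(n) = 1 − 3/(4n − 1), and Cliff's δ (paired: 2·P(X>Y) + P(X=Y) − 1;
unpaired: (#{x>y} − #{x<y})/(N·M)). Significance per taxonomic rank uses the
two-sided Wilcoxon signed-rank test with Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class PairedDensities:
    """Paired observed (real) and expected (shuffled-control) densities."""

    unit_ids: list[str]
    observed: np.ndarray
    expected: np.ndarray

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        self.expected = np.asarray(self.expected, dtype=float)
        if not (len(self.unit_ids) == len(self.observed) == len(self.expected)):
            raise ValueError("unit_ids, observed, expected must have equal lengths")
        if not (np.all(np.isfinite(self.observed)) and np.all(np.isfinite(self.expected))):
            raise ValueError("densities must be finite")
        if np.any(self.observed < 0) or np.any(self.expected < 0):
            raise ValueError("densities must be non-negative")

    def __len__(self) -> int:
        return len(self.unit_ids)


def enrichment_fe(observed: float, expected: float) -> float:
    """(O − E)/(O + E); 0 when O = E (including O = E = 0)."""
    if observed < 0 or expected < 0:
        raise ValueError("observed and expected must be non-negative")
    if observed == expected:
        return 0.0
    return (observed - expected) / (observed + expected)


def hedges_j(n: int) -> float:
    """Small-sample correction J(n) = 1 − 3/(4n − 1)."""
    return 1.0 - 3.0 / (4.0 * n - 1.0)


def hedges_g_paired(pairs: PairedDensities, sd_mode: str = "sample") -> float:
    """J(N−1)-corrected standardized mean of paired differences.

    sd_mode="sample" (default) uses the n−1 denominator; "population" uses n.
    Raises on N < 2 or zero-variance differences (undefined effect size).
    """
    d = pairs.observed - pairs.expected
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    ddof = 1 if sd_mode == "sample" else 0
    sd = float(np.std(d, ddof=ddof))
    if sd == 0:
        raise ZeroDivisionError("all paired differences identical; g undefined")
    return hedges_j(n - 1) * float(np.mean(d)) / sd


def cliffs_delta_paired(pairs: PairedDensities) -> float:
    """2·P(X>Y) + P(X=Y) − 1 with empirical plug-in proportions."""
    n = len(pairs)
    if n < 1:
        raise ValueError("need at least 1 pair")
    gt = float(np.sum(pairs.observed > pairs.expected)) / n
    eq = float(np.sum(pairs.observed == pairs.expected)) / n
    return 2.0 * gt + eq - 1.0


def cliffs_delta_unpaired(x, y) -> float:
    """(#{x > y} − #{x < y}) / (N·M) over all cross pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    diff = x[:, None] - y[None, :]
    return float((np.sum(diff > 0) - np.sum(diff < 0)) / diff.size)


def species_density(assembly_densities) -> float:
    """Species density f(S): mean IR density over the species' assemblies."""
    vals = np.asarray(list(assembly_densities), dtype=float)
    if vals.size == 0:
        raise ValueError("empty density list")
    return float(np.mean(vals))


def rank_density(species_densities) -> float:
    """Rank density F(R): mean of member-species densities f(S_j)."""
    vals = np.asarray(list(species_densities), dtype=float)
    if vals.size == 0:
        raise ValueError("empty density list")
    return float(np.mean(vals))


def paired_test_with_bh(
    groups: dict[str, PairedDensities], alpha: float = 0.05, sd_mode: str = "sample"
) -> pd.DataFrame:
    """Per-rank Wilcoxon signed-rank tests with BH adjustment across ranks.

    Returns one row per rank: n, W statistic, p, p_adj, significant, Hedges' g,
    paired Cliff's δ, mean FE, and a ``flagged`` column for degenerate groups
    (all-zero differences), whose p/p_adj are NaN and excluded from BH.
    """
    rows = []
    for rank, pairs in groups.items():
        if len(pairs) < 2:
            raise ValueError(f"rank {rank!r}: need at least 2 pairs")
        d = pairs.observed - pairs.expected
        flagged = bool(np.all(d == 0))
        if flagged:
            w = p = np.nan
        else:
            w, p = stats.wilcoxon(pairs.observed, pairs.expected, alternative="two-sided")
        try:
            g = hedges_g_paired(pairs, sd_mode=sd_mode)
        except ZeroDivisionError:
            g = np.nan
        fe = np.mean(
            [enrichment_fe(o, e) for o, e in zip(pairs.observed, pairs.expected)]
        )
        rows.append(
            dict(
                rank=rank,
                n=len(pairs),
                W=w,
                p=p,
                g=g,
                delta=cliffs_delta_paired(pairs),
                mean_fe=float(fe),
                flagged=flagged,
            )
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = np.nan
    ok = df["p"].notna()
    if ok.any():
        _, p_adj, _, _ = multipletests(df.loc[ok, "p"].to_numpy(), alpha=alpha, method="fdr_bh")
        df.loc[ok, "p_adj"] = p_adj
    df["significant"] = df["p_adj"] < alpha
    return df[["rank", "n", "W", "p", "p_adj", "significant", "g", "delta", "mean_fe", "flagged"]]
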