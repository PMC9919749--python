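"""Activity ratios and abundance-vs-performance correlation screens.

Two observational layers support the ecology analysis: the
rRNA : rRNA-gene relative-abundance ratio as a proxy for metabolic
activity of a taxon, and a Spearman rank-correlation screen linking
taxon abundances to treatment-plant performance variables (BOD/COD/
NH4-N/TN/TP removal, conductivity, hydraulic retention time, pH) with
Benjamini-Hochberg FDR control.  Group comparisons (aerobic vs
anaerobic sludge, transcript vs gene abundances) use the Mann-Whitney U
test (unpaired) or the paired Wilcoxon signed-rank test.

Statistical conventions: mid-ranks for ties throughout; Spearman p via
the t approximation for n > 10 and exact permutation for n <= 10; rank
tests use the exact null for n <= 12 and tie-free data, otherwise a
normal approximation with tie and continuity corrections (the switch is
logged).  BH families default to per-variable, matching screens where
each performance metric has its own sample count.
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "activity_ratio",
    "activity_table",
    "spearman",
    "bh_adjust",
    "group_compare",
    "kruskal_groups",
    "CorrelationScreen",
    "correlation_screen",
]

logger = logging.getLogger(__name__)


def activity_ratio(rna_relab: float, dna_relab: float) -> float:
    """rRNA : rRNA-gene relative-abundance ratio; NaN when the gene-based
    abundance is zero (undefined)."""
    for name, v in (("rna_relab", rna_relab), ("dna_relab", dna_relab)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if dna_relab == 0.0:
        return float("nan")
    return rna_relab / dna_relab


def activity_table(
    rna_relab: Mapping[str, float], dna_relab: Mapping[str, float]
) -> pd.DataFrame:
    """Per-taxon activity ratios over the union of taxa."""
    taxa = sorted(set(rna_relab) | set(dna_relab))
    rows = []
    for t in taxa:
        r = rna_relab.get(t, 0.0)
        d = dna_relab.get(t, 0.0)
        rows.append({
            "taxon": t, "rna_relab": r, "dna_relab": d,
            "ratio": activity_ratio(r, d),
        })
    return pd.DataFrame(rows)


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, r_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's rho (n <= 10)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
    obs = abs(r_obs) - 1e-12
    n_extreme = 0
    n_total = 0
    for perm in itertools.permutations(ry_c):
        r = float(np.dot(rx_c, perm)) / denom
        n_extreme += abs(r) >= obs
        n_total += 1
    return n_extreme / n_total


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    r_s is the Pearson correlation of mid-ranks.  For n <= 10 the
    p-value is computed by exhaustive permutation; for larger n the
    t approximation is used.  Constant input yields (nan, nan).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 4:
        raise ValueError(f"spearman requires n >= 4, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.info("spearman: constant input vector; correlation undefined")
        return float("nan"), float("nan")
    r, p_approx = stats.spearmanr(x, y)
    if n <= 10:
        return float(r), _exact_spearman_p(x, y, float(r))
    return float(r), float(p_approx)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _has_ties(v: np.ndarray) -> bool:
    return len(np.unique(v)) < len(v)


def group_compare(
    a: Sequence[float], b: Sequence[float], paired: bool = False
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (unpaired) or Wilcoxon signed-rank
    (paired) comparison.

    Exact null distribution for n <= 12 without ties; otherwise a normal
    approximation with tie/continuity correction (logged).  Identical
    paired vectors (no non-zero differences) return p = 1.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired comparison requires equal lengths")
        if len(a) < 5:
            raise ValueError("paired comparison requires n >= 5")
        d = a - b
        nz = d[d != 0]
        if nz.size == 0:
            return 0.0, 1.0
        if nz.size <= 12 and not _has_ties(np.abs(nz)):
            method = "exact"
        else:
            method = "approx"
            logger.info("wilcoxon: ties or n > 12, using normal approximation")
        res = stats.wilcoxon(a, b, alternative="two-sided", method=method,
                             correction=(method == "approx"))
        return float(res.statistic), float(res.pvalue)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("unpaired comparison requires n >= 3 per group")
    pooled = np.concatenate([a, b])
    if max(len(a), len(b)) <= 12 and not _has_ties(pooled):
        method = "exact"
    else:
        method = "asymptotic"
        logger.info("mannwhitneyu: ties or n > 12, using normal approximation")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_groups(*groups: Sequence[float]) -> tuple[float, float]:
    """Kruskal-Wallis H across several groups (tie-corrected); thin
    convenience wrapper for multi-group abundance comparisons."""
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


RESULT_COLUMNS = ["taxon", "variable", "n", "r_s", "p", "p_adj", "significant"]


class CorrelationScreen(BaseEstimator):
    """Taxon-abundance vs sample-variable Spearman screen with FDR control.

    ``fit(abundance, metadata)`` takes a taxa x samples abundance table
    and a samples x variables metadata table (shared sample ids), runs
    pairwise-complete Spearman correlations, and adjusts p-values with
    Benjamini-Hochberg within the chosen family.

    Parameters
    ----------
    alpha : default 0.05
        FDR level; significant <=> p_adj < alpha (strict).
    family : {'per_variable', 'global'}
        BH family: per-variable corrects each performance metric across
        taxa (each metric has its own n); 'global' pools all pairs.
    min_n : default 4
        Minimum overlapping samples per pair.

    Attributes
    ----------
    results_ : DataFrame with columns taxon, variable, n, r_s, p, p_adj,
        significant.
    skipped_ : list of (taxon, variable, reason) for pairs without a
        defined correlation (constant vectors, insufficient overlap).
    """

    def __init__(self, alpha: float = 0.05, family: str = "per_variable",
                 min_n: int = 4):
        self.alpha = alpha
        self.family = family
        self.min_n = min_n

    def fit(self, X: pd.DataFrame, y: pd.DataFrame):
        if self.family not in ("per_variable", "global"):
            raise ValueError("family must be 'per_variable' or 'global'")
        abundance, metadata = X, y
        samples = [s for s in abundance.columns if s in metadata.index]
        if not samples:
            raise ValueError("no overlapping samples between abundance and metadata")

        rows = []
        skipped = []
        for variable in metadata.columns:
            mvals = metadata.loc[samples, variable].astype(float)
            for taxon in abundance.index:
                avals = abundance.loc[taxon, samples].astype(float)
                mask = ~(avals.isna() | mvals.isna())
                n = int(mask.sum())
                if n < self.min_n:
                    skipped.append((taxon, variable, f"only {n} complete pairs"))
                    continue
                xa = avals[mask].to_numpy()
                xm = mvals[mask].to_numpy()
                if np.ptp(xa) == 0 or np.ptp(xm) == 0:
                    skipped.append((taxon, variable, "constant vector"))
                    logger.info(
                        "correlation_screen: skipping %s ~ %s (constant vector)",
                        taxon, variable,
                    )
                    continue
                r, p = spearman(xa, xm)
                rows.append({
                    "taxon": taxon, "variable": variable, "n": n,
                    "r_s": r, "p": p,
                })

        res = pd.DataFrame(rows, columns=RESULT_COLUMNS[:5])
        if len(res):
            if self.family == "per_variable":
                res["p_adj"] = np.nan
                for variable, idx in res.groupby("variable").groups.items():
                    res.loc[idx, "p_adj"] = bh_adjust(res.loc[idx, "p"].to_numpy())
            else:
                res["p_adj"] = bh_adjust(res["p"].to_numpy())
            res["significant"] = res["p_adj"] < self.alpha
        else:
            res = pd.DataFrame(columns=RESULT_COLUMNS)
        self.results_ = res
        self.skipped_ = skipped
        return self


def correlation_screen(
    abundance: pd.DataFrame,
    metadata: pd.DataFrame,
    alpha: float = 0.05,
    family: str = "per_variable",
    min_n: int = 4,
) -> pd.DataFrame:
    """Functional wrapper over :class:`CorrelationScreen`."""
    return CorrelationScreen(alpha=alpha, family=family, min_n=min_n).fit(
        abundance, metadata
    ).results_
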