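"""Enrichment-factor (EF) computation and incorporator labeling.

The EF infers isotope incorporation of a taxon from paired 13C/12C
gradients::

    EF = r13_heavy / r13_light  -  r12_heavy / r12_light

where each term is the taxon's relative sequence abundance in the
representative heavy or light fraction of the 13C- or 12C-treatment
gradient.  Taxa whose rRNA became heavier in the 13C treatment (but not
in the 12C control treatment) over-represent in the 13C heavy fraction
and obtain EF > 0.  A taxon is called 13C-labeled when EF > 0.1
(strict), after an abundance filter: genera must exceed 1% and ASVs
0.1% relative abundance in the heavy fraction of at least one 13C
treatment x timepoint (strict inequalities throughout, reading the
printed ">" thresholds literally).

Groups (prey x timepoint) whose 12C gradient yielded no usable heavy
data produce records with status ``missing_12C`` and no EF, mirroring
how such groups are dropped from reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .gradient import (
    HEAVY_WINDOW,
    LIGHT_WINDOW,
    DensityWindow,
    GradientSet,
    WindowEmptyError,
    select_representative,
)

__all__ = [
    "FilterConfig",
    "DegenerateInputError",
    "UndefinedRatioError",
    "EmptyExperimentError",
    "DISPLAY_FLOOR",
    "relative_abundance",
    "enrichment_factor",
    "call_labeled",
    "passes_abundance_filter",
    "aggregate_to_genus",
    "display_floor",
    "summarize_ef",
    "IncorporatorDetector",
    "ef_table",
]

#: Positive EFs below this value (and all negative EFs) are clipped to it
#: in visualization exports only; labeling calls never use the floor.
DISPLAY_FLOOR = 10.0 ** -1.5

EF_COLUMNS = [
    "taxon", "level", "prey", "timepoint",
    "r13H", "r13L", "r12H", "r12L",
    "ef", "passed_filter", "labeled", "status",
]


class DegenerateInputError(ValueError):
    """Raised on empty or all-zero count input."""


class UndefinedRatioError(ValueError):
    """Raised when a light-fraction relative abundance is zero."""


class EmptyExperimentError(ValueError):
    """Raised when an experiment contains no 13C gradient."""


@dataclass(frozen=True)
class FilterConfig:
    """Abundance-filter and labeling thresholds.

    genus_min_heavy_relab : proportion, default 0.01
        A genus must strictly exceed this relative abundance in at least
        one 13C heavy fraction to be evaluated.
    asv_min_heavy_relab : proportion, default 0.001
        Same rule at ASV level.
    ef_threshold : default 0.1
        EF must strictly exceed this to call a taxon 13C-labeled.
    pseudocount : reads, default 0.5
        Added to every taxon in a selected fraction before normalization
        so light-fraction abundances stay positive; 0 disables it, in
        which case zero light abundance yields status ``undefined_ratio``.
    """

    genus_min_heavy_relab: float = 0.01
    asv_min_heavy_relab: float = 0.001
    ef_threshold: float = 0.1
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.genus_min_heavy_relab <= 0 or self.asv_min_heavy_relab <= 0:
            raise ValueError("abundance thresholds must be > 0")
        if self.ef_threshold <= 0:
            raise ValueError("ef_threshold must be > 0")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")

    def min_relab(self, level: str) -> float:
        if level == "genus":
            return self.genus_min_heavy_relab
        if level == "ASV":
            return self.asv_min_heavy_relab
        raise ValueError(f"unknown level {level!r}; expected 'genus' or 'ASV'")


def relative_abundance(
    counts: Mapping[str, float],
    pseudocount: float = 0.5,
    universe: Sequence[str] | None = None,
) -> dict[str, float]:
    """Pseudocounted relative abundances of one selected fraction.

    Each taxon's value is ``(count + pseudocount) / sum(count + pseudocount)``
    over ``universe`` (defaults to the taxa present in ``counts``).  With
    pseudocount 0 this reduces to plain read proportions.
    """
    taxa = list(universe) if universe is not None else list(counts)
    if not taxa:
        raise DegenerateInputError("empty count table")
    vals = np.array([counts.get(t, 0) + pseudocount for t in taxa], float)
    total = vals.sum()
    if total <= 0:
        raise DegenerateInputError("all counts zero and pseudocount 0")
    vals /= total
    return dict(zip(taxa, vals))


def enrichment_factor(r13h: float, r13l: float, r12h: float, r12l: float) -> float:
    """EF = r13h/r13l - r12h/r12l; may be negative.

    Raises :class:`UndefinedRatioError` if either light abundance is zero
    (callers at pipeline level record this as status ``undefined_ratio``
    rather than propagating the exception).
    """
    if r13l <= 0 or r12l <= 0:
        raise UndefinedRatioError(
            f"light-fraction abundance must be > 0 (got r13L={r13l}, r12L={r12l})"
        )
    return r13h / r13l - r12h / r12l


def call_labeled(ef: float, threshold: float = 0.1) -> bool:
    """True iff ``ef`` strictly exceeds the threshold (EF > 0.1 rule)."""
    return bool(ef > threshold)


def passes_abundance_filter(
    taxon: str,
    level: str,
    heavy_relabs: Iterable[Mapping[str, float]],
    cfg: FilterConfig | None = None,
) -> bool:
    """True iff the taxon strictly exceeds the level threshold in at least
    one 13C heavy fraction (one mapping per treatment x timepoint)."""
    cfg = cfg or FilterConfig()
    thr = cfg.min_relab(level)
    return any(r.get(taxon, 0.0) > thr for r in heavy_relabs)


def _genus_of(lineage: str) -> str:
    """Resolve a taxonomy-map value to a genus bucket.

    Plain strings are taken as genus names.  Semicolon-ranked lineages
    (domain;phylum;class;order;family;genus) resolve to the genus entry
    when present, otherwise to ``unclassified:<highest resolved rank>``.
    """
    if ";" not in lineage:
        return lineage if lineage else "unclassified:unknown"
    ranks = [r.strip() for r in lineage.split(";")]
    resolved = [r for r in ranks if r]
    if len(resolved) >= 6:
        return resolved[5]
    if resolved:
        return f"unclassified:{resolved[-1]}"
    return "unclassified:unknown"


def aggregate_to_genus(
    asv_counts: pd.DataFrame, taxonomy: Mapping[str, str]
) -> pd.DataFrame:
    """Sum ASV x fraction counts into genus x fraction counts.

    Column totals are conserved exactly.  ASVs absent from the taxonomy
    map are grouped under ``unclassified:unknown``.
    """
    buckets = [
        _genus_of(taxonomy[a]) if a in taxonomy else "unclassified:unknown"
        for a in asv_counts.index
    ]
    out = asv_counts.groupby(pd.Index(buckets, name="taxon"), sort=True).sum()
    return out


def display_floor(ef: float, floor: float = DISPLAY_FLOOR) -> float:
    """Clip EF to the visualization floor (negative and tiny positive EFs
    are set to 10**-1.5 so they can be drawn on a log scale).  Used only
    for display exports, never for labeling calls."""
    return max(ef, floor)


def summarize_ef(records: pd.DataFrame, by: str = "taxon") -> pd.DataFrame:
    """Arithmetic-mean EF per taxon over status-ok records.

    The averaging set is records with status ``ok`` only (missing-12C
    groups carry no EF and cannot enter a mean); records per group are
    never averaged implicitly elsewhere in the pipeline.
    """
    ok = records[records["status"] == "ok"]
    g = ok.groupby(by)["ef"]
    return pd.DataFrame({
        "mean_ef": g.mean(),
        "max_ef": g.max(),
        "n_groups": g.size(),
        "n_labeled": ok.groupby(by)["labeled"].sum().astype(int),
    }).reset_index()


def _as_window(w, label: str) -> DensityWindow:
    if isinstance(w, DensityWindow):
        return w
    return DensityWindow(float(w[0]), float(w[1]), label)


class IncorporatorDetector(BaseEstimator):
    """Detect 13C-labeled taxa from paired 13C/12C SIP gradients.

    A scikit-learn-style estimator: ``fit`` takes the experiment (a list
    of :class:`~sipscreen.gradient.GradientSet` spanning treatments x
    prey x timepoint), selects representative heavy/light fractions,
    applies the abundance filter, computes EF per taxon per group and
    calls labels.

    Parameters
    ----------
    level : {'genus', 'ASV'}
        Determines the abundance-filter threshold (1% vs 0.1%).
    heavy_window, light_window : (lo, hi) in g/ml
        Buoyant-density windows for the representative fractions.
    genus_min_heavy_relab, asv_min_heavy_relab, ef_threshold, pseudocount
        See :class:`FilterConfig`.
    policy : {'max_copies', 'mid_density'}
        Representative-fraction selection policy.
    filter_to_passing : bool
        If False, emit records for every taxon (the abundance filter is
        still recorded in ``passed_filter``); useful for dose-response
        summaries over planted taxa.
    filter_include_12c : bool
        If True the abundance filter also considers 12C heavy fractions
        (sensitivity analysis); default False — incorporators are
        identified in 13C heavy fractions.

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per (taxon, prey, timepoint) with columns
        taxon, level, prey, timepoint, r13H, r13L, r12H, r12L, ef,
        passed_filter, labeled, status.
    labeled_taxa_ : list of str
        Taxa labeled in at least one group.
    groups_ : list of (prey, timepoint)
        Groups encountered, in processing order.
    missing_12c_groups_ : list of (prey, timepoint)
        Groups lacking usable 12C heavy/light data.
    """

    def __init__(
        self,
        level: str = "genus",
        heavy_window=(HEAVY_WINDOW.lo, HEAVY_WINDOW.hi),
        light_window=(LIGHT_WINDOW.lo, LIGHT_WINDOW.hi),
        genus_min_heavy_relab: float = 0.01,
        asv_min_heavy_relab: float = 0.001,
        ef_threshold: float = 0.1,
        pseudocount: float = 0.5,
        policy: str = "max_copies",
        filter_to_passing: bool = True,
        filter_include_12c: bool = False,
    ):
        self.level = level
        self.heavy_window = heavy_window
        self.light_window = light_window
        self.genus_min_heavy_relab = genus_min_heavy_relab
        self.asv_min_heavy_relab = asv_min_heavy_relab
        self.ef_threshold = ef_threshold
        self.pseudocount = pseudocount
        self.policy = policy
        self.filter_to_passing = filter_to_passing
        self.filter_include_12c = filter_include_12c

    # -- internals ---------------------------------------------------------

    def _config(self) -> FilterConfig:
        return FilterConfig(
            genus_min_heavy_relab=self.genus_min_heavy_relab,
            asv_min_heavy_relab=self.asv_min_heavy_relab,
            ef_threshold=self.ef_threshold,
            pseudocount=self.pseudocount,
        )

    @staticmethod
    def _union_counts(gradients: Sequence[GradientSet]) -> list[str]:
        taxa: set[str] = set()
        for g in gradients:
            for f in g.fractions:
                taxa.update(f.counts)
        return sorted(taxa)

    def _reps(self, g: GradientSet, heavy: DensityWindow, light: DensityWindow):
        h = select_representative(g.fractions, heavy, self.policy)
        l = select_representative(g.fractions, light, self.policy)
        return h, l

    # -- estimator API -----------------------------------------------------

    def fit(self, X: Sequence[GradientSet], y=None, taxonomy=None):
        """Compute EF records from an experiment.

        Parameters
        ----------
        X : sequence of GradientSet
            Paired 13C/12C gradients across prey x timepoint.
        taxonomy : mapping, optional
            ASV -> genus (or semicolon lineage); when given and
            ``level='genus'`` counts are aggregated before analysis.
        """
        cfg = self._config()
        heavy = _as_window(self.heavy_window, "heavy")
        light = _as_window(self.light_window, "light")
        if heavy.lo <= light.hi and light.lo <= heavy.hi:
            raise ValueError("heavy and light windows overlap")

        gradients = list(X)
        if taxonomy is not None and self.level == "genus":
            gradients = [_aggregate_gradient(g, taxonomy) for g in gradients]

        c13 = [g for g in gradients if g.meta.treatment == "C13"]
        if not c13:
            raise EmptyExperimentError("experiment contains no 13C gradient")
        c12 = {
            (g.meta.prey, g.meta.timepoint, g.meta.target): g
            for g in gradients
            if g.meta.treatment == "C12"
        }

        universe = self._union_counts(gradients)
        if not universe:
            raise EmptyExperimentError("experiment contains no counts")

        # Per-group representative fractions and 13C relative abundances.
        groups = []
        for g in sorted(c13, key=lambda g: (g.meta.prey, g.meta.timepoint)):
            h13, l13 = self._reps(g, heavy, light)
            r13h = relative_abundance(h13.counts, cfg.pseudocount, universe)
            r13l = relative_abundance(l13.counts, cfg.pseudocount, universe)
            groups.append((g.meta, r13h, r13l))

        # Abundance filter over 13C heavy fractions (optionally also 12C).
        heavy_relabs = [r13h for _, r13h, _ in groups]
        if self.filter_include_12c:
            for g in c12.values():
                try:
                    h12, _ = self._reps(g, heavy, light)
                except WindowEmptyError:
                    continue
                heavy_relabs.append(
                    relative_abundance(h12.counts, cfg.pseudocount, universe)
                )
        passed = {
            t: passes_abundance_filter(t, self.level, heavy_relabs, cfg)
            for t in universe
        }

        rows = []
        missing = []
        for meta, r13h, r13l in groups:
            key = (meta.prey, meta.timepoint, meta.target)
            pair = c12.get(key)
            r12h = r12l = None
            if pair is not None:
                try:
                    h12, l12 = self._reps(pair, heavy, light)
                    r12h = relative_abundance(h12.counts, cfg.pseudocount, universe)
                    r12l = relative_abundance(l12.counts, cfg.pseudocount, universe)
                except WindowEmptyError:
                    pair = None
            if pair is None:
                missing.append((meta.prey, meta.timepoint))

            for taxon in universe:
                if self.filter_to_passing and not passed[taxon]:
                    continue
                row = {
                    "taxon": taxon,
                    "level": self.level,
                    "prey": meta.prey,
                    "timepoint": meta.timepoint,
                    "r13H": r13h[taxon],
                    "r13L": r13l[taxon],
                    "r12H": np.nan,
                    "r12L": np.nan,
                    "ef": np.nan,
                    "passed_filter": passed[taxon],
                    "labeled": False,
                    "status": "missing_12C",
                }
                if pair is not None:
                    row["r12H"] = r12h[taxon]
                    row["r12L"] = r12l[taxon]
                    try:
                        ef = enrichment_factor(
                            r13h[taxon], r13l[taxon], r12h[taxon], r12l[taxon]
                        )
                    except UndefinedRatioError:
                        row["status"] = "undefined_ratio"
                    else:
                        row["ef"] = ef
                        row["status"] = "ok"
                        row["labeled"] = passed[taxon] and call_labeled(
                            ef, cfg.ef_threshold
                        )
                rows.append(row)

        self.results_ = pd.DataFrame(rows, columns=EF_COLUMNS)
        self.groups_ = [(m.prey, m.timepoint) for m, _, _ in groups]
        self.missing_12c_groups_ = missing
        self.labeled_taxa_ = sorted(
            self.results_.loc[self.results_["labeled"], "taxon"].unique()
        )
        return self

    def summary(self) -> pd.DataFrame:
        """Mean/max EF per taxon over status-ok records (reporting step)."""
        return summarize_ef(self.results_)


def _aggregate_gradient(g: GradientSet, taxonomy: Mapping[str, str]) -> GradientSet:
    from .gradient import FractionRecord

    new = []
    for f in g.fractions:
        agg: dict[str, int] = {}
        for asv, n in f.counts.items():
            bucket = _genus_of(taxonomy[asv]) if asv in taxonomy else "unclassified:unknown"
            agg[bucket] = agg.get(bucket, 0) + n
        new.append(
            FractionRecord(f.gradient_id, f.fraction_index, f.density, f.copies, agg)
        )
    return GradientSet(g.meta, new)


def ef_table(experiment: Sequence[GradientSet], taxonomy=None, **params) -> pd.DataFrame:
    """Functional wrapper: fit an :class:`IncorporatorDetector` and return
    its EF record table."""
    det = IncorporatorDetector(**params)
    det.fit(experiment, taxonomy=taxonomy)
    return det.results_
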