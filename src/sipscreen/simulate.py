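"""Forward simulation of rRNA-SIP experiments and companion fixtures.

The simulator emulates everything the analysis consumes, with ground
truth attached:

* an activated-sludge-like community (heavy-tailed baseline abundances,
  roles: predator / cross-feeder / inactive / prey spike) where each
  taxon carries an isotope-incorporation level ``alpha`` in [0, 1];
* 13-fraction isopycnic gradients: each taxon's rRNA mass spreads over
  the buoyant-density grid as a two-component Gaussian mixture with
  weight ``alpha`` shifted by ``atom_pct * delta_max`` g/ml, reads are
  drawn multinomially per fraction (equal sequencing depth per selected
  fraction, as in amplicon practice), and RT-qPCR copy numbers follow
  the total rRNA mass with log-normal noise;
* 16S reference/query sequence sets with controlled divergence for the
  percent-identity screen;
* sample metadata tables with planted monotone taxon-variable links for
  the correlation screen.

All outputs are bit-reproducible given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .gradient import FractionRecord, GradientMeta, GradientSet

__all__ = [
    "SimConfig",
    "CommunityTruth",
    "DEFAULT_ROLES",
    "simulate_community",
    "plant_incorporators",
    "simulate_gradient",
    "simulate_experiment",
    "simulate_sequences",
    "simulate_metadata",
    "write_fixture_bundle",
]

#: Default role mix: a few percent each of predators and cross-feeders
#: in a mostly non-incorporating community.
DEFAULT_ROLES: dict[str, float] = {
    "predator": 0.05,
    "cross_feeder": 0.05,
    "inactive": 0.90,
}

METADATA_VARIABLES = [
    "BOD_removal", "COD_removal", "NH4N_removal", "TN_removal",
    "TP_removal", "conductivity", "HRT", "pH",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the gradient simulator.

    seed : int (required)
        Master seed; every stochastic draw derives from it.
    n_taxa : community size (prey-spike taxa are added on top).
    reads_per_fraction : sequencing depth per selected fraction
        (100 000, a typical NovaSeq amplicon depth per sample).
    n_fractions : 13 fractions per gradient.
    density_lo, density_hi : g/ml, equal-width fraction grid.
    mu0 : 1.812 g/ml, mean buoyant density of unlabeled rRNA (inside
        the light window).
    delta_max : 0.045 g/ml, density shift at 100 atom% 13C (placing
        ~97%-labeled rRNA inside the heavy window).
    sigma_bd : 0.008 g/ml, within-taxon density spread.
    atom_pct : 0.97, label purity of the prey biomass.
    qpcr_noise_cv : 0.15, log-normal CV of the RT-qPCR copy readout.
    copies_scale : arbitrary copy-number unit scale.
    """

    seed: int
    n_taxa: int = 150
    reads_per_fraction: int = 100_000
    n_fractions: int = 13
    density_lo: float = 1.780
    density_hi: float = 1.900
    mu0: float = 1.812
    delta_max: float = 0.045
    sigma_bd: float = 0.008
    atom_pct: float = 0.97
    qpcr_noise_cv: float = 0.15
    copies_scale: float = 1e8

    def __post_init__(self) -> None:
        if self.n_taxa < 2 or self.n_fractions < 2:
            raise ValueError("n_taxa and n_fractions must be >= 2")
        for name in ("reads_per_fraction", "delta_max", "sigma_bd",
                     "atom_pct", "qpcr_noise_cv", "copies_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (self.density_lo < self.mu0 < self.density_hi):
            raise ValueError("mu0 must lie inside the density grid")
        if self.mu0 + self.delta_max > self.density_hi:
            raise ValueError(
                "density grid does not cover mu0 + delta_max "
                f"({self.mu0 + self.delta_max:.4f} > {self.density_hi})"
            )

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(self.density_lo, self.density_hi, self.n_fractions + 1)

    @property
    def bin_mids(self) -> np.ndarray:
        e = self.bin_edges
        return 0.5 * (e[:-1] + e[1:])


@dataclass
class CommunityTruth:
    """Ground truth: one row per taxon with columns ``taxon``, ``genus``,
    ``baseline_relab``, ``alpha``, ``role``, ``prey``."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        total = self.table["baseline_relab"].sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"baseline abundances sum to {total}, not 1")
        inactive = self.table[self.table["role"] == "inactive"]
        if (inactive["alpha"] != 0).any():
            raise ValueError("inactive taxa must have alpha = 0")

    @property
    def taxa(self) -> list[str]:
        return list(self.table["taxon"])

    def genus_map(self) -> dict[str, str]:
        return dict(zip(self.table["taxon"], self.table["genus"]))


def _role_counts(roles: Mapping[str, float], n: int) -> dict[str, int]:
    """Deterministic largest-remainder apportionment of n taxa to roles."""
    if abs(sum(roles.values()) - 1.0) > 1e-9:
        raise ValueError(f"role proportions must sum to 1, got {sum(roles.values())}")
    if any(v < 0 for v in roles.values()):
        raise ValueError("role proportions must be non-negative")
    items = list(roles.items())
    floors = [int(np.floor(p * n)) for _, p in items]
    remainder = n - sum(floors)
    order = sorted(
        range(len(items)),
        key=lambda i: (-(items[i][1] * n - floors[i]), i),
    )
    for i in order[:remainder]:
        floors[i] += 1
    return {name: c for (name, _), c in zip(items, floors)}


def simulate_community(
    cfg: SimConfig,
    roles: Mapping[str, float] | None = None,
    preys: Sequence[str] = (),
    prey_relab: float | None = None,
    predator_relab_range: tuple[float, float] = (0.01, 0.05),
    predator_alpha_range: tuple[float, float] = (0.5, 1.0),
    crossfeeder_alpha_range: tuple[float, float] = (0.1, 0.3),
    lognormal_sigma: float = 1.5,
    rng: np.random.Generator | None = None,
) -> CommunityTruth:
    """Draw a ground-truth community.

    Baseline abundances are log-normal (heavy-tailed) and normalized.
    Predators are planted at 1-5% baseline (abundant myxobacterial
    clades in sludge sit in this range) with alpha in [0.5, 1];
    cross-feeders receive intermediate alpha in [0.1, 0.3] to model
    indirect label acquisition; inactive taxa have alpha 0.  One
    prey-spike taxon per entry of ``preys`` carries alpha 1; its
    baseline is ``prey_relab`` per prey, or drawn uniformly so the spike
    totals 40-50% of reads (the amendment-time condition) when
    ``prey_relab`` is None.
    """
    roles = dict(roles) if roles is not None else dict(DEFAULT_ROLES)
    if "prey_spike" in roles:
        raise ValueError("prey spikes are configured via `preys`, not `roles`")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    counts = _role_counts(roles, cfg.n_taxa)

    rows = []
    idx = 0
    # draw in a fixed order so the stream is reproducible
    base_draw = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=cfg.n_taxa)
    spike_total = 0.0
    if preys:
        if prey_relab is None:
            spike_total = float(rng.uniform(0.40, 0.50))
        else:
            spike_total = prey_relab * len(preys)
    pred_budget_draw = rng.uniform(*predator_relab_range, size=counts.get("predator", 0))
    pred_alpha = rng.uniform(*predator_alpha_range, size=counts.get("predator", 0))
    cf_alpha = rng.uniform(*crossfeeder_alpha_range, size=counts.get("cross_feeder", 0))

    pred_total = float(pred_budget_draw.sum())
    if spike_total + pred_total >= 0.95:
        raise ValueError("prey spike + predator budget leaves no community mass")
    rest_budget = 1.0 - spike_total - pred_total

    pred_i = cf_i = 0
    rest_relabs = []
    for role in roles:
        for _ in range(counts[role]):
            taxon = f"t{idx:04d}"
            if role == "predator":
                relab, alpha = float(pred_budget_draw[pred_i]), float(pred_alpha[pred_i])
                pred_i += 1
            elif role == "cross_feeder":
                relab, alpha = float(base_draw[idx]), float(cf_alpha[cf_i])
                cf_i += 1
                rest_relabs.append(idx)
            else:
                relab, alpha = float(base_draw[idx]), 0.0
                rest_relabs.append(idx)
            rows.append({
                "taxon": taxon, "genus": f"g_{taxon}",
                "baseline_relab": relab, "alpha": alpha,
                "role": role, "prey": "",
            })
            idx += 1
    # normalize the non-predator, non-spike mass to its budget
    rest_sum = sum(rows[i]["baseline_relab"] for i in rest_relabs)
    for i in rest_relabs:
        rows[i]["baseline_relab"] *= rest_budget / rest_sum
    for prey in preys:
        rows.append({
            "taxon": f"prey_{prey}", "genus": f"g_prey_{prey}",
            "baseline_relab": spike_total / len(preys), "alpha": 1.0,
            "role": "prey_spike", "prey": prey,
        })
    return CommunityTruth(pd.DataFrame(rows))


def plant_incorporators(
    truth: CommunityTruth,
    alphas: Sequence[float],
    relab: float = 0.02,
) -> tuple[CommunityTruth, list[str]]:
    """Replace the last ``len(alphas)`` inactive taxa by planted
    incorporators at a fixed baseline abundance (scenario construction
    for dose-response checks).  Returns the new truth and the planted
    taxon names (in the order of ``alphas``)."""
    table = truth.table.copy()
    inactive_idx = table.index[table["role"] == "inactive"]
    if len(inactive_idx) < len(alphas):
        raise ValueError("not enough inactive taxa to plant into")
    chosen = list(inactive_idx[-len(alphas):])
    names = []
    for pos, alpha in zip(chosen, alphas):
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        table.loc[pos, ["alpha", "role", "baseline_relab"]] = [
            float(alpha), "planted", relab,
        ]
        names.append(table.loc[pos, "taxon"])
    others = table.index.difference(chosen)
    other_sum = table.loc[others, "baseline_relab"].sum()
    target = 1.0 - relab * len(alphas)
    table.loc[others, "baseline_relab"] *= target / other_sum
    return CommunityTruth(table), names


def _mass_matrix(alpha_eff: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Per-taxon rRNA mass in each density bin: mixture of an unlabeled
    Gaussian at mu0 and a labeled Gaussian at mu0 + atom_pct*delta_max."""
    edges = cfg.bin_edges
    cdf0 = norm.cdf(edges, loc=cfg.mu0, scale=cfg.sigma_bd)
    mu1 = cfg.mu0 + cfg.atom_pct * cfg.delta_max
    cdf1 = norm.cdf(edges, loc=mu1, scale=cfg.sigma_bd)
    light = np.diff(cdf0)
    heavy = np.diff(cdf1)
    a = alpha_eff[:, None]
    return (1.0 - a) * light[None, :] + a * heavy[None, :]


def simulate_gradient(
    truth: CommunityTruth,
    meta: GradientMeta,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[FractionRecord]:
    """Simulate the 13 fractions of one gradient.

    In the C13 treatment each taxon's labeled mixture weight is its
    ground-truth alpha; in C12/control treatments it is 0.  Prey-spike
    taxa of other prey species are excluded and the community
    renormalized.  Reads are multinomial per fraction (fixed depth,
    probabilities proportional to baseline_relab x bin mass, renormalized
    within the fraction); copies follow total bin mass with log-normal
    noise of the configured CV.  Fractions whose total mass underflows
    to zero (far tails with no labeled taxa) fall back to the baseline
    composition, the limit of the renormalized mixture.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    table = truth.table
    include = (table["role"] != "prey_spike") | (table["prey"] == meta.prey)
    sub = table[include].reset_index(drop=True)
    w = sub["baseline_relab"].to_numpy(float)
    w = w / w.sum()
    alpha_eff = (
        sub["alpha"].to_numpy(float)
        if meta.treatment == "C13"
        else np.zeros(len(sub))
    )
    M = _mass_matrix(alpha_eff, cfg)
    taxa = list(sub["taxon"])
    mids = cfg.bin_mids

    # log-normal noise with unit mean at the configured CV
    sigma = np.sqrt(np.log1p(cfg.qpcr_noise_cv ** 2))

    fractions = []
    for j in range(cfg.n_fractions):
        p = w * M[:, j]
        total_mass = p.sum()
        if total_mass > 0:
            probs = p / total_mass
        else:
            probs = w
        reads = rng.multinomial(cfg.reads_per_fraction, probs)
        noise = rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma)
        copies = float(total_mass * cfg.copies_scale * noise)
        counts = {t: int(c) for t, c in zip(taxa, reads) if c > 0}
        fractions.append(
            FractionRecord(
                gradient_id=meta.gradient_id,
                fraction_index=j + 1,
                density=float(mids[j]),
                copies=copies,
                counts=counts,
            )
        )
    return fractions


def simulate_experiment(
    cfg: SimConfig,
    truth: CommunityTruth | None = None,
    preys: Sequence[str] = ("E_coli",),
    timepoints: Sequence[str] = ("1d",),
    treatments: Sequence[str] = ("C13", "C12"),
    roles: Mapping[str, float] | None = None,
    prey_relab: float | None = 0.01,
    drop: Sequence[tuple[str, str, str]] = (),
) -> tuple[list[GradientSet], CommunityTruth]:
    """Simulate paired gradients across prey x timepoint x treatment.

    One community underlies all gradients.  ``prey_relab`` defaults to
    1% per spike — the incubated-timepoint condition, where the amended
    biomass has decayed from its 40-50% share at amendment time (pass
    None to draw the amendment-time share instead).  ``drop`` removes
    (treatment, prey, timepoint) combinations, e.g. to model 12C
    gradients whose heavy fractions yielded no usable data.
    """
    master = np.random.default_rng(cfg.seed)
    streams = master.spawn(1 + len(treatments) * len(preys) * len(timepoints))
    if truth is None:
        truth = simulate_community(
            cfg, roles=roles, preys=preys, prey_relab=prey_relab, rng=streams[0]
        )
    dropped = {tuple(d) for d in drop}
    out = []
    k = 1
    for prey in preys:
        for tp in timepoints:
            for tr in treatments:
                stream = streams[k]
                k += 1
                if (tr, prey, tp) in dropped:
                    continue
                meta = GradientMeta(
                    gradient_id=f"{tr}_{prey}_{tp}",
                    treatment=tr,
                    prey=prey,
                    timepoint=tp,
                )
                out.append(GradientSet(meta, simulate_gradient(truth, meta, cfg, stream)))
    return out, truth


_BASES = np.array(list("ACGT"))


def simulate_sequences(
    n_refs: int,
    n_queries: int,
    length: int,
    mutation_rates: float | Sequence[float],
    seed: int,
    exact: bool = False,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], pd.DataFrame]:
    """Reference and point-mutated query sequence sets.

    Queries cycle over the references as mutation sources.  With
    ``exact=True`` each query receives exactly ``round(rate * length)``
    substitutions at distinct sites (realized identity is then exactly
    ``(1 - k/length) * 100``); otherwise substitutions are per-site
    Bernoulli draws.  Returns (references, queries, truth table).
    """
    rates = np.broadcast_to(np.asarray(mutation_rates, float), (n_queries,))
    if np.any((rates < 0) | (rates > 1)):
        raise ValueError("mutation rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    refs = []
    for i in range(n_refs):
        seq = "".join(rng.choice(_BASES, size=length))
        refs.append((f"ref_{i + 1:03d}", seq))
    queries = []
    rows = []
    for i in range(n_queries):
        rid, rseq = refs[i % n_refs]
        arr = np.array(list(rseq))
        if exact:
            k = int(round(rates[i] * length))
            sites = rng.choice(length, size=k, replace=False)
        else:
            sites = np.flatnonzero(rng.random(length) < rates[i])
        for s in sites:
            choices = _BASES[_BASES != arr[s]]
            arr[s] = rng.choice(choices)
        qid = f"query_{i + 1:03d}"
        queries.append((qid, "".join(arr)))
        rows.append({
            "query": qid, "source": rid, "rate": float(rates[i]),
            "n_mut": int(len(sites)),
            "expected_identity": 100.0 * (1.0 - rates[i]),
            "realized_identity": 100.0 * (1.0 - len(sites) / length),
        })
    return refs, queries, pd.DataFrame(rows)


def simulate_metadata(
    n_samples: int,
    planted_links: Sequence[tuple[str, str, int, float]],
    seed: int,
    n_taxa: int = 50,
    n_variables: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Abundance and metadata tables with planted monotone links.

    Each planted link (taxon, variable, sign, strength) couples the
    taxon's abundance and the variable through a shared latent Gaussian;
    the latent loading is calibrated via the Gaussian-copula relation
    rho = 2 sin(pi * r_s / 6) so the expected Spearman correlation is
    ~``strength`` (signed).  Abundances pass through exp() — a strictly
    monotone transform, so rank correlations are unaffected.  Unplanted
    pairs are independent.
    """
    seen = set()
    for taxon, variable, sign, strength in planted_links:
        if (taxon, variable) in seen:
            raise ValueError(f"duplicate planted pair ({taxon}, {variable})")
        seen.add((taxon, variable))
        if not 0.0 <= strength <= 1.0:
            raise ValueError("strength must lie in [0, 1]")
        if sign not in (-1, 1):
            raise ValueError("sign must be -1 or +1")

    rng = np.random.default_rng(seed)
    samples = [f"s{i + 1:03d}" for i in range(n_samples)]
    taxa = [f"tax_{i + 1:03d}" for i in range(n_taxa)]
    variables = (METADATA_VARIABLES + [
        f"var_{i + 1:02d}" for i in range(max(0, n_variables - len(METADATA_VARIABLES)))
    ])[:n_variables]

    abundance = pd.DataFrame(
        rng.lognormal(mean=0.0, sigma=1.0, size=(n_taxa, n_samples)),
        index=taxa, columns=samples,
    )
    metadata = pd.DataFrame(
        rng.normal(size=(n_samples, n_variables)),
        index=samples, columns=variables,
    )

    latents: dict[str, np.ndarray] = {}
    rows = []
    for taxon, variable, sign, strength in planted_links:
        if taxon not in abundance.index or variable not in metadata.columns:
            raise ValueError(f"unknown planted pair ({taxon}, {variable})")
        if taxon not in latents:
            latents[taxon] = rng.normal(size=n_samples)
        z = latents[taxon]
        rho = 2.0 * np.sin(np.pi * strength / 6.0)
        w = np.sqrt(rho) if rho > 0 else 0.0
        taxon_signal = w * z + np.sqrt(1.0 - w ** 2) * rng.normal(size=n_samples)
        var_signal = w * z + np.sqrt(1.0 - w ** 2) * rng.normal(size=n_samples)
        abundance.loc[taxon] = np.exp(taxon_signal)
        metadata[variable] = sign * var_signal
        rows.append({
            "taxon": taxon, "variable": variable,
            "sign": sign, "strength": strength,
        })
    return abundance, metadata, pd.DataFrame(
        rows, columns=["taxon", "variable", "sign", "strength"]
    )


def write_fixture_bundle(outdir, seed: int = 20230211):
    """Write a small, seeded TSV fixture bundle (gradient metadata,
    fraction metadata, counts, ground truth) consumed by the test suite
    and the documentation walkthrough.  Returns the written paths."""
    from . import io as sio
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=seed, n_taxa=30, reads_per_fraction=5000)
    gradients, truth = simulate_experiment(
        cfg, preys=("E_coli",), timepoints=("1d", "2d")
    )
    meta = {"seed": seed, "bundle": "sipscreen-fixture-v1"}
    paths = sio.write_experiment(outdir, gradients, meta=meta)
    truth_path = outdir / "truth.tsv"
    sio.write_tsv(truth.table, truth_path, meta=meta)
    return {**paths, "truth": truth_path}
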