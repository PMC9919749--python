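"""End-to-end run configuration and pipeline composition.

``run_pipeline`` ties the stages together: gradient assembly and
representative-fraction selection, EF computation and labeling calls,
optional predator screening of 16S queries, and the optional ecology
correlation screen.  All outputs are TSVs with self-describing headers
plus a machine-readable JSON manifest; identical config + inputs yield
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import io as sio
from .ecology import CorrelationScreen
from .enrichment import DISPLAY_FLOOR, IncorporatorDetector, display_floor, summarize_ef
from .gradient import DensityWindow
from .predator import ReferencePredatorDB, screen_batch

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass
class RunConfig:
    """Paths and parameters of one analysis run.

    Required inputs are the three gradient tables; the predator screen
    runs when both query and reference FASTAs are given, and the
    correlation screen when abundance + metadata tables are given.
    """

    gradients: str
    fractions: str
    counts: str
    outdir: str = "sipscreen_out"
    taxonomy: str | None = None
    queries_fasta: str | None = None
    refs_fasta: str | None = None
    ref_taxonomy: str | None = None
    abundance: str | None = None
    metadata: str | None = None
    heavy_window: tuple[float, float] = (1.851, 1.872)
    light_window: tuple[float, float] = (1.805, 1.819)
    level: str = "genus"
    genus_min_heavy_relab: float = 0.01
    asv_min_heavy_relab: float = 0.001
    ef_threshold: float = 0.1
    pseudocount: float = 0.5
    policy: str = "max_copies"
    predator_threshold: float = 94.5
    alpha: float = 0.05
    bh_family: str = "per_variable"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("heavy_window", "light_window"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["heavy_window"] = list(self.heavy_window)
        d["light_window"] = list(self.light_window)
        return d


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r}: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured analysis; returns paths and result frames.

    Validation (file existence, window sanity) happens before any
    computation; any stage error aborts with the stage name and context.
    """
    # -- validate config before touching data ------------------------------
    required = {"gradients": cfg.gradients, "fractions": cfg.fractions,
                "counts": cfg.counts}
    optional = {"taxonomy": cfg.taxonomy, "queries_fasta": cfg.queries_fasta,
                "refs_fasta": cfg.refs_fasta, "ref_taxonomy": cfg.ref_taxonomy,
                "abundance": cfg.abundance, "metadata": cfg.metadata}
    for name, p in {**required, **{k: v for k, v in optional.items() if v}}.items():
        if not Path(p).is_file():
            raise PipelineError(f"stage 'validate': input {name} not found: {p}")
    heavy = DensityWindow(*cfg.heavy_window, "heavy")
    light = DensityWindow(*cfg.light_window, "light")
    if heavy.lo <= light.hi and light.lo <= heavy.hi:
        raise PipelineError("stage 'validate': heavy and light windows overlap")

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = sio.config_hash(cfg.to_dict())
    meta = {"config_hash": chash, "seed": cfg.seed, "version": __version__}

    results: dict = {"outputs": {}}

    # -- EF stage ----------------------------------------------------------
    @_stage("enrichment")
    def ef_stage():
        experiment = sio.read_experiment(cfg.gradients, cfg.fractions, cfg.counts)
        taxonomy = sio.read_taxonomy(cfg.taxonomy) if cfg.taxonomy else None
        det = IncorporatorDetector(
            level=cfg.level,
            heavy_window=cfg.heavy_window,
            light_window=cfg.light_window,
            genus_min_heavy_relab=cfg.genus_min_heavy_relab,
            asv_min_heavy_relab=cfg.asv_min_heavy_relab,
            ef_threshold=cfg.ef_threshold,
            pseudocount=cfg.pseudocount,
            policy=cfg.policy,
        ).fit(experiment, taxonomy=taxonomy)
        return det

    det = ef_stage()
    ef = det.results_
    results["ef_table"] = ef
    results["outputs"]["ef_table"] = sio.write_tsv(ef, outdir / "ef_table.tsv", meta)

    viz = ef[ef["status"] == "ok"][["taxon", "prey", "timepoint", "ef"]].copy()
    viz["ef_display"] = [display_floor(v) for v in viz["ef"]]
    viz["log10_ef_display"] = np.log10(viz["ef_display"])
    results["outputs"]["ef_viz"] = sio.write_tsv(viz, outdir / "ef_viz.tsv", meta)

    summary = summarize_ef(ef)
    results["summary"] = summary
    results["outputs"]["ef_summary"] = sio.write_tsv(
        summary, outdir / "ef_summary.tsv", meta
    )

    # -- predator screen (optional) ---------------------------------------
    if cfg.queries_fasta and cfg.refs_fasta:
        @_stage("predator_screen")
        def predator_stage():
            tax = sio.read_taxonomy(cfg.ref_taxonomy) if cfg.ref_taxonomy else None
            db = ReferencePredatorDB.from_fasta(cfg.refs_fasta, taxonomy=tax)
            queries = sio.read_fasta(cfg.queries_fasta)
            return screen_batch(queries, db, threshold=cfg.predator_threshold)

        hits, psummary = predator_stage()
        results["predator_hits"] = hits
        results["outputs"]["predator_hits"] = sio.write_tsv(
            hits, outdir / "predator_hits.tsv", meta
        )
        results["outputs"]["predator_summary"] = sio.write_tsv(
            psummary, outdir / "predator_summary.tsv", meta
        )

    # -- correlation screen (optional) ------------------------------------
    if cfg.abundance and cfg.metadata:
        @_stage("ecology_screen")
        def ecology_stage():
            abundance = sio.read_tsv(cfg.abundance, index_col=0)
            metadata = sio.read_tsv(cfg.metadata, index_col=0)
            return CorrelationScreen(alpha=cfg.alpha, family=cfg.bh_family).fit(
                abundance, metadata
            )

        screen = ecology_stage()
        results["correlations"] = screen.results_
        results["outputs"]["correlations"] = sio.write_tsv(
            screen.results_, outdir / "correlations.tsv", meta
        )

    # -- manifest ----------------------------------------------------------
    manifest = {
        "tool": "sipscreen",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": chash,
        "config": cfg.to_dict(),
        "inputs": {k: str(v) for k, v in {**required, **optional}.items() if v},
        "outputs": {k: str(v) for k, v in results["outputs"].items()},
        "groups": [list(g) for g in det.groups_],
        "missing_12C_groups": [list(g) for g in det.missing_12c_groups_],
        "n_labeled_taxa": len(det.labeled_taxa_),
        "labeled_taxa": det.labeled_taxa_,
        "display_floor": DISPLAY_FLOOR,
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    results["outputs"]["manifest"] = manifest_path
    results["manifest"] = manifest
    return results
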