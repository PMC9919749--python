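"""TSV/FASTA interchange and deterministic result writing.

Canonical on-disk formats (all plain text, inspectable):

* gradient metadata TSV: gradient_id, treatment, prey, timepoint, target;
* fraction metadata TSV: gradient_id, fraction_index, density, copies;
* count tables: taxon rows x fraction columns keyed "gradient_id:fraction_index"
  (integer cells);
* FASTA for sequences; two-column TSV (id, taxonomy) for reference taxonomy.

Every written table starts with '# key: value' header lines carrying the
run seed and a configuration hash, so outputs are self-describing and a
rerun with identical inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .gradient import FractionRecord, GradientMeta, GradientSet

__all__ = [
    "ParseError",
    "config_hash",
    "write_tsv",
    "read_tsv",
    "read_count_table",
    "write_count_table",
    "read_fraction_metadata",
    "read_gradient_metadata",
    "build_gradient_sets",
    "write_experiment",
    "read_experiment",
    "read_fasta",
    "write_fasta",
    "read_taxonomy",
]

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


class ParseError(ValueError):
    """Raised on malformed input tables, with cell coordinates."""


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_lines(meta: Mapping | None) -> str:
    lines = [f"# sipscreen output"]
    for key in sorted(meta or {}):
        lines.append(f"# {key}: {meta[key]}")
    return "\n".join(lines) + "\n"


def write_tsv(df: pd.DataFrame, path, meta: Mapping | None = None,
              index: bool = False) -> Path:
    """Write a TSV with commented header lines and fixed float format."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        df.to_csv(fh, sep="\t", index=index, float_format=FLOAT_FORMAT,
                  lineterminator="\n")
    return path


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_count_table(path) -> pd.DataFrame:
    """Read a taxon x fraction count table (integer cells).

    Non-integer cells and duplicate taxon ids raise :class:`ParseError`
    naming the offending row/column.
    """
    raw = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: expected a taxon column plus fraction columns")
    taxon_col = raw.columns[0]
    taxa = raw[taxon_col]
    dup = taxa[taxa.duplicated()]
    if len(dup):
        raise ParseError(f"{path}: duplicate taxon id {dup.iloc[0]!r}")
    out = {}
    for col in raw.columns[1:]:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() | (vals % 1 != 0) | (vals < 0)
        if bad.any():
            i = int(bad.idxmax())
            raise ParseError(
                f"{path}: non-integer count {raw[col][i]!r} at "
                f"row {taxa[i]!r}, column {col!r}"
            )
        out[col] = vals.astype(int)
    df = pd.DataFrame(out)
    df.index = pd.Index(taxa, name="taxon")
    return df


def write_count_table(df: pd.DataFrame, path, meta: Mapping | None = None) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        df.to_csv(fh, sep="\t", index=True, index_label="taxon",
                  lineterminator="\n")
    return path


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")


def read_fraction_metadata(path) -> pd.DataFrame:
    df = read_tsv(path, dtype={"gradient_id": str})
    _require_columns(df, ["gradient_id", "fraction_index", "density", "copies"], path)
    return df


def read_gradient_metadata(path) -> pd.DataFrame:
    df = read_tsv(path, dtype=str)
    _require_columns(df, ["gradient_id", "treatment", "prey", "timepoint"], path)
    if "target" not in df.columns:
        df["target"] = "prok_16S"
    return df


def build_gradient_sets(
    gradients: pd.DataFrame,
    fractions: pd.DataFrame,
    counts: pd.DataFrame,
) -> list[GradientSet]:
    """Assemble GradientSets from the three canonical tables.

    Count columns are keyed ``gradient_id:fraction_index``; a fraction
    without a count column gets an empty count mapping.
    """
    out = []
    for _, g in gradients.iterrows():
        meta = GradientMeta(
            gradient_id=g["gradient_id"],
            treatment=g["treatment"],
            prey=g["prey"],
            timepoint=str(g["timepoint"]),
            target=g.get("target", "prok_16S"),
        )
        sub = fractions[fractions["gradient_id"] == meta.gradient_id]
        if sub.empty:
            raise ParseError(f"no fractions found for gradient {meta.gradient_id}")
        recs = []
        for _, f in sub.iterrows():
            key = f"{meta.gradient_id}:{int(f['fraction_index'])}"
            if key in counts.columns:
                col = counts[key]
                cnt = {t: int(v) for t, v in col.items() if v > 0}
            else:
                cnt = {}
            recs.append(
                FractionRecord(
                    gradient_id=meta.gradient_id,
                    fraction_index=int(f["fraction_index"]),
                    density=float(f["density"]),
                    copies=float(f["copies"]),
                    counts=cnt,
                )
            )
        out.append(GradientSet(meta, recs))
    return out


def write_experiment(outdir, gradients: Sequence[GradientSet],
                     meta: Mapping | None = None) -> dict[str, Path]:
    """Write an experiment as the three canonical TSVs; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grows = []
    frows = []
    taxa: set[str] = set()
    for g in gradients:
        grows.append({
            "gradient_id": g.meta.gradient_id,
            "treatment": g.meta.treatment,
            "prey": g.meta.prey,
            "timepoint": g.meta.timepoint,
            "target": g.meta.target,
        })
        for f in g.fractions:
            frows.append({
                "gradient_id": f.gradient_id,
                "fraction_index": f.fraction_index,
                "density": f.density,
                "copies": f.copies,
            })
            taxa.update(f.counts)
    taxa_sorted = sorted(taxa)
    cols = {}
    for g in gradients:
        for f in g.fractions:
            key = f"{f.gradient_id}:{f.fraction_index}"
            cols[key] = [f.counts.get(t, 0) for t in taxa_sorted]
    counts = pd.DataFrame(cols, index=pd.Index(taxa_sorted, name="taxon"))
    paths = {
        "gradients": write_tsv(pd.DataFrame(grows), outdir / "gradients.tsv", meta),
        "fractions": write_tsv(pd.DataFrame(frows), outdir / "fractions.tsv", meta),
        "counts": write_count_table(counts, outdir / "counts.tsv", meta),
    }
    return paths


def read_experiment(gradients_path, fractions_path, counts_path) -> list[GradientSet]:
    return build_gradient_sets(
        read_gradient_metadata(gradients_path),
        read_fraction_metadata(fractions_path),
        read_count_table(counts_path),
    )


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence) with U normalized to T and
    case folded to upper.  Empty files and duplicate ids are errors."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: empty or not a FASTA file")
    ids = [r.id for r in records]
    if len(ids) != len(set(ids)):
        seen = set()
        dup = next(i for i in ids if i in seen or seen.add(i))
        raise ParseError(f"{path}: duplicate sequence id {dup!r}")
    out = []
    for r in records:
        seq = str(r.seq).upper()
        if "U" in seq:
            logger.info("read_fasta: normalizing U -> T in %s", r.id)
            seq = seq.replace("U", "T")
        out.append((r.id, seq))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 80) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    return path


def read_taxonomy(path) -> dict[str, str]:
    """Two-column TSV (id, taxonomy string, semicolon-ranked)."""
    df = read_tsv(path, dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (id, taxonomy)")
    id_col, tax_col = df.columns[:2]
    return dict(zip(df[id_col], df[tax_col].fillna("")))
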