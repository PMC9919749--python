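"""Predator classification by 16S rRNA gene percent identity.

Query sequences are compared to a reference database of 16S sequences
from experimentally verified predatory isolates; a query whose best
global-alignment identity reaches at least genus-level similarity
(>= 94.5%, inclusive) is classified a potential predator.

Alignment model
---------------
Needleman-Wunsch-style global alignment with free terminal gaps
("semi-global"), match +1 / mismatch -1 / linear gap -2 by default.
Percent identity = matching columns / alignment columns, where columns
inside terminal-gap overhangs are excluded from the denominator — the
natural convention for near-full-length 16S comparisons whose reads may
differ slightly in trimmed length.  IUPAC ambiguity codes are accepted
but never count as matches (nor score as matches).  Determinism: ties
in the dynamic program are broken by a fixed traceback preference
(diagonal, then gap-in-second-sequence, then gap-in-first), the end
cell is the first maximum scanning the last row left-to-right then the
last column top-to-bottom, and the two sequences are put in canonical
(lexicographic) order before alignment so that identity is symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "SequenceInputError",
    "AlignmentResult",
    "IdentityHit",
    "ReferencePredatorDB",
    "PredatorScreen",
    "normalize_sequence",
    "global_percent_identity",
    "align_stats",
    "classify_predator",
    "screen_batch",
    "PREDATOR_IDENTITY_THRESHOLD",
]

#: Inclusive genus-level identity threshold for the predator call.
PREDATOR_IDENTITY_THRESHOLD = 94.5

_IUPAC = set("ACGTRYSWKMBDHVN")
_UNAMBIGUOUS = set("ACGT")


class SequenceInputError(ValueError):
    """Raised on empty sequences or non-IUPAC characters."""


def normalize_sequence(seq: str, name: str = "<sequence>") -> str:
    """Upper-case, convert U to T, and validate the IUPAC alphabet."""
    s = seq.upper().replace("U", "T")
    if not s:
        raise SequenceInputError(f"{name}: empty sequence")
    bad = set(s) - _IUPAC
    if bad:
        raise SequenceInputError(
            f"{name}: non-IUPAC characters {sorted(bad)!r}"
        )
    return s


@dataclass(frozen=True)
class AlignmentResult:
    """Score and identity bookkeeping of one pairwise alignment."""

    score: float
    matches: int
    columns: int  # alignment columns excluding terminal-gap overhangs

    @property
    def percent_identity(self) -> float:
        if self.columns == 0:
            return 0.0
        return 100.0 * self.matches / self.columns


def _dp_matrix(a: str, b: str, match: float, mismatch: float, gap: float) -> np.ndarray:
    """Fill the semi-global DP matrix (free terminal gaps: first row and
    column zero; score read off the last row/column)."""
    n, m = len(a), len(b)
    b_arr = np.frombuffer(b.encode(), dtype="S1")
    H = np.zeros((n + 1, m + 1))
    jg = gap * np.arange(m + 1)
    for i in range(1, n + 1):
        ai = a[i - 1]
        if ai in _UNAMBIGUOUS:
            s = np.where(b_arr == ai.encode(), match, mismatch)
        else:
            s = np.full(m, mismatch)
        cand = np.empty(m + 1)
        cand[0] = H[i, 0]  # zero: free leading gap
        np.maximum(H[i - 1, :-1] + s, H[i - 1, 1:] + gap, out=cand[1:])
        # resolve the within-row (gap-in-a) dependency with a running max:
        # H[i, j] = max_k<=j cand[k] + gap * (j - k)
        H[i] = np.maximum.accumulate(cand - jg) + jg
    return H


def _end_cell(H: np.ndarray) -> tuple[int, int]:
    """First maximum scanning last row left-to-right then last column
    top-to-bottom (fixed, documented tie-break)."""
    n = H.shape[0] - 1
    m = H.shape[1] - 1
    best = -np.inf
    cell = (n, m)
    for j in range(m + 1):
        if H[n, j] > best:
            best = H[n, j]
            cell = (n, j)
    for i in range(n):
        if H[i, m] > best:
            best = H[i, m]
            cell = (i, m)
    return cell


def _align(a: str, b: str, match: float, mismatch: float, gap: float) -> AlignmentResult:
    H = _dp_matrix(a, b, match, mismatch, gap)
    i, j = _end_cell(H)
    score = float(H[i, j])
    matches = 0
    columns = 0
    eps = 1e-9
    while i > 0 and j > 0:
        ai, bj = a[i - 1], b[j - 1]
        is_match = ai == bj and ai in _UNAMBIGUOUS
        s = match if is_match else mismatch
        if abs(H[i, j] - (H[i - 1, j - 1] + s)) < eps:
            matches += int(is_match)
            i -= 1
            j -= 1
        elif abs(H[i, j] - (H[i - 1, j] + gap)) < eps:
            i -= 1
        else:
            j -= 1
        columns += 1
    # remaining prefix (i or j > 0) is a free terminal-gap overhang
    return AlignmentResult(score=score, matches=matches, columns=columns)


def align_stats(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> AlignmentResult:
    """Align two nucleotide sequences and return score/matches/columns.

    Sequences are normalized (case, U->T) and put in canonical order so
    the result is symmetric in its arguments.
    """
    a = normalize_sequence(a, "first sequence")
    b = normalize_sequence(b, "second sequence")
    if b < a:
        a, b = b, a
    return _align(a, b, match, mismatch, gap)


def global_percent_identity(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> float:
    """Percent identity (0..100) of the best semi-global alignment."""
    return align_stats(a, b, match, mismatch, gap).percent_identity


@dataclass(frozen=True)
class IdentityHit:
    """Best-reference hit of one query against the predator database."""

    query_id: str
    best_ref_id: str
    percent_identity: float
    is_potential_predator: bool


@dataclass
class ReferencePredatorDB:
    """16S sequences of experimentally verified predatory isolates.

    records : list of (sequence id, taxonomy string, nucleotide sequence)
    provenance : free-text note on where the references came from
    """

    records: list[tuple[str, str, str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("reference predator database is empty")
        ids = [r[0] for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate ids in reference predator database")
        self.records = [
            (rid, tax, normalize_sequence(seq, rid)) for rid, tax, seq in self.records
        ]

    @classmethod
    def from_fasta(cls, path, taxonomy: dict[str, str] | None = None,
                   provenance: str = "") -> "ReferencePredatorDB":
        from .io import read_fasta

        taxonomy = taxonomy or {}
        recs = [(rid, taxonomy.get(rid, ""), seq) for rid, seq in read_fasta(path)]
        return cls(records=recs, provenance=provenance)

    @property
    def taxonomy(self) -> dict[str, str]:
        return {rid: tax for rid, tax, _ in self.records}


class PredatorScreen(BaseEstimator):
    """Classify 16S queries as potential predators by best-hit identity.

    ``fit`` stores the reference database; ``predict`` returns the
    boolean predator call per query (identity >= threshold, inclusive —
    "at least genus-level"); ``decision_function`` returns best-hit
    percent identities.

    Parameters
    ----------
    threshold : percent, default 94.5
    match_score, mismatch_score, gap_score : alignment scoring
        (+1 / -1 / -2 linear with free terminal gaps by default).
    """

    def __init__(
        self,
        threshold: float = PREDATOR_IDENTITY_THRESHOLD,
        match_score: float = 1.0,
        mismatch_score: float = -1.0,
        gap_score: float = -2.0,
    ):
        self.threshold = threshold
        self.match_score = match_score
        self.mismatch_score = mismatch_score
        self.gap_score = gap_score

    def fit(self, X, y=None):
        """X: a ReferencePredatorDB, or an iterable of (id, seq) or
        (id, taxonomy, seq) tuples."""
        if isinstance(X, ReferencePredatorDB):
            self.db_ = X
        else:
            recs = []
            for item in X:
                if len(item) == 2:
                    rid, seq = item
                    recs.append((rid, "", seq))
                else:
                    recs.append(tuple(item))
            self.db_ = ReferencePredatorDB(records=recs)
        return self

    def _best_hit(self, qid: str, qseq: str) -> IdentityHit:
        best_pid = -1.0
        best_ref = ""
        # lexicographic id order so that identity ties resolve to the
        # first reference id
        for rid, _tax, rseq in sorted(self.db_.records, key=lambda r: r[0]):
            pid = global_percent_identity(
                qseq, rseq, self.match_score, self.mismatch_score, self.gap_score
            )
            if pid > best_pid:
                best_pid = pid
                best_ref = rid
        return IdentityHit(
            query_id=qid,
            best_ref_id=best_ref,
            percent_identity=best_pid,
            is_potential_predator=best_pid >= self.threshold,
        )

    def decision_function(self, X: Iterable[tuple[str, str]]) -> np.ndarray:
        """Best-hit percent identity per query (id, sequence) pair."""
        return np.array([self._best_hit(qid, qseq).percent_identity for qid, qseq in X])

    def predict(self, X: Iterable[tuple[str, str]]) -> np.ndarray:
        return self.decision_function(X) >= self.threshold

    def screen(self, X: Iterable[tuple[str, str]]) -> pd.DataFrame:
        """One row per query; per-sequence input errors are reported in
        the ``error`` column rather than aborting the batch."""
        rows = []
        for qid, qseq in X:
            try:
                hit = self._best_hit(qid, qseq)
                rows.append({
                    "query": qid,
                    "best_ref": hit.best_ref_id,
                    "pct_identity": hit.percent_identity,
                    "is_potential_predator": hit.is_potential_predator,
                    "error": "",
                })
            except SequenceInputError as exc:
                rows.append({
                    "query": qid,
                    "best_ref": "",
                    "pct_identity": np.nan,
                    "is_potential_predator": False,
                    "error": str(exc),
                })
        return pd.DataFrame(
            rows,
            columns=["query", "best_ref", "pct_identity",
                     "is_potential_predator", "error"],
        )


def classify_predator(
    query: str,
    db: ReferencePredatorDB,
    threshold: float = PREDATOR_IDENTITY_THRESHOLD,
    query_id: str = "query",
    **scoring,
) -> IdentityHit:
    """Best-hit identity of one query against the database (ties go to
    the lexicographically first reference id)."""
    screen = PredatorScreen(threshold=threshold, **scoring).fit(db)
    return screen._best_hit(query_id, normalize_sequence(query, query_id))


def screen_batch(
    queries: Sequence[tuple[str, str]],
    db: ReferencePredatorDB,
    threshold: float = PREDATOR_IDENTITY_THRESHOLD,
    **scoring,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen a query batch; returns (per-query hits, per-group summary).

    The summary counts potential predators per taxonomy group of the
    best-hit reference.
    """
    if not queries:
        raise ValueError("screen_batch requires at least one query")
    screen = PredatorScreen(threshold=threshold, **scoring).fit(db)
    hits = screen.screen(queries)
    tax = db.taxonomy
    ok = hits[hits["error"] == ""].copy()
    ok["group"] = [tax.get(r, "") or "unannotated" for r in ok["best_ref"]]
    summary = (
        ok.groupby("group")
        .agg(
            n_queries=("query", "size"),
            n_potential_predators=("is_potential_predator", "sum"),
        )
        .reset_index()
    )
    summary["n_potential_predators"] = summary["n_potential_predators"].astype(int)
    return hits, summary
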