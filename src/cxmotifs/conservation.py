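"""Cross-species conservation of endocytic motifs.

A motif found in a human protein is better evidence of a functional
sorting signal when the same signal exists in a close ortholog (here:
rat).  The test is performed by global pairwise alignment of the human
and rat sequences, mapping the human motif footprint through the
alignment, and re-running the motif grammar on the rat side.

The aligner is a Needleman–Wunsch/Gotoh implementation with affine gap
penalties (a gap of length *k* costs ``gap_open + (k-1)*gap_extend``) and
a fixed, documented traceback preference (diagonal, then gap-in-subject,
then gap-in-query), so results are fully deterministic.  Substitution
matrices are taken from Biopython's collection (default BLOSUM62).

Two conservation modes are offered:

* ``aligned_overlap`` (default, positional): the rat match must be
  anchored inside the aligned footprint of the human motif, widened by
  the grammar's spacer slack, and must fall in the same topological
  domain;
* ``domain_level`` (lenient): any same-family match anywhere in the rat
  segment of the same kind counts.

Rat topologies may be supplied, or projected from the human topology
through the alignment (the default, so a single annotation source
suffices).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from .motif_grammar import DEFAULT_GRAMMAR, GrammarConfig, match_at
from .scan_pipeline import FilteredHit
from .sequence_io import ProteinRecord, TopologyMap, TopologySegment, SEGMENT_ORDER

logger = logging.getLogger(__name__)

GAP = "-"
NEG = -np.inf

MODES = ("aligned_overlap", "domain_level")


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentParams:
    matrix_name: str = "BLOSUM62"
    gap_open: int = 10    # cost of the first residue of a gap
    gap_extend: int = 1   # cost of each further residue

    def __post_init__(self) -> None:
        if not self.gap_open >= self.gap_extend >= 0:
            raise AlignmentError("require gap_open >= gap_extend >= 0")


DEFAULT_ALIGNMENT = AlignmentParams()


@lru_cache(maxsize=8)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


def _encode(seq: str, matrix) -> np.ndarray:
    alphabet = matrix.alphabet
    try:
        return np.array([alphabet.index(c) for c in seq], dtype=np.intp)
    except ValueError:
        missing = sorted({c for c in seq if c not in alphabet})
        raise AlignmentError(
            f"residue(s) {''.join(missing)!r} absent from substitution matrix"
        ) from None


@dataclass(frozen=True)
class PairwiseAlignment:
    query_id: str
    subject_id: str
    aligned_query: str
    aligned_subject: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_subject):
            raise AlignmentError("aligned strings differ in length")

    @property
    def query(self) -> str:
        return self.aligned_query.replace(GAP, "")

    @property
    def subject(self) -> str:
        return self.aligned_subject.replace(GAP, "")


def align_global(
    a: ProteinRecord | str,
    b: ProteinRecord | str,
    params: AlignmentParams = DEFAULT_ALIGNMENT,
) -> PairwiseAlignment:
    """Optimal global alignment of two protein sequences (Gotoh, affine gaps).

    End gaps are penalised like internal gaps.  The dynamic program is
    vectorised row-wise with numpy; traceback prefers diagonal moves, then
    gaps in the subject, then gaps in the query, making the reported
    alignment unique.
    """
    qid, qseq = (a.id, a.sequence) if isinstance(a, ProteinRecord) else ("query", a.upper())
    sid, sseq = (b.id, b.sequence) if isinstance(b, ProteinRecord) else ("subject", b.upper())
    if not qseq or not sseq:
        raise AlignmentError("cannot align an empty sequence")
    matrix = _load_matrix(params.matrix_name)
    sub = np.asarray(matrix)
    ai = _encode(qseq, matrix)
    bi = _encode(sseq, matrix)
    n, m = len(ai), len(bi)
    open_, ext = float(params.gap_open), float(params.gap_extend)

    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in subject (consumes query residue)
    Y = np.full((n + 1, m + 1), NEG)  # gap in query   (consumes subject residue)
    M[0, 0] = 0.0
    X[1:, 0] = -(open_ + np.arange(n) * ext)
    Y[0, 1:] = -(open_ + np.arange(m) * ext)

    jx = np.arange(m + 1) * ext
    for i in range(1, n + 1):
        srow = sub[ai[i - 1], bi]  # S(a_i, b_j) for j=1..m
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev_best[:-1] + srow
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) - open_,
            X[i - 1, 1:] - ext,
        )
        # Y[i, j] = max over k<j of (max(M[i,k], X[i,k]) - open - (j-1-k)*ext),
        # computed as a running maximum of c[k] + k*ext
        c = np.maximum(M[i], X[i]) - open_
        run = np.maximum.accumulate(c + jx)
        Y[i, 1:] = run[:-1] - jx[:-1]
        Y[i, 0] = NEG

    # traceback
    i, j = n, m
    final = (M[i, j], X[i, j], Y[i, j])
    state = int(np.argmax([final[0], final[1], final[2]]))  # preference M > X > Y
    score = float(final[state])
    out_q: list[str] = []
    out_s: list[str] = []
    while i > 0 or j > 0:
        if state == 0:  # diagonal
            val = M[i, j] - sub[ai[i - 1], bi[j - 1]]
            out_q.append(qseq[i - 1])
            out_s.append(sseq[j - 1])
            i, j = i - 1, j - 1
            for nxt, ref in ((0, M[i, j]), (1, X[i, j]), (2, Y[i, j])):
                if ref == val:
                    state = nxt
                    break
            else:  # pragma: no cover - DP consistency
                raise AssertionError("traceback failed in M state")
            if i == 0 and j == 0:
                break
        elif state == 1:  # gap in subject, consume query residue
            val = X[i, j]
            out_q.append(qseq[i - 1])
            out_s.append(GAP)
            i -= 1
            if M[i, j] - open_ == val:
                state = 0
            elif X[i, j] - ext == val:
                state = 1
            elif Y[i, j] - open_ == val:
                state = 2
            else:  # boundary column
                state = 1
        else:  # gap in query, consume subject residue
            val = Y[i, j]
            out_q.append(GAP)
            out_s.append(sseq[j - 1])
            j -= 1
            if M[i, j] - open_ == val:
                state = 0
            elif X[i, j] - open_ == val:
                state = 1
            elif Y[i, j] - ext == val:
                state = 2
            else:
                state = 2
        if i == 0 and j == 0:
            break
    return PairwiseAlignment(
        query_id=qid,
        subject_id=sid,
        aligned_query="".join(reversed(out_q)),
        aligned_subject="".join(reversed(out_s)),
        score=score,
    )


def map_position(alignment: PairwiseAlignment, query_position: int) -> int | None:
    """Subject residue index aligned to a 1-based query position (None = gap)."""
    qlen = len(alignment.query)
    if not 1 <= query_position <= qlen:
        raise IndexError(f"query position {query_position} outside 1..{qlen}")
    q = s = 0
    for qc, sc in zip(alignment.aligned_query, alignment.aligned_subject):
        if qc != GAP:
            q += 1
        if sc != GAP:
            s += 1
        if q == query_position and qc != GAP:
            return s if sc != GAP else None
    raise AssertionError("alignment does not cover query")  # pragma: no cover


def project_topology(
    alignment: PairwiseAlignment,
    topology: TopologyMap,
    subject_id: str | None = None,
) -> TopologyMap:
    """Project the query topology onto the subject through the alignment.

    Segment boundaries map to the last subject residue consumed at or
    before each query boundary; gaps collapse outward.  Degenerate
    segments are widened to one residue where possible.
    """
    qlen = len(alignment.query)
    slen = len(alignment.subject)
    if topology.length != qlen:
        raise AlignmentError(
            f"topology covers {topology.length} residues, aligned query has {qlen}"
        )
    if slen < len(SEGMENT_ORDER):
        raise AlignmentError("subject too short to carry a nine-segment topology")
    # subject residues consumed at or before each query residue
    consumed = np.zeros(qlen + 1, dtype=int)
    q = s = 0
    for qc, sc in zip(alignment.aligned_query, alignment.aligned_subject):
        if sc != GAP:
            s += 1
        if qc != GAP:
            q += 1
            consumed[q] = s
    ends = [int(consumed[seg.end]) for seg in topology.segments]
    ends[-1] = slen
    # enforce strictly increasing ends within [1, slen]
    for k in range(len(ends)):
        lo = (ends[k - 1] + 1) if k else 1
        ends[k] = max(ends[k], lo)
    for k in range(len(ends) - 1, -1, -1):
        hi = slen - (len(ends) - 1 - k)
        ends[k] = min(ends[k], hi)
    segs = []
    start = 1
    for kind, end in zip(SEGMENT_ORDER, ends):
        segs.append(TopologySegment(kind=kind, start=start, end=end))
        start = end + 1
    return TopologyMap(
        protein_id=subject_id or alignment.subject_id, segments=tuple(segs)
    )


@dataclass(frozen=True)
class ConservationCall:
    hit: FilteredHit
    ortholog_id: str
    mode: str
    conserved: bool
    ortholog_anchor: int | None = None


def _spacer_slack(family: str, config: GrammarConfig) -> int:
    if family == "tyrosine":
        spacers = config.tyr_spacers()
    elif family == "dileucine":
        spacers = config.dileu_spacers()
    else:
        return 0
    return max(spacers) - min(spacers) if spacers else 0


def assess_conservation(
    hit: FilteredHit,
    human: ProteinRecord,
    rat: ProteinRecord,
    rat_topology: TopologyMap | None = None,
    grammar_config: GrammarConfig = DEFAULT_GRAMMAR,
    params: AlignmentParams = DEFAULT_ALIGNMENT,
    mode: str = "aligned_overlap",
    alignment: PairwiseAlignment | None = None,
    human_topology: TopologyMap | None = None,
) -> ConservationCall:
    """Decide whether a human motif also exists in the rat ortholog.

    The rat match may use any spacer the grammar allows and may be
    canonical where the human motif was not (or vice versa); only the
    family and the topological domain must agree.  When ``rat_topology``
    is not supplied it is projected from ``human_topology`` through the
    alignment (the default route, so a single annotation source suffices).
    """
    if mode not in MODES:
        raise ValueError(f"unknown conservation mode {mode!r}")
    if alignment is None:
        alignment = align_global(human, rat, params)
    if rat_topology is None:
        if human_topology is None:
            raise ValueError(
                "pass rat_topology, or human_topology to project it through the alignment"
            )
        rat_topology = project_topology(alignment, human_topology, rat.id)
    rat_topology.check_against(rat)
    if mode == "domain_level":
        seg = rat_topology.segment(hit.domain_kind)
        anchors = range(seg.start, seg.end + 1)
    else:
        mapped = [map_position(alignment, p) for p in range(hit.start, hit.end + 1)]
        mapped = [p for p in mapped if p is not None]
        if not mapped:
            return ConservationCall(hit=hit, ortholog_id=rat.id, mode=mode, conserved=False)
        slack = _spacer_slack(hit.family, grammar_config)
        lo, hi = min(mapped) - slack, max(mapped) + slack
        anchors = range(max(1, lo), min(len(rat.sequence), hi) + 1)
    for anchor in anchors:
        m = match_at(rat.sequence, anchor, hit.family, grammar_config, protein_id=rat.id)
        if m is None or m.end > len(rat.sequence):
            continue
        if rat_topology.domain_of(anchor) != hit.domain_kind:
            continue
        return ConservationCall(
            hit=hit, ortholog_id=rat.id, mode=mode, conserved=True, ortholog_anchor=anchor
        )
    return ConservationCall(hit=hit, ortholog_id=rat.id, mode=mode, conserved=False)


def pick_ortholog(
    human: ProteinRecord,
    candidates: list[ProteinRecord],
    params: AlignmentParams = DEFAULT_ALIGNMENT,
) -> ProteinRecord:
    """Best-scoring candidate under global alignment (ties: lexicographic id)."""
    if not candidates:
        raise ValueError("empty candidate set")
    scored = sorted(
        ((-align_global(human, cand, params).score, cand.id, cand) for cand in candidates),
    )
    _, best_id, best = scored[0]
    logger.info("%s: picked ortholog %s among %d candidates", human.id, best_id, len(candidates))
    return best
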