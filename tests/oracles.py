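"""Independent oracles used only by the tests.

The motif oracle re-derives every hit with regular expressions over
explicit character classes, then applies the per-anchor preference rule;
it shares no code with the package's slot-based matcher.  The alignment
re-scorer walks an alignment column by column and recomputes its score
from the substitution matrix and affine gap costs.
"""

from __future__ import annotations

import re

X_CLASS = "[ACDEFGHIKLMNPQRSTVWYXBZU]"   # any standard residue or ambiguity letter
PHI_CLASS = "[FMLIV]"

# (family, classification, spacer, compiled pattern), in per-anchor
# preference order: canonical first, then ascending spacer.
_PATTERNS = []
for spacer in (2, 3, 4, 5):
    cls = "canonical" if spacer == 2 else "non_canonical"
    _PATTERNS.append(
        ("tyrosine", cls, spacer, re.compile(f"Y{X_CLASS}{{{spacer}}}{PHI_CLASS}"))
    )
_PATTERNS.append(
    ("dileucine", "canonical", 3, re.compile(f"[DE]{X_CLASS}{{3}}L[LI]"))
)
for spacer in (2, 3, 4, 5):
    _PATTERNS.append(
        ("dileucine", "non_canonical", spacer,
         re.compile(f"[DEL]{X_CLASS}{{{spacer}}}L[LIVR]"))
    )
_PATTERNS.append(("npxy", "canonical", 1, re.compile(f"NP{X_CLASS}Y")))


def brute_force_hits(sequence: str) -> list[tuple]:
    """Every (start, family) hit under the default grammar, by brute force.

    Returns tuples (start, end, family, classification, peptide) sorted by
    start then family, at most one entry per (anchor, family).
    """
    sequence = sequence.upper()
    hits = []
    for anchor in range(1, len(sequence) + 1):
        best: dict[str, tuple] = {}
        for family, cls, spacer, pattern in _PATTERNS:
            if family in best:
                # canonical listed first, then ascending spacer: keep only
                # the first (preferred) match per family... except a
                # canonical di-leucine must displace nothing because it is
                # listed before all non-canonical spacers.
                continue
            m = pattern.match(sequence, anchor - 1)
            if m:
                best[family] = (
                    anchor, anchor + m.end() - m.start() - 1, family, cls,
                    sequence[anchor - 1:anchor - 1 + (m.end() - m.start())],
                )
        hits.extend(best.values())
    hits.sort(key=lambda h: (h[0], h[2]))
    return hits


def rescore_alignment(
    aligned_a: str, aligned_b: str, matrix, gap_open: float, gap_extend: float
) -> float:
    """Recompute an alignment's score column by column (affine gaps:
    a run of k gap columns costs gap_open + (k-1)*gap_extend)."""
    assert len(aligned_a) == len(aligned_b)
    score = 0.0
    in_gap_a = in_gap_b = False
    for ca, cb in zip(aligned_a, aligned_b):
        assert not (ca == "-" and cb == "-")
        if ca == "-":
            score -= gap_extend if in_gap_a else gap_open
            in_gap_a, in_gap_b = True, False
        elif cb == "-":
            score -= gap_extend if in_gap_b else gap_open
            in_gap_a, in_gap_b = False, True
        else:
            score += matrix[ca, cb]
            in_gap_a = in_gap_b = False
    return score
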