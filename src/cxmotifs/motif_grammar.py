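"""Endocytic sorting-signal grammars.

Clathrin adaptors such as AP-2 recognise short linear motifs in the
cytoplasmic domains of membrane cargo.  Two families dominate in polytopic
proteins:

* tyrosine-based signals ``YXXΦ`` — an invariant tyrosine anchor, two
  unconstrained residues and a bulky-hydrophobic Φ (F, M, L, I or V); and
* di-leucine signals ``[D/E]XXXL[L/I]`` — an acidic first residue, three
  unconstrained residues and a leucine pair.

``NPXY``, the tyrosine signal of single-pass receptors, is scanned as well
(it does not occur in connexins).  A *canonical* hit satisfies the strict
pattern; a *non-canonical* (cryptic) hit uses one or more experimentally
tolerated relaxations: the spacer may shrink or grow (tyrosine 3–5 X
residues, di-leucine 2–5), the di-leucine terminal residue may be V or R,
and the di-leucine first residue may be L.  Relaxations combine freely.

Constrained slots (the Y anchor, Φ, the acidic/leucine slots) accept only
their stated residue sets and never ambiguity letters; unconstrained "X"
slots accept any standard residue plus the ambiguity letters X/B/Z/U.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .sequence_io import STANDARD_AA, VALID_AA

FAMILIES = ("tyrosine", "dileucine", "npxy")

#: Preference order used when one anchor admits several matches.
#: Canonical beats non-canonical; among non-canonical, the smallest spacer
#: wins; across families (only possible for whole-peptide classification)
#: this tuple breaks remaining ties.
_FAMILY_RANK = {"tyrosine": 0, "dileucine": 1, "npxy": 2}

CANONICAL = "canonical"
NON_CANONICAL = "non_canonical"


class GrammarError(ValueError):
    """Invalid grammar configuration or query."""


@dataclass(frozen=True)
class GrammarConfig:
    """Residue sets and spacer ranges defining both grammars.

    Defaults encode the strict patterns plus the relaxed search criteria
    described in the module docstring.  Canonical sets must be subsets of
    their extended counterparts.
    """

    phi_set: frozenset[str] = frozenset("FMLIV")
    tyr_spacer_canonical: int = 2
    tyr_spacer_extended: tuple[int, ...] = (3, 4, 5)
    dileu_first_canonical: frozenset[str] = frozenset("DE")
    dileu_first_extended: frozenset[str] = frozenset("DEL")
    dileu_spacer_canonical: int = 3
    dileu_spacer_extended: tuple[int, ...] = (2, 3, 4, 5)
    dileu_last_canonical: frozenset[str] = frozenset("LI")
    dileu_last_extended: frozenset[str] = frozenset("LIVR")
    include_npxy: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "phi_set", frozenset(self.phi_set))
        object.__setattr__(self, "dileu_first_canonical", frozenset(self.dileu_first_canonical))
        object.__setattr__(self, "dileu_first_extended", frozenset(self.dileu_first_extended))
        object.__setattr__(self, "dileu_last_canonical", frozenset(self.dileu_last_canonical))
        object.__setattr__(self, "dileu_last_extended", frozenset(self.dileu_last_extended))
        object.__setattr__(self, "tyr_spacer_extended", tuple(sorted(self.tyr_spacer_extended)))
        object.__setattr__(self, "dileu_spacer_extended", tuple(sorted(self.dileu_spacer_extended)))
        if not self.dileu_first_canonical <= self.dileu_first_extended:
            raise GrammarError("dileu first-slot canonical set must be within extended set")
        if not self.dileu_last_canonical <= self.dileu_last_extended:
            raise GrammarError("dileu last-slot canonical set must be within extended set")

    # spacer values tried at one anchor, most-preferred first
    def tyr_spacers(self) -> tuple[int, ...]:
        return (self.tyr_spacer_canonical, *[
            s for s in self.tyr_spacer_extended if s != self.tyr_spacer_canonical
        ])

    def dileu_spacers(self) -> tuple[int, ...]:
        rest = [s for s in self.dileu_spacer_extended if s != self.dileu_spacer_canonical]
        return (self.dileu_spacer_canonical, *rest)

    def canonical_only(self) -> "GrammarConfig":
        """A restriction of this grammar to the strict patterns."""
        return GrammarConfig(
            phi_set=self.phi_set,
            tyr_spacer_canonical=self.tyr_spacer_canonical,
            tyr_spacer_extended=(),
            dileu_first_canonical=self.dileu_first_canonical,
            dileu_first_extended=self.dileu_first_canonical,
            dileu_spacer_canonical=self.dileu_spacer_canonical,
            dileu_spacer_extended=(self.dileu_spacer_canonical,),
            dileu_last_canonical=self.dileu_last_canonical,
            dileu_last_extended=self.dileu_last_canonical,
            include_npxy=self.include_npxy,
        )


DEFAULT_GRAMMAR = GrammarConfig()


@dataclass(frozen=True)
class MotifHit:
    """One matched sorting-signal occurrence (1-based inclusive span)."""

    protein_id: str
    family: str
    classification: str
    start: int
    end: int
    peptide: str
    spacer: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def formatted(self) -> str:
        """Catalogue notation, e.g. ``Y230VFF`` or ``(L260KDILR)``."""
        text = f"{self.peptide[0]}{self.start}{self.peptide[1:]}"
        return f"({text})" if self.classification == NON_CANONICAL else text


def _is_x(residue: str) -> bool:
    # unconstrained slot: any standard residue or ambiguity letter
    return residue in VALID_AA


def _try_tyrosine(seq: str, anchor: int, config: GrammarConfig,
                  required_spacer: int | None = None) -> tuple[str, int] | None:
    """Return (classification, spacer) for the best tyrosine match at anchor."""
    if seq[anchor - 1] != "Y":
        return None
    spacers = config.tyr_spacers() if required_spacer is None else (required_spacer,)
    for spacer in spacers:
        end = anchor + spacer + 1
        if end > len(seq):
            continue
        body = seq[anchor:anchor + spacer]
        if not all(_is_x(c) for c in body):
            continue
        if seq[end - 1] not in config.phi_set:
            continue
        cls = CANONICAL if spacer == config.tyr_spacer_canonical else NON_CANONICAL
        return cls, spacer
    return None


def _try_dileucine(seq: str, anchor: int, config: GrammarConfig,
                   required_spacer: int | None = None) -> tuple[str, int] | None:
    first = seq[anchor - 1]
    if first not in config.dileu_first_extended:
        return None
    if required_spacer is not None:
        spacers = (required_spacer,)
    else:
        spacers = config.dileu_spacers()
    best: tuple[str, int] | None = None
    for spacer in spacers:
        end = anchor + spacer + 2
        if end > len(seq):
            continue
        body = seq[anchor:anchor + spacer]
        if not all(_is_x(c) for c in body):
            continue
        penult, last = seq[end - 2], seq[end - 1]
        if penult != "L" or last not in config.dileu_last_extended:
            continue
        canonical = (
            first in config.dileu_first_canonical
            and spacer == config.dileu_spacer_canonical
            and last in config.dileu_last_canonical
        )
        if canonical:
            return CANONICAL, spacer
        if best is None or spacer < best[1]:
            best = (NON_CANONICAL, spacer)
    return best


def _try_npxy(seq: str, anchor: int) -> tuple[str, int] | None:
    end = anchor + 3
    if end > len(seq):
        return None
    n, p, x, y = seq[anchor - 1:end]
    if n == "N" and p == "P" and _is_x(x) and y == "Y":
        return CANONICAL, 1
    return None


def match_at(
    sequence: str,
    anchor: int,
    family: str,
    config: GrammarConfig = DEFAULT_GRAMMAR,
    protein_id: str = "",
    required_spacer: int | None = None,
) -> MotifHit | None:
    """Best motif of ``family`` anchored at ``anchor`` (1-based), or None.

    All spacer values the grammar allows are tried; canonical matches beat
    non-canonical ones, and among non-canonical matches the smallest spacer
    wins, so at most one hit exists per (anchor, family).
    """
    sequence = sequence.upper()
    if family not in FAMILIES:
        raise GrammarError(f"unknown motif family {family!r}")
    if not 1 <= anchor <= len(sequence):
        raise IndexError(f"anchor {anchor} outside 1..{len(sequence)}")
    if family == "tyrosine":
        res = _try_tyrosine(sequence, anchor, config, required_spacer)
        tail = 1
    elif family == "dileucine":
        res = _try_dileucine(sequence, anchor, config, required_spacer)
        tail = 2
    else:
        if not config.include_npxy:
            return None
        res = _try_npxy(sequence, anchor)
        tail = 2
    if res is None:
        return None
    cls, spacer = res
    end = anchor + spacer + tail
    return MotifHit(
        protein_id=protein_id,
        family=family,
        classification=cls,
        start=anchor,
        end=end,
        peptide=sequence[anchor - 1:end],
        spacer=spacer,
    )


def enumerate_hits(
    sequence: str,
    config: GrammarConfig = DEFAULT_GRAMMAR,
    protein_id: str = "",
) -> list[MotifHit]:
    """All motif hits in a sequence, at most one per (anchor, family).

    Overlapping hits of different families are all retained; output is
    sorted by start position, then family name.
    """
    hits: list[MotifHit] = []
    for anchor in range(1, len(sequence) + 1):
        for family in FAMILIES:
            if family == "npxy" and not config.include_npxy:
                continue
            hit = match_at(sequence, anchor, family, config, protein_id=protein_id)
            if hit is not None:
                hits.append(hit)
    hits.sort(key=lambda h: (h.start, h.family))
    return hits


def classify_peptide(
    peptide: str,
    config: GrammarConfig = DEFAULT_GRAMMAR,
) -> tuple[str, str]:
    """Classify a whole peptide as one motif occurrence.

    The peptide is anchored at its first residue and must be matched in
    full (its length fixes the spacer for each family).  Returns
    ``(family, classification)``; raises :class:`GrammarError` when the
    length is outside 4..8 or nothing matches.
    """
    peptide = peptide.upper()
    if not 4 <= len(peptide) <= 8:
        raise GrammarError(
            f"peptide {peptide!r}: length {len(peptide)} outside the 4..8 motif range"
        )
    candidates: list[tuple[int, int, int, str, str]] = []
    for family in FAMILIES:
        tail = 1 if family == "tyrosine" else 2
        spacer = len(peptide) - tail - 1
        if family == "tyrosine":
            allowed = set(config.tyr_spacers())
        elif family == "dileucine":
            allowed = set(config.dileu_spacers())
        else:
            allowed = {1} if config.include_npxy else set()
        if spacer not in allowed:
            continue
        hit = match_at(peptide, 1, family, config, required_spacer=spacer)
        if hit is not None and hit.end == len(peptide):
            candidates.append(
                (0 if hit.classification == CANONICAL else 1,
                 hit.spacer, _FAMILY_RANK[family], family, hit.classification)
            )
    if not candidates:
        raise GrammarError(f"peptide {peptide!r} matches no endocytic-motif grammar")
    candidates.sort()
    _, _, _, family, classification = candidates[0]
    return family, classification
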