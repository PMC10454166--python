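"""Topology-aware motif scanning.

The grammar of :mod:`cxmotifs.motif_grammar` fires anywhere in a sequence;
only a subset of those matches can plausibly engage the clathrin adaptor
machinery.  This module applies the biological filters:

* only cytoplasm-exposed domains are searched (by default the
  intracellular loop and the C-terminal domain — the N terminus, although
  cytoplasmic, is buried in the channel vestibule and excluded);
* a motif must sit at least ``min_tm_distance`` residues away from the
  nearest flanking transmembrane helix, because clathrin adaptors need
  physical clearance from the membrane (a per-hit whitelist can exempt
  documented exceptions, e.g. the membrane-proximal Cx43 Y230 signal that
  the reference catalogue lists despite its position);
* motifs straddling a segment boundary are dropped (they cannot be
  assigned to a single domain) with a logged reason.

Separately, every connexin carries a di-leucine-like motif of unknown
function at the TM4/C-terminal transition zone; :func:`scan_junction`
locates it inside a window around the TM4 end, deliberately ignoring the
distance rule.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace

from .motif_grammar import (
    CANONICAL,
    DEFAULT_GRAMMAR,
    GrammarConfig,
    MotifHit,
    NON_CANONICAL,
    enumerate_hits,
)
from .sequence_io import (
    CYTOPLASMIC_KINDS,
    ProteinRecord,
    TopologyError,
    TopologyMap,
)

logger = logging.getLogger(__name__)

CATEGORIES = ("TYR_CANONICAL", "DILEU_CANONICAL", "NONCANONICAL_ONLY", "NONE")


@dataclass(frozen=True)
class ScanConfig:
    """Filtering parameters for the cytoplasmic scan.

    ``min_tm_distance`` counts residues strictly between the motif's
    nearest residue and the nearest flanking TM boundary; a hit is kept
    when that count is >= the threshold.  ``whitelist`` holds
    ``(protein_id, anchor, family)`` triples exempt from the distance rule
    (matched case-insensitively on the protein id).
    """

    min_tm_distance: int = 10
    searched_domains: frozenset[str] = frozenset({"IL", "CT"})
    whitelist: frozenset[tuple[str, int, str]] = frozenset({("CX43", 230, "tyrosine")})
    junction_window: tuple[int, int] = (10, 10)  # (upstream, downstream) of TM4 end

    def __post_init__(self) -> None:
        object.__setattr__(self, "searched_domains", frozenset(self.searched_domains))
        object.__setattr__(
            self,
            "whitelist",
            frozenset((pid.upper(), int(pos), fam) for pid, pos, fam in self.whitelist),
        )
        bad = self.searched_domains - CYTOPLASMIC_KINDS
        if bad:
            raise ValueError(
                f"searched_domains may only contain cytoplasmic kinds; got {sorted(bad)}"
            )
        if self.min_tm_distance < 0:
            raise ValueError("min_tm_distance must be non-negative")

    def is_whitelisted(self, protein_id: str, anchor: int, family: str) -> bool:
        return (protein_id.upper(), anchor, family) in self.whitelist


DEFAULT_SCAN = ScanConfig()


@dataclass(frozen=True)
class FilteredHit:
    """A motif hit that survived the domain and TM-distance filters."""

    hit: MotifHit
    domain_kind: str
    tm_distance: int
    whitelisted: bool = False

    # convenience pass-throughs
    @property
    def protein_id(self) -> str:
        return self.hit.protein_id

    @property
    def family(self) -> str:
        return self.hit.family

    @property
    def classification(self) -> str:
        return self.hit.classification

    @property
    def start(self) -> int:
        return self.hit.start

    @property
    def end(self) -> int:
        return self.hit.end

    @property
    def peptide(self) -> str:
        return self.hit.peptide


@dataclass(frozen=True)
class JunctionMotif:
    """Di-leucine-like motif at the TM4/CT transition zone.

    Layout is fixed: an acidic first residue, three unconstrained
    residues, then a two-residue terminus whose composition defines
    ``terminus_class``.
    """

    protein_id: str
    start: int
    peptide: str
    first_slot: str
    terminus: str
    terminus_class: str


def tm_distance_of(hit: MotifHit, topology: TopologyMap, domain_kind: str) -> int:
    """Residues strictly between the motif and the nearest flanking TM helix.

    CT motifs are bounded upstream by TM4 only; IL motifs by TM2 upstream
    and TM3 downstream; NT motifs by TM1 downstream.
    """
    if domain_kind == "CT":
        return hit.start - topology.segment("TM4").end - 1
    if domain_kind == "IL":
        return min(
            hit.start - topology.segment("TM2").end - 1,
            topology.segment("TM3").start - hit.end - 1,
        )
    if domain_kind == "NT":
        return topology.segment("TM1").start - hit.end - 1
    raise ValueError(f"no TM distance defined for domain {domain_kind!r}")


def filter_hits(
    hits: list[MotifHit],
    topology: TopologyMap,
    config: ScanConfig = DEFAULT_SCAN,
) -> list[FilteredHit]:
    """Apply the domain and TM-proximity filters, preserving input order."""
    kept: list[FilteredHit] = []
    for hit in hits:
        start_kind = topology.domain_of(hit.start)
        if hit.end > topology.length or topology.domain_of(hit.end) != start_kind:
            logger.info(
                "%s: dropped %s %s at %d: span crosses a segment boundary",
                hit.protein_id, hit.family, hit.peptide, hit.start,
            )
            continue
        if start_kind not in config.searched_domains:
            continue
        distance = tm_distance_of(hit, topology, start_kind)
        white = config.is_whitelisted(hit.protein_id, hit.start, hit.family)
        if distance < config.min_tm_distance and not white:
            logger.info(
                "%s: dropped %s %s at %d: %d residues from TM (< %d)",
                hit.protein_id, hit.family, hit.peptide, hit.start,
                distance, config.min_tm_distance,
            )
            continue
        if white and distance < config.min_tm_distance:
            logger.info(
                "%s: whitelisted %s %s at %d despite TM distance %d",
                hit.protein_id, hit.family, hit.peptide, hit.start, distance,
            )
        kept.append(
            FilteredHit(hit=hit, domain_kind=start_kind,
                        tm_distance=distance, whitelisted=white)
        )
    return kept


def _terminus_class(penult: str, last: str) -> str:
    if penult == "L" and last in "LI":
        return "canonical"
    if penult == "L":
        return "last_atypical"
    if last in "LI":
        return "second_last_atypical"
    return "both_atypical"


def scan_junction(
    record: ProteinRecord,
    topology: TopologyMap,
    config: ScanConfig = DEFAULT_SCAN,
) -> JunctionMotif | None:
    """Find the [D/E]XXX?? junction motif around the TM4 end.

    Anchors within ``junction_window`` of the TM4 end are tested for an
    acidic first residue followed by a full six-residue window; the anchor
    closest to the TM4 end wins (ties break upstream).  Returns None when
    no D/E anchor yields a complete window.
    """
    tm4_end = topology.segment("TM4").end
    up, down = config.junction_window
    seq = record.sequence
    candidates: list[tuple[int, int, int]] = []
    for anchor in range(max(1, tm4_end - up), min(len(seq) - 5, tm4_end + down) + 1):
        if seq[anchor - 1] in "DE":
            # sort key: distance to TM4 end, then upstream-first
            candidates.append((abs(anchor - tm4_end), 0 if anchor <= tm4_end else 1, anchor))
    if not candidates:
        return None
    _, _, anchor = min(candidates)
    peptide = seq[anchor - 1:anchor + 5]
    return JunctionMotif(
        protein_id=record.id,
        start=anchor,
        peptide=peptide,
        first_slot=peptide[0],
        terminus=peptide[4:6],
        terminus_class=_terminus_class(peptide[4], peptide[5]),
    )


@dataclass(frozen=True)
class ScanResult:
    protein_id: str
    hits: tuple[FilteredHit, ...]
    junction: JunctionMotif | None
    category: str


def categorize(hits: list[FilteredHit] | tuple[FilteredHit, ...]) -> str:
    if any(h.family == "tyrosine" and h.classification == CANONICAL for h in hits):
        return "TYR_CANONICAL"
    if any(h.family == "dileucine" and h.classification == CANONICAL for h in hits):
        return "DILEU_CANONICAL"
    if any(h.classification == NON_CANONICAL for h in hits):
        return "NONCANONICAL_ONLY"
    return "NONE"


def scan_protein(
    record: ProteinRecord,
    topology: TopologyMap,
    grammar_config: GrammarConfig = DEFAULT_GRAMMAR,
    scan_config: ScanConfig = DEFAULT_SCAN,
) -> ScanResult:
    """Full per-protein pipeline: enumerate, filter, junction scan, categorise."""
    topology.check_against(record)
    raw = enumerate_hits(record.sequence, grammar_config, protein_id=record.id)
    kept = filter_hits(raw, topology, scan_config)
    junction = scan_junction(record, topology, scan_config)
    return ScanResult(
        protein_id=record.id,
        hits=tuple(kept),
        junction=junction,
        category=categorize(kept),
    )


@dataclass(frozen=True)
class SummaryCounts:
    """Family-wide tallies over a set of scan results."""

    n_proteins: int
    category_counts: dict[str, int]
    n_canonical_any: int            # proteins with >=1 canonical motif of any family
    n_motifs_total: int
    n_noncanonical_motifs: int
    n_proteins_with_noncanonical: int
    location_counts: dict[str, int]  # IL_only / CT_only / both, over proteins with hits


def summarize(results: list[ScanResult]) -> SummaryCounts:
    seen: set[str] = set()
    for res in results:
        if res.protein_id in seen:
            raise ValueError(f"duplicate protein_id {res.protein_id!r} in results")
        seen.add(res.protein_id)
    cats = Counter(res.category for res in results)
    locations = Counter()
    n_canon_any = 0
    n_motifs = 0
    n_noncanon = 0
    n_prot_noncanon = 0
    for res in results:
        n_motifs += len(res.hits)
        noncanon = [h for h in res.hits if h.classification == NON_CANONICAL]
        n_noncanon += len(noncanon)
        if noncanon:
            n_prot_noncanon += 1
        if any(h.classification == CANONICAL for h in res.hits):
            n_canon_any += 1
        kinds = {h.domain_kind for h in res.hits}
        if kinds >= {"IL", "CT"}:
            locations["both"] += 1
        elif kinds == {"IL"}:
            locations["IL_only"] += 1
        elif kinds == {"CT"}:
            locations["CT_only"] += 1
    return SummaryCounts(
        n_proteins=len(results),
        category_counts={cat: cats.get(cat, 0) for cat in CATEGORIES},
        n_canonical_any=n_canon_any,
        n_motifs_total=n_motifs,
        n_noncanonical_motifs=n_noncanon,
        n_proteins_with_noncanonical=n_prot_noncanon,
        location_counts=dict(locations),
    )
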