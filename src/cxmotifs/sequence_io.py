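"""Protein sequence and membrane-topology I/O.

Connexins are four-pass transmembrane proteins whose N terminus, single
intracellular loop (IL) and C terminus face the cytoplasm.  This module
reads protein sequences (FASTA) and per-protein topology annotations
(a flat TSV mirroring UniProt feature tables) and validates the fixed
nine-segment connexin topology model::

    NT - TM1 - E1 - TM2 - IL - TM3 - E2 - TM4 - CT

All residue coordinates are 1-based and inclusive throughout the package,
so that a tyrosine reported at position 230 is ``sequence[230]`` in this
convention (``sequence[229]`` in Python's 0-based strings).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Ambiguity letters accepted at ingest; they never satisfy a constrained
#: grammar slot (see :mod:`cxmotifs.motif_grammar`).
AMBIGUOUS_AA = frozenset("XBZU")
VALID_AA = STANDARD_AA | AMBIGUOUS_AA

#: The nine topology segment kinds, in their mandatory N→C order.
SEGMENT_ORDER = ("NT", "TM1", "E1", "TM2", "IL", "TM3", "E2", "TM4", "CT")
TM_KINDS = frozenset({"TM1", "TM2", "TM3", "TM4"})
CYTOPLASMIC_KINDS = frozenset({"NT", "IL", "CT"})
EXTRACELLULAR_KINDS = frozenset({"E1", "E2"})


class FastaError(ValueError):
    """Malformed FASTA input (empty sequence, duplicate id, illegal residue)."""


class TopologyError(ValueError):
    """Malformed or inconsistent topology annotation."""


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence.

    ``sequence`` is stored upper-case; indexing helpers are 1-based.
    """

    id: str
    sequence: str
    gene_name: str = ""
    protein_name: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.id:
            raise FastaError("record id must be non-empty")
        if not self.sequence:
            raise FastaError(f"empty sequence for record {self.id!r}")
        bad = sorted(set(self.sequence) - VALID_AA)
        if bad:
            raise FastaError(
                f"illegal residue(s) {''.join(bad)!r} in record {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(
                f"position {position} outside 1..{len(self.sequence)} "
                f"for record {self.id!r}"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True)
class TopologySegment:
    kind: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_ORDER:
            raise TopologyError(f"unknown segment kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise TopologyError(
                f"segment {self.kind}: invalid span {self.start}..{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class TopologyMap:
    """Ordered, contiguous nine-segment topology of one protein.

    Segments must appear exactly once each in ``SEGMENT_ORDER``, be
    contiguous, and start at residue 1.
    """

    protein_id: str
    segments: tuple[TopologySegment, ...]

    def __post_init__(self) -> None:
        kinds = tuple(s.kind for s in self.segments)
        if kinds != SEGMENT_ORDER:
            missing = [k for k in SEGMENT_ORDER if k not in kinds]
            if missing:
                raise TopologyError(
                    f"{self.protein_id}: missing segment(s) {', '.join(missing)}"
                )
            raise TopologyError(
                f"{self.protein_id}: segments out of order or duplicated: {kinds}"
            )
        if self.segments[0].start != 1:
            raise TopologyError(f"{self.protein_id}: topology must start at residue 1")
        for prev, nxt in zip(self.segments, self.segments[1:]):
            if nxt.start != prev.end + 1:
                kind_rel = "gap" if nxt.start > prev.end + 1 else "overlap"
                raise TopologyError(
                    f"{self.protein_id}: {kind_rel} between {prev.kind} "
                    f"(ends {prev.end}) and {nxt.kind} (starts {nxt.start})"
                )

    @property
    def length(self) -> int:
        return self.segments[-1].end

    def segment(self, kind: str) -> TopologySegment:
        for seg in self.segments:
            if seg.kind == kind:
                return seg
        raise TopologyError(f"{self.protein_id}: no segment {kind!r}")

    def domain_of(self, position: int) -> str:
        """Segment kind containing a 1-based residue position."""
        if not 1 <= position <= self.length:
            raise IndexError(
                f"position {position} outside covered range 1..{self.length} "
                f"for {self.protein_id!r}"
            )
        for seg in self.segments:
            if position in seg:
                return seg.kind
        raise AssertionError("contiguous topology must cover every position")

    def check_against(self, record: ProteinRecord) -> None:
        if self.length != len(record.sequence):
            raise TopologyError(
                f"{self.protein_id}: topology covers {self.length} residues but "
                f"sequence has {len(record.sequence)}"
            )


# ---------------------------------------------------------------------------
# FASTA

_META_KEYS = ("gene", "protein", "species")


def _parse_description(description: str) -> dict[str, str]:
    meta: dict[str, str] = {}
    for token in description.split()[1:]:
        if "=" in token:
            key, _, value = token.partition("=")
            if key in _META_KEYS:
                meta[key] = value
    return meta


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into :class:`ProteinRecord` objects.

    The header token before the first whitespace becomes the record id;
    optional ``gene=``/``protein=``/``species=`` tokens in the description
    populate the naming fields (they are what :func:`write_fasta` emits).
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise FastaError(f"duplicate record id {entry.id!r} in {path.name}")
        seen.add(entry.id)
        meta = _parse_description(entry.description)
        try:
            records.append(
                ProteinRecord(
                    id=entry.id,
                    sequence=str(entry.seq),
                    gene_name=meta.get("gene", ""),
                    protein_name=meta.get("protein", ""),
                    species=meta.get("species", ""),
                )
            )
        except FastaError as exc:
            raise FastaError(f"{path.name}: {exc}") from exc
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    entries = []
    for rec in records:
        desc = " ".join(
            f"{key}={value}"
            for key, value in (
                ("gene", rec.gene_name),
                ("protein", rec.protein_name),
                ("species", rec.species),
            )
            if value
        )
        entries.append(SeqRecord(Seq(rec.sequence), id=rec.id, description=desc))
    SeqIO.write(entries, str(path), "fasta")


# ---------------------------------------------------------------------------
# Topology TSV

TOPOLOGY_HEADER = ("protein_id", "kind", "start", "end")


def read_topology(
    path: str | Path,
    records: Sequence[ProteinRecord] | None = None,
) -> dict[str, TopologyMap]:
    """Read the flat topology TSV (``protein_id\tkind\tstart\tend``).

    When ``records`` is given, each topology's coverage is checked against
    the corresponding sequence length.
    """
    path = Path(path)
    rows: dict[str, list[TopologySegment]] = {}
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != TOPOLOGY_HEADER:
            raise TopologyError(
                f"{path.name}: expected header {TOPOLOGY_HEADER}, got {tuple(header)}"
            )
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise TopologyError(f"{path.name}:{lineno}: expected 4 columns")
            pid, kind, start, end = fields
            try:
                seg = TopologySegment(kind=kind, start=int(start), end=int(end))
            except (ValueError, TopologyError) as exc:
                raise TopologyError(f"{path.name}:{lineno} ({pid}): {exc}") from exc
            rows.setdefault(pid, []).append(seg)
    maps = {
        pid: TopologyMap(protein_id=pid, segments=tuple(segs))
        for pid, segs in rows.items()
    }
    if records is not None:
        by_id = {rec.id: rec for rec in records}
        for pid, topo in maps.items():
            if pid in by_id:
                topo.check_against(by_id[pid])
    return maps


def write_topology(maps: Iterable[TopologyMap], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(TOPOLOGY_HEADER) + "\n")
        for topo in maps:
            for seg in topo.segments:
                handle.write(
                    f"{topo.protein_id}\t{seg.kind}\t{seg.start}\t{seg.end}\n"
                )


def make_topology(protein_id: str, lengths: dict[str, int]) -> TopologyMap:
    """Build a contiguous TopologyMap from per-segment lengths."""
    segs = []
    pos = 1
    for kind in SEGMENT_ORDER:
        n = lengths[kind]
        segs.append(TopologySegment(kind=kind, start=pos, end=pos + n - 1))
        pos += n
    return TopologyMap(protein_id=protein_id, segments=tuple(segs))
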