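"""Connexin-like synthetic benchmark proteins.

Real connexin sequences carry their motifs at positions fixed by
evolution; to test a scanner one needs proteins where the ground truth is
known by construction.  This module generates four-pass membrane proteins
with the standard nine-segment topology (NT-TM1-E1-TM2-IL-TM3-E2-TM4-CT),
plants sorting-signal motifs at controlled distances from the
transmembrane helices, places decoys where the pipeline must *not* report
them (extracellular loops, the membrane-proximal zone, or near-miss
patterns with one constrained slot broken), and derives divergent
"ortholog" copies whose motifs are either preserved or deliberately
destroyed.

Every generated protein comes with a complete truth table.  Accidental
grammar matches arising from the random background are enumerated rather
than prevented (preventing them would bias the background composition);
they are listed in the truth table so recovery tests can account for
them.

Randomness contract: one root seed; streams are spawned per protein and,
within a protein, in the fixed order topology → background → planting →
decoys → ortholog, so adding proteins to a spec never reshuffles earlier
ones.  Same spec + seed ⇒ byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .motif_grammar import (
    CANONICAL,
    DEFAULT_GRAMMAR,
    NON_CANONICAL,
    MotifHit,
    enumerate_hits,
    match_at,
)
from .scan_pipeline import DEFAULT_SCAN, ScanConfig, filter_hits, tm_distance_of
from .sequence_io import (
    STANDARD_AA,
    ProteinRecord,
    TopologyMap,
    make_topology,
    write_fasta,
    write_topology,
)

#: Residues safe for unconstrained slots inside planted motifs: the 20
#: standard residues minus everything that could seed or terminate a grammar
#: slot (Y, D, E, L, I, V, F, M, R, N); guarantees a planted motif is
#: matched at exactly its intended spacer and classification.
_INERT = "ACGHKPQSTW"
_BACKGROUND = "".join(sorted(STANDARD_AA))  # uniform over the 20 standard residues
_TM_RESIDUES = "AILVFGMW"  # hydrophobic alphabet for TM helices

DECOY_PLACEMENTS = ("extracellular", "near_TM", "near_miss")


class PlacementError(ValueError):
    """A planted motif or decoy does not fit its target segment."""


@dataclass(frozen=True)
class PlantedMotif:
    family: str
    classification: str
    domain: str               # NT, IL or CT
    tm_distance: int
    preserve_in_ortholog: bool = True


@dataclass(frozen=True)
class Decoy:
    pattern: str
    placement: str            # extracellular | near_TM | near_miss

    def __post_init__(self) -> None:
        if self.placement not in DECOY_PLACEMENTS:
            raise ValueError(f"unknown decoy placement {self.placement!r}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters; ``seed`` is required."""

    seed: int
    n_proteins: int = 1
    planted: tuple[PlantedMotif, ...] = ()
    decoys: tuple[Decoy, ...] = ()
    ortholog_sub_prob: float = 0.05
    segment_ranges: dict[str, tuple[int, int]] = field(default_factory=lambda: {
        "NT": (20, 25), "TM1": (18, 24), "E1": (28, 36), "TM2": (18, 24),
        "IL": (40, 60), "TM3": (18, 24), "E2": (28, 36), "TM4": (18, 24),
        "CT": (80, 130),
    })

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted", tuple(self.planted))
        object.__setattr__(self, "decoys", tuple(self.decoys))
        if not 0.0 <= self.ortholog_sub_prob <= 1.0:
            raise ValueError("ortholog_sub_prob must be in [0, 1]")


@dataclass
class TruthEntry:
    protein_id: str
    kind: str                 # planted | decoy | accidental
    family: str
    classification: str
    start: int
    end: int
    expected_kept: bool
    preserve_in_ortholog: bool | None = None
    expected_conserved: bool | None = None


@dataclass
class TruthTable:
    entries: list[TruthEntry] = field(default_factory=list)

    def for_protein(self, protein_id: str, kind: str | None = None) -> list[TruthEntry]:
        return [
            e for e in self.entries
            if e.protein_id == protein_id and (kind is None or e.kind == kind)
        ]

    def protein_ids(self) -> list[str]:
        seen: list[str] = []
        for e in self.entries:
            if e.protein_id not in seen:
                seen.append(e.protein_id)
        return seen

    def write_tsv(self, path: str | Path) -> None:
        cols = ("protein_id", "kind", "family", "class", "start", "end",
                "expected_kept", "expected_conserved")
        with open(path, "w") as handle:
            handle.write("\t".join(cols) + "\n")
            for e in self.entries:
                conserved = "" if e.expected_conserved is None else str(e.expected_conserved)
                handle.write(
                    f"{e.protein_id}\t{e.kind}\t{e.family}\t{e.classification}\t"
                    f"{e.start}\t{e.end}\t{e.expected_kept}\t{conserved}\n"
                )


def _streams(spec: SyntheticSpec, index: int) -> dict[str, np.random.Generator]:
    """Named RNG streams for protein ``index`` (documented spawn order)."""
    root = np.random.SeedSequence([int(spec.seed), int(index)])
    names = ("topology", "background", "planting", "decoys", "ortholog")
    children = root.spawn(len(names))
    return {name: np.random.Generator(np.random.PCG64(child))
            for name, child in zip(names, children)}


def _draw(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))


def _make_peptide(planted: PlantedMotif, rng: np.random.Generator) -> str:
    """A peptide whose best match at its first residue has exactly the
    requested family and classification (inert X slots prevent shorter
    shadow matches)."""
    grammar = DEFAULT_GRAMMAR
    fam, cls = planted.family, planted.classification
    if fam == "tyrosine":
        if cls == CANONICAL:
            spacer = grammar.tyr_spacer_canonical
        else:
            spacer = int(rng.choice(grammar.tyr_spacer_extended))
        return "Y" + _draw(rng, _INERT, spacer) + str(rng.choice(sorted(grammar.phi_set)))
    if fam == "dileucine":
        first = str(rng.choice(["D", "E"]))
        spacer = grammar.dileu_spacer_canonical
        last = str(rng.choice(["L", "I"]))
        if cls == NON_CANONICAL:
            relax = rng.choice(["first", "spacer", "last"])
            if relax == "first":
                first = "L"
            elif relax == "spacer":
                spacer = int(rng.choice([s for s in grammar.dileu_spacer_extended
                                         if s != grammar.dileu_spacer_canonical]))
                if spacer < grammar.dileu_spacer_canonical:
                    # a trailing background L/I could otherwise extend this
                    # into a canonical spacer-3 match: the spacer-3 penult
                    # slot coincides with our last slot, so force I there
                    last = "I"
            else:
                last = str(rng.choice(["V", "R"]))
        return first + _draw(rng, _INERT, spacer) + "L" + last
    if fam == "npxy":
        return "NP" + _draw(rng, _INERT, 1) + "Y"
    raise ValueError(f"unknown family {fam!r}")


def _planting_span(
    planted: PlantedMotif, length: int, topology: TopologyMap
) -> tuple[int, int]:
    """1-based span realising the requested domain and TM distance."""
    d = planted.tm_distance
    if planted.domain == "CT":
        start = topology.segment("TM4").end + 1 + d
        end = start + length - 1
        if end > topology.segment("CT").end:
            raise PlacementError(f"{planted}: does not fit CT at distance {d}")
    elif planted.domain == "IL":
        start = topology.segment("TM2").end + 1 + d
        end = start + length - 1
        if topology.segment("TM3").start - end - 1 < d:
            raise PlacementError(f"{planted}: does not fit IL at distance {d}")
    elif planted.domain == "NT":
        end = topology.segment("TM1").start - 1 - d
        start = end - length + 1
        if start < 1:
            raise PlacementError(f"{planted}: does not fit NT at distance {d}")
    else:
        raise PlacementError(f"{planted}: domain must be cytoplasmic (NT/IL/CT)")
    return start, end


def _break_motif(pattern: str) -> str:
    """Corrupt exactly one constrained slot of a real motif pattern."""
    if pattern[0] == "Y":
        return "F" + pattern[1:]            # anchor Y -> F (not tolerated)
    if pattern[0] == "N" and pattern[1] == "P":
        return pattern[0] + "A" + pattern[2:]
    # di-leucine: penultimate L -> A
    return pattern[:-2] + "A" + pattern[-1]


def _occupy(occupied: list[tuple[int, int]], span: tuple[int, int], what: str) -> None:
    for s, e in occupied:
        if not (span[1] < s or span[0] > e):
            raise PlacementError(f"{what}: span {span} collides with {s, e}")
    occupied.append(span)


def generate(
    spec: SyntheticSpec,
    scan_config: ScanConfig = DEFAULT_SCAN,
) -> tuple[list[ProteinRecord], dict[str, TopologyMap], TruthTable]:
    """Generate records, topologies and the complete truth table.

    ``scan_config`` defines which planted items count as in-scope
    (``expected_kept``); it defaults to the standard pipeline settings.
    """
    records: list[ProteinRecord] = []
    topologies: dict[str, TopologyMap] = {}
    truth = TruthTable()
    for index in range(spec.n_proteins):
        pid = f"SYN{index + 1:03d}"
        streams = _streams(spec, index)
        lengths = {
            kind: int(streams["topology"].integers(lo, hi + 1))
            for kind, (lo, hi) in spec.segment_ranges.items()
        }
        topology = make_topology(pid, lengths)
        seq = list(_draw(streams["background"], _BACKGROUND, topology.length))
        for seg_kind in ("TM1", "TM2", "TM3", "TM4"):
            seg = topology.segment(seg_kind)
            seq[seg.start - 1:seg.end] = _draw(
                streams["background"], _TM_RESIDUES, len(seg)
            )

        occupied: list[tuple[int, int]] = []
        planted_spans: list[tuple[PlantedMotif, int, int, str]] = []
        for planted in spec.planted:
            peptide = _make_peptide(planted, streams["planting"])
            span = _planting_span(planted, len(peptide), topology)
            _occupy(occupied, span, f"{pid} planted {planted.family}")
            seq[span[0] - 1:span[1]] = peptide
            planted_spans.append((planted, span[0], span[1], peptide))

        decoy_spans: list[tuple[Decoy, int, int, str]] = []
        e1_cursor = topology.segment("E1").start + 2
        near_tm_cursor = topology.segment("TM4").end + 3  # 2 residues clearance
        near_miss_cursor = topology.segment("CT").end
        for decoy in spec.decoys:
            pattern = decoy.pattern.upper()
            if decoy.placement == "extracellular":
                span = (e1_cursor, e1_cursor + len(pattern) - 1)
                if span[1] > topology.segment("E1").end:
                    raise PlacementError(f"{pid}: decoy {pattern} does not fit E1")
                e1_cursor = span[1] + 2
            elif decoy.placement == "near_TM":
                span = (near_tm_cursor, near_tm_cursor + len(pattern) - 1)
                dist = span[0] - topology.segment("TM4").end - 1
                if dist >= scan_config.min_tm_distance:
                    raise PlacementError(
                        f"{pid}: near_TM decoy would sit {dist} residues from TM4"
                    )
                near_tm_cursor = span[1] + 2
            else:  # near_miss: valid location, broken pattern
                pattern = _break_motif(pattern)
                span = (near_miss_cursor - len(pattern) + 1, near_miss_cursor)
                near_miss_cursor = span[0] - 2
            if span[0] < 1 or span[1] > topology.length:
                raise PlacementError(f"{pid}: decoy {pattern} outside sequence")
            _occupy(occupied, span, f"{pid} decoy {pattern}")
            seq[span[0] - 1:span[1]] = pattern
            decoy_spans.append((decoy, span[0], span[1], pattern))

        sequence = "".join(seq)
        record = ProteinRecord(
            id=pid, sequence=sequence, gene_name=f"SYNG{index + 1}",
            protein_name=pid, species="synthetic",
        )
        records.append(record)
        topologies[pid] = topology

        planted_keys: set[tuple[int, str]] = set()
        for planted, start, end, peptide in planted_spans:
            hit = match_at(sequence, start, planted.family, protein_id=pid)
            if hit is None or hit.classification != planted.classification or hit.end != end:
                raise PlacementError(
                    f"{pid}: planted {planted.family} at {start} corrupted by overlap"
                )
            kept = (
                planted.domain in scan_config.searched_domains
                and tm_distance_of(hit, topology, planted.domain)
                >= scan_config.min_tm_distance
            )
            planted_keys.add((start, planted.family))
            truth.entries.append(TruthEntry(
                protein_id=pid, kind="planted", family=planted.family,
                classification=planted.classification, start=start, end=end,
                expected_kept=kept, preserve_in_ortholog=planted.preserve_in_ortholog,
            ))
        for decoy, start, end, pattern in decoy_spans:
            truth.entries.append(TruthEntry(
                protein_id=pid, kind="decoy", family="", classification="",
                start=start, end=end, expected_kept=False,
            ))
        # accidental matches: everything the grammar finds that was not planted
        accidental = [
            h for h in enumerate_hits(sequence, protein_id=pid)
            if (h.start, h.family) not in planted_keys
        ]
        kept_accidental = {
            (fh.start, fh.family)
            for fh in filter_hits(accidental, topology, scan_config)
        }
        for h in accidental:
            truth.entries.append(TruthEntry(
                protein_id=pid, kind="accidental", family=h.family,
                classification=h.classification, start=h.start, end=h.end,
                expected_kept=(h.start, h.family) in kept_accidental,
            ))
    return records, topologies, truth


def mutate_ortholog(
    record: ProteinRecord,
    truth: TruthTable,
    spec: SyntheticSpec,
) -> tuple[ProteinRecord, TruthTable]:
    """Derive a divergent ortholog of one generated protein.

    Point substitutions are applied outside planted footprints at
    ``spec.ortholog_sub_prob`` per site.  Preserve-flagged motifs are left
    untouched; destroy-flagged motifs have one constrained slot
    substituted with a disallowed residue, and any residual same-family
    match inside the conservation search window (footprint ± spacer
    slack) is scrubbed with further single-residue substitutions so the
    expected call is unambiguous.  Truth entries gain
    ``expected_conserved``.
    """
    index = truth.protein_ids().index(record.id)
    rng = _streams(spec, index)["ortholog"]
    planted = truth.for_protein(record.id, "planted")
    footprint: set[int] = set()
    for entry in planted:
        footprint.update(range(entry.start, entry.end + 1))

    seq = list(record.sequence)
    standard = sorted(STANDARD_AA)
    for pos in range(1, len(seq) + 1):
        if pos in footprint:
            continue
        if rng.random() < spec.ortholog_sub_prob:
            current = seq[pos - 1]
            choices = [c for c in standard if c != current]
            seq[pos - 1] = str(rng.choice(choices))

    slack = 3
    for entry in planted:
        if entry.preserve_in_ortholog:
            entry.expected_conserved = True
            continue
        # one constrained-slot substitution destroys the motif itself
        if entry.family == "tyrosine":
            seq[entry.start - 1] = "A"
        elif entry.family == "dileucine":
            seq[entry.end - 2] = "A"   # penultimate L
        else:
            seq[entry.start] = "A"     # the P of NPXY
        # scrub shadow matches inside the search window
        lo = max(1, entry.start - slack)
        hi = min(len(seq), entry.end + slack)
        for _ in range(32):
            residual = None
            for anchor in range(lo, hi + 1):
                m = match_at("".join(seq), anchor, entry.family)
                if m is not None:
                    residual = m
                    break
            if residual is None:
                break
            if entry.family == "tyrosine":
                seq[residual.start - 1] = "A"
            elif entry.family == "dileucine":
                seq[residual.end - 2] = "A"
            else:
                seq[residual.start] = "A"
        else:  # pragma: no cover - 32 scrubs always suffice on a finite window
            raise RuntimeError("failed to scrub destroyed motif neighbourhood")
        entry.expected_conserved = False

    ortholog = ProteinRecord(
        id=f"{record.id}_ORT", sequence="".join(seq),
        gene_name=record.gene_name, protein_name=record.protein_name,
        species="synthetic_ortholog",
    )
    return ortholog, truth


def emit(
    spec: SyntheticSpec,
    out_prefix: str | Path,
    scan_config: ScanConfig = DEFAULT_SCAN,
    with_orthologs: bool = True,
) -> None:
    """Write FASTA + topology TSV + truth TSV (and ortholog FASTA) to disk."""
    out_prefix = Path(out_prefix)
    records, topologies, truth = generate(spec, scan_config)
    orthologs = []
    if with_orthologs:
        for rec in records:
            ortholog, truth = mutate_ortholog(rec, truth, spec)
            orthologs.append(ortholog)
    write_fasta(records, out_prefix.with_suffix(".fasta"))
    write_topology(topologies.values(), out_prefix.with_suffix(".topology.tsv"))
    truth.write_tsv(out_prefix.with_suffix(".truth.tsv"))
    if orthologs:
        write_fasta(orthologs, out_prefix.with_suffix(".orthologs.fasta"))
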