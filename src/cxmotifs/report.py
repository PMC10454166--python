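"""Catalogue-style reporting.

Connexin genes are named by clade letter plus number (A1/GJA1, B2/GJB2,
...); the letter encodes the phylogenetic subfamily (alpha–epsilon).
This module renders per-protein scan results into the reference
catalogue's layout — one row per protein, motifs written in compact
``Y230VFF`` notation with non-canonical motifs in parentheses — plus a
machine-readable summary block.  Output is TSV/JSON rather than a styled
table: colour and underline semantics become explicit category and
conserved-flag columns so results stay diffable and testable.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, asdict
from pathlib import Path

from .motif_grammar import (
    CANONICAL,
    DEFAULT_GRAMMAR,
    GrammarConfig,
    NON_CANONICAL,
    classify_peptide,
)
from .scan_pipeline import ScanResult, SummaryCounts, summarize

logger = logging.getLogger(__name__)

CLADES = {"A": "alpha", "B": "beta", "C": "gamma", "D": "delta", "E": "epsilon"}
_CLADE_ORDER = {"alpha": 0, "beta": 1, "gamma": 2, "delta": 3, "epsilon": 4, "unknown": 5}

_SIGNAL_LABELS = {
    "TYR_CANONICAL": "tyrosine-based",
    "DILEU_CANONICAL": "di-leucine-based",
    "NONCANONICAL_ONLY": "non-canonical only",
    "NONE": "not identifiable",
}


@dataclass(frozen=True)
class CladeLabel:
    gene_name: str
    clade: str


def clade_of(gene_name: str) -> CladeLabel:
    """Clade from the gene-name letter; accepts both ``A1`` and ``GJA1``."""
    name = gene_name.strip().upper()
    core = name[2:] if name.startswith("GJ") else name
    if not core or core[0] not in CLADES:
        raise ValueError(f"unrecognized connexin gene name {gene_name!r}")
    return CladeLabel(gene_name=gene_name, clade=CLADES[core[0]])


def _gene_number(gene_name: str) -> float:
    m = re.search(r"(\d+(?:\.\d+)?)", gene_name)
    return float(m.group(1)) if m else float("inf")


@dataclass(frozen=True)
class ReportRow:
    gene_name: str
    protein_name: str
    clade: str
    category: str
    signal_type: str
    il_motifs: tuple[str, ...]
    ct_motifs: tuple[str, ...]
    not_conserved: tuple[str, ...]


def render_report(
    results: list[ScanResult],
    conservation_calls: list | None = None,
    names: dict[str, tuple[str, str]] | None = None,
) -> tuple[list[ReportRow], SummaryCounts, dict[str, dict[str, int]]]:
    """Build catalogue rows plus the summary block.

    ``names`` maps protein_id -> (gene_name, protein_name); missing ids
    fall back to the protein_id itself (clade becomes ``unknown``).
    ``conservation_calls`` (optional) marks motifs whose ortholog check
    failed.  Returns (rows, summary counts, per-clade category tallies).
    """
    names = names or {}
    not_conserved: dict[str, set[tuple[int, str]]] = {}
    for call in conservation_calls or []:
        if not call.conserved:
            not_conserved.setdefault(call.hit.protein_id, set()).add(
                (call.hit.start, call.hit.family)
            )
    missing = [res.protein_id for res in results
               if res.protein_id not in names and names]
    if missing and names:
        raise ValueError(f"no naming entry for protein id(s): {', '.join(missing)}")
    rows: list[ReportRow] = []
    for res in results:
        gene, protein = names.get(res.protein_id, (res.protein_id, res.protein_id))
        try:
            clade = clade_of(gene).clade
        except ValueError:
            logger.info("no clade for gene name %r; marking unknown", gene)
            clade = "unknown"
        il = tuple(h.hit.formatted() for h in res.hits if h.domain_kind == "IL")
        ct = tuple(h.hit.formatted() for h in res.hits if h.domain_kind == "CT")
        flagged = tuple(
            h.hit.formatted() for h in res.hits
            if (h.start, h.family) in not_conserved.get(res.protein_id, set())
        )
        rows.append(ReportRow(
            gene_name=gene, protein_name=protein, clade=clade,
            category=res.category, signal_type=_SIGNAL_LABELS[res.category],
            il_motifs=il, ct_motifs=ct, not_conserved=flagged,
        ))
    rows.sort(key=lambda r: (_CLADE_ORDER.get(r.clade, 5), _gene_number(r.gene_name)))
    summary = summarize(results)
    per_clade: dict[str, dict[str, int]] = {}
    for row in rows:
        per_clade.setdefault(row.clade, {}).setdefault(row.category, 0)
        per_clade[row.clade][row.category] += 1
    return rows, summary, per_clade


REPORT_COLUMNS = (
    "gene_name", "protein_name", "clade", "category", "signal_type",
    "il_motifs", "ct_motifs", "not_conserved",
)


def write_report_tsv(rows: list[ReportRow], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(REPORT_COLUMNS) + "\n")
        for row in rows:
            handle.write("\t".join([
                row.gene_name, row.protein_name, row.clade, row.category,
                row.signal_type,
                "; ".join(row.il_motifs), "; ".join(row.ct_motifs),
                "; ".join(row.not_conserved),
            ]) + "\n")


def write_report_json(
    rows: list[ReportRow],
    summary: SummaryCounts,
    per_clade: dict[str, dict[str, int]],
    path: str | Path,
) -> None:
    payload = {
        "proteins": [asdict(row) for row in rows],
        "summary": asdict(summary),
        "per_clade": per_clade,
    }
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2)
        handle.write("\n")


_MOTIF_RE = re.compile(r"^(\()?([A-Z])(\d+)([A-Z]+)(\))?$")


@dataclass(frozen=True)
class ParsedMotif:
    """A motif recovered from catalogue notation."""

    family: str
    classification: str
    start: int
    end: int
    peptide: str
    domain_kind: str


def parse_motif_token(
    token: str, domain_kind: str, config: GrammarConfig = DEFAULT_GRAMMAR
) -> ParsedMotif:
    """Parse ``Y230VFF`` / ``(L260KDILR)`` notation back into a motif."""
    m = _MOTIF_RE.match(token.strip())
    if not m:
        raise ValueError(f"unparseable motif token {token!r}")
    open_paren, first, pos, rest, close_paren = m.groups()
    if bool(open_paren) != bool(close_paren):
        raise ValueError(f"unbalanced parentheses in {token!r}")
    peptide = first + rest
    start = int(pos)
    family, classification = classify_peptide(peptide, config)
    expected = NON_CANONICAL if open_paren else CANONICAL
    if classification != expected:
        raise ValueError(
            f"{token!r}: bracket convention says {expected}, grammar says {classification}"
        )
    return ParsedMotif(
        family=family, classification=classification, start=start,
        end=start + len(peptide) - 1, peptide=peptide, domain_kind=domain_kind,
    )


def parse_report_tsv(path: str | Path) -> dict[str, list[ParsedMotif]]:
    """Inverse of :func:`write_report_tsv` for the motif columns."""
    out: dict[str, list[ParsedMotif]] = {}
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        idx = {name: header.index(name) for name in REPORT_COLUMNS}
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < len(REPORT_COLUMNS):
                continue
            motifs: list[ParsedMotif] = []
            for column, kind in (("il_motifs", "IL"), ("ct_motifs", "CT")):
                cell = fields[idx[column]].strip()
                if cell:
                    for token in cell.split(";"):
                        motifs.append(parse_motif_token(token, kind))
            out[fields[idx["protein_name"]]] = motifs
    return out
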