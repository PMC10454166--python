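"""The published human-connexin motif catalogue.

The reference compilation lists, for each of the 21 human connexins, the
endocytic-motif peptides found in its intracellular loop (IL) and
C-terminal domain (CT), with 1-based anchor positions, a bracket
convention for non-canonical motifs and an underline convention for
motifs not conserved between human and rat.  That printed table is
bundled here as plain TSV so the grammar and the reporting layer can be
exercised against it without any sequence download.

Note the catalogue records what was *printed*; classification is always
recomputed from the peptide by :func:`cxmotifs.motif_grammar.classify_peptide`,
and the printed bracket flag is kept only so the two can be compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from types import SimpleNamespace

from .motif_grammar import DEFAULT_GRAMMAR, GrammarConfig, classify_peptide
from .scan_pipeline import categorize


@dataclass(frozen=True)
class CatalogMotif:
    gene_name: str
    protein_name: str
    domain: str            # IL or CT
    anchor: int
    peptide: str
    printed_noncanonical: bool
    conserved_in_rat: bool

    @property
    def end(self) -> int:
        return self.anchor + len(self.peptide) - 1


def _read_data(name: str) -> list[list[str]]:
    text = resources.files("cxmotifs.data").joinpath(name).read_text()
    lines = [line.split("\t") for line in text.strip().splitlines()]
    return lines[1:]  # drop header


def load_proteins() -> list[tuple[str, str]]:
    """All 21 human connexins as (gene_name, protein_name), catalogue order."""
    return [(gene, protein) for gene, protein in _read_data("connexin_proteins.tsv")]


def load_catalog() -> list[CatalogMotif]:
    """All catalogued motif entries (33 across 17 connexins)."""
    out = []
    for gene, protein, domain, anchor, peptide, noncanon, conserved in _read_data(
        "connexin_catalog.tsv"
    ):
        out.append(CatalogMotif(
            gene_name=gene, protein_name=protein, domain=domain,
            anchor=int(anchor), peptide=peptide,
            printed_noncanonical=noncanon == "True",
            conserved_in_rat=conserved == "True",
        ))
    return out


def classify_catalog(
    config: GrammarConfig = DEFAULT_GRAMMAR,
) -> dict[str, list[SimpleNamespace]]:
    """Run the grammar over every catalogued peptide.

    Returns, per protein name, pseudo-hits carrying the recomputed family
    and classification alongside the printed metadata; proteins without
    motifs map to an empty list.
    """
    hits: dict[str, list[SimpleNamespace]] = {
        protein: [] for _, protein in load_proteins()
    }
    for motif in load_catalog():
        family, classification = classify_peptide(motif.peptide, config)
        hits[motif.protein_name].append(SimpleNamespace(
            protein_id=motif.protein_name,
            gene_name=motif.gene_name,
            family=family,
            classification=classification,
            start=motif.anchor,
            end=motif.end,
            peptide=motif.peptide,
            domain_kind=motif.domain,
            printed_noncanonical=motif.printed_noncanonical,
            conserved_in_rat=motif.conserved_in_rat,
        ))
    return hits


def catalog_categories(
    config: GrammarConfig = DEFAULT_GRAMMAR,
) -> dict[str, str]:
    """Per-protein category recomputed from the catalogued peptides."""
    return {
        protein: categorize(hits)
        for protein, hits in classify_catalog(config).items()
    }
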