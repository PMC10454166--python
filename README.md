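# cxmotifs

Discovery of clathrin-adaptor endocytic sorting signals in the
cytoplasmic domains of connexins and other four-pass membrane proteins.

## The problem

Membrane proteins destined for clathrin-mediated endocytosis carry short
linear sorting signals that adaptor proteins such as AP-2 recognise. In
polytopic proteins two families dominate:

* **tyrosine-based signals** `YXXΦ` — an invariant tyrosine anchor
  (which cannot be replaced, even by phenylalanine or phosphotyrosine),
  two unconstrained residues, and a bulky-hydrophobic Φ ∈ {F, M, L, I, V};
* **di-leucine-based signals** `[D/E]XXXL[L/I]` — an acidic first
  residue, three unconstrained residues, and a leucine pair.

Experimentally tolerated relaxations define **non-canonical (cryptic)**
variants: the tyrosine spacer may grow to 3–5 X residues; the di-leucine
spacer may range over 2–5; the terminal di-leucine residue may be V or R;
and the first residue may be L instead of D/E. `NPXY`, the tyrosine
signal of single-pass receptors, is scanned too (it does not occur in
connexins).

A grammar match alone is not a sorting signal. Connexins are four-pass
transmembrane proteins whose N terminus, intracellular loop (IL) and C
terminus (CT) face the cytoplasm; only the IL and CT are accessible to
the endocytic machinery in an assembled gap junction, and a motif must
additionally sit ~6–10 residues clear of a transmembrane helix for
adaptor access. `cxmotifs` implements this topology-aware scan, the
separate census of the conserved di-leucine-like motif at the TM4/CT
transition zone, and human–rat motif conservation assessed by global
pairwise alignment (Needleman–Wunsch/Gotoh, BLOSUM62, affine gaps)
followed by motif re-evaluation inside the aligned footprint.

A synthetic-data generator produces connexin-like proteins with planted
motifs, decoys (extracellular, membrane-proximal, near-miss) and
divergent ortholog copies with a complete truth table, so every pipeline
stage is testable without sequence downloads.

## Worked example

Re-classify the bundled catalogue of the 33 endocytic-motif peptides
printed for the 21 human connexins:

```bash
python examples/classify_catalogue.py
```

```
catalogued motifs: 33
  CX43     CT Y230VFF       tyrosine  canonical
  ...
  CX32     CT E247INKLL     dileucine canonical
  CX32     CT L260KDILR     dileucine non_canonical
  ...
label disagreements: 0

per-protein categories (21 connexins):
  TYR_CANONICAL      10
  DILEU_CANONICAL    4
  NONCANONICAL_ONLY  3
  NONE               4
connexins with >=1 canonical motif: 14 of 21
```

Ten connexins carry a canonical tyrosine signal, four a canonical
di-leucine signal, three only cryptic (non-canonical) motifs and four no
recognisable motif at all; 14 of 21 carry at least one canonical signal,
and every recomputed canonical/non-canonical label agrees with the
printed bracket convention. Other examples generate and scan a synthetic
panel (`scan_synthetic_panel.py`), locate the TM4/CT junction motif
(`junction_scan.py`) and assess conservation in a divergent ortholog
(`conservation_demo.py`).

The same machinery is scriptable from a shell:

```bash
cxmotifs simulate --spec sim.cfg --seed 9 --out-prefix panel
cxmotifs scan --fasta panel.fasta --topology panel.topology.tsv --out-prefix out
cxmotifs conserve --human-fasta panel.fasta --rat-fasta panel.orthologs.fasta \
    --pairs pairs.tsv --topology panel.topology.tsv --out conservation.tsv
```

To scan real connexins, supply their FASTA sequences plus a topology TSV
(`protein_id  kind  start  end` with the nine segments
NT, TM1, E1, TM2, IL, TM3, E2, TM4, CT) derived from UniProt feature
annotations.

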