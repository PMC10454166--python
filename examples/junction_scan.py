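"""Locate the di-leucine-like motif at the TM4/CT transition zone.

Connexins carry a conserved [D/E]XXX?? motif straddling the end of their
fourth transmembrane helix.  It sits too close to the membrane to act as
a clathrin-adaptor site, so the main scan excludes it; scan_junction
looks for it explicitly inside a +/-10 residue window around the TM4
end and classifies its two-residue terminus.
"""

from cxmotifs import ProteinRecord, make_topology, scan_junction

# a compact protein whose TM4 ends at residue 200, carrying E198-VVYLI:
# the motif starts inside TM4 and reaches into the C-terminal domain
topology = make_topology("DEMO", {
    "NT": 20, "TM1": 20, "E1": 30, "TM2": 20, "IL": 40,
    "TM3": 20, "E2": 30, "TM4": 20, "CT": 30,
})
sequence = list("A" * topology.length)
sequence[197:203] = "EVVYLI"
record = ProteinRecord(id="DEMO", sequence="".join(sequence))

junction = scan_junction(record, topology)
print(f"anchor:         {junction.start} (TM4 ends at "
      f"{topology.segment('TM4').end})")
print(f"peptide:        {junction.peptide}")
print(f"first slot:     {junction.first_slot} (acidic)")
print(f"terminus:       {junction.terminus}")
print(f"terminus class: {junction.terminus_class}")
# 'canonical' terminus means L followed by L or I, as in a strict
# di-leucine signal; atypical classes record which of the two final
# residues deviates.
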