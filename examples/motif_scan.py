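"""Catalytic-Asp verification: scanning for the HRDLKxxN catalytic loop.

A kinase is only considered potentially active when the catalytic
aspartate is present: the scanner looks for 8-residue windows with D at
position 3 and N at position 8 of the HRDLKxxN consensus, scores the
optional H/R/L/K positions, and reports the best window.
"""

from kinout import is_putative_active, locate_catalytic_motif

active = "GSILTEWKAQHRDLKPENLLLDHAGHL"          # PKA-style catalytic loop
dead = active.replace("HRDLKPEN", "HRELKPEN")  # D -> E knock-out

for name, seq in (("active kinase", active), ("Asp-to-Glu mutant", dead)):
    motif = locate_catalytic_motif(seq, (0, len(seq)))
    print(f"{name}:")
    if motif is None:
        print("  no catalytic motif -> excluded from the kinase dataset")
    else:
        print(f"  window {motif.window!r}, catalytic D at {motif.d_position}, "
              f"paired N at {motif.n_position}, "
              f"consensus matches {motif.consensus_matches}/6")
    print(f"  putative active: {is_putative_active(motif)}")
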