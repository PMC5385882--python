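# Five-bead mapping table: residue, bead type, all-atom anchor name.
# Bead order per residue: P, S, B1 (ring, sugar-bonded), B2 (WC imino), B3 (WC edge).
# The three base anchors lie in the base plane.  The type assignment
# (9 types total: P, S, RA, RY, NI, N6, O6, N4, O4) is a modelling
# convention transcribed as data so alternative assignments can be
# supplied without code changes.
A  P   P
A  S   C4'
A  RA  C8
A  NI  N1
A  N6  N6
G  P   P
G  S   C4'
G  RA  C8
G  NI  N1
G  O6  O6
C  P   P
C  S   C4'
C  RY  C6
C  NI  N3
C  N4  N4
U  P   P
U  S   C4'
U  RY  C6
U  NI  N3
U  O4  O4
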