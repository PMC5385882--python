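# Default coarse-grained RNA force field.
#
# Provenance annotations:
#   [printed]   constants fixed by the published model description
#               (hbond eps_max/sigma_eq/cutoff, dielectric)
#   [lattice]   equilibrium geometry measured once from the package's
#               ideal A-form fixture lattice (rise 2.8 A, twist 32.7 deg)
#   [assigned]  stiffnesses, vdW well parameters, Debye length and
#               phosphate charge chosen as physically reasonable values;
#               the published numerical tables are not public, so these
#               are this package's own parameterization
#
# Conventions: harmonic terms k*(x-x0)^2 (no 1/2), angles/phases in
# degrees in this file, energies kcal/mol, distances Angstrom.

[types]
# name group mass(amu) charge(e)   # masses: summed moiety mass [assigned]
P   phosphate   94.97  -1.0
S   sugar       97.05   0.0
RA  base        44.70   0.0
RY  base        37.00   0.0
NI  base        44.70   0.0
N6  base        44.70   0.0
O6  base        44.70   0.0
N4  base        37.00   0.0
O4  base        37.00   0.0

[bonds]
# typeA typeB k(kcal/mol/A^2) r0(A)   # k [assigned], r0 [lattice]
N4  NI    60.0   2.2897
N4  RY    60.0   2.6833
N6  NI    60.0   2.2897
N6  RA    60.0   2.6833
NI  O4    60.0   2.2897
NI  O6    60.0   2.2897
NI  RA    60.0   3.3708
NI  RY    60.0   3.3708
O4  RY    60.0   2.6833
O6  RA    60.0   2.6833
P   S     40.0   3.3375
RA  S     25.0   5.0242
RY  S     25.0   5.0242

[angles]
# tA tB tC k(kcal/mol/rad^2) theta0(deg)   # k [assigned], theta0 [lattice]
N4  NI  RY    40.0    52.462
N4  RY  NI    40.0    42.580
N4  RY  S     20.0   170.803
N6  NI  RA    40.0    52.462
N6  RA  NI    40.0    42.580
N6  RA  S     20.0   170.803
NI  N4  RY    40.0    84.958
NI  N6  RA    40.0    84.958
NI  O4  RY    40.0    84.958
NI  O6  RA    40.0    84.958
NI  RA  O6    40.0    42.580
NI  RA  S     20.0   146.616
NI  RY  O4    40.0    42.580
NI  RY  S     20.0   146.616
O4  NI  RY    40.0    52.462
O4  RY  S     20.0   170.803
O6  NI  RA    40.0    52.462
O6  RA  S     20.0   170.803
P   S   P     20.0   152.989
P   S   RA    20.0    97.591
P   S   RY    20.0    97.591
S   P   S     20.0   123.797

[torsions]
# tA tB tC tD k1 d1 k2 d2 k3 d3 (kcal/mol, deg)
# k_n [assigned]; phases put each term's minimum at the lattice dihedral [lattice]
N4  NI  RY  S    0.60     0.00  0.30  -180.00  0.15     0.00
N4  RY  S   P    0.60  -159.42  0.30  -138.85  0.15  -118.27
N6  NI  RA  S    0.60     0.00  0.30  -180.00  0.15     0.00
N6  RA  S   P    0.60  -159.42  0.30  -138.85  0.15  -118.27
NI  N4  RY  S    0.60     0.00  0.30  -180.00  0.15     0.00
NI  N6  RA  S    0.60     0.00  0.30  -180.00  0.15     0.00
NI  O4  RY  S    0.60     0.00  0.30  -180.00  0.15     0.00
NI  O6  RA  S    0.60     0.00  0.30  -180.00  0.15     0.00
NI  RA  S   P    0.60    20.58  0.30  -138.85  0.15    61.73
NI  RY  S   P    0.60    20.58  0.30  -138.85  0.15    61.73
O4  NI  RY  S    0.60     0.00  0.30  -180.00  0.15     0.00
O4  RY  S   P    0.60  -159.42  0.30  -138.85  0.15  -118.27
O6  NI  RA  S    0.60     0.00  0.30  -180.00  0.15     0.00
O6  RA  S   P    0.60  -159.42  0.30  -138.85  0.15  -118.27
P   S   P   S    0.60     7.91  0.30  -164.17  0.15    23.74
RA  S   P   S    0.60  -172.75  0.30  -165.49  0.15  -158.24
RY  S   P   S    0.60  -172.75  0.30  -165.49  0.15  -158.24

[vdw]
# type eps(kcal/mol) sigma(A) gamma   # [assigned]
P    0.20  4.5  10.0
S    0.20  4.6  10.0
RA   0.30  3.4  10.0
RY   0.28  3.4  10.0
NI   0.20  2.9  10.0
N6   0.20  2.9  10.0
O6   0.20  2.9  10.0
N4   0.20  2.9  10.0
O4   0.20  2.9  10.0

[hbond]
eps_max 2.0     # kcal/mol [printed]
sigma_eq 2.9    # A [printed]
cutoff 6.0      # A [printed]
switch_on 4.5   # A, smooth truncation start [assigned]
# pair typeA typeB class scale; canonical Watson-Crick edges first
pair NI NI canonical 1.0
pair N6 O4 canonical 1.0
pair O6 N4 canonical 1.0
pair NI N6 noncanonical 1.0
pair NI O6 noncanonical 1.0
pair NI N4 noncanonical 1.0
pair NI O4 noncanonical 1.0
pair N6 N6 noncanonical 1.0
pair N6 O6 noncanonical 1.0
pair N6 N4 noncanonical 1.0
pair O6 O6 noncanonical 1.0
pair O6 O4 noncanonical 1.0
pair N4 N4 noncanonical 1.0
pair N4 O4 noncanonical 1.0
pair O4 O4 noncanonical 1.0

[electrostatics]
dielectric 25.0     # [printed]
debye_length 10.0   # A [assigned]
cutoff_factor 4.0   # cutoff = factor * debye_length [assigned]

[options]
vdw_cutoff 12.0     # A, energy-shifted truncation [assigned]
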