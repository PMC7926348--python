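# Canonical parameter set for the four-site NaChBac selectivity filter:
# fitted site excess chemical potentials (kT), capacitor electrostatics,
# pore diffusivity at a tenth of bulk, and the homology-model site geometry.

seed = 0

[energy]
Uc = 10.0     # self-energy e^2/2C, kT
nf = -2.5     # effective fixed pore charge, e
z = 1         # ionic valence (Na+)

[sites]
dmu = [2.3, 3.4, 2.8, 2.4]                        # kT, S1..S4
D = [1.33e-10, 1.33e-10, 1.33e-10, 1.33e-10]      # m^2/s

[bath]
c = 0.14      # mol/L NaCl
cw = 55.5     # mol/L solvent (water)
T = 298.15    # K
clamp = 1e-4  # mol/L floor for chemical gradients

[geometry]
radius = [3.06, 2.77, 2.75, 2.77]  # Å
length = [3.0, 4.0, 3.0, 2.0]      # Å
area = [116.0, 126.0, 90.0, 78.0]  # Å^2
volume = [117.0, 129.0, 80.0, 63.0]  # Å^3
Lc = 12.0                          # Å
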