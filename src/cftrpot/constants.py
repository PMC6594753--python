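"""Physical constants and package-wide default conventions.

Units are fixed package-wide: concentrations in mol/L (M), time in s,
second-order rates in M^-1 s^-1, energies in J/mol.
"""

AVOGADRO = 6.02214076e23  # mol^-1

#: Gas constant, J mol^-1 K^-1. Two-decimal value used throughout so that
#: thermodynamic outputs round to the conventional printed precision.
R_GAS = 8.31

#: Default octanol/water distribution coefficient at pH 7.1 used to constrain
#: the membrane entry/exit rate ratio k_in/k_out in ensemble fits.
D_OCT_WAT = 62580.0

#: Aqueous solubility of ivacaftor at 25 C, pH 7.1 (mol/L); the concentration
#: of a "1x saturated" stock solution. Overridable wherever it is consumed.
SATURATED_CONC = 62e-9

#: Membrane-compartment volumes (L) used to convert channel counts into a
#: channel-site concentration C_t: whole patch membrane for the single
#: compartment models, outer leaflet only for the two-leaflet models.
MEMBRANE_VOLUME = 1e-16
OUTER_LEAFLET_VOLUME = 5e-17

#: Basal open probability assumed for phosphorylated channels in ATP, used to
#: estimate channel counts from pre-drug mean current.
PO_BASAL = 0.16

#: Idealization dead time (s): dwells shorter than this are unresolvable after
#: 50 Hz filtering and are merged into the neighbouring event.
DEAD_TIME = 6e-3

#: Width (s) of the non-overlapping windows used for open-probability
#: stability plots.
STABILITY_WINDOW = 46.0
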