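"""Constants of the 7-species yeast glycolysis oscillator (generating model).

The benchmark's ground truth is the published anaerobic yeast glycolysis
model in which intermediate concentrations oscillate with a period near one
minute.  Species (concentrations in mM, time in min):

====  =========================================================
S1    glucose
S2    triose phosphate pool (GAP / DHAP)
S3    1,3-bisphosphoglycerate
S4    intracellular pyruvate / acetaldehyde pool
S5    NADH
S6    ATP
S7    extracellular pyruvate / acetaldehyde
====  =========================================================

Rate equations (v1 is the PFK step with cooperative ATP inhibition)::

    v1    = k1 * S1 * S6 / (1 + (S6 / K1)**q)
    dS1   = J0 - v1
    dS2   = s_upper * v1 - k2 * S2 * (N - S5) - k6 * S2 * S5
    dS3   = k2 * S2 * (N - S5) - k3 * S3 * (A - S6)
    dS4   = k3 * S3 * (A - S6) - k4 * S4 * S5 - kappa * (S4 - S7)
    dS5   = k2 * S2 * (N - S5) - k4 * S4 * S5 - k6 * S2 * S5
    dS6   = -s_upper * v1 + s_lower * k3 * S3 * (A - S6) - k5 * S6
    dS7   = psi * kappa * (S4 - S7) - k * S7

The 16 free parameters of the generating model are the 14 kinetic /
saturation / conservation constants below plus the two stoichiometric yield
coefficients ``s_upper`` (triose phosphates formed -- and ATP invested --
per glucose in upper glycolysis) and ``s_lower`` (ATP yielded per
phosphoglycerate step in lower glycolysis).
"""

#: version of this transcription of the generating model
VERSION = "1.0"

PARAMETERS: dict[str, float] = {
    "J0": 2.5,      # mM/min   glucose influx
    "k1": 100.0,    # /mM/min  hexokinase-PFK rate constant
    "k2": 6.0,      # /mM/min  GAPDH step
    "k3": 16.0,     # /mM/min  PGK step
    "k4": 100.0,    # /mM/min  alcohol dehydrogenase step
    "k5": 1.28,     # /min     ATP consumption
    "k6": 12.0,     # /mM/min  triose-NADH side reaction
    "k": 1.8,       # /min     external degradation
    "kappa": 13.0,  # /min     membrane transport
    "q": 4.0,       # -        ATP inhibition cooperativity
    "K1": 0.52,     # mM       ATP inhibition constant
    "psi": 0.1,     # -        extracellular dilution factor
    "N": 1.0,       # mM       total NAD(H)
    "A": 4.0,       # mM       total adenine nucleotides
    "s_upper": 2.0, # -        trioses per glucose (upper glycolysis yield)
    "s_lower": 2.0, # -        ATP yield factor (lower glycolysis)
}

SPECIES: tuple[str, ...] = ("S1", "S2", "S3", "S4", "S5", "S6", "S7")

#: a point near the limit cycle, used to initialize range calibration
REFERENCE_STATE: tuple[float, ...] = (1.2, 0.2, 0.04, 0.1, 0.1, 0.14, 0.05)
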