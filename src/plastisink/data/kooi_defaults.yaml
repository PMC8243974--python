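# Default biological/physical constants of the biofouling model.
# key: [value, units, provenance]
#
# Rates are stored in the units they are usually quoted in (d^-1); the code
# converts to s^-1 internally.
m_a:           [0.39, "d^-1", "grazing/mortality rate, Kooi et al. (2017) model constant"]
r20:           [0.1,  "d^-1", "respiration rate at 20 degC, Kooi et al. (2017)"]
q10:           [2.0,  "-",    "respiration temperature coefficient, Kooi et al. (2017)"]
algal_volume:  [2.0e-16, "m^3", "volume of one algal cell, Kooi et al. (2017); Lopez-Sandoval et al."]
biofilm_density: [1388.0, "kg m^-3", "wet biofilm density, Kooi et al. (2017)"]
shear_rate:    [1.7e5, "d^-1", "advective shear rate gamma, Kooi et al. (2017); ~2 s^-1"]
boltzmann:     [1.380649e-23, "J K^-1", "CODATA exact value"]
nitrogen_mg_per_mmol: [14.007, "mg mmol^-1", "atomic weight of nitrogen"]
cells_per_mg_nitrogen: [3.5604e11, "cells mg^-1 N", "median algal-cell/nitrogen conversion, Menden-Deuer & Lessard (2000); see docs/methods.md for the per-mg vs per-g units caveat"]
gravity:       [9.81, "m s^-2", "standard gravity"]
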