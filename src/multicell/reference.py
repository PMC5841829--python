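"""Reference parameter table (breast-epithelium-like cells).

One editable place for the default phenotype used across the built-in
models and examples.  Values are reference magnitudes for mammary
epithelial cells in the tumor-growth literature; all times in minutes,
lengths in um, oxygen tensions in mmHg.
"""

from __future__ import annotations

#: mature (cycling) total cell volume, um^3; radius ~8.4 um
MATURE_VOLUME = 2494.0
#: target fluid fraction of total volume
FLUID_FRACTION = 0.75
#: target nuclear solid volume, um^3 (nuclear radius ~5 um with fluid share)
NUCLEAR_SOLID_TARGET = 135.0
#: volume relaxation rates for a live cycling cell, 1/min
VOLUME_RATES = {"r_F": 3.0 / 60.0, "r_N": 0.33 / 60.0, "r_C": 0.27 / 60.0}

#: oxygen transport: diffusion coefficient um^2/min, decay 1/min,
#: per-cell uptake rate 1/min, physioxic boundary tension mmHg
OXYGEN = {
    "D": 1.0e5,
    "lambda": 0.01,
    "uptake_rate": 10.0,
    "boundary_value": 38.0,
}

#: Ki67-advanced cycle model (min / mmHg)
KI67_ADVANCED = {
    "T_1": 13.0 * 60.0,
    "T_2": 2.5 * 60.0,
    "T_Q_bar": 74.35 * 60.0,
    "pO2_hypoxia": 5.0,
    "pO2_bar": 38.0,
}

#: death parameters
DEATH = {
    "apoptosis_rate": 5.31667e-05,   # 1/min; ~2% apoptotic fraction
    "T_A": 8.6 * 60.0,               # mean apoptosis duration, min
    "pO2_threshold": 5.0,            # necrosis begins below, mmHg
    "pO2_crit": 2.5,                 # necrosis rate saturates below, mmHg
    "r_N_max": 1.0 / 360.0,          # 1/min; ~6 h mean survival in anoxia
}

#: cell mechanics strengths (um/min) and ranges
MECHANICS = {
    "c_cca": 0.4,
    "c_ccr": 10.0,
    "c_cba": 1.0,
    "c_cbr": 10.0,
    "R_A_multiple": 1.25,
    "n": 1,
}

#: interaction-grid voxel edge, um (>= max interaction distance for the
#: reference cell: 2 * 1.25 * 8.4 = 21 um)
MECHANICS_VOXEL_EDGE = 30.0
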