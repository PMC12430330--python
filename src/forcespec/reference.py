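"""Published operating points of the HSA-TKI electric-field study conditions.

These tables hold the reported force and topography levels for human serum
albumin (HSA) layers probed in the presence of six tyrosine kinase inhibitors
(TKIs) under DC field strengths of 0-100 mV/mm.  They serve two roles: as the
ground-truth operating points the synthetic-data generator emulates, and as
printed inputs for worked-example arithmetic (percent reductions between
conditions).  Values are Gaussian-peak forces in pN (value, reported
uncertainty) and heights/roughness in nm.
"""

from __future__ import annotations

DRUGS = ("imatinib", "bosutinib", "dasatinib", "nilotinib", "ponatinib", "radotinib")
FIELDS_MV_MM = (0, 20, 40, 60, 80, 100)

#: specific (per-bond) force F_i in pN: drug -> {field -> (value, sd)}
SPECIFIC_FORCE_PN = {
    "imatinib": {0: (35.1, 0.5), 20: (33.4, 0.4), 40: (31.6, 0.2), 60: (28.9, 0.3), 80: (27.2, 0.5), 100: (25.2, 0.3)},
    "bosutinib": {0: (29.1, 0.4), 20: (27.0, 0.4), 40: (25.8, 0.6), 60: (24.7, 0.2), 80: (23.2, 0.3), 100: (21.3, 0.7)},
    "dasatinib": {0: (37.3, 0.8), 20: (35.6, 0.7), 40: (32.7, 0.7), 60: (30.3, 0.5), 80: (27.5, 0.4), 100: (26.0, 0.8)},
    "nilotinib": {0: (34.1, 0.6), 20: (32.0, 0.7), 40: (30.1, 0.5), 60: (28.2, 0.3), 80: (26.8, 0.4), 100: (24.5, 0.5)},
    "ponatinib": {0: (40.4, 0.7), 20: (36.9, 0.5), 40: (34.4, 0.6), 60: (31.5, 0.9), 80: (28.9, 0.5), 100: (25.4, 0.6)},
    "radotinib": {0: (42.1, 0.6), 20: (37.7, 0.5), 40: (34.6, 0.4), 60: (31.2, 0.7), 80: (27.4, 0.7), 100: (23.6, 0.4)},
}

#: non-specific force F_0 in pN: drug -> {field -> (value, sd)}
NONSPECIFIC_FORCE_PN = {
    "imatinib": {0: (101, 2), 20: (90, 2), 40: (80, 1), 60: (71, 2), 80: (62, 2), 100: (52, 1)},
    "bosutinib": {0: (114, 1), 20: (103.7, 0.9), 40: (93, 2), 60: (81, 1), 80: (72, 2), 100: (64, 1)},
    "dasatinib": {0: (112, 1), 20: (103, 1), 40: (95, 2), 60: (85, 1), 80: (75, 2), 100: (67, 2)},
    "nilotinib": {0: (103, 1), 20: (91.4, 0.9), 40: (81, 2), 60: (70, 2), 80: (59, 1), 100: (49, 1)},
    "ponatinib": {0: (108, 1), 20: (100, 1), 40: (92.6, 0.9), 60: (84, 2), 80: (76, 3), 100: (67, 1)},
    "radotinib": {0: (116, 2), 20: (103, 1), 40: (93, 1), 60: (81, 2), 80: (68, 2), 100: (57, 2)},
}

#: reported adhesion Gaussian peaks (pN) where printed: (drug, field) -> (value, sd)
ADHESION_PEAK_PN = {
    ("bosutinib", 20): (347, 1), ("bosutinib", 100): (244, 3),
    ("nilotinib", 20): (372, 2), ("nilotinib", 100): (228, 4),
    ("radotinib", 20): (367, 2), ("radotinib", 100): (256, 6),
}

#: loop-friction Gaussian peaks (pN) where printed
LOOP_FRICTION_PN = {
    ("imatinib", 20): (202, 5), ("imatinib", 100): (126, 4),
    ("bosutinib", 20): (157, 4),
    ("dasatinib", 20): (185, 5), ("dasatinib", 100): (92, 3),
    ("nilotinib", 20): (274, 6),
    ("ponatinib", 20): (206, 4),
    ("radotinib", 20): (292, 5),
}

#: constant-load (1 nN) friction Gaussian peaks (pN) where printed
CONSTANT_LOAD_FRICTION_PN = {
    ("imatinib", 0): (398, 7),
    ("bosutinib", 0): (365, 7),
    ("dasatinib", 0): (386, 5),
    ("nilotinib", 0): (423, 8), ("nilotinib", 20): (379, 8), ("nilotinib", 100): (240, 4),
    ("ponatinib", 0): (410, 7),
    ("radotinib", 0): (448, 4), ("radotinib", 20): (395, 6), ("radotinib", 100): (246, 4),
}

#: bare-substrate and protein-layer topography references (nm)
GOLD_SUBSTRATE_HEIGHT_NM = 6.9
GOLD_SUBSTRATE_SQ_NM = 1.4
HSA_LAYER_HEIGHT_NM = 15.4
HSA_LAYER_SQ_NM = 2.6

#: average surface height of drug-HSA layers (nm) where printed
LAYER_HEIGHT_NM = {
    ("imatinib", 0): (14.6, 0.1), ("imatinib", 100): (8.6, 0.2),
    ("bosutinib", 0): (15.3, 0.1),
    ("dasatinib", 0): (14.2, 0.1),
}

#: average roughness Sa of drug-HSA layers (nm) where printed
LAYER_SA_NM = {
    ("bosutinib", 0): (2.1, 0.1),
    ("radotinib", 0): (2.7, 0.1),
    ("nilotinib", 0): (2.4, 0.1), ("nilotinib", 100): (1.6, 0.1),
}
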