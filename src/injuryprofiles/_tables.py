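"""Default parameter tables for the seven-profile synthetic cohort.

These constants encode the published study conditions the generator
emulates: per-class conditional probabilities for the 26 injury
indicators that carry class signal, assigned class sizes (N = 5,227), and
class-conditional covariate counts.  One inconsistency in the printed
counts (class 4 injured 2009-2019) is resolved toward the printed
percentage (66.3% of 804 -> 533).
"""

from __future__ import annotations

# (nature_code, region_code) for the 26 signal indicators, in display order.
SIGNAL_ITEMS: list[tuple[str, str]] = [
    ("internal-organ", "type-1-tbi"),
    ("internal-organ", "type-2-tbi"),
    ("internal-organ", "chest"),
    ("internal-organ", "abdomen"),
    ("open-wound", "face"),
    ("open-wound", "pelvis-urogenital"),
    ("open-wound", "shoulder-upper-arm"),
    ("open-wound", "forearm-elbow"),
    ("open-wound", "wrist-hand-fingers"),
    ("open-wound", "other-lower-extremity"),
    ("contusion-superficial", "eye"),
    ("contusion-superficial", "head-face-neck-unspecified"),
    ("burn", "head-face-neck-unspecified"),
    ("burn", "wrist-hand-fingers"),
    ("burn", "other-multiple"),
    ("burn", "unspecified-site"),
    ("fracture-closed", "chest"),
    ("fracture-closed", "pelvis-urogenital"),
    ("fracture-closed", "lower-leg-ankle"),
    ("fracture-closed", "foot-toes"),
    ("fracture-open", "face"),
    ("fracture-open", "thoracic-dorsal-vci"),
    ("fracture-open", "lumbar-vci"),
    ("fracture-open", "sacrum-coccyx-vci"),
    ("fracture-open", "wrist-hand-fingers"),
    ("fracture-open", "lower-leg-ankle"),
]

# Conditional item probabilities, one row per signal item, columns = classes
# 1..7 (1 open wounds, 2 Type 1 TBI/facial, 3 disseminated, 4 Type 2 TBI,
# 5 lower extremity, 6 burns, 7 chest/abdominal).
SIGNAL_PROBS: list[list[float]] = [
    [0.035, 0.483, 0.275, 0.041, 0.010, 0.053, 0.011],
    [0.355, 0.256, 0.362, 0.835, 0.168, 0.312, 0.102],
    [0.194, 0.174, 0.459, 0.101, 0.017, 0.123, 0.385],
    [0.180, 0.065, 0.489, 0.051, 0.038, 0.083, 0.312],
    [0.613, 0.670, 0.587, 0.400, 0.113, 0.327, 0.073],
    [0.531, 0.051, 0.104, 0.014, 0.100, 0.063, 0.043],
    [0.292, 0.303, 0.078, 0.027, 0.075, 0.091, 0.145],
    [0.476, 0.205, 0.160, 0.078, 0.076, 0.111, 0.074],
    [0.502, 0.178, 0.124, 0.053, 0.069, 0.101, 0.057],
    [0.791, 0.390, 0.452, 0.177, 0.516, 0.347, 0.125],
    [0.182, 0.366, 0.142, 0.080, 0.012, 0.253, 0.002],
    [0.206, 0.234, 0.277, 0.309, 0.054, 0.177, 0.028],
    [0.041, 0.060, 0.017, 0.006, 0.002, 0.597, 0.000],
    [0.021, 0.016, 0.013, 0.000, 0.000, 0.511, 0.000],
    [0.011, 0.017, 0.003, 0.020, 0.004, 0.324, 0.004],
    [0.114, 0.110, 0.050, 0.007, 0.004, 0.986, 0.009],
    [0.011, 0.027, 0.352, 0.077, 0.001, 0.034, 0.031],
    [0.046, 0.000, 0.331, 0.029, 0.003, 0.021, 0.005],
    [0.047, 0.010, 0.400, 0.181, 0.086, 0.080, 0.002],
    [0.032, 0.000, 0.302, 0.183, 0.076, 0.052, 0.003],
    [0.078, 0.417, 0.125, 0.060, 0.010, 0.047, 0.007],
    [0.013, 0.008, 0.332, 0.155, 0.003, 0.034, 0.051],
    [0.036, 0.017, 0.584, 0.243, 0.012, 0.072, 0.041],
    [0.048, 0.003, 0.326, 0.034, 0.004, 0.014, 0.033],
    [0.394, 0.086, 0.067, 0.007, 0.014, 0.040, 0.033],
    [0.247, 0.034, 0.339, 0.064, 0.482, 0.177, 0.008],
]

# Assigned class sizes (sum to the study N of 5,227); the default mixing
# proportions are these counts normalised, so they form an exact simplex.
CLASS_COUNTS: list[int] = [981, 742, 353, 804, 1036, 387, 924]
STUDY_N: int = 5227

# Class-conditional covariate counts (levels x classes 1..7); each class
# column sums to its CLASS_COUNTS entry.
COVARIATE_COUNTS: dict[str, dict[str, list[int]]] = {
    "age": {
        "18-24": [560, 405, 189, 448, 589, 213, 517],
        "25-29": [267, 177, 87, 196, 255, 87, 216],
        "30+": [154, 160, 77, 160, 192, 87, 191],
    },
    "sex": {
        "Male": [966, 732, 349, 788, 1010, 381, 910],
        "Female": [15, 10, 4, 16, 26, 6, 14],
    },
    "service": {
        "Army": [620, 532, 264, 607, 731, 300, 637],
        "Marine Corps": [329, 185, 82, 176, 268, 75, 256],
        "Navy": [21, 15, 4, 15, 24, 8, 22],
        "Air Force": [11, 10, 3, 6, 13, 4, 9],
    },
    "location": {
        "Afghanistan": [606, 279, 215, 556, 442, 102, 401],
        "Iraq": [375, 463, 138, 248, 594, 285, 523],
    },
    "year": {
        "2002-2008": [393, 471, 157, 271, 640, 307, 549],
        "2009-2019": [588, 271, 196, 533, 396, 80, 375],
    },
    "mechanism": {
        "Blast": [914, 580, 328, 753, 707, 368, 316],
        "Gunshot wound": [48, 127, 7, 22, 295, 4, 571],
        "Other": [19, 35, 18, 29, 34, 15, 37],
    },
    "posture": {
        "Mounted": [227, 265, 277, 602, 400, 285, 152],
        "Dismounted": [645, 277, 35, 130, 442, 44, 494],
        "Unknown": [109, 200, 41, 72, 194, 58, 278],
    },
    "iss_category": {
        "Serious": [419, 344, 61, 653, 865, 186, 569],
        "Severe": [309, 209, 126, 126, 152, 101, 202],
        "Critical": [253, 189, 166, 25, 19, 100, 153],
    },
}
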