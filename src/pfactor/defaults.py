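"""Reference constants: the 12 parent-rated symptom scales, the bifactor
loading pattern, and the default generating parameters for simulation.

The default loading matrix and structural coefficients are the package's
reference values for a mid-childhood (age ~7) general-psychopathology
bifactor solution; the simulation module uses them as generating truth so
that recovery of known parameters can be tested end to end.
"""

from __future__ import annotations

import numpy as np

# Factor order used everywhere: general first, then the three specifics.
FACTORS = ("P", "E", "B", "N")
FACTOR_LABELS = {
    "P": "general psychopathology",
    "E": "emotional",
    "B": "behavioural",
    "N": "neurodevelopmental",
}

# scale name -> (number of items, specific-factor membership)
# Items are parent-rated, each scored 0-2.
SCALE_ITEMS = {
    "depression": (12, "E"),
    "generalized_anxiety": (7, "E"),
    "separation_anxiety": (10, "E"),
    "social_anxiety": (6, "E"),
    "specific_phobia": (7, "E"),
    "irritability": (3, "B"),
    "headstrong": (4, "B"),
    "hurtful": (2, "B"),
    "conduct": (7, "B"),
    "hyperactivity_impulsivity": (9, "N"),
    "inattention": (9, "N"),
    "social_communication": (12, "N"),
}

SCALE_NAMES = tuple(SCALE_ITEMS)
ITEM_MAX = 2

# Reference standardized loadings (rows follow SCALE_NAMES, columns FACTORS).
# Conduct problems load on the general factor only in the default pattern;
# see BifactorSpec for the alternative placement on the behavioural factor.
DEFAULT_TRUE_LOADINGS = np.array(
    [
        # P      E      B      N
        [0.292, 0.311, 0.0, 0.0],  # depression
        [0.230, 0.566, 0.0, 0.0],  # generalized anxiety
        [0.296, 0.500, 0.0, 0.0],  # separation anxiety
        [0.206, 0.402, 0.0, 0.0],  # social anxiety
        [0.158, 0.447, 0.0, 0.0],  # specific phobia
        [0.731, 0.0, 0.416, 0.0],  # irritability
        [0.824, 0.0, 0.374, 0.0],  # headstrong
        [0.622, 0.0, 0.351, 0.0],  # hurtful
        [0.557, 0.0, 0.0, 0.0],  # conduct (general only)
        [0.697, 0.0, 0.0, 0.535],  # hyperactivity/impulsivity
        [0.608, 0.0, 0.0, 0.564],  # inattention
        [0.795, 0.0, 0.0, 0.199],  # social-communication
    ]
)

# Predictor order for the structural part of the generator.
PRS_TRAITS = ("scz", "adhd", "asd", "dep")
PREDICTORS = PRS_TRAITS + ("sex",)

# Reference standardized effects of the four PRS (per SD) and female sex
# (binary contrast) on the four latent factors: rows FACTORS, cols PREDICTORS.
DEFAULT_FACTOR_BETAS = np.array(
    [
        # scz     adhd    asd     dep     sex(female)
        [0.042, 0.087, 0.002, 0.026, -0.106],  # P
        [0.040, -0.046, 0.007, 0.035, 0.117],  # E
        [0.015, -0.050, -0.022, -0.017, 0.028],  # B
        [-0.002, 0.041, -0.021, -0.002, -0.147],  # N
    ]
)
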