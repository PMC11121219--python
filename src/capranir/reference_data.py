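"""Breed-level summary statistics of the Transmontano suckling-kid population.

Published breed means (and standard errors of the mean) for carcass traits,
physicochemical meat attributes and the intramuscular fatty-acid profile of
"Serrana" and "Preta de Montesinho" kids (16 animals per breed, 8 per sex).
They serve two roles here: as generating parameters for the synthetic
cohort, and as worked-example inputs for the closed-form quality indices.

Fatty-acid percentages are g FA / 100 g total FA.  The family totals are
the published ones, which include trace acids below the 0.1% per-acid
reporting threshold; recomputing totals from the listed acids therefore
undershoots them slightly.
"""

from __future__ import annotations

BREEDS = ("Serrana", "Preta de Montesinho")
SEXES = ("M", "F")

N_PER_BREED = 16
N_PER_BREED_SEX = 8

# Carcass traits by (breed, sex): mean, with one pooled SEM per trait.
CARCASS_MEANS = {
    ("Serrana", "M"): {"age": 72.4, "dg": 118.3, "lws": 10.9, "ccw": 5.8},
    ("Serrana", "F"): {"age": 73.6, "dg": 119.4, "lws": 10.8, "ccw": 6.0},
    ("Preta de Montesinho", "M"): {"age": 73.1, "dg": 110.6, "lws": 10.2, "ccw": 5.7},
    ("Preta de Montesinho", "F"): {"age": 67.0, "dg": 110.9, "lws": 9.2, "ccw": 5.1},
}
CARCASS_SEM = {"age": 5.012, "dg": 11.51, "lws": 0.559, "ccw": 0.325}

# Physicochemical attributes by breed: mean and SEM (n = 16 per breed).
MEAT_MEANS = {
    "Serrana": {
        "pH": 5.98, "WHC": 12.93, "SF": 2.33,
        "L*": 54.71, "a*": 18.39, "b*": 12.96,
        "moisture": 75.80, "ash": 1.20, "protein": 21.06, "IMF": 1.20,
    },
    "Preta de Montesinho": {
        "pH": 5.88, "WHC": 19.23, "SF": 3.88,
        "L*": 52.56, "a*": 14.70, "b*": 11.42,
        "moisture": 74.78, "ash": 1.22, "protein": 21.66, "IMF": 1.81,
    },
}
MEAT_SEM = {
    "pH": 0.041, "WHC": 1.222, "SF": 0.156,
    "L*": 0.869, "a*": 0.611, "b*": 0.257,
    "moisture": 0.530, "ash": 0.086, "protein": 0.254, "IMF": 0.162,
}

# Intramuscular fatty-acid profile by breed (acids >= 0.1% of total FA).
FA_MEANS = {
    "Serrana": {
        "C10:0": 0.114, "C12:0": 0.483, "C14:0": 5.435, "C14:1": 0.206,
        "C15:0": 0.211, "C15:1": 0.163, "C16:0": 26.198, "C16:1n-7": 2.300,
        "C17:0": 0.765, "C17:1n-7": 0.592, "C18:0": 11.682, "9t-C18:1": 1.637,
        "C18:1n-9": 38.749, "9t, 12t-C18:2": 0.281, "C18:2n-6": 6.489,
        "C20:0": 0.045, "C18:3n-6": 0.066, "C20:1n-9": 0.439, "C18:3n-3": 0.665,
        "C21:0": 0.012, "C20:2n-6": 0.042, "C22:0": 0.169, "C20:3n-6": 0.141,
        "C22:1n-9": 0.015, "C20:4n-6": 2.339, "C20:3n-3": 0.044,
        "C22:2n-6": 0.000, "C24:0": 0.214, "C24:1n-9": 0.231, "C22:6n-3": 0.234,
    },
    "Preta de Montesinho": {
        "C10:0": 0.090, "C12:0": 0.424, "C14:0": 4.564, "C14:1": 0.176,
        "C15:0": 0.211, "C15:1": 0.121, "C16:0": 25.032, "C16:1n-7": 2.314,
        "C17:0": 0.738, "C17:1n-7": 0.585, "C18:0": 11.935, "9t-C18:1": 1.592,
        "C18:1n-9": 38.666, "9t, 12t-C18:2": 0.275, "C18:2n-6": 6.614,
        "C20:0": 0.027, "C18:3n-6": 0.069, "C20:1n-9": 1.048, "C18:3n-3": 0.679,
        "C21:0": 0.010, "C20:2n-6": 0.027, "C22:0": 0.237, "C20:3n-6": 0.198,
        "C22:1n-9": 0.023, "C20:4n-6": 2.387, "C20:3n-3": 0.004,
        "C22:2n-6": 0.002, "C24:0": 0.865, "C24:1n-9": 0.402, "C22:6n-3": 0.670,
    },
}
FA_SEM = {
    "C10:0": 0.014, "C12:0": 0.038, "C14:0": 0.359, "C14:1": 0.026,
    "C15:0": 0.027, "C15:1": 0.011, "C16:0": 0.573, "C16:1n-7": 0.130,
    "C17:0": 0.043, "C17:1n-7": 0.032, "C18:0": 0.487, "9t-C18:1": 0.093,
    "C18:1n-9": 0.984, "9t, 12t-C18:2": 0.020, "C18:2n-6": 0.607,
    "C20:0": 0.007, "C18:3n-6": 0.010, "C20:1n-9": 0.085, "C18:3n-3": 0.042,
    "C21:0": 0.006, "C20:2n-6": 0.008, "C22:0": 0.046, "C20:3n-6": 0.029,
    "C22:1n-9": 0.008, "C20:4n-6": 0.335, "C20:3n-3": 0.022,
    "C22:2n-6": 0.000, "C24:0": 0.141, "C24:1n-9": 0.116, "C22:6n-3": 0.135,
}

# Published family totals per breed (include sub-threshold trace acids).
FA_PUBLISHED_SUMS = {
    "Serrana": {
        "SFA": 45.355, "MUFA": 44.335, "PUFA": 10.308,
        "PUFA n-6": 9.025, "PUFA n-3": 1.222,
    },
    "Preta de Montesinho": {
        "SFA": 44.139, "MUFA": 44.931, "PUFA": 10.929,
        "PUFA n-6": 9.299, "PUFA n-3": 1.354,
    },
}

# Published per-animal-averaged quality summaries per breed.
PUBLISHED_INDICES = {
    "Serrana": {"n6/n3": 7.385, "IA": 0.892, "IT": 1.225, "h/H": 1.538},
    "Preta de Montesinho": {"n6/n3": 6.867, "IA": 0.797, "IT": 1.1528, "h/H": 1.688},
}

PUBLISHED_YIELD = {
    ("Serrana", "M"): 53.2, ("Serrana", "F"): 55.5,
    ("Preta de Montesinho", "M"): 55.8, ("Preta de Montesinho", "F"): 55.4,
}
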