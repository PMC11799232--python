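"""Published summary tables bundled as example inputs.

These are the printed summary statistics of a public FAERS
disproportionality study of three triazole antifungals (voriconazole,
posaconazole, isavuconazole): the per-drug demographic marginals of the
primary-suspect reports, and the per-drug top-20 signal rows
(PT, report count a, PRR, chi-square, ROR with 95% CI) exactly as printed.

They serve two purposes:

* worked-example / self-consistency inputs — the demographic percentages
  can be recomputed from the counts, and each signal row's CI bounds can be
  checked against its ROR via the geometric-mean identity;
* inputs to :func:`pvsignal.stats.invert_summary`, which recovers the
  underlying 2x2 tables from the printed rows alone.

One posaconazole row ("drug level decreased") is known to be internally
inconsistent as printed (its PRR exceeds its ROR, and its CI duplicates the
hepatotoxicity row's): it is kept verbatim so that the inversion's
consistency checks have a real negative example.
"""

from __future__ import annotations

import pandas as pd

DRUGS = ("voriconazole", "posaconazole", "isavuconazole")

#: total PS reports, sex counts, age-bin counts, top-5 reporting countries
DEMOGRAPHICS: dict[str, dict] = {
    "voriconazole": {
        "total": 8898,
        "sex": {"female": 2857, "male": 4477, "unknown": 1564},
        "age": {"<18": 586, "18-44": 986, "45-64": 2067, ">=65": 2624, "unknown": 2635},
        "countries": [("US", 3904), ("JP", 968), ("FR", 697), ("CN", 640), ("GB", 349)],
    },
    "posaconazole": {
        "total": 1948,
        "sex": {"female": 640, "male": 914, "unknown": 394},
        "age": {"<18": 152, "18-44": 278, "45-64": 437, ">=65": 312, "unknown": 769},
        "countries": [("US", 1052), ("FR", 167), ("GB", 98), ("DE", 89), ("CN", 64)],
    },
    "isavuconazole": {
        "total": 944,
        "sex": {"female": 296, "male": 553, "unknown": 95},
        "age": {"<18": 38, "18-44": 117, "45-64": 315, ">=65": 222, "unknown": 252},
        "countries": [("US", 416), ("CN", 134), ("ES", 81), ("GB", 71), ("FR", 66)],
    },
}

#: printed percentage columns, kept for cross-checking the arithmetic
DEMOGRAPHICS_PERCENT: dict[str, dict] = {
    "voriconazole": {
        "sex": {"female": 32.11, "male": 50.31, "unknown": 17.58},
        "age": {"<18": 6.59, "18-44": 11.08, "45-64": 23.23, ">=65": 29.49, "unknown": 29.61},
        "countries": {"US": 43.88, "JP": 10.88, "FR": 7.83, "CN": 7.19, "GB": 3.92},
    },
    "posaconazole": {
        "sex": {"female": 32.85, "male": 46.92, "unknown": 20.23},
        "age": {"<18": 7.80, "18-44": 14.27, "45-64": 22.43, ">=65": 16.02, "unknown": 39.48},
        "countries": {"US": 54.00, "FR": 8.57, "GB": 5.03, "DE": 4.57, "CN": 3.29},
    },
    "isavuconazole": {
        "sex": {"female": 31.36, "male": 58.58, "unknown": 10.06},
        "age": {"<18": 4.03, "18-44": 12.39, "45-64": 33.37, ">=65": 23.52, "unknown": 26.69},
        "countries": {"US": 44.07, "CN": 14.19, "ES": 8.58, "GB": 7.52, "FR": 6.99},
    },
}

_TOP20_COLUMNS = ("drug", "pt", "a", "prr", "chi2", "ror", "ror_ci_low", "ror_ci_high")

#: top-20 signal rows per drug, in printed (frequency-ranked) order
TOP20_ROWS: tuple[tuple, ...] = (
    # voriconazole
    ("voriconazole", "death", 734, 2.090, 436.146, 2.208, 2.046, 2.383),
    ("voriconazole", "drug interaction", 513, 9.950, 4121.642, 10.604, 9.692, 11.601),
    ("voriconazole", "hallucination", 275, 11.673, 2660.468, 12.077, 10.702, 13.629),
    ("voriconazole", "condition aggravated", 241, 2.746, 2660.468, 2.804, 2.466, 3.188),
    ("voriconazole", "photosensitivity reaction", 238, 44.335, 9752.817, 45.748, 40.133, 52.150),
    ("voriconazole", "visual impairment", 186, 4.766, 550.795, 4.861, 4.202, 5.624),
    ("voriconazole", "drug level increased", 171, 30.240, 4712.754, 30.919, 26.529, 36.035),
    ("voriconazole", "disease progression", 145, 3.578, 267.567, 3.629, 3.078, 4.278),
    ("voriconazole", "vision blurred", 145, 3.233, 222.215, 3.277, 2.779, 3.863),
    ("voriconazole", "drug resistance", 143, 16.064, 1985.808, 16.355, 13.849, 19.315),
    ("voriconazole", "hallucination visual", 141, 21.608, 2713.417, 22.001, 18.602, 26.021),
    ("voriconazole", "respiratory failure", 106, 4.684, 303.415, 4.737, 3.909, 5.739),
    ("voriconazole", "hepatic function abnormal", 96, 8.672, 641.149, 8.771, 7.168, 10.734),
    ("voriconazole", "drug level decreased", 92, 33.524, 2807.958, 33.926, 27.558, 41.766),
    ("voriconazole", "hepatotoxicity", 91, 11.833, 885.558, 11.966, 9.723, 14.726),
    ("voriconazole", "treatment failure", 91, 3.289, 142.869, 3.317, 2.697, 4.079),
    ("voriconazole", "drug-induced liver injury", 87, 10.001, 691.928, 10.106, 8.175, 12.493),
    ("voriconazole", "delirium", 84, 7.898, 497.272, 7.976, 6.429, 9.895),
    ("voriconazole", "actinic keratosis", 78, 105.868, 7464.528, 106.965, 84.915, 134.740),
    ("voriconazole", "neurotoxicity", 73, 14.654, 906.731, 14.787, 11.730, 18.642),
    # posaconazole
    ("posaconazole", "drug interaction", 92, 7.733, 535.677, 8.111, 6.574, 10.008),
    ("posaconazole", "product use issue", 48, 6.08, 341.043, 6.329, 5.063, 7.912),
    ("posaconazole", "hypokalaemia", 42, 16.663, 690.478, 17.11, 12.837, 22.803),
    ("posaconazole", "drug level below therapeutic", 29, 138.221, 5468.931, 141.636, 103.949, 192.986),
    ("posaconazole", "antibiotic level below therapeutic", 26, 5053.084, 79310.610, 5139.216, 3153.396, 8375.587),
    ("posaconazole", "pseudoaldosteronism", 25, 4411.131, 65472.613, 4478.422, 2713.308, 7391.812),
    ("posaconazole", "electrocardiogram qt prolonged", 24, 8.532, 158.839, 8.642, 5.821, 12.830),
    ("posaconazole", "respiratory failure", 22, 4.610, 64.437, 4.661, 3.115, 6.975),
    ("posaconazole", "hepatotoxicity", 20, 11.263, 176.788, 11.383, 7.322, 17.696),
    ("posaconazole", "drug-induced liver injury", 19, 9.967, 152.441, 10.072, 6.479, 15.657),
    ("posaconazole", "febrile neutropenia", 18, 4.944, 55.978, 4.988, 3.173, 7.840),
    ("posaconazole", "liver function test abnormal", 17, 7.025, 87.126, 7.089, 4.454, 11.282),
    ("posaconazole", "hepatocellular injury", 17, 18.248, 259.577, 18.420, 11.416, 29.720),
    ("posaconazole", "pancytopenia", 16, 4.670, 45.491, 4.706, 2.918, 7.59),
    ("posaconazole", "cardiac arrest", 16, 2.508, 13.080, 2.522, 1.541, 4.126),
    ("posaconazole", "treatment failure", 15, 2.358, 10.446, 2.370, 1.425, 3.940),
    ("posaconazole", "neuropathy peripheral", 13, 2.029, 5.816, 2.037, 1.180, 3.516),
    ("posaconazole", "cholestasis", 12, 10.524, 94.035, 10.591, 6.000, 18.694),
    ("posaconazole", "hepatic enzyme increased", 12, 2.582, 10.125, 2.593, 1.469, 4.575),
    ("posaconazole", "drug level decreased", 11, 17.083, 150.941, 11.383, 7.322, 17.696),
    # isavuconazole
    ("isavuconazole", "death", 105, 5.061, 354.522, 6.315, 5.073, 7.859),
    ("isavuconazole", "off label use", 88, 6.121, 384.208, 7.383, 5.847, 9.323),
    ("isavuconazole", "febrile neutropenia", 12, 12.137, 111.941, 12.445, 7.012, 22.089),
    ("isavuconazole", "drug interaction", 12, 3.918, 23.397, 3.999, 2.253, 7.096),
    ("isavuconazole", "hepatotoxicity", 8, 17.499, 108.529, 17.801, 8.844, 35.829),
    ("isavuconazole", "thrombocytopenia", 8, 4.165, 16.275, 4.223, 2.099, 8.499),
    ("isavuconazole", "neutropenia", 7, 2.893, 6.918, 2.923, 1.385, 6.169),
    ("isavuconazole", "therapy non-responder", 7, 8.874, 41.409, 9.0, 4.265, 18.993),
    ("isavuconazole", "respiratory failure", 6, 4.479, 12.957, 4.526, 2.022, 10.131),
    ("isavuconazole", "disease progression", 6, 2.503, 4.037, 2.523, 1.127, 5.648),
    ("isavuconazole", "visual impairment", 6, 2.597, 4.425, 2.619, 1.17, 5.861),
    ("isavuconazole", "multiple organ dysfunction syndrome", 5, 12.043, 40.208, 12.169, 5.039, 29.388),
    ("isavuconazole", "nervous system disorder", 5, 6.226, 17.043, 6.285, 2.603, 15.177),
    ("isavuconazole", "blood creatinine increased", 5, 4.155, 9.055, 4.191, 1.736, 10.12),
    ("isavuconazole", "general physical health deterioration", 5, 2.732, 3.911, 2.752, 1.14, 6.645),
    ("isavuconazole", "underdose", 4, 2.842, 3.121, 2.859, 1.068, 7.652),
    ("isavuconazole", "eosinophilia", 4, 13.828, 35.641, 13.944, 5.209, 37.329),
    ("isavuconazole", "electrocardiogram qt prolonged", 4, 5.302, 10.006, 5.341, 1.995, 14.295),
    ("isavuconazole", "drug level increased", 4, 11.750, 29.335, 11.848, 4.426, 31.716),
    ("isavuconazole", "drug-induced liver injury", 4, 7.739, 17.237, 7.802, 2.915, 20.883),
)

#: rows known to be transcription-inconsistent as printed (PRR > ROR > 1,
#: impossible for any positive 2x2 table)
INCONSISTENT_ROWS = (("posaconazole", "drug level decreased"),)


def load_triazole_top20() -> pd.DataFrame:
    """The printed top-20 signal rows as a DataFrame."""
    return pd.DataFrame(list(TOP20_ROWS), columns=list(_TOP20_COLUMNS))


def load_triazole_demographics() -> dict[str, dict]:
    """The printed demographic count tables (per drug)."""
    return {drug: dict(block) for drug, block in DEMOGRAPHICS.items()}
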