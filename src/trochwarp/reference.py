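"""Literature comparison values for hip-muscle trajectory angles.

Reference constants only: these are previously published trajectory angles
(Dostal/Neumann, Dunkelberg, Seireg & Arvikar, Jensen & Davy) tabulated for
comparison with the present straight-line measurements.  They are stored
as printed and are not recomputed by this package.  Sign conventions differ
between sources (some measure to the vertical rather than the horizontal)
and are not reconciled here.

Entries suspected to be decimal-point artifacts in the printed source are
listed in :data:`SUSPECT_ENTRIES` rather than silently altered.
"""

from __future__ import annotations

__all__ = [
    "FRONTAL_COMPARISON_ABDUCTORS",
    "FRONTAL_COMPARISON_ROTATORS",
    "TRANSVERSE_COMPARISON_ABDUCTORS",
    "TRANSVERSE_COMPARISON_ROTATORS",
    "SUSPECT_ENTRIES",
]

# Frontal plane, relative to the body horizontal; minus = caudomedial.
FRONTAL_COMPARISON_ABDUCTORS = {
    "dostal/neumann": {"gluteus maximus": 30.0, "tensor fasciae latae": 4.0,
                       "gluteus minimus": 24.0, "gluteus medius": 22.5},
    "dunkelberg": {"gluteus maximus": 44.6375, "tensor fasciae latae": 7.45,
                   "gluteus minimus": 28.725, "gluteus medius": 12.14166667},
    "seireg/arvikar": {"gluteus medius": 30.33},
    "jensen/davy": {"gluteus medius": 41.3},
    "this work": {"gluteus maximus": 58.0325, "tensor fasciae latae": 19.85,
                  "gluteus minimus": 38.175, "gluteus medius": 31.4},
}

FRONTAL_COMPARISON_ROTATORS = {
    "dostal/neumann": {"piriformis": 63.0, "quadratus femoris": -84.5},
    "dunkelberg": {"piriformis": 66.425, "triceps coxae": -78.14,
                   "obturator externus": -73.55, "quadratus femoris": -73.55},
    "this work": {"piriformis": 48.92, "triceps coxae": 81.36,
                  "obturator externus": -70.79, "quadratus femoris": 82.47},
}

# Transverse plane, relative to the body vertical in the sources;
# minus = dorsomedial.
TRANSVERSE_COMPARISON_ABDUCTORS = {
    "dostal/neumann": {"gluteus maximus": -39.0, "gluteus minimus": -48.73,
                       "gluteus medius": 1.24},
    "dunkelberg": {"gluteus maximus": -28.86, "tensor fasciae latae": 4375.0,
                   "gluteus minimus": -61.19, "gluteus medius": -69.3},
    "seireg/arvikar": {"gluteus medius": -93.08},
    "jensen/davy": {"gluteus medius": -82.23},
    "this work": {"gluteus maximus": -8.41},
}

TRANSVERSE_COMPARISON_ROTATORS = {
    "dostal/neumann": {"piriformis": 38.0, "triceps coxae": 35.3,
                       "obturator externus": 12.0, "quadratus femoris": -6.8},
    "dunkelberg": {"piriformis": 24.55, "triceps coxae": 38.58,
                   "obturator externus": 18.62, "quadratus femoris": -3.0},
    "this work": {"piriformis": 22.38, "triceps coxae": 26.06,
                  "obturator externus": 31.84, "quadratus femoris": -6.47},
}

#: Printed values that are almost certainly decimal-point artifacts, with a
#: plausible reading.  Stored as printed above; never silently fixed.
SUSPECT_ENTRIES = {
    ("transverse_abductors", "dunkelberg", "tensor fasciae latae"):
        {"printed": 4375.0, "plausible": 43.75},
}
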