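"""Bundled worked-example reference data.

Small published summary tables from the repeated-dose toxicity literature,
used as fixed inputs for worked examples and regression checks of the
statistics in :mod:`toxclust.clusterstats`.  All values are printed table
entries (the underlying per-study data are confidential and not included).
"""

from __future__ import annotations

# Per-chemical LOEL geometric means (mmol/kg bw/day) for a published
# 24-member cluster of ethylene glycols and alcohols -- substrates of
# alcohol dehydrogenase sharing kidney/liver/red-blood-cell/spleen targets.
# Printed cluster summary: geometric mean 2.78, range 0.06-137.88.
GLYCOL_ALCOHOL_CLUSTER_LOELS_MMOL: list[float] = [
    4.04,    # ethylene glycol
    2.83,    # diethylene glycol
    29.21,   # diethylene glycol monoethyl ether
    0.92,    # ethylene glycol monomethyl ether
    2.27,    # ethylene glycol monoethyl ether
    0.56,    # ethylene glycol monoisopropyl ether
    10.14,   # triethylene glycol
    2.44,    # triethylene glycol monomethyl ether
    2.99,    # propylene glycol
    28.38,   # 2-propylene glycol-1-methyl ether
    2.84,    # 2-propylene glycol mono-1-ethyl ether
    0.14,    # confidential member
    11.11,   # confidential member
    6.37,    # confidential member
    6.85,    # confidential member
    0.06,    # butynediol
    4.09,    # thiodiglycol
    1.49,    # trimethylolpropane
    2.85,    # methanol
    137.88,  # ethanol
    13.95,   # 2-propanol
    0.10,    # allyl alcohol
    1.19,    # 2-methyl-3-butyn-2-ol
    1.26,    # tert-butyl alcohol
]

# Published 2x2 feature-enrichment counts for the endpoint "spleen":
# 208 compounds with spleen effects vs 691 without; per feature the number
# of compounds carrying the structural feature in each group.  The three
# starred rows were reported significant after multiplicity correction.
SPLEEN_ENRICHMENT_COUNTS: dict[str, dict] = {
    "n_active": 208,
    "n_inactive": 691,
    "features": {
        "NA(A)A":     {"active_with": 125, "inactive_with": 291},
        "N":          {"active_with": 140, "inactive_with": 342},
        "Ether":      {"active_with": 74,  "inactive_with": 152},
        "Aromatic":   {"active_with": 142, "inactive_with": 411},
        "6M Ring":    {"active_with": 150, "inactive_with": 454},
        "Ring":       {"active_with": 164, "inactive_with": 509},
        "O > 1":      {"active_with": 122, "inactive_with": 445},
        "O":          {"active_with": 159, "inactive_with": 565},
        "X (Halogen)": {"active_with": 64, "inactive_with": 207},
        "6M Ring >1": {"active_with": 55,  "inactive_with": 195},
        "5 M Ring":   {"active_with": 42,  "inactive_with": 162},
    },
}

# Published read-across candidate clusters (gm/min ratio <= 5): cluster id,
# structural feature, LOEL geometric mean [mmol], range lower/upper [mmol],
# printed gm/lower ratio.
READACROSS_CANDIDATE_CLUSTERS: list[dict] = [
    {"cluster": 61, "feature": "azoles", "gm": 0.52, "lo": 0.49, "hi": 0.59, "ratio": 1.1},
    {"cluster": 13, "feature": "methylphenols", "gm": 0.58, "lo": 0.32, "hi": 1.39, "ratio": 1.8},
    {"cluster": 107, "feature": "alcohols", "gm": 0.03, "lo": 0.01, "hi": 0.09, "ratio": 3.0},
    {"cluster": 53, "feature": "nitroaromates", "gm": 0.77, "lo": 0.24, "hi": 2.01, "ratio": 3.2},
    {"cluster": 16, "feature": "aromatic phenols", "gm": 0.87, "lo": 0.23, "hi": 13.50, "ratio": 3.8},
    {"cluster": 76, "feature": "nitrophenols/-anilines", "gm": 0.21, "lo": 0.05, "hi": 0.66, "ratio": 4.2},
    {"cluster": 44, "feature": "carboxylether", "gm": 1.00, "lo": 0.22, "hi": 3.85, "ratio": 4.5},
    {"cluster": 75, "feature": "glycolether", "gm": 0.75, "lo": 0.14, "hi": 2.84, "ratio": 5.0},
]
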