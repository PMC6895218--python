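"""Frozen published fecundity-table inputs used as test oracles.

Per length class and spawning season: batch fecundity (thousands of
oocytes), the seven cumulative potential-fecundity values (thousands, from
VTO back to +PVO1-3), and the printed accumulated-batch and duration
columns.  ``None`` marks cells printed as dashes (no data).
"""

CUMULATIVE_ROWS = ("VTO", "+EVTO", "+CA", "+PVO4c", "+PVO4b", "+PVO4a", "+PVO1-3")

BF = {
    "40-50": {"SS1": None, "SS2": None, "SS3": 142},
    "50-60": {"SS1": 125, "SS2": 177, "SS3": 128},
    "60-70": {"SS1": 306, "SS2": 188, "SS3": 157},
    "70-80": {"SS1": 393, "SS2": 290, "SS3": 462},
}

PF = {
    "40-50": {"SS3": [283, 567, 850, 1417, 1700, 3401, 10202]},
    "50-60": {
        "SS1": [249, 498, 995, 1742, 2737, 3981, 7713],
        "SS2": [353, 706, 1059, 1764, 2823, 4235, 8469],
        "SS3": [255, 511, 766, 1277, 2042, 3064, 9702],
    },
    "60-70": {
        "SS1": [612, 1225, 1837, 3062, 4900, 6737, 11637],
        "SS2": [375, 749, 1498, 2622, 4869, 6742, 11985],
        "SS3": [313, 626, 1253, 1879, 3758, 5323, 12525],
    },
    "70-80": {
        "SS1": [786, 1572, 2357, 3929, 7072, 9430, 14930],
        "SS2": [579, 1158, 2317, 3475, 6950, 9845, 18532],
        "SS3": [924, 1847, 2771, 3694, 5541, 9236, 22166],
    },
}

BATCHES = {
    "40-50": {"SS3": [2, 4, 6, 10, 12, 24, 72]},
    "50-60": {
        "SS1": [2, 4, 8, 14, 22, 32, 62],
        "SS2": [2, 4, 6, 10, 16, 24, 48],
        "SS3": [2, 4, 6, 10, 16, 24, 76],
    },
    "60-70": {
        "SS1": [2, 4, 6, 10, 16, 22, 38],
        "SS2": [2, 4, 8, 14, 26, 36, 64],
        "SS3": [2, 4, 8, 12, 24, 34, 80],
    },
    "70-80": {
        "SS1": [2, 4, 6, 10, 18, 24, 38],
        "SS2": [2, 4, 8, 12, 24, 34, 64],
        "SS3": [2, 4, 6, 8, 12, 20, 48],
    },
}

DURATIONS = {
    "40-50": {"SS3": [0.3, 0.5, 0.8, 1.3, 1.6, 3.2, 9.6]},
    "50-60": {
        "SS1": [0.3, 0.5, 1.1, 1.9, 2.9, 4.3, 8.3],
        "SS2": [0.3, 0.5, 0.8, 1.3, 2.1, 3.2, 6.4],
        "SS3": [0.3, 0.5, 0.8, 1.3, 2.1, 3.2, 10.0],
    },
    "60-70": {
        "SS1": [0.3, 0.5, 0.8, 1.3, 2.1, 2.9, 5.1],
        "SS2": [0.3, 0.5, 1.1, 1.9, 3.5, 4.8, 8.5],
        "SS3": [0.3, 0.5, 1.1, 1.6, 3.2, 4.5, 11.0],
    },
    "70-80": {
        "SS1": [0.3, 0.5, 0.8, 1.3, 2.4, 3.2, 5.1],
        "SS2": [0.3, 0.5, 1.1, 1.6, 3.2, 4.5, 8.5],
        "SS3": [0.3, 0.5, 0.8, 1.1, 1.6, 2.7, 6.4],
    },
}


def populated_cells():
    """Yield (tl_class, season, row_index, bf, pf, batches, duration)."""
    for tl_class, seasons in PF.items():
        for season, pf_col in seasons.items():
            bf = BF[tl_class][season]
            for i, pf in enumerate(pf_col):
                yield (
                    tl_class,
                    season,
                    i,
                    bf,
                    pf,
                    BATCHES[tl_class][season][i],
                    DURATIONS[tl_class][season][i],
                )
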