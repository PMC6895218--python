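"""Controlled vocabulary: oocyte stages, ovarian maturity phases, grid components.

Stage ordering follows oocyte development: previtellogenic stages PVO1
through PVO4c (primary growth), then cortical alveoli (CAO), early (EVTO)
and medium-late (VTO) vitellogenic, migratory nucleus (MNO) and hydrated
(HYO) oocytes (secondary growth).
"""

from __future__ import annotations

from enum import Enum


class OocyteStage(str, Enum):
    PVO1 = "PVO1"
    PVO2 = "PVO2"
    PVO3 = "PVO3"
    PVO4A = "PVO4A"
    PVO4B = "PVO4B"
    PVO4C = "PVO4C"
    CAO = "CAO"
    EVTO = "EVTO"
    VTO = "VTO"
    MNO = "MNO"
    HYO = "HYO"

    @property
    def is_primary(self) -> bool:
        return self.name.startswith("PVO")

    @property
    def is_secondary(self) -> bool:
        return not self.is_primary

    @property
    def order(self) -> int:
        """Developmental rank, PVO1 = 0 ... HYO = 10."""
        return _STAGE_ORDER[self]

    def __str__(self) -> str:  # keeps CSV round-trips clean
        return self.value


_STAGE_ORDER = {s: i for i, s in enumerate(OocyteStage)}

#: Stages pooled into a single "PVO1-3" category for fecundity accounting.
PVO_POOL = (OocyteStage.PVO1, OocyteStage.PVO2, OocyteStage.PVO3)

#: Label used for the pooled smallest previtellogenic stages.
POOLED_PVO_LABEL = "PVO1-3"

#: Backwards accumulation order for batch accounting: most advanced
#: yolked stage first, then earlier stages.  MNO and HYO are excluded.
ACCUMULATION_ORDER = (
    OocyteStage.VTO.value,
    OocyteStage.EVTO.value,
    OocyteStage.CAO.value,
    OocyteStage.PVO4C.value,
    OocyteStage.PVO4B.value,
    OocyteStage.PVO4A.value,
    POOLED_PVO_LABEL,
)

#: Display labels for cumulative rows of the fecundity report.
CUMULATIVE_LABELS = (
    "VTO",
    "+EVTO",
    "+CA",
    "+PVO4c",
    "+PVO4b",
    "+PVO4a",
    "+PVO1-3",
)


class MaturityPhase(str, Enum):
    """Ovarian maturity phase (macroscopic/histological)."""

    IM = "IM"  # immature
    DV = "DV"  # developing
    SC = "SC"  # spawning capable
    AS = "AS"  # actively spawning
    RS = "RS"  # regressing
    RT = "RT"  # regenerating

    def __str__(self) -> str:
        return self.value


#: Phases counted as sexually mature when computing spawning fraction.
MATURE_PHASES = frozenset(
    {MaturityPhase.DV, MaturityPhase.SC, MaturityPhase.AS, MaturityPhase.RS, MaturityPhase.RT}
)

#: Phases pooled into the fecundity report (developing through actively spawning).
REPORT_PHASES = frozenset({MaturityPhase.DV, MaturityPhase.SC, MaturityPhase.AS})

# --- grid-count components -------------------------------------------------

#: Non-stage components a grid point can hit.
ATRESIA_EARLY_ALPHA = "ATR_EA"
ATRESIA_LATE_ALPHA = "ATR_LA"
ATRESIA_BETA = "ATR_B"
POF = "POF"
BLOOD = "BLOOD"
MISSING_OOCYTES = "MISSING"
TISSUE = "TISSUE"  # unclassified sectioned tissue (stroma, ovarian wall interior)
EMPTY_SPACE = "EMPTY"
OUTSIDE_WALL = "OUTSIDE"

NON_STAGE_COMPONENTS = (
    ATRESIA_EARLY_ALPHA,
    ATRESIA_LATE_ALPHA,
    ATRESIA_BETA,
    POF,
    BLOOD,
    MISSING_OOCYTES,
    TISSUE,
    EMPTY_SPACE,
    OUTSIDE_WALL,
)

#: Every component token a grid-count file may contain.
ALL_COMPONENTS = tuple(s.value for s in OocyteStage) + NON_STAGE_COMPONENTS

#: Components excluded from the valid-point denominator of volume fractions.
INVALID_POINT_COMPONENTS = (EMPTY_SPACE, OUTSIDE_WALL)
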