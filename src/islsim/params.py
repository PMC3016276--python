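"""Simulation parameter vector and compound presets.

The parameter names follow the vocabulary of the original in silico liver
(ISL) literature verbatim (``StepsPerCycle``, ``SSTypeRatio``, ...), so a
parameter file written against that vocabulary maps one-to-one onto
:class:`ISLParams` fields.  A handful of additional knobs that the published
parameter table does not cover (core/rim exchange probabilities, the
cycle-to-seconds calibration, the run-length cap) are documented below and
carry lowercase names to keep them visually distinct.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

__all__ = ["ISLParams", "SpeciesProperties", "COMPOUND_PRESETS", "PROBABILITY_FIELDS"]


@dataclass(frozen=True)
class SpeciesProperties:
    """Physicochemical flags of a mobile species.

    ``membrane_crossing`` gates cell entry (sucrose, an extracellular flow
    marker, never enters cells); ``bile_ratio`` is the probability that a
    freshly created metabolite is routed into the bile canaliculus rather
    than back into the intracellular space; ``bindable`` says whether
    binders/enzymes may sequester the species (metabolites are not bindable
    unless explicitly configured).
    """

    name: str
    membrane_crossing: bool
    bile_ratio: float
    bindable: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.bile_ratio <= 1.0:
            raise ValueError(f"bile_ratio must be in [0,1], got {self.bile_ratio}")


# MembraneCrossing / BileRatio are compound specific: the flow marker sucrose
# stays extracellular, the metabolized test drug diltiazem enters cells and
# routes half of its metabolite to bile.
COMPOUND_PRESETS: dict[str, dict[str, object]] = {
    "diltiazem": {"MembraneCrossing": True, "BileRatio": 0.5},
    "sucrose": {"MembraneCrossing": False, "BileRatio": 0.0},
}


@dataclass(frozen=True)
class ISLParams:
    """Complete parameter vector for one lobule simulation.

    Defaults reproduce the published reference parameterization of the
    enhanced ISL (the diltiazem setting).  All probabilities are plain
    fractions in [0, 1].
    """

    # -- discrete-time scheduling ------------------------------------------
    StepsPerCycle: int = 2            # random-walk sub-steps per simulation cycle
    # -- sinusoidal-segment geometry ---------------------------------------
    SSTypeRatio: float = 0.550        # probability a segment is short & wide
    DirSinCirc: int = 24              # circumference (grid cols) of short, wide SS
    DirSinLenAlpha: float = 1.000     # gamma shape for short, wide SS length
    DirSinLenBeta: float = 0.085      # gamma second parameter (see gamma_beta_is_rate)
    DirSinLenShift: float = 0.000     # additive shift, grid rows
    TortSinCirc: int = 10             # circumference of long, narrow SS
    TortSinLenAlpha: float = 8.000
    TortSinLenBeta: float = 0.075
    TortSinLenShift: float = -10.000
    # -- intra-segment movement --------------------------------------------
    SinusoidTurbo: float = 0.250      # P(forced downstream sub-step) in the space walk
    CoreFlowRate: int = 1             # rows advanced per cycle in Core and BileCanal
    BileCanalCirc: int = 1            # max metabolites handed to a successor per edge per cycle
    S2EJumpProb: float = 0.850        # Space A -> Space B
    E2SJumpProb: float = 0.150        # Space B -> Space A
    E2DJumpProb: float = 0.850        # Space B -> Space C
    D2EJumpProb: float = 0.150        # Space C -> Space B
    # -- cells and binders --------------------------------------------------
    ECDensity: float = 0.900          # fraction of Space B points holding an endothelial cell
    HepDensity: float = 0.900         # fraction of Space C points holding a hepatocyte
    BindersPerCellMin: int = 125
    BindersPerCellMax: int = 125
    MetabolismProb: float = 0.200     # per-cycle metabolism trial while bound in a hepatocyte
    SoluteBindingProb: float = 0.750  # P(binding) on cell entry given a free binder
    SoluteBindingCycles: int = 15     # cycles a bound compound stays sequestered
    SoluteScale: float = 1.0          # scaling from simulated to wet-lab dose fraction
    # -- compound properties -----------------------------------------------
    MembraneCrossing: bool = True     # dosed compound crosses cell membranes
    BileRatio: float = 0.5            # metabolite routed to bile with this probability
    # -- dosing -------------------------------------------------------------
    Dosage: int = 5000                # compound objects injected as an impulse
    DosageCycle: int = 2              # cycle at which the bolus is injected
    # -- knobs absent from the published table ------------------------------
    core_exit_prob: float = 0.5       # P(Core entity steps sideways into Space A) per cycle
    rim_to_core_prob: float = 0.5     # P(Space A entity re-enters the Core) per cycle
    seconds_per_cycle: float = 0.5    # wall-clock seconds one cycle represents
    max_cycles: int = 480             # hard cap on simulated cycles per lobule
    # -- interpretation switches -------------------------------------------
    ss_ratio_as_odds: bool = False    # read SSTypeRatio as odds short:long instead of P(short)
    gamma_beta_is_rate: bool = True   # read *LenBeta as a rate (scale = 1/beta)
    compound_name: str = "diltiazem"

    def __post_init__(self) -> None:
        for name in PROBABILITY_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("StepsPerCycle", "CoreFlowRate", "BileCanalCirc", "DirSinCirc", "TortSinCirc"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("Dosage", "DosageCycle", "BindersPerCellMin", "BindersPerCellMax",
                     "SoluteBindingCycles", "max_cycles"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.BindersPerCellMax < self.BindersPerCellMin:
            raise ValueError("BindersPerCellMax must be >= BindersPerCellMin")
        for name in ("DirSinLenAlpha", "DirSinLenBeta", "TortSinLenAlpha", "TortSinLenBeta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.seconds_per_cycle <= 0:
            raise ValueError("seconds_per_cycle must be > 0")
        if self.ss_ratio_as_odds:
            if self.SSTypeRatio < 0:
                raise ValueError("SSTypeRatio as odds must be >= 0")
        elif not 0.0 <= self.SSTypeRatio <= 1.0:
            raise ValueError(f"SSTypeRatio must be in [0,1], got {self.SSTypeRatio}")

    @classmethod
    def for_compound(cls, name: str, **overrides: object) -> "ISLParams":
        """Build a parameter vector for one of the preset compounds."""
        try:
            preset = COMPOUND_PRESETS[name]
        except KeyError:
            raise ValueError(
                f"unknown compound {name!r}; known: {sorted(COMPOUND_PRESETS)}"
            ) from None
        merged = dict(preset)
        merged["compound_name"] = name
        merged.update(overrides)
        return cls(**merged)  # type: ignore[arg-type]

    def with_(self, **overrides: object) -> "ISLParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **overrides)  # type: ignore[arg-type]

    # -- derived species table ---------------------------------------------
    def dosed_species(self) -> SpeciesProperties:
        return SpeciesProperties(
            name=self.compound_name,
            membrane_crossing=self.MembraneCrossing,
            bile_ratio=self.BileRatio,
            bindable=self.MembraneCrossing,
        )

    def metabolite_species(self) -> SpeciesProperties:
        # Enzymes cannot bind metabolites; their bile ratio is irrelevant
        # because only bindable species can be metabolized.
        return SpeciesProperties(
            name="metabolite", membrane_crossing=True, bile_ratio=0.0, bindable=False
        )

    def to_dict(self) -> dict[str, object]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


PROBABILITY_FIELDS: tuple[str, ...] = (
    "SinusoidTurbo",
    "S2EJumpProb",
    "E2SJumpProb",
    "E2DJumpProb",
    "D2EJumpProb",
    "ECDensity",
    "HepDensity",
    "MetabolismProb",
    "SoluteBindingProb",
    "BileRatio",
    "core_exit_prob",
    "rim_to_core_prob",
)
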