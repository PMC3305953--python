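"""Health-state enumeration for the colorectal neoplasia Markov model.

The model follows the adenoma--carcinoma sequence: normal epithelium ->
low-risk adenoma (<10 mm) -> intermediate/high-risk adenoma (>=10 mm) ->
preclinical cancer (AJCC stage I..IV) -> clinically diagnosed cancer ->
death.  Adenomas and preclinical cancers carry a colonic location
(distal/proximal) so that a test with distal-only reach (flexible
sigmoidoscopy) can be modelled; a fraction of cancers arises directly from
normal epithelium without a prior adenoma and is tracked through a
provenance flag on preclinical states.

Two enumerations are exposed:

* :func:`build_state_space` -- the canonical 22-state space (preclinical
  states keyed by stage x location, two lumped surveillance compartments).
* the *extended* natural-history space used by the simulator, in which
  preclinical states are additionally split by provenance (via-adenoma vs
  direct), giving 28 states.  The screening overlay further expands the
  surveillance compartments into tunnel cells; see ``screening.py``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional


class Compartment(str, Enum):
    NORMAL = "normal"
    ADENOMA_LOW = "adenoma_low"
    ADENOMA_HIGH = "adenoma_high"
    CRC_PRECLIN_I = "crc_preclin_I"
    CRC_PRECLIN_II = "crc_preclin_II"
    CRC_PRECLIN_III = "crc_preclin_III"
    CRC_PRECLIN_IV = "crc_preclin_IV"
    CRC_CLINICAL_I = "crc_clinical_I"
    CRC_CLINICAL_II = "crc_clinical_II"
    CRC_CLINICAL_III = "crc_clinical_III"
    CRC_CLINICAL_IV = "crc_clinical_IV"
    SURVEILLANCE_INT = "surveillance_int"
    SURVEILLANCE_HIGH = "surveillance_high"
    DEAD_CRC = "dead_crc"
    DEAD_PERFORATION = "dead_perforation"
    DEAD_OTHER = "dead_other"


class Location(str, Enum):
    DISTAL = "distal"
    PROXIMAL = "proximal"
    NONE = "none"


class Provenance(str, Enum):
    VIA_ADENOMA = "via_adenoma"
    DIRECT = "direct"


PRECLIN_COMPARTMENTS = (
    Compartment.CRC_PRECLIN_I,
    Compartment.CRC_PRECLIN_II,
    Compartment.CRC_PRECLIN_III,
    Compartment.CRC_PRECLIN_IV,
)
CLINICAL_COMPARTMENTS = (
    Compartment.CRC_CLINICAL_I,
    Compartment.CRC_CLINICAL_II,
    Compartment.CRC_CLINICAL_III,
    Compartment.CRC_CLINICAL_IV,
)
DEAD_COMPARTMENTS = (
    Compartment.DEAD_CRC,
    Compartment.DEAD_PERFORATION,
    Compartment.DEAD_OTHER,
)
ADENOMA_COMPARTMENTS = (Compartment.ADENOMA_LOW, Compartment.ADENOMA_HIGH)


@dataclass(frozen=True)
class HealthState:
    """One cell of the model state space.

    ``location`` is :attr:`Location.NONE` for states where laterality is
    meaningless (normal, clinical, surveillance, dead).  ``provenance`` is
    only set for cancer states and only in the extended enumeration.
    """

    compartment: Compartment
    location: Location = Location.NONE
    provenance: Optional[Provenance] = None

    def __post_init__(self) -> None:
        locless = (
            self.compartment in DEAD_COMPARTMENTS
            or self.compartment in CLINICAL_COMPARTMENTS
            or self.compartment
            in (
                Compartment.NORMAL,
                Compartment.SURVEILLANCE_INT,
                Compartment.SURVEILLANCE_HIGH,
            )
        )
        if locless and self.location is not Location.NONE:
            raise ValueError(f"{self.compartment.value} carries no location")
        if not locless and self.location is Location.NONE:
            raise ValueError(f"{self.compartment.value} requires a location")

    @property
    def is_dead(self) -> bool:
        return self.compartment in DEAD_COMPARTMENTS

    @property
    def is_clinical(self) -> bool:
        return self.compartment in CLINICAL_COMPARTMENTS

    @property
    def is_preclinical(self) -> bool:
        return self.compartment in PRECLIN_COMPARTMENTS

    @property
    def is_adenoma(self) -> bool:
        return self.compartment in ADENOMA_COMPARTMENTS

    def __str__(self) -> str:
        if self.location is Location.NONE:
            return self.compartment.value
        return f"{self.compartment.value}/{self.location.value}"


def build_state_space() -> list[HealthState]:
    """Canonical, deterministically ordered 22-state enumeration.

    One normal state; 2x2 adenoma states (risk class x location); 4x2
    preclinical cancer states (AJCC stage x location); 4 clinical cancer
    states; two surveillance compartments; three absorbing death states
    (colorectal cancer, endoscopic perforation, other causes).
    """
    states: list[HealthState] = [HealthState(Compartment.NORMAL)]
    for comp in ADENOMA_COMPARTMENTS:
        for loc in (Location.DISTAL, Location.PROXIMAL):
            states.append(HealthState(comp, loc))
    for comp in PRECLIN_COMPARTMENTS:
        for loc in (Location.DISTAL, Location.PROXIMAL):
            states.append(HealthState(comp, loc))
    for comp in CLINICAL_COMPARTMENTS:
        states.append(HealthState(comp))
    states.append(HealthState(Compartment.SURVEILLANCE_INT))
    states.append(HealthState(Compartment.SURVEILLANCE_HIGH))
    for comp in DEAD_COMPARTMENTS:
        states.append(HealthState(comp))
    return states


def build_extended_states() -> list[HealthState]:
    """28-state natural-history space: preclinical states split by provenance.

    Order (fixed; indices are relied on throughout the simulator):
    normal; adenoma (risk x location); preclinical (stage x location x
    provenance); clinical (stage); dead (crc, perforation, other).
    """
    states: list[HealthState] = [HealthState(Compartment.NORMAL)]
    for comp in ADENOMA_COMPARTMENTS:
        for loc in (Location.DISTAL, Location.PROXIMAL):
            states.append(HealthState(comp, loc))
    for comp in PRECLIN_COMPARTMENTS:
        for loc in (Location.DISTAL, Location.PROXIMAL):
            for prov in (Provenance.VIA_ADENOMA, Provenance.DIRECT):
                states.append(HealthState(comp, loc, prov))
    for comp in CLINICAL_COMPARTMENTS:
        states.append(HealthState(comp))
    for comp in DEAD_COMPARTMENTS:
        states.append(HealthState(comp))
    return states


# -- fixed indices into the extended 28-state vector --------------------------

N_EXT = 28
IDX_NORMAL = 0
IDX_AD_LOW_D, IDX_AD_LOW_P, IDX_AD_HIGH_D, IDX_AD_HIGH_P = 1, 2, 3, 4


def idx_preclin(stage: int, distal: bool, direct: bool) -> int:
    """Index of a preclinical state; ``stage`` in 1..4."""
    return 5 + 4 * (stage - 1) + 2 * (0 if distal else 1) + (1 if direct else 0)


def idx_clinical(stage: int) -> int:
    return 21 + (stage - 1)


IDX_CLIN = [idx_clinical(s) for s in (1, 2, 3, 4)]
IDX_DEAD_CRC = 25
IDX_DEAD_PERF = 26
IDX_DEAD_OTHER = 27
IDX_DEAD = [IDX_DEAD_CRC, IDX_DEAD_PERF, IDX_DEAD_OTHER]
IDX_LIVE = [i for i in range(N_EXT) if i not in IDX_DEAD]
IDX_PRECLIN_ALL = list(range(5, 21))
IDX_ADENOMA = [IDX_AD_LOW_D, IDX_AD_LOW_P, IDX_AD_HIGH_D, IDX_AD_HIGH_P]
# live states that have not yet been diagnosed (screening applies to these)
IDX_PREDIAG = [IDX_NORMAL] + IDX_ADENOMA + IDX_PRECLIN_ALL
N_PREDIAG = len(IDX_PREDIAG)  # 21
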