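"""Six-state treatment taxonomy for rheumatoid-arthritis DMARD sequences.

The state space distinguishes tocilizumab (TCZ, an IL-6 receptor antagonist)
used alone from TCZ combined with a conventional synthetic DMARD, because
monotherapy with this agent is the clinical endpoint the pathway analysis
targets.  TNF inhibitors form their own class; every other biologic (abatacept,
rituximab) and the JAK inhibitors share one bucket, since JAK inhibitors are
used sequentially after synthetic DMARDs and target specific immune pathways.
Patients who step back to conventional therapy only, or report no DMARD at
all, occupy the remaining two states.
"""

from __future__ import annotations

import enum


class TreatmentState(str, enum.Enum):
    """Treatment state of a patient over one six-month interval."""

    TCZ_MONO = "TCZ_MONO"
    TCZ_COMBO = "TCZ_COMBO"
    TNFI = "TNFI"
    OTHER_BDMARD = "OTHER_BDMARD"
    CSDMARD_ONLY = "CSDMARD_ONLY"
    NO_DMARD = "NO_DMARD"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical ordering used for matrices, tables and plots.
STATE_ORDER: tuple[TreatmentState, ...] = (
    TreatmentState.TCZ_MONO,
    TreatmentState.TCZ_COMBO,
    TreatmentState.TNFI,
    TreatmentState.OTHER_BDMARD,
    TreatmentState.CSDMARD_ONLY,
    TreatmentState.NO_DMARD,
)

STATE_INDEX: dict[TreatmentState, int] = {s: i for i, s in enumerate(STATE_ORDER)}

#: States that count as biologic (or targeted synthetic) DMARD use.
BDMARD_STATES: frozenset[TreatmentState] = frozenset(
    {
        TreatmentState.TCZ_MONO,
        TreatmentState.TCZ_COMBO,
        TreatmentState.TNFI,
        TreatmentState.OTHER_BDMARD,
    }
)

#: Medication indicator flags expected on a visit record, in precedence order.
MEDICATION_FLAGS: tuple[str, ...] = (
    "tcz",
    "tnfi",
    "other_bdmard_or_jak",
    "csdmard",
    "glucocorticoid",
)


def classify_visit(
    tcz: int | bool = 0,
    tnfi: int | bool = 0,
    other_bdmard_or_jak: int | bool = 0,
    csdmard: int | bool = 0,
    glucocorticoid: int | bool = 0,
) -> TreatmentState:
    """Classify one visit's medication flags into a treatment state.

    Precedence is TCZ > TNF inhibitor > other bDMARD/JAK inhibitor > csDMARD >
    nothing.  TCZ splits on monotherapy: if any *other* DMARD flag accompanies
    TCZ the state is ``TCZ_COMBO``, otherwise ``TCZ_MONO`` (monotherapy means
    no other DMARD treatment marked on the case report form at the time of TCZ
    use).  Glucocorticoids are a covariate, never a DMARD, and do not affect
    classification.  Total over all 2**5 flag combinations.
    """
    if tcz:
        if tnfi or other_bdmard_or_jak or csdmard:
            return TreatmentState.TCZ_COMBO
        return TreatmentState.TCZ_MONO
    if tnfi:
        return TreatmentState.TNFI
    if other_bdmard_or_jak:
        return TreatmentState.OTHER_BDMARD
    if csdmard:
        return TreatmentState.CSDMARD_ONLY
    return TreatmentState.NO_DMARD


def state_flags(state: TreatmentState, csdmard_concurrent: bool = False) -> dict[str, int]:
    """Medication flags a case report form would carry for ``state``.

    ``csdmard_concurrent`` sets the csDMARD flag alongside a TNFi or other
    bDMARD (both classes may be used with or without a csDMARD without
    changing state).  Inverse of :func:`classify_visit` up to that freedom.
    """
    f = {name: 0 for name in MEDICATION_FLAGS[:4]}
    if state is TreatmentState.TCZ_MONO:
        f["tcz"] = 1
    elif state is TreatmentState.TCZ_COMBO:
        f["tcz"] = 1
        f["csdmard"] = 1
    elif state is TreatmentState.TNFI:
        f["tnfi"] = 1
        f["csdmard"] = int(csdmard_concurrent)
    elif state is TreatmentState.OTHER_BDMARD:
        f["other_bdmard_or_jak"] = 1
        f["csdmard"] = int(csdmard_concurrent)
    elif state is TreatmentState.CSDMARD_ONLY:
        f["csdmard"] = 1
    return f
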