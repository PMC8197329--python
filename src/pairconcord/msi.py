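"""Microsatellite-instability classification from the five-marker Bethesda
panel (BAT25, BAT26, D5S346, D2S123, D17S250).

A tumor is MSI-H when two or more markers are unstable, MSI-L when exactly
one is, and MSS when none is unstable and at least four markers were
evaluable.  With fewer than four evaluable markers and no instability the
panel is considered uninformative and the result is ``unknown`` — a
conservative guard for partially failed panels.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

from pairconcord.model import MsiStatus


class MsiMarker(str, Enum):
    BAT25 = "BAT25"
    BAT26 = "BAT26"
    D5S346 = "D5S346"
    D2S123 = "D2S123"
    D17S250 = "D17S250"


@dataclass(frozen=True)
class MsiMarkerCall:
    """Stability call of one Bethesda marker for one patient.

    ``unstable`` is None when the marker assay failed (not evaluable).
    """

    patient_id: str
    marker: MsiMarker
    unstable: Optional[bool]


MIN_EVALUABLE_FOR_MSS = 4


def classify_msi(calls: Iterable[MsiMarkerCall]) -> MsiStatus:
    """Classify one patient's marker calls into MSI-H / MSI-L / MSS / unknown.

    Raises ``ValueError`` on a duplicated marker.
    """
    calls = list(calls)
    seen: set[MsiMarker] = set()
    for c in calls:
        if c.marker in seen:
            pid = c.patient_id
            raise ValueError(f"patient {pid}: duplicate marker {c.marker.value}")
        seen.add(c.marker)
    n_unstable = sum(1 for c in calls if c.unstable is True)
    n_evaluable = sum(1 for c in calls if c.unstable is not None)
    if n_unstable >= 2:
        return MsiStatus.MSI_H
    if n_unstable == 1:
        return MsiStatus.MSI_L
    if n_evaluable >= MIN_EVALUABLE_FOR_MSS:
        return MsiStatus.MSS
    return MsiStatus.UNKNOWN


def classify_cohort(calls: Iterable[MsiMarkerCall]) -> dict[str, MsiStatus]:
    """Group marker calls by patient and classify each patient."""
    by_patient: dict[str, list[MsiMarkerCall]] = {}
    for c in calls:
        by_patient.setdefault(c.patient_id, []).append(c)
    return {pid: classify_msi(pcalls) for pid, pcalls in by_patient.items()}
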