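"""Composite classification of perinatal asphyxia.

A neonate is classified as having sustained perinatal asphyxia when ANY
of the following holds: stillbirth or neonatal death attributable to
asphyxia; an established diagnosis of hypoxic-ischemic encephalopathy
(brain injury on imaging, HIE-consistent multisystem organ failure, or
therapeutic cooling); neonatal resuscitation at 10 minutes followed by
NICU admission; Apgar <=6 at 10 min or <=4 at 5 min; arterial cord blood
pH < 7.05 (strict); or seizures immediately after birth attributed to
asphyxia.

Unknown (missing) fields never satisfy a criterion, so partially
documented neonates are still classifiable from what is known; a
completeness flag accompanies each classification for sensitivity use.
External datasets that lack some components (e.g. no NICU events or HIE
imaging) are handled with a criteria mask restricting the rule to the
components they record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

#: Canonical criterion names, in rule order.
CRITERIA = (
    "stillbirth",
    "neonatal_death",
    "hie",
    "resuscitation_nicu",
    "apgar10_le6",
    "apgar5_le4",
    "cord_ph_lt_7_05",
    "asphyxial_seizures",
)

APGAR10_CUTOFF = 6
APGAR5_CUTOFF = 4
CORD_PH_CUTOFF = 7.05


@dataclass
class NeonatalRecord:
    """Outcome fields for one neonate; ``None`` marks unknown."""

    stillbirth_asphyxia: bool | None = False
    neonatal_death_asphyxia: bool | None = False
    hie_imaging: bool | None = False
    hie_multiorgan_failure: bool | None = False
    therapeutic_cooling: bool | None = False
    resuscitation_at_10min: bool | None = False
    nicu_admission: bool | None = False
    apgar_5min: int | None = None
    apgar_10min: int | None = None
    cord_arterial_ph: float | None = None
    asphyxial_seizures: bool | None = False

    def __post_init__(self) -> None:
        for name in ("apgar_5min", "apgar_10min"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 10:
                raise ValueError(f"{name}={v} outside 0-10")
        ph = self.cord_arterial_ph
        if ph is not None and not 6.5 < ph < 7.8:
            raise ValueError(f"cord_arterial_ph={ph} outside plausible (6.5, 7.8)")


def criteria_met(record: NeonatalRecord) -> list[str]:
    """Names of the composite criteria this record satisfies."""
    met = []
    if record.stillbirth_asphyxia:
        met.append("stillbirth")
    if record.neonatal_death_asphyxia:
        met.append("neonatal_death")
    if record.hie_imaging or record.hie_multiorgan_failure or record.therapeutic_cooling:
        met.append("hie")
    if record.resuscitation_at_10min and record.nicu_admission:
        met.append("resuscitation_nicu")
    if record.apgar_10min is not None and record.apgar_10min <= APGAR10_CUTOFF:
        met.append("apgar10_le6")
    if record.apgar_5min is not None and record.apgar_5min <= APGAR5_CUTOFF:
        met.append("apgar5_le4")
    if record.cord_arterial_ph is not None and record.cord_arterial_ph < CORD_PH_CUTOFF:
        met.append("cord_ph_lt_7_05")
    if record.asphyxial_seizures:
        met.append("asphyxial_seizures")
    return met


def is_complete(record: NeonatalRecord) -> bool:
    """True when every outcome field is known (no ``None``)."""
    return all(
        getattr(record, f) is not None
        for f in (
            "stillbirth_asphyxia",
            "neonatal_death_asphyxia",
            "hie_imaging",
            "hie_multiorgan_failure",
            "therapeutic_cooling",
            "resuscitation_at_10min",
            "nicu_admission",
            "apgar_5min",
            "apgar_10min",
            "cord_arterial_ph",
            "asphyxial_seizures",
        )
    )


def classify_asphyxia(
    record: NeonatalRecord, criteria_mask: Iterable[str] | None = None
) -> bool:
    """True iff any (unmasked) composite criterion is satisfied.

    ``criteria_mask`` restricts the rule to a subset of
    :data:`CRITERIA`, for datasets that do not record every component.
    """
    met = criteria_met(record)
    if criteria_mask is not None:
        allowed = set(criteria_mask)
        unknown = allowed - set(CRITERIA)
        if unknown:
            raise ValueError(f"unknown criteria in mask: {sorted(unknown)}")
        met = [c for c in met if c in allowed]
    return bool(met)


# Column names expected in a cohort table, mapped to NeonatalRecord fields.
_OUTCOME_COLUMNS = {
    "stillbirth_asphyxia": "stillbirth_asphyxia",
    "neonatal_death_asphyxia": "neonatal_death_asphyxia",
    "hie_imaging": "hie_imaging",
    "hie_multiorgan_failure": "hie_multiorgan_failure",
    "therapeutic_cooling": "therapeutic_cooling",
    "resuscitation_at_10min": "resuscitation_at_10min",
    "nicu_admission": "nicu_admission",
    "apgar_5min": "apgar_5min",
    "apgar_10min": "apgar_10min",
    "cord_arterial_ph": "cord_arterial_ph",
    "asphyxial_seizures": "asphyxial_seizures",
}


def _cell(value):
    return None if pd.isna(value) else value


def classify_cohort(
    cohort: pd.DataFrame, criteria_mask: Iterable[str] | None = None
) -> pd.DataFrame:
    """Apply the composite rule to the outcome columns of a cohort table.

    Missing columns are treated as wholly unknown.  Returns a frame with
    ``asphyxia`` (bool), ``criteria_met`` (comma-joined audit list) and
    ``outcome_complete`` columns, indexed like the input.
    """
    out = []
    for _, row in cohort.iterrows():
        kwargs = {}
        for col, fld in _OUTCOME_COLUMNS.items():
            if col in cohort.columns:
                v = _cell(row[col])
                if fld in ("apgar_5min", "apgar_10min") and v is not None:
                    v = int(v)
                elif fld == "cord_arterial_ph" and v is not None:
                    v = float(v)
                elif v is not None:
                    v = bool(v)
                kwargs[fld] = v
            else:
                kwargs[fld] = None
        rec = NeonatalRecord(**kwargs)
        out.append(
            dict(
                asphyxia=classify_asphyxia(rec, criteria_mask),
                criteria_met=",".join(
                    c
                    for c in criteria_met(rec)
                    if criteria_mask is None or c in set(criteria_mask)
                ),
                outcome_complete=is_complete(rec),
            )
        )
    return pd.DataFrame(out, index=cohort.index)
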