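"""ADME screening of a compound pool.

Five pharmacokinetic parameters gate whether a compound is considered
"active": oral bioavailability (OB, percent), drug-likeness (DL),
Caco-2 intestinal permeability, blood-brain-barrier penetration (BBB)
and drug half-life (HL, hours).  A compound passes when *all five*
values reach their thresholds (inclusive).  Compounds that fail the
screen may still be rescued through a literature whitelist; the active
set is the disjoint union of ADME passes and rescues.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from herbnet.errors import ValidationError

logger = logging.getLogger(__name__)

#: The five screened parameters, in conventional reporting order.
ADME_FIELDS = ("ob", "dl", "caco2", "bbb", "hl")


@dataclass(frozen=True)
class CompoundRecord:
    """One compound with its five ADME parameters and herb provenance."""

    compound_id: str
    name: str
    herbs: frozenset[str]
    ob: float
    dl: float
    caco2: float
    bbb: float
    hl: float
    whitelisted: bool = False

    def __post_init__(self):
        if not self.herbs:
            raise ValidationError(f"compound {self.compound_id!r}: herbs must be non-empty")


@dataclass(frozen=True)
class AdmeThresholds:
    """Inclusive lower bounds for the five ADME parameters.

    Defaults are the conventional screen for orally taken,
    centrally acting herbal compounds: OB >= 30 %, DL >= 0.18,
    Caco-2 >= -0.4, BBB >= -0.3, HL >= 4 h.
    """

    ob_min: float = 30.0
    dl_min: float = 0.18
    caco2_min: float = -0.4
    bbb_min: float = -0.3
    hl_min: float = 4.0

    def __post_init__(self):
        for name in ("ob_min", "dl_min", "caco2_min", "bbb_min", "hl_min"):
            v = getattr(self, name)
            if v is None or not math.isfinite(float(v)):
                raise ValidationError(f"threshold {name} must be finite, got {v!r}")

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f + "_min") for f in ADME_FIELDS}


@dataclass
class ActiveSet:
    """Partitioned result of a screen: ADME passes plus whitelist rescues."""

    adme_passed: list[CompoundRecord] = field(default_factory=list)
    rescued: list[CompoundRecord] = field(default_factory=list)

    @property
    def active(self) -> list[CompoundRecord]:
        return self.adme_passed + self.rescued

    @property
    def active_ids(self) -> set[str]:
        return {c.compound_id for c in self.active}

    def counts(self) -> dict[str, int]:
        return {
            "adme_passed": len(self.adme_passed),
            "rescued": len(self.rescued),
            "active": len(self.adme_passed) + len(self.rescued),
        }


def _checked_value(c: CompoundRecord, fieldname: str) -> float:
    v = getattr(c, fieldname, None)
    if v is None:
        raise ValidationError(f"compound {c.compound_id!r}: missing ADME field {fieldname!r}")
    try:
        fv = float(v)
    except (TypeError, ValueError):
        raise ValidationError(
            f"compound {c.compound_id!r}: non-numeric ADME field {fieldname!r} = {v!r}"
        ) from None
    if math.isnan(fv):
        raise ValidationError(f"compound {c.compound_id!r}: missing ADME field {fieldname!r} (NaN)")
    return fv


def passes_adme(c: CompoundRecord, t: AdmeThresholds | None = None) -> bool:
    """True iff every one of the five parameters reaches its threshold.

    All comparisons are inclusive (>=).  A missing or non-numeric value
    raises :class:`ValidationError` naming the compound and field rather
    than silently failing the screen.
    """
    t = t or AdmeThresholds()
    limits = t.as_dict()
    return all(_checked_value(c, f) >= limits[f] for f in ADME_FIELDS)


def screen_compounds(
    table: Sequence[CompoundRecord] | Iterable[CompoundRecord],
    thresholds: AdmeThresholds | None = None,
    whitelist: set[str] | None = None,
) -> ActiveSet:
    """Partition a compound table into ADME passes and whitelist rescues.

    Parameters
    ----------
    table:
        Compound records to screen.
    thresholds:
        Inclusive lower bounds; defaults to the standard five-parameter screen.
    whitelist:
        Compound ids rescued on literature grounds.  When ``None``, the
        records' own ``whitelisted`` flags are used.  Whitelisted ids that
        already pass ADME are *not* double-counted; whitelist ids absent
        from the table are logged, not fatal.
    """
    thresholds = thresholds or AdmeThresholds()
    records = list(table)
    if not records:
        logger.warning("screen_compounds: empty compound table, returning empty active set")
        return ActiveSet()

    table_ids = {c.compound_id for c in records}
    if whitelist is None:
        wl = {c.compound_id for c in records if c.whitelisted}
    else:
        wl = set(whitelist)
        missing = wl - table_ids
        if missing:
            logger.warning(
                "screen_compounds: %d whitelist ids not present in table: %s",
                len(missing),
                ", ".join(sorted(missing)[:10]),
            )

    result = ActiveSet()
    for c in records:
        if passes_adme(c, thresholds):
            result.adme_passed.append(c)
        elif c.compound_id in wl:
            result.rescued.append(c)
    logger.info(
        "ADME screen: %d compounds in, %d passed, %d rescued, %d active",
        len(records),
        len(result.adme_passed),
        len(result.rescued),
        len(result.active),
    )
    return result
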