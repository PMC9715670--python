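"""Domain types and patient-level plumbing for the platform trial.

The trial classifies each enrolled patient into one of 8 subtypes from three
binary baseline markers — hormone-receptor (HR) status, HER2 status and the
dichotomized MammaPrint risk stratum (MP1 high vs MP2 ultra-high) — and
evaluates efficacy within *signatures*, clinically meaningful unions of
subtypes (e.g. "all HER2-negative", "triple negative").

The primary endpoint is pathologic complete response (pCR), analyzed under a
modified intent-to-treat rule: every patient who received any allocated
therapy is evaluable, and patients who switched to non-protocol therapy,
withdrew, or never had surgery are coded non-pCR.  Patients still on
treatment at an interim analysis are a first-class "pending" state (pcr is
None) so the longitudinal imputation model can handle them.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence


# --------------------------------------------------------------------------
# Subtypes and signatures
# --------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Subtype:
    """One HR x HER2 x MammaPrint cell.

    ``mp2`` is True for the MammaPrint ultra-high (MP2) stratum.  The
    lexicographic dataclass ordering (hr, her2, mp2) gives the deterministic
    iteration order used throughout.
    """

    hr: bool
    her2: bool
    mp2: bool

    @property
    def label(self) -> str:
        return "HR{}/HER2{}/{}".format(
            "+" if self.hr else "-",
            "+" if self.her2 else "-",
            "MP2" if self.mp2 else "MP1",
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


#: All 8 subtypes in deterministic order.
ALL_SUBTYPES: tuple[Subtype, ...] = tuple(
    sorted(
        Subtype(hr, her2, mp2)
        for hr in (False, True)
        for her2 in (False, True)
        for mp2 in (False, True)
    )
)


@dataclass(frozen=True)
class Signature:
    """A named, nonempty union of subtypes in which efficacy is evaluated."""

    name: str
    member_subtypes: frozenset[Subtype]

    def __post_init__(self) -> None:
        if not self.member_subtypes:
            raise ValueError(f"signature {self.name!r} has no member subtypes")

    def contains(self, s: Subtype) -> bool:
        return s in self.member_subtypes


def _sig(name: str, pred) -> Signature:
    return Signature(name, frozenset(s for s in ALL_SUBTYPES if pred(s)))


def default_signature_catalogue() -> list[Signature]:
    """The ten-signature catalogue used by default.

    The platform evaluates ten clinically relevant HR/HER2/MammaPrint
    signatures; only three are named in the primary efficacy report
    (HER2-; TN = HR-/HER2-; HR+/HER2-), so the full set here is a
    configurable reconstruction, not a protocol constant.
    """
    return [
        _sig("all", lambda s: True),
        _sig("HR+", lambda s: s.hr),
        _sig("HR-", lambda s: not s.hr),
        _sig("HER2+", lambda s: s.her2),
        _sig("HER2-", lambda s: not s.her2),
        _sig("MP2", lambda s: s.mp2),
        _sig("HR+/HER2-", lambda s: s.hr and not s.her2),
        _sig("HR-/HER2-", lambda s: not s.hr and not s.her2),
        _sig("HR+/HER2+", lambda s: s.hr and s.her2),
        _sig("HR-/HER2+", lambda s: not s.hr and s.her2),
    ]


def subtype_signature(s: Subtype) -> Signature:
    """Singleton signature for one subtype (used for per-subtype randomization)."""
    return Signature(s.label, frozenset([s]))


# --------------------------------------------------------------------------
# Arms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ArmSpec:
    """Registration of one arm: identity, eligibility and accrual window."""

    arm_id: str
    is_control: bool
    eligible_subtypes: frozenset[Subtype] = frozenset(ALL_SUBTYPES)
    open_day: int = 0
    close_day: Optional[int] = None
    max_accrual: int = 10_000

    def __post_init__(self) -> None:
        if self.is_control and self.eligible_subtypes != frozenset(ALL_SUBTYPES):
            raise ValueError("control arm must be eligible for all subtypes")
        if self.max_accrual <= 0:
            raise ValueError("max_accrual must be positive")

    def is_open(self, day: int) -> bool:
        if day < self.open_day:
            return False
        return self.close_day is None or day < self.close_day


def control_arm(arms: Sequence[ArmSpec]) -> ArmSpec:
    controls = [a for a in arms if a.is_control]
    if len(controls) != 1:
        raise ValueError(f"expected exactly one control arm, found {len(controls)}")
    return controls[0]


# --------------------------------------------------------------------------
# Patient records
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientRecord:
    """One enrolled subject.

    Calendar time is integer days from trial start (day 0); the "present" of
    any analysis is always an explicit ``analysis_day`` argument elsewhere,
    never wall-clock.  ``pcr`` is None either because the outcome has not
    been assessed yet (pending) or because the record has not yet passed the
    evaluability filter.
    """

    patient_id: str
    rand_day: int
    arm_id: str
    hr: bool
    her2: bool
    mp2: bool
    received_treatment: bool = True
    switched_nonprotocol: bool = False
    withdrew: bool = False
    surgery_day: Optional[int] = None
    pcr: Optional[int] = None
    ftv: tuple[tuple[int, float], ...] = ()
    markers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.surgery_day is not None and self.surgery_day < self.rand_day:
            raise ValueError(
                f"patient {self.patient_id}: surgery_day {self.surgery_day} "
                f"precedes rand_day {self.rand_day}"
            )
        days = [d for d, _ in self.ftv]
        if any(b < a for a, b in zip(days, days[1:])):
            raise ValueError(f"patient {self.patient_id}: FTV days not nondecreasing")
        if any(v < 0 for _, v in self.ftv):
            raise ValueError(f"patient {self.patient_id}: negative FTV volume")
        if self.pcr is not None and self.pcr not in (0, 1):
            raise ValueError(f"patient {self.patient_id}: pcr must be 0/1 or empty")

    @property
    def subtype(self) -> Subtype:
        return Subtype(self.hr, self.her2, self.mp2)


# --------------------------------------------------------------------------
# Delimited I/O
# --------------------------------------------------------------------------

_MANDATORY = [
    "patient_id", "rand_day", "arm_id", "hr", "her2", "mp2",
    "received_treatment", "switched_nonprotocol", "withdrew",
    "surgery_day", "pcr", "ftv_days", "ftv_volumes",
]


class SchemaError(ValueError):
    pass


class RowError(ValueError):
    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


def _parse_bool(s: str, what: str, row: int) -> bool:
    if s in ("0", "1"):
        return s == "1"
    raise RowError(row, f"{what} must be 0/1, got {s!r}")


def read_patients(path, arms: Optional[Sequence[ArmSpec]] = None) -> list[PatientRecord]:
    """Read patient records from a CSV file.

    Booleans are 0/1; missing optional fields are empty strings; the FTV
    series is a pair of semicolon-joined columns (days, volumes); marker
    expression values live in ``marker_<name>`` columns.  Malformed rows
    raise :class:`RowError` naming the 1-based data row.
    """
    arm_ids = {a.arm_id for a in arms} if arms is not None else None
    records: list[PatientRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError("empty file: header row required")
        missing = [c for c in _MANDATORY if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
        marker_cols = [c for c in reader.fieldnames if c.startswith("marker_")]
        for i, row in enumerate(reader, start=1):
            try:
                arm_id = row["arm_id"]
                if arm_ids is not None and arm_id not in arm_ids:
                    raise RowError(i, f"unknown arm_id {arm_id!r}")
                ftv_days = row["ftv_days"].strip()
                ftv_vols = row["ftv_volumes"].strip()
                ftv: tuple[tuple[int, float], ...] = ()
                if ftv_days:
                    days = [int(x) for x in ftv_days.split(";")]
                    try:
                        vols = [float(x) for x in ftv_vols.split(";")]
                    except ValueError as e:
                        raise RowError(i, f"non-numeric FTV volume: {e}") from None
                    if len(days) != len(vols):
                        raise RowError(i, "ftv_days and ftv_volumes length mismatch")
                    ftv = tuple(zip(days, vols))
                markers = {
                    c[len("marker_"):]: float(row[c])
                    for c in marker_cols
                    if row[c].strip() != ""
                }
                rec = PatientRecord(
                    patient_id=row["patient_id"],
                    rand_day=int(row["rand_day"]),
                    arm_id=arm_id,
                    hr=_parse_bool(row["hr"], "hr", i),
                    her2=_parse_bool(row["her2"], "her2", i),
                    mp2=_parse_bool(row["mp2"], "mp2", i),
                    received_treatment=_parse_bool(row["received_treatment"], "received_treatment", i),
                    switched_nonprotocol=_parse_bool(row["switched_nonprotocol"], "switched_nonprotocol", i),
                    withdrew=_parse_bool(row["withdrew"], "withdrew", i),
                    surgery_day=int(row["surgery_day"]) if row["surgery_day"].strip() else None,
                    pcr=int(row["pcr"]) if row["pcr"].strip() else None,
                    ftv=ftv,
                    markers=markers,
                )
            except RowError:
                raise
            except (ValueError, KeyError) as e:
                raise RowError(i, str(e)) from None
            records.append(rec)
    return records


def write_patients(path, patients: Sequence[PatientRecord]) -> None:
    """Write records to CSV; inverse of :func:`read_patients`."""
    marker_names = sorted({m for p in patients for m in p.markers})
    cols = _MANDATORY + [f"marker_{m}" for m in marker_names]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for p in patients:
            row = [
                p.patient_id, p.rand_day, p.arm_id,
                int(p.hr), int(p.her2), int(p.mp2),
                int(p.received_treatment), int(p.switched_nonprotocol), int(p.withdrew),
                "" if p.surgery_day is None else p.surgery_day,
                "" if p.pcr is None else p.pcr,
                ";".join(str(d) for d, _ in p.ftv),
                ";".join(repr(v) for _, v in p.ftv),
            ]
            row += ["" if m not in p.markers else repr(p.markers[m]) for m in marker_names]
            w.writerow(row)


# --------------------------------------------------------------------------
# Modified intent-to-treat evaluability filter
# --------------------------------------------------------------------------

@dataclass
class EvaluabilityAudit:
    """Counts of how the modified-ITT rules were applied."""

    n_input: int = 0
    n_dropped_untreated: int = 0
    n_coded_switched: int = 0
    n_coded_withdrew: int = 0
    n_coded_no_surgery: int = 0
    n_observed: int = 0
    n_pending: int = 0

    @property
    def n_evaluable(self) -> int:
        return self.n_input - self.n_dropped_untreated

    @property
    def n_coded(self) -> int:
        return self.n_coded_switched + self.n_coded_withdrew + self.n_coded_no_surgery


def evaluability_filter(
    patients: Iterable[PatientRecord],
) -> tuple[list[PatientRecord], EvaluabilityAudit]:
    """Apply the modified intent-to-treat rule.

    Patients who never received allocated therapy are dropped.  Retained
    patients who switched to non-protocol therapy, withdrew, or have no
    surgery day are coded non-pCR (pcr=0), overriding any recorded outcome
    for protocol deviations.  Patients with a surgery day and an observed
    outcome keep it; the remainder (surgery pending, no deviation) are left
    pending (pcr None) — a valid interim state, never silently coded.

    Idempotent: filtering a filtered list is a no-op.
    """
    out: list[PatientRecord] = []
    audit = EvaluabilityAudit()
    for p in patients:
        audit.n_input += 1
        if not p.received_treatment:
            audit.n_dropped_untreated += 1
            continue
        if p.switched_nonprotocol:
            audit.n_coded_switched += 1
            out.append(replace(p, pcr=0))
        elif p.withdrew:
            audit.n_coded_withdrew += 1
            out.append(replace(p, pcr=0))
        elif p.surgery_day is None:
            audit.n_coded_no_surgery += 1
            out.append(replace(p, pcr=0))
        elif p.pcr is not None:
            audit.n_observed += 1
            out.append(p)
        else:
            audit.n_pending += 1
            out.append(p)
    return out, audit


def signature_members(
    sig: Signature, patients: Sequence[PatientRecord]
) -> list[PatientRecord]:
    """Patients whose subtype lies in the signature, in stable input order."""
    return [p for p in patients if sig.contains(p.subtype)]
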