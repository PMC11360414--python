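"""Domain types and class-boundary conventions for skin sensitization potency.

Everything downstream hinges on the murine Local Lymph Node Assay (LLNA) EC3
value: the interpolated concentration (in %) at which lymph node cell
proliferation reaches three times the vehicle control.  Lower EC3 means a
more potent sensitizer.  Non-sensitizers carry the conventional stand-in
EC3 of 100%.

Three nested categorical scales are defined on top of EC3:

* four potency classes -- NS < weak < moderate < strong/extreme,
* the UN GHS categories -- No Cat. / Cat. 1B / Cat. 1A,
* binary hazard -- NS / S,

with the coarser scales obtained by merging classes of the finer one, so a
prediction made on the 4-class scale collapses consistently all the way down
to hazard.

Boundary conventions (where published definitions disagree at the edges):
EC3 exactly 2% is strong/extreme, because GHS Cat. 1A is defined by
EC3 <= 2% and the 4-class scale must collapse consistently into GHS;
EC3 exactly 100% from a *positive* LLNA is weak (weak covers [10, 100]),
while NS is reserved for the explicit non-sensitizer flag, since 100 is
otherwise only the stand-in convention.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PotencyClass",
    "GHSCategory",
    "HazardClass",
    "NamInputs",
    "SubstanceRecord",
    "PoDWeights",
    "ValidationError",
    "UnknownReferenceError",
    "ec3_to_potency_class",
    "collapse_to_ghs",
    "collapse_to_hazard",
    "INPUT_FIELD_NAMES",
    "QUANTITATIVE_FIELDS",
    "CATEGORICAL_FIELDS",
    "read_substances_csv",
    "write_substances_csv",
]


class ValidationError(ValueError):
    """Raised when a domain object or input value violates its contract."""


class UnknownReferenceError(ValidationError):
    """Raised when a reference potency class is requested but no usable
    LLNA reference (EC3 / sensitizer flag) is available."""


class PotencyClass(enum.IntEnum):
    """The 4-class LLNA potency scale, ordered from least to most potent."""

    NS = 0
    WEAK = 1
    MODERATE = 2
    STRONG_EXTREME = 3

    @property
    def label(self) -> str:
        return _POTENCY_LABELS[self]

    @classmethod
    def from_label(cls, label: str) -> "PotencyClass":
        try:
            return _POTENCY_FROM_LABEL[label]
        except KeyError:
            raise ValidationError(f"unknown potency class label {label!r}") from None


_POTENCY_LABELS = {
    PotencyClass.NS: "NS",
    PotencyClass.WEAK: "weak",
    PotencyClass.MODERATE: "moderate",
    PotencyClass.STRONG_EXTREME: "strong_extreme",
}
_POTENCY_FROM_LABEL = {v: k for k, v in _POTENCY_LABELS.items()}


class GHSCategory(enum.IntEnum):
    """UN GHS skin sensitization categories, ordered by severity."""

    NO_CAT = 0
    CAT_1B = 1
    CAT_1A = 2

    @property
    def label(self) -> str:
        return _GHS_LABELS[self]


_GHS_LABELS = {
    GHSCategory.NO_CAT: "NoCat",
    GHSCategory.CAT_1B: "Cat1B",
    GHSCategory.CAT_1A: "Cat1A",
}


class HazardClass(enum.IntEnum):
    """Binary skin sensitization hazard."""

    NS = 0
    S = 1

    @property
    def label(self) -> str:
        return "NS" if self is HazardClass.NS else "S"


def ec3_to_potency_class(ec3: Optional[float], is_sensitizer: bool) -> PotencyClass:
    """Map an LLNA result to its 4-class potency category.

    Non-sensitizers map to NS regardless of the (conventional) EC3 of 100.
    For sensitizers: EC3 <= 2 -> strong/extreme, 2 < EC3 < 10 -> moderate,
    EC3 >= 10 -> weak.
    """
    if not is_sensitizer:
        return PotencyClass.NS
    if ec3 is None or (isinstance(ec3, float) and math.isnan(ec3)):
        raise UnknownReferenceError("sensitizer without an EC3 value")
    ec3 = float(ec3)
    if ec3 <= 0 or ec3 > 100:
        raise ValidationError(f"EC3 must lie in (0, 100], got {ec3}")
    if ec3 <= 2:
        return PotencyClass.STRONG_EXTREME
    if ec3 < 10:
        return PotencyClass.MODERATE
    return PotencyClass.WEAK


_GHS_COLLAPSE = {
    PotencyClass.NS: GHSCategory.NO_CAT,
    PotencyClass.WEAK: GHSCategory.CAT_1B,
    PotencyClass.MODERATE: GHSCategory.CAT_1B,
    PotencyClass.STRONG_EXTREME: GHSCategory.CAT_1A,
}


def collapse_to_ghs(potency: PotencyClass) -> GHSCategory:
    """Merge the 4-class scale into UN GHS: weak and moderate become Cat. 1B."""
    return _GHS_COLLAPSE[PotencyClass(potency)]


def collapse_to_hazard(potency: PotencyClass) -> HazardClass:
    """Merge the 4-class scale into binary hazard: anything but NS is S."""
    return HazardClass.NS if PotencyClass(potency) is PotencyClass.NS else HazardClass.S


# The default 13-input roster: 3 physico-chemical descriptors, 2 in-silico
# calls, 2 DPRA depletions, 3 KeratinoSens summaries, 3 U-SENS summaries.
QUANTITATIVE_FIELDS = (
    "mw",
    "clogp",
    "dpra_cys_depletion",
    "dpra_lys_depletion",
    "ks_ec15",
    "ks_ic50",
    "ks_imax",
    "usens_ec150",
    "usens_cv70",
)
CATEGORICAL_FIELDS = ("volatility", "times_ss_call", "toxtree_domain", "usens_call")
INPUT_FIELD_NAMES = (
    "mw",
    "clogp",
    "volatility",
    "times_ss_call",
    "toxtree_domain",
    "dpra_cys_depletion",
    "dpra_lys_depletion",
    "ks_ec15",
    "ks_ic50",
    "ks_imax",
    "usens_ec150",
    "usens_cv70",
    "usens_call",
)

# (low, high, low_inclusive, high_inclusive) for quantitative inputs;
# None = unbounded on that side.
_RANGES = {
    "mw": (0.0, None, False, True),
    "clogp": (None, None, False, False),
    "dpra_cys_depletion": (0.0, 100.0, True, True),
    "dpra_lys_depletion": (0.0, 100.0, True, True),
    "ks_ec15": (0.0, None, False, True),
    "ks_ic50": (0.0, None, False, True),
    "ks_imax": (1.0, None, True, True),
    "usens_ec150": (0.0, None, False, True),
    "usens_cv70": (0.0, None, False, True),
}


@dataclass
class NamInputs:
    """One substance's NAM and physico-chemical inputs.

    ``None`` means missing or inconclusive; such entries enter the network as
    absent evidence.  Units: mw in Da, clogp unitless (log10 octanol-water
    partition coefficient), DPRA depletions in % [0, 100], KeratinoSens
    EC1.5/IC50 in uM, Imax as fold induction >= 1, U-SENS EC150/CV70 in
    ug/mL.  Volatility is an ordinal category; TIMES-SS, ToxTree reactivity
    domain and the U-SENS call are categorical labels.
    """

    mw: Optional[float] = None
    clogp: Optional[float] = None
    volatility: Optional[str] = None
    times_ss_call: Optional[str] = None
    toxtree_domain: Optional[str] = None
    dpra_cys_depletion: Optional[float] = None
    dpra_lys_depletion: Optional[float] = None
    ks_ec15: Optional[float] = None
    ks_ic50: Optional[float] = None
    ks_imax: Optional[float] = None
    usens_ec150: Optional[float] = None
    usens_cv70: Optional[float] = None
    usens_call: Optional[str] = None

    def __post_init__(self) -> None:
        for name, (lo, hi, lo_inc, hi_inc) in _RANGES.items():
            value = getattr(self, name)
            if value is None:
                continue
            if isinstance(value, float) and math.isnan(value):
                setattr(self, name, None)
                continue
            value = float(value)
            setattr(self, name, value)
            if lo is not None and (value < lo or (value == lo and not lo_inc)):
                raise ValidationError(f"{name}={value} below valid range")
            if hi is not None and (value > hi or (value == hi and not hi_inc)):
                raise ValidationError(f"{name}={value} above valid range")

    def present_fields(self) -> tuple[str, ...]:
        return tuple(
            name for name in INPUT_FIELD_NAMES if getattr(self, name) is not None
        )

    @property
    def is_predictable(self) -> bool:
        """At least one input present -- the minimum for a prediction."""
        return len(self.present_fields()) > 0


@dataclass
class SubstanceRecord:
    """A substance's inputs plus (optionally) its LLNA reference.

    If ``is_sensitizer`` is explicitly False, ``ec3`` is stored as the
    conventional 100%.  When only an EC3 is given, ``ec3 == 100`` is read as
    the non-sensitizer convention and anything below 100 as a positive LLNA.
    """

    substance_id: str
    inputs: NamInputs = field(default_factory=NamInputs)
    ec3: Optional[float] = None
    is_sensitizer: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.ec3 is not None:
            if isinstance(self.ec3, float) and math.isnan(self.ec3):
                self.ec3 = None
            else:
                self.ec3 = float(self.ec3)
                if self.ec3 <= 0 or self.ec3 > 100:
                    raise ValidationError(
                        f"{self.substance_id}: EC3 must lie in (0, 100], got {self.ec3}"
                    )
        if self.is_sensitizer is False:
            self.ec3 = 100.0

    @property
    def has_reference(self) -> bool:
        return self.is_sensitizer is not None or self.ec3 is not None

    def reference_class(self) -> PotencyClass:
        """The LLNA reference potency class of this substance."""
        if self.is_sensitizer is not None:
            return ec3_to_potency_class(self.ec3, self.is_sensitizer)
        if self.ec3 is None:
            raise UnknownReferenceError(
                f"{self.substance_id}: no EC3 or sensitizer flag available"
            )
        if self.ec3 == 100.0:
            return PotencyClass.NS  # stand-in convention
        return ec3_to_potency_class(self.ec3, True)


@dataclass(frozen=True)
class PoDWeights:
    """Class weights (in % concentration) for the weighted-sum PoD.

    Each weight is the EC3-scale anchor of its class: 100 for a negative
    LLNA, 10 the lowest weak EC3, 2 the Cat. 1A/1B boundary, 0.2 a
    representative strong/extreme value.
    """

    w_ns: float = 100.0
    w_weak: float = 10.0
    w_moderate: float = 2.0
    w_strong: float = 0.2

    def __post_init__(self) -> None:
        w = self.as_array()
        if not np.all(w > 0):
            raise ValidationError("PoD weights must be strictly positive")
        if not np.all(np.diff(w) < 0):
            raise ValidationError("PoD weights must strictly decrease with potency")

    def as_array(self) -> np.ndarray:
        return np.array([self.w_ns, self.w_weak, self.w_moderate, self.w_strong])


# ---------------------------------------------------------------------------
# substance CSV dialect
# ---------------------------------------------------------------------------

CSV_COLUMNS = ("substance_id",) + INPUT_FIELD_NAMES + ("ec3", "is_sensitizer")

_BOOL_FROM_STR = {
    "true": True,
    "false": False,
    "1": True,
    "0": False,
    "yes": True,
    "no": False,
}


def _parse_float(text: str, column: str, line: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise ValidationError(
            f"line {line}: column {column!r}: cannot parse {text!r} as a number"
        ) from None


def read_substances_csv(path) -> list[SubstanceRecord]:
    """Read the substance CSV dialect (empty cell = missing/inconclusive).

    Raises :class:`ValidationError` with line numbers for unparseable rows.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "substance_id" not in frame.columns:
        raise ValidationError("substance CSV must have a 'substance_id' column")
    records: list[SubstanceRecord] = []
    for pos, row in enumerate(frame.itertuples(index=False)):
        line = pos + 2  # header is line 1
        values = dict(zip(frame.columns, row))
        kwargs: dict[str, object] = {}
        for name in INPUT_FIELD_NAMES:
            text = values.get(name, "").strip()
            if not text:
                continue
            if name in QUANTITATIVE_FIELDS:
                kwargs[name] = _parse_float(text, name, line)
            else:
                kwargs[name] = text
        ec3_text = values.get("ec3", "").strip()
        ec3 = _parse_float(ec3_text, "ec3", line) if ec3_text else None
        sens_text = values.get("is_sensitizer", "").strip().lower()
        if sens_text:
            if sens_text not in _BOOL_FROM_STR:
                raise ValidationError(
                    f"line {line}: is_sensitizer must be true/false, got {sens_text!r}"
                )
            is_sensitizer: Optional[bool] = _BOOL_FROM_STR[sens_text]
        else:
            is_sensitizer = None
        try:
            records.append(
                SubstanceRecord(
                    substance_id=str(values["substance_id"]),
                    inputs=NamInputs(**kwargs),
                    ec3=ec3,
                    is_sensitizer=is_sensitizer,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"line {line}: {exc}") from None
    return records


def _format_value(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)  # shortest exact round-trip representation
    return str(value)


def write_substances_csv(records: Iterable[SubstanceRecord], path) -> None:
    """Write records in the same CSV dialect ``read_substances_csv`` reads."""
    rows = []
    for rec in records:
        row = {"substance_id": rec.substance_id}
        for name in INPUT_FIELD_NAMES:
            row[name] = _format_value(getattr(rec.inputs, name))
        row["ec3"] = _format_value(rec.ec3)
        row["is_sensitizer"] = _format_value(rec.is_sensitizer)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    frame.to_csv(path, index=False)
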