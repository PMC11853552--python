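"""Cohort schema: variable names, label vocabulary, physical domains.

A cohort is a :class:`pandas.DataFrame` with one row per patient, the eleven
continuous clinical variables below, and a videourodynamics-derived lower
urinary tract dysfunction (LUTD) label. The bladder-outlet-obstruction (BOO)
group pools bladder neck dysfunction (BND) and benign prostatic obstruction
(BPO); every other label is non-BOO.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

from .errors import InputError

#: The eight videourodynamic LUTD diagnoses.
LUTD_LABELS: tuple[str, ...] = (
    "BND",      # bladder neck dysfunction
    "BPO",      # benign prostatic obstruction
    "PRES",     # poor relaxation of the external sphincter
    "DV",       # dysfunctional voiding
    "STABLE",   # stable (normal) bladder without BOO
    "DO",       # detrusor overactivity without BOO
    "HSB",      # hypersensitive bladder
    "DU",       # detrusor underactivity
)

#: Labels forming the obstructed (BOO) group; the rest are non-BOO.
BOO_LABELS: frozenset[str] = frozenset({"BND", "BPO"})

#: Continuous clinical variables, in canonical column order.
CONTINUOUS_VARS: tuple[str, ...] = (
    "age",            # years
    "ipss_voiding",   # IPSS voiding subscore, 0-20
    "ipss_storage",   # IPSS storage subscore, 0-15
    "ipss_vs",        # IPSS voiding/storage ratio, >= 0
    "qmax",           # maximum urinary flow rate, mL/s
    "voided_volume",  # mL
    "pvr",            # post-void residual, mL
    "tpv",            # total prostate volume, mL
    "tzi",            # transition-zone index, fraction of TPV in [0, 1]
    "ipp",            # intravesical prostatic protrusion, cm
    "puv_angle",      # prostatic urethrovesical angle, degrees
)

LABEL_COLUMN = "lutd_label"

#: Canonical cohort CSV header.
COHORT_COLUMNS: tuple[str, ...] = CONTINUOUS_VARS + (LABEL_COLUMN,)

#: Hard physical domain per variable (closed bounds); values outside are
#: rejected on read. These are wider than the generator's default truncation.
PHYSICAL_DOMAIN: dict[str, tuple[float, float]] = {
    "age": (0.0, 130.0),
    "ipss_voiding": (0.0, 20.0),
    "ipss_storage": (0.0, 15.0),
    "ipss_vs": (0.0, math.inf),
    "qmax": (0.0, math.inf),
    "voided_volume": (0.0, math.inf),
    "pvr": (0.0, math.inf),
    "tpv": (0.0, math.inf),
    "tzi": (0.0, 1.0),
    "ipp": (0.0, math.inf),
    "puv_angle": (0.0, 180.0),
}


@dataclass
class PatientRecord:
    """One subject's clinical variables plus the VUDS-derived LUTD label."""

    age: float
    ipss_voiding: float
    ipss_storage: float
    ipss_vs: float
    qmax: float
    voided_volume: float
    pvr: float
    tpv: float
    tzi: float
    ipp: float
    puv_angle: float
    lutd_label: str

    def validate(self) -> "PatientRecord":
        for f in fields(self):
            if f.name == LABEL_COLUMN:
                continue
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise InputError(f"{f.name} must be finite, got {v!r}")
            lo, hi = PHYSICAL_DOMAIN[f.name]
            if not (lo <= v <= hi):
                raise InputError(f"{f.name}={v!r} outside physical range [{lo}, {hi}]")
        if self.lutd_label not in LUTD_LABELS:
            raise InputError(
                f"unknown lutd_label {self.lutd_label!r}; expected one of {LUTD_LABELS}"
            )
        return self


def group_of(label: str) -> str:
    """Map an LUTD label to its obstruction group, ``"BOO"`` or ``"non-BOO"``."""
    if label not in LUTD_LABELS:
        raise InputError(f"unknown lutd_label {label!r}")
    return "BOO" if label in BOO_LABELS else "non-BOO"
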