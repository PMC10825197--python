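"""Accuracy metrics: absolute error in milliHartree and relative accuracy.

Chemical accuracy is 1 kcal/mol = 1.594 mHa.  Relative accuracy is defined
as 100 (1 - |dE| / |E_ref|) percent, the unique simple form consistent with
published error/accuracy pairs for these systems.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

CHEMICAL_ACCURACY_MHA = 1.594

__all__ = ["CHEMICAL_ACCURACY_MHA", "abs_error_mha", "relative_accuracy",
           "AccuracyReport"]


def abs_error_mha(e_method: float, e_reference: float) -> float:
    """|E_method - E_ref| in mHa, reported to 3 decimals."""
    return round(abs(e_method - e_reference) * 1000.0, 3)


def relative_accuracy(e_method: float, e_reference: float) -> float:
    """100 (1 - |dE|/|E_ref|) percent, reported to 5 decimals."""
    if e_reference == 0.0:
        raise ZeroDivisionError("relative accuracy undefined for zero reference")
    return round(100.0 * (1.0 - abs(e_method - e_reference) / abs(e_reference)), 5)


@dataclass(frozen=True)
class AccuracyReport:
    method: str
    reference: str
    e_method: float
    e_reference: float

    @property
    def abs_error_mHa(self) -> float:
        return abs_error_mha(self.e_method, self.e_reference)

    @property
    def relative_accuracy_pct(self) -> float:
        return relative_accuracy(self.e_method, self.e_reference)

    @property
    def chemically_accurate(self) -> bool:
        return self.abs_error_mHa <= CHEMICAL_ACCURACY_MHA

    def to_json(self, indent: int = 2) -> str:
        payload = asdict(self)
        payload["e_method"] = round(self.e_method, 12)
        payload["e_reference"] = round(self.e_reference, 12)
        payload["abs_error_mHa"] = self.abs_error_mHa
        payload["relative_accuracy_pct"] = self.relative_accuracy_pct
        payload["chemically_accurate"] = self.chemically_accurate
        return json.dumps(payload, indent=indent)
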