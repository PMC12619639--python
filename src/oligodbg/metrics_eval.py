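"""Precision / recall evaluation of reconstructed sequences.

Correctness is exact full-length string equality against the reference set;
both inputs are deduplicated first, so the metrics are set ratios. Raw
precision ignores any embedded checksum; final precision is the same ratio
restricted to outputs whose CRC field validates.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterable, Optional

from .codec_sim import OligoStructure, validate_crc
from .primer_anchor import PrimerScheme


@dataclasses.dataclass
class EvalReport:
    n_outputs: int
    n_references: int
    n_matched: int
    n_crc_valid: int
    n_crc_valid_matched: int
    raw_precision: float
    final_precision: Optional[float]
    recall: float
    empty_outputs: bool
    empty_crc_valid: bool

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


def _pct(num: int, den: int) -> float:
    return 100.0 * num / den if den else 0.0


def evaluate(
    outputs: Iterable[str],
    references: Iterable[str],
    scheme: Optional[PrimerScheme] = None,
    structure: Optional[OligoStructure] = None,
) -> EvalReport:
    """Compute raw precision, recall and (optionally) CRC-checked precision.

    ``final_precision`` is only computed when both a primer scheme and a
    field-width structure are supplied; it is the fraction of CRC-valid
    outputs that match a reference. Empty denominators report 0 with a flag.
    """
    out = set(outputs)
    ref = set(references)
    matched = out & ref
    report_final = scheme is not None and structure is not None
    if report_final:
        crc_valid = {s for s in out if validate_crc(s, scheme, structure)}
    else:
        crc_valid = set()
    crc_valid_matched = crc_valid & ref
    return EvalReport(
        n_outputs=len(out),
        n_references=len(ref),
        n_matched=len(matched),
        n_crc_valid=len(crc_valid),
        n_crc_valid_matched=len(crc_valid_matched),
        raw_precision=_pct(len(matched), len(out)),
        final_precision=_pct(len(crc_valid_matched), len(crc_valid))
        if report_final
        else None,
        recall=_pct(len(matched), len(ref)),
        empty_outputs=not out,
        empty_crc_valid=report_final and not crc_valid,
    )
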