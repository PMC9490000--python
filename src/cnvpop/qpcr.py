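"""qPCR copy-number estimation (2^-ddCt) and concordance with sequencing calls.

Relative quantification: dCt = Ct(target) - Ct(reference gene) per sample;
ddCt = dCt(sample) - dCt(calibrator); relative quantity = 2^-ddCt. Scaling
by the calibrator's copy number (2 for a diploid reference sample) turns
the fold change into an absolute copy-number estimate. Amplification
efficiency is assumed to be 2.0 per cycle, as the method requires.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .errors import InputDataError

__all__ = [
    "QPCRRecord",
    "read_ct_table",
    "ddct_copy_number",
    "copy_number_table",
    "concordance",
]


@dataclass(frozen=True)
class QPCRRecord:
    """Replicate-averaged Ct pair for one (sample, assay)."""

    sample: str
    assay: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for name, v in (("ct_target", self.ct_target), ("ct_reference", self.ct_reference)):
            if not (v > 0 and v == v and v != float("inf")):
                raise InputDataError(f"{self.sample}/{self.assay}: {name} must be finite and > 0")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


def read_ct_table(path) -> list[QPCRRecord]:
    """TSV ``sample assay replicate ct_target ct_reference``.

    Technical replicates are averaged (mean Ct) before any delta is taken,
    so the estimate is invariant to replicate order.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample", "assay", "ct_target", "ct_reference"}
    missing = required - set(df.columns)
    if missing:
        raise InputDataError(f"{path}: missing columns {sorted(missing)}")
    grouped = df.groupby(["sample", "assay"], sort=True)[["ct_target", "ct_reference"]].mean()
    return [
        QPCRRecord(sample=s, assay=a, ct_target=float(row["ct_target"]),
                   ct_reference=float(row["ct_reference"]))
        for (s, a), row in grouped.iterrows()
    ]


def ddct_copy_number(
    record: QPCRRecord,
    calibrator: QPCRRecord,
    reference_copy_number: float = 2.0,
) -> float:
    """Copy number = reference_copy_number * 2^-(dCt_sample - dCt_calibrator)."""
    if record.assay != calibrator.assay:
        raise InputDataError(
            f"assay mismatch: {record.assay!r} vs calibrator {calibrator.assay!r}"
        )
    ddct = record.delta_ct - calibrator.delta_ct
    return reference_copy_number * 2.0 ** (-ddct)


def copy_number_table(
    records: Sequence[QPCRRecord],
    calibrator_sample: str,
    reference_copy_number: float = 2.0,
) -> pd.DataFrame:
    """Per (sample, assay) copy-number estimates against a named calibrator."""
    calibrators = {r.assay: r for r in records if r.sample == calibrator_sample}
    if not calibrators:
        raise InputDataError(f"calibrator sample {calibrator_sample!r} not in table")
    rows = []
    for r in records:
        cal = calibrators.get(r.assay)
        if cal is None:
            raise InputDataError(f"no calibrator measurement for assay {r.assay!r}")
        rows.append(
            {
                "sample": r.sample,
                "assay": r.assay,
                "delta_ct": r.delta_ct,
                "ddct": r.delta_ct - cal.delta_ct,
                "copy_number": ddct_copy_number(r, cal, reference_copy_number),
            }
        )
    return pd.DataFrame(rows, columns=["sample", "assay", "delta_ct", "ddct", "copy_number"])


def concordance(
    estimates: pd.DataFrame,
    predicted: Mapping[tuple[str, str], str],
    gain_cutoff: float = 2.5,
    loss_cutoff: float = 1.5,
) -> pd.DataFrame:
    """Classify qPCR estimates (GAIN > 2.5, LOSS < 1.5, else NORMAL) and
    mark agreement with sequencing-based states per (sample, assay)."""
    rows = []
    for row in estimates.itertuples(index=False):
        cn = row.copy_number
        state = "GAIN" if cn > gain_cutoff else ("LOSS" if cn < loss_cutoff else "NORMAL")
        key = (row.sample, row.assay)
        if key not in predicted:
            continue
        rows.append(
            {
                "sample": row.sample,
                "assay": row.assay,
                "copy_number": cn,
                "qpcr_state": state,
                "predicted_state": predicted[key],
                "agree": state == predicted[key],
            }
        )
    return pd.DataFrame(
        rows,
        columns=["sample", "assay", "copy_number", "qpcr_state", "predicted_state", "agree"],
    )
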