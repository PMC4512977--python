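"""Reference diagnostic-performance table for internal-consistency checks.

One row per true-change threshold of a published EELV change-detection
analysis comparing |delta EELV_WI-WO| against CT-confirmed changes: AUC
with 95% CI, the Youden-optimal washin-washout cutoff, and the full
confusion-derived metrics.  The rows are used to verify that the
cutpoint-metric identities (Youden = Se + Sp - 1, NLR = (1 - Se)/Sp)
reproduce the reported columns from the reported Se/Sp pairs — a check
that the implementation matches the field's conventions, independent of
any simulated data.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ReferenceCutpointRow:
    """One reported row: threshold (mL), AUC (CI), cutoff (mL), metrics."""

    threshold: float
    auc: float
    auc_ci: tuple[float, float]
    cutoff: float
    se: float
    sp: float
    ppv: float
    npv: float
    plr: float
    nlr: float
    youden: float


_ROWS = (
    ReferenceCutpointRow(100.0, 0.58, (0.50, 0.66), 42.0, 0.84, 0.33, 0.57, 0.66, 1.25, 0.48, 0.17),
    ReferenceCutpointRow(150.0, 0.73, (0.64, 0.81), 166.0, 0.65, 0.75, 0.46, 0.87, 2.61, 0.47, 0.40),
    ReferenceCutpointRow(200.0, 0.79, (0.70, 0.89), 166.0, 0.80, 0.75, 0.42, 0.94, 3.26, 0.27, 0.55),
    ReferenceCutpointRow(250.0, 0.87, (0.79, 0.94), 169.0, 0.90, 0.77, 0.41, 0.97, 3.89, 0.13, 0.67),
    ReferenceCutpointRow(300.0, 0.89, (0.83, 0.95), 169.0, 0.93, 0.77, 0.41, 0.98, 4.05, 0.09, 0.70),
)


def printed_cutpoint_rows() -> tuple[ReferenceCutpointRow, ...]:
    """The reference change-detection table, one row per threshold."""
    return _ROWS
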