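"""Cell-level inclusion gates and regular-spiking classification.

Cells are excluded when the baseline resting membrane potential is more
depolarized than -50 mV or the uncompensated series resistance exceeds
35 MΩ — strict inequalities, so boundary values pass.  Putative
intratelencephalic pyramidal cells are kept when they co-express a
regular-spiking firing pattern and a physiology index below 5.

"Regular spiking" is not formally defined by the source workflow; the
operational surrogate here is the absence of an initial doublet (first
interspike interval at least half the median interval on a suprathreshold
step) together with no depolarization-block signature at moderate currents.
Both pieces are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spikes import FICurve

__all__ = [
    "QCThresholds",
    "QCResult",
    "assess_cell_qc",
    "regular_spiking",
    "classify_cell",
    "finalize_qc",
]


@dataclass(frozen=True)
class QCThresholds:
    rmp_max: float = -50.0  # mV; fail iff rmp > rmp_max
    rs_max: float = 35.0  # MΩ; fail iff r_s > rs_max
    physiology_index_max: float = 5.0  # fail iff index >= this (gate is "< 5")
    doublet_ratio: float = 0.5  # first ISI must be >= ratio x median ISI

    def __post_init__(self) -> None:
        if self.rmp_max >= 0:
            raise ValueError("rmp_max must be negative (mV)")
        if self.rs_max <= 0:
            raise ValueError("rs_max must be positive (MΩ)")


@dataclass
class QCResult:
    cell_id: str
    rmp: float
    r_s: float
    physiology_index: float | None = None
    regular_spiking: bool | None = None
    failed_checks: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.failed_checks


def assess_cell_qc(
    cell_id: str, rmp: float, r_s: float, thresholds: QCThresholds | None = None
) -> QCResult:
    """Recording-quality gates on RMP and series resistance (strict inequalities)."""
    thresholds = thresholds or QCThresholds()
    result = QCResult(cell_id=cell_id, rmp=rmp, r_s=r_s)
    if rmp > thresholds.rmp_max:
        result.failed_checks.append("rmp")
    if r_s > thresholds.rs_max:
        result.failed_checks.append("rs")
    return result


def regular_spiking(
    spike_times: np.ndarray,
    thresholds: QCThresholds | None = None,
    block_detected: bool = False,
) -> bool:
    """Initial-doublet surrogate for the regular-spiking firing pattern.

    ``spike_times`` should come from a suprathreshold step (nominally
    rheobase + 50 pA).  Trains of fewer than three spikes cannot exhibit a
    doublet and count as regular unless depolarization block was flagged.
    """
    thresholds = thresholds or QCThresholds()
    if block_detected:
        return False
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size < 3:
        return True
    isis = np.diff(spike_times)
    return bool(isis[0] >= thresholds.doublet_ratio * np.median(isis))


def classify_cell(
    fi: FICurve,
    spike_times: np.ndarray,
    physiology_index: float,
    thresholds: QCThresholds | None = None,
) -> tuple[bool, bool]:
    """(regular_spiking, included): include iff regular spiking and index < 5."""
    thresholds = thresholds or QCThresholds()
    rs = regular_spiking(spike_times, thresholds, block_detected=fi.block_detected)
    included = rs and physiology_index < thresholds.physiology_index_max
    return rs, included


def finalize_qc(
    result: QCResult,
    physiology_index: float,
    is_regular_spiking: bool,
    thresholds: QCThresholds | None = None,
) -> QCResult:
    """Fold the classification gates into a partial QC result."""
    thresholds = thresholds or QCThresholds()
    result.physiology_index = physiology_index
    result.regular_spiking = is_regular_spiking
    if physiology_index >= thresholds.physiology_index_max:
        result.failed_checks.append("physiology_index")
    if not is_regular_spiking:
        result.failed_checks.append("firing_pattern")
    return result
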