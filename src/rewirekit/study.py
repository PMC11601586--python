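"""Reported cohort metadata for the mouse smoke-exposure study.

Dataset A: C57BL/6J mice exposed to 6 months of room air or cigarette
smoke, four individually sequenced mice per arm.  The published retained
cell counts are recorded here so downstream reports can recompute the
cohort arithmetic (total retained cells and the per-mouse average) from
the per-arm numbers.
"""

from __future__ import annotations

DATASET_A_CELLS_AIR = 20_578
DATASET_A_CELLS_SMOKE = 19_055
DATASET_A_TOTAL_CELLS = 39_633
DATASET_A_MICE_PER_GROUP = 4
DATASET_A_PER_MOUSE_AVERAGE = 4_954


def total_retained_cells(air: int = DATASET_A_CELLS_AIR,
                         smoke: int = DATASET_A_CELLS_SMOKE) -> int:
    """Total retained cells = sum of the per-arm retained counts."""
    return int(air) + int(smoke)


def per_mouse_average(total: int | None = None,
                      n_mice: int = 2 * DATASET_A_MICE_PER_GROUP) -> int:
    """Average retained cells per mouse, rounded to the nearest integer."""
    if total is None:
        total = total_retained_cells()
    return int(round(total / n_mice))
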