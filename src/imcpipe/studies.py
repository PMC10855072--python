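"""Reported single-cell totals of the mouse PDAC reference study.

The pipeline was built against two imaging-mass-cytometry datasets of murine
pancreatic ductal adenocarcinoma: an orthotopic Panc02 model imaged at the
tumor core and margin, and the genetic KPC model (two mice). The raw images
are not publicly deposited; these per-compartment segmented-cell totals are
the published summary numbers and serve as arithmetic consistency inputs.
"""

from __future__ import annotations

#: segmented cells per compartment, orthotopic Panc02 model (8 core + 9 margin ROIs)
ORTHOTOPIC_CELL_COUNTS: dict[str, int] = {"core": 36_677, "margin": 41_439}

#: segmented cells per mouse, genetic KPC model (4 + 5 ROIs)
KPC_CELL_COUNTS: dict[str, int] = {"KPC1": 12_249, "KPC2": 14_612}


def compartment_percentages(counts: dict[str, int]) -> dict[str, float]:
    """Percent of all cells per compartment."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("counts must be positive")
    return {k: 100.0 * v / total for k, v in counts.items()}


def total_cells(counts: dict[str, int]) -> int:
    return sum(counts.values())
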