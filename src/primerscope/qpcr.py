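"""qPCR standard-curve efficiency.

For a dilution series, the quantification cycle Cq regresses linearly
on log10(template quantity) with negative slope; amplification
efficiency is E = (10^(-1/slope) - 1) x 100, so a slope of
-1/log10(2) ~ -3.32 (perfect doubling each cycle) gives 100%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["QpcrCurve", "pcr_efficiency"]


def pcr_efficiency(slope: float) -> float:
    """Amplification efficiency (%) from a standard-curve slope."""
    if not slope < 0:
        raise ValueError(
            f"dilution series slope must be negative, got {slope}"
        )
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


@dataclass(frozen=True)
class QpcrCurve:
    """A fitted Cq-vs-log10(quantity) standard curve."""

    slope: float

    @property
    def efficiency_pct(self) -> float:
        return pcr_efficiency(self.slope)
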