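"""Agreement statistics between estimated and reference walked distances.

Signed error is estimate minus reference; in percent mode it is scaled by
the reference. Summary statistics cover the absolute error (mean, sample
standard deviation, maximum, RMSE) and the Bland-Altman limits of
agreement, mean +/- 1.96 sd of the signed error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

LOA_FACTOR = 1.96


@dataclass(frozen=True)
class ErrorSummary:
    n: int
    mean_abs: float
    sd_abs: float
    max_abs: float
    rmse: float
    loa_low: float
    loa_high: float
    mode: str  # "absolute_m" or "percent"

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def error_summary(
    pairs: Iterable[Sequence[float]], mode: str = "absolute_m"
) -> ErrorSummary:
    """Summarize (reference, estimate) pairs.

    ``mode="percent"`` reports every statistic as a percentage of the
    reference; references must then be strictly positive.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        raise ValueError("no pairs to summarize")
    if mode not in ("absolute_m", "percent"):
        raise ValueError(f"unknown mode {mode!r}")
    ref, est = arr[:, 0], arr[:, 1]
    signed = est - ref
    if mode == "percent":
        if np.any(ref <= 0):
            raise ValueError("percent mode requires strictly positive references")
        signed = 100.0 * signed / ref
    abs_err = np.abs(signed)
    n = len(signed)
    sd_signed = float(np.std(signed, ddof=1)) if n > 1 else 0.0
    mean_signed = float(np.mean(signed))
    return ErrorSummary(
        n=n,
        mean_abs=float(np.mean(abs_err)),
        sd_abs=float(np.std(abs_err, ddof=1)) if n > 1 else 0.0,
        max_abs=float(np.max(abs_err)),
        rmse=float(np.sqrt(np.mean(signed**2))),
        loa_low=mean_signed - LOA_FACTOR * sd_signed,
        loa_high=mean_signed + LOA_FACTOR * sd_signed,
        mode=mode,
    )


def classify_error_band(abs_error_m: float, threshold_m: float = 30.0) -> str:
    """Band an absolute distance error as "low" or "high".

    The default 30 m threshold is a conservative minimal-detectable-change
    value for the six-minute walk distance. The boundary itself counts as
    low.
    """
    if abs_error_m < 0:
        raise ValueError("absolute error cannot be negative")
    return "low" if abs_error_m <= threshold_m else "high"
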