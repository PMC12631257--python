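"""Signal classification and ranking.

A drug–event pair is declared a signal only when all four
disproportionality methods agree, each at its conventional threshold:

* ROR:   a >= 3, ROR >= 3 and the lower 95% CI bound > 1
* PRR:   a >= 3, PRR >= 2 and the lower 95% CI bound > 1
* BCPNN: IC025 > 0
* EBGM:  EB05 > 2

All inequalities are evaluated on full-precision values (never on the
2-decimal display rounding), and any non-computable statistic fails its
flag with the reason recorded.  Requiring the intersection of the four
methods makes the combined criterion deliberately conservative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

from .dispro import DisproResult

__all__ = ["SignalThresholds", "evaluate_signal", "rank_signals"]


@dataclass(frozen=True)
class SignalThresholds:
    a_min: int = 3
    ror_min: float = 3.0
    ror_lo_min: float = 1.0  # strict >
    prr_min: float = 2.0
    prr_lo_min: float = 1.0  # strict >
    ic025_min: float = 0.0  # strict >
    ebgm05_min: float = 2.0  # strict >


DEFAULT_THRESHOLDS = SignalThresholds()


def _gt(value: float, bound: float) -> bool:
    return not math.isnan(value) and value > bound


def _ge(value: float, bound: float) -> bool:
    return not math.isnan(value) and value >= bound


def evaluate_signal(
    result: DisproResult, thresholds: SignalThresholds = DEFAULT_THRESHOLDS
) -> DisproResult:
    """Return a copy of ``result`` with per-method flags and the combined flag set."""
    a_ok = result.n_reports >= thresholds.a_min
    flags = {
        "ror": a_ok
        and _ge(result.ror, thresholds.ror_min)
        and _gt(result.ror_lo, thresholds.ror_lo_min),
        "prr": a_ok
        and _ge(result.prr, thresholds.prr_min)
        and _gt(result.prr_lo, thresholds.prr_lo_min),
        "ic": _gt(result.ic025, thresholds.ic025_min),
        "ebgm": _gt(result.ebgm05, thresholds.ebgm05_min),
    }
    notes = list(result.notes)
    for method, val in (("ror", result.ror), ("prr", result.prr),
                        ("ic", result.ic025), ("ebgm", result.ebgm05)):
        if math.isnan(val) and not flags[method]:
            msg = f"{method} flag false: statistic non-computable"
            if msg not in notes:
                notes.append(msg)
    return replace(result, flags=flags, signal=all(flags.values()), notes=notes)


def rank_signals(
    results: Sequence[DisproResult], by: str = "n_reports", top: int = 30
) -> list[DisproResult]:
    """Rank signal-positive results descending by ``by`` (n_reports or ror).

    Ties break on the other key descending, then event name ascending;
    the first ``top`` rows are returned.
    """
    if top <= 0:
        raise ValueError("top must be positive")
    if by not in ("n_reports", "ror"):
        raise ValueError(f"unknown ranking key {by!r}")
    other = "ror" if by == "n_reports" else "n_reports"

    def sort_key(r: DisproResult):
        primary = getattr(r, by)
        secondary = getattr(r, other)
        primary = -math.inf if isinstance(primary, float) and math.isnan(primary) else primary
        secondary = -math.inf if isinstance(secondary, float) and math.isnan(secondary) else secondary
        return (-primary, -secondary, r.event)

    ranked = sorted((r for r in results if r.signal), key=sort_key)
    return ranked[:top]
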