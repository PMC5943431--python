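"""Summary statistics over per-scenario metrics, with two median conventions.

Portfolio tables in this field are summarised by a median, a range and a
cumulative total.  Two median conventions are exposed side by side:

* ``median_standard`` — the conventional sample median (middle element for
  odd *n*, mean of the two middle elements for even *n*);
* ``median_paper`` — the ⌊n/2⌋-th smallest value (1-based), a lower-middle
  order statistic used by some published portfolio tables.

For odd *n* the lower-middle convention sits one order statistic below the
conventional median, so the two can disagree; every report in this package
labels which convention it used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = ["Summary", "median_standard", "median_paper", "summarize"]


def _require_nonempty(values: Sequence[float]) -> None:
    if len(values) == 0:
        raise ValueError("cannot summarise an empty list of values")


def median_standard(values: Sequence[float]) -> float:
    """Conventional sample median."""
    _require_nonempty(values)
    s = sorted(values)
    n = len(s)
    mid = n // 2
    if n % 2 == 1:
        return s[mid]
    return (s[mid - 1] + s[mid]) / 2.0


def median_paper(values: Sequence[float]) -> float:
    """Lower-middle order statistic: the k-th smallest with k = ⌊n/2⌋
    (1-based); for a single value, that value."""
    _require_nonempty(values)
    s = sorted(values)
    n = len(s)
    if n == 1:
        return s[0]
    return s[n // 2 - 1]


@dataclass(frozen=True)
class Summary:
    """Five-number summary of one metric over the portfolio."""

    n: int
    median_standard: float
    median_paper: float
    minimum: float
    maximum: float
    cumulative: float


def summarize(values: Sequence[float]) -> Summary:
    """Fill a :class:`Summary` (both medians, min, max, sum, count)."""
    _require_nonempty(values)
    return Summary(
        n=len(values),
        median_standard=median_standard(values),
        median_paper=median_paper(values),
        minimum=min(values),
        maximum=max(values),
        cumulative=sum(values),
    )
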