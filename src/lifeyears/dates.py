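"""Year/month-resolution calendar dates and development-interval arithmetic.

Drug discovery dates are usually only known to the month (the US patent
application date serves as the discovery surrogate) and sometimes only to
the year.  The :class:`ApproximateDate` type records exactly the precision
that is available, and :func:`duration_years` derives the
discovery-to-approval interval with rules that depend on that precision:
month arithmetic rounded to one decimal when both endpoints carry a month,
whole-year subtraction otherwise.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

__all__ = ["ApproximateDate", "duration_years"]

_DATE_RE = re.compile(r"^(?P<year>\d{4})(?:-(?P<month>\d{1,2}))?$")


@dataclass(frozen=True)
class ApproximateDate:
    """A calendar year with an optional month.

    Parameters
    ----------
    year : int
        Calendar year, 1900 or later.
    month : int, optional
        Month 1-12; ``None`` means the month is unknown (year resolution).
    """

    year: int
    month: Optional[int] = None

    def __post_init__(self) -> None:
        if not isinstance(self.year, int) or self.year < 1900:
            raise ValueError(f"year must be an integer >= 1900, got {self.year!r}")
        if self.month is not None and not (
            isinstance(self.month, int) and 1 <= self.month <= 12
        ):
            raise ValueError(f"month must be in 1..12 or absent, got {self.month!r}")

    @classmethod
    def parse(cls, text: str) -> "ApproximateDate":
        """Parse ``"YYYY"`` or ``"YYYY-MM"`` into an :class:`ApproximateDate`."""
        m = _DATE_RE.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse approximate date {text!r}; "
                             f"expected 'YYYY' or 'YYYY-MM'")
        month = m.group("month")
        return cls(int(m.group("year")), int(month) if month is not None else None)

    def isoformat(self) -> str:
        if self.month is None:
            return f"{self.year:04d}"
        return f"{self.year:04d}-{self.month:02d}"

    def sort_key(self) -> tuple:
        # Unknown months order before known ones within a year; this is a
        # deterministic tiebreak, not a claim about the true date.
        return (self.year, -1 if self.month is None else self.month)

    def provably_before(self, other: "ApproximateDate") -> bool:
        """True only when this date is earlier than *other* at the shared
        resolution; same-year comparisons with a missing month are treated
        as unresolved (returns ``False``)."""
        if self.year != other.year:
            return self.year < other.year
        if self.month is None or other.month is None:
            return False
        return self.month < other.month

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.isoformat()


def duration_years(discovery: ApproximateDate, approval: ApproximateDate) -> float:
    """Discovery-to-approval interval in years.

    With month resolution at both endpoints the interval is the month
    difference divided by 12, rounded half-up to one decimal.  When either
    endpoint is known only to the year, the interval is the whole-year
    difference.

    Raises
    ------
    ValueError
        If the approval date is provably earlier than the discovery date.
    """
    if approval.provably_before(discovery):
        raise ValueError(
            f"approval {approval} is earlier than discovery {discovery}"
        )
    if discovery.month is not None and approval.month is not None:
        months = (approval.year - discovery.year) * 12 + (approval.month - discovery.month)
        if months < 0:
            raise ValueError(
                f"approval {approval} is earlier than discovery {discovery}"
            )
        # exact integer half-up rounding of months/12 to one decimal
        tenths = (20 * months + 12) // 24
        return tenths / 10.0
    dy = approval.year - discovery.year
    if dy < 0:
        raise ValueError(f"approval {approval} is earlier than discovery {discovery}")
    return float(dy)
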