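"""Reference-coordinate mapping for signature positions.

Printed signature positions are region-local coordinates on the ungapped
bases of a designated reference sequence: the holotype-derived legitype for
the ITS region, and an external reference (S. cerevisiae rDNA style,
supplied as an ordinary alignment member with role ``reference``) for SSU,
5.8S, and LSU. Position 1 is the reference's first non-gap base at or after
the region start; bases upstream of the region count backwards from -1 with
NO zero position, so a signature spanning a region boundary can be printed
as, e.g., "−2–18" — which covers exactly 20 bases (−2, −1, 1..18).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import AnnotatedAlignment

#: Unicode minus and en dash used in printed position ranges.
MINUS = "−"
DASH = "–"


class CoordinateError(ValueError):
    pass


@dataclass(frozen=True)
class CoordinateSystem:
    """Region-local coordinates on one reference sequence's ungapped bases.

    convention 'no-zero' (default): positions ..., -2, -1, 1, 2, ...;
    'include-zero': the base just before the region start is 0.
    """

    reference_id: str
    region: str
    label: str | None = None
    convention: str = "no-zero"

    def __post_init__(self) -> None:
        if self.convention not in ("no-zero", "include-zero"):
            raise CoordinateError(f"unknown convention {self.convention!r}")

    @property
    def display(self) -> str:
        return self.label or self.reference_id


def _ref_row(aln: AnnotatedAlignment, system: CoordinateSystem) -> np.ndarray:
    try:
        idx = aln.index_of(system.reference_id)
    except Exception as exc:
        raise CoordinateError(f"unknown reference {system.reference_id!r}") from exc
    return aln.masks[idx] != 0  # True where the reference has a base


def column_to_position(
    aln: AnnotatedAlignment, system: CoordinateSystem, column: int
) -> int | None:
    """Signed region-local position of an alignment column, or None when the
    reference is gapped at that column."""
    if not (0 <= column < aln.width):
        raise CoordinateError("column outside alignment width")
    has_base = _ref_row(aln, system)
    if not has_base[column]:
        return None
    start, _ = aln.region_map.interval(system.region)
    if column >= start:
        pos = int(has_base[start : column + 1].sum())  # >= 1
    else:
        upstream = int(has_base[column:start].sum())  # >= 1
        pos = -upstream
        if system.convention == "include-zero":
            pos += 1  # ..., -1, 0 just before the region
    return pos


def position_to_column(
    aln: AnnotatedAlignment, system: CoordinateSystem, position: int
) -> int:
    """Inverse of :func:`column_to_position` on non-gap reference columns."""
    if system.convention == "no-zero" and position == 0:
        raise CoordinateError("no zero in convention")
    has_base = _ref_row(aln, system)
    start, _ = aln.region_map.interval(system.region)
    if system.convention == "include-zero" and position <= 0:
        k = 1 - position  # 0 -> 1st upstream base, -1 -> 2nd, ...
    elif position < 0:
        k = -position
    else:
        k = 0
    if position >= 1:
        cols = np.nonzero(has_base[start:])[0]
        if position > len(cols):
            raise CoordinateError("beyond reference")
        return start + int(cols[position - 1])
    cols = np.nonzero(has_base[:start])[0]
    if k > len(cols):
        raise CoordinateError("beyond reference")
    return int(cols[len(cols) - k])


def _fmt(pos: int) -> str:
    return f"{MINUS}{-pos}" if pos < 0 else str(pos)


def interval_positions(
    aln: AnnotatedAlignment,
    systems: list[CoordinateSystem],
    columns: tuple[int, int],
) -> str:
    """Dual-coordinate description of a half-open column interval.

    Renders "X–Y in <ref>" joined by " and " over the given systems, with
    negative starts printed as in "−2–18" for boundary-spanning windows.
    """
    lo, hi = columns
    if not (0 <= lo < hi <= aln.width):
        raise CoordinateError("interval outside alignment width")
    parts = []
    for system in systems:
        a = column_to_position(aln, system, lo)
        b = column_to_position(aln, system, hi - 1)
        if a is None or b is None:
            raise CoordinateError(
                f"reference {system.reference_id!r} gapped at interval boundary"
            )
        parts.append(f"{_fmt(a)}{DASH}{_fmt(b)} in {system.display}")
    return " and ".join(parts)
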