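"""Interval arithmetic on linear and circular replicons.

Intervals are 0-based half-open ``(start, end)`` with ``start < end``. On a
circle of length ``L`` an interval may wrap: it is stored with
``0 <= start < L`` and ``end`` possibly exceeding ``L``; the covered set is
``{start mod L, ..., (end - 1) mod L}``. An interval of length >= L covers
the whole circle.
"""

from __future__ import annotations

Interval = tuple[int, int]


def length(iv: Interval) -> int:
    return iv[1] - iv[0]


def normalize(iv: Interval, L: int) -> Interval:
    """Shift a circular interval so that ``0 <= start < L``."""
    s, e = iv
    if length(iv) <= 0:
        raise ValueError(f"empty interval {iv}")
    shift = s % L - s
    return (s + shift, e + shift)


def segments(iv: Interval, L: int) -> list[Interval]:
    """Decompose a circular interval into 1-2 non-wrapping linear segments."""
    s, e = normalize(iv, L)
    if e - s >= L:
        return [(0, L)]
    if e <= L:
        return [(s, e)]
    return [(s, L), (0, e - L)]


def overlap_linear(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def overlaps(a: Interval, b: Interval, L: int, circular: bool) -> bool:
    """True if the two intervals share at least one base."""
    if not circular:
        return overlap_linear(a, b) > 0
    return any(
        overlap_linear(sa, sb) > 0 for sa in segments(a, L) for sb in segments(b, L)
    )


def contains_point(iv: Interval, pos: float, L: int, circular: bool) -> bool:
    """True if position ``pos`` lies inside the interval."""
    if circular:
        pos = pos % L
        return any(s <= pos < e for s, e in segments(iv, L))
    s, e = iv
    return s <= pos < e


def circular_gap(a: Interval, b: Interval, L: int) -> int:
    """Minimum separation in bp between two intervals on a circle (0 if they
    overlap or touch)."""
    segs_a = segments(a, L)
    segs_b = segments(b, L)
    best = L
    for sa in segs_a:
        for sb in segs_b:
            if overlap_linear(sa, sb) > 0:
                return 0
            # gap between linear segments, measured both ways around
            d1 = (sb[0] - sa[1]) % L
            d2 = (sa[0] - sb[1]) % L
            best = min(best, d1, d2)
    return best


def linear_gap(a: Interval, b: Interval) -> int:
    """Separation in bp between two linear intervals (0 if overlapping)."""
    if overlap_linear(a, b) > 0:
        return 0
    if a[1] <= b[0]:
        return b[0] - a[1]
    return a[0] - b[1]
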