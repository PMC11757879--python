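"""Exception hierarchy.

Everything raised on purpose derives from :class:`TrackmetsError`, so callers
(and the CLI) can distinguish data/validation problems from programming bugs.
"""

from __future__ import annotations


class TrackmetsError(Exception):
    """Base class for all errors raised by trackmets."""


class GPXParseError(TrackmetsError):
    """The file is not well-formed XML or not a usable GPX document."""


class SchemaError(TrackmetsError):
    """A CSV input is missing mandatory columns or has an unparseable row."""


class EmptyTrackError(TrackmetsError):
    """A track has no points (or no usable segments) where at least one is required."""


class OrderingError(TrackmetsError):
    """Timestamps are not non-decreasing; ``index`` names the offending point."""

    def __init__(self, index: int, message: str | None = None):
        self.index = index
        super().__init__(message or f"timestamp at point {index} precedes point {index - 1}")


class IncompleteElevationError(TrackmetsError):
    """Points lack elevation where slope computation requires it."""

    def __init__(self, indices: list[int], message: str | None = None):
        self.indices = list(indices)
        n = len(self.indices)
        shown = ", ".join(map(str, self.indices[:10])) + ("…" if n > 10 else "")
        super().__init__(message or f"{n} point(s) lack elevation (indices: {shown})")


class ParameterError(TrackmetsError, ValueError):
    """An argument is outside its documented domain."""


class ProfileError(TrackmetsError):
    """Athlete profile missing or invalid for the requested output (e.g. no body mass)."""
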