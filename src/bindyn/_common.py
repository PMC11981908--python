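"""Shared helpers: rounding convention and error types."""

from __future__ import annotations

import math


class BindynError(Exception):
    """Base class for all package errors."""


class FormatError(BindynError):
    """A file does not conform to its documented schema."""


class IntegrityError(BindynError):
    """Parsed data violates an invariant (e.g. duplicate gene ids)."""


class ConfigurationError(BindynError):
    """Invalid configuration (unknown pathway, infeasible simulation spec...)."""


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero.

    This is the convention used for every printed percentage in this
    package (86.67 -> 87, -15.79 -> -16, -0.5 -> -1), as opposed to
    Python's built-in banker's rounding.
    """
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))
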