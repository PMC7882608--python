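"""Shared helpers: exceptions, rounding, packaged-data access."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP, ROUND_DOWN
from importlib import resources


class SchemaError(ValueError):
    """An input table is missing a mandatory column or cannot be interpreted."""


class ConfigError(ValueError):
    """A configuration value is inconsistent or refers to an unknown entity."""


class ValidationError(ValueError):
    """Data violate an internal invariant (e.g. a negative implied cell count)."""


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (1.005 -> 1.01, -1.005 -> -1.01).

    Display rounding for result tables; Python's banker's rounding would
    disagree with conventionally rounded published tables on exact halves.
    """
    x = float(x)
    if x != x or x in (float("inf"), float("-inf")):
        return x
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(x))
    sign = -1 if d < 0 else 1
    return float(sign * abs(d).quantize(q, rounding=ROUND_HALF_UP))


def truncate_to(x: float, ndigits: int = 1) -> float:
    """Truncate toward zero at ``ndigits`` decimals (3.89 -> 3.8)."""
    x = float(x)
    if x != x or x in (float("inf"), float("-inf")):
        return x
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(x))
    sign = -1 if d < 0 else 1
    return float(sign * abs(d).quantize(q, rounding=ROUND_DOWN))


def data_path(name: str):
    """Path to a packaged data file under ``pvsignal/data``."""
    return resources.files("pvsignal").joinpath("data", name)
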