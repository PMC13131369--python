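"""Static farm descriptions and the summary quantities derived from them.

A farm is described by its lactating herd size, barn area, cubicle and
water-trough counts, the number of automatic milking systems (AMS) and the
camera installation.  Two derived quantities are routinely reported when
benchmarking barn monitoring systems: the stocking density (m^2 of barn area
per cow; the EFSA welfare guideline is >= 9 m^2/cow) and the camera-to-cow
ratio (cows per camera).
"""

from __future__ import annotations

import numbers
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional

import yaml

__all__ = [
    "FarmConfig",
    "validate_farm_config",
    "load_farm_config",
    "stocking_density",
    "camera_to_cow_ratio",
    "round_half_up",
]

#: integer count fields that must be strictly positive
_COUNT_FIELDS = ("n_cows", "n_cubicles", "n_water_troughs", "n_ams", "n_cameras")
_REQUIRED_FIELDS = ("farm_id",) + _COUNT_FIELDS + ("barn_area",)
_OPTIONAL_FIELDS = ("camera_height", "camera_spacing")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties away from zero.

    Python's built-in ``round`` uses banker's rounding (8.75 -> 8.7 at one
    decimal); reported farm summaries use conventional half-up rounding
    (8.75 -> 8.8), so the decimal module is used explicitly.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FarmConfig:
    """Validated static description of one farm."""

    farm_id: str
    n_cows: int
    barn_area: float  # m^2
    n_cubicles: int
    n_water_troughs: int
    n_ams: int
    n_cameras: int
    camera_height: Optional[float] = None  # m, metadata only
    camera_spacing: Optional[float] = None  # m, metadata only


def _require_number(raw: Mapping, field: str) -> float:
    if field not in raw or raw[field] is None:
        raise ValueError(f"farm config: missing required field '{field}'")
    value = raw[field]
    if isinstance(value, bool) or not isinstance(value, numbers.Real):
        raise ValueError(f"farm config: field '{field}' must be numeric, got {value!r}")
    return float(value)


def validate_farm_config(raw: Mapping) -> FarmConfig:
    """Validate a raw mapping (parsed from YAML/JSON) into a :class:`FarmConfig`.

    Raises :class:`ValueError` naming the offending field on a missing field,
    a non-numeric value, or a non-positive count/area.  Unknown keys raise a
    warning, not an error, so configs may carry forward-compatible metadata.
    """
    if "farm_id" not in raw or raw["farm_id"] in (None, ""):
        raise ValueError("farm config: missing required field 'farm_id'")
    farm_id = str(raw["farm_id"])

    counts = {}
    for field in _COUNT_FIELDS:
        value = _require_number(raw, field)
        if value != int(value):
            raise ValueError(f"farm config: field '{field}' must be an integer count, got {value!r}")
        if value <= 0:
            raise ValueError(f"farm config: field '{field}' must be strictly positive, got {int(value)}")
        counts[field] = int(value)

    barn_area = _require_number(raw, "barn_area")
    if barn_area <= 0:
        raise ValueError(f"farm config: field 'barn_area' must be > 0, got {barn_area!r}")

    optional = {}
    for field in _OPTIONAL_FIELDS:
        if raw.get(field) is not None:
            optional[field] = _require_number(raw, field)

    known = set(_REQUIRED_FIELDS) | set(_OPTIONAL_FIELDS)
    unknown = set(raw) - known
    if unknown:
        warnings.warn(
            f"farm config '{farm_id}': ignoring unknown fields {sorted(unknown)}",
            stacklevel=2,
        )

    return FarmConfig(farm_id=farm_id, barn_area=barn_area, **counts, **optional)


def load_farm_config(path) -> FarmConfig:
    """Read a flat key-value YAML (or JSON) farm config file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ValueError(f"farm config file {path} did not parse to a mapping")
    return validate_farm_config(raw)


def stocking_density(cfg: FarmConfig) -> float:
    """Barn area per cow in m^2, half-up rounded to one decimal."""
    return round_half_up(cfg.barn_area / cfg.n_cows, 1)


def camera_to_cow_ratio(cfg: FarmConfig) -> float:
    """Cows per camera, half-up rounded to one decimal."""
    if cfg.n_cameras < 1:
        raise ValueError("camera_to_cow_ratio: farm has no cameras")
    return round_half_up(cfg.n_cows / cfg.n_cameras, 1)
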