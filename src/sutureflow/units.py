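"""Unit conversions between clinical and SI units.

All internal computation in this package is done in SI (Pa, m, m^3/s, Pa·s);
every public interface accepts and emits the clinical units ophthalmologists
use (mm Hg, µm, mm, µl/min, mPa·s).  Raising a tube diameter expressed in
micrometres to the fourth power invites overflow and precision mistakes, so
the conversion is centralized here and nowhere else.

The mm Hg conversion constant is fixed at 133.322 Pa (conventional value) so
results are bit-stable across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import UnitError

#: Conventional conversion constant, Pa per mm Hg.
MMHG_TO_PA = 133.322

#: m^3/s per µl/min.
UL_PER_MIN_TO_M3_PER_S = 1e-9 / 60.0

# unit symbol -> factor to SI
_TO_SI: dict[str, float] = {
    # pressure (SI: Pa)
    "mmHg": MMHG_TO_PA,
    "mm Hg": MMHG_TO_PA,
    "Pa": 1.0,
    # volumetric flow (SI: m^3/s)
    "ul/min": UL_PER_MIN_TO_M3_PER_S,
    "µl/min": UL_PER_MIN_TO_M3_PER_S,
    "m^3/s": 1.0,
    # length (SI: m)
    "um": 1e-6,
    "µm": 1e-6,
    "mm": 1e-3,
    "m": 1.0,
    # dynamic viscosity (SI: Pa·s)
    "mPa*s": 1e-3,
    "mPa s": 1e-3,
    "Pa*s": 1.0,
    "Pa s": 1.0,
    # dimensionless
    "": 1.0,
}

_DIMENSION: dict[str, str] = {}
for _u, _d in [
    ("mmHg", "pressure"), ("mm Hg", "pressure"), ("Pa", "pressure"),
    ("ul/min", "flow"), ("µl/min", "flow"), ("m^3/s", "flow"),
    ("um", "length"), ("µm", "length"), ("mm", "length"), ("m", "length"),
    ("mPa*s", "viscosity"), ("mPa s", "viscosity"),
    ("Pa*s", "viscosity"), ("Pa s", "viscosity"),
    ("", "dimensionless"),
]:
    _DIMENSION[_u] = _d


def si_factor(unit: str) -> float:
    """Multiplicative factor converting ``unit`` to its SI base unit."""
    try:
        return _TO_SI[unit]
    except KeyError:
        raise UnitError(f"unknown unit {unit!r}") from None


def convert(value: float, src: str, dst: str) -> float:
    """Convert ``value`` from unit ``src`` to unit ``dst``.

    Raises :class:`UnitError` if either unit is unknown or the two units do
    not measure the same physical dimension.
    """
    fs, fd = si_factor(src), si_factor(dst)
    if _DIMENSION[src] != _DIMENSION[dst]:
        raise UnitError(
            f"cannot convert {src!r} ({_DIMENSION[src]}) "
            f"to {dst!r} ({_DIMENSION[dst]})"
        )
    return value * fs / fd


@dataclass(frozen=True)
class Quantity:
    """A magnitude with a unit symbol; used for config (de)serialization."""

    magnitude: float
    unit: str

    def to(self, unit: str) -> "Quantity":
        return Quantity(convert(self.magnitude, self.unit, unit), unit)

    @property
    def si(self) -> float:
        """Magnitude expressed in the SI base unit of its dimension."""
        return self.magnitude * si_factor(self.unit)

    def as_dict(self) -> dict:
        return {"value": self.magnitude, "unit": self.unit}

    @classmethod
    def from_dict(cls, d: dict) -> "Quantity":
        if set(d) != {"value", "unit"}:
            raise UnitError(f"quantity mapping must have keys value, unit; got {sorted(d)}")
        si_factor(d["unit"])  # validate eagerly
        return cls(float(d["value"]), str(d["unit"]))


# convenience wrappers used throughout the package
def mmhg_to_pa(p: float) -> float:
    return p * MMHG_TO_PA


def pa_to_mmhg(p: float) -> float:
    return p / MMHG_TO_PA


def ul_min_to_m3_s(q: float) -> float:
    return q * UL_PER_MIN_TO_M3_PER_S


def m3_s_to_ul_min(q: float) -> float:
    return q / UL_PER_MIN_TO_M3_PER_S
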