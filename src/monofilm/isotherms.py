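"""Surface pressure–area isotherm data model, CSV I/O and pressure-grid resampling.

A Langmuir compression run is stored as paired arrays of mean molecular area
(Å²/molecule) and surface pressure (mN/m) in acquisition order, i.e. decreasing
area.  Analysis proceeds in order of increasing pressure, which for a
compression run is the same row order; the conversion is internal and callers
never reorder data themselves.

The on-disk dialect is a two-column UTF-8 CSV with the exact header
``area_A2,pressure_mN_m``.  Film metadata (components, mole fractions,
temperature, label) lives in a plain key–value sidecar file sharing the CSV's
stem with the extension ``.meta``, keeping the numeric table tool-agnostic.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "MonofilmError",
    "ParseError",
    "ValidationError",
    "RangeError",
    "DetectionError",
    "Isotherm",
    "PressureGrid",
    "CompositionSeries",
    "read_isotherm",
    "write_isotherm",
    "resample_to_grid",
]

CSV_HEADER = "area_A2,pressure_mN_m"

#: sensor-noise floor: pressures slightly below zero are tolerated, not errors
PRESSURE_FLOOR = -0.5

#: tolerance (Å²) for non-monotone area jitter in acquisition order
AREA_ORDER_TOL = 0.5


class MonofilmError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(MonofilmError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(MonofilmError):
    """A domain invariant was violated; the message names the invariant."""


class RangeError(MonofilmError):
    """A requested pressure lies outside an isotherm's usable range."""


class DetectionError(MonofilmError):
    """A feature (lift-off, collapse) could not be detected in the data."""


@dataclass
class Isotherm:
    """One compression run: A (Å²/molecule) and π (mN/m) plus film metadata.

    Rows are in acquisition order (decreasing area).  ``mole_fractions`` is
    aligned with ``components`` and must sum to one.
    """

    area: np.ndarray
    pressure: np.ndarray
    components: tuple[str, ...] = ("unknown",)
    mole_fractions: tuple[float, ...] = (1.0,)
    temperature: float = 20.0
    label: str = ""

    def __post_init__(self) -> None:
        self.area = np.asarray(self.area, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.components = tuple(str(c) for c in self.components)
        self.mole_fractions = tuple(float(x) for x in self.mole_fractions)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        a, p = self.area, self.pressure
        if a.ndim != 1 or p.ndim != 1 or a.size != p.size:
            raise ValidationError("area and pressure arrays must have equal length")
        if a.size < 10:
            raise ValidationError("area and pressure arrays have equal length >= 10")
        if not np.all(np.isfinite(a)) or not np.all(np.isfinite(p)):
            raise ValidationError("all areas and pressures must be finite")
        if np.any(a <= 0):
            raise ValidationError("all areas > 0")
        if np.any(p < PRESSURE_FLOOR):
            raise ValidationError(f"pressures >= {PRESSURE_FLOOR} mN/m (sensor-noise floor)")
        if p.max() <= 1.0:
            raise ValidationError("max pressure > 1 mN/m")
        if np.any(np.diff(a) > AREA_ORDER_TOL):
            raise ValidationError(
                f"area is non-increasing in acquisition order (tolerance {AREA_ORDER_TOL} Å²)"
            )
        if len(self.components) != len(self.mole_fractions):
            raise ValidationError("one mole fraction per component")
        x = np.asarray(self.mole_fractions)
        if np.any(x < -1e-12) or np.any(x > 1 + 1e-12):
            raise ValidationError("each mole fraction in [0, 1]")
        if abs(x.sum() - 1.0) > 1e-9:
            raise ValidationError("mole_fractions sum to 1 within 1e-9")

    # -- conveniences -------------------------------------------------------
    @property
    def n_points(self) -> int:
        return int(self.area.size)

    @property
    def usable_pressure_max(self) -> float:
        """Largest pressure on the monotone (pre-plateau) branch.

        This is the global pressure maximum; for a run with a post-collapse
        plateau it coincides with the collapse pressure.
        """
        return float(self.pressure.max())

    def fraction_of(self, component: str) -> float:
        """Mole fraction of ``component`` (0.0 if absent from this film)."""
        for name, x in zip(self.components, self.mole_fractions):
            if name == component:
                return x
        return 0.0


@dataclass(frozen=True)
class PressureGrid:
    """Strictly increasing surface-pressure grid starting at 0 mN/m."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise ValidationError("pressure grid needs at least two points")
        if v[0] != 0.0:
            raise ValidationError("pressure grid first element = 0")
        if np.any(np.diff(v) <= 0):
            raise ValidationError("pressure grid strictly increasing")

    @classmethod
    def regular(cls, pi_max: float, step: float = 0.25) -> "PressureGrid":
        """Uniform grid 0, step, 2·step, … with the last point exactly pi_max."""
        if pi_max <= 0 or step <= 0:
            raise ValidationError("pi_max and step must be positive")
        n = int(np.floor(pi_max / step + 1e-9))
        v = np.arange(n + 1) * step
        if v[-1] < pi_max - 1e-9:
            v = np.append(v, pi_max)
        else:
            v[-1] = pi_max
        return cls(v)

    @property
    def pi_max(self) -> float:
        return float(self.values[-1])

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class CompositionSeries:
    """Isotherms of one mixed system over a mole-fraction grid.

    ``pure_isotherms`` is aligned with ``components``.  For ternary
    pseudo-binary series the first two components are the host film and
    ``fixed_ratio`` is their constant mole-fraction ratio; the last component
    (``probe_component``) is the one whose fraction varies.
    """

    system_name: str
    components: tuple[str, ...]
    pure_isotherms: tuple[Isotherm, ...]
    mixed_isotherms: list[Isotherm] = field(default_factory=list)
    fixed_ratio: Optional[float] = None

    def __post_init__(self) -> None:
        self.components = tuple(self.components)
        self.pure_isotherms = tuple(self.pure_isotherms)
        if len(self.components) not in (2, 3):
            raise ValidationError("a composition series has 2 or 3 components")
        if len(self.pure_isotherms) != len(self.components):
            raise ValidationError("one pure isotherm per component")
        for iso in self.mixed_isotherms:
            if not set(iso.components) <= set(self.components):
                raise ValidationError(
                    f"mixed isotherm {iso.label!r}: components must be a subset "
                    f"of series components {self.components}"
                )
        if self.fixed_ratio is not None:
            if len(self.components) != 3:
                raise ValidationError("fixed_ratio applies to ternary series only")
            r = float(self.fixed_ratio)
            for iso in self.mixed_isotherms:
                x0 = iso.fraction_of(self.components[0])
                x1 = iso.fraction_of(self.components[1])
                if x1 > 1e-12 and abs(x0 / x1 - r) > 1e-6:
                    raise ValidationError(
                        f"host-component ratio must be constant ({r}) across mixed "
                        f"isotherms; {iso.label!r} has {x0 / x1:.8f}"
                    )

    @property
    def probe_component(self) -> str:
        """Component whose mole fraction varies along the series (listed last)."""
        return self.components[-1]

    def pure(self, component: str) -> Isotherm:
        for name, iso in zip(self.components, self.pure_isotherms):
            if name == component:
                return iso
        raise KeyError(component)

    def sorted_mixed(self) -> list[Isotherm]:
        return sorted(self.mixed_isotherms, key=lambda i: i.fraction_of(self.probe_component))


# ---------------------------------------------------------------------------
# CSV + sidecar I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: str) -> str:
    stem, _ = os.path.splitext(path)
    return stem + ".meta"


def write_isotherm(iso: Isotherm, path: str, metadata: Optional[str] = None) -> None:
    """Write ``iso`` to a two-column CSV plus a key–value metadata sidecar."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(CSV_HEADER + "\n")
        for a, p in zip(iso.area, iso.pressure):
            fh.write(f"{a:.10g},{p:.10g}\n")
    meta = metadata or _sidecar_path(path)
    with open(meta, "w", encoding="utf-8") as fh:
        fh.write("components = " + ", ".join(iso.components) + "\n")
        fh.write("mole_fractions = " + ", ".join(f"{x:.12g}" for x in iso.mole_fractions) + "\n")
        fh.write(f"temperature_C = {iso.temperature:.12g}\n")
        fh.write(f"label = {iso.label}\n")


def _read_sidecar(path: str) -> dict:
    out: dict = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ParseError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, _, value = line.partition("=")
            out[key.strip()] = value.strip()
    return out


def read_isotherm(path: str, metadata: Optional[str] = None) -> Isotherm:
    """Read a CSV isotherm (plus optional sidecar metadata) and validate it.

    Rows are sorted by decreasing area and rows sharing an identical area value
    are averaged (real troughs emit duplicates); malformed numeric fields raise
    :class:`ParseError` naming the line, invariant violations raise
    :class:`ValidationError` naming the invariant.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    areas: list[float] = []
    pressures: list[float] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(",")]
            if lineno == 1 and not _is_number(parts[0]):
                continue  # header row
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected two comma-separated columns")
            try:
                areas.append(float(parts[0]))
                pressures.append(float(parts[1]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed numeric field: {line!r}") from exc
    if not areas:
        raise ParseError(f"{path}: no data rows")
    a = np.asarray(areas)
    p = np.asarray(pressures)
    order = np.argsort(-a, kind="stable")
    a, p = a[order], p[order]
    # average duplicate-area rows
    uniq, inverse, counts = np.unique(-a, return_inverse=True, return_counts=True)
    if np.any(counts > 1):
        p_avg = np.bincount(inverse, weights=p) / counts
        a, p = -uniq, p_avg

    meta_path = metadata or _sidecar_path(path)
    kwargs: dict = {}
    if os.path.exists(meta_path):
        meta = _read_sidecar(meta_path)
        if "components" in meta:
            kwargs["components"] = tuple(s.strip() for s in meta["components"].split(","))
        if "mole_fractions" in meta:
            try:
                kwargs["mole_fractions"] = tuple(
                    float(s) for s in meta["mole_fractions"].split(",")
                )
            except ValueError as exc:
                raise ParseError(f"{meta_path}: malformed mole_fractions") from exc
        if "temperature_C" in meta:
            kwargs["temperature"] = float(meta["temperature_C"])
        if "label" in meta:
            kwargs["label"] = meta["label"]
    return Isotherm(area=a, pressure=p, **kwargs)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Resampling onto pressure grids
# ---------------------------------------------------------------------------

def _lift_off_scan(
    area: np.ndarray,
    pressure: np.ndarray,
    threshold: float = 0.5,
    run_length: int = 3,
) -> Optional[int]:
    """Index of the first point (in decreasing-area order) from which the
    pressure stays at or above ``threshold`` for ``run_length`` consecutive
    points, or None if no such run exists."""
    n = pressure.size
    if run_length < 1 or n < run_length:
        return None
    above = pressure >= threshold
    run = 0
    for i in range(n):
        run = run + 1 if above[i] else 0
        if run >= run_length:
            return i - run_length + 1
    return None


def resample_to_grid(iso: Isotherm, grid: PressureGrid) -> np.ndarray:
    """Areas A(π) on ``grid`` by monotone piecewise-linear interpolation.

    Only the pre-collapse branch is used (points up to the first occurrence of
    the global pressure maximum, filtered to strictly increasing pressure).
    A(0) is anchored at the lift-off area so mixing integrals can start exactly
    at π = 0.  Splines are deliberately avoided: isotherms have kinks (LE–LC
    plateaus, collapses) that splines overshoot.
    """
    a, p = iso.area, iso.pressure
    imax = int(np.argmax(p))
    a, p = a[: imax + 1], p[: imax + 1]

    usable = float(p[-1])
    if grid.pi_max > usable + 1e-9:
        raise RangeError(
            f"grid extends to {grid.pi_max:g} mN/m but isotherm "
            f"{iso.label or '<unnamed>'!r} is usable only up to {usable:g} mN/m"
        )

    start = _lift_off_scan(a, p)
    if start is None:
        start = int(np.argmax(p > 0.0))
    # walk back through the strictly rising low-pressure toe so the π→0 end
    # is anchored by data, not by the detection threshold; on noisy data the
    # walk stops at the first non-monotone jitter
    while start > 0 and 0.0 < p[start - 1] < p[start]:
        start -= 1
    # strictly increasing pressure subsequence from the lift-off onward
    keep_a: list[float] = []
    keep_p: list[float] = []
    pmax = -np.inf
    for i in range(start, p.size):
        if p[i] > pmax:
            keep_a.append(a[i])
            keep_p.append(p[i])
            pmax = p[i]
    ka = np.asarray(keep_a)
    kp = np.asarray(keep_p)
    if kp.size < 2:
        raise RangeError(f"isotherm {iso.label!r}: too few rising-pressure points")

    if kp[0] > 0.0:
        if kp[0] < 0.3 and kp[1] > kp[0]:
            # dense data: short linear back-extrapolation to π = 0
            a0 = ka[0] + (ka[0] - ka[1]) / (kp[1] - kp[0]) * kp[0]
        else:
            a0 = ka[0]
        ka = np.concatenate([[max(a0, ka[0])], ka])
        kp = np.concatenate([[0.0], kp])

    # np.interp needs increasing x; kp is increasing by construction
    return np.interp(grid.values, kp, ka)
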