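"""Mixing behavior of multicomponent monolayers: excess area, excess free
enthalpy, and collapse-pressure miscibility.

The ideal (additive) reference at a given surface pressure is the
mole-fraction-weighted mean of the pure-component areas,
A_id(π) = Σ Xᵢ·Aᵢ(π); the excess area is A^exc = A_mix − A_id, and the excess
free enthalpy of mixing follows by integrating the excess area over pressure
from zero:

    ΔG^exc(π) = N_A ∫₀^π A^exc dπ'

With areas in Å²/molecule and pressures in mN/m, 1 Å²·mN/m = 10⁻²³ J, so the
conversion to J/mol is the exact factor N_A·10⁻²³ = 6.02214076.  Negative
ΔG^exc means mixing is thermodynamically favorable (attraction/condensation);
positive means repulsion with a tendency to film separation.  Quadrature is
trapezoidal on a uniform pressure grid (default 0.25 mN/m): robust to the
kinks real isotherms carry, and its convergence is directly testable.

For ternary films built by adding a probe lipid to a fixed-ratio binary host
film, the default ideal reference is the three-component weighted sum (the
direct generalization of the binary formula); a pseudo-binary alternative —
probe vs the intact host film — is exposed via ``reference="pseudo_binary"``
without asserting that either is canonical.

Miscibility uses the two-dimensional phase rule: components that mix show a
collapse pressure that varies with film composition, while an immiscible pair
collapses independently — either two collapses in one run (the first at the
less stable pure component's π_coll, the ejected component) or a π_coll that
stays pinned at a pure-component value across a composition range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .descriptors import DescriptorSet
from .isotherms import (
    CompositionSeries,
    Isotherm,
    PressureGrid,
    RangeError,
    resample_to_grid,
)

__all__ = [
    "UNIT_FACTOR",
    "ExcessProfile",
    "MiscibilityEntry",
    "MiscibilityReport",
    "ideal_area",
    "excess_gibbs",
    "excess_area_curve",
    "dg_vs_composition",
    "assess_miscibility",
]

#: J·mol⁻¹ per (Å²·mN/m): Avogadro constant × 10⁻²³, exact
UNIT_FACTOR = 6.02214076


@dataclass
class ExcessProfile:
    """A^exc(π) and ΔG^exc(π) for one composition on a common pressure grid."""

    composition: tuple[float, ...]
    grid: PressureGrid
    a_mixed: np.ndarray     # Å²
    a_ideal: np.ndarray     # Å²
    a_excess: np.ndarray    # Å²
    dg_excess: np.ndarray   # J/mol, cumulative in π; dg_excess[0] = 0

    def at(self, pi: float) -> tuple[float, float]:
        """(A^exc, ΔG^exc) interpolated at pressure ``pi``."""
        v = self.grid.values
        return (
            float(np.interp(pi, v, self.a_excess)),
            float(np.interp(pi, v, self.dg_excess)),
        )


def ideal_area(pure_areas: Sequence[float], fractions: Sequence[float]) -> float:
    """Mole-fraction-weighted mean area Σ Xᵢ·Aᵢ at one pressure (Å²)."""
    a = np.asarray(pure_areas, dtype=float)
    x = np.asarray(fractions, dtype=float)
    if a.shape != x.shape or a.ndim != 1:
        raise ValueError("one pure-component area per mole fraction")
    if abs(x.sum() - 1.0) > 1e-6:
        raise ValueError("mole fractions must sum to 1")
    return float(np.dot(a, x))


def _match_mixed(series: CompositionSeries, composition: Sequence[float]) -> Isotherm:
    target = np.asarray(composition, dtype=float)
    if target.size != len(series.components):
        raise ValueError("composition vector must align with series components")
    for iso in series.mixed_isotherms:
        vec = np.array([iso.fraction_of(c) for c in series.components])
        if np.allclose(vec, target, atol=1e-6):
            return iso
    raise ValueError(f"no mixed isotherm at composition {tuple(target)} in series")


def _resample(iso: Isotherm, grid: PressureGrid) -> np.ndarray:
    try:
        return resample_to_grid(iso, grid)
    except RangeError as exc:
        raise RangeError(f"limiting isotherm {iso.label!r}: {exc}") from exc


def excess_gibbs(
    series: CompositionSeries,
    composition: Sequence[float],
    pi_max: float,
    grid_step: float = 0.25,
    reference: str = "pure",
) -> ExcessProfile:
    """Full excess profile for one composition, integrated from π = 0.

    ``reference="pure"`` uses the weighted sum of all pure components (two or
    three); ``reference="pseudo_binary"`` (ternary series only) references the
    probe against the intact binary host film, i.e. the series member with
    zero probe fraction.
    """
    if grid_step <= 0:
        raise ValueError("grid_step > 0")
    grid = PressureGrid.regular(pi_max, grid_step)
    mixed = _match_mixed(series, composition)
    x = np.asarray(composition, dtype=float)
    a_mixed = _resample(mixed, grid)

    if reference == "pure":
        a_ideal = np.zeros(len(grid))
        for name, xi in zip(series.components, x):
            if xi > 1e-12:
                a_ideal += xi * _resample(series.pure(name), grid)
    elif reference == "pseudo_binary":
        if len(series.components) != 3:
            raise ValueError("pseudo_binary reference applies to ternary series")
        probe = series.probe_component
        x_probe = x[-1]
        host = None
        for iso in series.mixed_isotherms:
            if iso.fraction_of(probe) < 1e-12:
                host = iso
                break
        if host is None:
            raise ValueError("pseudo_binary reference needs a zero-probe host film in the series")
        a_ideal = x_probe * _resample(series.pure(probe), grid) + (1.0 - x_probe) * _resample(
            host, grid
        )
    else:
        raise ValueError("reference is 'pure' or 'pseudo_binary'")

    a_excess = a_mixed - a_ideal
    dg = UNIT_FACTOR * cumulative_trapezoid(a_excess, grid.values, initial=0.0)
    return ExcessProfile(
        composition=tuple(x),
        grid=grid,
        a_mixed=a_mixed,
        a_ideal=a_ideal,
        a_excess=a_excess,
        dg_excess=dg,
    )


def _series_compositions(series: CompositionSeries) -> list[tuple[float, np.ndarray]]:
    probe = series.probe_component
    rows = []
    for iso in series.sorted_mixed():
        vec = np.array([iso.fraction_of(c) for c in series.components])
        rows.append((iso.fraction_of(probe), vec))
    return rows


def excess_area_curve(
    series: CompositionSeries, pi: float, grid_step: float = 0.25
) -> pd.DataFrame:
    """Table of (X, A₁₂, A₁₂^id, A^exc) at fixed pressure, one row per film.

    X is the mole fraction of the series' probe component.
    """
    rows = []
    for x_probe, vec in _series_compositions(series):
        prof = excess_gibbs(series, vec, pi_max=pi, grid_step=grid_step)
        rows.append(
            {
                "X": x_probe,
                "A12": prof.a_mixed[-1],
                "A12_id": prof.a_ideal[-1],
                "A_exc": prof.a_excess[-1],
            }
        )
    return pd.DataFrame(rows)


def dg_vs_composition(
    series: CompositionSeries,
    pi: float = 30.0,
    grid_step: float = 0.25,
    reference: str = "pure",
) -> pd.DataFrame:
    """ΔG^exc at fixed pressure for every composition in the series.

    The 30 mN/m default is the conventional monolayer–bilayer correspondence
    pressure at which mixed-film thermodynamics are compared.
    """
    rows = []
    for x_probe, vec in _series_compositions(series):
        prof = excess_gibbs(series, vec, pi_max=pi, grid_step=grid_step, reference=reference)
        rows.append({"X": x_probe, "dG_exc": prof.dg_excess[-1]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# miscibility
# ---------------------------------------------------------------------------

@dataclass
class MiscibilityEntry:
    x: float
    collapse_pressures: tuple[float, ...]
    classification: str  # "miscible" | "immiscible" | "partial"
    rationale: str


@dataclass
class MiscibilityReport:
    system_name: str
    pure_collapses: dict
    tolerance: float
    entries: list[MiscibilityEntry]

    def summary(self) -> str:
        lines = [f"Miscibility report: {self.system_name}"]
        lines.append(
            "pure collapse pressures: "
            + ", ".join(f"{k} {v:.1f} mN/m" for k, v in self.pure_collapses.items())
        )
        lines.append(f"tolerance: {self.tolerance:.2f} mN/m")
        for e in self.entries:
            cps = ", ".join(f"{c:.1f}" for c in e.collapse_pressures) or "none"
            lines.append(f"  X={e.x:.2f}: pi_coll [{cps}] -> {e.classification} ({e.rationale})")
        ranges = self.immiscible_range()
        if ranges:
            lines.append(f"immiscible composition range: X in [{ranges[0]:.2f}, {ranges[1]:.2f}]")
        return "\n".join(lines)

    def immiscible_range(self) -> Optional[tuple[float, float]]:
        xs = [e.x for e in self.entries if e.classification == "immiscible"]
        return (min(xs), max(xs)) if xs else None


def assess_miscibility(
    series: CompositionSeries,
    descriptors: Sequence[DescriptorSet],
    tolerance: float = 1.5,
) -> MiscibilityReport:
    """Phase-rule miscibility assessment for every mixed composition.

    ``descriptors`` is ordered as the series: one per pure component, then one
    per mixed isotherm (the order of ``series.mixed_isotherms``).  The default
    tolerance of 1.5 mN/m reflects typical isotherm reproducibility.

    Per composition: immiscible when the run shows two or more collapses with
    the first at a pure component's π_coll (ejection of the less stable
    component), or when a single collapse is pinned at a pure value and the
    neighboring compositions are pinned there too (constant-π_coll run);
    miscible when the single collapse lies away from both pure values or
    varies across the composition grid; partial otherwise (including runs
    truncated before any collapse — barrier range exhausted).
    """
    n_pure = len(series.components)
    if len(descriptors) != n_pure + len(series.mixed_isotherms):
        raise ValueError(
            "descriptors must cover the pure components then every mixed isotherm"
        )
    pure_cp: dict = {}
    for name, des in zip(series.components, descriptors[:n_pure]):
        ev = des.primary_collapse
        if ev is None:
            raise ValueError(f"pure component {name!r} has no detected collapse")
        pure_cp[name] = ev.pressure
    pure_values = np.array(list(pure_cp.values()))

    probe = series.probe_component
    mixed = list(zip(series.mixed_isotherms, descriptors[n_pure:]))
    # pure vertices (a mole fraction of 0 or 1 in the probe) are one-component
    # films; they would trivially pin their neighbours at a pure value
    mixed = [
        (iso, d)
        for iso, d in mixed
        if 1e-9 < iso.fraction_of(probe) < 1.0 - 1e-9
    ]
    mixed.sort(key=lambda t: t[0].fraction_of(probe))
    xs = [iso.fraction_of(probe) for iso, _ in mixed]
    primaries = [
        (d.primary_collapse.pressure if d.primary_collapse else np.nan) for _, d in mixed
    ]

    entries: list[MiscibilityEntry] = []
    for k, (iso, des) in enumerate(mixed):
        cps = tuple(e.pressure for e in des.collapses)
        if len(cps) == 0:
            entries.append(
                MiscibilityEntry(
                    xs[k], cps, "partial", "no collapse within barrier range"
                )
            )
            continue
        matched = [
            name for name, v in pure_cp.items() if any(abs(c - v) <= tolerance for c in cps)
        ]
        if len(cps) >= 2:
            first_matches = [
                name for name, v in pure_cp.items() if abs(cps[0] - v) <= tolerance
            ]
            if first_matches:
                entries.append(
                    MiscibilityEntry(
                        xs[k],
                        cps,
                        "immiscible",
                        f"two collapses; first at pure {first_matches[0]} pressure "
                        f"({cps[0]:.1f} mN/m) — component ejection",
                    )
                )
            else:
                entries.append(
                    MiscibilityEntry(
                        xs[k], cps, "partial", "two collapses, neither at a pure value"
                    )
                )
            continue
        c = cps[0]
        if not matched:
            entries.append(
                MiscibilityEntry(
                    xs[k],
                    cps,
                    "miscible",
                    "single collapse away from both pure values",
                )
            )
            continue
        neighbor_pinned = False
        for j in (k - 1, k + 1):
            if 0 <= j < len(primaries) and np.isfinite(primaries[j]):
                if any(abs(primaries[j] - pure_cp[name]) <= tolerance for name in matched):
                    neighbor_pinned = True
        if neighbor_pinned:
            entries.append(
                MiscibilityEntry(
                    xs[k],
                    cps,
                    "immiscible",
                    f"collapse pinned at pure {matched[0]} pressure across neighboring "
                    "compositions (constant-pi_coll run)",
                )
            )
            continue
        varies = False
        for j in (k - 1, k + 1):
            if 0 <= j < len(primaries) and np.isfinite(primaries[j]):
                if abs(primaries[j] - c) > tolerance / 2:
                    varies = True
        if varies:
            entries.append(
                MiscibilityEntry(
                    xs[k], cps, "miscible", "collapse pressure varies with composition"
                )
            )
        else:
            entries.append(
                MiscibilityEntry(
                    xs[k],
                    cps,
                    "partial",
                    "collapse near a pure value; composition dependence inconclusive",
                )
            )
    return MiscibilityReport(
        system_name=series.system_name,
        pure_collapses=pure_cp,
        tolerance=tolerance,
        entries=entries,
    )
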