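"""Per-isotherm characteristics: compression modulus, lift-off, A0, collapses,
LE–LC transition plateau and phase-state class.

The compression modulus C_s⁻¹ = −A·(dπ/dA) is the central quantity: its
magnitude classifies the film (gaseous / liquid-expanded / liquid /
liquid-condensed / solid, using the conventional Davies–Rideal bands
12.5 / 50 / 100 / 250 mN/m) and its profile locates the steep branch used for
the zero-pressure extrapolated area A0.  Raw finite differences on ±0.1 mN/m
sensor noise are unusable, so derivatives come from a local least-squares
polynomial (default window 11 points, degree 3) evaluated per point; this also
handles the non-uniform area spacing of real troughs.

Collapse events are reported at onset (the first point where the isotherm
slope |dπ/dA| drops below a fraction of its running maximum, or where pressure
falls on further compression), matching the reading of mixed-film isotherms in
which the first collapse is the ejection of the less stable component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .isotherms import DetectionError, Isotherm, MonofilmError, ValidationError

__all__ = [
    "FitError",
    "CompressionProfile",
    "CollapseEvent",
    "DescriptorSet",
    "compression_modulus",
    "lift_off",
    "extrapolated_area",
    "detect_collapses",
    "classify_phase",
    "detect_transition_plateau",
    "describe",
    "PHASE_BANDS",
]

#: Davies–Rideal style C_s⁻¹ bands (upper edges, mN/m) → phase class
PHASE_BANDS = (
    (12.5, "gaseous"),
    (50.0, "liquid-expanded"),
    (100.0, "liquid"),
    (250.0, "liquid-condensed"),
    (np.inf, "solid"),
)


class FitError(MonofilmError):
    """A least-squares fit had too few qualifying points."""


@dataclass
class CompressionProfile:
    """C_s⁻¹(π) on the pre-collapse branch of one isotherm.

    ``pressure``/``area``/``cs_inv`` are truncated at the first collapse onset;
    the private full-branch arrays (smoothed pressure and slope dπ/dA in
    analysis order) are kept for collapse and plateau detection.
    """

    pressure: np.ndarray
    area: np.ndarray
    cs_inv: np.ndarray
    cs_inv_max: float
    pressure_at_max: float
    smoothing_window: int = 11
    _full_area: np.ndarray = field(default=None, repr=False)
    _full_pressure_raw: np.ndarray = field(default=None, repr=False)
    _full_pressure: np.ndarray = field(default=None, repr=False)
    _full_slope: np.ndarray = field(default=None, repr=False)


@dataclass(frozen=True)
class CollapseEvent:
    """Monolayer failure onset: (π, A) and whether it is the first event."""

    pressure: float
    area: float
    kind: str  # "primary" | "secondary"

    def __post_init__(self) -> None:
        if self.pressure <= 0:
            raise ValidationError("collapse pressure > 0")
        if self.kind not in ("primary", "secondary"):
            raise ValidationError("collapse kind is 'primary' or 'secondary'")


@dataclass
class DescriptorSet:
    """Scalar characteristics of one isotherm (Table-1 style summary)."""

    label: str
    lift_off_area: float
    a0_extrapolated: float
    collapses: list[CollapseEvent]
    cs_inv_max: float
    phase_class: str
    transition_plateau: Optional[tuple[float, float, float]] = None  # (π, A_start, A_end)

    @property
    def primary_collapse(self) -> Optional[CollapseEvent]:
        return self.collapses[0] if self.collapses else None

    def is_consistent(self, tol: float = 1.0) -> bool:
        """lift-off > A0 > first collapse area (within ``tol`` Å² of slack)."""
        if not self.collapses:
            return self.lift_off_area + tol > self.a0_extrapolated
        return (
            self.lift_off_area + tol > self.a0_extrapolated
            and self.a0_extrapolated + tol > self.collapses[0].area
        )


# ---------------------------------------------------------------------------
# smoothing / differentiation
# ---------------------------------------------------------------------------

def _local_poly_derivative(
    x: np.ndarray, y: np.ndarray, window: int, degree: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Per-point local least-squares polynomial value and derivative dy/dx.

    Works on non-uniform ``x``; windows are clamped at the ends so every fit
    uses exactly ``window`` points.
    """
    n = x.size
    deg = min(degree, window - 2)
    half = window // 2
    ys = np.empty(n)
    dy = np.empty(n)
    for i in range(n):
        lo = min(max(0, i - half), n - window)
        xs = x[lo : lo + window] - x[i]
        coef = np.polyfit(xs, y[lo : lo + window], deg)
        ys[i] = coef[-1]
        dy[i] = coef[-2]
    return ys, dy


def compression_modulus(iso: Isotherm, smoothing_window: int = 11) -> CompressionProfile:
    """C_s⁻¹(π) = −A·(dπ/dA), smoothed, reported up to the first collapse."""
    if smoothing_window < 5 or smoothing_window % 2 == 0:
        raise ValidationError("smoothing_window must be an odd count >= 5")
    if iso.n_points < smoothing_window:
        raise ValidationError(
            f"need at least smoothing_window={smoothing_window} points, "
            f"got {iso.n_points}"
        )
    from .isotherms import _lift_off_scan

    # restrict to the film (from lift-off onward): windows straddling the
    # zero-pressure foot's kink would overshoot the slope at the branch start
    start = _lift_off_scan(iso.area, iso.pressure)
    if start is None:
        start = 0
    a = iso.area[start:]
    p_raw = iso.pressure[start:]
    if a.size < smoothing_window:
        raise ValidationError(
            f"fewer than smoothing_window={smoothing_window} points above lift-off"
        )
    p_s, slope = _local_poly_derivative(a, p_raw, smoothing_window)

    onsets = _collapse_scan(a, p_raw, p_s, slope)
    k = onsets[0] if onsets else a.size
    cs = -a[:k] * slope[:k]
    if cs.size == 0 or not np.all(np.isfinite(cs)):
        raise ValidationError("compression modulus not finite on pre-collapse branch")
    imax = int(np.argmax(cs))
    return CompressionProfile(
        pressure=p_s[:k],
        area=a[:k],
        cs_inv=cs,
        cs_inv_max=float(cs[imax]),
        pressure_at_max=float(p_s[imax]),
        smoothing_window=smoothing_window,
        _full_area=a,
        _full_pressure_raw=p_raw,
        _full_pressure=p_s,
        _full_slope=slope,
    )


# ---------------------------------------------------------------------------
# collapse detection
# ---------------------------------------------------------------------------

def _collapse_scan(
    area: np.ndarray,
    p_raw: np.ndarray,
    p_smooth: np.ndarray,
    slope: np.ndarray,
    slope_fraction: float = 0.1,
    min_pressure: float = 5.0,
) -> list[int]:
    """Indices of collapse onsets.

    A collapse is the first point (raw π > min_pressure) where |dπ/dA| falls
    below ``slope_fraction`` × its running maximum, or where the smoothed
    pressure drops below its running maximum by more than a 0.2 mN/m deadband.
    After an onset, the search resumes once |dπ/dA| re-steepens above 3× the
    plateau slope (with a small floor against numerical noise), allowing a
    secondary event at higher pressure.
    """
    n = area.size
    # noise-aware margin on the pressure gate: an LE-LC plateau sitting right
    # at min_pressure must not leak past it through sensor jitter
    sigma = 1.4826 * float(np.median(np.abs(p_raw - p_smooth)))
    p_gate = min_pressure + 3.0 * sigma
    events: list[int] = []
    runmax_slope = 0.0
    prev_runmax = 0.0
    pmax = -np.inf
    last_event_p = -np.inf
    searching = True
    plateau_slopes: list[float] = []
    for i in range(n):
        s = abs(slope[i])
        if searching:
            runmax_slope = max(runmax_slope, s)
            pmax = max(pmax, p_smooth[i])
            # a further event must sit at genuinely higher pressure than the
            # previous one (0.5 mN/m margin guards against plateau noise)
            if (
                p_raw[i] > p_gate
                and p_smooth[i] > last_event_p + 0.5
                and (s < slope_fraction * runmax_slope or p_smooth[i] < pmax - 0.2)
            ):
                events.append(i)
                searching = False
                prev_runmax = runmax_slope
                last_event_p = p_smooth[i]
                plateau_slopes = [s]
        else:
            plateau_slopes.append(s)
            plateau = float(np.median(plateau_slopes))
            if s > max(3.0 * plateau, 0.15 * prev_runmax):
                searching = True
                runmax_slope = s
                pmax = p_smooth[i]
    return events


def detect_collapses(
    iso: Isotherm,
    profile: Optional[CompressionProfile] = None,
    slope_fraction: float = 0.1,
    min_pressure: float = 5.0,
) -> list[CollapseEvent]:
    """Collapse onsets (π, A); empty when no collapse lies in the barrier range.

    An isotherm can legitimately end before collapsing (e.g. when a minority
    component's collapse would occur below the barrier range), so an empty
    list is a valid result, not an error.
    """
    if profile is None:
        profile = compression_modulus(iso)
    onsets = _collapse_scan(
        profile._full_area,
        profile._full_pressure_raw,
        profile._full_pressure,
        profile._full_slope,
        slope_fraction=slope_fraction,
        min_pressure=min_pressure,
    )
    events: list[CollapseEvent] = []
    for j, i in enumerate(onsets):
        events.append(
            CollapseEvent(
                pressure=float(profile._full_pressure[i]),
                area=float(profile._full_area[i]),
                kind="primary" if j == 0 else "secondary",
            )
        )
    return events


# ---------------------------------------------------------------------------
# lift-off and extrapolated area
# ---------------------------------------------------------------------------

def lift_off(iso: Isotherm, threshold: float = 0.5, run_length: int = 3) -> float:
    """Lift-off area: onset of measurable surface pressure, in Å²/molecule.

    Finds the largest area at which π ≥ ``threshold`` for ``run_length``
    consecutive points (the run guard prevents single-point noise spikes from
    defining lift-off), then refines the onset by a local linear
    back-extrapolation of π(A) to π = 0, so the result is not biased low by
    the threshold itself.
    """
    if threshold <= 0:
        raise ValidationError("threshold must exceed the noise floor (> 0)")
    from .isotherms import _lift_off_scan

    idx = _lift_off_scan(iso.area, iso.pressure, threshold, run_length)
    if idx is None:
        raise DetectionError(
            f"pressure never reaches {threshold} mN/m for {run_length} consecutive points"
        )
    w = max(run_length, 7)
    a_w = iso.area[idx : idx + w]
    p_w = iso.pressure[idx : idx + w]
    if a_w.size >= 2 and a_w[0] - a_w[-1] > 1e-12:
        m, b = np.polyfit(a_w, p_w, 1)
        if m < 0:
            a0 = -b / m
            return float(np.clip(a0, iso.area[idx], iso.area[0]))
    return float(iso.area[idx])


def extrapolated_area(
    iso: Isotherm, profile: Optional[CompressionProfile] = None, fraction: float = 0.85
) -> float:
    """Zero-pressure intercept A0 of a line through the steep condensed branch.

    The fit region is all pre-collapse points where C_s⁻¹ ≥ fraction × max —
    the common "steepest linear segment" recipe.  Raising ``fraction`` toward
    1 shrinks the region and destabilises the fit; 0.85 is a robust default.
    """
    if not (0.0 < fraction < 1.0):
        raise ValidationError("fraction must be in (0, 1)")
    if profile is None:
        profile = compression_modulus(iso)
    mask = profile.cs_inv >= fraction * profile.cs_inv_max
    if int(mask.sum()) < 5:
        raise FitError(
            f"fewer than 5 points with C_s^-1 >= {fraction:g} x max; lower 'fraction'"
        )
    m, b = np.polyfit(profile.pressure[mask], profile.area[mask], 1)
    return float(b)


# ---------------------------------------------------------------------------
# phase state and LE-LC transition
# ---------------------------------------------------------------------------

def classify_phase(profile: Union[CompressionProfile, float]) -> str:
    """Phase class from the maximum compression modulus (pure banding)."""
    cs = profile.cs_inv_max if isinstance(profile, CompressionProfile) else float(profile)
    if not np.isfinite(cs):
        raise ValidationError("cs_inv_max must be finite")
    if cs < 12.5:
        return "gaseous"
    if cs < 50.0:
        return "liquid-expanded"
    if cs < 100.0:
        return "liquid"
    if cs <= 250.0:
        return "liquid-condensed"
    return "solid"


def detect_transition_plateau(
    iso: Isotherm,
    profile: Optional[CompressionProfile] = None,
    cs_threshold: float = 30.0,
) -> Optional[tuple[float, float, float]]:
    """LE–LC transition: a C_s⁻¹ local minimum (< 30 mN/m) between two maxima.

    Returns (π at the minimum, area at plateau start, area at plateau end), or
    None when the isotherm has no transition region.  The profile is already
    truncated at the first collapse, so a low-modulus region beyond collapse
    can never masquerade as a transition.
    """
    if profile is None:
        profile = compression_modulus(iso)
    cs = profile.cs_inv
    n = cs.size
    if n < 5:
        return None
    best = None
    for i in range(1, n - 1):
        if cs[i] >= cs_threshold:
            continue
        left = cs[:i].max(initial=-np.inf)
        right = cs[i + 1 :].max(initial=-np.inf)
        # prominence guard: both flanking maxima must clearly tower over the
        # minimum, so noise dips in a liquid film do not read as transitions
        needed = max(cs_threshold, 2.0 * cs[i] + 20.0)
        if left > needed and right > needed:
            if best is None or cs[i] < cs[best]:
                best = i
    if best is None:
        return None
    lo = best
    while lo > 0 and cs[lo - 1] < cs_threshold:
        lo -= 1
    hi = best
    while hi < n - 1 and cs[hi + 1] < cs_threshold:
        hi += 1
    return (
        float(profile.pressure[best]),
        float(profile.area[lo]),
        float(profile.area[hi]),
    )


# ---------------------------------------------------------------------------
# one-call summary
# ---------------------------------------------------------------------------

def describe(
    iso: Isotherm,
    smoothing_window: int = 11,
    lift_off_threshold: float = 0.5,
    run_length: int = 3,
    a0_fraction: float = 0.85,
    slope_fraction: float = 0.1,
    min_pressure: float = 5.0,
) -> DescriptorSet:
    """Compute the full descriptor set for one isotherm."""
    profile = compression_modulus(iso, smoothing_window)
    try:
        lift = lift_off(iso, lift_off_threshold, run_length)
    except DetectionError:
        lift = float("nan")
    try:
        a0 = extrapolated_area(iso, profile, a0_fraction)
    except FitError:
        a0 = float("nan")
    collapses = detect_collapses(iso, profile, slope_fraction, min_pressure)
    plateau = detect_transition_plateau(iso, profile)
    return DescriptorSet(
        label=iso.label,
        lift_off_area=lift,
        a0_extrapolated=a0,
        collapses=collapses,
        cs_inv_max=profile.cs_inv_max,
        phase_class=classify_phase(profile),
        transition_plateau=plateau,
    )
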