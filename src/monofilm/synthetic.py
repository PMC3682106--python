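"""Synthetic π–A isotherm and composition-series generator with exact oracles.

No raw trough data ships with this package, so every analysis stage is
exercised against curves whose ground truth is known in closed form.

Pre-collapse branch (exposed for oracle use via :func:`area_of_pressure`)::

    A(π) = a_coll + (a_lift − a_coll) · ((π_coll − π)/π_coll)^γ ,  π ∈ [0, π_coll]

so A(0) = a_lift and A(π_coll) = a_coll exactly.  The implied compression
modulus is

    C_s⁻¹(π) = A(π) · π_coll / (γ·(a_lift − a_coll)) · u^(1−γ),  u = (π_coll − π)/π_coll

whose value at π = 0 is π_coll·a_lift / (γ·(a_lift − a_coll)); fixture authors
control the modulus through γ and the area span.  Optional features: an LE–LC
transition plateau of stated width inserted at π_t (the condensed branch is
affinely remapped so a_coll is preserved), a post-collapse plateau or decline,
and a secondary collapse at elevated pressure (rise to π₂ then plateau),
emulating the two-collapse signature of immiscible mixed films.

Mixtures are built in A(π) form::

    A_mix(π) = Σ Xᵢ·Aᵢ(π) − β·X_a·X_b·(1 + π/π_ref)

with a single symmetric interaction term between a designated pair (a, b):
β > 0 → negative excess area (attraction), β < 0 → positive (repulsion).  The
analytic excess free enthalpy, used as the integration oracle, is

    ΔG^exc(π) = −N_A·10⁻²³ · β·X_a·X_b · (π + π²/(2·π_ref))   [J/mol].

Generation is seeded always; unseeded generation is an error so that fixtures
are reproducible by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .isotherms import CompositionSeries, Isotherm, MonofilmError

__all__ = [
    "SpecError",
    "IsothermSpec",
    "MixtureSpec",
    "generate_isotherm",
    "generate_mixture_series",
    "area_of_pressure",
    "analytic_cs_inv",
    "analytic_excess_area",
    "analytic_excess_gibbs",
    "fixture_library",
    "UNIT_FACTOR",
]

#: N_A × 10⁻²³ — J/mol per (Å²·mN/m); see mixing module
UNIT_FACTOR = 6.02214076


class SpecError(MonofilmError):
    """A generator spec violates its invariants."""


@dataclass(frozen=True)
class IsothermSpec:
    """Ground-truth parameters of one synthetic compression run."""

    name: str
    a_lift: float                 # Å², A at π = 0
    a_coll: float                 # Å², A at collapse onset
    pi_coll: float                # mN/m, collapse pressure
    gamma: float = 1.0            # shape exponent of the pre-collapse branch
    plateau: Optional[tuple[float, float]] = None   # (π_t mN/m, width Å²)
    post_collapse: str = "plateau"                  # "plateau" | "decline"
    second_collapse: Optional[float] = None         # mN/m, > pi_coll
    noise_sd_pi: float = 0.0      # mN/m, Gaussian pressure noise
    n_points: int = 400
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (self.a_lift > self.a_coll > 0):
            raise SpecError("a_lift > a_coll > 0")
        if self.pi_coll <= 0:
            raise SpecError("pi_coll > 0")
        if self.gamma <= 0:
            raise SpecError("gamma > 0")
        if self.post_collapse not in ("plateau", "decline"):
            raise SpecError("post_collapse is 'plateau' or 'decline'")
        if self.plateau is not None:
            pi_t, width = self.plateau
            if not (0 < pi_t < self.pi_coll):
                raise SpecError("plateau pi_t must lie below pi_coll")
            if width <= 0:
                raise SpecError("plateau width > 0")
            if width >= _base_area(self, pi_t) - self.a_coll:
                raise SpecError("plateau width leaves no condensed branch")
        if self.second_collapse is not None and self.second_collapse <= self.pi_coll:
            raise SpecError("second collapse pressure must exceed pi_coll")
        if self.noise_sd_pi < 0:
            raise SpecError("noise_sd_pi >= 0")
        if self.n_points < 50:
            raise SpecError("n_points >= 50")


def _base_area(spec: IsothermSpec, pi) -> np.ndarray:
    u = (spec.pi_coll - np.asarray(pi, dtype=float)) / spec.pi_coll
    return spec.a_coll + (spec.a_lift - spec.a_coll) * np.power(np.clip(u, 0.0, 1.0), spec.gamma)


def _plateau_edges(spec: IsothermSpec) -> tuple[float, float, float]:
    """(A_hi, A_lo, k): plateau edge areas and condensed-branch remap factor."""
    pi_t, width = spec.plateau
    a_hi = float(_base_area(spec, pi_t))
    a_lo = a_hi - width
    k = (a_lo - spec.a_coll) / (a_hi - spec.a_coll)
    return a_hi, a_lo, k


def area_of_pressure(spec: IsothermSpec, pi) -> np.ndarray:
    """Closed-form pre-collapse A(π) including the optional plateau.

    At π = π_t exactly, the upper plateau edge is returned (the limit from
    below); this is the oracle that analysis-side interpolation is checked
    against.
    """
    pi = np.asarray(pi, dtype=float)
    if np.any(pi < 0) or np.any(pi > spec.pi_coll + 1e-12):
        raise SpecError(f"oracle defined on [0, {spec.pi_coll}] mN/m")
    a = _base_area(spec, pi)
    if spec.plateau is not None:
        pi_t, _ = spec.plateau
        a_hi, a_lo, k = _plateau_edges(spec)
        below = pi > pi_t
        a = np.where(below, spec.a_coll + (a - spec.a_coll) * k, a)
    return a if a.ndim else float(a)


def analytic_cs_inv(spec: IsothermSpec, pi) -> np.ndarray:
    """Closed-form C_s⁻¹(π) of the plateau-free branch (oracle)."""
    pi = np.asarray(pi, dtype=float)
    u = np.clip((spec.pi_coll - pi) / spec.pi_coll, 1e-15, 1.0)
    delta = spec.a_lift - spec.a_coll
    a = _base_area(spec, pi)
    return a * spec.pi_coll / (spec.gamma * delta) * np.power(u, 1.0 - spec.gamma)


def _pressure_of_area(spec: IsothermSpec, area: np.ndarray) -> np.ndarray:
    """Inverse of the pre-collapse closed form, for sampling in area."""
    delta = spec.a_lift - spec.a_coll
    a = np.asarray(area, dtype=float)
    out = np.zeros_like(a)
    if spec.plateau is None:
        branch = (a < spec.a_lift) & (a > spec.a_coll)
        u = np.power((a[branch] - spec.a_coll) / delta, 1.0 / spec.gamma)
        out[branch] = spec.pi_coll * (1.0 - u)
    else:
        pi_t, _ = spec.plateau
        a_hi, a_lo, k = _plateau_edges(spec)
        upper = (a < spec.a_lift) & (a > a_hi)
        u = np.power((a[upper] - spec.a_coll) / delta, 1.0 / spec.gamma)
        out[upper] = spec.pi_coll * (1.0 - u)
        out[(a <= a_hi) & (a >= a_lo)] = pi_t
        lower = (a < a_lo) & (a > spec.a_coll)
        a_equiv = spec.a_coll + (a[lower] - spec.a_coll) / k
        u = np.power((a_equiv - spec.a_coll) / delta, 1.0 / spec.gamma)
        out[lower] = spec.pi_coll * (1.0 - u)
    out[a <= spec.a_coll] = spec.pi_coll
    out[a >= spec.a_lift] = 0.0
    return out


def generate_isotherm(spec: IsothermSpec) -> Isotherm:
    """Sample a compression run at ``n_points`` decreasing areas.

    The run has a short zero-pressure foot above the lift-off area, the
    closed-form pre-collapse branch, and a post-collapse segment (plateau,
    decline, or rise to a secondary collapse).  Gaussian pressure noise of the
    stated standard deviation is added with the mandatory seed.
    """
    if spec.seed is None:
        raise SpecError("unseeded generation is an error; set spec.seed")
    delta = spec.a_lift - spec.a_coll
    a_start = spec.a_lift + max(0.05 * delta, 1.0)
    post_len = 0.35 * delta
    a_end = spec.a_coll - post_len
    if a_end <= 0:
        raise SpecError("post-collapse segment would reach non-positive area")
    area = np.linspace(a_start, a_end, spec.n_points)

    pressure = np.empty_like(area)
    pre = area >= spec.a_coll
    pressure[pre] = _pressure_of_area(spec, area[pre])
    d = spec.a_coll - area[~pre]
    if spec.second_collapse is not None:
        pi2 = spec.second_collapse
        rise_lo, rise_hi = 0.4 * post_len, 0.85 * post_len
        seg = np.empty_like(d)
        seg[d <= rise_lo] = spec.pi_coll
        mid = (d > rise_lo) & (d <= rise_hi)
        seg[mid] = spec.pi_coll + (pi2 - spec.pi_coll) * (d[mid] - rise_lo) / (rise_hi - rise_lo)
        seg[d > rise_hi] = pi2
        pressure[~pre] = seg
    elif spec.post_collapse == "plateau":
        pressure[~pre] = spec.pi_coll
    else:
        pressure[~pre] = spec.pi_coll * (1.0 - 0.2 * d / post_len)

    if spec.noise_sd_pi > 0:
        rng = np.random.default_rng(spec.seed)
        pressure = pressure + rng.normal(0.0, spec.noise_sd_pi, pressure.size)
        pressure = np.maximum(pressure, -0.45)

    return Isotherm(
        area=area,
        pressure=pressure,
        components=(spec.name,),
        mole_fractions=(1.0,),
        temperature=20.0,
        label=spec.name,
    )


# ---------------------------------------------------------------------------
# mixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureSpec:
    """Ground truth for a mixed-film composition series.

    ``fractions_grid`` lists one mole-fraction vector per mixed film, aligned
    with ``components``; vectors where one entry is 1 reuse the pure member.
    ``interaction_beta`` (Å²) acts between ``interacting_pair``; the sign
    convention is β > 0 → negative excess area (attraction).
    """

    name: str
    components: tuple[IsothermSpec, ...]
    fractions_grid: tuple[tuple[float, ...], ...]
    interaction_beta: float = 0.0
    pi_ref: float = 30.0
    interacting_pair: tuple[int, int] = (0, 1)
    fixed_ratio: Optional[float] = None
    noise_sd_pi: float = 0.0
    n_points: int = 400
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.components) not in (2, 3):
            raise SpecError("2 or 3 components")
        for x in self.fractions_grid:
            if len(x) != len(self.components):
                raise SpecError("one fraction per component")
            if abs(sum(x) - 1.0) > 1e-9 or any(xi < 0 or xi > 1 for xi in x):
                raise SpecError("fractions each sum to 1 and lie in [0, 1]")
        if self.pi_ref <= 0:
            raise SpecError("pi_ref > 0")
        i, j = self.interacting_pair
        if i == j or not (0 <= i < len(self.components)) or not (0 <= j < len(self.components)):
            raise SpecError("interacting_pair must index two distinct components")


def analytic_excess_area(spec: MixtureSpec, fractions: Sequence[float], pi) -> np.ndarray:
    """A^exc(π) = −β·X_a·X_b·(1 + π/π_ref) — the generator's exact excess area."""
    i, j = spec.interacting_pair
    xab = fractions[i] * fractions[j]
    return -spec.interaction_beta * xab * (1.0 + np.asarray(pi, dtype=float) / spec.pi_ref)


def analytic_excess_gibbs(spec: MixtureSpec, fractions: Sequence[float], pi) -> np.ndarray:
    """ΔG^exc(π) in J/mol — exact antiderivative of the excess area term."""
    i, j = spec.interacting_pair
    xab = fractions[i] * fractions[j]
    pi = np.asarray(pi, dtype=float)
    return -UNIT_FACTOR * spec.interaction_beta * xab * (pi + pi**2 / (2.0 * spec.pi_ref))


def _child_seed(seed: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_mixture_series(spec: MixtureSpec) -> CompositionSeries:
    """Build a :class:`CompositionSeries` with known interaction ground truth.

    Pure members are generated from their own specs (seeded from the mixture
    seed); each mixed film is sampled on a uniform pressure grid up to the
    lowest collapse pressure among its present components, with a short
    zero-pressure foot and a post-collapse plateau appended.  β = 0 yields
    exactly ideal mixtures.
    """
    if spec.seed is None:
        raise SpecError("unseeded generation is an error; set spec.seed")
    # the series' noise level governs every member, so a noise-free series
    # (noise_sd_pi = 0) is exactly ideal when beta = 0
    comps = [
        dataclasses.replace(c, seed=_child_seed(spec.seed, k), noise_sd_pi=spec.noise_sd_pi)
        for k, c in enumerate(spec.components)
    ]
    pures = tuple(generate_isotherm(c) for c in comps)
    names = tuple(c.name for c in comps)

    mixed: list[Isotherm] = []
    for m, fractions in enumerate(spec.fractions_grid):
        x = np.asarray(fractions, dtype=float)
        if np.any(x > 1.0 - 1e-12):
            k = int(np.argmax(x))
            iso = pures[k]
            mixed.append(
                Isotherm(
                    area=iso.area.copy(),
                    pressure=iso.pressure.copy(),
                    components=names,
                    mole_fractions=tuple(x),
                    temperature=20.0,
                    label=f"{spec.name} X({names[-1]})={x[-1]:.2f}",
                )
            )
            continue
        present = x > 1e-12
        pi_lim = min(c.pi_coll for c, keep in zip(comps, present) if keep)
        n_foot = max(5, spec.n_points // 20)
        n_post = max(5, spec.n_points // 10)
        n_branch = spec.n_points - n_foot - n_post
        pi = np.linspace(0.0, pi_lim, n_branch)
        # represent any component's LE-LC plateau discontinuity exactly, so
        # the mixture and the resampled ideal reference share the same jump
        for c, keep in zip(comps, present):
            if keep and c.plateau is not None and c.plateau[0] < pi_lim:
                pi = np.unique(np.concatenate([pi, [c.plateau[0], c.plateau[0] + 1e-6]]))
        a_mix = np.zeros_like(pi)
        for c, xi in zip(comps, x):
            if xi > 1e-12:
                a_mix += xi * np.asarray(area_of_pressure(c, np.minimum(pi, c.pi_coll)))
        a_mix += analytic_excess_area(spec, x, pi)
        if np.any(a_mix <= 0):
            raise SpecError("interaction_beta too large: mixed area reaches zero")
        if np.any(np.diff(a_mix) >= 0):
            raise SpecError("interaction_beta too large: mixed area not decreasing in pressure")
        foot_a = np.linspace(1.04 * a_mix[0], a_mix[0], n_foot, endpoint=False)
        post_a = np.linspace(a_mix[-1], 0.85 * a_mix[-1], n_post + 1)[1:]
        area = np.concatenate([foot_a, a_mix, post_a])
        pressure = np.concatenate([np.zeros(n_foot), pi, np.full(n_post, pi_lim)])
        if spec.noise_sd_pi > 0:
            rng = np.random.default_rng(_child_seed(spec.seed, 100 + m))
            pressure = np.maximum(
                pressure + rng.normal(0.0, spec.noise_sd_pi, pressure.size), -0.45
            )
        mixed.append(
            Isotherm(
                area=area,
                pressure=pressure,
                components=names,
                mole_fractions=tuple(x),
                temperature=20.0,
                label=f"{spec.name} X({names[-1]})={x[-1]:.2f}",
            )
        )
    return CompositionSeries(
        system_name=spec.name,
        components=names,
        pure_isotherms=pures,
        mixed_isotherms=mixed,
        fixed_ratio=spec.fixed_ratio,
    )


# ---------------------------------------------------------------------------
# bundled fixture library
# ---------------------------------------------------------------------------

def _gamma_for_cs(a_lift: float, a_coll: float, pi_coll: float, cs_max: float) -> float:
    """γ that places the closed-form C_s⁻¹ at π = 0 at ``cs_max``."""
    return pi_coll * a_lift / ((a_lift - a_coll) * cs_max)


def fixture_library(seed: int = 20130515) -> dict:
    """Named generator specs emulating the studied film-formers.

    Single-chain antitumor lipids (HePC = miltefosine C16, OcPC C18, ErPC
    C22:1) are parameterized from their measured monolayer characteristics
    (lift-off / collapse area / collapse pressure, with γ set so the implied
    compression-modulus maximum matches the measured one); the membrane lipids
    use their textbook isotherm features (DPPC with its LE–LC plateau near
    5 mN/m and collapse at 63 mN/m; POPC liquid-expanded, collapse 50 mN/m;
    cholesterol very condensed, collapse 44 mN/m, C_s⁻¹ ≈ 1000 mN/m).  The
    default pressure noise of 0.05 mN/m reflects a ±0.1 mN/m Wilhelmy-plate
    accuracy.

    Mixture fixtures: ``hepc_chol`` (attractive, β calibrated so the 1:1 film
    has ΔG^exc(30 mN/m) = −2500 J/mol); ``normal_membrane`` — cholesterol/DPPC
    host at ratio 0.67 (X_chol ≈ 0.40 of the host film) with a repulsive
    APC–cholesterol term; ``tumor_membrane`` — cholesterol/POPC host at ratio
    0.25 with an attractive term; ``ocpc_chol_x07`` — a single two-collapse
    run (38 then 53 mN/m) emulating an immiscible OcPC-rich film.
    """
    noise = 0.05
    lib: dict = {}
    lib["hepc_like"] = IsothermSpec(
        "HePC", a_lift=98.0, a_coll=32.0, pi_coll=31.0,
        gamma=_gamma_for_cs(98.0, 32.0, 31.0, 41.0),
        noise_sd_pi=noise, seed=_child_seed(seed, 1),
    )
    lib["ocpc_like"] = IsothermSpec(
        "OcPC", a_lift=70.0, a_coll=28.0, pi_coll=38.0,
        gamma=_gamma_for_cs(70.0, 28.0, 38.0, 63.0),
        noise_sd_pi=noise, seed=_child_seed(seed, 2),
    )
    lib["erpc_like"] = IsothermSpec(
        "ErPC", a_lift=93.0, a_coll=40.0, pi_coll=44.0,
        gamma=_gamma_for_cs(93.0, 40.0, 44.0, 78.0),
        noise_sd_pi=noise, seed=_child_seed(seed, 3),
    )
    lib["dppc_like"] = IsothermSpec(
        "DPPC", a_lift=95.0, a_coll=40.0, pi_coll=63.0, gamma=1.0,
        plateau=(5.0, 15.0), noise_sd_pi=noise, seed=_child_seed(seed, 4),
    )
    lib["popc_like"] = IsothermSpec(
        "POPC", a_lift=100.0, a_coll=41.0, pi_coll=50.0, gamma=1.0,
        noise_sd_pi=noise, seed=_child_seed(seed, 5),
    )
    lib["chol_like"] = IsothermSpec(
        "cholesterol", a_lift=40.0, a_coll=38.0, pi_coll=44.0,
        gamma=_gamma_for_cs(40.0, 38.0, 44.0, 1000.0),
        noise_sd_pi=noise, seed=_child_seed(seed, 6),
    )
    lib["ocpc_chol_x07"] = IsothermSpec(
        "OcPC/cholesterol X=0.7", a_lift=60.0, a_coll=30.0, pi_coll=38.0,
        gamma=1.0, second_collapse=53.0, noise_sd_pi=noise, seed=_child_seed(seed, 7),
    )

    x_apc = (0.0, 0.1, 0.3, 0.5, 0.7, 0.9, 1.0)
    lib["hepc_chol"] = MixtureSpec(
        name="HePC/cholesterol",
        components=(lib["chol_like"], lib["hepc_like"]),
        fractions_grid=tuple((1.0 - x, x) for x in x_apc),
        interaction_beta=36.9, pi_ref=30.0, interacting_pair=(0, 1),
        noise_sd_pi=noise, seed=_child_seed(seed, 8),
    )

    def _ternary(name: str, host2: IsothermSpec, ratio: float, beta: float, idx: int) -> MixtureSpec:
        c_host = ratio / (1.0 + ratio)      # cholesterol share of the host film
        grid = []
        for x in x_apc:
            grid.append(((1.0 - x) * c_host, (1.0 - x) * (1.0 - c_host), x))
        return MixtureSpec(
            name=name,
            components=(lib["chol_like"], host2, lib["hepc_like"]),
            fractions_grid=tuple(grid),
            interaction_beta=beta, pi_ref=30.0, interacting_pair=(0, 2),
            fixed_ratio=ratio, noise_sd_pi=noise, seed=_child_seed(seed, idx),
        )

    # normal leucocyte membrane: cholesterol/DPPC 0.67, APC incorporation
    # thermodynamically unfavorable (repulsive term, ΔG^exc > 0)
    lib["normal_membrane"] = _ternary("chol/DPPC/APC", lib["dppc_like"], 0.67, -15.0, 9)
    # leukemic cell membrane: cholesterol/POPC 0.25, favorable (ΔG^exc < 0)
    lib["tumor_membrane"] = _ternary("chol/POPC/APC", lib["popc_like"], 0.25, +15.0, 10)
    return lib
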