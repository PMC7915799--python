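"""Hydraulic model of nasal airflow resistance.

The nasal cavity is treated as two parallel ducts (the nasal passages)
sharing a common pressure drop between the nares and the nasopharynx.
Each duct is a series of short sections with cross-sectional area ``S``,
hydraulic diameter ``dh = 4S/P`` and length ``Δl``.  The pressure loss
of a duct carrying volumetric flow ``Q`` sums Darcy friction and local
losses:

    Δp = Σ [ λ(Re) · ρ · Δl / dh + ξ · ρ ] · Q² / (2 S²)

with λ = 64/Re for laminar flow and λ = 0.32/Re^0.25 for turbulent flow
(Re evaluated per section from the mean velocity Q/S).  In the laminar
regime λ ∝ 1/Q makes Δp linear in Q, and for a circular tube the sum
reduces exactly to Hagen–Poiseuille.

The two parallel passages split the total flow so that their pressure
drops are equal (continuity Q₁ + Q₂ = QΣ, equal Δp); the split is found
by bracketed root finding, unique because Δp is strictly increasing
in Q.  The clinically reported quantity is the aerodynamic nasal drag
coefficient A = Δp/Q in kPa/(L/s) — indicator x5 — obtainable either
from this geometric model or directly from a rhinomanometric
(Δp, Q) pair.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "AIR_DENSITY",
    "AIR_VISCOSITY",
    "RE_TRANSITION",
    "ChannelSection",
    "ChannelModel",
    "FlowResult",
    "hydraulic_diameter",
    "reynolds",
    "darcy_lambda",
    "pressure_drop",
    "channel_resistance",
    "split_flow",
    "drag_coefficient",
    "circular_tube",
    "load_channel_csv",
]

AIR_DENSITY = 1.205  # kg/m^3
AIR_VISCOSITY = 1.81e-5  # Pa*s, dry air near 20 degC
RE_TRANSITION = 2300.0  # classical pipe-flow transition
TURBULENT_COEFF = 0.32  # lambda = coeff / Re^0.25 in the turbulent regime


def hydraulic_diameter(S: float, P: float) -> float:
    """Equivalent diameter 4S/P of a duct cross-section (SI units)."""
    if S <= 0 or P <= 0:
        raise ValueError(f"area and perimeter must be positive, got S={S}, P={P}")
    return 4.0 * S / P


@dataclass(frozen=True)
class ChannelSection:
    """One calculated section of an air channel (SI units).

    ``xi`` is the dimensionless local-loss coefficient assigned to the
    section's transition (0 when no expansion/contraction loss applies).
    """

    S: float  # cross-sectional area, m^2
    P: float  # perimeter, m
    dh: float  # hydraulic diameter, m
    dl: float  # section length, m
    xi: float = 0.0

    def __post_init__(self) -> None:
        for name in ("S", "P", "dh", "dl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"section {name} must be positive, got {getattr(self, name)}")
        if self.xi < 0:
            raise ValueError(f"xi must be non-negative, got {self.xi}")

    @classmethod
    def from_area_perimeter(cls, S: float, P: float, dl: float, xi: float = 0.0) -> "ChannelSection":
        return cls(S=S, P=P, dh=hydraulic_diameter(S, P), dl=dl, xi=xi)


@dataclass(frozen=True)
class ChannelModel:
    """Sectioned duct with the fluid properties used to evaluate it."""

    sections: tuple[ChannelSection, ...]
    rho: float = AIR_DENSITY
    mu: float = AIR_VISCOSITY
    re_transition: float = RE_TRANSITION

    def __post_init__(self) -> None:
        object.__setattr__(self, "sections", tuple(self.sections))
        if not self.sections:
            raise ValueError("channel needs at least one section")
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("rho and mu must be positive")


@dataclass
class FlowResult:
    """Flow split of two parallel channels at a common pressure drop."""

    q1: float  # m^3/s
    q2: float
    q_total: float
    dp_pa: float
    a1: float  # Pa/(m^3/s)^2, so that dp = Q^2 * A at the solved Q
    a2: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def dp_kpa(self) -> float:
        return self.dp_pa / 1000.0

    @property
    def q_total_lps(self) -> float:
        return self.q_total * 1000.0

    @property
    def drag_total_kpa_per_lps(self) -> float:
        """Integral nasal drag coefficient A = Δp/QΣ in kPa/(L/s)."""
        return drag_coefficient(self.dp_kpa, self.q_total_lps)


def reynolds(Q: float, S: float, dh: float, rho: float = AIR_DENSITY, mu: float = AIR_VISCOSITY) -> float:
    """Section Reynolds number from the mean velocity Q/S."""
    if min(Q, S, dh, rho, mu) <= 0:
        raise ValueError("all arguments to reynolds must be positive")
    return rho * (Q / S) * dh / mu


def darcy_lambda(Re: float, regime: str | None = None, *, re_transition: float = RE_TRANSITION,
                 turbulent_coeff: float = TURBULENT_COEFF) -> float:
    """Darcy friction coefficient: 64/Re laminar, coeff/Re^0.25 turbulent.

    ``regime`` forces "laminar" or "turbulent"; by default it is chosen
    by comparing Re with the transition threshold.
    """
    if Re <= 0:
        raise ValueError(f"Reynolds number must be positive, got {Re}")
    if regime is None:
        regime = "laminar" if Re < re_transition else "turbulent"
    if regime == "laminar":
        return 64.0 / Re
    if regime == "turbulent":
        return turbulent_coeff / Re ** 0.25
    raise ValueError(f"unknown regime {regime!r}")


def _section_terms(channel: ChannelModel, Q: float, lambda_override: float | None):
    """Per-section (dp, Re, lambda, regime) at flow Q."""
    terms = []
    for sec in channel.sections:
        Re = reynolds(Q, sec.S, sec.dh, channel.rho, channel.mu)
        regime = "laminar" if Re < channel.re_transition else "turbulent"
        lam = lambda_override if lambda_override is not None else darcy_lambda(
            Re, regime)
        dyn = channel.rho * Q * Q / (2.0 * sec.S * sec.S)
        dp = (lam * sec.dl / sec.dh + sec.xi) * dyn
        terms.append((dp, Re, lam, regime))
    return terms


def pressure_drop(channel: ChannelModel, Q: float, *, lambda_override: float | None = None) -> float:
    """Total pressure loss (Pa) of a channel at volumetric flow Q (m³/s).

    Sums friction and local losses over the sections with λ evaluated at
    the per-section Reynolds number.  ``lambda_override`` pins λ (e.g. 0
    to isolate local losses).
    """
    if Q <= 0:
        raise ValueError(f"flow must be positive, got {Q}")
    return float(sum(t[0] for t in _section_terms(channel, Q, lambda_override)))


def channel_resistance(channel: ChannelModel, Q: float) -> float:
    """Drag constant A (Pa·s²/m⁶) with Δp = Q²·A, λ evaluated at Q.

    In the laminar regime λ ∝ 1/Q so A itself scales as 1/Q and Δp is
    linear in Q, as expected for Poiseuille flow.
    """
    return pressure_drop(channel, Q) / (Q * Q)


def split_flow(channel1: ChannelModel, channel2: ChannelModel, q_total: float,
               *, rtol: float = 1e-8) -> FlowResult:
    """Split a total flow between two parallel channels.

    Finds Q₁ ∈ (0, QΣ) with Δp₁(Q₁) = Δp₂(QΣ − Q₁).  Δp is strictly
    increasing in Q for every valid channel, so the difference is
    strictly monotone and the root unique.
    """
    if q_total <= 0:
        raise ValueError(f"total flow must be positive, got {q_total}")

    def imbalance(q1: float) -> float:
        return pressure_drop(channel1, q1) - pressure_drop(channel2, q_total - q1)

    eps = q_total * 1e-12
    lo, hi = eps, q_total - eps
    f_lo, f_hi = imbalance(lo), imbalance(hi)
    if not (f_lo < 0 < f_hi):
        raise ValueError("cannot bracket the flow split; degenerate channel geometry")
    q1 = brentq(imbalance, lo, hi, rtol=rtol)
    q2 = q_total - q1
    dp = pressure_drop(channel1, q1)
    diag = {
        "channel1": [
            {"Re": Re, "lambda": lam, "regime": reg}
            for (_, Re, lam, reg) in _section_terms(channel1, q1, None)
        ],
        "channel2": [
            {"Re": Re, "lambda": lam, "regime": reg}
            for (_, Re, lam, reg) in _section_terms(channel2, q2, None)
        ],
    }
    return FlowResult(
        q1=q1, q2=q2, q_total=q_total, dp_pa=dp,
        a1=channel_resistance(channel1, q1),
        a2=channel_resistance(channel2, q2),
        diagnostics=diag,
    )


def drag_coefficient(dp_kpa: float, q_lps: float) -> float:
    """Aerodynamic nasal drag A = Δp/Q in kPa/(L/s) — indicator x5.

    Accepts a rhinomanometric pressure-drop/flow pair; Δp = 0 gives 0.
    """
    if q_lps <= 0:
        raise ValueError(f"flow must be positive, got {q_lps}")
    if dp_kpa < 0:
        raise ValueError(f"pressure drop must be non-negative, got {dp_kpa}")
    return dp_kpa / q_lps


# ---------------------------------------------------------------------------
# geometry constructors / loaders


def circular_tube(diameter_m: float, length_m: float, *, n_sections: int = 1,
                  xi: float = 0.0, rho: float = AIR_DENSITY, mu: float = AIR_VISCOSITY) -> ChannelModel:
    """Straight circular tube split into equal sections (dh = d)."""
    if diameter_m <= 0 or length_m <= 0:
        raise ValueError("diameter and length must be positive")
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    S = np.pi * diameter_m ** 2 / 4.0
    P = np.pi * diameter_m
    dl = length_m / n_sections
    secs = [ChannelSection.from_area_perimeter(S, P, dl, xi=xi if i == 0 else 0.0)
            for i in range(n_sections)]
    return ChannelModel(tuple(secs), rho=rho, mu=mu)


def load_channel_csv(path: str | Path, *, rho: float = AIR_DENSITY, mu: float = AIR_VISCOSITY) -> ChannelModel:
    """Load a channel from CSV rows ``S_mm2, P_mm, dl_mm, xi``."""
    path = Path(path)
    sections = []
    with path.open(newline="") as fh:
        for row in csv.DictReader(fh):
            sections.append(ChannelSection.from_area_perimeter(
                S=float(row["S_mm2"]) * 1e-6,
                P=float(row["P_mm"]) * 1e-3,
                dl=float(row["dl_mm"]) * 1e-3,
                xi=float(row.get("xi", 0) or 0),
            ))
    if not sections:
        raise ValueError(f"no sections in {path}")
    return ChannelModel(tuple(sections), rho=rho, mu=mu)


def dump_channel_json(channel: ChannelModel) -> dict:
    """JSON-serialisable description of a channel (reporting aid)."""
    return {
        "rho_kg_m3": channel.rho,
        "mu_pa_s": channel.mu,
        "sections": [
            {"S_m2": s.S, "P_m": s.P, "dh_m": s.dh, "dl_m": s.dl, "xi": s.xi}
            for s in channel.sections
        ],
    }
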