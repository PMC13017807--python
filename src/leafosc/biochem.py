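"""C3 photosynthesis biochemistry with temperature responses.

Implements the two-branch (carboxylation-limited / electron-transport-limited)
net assimilation model with peaked-Arrhenius temperature corrections, the
shared mathematical core used by the calibration, marginal-cost and coupled
stomatal-optimisation modules.

Conventions
-----------
* Rates (``Vcmax``, ``Jmax``, ``Rd``, ``A``, ``J``) are in μmol·m⁻²·s⁻¹.
* CO2 mole fractions (``ci``, ``Kc``, ``Km``, ``gamma_star``) in μmol·mol⁻¹;
  the O2 mole fraction ``O`` and ``Ko`` in mmol·mol⁻¹.
* Temperatures are Kelvin where named ``Tk``; the reference temperature in
  all response functions is 298 K (as the constants were published), while
  ``Tk`` itself is derived from Celsius as ``Tl + 273.15``.
* Mesophyll conductance is treated as infinite, so the chloroplast CO2
  concentration is identified with ``ci`` throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

__all__ = [
    "GAS_CONSTANT",
    "T_REF",
    "CELSIUS_TO_KELVIN",
    "Limitation",
    "SpeciesParams",
    "MeteoInputs",
    "KineticsAtT",
    "AssimilationResult",
    "peaked_arrhenius",
    "gamma_star",
    "michaelis",
    "electron_transport",
    "kinetics_at",
    "assimilation",
    "assimilation_slope",
]

#: Universal gas constant, J·mol⁻¹·K⁻¹.
GAS_CONSTANT = 8.314

#: Reference Kelvin temperature used inside the response functions.
#: Kept at 298 (not 298.15) to match the published constants exactly.
T_REF = 298.0

#: Offset used to build ``Tk`` from a Celsius leaf temperature.
CELSIUS_TO_KELVIN = 273.15

# Prefactors (value at T_REF) and activation energies of the kinetic
# coefficient response functions.
_GAMMA_STAR_25 = 42.75   # μmol·mol⁻¹
_GAMMA_STAR_EA = 37830.0  # J·mol⁻¹
_KC_25 = 274.6           # μmol·mol⁻¹
_KC_EA = 80500.0
_KO_25 = 419.8           # mmol·mol⁻¹
_KO_EA = 14500.0


class Limitation(str, Enum):
    """Which biochemical branch limits net assimilation."""

    VC = "Vc"  # carboxylation (Rubisco) limited
    VJ = "Vj"  # RuBP-regeneration (electron transport) limited


def _require_finite(**values: float) -> None:
    for name, v in values.items():
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class SpeciesParams:
    """Species-level photosynthetic traits and fixed coefficients.

    Defaults are the calibrated citrus values and standard coefficients.
    ``rd_temperature_mode`` selects how dark respiration responds to
    temperature: ``"constant"`` keeps ``Rd = Rd25`` at every temperature
    (the default; no deactivation coefficients are available for Rd), while
    ``"arrhenius"`` applies a simple exponential response with activation
    energy ``Ea_rd``.
    """

    Vcmax25: float = 43.21   # μmol·m⁻²·s⁻¹
    Jmax25: float = 75.56    # μmol·m⁻²·s⁻¹
    Rd25: float = 1.77       # μmol·m⁻²·s⁻¹
    alpha: float = 0.24      # quantum yield of electron transport, -
    O: float = 210.0         # intercellular O2, mmol·mol⁻¹
    gmin: float = 0.01       # minimum stomatal conductance, mol·m⁻²·s⁻¹
    R: float = GAS_CONSTANT  # J·mol⁻¹·K⁻¹
    dS_v: float = 629.26     # entropy term for Vcmax, J·mol⁻¹·K⁻¹
    dS_j: float = 631.88     # entropy term for Jmax, J·mol⁻¹·K⁻¹
    Ea_v: float = 58550.0    # activation energy for Vcmax, J·mol⁻¹
    Ea_j: float = 29680.0    # activation energy for Jmax, J·mol⁻¹
    Hd: float = 200000.0     # deactivation energy, J·mol⁻¹
    rd_temperature_mode: str = "constant"
    Ea_rd: float = 46390.0   # only used in "arrhenius" rd mode
    gm: float = math.inf     # mesophyll conductance: fixed at infinity

    def __post_init__(self) -> None:
        for name in ("Vcmax25", "Jmax25", "Rd25", "gmin", "O", "R"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"SpeciesParams.{name} must be positive and finite, got {v!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"SpeciesParams.alpha must lie in (0, 1), got {self.alpha!r}")
        if self.rd_temperature_mode not in ("constant", "arrhenius"):
            raise ValueError(
                "rd_temperature_mode must be 'constant' or 'arrhenius', "
                f"got {self.rd_temperature_mode!r}"
            )
        if not math.isinf(self.gm):
            raise ValueError("finite mesophyll conductance is not supported (gm must be inf)")

    def with_(self, **kwargs) -> "SpeciesParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class MeteoInputs:
    """Leaf-surface meteorological drivers for a single observation.

    ``Tl`` (leaf temperature, °C) defaults to the leaf-surface air
    temperature ``Ta``; the Kelvin temperature ``Tk`` is always
    ``Tl + 273.15``.
    """

    Q: float            # photosynthetic photon flux density, μmol·m⁻²·s⁻¹
    Ta: float           # leaf-surface air temperature, °C
    D: float            # vapor pressure deficit, kPa
    ca: float           # ambient CO2, μmol·mol⁻¹
    P: float            # air pressure, kPa
    Tl: Optional[float] = None
    day_id: Optional[str] = None
    timestamp: Optional[str] = None

    def __post_init__(self) -> None:
        _require_finite(Q=self.Q, Ta=self.Ta, D=self.D, ca=self.ca, P=self.P)
        if self.Q < 0:
            raise ValueError(f"Q must be >= 0, got {self.Q!r}")
        if self.D <= 0:
            raise ValueError(f"D must be > 0, got {self.D!r}")
        if self.P <= 0:
            raise ValueError(f"P must be > 0, got {self.P!r}")
        if self.ca <= 0:
            raise ValueError(f"ca must be > 0, got {self.ca!r}")
        if self.Tl is None:
            object.__setattr__(self, "Tl", self.Ta)

    @property
    def Tk(self) -> float:
        """Leaf Kelvin temperature, ``Tl + 273.15``."""
        return self.Tl + CELSIUS_TO_KELVIN


@dataclass(frozen=True)
class KineticsAtT:
    """Temperature-adjusted kinetic state at one observation.

    All rate fields are at the observation's ``Tk``; ``J`` additionally
    depends on the light level ``Q`` the bundle was built with.
    """

    Vcmax: float        # μmol·m⁻²·s⁻¹
    Jmax: float         # μmol·m⁻²·s⁻¹
    Rd: float           # μmol·m⁻²·s⁻¹
    Kc: float           # μmol·mol⁻¹
    Ko: float           # mmol·mol⁻¹
    Km: float           # μmol·mol⁻¹
    gamma_star: float   # μmol·mol⁻¹
    J: float            # μmol·m⁻²·s⁻¹
    alpha: float = 0.24
    Q: float = 0.0


@dataclass(frozen=True)
class AssimilationResult:
    """Net assimilation split into its two limiting branches.

    ``A = min(Ac, Aj)``; ``limitation`` is ``Vc`` whenever ``Ac <= Aj``
    (ties assigned to the carboxylation branch). ``cc`` equals ``ci``
    because mesophyll conductance is infinite.
    """

    A: float
    Ac: float
    Aj: float
    wc: float
    wJ: float
    limitation: Limitation
    cc: float


def peaked_arrhenius(k25: float, Tk: float, Ea: float, dS: float, Hd: float,
                     R: float = GAS_CONSTANT) -> float:
    """Peaked Arrhenius temperature response normalised to 25 °C.

    ``k25 · exp[Ea(Tk−298)/(298·R·Tk)] · [1+exp((298·dS−Hd)/(298R))]
    / [1+exp((Tk·dS−Hd)/(Tk·R))]``

    Equals ``k25`` exactly at ``Tk = 298``.
    """
    _require_finite(k25=k25, Tk=Tk, Ea=Ea, dS=dS, Hd=Hd)
    if k25 <= 0:
        raise ValueError(f"k25 must be > 0, got {k25!r}")
    if Tk <= 0:
        raise ValueError(f"Tk must be > 0 K, got {Tk!r}")
    arr = math.exp(Ea * (Tk - T_REF) / (T_REF * R * Tk))
    peak = (1.0 + math.exp((T_REF * dS - Hd) / (T_REF * R))) \
        / (1.0 + math.exp((Tk * dS - Hd) / (Tk * R)))
    return k25 * arr * peak


def _arrhenius_factor(Tk: float, Ea: float, R: float = GAS_CONSTANT) -> float:
    return math.exp(Ea * (Tk - T_REF) / (T_REF * R * Tk))


def gamma_star(Tk: float, R: float = GAS_CONSTANT) -> float:
    """CO2 compensation concentration of the chloroplast, μmol·mol⁻¹."""
    _require_finite(Tk=Tk)
    if Tk <= 0:
        raise ValueError(f"Tk must be > 0 K, got {Tk!r}")
    return _GAMMA_STAR_25 * _arrhenius_factor(Tk, _GAMMA_STAR_EA, R)


def michaelis(Tk: float, O: float = 210.0, R: float = GAS_CONSTANT) -> tuple[float, float, float]:
    """Michaelis-Menten coefficients ``(Kc, Ko, Km)`` at ``Tk``.

    ``Km = Kc·(1 + O/Ko)`` with ``Kc`` in μmol·mol⁻¹ and ``Ko``/``O`` in
    mmol·mol⁻¹.
    """
    _require_finite(Tk=Tk, O=O)
    if Tk <= 0:
        raise ValueError(f"Tk must be > 0 K, got {Tk!r}")
    if O <= 0:
        raise ValueError(f"O must be > 0, got {O!r}")
    Kc = _KC_25 * _arrhenius_factor(Tk, _KC_EA, R)
    Ko = _KO_25 * _arrhenius_factor(Tk, _KO_EA, R)
    Km = Kc * (1.0 + O / Ko)
    return Kc, Ko, Km


def electron_transport(Q: float, Jmax: float, alpha: float) -> float:
    """Electron transport rate ``J = αQ / sqrt(1 + α²Q²/Jmax²)``.

    Saturates toward ``Jmax`` at high light; ``J(0) = 0``.
    """
    _require_finite(Q=Q, Jmax=Jmax, alpha=alpha)
    if Q < 0:
        raise ValueError(f"Q must be >= 0, got {Q!r}")
    if Jmax <= 0:
        raise ValueError(f"Jmax must be > 0, got {Jmax!r}")
    aq = alpha * Q
    return aq / math.sqrt(1.0 + aq * aq / (Jmax * Jmax))


def kinetics_at(meteo: MeteoInputs, params: SpeciesParams) -> KineticsAtT:
    """Bundle all temperature-adjusted kinetic quantities for one record."""
    Tk = meteo.Tk
    Vcmax = peaked_arrhenius(params.Vcmax25, Tk, params.Ea_v, params.dS_v, params.Hd, params.R)
    Jmax = peaked_arrhenius(params.Jmax25, Tk, params.Ea_j, params.dS_j, params.Hd, params.R)
    if params.rd_temperature_mode == "arrhenius":
        Rd = params.Rd25 * _arrhenius_factor(Tk, params.Ea_rd, params.R)
    else:
        Rd = params.Rd25
    Kc, Ko, Km = michaelis(Tk, params.O, params.R)
    gs_ = gamma_star(Tk, params.R)
    J = electron_transport(meteo.Q, Jmax, params.alpha)
    return KineticsAtT(Vcmax=Vcmax, Jmax=Jmax, Rd=Rd, Kc=Kc, Ko=Ko, Km=Km,
                       gamma_star=gs_, J=J, alpha=params.alpha, Q=meteo.Q)


def assimilation(ci: float, kin: KineticsAtT) -> AssimilationResult:
    """Net assimilation at intercellular CO2 ``ci``.

    Ac = Vcmax·(ci−Γ*)/(ci+Km) − Rd  (carboxylation limited)
    Aj = J·(ci−Γ*)/(4ci+8Γ*) − Rd    (electron-transport limited)
    A  = min(Ac, Aj)
    """
    _require_finite(ci=ci)
    if ci <= 0:
        raise ValueError(f"ci must be > 0, got {ci!r}")
    g = kin.gamma_star
    wc = kin.Vcmax * ci / (ci + kin.Km)
    wJ = kin.J * ci / (4.0 * ci + 8.0 * g)
    Ac = kin.Vcmax * (ci - g) / (ci + kin.Km) - kin.Rd
    Aj = kin.J * (ci - g) / (4.0 * ci + 8.0 * g) - kin.Rd
    if Ac <= Aj:
        return AssimilationResult(A=Ac, Ac=Ac, Aj=Aj, wc=wc, wJ=wJ,
                                  limitation=Limitation.VC, cc=ci)
    return AssimilationResult(A=Aj, Ac=Ac, Aj=Aj, wc=wc, wJ=wJ,
                              limitation=Limitation.VJ, cc=ci)


def assimilation_slope(ci: float, kin: KineticsAtT, branch: Limitation) -> float:
    """Analytic ∂A/∂ci of the given branch; strictly positive.

    Vc branch: ``Vcmax(Km+Γ*)/(ci+Km)²``
    Vj branch: ``3JΓ*/(4(ci+2Γ*)²)``
    """
    _require_finite(ci=ci)
    if ci <= 0:
        raise ValueError(f"ci must be > 0, got {ci!r}")
    branch = Limitation(branch)
    g = kin.gamma_star
    if branch is Limitation.VC:
        return kin.Vcmax * (kin.Km + g) / (ci + kin.Km) ** 2
    return 3.0 * kin.J * g / (4.0 * (ci + 2.0 * g) ** 2)
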