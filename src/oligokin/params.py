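"""Domain types: rate constants, experimental conditions, geometry, protocols.

Units contract (used throughout the package):

* concentrations        molar (M)
* surface densities     molecules per um^2
* time                  seconds
* lengths (geometry)    nanometres
* bimolecular rates     M^-1 s^-1
* surface capture rates s^-1 um^2  (rate constant x epitope density -> s^-1)
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Mapping

__all__ = [
    "RateParameters",
    "SpaParameters",
    "Condition",
    "ScreeningGeometry",
    "Protocol",
    "dnp_density",
    "IGG1_PARAMS",
    "IGG3_PARAMS",
    "IGG4_PARAMS",
    "default_parameters",
]

#: Whole IgG on-rate for an epitope is this multiple of the Fab fragment on-rate
#: (two Fab arms minus steric interference).
IGG_OVER_FAB_ON_RATE = 1.7

#: Linear map from DNP-lipid mole fraction to epitope surface density,
#: anchored at 0.5% -> 8.1e3 um^-2 (equivalently 5% -> 81e3 um^-2).
DNP_DENSITY_PER_MOLE_FRACTION = 1.62e6  # um^-2

#: Conversion between a surface density change of 1 IgG um^-2 and the molarity
#: change in a 1-um-high, instantaneously mixed surface compartment.
SURFACE_COMPARTMENT_ALPHA = 1.0 / 6.022e8  # M per um^-2


def dnp_density(mole_fraction: float) -> float:
    """Epitope surface density (um^-2) for a DNP-lipid mole fraction.

    Linear through the measured anchor 0.5% -> 8.1e3 molecules um^-2, so
    5% -> 81e3 um^-2, 2.5% -> 40.5e3 um^-2 and 0.85% -> 13.77e3 um^-2.
    """
    if not 0.0 <= mole_fraction <= 1.0:
        raise ValueError(f"DNP mole fraction must be in [0, 1], got {mole_fraction}")
    return mole_fraction * DNP_DENSITY_PER_MOLE_FRACTION


@dataclass(frozen=True)
class SpaParameters:
    """Kinetics of the SpA B-domain binding an IgG Fc-Fc interface."""

    kC: float = 1.9e5       # M^-1 s^-1, association
    k_minusC: float = 3.2e-3  # s^-1, dissociation

    def __post_init__(self) -> None:
        if self.kC <= 0 or self.k_minusC <= 0:
            raise ValueError("SpA rate constants must be strictly positive")

    @property
    def kd(self) -> float:
        """Equilibrium dissociation constant (M)."""
        return self.k_minusC / self.kC


@dataclass(frozen=True)
class RateParameters:
    """Kinetic constants and scaling factors of the oligomerization model.

    ``k1b``, ``k3`` and ``k4`` are the surface epitope-capture rates of the
    reference (5% DNP) surface; on sparser surfaces they are multiplied by
    the ``alpha_prefactors`` entry for that surface, and ``k3``/``k4`` are
    additionally multiplied by ``e430g_factor`` for E430G Fc mutants.
    """

    k1b: float = 3.2e-4        # s^-1 um^2, monovalent -> bivalent ring closure
    k2: float = 5.7e5          # M^-1 s^-1, Fc-Fc association of solution IgG
    k_minus2: float = 1.5      # s^-1, Fc-Fc dissociation
    k3: float = 2.5e-4         # s^-1 um^2, dimer epitope capture
    k4: float = 6.5e-4         # s^-1 um^2, higher-oligomer epitope capture
    kT: float = 3.5e-1         # s^-1, bulk -> surface mass transport
    e430g_factor: float = 1.9  # dimensionless, scales k3/k4 for E430G
    alpha_prefactors: Mapping[float, float] = field(
        default_factory=lambda: {0.0085: 2.0, 0.025: 1.5, 0.05: 1.0}
    )
    kon_fab_by_surface: Mapping[float, float] = field(
        default_factory=lambda: {0.0085: 3.1e4, 0.025: 2.8e4, 0.05: 0.6e4}
    )
    koff_fab_by_surface: Mapping[float, float] = field(
        default_factory=lambda: {0.0085: 1.3e-1, 0.025: 2.1e-1, 0.05: 2.1e-1}
    )
    spa: SpaParameters = field(default_factory=SpaParameters)

    def __post_init__(self) -> None:
        for name in ("k1b", "k2", "k_minus2", "k3", "k4", "kT", "e430g_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"rate parameter {name} must be strictly positive")
        for mapping in (self.alpha_prefactors, self.kon_fab_by_surface,
                        self.koff_fab_by_surface):
            if any(v <= 0 for v in mapping.values()):
                raise ValueError("per-surface rate entries must be strictly positive")

    def kon_fab(self, dnp_fraction: float) -> float:
        try:
            return self.kon_fab_by_surface[dnp_fraction]
        except KeyError:
            raise KeyError(
                f"no Fab association rate registered for DNP fraction {dnp_fraction}"
            ) from None

    def koff_fab(self, dnp_fraction: float) -> float:
        try:
            return self.koff_fab_by_surface[dnp_fraction]
        except KeyError:
            raise KeyError(
                f"no Fab dissociation rate registered for DNP fraction {dnp_fraction}"
            ) from None

    def alpha(self, dnp_fraction: float) -> float:
        try:
            return self.alpha_prefactors[dnp_fraction]
        except KeyError:
            raise KeyError(
                f"no surface prefactor registered for DNP fraction {dnp_fraction}"
            ) from None

    def k1(self, dnp_fraction: float) -> float:
        """Whole-IgG epitope association rate: 1.7x the Fab on-rate."""
        return IGG_OVER_FAB_ON_RATE * self.kon_fab(dnp_fraction)

    def updated(self, **changes: object) -> "RateParameters":
        """Return a copy with scalar fields or per-surface entries replaced.

        Per-surface entries are addressed with dotted names, e.g.
        ``{"kon_fab.0.025": 2.8e4, "alpha.0.0085": 2.0}``.
        """
        scalar: dict[str, object] = {}
        maps = {
            "kon_fab": dict(self.kon_fab_by_surface),
            "koff_fab": dict(self.koff_fab_by_surface),
            "alpha": dict(self.alpha_prefactors),
        }
        map_fields = {
            "kon_fab": "kon_fab_by_surface",
            "koff_fab": "koff_fab_by_surface",
            "alpha": "alpha_prefactors",
        }
        touched = set()
        valid = {f.name for f in dataclasses.fields(self)}
        for name, value in changes.items():
            if "." in name:
                prefix, frac = name.split(".", 1)
                if prefix not in maps:
                    raise KeyError(f"unknown per-surface parameter group {prefix!r}")
                maps[prefix][float(frac)] = float(value)  # type: ignore[arg-type]
                touched.add(prefix)
            else:
                if name not in valid:
                    raise KeyError(f"unknown rate parameter {name!r}")
                scalar[name] = value
        for prefix in touched:
            scalar[map_fields[prefix]] = maps[prefix]
        return replace(self, **scalar)


# Best-fit parameter sets from the package's reference calibration of the
# model against oligomer distributions of the three fitted subclasses.
IGG1_PARAMS = RateParameters()

IGG3_PARAMS = RateParameters(
    k1b=1.7e-4,
    k2=5.7e5,
    k_minus2=0.07,
    k3=1.2e-5,
    k4=2.2e-5,
    kT=0.93e-1,
    e430g_factor=1.2,
    alpha_prefactors={0.05: 1.0},
    kon_fab_by_surface={0.05: 0.6e4},
    koff_fab_by_surface={0.05: 2.1e-1},
)

IGG4_PARAMS = RateParameters(
    k1b=2.2e-4,
    k2=5.7e5,
    k_minus2=0.55,
    k3=1.0e-4,
    k4=2.1e-4,
    kT=0.93e-1,
    e430g_factor=1.4,
    alpha_prefactors={0.05: 1.0},
    kon_fab_by_surface={0.05: 0.6e4},
    koff_fab_by_surface={0.05: 2.1e-1},
)


def default_parameters(subclass: str) -> RateParameters:
    """Reference best-fit :class:`RateParameters` for an IgG subclass."""
    try:
        return {"IgG1": IGG1_PARAMS, "IgG3": IGG3_PARAMS, "IgG4": IGG4_PARAMS}[subclass]
    except KeyError:
        raise KeyError(
            f"no reference parameter set for subclass {subclass!r} "
            "(available: IgG1, IgG3, IgG4)"
        ) from None


@dataclass(frozen=True)
class Condition:
    """One experimental scenario of the oligomerization assay."""

    variant: str = "IgG1"          # IgG subclass: IgG1, IgG3 or IgG4
    mutant: bool = False           # True for the E430G Fc point mutant
    c_bulk: float = 33e-9          # M, bulk IgG concentration
    dnp_fraction: float = 0.05     # DNP-lipid mole fraction
    t_incubation: float = 180.0    # s
    spa_conc: float = 0.0          # M, SpA B-domain concentration (0 = absent)

    def __post_init__(self) -> None:
        if self.variant not in ("IgG1", "IgG3", "IgG4"):
            raise ValueError(
                f"unsupported IgG variant {self.variant!r} "
                "(supported: IgG1, IgG3, IgG4)"
            )
        if self.c_bulk < 0:
            raise ValueError("bulk concentration must be non-negative")
        if self.t_incubation <= 0:
            raise ValueError("incubation time must be positive")
        if self.spa_conc < 0:
            raise ValueError("SpA concentration must be non-negative")
        if self.rho_epi <= 0:
            raise ValueError("epitope density must be positive")

    @property
    def rho_epi(self) -> float:
        """Total epitope surface density (um^-2) from the DNP mole fraction."""
        return dnp_density(self.dnp_fraction)


@dataclass(frozen=True)
class ScreeningGeometry:
    """Footprint geometry of surface-bound IgG species for epitope screening.

    A monovalently bound monomer hides a circular patch of diameter ``d1``;
    a bivalently bound one a patch of diameter ``gamma * d1``; a hexamer a
    patch of diameter ``d2``; oligomers of 2-5 IgGs the corresponding
    fraction of the hexamer disc plus a rim-overlap strip ``d2 * delta``.
    """

    d1: float = 8.8        # nm, monomer footprint diameter
    gamma: float = 1.6     # bivalent footprint scale
    d2: float = 23.0       # nm, hexamer footprint diameter
    delta: float = 2.9     # nm, rim-overlap length for partial rings
    alpha_volume: float = SURFACE_COMPARTMENT_ALPHA  # M per um^-2
    #: 'total' screens proportional to the constant total epitope density,
    #: 'free' proportional to the instantaneous unbound density.
    screening: str = "total"

    def __post_init__(self) -> None:
        for name in ("d1", "gamma", "d2", "delta", "alpha_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"geometry parameter {name} must be positive")
        if self.screening not in ("total", "free"):
            raise ValueError("screening mode must be 'total' or 'free'")


@dataclass(frozen=True)
class Protocol:
    """Incubation / wash / observation schedule of the simulated assay."""

    t_wash: float = 180.0        # s, wash duration
    t_observe: float = 3600.0    # s, post-wash observation horizon
    averaging: bool = True       # time-average distribution over observation
    #: bulk concentration during the wash: held at c_bulk ('hold', default)
    #: or set to zero at the start of the wash ('zero').
    wash_bulk: str = "hold"

    def __post_init__(self) -> None:
        if self.t_wash < 0 or self.t_observe < 0:
            raise ValueError("protocol durations must be non-negative")
        if self.wash_bulk not in ("hold", "zero"):
            raise ValueError("wash_bulk must be 'hold' or 'zero'")
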