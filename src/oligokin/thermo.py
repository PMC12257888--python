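"""Equilibrium constants, standard free energies and entropy differences
derived from the kinetic rate constants.

For a reaction with forward rate ``k_f`` and backward rate ``k_b`` the
equilibrium dissociation constant is ``K = k_b / k_f`` and the standard
free-energy change of binding is ``dG = R T ln K`` (natural logarithm,
unity activity coefficients).  Solution reactions have ``K`` directly in
molar.  Surface capture reactions (forward rate in s^-1 um^2) have ``K`` in
um^-2; it is converted to a molar scale with ``surface_to_molar_divisor``
before taking the logarithm.  Entropy differences between two binding steps
follow from equal-enthalpy assumptions: ``ddS = -(dG_i - dG_j) / T``.

Note the surface standard state (divisor 6.022e11 um^-2 per M) is a
reporting convention for the free-energy table and deliberately differs
from the 1-um compartment factor used in the transport equation; entropy
differences are invariant to this choice because it cancels.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .params import RateParameters

__all__ = ["ThermoConfig", "delta_g", "entropy_difference", "thermo_table"]


@dataclass(frozen=True)
class ThermoConfig:
    temperature: float = 300.0          # K
    gas_constant: float = 8.3145e-3     # kJ mol^-1 K^-1
    surface_to_molar_divisor: float = 6.022e11  # um^-2 per M

    def __post_init__(self) -> None:
        if min(self.temperature, self.gas_constant,
               self.surface_to_molar_divisor) <= 0:
            raise ValueError("all thermodynamic configuration values must be positive")


def delta_g(
    k_forward: float,
    k_backward: float,
    config: ThermoConfig | None = None,
    surface: bool = False,
) -> float:
    """Standard free-energy change (kJ/mol) of a binding step.

    ``surface=True`` marks a surface capture reaction whose equilibrium
    constant ``k_backward / k_forward`` is a density (um^-2) and is divided
    by ``config.surface_to_molar_divisor`` to reach the molar scale.
    """
    config = config or ThermoConfig()
    if k_forward <= 0 or k_backward <= 0:
        raise ValueError("rate constants must be strictly positive")
    kd = k_backward / k_forward
    if surface:
        kd /= config.surface_to_molar_divisor
    return config.gas_constant * config.temperature * math.log(kd)


def entropy_difference(
    dg_i: float, dg_j: float, config: ThermoConfig | None = None
) -> float:
    """Entropy difference ``dS_i - dS_j`` in J mol^-1 K^-1.

    Assumes equal enthalpies for the two steps so that the free-energy
    difference is purely entropic: ``ddS = -(dG_i - dG_j) / T``.
    """
    config = config or ThermoConfig()
    if not (math.isfinite(dg_i) and math.isfinite(dg_j)):
        raise ValueError("free energies must be finite")
    return -(dg_i - dg_j) / config.temperature * 1e3  # kJ -> J


def _column_dgs(
    params: RateParameters,
    dnp_fraction: float,
    config: ThermoConfig,
) -> dict[str, float]:
    """All free-energy rows for one table column (variant x surface)."""
    a = params.alpha(dnp_fraction)
    nu = params.e430g_factor
    k1 = params.k1(dnp_fraction)
    koff = params.koff_fab(dnp_fraction)
    rt = config.gas_constant * config.temperature
    dg3 = delta_g(params.k3 * a, koff, config, surface=True)
    dg4 = delta_g(params.k4 * a, koff, config, surface=True)
    return {
        "dG1": delta_g(k1, koff, config),
        "dG1b": delta_g(params.k1b * a, koff, config, surface=True),
        "dG2": delta_g(params.k2, params.k_minus2, config),
        "dG3": dg3,
        "dG4": dg4,
        "dG3_E430G": dg3 - rt * math.log(nu),
        "dG4_E430G": dg4 - rt * math.log(nu),
    }


def thermo_table(
    params_by_column: dict[str, tuple[RateParameters, float]] | None = None,
    config: ThermoConfig | None = None,
) -> pd.DataFrame:
    """Free-energy and entropy-difference report across variants/surfaces.

    ``params_by_column`` maps a column label to ``(RateParameters,
    dnp_fraction)``; by default the five reference columns (IgG1 on the
    three surfaces, IgG3 and IgG4 on the 5% surface) are used.  Rows are
    the seven ``dG`` entries plus the four entropy-difference rows, all
    computed from unrounded rate constants.  Missing rates leave an
    explicit NaN gap.
    """
    from .params import IGG1_PARAMS, IGG3_PARAMS, IGG4_PARAMS

    config = config or ThermoConfig()
    if params_by_column is None:
        params_by_column = {
            "IgG1 0.85% DNP": (IGG1_PARAMS, 0.0085),
            "IgG1 2.5% DNP": (IGG1_PARAMS, 0.025),
            "IgG1 5% DNP": (IGG1_PARAMS, 0.05),
            "IgG3 5% DNP": (IGG3_PARAMS, 0.05),
            "IgG4 5% DNP": (IGG4_PARAMS, 0.05),
        }

    columns: dict[str, dict[str, float]] = {}
    for label, (params, frac) in params_by_column.items():
        try:
            dgs = _column_dgs(params, frac, config)
        except KeyError as exc:
            raise KeyError(f"column {label!r}: {exc}") from None
        dgs["dS1b-dS1"] = entropy_difference(dgs["dG1b"], dgs["dG1"], config)
        dgs["dS3-dS3_E430G"] = entropy_difference(dgs["dG3"], dgs["dG3_E430G"], config)
        dgs["dS3-dS4"] = entropy_difference(dgs["dG3"], dgs["dG4"], config)
        columns[label] = dgs

    table = pd.DataFrame(columns)
    # cross-column row: entropy of the dimer epitope-capture step of IgG1
    # (reference surface) relative to the other subclasses
    ref = "IgG1 5% DNP"
    if ref in table.columns:
        row = {}
        for label in table.columns:
            if label == ref or not label.startswith(("IgG3", "IgG4")):
                row[label] = float("nan")
            else:
                row[label] = entropy_difference(
                    table.at["dG3", ref], table.at["dG3", label], config
                )
        table.loc["dS3_IgG1-dS3"] = pd.Series(row)
    return table
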