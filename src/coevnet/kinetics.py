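"""Michaelis–Menten kinetics and double-mutant-cycle energetics.

The specificity constant ``kcat/Km`` (µM⁻¹ s⁻¹) is the quantity compared
across enzyme variants. A mutant's change in transition-state stabilization
free energy relative to wild type is

    ΔΔG‡ = -R T ln[(kcat/Km)_mut / (kcat/Km)_wt]      (kcal/mol)

with R = 1.9872e-3 kcal mol⁻¹ K⁻¹; ΔΔG‡ is positive for an impaired mutant.
For a double-mutant cycle over positions X and Y the coupling energy is

    ΔG_I = ΔΔG‡_XY - (ΔΔG‡_X + ΔΔG‡_Y)

which is zero when the two mutations act additively on kcat/Km (the double
mutant's specificity ratio is the product of the singles').
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitError

#: Gas constant in kcal mol^-1 K^-1.
R_GAS = 1.9872e-3
#: Default assay temperature (25 °C) in Kelvin.
DEFAULT_T = 298.15


@dataclass
class KineticParams:
    """Steady-state parameters of one enzyme variant.

    ``spec`` is kcat/Km in µM⁻¹ s⁻¹. When omitted it is computed from kcat
    and Km; it may also be supplied explicitly (e.g. a published, separately
    rounded value). ``consistent()`` checks the two agree within 1%, which
    holds for fitted parameters but can fail for rounded published pairs.
    """

    name: str
    kcat: float                 # s^-1
    km: float                   # µM
    spec: float | None = None   # µM^-1 s^-1
    kcat_se: float | None = None
    km_se: float | None = None
    spec_se: float | None = None

    def __post_init__(self):
        if self.kcat <= 0 or self.km <= 0:
            raise ValueError(f"{self.name}: kcat and Km must be positive")
        if self.spec is None:
            self.spec = self.kcat / self.km
        if self.spec <= 0:
            raise ValueError(f"{self.name}: kcat/Km must be positive")
        if self.spec_se is None and self.kcat_se is not None and self.km_se is not None:
            self.spec_se = self.spec * math.hypot(
                self.kcat_se / self.kcat, self.km_se / self.km
            )

    def consistent(self, rtol: float = 0.01) -> bool:
        return abs(self.spec - self.kcat / self.km) <= rtol * self.spec


def michaelis_menten(s, kcat: float, km: float, e0: float):
    """Initial rate v = kcat * E0 * S / (Km + S)."""
    s = np.asarray(s, dtype=float)
    return kcat * e0 * s / (km + s)


def fit_michaelis_menten(s, v, e0: float, name: str = "fit") -> KineticParams:
    """Least-squares fit of initial-rate data to the Michaelis–Menten equation.

    Requires at least 4 distinct substrate concentrations (fewer cannot
    constrain both kcat and Km). Standard errors come from the fit's
    covariance matrix.
    """
    s = np.asarray(s, dtype=float)
    v = np.asarray(v, dtype=float)
    if s.shape != v.shape:
        raise FitError("substrate and rate arrays differ in length")
    if len(np.unique(s)) < 4:
        raise FitError(
            f"need >= 4 distinct substrate concentrations, got {len(np.unique(s))}"
        )
    kcat0 = max(float(v.max()) / e0, 1e-9)
    km0 = float(np.median(s))
    try:
        popt, pcov = curve_fit(
            lambda x, kcat, km: michaelis_menten(x, kcat, km, e0),
            s, v, p0=[kcat0, km0], bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    kcat, km = float(popt[0]), float(popt[1])
    if not (np.isfinite(kcat) and np.isfinite(km)) or kcat <= 0 or km <= 0:
        raise FitError(f"non-positive or non-finite estimates: kcat={kcat}, Km={km}")
    ses = np.sqrt(np.diag(pcov))
    return KineticParams(
        name=name, kcat=kcat, km=km,
        kcat_se=float(ses[0]) if np.isfinite(ses[0]) else None,
        km_se=float(ses[1]) if np.isfinite(ses[1]) else None,
    )


def ddg_transition(wt: KineticParams, mut: KineticParams, t: float = DEFAULT_T) -> float:
    """ΔΔG‡ (kcal/mol) of ``mut`` relative to ``wt`` at temperature ``t`` (K)."""
    if wt.spec <= 0 or mut.spec <= 0:
        raise ValueError("specificity constants must be positive")
    return -R_GAS * t * math.log(mut.spec / wt.spec)


def _ddg_se(wt: KineticParams, mut: KineticParams, t: float) -> float | None:
    if wt.spec_se is None or mut.spec_se is None:
        return None
    return R_GAS * t * math.hypot(wt.spec_se / wt.spec, mut.spec_se / mut.spec)


@dataclass
class MutantCycle:
    """The four variants of a double-mutant cycle over positions X and Y."""

    wt: KineticParams
    mut_x: KineticParams
    mut_y: KineticParams
    mut_xy: KineticParams
    temperature: float = DEFAULT_T

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (Kelvin)")


@dataclass
class CycleResult:
    """ΔΔG‡ of each mutant and the cycle's coupling energy, kcal/mol."""

    ddg_x: float
    ddg_y: float
    ddg_xy: float
    coupling: float
    temperature: float
    coupling_se: float | None = None


def coupling_energy(cycle: MutantCycle) -> CycleResult:
    """Coupling energy ΔG_I = ΔΔG‡_XY - ΔΔG‡_X - ΔΔG‡_Y of a cycle.

    Symmetric in X and Y. The optional standard error is first-order
    propagation from the four variants' kcat/Km uncertainties (treated as
    independent).
    """
    t = cycle.temperature
    ddg_x = ddg_transition(cycle.wt, cycle.mut_x, t)
    ddg_y = ddg_transition(cycle.wt, cycle.mut_y, t)
    ddg_xy = ddg_transition(cycle.wt, cycle.mut_xy, t)
    coupling = ddg_xy - (ddg_x + ddg_y)
    se = None
    rel = []
    for p in (cycle.wt, cycle.mut_x, cycle.mut_y, cycle.mut_xy):
        if p.spec_se is None:
            rel = None
            break
        rel.append(p.spec_se / p.spec)
    if rel is not None:
        se = R_GAS * t * math.sqrt(sum(r * r for r in rel))
    return CycleResult(ddg_x=ddg_x, ddg_y=ddg_y, ddg_xy=ddg_xy,
                       coupling=coupling, temperature=t, coupling_se=se)


def percent_wt(mut: KineticParams, wt: KineticParams) -> float:
    """Specificity of ``mut`` as a percentage of wild type.

    Rounded to the nearest integer; values below 1% are reported to one
    decimal place instead.
    """
    ratio = 100.0 * mut.spec / wt.spec
    if ratio >= 1.0:
        return float(round(ratio))
    return round(ratio, 1)


def read_kinetics_table(path) -> dict[str, KineticParams]:
    """Read a variant kinetics table (CSV/TSV) into KineticParams by name.

    Expected columns: ``name, kcat, Km`` with optional ``kcat_se, Km_se,
    spec`` (explicit kcat/Km, e.g. published rounded values).
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    out = {}
    for _, row in df.iterrows():
        out[row["name"]] = KineticParams(
            name=row["name"],
            kcat=float(row["kcat"]),
            km=float(row["Km"]),
            spec=float(row["spec"]) if "spec" in df.columns and pd.notna(row.get("spec")) else None,
            kcat_se=float(row["kcat_se"]) if "kcat_se" in df.columns and pd.notna(row.get("kcat_se")) else None,
            km_se=float(row["Km_se"]) if "Km_se" in df.columns and pd.notna(row.get("Km_se")) else None,
        )
    return out
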