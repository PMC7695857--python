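"""Mass-action DSB repair kinetics and foci curves.

Five pathways (NHEJ, HR, SSA, micro-SSA, Alt-NHEJ) are modelled as linear
chains of enzyme-bound intermediates.  The remaining-DSB pool N0 feeds the
first complex of each chain; every internal step is reversible, the final
step of each chain irreversibly releases repaired DNA:

    dN0/dt = -sum_p (k_p1+ * N0 - k_p1- * X_p1)
    dX_pi/dt = k_pi+ * X_p(i-1) - k_pi- * X_pi - k_p(i+1)+ * X_pi
               + k_p(i+1)- * X_p(i+1)

with 53 attachment/detachment rate constants in total (NHEJ 11, HR 13,
SSA 11, micro-SSA 9, Alt-NHEJ 9).  The irradiation is instantaneous: the
induction term alpha(L) * dD/dt * N_cDSB acts only at t = 0 and is realized
as the initial condition N0(0) = N_ncDSB + N_cDSB with all intermediates
zero.  An irreparable sub-pool (default fraction N_cDSB / N0(0)) is held
out of the kinetics and persists at late times.

gamma-H2AX induction is a Michaelis-Menten transform of the summed active
DNA-PKcs-bearing complexes plus the irreparable pool.

The shipped default rate values are package defaults chosen to give
qualitatively realistic kinetics (fast NHEJ, slower HR/SSA, minor backup
pathways); they are fully configurable through a keyed JSON table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.stats import linregress

# ---------------------------------------------------------------------------
# pathway topology: ordered step names; step i has forward constant <name>
# and (except the last, irreversible release) reverse constant <name>_rev
PATHWAY_STEPS: Dict[str, List[str]] = {
    "NHEJ": ["nhej_ku_attach", "nhej_dnapkcs_attach", "nhej_artemis_attach",
             "nhej_polmu_attach", "nhej_lig4_attach", "nhej_ligate"],
    "HR": ["hr_mrn_attach", "hr_ctip_resect", "hr_rpa_attach",
           "hr_rad51_attach", "hr_dloop_form", "hr_poldelta_extend",
           "hr_resolve"],
    "SSA": ["ssa_mrn_attach", "ssa_resect", "ssa_rpa_attach",
            "ssa_rad52_attach", "ssa_xpf_cleave", "ssa_ligate"],
    "microSSA": ["mssa_resect", "mssa_anneal", "mssa_trim", "mssa_fill",
                 "mssa_ligate"],
    "AltNHEJ": ["alt_parp1_attach", "alt_mrn_attach", "alt_polq_attach",
                "alt_lig3_attach", "alt_seal"],
}

# species bound after each non-final step (chain intermediates)
PATHWAY_SPECIES: Dict[str, List[str]] = {
    "NHEJ": ["NHEJ_Ku", "NHEJ_DNAPKcs", "NHEJ_Artemis", "NHEJ_PolMu",
             "NHEJ_Lig4"],
    "HR": ["HR_MRN", "HR_Resected", "HR_RPA", "HR_Rad51", "HR_Dloop",
           "HR_Extended"],
    "SSA": ["SSA_MRN", "SSA_Resected", "SSA_RPA", "SSA_Rad52", "SSA_Flap"],
    "microSSA": ["mSSA_Resected", "mSSA_Annealed", "mSSA_Trimmed",
                 "mSSA_Filled"],
    "AltNHEJ": ["Alt_PARP1", "Alt_MRN", "Alt_PolQ", "Alt_Lig3"],
}

SPECIES_NAMES: List[str] = [s for pw in PATHWAY_STEPS for s in PATHWAY_SPECIES[pw]]


def rate_constant_names() -> List[str]:
    names: List[str] = []
    for pw, steps in PATHWAY_STEPS.items():
        for s in steps:
            names.append(s)
        for s in steps[:-1]:
            names.append(s + "_rev")
    return names


RATE_NAMES = rate_constant_names()
assert len(RATE_NAMES) == 53

# DNA-PKcs-bearing NHEJ complexes: everything downstream of DNA-PKcs binding
DEFAULT_H2AX_SPECIES = ["NHEJ_DNAPKcs", "NHEJ_Artemis", "NHEJ_PolMu",
                        "NHEJ_Lig4"]


def _default_rates() -> Dict[str, float]:
    """Package-default rate table (per hour).

    NHEJ dominates with a repair half-time of roughly an hour; HR and SSA
    are an order of magnitude slower; micro-SSA and Alt-NHEJ are minor
    backup channels.  Detachment rates are a tenth of attachment rates.
    """
    forward = {
        "NHEJ": [3.0, 4.0, 3.0, 2.5, 2.0, 1.5],
        "HR": [0.35, 0.4, 0.5, 0.4, 0.3, 0.3, 0.25],
        "SSA": [0.15, 0.25, 0.3, 0.25, 0.2, 0.2],
        "microSSA": [0.05, 0.15, 0.15, 0.12, 0.1],
        "AltNHEJ": [0.05, 0.12, 0.1, 0.1, 0.08],
    }
    rates: Dict[str, float] = {}
    for pw, steps in PATHWAY_STEPS.items():
        for name, kf in zip(steps, forward[pw]):
            rates[name] = kf
        for name, kf in zip(steps[:-1], forward[pw][:-1]):
            rates[name + "_rev"] = 0.1 * kf
    return rates


@dataclass(frozen=True)
class RepairRateTable:
    """53 named rate constants plus induction slope and MM parameters."""

    rates: Dict[str, float] = field(default_factory=_default_rates)
    alpha_per_gy: float = 35.0        # DSB induction slope, Gy^-1 per cell
    mm_vmax: float = 1.0
    mm_km: float = 10.0
    h2ax_species: Sequence[str] = tuple(DEFAULT_H2AX_SPECIES)

    def __post_init__(self) -> None:
        missing = set(RATE_NAMES) - set(self.rates)
        extra = set(self.rates) - set(RATE_NAMES)
        if missing or extra:
            raise ValueError(
                f"rate table schema mismatch: missing={sorted(missing)} "
                f"unknown={sorted(extra)}")
        bad = {k: v for k, v in self.rates.items() if v < 0}
        if bad:
            raise ValueError(f"negative rate constants: {bad}")
        if self.mm_vmax < 0 or self.mm_km <= 0:
            raise ValueError("need mm_vmax >= 0 and mm_km > 0")
        unknown = set(self.h2ax_species) - set(SPECIES_NAMES)
        if unknown:
            raise ValueError(f"unknown gamma-H2AX species: {sorted(unknown)}")

    @classmethod
    def from_json(cls, path) -> "RepairRateTable":
        with open(path) as fh:
            data = json.load(fh)
        return cls(rates=data["rates"],
                   alpha_per_gy=data.get("alpha_per_gy", 35.0),
                   mm_vmax=data.get("mm_vmax", 1.0),
                   mm_km=data.get("mm_km", 10.0),
                   h2ax_species=tuple(data.get("h2ax_species",
                                               DEFAULT_H2AX_SPECIES)))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"rates": self.rates, "alpha_per_gy": self.alpha_per_gy,
                       "mm_vmax": self.mm_vmax, "mm_km": self.mm_km,
                       "h2ax_species": list(self.h2ax_species)}, fh, indent=1)

    def zeroed_except(self, pathway: str, **overrides) -> "RepairRateTable":
        """All constants zero except the named pathway's (testing helper)."""
        rates = {k: 0.0 for k in RATE_NAMES}
        for name in PATHWAY_STEPS[pathway]:
            rates[name] = self.rates[name]
            if name + "_rev" in self.rates:
                rates[name + "_rev"] = self.rates[name + "_rev"]
        rates.update(overrides)
        return replace(self, rates=rates)


@dataclass(frozen=True)
class RepairInputs:
    """DSB counts per cell driving the kinetics."""

    n_ncdsb: float
    n_cdsb: float
    dose_gy: float = 1.0
    irreparable_fraction: float | None = None   # default N_cDSB / N0

    def __post_init__(self) -> None:
        if self.n_ncdsb < 0 or self.n_cdsb < 0:
            raise ValueError("DSB counts must be non-negative")
        f = self.resolved_irreparable_fraction
        if not 0.0 <= f <= 1.0:
            raise ValueError("irreparable fraction must be in [0, 1]")

    @property
    def n0(self) -> float:
        return self.n_ncdsb + self.n_cdsb

    @property
    def resolved_irreparable_fraction(self) -> float:
        if self.irreparable_fraction is not None:
            return self.irreparable_fraction
        return self.n_cdsb / self.n0 if self.n0 > 0 else 0.0


class IntegrationError(RuntimeError):
    """Raised when the stiff solver fails; never silently clamped."""


@dataclass
class RepairTrajectory:
    time_h: np.ndarray
    n0: np.ndarray                    # remaining DSBs incl. irreparable pool
    species: pd.DataFrame             # intermediate levels, one column each
    fluxes: pd.DataFrame              # V_NHEJ ... per pathway
    n_irreparable: float
    inputs: RepairInputs
    rates: RepairRateTable

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"time_h": self.time_h, "n0": self.n0})
        return pd.concat([out, self.species, self.fluxes], axis=1)


def _build_ode(rates: RepairRateTable):
    """Right-hand side over y = [N0_rep, X_1 ... X_24]."""
    k = rates.rates
    chains = []
    offset = 1
    for pw, steps in PATHWAY_STEPS.items():
        m = len(steps)
        kf = np.array([k[s] for s in steps])
        kr = np.array([k[s + "_rev"] for s in steps[:-1]] + [0.0])
        chains.append((pw, offset, m - 1, kf, kr))
        offset += m - 1

    def rhs(t, y):
        dy = np.zeros_like(y)
        n0 = y[0]
        for _, off, n_int, kf, kr in chains:
            x = y[off:off + n_int]
            prev = np.concatenate([[n0], x[:-1]])
            inflow = kf[:-1] * prev            # into X_i from upstream
            outflow_rev = kr[:-1] * x          # X_i back upstream
            onward = kf[1:] * x                # X_i to downstream/release
            back_in = np.concatenate([kr[1:-1] * x[1:], [0.0]]) if n_int > 1 \
                else np.zeros(1)
            dy[off:off + n_int] = inflow - outflow_rev - onward + back_in
            dy[0] -= kf[0] * n0 - kr[0] * x[0]
        return dy

    return rhs, chains


def simulate_repair(inputs: RepairInputs, rates: RepairRateTable | None = None,
                    t_end_h: float = 25.0, dt_out_h: float = 0.1,
                    rtol: float = 1e-8, atol: float = 1e-9,
                    method: str = "Radau") -> RepairTrajectory:
    """Integrate the repair network from an instantaneous irradiation.

    N0(0) is the total DSB count; the irreparable sub-pool is excluded from
    the kinetics and re-added to the reported remaining-DSB curve.
    """
    if rates is None:
        rates = RepairRateTable()
    if t_end_h <= 0:
        raise ValueError("t_end must be positive")
    f_irr = inputs.resolved_irreparable_fraction
    n_irr = f_irr * inputs.n0
    n_rep0 = inputs.n0 - n_irr

    rhs, chains = _build_ode(rates)
    n_state = 1 + len(SPECIES_NAMES)
    t_eval = np.arange(0.0, t_end_h + dt_out_h / 2, dt_out_h)
    y0 = np.zeros(n_state)
    y0[0] = n_rep0

    if inputs.n0 == 0:
        y = np.zeros((n_state, t_eval.size))
    else:
        sol = solve_ivp(rhs, (0.0, t_end_h), y0, method=method,
                        t_eval=t_eval, rtol=rtol, atol=atol)
        if not sol.success:
            raise IntegrationError(f"stiff solver failed: {sol.message}")
        y = sol.y

    species = pd.DataFrame(y[1:].T, columns=SPECIES_NAMES)
    flux = {}
    for pw, off, _, kf, kr in chains:
        flux[f"V_{pw}"] = kf[0] * y[0] - kr[0] * y[off]
    return RepairTrajectory(
        time_h=t_eval, n0=y[0] + n_irr, species=species,
        fluxes=pd.DataFrame(flux), n_irreparable=n_irr, inputs=inputs,
        rates=rates)


def michaelis_menten(substrate, vmax: float, km: float):
    """MM kernel v = vmax * S / (km + S); v(km) = vmax / 2."""
    s = np.asarray(substrate, dtype=float)
    return vmax * s / (km + s)


@dataclass
class FociCurve:
    time_h: np.ndarray
    ku: np.ndarray
    dnapkcs: np.ndarray
    rpa: np.ndarray
    rad51: np.ndarray
    h2ax: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.time_h, "Ku": self.ku,
                             "DNA-PKcs": self.dnapkcs, "RPA": self.rpa,
                             "Rad51": self.rad51, "gamma-H2AX": self.h2ax})


def gamma_h2ax_curve(trajectory: RepairTrajectory,
                     rates: RepairRateTable | None = None,
                     normalize: str = "max") -> FociCurve:
    """Foci accumulation curves derived from a repair trajectory.

    gamma-H2AX is the MM transform of the summed active DNA-PKcs-bearing
    complexes plus the persistent irreparable pool, so the curve plateaus at
    the level set by the irreparable fraction instead of decaying to zero.
    ``normalize``: "max" scales gamma-H2AX to its own maximum, "absolute"
    leaves MM units.
    """
    if rates is None:
        rates = trajectory.rates
    sp = trajectory.species
    missing = set(rates.h2ax_species) - set(sp.columns)
    if missing:
        raise ValueError(f"species missing from trajectory: {sorted(missing)}")
    signal = sp[list(rates.h2ax_species)].sum(axis=1).to_numpy()
    signal = signal + trajectory.n_irreparable
    h2ax = michaelis_menten(signal, rates.mm_vmax, rates.mm_km)
    if normalize == "max":
        peak = h2ax.max()
        if peak > 0:
            h2ax = h2ax / peak
    elif normalize != "absolute":
        raise ValueError("normalize must be 'max' or 'absolute'")
    ku = sp["NHEJ_Ku"].to_numpy()
    dnapk = sp[DEFAULT_H2AX_SPECIES].sum(axis=1).to_numpy()
    rpa = (sp["HR_RPA"] + sp["SSA_RPA"]).to_numpy()
    rad51 = sp["HR_Rad51"].to_numpy()
    return FociCurve(trajectory.time_h, ku, dnapk, rpa, rad51, h2ax)


# ---------------------------------------------------------------------------
# degree of protection (DMSO scavenger analysis)

def degree_of_protection(sf0: float, sfx: float) -> float:
    """DP = (ln SF0 - ln SFx) / ln SF0 for survival with/without scavenger."""
    if not 0 < sf0 < 1:
        raise ValueError("SF0 must be in (0, 1)")
    if not 0 < sfx <= 1:
        raise ValueError("SFx must be in (0, 1]")
    return (np.log(sf0) - np.log(sfx)) / np.log(sf0)


@dataclass(frozen=True)
class ProtectionFit:
    k: float
    y_inf: float
    max_dp: float
    stderr_k: float
    stderr_y_inf: float
    r_squared: float
    status: str        # "ok" | "non-physical-intercept"


def fit_max_protection(concentrations: Sequence[float],
                       dp_values: Sequence[float]) -> ProtectionFit:
    """Reciprocal fit 1/DP = k * (1/x) + y_inf; max DP = 1 / y_inf.

    Ordinary least squares of 1/DP on 1/x.  A non-positive intercept is
    non-physical (DP would exceed 1 at infinite scavenger concentration)
    and is returned flagged, not raised.
    """
    x = np.asarray(concentrations, dtype=float)
    dp = np.asarray(dp_values, dtype=float)
    if x.size != dp.size:
        raise ValueError("concentrations and DP values must align")
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    if np.any((dp <= 0) | (dp > 1)):
        raise ValueError("DP values must be in (0, 1]")
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct concentrations")
    res = linregress(1.0 / x, 1.0 / dp)
    y_inf = float(res.intercept)
    if y_inf <= 0:
        return ProtectionFit(float(res.slope), y_inf, float("nan"),
                             float(res.stderr), float(res.intercept_stderr),
                             float(res.rvalue ** 2), "non-physical-intercept")
    return ProtectionFit(float(res.slope), y_inf, 1.0 / y_inf,
                         float(res.stderr), float(res.intercept_stderr),
                         float(res.rvalue ** 2), "ok")
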