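"""Drug-perturbation kinetic model of the JAK-STAT axis.

A minimal ODE model of STAT3 phosphorylation driven by three JAK subtypes,
SOCS3 negative feedback with a transcriptional synthesis lag, and a
downstream TNF read-out.  Drug effect enters as competitive single-site
inhibition of each JAK subtype, a_i = 1 / (1 + D(t)/ki_i), with
single-dose exponential pharmacokinetics D(t) = dose * 2^(-t/half_life).

State equations (pS = phosphorylated STAT3, A = lagged pS driving SOCS3
synthesis, M = SOCS3, T = TNF; u(t) = w1 a1 + w2 a2 + w3 a3):

    dpS/dt = k_act * u * (S_tot - pS) / (1 + (M/K_s)^h_s) - k_dp * pS
    dA/dt  = (pS - A) / tau
    dM/dt  = k_m * (b0 + A^n_m / (c_m^n_m + A^n_m)) - (d0 + d1 * pS) * M
    dT/dt  = k_T * pS^n / (K_T^n + pS^n) - d_T * T

SOCS3 synthesis is sigmoidal in the lagged pSTAT3 signal (STAT3 acts on
the SOCS3 promoter as a dimer, hence cooperatively); paired with
pS-coupled degradation this yields the transient SOCS3 surge when pS drops
abruptly after dosing, and lets a deep pSTAT3 crash (a JAK1/2-selective
drug) shut synthesis off sharply while a shallow drop keeps it saturated.
Trajectories are reported normalized to the pre-dose steady state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "DrugProfile",
    "KineticParams",
    "TrajectorySet",
    "BARICITINIB",
    "TOFACITINIB",
    "DRUGS",
    "DEFAULT_PARAMS",
    "dg_to_ki",
    "jak_inhibition",
    "steady_state",
    "simulate_timecourse",
    "trajectory_metrics",
    "dose_response",
]

R_KCAL = 1.98720425e-3  # gas constant, kcal / (mol K)


@dataclass(frozen=True)
class DrugProfile:
    """JAK-subtype inhibitory constants (nM) and simple PK for one drug."""

    name: str
    ki_jak1: float
    ki_jak2: float
    ki_jak3: float
    pk_half_life: float       # hours
    reference_dose: float = 26.29  # nM

    def __post_init__(self):
        if min(self.ki_jak1, self.ki_jak2, self.ki_jak3) <= 0:
            raise ValueError("ki values must be positive")
        if self.pk_half_life <= 0:
            raise ValueError("pk_half_life must be positive")

    @property
    def kis(self) -> np.ndarray:
        return np.array([self.ki_jak1, self.ki_jak2, self.ki_jak3])


# ki values as printed for the two modeled drugs; half-lives reflect their
# short (tofacitinib) vs long (baricitinib) clinical PK.
BARICITINIB = DrugProfile("baricitinib", ki_jak1=0.8, ki_jak2=1.2,
                          ki_jak3=45.0, pk_half_life=12.0)
TOFACITINIB = DrugProfile("tofacitinib", ki_jak1=12.0, ki_jak2=25.0,
                          ki_jak3=1.5, pk_half_life=3.33)
DRUGS = {d.name: d for d in (BARICITINIB, TOFACITINIB)}


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the JAK-STAT model (rates in 1/h, S_tot = 1)."""

    w1: float = 0.49852416
    w2: float = 0.44137584
    w3: float = 0.0601
    k_act: float = 10.8523
    k_dp: float = 0.9966
    k_s: float = 2.3741
    h_s: float = 4.3665
    tau: float = 0.5691
    k_m: float = 3.5214
    b0: float = 0.3165
    c_m: float = 0.1696
    n_m: float = 4.041
    d0: float = 0.2489
    d1: float = 2.0134
    k_t: float = 1.0
    kk_t: float = 0.4
    n_t: float = 2.0
    d_t: float = 0.4
    s_tot: float = 1.0

    def __post_init__(self):
        vals = [self.k_act, self.k_dp, self.k_s, self.h_s, self.tau,
                self.k_m, self.b0, self.c_m, self.n_m, self.d0, self.d1,
                self.k_t, self.kk_t, self.d_t]
        if any(v < 0 for v in vals):
            raise ValueError("rates must be non-negative")
        if abs(self.w1 + self.w2 + self.w3 - 1.0) > 1e-9:
            raise ValueError("pathway weights must sum to 1")
        if self.s_tot != 1.0:
            raise ValueError("total STAT3 is normalized to 1")

    @property
    def weights(self) -> np.ndarray:
        return np.array([self.w1, self.w2, self.w3])


# Frozen default parameter vector; see docs/methods.md for the calibration
# procedure that fixed it.
DEFAULT_PARAMS = KineticParams()


@dataclass(frozen=True)
class TrajectorySet:
    """Normalized trajectories on a common time grid (hours)."""

    time: np.ndarray
    pstat3: np.ndarray
    socs3: np.ndarray
    tnf: np.ndarray
    drug: np.ndarray
    drug_name: str
    dose: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.time, "pSTAT3": self.pstat3,
                             "SOCS3": self.socs3, "TNF": self.tnf,
                             "drug_nM": self.drug})


def dg_to_ki(delta_g: float, temperature: float = 298.15) -> float:
    """Inhibitory constant (molar, 1 M standard state) from binding free energy.

    ki = exp(dG / (R T)) with dG in kcal/mol.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if not math.isfinite(delta_g):
        raise ValueError("delta_g must be finite")
    return math.exp(delta_g / (R_KCAL * temperature))


def jak_inhibition(d: float, ki: float) -> float:
    """Residual activity of one JAK subtype under competitive inhibition."""
    if ki <= 0:
        raise ValueError("ki must be positive")
    if d < 0:
        raise ValueError("concentration must be non-negative")
    return 1.0 / (1.0 + d / ki)


def _drive(params: KineticParams, drug: DrugProfile, conc: float) -> float:
    a = 1.0 / (1.0 + conc / drug.kis)
    return float(params.weights @ a)


def _socs3_synthesis(p: KineticParams, a: float) -> float:
    a = max(a, 0.0)
    return p.k_m * (p.b0 + a ** p.n_m / (p.c_m ** p.n_m + a ** p.n_m))


def steady_state(params: KineticParams) -> np.ndarray:
    """Pre-dose steady state (pS, A, M, T) at zero drug (u = 1)."""
    p = params

    def imbalance(ps: float) -> float:
        m = _socs3_synthesis(p, ps) / (p.d0 + p.d1 * ps)
        return (p.k_act * (p.s_tot - ps) / (1.0 + (m / p.k_s) ** p.h_s)
                - p.k_dp * ps)

    lo, hi = 1e-9, p.s_tot - 1e-9
    if imbalance(lo) <= 0:
        raise RuntimeError("no positive steady state: activation too weak")
    ps = brentq(imbalance, lo, hi, xtol=1e-14, rtol=1e-14)
    m = _socs3_synthesis(p, ps) / (p.d0 + p.d1 * ps)
    t = (p.k_t * ps ** p.n_t / (p.kk_t ** p.n_t + ps ** p.n_t)) / p.d_t
    return np.array([ps, ps, m, t])


def _rhs(t, y, p: KineticParams, drug: DrugProfile, dose: float):
    ps, a, m, tnf = y
    conc = dose * 2.0 ** (-t / drug.pk_half_life)
    u = _drive(p, drug, conc)
    dps = (p.k_act * u * (p.s_tot - ps) / (1.0 + (m / p.k_s) ** p.h_s)
           - p.k_dp * ps)
    da = (ps - a) / p.tau
    dm = _socs3_synthesis(p, a) - (p.d0 + p.d1 * ps) * m
    dtnf = (p.k_t * ps ** p.n_t / (p.kk_t ** p.n_t + ps ** p.n_t)
            - p.d_t * tnf)
    return [dps, da, dm, dtnf]


def simulate_timecourse(params: KineticParams = DEFAULT_PARAMS,
                        drug: DrugProfile = BARICITINIB,
                        dose: float | None = None,
                        t_end: float = 24.0,
                        n_grid: int = 481,
                        method: str = "LSODA",
                        rtol: float = 1e-9,
                        atol: float = 1e-11) -> TrajectorySet:
    """Simulate the model for ``t_end`` hours after a dose at t = 0.

    The pre-dose steady state is solved first and trajectories are reported
    relative to it (all read-outs equal 1 at t = 0-).
    """
    if dose is None:
        dose = drug.reference_dose
    if dose < 0:
        raise ValueError("dose must be non-negative")
    y0 = steady_state(params)
    tgrid = np.linspace(0.0, t_end, n_grid)
    sol = solve_ivp(_rhs, (0.0, t_end), y0, t_eval=tgrid, method=method,
                    rtol=rtol, atol=atol, args=(params, drug, dose))
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    ps0, _, m0, t0 = y0
    conc = dose * 2.0 ** (-tgrid / drug.pk_half_life)
    return TrajectorySet(time=tgrid, pstat3=sol.y[0] / ps0,
                         socs3=sol.y[2] / m0, tnf=sol.y[3] / t0,
                         drug=conc, drug_name=drug.name, dose=dose)


def trajectory_metrics(traj: TrajectorySet) -> dict:
    """Summary response metrics of a normalized trajectory set.

    ``reduction_at(t)``: percent pSTAT3 reduction versus baseline at time t
    (linear interpolation on the grid); ``max_inhibition``: maximum over the
    grid; ``t_min_pstat3``: time of the global pSTAT3 minimum (recovery
    onset); SOCS3 peak time and fold-height over baseline.
    """
    ps = traj.pstat3
    degenerate = bool(np.ptp(ps) < 1e-7)
    reductions = 100.0 * (1.0 - ps)
    imin = int(np.argmin(ps))
    ipk = int(np.argmax(traj.socs3))

    def reduction_at(t: float) -> float:
        return float(np.interp(t, traj.time, reductions))

    return {
        "reduction_at": reduction_at,
        "max_inhibition": float(reductions[imin]) if not degenerate else 0.0,
        "t_min_pstat3": float(traj.time[imin]),
        "socs3_peak_time": float(traj.time[ipk]),
        "socs3_peak_height": float(traj.socs3[ipk]),
        "degenerate": degenerate,
    }


def dose_response(params: KineticParams = DEFAULT_PARAMS,
                  drug: DrugProfile = BARICITINIB,
                  doses=(0.0, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0),
                  t_end: float = 24.0) -> pd.DataFrame:
    """Steady-state inhibition of pSTAT3 and TNF per maintained dose.

    The concentration is held constant (maintained exposure rather than a
    single decaying dose, so the read-out is the steady-state inhibition
    level); trajectories are evaluated at the end of the window, by which
    the system has settled.  Doses are reported sorted ascending.
    """
    import dataclasses

    held = dataclasses.replace(drug, pk_half_life=math.inf)
    rows = []
    for dose in sorted(float(d) for d in doses):
        traj = simulate_timecourse(params, held, dose=dose, t_end=t_end)
        rows.append({
            "dose_nM": dose,
            "pstat3_inhibition_pct": 100.0 * (1.0 - traj.pstat3[-1]),
            "tnf_inhibition_pct": 100.0 * (1.0 - traj.tnf[-1]),
        })
    return pd.DataFrame(rows)
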