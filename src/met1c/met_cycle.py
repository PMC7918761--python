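"""Deterministic kinetic model of the methionine cycle.

The model tracks four metabolite pools (methionine, SAM, SAH, homocysteine,
all in µM) connected by the canonical cycle enzymes: the three methionine
adenosyltransferase isoforms (MATI/II/III), glycine N-methyltransferase
(GNMT), a generic SAM-dependent methyltransferase flux (``DNMT``) standing
for SAM-mediated transmethylation, reversible SAH hydrolase (AHCY),
cystathionine β-synthase (CBS, the transsulfuration exit), and the two
homocysteine remethylation routes: folate/B12-dependent methionine synthase
(MTR) and betaine-dependent BHMT.  Cofactor pools (5-methyl-THF, betaine,
adenosine) are held constant.

The scientific question the module answers is how the presence or absence
of BHMT changes the volatility of the transmethylation flux when methionine
supply fluctuates: follicular and embryonic cells, which lack BHMT, are
predicted to show larger swings in SAM-mediated transmethylation than
BHMT-expressing (hepatic-like) cells under the same forcing.

Units are fixed: time in hours, concentrations in µM, fluxes in µM·h⁻¹.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "MetCycleState",
    "EnzymeParams",
    "EnzymeProfile",
    "InputProtocol",
    "Trajectory",
    "VolatilityResult",
    "KnockoutComparison",
    "SolverError",
    "ENZYMES",
    "FLUX_NAMES",
    "load_profile",
    "reaction_fluxes",
    "rhs",
    "simulate",
    "steady_state",
    "transmethylation_volatility",
    "knockout_experiment",
]

ENZYMES = ("MATI", "MATII", "MATIII", "GNMT", "DNMT", "AHCY", "CBS", "MTR", "BHMT")
FLUX_NAMES = (
    "V_MATI",
    "V_MATII",
    "V_MATIII",
    "V_GNMT",
    "V_DNMT",
    "V_AHCY",
    "V_CBS",
    "V_MTR",
    "V_BHMT",
)

# integration / root-finding tolerances (fixed package policy)
RTOL = 1e-8
ATOL = 1e-10
STEADY_TOL = 1e-10


class SolverError(RuntimeError):
    """Raised when the integrator or root finder fails to converge."""


@dataclass(frozen=True)
class MetCycleState:
    """Concentrations of the four cycle metabolites (µM)."""

    met: float
    sam: float
    sah: float
    hcy: float

    def as_array(self) -> np.ndarray:
        return np.array([self.met, self.sam, self.sah, self.hcy], dtype=float)

    @staticmethod
    def from_array(x: Sequence[float]) -> "MetCycleState":
        return MetCycleState(float(x[0]), float(x[1]), float(x[2]), float(x[3]))

    def validate(self) -> None:
        for name, v in zip(("met", "sam", "sah", "hcy"), self.as_array()):
            if v < 0:
                raise ValueError(f"negative concentration {name}={v} µM")


@dataclass(frozen=True)
class EnzymeParams:
    """Kinetic constants for one enzyme (µM and µM·h⁻¹) plus a presence flag."""

    vmax: float = 0.0
    km: float = 1.0
    ki: float = 1.0   # product/feedback inhibition constant where applicable
    ka: float = 1.0   # activation constant where applicable
    alpha: float = 0.0  # activation amplitude (MATIII) / reverse rate (AHCY)
    km2: float = 1.0  # second substrate Km (MTR: 5mTHF; BHMT: betaine)
    present: bool = True

    def __post_init__(self) -> None:
        if self.vmax < 0:
            raise ValueError("vmax must be >= 0")
        for k in (self.km, self.ki, self.ka, self.km2):
            if k <= 0:
                raise ValueError("Michaelis/modulation constants must be > 0")

    @property
    def v(self) -> float:
        """Effective vmax: absent enzymes contribute exactly zero flux."""
        return self.vmax if self.present else 0.0


@dataclass(frozen=True)
class EnzymeProfile:
    """Full kinetic parameterisation of the cycle for one cell type.

    ``fivemthf``, ``betaine`` and ``adenosine`` are fixed cofactor/substrate
    pools (µM), treated as model inputs rather than states.
    """

    enzymes: dict[str, EnzymeParams]
    fivemthf: float = 5.2
    betaine: float = 50.0
    adenosine: float = 1.0
    name: str = "custom"

    def __post_init__(self) -> None:
        missing = set(ENZYMES) - set(self.enzymes)
        if missing:
            raise ValueError(f"profile missing enzymes: {sorted(missing)}")

    def __getitem__(self, enzyme: str) -> EnzymeParams:
        return self.enzymes[enzyme]

    def knockout(self, names: Iterable[str]) -> "EnzymeProfile":
        """Return a copy with the given enzymes marked absent."""
        names = list(names)
        unknown = set(names) - set(ENZYMES)
        if unknown:
            raise ValueError(f"unknown enzymes: {sorted(unknown)}")
        new = dict(self.enzymes)
        for n in names:
            new[n] = replace(new[n], present=False)
        label = self.name + ("-Δ" + "Δ".join(names) if names else "")
        return EnzymeProfile(new, self.fivemthf, self.betaine, self.adenosine, label)


@dataclass(frozen=True)
class InputProtocol:
    """Methionine supply protocol V_in(t) in µM·h⁻¹.

    kinds: ``constant`` (baseline), ``step`` (baseline → step_to at
    step_time), ``sinusoid`` (baseline·(1 + rel_amplitude·sin(2πt/period))).
    """

    kind: str = "constant"
    baseline: float = 50.0
    step_to: float = 50.0
    step_time: float = 0.0
    rel_amplitude: float = 0.0
    period: float = 12.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "step", "sinusoid"):
            raise ValueError(f"unknown input kind {self.kind!r}")
        if self.baseline < 0:
            raise ValueError("baseline must be >= 0")
        if not (0 <= self.rel_amplitude < 1):
            raise ValueError("rel_amplitude must be in [0, 1)")
        if self.kind == "sinusoid" and self.period <= 0:
            raise ValueError("period must be > 0 for a sinusoid")

    def rate(self, t: float) -> float:
        if self.kind == "constant":
            return self.baseline
        if self.kind == "step":
            return self.baseline if t < self.step_time else self.step_to
        return self.baseline * (1.0 + self.rel_amplitude * math.sin(2.0 * math.pi * t / self.period))


@dataclass
class Trajectory:
    """Time course of states and per-reaction fluxes."""

    times: np.ndarray                  # h, strictly increasing
    states: np.ndarray                 # (n, 4): met, sam, sah, hcy
    fluxes: np.ndarray                 # (n, 9) columns in FLUX_NAMES order
    input_rates: np.ndarray            # (n,) V_in(t)

    def state_at(self, i: int) -> MetCycleState:
        return MetCycleState.from_array(self.states[i])

    def flux(self, name: str) -> np.ndarray:
        return self.fluxes[:, FLUX_NAMES.index(name)]

    def to_tsv(self, path) -> None:
        header = "time\tmet\tsam\tsah\thcy\t" + "\t".join(FLUX_NAMES)
        data = np.column_stack([self.times, self.states, self.fluxes])
        np.savetxt(path, data, delimiter="\t", header=header, comments="")


@dataclass(frozen=True)
class VolatilityResult:
    """Relative amplitude of one flux over the analysis window."""

    flux_name: str
    mean_flux: float
    rel_amplitude: float  # (max - min) / mean


@dataclass(frozen=True)
class KnockoutComparison:
    baseline: VolatilityResult
    knockout: VolatilityResult
    baseline_steady: MetCycleState
    knockout_steady: MetCycleState
    mtr_fraction_baseline: float  # V_MTR / (V_MTR + V_BHMT) at steady state
    mtr_fraction_knockout: float


# ---------------------------------------------------------------------------
# parameter tables


def _load_param_table() -> dict:
    with resources.files("met1c.params").joinpath("default.toml").open("rb") as fh:
        return tomllib.load(fh)


def load_profile(preset_or_path: str = "hepatic") -> EnzymeProfile:
    """Build an :class:`EnzymeProfile` from a preset name or a TOML file.

    Presets: ``hepatic`` (all enzymes present, including MATI/MATIII and
    BHMT) and ``follicular`` (MATII as the sole MAT isoform, BHMT absent),
    mirroring the expression pattern of liver versus ovarian-follicle and
    embryonic cells.  Parameter values are package defaults chosen to give a
    physiologically plausible operating point, not literature constants.
    """
    if preset_or_path in ("hepatic", "follicular"):
        table = _load_param_table()
    else:
        with open(preset_or_path, "rb") as fh:
            table = tomllib.load(fh)
    pools = table.get("pools", {})
    enzymes = {
        name: EnzymeParams(**{k: v for k, v in table[name].items()})
        for name in ENZYMES
    }
    prof = EnzymeProfile(
        enzymes,
        fivemthf=pools.get("fivemthf", 5.2),
        betaine=pools.get("betaine", 50.0),
        adenosine=pools.get("adenosine", 1.0),
        name=preset_or_path,
    )
    if preset_or_path == "follicular":
        prof = EnzymeProfile(
            prof.knockout(["MATI", "MATIII", "BHMT"]).enzymes,
            prof.fivemthf, prof.betaine, prof.adenosine, "follicular",
        )
    return prof


# ---------------------------------------------------------------------------
# rate laws

def reaction_fluxes(state: MetCycleState, profile: EnzymeProfile) -> dict[str, float]:
    """Evaluate every reaction rate (µM·h⁻¹) at a state.

    Rate laws encode the canonical regulatory motifs of the cycle:
    SAM product-inhibits MATI/II and activates MATIII; GNMT is cooperative
    in SAM and inhibited by SAH; the generic transmethylation flux (DNMT)
    is Michaelis–Menten in SAM with SAH inhibition; AHCY is reversible
    mass action; CBS is activated by (SAM+SAH); MTR and BHMT are bi-substrate
    Michaelis–Menten in Hcy and their respective methyl donors.
    """
    state.validate()
    met, sam, sah, hcy = state.met, state.sam, state.sah, state.hcy
    e = profile.enzymes

    m1 = e["MATI"]
    v_mat1 = m1.v * met / (m1.km + met) * m1.ki / (m1.ki + sam)
    m2 = e["MATII"]
    v_mat2 = m2.v * met / (m2.km + met) * m2.ki / (m2.ki + sam)
    m3 = e["MATIII"]
    v_mat3 = m3.v * met / (m3.km + met) * (1.0 + m3.alpha * sam**2 / (m3.ka**2 + sam**2))
    g = e["GNMT"]
    v_gnmt = g.v * sam**2 / (g.km**2 + sam**2) * g.ki / (g.ki + sah)
    d = e["DNMT"]
    v_dnmt = d.v * sam / (d.km + sam) * d.ki / (d.ki + sah)
    a = e["AHCY"]
    # vmax acts as forward rate constant (h⁻¹); alpha as reverse (µM⁻¹·h⁻¹)
    v_ahcy = a.v * sah - (a.alpha if a.present else 0.0) * hcy * profile.adenosine
    c = e["CBS"]
    act = (sam + sah) ** 2 / (c.ka**2 + (sam + sah) ** 2)
    v_cbs = c.v * hcy * act
    r = e["MTR"]
    v_mtr = r.v * hcy / (r.km + hcy) * profile.fivemthf / (r.km2 + profile.fivemthf)
    b = e["BHMT"]
    v_bhmt = b.v * hcy / (b.km + hcy) * profile.betaine / (b.km2 + profile.betaine)

    return {
        "V_MATI": v_mat1,
        "V_MATII": v_mat2,
        "V_MATIII": v_mat3,
        "V_GNMT": v_gnmt,
        "V_DNMT": v_dnmt,
        "V_AHCY": v_ahcy,
        "V_CBS": v_cbs,
        "V_MTR": v_mtr,
        "V_BHMT": v_bhmt,
    }


def _fluxes_arr(x: np.ndarray, profile: EnzymeProfile) -> np.ndarray:
    f = reaction_fluxes(MetCycleState.from_array(x), profile)
    return np.array([f[n] for n in FLUX_NAMES])


def rhs(state: MetCycleState, t: float, profile: EnzymeProfile,
        protocol: InputProtocol) -> np.ndarray:
    """Time derivative of (met, sam, sah, hcy) under the stoichiometry

    dMet/dt = V_in + V_MTR + V_BHMT − V_MATI − V_MATII − V_MATIII
    dSAM/dt = ΣV_MAT − V_GNMT − V_DNMT
    dSAH/dt = V_GNMT + V_DNMT − V_AHCY
    dHcy/dt = V_AHCY − V_MTR − V_BHMT − V_CBS
    """
    f = reaction_fluxes(state, profile)
    v_in = protocol.rate(t)
    dmet = v_in + f["V_MTR"] + f["V_BHMT"] - f["V_MATI"] - f["V_MATII"] - f["V_MATIII"]
    dsam = f["V_MATI"] + f["V_MATII"] + f["V_MATIII"] - f["V_GNMT"] - f["V_DNMT"]
    dsah = f["V_GNMT"] + f["V_DNMT"] - f["V_AHCY"]
    dhcy = f["V_AHCY"] - f["V_MTR"] - f["V_BHMT"] - f["V_CBS"]
    return np.array([dmet, dsam, dsah, dhcy])


def _rhs_arr(t: float, x: np.ndarray, profile: EnzymeProfile,
             protocol: InputProtocol) -> np.ndarray:
    # clip tiny negative excursions of the solver before rate evaluation
    xc = np.maximum(x, 0.0)
    return rhs(MetCycleState.from_array(xc), t, profile, protocol)


def simulate(profile: EnzymeProfile, protocol: InputProtocol,
             init: MetCycleState, t_end: float, dt_report: float = 0.05,
             ) -> Trajectory:
    """Integrate the cycle with a stiff-capable solver (LSODA, rtol 1e-8)."""
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    init.validate()
    t_eval = np.arange(0.0, t_end + 0.5 * dt_report, dt_report)
    t_eval = t_eval[t_eval <= t_end]
    sol = solve_ivp(
        _rhs_arr, (0.0, t_end), init.as_array(), t_eval=t_eval,
        args=(profile, protocol), method="LSODA", rtol=RTOL, atol=ATOL,
    )
    if not sol.success:
        raise SolverError(f"integration failed near t={sol.t[-1]:.4g} h: {sol.message}")
    states = np.maximum(sol.y.T, 0.0)
    fluxes = np.array([_fluxes_arr(s, profile) for s in states])
    vin = np.array([protocol.rate(t) for t in sol.t])
    return Trajectory(sol.t, states, fluxes, vin)


def steady_state(profile: EnzymeProfile, constant_input: float,
                 t_burn: float = 3000.0) -> MetCycleState:
    """Steady state under constant input, by root-finding seeded from a
    long integration.  Raises :class:`SolverError` unless ‖rhs‖∞ < 1e-10."""
    protocol = InputProtocol(kind="constant", baseline=constant_input)
    if constant_input == 0.0:
        # the empty cycle: every rate law vanishes at the origin
        zero = MetCycleState(0.0, 0.0, 0.0, 0.0)
        if np.max(np.abs(rhs(zero, 0.0, profile, protocol))) < STEADY_TOL:
            return zero
    traj = simulate(profile, protocol, MetCycleState(10.0, 1.0, 1.0, 1.0),
                    t_end=t_burn, dt_report=t_burn / 100)
    x0 = traj.states[-1]

    def fun(x: np.ndarray) -> np.ndarray:
        return _rhs_arr(0.0, x, profile, protocol)

    sol = root(fun, x0, method="hybr", tol=1e-13)
    resid = np.max(np.abs(fun(sol.x)))
    if resid >= STEADY_TOL or np.any(sol.x < -1e-9):
        raise SolverError(
            f"no steady state found for input {constant_input} µM/h "
            f"(‖rhs‖∞={resid:.3g}); the configuration may be non-physiological"
        )
    return MetCycleState.from_array(np.maximum(sol.x, 0.0))


def transmethylation_volatility(
    profile: EnzymeProfile, protocol: InputProtocol,
    n_transient_periods: int = 5, n_analysis_periods: int = 3,
    flux_name: str = "V_DNMT",
) -> VolatilityResult:
    """Relative amplitude (max−min)/mean of a flux under periodic forcing.

    The system starts at the constant-input steady state, the first
    ``n_transient_periods`` forcing periods are discarded, and volatility is
    measured over the following ``n_analysis_periods``.
    """
    if protocol.kind != "sinusoid":
        raise ValueError("volatility analysis requires a sinusoid protocol")
    if n_transient_periods < 1 or n_analysis_periods < 1:
        raise ValueError("period counts must be >= 1")
    init = steady_state(profile, protocol.baseline)
    t_end = (n_transient_periods + n_analysis_periods) * protocol.period
    traj = simulate(profile, protocol, init, t_end,
                    dt_report=protocol.period / 200.0)
    mask = traj.times >= n_transient_periods * protocol.period
    v = traj.flux(flux_name)[mask]
    mean = float(np.mean(v))
    rel = float((np.max(v) - np.min(v)) / mean) if mean > 0 else 0.0
    return VolatilityResult(flux_name, mean, rel)


def knockout_experiment(
    base_profile: EnzymeProfile, enzymes_to_remove: Iterable[str],
    protocol: InputProtocol,
) -> KnockoutComparison:
    """Compare transmethylation volatility and steady-state remethylation
    routing between a base profile and the same profile with enzymes removed.

    The MTR fraction V_MTR/(V_MTR+V_BHMT) quantifies how much homocysteine
    remethylation relies on the folate/B12 route.
    """
    ko = base_profile.knockout(enzymes_to_remove)
    results = []
    for prof in (base_profile, ko):
        ss = steady_state(prof, protocol.baseline)
        f = reaction_fluxes(ss, prof)
        remeth = f["V_MTR"] + f["V_BHMT"]
        frac = f["V_MTR"] / remeth if remeth > 0 else float("nan")
        vol = transmethylation_volatility(prof, protocol)
        results.append((vol, ss, frac))
    (vol_b, ss_b, fr_b), (vol_k, ss_k, fr_k) = results
    return KnockoutComparison(vol_b, vol_k, ss_b, ss_k, fr_b, fr_k)
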