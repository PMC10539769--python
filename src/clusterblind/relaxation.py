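"""Paramagnetic relaxation enhancement and 15N-derived correlation times.

Three paramagnetic contributions to nuclear relaxation near an Fe-S
cluster are modeled: Solomon point-dipole (dipolar), contact (scalar), and
Curie-spin. Dipolar and Curie terms fall off as r^-6 with the
metal-to-proton distance, which is what makes distance-calibrated
linewidth prediction possible even when the electron relaxation time is
unknown: the r^-6 law lets one observed (distance, linewidth) pair anchor
predictions at all other distances.

The module also contains the rigid-isotropic-rotor 15N relaxation model
(N-H dipolar + CSA) used to estimate the molecular rotational correlation
time from the R2/R1 ratio, which is field-dependent but independent of
the N-H bond order parameter in the rigid limit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .constants import CONSTANTS, PhysicalConstants

DETECTION_THRESHOLD_HZ = 4000.0    # linewidths above this: broadened beyond detection
DIAMAGNETIC_FLOOR_HZ = 30.0        # default diamagnetic linewidth floor

# 15N relaxation model parameters (standard values for backbone amides)
N15_CSA_PPM = -160.0
NH_BOND_M = 1.02e-10


@dataclass(frozen=True)
class RelaxationEnvironment:
    """Magnetic field, temperature and correlation times for PRE formulas.

    ``tau_r`` is the molecular rotational correlation time, ``tau_s`` the
    electron spin relaxation time. Fe-S clusters have fast-relaxing
    electrons (tau_s ~ 1e-11 - 1e-10 s), so the dipolar correlation time
    tau_c = (1/tau_r + 1/tau_s)^-1 is electron-dominated while the
    Curie-spin term is modulated by tau_r alone.
    """

    b0_tesla: float
    t_kelvin: float
    tau_r: float
    tau_s: float
    nucleus: str = "1H"
    g: float = 2.0
    const: PhysicalConstants = CONSTANTS

    @classmethod
    def from_proton_mhz(cls, freq_mhz: float, **kw) -> "RelaxationEnvironment":
        b0 = 2.0 * np.pi * freq_mhz * 1e6 / CONSTANTS.gamma_of("1H")
        return cls(b0_tesla=b0, **kw)

    def __post_init__(self):
        if self.tau_r <= 0 or self.tau_s <= 0:
            raise ValueError("correlation times must be positive")
        if self.t_kelvin <= 0:
            raise ValueError("temperature must be positive")

    @property
    def omega_i(self) -> float:
        """Nuclear Larmor frequency, rad/s (signed by gamma)."""
        return self.const.gamma_of(self.nucleus) * self.b0_tesla

    @property
    def omega_s(self) -> float:
        """Electron Larmor frequency, rad/s."""
        return self.g * self.const.mu_B * self.b0_tesla / self.const.hbar

    @property
    def tau_c(self) -> float:
        """Dipolar correlation time: harmonic combination of tau_r, tau_s."""
        return 1.0 / (1.0 / self.tau_r + 1.0 / self.tau_s)


def _dd_prefactor(env: RelaxationEnvironment, ss: float, r_m: float) -> float:
    """Dipolar prefactor with ss = S(S+1) (or its ladder-averaged value)."""
    c = env.const
    gamma_i = c.gamma_of(env.nucleus)
    return ((c.mu_0 / (4 * np.pi)) ** 2 * gamma_i ** 2 * env.g ** 2
            * c.mu_B ** 2 * ss / r_m ** 6)


def dipolar_rate(env: RelaxationEnvironment, s_eff: float, r_angstrom: float,
                 which: Literal["R1", "R2"] = "R2",
                 s_squared: float | None = None) -> float:
    """Solomon point-dipole R1 or R2 in s^-1 at distance r from the metal.

    ``s_eff`` is an effective spin quantum number; for an exchange-coupled
    cluster pass ``s_squared`` = Boltzmann-averaged <S(S+1)> from
    :func:`clusterblind.spinladder.effective_s_squared` instead, which
    overrides ``s_eff``.
    """
    if r_angstrom <= 0:
        raise ValueError("distance must be positive")
    r_m = r_angstrom * 1e-10
    tc = env.tau_c
    wi, ws = abs(env.omega_i), env.omega_s
    ss = s_squared if s_squared is not None else s_eff * (s_eff + 1)
    pref = _dd_prefactor(env, ss, r_m)
    if which == "R2":
        spectral = (4 * tc
                    + 3 * tc / (1 + (wi * tc) ** 2)
                    + 13 * tc / (1 + (ws * tc) ** 2))
        return float(pref * spectral / 15.0)
    if which == "R1":
        spectral = (3 * tc / (1 + (wi * tc) ** 2)
                    + 7 * tc / (1 + (ws * tc) ** 2))
        return float(pref * spectral * 2.0 / 15.0)
    raise ValueError("which must be 'R1' or 'R2'")


def contact_r2(env: RelaxationEnvironment, a_mhz: float, s_eff: float,
               s_squared: float | None = None) -> float:
    """Scalar (contact) R2 in s^-1: distance-independent, set by A/h and tau_e."""
    if not np.isfinite(a_mhz):
        raise ValueError("A/h must be finite")
    ss = s_squared if s_squared is not None else s_eff * (s_eff + 1)
    a_rad = 2.0 * np.pi * a_mhz * 1e6
    te = env.tau_c   # tau_e^-1 = tau_r^-1 + tau_s^-1 ~ tau_s^-1
    ws = env.omega_s
    return float(a_rad ** 2 * ss / 3.0 * (te + te / (1 + (ws * te) ** 2)))


def curie_r2(env: RelaxationEnvironment, s_eff: float, r_angstrom: float,
             s_squared: float | None = None) -> float:
    """Curie-spin R2 in s^-1: from the static thermal electron moment.

    Scales as B0^2 (through omega_i^2) and is modulated by the rotational
    correlation time only.
    """
    if r_angstrom <= 0:
        raise ValueError("distance must be positive")
    c = env.const
    ss = s_squared if s_squared is not None else s_eff * (s_eff + 1)
    r_m = r_angstrom * 1e-10
    wi = abs(env.omega_i)
    tr = env.tau_r
    pref = ((c.mu_0 / (4 * np.pi)) ** 2 * wi ** 2 * env.g ** 4 * c.mu_B ** 4
            * ss ** 2 / ((3 * c.k_B * env.t_kelvin) ** 2 * r_m ** 6))
    return float(pref / 5.0 * (4 * tr + 3 * tr / (1 + (wi * tr) ** 2)))


def linewidth_from_r2(r2: float) -> float:
    """Lorentzian half-height linewidth in Hz from R2 in s^-1."""
    if r2 < 0:
        raise ValueError("R2 must be non-negative")
    return r2 / np.pi


def r2_from_linewidth(dnu_hz: float) -> float:
    """Inverse of :func:`linewidth_from_r2`."""
    if dnu_hz < 0:
        raise ValueError("linewidth must be non-negative")
    return dnu_hz * np.pi


@dataclass(frozen=True)
class Calibration:
    """One observed (distance, linewidth) anchor for r^-6 prediction."""

    r_ref_angstrom: float
    dnu_ref_hz: float
    floor_hz: float = DIAMAGNETIC_FLOOR_HZ

    def __post_init__(self):
        if self.r_ref_angstrom <= 0:
            raise ValueError("reference distance must be positive")
        if self.dnu_ref_hz <= self.floor_hz:
            raise ValueError(
                "calibration error: reference linewidth must exceed the "
                "diamagnetic floor"
            )


def calibrated_prediction(cal: Calibration, r_angstrom: float) -> float:
    """Predicted linewidth in Hz at distance r by the r^-6 scaling law.

    Delta_nu(r) = floor + (Delta_nu_ref - floor) (r_ref / r)^6. This bypasses
    the unknown electron relaxation time: the anchor absorbs all prefactors
    shared by the dipolar and Curie terms.
    """
    if r_angstrom <= 0:
        raise ValueError("distance must be positive")
    return cal.floor_hz + (cal.dnu_ref_hz - cal.floor_hz) * \
        (cal.r_ref_angstrom / r_angstrom) ** 6


def detectability(dnu_hz: float,
                  threshold_hz: float = DETECTION_THRESHOLD_HZ) -> str:
    """'observable' or 'beyond_detection' (strictly above the threshold)."""
    if dnu_hz < 0:
        raise ValueError("linewidth must be non-negative")
    return "beyond_detection" if dnu_hz > threshold_hz else "observable"


# ---------------------------------------------------------------------------
# 15N relaxation: rigid isotropic rotor, N-H dipolar + CSA

def _n15_rates(tau_c: float, b0_tesla: float,
               const: PhysicalConstants = CONSTANTS) -> tuple[float, float, float]:
    """(R1, R2, hetNOE) for a rigid isotropic rotor backbone 15N."""
    gh = const.gamma_of("1H")
    gn = const.gamma_of("15N")
    wh = gh * b0_tesla
    wn = gn * b0_tesla
    d = (const.mu_0 / (4 * np.pi)) * const.hbar * gh * gn / NH_BOND_M ** 3
    c = wn * (N15_CSA_PPM * 1e-6) / np.sqrt(3.0)

    def j(w):
        return 0.4 * tau_c / (1 + (w * tau_c) ** 2)

    r1 = (d ** 2 / 4.0) * (3 * j(wn) + j(wh - wn) + 6 * j(wh + wn)) \
        + c ** 2 * j(wn)
    r2 = (d ** 2 / 8.0) * (4 * j(0) + 3 * j(wn) + j(wh - wn)
                           + 6 * j(wh) + 6 * j(wh + wn)) \
        + (c ** 2 / 6.0) * (4 * j(0) + 3 * j(wn))
    sigma = (d ** 2 / 4.0) * (6 * j(wh + wn) - j(wh - wn))
    noe = 1.0 + (gh / gn) * sigma / r1
    return float(r1), float(r2), float(noe)


def simulate_n15_relaxation(tau_c_ns: float, freq_mhz: float) -> tuple[float, float, float]:
    """Forward-model (R1, R2, NOE) for a rigid rotor at the given 1H field."""
    b0 = 2.0 * np.pi * freq_mhz * 1e6 / CONSTANTS.gamma_of("1H")
    return _n15_rates(tau_c_ns * 1e-9, b0)


def tauc_from_n15(r1: float, r2: float, freq_mhz: float,
                  bracket_ns: tuple[float, float] = (1.0, 50.0)) -> float:
    """Rotational correlation time in ns from the 15N R2/R1 ratio.

    Numerically inverts the rigid-rotor ratio; requires the slow-tumbling
    regime (R2/R1 > 1). Raises a regime error when the observed ratio falls
    outside what the model can produce within the bracket.
    """
    if r1 <= 0 or r2 <= 0:
        raise ValueError("rates must be positive")
    ratio = r2 / r1
    if ratio <= 1.0:
        raise ValueError(
            f"regime error: R2/R1 = {ratio:.3f} <= 1 (extreme narrowing); "
            "the slow-tumbling inversion does not apply"
        )
    b0 = 2.0 * np.pi * freq_mhz * 1e6 / CONSTANTS.gamma_of("1H")

    def f(tc_ns):
        m1, m2, _ = _n15_rates(tc_ns * 1e-9, b0)
        return m2 / m1 - ratio

    lo, hi = bracket_ns
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError(
            f"regime error: R2/R1 = {ratio:.3f} not invertible within "
            f"{bracket_ns} ns"
        )
    return float(brentq(f, lo, hi, xtol=1e-6))


def tauc_from_mass(mass_kda: float, ns_per_kda: float = 0.6) -> float:
    """Empirical rule of thumb: tau_c ~ 0.6 ns per kDa near 298 K."""
    if mass_kda <= 0:
        raise ValueError("mass must be positive")
    return ns_per_kda * mass_kda
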