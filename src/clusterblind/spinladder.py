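"""Exchange-coupled two-spin ladder for Fe-S clusters and hyperfine contact shifts.

The two iron ions of an [Fe2S2] cluster are exchange-coupled,
``H = J S1.S2`` with ``J > 0`` antiferromagnetic (spectroscopy sign
convention, J in cm^-1). The eigenstates are total-spin multiplets
S' = |S1-S2| ... S1+S2 — the "spin ladder". Each level contributes to the
hyperfine shift of a ligand proton through the projection coefficient of
the iron site the proton is coupled to, weighted by the Boltzmann
population of the level. An oxidized [Fe2S2]2+ cluster (two high-spin
Fe3+, S1 = S2 = 5/2) has an S' = 0 diamagnetic ground state, so the
contact shift grows with temperature (anti-Curie behaviour) as excited
levels populate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

from .constants import CONSTANTS, PhysicalConstants

ADMISSIBLE_SPINS = (0.5, 1.0, 1.5, 2.0, 2.5)


@dataclass(frozen=True)
class SpinSystem:
    """Two exchange-coupled site spins.

    Parameters
    ----------
    s1, s2:
        Site spin quantum numbers (half-integers up to 5/2; high-spin
        Fe3+ is 5/2, high-spin Fe2+ is 2).
    j_cm:
        Isotropic exchange coupling in cm^-1 for ``H = J S1.S2``;
        positive J is antiferromagnetic.
    g:
        Electron g-factor (isotropic; Fe-S clusters have negligible
        g-anisotropy).
    """

    s1: float
    s2: float
    j_cm: float
    g: float = 2.0

    def __post_init__(self):
        if self.s1 not in ADMISSIBLE_SPINS or self.s2 not in ADMISSIBLE_SPINS:
            raise ValueError(
                f"site spins must be in {ADMISSIBLE_SPINS}, got ({self.s1}, {self.s2})"
            )
        if self.g <= 0:
            raise ValueError("g-factor must be positive")


@dataclass(frozen=True)
class SpinLevel:
    """One total-spin multiplet of the ladder."""

    s_tot: float
    energy_cm: float       # relative to the ground multiplet
    degeneracy: int        # 2 S' + 1
    c1: float              # projection coefficient of site 1
    c2: float              # projection coefficient of site 2


@dataclass(frozen=True)
class HyperfineCoupling:
    """Contact coupling of one proton to one iron site, A/h in MHz."""

    proton_id: str
    a_mhz: float
    site: Literal[1, 2]

    def __post_init__(self):
        if not np.isfinite(self.a_mhz):
            raise ValueError("A/h must be finite")
        if self.site not in (1, 2):
            raise ValueError("coupled site must be 1 or 2")


def ladder(sys: SpinSystem) -> list[SpinLevel]:
    """Total-spin multiplets of ``H = J S1.S2``, energies relative to ground.

    E(S') = (J/2) [S'(S'+1) - S1(S1+1) - S2(S2+1)]; only differences matter,
    so energies are shifted to put the ground multiplet at zero. Projection
    coefficients follow the Landé-type formula
    ``c1 = [S'(S'+1) + S1(S1+1) - S2(S2+1)] / (2 S'(S'+1))``; the S' = 0
    singlet carries no electron moment and gets c1 = c2 = 0 by convention.
    """
    s1, s2, j = sys.s1, sys.s2, sys.j_cm
    smin, smax = abs(s1 - s2), s1 + s2
    s_values = np.arange(smin, smax + 0.5, 1.0)
    raw = 0.5 * j * (s_values * (s_values + 1))
    # ground multiplet is smin for AF (J>0), smax for ferromagnetic coupling
    e0 = raw[0] if j >= 0 else raw[-1]
    levels = []
    for s, e in zip(s_values, raw):
        if s == 0:
            c1 = c2 = 0.0
        else:
            denom = 2.0 * s * (s + 1)
            c1 = (s * (s + 1) + s1 * (s1 + 1) - s2 * (s2 + 1)) / denom
            c2 = (s * (s + 1) + s2 * (s2 + 1) - s1 * (s1 + 1)) / denom
        levels.append(SpinLevel(
            s_tot=float(s),
            energy_cm=float(e - e0),
            degeneracy=int(round(2 * s + 1)),
            c1=c1,
            c2=c2,
        ))
    return levels


def _populations(levels: Sequence[SpinLevel], t_kelvin: float,
                 const: PhysicalConstants = CONSTANTS) -> np.ndarray:
    """Degeneracy-weighted Boltzmann populations, summing to one."""
    if t_kelvin <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    e_j = np.array([const.wavenumber_to_joule(lv.energy_cm) for lv in levels])
    g = np.array([lv.degeneracy for lv in levels], dtype=float)
    w = g * np.exp(-(e_j - e_j.min()) / (const.k_B * t_kelvin))
    return w / w.sum()


def spin_expectation(sys: SpinSystem, t_kelvin: float, site: Literal[1, 2],
                     const: PhysicalConstants = CONSTANTS) -> float:
    """Thermal average W = <c_site S'(S'+1)> over the ladder.

    This is the quantity that multiplies the Curie prefactor in the contact
    shift; for an uncoupled (J = 0) homodimer it equals S(S+1) of one site.
    """
    levels = ladder(sys)
    pop = _populations(levels, t_kelvin, const)
    c = np.array([lv.c1 if site == 1 else lv.c2 for lv in levels])
    ss1 = np.array([lv.s_tot * (lv.s_tot + 1) for lv in levels])
    return float(np.sum(c * ss1 * pop))


def effective_s_squared(sys: SpinSystem, t_kelvin: float, site: Literal[1, 2],
                        const: PhysicalConstants = CONSTANTS) -> float:
    """Effective <S(S+1)> for relaxation: c_i^2-weighted Boltzmann average."""
    levels = ladder(sys)
    pop = _populations(levels, t_kelvin, const)
    c = np.array([lv.c1 if site == 1 else lv.c2 for lv in levels])
    ss1 = np.array([lv.s_tot * (lv.s_tot + 1) for lv in levels])
    return float(np.sum(c ** 2 * ss1 * pop))


def contact_shift(sys: SpinSystem, coupling: HyperfineCoupling, t_kelvin: float,
                  nucleus: str = "1H",
                  const: PhysicalConstants = CONSTANTS) -> float:
    """Hyperfine contact shift in ppm for one proton at one temperature.

    delta_con = 2 pi (A/h) * g mu_B / (3 k T gamma_I) * W * 1e6,
    with W = spin_expectation (Boltzmann average of the projected electron
    moment over the ladder). Only the contact (through-bond) contribution is
    returned; the diamagnetic reference shift is handled by the caller.
    """
    if t_kelvin <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    w = spin_expectation(sys, t_kelvin, coupling.site, const)
    a_rad = 2.0 * np.pi * coupling.a_mhz * 1e6     # A/hbar, rad/s
    gamma_i = const.gamma_of(nucleus)
    delta = a_rad * sys.g * const.mu_B * w / (3.0 * const.k_B * t_kelvin * gamma_i)
    return float(delta * 1e6)


def classify_t_dependence(shifts: Sequence[tuple[float, float]],
                          tolerance_ppm: float = 0.05,
                          reference_ppm: float = 0.0) -> str:
    """Classify a (T, ppm) series as 'curie', 'anti-curie' or 'flat'.

    The sign is judged on the magnitude of the hyperfine part
    ``|shift - reference|``: anti-Curie if it grows with temperature by more
    than the tolerance, Curie if it shrinks, flat otherwise.
    """
    if len(shifts) < 2:
        raise ValueError("need at least two temperatures")
    temps = [t for t, _ in shifts]
    if len(set(temps)) != len(temps):
        raise ValueError("duplicate temperatures")
    ordered = sorted(shifts)
    mags = [abs(ppm - reference_ppm) for _, ppm in ordered]
    slope = mags[-1] - mags[0]
    if slope > tolerance_ppm:
        return "anti-curie"
    if slope < -tolerance_ppm:
        return "curie"
    return "flat"


@dataclass
class CouplingFit:
    """Result of fitting J and per-proton A/h to shift-vs-T data."""

    j_cm: float | None
    a_mhz: dict
    residual_rms: float
    under_determined: bool
    # (J grid, per-proton best A/h, RSS) profile when under-determined
    j_profile: list = field(default_factory=list)


def fit_coupling(data: dict, template: SpinSystem,
                 j_bounds: tuple[float, float] = (1.0, 2000.0),
                 site: Literal[1, 2] = 1,
                 diamagnetic_ppm: float = 0.0) -> CouplingFit:
    """Least-squares fit of the ladder model to shift-vs-temperature data.

    Parameters
    ----------
    data:
        Mapping proton id -> list of (T kelvin, observed ppm).
    template:
        SpinSystem providing S1, S2, g; its J is ignored.
    diamagnetic_ppm:
        Reference shift subtracted from observations before fitting.

    With only two temperatures the (J, A/h) pair is under-determined (a
    ridge in parameter space); in that case no point estimate is returned —
    instead a profile of best-fit A/h and residuals along a J grid.
    """
    if not data:
        raise ValueError("no data")
    temps = sorted({t for series in data.values() for t, _ in series})
    if len(temps) < 2:
        raise ValueError("non-identifiable: need at least two temperatures")
    protons = sorted(data)
    obs = {p: [(t, ppm - diamagnetic_ppm) for t, ppm in data[p]] for p in protons}
    flat = [abs(series[-1][1] - series[0][1]) < 1e-12 for series in obs.values()]
    if all(flat):
        raise ValueError("non-identifiable: shifts are flat in temperature")

    def shift_model(j, a, proton_series):
        sys = SpinSystem(template.s1, template.s2, j, template.g)
        return [contact_shift(sys, HyperfineCoupling("p", a, site), t)
                for t, _ in proton_series]

    def best_a_given_j(j):
        """Contact shift is linear in A/h, so per-proton A is a 1-D lsq."""
        a_hat, rss = {}, 0.0
        for p in protons:
            unit = np.array(shift_model(j, 1.0, obs[p]))
            y = np.array([ppm for _, ppm in obs[p]])
            denom = float(unit @ unit)
            a = float(unit @ y) / denom if denom > 0 else 0.0
            a_hat[p] = a
            rss += float(np.sum((y - a * unit) ** 2))
        return a_hat, rss

    if len(temps) == 2:
        grid = np.geomspace(j_bounds[0], j_bounds[1], 60)
        profile = []
        for j in grid:
            a_hat, rss = best_a_given_j(j)
            profile.append((float(j), a_hat, rss))
        best = min(profile, key=lambda row: row[2])
        n = sum(len(s) for s in obs.values())
        return CouplingFit(j_cm=None, a_mhz=best[1],
                           residual_rms=float(np.sqrt(best[2] / n)),
                           under_determined=True, j_profile=profile)

    def residuals(theta):
        j = theta[0]
        res = []
        for i, p in enumerate(protons):
            model = shift_model(j, theta[1 + i], obs[p])
            res.extend(m - y for m, (_, y) in zip(model, obs[p]))
        return res

    a0, _ = best_a_given_j(float(np.sqrt(j_bounds[0] * j_bounds[1])))
    x0 = [float(np.sqrt(j_bounds[0] * j_bounds[1]))] + [a0[p] for p in protons]
    lb = [j_bounds[0]] + [-np.inf] * len(protons)
    ub = [j_bounds[1]] + [np.inf] * len(protons)
    sol = least_squares(residuals, x0, bounds=(lb, ub))
    n = sum(len(s) for s in obs.values())
    return CouplingFit(
        j_cm=float(sol.x[0]),
        a_mhz={p: float(a) for p, a in zip(protons, sol.x[1:])},
        residual_rms=float(np.sqrt(np.sum(sol.fun ** 2) / n)),
        under_determined=False,
    )


# ---------------------------------------------------------------------------
# brute-force reference (kept here for reuse by tests and the methods note)

def _spin_matrices(s: float):
    dim = int(round(2 * s + 1))
    m = np.array([s - k for k in range(dim)])
    sz = np.diag(m)
    sp = np.zeros((dim, dim))
    for k in range(1, dim):
        sp[k - 1, k] = np.sqrt(s * (s + 1) - m[k] * (m[k] + 1))
    sm = sp.T
    return sz, sp, sm


def brute_force_ladder(sys: SpinSystem) -> list[tuple[float, float, int]]:
    """Diagonalize H = J S1.S2 in the full product basis.

    Returns (S_tot, energy_cm relative to ground, degeneracy) per multiplet,
    with S_tot recovered from eigenvalues of S^2. Independent of `ladder`:
    builds explicit spin matrices and uses dense diagonalization.
    """
    s1z, s1p, s1m = _spin_matrices(sys.s1)
    s2z, s2p, s2m = _spin_matrices(sys.s2)
    d1, d2 = s1z.shape[0], s2z.shape[0]
    i1, i2 = np.eye(d1), np.eye(d2)
    kron = np.kron
    s1s2 = (kron(s1z, s2z)
            + 0.5 * (kron(s1p, s2m) + kron(s1m, s2p)))
    h = sys.j_cm * s1s2
    sz = kron(s1z, i2) + kron(i1, s2z)
    sp = kron(s1p, i2) + kron(i1, s2p)
    sm = kron(s1m, i2) + kron(i1, s2m)
    s_sq = sz @ sz + 0.5 * (sp @ sm + sm @ sp)
    # H and S^2 commute; diagonalize H + eps*S^2 to sort degeneracies cleanly
    evals_h, vecs = np.linalg.eigh(h + 1e-9 * s_sq)
    e_pure = np.einsum("ij,ij->j", vecs, h @ vecs)
    s_pure = np.einsum("ij,ij->j", vecs, s_sq @ vecs)
    s_tot = np.round((-1 + np.sqrt(1 + 4 * s_pure)) / 2, 6)
    out = {}
    for e, s in zip(e_pure, s_tot):
        key = float(s)
        out.setdefault(key, []).append(e)
    ground = min(np.mean(v) for v in out.values())
    return sorted(
        (s, float(np.mean(v) - ground), len(v)) for s, v in out.items()
    )


def brute_force_projection(sys: SpinSystem, s_tot: float) -> tuple[float, float]:
    """Projection coefficients (c1, c2) = <S1z>/<Sz>, <S2z>/<Sz> by diagonalization.

    Evaluated in the stretched M = S_tot eigenstate of the requested
    multiplet; independent of the closed-form Landé expression in `ladder`.
    """
    s1z, s1p, s1m = _spin_matrices(sys.s1)
    s2z, s2p, s2m = _spin_matrices(sys.s2)
    i1, i2 = np.eye(s1z.shape[0]), np.eye(s2z.shape[0])
    kron = np.kron
    s1s2 = kron(s1z, s2z) + 0.5 * (kron(s1p, s2m) + kron(s1m, s2p))
    sz = kron(s1z, i2) + kron(i1, s2z)
    sp = kron(s1p, i2) + kron(i1, s2p)
    sm = kron(s1m, i2) + kron(i1, s2m)
    s_sq = sz @ sz + 0.5 * (sp @ sm + sm @ sp)
    # simultaneous eigenbasis of commuting S^2 and Sz
    _, vecs = np.linalg.eigh(s_sq + 1e-7 * sz)
    s2_val = np.einsum("ij,ij->j", vecs, s_sq @ vecs)
    m_val = np.einsum("ij,ij->j", vecs, sz @ vecs)
    target = s_tot * (s_tot + 1)
    pick = np.argmin(np.abs(s2_val - target) + np.abs(m_val - s_tot))
    v = vecs[:, pick]
    z1 = float(v @ (kron(s1z, i2) @ v))
    z2 = float(v @ (kron(i1, s2z) @ v))
    m = float(v @ (sz @ v))
    return z1 / m, z2 / m
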