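"""Tissue-factor-pathway coagulation cascade as a mass-action reaction network.

The model tracks 18 species (zymogens, enzymes and their transient
enzyme--substrate complexes) through 16 reactions of the extrinsic pathway
up to thrombin (IIa), with the thrombin positive feedback through factors
V and VIII and the meizothrombin (mIIa) intermediate.  Inhibitors (TFPI,
antithrombin, the protein-C system) are deliberately absent: in an
aneurysmal lumen the endothelium that hosts them is largely gone.

Units are SI throughout: concentrations in mol/m^3 (numerically equal to
mM), time in s, second-order rate constants in mol^-1 m^3 s^-1.

Reversible bindings are represented as single reaction columns whose rate
is (forward - backward), so the stoichiometric matrix has 16 columns; the
governing ODE is ``dc/dt = S r(c)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "SPECIES",
    "MOIETIES",
    "RateConstants",
    "ReactionNetwork",
    "BatchTrajectory",
    "PhaseReport",
    "build_network",
    "reaction_rates",
    "ode_rhs",
    "simulate_batch",
    "moiety_totals",
    "detect_phases",
    "initial_concentrations",
]

#: Canonical species ordering of the concentration vector.
SPECIES: tuple[str, ...] = (
    "IX", "TF:VIIa", "IX:TF:VIIa", "IXa", "X", "X:TF:VIIa", "Xa",
    "VIIIa:IXa", "X:VIIIa:IXa", "V", "Va", "VIII", "VIIIa", "IIa", "II",
    "Va:Xa", "II:Va:Xa", "mIIa",
)

N_SPECIES = len(SPECIES)
N_REACTIONS = 16

_IDX = {name: i for i, name in enumerate(SPECIES)}

#: Conserved moieties: groups of species sharing a factor backbone.  Each
#: indicator vector lies in the left null space of the stoichiometric matrix,
#: so the summed concentration is a dynamical invariant.
MOIETIES: dict[str, tuple[str, ...]] = {
    "IX": ("IX", "IX:TF:VIIa", "IXa", "VIIIa:IXa", "X:VIIIa:IXa"),
    "TF:VIIa": ("TF:VIIa", "IX:TF:VIIa", "X:TF:VIIa"),
    "X": ("X", "X:TF:VIIa", "X:VIIIa:IXa", "Xa", "Va:Xa", "II:Va:Xa"),
    "V": ("V", "Va", "Va:Xa", "II:Va:Xa"),
    "VIII": ("VIII", "VIIIa", "VIIIa:IXa", "X:VIIIa:IXa"),
    "II": ("II", "II:Va:Xa", "mIIa", "IIa"),
}

#: Physiological initial concentrations (mol/m^3); complexes and most active
#: enzymes start at zero, trace activated factor VIII is present.
DEFAULT_INITIAL: dict[str, float] = {
    "IX": 90e-6,
    "TF:VIIa": 1e-6,
    "X": 170e-6,
    "V": 20e-6,
    "VIII": 0.7e-6,
    "VIIIa": 100e-9,
    "II": 1.4e-3,
}


@dataclass(frozen=True)
class RateConstants:
    """Rate constants of the cascade.

    ``k1``--``k8`` and ``k15`` are second-order (mol^-1 m^3 s^-1); ``k9``--``k14``
    and ``k16``--``k19`` are first-order (s^-1).  Defaults are the standard
    empirical set for the tissue-factor pathway at 37 degC.
    """

    k1: float = 2e4    # activation of V by Xa
    k2: float = 2e4    # activation of V by IIa
    k3: float = 1e4    # activation of VIII by Xa
    k4: float = 2e4    # activation of VIII by IIa
    k5: float = 1e4    # conversion of mIIa to IIa by Va:Xa
    k6: float = 1e5    # on-rate for rapidly formed complexes
    k7: float = 1e4    # on-rate for VIIIa:IXa
    k8: float = 4e5    # on-rate for Va:Xa
    k9: float = 0.005  # off-rate for VIIIa:IXa
    k10: float = 0.4   # off-rate for Va:Xa
    k11: float = 0.3   # turnover: IX activation by TF:VIIa
    k12: float = 1.15  # turnover: X activation by TF:VIIa
    k13: float = 8.2   # turnover: X activation by VIIIa:IXa
    k14: float = 32.0  # turnover: mIIa formation by Va:Xa
    k15: float = 1e2   # activation of IX by Xa
    k16: float = 24.0  # off-rate for IX on TF:VIIa
    k17: float = 44.0  # off-rate for X on TF:VIIa
    k18: float = 0.001 # off-rate for X on VIIIa:IXa
    k19: float = 70.0  # off-rate for II on Va:Xa

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v > 0) or not np.isfinite(v):
                raise ValueError(
                    f"rate constant {f.name} must be strictly positive, got {v!r}"
                )

    def replace(self, **kwargs: float) -> "RateConstants":
        return replace(self, **kwargs)


# Reaction table: (consumed, produced, kind, kinetics).  ``kind`` is either
# "rev" (reversible binding, rate = kf*prod(reactants) - kb*[complex]) or
# "irr" (irreversible, rate = k*prod(reactants); catalysts appear on both
# sides and cancel in the stoichiometry).
_REACTIONS: tuple[dict, ...] = (
    dict(reactants=("IX", "TF:VIIa"), complex="IX:TF:VIIa", kf="k6", kb="k16"),
    dict(substrate="IX:TF:VIIa", products=("TF:VIIa", "IXa"), k="k11"),
    dict(reactants=("X", "TF:VIIa"), complex="X:TF:VIIa", kf="k6", kb="k17"),
    dict(substrate="X:TF:VIIa", products=("TF:VIIa", "Xa"), k="k12"),
    dict(reactants=("X", "VIIIa:IXa"), complex="X:VIIIa:IXa", kf="k6", kb="k18"),
    dict(substrate="X:VIIIa:IXa", products=("VIIIa:IXa", "Xa"), k="k13"),
    dict(substrate="IX", catalyst="Xa", products=("IXa",), k="k15"),
    dict(substrate="V", catalyst="Xa", products=("Va",), k="k1"),
    dict(substrate="VIII", catalyst="Xa", products=("VIIIa",), k="k3"),
    dict(substrate="V", catalyst="IIa", products=("Va",), k="k2"),
    dict(substrate="VIII", catalyst="IIa", products=("VIIIa",), k="k4"),
    dict(reactants=("II", "Va:Xa"), complex="II:Va:Xa", kf="k6", kb="k19"),
    dict(substrate="II:Va:Xa", products=("Va:Xa", "mIIa"), k="k14"),
    dict(substrate="mIIa", catalyst="Va:Xa", products=("IIa",), k="k5"),
    dict(reactants=("VIIIa", "IXa"), complex="VIIIa:IXa", kf="k7", kb="k9"),
    dict(reactants=("Va", "Xa"), complex="Va:Xa", kf="k8", kb="k10"),
)


@dataclass(frozen=True)
class ReactionNetwork:
    """Stoichiometric matrix plus vectorized mass-action rate laws."""

    constants: RateConstants
    S: np.ndarray  # (18, 16) integer stoichiometric matrix
    # per-column descriptors, precompiled to index arrays:
    i_a: np.ndarray       # first reactant index per column
    i_b: np.ndarray       # second reactant index (-1 if first-order)
    i_cx: np.ndarray      # complex index for reversible columns (-1 otherwise)
    k_fwd: np.ndarray     # forward constant per column
    k_back: np.ndarray    # backward constant per column (0 if irreversible)

    @property
    def species(self) -> tuple[str, ...]:
        return SPECIES

    def rates(self, c: np.ndarray) -> np.ndarray:
        """Reaction-rate vector for concentrations ``c``.

        ``c`` may be shape (18,) or (18, n) for vectorized evaluation over
        many cells; the result has matching trailing shape (16,) / (16, n).
        """
        c = np.asarray(c, dtype=float)
        a = c[self.i_a]
        mask2 = self.i_b >= 0
        rev = self.i_cx >= 0
        if c.ndim == 1:
            r = self.k_fwd * a
            r[mask2] *= c[self.i_b[mask2]]
            r[rev] -= self.k_back[rev] * c[self.i_cx[rev]]
        else:
            r = self.k_fwd[:, None] * a
            r[mask2] *= c[self.i_b[mask2]]
            r[rev] -= self.k_back[rev, None] * c[self.i_cx[rev]]
        return r

    def rhs(self, c: np.ndarray) -> np.ndarray:
        """Net production rates ``S @ r(c)``; shape matches ``c``."""
        return self.S @ self.rates(c)

    def jacobian(self, c: np.ndarray) -> np.ndarray:
        """Analytic Jacobian d(rhs)/dc for a single state, shape (18, 18)."""
        c = np.asarray(c, dtype=float)
        dr = np.zeros((N_REACTIONS, N_SPECIES))
        for j in range(N_REACTIONS):
            ia, ib, icx = self.i_a[j], self.i_b[j], self.i_cx[j]
            if ib >= 0:
                dr[j, ia] += self.k_fwd[j] * c[ib]
                dr[j, ib] += self.k_fwd[j] * c[ia]
            else:
                dr[j, ia] += self.k_fwd[j]
            if icx >= 0:
                dr[j, icx] -= self.k_back[j]
        return self.S @ dr


@dataclass(frozen=True)
class BatchTrajectory:
    """Well-mixed batch-reactor solution: times (n,) and concentrations (n, 18)."""

    t: np.ndarray
    c: np.ndarray

    def species(self, name: str) -> np.ndarray:
        return self.c[:, _IDX[name]]


@dataclass(frozen=True)
class PhaseReport:
    """Sigmoidal thrombin-generation phases of a batch run.

    ``plateaued`` is False when the trajectory never settles (then the time
    fields are NaN); this is an outcome, not an error.
    """

    plateaued: bool
    t_lag_end: float = float("nan")
    t_plateau_start: float = float("nan")
    plateau_IIa: float = float("nan")


def initial_concentrations(overrides: dict[str, float] | None = None) -> np.ndarray:
    """Default physiological initial state as an (18,) vector, with optional
    per-species overrides keyed by species name."""
    c0 = np.zeros(N_SPECIES)
    values = dict(DEFAULT_INITIAL)
    if overrides:
        for name, v in overrides.items():
            if name not in _IDX:
                raise KeyError(f"unknown species {name!r}")
            values[name] = float(v)
    for name, v in values.items():
        c0[_IDX[name]] = v
    return c0


def build_network(constants: RateConstants | None = None) -> ReactionNetwork:
    """Assemble the 18 x 16 stoichiometric matrix and rate-law tables.

    The matrix is constructed from the reaction list (catalysts cancel, so
    they do not appear in S) and, by construction, every moiety indicator of
    :data:`MOIETIES` lies in its left null space.
    """
    constants = constants or RateConstants()
    S = np.zeros((N_SPECIES, N_REACTIONS), dtype=int)
    i_a = np.zeros(N_REACTIONS, dtype=int)
    i_b = np.full(N_REACTIONS, -1, dtype=int)
    i_cx = np.full(N_REACTIONS, -1, dtype=int)
    k_fwd = np.zeros(N_REACTIONS)
    k_back = np.zeros(N_REACTIONS)

    for j, rx in enumerate(_REACTIONS):
        if "complex" in rx:  # reversible binding A + B <-> AB
            a, b = rx["reactants"]
            cx = rx["complex"]
            S[_IDX[a], j] -= 1
            S[_IDX[b], j] -= 1
            S[_IDX[cx], j] += 1
            i_a[j], i_b[j], i_cx[j] = _IDX[a], _IDX[b], _IDX[cx]
            k_fwd[j] = getattr(constants, rx["kf"])
            k_back[j] = getattr(constants, rx["kb"])
        else:  # irreversible step, possibly catalytic
            sub = rx["substrate"]
            S[_IDX[sub], j] -= 1
            for p in rx["products"]:
                S[_IDX[p], j] += 1
            i_a[j] = _IDX[sub]
            if "catalyst" in rx:
                i_b[j] = _IDX[rx["catalyst"]]
            k_fwd[j] = getattr(constants, rx["k"])
    return ReactionNetwork(constants, S, i_a, i_b, i_cx, k_fwd, k_back)


def _validated(c: np.ndarray, atol: float) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    cmin = c.min()
    if cmin < -atol:
        i = int(np.unravel_index(np.argmin(c), c.shape)[0])
        raise ValueError(
            f"negative concentration {cmin:.3e} mol/m^3 for species "
            f"{SPECIES[i]} exceeds clipping tolerance {atol:.1e}"
        )
    return np.clip(c, 0.0, None)


def reaction_rates(network: ReactionNetwork, c: np.ndarray, *,
                   atol: float = 1e-12) -> np.ndarray:
    """Rate vector (16,) in mol/(m^3 s); reversible columns may be negative.

    Concentrations in [-atol, 0) are clipped to zero; more negative values
    are rejected.
    """
    return network.rates(_validated(c, atol))


def ode_rhs(network: ReactionNetwork, c: np.ndarray, *,
            atol: float = 1e-12) -> np.ndarray:
    """Net species production ``S r(c)``, shape (18,), mol/(m^3 s)."""
    return network.rhs(_validated(c, atol))


def moiety_totals(c: np.ndarray) -> dict[str, float | np.ndarray]:
    """Summed concentration of each conserved moiety (mol/m^3).

    Accepts (18,) or (18, n) arrays; totals follow the trailing shape.
    """
    c = np.asarray(c, dtype=float)
    return {name: sum(c[_IDX[s]] for s in members)
            for name, members in MOIETIES.items()}


def simulate_batch(
    network: ReactionNetwork,
    c0: np.ndarray | None = None,
    t_end: float = 1000.0,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    n_out: int = 2000,
    extend_to_plateau: bool = True,
    plateau_rate_tol: float = 1e-6,
    max_t_end: float = 64000.0,
) -> BatchTrajectory:
    """Integrate the cascade in a well-mixed batch reactor.

    Uses a stiff BDF integrator with the analytic Jacobian; the rate
    constants span many orders of magnitude.  If ``extend_to_plateau`` the
    horizon doubles (up to ``max_t_end``) until thrombin has settled per
    :func:`detect_phases`.
    """
    c0 = initial_concentrations() if c0 is None else np.asarray(c0, dtype=float)
    if c0.shape != (N_SPECIES,):
        raise ValueError(f"c0 must have shape ({N_SPECIES},)")
    if (c0 < 0).any():
        raise ValueError("initial concentrations must be non-negative")
    if not t_end > 0:
        raise ValueError("t_end must be positive")

    def f(t: float, c: np.ndarray) -> np.ndarray:
        return network.rhs(np.clip(c, 0.0, None))

    def jac(t: float, c: np.ndarray) -> np.ndarray:
        return network.jacobian(np.clip(c, 0.0, None))

    while True:
        t_eval = np.linspace(0.0, t_end, n_out)
        sol = solve_ivp(f, (0.0, t_end), c0, method="BDF", jac=jac,
                        rtol=rtol, atol=atol, t_eval=t_eval)
        if not sol.success:
            raise RuntimeError(
                f"stiff integration failed at t = {sol.t[-1]:.4g} s: {sol.message}"
            )
        traj = BatchTrajectory(sol.t, sol.y.T)
        if not extend_to_plateau or t_end >= max_t_end:
            return traj
        if detect_phases(traj, plateau_rate_tol=plateau_rate_tol).plateaued:
            return traj
        t_end *= 2.0


def detect_phases(
    traj: BatchTrajectory,
    lag_fraction: float = 0.01,
    plateau_rate_tol: float = 1e-6,
) -> PhaseReport:
    """Locate the lag / accelerated / plateau phases of thrombin generation.

    ``t_lag_end`` is the first time [IIa] exceeds ``lag_fraction`` of its
    final value; ``t_plateau_start`` the first time after which the relative
    growth rate |d[IIa]/dt| / [IIa]_final stays below ``plateau_rate_tol``
    (per second).  A flat or unsettled trajectory yields ``plateaued=False``.
    """
    iia = traj.species("IIa")
    t = traj.t
    final = iia[-1]
    if final <= 0:
        return PhaseReport(plateaued=False)
    rate = np.abs(np.gradient(iia, t)) / final
    quiet = rate < plateau_rate_tol
    if not quiet[-1]:
        return PhaseReport(plateaued=False)
    # last index where the rate was above tolerance; plateau starts after it
    above = np.nonzero(~quiet)[0]
    i_plateau = (above[-1] + 1) if above.size else 0
    i_lag = int(np.argmax(iia > lag_fraction * final))
    if iia[i_lag] <= lag_fraction * final:
        return PhaseReport(plateaued=False)
    return PhaseReport(
        plateaued=True,
        t_lag_end=float(t[i_lag]),
        t_plateau_start=float(t[i_plateau]),
        plateau_IIa=float(final),
    )
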