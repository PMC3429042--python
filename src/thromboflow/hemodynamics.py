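"""Incompressible axisymmetric Navier-Stokes solver with shear-thinning
viscosity, plus analytic flow fixtures.

The solver is a finite-volume incremental projection (predictor, TPFA
pressure Poisson, corrector) on the body-fitted grid of
:class:`~thromboflow.geometry.StructuredGrid`:

* collocated cell velocities (u_z, u_r) with first-order upwind convection
  (explicit) and implicit-Euler viscous terms; the apparent viscosity
  follows the Carreau-Yasuda law and is refreshed on a configurable cadence;
* the divergence constraint is enforced on *face volume fluxes*: after the
  Poisson correction every cell's net face flux vanishes to linear-solver
  precision, so instantaneous inlet/outlet mass balance holds by
  construction and the same fluxes drive conservative scalar transport;
* boundary conditions: parabolic inlet profile scaled to Q(t), no-slip
  wall, symmetry axis, zero-gradient outflow with fixed reference pressure.

All quantities SI: m, s, Pa, kg/m^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csc_matrix
from scipy.sparse.linalg import splu

from thromboflow.geometry import InletWaveform, StructuredGrid
from thromboflow.rheology import CarreauYasudaParams, shear_rate, viscosity

__all__ = [
    "FlowField",
    "FlowSeries",
    "FlowSolverConfig",
    "PlanarField",
    "analytic_fixture",
    "velocity_gradient",
    "solve_flow",
]


# ---------------------------------------------------------------------------
# field containers
# ---------------------------------------------------------------------------

@dataclass
class FlowField:
    """Velocity/pressure snapshot on a structured axisymmetric grid.

    ``phi_ax``/``phi_rad`` are the divergence-free face volume fluxes
    (m^3/s) through constant-z and constant-eta faces.
    """

    grid: StructuredGrid
    t: float
    u_z: np.ndarray          # (nz, nr)
    u_r: np.ndarray          # (nz, nr)
    p: np.ndarray            # (nz, nr)
    phi_ax: np.ndarray       # (nz+1, nr)
    phi_rad: np.ndarray      # (nz, nr+1)

    def divergence(self) -> np.ndarray:
        """Net out-flux per unit volume (1/s) in every cell."""
        net = (np.diff(self.phi_ax, axis=0) + np.diff(self.phi_rad, axis=1))
        return net / self.grid.volume

    def inlet_flow(self) -> float:
        return float(self.phi_ax[0].sum())

    def outlet_flow(self) -> float:
        return float(self.phi_ax[-1].sum())


@dataclass
class FlowSeries:
    """One cardiac cycle of flow snapshots (after washout), periodic in t."""

    grid: StructuredGrid
    period: float
    times: np.ndarray               # within [0, period)
    fields: list[FlowField]
    cycle_l2_change: np.ndarray     # per washout cycle, velocity L2 diff

    def fluxes_at(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Face fluxes at arbitrary t by periodic linear interpolation.

        A convex combination of divergence-free flux fields is itself
        divergence-free, so interpolation preserves the constraint.
        """
        tau = t % self.period
        tt = self.times
        i1 = int(np.searchsorted(tt, tau, side="right") % len(tt))
        i0 = (i1 - 1) % len(tt)
        t0, t1 = tt[i0], tt[i1]
        span = (t1 - t0) % self.period
        w = 0.0 if span == 0 else ((tau - t0) % self.period) / span
        f0, f1 = self.fields[i0], self.fields[i1]
        return ((1 - w) * f0.phi_ax + w * f1.phi_ax,
                (1 - w) * f0.phi_rad + w * f1.phi_rad)


@dataclass
class PlanarField:
    """In-plane 2D velocity field on a rectangular grid (for vortex tests)."""

    x: np.ndarray      # (nx,)
    y: np.ndarray      # (ny,)
    u: np.ndarray      # (nx, ny)
    v: np.ndarray      # (nx, ny)

    def gradient_tensor(self) -> np.ndarray:
        """Velocity-gradient tensors (nx, ny, 3, 3); out-of-plane row and
        column are zero (planar flow)."""
        dudx = np.gradient(self.u, self.x, axis=0)
        dudy = np.gradient(self.u, self.y, axis=1)
        dvdx = np.gradient(self.v, self.x, axis=0)
        dvdy = np.gradient(self.v, self.y, axis=1)
        l = np.zeros(self.u.shape + (3, 3))
        l[..., 0, 0] = dudx
        l[..., 0, 1] = dudy
        l[..., 1, 0] = dvdx
        l[..., 1, 1] = dvdy
        return l


# ---------------------------------------------------------------------------
# analytic fixtures
# ---------------------------------------------------------------------------

def _parabolic_face_fluxes(grid: StructuredGrid, Q: float) -> np.ndarray:
    """Exact annular fluxes of a Poiseuille profile through every axial
    face column, shape (nz+1, nr); per-column sums equal Q exactly."""
    R = grid.R_nodes[:, None]
    ra, rb = grid.ax_face_r_in, grid.ax_face_r_out
    return (4.0 * Q / R**2) * ((rb**2 - ra**2) / 2.0
                               - (rb**4 - ra**4) / (4.0 * R**2))


def analytic_fixture(kind: str, params: dict, grid) -> "FlowField | PlanarField":
    """Exact reference flows.

    ``poiseuille`` (params ``Q``) needs a :class:`StructuredGrid` straight
    tube and returns a :class:`FlowField`; ``pure_shear`` (``gamma``),
    ``solid_rotation`` (``omega``, optional ``center``) and ``lamb_oseen``
    (``Gamma``, ``r_c``, optional ``center``) need a planar rectangular grid
    given as a tuple ``(x, y)`` of coordinate vectors and return a
    :class:`PlanarField`.
    """
    if kind == "poiseuille":
        if not isinstance(grid, StructuredGrid):
            raise TypeError("poiseuille fixture requires a StructuredGrid")
        Q = float(params["Q"])
        R = grid.geometry.R0
        phi_ax = _parabolic_face_fluxes(grid, Q)
        u_z = 2.0 * Q / (np.pi * R**2) * (1.0 - (grid.rc / R) ** 2)
        zero = np.zeros_like(u_z)
        return FlowField(grid, 0.0, u_z, zero.copy(), zero.copy(),
                         phi_ax, np.zeros((grid.nz, grid.nr + 1)))

    x, y = grid
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X, Y = np.meshgrid(x, y, indexing="ij")
    if kind == "pure_shear":
        gamma = float(params["gamma"])
        return PlanarField(x, y, gamma * Y, np.zeros_like(Y))
    if kind == "solid_rotation":
        omega = float(params["omega"])
        xc, yc = params.get("center", (0.0, 0.0))
        return PlanarField(x, y, -omega * (Y - yc), omega * (X - xc))
    if kind == "lamb_oseen":
        Gamma = float(params["Gamma"])
        r_c = float(params["r_c"])
        xc, yc = params.get("center", (0.0, 0.0))
        dx, dy = X - xc, Y - yc
        d2 = dx**2 + dy**2
        d2 = np.where(d2 > 0, d2, 1e-300)
        vtheta_over_d = Gamma / (2.0 * np.pi * d2) * (1.0 - np.exp(-d2 / r_c**2))
        return PlanarField(x, y, -vtheta_over_d * dy, vtheta_over_d * dx)
    raise ValueError(f"unknown analytic fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# cell-centered derivatives on the body-fitted mapping
# ---------------------------------------------------------------------------

def _mapped_gradients(grid: StructuredGrid, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(df/dz|_r, df/dr) at cell centers via the (z, eta) mapping chain rule;
    centered differences inside, one-sided at boundaries."""
    eta_c = 0.5 * (grid.eta_nodes[:-1] + grid.eta_nodes[1:])
    z_c = 0.5 * (grid.z_nodes[:-1] + grid.z_nodes[1:])
    f_xi = np.gradient(f, z_c, axis=0)
    f_eta = np.gradient(f, eta_c, axis=1)
    R = grid.geometry.R(z_c)[:, None]
    dR = grid.geometry.dRdz(z_c)[:, None]
    dfdz = f_xi - (eta_c[None, :] * dR / R) * f_eta
    dfdr = f_eta / R
    return dfdz, dfdr


def velocity_gradient(flow: FlowField, grid: StructuredGrid | None = None) -> np.ndarray:
    """Velocity-gradient tensor field (nz, nr, 3, 3) in cylindrical
    components ordered (z, r, theta); swirl-free axisymmetric flow, so the
    only hoop entry is u_r / r."""
    grid = grid or flow.grid
    duzdz, duzdr = _mapped_gradients(grid, flow.u_z)
    durdz, durdr = _mapped_gradients(grid, flow.u_r)
    l = np.zeros(flow.u_z.shape + (3, 3))
    l[..., 0, 0] = duzdz
    l[..., 0, 1] = duzdr
    l[..., 1, 0] = durdz
    l[..., 1, 1] = durdr
    l[..., 2, 2] = flow.u_r / grid.rc
    return l


# ---------------------------------------------------------------------------
# the projection solver
# ---------------------------------------------------------------------------

@dataclass
class FlowSolverConfig:
    cfl: float = 0.35
    dt_max: float = 2e-3
    dt: float | None = None            # explicit override
    cycles: int = 4                    # total simulated cycles; last is recorded
    snapshots_per_cycle: int = 50
    viscosity_refresh: int = 10        # steps between viscosity/LU refresh
    div_tol: float = 1e-8              # max |div| (1/s) after projection
    record_last_cycle: bool = True

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")


class _Stencil:
    """Fixed 5-point sparsity pattern on the cell grid with vectorized
    data assembly (diagonal + interior axial/radial face couplings)."""

    def __init__(self, grid: StructuredGrid) -> None:
        nz, nr = grid.nz, grid.nr
        self.n = nz * nr
        idx = np.arange(self.n).reshape(nz, nr)
        axP, axN = idx[:-1, :].ravel(), idx[1:, :].ravel()
        radP, radN = idx[:, :-1].ravel(), idx[:, 1:].ravel()
        self.rows = np.concatenate([idx.ravel(), axP, axN, radP, radN])
        self.cols = np.concatenate([idx.ravel(), axN, axP, radN, radP])

    def matrix(self, diag: np.ndarray, g_ax: np.ndarray, g_rad: np.ndarray) -> csc_matrix:
        """diag (nz, nr); g_ax (nz-1, nr) and g_rad (nz, nr-1) are the
        (positive) off-diagonal couplings, entered with a minus sign."""
        data = np.concatenate([
            diag.ravel(),
            -g_ax.ravel(), -g_ax.ravel(),
            -g_rad.ravel(), -g_rad.ravel(),
        ])
        return csc_matrix((data, (self.rows, self.cols)), shape=(self.n, self.n))


class FlowSolver:
    def __init__(self, grid: StructuredGrid, waveform: InletWaveform,
                 cy: CarreauYasudaParams, config: FlowSolverConfig | None = None) -> None:
        self.grid = grid
        self.waveform = waveform
        self.cy = cy
        self.cfg = config or FlowSolverConfig()
        g = grid
        self.nz, self.nr = g.nz, g.nr
        self.stencil = _Stencil(g)
        self.rho = cy.rho

        # geometric TPFA factors A/d for interior faces and boundaries
        self.gax_geo = g.ax_face_area[1:-1] / g.ax_dist[1:-1]        # (nz-1, nr)
        self.grad_geo = g.rad_face_area[:, 1:-1] / g.rad_dist[:, 1:-1]  # (nz, nr-1)
        self.g_in_geo = g.ax_face_area[0] / g.ax_dist[0]             # (nr,)
        self.g_out_geo = g.ax_face_area[-1] / g.ax_dist[-1]          # (nr,)
        self.g_wall_geo = g.rad_face_area[:, -1] / g.rad_dist[:, -1]  # (nz,)

        # pressure Poisson operator (dt-independent scaling, see _project)
        diag = np.zeros((self.nz, self.nr))
        diag[1:, :] -= self.gax_geo
        diag[:-1, :] -= self.gax_geo
        diag[:, 1:] -= self.grad_geo
        diag[:, :-1] -= self.grad_geo
        diag[-1, :] -= self.g_out_geo   # outlet Dirichlet reference pressure
        A = self.stencil.matrix(diag, -self.gax_geo, -self.grad_geo)
        self.poisson_lu = splu(A)

        # per-cell sizes for the convective CFL criterion
        self.dz_cell = np.diff(g.z_nodes)[:, None]                   # (nz, 1)
        self.dr_cell = (np.diff(g.eta_nodes)[None, :]
                        * g.R_nodes[:-1, None])                      # (nz, nr)

        self.t = 0.0
        self.u_z = np.zeros((self.nz, self.nr))
        self.u_r = np.zeros((self.nz, self.nr))
        self.p = np.zeros((self.nz, self.nr))
        self.phi_ax = np.zeros((self.nz + 1, self.nr))
        self.phi_rad = np.zeros((self.nz, self.nr + 1))
        self._step_count = 0
        self._visc_lu = None
        self.dt = self.cfg.dt or self.cfg.dt_max

    # -- time step --------------------------------------------------------
    def _cfl_rate(self) -> float:
        """Max convective rate |u_z|/dz + |u_r|/dr over cells (1/s)."""
        rate = (np.abs(self.u_z) / self.dz_cell
                + np.abs(self.u_r) / self.dr_cell).max()
        # floor: the inlet profile that is about to be imposed over the next
        # refresh window (centerline of a parabolic profile = 2 * mean)
        g = self.grid
        tt = self.t + np.linspace(0.0, 50 * self.dt + 0.02, 16)
        u_inlet = 2.2 * np.max(self.waveform(tt)) / (np.pi * g.geometry.R0**2)
        return float(max(rate, u_inlet / self.dz_cell.min()))

    def _compute_dt(self) -> float:
        if self.cfg.dt is not None:
            return self.cfg.dt
        dt = self.cfg.cfl / max(self._cfl_rate(), 1e-12)
        return float(min(dt, self.cfg.dt_max))

    # -- pieces -----------------------------------------------------------
    def _inlet_fluxes(self, t: float) -> np.ndarray:
        Q = self.waveform(t)
        g = self.grid
        ra, rb = g.ax_face_r_in[0], g.ax_face_r_out[0]
        R = g.R_nodes[0]
        return (4.0 * Q / R**2) * ((rb**2 - ra**2) / 2.0
                                   - (rb**4 - ra**4) / (4.0 * R**2))

    def _convect(self, f: np.ndarray, f_in: np.ndarray) -> np.ndarray:
        """Net upwind out-flux of cell quantity f (units f * m^3/s)."""
        net = np.zeros_like(f)
        phi = self.phi_ax[1:-1]
        up = np.where(phi > 0, f[:-1], f[1:])
        flux = phi * up
        net[:-1] += flux
        net[1:] -= flux
        phi = self.phi_rad[:, 1:-1]
        up = np.where(phi > 0, f[:, :-1], f[:, 1:])
        flux = phi * up
        net[:, :-1] += flux
        net[:, 1:] -= flux
        phi_in = self.phi_ax[0]
        net[0] -= phi_in * np.where(phi_in > 0, f_in, f[0])
        phi_out = self.phi_ax[-1]
        net[-1] += phi_out * f[-1]
        return net

    def _refresh_viscosity(self, dt: float | None = None) -> None:
        self.dt = dt if dt is not None else self._compute_dt()
        l = velocity_gradient(self.field())
        gdot = shear_rate(0.5 * (l + np.swapaxes(l, -1, -2)))
        self.mu = viscosity(self.cy, gdot)
        mu = self.mu
        g = self.grid
        mu_ax = 0.5 * (mu[:-1] + mu[1:])
        mu_rad = 0.5 * (mu[:, :-1] + mu[:, 1:])
        self.gax = mu_ax * self.gax_geo
        self.grad_ = mu_rad * self.grad_geo
        self.g_in = mu[0] * self.g_in_geo
        self.g_wall = mu[:, -1] * self.g_wall_geo

        rhoVdt = self.rho * g.volume / self.dt
        diag_z = rhoVdt.copy()
        diag_r = rhoVdt + mu * g.volume / g.rc**2   # hoop damping of u_r
        for d in (diag_z, diag_r):
            d[1:, :] += self.gax
            d[:-1, :] += self.gax
            d[:, 1:] += self.grad_
            d[:, :-1] += self.grad_
            d[0, :] += self.g_in
            d[:, -1] += self.g_wall
        Mz = self.stencil.matrix(diag_z, self.gax, self.grad_)
        Mr = self.stencil.matrix(diag_r, self.gax, self.grad_)
        self._visc_lu = (splu(Mz), splu(Mr))

    def _project(self, u_z_star: np.ndarray, u_r_star: np.ndarray,
                 phi_in: np.ndarray) -> None:
        g = self.grid
        # face fluxes from the predictor velocity
        phi_ax = np.empty((self.nz + 1, self.nr))
        phi_ax[0] = phi_in
        uf = 0.5 * (u_z_star[:-1] + u_z_star[1:])
        phi_ax[1:-1] = uf * g.ax_face_area[1:-1]
        phi_ax[-1] = u_z_star[-1] * g.ax_face_area[-1]
        phi_rad = np.zeros((self.nz, self.nr + 1))
        uzf = 0.5 * (u_z_star[:, :-1] + u_z_star[:, 1:])
        urf = 0.5 * (u_r_star[:, :-1] + u_r_star[:, 1:])
        phi_rad[:, 1:-1] = (uzf * g.rad_face_nz[:, 1:-1]
                            + urf * g.rad_face_nr[:, 1:-1]) * g.rad_face_area[:, 1:-1]

        div = np.diff(phi_ax, axis=0) + np.diff(phi_rad, axis=1)
        # solve  sum_f g_geo (psi_N - psi_P) = div  with psi = (dt/rho) p_inc
        psi = self.poisson_lu.solve(div.ravel()).reshape(self.nz, self.nr)

        dpsi_ax = psi[1:] - psi[:-1]
        phi_ax[1:-1] -= self.gax_geo * dpsi_ax
        phi_ax[-1] -= self.g_out_geo * (0.0 - psi[-1])
        dpsi_rad = psi[:, 1:] - psi[:, :-1]
        phi_rad[:, 1:-1] -= self.grad_geo * dpsi_rad

        # corrected cell velocities and pressure
        dpsidz, dpsidr = _mapped_gradients(g, psi)
        self.u_z = u_z_star - dpsidz
        self.u_r = u_r_star - dpsidr
        self.p = self.p + (self.rho / self.dt) * psi
        self.phi_ax = phi_ax
        self.phi_rad = phi_rad

    # -- main loop --------------------------------------------------------
    def step(self, t_stop: float | None = None) -> None:
        """Advance one time step; ``t_stop`` clamps the step to end exactly
        there (the implicit operators are rebuilt for the clamped dt)."""
        g = self.grid
        refresh_due = (self._visc_lu is None
                       or self._step_count % self.cfg.viscosity_refresh == 0)
        # CFL guard with the current dt (first-order upwind needs CFL < 1)
        if not refresh_due and self.dt * self._cfl_rate() > min(0.9, 2.5 * self.cfg.cfl):
            refresh_due = True
        dt_clamp = None
        if t_stop is not None and self.t + self.dt > t_stop - 1e-12:
            dt_clamp = max(t_stop - self.t, 1e-9)
            refresh_due = True
        if refresh_due:
            self._refresh_viscosity(dt_clamp)
        dt = self.dt
        cfl = dt * self._cfl_rate()
        if cfl > 1.0:
            raise RuntimeError(
                f"convective CFL {cfl:.2f} > 1 at t = {self.t:.4f} s even "
                f"after step-size refresh (dt = {dt:.3e} s)")

        t_new = self.t + dt
        phi_in = self._inlet_fluxes(t_new)
        u_in = phi_in / g.ax_face_area[0]

        dpdz, dpdr = _mapped_gradients(g, self.p)
        rhoVdt = self.rho * g.volume / dt

        rhs_z = (rhoVdt * self.u_z - self.rho * self._convect(self.u_z, u_in)
                 - g.volume * dpdz)
        rhs_z[0] += self.g_in * u_in
        rhs_r = (rhoVdt * self.u_r - self.rho * self._convect(self.u_r, 0.0)
                 - g.volume * dpdr)

        lu_z, lu_r = self._visc_lu
        u_z_star = lu_z.solve(rhs_z.ravel()).reshape(self.nz, self.nr)
        u_r_star = lu_r.solve(rhs_r.ravel()).reshape(self.nz, self.nr)

        self._project(u_z_star, u_r_star, phi_in)
        self.t = t_new
        self._step_count += 1
        if dt_clamp is not None:
            self._visc_lu = None  # clamped dt: rebuild operators next step

        div = np.abs(np.diff(self.phi_ax, axis=0)
                     + np.diff(self.phi_rad, axis=1)) / g.volume
        if div.max() > self.cfg.div_tol:
            raise RuntimeError(
                f"divergence {div.max():.3e} 1/s exceeds tolerance "
                f"{self.cfg.div_tol:.1e} at t = {self.t:.4f} s")

    def field(self) -> FlowField:
        return FlowField(self.grid, self.t, self.u_z.copy(), self.u_r.copy(),
                         self.p.copy(), self.phi_ax.copy(), self.phi_rad.copy())


def solve_flow(
    grid: StructuredGrid,
    waveform: InletWaveform,
    cy: CarreauYasudaParams | None = None,
    config: FlowSolverConfig | None = None,
    progress: bool = False,
) -> FlowSeries:
    """March ``config.cycles`` cardiac cycles from rest and record the last
    one; earlier cycles serve as washout of the impulsive start.

    Returns the recorded cycle as a periodic :class:`FlowSeries` together
    with the per-cycle L2 velocity change (periodicity diagnostic).
    """
    cy = cy or CarreauYasudaParams()
    cfg = config or FlowSolverConfig()
    solver = FlowSolver(grid, waveform, cy, cfg)
    T = waveform.period

    cycle_l2 = []
    prev_end = None
    fields: list[FlowField] = []
    times: list[float] = []
    for cycle in range(cfg.cycles):
        record = cycle == cfg.cycles - 1 and cfg.record_last_cycle
        cycle_start = cycle * T
        snap_times = cycle_start + np.linspace(0.0, T, cfg.snapshots_per_cycle,
                                               endpoint=False)
        k_snap = 0
        while solver.t < cycle_start + T - 1e-12:
            if record and k_snap < len(snap_times) and solver.t >= snap_times[k_snap] - 1e-12:
                fields.append(solver.field())
                times.append(solver.t - cycle_start)
                k_snap += 1
            solver.step(t_stop=cycle_start + T)
        u_end = np.hypot(solver.u_z, solver.u_r)
        if prev_end is not None:
            w = solver.grid.volume
            num = np.sqrt((w * (u_end - prev_end) ** 2).sum())
            den = np.sqrt((w * u_end**2).sum())
            cycle_l2.append(num / max(den, 1e-300))
        prev_end = u_end
        if progress:
            print(f"cycle {cycle + 1}/{cfg.cycles} done, t = {solver.t:.3f} s",
                  flush=True)
    if not fields:
        fields = [solver.field()]
        times = [solver.t % T]
    return FlowSeries(grid, T, np.asarray(times), fields, np.asarray(cycle_l2))
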