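"""Idealized axisymmetric fusiform AAA geometry, body-fitted structured
grid, exposed-subendothelium wall patches, and a synthetic pulsatile inlet
waveform.

The lumen is a straight tube of radius ``R0`` carrying a cosine-shaped
fusiform bulge of maximum radius ``Rmax`` (default luminal diameter 4.4 cm):

    R(z) = R0 + (Rmax - R0) * (1 + cos(2 pi (z - z_c) / L_b)) / 2

for |z - z_c| <= L_b/2, else R0.  The cosine gives compact support and C^1
continuity at the bulge ends.  All lengths in m.

The structured grid is cell-centered and body-fitted: uniform axial nodes,
radial nodes at r = eta_j R(z_i) with tanh clustering of eta toward the
wall.  Cell volumes and face areas carry the 2 pi r axisymmetric weighting
exactly (linear-in-r quadrature), so discrete mass and species budgets close
to round-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AAAGeometry",
    "ExposurePatch",
    "InletWaveform",
    "StructuredGrid",
    "build_geometry",
    "generate_grid",
    "default_waveform",
    "exposure_patches",
]


@dataclass(frozen=True)
class AAAGeometry:
    """Fusiform AAA lumen profile.  Defaults: 2 cm inlet diameter (typical
    non-aneurysmal infrarenal aorta), 4.4 cm maximum luminal diameter,
    10 cm bulge between 6 cm entrance and exit segments."""

    R0: float = 0.010
    Rmax: float = 0.022
    entrance_length: float = 0.06
    bulge_length: float = 0.10
    exit_length: float = 0.06

    def __post_init__(self) -> None:
        if not self.Rmax >= self.R0 > 0:
            raise ValueError("require Rmax >= R0 > 0")
        if min(self.entrance_length, self.bulge_length, self.exit_length) <= 0:
            raise ValueError("segment lengths must be positive")

    @property
    def z_c(self) -> float:
        """Axial position of the bulge apex (m)."""
        return self.entrance_length + 0.5 * self.bulge_length

    @property
    def length(self) -> float:
        return self.entrance_length + self.bulge_length + self.exit_length

    def R(self, z: np.ndarray | float) -> np.ndarray | float:
        z = np.asarray(z, dtype=float)
        s = z - self.z_c
        inside = np.abs(s) <= 0.5 * self.bulge_length
        bump = 0.5 * (1.0 + np.cos(2.0 * np.pi * s / self.bulge_length))
        r = np.where(inside, self.R0 + (self.Rmax - self.R0) * bump, self.R0)
        return float(r) if r.ndim == 0 else r

    def dRdz(self, z: np.ndarray | float) -> np.ndarray | float:
        z = np.asarray(z, dtype=float)
        s = z - self.z_c
        inside = np.abs(s) <= 0.5 * self.bulge_length
        w = 2.0 * np.pi / self.bulge_length
        d = np.where(inside, -0.5 * (self.Rmax - self.R0) * w * np.sin(w * s), 0.0)
        return float(d) if d.ndim == 0 else d


build_geometry = AAAGeometry  # alias: the constructor is the builder


@dataclass(frozen=True)
class ExposurePatch:
    """Wall strip(s) of exposed subendothelium where TF:VIIa is prescribed."""

    case: str
    intervals: tuple[tuple[float, float], ...]

    def length(self) -> float:
        return sum(z1 - z0 for z0, z1 in self.intervals)

    def contains(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        mask = np.zeros(z.shape, dtype=bool)
        for z0, z1 in self.intervals:
            mask |= (z >= z0) & (z <= z1)
        return mask


def exposure_patches(
    geometry: AAAGeometry,
    case: str,
    z_start: float | None = None,
    z_end: float | None = None,
) -> ExposurePatch:
    """Default damage regions on the proximal bulge wall.

    Case ``A`` (large exposure) covers the proximal half of the bulge;
    case ``B`` (focal exposure) a strip of 10% of the bulge length on the
    proximal bulge wall.  Explicit ``z_start``/``z_end`` override defaults.
    """
    if case not in ("A", "B"):
        raise ValueError(f"unknown exposure case {case!r}; expected 'A' or 'B'")
    zb0 = geometry.z_c - 0.5 * geometry.bulge_length
    if z_start is None or z_end is None:
        if case == "A":
            z_start, z_end = zb0, geometry.z_c
        else:
            z_start = zb0 + 0.20 * geometry.bulge_length
            z_end = zb0 + 0.30 * geometry.bulge_length
    if not z_end > z_start:
        raise ValueError("patch requires z_end > z_start")
    return ExposurePatch(case=case, intervals=((float(z_start), float(z_end)),))


class InletWaveform:
    """Periodic volumetric inflow Q(t) (m^3/s) with one systolic peak.

    Built from a von-Mises-type bump g(t) = exp(kappa (cos(2 pi (t-t_peak)/T) - 1))
    rescaled so that the period mean equals ``q_mean`` exactly and the peak
    value equals ``q_peak``.
    """

    def __init__(self, period: float = 1.2, q_mean: float = 1.667e-5,
                 q_peak: float = 1.0e-4, t_peak: float = 0.25,
                 sharpness: float = 8.0) -> None:
        if period <= 0:
            raise ValueError("period must be positive")
        if q_peak < q_mean:
            raise ValueError("require q_peak >= q_mean")
        self.period = float(period)
        self.q_mean = float(q_mean)
        self.q_peak = float(q_peak)
        self.t_peak = float(t_peak)
        self.sharpness = float(sharpness)
        # period mean of the bump; trapezoid on a smooth periodic function is
        # spectrally accurate
        tt = np.linspace(0.0, period, 4096, endpoint=False)
        self._g_mean = float(np.mean(self._g(tt)))

    def _g(self, t: np.ndarray) -> np.ndarray:
        phase = 2.0 * np.pi * (np.asarray(t, dtype=float) - self.t_peak) / self.period
        return np.exp(self.sharpness * (np.cos(phase) - 1.0))

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        if self.q_peak == self.q_mean:
            q = np.broadcast_to(np.float64(self.q_mean), np.shape(np.asarray(t))).copy()
            return float(self.q_mean) if q.ndim == 0 else q
        f = (self._g(t) - self._g_mean) / (1.0 - self._g_mean)
        q = self.q_mean + (self.q_peak - self.q_mean) * f
        return float(q) if np.ndim(q) == 0 else q


default_waveform = InletWaveform


class StructuredGrid:
    """Cell-centered body-fitted grid of the axisymmetric lumen.

    Cells are indexed ``[i, j]`` with ``i`` axial (0..nz-1, inlet to outlet)
    and ``j`` radial (0..nr-1, axis to wall).  Boundary faces: inlet
    (i = 0), outlet (i = nz), axis (j = 0, zero area), wall (j = nr).
    """

    def __init__(self, geometry: AAAGeometry, nz: int = 200, nr: int = 40,
                 wall_clustering: float = 1.5) -> None:
        if nz < 4 or nr < 4:
            raise ValueError("grid requires nz >= 4 and nr >= 4")
        self.geometry = geometry
        self.nz, self.nr = int(nz), int(nr)
        self.wall_clustering = float(wall_clustering)
        self.has_wall = True

        L = geometry.length
        self.z_nodes = np.linspace(0.0, L, nz + 1)
        s = np.linspace(0.0, 1.0, nr + 1)
        beta = self.wall_clustering
        if beta > 1e-8:
            # tanh stretching: radial spacing shrinks monotonically toward
            # the wall (eta = 1), resolving the WSS/concentration boundary layer
            self.eta_nodes = np.tanh(beta * s) / np.tanh(beta)
        else:
            self.eta_nodes = s.copy()
        self.eta_nodes[0], self.eta_nodes[-1] = 0.0, 1.0

        self.R_nodes = geometry.R(self.z_nodes)                  # (nz+1,)
        # node coordinates (nz+1, nr+1)
        self.Zn = np.broadcast_to(self.z_nodes[:, None],
                                  (nz + 1, nr + 1)).copy()
        self.Rn = self.eta_nodes[None, :] * self.R_nodes[:, None]

        self._build_metrics()

    # -- metric construction ------------------------------------------------
    def _build_metrics(self) -> None:
        nz, nr = self.nz, self.nr
        Zn, Rn = self.Zn, self.Rn

        # quad corners per cell: 00=(i,j) 10=(i+1,j) 11=(i+1,j+1) 01=(i,j+1)
        z00, r00 = Zn[:-1, :-1], Rn[:-1, :-1]
        z10, r10 = Zn[1:, :-1], Rn[1:, :-1]
        z11, r11 = Zn[1:, 1:], Rn[1:, 1:]
        z01, r01 = Zn[:-1, 1:], Rn[:-1, 1:]

        def tri_area(za, ra, zb, rb, zc, rc):
            return 0.5 * np.abs((zb - za) * (rc - ra) - (zc - za) * (rb - ra))

        A1 = tri_area(z00, r00, z10, r10, z11, r11)
        A2 = tri_area(z00, r00, z11, r11, z01, r01)
        self.cell_area = A1 + A2  # meridional (z, r) plane area
        # axisymmetric volume 2 pi * int r dA, exact for linear r over triangles
        V1 = 2.0 * np.pi * A1 * (r00 + r10 + r11) / 3.0
        V2 = 2.0 * np.pi * A2 * (r00 + r11 + r01) / 3.0
        self.volume = V1 + V2
        if (self.volume <= 0).any():
            raise ValueError("degenerate grid: non-positive cell volume")
        # area centroids (meridional)
        cz1 = (z00 + z10 + z11) / 3.0
        cr1 = (r00 + r10 + r11) / 3.0
        cz2 = (z00 + z11 + z01) / 3.0
        cr2 = (r00 + r11 + r01) / 3.0
        self.zc = (A1 * cz1 + A2 * cz2) / self.cell_area
        self.rc = (A1 * cr1 + A2 * cr2) / self.cell_area
        # characteristic cell size: quad diagonal
        self.h = np.hypot(z11 - z00, r11 - r00)

        # axial faces (constant-z), shape (nz+1, nr): annulus between radial
        # nodes; flux area = pi (r_out^2 - r_in^2), normal = +z.
        r_in = Rn[:, :-1]
        r_out = Rn[:, 1:]
        self.ax_face_area = np.pi * (r_out**2 - r_in**2)
        self.ax_face_r_in = r_in
        self.ax_face_r_out = r_out

        # radial faces (constant-eta), shape (nz, nr+1): revolved slanted
        # segment from node (i, j) to (i+1, j); lateral frustum area.
        dz = Zn[1:, :] - Zn[:-1, :]
        dr = Rn[1:, :] - Rn[:-1, :]
        seg = np.hypot(dz, dr)
        rmid = 0.5 * (Rn[1:, :] + Rn[:-1, :])
        self.rad_face_area = 2.0 * np.pi * rmid * seg
        with np.errstate(invalid="ignore", divide="ignore"):
            nzc = np.where(seg > 0, -dr / seg, 0.0)
            nrc = np.where(seg > 0, dz / seg, 1.0)
        self.rad_face_nz = nzc  # unit normal, points toward increasing j
        self.rad_face_nr = nrc
        self.rad_face_zc = 0.5 * (Zn[1:, :] + Zn[:-1, :])

        # TPFA coupling distances (centroid-to-centroid projected on normal)
        self.ax_dist = np.empty((nz + 1, nr))
        self.ax_dist[1:-1] = self.zc[1:] - self.zc[:-1]
        self.ax_dist[0] = self.zc[0] - self.z_nodes[0]          # half-cell at inlet
        self.ax_dist[-1] = self.z_nodes[-1] - self.zc[-1]       # half-cell at outlet

        self.rad_dist = np.empty((nz, nr + 1))
        dzc = self.zc[:, 1:] - self.zc[:, :-1]
        drc = self.rc[:, 1:] - self.rc[:, :-1]
        self.rad_dist[:, 1:-1] = (dzc * self.rad_face_nz[:, 1:-1]
                                  + drc * self.rad_face_nr[:, 1:-1])
        self.rad_dist[:, 0] = self.rc[:, 0]  # centroid to axis
        # wall: centroid to wall face along wall normal
        fz = 0.5 * (Zn[1:, -1] + Zn[:-1, -1])
        fr = 0.5 * (Rn[1:, -1] + Rn[:-1, -1])
        self.rad_dist[:, -1] = ((fz - self.zc[:, -1]) * self.rad_face_nz[:, -1]
                                + (fr - self.rc[:, -1]) * self.rad_face_nr[:, -1])

        # wall-face diagnostics used by WSS
        self.wall_face_z = fz
        self.wall_face_r = fr
        self.wall_face_area = self.rad_face_area[:, -1]
        self.wall_d1 = self.rad_dist[:, -1]
        self.wall_d2 = self.wall_d1 + (
            (self.zc[:, -1] - self.zc[:, -2]) * self.rad_face_nz[:, -1]
            + (self.rc[:, -1] - self.rc[:, -2]) * self.rad_face_nr[:, -1]
        )

    # -- wall helpers -------------------------------------------------------
    def wall_tangent(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit tangent (t_z, t_r) of each wall face, pointing downstream."""
        dz = self.Zn[1:, -1] - self.Zn[:-1, -1]
        dr = self.Rn[1:, -1] - self.Rn[:-1, -1]
        L = np.hypot(dz, dr)
        return dz / L, dr / L

    def wall_faces_in(self, patch: ExposurePatch) -> np.ndarray:
        """Boolean mask over wall faces whose center lies in the patch."""
        return patch.contains(self.wall_face_z)

    # -- integral checks ----------------------------------------------------
    def total_volume(self) -> float:
        return float(self.volume.sum())

    def total_meridional_area(self) -> float:
        return float(self.cell_area.sum())


generate_grid = StructuredGrid  # alias: the constructor is the generator
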