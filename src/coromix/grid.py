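"""Structured cylindrical-section grid and per-plane discrete operators.

The transport solver replaces an unstructured 3D CFD mesh with a structured
cylindrical lattice of cells (axial x radial x angular).  Each axial plane
carries a mask pattern (lumen / catheter / wire); identical patterns share
their discrete operators:

* a laminar quasi-steady axial-velocity profile, obtained by solving a
  Poisson problem on the open cells of the plane (unit forcing, zero
  velocity on walls, catheter and wire) — the cross-section shape of fully
  developed duct flow in an arbitrarily obstructed section;
* a transverse graph Laplacian used to compute the in-plane redistribution
  fluxes that make the prescribed velocity field discretely divergence-free;
* a finite-volume diffusion operator with adiabatic walls.

All lengths are mm, areas mm^2, volumes mm^3, flows mm^3/s.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu, spsolve

from .design import VesselCatheterGeometry, WirePlacement
from .errors import GeometryError

#: Cell labels.
LUMEN, CATHETER, WIRE = 0, 1, 2


@dataclass(frozen=True)
class SolverResolution:
    """Grid resolution and time-stepping control for the transport solver.

    Defaults resolve the 4 x 70 mm lumen with ~1.1 mm axial, 0.2 mm radial
    and 22.5 degree angular cells — coarse by CFD standards but sufficient
    for the mixing statistics the pipeline computes.
    """

    n_axial: int = 63
    n_radial: int = 10
    n_angular: int = 16
    cfl: float = 0.7
    snapshots_per_cycle: int = 32
    n_cycles: int = 2

    def refined(self, factor: int = 2) -> "SolverResolution":
        """Same configuration with cell spacing divided by ``factor``."""
        return replace(
            self,
            n_axial=self.n_axial * factor,
            n_radial=self.n_radial * factor,
            n_angular=self.n_angular * factor,
        )


#: Budget resolution used by batch runs and smoke tests.
COARSE = SolverResolution(n_axial=42, n_radial=8, n_angular=12, snapshots_per_cycle=24)


class CylindricalGrid:
    """Cell-centred cylindrical lattice filling the vessel lumen."""

    def __init__(self, geometry: VesselCatheterGeometry, resolution: SolverResolution):
        self.geometry = geometry
        self.resolution = resolution
        nz, nr, nth = resolution.n_axial, resolution.n_radial, resolution.n_angular
        if min(nz, nr, nth) < 3:
            raise GeometryError("need at least 3 cells per direction")
        self.nz, self.nr, self.ntheta = nz, nr, nth
        radius = geometry.vessel_radius
        self.z_faces = np.linspace(0.0, geometry.vessel_length, nz + 1)
        self.r_faces = np.linspace(0.0, radius, nr + 1)
        self.theta_faces = np.linspace(0.0, 2.0 * np.pi, nth + 1)
        self.dz = self.z_faces[1] - self.z_faces[0]
        self.dr = self.r_faces[1] - self.r_faces[0]
        self.dtheta = self.theta_faces[1] - self.theta_faces[0]
        self.z_centers = 0.5 * (self.z_faces[:-1] + self.z_faces[1:])
        self.r_centers = 0.5 * (self.r_faces[:-1] + self.r_faces[1:])
        self.theta_centers = 0.5 * (self.theta_faces[:-1] + self.theta_faces[1:])
        # per-ring cross-section area of one cell, mm^2
        self.cell_area = 0.5 * (self.r_faces[1:] ** 2 - self.r_faces[:-1] ** 2) * self.dtheta
        self.cell_volume = self.cell_area * self.dz
        # axial face nearest the catheter outlet: the infusion enters here
        self.i_injection = int(round(geometry.outlet_axial_position / self.dz))
        self.i_injection = min(max(self.i_injection, 1), nz - 2)
        self.z_injection = self.z_faces[self.i_injection]

    def plane_index(self, z: float) -> int:
        """Index of the axial plane whose cell contains ``z`` (clamped)."""
        return int(np.clip(int(z / self.dz), 0, self.nz - 1))


def build_mask(grid: CylindricalGrid, geometry: VesselCatheterGeometry) -> np.ndarray:
    """Label every cell LUMEN, CATHETER or WIRE.

    The catheter shaft blocks the centre upstream of its outlet.  The
    pressure/temperature wire continues over the full length: on the axis
    when it runs inside the catheter (side-hole topology), or offset beside
    the catheter shaft (end-hole topology).
    """
    nz, nr, nth = grid.nz, grid.nr, grid.ntheta
    mask = np.zeros((nz, nr, nth), dtype=np.int8)
    rc = grid.r_centers[None, :, None]
    zc = grid.z_centers[:, None, None]
    upstream = zc < grid.z_injection
    mask[np.broadcast_to(upstream & (rc < geometry.catheter_radius), mask.shape)] = CATHETER

    if geometry.wire_placement is WirePlacement.INSIDE:
        wire = np.broadcast_to(rc < geometry.wire_radius, mask.shape) & (mask == LUMEN)
    else:
        # wire axis sits against the catheter shaft at theta = 0
        r_w = geometry.catheter_radius + geometry.wire_radius
        x = grid.r_centers[:, None] * np.cos(grid.theta_centers[None, :])
        y = grid.r_centers[:, None] * np.sin(grid.theta_centers[None, :])
        inside = (x - r_w) ** 2 + y**2 < geometry.wire_radius**2
        wire = np.broadcast_to(inside[None, :, :], mask.shape) & (mask == LUMEN)
    mask[wire] = WIRE

    open_counts = (mask == LUMEN).reshape(nz, -1).sum(axis=1)
    if open_counts.min() < 4:
        raise GeometryError(
            "degenerate geometry: catheter/wire leave fewer than 4 open "
            f"cells in some cross-section (min {open_counts.min()})"
        )
    return mask


class PlanePattern:
    """Discrete operators for one cross-section mask pattern."""

    def __init__(self, open2d: np.ndarray, grid: CylindricalGrid):
        self.open2d = open2d
        nr, nth = grid.nr, grid.ntheta
        self.nr, self.ntheta = nr, nth
        flat_index = -np.ones(nr * nth, dtype=np.int64)
        open_flat = np.flatnonzero(open2d.ravel())
        flat_index[open_flat] = np.arange(open_flat.size)
        self.open_flat = open_flat
        self.n_open = open_flat.size

        dr, dtheta = grid.dr, grid.dtheta
        r_faces, r_centers = grid.r_faces, grid.r_centers

        rad_faces = []  # (j_face, k, ia, ib) flux a->b is radially outward
        ang_faces = []  # (j, k, ia, ib)     flux a->b is + theta direction
        dir_diag = {}  # Dirichlet contributions for the velocity Poisson

        def add_dirichlet(cell, c):
            dir_diag[cell] = dir_diag.get(cell, 0.0) + c

        for j in range(nr):
            for k in range(nth):
                if j + 1 < nr:
                    a, b = open2d[j, k], open2d[j + 1, k]
                    c = r_faces[j + 1] * dtheta / dr
                    if a and b:
                        rad_faces.append(
                            (j + 1, k, flat_index[j * nth + k], flat_index[(j + 1) * nth + k])
                        )
                    elif a:
                        add_dirichlet(flat_index[j * nth + k], 2.0 * c)
                    elif b:
                        add_dirichlet(flat_index[(j + 1) * nth + k], 2.0 * c)
                k2 = (k + 1) % nth
                a, b = open2d[j, k], open2d[j, k2]
                c = dr / (r_centers[j] * dtheta)
                if a and b:
                    ang_faces.append((j, k, flat_index[j * nth + k], flat_index[j * nth + k2]))
                elif a:
                    add_dirichlet(flat_index[j * nth + k], 2.0 * c)
                elif b:
                    add_dirichlet(flat_index[j * nth + k2], 2.0 * c)
            # vessel wall (outermost ring): no-slip Dirichlet face
        for k in range(nth):
            if open2d[nr - 1, k]:
                c = r_faces[nr] * dtheta / (dr / 2.0)
                add_dirichlet(flat_index[(nr - 1) * nth + k], c)

        self._rad = np.array(rad_faces, dtype=np.int64).reshape(-1, 4)
        self._ang = np.array(ang_faces, dtype=np.int64).reshape(-1, 4)

        self.area_open = np.repeat(grid.cell_area, nth)[open_flat]

        # geometric conductances of open-open faces
        c_rad = grid.r_faces[self._rad[:, 0]] * dtheta / dr
        c_ang = dr / (r_centers[self._ang[:, 0]] * dtheta)

        n = self.n_open
        self._velocity_weights = self._solve_velocity(c_rad, c_ang, dir_diag, grid)
        self._lu_unit = self._pinned_unit_laplacian()
        self._diff_flux = self._flux_operator(c_rad, c_ang)

    # -- velocity profile ------------------------------------------------
    def _assemble(self, c_rad, c_ang, dirichlet=None):
        n = self.n_open
        rows, cols, vals = [], [], []
        for faces, conds in ((self._rad, c_rad), (self._ang, c_ang)):
            if faces.size == 0:
                continue
            ia, ib = faces[:, 2], faces[:, 3]
            rows += [ia, ib, ia, ib]
            cols += [ia, ib, ib, ia]
            vals += [conds, conds, -conds, -conds]
        mat = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        ).tocsr()
        if dirichlet:
            diag = np.zeros(n)
            for cell, c in dirichlet.items():
                diag[cell] += c
            mat = mat + sp.diags(diag)
        return mat

    def _solve_velocity(self, c_rad, c_ang, dir_diag, grid):
        """Unit-forced Poisson profile -> normalized axial-flux weights."""
        mat = self._assemble(c_rad, c_ang, dir_diag)
        v = spsolve(mat.tocsc(), self.area_open)
        v = np.maximum(v, 0.0)
        w = v * self.area_open
        total = w.sum()
        if total <= 0:
            raise GeometryError("velocity profile has zero net flux")
        w2d = np.zeros(self.nr * self.ntheta)
        w2d[self.open_flat] = w / total
        return w2d.reshape(self.nr, self.ntheta)

    @property
    def velocity_weights(self) -> np.ndarray:
        """Fraction of the plane's axial volume flux carried by each cell."""
        return self._velocity_weights

    # -- divergence-free redistribution ---------------------------------
    def _pinned_unit_laplacian(self):
        lap = self._assemble(np.ones(len(self._rad)), np.ones(len(self._ang)))
        lap = lap.tolil()
        lap[0, :] = 0.0
        lap[0, 0] = 1.0
        return splu(lap.tocsc())

    def redistribution(self, residual2d: np.ndarray):
        """In-plane face fluxes whose divergence cancels ``residual2d``.

        ``residual2d`` is the per-cell continuity excess (axial outflux
        minus influx minus sources, mm^3/s); it must sum to ~0 over the
        plane.  Returns radial face fluxes ``G`` ((nr+1, ntheta), positive
        outward) and angular face fluxes ``H`` ((nr, ntheta), positive
        towards increasing theta, face k between cells k and k+1).
        """
        rhs = residual2d.ravel()[self.open_flat].astype(float).copy()
        rhs[0] = 0.0
        phi = self._lu_unit.solve(rhs)
        g = np.zeros((self.nr + 1, self.ntheta))
        h = np.zeros((self.nr, self.ntheta))
        if self._rad.size:
            g[self._rad[:, 0], self._rad[:, 1]] = phi[self._rad[:, 2]] - phi[self._rad[:, 3]]
        if self._ang.size:
            h[self._ang[:, 0], self._ang[:, 1]] = phi[self._ang[:, 2]] - phi[self._ang[:, 3]]
        return g, h

    # -- diffusion -------------------------------------------------------
    def _flux_operator(self, c_rad, c_ang):
        """Symmetric flux-form Laplacian C with adiabatic boundaries."""
        return -self._assemble(c_rad, c_ang)

    def diffusion_solver(self, dt: float, diffusivity: float):
        """LU factor of the backward-Euler operator ``I - dt D A^-1 C``."""
        n = self.n_open
        mat = sp.eye(n, format="csr") - dt * diffusivity * sp.diags(
            1.0 / self.area_open
        ) @ self._diff_flux
        return splu(mat.tocsc())


def plane_patterns(grid: CylindricalGrid, mask: np.ndarray):
    """Group axial planes by identical cross-section mask pattern.

    Returns ``(patterns, plane_pattern_id)`` where ``patterns[i]`` is a
    :class:`PlanePattern` and ``plane_pattern_id[z]`` indexes into it.
    """
    flat = mask.reshape(grid.nz, -1)
    _, ids = np.unique(flat, axis=0, return_inverse=True)
    patterns = {}
    for z in range(grid.nz):
        pid = int(ids[z])
        if pid not in patterns:
            patterns[pid] = PlanePattern((mask[z] == LUMEN), grid)
    ordered = [patterns[pid] for pid in sorted(patterns)]
    remap = {pid: i for i, pid in enumerate(sorted(patterns))}
    return ordered, np.array([remap[int(p)] for p in ids], dtype=np.int64)
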