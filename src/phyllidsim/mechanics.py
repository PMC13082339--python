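"""Growing finite-element membrane mechanics.

Each cell is refined into three-node triangular membrane elements with their
own rest configuration.  A St. Venant-Kirchhoff isotropic material under
plane stress (unit thickness) gives the strain energy per element

    A_rest * [ (lambda/2) tr(E)^2 + mu tr(E^2) ],   E = (F^T F - I)/2

with F the deformation gradient from rest to current shape and plane-stress
moduli lambda = E nu/(1-nu^2), mu = E/(2(1+nu)).  Specified growth scales
the rest configurations anisotropically along the cell polarity; after each
growth step the elastic equilibrium is solved and residual stresses are
released (rest := current), so the tissue is stress-free between steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .tissue import CONSTRAINT_FIXED, CONSTRAINT_LONGITUDINAL, Tissue


@dataclass
class Material:
    """Membrane material; E in MPa."""

    E: float = 100.0
    nu: float = 0.3

    @property
    def lam(self) -> float:  # plane-stress first Lame parameter
        return self.E * self.nu / (1.0 - self.nu ** 2)

    @property
    def mu(self) -> float:
        return self.E / (2.0 * (1.0 + self.nu))


DEFAULT_MATERIAL = Material()

_EYE2 = np.eye(2)


class EquilibriumError(RuntimeError):
    pass


class FEMSystem:
    """Vectorized view of a tissue's elements for energy/force evaluation.

    Near-degenerate (sliver) elements can invert numerically; below a det F
    threshold the energy is extended with a convex quadratic penalty on the
    area ratio, which pushes such elements back without affecting healthy
    configurations (the penalty is identically zero for det F above the
    threshold).
    """

    DET_THRESHOLD = 0.2

    def __init__(self, tissue: Tissue, material: Material = DEFAULT_MATERIAL):
        self.tissue = tissue
        self.material = material
        self.vids = sorted(tissue.vertices)
        self.index = {v: i for i, v in enumerate(self.vids)}
        self.positions = np.array([tissue.vertices[v].pos for v in self.vids])
        els = tissue.elements
        self.n_el = len(els)
        self.tri = np.array([[self.index[v] for v in e.vids] for e in els],
                            dtype=int) if els else np.zeros((0, 3), dtype=int)
        rest = np.array([e.rest for e in els]) if els else np.zeros((0, 3, 2))
        d_rest = np.stack([rest[:, 1] - rest[:, 0],
                           rest[:, 2] - rest[:, 0]], axis=-1) if els else \
            np.zeros((0, 2, 2))
        det = (d_rest[:, 0, 0] * d_rest[:, 1, 1] -
               d_rest[:, 0, 1] * d_rest[:, 1, 0])
        if np.any(det <= 0):
            bad = [els[i].cell_id for i in np.nonzero(det <= 0)[0]]
            raise ValueError(f"degenerate rest elements in cells {sorted(set(bad))}")
        self.rest_area = 0.5 * det
        inv = np.empty_like(d_rest)
        inv[:, 0, 0] = d_rest[:, 1, 1]
        inv[:, 0, 1] = -d_rest[:, 0, 1]
        inv[:, 1, 0] = -d_rest[:, 1, 0]
        inv[:, 1, 1] = d_rest[:, 0, 0]
        self.inv_rest = inv / det[:, None, None]

    # -------------------------------------------------------------- energy
    def energy_grad(self, pos: np.ndarray):
        """Total elastic energy and its gradient wrt vertex positions.

        pos: (n_vertices, 2).  Returns (energy, grad) with grad same shape.
        """
        lam, mu = self.material.lam, self.material.mu
        if self.n_el == 0:
            return 0.0, np.zeros_like(pos)
        p = pos[self.tri]  # (n_el, 3, 2)
        dc = np.empty((self.n_el, 2, 2))
        dc[:, :, 0] = p[:, 1] - p[:, 0]
        dc[:, :, 1] = p[:, 2] - p[:, 0]
        F = dc @ self.inv_rest  # (n_el, 2, 2)
        C = np.swapaxes(F, 1, 2) @ F
        Eg = 0.5 * (C - _EYE2)
        trE = Eg[:, 0, 0] + Eg[:, 1, 1]
        W = 0.5 * lam * trE ** 2 + mu * np.einsum("eij,eij->e", Eg, Eg)
        energy = float(np.dot(self.rest_area, W))
        # second Piola-Kirchhoff stress, then nodal gradient
        S = lam * trE[:, None, None] * _EYE2 + 2.0 * mu * Eg
        P = F @ S
        G = self.rest_area[:, None, None] * (P @ np.swapaxes(self.inv_rest, 1, 2))
        # convex extension below the det F threshold (anti-inversion guard)
        J = F[:, 0, 0] * F[:, 1, 1] - F[:, 0, 1] * F[:, 1, 0]
        low = J < self.DET_THRESHOLD
        if np.any(low):
            kpen = self.material.E
            gap = self.DET_THRESHOLD - J[low]
            energy += float(np.dot(0.5 * kpen * self.rest_area[low], gap ** 2))
            # dJ/dDc = cof(Dc)/det(Dr); build cof(Dc) for the low elements
            dcl = dc[low]
            cof = np.empty_like(dcl)
            cof[:, 0, 0] = dcl[:, 1, 1]
            cof[:, 0, 1] = -dcl[:, 1, 0]
            cof[:, 1, 0] = -dcl[:, 0, 1]
            cof[:, 1, 1] = dcl[:, 0, 0]
            det_rest = 2.0 * self.rest_area[low]
            dJ = cof / det_rest[:, None, None]
            G[low] += (-kpen * self.rest_area[low] * gap)[:, None, None] * dJ
        grad = np.zeros_like(pos)
        np.add.at(grad, self.tri[:, 1], G[:, :, 0])
        np.add.at(grad, self.tri[:, 2], G[:, :, 1])
        np.add.at(grad, self.tri[:, 0], -G[:, :, 0] - G[:, :, 1])
        return energy, grad

    def det_F(self, pos: np.ndarray) -> np.ndarray:
        p = pos[self.tri]
        dc = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]], axis=-1)
        F = dc @ self.inv_rest
        return F[:, 0, 0] * F[:, 1, 1] - F[:, 0, 1] * F[:, 1, 0]

    # ---------------------------------------------------------- constraints
    def free_mask(self) -> np.ndarray:
        mask = np.ones((len(self.vids), 2), dtype=bool)
        for i, v in enumerate(self.vids):
            c = self.tissue.vertices[v].constraint
            if c == CONSTRAINT_LONGITUDINAL:
                mask[i, 1] = False
            elif c == CONSTRAINT_FIXED:
                mask[i, :] = False
        return mask


def elastic_energy_and_forces(tissue: Tissue, material: Material = DEFAULT_MATERIAL):
    """Energy and per-vertex forces (-dE/dx) at the current configuration."""
    sys = FEMSystem(tissue, material)
    e, g = sys.energy_grad(sys.positions)
    forces = {v: -g[i] for i, v in enumerate(sys.vids)}
    return e, forces


def apply_growth(tissue: Tissue, dt: float):
    """Grow element rest configurations by the cell-level specified growth.

    Each element's rest shape is mapped about its centroid by
    G = R diag(exp(k_par dt), exp(k_per dt)) R^T, where R rotates the owning
    cell's polarity onto the first axis.  Rest area multiplies by
    exp((k_par + k_per) dt), making rates step-size independent.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    gcache: dict[int, np.ndarray] = {}
    for el in tissue.elements:
        cell = tissue.cells[el.cell_id]
        if cell.k_par == 0.0 and cell.k_per == 0.0:
            continue
        G = gcache.get(el.cell_id)
        if G is None:
            if cell.polarity is None:
                raise ValueError(f"cell {el.cell_id} grows but has no polarity")
            px, py = cell.polarity
            R = np.array([[px, -py], [py, px]])
            D = np.diag([np.exp(cell.k_par * dt), np.exp(cell.k_per * dt)])
            G = R @ D @ R.T
            gcache[el.cell_id] = G
        c = el.rest.mean(axis=0)
        el.rest = (el.rest - c) @ G.T + c


def solve_equilibrium(tissue: Tissue, material: Material = DEFAULT_MATERIAL,
                      tol: float | None = None, max_iter: int = 2000):
    """Minimize elastic energy over free vertex coordinates; update positions.

    Base vertices keep their longitudinal (y) coordinate fixed; the anchor
    vertex is fully fixed.  Quasi-Newton (L-BFGS) with the analytic gradient.
    Returns the residual force norm (max abs component on free coordinates).
    """
    sys = FEMSystem(tissue, material)
    if sys.n_el == 0:
        return 0.0
    if tol is None:
        tol = 1e-8 * material.E * float(np.mean(sys.rest_area))
    mask = sys.free_mask()
    x0 = sys.positions.copy()
    flat_free = x0[mask]

    def fun(xf):
        pos = x0.copy()
        pos[mask] = xf
        e, g = sys.energy_grad(pos)
        return e, g[mask]

    res = minimize(fun, flat_free, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "gtol": 0.5 * tol,
                            "ftol": 0.0, "maxcor": 20})
    pos = x0.copy()
    pos[mask] = res.x
    _, g = sys.energy_grad(pos)
    resid = float(np.abs(g[mask]).max()) if mask.any() else 0.0
    if resid > tol:
        # one longer polish pass before giving up
        res = minimize(fun, pos[mask], jac=True, method="L-BFGS-B",
                       options={"maxiter": 2 * max_iter, "gtol": 0.1 * tol,
                                "ftol": 0.0, "maxcor": 20})
        pos[mask] = res.x
        _, g = sys.energy_grad(pos)
        resid = float(np.abs(g[mask]).max())
    if resid > tol:
        raise EquilibriumError(
            f"equilibrium not converged: residual {resid:.3e} > tol {tol:.3e}")
    det = sys.det_F(pos)
    if np.any(det <= 0):
        bad = [sys.tissue.elements[i].cell_id for i in np.nonzero(det <= 0)[0]]
        warnings.warn(f"inverted sliver element(s) after equilibrium in "
                      f"cells {sorted(set(bad))}; regularized energy keeps "
                      f"them bounded", RuntimeWarning)
    for i, v in enumerate(sys.vids):
        tissue.vertices[v].pos = pos[i].copy()
    return resid


def release_residual_stress(tissue: Tissue):
    """Set every element's rest shape to its current shape (energy -> 0)."""
    for el in tissue.elements:
        el.rest = np.array([tissue.vertices[v].pos for v in el.vids])


def uniaxial_test(material: Material = DEFAULT_MATERIAL, strain: float = 1e-4):
    """Single-element plane-stress extension test.

    Builds one right-triangle element, imposes an axial (x) stretch
    1 + strain on its nodes and relaxes the free lateral (y) coordinate to
    elastic equilibrium.  Returns (effective_modulus, lateral_ratio): axial
    2nd Piola-Kirchhoff stress over axial Green strain, and minus the
    lateral/axial strain ratio.  For the default material these recover
    E = 100 MPa and nu = 0.3.
    """
    from scipy.optimize import minimize_scalar

    from .tissue import triangulate_cell

    t = Tissue()
    v0 = t.new_vertex((0.0, 0.0))
    v1 = t.new_vertex((1.0, 0.0))
    v2 = t.new_vertex((0.0, 1.0))
    t.new_cell([v0, v1, v2])
    triangulate_cell(t, 0)
    sys = FEMSystem(t, material)
    base = sys.positions.copy()
    base[:, 0] *= 1.0 + strain
    i2 = sys.index[v2]

    def energy(y2):
        pos = base.copy()
        pos[i2, 1] = y2
        e, _ = sys.energy_grad(pos)
        return e

    res = minimize_scalar(energy, bounds=(1.0 - 10 * strain, 1.0 + 10 * strain),
                          method="bounded", options={"xatol": 1e-15})
    lat = float(res.x)
    Exx = 0.5 * ((1.0 + strain) ** 2 - 1.0)
    Eyy = 0.5 * (lat ** 2 - 1.0)
    Sxx = material.lam * (Exx + Eyy) + 2.0 * material.mu * Exx
    return Sxx / Exx, -Eyy / Exx
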