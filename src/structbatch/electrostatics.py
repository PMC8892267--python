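"""Continuum electrostatics: formal charges, a finite-difference linear
Poisson-Boltzmann solver, surface potential classing and equipotential masks.

Model. The linearized Poisson-Boltzmann equation

    div( eps(r) grad(phi) ) - eps_out * kappa^2(r) * phi = -4 pi l_B q(r)

is discretized on a cubic grid with a 7-point stencil; phi is in kT/e units
(1 kT/e = 25.693 mV at 298 K), lengths in Angstroms, charges in elementary
charges, and l_B is the vacuum Bjerrum length e^2/(4 pi eps0 kT). The
dielectric is eps_in inside probe-inflated atom spheres and eps_out outside;
kappa^2 (set by the 1:1 salt concentration) acts only outside the
ion-exclusion region. Charges are spread to the eight surrounding grid nodes
by trilinear weights; the boundary condition is the Debye-Hueckel monopole
of the total charge. The system is solved by conjugate gradients with a
Jacobi preconditioner to a relative residual of 1e-6.

Charging is a formal-charge scheme at pH 7 spread over the charged-group
heavy atoms (no hydrogens, no partial-charge force field): Asp/Glu
carboxylates -0.5 per O, Lys +1 on NZ, Arg +1/3 on the guanidinium N's,
His neutral, nucleotide phosphates -0.5 per non-bridging O, and optional
termini (+1 N-terminal N; -0.5 on O and OXT where OXT is present).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import constants as sc
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import cg, LinearOperator

from .chemistry import vdw_radius
from .structure_io import Atom, Residue, Structure

__all__ = [
    "ChargeAssignment", "PotentialGrid", "assign_charges", "solve_lpbe",
    "surface_potential", "equipotential_mask", "grid_to_opendx",
    "KT_MV", "bjerrum_length_vacuum", "debye_kappa2",
]

log = logging.getLogger(__name__)

PROBE_RADIUS = 1.4      # A, solvent probe inflating the dielectric boundary
ION_PROBE = 2.0         # A, Stern-layer inflation for the ion exclusion map
TEMPERATURE = 298.0     # K
KT_MV = 1000.0 * sc.k * TEMPERATURE / sc.e    # 25.693 mV per kT/e at 298 K

_NUC_TYPES = {"A", "C", "G", "U", "DA", "DC", "DG", "DT", "DI", "I"}
_SIDE_CHARGES = {
    "ASP": {"OD1": -0.5, "OD2": -0.5},
    "GLU": {"OE1": -0.5, "OE2": -0.5},
    "LYS": {"NZ": 1.0},
    "ARG": {"NE": 1.0 / 3.0, "NH1": 1.0 / 3.0, "NH2": 1.0 / 3.0},
}
_NUC_CHARGES = {"OP1": -0.5, "OP2": -0.5, "O1P": -0.5, "O2P": -0.5}


def bjerrum_length_vacuum(temperature: float = TEMPERATURE) -> float:
    """e^2 / (4 pi eps0 kT) in Angstroms (~560 A at 298 K)."""
    return sc.e ** 2 / (4.0 * np.pi * sc.epsilon_0 * sc.k * temperature) * 1e10


def debye_kappa2(salt: float, eps_out: float,
                 temperature: float = TEMPERATURE) -> float:
    """kappa^2 in A^-2 for a 1:1 salt of ionic strength `salt` (mol/L)."""
    n_density = sc.N_A * salt * 1e-27          # ions per A^3 (per species)
    l_b = bjerrum_length_vacuum(temperature) / eps_out
    return 8.0 * np.pi * l_b * n_density


@dataclass
class ChargeAssignment:
    atoms: list[Atom]
    charges: np.ndarray          # elementary charges
    radii: np.ndarray            # A
    warnings: list[str] = field(default_factory=list)

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms])


def assign_charges(structure: Structure, charge_termini: bool = True,
                   ligand_charges: Optional[dict] = None) -> ChargeAssignment:
    """Formal charges at pH 7 over heavy atoms; see the module docstring for
    the scheme. Unknown ligand atoms get 0 with a warning unless
    `ligand_charges` maps (residue type, atom name) to a charge."""
    ligand_charges = ligand_charges or {}
    atoms: list[Atom] = []
    charges: list[float] = []
    warnings: list[str] = []
    for chain in structure.models[0].chains:
        amino = [r for r in chain.residues if r.is_amino]
        first = amino[0] if amino else None
        last = amino[-1] if amino else None
        for r in chain.residues:
            table = {}
            if r.is_amino:
                table.update(_SIDE_CHARGES.get(r.type, {}))
                if charge_termini and r is first:
                    table["N"] = table.get("N", 0.0) + 1.0
                if charge_termini and r is last and r.atom("OXT") is not None:
                    table["O"] = table.get("O", 0.0) - 0.5
                    table["OXT"] = table.get("OXT", 0.0) - 0.5
            elif r.type in _NUC_TYPES:
                table.update(_NUC_CHARGES)
            for a in r.heavy_atoms():
                q = table.get(a.name)
                if q is None:
                    if r.is_amino or r.is_water or r.type in _NUC_TYPES:
                        q = 0.0
                    else:
                        key = (r.type, a.name)
                        if key in ligand_charges:
                            q = float(ligand_charges[key])
                        else:
                            q = 0.0
                            warnings.append(
                                f"ligand atom {r.type}:{a.name} has no charge "
                                "assigned; using 0")
                atoms.append(a)
                charges.append(q)
                a.charge = q
    for w in warnings[:5]:
        log.warning(w)
    return ChargeAssignment(atoms=atoms, charges=np.array(charges),
                            radii=np.array([vdw_radius(a.element)
                                            for a in atoms]),
                            warnings=warnings)


@dataclass
class PotentialGrid:
    n: int
    origin: np.ndarray           # A
    spacing: float               # A
    values: np.ndarray           # n^3, kT/e
    salt: float
    eps_in: float
    eps_out: float

    @property
    def values_mv(self) -> np.ndarray:
        return self.values * KT_MV

    def axis(self, i: int) -> np.ndarray:
        return self.origin[i] + self.spacing * np.arange(self.n)

    def interpolate(self, points: np.ndarray, in_mv: bool = False) -> np.ndarray:
        """Trilinear interpolation of the potential at Cartesian points."""
        from scipy.ndimage import map_coordinates
        pts = (np.atleast_2d(points) - self.origin) / self.spacing
        vals = map_coordinates(self.values, pts.T, order=1, mode="nearest")
        return vals * KT_MV if in_mv else vals


def _mark_spheres(n: int, origin: np.ndarray, h: float, coords: np.ndarray,
                  radii: np.ndarray) -> np.ndarray:
    """Boolean n^3 mask of grid nodes inside any atom sphere."""
    return _sphere_occupancy(n, origin, h, coords, radii, smooth=0.0) >= 0.5


def _sphere_occupancy(n: int, origin: np.ndarray, h: float,
                      coords: np.ndarray, radii: np.ndarray,
                      smooth: float) -> np.ndarray:
    """Per-node occupancy of the union of atom spheres.

    With smooth = 0 this is a 0/1 indicator; otherwise nodes within `smooth`
    (A) of a sphere surface get a fractional value, which anti-aliases the
    dielectric boundary and removes most of the staircase grid sensitivity.
    """
    occ = np.zeros((n, n, n))
    ax = origin[0] + h * np.arange(n)
    ay = origin[1] + h * np.arange(n)
    az = origin[2] + h * np.arange(n)
    axes = (ax, ay, az)
    pad = smooth + h
    for (x, y, z), r in zip(coords, radii):
        lo = [np.searchsorted(a, v - r - pad) for a, v in zip(axes, (x, y, z))]
        hi = [np.searchsorted(a, v + r + pad, side="right")
              for a, v in zip(axes, (x, y, z))]
        sl = tuple(slice(max(a - 1, 0), min(b + 1, n)) for a, b in zip(lo, hi))
        gx = axes[0][sl[0]][:, None, None] - x
        gy = axes[1][sl[1]][None, :, None] - y
        gz = axes[2][sl[2]][None, None, :] - z
        dist = np.sqrt(gx * gx + gy * gy + gz * gz)
        if smooth > 0:
            local = np.clip((r + smooth / 2.0 - dist) / smooth, 0.0, 1.0)
        else:
            local = (dist <= r).astype(float)
        np.maximum(occ[sl], local, out=occ[sl])
    return occ


def solve_lpbe(structure: Structure, charges: ChargeAssignment,
               n: int = 65, salt: float = 0.15,
               eps_in: float = 2.0, eps_out: float = 80.0,
               box: Optional[float] = None, fill: float = 0.7,
               rtol: float = 1e-6, ion_exclusion: bool = True,
               center: Optional[Sequence[float]] = None) -> PotentialGrid:
    """Solve the linear PB equation on an n^3 grid around the structure.

    The grid is centred on the molecule; its edge length is chosen so the
    molecule (with dielectric inflation) spans `fill` of the box, unless
    `box` (A) is given explicitly. Zero total charge with all-zero partial
    charges short-circuits to a zero field.
    """
    if n < 17 or n % 2 == 0:
        raise ValueError("grid size n must be odd and at least 17")
    coords = charges.coords
    q = charges.charges
    centre = (coords.mean(axis=0) if center is None
              else np.asarray(center, float))
    extent = float(2.0 * (np.linalg.norm(coords - centre, axis=1)
                          + charges.radii + PROBE_RADIUS).max())
    if box is None:
        box = max(extent / fill, 12.0)
    elif extent > box:
        raise ValueError(
            f"molecule extent {extent:.1f} A exceeds the requested box "
            f"{box:.1f} A; enlarge the box or the grid")
    h = box / (n - 1)
    origin = centre - box / 2.0
    grid = PotentialGrid(n=n, origin=origin, spacing=h,
                         values=np.zeros((n, n, n)), salt=salt,
                         eps_in=eps_in, eps_out=eps_out)
    if not np.any(q):
        return grid

    l_b = bjerrum_length_vacuum()
    kappa2 = debye_kappa2(salt, eps_out)

    occ = _sphere_occupancy(n, origin, h, coords,
                            charges.radii + PROBE_RADIUS, smooth=h)
    # harmonic blend across the anti-aliased interface
    eps_node = 1.0 / (occ / eps_in + (1.0 - occ) / eps_out)
    # eps_out * kappa^2 outside the Stern layer, in the Helmholtz term;
    # with ion_exclusion off the salt term acts everywhere (the uniform-
    # medium case solved in closed form by Debye-Hueckel)
    if ion_exclusion:
        ion_free = _mark_spheres(n, origin, h, coords, charges.radii + ION_PROBE)
        helm = np.where(ion_free, 0.0, eps_out * kappa2)
    else:
        helm = np.full((n, n, n), eps_out * kappa2)

    # trilinear charge spreading -> source term 4 pi l_B q / h^3
    rho = np.zeros((n, n, n))
    frac = (coords - origin) / h
    base = np.floor(frac).astype(int)
    t = frac - base
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (np.where(dx, t[:, 0], 1 - t[:, 0])
                     * np.where(dy, t[:, 1], 1 - t[:, 1])
                     * np.where(dz, t[:, 2], 1 - t[:, 2]))
                np.add.at(rho, (base[:, 0] + dx, base[:, 1] + dy,
                                base[:, 2] + dz), w * q)
    b_grid = 4.0 * np.pi * l_b * rho / h ** 3

    # Dirichlet boundary: superposed Debye-Hueckel monopoles, one per
    # charge, so the boundary (and hence the solution) is linear in the
    # charge set
    phi = np.zeros((n, n, n))
    boundary = np.zeros((n, n, n), dtype=bool)
    boundary[0, :, :] = boundary[-1, :, :] = True
    boundary[:, 0, :] = boundary[:, -1, :] = True
    boundary[:, :, 0] = boundary[:, :, -1] = True
    ax = [origin[i] + h * np.arange(n) for i in range(3)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    bpts = np.column_stack([gx[boundary], gy[boundary], gz[boundary]])
    kap = np.sqrt(kappa2)
    dh = np.zeros(len(bpts))
    for (x0, y0, z0), qi in zip(coords, q):
        if qi == 0.0:
            continue
        r = np.linalg.norm(bpts - (x0, y0, z0), axis=1)
        r = np.maximum(r, h)
        dh += (l_b / eps_out) * qi * np.exp(-kap * r) / r
    phi[boundary] = dh

    # assemble the 7-point operator over interior nodes
    interior = ~boundary
    idx = -np.ones((n, n, n), dtype=np.int64)
    idx[interior] = np.arange(int(interior.sum()))
    n_unk = int(interior.sum())
    h2 = h * h

    rows, cols, vals = [], [], []
    diag = helm[interior].astype(float).copy()
    rhs = b_grid[interior].astype(float).copy()

    def faces(axis):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(0, n - 1)
        sl_b[axis] = slice(1, n)
        ea = eps_node[tuple(sl_a)]
        eb = eps_node[tuple(sl_b)]
        return tuple(sl_a), tuple(sl_b), 2.0 * ea * eb / (ea + eb) / h2

    for axis in range(3):
        sl_a, sl_b, w = faces(axis)
        ia, ib = idx[sl_a], idx[sl_b]
        pa, pb = phi[sl_a], phi[sl_b]
        both = (ia >= 0) & (ib >= 0)
        rows.append(ia[both]); cols.append(ib[both]); vals.append(-w[both])
        rows.append(ib[both]); cols.append(ia[both]); vals.append(-w[both])
        np.add.at(diag, ia[ia >= 0], w[ia >= 0])
        np.add.at(diag, ib[ib >= 0], w[ib >= 0])
        a_only = (ia >= 0) & (ib < 0)      # neighbour is boundary
        np.add.at(rhs, ia[a_only], w[a_only] * pb[a_only])
        b_only = (ib >= 0) & (ia < 0)
        np.add.at(rhs, ib[b_only], w[b_only] * pa[b_only])

    rows.append(np.arange(n_unk)); cols.append(np.arange(n_unk)); vals.append(diag)
    a_mat = coo_matrix((np.concatenate(vals),
                        (np.concatenate(rows), np.concatenate(cols))),
                       shape=(n_unk, n_unk)).tocsr()
    m_inv = 1.0 / diag
    precond = LinearOperator((n_unk, n_unk), matvec=lambda x: m_inv * x)
    sol, info = cg(a_mat, rhs, rtol=rtol, maxiter=10_000, M=precond)
    if info != 0:
        raise RuntimeError(f"LPBE conjugate-gradient solve failed (info={info})")
    phi[interior] = sol
    grid.values = phi
    return grid


@dataclass
class SurfacePoint:
    coord: np.ndarray
    potential_mv: float
    klass: str                  # "blue" | "red" | "white"
    atom_serial: int = 0


def surface_potential(grid: PotentialGrid, structure: Structure,
                      charges: Optional[ChargeAssignment] = None,
                      level_mv: float = 50.0,
                      points_per_atom: int = 42) -> list[SurfacePoint]:
    """Sample the probe-inflated molecular surface and class each exterior
    point blue (> +level), red (< -level) or white (in between)."""
    if charges is None:
        charges = assign_charges(structure)
    coords = charges.coords
    radii = charges.radii + PROBE_RADIUS
    # golden-spiral directions, shared by all atoms
    k = np.arange(points_per_atom) + 0.5
    theta = np.arccos(1 - 2 * k / points_per_atom)
    golden = np.pi * (1 + 5 ** 0.5)
    dirs = np.column_stack([np.sin(theta) * np.cos(golden * k),
                            np.sin(theta) * np.sin(golden * k),
                            np.cos(theta)])
    out: list[SurfacePoint] = []
    for i, (c, r) in enumerate(zip(coords, radii)):
        pts = c + r * dirs
        d = np.linalg.norm(pts[:, None, :] - coords[None, :, :], axis=-1)
        d[:, i] = np.inf
        exterior = (d >= radii[None, :] - 1e-9).all(axis=1)
        if not exterior.any():
            continue
        vals = grid.interpolate(pts[exterior], in_mv=True)
        for p, v in zip(pts[exterior], vals):
            klass = "blue" if v > level_mv else ("red" if v < -level_mv
                                                 else "white")
            out.append(SurfacePoint(coord=p, potential_mv=float(v),
                                    klass=klass,
                                    atom_serial=charges.atoms[i].serial))
    return out


def surface_to_tsv(points: Sequence[SurfacePoint]) -> str:
    rows = ["x\ty\tz\tmV\tclass"]
    for p in points:
        rows.append(f"{p.coord[0]:.3f}\t{p.coord[1]:.3f}\t{p.coord[2]:.3f}\t"
                    f"{p.potential_mv:.3f}\t{p.klass}")
    return "\n".join(rows) + "\n"


def equipotential_mask(grid: PotentialGrid, level_mv: float = 50.0
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks of grid nodes with phi >= +level and phi <= -level (mV)."""
    if level_mv < 0:
        raise ValueError("level must be non-negative")
    mv = grid.values_mv
    return mv >= level_mv, mv <= -level_mv


def grid_to_opendx(grid: PotentialGrid, in_mv: bool = True) -> str:
    """Serialize the potential as an OpenDX scalar field."""
    vals = grid.values_mv if in_mv else grid.values
    n = grid.n
    lines = [
        f"object 1 class gridpositions counts {n} {n} {n}",
        f"origin {grid.origin[0]:.6e} {grid.origin[1]:.6e} {grid.origin[2]:.6e}",
        f"delta {grid.spacing:.6e} 0.000000e+00 0.000000e+00",
        f"delta 0.000000e+00 {grid.spacing:.6e} 0.000000e+00",
        f"delta 0.000000e+00 0.000000e+00 {grid.spacing:.6e}",
        f"object 2 class gridconnections counts {n} {n} {n}",
        f"object 3 class array type double rank 0 items {n ** 3} data follows",
    ]
    flat = vals.ravel()
    for i in range(0, len(flat), 3):
        lines.append(" ".join(f"{x:.6e}" for x in flat[i:i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "regular positions regular connections" class field')
    lines.append('component "positions" value 1')
    lines.append('component "connections" value 2')
    lines.append('component "data" value 3')
    return "\n".join(lines) + "\n"
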