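"""Independent oracle implementations used by the test suite.

Deliberately written with straightforward loops and dense linear algebra,
separate from the package's vectorized/matrix-free code paths.
"""

import numpy as np


def dense_hex_stiffness(E: float, nu: float, h: float) -> np.ndarray:
    """24x24 hexahedral stiffness by direct 2x2x2 Gauss quadrature loops."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    for i in range(3):
        for j in range(3):
            D[i, j] = lam
        D[i, i] = lam + 2 * mu
    for i in range(3, 6):
        D[i, i] = mu
    # node local coordinates
    nodes = [
        (-1, -1, -1), (1, -1, -1), (1, 1, -1), (-1, 1, -1),
        (-1, -1, 1), (1, -1, 1), (1, 1, 1), (-1, 1, 1),
    ]
    g = 1.0 / np.sqrt(3.0)
    Ke = np.zeros((24, 24))
    for gx in (-g, g):
        for gy in (-g, g):
            for gz in (-g, g):
                B = np.zeros((6, 24))
                for a, (sx, sy, sz) in enumerate(nodes):
                    dndx = sx * (1 + sy * gy) * (1 + sz * gz) / 8 * 2 / h
                    dndy = (1 + sx * gx) * sy * (1 + sz * gz) / 8 * 2 / h
                    dndz = (1 + sx * gx) * (1 + sy * gy) * sz / 8 * 2 / h
                    B[0, 3 * a] = dndx
                    B[1, 3 * a + 1] = dndy
                    B[2, 3 * a + 2] = dndz
                    B[3, 3 * a] = dndy
                    B[3, 3 * a + 1] = dndx
                    B[4, 3 * a + 1] = dndz
                    B[4, 3 * a + 2] = dndy
                    B[5, 3 * a] = dndz
                    B[5, 3 * a + 2] = dndx
                Ke += B.T @ D @ B * (h / 2) ** 3
    return Ke, D


def dense_sed_solve(grid, A_affine, tissue_modulus=10000.0, nu=0.3, exponent=2.0):
    """Dense direct micro-FE solve for tiny grids.

    Assembles the full stiffness matrix over bone voxels, applies affine
    Dirichlet displacements u = A x on domain-boundary nodes of bone
    elements, solves with numpy, and returns the per-voxel SED field from
    centroid strains.
    """
    bone = grid.tissue != 0
    nz, ny, nx = grid.shape
    h = grid.voxel_size
    node_shape = (nz + 1, ny + 1, nx + 1)
    nn = node_shape[0] * node_shape[1] * node_shape[2]
    Ke1, D1 = dense_hex_stiffness(1.0, nu, h)
    K = np.zeros((3 * nn, 3 * nn))
    offsets = [
        (0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
        (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1),
    ]  # (dx, dy, dz)
    elements = []
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not bone[z, y, x]:
                    continue
                E_e = tissue_modulus * grid.mineral[z, y, x] ** exponent
                dofs = []
                for dx, dy, dz in offsets:
                    nid = ((z + dz) * node_shape[1] + (y + dy)) * node_shape[2] + (x + dx)
                    dofs.extend([3 * nid, 3 * nid + 1, 3 * nid + 2])
                dofs = np.array(dofs)
                K[np.ix_(dofs, dofs)] += Ke1 * E_e
                elements.append(((z, y, x), dofs, E_e))
    # Dirichlet: boundary nodes of bone elements
    used = np.zeros(nn, dtype=bool)
    for _, dofs, _ in elements:
        used[dofs[::3] // 3] = True
    u = np.zeros(3 * nn)
    fixed = np.zeros(3 * nn, dtype=bool)
    for nid in np.flatnonzero(used):
        z, y, x = np.unravel_index(nid, node_shape)
        if (
            z in (0, node_shape[0] - 1)
            or y in (0, node_shape[1] - 1)
            or x in (0, node_shape[2] - 1)
        ):
            pos = np.array([x, y, z]) * h
            u[3 * nid: 3 * nid + 3] = A_affine @ pos
            fixed[3 * nid: 3 * nid + 3] = True
    active = np.zeros(3 * nn, dtype=bool)
    for nid in np.flatnonzero(used):
        active[3 * nid: 3 * nid + 3] = True
    free = active & ~fixed
    b = -K[np.ix_(free, np.flatnonzero(fixed))] @ u[fixed]
    u[free] = np.linalg.solve(K[np.ix_(free, free)], b)
    # centroid strains -> SED
    B0 = np.zeros((6, 24))
    for a, (dx, dy, dz) in enumerate(offsets):
        sx, sy, sz = 2 * dx - 1, 2 * dy - 1, 2 * dz - 1
        B0[0, 3 * a] = sx / 8 * 2 / h
        B0[1, 3 * a + 1] = sy / 8 * 2 / h
        B0[2, 3 * a + 2] = sz / 8 * 2 / h
        B0[3, 3 * a] = sy / 8 * 2 / h
        B0[3, 3 * a + 1] = sx / 8 * 2 / h
        B0[4, 3 * a + 1] = sz / 8 * 2 / h
        B0[4, 3 * a + 2] = sy / 8 * 2 / h
        B0[5, 3 * a] = sz / 8 * 2 / h
        B0[5, 3 * a + 2] = sx / 8 * 2 / h
    sed = np.zeros(grid.shape)
    for (z, y, x), dofs, E_e in elements:
        eps = B0 @ u[dofs]
        sed[z, y, x] = 0.5 * eps @ (D1 * E_e) @ eps
    return sed


def brute_force_two_step_selection(entries, criteria):
    """Exhaustive two-step cohort selection with plain loops (no shortlist
    shortcuts beyond the specified two-step procedure)."""
    from itertools import combinations

    entries = sorted(entries, key=lambda e: e.id)
    scored = []
    for combo in combinations(range(len(entries)), criteria.k):
        bv = np.array([entries[i].bv_tv for i in combo]) * 100.0
        ages = np.array([entries[i].age for i in combo])
        w = criteria.weights
        err = (
            w["mean_bv_tv"] * abs(criteria.mean_bv_tv - bv.mean()) / criteria.mean_bv_tv
            + w["mean_age"] * abs(criteria.mean_age - ages.mean()) / criteria.mean_age
            + w["sd_age"] * abs(criteria.sd_age - ages.std(ddof=1)) / criteria.sd_age
            + w["sd_bv_tv"] * abs(criteria.sd_bv_tv - bv.std(ddof=1)) / criteria.sd_bv_tv
        )
        inc = np.diff(np.sort(bv))
        if len(inc) >= 2 and inc.mean() > 0:
            err += w["uniformity"] * inc.std(ddof=1) / inc.mean()
        scored.append((err, combo, bv.mean()))
    scored.sort(key=lambda s: s[0])
    shortlist = scored[: criteria.shortlist]
    best = min(shortlist, key=lambda s: abs(s[2] - criteria.mean_bv_tv))
    return [entries[i] for i in best[1]]
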