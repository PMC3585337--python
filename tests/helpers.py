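"""Independent oracles used by the test suite.

These deliberately avoid the code paths they are checking: the RMSD oracle
uses Horn's quaternion method, the distance oracle an explicit double loop,
and the SASA oracle is biotite's own Shrake-Rupley implementation.
"""

import numpy as np


def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Optimal-superposition RMSD via Horn's quaternion eigenvalue method."""
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)
    n = x.shape[0]
    s = x.T @ y
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    ga = (x ** 2).sum()
    gb = (y ** 2).sum()
    msd = max((ga + gb - 2.0 * lam) / n, 0.0)
    return float(np.sqrt(msd))


def brute_force_min_distance(coords_a: np.ndarray,
                             coords_b: np.ndarray) -> float:
    """Exhaustive all-pairs minimum distance (plain double loop)."""
    best = np.inf
    for a in coords_a:
        for b in coords_b:
            d = float(np.sqrt(((a - b) ** 2).sum()))
            if d < best:
                best = d
    return best


def biotite_sasa_per_residue(struct, probe_radius=1.4, point_number=960):
    """Residue SASA from biotite's independent Shrake-Rupley implementation."""
    import biotite.structure as bst

    n = struct.n_atoms
    arr = bst.AtomArray(n)
    arr.coord = struct.coords.astype(np.float32)
    arr.atom_name = struct.names.astype("U6")
    arr.element = struct.elements.astype("U2")
    arr.res_id = struct.residue_numbers
    arr.res_name = struct.residue_names.astype("U5")
    arr.chain_id = struct.chains.astype("U4")
    arr.hetero = np.zeros(n, dtype=bool)
    per_atom = bst.sasa(arr, probe_radius=probe_radius,
                        point_number=point_number, vdw_radii="Single")
    out: dict[int, float] = {}
    for i in range(n):
        if np.isnan(per_atom[i]):
            continue
        r = int(arr.res_id[i])
        out[r] = out.get(r, 0.0) + float(per_atom[i])
    return out


def random_rigid_transform(rng):
    """A uniformly random proper rotation plus a random translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    trans = rng.normal(scale=10.0, size=3)
    return rot, trans
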