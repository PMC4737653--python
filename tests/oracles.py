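"""Independent reference implementations used only to cross-check the package.

These deliberately use different formulations than the library: quaternion
(Horn) superposition instead of SVD Kabsch, brute-force enumeration instead of
the scan/KD-tree paths, and a from-scratch dihedral routine.
"""

import itertools

import numpy as np


def horn_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    """Optimal superposition RMSD via Horn's quaternion eigenvalue method."""
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    n = len(mobile)
    am = mobile - mobile.mean(axis=0)
    at = target - target.mean(axis=0)
    m = am.T @ at
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam_max = np.linalg.eigvalsh(k)[-1]
    sq = (np.sum(am * am) + np.sum(at * at) - 2.0 * lam_max) / n
    return float(np.sqrt(max(sq, 0.0)))


def dihedral_ref(p0, p1, p2, p3) -> float:
    """Dihedral angle (degrees) via the atan2-free cross-product formulation."""
    b1 = np.asarray(p1) - np.asarray(p0)
    b2 = np.asarray(p2) - np.asarray(p1)
    b3 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cos = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
    if np.dot(np.cross(n1, n2), b2) < 0:
        ang = -ang
    return float(ang)


def brute_force_sites(host, insert, config):
    """Exhaustive enumeration of accepted (probe, host-pair) combinations,
    independent of scan_insertion_sites' loop structure and ordering."""
    k = config.n_terminal_probe
    hc = host.backbone_coords()
    ic = insert.backbone_coords()
    n_i = len(insert)
    accepted = set()
    for ni, ci in itertools.product(range(k), range(n_i - k, n_i)):
        probe = np.concatenate([ic[ni], ic[ci]])
        for i, j in itertools.combinations(range(len(host)), 2):
            if j - i - 1 >= config.host_segment_max:
                continue
            if any(b in host.breaks for b in range(i, j)):
                continue
            rmsd = horn_rmsd(probe, np.concatenate([hc[i], hc[j]]))
            if rmsd <= config.pair_rmsd_max:
                accepted.add((ni, ci, i, j))
    return accepted


def brute_force_clashes(chain, config) -> int:
    """All-pairs backbone clash count without spatial indexing."""
    coords = chain.backbone_coords()
    n = len(coords)
    count = 0
    for i in range(n):
        for j in range(i + config.clash_min_seq_sep, n):
            d = np.linalg.norm(coords[i][:, None, :] - coords[j][None, :, :], axis=-1)
            # the CA-CA pair uses the wider threshold; every other pair the tighter one
            other = d.copy()
            other[1, 1] = np.inf
            clash = (d[1, 1] < config.clash_dist_ca) or (other < config.clash_dist_bb).any()
            if clash:
                count += 1
    return count
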