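"""Rigid-body superposition, torsion geometry, and backbone construction.

Coordinates are Å throughout; angles are degrees at every public interface
(radians only inside helper math).  Superpositions are least-squares optimal
proper rotations (Kabsch via SVD, reflections forbidden), the operation that
aligns an insert-domain residue pair onto a candidate host pair during the
insertion-point scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Ideal backbone covalent geometry (Engh–Huber-like), Å and degrees.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x ↦ R·x + t."""

    rotation: np.ndarray   # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def random(rng: np.random.Generator, max_translation: float = 20.0) -> "RigidTransform":
        """Uniform random rotation (QR of a Gaussian matrix, det corrected) and
        uniform translation in a cube — used by invariance tests."""
        m = rng.normal(size=(3, 3))
        q, r = np.linalg.qr(m)
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        t = rng.uniform(-max_translation, max_translation, size=3)
        return RigidTransform(q, t)


@dataclass(frozen=True)
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_atoms: int
    ill_conditioned: bool = False


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray,
                     weights: np.ndarray | None = None) -> SuperpositionResult:
    """Least-squares optimal proper rigid superposition of ``mobile`` onto ``target``.

    Uses the SVD form of the Kabsch algorithm with the sign of the smallest
    singular vector corrected so the rotation is never a reflection (protein
    backbones are chiral).  Degenerate (collinear) point sets still return the
    optimum but are flagged ``ill_conditioned``.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError(f"point sets differ in shape: {mobile.shape} vs {target.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")
    if not (np.all(np.isfinite(mobile)) and np.all(np.isfinite(target))):
        raise ValueError("coordinates must be finite")

    if weights is None:
        w = np.ones(len(mobile))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(mobile),) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()

    cm = w @ mobile
    ct = w @ target
    m0 = mobile - cm
    t0 = target - ct
    h = (m0 * w[:, None]).T @ t0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = ct - rot @ cm
    transform = RigidTransform(rot, trans)

    diff = transform.apply(mobile) - target
    # unweighted rmsd when no weights given; weighted quadratic mean otherwise
    rmsd = float(np.sqrt(np.sum(w * np.sum(diff * diff, axis=1))))
    ill = bool(s[1] < 1e-8 * max(s[0], 1.0))
    return SuperpositionResult(transform=transform, rmsd=rmsd,
                               n_atoms=len(mobile), ill_conditioned=ill)


def apply_transform(chain, t: RigidTransform):
    """Return a copy of a BackboneChain with all backbone atoms mapped x ↦ R·x + t."""
    return chain.with_coords(t.apply(chain.backbone_coords().reshape(-1, 3)).reshape(-1, 4, 3))


# ---------------------------------------------------------------------------
# internal-to-Cartesian construction (NeRF) and torsion measurement
# ---------------------------------------------------------------------------

def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom d given predecessors a–b–c, the c–d bond length, the
    b–c–d angle, and the a–b–c–d torsion (natural extension reference frame)."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(angle),
        np.sin(angle) * np.cos(torsion),
        np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle in degrees, IUPAC convention."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def build_from_torsions(spec, seed_frame: np.ndarray | None = None) -> np.ndarray:
    """Build backbone coordinates from per-residue (phi, psi[, omega]) torsions.

    Returns an (n, 4, 3) array of N/CA/C/O positions built with ideal bond
    lengths and angles.  omega (the peptide torsion preceding residue i)
    defaults to 180°; phi of the first and omega of the first residue are
    unused, psi of the last residue only orients its carbonyl oxygen.
    ``seed_frame`` optionally supplies the first residue's N/CA/C positions.
    """
    spec = [tuple(s) + (180.0,) * (3 - len(tuple(s))) for s in spec]
    if len(spec) < 1:
        raise ValueError("need at least one residue")
    n = len(spec)
    coords = np.zeros((n, 4, 3))

    if seed_frame is None:
        coords[0, 0] = [0.0, 0.0, 0.0]
        coords[0, 1] = [BOND_N_CA, 0.0, 0.0]
        ang = np.radians(ANGLE_N_CA_C)
        coords[0, 2] = coords[0, 1] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    else:
        coords[0, :3] = np.asarray(seed_frame, dtype=float)

    for i in range(n):
        phi_i, psi_i, _ = spec[i]
        ni, cai, ci = coords[i, 0], coords[i, 1], coords[i, 2]
        # carbonyl O is anti to the next N: torsion N–CA–C–O = psi − 180
        coords[i, 3] = place_atom(ni, cai, ci, BOND_C_O, ANGLE_CA_C_O, psi_i - 180.0)
        if i + 1 < n:
            phi_next, _, omega_next = spec[i + 1]
            n_next = place_atom(ni, cai, ci, BOND_C_N, ANGLE_CA_C_N, psi_i)
            ca_next = place_atom(cai, ci, n_next, BOND_N_CA, ANGLE_C_N_CA, omega_next)
            c_next = place_atom(ci, n_next, ca_next, BOND_CA_C, ANGLE_N_CA_C, phi_next)
            coords[i + 1, 0] = n_next
            coords[i + 1, 1] = ca_next
            coords[i + 1, 2] = c_next
    return coords


def measure_torsions(chain) -> list[tuple[float | None, float | None, float | None]]:
    """Per-residue (phi, psi, omega) in degrees; undefined values are None.

    phi(i) = C(i−1)–N(i)–CA(i)–C(i); psi(i) = N(i)–CA(i)–C(i)–N(i+1);
    omega(i) = CA(i−1)–C(i−1)–N(i)–CA(i), the peptide torsion preceding
    residue i.  Values spanning a flagged chain break are None, as are
    phi/omega of the first residue and psi of the last.
    """
    coords = chain.backbone_coords()
    n = len(coords)
    breaks = getattr(chain, "breaks", frozenset())
    if n < 1:
        raise ValueError("empty chain")
    out: list[tuple[float | None, float | None, float | None]] = []
    for i in range(n):
        phi = psi = omega = None
        if i > 0 and (i - 1) not in breaks:
            phi = dihedral(coords[i - 1, 2], coords[i, 0], coords[i, 1], coords[i, 2])
            omega = dihedral(coords[i - 1, 1], coords[i - 1, 2], coords[i, 0], coords[i, 1])
        if i + 1 < n and i not in breaks:
            psi = dihedral(coords[i, 0], coords[i, 1], coords[i, 2], coords[i + 1, 0])
        out.append((phi, psi, omega))
    return out


# ---------------------------------------------------------------------------
# deterministic gap closure by coordinate descent over free torsions
# ---------------------------------------------------------------------------

class UnclosableGapError(ValueError):
    """The bridging segment cannot reach the target within its span."""


def _segment_coords(anchor_n: np.ndarray, anchor_ca: np.ndarray, anchor_c: np.ndarray,
                    torsions: np.ndarray, n_res: int) -> np.ndarray:
    """Build n_res residues continuing from an anchored residue frame.

    ``torsions`` packs [psi_anchor, phi_1, psi_1, ..., phi_n, psi_n];
    omegas are fixed trans (180°).
    """
    coords = np.zeros((n_res, 4, 3))
    prev_n, prev_ca, prev_c = anchor_n, anchor_ca, anchor_c
    psi_prev = torsions[0]
    for i in range(n_res):
        phi_i = torsions[1 + 2 * i]
        psi_i = torsions[2 + 2 * i]
        ni = place_atom(prev_n, prev_ca, prev_c, BOND_C_N, ANGLE_CA_C_N, psi_prev)
        cai = place_atom(prev_ca, prev_c, ni, BOND_N_CA, ANGLE_C_N_CA, 180.0)
        ci = place_atom(prev_c, ni, cai, BOND_CA_C, ANGLE_N_CA_C, phi_i)
        oi = place_atom(ni, cai, ci, BOND_C_O, ANGLE_CA_C_O, psi_i - 180.0)
        coords[i] = [ni, cai, ci, oi]
        prev_n, prev_ca, prev_c = ni, cai, ci
        psi_prev = psi_i
    return coords


def close_gap(anchor_residue: np.ndarray, target_n: np.ndarray, n_res: int,
              init_torsions=None, free: list[int] | None = None,
              bond_target: float = BOND_C_N, tol: float = 0.05,
              max_iter: int = 200) -> np.ndarray:
    """Build an n_res-residue bridging segment from an anchor residue toward a
    fixed downstream N atom, then close the terminal C–N bond to ``bond_target``
    by deterministic coordinate descent over the free torsions.

    ``anchor_residue`` is the (4, 3) N/CA/C/O of the residue preceding the
    segment; ``target_n`` the N of the residue that follows it.  The free
    torsion vector is [psi_anchor, phi_1, psi_1, ..., phi_n, psi_n]; ``free``
    restricts which of those indices may move (default: all except the last
    psi, which cannot affect the gap).  Raises :class:`UnclosableGapError`
    when the straight-line gap exceeds 3.8 Å per placed residue plus the
    closing bond, or when descent cannot reach ``tol``.
    """
    anchor_residue = np.asarray(anchor_residue, dtype=float)
    target_n = np.asarray(target_n, dtype=float)
    if n_res < 1:
        raise ValueError("segment needs at least one residue")
    gap = float(np.linalg.norm(target_n - anchor_residue[2]))
    if gap > 3.8 * (n_res + 1):
        raise UnclosableGapError(
            f"unclosable junction: gap {gap:.2f} Å exceeds {3.8 * (n_res + 1):.2f} Å "
            f"spannable by {n_res} residues")

    if free is None:
        free = list(range(1 + 2 * n_res - 1))  # last psi never moves the gap

    an, aca, ac = anchor_residue[0], anchor_residue[1], anchor_residue[2]

    def axis_atoms(seg: np.ndarray, idx: int) -> tuple[np.ndarray, np.ndarray]:
        """The two atoms defining the rotation axis of torsion ``idx``."""
        if idx == 0:
            return aca, ac           # psi of the anchor: CA->C
        i, kind = divmod(idx - 1, 2)
        if kind == 0:                # phi_i: N->CA
            return seg[i, 0], seg[i, 1]
        return seg[i, 1], seg[i, 2]  # psi_i: CA->C

    def objective(tv: np.ndarray) -> float:
        seg = _segment_coords(an, aca, ac, tv, n_res)
        return abs(float(np.linalg.norm(target_n - seg[-1, 2])) - bond_target)

    def descend(torsions: np.ndarray) -> tuple[float, np.ndarray]:
        """Cyclic coordinate descent: each torsion rotates the terminal C on a
        circle, so its optimal update is found from the circle geometry in one
        vectorized pass."""
        best = objective(torsions)
        for _ in range(max_iter):
            if best <= tol:
                break
            improved = False
            for idx in free:
                seg = _segment_coords(an, aca, ac, torsions, n_res)
                tip = seg[-1, 2]
                p, q = axis_atoms(seg, idx)
                u = q - p
                u /= np.linalg.norm(u)
                rel = tip - p
                axial = np.dot(rel, u) * u
                radial = rel - axial
                r = np.linalg.norm(radial)
                if r < 1e-9:
                    continue  # terminal C on the axis: torsion has no effect
                v = radial / r
                w = np.cross(u, v)
                center = p + axial
                # |tip(theta) - target|^2 = A + B cos(theta - phi): solve for
                # the angle putting the tip at bond_target from the target, or
                # take the nearest extremum when that distance is unreachable
                g = center - target_n
                gv, gw = float(np.dot(g, v)), float(np.dot(g, w))
                amp = 2.0 * r * float(np.hypot(gv, gw))
                if amp < 1e-12:
                    continue
                a0 = float(np.dot(g, g)) + r * r
                phi = np.degrees(np.arctan2(gw, gv))
                c = (bond_target ** 2 - a0) / amp
                if c >= 1.0:
                    cands = [phi]
                elif c <= -1.0:
                    cands = [phi + 180.0]
                else:
                    off = np.degrees(np.arccos(c))
                    cands = [phi + off, phi - off]
                # the torsion sign convention vs the (v, w) basis is settled by
                # evaluating the true objective for both rotation directions
                saved = torsions[idx]
                cand_best, cand_val = saved, best
                for theta in cands:
                    for delta in (theta, -theta):
                        torsions[idx] = saved + delta
                        val = objective(torsions)
                        if val < cand_val:
                            cand_best, cand_val = torsions[idx], val
                torsions[idx] = cand_best
                if cand_val < best - 1e-9:
                    best = cand_val
                    improved = True
            if not improved:
                break
        return best, torsions

    # the distance landscape has local minima the descent can stall in; a fixed
    # ladder of start schedules keeps closure deterministic while escaping them
    starts: list[np.ndarray] = []
    if init_torsions is not None:
        starts.append(np.asarray(init_torsions, dtype=float).copy())
    for phi, psi in ((-120.0, 120.0), (-60.0, -30.0), (60.0, 30.0),
                     (-75.0, 145.0), (100.0, -100.0), (-57.0, -47.0),
                     (140.0, -140.0), (0.0, 90.0)):
        starts.append(np.array([120.0] + [phi, psi] * n_res, dtype=float))
    for pair in (((-120.0, 120.0), (-60.0, -30.0)),
                 ((60.0, 30.0), (-120.0, 120.0)),
                 ((-57.0, -47.0), (-75.0, 145.0))):
        tv = [120.0]
        for i in range(n_res):
            tv.extend(pair[i % 2])
        starts.append(np.array(tv, dtype=float))

    best_val = np.inf
    best_tv: np.ndarray | None = None
    for start in starts:
        val, tv = descend(start)
        if val < best_val:
            best_val, best_tv = val, tv.copy()
        if best_val <= tol:
            break
    if best_val > tol:
        raise UnclosableGapError(
            f"unclosable junction: residual gap {best_val:.3f} Å above tolerance {tol} Å")
    return _segment_coords(an, aca, ac, best_tv, n_res)
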