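"""Independent reference implementations used only as test oracles."""

from __future__ import annotations

import numpy as np


def horn_superpose_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """RMSD after optimal rigid superposition via Horn's quaternion method.

    Builds the 4x4 key matrix from the cross-covariance of the centered
    point sets; the largest eigenvalue lambda_max gives the optimal rotation
    and the residual is ``sum(|p|^2 + |q|^2) - 2*lambda_max``.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    p = P - P.mean(axis=0)
    q = Q - Q.mean(axis=0)
    S = p.T @ q
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam_max = np.linalg.eigvalsh(K)[-1]
    residual = float(np.sum(p**2) + np.sum(q**2) - 2.0 * lam_max)
    return float(np.sqrt(max(residual, 0.0) / len(P)))


def brute_force_environment_count(structure, frame, half_width: float) -> int:
    """O(N) scan over all atoms: strict max(|x|,|y|,|z|) < half_width."""
    count = 0
    for _, atom in structure.iter_atoms():
        local = frame.rotation @ (atom.position - frame.origin)
        if np.max(np.abs(local)) < half_width:
            count += 1
    return count


def direct_conv3d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Naive loop valid cross-correlation; the ground truth for conv layers."""
    B, C, D, H, Wd = x.shape
    O, _, k, _, _ = w.shape
    Do, Ho, Wo = D - k + 1, H - k + 1, Wd - k + 1
    y = np.zeros((B, O, Do, Ho, Wo))
    for bi in range(B):
        for o in range(O):
            for i in range(Do):
                for j in range(Ho):
                    for l in range(Wo):
                        y[bi, o, i, j, l] = np.sum(
                            x[bi, :, i:i + k, j:j + k, l:l + k] * w[o]
                        ) + b[o]
    return y


def random_rigid_transform(rng: np.random.Generator):
    """A uniformly random proper rotation and a random translation."""
    A = rng.normal(size=(3, 3))
    Qm, R = np.linalg.qr(A)
    Qm = Qm @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Qm) < 0:
        Qm[:, 0] = -Qm[:, 0]
    t = rng.uniform(-20, 20, size=3)
    return Qm, t


def apply_rigid(structure, rotation: np.ndarray, translation: np.ndarray):
    """Rigidly move every atom of a copied structure."""
    moved = structure.copy()
    for _, atom in moved.iter_atoms():
        atom.position = rotation @ atom.position + translation
    return moved
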