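"""Optimal rigid-body superposition (Kabsch) and RMSD."""

from __future__ import annotations

import numpy as np

from .errors import UndefinedSuperpositionError


def superposed_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD between two coordinate sets over proper rigid motions.

    Both arrays must have shape (n, 3) with n >= 3.  The rotation is
    constrained to be proper (det +1), so mirror images are not matched.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinate arrays must both have shape (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise UndefinedSuperpositionError(
            f"superposition needs at least 3 points, got {n}")

    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)
    # Kabsch via SVD of the covariance; flip the smallest singular vector
    # if the optimal orthogonal transform would be improper.
    cov = x.T @ y
    u, s, vt = np.linalg.svd(cov)
    sign = np.sign(np.linalg.det(u @ vt))
    s = s.copy()
    s[-1] *= sign
    e0 = np.sum(x * x) + np.sum(y * y)
    msd = max((e0 - 2.0 * np.sum(s)) / n, 0.0)
    return float(np.sqrt(msd))
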