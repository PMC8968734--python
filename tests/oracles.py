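"""Independent brute-force oracles used only by the test suite.

Each oracle is written directly from the defining formulas as plain
double loops, independent of the vectorized implementation paths it
cross-checks.
"""

import math

import numpy as np

_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_bruteforce(window: np.ndarray, d: int, theta: int,
                    n_levels: int) -> np.ndarray:
    """Normalized co-occurrence matrix by explicit pair enumeration."""
    dr, dc = (d * o for o in _OFFSETS[theta])
    counts = np.zeros((n_levels, n_levels))
    h, w = window.shape
    for m in range(h):
        for n in range(w):
            x, y = m + dr, n + dc
            if 0 <= x < h and 0 <= y < w:
                counts[window[m, n], window[x, y]] += 1
    total = counts.sum()
    return counts / total


def texture_bruteforce(p: np.ndarray, log_base: float = 2.0) -> np.ndarray:
    """(ASM, contrast, correlation, variance, entropy) by double loops."""
    ng = p.shape[0]
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i, j] for i in range(ng)) for j in range(ng)]
    mu_x = sum(i * px[i] for i in range(ng))
    mu_y = sum(j * py[j] for j in range(ng))
    sig_x = math.sqrt(max(sum(i * i * px[i] for i in range(ng)) - mu_x**2, 0))
    sig_y = math.sqrt(max(sum(j * j * py[j] for j in range(ng)) - mu_y**2, 0))
    asm = contrast = entropy = variance = cross = 0.0
    for i in range(ng):
        for j in range(ng):
            asm += p[i, j] ** 2
            contrast += p[i, j] * (i - j) ** 2
            cross += i * j * p[i, j]
            variance += (i * j - mu_x * mu_y) * p[i, j]
            if p[i, j] > 0:
                entropy -= p[i, j] * math.log(p[i, j]) / math.log(log_base)
    corr = ((cross - mu_x * mu_y) / (sig_x * sig_y)
            if sig_x * sig_y > 1e-12 else 0.0)
    return np.array([asm, contrast, corr, variance, entropy])


def rigid_procrustes_closed_form(src: np.ndarray, dst: np.ndarray,
                                 weights: np.ndarray | None = None
                                 ) -> tuple[float, np.ndarray]:
    """2D weighted rigid fit via the atan2 closed form (no SVD).

    Returns ``(angle_deg, translation)`` for ``q = R p + t``. The
    rotation angle solves ``atan2(sum w (p~ x q~), sum w (p~ . q~))``
    on centred points — an independent route from the Kabsch/SVD path.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    w = np.ones(len(src)) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    p_bar = w @ src
    q_bar = w @ dst
    ps = src - p_bar
    qs = dst - q_bar
    dot = float(np.sum(w * (ps * qs).sum(axis=1)))
    cross = float(np.sum(w * (ps[:, 0] * qs[:, 1] - ps[:, 1] * qs[:, 0])))
    theta = math.atan2(cross, dot)
    c, s = math.cos(theta), math.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    t = q_bar - rot @ p_bar
    return math.degrees(theta), t
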