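"""Gray-level co-occurrence matrices and texture statistics.

A GLCM counts, over a region, how often gray level i occurs at a pixel
``(m, n)`` and gray level j at the offset pixel ``(m, n) + d * (cos t,
sin t)``, then normalizes the counts to a probability matrix p(i, j).
Five scalar texture statistics are derived from p:

    ASM         = sum_ij p(i, j)^2
    Contrast    = sum_ij p(i, j) (i - j)^2
    Correlation = (sum_ij i j p(i, j) - mu_x mu_y) / (sigma_x sigma_y)
    Variance    = sum_ij (i j - mu_x mu_y) p(i, j)
    Entropy     = -sum_ij p(i, j) log p(i, j)      (0 log 0 := 0)

where mu/sigma are the means and SDs of the row and column marginals.
Note the Variance statistic is the covariance-like form written above,
*not* the conventional GLCM variance ``sum (i - mu)^2 p``; the form
above is what this toolkit computes, by design, and it equals the
numerator of Correlation. Correlation is defined as 0 when
``sigma_x * sigma_y = 0`` (flat windows).

Orientations follow the Haralick offset convention at distance d:
0 deg -> (0, +d), 45 deg -> (-d, +d), 90 deg -> (-d, 0),
135 deg -> (-d, -d) in (row, col). Accumulation is single-direction by
default; a ``symmetric`` flag adds the reverse pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .errors import EmptyGLCMError

_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class TextureConfig:
    """Window, offset, and quantization settings for texture maps."""

    window: int = 7
    d: int = 1
    thetas: tuple[int, ...] = (0, 45, 90, 135)
    n_levels: int = 16
    log_base: float = 2.0
    symmetric: bool = False

    def validate(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        bad = set(self.thetas) - set(_OFFSETS)
        if bad or not self.thetas:
            raise ValueError(
                f"thetas must be a non-empty subset of {sorted(_OFFSETS)}")
        if self.log_base <= 1:
            raise ValueError("log_base must exceed 1")


class TextureVector(NamedTuple):
    """The five texture statistics of one GLCM."""

    asm: float
    contrast: float
    correlation: float
    variance: float
    entropy: float


@dataclass(frozen=True)
class GLCM:
    """Normalized co-occurrence matrix with marginal moments."""

    p: np.ndarray
    n_levels: int
    d: int = 1
    theta: int = 0

    @classmethod
    def from_counts(cls, counts: np.ndarray, d: int = 1,
                    theta: int = 0) -> "GLCM":
        counts = np.asarray(counts, dtype=float)
        total = counts.sum()
        if total <= 0:
            raise EmptyGLCMError("co-occurrence counts are empty")
        return cls(p=counts / total, n_levels=counts.shape[0], d=d, theta=theta)

    @property
    def px(self) -> np.ndarray:
        return self.p.sum(axis=1)

    @property
    def py(self) -> np.ndarray:
        return self.p.sum(axis=0)

    @property
    def mu_x(self) -> float:
        return float(self.px @ np.arange(self.n_levels))

    @property
    def mu_y(self) -> float:
        return float(self.py @ np.arange(self.n_levels))

    @property
    def sigma_x(self) -> float:
        lev = np.arange(self.n_levels)
        return float(np.sqrt(max(self.px @ lev**2 - self.mu_x**2, 0.0)))

    @property
    def sigma_y(self) -> float:
        lev = np.arange(self.n_levels)
        return float(np.sqrt(max(self.py @ lev**2 - self.mu_y**2, 0.0)))


def quantize_image(image: np.ndarray, n_levels: int) -> np.ndarray:
    """Uniformly bin ``[min, max]`` into ``n_levels`` integer levels.

    A constant image maps to level 0 everywhere.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    img = np.asarray(image, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return np.zeros(img.shape, dtype=np.intp)
    levels = np.floor((img - lo) / (hi - lo) * n_levels).astype(np.intp)
    return np.clip(levels, 0, n_levels - 1)


def _pair_slices(shape, dr: int, dc: int):
    h, w = shape
    r0, r1 = max(0, -dr), h - max(0, dr)
    c0, c1 = max(0, -dc), w - max(0, dc)
    if r1 <= r0 or c1 <= c0:
        return None
    first = (slice(r0, r1), slice(c0, c1))
    second = (slice(r0 + dr, r1 + dr), slice(c0 + dc, c1 + dc))
    return first, second


def compute_glcm(window: np.ndarray, d: int = 1, theta: int = 0,
                 n_levels: int | None = None, symmetric: bool = False) -> GLCM:
    """Co-occurrence matrix of one integer-level window.

    Raises :class:`EmptyGLCMError` when the window is smaller than the
    offset so no valid pixel pair exists.
    """
    win = np.asarray(window, dtype=np.intp)
    if theta not in _OFFSETS:
        raise ValueError(f"theta must be one of {sorted(_OFFSETS)}")
    if n_levels is None:
        n_levels = int(win.max()) + 1
    if win.min() < 0 or win.max() >= n_levels:
        raise ValueError("window levels must lie in [0, n_levels)")
    dr, dc = (d * o for o in _OFFSETS[theta])
    pair = _pair_slices(win.shape, dr, dc)
    if pair is None:
        raise EmptyGLCMError(
            f"window {win.shape} has no valid pair for offset ({dr}, {dc})")
    a = win[pair[0]].ravel()
    b = win[pair[1]].ravel()
    counts = np.zeros((n_levels, n_levels))
    np.add.at(counts, (a, b), 1.0)
    if symmetric:
        counts = counts + counts.T
    return GLCM.from_counts(counts, d=d, theta=theta)


def texture_features(glcm: GLCM, log_base: float = 2.0) -> TextureVector:
    """The five texture statistics of a normalized GLCM."""
    p = np.asarray(glcm.p, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6 or (p < 0).any():
        raise ValueError("GLCM must be a normalized probability matrix")
    lev = np.arange(glcm.n_levels)
    i = lev[:, None]
    j = lev[None, :]
    asm = float((p ** 2).sum())
    contrast = float((p * (i - j) ** 2).sum())
    mu_x, mu_y = glcm.mu_x, glcm.mu_y
    sig_x, sig_y = glcm.sigma_x, glcm.sigma_y
    cov = float((p * i * j).sum()) - mu_x * mu_y
    correlation = cov / (sig_x * sig_y) if sig_x * sig_y > 1e-12 else 0.0
    variance = float(((i * j - mu_x * mu_y) * p).sum())
    pos = p[p > 0]
    entropy = float(-(pos * np.log(pos)).sum() / np.log(log_base))
    return TextureVector(asm, contrast, correlation, variance, entropy)


def _windowed_counts(code: np.ndarray, n_codes: int, out_shape,
                     win_h: int, win_w: int) -> np.ndarray:
    """Sliding box sums of per-code indicators via integral images.

    ``code`` holds the pair code at every first-point position of the
    padded grid; the window of output pixel (i, j) covers the
    ``win_h x win_w`` rectangle with top-left (i, j). Returns counts of
    shape ``(H, W, n_codes)``.
    """
    h_out, w_out = out_shape
    onehot = (code[None, :, :] == np.arange(n_codes)[:, None, None])
    integ = np.zeros((n_codes, code.shape[0] + 1, code.shape[1] + 1))
    np.cumsum(onehot, axis=1, out=integ[:, 1:, 1:])
    np.cumsum(integ[:, 1:, 1:], axis=2, out=integ[:, 1:, 1:])
    counts = (integ[:, win_h:win_h + h_out, win_w:win_w + w_out]
              - integ[:, :h_out, win_w:win_w + w_out]
              - integ[:, win_h:win_h + h_out, :w_out]
              + integ[:, :h_out, :w_out])
    return np.moveaxis(counts, 0, -1)


def feature_map(image: np.ndarray, config: TextureConfig | None = None,
                mask: np.ndarray | None = None) -> np.ndarray:
    """Per-pixel texture features over centered sliding windows.

    The image is globally quantized to ``config.n_levels`` and padded by
    reflection so the output has the image's dimensions. The feature
    axis holds, for each orientation in ``config.thetas`` in order, the
    block (ASM, contrast, correlation, variance, entropy). When ``mask``
    is given, features outside it are zeroed.
    """
    config = config or TextureConfig()
    config.validate()
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    if min(h, w) < config.window:
        raise ValueError(
            f"image {img.shape} smaller than the {config.window}x"
            f"{config.window} window")
    r = config.window // 2
    ng = config.n_levels
    quant = np.pad(quantize_image(img, ng), r, mode="reflect")
    lev = np.arange(ng, dtype=float)
    code_i = np.repeat(lev, ng)
    code_j = np.tile(lev, ng)

    out = np.empty((h, w, 5 * len(config.thetas)))
    for t_idx, theta in enumerate(config.thetas):
        dr, dc = (config.d * o for o in _OFFSETS[theta])
        pair = _pair_slices(quant.shape, dr, dc)
        if pair is None:
            raise EmptyGLCMError(
                f"offset ({dr}, {dc}) exceeds the padded image")
        win_h = config.window - abs(dr)
        win_w = config.window - abs(dc)
        if win_h <= 0 or win_w <= 0:
            raise EmptyGLCMError(
                f"offset ({dr}, {dc}) exceeds the {config.window} window")
        code = quant[pair[0]] * ng + quant[pair[1]]
        counts = _windowed_counts(code, ng * ng, (h, w), win_h, win_w)
        if config.symmetric:
            rev = counts.reshape(h, w, ng, ng).swapaxes(2, 3).reshape(h, w, -1)
            counts = counts + rev
        p = counts / counts.sum(axis=-1, keepdims=True)

        asm = np.einsum("hwk,hwk->hw", p, p)
        contrast = p @ ((code_i - code_j) ** 2)
        pij = p @ (code_i * code_j)
        p4 = p.reshape(h, w, ng, ng)
        px = p4.sum(axis=3)
        py = p4.sum(axis=2)
        mu_x = px @ lev
        mu_y = py @ lev
        sig_x = np.sqrt(np.clip(px @ lev**2 - mu_x**2, 0.0, None))
        sig_y = np.sqrt(np.clip(py @ lev**2 - mu_y**2, 0.0, None))
        denom = sig_x * sig_y
        cov = pij - mu_x * mu_y
        correlation = np.where(denom > 1e-12, cov / np.where(denom > 1e-12, denom, 1.0), 0.0)
        variance = cov  # sum (ij - mu_x mu_y) p == sum ij p - mu_x mu_y
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        entropy = -plogp.sum(axis=-1) / np.log(config.log_base)

        block = slice(5 * t_idx, 5 * t_idx + 5)
        out[:, :, block] = np.stack(
            [asm, contrast, correlation, variance, entropy], axis=-1)

    if mask is not None:
        out = np.where(np.asarray(mask, dtype=bool)[:, :, None], out, 0.0)
    return out


def window_features(window: np.ndarray, config: TextureConfig | None = None
                    ) -> dict[int, TextureVector]:
    """Texture statistics of a single pre-quantized window, per theta."""
    config = config or TextureConfig()
    config.validate()
    return {theta: texture_features(
        compute_glcm(window, d=config.d, theta=theta,
                     n_levels=config.n_levels, symmetric=config.symmetric),
        log_base=config.log_base) for theta in config.thetas}
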