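"""Rigid registration of brain functional time-series frames.

Each frame of a time series is aligned to frame 0 by a block-matching
pipeline: the reference is tiled into small square sub-blocks (default
4 x 4 px); each non-flat block searches a window of integer
displacements in the moving frame for the maximum normalized
cross-correlation (NCC), refined to sub-pixel precision by a parabolic
fit and accumulated across a two-level coarse-to-fine pass with the
geometric recursion

    B(k) = phi * B(k-1) + d(k),    B(0) = d(0),

whose fixed point for bounded increments is bounded by c / (1 - phi).
A boosted ensemble of decision stumps (AdaBoost) scores the
reliability of every block match from its NCC, gradient energy, and
disagreement with the median displacement; the weighted matches feed a
closed-form weighted rigid (rotation + translation) least-squares fit.
The per-frame transform is polished by a damped fixed-point loop:
re-warp, re-match, and apply a fraction (the descent rate) of the
residual fit until the residual motion is negligible.

Two diagnostic constructs accompany the pipeline without influencing
the recovered transforms: a seeded mode-seeking clustering of sampled
pixel coordinates (fuzzy-pixel set), and a spherical-coordinate report
of the mean displacement (template-matching radius T, inclination
gamma, azimuth phi) with a sign gate flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import AdaBoostClassifier
from sklearn.tree import DecisionTreeClassifier

from .errors import DegenerateFitError
from .phantom import MotionSeries
from .transforms import IDENTITY, RigidTransform2D, grid_center, resample


@dataclass(frozen=True)
class RegParams:
    """Clustering, block-matching, and refinement settings.

    ``m_threshold`` is the regional gradient threshold M (mean-shift
    step clip and cluster-merge distance, px); ``tau`` the mode-seeking
    convergence threshold (px); ``neighborhood_radius`` the radius of
    the marking region around a converged centre (px). ``block`` is the
    sub-block edge (px), ``search_radius`` the block-match search
    extent, ``phi_coeff`` the coefficient of the similarity recursion.
    ``n_iters`` / ``iter_step`` bound the damped refinement loop at
    ``n_iters / iter_step`` rounds (also the boosting ensemble size),
    ``descent_rate`` is the damping factor applied to each residual
    transform, and ``edge_quant_coeff`` the NCC floor a block must reach
    to enter the match set.
    """

    m_threshold: float = 5.0
    tau: float = 0.05
    neighborhood_radius: float = 5.0
    block: int = 4
    search_radius: int = 5
    phi_coeff: float = 0.5
    n_iters: int = 100
    iter_step: int = 10
    descent_rate: float = 0.45
    edge_quant_coeff: float = 0.62
    seed: int = 0
    n_sample_pixels: int = 100

    def validate(self) -> None:
        if self.m_threshold <= 0 or self.tau <= 0:
            raise ValueError("m_threshold and tau must be positive")
        if self.block < 2 or self.search_radius < 1:
            raise ValueError("block >= 2 and search_radius >= 1 required")
        if not 0.0 < self.phi_coeff < 1.0:
            raise ValueError("phi_coeff must lie in (0, 1)")
        if not 0.0 < self.descent_rate <= 1.0:
            raise ValueError("descent_rate must lie in (0, 1]")

    @property
    def refine_rounds(self) -> int:
        return max(1, self.n_iters // self.iter_step)


@dataclass
class ClusterSet:
    """Mode-seeking clustering output over pixel coordinates."""

    centers: np.ndarray          # (k, 2)
    memberships: np.ndarray      # (n,) cluster index per point
    fuzzy_set: np.ndarray        # indices in the order they were marked
    trajectories: list = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]


@dataclass
class SimilarityTrace:
    """Accumulated correlation recursion B alongside its increments."""

    values: np.ndarray
    increments: np.ndarray
    phi_coeff: float


@dataclass
class BlockMatches:
    """Per-block displacement estimates and their descriptors."""

    centers: np.ndarray        # (k, 2) block centres in (row, col)
    displacements: np.ndarray  # (k, 2) sub-pixel (drow, dcol)
    ncc: np.ndarray            # (k,) best fine-level NCC
    similarity: np.ndarray     # (k,) accumulated coarse-to-fine score
    grad_energy: np.ndarray    # (k,) mean squared gradient of the ref block
    structure: np.ndarray = None  # (k,) min eigenvalue of context tensor
    accepted: np.ndarray = None   # (k,) NCC >= edge_quant_coeff
    n_flat: int = 0

    def __post_init__(self) -> None:
        k = self.centers.shape[0]
        if self.structure is None:
            self.structure = np.zeros(k)
        if self.accepted is None:
            self.accepted = np.ones(k, dtype=bool)

    def __len__(self) -> int:
        return self.centers.shape[0]

    def subset(self, mask: np.ndarray) -> "BlockMatches":
        return BlockMatches(
            centers=self.centers[mask],
            displacements=self.displacements[mask],
            ncc=self.ncc[mask], similarity=self.similarity[mask],
            grad_energy=self.grad_energy[mask],
            structure=self.structure[mask],
            accepted=self.accepted[mask], n_flat=self.n_flat)


@dataclass
class PolarOutput:
    """Spherical-coordinate view of a displacement (diagnostic only)."""

    radius: float          # template-matching coefficient T
    gamma_deg: float       # inclination from the +z axis
    phi_deg: float         # azimuth in the xy plane
    cartesian: tuple[float, float, float]
    gate: bool             # True when the gate value is <= 0


@dataclass
class RegistrationResult:
    """Recovered transforms, aligned frames, and diagnostics."""

    transforms: list[RigidTransform2D]
    aligned: np.ndarray
    diagnostics: dict


# ---------------------------------------------------------------------------
# fuzzy-pixel mode-seeking clustering
# ---------------------------------------------------------------------------

def cluster_fuzzy_pixels(points: np.ndarray,
                         params: RegParams | None = None) -> ClusterSet:
    """Seeded mode-seeking clustering of 2D points.

    Repeatedly picks a random unmarked point, shifts it toward the
    local density mean within ``neighborhood_radius`` (each shift
    clipped to magnitude ``m_threshold``) until the shift magnitude
    drops below ``tau``, marks the points around the converged centre
    into a cluster, and merges centres closer than ``m_threshold``.
    The random selection stream walks the points in sorted-coordinate
    order, so clustering is stable under permutations of the input.
    """
    params = params or RegParams()
    params.validate()
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = pts.shape[0]
    if n == 0:
        raise ValueError("at least one point is required")
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    rng = np.random.default_rng(params.seed)

    marked = np.zeros(n, dtype=bool)
    membership = np.full(n, -1, dtype=int)
    centers: list[np.ndarray] = []
    weights: list[int] = []
    trajectories: list[np.ndarray] = []
    marked_order: list[int] = []

    while not marked.all():
        candidates = order[~marked[order]]
        h_idx = int(candidates[rng.integers(candidates.size)])
        center = pts[h_idx].copy()
        traj = [center.copy()]
        for _ in range(200):
            near = pts[np.linalg.norm(pts - center, axis=1)
                       <= params.neighborhood_radius]
            shift = near.mean(axis=0) - center
            mag = float(np.linalg.norm(shift))
            if mag > params.m_threshold:
                shift *= params.m_threshold / mag
                mag = params.m_threshold
            center = center + shift
            traj.append(center.copy())
            if mag < params.tau:
                break
        trajectories.append(np.asarray(traj))

        members = np.nonzero(
            ~marked & (np.linalg.norm(pts - center, axis=1)
                       <= params.neighborhood_radius))[0]
        if members.size == 0:
            members = np.array([h_idx])

        target = None
        for ci, c in enumerate(centers):
            if np.linalg.norm(c - center) < params.m_threshold:
                target = ci
                break
        if target is None:
            centers.append(center)
            weights.append(members.size)
            target = len(centers) - 1
        else:  # merge: count-weighted average of the two centres
            w_old, w_new = weights[target], members.size
            centers[target] = (centers[target] * w_old + center * w_new) \
                / (w_old + w_new)
            weights[target] += w_new
        membership[members] = target
        marked[members] = True
        marked_order.extend(int(m) for m in members)

    centers_arr, membership = _merge_close_centers(
        np.asarray(centers), np.asarray(weights, dtype=float), membership,
        params.m_threshold)
    return ClusterSet(centers=centers_arr, memberships=membership,
                      fuzzy_set=np.asarray(marked_order),
                      trajectories=trajectories)


def _merge_close_centers(centers, weights, membership, threshold):
    """Repeat pairwise merges until all centres are >= threshold apart."""
    while centers.shape[0] > 1:
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if d[i, j] >= threshold:
            break
        keep, drop = min(i, j), max(i, j)
        centers[keep] = (centers[keep] * weights[keep]
                         + centers[drop] * weights[drop]) \
            / (weights[keep] + weights[drop])
        weights[keep] += weights[drop]
        centers = np.delete(centers, drop, axis=0)
        weights = np.delete(weights, drop)
        membership = np.where(membership == drop, keep, membership)
        membership = np.where(membership > drop, membership - 1, membership)
    return centers, membership


# ---------------------------------------------------------------------------
# similarity recursion and block matching
# ---------------------------------------------------------------------------

def recursive_similarity(increments: Sequence[float],
                         phi_coeff: float) -> SimilarityTrace:
    """Geometric accumulation ``B(k) = phi B(k-1) + d(k)``."""
    inc = np.asarray(increments, dtype=float)
    if inc.size == 0:
        raise ValueError("increments must be non-empty")
    values = np.empty_like(inc)
    values[0] = inc[0]
    for k in range(1, inc.size):
        values[k] = phi_coeff * values[k - 1] + inc[k]
    return SimilarityTrace(values=values, increments=inc,
                           phi_coeff=phi_coeff)


def _tile(img: np.ndarray, block: int) -> np.ndarray:
    h, w = img.shape
    nbr, nbc = h // block, w // block
    return (img[:nbr * block, :nbc * block]
            .reshape(nbr, block, nbc, block).swapaxes(1, 2))


#: Matching context: each block is matched using the patch of this many
#: block widths centred on it, which suppresses the aperture ambiguity
#: of tiny straight-edge blocks.
_CONTEXT_FACTOR = 3


def _context_tiles(img: np.ndarray, block: int, ctx: int) -> np.ndarray:
    """(nbr, nbc, ctx, ctx) context patches centred on the block tiling."""
    pad = (ctx - block) // 2
    padded = np.pad(img, pad, mode="edge")
    view = np.lib.stride_tricks.sliding_window_view(padded, (ctx, ctx))
    return view[::block, ::block]


def _ncc_search(ref: np.ndarray, moving: np.ndarray, block: int,
                radius: int, ctx: int | None = None):
    """Integer-displacement NCC over all blocks and offsets.

    Each block of the reference tiling is compared through its centred
    ``ctx x ctx`` context patch. Returns ``(scores, flat)`` where
    ``scores`` has shape ``(nbr, nbc, 2r+1, 2r+1)`` and flat blocks
    (zero variance in the reference context) are marked in ``flat``.
    The moving frame is edge-padded so every offset is defined near the
    border.
    """
    if ctx is None:
        ctx = block
    h, w = ref.shape
    nbr, nbc = h // block, w // block
    tiles = _context_tiles(ref, block, ctx)[:nbr, :nbc]
    rc = tiles - tiles.mean(axis=(2, 3), keepdims=True)
    rnorm = np.sqrt((rc ** 2).sum(axis=(2, 3)))
    flat = rnorm <= 1e-10
    pad = (ctx - block) // 2
    mp = np.pad(moving, pad + radius, mode="edge")
    scores = np.full((nbr, nbc, 2 * radius + 1, 2 * radius + 1), -1.0)
    for iu, du in enumerate(range(-radius, radius + 1)):
        for iv, dv in enumerate(range(-radius, radius + 1)):
            view = mp[radius + du: radius + du + h + 2 * pad,
                      radius + dv: radius + dv + w + 2 * pad]
            mt = np.lib.stride_tricks.sliding_window_view(
                view, (ctx, ctx))[::block, ::block][:nbr, :nbc]
            mc = mt - mt.mean(axis=(2, 3), keepdims=True)
            mnorm = np.sqrt((mc ** 2).sum(axis=(2, 3)))
            denom = rnorm * mnorm
            ok = denom > 1e-12
            s = np.zeros((nbr, nbc))
            s[ok] = (rc * mc).sum(axis=(2, 3))[ok] / denom[ok]
            scores[:, :, iu, iv] = s
    return scores, flat


def _structure_min_eig(ref: np.ndarray, block: int, ctx: int) -> np.ndarray:
    """Smallest eigenvalue of the context structure tensor per block.

    High values mark patches with two-dimensional structure (corners,
    curved boundaries) whose displacement is fully determined; straight
    edges and smooth patches score low.
    """
    gr, gc = np.gradient(ref)
    h, w = ref.shape
    nbr, nbc = h // block, w // block

    def tile_sum(x):
        return _context_tiles(x, block, ctx)[:nbr, :nbc].sum(axis=(2, 3))

    a = tile_sum(gr * gr)
    b = tile_sum(gr * gc)
    c = tile_sum(gc * gc)
    half_tr = (a + c) / 2.0
    disc = np.sqrt(np.maximum(half_tr ** 2 - (a * c - b * b), 0.0))
    return half_tr - disc


def _subpixel_peak(scores: np.ndarray, iu: np.ndarray, iv: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """1D parabolic refinement of each block's NCC peak, per axis."""
    nbr, nbc, nu, nv = scores.shape
    bi, bj = np.meshgrid(np.arange(nbr), np.arange(nbc), indexing="ij")

    def refine(idx, size, axis_take):
        frac = np.zeros(idx.shape)
        interior = (idx > 0) & (idx < size - 1)
        s0 = axis_take(idx)
        sm = axis_take(np.clip(idx - 1, 0, size - 1))
        sp = axis_take(np.clip(idx + 1, 0, size - 1))
        denom = sm - 2.0 * s0 + sp
        ok = interior & (np.abs(denom) > 1e-12)
        frac[ok] = 0.5 * (sm - sp)[ok] / denom[ok]
        return np.clip(frac, -0.5, 0.5)

    du = refine(iu, nu, lambda k: scores[bi, bj, np.clip(k, 0, nu - 1), iv])
    dv = refine(iv, nv, lambda k: scores[bi, bj, iu, np.clip(k, 0, nv - 1)])
    return du, dv


def block_match(ref: np.ndarray, moving: np.ndarray,
                params: RegParams | None = None) -> BlockMatches:
    """Tile the reference and match each block into the moving frame.

    Each ``block x block`` tile is matched through its centred
    3-block-wide context patch (tiny blocks on straight boundaries are
    otherwise ambiguous along the boundary). Runs a half-resolution
    coarse pass and a full-resolution fine pass; the per-block
    similarity is the ``recursive_similarity`` accumulation of the two
    NCC peaks. Flat (zero-variance) blocks are excluded; blocks whose
    fine NCC falls below ``edge_quant_coeff`` are kept but flagged
    unaccepted.
    """
    params = params or RegParams()
    params.validate()
    ref = np.asarray(ref, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if ref.shape != moving.shape:
        raise ValueError(f"shape mismatch {ref.shape} vs {moving.shape}")
    b, r = params.block, params.search_radius
    if min(ref.shape) < b + 2 * r:
        raise ValueError("image smaller than block + 2*search_radius")
    ctx = _CONTEXT_FACTOR * b

    scores, flat = _ncc_search(ref, moving, b, r, ctx=ctx)
    nbr, nbc = flat.shape
    # tie-break exact NCC ties toward the smallest displacement
    offs = np.arange(-r, r + 1)
    penalty = 1e-9 * (offs[:, None] ** 2 + offs[None, :] ** 2)
    best = (scores - penalty).reshape(nbr, nbc, -1)
    arg = best.argmax(axis=2)
    iu, iv = np.unravel_index(arg, (2 * r + 1, 2 * r + 1))
    bi, bj = np.meshgrid(np.arange(nbr), np.arange(nbc), indexing="ij")
    ncc_fine = scores[bi, bj, iu, iv]
    fu, fv = _subpixel_peak(scores, iu, iv)
    exact = ncc_fine >= 1.0 - 1e-9  # perfect match: the integer peak is exact
    fu[exact] = 0.0
    fv[exact] = 0.0
    drow = (iu - r) + fu
    dcol = (iv - r) + fv

    # coarse pass at half resolution (skipped when blocks do not nest)
    coarse_ncc = None
    if b % 2 == 0 and min(ref.shape) // 2 >= b // 2 + 2:
        cb = b // 2
        cr = max(1, math.ceil(r / 2))
        ref2 = _halve(ref)
        mov2 = _halve(moving)
        if min(ref2.shape) >= cb + 2 * cr:
            cscores, _ = _ncc_search(ref2, mov2, cb, cr,
                                     ctx=_CONTEXT_FACTOR * cb)
            cbest = cscores.reshape(cscores.shape[0], cscores.shape[1], -1)
            cmax = cbest.max(axis=2)
            if cmax.shape == flat.shape:
                coarse_ncc = cmax

    centers = np.stack([
        (bi * b + (b - 1) / 2.0).astype(float),
        (bj * b + (b - 1) / 2.0).astype(float)], axis=-1)

    grad_r, grad_c = np.gradient(ref)
    ge_map = _tile(grad_r ** 2 + grad_c ** 2, b).mean(axis=(2, 3))
    struct = _structure_min_eig(ref, b, ctx)

    keep = ~flat
    k = int(keep.sum())
    similarity = np.empty(k)
    inc_fine = ncc_fine[keep]
    inc_coarse = coarse_ncc[keep] if coarse_ncc is not None else None
    for out_i in range(k):
        inc = ([inc_coarse[out_i], inc_fine[out_i]]
               if inc_coarse is not None else [inc_fine[out_i]])
        similarity[out_i] = recursive_similarity(
            inc, params.phi_coeff).values[-1]

    return BlockMatches(
        centers=centers[keep],
        displacements=np.stack([drow[keep], dcol[keep]], axis=-1),
        ncc=ncc_fine[keep],
        similarity=similarity,
        grad_energy=ge_map[keep],
        structure=struct[keep],
        accepted=ncc_fine[keep] >= params.edge_quant_coeff,
        n_flat=int(flat.sum()))


def _halve(img: np.ndarray) -> np.ndarray:
    h, w = img.shape
    h2, w2 = h // 2, w // 2
    return img[:h2 * 2, :w2 * 2].reshape(h2, 2, w2, 2).mean(axis=(1, 3))


# ---------------------------------------------------------------------------
# boosted match weighting and rigid estimation
# ---------------------------------------------------------------------------

def boost_match_weights(matches: BlockMatches,
                        params: RegParams | None = None,
                        truth_labels: np.ndarray | None = None) -> np.ndarray:
    """AdaBoost (decision stumps) reliability weight per match, in [0, 1].

    Descriptors are the fine NCC, the reference block's gradient
    energy, and the match's distance to the median displacement. In
    unsupervised mode the pseudo-label marks matches within 1 px
    (Chebyshev) of the field's median displacement as inliers. With a
    single pseudo-class or identical descriptors the weights degenerate
    to a uniform value.
    """
    params = params or RegParams()
    k = len(matches)
    if k < 10:
        raise ValueError("at least 10 matches are required for boosting")
    d = matches.displacements
    med = np.median(d, axis=0)
    disagreement = np.linalg.norm(d - med, axis=1)
    desc = np.column_stack([matches.ncc, matches.grad_energy, disagreement])
    if truth_labels is not None:
        labels = np.asarray(truth_labels, dtype=bool)
    else:
        labels = np.max(np.abs(d - med), axis=1) <= 1.0

    if np.unique(labels).size < 2:
        return np.ones(k) if labels.all() else np.full(k, 0.5)
    if np.allclose(desc, desc[0]):
        return np.full(k, 0.5)

    clf = AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_depth=1, random_state=0),
        n_estimators=params.refine_rounds,
        random_state=params.seed % (2**31))
    clf.fit(desc, labels)
    proba = clf.predict_proba(desc)
    col = int(np.nonzero(clf.classes_ == True)[0][0])  # noqa: E712
    return proba[:, col]


def estimate_rigid_transform(src: np.ndarray, dst: np.ndarray,
                             weights: np.ndarray | None = None,
                             center=(0.0, 0.0)) -> RigidTransform2D:
    """Weighted least-squares rigid fit mapping ``src`` onto ``dst``.

    Closed-form Kabsch solution via the SVD of the weighted
    cross-covariance, reflections excluded. Invariant to a positive
    rescaling of the weights. Raises :class:`DegenerateFitError` when
    the weighted point spread vanishes (all effective points coincide).
    """
    src = np.atleast_2d(np.asarray(src, dtype=float))
    dst = np.atleast_2d(np.asarray(dst, dtype=float))
    if src.shape != dst.shape or src.shape[0] < 2:
        raise DegenerateFitError("need >= 2 matched point pairs")
    w = np.ones(src.shape[0]) if weights is None \
        else np.asarray(weights, dtype=float)
    if w.min() < 0 or w.sum() <= 0:
        raise DegenerateFitError("weights must be non-negative, not all zero")
    w = w / w.sum()
    p_bar = w @ src
    q_bar = w @ dst
    x = src - p_bar
    y = dst - q_bar
    if float(w @ (x ** 2).sum(axis=1)) < 1e-12:
        raise DegenerateFitError("weighted point spread is degenerate")
    cov = (w[:, None] * x).T @ y
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, d]) @ u.T
    t = q_bar - rot @ p_bar
    c = np.asarray(center, dtype=float)
    t_c = rot @ c - c + t
    angle = math.degrees(math.atan2(rot[1, 0], rot[0, 0]))
    return RigidTransform2D(tx=float(t_c[1]), ty=float(t_c[0]),
                            angle_deg=angle)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def to_polar_output(displacement, gate_value: float = 0.0) -> PolarOutput:
    """Spherical-coordinate conversion of a (2- or 3-) displacement.

    2D displacements ``(drow, dcol)`` are embedded as ``(x=dcol,
    y=drow, z=0)``. The zero vector maps to radius 0 with both angles 0
    by convention. Round-trips exactly; diagnostic only — it never
    alters a transform.
    """
    v = np.asarray(displacement, dtype=float).ravel()
    if v.size == 2:
        v = np.array([v[1], v[0], 0.0])
    elif v.size != 3:
        raise ValueError("displacement must have 2 or 3 components")
    radius = float(np.linalg.norm(v))
    if radius == 0.0:
        gamma = phi = 0.0
    else:
        gamma = math.degrees(math.acos(np.clip(v[2] / radius, -1.0, 1.0)))
        phi = math.degrees(math.atan2(v[1], v[0])) if (v[0] or v[1]) else 0.0
    sg, cg = math.sin(math.radians(gamma)), math.cos(math.radians(gamma))
    sp, cp = math.sin(math.radians(phi)), math.cos(math.radians(phi))
    cart = (radius * sg * cp, radius * sg * sp, radius * cg)
    return PolarOutput(radius=radius, gamma_deg=gamma, phi_deg=phi,
                       cartesian=cart, gate=gate_value <= 0)


# ---------------------------------------------------------------------------
# full time-series registration
# ---------------------------------------------------------------------------

#: Fraction of non-flat blocks discarded as structureless before the
#: rigid fit (straight edges and smooth bias gradients carry an
#: ambiguous or empty motion signal).
_STRUCTURE_QUANTILE = 0.8


def _register_frame(ref: np.ndarray, frame: np.ndarray, params: RegParams,
                    cval: float) -> tuple[RigidTransform2D, dict]:
    center = grid_center(ref.shape)
    t = IDENTITY
    info: dict = {"iterations": 0, "n_matches": 0, "mean_weight": 1.0,
                  "mean_ncc": 0.0, "mean_similarity": 0.0}
    for _ in range(params.refine_rounds):
        warped = resample(frame, t.inverse(), order=1, cval=cval)
        matches = block_match(ref, warped, params)
        if len(matches) == 0:
            break
        thr = np.quantile(matches.structure, _STRUCTURE_QUANTILE)
        use = matches.accepted & (matches.structure >= thr)
        if use.sum() < 3:
            use = matches.accepted if matches.accepted.sum() >= 3 \
                else np.ones(len(matches), dtype=bool)
        picked = matches.subset(use)
        if len(picked) >= 10:
            weights = boost_match_weights(picked, params)
        else:
            weights = np.ones(len(picked))
        if len(picked) < 2:
            break
        delta = estimate_rigid_transform(
            picked.centers, picked.centers + picked.displacements,
            weights, center)
        info["iterations"] += 1
        info["n_matches"] = int(len(picked))
        info["mean_weight"] = float(weights.mean())
        info["mean_ncc"] = float(picked.ncc.mean())
        info["mean_similarity"] = float(picked.similarity.mean())
        # accumulated estimate maps reference coords into the frame:
        # T_new(p) = T(delta(p)); delta damped by the descent rate
        t = delta.scaled(params.descent_rate).then(t)
        shift, ang = delta.magnitude()
        if shift < 0.02 and ang < 0.01:
            break
    return t, info


def register_time_series(series: MotionSeries | np.ndarray,
                         params: RegParams | None = None,
                         compute_diagnostics: bool = True
                         ) -> RegistrationResult:
    """Align every frame of a series to frame 0 with rigid transforms.

    Returns the recovered per-frame transforms (frame 0 is the
    identity), the aligned frame stack, and a diagnostics dictionary
    with per-frame match statistics, the seeded 100-pixel
    cluster/polar report, and — when the input is a
    :class:`~csvmtk.phantom.MotionSeries` carrying ground truth — the
    per-frame target registration error over a fixed probe grid.
    """
    params = params or RegParams()
    params.validate()
    truth = None
    if isinstance(series, MotionSeries):
        frames = series.frames
        truth = series.truth_transforms
    else:
        frames = np.asarray(series, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("series must hold at least 2 frames")

    ref = frames[0]
    center = grid_center(ref.shape)
    cval = float(np.median(ref))
    rng = np.random.default_rng(params.seed)

    transforms: list[RigidTransform2D] = [IDENTITY]
    aligned = [ref.copy()]
    per_frame: list[dict] = [{}]
    for k in range(1, frames.shape[0]):
        t, info = _register_frame(ref, frames[k], params, cval)
        transforms.append(t)
        aligned.append(resample(frames[k], t.inverse(), order=1, cval=cval))

        if compute_diagnostics:
            pix = _sample_pixels(frames[k], params.n_sample_pixels, rng)
            clusters = cluster_fuzzy_pixels(pix, params)
            polar = to_polar_output(
                (t.ty, t.tx), gate_value=params.edge_quant_coeff
                - info.get("mean_ncc", 0.0))
            info["cluster_centers"] = clusters.centers.tolist()
            info["polar"] = {"radius": polar.radius,
                            "gamma_deg": polar.gamma_deg,
                            "phi_deg": polar.phi_deg,
                            "gate": polar.gate}
        per_frame.append(info)

    diagnostics: dict = {"frames": per_frame}
    if truth is not None:
        from .metrics import probe_grid, target_registration_error
        probes = probe_grid(ref.shape)
        diagnostics["tre_px"] = [
            target_registration_error(est, tru, probes, center)
            for est, tru in zip(transforms, truth)]
        diagnostics["mean_tre_px"] = float(np.mean(diagnostics["tre_px"][1:])) \
            if len(transforms) > 1 else 0.0
    return RegistrationResult(transforms=transforms,
                              aligned=np.stack(aligned),
                              diagnostics=diagnostics)


def _sample_pixels(frame: np.ndarray, n: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Seeded sample of pixel coordinates, gradient-weighted so the
    diagnostic clustering concentrates on structured image regions."""
    gr, gc = np.gradient(frame)
    weight = (gr ** 2 + gc ** 2).ravel()
    total = weight.sum()
    p = weight / total if total > 0 else None
    idx = rng.choice(frame.size, size=min(n, frame.size), replace=False, p=p)
    rows, cols = np.unravel_index(idx, frame.shape)
    return np.stack([rows, cols], axis=1).astype(float)
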