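"""Gaussian-kernel SVM tissue classification and the C-SVM pipeline.

The contour stage (Chan-Vese) separates brain from background; a
soft-margin SVM with the Gaussian kernel

    k(x, x') = exp(-||x - x'||^2 / (2 sigma^2))

then labels every pixel inside the contour as CSF, grey matter, or
white matter from a 22-dimensional feature vector: the 20 windowed
texture statistics (5 statistics x 4 orientations), the windowed mean
intensity, and the pixel's own intensity (the last disambiguates the
one-pixel boundary band that windowed features blur across). Multi-class decisions use one-vs-one majority voting
with ties broken by the summed pairwise margins. Features are z-scored
with statistics estimated on the training sample only, so the fixed
kernel width remains on a meaningful scale.

The quadratic-programming dual is solved by scikit-learn's SMO-based
libsvm backend; the model wrapper exposes the support vectors, dual
coefficients, and biases so the dual-feasibility box constraint
``|alpha_i y_i| <= C`` can be audited.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import ndimage
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVC

from .chanvese import CVParams, CVResult, segment_cv
from .errors import StratificationError, TrainingError
from .glcm import TextureConfig, feature_map
from .phantom import LabeledImage

TISSUE_CLASSES = (1, 2, 3)  # csf, gm, wm


@dataclass(frozen=True)
class KernelParams:
    """Gaussian kernel width and soft-margin penalty."""

    sigma: float = 0.5
    c: float = 1000.0

    def validate(self) -> None:
        if self.sigma <= 0 or self.c <= 0:
            raise ValueError("sigma and c must be positive")

    @property
    def gamma(self) -> float:
        """scikit-learn's ``gamma`` equivalent of ``1 / (2 sigma^2)``."""
        return 1.0 / (2.0 * self.sigma ** 2)


@dataclass
class TrainingSet:
    """Stratified, z-scored training pixels."""

    features: np.ndarray       # (n, n_features), already z-scored
    labels: np.ndarray         # (n,) tissue codes
    mean: np.ndarray           # per-feature mean of the raw sample
    sd: np.ndarray             # per-feature SD of the raw sample
    indices: np.ndarray        # (n, 2) source pixel coordinates

    @property
    def n(self) -> int:
        return self.features.shape[0]


@dataclass
class SVMModel:
    """Fitted one-vs-one Gaussian-kernel SVM plus feature standardization."""

    svc: SVC
    kernel: KernelParams
    mean: np.ndarray
    sd: np.ndarray

    @property
    def classes(self) -> np.ndarray:
        return self.svc.classes_

    @property
    def support_vectors(self) -> np.ndarray:
        return self.svc.support_vectors_

    @property
    def dual_coef(self) -> np.ndarray:
        """Signed dual coefficients ``alpha_i y_i`` (bounded by C)."""
        return self.svc.dual_coef_

    @property
    def intercepts(self) -> np.ndarray:
        return self.svc.intercept_

    def pairwise_margins(self, x: np.ndarray) -> np.ndarray:
        """(n, n_pairs) signed margins, pairs ordered (0,1), (0,2), ..."""
        df = self.svc.decision_function(np.atleast_2d(x))
        if df.ndim == 1:
            df = df[:, None]
        return df


@dataclass
class TissueLabelMap:
    """Per-pixel tissue codes and the stage that assigned each pixel."""

    labels: np.ndarray
    provenance: np.ndarray     # 0 = contour stage (outside), 1 = SVM
    cv_result: CVResult | None = None


def gaussian_kernel(x: np.ndarray, x_prime: np.ndarray, sigma: float) -> float:
    """``exp(-||x - x'||^2 / (2 sigma^2))``; symmetric, in (0, 1]."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    a = np.asarray(x, dtype=float).ravel()
    b = np.asarray(x_prime, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"vector lengths differ: {a.shape} vs {b.shape}")
    return float(np.exp(-np.sum((a - b) ** 2) / (2.0 * sigma ** 2)))


def gram_matrix(x: np.ndarray, sigma: float) -> np.ndarray:
    """Kernel Gram matrix of a sample (symmetric PSD by construction)."""
    x = np.asarray(x, dtype=float)
    sq = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-sq / (2.0 * sigma ** 2))


def _allocate(n: int, counts: dict[int, int]) -> dict[int, int]:
    """Proportional allocation with largest remainders, min 2 per class."""
    total = sum(counts.values())
    exact = {k: n * v / total for k, v in counts.items()}
    alloc = {k: int(np.floor(e)) for k, e in exact.items()}
    leftover = n - sum(alloc.values())
    for k in sorted(exact, key=lambda k: exact[k] - alloc[k], reverse=True):
        if leftover <= 0:
            break
        alloc[k] += 1
        leftover -= 1
    for k in alloc:  # guarantee the every-class-twice invariant
        while alloc[k] < min(2, counts[k]):
            donor = max(alloc, key=lambda q: alloc[q])
            alloc[donor] -= 1
            alloc[k] += 1
    for k in alloc:  # never request more than available
        if alloc[k] > counts[k]:
            surplus = alloc[k] - counts[k]
            alloc[k] = counts[k]
            for q in sorted(alloc, key=lambda q: counts[q] - alloc[q],
                            reverse=True):
                room = counts[q] - alloc[q]
                take = min(room, surplus)
                alloc[q] += take
                surplus -= take
                if surplus == 0:
                    break
    return alloc


def sample_training_pixels(image: LabeledImage, mask: np.ndarray,
                           features: np.ndarray, n: int,
                           seed: int) -> TrainingSet:
    """Seeded stratified sample of ``n`` tissue pixels inside ``mask``.

    Features are z-scored with the sample's own statistics, which are
    stored for reuse at prediction time. Raises
    :class:`StratificationError` when a tissue class is absent inside
    the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = image.labels
    tissue_names = {1: "csf", 2: "gm", 3: "wm"}
    counts = {}
    coords = {}
    for cls in TISSUE_CLASSES:
        rows, cols = np.nonzero(mask & (labels == cls))
        if rows.size == 0:
            raise StratificationError(
                f"tissue class '{tissue_names[cls]}' absent inside the mask")
        counts[cls] = rows.size
        coords[cls] = np.stack([rows, cols], axis=1)
    if sum(counts.values()) < n:
        raise StratificationError(
            f"mask holds only {sum(counts.values())} tissue pixels, "
            f"fewer than the requested {n}")

    rng = np.random.default_rng(seed)
    alloc = _allocate(n, counts)
    picked = []
    lab = []
    for cls in TISSUE_CLASSES:
        idx = rng.choice(counts[cls], size=alloc[cls], replace=False)
        picked.append(coords[cls][np.sort(idx)])
        lab.append(np.full(alloc[cls], cls))
    indices = np.concatenate(picked)
    lab = np.concatenate(lab)

    raw = features[indices[:, 0], indices[:, 1]]
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return TrainingSet(features=(raw - mean) / sd, labels=lab,
                       mean=mean, sd=sd, indices=indices)


def train_svm(train: TrainingSet, kernel: KernelParams | None = None,
              tol: float = 1e-3, max_iter: int = 100_000) -> SVMModel:
    """Fit the one-vs-one Gaussian-kernel SVM on a training set.

    Raises :class:`TrainingError` if libsvm's SMO loop hits the
    iteration cap before meeting the convergence tolerance.
    """
    kernel = kernel or KernelParams()
    kernel.validate()
    classes, cls_counts = np.unique(train.labels, return_counts=True)
    if classes.size < 2 or cls_counts.min() < 2:
        raise StratificationError(
            "training set needs >= 2 classes, each present at least twice")
    svc = SVC(C=kernel.c, kernel="rbf", gamma=kernel.gamma, tol=tol,
              max_iter=max_iter, decision_function_shape="ovo")
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            svc.fit(train.features, train.labels)
        except ConvergenceWarning as exc:
            raise TrainingError(
                f"SMO did not converge within {max_iter} iterations "
                f"(tol={tol}): {exc}") from exc
    return SVMModel(svc=svc, kernel=kernel, mean=train.mean, sd=train.sd)


def predict(model: SVMModel, features: np.ndarray,
            mask: np.ndarray | None = None) -> np.ndarray:
    """One-vs-one majority vote per pixel; ties broken by margin sums.

    ``features`` may be an ``(H, W, F)`` stack (returns a label grid,
    zeros outside ``mask``) or an ``(n, F)`` matrix (returns a vector).
    """
    feats = np.asarray(features, dtype=float)
    grid = feats.ndim == 3
    if grid:
        h, w, nf = feats.shape
        mask = np.ones((h, w), dtype=bool) if mask is None \
            else np.asarray(mask, dtype=bool)
        x = feats[mask]
    else:
        x = feats
    if x.shape[-1] != model.mean.shape[0]:
        raise ValueError(
            f"feature dimension {x.shape[-1]} does not match the "
            f"{model.mean.shape[0]} training dimensions")
    if x.size == 0:
        pred = np.empty(0, dtype=int)
    else:
        z = (x - model.mean) / model.sd
        pred = _ovo_vote(model, z)
    if not grid:
        return pred
    out = np.zeros((h, w), dtype=int)
    out[mask] = pred
    return out


def _ovo_vote(model: SVMModel, z: np.ndarray) -> np.ndarray:
    classes = model.classes
    margins = model.pairwise_margins(z)
    n = z.shape[0]
    votes = np.zeros((n, classes.size))
    margin_sum = np.zeros((n, classes.size))
    # sign convention: in the multiclass ovo decision a positive margin
    # favors the first class of the (a, b) pair; the binary special case
    # flips it (positive predicts classes_[1])
    sign = -1.0 if classes.size == 2 else 1.0
    for col, (a, b) in enumerate(combinations(range(classes.size), 2)):
        m = sign * margins[:, col]
        first_wins = m > 0
        votes[first_wins, a] += 1
        votes[~first_wins, b] += 1
        margin_sum[:, a] += m
        margin_sum[:, b] -= m
    # lexicographic argmax: votes first, summed margins as tie-break
    order = votes + (np.tanh(margin_sum) + 1.0) / (2.0 * (len(classes) + 1))
    return classes[np.argmax(order, axis=1)]


def build_feature_stack(image: np.ndarray,
                        config: TextureConfig | None = None) -> np.ndarray:
    """Texture features, windowed mean, and raw intensity (22 channels)."""
    config = config or TextureConfig()
    img = np.asarray(image, dtype=float)
    textures = feature_map(img, config)
    mean_int = ndimage.uniform_filter(img, size=config.window, mode="reflect")
    return np.concatenate(
        [textures, mean_int[:, :, None], img[:, :, None]], axis=2)


def csvm_segment(image: LabeledImage | np.ndarray,
                 cv_params: CVParams | None = None,
                 texture_config: TextureConfig | None = None,
                 kernel: KernelParams | None = None,
                 n_train: int = 1500, seed: int = 0,
                 train_labels: np.ndarray | None = None) -> TissueLabelMap:
    """Full C-SVM segmentation: contour gate, then SVM tissue labels.

    Training labels default to the phantom's own ground truth; for real
    images supply a (possibly partial) ``train_labels`` map with tissue
    codes on the pixels to learn from. Pixels outside the contour are
    labeled background and attributed to the contour stage.
    """
    if isinstance(image, LabeledImage):
        intensity = image.intensity
        if train_labels is None:
            train_labels = image.labels
    else:
        intensity = np.asarray(image, dtype=float)
        if train_labels is None:
            raise ValueError("train_labels required for a bare intensity grid")
    labeled = LabeledImage(intensity=intensity,
                           labels=np.asarray(train_labels, dtype=int))

    cv = segment_cv(intensity, cv_params)
    feats = build_feature_stack(intensity, texture_config)
    train = sample_training_pixels(labeled, cv.inside_mask, feats,
                                   n_train, seed)
    model = train_svm(train, kernel)
    labels = predict(model, feats, cv.inside_mask)
    provenance = cv.inside_mask.astype(int)
    return TissueLabelMap(labels=labels, provenance=provenance, cv_result=cv)
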