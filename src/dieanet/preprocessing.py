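"""Histopathology preprocessing: stain normalization, cropping, QC, fold assignment.

The stain pipeline follows the sparse-NMF stain-separation approach: pixels
are mapped to optical density (Beer–Lambert), a 2-atom nonnegative sparse
dictionary is learned whose atoms are the hematoxylin and eosin color
vectors, per-pixel stain concentrations are fitted by nonnegative least
squares, rescaled to a reference image's 99th-percentile intensities and
recomposed under the reference basis.

Patches are harvested by seeded uniform random cropping and filtered by the
blank rule: a patch is discarded when more than 75% of its pixels are
background-white.  Cross-validation folds are assigned at case (patient)
level, stratified by grade, so no case contributes to both the training and
the validation side of a fold.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from sklearn.decomposition import MiniBatchDictionaryLearning
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "GRADES", "CaseRecord", "StainBasis", "PatchRecord",
    "InsufficientTissueError", "DegenerateStainError",
    "rgb_to_od", "od_to_rgb", "estimate_stain_basis", "normalize_stain",
    "random_crops", "blank_fraction", "assign_folds", "preprocess_dataset",
    "load_manifest",
]

GRADES = ("low", "intermediate", "high")


class InsufficientTissueError(ValueError):
    """Raised when an image has too few non-background pixels to fit stains."""


class DegenerateStainError(ValueError):
    """Raised when the two learned stain atoms are degenerate (single-stain image)."""


@dataclass
class CaseRecord:
    case_id: str
    grade: str
    image_paths: list

    def __post_init__(self):
        if self.grade not in GRADES:
            raise ValueError(f"grade must be one of {GRADES}, got {self.grade!r}")
        if len(self.image_paths) < 1:
            raise ValueError("a case needs at least one image")


@dataclass
class StainBasis:
    """Columns of W are the hematoxylin and eosin optical-density vectors
    (unit L2 norm, nonnegative); conc_p99 holds the fitted 99th-percentile
    concentration per stain of the image the basis came from."""

    W: np.ndarray                       # 3x2
    conc_p99: np.ndarray | None = None  # length 2

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (3, 2):
            raise ValueError(f"W must be 3x2, got {self.W.shape}")
        if (self.W < -1e-12).any():
            raise ValueError("stain vectors must be nonnegative")
        norms = np.linalg.norm(self.W, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError(f"stain columns must be unit L2 norm, got {norms}")


@dataclass
class PatchRecord:
    pixels: np.ndarray                  # size x size x 3 uint8
    case_id: str
    grade: str
    fold: int
    blank_fraction: float
    qc_pass: bool
    patch_path: str = ""


# --------------------------------------------------------------------------
# optical density
# --------------------------------------------------------------------------

def rgb_to_od(image: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Beer–Lambert transform OD = -log10(I/I0), intensities clipped at 1."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB image (H,W,3), got shape {image.shape}")
    i = np.clip(image.astype(float), 1.0, i0)
    return -np.log10(i / i0)


def od_to_rgb(od: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Inverse Beer–Lambert, rounded to uint8."""
    i = i0 * np.power(10.0, -np.asarray(od, dtype=float))
    return np.clip(np.round(i), 0, 255).astype(np.uint8)


# --------------------------------------------------------------------------
# stain basis estimation and normalization
# --------------------------------------------------------------------------

def _tissue_od(image: np.ndarray, od_threshold: float) -> np.ndarray:
    od = rgb_to_od(image).reshape(-1, 3)
    return od[np.linalg.norm(od, axis=1) > od_threshold]


def estimate_stain_basis(image: np.ndarray, sparsity: float = 0.1, seed: int = 0,
                         od_threshold: float = 0.15, min_tissue: int = 1000,
                         max_pixels: int = 10000) -> StainBasis:
    """Learn the 2-stain optical-density basis by sparse nonnegative dictionary
    learning on tissue pixels.

    Columns are unit-normalized and ordered hematoxylin first (the more
    blue-appearing stain, i.e. the larger red-absorbing OD component).
    """
    od = _tissue_od(image, od_threshold)
    if od.shape[0] < min_tissue:
        raise InsufficientTissueError(
            f"only {od.shape[0]} tissue pixels above OD {od_threshold} "
            f"(need >= {min_tissue}) — image is (near-)blank")
    rng = np.random.default_rng(seed)
    if od.shape[0] > max_pixels:
        od = od[rng.choice(od.shape[0], max_pixels, replace=False)]
    dl = MiniBatchDictionaryLearning(
        n_components=2, alpha=sparsity, positive_code=True, positive_dict=True,
        fit_algorithm="cd", transform_algorithm="lasso_cd", batch_size=256,
        max_iter=60, transform_max_iter=2000, random_state=seed)
    dl.fit(od)
    W = dl.components_.T                                 # 3x2, columns = stains
    norms = np.linalg.norm(W, axis=0)
    if norms.min() < 1e-8:
        raise DegenerateStainError("second stain atom collapsed to zero "
                                   "(single-stain image?)")
    W = W / norms
    cos = float(W[:, 0] @ W[:, 1])
    if cos > 0.995:
        raise DegenerateStainError(
            f"learned stain vectors are nearly parallel (cos={cos:.4f}) — "
            "the image does not support a two-stain separation")
    if W[0, 0] < W[0, 1]:                                # hematoxylin first
        W = W[:, ::-1]
    basis = StainBasis(W=W)
    conc = fit_concentrations(od, basis)
    basis.conc_p99 = np.percentile(conc, 99, axis=0)
    return basis


def fit_concentrations(od_pixels: np.ndarray, basis: StainBasis) -> np.ndarray:
    """Nonnegative least-squares stain concentrations for OD pixel rows.

    With only two stains the NNLS has a closed-form case analysis: take the
    unconstrained normal-equation solution; if a coordinate is negative,
    clamp it to zero and refit the other stain alone.
    """
    W = basis.W
    G = W.T @ W                                          # 2x2 Gram
    b = od_pixels @ W                                    # n x 2
    det = G[0, 0] * G[1, 1] - G[0, 1] ** 2
    c0 = (G[1, 1] * b[:, 0] - G[0, 1] * b[:, 1]) / det
    c1 = (G[0, 0] * b[:, 1] - G[0, 1] * b[:, 0]) / det
    c = np.stack([c0, c1], axis=1)
    neg0, neg1 = c[:, 0] < 0, c[:, 1] < 0
    c[neg0, 0] = 0.0
    c[neg0, 1] = np.maximum(b[neg0, 1] / G[1, 1], 0.0)
    c[neg1 & ~neg0, 1] = 0.0
    c[neg1 & ~neg0, 0] = np.maximum(b[neg1 & ~neg0, 0] / G[0, 0], 0.0)
    return c


def normalize_stain(image: np.ndarray, source: StainBasis,
                    target: StainBasis) -> np.ndarray:
    """Map an image from its own stain characteristics onto the target's.

    Concentrations are fitted under the source basis, each stain channel is
    rescaled so its 99th percentile matches the target's, and the image is
    recomposed under the target basis.
    """
    od = rgb_to_od(image)
    shape = od.shape
    conc = fit_concentrations(od.reshape(-1, 3), source)
    if source.conc_p99 is not None and target.conc_p99 is not None:
        scale = target.conc_p99 / np.maximum(source.conc_p99, 1e-8)
        conc = conc * scale
    od_new = (conc @ target.W.T).reshape(shape)
    return od_to_rgb(od_new)


# --------------------------------------------------------------------------
# cropping and QC
# --------------------------------------------------------------------------

def random_crops(image: np.ndarray, n: int = 3, size: int = 256,
                 seed: int = 0) -> list[np.ndarray]:
    """n random size×size crops at uniform offsets, reproducible under seed."""
    h, w = image.shape[:2]
    if h < size or w < size:
        raise ValueError(f"image {h}×{w} is smaller than the crop size {size}")
    rng = np.random.default_rng(seed)
    crops = []
    for _ in range(n):
        top = int(rng.integers(0, h - size + 1))
        left = int(rng.integers(0, w - size + 1))
        crops.append(image[top:top + size, left:left + size].copy())
    return crops


def blank_fraction(patch: np.ndarray, white_threshold: int = 220) -> float:
    """Fraction of pixels whose every channel is >= white_threshold."""
    patch = np.asarray(patch)
    return float((patch.min(axis=2) >= white_threshold).mean())


def qc_pass(frac: float, max_blank: float = 0.75) -> bool:
    """A patch passes QC unless blank pixels exceed 75% of its area
    (strictly more than — a patch at exactly the threshold is kept)."""
    return frac <= max_blank


# --------------------------------------------------------------------------
# fold assignment
# --------------------------------------------------------------------------

def assign_folds(cases: list[CaseRecord], k: int = 5, seed: int = 0) -> dict[str, int]:
    """Case-level grade-stratified k-fold assignment: {case_id: fold}."""
    grades = [c.grade for c in cases]
    for g in set(grades):
        if grades.count(g) < k:
            raise ValueError(f"grade {g!r} has {grades.count(g)} cases, fewer "
                             f"than k={k} folds")
    ids = [c.case_id for c in cases]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate case ids")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = {}
    for fold, (_, test_idx) in enumerate(skf.split(ids, grades)):
        for i in test_idx:
            fold_of[ids[i]] = fold
    return fold_of


# --------------------------------------------------------------------------
# end-to-end preprocessing
# --------------------------------------------------------------------------

def _load_rgb(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def preprocess_dataset(cases: list[CaseRecord], out_dir, crops_per_image: int = 3,
                       size: int = 256, seed: int = 17, k: int = 5,
                       normalize: bool = True, target_image=None,
                       white_threshold: int = 220, max_blank: float = 0.75,
                       stain_seed: int = 0) -> pd.DataFrame:
    """Run the full stage-1 pipeline and write patches plus a manifest CSV.

    Per source image: stain-normalize (against the first image with
    sufficient tissue, or an explicit ``target_image`` path), take
    ``crops_per_image`` random crops, compute blank fractions and QC flags.
    Folds are assigned per case before cropping.  Returns the manifest (one
    row per kept patch; QC failures are dropped but counted in the CSV's
    companion columns).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fold_of = assign_folds(cases, k=k, seed=seed)

    target_basis = None
    if normalize:
        if target_image is not None:
            target_basis = estimate_stain_basis(_load_rgb(target_image), seed=stain_seed)
        else:
            for c in cases:
                for p in c.image_paths:
                    try:
                        target_basis = estimate_stain_basis(_load_rgb(p), seed=stain_seed)
                        break
                    except (InsufficientTissueError, DegenerateStainError):
                        continue
                if target_basis is not None:
                    break
            if target_basis is None:
                raise InsufficientTissueError("no image with sufficient tissue "
                                              "to serve as normalization target")

    rows = []
    for c in cases:
        for img_i, path in enumerate(c.image_paths):
            img = _load_rgb(path)
            if normalize:
                try:
                    src = estimate_stain_basis(img, seed=stain_seed)
                    img = normalize_stain(img, src, target_basis)
                except (InsufficientTissueError, DegenerateStainError):
                    pass                       # keep near-blank images unnormalized
            crop_seed = (seed * 100003
                         + zlib.crc32(f"{c.case_id}/{img_i}".encode())) % (2 ** 31)
            for p_i, patch in enumerate(random_crops(img, crops_per_image, size,
                                                     seed=crop_seed)):
                frac = blank_fraction(patch, white_threshold)
                ok = qc_pass(frac, max_blank)
                rel = f"{c.case_id}_img{img_i}_crop{p_i}.png"
                if ok:
                    Image.fromarray(patch).save(out_dir / rel)
                rows.append({"patch_path": rel if ok else "",
                             "case_id": c.case_id, "grade": c.grade,
                             "fold": fold_of[c.case_id],
                             "blank_fraction": round(frac, 6), "qc_pass": ok})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"patch_path", "case_id", "grade", "fold", "blank_fraction", "qc_pass"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    return df
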