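"""Synthetic cohorts with the statistical structure MIL classifiers assume.

A real recurrence-risk cohort is private; this module generates stand-ins
with its two key properties: (a) severe class imbalance — default tier
priors (0.45, 0.10, 0.45) reproduce a 210-case cohort with exactly 21
medium-tier cases under stratified allocation — and (b) bag/instance
structure in which only a fraction of patches carry class signal.

Each case is a bag of instance vectors: background instances are
``Normal(0, noise_sd^2 I)``; signal instances are ``Normal(mu_c,
noise_sd^2 I)`` where ``mu_c = effect_size * u_c`` for fixed orthonormal
class directions (seeded QR), so pairwise class separations are equal. An
optional "grey zone" mode places the medium-tier mean on the segment
between the low and high means, mimicking the intermediate biology of
medium-risk cases.

Also provides toy stained-slide rasters (saturated ellipses on near-white
glass, plus sub-threshold artifact specks) with exact ground-truth masks for
segmentation tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import label_binarize

from .bags import FeatureBag


@dataclass
class SynthBagConfig:
    n_cases: int = 210
    class_priors: tuple[float, float, float] = (0.45, 0.10, 0.45)
    dim: int = 64
    bag_size_range: tuple[int, int] = (16, 64)
    signal_fraction: float = 0.3
    effect_size: float = 2.0
    noise_sd: float = 1.0
    collinear_medium: bool = False
    seed: int = 0

    def __post_init__(self):
        priors = np.asarray(self.class_priors, dtype=float)
        if priors.shape != (3,) or np.any(priors < 0) or abs(priors.sum() - 1.0) > 1e-9:
            raise ValueError("class_priors must be a length-3 simplex")
        if not 0.0 <= self.signal_fraction <= 1.0:
            raise ValueError("signal_fraction must lie in [0, 1]")
        if self.bag_size_range[0] < 1 or self.bag_size_range[0] > self.bag_size_range[1]:
            raise ValueError("bag sizes must be >= 1 and ordered")


def _stratified_counts(n: int, priors: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of n cases to tiers (ties -> lowest index)."""
    raw = n * priors
    counts = np.floor(raw).astype(int)
    frac = raw - counts
    for _ in range(n - counts.sum()):
        i = int(np.argmax(frac))
        counts[i] += 1
        frac[i] = -1.0
    return counts


def class_directions(dim: int, seed: int, effect_size: float, collinear_medium: bool) -> np.ndarray:
    """3 x dim matrix of class means mu_c = effect_size * u_c (orthonormal u_c)."""
    if dim < 3:
        raise ValueError("dim must be >= 3 for three orthogonal directions")
    rng = np.random.default_rng(seed + 1_000_003)
    q, _ = np.linalg.qr(rng.standard_normal((dim, 3)))
    mu = effect_size * q.T
    if collinear_medium:
        mu[1] = 0.5 * (mu[0] + mu[2])
    return mu


def generate_bags(config: SynthBagConfig) -> tuple[list[FeatureBag], pd.DataFrame]:
    """Generate a synthetic cohort of feature bags plus a ground-truth table."""
    rng = np.random.default_rng(config.seed)
    priors = np.asarray(config.class_priors, dtype=float)
    counts = _stratified_counts(config.n_cases, priors)
    tiers = np.repeat(np.arange(3), counts)
    rng.shuffle(tiers)

    mu = class_directions(config.dim, config.seed, config.effect_size, config.collinear_medium)
    lo, hi = config.bag_size_range
    bags: list[FeatureBag] = []
    truth_rows = []
    for i, tier in enumerate(tiers):
        n = int(rng.integers(lo, hi + 1))
        n_signal = int(round(config.signal_fraction * n))
        x = rng.normal(0.0, config.noise_sd, size=(n, config.dim))
        signal_idx = rng.choice(n, size=n_signal, replace=False)
        x[signal_idx] += mu[tier]
        # fake row-major patch grid coordinates
        cols = int(np.ceil(np.sqrt(n)))
        coords = np.array([(256 * (j % cols), 256 * (j // cols)) for j in range(n)], dtype=np.int64)
        case_id = f"synth_{i:04d}"
        bags.append(
            FeatureBag(
                case_id=case_id,
                features=x.astype(np.float32),
                coords=coords,
                tier=int(tier),
                encoder_name="synthetic",
                patch_size=256,
            )
        )
        truth_rows.append(
            {"case_id": case_id, "tier": int(tier), "bag_size": n, "n_signal": n_signal}
        )
    return bags, pd.DataFrame(truth_rows)


def generate_toy_slide(
    width: int = 512,
    height: int = 512,
    ellipses: list[tuple[tuple[float, float], tuple[float, float], tuple[int, int, int]]] | None = None,
    background: tuple[int, int, int] = (245, 243, 244),
    artifact_specks: int = 0,
    speck_radius: int = 2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a stained-tissue-like raster and its exact foreground mask.

    ``ellipses`` is a list of ((cx, cy), (a, b), rgb) in pixel units; defaults
    to one saturated pink ellipse centered on the slide. Specks are small
    saturated dots excluded from the ground-truth mask (they model detached
    staining artifacts a segmenter should drop).
    """
    if width < 64 or height < 64:
        raise ValueError("slide dims must be >= 64")
    rng = np.random.default_rng(seed)
    if ellipses is None:
        ellipses = [((width / 2, height / 2), (width * 0.3, height * 0.22), (205, 120, 160))]
    img = np.empty((height, width, 3), dtype=np.uint8)
    img[:] = background
    # mild background noise so the slide is not perfectly constant
    noise = rng.integers(-3, 4, size=(height, width, 1))
    img = np.clip(img.astype(int) + noise, 0, 255).astype(np.uint8)

    yy, xx = np.mgrid[0:height, 0:width]
    mask = np.zeros((height, width), dtype=bool)
    for (cx, cy), (a, b), color in ellipses:
        inside = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
        jitter = rng.integers(-12, 13, size=(height, width, 3))
        tissue = np.clip(np.asarray(color, dtype=int) + jitter, 0, 255).astype(np.uint8)
        img[inside] = tissue[inside]
        mask |= inside

    for _ in range(artifact_specks):
        sx = rng.integers(speck_radius, width - speck_radius)
        sy = rng.integers(speck_radius, height - speck_radius)
        speck = (xx - sx) ** 2 + (yy - sy) ** 2 <= speck_radius ** 2
        speck &= ~mask
        img[speck] = (90, 60, 170)
    return img, mask


def linear_probe_sanity(
    bags: list[FeatureBag],
    tiers: np.ndarray | None = None,
    n_splits: int = 5,
    seed: int = 0,
) -> float:
    """Macro one-vs-rest AUC of a cross-validated linear probe on mean-pooled bags.

    A generator health check: near 0.5 at zero effect size, near 1 for
    well-separated classes.
    """
    x = np.stack([b.features.mean(axis=0) for b in bags])
    y = np.asarray([b.tier for b in bags] if tiers is None else tiers)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two classes for a probe")
    probs = np.zeros((len(y), len(classes)))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(x, y):
        clf = LogisticRegression(max_iter=2000)
        clf.fit(x[train_idx], y[train_idx])
        probs[test_idx] = clf.predict_proba(x[test_idx])
    y_bin = label_binarize(y, classes=classes)
    if y_bin.shape[1] == 1:  # two classes
        return float(roc_auc_score(y, probs[:, 1]))
    return float(roc_auc_score(y_bin, probs, average="macro"))
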