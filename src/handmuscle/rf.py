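"""Random-forest voxel classifier: training, the cross-validated parameter
search, classification, and raw-mask post-processing.

Labels are binary: muscle vs background, where background is everything
except muscle (soft tissue, bone, tendons, air). Training voxels are drawn
from the hand region only. Per-node feature subsampling is fixed at
√n_features; the remaining forest parameters (number of trees, maximal
depth, minimum samples per decision node) are part of the tunable set Ƥ_RF
and selected by k-fold cross-validation maximizing the mean Dice ratio.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .config import ElbpConfig, GaborConfig, ParamSet, RfParams
from .csa import _CONN26
from .features import CHANNEL_CATALOG, FeatureTensor, extract_features
from .metrics import dice
from .volume import BinaryMask, ScalarVolume

__all__ = [
    "TrainedModel",
    "CvResult",
    "sample_training_pairs",
    "train_rf",
    "param_grid",
    "cross_validated_search",
    "classify",
    "postprocess",
    "save_model",
    "load_model",
]

_MODEL_FORMAT_VERSION = 1


@dataclass
class TrainedModel:
    """A fitted forest plus the parameter set and feature catalog it expects."""

    forest: RandomForestClassifier
    params: ParamSet
    catalog: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def check_catalog(self, features: FeatureTensor) -> None:
        if tuple(features.channels) != tuple(self.catalog):
            raise ValueError(
                "feature channel catalog mismatch: model was trained on "
                f"{self.catalog}, got {features.channels}"
            )


@dataclass
class CvResult:
    """Grid-search outcome: winning parameter set and the full score table."""

    winner: ParamSet
    winner_dice: float
    table: pd.DataFrame  # one row per grid point with its mean validation Dice


def sample_training_pairs(
    features: FeatureTensor,
    labels: BinaryMask,
    fraction: float = 1.0,
    seed: int = 0,
    hand: BinaryMask | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Random subset of the available feature-label pairs.

    Pairs come from the hand region when a hand mask is given, otherwise
    from the whole grid. ``fraction`` keeps ``floor(fraction · N)`` pairs,
    reproducibly in ``seed``. Both classes must be represented.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if labels.shape != features.grid_shape:
        raise ValueError("labels are not aligned to the feature grid")
    domain = hand.data if hand is not None else np.ones(labels.shape, dtype=bool)
    X = features.data[:, domain].T
    y = labels.data[domain].astype(np.int8)
    n = X.shape[0]
    if fraction < 1.0:
        keep = int(fraction * n)
        idx = np.random.default_rng(seed).choice(n, size=keep, replace=False)
        idx.sort()
        X, y = X[idx], y[idx]
    if np.unique(y).size < 2:
        raise ValueError("training pairs contain a single class only")
    return X, y


def train_rf(
    X: np.ndarray,
    y: np.ndarray,
    params: ParamSet,
    seed: int = 0,
    catalog: tuple[str, ...] = CHANNEL_CATALOG,
    provenance: dict | None = None,
) -> TrainedModel:
    """Fit the forest on feature-label pairs; deterministic given ``seed``."""
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if np.unique(y).size < 2:
        raise ValueError("training requires both classes")
    rf = params.rf
    forest = RandomForestClassifier(
        n_estimators=rf.n_trees,
        max_depth=rf.max_depth,
        max_features="sqrt",
        min_samples_split=rf.min_samples_split(X.shape[0]),
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return TrainedModel(forest, params, tuple(catalog), provenance or {})


def param_grid(
    n_trees=(30,),
    max_depth=(30,),
    min_samples_frac=(1e-6,),
    kernel_size=(21,),
    sigma=(1.0,),
    wavelength=(1.0,),
    radius_outer=(3.0,),
    n_samples=(8,),
) -> list[ParamSet]:
    """Cartesian product over parameter ranges, in documented key order
    (forest parameters vary slowest, ELBP parameters fastest)."""
    grid = []
    for nt, md, ms, ks, sg, wl, ro, ns in itertools.product(
        n_trees, max_depth, min_samples_frac, kernel_size, sigma, wavelength, radius_outer, n_samples
    ):
        grid.append(
            ParamSet(
                rf=RfParams(n_trees=nt, max_depth=md, min_samples_frac=ms),
                gabor=GaborConfig(kernel_size=ks, sigma=sg, wavelength=wl),
                elbp=ElbpConfig(radius_outer=ro, n_samples=ns),
            )
        )
    return grid


def _fold_split(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Shuffle once with the run seed, then cut into k near-equal folds."""
    order = np.random.default_rng(seed).permutation(n)
    return [fold for fold in np.array_split(order, k)]


def cross_validated_search(
    datasets: list[tuple[ScalarVolume, BinaryMask, BinaryMask | None]],
    grid: list[ParamSet],
    k: int = 7,
    seed: int = 0,
    train_fraction: float = 0.25,
) -> CvResult:
    """k-fold cross-validated grid search maximizing the mean Dice ratio.

    ``datasets`` holds ``(normalized volume, gold muscle mask, hand mask)``
    triples (hand may be ``None``). For every grid point the forest is
    trained on the training folds and scored by the Dice ratio of its
    segmentation of the validation fold; the parameter set with the highest
    mean validation Dice wins. Ties break toward fewer trees, then smaller
    depth (the cheaper model). Traversal order is the grid order.
    """
    if len(datasets) < k:
        raise ValueError(f"need at least k={k} datasets, got {len(datasets)}")
    if not grid:
        raise ValueError("empty parameter grid")
    folds = _fold_split(len(datasets), k, seed)
    feature_cache: dict[tuple, list[FeatureTensor]] = {}

    def features_for(ps: ParamSet) -> list[FeatureTensor]:
        key = (ps.gabor, ps.elbp)
        if key not in feature_cache:
            feature_cache[key] = [
                extract_features(vol, ps.gabor, ps.elbp, hand=hand)
                for vol, _, hand in datasets
            ]
        return feature_cache[key]

    rows = []
    best = None  # (mean_dice, n_trees, max_depth, ParamSet)
    for gi, ps in enumerate(grid):
        feats = features_for(ps)
        scores = []
        for fold in folds:
            val = set(int(i) for i in fold)
            train_idx = [i for i in range(len(datasets)) if i not in val]
            Xs, ys = [], []
            for i in train_idx:
                X, y = sample_training_pairs(
                    feats[i], datasets[i][1], train_fraction, seed=seed + i, hand=datasets[i][2]
                )
                Xs.append(X)
                ys.append(y)
            model = train_rf(np.concatenate(Xs), np.concatenate(ys), ps, seed=seed)
            for i in val:
                vol, gold, hand = datasets[i]
                pred = classify(model, feats[i], hand)
                scores.append(dice(pred, gold))
        mean_dice = float(np.mean(scores))
        rows.append(
            {
                "grid_index": gi,
                "n_trees": ps.rf.n_trees,
                "max_depth": ps.rf.max_depth,
                "min_samples_frac": ps.rf.min_samples_frac,
                "gabor_kernel": ps.gabor.kernel_size,
                "gabor_sigma": ps.gabor.sigma,
                "gabor_wavelength": ps.gabor.wavelength,
                "elbp_radius": ps.elbp.radius_outer,
                "elbp_samples": ps.elbp.n_samples,
                "mean_dice": mean_dice,
            }
        )
        key = (-mean_dice, ps.rf.n_trees, ps.rf.max_depth)
        if best is None or key < best[0]:
            best = (key, ps, mean_dice)
    table = pd.DataFrame(rows)
    return CvResult(winner=best[1], winner_dice=best[2], table=table)


def classify(
    model: TrainedModel,
    features: FeatureTensor,
    hand: BinaryMask | None = None,
) -> BinaryMask:
    """Per-voxel muscle/background classification, restricted to the hand.

    The raw muscle mask is a subset of the hand mask; an empty hand mask
    yields an empty segmentation.
    """
    model.check_catalog(features)
    shape = features.grid_shape
    out = np.zeros(shape, dtype=bool)
    domain = hand.data if hand is not None else np.ones(shape, dtype=bool)
    if domain.any():
        X = features.data[:, domain].T
        out[domain] = model.forest.predict(X).astype(bool)
    return BinaryMask(out, features.spacing, features.origin)


# in-plane 4-connected radius-1 structuring element (no extent along z:
# dilating across 3 mm slices would leak between slices)
_CROSS_2D = np.zeros((1, 3, 3), dtype=bool)
_CROSS_2D[0] = ndimage.generate_binary_structure(2, 1)


def postprocess(
    raw: BinaryMask,
    volume: ScalarVolume,
    dilation_radius: int = 1,
    min_island: int = 10,
    sigma_factor: float = 3.0,
) -> BinaryMask:
    """Clean the raw classifier output.

    Steps: morphological dilation (in-plane, radius 1) to include a wider
    area of voxels; island extraction discarding connected components
    smaller than ``min_island`` voxels; finally a Gaussian f(μ, σ) is
    fitted to the grey values of the pre-dilation mask and voxels outside
    [μ − 3σ, μ + 3σ] are excluded. Fitting on the pre-dilation mask keeps
    the fit uncontaminated by the dilation shell, so wrongly included
    voxels actually get removed; with σ = 0 (or a tiny mask) the exclusion
    step is skipped.
    """
    if not raw.data.any():
        raise ValueError("raw segmentation is empty")
    if raw.shape != volume.shape:
        raise ValueError("raw mask is not aligned to the volume")
    mask = raw.data
    if dilation_radius > 0:
        mask = ndimage.binary_dilation(mask, structure=_CROSS_2D, iterations=dilation_radius)
    labels, n = ndimage.label(mask, structure=_CONN26)
    if n:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        keep = np.flatnonzero(sizes >= min_island)
        mask = np.isin(labels, keep)
    ref_values = volume.data[raw.data]
    mu = float(ref_values.mean())
    sigma = float(ref_values.std())
    if ref_values.size >= 2 and sigma > 0:
        lo, hi = mu - sigma_factor * sigma, mu + sigma_factor * sigma
        mask &= (volume.data >= lo) & (volume.data <= hi)
    return raw.like(mask)


def save_model(model: TrainedModel, path: str) -> None:
    """Serialize forest + parameter set + channel catalog (versioned)."""
    joblib.dump(
        {
            "format_version": _MODEL_FORMAT_VERSION,
            "forest": model.forest,
            "params": model.params.to_dict(),
            "catalog": list(model.catalog),
            "provenance": model.provenance,
        },
        path,
    )


def load_model(path: str) -> TrainedModel:
    blob = joblib.load(path)
    if blob.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model file version {blob.get('format_version')!r}")
    return TrainedModel(
        forest=blob["forest"],
        params=ParamSet.from_dict(blob["params"]),
        catalog=tuple(blob["catalog"]),
        provenance=blob.get("provenance", {}),
    )
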