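"""Synthetic paired T1/Dixon hand-like phantoms with ground-truth masks.

The phantom is not anatomically realistic; it reproduces the statistical
structure the pipeline relies on:

* background ≈ 10 vs hand tissue ≈ 500 intensity units (CSA thresholding),
* a bimodal in-hand histogram with a sharp cortical-bone peak and a sharp
  muscle peak on top of a broad soft-tissue hump (peak-based normalization),
* muscle regions whose cross-sectional area tapers towards the first and
  last slices, as real hand muscle does at the VOI boundaries,
* an optional smooth multiplicative bias field,
* a Dixon fat/water pair that is exactly consistent with a known per-voxel
  fat-fraction map.

Each slice is a hand-shaped ellipse containing circular "bone" inclusions
and elliptical "muscle" blobs, varying smoothly along z. Everything is
deterministic given the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import BinaryMask, ScalarVolume, VoiSpec

__all__ = [
    "PhantomSpec",
    "make_t1_phantom",
    "make_dixon_phantom",
    "make_operator_variants",
    "OperatorVariant",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic hand volume.

    Intensity levels follow the study conditions: background around 10 and
    hand tissue around 500 units after bias correction; the cortical-bone
    and muscle levels form the two resolvable histogram peaks used for
    normalization. ``bias_amplitude`` is multiplicative, 1.0 meaning no
    bias and e.g. 1.3 a ±30% smooth field. ``noise_sd`` is global additive
    Gaussian noise; ``tissue_noise_sd`` is extra texture confined to the
    unstructured soft tissue (clipped at 3σ so the hand stays bright).
    """

    shape: tuple[int, int, int] = (16, 96, 96)  # (nz, ny, nx)
    spacing: tuple[float, float, float] = (0.5, 0.5, 3.0)
    background: float = 10.0
    soft_tissue: float = 510.0
    muscle: float = 450.0
    cortical_bone: float = 420.0
    muscle_fraction: float = 0.25
    n_bones: int = 4
    bone_radius_frac: float = 0.16
    tissue_noise_sd: float = 15.0
    noise_sd: float = 4.0
    bias_amplitude: float = 1.0
    ff_base: float = 150.0         # ‰ at the left edge of the muscle
    ff_gradient: float = 100.0     # ‰ increase across the grid in x
    ff_soft_tissue: float = 400.0  # ‰ in non-muscle hand tissue
    dixon_signal: float = 500.0
    dixon_background: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 4 for n in self.shape):
            raise ValueError("phantom grid too small")
        if not 0 <= self.muscle_fraction < 0.8:
            raise ValueError("muscle_fraction must be in [0, 0.8)")
        if self.bias_amplitude < 1.0:
            raise ValueError("bias_amplitude is multiplicative; use ≥ 1.0")


def _hand_axes(spec: PhantomSpec, z: int) -> tuple[float, float]:
    nz = spec.shape[0]
    zn = (z + 0.5) / nz
    wobble = 1.0 + 0.06 * np.sin(np.pi * zn)
    a = 0.40 * spec.shape[2] * wobble  # x semi-axis, pixels
    b = 0.33 * spec.shape[1] * wobble
    return a, b


def _grids(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, float, float]:
    ny, nx = spec.shape[1], spec.shape[2]
    Y, X = np.mgrid[0:ny, 0:nx].astype(float)
    return Y, X, (ny - 1) / 2.0, (nx - 1) / 2.0


def _hand_slice(spec: PhantomSpec, z: int) -> np.ndarray:
    Y, X, cy, cx = _grids(spec)
    a, b = _hand_axes(spec, z)
    return ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 <= 1.0


# muscle blobs and bones sit on interleaved three-fold star patterns:
# their angular structure (a cos 3φ harmonic) is deliberately not
# representable by the low-order fields bias correction removes
_MUSCLE_ANGLES = (np.pi / 2, np.pi / 2 + 2 * np.pi / 3, np.pi / 2 + 4 * np.pi / 3)
_BONE_ANGLES = (np.pi / 6 + np.pi, np.pi / 6, np.pi / 6 + 2 * np.pi / 3 + np.pi / 12)


def _muscle_centers(spec: PhantomSpec) -> list[tuple[float, float, float, float]]:
    """(cx, cy, ax, ay) of the muscle blobs at unit scale, in pixels."""
    _, _, cy, cx = _grids(spec)
    a0, b0 = _hand_axes(spec, spec.shape[0] // 2)
    out = []
    for ang in _MUSCLE_ANGLES:
        mx = cx + 0.45 * a0 * np.cos(ang)
        my = cy + 0.45 * b0 * np.sin(ang)
        out.append((mx, my, 0.26 * a0, 0.26 * b0))
    return out


def _muscle_slice(spec: PhantomSpec, hand: np.ndarray, scale: float) -> np.ndarray:
    if scale <= 0:
        return np.zeros_like(hand)
    Y, X, _, _ = _grids(spec)
    m = np.zeros_like(hand)
    for mx, my, ax, ay in _muscle_centers(spec):
        m |= ((X - mx) / (scale * ax)) ** 2 + ((Y - my) / (scale * ay)) ** 2 <= 1.0
    return m & hand


def _bone_slice(spec: PhantomSpec, z: int, hand: np.ndarray) -> np.ndarray:
    Y, X, cy, cx = _grids(spec)
    a, b = _hand_axes(spec, z)
    zn = (z + 0.5) / spec.shape[0]
    rb = spec.bone_radius_frac * min(a, b)
    bone = np.zeros_like(hand)
    for j in range(spec.n_bones):
        ang = _BONE_ANGLES[j % len(_BONE_ANGLES)] + 0.1 * np.sin(np.pi * zn)
        ring = 0.62 if j < len(_BONE_ANGLES) else 0.30
        bx = cx + ring * a * np.cos(ang)
        by = cy + ring * b * np.sin(ang)
        bone |= (X - bx) ** 2 + (Y - by) ** 2 <= rb**2
    return bone & hand


def _taper(spec: PhantomSpec) -> np.ndarray:
    """Muscle area weight per slice: near-zero at both ends of the stack."""
    nz = spec.shape[0]
    z = np.arange(nz)
    return np.sin(np.pi * (z + 0.5) / nz) ** 2


def _solve_muscle_masks(spec: PhantomSpec, hands: list[np.ndarray]) -> list[np.ndarray]:
    """Per-slice bisection on the blob scale to hit the target muscle area."""
    areas = np.array([h.sum() for h in hands], dtype=float)
    w = _taper(spec) * areas
    total_target = spec.muscle_fraction * areas.sum()
    targets = total_target * w / w.sum() if w.sum() > 0 else np.zeros_like(w)
    out = []
    for hand, target in zip(hands, targets):
        if target < 1:
            out.append(np.zeros_like(hand))
            continue
        lo, hi = 0.0, 3.0
        for _ in range(30):
            mid = 0.5 * (lo + hi)
            if _muscle_slice(spec, hand, mid).sum() < target:
                lo = mid
            else:
                hi = mid
        out.append(_muscle_slice(spec, hand, hi))
    return out


def _bias_field(spec: PhantomSpec) -> np.ndarray:
    """Smooth multiplicative field, a low-order polynomial in [2−a, a]."""
    nz, ny, nx = spec.shape
    z = np.linspace(-1, 1, nz)[:, None, None]
    y = np.linspace(-1, 1, ny)[None, :, None]
    x = np.linspace(-1, 1, nx)[None, None, :]
    u = 0.6 * x + 0.3 * y + 0.2 * z + 0.4 * x * y - 0.3 * x * x
    u = u / np.max(np.abs(u))
    return 1.0 + (spec.bias_amplitude - 1.0) * u


def make_t1_phantom(
    spec: PhantomSpec,
) -> tuple[ScalarVolume, BinaryMask, BinaryMask]:
    """Build the T1-weighted phantom and its ground-truth CSA / muscle masks.

    Returns ``(t1, csa_truth, muscle_truth)``. The hand is the single
    largest bright component; the in-hand histogram has a cortical-bone
    peak and a muscle peak; the bias field (if any) is multiplicative.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    hands = [_hand_slice(spec, z) for z in range(nz)]
    if not any(h.any() for h in hands):
        raise ValueError("degenerate phantom spec: empty hand region")
    muscles = _solve_muscle_masks(spec, hands)
    data = np.empty(spec.shape, dtype=np.float64)
    csa = np.zeros(spec.shape, dtype=bool)
    mus = np.zeros(spec.shape, dtype=bool)
    for z in range(nz):
        hand, muscle = hands[z], muscles[z]
        bone = _bone_slice(spec, z, hand) & ~muscle
        other = hand & ~muscle & ~bone
        sl = np.full((ny, nx), spec.background)
        sl[other] = spec.soft_tissue
        sl[bone] = spec.cortical_bone
        sl[muscle] = spec.muscle
        if spec.tissue_noise_sd > 0:
            tex = rng.normal(0.0, spec.tissue_noise_sd, size=int(other.sum()))
            np.clip(tex, -3 * spec.tissue_noise_sd, 3 * spec.tissue_noise_sd, out=tex)
            sl[other] += tex
        data[z] = sl
        csa[z] = hand
        mus[z] = muscle
    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)
    if spec.bias_amplitude != 1.0:
        data *= _bias_field(spec)
    vol = ScalarVolume(data, spec.spacing)
    return (
        vol,
        BinaryMask(csa, spec.spacing),
        BinaryMask(mus, spec.spacing),
    )


def make_dixon_phantom(
    spec: PhantomSpec, muscle_truth: BinaryMask
) -> tuple[ScalarVolume, ScalarVolume, ScalarVolume]:
    """Build a Dixon fat/water pair consistent with a known fat-fraction map.

    Muscle carries ``ff_base`` plus a linear left-to-right gradient; other
    hand tissue carries ``ff_soft_tissue``; background is fat-free. By
    construction ``fat / (fat + water) * 1000`` recovers the returned
    ``ff_truth`` exactly up to float rounding.
    """
    if muscle_truth.shape != spec.shape:
        raise ValueError("muscle_truth geometry does not match the phantom spec")
    nz, ny, nx = spec.shape
    hand = np.stack([_hand_slice(spec, z) for z in range(nz)])
    muscle = muscle_truth.data
    xn = np.arange(nx, dtype=float)[None, None, :] / max(nx - 1, 1)
    ff = np.zeros(spec.shape, dtype=np.float64)
    ff[hand] = spec.ff_soft_tissue
    ff_mus = np.broadcast_to(spec.ff_base + spec.ff_gradient * xn, spec.shape)
    ff[muscle] = ff_mus[muscle]
    np.clip(ff, 0.0, 1000.0, out=ff)
    signal = np.where(hand, spec.dixon_signal, spec.dixon_background)
    fat = signal * ff / 1000.0
    water = signal * (1.0 - ff / 1000.0)
    sp = spec.spacing
    return ScalarVolume(fat, sp), ScalarVolume(water, sp), ScalarVolume(ff, sp)


@dataclass(frozen=True)
class OperatorVariant:
    """One simulated operator reanalysis: a jittered VOI and an edited mask."""

    voi: VoiSpec
    muscle: BinaryMask


def make_operator_variants(
    muscle_truth: BinaryMask,
    voi: VoiSpec,
    n: int,
    seed: int = 0,
    voi_jitter: int = 1,
    edit_fraction: float = 0.02,
) -> list[OperatorVariant]:
    """Simulate ``n`` operator reanalyses of the same dataset.

    Operator variability is modeled as occasional ±``voi_jitter`` slice
    misplacements of each VOI boundary (each boundary moves with
    probability 1/3, mirroring that operators usually agree on the
    delimiting slice) and removal of a small random fraction of mask
    surface voxels (operators mostly delete wrongly included voxels).
    Zero amplitudes give identical repeats; output is deterministic in
    ``seed``.
    """
    if n < 2:
        raise ValueError("precision analysis needs at least 2 repeats")
    voi.validate_for(muscle_truth.shape[0])
    rng = np.random.default_rng(seed)
    from scipy import ndimage

    surface = muscle_truth.data & ~ndimage.binary_erosion(muscle_truth.data)
    surf_idx = np.flatnonzero(surface.ravel())
    jitter_choices = [-voi_jitter, 0, voi_jitter] if voi_jitter else [0]
    jitter_probs = [1.0 / 6, 2.0 / 3, 1.0 / 6] if voi_jitter else [1.0]
    out = []
    nz = muscle_truth.shape[0]
    for _ in range(n):
        z0 = voi.z_start + int(rng.choice(jitter_choices, p=jitter_probs))
        z1 = voi.z_end + int(rng.choice(jitter_choices, p=jitter_probs))
        z0 = int(np.clip(z0, 0, nz - 1))
        z1 = int(np.clip(z1, z0, nz - 1))
        edited = muscle_truth.data.copy()
        k = int(round(edit_fraction * surf_idx.size))
        if k > 0:
            drop = rng.choice(surf_idx, size=k, replace=False)
            edited.ravel()[drop] = False
        out.append(OperatorVariant(VoiSpec(z0, z1), muscle_truth.like(edited)))
    return out
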