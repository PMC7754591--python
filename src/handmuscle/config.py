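"""Tunable pipeline parameters Ƥ = Ƥ_RF ∪ Ƥ_GF ∪ Ƥ_ELBP plus plumbing.

Defaults are the optimal parameter set found by the cross-validated training
(30 trees, depth 30, 0.0001% samples per node; 21×21 Gabor kernel, σ = 1 mm,
λ = 1 mm; ELBP radius 3 with inner radius 1.5 and 8 samples).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import yaml

__all__ = ["ElbpConfig", "GaborConfig", "RfParams", "ParamSet", "PipelineConfig"]


@dataclass(frozen=True)
class ElbpConfig:
    """Extended local binary pattern sampling geometry.

    ``radius_outer`` is the first circle radius r (pixels); the inner circle
    is fixed at r/2. ``n_samples`` points are placed equidistantly in angle.
    """

    radius_outer: float = 3.0
    n_samples: int = 8

    def __post_init__(self) -> None:
        if self.radius_outer <= 0:
            raise ValueError("ELBP radius must be positive")
        if self.n_samples < 4:
            raise ValueError("ELBP needs at least 4 circle samples")

    @property
    def radius_inner(self) -> float:
        return self.radius_outer / 2.0


@dataclass(frozen=True)
class GaborConfig:
    """Gabor filter bank: square kernel, Gaussian σ and sinusoid wavelength in
    mm, four fixed in-plane orientations."""

    kernel_size: int = 21
    sigma: float = 1.0
    wavelength: float = 1.0
    orientations_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)

    def __post_init__(self) -> None:
        if self.kernel_size < 3:
            raise ValueError("Gabor kernel must be at least 3 pixels")
        if self.sigma <= 0 or self.wavelength <= 0:
            raise ValueError("Gabor sigma and wavelength must be positive")
        if len(self.orientations_deg) != 4:
            raise ValueError("the bank uses exactly 4 orientations")

    @property
    def kernel_size_odd(self) -> int:
        """Configured size rounded up to odd so the kernel has a center pixel."""
        return self.kernel_size if self.kernel_size % 2 == 1 else self.kernel_size + 1


@dataclass(frozen=True)
class RfParams:
    """Random-forest hyperparameters Ƥ_RF.

    ``min_samples_frac`` is the minimum number of samples a decision node
    needs in order to split, expressed as a fraction of the training-pair
    count (0.0001% → 1e-6). Features per node are fixed at √n_features.
    """

    n_trees: int = 30
    max_depth: int = 30
    min_samples_frac: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.max_depth < 1:
            raise ValueError("n_trees and max_depth must be ≥ 1")
        if not 0 < self.min_samples_frac <= 1:
            raise ValueError("min_samples_frac must be in (0, 1]")

    def min_samples_split(self, n_pairs: int) -> int:
        """Absolute split threshold; scikit-learn requires ≥ 2."""
        return max(2, int(self.min_samples_frac * n_pairs))


@dataclass(frozen=True)
class ParamSet:
    """The full tunable set Ƥ: forest, Gabor and ELBP parameters."""

    rf: RfParams = field(default_factory=RfParams)
    gabor: GaborConfig = field(default_factory=GaborConfig)
    elbp: ElbpConfig = field(default_factory=ElbpConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ParamSet":
        g = dict(d.get("gabor", {}))
        if "orientations_deg" in g:
            g["orientations_deg"] = tuple(g["orientations_deg"])
        return cls(
            rf=RfParams(**d.get("rf", {})),
            gabor=GaborConfig(**g),
            elbp=ElbpConfig(**d.get("elbp", {})),
        )


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs: Ƥ, the CSA threshold, post-processing and
    registration constants, and the run seed."""

    params: ParamSet = field(default_factory=ParamSet)
    csa_threshold: float = 70.0
    csa_opening_radius: int = 1
    bias_method: str = "polyfit"
    post_dilation_radius: int = 1
    post_min_island: int = 10
    post_sigma_factor: float = 3.0
    reg_bins: int = 50
    reg_levels: int = 2
    reg_max_iterations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.csa_threshold <= 0:
            raise ValueError("CSA threshold must be positive")
        if self.bias_method not in ("none", "polyfit", "n4"):
            raise ValueError(f"unknown bias correction method {self.bias_method!r}")
        if self.post_min_island < 0 or self.post_sigma_factor <= 0:
            raise ValueError("invalid post-processing constants")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"] = self.params.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        params = ParamSet.from_dict(d.pop("params", {}))
        return cls(params=params, **d)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
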