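"""Synthetic nacre-like layer stacks.

A nacreous layer is modelled as a 1D stack of alternating aragonite plates
(thickness ``d1``, index ``n1``) and interlamellar gaps (thickness ``d2``,
index ``n2``: air for Ammolite-like fossils, organic for living shells).
:class:`StackSpec` is the stochastic recipe — means, standard deviations,
period count, depth profile and seed — and :func:`sample_stack` realizes it
as a concrete :class:`LayerStack` that the optical solver consumes.

Thicknesses are drawn from truncated Gaussians: the field reports mean ± SD
only, and the truncation floor (1 nm for plates, 0.5 nm for gaps) merely
guards against non-physical layers at the reported SDs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "RefractiveModel",
    "StackSpec",
    "LayerStack",
    "sample_stack",
    "depth_profile",
    "PLATE_FLOOR_NM",
    "GAP_FLOOR_NM",
]

#: Lower truncation bound for plate thicknesses (nm).
PLATE_FLOOR_NM = 1.0
#: Lower truncation bound for gap widths (nm).
GAP_FLOOR_NM = 0.5

_PROFILES = ("constant", "linear_drift", "custom")


@dataclass(frozen=True)
class RefractiveModel:
    """Real (lossless) refractive indices of the four media.

    Defaults are the Ammolite case: aragonite plates at the effective index
    1.63 over air-filled gaps, light entering from air, bulk aragonite below.
    (Aragonite is actually birefringent, 1.530/1.681/1.686 along the three
    crystal axes; the single effective value 1.63 is the standard treatment.)
    """

    n1: float = 1.63
    n2: float = 1.00
    n_ambient: float = 1.00
    n_substrate: float = 1.63

    def __post_init__(self) -> None:
        for name in ("n1", "n2", "n_ambient", "n_substrate"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 1.0:
                raise ValueError(f"{name} must be finite and >= 1.0, got {v!r}")


@dataclass(frozen=True)
class StackSpec:
    """Stochastic recipe for a nacre-like stack.

    Parameters
    ----------
    d1_mean, d1_sd : float
        Mean and SD of the aragonite plate thickness, nm.
    d2_mean, d2_sd : float
        Mean and SD of the interlamellar gap width, nm.
    n_periods : int
        Number of plate/gap pairs. The default 300 corresponds to ~50 µm of
        stack at a 164 nm lamination period, the depth of homogeneous
        periodicity associated with brilliant color.
    profile : {"constant", "linear_drift", "custom"}
        Depth profile of the lamination period. ``linear_drift`` adds
        ``drift_rate`` nm to the plate-thickness mean per period (emulating
        the drifting periods seen in abalone and pale fossil nacre);
        ``custom`` takes explicit per-period lamination periods.
    drift_rate : float
        nm of period drift per period (used by ``linear_drift``).
    custom_periods : sequence of float, optional
        Per-period lamination periods d = d1 + d2, nm (used by ``custom``).
    refr : RefractiveModel
    seed : int, optional
        Seed for the thickness draws; same seed ⇒ identical stack.
    """

    d1_mean: float = 160.0
    d1_sd: float = 0.0
    d2_mean: float = 4.0
    d2_sd: float = 0.0
    n_periods: int = 300
    profile: str = "constant"
    drift_rate: float = 0.0
    custom_periods: Optional[tuple] = None
    refr: RefractiveModel = field(default_factory=RefractiveModel)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.d1_mean <= 0:
            raise ValueError(f"d1_mean must be > 0, got {self.d1_mean}")
        if self.d2_mean < 0:
            raise ValueError(f"d2_mean must be >= 0, got {self.d2_mean}")
        if self.d1_sd < 0 or self.d2_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_periods < 1:
            raise ValueError(f"n_periods must be >= 1, got {self.n_periods}")
        if self.profile not in _PROFILES:
            raise ValueError(f"profile must be one of {_PROFILES}, got {self.profile!r}")
        if self.profile == "custom":
            if self.custom_periods is None or len(self.custom_periods) != self.n_periods:
                raise ValueError("custom profile requires n_periods custom_periods values")
            object.__setattr__(self, "custom_periods", tuple(float(p) for p in self.custom_periods))

    # -- per-period plate-thickness means implied by the depth profile -------
    def plate_means(self) -> np.ndarray:
        k = np.arange(self.n_periods, dtype=float)
        if self.profile == "constant":
            return np.full(self.n_periods, self.d1_mean)
        if self.profile == "linear_drift":
            return self.d1_mean + self.drift_rate * k
        periods = np.asarray(self.custom_periods, dtype=float)
        means = periods - self.d2_mean
        if np.any(means <= 0):
            raise ValueError("custom_periods imply non-positive plate thickness")
        return means

    # -- serialization --------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "d1_mean": self.d1_mean,
            "d1_sd": self.d1_sd,
            "d2_mean": self.d2_mean,
            "d2_sd": self.d2_sd,
            "n_periods": self.n_periods,
            "profile": self.profile,
            "drift_rate": self.drift_rate,
            "custom_periods": list(self.custom_periods) if self.custom_periods else None,
            "refr": {
                "n1": self.refr.n1,
                "n2": self.refr.n2,
                "n_ambient": self.refr.n_ambient,
                "n_substrate": self.refr.n_substrate,
            },
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StackSpec":
        d = dict(d)
        refr = d.pop("refr", None)
        if refr is not None:
            refr = RefractiveModel(**refr)
        else:
            refr = RefractiveModel()
        custom = d.pop("custom_periods", None)
        return cls(refr=refr, custom_periods=tuple(custom) if custom else None, **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "StackSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def with_(self, **kwargs) -> "StackSpec":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class LayerStack:
    """A concrete finite stack between two semi-infinite media.

    ``layers`` is an ordered (top → bottom) tuple of ``(index, thickness_nm)``
    pairs; zero- or negative-thickness layers are dropped at construction.
    """

    layers: tuple
    n_ambient: float = 1.00
    n_substrate: float = 1.63

    def __post_init__(self) -> None:
        kept = tuple((float(n), float(t)) for n, t in self.layers if t > 0)
        for n, t in kept:
            if not (np.isfinite(n) and np.isfinite(t)) or n < 1.0:
                raise ValueError(f"invalid layer (n={n}, t={t})")
        object.__setattr__(self, "layers", kept)

    def __len__(self) -> int:
        return len(self.layers)

    @property
    def indices(self) -> np.ndarray:
        return np.array([n for n, _ in self.layers])

    @property
    def thicknesses(self) -> np.ndarray:
        return np.array([t for _, t in self.layers])

    @property
    def total_thickness(self) -> float:
        return float(self.thicknesses.sum()) if self.layers else 0.0

    def reversed(self) -> "LayerStack":
        """The stack traversed from the substrate side."""
        return LayerStack(
            layers=tuple(reversed(self.layers)),
            n_ambient=self.n_substrate,
            n_substrate=self.n_ambient,
        )

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["index", "thickness_nm"])
            for n, t in self.layers:
                w.writerow([repr(n), repr(t)])

    @classmethod
    def from_csv(cls, path, n_ambient: float = 1.00, n_substrate: float = 1.63) -> "LayerStack":
        with open(path) as fh:
            rows = list(csv.reader(fh))
        if not rows or rows[0][:2] != ["index", "thickness_nm"]:
            raise ValueError(f"{path}: expected header 'index,thickness_nm'")
        layers = tuple((float(n), float(t)) for n, t in rows[1:])
        return cls(layers=layers, n_ambient=n_ambient, n_substrate=n_substrate)


def _draw(rng: np.random.Generator, means: np.ndarray, sd: float, floor: float) -> np.ndarray:
    """Truncated-Gaussian thickness draws with lower bound ``floor``."""
    if sd == 0:
        return means.copy()
    a = (floor - means) / sd  # per-sample standardized lower bound
    return stats.truncnorm.rvs(a, np.inf, loc=means, scale=sd, random_state=rng)


def sample_stack(spec: StackSpec, rng: Optional[np.random.Generator] = None) -> LayerStack:
    """Realize a :class:`StackSpec` as a concrete plate/gap stack.

    With all SDs zero the stack is exactly periodic (up to the depth
    profile); with a fixed seed the draw is bit-reproducible.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    plate_means = spec.plate_means()
    gap_means = np.full(spec.n_periods, float(spec.d2_mean))
    plates = _draw(rng, plate_means, spec.d1_sd, PLATE_FLOOR_NM)
    gaps = _draw(rng, gap_means, spec.d2_sd, GAP_FLOOR_NM)
    layers = []
    for dp, dg in zip(plates, gaps):
        layers.append((spec.refr.n1, dp))
        layers.append((spec.refr.n2, dg))
    return LayerStack(
        layers=tuple(layers),
        n_ambient=spec.refr.n_ambient,
        n_substrate=spec.refr.n_substrate,
    )


def depth_profile(stack: LayerStack) -> list:
    """Per-period lamination period d = d1 + d2 versus cumulative depth.

    Returns a list of ``(depth_nm, period_nm)`` tuples where depth is the
    bottom of each period — the quantity measured on cross-sectional
    micrograph grayscale profiles. Requires an even layer count (complete
    plate/gap pairs).
    """
    if len(stack) % 2 != 0:
        raise ValueError(f"stack has {len(stack)} layers; plate/gap pairs required")
    t = stack.thicknesses
    periods = t[0::2] + t[1::2]
    depths = np.cumsum(periods)
    return list(zip(depths.tolist(), periods.tolist()))
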