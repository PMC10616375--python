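"""Ground-truthed synthetic H&E-like data.

Real high-grade serous carcinoma slides and their pathologist annotations
are not redistributable, so every stage of the pipeline is exercised on
synthetic material generated here: image patches containing elliptical
nuclei of the five cell classes (neoplastic, inflammatory, connective,
dead, epithelial) rendered in hematoxylin-like colours on a pale
eosin-like background, together with the exact instance label map, class
labels and ellipse parameters; and per-sample (feature, ploidy) tables
with a controlled Spearman rank correlation for the downstream
correlation analysis.

All randomness flows from the single integer ``seed`` carried by each
spec; fixed seed implies bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import stats
from skimage.draw import ellipse as draw_ellipse

from .flow_postprocess import FlowField, compute_flow_targets

__all__ = [
    "CLASS_NAMES",
    "SyntheticImageSpec",
    "SyntheticScene",
    "SyntheticPloidySpec",
    "NetworkTargets",
    "generate_scene",
    "scene_to_training_targets",
    "generate_ploidy_dataset",
    "save_scene",
    "load_scene",
]

#: Cell classes, index 1..5 in label/class maps (0 is background).
CLASS_NAMES = ("neoplastic", "inflammatory", "connective", "dead", "epithelial")

# Hematoxylin-dominated nucleus colours per class; the exact hues are
# arbitrary but saturated enough that HSV-saturation tissue detection and
# the colour-based class heads have signal to work with.
_DEFAULT_CLASS_RGB = {
    "neoplastic": (94, 60, 132),
    "inflammatory": (52, 40, 110),
    "connective": (120, 85, 150),
    "dead": (150, 110, 160),
    "epithelial": (80, 62, 138),
}
_DEFAULT_BACKGROUND_RGB = (233, 206, 216)  # pale eosin pink

# Class mix of an annotated validation region set in ovarian HGSC tissue:
# 38% neoplastic, 18% inflammatory, 36% connective, 0.1% dead, balance
# non-neoplastic epithelial.
_DEFAULT_PROPORTIONS = (0.38, 0.18, 0.36, 0.001, 0.079)


@dataclass
class SyntheticImageSpec:
    """Parameters of one synthetic H&E-like patch.

    Axis ranges are full axis lengths in pixels (a nucleus with
    ``major=40`` spans 40 px along its major axis).  ``max_overlap_fraction``
    bounds, for every newly placed nucleus, both the fraction of its own
    pixels already occupied and the fraction of any earlier nucleus it may
    overwrite.
    """

    height: int = 256
    width: int = 256
    n_nuclei: int = 100
    class_proportions: tuple[float, ...] = _DEFAULT_PROPORTIONS
    major_axis_range: dict[str, tuple[float, float]] | tuple[float, float] = (14.0, 30.0)
    minor_axis_range: dict[str, tuple[float, float]] | tuple[float, float] = (9.0, 18.0)
    max_overlap_fraction: float = 0.15
    background_rgb: tuple[int, int, int] = _DEFAULT_BACKGROUND_RGB
    class_rgb: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(_DEFAULT_CLASS_RGB)
    )
    intensity_jitter: float = 10.0
    noise_sigma: float = 6.0
    seed: int = 0

    def axis_range(self, which: str, class_name: str) -> tuple[float, float]:
        rng = self.major_axis_range if which == "major" else self.minor_axis_range
        if isinstance(rng, dict):
            rng = rng[class_name]
        return float(rng[0]), float(rng[1])

    def validate(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        props = np.asarray(self.class_proportions, dtype=float)
        if props.size != len(CLASS_NAMES) or abs(props.sum() - 1.0) > 1e-9 or (props < 0).any():
            raise ValueError("class_proportions must be 5 non-negative fractions summing to 1")
        if not 0.0 <= self.max_overlap_fraction < 1.0:
            raise ValueError("max_overlap_fraction must be in [0, 1)")
        for cname in CLASS_NAMES:
            lo_a, hi_a = self.axis_range("major", cname)
            lo_b, hi_b = self.axis_range("minor", cname)
            if lo_a <= 0 or lo_b <= 0 or hi_a < lo_a or hi_b < lo_b:
                raise ValueError("axis ranges must be positive, ordered intervals")
            if hi_b > hi_a:
                raise ValueError(f"minor axis range exceeds major axis range for {cname!r}")


@dataclass
class SyntheticScene:
    """A rendered patch with full ground truth.

    ``classes`` maps instance label -> class index (1..5); ``ellipses`` maps
    label -> (center_y, center_x, major_axis, minor_axis, rotation_rad).
    """

    image: np.ndarray
    instances: np.ndarray
    classes: dict[int, int]
    ellipses: dict[int, tuple[float, float, float, float, float]]

    @property
    def class_map(self) -> np.ndarray:
        """Per-pixel class indices, consistent with ``instances``."""
        n = int(self.instances.max())
        lut = np.zeros(n + 1, dtype=np.int32)
        for lab, ci in self.classes.items():
            lut[lab] = ci
        return lut[self.instances]


@dataclass
class NetworkTargets:
    """Supervision for the three decoder heads."""

    foreground: np.ndarray  # (H, W) bool
    class_map: np.ndarray  # (H, W) int, 0 = background
    dist: np.ndarray  # (H, W) float
    flow: np.ndarray  # (2, H, W) float, unit norm on foreground


def generate_scene(spec: SyntheticImageSpec) -> SyntheticScene:
    """Render a synthetic patch and its ground truth.

    Nuclei are placed by rejection sampling honouring
    ``spec.max_overlap_fraction``; where placements overlap, the
    later-placed nucleus owns the contested pixels (the label map is
    single-valued, as real H&E instance masks are non-overlapping).

    Raises
    ------
    RuntimeError if the requested scene is too crowded to place all nuclei
    within the rejection budget (200 tries per nucleus).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    instances = np.zeros((h, w), dtype=np.int32)
    classes: dict[int, int] = {}
    ellipses: dict[int, tuple[float, float, float, float, float]] = {}

    props = np.asarray(spec.class_proportions, dtype=float)
    drawn_classes = rng.choice(len(CLASS_NAMES), size=spec.n_nuclei, p=props) + 1

    max_tries = 200 * max(spec.n_nuclei, 1)
    tries = 0
    areas = np.zeros(spec.n_nuclei + 1, dtype=np.int64)
    for i in range(spec.n_nuclei):
        lab = i + 1
        cname = CLASS_NAMES[drawn_classes[i] - 1]
        placed = False
        while tries < max_tries:
            tries += 1
            lo_a, hi_a = spec.axis_range("major", cname)
            lo_b, hi_b = spec.axis_range("minor", cname)
            major = rng.uniform(lo_a, hi_a)
            minor = rng.uniform(lo_b, min(hi_b, major))
            cy = rng.uniform(major / 2, h - major / 2) if h > major else h / 2
            cx = rng.uniform(major / 2, w - major / 2) if w > major else w / 2
            rot = rng.uniform(0, np.pi)
            rr, cc = draw_ellipse(cy, cx, major / 2, minor / 2, shape=(h, w), rotation=rot)
            if rr.size < 4:
                continue
            under = instances[rr, cc]
            n_over = int(np.count_nonzero(under))
            if n_over > spec.max_overlap_fraction * rr.size:
                continue
            stolen = np.bincount(under[under > 0], minlength=lab)
            victims = np.flatnonzero(stolen)
            if victims.size and np.any(
                stolen[victims] > spec.max_overlap_fraction * areas[victims]
            ):
                continue
            instances[rr, cc] = lab
            areas[victims] -= stolen[victims]
            areas[lab] = rr.size
            classes[lab] = int(drawn_classes[i])
            ellipses[lab] = (float(cy), float(cx), float(major), float(minor), float(rot))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place nucleus {lab}/{spec.n_nuclei} within the rejection "
                "budget: the SyntheticImageSpec is overcrowded (reduce n_nuclei, "
                "shrink axis ranges or raise max_overlap_fraction)"
            )

    image = np.empty((h, w, 3), dtype=np.float64)
    image[:] = np.asarray(spec.background_rgb, dtype=np.float64)
    for lab, ci in classes.items():
        base = np.asarray(spec.class_rgb[CLASS_NAMES[ci - 1]], dtype=np.float64)
        jitter = rng.uniform(-spec.intensity_jitter, spec.intensity_jitter, size=3)
        image[instances == lab] = base + jitter
    if spec.noise_sigma > 0:
        image += rng.normal(0.0, spec.noise_sigma, size=image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    return SyntheticScene(image=image, instances=instances, classes=classes, ellipses=ellipses)


def scene_to_training_targets(scene: SyntheticScene) -> NetworkTargets:
    """Targets for the foreground, class and geometry decoder heads."""
    ff: FlowField = compute_flow_targets(scene.instances)
    return NetworkTargets(
        foreground=scene.instances > 0,
        class_map=scene.class_map,
        dist=ff.dist,
        flow=ff.flow,
    )


# ---------------------------------------------------------------------------
# Ploidy association tables
# ---------------------------------------------------------------------------

#: Anatomical tumour sites with the cohort's slide counts (47 samples).
_DEFAULT_SITES = (("omentum", 18), ("peritoneum", 12), ("tubo-ovarian", 17))

_FEATURE_SCALE = {
    # rough per-sample medians in pixel units at 20x, used as log-normal scales
    "area": 350.0,
    "volume": 4000.0,
    "major_axis": 24.0,
    "minor_axis": 14.0,
    "perimeter": 70.0,
    "aspect_ratio": 1.6,
    "eccentricity": 0.7,
    "solidity": 0.95,
}


@dataclass
class SyntheticPloidySpec:
    """Parameters of a synthetic (feature summary, ploidy) cohort table.

    ``true_rho`` is the population Spearman correlation between ploidy and
    both the feature median and the feature variance; it is induced through
    a Gaussian copula (see :func:`generate_ploidy_dataset`).  Site labels
    are assigned independently of ploidy.
    """

    n_samples: int = 47
    true_rho: float = 0.5
    ploidy_range: tuple[float, float] = (1.5, 6.0)
    feature_names: tuple[str, ...] = ("area", "volume", "major_axis", "perimeter")
    site_labels: tuple[tuple[str, int], ...] = _DEFAULT_SITES
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if abs(self.true_rho) > 1.0:
            raise ValueError("true_rho must lie in [-1, 1]")
        if self.ploidy_range[0] <= 0 or self.ploidy_range[1] <= self.ploidy_range[0]:
            raise ValueError("ploidy_range must be a positive increasing interval")
        for f in self.feature_names:
            if f not in _FEATURE_SCALE:
                raise ValueError(f"unknown feature {f!r}; choose from {sorted(_FEATURE_SCALE)}")
        if sum(n for _, n in self.site_labels) != self.n_samples:
            raise ValueError("site label counts must sum to n_samples")


def generate_ploidy_dataset(spec: SyntheticPloidySpec) -> pd.DataFrame:
    """Draw a cohort table with a controlled Spearman correlation.

    A Gaussian copula is used: the target Spearman rho is mapped to the
    latent Pearson correlation r = 2*sin(pi*rho/6) (the exact inverse of the
    Spearman coefficient of a bivariate normal), a latent normal score for
    ploidy is drawn, and for each feature the latent scores of the median and
    variance columns are drawn with correlation r to the ploidy score.
    Marginals: ploidy uniform on ``ploidy_range``; medians log-normal around
    a per-feature scale; variances log-normal around the squared scale.

    For ``true_rho = +/-1`` the construction is comonotone, so the sample
    Spearman correlation equals true_rho exactly at any n.

    Returns a long-format table with columns
    ``sample, site, feature, median, variance, ploidy``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    r = 2.0 * np.sin(np.pi * spec.true_rho / 6.0)

    z_ploidy = rng.standard_normal(n)
    u_ploidy = stats.norm.cdf(z_ploidy)
    lo, hi = spec.ploidy_range
    ploidy = lo + u_ploidy * (hi - lo)

    sites = np.concatenate([[name] * cnt for name, cnt in spec.site_labels])
    rng.shuffle(sites)
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]

    rows = []
    root = np.sqrt(max(1.0 - r * r, 0.0))
    for feat in spec.feature_names:
        scale = _FEATURE_SCALE[feat]
        z_med = r * z_ploidy + root * rng.standard_normal(n)
        z_var = r * z_ploidy + root * rng.standard_normal(n)
        median = scale * np.exp(0.25 * z_med)
        variance = (0.15 * scale) ** 2 * np.exp(0.5 * z_var)
        for i in range(n):
            rows.append(
                {
                    "sample": sample_ids[i],
                    "site": sites[i],
                    "feature": feat,
                    "median": median[i],
                    "variance": variance[i],
                    "ploidy": ploidy[i],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Scene persistence (PNG image + 16-bit PNG labels + JSON classes)
# ---------------------------------------------------------------------------


def save_scene(scene: SyntheticScene, directory: str | Path) -> None:
    """Persist a scene as image.png + labels.png (16-bit) + classes.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    iio.imwrite(directory / "image.png", scene.image)
    if scene.instances.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 instances cannot be saved as 16-bit PNG")
    iio.imwrite(directory / "labels.png", scene.instances.astype(np.uint16))
    meta = {
        "classes": {str(k): CLASS_NAMES[v - 1] for k, v in scene.classes.items()},
        "ellipses": {str(k): list(v) for k, v in scene.ellipses.items()},
    }
    (directory / "classes.json").write_text(json.dumps(meta, indent=1))


def load_scene(directory: str | Path) -> SyntheticScene:
    """Inverse of :func:`save_scene`."""
    directory = Path(directory)
    image = iio.imread(directory / "image.png")
    instances = iio.imread(directory / "labels.png").astype(np.int32)
    meta = json.loads((directory / "classes.json").read_text())
    classes = {int(k): CLASS_NAMES.index(v) + 1 for k, v in meta["classes"].items()}
    ellipses = {int(k): tuple(v) for k, v in meta["ellipses"].items()}
    return SyntheticScene(image=image, instances=instances, classes=classes, ellipses=ellipses)
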