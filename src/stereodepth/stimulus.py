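"""Dynamic random-dot stereogram synthesis.

Generates correlated (CRDS) and anticorrelated (ACRDS) random-dot
stereograms in the two configurations used throughout the package: a
circular target embedded in a zero-disparity annulus, and a horizontal
depth edge between abutting rectangular target and reference regions.

Conventions
-----------
* All spatial quantities are in arc minutes unless a name says otherwise.
* Stimulus-centred coordinates: x rightward, y downward.
* Disparity sign: positive = crossed = near.  A target disparity ``d`` is
  applied symmetrically by default: target dots move ``+d/2`` in the left
  eye's image and ``-d/2`` in the right eye's image, so the left-minus-
  right horizontal offset equals ``d``.
* Luminances are in cd/m^2.  The three display levels are bright dot,
  dark dot and uniform background; contrast images are Weber contrast
  about the background.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np

ARCMIN_PER_DEG = 60.0
FRAME_RATE_HZ = 60.0

#: Study-replica geometry (arc minutes).
CIRCLE_TARGET_RADIUS = 2.3 * ARCMIN_PER_DEG     # 138
ANNULUS_OUTER_RADIUS = 3.4 * ARCMIN_PER_DEG     # 204
EDGE_RECT_WIDTH = 3.40 * ARCMIN_PER_DEG         # 204
EDGE_RECT_HEIGHT = 2.33 * ARCMIN_PER_DEG        # 139.8

#: Eccentricities (degrees) at which study-replica stimuli are placed.
REPLICA_ECCENTRICITIES_DEG = (0.0, 3.1, 6.2, 9.5, 12.7)
#: Target disparities (arc min) used in study-replica blocks.
REPLICA_DISPARITIES = (-28.0, 0.0, 28.0)

CONFIGURATIONS = ("circle", "edge")
CORRELATIONS = ("correlated", "anticorrelated")
MERIDIANS = ("horizontal_right", "vertical_below")


def frames_for_duration(duration_ms: float, frame_rate_hz: float = FRAME_RATE_HZ) -> int:
    """Number of stimulus frames for a duration, rounded to the nearest frame.

    80 ms -> 5 frames, 700 ms -> 42 frames at 60 Hz.
    """
    n = int(round(duration_ms / 1000.0 * frame_rate_hz))
    return max(n, 1)


@dataclass(frozen=True)
class StimulusSpec:
    """Full parameterisation of one stereogram condition."""

    configuration: str = "circle"
    correlation: str = "correlated"
    target_disparity: float = 28.0          # arcmin; + = crossed/near
    eccentricity: float = 0.0               # degrees along `meridian`
    meridian: str = "horizontal_right"
    duration_frames: int = 5
    dot_size: float = 9.0                   # arcmin, square side
    coverage_fraction: float = 0.25
    luminance_bright: float = 27.0
    luminance_dark: float = 0.0
    luminance_background: float = 13.5
    pixel_pitch: float = 1.9                # arcmin per pixel
    disparity_split: float = 0.5            # fraction of disparity to left eye
    anticorrelated_eye: str = "right"       # eye whose target dots flip polarity

    def __post_init__(self) -> None:
        if self.configuration not in CONFIGURATIONS:
            raise ValueError(f"unknown configuration {self.configuration!r}")
        if self.correlation not in CORRELATIONS:
            raise ValueError(f"unknown correlation {self.correlation!r}")
        if self.meridian not in MERIDIANS:
            raise ValueError(f"unknown meridian {self.meridian!r}")
        if not 0.0 < self.coverage_fraction <= 1.0:
            raise ValueError("coverage_fraction must be in (0, 1]")
        if self.dot_size <= 0:
            raise ValueError("dot_size must be positive")
        if self.duration_frames < 1:
            raise ValueError("duration_frames must be >= 1")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.anticorrelated_eye not in ("left", "right"):
            raise ValueError("anticorrelated_eye must be 'left' or 'right'")

    @property
    def eccentricity_arcmin(self) -> float:
        return self.eccentricity * ARCMIN_PER_DEG

    @property
    def centre_offset(self) -> tuple[float, float]:
        """Stimulus centre relative to fixation, (x, y) arcmin."""
        e = self.eccentricity_arcmin
        if self.meridian == "horizontal_right":
            return (e, 0.0)
        return (0.0, e)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "StimulusSpec":
        return cls(**json.loads(text))


_PRESETS = {
    "exp1_circle": dict(configuration="circle", meridian="horizontal_right"),
    "exp1_edge": dict(configuration="edge", meridian="horizontal_right"),
    "exp2_edge": dict(configuration="edge", meridian="vertical_below"),
    "exp2_circle": dict(configuration="circle", meridian="vertical_below"),
}


def preset(
    name: str,
    *,
    correlation: str = "correlated",
    target_disparity: float = 28.0,
    eccentricity: float = 0.0,
    duration_ms: float = 80.0,
    **overrides,
) -> StimulusSpec:
    """A study-replica :class:`StimulusSpec` by preset name.

    Presets fix the configuration and meridian (``exp1_*`` on the
    horizontal meridian to the right of fixation, ``exp2_*`` on the
    vertical meridian below fixation); everything else is the display
    default (9 arcmin dots, 25% coverage, 1.9 arcmin pixels, 60 Hz).
    """
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    return StimulusSpec(
        correlation=correlation,
        target_disparity=target_disparity,
        eccentricity=eccentricity,
        duration_frames=frames_for_duration(duration_ms),
        **_PRESETS[name],
        **overrides,
    )


@dataclass(frozen=True)
class RegionGeometry:
    """Target and reference region shapes for one configuration.

    The circle configuration has a disc target inside an annular
    reference; the edge configuration has the target rectangle directly
    above the horizontal midline and the reference directly below.  The
    reference always carries zero disparity.
    """

    configuration: str
    target_radius: float = CIRCLE_TARGET_RADIUS
    annulus_outer: float = ANNULUS_OUTER_RADIUS
    rect_width: float = EDGE_RECT_WIDTH
    rect_height: float = EDGE_RECT_HEIGHT

    @classmethod
    def for_configuration(cls, configuration: str) -> "RegionGeometry":
        if configuration not in CONFIGURATIONS:
            raise ValueError(f"unknown configuration {configuration!r}")
        return cls(configuration=configuration)

    def area(self, region: str) -> float:
        """Region area in arcmin^2."""
        if self.configuration == "circle":
            if region == "target":
                return math.pi * self.target_radius**2
            return math.pi * (self.annulus_outer**2 - self.target_radius**2)
        return self.rect_width * self.rect_height

    def outer_extent(self) -> float:
        """Half-extent of the stimulus bounding box from its centre."""
        if self.configuration == "circle":
            return self.annulus_outer
        return max(self.rect_width / 2.0, self.rect_height)

    def sample(self, region: str, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform positions (n, 2) in stimulus-centred arcmin coordinates."""
        if region not in ("target", "reference"):
            raise ValueError(f"unknown region {region!r}")
        if n == 0:
            return np.zeros((0, 2))
        if self.configuration == "circle":
            u = rng.random(n)
            if region == "target":
                r = self.target_radius * np.sqrt(u)
            else:
                r = np.sqrt(self.target_radius**2
                            + u * (self.annulus_outer**2 - self.target_radius**2))
            theta = rng.uniform(0.0, 2.0 * math.pi, n)
            return np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        x = rng.uniform(-self.rect_width / 2.0, self.rect_width / 2.0, n)
        y = rng.uniform(0.0, self.rect_height, n)
        if region == "target":           # above the midline; y is downward
            y = -y
        return np.column_stack([x, y])

    def contains(self, region: str, xy: np.ndarray) -> np.ndarray:
        """Boolean membership of points (n, 2) in a region."""
        x, y = xy[:, 0], xy[:, 1]
        if self.configuration == "circle":
            r = np.hypot(x, y)
            if region == "target":
                return r <= self.target_radius
            return (r > self.target_radius) & (r <= self.annulus_outer)
        inx = np.abs(x) <= self.rect_width / 2.0
        if region == "target":
            return inx & (y <= 0.0) & (y >= -self.rect_height)
        return inx & (y > 0.0) & (y <= self.rect_height)

    def mask(self, region: str, window: "Window", offset: tuple[float, float]) -> np.ndarray:
        """Pixel mask of a region placed at `offset`, on `window`'s lattice."""
        xg, yg = np.meshgrid(window.x - offset[0], window.y - offset[1])
        pts = np.column_stack([xg.ravel(), yg.ravel()])
        return self.contains(region, pts).reshape(window.shape)


@dataclass
class DotField:
    """Dots of one frame: continuous centres, polarities and region labels."""

    positions: np.ndarray          # (n, 2) arcmin, stimulus-centred
    polarities: np.ndarray         # (n,) int8, +1 bright / -1 dark
    is_target: np.ndarray          # (n,) bool

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        self.polarities = np.asarray(self.polarities, dtype=np.int8).ravel()
        self.is_target = np.asarray(self.is_target, dtype=bool).ravel()
        if not (len(self.positions) == len(self.polarities) == len(self.is_target)):
            raise ValueError("inconsistent dot field lengths")

    @property
    def n_dots(self) -> int:
        return len(self.polarities)

    def copy(self) -> "DotField":
        return DotField(self.positions.copy(), self.polarities.copy(),
                        self.is_target.copy())


def dot_count(region_area: float, dot_size: float, coverage_fraction: float) -> int:
    """Dot count from the coverage rule.

    ``round(coverage * area / dot_size^2)`` adjusted down to the nearest
    even number, so bright and dark dots can be balanced exactly.
    """
    if dot_size <= 0:
        raise ValueError("dot_size must be positive")
    if region_area <= 0:
        raise ValueError("region area must be positive")
    if not 0.0 < coverage_fraction <= 1.0:
        raise ValueError("coverage_fraction must be in (0, 1]")
    n = int(round(coverage_fraction * region_area / dot_size**2))
    return n - (n % 2)


def make_dot_field(
    geometry: RegionGeometry,
    region: str,
    dot_size: float,
    coverage_fraction: float,
    rng: np.random.Generator,
) -> DotField:
    """Sample one region's dots: uniform centres, half bright, half dark."""
    n = dot_count(geometry.area(region), dot_size, coverage_fraction)
    positions = geometry.sample(region, n, rng)
    polarities = np.empty(n, dtype=np.int8)
    polarities[: n // 2] = 1
    polarities[n // 2:] = -1
    polarities = rng.permutation(polarities)
    return DotField(positions, polarities, np.full(n, region == "target"))


def full_dot_field(spec: StimulusSpec, rng: np.random.Generator) -> DotField:
    """Reference plus target dots for one frame (reference drawn first)."""
    geom = RegionGeometry.for_configuration(spec.configuration)
    ref = make_dot_field(geom, "reference", spec.dot_size, spec.coverage_fraction, rng)
    tgt = make_dot_field(geom, "target", spec.dot_size, spec.coverage_fraction, rng)
    return DotField(
        np.vstack([ref.positions, tgt.positions]),
        np.concatenate([ref.polarities, tgt.polarities]),
        np.concatenate([ref.is_target, tgt.is_target]),
    )


def apply_disparity(
    dots: DotField, target_disparity: float, disparity_split: float = 0.5
) -> tuple[DotField, DotField]:
    """Left/right dot fields with the target region displaced.

    Target dots move ``+d*split`` in the left eye and ``-d*(1-split)``
    in the right eye, giving a left-minus-right offset of exactly ``d``
    (positive = crossed = near).  Reference dots are identical in the
    two eyes.
    """
    left, right = dots.copy(), dots.copy()
    left.positions[dots.is_target, 0] += target_disparity * disparity_split
    right.positions[dots.is_target, 0] -= target_disparity * (1.0 - disparity_split)
    return left, right


def anticorrelate(
    left: DotField, right: DotField, eye: str = "right"
) -> tuple[DotField, DotField]:
    """Flip the polarity of every target dot in exactly one eye."""
    left, right = left.copy(), right.copy()
    flip = left if eye == "left" else right
    flip.polarities[flip.is_target] *= -1
    return left, right


@dataclass(frozen=True)
class Window:
    """A pixel lattice: centre (x, y) arcmin from fixation, shape (ny, nx)."""

    centre: tuple[float, float]
    shape: tuple[int, int]
    pixel_pitch: float

    @property
    def x(self) -> np.ndarray:
        """Pixel-centre x coordinates (arcmin from fixation)."""
        nx = self.shape[1]
        return (np.arange(nx) - (nx - 1) / 2.0) * self.pixel_pitch + self.centre[0]

    @property
    def y(self) -> np.ndarray:
        ny = self.shape[0]
        return (np.arange(ny) - (ny - 1) / 2.0) * self.pixel_pitch + self.centre[1]

    @classmethod
    def around(cls, centre: tuple[float, float], half_extent: float,
               pixel_pitch: float) -> "Window":
        """Square window covering ±half_extent arcmin about `centre`."""
        half_px = int(math.ceil(half_extent / pixel_pitch))
        n = 2 * half_px + 1
        return cls(centre=tuple(centre), shape=(n, n), pixel_pitch=pixel_pitch)


def default_canvas(spec: StimulusSpec) -> Window:
    """Canvas centred on fixation, containing the stimulus at its
    eccentricity plus one stimulus diameter of margin."""
    geom = RegionGeometry.for_configuration(spec.configuration)
    ext = geom.outer_extent()
    half = spec.eccentricity_arcmin + ext + 2.0 * ext
    return Window.around((0.0, 0.0), half, spec.pixel_pitch)


def rasterize(
    dots: DotField,
    spec: StimulusSpec,
    window: Window,
    offset: tuple[float, float] | None = None,
) -> np.ndarray:
    """Draw dots as un-antialiased squares on the window's lattice.

    Continuous dot centres are snapped to the nearest pixel; dots are
    drawn in order, later dots overwriting earlier ones; dots partly or
    wholly outside the window are clipped.  Returns a luminance image
    (cd/m^2) initialised to the background level.
    """
    if offset is None:
        offset = spec.centre_offset
    ny, nx = window.shape
    img = np.full((ny, nx), spec.luminance_background, dtype=float)
    if dots.n_dots == 0:
        return img
    p = window.pixel_pitch
    s = max(1, int(round(spec.dot_size / p)))
    lo = (s - 1) // 2
    x0, y0 = window.x[0], window.y[0]
    ix = np.rint((dots.positions[:, 0] + offset[0] - x0) / p).astype(int) - lo
    iy = np.rint((dots.positions[:, 1] + offset[1] - y0) / p).astype(int) - lo
    lum = np.where(dots.polarities > 0, spec.luminance_bright, spec.luminance_dark)
    visible = np.nonzero((ix > -s) & (ix < nx) & (iy > -s) & (iy < ny))[0]
    for k in visible:
        r0, r1 = max(iy[k], 0), min(iy[k] + s, ny)
        c0, c1 = max(ix[k], 0), min(ix[k] + s, nx)
        if r0 < r1 and c0 < c1:
            img[r0:r1, c0:c1] = lum[k]
    return img


def to_contrast(image: np.ndarray, spec: StimulusSpec) -> np.ndarray:
    """Weber contrast about the background (bright -> +1, dark -> -1)."""
    bg = spec.luminance_background
    return (image - bg) / bg


@dataclass
class StereogramSequence:
    """Rendered dynamic stereogram: per-frame left/right luminance images."""

    frames: list[tuple[np.ndarray, np.ndarray]]
    target_mask: np.ndarray
    reference_mask: np.ndarray
    spec: StimulusSpec
    window: Window
    seed: int | None = None

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def contrast_frames(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(to_contrast(l, self.spec), to_contrast(r, self.spec))
                for l, r in self.frames]


def frame_dot_fields(
    spec: StimulusSpec, rng: np.random.Generator
) -> tuple[DotField, DotField]:
    """One frame's left/right dot fields, disparity and correlation applied."""
    dots = full_dot_field(spec, rng)
    left, right = apply_disparity(dots, spec.target_disparity, spec.disparity_split)
    if spec.correlation == "anticorrelated":
        left, right = anticorrelate(left, right, spec.anticorrelated_eye)
    return left, right


def render_sequence(
    spec: StimulusSpec,
    seed: int | np.random.Generator | None = None,
    window: Window | None = None,
) -> StereogramSequence:
    """Render a dynamic stereogram: dots independently repositioned each frame.

    With an integer seed the output is bit-reproducible.  A custom
    `window` restricts rasterisation to a crop (the dots are still drawn
    from the full stimulus); by default the full canvas is used.
    """
    if window is None:
        window = default_canvas(spec)
    if isinstance(seed, np.random.Generator):
        rng, seed_val = seed, None
    else:
        rng, seed_val = np.random.default_rng(seed), seed
    geom = RegionGeometry.for_configuration(spec.configuration)
    ext = geom.outer_extent() + spec.eccentricity_arcmin
    span = max(abs(window.x[0]), abs(window.x[-1]),
               abs(window.y[0]), abs(window.y[-1]))
    is_canvas = (window.centre == (0.0, 0.0)
                 and span >= geom.outer_extent() - spec.pixel_pitch)
    if is_canvas and ext > span + spec.dot_size:
        raise ValueError("stimulus extends beyond the canvas; enlarge the window")
    frames = []
    for _ in range(spec.duration_frames):
        left, right = frame_dot_fields(spec, rng)
        frames.append((rasterize(left, spec, window),
                       rasterize(right, spec, window)))
    offset = spec.centre_offset
    return StereogramSequence(
        frames=frames,
        target_mask=geom.mask("target", window, offset),
        reference_mask=geom.mask("reference", window, offset),
        spec=spec,
        window=window,
        seed=seed_val,
    )


def write_sequence(seq: StereogramSequence, outdir: str | Path) -> Path:
    """Write frames as 8-bit grayscale PNG pairs plus masks and metadata."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    peak = max(seq.spec.luminance_bright, seq.spec.luminance_background,
               seq.spec.luminance_dark, 1e-9)
    for i, (left, right) in enumerate(seq.frames, start=1):
        for eye, img in (("L", left), ("R", right)):
            u8 = np.clip(img / peak * 255.0, 0, 255).astype(np.uint8)
            iio.imwrite(outdir / f"f{i:04d}_{eye}.png", u8)
    iio.imwrite(outdir / "mask_target.png",
                (seq.target_mask * 255).astype(np.uint8))
    iio.imwrite(outdir / "mask_reference.png",
                (seq.reference_mask * 255).astype(np.uint8))
    meta = {"spec": asdict(seq.spec), "seed": seq.seed,
            "n_frames": seq.n_frames, "shape": list(seq.window.shape),
            "pixel_pitch": seq.window.pixel_pitch}
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=2))
    return outdir
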