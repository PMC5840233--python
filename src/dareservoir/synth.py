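"""Synthetic labelled "action clips" for exercising the whole pipeline.

Each clip is a short grayscale video of a textured foreground object moving
with a class-specific motion signature (horizontal oscillation, vertical
translation with bounce, circular orbit, or breathing expansion) over a
static background, optionally degraded by background clutter, whole-frame
jitter (camera shake) and salt-and-pepper flips.  The fine-grained texture
makes the moving object light up the frame-difference encoder over its whole
footprint, the way a real articulated subject does, so the downstream
activity filters see realistic active-pixel fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = ["SceneSpec", "Clip", "generate_clip", "generate_dataset",
           "default_class_specs"]

MOTION_CLASSES = ("oscillate_x", "translate_y", "circular", "expand")


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    Sizes in pixels, speed in px/frame, intensities in 8-bit grey levels.
    ``texture_contrast`` is the half-range of the object's per-pixel texture;
    it must comfortably exceed the encoder's binarization level for the
    moving object to register.  The default nuisance levels (no jitter, no
    clutter, no flip noise) emulate the clean static-background clips that
    few-shot action recognition is typically demonstrated on; the knobs are
    there to degrade them.
    """

    image_size: tuple[int, int] = (200, 300)
    n_frames: int = 120
    object_shape: str = "square"       # square | disc | bar
    object_size: int = 120
    motion_class: str = "oscillate_x"  # oscillate_x | translate_y | circular | expand
    speed: float = 2.0
    jitter_sigma: float = 0.0
    clutter_density: float = 0.0
    noise_flip_prob: float = 0.0
    seed: int = 0
    background: str = "uniform"        # uniform | texture
    bg_level: int = 32
    fg_level: int = 128
    texture_contrast: int = 32
    phase: float = 0.0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if self.object_size > min(h, w):
            raise ValueError(
                f"object_size {self.object_size} exceeds frame {self.image_size}"
            )
        if self.object_shape not in ("square", "disc", "bar"):
            raise ValueError(f"unknown object_shape {self.object_shape!r}")
        if self.motion_class not in MOTION_CLASSES:
            raise ValueError(f"unknown motion_class {self.motion_class!r}")
        for name in ("noise_flip_prob",):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0.0 <= self.clutter_density <= 1.0):
            raise ValueError("clutter_density must be in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass
class Clip:
    frames: np.ndarray   # (T, H, W) uint8
    label: str
    spec: SceneSpec


def _object_mask(shape: str, size: int) -> np.ndarray:
    if shape == "square":
        return np.ones((size, size), dtype=bool)
    if shape == "disc":
        r = size / 2.0
        yy, xx = np.ogrid[:size, :size]
        return (yy - r + 0.5) ** 2 + (xx - r + 0.5) ** 2 <= r * r
    # bar: horizontal, half as tall as wide
    mask = np.zeros((size, size), dtype=bool)
    q = max(1, size // 4)
    mask[size // 2 - q:size // 2 + q, :] = True
    return mask


def _trajectory(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Object center (row, col) per frame, guaranteed inside the frame."""
    h, w = spec.image_size
    half = spec.object_size / 2.0
    t = np.arange(spec.n_frames, dtype=float)
    cy = np.full_like(t, h / 2.0)
    cx = np.full_like(t, w / 2.0)
    if spec.motion_class == "oscillate_x":
        amp = max(2.0, (w - spec.object_size) / 2.0 - 1.0)
        omega = spec.speed / amp
        cx = w / 2.0 + amp * np.sin(omega * t + spec.phase)
    elif spec.motion_class == "translate_y":
        lo, hi = half + 1.0, h - half - 1.0
        span = hi - lo
        # triangle wave: constant |speed| with bounces at the margins
        pos = np.abs(((spec.speed * t + spec.phase * span) / span + 1.0) % 2.0 - 1.0)
        cy = lo + pos * span
    elif spec.motion_class == "circular":
        rad = max(2.0, (min(h, w) - spec.object_size) / 2.0 - 1.0)
        omega = spec.speed / rad
        cy = h / 2.0 + rad * np.sin(omega * t + spec.phase)
        cx = w / 2.0 + rad * np.cos(omega * t + spec.phase)
    # 'expand' keeps a fixed center; the size modulation happens at draw time
    cy = np.clip(cy, half, h - half)
    cx = np.clip(cx, half, w - half)
    return np.stack([cy, cx], axis=1)


def generate_clip(spec: SceneSpec) -> Clip:
    """Render one clip; deterministic for a fixed spec (incl. its seed)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    size = spec.object_size
    c = spec.texture_contrast
    # per-clip static texture patch, rigidly attached to the object
    texture = rng.uniform(spec.fg_level - c, spec.fg_level + c,
                          size=(size, size))
    mask = _object_mask(spec.object_shape, size)
    if spec.background == "texture":
        background = rng.uniform(spec.bg_level - c // 2, spec.bg_level + c // 2,
                                 size=(h, w))
    else:
        background = np.full((h, w), float(spec.bg_level))
    centers = _trajectory(spec, rng)

    n_clutter = int(round(spec.clutter_density * h * w / 9.0))
    clutter_pos = rng.uniform(0, [h - 3, w - 3], size=(n_clutter, 2))
    clutter_val = rng.uniform(spec.bg_level + 16, spec.fg_level,
                              size=n_clutter)

    if spec.motion_class == "expand":
        sizes = np.rint(
            size * (0.75 + 0.25 * np.sin(
                2.0 * np.pi * np.arange(spec.n_frames)
                / max(10.0, 2.0 * size / max(spec.speed, 1e-6))
                + spec.phase))
        ).astype(int)
        sizes = np.clip(sizes, 4, size)
    else:
        sizes = np.full(spec.n_frames, size, dtype=int)

    frames = np.empty((spec.n_frames, h, w), dtype=np.uint8)
    for i in range(spec.n_frames):
        frame = background.copy()
        # clutter: small independently wandering distractors
        if n_clutter:
            clutter_pos += rng.integers(-2, 3, size=clutter_pos.shape)
            np.clip(clutter_pos, [0, 0], [h - 3, w - 3], out=clutter_pos)
            for (r, cc), v in zip(clutter_pos.astype(int), clutter_val):
                frame[r:r + 3, cc:cc + 3] = v
        s_i = sizes[i]
        if s_i == size:
            tex, msk = texture, mask
        else:
            # breathing object: nearest-neighbour zoom of the whole texture,
            # so the interior flows radially as the object expands/contracts
            idx = np.minimum((np.arange(s_i) * (size / s_i)).astype(int),
                             size - 1)
            tex = texture[np.ix_(idx, idx)]
            msk = _object_mask(spec.object_shape, s_i)
        r0 = int(round(centers[i, 0] - s_i / 2.0))
        c0 = int(round(centers[i, 1] - s_i / 2.0))
        r0 = min(max(r0, 0), h - s_i)
        c0 = min(max(c0, 0), w - s_i)
        region = frame[r0:r0 + s_i, c0:c0 + s_i]
        region[msk] = tex[msk]
        # whole-frame jitter: integer camera shake, background-filled
        if spec.jitter_sigma > 0:
            dy, dx = np.rint(rng.normal(0.0, spec.jitter_sigma, 2)).astype(int)
            shifted = np.full_like(frame, float(spec.bg_level))
            ys, yd = (dy, 0) if dy >= 0 else (0, -dy)
            xs, xd = (dx, 0) if dx >= 0 else (0, -dx)
            shifted[ys:h - yd, xs:w - xd] = frame[yd:h - ys, xd:w - xs]
            frame = shifted
        if spec.noise_flip_prob > 0:
            flip = rng.random((h, w)) < spec.noise_flip_prob
            frame[flip] = 255.0 - frame[flip]
        frames[i] = np.clip(frame, 0, 255).astype(np.uint8)
    return Clip(frames=frames, label=spec.motion_class, spec=spec)


def default_class_specs(
    image_size: tuple[int, int] = (80, 80),
    n_frames: int = 120,
) -> dict[str, SceneSpec]:
    """Three separable motion classes at fixture scale.

    The object occupies just over half the frame side: its textured footprint
    keeps the encoded activity above the codec's minimum-activity bound (the
    whole-frame jitter filter would otherwise discard sparse frames), while
    its moving edges — the actual motion signature — stay within reach of the
    fixation windows.  Texture contrast is moderate so the edge bands stand
    out against the interior churn.
    """
    size = max(8, round(min(image_size) * 0.55))
    base = dict(image_size=image_size, n_frames=n_frames, object_size=size,
                texture_contrast=10)
    # speeds are spread so the classes' characteristic rhythms do not
    # coincide: fast horizontal shake (~13-frame period), slow vertical
    # bounce (~35), and a orbit (~21) whose edge orientation rotates
    return {
        "oscillate_x": SceneSpec(motion_class="oscillate_x", speed=8.0, **base),
        "translate_y": SceneSpec(motion_class="translate_y", speed=2.0, **base),
        "circular": SceneSpec(motion_class="circular", speed=5.0, **base),
    }


def generate_dataset(
    class_specs,
    n_train_per_class: int,
    n_test_per_class: int,
    seed: int = 0,
    size_jitter: float = 0.05,
    speed_jitter: float = 0.08,
) -> tuple[list[Clip], list[Clip]]:
    """Sample labelled train/test clips with within-class variation.

    ``class_specs`` maps class name -> base :class:`SceneSpec` (or is a
    sequence of (name, spec) pairs).  Per clip, object size and speed are
    scaled by uniform factors in [1 - jitter, 1 + jitter] and the motion
    phase is randomized; train and test draw from disjoint seed streams.
    """
    if not isinstance(class_specs, dict):
        pairs = list(class_specs)
        names = [n for n, _ in pairs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate class names")
        class_specs = dict(pairs)
    if len(class_specs) < 2:
        raise ValueError("need at least 2 classes")
    motions = [s.motion_class for s in class_specs.values()]
    if len(set(motions)) != len(motions):
        warnings.warn(
            "two classes share the same motion_class; they are "
            "indistinguishable by design", UserWarning,
        )

    def _sample(base: SceneSpec, rng: np.random.Generator, clip_seed: int) -> Clip:
        size = int(round(base.object_size
                         * rng.uniform(1.0 - size_jitter, 1.0 + size_jitter)))
        size = min(size, min(base.image_size))
        speed = base.speed * rng.uniform(1.0 - speed_jitter, 1.0 + speed_jitter)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        spec = replace(base, object_size=size, speed=speed, phase=phase,
                       seed=clip_seed)
        return generate_clip(spec)

    train: list[Clip] = []
    test: list[Clip] = []
    for ci, (name, base) in enumerate(sorted(class_specs.items())):
        rng_train = np.random.default_rng([seed, ci, 0])
        rng_test = np.random.default_rng([seed, ci, 1])
        for j in range(n_train_per_class):
            clip = _sample(base, rng_train,
                           int(rng_train.integers(0, 2**31)))
            clip.label = name
            train.append(clip)
        for j in range(n_test_per_class):
            clip = _sample(base, rng_test,
                           int(rng_test.integers(0, 2**31)))
            clip.label = name
            test.append(clip)
    return train, test
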