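"""Synthetic wheat-seed image generator.

Emulates the structure of the real dataset — a single centred grain on a
near-black background, five visually distinct variety styles, two shooting
angles per grain (groin up shows the longitudinal crease, groin down hides
it) — so the full pipeline can be exercised without any download.  The
appearance model (a shaded ellipse with sinusoidal texture and a crease
line) is deliberately simple; its contract is determinism and class
separability, not realism.

Every pixel is a pure function of (style, grain seed, angle, canvas, noise
level): the two angles of one grain share geometry, colour jitter and
background noise and differ only in the crease rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .data_io import SeedImageRecord, format_filename, load_image, write_manifest

__all__ = [
    "VarietyStyle",
    "GeneratorConfig",
    "default_styles",
    "render_seed",
    "generate_dataset",
    "separability_probe",
]


@dataclass(frozen=True)
class VarietyStyle:
    """Appearance parameters of one synthetic variety.

    Semi-axes are fractions of the canvas so styles scale with resolution;
    ``axis_jitter`` is the relative per-grain variation.  ``texture_freq`` is
    in cycles per grain length; ``crease_depth`` is the multiplicative
    darkening of the crease line (0 = invisible).
    """

    name: str
    semi_major: float
    semi_minor: float
    base_color: tuple[float, float, float]
    texture_freq: float
    texture_amp: float = 0.08
    crease_depth: float = 0.45
    axis_jitter: float = 0.06

    def __post_init__(self):
        if not (0 < self.semi_minor <= self.semi_major < 0.5):
            raise ValueError("semi-axes must satisfy 0 < minor <= major < 0.5 canvas")
        if any(not 0.0 <= c <= 1.0 for c in self.base_color):
            raise ValueError("base colour channels must lie in [0, 1]")


# Five stock styles, pairwise distinct in colour, elongation and texture
# frequency.  Colours are deliberately spread across hue space (pale cream,
# red-brown, golden, olive, dark violet-brown) so that a trivial mean-colour
# probe separates the classes — the generator's signal guarantee.
_DEFAULT_STYLES = (
    VarietyStyle("baimai1811", 0.34, 0.20, (0.88, 0.80, 0.55), 3.0),
    VarietyStyle("huaimai40", 0.30, 0.24, (0.72, 0.33, 0.20), 5.0),
    VarietyStyle("kelin201", 0.38, 0.17, (0.92, 0.62, 0.12), 2.0),
    VarietyStyle("xinong156", 0.28, 0.19, (0.42, 0.55, 0.25), 6.0),
    VarietyStyle("zhongmai698", 0.33, 0.26, (0.38, 0.24, 0.38), 4.0),
)


def default_styles(num_classes: int = 5) -> list[VarietyStyle]:
    """The five stock variety styles; beyond five, extra styles are derived
    by rotating the base hue."""
    styles = list(_DEFAULT_STYLES[:num_classes])
    for i in range(len(styles), num_classes):
        base = _DEFAULT_STYLES[i % len(_DEFAULT_STYLES)]
        r, g, b = base.base_color
        styles.append(VarietyStyle(
            f"synthetic{i}", base.semi_major, base.semi_minor,
            (b, r, g), base.texture_freq + 1.5))
    return styles


@dataclass
class GeneratorConfig:
    """Generation conditions.

    Defaults mirror the real dataset's structure: 5 balanced classes, both
    shooting angles per grain, a near-black background.  The canvas default
    matches the model's 224-pixel input; a 64-pixel canvas is the fast mode
    used for small-scale experiments.
    """

    classes: int = 5
    images_per_class: int = 50
    canvas_size: int = 224
    both_angles: bool = True
    noise_level: float = 0.02
    seed: int = 0
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.classes < 1:
            raise ValueError("need at least one class")
        if self.both_angles and self.images_per_class < 2:
            raise ValueError("images_per_class must be >= 2 when both angles are "
                             "rendered per grain")
        if self.noise_level < 0:
            raise ValueError("noise_level must be non-negative")
        if self.class_names and len(self.class_names) != self.classes:
            raise ValueError("class_names length must equal classes")


def render_seed(style: VarietyStyle, grain_seed, angle: int,
                canvas_size: int = 224, noise_level: float = 0.02) -> np.ndarray:
    """Render one grain image as an (S, S, 3) uint8 array.

    All random draws (axis jitter, rotation, translation, colour jitter,
    texture phase, background noise) come from a generator seeded with
    ``grain_seed`` and are made before the angle is consulted, so the two
    angles of a grain differ only where the crease is drawn (angle 1, groin
    up, shows it; angle 2 hides it).
    """
    if angle not in (1, 2):
        raise ValueError(f"angle must be 1 or 2, got {angle}")
    s = canvas_size
    rng = np.random.default_rng(grain_seed)
    # grain geometry and appearance jitter (angle-independent draws)
    a = style.semi_major * s * (1.0 + style.axis_jitter * rng.standard_normal())
    b = style.semi_minor * s * (1.0 + style.axis_jitter * rng.standard_normal())
    theta = np.deg2rad(rng.uniform(-15.0, 15.0))
    cx = s / 2 + rng.uniform(-0.02, 0.02) * s
    cy = s / 2 + rng.uniform(-0.02, 0.02) * s
    color = np.clip(np.asarray(style.base_color)
                    * (1.0 + 0.05 * rng.standard_normal(3)), 0.0, 1.0)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    bg_noise = rng.standard_normal((s, s, 1))

    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)   # along major axis
    v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)  # along minor axis
    r2 = (u / a) ** 2 + (v / b) ** 2
    mask = r2 <= 1.0

    img = np.clip(0.03 + noise_level * bg_noise, 0.0, 1.0)
    img = np.repeat(img, 3, axis=2)

    shading = 1.0 - 0.30 * r2  # convex-grain highlight falling off outward
    texture = 1.0 + style.texture_amp * np.sin(
        2.0 * np.pi * style.texture_freq * u / (2.0 * a) + phase)
    grain = shading * texture
    if angle == 1:  # groin up: longitudinal crease along the major axis
        crease_half_width = 0.10 * b
        crease = np.abs(v) < crease_half_width
        grain = np.where(crease & mask, grain * (1.0 - style.crease_depth), grain)
    pixels = np.clip(color[None, None, :] * grain[:, :, None], 0.0, 1.0)
    img = np.where(mask[:, :, None], pixels, img)
    return (img * 255.0 + 0.5).astype(np.uint8)


def generate_dataset(cfg: GeneratorConfig, out_dir) -> list[SeedImageRecord]:
    """Write a folder-per-variety tree of PNG images plus a manifest CSV.

    Filenames follow the ``particle-grain-angle`` grammar.  With
    ``both_angles`` every grain appears twice (an odd image count leaves the
    last grain groin-up only).  The entire tree is a pure function of the
    config; identical configs produce identical file bytes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    styles = default_styles(cfg.classes)
    names = cfg.class_names or [st.name for st in styles]
    records: list[SeedImageRecord] = []
    for cls_idx, (style, name) in enumerate(zip(styles, names)):
        class_dir = out / name
        class_dir.mkdir(exist_ok=True)
        angles_per_grain = 2 if cfg.both_angles else 1
        n_grains = -(-cfg.images_per_class // angles_per_grain)  # ceil
        written = 0
        for grain in range(1, n_grains + 1):
            for angle in range(1, angles_per_grain + 1):
                if written >= cfg.images_per_class:
                    break
                fname = format_filename(grain, cls_idx + 1, angle)
                path = class_dir / fname
                arr = render_seed(style, [cfg.seed, cls_idx, grain],
                                  angle, cfg.canvas_size, cfg.noise_level)
                Image.fromarray(arr).save(path)
                records.append(SeedImageRecord(
                    variety_label=name, particle_id=grain, grain_index=cls_idx + 1,
                    angle=angle, path=str(path)))
                written += 1
    write_manifest(records, out / "manifest.csv")
    return records


def separability_probe(dataset) -> float:
    """Accuracy of a nearest-centroid classifier on mean-RGB features.

    A fixture quality gate: the default styles must score well above chance,
    guaranteeing the generated data carries learnable class signal.
    ``dataset`` is a list of records or a root directory.
    """
    if isinstance(dataset, (str, Path)):
        from .data_io import scan_dataset
        dataset, _ = scan_dataset(dataset)
    if not dataset:
        raise ValueError("cannot probe an empty dataset")
    labels = sorted({r.variety_label for r in dataset})
    index = {name: i for i, name in enumerate(labels)}
    feats = np.stack([
        load_image(r.path).reshape(-1, 3).mean(axis=0) for r in dataset])
    y = np.asarray([index[r.variety_label] for r in dataset])
    centroids = np.stack([feats[y == k].mean(axis=0) for k in range(len(labels))])
    dists = ((feats[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return float((dists.argmin(axis=1) == y).mean())
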