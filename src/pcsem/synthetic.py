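"""Seeded generator of laparoscopy-like multi-label tool-presence scenes.

The generator does not attempt photorealism.  It reproduces the *statistical
shape* of the real task so the full pipeline (I/O → training → evaluation →
Grad-CAM) can be exercised without external data:

* 7 tool classes with visually distinct parametric silhouettes and colours
  (two-jaw grasper, paddle bipolar, L-hook, open scissors, pronged clipper,
  tube irrigator, bag polygon), each with a defined *tip* region;
* severe class imbalance — default marginal presence probabilities are
  proportional to the training-set class counts of the real corpus, under
  which the two dominant tools (grasper, hook) hold > 83 % of tool labels;
* multi-tool co-occurrence with a configurable pairwise boost;
* tissue-like low-frequency red-pink backgrounds and specular-highlight
  noise blobs;
* the annotation rule that a tool is labelled present only when at least
  half of its tip is visible — later-composited sprites occlude earlier
  ones, and an occluded tip clears the flag.

Everything is driven by one integer-seeded generator: identical seeds give
bitwise-identical images and annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.draw import disk, polygon
from skimage.transform import resize, rotate

from .data_io import TOOL_NAMES, AnnotationTable, write_tool_annotations

# marginal presence probabilities proportional to the real training-set
# class counts (86,304 annotated frames)
_TRAIN_COUNTS = np.array([56800, 4106, 48437, 1624, 3217, 5384, 5760], dtype=float)
DEFAULT_CLASS_PROBS = _TRAIN_COUNTS / 86304.0

TOOL_COLORS = np.array([
    [0.82, 0.82, 0.88],   # grasper: steel
    [0.25, 0.45, 0.95],   # bipolar: blue
    [0.95, 0.85, 0.20],   # hook: yellow
    [0.25, 0.85, 0.35],   # scissors: green
    [0.20, 0.85, 0.90],   # clipper: cyan
    [0.90, 0.30, 0.90],   # irrigator: magenta
    [0.97, 0.97, 0.92],   # specimen bag: off-white
])


@dataclass
class SceneSpec:
    """Statistical description of a synthetic scene distribution."""

    image_size: tuple[int, int] = (224, 224)
    class_probs: np.ndarray = field(default_factory=lambda: DEFAULT_CLASS_PROBS.copy())
    cooccurrence: np.ndarray = field(default_factory=lambda: np.zeros((7, 7)))
    max_tools_per_frame: int = 3
    highlight_prob: float = 0.7
    highlight_intensity: float = 0.5
    tip_visibility_min: float = 0.5
    sprite_scale: tuple[float, float] = (0.38, 0.55)   # sprite size / image side
    seed: int = 0

    def __post_init__(self):
        self.class_probs = np.asarray(self.class_probs, dtype=float)
        if self.class_probs.shape != (7,):
            raise ValueError("class_probs must have length 7")
        if np.any((self.class_probs < 0) | (self.class_probs > 1)):
            raise ValueError("class_probs must lie in [0, 1]")
        if not 0 <= self.tip_visibility_min <= 1:
            raise ValueError("tip_visibility_min must lie in [0, 1]")


@dataclass
class SyntheticDataset:
    images: np.ndarray                 # (n, H, W, 3) uint8
    annotations: AnnotationTable
    truth_boxes: list[dict]            # per frame: class_id -> (r0, c0, r1, c1)
    spec: SceneSpec

    def __len__(self) -> int:
        return len(self.images)

    def label_matrix(self) -> np.ndarray:
        return self.annotations.canonical_matrix()

    def training_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(N,3,H,W) float32 in [-1,1] plus (N,7) float32 labels."""
        x = self.images.astype(np.float32) / 127.5 - 1.0
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2)), \
            self.label_matrix().astype(np.float32)


# ---------------------------------------------------------------------------
# sprites

def _canvas(s: int):
    return np.zeros((s, s, 3)), np.zeros((s, s)), np.zeros((s, s), dtype=bool)


def _paint(rgb, alpha, rr, cc, color, a=1.0):
    rgb[rr, cc] = color
    alpha[rr, cc] = np.maximum(alpha[rr, cc], a)


def _shaft(rgb, alpha, s, color, width=0.11, top=0.45):
    w = max(int(s * width), 1)
    r0, r1 = int(s * top), s - 1
    c0 = s // 2 - w // 2
    rr, cc = np.mgrid[r0:r1, c0:c0 + w]
    _paint(rgb, alpha, rr.ravel(), cc.ravel(), color)


def _tool_canvas(class_id: int, s: int):
    """Draw class ``class_id`` upright (tip at top) on an s×s canvas."""
    rgb, alpha, _ = _canvas(s)
    col = TOOL_COLORS[class_id]
    mid = s // 2
    if class_id == 0:        # grasper: shaft + two open jaws (V)
        _shaft(rgb, alpha, s, col)
        for sign in (-1, 1):
            rr, cc = polygon([s * 0.48, s * 0.02, s * 0.20],
                             [mid, mid + sign * s * 0.30, mid + sign * s * 0.42],
                             shape=(s, s))
            _paint(rgb, alpha, rr, cc, col)
    elif class_id == 1:      # bipolar: shaft + paddle (wide ellipse-ish polygon)
        _shaft(rgb, alpha, s, col)
        rr, cc = polygon([s * 0.50, s * 0.04, s * 0.04, s * 0.50],
                         [mid - s * 0.26, mid - s * 0.16, mid + s * 0.16, mid + s * 0.26],
                         shape=(s, s))
        _paint(rgb, alpha, rr, cc, col)
    elif class_id == 2:      # hook: shaft + horizontal bar (L)
        _shaft(rgb, alpha, s, col, top=0.25)
        rr, cc = polygon([s * 0.06, s * 0.06, s * 0.24, s * 0.24],
                         [mid - s * 0.10, mid + s * 0.42, mid + s * 0.42, mid - s * 0.10],
                         shape=(s, s))
        _paint(rgb, alpha, rr, cc, col)
    elif class_id == 3:      # scissors: two crossing open blades
        for sign in (-1, 1):
            rr, cc = polygon([s * 0.95, s * 0.02, s * 0.02, s * 0.95],
                             [mid - sign * s * 0.08, mid + sign * s * 0.38,
                              mid + sign * s * 0.24, mid - sign * s * 0.18],
                             shape=(s, s))
            _paint(rgb, alpha, rr, cc, col)
    elif class_id == 4:      # clipper: shaft + two parallel prongs (U)
        _shaft(rgb, alpha, s, col)
        for sign in (-1, 1):
            c0 = mid + sign * int(s * 0.22)
            rr, cc = np.mgrid[int(s * 0.02):int(s * 0.50),
                              c0 - max(int(s * 0.09), 1):c0]
            _paint(rgb, alpha, rr.ravel(), cc.ravel(), col)
        rr, cc = np.mgrid[int(s * 0.40):int(s * 0.50),
                          mid - int(s * 0.26):mid + int(s * 0.26)]
        _paint(rgb, alpha, rr.ravel(), cc.ravel(), col)
    elif class_id == 5:      # irrigator: thick tube with rounded tip
        _shaft(rgb, alpha, s, col, width=0.20, top=0.12)
        rr, cc = disk((int(s * 0.14), mid), s * 0.13, shape=(s, s))
        _paint(rgb, alpha, rr, cc, col)
    else:                    # specimen bag: pentagon blob
        ang = np.linspace(-np.pi / 2, 3 * np.pi / 2, 6)[:-1]
        rr, cc = polygon(s * 0.5 + s * 0.42 * np.sin(ang),
                         mid + s * 0.40 * np.cos(ang), shape=(s, s))
        _paint(rgb, alpha, rr, cc, col)
    tip = alpha > 0
    tip[int(s * 0.5):, :] = False        # tip = distal (upper) half of the silhouette
    return rgb, alpha, tip


def render_tool(class_id: int, pose: float, size: int,
                rng: np.random.Generator | None = None):
    """Render one tool sprite.

    Parameters
    ----------
    class_id : 0..6 in canonical tool order.
    pose : rotation angle in degrees (counter-clockwise).
    size : side of the square sprite canvas in pixels.
    rng : optional generator for per-sprite colour jitter.

    Returns ``(rgb, alpha, tip_mask, tip_box)`` with arrays of shape
    (size', size', 3)/(size', size') — the canvas grows under rotation — and
    ``tip_box = (r0, c0, r1, c1)`` bounding the tip region.
    """
    if not 0 <= class_id < 7:
        raise ValueError("class_id must be in 0..6")
    rgb, alpha, tip = _tool_canvas(class_id, int(size))
    if rng is not None:
        jitter = rng.uniform(-0.06, 0.06, size=3)
        rgb = np.clip(rgb + jitter * (alpha[..., None] > 0), 0, 1)
    if pose % 360 != 0:
        rgb = rotate(rgb, pose, resize=True, order=1, mode="constant", cval=0.0)
        alpha = rotate(alpha, pose, resize=True, order=1, mode="constant", cval=0.0)
        tip = rotate(tip.astype(float), pose, resize=True, order=1,
                     mode="constant", cval=0.0) > 0.5
    ys, xs = np.nonzero(tip)
    if len(ys):
        tip_box = (int(ys.min()), int(xs.min()), int(ys.max()) + 1, int(xs.max()) + 1)
    else:
        tip_box = (0, 0, 0, 0)
    return rgb, alpha, tip, tip_box


# ---------------------------------------------------------------------------
# scenes

def _background(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    base = np.array([0.55, 0.22, 0.24])
    coarse = base + rng.normal(0, 0.10, size=(6, 6, 3))
    bg = resize(coarse, (h, w, 3), order=3, mode="reflect", anti_aliasing=False)
    bg += rng.normal(0, 0.02, size=bg.shape)
    return np.clip(bg, 0, 1)


def _sample_presence(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    present = np.zeros(7, dtype=bool)
    for c in range(7):
        p = spec.class_probs[c]
        if present.any():
            p = p + spec.cooccurrence[c][present].sum()
        present[c] = rng.random() < np.clip(p, 0.0, 1.0)
    if present.sum() > spec.max_tools_per_frame:
        on = np.flatnonzero(present)
        drop = rng.choice(on, size=present.sum() - spec.max_tools_per_frame,
                          replace=False)
        present[drop] = False
    return present


def _render_scene(spec: SceneSpec, rng: np.random.Generator):
    h, w = spec.image_size
    img = _background(h, w, rng)
    present = _sample_presence(spec, rng)
    owner = np.full((h, w), -1, dtype=np.int8)      # topmost tool at each pixel
    tips: dict[int, np.ndarray] = {}
    sprite_masks: dict[int, np.ndarray] = {}
    for cid in np.flatnonzero(present):             # fixed compositing order
        pose = rng.uniform(0.0, 360.0)
        size = int(rng.uniform(*spec.sprite_scale) * min(h, w))
        rgb, alpha, tip, _ = render_tool(int(cid), pose, size, rng)
        sh, sw = alpha.shape
        r0 = rng.integers(0, max(h - sh, 0) + 1)
        c0 = rng.integers(0, max(w - sw, 0) + 1)
        sl = (slice(r0, min(r0 + sh, h)), slice(c0, min(c0 + sw, w)))
        a = alpha[:sl[0].stop - r0, :sl[1].stop - c0]
        img[sl] = img[sl] * (1 - a[..., None]) + rgb[:a.shape[0], :a.shape[1]] * a[..., None]
        solid = a > 0.5
        owner[sl][solid] = cid
        full_tip = np.zeros((h, w), dtype=bool)
        full_tip[sl] = tip[:a.shape[0], :a.shape[1]]
        tips[int(cid)] = full_tip
        full_mask = np.zeros((h, w), dtype=bool)
        full_mask[sl] = solid
        sprite_masks[int(cid)] = full_mask
    flags = np.zeros(7, dtype=np.int8)
    boxes: dict[int, tuple] = {}
    for cid, tipmask in tips.items():
        total = tipmask.sum()
        visible = (tipmask & (owner == cid)).sum()
        if total > 0 and visible / total >= spec.tip_visibility_min:
            flags[cid] = 1
            vis = sprite_masks[cid] & (owner == cid)
            ys, xs = np.nonzero(vis)
            boxes[cid] = (int(ys.min()), int(xs.min()),
                          int(ys.max()) + 1, int(xs.max()) + 1)
    if rng.random() < spec.highlight_prob:
        for _ in range(rng.poisson(2) + 1):
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
            rad = rng.uniform(0.02, 0.06) * min(h, w)
            rr, cc = disk((cy, cx), rad, shape=(h, w))
            img[rr, cc] = np.clip(
                img[rr, cc] + spec.highlight_intensity * rng.uniform(0.6, 1.0), 0, 1)
    return np.round(img * 255).astype(np.uint8), flags, boxes


def generate_dataset(spec: SceneSpec, n_images: int,
                     video_id: str = "synthetic") -> SyntheticDataset:
    """Sample ``n_images`` scenes; labels exactly reflect the rendered content.

    Frame indices follow the native 25 fps / 1 annotation-per-second cadence
    (0, 25, 50, ...).
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    images = np.empty((n_images, h, w, 3), dtype=np.uint8)
    flags = np.empty((n_images, 7), dtype=np.int8)
    boxes = []
    for i in range(n_images):
        images[i], flags[i], b = _render_scene(spec, rng)
        boxes.append(b)
    import pandas as pd

    table = AnnotationTable(video_id, np.arange(n_images, dtype=np.int64) * 25,
                            pd.DataFrame(flags, columns=TOOL_NAMES))
    return SyntheticDataset(images, table, boxes, spec)


def write_dataset(dataset: SyntheticDataset, outdir) -> Path:
    """PNG frames + annotation file in the standard dialect."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    vid = dataset.annotations.video_id
    (outdir / vid).mkdir(parents=True, exist_ok=True)
    for i, frame_idx in enumerate(dataset.annotations.frames):
        iio.imwrite(outdir / vid / f"{int(frame_idx)}.png", dataset.images[i])
    write_tool_annotations(dataset.annotations, outdir / f"{vid}-tool.txt")
    return outdir
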