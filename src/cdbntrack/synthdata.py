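"""Deterministic synthetic data: pretraining patches and tracking sequences.

Two generators support offline experimentation:

* :func:`make_class_dataset` — a 10-class labeled set of 32x32 patches
  built from parametric texture families (gratings, blobs, rings,
  corners, edges, checkerboards ...) with per-sample jitter and noise.
  It stands in for a generic natural-image pretraining corpus: the
  classes are learnably separable yet varied enough that convolutional
  features generalize across them.

* :func:`make_sequence` — grayscale time-lapse-like sequences of a
  bright blob ("cell") moving over a textured background, with the
  nuisances typical of dense microscopy video: clutter blobs of similar
  appearance, global illumination ramps, target intensity drift,
  additive noise and full occlusion windows. Ground truth is the true
  bounding box per frame.

Everything is reproducible: a scenario's seed fully determines its output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tracker import ObjectState

__all__ = ["SequenceScenario", "make_class_dataset", "make_sequence", "presets"]


# ---------------------------------------------------------------------------
# labeled patch dataset

def _grid(size):
    y, x = np.mgrid[0:size, 0:size].astype(float)
    return x - (size - 1) / 2.0, y - (size - 1) / 2.0


def _class_patch(label: int, size: int, rng: np.random.Generator) -> np.ndarray:
    """One sample of texture family ``label`` with its jitter drawn from rng."""
    x, y = _grid(size)
    amp = rng.uniform(0.8, 1.2)
    dx, dy = rng.uniform(-1.5, 1.5, size=2)
    if label == 0:      # horizontal grating (wide stripes)
        p = np.sin(2 * np.pi * (y + dy) / 12.0)
    elif label == 1:    # vertical grating
        p = np.sin(2 * np.pi * (x + dx) / 12.0)
    elif label == 2:    # diagonal grating
        p = np.sin(2 * np.pi * (x + y + dx) / 16.0)
    elif label == 3:    # coarse checkerboard
        p = np.sign(np.sin(2 * np.pi * (x + dx) / 16.0)
                    * np.sin(2 * np.pi * (y + dy) / 16.0))
    elif label == 4:    # centered blob
        p = np.exp(-((x - dx) ** 2 + (y - dy) ** 2) / (2 * 5.0**2)) * 2 - 1
    elif label == 5:    # ring
        r = np.hypot(x - dx, y - dy)
        p = np.exp(-((r - 9.0) ** 2) / (2 * 2.5**2)) * 2 - 1
    elif label == 6:    # bright corner wedge
        p = np.where((x + dx > 0) & (y + dy > 0), 1.0, -1.0)
    elif label == 7:    # vertical step edge
        p = np.tanh((x + dx) / 2.0)
    elif label == 8:    # concentric square frame
        d = np.maximum(np.abs(x - dx), np.abs(y - dy))
        p = np.exp(-((d - 10.0) ** 2) / (2 * 2.0**2)) * 2 - 1
    elif label == 9:    # 2x2 grid of small blobs
        p = -np.ones_like(x)
        for ox in (-8, 8):
            for oy in (-8, 8):
                p += 2 * np.exp(-((x - ox - dx) ** 2 + (y - oy - dy) ** 2)
                                / (2 * 3.0**2))
    else:
        raise ValueError(f"no texture family for label {label}")
    return amp * p


def make_class_dataset(n_per_class: int, n_classes: int = 10, seed: int = 0,
                       channels: int = 3, size: int = 32,
                       noise_sigma: float = 0.1):
    """Balanced labeled patch set; returns ``(X, y)``.

    ``X`` is ``(n_per_class * n_classes, size, size, channels)`` float in
    roughly [0, 1]; ``y`` are integer labels. Multi-channel samples carry
    a mild class-specific tint so color is weakly informative, as in
    natural-image corpora.
    """
    if n_classes < 2:
        raise ValueError("need at least two classes")
    if n_classes > 10:
        raise ValueError("at most 10 texture families are defined")
    rng = np.random.default_rng(seed)
    X = np.empty((n_per_class * n_classes, size, size, channels))
    y = np.empty(n_per_class * n_classes, dtype=int)
    tints = 1.0 + 0.15 * np.sin(
        np.arange(n_classes)[:, None] * 2.4 + np.arange(channels)[None, :])
    i = 0
    for c in range(n_classes):
        for _ in range(n_per_class):
            base = _class_patch(c, size, rng)
            base = (base - base.min()) / (np.ptp(base) + 1e-9)
            for ch in range(channels):
                X[i, :, :, ch] = base * tints[c, ch]
            X[i] += rng.normal(0.0, noise_sigma, size=X[i].shape)
            y[i] = c
            i += 1
    order = rng.permutation(i)
    return X[order], y[order]


# ---------------------------------------------------------------------------
# tracking sequences

@dataclass
class SequenceScenario:
    """Full description of a synthetic tracking sequence.

    Geometry is (height, width); the target is a Gaussian blob whose
    ground-truth box is a square of side ``3 * radius`` centered on the
    blob. Motion is linear (``velocity`` px/frame) with an optional
    sinusoidal vertical component. Nuisance knobs: per-frame relative
    intensity drift of the target, a global linear illumination ramp over
    the sequence (peak-to-peak fraction of full scale), additive Gaussian
    noise, similar-appearance clutter blobs, and a full-occlusion window
    during which an occluding patch covers the target.
    """

    frame_shape: tuple = (240, 320)
    n_frames: int = 60
    start: tuple = (60.0, 60.0)          # initial blob center (x, y)
    velocity: tuple = (2.0, 1.0)         # px per frame
    sine_amplitude: float = 0.0
    sine_period: float = 40.0
    radius: float = 8.0
    peak_intensity: float = 0.8
    background: float = 0.15
    intensity_drift: float = 0.0         # relative change per frame
    illumination_amplitude: float = 0.0  # peak-to-peak temporal ramp
    noise_sigma: float = 0.0
    n_clutter: int = 0
    clutter_intensity: float | None = None
    occluder: tuple | None = None        # (start_frame, duration, intensity)
    occluder_scale: float = 2.0
    seed: int = 0

    def centers(self) -> np.ndarray:
        t = np.arange(self.n_frames, dtype=float)
        cx = self.start[0] + self.velocity[0] * t
        cy = (self.start[1] + self.velocity[1] * t
              + self.sine_amplitude * np.sin(2 * np.pi * t / self.sine_period))
        return np.stack([cx, cy], axis=1)

    def boxes(self) -> list[ObjectState]:
        side = 3.0 * self.radius
        return [ObjectState(cx - side / 2, cy - side / 2, side, side)
                for cx, cy in self.centers()]

    def validate(self) -> None:
        H, W = self.frame_shape
        for t, b in enumerate(self.boxes()):
            if b.x < 1 or b.y < 1 or b.x + b.w > W - 1 or b.y + b.h > H - 1:
                raise ValueError(
                    f"motion spec pushes the target out of frame at frame {t}")
        if self.occluder is not None:
            start, duration, _ = self.occluder
            if start < 0 or start + duration > self.n_frames:
                raise ValueError("occlusion window outside the sequence")


def _blob(H, W, cx, cy, radius, intensity):
    y, x = np.mgrid[0:H, 0:W].astype(float)
    sigma = radius / 1.5
    return intensity * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * sigma**2))


def make_sequence(scenario: SequenceScenario, return_masks: bool = False):
    """Render a scenario into 8-bit frames plus ground truth.

    Returns ``(frames, gt)`` — a list of (H, W) uint8 arrays and a list of
    :class:`ObjectState` — or ``(frames, gt, masks)`` when
    ``return_masks`` is set, where each mask entry records the target and
    occluder support (for measuring occlusion coverage).
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    H, W = scenario.frame_shape
    centers = scenario.centers()
    gt = scenario.boxes()

    clutter = []
    cint = (scenario.clutter_intensity if scenario.clutter_intensity is not None
            else 0.85 * scenario.peak_intensity)
    for _ in range(scenario.n_clutter):
        clutter.append(dict(
            x=rng.uniform(10, W - 10), y=rng.uniform(10, H - 10),
            vx=rng.uniform(-0.5, 0.5), vy=rng.uniform(-0.5, 0.5),
            r=scenario.radius * rng.uniform(0.7, 1.3),
            i=cint * rng.uniform(0.8, 1.2)))

    frames, masks = [], []
    for t in range(scenario.n_frames):
        ramp = scenario.illumination_amplitude * (t / max(scenario.n_frames - 1, 1) - 0.5)
        img = np.full((H, W), scenario.background + ramp)
        for c in clutter:
            img += _blob(H, W, c["x"] + c["vx"] * t, c["y"] + c["vy"] * t,
                         c["r"], c["i"])
        tgt_int = scenario.peak_intensity * (1.0 + scenario.intensity_drift * t)
        tgt = _blob(H, W, centers[t, 0], centers[t, 1], scenario.radius, tgt_int)
        img += tgt
        tgt_mask = tgt > 0.1 * tgt_int

        occ_mask = np.zeros((H, W), dtype=bool)
        if scenario.occluder is not None:
            start, duration, occ_int = scenario.occluder
            if start <= t < start + duration:
                side = scenario.occluder_scale * 3.0 * scenario.radius
                x0 = int(round(centers[t, 0] - side / 2))
                y0 = int(round(centers[t, 1] - side / 2))
                x1, y1 = int(x0 + side), int(y0 + side)
                x0, y0 = max(x0, 0), max(y0, 0)
                occ_mask[y0:min(y1, H), x0:min(x1, W)] = True
                img[occ_mask] = occ_int

        if scenario.noise_sigma > 0:
            img += rng.normal(0.0, scenario.noise_sigma, size=img.shape)
        frames.append((np.clip(img, 0.0, 1.0) * 255).round().astype(np.uint8))
        masks.append(dict(target=tgt_mask, occluder=occ_mask))
    if return_masks:
        return frames, gt, masks
    return frames, gt


def presets() -> dict[str, SequenceScenario]:
    """Named scenarios covering the study conditions.

    * ``linear-clean`` — constant-velocity target, no nuisances.
    * ``illumination-ramp`` — global brightness ramp plus noise.
    * ``occlusion-10`` — a 10-frame full occlusion mid-sequence.
    * ``cell-dense`` — many similar low-contrast blobs, mild ramp and
      noise, emulating dense time-lapse microscopy.
    """
    return {
        "linear-clean": SequenceScenario(
            n_frames=60, start=(60.0, 70.0), velocity=(3.0, 1.5), seed=11),
        "illumination-ramp": SequenceScenario(
            n_frames=60, start=(60.0, 70.0), velocity=(3.0, 1.5),
            illumination_amplitude=0.3, noise_sigma=0.02,
            intensity_drift=-0.003, seed=12),
        "occlusion-10": SequenceScenario(
            n_frames=60, start=(70.0, 80.0), velocity=(2.0, 1.0),
            occluder=(25, 10, 0.55), n_clutter=3, noise_sigma=0.02, seed=13),
        "cell-dense": SequenceScenario(
            n_frames=80, start=(60.0, 70.0), velocity=(2.0, 1.0),
            peak_intensity=0.4, background=0.22, n_clutter=25,
            clutter_intensity=0.34, illumination_amplitude=0.1,
            noise_sigma=0.03, seed=14),
    }
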