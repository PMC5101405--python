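"""Particle-filter tracking with an online-updated CDBN appearance model.

The object state is a bounding box x_t = (x, y, w, h) (top-left corner,
0-based pixels). Motion between frames is a Gaussian random walk
p(x_t | x_{t-1}) = N(x_t; x_{t-1}, Sigma); the observation likelihood
p(y_t | x_t) is the CDBN confidence of the 32x32-normalized patch under
the candidate box. Per frame the filter propagates N particles, weights
them by likelihood (weights multiply across frames, as in sequential
importance sampling), reports the maximum-weight particle, resamples
when the weight spread exceeds a threshold (effective sample size below
N/2), and then updates the appearance model online.

Drift resistance comes from the three-tier positive sample taxonomy used
for the update:

* ground-truth samples s_g+ — patches from the manually labeled first
  frame, never modified afterwards;
* long-term samples s_lt+ — a FIFO of the per-frame best patches, capped
  at T (default 25);
* short-term samples s_t+ — the 10 highest-confidence particle patches
  of the current frame.

Negatives s_t- are drawn each frame from an annulus around the estimate
with low overlap. The model is fine-tuned on the union every frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .cdbn import CDBNClassifier
from .crbm import standardize_patch

__all__ = [
    "ObjectState", "MotionModel", "ParticleSet", "SampleBuffers",
    "FrameRecord", "TrackResult", "crop_patch", "propagate", "weigh",
    "best_state", "resample_if_needed", "harvest_positives",
    "harvest_negatives", "update_buffers", "update_model", "iou",
    "default_motion_model", "ParticleFilterTracker", "track",
]

PATCH_SIZE = 32


@dataclass
class ObjectState:
    """Bounding box (top-left x, y, width, height) in 0-based pixels."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"box must have positive size, got w={self.w} h={self.h}")

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.w, self.h], dtype=np.float64)

    @staticmethod
    def from_array(a) -> "ObjectState":
        return ObjectState(float(a[0]), float(a[1]), float(a[2]), float(a[3]))


@dataclass
class MotionModel:
    """Gaussian random-walk covariance over (x, y, w, h)."""

    covariance: np.ndarray

    def __post_init__(self):
        S = np.asarray(self.covariance, dtype=np.float64)
        if S.shape != (4, 4):
            raise ValueError("covariance must be 4x4")
        if not np.allclose(S, S.T):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(S).min() < -1e-10:
            raise ValueError("covariance must be positive semidefinite")
        self.covariance = S


def default_motion_model(init_box: ObjectState, sigma_xy: float = 6.0,
                         scale_frac: float = 0.02) -> MotionModel:
    """diag(sigma_xy^2, sigma_xy^2, (f*w0)^2, (f*h0)^2) — a typical
    particle-tracker random walk with mild scale adaptation."""
    return MotionModel(np.diag([sigma_xy**2, sigma_xy**2,
                                (scale_frac * init_box.w) ** 2,
                                (scale_frac * init_box.h) ** 2]))


@dataclass
class ParticleSet:
    """N candidate states with normalized weights (and cached likelihoods)."""

    states: np.ndarray            # (N, 4)
    weights: np.ndarray           # (N,)
    confidences: np.ndarray | None = None

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.states.ndim != 2 or self.states.shape[1] != 4:
            raise ValueError("states must be (N, 4)")
        if self.weights.shape != (self.states.shape[0],):
            raise ValueError("weights must be (N,)")

    @property
    def n(self) -> int:
        return self.states.shape[0]

    @staticmethod
    def around(state: ObjectState, n: int) -> "ParticleSet":
        return ParticleSet(np.tile(state.as_array(), (n, 1)), np.full(n, 1.0 / n))

    def effective_sample_size(self) -> float:
        return 1.0 / float((self.weights**2).sum())


@dataclass
class SampleBuffers:
    """The four update sample sets: s_g+, s_lt+ (FIFO cap T), s_t+, s_t-.

    Each entry is a standardized 32x32 patch; ``long_term_frames`` records
    the source frame of every FIFO element.
    """

    ground_truth: list = field(default_factory=list)
    long_term: list = field(default_factory=list)
    long_term_frames: list = field(default_factory=list)
    short_term: list = field(default_factory=list)
    negatives: list = field(default_factory=list)
    capacity: int = 25

    def positives(self) -> list:
        return list(self.ground_truth) + list(self.long_term) + list(self.short_term)


@dataclass
class FrameRecord:
    frame: int
    state: ObjectState
    confidence: float
    ess: float
    resampled: bool
    lost: bool = False


@dataclass
class TrackResult:
    """Per-frame optimal states with confidences and filter diagnostics."""

    records: list = field(default_factory=list)

    def __len__(self):
        return len(self.records)

    @property
    def states(self) -> list:
        return [r.state for r in self.records]

    def to_rows(self):
        for r in self.records:
            yield dict(frame=r.frame, x=r.state.x, y=r.state.y, w=r.state.w,
                       h=r.state.h, confidence=r.confidence)


# ---------------------------------------------------------------------------
# geometric helpers

def iou(a: ObjectState, b: ObjectState) -> float:
    """Intersection-over-union of two boxes."""
    x1 = max(a.x, b.x)
    y1 = max(a.y, b.y)
    x2 = min(a.x + a.w, b.x + b.w)
    y2 = min(a.y + a.h, b.y + b.h)
    inter = max(0.0, x2 - x1) * max(0.0, y2 - y1)
    union = a.w * a.h + b.w * b.h - inter
    return inter / union if union > 0 else 0.0


def _to_gray(frame: np.ndarray) -> np.ndarray:
    f = np.asarray(frame, dtype=np.float64)
    if f.ndim == 3:
        f = f.mean(axis=2)
    return f


def crop_patch(frame: np.ndarray, state: ObjectState,
               out_size: int = PATCH_SIZE) -> np.ndarray:
    """Bilinearly resample a box to ``out_size`` square and standardize.

    Boxes partially outside the frame are clipped first; a box with no
    area inside the frame is an error. Returns (out_size, out_size, 1).
    """
    f = _to_gray(frame)
    H, W = f.shape
    x0 = max(state.x, 0.0)
    y0 = max(state.y, 0.0)
    x1 = min(state.x + state.w, float(W))
    y1 = min(state.y + state.h, float(H))
    if x1 - x0 <= 0 or y1 - y0 <= 0:
        raise ValueError("box does not intersect the frame")
    # sample at output pixel centers mapped into the clipped box
    u = (np.arange(out_size) + 0.5) * (x1 - x0) / out_size + x0 - 0.5
    v = (np.arange(out_size) + 0.5) * (y1 - y0) / out_size + y0 - 0.5
    cols, rows = np.meshgrid(u, v)
    patch = ndimage.map_coordinates(f, [rows, cols], order=1, mode="nearest")
    return standardize_patch(patch)[0]


# ---------------------------------------------------------------------------
# particle-filter steps

def propagate(particles: ParticleSet, motion: MotionModel,
              rng: np.random.Generator) -> ParticleSet:
    """Draw x_t^i ~ N(x_{t-1}^i, Sigma); weights are untouched."""
    S = motion.covariance
    if np.allclose(S, 0):
        noise = np.zeros((particles.n, 4))
    else:
        noise = rng.multivariate_normal(np.zeros(4), S, size=particles.n,
                                        method="cholesky" if _is_pd(S) else "svd")
    states = particles.states + noise
    states[:, 2] = np.maximum(states[:, 2], 4.0)   # keep boxes usable
    states[:, 3] = np.maximum(states[:, 3], 4.0)
    return ParticleSet(states, particles.weights.copy())


def _is_pd(S):
    try:
        np.linalg.cholesky(S)
        return True
    except np.linalg.LinAlgError:
        return False


def weigh(particles: ParticleSet, frame: np.ndarray,
          model: CDBNClassifier) -> ParticleSet:
    """w_t^i = w_{t-1}^i * p(y_t | x_t^i), then normalize.

    Candidate boxes that fall outside the frame get zero likelihood. If
    every weight underflows to zero the weights are reset to uniform with
    a warning.
    """
    patches, valid = [], np.ones(particles.n, dtype=bool)
    for i in range(particles.n):
        st = ObjectState.from_array(particles.states[i])
        try:
            patches.append(crop_patch(frame, st))
        except ValueError:
            valid[i] = False
            patches.append(np.zeros((PATCH_SIZE, PATCH_SIZE, 1)))
    conf = model.confidences(np.stack(patches))
    conf = np.where(valid, conf, 0.0)
    w = particles.weights * conf
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        warnings.warn("all particle likelihoods vanished; resetting to uniform")
        w = np.full(particles.n, 1.0 / particles.n)
    else:
        w = w / total
    return ParticleSet(particles.states.copy(), w, confidences=conf)


def best_state(particles: ParticleSet) -> ObjectState:
    """Maximum-weight particle; ties go to the lowest index."""
    if particles.n == 0:
        raise ValueError("empty particle set")
    return ObjectState.from_array(particles.states[int(np.argmax(particles.weights))])


def resample_if_needed(particles: ParticleSet, rng: np.random.Generator,
                       ess_fraction: float = 0.5) -> tuple[ParticleSet, bool]:
    """Multinomial resampling when the weight spread is too large.

    The trigger is the effective sample size N_eff = 1 / sum(w_i^2)
    dropping below ``ess_fraction * N`` — a monotone transform of the
    weight-variance criterion (for normalized weights,
    var(w) = (1/N_eff - 1/N)/N). On resampling, indices beta_j are drawn
    from the weight distribution and all weights reset to 1/N.
    """
    n = particles.n
    if particles.effective_sample_size() >= ess_fraction * n:
        return particles, False
    idx = rng.choice(n, size=n, p=particles.weights)
    conf = None if particles.confidences is None else particles.confidences[idx]
    return ParticleSet(particles.states[idx].copy(), np.full(n, 1.0 / n),
                       confidences=conf), True


# ---------------------------------------------------------------------------
# sample harvesting and model update

def harvest_positives(frame: np.ndarray, particles: ParticleSet,
                      n_samples: int = 10) -> list[np.ndarray]:
    """Patches of the highest-confidence particles (default 10).

    Identical candidate boxes are de-duplicated first; if fewer than
    ``n_samples`` distinct boxes exist, all of them are returned.
    Requires a particle set that has been weighed (confidences cached).
    """
    if particles.confidences is None:
        raise ValueError("particles carry no confidences; call weigh first")
    _, uniq_idx = np.unique(particles.states, axis=0, return_index=True)
    order = sorted(uniq_idx, key=lambda i: (-particles.confidences[i], i))
    out = []
    for i in order[:n_samples]:
        st = ObjectState.from_array(particles.states[i])
        try:
            out.append(crop_patch(frame, st))
        except ValueError:
            continue
    return out


def harvest_negatives(frame: np.ndarray, best: ObjectState,
                      rng: np.random.Generator, n_samples: int = 100,
                      iou_max: float = 0.3, ring: tuple[float, float] = (0.5, 2.0),
                      max_tries: int = 50) -> list[tuple[ObjectState, np.ndarray]]:
    """Background boxes from an annulus around the current estimate.

    Box centers are placed at distance in ``ring * max(w, h)`` from the
    estimate's center, at the same size, clipped to the frame and kept
    only when IoU with the estimate is below ``iou_max``.
    """
    f = _to_gray(frame)
    H, W = f.shape
    cx, cy = best.center
    scale = max(best.w, best.h)
    out = []
    for _ in range(n_samples):
        for _try in range(max_tries):
            r = rng.uniform(ring[0], ring[1]) * scale
            theta = rng.uniform(0.0, 2.0 * np.pi)
            nx = cx + r * np.cos(theta) - best.w / 2.0
            ny = cy + r * np.sin(theta) - best.h / 2.0
            nx = min(max(nx, 0.0), W - best.w) if best.w <= W else 0.0
            ny = min(max(ny, 0.0), H - best.h) if best.h <= H else 0.0
            cand = ObjectState(nx, ny, min(best.w, W), min(best.h, H))
            if iou(cand, best) < iou_max:
                out.append((cand, crop_patch(frame, cand)))
                break
    if len(out) < n_samples:
        warnings.warn(f"only {len(out)}/{n_samples} negatives could be placed")
    return out


def update_buffers(buffers: SampleBuffers, best_patch: np.ndarray,
                   frame_index: int) -> SampleBuffers:
    """Append the frame's best patch to the long-term FIFO (cap T)."""
    buffers.long_term.append(best_patch)
    buffers.long_term_frames.append(frame_index)
    if len(buffers.long_term) > buffers.capacity:
        excess = len(buffers.long_term) - buffers.capacity
        del buffers.long_term[:excess]
        del buffers.long_term_frames[:excess]
    return buffers


def update_model(model: CDBNClassifier, buffers: SampleBuffers, *,
                 n_epochs: int = 500, learning_rate: float = 0.1,
                 momentum: float = 0.5, batch_size: int = 64,
                 freeze_features: bool = False,
                 rng: np.random.Generator | None = None) -> CDBNClassifier:
    """Fine-tune the appearance model on s_g+ u s_lt+ u s_t+ vs s_t-."""
    pos = buffers.positives()
    neg = list(buffers.negatives)
    if not neg:
        raise ValueError("cannot update the model without negative samples")
    if not pos:
        raise ValueError("cannot update the model without positive samples")
    if n_epochs == 0:
        return model
    X = np.stack(pos + neg)
    y = np.array([1] * len(pos) + [0] * len(neg))
    return model.finetune(X, y, n_epochs=n_epochs, learning_rate=learning_rate,
                          momentum=momentum, batch_size=batch_size,
                          freeze_features=freeze_features, rng=rng)


# ---------------------------------------------------------------------------
# the full loop

class ParticleFilterTracker:
    """Algorithm-style tracking loop around a transferred CDBN.

    Parameters mirror the reference configuration: 1,000 particles,
    long-term buffer T=25, 10 short-term positives per frame, 500 update
    epochs per frame at learning rate 0.1 / momentum 0.5. All of them are
    constructor arguments so desk-scale runs can shrink the problem.

    ``positive_tiers`` selects which positive sets feed the online update
    (subset of {"ground_truth", "long_term", "short_term"}); the default
    uses all three. Restricting it to {"short_term"} gives the
    drift-prone ablation.
    """

    def __init__(self, model: CDBNClassifier, *, n_particles: int = 1000,
                 buffer_size: int = 25, n_short_term: int = 10,
                 n_negatives: int = 100, epochs_per_frame: int = 500,
                 init_epochs: int | None = None, learning_rate: float = 0.1,
                 momentum: float = 0.5, batch_size: int = 64,
                 motion: MotionModel | None = None, sigma_xy: float = 6.0,
                 update_every: int = 1, freeze_features: bool = False,
                 positive_tiers: tuple = ("ground_truth", "long_term", "short_term"),
                 confidence_floor: float = 0.2, lost_after: int = 5,
                 seed: int | np.random.Generator | None = None):
        self.model = model
        self.n_particles = n_particles
        self.buffer_size = buffer_size
        self.n_short_term = n_short_term
        self.n_negatives = n_negatives
        self.epochs_per_frame = epochs_per_frame
        self.init_epochs = epochs_per_frame if init_epochs is None else init_epochs
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.batch_size = batch_size
        self.motion = motion
        self.sigma_xy = sigma_xy
        self.update_every = update_every
        self.freeze_features = freeze_features
        self.positive_tiers = tuple(positive_tiers)
        self.confidence_floor = confidence_floor
        self.lost_after = lost_after
        self.rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)

    def _tier_buffers(self, buffers: SampleBuffers) -> SampleBuffers:
        return SampleBuffers(
            ground_truth=buffers.ground_truth if "ground_truth" in self.positive_tiers else [],
            long_term=buffers.long_term if "long_term" in self.positive_tiers else [],
            long_term_frames=buffers.long_term_frames,
            short_term=buffers.short_term if "short_term" in self.positive_tiers else [],
            negatives=buffers.negatives,
            capacity=buffers.capacity,
        )

    def track(self, frames, init_box: ObjectState) -> TrackResult:
        """Run the full loop over an iterable of frames."""
        frames = list(frames)
        if len(frames) < 2:
            raise ValueError("tracking needs at least two frames")
        if self.model.n_out_ != 1:
            raise ValueError("model must be transferred to a one-unit output")
        first = frames[0]
        H, W = _to_gray(first).shape
        if not (0 <= init_box.x and 0 <= init_box.y
                and init_box.x + init_box.w <= W and init_box.y + init_box.h <= H):
            raise ValueError("initial box must lie inside the first frame")

        motion = self.motion or default_motion_model(init_box, self.sigma_xy)
        buffers = SampleBuffers(capacity=self.buffer_size)

        # initialization: ground-truth positives = init box + 1-px jitters
        jitters = [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)]
        for dx, dy in jitters:
            st = ObjectState(init_box.x + dx, init_box.y + dy,
                             init_box.w, init_box.h)
            try:
                buffers.ground_truth.append(crop_patch(first, st))
            except ValueError:
                continue
        buffers.negatives = [p for _, p in harvest_negatives(
            first, init_box, self.rng, self.n_negatives)]
        # the first-frame model is always built from the manual labels,
        # whatever positive tiers the online updates are restricted to
        update_model(self.model, buffers,
                     n_epochs=self.init_epochs, learning_rate=self.learning_rate,
                     momentum=self.momentum, batch_size=self.batch_size,
                     freeze_features=self.freeze_features, rng=self.rng)

        particles = ParticleSet.around(init_box, self.n_particles)
        result = TrackResult()
        conf0 = self.model.confidence(crop_patch(first, init_box))
        result.records.append(FrameRecord(0, init_box, conf0,
                                          particles.effective_sample_size(), False))
        low_conf_streak = 0

        for t in range(1, len(frames)):
            frame = frames[t]
            particles = propagate(particles, motion, self.rng)
            particles = weigh(particles, frame, self.model)
            best = best_state(particles)
            best_conf = float(particles.confidences[int(np.argmax(particles.weights))])
            ess = particles.effective_sample_size()
            particles, resampled = resample_if_needed(particles, self.rng)

            if particles.confidences.max() < self.confidence_floor:
                low_conf_streak += 1
            else:
                low_conf_streak = 0
            lost = low_conf_streak >= self.lost_after

            if t % self.update_every == 0:
                buffers.short_term = harvest_positives(frame, particles,
                                                       self.n_short_term)
                buffers.negatives = [p for _, p in harvest_negatives(
                    frame, best, self.rng, self.n_negatives)]
                update_buffers(buffers, crop_patch(frame, best), t)
                update_model(self.model, self._tier_buffers(buffers),
                             n_epochs=self.epochs_per_frame,
                             learning_rate=self.learning_rate,
                             momentum=self.momentum, batch_size=self.batch_size,
                             freeze_features=self.freeze_features, rng=self.rng)
            result.records.append(FrameRecord(t, best, best_conf, ess,
                                              resampled, lost))
        return result


def track(frames, init_box: ObjectState, model: CDBNClassifier,
          config=None, rng=None, **kwargs) -> TrackResult:
    """Functional entry point; ``config`` may be a RunConfig-like object."""
    if config is not None:
        kwargs = {**config.tracker_kwargs(), **kwargs}
    if rng is not None:
        kwargs["seed"] = rng
    return ParticleFilterTracker(model, **kwargs).track(frames, init_box)
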