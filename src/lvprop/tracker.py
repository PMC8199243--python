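"""Correlation-filter tracking for fast anchor generation along a slice sequence.

Once one slice of an individual has a detection box, subsequent slices do
not need dictionary classification: a bank of frequency-domain correlation
filters follows the left ventricle.  The detection box is tiled into 9
blocks, each with its own translation filter

    A^l = conj(G) F^l,      B = sum_k conj(F^k) F^k,
    y   = ifft( sum_l conj(A^l) Z^l / (B + lam) ),

where ``F``/``Z`` are Fourier transforms of (windowed) template/probe
features and ``G`` the transform of a Gaussian response target.  Block peak
displacements are averaged into a predicted center ``P1``, blended with the
prior center ``P2`` as ``P_t = w1*P1 + w2*P2`` (w1 = 0.2, w2 = 0.8).  The
prior center is the constant-velocity extrapolation of the previous
estimate, so the heavy prior weight smooths jitter without lagging a steady
drift.  A separate 1-D filter over ``s = 33`` geometric scales
``a^n, n in [-16, 16]`` (a = 1.02) re-estimates the box size.  Numerator
and denominator are updated by exponential moving average with learning
rate ``theta = 0.025``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .evaluation import DetectionBox

__all__ = [
    "TrackerConfig",
    "CorrelationFilter",
    "TrackingError",
    "gaussian_target",
    "gaussian_target_1d",
    "train_filter",
    "respond",
    "update_filter",
    "peak_displacement",
    "extract_patch",
    "BlockTracker",
    "track_step",
]


class TrackingError(RuntimeError):
    """Raised when a response map degenerates; tracker state is left frozen."""


@dataclass
class TrackerConfig:
    lam: float = 0.01  # spectrum regularizer
    theta: float = 0.025  # template learning rate
    scale_step: float = 1.02  # geometric scale factor a
    n_scales: int = 33  # s, must be odd
    w1: float = 0.2  # weight of the block-averaged prediction P1
    w2: float = 0.8  # weight of the prior center P2
    sigma_factor: float = 1.0 / 16.0  # translation sigma = sqrt(w*h)/16
    scale_patch: tuple[int, int] = (24, 24)  # resample size of scale samples
    min_block_template: int = 8
    use_gradients: bool = False  # add gradient-orientation channels (d = 3)

    def __post_init__(self):
        if self.n_scales % 2 == 0:
            raise ValueError("n_scales must be odd")
        if abs(self.w1 + self.w2 - 1.0) > 1e-9:
            raise ValueError("w1 + w2 must equal 1")

    @property
    def scale_sigma(self) -> float:
        return self.scale_step * self.n_scales / 16.0

    @property
    def scale_exponents(self) -> np.ndarray:
        half = (self.n_scales - 1) // 2
        return np.arange(-half, half + 1)


@dataclass
class CorrelationFilter:
    """Numerator/denominator of a learned filter in the frequency domain."""

    A: np.ndarray  # (d, *shape) complex
    B: np.ndarray  # (*shape,) real
    G: np.ndarray  # (*shape,) complex transform of the response target
    lam: float

    @property
    def shape(self) -> tuple[int, ...]:
        return self.A.shape[1:]


def gaussian_target(shape: tuple[int, int], sigma: float) -> np.ndarray:
    """2-D Gaussian response target, peak value 1 at (h//2, w//2)."""
    h, w = shape
    if h < 1 or w < 1:
        raise ValueError("target shape must be positive")
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    return np.exp(-((yy - h // 2) ** 2 + (xx - w // 2) ** 2) / (2 * sigma**2))


def gaussian_target_1d(n: int, sigma: float) -> np.ndarray:
    """1-D Gaussian response target for the scale filter, peak at n//2."""
    x = np.arange(n, dtype=float)
    return np.exp(-((x - n // 2) ** 2) / (2 * sigma**2))


def _feature_axes(features: np.ndarray) -> tuple[int, ...]:
    return tuple(range(1, features.ndim))


def train_filter(
    features: np.ndarray, g: np.ndarray, lam: float
) -> CorrelationFilter:
    """Build a filter from one template: A = conj(G) F, B = sum |F|^2.

    ``features`` has shape ``(d, *patch_shape)`` matching ``g``.
    """
    features = np.asarray(features, dtype=float)
    g = np.asarray(g, dtype=float)
    if features.shape[1:] != g.shape:
        raise ValueError("feature and target shapes differ")
    axes = _feature_axes(features)
    F = np.fft.fftn(features, axes=axes)
    G = np.fft.fftn(g)
    A = np.conj(G)[None] * F
    B = (np.conj(F) * F).sum(axis=0).real
    return CorrelationFilter(A=A, B=B, G=G, lam=lam)


def respond(filt: CorrelationFilter, features: np.ndarray) -> np.ndarray:
    """Real response map of a probe; the peak locates the translation."""
    features = np.asarray(features, dtype=float)
    if features.shape != filt.A.shape:
        raise ValueError("probe shape does not match the filter template")
    axes = _feature_axes(features)
    Z = np.fft.fftn(features, axes=axes)
    num = (np.conj(filt.A) * Z).sum(axis=0)
    return np.fft.ifftn(num / (filt.B + filt.lam)).real


def update_filter(
    filt: CorrelationFilter, features: np.ndarray, theta: float = 0.025
) -> CorrelationFilter:
    """Exponential moving average of filter numerator and denominator."""
    features = np.asarray(features, dtype=float)
    if features.shape != filt.A.shape:
        raise ValueError("feature shape does not match the filter template")
    axes = _feature_axes(features)
    F = np.fft.fftn(features, axes=axes)
    A = (1.0 - theta) * filt.A + theta * np.conj(filt.G)[None] * F
    B = (1.0 - theta) * filt.B + theta * (np.conj(F) * F).sum(axis=0).real
    return CorrelationFilter(A=A, B=B, G=filt.G, lam=filt.lam)


def peak_displacement(y: np.ndarray) -> tuple[int, ...]:
    """Signed displacement of the response peak from the reference position.

    Integer argmax with lowest-index tie-break; displacements wrap to
    ``[-s/2, s/2)`` per axis.
    """
    if not np.all(np.isfinite(y)):
        raise TrackingError("non-finite response map")
    idx = np.unravel_index(int(np.argmax(y)), y.shape)
    # reference is the axis center s//2, so p - s//2 is already the wrapped
    # representative in [-s//2, s//2)
    return tuple(int(p) - s // 2 for p, s in zip(idx, y.shape))


def _subpixel_displacement(y: np.ndarray) -> np.ndarray:
    """Peak displacement refined by a 3-point parabola per axis (circular)."""
    base = peak_displacement(y)
    idx = np.unravel_index(int(np.argmax(y)), y.shape)
    out = []
    for ax, (p, s) in enumerate(zip(idx, y.shape)):
        sel = list(idx)
        sel[ax] = (p - 1) % s
        ym = y[tuple(sel)]
        sel[ax] = (p + 1) % s
        yp = y[tuple(sel)]
        denom = ym - 2.0 * y[idx] + yp
        delta = 0.5 * (ym - yp) / denom if abs(denom) > 1e-12 else 0.0
        out.append(base[ax] + float(np.clip(delta, -0.5, 0.5)))
    return np.array(out)


def extract_patch(
    frame: np.ndarray, center: tuple[float, float], size: tuple[int, int]
) -> np.ndarray:
    """Integer-grid patch of ``size`` (h, w) centered at (row, col), edge-padded."""
    ph, pw = int(size[0]), int(size[1])
    r0 = int(round(center[0])) - ph // 2
    c0 = int(round(center[1])) - pw // 2
    H, W = frame.shape
    rows = np.clip(np.arange(r0, r0 + ph), 0, H - 1)
    cols = np.clip(np.arange(c0, c0 + pw), 0, W - 1)
    return frame[np.ix_(rows, cols)]


def _even_up(x: int) -> int:
    return x if x % 2 == 0 else x + 1


def _window2d(shape: tuple[int, int]) -> np.ndarray:
    return np.outer(np.hanning(shape[0]), np.hanning(shape[1]))


def _patch_features(
    frame: np.ndarray,
    center: tuple[float, float],
    size: tuple[float, float],
    template: tuple[int, int],
    window: np.ndarray,
    use_gradients: bool,
) -> np.ndarray:
    """Windowed, mean-subtracted features of a patch resampled to the template."""
    ph = max(int(round(size[0])), 2)
    pw = max(int(round(size[1])), 2)
    patch = extract_patch(frame, center, (ph, pw))
    patch = resize(patch, template, order=1, mode="edge",
                   anti_aliasing=False, preserve_range=True)
    chans = [patch - patch.mean()]
    if use_gradients:
        gy, gx = np.gradient(patch)
        chans += [gy, gx]
    return np.stack([c * window for c in chans])


_BLOCK_OFFSETS = [(r, c) for r in (-1, 0, 1) for c in (-1, 0, 1)]


class BlockTracker:
    """9-block translation + 1-D scale correlation tracker of one LV box.

    Initialized from a detection box on the first slice; ``step`` estimates
    the new center (block average blended with the prior center), then the
    scale, then refreshes all templates.
    """

    def __init__(
        self,
        frame: np.ndarray,
        box: tuple[float, float, float, float],
        config: TrackerConfig | None = None,
    ):
        self.cfg = config or TrackerConfig()
        x1, y1, x2, y2 = box
        if x2 <= x1 or y2 <= y1:
            raise ValueError("seed box must have positive size")
        self.center = np.array([(y1 + y2) / 2.0, (x1 + x2) / 2.0])
        self.size = np.array([y2 - y1, x2 - x1], dtype=float)  # (h, w)
        self.velocity = np.zeros(2)
        self.last_p1 = self.center.copy()
        m = self.cfg.min_block_template
        self.block_template = (
            _even_up(max(int(np.ceil(self.size[0] / 3)), m)),
            _even_up(max(int(np.ceil(self.size[1] / 3)), m)),
        )
        self.block_window = _window2d(self.block_template)
        th, tw = self.block_template
        self.block_g = gaussian_target(
            self.block_template, self.cfg.sigma_factor * np.sqrt(th * tw)
        )
        self.scale_window = np.hanning(self.cfg.n_scales)
        self.scale_g = gaussian_target_1d(self.cfg.n_scales,
                                          self.cfg.scale_sigma)
        self.block_filters = [
            train_filter(f, self.block_g, self.cfg.lam)
            for f in self._block_features(frame, self.center, self.size)
        ]
        self.scale_filter = train_filter(
            self._scale_features(frame, self.center, self.size),
            self.scale_g, self.cfg.lam,
        )
        self.frame_index = 0

    # -- feature extraction ------------------------------------------------

    def _block_centers(self, center: np.ndarray, size: np.ndarray):
        return [
            center + np.array([r * size[0] / 3.0, c * size[1] / 3.0])
            for r, c in _BLOCK_OFFSETS
        ]

    def _block_features(self, frame, center, size):
        bsize = (size[0] / 3.0, size[1] / 3.0)
        return [
            _patch_features(frame, bc, bsize, self.block_template,
                            self.block_window, self.cfg.use_gradients)
            for bc in self._block_centers(center, size)
        ]

    def _scale_features(self, frame, center, size) -> np.ndarray:
        cols = []
        for k, n in enumerate(self.cfg.scale_exponents):
            f = self.cfg.scale_step ** float(n)
            ph = max(int(round(size[0] * f)), 2)
            pw = max(int(round(size[1] * f)), 2)
            patch = extract_patch(frame, center, (ph, pw))
            patch = resize(patch, self.cfg.scale_patch, order=1, mode="edge",
                           anti_aliasing=False, preserve_range=True)
            cols.append((patch - patch.mean()).ravel() * self.scale_window[k])
        return np.stack(cols, axis=-1)  # (d, n_scales)

    # -- tracking steps ----------------------------------------------------

    def estimate_center(self, frame: np.ndarray):
        """Block-averaged prediction P1 and blended center P_t.

        Each block's response peak gives a displacement estimate; their mean
        added to the prior center P2 is P1, and
        ``P_t = w1*P1 + w2*P2``.
        """
        p2 = self.center + self.velocity
        bsize = (self.size[0] / 3.0, self.size[1] / 3.0)
        scale_back = np.array([
            max(bsize[0], 2) / self.block_template[0],
            max(bsize[1], 2) / self.block_template[1],
        ])
        # two passes: re-probing at the first estimate reduces the bias the
        # cosine window puts on off-center peaks
        p1 = p2
        for _ in range(2):
            disps = []
            for filt, bc in zip(self.block_filters,
                                self._block_centers(p1, self.size)):
                feats = _patch_features(frame, bc, bsize, self.block_template,
                                        self.block_window,
                                        self.cfg.use_gradients)
                y = respond(filt, feats)
                if not np.all(np.isfinite(y)):
                    raise TrackingError("non-finite translation response")
                disps.append(_subpixel_displacement(y) * scale_back)
            p1 = p1 + np.mean(disps, axis=0)
        pt = self.cfg.w1 * p1 + self.cfg.w2 * p2
        return p1, pt

    def estimate_scale(self, frame: np.ndarray, center: np.ndarray):
        """Best of the 33 geometric scales at the new center."""
        feats = self._scale_features(frame, center, self.size)
        y = respond(self.scale_filter, feats)
        if not np.all(np.isfinite(y)):
            raise TrackingError("non-finite scale response")
        n_star = int(np.argmax(y)) - (self.cfg.n_scales - 1) // 2
        factor = self.cfg.scale_step ** float(n_star)
        return n_star, self.size * factor

    def step(self, frame: np.ndarray) -> DetectionBox:
        """Track one frame: center, scale, template update; emits the box."""
        p1, pt = self.estimate_center(frame)
        # scale is sampled at the unsmoothed estimate P1: the blended center
        # deliberately lags transients, which would bias the scale pyramid
        n_star, new_size = self.estimate_scale(frame, p1)
        new_feats = self._block_features(frame, pt, new_size)
        new_scale_feats = self._scale_features(frame, pt, new_size)
        # estimates are complete; now commit state
        self.block_filters = [
            update_filter(f, z, self.cfg.theta)
            for f, z in zip(self.block_filters, new_feats)
        ]
        self.scale_filter = update_filter(self.scale_filter, new_scale_feats,
                                          self.cfg.theta)
        # constant-velocity prior: velocity is the change of the unsmoothed
        # block-averaged estimate, which does not lag under steady drift
        self.velocity = p1 - self.last_p1
        self.last_p1 = p1
        self.center = pt
        self.size = new_size
        self.frame_index += 1
        self.last_scale_index = n_star
        cy, cx = self.center
        h, w = self.size
        return DetectionBox(
            x1=cx - w / 2, y1=cy - h / 2, x2=cx + w / 2, y2=cy + h / 2,
            score=1.0, image_id=self.frame_index,
        )


def track_step(state: BlockTracker, frame: np.ndarray) -> DetectionBox:
    """Functional wrapper over :meth:`BlockTracker.step`."""
    return state.step(frame)
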