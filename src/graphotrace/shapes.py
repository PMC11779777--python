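"""Parametric synthesis of closed amoeboid contours and the shape-space metric.

The stimuli are radial-frequency patterns: closed contours whose radius is a
base circle modulated by a small set of cosine harmonics ("bumps and
dimples").  Eight stimuli are arranged on a ring in shape space such that the
seven consecutive similarity steps 1-2, 2-3, ..., 7-8 are equal, while the
gap between shapes 8 and 1 spans three such steps.  Similarity is measured by
the root-mean-square difference of centroid-referenced radial profiles,
minimised over cyclic rotation of the arc-length start index, which makes the
metric independent of where along the contour sampling begins.

Geometry conventions: planar centimetres, origin at the contour's vertex
centroid, y axis up.  Contours are stored closed (first point repeated as the
last point) and are rescaled so the largest caliper extent equals the
configured presentation size (4.9 cm by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import ConvexHull
from shapely.geometry import LinearRing

from .exceptions import ConstructiveFailureError, InvalidProfileError

logger = logging.getLogger(__name__)

#: Default presentation size (largest caliper extent) in cm.
DEFAULT_SIZE_CM = 4.9
#: Default viewing distance in cm.
DEFAULT_VIEWING_DISTANCE_CM = 40.0


def visual_angle_deg(size_cm: float = DEFAULT_SIZE_CM,
                     distance_cm: float = DEFAULT_VIEWING_DISTANCE_CM) -> float:
    """Visual angle (degrees) subtended by ``size_cm`` at ``distance_cm``."""
    return math.degrees(2.0 * math.atan(size_cm / (2.0 * distance_cm)))


# ---------------------------------------------------------------------------
# Radial profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RadialProfile:
    """Polar description of a closed contour: r(theta) = R(1 + sum A_k cos(k theta + phi_k)).

    Parameters
    ----------
    base_radius : float
        Base circle radius R in cm (before the caliper rescaling applied at
        synthesis time).
    harmonics : tuple of (int k, float amplitude, float phase)
        Cosine harmonics; amplitude is a dimensionless fraction of the base
        radius, phase in radians.
    """

    base_radius: float = 1.0
    harmonics: tuple[tuple[int, float, float], ...] = ()

    def radius(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        r = np.ones_like(theta)
        for k, amp, phase in self.harmonics:
            r += amp * np.cos(k * theta + phase)
        return self.base_radius * r

    def radius_derivative(self, theta: np.ndarray) -> np.ndarray:
        """dr/dtheta, used to count protrusions."""
        theta = np.asarray(theta, dtype=float)
        dr = np.zeros_like(theta)
        for k, amp, phase in self.harmonics:
            dr -= amp * k * np.sin(k * theta + phase)
        return self.base_radius * dr

    def min_radius(self, n_grid: int = 4096) -> float:
        theta = np.linspace(0.0, 2.0 * np.pi, n_grid, endpoint=False)
        return float(self.radius(theta).min())


def morph_profiles(a: RadialProfile, b: RadialProfile, t: float) -> RadialProfile:
    """Linear interpolation of two profiles' harmonic amplitude/phase vectors.

    Both profiles must list the same harmonic frequencies in the same order.
    ``t=0`` returns ``a``, ``t=1`` returns ``b``.
    """
    ka = [h[0] for h in a.harmonics]
    kb = [h[0] for h in b.harmonics]
    if ka != kb:
        raise ValueError("profiles must share the same harmonic frequencies")
    harmonics = tuple(
        (k, (1 - t) * aa + t * ab, (1 - t) * pa + t * pb)
        for (k, aa, pa), (_, ab, pb) in zip(a.harmonics, b.harmonics)
    )
    base = (1 - t) * a.base_radius + t * b.base_radius
    return RadialProfile(base_radius=base, harmonics=harmonics)


# ---------------------------------------------------------------------------
# Contours
# ---------------------------------------------------------------------------

@dataclass
class ContourShape:
    """A closed planar contour sampled uniformly by arc length.

    ``points`` has shape ``(n_points + 1, 2)``: the first vertex is repeated
    as the last so the stored polyline is explicitly closed.
    """

    points: np.ndarray
    shape_id: int = 0

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if not np.allclose(self.points[0], self.points[-1]):
            # store closed by convention
            self.points = np.vstack([self.points, self.points[0]])

    @property
    def n_points(self) -> int:
        return self.points.shape[0] - 1

    @property
    def open_points(self) -> np.ndarray:
        """Vertices without the repeated closure point."""
        return self.points[:-1]

    @property
    def centroid(self) -> np.ndarray:
        return self.open_points.mean(axis=0)

    def radial_profile(self) -> np.ndarray:
        """Distances of the (open) vertices from the vertex centroid."""
        return np.linalg.norm(self.open_points - self.centroid, axis=1)

    def caliper_extent(self) -> float:
        """Largest caliper extent (diameter of the vertex set)."""
        pts = self.open_points
        hull = pts[ConvexHull(pts).vertices]
        diff = hull[:, None, :] - hull[None, :, :]
        return float(np.sqrt((diff ** 2).sum(-1)).max())

    def perimeter(self) -> float:
        seg = np.diff(self.points, axis=0)
        return float(np.linalg.norm(seg, axis=1).sum())

    def is_simple(self) -> bool:
        return bool(LinearRing(self.open_points).is_valid)


def _resample_by_arc_length(points: np.ndarray, n_points: int) -> np.ndarray:
    """Resample an open vertex ring to ``n_points`` arc-length-uniform vertices."""
    closed = np.vstack([points, points[0]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    target = np.linspace(0.0, total, n_points, endpoint=False)
    x = np.interp(target, s, closed[:, 0])
    y = np.interp(target, s, closed[:, 1])
    return np.column_stack([x, y])


def synthesize_shape(profile: RadialProfile, n_points: int = 256, *,
                     size: float = DEFAULT_SIZE_CM, shape_id: int = 0,
                     dense_grid: int = 2048) -> ContourShape:
    """Realise a radial profile as a sampled, sized, centred closed contour.

    The polar graph of ``r(theta)`` is densely evaluated, resampled to
    ``n_points`` arc-length-uniform vertices, centred on its vertex centroid
    and rescaled so the largest caliper extent equals ``size``.

    Raises
    ------
    InvalidProfileError
        If the radius is non-positive anywhere on the dense grid.
    """
    if n_points < 64:
        raise ValueError("n_points must be >= 64")
    theta = np.linspace(0.0, 2.0 * np.pi, dense_grid, endpoint=False)
    r = profile.radius(theta)
    if r.min() <= 0.0:
        raise InvalidProfileError(
            f"radius non-positive (min {r.min():.4g}); profile invalid")
    dense = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    pts = _resample_by_arc_length(dense, n_points)
    pts = pts - pts.mean(axis=0)
    shape = ContourShape(pts, shape_id=shape_id)
    scale = size / shape.caliper_extent()
    pts = pts * scale
    pts = pts - pts.mean(axis=0)
    return ContourShape(pts, shape_id=shape_id)


# ---------------------------------------------------------------------------
# Shape-space metric
# ---------------------------------------------------------------------------

def shape_distance(a: ContourShape, b: ContourShape) -> float:
    """RMS difference of centroid-referenced radial profiles, minimised over
    cyclic rotation of the sampling start index.

    Symmetric; zero iff the two sampled profiles are identical up to a
    rotation of the start index.  Contours with mismatched sample counts are
    resampled internally (logged).
    """
    ra = a.radial_profile()
    rb = b.radial_profile()
    if ra.size != rb.size:
        logger.info("shape_distance: resampling %d -> %d points",
                    b.n_points, a.n_points)
        rb = ContourShape(_resample_by_arc_length(b.open_points, ra.size)).radial_profile()
    n = ra.size
    # ||ra - roll(rb, s)||^2 = ||ra||^2 + ||rb||^2 - 2 * circular_corr(s)
    fa = np.fft.rfft(ra)
    fb = np.fft.rfft(rb)
    corr = np.fft.irfft(fa * np.conj(fb), n)
    sq = float((ra ** 2).sum() + (rb ** 2).sum()) - 2.0 * corr
    best = max(float(sq.min()), 0.0)
    return math.sqrt(best / n)


# ---------------------------------------------------------------------------
# Equidistant ring construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthesisConfig:
    """Configuration of the 8-shape ring construction.

    The morph path is a closed loop: a circle in harmonic-amplitude space
    centred on a base amplitude vector, passing through the two endpoint
    profiles that span the loop plane.  Shapes sit at angular positions along
    the loop; the positions are iteratively adjusted until the measured
    consecutive shape distances are equal and the 8->1 gap equals three steps.
    """

    n_points: int = 256
    size: float = DEFAULT_SIZE_CM
    frequencies: tuple[int, ...] = (3, 4, 5, 6, 7)
    base_amplitude: float = 0.05
    loop_radius: float = 0.06
    tolerance: float = 0.01
    max_outer_iter: int = 60
    dense_grid: int = 1024


#: Number of stimuli on the ring.
RING_SIZE = 8
#: Ring-gap between shapes 8 and 1, in consecutive-step units.
WRAP_STEPS = 3


def _ring_gap_angle(alpha: float) -> float:
    """Angle subtended by the 8->1 gap when consecutive spacing is ``alpha``."""
    return 2.0 * np.pi - (RING_SIZE - 1) * alpha


def _initial_spacing() -> float:
    """Euclidean-circle initialisation: chord(gap) = 3 * chord(step)."""
    def f(alpha):
        return math.sin(_ring_gap_angle(alpha) / 2.0) - WRAP_STEPS * math.sin(alpha / 2.0)
    return brentq(f, 0.05, 2.0 * np.pi / (RING_SIZE - 1) - 1e-6)


@dataclass
class ShapeSet:
    """The 8 ring stimuli plus the measured pairwise distance structure."""

    shapes: list[ContourShape]
    step_distance: float
    distance_matrix: np.ndarray
    set_id: str = "ring"
    config: SynthesisConfig = field(default_factory=SynthesisConfig)

    def consecutive_distances(self) -> np.ndarray:
        d = self.distance_matrix
        return np.array([d[i, i + 1] for i in range(RING_SIZE - 1)])

    def wrap_distance(self) -> float:
        return float(self.distance_matrix[RING_SIZE - 1, 0])

    def shape(self, shape_id: int) -> ContourShape:
        for s in self.shapes:
            if s.shape_id == shape_id:
                return s
        raise KeyError(f"no shape with id {shape_id}")


class _LoopFamily:
    """Shapes parameterised by an angle on the amplitude-space loop."""

    def __init__(self, config: SynthesisConfig, rng: np.random.Generator):
        m = len(config.frequencies)
        self.config = config
        self.phases = rng.uniform(0.0, 2.0 * np.pi, size=m)
        signs = rng.choice([-1.0, 1.0], size=m)
        self.center = signs * rng.uniform(0.5, 1.0, size=m) * config.base_amplitude
        # orthonormal loop plane
        e1 = rng.normal(size=m)
        e1 /= np.linalg.norm(e1)
        e2 = rng.normal(size=m)
        e2 -= e1 * (e1 @ e2)
        e2 /= np.linalg.norm(e2)
        self.e1, self.e2 = e1, e2
        self._cache: dict[float, ContourShape] = {}

    def profile(self, psi: float) -> RadialProfile:
        amps = self.center + self.config.loop_radius * (
            math.cos(psi) * self.e1 + math.sin(psi) * self.e2)
        harmonics = tuple(
            (int(k), float(a), float(p))
            for k, a, p in zip(self.config.frequencies, amps, self.phases))
        return RadialProfile(base_radius=1.0, harmonics=harmonics)

    def shape(self, psi: float) -> ContourShape:
        key = round(psi, 12)
        if key not in self._cache:
            self._cache[key] = synthesize_shape(
                self.profile(psi), self.config.n_points, size=self.config.size,
                dense_grid=self.config.dense_grid)
        return self._cache[key]


def _place_ring(family: _LoopFamily, step: float, alpha0: float) -> np.ndarray:
    """Place 8 loop angles so each consecutive shape distance equals ``step``.

    Sequential bisection on each angle; the distance to the previous shape is
    monotone in the angular separation for separations below pi.
    """
    psis = np.zeros(RING_SIZE)
    for i in range(1, RING_SIZE):
        prev_shape = family.shape(psis[i - 1])

        def gap(dpsi):
            return shape_distance(prev_shape, family.shape(psis[i - 1] + dpsi)) - step

        lo, hi = 1e-4, alpha0
        while gap(hi) < 0.0 and hi < 2.5:
            hi *= 1.3
        dpsi = brentq(gap, lo, hi, xtol=1e-6)
        psis[i] = psis[i - 1] + dpsi
    return psis


def generate_shape_set(config: SynthesisConfig | None = None, seed: int = 0) -> ShapeSet:
    """Construct the 8-member equidistant ring of amoeboid stimuli.

    Deterministic given ``seed``.  The outer loop solves for the common step
    size so that the measured 8->1 distance equals three steps; the inner
    loop places each shape by bisection so that all seven consecutive
    distances equal the step.

    Raises
    ------
    ConstructiveFailureError
        If the ring invariants cannot be met within tolerance; the error
        carries the diagnostic consecutive distances.
    """
    config = config or SynthesisConfig()
    rng = np.random.default_rng(seed)
    family = _LoopFamily(config, rng)
    alpha0 = _initial_spacing()

    # Euclidean-prediction of the step from the initial spacing.
    s0 = shape_distance(family.shape(0.0), family.shape(alpha0))

    def wrap_residual(step):
        psis = _place_ring(family, step, alpha0)
        d81 = shape_distance(family.shape(psis[-1]), family.shape(psis[0]))
        return d81 - WRAP_STEPS * step

    lo, hi = 0.6 * s0, 1.4 * s0
    flo, fhi = wrap_residual(lo), wrap_residual(hi)
    tries = 0
    while flo * fhi > 0 and tries < 8:
        lo *= 0.8
        hi *= 1.2
        flo, fhi = wrap_residual(lo), wrap_residual(hi)
        tries += 1
    if flo * fhi > 0:
        raise ConstructiveFailureError(
            "could not bracket the ring step size", distances=None)
    step = brentq(wrap_residual, lo, hi, xtol=s0 * 1e-6,
                  maxiter=config.max_outer_iter)

    psis = _place_ring(family, step, alpha0)
    shapes = []
    for i, psi in enumerate(psis):
        s = family.shape(psi)
        shapes.append(ContourShape(s.points.copy(), shape_id=i + 1))

    dist = np.zeros((RING_SIZE, RING_SIZE))
    for i in range(RING_SIZE):
        for j in range(i + 1, RING_SIZE):
            dist[i, j] = dist[j, i] = shape_distance(shapes[i], shapes[j])

    consecutive = np.array([dist[i, i + 1] for i in range(RING_SIZE - 1)])
    rel_dev = np.abs(consecutive - step) / step
    wrap_dev = abs(dist[RING_SIZE - 1, 0] - WRAP_STEPS * step) / step
    if rel_dev.max() > config.tolerance or wrap_dev > WRAP_STEPS * config.tolerance:
        raise ConstructiveFailureError(
            f"equidistance not achieved: consecutive rel dev {rel_dev.max():.3g}, "
            f"wrap dev {wrap_dev:.3g}", distances=consecutive)

    return ShapeSet(shapes=shapes, step_distance=float(step),
                    distance_matrix=dist, config=config)


def familiarization_profiles(seed: int = 0, n: int = 4,
                             config: SynthesisConfig | None = None) -> list[RadialProfile]:
    """Out-of-set profiles for the familiarization/catch block (shape_id 0)."""
    config = config or SynthesisConfig()
    rng = np.random.default_rng([seed, 97])
    profiles = []
    for _ in range(n):
        m = len(config.frequencies)
        amps = rng.uniform(-1.5, 1.5, size=m) * config.base_amplitude
        phases = rng.uniform(0, 2 * np.pi, size=m)
        profiles.append(RadialProfile(1.0, tuple(
            (int(k), float(a), float(p))
            for k, a, p in zip(config.frequencies, amps, phases))))
    return profiles
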