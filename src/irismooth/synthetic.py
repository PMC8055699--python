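"""Synthetic AS-OCT-like scenes with analytically known smoothness index.

A scene is a dark speckled background with a bright, roughly horizontal iris
band on each side of a central pupil gap.  The top edge of each band follows
a parametric crypt curve ``row = f(col)`` whose arc length — and hence the
true SI — is computable by quadrature, so the whole measurement pipeline can
be validated without patient data.

Rendering is deterministic: the same spec (including its seed) produces a
byte-identical image.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, replace
from typing import Callable, List, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import brentq

from .errors import SyntheticSpecError
from .preprocess import GrayImage
from .smoothness import LandmarkSet

Point = Tuple[int, int]


@dataclass(frozen=True)
class SyntheticIrisSpec:
    """Parameters of one synthetic scene."""

    width: int = 1000
    height: int = 320
    side_span: int = 380
    margin: int = 30
    baseline_row: float = 140.0
    crypt_amplitude: float = 6.0
    crypt_frequency: int = 2
    crypt_profile: str = "sinusoid"  # "sinusoid" | "gaussians"
    iris_thickness: int = 60
    tissue_level: float = 200.0
    background_level: float = 30.0
    speckle_sigma: float = 0.08
    blur_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.crypt_amplitude < 0:
            raise SyntheticSpecError("crypt_amplitude must be >= 0")
        if not (0 <= self.background_level <= 255 and 0 <= self.tissue_level <= 255):
            raise SyntheticSpecError("intensity levels must lie in [0, 255]")
        if self.speckle_sigma < 0 or self.blur_sigma < 0:
            raise SyntheticSpecError("noise parameters must be >= 0")
        if self.crypt_profile not in ("sinusoid", "gaussians"):
            raise SyntheticSpecError(f"unknown crypt profile {self.crypt_profile!r}")
        if self.crypt_frequency < 1:
            raise SyntheticSpecError("crypt_frequency must be >= 1")
        gap = self.width - 2 * self.margin - 2 * self.side_span
        if gap < 10:
            raise SyntheticSpecError(
                f"pupil gap of {gap} px is too small; reduce side_span or margin"
            )


@dataclass
class BorderCurve:
    """Continuous anterior-border curve ``row = f(col)`` on ``[a, b]``."""

    f: Callable[[np.ndarray], np.ndarray]
    df: Callable[[np.ndarray], np.ndarray]
    a: float
    b: float

    def endpoints(self) -> Tuple[Tuple[float, float], Tuple[float, float]]:
        return (
            (float(self.f(np.array(self.a))), self.a),
            (float(self.f(np.array(self.b))), self.b),
        )


@dataclass
class SyntheticTruth:
    """Analytic ground truth attached to a rendered scene."""

    nasal_curve: BorderCurve
    temporal_curve: BorderCurve
    true_si_nasal: float
    true_si_temporal: float
    true_si_overall: float
    landmarks: LandmarkSet


def _gauss_legendre_arc(
    df: Callable[[np.ndarray], np.ndarray],
    a: float,
    b: float,
    spacing: Tuple[float, float],
    n_segments: int,
) -> float:
    sy, sx = spacing
    nodes, weights = np.polynomial.legendre.leggauss(20)
    edges = np.linspace(a, b, n_segments + 1)
    mid = (edges[:-1] + edges[1:]) / 2.0
    half = (edges[1:] - edges[:-1]) / 2.0
    x = (mid[:, None] + half[:, None] * nodes[None, :]).ravel()
    g = np.sqrt((sy * np.asarray(df(x), dtype=float)) ** 2 + sx**2)
    if not np.isfinite(g).all():
        raise SyntheticSpecError("curve derivative is not finite on the interval")
    return float((g.reshape(-1, 20) * weights).sum(axis=1) @ half)


def arc_length(
    curve: BorderCurve,
    spacing: Tuple[float, float] = (1.0, 1.0),
    rel_tol: float = 1e-8,
) -> float:
    """Arc length of the curve by adaptive composite Gauss-Legendre quadrature."""
    n = 8
    prev = _gauss_legendre_arc(curve.df, curve.a, curve.b, spacing, n)
    for _ in range(12):
        n *= 2
        cur = _gauss_legendre_arc(curve.df, curve.a, curve.b, spacing, n)
        if abs(cur - prev) <= rel_tol * abs(cur):
            return cur
        prev = cur
    return prev


def analytic_si(
    curve: BorderCurve,
    spacing: Tuple[float, float] = (1.0, 1.0),
) -> float:
    """Chord length over arc length of a continuous border curve."""
    if not curve.a < curve.b:
        raise SyntheticSpecError("curve interval is empty")
    sy, sx = spacing
    (ra, ca), (rb, cb) = curve.endpoints()
    if not (np.isfinite(ra) and np.isfinite(rb)):
        raise SyntheticSpecError("curve is not finite at the interval endpoints")
    chord = float(np.hypot((ra - rb) * sy, (ca - cb) * sx))
    return chord / arc_length(curve, spacing)


def _make_curve(spec: SyntheticIrisSpec, a: float, b: float, rng: np.random.Generator) -> BorderCurve:
    span = b - a
    amp = spec.crypt_amplitude
    k = spec.crypt_frequency
    if spec.crypt_profile == "sinusoid":
        phase = rng.uniform(0, 2 * np.pi)
        omega = 2 * np.pi * k / span

        def f(x, phase=phase, omega=omega, a=a, amp=amp):
            return spec.baseline_row + amp * np.sin(omega * (np.asarray(x, float) - a) + phase)

        def df(x, phase=phase, omega=omega, a=a, amp=amp):
            return amp * omega * np.cos(omega * (np.asarray(x, float) - a) + phase)

    else:  # sum-of-Gaussians crypt pits
        width = span / (6.0 * k)
        centers = a + span * (np.arange(k) + 0.5) / k
        centers = centers + rng.uniform(-0.5, 0.5, size=k) * span / (4.0 * k)

        def f(x, centers=centers, width=width, amp=amp):
            x = np.asarray(x, float)[..., None]
            return spec.baseline_row + amp * np.exp(
                -((x - centers) ** 2) / (2 * width**2)
            ).sum(axis=-1)

        def df(x, centers=centers, width=width, amp=amp):
            x = np.asarray(x, float)[..., None]
            z = x - centers
            return (-amp * z / width**2 * np.exp(-(z**2) / (2 * width**2))).sum(axis=-1)

    return BorderCurve(f=f, df=df, a=a, b=b)


def render_iris(spec: SyntheticIrisSpec) -> Tuple[GrayImage, SyntheticTruth, LandmarkSet]:
    """Render a scene and return it with its analytic truth and landmarks.

    The left band is labelled nasal, the right temporal (the measurement is
    orientation-agnostic).  Peripheral landmarks sit at the outer end of each
    band's top edge, central landmarks at the pupillary end, exactly on the
    continuous curve (rounded to the pixel grid).
    """
    rng = np.random.default_rng(spec.seed)
    a_n = float(spec.margin)
    b_n = float(spec.margin + spec.side_span)
    b_t = float(spec.width - spec.margin)
    a_t = float(spec.width - spec.margin - spec.side_span)
    nasal = _make_curve(spec, a_n, b_n, rng)
    temporal = _make_curve(spec, a_t, b_t, rng)

    field = np.full((spec.height, spec.width), spec.background_level, dtype=float)
    rows = np.arange(spec.height, dtype=float)[:, None]
    for curve in (nasal, temporal):
        cols = np.arange(int(curve.a), int(curve.b) + 1)
        top = np.asarray(curve.f(cols.astype(float)), dtype=float)[None, :]
        if float(top.min()) < 2 or float(top.max()) + spec.iris_thickness > spec.height - 2:
            raise SyntheticSpecError("iris band leaves the frame; adjust baseline/amplitude")
        band = (rows >= top) & (rows < top + spec.iris_thickness)
        field[:, cols[0] : cols[-1] + 1][band] = spec.tissue_level

    if spec.speckle_sigma > 0:
        field = field * rng.lognormal(
            mean=-0.5 * spec.speckle_sigma**2, sigma=spec.speckle_sigma, size=field.shape
        )
    if spec.blur_sigma > 0:
        field = ndi.gaussian_filter(field, spec.blur_sigma)
    image = GrayImage(
        np.clip(field, 0, 255),
        provenance=f"synthetic:seed={spec.seed}",
    )

    def _pt(curve: BorderCurve, x: float) -> Point:
        return (int(round(float(curve.f(np.array(x))))), int(round(x)))

    landmarks = LandmarkSet(
        nasal_peripheral=_pt(nasal, nasal.a),
        nasal_central=_pt(nasal, nasal.b),
        temporal_peripheral=_pt(temporal, temporal.b),
        temporal_central=_pt(temporal, temporal.a),
    )
    si_n = analytic_si(nasal)
    si_t = analytic_si(temporal)
    chord_n = _chord(nasal)
    chord_t = _chord(temporal)
    overall = (chord_n + chord_t) / (chord_n / si_n + chord_t / si_t)
    truth = SyntheticTruth(
        nasal_curve=nasal,
        temporal_curve=temporal,
        true_si_nasal=si_n,
        true_si_temporal=si_t,
        true_si_overall=overall,
        landmarks=landmarks,
    )
    return image, truth, landmarks


def _chord(curve: BorderCurve) -> float:
    (ra, ca), (rb, cb) = curve.endpoints()
    return float(np.hypot(ra - rb, ca - cb))


#: Spec of the canonical clean scene whose histogram is the default
#: histogram-matching reference.
CANONICAL_REFERENCE_SPEC = SyntheticIrisSpec(
    crypt_amplitude=6.0, speckle_sigma=0.0, blur_sigma=0.0, seed=0
)


@functools.lru_cache(maxsize=1)
def default_reference_histogram() -> np.ndarray:
    """256-bin histogram of the canonical clean synthetic scene."""
    image, _, _ = render_iris(CANONICAL_REFERENCE_SPEC)
    return image.histogram()


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass
class EyeRecord:
    subject: str
    group: str  # "FU" | "control"
    eye: str  # "OD" | "OS"
    affected: bool
    spec: SyntheticIrisSpec
    truth: SyntheticTruth
    landmarks: LandmarkSet
    image: Optional[GrayImage] = None


def _overall_si_for_amplitude(
    base: SyntheticIrisSpec, amplitude: float, seed: int
) -> float:
    spec = replace(base, crypt_amplitude=float(amplitude), seed=seed)
    rng = np.random.default_rng(spec.seed)
    a_n = float(spec.margin)
    b_n = float(spec.margin + spec.side_span)
    b_t = float(spec.width - spec.margin)
    a_t = float(spec.width - spec.margin - spec.side_span)
    nasal = _make_curve(spec, a_n, b_n, rng)
    temporal = _make_curve(spec, a_t, b_t, rng)
    cn, ct = _chord(nasal), _chord(temporal)
    return (cn + ct) / (arc_length(nasal) + arc_length(temporal))


def generate_cohort(
    n_subjects: int,
    fu_effect: float,
    seed: int = 0,
    base_spec: Optional[SyntheticIrisSpec] = None,
    render: bool = True,
    max_amplitude: float = 38.0,
) -> List[EyeRecord]:
    """Simulate ``n_subjects`` FU subjects and ``n_subjects`` controls, two
    eyes each.

    In each FU subject one eye (randomly chosen) gets a crypt amplitude
    solved so that its analytic overall SI is lower than the fellow eye's by
    ``fu_effect``.  Control eyes share the subject's base amplitude.  With
    ``render=False`` only specs/truths are produced (fast; used for
    large-``n`` convergence checks).
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if not (0 <= fu_effect < 1):
        raise ValueError("fu_effect must lie in [0, 1)")
    base = base_spec or SyntheticIrisSpec()
    rng = np.random.default_rng(seed)
    records: List[EyeRecord] = []

    def make_eye(subject, group, eye, affected, amplitude, eye_seed):
        spec = replace(base, crypt_amplitude=float(amplitude), seed=int(eye_seed))
        if render:
            image, truth, lms = render_iris(spec)
        else:
            image = None
            _, truth, lms = _truth_only(spec)
        records.append(
            EyeRecord(subject, group, eye, affected, spec, truth, lms, image)
        )

    def _truth_only(spec):
        r = np.random.default_rng(spec.seed)
        a_n = float(spec.margin)
        b_n = float(spec.margin + spec.side_span)
        b_t = float(spec.width - spec.margin)
        a_t = float(spec.width - spec.margin - spec.side_span)
        nasal = _make_curve(spec, a_n, b_n, r)
        temporal = _make_curve(spec, a_t, b_t, r)
        si_n, si_t = analytic_si(nasal), analytic_si(temporal)
        cn, ct = _chord(nasal), _chord(temporal)
        overall = (cn + ct) / (cn / si_n + ct / si_t)
        lms = LandmarkSet(
            nasal_peripheral=(int(round(float(nasal.f(np.array(nasal.a))))), int(nasal.a)),
            nasal_central=(int(round(float(nasal.f(np.array(nasal.b))))), int(nasal.b)),
            temporal_peripheral=(int(round(float(temporal.f(np.array(temporal.b))))), int(temporal.b)),
            temporal_central=(int(round(float(temporal.f(np.array(temporal.a))))), int(temporal.a)),
        )
        truth = SyntheticTruth(nasal, temporal, si_n, si_t, overall, lms)
        return None, truth, lms

    for i in range(n_subjects):
        subject = f"FU{i + 1:03d}"
        base_amp = rng.uniform(4.0, 9.0)
        affected_eye = "OD" if rng.integers(2) == 0 else "OS"
        fellow_seed = int(rng.integers(2**31 - 1))
        affected_seed = int(rng.integers(2**31 - 1))
        fellow_si = _overall_si_for_amplitude(base, base_amp, fellow_seed)
        target = fellow_si - fu_effect

        def gap(amp, s=affected_seed, t=target):
            return _overall_si_for_amplitude(base, amp, s) - t

        lo, hi = 0.0, max_amplitude
        if gap(hi) > 0:
            raise SyntheticSpecError(
                "fu_effect not reachable within max_amplitude; widen the bracket"
            )
        affected_amp = brentq(gap, lo, hi, xtol=1e-4)
        for eye in ("OD", "OS"):
            is_aff = eye == affected_eye
            make_eye(
                subject,
                "FU",
                eye,
                is_aff,
                affected_amp if is_aff else base_amp,
                affected_seed if is_aff else fellow_seed,
            )

    for i in range(n_subjects):
        subject = f"CT{i + 1:03d}"
        base_amp = rng.uniform(4.0, 9.0)
        for eye in ("OD", "OS"):
            make_eye(subject, "control", eye, False, base_amp, int(rng.integers(2**31 - 1)))

    return records
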