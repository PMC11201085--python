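"""Width normalization of arch forms and fixed-length shape vectors.

An arch curve (x, y) in the occlusal frame is reduced to a dimensionless
2D shape by max-min normalizing x to [0, 1] and scaling y by the same factor,

    x' = (x - min x) / (max x - min x)
    y' = (y - min y) / (max x - min x)

so the arch width becomes 1 and the aspect ratio (depth/width) is preserved
exactly: max y' equals the depth-to-width ratio.  For statistics, a
normalized form is sampled at m evenly spaced x' values into a shape vector;
the Euclidean distance between shape vectors is the shape distance used by
clustering and anomaly detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import Polynomial

__all__ = [
    "NormalizationError",
    "NormalizedArchForm",
    "ShapeVector",
    "normalize_arch",
    "normalize_curve",
    "to_shape_vector",
]


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class NormalizedArchForm:
    """Width-normalized 2D arch shape.

    ``x_prime``/``y_prime`` are matched samples of the normalized curve;
    ``poly`` (if present) is the exact degree-6 polynomial of the normalized
    curve, y'(x') on [0, 1].
    """

    x_prime: np.ndarray
    y_prime: np.ndarray
    source: str = "dental"
    subject_id: str | int | None = None
    jaw: str | None = None
    poly: Polynomial | None = field(default=None, compare=False, repr=False)


@dataclass(frozen=True)
class ShapeVector:
    """y' sampled at m evenly spaced x' in [0, 1]."""

    values: np.ndarray
    m: int

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.ndim != 1 or len(v) != self.m:
            raise NormalizationError("values must be a length-m vector")
        if not np.all(np.isfinite(v)):
            raise NormalizationError("shape vector contains non-finite values")
        object.__setattr__(self, "values", v)


def normalize_arch(
    points: np.ndarray,
    source: str = "dental",
    subject_id=None,
    jaw: str | None = None,
) -> NormalizedArchForm:
    """Normalize an ordered 2D arch curve (Eq. of max-min width scaling)."""
    pts = np.atleast_2d(np.asarray(points, float))
    if pts.shape[1] != 2:
        raise NormalizationError("points must be (n, 2)")
    x, y = pts[:, 0], pts[:, 1]
    width = x.max() - x.min()
    if width <= 0:
        raise NormalizationError("zero arch width; cannot normalize")
    return NormalizedArchForm(
        x_prime=(x - x.min()) / width,
        y_prime=(y - y.min()) / width,
        source=source,
        subject_id=subject_id,
        jaw=jaw,
    )


def normalize_curve(curve, n_samples: int = 500, subject_id=None, jaw=None) -> NormalizedArchForm:
    """Normalize a fitted :class:`~archform.arch_extraction.ArchCurve`.

    Min/max are taken over a dense sample of the fitted polynomial (curve
    extrema, not raw landmarks), and the exact normalized polynomial is
    attached: y'(x') = (p(x0 + w x') - min y) / w.
    """
    x0, x1 = curve.domain
    w = x1 - x0
    if w <= 0:
        raise NormalizationError("degenerate curve domain")
    p = Polynomial(curve.coefficients)
    xs = np.linspace(x0, x1, n_samples)
    ys = p(xs)
    ymin = ys.min()
    q = (p(Polynomial([x0, w])) - ymin) / w  # exact affine substitution
    return NormalizedArchForm(
        x_prime=(xs - x0) / w,
        y_prime=(ys - ymin) / w,
        source=curve.source,
        subject_id=subject_id,
        jaw=jaw,
        poly=q,
    )


def to_shape_vector(form: NormalizedArchForm, m: int = 50) -> ShapeVector:
    """Sample a normalized form at m evenly spaced x' values.

    Forms built from a fitted curve are evaluated on their exact normalized
    polynomial; point-based forms get a degree-6 least-squares fit first.
    """
    if m < 7:
        raise NormalizationError("shape vector needs m >= 7 (degree-6 fit)")
    grid = np.linspace(0.0, 1.0, m)
    if form.poly is not None:
        return ShapeVector(values=form.poly(grid), m=m)
    if len(np.unique(form.x_prime)) < 7:
        raise NormalizationError("need at least 7 distinct x' values to fit")
    fit = Polynomial.fit(form.x_prime, form.y_prime, 6)
    return ShapeVector(values=fit(grid), m=m)
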