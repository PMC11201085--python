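"""Synthetic dental casts and cohorts with known ground truth.

No public dental-cast collection exists for this kind of analysis, so every
stage of the pipeline is exercised on synthetic casts that emulate the
structure the method assumes:

* a horseshoe row of 12 crown-like bumps (mixed dentition: primary molars,
  canines, incisors plus first permanent molars) whose apices -- the buccal
  cusp / cusp tip / incisal edge landmarks -- lie on a degree-6 dental arch
  template;
* a buccal soft-tissue skirt whose horizontal contour at one planted layer
  height is an exact offset of a degree-6 dentoalveolar (alveolar) arch
  template, while every other layer carries seeded sinusoidal corrugation
  ("corner points", emulating the festooned gingival margin);
* cohorts sampled from 6 dental x 6 dentoalveolar shape templates via an
  association table, with Gaussian within-cluster shape noise and optional
  planted outliers and mismatched template pairs.

Anatomical realism (lingual anatomy, root/bone interior, palate) is out of
scope; the generator targets the statistical and geometric assumptions of
the pipeline, not dental morphology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial

from .anomaly import AnomalyFlags
from .arch_extraction import ArchCurve, ArchLandmarks
from .geometry import DentalMesh, measure_depth_width
from .normalization import normalize_curve, to_shape_vector

__all__ = [
    "SyntheticDataError",
    "ArchTemplate",
    "SyntheticCohortConfig",
    "SyntheticCast",
    "MeshParams",
    "SHAPE_FAMILIES",
    "make_arch_template",
    "template_curve",
    "template_shape_vector",
    "default_dental_templates",
    "default_alveolar_templates",
    "default_association_table",
    "generate_synthetic_cast",
    "generate_cohort",
]


class SyntheticDataError(ValueError):
    pass


#: even-polynomial shape families: y(t) = depth * (1 - a t^2 - b t^4 - c t^6)
#: on t in [-1, 1] with a + b + c = 1 (endpoints at zero, apex at depth).
#: "square" arches are flat anteriorly, "tapered" arches pointed; the
#: narrow/wide variants push the profile further in each direction.
SHAPE_FAMILIES: dict[str, tuple[float, float, float]] = {
    "parabolic": (1.0, 0.0, 0.0),
    "ovoid": (0.4, 0.6, 0.0),
    "narrow_ovoid": (0.7, 0.3, 0.0),
    "tapered": (1.6, -0.6, 0.0),
    "narrow_tapered": (2.0, -1.2, 0.2),
    "square": (0.1, 0.3, 0.6),
    "wide_square": (0.0, 0.2, 0.8),
}


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArchTemplate:
    """Degree-6 polynomial arch-form generating center.

    ``coefficients`` are ascending powers of y(x) in mm on the domain
    [-width/2, width/2]; the measured arch width and depth equal the
    ``width``/``depth`` fields exactly.
    """

    template_id: int
    coefficients: np.ndarray
    width: float
    depth: float
    family: str = ""

    def __post_init__(self):
        object.__setattr__(self, "coefficients", np.asarray(self.coefficients, float))

    @property
    def domain(self) -> tuple[float, float]:
        return (-self.width / 2.0, self.width / 2.0)

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        return Polynomial(self.coefficients)(np.asarray(x, float))


def make_arch_template(
    shape_family: str, width: float, depth: float, template_id: int = 0
) -> ArchTemplate:
    """Construct a degree-6 arch template of a named shape family.

    The polynomial is y(x) = depth * q(2x/width) with q an even degree-6
    profile that is 1 at the apex and 0 at the distal endpoints, so the
    measured depth and width reproduce the requested values exactly.
    """
    if shape_family not in SHAPE_FAMILIES:
        raise SyntheticDataError(
            f"unknown shape family {shape_family!r}; known: {sorted(SHAPE_FAMILIES)}"
        )
    if not (width > 0 and depth > 0):
        raise SyntheticDataError("width and depth must be positive")
    a, b, c = SHAPE_FAMILIES[shape_family]
    s = 2.0 / width
    coef = depth * np.array([1.0, 0.0, -a * s**2, 0.0, -b * s**4, 0.0, -c * s**6])
    tpl = ArchTemplate(
        template_id=template_id, coefficients=coef, width=width, depth=depth, family=shape_family
    )
    meas = measure_depth_width(_dense_template_points(tpl))
    if abs(meas.width - width) > 1e-9 or abs(meas.depth - depth) > 1e-9:
        raise SyntheticDataError("template construction failed its depth/width check")
    return tpl


def _dense_template_points(tpl: ArchTemplate, n: int = 2001) -> np.ndarray:
    x = np.linspace(*tpl.domain, n)
    return np.column_stack([x, tpl.evaluate(x)])


def template_curve(tpl: ArchTemplate, source: str) -> ArchCurve:
    return ArchCurve(
        coefficients=tpl.coefficients, domain=tpl.domain, source=source, rms_residual=0.0
    )


def template_shape_vector(tpl: ArchTemplate, m: int = 50) -> np.ndarray:
    """Normalized shape vector of a template: (depth/width) * q at m x' values."""
    source = "dental"
    form = normalize_curve(template_curve(tpl, source))
    return to_shape_vector(form, m=m).values


def default_dental_templates(width: float = 34.0) -> list[ArchTemplate]:
    """Six dental arch-shape templates (cluster generating centers).

    Families and depth/width aspects chosen to spread the normalized shapes
    roughly evenly (pairwise shape-vector distances well above the default
    within-cluster noise), emulating six distinct dental arch clusters.
    """
    spec = [
        ("wide_square", 0.64),
        ("square", 0.72),
        ("ovoid", 0.78),
        ("tapered", 0.84),
        ("narrow_ovoid", 0.90),
        ("narrow_tapered", 0.97),
    ]
    return [
        make_arch_template(fam, width, aspect * width, template_id=i + 1)
        for i, (fam, aspect) in enumerate(spec)
    ]


def default_alveolar_templates(width: float = 42.0) -> list[ArchTemplate]:
    """Six dentoalveolar (alveolar contour) templates; wider than the teeth."""
    spec = [
        ("wide_square", 0.70),
        ("square", 0.76),
        ("ovoid", 0.82),
        ("ovoid", 0.89),
        ("narrow_ovoid", 0.96),
        ("narrow_ovoid", 1.04),
    ]
    return [
        make_arch_template(fam, width, aspect * width, template_id=i + 1)
        for i, (fam, aspect) in enumerate(spec)
    ]


def default_association_table(k_d: int = 6, k_a: int = 6) -> np.ndarray:
    """One-to-many dental/dentoalveolar pair probabilities.

    Mass concentrates on matching and neighbouring template pairs; pairs
    more than two clusters apart have probability exactly 0 (the unusual
    associations that mismatch planting draws from).
    """
    w = np.zeros((k_d, k_a))
    weights = {0: 1.0, 1: 0.45, 2: 0.15}
    for i in range(k_d):
        for j in range(k_a):
            w[i, j] = weights.get(abs(i - j), 0.0)
    return w / w.sum()


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Cohort-level generating conditions.

    ``shape_noise_sd`` is the within-cluster Gaussian perturbation of the
    normalized shape vector (normalized units, i.e. fractions of arch
    width); ``outlier_magnitude`` is the planted radial displacement in
    multiples of ``shape_noise_sd``.  Defaults emulate the normal-occlusion
    cohort size of 209 subjects with 6 dental and 6 dentoalveolar shape
    clusters.
    """

    n_subjects: int = 209
    n_dental_templates: int = 6
    n_alveolar_templates: int = 6
    association_table: np.ndarray | None = None
    shape_noise_sd: float = 0.02
    outlier_rate: float = 0.0
    outlier_magnitude: float = 8.0
    mismatch_rate: float = 0.0
    seed: int = 0

    def table(self) -> np.ndarray:
        if self.association_table is None:
            return default_association_table(self.n_dental_templates, self.n_alveolar_templates)
        return np.asarray(self.association_table, float)

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise SyntheticDataError("n_subjects must be >= 2")
        for name in ("outlier_rate", "mismatch_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SyntheticDataError(f"{name} must lie in [0, 1]")
        if self.shape_noise_sd < 0:
            raise SyntheticDataError("shape_noise_sd must be non-negative")
        t = self.table()
        if t.shape != (self.n_dental_templates, self.n_alveolar_templates):
            raise SyntheticDataError("association_table shape mismatch")
        if np.any(t < 0) or abs(t.sum() - 1.0) > 1e-9:
            raise SyntheticDataError("association_table entries must be >= 0 and sum to 1")


@dataclass(frozen=True)
class MeshParams:
    """Geometric parameters of a synthetic cast mesh (mm).

    The skirt spans z in [0, gum_height] with contour layers planted at the
    same heights the extractor slices at; ``lilo_layer`` (0-based, counted
    from the gingival margin downward) is the corrugation-free layer.
    """

    n_teeth: int = 12
    nx: int = 401                     # base column count (~20k vertices)
    n_layers: int = 10
    lilo_layer: int = 5
    gum_height: float = 6.0
    crown_height: float = 4.0
    crown_rows: int = 12
    bulge: float = 1.5                # buccal crown overhang above the margin
    sulcus_depth: float = 0.5         # gingival-sulcus inset carving the separating contour
    rim_height: float = 0.35          # free gingival margin rising above the sulcus
    notch_depth: float = 1.0          # interproximal cut separating neighbouring crowns
    tilt: float = 0.4                 # lateral skirt flare per mm below the margin
    corrugation_amplitude: float = 0.25
    plateau_frac: float = 0.25        # half-width of a layer's constant-corrugation band


@dataclass
class SyntheticCast:
    """One synthetic subject with full ground truth."""

    subject_id: str
    mesh: DentalMesh | None
    true_landmarks: ArchLandmarks | None
    true_lilo_layer: int
    true_dental_template: int
    true_alveolar_template: int
    true_anomaly_flags: AnomalyFlags
    dental_shape: np.ndarray
    alveolar_shape: np.ndarray
    true_vertex_labels: np.ndarray | None = None
    jaw: str = "mandible"


# ---------------------------------------------------------------------------
# single-cast mesh construction
# ---------------------------------------------------------------------------


def _tooth_roles(n: int) -> tuple:
    half = ["buccal_cusp", "buccal_cusp", "buccal_cusp", "cusp_tip", "incisal_edge", "incisal_edge"]
    if n == 12:
        return tuple(half + half[::-1])
    side = ["buccal_cusp"] * max(1, n // 2 - 3) + ["cusp_tip"]
    mid = ["incisal_edge"] * (n - 2 * len(side))
    return tuple(side + mid + side[::-1])


def _envelope(cols: np.ndarray, centers: np.ndarray, half_width: float):
    """Per-column crown envelope and owning tooth (-1 between crowns)."""
    e = np.zeros(len(cols))
    owner = -np.ones(len(cols), dtype=np.int64)
    for t, xc in enumerate(centers):
        s = (cols - xc) / half_width
        mask = np.abs(s) < 1.0
        # sqrt(cos) profile: rounded cap, steep interproximal walls
        f = np.sqrt(np.cos(np.pi * s[mask] / 2.0))
        e[mask] = np.maximum(e[mask], f)
        owner[mask] = np.where(f > 1e-9, t, owner[mask])
    return e, owner


def _layer_heights(gum_height: float, n_layers: int) -> np.ndarray:
    step = gum_height / (n_layers + 1)
    return gum_height - step * np.arange(1, n_layers + 1)


def _build_cast_mesh(
    tooth_x: np.ndarray,
    apex_y: np.ndarray,
    alv_poly: Polynomial,
    alv_width: float,
    params: MeshParams,
    rng: np.random.Generator,
    jaw: str,
):
    p = params
    wa2 = alv_width / 2.0
    half = (tooth_x[1] - tooth_x[0]) / 2.0
    # columns: tooth centers, interproximal boundaries and domain ends are
    # exact grid abscissae; the segments between them are subdivided close
    # to the target spacing so the grid stays locally uniform
    forced = np.concatenate(
        [tooth_x, (tooth_x[:-1] + tooth_x[1:]) / 2.0, [tooth_x[0] - half, tooth_x[-1] + half]]
    )
    forced = np.unique(np.concatenate([forced[(forced > -wa2) & (forced < wa2)], [-wa2, wa2]]))
    dx = 2 * wa2 / (p.nx - 1)
    pieces = []
    for a, b in zip(forced[:-1], forced[1:]):
        n_seg = max(1, int(round((b - a) / dx)))
        pieces.append(np.linspace(a, b, n_seg + 1)[:-1])
    cols = np.concatenate(pieces + [forced[-1:]])
    ncol = len(cols)
    e, owner = _envelope(cols, tooth_x, half)

    # per-column curves
    ym = alv_poly(cols)  # margin line (z = gum_height)
    # crown line: piecewise-linear between apices, clamped beyond the
    # terminal teeth (keeps the surface continuous at the window edges)
    yc = np.interp(cols, tooth_x, apex_y)

    H, h = p.gum_height, p.crown_height
    heights = _layer_heights(H, p.n_layers)
    step = H / (p.n_layers + 1)
    delta = p.plateau_frac * step

    # corrugation profile per layer band (constant across the band's 3 rows)
    corr = np.zeros((p.n_layers, ncol))
    for i in range(p.n_layers):
        if i == p.lilo_layer:
            continue
        amp = p.corrugation_amplitude * rng.uniform(0.7, 1.2)
        f1 = rng.uniform(5.0, 9.0)
        f2 = rng.uniform(9.0, 14.0)
        ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)
        u = cols / alv_width
        corr[i] = amp * np.sin(2 * np.pi * f1 * u + ph1) + 0.5 * amp * np.sin(
            2 * np.pi * f2 * u + ph2
        )

    rows_y, rows_z, rows_label = [], [], []

    def add_row(y, z, label):
        rows_y.append(np.broadcast_to(np.asarray(y, float), (ncol,)).copy())
        rows_z.append(np.broadcast_to(np.asarray(z, float), (ncol,)).copy())
        rows_label.append(label)

    # skirt: base, then each layer's plateau triplet bottom-up, then margin
    def skirt_y(z, band):
        c = corr[band] if band is not None else 0.0
        return ym + p.tilt * (H - z) + c

    add_row(skirt_y(0.0, None), 0.0, None)
    for i in range(p.n_layers - 1, -1, -1):
        for z in (heights[i] - delta, heights[i], heights[i] + delta):
            add_row(skirt_y(z, i), z, None)
    # free gingival margin: the skirt curls up into a rim and dips into a
    # sulcus groove at the margin height -- the concave contour line that
    # separates every crown (and the distal ledges) from the skirt
    add_row(ym - 0.15, H + p.rim_height, None)
    m0 = ym - p.sulcus_depth
    add_row(m0, H, None)

    # crown heights use an embrasure floor: neighbouring crowns touch, so
    # the interproximal saddle stays shallow instead of slotting down to the
    # gum (which would degenerate the surface normals)
    in_arch = (cols >= tooth_x[0] - half) & (cols <= tooth_x[-1] + half)
    ez = np.where(in_arch, np.maximum(e, 0.25), e)
    # crown buccal flank: sulcus -> apex; the bulge pushes crown flanks
    # buccally while the interproximal notch cuts inward between crowns,
    # keeping the separating contour concave along its whole length.  The
    # mesh ends at the buccal cusp/edge line (lingual anatomy is out of
    # scope), so the apex row is a mesh border.
    for j in range(1, p.crown_rows + 1):
        lam = j / p.crown_rows
        w = np.sin(np.pi * lam / 2.0)
        y = (
            m0
            + (yc - m0) * w
            + p.bulge * e * np.sin(np.pi * lam)
            - p.notch_depth * (1.0 - e) * np.sqrt(w)
        )
        z = H + h * ez * w
        add_row(y, z, "crown")

    nrow = len(rows_y)
    X = np.tile(cols, nrow)
    Y = np.concatenate(rows_y)
    Z = np.concatenate(rows_z)
    vertices = np.column_stack([X, Y, Z])
    faces = []
    for r in range(nrow - 1):
        a = r * ncol + np.arange(ncol - 1)
        b = a + 1
        c = a + ncol
        d = b + ncol
        faces.append(np.column_stack([a, b, d]))
        faces.append(np.column_stack([a, d, c]))
    faces = np.vstack(faces)
    mesh = DentalMesh(vertices=vertices, faces=faces, jaw=jaw)

    labels = -np.ones(len(vertices), dtype=np.int64)
    crown_rows = [r for r, lab in enumerate(rows_label) if lab == "crown"]
    col_owner = np.where(e > 0.05, owner, -1)
    for r in crown_rows:
        labels[r * ncol : (r + 1) * ncol] = col_owner
    # apex vertex indices: last crown buccal row at tooth-center columns
    apex_row = next(r for r, lab in enumerate(rows_label) if lab == "crown") + p.crown_rows - 1
    apex_cols = [int(np.argmin(np.abs(cols - x))) for x in tooth_x]
    apex_ids = [apex_row * ncol + c for c in apex_cols]
    apices = vertices[apex_ids]
    return mesh, labels, apices


def generate_synthetic_cast(
    dental_template: ArchTemplate,
    alveolar_template: ArchTemplate,
    config: SyntheticCohortConfig | None = None,
    params: MeshParams | None = None,
    seed: int | None = None,
    plant_ad: bool = False,
    plant_aa: bool = False,
    m: int = 50,
    subject_id: str = "S0001",
    jaw: str = "mandible",
    build_mesh: bool = True,
) -> SyntheticCast:
    """Generate one synthetic cast from a dental/alveolar template pair.

    Crown apices are the dental template samples perturbed per tooth by
    ``shape_noise_sd`` (in units of arch width); the skirt follows a
    degree-6 refit of noise-perturbed alveolar template nodes, so at zero
    noise both generating polynomials are reproduced exactly.  Planted
    outliers displace the apex/node sets radially by
    ``outlier_magnitude * shape_noise_sd``.
    """
    config = config or SyntheticCohortConfig()
    config.validate()
    params = params or MeshParams()
    if alveolar_template.width <= dental_template.width:
        raise SyntheticDataError("templates crossing: alveolar arch must be wider than dental")
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    sd = config.shape_noise_sd
    wd, wa = dental_template.width, alveolar_template.width

    tooth_x = np.linspace(-wd / 2.0, wd / 2.0, params.n_teeth)
    apex_y = dental_template.evaluate(tooth_x) + rng.normal(0.0, sd * wd, params.n_teeth)
    if plant_ad:
        u = rng.normal(size=params.n_teeth)
        u /= np.linalg.norm(u)
        apex_y = apex_y + config.outlier_magnitude * sd * wd * u

    nodes = np.cos(np.linspace(np.pi, 0.0, 13)) * (wa / 2.0)
    node_y = alveolar_template.evaluate(nodes) + rng.normal(0.0, sd * wa, 13)
    if plant_aa:
        u = rng.normal(size=13)
        u /= np.linalg.norm(u)
        node_y = node_y + config.outlier_magnitude * sd * wa * u
    alv_fit = Polynomial.fit(nodes, node_y, 6)
    alv_poly = Polynomial(np.pad(alv_fit.convert().coef, (0, 7))[:7])
    if np.min(alv_poly(tooth_x) - apex_y) <= 0:
        raise SyntheticDataError(
            "templates crossing: alveolar contour must stay buccal of the crown apices"
        )

    dental_curve = ArchCurve(
        coefficients=np.pad(Polynomial.fit(tooth_x, apex_y, 6).convert().coef, (0, 7))[:7],
        domain=(float(tooth_x[0]), float(tooth_x[-1])),
        source="dental",
    )
    alveolar_curve = ArchCurve(
        coefficients=alv_poly.coef if len(alv_poly.coef) == 7 else np.pad(alv_poly.coef, (0, 7))[:7],
        domain=(-wa / 2.0, wa / 2.0),
        source="dentoalveolar",
    )
    dental_shape = to_shape_vector(normalize_curve(dental_curve), m=m).values
    alveolar_shape = to_shape_vector(normalize_curve(alveolar_curve), m=m).values

    mesh = labels = landmarks = None
    if build_mesh:
        mesh, labels, apices = _build_cast_mesh(
            tooth_x, apex_y, alv_poly, wa, params, rng, jaw
        )
        landmarks = ArchLandmarks(
            points=apices,
            roles=_tooth_roles(params.n_teeth),
            tooth_labels=tuple(f"T{t + 1}" for t in range(params.n_teeth)),
        )
    return SyntheticCast(
        subject_id=subject_id,
        mesh=mesh,
        true_landmarks=landmarks,
        true_lilo_layer=params.lilo_layer,
        true_dental_template=dental_template.template_id,
        true_alveolar_template=alveolar_template.template_id,
        true_anomaly_flags=AnomalyFlags(ad=plant_ad, aa=plant_aa, mda=False),
        dental_shape=dental_shape,
        alveolar_shape=alveolar_shape,
        true_vertex_labels=labels,
        jaw=jaw,
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


def generate_cohort(
    config: SyntheticCohortConfig,
    dental_templates: list[ArchTemplate] | None = None,
    alveolar_templates: list[ArchTemplate] | None = None,
    m: int = 50,
    meshes: bool = False,
    params: MeshParams | None = None,
):
    """Generate a cohort of synthetic subjects with ground truth.

    Template pairs are drawn from the association table; each subject's
    dental/dentoalveolar shape vectors are the template shapes plus i.i.d.
    Gaussian noise (sd ``shape_noise_sd``).  Exactly
    ``round(outlier_rate * n)`` subjects carry a planted shape outlier
    (radially displaced by ``outlier_magnitude * shape_noise_sd``) and
    ``round(mismatch_rate * n)`` subjects are re-drawn from a
    zero-probability template pair.  With ``meshes=True`` full cast meshes
    are built per subject; otherwise only shape-level ground truth is
    generated (identical sampling, bit-reproducible per seed).

    Returns ``(casts, truth)`` where truth is a pandas DataFrame.
    """
    import pandas as pd

    config.validate()
    dental_templates = dental_templates or default_dental_templates()
    alveolar_templates = alveolar_templates or default_alveolar_templates()
    if len(dental_templates) != config.n_dental_templates:
        raise SyntheticDataError("dental template count does not match config")
    if len(alveolar_templates) != config.n_alveolar_templates:
        raise SyntheticDataError("alveolar template count does not match config")
    table = config.table()
    n = config.n_subjects
    rng = np.random.default_rng(config.seed)

    flat = table.ravel()
    pair_idx = rng.choice(len(flat), size=n, p=flat)
    di, ai = np.unravel_index(pair_idx, table.shape)

    n_mis = int(round(config.mismatch_rate * n))
    if n_mis > 0:
        zi, zj = np.nonzero(table == 0)
        if len(zi) == 0:
            raise SyntheticDataError("mismatch planting needs zero-probability pairs in the table")
        mis_subjects = rng.choice(n, size=n_mis, replace=False)
        picks = rng.integers(0, len(zi), size=n_mis)
        di[mis_subjects] = zi[picks]
        ai[mis_subjects] = zj[picks]
    else:
        mis_subjects = np.array([], dtype=int)

    n_out = int(round(config.outlier_rate * n))
    out_subjects = rng.choice(n, size=n_out, replace=False) if n_out else np.array([], dtype=int)
    out_kind = rng.integers(0, 2, size=n_out)  # 0 -> AD, 1 -> AA
    is_mis = np.zeros(n, dtype=bool)
    is_mis[mis_subjects] = True
    plant_ad = np.zeros(n, dtype=bool)
    plant_aa = np.zeros(n, dtype=bool)
    plant_ad[out_subjects[out_kind == 0]] = True
    plant_aa[out_subjects[out_kind == 1]] = True

    dental_vectors = np.array([template_shape_vector(t, m) for t in dental_templates])
    alveolar_vectors = np.array([template_shape_vector(t, m) for t in alveolar_templates])
    sd = config.shape_noise_sd

    casts: list[SyntheticCast] = []
    rows = []
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    for i in range(n):
        sid = f"S{i + 1:04d}"
        if meshes:
            cast = generate_synthetic_cast(
                dental_templates[di[i]],
                alveolar_templates[ai[i]],
                config=config,
                params=params,
                seed=int(child_seeds[i]),
                plant_ad=bool(plant_ad[i]),
                plant_aa=bool(plant_aa[i]),
                m=m,
                subject_id=sid,
            )
            cast.true_anomaly_flags = AnomalyFlags(
                ad=bool(plant_ad[i]), aa=bool(plant_aa[i]), mda=bool(is_mis[i])
            )
        else:
            sub_rng = np.random.default_rng(int(child_seeds[i]))
            vd = dental_vectors[di[i]] + sub_rng.normal(0.0, sd, m)
            va = alveolar_vectors[ai[i]] + sub_rng.normal(0.0, sd, m)
            if plant_ad[i]:
                u = sub_rng.normal(size=m)
                vd = vd + config.outlier_magnitude * sd * u / np.linalg.norm(u)
            if plant_aa[i]:
                u = sub_rng.normal(size=m)
                va = va + config.outlier_magnitude * sd * u / np.linalg.norm(u)
            cast = SyntheticCast(
                subject_id=sid,
                mesh=None,
                true_landmarks=None,
                true_lilo_layer=(params or MeshParams()).lilo_layer,
                true_dental_template=dental_templates[di[i]].template_id,
                true_alveolar_template=alveolar_templates[ai[i]].template_id,
                true_anomaly_flags=AnomalyFlags(
                    ad=bool(plant_ad[i]), aa=bool(plant_aa[i]), mda=bool(is_mis[i])
                ),
                dental_shape=vd,
                alveolar_shape=va,
            )
        casts.append(cast)
        rows.append(
            {
                "subject_id": sid,
                "dental_template": cast.true_dental_template,
                "alveolar_template": cast.true_alveolar_template,
                "ad": bool(plant_ad[i]),
                "aa": bool(plant_aa[i]),
                "mda": bool(is_mis[i]),
            }
        )
    return casts, pd.DataFrame(rows)
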