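"""Morphological anomaly detection for dental/dentoalveolar arch pairs.

Three basic anomalies are screened against cluster models fitted on a
normal-occlusion reference cohort:

* AD -- abnormal dental arch form: the Euclidean distance from the dental
  shape to its nearest dental cluster center falls outside mu_d +/- 1.96
  sigma_d of that cluster's member distances;
* AA -- the same rule for the dentoalveolar shape;
* MDA -- mismatched pair: the reference association-matrix cell of the
  assigned (dental, dentoalveolar) cluster pair is close to zero.

Combinations give 7 defined anomaly categories (AD, AA, MDA, AD+AA, AD+MDA,
AA+MDA, AD+AA+MDA); everything else is "none".  Because k-means is unstable
under re-initialization, detection is repeated over multiple rounds with
refitted models and a subject is flagged when the detection count exceeds a
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .shape_stats import (
    ArchClusterModel,
    AssociationMatrix,
    ShapeStatsError,
    build_association_matrix,
    cluster_arch_forms,
)

__all__ = [
    "AnomalyError",
    "AnomalyFlags",
    "AnomalyReport",
    "CATEGORIES",
    "detect_form_outlier",
    "detect_mismatch",
    "classify_anomaly",
    "score_anomalies",
    "estimate_anomaly_probability",
    "summarize_proportions",
]


class AnomalyError(ValueError):
    pass


CATEGORIES = ("none", "AD", "AA", "MDA", "AD+AA", "AD+MDA", "AA+MDA", "AD+AA+MDA")


@dataclass(frozen=True)
class AnomalyFlags:
    ad: bool = False
    aa: bool = False
    mda: bool = False


@dataclass
class AnomalyReport:
    subject_id: str | int | None
    jaw: str | None
    flags: AnomalyFlags
    category: str
    detection_fraction: dict
    rounds: int
    threshold: int


def detect_form_outlier(
    form: np.ndarray, model: ArchClusterModel, two_sided: bool = True
) -> tuple[bool, int]:
    """Flag a shape whose distance to its nearest cluster center is atypical.

    Assigns the nearest center and flags when the distance leaves the range
    mu +/- 1.96 sigma of that cluster's member distances.  The rule is
    two-sided by default (a distance below mu - 1.96 sigma also flags);
    ``two_sided=False`` keeps only the upper tail, which can be preferable
    since distances are non-negative.

    Returns (is_outlier, assigned cluster id in 1..k).
    """
    v = np.asarray(form, float).ravel()
    if v.shape[0] != model.centers.shape[1]:
        raise AnomalyError(
            f"form dimension {v.shape[0]} does not match centers ({model.centers.shape[1]})"
        )
    d = np.linalg.norm(model.centers - v, axis=1)
    j = int(np.argmin(d))
    dist = d[j]
    hi = model.mu[j] + 1.96 * model.sigma[j]
    lo = model.mu[j] - 1.96 * model.sigma[j]
    out = dist > hi or (two_sided and dist < lo)
    return bool(out), j + 1


def detect_mismatch(
    cluster_d: int, cluster_a: int, assoc: AssociationMatrix, epsilon: float
) -> bool:
    """True when the (dental, dentoalveolar) pair is an unusual association,
    i.e. its association-matrix cell is below ``epsilon``."""
    return assoc.cell(cluster_d, cluster_a) < epsilon


def classify_anomaly(flags: AnomalyFlags) -> str:
    """Map the three basic flags to one of the 7 anomaly categories or none."""
    parts = [name for name, on in (("AD", flags.ad), ("AA", flags.aa), ("MDA", flags.mda)) if on]
    return "+".join(parts) if parts else "none"


def default_epsilon(n_reference: int) -> float:
    """Half a subject's worth of association mass."""
    return 0.5 / n_reference


def score_anomalies(
    forms_d: np.ndarray,
    forms_a: np.ndarray,
    reference_d: np.ndarray,
    reference_a: np.ndarray,
    rounds: int = 100,
    threshold: int | None = None,
    epsilon: float | None = None,
    seed: int | None = None,
    k: int | str = "auto",
    n_init: int = 10,
    two_sided: bool = True,
    subject_ids=None,
    jaw: str | None = None,
) -> list[AnomalyReport]:
    """Multi-round anomaly screening of subjects against a reference cohort.

    Per round, dental and dentoalveolar cluster models and the association
    matrix are refitted on the reference shapes with a fresh seeded
    initialization (the reference is never refit on the screened subjects).
    Per-flag detection counts accumulate over rounds; a final flag is set
    when its count exceeds ``threshold`` (default rounds // 2).
    """
    fd = np.atleast_2d(np.asarray(forms_d, float))
    fa = np.atleast_2d(np.asarray(forms_a, float))
    if len(fd) != len(fa):
        raise AnomalyError("dental and dentoalveolar form counts differ")
    if rounds < 1:
        raise AnomalyError("rounds must be >= 1")
    if threshold is None:
        threshold = rounds // 2
    if not 0 <= threshold <= rounds:
        raise AnomalyError("threshold must lie in [0, rounds]")
    if epsilon is None:
        epsilon = default_epsilon(len(np.atleast_2d(reference_d)))
    n = len(fd)
    counts = np.zeros((n, 3), dtype=int)
    ss = np.random.SeedSequence(seed)
    round_seeds = ss.generate_state(rounds) % (2**31)
    for r in range(rounds):
        model_d = cluster_arch_forms(reference_d, k=k, n_init=n_init, seed=int(round_seeds[r]))
        model_a = cluster_arch_forms(reference_a, k=k, n_init=n_init, seed=int(round_seeds[r]) + 1)
        assoc = build_association_matrix(
            model_d.labels, model_a.labels, k_d=model_d.k, k_a=model_a.k
        )
        for i in range(n):
            ad, cd = detect_form_outlier(fd[i], model_d, two_sided=two_sided)
            aa, ca = detect_form_outlier(fa[i], model_a, two_sided=two_sided)
            mda = detect_mismatch(cd, ca, assoc, epsilon)
            counts[i] += (ad, aa, mda)
    reports = []
    for i in range(n):
        flags = AnomalyFlags(
            ad=bool(counts[i, 0] > threshold),
            aa=bool(counts[i, 1] > threshold),
            mda=bool(counts[i, 2] > threshold),
        )
        reports.append(
            AnomalyReport(
                subject_id=subject_ids[i] if subject_ids is not None else i,
                jaw=jaw,
                flags=flags,
                category=classify_anomaly(flags),
                detection_fraction={
                    "ad": counts[i, 0] / rounds,
                    "aa": counts[i, 1] / rounds,
                    "mda": counts[i, 2] / rounds,
                },
                rounds=rounds,
                threshold=threshold,
            )
        )
    return reports


def estimate_anomaly_probability(
    form_d: np.ndarray,
    form_a: np.ndarray,
    reference_shapes: tuple,
    rounds: int = 100,
    threshold: int | None = None,
    seed: int | None = None,
    **kwargs,
) -> AnomalyReport:
    """Single-subject wrapper around :func:`score_anomalies`.

    ``reference_shapes`` is the (reference dental, reference dentoalveolar)
    shape-vector pair of the normal-occlusion cohort.
    """
    ref_d, ref_a = reference_shapes
    return score_anomalies(
        np.atleast_2d(form_d),
        np.atleast_2d(form_a),
        ref_d,
        ref_a,
        rounds=rounds,
        threshold=threshold,
        seed=seed,
        **kwargs,
    )[0]


def summarize_proportions(reports: list) -> dict:
    """Per-jaw category proportions.

    Returns ``{jaw: {"proportions": {category: fraction}, "overall": x}}``
    where proportions cover all 8 categories and sum to 1, and overall is
    the total anomaly proportion 1 - proportion(none).
    """
    if not reports:
        raise AnomalyError("no reports to summarize")
    out: dict = {}
    jaws = sorted({r.jaw for r in reports}, key=str)
    for jaw in jaws:
        sub = [r for r in reports if r.jaw == jaw]
        props = {c: sum(r.category == c for r in sub) / len(sub) for c in CATEGORIES}
        out[jaw] = {"proportions": props, "overall": 1.0 - props["none"]}
    return out
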