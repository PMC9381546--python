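"""Confidence-interval re-estimation and QTL transfer to the consensus map."""

from __future__ import annotations

from .consensus import AnchorSet, local_expansion, project_position
from .errors import DomainError, UnusableRecordError
from .types import CI95_FACTOR, ProjectedQtl, QtlRecord

#: CI policies: prefer the study-reported interval, or recompute from N and R².
CI_POLICIES = ("reported_first", "recomputed_always")


def darvasi_soller_ci(pop_size: int, r2: float) -> float:
    """Empirical 95% CI width (cM) for a QTL in a biparental population:
    530 / (N * R²), with N the population size and R² the proportion of
    phenotypic variance explained."""
    if pop_size < 2:
        raise DomainError(f"pop_size must be >= 2, got {pop_size}")
    if not 0 < r2 <= 1:
        raise DomainError(f"r2 must be in (0, 1], got {r2}")
    return 530.0 / (pop_size * r2)


def sigma_from_ci(ci95: float) -> float:
    """Gaussian sd implied by a 95% CI width (CI = 2 * 1.96 * sd)."""
    if ci95 <= 0:
        raise DomainError(f"ci95 must be > 0, got {ci95}")
    return ci95 / CI95_FACTOR


def _source_ci(q: QtlRecord, policy: str) -> tuple[float, str]:
    reported = q.reported_ci()
    recomputed = (
        darvasi_soller_ci(q.pop_size, q.r2)
        if q.pop_size is not None and q.r2 is not None
        else None
    )
    if policy == "reported_first":
        choices = [(reported, "reported"), (recomputed, "darvasi_soller")]
    elif policy == "recomputed_always":
        choices = [(recomputed, "darvasi_soller"), (reported, "reported")]
    else:
        raise DomainError(f"unknown ci_policy {policy!r}")
    for ci, label in choices:
        if ci is not None:
            return ci, label
    missing = []
    if reported is None:
        missing.append("ci_start/ci_end")
    if q.pop_size is None:
        missing.append("pop_size")
    if q.r2 is None:
        missing.append("r2")
    raise UnusableRecordError(q.qtl_id, missing)


def project_qtl(
    q: QtlRecord, anchors: AnchorSet, ci_policy: str = "reported_first"
) -> ProjectedQtl:
    """Express a QTL on the consensus map.

    The position is transferred through the anchor interpolation; the chosen
    source-map CI is rescaled by the local expansion ratio λ of the anchor
    interval containing the QTL, and the Gaussian sd follows as ci95 / 3.92.
    """
    ci_source_cm, ci_label = _source_ci(q, ci_policy)
    lam = local_expansion(q.position, anchors)
    ci95 = ci_source_cm * lam
    return ProjectedQtl(
        qtl_id=q.qtl_id,
        chromosome=q.chromosome,
        position=project_position(q.position, anchors),
        sigma=sigma_from_ci(ci95),
        ci95=ci95,
        study_id=q.study_id,
        lod=q.lod,
        r2=q.r2,
        pop_size=q.pop_size,
        expansion=lam,
        ci_source=ci_label,
    )


def project_records(
    records: list[QtlRecord],
    anchor_sets: dict[str, dict[int, AnchorSet]],
    ci_policy: str = "reported_first",
) -> tuple[list[ProjectedQtl], list[tuple[QtlRecord, str]]]:
    """Project a compilation; returns (projected, skipped-with-reason).

    ``anchor_sets`` maps study_id -> chromosome -> filtered AnchorSet.
    """
    projected: list[ProjectedQtl] = []
    skipped: list[tuple[QtlRecord, str]] = []
    for q in records:
        anchors = anchor_sets.get(q.study_id, {}).get(q.chromosome)
        if anchors is None:
            skipped.append((q, "no anchors for study map on this chromosome"))
            continue
        try:
            projected.append(project_qtl(q, anchors, ci_policy))
        except UnusableRecordError as exc:
            skipped.append((q, str(exc)))
    projected.sort(key=lambda p: (p.chromosome, p.position, p.qtl_id))
    return projected, skipped
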