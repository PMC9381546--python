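"""Synthetic multi-study QTL compilations with companion maps.

The generator mirrors the statistical shape of a published grain-weight QTL
compilation: 22 studies contributing 114 QTL over 12 chromosomes (22 of them
on chromosome 3, 4 on chromosome 12), population sizes in [39, 353], PVE
with mean 10.8% on (0.4%, 60%), about 49% of LOD scores below 5, and QTL
positions scattered around a small number of true meta-loci with per-QTL
spread implied by the 530/(N·R²) confidence-interval rule.

Positions are drawn in reference-map coordinates and then re-expressed on
each study's own (jittered, subsampled) map, so a bundle exercises the whole
pipeline: map projection, CI re-estimation, clustering, and annotation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .consensus import AnchorSet, monotone_filter, project_position, shared_anchors
from .errors import DomainError
from .types import CI95_FACTOR, GeneticMap, QtlRecord
from .qtl_io import write_genetic_maps, write_qtl_table

CM_TO_BP = 250_000

_DEFAULT_LENGTHS = {
    1: 180.0, 2: 160.0, 3: 170.0, 4: 130.0, 5: 125.0, 6: 125.0,
    7: 120.0, 8: 125.0, 9: 95.0, 10: 85.0, 11: 120.0, 12: 110.0,
}
# per-chromosome QTL allocation of the emulated compilation (sums to 114)
_DEFAULT_N_QTL = {
    1: 8, 2: 14, 3: 22, 4: 3, 5: 14, 6: 9, 7: 5, 8: 12, 9: 9, 10: 8, 11: 6, 12: 4,
}
# number of true meta-loci per chromosome in the emulated compilation
_DEFAULT_N_MQTL = {1: 4, 2: 4, 4: 3, 5: 4, 6: 2, 7: 3, 8: 4, 9: 3, 10: 3, 11: 4, 12: 2}
# chromosome 3 truth: three components; raw weights 0.19/0.33/0.37 normalized
_CHR3_TRUTH = [(39.5, 0.19 / 0.89), (92.82, 0.33 / 0.89), (116.66, 0.37 / 0.89)]


def _default_true_mqtl() -> dict[int, list[tuple[float, float]]]:
    truth: dict[int, list[tuple[float, float]]] = {3: list(_CHR3_TRUTH)}
    for chrom, m in _DEFAULT_N_MQTL.items():
        length = _DEFAULT_LENGTHS[chrom]
        truth[chrom] = [(length * (i + 1) / (m + 1), 1.0 / m) for i in range(m)]
    return truth


@dataclass
class SimConfig:
    """All knobs of the generator; defaults emulate the reference study."""

    seed: int = 0
    n_studies: int = 22
    chrom_length_cm: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_LENGTHS)
    )
    n_qtl: dict[int, int] = field(default_factory=lambda: dict(_DEFAULT_N_QTL))
    true_mqtl: dict[int, list[tuple[float, float]]] = field(
        default_factory=_default_true_mqtl
    )
    pop_size_range: tuple[int, int] = (39, 353)
    r2_bounds: tuple[float, float] = (0.004, 0.60)
    r2_beta: tuple[float, float] = (1.3, 6.15)
    r2_target_mean: float | None = 0.108
    lod_frac_below5: float = 56 / 114
    lod_low_range: tuple[float, float] = (2.0, 5.0)
    lod_high_range: tuple[float, float] = (5.0, 14.0)
    anchor_density: float = 0.5  # markers per cM on the reference map
    map_jitter: float = 0.1  # sd (cM) of study-map position noise
    study_marker_frac: float = 0.7
    genes_per_mqtl: int = 6

    def __post_init__(self) -> None:
        for chrom, comps in self.true_mqtl.items():
            total = sum(w for _, w in comps)
            if abs(total - 1.0) > 1e-9:
                raise DomainError(
                    f"chromosome {chrom}: component weights sum to {total}, not 1"
                )
        lo, hi = self.pop_size_range
        if not 2 <= lo <= hi:
            raise DomainError(f"invalid pop_size_range {self.pop_size_range}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("chrom_length_cm", "n_qtl"):
            if key in raw:
                raw[key] = {int(k): v for k, v in raw[key].items()}
        if "true_mqtl" in raw:
            raw["true_mqtl"] = {
                int(k): [tuple(pair) for pair in v]
                for k, v in raw["true_mqtl"].items()
            }
        for key in (
            "pop_size_range", "r2_bounds", "r2_beta", "lod_low_range", "lod_high_range"
        ):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def calibrate_mean(
    values: np.ndarray, target: float, lo: float, hi: float, iters: int = 500
) -> np.ndarray:
    """Rescale a bounded sample so its mean hits ``target`` exactly.

    Repeated multiplicative scaling with re-clipping; converges to machine
    precision because the target lies strictly inside (lo, hi).
    """
    v = np.asarray(values, dtype=float).copy()
    for _ in range(iters):
        m = v.mean()
        if abs(m - target) < 1e-13:
            break
        v = np.clip(v * (target / m), lo, hi)
    return v


def _draw_r2(cfg: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    lo, hi = cfg.r2_bounds
    a, b = cfg.r2_beta
    return lo + (hi - lo) * rng.beta(a, b, size=n)


def _draw_lod(
    cfg: SimConfig, rng: np.random.Generator, below5: np.ndarray
) -> np.ndarray:
    lod = np.empty(below5.size)
    n_low = int(below5.sum())
    lod[below5] = rng.uniform(*cfg.lod_low_range, size=n_low)
    lod[~below5] = rng.uniform(*cfg.lod_high_range, size=below5.size - n_low)
    return lod


def simulate_chromosome(
    cfg: SimConfig,
    chromosome: int,
    rng: np.random.Generator | None = None,
    pop_sizes: np.ndarray | None = None,
    r2: np.ndarray | None = None,
    lod: np.ndarray | None = None,
    study_ids: list[str] | None = None,
) -> tuple[list[QtlRecord], dict]:
    """Draw one chromosome's QTL around its true meta-loci.

    Each QTL: a component k ~ Categorical(weights); N and R² (drawn here
    unless pre-drawn arrays are passed in by the bundle writer); a Gaussian
    sd s = (530/(N·R²))/3.92; an observed position ~ Normal(μ_k, s²)
    truncated to the chromosome; and a reported CI of position ± 1.96 s
    clipped to the chromosome.  The truth record keeps the component
    assignments and true means.
    """
    n = cfg.n_qtl.get(chromosome, 0)
    if n < 1:
        raise DomainError(f"chromosome {chromosome}: n_qtl must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    length = cfg.chrom_length_cm[chromosome]
    comps = cfg.true_mqtl[chromosome]
    weights = np.array([w for _, w in comps])
    mus = np.array([p for p, _ in comps])

    assignment = rng.choice(len(comps), size=n, p=weights)
    if pop_sizes is None:
        pop_sizes = rng.integers(cfg.pop_size_range[0], cfg.pop_size_range[1] + 1, n)
    if r2 is None:
        r2 = _draw_r2(cfg, rng, n)
    if lod is None:
        lod = _draw_lod(cfg, rng, rng.random(n) < cfg.lod_frac_below5)
    if study_ids is None:
        study_ids = [f"study{rng.integers(cfg.n_studies) + 1:02d}" for _ in range(n)]

    records: list[QtlRecord] = []
    for i in range(n):
        sd = (530.0 / (pop_sizes[i] * r2[i])) / CI95_FACTOR
        mu = mus[assignment[i]]
        a, b = (0.0 - mu) / sd, (length - mu) / sd
        pos = float(truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))
        ci_lo = max(0.0, pos - 1.96 * sd)
        ci_hi = min(length, pos + 1.96 * sd)
        records.append(
            QtlRecord(
                study_id=study_ids[i],
                qtl_id=f"q{chromosome}.{i + 1}",
                chromosome=chromosome,
                position=pos,
                lod=round(float(lod[i]), 2),
                r2=float(r2[i]),
                pop_size=int(pop_sizes[i]),
                ci_start=ci_lo,
                ci_end=ci_hi,
            )
        )
    truth = {
        "chromosome": chromosome,
        "n_qtl": n,
        "true_k": len(comps),
        "components": [{"position": p, "weight": w} for p, w in comps],
        "assignments": [int(k) for k in assignment],
    }
    return records, truth


def simulate_study_maps(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GeneticMap, dict[str, GeneticMap]]:
    """Reference map plus one subsampled, jittered map per study.

    Reference markers are placed uniformly at 1/anchor_density spacing.  Each
    study keeps a random subset (terminal markers always retained, so every
    chromosome has at least two anchors) and perturbs positions with Gaussian
    noise; jittered positions are re-sorted onto the original marker order,
    so marker order is preserved by construction.
    """
    if cfg.anchor_density <= 0:
        raise DomainError("anchor_density must be > 0")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    spacing = 1.0 / cfg.anchor_density
    ref_entries: list[tuple[str, int, float]] = []
    for chrom in sorted(cfg.chrom_length_cm):
        length = cfg.chrom_length_cm[chrom]
        n_mark = int(np.floor(length / spacing)) + 1
        for i in range(n_mark):
            ref_entries.append((f"M{chrom:02d}_{i:03d}", chrom, round(i * spacing, 6)))
    reference = GeneticMap("reference", ref_entries)

    study_maps: dict[str, GeneticMap] = {}
    for s in range(1, cfg.n_studies + 1):
        entries: list[tuple[str, int, float]] = []
        for chrom in sorted(cfg.chrom_length_cm):
            markers = reference.markers_on(chrom)
            keep = rng.random(len(markers)) < cfg.study_marker_frac
            keep[0] = keep[-1] = True
            kept = [m for m, k in zip(markers, keep) if k]
            pos = np.array([p for _, p in kept])
            jittered = np.sort(pos + rng.normal(0.0, cfg.map_jitter, len(kept)))
            entries.extend(
                (name, chrom, float(jp)) for (name, _), jp in zip(kept, jittered)
            )
        sid = f"study{s:02d}"
        study_maps[sid] = GeneticMap(sid, entries)
    return reference, study_maps


def _study_anchor(
    study_map: GeneticMap, reference: GeneticMap, chromosome: int
) -> AnchorSet:
    """Anchors mapping reference cM -> study cM (the inverse direction)."""
    fwd = monotone_filter(shared_anchors(study_map, reference, chromosome))
    return AnchorSet(
        chromosome=chromosome,
        pairs=sorted((c, s) for s, c in fwd.pairs),
        markers=fwd.markers,
    )


def _assign_studies(cfg: SimConfig, rng: np.random.Generator, total: int) -> list[str]:
    """Spread QTL over studies: every study contributes at least 3 (when the
    total allows), remaining slots are random."""
    base = min(3, total // cfg.n_studies)
    ids = [s for s in range(1, cfg.n_studies + 1) for _ in range(base)]
    ids += list(rng.integers(1, cfg.n_studies + 1, size=total - len(ids)))
    rng.shuffle(ids)
    return [f"study{s:02d}" for s in ids]


def simulate_compilation(
    cfg: SimConfig,
) -> tuple[list[QtlRecord], dict, GeneticMap, dict[str, GeneticMap]]:
    """Full multi-chromosome draw with bundle-level calibrations.

    R² values are drawn for the whole compilation and rescaled so the sample
    mean matches ``r2_target_mean`` exactly; the count of LOD scores below 5
    is fixed at round(lod_frac_below5 × total).  QTL positions and CIs are
    re-expressed on their study's own map.
    """
    rng = np.random.default_rng(cfg.seed)
    reference, study_maps = simulate_study_maps(cfg, rng)

    chroms = sorted(cfg.n_qtl)
    total = sum(cfg.n_qtl[c] for c in chroms)
    pop_sizes = rng.integers(cfg.pop_size_range[0], cfg.pop_size_range[1] + 1, total)
    r2 = _draw_r2(cfg, rng, total)
    if cfg.r2_target_mean is not None:
        r2 = calibrate_mean(r2, cfg.r2_target_mean, *cfg.r2_bounds)
    below5 = np.zeros(total, dtype=bool)
    below5[rng.permutation(total)[: round(cfg.lod_frac_below5 * total)]] = True
    lod = _draw_lod(cfg, rng, below5)
    study_ids = _assign_studies(cfg, rng, total)

    records: list[QtlRecord] = []
    truth: dict = {"chromosomes": {}, "seed": cfg.seed, "n_qtl_total": total}
    offset = 0
    for chrom in chroms:
        n = cfg.n_qtl[chrom]
        sl = slice(offset, offset + n)
        chrom_records, chrom_truth = simulate_chromosome(
            cfg,
            chrom,
            rng,
            pop_sizes=pop_sizes[sl],
            r2=r2[sl],
            lod=lod[sl],
            study_ids=study_ids[sl],
        )
        offset += n
        # re-express positions and CI bounds in the study map's coordinates
        for q in chrom_records:
            inv = _study_anchor(study_maps[q.study_id], reference, chrom)
            q.ci_start = project_position(q.ci_start, inv)
            q.position = project_position(q.position, inv)
            q.ci_end = project_position(q.ci_end, inv)
            markers = study_maps[q.study_id].markers_on(chrom)
            left = [m for m, p in markers if p <= q.position]
            right = [m for m, p in markers if p > q.position]
            q.flank_left = left[-1] if left else None
            q.flank_right = right[0] if right else None
        records.extend(chrom_records)
        truth["chromosomes"][str(chrom)] = chrom_truth

    records.sort(key=lambda q: (q.chromosome, q.position, q.qtl_id))
    return records, truth, reference, study_maps


def simulate_panel(
    cfg: SimConfig, rng: np.random.Generator, n_per_class: int = 7
) -> pd.DataFrame:
    """An extreme-phenotype validation panel with a perfectly linked marker.

    The printed extremes of the emulated panel (9.50 g and 37.27 g) anchor
    the two classes; the remaining genotypes are drawn inside the class
    ranges.  Low-class genotypes carry the 100 bp amplicon, high-class the
    85 bp one.
    """
    rows = [("Adam Chini", 9.50, "100bp")]
    for i in range(n_per_class - 1):
        rows.append((f"low{i + 1:02d}", round(rng.uniform(9.6, 12.4), 2), "100bp"))
    rows.append(("Niiaw Hawm", 37.27, "85bp"))
    for i in range(n_per_class - 1):
        rows.append((f"high{i + 1:02d}", round(rng.uniform(25.1, 37.0), 2), "85bp"))
    return pd.DataFrame(rows, columns=["genotype_id", "tgw_g", "allele"])


def _write_markers_bp(reference: GeneticMap, path: Path) -> None:
    rows = [
        {"marker": m, "chromosome": c, "bp": int(round(p * CM_TO_BP)) + 1}
        for m, c, p in reference.entries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_genes_gff3(cfg: SimConfig, path: Path) -> None:
    """Toy genes tiled inside each true meta-locus's physical neighbourhood."""
    lines = ["##gff-version 3"]
    for chrom in sorted(cfg.true_mqtl):
        for ci, (pos, _) in enumerate(cfg.true_mqtl[chrom], start=1):
            centre = int(round(pos * CM_TO_BP)) + 1
            width, step = 3000, 12000
            first = centre - step * (cfg.genes_per_mqtl // 2)
            for gi in range(cfg.genes_per_mqtl):
                start = max(1, first + gi * step)
                end = start + width - 1
                strand = "+" if gi % 2 == 0 else "-"
                locus = f"LOC_sim{chrom:02d}g{ci}{gi:02d}"
                lines.append(
                    f"Chr{chrom}\tsim\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
                    f"ID={locus};description=synthetic locus near {pos} cM"
                )
    path.write_text("\n".join(lines) + "\n")


def write_bundle(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Emit a complete end-to-end fixture directory.

    Files: qtl.tsv, maps.tsv, ref_map.tsv, markers_bp.tsv, genes.gff3,
    panel.tsv, truth.json — all plain text, all parseable by ``qtl_io``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, truth, reference, study_maps = simulate_compilation(cfg)
    panel_rng = np.random.default_rng(cfg.seed + 77)

    paths = {name: outdir / fname for name, fname in [
        ("qtl", "qtl.tsv"),
        ("maps", "maps.tsv"),
        ("ref_map", "ref_map.tsv"),
        ("markers_bp", "markers_bp.tsv"),
        ("genes", "genes.gff3"),
        ("panel", "panel.tsv"),
        ("truth", "truth.json"),
    ]}
    write_qtl_table(records, paths["qtl"])
    write_genetic_maps(list(study_maps.values()), paths["maps"])
    write_genetic_maps([reference], paths["ref_map"])
    _write_markers_bp(reference, paths["markers_bp"])
    _write_genes_gff3(cfg, paths["genes"])
    simulate_panel(cfg, panel_rng).to_csv(paths["panel"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return paths
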