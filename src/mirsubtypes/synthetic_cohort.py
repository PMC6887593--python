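"""Two-cohort synthetic study generator with planted ground truth.

The generator emulates a discovery/validation pair of NSCLC-style cohorts on
one shared gene universe: tumor samples drawn from 3 (AD-like) or 4
(SCC-like) expression subtypes at cohort-specific frequencies, normal
samples in the validation cohort only, a centroid model over a classifier
gene list driving the subtype structure of the mRNA matrix, hallmark-style
gene sets with planted per-subtype activity shifts, subtype-specific miRNAs
planted as additive log2 shifts, planted miRNA->target repression producing
a negative rank correlation, per-feature detection dropout, and a predicted
target rank table mixing the planted pairs (class very_high) with decoys.

Everything is drawn from one seeded generator, so the same configuration and
seed reproduce the study bit for bit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from mirsubtypes.io_formats import (
    CentroidModel,
    CohortAnnotation,
    ExprMatrix,
    GeneSetCollection,
    TargetRankTable,
)

logger = logging.getLogger(__name__)

DISCOVERY = "discovery"
VALIDATION = "validation"


@dataclass(frozen=True)
class MarkerSpec:
    mirna_index: int
    subtype: str
    direction: str  # "up" or "down"
    shift: float = 1.5  # additive log2 shift in the marker subtype's tumors
    normal_shift: float = 0.0  # shift also present in normals (normal-like marker)


@dataclass(frozen=True)
class PathwaySpec:
    set_name: str
    subtype: str
    shift: float  # mean log2 shift applied to the set's shifted members


@dataclass(frozen=True)
class TargetSpec:
    mirna_index: int
    gene_index: int
    slope: float = -0.65  # log2 change in the gene per unit miRNA deviation


@dataclass
class SimConfig:
    """Study conditions for the synthetic two-cohort experiment.

    Cohort sizes and subtype frequencies default to the AD-like design:
    discovery frequencies (TRU 0.614, PI 0.212, PP 0.174), validation
    frequencies (TRU 0.458, PI 0.353, PP 0.189), 45 normal samples in the
    validation cohort only.  Marker shifts default to 1.5 log2 units on
    Gaussian noise with sd 1.0; planted targets use a slope giving a design
    rank correlation of about -0.6.
    """

    n_discovery: int = 240
    n_validation: int = 500
    n_normal_validation: int = 45
    subtype_names: tuple[str, ...] = ("TRU", "PI", "PP")
    freq_discovery: tuple[float, ...] = (0.614, 0.212, 0.174)
    freq_validation: tuple[float, ...] = (0.458, 0.353, 0.189)
    histology_branch: str = "AD-like"
    n_mirnas: int = 300
    n_genes: int = 800
    n_classifier_genes: int = 120
    centroid_scale: float = 2.0
    n_gene_sets: int = 50
    set_size: int = 30
    shifted_fraction: float = 0.7  # fraction of a shifted set's genes that move
    n_markers: int = 12
    marker_shift: float = 1.5
    n_targets: int = 20
    target_slope: float = -0.65
    pathway_shift: float = 1.0
    noise_sd: float = 1.0
    sample_offset_sd: float = 0.0  # per-sample technical offset (off by default)
    detect_prob: float = 0.98
    low_detect_fraction: float = 0.06
    low_detect_prob: float = 0.05
    feature_mismatch_fraction: float = 0.0  # miRNAs dropped from validation
    marker_spec: tuple[MarkerSpec, ...] | None = None
    pathway_spec: tuple[PathwaySpec, ...] | None = None
    target_spec: tuple[TargetSpec, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_discovery", "n_validation", "n_mirnas", "n_genes",
                     "n_classifier_genes", "n_gene_sets", "set_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_normal_validation < 0:
            raise ValueError("n_normal_validation must be >= 0")
        for freqs in (self.freq_discovery, self.freq_validation):
            if len(freqs) != len(self.subtype_names):
                raise ValueError("frequency vector length must match subtype_names")
            if abs(sum(freqs) - 1.0) > 1e-9:
                raise ValueError(f"subtype frequencies must sum to 1, got {sum(freqs)}")
        if self.n_classifier_genes > self.n_genes:
            raise ValueError("n_classifier_genes cannot exceed n_genes")
        for spec in self.marker_spec or ():
            if spec.subtype not in self.subtype_names:
                raise ValueError(f"marker references unknown subtype {spec.subtype!r}")
            if not 0 <= spec.mirna_index < self.n_mirnas:
                raise ValueError(f"marker references miRNA index {spec.mirna_index} out of range")
            if spec.direction not in ("up", "down"):
                raise ValueError(f"marker direction must be up/down, got {spec.direction!r}")


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside the synthetic study, for recovery scoring."""

    markers: pd.DataFrame          # mirna_id, subtype, direction, normal_like
    pathway_shifts: pd.DataFrame   # set_name, subtype, sign
    couplings: pd.DataFrame        # mirna_id, set_name (genuinely anticorrelated pairs)
    targets: pd.DataFrame          # mirna_id, gene_id, set_name
    sample_subtypes: pd.DataFrame  # sample_id, cohort, subtype

    @property
    def markers_for_recovery(self) -> pd.DataFrame:
        """Markers a normal-filtered pipeline is expected to recover."""
        return self.markers[~self.markers["normal_like"]].reset_index(drop=True)


@dataclass
class SimulatedStudy:
    mirna: dict[str, ExprMatrix]
    mrna: dict[str, ExprMatrix]
    annotation: CohortAnnotation
    centroids: CentroidModel
    gene_sets: GeneSetCollection
    target_ranks: TargetRankTable
    truth: PlantedTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# Default planted design
# ---------------------------------------------------------------------------


def default_marker_spec(cfg: SimConfig) -> tuple[MarkerSpec, ...]:
    """Spread ``n_markers`` over the subtypes, alternating directions.

    miRNA indices 0..n_markers-1 become markers; within each subtype roughly
    half are up, half down (first ones up, mirroring that most reported
    subtype markers are gains).
    """
    k = len(cfg.subtype_names)
    per = [cfg.n_markers // k + (1 if i < cfg.n_markers % k else 0) for i in range(k)]
    specs = []
    idx = 0
    for s, count in zip(cfg.subtype_names, per):
        n_up = math.ceil(count / 2)
        for j in range(count):
            direction = "up" if j < n_up else "down"
            specs.append(MarkerSpec(idx, s, direction, shift=cfg.marker_shift))
            idx += 1
    return tuple(specs)


def default_pathway_spec(cfg: SimConfig) -> tuple[PathwaySpec, ...]:
    """Plant one down-shifted set per subtype plus one up-shifted set in the
    last subtype, so both marker directions have an anticorrelated program."""
    names = [f"HALLMARK_SIM_{i + 1:02d}" for i in range(cfg.n_gene_sets)]
    specs = []
    for i, s in enumerate(cfg.subtype_names):
        specs.append(PathwaySpec(names[i], s, -cfg.pathway_shift))
    specs.append(PathwaySpec(names[len(cfg.subtype_names)], cfg.subtype_names[-1], cfg.pathway_shift))
    return tuple(specs)


def derive_couplings(
    markers: tuple[MarkerSpec, ...], pathways: tuple[PathwaySpec, ...]
) -> list[tuple[MarkerSpec, PathwaySpec]]:
    """Marker/pathway pairs that are anticorrelated by construction: same
    subtype, opposite sign (up marker with down-shifted set and vice versa)."""
    pairs = []
    for m in markers:
        for p in pathways:
            if p.subtype != m.subtype:
                continue
            if (m.direction == "up") == (p.shift < 0):
                pairs.append((m, p))
    return pairs


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def simulate_cohorts(cfg: SimConfig) -> SimulatedStudy:
    """Generate the full synthetic study (both cohorts plus ground truth)."""
    rng = np.random.default_rng(cfg.seed)
    mirna_ids = [f"miR-{i + 1:04d}" for i in range(cfg.n_mirnas)]
    gene_ids = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    subtypes = list(cfg.subtype_names)

    markers = cfg.marker_spec if cfg.marker_spec is not None else default_marker_spec(cfg)
    pathways = cfg.pathway_spec if cfg.pathway_spec is not None else default_pathway_spec(cfg)
    for m in markers:
        if not 0 <= m.mirna_index < cfg.n_mirnas:
            raise ValueError(
                f"marker miRNA index {m.mirna_index} out of range for n_mirnas={cfg.n_mirnas}"
            )

    # hallmark-style sets drawn from the non-classifier gene pool
    pool = np.arange(cfg.n_classifier_genes, cfg.n_genes)
    if cfg.set_size > pool.size:
        raise ValueError("set_size exceeds the non-classifier gene pool")
    set_names = [f"HALLMARK_SIM_{i + 1:02d}" for i in range(cfg.n_gene_sets)]
    set_members: dict[str, np.ndarray] = {
        name: rng.choice(pool, size=cfg.set_size, replace=False) for name in set_names
    }
    for p in pathways:
        if p.set_name not in set_members:
            raise ValueError(f"pathway spec references unknown set {p.set_name!r}")
    n_shifted = int(round(cfg.shifted_fraction * cfg.set_size))
    shifted_members = {p.set_name: set_members[p.set_name][:n_shifted] for p in pathways}

    # planted targets: cycle over couplings, consuming shifted member genes
    couplings = derive_couplings(markers, pathways)
    targets = cfg.target_spec
    if targets is None:
        targets = _derive_targets(cfg, couplings, shifted_members)
    target_set_name = _target_set_names(targets, set_members, gene_ids)

    # centroids over the classifier genes
    C = rng.normal(0.0, cfg.centroid_scale, size=(cfg.n_classifier_genes, len(subtypes)))
    centroid_df = pd.DataFrame(
        C - C.mean(axis=1, keepdims=True),
        index=gene_ids[: cfg.n_classifier_genes],
        columns=subtypes,
    )
    centroids = CentroidModel(centroid_df, center_genes=True)

    mirna_base = rng.normal(7.0, 1.0, size=cfg.n_mirnas)
    gene_base = rng.normal(9.0, 1.0, size=cfg.n_genes)

    # detection dropout model: a fraction of non-marker miRNAs is barely detected
    marker_idx = {m.mirna_index for m in markers}
    non_marker = np.array(
        [i for i in range(cfg.n_mirnas) if i not in marker_idx], dtype=int
    )
    n_low = min(int(round(cfg.low_detect_fraction * cfg.n_mirnas)), non_marker.size)
    low_idx = rng.choice(non_marker, size=n_low, replace=False) if n_low else np.array([], int)
    detect_prob = np.full(cfg.n_mirnas, cfg.detect_prob)
    detect_prob[low_idx] = cfg.low_detect_prob

    cohorts = {
        DISCOVERY: (cfg.n_discovery, 0, np.asarray(cfg.freq_discovery), "D"),
        VALIDATION: (cfg.n_validation, cfg.n_normal_validation, np.asarray(cfg.freq_validation), "V"),
    }
    mirna_mats: dict[str, ExprMatrix] = {}
    mrna_mats: dict[str, ExprMatrix] = {}
    ann_rows = []
    truth_rows = []
    for cohort, (n_tumor, n_normal, freqs, prefix) in cohorts.items():
        labels = rng.choice(len(subtypes), size=n_tumor, p=freqs)
        tumor_ids = [f"{prefix}{i + 1:04d}" for i in range(n_tumor)]
        normal_ids = [f"{prefix}N{i + 1:03d}" for i in range(n_normal)]
        sample_ids = tumor_ids + normal_ids
        n_all = len(sample_ids)

        # --- miRNA matrix ---
        M = mirna_base[:, None] + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_mirnas, n_all))
        for m in markers:
            s_idx = subtypes.index(m.subtype)
            cols = np.flatnonzero(labels == s_idx)
            sign = 1.0 if m.direction == "up" else -1.0
            M[m.mirna_index, cols] += sign * m.shift
            if n_normal and m.normal_shift:
                M[m.mirna_index, n_tumor:] += m.normal_shift

        # --- mRNA matrix ---
        G = gene_base[:, None] + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n_all))
        G[: cfg.n_classifier_genes, :n_tumor] += C[:, labels]
        for p in pathways:
            s_idx = subtypes.index(p.subtype)
            cols = np.flatnonzero(labels == s_idx)
            G[np.ix_(shifted_members[p.set_name], cols)] += p.shift
        for t in targets:
            G[t.gene_index] += t.slope * (M[t.mirna_index] - mirna_base[t.mirna_index])

        if cfg.sample_offset_sd > 0:
            M += rng.normal(0.0, cfg.sample_offset_sd, size=n_all)[None, :]
            G += rng.normal(0.0, cfg.sample_offset_sd, size=n_all)[None, :]

        detected = rng.random(size=(cfg.n_mirnas, n_all)) < detect_prob[:, None]

        mirna_mats[cohort] = ExprMatrix(
            pd.DataFrame(M, index=mirna_ids, columns=sample_ids),
            pd.DataFrame(detected, index=mirna_ids, columns=sample_ids),
        )
        mrna_mats[cohort] = ExprMatrix(pd.DataFrame(G, index=gene_ids, columns=sample_ids))

        for sid, lab in zip(tumor_ids, labels):
            ann_rows.append((sid, cohort, "tumor", cfg.histology_branch))
            truth_rows.append((sid, cohort, subtypes[lab]))
        for sid in normal_ids:
            ann_rows.append((sid, cohort, "normal", cfg.histology_branch))

    # cross-platform feature mismatch: drop a fraction of miRNAs from validation
    if cfg.feature_mismatch_fraction > 0:
        n_drop = int(round(cfg.feature_mismatch_fraction * cfg.n_mirnas))
        drop = rng.choice(cfg.n_mirnas, size=n_drop, replace=False)
        keep = [mirna_ids[i] for i in range(cfg.n_mirnas) if i not in set(drop)]
        mirna_mats[VALIDATION] = mirna_mats[VALIDATION].subset_features(keep)
        logger.info("feature mismatch dropped %d miRNAs from the validation cohort", n_drop)

    annotation = CohortAnnotation(
        pd.DataFrame(
            ann_rows, columns=["sample_id", "cohort", "tissue", "histology_branch"]
        ).set_index("sample_id")
    )
    gene_sets = GeneSetCollection(
        {name: [gene_ids[i] for i in idx] for name, idx in set_members.items()},
        {name: "synthetic hallmark-style program" for name in set_names},
    )
    target_ranks = _build_rank_table(
        cfg, rng, mirna_ids, gene_ids, markers, targets, couplings,
        set_members, shifted_members,
    )

    truth = PlantedTruth(
        markers=pd.DataFrame(
            [
                (mirna_ids[m.mirna_index], m.subtype, m.direction, bool(m.normal_shift))
                for m in markers
            ],
            columns=["mirna_id", "subtype", "direction", "normal_like"],
        ),
        pathway_shifts=pd.DataFrame(
            [(p.set_name, p.subtype, int(np.sign(p.shift))) for p in pathways],
            columns=["set_name", "subtype", "sign"],
        ),
        couplings=pd.DataFrame(
            [(mirna_ids[m.mirna_index], p.set_name) for m, p in couplings],
            columns=["mirna_id", "set_name"],
        ),
        targets=pd.DataFrame(
            [
                (mirna_ids[t.mirna_index], gene_ids[t.gene_index], target_set_name[t])
                for t in targets
            ],
            columns=["mirna_id", "gene_id", "set_name"],
        ),
        sample_subtypes=pd.DataFrame(truth_rows, columns=["sample_id", "cohort", "subtype"]),
    )
    return SimulatedStudy(
        mirna=mirna_mats,
        mrna=mrna_mats,
        annotation=annotation,
        centroids=centroids,
        gene_sets=gene_sets,
        target_ranks=target_ranks,
        truth=truth,
        config=cfg,
    )


def _derive_targets(cfg, couplings, shifted_members) -> tuple[TargetSpec, ...]:
    if not couplings:
        return ()
    used: set[int] = set()
    specs: list[TargetSpec] = []
    i = 0
    while len(specs) < cfg.n_targets:
        m, p = couplings[i % len(couplings)]
        i += 1
        gene = next((g for g in shifted_members[p.set_name] if g not in used), None)
        if gene is None:
            if i > cfg.n_targets * max(len(couplings), 1) * 4:
                break  # exhausted every coupled set
            continue
        used.add(int(gene))
        specs.append(TargetSpec(m.mirna_index, int(gene), slope=cfg.target_slope))
    return tuple(specs)


def _target_set_names(targets, set_members, gene_ids) -> dict[TargetSpec, str]:
    names = {}
    for t in targets:
        names[t] = ""
        for name, idx in set_members.items():
            if t.gene_index in set(int(i) for i in idx):
                names[t] = name
                break
    return names


def _build_rank_table(
    cfg, rng, mirna_ids, gene_ids, markers, targets, couplings, set_members, shifted_members
) -> TargetRankTable:
    """Planted pairs as very_high plus 10x decoys.

    Decoys exercise each gate separately: very_high pairs on unshifted set
    members (survive the class and set gates, fail the correlation gate),
    ``high`` pairs on genuinely anticorrelated shifted members (fail the
    class gate), and random medium/low pairs.
    """
    rows: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str]] = set()

    def add(mirna: str, gene: str, cls: str) -> bool:
        if (mirna, gene) in seen:
            return False
        seen.add((mirna, gene))
        rows.append((mirna, gene, cls))
        return True

    target_genes = {t.gene_index for t in targets}
    for t in targets:
        add(mirna_ids[t.mirna_index], gene_ids[t.gene_index], "very_high")

    n_decoys = 10 * max(len(targets), 1)
    budget = n_decoys
    for m, p in couplings:
        unshifted = [g for g in set_members[p.set_name] if g not in set(shifted_members[p.set_name])]
        for g in unshifted[:2]:
            if budget > 0 and add(mirna_ids[m.mirna_index], gene_ids[int(g)], "very_high"):
                budget -= 1
        for g in shifted_members[p.set_name]:
            if int(g) in target_genes:
                continue
            if budget > 0 and add(mirna_ids[m.mirna_index], gene_ids[int(g)], "high"):
                budget -= 1
                break
    while budget > 0:
        mi = int(rng.integers(0, len(mirna_ids)))
        gi = int(rng.integers(0, len(gene_ids)))
        cls = "medium" if rng.random() < 0.5 else "low"
        if add(mirna_ids[mi], gene_ids[gi], cls):
            budget -= 1
    return TargetRankTable(pd.DataFrame(rows, columns=["mirna_id", "gene_id", "confidence_class"]))


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------


@dataclass
class RecoveryScore:
    precision: float
    recall: float
    tp: int
    fp: int
    fn: int
    note: str = ""


_KEYS = {
    "markers": ("mirna_id", "subtype", "direction"),
    "targets": ("mirna_id", "gene_id"),
    "couplings": ("mirna_id", "set_name"),
}


def score_recovery(calls: pd.DataFrame, truth: pd.DataFrame, kind: str = "markers") -> RecoveryScore:
    """Precision/recall of a call table against planted truth.

    A marker call counts as a true positive only when miRNA, subtype and
    direction all match.  Empty calls give recall 0 and, by convention,
    precision 1 (with a note).
    """
    keys = _KEYS[kind]
    call_set = set(map(tuple, calls[list(keys)].itertuples(index=False))) if len(calls) else set()
    truth_set = set(map(tuple, truth[list(keys)].itertuples(index=False))) if len(truth) else set()
    tp = len(call_set & truth_set)
    fp = len(call_set - truth_set)
    fn = len(truth_set - call_set)
    note = ""
    if not call_set:
        note = "no calls made; precision reported as 1 by convention"
        logger.warning(note)
        precision = 1.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if truth_set else 1.0
    return RecoveryScore(precision=precision, recall=recall, tp=tp, fp=fp, fn=fn, note=note)


def null_config(cfg: SimConfig) -> SimConfig:
    """The same study conditions with no planted structure (for null runs)."""
    return replace(cfg, marker_spec=(), pathway_spec=(), target_spec=())
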