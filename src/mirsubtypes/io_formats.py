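"""Readers, writers and run configuration for every external artifact.

All tabular artifacts use one dialect: UTF-8 tab-separated text, first column
holds the row identifier, ``NA`` or an empty cell marks a missing value.  Gene
set collections use the Broad GMT dialect (name, description, then member
genes, one set per line).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

MISSING_TOKENS = {"", "NA", "NaN", "nan"}
CONFIDENCE_CLASSES = ("very_high", "high", "medium", "low")
UNASSIGNED = "UNASSIGNED"


class FormatError(ValueError):
    """Raised when an external file violates the expected dialect."""


def _first_duplicate(items: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class ExprMatrix:
    """Log-scale expression matrix, features x samples.

    ``values`` is a pandas DataFrame indexed by feature id with sample ids as
    columns; ``detected`` is an optional boolean DataFrame of identical shape
    flagging which measurements are above the platform detection floor.
    """

    values: pd.DataFrame
    detected: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        dup = _first_duplicate(self.values.index)
        if dup is not None:
            raise FormatError(f"duplicate feature id: {dup!r}")
        dup = _first_duplicate(self.values.columns)
        if dup is not None:
            raise FormatError(f"duplicate sample id: {dup!r}")
        if self.detected is not None:
            if self.detected.shape != self.values.shape:
                raise FormatError("detected flags must match matrix dimensions")
            self.detected = self.detected.set_axis(self.values.index, axis=0).set_axis(
                self.values.columns, axis=1
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_features(self, ids: Iterable[str]) -> "ExprMatrix":
        ids = list(ids)
        det = self.detected.loc[ids] if self.detected is not None else None
        return ExprMatrix(self.values.loc[ids], det)

    def subset_samples(self, ids: Iterable[str]) -> "ExprMatrix":
        ids = list(ids)
        det = self.detected[ids] if self.detected is not None else None
        return ExprMatrix(self.values[ids], det)

    def copy(self) -> "ExprMatrix":
        det = self.detected.copy() if self.detected is not None else None
        return ExprMatrix(self.values.copy(), det)


@dataclass
class CohortAnnotation:
    """Per-sample annotation: cohort label, tumor/normal tissue, histology branch."""

    table: pd.DataFrame  # index sample_id; columns cohort, tissue, histology_branch

    def __post_init__(self) -> None:
        dup = _first_duplicate(self.table.index)
        if dup is not None:
            raise FormatError(f"duplicate sample id in annotation: {dup!r}")
        bad = set(self.table["tissue"]) - {"tumor", "normal"}
        if bad:
            raise FormatError(f"unknown tissue values: {sorted(bad)}")
        for cohort, sub in self.table.groupby("cohort"):
            if not (sub["tissue"] == "tumor").any():
                raise FormatError(f"cohort {cohort!r} has no tumor samples")

    @property
    def cohorts(self) -> list[str]:
        return list(dict.fromkeys(self.table["cohort"]))

    def samples(self, cohort: str | None = None, tissue: str | None = None) -> list[str]:
        t = self.table
        if cohort is not None:
            t = t[t["cohort"] == cohort]
        if tissue is not None:
            t = t[t["tissue"] == tissue]
        return list(t.index)


@dataclass
class GeneSetCollection:
    """Named gene sets (hallmark-style); member lists are deduplicated."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> set[str]:
        return set(self.sets[name])


@dataclass
class CentroidModel:
    """Per-subtype centroid profiles over a fixed classifier gene list."""

    values: pd.DataFrame  # genes x subtypes
    center_genes: bool = True

    def __post_init__(self) -> None:
        dup = _first_duplicate(self.values.index)
        if dup is not None:
            raise FormatError(f"duplicate classifier gene: {dup!r}")
        if self.values.shape[1] < 2:
            raise FormatError("centroid model needs at least 2 subtypes")

    @property
    def classifier_genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def subtype_names(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class TargetRankTable:
    """Predicted miRNA->gene pairs with an integrated confidence class."""

    table: pd.DataFrame  # columns mirna_id, gene_id, confidence_class

    def __post_init__(self) -> None:
        t = self.table
        pairs = list(zip(t["mirna_id"], t["gene_id"]))
        dup = _first_duplicate(pairs)  # type: ignore[arg-type]
        if dup is not None:
            raise FormatError(f"duplicate target pair: {dup!r}")
        bad = set(t["confidence_class"]) - set(CONFIDENCE_CLASSES)
        if bad:
            raise FormatError(f"unknown confidence classes: {sorted(bad)}")

    def genes_for(self, mirna_id: str, confidence_class: str = "very_high") -> set[str]:
        t = self.table
        sel = (t["mirna_id"] == mirna_id) & (t["confidence_class"] == confidence_class)
        return set(t.loc[sel, "gene_id"])


@dataclass
class RunConfig:
    """Thresholds and switches for one pipeline run; defaults mirror the study design.

    ``detection_fraction`` maps histology branch to the minimum detection
    fraction a miRNA needs to survive filtering (strictly-below is removed).
    ``borderline_relax`` maps a subtype name to a relaxed discovery-cohort
    alpha used for small subtypes when the validation cohort passes at the
    ordinary threshold.  ``extra_gene_sets`` maps a subtype to set names that
    are force-considered in target analysis (when significantly anticorrelated).
    """

    kw_fdr: float = 0.05
    dunn_fdr: float = 0.05
    assoc_alpha: float = 0.05
    normal_fdr: float = 0.05
    detection_fraction: dict[str, float] = field(
        default_factory=lambda: {"AD-like": 0.10, "SCC-like": 0.20}
    )
    borderline_relax: dict[str, float] = field(default_factory=dict)
    extra_gene_sets: dict[str, list[str]] = field(default_factory=dict)
    es_convention: str = "max_diff"
    es_tau: float = 1.0
    min_set_size: int = 2
    center_genes: bool = True
    set_pick_rule: str = "minimax"  # or "mean"
    allow_skip_normal_filter: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("kw_fdr", "dunn_fdr", "assoc_alpha", "normal_fdr"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for branch, frac in self.detection_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"detection_fraction[{branch!r}] must be in [0, 1]")
        for sub, alpha in self.borderline_relax.items():
            if not 0.0 < alpha <= 1.0:
                raise ValueError(f"borderline_relax[{sub!r}] must be in (0, 1]")
        if self.es_convention not in ("max_diff", "max_abs"):
            raise ValueError("es_convention must be 'max_diff' or 'max_abs'")
        if self.set_pick_rule not in ("minimax", "mean"):
            raise ValueError("set_pick_rule must be 'minimax' or 'mean'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


def read_expr_matrix(
    path: str | Path,
    transpose: bool = False,
    detected_path: str | Path | None = None,
) -> ExprMatrix:
    """Read a features x samples TSV matrix.

    Duplicate identifiers and non-numeric cells are hard errors that name the
    offending identifier / coordinates.  ``transpose=True`` accepts files with
    samples in rows.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
    dup = _first_duplicate(header[1:])
    if dup is not None:
        raise FormatError(f"{path.name}: duplicate column id {dup!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    dup = _first_duplicate(df.index)
    if dup is not None:
        raise FormatError(f"{path.name}: duplicate row id {dup!r}")

    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        raw = df[col]
        missing = raw.isin(MISSING_TOKENS)
        conv = pd.to_numeric(raw.where(~missing), errors="coerce")
        bad = conv.isna() & ~missing
        if bad.any():
            row = bad.idxmax()
            raise FormatError(
                f"{path.name}: non-numeric cell {raw[row]!r} at row {row!r}, column {col!r}"
            )
        numeric[col] = conv
    if transpose:
        numeric = numeric.T
    detected = None
    if detected_path is not None:
        det = pd.read_csv(detected_path, sep="\t", index_col=0)
        detected = det.astype(bool)
        if transpose:
            detected = detected.T
    return ExprMatrix(numeric, detected)


def write_expr_matrix(
    m: ExprMatrix, path: str | Path, detected_path: str | Path | None = None
) -> None:
    """Write a matrix in the package dialect.  Values round-trip within 1e-12
    (pandas emits shortest round-trip float representations)."""
    m.values.to_csv(path, sep="\t", na_rep="NA", index_label="feature_id")
    if detected_path is not None and m.detected is not None:
        m.detected.astype(int).to_csv(path_or_buf=detected_path, sep="\t", index_label="feature_id")


def read_annotation(path: str | Path) -> CohortAnnotation:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return CohortAnnotation(df)


def write_annotation(ann: CohortAnnotation, path: str | Path) -> None:
    ann.table.to_csv(path, sep="\t", index_label="sample_id")


def read_centroids(path: str | Path, center_genes: bool = True) -> CentroidModel:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CentroidModel(df.astype(float), center_genes=center_genes)


def write_centroids(model: CentroidModel, path: str | Path) -> None:
    model.values.to_csv(path, sep="\t", index_label="gene_id")


def read_target_table(path: str | Path) -> TargetRankTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return TargetRankTable(df[["mirna_id", "gene_id", "confidence_class"]])


def write_target_table(table: TargetRankTable, path: str | Path) -> None:
    table.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a Broad-dialect GMT file: name TAB description TAB gene TAB gene..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path.name}:{lineno}: GMT line has <3 fields")
            name, desc, *genes = fields
            if name in sets:
                raise FormatError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            members = list(dict.fromkeys(g for g in genes if g))
            if not members:
                raise FormatError(f"{path.name}:{lineno}: set {name!r} has no genes")
            sets[name] = members
            descriptions[name] = desc
    if not sets:
        logger.warning("GMT file %s contains no gene sets", path)
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# Result bundles
# ---------------------------------------------------------------------------


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
    extra: Mapping[str, object] | None = None,
) -> dict:
    """Write one TSV per result table plus a JSON run manifest.

    Column order is the table's own order; rows are written as given, so a
    rerun with identical config and seed produces byte-identical files.
    Returns the manifest dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    for name in sorted(tables):
        fname = f"{name}.tsv"
        tables[name].to_csv(out_dir / fname, sep="\t", index=False, na_rep="NA")
        written[name] = fname
    manifest = {
        "config": config.to_dict() if config is not None else None,
        "seed": seed,
        "tables": written,
        "versions": {
            "mirsubtypes": _package_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
    }
    if extra:
        manifest["extra"] = dict(extra)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _package_version() -> str:
    from mirsubtypes import __version__

    return __version__
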