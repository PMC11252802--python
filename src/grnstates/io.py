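"""Shared data model and readers/writers for every external format the pipeline touches.

The containers are deliberately thin: a genes x cells matrix with id lists and a
layer tag, a long-format cell annotation table, a GMT-backed regulon collection
and a long-format TMA H-score table. Validation happens at construction so that
every downstream stage can assume consistent, deduplicated inputs.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

__all__ = [
    "FormatError",
    "ValidationError",
    "CATEGORIES",
    "HISTOLOGIES",
    "ExpressionMatrix",
    "CellAnnotation",
    "Regulon",
    "RegulonSet",
    "HScoreTable",
    "AnalysisConfig",
    "read_expression",
    "write_expression_mtx",
    "read_regulons",
    "write_regulons",
    "read_hscores",
    "lognormalize",
    "write_table",
    "get_logger",
]

logger = logging.getLogger("grnstates")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Parsed content violates a data-model invariant."""


#: closed set of disease categories used for cohort annotation
CATEGORIES = frozenset({"naive_CSPC", "CRPC_adeno", "NEPC"})
#: TMA histology strata
HISTOLOGIES = frozenset({"PRAD", "HGC", "NEPC"})
#: marker names treated as proliferation index (0-100 scale instead of 0-200)
KI67_ALIASES = frozenset({"Ki67", "KI67", "Ki-67", "ki67", "MKI67"})

_LAYERS = ("counts", "lognorm", "imputed")


def _check_unique(ids: Sequence[str], what: str) -> None:
    s = pd.Series(ids)
    dup = s[s.duplicated()].unique()
    if len(dup):
        raise ValidationError(f"duplicate {what}: {', '.join(map(str, dup[:10]))}")


@dataclass
class ExpressionMatrix:
    """Genes x cells expression values with a layer tag.

    ``layer`` is one of ``counts`` (non-negative integers), ``lognorm`` or
    ``imputed`` (non-negative reals).
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    layer: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.cell_ids, "cell ids")
        if self.layer not in _LAYERS:
            raise ValidationError(f"layer must be one of {_LAYERS}, got {self.layer!r}")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValidationError(f"{self.layer} layer must be finite and non-negative")
        if self.layer == "counts" and not np.allclose(self.values, np.round(self.values)):
            raise ValidationError("counts layer must contain integers")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([pos[g] for g in genes if g in pos], dtype=int)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    def subset_cells(self, cells: Sequence[str]) -> "ExpressionMatrix":
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        idx = np.array([pos[c] for c in cells], dtype=int)
        return replace(self, values=self.values[:, idx], cell_ids=list(cells))


@dataclass
class CellAnnotation:
    """Per-cell metadata: patient, disease category, site and free extra labels."""

    table: pd.DataFrame  # columns: cell_id, patient_id, category, site, ...

    def __post_init__(self) -> None:
        req = {"cell_id", "patient_id", "category"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValidationError(f"annotation missing columns: {sorted(missing)}")
        if "site" not in self.table.columns:
            self.table = self.table.assign(site="unknown")
        _check_unique(list(self.table["cell_id"]), "annotation cell ids")
        bad = set(self.table["category"]) - CATEGORIES
        if bad:
            raise ValidationError(f"unknown categories {sorted(bad)}; allowed {sorted(CATEGORIES)}")
        self.table = self.table.reset_index(drop=True)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.table["cell_id"])

    def patient_of(self) -> pd.Series:
        return self.table.set_index("cell_id")["patient_id"]

    def category_of(self) -> pd.Series:
        return self.table.set_index("cell_id")["category"]


@dataclass(frozen=True)
class Regulon:
    tf: str
    targets: frozenset[str]
    include_tf: bool = False

    @property
    def size(self) -> int:
        return len(self.targets) + (1 if self.include_tf else 0)

    @property
    def label(self) -> str:
        """Display label in the ``TF(n g)`` convention, e.g. ``ASCL1(34 g)``."""
        return f"{self.tf}({self.size} g)"

    def genes(self) -> frozenset[str]:
        return self.targets | {self.tf} if self.include_tf else self.targets


@dataclass
class RegulonSet:
    """Ordered transcription-factor -> target-gene-set mapping."""

    entries: list[Regulon]

    def __post_init__(self) -> None:
        _check_unique([r.tf for r in self.entries], "regulon TF names")
        for r in self.entries:
            if not r.targets:
                raise ValidationError(f"regulon {r.tf} has an empty target set")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, tf: str) -> Regulon:
        for r in self.entries:
            if r.tf == tf:
                return r
        raise KeyError(tf)

    @property
    def tf_names(self) -> list[str]:
        return [r.tf for r in self.entries]


@dataclass
class HScoreTable:
    """Long-format TMA immunohistochemistry scores (one row per core x marker).

    H-scores live on a 0-200 scale; Ki-67 proliferation index on 0-100. A core
    with no stain for a marker is an absent row, never a zero.
    """

    table: pd.DataFrame  # columns: core_id, patient_id, site, histology, marker, score

    def __post_init__(self) -> None:
        req = {"core_id", "marker", "score"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValidationError(f"H-score table missing columns: {sorted(missing)}")
        for col, default in (("patient_id", "unknown"), ("site", "unknown"), ("histology", "PRAD")):
            if col not in self.table.columns:
                self.table = self.table.assign(**{col: default})
        t = self.table.reset_index(drop=True)
        bad_hist = set(t["histology"].dropna()) - HISTOLOGIES
        if bad_hist:
            raise ValidationError(f"unknown histologies {sorted(bad_hist)}")
        scores = pd.to_numeric(t["score"], errors="coerce")
        if scores.isna().any():
            raise ValidationError(
                f"non-numeric score at rows {list(t.index[scores.isna()][:10])}"
            )
        out = (scores < 0) | (scores > 200)
        ki = t["marker"].isin(KI67_ALIASES)
        out |= ki & (scores > 100)
        if out.any():
            raise ValidationError(
                f"H-score out of range at rows {list(t.index[out][:10])} "
                "(0-200; Ki-67 0-100)"
            )
        dup = t.duplicated(subset=["core_id", "marker"])
        if dup.any():
            raise ValidationError(
                f"duplicate (core_id, marker) rows at {list(t.index[dup][:10])}"
            )
        t["score"] = scores
        self.table = t

    def wide(self) -> pd.DataFrame:
        """Core x marker matrix with NaN for missing stains."""
        return self.table.pivot(index="core_id", columns="marker", values="score")

    def pair(self, marker_x: str, marker_y: str) -> pd.DataFrame:
        """Complete-case (x, y) score pairs for two markers across cores."""
        w = self.wide()
        for m in (marker_x, marker_y):
            if m not in w.columns:
                raise KeyError(f"marker {m!r} not in table")
        return w[[marker_x, marker_y]].dropna()


@dataclass
class AnalysisConfig:
    """Tunable parameters of the pipeline, mirrored by the YAML config file."""

    seed: int = 0
    aucell_top_fraction: float = 0.05
    knn_k: int = 30
    magic_k: int = 20
    magic_t: int = 1
    subsample_n: int = 100
    subsample_reps: int = 100
    zclip: float = 2.0
    fc_threshold: float = 0.4
    fdr_threshold: float = 0.05
    scale_factor: float = 1e4
    n_pcs: int = 20

    def __post_init__(self) -> None:
        if not (0 < self.aucell_top_fraction <= 1):
            raise ValidationError("aucell_top_fraction must be in (0, 1]")
        for name in ("knn_k", "magic_k", "subsample_n", "subsample_reps",
                     "zclip", "fc_threshold", "fdr_threshold", "scale_factor", "n_pcs"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.magic_t < 0:
            raise ValidationError("magic_t must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: getattr(self, k) for k in self.__dataclass_fields__}, fh)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _open_maybe_gz(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _find(dirpath: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            p = dirpath / f"{stem}{suffix}"
            if p.exists():
                return p
    raise FormatError(f"none of {stems} found in {dirpath}")


def read_expression(path: str | Path, format: str = "mtx_triplet",
                    genes_in_rows: bool = True) -> ExpressionMatrix:
    """Read a counts matrix from a 10x-style MTX triplet directory or a dense CSV.

    The MTX triplet is ``matrix.mtx[.gz]`` plus ``features.tsv[.gz]`` (or
    ``genes.tsv``) and ``barcodes.tsv[.gz]``; 10x matrices are genes x cells.
    CSV input is genes-in-rows with a header of cell ids unless
    ``genes_in_rows=False``.
    """
    path = Path(path)
    if format == "mtx_triplet":
        mtx = _find(path, ["matrix.mtx"])
        feats = _find(path, ["features.tsv", "genes.tsv"])
        bcs = _find(path, ["barcodes.tsv"])
        mat = spio.mmread(str(mtx))
        mat = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=float)
        with _open_maybe_gz(feats) as fh:
            gene_ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
        with _open_maybe_gz(bcs) as fh:
            cell_ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
        if mat.shape != (len(gene_ids), len(cell_ids)):
            raise FormatError(
                f"matrix is {mat.shape} but features/barcodes give "
                f"{len(gene_ids)} x {len(cell_ids)}"
            )
    elif format == "csv":
        df = pd.read_csv(path, index_col=0)
        if not genes_in_rows:
            df = df.T
        mat = df.to_numpy(dtype=float)
        gene_ids = [str(i) for i in df.index]
        cell_ids = [str(c) for c in df.columns]
    else:
        raise FormatError(f"unknown expression format {format!r}")
    return ExpressionMatrix(mat, gene_ids, cell_ids, layer="counts")


def write_expression_mtx(em: ExpressionMatrix, outdir: str | Path) -> None:
    """Write an MTX triplet (matrix.mtx, features.tsv, barcodes.tsv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(outdir / "matrix.mtx"), sparse.coo_matrix(em.values))
    (outdir / "features.tsv").write_text("".join(f"{g}\n" for g in em.gene_ids))
    (outdir / "barcodes.tsv").write_text("".join(f"{c}\n" for c in em.cell_ids))


def read_regulons(path: str | Path) -> RegulonSet:
    """Parse a GMT file: one regulon per line, ``TF<TAB>description<TAB>gene...``."""
    entries: list[Regulon] = []
    with _open_maybe_gz(Path(path)) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            tf, _desc, *genes = parts
            genes = [g for g in genes if g]
            if not genes:
                raise ValidationError(f"{path}:{lineno}: regulon {tf!r} has no genes")
            entries.append(Regulon(tf=tf, targets=frozenset(genes)))
    return RegulonSet(entries)


def write_regulons(regulons: RegulonSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regulons:
            fh.write("\t".join([r.tf, "na", *sorted(r.targets)]) + "\n")


_HS_META = ["core_id", "patient_id", "site", "histology"]


def read_hscores(path: str | Path) -> HScoreTable:
    """Read a TMA H-score table from CSV or XLSX, long or wide format.

    Long format has a ``marker``/``score`` column pair; wide format has one
    column per marker, with empty cells meaning "no stain" (dropped, not 0).
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    df.columns = [str(c) for c in df.columns]
    if "marker" in df.columns and "score" in df.columns:
        return HScoreTable(df)
    meta = [c for c in _HS_META if c in df.columns]
    if "core_id" not in meta:
        raise FormatError("H-score table needs a core_id column")
    markers = [c for c in df.columns if c not in meta]
    long = df.melt(id_vars=meta, value_vars=markers, var_name="marker", value_name="score")
    long = long.dropna(subset=["score"])
    return HScoreTable(long.reset_index(drop=True))


def lognormalize(em: ExpressionMatrix, scale_factor: float = 1e4) -> ExpressionMatrix:
    """Depth-normalize each cell and apply log(1 + x).

    value = log(1 + scale_factor * count / cell_total), natural log. Cells with
    zero total counts are kept (all-zero profile) with a warning.
    """
    if em.layer != "counts":
        raise ValidationError(f"lognormalize expects a counts layer, got {em.layer!r}")
    totals = em.values.sum(axis=0)
    zero = totals == 0
    if zero.any():
        logger.warning("%d cells have zero total counts; kept as all-zero", int(zero.sum()))
    safe = np.where(zero, 1.0, totals)
    vals = np.log1p(scale_factor * em.values / safe[None, :])
    return ExpressionMatrix(vals, list(em.gene_ids), list(em.cell_ids), layer="lognorm")


def write_table(obj, path: str | Path, format: str = "csv") -> None:
    """Write any tabular result (DataFrame or object with .table/.to_dataframe)."""
    if isinstance(obj, pd.DataFrame):
        df = obj
    elif hasattr(obj, "table"):
        df = obj.table
    elif hasattr(obj, "to_dataframe"):
        df = obj.to_dataframe()
    else:
        raise TypeError(f"cannot tabulate object of type {type(obj).__name__}")
    sep = {"csv": ",", "tsv": "\t"}.get(format)
    if sep is None:
        raise FormatError(f"unknown table format {format!r}")
    df.to_csv(path, sep=sep, index=isinstance(df.index, pd.MultiIndex) or df.index.name is not None)


def get_logger(level: str = "INFO", seed: int | None = None) -> logging.Logger:
    """Configure the package logger (timestamped); echoes the seed at startup."""
    if not logger.handlers:
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
        logger.addHandler(h)
    logger.setLevel(level.upper())
    if seed is not None:
        logger.info("random seed = %d", seed)
    return logger
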