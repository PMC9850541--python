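"""Domain types, file readers/writers, configuration and logging.

The pipeline works on a gene x cell :class:`ExpressionMatrix` with an
optional raw-count layer and an optional log-scale normalized layer.
Gene sets are read from GMT (MSigDB dialect) or plain one-gene-per-line
lists; cell metadata from CSV.  All stage parameters live in
:class:`PipelineConfig`, validated at load time.
"""

from __future__ import annotations

import json
import logging
import re
import sys
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

__all__ = [
    "FormatError",
    "ValidationError",
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "PipelineConfig",
    "read_matrix",
    "write_matrix",
    "read_gene_sets",
    "write_gene_sets",
    "read_gene_list",
    "read_cell_meta",
    "get_logger",
    "log_stage",
]

CARDINAL_CLASSES = ("NPC", "ExN", "IN", "OPC", "Astrocyte", "Microglia")


class FormatError(ValueError):
    """Malformed input file (bad dimensions, unparseable line, ...)."""


class ValidationError(ValueError):
    """Structurally valid input that violates a domain invariant."""


def get_logger(name: str = "scvuln") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
        logger.propagate = False
    return logger


def log_stage(stage: str, **kv: object) -> None:
    """Emit one structured ``key=value`` log line for a pipeline stage."""
    parts = " ".join(f"{k}={v}" for k, v in kv.items())
    get_logger().info("stage=%s %s", stage, parts)


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene x cell expression values with optional ``counts``/``norm`` layers.

    ``counts`` holds raw (non-negative) counts; ``norm`` holds log-scale
    normalized values.  Both layers, when present, are dense float arrays of
    shape ``(n_genes, n_cells)`` sharing the same gene/cell ordering.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    counts: np.ndarray | None = None
    norm: np.ndarray | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids")
        if self.counts is None and self.norm is None:
            raise ValidationError("at least one layer (counts or norm) required")
        shape = (len(self.gene_ids), len(self.cell_ids))
        for name in ("counts", "norm"):
            layer = getattr(self, name)
            if layer is None:
                continue
            layer = np.asarray(layer, dtype=float)
            if layer.shape != shape:
                raise ValidationError(
                    f"{name} layer shape {layer.shape} != (genes, cells) {shape}"
                )
            if not np.all(np.isfinite(layer)):
                raise ValidationError(f"{name} layer contains non-finite values")
            if layer.min(initial=0.0) < 0:
                raise ValidationError(f"{name} layer contains negative values")
            setattr(self, name, layer)

    # -- basic accessors ----------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_genes, self.n_cells)

    def layer(self, name: str) -> np.ndarray:
        arr = getattr(self, name, None)
        if arr is None:
            raise ValidationError(f"layer {name!r} not present")
        return arr

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def gene_index_upper(self) -> dict[str, int]:
        """Case-insensitive gene lookup (first occurrence wins)."""
        out: dict[str, int] = {}
        for i, g in enumerate(self.gene_ids):
            out.setdefault(g.upper(), i)
        return out

    def cell_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.cell_ids)}

    # -- subsetting ---------------------------------------------------------

    def _take(self, gene_idx: np.ndarray | None, cell_idx: np.ndarray | None,
              note: str) -> "ExpressionMatrix":
        gi = np.arange(self.n_genes) if gene_idx is None else np.asarray(gene_idx)
        ci = np.arange(self.n_cells) if cell_idx is None else np.asarray(cell_idx)
        kw = {}
        for name in ("counts", "norm"):
            layer = getattr(self, name)
            if layer is not None:
                kw[name] = layer[np.ix_(gi, ci)]
        return ExpressionMatrix(
            gene_ids=[self.gene_ids[i] for i in gi],
            cell_ids=[self.cell_ids[i] for i in ci],
            provenance=self.provenance + [note],
            **kw,
        )

    def subset_genes(self, keep: Sequence[str] | np.ndarray, note: str = "subset_genes") -> "ExpressionMatrix":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            index = self.gene_index()
            idx = np.array([index[g] for g in keep], dtype=int)
        return self._take(idx, None, note)

    def subset_cells(self, keep: Sequence[str] | np.ndarray, note: str = "subset_cells") -> "ExpressionMatrix":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            index = self.cell_index()
            idx = np.array([index[c] for c in keep], dtype=int)
        return self._take(None, idx, note)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            cell_ids=list(self.cell_ids),
            counts=None if self.counts is None else self.counts.copy(),
            norm=None if self.norm is None else self.norm.copy(),
            provenance=list(self.provenance),
        )


# ---------------------------------------------------------------------------
# Matrix I/O
# ---------------------------------------------------------------------------


def _infer_format(path: Path) -> str:
    if path.suffix.lower() == ".mtx":
        return "mtx"
    return "tsv"


def _sidecar_paths(path: Path, genes_path, cells_path) -> tuple[Path, Path]:
    genes = Path(genes_path) if genes_path else path.parent / "genes.tsv"
    cells = Path(cells_path) if cells_path else path.parent / "barcodes.tsv"
    return genes, cells


def read_matrix(path, fmt: str | None = None, layer: str = "counts",
                genes_path=None, cells_path=None, transpose: bool = False) -> ExpressionMatrix:
    """Read a gene x cell matrix from MTX (+ id sidecars) or dense TSV.

    Orientation is gene x cell on disk; set ``transpose=True`` when the file
    is cell x gene.  The values populate the requested ``layer``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or _infer_format(path)
    if layer not in ("counts", "norm"):
        raise ValueError(f"unknown layer {layer!r}")
    if fmt == "mtx":
        genes_p, cells_p = _sidecar_paths(path, genes_path, cells_path)
        for p in (genes_p, cells_p):
            if not p.exists():
                raise FormatError(f"MTX sidecar file missing: {p}")
        values = scipy.io.mmread(str(path))
        if scipy.sparse.issparse(values):
            values = values.toarray()
        values = np.asarray(values, dtype=float)
        gene_ids = [ln.split("\t")[0] for ln in _read_lines(genes_p)]
        cell_ids = [ln.split("\t")[0] for ln in _read_lines(cells_p)]
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0,
                         float_precision="round_trip")
        values = df.to_numpy(dtype=float)
        gene_ids = [str(g) for g in df.index]
        cell_ids = [str(c) for c in df.columns]
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")
    if transpose:
        values = values.T
        gene_ids, cell_ids = cell_ids, gene_ids
    if values.shape != (len(gene_ids), len(cell_ids)):
        raise FormatError(
            f"matrix shape {values.shape} does not match id counts "
            f"({len(gene_ids)} genes, {len(cell_ids)} cells)"
        )
    kw = {layer: values}
    return ExpressionMatrix(gene_ids=gene_ids, cell_ids=cell_ids,
                            provenance=[f"read_matrix:{path.name}:{layer}"], **kw)


def _read_lines(path: Path) -> list[str]:
    return [ln for ln in path.read_text().splitlines() if ln.strip()]


def write_matrix(m: ExpressionMatrix, path, fmt: str | None = None,
                 layer: str = "counts", genes_path=None, cells_path=None) -> None:
    """Write one layer to MTX (+ sidecars) or dense TSV, value-preserving."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    values = m.layer(layer)
    if fmt == "mtx":
        genes_p, cells_p = _sidecar_paths(path, genes_path, cells_path)
        sparse = scipy.sparse.coo_matrix(values)
        # precision=17 so float64 values survive the text round trip
        scipy.io.mmwrite(str(path), sparse, field="real", precision=17)
        genes_p.write_text("".join(g + "\n" for g in m.gene_ids))
        cells_p.write_text("".join(c + "\n" for c in m.cell_ids))
    elif fmt == "tsv":
        df = pd.DataFrame(values, index=m.gene_ids, columns=m.cell_ids)
        # %.17g guarantees float64 values survive the text round trip
        df.to_csv(path, sep="\t", float_format="%.17g")
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str = ""
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene set {self.name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


class GeneSetCollection:
    """Ordered collection of named gene sets."""

    def __init__(self, sets: Iterable[GeneSet]):
        self.sets = list(sets)
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate gene-set names in collection")
        self._by_name = {s.name: s for s in self.sets}

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, key: str | int) -> GeneSet:
        if isinstance(key, int):
            return self.sets[key]
        return self._by_name[key]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


def read_gene_sets(path, uppercase: bool = True) -> GeneSetCollection:
    """Parse a GMT file: one set per line, TAB-separated name/description/genes."""
    path = Path(path)
    sets: list[GeneSet] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name, desc, raw_genes = parts[0], parts[1], parts[2:]
        genes: list[str] = []
        seen: set[str] = set()
        for g in raw_genes:
            g = g.strip()
            if not g:
                continue
            if uppercase:
                g = g.upper()
            if g in seen:
                get_logger().warning("gene set %s line %d: duplicate gene %s dropped",
                                     name, lineno, g)
                continue
            seen.add(g)
            genes.append(g)
        sets.append(GeneSet(name=name, description=desc, genes=tuple(genes)))
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    lines = ["\t".join([s.name, s.description, *s.genes]) for s in collection]
    Path(path).write_text("".join(ln + "\n" for ln in lines))


def read_gene_list(path, uppercase: bool = True) -> list[str]:
    """Plain one-gene-per-line list; order preserved, duplicates dropped."""
    out: list[str] = []
    seen: set[str] = set()
    for ln in _read_lines(Path(path)):
        g = ln.strip().upper() if uppercase else ln.strip()
        if g and g not in seen:
            seen.add(g)
            out.append(g)
    return out


# ---------------------------------------------------------------------------
# Cell metadata
# ---------------------------------------------------------------------------


def read_cell_meta(path, class_vocabulary: Sequence[str] | None = None,
                   stage_vocabulary: Sequence[str] | None = None,
                   matrix: ExpressionMatrix | None = None) -> pd.DataFrame:
    """Read per-cell metadata CSV with at least a ``cell_id`` column.

    Optional vocabularies constrain ``cardinal_class``/``stage`` values; a
    matrix, when given, is used to flag cells absent from it (``in_matrix``
    column).  An empty matrix/metadata intersection is a hard error.
    """
    df = pd.read_csv(path, dtype=str)
    if "cell_id" not in df.columns:
        raise FormatError("cell metadata CSV is missing the cell_id column")
    if df["cell_id"].duplicated().any():
        dups = df.loc[df["cell_id"].duplicated(), "cell_id"].tolist()
        raise ValidationError(f"duplicate cell ids in metadata: {dups[:5]}")
    if class_vocabulary is not None and "cardinal_class" in df.columns:
        bad = sorted(set(df["cardinal_class"].dropna()) - set(class_vocabulary))
        if bad:
            raise ValidationError(f"unknown cardinal_class values: {bad}")
    if stage_vocabulary is not None and "stage" in df.columns:
        bad = sorted(set(df["stage"].dropna()) - set(stage_vocabulary))
        if bad:
            raise ValidationError(f"unknown stage values: {bad}")
    if matrix is not None:
        in_matrix = df["cell_id"].isin(set(matrix.cell_ids))
        if not in_matrix.any():
            raise ValidationError("no metadata cell id matches the matrix")
        df = df.assign(in_matrix=in_matrix.to_numpy())
    return df


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """All stage parameters with their defaults; validated on construction."""

    # QC / normalization
    min_genes_per_cell: int = 1000
    min_cells_per_gene: int = 3
    min_norm_value: float = 1.0
    scale_factor: float = 10_000.0
    # HVG selection
    hvg_mean_min: float = 1.0
    hvg_mean_max: float = 8.0
    hvg_vmr_cut: float = 1.2
    hvg_vmr_side: str = "below"
    # PCA / jackstraw / embedding
    n_pcs: int = 20
    max_significant_pcs: int | None = None
    jackstraw_iterations: int = 100
    jackstraw_perm_fraction: float = 0.01
    jackstraw_alpha: float = 0.01
    perplexity: float = 20.0
    # graph clustering
    knn_k: int = 30
    resolution: float = 1.0
    class_resolutions: dict = field(
        default_factory=lambda: {"NPC": 1.0, "ExN": 0.1, "IN": 0.5})
    cluster_on: str = "embedding"  # or "pca"
    cluster_method: str = "louvain"  # or "leiden"
    top_n_hvg: int = 3000
    # differential expression
    de_min_frac: float = 0.33
    de_lfc_threshold: float = 0.33
    de_alpha: float = 0.05
    p_adjust_method: str = "bonferroni"
    # label transfer
    transfer_k: int = 30
    min_votes: int = 5
    n_cc: int = 4
    transfer_perplexity: float = 40.0
    # global
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        checks = [
            (self.min_genes_per_cell >= 0, "min_genes_per_cell must be >= 0"),
            (self.min_cells_per_gene >= 0, "min_cells_per_gene must be >= 0"),
            (self.min_norm_value >= 0, "min_norm_value must be >= 0"),
            (self.scale_factor > 0, "scale_factor must be > 0"),
            (self.hvg_mean_min <= self.hvg_mean_max, "hvg mean range inverted"),
            (self.hvg_vmr_cut >= 0, "hvg_vmr_cut must be >= 0"),
            (self.hvg_vmr_side in ("below", "above"), "hvg_vmr_side must be below/above"),
            (self.n_pcs >= 1, "n_pcs must be >= 1"),
            (self.jackstraw_iterations >= 1, "jackstraw_iterations must be >= 1"),
            (0 < self.jackstraw_perm_fraction <= 1, "jackstraw_perm_fraction in (0,1]"),
            (0 < self.jackstraw_alpha <= 1, "jackstraw_alpha in (0,1]"),
            (self.perplexity > 0, "perplexity must be > 0"),
            (self.knn_k >= 1, "knn_k must be >= 1"),
            (self.resolution > 0, "resolution must be > 0"),
            (all(r > 0 for r in self.class_resolutions.values()),
             "class resolutions must be > 0"),
            (self.cluster_on in ("embedding", "pca"), "cluster_on must be embedding/pca"),
            (self.cluster_method in ("louvain", "leiden"),
             "cluster_method must be louvain/leiden"),
            (self.top_n_hvg >= 1, "top_n_hvg must be >= 1"),
            (0 <= self.de_min_frac <= 1, "de_min_frac in [0,1]"),
            (0 < self.de_alpha <= 1, "de_alpha in (0,1]"),
            (self.p_adjust_method in ("bonferroni", "bh"),
             "p_adjust_method must be bonferroni/bh"),
            (self.transfer_k >= 1, "transfer_k must be >= 1"),
            (self.min_votes >= 1, "min_votes must be >= 1"),
            (self.n_cc >= 1, "n_cc must be >= 1"),
            (self.transfer_perplexity > 0, "transfer_perplexity must be > 0"),
            (int(self.seed) == self.seed, "seed must be an integer"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValidationError(f"invalid config: {msg}")

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValidationError(f"unknown config keys: {unknown}")
        return cls(**d)  # type: ignore[arg-type]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise FormatError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def replace(self, **kv) -> "PipelineConfig":
        return replace(self, **kv)
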