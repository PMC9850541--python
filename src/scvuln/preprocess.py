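"""Cell/gene QC filters, blacklist exclusion, normalization, HVG selection.

Filter semantics follow the strict/inclusive boundary conventions of the
upstream protocol: cells with *fewer than* ``min_genes`` expressed genes are
removed; a gene is kept iff at least ``min_cells`` cells reach
``min_value`` on the normalized scale; "between" bounds for HVG means are
inclusive and the VMR cut is strict.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, ValidationError, log_stage

__all__ = [
    "QCReport",
    "DEFAULT_BLACKLIST",
    "filter_cells",
    "filter_genes",
    "exclude_blacklist",
    "normalize",
    "hvg_stats",
    "select_hvg",
]

# default regexes per blacklist category; anchors include the hyphen so that
# e.g. MTOR survives ^MT-
DEFAULT_BLACKLIST: dict[str, list[str]] = {
    "pseudogene": [],
    "miRNA": [r"^MIR"],
    "rRNA": [r"^RNA5"],
    "mito": [r"^MT-"],
    "ribo": [r"^RPL", r"^RPS"],
}


@dataclass
class QCReport:
    step: str
    cells_in: int
    cells_out: int
    genes_in: int
    genes_out: int
    details: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "step": self.step,
            "cells_in": self.cells_in,
            "cells_out": self.cells_out,
            "genes_in": self.genes_in,
            "genes_out": self.genes_out,
            "details": self.details,
        }


def _expression_layer(m: ExpressionMatrix) -> np.ndarray:
    return m.counts if m.counts is not None else m.layer("norm")


def filter_cells(m: ExpressionMatrix, min_genes: int = 1000
                 ) -> tuple[ExpressionMatrix, QCReport]:
    """Remove cells with fewer than ``min_genes`` expressed (value > 0) genes."""
    x = _expression_layer(m)
    n_expressed = (x > 0).sum(axis=0)
    keep = n_expressed >= min_genes
    if not keep.any():
        raise ValidationError(
            f"filter_cells removed every cell (min_genes={min_genes})")
    out = m.subset_cells(keep, note=f"filter_cells:min_genes={min_genes}")
    report = QCReport("filter_cells", m.n_cells, out.n_cells, m.n_genes, out.n_genes,
                      {"min_genes": min_genes,
                       "removed": int((~keep).sum())})
    log_stage("filter_cells", cells_in=m.n_cells, cells_out=out.n_cells)
    return out, report


def filter_genes(m: ExpressionMatrix, min_cells: int = 3, min_value: float = 1.0
                 ) -> tuple[ExpressionMatrix, QCReport]:
    """Keep genes with normalized value >= min_value in >= min_cells cells."""
    x = m.layer("norm")
    n_cells_ok = (x >= min_value).sum(axis=1)
    keep = n_cells_ok >= min_cells
    out = m.subset_genes(keep,
                         note=f"filter_genes:min_cells={min_cells},min_value={min_value}")
    report = QCReport("filter_genes", m.n_cells, out.n_cells, m.n_genes, out.n_genes,
                      {"min_cells": min_cells, "min_value": min_value,
                       "removed": int((~keep).sum())})
    log_stage("filter_genes", genes_in=m.n_genes, genes_out=out.n_genes)
    return out, report


def exclude_blacklist(m: ExpressionMatrix,
                      patterns: dict[str, list[str]] | None = None,
                      explicit_ids: list[str] | None = None
                      ) -> tuple[ExpressionMatrix, QCReport]:
    """Drop genes matching per-category regexes or an explicit id list."""
    patterns = DEFAULT_BLACKLIST if patterns is None else patterns
    compiled: dict[str, list[re.Pattern]] = {}
    for category, regexes in patterns.items():
        try:
            compiled[category] = [re.compile(r) for r in regexes]
        except re.error as exc:
            raise ValidationError(
                f"bad blacklist regex in category {category!r}: {exc}") from exc
    explicit = {g.upper() for g in (explicit_ids or [])}

    hits: dict[str, int] = {c: 0 for c in compiled}
    hits["explicit"] = 0
    keep = np.ones(m.n_genes, dtype=bool)
    for i, gene in enumerate(m.gene_ids):
        for category, regexes in compiled.items():
            if any(r.match(gene) for r in regexes):
                keep[i] = False
                hits[category] += 1
        if gene.upper() in explicit:
            if keep[i]:
                hits["explicit"] += 1
            keep[i] = False
    out = m.subset_genes(keep, note="exclude_blacklist")
    report = QCReport("exclude_blacklist", m.n_cells, out.n_cells,
                      m.n_genes, out.n_genes, {"hits": hits})
    log_stage("exclude_blacklist", genes_in=m.n_genes, genes_out=out.n_genes)
    return out, report


def normalize(m: ExpressionMatrix, scale_factor: float = 10_000.0
              ) -> ExpressionMatrix:
    """Library-size normalization: norm = log1p(count / libsize * scale).

    Natural log; ``libsize`` is the per-cell count sum.  Cells with zero
    library size are a hard error (remove them with :func:`filter_cells`).
    """
    counts = m.layer("counts")
    libsize = counts.sum(axis=0)
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        names = [m.cell_ids[i] for i in zero[:5]]
        raise ValidationError(f"zero library size for cells {names}")
    norm = np.log1p(counts / libsize[None, :] * scale_factor)
    out = m.copy()
    out.norm = norm
    out.provenance.append(f"normalize:scale_factor={scale_factor}")
    return out


def hvg_stats(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene mean of log-scale values and linear-scale variance/mean ratio.

    The VMR is computed on ``expm1`` of the normalized layer with the mean
    taken over all cells; genes with linear mean 0 get NaN.
    """
    norm = m.layer("norm")
    mean_log = norm.mean(axis=1)
    linear = np.expm1(norm)
    lin_mean = linear.mean(axis=1)
    lin_var = linear.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        vmr = np.where(lin_mean > 0, lin_var / np.where(lin_mean > 0, lin_mean, 1.0),
                       np.nan)
    constant = np.ptp(norm, axis=1) == 0  # robust against fp residue in var
    return pd.DataFrame({
        "gene": m.gene_ids,
        "mean_log_expr": mean_log,
        "vmr": vmr,
        "variance": np.where(constant, 0.0, lin_var),
    }).set_index("gene")


def select_hvg(m: ExpressionMatrix, mean_min: float = 1.0, mean_max: float = 8.0,
               vmr_cut: float = 1.2, vmr_side: str = "below") -> pd.DataFrame:
    """Flag highly variable genes by mean-expression window and VMR cut.

    ``selected`` is True iff ``mean_min <= mean_log_expr <= mean_max`` and
    the VMR falls strictly on the configured side of ``vmr_cut``.  Zero
    variance genes are never selected.  Raises when nothing is selected.
    """
    if vmr_side not in ("below", "above"):
        raise ValidationError("vmr_side must be 'below' or 'above'")
    table = hvg_stats(m)
    in_window = (table["mean_log_expr"] >= mean_min) & (table["mean_log_expr"] <= mean_max)
    vmr = table["vmr"]
    on_side = vmr < vmr_cut if vmr_side == "below" else vmr > vmr_cut
    on_side = on_side.fillna(False)
    selected = in_window & on_side & (table["variance"] > 0)
    table = table.assign(selected=selected)
    table.attrs["params"] = {
        "mean_min": mean_min, "mean_max": mean_max,
        "vmr_cut": vmr_cut, "vmr_side": vmr_side,
    }
    if not selected.any():
        raise ValidationError(
            "no highly variable gene selected; review mean/VMR parameters "
            f"(mean range [{mean_min}, {mean_max}], vmr {vmr_side} {vmr_cut})")
    log_stage("select_hvg", n_selected=int(selected.sum()), n_genes=m.n_genes)
    return table
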