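"""Expression normalization for developmental RNA-seq.

Turns a raw gene x sample count matrix into the two expression objects the
downstream analyses consume:

* :class:`StageExpression` -- per-stage relative transcript abundances
  (fraction-of-transcripts, "tau"), obtained by normalizing each sample to
  relative abundance and collapsing replicates with the per-stage median.
  These are the ``e_i`` weights of every transcriptome index.
* :class:`StandardizedExpression` -- per-gene log2 profiles centered on the
  gene's own median, after discarding genes with too many zero stages and
  filling isolated zeros from neighboring stages.  Used for upregulated-gene
  selection, enrichment and stage-stage correlation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "StageExpression",
    "StandardizedExpression",
    "read_count_matrix",
    "normalize_fraction_of_transcripts",
    "collapse_replicates",
    "standardize_expression",
    "stage_correlation",
]


@dataclass
class CountMatrix:
    """Raw counts plus the sample -> (stage, replicate) design.

    Parameters
    ----------
    counts
        Gene x sample DataFrame of non-negative integers.
    design
        DataFrame indexed by sample id with columns ``stage`` and
        ``replicate``.  Stage order is taken from ``stage_order`` if given,
        otherwise from first appearance in the design.
    gene_lengths
        Optional per-gene lengths in bp (for length-normalized fractions).
    """

    counts: pd.DataFrame
    design: pd.DataFrame
    gene_lengths: pd.Series | None = None
    stage_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [s for s in self.counts.columns if s not in self.design.index]
        if missing:
            raise ValueError(f"samples absent from design: {missing}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.isfinite(self.counts.to_numpy(dtype=float)).all():
            raise ValueError("counts must be finite")
        if not self.stage_order:
            seen: dict[str, None] = {}
            for s in self.counts.columns:
                seen.setdefault(str(self.design.loc[s, "stage"]), None)
            self.stage_order = list(seen)
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
            if self.gene_lengths.isna().any() or (self.gene_lengths <= 0).any():
                raise ValueError("gene_lengths must be positive and cover all genes")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]


@dataclass
class StageExpression:
    """Gene x stage non-negative normalized expression (tau fractions)."""

    values: pd.DataFrame
    stage_order: list[str]

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("stage expression must be non-negative")
        self.values = self.values[self.stage_order]


@dataclass
class StandardizedExpression:
    """Gene x stage log2 profiles; 0 marks the gene's own median.

    ``audit`` counts genes by what happened during standardization:
    ``discarded`` (more than two zero stages), ``interpolated`` (at least one
    interior zero filled from the adjacent-stage mean), ``edge_filled``
    (boundary zeros only, copied from the single neighbor) and ``retained``.
    """

    values: pd.DataFrame
    stage_order: list[str]
    audit: dict[str, int]


def read_count_matrix(
    counts_path: str | Path,
    design_path: str | Path,
    lengths_path: str | Path | None = None,
) -> CountMatrix:
    """Load counts TSV (genes x samples), design TSV (sample, stage, replicate)
    and optionally a gene-length TSV (gene, length)."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t", index_col=0)
    lengths = None
    if lengths_path is not None:
        lt = pd.read_csv(lengths_path, sep="\t", index_col=0)
        lengths = lt.iloc[:, 0]
    return CountMatrix(counts=counts, design=design, gene_lengths=lengths)


def normalize_fraction_of_transcripts(
    cm: CountMatrix, use_lengths: bool = True
) -> pd.DataFrame:
    """Per-sample fraction of transcripts.

    With ``use_lengths`` the count of each gene is first divided by its length
    (so the fraction estimates relative transcript molarity, TPM on a 0-1
    scale); without, plain count fractions are used.  Every sample column of
    the result sums to 1.
    """
    counts = cm.counts.astype(float)
    zero_samples = counts.columns[counts.sum(axis=0) == 0].tolist()
    if zero_samples:
        raise ValueError(f"samples with all-zero counts: {zero_samples}")
    if use_lengths:
        if cm.gene_lengths is None:
            raise ValueError("use_lengths requested but CountMatrix has no gene_lengths")
        rates = counts.div(cm.gene_lengths, axis=0)
    else:
        rates = counts
    return rates.div(rates.sum(axis=0), axis=1)


def collapse_replicates(fractions: pd.DataFrame, cm: CountMatrix) -> StageExpression:
    """Collapse replicate samples to one column per stage via the median.

    The per-gene median of per-sample fractions does not itself sum to one
    over genes, so each stage column is renormalized to unit sum afterwards;
    all downstream indices are invariant to this per-stage rescaling.
    """
    missing = [s for s in fractions.columns if s not in cm.design.index]
    if missing:
        raise ValueError(f"design is missing samples: {missing}")
    stage_of = cm.design["stage"].astype(str)
    cols = {}
    for stage in cm.stage_order:
        samples = [s for s in fractions.columns if stage_of[s] == stage]
        if not samples:
            raise ValueError(f"stage {stage!r} has no replicate samples")
        cols[stage] = fractions[samples].median(axis=1)
    values = pd.DataFrame(cols)
    values = values.div(values.sum(axis=0), axis=1)
    return StageExpression(values=values, stage_order=list(cm.stage_order))


def _fill_zeros_inplace(row: np.ndarray) -> tuple[bool, bool]:
    """Fill zero entries from neighbors, left to right.

    Interior zeros take the mean of the two adjacent stage values; a zero in
    the first or last stage copies the single neighboring value.  Two adjacent
    zeros are resolved iteratively left to right, so the left one is filled
    first and then feeds the right one.  Returns flags (any interior fill,
    any edge fill).
    """
    interior = edge = False
    n = row.size
    while True:
        zeros = np.flatnonzero(row == 0)
        if zeros.size == 0:
            return interior, edge
        progressed = False
        for j in zeros:
            if j == 0:
                if row[1] > 0:
                    row[0] = row[1]
                    edge = progressed = True
            elif j == n - 1:
                if row[-2] > 0:
                    row[-1] = row[-2]
                    edge = progressed = True
            else:
                fill = 0.5 * (row[j - 1] + row[j + 1])
                if fill > 0:
                    row[j] = fill
                    interior = progressed = True
        if not progressed:
            return interior, edge


def standardize_expression(stage_expr: StageExpression) -> StandardizedExpression:
    """Median-centered log2 profiles with the zero-handling audit.

    Genes with more than two zero stages are discarded.  Remaining zeros are
    filled (interior: adjacent-stage mean; boundary: neighbor copy), each gene
    is divided by its own median, and log2 is taken.  A retained gene is
    counted once in the audit: under ``interpolated`` if any interior zero was
    filled, else under ``edge_filled`` if a boundary zero was, and always
    under ``retained``.
    """
    values = stage_expr.values
    if values.shape[1] < 3:
        raise ValueError("standardization requires at least 3 stages")
    mat = values.to_numpy(dtype=float).copy()
    n_zero = (mat == 0).sum(axis=1)
    keep = n_zero <= 2
    audit = {
        "discarded": int((~keep).sum()),
        "interpolated": 0,
        "edge_filled": 0,
        "retained": int(keep.sum()),
    }
    mat = mat[keep]
    genes = values.index[keep]
    for i in range(mat.shape[0]):
        if (mat[i] == 0).any():
            interior, edge = _fill_zeros_inplace(mat[i])
            if interior:
                audit["interpolated"] += 1
            elif edge:
                audit["edge_filled"] += 1
    bad = np.flatnonzero((mat == 0).any(axis=1))
    if bad.size:
        raise ValueError(
            "degenerate profiles still zero after filling: "
            f"{list(genes[bad[:10]])}"
        )
    logmat = np.log2(mat)
    # centering on the log scale keeps the row median exactly 0 even when the
    # stage count is even (the two definitions differ only then)
    std = logmat - np.median(logmat, axis=1)[:, None]
    out = pd.DataFrame(std, index=genes, columns=values.columns)
    return StandardizedExpression(
        values=out, stage_order=list(stage_expr.stage_order), audit=audit
    )


def stage_correlation(std: StandardizedExpression) -> pd.DataFrame:
    """All-against-all Pearson correlation between stages over genes.

    Stages with zero variance produce undefined (NaN) entries and are
    reported via a warning rather than silently set to 0.
    """
    values = std.values
    if values.shape[0] < 2:
        raise ValueError("stage correlation requires at least 2 genes")
    sd = values.std(axis=0, ddof=1)
    flat = sd.index[sd == 0].tolist()
    if flat:
        warnings.warn(
            f"stages with zero variance, correlations undefined: {flat}",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        return values.corr(method="pearson")


def write_stage_expression(expr: StageExpression, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")


def write_standardized(std: StandardizedExpression, path: str | Path) -> None:
    """Write the standardized matrix as TSV with a JSON audit sidecar."""
    path = Path(path)
    std.values.to_csv(path, sep="\t", index_label="gene")
    path.with_suffix(path.suffix + ".audit.json").write_text(
        json.dumps(std.audit, indent=2) + "\n"
    )
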