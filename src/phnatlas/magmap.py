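"""Coverage-based quantification of a gene in genome/MAG populations.

Mean per-base read depth over each annotated gene is computed from mapped
read intervals, and the focal gene's coverage is normalized by the mean
coverage of the 40 single-copy marker genes of the same genome. The
resulting percent is the fraction of the population's cells carrying the
gene; values above 100% read as copies per cell (628% ~ 6 copies/cell).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from phnatlas.io import IntervalSet, ValidationError

__all__ = ["CoverageTable", "gene_coverage", "mag_percent"]


@dataclass
class CoverageTable:
    """Per-gene mean per-base depth. ``table`` columns: gene_id, mean_coverage."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        cov = self.table["mean_coverage"].to_numpy(float)
        if not np.isfinite(cov).all() or (cov < 0).any():
            raise ValidationError("mean_coverage must be finite and >= 0")

    def as_series(self) -> pd.Series:
        return self.table.set_index("gene_id")["mean_coverage"]


def gene_coverage(reads: IntervalSet, genes: IntervalSet) -> CoverageTable:
    """Mean per-base depth of each gene: summed read overlap / gene length.

    Intervals are 0-based half-open on a shared contig namespace; a read
    spanning a gene boundary contributes only its overlapping bases, and
    each input interval is counted once (multi-mapping is the caller's
    concern). Unstranded.
    """
    if not genes.has_ids:
        raise ValidationError("gene interval set lacks gene_id")
    gt = genes.table
    if (gt["end"] - gt["start"] <= 0).any():
        raise ValidationError("zero-length gene")

    reads_by_contig = {
        contig: (grp["start"].to_numpy(np.int64), grp["end"].to_numpy(np.int64))
        for contig, grp in reads.table.groupby("contig")
    }
    records = []
    for row in gt.itertuples(index=False):
        length = row.end - row.start
        starts_ends = reads_by_contig.get(row.contig)
        if starts_ends is None:
            overlap = 0
        else:
            starts, ends = starts_ends
            overlap = int(
                np.clip(
                    np.minimum(ends, row.end) - np.maximum(starts, row.start), 0, None
                ).sum()
            )
        records.append({"gene_id": row.gene_id, "mean_coverage": overlap / length})
    return CoverageTable(pd.DataFrame(records, columns=["gene_id", "mean_coverage"]))


def mag_percent(
    cov: CoverageTable | Mapping[str, float],
    focal_gene_id: str,
    scg_gene_ids: Sequence[str],
) -> float:
    """Percent of the population carrying the focal gene.

    100 * coverage(focal) / mean coverage of the single-copy marker genes;
    NaN when the marker mean is zero. percent / 100 is copies per cell.
    """
    series = cov.as_series() if isinstance(cov, CoverageTable) else pd.Series(cov)
    missing = [g for g in [focal_gene_id, *scg_gene_ids] if g not in series.index]
    if missing:
        raise ValidationError(f"coverage missing for genes: {missing[:5]}")
    scg_mean = float(series.loc[list(scg_gene_ids)].mean())
    if scg_mean == 0:
        return float("nan")
    return 100.0 * float(series.loc[focal_gene_id]) / scg_mean
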