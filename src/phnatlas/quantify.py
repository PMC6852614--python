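"""Marker-gene-normalized gene prevalence: the "percent of organisms" estimand.

Gene-length-normalized abundances of all catalogue genes assigned to a
function are summed per sample and divided by the summed abundance of the
single-copy marker recA, then scaled to percent. Because every genome
carries exactly one recA, the ratio estimates the mean number of copies
of the function per organism; values above 100% therefore indicate
multiple gene copies per genome rather than an error. Samples are
stratified into the epipelagic zone (5 m surface plus the 17-183 m deep
chlorophyll maximum layer) and the mesopelagic zone (200-1000 m).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from phnatlas.io import (
    DEFAULT_MARKER_FUNCTION,
    AbundanceProfile,
    GeneCatalog,
    SampleTable,
    ValidationError,
)

__all__ = [
    "FunctionAbundanceTable",
    "length_normalize",
    "percent_organisms",
    "assign_depth_zone",
    "add_depth_zones",
]


@dataclass
class FunctionAbundanceTable:
    """Per-sample prevalence of one function.

    ``table`` columns: sample_id, function_id, percent_organisms (NaN when
    the marker is absent from the sample), n_genes_summed, marker_abundance.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        vals = t["percent_organisms"].to_numpy(float)
        ok = np.isnan(vals) | (vals >= 0)
        if not ok.all():
            raise ValidationError("negative percent_organisms")


def length_normalize(counts, lengths):
    """Reads-per-base abundance: counts / gene length.

    Zeros are preserved; a zero length is invalid.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if (counts < 0).any():
        raise ValidationError("negative counts")
    if (lengths < 1).any():
        raise ValidationError("gene lengths must be >= 1")
    return counts / lengths


def percent_organisms(
    profile: AbundanceProfile,
    catalog: GeneCatalog,
    function_id: str,
    marker_id: str = DEFAULT_MARKER_FUNCTION,
) -> FunctionAbundanceTable:
    """Percent of organisms possessing ``function_id``, per sample.

    percent = 100 * sum of function-gene abundances / sum of marker-gene
    abundances. Genes sharing the function are summed (multiple catalogue
    entries for one function are distinct sequence variants of the same
    gene). Samples whose marker abundance is zero get a missing value --
    a zero denominator is a data failure, not a zero prevalence.
    """
    func_genes = [g for g in catalog.genes_for_function(function_id) if g in profile.genes]
    marker_genes = [g for g in catalog.genes_for_function(marker_id) if g in profile.genes]
    if not marker_genes:
        raise ValidationError(f"no catalogue gene maps to marker {marker_id!r}")

    func_sum = (
        profile.values.loc[func_genes].sum(axis=0)
        if func_genes
        else pd.Series(0.0, index=profile.samples)
    )
    marker_sum = profile.values.loc[marker_genes].sum(axis=0)

    percent = pd.Series(np.nan, index=profile.samples, dtype=float)
    nonzero = marker_sum > 0
    percent[nonzero] = 100.0 * func_sum[nonzero] / marker_sum[nonzero]
    n_zero = int((~nonzero).sum())
    if n_zero:
        warnings.warn(
            f"{function_id}: marker abundance zero in {n_zero} samples; "
            "prevalence reported missing there",
            stacklevel=2,
        )

    return FunctionAbundanceTable(
        pd.DataFrame(
            {
                "sample_id": profile.samples,
                "function_id": function_id,
                "percent_organisms": percent.to_numpy(),
                "n_genes_summed": len(func_genes),
                "marker_abundance": marker_sum.to_numpy(),
            }
        )
    )


def assign_depth_zone(depth: float) -> str:
    """EPZ (5 m surface or 17-183 m DCM), MPZ (200-1000 m), else OTHER.

    Only the sampled depth horizons define the zones; depths in the gaps
    (e.g. 6-16 m, 184-199 m, > 1000 m) are OTHER -- no interpolation.
    """
    if not np.isfinite(depth) or depth < 0:
        raise ValidationError(f"invalid depth {depth}")
    if depth == 5.0 or 17.0 <= depth <= 183.0:
        return "EPZ"
    if 200.0 <= depth <= 1000.0:
        return "MPZ"
    return "OTHER"


def add_depth_zones(samples: SampleTable) -> pd.DataFrame:
    """Sample table with a ``depth_zone`` column appended."""
    t = samples.table.copy()
    t["depth_zone"] = [assign_depth_zone(d) for d in t["depth"]]
    return t
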