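"""Phylogeny-driven taxon binning and taxon-specific enrichment.

Query sequences (catalogue genes placed on a reference protein tree) are
classified conservatively: each query leaf receives the taxon of the
reference leaf at minimum patristic distance; when several references tie,
the assignment is truncated to the longest shared prefix of their
semicolon-delimited rank paths (whole ranks, never substrings). Patristic
distance is a path-length sum, so classifications are independent of where
the tree is rooted.

Upstream of tree inference the alignment is prepared by removing columns
with more than 10% gaps (strictly greater: boundary columns are kept) and
then collapsing exact duplicate rows, keeping the first-seen name.

Downstream, per-taxon gene abundance is expressed two ways: as the
fraction of the focal function's total abundance contributed by the taxon,
and as a percent of the taxon's organisms (summed focal abundance over the
mean of the 40 taxon-matched single-copy marker-gene abundances; values
above 100% indicate multiple copies per genome).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from phnatlas.io import (
    AbundanceProfile,
    AlignmentBlock,
    GeneCatalog,
    ValidationError,
)

__all__ = [
    "TaxonBinTable",
    "trim_and_dedup",
    "classify_queries",
    "taxon_contribution",
    "taxon_enrichment",
    "common_rank_prefix",
]

UNCLASSIFIED = "unclassified"

# relative tolerance for calling two patristic distances tied; float
# path sums over different routes can differ in the last few ulps
_TIE_RTOL = 1e-9


@dataclass
class TaxonBinTable:
    """Per-query taxon assignment with its supporting distance.

    ``table`` columns: gene_id, taxon, support (patristic distance to the
    nearest reference), tie_flag (assignment was rank-truncated over tied
    references).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t["gene_id"].duplicated().any():
            raise ValidationError("duplicate gene_id in bin table")
        if (t["support"] < 0).any():
            raise ValidationError("negative support distance")

    def as_mapping(self) -> dict[str, str]:
        return dict(zip(self.table["gene_id"], self.table["taxon"]))


def trim_and_dedup(
    aln: AlignmentBlock, max_gap_fraction: float = 0.10
) -> AlignmentBlock:
    """Remove columns with a gap fraction strictly above ``max_gap_fraction``,
    then collapse rows that are identical after trimming (first name kept).

    Idempotent: a second application changes nothing.
    """
    if aln.n_sequences == 0:
        raise ValidationError("empty alignment")
    mat = np.array([list(r) for r in aln.rows])
    gap_fraction = (mat == "-").mean(axis=0)
    keep = gap_fraction <= max_gap_fraction
    if not keep.any():
        raise ValidationError("alignment fully gapped: no columns survive trimming")
    trimmed = mat[:, keep]

    seen: dict[str, str] = {}
    names, rows = [], []
    for name, row in zip(aln.names, ("".join(r) for r in trimmed)):
        if row in seen:
            continue
        seen[row] = name
        names.append(name)
        rows.append(row)
    return AlignmentBlock(names, rows)


def common_rank_prefix(taxonomies: Sequence[str]) -> str:
    """Longest shared prefix of semicolon-delimited rank paths.

    Operates on whole ranks: 'Alpha;SAR11' and 'Alpha;SAR116' share
    'Alpha', never 'Alpha;SAR11'. An empty shared prefix yields the
    unclassified label.
    """
    split = [t.split(";") for t in taxonomies]
    prefix: list[str] = []
    for ranks in zip(*split):
        if len(set(ranks)) == 1:
            prefix.append(ranks[0])
        else:
            break
    return ";".join(prefix) if prefix else UNCLASSIFIED


def classify_queries(
    tree: dendropy.Tree, ref_taxonomy: Mapping[str, str]
) -> TaxonBinTable:
    """Assign each query leaf the taxon of its patristically nearest
    reference leaf; distance ties fall back to the tied references'
    common rank prefix.

    Leaves named in ``ref_taxonomy`` are references; all other leaves are
    queries. Root placement does not affect the result.
    """
    leaves = list(tree.leaf_node_iter())
    ref_leaves = [lf for lf in leaves if lf.taxon.label in ref_taxonomy]
    query_leaves = [lf for lf in leaves if lf.taxon.label not in ref_taxonomy]
    if not ref_leaves:
        raise ValidationError("no reference leaves on tree")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValidationError("negative branch length")

    pdm = tree.phylogenetic_distance_matrix()
    ref_taxa_labels = [lf.taxon.label for lf in ref_leaves]
    records = []
    for q in query_leaves:
        dists = np.array(
            [pdm.patristic_distance(q.taxon, r.taxon) for r in ref_leaves]
        )
        dmin = dists.min()
        tied = np.flatnonzero(dists <= dmin + _TIE_RTOL * max(dmin, 1e-300))
        if dmin == 0 and len(tied) == len(ref_leaves) and len(ref_leaves) > 1:
            raise ValidationError(
                f"query {q.taxon.label!r}: degenerate zero-length tree"
            )
        if len(tied) == 1:
            taxon = ref_taxonomy[ref_taxa_labels[tied[0]]]
            tie = False
        else:
            taxon = common_rank_prefix(
                [ref_taxonomy[ref_taxa_labels[i]] for i in tied]
            )
            tie = True
        records.append(
            {
                "gene_id": q.taxon.label,
                "taxon": taxon,
                "support": float(dmin),
                "tie_flag": tie,
            }
        )
    return TaxonBinTable(
        pd.DataFrame(records, columns=["gene_id", "taxon", "support", "tie_flag"])
    )


def taxon_contribution(
    profile: AbundanceProfile,
    bins: TaxonBinTable | Mapping[str, str],
    catalog: GeneCatalog,
    function_id: str = "COG3627",
) -> pd.DataFrame:
    """Fraction of the focal function's abundance contributed by each taxon.

    contribution(taxon, sample) = sum of the taxon's focal-gene abundances
    over the total focal abundance; focal genes without a bin pool into
    'unclassified'. Contributions sum to 1 per sample; samples with zero
    total focal abundance are missing.
    """
    bin_map = bins.as_mapping() if isinstance(bins, TaxonBinTable) else dict(bins)
    focal_genes = [g for g in catalog.genes_for_function(function_id) if g in profile.genes]
    if not focal_genes:
        raise ValidationError(f"no profile genes for function {function_id!r}")
    taxa = pd.Series(
        [bin_map.get(g, UNCLASSIFIED) for g in focal_genes], index=focal_genes
    )
    sub = profile.values.loc[focal_genes]
    by_taxon = sub.groupby(taxa).sum()  # taxa x samples
    total = sub.sum(axis=0)
    contribution = by_taxon.divide(total.where(total > 0), axis=1)
    out = (
        contribution.stack(future_stack=True)
        .rename("contribution")
        .reset_index()
        .rename(columns={"level_0": "taxon", "level_1": "sample_id"})
    )
    out.columns = ["taxon", "sample_id", "contribution"]
    return out[["sample_id", "taxon", "contribution"]].sort_values(
        ["sample_id", "taxon"], ignore_index=True
    )


def taxon_enrichment(
    profile: AbundanceProfile,
    bins: TaxonBinTable | Mapping[str, str],
    catalog: GeneCatalog,
    scg_ids: Sequence[str],
    function_id: str = "COG3627",
) -> pd.DataFrame:
    """Percent of a taxon's organisms possessing the focal function.

    Denominator: for each of the single-copy marker functions, the
    taxon-matched gene abundances are summed; the mean over the marker
    functions estimates the taxon's organism abundance. percent_in_taxon
    may exceed 100 (multiple copies per genome, or reference misbinning).
    Taxa whose marker mean is zero are missing for that sample.
    """
    catalog.require_scg_bins()
    bin_map = bins.as_mapping() if isinstance(bins, TaxonBinTable) else dict(bins)
    focal_genes = [g for g in catalog.genes_for_function(function_id) if g in profile.genes]
    if not focal_genes:
        raise ValidationError(f"no profile genes for function {function_id!r}")
    focal_taxa = pd.Series(
        [bin_map.get(g, UNCLASSIFIED) for g in focal_genes], index=focal_genes
    )
    focal_by_taxon = profile.values.loc[focal_genes].groupby(focal_taxa).sum()

    cat = catalog.table
    scg = cat[cat["function_id"].isin(scg_ids) & cat["gene_id"].isin(profile.genes)]
    if scg.empty:
        raise ValidationError("no single-copy marker genes in profile")
    scg_values = profile.values.loc[scg["gene_id"]]
    # per (taxon, function) summed abundance, then mean over functions
    taxon_key = pd.Series(scg["taxon_bin"].to_numpy(), index=scg_values.index, name="taxon")
    func_key = pd.Series(scg["function_id"].to_numpy(), index=scg_values.index, name="function_id")
    per_function = scg_values.groupby([taxon_key, func_key]).sum()
    # absent (taxon, function) combinations count as 0 in the mean: the
    # denominator is the mean over all len(scg_ids) marker functions
    scg_mean = per_function.groupby(level="taxon").sum() / len(scg_ids)

    taxa = sorted(set(focal_by_taxon.index) | set(scg_mean.index))
    records = []
    for taxon in taxa:
        num = (
            focal_by_taxon.loc[taxon]
            if taxon in focal_by_taxon.index
            else pd.Series(0.0, index=profile.samples)
        )
        if taxon in scg_mean.index:
            den = scg_mean.loc[taxon]
        else:
            den = pd.Series(0.0, index=profile.samples)
        percent = 100.0 * num / den.where(den > 0)
        for sample in profile.samples:
            records.append(
                {
                    "sample_id": sample,
                    "taxon": taxon,
                    "percent_in_taxon": float(percent[sample]),
                }
            )
    return pd.DataFrame(records)
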