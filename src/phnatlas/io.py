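"""Readers, writers and validated in-memory containers for every external
format the pipeline touches.

Formats
-------
* gene catalogue, abundance profiles, sample metadata, climatologies,
  taxonomy maps and all outputs: TSV (tab-separated, ``.`` decimal, UTF-8);
* protein alignments: FASTA;
* phylogenetic trees: Newick with branch lengths;
* read alignments: BED (0-based half-open);
* gene coordinates: GFF-lite, four columns ``contig  start  end  gene_id``
  with 1-based inclusive coordinates, converted internally to the canonical
  0-based half-open convention.

Missing environmental measurements are encoded as empty fields and become
NaN, never 0 -- zero is a legal concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "DEFAULT_FUNCTION_MAP",
    "DEFAULT_MARKER_FUNCTION",
    "REGIONS",
    "GeneCatalog",
    "AbundanceProfile",
    "SampleTable",
    "AlignmentBlock",
    "IntervalSet",
    "ValidationError",
    "ParseError",
    "read_catalog",
    "write_catalog",
    "read_profile",
    "write_profile",
    "read_sample_table",
    "write_sample_table",
    "read_alignment",
    "write_alignment",
    "read_tree_with_taxonomy",
    "read_intervals",
    "read_bed",
    "read_gff_genes",
    "write_bed",
    "write_gff_genes",
]

#: Gene-name -> COG/KEGG function identifier map for the phosphorus
#: acquisition genes the pipeline profiles by default: the high-affinity
#: phosphate transporter pstABCS, the C-P lyase catalytic core phnGHIJKL,
#: the phosphonate ABC transporter phnCDE, the hydrolytic phosphonate
#: pathways phnWX and phnA, the alkaline phosphatases phoA/phoD/phoX, the
#: Pho-regulon response regulator phoB, and the universal single-copy
#: marker recA used as the per-genome denominator.
DEFAULT_FUNCTION_MAP: Mapping[str, str] = {
    "pstA": "COG0581",
    "pstB": "COG1117",
    "pstC": "COG0573",
    "pstS": "COG0226",
    "phnG": "COG3624",
    "phnH": "COG3625",
    "phnI": "COG3626",
    "phnJ": "COG3627",
    "phnK": "COG4107",
    "phnL": "COG4778",
    "phnC": "COG3638",
    "phnD": "COG3221",
    "phnE": "COG2629",
    "phnW": "K03430",
    "phnX": "K05306",
    "phnA": "COG1524",
    "phoA": "COG1785",
    "phoD": "COG3540",
    "phoX": "COG3211",
    "phoB": "K07657",
    "recA": "COG0468",
}

#: recA, the universal bacterial single-copy gene used to convert summed
#: gene abundance into "percent of organisms".
DEFAULT_MARKER_FUNCTION = "COG0468"

#: Ocean-region vocabulary: Mediterranean Sea, Red Sea, North/South
#: Atlantic, North/South Pacific, Indian Ocean, Southern Ocean.
REGIONS = ("MS", "RS", "NAO", "SAO", "NPO", "SPO", "IO", "SO")

_FLOAT_FMT = "%.12g"  # 12 significant digits: round-trip stable for profiles


class ValidationError(ValueError):
    """Input violates a container invariant."""


class ParseError(ValueError):
    """Input file is syntactically malformed."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GeneCatalog:
    """Per-gene function assignment, length and optional taxon bin.

    ``table`` columns: gene_id (unique), function_id, length (bp, >= 1),
    taxon_bin (nullable string), is_scg (bool; member of the 40-gene
    universal single-copy marker set).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"gene_id", "function_id", "length"}
        missing = required - set(t.columns)
        if missing:
            raise ValidationError(f"catalog missing columns: {sorted(missing)}")
        if "taxon_bin" not in t.columns:
            t = t.assign(taxon_bin=pd.NA)
        if "is_scg" not in t.columns:
            t = t.assign(is_scg=False)
        if t["gene_id"].duplicated().any():
            dup = t.loc[t["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValidationError(f"duplicate gene_id {dup!r}")
        if (t["length"] < 1).any() or not np.issubdtype(
            np.asarray(t["length"]).dtype, np.integer
        ):
            raise ValidationError("gene lengths must be integers >= 1")
        self.table = t.reset_index(drop=True)

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.table["gene_id"])

    def genes_for_function(self, function_id: str) -> list[str]:
        t = self.table
        return list(t.loc[t["function_id"] == function_id, "gene_id"])

    def lengths(self) -> pd.Series:
        return self.table.set_index("gene_id")["length"]

    def taxon_bins(self) -> pd.Series:
        return self.table.set_index("gene_id")["taxon_bin"]

    def require_scg_bins(self) -> None:
        """Taxon-level enrichment needs a taxon bin on every marker gene."""
        t = self.table
        bad = t.loc[t["is_scg"] & t["taxon_bin"].isna(), "gene_id"]
        if len(bad):
            raise ValidationError(
                f"{len(bad)} single-copy marker genes lack a taxon_bin "
                f"(first: {bad.iloc[0]!r})"
            )


@dataclass
class AbundanceProfile:
    """Gene-length-normalized abundance matrix, genes x samples.

    Values are reads-per-base on an arbitrary per-sample scale; every
    downstream quantity is a ratio within a sample, so the scale cancels.
    """

    values: pd.DataFrame  # index: gene_id, columns: sample_id

    def __post_init__(self) -> None:
        v = self.values
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("profile contains non-finite values")
        if (arr < 0).any():
            raise ValidationError("profile contains negative abundances")
        if v.index.duplicated().any():
            raise ValidationError("duplicate gene ids in profile")
        if v.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in profile")
        v.index.name = "gene_id"
        v.columns.name = None

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def check_against(self, catalog: GeneCatalog, strict: bool = True) -> None:
        unknown = self.genes.difference(catalog.gene_ids)
        if len(unknown):
            msg = f"{len(unknown)} profile genes absent from catalog (first: {unknown[0]!r})"
            if strict:
                raise ValidationError(msg)
            warnings.warn(msg, stacklevel=2)


@dataclass
class SampleTable:
    """Per-sample station metadata and in-situ environmental measurements.

    ``table`` columns: sample_id (unique), station_id, latitude, longitude,
    depth (m), month (1-12 or NaN), region (8-label ocean vocabulary),
    size_fraction, plus any named environmental columns (Pi, N, silicate,
    O2, temperature; micromol/kg or degrees C).
    """

    table: pd.DataFrame

    ENV_COLUMNS = ("Pi", "N", "silicate", "O2", "temperature")

    def __post_init__(self) -> None:
        t = self.table
        required = {
            "sample_id",
            "station_id",
            "latitude",
            "longitude",
            "depth",
            "region",
            "size_fraction",
        }
        missing = required - set(t.columns)
        if missing:
            raise ValidationError(f"sample table missing columns: {sorted(missing)}")
        if t["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id")
        if ((t["latitude"] < -90) | (t["latitude"] > 90)).any():
            raise ValidationError("latitude outside [-90, 90]")
        if ((t["longitude"] <= -180) | (t["longitude"] > 180)).any():
            raise ValidationError("longitude outside (-180, 180]")
        if (~np.isfinite(t["depth"].to_numpy(float))).any() or (t["depth"] < 0).any():
            raise ValidationError("depth must be finite and >= 0")
        bad_region = set(t["region"].dropna()) - set(REGIONS)
        if bad_region:
            raise ValidationError(f"unknown region labels: {sorted(bad_region)}")
        if "month" in t.columns:
            m = t["month"].dropna()
            if ((m < 1) | (m > 12)).any():
                raise ValidationError("month outside 1..12")
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.table["sample_id"])


@dataclass
class AlignmentBlock:
    """A rectangular protein multiple alignment (rows over AA alphabet + '-')."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValidationError("names/rows length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("duplicate sequence names in alignment")
        if self.rows:
            width = len(self.rows[0])
            if any(len(r) != width for r in self.rows):
                raise ValidationError("alignment rows have unequal lengths")

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def n_positions(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass
class IntervalSet:
    """Genomic intervals in the canonical 0-based half-open convention.

    ``table`` columns: contig, start, end (start < end), and optionally
    gene_id when the set describes annotated genes.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"contig", "start", "end"}
        missing = required - set(t.columns)
        if missing:
            raise ValidationError(f"interval set missing columns: {sorted(missing)}")
        if (t["start"] < 0).any():
            raise ValidationError("interval start < 0")
        if (t["end"] <= t["start"]).any():
            bad = t.loc[t["end"] <= t["start"]].iloc[0]
            raise ValidationError(
                f"empty or inverted interval {bad['contig']}:{bad['start']}-{bad['end']}"
            )
        self.table = t.reset_index(drop=True)

    @property
    def has_ids(self) -> bool:
        return "gene_id" in self.table.columns

    def widths(self) -> pd.Series:
        return self.table["end"] - self.table["start"]


# ---------------------------------------------------------------------------
# TSV readers/writers
# ---------------------------------------------------------------------------


def read_catalog(path: str | Path) -> GeneCatalog:
    t = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "function_id": str})
    if "taxon_bin" in t.columns:
        t["taxon_bin"] = t["taxon_bin"].astype("string")
    if "is_scg" in t.columns:
        t["is_scg"] = t["is_scg"].astype(bool)
    return GeneCatalog(t)


def write_catalog(catalog: GeneCatalog, path: str | Path) -> None:
    catalog.table.to_csv(path, sep="\t", index=False)


def read_profile(
    path: str | Path,
    catalog: GeneCatalog | None = None,
    strict: bool = True,
) -> AbundanceProfile:
    """Read a profile TSV: first column ``gene_id``, one column per sample.

    Mirrors the layout of ocean gene-catalogue profile releases. Genes
    absent from ``catalog`` raise (``strict``) or warn.
    """
    try:
        t = pd.read_csv(path, sep="\t", dtype={0: str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if t.shape[1] < 2:
        raise ParseError(f"{path}: profile needs a gene_id column and >=1 sample")
    if t.columns[0] != "gene_id":
        raise ParseError(f"{path}: first column must be 'gene_id', got {t.columns[0]!r}")
    body = t.set_index("gene_id")
    try:
        body = body.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric profile body: {exc}") from exc
    profile = AbundanceProfile(body)
    if catalog is not None:
        profile.check_against(catalog, strict=strict)
    return profile


def write_profile(profile: AbundanceProfile, path: str | Path) -> None:
    out = profile.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_sample_table(path: str | Path) -> SampleTable:
    t = pd.read_csv(
        path,
        sep="\t",
        dtype={"sample_id": str, "station_id": str, "region": str, "size_fraction": str},
    )
    return SampleTable(t)


def write_sample_table(samples: SampleTable, path: str | Path) -> None:
    samples.table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# FASTA alignments
# ---------------------------------------------------------------------------


def read_alignment(path: str | Path) -> AlignmentBlock:
    names, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not names:
        raise ParseError(f"{path}: no FASTA records")
    return AlignmentBlock(names, rows)


def write_alignment(aln: AlignmentBlock, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, row in zip(aln.names, aln.rows):
            fh.write(f">{name}\n{row}\n")


# ---------------------------------------------------------------------------
# Newick trees + taxonomy maps
# ---------------------------------------------------------------------------


def read_tree_with_taxonomy(
    tree_path: str | Path, taxonomy_path: str | Path
) -> tuple[dendropy.Tree, dict[str, str]]:
    """Read a Newick tree and a two-column leaf -> taxon TSV.

    Leaves absent from the taxonomy map are the query sequences to be
    classified; reference leaves carry semicolon-delimited rank paths.
    Branch lengths must be present and non-negative (a missing length is
    treated as 0 only on the root edge).
    """
    try:
        tree = dendropy.Tree.get(
            path=str(tree_path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ParseError(f"{tree_path}: {exc}") from exc
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValidationError(f"{tree_path}: negative branch length {edge.length}")
    taxonomy = read_taxonomy_map(taxonomy_path)
    leaf_names = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    extraneous = set(taxonomy) - leaf_names
    if extraneous:
        warnings.warn(
            f"{len(extraneous)} taxonomy entries have no tree leaf", stacklevel=2
        )
    return tree, taxonomy


def read_taxonomy_map(path: str | Path) -> dict[str, str]:
    taxonomy: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-separated fields")
            leaf, taxon = parts
            if leaf in taxonomy:
                raise ValidationError(f"{path}:{lineno}: duplicate leaf {leaf!r}")
            taxonomy[leaf] = taxon
    return taxonomy


def write_taxonomy_map(taxonomy: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for leaf, taxon in taxonomy.items():
            fh.write(f"{leaf}\t{taxon}\n")


def query_leaves(tree: dendropy.Tree, taxonomy: Mapping[str, str]) -> list[str]:
    """Leaves lacking a taxonomy entry, i.e. the sequences to classify."""
    return [
        leaf.taxon.label
        for leaf in tree.leaf_node_iter()
        if leaf.taxon.label not in taxonomy
    ]


# ---------------------------------------------------------------------------
# BED + GFF-lite intervals
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> IntervalSet:
    """BED3(+): contig, start, end, 0-based half-open; extra columns ignored
    (strand in particular -- per-base depth is strand-agnostic)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            rows.append((parts[0], start, end))
    t = pd.DataFrame(rows, columns=["contig", "start", "end"])
    try:
        return IntervalSet(t)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def read_gff_genes(path: str | Path) -> IntervalSet:
    """GFF-lite gene table: contig, start, end, gene_id with 1-based
    inclusive coordinates, converted to 0-based half-open (start-1, end)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 GFF-lite fields")
            try:
                start1, end1 = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start1 < 1:
                raise ValidationError(f"{path}:{lineno}: 1-based start < 1")
            rows.append((parts[0], start1 - 1, end1, parts[3]))
    t = pd.DataFrame(rows, columns=["contig", "start", "end", "gene_id"])
    if t["gene_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate gene_id in gene table")
    try:
        return IntervalSet(t)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def read_intervals(
    bed_path: str | Path, gff_path: str | Path
) -> tuple[IntervalSet, IntervalSet]:
    """Read mapped-read intervals (BED) and gene coordinates (GFF-lite),
    both returned in the canonical 0-based half-open convention."""
    return read_bed(bed_path), read_gff_genes(gff_path)


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    cols = ["contig", "start", "end"]
    intervals.table[cols].to_csv(path, sep="\t", index=False, header=False)


def write_gff_genes(genes: IntervalSet, path: str | Path) -> None:
    if not genes.has_ids:
        raise ValidationError("gene interval set lacks gene_id")
    out = genes.table.copy()
    out["start"] = out["start"] + 1  # back to 1-based inclusive
    out[["contig", "start", "end", "gene_id"]].to_csv(
        path, sep="\t", index=False, header=False
    )
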