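"""Synthetic marine-community generator with full ground truth.

Every downstream stage of the pipeline (marker normalization, taxon
binning, coverage quantification, climatology matching, regression) is
exercised on data produced here, so each generator records the truth
tables needed to compute every estimand exactly without re-simulation.

The community model
-------------------
A community of ``n_genomes`` genomes. Every genome carries exactly one
copy of the recA marker and of each of the 40 universal single-copy
marker genes; copies of the focal function (by default *phnJ*, the C-P
lyase catalytic gene) are drawn per genome from a configurable copy-number
distribution. Gene lengths are uniform on [600, 2400] bp, bracketing
typical bacterial coding sequences so length normalization is exercised
nontrivially.

Per sample, an inorganic-phosphate concentration Pi is drawn log-uniform
over ``pi_range`` and the community composition is drawn from a Dirichlet
whose expected carrier abundance fraction follows the log-linear response

    log10(percent carriers) = a + b * log10(Pi),

the relationship the regression layer is designed to recover. Read counts
are Poisson on length-proportional expectations (the minimal sequencing
noise model; it keeps every oracle analytic), and a noise-free switch
replaces sampled counts by their expectations so estimator correctness can
be separated from sampling error.
"""

from __future__ import annotations

import math
import random as _random
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from phnatlas.envmatch import ClimatologyGrid
from phnatlas.io import (
    REGIONS,
    AbundanceProfile,
    GeneCatalog,
    IntervalSet,
    SampleTable,
    ValidationError,
)

__all__ = [
    "DEFAULT_SCG_FUNCTIONS",
    "DEFAULT_TAXA",
    "SimulationConfig",
    "CommunityTruth",
    "SimulatedDataset",
    "generate_community",
    "simulate_profiles",
    "generate_reference_tree",
    "pi_from_latitude",
    "carrier_target",
    "generate_climatology",
    "simulate_mag_alignments",
    "make_mag_gene_table",
    "generate_untrimmed_alignment",
]

#: The 40 universal single-copy marker COGs (ribosomal proteins,
#: tRNA-synthetases and other core informational genes) whose mean
#: abundance serves as the per-taxon/per-genome denominator.
DEFAULT_SCG_FUNCTIONS: tuple[str, ...] = (
    "COG0012", "COG0016", "COG0018", "COG0048", "COG0049",
    "COG0052", "COG0080", "COG0081", "COG0085", "COG0087",
    "COG0088", "COG0090", "COG0091", "COG0092", "COG0093",
    "COG0094", "COG0096", "COG0097", "COG0098", "COG0099",
    "COG0100", "COG0102", "COG0103", "COG0124", "COG0172",
    "COG0184", "COG0185", "COG0186", "COG0197", "COG0200",
    "COG0201", "COG0202", "COG0215", "COG0256", "COG0495",
    "COG0522", "COG0525", "COG0533", "COG0541", "COG0552",
)

#: Semicolon-delimited rank paths used to label synthetic taxon bins;
#: chosen to mirror the lineages in which C-P lyase is actually found.
DEFAULT_TAXA: tuple[str, ...] = (
    "Proteobacteria;Alphaproteobacteria;Pelagibacterales",
    "Proteobacteria;Alphaproteobacteria;SAR116",
    "Proteobacteria;Alphaproteobacteria;Rhodobacteraceae",
    "Proteobacteria;Alphaproteobacteria;Rhodospirillales",
    "Proteobacteria;Gammaproteobacteria;Oceanospirillales",
    "Actinobacteria;Acidimicrobiia;OM1",
    "Firmicutes;Bacilli;Bacillales",
    "Chloroflexi;Dehalococcoidia;SAR202",
)

FOCAL_FUNCTION = "COG3627"  # phnJ
MARKER_FUNCTION = "COG0468"  # recA

_LENGTH_RANGE = (600, 2400)  # bp, inclusive


@dataclass
class SimulationConfig:
    """Conditions of a synthetic community study.

    Parameters
    ----------
    n_genomes, n_samples:
        Community and survey size. Defaults (500 genomes, 118 samples)
        match the scale of an epipelagic ocean survey.
    pi_range:
        (low, high) inorganic phosphate, micromol/kg; samples draw Pi
        log-uniform over this range so the log-log regression design is
        balanced.
    response:
        (a, b) of the true relation log10(percent carriers) = a + b*log10(Pi).
        The default slope -1.0 with intercept -0.5 keeps carrier
        prevalence between ~0.3% (replete) and ~16% (depleted) over the
        default Pi range, the dynamic range observed for C-P lyase in
        ocean surveys.
    copy_model:
        Copy-number distribution of the focal function per genome,
        {copies: probability}. Genomes with >= 1 copy are carriers.
    read_depth:
        Expected total reads per sample (Poisson thinning target).
    dirichlet_concentration:
        Total concentration of the per-sample composition Dirichlet;
        larger = realized carrier fraction closer to its target.
    noise_free:
        Replace Poisson counts by their expectations (exact-recovery mode).
    """

    n_genomes: int = 500
    n_samples: int = 118
    pi_range: tuple[float, float] = (0.02, 1.0)
    response: tuple[float, float] = (-0.5, -1.0)
    copy_model: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.5, 1: 0.4, 2: 0.1}
    )
    read_depth: float = 1e6
    dirichlet_concentration: float = 200.0
    focal_function: str = FOCAL_FUNCTION
    marker_function: str = MARKER_FUNCTION
    scg_functions: tuple[str, ...] = DEFAULT_SCG_FUNCTIONS
    taxa: tuple[str, ...] = DEFAULT_TAXA
    noise_free: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 2:
            raise ValidationError("n_genomes must be >= 2")
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        lo, hi = self.pi_range
        if not (0 < lo < hi):
            raise ValidationError("pi_range must be positive and increasing")
        if self.read_depth <= 0:
            raise ValidationError("read_depth must be > 0")
        probs = np.array(list(self.copy_model.values()), dtype=float)
        if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValidationError("copy_model probabilities must sum to 1")
        if any(c < 0 for c in self.copy_model):
            raise ValidationError("copy numbers must be >= 0")
        a, b = self.response
        # the response must be a feasible prevalence over the whole Pi range
        for pi in self.pi_range:
            if carrier_target(pi, a, b) > 1.0 + 1e-12:
                raise ValidationError(
                    f"response implies carrier fraction > 1 at Pi={pi}"
                )

    @property
    def functions(self) -> list[str]:
        return [self.focal_function, self.marker_function, *self.scg_functions]


def carrier_target(pi: float, a: float, b: float) -> float:
    """True fraction of organisms carrying the focal function at Pi."""
    return 10.0 ** (a + b * math.log10(pi)) / 100.0


def pi_from_latitude(latitude, pi_range: tuple[float, float]):
    """Deterministic Pi field: log10(Pi) linear in |latitude| up to 65 deg.

    Phosphate is depleted at low latitudes (the oligotrophic gyres) and
    replete toward the poles; with latitudes uniform on [-65, 65] the
    induced Pi distribution is log-uniform over ``pi_range``, keeping the
    log-log regression design balanced. The same field generates the
    synthetic climatology grid, so matched climatology values agree with
    in-situ Pi up to grid discretization.
    """
    lo, hi = pi_range
    frac = np.minimum(np.abs(np.asarray(latitude, dtype=float)) / 65.0, 1.0)
    return 10.0 ** (math.log10(lo) + frac * (math.log10(hi) - math.log10(lo)))


@dataclass
class CommunityTruth:
    """Ground truth of a simulated community.

    ``copy_number`` is genomes x functions (integer copies per genome);
    ``genome_abundance`` is samples x genomes with rows summing to 1;
    ``carrier_fraction`` / ``mean_copies`` are the per-sample
    abundance-weighted fraction of carrier organisms and mean focal-gene
    copies per organism -- the estimands of the quantification layer.
    """

    genomes: list[str]
    copy_number: pd.DataFrame
    focal_function: str
    genome_taxon: pd.Series
    genome_abundance: pd.DataFrame | None = None
    carrier_fraction: pd.Series | None = None
    mean_copies: pd.Series | None = None

    def validate(self) -> None:
        if (self.copy_number.to_numpy() < 0).any():
            raise ValidationError("negative copy number")
        if self.genome_abundance is not None:
            rows = self.genome_abundance.to_numpy().sum(axis=1)
            if np.abs(rows - 1.0).max() > 1e-9:
                raise ValidationError("genome abundance rows must sum to 1")
        if self.carrier_fraction is not None:
            cf = self.carrier_fraction.to_numpy()
            if ((cf < -1e-9) | (cf > 1 + 1e-9)).any():
                raise ValidationError("carrier_fraction outside [0, 1]")
            if self.mean_copies is not None:
                if (self.mean_copies.to_numpy() + 1e-12 < cf).any():
                    raise ValidationError("mean_copies < carrier_fraction")


@dataclass
class SimulatedDataset:
    """Profile + metadata + completed truth, as emitted by simulate_profiles."""

    profile: AbundanceProfile
    samples: SampleTable
    truth: CommunityTruth


def _gene_id(genome: str, function: str) -> str:
    return f"{genome}_{function}"


def generate_community(
    config: SimulationConfig,
) -> tuple[CommunityTruth, GeneCatalog]:
    """Draw the genome inventory: copy numbers, gene lengths, taxon bins.

    Every genome carries one copy of the marker and of each single-copy
    marker gene; focal-function copies follow ``config.copy_model``.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 0x10])
    genomes = [f"g{i:04d}" for i in range(config.n_genomes)]
    functions = config.functions

    copies = np.ones((config.n_genomes, len(functions)), dtype=int)
    levels = np.array(list(config.copy_model.keys()), dtype=int)
    probs = np.array(list(config.copy_model.values()), dtype=float)
    copies[:, 0] = rng.choice(levels, size=config.n_genomes, p=probs)
    copy_number = pd.DataFrame(copies, index=genomes, columns=functions)

    taxa = list(config.taxa)
    genome_taxon = pd.Series(
        [taxa[i % len(taxa)] for i in range(config.n_genomes)],
        index=genomes,
        name="taxon",
    )

    rows = []
    for gi, genome in enumerate(genomes):
        for fj, function in enumerate(functions):
            if copies[gi, fj] == 0:
                continue
            rows.append(
                {
                    "gene_id": _gene_id(genome, function),
                    "function_id": function,
                    "length": int(rng.integers(_LENGTH_RANGE[0], _LENGTH_RANGE[1] + 1)),
                    "taxon_bin": genome_taxon[genome],
                    "is_scg": function in config.scg_functions,
                }
            )
    catalog = GeneCatalog(pd.DataFrame(rows))
    truth = CommunityTruth(
        genomes=genomes,
        copy_number=copy_number,
        focal_function=config.focal_function,
        genome_taxon=genome_taxon,
    )
    truth.validate()
    return truth, catalog


def simulate_profiles(
    truth: CommunityTruth,
    catalog: GeneCatalog,
    config: SimulationConfig,
) -> SimulatedDataset:
    """Draw per-sample compositions, Pi values and sequencing counts.

    Composition: Dirichlet over genomes with carrier total concentration
    proportional to the target f(Pi), so E[carrier abundance] = f(Pi).
    Counts: gene g of genome i gets Poisson(depth * ab_i * copies * len_g / T)
    reads where T is the abundance-weighted community genome length, so the
    expected total equals ``read_depth``. Profile values are counts / length.
    The recorded truth is the *realized* composition, not the target.
    """
    rng = np.random.default_rng([config.seed, 0x20])
    a, b = config.response
    n_s, n_g = config.n_samples, config.n_genomes
    genomes = truth.genomes
    sample_ids = [f"s{j:04d}" for j in range(n_s)]

    is_carrier = (truth.copy_number[truth.focal_function] >= 1).to_numpy()
    n_carrier = int(is_carrier.sum())
    if n_carrier == 0 or n_carrier == n_g:
        # degenerate: no carrier/non-carrier split to steer; plain Dirichlet
        steer = False
    else:
        steer = True

    latitude = rng.uniform(-65, 65, n_s).round(4)
    pi = pi_from_latitude(latitude, config.pi_range)

    conc = config.dirichlet_concentration
    abundance = np.empty((n_s, n_g))
    for s in range(n_s):
        if steer:
            f = carrier_target(pi[s], a, b)
            if f > 1.0:
                raise ValidationError(f"target carrier fraction {f:.3f} > 1")
            alpha = np.where(
                is_carrier, conc * f / n_carrier, conc * (1 - f) / (n_g - n_carrier)
            )
        else:
            alpha = np.full(n_g, conc / n_g)
        abundance[s] = rng.dirichlet(alpha)

    lengths = catalog.lengths()
    cat = catalog.table
    genome_of_gene = cat["gene_id"].str.rsplit("_", n=1).str[0].to_numpy()
    genome_index = pd.Index(genomes).get_indexer(genome_of_gene)
    func_index = truth.copy_number.columns.get_indexer(cat["function_id"])
    gene_copies = truth.copy_number.to_numpy()[genome_index, func_index]
    gene_len = cat["length"].to_numpy(float)

    # abundance-weighted genome length per sample (normalizer T_s)
    per_gene_mass = gene_copies * gene_len  # (genes,)
    genome_length = np.zeros(n_g)
    np.add.at(genome_length, genome_index, per_gene_mass)
    T = abundance @ genome_length  # (samples,)

    expected = (
        config.read_depth
        * abundance[:, genome_index]
        * per_gene_mass[None, :]
        / T[:, None]
    )  # samples x genes
    if config.noise_free:
        counts = expected
    else:
        counts = rng.poisson(expected).astype(float)
    values = counts / gene_len[None, :]

    profile = AbundanceProfile(
        pd.DataFrame(values.T, index=cat["gene_id"].to_numpy(), columns=sample_ids)
    )

    ab = pd.DataFrame(abundance, index=sample_ids, columns=genomes)
    carrier_fraction = pd.Series(
        abundance[:, is_carrier].sum(axis=1), index=sample_ids, name="carrier_fraction"
    )
    copies_focal = truth.copy_number[truth.focal_function].to_numpy(float)
    mean_copies = pd.Series(
        abundance @ copies_focal, index=sample_ids, name="mean_copies"
    )
    truth.genome_abundance = ab
    truth.carrier_fraction = carrier_fraction
    truth.mean_copies = mean_copies
    truth.validate()

    samples = SampleTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "station_id": [f"st{j:03d}" for j in range(n_s)],
                "latitude": latitude,
                "longitude": rng.uniform(-179.999, 180, n_s).round(4),
                "depth": np.full(n_s, 5.0),
                "month": rng.integers(1, 13, n_s),
                "region": rng.choice(REGIONS, n_s),
                "size_fraction": "0.22",
                "Pi": pi,
                "N": 16.0 * pi * np.exp(rng.normal(0, 0.2, n_s)),
                "silicate": 2.0 * pi * np.exp(rng.normal(0, 0.3, n_s)),
                "O2": rng.uniform(180, 250, n_s).round(2),
                "temperature": rng.uniform(8, 28, n_s).round(2),
            }
        )
    )
    return SimulatedDataset(profile=profile, samples=samples, truth=truth)


# ---------------------------------------------------------------------------
# reference trees with planted queries
# ---------------------------------------------------------------------------


def generate_reference_tree(
    n_ref: int,
    n_query: int,
    n_taxa: int,
    seed: int = 0,
    taxa: Sequence[str] = DEFAULT_TAXA,
    query_names: Sequence[str] | None = None,
    query_ref_names: Sequence[str] | None = None,
) -> tuple[dendropy.Tree, dict[str, str], dict[str, str]]:
    """Random coalescent reference tree with query leaves planted on it.

    Each query is attached as sister to a chosen reference leaf: the
    reference's pendant edge is split at a quarter of its length and the
    query hangs there on a short pendant branch (at most 5% of tree height
    and under a quarter of the split edge), which guarantees that the
    planted reference is the query's patristically nearest reference.

    ``query_names`` / ``query_ref_names`` optionally fix the query leaf
    labels and their target references (e.g. to plant catalogue gene ids
    next to a reference of the right taxon); by default queries are named
    ``queryNNN`` and attached to uniformly chosen references.

    Returns (tree, reference taxonomy map, query truth labels).
    """
    if n_taxa > n_ref:
        raise ValidationError("n_taxa must be <= n_ref")
    if n_taxa < 1 or n_ref < 2:
        raise ValidationError("need >= 2 references and >= 1 taxon")
    pyrng = _random.Random(seed)
    rng = np.random.default_rng([seed, 0x30])

    ns = dendropy.TaxonNamespace([f"ref{i:03d}" for i in range(n_ref)])
    tree = treesim.pure_kingman_tree(taxon_namespace=ns, pop_size=1.0, rng=pyrng)
    height = max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )

    labels = [taxa[i % len(taxa)] for i in range(n_taxa)]
    ref_names = [t.label for t in ns]
    taxonomy = {
        name: labels[i % n_taxa] for i, name in enumerate(ref_names)
    }

    if query_names is None:
        query_names = [f"query{q:03d}" for q in range(n_query)]
    if query_ref_names is not None and len(query_ref_names) != len(query_names):
        raise ValidationError("query_ref_names must align with query_names")

    truth: dict[str, str] = {}
    leaves_by_name = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    for q, qname in enumerate(query_names):
        if query_ref_names is not None:
            ref_name = query_ref_names[q]
        else:
            ref_name = ref_names[int(rng.integers(0, n_ref))]
        ref_leaf = leaves_by_name[ref_name]
        edge_len = ref_leaf.edge.length
        split = edge_len * 0.25
        pendant = min(0.05 * height, edge_len * 0.25) * float(rng.uniform(0.2, 1.0))

        parent = ref_leaf.parent_node
        parent.remove_child(ref_leaf)
        joint = parent.new_child(edge_length=edge_len - split)
        joint.add_child(ref_leaf)
        ref_leaf.edge.length = split
        qtaxon = dendropy.Taxon(label=qname)
        tree.taxon_namespace.add_taxon(qtaxon)
        joint.new_child(taxon=qtaxon, edge_length=pendant)

        leaves_by_name[qname] = joint.child_nodes()[-1]
        truth[qname] = taxonomy[ref_name]
    return tree, taxonomy, truth


# ---------------------------------------------------------------------------
# untrimmed protein alignments
# ---------------------------------------------------------------------------

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def generate_untrimmed_alignment(
    n_unique: int = 440,
    n_positions: int = 276,
    n_gap_columns: int = 40,
    n_shadow_duplicates: int = 60,
    boundary_columns: int = 4,
    seed: int = 0,
):
    """Synthetic untrimmed protein alignment with known trimming truth.

    Emulates the raw output of a multiple aligner over a redundant PhnJ
    sequence set (this is a constructed stand-in, not a real alignment):

    * ``n_positions`` conserved columns that must survive trimming, of
      which ``boundary_columns`` carry a gap fraction of exactly 10% of
      the unique rows (boundary case: kept, since only columns strictly
      above 10% are removed -- both before and after duplicate collapse);
    * ``n_gap_columns`` ragged columns with 20-60% gaps that trimming
      must remove, shuffled in among the conserved ones;
    * ``n_shadow_duplicates`` rows identical to some unique row on every
      conserved column but differing inside removed columns, so they
      collapse only if deduplication runs *after* trimming.

    By construction ``trim_and_dedup`` must return exactly
    (``n_unique`` sequences, ``n_positions`` columns). Returns the
    AlignmentBlock and the expected (n_unique, n_positions).
    """
    from phnatlas.io import AlignmentBlock

    rng = np.random.default_rng([seed, 0x80])
    n_total = n_unique + n_shadow_duplicates
    if boundary_columns and (n_unique % 10):
        raise ValidationError(
            "n_unique must be divisible by 10 to place exact-10% columns"
        )

    core = rng.choice(_AA, size=(n_unique, n_positions))
    # guarantee row uniqueness on the conserved columns
    for i in range(1, n_unique):
        while any((core[i] == core[j]).all() for j in range(i)):
            core[i] = rng.choice(_AA, size=n_positions)

    dup_of = rng.integers(0, n_unique, size=n_shadow_duplicates)
    rows_core = np.vstack([core, core[dup_of]])

    # exact-10% boundary gap columns (kept by the strict > rule); gaps go
    # only into unique rows without shadow copies so duplicate rows stay
    # column-identical to their source and the count stays exactly 10%
    free_rows = np.array(sorted(set(range(n_unique)) - set(dup_of.tolist())))
    if boundary_columns:
        if len(free_rows) < n_unique // 10:
            raise ValidationError("not enough non-duplicated rows for boundary columns")
        for c in rng.choice(n_positions, size=boundary_columns, replace=False):
            gap_rows = rng.choice(free_rows, size=n_unique // 10, replace=False)
            rows_core[gap_rows, c] = "-"

    gappy = rng.choice(_AA, size=(n_total, n_gap_columns))
    for c in range(n_gap_columns):
        frac = rng.uniform(0.2, 0.6)
        gap_rows = rng.choice(n_total, size=int(np.ceil(frac * n_total)), replace=False)
        gappy[gap_rows, c] = "-"
    # shadow duplicates must differ from their source somewhere: force a
    # difference in the first removed column
    for d, src in enumerate(dup_of):
        if (gappy[n_unique + d] == gappy[src]).all():
            gappy[n_unique + d, 0] = "-" if gappy[src, 0] != "-" else "A"

    full = np.hstack([rows_core, gappy])
    order = rng.permutation(n_positions + n_gap_columns)
    full = full[:, order]

    names = [f"seq{i:04d}" for i in range(n_total)]
    aln = AlignmentBlock(names, ["".join(r) for r in full])
    return aln, (n_unique, n_positions)


# ---------------------------------------------------------------------------
# climatology grids
# ---------------------------------------------------------------------------


def generate_climatology(
    lat_axis: Sequence[float],
    lon_axis: Sequence[float],
    depth_axis: Sequence[float],
    field_fn: Callable[..., float],
    monthly: bool = False,
    noise_sd: float = 0.0,
    missing_fraction: float = 0.0,
    variable: str = "Pi",
    units: str = "umol kg-1",
    seed: int = 0,
) -> ClimatologyGrid:
    """Gridded field evaluated on the node product of the given axes.

    ``field_fn`` takes (lat, lon, depth) or (lat, lon, depth, month) when
    ``monthly``; optional Gaussian noise and a fraction of missing cells
    emulate observational climatology gaps. Deterministic given ``seed``.
    """
    for name, ax in (("lat", lat_axis), ("lon", lon_axis), ("depth", depth_axis)):
        ax = np.asarray(ax, dtype=float)
        if ax.size == 0:
            raise ValidationError(f"empty {name} axis")
        if ax.size > 1 and not (np.diff(ax) > 0).all():
            raise ValidationError(f"{name} axis must be strictly increasing")
    rng = np.random.default_rng([seed, 0x40])
    months = range(1, 13) if monthly else (None,)
    rows = []
    for month in months:
        for lat in lat_axis:
            for lon in lon_axis:
                for depth in depth_axis:
                    if month is None:
                        value = field_fn(lat, lon, depth)
                    else:
                        value = field_fn(lat, lon, depth, month)
                    rows.append((lat, lon, depth, month, float(value)))
    t = pd.DataFrame(rows, columns=["lat", "lon", "depth", "month", "value"])
    if not monthly:
        t = t.drop(columns=["month"])
    if noise_sd > 0:
        t["value"] = t["value"] + rng.normal(0, noise_sd, len(t))
    if missing_fraction > 0:
        mask = rng.random(len(t)) < missing_fraction
        t.loc[mask, "value"] = np.nan
    return ClimatologyGrid(t, variable=variable, units=units)


# ---------------------------------------------------------------------------
# MAG read-mapping fixtures
# ---------------------------------------------------------------------------


def make_mag_gene_table(
    n_genes: int,
    gene_length: int = 1000,
    read_length: int = 100,
    seed: int = 0,
) -> tuple[IntervalSet, dict[str, int]]:
    """One padded contig per gene, so simulated reads never hit an edge."""
    rng = np.random.default_rng([seed, 0x50])
    rows = []
    contig_lengths = {}
    for i in range(n_genes):
        length = int(rng.integers(gene_length // 2, gene_length * 2))
        contig = f"contig{i:03d}"
        start = read_length
        rows.append((contig, start, start + length, f"mag_gene{i:03d}"))
        contig_lengths[contig] = start + length + read_length
    genes = IntervalSet(pd.DataFrame(rows, columns=["contig", "start", "end", "gene_id"]))
    return genes, contig_lengths


def simulate_mag_alignments(
    genes: IntervalSet,
    true_coverage: Mapping[str, float],
    contig_lengths: Mapping[str, int],
    read_length: int = 100,
    seed: int = 0,
) -> tuple[IntervalSet, pd.Series]:
    """Place reads so expected per-base depth over each gene equals its
    true coverage; read counts are Poisson.

    A read overlapping a gene of length L can start at L + read_length - 1
    positions; drawing starts uniform over those and the count from
    Poisson(cov * (L + read_length - 1) / read_length) gives expected
    depth exactly ``cov`` at every base of the gene. Reads are clipped at
    contig bounds, so gene tables should leave ``read_length`` of padding
    (see make_mag_gene_table).
    """
    if not genes.has_ids:
        raise ValidationError("gene table lacks gene_id")
    rng = np.random.default_rng([seed, 0x60])
    reads = []
    truth = {}
    for row in genes.table.itertuples(index=False):
        contig_len = contig_lengths[row.contig]
        if read_length > contig_len:
            raise ValidationError(
                f"read_length {read_length} exceeds contig {row.contig} "
                f"length {contig_len}"
            )
        cov = float(true_coverage[row.gene_id])
        if cov < 0:
            raise ValidationError(f"negative coverage for {row.gene_id}")
        truth[row.gene_id] = cov
        if cov == 0:
            continue
        gene_len = row.end - row.start
        n_positions = gene_len + read_length - 1
        n_reads = rng.poisson(cov * n_positions / read_length)
        starts = rng.integers(
            row.start - read_length + 1, row.end, size=n_reads
        )
        for s in starts:
            reads.append((row.contig, max(0, int(s)), min(contig_len, int(s) + read_length)))
    reads_table = pd.DataFrame(reads, columns=["contig", "start", "end"])
    if reads_table.empty:
        reads_table = pd.DataFrame(columns=["contig", "start", "end"])
    reads_set = (
        IntervalSet(reads_table)
        if len(reads_table)
        else IntervalSet(pd.DataFrame({"contig": [], "start": [], "end": []}))
    )
    return reads_set, pd.Series(truth, name="true_coverage")
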