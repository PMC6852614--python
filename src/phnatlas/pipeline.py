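"""End-to-end orchestration: quantify -> classify/enrich -> magquant ->
envmatch -> stats, driven by a flat key=value config file.

Stages communicate only through TSV files in the output directory (no
hidden state), are skipped gracefully when their inputs are absent, and a
manifest records input checksums, package version, seed and per-stage row
counts so every number in the outputs can be reproduced by calling the
underlying module operation on the intermediate files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from phnatlas import envmatch as em
from phnatlas import io, magmap, quantify, stats, synth, taxonomy
from phnatlas._version import __version__

__all__ = ["RunConfig", "run_all", "write_synthetic_bundle"]

log = logging.getLogger("phnatlas")

_FMT = "%.12g"


@dataclass
class RunConfig:
    """Paths and knobs of one pipeline run. Optional inputs left empty
    skip their stage."""

    catalog: Path
    profile: Path
    samples: Path
    outdir: Path
    tree: Path | None = None
    taxonomy_map: Path | None = None
    climatology: Path | None = None
    reads_bed: Path | None = None
    genes_gff: Path | None = None
    mag_focal_gene: str = "mag_gene000"
    match_preset: str = "woa"
    functions: Sequence[str] = dc_field(
        default_factory=lambda: sorted(set(io.DEFAULT_FUNCTION_MAP.values()))
    )
    focal_function: str = "COG3627"
    marker_function: str = io.DEFAULT_MARKER_FUNCTION
    scg_functions: Sequence[str] = dc_field(
        default_factory=lambda: list(synth.DEFAULT_SCG_FUNCTIONS)
    )
    truth_dir: Path | None = None
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a flat ``key = value`` config file (# comments allowed)."""
        raw: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise io.ParseError(f"{path}:{lineno}: expected key = value")
            key, _, value = line.partition("=")
            raw[key.strip()] = value.strip()

        base = Path(path).parent

        def p(key: str, required: bool = False) -> Path | None:
            if key not in raw or not raw[key]:
                if required:
                    raise io.ValidationError(f"{path}: missing required key {key!r}")
                return None
            candidate = Path(raw[key])
            return candidate if candidate.is_absolute() else base / candidate

        kwargs: dict = {
            "catalog": p("catalog", required=True),
            "profile": p("profile", required=True),
            "samples": p("samples", required=True),
            "outdir": p("outdir", required=True),
            "tree": p("tree"),
            "taxonomy_map": p("taxonomy_map"),
            "climatology": p("climatology"),
            "reads_bed": p("reads_bed"),
            "genes_gff": p("genes_gff"),
            "truth_dir": p("truth_dir"),
        }
        for key in ("match_preset", "focal_function", "marker_function", "mag_focal_gene"):
            if raw.get(key):
                kwargs[key] = raw[key]
        if raw.get("functions"):
            kwargs["functions"] = raw["functions"].split(",")
        if raw.get("scg_functions"):
            kwargs["scg_functions"] = raw["scg_functions"].split(",")
        if raw.get("seed"):
            kwargs["seed"] = int(raw["seed"])
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False, float_format=_FMT)
    return len(df)


def run_all(config: RunConfig) -> Path:
    """Run every stage whose inputs exist; returns the output directory.

    On stage failure the partial output directory is preserved with a
    ``<stage>.partial`` marker file and the exception propagates.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {},
        "stages": {},
    }
    for key in ("catalog", "profile", "samples", "tree", "taxonomy_map",
                "climatology", "reads_bed", "genes_gff"):
        path = getattr(config, key)
        if path is not None and Path(path).exists():
            manifest["inputs"][key] = {
                "path": str(path), "sha256": _sha256(Path(path))
            }

    stage = "load"
    try:
        catalog = io.read_catalog(config.catalog)
        profile = io.read_profile(config.profile, catalog)
        samples = io.read_sample_table(config.samples)

        # ---- quantify ---------------------------------------------------
        stage = "quantify"
        zones = quantify.add_depth_zones(samples)[
            ["sample_id", "depth_zone", "region"]
        ]
        frames = []
        for function_id in config.functions:
            if function_id == config.marker_function:
                continue
            if not catalog.genes_for_function(function_id):
                log.warning("no catalogue genes for %s; skipped", function_id)
                continue
            tab = quantify.percent_organisms(
                profile, catalog, function_id, config.marker_function
            ).table
            frames.append(tab)
        prevalence = pd.concat(frames, ignore_index=True).merge(zones, on="sample_id")
        n = _write(prevalence, out / "prevalence.tsv")
        manifest["stages"]["quantify"] = {"rows": n}
        log.info("quantify: %d rows", n)

        # ---- taxonomy ---------------------------------------------------
        if config.tree is not None and config.taxonomy_map is not None:
            stage = "taxonomy"
            tree, ref_tax = io.read_tree_with_taxonomy(
                config.tree, config.taxonomy_map
            )
            bins = taxonomy.classify_queries(tree, ref_tax)
            _write(bins.table, out / "taxon_bins.tsv")
            contrib = taxonomy.taxon_contribution(
                profile, bins, catalog, config.focal_function
            )
            _write(contrib, out / "taxon_contribution.tsv")
            has_bins = catalog.table.loc[
                catalog.table["is_scg"], "taxon_bin"
            ].notna().all()
            if has_bins:
                enrich = taxonomy.taxon_enrichment(
                    profile, bins, catalog, config.scg_functions,
                    config.focal_function,
                )
                _write(enrich, out / "taxon_enrichment.tsv")
            manifest["stages"]["taxonomy"] = {
                "queries": len(bins.table), "rows": len(contrib)
            }
            log.info("taxonomy: %d queries classified", len(bins.table))
        else:
            log.warning("no tree/taxonomy map; taxonomy stage skipped")

        # ---- magquant ---------------------------------------------------
        if config.reads_bed is not None and config.genes_gff is not None:
            stage = "magquant"
            reads, genes = io.read_intervals(config.reads_bed, config.genes_gff)
            cov = magmap.gene_coverage(reads, genes)
            _write(cov.table, out / "gene_coverage.tsv")
            scg_gene_ids = [
                g for g in genes.table["gene_id"] if g != config.mag_focal_gene
            ]
            percent = magmap.mag_percent(cov, config.mag_focal_gene, scg_gene_ids)
            _write(
                pd.DataFrame(
                    {
                        "focal_gene": [config.mag_focal_gene],
                        "percent": [percent],
                        "copies_per_cell": [percent / 100.0],
                    }
                ),
                out / "mag_percent.tsv",
            )
            manifest["stages"]["magquant"] = {
                "genes": len(cov.table), "percent": percent
            }
            log.info("magquant: focal population percent %.3f", percent)
        else:
            log.warning("no read/gene intervals; magquant stage skipped")

        # ---- envmatch ---------------------------------------------------
        matched_pi = None
        if config.climatology is not None:
            stage = "envmatch"
            grid = em.read_climatology(config.climatology, variable="Pi")
            policy = em.PRESETS[config.match_preset]
            matched = em.match_stations(samples, grid, policy)
            matched = matched.rename(columns={"value": "climatology_Pi"})
            _write(matched.reset_index(), out / "climatology_match.tsv")
            matched_pi = matched["climatology_Pi"]
            manifest["stages"]["envmatch"] = {
                "matched": int(matched_pi.notna().sum()),
                "missing": int(matched_pi.isna().sum()),
            }
            log.info("envmatch: %d matched", int(matched_pi.notna().sum()))
        else:
            log.warning("no climatology; envmatch stage skipped")

        # ---- stats ------------------------------------------------------
        stage = "stats"
        sample_env = samples.table.set_index("sample_id")
        pi_source = (
            matched_pi
            if matched_pi is not None
            else sample_env.get("Pi", pd.Series(dtype=float))
        )
        fits = []
        comparisons = []
        correlations = []
        for function_id, grp in prevalence.groupby("function_id"):
            grp = grp.set_index("sample_id")
            epz = grp[grp["depth_zone"] == "EPZ"]
            pct = epz["percent_organisms"]
            pi = pi_source.reindex(epz.index)
            try:
                fit = stats.loglog_fit(pct.to_numpy(), pi.to_numpy())
                fits.append({"function_id": function_id, **fit.__dict__})
            except (stats.DegenerateInputError, ValueError) as exc:
                log.warning("loglog_fit %s: %s", function_id, exc)
            for env_name in ("Pi", "N", "silicate", "O2", "temperature"):
                if env_name not in sample_env.columns:
                    continue
                try:
                    r, p, n_used = stats.pearson_test(
                        np.log10(pct.where(pct > 0)),
                        np.log10(sample_env[env_name].reindex(epz.index).where(lambda s: s > 0)),
                    )
                    correlations.append(
                        {"function_id": function_id, "parameter": env_name,
                         "r": r, "p": p, "n": n_used,
                         "stars": _stars(p)}
                    )
                except stats.DegenerateInputError:
                    pass
            try:
                comp = stats.kruskal_wallis(
                    pct.to_numpy(), epz["region"].to_numpy()
                )
                pw = stats.pairwise_wilcoxon_bh(
                    pct.to_numpy(), epz["region"].to_numpy()
                )
                comparisons.append(
                    {
                        "function_id": function_id,
                        "H": comp[0],
                        "df": comp[1],
                        "p": comp[2],
                        "enriched_regions": ",".join(
                            sorted(pw.enriched_flags[pw.enriched_flags].index)
                        ),
                    }
                )
            except stats.DegenerateInputError as exc:
                log.warning("group comparison %s: %s", function_id, exc)
        _write(pd.DataFrame(fits), out / "regressions.tsv")
        _write(pd.DataFrame(correlations), out / "correlations.tsv")
        _write(pd.DataFrame(comparisons), out / "region_comparisons.tsv")
        manifest["stages"]["stats"] = {
            "fits": len(fits), "comparisons": len(comparisons)
        }

        # ---- truth recovery ---------------------------------------------
        if config.truth_dir is not None and Path(config.truth_dir).exists():
            stage = "truth_recovery"
            truth_path = Path(config.truth_dir) / "sample_truth.tsv"
            if truth_path.exists():
                truth = pd.read_csv(truth_path, sep="\t").set_index("sample_id")
                focal = prevalence[
                    prevalence["function_id"] == config.focal_function
                ].set_index("sample_id")
                joined = focal.join(truth, how="inner")
                joined["true_percent"] = 100.0 * joined["mean_copies"]
                joined["abs_error"] = (
                    joined["percent_organisms"] - joined["true_percent"]
                ).abs()
                report = joined.reset_index()[
                    ["sample_id", "percent_organisms", "true_percent", "abs_error"]
                ]
                _write(report, out / "truth_recovery.tsv")
                manifest["stages"]["truth_recovery"] = {
                    "max_abs_error": float(report["abs_error"].max()),
                    "rows": len(report),
                }
    except Exception:
        (out / f"{stage}.partial").write_text("stage failed\n")
        log.exception("stage %s failed", stage)
        log.removeHandler(handler)
        handler.close()
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.removeHandler(handler)
    handler.close()
    return out


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# synthetic bundle
# ---------------------------------------------------------------------------


def write_synthetic_bundle(
    outdir: str | Path,
    config: synth.SimulationConfig | None = None,
    n_ref: int = 64,
) -> Path:
    """Emit a complete synthetic input bundle plus truth tables and a
    ready-to-run pipeline config file.

    Contents: catalog.tsv, profile.tsv, samples.tsv, tree.nwk,
    taxonomy.tsv, reads.bed, genes.gff, climatology.tsv, run.cfg and a
    truth/ directory. Deterministic given the simulation seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    if config is None:
        config = synth.SimulationConfig()

    truth, catalog = synth.generate_community(config)
    dataset = synth.simulate_profiles(truth, catalog, config)
    io.write_catalog(catalog, outdir / "catalog.tsv")
    io.write_profile(dataset.profile, outdir / "profile.tsv")
    io.write_sample_table(dataset.samples, outdir / "samples.tsv")

    # tree: plant each focal catalogue gene next to a reference of its
    # genome's taxon, so classification can recover the true bins
    focal_genes = catalog.table[
        catalog.table["function_id"] == config.focal_function
    ]
    rng = np.random.default_rng([config.seed, 0x70])
    taxa_cycle = [config.taxa[i % len(config.taxa)] for i in range(len(config.taxa))]
    ref_taxon = {
        f"ref{i:03d}": taxa_cycle[i % len(taxa_cycle)] for i in range(n_ref)
    }
    refs_by_taxon: dict[str, list[str]] = {}
    for name, taxon in ref_taxon.items():
        refs_by_taxon.setdefault(taxon, []).append(name)
    query_names = list(focal_genes["gene_id"])
    query_refs = [
        refs_by_taxon[t][int(rng.integers(0, len(refs_by_taxon[t])))]
        for t in focal_genes["taxon_bin"]
    ]
    tree, taxonomy_map, tree_truth = synth.generate_reference_tree(
        n_ref=n_ref,
        n_query=len(query_names),
        n_taxa=len(config.taxa),
        seed=config.seed,
        taxa=config.taxa,
        query_names=query_names,
        query_ref_names=query_refs,
    )
    tree.write(path=str(outdir / "tree.nwk"), schema="newick")
    io.write_taxonomy_map(taxonomy_map, outdir / "taxonomy.tsv")

    # MAG read-mapping fixture: one focal gene + the 40 marker genes of a
    # single population at 10x, focal at 25x (2.5 copies per cell)
    genes, contig_lengths = synth.make_mag_gene_table(
        41, gene_length=1000, read_length=100, seed=config.seed
    )
    coverage = {g: 10.0 for g in genes.table["gene_id"]}
    coverage["mag_gene000"] = 25.0
    reads, cov_truth = synth.simulate_mag_alignments(
        genes, coverage, contig_lengths, read_length=100, seed=config.seed
    )
    io.write_bed(reads, outdir / "reads.bed")
    io.write_gff_genes(genes, outdir / "genes.gff")

    lo, hi = config.pi_range
    grid = synth.generate_climatology(
        lat_axis=np.arange(-66.0, 67.0, 1.0),
        lon_axis=np.arange(-179.0, 181.0, 2.0),
        depth_axis=[5.0],
        field_fn=lambda lat, lon, depth: synth.pi_from_latitude(lat, (lo, hi)),
        monthly=False,
        seed=config.seed,
        variable="Pi",
    )
    em.write_climatology(grid, outdir / "climatology.tsv")

    # truth tables
    sample_truth = pd.DataFrame(
        {
            "sample_id": dataset.truth.carrier_fraction.index,
            "carrier_fraction": dataset.truth.carrier_fraction.to_numpy(),
            "mean_copies": dataset.truth.mean_copies.to_numpy(),
        }
    )
    _write(sample_truth, truth_dir / "sample_truth.tsv")
    dataset.truth.copy_number.rename_axis("genome").reset_index().to_csv(
        truth_dir / "copy_number.tsv", sep="\t", index=False
    )
    dataset.truth.genome_abundance.rename_axis("sample_id").reset_index().to_csv(
        truth_dir / "genome_abundance.tsv", sep="\t", index=False, float_format=_FMT
    )
    pd.DataFrame(
        {"gene_id": list(tree_truth), "taxon": list(tree_truth.values())}
    ).to_csv(truth_dir / "tree_truth.tsv", sep="\t", index=False)
    cov_truth.rename_axis("gene_id").reset_index().to_csv(
        truth_dir / "coverage_truth.tsv", sep="\t", index=False
    )

    (outdir / "run.cfg").write_text(
        "\n".join(
            [
                "catalog = catalog.tsv",
                "profile = profile.tsv",
                "samples = samples.tsv",
                "tree = tree.nwk",
                "taxonomy_map = taxonomy.tsv",
                "climatology = climatology.tsv",
                "reads_bed = reads.bed",
                "genes_gff = genes.gff",
                "truth_dir = truth",
                "outdir = results",
                f"seed = {config.seed}",
                f"focal_function = {config.focal_function}",
                f"marker_function = {config.marker_function}",
                "scg_functions = " + ",".join(config.scg_functions),
                "functions = "
                + ",".join([config.focal_function]),
                "",
            ]
        )
    )
    return outdir
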