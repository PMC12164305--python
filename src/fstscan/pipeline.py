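"""End-to-end orchestration: QC -> structure -> pair scans -> annotation.

``run_all`` drives the full analysis from a single :class:`RunConfig` and
writes every stage's output as plain text (TSV/newick/BED/JSON) so any stage
can be re-run or inspected independently. A thin click CLI exposes the stages
as subcommands.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import __version__
from .annotate import gene_map_to_frame, map_regions_to_genes, read_gff_genes
from .dsrscan import ScanConfig, regions_to_frame, run_pair_scan
from .genio import QCConfig, apply_qc, read_vcf
from .simdata import SimulationConfig, simulate_panel, three_breed_config, write_fixture
from .structure import classical_mds, distance_matrix, nj_tree, wc_weighted_fst

log = logging.getLogger("fstscan")

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``vcf`` (with ``sample_map``) or ``sim`` must be given.
    ``pairs`` lists the population pairs to scan; by default every pair of
    non-outgroup populations present in the panel.
    """

    outdir: Path
    vcf: Path | None = None
    sample_map: Path | None = None
    sim: SimulationConfig | None = None
    qc: QCConfig = field(default_factory=QCConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    pairs: list[tuple[str, str]] | None = None
    gff: Path | None = None
    mds_components: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.vcf is None) == (self.sim is None):
            raise ValueError("provide exactly one of vcf or sim")
        if self.vcf is not None and self.sample_map is None:
            raise ValueError("a VCF input needs a sample map")


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def export_manhattan(stats: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
    """Manhattan-plot table with genome-cumulative positions and the realized
    two-tier FST thresholds of the scan.

    Returns (table with chrom, pos, cum_pos, fst, label; thresholds dict).
    """
    offsets: dict[str, int] = {}
    offset = 0
    for chrom, sub in stats.groupby("chrom", sort=False):
        offsets[chrom] = offset
        offset += int(sub["pos"].max())
    table = stats[["chrom", "pos", "fst", "label"]].copy()
    table.insert(
        2, "cum_pos", [int(p) + offsets[c] for c, p in zip(stats["chrom"], stats["pos"])]
    )
    thresholds = {
        "extreme": stats.attrs["threshold_extreme"],
        "significant": stats.attrs["threshold_significant"],
    }
    return table, thresholds


def run_all(cfg: RunConfig) -> dict:
    """Run every stage and write the output bundle; returns a result summary.

    Outputs under ``cfg.outdir``: QC report, labelled distance matrix, newick
    tree, MDS coordinates, pairwise weighted FST table, per-pair SNP statistics
    and DSR tables (TSV + BED), Manhattan export with realized thresholds,
    per-region gene maps when a GFF3 is given, and a deterministic manifest.
    Re-running with identical inputs reproduces identical bytes.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    log.info("stage input: loading panel")
    truth = None
    if cfg.sim is not None:
        panel, truth = simulate_panel(cfg.sim)
        write_fixture(panel, out / "panel", truth=truth)
    else:
        panel = read_vcf(cfg.vcf, cfg.sample_map)
    log.info("panel: %d samples, %d SNPs", panel.n_samples, panel.n_snps)

    log.info("stage qc")
    panel, report = apply_qc(panel, cfg.qc)
    _write_tsv(report.to_frame(), out / "qc_report.tsv")
    for stage, removed, remaining in report.stages:
        log.info("qc %-12s removed=%d remaining=%d", stage, removed, remaining)
    results["qc_report"] = report
    results["panel"] = panel

    log.info("stage structure")
    dm = distance_matrix(panel)
    dm_df = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
    dm_df.to_csv(out / "distance_matrix.tsv", sep="\t", float_format=_FLOAT_FMT)
    tree = nj_tree(dm)
    (out / "tree.nwk").write_text(str(tree))
    mds = classical_mds(dm, k=cfg.mds_components)
    _write_tsv(mds.to_frame(), out / "mds.tsv")
    results.update(distance=dm, tree=tree, mds=mds)

    pops = panel.populations
    pairs = cfg.pairs or [
        (a, b)
        for i, a in enumerate(pops)
        for b in pops[i + 1 :]
        if "OUT" not in (a, b)
    ]
    fst_rows = []
    for a, b in pairs:
        theta, _ = wc_weighted_fst(panel, a, b)
        fst_rows.append({"pop_a": a, "pop_b": b, "weighted_fst": theta})
        log.info("weighted FST %s-%s: %.4f", a, b, theta)
    fst_df = pd.DataFrame(fst_rows)
    _write_tsv(fst_df, out / "fst_pairs.tsv")
    results["fst"] = fst_df

    genes = read_gff_genes(cfg.gff) if cfg.gff else None
    if genes is None:
        log.info("stage annotate: skipped (no GFF3 given)")

    results["scans"] = {}
    for a, b in pairs:
        tag = f"{a}_vs_{b}"
        log.info("stage scan %s", tag)
        stats, regions = run_pair_scan(panel, a, b, cfg.scan)
        _write_tsv(stats, out / f"{tag}.snp_stats.tsv")
        reg_df = regions_to_frame(regions)
        _write_tsv(reg_df, out / f"{tag}.dsr.tsv")
        with open(out / f"{tag}.dsr.bed", "w") as fh:
            for r in regions:
                fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.name}\n")
        manh, thresholds = export_manhattan(stats)
        _write_tsv(manh, out / f"{tag}.manhattan.tsv")
        (out / f"{tag}.thresholds.json").write_text(
            json.dumps(thresholds, sort_keys=True) + "\n"
        )
        entry = {"stats": stats, "regions": regions, "thresholds": thresholds}
        log.info("scan %s: %d regions", tag, len(regions))
        if genes is not None:
            per_region, unique = map_regions_to_genes(regions, genes)
            _write_tsv(gene_map_to_frame(regions, per_region), out / f"{tag}.genes.tsv")
            pd.DataFrame({"gene_id": unique}).to_csv(
                out / f"{tag}.unique_genes.tsv", sep="\t", index=False
            )
            entry.update(per_region_genes=per_region, unique_genes=unique)
            log.info("scan %s: %d unique genes", tag, len(unique))
        results["scans"][(a, b)] = entry

    if truth is not None:
        results["truth"] = truth

    manifest = {
        "fstscan_version": __version__,
        "numpy_version": np.__version__,
        "seed": cfg.seed,
        "qc": {
            "max_missing_rate": cfg.qc.max_missing_rate,
            "min_maf": cfg.qc.min_maf,
            "hwe_alpha": cfg.qc.hwe_alpha,
            "autosomes": sorted(cfg.qc.autosomes, key=str),
        },
        "scan": {
            "q_extreme": cfg.scan.q_extreme,
            "q_sig": cfg.scan.q_sig,
            "alpha": cfg.scan.alpha,
            "break_len": cfg.scan.break_len,
            "min_run": cfg.scan.min_run,
        },
        "pairs": [list(p) for p in pairs],
        "input": str(cfg.vcf) if cfg.vcf else "simulated",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return results


# ---------------------------------------------------------------------------
# CLI


def _common_scan_options(fn):
    for opt in reversed(
        [
            click.option("--max-missing-rate", default=0.10, show_default=True),
            click.option("--min-maf", default=0.10, show_default=True),
            click.option("--hwe-alpha", default=0.01, show_default=True),
            click.option("--q-extreme", default=0.0001, show_default=True),
            click.option("--q-sig", default=0.005, show_default=True),
            click.option("--alpha", default=0.05, show_default=True),
        ]
    ):
        fn = opt(fn)
    return fn


@click.group()
def cli():
    """Genotype QC, population structure and selection-region scanning."""
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")


@cli.command()
@click.option("--outdir", type=click.Path(), required=True)
@click.option("--n-snps-per-chrom", default=1500, show_default=True)
@click.option("--missing-rate", default=0.02, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--planted/--no-planted", default=True, show_default=True)
def simulate(outdir, n_snps_per_chrom, missing_rate, seed, planted):
    """Write a synthetic three-breed + outgroup panel (VCF + sample map + truth BED)."""
    cfg = three_breed_config(
        n_snps_per_chrom=n_snps_per_chrom,
        missing_rate=missing_rate,
        seed=seed,
        planted=planted,
    )
    panel, truth = simulate_panel(cfg)
    paths = write_fixture(panel, Path(outdir) / "panel", truth=truth)
    for k, p in paths.items():
        click.echo(f"{k}: {p}")


@cli.command("all")
@click.option("--vcf", type=click.Path(exists=True), required=True)
@click.option("--sample-map", type=click.Path(exists=True), required=True)
@click.option("--gff", type=click.Path(exists=True), default=None)
@click.option("--outdir", type=click.Path(), required=True)
@click.option(
    "--pair",
    "pair_opts",
    multiple=True,
    help="Population pair 'A,B'; repeatable. Default: all non-outgroup pairs.",
)
@_common_scan_options
def run_all_cmd(
    vcf, sample_map, gff, outdir, pair_opts, max_missing_rate, min_maf, hwe_alpha,
    q_extreme, q_sig, alpha,
):
    """Run QC, structure, all pair scans and (optionally) gene annotation."""
    pairs = [tuple(p.split(",")) for p in pair_opts] or None
    cfg = RunConfig(
        outdir=Path(outdir),
        vcf=Path(vcf),
        sample_map=Path(sample_map),
        gff=Path(gff) if gff else None,
        pairs=pairs,
        qc=QCConfig(max_missing_rate=max_missing_rate, min_maf=min_maf, hwe_alpha=hwe_alpha),
        scan=ScanConfig(q_extreme=q_extreme, q_sig=q_sig, alpha=alpha),
    )
    run_all(cfg)


@cli.command()
@click.option("--vcf", type=click.Path(exists=True), required=True)
@click.option("--sample-map", type=click.Path(exists=True), required=True)
@click.option("--out", type=click.Path(), required=True)
@click.option("--max-missing-rate", default=0.10, show_default=True)
@click.option("--min-maf", default=0.10, show_default=True)
@click.option("--hwe-alpha", default=0.01, show_default=True)
def qc(vcf, sample_map, out, max_missing_rate, min_maf, hwe_alpha):
    """Apply the staged SNP filters; write the QC report TSV."""
    panel = read_vcf(vcf, sample_map)
    _, report = apply_qc(
        panel, QCConfig(max_missing_rate=max_missing_rate, min_maf=min_maf, hwe_alpha=hwe_alpha)
    )
    _write_tsv(report.to_frame(), Path(out))
    click.echo(report.to_frame().to_string(index=False))


@cli.command()
@click.option("--vcf", type=click.Path(exists=True), required=True)
@click.option("--sample-map", type=click.Path(exists=True), required=True)
@click.option("--outdir", type=click.Path(), required=True)
def structure(vcf, sample_map, outdir):
    """IBS distance matrix, NJ tree and MDS coordinates (no QC applied)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    panel = read_vcf(vcf, sample_map)
    dm = distance_matrix(panel)
    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
        out / "distance_matrix.tsv", sep="\t", float_format=_FLOAT_FMT
    )
    (out / "tree.nwk").write_text(str(nj_tree(dm)))
    _write_tsv(classical_mds(dm).to_frame(), out / "mds.tsv")


@cli.command()
@click.option("--vcf", type=click.Path(exists=True), required=True)
@click.option("--sample-map", type=click.Path(exists=True), required=True)
@click.option("--pair", required=True, help="Population pair 'A,B'.")
@click.option("--outdir", type=click.Path(), required=True)
@click.option("--q-extreme", default=0.0001, show_default=True)
@click.option("--q-sig", default=0.005, show_default=True)
@click.option("--alpha", default=0.05, show_default=True)
def scan(vcf, sample_map, pair, outdir, q_extreme, q_sig, alpha):
    """DSR scan for one breed pair (expects a QC'd VCF)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    a, b = pair.split(",")
    panel = read_vcf(vcf, sample_map)
    stats, regions = run_pair_scan(
        panel, a, b, ScanConfig(q_extreme=q_extreme, q_sig=q_sig, alpha=alpha)
    )
    tag = f"{a}_vs_{b}"
    _write_tsv(stats, out / f"{tag}.snp_stats.tsv")
    _write_tsv(regions_to_frame(regions), out / f"{tag}.dsr.tsv")
    click.echo(f"{len(regions)} regions")


@cli.command()
@click.option("--dsr", type=click.Path(exists=True), required=True, help="DSR TSV from scan.")
@click.option("--gff", type=click.Path(exists=True), required=True)
@click.option("--outdir", type=click.Path(), required=True)
def annotate(dsr, gff, outdir):
    """Map a DSR table onto gene intervals from a GFF3."""
    from .dsrscan import DSRegion

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(dsr, sep="\t", dtype={"chrom": str})
    regions = [
        DSRegion(
            id=i + 1,
            chrom=str(row["chrom"]),
            start=int(row["start"]),
            end=int(row["end"]),
            n_snps_spanned=int(row.get("n_snps_spanned", 0)),
            n_significant=int(row.get("n_significant", 0)),
            n_extreme=int(row.get("n_extreme", 0)),
        )
        for i, (_, row) in enumerate(df.iterrows())
    ]
    genes = read_gff_genes(gff)
    per_region, unique = map_regions_to_genes(regions, genes)
    _write_tsv(gene_map_to_frame(regions, per_region), out / "region_genes.tsv")
    pd.DataFrame({"gene_id": unique}).to_csv(out / "unique_genes.tsv", sep="\t", index=False)
    click.echo(f"{len(unique)} unique genes")
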