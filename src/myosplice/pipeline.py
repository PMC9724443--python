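"""End-to-end pipeline driver.

Sequences the analysis over a directory of inputs (typically written by
the synthetic generator): AS event cataloguing -> FPKM/PSI
quantification -> differential expression and splicing -> MeRIP peak
calling and differential methylation -> m6A x AS integration -> the
splicing-factor correlation network. Writes per-stage TSVs and a
machine-readable JSON report; identical config and inputs give a
byte-identical report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel

from . import annotation, differential, integration, io as msio, methylation, network, quantify

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Input locations and the decision thresholds of every stage."""

    input_dir: str
    outdir: str
    fpkm_min: float = 0.5
    de_log2fc: float = 1.0
    fdr: float = 0.05
    rho_min: float = 0.9
    peak_fold: float = 2.0
    flank: int = 1000
    psi_min_total: int = 10
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must be in (0, 1)")
        if self.peak_fold < 1 or self.rho_min < 0 or self.flank < 0:
            raise ValueError("threshold out of range")
        required = ["annotation.gtf", "event_catalogue.tsv", "event_counts.tsv",
                    "gene_counts.tsv", "gene_lengths.tsv", "merip_bins.tsv",
                    "merip_ip_counts.tsv", "merip_input_counts.tsv",
                    "sample_sheet.tsv", "sf_list.txt"]
        missing = [f for f in required if not (Path(self.input_dir) / f).exists()]
        if missing:
            raise FileNotFoundError(f"missing inputs in {self.input_dir}: {missing}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


class RunReport(BaseModel):
    """Schema of the machine-readable run report."""

    package_version: str
    seed: int
    thresholds: dict[str, float]
    catalogue: dict
    n_expressed_genes: int
    n_deg: int
    n_das: int
    n_das_tested: int
    deg_dasg_venn: dict
    n_peaks: int
    n_dm_peaks: int
    as_fraction: dict
    as_count_groups: dict
    sedmas: dict
    knockdown: dict | None = None
    network: dict
    n_warnings: int


def _stage(name):
    logger.info("stage: %s", name)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the validated report dictionary."""
    config.validate()
    indir = Path(config.input_dir)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_warnings = 0

    _stage("annotation")
    genes = msio.read_gtf(indir / "annotation.gtf")
    events_list = [ev for g in genes for ev in annotation.classify_as_events(g)]
    summary = annotation.count_events_per_gene(events_list)
    catalogue = annotation.summarize_event_catalogue(summary.per_type_counts)
    catalogue["per_type_gene_counts"] = summary.per_type_gene_counts
    catalogue["n_multi_event_genes"] = len(summary.multi_event_genes)
    event_meta = msio.read_tsv(indir / "event_catalogue.tsv")

    _stage("quantification")
    sheet = msio.read_tsv(indir / "sample_sheet.tsv")
    design = sheet["condition"]
    counts = msio.read_tsv(indir / "gene_counts.tsv")
    lengths = msio.read_tsv(indir / "gene_lengths.tsv")["length"]
    fpkm = quantify.compute_fpkm(counts, lengths)
    expressed = quantify.filter_expressed(fpkm, config.fpkm_min)
    event_counts = msio.read_tsv(indir / "event_counts.tsv", index_col=None)
    psi = quantify.psi_matrix(event_counts, event_meta, min_total=config.psi_min_total)
    msio.write_tsv(fpkm, outdir / "fpkm.tsv")
    msio.write_tsv(psi, outdir / "psi.tsv")

    _stage("differential")
    de = differential.test_differential_expression(
        counts.loc[expressed], design, lfc_threshold=config.de_log2fc, alpha=config.fdr
    )
    das = differential.test_differential_psi(
        event_counts, event_meta, design,
        min_total=config.psi_min_total, alpha=config.fdr,
    )
    das = das.join(event_meta[["gene_id", "event_type", "cassette_start", "cassette_end", "strand"]])
    venn = differential.intersect_deg_dasg(
        de.index[de["deg"]], das.loc[das["das"], "gene_id"].unique()
    )
    msio.write_tsv(de, outdir / "differential_expression.tsv")
    msio.write_tsv(das, outdir / "differential_splicing.tsv")

    _stage("methylation")
    bins = msio.read_tsv(indir / "merip_bins.tsv")
    ip = msio.read_tsv(indir / "merip_ip_counts.tsv")
    inp = msio.read_tsv(indir / "merip_input_counts.tsv")
    peaks, peak_ip, peak_input = methylation.call_peaks(
        bins, ip, inp, design, alpha=config.fdr, min_fold=config.peak_fold
    )
    dm = methylation.test_differential_methylation(
        peak_ip, peak_input, design, alpha=config.fdr,
        ip_library_sizes=ip.sum(axis=0), input_library_sizes=inp.sum(axis=0),
    )
    dm = dm.join(peaks[["chrom", "start", "end", "gene_id"]])
    se_meta = event_meta[event_meta["event_type"] == "SE"]
    features = pd.DataFrame(
        {
            "chrom": se_meta["chrom"],
            "start": se_meta["cassette_start"].astype(int),
            "end": se_meta["cassette_end"].astype(int),
        },
        index=se_meta.index,
    )
    overlaps = methylation.overlap_peaks_features(peaks, features, flank=config.flank)
    msio.write_bed(peaks, outdir / "peaks.bed")
    msio.write_tsv(dm, outdir / "differential_methylation.tsv")
    msio.write_tsv(overlaps, outdir / "peak_event_overlaps.tsv", index=False)

    _stage("integration")
    expressed_real = [g for g in expressed if g in set(lengths.index)]
    gene_has_peak = pd.Series(False, index=pd.Index(expressed_real, name="gene_id"))
    for g in peaks["gene_id"]:
        if g in gene_has_peak.index:
            gene_has_peak[g] = True
    events_per_gene = {g: sum(c.values()) for g, c in summary.per_gene_types.items()}
    gene_has_as = pd.Series(
        [events_per_gene.get(g, 0) > 0 for g in gene_has_peak.index], index=gene_has_peak.index
    )
    try:
        fractions = integration.as_fraction_by_modification(gene_has_peak, gene_has_as)
    except ValueError:
        fractions = {"error": "empty modification class"}
        n_warnings += 1
    m6a_gene_counts = pd.Series(
        {g: events_per_gene.get(g, 0) for g in gene_has_peak.index[gene_has_peak]}
    )
    if len(m6a_gene_counts) >= 4:
        groups = integration.group_by_as_counts(m6a_gene_counts)
        gene_m6a_lfc = dm.groupby("gene_id")["log2fc"].mean()
        group_stats = integration.compare_group_enrichment(groups, gene_m6a_lfc)
        group_sizes = groups["group"].value_counts().to_dict()
    else:
        group_stats, group_sizes = {}, {}
        n_warnings += 1
    sedmas_records, sedmas_summary = integration.classify_sedmas(
        das.rename(columns={"padj": "padj"}), dm.rename(columns={"padj": "padj"}),
        overlaps, das_alpha=config.fdr, peak_alpha=config.fdr,
    )
    msio.write_tsv(sedmas_records, outdir / "sedmas.tsv")

    knockdown = None
    kd_path = indir / "knockdown_das.tsv"
    if kd_path.exists():
        kd = msio.read_tsv(kd_path)
        tissue = das.loc[sedmas_records.index, ["gene_id", "cassette_start", "cassette_end", "strand"]]
        kd_venn = integration.intersect_knockdown(tissue, kd)
        knockdown = {k: kd_venn[k] for k in ("n_tissue", "n_knockdown", "n_shared", "shared_percent_of_tissue")}

    _stage("network")
    with open(indir / "sf_list.txt") as fh:
        sf_ids = [line.strip() for line in fh if line.strip()]
    sf_fpkm = fpkm.loc[[s for s in sf_ids if s in fpkm.index]]
    das_ids = das.index[das["das"]]
    net = network.build_sf_network(
        sf_fpkm, psi, das_events=das_ids,
        event_types=event_meta["event_type"],
        sf_de_flags=de["deg"].reindex(sf_fpkm.index).fillna(False),
        rho_min=config.rho_min, alpha=config.fdr,
    )
    network.export_network(net.edges, outdir / "sf_network.graphml", outdir / "sf_network.sif")
    msio.write_tsv(net.edges, outdir / "sf_network_edges.tsv", index=False)

    report = {
        "package_version": _version(),
        "seed": config.seed,
        "thresholds": {
            "fpkm_min": config.fpkm_min,
            "de_log2fc": config.de_log2fc,
            "fdr": config.fdr,
            "rho_min": config.rho_min,
            "peak_fold": config.peak_fold,
            "flank": float(config.flank),
            "psi_min_total": float(config.psi_min_total),
        },
        "catalogue": catalogue,
        "n_expressed_genes": int(len(expressed)),
        "n_deg": int(de["deg"].sum()),
        "n_das": int(das["das"].sum()),
        "n_das_tested": int(das["tested"].sum()),
        "deg_dasg_venn": {k: venn[k] for k in ("n_deg", "n_dasg", "n_intersection")},
        "n_peaks": int(len(peaks)),
        "n_dm_peaks": int(dm["significant"].sum()),
        "as_fraction": {k: v for k, v in fractions.items() if k != "error"},
        "as_count_groups": {"sizes": group_sizes, **{k: v for k, v in group_stats.items()}},
        "sedmas": sedmas_summary,
        "knockdown": knockdown,
        "network": {"n_edges": int(len(net.edges)), "n_tested": net.n_tested,
                    "hubs": {str(k): int(v) for k, v in net.hubs.items()}},
        "n_warnings": n_warnings,
    }
    RunReport.model_validate(report)  # bundled schema check
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_jsonable)
        fh.write("\n")
    return report


def _jsonable(x):
    try:
        return x.item()
    except AttributeError:
        return str(x)


def _version() -> str:
    from importlib.metadata import version, PackageNotFoundError

    try:
        return version("myosplice")
    except PackageNotFoundError:
        return "0.0.0"
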