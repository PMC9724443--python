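"""File formats and coordinate-convention boundaries.

Internally every interval is 0-based half-open. GTF is written and read
as 1-based closed (converted at this boundary only); BED is 0-based
half-open. All tabular interchange is TSV with a header row; every file
written here carries a leading ``#`` comment declaring its coordinate
convention.
"""

from __future__ import annotations

import json
from pathlib import Path

import gffutils
import pandas as pd

from .annotation import GeneModel


def write_gtf(genes, path) -> None:
    """Write gene/transcript/exon features, 1-based closed coordinates."""
    with open(path, "w") as fh:
        fh.write("#!coordinate convention: 1-based closed (GTF)\n")
        for g in sorted(genes, key=lambda g: g.gene_id):
            gs, ge = g.span
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\tmyosplice\tgene\t{gs + 1}\t{ge}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for tid, tx in zip(g.transcript_ids, g.transcripts):
                tattrs = f'gene_id "{g.gene_id}"; transcript_id "{tid}";'
                fh.write(
                    f"{g.chrom}\tmyosplice\ttranscript\t{tx[0][0] + 1}\t{tx[-1][1]}"
                    f"\t.\t{g.strand}\t.\t{tattrs}\n"
                )
                for s, e in tx:
                    fh.write(
                        f"{g.chrom}\tmyosplice\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{tattrs}\n"
                    )


def read_gtf(path) -> list[GeneModel]:
    """Parse a GTF into gene models (converted to 0-based half-open).

    Exons are grouped by transcript and sorted, so unsorted exon lines
    yield the same model as sorted input. Raises on missing gene_id /
    transcript_id attributes or inverted exons.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_gene: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        if "gene_id" not in exon.attributes or "transcript_id" not in exon.attributes:
            raise ValueError(f"exon at {exon.seqid}:{exon.start} lacks gene_id/transcript_id")
        if exon.end < exon.start:
            raise ValueError(f"exon with end < start at {exon.seqid}:{exon.start}")
        gid = exon.attributes["gene_id"][0]
        tid = exon.attributes["transcript_id"][0]
        info = per_gene.setdefault(
            gid, {"chrom": exon.seqid, "strand": exon.strand, "transcripts": {}}
        )
        info["transcripts"].setdefault(tid, []).append((exon.start - 1, exon.end))
    genes = []
    for gid in sorted(per_gene):
        info = per_gene[gid]
        tids = sorted(info["transcripts"])
        txs = tuple(tuple(sorted(info["transcripts"][t])) for t in tids)
        gene = GeneModel(gid, info["chrom"], info["strand"], txs, tuple(tids))
        gene.validate()
        genes.append(gene)
    return genes


_CONVENTION = "# coordinate convention: 0-based half-open\n"


def write_tsv(df: pd.DataFrame, path, index=True) -> None:
    with open(path, "w") as fh:
        fh.write(_CONVENTION)
        df.to_csv(fh, sep="\t", index=index, na_rep="NA")


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col, na_values=["NA"])


def write_bed(intervals: pd.DataFrame, path) -> None:
    """BED6 from a frame with chrom/start/end (+ optional strand), ids as index."""
    with open(path, "w") as fh:
        fh.write("# coordinate convention: 0-based half-open (BED)\n")
        for iv_id, row in intervals.iterrows():
            strand = row.get("strand", ".")
            fh.write(
                f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}\t{iv_id}\t0\t{strand}\n"
            )


def write_truth(truth, path) -> None:
    payload = {
        "true_psi": truth.true_psi.round(6).to_dict(orient="index"),
        "das_events": sorted(truth.das_events),
        "das_signs": truth.das_signs,
        "dm_peaks": truth.dm_peaks.reset_index().to_dict(orient="records"),
        "sf_targets": truth.sf_targets,
        "de_genes": sorted(truth.de_genes),
        "de_signs": truth.de_signs,
        "m6a_genes": sorted(truth.m6a_genes),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def write_dataset(dataset, outdir: Path) -> None:
    """Write every pipeline input (plus the truth) of a simulated study."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gtf(dataset.genes, outdir / "annotation.gtf")
    write_tsv(dataset.events, outdir / "event_catalogue.tsv")
    write_tsv(dataset.event_counts, outdir / "event_counts.tsv", index=False)
    write_tsv(dataset.gene_counts, outdir / "gene_counts.tsv")
    write_tsv(dataset.gene_lengths.to_frame(), outdir / "gene_lengths.tsv")
    write_tsv(dataset.bins, outdir / "merip_bins.tsv")
    write_bed(dataset.bins, outdir / "merip_bins.bed")
    write_tsv(dataset.ip_counts, outdir / "merip_ip_counts.tsv")
    write_tsv(dataset.input_counts, outdir / "merip_input_counts.tsv")
    write_tsv(dataset.sf_expression, outdir / "sf_expression.tsv")
    with open(outdir / "sf_list.txt", "w") as fh:
        for sf in dataset.sf_ids:
            fh.write(sf + "\n")
    sheet = dataset.design.to_frame()
    sheet["replicate"] = [s.rsplit("_", 1)[1] for s in sheet.index]
    write_tsv(sheet.rename_axis("sample_id"), outdir / "sample_sheet.tsv")
    write_truth(dataset.truth, outdir / "truth.json")
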