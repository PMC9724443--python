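"""Synthetic two-muscle study generator with planted ground truth.

Emulates the design of a two-condition (oxidative SOL-like vs glycolytic
EDL-like) by three-biological-replicate muscle study with paired MeRIP
IP/input libraries: gene models carrying each AS event type by
construction, binomial junction counts around planted PSI values,
negative-binomial gene expression with planted fold changes, binned
IP/input MeRIP counts with planted enriched and differentially enriched
peaks, and splicing-factor expression monotonically coupled to target
event PSI.

Every planted effect is recorded in a :class:`SyntheticTruth` so that all
downstream statistics can be scored against known truth. One global seed
feeds a per-stream splittable RNG (`numpy.random.SeedSequence.spawn`), so
adding a stage never perturbs the draws of earlier stages; identical
configs produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import ASEvent, GeneModel

EVENT_TYPE_WEIGHTS = {
    # catalogue composition loosely follows the SE-dominated split seen in
    # muscle transcriptomes; "none" genes have a single transcript
    "SE": 0.40,
    "SE2": 0.10,  # two cassette exons in one gene (multi-event genes)
    "A5SS": 0.07,
    "A3SS": 0.07,
    "MXE": 0.13,
    "RI": 0.13,
    "none": 0.10,
}

CONDITIONS = ("EDL", "SOL")  # condition2 (SOL) minus condition1 (EDL) throughout


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic generator.

    The defaults encode the emulated study: 2 conditions x 3 biological
    replicates with paired IP/input MeRIP libraries, a planted
    delta-PSI of 0.3 on a subset of skipped exons and a planted 4-fold
    m6A enrichment change on a subset of exon-overlapping peaks.
    """

    n_genes: int = 200
    n_transcripts_per_gene: tuple[int, int] = (1, 2)
    n_conditions: int = 2
    n_replicates: int = 3
    depth_per_event: float = 100.0
    nb_dispersion: float = 0.05
    planted_dpsi: float = 0.3
    planted_m6a_log2fc: float = 2.0
    sf_coupling_noise: float = 0.1
    seed: int = 0
    # planted-effect composition
    das_fraction: float = 0.4
    sedmas_fraction: float = 0.5
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    m6a_gene_fraction: float = 0.5
    dm_background_fraction: float = 0.2
    m6a_base_log2: float = 2.0
    # depths and geometry
    mean_expression: float = 200.0
    merip_depth_per_bin: float = 50.0
    bin_width: int = 50
    psi_replicate_sd: float = 0.02
    n_sf: int = 5
    read_length: int = 100

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_conditions != 2:
            raise ValueError("the study design has exactly two conditions")
        if self.n_replicates < 2:
            raise ValueError("need at least two biological replicates")
        if self.depth_per_event < 0:
            raise ValueError("depth_per_event must be >= 0")
        if not 0.0 <= self.planted_dpsi <= 1.0:
            raise ValueError("planted_dpsi must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("negative dispersion rejected")
        lo, hi = self.n_transcripts_per_gene
        if lo < 1 or hi < lo:
            raise ValueError("invalid n_transcripts_per_gene range")
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1")

    @property
    def samples(self) -> list[str]:
        return [f"{c}_{r + 1}" for c in CONDITIONS for r in range(self.n_replicates)]

    @property
    def design(self) -> pd.Series:
        return pd.Series(
            {s: s.rsplit("_", 1)[0] for s in self.samples}, name="condition"
        )


@dataclass
class SyntheticTruth:
    """Planted ground truth of a simulated dataset."""

    true_psi: pd.DataFrame          # event x condition
    psi_samples: pd.DataFrame       # event x sample (replicate jitter applied)
    das_events: set[str]
    das_signs: dict[str, int]
    dm_peaks: pd.DataFrame          # planted peak intervals with log2fc and event link
    sf_targets: dict[str, list[str]]
    de_genes: set[str]
    de_signs: dict[str, int]
    events: list[ASEvent] = field(default_factory=list)
    m6a_genes: set[str] = field(default_factory=set)

    @property
    def sedmas_truth(self) -> pd.DataFrame:
        """Planted SE-DMAS events: rows of dm_peaks tied to a DAS event."""
        linked = self.dm_peaks[self.dm_peaks["event_id"].notna() & (self.dm_peaks["log2fc"] != 0)]
        out = linked[["event_id", "gene_id", "log2fc"]].copy()
        out["psi_sign"] = [self.das_signs.get(e, 0) for e in out["event_id"]]
        out["m6a_sign"] = np.sign(out["log2fc"]).astype(int)
        return out.set_index("event_id")


# ---------------------------------------------------------------------------
# gene models


def _exon_chain(rng, cursor, n, exon_len=(100, 300), intron_len=(200, 1000)):
    exons = []
    pos = cursor
    for i in range(n):
        if i:
            pos += int(rng.integers(*intron_len))
        length = int(rng.integers(*exon_len))
        exons.append((pos, pos + length))
        pos = exons[-1][1]
    return exons


def _build_gene(gene_id, chrom, strand, etype, cursor, rng):
    """Construct one gene carrying exactly the requested AS event type."""
    if etype == "SE":
        e1, e2, e3 = _exon_chain(rng, cursor, 3)
        txs = ((e1, e2, e3), (e1, e3))
        truth = ASEvent("SE", gene_id, chrom, strand, (e1, e2, e3))
    elif etype == "SE2":
        e1, e2, e3, e4, e5 = _exon_chain(rng, cursor, 5)
        txs = ((e1, e2, e3, e4, e5), (e1, e3, e5))
        truth = [
            ASEvent("SE", gene_id, chrom, strand, (e1, e2, e3)),
            ASEvent("SE", gene_id, chrom, strand, (e3, e4, e5)),
        ]
    elif etype == "MXE":
        e1, e2, e3, e4 = _exon_chain(rng, cursor, 4)
        txs = ((e1, e2, e4), (e1, e3, e4))
        truth = ASEvent("MXE", gene_id, chrom, strand, (e1, e2, e3, e4))
    elif etype == "RI":
        e1, e2 = _exon_chain(rng, cursor, 2)
        txs = ((e1, e2), ((e1[0], e2[1]),))
        truth = ASEvent("RI", gene_id, chrom, strand, (e1, (e1[1], e2[0]), e2))
    elif etype in ("A5SS", "A3SS"):
        e1, e2 = _exon_chain(rng, cursor, 2)
        ext = int(rng.integers(30, min(100, e2[0] - e1[1] - 10)))
        # right-end (genomic donor) variation is A5SS on '+', A3SS on '-'
        right_varies = (etype == "A5SS") == (strand == "+")
        if right_varies:
            long_exon, short_exon = (e1[0], e1[1] + ext), e1
            txs = ((long_exon, e2), (short_exon, e2))
            truth = ASEvent(etype, gene_id, chrom, strand, (long_exon, short_exon, e2))
        else:
            long_exon, short_exon = (e2[0] - ext, e2[1]), e2
            txs = ((e1, long_exon), (e1, short_exon))
            truth = ASEvent(etype, gene_id, chrom, strand, (long_exon, short_exon, e1))
    elif etype == "none":
        n = int(rng.integers(2, 5))
        txs = (tuple(_exon_chain(rng, cursor, n)),)
        truth = None
    else:  # pragma: no cover
        raise ValueError(f"unknown event type {etype}")
    gene = GeneModel(gene_id, chrom, strand, tuple(tuple(t) for t in txs))
    gene.validate()
    return gene, truth


def generate_gene_models(config: SimulationConfig, rng=None):
    """Generate gene models with a known planted AS event per gene.

    Returns ``(genes, truth_events)`` where every truth event is exactly
    what :func:`myosplice.annotation.classify_as_events` recovers from the
    corresponding gene.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(6)[0])
    types = list(EVENT_TYPE_WEIGHTS)
    probs = np.array([EVENT_TYPE_WEIGHTS[t] for t in types])
    chroms = [str(c + 1) for c in range(3)]
    cursors = {c: 10_000 for c in chroms}
    genes, truth = [], []
    for i in range(config.n_genes):
        chrom = chroms[i % len(chroms)]
        strand = "+" if rng.random() < 0.5 else "-"
        etype = str(rng.choice(types, p=probs))
        gene_id = f"G{i + 1:05d}"
        gene, ev = _build_gene(gene_id, chrom, strand, etype, cursors[chrom], rng)
        cursors[chrom] = gene.span[1] + 5_000
        genes.append(gene)
        if ev is None:
            continue
        truth.extend(ev if isinstance(ev, list) else [ev])
    return genes, truth


# ---------------------------------------------------------------------------
# planted PSI and junction counts


def _plant_psi(events, config: SimulationConfig, rng):
    """Baseline PSI per event plus planted delta-PSI on a subset of SEs."""
    event_ids = [e.event_id for e in events]
    se_ids = [e.event_id for e in events if e.event_type == "SE"]
    n_das = int(round(config.das_fraction * len(se_ids)))
    das = sorted(rng.choice(se_ids, size=n_das, replace=False)) if n_das else []
    signs = {e: int(s) for e, s in zip(das, rng.choice([-1, 1], size=len(das)))}

    d = config.planted_dpsi
    base = rng.uniform(0.2, 0.8, size=len(event_ids))
    psi = pd.DataFrame({c: base for c in CONDITIONS}, index=pd.Index(event_ids, name="event_id"))
    for ev in das:
        s = signs[ev]
        lo, hi = (0.05, 0.95 - d) if s > 0 else (0.05 + d, 0.95)
        b = rng.uniform(lo, hi)
        psi.loc[ev, CONDITIONS[0]] = b
        psi.loc[ev, CONDITIONS[1]] = b + s * d
    return psi, set(das), signs


def _psi_per_sample(true_psi: pd.DataFrame, config: SimulationConfig, rng) -> pd.DataFrame:
    cond_of = config.design
    cols = {}
    for s in config.samples:
        base = true_psi[cond_of[s]].to_numpy()
        jitter = rng.normal(0.0, config.psi_replicate_sd, size=len(base))
        cols[s] = np.clip(base + jitter, 0.0, 1.0)
    return pd.DataFrame(cols, index=true_psi.index)


def event_table(events, config: SimulationConfig) -> pd.DataFrame:
    """Catalogue frame with coordinates and effective junction lengths."""
    rl = config.read_length
    rows = []
    for ev in events:
        rows.append(
            {
                "event_id": ev.event_id,
                "event_type": ev.event_type,
                "gene_id": ev.gene_id,
                "chrom": ev.chrom,
                "strand": ev.strand,
                "coords": ";".join(f"{s}-{e}" for s, e in ev.exons),
                "cassette_start": ev.cassette[0],
                "cassette_end": ev.cassette[1],
                "inclusion_length": 2 * (rl - 1),
                "skipping_length": rl - 1,
            }
        )
    return pd.DataFrame(rows).set_index("event_id")


def simulate_event_counts(
    events: pd.DataFrame,
    psi_samples: pd.DataFrame,
    config: SimulationConfig,
    rng=None,
) -> pd.DataFrame:
    """Binomial inclusion/skipping junction counts per event and sample.

    The per-sample event depth is Poisson(depth_per_event); the inclusion
    probability converts the transcript-level PSI into a read-level
    proportion via the effective lengths, so that the length-normalised
    PSI estimator is unbiased for the planted PSI.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(6)[1])
    psi = psi_samples.reindex(events.index)
    l_i = events["inclusion_length"].to_numpy(dtype=float)[:, None]
    l_s = events["skipping_length"].to_numpy(dtype=float)[:, None]
    p = psi.to_numpy()
    with np.errstate(invalid="ignore"):
        p_read = (p * l_i) / (p * l_i + (1 - p) * l_s)
    p_read = np.nan_to_num(p_read, nan=0.0)
    depth = rng.poisson(config.depth_per_event, size=p.shape)
    incl = rng.binomial(depth, p_read)
    skip = depth - incl
    long = pd.DataFrame(
        {
            "event_id": np.repeat(events.index.to_numpy(), psi.shape[1]),
            "sample_id": np.tile(psi.columns.to_numpy(), len(events)),
            "inclusion_count": incl.ravel(),
            "skipping_count": skip.ravel(),
        }
    )
    return long


# ---------------------------------------------------------------------------
# gene expression


def simulate_expression(
    gene_lengths: pd.Series,
    config: SimulationConfig,
    rng=None,
    de_genes: set[str] | None = None,
    de_signs: dict[str, int] | None = None,
):
    """Negative-binomial gene counts with planted expression fold changes.

    Mean = baseline x (length/1kb) x library factor x 2^(log2FC x cond2);
    dispersion is the common ``nb_dispersion`` (Poisson in the limit 0).
    Returns (counts, libfactors).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(6)[3])
    gene_ids = list(gene_lengths.index)
    if de_genes is None:
        n_de = int(round(config.de_fraction * len(gene_ids)))
        de = sorted(rng.choice(gene_ids, size=n_de, replace=False)) if n_de else []
        de_genes = set(de)
        de_signs = {g: int(s) for g, s in zip(de, rng.choice([-1, 1], size=len(de)))}
    lfc = np.array(
        [de_signs.get(g, 0) * config.de_log2fc if g in de_genes else 0.0 for g in gene_ids]
    )
    baseline = rng.lognormal(mean=np.log(config.mean_expression), sigma=0.8, size=len(gene_ids))
    libfac = pd.Series(rng.uniform(0.85, 1.15, size=len(config.samples)), index=config.samples)
    length_kb = gene_lengths.to_numpy(dtype=float) / 1e3
    is_c2 = np.array([config.design[s] == CONDITIONS[1] for s in config.samples], dtype=float)
    mean = (
        baseline[:, None]
        * length_kb[:, None]
        * libfac.to_numpy()[None, :]
        * 2.0 ** (lfc[:, None] * is_c2[None, :])
    )
    counts = _nb_sample(rng, mean, config.nb_dispersion)
    df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=config.samples)
    return df, libfac, de_genes, de_signs


def _nb_sample(rng, mean, dispersion):
    if dispersion < 1e-12:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


# ---------------------------------------------------------------------------
# MeRIP-seq


def tile_gene_bins(genes, bin_width: int) -> pd.DataFrame:
    """Tile each gene body with fixed-width bins (last bin truncated)."""
    rows = []
    for g in genes:
        start, end = g.span
        for s in range(start, end, bin_width):
            e = min(s + bin_width, end)
            rows.append((f"bin:{g.chrom}:{s}-{e}", g.chrom, s, e, g.gene_id))
    return pd.DataFrame(
        rows, columns=["bin_id", "chrom", "start", "end", "gene_id"]
    ).set_index("bin_id")


def plant_peaks(
    genes,
    events: pd.DataFrame,
    das_events: set[str],
    das_signs: dict[str, int],
    config: SimulationConfig,
    rng,
) -> tuple[pd.DataFrame, set[str]]:
    """Choose m6A-modified genes and plant (differential) peaks.

    Every modified gene gets one peak over a randomly chosen exon. Genes
    carrying a planted differential SE event are preferentially selected
    so that a configurable fraction of DAS cassette exons also carries a
    differentially methylated peak (the planted SE-DMAS truth); a further
    background fraction of modified genes gets a differential peak not
    tied to any event.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    se_das = events.loc[sorted(das_events)]
    n_sedmas = int(round(config.sedmas_fraction * len(se_das)))
    sedmas_ids = sorted(rng.choice(se_das.index, size=n_sedmas, replace=False)) if n_sedmas else []
    sedmas_genes = {events.loc[e, "gene_id"] for e in sedmas_ids}

    other = sorted(set(gene_by_id) - sedmas_genes)
    n_more = max(int(round(config.m6a_gene_fraction * len(gene_by_id))) - len(sedmas_genes), 0)
    n_more = min(n_more, len(other))
    more = sorted(rng.choice(other, size=n_more, replace=False)) if n_more else []
    m6a_genes = sorted(sedmas_genes | set(more))

    n_bg_dm = int(round(config.dm_background_fraction * len(more)))
    bg_dm = set(rng.choice(more, size=n_bg_dm, replace=False)) if n_bg_dm else set()

    rows = []
    covered = set()
    for eid in sedmas_ids:
        ev = events.loc[eid]
        sign = int(rng.choice([-1, 1]))
        rows.append(
            {
                "peak_id": f"tpeak:{ev['gene_id']}:{int(ev['cassette_start'])}",
                "gene_id": ev["gene_id"],
                "chrom": ev["chrom"],
                "start": int(ev["cassette_start"]),
                "end": int(ev["cassette_end"]),
                "log2fc": sign * config.planted_m6a_log2fc,
                "event_id": eid,
            }
        )
        covered.add(ev["gene_id"])
    # background peaks sit on constitutive exons only: keeping cassette
    # exons free of incidental peaks makes the planted SE-DMAS truth the
    # unique source of DAS/peak co-occurrence
    cassettes: dict[str, set] = {}
    for eid in events.index[events["event_type"] == "SE"]:
        ev = events.loc[eid]
        cassettes.setdefault(ev["gene_id"], set()).add(
            (int(ev["cassette_start"]), int(ev["cassette_end"]))
        )
    for gid in m6a_genes:
        if gid in covered:
            continue
        g = gene_by_id[gid]
        blocked = cassettes.get(gid, set())
        exons = [e for e in g.transcripts[0] if (e[0], e[1]) not in blocked]
        if not exons:
            continue
        ex = exons[int(rng.integers(0, len(exons)))]
        sign = int(rng.choice([-1, 1])) if gid in bg_dm else 0
        rows.append(
            {
                "peak_id": f"tpeak:{gid}:{ex[0]}",
                "gene_id": gid,
                "chrom": g.chrom,
                "start": ex[0],
                "end": ex[1],
                "log2fc": sign * config.planted_m6a_log2fc,
                "event_id": None,
            }
        )
    dm = pd.DataFrame(
        rows, columns=["peak_id", "gene_id", "chrom", "start", "end", "log2fc", "event_id"]
    ).set_index("peak_id")
    return dm, set(m6a_genes)


def simulate_merip(
    bins: pd.DataFrame,
    planted_peaks: pd.DataFrame,
    config: SimulationConfig,
    rng=None,
    gene_factors: pd.Series | None = None,
):
    """Paired IP/input NB counts per bin and sample.

    Input counts follow an expression-proportional mean; IP means multiply
    the paired input mean by the bin's enrichment: 1.0 for background,
    2^(base + cond x planted log2FC) inside planted peaks.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(6)[4])
    gene_ids = bins["gene_id"].unique()
    if gene_factors is None:
        gene_factors = pd.Series(
            rng.lognormal(0.0, 0.5, size=len(gene_ids)), index=gene_ids
        )
    bad = set(bins["gene_id"]) - set(gene_factors.index)
    if bad:
        raise ValueError(f"bins outside any gene: {sorted(bad)[:5]}")

    log2_enr = {c: np.zeros(len(bins)) for c in CONDITIONS}
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()
    chroms = bins["chrom"].to_numpy()
    for _, pk in planted_peaks.iterrows():
        inside = (chroms == pk["chrom"]) & (starts < pk["end"]) & (ends > pk["start"])
        log2_enr[CONDITIONS[0]][inside] = config.m6a_base_log2
        log2_enr[CONDITIONS[1]][inside] = config.m6a_base_log2 + pk["log2fc"]

    gf = gene_factors.reindex(bins["gene_id"]).to_numpy()
    libfac = rng.uniform(0.85, 1.15, size=2 * len(config.samples))
    ip_cols, input_cols = {}, {}
    for k, s in enumerate(config.samples):
        cond = config.design[s]
        mu_in = config.merip_depth_per_bin * gf * libfac[2 * k]
        mu_ip = mu_in / libfac[2 * k] * libfac[2 * k + 1] * 2.0 ** log2_enr[cond]
        input_cols[s] = _nb_sample(rng, mu_in, config.nb_dispersion)
        ip_cols[s] = _nb_sample(rng, mu_ip, config.nb_dispersion)
    ip = pd.DataFrame(ip_cols, index=bins.index)
    inp = pd.DataFrame(input_cols, index=bins.index)
    return ip, inp


# ---------------------------------------------------------------------------
# splicing-factor coupling


def simulate_sf_coupling(
    sf_ids,
    target_events: dict[str, list[str]],
    psi_samples: pd.DataFrame,
    config: SimulationConfig,
    rng=None,
    existing_gene_ids=None,
    intercept: float = np.log(100.0),
    slope: float = 3.0,
) -> pd.DataFrame:
    """SF expression monotonically coupled to the PSI of target events.

    log-expression = a + b x PSI_sample + Normal(0, sf_coupling_noise)
    with alternating slope sign per SF. With zero noise the SF-PSI
    Spearman correlation of each planted pair is exactly +/-1.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(6)[5])
    sf_ids = list(sf_ids)
    if existing_gene_ids is not None:
        clash = set(sf_ids) & set(existing_gene_ids)
        if clash:
            raise ValueError(f"SF ids collide with existing gene ids: {sorted(clash)}")
    rows = {}
    for k, sf in enumerate(sf_ids):
        targets = target_events.get(sf, [])
        if not targets:
            psi = rng.uniform(0.2, 0.8, size=psi_samples.shape[1])  # uncoupled SF
        else:
            psi = psi_samples.loc[targets].mean(axis=0).to_numpy()
        b = slope if k % 2 == 0 else -slope
        noise = rng.normal(0.0, config.sf_coupling_noise, size=len(psi))
        rows[sf] = np.exp(intercept + b * psi + noise)
    return pd.DataFrame(rows, index=psi_samples.columns).T


# ---------------------------------------------------------------------------
# the full dataset


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genes: list[GeneModel]
    events: pd.DataFrame                # catalogue with lengths and cassette coords
    event_counts: pd.DataFrame          # long junction-count table
    gene_counts: pd.DataFrame           # gene x sample (SF rows included)
    gene_lengths: pd.Series
    bins: pd.DataFrame
    ip_counts: pd.DataFrame
    input_counts: pd.DataFrame
    sf_ids: list[str]
    sf_expression: pd.DataFrame
    truth: SyntheticTruth

    @property
    def design(self) -> pd.Series:
        return self.config.design

    def write(self, outdir) -> None:
        from . import io as msio

        msio.write_dataset(self, Path(outdir))


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a complete synthetic study with planted truth."""
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_models = np.random.default_rng(streams[0])
    rng_psi = np.random.default_rng(streams[1])
    rng_counts = np.random.default_rng(streams[2])
    rng_expr = np.random.default_rng(streams[3])
    rng_merip = np.random.default_rng(streams[4])
    rng_sf = np.random.default_rng(streams[5])

    genes, truth_events = generate_gene_models(config, rng_models)
    events = event_table(truth_events, config)

    true_psi, das_events, das_signs = _plant_psi(truth_events, config, rng_psi)
    psi_samples = _psi_per_sample(true_psi, config, rng_psi)
    event_counts = simulate_event_counts(events, psi_samples, config, rng_counts)

    gene_lengths = pd.Series(
        {g.gene_id: g.exon_union_length() for g in genes}, name="length"
    ).sort_index()
    gene_counts, libfac, de_genes, de_signs = simulate_expression(
        gene_lengths, config, rng_expr
    )

    bins = tile_gene_bins(genes, config.bin_width)
    planted, m6a_genes = plant_peaks(genes, events, das_events, das_signs, config, rng_merip)
    ip_counts, input_counts = simulate_merip(bins, planted, config, rng_merip)

    sf_ids = [f"SF{k + 1:03d}" for k in range(config.n_sf)]
    das_sorted = sorted(das_events)
    targets = {
        sf: [das_sorted[k % len(das_sorted)]] if das_sorted else []
        for k, sf in enumerate(sf_ids)
    }
    sf_expr = simulate_sf_coupling(
        sf_ids, targets, psi_samples, config, rng_sf,
        existing_gene_ids=gene_lengths.index,
    )
    # append SFs to the count matrix so they flow through FPKM like genes
    sf_len = 1500
    sf_counts = (
        sf_expr.to_numpy() * (sf_len / 1e3) * libfac.to_numpy()[None, :]
    ).round().astype(int)
    sf_counts = pd.DataFrame(sf_counts, index=sf_expr.index, columns=sf_expr.columns)
    gene_counts = pd.concat([gene_counts, sf_counts])
    gene_lengths = pd.concat(
        [gene_lengths, pd.Series(sf_len, index=sf_ids, name="length")]
    )

    truth = SyntheticTruth(
        true_psi=true_psi,
        psi_samples=psi_samples,
        das_events=das_events,
        das_signs=das_signs,
        dm_peaks=planted,
        sf_targets=targets,
        de_genes=de_genes,
        de_signs=de_signs,
        events=truth_events,
        m6a_genes=m6a_genes,
    )
    return SimulatedDataset(
        config=config,
        genes=genes,
        events=events,
        event_counts=event_counts,
        gene_counts=gene_counts,
        gene_lengths=gene_lengths,
        bins=bins,
        ip_counts=ip_counts,
        input_counts=input_counts,
        sf_ids=sf_ids,
        sf_expression=sf_expr,
        truth=truth,
    )


def simulate_knockdown_das(
    dataset: SimulatedDataset,
    shared_fraction: float = 0.5,
    n_extra: int = 10,
    seed_offset: int = 1,
) -> tuple[pd.DataFrame, set[str]]:
    """A methyltransferase-knockdown SE-DAS table sharing part of the
    tissue truth.

    A fraction of the tissue's planted DAS skipped exons is perturbed in
    the knockdown too (the planted intersection); extra SE events outside
    the tissue DAS set model knockdown-specific splicing changes.
    Returns (knockdown event table, planted shared event-id set).
    """
    derived = int(
        np.random.SeedSequence([dataset.config.seed, seed_offset]).generate_state(1)[0]
        % (2**31)
    )
    rng = np.random.default_rng(derived)
    das = sorted(dataset.truth.das_events)
    n_shared = int(round(shared_fraction * len(das)))
    shared = sorted(rng.choice(das, size=n_shared, replace=False)) if n_shared else []
    se_pool = dataset.events[dataset.events["event_type"] == "SE"].index
    extra_pool = sorted(set(se_pool) - set(das))
    n_extra = min(n_extra, len(extra_pool))
    extra = sorted(rng.choice(extra_pool, size=n_extra, replace=False)) if n_extra else []
    kd = dataset.events.loc[shared + extra, ["gene_id", "cassette_start", "cassette_end", "strand"]].copy()
    return kd, set(shared)
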