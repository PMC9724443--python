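"""Alternative-splicing event classification from gene models.

A gene model is a set of transcripts, each an ordered list of exon
intervals. Comparing transcripts pairwise yields the five classic AS event
types:

* **SE** — skipped (cassette) exon: an internal exon of one transcript is
  absent from another transcript that splices directly from the same
  upstream donor to the same downstream acceptor.
* **A5SS / A3SS** — alternative 5'/3' splice site: two transcripts share
  one boundary of an exon but use a different donor (5') or acceptor (3')
  site; the 5'/3' label is strand-aware.
* **MXE** — mutually exclusive exons: two non-overlapping internal exons,
  each flanked by the same splice junctions, that never co-occur in a
  transcript of the gene.
* **RI** — retained intron: one transcript's single exon spans two exons
  of another transcript plus the intervening intron.

All coordinates are 0-based half-open throughout this module; GTF's
1-based closed convention is converted at the I/O boundary.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Iterable, Mapping, Sequence

Interval = tuple[int, int]

EVENT_TYPES = ("SE", "A5SS", "A3SS", "MXE", "RI")


class InvalidGeneModelError(ValueError):
    """Raised when a gene model violates exon-geometry invariants."""


@dataclass(frozen=True)
class GeneModel:
    """A gene with its transcripts as ordered exon interval lists."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[tuple[Interval, ...], ...]
    transcript_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.transcript_ids:
            object.__setattr__(
                self,
                "transcript_ids",
                tuple(f"{self.gene_id}.t{i + 1}" for i in range(len(self.transcripts))),
            )

    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise InvalidGeneModelError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.transcripts:
            raise InvalidGeneModelError(f"{self.gene_id}: gene has no transcripts")
        for tid, tx in zip(self.transcript_ids, self.transcripts):
            if not tx:
                raise InvalidGeneModelError(f"{self.gene_id}/{tid}: transcript has no exons")
            for start, end in tx:
                if start >= end:
                    raise InvalidGeneModelError(
                        f"{self.gene_id}/{tid}: empty or inverted exon ({start}, {end})"
                    )
            for (s0, e0), (s1, e1) in zip(tx, tx[1:]):
                if e0 >= s1:
                    raise InvalidGeneModelError(
                        f"{self.gene_id}/{tid}: exons ({s0},{e0}) and ({s1},{e1}) "
                        "overlap or touch; transcript exons must be strictly increasing"
                    )

    @property
    def span(self) -> Interval:
        start = min(tx[0][0] for tx in self.transcripts)
        end = max(tx[-1][1] for tx in self.transcripts)
        return start, end

    def exon_union_length(self) -> int:
        """Total length of the union of all exons across transcripts."""
        ivs = sorted(iv for tx in self.transcripts for iv in tx)
        total = 0
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
        return total


@dataclass(frozen=True)
class ASEvent:
    """A typed alternative-splicing event.

    ``exons`` is role-ordered per type:

    * SE:   (upstream, cassette, downstream)
    * MXE:  (upstream, exon_a, exon_b, downstream) with exon_a left of exon_b
    * A5SS/A3SS: (long_exon, short_exon, flanking_exon)
    * RI:   (upstream_exon, retained_intron, downstream_exon)
    """

    event_type: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]

    @property
    def event_id(self) -> str:
        coords = "|".join(f"{s}-{e}" for s, e in self.exons)
        return f"{self.event_type}:{self.gene_id}:{self.chrom}:{self.strand}:{coords}"

    @property
    def cassette(self) -> Interval:
        """The alternative region: cassette exon (SE), retained intron (RI),
        the exclusive pair span's first exon (MXE), or the alternative
        extension (A5SS/A3SS)."""
        if self.event_type == "SE":
            return self.exons[1]
        if self.event_type == "RI":
            return self.exons[1]
        if self.event_type == "MXE":
            return self.exons[1]
        # alt splice sites: the region between short and long boundaries
        long_exon, short_exon, _ = self.exons
        if long_exon[0] == short_exon[0]:
            return (short_exon[1], long_exon[1])
        return (long_exon[0], short_exon[0])


def classify_as_events(gene: GeneModel) -> list[ASEvent]:
    """Enumerate AS events from all pairwise transcript comparisons.

    Duplicate events (same type, coordinates and strand) are emitted once;
    the output order is deterministic (sorted by type then coordinates).
    MXE candidates are suppressed if any transcript of the gene contains
    both exclusive exons (they must never co-occur).
    """
    gene.validate()
    found: set[ASEvent] = set()
    txs = gene.transcripts
    for a in txs:
        for b in txs:
            if a is b:
                continue
            _find_se(gene, a, b, found)
            _find_ri(gene, a, b, found)
            _find_alt_ss(gene, a, b, found)
    for i in range(len(txs)):
        for j in range(i + 1, len(txs)):
            _find_mxe(gene, txs[i], txs[j], found)
    # never-co-occurring rule for MXE, checked gene-wide
    all_tx_sets = [set(tx) for tx in txs]
    events = [
        ev
        for ev in found
        if not (
            ev.event_type == "MXE"
            and any(ev.exons[1] in t and ev.exons[2] in t for t in all_tx_sets)
        )
    ]
    return sorted(events, key=lambda e: (e.event_type, e.exons))


def _find_se(gene: GeneModel, a: Sequence[Interval], b: Sequence[Interval], out: set) -> None:
    b_junctions = {(x[1], y[0]) for x, y in zip(b, b[1:])}
    for i in range(1, len(a) - 1):
        up, cas, dn = a[i - 1], a[i], a[i + 1]
        if (up[1], dn[0]) in b_junctions and cas not in b:
            out.add(ASEvent("SE", gene.gene_id, gene.chrom, gene.strand, (up, cas, dn)))


def _find_ri(gene: GeneModel, a: Sequence[Interval], b: Sequence[Interval], out: set) -> None:
    # intron between consecutive exons of `a` retained inside one exon of `b`
    b_exons = set(b)
    for x, y in zip(a, a[1:]):
        if (x[0], y[1]) in b_exons:
            out.add(
                ASEvent(
                    "RI", gene.gene_id, gene.chrom, gene.strand, (x, (x[1], y[0]), y)
                )
            )


def _find_alt_ss(gene: GeneModel, a: Sequence[Interval], b: Sequence[Interval], out: set) -> None:
    for ia in range(len(a) - 1):
        ea, da = a[ia], a[ia + 1]
        for ib in range(len(b) - 1):
            eb, db = b[ib], b[ib + 1]
            # donor-side variation (genomic right end of the upstream exon)
            if ea[0] == eb[0] and ea[1] != eb[1] and da[0] == db[0] and ea != da:
                long_exon, short_exon = (ea, eb) if ea[1] > eb[1] else (eb, ea)
                flank = da if long_exon is ea else db
                etype = "A5SS" if gene.strand == "+" else "A3SS"
                out.add(
                    ASEvent(
                        etype, gene.gene_id, gene.chrom, gene.strand,
                        (long_exon, short_exon, flank),
                    )
                )
            # acceptor-side variation (genomic left start of the downstream exon)
            if da[1] == db[1] and da[0] != db[0] and ea[1] == eb[1]:
                long_exon, short_exon = (da, db) if da[0] < db[0] else (db, da)
                flank = ea if long_exon is da else eb
                etype = "A3SS" if gene.strand == "+" else "A5SS"
                out.add(
                    ASEvent(
                        etype, gene.gene_id, gene.chrom, gene.strand,
                        (long_exon, short_exon, flank),
                    )
                )


def _find_mxe(gene: GeneModel, a: Sequence[Interval], b: Sequence[Interval], out: set) -> None:
    for i in range(1, len(a) - 1):
        for j in range(1, len(b) - 1):
            ex_a, ex_b = a[i], b[j]
            if ex_a == ex_b or not (ex_a[1] <= ex_b[0] or ex_b[1] <= ex_a[0]):
                continue  # identical or overlapping: not mutually exclusive
            if a[i - 1][1] != b[j - 1][1] or a[i + 1][0] != b[j + 1][0]:
                continue  # flanking junctions not shared
            if ex_a in b or ex_b in a:
                continue
            first, second = sorted((ex_a, ex_b))
            up = a[i - 1] if a[i - 1][1] <= b[j - 1][1] else b[j - 1]
            dn = a[i + 1] if a[i + 1][0] >= b[j + 1][0] else b[j + 1]
            # flank choice is deterministic: shared junction coordinates matter,
            # distal flank boundaries come from whichever transcript is tighter
            out.add(
                ASEvent("MXE", gene.gene_id, gene.chrom, gene.strand, (up, first, second, dn))
            )


# ---------------------------------------------------------------------------
# catalogue bookkeeping


@dataclass
class EventCatalogueSummary:
    """Per-type event counts, parent-gene counts and per-gene multisets."""

    per_type_counts: dict[str, int] = field(default_factory=dict)
    per_type_gene_counts: dict[str, int] = field(default_factory=dict)
    per_gene_types: dict[str, Counter] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.per_type_counts.values())

    @property
    def multi_event_genes(self) -> list[str]:
        """Genes carrying two or more AS events."""
        return sorted(g for g, c in self.per_gene_types.items() if sum(c.values()) >= 2)


def count_events_per_gene(events: Iterable[ASEvent]) -> EventCatalogueSummary:
    summary = EventCatalogueSummary(
        per_type_counts={t: 0 for t in EVENT_TYPES},
        per_type_gene_counts={},
        per_gene_types={},
    )
    genes_per_type: dict[str, set[str]] = {t: set() for t in EVENT_TYPES}
    for ev in events:
        summary.per_type_counts[ev.event_type] = summary.per_type_counts.get(ev.event_type, 0) + 1
        genes_per_type.setdefault(ev.event_type, set()).add(ev.gene_id)
        summary.per_gene_types.setdefault(ev.gene_id, Counter())[ev.event_type] += 1
    summary.per_type_gene_counts = {t: len(g) for t, g in genes_per_type.items()}
    return summary


def round_percentage(part: int | float, total: int | float, ndigits: int = 2) -> float:
    """100*part/total rounded to ``ndigits`` decimals, round half to even."""
    q = Decimal(1).scaleb(-ndigits)
    pct = Decimal(part) * 100 / Decimal(total)
    return float(pct.quantize(q, rounding=ROUND_HALF_EVEN))


def summarize_event_catalogue(per_type_counts: Mapping[str, int]) -> dict:
    """Totals and per-type percentages (two decimals, round half to even).

    Raises ``ValueError`` on all-zero counts (percentages undefined) or a
    negative count.
    """
    counts = {t: int(per_type_counts.get(t, 0)) for t in EVENT_TYPES}
    if any(c < 0 for c in counts.values()):
        raise ValueError("event counts must be non-negative")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("all event counts are zero; percentages undefined")
    return {
        "total": total,
        "per_type_counts": counts,
        "per_type_percent": {t: round_percentage(c, total) for t, c in counts.items()},
        "se_ri_percent": round_percentage(counts["SE"] + counts["RI"], total),
    }
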