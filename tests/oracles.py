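"""Independent brute-force oracles used to validate the implementation.

Each oracle is a direct, unoptimised transcription of the defining rule,
kept deliberately separate from the library code paths it checks.
"""

from __future__ import annotations

from fractions import Fraction


def naive_bh(pvalues):
    """Naive Benjamini-Hochberg step-up straight from the definition:
    padj_i = min(1, min over {j : p_j >= p_i} of m * p_j / rank(p_j)),
    rank(p_j) = #{k : p_k <= p_j}. Quadratic on purpose."""
    m = len(pvalues)
    padj = []
    for i in range(m):
        candidates = []
        for j in range(m):
            if pvalues[j] >= pvalues[i]:
                rank = sum(1 for k in range(m) if pvalues[k] <= pvalues[j])
                candidates.append(m * pvalues[j] / rank)
        padj.append(min(1.0, min(candidates)))
    return padj


def midranks(values):
    n = len(values)
    ranks = [0.0] * n
    for i, v in enumerate(values):
        smaller = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        ranks[i] = smaller + (equal + 1) / 2.0
    return ranks


def spearman_rank_formula(x, y):
    """Pearson correlation of mid-ranks, evaluated with exact rationals."""
    rx = [Fraction(r).limit_denominator() for r in midranks(x)]
    ry = [Fraction(r).limit_denominator() for r in midranks(y)]
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return float(cov) / (float(vx) ** 0.5 * float(vy) ** 0.5)


def brute_rrach_positions(seq):
    """Scan for RRACH (R=A/G, H=A/C/U) with explicit per-position checks."""
    seq = seq.upper().replace("U", "T")
    hits = []
    for i in range(len(seq) - 4):
        a, b, c, d, e = seq[i : i + 5]
        if a in "AG" and b in "AG" and c == "A" and d == "C" and e in "ACT":
            hits.append(i)
    return hits


def brute_overlaps(peaks, features, flank):
    """All-pairs half-open interval overlap with the flank rule.

    ``peaks``/``features``: dicts id -> (chrom, start, end). Returns
    {(peak_id, feature_id): (overlap_bp, relation)}.
    """
    out = {}
    for pid, (pc, ps, pe) in peaks.items():
        for fid, (fc, fs, fe) in features.items():
            if pc != fc:
                continue
            ov = min(pe, fe) - max(ps, fs)
            if ov > 0:
                rel = "within-exon" if ps >= fs and pe <= fe else "spans-boundary"
                out[(pid, fid)] = (ov, rel)
            else:
                gap = max(fs - pe, ps - fe)
                if gap <= flank and (ps < fe + flank and pe > fs - flank):
                    out[(pid, fid)] = (0, "flanking-1kb")
    return out


def enumerate_as_events(gene):
    """Exhaustive evaluation of the five AS definitions over transcript pairs.

    Returns a set of (event_type, exons_tuple) pairs; coordinates follow
    the role ordering SE=(up, cassette, down), RI=(up, intron, down),
    A5SS/A3SS=(long, short, flank), MXE=(up, first, second, down).
    """
    found = set()
    txs = [list(t) for t in gene.transcripts]
    plus = gene.strand == "+"

    for A in txs:
        for B in txs:
            if A == B:
                continue
            # skipped exon: internal exon of A absent from B, whose flanking
            # junction (up_end -> down_start) is an intron of B
            for i in range(1, len(A) - 1):
                up, cas, dn = A[i - 1], A[i], A[i + 1]
                if cas in B:
                    continue
                for j in range(len(B) - 1):
                    if B[j][1] == up[1] and B[j + 1][0] == dn[0]:
                        found.add(("SE", (tuple(up), tuple(cas), tuple(dn))))
            # retained intron: consecutive exons of A merged into one exon of B
            for i in range(len(A) - 1):
                x, y = A[i], A[i + 1]
                if (x[0], y[1]) in [tuple(e) for e in B]:
                    found.add(("RI", (tuple(x), (x[1], y[0]), tuple(y))))
            # alternative donor / acceptor
            for i in range(len(A) - 1):
                for j in range(len(B) - 1):
                    ea, da = A[i], A[i + 1]
                    eb, db = B[j], B[j + 1]
                    if ea[0] == eb[0] and ea[1] != eb[1] and da[0] == db[0]:
                        lng, shrt = (ea, eb) if ea[1] > eb[1] else (eb, ea)
                        flank = da if lng == ea else db
                        label = "A5SS" if plus else "A3SS"
                        found.add((label, (tuple(lng), tuple(shrt), tuple(flank))))
                    if da[1] == db[1] and da[0] != db[0] and ea[1] == eb[1]:
                        lng, shrt = (da, db) if da[0] < db[0] else (db, da)
                        flank = ea if lng == da else eb
                        label = "A3SS" if plus else "A5SS"
                        found.add((label, (tuple(lng), tuple(shrt), tuple(flank))))

    # mutually exclusive exons over unordered pairs, then the gene-wide
    # never-co-occur rule
    for ai in range(len(txs)):
        for bi in range(ai + 1, len(txs)):
            A, B = txs[ai], txs[bi]
            for i in range(1, len(A) - 1):
                for j in range(1, len(B) - 1):
                    xa, xb = A[i], B[j]
                    if tuple(xa) == tuple(xb):
                        continue
                    if not (xa[1] <= xb[0] or xb[1] <= xa[0]):
                        continue
                    if A[i - 1][1] != B[j - 1][1] or A[i + 1][0] != B[j + 1][0]:
                        continue
                    if xa in B or xb in A:
                        continue
                    first, second = sorted([tuple(xa), tuple(xb)])
                    up = A[i - 1] if A[i - 1][1] <= B[j - 1][1] else B[j - 1]
                    dn = A[i + 1] if A[i + 1][0] >= B[j + 1][0] else B[j + 1]
                    cooccur = any(
                        list(first) in t and list(second) in t
                        or (tuple(first) in [tuple(e) for e in t] and tuple(second) in [tuple(e) for e in t])
                        for t in txs
                    )
                    if not cooccur:
                        found.add(("MXE", (tuple(up), first, second, tuple(dn))))
    return found
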