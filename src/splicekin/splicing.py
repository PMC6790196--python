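"""Spliced alignment of clone transcripts and splice-event classification.

A transcript is aligned to its gene model by exact unique k-mer anchoring
extended across substitution mismatches (clone errors and allelic SNPs are
substitutions only), producing a chain of blocks whose genomic gaps are the
introns the spliceosome removed. Each gap is then compared with the annotated
exon chain and classified by mechanism: exon skipping (single or multiple),
alternative 3'/5' splice sites, partial intron retention, full intron
retention, cryptic exon inclusion, and the paired exon-internal
alternative-3'SS/5'SS deletion class.

Junction placement follows the standard spliced-alignment ambiguity rule:
when identical bases flank both ends of a gap, the gap is shifted maximally
5'-ward — unless some equivalent placement lands on annotated splice sites,
which is always preferred.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import GeneModel, TranscriptSeq, translate_and_scan

__all__ = [
    "AlignmentError",
    "Block",
    "BlockChain",
    "SpliceEvent",
    "IsoformConsequence",
    "align_transcript",
    "classify_events",
    "predict_consequence",
    "classify_transcript",
    "tally_events",
    "canonicalize_gap",
]

MECHANISMS = (
    "exon_skip",
    "multi_exon_skip",
    "alt3ss",
    "alt5ss",
    "alt3ss_alt5ss",
    "intron_retention",
    "partial_intron_retention",
    "cryptic_exon",
)


class AlignmentError(ValueError):
    """Transcript could not be aligned to the gene model."""


@dataclass(frozen=True)
class Block:
    """One gap-free aligned block; coordinates 0-based half-open."""

    gs: int  # genomic start
    ge: int  # genomic end
    ts: int  # transcript start
    te: int  # transcript end
    mismatches: int = 0

    def __post_init__(self):
        if self.ge - self.gs != self.te - self.ts or self.ge <= self.gs:
            raise ValueError("malformed block")

    @property
    def diag(self) -> int:
        return self.gs - self.ts


@dataclass(frozen=True)
class BlockChain:
    gene_id: str
    blocks: tuple[Block, ...]
    transcript_len: int

    def __post_init__(self):
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b.ts != a.te:
                raise ValueError("transcript gap between blocks")
            if b.gs <= a.ge:
                raise ValueError("blocks not increasing in genomic coordinates")

    @property
    def gaps(self) -> tuple[tuple[int, int], ...]:
        return tuple((a.ge, b.gs) for a, b in zip(self.blocks, self.blocks[1:]))


@dataclass(frozen=True)
class SpliceEvent:
    """A classified deviation from the constitutive exon chain."""

    mechanism: str
    affected: tuple[int, ...]        # exon indices (skip/cryptic) or intron index
    gap: tuple[int, int]             # genomic coordinates of the deviant gap/block
    shift_nt: int | None             # signed offset from the annotated site
    delta_len: int                   # net transcript-length change vs constitutive

    def __post_init__(self):
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")

    @property
    def key(self) -> tuple:
        return (self.mechanism, self.gap[0], self.gap[1])


@dataclass(frozen=True)
class IsoformConsequence:
    in_frame: bool
    premature_stop: bool
    domains_retained: frozenset
    soluble: bool
    product_expected: bool
    delta_len: int
    first_stop_codon: int | None = None

    def __post_init__(self):
        if self.product_expected == self.premature_stop:
            raise ValueError("product_expected must equal NOT premature_stop")


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def _kmer_index(seq: str, k: int) -> dict[str, int]:
    index: dict[str, int] = {}
    dup = set()
    for pos in range(len(seq) - k + 1):
        km = seq[pos : pos + k]
        if km in index or km in dup:
            dup.add(km)
            index.pop(km, None)
        else:
            index[km] = pos
    return index


class GeneIndex:
    """Reusable unique-k-mer index of one gene's genomic sequence."""

    def __init__(self, model: GeneModel, k: int = 15):
        self.model = model
        self.k = k
        self.index = _kmer_index(model.genomic_seq, k)


def _seed_runs(seq: str, index: dict[str, int], k: int) -> list[list[int]]:
    """Maximal runs of consecutive co-diagonal anchor hits as raw blocks
    [ts, te, gs, ge] of exact matches."""
    runs = []
    cur = None
    for i in range(len(seq) - k + 1):
        g = index.get(seq[i : i + k])
        if g is None:
            continue
        if cur is not None and i == cur[1] - k + 1 and g - i == cur[2] - cur[0]:
            cur[1] = i + k
            cur[3] = g + k
        else:
            if cur is not None:
                runs.append(cur)
            cur = [i, i + k, g, g + k]
    if cur is not None:
        runs.append(cur)
    return runs


def _chain(runs: list[list[int]], k: int) -> list[list[int]]:
    """Highest-coverage chain of runs, increasing in both coordinate systems
    with non-decreasing diagonal (substitution-only error model).

    Junction ambiguity makes neighbouring runs overlap by a few bases (a
    junction-spanning k-mer can match both flanks), so overlaps up to k-1 are
    tolerated and trimmed from the later run's front.
    """
    if not runs:
        return []
    runs = sorted(runs, key=lambda r: (r[0], r[2]))
    n = len(runs)
    best = [0.0] * n
    prev = [-1] * n
    for i in range(n):
        ti, te, gi, ge = runs[i]
        best[i] = float(te - ti)
        for j in range(i):
            tj, tej, gj, gej = runs[j]
            overlap = max(0, tej - ti)
            if overlap >= k:
                continue
            if gej - gj != tej - tj:  # defensive
                continue
            if gi - ti < gj - tj:  # diagonal must not decrease
                continue
            if gi + overlap < gej:
                continue
            cand = best[j] + (te - max(ti, tej))
            if cand > best[i]:
                best[i] = cand
                prev[i] = j
    i = max(range(n), key=lambda x: best[x])
    chain = []
    while i != -1:
        chain.append(runs[i][:])
        i = prev[i]
    chain.reverse()
    # trim overlaps from the later run
    out = [chain[0]]
    for r in chain[1:]:
        a = out[-1]
        cut = max(0, a[1] - r[0])
        r[0] += cut
        r[2] += cut
        if r[1] > r[0]:
            out.append(r)
    return out


def _count_mismatch(s: str, g: str, toff: int, goff: int, n: int) -> int:
    return sum(1 for x in range(n) if s[toff + x] != g[goff + x])


def align_transcript(
    t: TranscriptSeq,
    model: GeneModel | GeneIndex,
    k: int = 15,
    min_anchor_frac: float = 0.8,
    max_mismatch_frac: float = 0.1,
) -> BlockChain:
    """Anchor, chain, rescue and junction-resolve one transcript.

    Raises :class:`AlignmentError` when fewer than ``min_anchor_frac`` of the
    transcript bases are anchored/rescued (wrong gene) or when a residual
    segment cannot be placed (unalignable segment).
    """
    gi = model if isinstance(model, GeneIndex) else GeneIndex(model, k)
    model = gi.model
    g = model.genomic_seq
    s = t.seq
    runs = _chain(_seed_runs(s, gi.index, gi.k), gi.k)
    if not runs:
        raise AlignmentError(f"{t.clone_id}: no anchors on {model.gene_id} (wrong gene?)")

    # merge co-diagonal neighbours across substitution runs
    merged = [runs[0][:]]
    for r in runs[1:]:
        a = merged[-1]
        if r[2] - r[0] == a[2] - a[0]:
            span = r[0] - a[1]
            mm = _count_mismatch(s, g, a[1], a[3], span)
            if mm <= max(1, int(max_mismatch_frac * (r[1] - a[0]))):
                a[1], a[3] = r[1], r[3]
                continue
        merged.append(r[:])

    # rescue unanchored internal segments (e.g. an error/SNP in a very short
    # exon kills all its anchors); boundaries are refined afterwards
    rescued = True
    while rescued:
        rescued = False
        out = [merged[0]]
        for r in merged[1:]:
            a = out[-1]
            tlo, thi = a[1], r[0]
            glo, ghi = a[3], r[2]
            seg = thi - tlo
            if seg >= 10 and ghi - glo > seg:
                best_mm, best_off = None, None
                for off in range(glo, ghi - seg + 1):
                    mm = _count_mismatch(s, g, tlo, off, seg)
                    if best_mm is None or mm < best_mm:
                        best_mm, best_off = mm, off
                if best_mm is not None and best_mm <= max(2, int(0.2 * seg)):
                    out.append([tlo, thi, best_off, best_off + seg])
                    rescued = True
            out.append(r)
        merged = out

    anchored = sum(r[1] - r[0] for r in merged)
    if anchored < min_anchor_frac * len(s):
        raise AlignmentError(
            f"{t.clone_id}: only {anchored}/{len(s)} bases anchored on {model.gene_id}"
        )

    # extend outermost blocks to transcript ends
    first = merged[0]
    d0 = first[2] - first[0]
    if first[0] > 0:
        if d0 < 0:
            raise AlignmentError(f"{t.clone_id}: transcript overhangs gene start")
        first[2] -= first[0]
        first[0] = 0
    last = merged[-1]
    dN = last[2] - last[0]
    tail = len(s) - last[1]
    if tail:
        if last[3] + tail > len(g):
            raise AlignmentError(f"{t.clone_id}: transcript overhangs gene end")
        last[1] = len(s)
        last[3] = last[1] + dN

    # resolve junctions between consecutive blocks of different diagonals;
    # the split point may sit a little inside either block (pad), so sloppy
    # rescue boundaries are corrected here
    donors = {e: i for i, (_, e) in enumerate(model.exons[:-1])}
    acceptors = {sx: i + 1 for i, (sx, _) in enumerate(model.exons[1:])}
    pad = gi.k + 1
    blocks: list[Block] = []
    cur = merged[0][:]
    for r in merged[1:]:
        if r[2] - r[0] == cur[2] - cur[0]:  # same diagonal: merge (residual)
            cur[1], cur[3] = r[1], r[3]
            continue
        dA = cur[2] - cur[0]
        dB = r[2] - r[0]
        lo = max(cur[0] + 1, cur[1] - pad)
        hi = min(r[1] - 1, r[0] + pad)
        if lo > hi:
            raise AlignmentError(f"{t.clone_id}: blocks collapsed at {cur[1]}")
        # prefix mismatch counts over the evaluation region for both diagonals
        span = hi - lo
        mmA_pre = [0] * (span + 1)
        mmB_pre = [0] * (span + 1)
        for x in range(span):
            mmA_pre[x + 1] = mmA_pre[x] + (s[lo + x] != g[lo + x + dA])
            mmB_pre[x + 1] = mmB_pre[x] + (s[lo + x] != g[lo + x + dB])
        scored = [
            (mmA_pre[x] + (mmB_pre[span] - mmB_pre[x]), lo + x)
            for x in range(span + 1)
        ]
        best_mm = min(x[0] for x in scored)
        gap_len = cur[1] <= r[0] and r[0] - cur[1] or 0
        if best_mm > max(2, int(max_mismatch_frac * max(gap_len, span))):
            raise AlignmentError(f"{t.clone_id}: unalignable segment at {lo}-{hi}")

        # a placement using both annotated sites may absorb one extra
        # mismatch (a sequencing error at the junction base must not fake a
        # 1-nt-shifted novel junction); ties resolve 5'-most
        def placement_rank(item):
            mm, tstar = item
            annot = (tstar + dA in donors) + (tstar + dB in acceptors)
            adj = mm - 1 if annot == 2 else mm
            return (max(adj, best_mm), -annot, tstar)

        _, tstar = min(
            ((mm, ts) for mm, ts in scored if mm <= best_mm + 1),
            key=placement_rank,
        )
        mmA = _count_mismatch(s, g, cur[0], cur[0] + dA, tstar - cur[0])
        blocks.append(Block(cur[0] + dA, tstar + dA, cur[0], tstar, mmA))
        cur = [tstar, r[1], tstar + dB, r[3]]
    mmA = _count_mismatch(s, g, cur[0], cur[2], cur[1] - cur[0])
    blocks.append(Block(cur[2], cur[3], cur[0], cur[1], mmA))
    return BlockChain(model.gene_id, tuple(blocks), len(s))


def canonicalize_gap(
    genomic: str,
    gs: int,
    ge: int,
    donors: dict[int, int] | None = None,
    acceptors: dict[int, int] | None = None,
) -> tuple[int, int]:
    """Canonical placement of an intron-like gap among its equivalents.

    All placements ``(gs+s, ge+s)`` yielding an identical spliced sequence are
    equivalent. A placement whose boundaries coincide with annotated sites is
    preferred (most annotated sites first); otherwise the 5'-most placement.
    """
    left = 0
    while gs - left - 1 >= 0 and genomic[gs - left - 1] == genomic[ge - left - 1]:
        left += 1
    right = 0
    while ge + right < len(genomic) and genomic[gs + right] == genomic[ge + right]:
        right += 1
    donors = donors or {}
    acceptors = acceptors or {}

    def rank(sft):
        annot = (gs + sft in donors) + (ge + sft in acceptors)
        return (-annot, sft)

    shift = min(range(-left, right + 1), key=rank)
    return gs + shift, ge + shift


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _locate(model: GeneModel, pos: int):
    """('exon'|'intron', index) of a genomic position; boundaries resolve to
    the interval starting at the position."""
    for i, (sx, e) in enumerate(model.exons):
        if sx <= pos < e:
            return ("exon", i)
    for i, (sx, e) in enumerate(model.introns):
        if sx <= pos < e:
            return ("intron", i)
    raise ValueError(f"position {pos} outside gene body")


def classify_events(chain: BlockChain, model: GeneModel) -> list[SpliceEvent]:
    """Classify every deviation of an aligned transcript from the annotated
    exon chain. A constitutive transcript yields an empty list."""
    donors = {e: i for i, (_, e) in enumerate(model.exons[:-1])}
    acceptors = {sx: i + 1 for i, (sx, _) in enumerate(model.exons[1:])}
    introns = set(model.introns)
    g = model.genomic_seq
    events: list[SpliceEvent] = []
    cryptic_flanks: set[int] = set()

    # intron retention / cryptic exon: inspect blocks themselves
    for b in chain.blocks:
        inside = [
            i for i, (sx, e) in enumerate(model.introns) if b.gs <= sx and e <= b.ge
        ]
        for i in inside:
            sx, e = model.introns[i]
            if b.gs < sx and e < b.ge:
                events.append(
                    SpliceEvent("intron_retention", (i,), (sx, e), None, e - sx)
                )
        loc_s = _locate(model, b.gs)
        if loc_s[0] == "intron" and not inside:
            loc_e = _locate(model, b.ge - 1)
            if loc_e == loc_s:
                events.append(
                    SpliceEvent("cryptic_exon", (loc_s[1],), (b.gs, b.ge), None, b.ge - b.gs)
                )
                cryptic_flanks.update((b.gs, b.ge))

    for gs, ge in chain.gaps:
        gs, ge = canonicalize_gap(g, gs, ge, donors, acceptors)
        if (gs, ge) in introns:
            continue
        don_ok = gs in donors
        acc_ok = ge in acceptors
        if don_ok and acc_ok:
            i, j = donors[gs], acceptors[ge]
            skipped = tuple(range(i + 1, j))
            if not skipped:
                continue  # annotated intron (already excluded) — defensive
            name = "exon_skip" if len(skipped) == 1 else "multi_exon_skip"
            delta = -sum(model.exons[x][1] - model.exons[x][0] for x in skipped)
            events.append(SpliceEvent(name, skipped, (gs, ge), None, delta))
            continue
        loc_s = _locate(model, gs) if not don_ok else ("donor", donors[gs])
        loc_e = _locate(model, ge) if not acc_ok else ("acceptor", acceptors[ge])
        if loc_s[0] == "exon" and loc_e[0] == "exon" and loc_s[1] == loc_e[1]:
            events.append(
                SpliceEvent("alt3ss_alt5ss", (loc_s[1],), (gs, ge), None, -(ge - gs))
            )
            continue
        # complete exons removed inside the gap count as skipping
        skipped = tuple(
            x
            for x, (sx, e) in enumerate(model.exons)
            if gs <= sx and e <= ge and (gs < sx or ge > e)
        )
        if skipped:
            dsk = -sum(model.exons[x][1] - model.exons[x][0] for x in skipped)
            name = "exon_skip" if len(skipped) == 1 else "multi_exon_skip"
            events.append(SpliceEvent(name, skipped, (gs, ge), None, dsk))
        if not don_ok and gs not in cryptic_flanks:
            if loc_s[0] == "exon":
                i = loc_s[1]
                shift = gs - model.exons[i][1]
                events.append(SpliceEvent("alt5ss", (i,), (gs, ge), shift, shift))
            else:  # donor inside an intron: 5' part of that intron retained
                i = loc_s[1]
                shift = gs - model.exons[i][1]
                events.append(
                    SpliceEvent("partial_intron_retention", (i,), (gs, ge), shift, shift)
                )
        if not acc_ok and ge not in cryptic_flanks:
            if loc_e[0] == "exon":
                j = loc_e[1]
                shift = ge - model.exons[j][0]
                events.append(SpliceEvent("alt3ss", (j,), (gs, ge), shift, -shift))
            else:  # acceptor inside an intron: 3' part of that intron retained
                j = loc_e[1]
                shift = ge - model.exons[j + 1][0]
                events.append(
                    SpliceEvent("partial_intron_retention", (j,), (gs, ge), shift, -shift)
                )
    return events


# ---------------------------------------------------------------------------
# Protein consequence
# ---------------------------------------------------------------------------

def _isoform_coverage(model: GeneModel, events) -> list[tuple[int, int]]:
    """Genomic coverage of the isoform implied by a set of events."""
    marks = []
    for sx, e in model.exons:
        marks.append((sx, 1))
        marks.append((e, -1))
    for ev in events:
        if ev.mechanism in ("intron_retention", "cryptic_exon"):
            marks.append((ev.gap[0], 1))
            marks.append((ev.gap[1], -1))
        else:
            marks.append((ev.gap[0], -1))
            marks.append((ev.gap[1], 1))
    marks.sort()
    out = []
    depth = 0
    start = None
    for pos, d in marks:
        prev = depth
        depth += d
        if prev <= 0 and depth > 0:
            start = pos
        elif prev > 0 and depth <= 0 and start is not None and pos > start:
            out.append((start, pos))
            start = None
    return out


def predict_consequence(events, model: GeneModel) -> IsoformConsequence:
    """Predicted protein outcome of an event combination.

    The isoform CDS is rebuilt from the gene sequence (clone errors play no
    role), translated, and scanned for a premature stop. An isoform is
    in-frame iff the summed length change is 0 mod 3; it is soluble when it
    is intact and the transmembrane exon is absent.
    """
    events = list(events)
    cover = _isoform_coverage(model, events)
    iso = "".join(model.genomic_seq[sx:e] for sx, e in cover)
    # map CDS start into isoform coordinates
    off = 0
    cds_iso = None
    for sx, e in cover:
        if sx <= model.cds_start < e:
            cds_iso = off + model.cds_start - sx
            break
        off += e - sx
    delta = sum(ev.delta_len for ev in events)
    in_frame = delta % 3 == 0
    if cds_iso is None:
        # start codon spliced away: no product
        return IsoformConsequence(
            in_frame, True, frozenset(), False, False, delta, None
        )
    # the expected terminal codon shifts with in-frame length changes; for
    # frameshifts any stop ahead of further complete codons is premature
    expected = model.cds_codons + delta // 3 if (in_frame and model.cds_codons) else None
    res = translate_and_scan(iso, cds_iso, expected)
    stop_iso_end = (
        cds_iso + 3 * res.first_stop_codon_index if res.first_stop_codon_index else len(iso)
    )
    retained = []
    off = 0
    cover_iso = []
    for sx, e in cover:
        cover_iso.append((sx, e, off))
        off += e - sx
    for idx, (sx, e) in enumerate(model.exons):
        present = any(cs <= sx and e <= ce for cs, ce, _ in cover_iso)
        if not present:
            continue
        iso_end = next(o + (e - cs) for cs, ce, o in cover_iso if cs <= sx and e <= ce)
        if res.premature and iso_end > stop_iso_end:
            continue
        retained.append(idx)
    labels = frozenset(
        model.domain_labels.get(i, "other") for i in retained
    )
    tm_present = any(model.domain_labels.get(i) == "TM" for i in retained)
    soluble = (not tm_present) and in_frame and not res.premature
    return IsoformConsequence(
        in_frame=in_frame,
        premature_stop=res.premature,
        domains_retained=labels,
        soluble=soluble,
        product_expected=not res.premature,
        delta_len=delta,
        first_stop_codon=res.first_stop_codon_index,
    )


def classify_transcript(t: TranscriptSeq, model: GeneModel | GeneIndex):
    """Convenience: align then classify; returns (chain, events)."""
    chain = align_transcript(t, model)
    gm = model.model if isinstance(model, GeneIndex) else model
    return chain, classify_events(chain, gm)


# ---------------------------------------------------------------------------
# Tally
# ---------------------------------------------------------------------------

def tally_events(per_clone_events, min_count: int = 4) -> pd.DataFrame:
    """Pool identical event combinations across clones and animals.

    ``per_clone_events`` is an iterable of ``(clone_id, gene_id, events)``
    where ``events`` is the clone's event list (possibly empty). Events
    co-occurring in one clone form a single compound key. A combination is
    categorized when seen at least ``min_count`` times (the more-than-three
    rule).
    """
    rows: dict[tuple, dict] = {}
    for clone_id, gene_id, events in per_clone_events:
        if not events:
            continue
        keys = tuple(sorted(ev.key for ev in events))
        mechs = "+".join(k[0] for k in keys)
        r = rows.setdefault(
            (gene_id, keys),
            {"gene": gene_id, "events": keys, "mechanism": mechs, "count": 0, "clones": []},
        )
        r["count"] += 1
        r["clones"].append(clone_id)
    records = sorted(rows.values(), key=lambda r: (-r["count"], r["gene"], str(r["events"])))
    df = pd.DataFrame(
        records, columns=["gene", "events", "mechanism", "count", "clones"]
    )
    if len(df):
        df["categorized"] = df["count"] >= min_count
    else:
        df["categorized"] = pd.Series(dtype=bool)
    return df
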