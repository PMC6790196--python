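"""Spliced alignment, event classification, consequences and tallies."""

import pytest

from splicekin.cohort import DEL_LEN, TM_EXON
from splicekin.model import TranscriptSeq
from splicekin.splicing import (
    AlignmentError,
    SpliceEvent,
    align_transcript,
    canonicalize_gap,
    classify_events,
    classify_transcript,
    predict_consequence,
    tally_events,
)


def transcript(model, intervals, clone_id="t"):
    seq = "".join(model.genomic_seq[s:e] for s, e in intervals)
    return TranscriptSeq(clone_id, seq, "A", "A|g|b1")


@pytest.fixture(scope="module")
def gene1(cohort0):
    return cohort0[1]["gene1"]


@pytest.fixture(scope="module")
def scaffold1(cohort0):
    return cohort0[3].scaffolds["gene1"]


class TestAlignTranscript:
    def test_constitutive_one_block_per_exon(self, gene1):
        chain = align_transcript(transcript(gene1, gene1.exons), gene1)
        assert len(chain.blocks) == gene1.n_exons
        assert chain.gaps == gene1.introns
        assert all(b.mismatches == 0 for b in chain.blocks)

    def test_exon_skip_gap_spans_flanking_introns(self, gene1):
        e = gene1.exons
        iv = [x for i, x in enumerate(e) if i != TM_EXON]
        chain = align_transcript(transcript(gene1, iv), gene1)
        gaps = set(chain.gaps)
        assert (e[TM_EXON - 1][1], e[TM_EXON + 1][0]) in gaps

    def test_internal_deletion_splits_exon(self, gene1, scaffold1):
        """A 112-nt exon-internal deletion yields two blocks with a 112-nt
        genomic gap and zero transcript gap."""
        ds, de = scaffold1.del_window
        e = list(gene1.exons)
        ex2 = e[1]
        iv = e[:1] + [(ex2[0], ds), (de, ex2[1])] + e[2:]
        chain = align_transcript(transcript(gene1, iv), gene1)
        gaps = [(gs, ge) for gs, ge in chain.gaps if (gs, ge) not in set(gene1.introns)]
        assert len(gaps) == 1
        gs, ge = gaps[0]
        assert ge - gs == DEL_LEN == 112

    def test_wrong_gene_raises(self, cohort0):
        _, models, _, _, _ = cohort0
        t = transcript(models["gene2"], models["gene2"].exons)
        with pytest.raises(AlignmentError):
            align_transcript(t, models["gene1"])

    def test_substitutions_tolerated_inside_blocks(self, gene1):
        t = transcript(gene1, gene1.exons)
        s = list(t.seq)
        for pos in (200, 700, 1200):
            s[pos] = "A" if s[pos] != "A" else "C"
        chain = align_transcript(
            TranscriptSeq("m", "".join(s), "A", "A|g|b1"), gene1
        )
        assert sum(b.mismatches for b in chain.blocks) == 3
        assert chain.gaps == gene1.introns


class TestClassifyEvents:
    def test_constitutive_empty(self, gene1):
        chain = align_transcript(transcript(gene1, gene1.exons), gene1)
        assert classify_events(chain, gene1) == []

    def test_single_exon_skip(self, gene1):
        iv = [x for i, x in enumerate(gene1.exons) if i != TM_EXON]
        _, events = classify_transcript(transcript(gene1, iv), gene1)
        (ev,) = events
        assert ev.mechanism == "exon_skip"
        assert ev.affected == (TM_EXON,)
        tm_len = gene1.exons[TM_EXON][1] - gene1.exons[TM_EXON][0]
        assert ev.delta_len == -tm_len

    def test_multi_exon_skip(self, gene1):
        """Skipping exons 3–5 (indices 2–4) is one multi-exon event."""
        iv = [x for i, x in enumerate(gene1.exons) if i not in (2, 3, 4)]
        _, events = classify_transcript(transcript(gene1, iv), gene1)
        (ev,) = events
        assert ev.mechanism == "multi_exon_skip"
        assert ev.affected == (2, 3, 4)

    def test_paired_exonic_deletion(self, gene1, scaffold1):
        ds, de = scaffold1.del_window
        e = list(gene1.exons)
        iv = e[:1] + [(e[1][0], ds), (de, e[1][1])] + e[2:]
        _, events = classify_transcript(transcript(gene1, iv), gene1)
        (ev,) = events
        assert ev.mechanism == "alt3ss_alt5ss"
        assert ev.affected == (1,)
        assert ev.delta_len == -112
        want = canonicalize_gap(gene1.genomic_seq, ds, de)
        assert ev.gap == want

    def test_alt3ss_truncation(self, gene1):
        e = list(gene1.exons)
        iv = e[:2] + [(e[2][0] + 5, e[2][1])] + e[3:]
        _, events = classify_transcript(transcript(gene1, iv), gene1)
        (ev,) = events
        assert ev.mechanism == "alt3ss"
        assert ev.shift_nt == 5
        assert ev.delta_len == -5

    def test_alt5ss_truncation(self, gene1):
        e = list(gene1.exons)
        iv = e[:2] + [(e[2][0], e[2][1] - 4)] + e[3:]
        _, events = classify_transcript(transcript(gene1, iv), gene1)
        (ev,) = events
        assert ev.mechanism == "alt5ss"
        assert ev.shift_nt == -4
        assert ev.delta_len == -4

    def test_partial_intron_retention(self, gene1):
        e = list(gene1.exons)
        iv = e[:2] + [(e[2][0], e[2][1] + 7)] + e[3:]
        _, events = classify_transcript(transcript(gene1, iv), gene1)
        (ev,) = events
        assert ev.mechanism == "partial_intron_retention"
        assert ev.delta_len == 7

    def test_full_intron_retention(self, gene1):
        e = list(gene1.exons)
        iv = e[:4] + [(e[4][0], e[5][1])] + e[6:]
        _, events = classify_transcript(transcript(gene1, iv), gene1)
        (ev,) = events
        assert ev.mechanism == "intron_retention"
        assert ev.affected == (4,)
        assert ev.delta_len == e[5][0] - e[4][1]

    def test_cryptic_exon_inclusion(self, gene1):
        intron2 = gene1.introns[2]
        block = (intron2[0] + 60, intron2[0] + 90)
        e = list(gene1.exons)
        iv = e[:3] + [block] + e[3:]
        _, events = classify_transcript(transcript(gene1, iv), gene1)
        mechs = sorted(ev.mechanism for ev in events)
        assert "cryptic_exon" in mechs
        ev = next(ev for ev in events if ev.mechanism == "cryptic_exon")
        assert ev.delta_len == 30


class TestPredictConsequence:
    def test_tm_skip_yields_soluble_isoform(self, gene1):
        iv = [x for i, x in enumerate(gene1.exons) if i != TM_EXON]
        _, events = classify_transcript(transcript(gene1, iv), gene1)
        cons = predict_consequence(events, gene1)
        assert cons.in_frame
        assert not cons.premature_stop
        assert cons.product_expected
        assert "TM" not in cons.domains_retained
        assert cons.soluble

    def test_frameshift_deletion_kills_product(self, gene1, scaffold1):
        """112 ≡ 1 (mod 3): out of frame, premature stop, no product."""
        ds, de = scaffold1.del_window
        e = list(gene1.exons)
        iv = e[:1] + [(e[1][0], ds), (de, e[1][1])] + e[2:]
        _, events = classify_transcript(transcript(gene1, iv), gene1)
        cons = predict_consequence(events, gene1)
        assert not cons.in_frame
        assert cons.premature_stop
        assert not cons.product_expected
        assert not cons.soluble

    def test_no_events_keeps_all_domains(self, gene1):
        cons = predict_consequence([], gene1)
        assert cons.in_frame and not cons.premature_stop
        assert cons.domains_retained == frozenset(
            {"other", "IgV", "IgC", "TM", "heptad", "B30.2"}
        )
        assert not cons.soluble  # TM present

    def test_frame_flag_matches_length_arithmetic(self, cohort0, classified0):
        """in_frame ⇔ observed length change ≡ 0 mod 3, for every simulated
        isoform class in the cohort."""
        _, models, _, truth, _ = cohort0
        const_len = {g: len(models[g].mrna()) for g in truth.gene_order}
        seen = set()
        for clone, chain, events in classified0:
            if not events:
                continue
            key = (clone.gene_hint, tuple(sorted(e.key for e in events)))
            if key in seen:
                continue
            seen.add(key)
            cons = predict_consequence(events, models[clone.gene_hint])
            delta = len(clone.seq) - const_len[clone.gene_hint]
            assert cons.delta_len == delta
            assert cons.in_frame == (delta % 3 == 0)
        assert seen


class TestTally:
    def _ev(self, gap=(100, 200)):
        return SpliceEvent("exon_skip", (1,), gap, None, -50)

    def test_min_count_threshold(self):
        rows3 = [(f"c{i}", "g", [self._ev()]) for i in range(3)]
        assert not tally_events(rows3)["categorized"].any()
        rows4 = rows3 + [("c3", "g", [self._ev()])]
        assert tally_events(rows4)["categorized"].all()

    def test_empty_input_empty_table(self):
        df = tally_events([])
        assert len(df) == 0

    def test_constitutive_clones_not_tallied(self):
        df = tally_events([("c0", "g", []), ("c1", "g", [self._ev()])])
        assert len(df) == 1
        assert df.iloc[0]["count"] == 1

    def test_cooccurring_events_form_compound_key(self):
        both = [self._ev(), SpliceEvent("alt3ss_alt5ss", (1,), (10, 20), None, -10)]
        df = tally_events([("c0", "g", both), ("c1", "g", [self._ev()])])
        assert len(df) == 2
        assert set(df["mechanism"]) == {"alt3ss_alt5ss+exon_skip", "exon_skip"}

    def test_raising_min_count_never_adds_categorized(self, classified0):
        rows = [(c.clone_id, c.gene_hint, ev) for c, _, ev in classified0]
        prev = None
        for mc in (1, 2, 4, 8, 16):
            cat = set(
                map(tuple, tally_events(rows, min_count=mc)
                    .loc[lambda d: d["categorized"], ["gene", "mechanism"]]
                    .itertuples(index=False))
            )
            if prev is not None:
                assert cat <= prev
            prev = cat
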