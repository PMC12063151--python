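import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncpipe.genomics import AnnotationSet, GenomicInterval, TranscriptRecord, reverse_complement
from lncpipe.triplex import (
    CONTEXT_CLASSES,
    Tract,
    TriplexParams,
    assign_interaction_context,
    classify_genome_context,
    find_tracts,
    interaction_pairs,
    match_triplexes,
    promoter_window,
    scan_genome,
)
from oracles import (
    oracle_genome_context,
    oracle_matches,
    oracle_tfo_tracts,
    oracle_tts_tracts,
)

PARAMS = TriplexParams()


def tx(tid, chrom, start, end, strand, gene=None, biotype="coding", exons=None):
    iv = GenomicInterval(chrom, start, end, strand)
    return TranscriptRecord(tid, gene or tid, iv, exons or [iv], biotype)


class TestParams:
    def test_invalid_error_rate(self):
        with pytest.raises(ValueError):
            TriplexParams(max_error_rate=0.0)

    def test_min_length_floor(self):
        with pytest.raises(ValueError):
            TriplexParams(min_length=5)


class TestFindTracts:
    def test_pure_ga_repeat_is_r_motif(self):
        seq = "GA" * 10  # 20 nt
        tracts = find_tracts(seq, PARAMS, "TFO_on_rna")
        r = [t for t in tracts if t.motif == "R"]
        assert len(r) == 1
        t = r[0]
        assert (t.start, t.end, t.errors) == (0, 20, 0)
        assert t.guanine == pytest.approx(0.5)

    def test_19nt_below_min_length(self):
        seq = "G" * 19
        tracts = find_tracts(seq, PARAMS, "TFO_on_rna")
        assert tracts == []

    def test_three_consecutive_interruptions_split(self):
        # 24 purines with CCC inside: halves too short -> nothing survives
        seq = "G" * 12 + "CCC" + "G" * 12
        tts = [t for t in find_tracts(seq, PARAMS, "TTS_on_duplex") if t.motif == "+"]
        assert tts == []
        # but lengthened halves are found separately
        seq2 = "G" * 25 + "CCC" + "G" * 25
        tts2 = [t for t in find_tracts(seq2, PARAMS, "TTS_on_duplex") if t.motif == "+"]
        assert [(t.start, t.end) for t in tts2] == [(0, 25), (28, 53)]

    def test_tts_purine_on_minus_strand(self):
        seq = "C" * 30  # purine strand is the complement (G30)
        tracts = find_tracts(seq, PARAMS, "TTS_on_duplex")
        minus = [t for t in tracts if t.motif == "-"]
        assert len(minus) == 1
        assert minus[0].sequence == "G" * 30
        assert minus[0].guanine == pytest.approx(1.0)

    def test_guanine_threshold(self):
        seq = "A" * 30  # purine but zero guanine
        tracts = [t for t in find_tracts(seq, PARAMS, "TTS_on_duplex") if t.motif == "+"]
        assert tracts == []
        relaxed = TriplexParams(min_guanine=0.0)
        tracts = [t for t in find_tracts(seq, relaxed, "TTS_on_duplex") if t.motif == "+"]
        assert len(tracts) == 1

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            find_tracts("", PARAMS, "TFO_on_rna")

    @pytest.mark.parametrize("seed", range(8))
    def test_tfo_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=150, p=[0.3, 0.2, 0.3, 0.2]))
        got = find_tracts(seq, PARAMS, "TFO_on_rna")
        expected = oracle_tfo_tracts(seq, PARAMS)
        for motif in "RYM":
            mine = [(t.start, t.end, t.errors, t.guanine) for t in got if t.motif == motif]
            assert mine == [tuple(w) for w in expected[motif]], motif

    @pytest.mark.parametrize("seed", range(8))
    def test_tts_matches_bruteforce(self, seed):
        rng = np.random.default_rng(100 + seed)
        seq = "".join(rng.choice(list("ACGT"), size=150, p=[0.35, 0.15, 0.35, 0.15]))
        got = find_tracts(seq, PARAMS, "TTS_on_duplex")
        expected = oracle_tts_tracts(seq, PARAMS)
        for strand in "+-":
            mine = [(t.start, t.end, t.errors, t.guanine) for t in got if t.motif == strand]
            assert mine == [tuple(w) for w in expected[strand]], strand

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_strand_symmetry(self, seed):
        """Reverse-complementing the duplex swaps purine-strand labels but
        leaves the TTS set invariant."""
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=120, p=[0.35, 0.15, 0.35, 0.15]))
        fwd = find_tracts(seq, PARAMS, "TTS_on_duplex")
        rev = find_tracts(reverse_complement(seq), PARAMS, "TTS_on_duplex")
        n = len(seq)
        fwd_set = {(t.start, t.end, t.motif, t.errors, round(t.guanine, 9), t.sequence) for t in fwd}
        rev_set = {
            (n - t.end, n - t.start, "+" if t.motif == "-" else "-", t.errors,
             round(t.guanine, 9), t.sequence)
            for t in rev
        }
        assert fwd_set == rev_set


class TestMatchTriplexes:
    def test_identity_g_match(self):
        params = TriplexParams(merge_overlapping=False)
        tfo = Tract("lnc", 0, 20, "R", 0, 1.0, "G" * 20)
        tts = Tract("chr1", 100, 120, "+", 0, 1.0, "G" * 20)
        out = match_triplexes([tfo], [tts], params)
        assert len(out) == 1
        x = out[0]
        assert (x.tts.start, x.tts.end) == (100, 120)
        assert x.errors == 0 and x.length == 20

    def test_ga_vs_gt_no_r_match(self):
        params = TriplexParams(merge_overlapping=False)
        tfo = Tract("lnc", 0, 20, "R", 0, 0.5, "GA" * 10)
        tts = Tract("chr1", 0, 20, "+", 0, 0.5, "GT" * 10)
        # A<->T is not an R-motif pair: every 2nd position errors (50 %)
        assert match_triplexes([tfo], [tts], params) == []

    def test_empty_tfo_list(self):
        tts = Tract("chr1", 0, 20, "+", 0, 1.0, "G" * 20)
        assert match_triplexes([], [tts], PARAMS) == []

    def test_y_motif_parallel(self):
        params = TriplexParams(merge_overlapping=False)
        # TFO CT repeat pairs with GA repeat purine strand (C<->G, T<->A)
        tfo = Tract("lnc", 0, 20, "Y", 0, 0.5, "CT" * 10)
        tts = Tract("chr1", 0, 20, "+", 0, 0.5, "GA" * 10)
        out = match_triplexes([tfo], [tts], params)
        assert len(out) == 1 and out[0].errors == 0

    def test_antiparallel_coordinates(self):
        params = TriplexParams(merge_overlapping=False)
        # R motif is antiparallel: reversed TFO must equal the purine strand
        purine = "GGGGGAAAAAGGGGGAAAAA"
        tfo_seq = purine[::-1]
        tfo = Tract("lnc", 5, 25, "R", 0, 0.5, tfo_seq)
        tts = Tract("chr1", 40, 60, "+", 0, 0.5, purine)
        out = match_triplexes([tfo], [tts], params)
        assert len(out) == 1
        x = out[0]
        assert (x.tfo_start, x.tfo_end) == (5, 25)
        assert (x.tts.start, x.tts.end) == (40, 60)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(300 + seed)
        purine_rich = "".join(rng.choice(list("GACT"), size=80, p=[0.45, 0.35, 0.1, 0.1]))
        rna = "".join(rng.choice(list("GACT"), size=80, p=[0.4, 0.3, 0.15, 0.15]))
        tfos = find_tracts(rna, PARAMS, "TFO_on_rna", seq_id="rna")
        ttss = find_tracts(purine_rich, PARAMS, "TTS_on_duplex", seq_id="chr")
        got = match_triplexes(tfos, ttss, PARAMS)
        expected = []
        for tts in ttss:
            for tfo in tfos:
                for ts, te, fs, fe, e, g in oracle_matches(
                    tfo.sequence, tfo.motif, tts.sequence, PARAMS
                ):
                    # map oracle purine-strand coords to genome coords
                    if tts.motif == "-":
                        L = tts.end - tts.start
                        gs, ge = tts.start + (L - te), tts.start + (L - ts)
                    else:
                        gs, ge = tts.start + ts, tts.start + te
                    expected.append(
                        (tfo.seq_id, tfo.start + fs, tfo.start + fe, tfo.motif,
                         gs, ge, e, round(g, 9))
                    )
        mine = [
            (x.lnc_id, x.tfo_start, x.tfo_end, x.motif, x.tts.start, x.tts.end,
             x.errors, round(x.guanine, 9))
            for x in got
        ]
        assert sorted(mine) == sorted(expected)

    def test_reported_matches_satisfy_constraints(self, dataset, pipeline_result):
        """Re-validate every reported interaction against the parameter
        contract using raw sequences."""
        from lncpipe.genomics import extract_transcript_sequence
        from oracles import PAIRING, ANTIPARALLEL

        params = TriplexParams()
        lncs = {t.transcript_id: t for t in pipeline_result.lncs}
        for x in pipeline_result.interactions:
            assert x.length >= params.min_length
            assert x.errors / x.length <= params.max_error_rate
            assert x.guanine >= params.min_guanine
            duplex = dataset.genome[x.tts.chrom][x.tts.start : x.tts.end]
            purine = duplex if x.tts.strand == "+" else reverse_complement(duplex)
            rna = extract_transcript_sequence(lncs[x.lnc_id], dataset.genome)
            tfo = rna[x.tfo_start : x.tfo_end]
            aligned = tfo[::-1] if ANTIPARALLEL[x.motif] else tfo
            rule = PAIRING[x.motif]
            errs = [0 if rule.get(a.replace("U", "T")) == b else 1
                    for a, b in zip(aligned, purine)]
            assert len(aligned) == len(purine) == x.length
            assert sum(errs) == x.errors
            # no run longer than allowed
            run = 0
            for e in errs:
                run = run + 1 if e else 0
                assert run <= params.max_consecutive_errors
            assert sum(1 for b in purine if b == "G") / x.length == pytest.approx(x.guanine)


class TestGenomeContext:
    def _toy(self):
        ann = AnnotationSet(
            [
                tx("g1.t1", "chrT", 3000, 4000, "+", gene="g1"),
            ],
            {"chrT": 10_000},
        )
        return ann

    def test_empty_annotation_all_intergenic(self):
        ann = AnnotationSet([], {"chrT": 5000})
        cmap = classify_genome_context(ann)
        assert cmap.fractions()["intergenic"] == pytest.approx(1.0)

    def test_single_gene_matches_per_base_oracle(self):
        ann = self._toy()
        cmap = classify_genome_context(ann, (1000, 250))
        expected = oracle_genome_context(ann, (1000, 250))
        got = [CONTEXT_CLASSES[v] for v in cmap.classes["chrT"]]
        assert got == expected["chrT"]
        fr = cmap.fractions()
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-12)
        # hand numbers: promoter [2000,3250) = 1250; exon [3250,4000) = 750
        assert fr["promoter"] == pytest.approx(1250 / 10_000)
        assert fr["exon"] == pytest.approx(750 / 10_000)

    def test_promoter_beats_exon(self):
        ann = AnnotationSet(
            [
                tx("g1.t1", "chrT", 3000, 4000, "+", gene="g1"),
                tx("g2.t1", "chrT", 2000, 2600, "+", gene="g2"),  # exon under g1 promoter
            ],
            {"chrT": 10_000},
        )
        cmap = classify_genome_context(ann, (1000, 250))
        assert cmap.label_at("chrT", 2500) == "promoter"

    @pytest.mark.parametrize("seed", range(6))
    def test_random_annotations_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(3000, 6000))
        transcripts = []
        for i in range(rng.integers(1, 6)):
            start = int(rng.integers(0, length - 400))
            end = int(start + rng.integers(100, 400))
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(1, 3))
            if n_ex == 1 or end - start < 150:
                exons = [GenomicInterval("c", start, end, strand)]
            else:
                mid = (start + end) // 2
                exons = [
                    GenomicInterval("c", start, mid - 20, strand),
                    GenomicInterval("c", mid + 20, end, strand),
                ]
            transcripts.append(
                TranscriptRecord(f"t{i}", f"g{i}", GenomicInterval("c", start, end, strand), exons)
            )
        ann = AnnotationSet(transcripts, {"c": length})
        cmap = classify_genome_context(ann, (500, 100))
        expected = oracle_genome_context(ann, (500, 100))
        got = [CONTEXT_CLASSES[v] for v in cmap.classes["c"]]
        assert got == expected["c"]

    def test_minus_strand_promoter_window(self):
        t = tx("t", "c", 1000, 2000, "-")
        win = promoter_window(t, 1000, 250, 10_000)
        assert (win.start, win.end) == (1750, 3000)


class TestInteractionContext:
    def _cmap(self):
        ann = AnnotationSet([tx("g1.t1", "chrT", 3000, 4000, "+", gene="g1")], {"chrT": 10_000})
        return classify_genome_context(ann, (1000, 250))

    def _interaction(self, start, end):
        from lncpipe.triplex import TriplexInteraction

        return TriplexInteraction(
            "l", 0, end - start, "R", GenomicInterval("chrT", start, end, "+"),
            end - start, 0, 0.5,
        )

    def test_promoter_beats_exon(self):
        # TTS spanning promoter tail [.., 3250) and exon
        out = assign_interaction_context([self._interaction(3200, 3300)], self._cmap())
        assert out[0].context == "promoter"

    def test_pure_intergenic(self):
        out = assign_interaction_context([self._interaction(8000, 8030)], self._cmap())
        assert out[0].context == "intergenic"

    def test_exon_beats_intron(self):
        # two-exon gene: TTS spans exon/intron boundary
        e1 = GenomicInterval("chrT", 3000, 3400, "+")
        e2 = GenomicInterval("chrT", 3700, 4000, "+")
        ann = AnnotationSet(
            [TranscriptRecord("g1.t1", "g1", GenomicInterval("chrT", 3000, 4000, "+"), [e1, e2])],
            {"chrT": 10_000},
        )
        cmap = classify_genome_context(ann, (100, 50))
        out = assign_interaction_context([self._interaction(3380, 3420)], cmap)
        assert out[0].context == "exon"

    def test_outside_genome_rejected(self):
        with pytest.raises(ValueError):
            assign_interaction_context([self._interaction(9990, 10_030)], self._cmap())


class TestInteractionPairs:
    def test_promoter_scope_dedup(self):
        from lncpipe.triplex import TriplexInteraction

        ann = AnnotationSet([tx("gA.t1", "chrT", 5000, 6000, "+", gene="gA")], {"chrT": 20_000})
        # two TTSs in gA's (1500, 250) promoter window [3500, 5250)
        xs = [
            TriplexInteraction("l1", 0, 20, "R", GenomicInterval("chrT", 4000, 4020, "+"), 20, 0, 0.5),
            TriplexInteraction("l1", 30, 50, "R", GenomicInterval("chrT", 4500, 4520, "+"), 20, 0, 0.5),
        ]
        pairs = interaction_pairs(xs, ann)
        prom = pairs["promoter"]
        assert len(prom) == 1
        assert prom.iloc[0]["n_interactions"] == 2

    def test_scope_separation(self):
        from lncpipe.triplex import TriplexInteraction

        ann = AnnotationSet([tx("gA.t1", "chrT", 5000, 6000, "+", gene="gA")], {"chrT": 20_000})
        in_exon = TriplexInteraction("l1", 0, 20, "R", GenomicInterval("chrT", 5500, 5520, "+"), 20, 0, 0.5)
        pairs = interaction_pairs([in_exon], ann)
        assert len(pairs["promoter"]) == 0
        assert len(pairs["exon"]) == 1
        assert len(pairs["gene_promoter"]) == 1

    def test_planted_sites_link_three_promoters(self, dataset, pipeline_result):
        prom = pipeline_result.pairs["promoter"]
        planted_pairs = {(p["lnc_id"], p["gene_id"]) for p in dataset.truth.planted_tts}
        got = set(zip(prom["lnc_id"], prom["gene_id"]))
        assert planted_pairs <= got


def test_planted_triplex_recovery(dataset, pipeline_result):
    for p in dataset.truth.planted_tts:
        hits = [
            x
            for x in pipeline_result.interactions
            if x.lnc_id == p["lnc_id"]
            and x.tts.chrom == p["chrom"]
            and x.tts.start < p["tts_end"]
            and p["tts_start"] < x.tts.end
        ]
        assert hits, f"planted TTS not recovered: {p}"


def test_negative_control_19nt_tract(dataset):
    """A 19-nt planted tract is not recoverable at min_length 20."""
    import copy

    from lncpipe import simulate as sim

    ds = sim.generate_genome_annotation(seed=5)
    ds = sim.plant_triplex_sites(ds, seed=5, n_sites=1, tract_length=19)
    p = ds.truth.planted_tts[0]
    lncs = AnnotationSet(
        [t for t in ds.candidates if t.transcript_id == p["lnc_id"]],
        dict(ds.candidates.chrom_lengths),
    )
    interactions = scan_genome(lncs, ds.genome, TriplexParams())
    # no recovered interaction may lie fully inside the 19-nt planted site
    for x in interactions:
        inside = x.tts.start >= p["tts_start"] and x.tts.end <= p["tts_end"]
        assert not inside
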