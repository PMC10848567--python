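"""Assembly pipeline stages: filter, demux, screen, assign, position,
consensus, validation, end-to-end composition."""

import itertools

import pytest

import museumharvest as mh
from museumharvest.assemble import (
    PipelineConfig,
    PlacedFragment,
    Read,
    assign_amplicon,
    call_consensus,
    demultiplex,
    filter_reads,
    position_fragments,
    run_pipeline,
    taxonomy_screen,
    validate_consensus,
)
from museumharvest.classify import ReferenceEntry, ReferenceLibrary
from museumharvest.panel import revcomp
from museumharvest.simulate import DegradationModel, reference_from_barcodes
from museumharvest.taxonomy import Taxonomy

CFG = PipelineConfig()

DIPTERA = Taxonomy(phylum="Arthropoda", class_="Insecta", order="Diptera",
                   family="Asilidae", genus="Laphria", species="Laphria flava")
LEP = Taxonomy(phylum="Arthropoda", class_="Insecta", order="Lepidoptera",
               family="Tineidae", genus="Tinea", species="Tinea sp1")


class TestFilterReads:
    def test_rejection_reasons(self):
        reads = [
            Read("short", "A" * 99, 40.0),
            Read("lowq", "A" * 150, 19.0),
            Read("good", "A" * 150, 20.0),
            Read("edge", "A" * 100, 40.0),
        ]
        kept, rejected = filter_reads(reads, CFG)
        assert [r.id for r in kept] == ["good", "edge"]
        assert {r.id: reason for r, reason in rejected} == {
            "short": "too_short", "lowq": "low_qv",
        }

    def test_empty_input(self):
        assert filter_reads([], CFG) == ([], [])

    def test_conservation(self):
        reads = [Read(f"r{i}", "A" * (90 + i), float(i)) for i in range(40)]
        kept, rejected = filter_reads(reads, CFG)
        assert len(kept) + len(rejected) == len(reads)


def tagged_read(tagset, panel, well, amplicon_idx, insert="T" * 50,
                f_err=0, r_err=0, rid="r0"):
    """Construct a structurally valid read for a given well/amplicon."""
    fi, ri = tagset.well_assignment[well]
    amp = panel.amplicons[amplicon_idx]

    def corrupt(tag, k):
        out = list(tag)
        for p in range(k):
            out[p] = "A" if out[p] != "A" else "C"
        return "".join(out)

    seq = (
        corrupt(tagset.forward_tags[fi], f_err) + amp.fwd.sequence + insert
        + revcomp(amp.rev.sequence) + revcomp(corrupt(tagset.reverse_tags[ri], r_err))
    )
    return Read(rid, seq, 40.0)


class TestDemultiplex:
    def test_exact_tags_assign_to_well(self, tagset, ngs_panel):
        well = mh.WellAddress("A", 1)
        read = tagged_read(tagset, ngs_panel, well, 0)
        bins, unassigned = demultiplex([read], tagset, CFG)
        assert not unassigned
        assert list(bins) == ["A01"]

    def test_one_mismatch_within_tolerance(self, tagset, ngs_panel):
        well = mh.WellAddress("B", 2)
        read = tagged_read(tagset, ngs_panel, well, 1, f_err=1, rid="m1")
        bins, unassigned = demultiplex([read], tagset, CFG)
        assert list(bins) == ["B02"]

    def test_reverse_complement_assigned(self, tagset, ngs_panel):
        well = mh.WellAddress("C", 3)
        read = tagged_read(tagset, ngs_panel, well, 2)
        flipped = Read(read.id, revcomp(read.sequence), read.mean_qv)
        bins, _ = demultiplex([flipped], tagset, CFG)
        assert list(bins) == ["C03"]

    def test_inconsistent_tag_pair_is_conflict(self, tagset, ngs_panel):
        # forward tag of A01 with reverse tag of B02: no such pairing in the
        # asymmetric scheme
        fa, _ = tagset.well_assignment[mh.WellAddress("A", 1)]
        _, rb = tagset.well_assignment[mh.WellAddress("B", 2)]
        amp = ngs_panel.amplicons[0]
        seq = (
            tagset.forward_tags[fa] + amp.fwd.sequence + "T" * 50
            + revcomp(amp.rev.sequence) + revcomp(tagset.reverse_tags[rb])
        )
        bins, unassigned = demultiplex([Read("x", seq, 40.0)], tagset, CFG)
        assert not bins
        assert unassigned[0][1] == "tag_conflict"

    def test_partition_property(self, tagset, ngs_panel):
        """Each read lands in exactly one bin or in the unassigned log."""
        bars = mh.simulate_barcodes(20, seed=21, collection_years=[2017] * 20)
        rs = mh.simulate_reads(bars, ngs_panel, tagset,
                               DegradationModel(), depth=2, seed=22)
        reads = [Read(r.id, r.sequence, r.mean_qv) for r in rs.reads]
        bins, unassigned = demultiplex(reads, tagset, CFG)
        binned = [r.id for rs_ in bins.values() for r in rs_]
        assert len(binned) == len(set(binned))
        assert len(binned) + len(unassigned) == len(reads)


@pytest.fixture(scope="module")
def screen_reference():
    import numpy as np

    rng = np.random.default_rng(30)
    dip = "".join(rng.choice(list("ACGT"), size=658))
    lep = "".join(rng.choice(list("ACGT"), size=658))
    return ReferenceLibrary([
        ReferenceEntry("dip1", dip, DIPTERA),
        ReferenceEntry("lep1", lep, LEP),
    ])


class TestTaxonomyScreen:

    def test_matching_order_kept(self, screen_reference):
        read = Read("ok", screen_reference.entries[0].sequence[100:300], 40.0)
        kept, discarded = taxonomy_screen([read], "Diptera", screen_reference, CFG)
        assert [r.id for r in kept] == ["ok"]

    def test_wrong_order_discarded(self, screen_reference):
        read = Read("moth", screen_reference.entries[1].sequence[100:300], 40.0)
        kept, discarded = taxonomy_screen([read], "Diptera", screen_reference, CFG)
        assert not kept
        assert discarded[0][1] == "wrong_order"

    def test_random_sequence_unclassifiable(self, screen_reference):
        import numpy as np

        rng = np.random.default_rng(31)
        read = Read("junk", "".join(rng.choice(list("ACGT"), size=200)), 40.0)
        kept, discarded = taxonomy_screen([read], "Diptera", screen_reference, CFG)
        assert not kept
        assert discarded[0][1] == "unclassifiable"

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError):
            taxonomy_screen([], "Diptera", ReferenceLibrary([]), CFG)


class TestAssignAmplicon:
    def test_forward_and_reverse_orientation(self, tagset, ngs_panel):
        well = mh.WellAddress("A", 1)
        read = tagged_read(tagset, ngs_panel, well, 2)
        hit = assign_amplicon(read, ngs_panel, CFG)
        assert (hit.amplicon_id, hit.orientation) == ("ngs_tiled_a3", "forward")
        flipped = Read("f", revcomp(read.sequence), 40.0)
        hit2 = assign_amplicon(flipped, ngs_panel, CFG)
        assert (hit2.amplicon_id, hit2.orientation) == ("ngs_tiled_a3", "reverse")

    def test_equally_matched_pairs_are_ambiguous(self, ngs_panel):
        a1, a2 = ngs_panel.amplicons[0], ngs_panel.amplicons[1]
        seq = (
            a1.fwd.sequence + "T" * 30 + revcomp(a1.rev.sequence)
            + a2.fwd.sequence + "G" * 30 + revcomp(a2.rev.sequence)
        )
        assert assign_amplicon(Read("amb", seq, 40.0), ngs_panel, CFG) is None

    def test_primerless_read_unassigned(self, ngs_panel):
        assert assign_amplicon(Read("none", "A" * 200, 40.0), ngs_panel, CFG) is None


class TestPositionFragments:
    def test_anchor_and_orientation(self, tagset, ngs_panel):
        amp = ngs_panel.amplicons[2]  # interval [220, 340)
        insert = "ACGT" * 30
        read = tagged_read(tagset, ngs_panel, mh.WellAddress("A", 1), 2, insert=insert)
        hit = assign_amplicon(read, ngs_panel, CFG)
        placed, dropped = position_fragments([(read, "S1", hit)], ngs_panel)
        frag = placed[0]
        assert (frag.frame_start, frag.frame_end) == (amp.start, amp.start + 120)
        assert frag.sequence == insert

        flipped = Read("f", revcomp(read.sequence), 40.0)
        hit2 = assign_amplicon(flipped, ngs_panel, CFG)
        placed2, _ = position_fragments([(flipped, "S1", hit2)], ngs_panel)
        assert placed2[0].sequence == insert  # normalised to frame strand

    def test_deletion_shortens_coverage(self, tagset, ngs_panel):
        amp = ngs_panel.amplicons[2]
        insert = ("ACGT" * 30)[:118]  # 2-bp deletion
        read = tagged_read(tagset, ngs_panel, mh.WellAddress("A", 1), 2, insert=insert)
        hit = assign_amplicon(read, ngs_panel, CFG)
        placed, _ = position_fragments([(read, "S1", hit)], ngs_panel)
        assert placed[0].frame_start == amp.start
        assert placed[0].frame_end == amp.start + 118

    def test_empty_insert_dropped(self, tagset, ngs_panel):
        read = tagged_read(tagset, ngs_panel, mh.WellAddress("A", 1), 0, insert="")
        hit = assign_amplicon(read, ngs_panel, CFG)
        placed, dropped = position_fragments([(read, "S1", hit)], ngs_panel)
        assert not placed
        assert dropped[0][1] == "empty_after_trim"


def frag(seq, start, sample="S1", aid="a", rid="r"):
    return PlacedFragment(rid, sample, aid, seq, start, start + len(seq))


class TestCallConsensus:
    def test_n_fill_between_fragments(self, ngs_panel):
        frags = [frag("A" * 100, 0), frag("C" * 100, 200)]
        bc = call_consensus(frags, ngs_panel, CFG)
        assert len(bc.sequence) == 300
        assert bc.sequence == "A" * 100 + "N" * 100 + "C" * 100
        assert bc.n_positions == set(range(100, 200))

    def test_single_fragment_identity(self, ngs_panel):
        frags = [frag("ACGTACGT" * 10, 50)]
        bc = call_consensus(frags, ngs_panel, CFG)
        assert bc.sequence == "ACGTACGT" * 10
        assert bc.frame_start == 50

    def test_majority_and_tie_rules(self, ngs_panel):
        frags = [frag("AA", 0), frag("AG", 0), frag("GG", 0, rid="r3")]
        # column 0: {A,A,G} -> A; column 1: {A,G,G} -> G
        bc = call_consensus(frags, ngs_panel, CFG)
        assert bc.sequence == "AG"
        bc2 = call_consensus([frag("A", 0), frag("G", 0)], ngs_panel, CFG)
        assert bc2.sequence == "N"

    def test_column_enumeration_oracle(self, ngs_panel):
        """All <=3-read single-column compositions match the majority
        oracle: strict plurality wins, anything else is N."""

        def oracle(bases):
            counts = {b: bases.count(b) for b in set(bases)}
            top = max(counts.values())
            winners = [b for b, c in counts.items() if c == top]
            return winners[0] if len(winners) == 1 else "N"

        for n in (1, 2, 3):
            for combo in itertools.product("ACGT", repeat=n):
                frags = [frag(b, 0, rid=f"r{i}") for i, b in enumerate(combo)]
                bc = call_consensus(frags, ngs_panel, CFG)
                assert bc.sequence == oracle(list(combo)), combo

    def test_no_reads_flag(self, ngs_panel):
        bc = call_consensus([], ngs_panel, CFG)
        assert bc.sequence == ""
        assert bc.flags == {"no_reads"}

    def test_short_flag(self, ngs_panel):
        bc = call_consensus([frag("A" * 100, 0)], ngs_panel, CFG)
        assert "short" in bc.flags
        bc2 = call_consensus([frag("A" * 301, 0)], ngs_panel, CFG)
        assert "short" not in bc2.flags

    def test_min_depth_masks_singletons(self, ngs_panel):
        cfg = PipelineConfig(consensus_min_depth=2)
        frags = [frag("AAAA", 0), frag("AA", 0)]
        bc = call_consensus(frags, ngs_panel, cfg)
        assert bc.sequence == "AA"  # columns 2-3 fall below depth 2


class TestValidateConsensus:
    def test_clean_consensus_unflagged(self, noiseless_run):
        result = noiseless_run["result"]
        flagged = [s for s, b in result.consensus.items() if "contaminated" in b.flags]
        assert flagged == []

    def test_contaminated_consensus_flagged(self, ngs_panel, noiseless_run):
        from museumharvest.assemble import ConsensusBarcode

        reference = noiseless_run["reference"]
        # a "Diptera" specimen whose consensus copies the Lepidoptera decoy
        decoy = next(e for e in reference if e.taxonomy.order == "Lepidoptera")
        bc = ConsensusBarcode("CCDB-90001-A01", decoy.sequence)
        flags = validate_consensus(bc, "Diptera", reference)
        assert "contaminated" in flags

    def test_all_n_consensus_skips_validation(self, ngs_panel, noiseless_run):
        from museumharvest.assemble import ConsensusBarcode

        bc = ConsensusBarcode("CCDB-90001-A02", "N" * 300)
        flags = validate_consensus(bc, "Diptera", noiseless_run["reference"])
        assert "no_reads" in flags and "contaminated" not in flags


class TestRunPipeline:
    def test_noiseless_end_to_end_identity(self, noiseless_run):
        result = noiseless_run["result"]
        for bc in noiseless_run["barcodes"]:
            got = result.consensus[str(bc.sample_id)]
            assert got.sequence == bc.sequence
            assert got.frame_start == 0
            assert "N" not in got.sequence

    def test_stage_conservation(self, noiseless_run):
        rep = noiseless_run["result"].report
        assert rep.n_input == rep.n_filtered + sum(
            rep.rejections[k] for k in ("too_short", "low_qv")
        )
        assert rep.n_filtered == rep.n_demuxed + sum(
            rep.rejections[k] for k in ("no_tag", "tag_conflict")
        )

    def test_empty_input_flags_all_no_reads(self, noiseless_run, ngs_panel, tagset):
        result = run_pipeline([], noiseless_run["plate"], ngs_panel, tagset,
                              noiseless_run["reference"])
        assert len(result.consensus) == 95
        assert all("no_reads" in b.flags for b in result.consensus.values())

    def test_majority_vote_beats_read_error_rate(self, ngs_panel, tagset):
        """At 1% per-base error and depth 5, the per-column consensus error
        rate falls below the read error rate."""
        e = 0.01
        bars = mh.simulate_barcodes(30, seed=55, collection_years=[2017] * 30)
        plates = mh.barcodes_to_plates(bars)
        ref = reference_from_barcodes(bars)
        model = DegradationModel(base_error_rate=e, indel_rate=0.0)
        rs = mh.simulate_reads(bars, ngs_panel, tagset, model, depth=5, seed=56)
        reads = [Read(r.id, r.sequence, r.mean_qv) for r in rs.reads]
        result = run_pipeline(reads, plates[0], ngs_panel, tagset, ref)
        errors = called = 0
        for bc in bars:
            got = result.consensus[str(bc.sample_id)]
            for i, b in enumerate(got.sequence):
                if b == "N":
                    continue
                called += 1
                errors += b != bc.sequence[got.frame_start + i]
        assert called > 10_000
        assert errors / called < e

    def test_dropped_amplicon_leaves_private_gap(self, ngs_panel, tagset):
        """Removing one amplicon's reads leaves N exactly over the interval
        covered by no other amplicon (set arithmetic on panel intervals)."""
        bars = mh.simulate_barcodes(5, seed=33, collection_years=[2017] * 5)
        plates = mh.barcodes_to_plates(bars)
        ref = reference_from_barcodes(bars)
        model = DegradationModel(base_error_rate=0.0, indel_rate=0.0)
        rs = mh.simulate_reads(bars, ngs_panel, tagset, model, depth=1, seed=34)
        dropped_amp = ngs_panel.amplicons[2]
        reads = [
            Read(r.id, r.sequence, r.mean_qv) for r in rs.reads
            if rs.truth[r.id][1] != dropped_amp.id
        ]
        result = run_pipeline(reads, plates[0], ngs_panel, tagset, ref)
        others = {a.id for a in ngs_panel.amplicons} - {dropped_amp.id}
        private = set(range(*dropped_amp.interval)) - ngs_panel.covered_positions(others)
        assert private  # the middle amplicons do have private columns
        for bc in bars:
            got = result.consensus[str(bc.sample_id)]
            assert got.n_positions == private
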