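"""Tiled-amplicon barcode assembly: filter, demultiplex, screen, assign,
position and call consensus.

The pipeline mirrors the six steps used to turn short high-accuracy amplicon
reads into contiguous COI barcodes:

i.   quality/length filter (mean QV >= 20, length >= 100 bp by default);
ii.  demultiplex to source specimens via the terminal UMI tag pair;
iii. order-level taxonomy screen against a reference library, discarding
     reads that do not match the specimen's expected order;
iv.  amplicon assignment via locus-specific primers (both strands);
v.   alignment-free positioning: each trimmed fragment is anchored at its
     amplicon's known start coordinate on the 658-bp barcode frame — no
     pairwise alignment anywhere;
vi.  per-column majority consensus; uncovered columns strictly inside the
     covered span are filled with N so the final sequence is contiguous.

Fragments are anchored without realignment, so a fragment carrying a
deletion simply covers fewer columns; this keeps the positioning strictly
alignment-free at the cost of some per-column error when indel rates are
high (a documented trade-off).
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np
from Bio import SeqIO

from .classify import DistanceUndefinedError, ReferenceLibrary, p_distance
from .panel import IUPAC_EXPAND, AmpliconPanel, TagSet, revcomp
from .plate import PlateArray, format_sample_id

_EQUALITIES = [
    (code, base) for code, bases in IUPAC_EXPAND.items() if len(bases) > 1
    for base in bases
]


@dataclass(frozen=True)
class Read:
    id: str
    sequence: str
    mean_qv: float

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PlacedFragment:
    read_id: str
    sample_id: str
    amplicon_id: str
    sequence: str  # oriented to the barcode-frame strand, primers/tags removed
    frame_start: int
    frame_end: int


@dataclass
class ConsensusBarcode:
    sample_id: str
    sequence: str  # over {A,C,G,T,N}, spanning first..last covered column
    frame_start: int = 0
    coverage: list[int] = field(default_factory=list)  # per frame column
    flags: set[str] = field(default_factory=set)

    @property
    def nonN_length(self) -> int:
        return sum(1 for b in self.sequence if b != "N")

    @property
    def n_positions(self) -> set[int]:
        """Frame coordinates of N columns inside the covered span."""
        return {self.frame_start + i for i, b in enumerate(self.sequence) if b == "N"}


@dataclass
class PipelineConfig:
    """Numeric thresholds of the assembly pipeline (defaults follow the
    published protocol: QV 20, 100 bp, 99% predicted accuracy, >300 bp
    barcode compliance)."""

    min_qv: float = 20.0
    min_read_length: int = 100
    min_predicted_accuracy: float = 0.99
    umi_tolerance: int = 1
    order_filter_max_distance: float = 0.25
    primer_mismatch_fraction: float = 0.10
    consensus_min_depth: int = 1
    acceptable_barcode_bp: int = 301  # non-N bases; ">300 bp"

    def __post_init__(self) -> None:
        if self.min_qv < 0 or self.min_read_length < 0 or self.umi_tolerance < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0 < self.min_predicted_accuracy <= 1:
            raise ValueError("min_predicted_accuracy must be in (0, 1]")
        if self.consensus_min_depth < 1:
            raise ValueError("consensus_min_depth must be >= 1")


# ---------------------------------------------------------------------------
# step i: quality filter

def filter_reads(reads: list[Read], cfg: PipelineConfig) -> tuple[list[Read], list[tuple[Read, str]]]:
    """Keep reads with mean QV >= min_qv and length >= min_read_length;
    the rejection log records one reason per dropped read (length first)."""
    kept, rejected = [], []
    for r in reads:
        if r.length < cfg.min_read_length:
            rejected.append((r, "too_short"))
        elif r.mean_qv < cfg.min_qv:
            rejected.append((r, "low_qv"))
        else:
            kept.append(r)
    return kept, rejected


# ---------------------------------------------------------------------------
# step ii: UMI demultiplexing

def _decode_strand(seq: str, tags: TagSet, tol: int) -> tuple[int, int] | None:
    k = tags.tag_length
    if len(seq) < 2 * k:
        return None
    fi = tags.decode(seq[:k], "forward", tol)
    ri = tags.decode(revcomp(seq[-k:]), "reverse", tol)
    if fi is None or ri is None:
        return None
    return fi, ri


def demultiplex(
    reads: list[Read],
    tags: TagSet,
    cfg: PipelineConfig,
    plate: PlateArray | None = None,
) -> tuple[dict[str, list[Read]], list[tuple[Read, str]]]:
    """Partition reads into per-sample bins via their terminal tag pair.

    Both strands are tried; a read is assigned iff exactly one strand yields
    a tag pair present in the well assignment.  Keys are sample IDs when a
    plate is given, else well addresses.  Every read lands in exactly one
    bin or in the unassigned log.
    """
    assigned: dict[str, list[Read]] = {}
    unassigned: list[tuple[Read, str]] = []
    for r in reads:
        candidates = []
        decoded_any = False
        for seq in (r.sequence, revcomp(r.sequence)):
            pair = _decode_strand(seq, tags, cfg.umi_tolerance)
            if pair is None:
                continue
            decoded_any = True
            well = tags.well_for(*pair)
            if well is not None:
                candidates.append(well)
        wells = set(candidates)
        if len(wells) == 1:
            well = wells.pop()
            key = format_sample_id(plate.plate_code, well) if plate else str(well)
            assigned.setdefault(key, []).append(r)
        elif decoded_any:
            unassigned.append((r, "tag_conflict"))
        else:
            unassigned.append((r, "no_tag"))
    return assigned, unassigned


# ---------------------------------------------------------------------------
# step iii: order-level taxonomy screen

def _nearest_by_edlib(seq: str, entries, max_fraction: float, both_strands: bool):
    """Fast nearest-candidate search: bounded edit distance (infix mode)
    against every entry, shrinking the bound as better hits appear.  Returns
    ``(oriented_sequence, entry)`` for the best hit or None when nothing
    aligns within the bound (the exact p-distance is computed by the caller
    against this single candidate)."""
    best = None
    # slack above the screen threshold: edit distance counts primer/tag
    # flanks that p-distance will exclude
    k = max(1, int(round((max_fraction + 0.12) * len(seq))))
    strands = (seq, revcomp(seq)) if both_strands else (seq,)
    for oriented in strands:
        for entry in entries:
            res = edlib.align(oriented, entry.sequence, mode="HW", k=k)
            ed = res["editDistance"]
            if ed < 0:
                continue
            if best is None or ed < best[0]:
                best = (ed, oriented, entry)
                k = max(1, ed - 1) if ed > 0 else 1
    if best is None:
        return None
    return best[1], best[2]


def taxonomy_screen(
    reads: list[Read],
    expected_order: str,
    reference: ReferenceLibrary,
    cfg: PipelineConfig,
) -> tuple[list[Read], list[tuple[Read, str]]]:
    """Keep reads whose nearest reference (p-distance, both strands) belongs
    to the expected order and lies within the screen distance."""
    if len(reference) == 0:
        raise ValueError("taxonomy screen requires a non-empty reference library")
    kept, discarded = [], []
    entries = list(reference)
    max_frac = cfg.order_filter_max_distance
    for r in reads:
        hit = _nearest_by_edlib(r.sequence, entries, max_frac, both_strands=True)
        if hit is None:
            discarded.append((r, "unclassifiable"))
            continue
        oriented, entry = hit
        try:
            d = p_distance(oriented, entry.sequence)
        except DistanceUndefinedError:
            discarded.append((r, "unclassifiable"))
            continue
        if d > cfg.order_filter_max_distance:
            discarded.append((r, "unclassifiable"))
        elif entry.taxonomy.order != expected_order:
            discarded.append((r, "wrong_order"))
        else:
            kept.append(r)
    return kept, discarded


# ---------------------------------------------------------------------------
# step iv: amplicon assignment

@dataclass(frozen=True)
class AmpliconHit:
    amplicon_id: str
    orientation: str  # "forward" | "reverse"
    score: int  # summed primer edit distances
    insert_start: int  # on the oriented sequence
    insert_end: int


def _find_primer(primer_seq: str, target: str, max_dist: int):
    res = edlib.align(primer_seq, target, mode="HW", task="locations",
                      k=max_dist, additionalEqualities=_EQUALITIES)
    if res["editDistance"] < 0:
        return None
    start, end = res["locations"][0]
    return res["editDistance"], start, end + 1  # half-open end


def _scan_strand(seq: str, panel: AmpliconPanel, cfg: PipelineConfig) -> list[AmpliconHit]:
    hits = []
    for amp in panel.amplicons:
        tol_f = int(cfg.primer_mismatch_fraction * len(amp.fwd.sequence))
        tol_r = int(cfg.primer_mismatch_fraction * len(amp.rev.sequence))
        f = _find_primer(amp.fwd.sequence, seq, tol_f)
        r = _find_primer(revcomp(amp.rev.sequence), seq, tol_r)
        if f is None or r is None:
            continue
        fd, _, f_end = f
        rd, r_start, _ = r
        if f_end > r_start:
            continue
        hits.append(AmpliconHit(amp.id, "forward", fd + rd, f_end, r_start))
    return hits


def assign_amplicon(read: Read, panel: AmpliconPanel, cfg: PipelineConfig) -> AmpliconHit | None:
    """Best fwd/rev primer pair over both strands within the mismatch
    tolerance (default 10% of primer length); ties between amplicons are
    ambiguous and return None."""
    fwd_hits = _scan_strand(read.sequence, panel, cfg)
    rev_hits = [
        AmpliconHit(h.amplicon_id, "reverse", h.score, h.insert_start, h.insert_end)
        for h in _scan_strand(revcomp(read.sequence), panel, cfg)
    ]
    hits = fwd_hits + rev_hits
    if not hits:
        return None
    best = min(h.score for h in hits)
    top = [h for h in hits if h.score == best]
    if len({h.amplicon_id for h in top}) > 1:
        return None  # ambiguous between amplicons
    # same amplicon found on both strands only happens for pathological
    # primers; prefer the forward hit deterministically
    top.sort(key=lambda h: h.orientation)
    return top[0]


# ---------------------------------------------------------------------------
# step v: alignment-free positioning

def position_fragments(
    assigned: list[tuple[Read, str, AmpliconHit]],
    panel: AmpliconPanel,
) -> tuple[list[PlacedFragment], list[tuple[Read, str]]]:
    """Trim tags/primers, orient to the frame strand and anchor each
    fragment at its amplicon's start coordinate.  No alignment is performed;
    a fragment covers ``len(fragment)`` columns from the anchor."""
    placed, dropped = [], []
    for read, sample_id, hit in assigned:
        amp = panel.get(hit.amplicon_id)
        oriented = read.sequence if hit.orientation == "forward" else revcomp(read.sequence)
        insert = oriented[hit.insert_start:hit.insert_end]
        # clip anything running past the frame (insertions near the 3' end)
        max_len = panel.frame_length - amp.start
        insert = insert[:max_len]
        if not insert:
            dropped.append((read, "empty_after_trim"))
            continue
        placed.append(
            PlacedFragment(
                read_id=read.id,
                sample_id=sample_id,
                amplicon_id=amp.id,
                sequence=insert,
                frame_start=amp.start,
                frame_end=amp.start + len(insert),
            )
        )
    return placed, dropped


# ---------------------------------------------------------------------------
# step vi: positional consensus with N-fill

def call_consensus(
    fragments: list[PlacedFragment],
    panel: AmpliconPanel,
    cfg: PipelineConfig,
    sample_id: str = "",
) -> ConsensusBarcode:
    """Per-column majority vote over the covering fragments.

    A column is *covered* when at least ``consensus_min_depth`` fragments
    span it; the strict majority base is emitted, ties and all-ambiguous
    columns emit N.  Zero-coverage columns strictly inside the covered span
    emit N (the contiguity rule); the sequence runs from the first to the
    last covered column.
    """
    frame = panel.frame_length
    coverage = np.zeros(frame, dtype=int)
    counts: list[Counter] = [Counter() for _ in range(frame)]
    for frag in fragments:
        if not sample_id:
            sample_id = frag.sample_id
        for j, base in enumerate(frag.sequence):
            col = frag.frame_start + j
            if col >= frame:
                break
            coverage[col] += 1
            if base in "ACGT":
                counts[col][base] += 1
    covered = np.flatnonzero(coverage >= cfg.consensus_min_depth)
    if covered.size == 0:
        return ConsensusBarcode(sample_id, "", 0, coverage.tolist(), {"no_reads"})
    span_start, span_end = int(covered[0]), int(covered[-1]) + 1
    seq = []
    for col in range(span_start, span_end):
        if coverage[col] < cfg.consensus_min_depth or not counts[col]:
            seq.append("N")
            continue
        (top_base, top_n), *rest = counts[col].most_common()
        if rest and rest[0][1] == top_n:
            seq.append("N")  # tie
        else:
            seq.append(top_base)
    consensus = ConsensusBarcode(sample_id, "".join(seq), span_start, coverage.tolist())
    if consensus.nonN_length < cfg.acceptable_barcode_bp:
        consensus.flags.add("short")
    return consensus


def validate_consensus(
    barcode: ConsensusBarcode,
    expected_order: str,
    reference: ReferenceLibrary,
) -> set[str]:
    """Automated contamination check: flag the barcode when its nearest
    reference belongs to a different order than expected."""
    if len(reference) == 0:
        raise ValueError("validation requires a non-empty reference library")
    if "no_reads" in barcode.flags or barcode.nonN_length == 0:
        barcode.flags.add("no_reads")
        return barcode.flags
    hit = _nearest_by_edlib(barcode.sequence, list(reference), 0.5, both_strands=False)
    if hit is not None and hit[1].taxonomy.order != expected_order:
        barcode.flags.add("contaminated")
    return barcode.flags


# ---------------------------------------------------------------------------
# composition

@dataclass
class RunReport:
    """Per-stage read accounting; kept + rejected equals the stage input."""

    n_input: int = 0
    n_filtered: int = 0
    n_demuxed: int = 0
    n_screened: int = 0
    n_assigned: int = 0
    n_positioned: int = 0
    rejections: Counter = field(default_factory=Counter)
    per_sample_reads: dict[str, int] = field(default_factory=dict)

    def to_rows(self) -> list[tuple[str, int]]:
        return [
            ("input", self.n_input),
            ("passed_filter", self.n_filtered),
            ("demultiplexed", self.n_demuxed),
            ("passed_taxonomy_screen", self.n_screened),
            ("amplicon_assigned", self.n_assigned),
            ("positioned", self.n_positioned),
        ]

    def write_tsv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["stage", "reads"])
            w.writerows(self.to_rows())
            for reason, n in sorted(self.rejections.items()):
                w.writerow([f"rejected:{reason}", n])


@dataclass
class PipelineResult:
    consensus: dict[str, ConsensusBarcode]
    report: RunReport


def read_fastq(path) -> list[Read]:
    """Load reads with their mean Phred quality from a FASTQ file."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        mean_qv = float(np.mean(quals)) if quals else 0.0
        out.append(Read(rec.id, str(rec.seq).upper(), mean_qv))
    return out


def read_fasta_with_qv(fasta_path, qv_tsv=None, default_qv: float = 40.0) -> list[Read]:
    """Load FASTA reads with an optional per-read QV sidecar TSV
    (columns: read_id, mean_qv)."""
    qvs: dict[str, float] = {}
    if qv_tsv is not None:
        with open(qv_tsv, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                qvs[row["read_id"]] = float(row["mean_qv"])
    return [
        Read(rec.id, str(rec.seq).upper(), qvs.get(rec.id, default_qv))
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    ]


def run_pipeline(
    reads,
    plate: PlateArray,
    panel: AmpliconPanel,
    tags: TagSet,
    reference: ReferenceLibrary,
    cfg: PipelineConfig | None = None,
) -> PipelineResult:
    """Steps i-vi end to end for one plate.

    ``reads`` may be a FASTQ path or an in-memory list of :class:`Read`.
    Every specimen on the plate gets a consensus entry; specimens with no
    surviving reads are flagged ``no_reads``.
    """
    cfg = cfg or PipelineConfig()
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)
    report = RunReport(n_input=len(reads))

    kept, rejected = filter_reads(reads, cfg)
    report.n_filtered = len(kept)
    report.rejections.update(reason for _, reason in rejected)

    bins, unassigned = demultiplex(kept, tags, cfg, plate=plate)
    report.n_demuxed = sum(len(v) for v in bins.values())
    report.rejections.update(reason for _, reason in unassigned)

    consensus: dict[str, ConsensusBarcode] = {}
    for rec in plate.specimens:
        sid = str(rec.sample_id)
        sample_reads = bins.get(sid, [])
        expected_order = rec.taxonomy.order
        screened, discarded = taxonomy_screen(sample_reads, expected_order, reference, cfg)
        report.n_screened += len(screened)
        report.rejections.update(reason for _, reason in discarded)

        assigned = []
        for r in screened:
            hit = assign_amplicon(r, panel, cfg)
            if hit is None:
                report.rejections["amplicon_unassigned"] += 1
            else:
                assigned.append((r, sid, hit))
        report.n_assigned += len(assigned)

        placed, dropped = position_fragments(assigned, panel)
        report.n_positioned += len(placed)
        report.rejections.update(reason for _, reason in dropped)
        report.per_sample_reads[sid] = len(placed)

        barcode = call_consensus(placed, panel, cfg, sample_id=sid)
        validate_consensus(barcode, expected_order, reference)
        consensus[sid] = barcode
    return PipelineResult(consensus, report)


def write_consensus_fasta(result: PipelineResult, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, bc in sorted(result.consensus.items()):
            fh.write(f">{sid}\n{bc.sequence}\n")


def write_flags_tsv(result: PipelineResult, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "nonN_length", "flags"])
        for sid, bc in sorted(result.consensus.items()):
            w.writerow([sid, bc.nonN_length, ";".join(sorted(bc.flags))])
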