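"""Sequence divergence, BIN-proxy clustering and two-route taxonomy assignment.

Divergence is the p-distance on an end-gap-free global alignment: the
proportion of differing sites among compared positions, where any column
containing a gap or an ambiguous base (non-ACGT) is excluded from both the
numerator and the denominator.

Reference clusters are a *proxy* for Barcode Index Numbers (BINs): plain
single-linkage components at a fixed divergence threshold (default 2.2%).
This is NOT the refined RESL algorithm that mints real BINs; it merely
reproduces the "same cluster" relation closely enough for library-building
logic and tests.

Assignment follows two routes in strict order:

1. *BIN taxonomy match* — if the query's cluster contains taxonomically
   identified references, copy their taxonomy down to the deepest rank on
   which all identified members agree ("lowest level without conflict").
2. *ID-engine thresholds* — otherwise take the nearest references; best
   divergence < 2% supports a species-level match, < 5% a genus-level match
   (strict "less than"), truncated to the deepest conflict-free rank among
   the top matches inside the governing threshold.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Align import PairwiseAligner

from .taxonomy import Taxonomy, deepest_shared_rank, rank_depth

_ACGT = frozenset("ACGT")


class DistanceUndefinedError(ValueError):
    """Raised when two sequences share zero comparable (unambiguous) sites."""


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.5
    aligner.extend_gap_score = -0.5
    # end-gap-free: overhangs cost nothing, so fragments nest in full frames
    aligner.end_gap_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


def p_distance(a: str, b: str) -> float:
    """Pairwise p-distance between two nucleotide sequences.

    Sequences are globally aligned with free end gaps; internal gap columns
    and columns where either base is not a plain A/C/G/T are skipped.
    """
    if not a or not b:
        raise DistanceUndefinedError("p_distance needs two non-empty sequences")
    a, b = a.upper(), b.upper()
    if len(a) == len(b):
        # fast path: equal lengths compare site-by-site (the aligner would
        # produce the same columns for high-identity pairs; for truly
        # dissimilar pairs the ungapped comparison is the conservative one)
        pairs = zip(a, b)
        compared = mismatches = 0
        for x, y in pairs:
            if x in _ACGT and y in _ACGT:
                compared += 1
                mismatches += x != y
        if compared == 0:
            raise DistanceUndefinedError("no comparable sites")
        return mismatches / compared
    if a > b:
        a, b = b, a  # canonical order keeps the measure exactly symmetric
    alignment = _ALIGNER.align(a, b)[0]
    compared = mismatches = 0
    for (t0, t1), (q0, q1) in zip(*alignment.aligned):
        for x, y in zip(a[t0:t1], b[q0:q1]):
            if x in _ACGT and y in _ACGT:
                compared += 1
                mismatches += x != y
    if compared == 0:
        raise DistanceUndefinedError("no comparable sites after alignment")
    return mismatches / compared


@dataclass(frozen=True)
class ReferenceEntry:
    id: str
    sequence: str
    taxonomy: Taxonomy = field(default_factory=Taxonomy)
    cluster_id: str | None = None

    @property
    def identified(self) -> bool:
        """Taxonomically identified = named at least to genus."""
        return bool(self.taxonomy.genus)


@dataclass
class ReferenceLibrary:
    entries: list[ReferenceEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.id for e in self.entries]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate reference id {dup!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @classmethod
    def from_files(cls, fasta_path, taxonomy_tsv=None) -> "ReferenceLibrary":
        """Build from a FASTA file plus an optional taxonomy TSV whose columns
        are ``id`` followed by the seven rank names."""
        taxa: dict[str, Taxonomy] = {}
        if taxonomy_tsv is not None:
            with open(taxonomy_tsv, newline="", encoding="utf-8") as fh:
                for row in csv.DictReader(fh, delimiter="\t"):
                    taxa[row["id"]] = Taxonomy.from_mapping(row)
        entries = [
            ReferenceEntry(rec.id, str(rec.seq).upper(), taxa.get(rec.id, Taxonomy()))
            for rec in SeqIO.parse(str(fasta_path), "fasta")
        ]
        return cls(entries)


@dataclass
class ClassifierConfig:
    species_max_divergence: float = 0.02
    genus_max_divergence: float = 0.05
    bin_proxy_threshold: float = 0.022
    top_match_count: int = 20

    def __post_init__(self) -> None:
        if not self.species_max_divergence < self.genus_max_divergence:
            raise ValueError("species threshold must be below the genus threshold")


@dataclass
class AssignmentResult:
    query_id: str
    method: str  # "bin_match" | "id_engine" | "none"
    taxonomy: Taxonomy = field(default_factory=Taxonomy)
    best_distance: float | None = None
    supporting: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.method == "none" and self.taxonomy.deepest_rank is not None:
            raise ValueError("unassigned result cannot carry taxonomy")

    @property
    def rank(self) -> str | None:
        return self.taxonomy.deepest_rank


def nearest_references(query_seq: str, library: ReferenceLibrary,
                       both_strands: bool = False) -> list[tuple[float, ReferenceEntry]]:
    """All references sorted by p-distance to the query (ties by id)."""
    from .panel import revcomp  # local import avoids a cycle at module load

    out = []
    for entry in library:
        try:
            d = p_distance(query_seq, entry.sequence)
        except DistanceUndefinedError:
            continue
        if both_strands:
            try:
                d = min(d, p_distance(revcomp(query_seq), entry.sequence))
            except DistanceUndefinedError:
                pass
        out.append((d, entry))
    out.sort(key=lambda t: (t[0], t[1].id))
    return out


def cluster_bins(library: ReferenceLibrary,
                 cfg: ClassifierConfig | None = None) -> dict[str, str]:
    """Single-linkage clusters: connected components of the graph whose edges
    join entries with p-distance strictly below the BIN-proxy threshold.
    Cluster labels are the lexicographically smallest member id."""
    cfg = cfg or ClassifierConfig()
    if len(library) == 0:
        raise ValueError("cannot cluster an empty library")
    entries = library.entries
    parent = list(range(len(entries)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(entries)):
        for j in range(i + 1, len(entries)):
            try:
                d = p_distance(entries[i].sequence, entries[j].sequence)
            except DistanceUndefinedError:
                continue
            if d < cfg.bin_proxy_threshold:
                parent[find(i)] = find(j)

    members: dict[int, list[str]] = {}
    for i, e in enumerate(entries):
        members.setdefault(find(i), []).append(e.id)
    labels = {root: min(ids) for root, ids in members.items()}
    return {e.id: labels[find(i)] for i, e in enumerate(entries)}


def assign_bin_match(query_id: str, query_cluster: str, library: ReferenceLibrary,
                     cfg: ClassifierConfig | None = None,
                     query_seq: str | None = None) -> AssignmentResult | None:
    """Copy taxonomy from identified co-members of the query's cluster.

    Returns None when the cluster holds no identified reference, letting the
    caller fall through to the ID-engine route.
    """
    cfg = cfg or ClassifierConfig()
    co = [e for e in library if e.cluster_id == query_cluster and e.identified]
    if not co:
        return None
    taxonomy = deepest_shared_rank([e.taxonomy for e in co])
    supporting = []
    best = None
    if query_seq:
        for e in co:
            try:
                d = p_distance(query_seq, e.sequence)
            except DistanceUndefinedError:
                continue
            supporting.append((e.id, d))
        supporting.sort(key=lambda t: (t[1], t[0]))
        best = supporting[0][1] if supporting else None
    return AssignmentResult(query_id, "bin_match", taxonomy, best, supporting)


def assign_id_engine(query_id: str, query_seq: str, library: ReferenceLibrary,
                     cfg: ClassifierConfig | None = None) -> AssignmentResult:
    """Nearest-match thresholds: best divergence < 2% -> species candidate,
    < 5% -> genus candidate, else unassigned; the candidate is truncated to
    the deepest conflict-free rank among top matches within the governing
    threshold."""
    cfg = cfg or ClassifierConfig()
    if len(library) == 0:
        raise ValueError("empty reference library")
    ranked = nearest_references(query_seq, library)
    if not ranked:
        return AssignmentResult(query_id, "none")
    best = ranked[0][0]
    if best < cfg.species_max_divergence:
        candidate, governing = "species", cfg.species_max_divergence
    elif best < cfg.genus_max_divergence:
        candidate, governing = "genus", cfg.genus_max_divergence
    else:
        return AssignmentResult(query_id, "none", best_distance=best,
                                supporting=[(e.id, d) for d, e in ranked[: cfg.top_match_count]])
    top = ranked[: cfg.top_match_count]
    # include ties at the cutoff distance
    if len(ranked) > len(top):
        cut = top[-1][0]
        for d, e in ranked[len(top):]:
            if d == cut:
                top.append((d, e))
            else:
                break
    within = [e for d, e in top if d < governing and e.identified]
    if not within:
        return AssignmentResult(query_id, "none", best_distance=best)
    taxonomy = deepest_shared_rank([e.taxonomy for e in within])
    if rank_depth(taxonomy.deepest_rank) > rank_depth(candidate):
        taxonomy = taxonomy.truncated(candidate)
    if taxonomy.deepest_rank is None:
        return AssignmentResult(query_id, "none", best_distance=best)
    return AssignmentResult(query_id, "id_engine", taxonomy, best,
                            [(e.id, d) for d, e in top])


def assign_all(queries: list[tuple[str, str]], library: ReferenceLibrary,
               cfg: ClassifierConfig | None = None):
    """Assign every query, BIN-match route first, then ID-engine.

    Queries and references are clustered together so an unidentified query
    can land in an identified reference cluster.  Returns
    ``(results, summary)`` where summary counts method x rank.
    """
    cfg = cfg or ClassifierConfig()
    combined = ReferenceLibrary(
        list(library.entries)
        + [ReferenceEntry(qid, seq.upper()) for qid, seq in queries]
    )
    clusters = cluster_bins(combined, cfg)
    clustered_lib = ReferenceLibrary([
        ReferenceEntry(e.id, e.sequence, e.taxonomy, clusters[e.id]) for e in library
    ])
    results: list[AssignmentResult] = []
    for qid, seq in queries:
        res = assign_bin_match(qid, clusters[qid], clustered_lib, cfg, query_seq=seq)
        if res is None:
            res = assign_id_engine(qid, seq, clustered_lib, cfg)
        results.append(res)
    summary = summarize_assignments(results)
    return results, summary


def summarize_assignments(results: list[AssignmentResult]) -> dict:
    """Counts keyed (method, rank) for genus- and species-level assignments,
    plus totals; assignments coarser than genus count under their own rank."""
    counts: dict[tuple[str, str], int] = {}
    for r in results:
        rank = r.rank if r.method != "none" else None
        key = (r.method, rank or "none")
        counts[key] = counts.get(key, 0) + 1
    return counts


def write_assignments(results: list[AssignmentResult], path) -> None:
    """TSV export: query_id, method, rank, taxon, distance."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["query_id", "method", "rank", "taxon", "distance"])
        for r in results:
            rank = r.rank or ""
            taxon = r.taxonomy.rank(rank) if rank else ""
            w.writerow([r.query_id, r.method, rank, taxon,
                        "" if r.best_distance is None else f"{r.best_distance:.6f}"])
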