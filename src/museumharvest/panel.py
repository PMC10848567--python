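"""Amplicon tiling schemes, primers and UMI tag sets.

All coordinates are 0-based, half-open, on a canonical 658-bp COI barcode
frame.  Two presets ship with the package:

``sanger2``
    two overlapping amplicons of insert length 307 and 407 bp, the classic
    two-fragment Sanger design covering the full barcode;
``ngs_tiled``
    six short overlapping amplicons tiling the frame, the failure-tracking
    design for degraded templates.

Preset primer sequences are synthetic placeholders generated for simulation
(real panels publish their primers separately); swap them via a YAML config
for real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import yaml

from .plate import N_WELLS, WellAddress, all_wells

FRAME_LENGTH = 658

IUPAC = set("ACGTRYSWKMBDHVN")
#: IUPAC code -> set of bases it matches (used for tolerant primer search)
IUPAC_EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class PanelError(ValueError):
    """Malformed panel or tag-set configuration."""


@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str
    orientation: str  # "forward" | "reverse"
    anneal_start: int  # position on the barcode frame

    def __post_init__(self) -> None:
        if not self.sequence or any(b not in IUPAC for b in self.sequence):
            raise PanelError(f"primer {self.name!r}: sequence must be non-empty IUPAC")
        if self.orientation not in ("forward", "reverse"):
            raise PanelError(f"primer {self.name!r}: bad orientation {self.orientation!r}")
        if self.anneal_start < 0:
            raise PanelError(f"primer {self.name!r}: negative anneal position")


@dataclass(frozen=True)
class Amplicon:
    id: str
    start: int
    end: int
    fwd: Primer
    rev: Primer

    @property
    def insert_length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def anneal_mismatch(self) -> bool:
        # forward primer anneals immediately upstream of the insert, reverse
        # immediately downstream
        return self.fwd.anneal_start != self.start or self.rev.anneal_start != self.end


@dataclass
class AmpliconPanel:
    name: str
    amplicons: list[Amplicon]
    frame_length: int = FRAME_LENGTH

    def __post_init__(self) -> None:
        bad = []
        seen = set()
        for a in self.amplicons:
            if a.id in seen:
                bad.append(f"duplicate amplicon id {a.id!r}")
            seen.add(a.id)
            if not (0 <= a.start < a.end <= self.frame_length):
                bad.append(
                    f"amplicon {a.id!r}: interval [{a.start},{a.end}) outside "
                    f"[0,{self.frame_length})"
                )
            if a.anneal_mismatch():
                bad.append(f"amplicon {a.id!r}: primer anneal positions inconsistent")
        if bad:
            raise PanelError("invalid panel: " + "; ".join(bad))

    @property
    def coverage_complete(self) -> bool:
        """Does the union of amplicon intervals cover [0, frame_length)?"""
        return not self.uncovered_positions()

    def covered_positions(self, amplicon_ids=None) -> set[int]:
        cols: set[int] = set()
        for a in self.amplicons:
            if amplicon_ids is None or a.id in amplicon_ids:
                cols.update(range(a.start, a.end))
        return cols

    def uncovered_positions(self) -> set[int]:
        return set(range(self.frame_length)) - self.covered_positions()

    def get(self, amplicon_id: str) -> Amplicon:
        for a in self.amplicons:
            if a.id == amplicon_id:
                return a
        raise KeyError(amplicon_id)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal lengths")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class TagSet:
    """96 forward + 96 reverse sample-indexing tags (asymmetric dual-tagging).

    Each well receives a unique (forward index, reverse index) pair; a pair
    not in the scheme is evidence of tag jumping/conflict during demux.
    """

    forward_tags: list[str]
    reverse_tags: list[str]
    well_assignment: dict[WellAddress, tuple[int, int]] = field(default_factory=dict)
    tolerance: int = 1

    def __post_init__(self) -> None:
        if not self.well_assignment:
            self.well_assignment = {w: (w.index, w.index) for w in all_wells()}
        for name, tags in (("forward", self.forward_tags), ("reverse", self.reverse_tags)):
            if len(tags) != N_WELLS:
                raise PanelError(f"{name} tag list must have {N_WELLS} tags, got {len(tags)}")
            if len(set(len(t) for t in tags)) != 1:
                raise PanelError(f"{name} tags must share one length")
            if len(set(tags)) != len(tags):
                dup = next(t for t in tags if tags.count(t) > 1)
                raise PanelError(f"duplicate {name} tag {dup!r}")
        self.validate_distance(self.tolerance)
        self._pair_to_well = {pair: w for w, pair in self.well_assignment.items()}
        # decode table: every observation within `tolerance` mismatches of a
        # tag maps to that tag (unique by the distance property); built for
        # tolerance <= 1 where enumeration is tiny
        self._decode_cache: dict[str, dict[str, int]] = {}
        if self.tolerance <= 1:
            for name, tags in (("forward", self.forward_tags),
                               ("reverse", self.reverse_tags)):
                table = {t: i for i, t in enumerate(tags)}
                if self.tolerance == 1:
                    for i, t in enumerate(tags):
                        for pos in range(len(t)):
                            for b in "ACGT":
                                if b != t[pos]:
                                    table[t[:pos] + b + t[pos + 1:]] = i
                self._decode_cache[name] = table

    @property
    def tag_length(self) -> int:
        return len(self.forward_tags[0])

    def validate_distance(self, tolerance: int) -> None:
        """Unique decoding under <=tolerance mismatches needs pairwise
        Hamming distance >= 2*tolerance + 1 within each direction."""
        need = 2 * tolerance + 1
        for name, tags in (("forward", self.forward_tags), ("reverse", self.reverse_tags)):
            for a, b in combinations(tags, 2):
                d = hamming(a, b)
                if d < need:
                    raise PanelError(
                        f"{name} tags {a!r} and {b!r} at Hamming distance {d} are "
                        f"ambiguous under tolerance {tolerance} (need >= {need})"
                    )

    def decode(self, observed: str, direction: str, tolerance: int | None = None) -> int | None:
        """Index of the unique tag within tolerance of *observed*, else None."""
        tol = self.tolerance if tolerance is None else tolerance
        tags = self.forward_tags if direction == "forward" else self.reverse_tags
        if len(observed) != self.tag_length:
            return None
        if tol == self.tolerance and direction in self._decode_cache:
            return self._decode_cache[direction].get(observed)
        best_i, best_d = None, tol + 1
        for i, t in enumerate(tags):
            d = hamming(observed, t)
            if d < best_d:
                best_i, best_d = i, d
        return best_i

    def well_for(self, fwd_index: int, rev_index: int) -> WellAddress | None:
        return self._pair_to_well.get((fwd_index, rev_index))


# ---------------------------------------------------------------------------
# presets and config loading

_PRIMER_LEN = 22


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _placeholder_primers(amplicon_intervals, seed: int = 658_001):
    """Deterministic synthetic primer pairs, one pair per amplicon."""
    rng = np.random.default_rng(seed)
    out = []
    for i, (s, e) in enumerate(amplicon_intervals, start=1):
        fwd = Primer(f"fwdP{i}", _random_seq(rng, _PRIMER_LEN), "forward", s)
        rev = Primer(f"revP{i}", _random_seq(rng, _PRIMER_LEN), "reverse", e)
        out.append((fwd, rev))
    return out


_SANGER2_INTERVALS = [(0, 307), (251, 658)]  # insert lengths 307 and 407 bp
_NGS_TILED_INTERVALS = [
    (0, 120), (110, 230), (220, 340), (330, 450), (440, 560), (550, 658),
]


def _preset_panel(name: str, intervals) -> AmpliconPanel:
    primers = _placeholder_primers(intervals)
    amps = [
        Amplicon(f"{name}_a{i}", s, e, f, r)
        for i, ((s, e), (f, r)) in enumerate(zip(intervals, primers), start=1)
    ]
    return AmpliconPanel(name, amps)


PRESETS = {
    "sanger2": lambda: _preset_panel("sanger2", _SANGER2_INTERVALS),
    "ngs_tiled": lambda: _preset_panel("ngs_tiled", _NGS_TILED_INTERVALS),
}


def load_panel(source) -> AmpliconPanel:
    """Load a panel from a preset name or a YAML file.

    YAML schema::

        name: mypanel
        frame_length: 658
        amplicons:
          - id: a1
            start: 0
            end: 307
            fwd: {name: f1, sequence: ACGT...}
            rev: {name: r1, sequence: TTGA...}
    """
    if isinstance(source, str) and source in PRESETS:
        return PRESETS[source]()
    with open(source) as fh:
        doc = yaml.safe_load(fh) or {}
    frame = int(doc.get("frame_length", FRAME_LENGTH))
    amps = []
    for item in doc.get("amplicons", []):
        s, e = int(item["start"]), int(item["end"])
        fwd = Primer(item["fwd"]["name"], item["fwd"]["sequence"].upper(), "forward",
                     int(item["fwd"].get("anneal_start", s)))
        rev = Primer(item["rev"]["name"], item["rev"]["sequence"].upper(), "reverse",
                     int(item["rev"].get("anneal_start", e)))
        amps.append(Amplicon(str(item["id"]), s, e, fwd, rev))
    return AmpliconPanel(str(doc.get("name", "custom")), amps, frame_length=frame)


def default_tagset(tag_length: int = 8, tolerance: int = 1, seed: int = 96_031) -> TagSet:
    """Generate the shipped tag set: 96+96 random tags kept only if they stay
    at Hamming distance >= 2*tolerance+1 from every accepted same-direction
    tag.  Deterministic for a given seed."""
    rng = np.random.default_rng(seed)
    need = 2 * tolerance + 1

    def build() -> list[str]:
        tags: list[str] = []
        while len(tags) < N_WELLS:
            cand = _random_seq(rng, tag_length)
            if all(hamming(cand, t) >= need for t in tags):
                tags.append(cand)
        return tags

    return TagSet(build(), build(), tolerance=tolerance)


def load_tagset(path, tolerance: int = 1) -> TagSet:
    """Load a tag set from YAML: keys ``forward_tags``, ``reverse_tags`` and
    optional ``well_assignment`` ({"A01": [0, 0], ...})."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    assignment = {
        WellAddress.parse(k): (int(v[0]), int(v[1]))
        for k, v in (doc.get("well_assignment") or {}).items()
    }
    return TagSet(
        [t.upper() for t in doc["forward_tags"]],
        [t.upper() for t in doc["reverse_tags"]],
        well_assignment=assignment,
        tolerance=tolerance,
    )
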