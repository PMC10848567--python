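"""Synthetic barcodes, age-degraded fragments and tagged reads.

The generator stands in for voucher specimens: it emits 658-bp "true"
barcodes organised in a genus/species hierarchy, then amplicon fragments
whose survival decays exponentially with specimen age, wrapped in the full
read structure the wet protocol produces::

    UMI_f + fwd_primer + insert + revcomp(rev_primer) + revcomp(UMI_r)

Degradation model: an amplicon survives PCR from a specimen of age ``t``
(years) with probability ``2**(-t / half_life_years)`` — the standard
exponential-fragmentation assumption, parameterised so that at the default
half-life of 40 years a specimen of the study's mean age (~38 yr) keeps
roughly half of its amplicons.  Surviving amplicons emit ``depth`` reads
carrying independent per-base substitutions and geometric-length indels;
about half of all reads are emitted reverse-complemented.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np

from .panel import AmpliconPanel, TagSet, revcomp
from .plate import (
    DEFAULT_ANALYSIS_YEAR,
    PlateArray,
    SampleID,
    SpecimenRecord,
    WellAddress,
    all_wells,
    format_sample_id,
    parse_sample_id,
)
from .taxonomy import Taxonomy

_BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class TrueBarcode:
    sample_id: SampleID
    sequence: str
    taxonomy: Taxonomy
    collection_year: int

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGT"):
            raise SimulationError("true barcodes are over A/C/G/T only")


@dataclass
class DegradationModel:
    """Study conditions for read simulation.

    half_life_years
        age at which an amplicon's survival probability halves (default 40:
        at the study's mean specimen age of ~38 yr this yields ~50%
        per-amplicon survival, matching observed recovery at the mean age).
    base_error_rate
        per-base substitution probability (default 0.5%; CCS reads carry a
        minimum predicted accuracy of 99%, i.e. <=1% total error).
    indel_rate
        per-base probability of starting an indel whose length is
        geometric(0.5); default 0.1%.
    """

    half_life_years: float = 40.0
    base_error_rate: float = 0.005
    indel_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.half_life_years > 0:
            raise SimulationError("half_life_years must be positive")
        for r in (self.base_error_rate, self.indel_rate):
            if not 0 <= r < 1:
                raise SimulationError("error rates must lie in [0, 1)")

    def survival(self, age_years: float) -> float:
        if math.isinf(self.half_life_years):
            return 1.0
        return 2.0 ** (-age_years / self.half_life_years)


@dataclass(frozen=True)
class SimulatedRead:
    id: str
    sequence: str
    mean_qv: float


@dataclass
class SimulatedReadSet:
    reads: list[SimulatedRead] = field(default_factory=list)
    #: read id -> (sample_id string, amplicon id)
    truth: dict[str, tuple[str, str]] = field(default_factory=dict)

    def write_fastq(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for r in self.reads:
                q = chr(min(93, int(round(r.mean_qv))) + 33) * len(r.sequence)
                fh.write(f"@{r.id}\n{r.sequence}\n+\n{q}\n")

    def write_truth(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["read_id", "sample_id", "amplicon_id"])
            for rid, (sid, aid) in self.truth.items():
                w.writerow([rid, sid, aid])


@dataclass
class DivergenceConfig:
    """Per-rank divergence of the simulated barcode phylogeny.

    Fractions are mutation loads applied from a common ancestor down the
    genus -> species -> individual chain; defaults put intra-species
    p-distance well under 2% and inter-genus distance above 5%, matching the
    thresholds the classifier is built around.
    """

    genus_divergence: float = 0.06
    species_divergence: float = 0.02
    individual_divergence: float = 0.004

    def __post_init__(self) -> None:
        if self.species_divergence >= self.genus_divergence:
            raise SimulationError(
                "species divergence must be below genus divergence"
            )
        if self.individual_divergence >= self.species_divergence:
            raise SimulationError(
                "individual divergence must be below species divergence"
            )


def _mutate(seq: str, fraction: float, rng: np.random.Generator) -> str:
    """Substitute a *fraction* of sites (distinct positions, changed base)."""
    n = len(seq)
    k = int(round(fraction * n))
    if k == 0:
        return seq
    pos = rng.choice(n, size=k, replace=False)
    out = list(seq)
    for p in pos:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(3)]
    return "".join(out)


def _plate_wells(n: int, control_well: WellAddress) -> list[tuple[str, WellAddress]]:
    """Assign n specimens to consecutive simulated plates, skipping the
    control well on each."""
    out = []
    plate_i = 0
    wells = [w for w in all_wells()]
    while len(out) < n:
        code = f"CCDB-{90001 + plate_i}"
        for w in wells:
            if w == control_well:
                continue
            out.append((code, w))
            if len(out) == n:
                break
        plate_i += 1
    return out


def simulate_barcodes(
    n: int,
    divergence: DivergenceConfig | None = None,
    seed: int = 0,
    frame_length: int = 658,
    species_per_genus: int = 1,
    specimens_per_species: int = 1,
    year_range: tuple[int, int] = (1901, 2017),
    collection_years: list[int] | None = None,
    control_well: WellAddress | None = None,
) -> list[TrueBarcode]:
    """Generate *n* true barcodes on a genus/species hierarchy.

    Sequences descend from one random ancestor: each genus founder mutates
    the ancestor by ``genus_divergence``, each species founder mutates its
    genus by ``species_divergence`` and each specimen mutates its species by
    ``individual_divergence``.  Collection years default to uniform draws
    over 1901-2017 (the study's observed range).
    """
    divergence = divergence or DivergenceConfig()
    rng = np.random.default_rng(seed)
    control_well = control_well or WellAddress("H", 12)
    if n < 0:
        raise SimulationError("n must be non-negative")
    if n == 0:
        return []
    ancestor = "".join(rng.choice(_BASES, size=frame_length))
    per_genus = species_per_genus * specimens_per_species
    n_genera = math.ceil(n / per_genus)
    slots = _plate_wells(n, control_well)
    if collection_years is None:
        lo, hi = year_range
        collection_years = list(rng.integers(lo, hi + 1, size=n))
    elif len(collection_years) != n:
        raise SimulationError("collection_years must have length n")
    out: list[TrueBarcode] = []
    i = 0
    for g in range(n_genera):
        genus_seq = _mutate(ancestor, divergence.genus_divergence, rng)
        genus = f"Simgenus{g + 1:03d}"
        for s in range(species_per_genus):
            species_seq = _mutate(genus_seq, divergence.species_divergence, rng)
            species = f"{genus} sp{s + 1}"
            for _ in range(specimens_per_species):
                if i == n:
                    break
                seq = _mutate(species_seq, divergence.individual_divergence, rng)
                code, well = slots[i]
                out.append(
                    TrueBarcode(
                        sample_id=SampleID(code, well),
                        sequence=seq,
                        taxonomy=Taxonomy(
                            phylum="Arthropoda",
                            class_="Insecta",
                            order="Diptera",
                            family="Simfamily",
                            genus=genus,
                            species=species,
                        ),
                        collection_year=int(collection_years[i]),
                    )
                )
                i += 1
    return out


def barcodes_to_plates(barcodes: list[TrueBarcode],
                       control_well: WellAddress | None = None) -> list[PlateArray]:
    """Specimen metadata plates matching a simulated barcode set."""
    control_well = control_well or WellAddress("H", 12)
    plates: dict[str, PlateArray] = {}
    for bc in barcodes:
        code = bc.sample_id.plate_code
        plate = plates.setdefault(code, PlateArray(code, control_well=control_well))
        plate.add(
            SpecimenRecord(
                sample_id=bc.sample_id,
                taxonomy=bc.taxonomy,
                collection_year=bc.collection_year,
            )
        )
    return list(plates.values())


def reference_from_barcodes(barcodes: list[TrueBarcode], per_genus: int = 1,
                            decoys: int = 1, seed: int = 0):
    """A screening/assignment reference library emulating an established
    barcode database: up to ``per_genus`` identified entries per simulated
    genus, plus ``decoys`` random off-target entries from a different order
    (for wrong-order and contamination checks)."""
    from .classify import ReferenceEntry, ReferenceLibrary

    rng = np.random.default_rng(seed)
    entries: list[ReferenceEntry] = []
    seen: dict[str, int] = {}
    for bc in barcodes:
        genus = bc.taxonomy.genus
        if seen.get(genus, 0) >= per_genus:
            continue
        seen[genus] = seen.get(genus, 0) + 1
        entries.append(
            ReferenceEntry(f"ref_{bc.sample_id}", bc.sequence, bc.taxonomy)
        )
    n = len(barcodes[0].sequence) if barcodes else 658
    for d in range(decoys):
        entries.append(
            ReferenceEntry(
                f"decoy{d + 1}",
                "".join(rng.choice(_BASES, size=n)),
                Taxonomy(phylum="Arthropoda", class_="Insecta", order="Lepidoptera",
                         family="Decoyidae", genus=f"Decoygenus{d + 1}",
                         species=f"Decoygenus{d + 1} sp1"),
            )
        )
    return ReferenceLibrary(entries)


def _apply_noise(seq: str, model: DegradationModel, rng: np.random.Generator) -> str:
    if model.base_error_rate == 0 and model.indel_rate == 0:
        return seq
    out = []
    for b in seq:
        if model.indel_rate and rng.random() < model.indel_rate:
            length = rng.geometric(0.5)
            if rng.random() < 0.5:  # deletion
                continue
            out.append("".join(rng.choice(_BASES, size=length)))
        if model.base_error_rate and rng.random() < model.base_error_rate:
            b = [c for c in "ACGT" if c != b][rng.integers(3)]
        out.append(b)
    return "".join(out)


def _read_qv(model: DegradationModel) -> float:
    total = model.base_error_rate + model.indel_rate
    if total <= 0:
        return 40.0
    return min(40.0, -10.0 * math.log10(total))


def simulate_reads(
    barcodes: list[TrueBarcode],
    panel: AmpliconPanel,
    tags: TagSet,
    model: DegradationModel | None = None,
    depth: int = 5,
    seed: int | None = None,
    analysis_year: int = DEFAULT_ANALYSIS_YEAR,
    flip_fraction: float = 0.5,
) -> SimulatedReadSet:
    """Emit tagged reads for every surviving (specimen, amplicon) pair.

    Every specimen's well must exist in the tag set's well assignment.
    ``flip_fraction`` of reads are reverse-complemented before output.
    """
    model = model or DegradationModel()
    rng = np.random.default_rng(model.seed if seed is None else seed)
    out = SimulatedReadSet()
    counter = 0
    for bc in barcodes:
        well = bc.sample_id.well
        if well not in tags.well_assignment:
            raise SimulationError(f"no tag assignment for well {well} ({bc.sample_id})")
        fi, ri = tags.well_assignment[well]
        umi_f, umi_r = tags.forward_tags[fi], tags.reverse_tags[ri]
        age = max(0, analysis_year - bc.collection_year)
        p_survive = model.survival(age)
        for amp in panel.amplicons:
            if rng.random() >= p_survive:
                continue
            insert = bc.sequence[amp.start:amp.end]
            template = (
                umi_f + amp.fwd.sequence + insert
                + revcomp(amp.rev.sequence) + revcomp(umi_r)
            )
            for _ in range(depth):
                seq = _apply_noise(template, model, rng)
                if rng.random() < flip_fraction:
                    seq = revcomp(seq)
                rid = f"read{counter:07d}"
                counter += 1
                out.reads.append(SimulatedRead(rid, seq, _read_qv(model)))
                out.truth[rid] = (str(bc.sample_id), amp.id)
    return out


def simulate_negative_control(
    tags: TagSet,
    seed: int = 0,
    contamination_rate: float = 0.0,
    donors: list[TrueBarcode] | None = None,
    panel: AmpliconPanel | None = None,
    depth: int = 5,
    control_well: WellAddress | None = None,
    plate_code: str = "CCDB-90001",
) -> SimulatedReadSet:
    """Reads for the negative-control well: none by default; with
    ``contamination_rate`` > 0, reads copy a donor specimen's template but
    carry the control well's tags (for contamination-flag tests)."""
    control_well = control_well or WellAddress("H", 12)
    rng = np.random.default_rng(seed)
    out = SimulatedReadSet()
    if contamination_rate <= 0:
        return out
    if not donors:
        raise SimulationError("contamination requires a non-empty donor pool")
    if panel is None:
        raise SimulationError("contamination requires an amplicon panel")
    if control_well not in tags.well_assignment:
        raise SimulationError(f"no tag assignment for control well {control_well}")
    fi, ri = tags.well_assignment[control_well]
    umi_f, umi_r = tags.forward_tags[fi], tags.reverse_tags[ri]
    control_id = format_sample_id(plate_code, control_well)
    donor = donors[rng.integers(len(donors))]
    for _ in range(depth):
        if rng.random() >= contamination_rate:
            continue
        amp = panel.amplicons[rng.integers(len(panel.amplicons))]
        insert = donor.sequence[amp.start:amp.end]
        seq = (
            umi_f + amp.fwd.sequence + insert
            + revcomp(amp.rev.sequence) + revcomp(umi_r)
        )
        rid = f"ctrl{len(out.reads):05d}"
        out.reads.append(SimulatedRead(rid, seq, 40.0))
        out.truth[rid] = (control_id, amp.id)
    return out
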