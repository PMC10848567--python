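"""Ranked Linnaean taxonomy shared by the plate, classifier and simulator modules.

Seven ranks are tracked (phylum .. species). A taxonomy is *hierarchical*:
naming a rank implies every coarser rank is named too.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

RANKS = ("phylum", "class_", "order", "family", "subfamily", "genus", "species")
#: column names used in TSV files (``class`` is a Python keyword)
RANK_COLUMNS = ("phylum", "class", "order", "family", "subfamily", "genus", "species")


@dataclass(frozen=True)
class Taxonomy:
    """Ranked names, any suffix of which may be empty.

    ``subfamily`` is allowed to be empty between family and genus: many
    dipteran classifications skip it, so the hierarchy check treats it as
    optional rather than as a gap.
    """

    phylum: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    subfamily: str = ""
    genus: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        named = [bool(getattr(self, r)) for r in RANKS]
        # drop the optional subfamily slot from the prefix check
        required = [n for r, n in zip(RANKS, named) if r != "subfamily"]
        seen_gap = False
        for n in required:
            if not n:
                seen_gap = True
            elif seen_gap:
                raise ValueError(
                    f"taxonomy is not hierarchical: a fine rank is named "
                    f"below an unnamed coarser rank in {self.as_tuple()}"
                )

    def as_tuple(self) -> tuple[str, ...]:
        return tuple(getattr(self, r) for r in RANKS)

    def rank(self, name: str) -> str:
        return getattr(self, "class_" if name == "class" else name)

    @property
    def deepest_rank(self) -> str | None:
        """Finest rank with a name, or None for an empty taxonomy."""
        for r in reversed(RANKS):
            if getattr(self, r):
                return "class" if r == "class_" else r
        return None

    def truncated(self, rank: str) -> "Taxonomy":
        """Copy truncated at *rank* (finer ranks blanked)."""
        key = "class_" if rank == "class" else rank
        idx = RANKS.index(key)
        return Taxonomy(**{r: getattr(self, r) if i <= idx else "" for i, r in enumerate(RANKS)})

    @classmethod
    def from_mapping(cls, row) -> "Taxonomy":
        kw = {}
        for key, col in zip(RANKS, RANK_COLUMNS):
            v = row.get(col, "")
            kw[key] = "" if v is None else str(v).strip()
        return cls(**kw)


def rank_depth(rank: str | None) -> int:
    """Ordinal depth of a rank name (-1 for None); deeper is larger."""
    if rank is None:
        return -1
    key = "class_" if rank == "class" else rank
    return RANKS.index(key)


def deepest_shared_rank(taxa: list[Taxonomy]) -> Taxonomy:
    """Deepest conflict-free taxonomy across *taxa*.

    Walks ranks from coarse to fine; stops at the first rank where the
    named values disagree or where no member names the rank.  The optional
    subfamily rank never blocks descent to genus/species: disagreement or
    absence there blanks subfamily only.
    """
    if not taxa:
        return Taxonomy()
    out: dict[str, str] = {}
    for r in RANKS:
        values = {getattr(t, r) for t in taxa}
        values.discard("")
        agreed = next(iter(values)) if len(values) == 1 else ""
        # a rank counts as agreed only if *every* member names it identically
        if agreed and any(not getattr(t, r) for t in taxa):
            agreed = ""
        if r == "subfamily":
            out[r] = agreed
            continue
        if not agreed:
            break
        out[r] = agreed
    full = {r: out.get(r, "") for r in RANKS}
    if not full["genus"]:
        full["species"] = ""  # keep hierarchy if the loop broke at genus
    return Taxonomy(**full)
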