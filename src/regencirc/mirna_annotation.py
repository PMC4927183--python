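"""Assignment of sequence tags to mature miRNA catalogs, isomiR
classification, and tRNA/rRNA-fragment identification.

A tag is matched against each catalog entry by shifted exact matching: the
tag is slid along the mature sequence (no internal indels, only terminal 5'
and 3' shifts), and mismatches within the overlap are counted as
substitutions. Variants are named in isomiR terms; substitutions inside the
seed (mature positions 2-8, 1-based) define the seed-variant class, which
can retarget the miRNA. Tags that hit no miRNA are checked for exact
substring identity to tRNA / rRNA references (processed tRFs / rRFs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

from ._dna import normalize
from .smallrna_io import TagTable

SEED_START = 2  # 1-based, inclusive
SEED_END = 8  # 1-based, inclusive


def seed_of(mature: str) -> str:
    """Seed of a mature miRNA: positions 2-8, 1-based from the 5' end."""
    if len(mature) < SEED_END:
        raise ValueError(f"mature sequence shorter than {SEED_END} nt: {mature!r}")
    return mature[SEED_START - 1 : SEED_END]


@dataclass(frozen=True)
class MatureMiRNA:
    name: str
    species: str
    mature: str

    def __post_init__(self) -> None:
        if set(self.mature) - set("ACGT"):
            raise ValueError(f"{self.name}: mature sequence must be ACGT")
        if len(self.mature) < SEED_END:
            raise ValueError(f"{self.name}: mature sequence too short")

    @property
    def seed(self) -> str:
        return seed_of(self.mature)


@dataclass
class MiRNACatalog:
    """Ordered catalog of mature miRNAs for one species; order is the
    documented tie-break for ambiguous tag assignments."""

    species: str
    entries: list[MatureMiRNA] = field(default_factory=list)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def mature_sequences(self) -> set[str]:
        return {e.mature for e in self.entries}

    @classmethod
    def from_fasta(cls, path: str | Path, species: str) -> "MiRNACatalog":
        entries = []
        with open(path) as handle:
            for title, seq in SimpleFastaParser(handle):
                entries.append(
                    MatureMiRNA(title.split()[0], species, normalize(seq))
                )
        return cls(species, entries)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            for e in self.entries:
                handle.write(f">{e.name}\n{e.mature}\n")


@dataclass
class IsomiRCall:
    tag: str
    parent: str
    variant_class: str  # canonical | 5p_shift | 3p_shift | internal_sub | seed_sub | multi
    offsets: tuple[int, int]  # (5' shift, 3' shift), nt; +ve = extension at 3', trim at 5'
    substitutions: list[tuple[int, str, str]]  # (1-based mature position, from, to)


@dataclass
class TagAssignment:
    tag: str
    cls: str  # miRNA | tRF | rRF | unknown
    detail: IsomiRCall | str | None = None


def _variant_class(o5: int, o3: int, subs: list[tuple[int, str, str]]) -> str:
    if o5 == 0 and o3 == 0 and not subs:
        return "canonical"
    if any(SEED_START <= pos <= SEED_END for pos, _, _ in subs):
        return "seed_sub"
    shifted5, shifted3 = o5 != 0, o3 != 0
    if subs and not (shifted5 or shifted3):
        return "internal_sub"
    if shifted5 and not shifted3 and not subs:
        return "5p_shift"
    if shifted3 and not shifted5 and not subs:
        return "3p_shift"
    return "multi"


def match_tag(
    tag: str,
    catalog: MiRNACatalog | Iterable[MatureMiRNA],
    max_5p_shift: int = 2,
    max_3p_shift: int = 3,
    max_sub: int = 2,
) -> TagAssignment:
    """Best catalog assignment for a tag, or an ``unknown`` assignment.

    The best hit minimizes ``(substitutions, |5' shift| + |3' shift|)``
    lexicographically; ties are broken by catalog order. The 5' offset is
    the tag start minus the mature start in mature coordinates (negative =
    5' extension); the 3' offset is tag end minus mature end (positive =
    3' extension). Bases extending beyond the mature sequence are not
    counted as substitutions (they derive from the precursor).
    """
    best: tuple[int, int, int] | None = None
    best_call: IsomiRCall | None = None
    for order, entry in enumerate(catalog):
        mature = entry.mature
        for o5 in range(-max_5p_shift, max_5p_shift + 1):
            o3 = o5 + len(tag) - len(mature)
            if abs(o3) > max_3p_shift:
                continue
            lo = max(0, o5)
            hi = min(len(mature), len(mature) + o3)
            if hi - lo < SEED_END:  # overlap must at least span the seed
                continue
            subs = [
                (c + 1, mature[c], tag[c - o5])
                for c in range(lo, hi)
                if mature[c] != tag[c - o5]
            ]
            if len(subs) > max_sub:
                continue
            key = (len(subs), abs(o5) + abs(o3), order)
            if best is None or key < best:
                best = key
                best_call = IsomiRCall(
                    tag=tag,
                    parent=entry.name,
                    variant_class=_variant_class(o5, o3, subs),
                    offsets=(o5, o3),
                    substitutions=subs,
                )
    if best_call is None:
        return TagAssignment(tag, "unknown", None)
    return TagAssignment(tag, "miRNA", best_call)


def _load_reference(ref: str | Path | Mapping[str, str]) -> dict[str, str]:
    if isinstance(ref, (str, Path)):
        with open(ref) as handle:
            return {
                title.split()[0]: normalize(seq)
                for title, seq in SimpleFastaParser(handle)
            }
    return {name: normalize(seq) for name, seq in ref.items()}


def classify_noncoding(
    tag: str,
    catalog: MiRNACatalog | Iterable[MatureMiRNA],
    trna_ref: str | Path | Mapping[str, str],
    rrna_ref: str | Path | Mapping[str, str],
    **match_kwargs,
) -> TagAssignment:
    """Classify a tag with precedence miRNA > tRF > rRF > unknown.

    tRF/rRF assignment requires the full tag to be an exact substring of a
    reference sequence, on the stated strand only.
    """
    hit = match_tag(tag, catalog, **match_kwargs)
    if hit.cls == "miRNA":
        return hit
    for cls, ref in (("tRF", trna_ref), ("rRF", rrna_ref)):
        for name, seq in _load_reference(ref).items():
            if tag in seq:
                return TagAssignment(tag, cls, name)
    return TagAssignment(tag, "unknown", None)


def conserved_tags(
    tag_tables: Sequence[TagTable], min_count: int = 1
) -> set[str]:
    """Tags present (count >= min_count) in every sample of every species."""
    if not tag_tables or any(t.counts.empty for t in tag_tables):
        raise ValueError("each tag table must be non-empty")
    conserved: set[str] | None = None
    for table in tag_tables:
        present = set(table.counts.index[(table.counts >= min_count).all(axis=1)])
        conserved = present if conserved is None else conserved & present
    return conserved or set()


def partition_conserved(
    conserved: Iterable[str],
    catalog: MiRNACatalog | Iterable[MatureMiRNA],
    trna_ref: str | Path | Mapping[str, str],
    rrna_ref: str | Path | Mapping[str, str],
    **match_kwargs,
) -> dict[str, set[str]]:
    """Partition a conserved tag set into miRNA / tRF / rRF / unknown, with
    the seed-variant isomiRs reported as a subset of the miRNA class.

    Returns keys ``mirna``, ``seed_sub`` (subset of ``mirna``), ``trf``,
    ``rrf``, ``unknown``; the top-level classes are pairwise disjoint and
    their union is the input set.
    """
    catalog = list(catalog)
    trna = _load_reference(trna_ref)
    rrna = _load_reference(rrna_ref)
    out: dict[str, set[str]] = {
        "mirna": set(),
        "seed_sub": set(),
        "trf": set(),
        "rrf": set(),
        "unknown": set(),
    }
    for tag in conserved:
        assignment = classify_noncoding(tag, catalog, trna, rrna, **match_kwargs)
        if assignment.cls == "miRNA":
            out["mirna"].add(tag)
            if assignment.detail.variant_class == "seed_sub":
                out["seed_sub"].add(tag)
        elif assignment.cls == "tRF":
            out["trf"].add(tag)
        elif assignment.cls == "rRF":
            out["rrf"].add(tag)
        else:
            out["unknown"].add(tag)
    return out


def aggregate_mirna_counts(
    table: TagTable,
    catalog: MiRNACatalog | Iterable[MatureMiRNA],
    **match_kwargs,
):
    """Sum tag counts per parent miRNA (canonical + isomiR tags together).

    Returns a features-by-samples DataFrame keyed by miRNA name, the input
    for differential expression of annotated miRNAs.
    """
    import pandas as pd

    catalog = list(catalog)
    rows: dict[str, "pd.Series"] = {}
    for tag in table.counts.index:
        hit = match_tag(tag, catalog, **match_kwargs)
        if hit.cls != "miRNA":
            continue
        parent = hit.detail.parent
        if parent in rows:
            rows[parent] = rows[parent] + table.counts.loc[tag]
        else:
            rows[parent] = table.counts.loc[tag].copy()
    if not rows:
        return pd.DataFrame(columns=table.counts.columns, dtype=int)
    df = pd.DataFrame(rows).T.astype(int)
    df.index.name = "mirna"
    return df.sort_index()
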