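"""Small-RNA read handling: parsing, adapter clipping, quality trimming and
collapsing reads into unique sequence tags with per-sample counts.

The unit of downstream analysis is the *sequence tag*: a unique 20-25 nt
insert sequence with a count per sample. Reads are 3'-adapter clipped
(small-RNA inserts are shorter than the read, so a missing adapter means the
insert was not fully sequenced and the read is discarded), quality trimmed
by first-failure 3' truncation, then collapsed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._dna import normalize

DEFAULT_LENGTH_BOUNDS = (20, 25)


class FileFormatError(ValueError):
    """Raised for malformed FASTQ/FASTA records; names the offending line."""


@dataclass
class Read:
    """A sequencing read; qualities are Phred scores, absent for FASTA."""

    id: str
    sequence: str
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise FileFormatError(
                f"read {self.id!r}: sequence and quality lengths differ"
            )


def _infer_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    if suffix in {".fa", ".fasta", ".fna"}:
        return "fasta"
    raise ValueError(f"cannot infer sequence format from {path}")


def read_sequences(path: str | Path, format: str | None = None) -> Iterator[Read]:
    """Stream reads from a FASTQ (Phred+33) or FASTA file.

    Sequences are uppercased and U->T normalized. Malformed records raise
    :class:`FileFormatError` naming the line where the record starts.
    """
    fmt = format or _infer_format(path)
    if fmt not in {"fastq", "fasta"}:
        raise ValueError(f"unsupported format {fmt!r}")
    with open(path) as handle:
        if fmt == "fastq":
            parser = FastqGeneralIterator(handle)
            index = 0
            while True:
                line = 4 * index + 1
                try:
                    title, seq, qual = next(parser)
                except StopIteration:
                    return
                except ValueError as exc:
                    raise FileFormatError(
                        f"{path}: malformed FASTQ record at line {line}: {exc}"
                    ) from exc
                if len(seq) != len(qual):
                    raise FileFormatError(
                        f"{path}: sequence/quality length mismatch at line {line}"
                    )
                yield Read(
                    id=title.split()[0],
                    sequence=normalize(seq),
                    qualities=[ord(c) - 33 for c in qual],
                )
                index += 1
        else:
            try:
                for title, seq in SimpleFastaParser(handle):
                    yield Read(id=title.split()[0], sequence=normalize(seq))
            except ValueError as exc:
                raise FileFormatError(f"{path}: malformed FASTA: {exc}") from exc


def clip_adapter(
    sequence: str,
    adapter: str,
    min_overlap: int = 5,
    max_mismatch: int = 1,
) -> str | None:
    """Clip the 3' adapter from a read sequence.

    Finds the leftmost occurrence of the adapter -- either the full adapter
    anywhere in the read, or a 3'-terminal prefix of the adapter of length
    >= ``min_overlap`` -- allowing up to ``max_mismatch`` mismatches, and
    returns everything 5' of it. Returns ``None`` (discard) when no
    occurrence is found or the clipped insert is empty.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if not 1 <= min_overlap <= len(adapter):
        raise ValueError("require adapter length >= min_overlap >= 1")
    n = len(sequence)
    for start in range(n):
        span = min(len(adapter), n - start)
        if span < len(adapter) and span < min_overlap:
            break  # remaining terminal windows only get shorter
        if span < len(adapter) and start + span != n:
            continue  # partial adapter must sit at the 3' end
        mismatches = sum(
            1 for a, b in zip(sequence[start : start + span], adapter) if a != b
        )
        if mismatches <= max_mismatch:
            return sequence[:start] if start > 0 else None
    return None


def quality_trim(
    sequence: str, qualities: Sequence[int] | None, q_threshold: int = 20
) -> str:
    """3'-truncate at the first base whose Phred score falls below threshold.

    Identity for quality-less (FASTA) reads.
    """
    if qualities is None:
        return sequence
    for i, q in enumerate(qualities):
        if q < q_threshold:
            return sequence[:i]
    return sequence


@dataclass
class TagTable:
    """Unique sequence tags x samples count table.

    ``counts`` is a features-by-samples integer DataFrame indexed by tag
    sequence; every tag length lies within ``length_bounds``.
    """

    counts: pd.DataFrame
    length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def __post_init__(self) -> None:
        lo, hi = self.length_bounds
        bad = [t for t in self.counts.index if not lo <= len(t) <= hi]
        if bad:
            raise ValueError(f"tag lengths outside bounds {self.length_bounds}: {bad[:3]}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative tag counts")

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "sequence"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(
        cls, path: str | Path, length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS
    ) -> "TagTable":
        df = pd.read_csv(path, sep="\t", index_col="sequence")
        return cls(df.astype(int), length_bounds)


def collapse_tags(
    reads_per_sample: Mapping[str, Iterable[str]],
    length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS,
) -> TagTable:
    """Collapse clipped/trimmed read sequences into a TagTable.

    Sequences outside ``length_bounds`` are excluded; the retained read count
    equals the total tag count per sample (conservation). Empty input yields
    an empty table.
    """
    lo, hi = length_bounds
    samples = list(reads_per_sample)
    per_sample: dict[str, dict[str, int]] = {}
    for sample in samples:
        tally: dict[str, int] = {}
        for seq in reads_per_sample[sample]:
            if lo <= len(seq) <= hi:
                tally[seq] = tally.get(seq, 0) + 1
        per_sample[sample] = tally
    all_tags = sorted(set().union(*per_sample.values())) if per_sample else []
    df = pd.DataFrame(
        {s: [per_sample[s].get(t, 0) for t in all_tags] for s in samples},
        index=pd.Index(all_tags, name="sequence"),
        dtype=int,
    )
    return TagTable(df, length_bounds)


def process_reads(
    reads: Iterable[Read],
    adapter: str,
    min_overlap: int = 5,
    max_mismatch: int = 1,
    q_threshold: int = 20,
) -> list[str]:
    """Clip + quality-trim a read stream, returning surviving insert sequences."""
    out = []
    for read in reads:
        clipped = clip_adapter(read.sequence, adapter, min_overlap, max_mismatch)
        if not clipped:
            continue
        quals = read.qualities[: len(clipped)] if read.qualities is not None else None
        trimmed = quality_trim(clipped, quals, q_threshold)
        if trimmed:
            out.append(trimmed)
    return out
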