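"""Read cleanup: adapter trimming, length/junk filtering, tag collapsing and
contaminant subtraction.

Rejection accounting is kept per reason so that raw = rejected + filtered
holds exactly at every run (the conservation checked by the pipeline).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from ._util import revcomp

MIN_LEN = 15
MAX_LEN = 26

#: sentinel returned by trim_adapter when no adapter evidence is found
REJECTED = None


@dataclass
class SmallRNATag:
    """A unique collapsed read sequence with per-library counts."""

    sequence: str
    count_female: int = 0
    count_male: int = 0

    @property
    def total(self) -> int:
        return self.count_female + self.count_male


@dataclass
class FilterStats:
    raw_reads: int = 0
    no_adapter: int = 0
    length_rejected: int = 0
    junk_rejected: int = 0
    filtered_reads: int = 0  # survivors entering collapse

    def check_conservation(self) -> None:
        rejected = self.no_adapter + self.length_rejected + self.junk_rejected
        assert self.raw_reads == rejected + self.filtered_reads, (
            "read accounting violated"
        )


@dataclass
class LibraryAccounting:
    """Mappable-read accounting in the style of a per-library annotation table."""

    library: str
    raw_reads: int
    after_filter_reads: int
    mappable_reads: int
    categories: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        assert self.mappable_reads <= self.after_filter_reads <= self.raw_reads
        assert sum(self.categories.values()) == self.mappable_reads, (
            "categories must sum exactly to mappable reads"
        )


def trim_adapter(read: str, adapter: str, min_overlap: int = 6) -> Optional[str]:
    """Return the insert upstream of the leftmost adapter occurrence.

    A full adapter match anywhere wins; otherwise a >= ``min_overlap`` prefix
    of the adapter at the read's 3' end counts as evidence.  ``REJECTED``
    (None) when no adapter evidence is found or the read is empty.
    """
    if not 1 <= min_overlap <= len(adapter):
        raise ValueError("require adapter length >= min_overlap >= 1")
    if not read:
        return REJECTED
    hit = read.find(adapter)
    if hit >= 0:
        return read[:hit]
    for k in range(min(len(adapter) - 1, len(read)), min_overlap - 1, -1):
        if read.endswith(adapter[:k]):
            return read[: len(read) - k]
    return REJECTED


def filter_length(insert: str, min_len: int = MIN_LEN, max_len: int = MAX_LEN) -> bool:
    """KEEP (True) iff min_len <= length <= max_len (inclusive window)."""
    return min_len <= len(insert) <= max_len


def drop_junk(insert: str) -> bool:
    """DROP (True) iff the insert has a non-ACGT symbol or any single base
    makes up >= 80% of positions (low-complexity rule)."""
    counts = Counter(insert)
    if set(counts) - set("ACGT"):
        return True
    return max(counts.values()) >= 0.8 * len(insert)


def clean_reads(reads: Iterable[str], adapter: str, min_overlap: int = 6,
                min_len: int = MIN_LEN, max_len: int = MAX_LEN
                ) -> tuple[list[str], FilterStats]:
    """Run the adapter/length/junk cascade over raw read sequences."""
    stats = FilterStats()
    kept: list[str] = []
    for read in reads:
        stats.raw_reads += 1
        insert = trim_adapter(read, adapter, min_overlap)
        if insert is REJECTED:
            stats.no_adapter += 1
            continue
        if not filter_length(insert, min_len, max_len):
            stats.length_rejected += 1
            continue
        if drop_junk(insert):
            stats.junk_rejected += 1
            continue
        stats.filtered_reads += 1
        kept.append(insert)
    stats.check_conservation()
    return kept, stats


def collapse(female_inserts: Iterable[str],
             male_inserts: Iterable[str]) -> list[SmallRNATag]:
    """One tag per distinct sequence, sorted by total count descending then
    sequence ascending; per-library count sums are preserved exactly."""
    cf = Counter(female_inserts)
    cm = Counter(male_inserts)
    tags = [
        SmallRNATag(seq, cf.get(seq, 0), cm.get(seq, 0))
        for seq in set(cf) | set(cm)
    ]
    tags.sort(key=lambda t: (-t.total, t.sequence))
    return tags


def subtract_contaminants(
    tags: list[SmallRNATag],
    contaminant_refs: list[tuple[str, str, str]],
) -> tuple[list[SmallRNATag], list[tuple[str, str, str]]]:
    """Split tags into (clean, contaminant assignments).

    A tag is a contaminant iff it occurs exactly as a substring of a
    contaminant reference on either strand; assignments are
    (tag sequence, reference name, reference class).
    """
    haystack = "#".join(seq for _, seq, _ in contaminant_refs)
    clean: list[SmallRNATag] = []
    assigned: list[tuple[str, str, str]] = []
    for tag in tags:
        rc = revcomp(tag.sequence)
        if tag.sequence not in haystack and rc not in haystack:
            clean.append(tag)
            continue
        for name, seq, cls in contaminant_refs:
            if tag.sequence in seq or rc in seq:
                assigned.append((tag.sequence, name, cls))
                break
        else:  # separator-spanning false positive
            clean.append(tag)
    return clean, assigned


def write_collapsed_fasta(path, tags: list[SmallRNATag], library: str) -> None:
    """Collapsed-FASTA dialect with headers ``tag{index}_x{count}``."""
    count_of = {
        "female": lambda t: t.count_female,
        "male": lambda t: t.count_male,
    }[library]
    with open(path, "w") as fh:
        for i, tag in enumerate(t for t in tags if count_of(t) > 0):
            fh.write(f">tag{i + 1}_x{count_of(tag)}\n{tag.sequence}\n")
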