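"""Tag annotation: known-miRNA matching, known/KC splitting, star detection,
isomiR variation classes and 5' first-base composition.

Matching is ungapped: a tag matches a mature reference if, at some offset
allowing a 5'/3' overhang of at most 3 nt on either side, the Hamming
distance over the overlap is <= 1 and the overlap is >= 15 nt.  Indel-like
variants are therefore captured as 5'/3' length variation rather than as
mismatches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from ._util import revcomp, to_dna
from .folding import parse_pairs, stacking_fold
from .preprocess import SmallRNATag
from .simulate import Precursor

logger = logging.getLogger(__name__)

MAX_MISMATCH = 1
MAX_OVERHANG = 3
MIN_OVERLAP = 15
_PREFILTER_K = 7  # an <=1-mismatch, >=15-nt overlap match shares an exact 7-mer


@dataclass(frozen=True)
class Alignment:
    ref_name: str
    offset: int      # position of tag[0] in reference coordinates (may be < 0)
    mismatches: int
    overlap: int


@dataclass
class AnnotationRecord:
    tag: str
    status: str                   # known | KC | star | unknown
    ref_name: str | None = None
    mismatches: int | None = None
    arm: str = "NA"               # 5p | 3p | NA
    variation: str = "none"


@dataclass
class MiRNACountRow:
    name: str                     # display name; KC rows carry the 'KC-' prefix
    representative: str           # variant sequence with the most reads
    count_female: int
    count_male: int
    status: str = "known"

    @property
    def total(self) -> int:
        return self.count_female + self.count_male


@dataclass
class StarRecord:
    mature_name: str
    precursor_name: str
    star_tags: list[str]
    count_female: int
    count_male: int
    mature_count_female: int
    mature_count_male: int

    @property
    def ratio(self) -> float:
        mat = self.mature_count_female + self.mature_count_male
        return (self.count_female + self.count_male) / mat if mat else float("inf")

    @property
    def dominant(self) -> bool:
        return self.ratio > 1.0


def _align_pair(tag: str, ref: str, max_mismatch: int = MAX_MISMATCH,
                max_overhang: int = MAX_OVERHANG,
                min_overlap: int = MIN_OVERLAP) -> tuple[int, int, int] | None:
    """Best ungapped placement of tag on ref: (mismatches, overlap, offset),
    minimizing mismatches then maximizing overlap then smallest offset."""
    lt, lr = len(tag), len(ref)
    best = None
    for o in range(-max_overhang, lr + max_overhang - lt + 1):
        lo, hi = max(0, o), min(lr, o + lt)
        overlap = hi - lo
        if overlap < min_overlap:
            continue
        mm = 0
        for p in range(lo, hi):
            if ref[p] != tag[p - o]:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            key = (mm, -overlap, o)
            if best is None or key < best[0]:
                best = (key, (mm, overlap, o))
    return best[1] if best else None


def match_known(tag: str, mature_refs: list[tuple[str, str]],
                max_mismatch: int = MAX_MISMATCH,
                max_overhang: int = MAX_OVERHANG,
                min_overlap: int = MIN_OVERLAP) -> Alignment | None:
    """Best mature-reference assignment: fewest mismatches, then longest
    overlap, then lexicographically first reference name; None if no match."""
    best: tuple | None = None
    for name, seq in mature_refs:
        hit = _align_pair(tag, to_dna(seq), max_mismatch, max_overhang, min_overlap)
        if hit is None:
            continue
        mm, overlap, offset = hit
        key = (mm, -overlap, name)
        if best is None or key < best[0]:
            best = (key, Alignment(name, offset, mm, overlap))
    return best[1] if best else None


class _KmerIndex:
    """Exact 7-mer prefilter; guarantees no false negatives for the
    <=1-mismatch, >=15-overlap matching rule (a shared exact run >= 7 nt
    always exists in such a match)."""

    def __init__(self, refs: list[tuple[str, str]], k: int = _PREFILTER_K):
        self.k = k
        self.refs = [(name, to_dna(seq)) for name, seq in refs]
        self.index: dict[str, set[int]] = {}
        for i, (_name, seq) in enumerate(self.refs):
            for j in range(len(seq) - k + 1):
                self.index.setdefault(seq[j : j + k], set()).add(i)

    def candidates(self, tag: str) -> list[tuple[str, str]]:
        hits: set[int] = set()
        for j in range(len(tag) - self.k + 1):
            hits |= self.index.get(tag[j : j + self.k], set())
        return [self.refs[i] for i in sorted(hits)]


def split_known_vs_kc(mature_names: list[str],
                      precursor_by_mature: dict[str, Precursor],
                      genome: dict[str, str]) -> dict[str, tuple[str, str]]:
    """Per-miRNA status: 'known' iff the precursor occurs exactly (either
    strand) in the genome, else 'KC' with a 'KC-'-prefixed display name."""
    out: dict[str, tuple[str, str]] = {}
    contigs = list(genome.values())
    for name in mature_names:
        prec = precursor_by_mature.get(name)
        if prec is None:
            logger.warning("no precursor for assigned miRNA %s; treated as KC", name)
            out[name] = ("KC", f"KC-{name}")
            continue
        rc = revcomp(prec.seq)
        mapped = any(prec.seq in c or rc in c for c in contigs)
        out[name] = ("known", name) if mapped else ("KC", f"KC-{name}")
    return out


def classify_variation(tag: str, ref_seq: str) -> str:
    """IsomiR class of a tag relative to its assigned mature reference.

    Reference coordinates are 1-based; seed = positions 2-8.  A substitution
    at the very first position counts as a 5'-end variation (the 5' terminal
    base differs); substitutions strictly inside the seed with identical
    termini are reported as the flagged class 'seed_variant'.
    """
    ref = to_dna(ref_seq)
    hit = _align_pair(tag, ref)
    if hit is None:
        raise ValueError("tag does not align to the reference within tolerance")
    _mm, _overlap, o = hit
    cats: set[str] = set()
    seed_sub = False
    if o != 0:
        cats.add("five_prime_end")
    if o + len(tag) != len(ref):
        cats.add("three_prime_end")
    for p in range(max(0, o), min(len(ref), o + len(tag))):
        if ref[p] == tag[p - o]:
            continue
        pos = p + 1
        if pos == 1:
            cats.add("five_prime_end")
        elif 2 <= pos <= 8:
            seed_sub = True
        elif 9 <= pos <= 15:
            cats.add("seed_adjacent")
        else:
            cats.add("three_prime_end")
    if seed_sub:
        if not cats:
            return "seed_variant"
        return "mixed"
    if not cats:
        return "none"
    if len(cats) == 1:
        return cats.pop()
    return "mixed"


def group_count_rows(assignments: dict[str, Alignment],
                     tag_counts: dict[str, tuple[int, int]],
                     status_by_name: dict[str, tuple[str, str]]) -> list[MiRNACountRow]:
    """Group tag-level assignments into per-miRNA count rows.

    The representative is the variant with the most total reads (ties broken
    lexicographically); per-library counts sum over all grouped variants.
    """
    groups: dict[str, list[str]] = {}
    for tag, aln in assignments.items():
        groups.setdefault(aln.ref_name, []).append(tag)
    rows = []
    for name, tags in groups.items():
        tags.sort(key=lambda t: (-(tag_counts[t][0] + tag_counts[t][1]), t))
        cf = sum(tag_counts[t][0] for t in tags)
        cm = sum(tag_counts[t][1] for t in tags)
        status, display = status_by_name[name]
        rows.append(MiRNACountRow(display, tags[0], cf, cm, status))
    rows.sort(key=lambda r: (-r.total, r.name))
    return rows


def detect_star(unassigned: list[SmallRNATag],
                precursors: list[Precursor],
                count_rows: list[MiRNACountRow]) -> list[StarRecord]:
    """Find star-strand tags: <=1-mismatch ungapped placements on the arm
    opposite an observed mature of the same precursor."""
    observed = {}
    for row in count_rows:
        observed[row.name.removeprefix("KC-")] = row
    active = [p for p in precursors if p.mature_name in observed]
    if not active:
        return []
    index = _KmerIndex([(p.name, p.seq) for p in active])
    by_name = {p.name: p for p in active}
    hits: dict[str, list[tuple[str, SmallRNATag]]] = {}
    for tag in unassigned:
        for pname, pseq in index.candidates(tag.sequence):
            prec = by_name[pname]
            hit = _align_pair(tag.sequence, pseq)
            if hit is None:
                continue
            _mm, _overlap, o = hit
            lo, hi = o, o + len(tag.sequence)
            if prec.star_start - MAX_OVERHANG <= lo and hi <= prec.star_end + MAX_OVERHANG:
                hits.setdefault(pname, []).append((tag.sequence, tag))
                break
    records = []
    for pname, tagged in sorted(hits.items()):
        prec = by_name[pname]
        row = observed[prec.mature_name]
        records.append(
            StarRecord(
                mature_name=prec.mature_name,
                precursor_name=pname,
                star_tags=sorted(t for t, _ in tagged),
                count_female=sum(t.count_female for _, t in tagged),
                count_male=sum(t.count_male for _, t in tagged),
                mature_count_female=row.count_female,
                mature_count_male=row.count_male,
            )
        )
    return records


def first_base_composition(rows: list[MiRNACountRow],
                           weighted: bool = True) -> dict[str, float]:
    """Fractions of the 5' first base over {A, C, G, U}.

    Read-weighted by default; ``weighted=False`` counts each miRNA once
    (the composition of the identified catalog rather than of the reads).
    """
    if not rows:
        raise ValueError("no count rows given")
    weights = {b: 0.0 for b in "ACGU"}
    total = 0.0
    for row in rows:
        first = row.representative[0].replace("T", "U")
        w = row.total if weighted else 1.0
        weights[first] += w
        total += w
    if total == 0:
        raise ValueError("all count rows are empty")
    return {b: w / total for b, w in weights.items()}


def infer_precursor(name: str, seq: str, mature_name: str,
                    mature_seq: str) -> Precursor | None:
    """Reconstruct arm coordinates for an externally supplied precursor.

    Locates the mature as an exact substring and takes the star arm as the
    span of positions pairing with the mature under the default fold engine.
    """
    seq = to_dna(seq)
    ms = seq.find(to_dna(mature_seq))
    if ms < 0:
        return None
    me = ms + len(mature_seq)
    db, _dg = stacking_fold(seq)
    partners = [
        (j if ms <= i < me else i)
        for i, j in parse_pairs(db)
        if ms <= i < me or ms <= j < me
    ]
    if not partners:
        return None
    return Precursor(name, seq, mature_name, ms, me,
                     min(partners), max(partners) + 1)


@dataclass
class AnnotationResult:
    records: list[AnnotationRecord]
    count_rows: list[MiRNACountRow]
    star_records: list[StarRecord]
    unassigned: list[SmallRNATag] = field(default_factory=list)
    first_base: dict[str, float] = field(default_factory=dict)


def annotate_tags(tags: list[SmallRNATag],
                  mature_refs: list[tuple[str, str]],
                  precursor_by_mature: dict[str, Precursor],
                  genome: dict[str, str]) -> AnnotationResult:
    """Full annotation pass over clean tags.

    Every tag receives exactly one status: known / KC (mature match split by
    precursor-to-genome mapping), star (opposite-arm placement), or unknown.
    """
    refs = [(n, to_dna(s)) for n, s in mature_refs]
    index = _KmerIndex(refs)
    assignments: dict[str, Alignment] = {}
    tag_counts = {t.sequence: (t.count_female, t.count_male) for t in tags}
    unmatched: list[SmallRNATag] = []
    for tag in tags:
        cands = index.candidates(tag.sequence)
        aln = match_known(tag.sequence, cands) if cands else None
        if aln is None:
            unmatched.append(tag)
        else:
            assignments[tag.sequence] = aln

    status_by_name = split_known_vs_kc(
        sorted({a.ref_name for a in assignments.values()}),
        precursor_by_mature, genome,
    )
    count_rows = group_count_rows(assignments, tag_counts, status_by_name)
    star_records = detect_star(unmatched, list(precursor_by_mature.values()),
                               count_rows)
    star_tags = {t for rec in star_records for t in rec.star_tags}

    ref_seq = dict(refs)
    arm_of = {}
    for mname, prec in precursor_by_mature.items():
        arm_of[mname] = "5p" if prec.mature_start < prec.star_start else "3p"
    records: list[AnnotationRecord] = []
    for tag in tags:
        seq = tag.sequence
        if seq in assignments:
            aln = assignments[seq]
            status, _display = status_by_name[aln.ref_name]
            records.append(
                AnnotationRecord(
                    tag=seq,
                    status=status,
                    ref_name=aln.ref_name,
                    mismatches=aln.mismatches,
                    arm=arm_of.get(aln.ref_name, "NA"),
                    variation=classify_variation(seq, ref_seq[aln.ref_name]),
                )
            )
        elif seq in star_tags:
            rec = next(r for r in star_records if seq in r.star_tags)
            mature_arm = arm_of.get(rec.mature_name, "NA")
            star_arm = {"5p": "3p", "3p": "5p"}.get(mature_arm, "NA")
            records.append(
                AnnotationRecord(tag=seq, status="star",
                                 ref_name=rec.mature_name, arm=star_arm)
            )
        else:
            records.append(AnnotationRecord(tag=seq, status="unknown"))

    result = AnnotationResult(records, count_rows, star_records,
                              [t for t in unmatched
                               if t.sequence not in star_tags])
    if count_rows:
        result.first_base = first_base_composition(count_rows)
    return result
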