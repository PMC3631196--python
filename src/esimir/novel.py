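"""Novel miRNA prediction: genome mapping, flank extraction, hairpin folding
and the free-energy / stem-loop acceptance criteria.

A tag unassigned by annotation is mapped exactly to the proxy genome (both
strands, discarding repetitive tags with more than ``max_hits`` placements).
Two candidate precursor windows around each locus are folded; a window is
ACCEPTed when the fold reaches dG <= -15 kcal/mol, the dominant pairing forms
a single stem-loop, the tag lies entirely within one arm of that stem-loop,
and at least 14 of the tag's bases pair as a compact mature:star-style duplex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import revcomp
from .folding import FoldEngine, fold, main_stemloop
from .preprocess import SmallRNATag

DG_MAX = -15.0
FLANK = 70
INNER_FLANK = 15
MAX_GENOME_HITS = 10
MIN_TAG_PAIRED = 14
#: the genomic partners of the tag's paired bases must span at most
#: tag length + this slack (a mature:star duplex with modest bulges)
DUPLEX_SPAN_SLACK = 10


@dataclass(frozen=True)
class GenomeLocus:
    contig: str
    start: int   # 0-based, half-open, forward-strand coordinates
    end: int
    strand: str  # '+' | '-'


@dataclass
class HairpinCall:
    locus: GenomeLocus
    window: str
    tag: str
    tag_start: int          # tag offset within the window (tag orientation)
    structure: str = ""
    dg: float = 0.0
    decision: str = "REJECT"
    reason: str = ""
    count_female: int = 0
    count_male: int = 0

    @property
    def accepted(self) -> bool:
        return self.decision == "ACCEPT"


def map_to_genome(tag: str, genome: dict[str, str],
                  max_hits: int = MAX_GENOME_HITS) -> list[GenomeLocus]:
    """Exact both-strand occurrences; repetitive tags (> max_hits) return []."""
    loci: list[GenomeLocus] = []
    rc = revcomp(tag)
    for contig, seq in genome.items():
        for query, strand in ((tag, "+"), (rc, "-")):
            pos = seq.find(query)
            while pos >= 0:
                loci.append(GenomeLocus(contig, pos, pos + len(tag), strand))
                if len(loci) > max_hits:
                    return []
                pos = seq.find(query, pos + 1)
    loci.sort(key=lambda l: (l.contig, l.start, l.strand))
    return loci


def extract_flanks(locus: GenomeLocus, genome: dict[str, str],
                   upstream: int = FLANK, downstream: int = FLANK,
                   inner: int = INNER_FLANK) -> list[tuple[str, int]]:
    """Two candidate windows around the locus, as (window, tag offset) pairs.

    Window A extends ``upstream`` nt 5' of the tag (plus ``inner`` nt 3');
    window B extends ``downstream`` nt 3' (plus ``inner`` nt 5').  Both are
    clipped at contig bounds, and minus-strand loci are reverse-complemented
    so the tag always reads 5'->3' within the window.
    """
    seq = genome[locus.contig]
    n = len(seq)
    tag_len = locus.end - locus.start
    if locus.strand == "+":
        spans = [
            (max(0, locus.start - upstream), min(n, locus.end + inner)),
            (max(0, locus.start - inner), min(n, locus.end + downstream)),
        ]
        out = [(seq[a:b], locus.start - a) for a, b in spans]
    else:
        # in tag orientation, genomic downstream is the tag's 5' side
        spans = [
            (max(0, locus.start - inner), min(n, locus.end + upstream)),
            (max(0, locus.start - downstream), min(n, locus.end + inner)),
        ]
        out = [(revcomp(seq[a:b]), b - locus.end) for a, b in spans]
    return [(w, off) for w, off in out if len(w) >= tag_len]


def call_hairpin(window: str, structure: str, dg: float,
                 tag_start: int, tag_len: int,
                 dg_max: float = DG_MAX,
                 min_tag_paired: int = MIN_TAG_PAIRED,
                 duplex_span_slack: int = DUPLEX_SPAN_SLACK) -> tuple[str, str]:
    """(decision, reason) for one folded window.

    REJECT carries the first failed criterion: energy, multiloop (the longest
    helix does not anchor a single stem-loop), arm_placement, tag_pairing, or
    duplex_span (the tag's pairing partners are scattered instead of forming
    a compact mature:star-style duplex).
    """
    if dg > dg_max:
        return "REJECT", "energy"
    stem = main_stemloop(structure)
    if stem is None or stem == "multiloop":
        return "REJECT", "multiloop" if stem == "multiloop" else "no_hairpin"
    (_oi, _oj), (ii, ij) = stem["outer"], stem["inner"]
    ts, te = tag_start, tag_start + tag_len - 1  # inclusive
    # one arm = everything 5' of the loop-closing pair (or 3' of it); a tag
    # touching the loop interior or straddling onto the opposite arm fails
    in_5p = te <= ii
    in_3p = ts >= ij
    if not (in_5p or in_3p):
        return "REJECT", "arm_placement"
    pairs = _structure_pairs(structure)
    tag_pos = set(range(ts, te + 1))
    partners = sorted(j if i in tag_pos else i
                      for i, j in pairs if i in tag_pos or j in tag_pos)
    n_paired = len({k for i, j in pairs for k in (i, j) if k in tag_pos})
    needed = min(min_tag_paired, tag_len)
    if n_paired < needed:
        return "REJECT", "tag_pairing"
    # duplex compactness: at least `needed` of the tag's pairing partners
    # must fall inside one window of tag length + slack (a mature:star-style
    # duplex, tolerating a couple of stray long-range pairs)
    width = tag_len + duplex_span_slack
    best = 0
    lo = 0
    for hi in range(len(partners)):
        while partners[hi] - partners[lo] + 1 > width:
            lo += 1
        best = max(best, hi - lo + 1)
    if best < needed:
        return "REJECT", "duplex_span"
    return "ACCEPT", ""


def _structure_pairs(structure: str):
    from .folding import parse_pairs

    return parse_pairs(structure)


@dataclass
class NovelMiRNA:
    name: str
    locus: GenomeLocus
    tag: str
    dg: float
    structure: str
    window: str
    count_female: int
    count_male: int


def predict_novel(tags: list[SmallRNATag], genome: dict[str, str],
                  engine: FoldEngine | None = None,
                  dg_max: float = DG_MAX, flank: int = FLANK,
                  max_hits: int = MAX_GENOME_HITS,
                  min_tag_paired: int = MIN_TAG_PAIRED
                  ) -> tuple[list[HairpinCall], list[NovelMiRNA]]:
    """Run the full novel-prediction stage over unassigned tags."""
    calls: list[HairpinCall] = []
    for tag in tags:
        for locus in map_to_genome(tag.sequence, genome, max_hits):
            for window, off in extract_flanks(locus, genome, flank, flank):
                call = HairpinCall(locus, window, tag.sequence, off,
                                   count_female=tag.count_female,
                                   count_male=tag.count_male)
                if not 40 <= len(window) <= 200:
                    call.reason = "window_length"
                    calls.append(call)
                    continue
                call.structure, call.dg = fold(window, engine)
                call.decision, call.reason = call_hairpin(
                    window, call.structure, call.dg, off, len(tag.sequence),
                    dg_max, min_tag_paired,
                )
                calls.append(call)
    return calls, dedupe_and_name([c for c in calls if c.accepted])


def dedupe_and_name(accepted: list[HairpinCall]) -> list[NovelMiRNA]:
    """Merge accepted calls whose loci overlap >= 50% reciprocally, keeping
    the lowest-dG call per group; names 'esi-novel-N' follow genome order."""
    groups: list[list[HairpinCall]] = []
    for call in sorted(accepted, key=lambda c: (c.locus.contig, c.locus.start,
                                                c.locus.end, c.dg)):
        for group in groups:
            ref = group[0].locus
            loc = call.locus
            if ref.contig != loc.contig:
                continue
            ov = min(ref.end, loc.end) - max(ref.start, loc.start)
            if ov <= 0:
                continue
            if (ov >= 0.5 * (ref.end - ref.start)
                    and ov >= 0.5 * (loc.end - loc.start)):
                group.append(call)
                break
        else:
            groups.append([call])
    out = []
    for i, group in enumerate(
        sorted(groups, key=lambda g: (g[0].locus.contig, g[0].locus.start))
    ):
        best = min(group, key=lambda c: (c.dg, c.locus.start))
        out.append(
            NovelMiRNA(
                name=f"esi-novel-{i + 1}",
                locus=best.locus,
                tag=best.tag,
                dg=best.dg,
                structure=best.structure,
                window=best.window,
                count_female=sum({c.tag: c.count_female for c in group}.values()),
                count_male=sum({c.tag: c.count_male for c in group}.values()),
            )
        )
    return out


def shuffle_controls(calls: list[HairpinCall], seed: int,
                     engine: FoldEngine | None = None,
                     dg_max: float = DG_MAX,
                     min_tag_paired: int = MIN_TAG_PAIRED,
                     replicates: int = 1) -> list[HairpinCall]:
    """Shuffled-flank negative controls for the false-call rate.

    For each input call the tag is kept in place and the flanking window
    positions are permuted (``replicates`` times), destroying any genuine
    hairpin context while preserving composition; the same acceptance
    criteria are then applied.
    """
    rng = np.random.default_rng(seed)
    controls = []
    for call in calls:
        for _rep in range(replicates):
            w = list(call.window)
            ts, te = call.tag_start, call.tag_start + len(call.tag)
            flanks = w[:ts] + w[te:]
            rng.shuffle(flanks)
            shuffled = "".join(flanks[:ts]) + call.tag + "".join(flanks[ts:])
            ctrl = HairpinCall(call.locus, shuffled, call.tag, ts)
            ctrl.structure, ctrl.dg = fold(shuffled, engine)
            ctrl.decision, ctrl.reason = call_hairpin(
                shuffled, ctrl.structure, ctrl.dg, ts, len(call.tag),
                dg_max, min_tag_paired,
            )
            controls.append(ctrl)
    return controls
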