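"""Synthetic reference bundles and paired small-RNA libraries with ground truth.

The generator emulates the statistical structure of a two-library (female /
male) insect small-RNA sequencing experiment: ~22-nt modal insert lengths,
heavy-tailed (log-normal) miRNA abundance with a few dominating miRNAs,
low-ratio star strands, isomiR variation at the 5' end, at seed-adjacent
positions 9-15 and at the 3' end, a "known-candidate" subset of matures whose
precursors are absent from the proxy genome, planted novel hairpin loci, and
a configurable differentially-expressed subset with exact expected
male/female fold changes.  Every simulated read is covered by one truth
record, so each downstream stage can be scored for recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import revcomp, write_fasta, write_fastq
from .folding import stacking_fold

BASES = "ACGT"

#: standard Illumina TruSeq small-RNA 3' adapter (the adapter is a free parameter)
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

CONTAMINANT_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat")


class CapacityError(ValueError):
    """Planted loci do not fit in the genome without overlap."""


class EmptySimulationError(ValueError):
    """Requested library depth is zero."""


@dataclass(frozen=True)
class Precursor:
    """A hairpin precursor with recorded mature/star arm coordinates (0-based,
    half-open, precursor coordinates)."""

    name: str
    seq: str
    mature_name: str
    mature_start: int
    mature_end: int
    star_start: int
    star_end: int

    @property
    def mature_seq(self) -> str:
        return self.seq[self.mature_start : self.mature_end]

    @property
    def star_seq(self) -> str:
        return self.seq[self.star_start : self.star_end]


@dataclass(frozen=True)
class PlantedLocus:
    name: str
    kind: str  # 'known' | 'novel'
    contig: str
    start: int
    end: int
    strand: str


@dataclass
class ReferenceBundle:
    mature: list[tuple[str, str]]          # known + KC matures (DNA alphabet)
    kc_names: set[str]
    precursors: list[Precursor]            # precursors of known + KC matures
    novel_precursors: list[Precursor]      # planted loci; matures not in `mature`
    contaminants: list[tuple[str, str, str]]
    genome: dict[str, str]
    loci: list[PlantedLocus]

    @property
    def precursor_by_mature(self) -> dict[str, Precursor]:
        return {p.mature_name: p for p in self.precursors}


@dataclass
class SimulationConfig:
    depth_per_library: int = 100_000
    adapter: str = DEFAULT_ADAPTER
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.5
    de_subset: dict[str, float] = field(default_factory=dict)
    star_ratio: float = 0.05
    isomir_rates: dict[str, float] = field(
        default_factory=lambda: {
            "five_prime": 0.05,
            "seed_adjacent": 0.05,
            "three_prime": 0.15,
        }
    )
    contaminant_fraction: float = 0.15
    novel_fraction: float = 0.02
    junk_fraction: float = 0.45
    seed: int = 0

    def validate(self) -> None:
        if self.depth_per_library == 0:
            raise EmptySimulationError("depth_per_library must be > 0")
        if self.depth_per_library < 0:
            raise ValueError("depth_per_library must be positive")
        fracs = (self.contaminant_fraction, self.novel_fraction, self.junk_fraction)
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if sum(fracs) > 1.0:
            raise ValueError("category fractions sum to more than 1")
        if not 0.0 < self.star_ratio <= 1.0:
            raise ValueError("star_ratio must be in (0, 1]")
        for k, v in self.isomir_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"isomir rate {k} outside [0, 1]")
        if any(fc <= 0 for fc in self.de_subset.values()):
            raise ValueError("fold changes must be > 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class SimResult:
    reads_female: list[tuple[str, str]]
    reads_male: list[tuple[str, str]]
    truth: pd.DataFrame  # read_id, library, tag, source, true_class, variation, fold_change


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[b] for b in rng.integers(0, 4, n))


def _make_mature(rng: np.random.Generator, ua_first_prob: float) -> str:
    n = int(rng.integers(21, 24))
    if rng.random() < ua_first_prob:
        first = "T" if rng.random() < 0.5 else "A"
    else:
        first = "C" if rng.random() < 0.5 else "G"
    return first + _rand_seq(rng, n - 1)


def _make_precursor(rng: np.random.Generator, name: str, mature_name: str,
                    mature: str) -> Precursor:
    """leader + mature (5' arm) + loop + star (3' arm) + trailer.

    The star arm is the reverse complement of the mature with 1-2 interior
    substitutions, giving an imperfect but strongly pairing stem.
    """
    leader = _rand_seq(rng, 3)
    trailer = _rand_seq(rng, 3)
    loop = _rand_seq(rng, int(rng.integers(9, 14)))
    star = list(revcomp(mature))
    for pos in rng.choice(
        np.arange(3, len(star) - 3), size=int(rng.integers(1, 3)), replace=False
    ):
        star[pos] = BASES[(BASES.index(star[pos]) + int(rng.integers(1, 4))) % 4]
    star_seq = "".join(star)
    seq = leader + mature + loop + star_seq + trailer
    ms = len(leader)
    ss = ms + len(mature) + len(loop)
    prec = Precursor(name, seq, mature_name, ms, ms + len(mature),
                     ss, ss + len(star_seq))
    _, dg = stacking_fold(seq)
    assert dg <= -15.0, f"precursor {name} fails the dG <= -15 criterion ({dg})"
    return prec


def make_reference_bundle(
    n_known: int,
    n_kc: int,
    n_novel_loci: int,
    n_contaminants: int,
    seed: int,
    genome_len: int = 30_000,
    ua_first_prob: float = 0.815,
) -> ReferenceBundle:
    """Build a deterministic reference bundle with planted ground truth.

    Known matures have precursors planted in the genome; KC matures have
    precursors in the reference set but absent from the genome; novel loci
    are hairpins planted in the genome whose matures are NOT in the mature
    reference set (to be rediscovered).  ``ua_first_prob`` biases the first
    5' base of matures towards U/A, mirroring the strong U/A preference seen
    in real mature miRNA sets.
    """
    if min(n_known, n_kc, n_novel_loci, n_contaminants) < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)

    mature: list[tuple[str, str]] = []
    seen: set[str] = set()
    precursors: list[Precursor] = []
    kc_names: set[str] = set()

    def fresh_mature() -> str:
        while True:
            m = _make_mature(rng, ua_first_prob)
            if m not in seen:
                seen.add(m)
                return m

    for i in range(n_known):
        name = f"esi-miR-{i + 1}"
        m = fresh_mature()
        mature.append((name, m))
        precursors.append(_make_precursor(rng, f"esi-mir-{i + 1}", name, m))
    for j in range(n_kc):
        name = f"esi-miR-{n_known + j + 1}"
        m = fresh_mature()
        mature.append((name, m))
        kc_names.add(name)
        precursors.append(
            _make_precursor(rng, f"esi-mir-{n_known + j + 1}", name, m)
        )

    novel_precursors = [
        _make_precursor(rng, f"novel-locus-{k + 1}", f"novel-{k + 1}", fresh_mature())
        for k in range(n_novel_loci)
    ]

    contaminants = [
        (
            f"{CONTAMINANT_CLASSES[c % len(CONTAMINANT_CLASSES)]}-{c + 1}",
            _rand_seq(rng, int(rng.integers(80, 201))),
            CONTAMINANT_CLASSES[c % len(CONTAMINANT_CLASSES)],
        )
        for c in range(n_contaminants)
    ]

    # plant known + novel precursors in a random genome, non-overlapping
    to_plant = [(p, "known") for p in precursors[:n_known]] + [
        (p, "novel") for p in novel_precursors
    ]
    total = sum(len(p.seq) + 10 for p, _ in to_plant)
    if total > 0.9 * genome_len:
        raise CapacityError(
            f"{len(to_plant)} loci ({total} nt with spacing) exceed genome "
            f"capacity ({genome_len} nt)"
        )
    genome = list(_rand_seq(rng, genome_len))
    occupied: list[tuple[int, int]] = []
    loci: list[PlantedLocus] = []
    for prec, kind in to_plant:
        L = len(prec.seq)
        for _attempt in range(10_000):
            start = int(rng.integers(0, genome_len - L))
            if all(start >= e + 10 or start + L + 10 <= s for s, e in occupied):
                break
        else:
            raise CapacityError("could not place locus without overlap")
        strand = "+" if rng.random() < 0.5 else "-"
        planted = prec.seq if strand == "+" else revcomp(prec.seq)
        genome[start : start + L] = list(planted)
        occupied.append((start, start + L))
        loci.append(PlantedLocus(prec.name, kind, "chr1", start, start + L, strand))

    return ReferenceBundle(
        mature=mature,
        kc_names=kc_names,
        precursors=precursors,
        novel_precursors=novel_precursors,
        contaminants=contaminants,
        genome={"chr1": "".join(genome)},
        loci=loci,
    )


def default_config(bundle: ReferenceBundle, depth: int = 100_000,
                   seed: int = 0, **overrides) -> SimulationConfig:
    """Study-condition defaults with a 10-miRNA DE subset (8 down / 2 up,
    male relative to female) drawn from the more abundant known matures."""
    folds = [0.25, 0.2, 0.25, 0.125, 0.25, 0.2, 0.25, 0.125, 8.0, 4.0]
    known = [n for n, _ in bundle.mature if n not in bundle.kc_names]
    # mid-abundance ranks: keeps the DE mass a small share of mappable reads,
    # as in real libraries, so composition shifts do not distort null CPMs
    de = {name: fc for name, fc in zip(known[5:15], folds)}
    cfg = SimulationConfig(depth_per_library=depth, de_subset=de, seed=seed)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def _mirna_probs(bundle: ReferenceBundle, config: SimulationConfig,
                 rng: np.random.Generator):
    """Female per-miRNA probabilities (sorted log-normal abundance law) and
    the per-miRNA male/female fold-change vector."""
    n = len(bundle.mature)
    w = np.sort(rng.lognormal(config.abundance_mu, config.abundance_sigma, n))[::-1]
    p_f = w / w.sum()
    fc = np.ones(n)
    names = [name for name, _ in bundle.mature]
    for name, f in config.de_subset.items():
        if name not in names:
            raise ValueError(f"de_subset name {name!r} not in the bundle")
        fc[names.index(name)] = f
    return p_f, fc


def _simulate_library(bundle, config, rng, lib, p_mirna, fc, mirna_mass=1.0):
    """One library.

    ``mirna_mass`` scales the miRNA category in the male library (sum of
    female probabilities times fold changes); the junk category absorbs the
    difference, so the expected per-read probability of every individual
    miRNA is exactly its female probability times its fold change and null
    miRNAs keep identical expected composition in both libraries.
    """
    depth = config.depth_per_library
    rates = config.isomir_rates
    star_p = config.star_ratio / (1.0 + config.star_ratio)
    base_mirna = 1.0 - (config.contaminant_fraction + config.novel_fraction
                        + config.junk_fraction)
    junk = config.junk_fraction + base_mirna * (1.0 - mirna_mass)
    if junk < 0:
        raise ValueError(
            "DE subset up-regulation mass too large for the junk category "
            "to absorb; reduce fold changes or increase junk_fraction"
        )
    fracs = np.array([
        config.contaminant_fraction,
        config.novel_fraction,
        junk,
        base_mirna * mirna_mass,
    ])
    n_con, n_nov, n_junk, n_mir = rng.multinomial(depth, fracs)

    reads: list[tuple[str, str]] = []
    rows: list[tuple] = []
    idx = 0

    def emit(insert, source, cls, variation, fold):
        nonlocal idx
        rid = f"{lib}_{idx:07d}"
        reads.append((rid, insert + config.adapter))
        rows.append((rid, lib, insert, source, cls, variation, fold))
        idx += 1

    # contaminant reads: exact substrings of contaminant references
    if n_con:
        refi = rng.integers(0, len(bundle.contaminants), n_con)
        lens = np.clip(np.rint(rng.normal(22, 1.8, n_con)).astype(int), 18, 25)
        u = rng.random(n_con)
        for r, L, x in zip(refi, lens, u):
            name, seq, _cls = bundle.contaminants[r]
            L = min(L, len(seq))
            start = int(x * (len(seq) - L + 1))
            emit(seq[start : start + L], name, "contaminant", "none", 1.0)

    # novel-locus reads: exact copies of the planted novel mature
    if n_nov:
        for r in rng.integers(0, len(bundle.novel_precursors), n_nov):
            p = bundle.novel_precursors[r]
            emit(p.mature_seq, p.name, "novel", "none", 1.0)

    # junk: unannotated or low-complexity material
    if n_junk:
        lens = rng.integers(10, 31, n_junk)
        kind = rng.random(n_junk)
        for L, k in zip(lens, kind):
            if k < 0.10:
                insert = BASES[int(k * 40) % 4] * int(L)
            else:
                insert = _rand_seq(rng, int(L))
                if k > 0.95 and L > 2:
                    pos = int((k - 0.95) * 20 * (L - 1))
                    insert = insert[:pos] + "N" + insert[pos + 1 :]
            emit(insert, "junk", "junk", "none", 1.0)

    # miRNA reads: mature / star / isomiR variants
    if n_mir:
        mi = rng.choice(len(bundle.mature), n_mir, p=p_mirna)
        is_star = rng.random(n_mir) < star_p
        u5 = rng.random(n_mir) < rates.get("five_prime", 0.0)
        us = rng.random(n_mir) < rates.get("seed_adjacent", 0.0)
        u3 = rng.random(n_mir) < rates.get("three_prime", 0.0)
        mode5 = rng.integers(0, 2, n_mir)
        pos_s = rng.integers(9, 16, n_mir)      # 1-based seed-adjacent position
        shift_s = rng.integers(1, 4, n_mir)
        mode3 = rng.integers(0, 2, n_mir)
        base3 = rng.integers(0, 2, n_mir)       # non-templated A or T
        prec_by_mature = bundle.precursor_by_mature
        for r in range(n_mir):
            name, mseq = bundle.mature[mi[r]]
            cls = "KC" if name in bundle.kc_names else "known"
            fold = float(fc[mi[r]])
            if is_star[r]:
                emit(prec_by_mature[name].star_seq, name, "star", "none", fold)
                continue
            tag = mseq
            kinds = []
            if u5[r]:
                prec = prec_by_mature[name]
                if mode5[r] == 0:
                    tag = tag[1:]
                else:
                    tag = prec.seq[prec.mature_start - 1] + tag
                kinds.append("five_prime_end")
            if us[r]:
                p = int(pos_s[r])
                if p <= len(mseq):
                    # position indexed on the reference mature, applied to the
                    # matching offset of the current tag
                    off = (len(tag) - len(mseq)) if "five_prime_end" in kinds else 0
                    q = p - 1 + off
                    if 0 <= q < len(tag):
                        old = tag[q]
                        new = BASES[(BASES.index(old) + int(shift_s[r])) % 4]
                        tag = tag[:q] + new + tag[q + 1 :]
                        kinds.append("seed_adjacent")
            if u3[r]:
                tag = tag + BASES[::3][base3[r]] if mode3[r] else tag[:-1]
                kinds.append("three_prime_end")
            variation = kinds[0] if len(kinds) == 1 else ("mixed" if kinds else "none")
            emit(tag, name, cls, variation, fold)

    return reads, rows


def simulate_libraries(bundle: ReferenceBundle,
                       config: SimulationConfig) -> SimResult:
    """Simulate the female and male libraries plus the per-read truth table."""
    config.validate()
    frac_mirna = 1.0 - (config.contaminant_fraction + config.novel_fraction
                        + config.junk_fraction)
    if frac_mirna > 0 and not bundle.mature:
        raise ValueError("bundle has no mature miRNAs but miRNA fraction > 0")
    if config.contaminant_fraction > 0 and not bundle.contaminants:
        raise ValueError("bundle has no contaminants but contaminant fraction > 0")
    if config.novel_fraction > 0 and not bundle.novel_precursors:
        raise ValueError("bundle has no novel loci but novel fraction > 0")

    rng = np.random.default_rng(config.seed)
    if bundle.mature:
        p_f, fc = _mirna_probs(bundle, config, rng)
        mass_m = float((p_f * fc).sum())
        p_m = p_f * fc / mass_m
    else:
        p_f = p_m = fc = np.array([])
        mass_m = 1.0
    reads_f, rows_f = _simulate_library(bundle, config, rng, "female", p_f, fc)
    reads_m, rows_m = _simulate_library(bundle, config, rng, "male", p_m, fc,
                                        mirna_mass=mass_m)
    truth = pd.DataFrame(
        rows_f + rows_m,
        columns=["read_id", "library", "tag", "source", "true_class",
                 "variation", "fold_change"],
    )
    return SimResult(reads_f, reads_m, truth)


# ---------------------------------------------------------------------------
# writers


def write_bundle(bundle: ReferenceBundle, outdir) -> dict[str, Path]:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mature": out / "mature.fa",
        "precursors": out / "precursors.fa",
        "contaminants": out / "contaminants.fa",
        "genome": out / "genome.fa",
        "loci": out / "planted_loci.tsv",
    }
    write_fasta(paths["mature"], bundle.mature)
    write_fasta(paths["precursors"], [(p.name, p.seq) for p in bundle.precursors])
    write_fasta(
        paths["contaminants"],
        [(f"{name} class={cls}", seq) for name, seq, cls in bundle.contaminants],
    )
    write_fasta(paths["genome"], bundle.genome.items())
    pd.DataFrame([dataclasses.asdict(l) for l in bundle.loci]).to_csv(
        paths["loci"], sep="\t", index=False
    )
    return paths


def write_libraries(sim: SimResult, outdir) -> dict[str, Path]:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "female": out / "female.fastq",
        "male": out / "male.fastq",
        "truth": out / "truth.tsv",
    }
    write_fastq(paths["female"], sim.reads_female)
    write_fastq(paths["male"], sim.reads_male)
    sim.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def simulate_ct_table(true_folds: dict[str, float], n_reps: int = 3,
                      sigma: float = 0.1, seed: int = 0) -> pd.DataFrame:
    """Synthetic qPCR Ct table for targets with known male/female fold changes.

    Ct noise is Gaussian with standard deviation ``sigma`` cycles; the
    reference gene (U6-style) has a constant mean Ct in both samples.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for target, fold in true_folds.items():
        base_dct = float(rng.uniform(3.0, 8.0))
        for sample, dct in (("female", base_dct),
                            ("male", base_dct - np.log2(fold))):
            for rep in range(1, n_reps + 1):
                ct_ref = 20.0 + rng.normal(0.0, sigma)
                ct_target = ct_ref + dct + rng.normal(0.0, sigma)
                rows.append((target, sample, rep, ct_target, ct_ref))
    return pd.DataFrame(
        rows, columns=["target", "sample", "replicate", "ct_target", "ct_reference"]
    )
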