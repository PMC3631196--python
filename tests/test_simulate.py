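"""Synthetic-data generator: forced counts, determinism, planted structure,
sampling laws against binomial oracles."""

import numpy as np
import pytest

from esimir._util import revcomp
from esimir.folding import stacking_fold
from esimir.simulate import (
    CapacityError,
    EmptySimulationError,
    SimulationConfig,
    default_config,
    make_reference_bundle,
    simulate_libraries,
    write_bundle,
    write_libraries,
)


def test_bundle_counts_forced_by_arguments():
    b = make_reference_bundle(10, 3, 5, 20, seed=1)
    assert len(b.mature) == 13
    assert len(b.kc_names) == 3
    assert len(b.precursors) == 13
    assert len(b.novel_precursors) == 5
    assert len(b.contaminants) == 20
    assert len([l for l in b.loci if l.kind == "known"]) == 10
    assert len([l for l in b.loci if l.kind == "novel"]) == 5


def test_empty_bundle_is_genome_only():
    b = make_reference_bundle(0, 0, 0, 0, seed=1)
    assert b.mature == [] and b.precursors == [] and b.contaminants == []
    assert len(b.genome["chr1"]) == 30_000


def test_bundle_deterministic_for_fixed_seed(tmp_path):
    out = []
    for run in ("a", "b"):
        b = make_reference_bundle(5, 2, 2, 4, seed=9)
        write_bundle(b, tmp_path / run)
        out.append({p.name: p.read_bytes()
                    for p in sorted((tmp_path / run).iterdir())})
    assert out[0] == out[1]


def test_capacity_error_when_loci_exceed_genome():
    with pytest.raises(CapacityError):
        make_reference_bundle(50, 0, 50, 0, seed=1, genome_len=2_000)


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        make_reference_bundle(-1, 0, 0, 0, seed=1)


def test_mature_is_substring_of_exactly_one_arm(small_bundle):
    for prec in small_bundle.precursors + small_bundle.novel_precursors:
        m = prec.mature_seq
        assert prec.seq.count(m) == 1
        # mature arm and star arm do not overlap
        assert prec.mature_end <= prec.star_start or prec.star_end <= prec.mature_start


def test_planted_loci_occur_exactly_at_recorded_coordinates(small_bundle):
    by_name = {p.name: p for p in small_bundle.precursors + small_bundle.novel_precursors}
    for locus in small_bundle.loci:
        seq = small_bundle.genome[locus.contig][locus.start : locus.end]
        prec = by_name[locus.name]
        assert seq == (prec.seq if locus.strand == "+" else revcomp(prec.seq))


def test_kc_precursors_absent_from_genome(small_bundle):
    genome = small_bundle.genome["chr1"]
    for prec in small_bundle.precursors:
        in_genome = prec.seq in genome or revcomp(prec.seq) in genome
        assert in_genome == (prec.mature_name not in small_bundle.kc_names)


def test_planted_hairpins_pass_energy_criterion(small_bundle):
    for prec in small_bundle.precursors + small_bundle.novel_precursors:
        _db, dg = stacking_fold(prec.seq)
        assert dg <= -15.0


def test_depth_and_truth_conservation(small_sim):
    cfg, sim = small_sim
    assert len(sim.reads_female) == cfg.depth_per_library
    assert len(sim.reads_male) == cfg.depth_per_library
    assert len(sim.truth) == 2 * cfg.depth_per_library
    assert sim.truth.read_id.is_unique


def test_reads_carry_adapter_after_insert(small_sim):
    cfg, sim = small_sim
    truth_f = sim.truth[sim.truth.library == "female"]
    tag_by_id = dict(zip(truth_f.read_id, truth_f.tag))
    for rid, seq in sim.reads_female[:500]:
        assert seq == tag_by_id[rid] + cfg.adapter


def test_simulation_deterministic_bytes(small_bundle, tmp_path):
    digests = []
    for run in ("a", "b"):
        cfg = default_config(small_bundle, depth=5_000, seed=3)
        sim = simulate_libraries(small_bundle, cfg)
        paths = write_libraries(sim, tmp_path / run)
        digests.append({k: p.read_bytes() for k, p in paths.items()})
    assert digests[0] == digests[1]


def test_planted_fold_change_within_three_binomial_se(small_bundle):
    fc = 2.0
    name = small_bundle.mature[0][0]  # most abundant: tight relative SE
    cfg = default_config(small_bundle, depth=100_000, seed=21,
                         de_subset={name: fc})
    sim = simulate_libraries(small_bundle, cfg)
    mir = sim.truth[(sim.truth.source == name)
                    & sim.truth.true_class.isin(["known", "KC"])]
    nf = (mir.library == "female").sum()
    nm = (mir.library == "male").sum()
    ratio = nm / nf
    se = ratio * np.sqrt(1 / nf + 1 / nm)  # delta-method SE of a count ratio
    assert abs(ratio - fc) <= 3 * se


def test_pure_contaminant_composition(small_bundle):
    cfg = SimulationConfig(depth_per_library=2_000, contaminant_fraction=1.0,
                           novel_fraction=0.0, junk_fraction=0.0, seed=4)
    sim = simulate_libraries(small_bundle, cfg)
    assert (sim.truth.true_class == "contaminant").all()
    # contaminant inserts are exact substrings of their source reference
    refs = {name: seq for name, seq, _cls in small_bundle.contaminants}
    sample = sim.truth.head(200)
    assert all(row.tag in refs[row.source] for row in sample.itertuples())


def test_star_ratio_within_three_se(small_bundle):
    cfg = default_config(small_bundle, depth=100_000, seed=6, star_ratio=0.05)
    sim = simulate_libraries(small_bundle, cfg)
    n_star = (sim.truth.true_class == "star").sum()
    n_mat = sim.truth.true_class.isin(["known", "KC"]).sum()
    ratio = n_star / n_mat
    se = ratio * np.sqrt(1 / n_star + 1 / n_mat)
    assert abs(ratio - 0.05) <= 3 * se


def test_insert_length_law_peaks_near_22(small_sim):
    _cfg, sim = small_sim
    mir = sim.truth[sim.truth.true_class.isin(["known", "KC", "star", "novel"])]
    lengths = mir.tag.str.len()
    assert lengths.between(18, 25).all()
    assert 21 <= lengths.mode().iloc[0] <= 23


def test_zero_depth_raises_empty_simulation_error(small_bundle):
    with pytest.raises(EmptySimulationError):
        simulate_libraries(small_bundle,
                           SimulationConfig(depth_per_library=0, seed=1))


@pytest.mark.parametrize(
    "kwargs",
    [
        {"contaminant_fraction": 0.7, "junk_fraction": 0.7},
        {"star_ratio": 0.0},
        {"star_ratio": 1.5},
        {"isomir_rates": {"five_prime": 1.2}},
        {"de_subset": {"x": -1.0}},
    ],
)
def test_invalid_config_rejected(kwargs):
    with pytest.raises(ValueError):
        SimulationConfig(depth_per_library=10, seed=1, **kwargs).validate()


def test_first_base_bias_matches_binomial_oracle():
    b = make_reference_bundle(150, 0, 0, 0, seed=17, genome_len=60_000)
    firsts = [seq[0] for _name, seq in b.mature]
    frac = sum(f in "TA" for f in firsts) / len(firsts)
    se = np.sqrt(0.815 * 0.185 / len(firsts))
    assert abs(frac - 0.815) <= 3 * se
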