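"""CRISPR array detection against brute-force enumeration; spacer dedup."""

import numpy as np
import pytest

from bifiphage.crispr import Spacer, dedupe_spacers, find_arrays
from bifiphage.genome_io import GenomeRecord
from oracles import brute_crispr, rc


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def _with_array(rng, n, n_spacers, repeat_len=30, spacer_len=33, at=None):
    seq = _random_seq(rng, n)
    repeat = _random_seq(rng, repeat_len)
    spacers = [_random_seq(rng, spacer_len) for _ in range(n_spacers)]
    locus = repeat + "".join(s + repeat for s in spacers)
    at = at if at is not None else n // 2
    seq = seq[:at] + locus + seq[at + len(locus) :]
    return seq, repeat, spacers, at


def test_implanted_locus_yields_expected_array():
    rng = np.random.default_rng(1)
    seq, repeat, spacers, at = _with_array(rng, 10_000, n_spacers=3)
    arrays = find_arrays(GenomeRecord(id="g", sequence=seq))
    assert len(arrays) == 1
    arr = arrays[0]
    assert arr.repeat == repeat
    assert len(arr.copies) == 4 and len(arr.spacers) == 3
    assert [s.sequence for s in arr.spacers] == spacers
    assert arr.start == at and arr.end == at + 4 * 30 + 3 * 33


def test_two_copies_not_reported():
    rng = np.random.default_rng(2)
    seq = _random_seq(rng, 5_000)
    repeat = _random_seq(rng, 30)
    locus = repeat + _random_seq(rng, 33) + repeat
    seq = seq[:2000] + locus + seq[2000 + len(locus) :]
    assert find_arrays(GenomeRecord(id="g", sequence=seq)) == []


@pytest.mark.parametrize("seed", [10, 11, 12, 13, 14])
def test_detector_matches_brute_force_on_random_sequences(seed):
    """On i.i.d. random 10 kb sequences the qualifying-repeat-triple
    enumeration is (typically) empty and the detector agrees exactly."""
    rng = np.random.default_rng(seed)
    seq = _random_seq(rng, 10_000)
    got = {tuple(a.copies) for a in find_arrays(GenomeRecord(id="g", sequence=seq))}
    assert got == brute_crispr(seq)


@pytest.mark.parametrize("seed,n_spacers", [(20, 3), (21, 5)])
def test_detector_matches_brute_force_on_implanted_arrays(seed, n_spacers):
    rng = np.random.default_rng(seed)
    seq, _, _, _ = _with_array(rng, 10_000, n_spacers=n_spacers)
    got = {tuple(a.copies) for a in find_arrays(GenomeRecord(id="g", sequence=seq))}
    assert got == brute_crispr(seq)
    assert len(got) == 1


def test_spacer_count_is_copies_minus_one(pipeline_run):
    for arr in pipeline_run.arrays:
        assert len(arr.spacers) == len(arr.copies) - 1


def _spacer(i, seq):
    return Spacer(id=f"s{i}", sequence=seq, genome_id="g", array_index=0, position=i)


def test_dedupe_basic_rules():
    rng = np.random.default_rng(3)
    a = _random_seq(rng, 33)
    reps, asg = dedupe_spacers([_spacer(0, a), _spacer(1, a)])
    assert len(reps) == 1 and len(set(asg.values())) == 1

    b = list(a)
    for p in range(0, 33, 3):  # ~40% of positions changed
        b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
    reps, _ = dedupe_spacers([_spacer(0, a), _spacer(1, "".join(b))])
    assert len(reps) == 2

    # reverse-complement copies cluster together
    reps, _ = dedupe_spacers([_spacer(0, a), _spacer(1, rc(a))])
    assert len(reps) == 1


def test_dedupe_recovers_original_count_with_identity_oracle():
    """100 spacers = 10 originals x 10 copies with <= 1 substitution each
    (identity >= 32/33 > 0.9) collapse to 10 representatives; verified with
    an all-pairs identity oracle."""
    rng = np.random.default_rng(4)
    originals = [_random_seq(rng, 33) for _ in range(10)]
    pool = []
    i = 0
    for orig in originals:
        for _ in range(10):
            s = list(orig)
            if rng.random() < 0.8:
                p = int(rng.integers(0, 33))
                s[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[p]]
            pool.append(_spacer(i, "".join(s)))
            i += 1
    reps, asg = dedupe_spacers(pool, identity_threshold=0.9)
    assert len(reps) == 10
    by_id = {s.id: s.sequence for s in pool}
    for sp in pool:
        rep_seq = by_id[asg[sp.id]]
        matches = max(
            sum(1 for x, y in zip(sp.sequence, rep_seq) if x == y),
            sum(1 for x, y in zip(rc(sp.sequence), rep_seq) if x == y),
        )
        assert matches / 33 >= 0.9
    rep_seqs = [r.sequence for r in reps]
    for i in range(10):
        for j in range(i + 1, 10):
            matches = max(
                sum(1 for x, y in zip(rep_seqs[i], rep_seqs[j]) if x == y),
                sum(1 for x, y in zip(rc(rep_seqs[i]), rep_seqs[j]) if x == y),
            )
            assert matches / 33 < 0.9


def test_dedupe_deterministic_and_idempotent():
    rng = np.random.default_rng(5)
    pool = [_spacer(i, _random_seq(rng, int(rng.integers(25, 61)))) for i in range(30)]
    reps1, asg1 = dedupe_spacers(pool)
    reps2, asg2 = dedupe_spacers(list(reversed(pool)))
    assert [r.id for r in reps1] == [r.id for r in reps2]
    assert asg1 == asg2
    reps3, asg3 = dedupe_spacers(reps1)
    assert [r.id for r in reps3] == [r.id for r in reps1]
    assert all(asg3[r.id] == r.id for r in reps1)


def test_dedupe_requires_input():
    with pytest.raises(ValueError):
        dedupe_spacers([])
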