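"""Flank location, insert extraction, pair reconciliation and QC accounting."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selexpipe import (
    LibraryDesign,
    ReadPair,
    SeqRecord,
    Status,
    extract_pair,
    extract_pool,
    find_flanks,
    reverse_complement,
)
from conftest import SP_SEQUENCES, random_bases
from oracle_flanks import brute_force_find_flanks


class TestLibraryDesign:
    def test_n40_amplicon_geometry(self, design):
        # 18-nt flanks around a 40-nt random region: 76 bp full construct
        assert design.amplicon_length == 76
        assert design.length_window == (38, 42)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"flank5": ""},
            {"flank3": "ACGU"},
            {"n_length": 0},
            {"length_tolerance": -1},
            {"max_mismatch": 9},  # >= half the 18-nt flank
        ],
    )
    def test_invalid_designs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LibraryDesign(**kwargs)


class TestFindFlanks:
    @pytest.mark.parametrize("name", sorted(SP_SEQUENCES))
    def test_printed_candidates_forward(self, design, name):
        insert = SP_SEQUENCES[name]
        result = find_flanks(design.wrap(insert), design)
        assert result.status is Status.PASS
        assert result.insert == insert
        assert result.insert_length == 40
        assert result.orientation == "forward"
        assert result.mismatches5 == result.mismatches3 == 0

    @pytest.mark.parametrize("name", sorted(SP_SEQUENCES))
    def test_printed_candidates_reverse_strand(self, design, name):
        insert = SP_SEQUENCES[name]
        result = find_flanks(reverse_complement(design.wrap(insert)), design)
        assert result.status is Status.PASS
        assert result.insert == insert
        assert result.orientation == "reverse"

    def test_37nt_insert_below_window_fails(self, design, rng):
        short = design.wrap(random_bases(rng, 37))
        assert find_flanks(short, design).status is Status.LENGTH_FAIL

    def test_byproduct_like_50nt_insert_fails_even_under_enumeration(
        self, design, rng
    ):
        # no alternative flank placement may rescue an over-long insert
        read = design.wrap(random_bases(rng, 50))
        assert find_flanks(read, design).status is Status.LENGTH_FAIL
        status, insert, _ = brute_force_find_flanks(read, design)
        assert status == "LENGTH_FAIL" and insert is None

    @pytest.mark.parametrize(
        "build,expected",
        [
            (lambda d, ins: ins + d.flank3, Status.NO_FLANK5),
            (lambda d, ins: d.flank5 + ins, Status.NO_FLANK3),
            (lambda d, ins: d.flank3 + ins + d.flank5, Status.NO_FLANK3),
        ],
    )
    def test_missing_flank_statuses(self, design, rng, build, expected):
        read = build(design, random_bases(rng, 40))
        assert find_flanks(read, design).status is expected

    def test_n_inside_insert_is_ambiguous(self, design, rng):
        insert = random_bases(rng, 20) + "N" + random_bases(rng, 19)
        read = design.wrap(insert)
        assert find_flanks(read, design).status is Status.AMBIGUOUS_BASE

    def test_single_flank_mismatch_fails_at_zero_tolerance(self, design, rng):
        insert = random_bases(rng, 40)
        mutated5 = "G" + design.flank5[1:]
        read = mutated5 + insert + design.flank3
        assert find_flanks(read, design).status is not Status.PASS

    def test_mismatch_tolerance_recovers_mutated_flank(self, rng):
        tolerant = LibraryDesign(max_mismatch=1)
        insert = random_bases(rng, 40)
        mutated5 = "G" + tolerant.flank5[1:]
        result = find_flanks(mutated5 + insert + tolerant.flank3, tolerant)
        assert result.status is Status.PASS
        assert result.insert == insert
        assert (result.mismatches5, result.mismatches3) == (1, 0)

    def test_read_with_sequencing_padding(self, design, rng):
        # flanked construct embedded inside extraneous bases still extracts
        insert = random_bases(rng, 40)
        read = random_bases(rng, 12) + design.wrap(insert) + random_bases(rng, 7)
        result = find_flanks(read, design)
        assert result.status is Status.PASS
        assert result.insert == insert


class TestExtractPair:
    def _pair(self, b1, b2):
        return ReadPair(SeqRecord("f/1", b1), SeqRecord("f/2", b2))

    def test_one_pass_mate_wins(self, design, rng):
        insert = random_bases(rng, 40)
        pair = self._pair(design.wrap(insert), random_bases(rng, 76))
        result = extract_pair(pair, design)
        assert result.status is Status.PASS
        assert result.insert == insert

    def test_agreeing_mates_pass(self, design, rng):
        insert = random_bases(rng, 40)
        read = design.wrap(insert)
        pair = self._pair(read, reverse_complement(read))
        assert extract_pair(pair, design).insert == insert

    def test_disagreeing_mates_discordant(self, design, rng):
        a, b = random_bases(rng, 40), random_bases(rng, 40)
        pair = self._pair(design.wrap(a), reverse_complement(design.wrap(b)))
        assert extract_pair(pair, design).status is Status.DISCORDANT_PAIR

    def test_double_failure_reports_r1_status(self, design, rng):
        pair = self._pair(
            random_bases(rng, 40) + design.flank3,  # NO_FLANK5 on r1
            design.wrap(random_bases(rng, 50)),     # LENGTH_FAIL on r2
        )
        assert extract_pair(pair, design).status is Status.NO_FLANK5


class TestExtractPool:
    def test_ledger_accounts_for_every_pair(self, design, rng):
        good = [
            ReadPair(
                SeqRecord(f"g{i}/1", design.wrap(random_bases(rng, 40))),
                SeqRecord(f"g{i}/2", random_bases(rng, 76)),
            )
            for i in range(10)
        ]
        flankless = [
            ReadPair(
                SeqRecord(f"b{i}/1", random_bases(rng, 76)),
                SeqRecord(f"b{i}/2", random_bases(rng, 76)),
            )
            for i in range(2)
        ]
        inserts, ledger = extract_pool(good + flankless, design)
        assert len(inserts) == 10
        assert ledger.counts["PASS"] == 10
        assert ledger.counts["NO_FLANK5"] == 2
        assert ledger.total == 12
        assert ledger.is_conserved()
        assert ledger.pass_fraction == pytest.approx(10 / 12)

    def test_empty_stream(self, design):
        inserts, ledger = extract_pool([], design)
        assert inserts == [] and ledger.total == 0
        assert ledger.pass_fraction == 0.0


def _random_readish(rng, design):
    """Mixed bag: random reads, clean/mutated/truncated constructs, chimeras."""
    kind = rng.integers(0, 6)
    if kind == 0:
        return random_bases(rng, int(rng.integers(40, 121)))
    insert = random_bases(rng, int(rng.integers(35, 46)))
    read = design.wrap(insert)
    if kind == 2:  # point mutations anywhere
        chars = list(read)
        for _ in range(int(rng.integers(1, 4))):
            pos = int(rng.integers(0, len(chars)))
            chars[pos] = rng.choice(list("ACGTN"))
        read = "".join(chars)
    elif kind == 3:  # truncation
        cut = int(rng.integers(1, 30))
        read = read[cut:] if rng.random() < 0.5 else read[:-cut]
    elif kind == 4:  # over-long chimera-like insert
        read = design.wrap(random_bases(rng, int(rng.integers(43, 81))))
    if rng.random() < 0.5:
        read = reverse_complement(read)
    pad5 = random_bases(rng, int(rng.integers(0, 15)))
    pad3 = random_bases(rng, int(rng.integers(0, 15)))
    return (pad5 + read + pad3)[:120]


@pytest.mark.parametrize("max_mismatch", [0, 1])
def test_scanner_matches_brute_force_enumeration(rng, max_mismatch):
    """Oracle equivalence on adversarial short reads, exact and 1-mismatch."""
    design = LibraryDesign(max_mismatch=max_mismatch)
    for _ in range(300):
        read = _random_readish(rng, design)
        got = find_flanks(read, design)
        status, insert, orientation = brute_force_find_flanks(read, design)
        assert got.status.value == status, read
        assert got.insert == insert, read
        if status == "PASS":
            assert got.orientation == orientation, read


def test_pass_insert_reconstruction_property(design, rng):
    """With exact matching, re-wrapping a PASS insert reproduces a substring
    of the read or of its reverse complement."""
    checked = 0
    for _ in range(400):
        read = _random_readish(rng, design)
        result = find_flanks(read, design)
        if result.status is Status.PASS:
            wrapped = design.wrap(result.insert)
            assert wrapped in read or wrapped in reverse_complement(read)
            checked += 1
    assert checked > 30  # the mixture must actually exercise PASS reads


def test_relaxing_tolerances_never_loses_passes(rng):
    """PASS count is monotone in max_mismatch and length_tolerance."""
    base = LibraryDesign()
    reads = [_random_readish(rng, base) for _ in range(400)]

    def n_pass(design):
        return sum(
            find_flanks(r, design).status is Status.PASS for r in reads
        )

    strict = n_pass(base)
    assert n_pass(LibraryDesign(max_mismatch=1)) >= strict
    assert n_pass(LibraryDesign(max_mismatch=2)) >= n_pass(
        LibraryDesign(max_mismatch=1)
    )
    assert n_pass(LibraryDesign(length_tolerance=3)) >= strict
    assert n_pass(LibraryDesign(length_tolerance=5)) >= n_pass(
        LibraryDesign(length_tolerance=3)
    )


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.text(alphabet="ACGT", min_size=38, max_size=42))
def test_any_window_length_insert_passes(insert):
    design = LibraryDesign()
    result = find_flanks(design.wrap(insert), design)
    assert result.status is Status.PASS
    assert result.insert == insert
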