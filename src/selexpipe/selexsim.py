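"""Synthetic multi-round SELEX sequencing with per-read ground truth.

The generator emulates what the downstream pipeline actually observes from a
whole-cell selection experiment sequenced round by round:

* a handful of true binders whose pool share grows geometrically with the
  round number (weight ``enrichment_factor**(round-1)`` against background
  weight 1 per distinct background sequence);
* uniform per-base substitution sequencing error, applied independently to
  each mate (no indels, so a Hamming-matched flank has a closed-form clean
  probability);
* PCR by-product chimeras: library molecules priming each other inside the
  randomized region yields elongated inserts, modelled as a prefix of one
  insert joined to a suffix of another so that the product always exceeds
  the design length window.

Each simulated fragment is rendered as ``flank5 + insert + flank3``; R1 is
the sense strand, R2 its reverse complement, both at constant Q30.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .extraction import LibraryDesign
from .seqio import PathLike, SeqRecord, reverse_complement, write_fastq

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SelexSimConfig:
    """World description for a simulated selection experiment.

    Defaults reflect a 14-round whole-cell selection of an N40 library
    sequenced on a short-read instrument: a few genuine binders enriching
    ~1.8x in pool share per round, ~10^-3 per-base substitution error, and a
    modest chimeric by-product load (the wet experiment only shows these as a
    secondary gel band, so 5% is a documented, arbitrary default).
    """

    design: LibraryDesign = field(default_factory=LibraryDesign)
    n_binders: int = 3
    enrichment_factor: float = 1.8
    n_background: int = 10_000
    n_rounds: int = 14
    reads_per_round: int = 100_000
    error_rate: float = 0.001
    byproduct_fraction: float = 0.05
    byproduct_extra_length: tuple[int, int] = (3, 40)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must be in [0, 1]")
        if not 0 <= self.byproduct_fraction <= 1:
            raise ValueError("byproduct_fraction must be in [0, 1]")
        if self.reads_per_round <= 0:
            raise ValueError("reads_per_round must be positive")
        if self.enrichment_factor <= 1:
            raise ValueError("enrichment_factor must be > 1")
        if self.n_binders < 0 or self.n_background < 1:
            raise ValueError("need n_binders >= 0 and n_background >= 1")
        lo, hi = self.byproduct_extra_length
        if not 1 <= lo <= hi:
            raise ValueError("byproduct_extra_length must satisfy 1 <= lo <= hi")


@dataclass(frozen=True)
class SimulatedRound:
    """One round's paired reads plus per-read ground truth."""

    round_index: int
    r1: list[SeqRecord]
    r2: list[SeqRecord]
    truth: pd.DataFrame  # read_id, label, origin, true_insert, r1_errors, r2_errors


def random_insert(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


def make_library(config: SelexSimConfig) -> tuple[list[str], list[str]]:
    """Draw the fixed binder and background sequence sets for an experiment.

    Seeded from ``config.seed`` alone so every round samples the same world.
    Sequences are distinct (collisions at N40 are astronomically unlikely but
    re-drawn anyway).
    """
    rng = np.random.default_rng(config.seed)
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < config.n_binders + config.n_background:
        seq = random_insert(rng, config.design.n_length)
        if seq not in seen:
            seen.add(seq)
            out.append(seq)
    return out[: config.n_binders], out[config.n_binders:]


def simulate_pool_weights(config: SelexSimConfig, round_index: int) -> np.ndarray:
    """Sampling frequencies over binders then background for one round.

    Binder i carries weight ``enrichment_factor**(round_index - 1)`` against
    weight 1 per background sequence; the vector is normalized to sum to 1.
    """
    if not 1 <= round_index <= config.n_rounds:
        raise ValueError(f"round_index {round_index} outside [1, {config.n_rounds}]")
    weights = np.ones(config.n_binders + config.n_background)
    weights[: config.n_binders] = config.enrichment_factor ** (round_index - 1)
    return weights / weights.sum()


def expected_binder_frequency(config: SelexSimConfig, round_index: int) -> float:
    """Closed-form per-binder pool share at a round (before error/chimeras)."""
    return float(simulate_pool_weights(config, round_index)[0]) if config.n_binders else 0.0


def make_byproduct(
    insert_a: str,
    insert_b: str,
    rng: np.random.Generator,
    design: LibraryDesign,
    extra_range: tuple[int, int] = (3, 40),
) -> str:
    """Join a prefix of one insert to a suffix of another into a long chimera.

    The prefix keeps at least ``n_length - length_tolerance`` bases (the
    priming event happens inside the randomized region) and the total length
    is ``n_length + length_tolerance + extra`` with ``extra`` drawn uniformly
    from ``extra_range`` (clamped so the product fits in the two parents), so
    the chimera always fails the extraction length window.
    """
    lo_extra, hi_extra = extra_range
    max_total = len(insert_a) + len(insert_b)
    _, window_hi = design.length_window
    extra = int(rng.integers(lo_extra, hi_extra + 1))
    total = min(window_hi + extra, max_total)
    min_prefix = max(design.n_length - design.length_tolerance, total - len(insert_b))
    max_prefix = min(len(insert_a), total - 1)
    prefix_len = int(rng.integers(min_prefix, max_prefix + 1))
    chimera = insert_a[:prefix_len] + insert_b[-(total - prefix_len):]
    assert len(chimera) == total > window_hi
    return chimera


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> tuple[str, list[int]]:
    """Substitute bases at error_rate; returns mutated sequence and positions."""
    if error_rate <= 0:
        return seq, []
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq, []
    positions = sorted(int(p) for p in rng.choice(len(seq), size=n_err, replace=False))
    chars = list(seq)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars), positions


def simulate_round(config: SelexSimConfig, round_index: int) -> SimulatedRound:
    """Generate one round of paired reads with ground-truth labels.

    Reproducible: the per-round RNG is seeded ``config.seed + round_index``
    (the sequence library itself depends only on ``config.seed``). Ground
    truth has exactly one row per fragment; labels are ``byproduct`` for
    chimeric fragments, ``flank_mutated`` for reads whose sequencing errors
    hit a constant region on either mate, else ``binder``/``background``.
    """
    binders, background = make_library(config)
    sequences = binders + background
    weights = simulate_pool_weights(config, round_index)
    rng = np.random.default_rng(config.seed + round_index)
    design = config.design
    len5, len3 = len(design.flank5), len(design.flank3)

    choices = rng.choice(len(sequences), size=config.reads_per_round, p=weights)
    chimeric = rng.random(config.reads_per_round) < config.byproduct_fraction

    r1_records: list[SeqRecord] = []
    r2_records: list[SeqRecord] = []
    truth_rows = []
    for i in range(config.reads_per_round):
        origin_idx = int(choices[i])
        if chimeric[i]:
            partner = sequences[int(rng.integers(0, len(sequences)))]
            insert = make_byproduct(
                sequences[origin_idx], partner, rng, design,
                config.byproduct_extra_length,
            )
            origin = "byproduct"
        else:
            insert = sequences[origin_idx]
            origin = (
                f"binder{origin_idx}" if origin_idx < config.n_binders else "background"
            )
        construct = design.wrap(insert)
        length = len(construct)
        r1_seq, r1_pos = _mutate(construct, rng, config.error_rate)
        r2_seq, r2_pos = _mutate(reverse_complement(construct), rng, config.error_rate)
        flank_hit = any(p < len5 or p >= length - len3 for p in r1_pos) or any(
            p < len3 or p >= length - len5 for p in r2_pos
        )
        if origin == "byproduct":
            label = "byproduct"
        elif flank_hit:
            label = "flank_mutated"
        else:
            label = "binder" if origin.startswith("binder") else "background"
        read_id = f"sim_r{round_index}_{i}"
        r1_records.append(SeqRecord(read_id=f"{read_id}/1", bases=r1_seq))
        r2_records.append(SeqRecord(read_id=f"{read_id}/2", bases=r2_seq))
        truth_rows.append(
            (read_id, label, origin, insert, len(r1_pos), len(r2_pos))
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "label", "origin", "true_insert", "r1_errors", "r2_errors"],
    )
    return SimulatedRound(round_index=round_index, r1=r1_records, r2=r2_records, truth=truth)


def write_round(
    simulated: SimulatedRound, outdir: PathLike, prefix: Optional[str] = None
) -> dict[str, Path]:
    """Write one round as paired FASTQ (Q30) plus a ground-truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or f"round{simulated.round_index:02d}"
    paths = {
        "r1": outdir / f"{prefix}_R1.fastq",
        "r2": outdir / f"{prefix}_R2.fastq",
        "truth": outdir / f"{prefix}_truth.tsv",
    }
    write_fastq(simulated.r1, paths["r1"])
    write_fastq(simulated.r2, paths["r2"])
    simulated.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def simulate_experiment(
    config: SelexSimConfig,
    outdir: PathLike,
    rounds: Optional[list[int]] = None,
) -> dict[int, dict[str, Path]]:
    """Simulate and write several rounds; returns per-round file paths."""
    rounds = rounds or list(range(1, config.n_rounds + 1))
    return {
        r: write_round(simulate_round(config, r), outdir) for r in rounds
    }


def scaled_config(config: SelexSimConfig, reads_per_round: int) -> SelexSimConfig:
    """Same world, fewer reads per round (for quick runs and tests)."""
    return replace(config, reads_per_round=reads_per_round)
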