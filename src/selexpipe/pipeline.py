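"""End-to-end wiring: per-round extraction, collapse, enrichment, candidates.

This is the library entry point that strings the modules into the full
selection-analysis flow: for every round, paired FASTQ -> extraction with a
QC ledger -> collapse -> counts table; then a cross-round enrichment table
between a designated early and late round, and a ranked candidate report
from the late round. All outputs are plain text (TSV/JSON) and the whole
run is deterministic for fixed inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import seqio
from .extraction import LibraryDesign, QCLedger, extract_pool, extract_reads
from .pooling import (
    DEFAULT_MIN_COUNT,
    DEFAULT_PSEUDOCOUNT,
    PoolCounts,
    collapse,
    enrichment,
    top_candidates,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A round failed; the message names the failing round."""


@dataclass
class RunConfig:
    """Configuration for a full multi-round analysis run.

    ``rounds`` maps a unique round label to a ``(r1_path, r2_path)`` tuple;
    ``r2_path`` may be ``None`` for single-end data. ``compare`` names the
    (early, late) rounds for the enrichment table and defaults to the first
    and last labels in insertion order.
    """

    rounds: dict[str, tuple[Path, Optional[Path]]]
    output_dir: Path
    design: LibraryDesign = field(default_factory=LibraryDesign)
    min_count: int = DEFAULT_MIN_COUNT
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    compare: Optional[tuple[str, str]] = None

    def __post_init__(self) -> None:
        if not self.rounds:
            raise ValueError("at least one round is required")
        self.output_dir = Path(self.output_dir)
        self.rounds = {
            label: (Path(r1), Path(r2) if r2 is not None else None)
            for label, (r1, r2) in self.rounds.items()
        }
        if self.compare is None and len(self.rounds) >= 2:
            labels = list(self.rounds)
            self.compare = (labels[0], labels[-1])
        if self.compare is not None:
            for label in self.compare:
                if label not in self.rounds:
                    raise ValueError(f"compare round {label!r} not among rounds")


@dataclass
class RunReport:
    """Everything a run produced, in memory and on disk."""

    pools: dict[str, PoolCounts]
    ledgers: dict[str, QCLedger]
    candidates: pd.DataFrame
    enrichment: Optional[pd.DataFrame]
    files: dict[str, Path]


def _process_round(
    label: str, r1_path: Path, r2_path: Optional[Path], design: LibraryDesign
) -> tuple[list[str], QCLedger]:
    if r2_path is None:
        return extract_reads(seqio.read_fastq(r1_path), design)
    pairs = seqio.pair_reads(seqio.read_fastq(r1_path), seqio.read_fastq(r2_path))
    return extract_pool(pairs, design)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full flow; writes the report bundle under ``output_dir``.

    Produces per round ``counts_<label>.tsv`` and ``qc_<label>.json``, plus
    ``enrichment.tsv`` (when two rounds are available), ``candidates.tsv``
    and ``summary.json``. Any failure is re-raised as
    :class:`PipelineError` naming the round.
    """
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    pools: dict[str, PoolCounts] = {}
    ledgers: dict[str, QCLedger] = {}
    files: dict[str, Path] = {}

    for label, (r1_path, r2_path) in config.rounds.items():
        for path in (r1_path, r2_path):
            if path is not None and not path.exists():
                raise PipelineError(f"round {label!r}: input file not found: {path}")
        try:
            inserts, ledger = _process_round(label, r1_path, r2_path, config.design)
        except Exception as exc:  # noqa: BLE001 - annotate with the round
            raise PipelineError(f"round {label!r}: {exc}") from exc
        pools[label] = collapse(inserts, round_label=label)
        ledgers[label] = ledger
        counts_path = outdir / f"counts_{label}.tsv"
        qc_path = outdir / f"qc_{label}.json"
        seqio.write_counts_table(pools[label], counts_path)
        qc_path.write_text(ledger.to_json() + "\n")
        files[f"counts_{label}"] = counts_path
        files[f"qc_{label}"] = qc_path
        logger.info(
            "round %s: %d reads, %.1f%% pass, %d unique inserts",
            label, ledger.total, 100 * ledger.pass_fraction, len(pools[label]),
        )

    final_label = list(config.rounds)[-1]
    candidates = top_candidates(pools[final_label], min_count=config.min_count)
    candidates_path = outdir / "candidates.tsv"
    candidates.to_csv(candidates_path, sep="\t", index=False)
    files["candidates"] = candidates_path

    enrich_table: Optional[pd.DataFrame] = None
    if config.compare is not None:
        early_label, late_label = config.compare
        if pools[early_label].counts and pools[late_label].counts:
            enrich_table = enrichment(
                pools[early_label], pools[late_label], pseudocount=config.pseudocount
            )
            enrich_path = outdir / "enrichment.tsv"
            enrich_table.to_csv(enrich_path, sep="\t", index=False)
            files["enrichment"] = enrich_path

    summary = {
        "rounds": {
            label: {
                "qc": ledgers[label].to_dict(),
                "unique_sequences": len(pools[label]),
            }
            for label in config.rounds
        },
        "candidate_round": final_label,
        "min_count": config.min_count,
        "pseudocount": config.pseudocount,
        "n_candidates": int(len(candidates)),
        "compare": list(config.compare) if config.compare else None,
    }
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2) + "\n")
    files["summary"] = summary_path

    return RunReport(
        pools=pools,
        ledgers=ledgers,
        candidates=candidates,
        enrichment=enrich_table,
        files=files,
    )
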