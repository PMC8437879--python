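# Methods

## The analysis problem

A SELEX pool sequenced on a short-read instrument yields reads that should
each contain one library molecule: a fixed 5' constant region, a randomized
insert near the design length, and a fixed 3' constant region — possibly
reverse-complemented, since either strand may be sequenced. Real pools also
contain artifacts: reads missing a recognizable flank (sequencing error in
a primer site, adapter junk) and elongated PCR by-products formed when
library molecules prime each other inside the randomized region and get
extended by the polymerase. The analysis must (i) keep exactly the reads
consistent with the library design, (ii) account for every discarded read,
and (iii) turn the survivors into comparable per-round counts.

## Extraction model

`find_flanks` scans a read for an occurrence of the 5' flank followed
downstream by the 3' flank such that the intervening insert length lies in
`n_length ± length_tolerance` (default 40 ± 2, i.e. 38–42 nt). Matching is
Hamming-distance only — no indels — with `max_mismatch = 0` by default, so
the default filter is exact text matching; mismatch tolerance is opt-in.
The forward strand is scanned first, then the reverse complement.

Numerical/tie-break choices (all deterministic):

- Among valid layouts: smallest total flank mismatches, then insert length
  closest to `n_length`, then leftmost 5' flank. This favors the designed
  construct over spurious placements.
- A read passing on both strands (requires a near-palindrome; astronomically
  rare) keeps the forward result and increments a dedicated QC counter.
- Failure verdicts follow the filter chain 5' flank → 3' flank → length →
  base content; when both strands fail, the verdict that progressed furthest
  is reported (forward wins ties). This makes the failure taxonomy stable
  under strand flips.
- Inserts containing `N` are rejected (`AMBIGUOUS_BASE`) because collapse
  operates on exact sequence identity; an `N` would create spurious unique
  sequences.
- Base qualities are ignored during extraction, mirroring a pipeline that
  discards them before filtering. An optional mean-quality pre-filter was
  considered and deliberately omitted: it would change no verdict in the
  exact-matching regime, which already rejects error-bearing flanks.

Pair reconciliation is the package's own policy (upstream descriptions of
joined-mate processing leave it open): each mate is extracted
independently; exactly one PASS wins; two PASSes must agree on the insert,
otherwise the fragment is `DISCORDANT_PAIR` and dropped; two failures
report the R1 verdict. The window is therefore enforced per mate, not per
joined record. With independent per-mate sequencing errors this policy
discards fragments whose two mates disagree inside the insert (~2 x 40 x
error_rate of pairs); that is intentional — a disagreement means at least
one copy of the insert is corrupted and exact-identity counting would
credit a phantom sequence.

The QC ledger counts every input read/pair exactly once; conservation
(counts sum to total) is asserted in tests, and the scanner is checked
against a brute-force enumeration of all (offset5, offset3, strand)
triples on adversarial reads.

## Counting and ranking

Collapse is exact-identity counting. RPM (`count / total_pass * 1e6`)
normalizes for per-round sequencing depth. The candidate report keeps
sequences with count strictly greater than the threshold (default 25 —
chosen so a report on the reference final-round counts keeps exactly the
sequences exceeding 25 reads, the smallest retained count being 26),
ranked by count descending with lexicographic tie-break. Cross-round
enrichment is `(rpm_late + p) / (rpm_early + p)` with `p = 0.5` RPM over
the union of sequences: the pseudocount keeps fold-changes finite and
positive when a sequence is absent from one round. Fold-change ranking is
noisy for sequences observed a handful of times (0 → 3 reads looks
enormous); the `min_count` argument restricts the table to well-sampled
rows and is the recommended view.

## Simulator: what it emulates, what it does not

The generator states a world in which the pipeline's behavior has closed
forms:

- **Enrichment**: binder i has sampling weight `enrichment_factor^(r-1)`
  in round r against weight 1 per distinct background sequence; reads are
  drawn multinomially. Geometric growth is the simplest monotone model of
  round-over-round enrichment; no binding kinetics are implied. Defaults
  (3 binders, factor 1.8, 14 rounds, 1e5 reads/round, 1e4 distinct
  background sequences) describe a late-converging whole-cell selection in
  which repeated sequences only dominate in the final round.
- **Error**: uniform per-base substitution to a different base at
  `error_rate` (default 1e-3, short-read scale), applied independently to
  each mate; no indels. Exact flank matching then passes a single-end read
  with probability `(1-e)^36` (both 18-nt flanks clean), and recovers the
  ground-truth insert exactly with probability `(1-e)^76` (every position
  of the 76-nt construct clean). Both closed forms are asserted against
  simulation at 3 binomial standard errors.
- **By-products**: with probability `byproduct_fraction` (default 0.05 — a
  documented, arbitrary choice; the wet observation is only a secondary gel
  band) a read's insert is a chimera: a prefix of one insert (at least the
  window minimum, since priming occurs inside the randomized region)
  joined to a suffix of another, total length `n_length +
  length_tolerance + extra` with `extra` drawn from `byproduct_extra_length`
  (default 3–40 nt, clamped to the two parents' combined length). By
  construction every chimera exceeds the retention window, which is all the
  extraction stage can observe about the hybridization mechanism.
- **Reproducibility**: the binder/background sequence sets depend only on
  `seed`; each round uses one RNG stream seeded `seed + round_index`, so any
  round can be regenerated independently and byte-identically. R2 is the
  reverse complement of the (pre-error) construct with its own errors;
  qualities are constant Q30 placeholders.

Not modelled: PCR cycle-level amplification bias and polymerase error
spectra, strand-separation losses, cell-binding biophysics, indels, quality
degradation along the read. A green simulator-based test therefore
establishes that the pipeline's logic behaves as specified in a stated
world — not that real selection data meets these rates, and dataset-level
numbers from any particular experiment (total repeated sequences, absolute
candidate counts) are not reproducible from simulation.

## Dose-response module

MST titrations arrive as normalized fluorescence (Fnorm, per-mille) per
concentration step per replicate; the design emulated by the tests is a
16-step 1:1 dilution from 2e7 cells/mL in triplicate. dFnorm subtracts a
baseline from the per-point replicate means. The baseline defaults to the
lowest-concentration point (so dFnorm is zero there by construction) but an
explicit value, e.g. from a target-free control well, may be passed
instead — which of the two an upstream instrument analysis used is often
unstated, so both are supported and the default is documented here.

The saturation summary fits `dF(c) = A*c/(m+c)` by least squares
(Levenberg-Marquardt via `scipy.optimize.curve_fit`, initialized from the
terminal response and the median concentration; tolerances 1e-14, so a
noiseless curve is recovered to float precision). `A` may be negative —
the sign of a thermophoretic response is assay-dependent. `m` is reported
as a *response midpoint*, never a dissociation constant: a whole-cell
titration has no well-defined ligand concentration scale for a Kd.
Signal-to-noise is `|A|` over the residual standard deviation
(`sqrt(RSS/(n-2))`). A flat response short-circuits to a `non_binding`
flag; a fitted amplitude within 3 residual SDs of zero is likewise flagged
`non_binding`; optimizer non-convergence yields `fit_failed` with the raw
dFnorm values still returned.

## Degenerate inputs and edge policies

- FASTQ records are validated (quality/sequence length equality, non-empty
  sequence, ACGTN alphabet); a malformed record aborts with its index.
- RPM on an empty pool raises rather than returning NaN.
- `top_candidates` with a threshold at or above the maximum count returns
  an empty, well-formed table.
- Titrations require ≥ 2 distinct positive concentrations (≥ 4 for the
  fit) and equal replicate counts per point.

## Known limitations

- Flank matching tolerates substitutions only; an indel in a flank fails
  the read even with `max_mismatch > 0`.
- Exact-identity collapse treats a 1-error insert as a distinct sequence;
  no clustering or error correction is attempted (out of scope).
- The enrichment table is descriptive; no significance testing is attached
  to fold-changes.
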