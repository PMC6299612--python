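# Methods

This document records the models, parameter choices and numerical conventions
behind each `pldtox` module, together with the scope and known limitations of
the synthetic-data generator. Design decisions with non-obvious rationale are
cross-referenced to the relevant public function.

## 1. Homology screening (`pldtox.homology_screen`)

Input is a 12-column tabular hit file (query, subject, percent identity,
alignment length, mismatches, gap opens, query start/end, subject start/end,
E-value, bit score) plus a query-length table. Coverage of a hit is
`(query_end − query_start + 1) / query_length`, clamped to `[0, 1]` with a
warning if the raw value exceeds 1 (overlapping HSP coordinates).

`accept_hits` accepts a subject if, **among hits with coverage strictly
greater than 0.75**, either

* its best E-value to any single query is strictly below `1e-05`
  (`single_query` branch), or
* it has E-values strictly below `1e-03` to at least two *distinct* queries
  (`multi_query` branch).

All three inequalities are strict: a hit at exactly `E = 1e-05`, or at exactly
75% coverage, does not qualify. Subjects that satisfy either E-value rule only
through hits at or below the coverage gate are not accepted but flagged
`"fragmentary hit"`, so downstream users can distinguish "no homology
evidence" from "strong but truncated evidence". `expand_rounds` iterates the
rule with accepted subjects promoted to queries, recording the earliest round
each subject was recruited; it is a plain transitive closure and is tested
against a breadth-first-search oracle.

## 2. Curation (`pldtox.curation`)

Rules run in a fixed order inside `pldtox.pipeline.curate_records`:
**contaminants → fragments → active site → redundancy → evidence
confidence**. Order matters: a planted contaminant is also a 100% duplicate
of its source, and attributing it to the contaminant rule first keeps the
audit trail unambiguous. Every removal writes one audit row
`(record_id, stage, action, reason)`.

### 2.1 Pairwise identity and its degenerate cases

`pairwise_identity(a, b)` aligns globally with BLOSUM62, affine gaps
(open 10, extend 1) and **free terminal gaps** (Biopython
`PairwiseAligner`). Identity is `matches / aligned columns` computed over the
region between the first and last column in which *both* sequences have a
residue — terminal overhangs are excluded from the denominator. Where several
alignments are co-optimal in score, the maximum identity over co-optimal
alignments is reported (enumeration capped at 2000 alignments; ties broken
toward the larger aligned core).

This convention has a deliberate and a degenerate consequence:

* *Deliberate:* an exact fragment of a longer sequence scores 100%, which is
  what the redundancy and contamination rules need.
* *Degenerate:* for two essentially unrelated sequences the optimal
  free-end-gap alignment can collapse to a **single aligned column** (any
  shared high-scoring residue, e.g. one tryptophan, outscores alignments
  that must pay gap opens), giving an identity of 100% over one column.
  "Identity 100 ⟺ sequences identical" therefore cannot hold for this metric,
  and `pldtox` does not pretend it does.

The metric is kept as defined (it is simple, symmetric, and exactly matched
by an exhaustive-alignment oracle in the test suite); the *rules* that
consume it are guarded instead, as follows.

### 2.2 Contaminants

`flag_contaminants(records, references)` flags a record when a reference in a
**different phylum** (lineage rank 1) aligns with identity strictly above the
policy threshold (default 97.5) or exactly 100. Two guards:

* **Overlap gate.** `alignment_overlap_fraction(a, b)` = aligned-core columns
  of the identity-maximising alignment divided by the shorter sequence's
  length. References with overlap below `MIN_CONTAMINANT_OVERLAP = 0.5` are
  ignored, which exactly excludes the degenerate single-column anchors of
  §2.1 while retaining genuine contained fragments (overlap ≈ 1).
* **Best reference.** The flag reports the *highest-identity* qualifying
  reference, not the first one encountered, so that a genuine 100% match is
  never shadowed by a weaker cross-phylum homolog. The pipeline then applies
  a second, conservative gate: only flags whose identity also reaches the
  redundancy threshold (90) are acted on, and the record removed is the one
  from the phylum that is rarer for that sequence's neighbourhood.

Records or references without lineage information cannot be assessed and
produce a warning, never a flag.

### 2.3 Fragments, active sites, redundancy, confidence

* `filter_fragments`: removal reasons in precedence order — shorter than
  `min_length` (default 225 aa) → mapped domain fraction below
  `min_domain_fraction` (0.75) → a required active-site position deleted.
  Named exceptions are retained with an audit note.
* `screen_active_site`: each of His12, Glu32, Asp34, His47, Asp91, Lys93 is
  scored `canonical` (exact residue), `conservative` (BLOSUM62 score > 0),
  `nonconservative` (score ≤ 0) or `missing` (unmapped or `X`). A record is
  `divergent` only if *all* core positions (His12, Glu32, His47) are
  non-canonical — single substitutions at non-core sites are annotated, not
  removed.
* `filter_redundancy`: greedy clustering at ≥ 90% identity, longest sequence
  retained as representative. Purely identity-based — the degenerate case of
  §2.1 cannot fire here because contaminants and fragments have already been
  removed and surviving family members share the full domain.
* `flag_low_confidence`: evidence types are pooled per (phylum, class) group;
  a group with only transcriptome-type evidence is `low-confidence`
  (annotation only; nothing is removed).

## 3. Reference profile and classification (`pldtox.signatures`)

### 3.1 Profile

`default_profile()` compiles a deterministic exemplar alignment (built from
the same clade templates the generator uses) into a position-specific scoring
matrix: log₂-odds with Laplace pseudocount 1 against a uniform background.
Columns are annotated by region (βα1 loop, catalytic loop, active-site
columns, 6 + 11 plug columns, βα6 linker-Cys column). Profiles round-trip
through JSON (`profile_to_json`/`profile_from_json`), and
`build_reference_profile` accepts a user-supplied exemplar alignment.

### 3.2 Mapping

`map_to_reference` runs an affine-gap (open 10, extend 1) Needleman–Wunsch
against the PSSM with free terminal gaps and **position-specific gap costs**:
deleting a loop-region column, or inserting record residues while inside a
loop region, is free, because loop columns model a variable-length region
whose occupancy must not be penalised. Re-opening a gap on exiting a loop
region pays the normal open cost. The mapping reports per-column record
positions, `covered_fraction`, and a total score.

Two calibrated thresholds make "maps at all" and "has a plug" statistically
meaningful: at profile build time, 1000 seeded shuffles
(`CALIBRATION_SEED = 97301`) of family-composition sequences are mapped, and
`score_floor` / `plug_threshold` are set to the 99th percentile of the null
score distributions, so fewer than 1% of shuffled sequences pass either test.
Both thresholds are stored in the profile and survive JSON round trips, so
classification never re-runs calibration.

### 3.3 Feature measurement

* `measure_loops`: a loop length is the count of record residues between the
  fixed anchor columns flanking the loop region, so insertions within the
  loop count toward its length and deletions shorten it. Unmeasurable loops
  (an anchor unmapped) are `None`, never 0.
* `score_plug_motif`: the plug is scored over the 11 C-terminal motif columns
  only (the 6 N-terminal interacting residues are reported but not gated on,
  since fragments may lack them); unmatched motif columns pay
  `GAP_COLUMN_PENALTY = −2` each. If the mapping leaves the motif columns
  unmatched, a windowed rescan over the record's C-terminus is attempted
  (plug may be present with `span = None`). Present ⟺ score >
  `plug_threshold`.
* `detect_dufb_repeats`: scans C-terminal sequence for the 10-Cys repeat
  architecture with a ±2-residue spacing tolerance per inter-Cys segment,
  requiring the Gly-rich stretch and terminal Tyr.

### 3.4 Classifier

`classify_clade(features)` applies rules in a fixed order, returning
`(label, trace)` where the trace lists every rule consulted:

1. **non-family**: record unmappable (score below floor), plug absent, βα1
   unmeasurable, or βα1 length > 3 (the GDPD-insert signature);
2. **ST-like**: catalytic-loop length within 15 ± 1 *and* ≥ 2 catalytic-loop
   cysteines;
3. **Aquatic**: length ≥ 17 and ≥ 4 cysteines (DUF-B repeats are annotated
   but not required — some aquatic members lack them);
4. **AT-like**: length 9–13 and 0 cysteines;
5. **basal/unclassified** otherwise, with an explicit ambiguity note where
   AT-like could not be excluded: the loop signature alone cannot separate
   basal from AT-like sequences, and the classifier does not guess.

Fragmentary records that fail plug detection because the C-terminus is absent
fall into non-family with a trace naming the failed rule; callers needing to
rescue fragments should classify only curated full-length records (as the
pipeline does).

## 4. Gain/loss analysis (`pldtox.loss_analysis`)

### 4.1 Dollo loss counting

`dollo_losses(tree, states, origin_mode)` assumes a single origin — at the
root (`"root"`) or at the most recent common ancestor of the present tips
(`"mrca"`) — and no gains below it. The loss count is then exact, not
heuristic: losses are the **maximal all-absent subtrees** strictly below the
origin (a subtree counts once no matter how many absent tips it contains; a
subtree containing any present tip cannot be a loss; children of a polytomy
are assessed independently). Tips in state `unknown` are handled per
`unknown_mode`:

* `"excluded"` (default): unknown tips constrain nothing; branches whose
  status depends on them are reported in `unresolved_branches`;
* `"as_absent"` / `"as_present"`: recode and count normally.

The report carries the loss branches as frozensets of subtended tip names, so
equality with planted scenarios is testable exactly.

### 4.2 Minimum-cost histories

`min_cost_history` is a two-state Sankoff dynamic programme with asymmetric
costs `EventCosts(gain, loss)`. `gain = inf` selects the Dollo regime: gains
on branches are forbidden, and a single origin at the root is allowed *free
of charge* (it is reported as an event but contributes nothing to
`total_cost`; reporting it keeps the event list a complete history).
Root-state ties are resolved toward `absent` so that reported gains are never
gratuitous. `n_optimal` counts co-optimal full ancestral assignments.
`scenario_table` sweeps gain cost over a grid (including the Dollo row) and
reports costs and event counts; the number of gains is non-increasing in the
gain cost, and the Dollo row always has exactly one gain.

Both functions are verified against exhaustive enumeration of all ancestral
assignments (and, for Dollo, all origin placements) on hundreds of random
trees with polytomies and unknown tips (oracles in `tests/oracles.py`;
instances capped at 14 free nodes to keep 2¹⁴ enumeration tractable).

### 4.3 Packaged data

`src/pldtox/data/eukaryote_tree.nwk` (31 tips, with polytomies where
resolution is not defensible) and `eukaryote_presence.tsv` (`present` /
`absent` per family) encode the eukaryote species sample and the ST-like and
Aquatic presence annotations. Under root-origin Dollo counting these yield
15 ST-like and 18 Aquatic independent losses; `scripts/acceptance.py`
recomputes both at runtime.

## 5. Synthetic data (`pldtox.synthetic_data`)

### 5.1 Scope — what the generator is and is not

The generator produces sequences that *carry the family's diagnostic
signatures* with planted, machine-readable truth. It is **not** a model of
sequence evolution: there is no phylogeny relating the records, no
site-rate heterogeneity, no indel process, and no correlation between
records beyond the explicitly planted duplicate/contaminant pairs. Its
purpose is controlled, offline end-to-end testing of the screening, curation
and classification code paths — conclusions about real sequences must come
from real data.

### 5.2 Sequence model

`make_family_sequence(clade, rng, mutation_rate)` assembles a record from
clade templates: framework blocks, active-site residues, a clade-appropriate
catalytic loop (length and Cys content drawn from the clade's signature
range), βα1 loop, plug motif `GRDALNPIWSQ`, and, for Aquatic records, 1–4
DUF-B repeats. `GDPD-decoy` records carry a long βα1 loop and no plug.
Substitution noise is i.i.d. at `mutation_rate` (default 0.15) **at
non-diagnostic sites only**: active sites, loop cysteines, plug and DUF-B
cysteines are never mutated, and mutations never *introduce* cysteine (which
would corrupt Cys-count signatures). This keeps planted truth exact at the
cost of realism; the classifier-robustness test perturbs at 10% and requires
≥ 95% recovery rather than 100%.

### 5.3 Dataset model

`make_dataset(GeneratorConfig(seed))` draws 50 base records (12 ST, 12 AT,
12 Aquatic, 6 basal, 8 decoy) and plants, with truth columns for each:
5 fragments (truncated to 180 aa, below the 225-aa gate), 3 near-duplicate
pairs (2% divergence, ≥ 90% identity to source), 1 cross-phylum contaminant
(identical sequence, mismatched lineage), 2 active-site-divergent records,
and 2 low-confidence (transcriptome-only, isolated-group) records — 61
records total by default. The hit table cycles 8 boundary scenarios
(E-values and coverages straddling every strict inequality of §1) over all
records, with the intended decision stored in `truth.hit_decision` as
`scenario:accept|reject`. All draws come from a single `numpy` Generator
seeded by `GeneratorConfig.seed`; datasets are bit-reproducible.

Defaults are fixed study conditions chosen to exercise every rule at its
boundary; they are not tuned to any particular downstream outcome.

### 5.4 Dollo scenario simulator

`simulate_dollo(tree, n_losses, rng)` plants `n_losses` maximal, non-nested
loss subtrees such that every loss's parent retains a present tip (otherwise
the loss would merge with a sibling into a larger maximal subtree and the
count would not be recoverable). `max_feasible_losses` computes the largest
plantable count by dynamic programming; requests beyond it raise. Under
root-origin counting, recovery of both the count and the exact branch set is
guaranteed and tested on 100+ random scenarios.

## 6. Pipeline (`pldtox.pipeline`)

`run_pipeline(PipelineConfig)` chains simulate/ingest → screen → curate →
classify → gain/loss, writing per-stage TSVs, an audit trail, and
`manifest.json` with the full configuration echo, library versions, stage
counts and SHA-256 digests of every output. All stages are deterministic
given the seed; reruns are byte-identical (asserted in tests). Configuration
comes from a flat TOML file or keyword overrides; unknown keys are rejected,
`gain_cost = "inf"` selects the Dollo regime, and stage failures raise
`PipelineStageError` naming the stage.

## 7. Numerical conventions

* Alignment scoring uses BLOSUM62 throughout (substitution scoring in
  identity and active-site conservativeness; the profile uses log₂-odds).
* Gap costs are open 10 / extend 1 everywhere, with the first gap position
  charged `open` and each subsequent position `extend` (Biopython's
  convention), and terminal gap runs free.
* Percent identities are floats in `[0, 100]`; comparisons against policy
  thresholds use strict `>` for "above threshold" rules (§1, §2.2) and `>=`
  only where stated (redundancy at exactly 90% *is* redundant).
* Randomness: `numpy.random.default_rng` exclusively; every stochastic
  routine takes a seed or Generator, and no global seeding is used.

## 8. Known limitations

* The identity metric's degenerate-anchor behaviour (§2.1) is inherent to
  free-end-gap optimal alignment; it is contained by the overlap gate in the
  contaminant rule, but `pairwise_identity` itself should not be read as a
  similarity measure for unrelated sequences.
* The generator's noise model (§5.2) protects diagnostic residues, so
  classifier recovery rates on synthetic data are upper bounds on real-data
  performance.
* `mrca` origin mode conditions on the observed present tips; with many
  unknown tips the MRCA itself is uncertain and only the `unresolved_branches`
  report conveys that uncertainty.
* The packaged species tree intentionally keeps polytomies; loss counts on a
  fully resolved tree could differ, and `scenario_table` is the intended tool
  for sensitivity analysis rather than a single headline number.
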