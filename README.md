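# pldtox

Discovery, curation, signature classification and gene gain/loss analysis of
**GDPD-like SMase D/PLD** protein families — the derived toxin lineage of the
ubiquitous glycerophosphoryl diester phosphodiesterase (GDPD) superfamily that
includes sicariid spider venom sphingomyelinase D.

## Scientific background

GDPD-like SMase D/PLD domains occur patchily across eukaryotes and bacteria.
Members fall into recognisable clades distinguished by structural signatures:

* **ST-like** (sicariid-toxin-like): a 15-residue catalytic (βα2) loop
  carrying a conserved disulfide-forming cysteine pair, plus a third cysteine
  in the βα6 linker;
* **AT-like** (actinobacterial-toxin-like; bacterial and fungal members): a
  shorter 9–13-residue catalytic loop with no cysteines;
* **Aquatic**: an expanded (≥ 17-residue) catalytic loop with two cysteine
  pairs and one to four C-terminal cysteine-rich (DUF-B) repeats;
* **basal** sequences with a very short loop, not separable from AT-like
  members by the loop signature alone.

All true family members share the catalytic residues (His12, Glu32, Asp34,
His47, Asp91, Lys93 in mature ST numbering), a short (≈3-residue) βα1 loop,
and a conserved C-terminal "plug" motif; ancestral GDPD enzymes lack the plug
and carry a much longer βα1 loop, which is what the non-family gate detects.

The family's patchy phyletic distribution admits two competing histories:
repeated lateral transfer, or a single ancient origin followed by many
independent gene losses. `pldtox` quantifies the vertical-descent side of that
argument: under Dollo parsimony (one gain, losses only), the packaged
31-taxon eukaryote species tree and presence/absence annotations imply **15
independent losses of the ST-like family and 18 of the Aquatic family** when
the origin is placed at the root. A configurable-cost reconstruction
(`min_cost_history`) sweeps the gain/loss cost ratio to show how expensive
gains must be before the single-origin explanation wins.

Because the original discovery pipeline depends on live sequence databases,
`pldtox` ships a synthetic-data generator that plants every signature and
curation defect with machine-readable truth, so the full pipeline is testable
offline and end to end.

## Worked example

Run the full pipeline on a simulated dataset (simulation happens automatically
when no input FASTA/hit table is given):

```console
$ pldtox run --seed 7 --out results
{
 "classify": {
  "AT-like": 4,
  "Aquatic": 5,
  "ST-like": 6,
  "basal/unclassified": 3,
  "non-family": 3
 },
 "curate": {
  "active_site": 0,
  "contaminant": 1,
  "fragment": 2,
  "kept": 21,
  "records_in": 24,
  "redundant": 0
 },
 "gainloss": {
  "Aquatic": 18,
  "ST-like": 15
 },
 "inputs": {
  "hit_rows": 76,
  "records": 61
 },
 "screen": {
  "accepted": 24,
  "fragmentary_flagged": 15,
  "records_in": 61,
  "records_kept": 24,
  "records_removed": 37,
  "rejected": 37,
  "subjects": 61
 }
}
```

`results/` now contains `accepted.tsv` (screening decisions), `audit.tsv`
(one row per removed record with the rule and reason), `kept.fa`,
`features.tsv`, `calls.tsv` (clade labels with rule traces), `gainloss.tsv`,
and `manifest.json` (tool versions, seed, full config echo, stage counts, and
SHA-256 of every output — reruns are byte-identical).

Summarise the classification by lineage:

```console
$ pldtox summarize --calls results/calls.tsv
         group              label  count  low_confidence
Actinobacteria            AT-like      1               0
    Arthropoda            Aquatic      2               2
    Arthropoda            ST-like      6               0
    Ascomycota            AT-like      3               0
      Chordata         non-family      1               0
    Ctenophora            Aquatic      2               0
Proteobacteria basal/unclassified      3               0
Proteobacteria         non-family      2               0
      Rotifera            Aquatic      1               0
         TOTAL                        21               2
```

Count Dollo losses on the packaged eukaryote tree directly:

```console
$ pldtox gainloss --family ST-like --origin root -o st.tsv
ST-like: 15 Dollo losses (origin root) -> st.tsv
$ pldtox gainloss --family Aquatic --origin root -o aq.tsv
Aquatic: 18 Dollo losses (origin root) -> aq.tsv
```

The same from Python:

```python
from pldtox import dollo_losses, load_eukaryote_tree, load_pld_presence

tree = load_eukaryote_tree()
presence = load_pld_presence()
report = dollo_losses(tree, presence["ST-like"].to_dict(), origin_mode="root")
print(report.loss_count)        # 15
print(sorted(map(sorted, report.loss_branches))[:2])
```

Other subcommands: `pldtox simulate` (write a synthetic dataset with planted
truth), `pldtox screen` (hit-table acceptance only), `pldtox curate`,
`pldtox classify`, and `pldtox run --config run.toml` for a flat TOML config
(unknown keys are rejected; `gain_cost = "inf"` selects the Dollo regime).

## Layout

| Module | Purpose |
| --- | --- |
| `pldtox.io_formats` | FASTA / 12-column hit tables / Newick / presence matrices / ORF inference |
| `pldtox.homology_screen` | hit acceptance rules and multi-round search bookkeeping |
| `pldtox.curation` | redundancy, fragment, active-site, contaminant and confidence rules |
| `pldtox.signatures` | reference profile, loop/plug/DUF-B measurement, clade classification |
| `pldtox.loss_analysis` | Dollo loss counting, min-cost gain/loss histories, monophyly |
| `pldtox.synthetic_data` | sequence/dataset generator with planted truth; Dollo scenario simulator |
| `pldtox.pipeline` | stage orchestration, audit trail, manifest; `pldtox.cli` exposes it |

Methodological details and known limitations are documented in
[`docs/methods.md`](docs/methods.md).
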