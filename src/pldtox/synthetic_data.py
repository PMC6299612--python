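"""Synthetic GDPD-like SMase D/PLD datasets with planted, machine-readable truth.

The generator emulates the sequence structure the analysis pipeline relies on,
so that every downstream stage (hit screening, curation, signature
classification, gain/loss reconciliation) is testable without any database
download:

* family members carry the canonical active-site residues (His12, Glu32,
  Asp34, His47, Asp91, Lys93 in mature numbering), a short βα1 loop, a
  clade-diagnostic catalytic (βα2) loop, and the conserved C-terminal plug
  motif;
* the four family clade classes differ in catalytic-loop length and cysteine
  topology — ST-like: 15 residues with a conserved Cys pair plus a βα6-linker
  Cys; AT-like: 9–13 residues, no Cys; Aquatic: ≥ 17 residues, the ST Cys pair
  plus an extra pair, plus 1–4 C-terminal cysteine-rich (DUF-B) repeats;
  basal: a very short loop with no Cys;
* GDPD decoys lack the plug motif and carry a βα1 loop at least six residues
  longer plus a large GDPD-I insert in place of the catalytic loop;
* datasets additionally plant near-duplicate pairs, sub-length fragments,
  active-site-divergent variants, cross-lineage contaminant pairs and
  low-confidence (single-evidence-type) taxon groups, plus a tabular hit file
  whose E-values and coverages straddle every acceptance boundary.

Within-clade divergence is i.i.d. substitution noise applied to
*non-diagnostic* positions only: the planted active-site residues, cysteines
and key plug residues are conserved characters by definition of the clade
signatures, and the background never substitutes *into* Cys, so cysteine
topology cannot arise or vanish by chance.  No attempt is made to model
realistic phylogenetic sequence evolution.

All randomness flows from one integer seed through per-record substreams, so a
fixed seed yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io_formats import (
    HitRecord,
    SequenceRecord,
    SpeciesTree,
    write_fasta,
    write_hits_tabular,
)

__all__ = [
    "CLADES",
    "GeneratorConfig",
    "FamilyTruth",
    "GainLossScenario",
    "make_family_sequence",
    "make_dataset",
    "SyntheticDataset",
    "simulate_dollo",
    "max_feasible_losses",
    "consensus_sequence",
]

CLADES = ("ST", "AT", "Aquatic", "basal", "GDPD-decoy")

# Amino-acid background: uniform over the 19 non-Cys residues.  Cysteines are
# planted only, so cysteine topology is always signal, never chance.
BACKGROUND = "ADEFGHIKLMNPQRSTVWY"

# ---------------------------------------------------------------------------
# Domain architecture (mature ST numbering)
# ---------------------------------------------------------------------------
# nterm(11) H12 ba1(3) alpha1(16) E32 x33 D34 beta2(12) H47 catloop(clade)
# mid(28) D91 x92 K93 linker(17, Cys at +6) cterm(156) plug(11) tail(3)

NTERM = "KYLGVELSTQN"            # plug-interacting N-terminal residues at 1-3, 5
ALPHA1 = "AEQLDSLMKAIAESGA"
BETA2 = "TVKLVGDFVETS"
MID = "GLNDLVAGIRENPSATLMVKLDNIAEPG"
LINKER = "SPETGA" + "?" + "SVDKLIAEYR"   # '?' = linker-Cys slot (mature 100)
LINKER_CYS_OFFSET = 6
PLUG_CT = "GRDALNPIWSQ"          # Arg-Asp salt bridge, Ala/Pro, buried Trp
PLUG_CT_KEY = (1, 2, 3, 6, 8)    # offsets of R, D, A, P, W within PLUG_CT
NTERM_KEY = (0, 1, 2, 4)         # plug-interacting positions 1-3 and 5
TAIL = "GSL"
BA1_FAMILY_LEN = 3
X33, X92 = "A", "G"

ST_LOOP = "DGCKTLENGAPCSTD"      # 15 residues, Cys at loop offsets 2 and 11
ST_LOOP_CYS = (2, 11)

# DUF-B repeat: 70 residues, 10 conserved Cys, Gly-rich motif + Tyr at the end
DUFB_LEN = 70
DUFB_CYS = (2, 8, 15, 21, 29, 36, 44, 51, 57, 62)
DUFB_GLY_RICH = (63, 67)         # half-open span filled with Gly
DUFB_TYR = 68

GDPD_INSERT_LEN = 50             # GDPD-I stand-in occupying the βα2 region

_CTERM_SEED = 580_2018           # fixed stream for the shared framework filler


def _fixed_filler(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(BACKGROUND), size=n))


CTERM = _fixed_filler(156, _CTERM_SEED)


@dataclass
class FamilyTruth:
    """Ground-truth annotation for one generated record (1-based coordinates)."""

    id: str
    clade: str
    ba1_span: tuple[int, int]
    ba1_length: int
    cat_loop_span: tuple[int, int]
    cat_loop_length: int
    loop_cys_positions: tuple[int, ...]
    linker_cys_position: int | None
    active_sites: dict[str, int]
    plug_span: tuple[int, int] | None
    dufb_count: int
    dufb_spans: tuple[tuple[int, int], ...] = ()
    fragment: bool = False
    duplicate_of: str | None = None
    contaminant_of: str | None = None
    active_site_divergent: bool = False
    low_confidence_group: bool = False
    hit_decision: str | None = None

    @property
    def plug_present(self) -> bool:
        return self.plug_span is not None

    @property
    def loop_cys_count(self) -> int:
        return len(self.loop_cys_positions)


_LINEAGES = {
    "ST": [
        ("Eukaryota", "Arthropoda", "Chelicerata"),
        ("Eukaryota", "Arthropoda", "Acari"),
        ("Eukaryota", "Arthropoda", "Myriapoda"),
        ("Eukaryota", "Cnidaria", "Anthozoa"),
    ],
    "AT": [
        ("Bacteria", "Actinobacteria", "Streptomycetales"),
        ("Fungi", "Ascomycota", "Eurotiomycetes"),
        ("Fungi", "Ascomycota", "Sordariomycetes"),
    ],
    "Aquatic": [
        ("Eukaryota", "Ctenophora", "Tentaculata"),
        ("Eukaryota", "Rotifera", "Bdelloidea"),
        ("Eukaryota", "Cnidaria", "Hydrozoa"),
        ("Eukaryota", "Platyhelminthes", "Rhabditophora"),
    ],
    "basal": [
        ("Bacteria", "Proteobacteria", "Gammaproteobacteria"),
        ("Bacteria", "Proteobacteria", "Betaproteobacteria"),
    ],
    "GDPD-decoy": [
        ("Bacteria", "Proteobacteria", "Gammaproteobacteria"),
        ("Eukaryota", "Chordata", "Mammalia"),
    ],
}
_LOW_CONFIDENCE_LINEAGE = ("Eukaryota", "Arthropoda", "Malacostraca")
_CONTAMINANT_LINEAGE = ("Eukaryota", "Streptophyta", "Magnoliopsida")


def _rand_filler(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BACKGROUND), size=n))


def make_family_sequence(
    clade_label: str,
    rng: np.random.Generator,
    *,
    mutation_rate: float = 0.0,
    record_id: str = "syn_000",
    taxon: tuple[str, ...] = (),
    evidence: frozenset[str] = frozenset({"genome", "transcriptome"}),
) -> tuple[SequenceRecord, FamilyTruth]:
    """Generate one sequence of the requested clade class with truth annotation.

    ``mutation_rate`` substitutes non-diagnostic positions i.i.d. from the
    non-Cys background; diagnostic positions (active sites, cysteines, key plug
    residues, clade-invariant anchors used for length signatures) are kept.
    """
    if clade_label not in CLADES:
        raise ValueError(f"unknown clade label {clade_label!r}; expected one of {CLADES}")
    if not 0 <= mutation_rate <= 1:
        raise ValueError("mutation_rate must lie in [0, 1]")

    segments: list[tuple[str, str]] = []  # (segment name, residues)

    # βα1 loop
    if clade_label == "GDPD-decoy":
        ba1_len = int(rng.integers(BA1_FAMILY_LEN + 6, BA1_FAMILY_LEN + 10))
        ba1 = _rand_filler(rng, ba1_len)
    else:
        ba1_len = BA1_FAMILY_LEN
        ba1 = "GST"

    # catalytic (βα2) loop and cysteine topology
    loop_cys_offsets: tuple[int, ...] = ()
    if clade_label == "ST":
        loop = ST_LOOP
        loop_cys_offsets = ST_LOOP_CYS
    elif clade_label == "AT":
        loop = _rand_filler(rng, int(rng.integers(9, 14)))
    elif clade_label == "Aquatic":
        loop_len = int(rng.integers(17, 24))
        extra = (5, loop_len - 3)
        loop_cys_offsets = tuple(sorted(set(ST_LOOP_CYS) | set(extra)))
        chars = list(_rand_filler(rng, loop_len))
        for off in loop_cys_offsets:
            chars[off] = "C"
        loop = "".join(chars)
    elif clade_label == "basal":
        loop = _rand_filler(rng, int(rng.integers(6, 9)))
    else:  # GDPD decoy: the βα2 region is an entire small insert domain
        loop = _rand_filler(rng, GDPD_INSERT_LEN)

    has_linker_cys = clade_label in ("ST", "Aquatic")
    linker = LINKER.replace("?", "C" if has_linker_cys else "S")
    has_plug = clade_label != "GDPD-decoy"
    plug = PLUG_CT if has_plug else _rand_filler(rng, len(PLUG_CT))

    segments = [
        ("nterm", NTERM),
        ("H12", "H"),
        ("ba1", ba1),
        ("alpha1", ALPHA1),
        ("E32", "E"),
        ("x33", X33),
        ("D34", "D"),
        ("beta2", BETA2),
        ("H47", "H"),
        ("catloop", loop),
        ("mid", MID),
        ("D91", "D"),
        ("x92", X92),
        ("K93", "K"),
        ("linker", linker),
        ("cterm", CTERM),
        ("plug", plug),
        ("tail", TAIL),
    ]

    # DUF-B repeats C-terminal of the catalytic domain (Aquatic only)
    dufb_count = 0
    if clade_label == "Aquatic":
        dufb_count = int(rng.integers(1, 5))
        for r in range(dufb_count):
            segments.append((f"dufb{r}", _make_dufb_repeat(rng)))

    seq_chars: list[str] = []
    spans: dict[str, tuple[int, int]] = {}
    for name, residues in segments:
        start = len(seq_chars) + 1
        seq_chars.extend(residues)
        spans[name] = (start, len(seq_chars))

    diagnostic = _diagnostic_positions(spans, clade_label, loop_cys_offsets, has_linker_cys, has_plug)

    if mutation_rate > 0:
        mask = rng.random(len(seq_chars)) < mutation_rate
        for i in np.nonzero(mask)[0]:
            if (i + 1) in diagnostic:
                continue
            choices = [a for a in BACKGROUND if a != seq_chars[i]]
            seq_chars[i] = choices[int(rng.integers(len(choices)))]

    residues = "".join(seq_chars)
    loop_start = spans["catloop"][0]
    dufb_spans = tuple(spans[f"dufb{r}"] for r in range(dufb_count))
    truth = FamilyTruth(
        id=record_id,
        clade=clade_label,
        ba1_span=spans["ba1"],
        ba1_length=ba1_len,
        cat_loop_span=spans["catloop"],
        cat_loop_length=len(loop),
        loop_cys_positions=tuple(loop_start + off for off in loop_cys_offsets),
        linker_cys_position=(spans["linker"][0] + LINKER_CYS_OFFSET) if has_linker_cys else None,
        active_sites={
            "His12": spans["H12"][0],
            "Glu32": spans["E32"][0],
            "Asp34": spans["D34"][0],
            "His47": spans["H47"][0],
            "Asp91": spans["D91"][0],
            "Lys93": spans["K93"][0],
        },
        plug_span=spans["plug"] if has_plug else None,
        dufb_count=dufb_count,
        dufb_spans=dufb_spans,
    )
    record = SequenceRecord(
        id=record_id, residues=residues, taxon=taxon, evidence=evidence
    )
    return record, truth


def _make_dufb_repeat(rng: np.random.Generator) -> str:
    chars = list(_rand_filler(rng, DUFB_LEN))
    for off in DUFB_CYS:
        chars[off] = "C"
    for i in range(*DUFB_GLY_RICH):
        chars[i] = "G"
    chars[DUFB_TYR] = "Y"
    return "".join(chars)


def _diagnostic_positions(
    spans: Mapping[str, tuple[int, int]],
    clade: str,
    loop_cys_offsets: tuple[int, ...],
    has_linker_cys: bool,
    has_plug: bool,
) -> frozenset[int]:
    """1-based positions never touched by within-clade substitution noise."""
    diag: set[int] = set()
    for name in ("H12", "E32", "D34", "H47", "D91", "K93"):
        diag.add(spans[name][0])
    loop_start = spans["catloop"][0]
    diag.update(loop_start + off for off in loop_cys_offsets)
    if has_linker_cys:
        diag.add(spans["linker"][0] + LINKER_CYS_OFFSET)
    if has_plug:
        plug_start = spans["plug"][0]
        diag.update(plug_start + off for off in PLUG_CT_KEY)
        nterm_start = spans["nterm"][0]
        diag.update(nterm_start + off for off in NTERM_KEY)
    for name, (start, end) in spans.items():
        if name.startswith("dufb"):
            diag.update(start + off for off in DUFB_CYS)
            diag.update(range(start + DUFB_GLY_RICH[0], start + DUFB_GLY_RICH[1]))
            diag.add(start + DUFB_TYR)
    return frozenset(diag)


def consensus_sequence(clade_label: str = "ST") -> str:
    """Noise-free representative sequence of a clade (fixed substream)."""
    rec, _ = make_family_sequence(clade_label, np.random.default_rng(0))
    return rec.residues


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

@dataclass
class GeneratorConfig:
    """Knobs for :func:`make_dataset`; a fixed seed gives byte-identical output.

    Defaults plant a dataset at the scale the curation rules were designed
    around: moderate within-clade divergence (15% substitutions at
    non-diagnostic sites), a few near-duplicate pairs above the redundancy
    threshold, ~10% fragmentary records, and single-figure counts of
    contaminant pairs, active-site-divergent variants and transcriptome-only
    records.
    """

    seed: int = 0
    counts: Mapping[str, int] = field(
        default_factory=lambda: {
            "ST": 12, "AT": 12, "Aquatic": 12, "basal": 6, "GDPD-decoy": 8
        }
    )
    mutation_rate: float = 0.15
    fragment_fraction: float = 0.1
    contaminant_pairs: int = 1
    redundancy_pairs: int = 3
    divergent_active_sites: int = 2
    low_confidence_records: int = 2
    duplicate_divergence: float = 0.02  # substitution rate copy vs. source

    def __post_init__(self) -> None:
        for clade, n in self.counts.items():
            if clade not in CLADES:
                raise ValueError(f"unknown clade {clade!r} in counts")
            if n < 0:
                raise ValueError("counts must be >= 0")
        for name in ("mutation_rate", "fragment_fraction", "duplicate_divergence"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("contaminant_pairs", "redundancy_pairs",
                     "divergent_active_sites", "low_confidence_records"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


FRAGMENT_KEEP = 180  # C-terminal residues kept in planted fragments (< 225)

# Screening boundary scenarios cycled over subjects in the planted hit table.
# (name, rows as (query, evalue, coverage), expected decision)
_HIT_SCENARIOS = [
    ("accept_single", [("q1", 1e-08, 0.90)], "accept"),
    ("accept_multi", [("q1", 5e-04, 0.80), ("q2", 5e-04, 0.85)], "accept"),
    ("reject_single_weak", [("q1", 5e-04, 0.90)], "reject"),
    ("reject_low_coverage", [("q1", 1e-30, 0.50)], "reject"),
    ("accept_near_single_boundary", [("q1", 9.9e-06, 0.80)], "accept"),
    ("reject_at_single_boundary", [("q1", 1e-05, 0.80)], "reject"),
    ("reject_at_multi_boundary", [("q1", 1e-03, 0.80), ("q2", 1e-03, 0.80)], "reject"),
    ("reject_at_coverage_boundary", [("q1", 1e-08, 0.75)], "reject"),
]
QUERY_LENGTH = 280
QUERY_IDS = ("q1", "q2", "q3")


@dataclass
class SyntheticDataset:
    """A generated dataset: records, planted truth, and a tabular hit file."""

    records: list[SequenceRecord]
    truth: pd.DataFrame
    hits: list[HitRecord]
    query_lengths: dict[str, int]
    config: GeneratorConfig

    def truth_for(self, record_id: str) -> pd.Series:
        return self.truth.loc[record_id]

    def write(self, outdir) -> None:
        """Write FASTA + truth TSV + hits TSV into ``outdir``."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "sequences.fasta", "w") as fh:
            write_fasta(self.records, fh)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t")
        with open(outdir / "hits.tsv", "w") as fh:
            write_hits_tabular(self.hits, fh)
        with open(outdir / "query_lengths.tsv", "w") as fh:
            for q, n in self.query_lengths.items():
                fh.write(f"{q}\t{n}\n")


def make_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Generate a full fixture dataset with planted curation defects.

    The planted defects are disjoint by construction — fragments and
    active-site-divergent variants are fresh draws rather than copies of base
    records, near-duplicates sit well above the redundancy threshold while
    base records sit well below it — so the number of records removed by each
    curation rule equals the planted count exactly.
    """
    ss = np.random.SeedSequence(config.seed)
    streams = iter(ss.spawn(4096))

    records: list[SequenceRecord] = []
    truths: list[FamilyTruth] = []

    def add(clade, rid, taxon, evidence, *, mutation_rate=None, low_conf=False):
        rng = np.random.default_rng(next(streams))
        rec, truth = make_family_sequence(
            clade,
            rng,
            mutation_rate=config.mutation_rate if mutation_rate is None else mutation_rate,
            record_id=rid,
            taxon=taxon,
            evidence=evidence,
        )
        truth.low_confidence_group = low_conf
        records.append(rec)
        truths.append(truth)
        return rec, truth

    # --- base family/decoy members ---
    n_low_conf = config.low_confidence_records
    for clade in CLADES:
        lineages = _LINEAGES[clade]
        for i in range(config.counts.get(clade, 0)):
            rid = f"{clade.replace('-', '')}_{i:03d}"
            if clade == "Aquatic" and i < n_low_conf:
                taxon, evidence, low = (
                    _LOW_CONFIDENCE_LINEAGE,
                    frozenset({"transcriptome"}),
                    True,
                )
            else:
                taxon = lineages[i % len(lineages)]
                evidence, low = frozenset({"genome", "transcriptome"}), False
            add(clade, rid, taxon, evidence, low_conf=low)

    base_records = list(records)
    base_truths = list(truths)
    base_family = [
        (r, t) for r, t in zip(base_records, base_truths) if t.clade != "GDPD-decoy"
    ]
    if not base_family and (
        config.redundancy_pairs or config.contaminant_pairs or config.fragment_fraction
    ):
        raise ValueError("cannot plant defects without family base records")

    # --- near-duplicate pairs (above the redundancy threshold) ---
    for k in range(config.redundancy_pairs):
        src, src_truth = base_family[k % len(base_family)]
        rng = np.random.default_rng(next(streams))
        dup_chars = list(src.residues)
        diag = {p - 1 for p in _truth_diag_positions(src_truth)}
        mask = rng.random(len(dup_chars)) < config.duplicate_divergence
        for i in np.nonzero(mask)[0]:
            if i in diag:
                continue
            choices = [a for a in BACKGROUND if a != dup_chars[i]]
            dup_chars[i] = choices[int(rng.integers(len(choices)))]
        dup_truth = dataclasses.replace(
            src_truth, id=f"{src.id}_dup{k}", duplicate_of=src.id
        )
        records.append(
            SequenceRecord(
                id=dup_truth.id,
                residues="".join(dup_chars),
                taxon=src.taxon,
                evidence=src.evidence,
            )
        )
        truths.append(dup_truth)

    # --- fragments (fresh draws truncated to the C-terminal part) ---
    n_base = len(base_records)
    n_frag = int(round(config.fragment_fraction * n_base))
    frag_clades = [c for c in ("ST", "AT", "Aquatic") if config.counts.get(c, 0)] or ["ST"]
    for k in range(n_frag):
        clade = frag_clades[k % len(frag_clades)]
        rng = np.random.default_rng(next(streams))
        rec, truth = make_family_sequence(
            clade,
            rng,
            mutation_rate=config.mutation_rate,
            record_id=f"frag_{k:03d}",
            taxon=_LINEAGES[clade][0],
            evidence=frozenset({"transcriptome"}),
        )
        cut = len(rec.residues) - FRAGMENT_KEEP
        frag_truth = dataclasses.replace(truth, id=rec.id, fragment=True)
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=rec.residues[cut:],
                taxon=rec.taxon,
                evidence=rec.evidence,
                source_note="fragment",
            )
        )
        truths.append(frag_truth)

    # --- active-site-divergent variants (nonconservative at the core triad) ---
    for k in range(config.divergent_active_sites):
        rng = np.random.default_rng(next(streams))
        rec, truth = make_family_sequence(
            "AT",
            rng,
            mutation_rate=config.mutation_rate,
            record_id=f"divergent_{k:03d}",
            taxon=_LINEAGES["AT"][1],
            evidence=frozenset({"genome", "transcriptome"}),
        )
        chars = list(rec.residues)
        chars[truth.active_sites["His12"] - 1] = "L"
        chars[truth.active_sites["Glu32"] - 1] = "G"
        chars[truth.active_sites["His47"] - 1] = "L"
        div_truth = dataclasses.replace(truth, active_site_divergent=True)
        records.append(
            SequenceRecord(
                id=rec.id, residues="".join(chars), taxon=rec.taxon, evidence=rec.evidence
            )
        )
        truths.append(div_truth)

    # --- contaminant pairs (identical sequence, incompatible lineage) ---
    mite_sources = [
        (r, t)
        for r, t in zip(base_records, base_truths)
        if t.clade == "ST" and "Acari" in r.taxon
    ] or base_family
    for k in range(config.contaminant_pairs):
        src, src_truth = mite_sources[k % len(mite_sources)]
        cont_truth = dataclasses.replace(
            src_truth, id=f"{src.id}_cont{k}", contaminant_of=src.id
        )
        records.append(
            SequenceRecord(
                id=cont_truth.id,
                residues=src.residues,
                taxon=_CONTAMINANT_LINEAGE,
                evidence=frozenset({"transcriptome"}),
            )
        )
        truths.append(cont_truth)

    # --- tabular hit file spanning the acceptance boundaries ---
    hits: list[HitRecord] = []
    for idx, (rec, truth) in enumerate(zip(records, truths)):
        name, rows, decision = _HIT_SCENARIOS[idx % len(_HIT_SCENARIOS)]
        truth.hit_decision = f"{name}:{decision}"
        for query, evalue, cov in rows:
            aln = int(round(cov * QUERY_LENGTH))
            hits.append(
                HitRecord(
                    query_id=query,
                    subject_id=rec.id,
                    percent_identity=40.0,
                    alignment_length=aln,
                    mismatches=int(aln * 0.6),
                    gap_opens=2,
                    query_span=(1, aln),
                    subject_span=(1, min(aln, len(rec.residues))),
                    evalue=evalue,
                    bitscore=max(30.0, 180.0 - 10 * np.log10(evalue + 1e-300)) if evalue else 400.0,
                    query_length=QUERY_LENGTH,
                )
            )

    truth_df = pd.DataFrame(
        [
            {
                "id": t.id,
                "clade": t.clade,
                "lineage": "|".join(r.taxon),
                "evidence": ",".join(sorted(r.evidence)),
                "length": len(r.residues),
                "ba1_length": t.ba1_length,
                "cat_loop_length": t.cat_loop_length,
                "cat_loop_start": t.cat_loop_span[0],
                "cat_loop_end": t.cat_loop_span[1],
                "loop_cys_count": t.loop_cys_count,
                "linker_cys": t.linker_cys_position is not None,
                "plug_present": t.plug_present,
                "dufb_repeats": t.dufb_count,
                "fragment": t.fragment,
                "duplicate_of": t.duplicate_of or "",
                "contaminant_of": t.contaminant_of or "",
                "active_site_divergent": t.active_site_divergent,
                "low_confidence_group": t.low_confidence_group,
                "hit_decision": t.hit_decision or "",
            }
            for r, t in zip(records, truths)
        ]
    ).set_index("id")

    return SyntheticDataset(
        records=records,
        truth=truth_df,
        hits=hits,
        query_lengths={q: QUERY_LENGTH for q in QUERY_IDS},
        config=config,
    )


def _truth_diag_positions(truth: FamilyTruth) -> set[int]:
    diag = set(truth.active_sites.values())
    diag.update(truth.loop_cys_positions)
    if truth.linker_cys_position:
        diag.add(truth.linker_cys_position)
    if truth.plug_span:
        diag.update(truth.plug_span[0] + off for off in PLUG_CT_KEY)
        diag.update(1 + off for off in NTERM_KEY)
    for start, _ in truth.dufb_spans:
        diag.update(start + off for off in DUFB_CYS)
    return diag


# ---------------------------------------------------------------------------
# Dollo scenario simulation
# ---------------------------------------------------------------------------

@dataclass
class GainLossScenario:
    """A planted single-gain-plus-losses history on a species tree.

    Loss branches are identified by the tip sets below them; they are mutually
    non-nested and each is maximal (its parent clade retains a present tip), so
    Dollo loss counting recovers them exactly.
    """

    tree: SpeciesTree
    gain_node_label: str
    loss_branches: frozenset[frozenset[str]]
    present_tips: frozenset[str]

    @property
    def n_losses(self) -> int:
        return len(self.loss_branches)

    def presence_column(self) -> dict[str, str]:
        return {
            tip: ("present" if tip in self.present_tips else "absent")
            for tip in self.tree.tip_names
        }


def max_feasible_losses(tree: SpeciesTree, gain_node=None) -> int:
    """Maximum number of maximal, mutually non-nested loss branches below a node
    that still leaves at least one tip present."""
    node = gain_node if gain_node is not None else tree.root
    score: dict[int, int] = {}
    for v in node.postorder_iter():
        if v.is_leaf():
            score[id(v)] = 0
            continue
        children = v.child_nodes()
        # each child is either lost whole (1 event) or kept partly present
        total = sum(max(score[id(c)], 1) for c in children)
        if all(score[id(c)] == 0 for c in children):
            total -= 1  # at least one child subtree must stay present
        score[id(v)] = total
    return score[id(node)]


def simulate_dollo(
    tree: SpeciesTree,
    n_losses: int,
    rng: np.random.Generator,
    *,
    gain_node_label: str | None = None,
    max_attempts: int = 200,
) -> GainLossScenario:
    """Plant a single gain plus ``n_losses`` maximal losses on a rooted tree.

    The gain sits at the named node (default: the root).  Loss branches are
    sampled so that no loss is nested in another and every loss branch's parent
    clade keeps at least one present tip — the conditions under which the
    planted set is exactly the Dollo-minimal explanation of the resulting
    presence pattern.
    """
    if n_losses < 0:
        raise ValueError("n_losses must be >= 0")
    gain = tree.find_node(gain_node_label) if gain_node_label else tree.root
    gain_label = gain_node_label or (tree.node_label(gain) or "root")
    feasible = max_feasible_losses(tree, gain)
    if n_losses > feasible:
        raise ValueError(
            f"cannot place {n_losses} maximal losses below {gain_label!r}: "
            f"maximum feasible is {feasible}"
        )
    gain_tips = tree.leaf_set(gain)
    candidates = [n for n in gain.preorder_iter() if n is not gain]

    parent_of = {id(n): n.parent_node for n in candidates}
    tipsets = {id(n): tree.leaf_set(n) for n in candidates}
    tipsets[id(gain)] = gain_tips

    for _ in range(max_attempts):
        order = [candidates[i] for i in rng.permutation(len(candidates))]
        chosen: list = []
        lost: set[str] = set()
        for v in order:
            if len(chosen) == n_losses:
                break
            vt = tipsets[id(v)]
            if vt & lost:  # overlaps (nested with) an existing loss
                continue
            new_lost = lost | vt
            # every chosen loss (incl. v) must leave its parent partly present
            ok = all(
                not (tipsets[id(parent_of[id(u)])] <= new_lost)
                for u in chosen + [v]
            )
            if ok and new_lost != gain_tips:
                chosen.append(v)
                lost = new_lost
        if len(chosen) == n_losses:
            present = gain_tips - lost
            return GainLossScenario(
                tree=tree,
                gain_node_label=gain_label,
                loss_branches=frozenset(tipsets[id(u)] for u in chosen),
                present_tips=frozenset(present),
            )
    raise RuntimeError(
        f"failed to sample {n_losses} losses in {max_attempts} attempts "
        f"(feasible maximum {feasible}); tree may be highly constrained"
    )
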