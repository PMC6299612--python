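"""End-to-end orchestration: screen -> curate -> classify -> gain/loss.

:func:`run_pipeline` sequences the analysis stages over a FASTA + tabular hit
file (or a freshly simulated dataset), writing a reproducible report bundle:

* ``accepted.tsv``  — per-subject screening decisions with rationale;
* ``audit.tsv``     — per-record curation dispositions (kept/removed/flagged);
* ``kept.fa``       — curated sequence set;
* ``features.tsv``  — measured signature features per kept record;
* ``calls.tsv``     — clade classifications with rule traces;
* ``gainloss.tsv``  — Dollo losses and min-cost histories per family;
* ``manifest.json`` — versions, seed, policy echo, per-stage counts, output
  hashes.  Identical config + seed gives byte-identical outputs.

Stage counts are conserved: every stage's input count equals its kept plus
removed counts, and the audit file carries the record-level reasons.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .curation import (
    ActiveSiteSpec,
    CurationPolicy,
    filter_fragments,
    filter_redundancy,
    flag_contaminants,
    flag_low_confidence,
)
from .datasets import load_eukaryote_tree, load_pld_presence
from .homology_screen import ScreenPolicy, accept_hits
from .io_formats import SequenceRecord, read_fasta, read_hits_tabular, write_fasta
from .loss_analysis import EventCosts, dollo_losses, min_cost_history
from .signatures import (
    CladeSignatureSpec,
    ReferenceProfile,
    classify_clade,
    default_profile,
    extract_features,
    profile_from_json,
)
from .synthetic_data import GeneratorConfig, make_dataset

__all__ = [
    "PipelineConfig",
    "PipelineStageError",
    "run_pipeline",
    "summarize_by_taxon",
]

log = logging.getLogger("pldtox.pipeline")


class PipelineStageError(RuntimeError):
    """An analysis stage failed; carries the stage name and context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Inputs, policies, and output location for one pipeline run.

    ``fasta``/``hits`` of None simulate a synthetic dataset from ``seed`` into
    ``outdir/inputs`` and analyse that.  ``tree``/``presence`` of None fall
    back to the packaged eukaryote tree and family presence matrix.
    """

    fasta: str | None = None
    hits: str | None = None
    tree: str | None = None
    presence: str | None = None
    profile: str | None = None          # JSON reference profile; None = packaged
    outdir: str = "results"
    seed: int = 0
    families: tuple[str, ...] = ("ST-like", "Aquatic")
    origin_mode: str = "root"
    screen_policy: ScreenPolicy = field(default_factory=ScreenPolicy)
    curation_policy: CurationPolicy = field(default_factory=CurationPolicy)
    signature_spec: CladeSignatureSpec = field(default_factory=CladeSignatureSpec)
    costs: EventCosts = field(default_factory=lambda: EventCosts(gain=4.0, loss=1.0))

    def validate(self) -> None:
        for name in ("fasta", "hits", "tree", "presence", "profile"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name} input does not exist: {value}")
        if self.origin_mode not in ("root", "mrca"):
            raise ValueError(f"invalid origin_mode {self.origin_mode!r}")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load a flat TOML config; unknown keys are an error."""
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls.from_flat(data)

    @classmethod
    def from_flat(cls, data: Mapping) -> "PipelineConfig":
        data = dict(data)
        kwargs: dict = {}
        for name in (
            "fasta", "hits", "tree", "presence", "profile", "outdir",
            "seed", "origin_mode",
        ):
            if name in data:
                kwargs[name] = data.pop(name)
        if "families" in data:
            kwargs["families"] = tuple(data.pop("families"))

        def sub(cls_, prefix_map):
            picked = {
                field_name: data.pop(key)
                for key, field_name in prefix_map.items()
                if key in data
            }
            return cls_(**picked)

        kwargs["screen_policy"] = sub(
            ScreenPolicy,
            {"e_single": "e_single", "e_multi": "e_multi",
             "min_coverage": "min_coverage", "min_queries_multi": "min_queries_multi"},
        )
        kwargs["curation_policy"] = sub(
            CurationPolicy,
            {"redundancy_identity": "redundancy_identity", "min_length": "min_length",
             "min_domain_fraction": "min_domain_fraction",
             "contaminant_identity": "contaminant_identity",
             "required_evidence_types": "required_evidence_types"},
        )
        kwargs["signature_spec"] = sub(
            CladeSignatureSpec,
            {"st_loop_length": "st_loop_length", "st_tolerance": "st_tolerance",
             "st_min_loop_cys": "st_min_loop_cys",
             "aquatic_min_length": "aquatic_min_length",
             "aquatic_min_cys": "aquatic_min_cys", "ba1_max": "ba1_max",
             "decoy_margin": "decoy_margin"},
        )
        gain = data.pop("gain_cost", 4.0)
        gain = math.inf if gain in ("inf", "Dollo") else float(gain)
        kwargs["costs"] = EventCosts(gain=gain, loss=float(data.pop("loss_cost", 1.0)))
        if data:
            raise ValueError(f"unknown config keys: {sorted(data)}")
        return cls(**kwargs)

    def echo(self) -> dict:
        """JSON-serialisable copy of every policy value (for the manifest)."""
        def plain(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, float) and math.isinf(obj):
                return "inf"
            if isinstance(obj, (tuple, list)):
                return [plain(v) for v in obj]
            if isinstance(obj, Mapping):
                return {k: plain(v) for k, v in obj.items()}
            return obj

        return plain(self)


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, dict] = {}

    # --- stage: inputs -----------------------------------------------------
    stage = "inputs"
    try:
        config.validate()
        if config.fasta is None or config.hits is None:
            log.info("no input FASTA/hits given; simulating dataset (seed %d)", config.seed)
            dataset = make_dataset(GeneratorConfig(seed=config.seed))
            inputs = outdir / "inputs"
            dataset.write(inputs)
            fasta_path = inputs / "sequences.fasta"
            hits_path = inputs / "hits.tsv"
        else:
            fasta_path, hits_path = Path(config.fasta), Path(config.hits)
        with open(fasta_path) as fh:
            records = read_fasta(fh)
        query_lengths = _sibling_query_lengths(hits_path)
        with open(hits_path) as fh:
            hits = read_hits_tabular(fh, query_lengths)
        if config.profile is not None:
            profile = profile_from_json(Path(config.profile).read_text())
        else:
            profile = default_profile()
    except Exception as err:  # noqa: BLE001 - re-raised with stage context
        raise PipelineStageError(stage, str(err)) from err
    counts["inputs"] = {"records": len(records), "hit_rows": len(hits)}
    log.info("inputs: %d records, %d hit rows", len(records), len(hits))

    # --- stage: screen -----------------------------------------------------
    stage = "screen"
    try:
        screen = accept_hits(hits, config.screen_policy)
        subjects = sorted({h.subject_id for h in hits})
        rows = []
        for subject in subjects:
            if subject in screen.accepted:
                r = screen.accepted[subject]
                rows.append(
                    {"subject_id": subject, "decision": "accepted",
                     "branch": r.branch,
                     "supporting_queries": ",".join(r.supporting_queries),
                     "best_evalue": r.best_evalue,
                     "flag": screen.flags.get(subject, "")}
                )
            else:
                rows.append(
                    {"subject_id": subject, "decision": "rejected", "branch": "",
                     "supporting_queries": "", "best_evalue": "",
                     "flag": screen.flags.get(subject, "")}
                )
        _write_tsv(pd.DataFrame(rows), outdir / "accepted.tsv")
        screened = [r for r in records if r.id in screen.accepted]
        screened_out = [r for r in records if r.id not in screen.accepted]
    except PipelineStageError:
        raise
    except Exception as err:  # noqa: BLE001
        raise PipelineStageError(stage, str(err)) from err
    counts["screen"] = {
        "subjects": len(subjects),
        "accepted": len(screen.accepted),
        "fragmentary_flagged": len(screen.flags),
        "rejected": len(subjects) - len(screen.accepted),
        "records_in": len(records),
        "records_kept": len(screened),
        "records_removed": len(screened_out),
    }
    log.info("screen: accepted %d of %d subjects", len(screen.accepted), len(subjects))

    # --- stage: curate -----------------------------------------------------
    stage = "curate"
    try:
        audit: list[dict] = []
        for rec in screened_out:
            audit.append({"record_id": rec.id, "stage": "screen",
                          "action": "removed", "reason": "no accepted hit"})
        outcome = curate_records(screened, config.curation_policy, profile)
        pool = outcome.kept
        feats = outcome.features
        confidence = outcome.confidence
        audit.extend(outcome.audit_rows)
        audit_df = pd.DataFrame(audit, columns=["record_id", "stage", "action", "reason"])
        _write_tsv(audit_df, outdir / "audit.tsv")
        with open(outdir / "kept.fa", "w") as fh:
            write_fasta(pool, fh)
    except PipelineStageError:
        raise
    except Exception as err:  # noqa: BLE001
        raise PipelineStageError(stage, str(err)) from err
    counts["curate"] = {"records_in": len(screened), **outcome.counts}
    assert counts["curate"]["records_in"] == (
        sum(outcome.counts[k] for k in ("contaminant", "fragment", "active_site", "redundant"))
        + outcome.counts["kept"]
    ), "stage counts not conserved"
    log.info("curate: kept %d of %d records", len(pool), len(screened))

    # --- stage: classify ---------------------------------------------------
    stage = "classify"
    try:
        feature_rows, call_rows = [], []
        label_counts: dict[str, int] = {}
        for rec in pool:
            f = feats[rec.id]
            label, trace = classify_clade(f, config.signature_spec)
            label_counts[label] = label_counts.get(label, 0) + 1
            cys_pattern = ";".join(str(p) for p in f.loop_cys_positions)
            feature_rows.append({
                "id": rec.id,
                "plug_score": round(f.plug_score, 3),
                "plug_present": f.plug_present,
                "ba1_length": "" if f.ba1_length is None else f.ba1_length,
                "cat_loop_length": "" if f.cat_loop_length is None else f.cat_loop_length,
                "loop_cys_positions": cys_pattern,
                "linker_cys": f.linker_cys_present,
                "dufb_repeats": f.dufb_repeat_count,
                "covered_fraction": round(f.covered_fraction, 4),
                "mappable": f.mappable,
            })
            call_rows.append({
                "id": rec.id,
                "label": label,
                "plug_score": round(f.plug_score, 3),
                "ba1_length": "" if f.ba1_length is None else f.ba1_length,
                "cat_loop_length": "" if f.cat_loop_length is None else f.cat_loop_length,
                "cys_pattern": cys_pattern,
                "dufb_repeats": f.dufb_repeat_count,
                "lineage": "|".join(rec.taxon),
                "confidence": confidence.get(rec.id, "confident"),
                "rule_trace": " ; ".join(trace),
            })
        _write_tsv(pd.DataFrame(feature_rows), outdir / "features.tsv")
        _write_tsv(pd.DataFrame(call_rows), outdir / "calls.tsv")
    except PipelineStageError:
        raise
    except Exception as err:  # noqa: BLE001
        raise PipelineStageError(stage, str(err)) from err
    counts["classify"] = dict(sorted(label_counts.items()))
    log.info("classify: %s", counts["classify"])

    # --- stage: gainloss ---------------------------------------------------
    stage = "gainloss"
    try:
        if config.tree is not None:
            from .io_formats import read_newick

            tree = read_newick(Path(config.tree).read_text())
        else:
            tree = load_eukaryote_tree()
        if config.presence is not None:
            from .io_formats import read_presence_matrix

            with open(config.presence) as fh:
                presence = read_presence_matrix(fh)
        else:
            presence = load_pld_presence()
        gl_rows = []
        loss_counts: dict[str, int] = {}
        for family in config.families:
            if family not in presence.columns:
                raise KeyError(f"family {family!r} not in presence matrix columns "
                               f"{list(presence.columns)}")
            column = presence[family].to_dict()
            report = dollo_losses(
                tree, column, origin_mode=config.origin_mode, family=family
            )
            hist = min_cost_history(tree, column, config.costs, family=family)
            loss_counts[family] = report.loss_count
            gl_rows.append({
                "family": family,
                "origin": report.origin_label,
                "dollo_losses": report.loss_count,
                "loss_branches": ";".join(
                    "|".join(sorted(b)) for b in sorted(report.loss_branches, key=sorted)
                ),
                "mincost_total": hist.total_cost,
                "mincost_gains": hist.n_gains,
                "mincost_losses": hist.n_losses,
                "n_optimal": hist.n_optimal,
            })
        _write_tsv(pd.DataFrame(gl_rows), outdir / "gainloss.tsv")
    except PipelineStageError:
        raise
    except Exception as err:  # noqa: BLE001
        raise PipelineStageError(stage, str(err)) from err
    counts["gainloss"] = loss_counts
    log.info("gainloss: %s", loss_counts)

    # --- manifest ----------------------------------------------------------
    manifest = {
        "versions": _versions(),
        "seed": config.seed,
        "config": config.echo(),
        "stage_counts": counts,
        "outputs": {
            name: _sha256(outdir / name)
            for name in ("accepted.tsv", "audit.tsv", "kept.fa", "features.tsv",
                         "calls.tsv", "gainloss.tsv")
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest




@dataclass
class CurationOutcome:
    """Result of the record-curation stage."""

    kept: list[SequenceRecord]
    audit_rows: list[dict]
    counts: dict[str, int]
    features: dict
    confidence: dict[str, str]


def curate_records(
    records: Sequence[SequenceRecord],
    policy: CurationPolicy = CurationPolicy(),
    profile: ReferenceProfile | None = None,
) -> CurationOutcome:
    """Apply the four curation rules in order, with a per-record audit trail.

    Order: contaminants, fragments/incomplete domains, active-site
    divergence, redundancy collapse; evidence-confidence flags are annotation
    only.  The rules are applied in that order so each removal has a single
    attributed reason.
    """
    profile = profile or default_profile()
    audit: list[dict] = []
    feats = {rec.id: extract_features(rec, profile) for rec in records}
    screened = list(records)

    # 1. contaminants.  Without an external reference set the dataset screens
    # itself, so only *near-duplicate* cross-phylum pairs count: distant
    # homologs in different phyla are expected in a widespread family, but
    # two copies of what is effectively the same gene cannot genuinely occur
    # in incompatible lineages.  "Near-duplicate" reuses the redundancy
    # threshold (the laxer contaminant_identity bar is meant for screening
    # against a curated external reference set via flag_contaminants).
    # The near-duplicate predicate is symmetric, so direction is decided by
    # lineage rarity: within a flagged pair the record whose phylum has fewer
    # members in the dataset is the contaminant (an isolated cross-phylum
    # occurrence of a sequence otherwise confined to one group); on a tie
    # both are removed, the conservative reading.
    contam = [
        f
        for f in flag_contaminants(screened, screened, policy)
        if f.identity >= policy.redundancy_identity
    ]
    phylum_counts: dict[str, int] = {}
    for rec in screened:
        if rec.taxon:
            key = rec.rank(1)
            phylum_counts[key] = phylum_counts.get(key, 0) + 1
    contam_ids: dict = {}
    for f in contam:
        own = phylum_counts.get(f.record_lineage[1] if len(f.record_lineage) > 1 else "", 0)
        other = phylum_counts.get(
            f.reference_lineage[1] if len(f.reference_lineage) > 1 else "", 0
        )
        if own <= other:
            contam_ids.setdefault(f.record_id, f)
    pool = []
    for rec in screened:
        if rec.id in contam_ids:
            audit.append({"record_id": rec.id, "stage": "contaminants",
                          "action": "removed",
                          "reason": f"contaminant (matches {contam_ids[rec.id].reference_id})"})
        else:
            pool.append(rec)
    n_contam = len(screened) - len(pool)

    # 2. fragments / incomplete domains
    domain_fraction = {rid: f.covered_fraction for rid, f in feats.items()}
    missing_sites = {
        rid: {s for s, state in f.active_site_states.items() if state == "missing"}
        for rid, f in feats.items()
    }
    pool, removed_frag = filter_fragments(
        pool, domain_fraction, policy, missing_active_sites=missing_sites
    )
    for rid, reason in removed_frag.items():
        action = "flagged" if reason.startswith("retained") else "removed"
        audit.append({"record_id": rid, "stage": "fragments",
                      "action": action, "reason": reason})
    n_frag = sum(1 for r in removed_frag.values() if not r.startswith("retained"))

    # 3. active-site divergence
    spec = ActiveSiteSpec()
    survivors = []
    n_divergent = 0
    for rec in pool:
        states = feats[rec.id].active_site_states
        bad = all(states[s] in ("nonconservative", "missing") for s in spec.core_positions)
        if bad:
            n_divergent += 1
            diverged = ",".join(s for s in spec.core_positions if states[s] != "canonical")
            audit.append({"record_id": rec.id, "stage": "active_site",
                          "action": "removed",
                          "reason": f"active-site divergent ({diverged})"})
        else:
            survivors.append(rec)
    pool = survivors

    # 4. redundancy collapse
    pool, removed_red = filter_redundancy(
        pool, policy.redundancy_identity, exceptions=policy.exceptions
    )
    for rid, rep in removed_red.items():
        audit.append({"record_id": rid, "stage": "redundancy",
                      "action": "removed", "reason": f"redundant with {rep}"})

    # 5. evidence-confidence flags (annotation only, never removal)
    confidence = flag_low_confidence(pool, policy)
    for rec in pool:
        if confidence.get(rec.id) == "low-confidence":
            audit.append({"record_id": rec.id, "stage": "confidence",
                          "action": "flagged", "reason": "low-confidence taxon group"})
        audit.append({"record_id": rec.id, "stage": "curate",
                      "action": "kept", "reason": ""})

    return CurationOutcome(
        kept=pool,
        audit_rows=audit,
        counts={
            "contaminant": n_contam,
            "fragment": n_frag,
            "active_site": n_divergent,
            "redundant": len(removed_red),
            "kept": len(pool),
        },
        features=feats,
        confidence=confidence,
    )


def _sibling_query_lengths(hits_path: Path) -> dict[str, int] | None:
    side = hits_path.with_name("query_lengths.tsv")
    if not side.exists():
        return None
    lengths = {}
    for line in side.read_text().splitlines():
        if line.strip():
            q, n = line.split("\t")
            lengths[q] = int(n)
    return lengths


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _versions() -> dict[str, str]:
    import importlib.metadata

    import Bio
    import dendropy
    import numpy
    import pandas

    return {
        "pldtox": __version__,
        "numpy": numpy.__version__,
        "pandas": pandas.__version__,
        "dendropy": dendropy.__version__,
        "biopython": Bio.__version__,
        "click": importlib.metadata.version("click"),
    }


def summarize_by_taxon(calls, lineage_rank: int = 1) -> pd.DataFrame:
    """Tabulate classification calls per lineage group and clade label.

    ``calls`` is the calls table (path or DataFrame with ``lineage``,
    ``label`` and ``confidence`` columns).  Groups are the lineage name at
    ``lineage_rank`` (0 = domain, 1 = phylum, ...).  Returns one row per
    group x label with a count and the number of low-confidence records, plus
    a totals row.  An empty input yields just the header.
    """
    if not isinstance(calls, pd.DataFrame):
        calls = pd.read_csv(calls, sep="\t", dtype=str).fillna("")
    columns = ["group", "label", "count", "low_confidence"]
    if calls.empty:
        return pd.DataFrame(columns=columns)

    def group_of(lineage: str) -> str:
        parts = [p for p in str(lineage).split("|") if p]
        return parts[lineage_rank] if len(parts) > lineage_rank else "(unranked)"

    work = calls.assign(group=calls["lineage"].map(group_of))
    rows = []
    for (group, label), sub in sorted(work.groupby(["group", "label"])):
        rows.append({
            "group": group,
            "label": label,
            "count": len(sub),
            "low_confidence": int((sub["confidence"] == "low-confidence").sum()),
        })
    total_low = sum(r["low_confidence"] for r in rows)
    rows.append({"group": "TOTAL", "label": "", "count": len(work),
                 "low_confidence": total_low})
    return pd.DataFrame(rows, columns=columns)
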