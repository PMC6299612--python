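"""Unit tests for curation: identity, redundancy, fragments, active sites,
contaminants, evidence confidence."""

import numpy as np
import pytest

from pldtox.curation import (
    ActiveSiteSpec,
    CurationPolicy,
    filter_fragments,
    filter_redundancy,
    flag_contaminants,
    flag_low_confidence,
    identity_from_alignment,
    pairwise_identity,
    screen_active_site,
)
from pldtox.io_formats import SequenceRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def rec(rid, residues, taxon=("Eukaryota", "Arthropoda", "Chelicerata"),
        evidence=frozenset({"genome", "transcriptome"})):
    return SequenceRecord(id=rid, residues=residues, taxon=taxon, evidence=evidence)


# ---------------------------------------------------------------------------
# Identity
# ---------------------------------------------------------------------------

def test_identity_identical_and_symmetric():
    assert pairwise_identity("MKVLH", "MKVLH") == 100.0
    rng = np.random.default_rng(3)
    for _ in range(10):
        a = "".join(rng.choice(list(AA), size=12))
        b = "".join(rng.choice(list(AA), size=10))
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))


def test_identity_single_substitution():
    a = "MKVLHGAKDE"
    b = "MKVLHGAKDF"  # one mismatch out of 10
    assert pairwise_identity(a, b) == pytest.approx(90.0)


def test_identity_terminal_overhang_excluded():
    # b is a with a 4-residue N-terminal extension; overhang columns free
    assert pairwise_identity("MKVLHGAKDE", "WWWWMKVLHGAKDE") == 100.0
    # explicit alignment arithmetic
    assert identity_from_alignment("----MKVL", "WWWWMKVL") == 100.0
    assert identity_from_alignment("MK-VL", "MKEVL") == pytest.approx(80.0)
    assert identity_from_alignment("----", "WWWW") == 0.0


def test_identity_empty_sequence_error():
    with pytest.raises(ValueError):
        pairwise_identity("", "MK")


# ---------------------------------------------------------------------------
# Redundancy
# ---------------------------------------------------------------------------

def test_filter_redundancy_removes_near_duplicates():
    base = "MKVLHGAKDEWFNPQRSTVY" * 3
    near = base[:-2] + "AA"  # ~97% identical
    far = "".join(np.random.default_rng(5).choice(list(AA), size=60))
    records = [rec("base", base), rec("near", near), rec("far", far)]
    kept, removed = filter_redundancy(records, threshold=90.0)
    assert [r.id for r in kept] == ["base", "far"]
    assert removed == {"near": "base"}


def test_filter_redundancy_longest_is_representative():
    short = "MKVLHGAKDEWFNPQRSTVY" * 2
    long = short + "GSLAAK"  # identical core, longer
    kept, removed = filter_redundancy([rec("short", short), rec("long", long)])
    assert [r.id for r in kept] == ["long"]
    assert removed == {"short": "long"}


def test_filter_redundancy_exceptions_kept():
    base = "MKVLHGAKDEWFNPQRSTVY" * 3
    records = [rec("a", base), rec("b", base)]
    kept, removed = filter_redundancy(
        records, exceptions={"b": "voucher specimen"}
    )
    assert {r.id for r in kept} == {"a", "b"} and not removed


# ---------------------------------------------------------------------------
# Fragments
# ---------------------------------------------------------------------------

def test_filter_fragments_reasons_in_precedence_order():
    policy = CurationPolicy(min_length=10, min_domain_fraction=0.75)
    records = [
        rec("short", "MKVLH"),
        rec("partial", "MKVLHGAKDEWF"),
        rec("nosites", "MKVLHGAKDEWF"),
        rec("good", "MKVLHGAKDEWF"),
    ]
    fractions = {"short": 0.2, "partial": 0.5, "nosites": 0.9, "good": 0.95}
    kept, removed = filter_fragments(
        records, fractions, policy,
        missing_active_sites={"nosites": {"His12"}},
    )
    assert [r.id for r in kept] == ["good"]
    assert removed["short"].startswith("short")
    assert removed["partial"] == "incomplete domain"
    assert "His12" in removed["nosites"]


def test_filter_fragments_exception_retained_with_note():
    policy = CurationPolicy(min_length=10, exceptions={"short": "type specimen"})
    kept, removed = filter_fragments([rec("short", "MKVLH")], {"short": 0.2}, policy)
    assert [r.id for r in kept] == ["short"]
    assert removed["short"].startswith("retained exception")


def test_filter_fragments_missing_fraction_is_error():
    with pytest.raises(KeyError):
        filter_fragments([rec("x", "MKVLHGAKDE")], {})


# ---------------------------------------------------------------------------
# Active sites
# ---------------------------------------------------------------------------

def test_screen_active_site_states_and_verdict():
    spec = ActiveSiteSpec()
    # craft a record whose positions 1..6 hold the residues we control
    record = rec("x", "HKLGEQ" + "A" * 20)
    mapping = {"His12": 1, "Glu32": 5, "Asp34": None,
               "His47": 2, "Asp91": 3, "Lys93": 2}
    states, verdict = screen_active_site(record, mapping, spec)
    assert states["His12"] == "canonical"
    assert states["Glu32"] == "canonical"
    assert states["Asp34"] == "missing"
    assert states["His47"] == "nonconservative"     # K for H: score <= 0
    assert states["Asp91"] == "nonconservative"     # L for D
    assert states["Lys93"] == "canonical"           # position 2 holds K
    assert verdict == "normal"                       # His12/Glu32 canonical


def test_screen_active_site_divergent_requires_all_core():
    spec = ActiveSiteSpec()
    record = rec("x", "LLGLLL" + "A" * 20)  # L at His12/His47, G at Glu32
    mapping = {"His12": 1, "Glu32": 3, "Asp34": 4, "His47": 2,
               "Asp91": 5, "Lys93": 6}
    states, verdict = screen_active_site(record, mapping, spec)
    assert verdict == "divergent"
    assert all(states[c] == "nonconservative" for c in spec.core_positions)
    # one canonical core site rescues the verdict
    record2 = rec("y", "HLGLLL" + "A" * 20)
    _, verdict2 = screen_active_site(record2, mapping, spec)
    assert verdict2 == "normal"


def test_screen_active_site_x_residue_is_missing():
    record = rec("x", "XKLGEQ" + "A" * 20)
    states, _ = screen_active_site(record, {"His12": 1}, ActiveSiteSpec(
        positions={"His12": "H"}, core_positions=("His12",)))
    assert states["His12"] == "missing"


# ---------------------------------------------------------------------------
# Contaminants
# ---------------------------------------------------------------------------

def test_flag_contaminants_identical_cross_phylum():
    seq = "MKVLHGAKDEWFNPQRSTVY" * 3
    spider = rec("spider", seq, taxon=("Eukaryota", "Arthropoda", "Acari"))
    plant = rec("plant", seq, taxon=("Eukaryota", "Streptophyta", "Magnoliopsida"))
    flags = flag_contaminants([plant], [spider, plant])
    assert len(flags) == 1
    assert flags[0].record_id == "plant" and flags[0].reference_id == "spider"
    assert flags[0].identity == 100.0


def test_flag_contaminants_same_phylum_exempt():
    seq = "MKVLHGAKDEWFNPQRSTVY" * 3
    a = rec("a", seq, taxon=("Eukaryota", "Arthropoda", "Acari"))
    b = rec("b", seq, taxon=("Eukaryota", "Arthropoda", "Araneae"))
    assert flag_contaminants([a], [a, b]) == []


def test_flag_contaminants_low_identity_not_flagged():
    rng = np.random.default_rng(9)
    a = rec("a", "".join(rng.choice(list(AA), size=60)),
            taxon=("Eukaryota", "Arthropoda", "Acari"))
    b = rec("b", "".join(rng.choice(list(AA), size=60)),
            taxon=("Eukaryota", "Streptophyta", "Rosids"))
    assert flag_contaminants([a], [a, b]) == []


def test_flag_contaminants_degenerate_anchor_not_flagged():
    # unrelated sequences sharing one Trp: the optimal free-end-gap alignment
    # is a single aligned column, overhang-excluded identity 100%, but the
    # overlap gate must reject it as contamination evidence
    from pldtox.curation import alignment_overlap_fraction

    a = rec("a", "W" + "AKDE" * 15, taxon=("Eukaryota", "Arthropoda", "Acari"))
    b = rec("b", "GLNP" * 15 + "W", taxon=("Eukaryota", "Streptophyta", "Rosids"))
    assert pairwise_identity(a, b) == 100.0  # the degenerate metric value
    assert alignment_overlap_fraction(a, b) < 0.5
    assert flag_contaminants([a], [a, b]) == []


def test_alignment_overlap_fraction_extremes():
    from pldtox.curation import alignment_overlap_fraction

    assert alignment_overlap_fraction("MKVLH", "MKVLH") == 1.0
    full = "MKVLHGAKDEWFNPQRSTVY" * 3
    assert alignment_overlap_fraction(full[10:40], full) == pytest.approx(1.0)


def test_flag_contaminants_missing_lineage_warns():
    seq = "MKVLHGAKDEWFNPQRSTVY" * 3
    anon = rec("anon", seq, taxon=())
    other = rec("other", seq)
    with pytest.warns(UserWarning):
        assert flag_contaminants([anon], [other]) == []


# ---------------------------------------------------------------------------
# Evidence confidence
# ---------------------------------------------------------------------------

def test_flag_low_confidence_pools_by_group():
    g1a = rec("g1a", "MKVLH", taxon=("Eukaryota", "Arthropoda", "Acari"),
              evidence=frozenset({"transcriptome"}))
    g1b = rec("g1b", "MKVLH", taxon=("Eukaryota", "Arthropoda", "Acari"),
              evidence=frozenset({"genome"}))
    lonely = rec("lonely", "MKVLH", taxon=("Eukaryota", "Rotifera", "Bdelloidea"),
                 evidence=frozenset({"transcriptome"}))
    labels = flag_low_confidence([g1a, g1b, lonely])
    # the Acari group pools genome+transcriptome -> confident
    assert labels["g1a"] == labels["g1b"] == "confident"
    assert labels["lonely"] == "low-confidence"


def test_policy_validation():
    with pytest.raises(ValueError):
        CurationPolicy(redundancy_identity=150.0)
    with pytest.raises(ValueError):
        CurationPolicy(min_domain_fraction=-0.1)
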