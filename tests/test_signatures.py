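"""Unit tests for signatures: profile building, mapping, feature measurement,
plug/DUF-B motifs, and clade classification."""

import numpy as np
import pytest

from pldtox.io_formats import SequenceRecord
from pldtox.signatures import (
    CladeSignatureSpec,
    FeatureProfile,
    build_reference_profile,
    classify_clade,
    column_frequencies,
    detect_dufb_repeats,
    extract_features,
    map_to_reference,
    measure_loops,
    profile_from_json,
    profile_to_json,
    score_plug_motif,
)
from pldtox.synthetic_data import consensus_sequence, make_family_sequence

BACKGROUND = "ADEFGHIKLMNPQRSTVWY"  # no Cys: matches the generator background


# ---------------------------------------------------------------------------
# Profile construction and serialisation
# ---------------------------------------------------------------------------

def test_profile_build_is_deterministic(profile):
    rebuilt = build_reference_profile()
    assert np.array_equal(profile.pssm, rebuilt.pssm)
    assert profile.plug_threshold == rebuilt.plug_threshold
    assert profile.score_floor == rebuilt.score_floor
    assert profile.regions == rebuilt.regions


def test_profile_json_round_trip(profile):
    back = profile_from_json(profile_to_json(profile))
    assert np.array_equal(profile.pssm, back.pssm)
    assert profile.active_site_cols == back.active_site_cols
    assert profile.core_cols == back.core_cols
    assert profile.plug_threshold == back.plug_threshold
    assert profile.score_floor == back.score_floor


def test_profile_active_site_columns_hold_canonical_residues(profile):
    freq = column_frequencies(profile.alignment)
    for label, aa in [("His12", "H"), ("Glu32", "E"), ("His47", "H"),
                      ("Asp91", "D"), ("Lys93", "K")]:
        col = profile.active_site_cols[label]
        assert freq.loc[col, aa] > 0.9, label


# ---------------------------------------------------------------------------
# Mapping
# ---------------------------------------------------------------------------

def test_consensus_maps_fully(profile):
    mapping = map_to_reference(consensus_sequence("ST"), profile)
    assert mapping.mappable
    assert mapping.covered_fraction == pytest.approx(1.0)


def test_random_sequence_unmappable(profile):
    rng = np.random.default_rng(4)
    junk = "".join(rng.choice(list(BACKGROUND), size=300))
    mapping = map_to_reference(junk, profile)
    assert not mapping.mappable


def test_cterm_fragment_partial_coverage(profile):
    seq = consensus_sequence("ST")
    frag = seq[len(seq) - 180:]
    mapping = map_to_reference(frag, profile)
    assert mapping.covered_fraction < 0.75


# ---------------------------------------------------------------------------
# Loop measurement
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("clade", ["ST", "AT", "Aquatic", "basal"])
def test_loop_lengths_match_generator_truth(profile, family_record, clade):
    rec, truth = family_record(clade, seed=17)
    mapping = map_to_reference(rec, profile)
    loops = measure_loops(rec, mapping, profile)
    assert loops["ba1_length"] == truth.ba1_length
    assert loops["catloop_length"] == truth.cat_loop_length
    assert loops["loop_cys_positions"] == truth.loop_cys_positions
    assert loops["linker_cys_present"] == (truth.linker_cys_position is not None)


def test_decoy_ba1_loop_measured_long(profile, family_record):
    rec, truth = family_record("GDPD-decoy", seed=21)
    mapping = map_to_reference(rec, profile)
    loops = measure_loops(rec, mapping, profile)
    assert loops["ba1_length"] == truth.ba1_length
    assert loops["ba1_length"] >= 3 + 6  # family max + decoy margin


# ---------------------------------------------------------------------------
# Plug motif
# ---------------------------------------------------------------------------

def test_plug_present_on_family_and_degrades_with_mutation(profile, family_record):
    rec, truth = family_record("ST", seed=5)
    mapping = map_to_reference(rec, profile)
    score, present, span = score_plug_motif(rec, profile, mapping)
    assert present
    assert span is not None and truth.plug_span is not None
    assert span[0] >= truth.plug_span[0] and span[1] <= truth.plug_span[1]
    # mutate the plug Arg (salt-bridge) to Glu: score must drop strictly
    arg_pos = truth.plug_span[0] + 1  # 1-based: PLUG_CT offset 1 is R
    assert rec.residues[arg_pos - 1] == "R"
    mutated = rec.residues[: arg_pos - 1] + "E" + rec.residues[arg_pos:]
    mrec = SequenceRecord(id="mut", residues=mutated, taxon=rec.taxon)
    mscore, _, _ = score_plug_motif(mrec, profile, map_to_reference(mrec, profile))
    assert mscore < score


def test_plug_absent_on_decoy(profile, family_record):
    rec, truth = family_record("GDPD-decoy", seed=8)
    assert truth.plug_span is None
    mapping = map_to_reference(rec, profile)
    _, present, _ = score_plug_motif(rec, profile, mapping)
    assert not present


def test_plug_window_fallback_without_mapping(profile, family_record):
    rec, _ = family_record("ST", seed=5)
    score, present, span = score_plug_motif(rec, profile, mapping=None)
    assert present and span is None


def test_plug_too_short_sequence(profile):
    score, present, span = score_plug_motif("MKVLH", profile)
    assert not present and span is None


# ---------------------------------------------------------------------------
# DUF-B repeats
# ---------------------------------------------------------------------------

def test_dufb_counts_match_truth(profile, family_record):
    for seed in (1, 2, 3, 4):
        rec, truth = family_record("Aquatic", seed=seed)
        count, spans = detect_dufb_repeats(rec)
        assert count == truth.dufb_count
        assert len(spans) == count
        for (lo, hi), (tlo, thi) in zip(spans, truth.dufb_spans):
            assert abs(lo - tlo) <= 2 and hi <= thi + 2


def test_dufb_zero_on_st_and_random(family_record):
    rec, truth = family_record("ST", seed=6)
    assert truth.dufb_count == 0
    assert detect_dufb_repeats(rec)[0] == 0
    rng = np.random.default_rng(11)
    junk = "".join(rng.choice(list(BACKGROUND), size=400))
    assert detect_dufb_repeats(junk)[0] == 0


def test_dufb_spacing_tolerance():
    from pldtox.synthetic_data import DUFB_CYS

    def repeat(extra=0):
        length = 70 + extra
        chars = ["A"] * length
        for k, off in enumerate(DUFB_CYS):
            chars[off + (extra if k >= 5 else 0)] = "C"
        for i in range(63 + extra, 67 + extra):
            chars[i] = "G"
        chars[68 + extra] = "Y"
        return "".join(chars)

    assert detect_dufb_repeats("AAA" + repeat(0) + "AAA")[0] == 1
    assert detect_dufb_repeats("AAA" + repeat(2) + "AAA")[0] == 1   # within ±2
    assert detect_dufb_repeats("AAA" + repeat(5) + "AAA")[0] == 0   # beyond ±2


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _features(**kw):
    base = dict(
        record_id="x",
        plug_score=20.0,
        plug_present=True,
        ba1_length=3,
        cat_loop_length=15,
        cat_loop_span=(60, 74),
        loop_cys_positions=(62, 71),
        linker_cys_present=True,
        active_site_states={},
        dufb_repeat_count=0,
        covered_fraction=1.0,
        mappable=True,
    )
    base.update(kw)
    return FeatureProfile(**base)


def test_classify_decision_order_and_traces():
    spec = CladeSignatureSpec()
    cases = [
        (_features(mappable=False), "non-family", "score floor"),
        (_features(plug_present=False), "non-family", "plug absent"),
        (_features(ba1_length=None), "non-family", "unmeasured"),
        (_features(ba1_length=12), "non-family", "family max"),
        (_features(), "ST-like", "ST rule"),
        (_features(cat_loop_length=16), "ST-like", "ST rule"),  # tolerance 1
        (_features(cat_loop_length=19,
                   loop_cys_positions=(60, 63, 70, 75)), "Aquatic", "Aquatic rule"),
        (_features(cat_loop_length=11, loop_cys_positions=()), "AT-like", "AT rule"),
        (_features(cat_loop_length=7, loop_cys_positions=()),
         "basal/unclassified", "no clade rule"),
        (_features(cat_loop_length=None), "basal/unclassified", "unmeasured"),
    ]
    for features, expected, fragment in cases:
        label, trace = classify_clade(features, spec)
        assert label == expected, trace
        assert any(fragment in line for line in trace), (expected, trace)


def test_classify_st_requires_cys_pair():
    # right length but no cysteines: not ST-like
    label, _ = classify_clade(_features(loop_cys_positions=()))
    assert label != "ST-like"


def test_classify_at_basal_ambiguity_noted():
    label, trace = classify_clade(_features(cat_loop_length=11, loop_cys_positions=()))
    assert label == "AT-like"
    assert any("not separable" in line for line in trace)


def test_signature_spec_validation():
    with pytest.raises(ValueError):
        CladeSignatureSpec(at_loop_range=(9, 16))  # overlaps the ST length
    with pytest.raises(ValueError):
        CladeSignatureSpec(st_tolerance=-1)


def test_extract_features_end_to_end(profile, family_record):
    rec, truth = family_record("Aquatic", seed=2)
    f = extract_features(rec, profile)
    assert f.mappable and f.plug_present
    assert f.cat_loop_length == truth.cat_loop_length
    assert f.dufb_repeat_count == truth.dufb_count
    assert f.active_site_states["His12"] == "canonical"
    label, _ = classify_clade(f)
    assert label == "Aquatic"
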