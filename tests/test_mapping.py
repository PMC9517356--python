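"""Comorbidity coding algorithms: normalization, matching, hierarchy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comoscore import MalformedCodeError, ValidationError
from comoscore.io import EpisodeRecord
from comoscore.mapping import (
    apply_hierarchy,
    category_frequencies,
    code_categories,
    flag_cohort,
    flag_comorbidities,
    normalize_code,
    profiles_from_frame,
)
from comoscore.io import Cohort


@pytest.mark.parametrize(
    "raw,expected",
    [("i50.9", "I509"), (" C78.0 ", "C780"), ("e11 9", "E119"), ("I10", "I10")],
)
def test_normalize_code(raw, expected):
    assert normalize_code(raw) == expected


@pytest.mark.parametrize("bad", ["", "   ", "509", "5A9", "I.."])
def test_normalize_rejects_malformed(bad):
    with pytest.raises(MalformedCodeError):
        normalize_code(bad)


def test_map_shapes(charlson_map, elixhauser_map):
    assert charlson_map.n_categories == 17
    assert elixhauser_map.n_categories == 31
    for cmap in (charlson_map, elixhauser_map):
        assert all(c.icd10_prefixes for c in cmap.categories)
        labels = cmap.labels
        for sup, inf in cmap.hierarchy_rules:
            assert sup in labels and inf in labels
    # hypertension stays split in the Elixhauser scheme
    assert "Hypertension, uncomplicated" in elixhauser_map.labels
    assert "Hypertension, complicated" in elixhauser_map.labels


def _episode(codes):
    return EpisodeRecord("t1", 60, "male", False, 1, tuple(codes))


def test_heart_failure_code_sets_only_chf(elixhauser_map):
    profile = flag_comorbidities(_episode(["I500"]), elixhauser_map)
    flagged = [
        lab for lab, f in zip(elixhauser_map.labels, profile.flags) if f
    ]
    assert flagged == ["Congestive heart failure"]


def test_no_matching_prefix_gives_all_false(elixhauser_map):
    profile = flag_comorbidities(_episode(["J189", "A090"]), elixhauser_map)
    assert not any(profile.flags)


def test_diabetes_hierarchy_keeps_only_complicated(elixhauser_map):
    # E119 -> uncomplicated, E112 -> complicated; hierarchy demotes the former
    profile = flag_comorbidities(_episode(["E119", "E112"]), elixhauser_map)
    flagged = {lab for lab, f in zip(elixhauser_map.labels, profile.flags) if f}
    assert flagged == {"Diabetes, complicated"}


def test_metastatic_demotes_any_malignancy(charlson_map):
    profile = flag_comorbidities(_episode(["C780", "C509"]), charlson_map)
    flagged = {lab for lab, f in zip(charlson_map.labels, profile.flags) if f}
    assert flagged == {"Metastatic solid tumor"}


def test_main_diagnosis_toggle(elixhauser_map):
    ep = _episode(["I500", "E669"])  # main CHF, secondary obesity
    with_main = flag_comorbidities(ep, elixhauser_map, include_main_dx=True)
    without = flag_comorbidities(ep, elixhauser_map, include_main_dx=False)
    chf = elixhauser_map.index_of("Congestive heart failure")
    obesity = elixhauser_map.index_of("Obesity")
    assert with_main.flags[chf] and with_main.flags[obesity]
    assert not without.flags[chf] and without.flags[obesity]


def test_malformed_code_names_episode_and_position(elixhauser_map):
    ep = EpisodeRecord.__new__(EpisodeRecord)  # bypass validation on purpose
    object.__setattr__(ep, "episode_id", "bad1")
    object.__setattr__(ep, "diagnoses", ("I500", "999"))
    with pytest.raises(MalformedCodeError, match="bad1.*position 2"):
        flag_comorbidities(ep, elixhauser_map)


def test_hierarchy_idempotent_exhaustively(charlson_map):
    """Brute force over all flag combinations of the hierarchy-involved
    categories: one application is idempotent and pairs never co-occur."""
    involved = sorted(
        {lab for pair in charlson_map.hierarchy_rules for lab in pair}
    )
    idx = [charlson_map.index_of(lab) for lab in involved]
    for bits in range(2 ** len(idx)):
        flags = np.zeros(charlson_map.n_categories, dtype=bool)
        for k, i in enumerate(idx):
            flags[i] = bool((bits >> k) & 1)
        once = apply_hierarchy(flags, charlson_map)
        assert (apply_hierarchy(once, charlson_map) == once).all()
        for s, i in charlson_map.hierarchy_index_pairs():
            assert not (once[s] and once[i])


def test_hierarchy_identity_when_no_pair_cooccurs(elixhauser_map):
    flags = np.zeros(elixhauser_map.n_categories, dtype=bool)
    flags[elixhauser_map.index_of("Obesity")] = True
    flags[elixhauser_map.index_of("Depression")] = True
    assert (apply_hierarchy(flags, elixhauser_map) == flags).all()


@settings(max_examples=50, deadline=None)
@given(st.lists(st.booleans(), min_size=31, max_size=31))
def test_hierarchy_only_ever_clears_inferior_flags(flags):
    from comoscore.mapping import load_map

    emap = load_map("elixhauser")
    before = np.array(flags, dtype=bool)
    after = apply_hierarchy(before, emap)
    # never sets a flag, and only clears flags that are inferior in some pair
    assert not (after & ~before).any()
    inferior = {i for _, i in emap.hierarchy_index_pairs()}
    cleared = np.nonzero(before & ~after)[0]
    assert set(cleared) <= inferior


def _naive_flags(codes, cmap):
    """O(codes x categories x prefixes) reference scan, then hierarchy."""
    flags = np.zeros(cmap.n_categories, dtype=bool)
    for raw in codes:
        code = normalize_code(raw)
        for i, cat in enumerate(cmap.categories):
            for p in cat.icd10_prefixes:
                if code.startswith(p):
                    flags[i] = True
    return apply_hierarchy(flags, cmap)


def test_flags_match_bruteforce_oracle(rng, charlson_map, elixhauser_map):
    vocab = [
        "I500", "I2510", "E119", "E112", "C780", "C509", "C819", "J449",
        "N184", "K703", "K746", "F0390", "G300", "I639", "I10", "I110",
        "E6601", "F329", "F1010", "D500", "D509", "E8770", "M0500", "B180",
        "B20", "G8100", "I4891", "I050", "I260", "J189", "A090", "K358",
        "R073", "Z9911", "Z940", "T5111", "R634", "E222", "Q230", "H340",
        "I219", "G459", "K257", "K259", "M320", "C900", "C770", "I850",
        "E890", "L940",
    ]
    episodes = []
    for k in range(100):
        n_dx = rng.integers(1, 8)
        codes = [vocab[i] for i in rng.integers(0, len(vocab), n_dx)]
        episodes.append(EpisodeRecord(f"r{k}", 60, "male", False, 1, tuple(codes)))
    for cmap in (charlson_map, elixhauser_map):
        frame = flag_cohort(Cohort(episodes=episodes), cmap)
        for ep in episodes:
            expected = _naive_flags(ep.diagnoses, cmap)
            got = frame.loc[ep.episode_id].to_numpy()
            assert (got == expected).all(), ep.diagnoses
            single = flag_comorbidities(ep, cmap)
            assert tuple(expected) == single.flags


def test_matching_invariant_to_case_and_dots(elixhauser_map):
    a = flag_comorbidities(_episode(["i50.0", " e11.9 "]), elixhauser_map)
    b = flag_comorbidities(_episode(["I500", "E119"]), elixhauser_map)
    assert a.flags == b.flags


def test_adding_a_diagnosis_is_monotone_prehierarchy(elixhauser_map):
    base = ["I500", "J449"]
    before = set()
    for c in base:
        before.update(code_categories(normalize_code(c), elixhauser_map))
    after = set(before)
    for c in base + ["E119"]:
        after.update(code_categories(normalize_code(c), elixhauser_map))
    assert before <= after


def test_category_frequencies(elixhauser_map):
    episodes = [
        EpisodeRecord(f"f{k}", 60, "male", False, 1, ("I500",) if k < 13 else ("J189",))
        for k in range(100)
    ]
    frame = flag_cohort(Cohort(episodes=episodes), elixhauser_map)
    freq = category_frequencies(profiles_from_frame(frame, elixhauser_map))
    chf = freq.loc[freq["label"] == "Congestive heart failure", "percent"].iloc[0]
    assert chf == pytest.approx(13.0)
    assert (freq.loc[freq["label"] == "Obesity", "percent"] == 0).all()


def test_mixed_scheme_frequencies_rejected(charlson_map, elixhauser_map):
    e1 = flag_comorbidities(_episode(["I500"]), charlson_map)
    e2 = flag_comorbidities(_episode(["I500"]), elixhauser_map)
    with pytest.raises(ValidationError):
        category_frequencies([e1, e2])
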