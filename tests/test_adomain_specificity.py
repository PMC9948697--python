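"""Identity metric and nearest-reference specificity classification."""

import numpy as np
import pytest

from lipopeptidome import adomain_specificity as ads
from lipopeptidome import synthetic_data as sd
from lipopeptidome._align import AA20
from lipopeptidome.knowledge_base import ReferenceADomain


def _levenshtein_oracle(a: str, b: str) -> int:
    """Independent Wagner-Fischer DP (quadratic, pure Python)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(
                prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)
            )
        prev = cur
    return prev[-1]


def _random_protein(rng, n):
    return "".join(rng.choice(list(AA20), n))


def test_identity_of_identical_sequences_is_one():
    assert ads.adomain_identity("ACDEFG", "ACDEFG") == 1.0


def test_identity_matches_dp_oracle_including_reversal():
    rng = np.random.default_rng(42)
    seq = _random_protein(rng, 100)
    rev = seq[::-1]
    expected = 1.0 - _levenshtein_oracle(seq, rev) / 100
    assert ads.adomain_identity(seq, rev) == pytest.approx(expected)
    for _ in range(8):
        a = _random_protein(rng, int(rng.integers(50, 150)))
        b = _random_protein(rng, int(rng.integers(50, 150)))
        expected = 1.0 - _levenshtein_oracle(a, b) / max(len(a), len(b))
        assert ads.adomain_identity(a, b) == pytest.approx(expected)


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.text(alphabet=AA20, min_size=1, max_size=60),
        st.text(alphabet=AA20, min_size=1, max_size=60),
    )
    @settings(max_examples=60, deadline=None)
    def test_identity_properties_hold_for_arbitrary_proteins(a, b):
        """0 <= identity <= 1, symmetric, 1 iff equal (fuzzed)."""
        ident = ads.adomain_identity(a, b)
        assert 0.0 <= ident <= 1.0
        assert ident == ads.adomain_identity(b, a)
        assert (ident == 1.0) == (a == b)

except ImportError:  # pragma: no cover - hypothesis is a test extra
    pass


def test_identity_symmetric_on_random_pairs():
    rng = np.random.default_rng(7)
    for _ in range(100):
        a = _random_protein(rng, int(rng.integers(10, 80)))
        b = _random_protein(rng, int(rng.integers(10, 80)))
        assert ads.adomain_identity(a, b) == ads.adomain_identity(b, a)


def test_identity_rejects_non_amino_acid_characters():
    with pytest.raises(ValueError):
        ads.adomain_identity("ACDX1", "ACDEF")
    with pytest.raises(ValueError):
        ads.adomain_identity("", "ACDEF")


def test_reference_classifies_as_itself(refset05):
    ref = refset05[0]
    call = ads.classify(ref.sequence, refset05)
    assert call.primary == ref.specificity
    assert call.confidence == 1.0
    assert call.neighbor_id == ref.id


def test_midpoint_mutant_is_ambiguous_between_glu_and_gln():
    """A query at an exact identity tie inflates the ambiguity set.

    Built from a common base: the Glu and Gln references each differ from
    the query by one isolated substitution, so the query is exactly
    equidistant (verified with the independent DP oracle).
    """
    rng = np.random.default_rng(3)
    base = _random_protein(rng, 450)

    def _mutated(position):
        chars = list(base)
        chars[position] = AA20[(AA20.index(chars[position]) + 1) % 20]
        return "".join(chars)

    glu_ref = ReferenceADomain("glu1", _mutated(100), "Glu")
    gln_ref = ReferenceADomain("gln1", _mutated(300), "Gln")
    d_glu = _levenshtein_oracle(base, glu_ref.sequence)
    d_gln = _levenshtein_oracle(base, gln_ref.sequence)
    assert d_glu == d_gln == 1
    call = ads.classify(base, [glu_ref, gln_ref])
    assert {"Glu", "Gln"} <= call.ambiguity_set
    assert call.confidence == pytest.approx(1.0 - 1 / 450)


def test_low_confidence_acidic_call_inflates_full_acidic_clade(cfg05):
    anchors = sd.specificity_anchors(cfg05)
    refs = [
        ReferenceADomain(f"{s}_0", anchors[s], s) for s in ("Glu", "Gln", "Asp", "Leu")
    ]
    query = sd.mutate_sequence(anchors["Glu"], 0.30, sd._rng(5, "acidic"))
    call = ads.classify(query, refs)
    assert call.primary == "Glu"
    assert call.confidence < ads.ACIDIC_CLADE_THRESHOLD
    assert {"Glu", "Gln", "Asp"} <= call.ambiguity_set


def test_moderate_ile_call_flagged_promiscuous(cfg05):
    anchors = sd.specificity_anchors(cfg05)
    refs = [ReferenceADomain(f"{s}_0", anchors[s], s) for s in ("Ile", "Val", "Leu")]
    query = sd.mutate_sequence(anchors["Ile"], 0.15, sd._rng(5, "ile"))
    call = ads.classify(query, refs)
    assert call.primary == "Ile"
    assert call.promiscuity == {"Val", "Leu"}
    confident = ads.classify(anchors["Ile"], refs)
    assert confident.promiscuity == frozenset()


def test_unclassifiable_query_reported_unknown(refset05):
    rng = np.random.default_rng(9)
    call = ads.classify(_random_protein(rng, 450), refset05)
    assert call.primary == "unknown"
    assert call.confidence < ads.UNKNOWN_FLOOR


def test_classification_stable_under_reference_permutation(cfg05, refset05):
    query = sd.mutate_sequence(
        sd.specificity_anchors(cfg05)["Ser"], 0.08, sd._rng(5, "perm")
    )
    base = ads.classify(query, refset05)
    shuffled = ads.classify(query, list(reversed(refset05)))
    assert (base.primary, base.confidence, base.neighbor_id) == (
        shuffled.primary, shuffled.confidence, shuffled.neighbor_id
    )


def test_empty_reference_set_is_configuration_error():
    with pytest.raises(ads.ClassifierConfigError):
        ads.classify("ACDEF", [])


def test_clade_tree_monophyly_and_planted_recruiter(cfg05):
    anchors = sd.specificity_anchors(cfg05)
    seqs, labels = {}, {}
    for spec in ("Leu", "Val", "Ser"):
        for i in range(3):
            key = f"{spec}{i}"
            seqs[key] = sd.mutate_sequence(anchors[spec], 0.05, sd._rng(5, key))
            labels[key] = spec
    _, monophyly = ads.clade_tree(seqs, labels)
    assert monophyly == {"Leu": True, "Ser": True, "Val": True}

    # an Ile-clade Val recruiter: Val-labelled leaf derived from the Ile anchor
    seqs2 = dict(seqs)
    labels2 = dict(labels)
    for i in range(3):
        key = f"Ile{i}"
        seqs2[key] = sd.mutate_sequence(anchors["Ile"], 0.05, sd._rng(5, key))
        labels2[key] = "Ile"
    seqs2["Val_recruit"] = sd.mutate_sequence(
        anchors["Ile"], 0.05, sd._rng(5, "recruit")
    )
    labels2["Val_recruit"] = "Val"
    _, monophyly2 = ads.clade_tree(seqs2, labels2)
    assert monophyly2["Val"] is False  # Val leaf sits inside the Ile clade
    assert monophyly2["Leu"] and monophyly2["Ser"]


def test_reference_fasta_round_trip(tmp_path, refset05):
    path = tmp_path / "refs.fasta"
    with open(path, "w") as fh:
        for r in refset05[:5]:
            fh.write(f">{r.id}|{r.specificity}|{r.system}|{r.position}\n")
            fh.write(r.sequence + "\n")
    back = ads.read_reference_fasta(path)
    assert [(r.id, r.specificity, r.sequence) for r in back] == [
        (r.id, r.specificity, r.sequence) for r in refset05[:5]
    ]
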