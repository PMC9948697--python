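"""Collinear prediction, family/variant status and superfamily grouping."""

import pytest

from lipopeptidome import nrps_parser as npar
from lipopeptidome import peptide_family as pf
from lipopeptidome import synthetic_data as sd
from lipopeptidome.nrps_parser import Module, NrpsSystem


def _system_from_anchor_list(sys_id, a_sequences):
    modules = [
        Module(index=i + 1, c_kind="Cs" if i == 0 else "CE", a_sequence=s, has_T=True)
        for i, s in enumerate(a_sequences)
    ]
    return NrpsSystem(
        id=sys_id,
        genes=[f"{sys_id}_g1"],
        modules=modules,
        te_tandem=True,
        concatenate="".join(a_sequences),
        module_config=(len(a_sequences),),
    )


def _diverged_system(cfg, variant, sys_id, tag, rate=0.05):
    ancestors = sd.module_anchor_set(cfg, variant)
    rng = sd._rng(cfg.seed, tag)
    return _system_from_anchor_list(
        sys_id, [sd.mutate_sequence(a, rate, rng) for a in ancestors]
    )


def test_viscosin_recovered_exactly_at_zero_noise(cfg0, domain_lib, refset05, kb):
    bgc = sd.make_bgc("Viscosin", "contiguous", cfg0, bgc_id="pp")
    parsed = [
        npar.parse_gene(g.gene_id, g.protein, domain_lib, genomic_order=i)
        for i, g in enumerate(bgc.genes)
    ]
    system = npar.assemble_system(parsed)
    pred = pf.predict_peptide(system, sd.make_reference_set(cfg0))
    assert pred.sequence_primary == kb.variants_of("Viscosin")[0].sequence
    assert len(pred) == 9


def test_putisolvin_template_gives_twelve_residues(cfg05, refset05, kb):
    system = _diverged_system(cfg05, kb.variants_of("Putisolvin")[0], "pso", "pso")
    pred = pf.predict_peptide(system, refset05)
    assert len(pred) == 12


def test_amphisin_prediction_mostly_unambiguous_at_default_divergence(
    cfg05, refset05, kb
):
    """20 diverged Amphisin systems: 11 residues, >= 9 unambiguous each."""
    var = kb.variants_of("Amphisin")[3]  # amphisin itself
    for seed_tag in range(20):
        system = _diverged_system(cfg05, var, f"ams{seed_tag}", f"ams:{seed_tag}")
        pred = pf.predict_peptide(system, refset05)
        assert len(pred) == 11
        assert len(pred) - pred.n_ambiguous >= 9
        assert pred.sequence_primary == var.sequence


def test_prediction_requires_a_domains(refset05):
    system = _system_from_anchor_list("bad", ["ACDEF" * 90])
    system.modules[0].a_sequence = None
    with pytest.raises(pf.PredictionError):
        pf.predict_peptide(system, refset05)


def test_exact_viscosin_sequence_is_known_member(cfg05, refset05, refsystems05, kb):
    system = _diverged_system(cfg05, kb.variants_of("Viscosin")[0], "vis", "vis")
    pred = pf.predict_peptide(system, refset05)
    assignment = pf.assign_family(
        pred,
        organization="contiguous",
        module_config=(2, 4, 3),
        a_sequences=system.a_sequences,
        reference_systems=refsystems05,
    )
    assert assignment.status == "known_member"
    assert assignment.family == "Viscosin"
    assert assignment.matched_variant == "viscosin"
    assert assignment.implied_macrocycle == 7


def test_single_substitution_amphisin_is_new_variant(cfg05, refset05, refsystems05, kb):
    var = kb.variants_of("Amphisin")[3]
    ancestors = sd.module_anchor_set(cfg05, var)
    # swap module 5 (Leu) for a Pro module: matches no packaged variant
    ancestors[4] = sd.specificity_anchors(cfg05)["Pro"]
    system = _system_from_anchor_list("amsx", ancestors)
    pred = pf.predict_peptide(system, refset05)
    assert pred.sequence_primary != var.sequence
    assignment = pf.assign_family(
        pred,
        organization="contiguous",
        module_config=(2, 4, 5),
        a_sequences=system.a_sequences,
        reference_systems=refsystems05,
    )
    assert assignment.status == "new_variant"
    assert assignment.family == "Amphisin"
    assert assignment.homology_score >= pf.FAMILY_HOMOLOGY_THRESHOLD


def test_decapeptide_disambiguation_orfamide_vs_poaeamide(
    cfg05, refset05, refsystems05, kb
):
    poa = _diverged_system(cfg05, kb.get_family("Poaeamide").variants[1], "poa", "poa")
    pred = pf.predict_peptide(poa, refset05)
    bifurcate = pf.assign_family(
        pred,
        organization="bifurcate",
        module_config=(2, 4, 4),
        a_sequences=poa.a_sequences,
        reference_systems=refsystems05,
    )
    assert bifurcate.family == "Poaeamide"

    orf = _diverged_system(cfg05, kb.variants_of("Orfamide")[0], "ofa", "ofa")
    pred_orf = pf.predict_peptide(orf, refset05)
    contiguous = pf.assign_family(
        pred_orf,
        organization="contiguous",
        module_config=(2, 4, 4),
        a_sequences=orf.a_sequences,
        reference_systems=refsystems05,
    )
    assert contiguous.family == "Orfamide"
    assert contiguous.status == "known_member"


def test_both_putisolvin_readings_match_the_family(cfg05, refset05, refsystems05, kb):
    """The A-domain reading (Leu4/Leu8) and the reported structure (Ile4/Ile8)
    are both packaged; either prediction dereplicates to Putisolvin."""
    for variant in kb.variants_of("Putisolvin"):
        system = _diverged_system(cfg05, variant, f"pso_{variant.name}", variant.name)
        pred = pf.predict_peptide(system, refset05)
        assignment = pf.assign_family(
            pred,
            organization="contiguous",
            module_config=(2, 7, 3),
            a_sequences=system.a_sequences,
            reference_systems=refsystems05,
        )
        assert assignment.status == "known_member"
        assert assignment.family == "Putisolvin"
        assert assignment.matched_variant == variant.name


def test_unmatched_length_is_candidate_new_family(refset05, cfg05, kb):
    var = kb.variants_of("Viscosin")[0]
    ancestors = sd.module_anchor_set(cfg05, var) + [
        sd.specificity_anchors(cfg05)["Lys"] * 1
    ]
    system = _system_from_anchor_list("odd", ancestors[:7])  # length-7 peptide
    pred = pf.predict_peptide(system, refset05)
    assignment = pf.assign_family(pred)
    assert assignment.status == "candidate_new_family"
    assert assignment.family is None
    assert assignment.implied_macrocycle is None  # never derived from sequence


def test_compare_variants_amphisin_positions(kb):
    groups = ["lokisin", "tensin", "arthrofactin", "amphisin"]
    seqs = [
        next(v.sequence for v in kb.variants_of("Amphisin") if v.name == n)
        for n in groups
    ]
    cmp = pf.compare_variants(seqs)
    assert cmp.variable_positions == {8, 9, 11}


def test_compare_variants_entolysin_vs_xantholysin_qs_switches(kb):
    ent = kb.variants_of("Entolysin")[0].sequence
    xtl = kb.variants_of("Xantholysin")[0].sequence
    cmp = pf.compare_variants([ent, xtl])
    assert cmp.variable_positions == {10, 13}
    assert cmp.qs_switch_positions == {10, 13}
    assert cmp.pairwise_differences[(0, 1)] == 2


def test_compare_variants_trivial_cases(kb):
    seq = kb.variants_of("Viscosin")[0].sequence
    assert pf.compare_variants([seq, seq]).variable_positions == frozenset()
    with pytest.raises(ValueError):
        pf.compare_variants([seq, seq[:-1]])


def test_superfamily_recovers_four_planted_pools(kb):
    """Systems drawn from 4 disjoint anchor pools form exactly 4 groups."""
    systems = {}
    var = kb.variants_of("Bananamide")[0]
    for pool in range(4):
        pool_cfg = sd.SimConfig(seed=200 + pool, mutation_rate=0.05)
        ancestors = sd.module_anchor_set(pool_cfg, var)
        for k in range(2):
            rng = sd._rng(pool_cfg.seed, f"sf:{pool}:{k}")
            systems[f"p{pool}_s{k}"] = [
                sd.mutate_sequence(a, 0.05, rng) for a in ancestors
            ]
    profiles = pf.cluster_a_domains(systems)
    groups = pf.superfamily_group(profiles)
    assert groups == [
        ["p0_s0", "p0_s1"], ["p1_s0", "p1_s1"],
        ["p2_s0", "p2_s1"], ["p3_s0", "p3_s1"],
    ]


def test_superfamily_trivial_cases(cfg05, kb):
    var = kb.variants_of("Bananamide")[0]
    ancestors = sd.module_anchor_set(cfg05, var)
    single = pf.cluster_a_domains({"only": ancestors})
    assert pf.superfamily_group(single) == [["only"]]
    twins = pf.cluster_a_domains({"a": ancestors, "b": list(ancestors)})
    assert pf.profile_overlap(twins[0], twins[1]) == 1.0
    assert pf.superfamily_group(twins) == [["a", "b"]]
    assert pf.superfamily_group([]) == []


def test_profile_matrix_export(tmp_path, cfg05, kb):
    var = kb.variants_of("Bananamide")[0]
    ancestors = sd.module_anchor_set(cfg05, var)
    profiles = pf.cluster_a_domains(
        {"sysA": ancestors}, residues={"sysA": var.sequence}
    )
    path = tmp_path / "profiles.tsv"
    pf.export_profile_matrix(profiles, path)
    lines = path.read_text().splitlines()
    assert lines[0].startswith("system\tm1")
    assert lines[1].split("\t")[1].endswith(":Leu")
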