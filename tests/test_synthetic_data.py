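"""Generator contracts: determinism, planted truth, divergence statistics."""

import numpy as np
import pytest

from lipopeptidome import bgc_miner as bm
from lipopeptidome import synthetic_data as sd
from lipopeptidome._align import sequence_identity


def test_same_seed_same_reference_set(cfg05):
    a = sd.make_reference_set(cfg05)
    b = sd.make_reference_set(sd.SimConfig(seed=cfg05.seed, mutation_rate=0.05))
    assert [(r.id, r.sequence) for r in a] == [(r.id, r.sequence) for r in b]


def test_zero_rate_copies_equal_anchor():
    cfg = sd.SimConfig(seed=3, mutation_rate=0.0, n_refs_per_specificity=3)
    anchors = sd.specificity_anchors(cfg)
    for ref in sd.make_reference_set(cfg):
        assert ref.sequence == anchors[ref.specificity]


def test_anchors_mutually_divergent(cfg05):
    anchors = list(sd.specificity_anchors(cfg05).values())
    assert len(anchors) == 14
    for i, a in enumerate(anchors):
        for b in anchors[i + 1 :]:
            assert sequence_identity(a, b) < sd.ANCHOR_MAX_IDENTITY


def test_within_group_identity_matches_site_model():
    """Mean pairwise identity of diverged copies equals the per-site oracle.

    Oracle: direct Bernoulli simulation of two substitution-only copies of
    one ancestor (10^4 sites, 19 equiprobable replacement residues).
    """
    rate = 0.1
    rng = np.random.default_rng(0)
    n_sites, n_rep = 10_000, 30
    agree = 0
    for _ in range(n_rep):
        base = rng.integers(0, 20, n_sites)
        copies = []
        for _ in range(2):
            c = base.copy()
            hit = rng.random(n_sites) < rate
            shift = rng.integers(1, 20, n_sites)
            c[hit] = (c[hit] + shift[hit]) % 20
            copies.append(c)
        agree += np.mean(copies[0] == copies[1])
    expected = agree / n_rep

    cfg = sd.SimConfig(seed=5, mutation_rate=rate, n_refs_per_specificity=4)
    refs = sd.make_reference_set(cfg)
    by_spec = {}
    for r in refs:
        by_spec.setdefault(r.specificity, []).append(r.sequence)
    idents = [
        sequence_identity(group[i], group[j])
        for group in by_spec.values()
        for i in range(len(group))
        for j in range(i + 1, len(group))
    ]
    assert abs(np.mean(idents) - expected) < 0.01


def test_bgc_viscosin_template_and_te_tandem(cfg0, kb):
    bgc = sd.make_bgc("Viscosin", "contiguous", cfg0)
    assert [len(g.modules) for g in bgc.genes] == [2, 4, 3]
    assert bgc.truth["genes"][-1]["domain_string"][-2:] == ["TE", "TE"]
    assert bgc.specificities == kb.variants_of("Viscosin")[0].sequence


def test_bgc_rejects_unobserved_organization(cfg0):
    with pytest.raises(sd.ConfigError):
        sd.make_bgc("Amphisin", "bifurcate", cfg0)


def test_spacers_stay_in_range(cfg05):
    for i in range(20):
        bgc = sd.make_bgc("Viscosin", "contiguous", cfg05, bgc_id=f"s{i}")
        lo, hi = cfg05.spacer_range
        assert all(lo <= s <= hi for s in bgc.spacers)
        assert len(bgc.spacers) == 2


def test_bifurcate_initiator_on_separate_record(cfg05):
    genome = sd.make_genome([("Xantholysin", "bifurcate")], cfg05, genome_id="gx")
    truth = genome.truth["clusters"][0]
    locs = truth["gene_locations"]
    initiator_rec = locs["gx_bgc1_nrps1"]["record_id"]
    operon_recs = {locs["gx_bgc1_nrps2"]["record_id"], locs["gx_bgc1_nrps3"]["record_id"]}
    assert initiator_rec not in operon_recs
    assert len(operon_recs) == 1


def test_genome_round_trip_exact(tmp_path, cfg05):
    genome = sd.make_genome(
        [("Viscosin", "contiguous")], cfg05, genome_id="rt"
    )
    path = tmp_path / "rt.gbk"
    genome.write_genbank(path)
    genes = bm.read_genome(path)
    truth = genome.truth["genes"]
    assert {g.gene_id for g in genes} == set(truth)
    planted_proteins = {
        feat.qualifiers["locus_tag"][0]: feat.qualifiers["translation"][0]
        for rec in genome.records
        for feat in rec.features
        if feat.type == "CDS"
    }
    for g in genes:
        assert (g.start, g.end, g.strand) == (
            truth[g.gene_id]["start"],
            truth[g.gene_id]["end"],
            truth[g.gene_id]["strand"],
        )
        assert g.translation == planted_proteins[g.gene_id]


def test_genome_bytes_deterministic(tmp_path, cfg05):
    paths = []
    for name in ("a", "b"):
        genome = sd.make_genome(
            [("Viscosin", "contiguous"), ("Tolaasin", "contiguous")],
            cfg05,
            genome_id="det",
        )
        p = tmp_path / f"{name}.gbk"
        genome.write_genbank(p)
        paths.append(p.read_bytes())
    assert paths[0] == paths[1]


def test_truth_sidecar_lists_every_module(cfg05, kb):
    genome = sd.make_genome(
        [("Tolaasin", "contiguous"), ("Viscosin", "contiguous")],
        cfg05,
        genome_id="dual",
    )
    assert len(genome.truth["clusters"]) == 2
    for cluster in genome.truth["clusters"]:
        fam = kb.get_family(cluster["family"])
        seen = [
            (g["gene_id"], m["module_index"], m["specificity"])
            for g in cluster["genes"]
            for m in g["modules"]
        ]
        assert len(seen) == fam.peptide_length
        assert [m[1] for m in seen] == list(range(1, fam.peptide_length + 1))


def test_hsqc_reference_and_jitter(cfg05, kb):
    ref = sd.hsqc_reference("viscosin", cfg05)
    assert len(ref) == 9  # one CHalpha peak per residue
    noiseless = sd.make_hsqc(
        "viscosin", sd.SimConfig(seed=cfg05.seed, peak_jitter=(0.0, 0.0))
    )
    assert [(p.h_ppm, p.c_ppm) for p in noiseless] == [
        (p.h_ppm, p.c_ppm) for p in ref
    ]
    with pytest.raises(KeyError):
        sd.make_hsqc("nonexistin", cfg05)


def test_hsqc_match_fraction_follows_truncation_probability(cfg05):
    """Jittered self-matches recover the Monte-Carlo truncation probability.

    Oracle: 10^5 draws of the tolerance-normalized jitter distance
    |(N(0,s_h)/tol_h, N(0,s_c)/tol_c)|; the per-peak match probability is
    P(d <= 1), and observed per-peak match fractions across replicates
    must agree with it.
    """
    from lipopeptidome import nmr_fingerprint as nmr

    sd_h, sd_c = cfg05.peak_jitter
    tol_h, tol_c = 0.03, 0.4
    rng = np.random.default_rng(1)
    d = np.hypot(
        rng.normal(0, sd_h, 100_000) / tol_h, rng.normal(0, sd_c, 100_000) / tol_c
    )
    expected = float(np.mean(d <= 1.0))

    ref = sd.hsqc_reference("amphisin", cfg05)
    matched = total = 0
    for rep in range(40):
        q = sd.make_hsqc("amphisin", cfg05, replicate=rep)
        res = nmr.match_peaks(q, ref, tol_h, tol_c)
        matched += res.n_matched
        total += len(ref)
    assert abs(matched / total - expected) < 0.05
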