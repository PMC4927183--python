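"""Ground-truth integrity of the synthetic study generator."""

import numpy as np
import pytest

from regencirc import (
    MatureMiRNA,
    SimConfig,
    bulge_site_scan,
    canonical_site_scan,
    simulate_catalogs,
    simulate_counts,
    simulate_interactions,
    simulate_utrs,
    venn_partition,
)
from regencirc.mirna_annotation import seed_of
from regencirc.synthetic_data import GroundTruth, SimulationError, plant_directions


def test_simulate_catalogs_structure():
    config = SimConfig(rng_seed=1, n_shared_mirnas=2, n_pairwise=0,
                       n_unique_per_species=1)
    catalogs, truth = simulate_catalogs(config)
    assert all(len(c) == 3 for c in catalogs.values())
    shared = set.intersection(*(c.mature_sequences for c in catalogs.values()))
    assert len(shared) == 2


def test_simulate_catalogs_determinism_and_seed_sensitivity():
    config_a = SimConfig(rng_seed=1, n_shared_mirnas=4, n_pairwise=1,
                         n_unique_per_species=2)
    cat1, truth1 = simulate_catalogs(config_a)
    cat2, truth2 = simulate_catalogs(config_a)
    assert truth1.mirna_sequences == truth2.mirna_sequences
    config_b = SimConfig(rng_seed=2, n_shared_mirnas=4, n_pairwise=1,
                         n_unique_per_species=2)
    cat3, truth3 = simulate_catalogs(config_b)
    assert truth1.mirna_sequences != truth3.mirna_sequences
    # membership structure is seed-independent
    for t in (truth1, truth3):
        sizes = sorted(len(m) for m in t.mirna_membership.values())
        assert sizes == sorted([3] * 4 + [2] * 3 + [1] * 6)


def test_simulate_catalogs_seed_separation():
    config = SimConfig(rng_seed=9, n_shared_mirnas=20, n_pairwise=3,
                       n_unique_per_species=5)
    _, truth = simulate_catalogs(config)
    seeds = [seed_of(m) for m in truth.mirna_sequences.values()]
    for i in range(len(seeds)):
        for j in range(i + 1, len(seeds)):
            assert sum(a != b for a, b in zip(seeds[i], seeds[j])) >= 3


def test_catalog_venn_matches_config():
    config = SimConfig(rng_seed=4, n_shared_mirnas=10, n_pairwise=2,
                       n_unique_per_species=3)
    catalogs, _ = simulate_catalogs(config)
    v = venn_partition(*(catalogs[sp].mature_sequences
                         for sp in ("zebrafish", "bichir", "axolotl")))
    assert v["ABC"] == 10
    assert v["AB"] == v["AC"] == v["BC"] == 2
    assert v["A"] == v["B"] == v["C"] == 3


def _count_config(**kw):
    base = dict(rng_seed=8, n_shared_mirnas=4, n_pairwise=0, n_unique_per_species=0,
                lib_sizes=1e5)
    base.update(kw)
    return SimConfig(**base)


def test_simulate_counts_poisson_limit(rng):
    config = _count_config(dispersion=0.0,
                           replicate_design={"zebrafish": (100, 100)})
    features = [f"f{i}" for i in range(100)]
    dirs = {f: "null" for f in features}
    cm = simulate_counts(features, config, dirs, "zebrafish", rng)
    ctrl = cm.counts[[c for c in cm.counts if "_ctrl_" in c]].to_numpy()
    ratios = ctrl.var(axis=1, ddof=1) / ctrl.mean(axis=1)
    assert 0.9 <= ratios.mean() <= 1.1


def test_simulate_counts_planted_effect(rng):
    config = _count_config(dispersion=0.1, effect_log2fc=2.0,
                           replicate_design={"zebrafish": (500, 500)})
    features = ["up1", "null1", "null2", "null3"]
    dirs = {"up1": "up", "null1": "null", "null2": "null", "null3": "null"}
    cm = simulate_counts(features, config, dirs, "zebrafish", rng)
    ctrl = cm.counts.loc["up1", [c for c in cm.counts if "_ctrl_" in c]].mean()
    case = cm.counts.loc["up1", [c for c in cm.counts if "_case_" in c]].mean()
    assert 3.4 <= case / ctrl <= 4.7


def test_simulate_counts_library_scale_equivariance(rng):
    features = [f"f{i}" for i in range(50)]
    dirs = {f: "null" for f in features}
    design = {"zebrafish": (200, 2)}
    base = {f: 1.0 for f in features}
    c1 = _count_config(dispersion=0.0, lib_sizes=5e4, replicate_design=design)
    c2 = _count_config(dispersion=0.0, lib_sizes=1e5, replicate_design=design)
    m1 = simulate_counts(features, c1, dirs, "zebrafish",
                         np.random.default_rng(0), base_abundance=base)
    m2 = simulate_counts(features, c2, dirs, "zebrafish",
                         np.random.default_rng(0), base_abundance=base)
    mean1 = m1.counts.to_numpy().mean()
    mean2 = m2.counts.to_numpy().mean()
    assert mean2 / mean1 == pytest.approx(2.0, rel=0.05)


def test_simulate_counts_rejects_negative_dispersion():
    with pytest.raises(ValueError, match="dispersion"):
        SimConfig(dispersion=-0.5).validate()


def _truth_with(mirnas):
    truth = GroundTruth()
    for name, seq in mirnas.items():
        truth.mirna_sequences[name] = seq
        truth.mirna_membership[name] = frozenset(
            ("zebrafish", "bichir", "axolotl")
        )
    return truth


def test_simulate_utrs_planted_8mer_exact(rng):
    config = SimConfig(rng_seed=2, utr_len=120)
    truth = _truth_with({"miR-a": "TAGCTTATCAGACTGATGTTGA"})
    utrs = simulate_utrs(
        ["g1"], config, truth, rng, target_plan={"g1": [("miR-a", "8mer")]}
    )
    ((mirna, gene, pos, cls),) = truth.planted_sites
    mi = MatureMiRNA(mirna, "zebrafish", truth.mirna_sequences[mirna])
    sites = canonical_site_scan(mi, utrs["g1"])
    assert [(s.site_class, s.start) for s in sites] == [("8mer", pos)]


def test_simulate_utrs_planted_bulge(rng):
    config = SimConfig(rng_seed=3, utr_len=120)
    truth = _truth_with({"miR-a": "TAGCTTATCAGACTGATGTTGA"})
    utrs = simulate_utrs(
        ["g1"], config, truth, rng, target_plan={"g1": [("miR-a", "bulge5_6")]}
    )
    ((_, _, pos, _),) = truth.planted_sites
    mi = MatureMiRNA("miR-a", "zebrafish", truth.mirna_sequences["miR-a"])
    (site,) = bulge_site_scan(mi, utrs["g1"])
    assert (site.start, site.site_class) == (pos, "bulge5_6")
    # with bulge variants disabled there is no canonical site at that locus
    assert canonical_site_scan(mi, utrs["g1"]) == []


def test_simulate_utrs_zero_targets_means_no_sites(rng):
    config = SimConfig(rng_seed=5, utr_len=100)
    truth = _truth_with({"miR-a": "TAGCTTATCAGACTGATGTTGA",
                         "miR-b": "TTTGGTCCCCTTCAACCAGCTG"})
    utrs = simulate_utrs(["g1", "g2"], config, truth, rng, target_plan={})
    for seq in utrs.values():
        for name, mat in truth.mirna_sequences.items():
            mi = MatureMiRNA(name, "zebrafish", mat)
            assert canonical_site_scan(mi, seq) == []
            assert bulge_site_scan(mi, seq) == []
    assert truth.planted_sites == []


def test_simulate_utrs_too_short_fails(rng):
    config = SimConfig(rng_seed=6, utr_len=12)
    truth = _truth_with({"miR-a": "TAGCTTATCAGACTGATGTTGA"})
    with pytest.raises(SimulationError):
        simulate_utrs(["g1"], config, truth, rng,
                      target_plan={"g1": [("miR-a", "8mer")] * 3})


def test_simulate_interactions_properties(rng):
    genes = [f"g{i}" for i in range(30)]
    config = SimConfig(rng_seed=7, n_interactions=100, frac_anchor_edges=0.4)
    table = simulate_interactions(genes, genes[:3], config, rng)
    assert len(table) == 100
    assert (table["score"] > 0).all() and (table["score"] <= 1000).all()
    assert (table["gene_a"] != table["gene_b"]).all()
    pairs = {frozenset((a, b)) for a, b in zip(table["gene_a"], table["gene_b"])}
    assert len(pairs) == 100  # no duplicate unordered pairs
    anchors = set(genes[:3])
    touching = sum(
        1 for a, b in zip(table["gene_a"], table["gene_b"])
        if a in anchors or b in anchors
    )
    assert touching >= 40


def test_simulate_interactions_requires_anchor_subset(rng):
    config = SimConfig(rng_seed=7)
    with pytest.raises(ValueError):
        simulate_interactions(["g1"], ["not_a_gene"], config, rng)


def test_plant_directions_fractions(rng):
    config = SimConfig(frac_planted_up=0.2, frac_planted_down=0.1)
    features = [f"f{i}" for i in range(200)]
    dirs = plant_directions(features, config, rng)
    counts = {d: sum(v == d for v in dirs.values()) for d in ("up", "down", "null")}
    assert counts == {"up": 40, "down": 20, "null": 140}


def test_trf_contamination_rate(tmp_path):
    """At trf_rate=0.1 about 1 read in 11 is a tRNA fragment."""
    from regencirc import (
        classify_noncoding, collapse_tags, process_reads, read_sequences,
        simulate_reads,
    )
    from regencirc.synthetic_data import make_noncoding_refs

    config = SimConfig(rng_seed=12, isomir_rate=0.0, trf_rate=0.1, rrf_rate=0.0,
                       n_shared_mirnas=4, n_pairwise=0, n_unique_per_species=0)
    catalogs, truth = simulate_catalogs(config)
    trna, rrna = make_noncoding_refs(config, config.child_rng(6),
                                     truth.mirna_sequences)
    seqs = list(truth.mirna_sequences.values())
    tags = {"s1": {seq: 2500 for seq in seqs}}  # 10,000 tag reads
    paths = simulate_reads(tags, config, trna, rrna, tmp_path)
    inserts = process_reads(read_sequences(paths["s1"], "fastq"), config.adapter)
    table = collapse_tags({"s1": inserts})
    n_trf = 0
    for tag in table.counts.index:
        cls = classify_noncoding(tag, catalogs["zebrafish"], trna, rrna).cls
        if cls == "tRF":
            n_trf += int(table.counts.at[tag, "s1"])
    frac = n_trf / int(table.counts["s1"].sum())
    assert 0.08 <= frac <= 0.12
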