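"""Shared-direction verdicts, Venn partitions and ortholog handling."""

import numpy as np
import pandas as pd
import pytest

from regencirc import (
    MatureMiRNA,
    MiRNACatalog,
    SpeciesDE,
    classify_shared_direction,
    mirna_identity_map,
    reciprocal_best_hits,
    shared_de_features,
    simulate_catalogs,
    venn_partition,
)
from regencirc.cross_species import apply_ortholog_map
from regencirc.synthetic_data import SimConfig

RULES3 = {"zebrafish": "significant", "bichir": "sign_only", "axolotl": "sign_only"}


def _de(lfc, p=None):
    return SpeciesDE(log2fc=lfc, p_value=p)


def test_classify_measured_rows():
    # the strongest commonly upregulated miRNA across the three models
    call = classify_shared_direction(
        "miR-21",
        {"zebrafish": _de(4.05, 3.28e-8), "bichir": _de(1.85), "axolotl": _de(5.21)},
        RULES3,
    )
    assert call.verdict == "shared_up"
    # downregulated everywhere; bichir at -0.57 passes by sign but not by threshold
    calls = {
        "zebrafish": _de(-2.60, 4.76e-5),
        "bichir": _de(-0.57),
        "axolotl": _de(-2.36),
    }
    assert classify_shared_direction("miR-204", calls, RULES3).verdict == "shared_down"
    thr = {"zebrafish": "significant", "bichir": "threshold", "axolotl": "threshold"}
    assert classify_shared_direction("miR-204", calls, thr).verdict == "not_shared"


def test_classify_discordant_and_missing():
    call = classify_shared_direction(
        "x",
        {"zebrafish": _de(2.0, 1e-4), "bichir": _de(-2.0), "axolotl": _de(2.0)},
        RULES3,
    )
    assert call.verdict == "discordant"
    call = classify_shared_direction(
        "x",
        {"zebrafish": _de(2.0, 1e-4), "bichir": None, "axolotl": _de(2.0)},
        RULES3,
    )
    assert call.verdict == "not_shared"
    assert call.species_set == {"zebrafish", "axolotl"}


def test_classify_insignificant_anchor():
    call = classify_shared_direction(
        "x",
        {"zebrafish": _de(2.0, 0.2), "bichir": _de(1.0), "axolotl": _de(1.0)},
        RULES3,
    )
    assert call.verdict == "not_shared"


def test_mirna_identity_map():
    cats = {
        "zebrafish": MiRNACatalog(
            "zebrafish", [MatureMiRNA("miR-21", "zebrafish", "TAGCTTATCAGACTGATGTTGA")]
        ),
        "bichir": MiRNACatalog(
            "bichir",
            [
                MatureMiRNA("psm-miR-21", "bichir", "TAGCTTATCAGACTGATGTTGA"),
                MatureMiRNA("psm-miR-x", "bichir", "TAGCTTATCAGACTGATGTTGG"),
            ],
        ),
    }
    groups = mirna_identity_map(cats, anchor="zebrafish")
    shared = groups[groups["mature"] == "TAGCTTATCAGACTGATGTTGA"].iloc[0]
    assert shared["name"] == "miR-21"  # anchor naming wins
    assert shared["species"] == ("bichir", "zebrafish")
    # 1-nt difference -> separate group
    assert len(groups) == 2


def test_identity_map_matches_simulated_membership():
    config = SimConfig(rng_seed=11, n_shared_mirnas=8, n_pairwise=2,
                       n_unique_per_species=3)
    catalogs, truth = simulate_catalogs(config)
    groups = mirna_identity_map(catalogs, anchor="zebrafish")
    by_n = groups["n_species"].value_counts().to_dict()
    assert by_n.get(3, 0) == 8
    assert by_n.get(2, 0) == 2 * 3
    assert by_n.get(1, 0) == 3 * 3


def test_venn_partition_cases_and_identities(rng):
    assert venn_partition([1, 2], [1, 2], [1, 2]) == {
        "ABC": 2, "AB": 0, "AC": 0, "BC": 0, "A": 0, "B": 0, "C": 0
    }
    disjoint = venn_partition([1], [2], [3, 4])
    assert (disjoint["A"], disjoint["B"], disjoint["C"]) == (1, 1, 2)
    assert disjoint["ABC"] == 0
    for _ in range(50):
        a, b, c = (set(rng.integers(0, 30, size=rng.integers(0, 25))) for _ in range(3))
        v = venn_partition(a, b, c)
        assert sum(v.values()) == len(a | b | c)
        assert v["ABC"] + v["AB"] + v["AC"] + v["A"] == len(a)
        assert v["ABC"] + v["AB"] + v["BC"] + v["B"] == len(b)
        assert v["ABC"] + v["AC"] + v["BC"] + v["C"] == len(c)


def _tables(flip=1.0):
    zf = pd.DataFrame(
        {
            "log2fc": np.array([2.0, -1.5, 1.2, 0.8, 2.5]) * flip,
            "p_value": [1e-5, 1e-4, 1e-3, 0.2, 1e-6],
            "fdr": [1e-4, 1e-3, 5e-3, 0.4, 1e-5],
            "de_flag": ["up", "down", "up", "ns", "up"],
        },
        index=[f"m{i}" for i in range(5)],
    )
    if flip < 0:
        zf["de_flag"] = ["down", "up", "down", "ns", "down"]
    bi = pd.DataFrame(
        {"log2fc": np.array([1.0, -2.0, -0.5, 1.0, 0.9]) * flip},
        index=[f"m{i}" for i in range(5)],
    )
    ax = pd.DataFrame(
        {"log2fc": np.array([3.0, -1.0, 0.4, 1.0]) * flip},
        index=["m0", "m1", "m2", "m3"],  # m4 absent in axolotl
    )
    return {"zebrafish": zf, "bichir": bi, "axolotl": ax}


def test_shared_de_features_partitions_disjoint_exhaustive():
    parts = shared_de_features(_tables(), "zebrafish")
    universe = {"m0", "m1", "m2", "m4"}  # zebrafish up/down flags
    seen = []
    for df in parts.values():
        seen += list(df["feature"])
    assert sorted(seen) == sorted(universe)  # exhaustive, no duplicates
    assert set(parts["all"]["feature"]) == {"m0", "m1"}
    assert set(parts["zebrafish+bichir"]["feature"]) == {"m4"}  # axolotl missing
    # bichir disagrees in sign for m2, axolotl agrees -> pairwise with axolotl
    assert set(parts["zebrafish+axolotl"]["feature"]) == {"m2"}
    assert parts["zebrafish_only"].empty
    # ordering: |anchor log2fc| descending
    assert parts["all"]["log2fc_zebrafish"].abs().is_monotonic_decreasing


def test_shared_de_features_sign_flip_symmetry():
    parts = shared_de_features(_tables(), "zebrafish")
    flipped = shared_de_features(_tables(-1.0), "zebrafish")
    for name in parts:
        assert list(parts[name]["feature"]) == list(flipped[name]["feature"])


def test_shared_de_features_no_anchor_threshold_rule():
    tables = {
        "bichir": pd.DataFrame(
            {"log2fc": [3.36, 0.59, 0.50, -1.41]}, index=["a", "b", "c", "d"]
        ),
        "axolotl": pd.DataFrame(
            {"log2fc": [5.88, 1.20, 2.0, -0.73]}, index=["a", "b", "c", "d"]
        ),
    }
    rules = {"bichir": "threshold", "axolotl": "threshold"}
    parts = shared_de_features(tables, None, rules)
    (key,) = parts
    assert set(parts[key]["feature"]) == {"a", "b", "d"}  # c fails |0.50| > 0.58


def _rbh_oracle(ab, ba):
    def best(df):
        out = {}
        for _, r in df.iterrows():
            q, s, sc = r["query"], r["subject"], r["score"]
            if q not in out or sc > out[q][0] or (sc == out[q][0] and s < out[q][1]):
                out[q] = (sc, s)
        return {q: s for q, (_, s) in out.items()}

    fwd, rev = best(ab), best(ba)
    return sorted((a, b) for a, b in fwd.items() if rev.get(b) == a)


def test_reciprocal_best_hits(rng):
    ab = pd.DataFrame(
        {"query": ["a1", "a1", "a2"], "subject": ["b1", "b2", "b1"],
         "score": [90, 50, 99]}
    )
    ba = pd.DataFrame(
        {"query": ["b1", "b2"], "subject": ["a1", "a1"], "score": [80, 70]}
    )
    out = reciprocal_best_hits(ab, ba)
    # a1<->b1 mutual best; a2->b1 not reciprocated
    assert out[["gene_a", "gene_b"]].values.tolist() == [["a1", "b1"]]
    for _ in range(30):
        n = int(rng.integers(2, 12))
        ab = pd.DataFrame(
            {
                "query": [f"a{rng.integers(n)}" for _ in range(3 * n)],
                "subject": [f"b{rng.integers(n)}" for _ in range(3 * n)],
                "score": rng.integers(0, 5, size=3 * n),
            }
        )
        ba = pd.DataFrame(
            {
                "query": [f"b{rng.integers(n)}" for _ in range(3 * n)],
                "subject": [f"a{rng.integers(n)}" for _ in range(3 * n)],
                "score": rng.integers(0, 5, size=3 * n),
            }
        )
        got = reciprocal_best_hits(ab, ba)[["gene_a", "gene_b"]].values.tolist()
        assert got == [list(t) for t in _rbh_oracle(ab, ba)]


def test_apply_ortholog_map_picks_highest_expression():
    table = pd.DataFrame(
        {"log2fc": [1.0, 2.0, -1.0], "log_cpm": [5.0, 9.0, 3.0]},
        index=["t1", "t2", "t3"],
    )
    omap = pd.DataFrame(
        {"gene_a": ["g1", "g1", "g2"], "gene_b": ["t1", "t2", "t3"]}
    )
    out = apply_ortholog_map(table, omap)
    assert out.loc["g1", "log2fc"] == 2.0  # t2 has the higher mean expression
    assert out.loc["g2", "log2fc"] == -1.0
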