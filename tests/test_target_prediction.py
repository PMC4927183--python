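"""Seed-site scanning, bulge detection and duplex scoring."""

import itertools

import numpy as np
import pytest

from regencirc import (
    MatureMiRNA,
    MiRNACatalog,
    bulge_site_scan,
    canonical_site_scan,
    duplex_score,
    inverse_expression_filter,
    predict_targets,
)
from regencirc._dna import random_dna, revcomp
from regencirc.target_prediction import GAP_EXTEND, GAP_OPEN, _pair_score

from conftest import WC

MIR = MatureMiRNA("miR-t", "zebrafish", "TAGCTTATCAGACTGATGTTGA")


def oracle_canonical(mature, utr):
    """Independent base-by-base complementarity check of the class rules."""
    sites = []
    for p in range(len(utr) - 5):
        if not all(WC[utr[p + i]] == mature[6 - i] for i in range(6)):
            continue  # positions 2-7 must pair
        has_m8 = p >= 1 and WC[utr[p - 1]] == mature[7]
        has_a1 = p + 6 < len(utr) and utr[p + 6] == "A"
        if has_m8 and has_a1:
            sites.append(("8mer", p - 1, p + 7))
        elif has_m8:
            sites.append(("7mer-m8", p - 1, p + 6))
        elif has_a1:
            sites.append(("7mer-A1", p, p + 7))
        else:
            sites.append(("6mer", p, p + 6))
    return sorted(sites)


def oracle_bulge(mature, utr):
    """Enumerate windows pairing positions 2-8 with one extra target base
    between the bases pairing positions 5 and 6."""
    hits = set()
    for p in range(len(utr) - 7):
        w = utr[p : p + 8]
        pairs = (
            WC[w[0]] == mature[7]
            and WC[w[1]] == mature[6]
            and WC[w[2]] == mature[5]
            # w[3] is the unpaired bulge nucleotide
            and WC[w[4]] == mature[4]
            and WC[w[5]] == mature[3]
            and WC[w[6]] == mature[2]
            and WC[w[7]] == mature[1]
        )
        if pairs:
            hits.add((p, p + 8))
    return sorted(hits)


def test_canonical_classes_by_construction():
    m = MIR.mature
    # reverse complement of positions 2-8 only, flanked away from A1/m8
    utr = "CC" + revcomp(m[1:8]) + "C" + "CC"
    (site,) = canonical_site_scan(MIR, utr)
    assert site.site_class == "7mer-m8"
    # drop the m8-pairing base, add the A1 -> 7mer-A1
    utr = "CC" + revcomp(m[1:7]) + "A" + "CC"
    (site,) = canonical_site_scan(MIR, utr)
    assert site.site_class == "7mer-A1"
    # no >=6-nt complementary run -> nothing
    assert canonical_site_scan(MIR, "C" * 40) == []


def test_canonical_scan_matches_oracle(rng):
    for _ in range(300):
        mature = random_dna(rng, 22)
        utr = random_dna(rng, 40)
        if rng.random() < 0.5:  # spike in a seed match half the time
            pos = int(rng.integers(0, 30))
            utr = utr[:pos] + revcomp(mature[1:8]) + utr[pos + 7 :]
        mi = MatureMiRNA("m", "s", mature)
        got = sorted(
            (s.site_class, s.start, s.end) for s in canonical_site_scan(mi, utr)
        )
        assert got == oracle_canonical(mature, utr)


def test_bulge_scan_matches_enumeration(rng):
    n_with_hits = 0
    for _ in range(1000):
        mature = random_dna(rng, 22)
        utr = random_dna(rng, 30)
        if rng.random() < 0.5:
            pos = int(rng.integers(0, 20))
            m7 = revcomp(mature[1:8])
            chunk = m7[:3] + str(rng.choice(list("ACGT"))) + m7[3:]
            utr = utr[:pos] + chunk + utr[pos + 8 :]
        mi = MatureMiRNA("m", "s", mature)
        got = sorted((s.start, s.end) for s in bulge_site_scan(mi, utr))
        assert got == oracle_bulge(mature, utr)
        n_with_hits += bool(got)
    assert n_with_hits > 300  # the spike-in actually exercises the scanner


def test_bulge_positional_rules():
    m = MIR.mature
    m7 = revcomp(m[1:8])
    # planted bulge: one inserted G between the bases pairing positions 5 and 6
    utr = "CC" + m7[:3] + "G" + m7[3:] + "CC"
    (site,) = bulge_site_scan(MIR, utr)
    assert (site.start, site.end, site.site_class) == (2, 10, "bulge5_6")
    # removing the inserted base leaves a canonical 7mer-m8 at the same locus
    collapsed = "CC" + m7 + "CC"
    assert bulge_site_scan(MIR, collapsed) == []
    (canon,) = canonical_site_scan(MIR, collapsed)
    assert canon.site_class == "7mer-m8" and canon.start == 2
    # insertion between the positions 3/4 pairing bases is not a pivot site
    utr_34 = "CC" + m7[:5] + "G" + m7[5:] + "CC"
    assert bulge_site_scan(MIR, utr_34) == []


def oracle_duplex(mirna, window):
    """Exhaustive path enumeration over all local alignments (tiny inputs)."""
    m = mirna[::-1]
    n_m, n_u = len(m), len(window)
    best = 0.0

    def extend(i, j, score, state):
        nonlocal best
        best = max(best, score)
        if i < n_m and j < n_u:
            pos = n_m - i
            extend(i + 1, j + 1, score + _pair_score(m[i], window[j], pos), "d")
        if j < n_u:
            pen = GAP_EXTEND if state == "e" else GAP_OPEN
            extend(i, j + 1, score + pen, "e")
        if i < n_m:
            pen = GAP_EXTEND if state == "f" else GAP_OPEN
            extend(i + 1, j, score + pen, "f")

    for i0 in range(n_m):
        for j0 in range(n_u):
            extend(i0, j0, 0.0, "d")
    return best


def test_duplex_score_perfect_and_errors():
    m = MIR.mature
    assert duplex_score(m, revcomp(m)) == 5 * 22 + 5 * 7
    with pytest.raises(ValueError):
        duplex_score(m, "")


def test_duplex_score_matches_bruteforce(rng):
    for _ in range(15):
        mirna = random_dna(rng, int(rng.integers(3, 6)))
        window = random_dna(rng, int(rng.integers(3, 6)))
        assert duplex_score(mirna, window) == pytest.approx(
            oracle_duplex(mirna, window)
        )


def test_predict_targets_order_invariance_and_monotonicity(rng):
    catalog = [
        MatureMiRNA("m1", "s", random_dna(rng, 22)),
        MatureMiRNA("m2", "s", random_dna(rng, 22)),
    ]
    utrs = {}
    for g in ("g1", "g2", "g3"):
        seq = random_dna(rng, 60)
        mi = catalog[int(rng.integers(2))]
        utrs[g] = seq[:20] + revcomp(mi.mature[1:8]) + "A" + seq[28:]
    t_fwd = predict_targets(catalog, utrs, min_score=0)
    t_rev = predict_targets(
        list(reversed(catalog)), dict(reversed(list(utrs.items()))), min_score=0
    )
    assert t_fwd.sort_values(list(t_fwd.columns)).reset_index(drop=True).equals(
        t_rev.sort_values(list(t_rev.columns)).reset_index(drop=True)
    )
    n_prev = None
    for threshold in (0, 40, 70, 90, 1000):
        n = len(predict_targets(catalog, utrs, min_score=threshold))
        if n_prev is not None:
            assert n <= n_prev
        n_prev = n


def test_predict_targets_reported_sites_pair_as_claimed(rng):
    catalog = [MatureMiRNA("m1", "s", random_dna(rng, 22))]
    utrs = {f"g{i}": random_dna(rng, 80) for i in range(5)}
    mi = catalog[0]
    utrs["g0"] = utrs["g0"][:10] + revcomp(mi.mature[1:8]) + "A" + utrs["g0"][18:]
    sites = predict_targets(catalog, utrs, min_score=0)
    for _, s in sites.iterrows():
        window = utrs[s["gene"]][s["start"] : s["end"]]
        if s["site_class"] == "8mer":
            assert window == revcomp(mi.mature[1:8]) + "A"
        elif s["site_class"] == "7mer-m8":
            assert window == revcomp(mi.mature[1:8])


def test_allow_bulge_toggle():
    m = MIR.mature
    m7 = revcomp(m[1:8])
    utrs = {
        "bulged": "CCCC" + m7[:3] + "G" + m7[3:] + "CCCC",
        "canonical": "CCCC" + m7 + "T" + "CCC",
    }
    with_bulge = predict_targets([MIR], utrs, min_score=0, allow_bulge=True)
    without = predict_targets([MIR], utrs, min_score=0, allow_bulge=False)
    removed = set(map(tuple, with_bulge[["gene", "site_class"]].values)) - set(
        map(tuple, without[["gene", "site_class"]].values)
    )
    assert removed == {("bulged", "bulge5_6")}


def test_inverse_expression_filter():
    import pandas as pd

    sites = pd.DataFrame(
        {
            "mirna": ["mUP", "mUP", "mUP", "mDOWN"],
            "gene": ["gDOWN", "gDOWN", "gUP", "gUP"],
            "start": [0, 20, 5, 9],
            "end": [8, 28, 13, 17],
            "site_class": ["8mer"] * 4,
            "score": [100.0, 90.0, 80.0, 95.0],
        }
    )
    pairs = inverse_expression_filter(
        sites,
        {"mUP": "shared_up", "mDOWN": "shared_down"},
        {"gDOWN": "shared_down", "gUP": "shared_up"},
    )
    got = {(r["mirna"], r["gene"]): (r["n_sites"], r["best_score"]) for _, r in pairs.iterrows()}
    assert got == {("mUP", "gDOWN"): (2, 100.0), ("mDOWN", "gUP"): (1, 95.0)}
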