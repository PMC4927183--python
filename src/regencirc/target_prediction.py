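"""miRNA target-site prediction in 3'-UTRs.

Canonical seed classes follow the usual nomenclature -- 6mer (miRNA
positions 2-7), 7mer-m8 (2-8), 7mer-A1 (2-7 plus a target A opposite
position 1) and 8mer (2-8 plus A1) -- with Watson-Crick reverse-complement
matching on the given UTR strand only. In addition, the nucleation-bulge
(pivot) class accepts exactly one unpaired target nucleotide between the
target bases pairing miRNA positions 5 and 6, detected by enumerating the
four single-nucleotide insertions into the expected 7mer-m8 match pattern.

Candidate duplexes are scored with a deterministic local anti-parallel
alignment (match +5, G:T wobble +1, mismatch -3, gap open -8, gap extend
-2, with substitution contributions at miRNA positions 2-8 doubled).
Coordinates are 0-based half-open on the UTR and 1-based on the miRNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._dna import revcomp
from .mirna_annotation import MatureMiRNA, MiRNACatalog

MIN_SCORE = 80.0

MATCH = 5.0
WOBBLE = 1.0
MISMATCH = -3.0
GAP_OPEN = -8.0
GAP_EXTEND = -2.0
SEED_MULT = 2.0  # applied to substitution scores at miRNA positions 2-8

CLASS_RANK = {"8mer": 4, "7mer-m8": 3, "7mer-A1": 2, "6mer": 1, "bulge5_6": 0}

_PAIR = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_WOBBLE = {("G", "T"), ("T", "G")}  # miRNA G : target U and miRNA U : target G


@dataclass(frozen=True)
class TargetSite:
    mirna: str
    gene: str
    start: int  # 0-based, half-open on the UTR
    end: int
    site_class: str
    score: float = 0.0


def _check_utr(utr: str) -> None:
    if set(utr) - set("ACGT"):
        raise ValueError("UTR must be an ACGT string")


def canonical_site_scan(mirna: MatureMiRNA, utr_seq: str, gene: str = "") -> list[TargetSite]:
    """Canonical seed sites of a miRNA in one UTR, highest class per locus.

    A locus is an occurrence of the reverse complement of miRNA positions
    2-7; the presence of pairing to position 8 and/or a target A opposite
    position 1 upgrades it to 7mer-m8, 7mer-A1 or 8mer.
    """
    _check_utr(utr_seq)
    mature = mirna.mature
    core = revcomp(mature[1:7])  # pairs positions 2-7; core[0] pairs m7
    m8_match = revcomp(mature[7])  # target base pairing position 8
    sites = []
    for p in range(len(utr_seq) - 5):
        if utr_seq[p : p + 6] != core:
            continue
        has_m8 = p >= 1 and utr_seq[p - 1] == m8_match
        has_a1 = p + 6 < len(utr_seq) and utr_seq[p + 6] == "A"
        if has_m8 and has_a1:
            cls, start, end = "8mer", p - 1, p + 7
        elif has_m8:
            cls, start, end = "7mer-m8", p - 1, p + 6
        elif has_a1:
            cls, start, end = "7mer-A1", p, p + 7
        else:
            cls, start, end = "6mer", p, p + 6
        sites.append(TargetSite(mirna.name, gene, start, end, cls))
    return sites


def bulge_site_scan(mirna: MatureMiRNA, utr_seq: str, gene: str = "") -> list[TargetSite]:
    """Nucleation-bulge sites: seed match to positions 2-8 with one extra
    target nucleotide between the bases pairing miRNA positions 5 and 6."""
    _check_utr(utr_seq)
    match7 = revcomp(mirna.mature[1:8])  # match7[i] pairs position 8-i
    hits: set[tuple[int, int]] = set()
    for base in "ACGT":
        pattern = match7[:3] + base + match7[3:]  # insertion between m6 and m5 pairing bases
        p = utr_seq.find(pattern)
        while p != -1:
            hits.add((p, p + 8))
            p = utr_seq.find(pattern, p + 1)
    return [
        TargetSite(mirna.name, gene, start, end, "bulge5_6")
        for start, end in sorted(hits)
    ]


def _pair_score(mirna_base: str, utr_base: str, mirna_pos: int) -> float:
    if (mirna_base, utr_base) in _PAIR:
        s = MATCH
    elif (mirna_base, utr_base) in _WOBBLE:
        s = WOBBLE
    else:
        s = MISMATCH
    if 2 <= mirna_pos <= 8:
        s *= SEED_MULT
    return s


def duplex_score(mirna_mature: str, utr_window: str) -> float:
    """Best local anti-parallel duplex alignment score (Gotoh, affine gaps).

    The miRNA is read 5'->3' with 1-based positions; the UTR window 5'->3'.
    Anti-parallel pairing aligns the miRNA reversed against the window.
    A perfect 22-nt complement scores 5*22 + 5*7 = 145 (seed doubling).
    """
    if not utr_window:
        raise ValueError("empty UTR window")
    if not mirna_mature:
        raise ValueError("empty miRNA sequence")
    m = mirna_mature[::-1]  # m[i-1] is miRNA position len-i+1 ... reversed order
    n_m, n_u = len(m), len(utr_window)
    neg = -np.inf
    H = np.zeros((n_m + 1, n_u + 1))
    E = np.full((n_m + 1, n_u + 1), neg)  # gap in miRNA (consume UTR)
    F = np.full((n_m + 1, n_u + 1), neg)  # gap in UTR (consume miRNA)
    best = 0.0
    for i in range(1, n_m + 1):
        pos = n_m - i + 1  # 1-based miRNA position of m[i-1]
        for j in range(1, n_u + 1):
            E[i][j] = max(H[i][j - 1] + GAP_OPEN, E[i][j - 1] + GAP_EXTEND)
            F[i][j] = max(H[i - 1][j] + GAP_OPEN, F[i - 1][j] + GAP_EXTEND)
            diag = H[i - 1][j - 1] + _pair_score(m[i - 1], utr_window[j - 1], pos)
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return float(best)


def _score_window(utr_seq: str, site: TargetSite, mirna: MatureMiRNA) -> float:
    # window spans from the site 3' boundary back over the miRNA length,
    # leaving room for 3' supplementary pairing and small bulges
    start = max(0, site.end - (len(mirna.mature) + 3))
    window = utr_seq[start : site.end]
    return duplex_score(mirna.mature, window)


def predict_targets(
    catalog: MiRNACatalog | Iterable[MatureMiRNA],
    utrs: Mapping[str, str],
    min_score: float = MIN_SCORE,
    allow_bulge: bool = True,
) -> pd.DataFrame:
    """Scan every miRNA against every UTR and score candidate sites.

    Returns a site table (mirna, gene, start, end, site_class, score)
    sorted by (gene, start, mirna); sites scoring below ``min_score`` are
    dropped. Results are invariant to UTR and catalog order.
    """
    rows = []
    for mirna in catalog:
        for gene in sorted(utrs):
            utr_seq = utrs[gene]
            if len(utr_seq) < 8:
                continue
            sites = canonical_site_scan(mirna, utr_seq, gene)
            if allow_bulge:
                sites += bulge_site_scan(mirna, utr_seq, gene)
            for site in sites:
                score = _score_window(utr_seq, site, mirna)
                if score >= min_score:
                    rows.append(
                        {
                            "mirna": site.mirna,
                            "gene": site.gene,
                            "start": site.start,
                            "end": site.end,
                            "site_class": site.site_class,
                            "score": score,
                        }
                    )
    df = pd.DataFrame(
        rows, columns=["mirna", "gene", "start", "end", "site_class", "score"]
    )
    return df.sort_values(["gene", "start", "mirna"], kind="stable").reset_index(
        drop=True
    )


def inverse_expression_filter(
    sites: pd.DataFrame,
    mirna_verdicts: Mapping[str, str],
    gene_verdicts: Mapping[str, str],
) -> pd.DataFrame:
    """Keep (miRNA, gene) pairs whose expression changes are inverse.

    A pair survives iff the miRNA verdict is shared_up and the gene verdict
    shared_down, or vice versa. Sites are aggregated per pair into n_sites
    and best_score.
    """
    if sites.empty:
        return pd.DataFrame(
            columns=["mirna", "gene", "n_sites", "best_score", "mirna_verdict", "gene_verdict"]
        )
    keep = []
    for (mirna, gene), group in sites.groupby(["mirna", "gene"], sort=True):
        mv = mirna_verdicts.get(mirna)
        gv = gene_verdicts.get(gene)
        inverse = (mv == "shared_up" and gv == "shared_down") or (
            mv == "shared_down" and gv == "shared_up"
        )
        if inverse:
            keep.append(
                {
                    "mirna": mirna,
                    "gene": gene,
                    "n_sites": len(group),
                    "best_score": float(group["score"].max()),
                    "mirna_verdict": mv,
                    "gene_verdict": gv,
                }
            )
    return pd.DataFrame(
        keep,
        columns=["mirna", "gene", "n_sites", "best_score", "mirna_verdict", "gene_verdict"],
    )
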