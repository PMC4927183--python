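"""Cross-species intersection of differential-expression calls.

miRNAs are identified across species by exact mature-sequence equality;
protein-coding genes through an ortholog map into the anchor species'
namespace. Concordance is judged per feature by a shared-direction verdict:
the replicated anchor species must be significant, while an unreplicated
species contributes either by sign alone (``sign_only``) or by a strict
|log2FC| threshold (``threshold``). Both rules exist because single-sample
designs support no significance testing, and the two rules bracket how
stringently a fold change is trusted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import math

import numpy as np
import pandas as pd

from .diffexpr import ALPHA, FC_THRESHOLD
from .mirna_annotation import MiRNACatalog

VERDICTS = ("shared_up", "shared_down", "discordant", "not_shared")


@dataclass
class SpeciesDE:
    """One species' evidence for one feature."""

    log2fc: float
    p_value: float | None = None  # raw p (replicated designs)
    fdr: float | None = None  # BH-adjusted p, preferred when present


@dataclass
class SharedCall:
    feature: str
    verdict: str
    species_set: frozenset[str]
    log2fc: dict[str, float]


def _passes(de: SpeciesDE, rule: str, alpha: float, fc_threshold: float) -> bool:
    if rule == "significant":
        sig = de.fdr if de.fdr is not None and not math.isnan(de.fdr) else de.p_value
        if sig is None or math.isnan(sig):
            return False
        return sig < alpha and de.log2fc != 0
    if rule == "sign_only":
        return de.log2fc != 0
    if rule == "threshold":
        return abs(de.log2fc) > fc_threshold
    raise ValueError(f"unknown sharing rule {rule!r}")


def classify_shared_direction(
    feature: str,
    calls: Mapping[str, SpeciesDE | None],
    rules: Mapping[str, str],
    alpha: float = ALPHA,
    fc_threshold: float = FC_THRESHOLD,
) -> SharedCall:
    """Shared-direction verdict for one feature across species.

    ``calls`` maps species to its DE evidence (None = feature not observed);
    ``rules`` maps species to one of ``significant`` (replicated anchor),
    ``sign_only`` or ``threshold``. The verdict is shared_up / shared_down
    when every species passes its rule and all fold changes agree in sign,
    discordant when all pass but signs differ, and not_shared otherwise
    (including any missing species, recorded via ``species_set``).
    """
    present = {sp: de for sp, de in calls.items() if de is not None}
    species_set = frozenset(present)
    lfc = {sp: de.log2fc for sp, de in present.items()}
    if set(present) != set(calls):
        return SharedCall(feature, "not_shared", species_set, lfc)
    if not all(
        _passes(de, rules[sp], alpha, fc_threshold) for sp, de in present.items()
    ):
        return SharedCall(feature, "not_shared", species_set, lfc)
    signs = {np.sign(de.log2fc) for de in present.values()}
    if signs == {1.0}:
        verdict = "shared_up"
    elif signs == {-1.0}:
        verdict = "shared_down"
    else:
        verdict = "discordant"
    return SharedCall(feature, verdict, species_set, lfc)


def mirna_identity_map(
    catalogs: Mapping[str, MiRNACatalog], anchor: str | None = None
) -> pd.DataFrame:
    """Group miRNAs across species by exact mature-sequence equality.

    Returns one row per distinct mature sequence with the member species and
    a representative name (the anchor species' name when available).
    """
    if not catalogs or any(len(c) == 0 for c in catalogs.values()):
        raise ValueError("catalogs must be non-empty")
    groups: dict[str, dict[str, str]] = {}
    for species, catalog in catalogs.items():
        for entry in catalog:
            groups.setdefault(entry.mature, {})[species] = entry.name
    rows = []
    for mature, members in groups.items():
        if anchor is not None and anchor in members:
            name = members[anchor]
        else:
            name = members[sorted(members)[0]]
        rows.append(
            {
                "mature": mature,
                "name": name,
                "species": tuple(sorted(members)),
                "n_species": len(members),
            }
        )
    return pd.DataFrame(rows).sort_values("name").reset_index(drop=True)


def venn_partition(
    set_a: Iterable, set_b: Iterable, set_c: Iterable
) -> dict[str, int]:
    """Counts of the 7 disjoint membership regions of three sets.

    Keys: 'A', 'B', 'C' (exclusive singles), 'AB', 'AC', 'BC' (exclusive
    pairs) and 'ABC'.
    """
    a, b, c = set(set_a), set(set_b), set(set_c)
    abc = a & b & c
    return {
        "ABC": len(abc),
        "AB": len((a & b) - c),
        "AC": len((a & c) - b),
        "BC": len((b & c) - a),
        "A": len(a - b - c),
        "B": len(b - a - c),
        "C": len(c - a - b),
    }


def _de_lookup(table: pd.DataFrame) -> dict[str, SpeciesDE]:
    out = {}
    for feature, row in table.iterrows():
        out[feature] = SpeciesDE(
            log2fc=float(row["log2fc"]),
            p_value=float(row["p_value"]) if "p_value" in row else None,
            fdr=float(row["fdr"]) if "fdr" in row else None,
        )
    return out


def shared_de_features(
    tables: Mapping[str, pd.DataFrame],
    anchor: str | None,
    rules: Mapping[str, str] | None = None,
    alpha: float = ALPHA,
    fc_threshold: float = FC_THRESHOLD,
) -> dict[str, pd.DataFrame]:
    """Partition features by the largest species subset sharing direction.

    ``tables`` are DE tables (index = feature id in a common namespace,
    columns log2fc / p_value / fdr / de_flag). With an anchor species, the
    universe is the anchor's significant features; each is assigned to the
    all-species partition when concordant everywhere, else to an
    anchor+other pairwise partition, else to the anchor-only partition.
    Without an anchor (two unreplicated species), the single partition
    holds features concordant under both species' rules.

    Partitions are disjoint and exhaustive over the universe; rows are
    ordered by |anchor log2fc| descending (|mean log2fc| without an anchor).
    """
    species = list(tables)
    if rules is None:
        rules = {
            sp: ("significant" if sp == anchor else "sign_only") for sp in species
        }
    lookups = {sp: _de_lookup(tables[sp]) for sp in species}

    def call(feature: str, subset: Sequence[str]) -> SharedCall:
        return classify_shared_direction(
            feature,
            {sp: lookups[sp].get(feature) for sp in subset},
            {sp: rules[sp] for sp in subset},
            alpha=alpha,
            fc_threshold=fc_threshold,
        )

    def as_frame(items: list[SharedCall]) -> pd.DataFrame:
        rows = [
            {
                "feature": c.feature,
                "verdict": c.verdict,
                **{f"log2fc_{sp}": c.log2fc.get(sp, np.nan) for sp in species},
            }
            for c in items
        ]
        df = pd.DataFrame(
            rows,
            columns=["feature", "verdict"] + [f"log2fc_{sp}" for sp in species],
        )
        key = f"log2fc_{anchor}" if anchor else None
        if not df.empty:
            order = (
                df[key].abs()
                if key
                else df[[c for c in df.columns if c.startswith("log2fc_")]]
                .abs()
                .mean(axis=1)
            )
            df = df.loc[order.sort_values(ascending=False, kind="stable").index]
        return df.reset_index(drop=True)

    if anchor is None:
        universe = sorted(set.intersection(*(set(lookups[sp]) for sp in species)))
        shared = [
            c
            for f in universe
            if (c := call(f, species)).verdict in ("shared_up", "shared_down")
        ]
        return {"+".join(sorted(species)): as_frame(shared)}

    anchor_table = tables[anchor]
    universe = [
        f
        for f, row in anchor_table.iterrows()
        if row.get("de_flag", "ns") in ("up", "down")
    ]
    others = [sp for sp in species if sp != anchor]
    partitions: dict[str, list[SharedCall]] = {"all": []}
    for sp in others:
        partitions[f"{anchor}+{sp}"] = []
    partitions[f"{anchor}_only"] = []
    for f in universe:
        c_all = call(f, species)
        if c_all.verdict in ("shared_up", "shared_down"):
            partitions["all"].append(c_all)
            continue
        placed = False
        for sp in others:
            c_pair = call(f, [anchor, sp])
            if c_pair.verdict in ("shared_up", "shared_down"):
                partitions[f"{anchor}+{sp}"].append(c_pair)
                placed = True
                break
        if not placed:
            partitions[f"{anchor}_only"].append(call(f, [anchor]))
    return {name: as_frame(items) for name, items in partitions.items()}


def reciprocal_best_hits(
    sim_ab: pd.DataFrame, sim_ba: pd.DataFrame
) -> pd.DataFrame:
    """Reciprocal-best-hit ortholog pairs from two similarity tables.

    Each table has columns query / subject / score. A pair (a, b) is kept
    iff b is a's best-scoring subject in ``sim_ab`` and a is b's best in
    ``sim_ba``; score ties resolve to the lexicographically smallest
    subject id. Returns columns gene_a, gene_b, provenance='rbh'.
    """

    def best(table: pd.DataFrame) -> dict[str, str]:
        out: dict[str, tuple[float, str]] = {}
        for _, row in table.iterrows():
            q, s, sc = str(row["query"]), str(row["subject"]), float(row["score"])
            cur = out.get(q)
            if cur is None or sc > cur[0] or (sc == cur[0] and s < cur[1]):
                out[q] = (sc, s)
        return {q: s for q, (_, s) in out.items()}

    ab, ba = best(sim_ab), best(sim_ba)
    pairs = sorted((a, b) for a, b in ab.items() if ba.get(b) == a)
    return pd.DataFrame(pairs, columns=["gene_a", "gene_b"]).assign(provenance="rbh")


def apply_ortholog_map(
    table: pd.DataFrame,
    ortholog_map: pd.DataFrame,
    expression: pd.Series | None = None,
) -> pd.DataFrame:
    """Re-key a DE table from transcript ids into the anchor gene namespace.

    ``ortholog_map`` has columns gene_a (anchor gene) and gene_b
    (transcript). When several transcripts map to one anchor gene the one
    with the highest mean expression (``expression``, else log_cpm, else
    first) represents the gene.
    """
    mapping = ortholog_map.set_index("gene_b")["gene_a"]
    sub = table.loc[table.index.intersection(mapping.index)].copy()
    sub["__gene"] = mapping.loc[sub.index]
    if expression is not None:
        pref = expression.reindex(sub.index)
    elif "log_cpm" in sub.columns:
        pref = sub["log_cpm"]
    else:
        pref = pd.Series(0.0, index=sub.index)
    sub["__pref"] = pref.fillna(-np.inf)
    sub = (
        sub.sort_values("__pref", ascending=False, kind="stable")
        .drop_duplicates("__gene")
        .set_index("__gene")
        .drop(columns="__pref")
    )
    sub.index.name = table.index.name
    return sub.sort_index()
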