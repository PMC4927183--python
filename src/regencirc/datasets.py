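"""Bundled worked-example datasets.

Small measured fold-change tables from published cross-species profiling of
regenerating appendages (zebrafish caudal fin at 4 dpa, bichir pectoral fin
at 7 dpa, axolotl forelimb at 6 dpa, each versus uninjured tissue). They
exercise the shared-direction classifier on real numbers at desk scale:

* ``load_mirna_foldchanges()`` -- miRNA log2 fold changes grouped by which
  species showed concordant regulation (zebrafish carries a raw p-value
  from its replicated design; bichir and axolotl are fold-change-only);
* ``load_bichir_axolotl_foldchanges()`` -- miRNAs commonly up- or
  downregulated between the two unreplicated species at the strict
  |log2FC| > 0.58 cutoff;
* ``load_blastema_genes()`` -- the 11 blastema-associated anchor genes
  with per-species fold changes (one bichir value reported as ">100" is
  stored as 100).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cross_species import SharedCall, SpeciesDE, classify_shared_direction


def _read(name: str) -> pd.DataFrame:
    with resources.files("regencirc.data").joinpath(name).open() as handle:
        return pd.read_csv(handle, sep="\t")


def load_mirna_foldchanges() -> pd.DataFrame:
    """miRNA log2FC table; ``section`` records the concordant species set."""
    return _read("mirna_foldchanges_three_species.tsv")


def load_bichir_axolotl_foldchanges() -> pd.DataFrame:
    return _read("mirna_foldchanges_bichir_axolotl.tsv")


def load_blastema_genes() -> pd.DataFrame:
    return _read("blastema_gene_foldchanges.tsv")


def classify_fixture_rows(
    table: pd.DataFrame,
    species: tuple[str, ...],
    rules: dict[str, str],
    alpha: float = 0.05,
    fc_threshold: float = 0.58,
) -> list[SharedCall]:
    """Run the shared-direction classifier over fixture rows.

    ``table`` needs ``symbol`` plus ``<species>_log2fc`` columns (and
    ``zebrafish_p`` when zebrafish is judged by significance).
    """
    calls = []
    for _, row in table.iterrows():
        evidence = {}
        for sp in species:
            lfc = row.get(f"{sp}_log2fc")
            if pd.isna(lfc):
                evidence[sp] = None
                continue
            p = row.get(f"{sp}_p")
            evidence[sp] = SpeciesDE(
                log2fc=float(lfc),
                p_value=float(p) if p is not None and not pd.isna(p) else None,
            )
        calls.append(
            classify_shared_direction(
                str(row["symbol"]), evidence, rules,
                alpha=alpha, fc_threshold=fc_threshold,
            )
        )
    return calls


def shared_mirna_counts() -> dict[str, int]:
    """Worked example: recompute the cross-species shared-miRNA tallies.

    Applies the default sharing rules to the bundled fold-change tables:
    zebrafish must be significant, bichir/axolotl contribute by sign for
    zebrafish-anchored comparisons, and the bichir-axolotl comparison uses
    the strict |log2FC| > 0.58 threshold for both species. Returns counts
    of shared-up / shared-down / total concordant miRNAs across all three
    species, the two zebrafish-anchored pairwise tallies, and the
    bichir-axolotl tally.
    """
    t1 = load_mirna_foldchanges()
    rules3 = {"zebrafish": "significant", "bichir": "sign_only", "axolotl": "sign_only"}
    three = classify_fixture_rows(
        t1[t1["section"] == "all_three"], ("zebrafish", "bichir", "axolotl"), rules3
    )
    zb = classify_fixture_rows(
        t1[t1["section"] == "zebrafish_bichir"],
        ("zebrafish", "bichir"),
        {"zebrafish": "significant", "bichir": "sign_only"},
    )
    za = classify_fixture_rows(
        t1[t1["section"] == "zebrafish_axolotl"],
        ("zebrafish", "axolotl"),
        {"zebrafish": "significant", "axolotl": "sign_only"},
    )
    t2 = load_bichir_axolotl_foldchanges()
    ba = classify_fixture_rows(
        t2, ("bichir", "axolotl"), {"bichir": "threshold", "axolotl": "threshold"}
    )

    def n_shared(calls, verdict=None):
        wanted = ("shared_up", "shared_down") if verdict is None else (verdict,)
        return sum(c.verdict in wanted for c in calls)

    return {
        "three_species_up": n_shared(three, "shared_up"),
        "three_species_down": n_shared(three, "shared_down"),
        "three_species_total": n_shared(three),
        "zebrafish_bichir": n_shared(zb),
        "zebrafish_axolotl": n_shared(za),
        "bichir_axolotl": n_shared(ba),
        "n_three_species_rows": int((t1["section"] == "all_three").sum()),
        "n_zebrafish_bichir_rows": int((t1["section"] == "zebrafish_bichir").sum()),
        "n_zebrafish_axolotl_rows": int((t1["section"] == "zebrafish_axolotl").sum()),
        "n_bichir_axolotl_rows": int(len(t2)),
    }
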