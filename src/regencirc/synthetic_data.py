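"""Synthetic three-species study generator with known ground truth.

Emulates the comparative design the pipeline analyzes: three species with
partially shared mature-miRNA catalogs (one replicated species, two with a
single replicate per group), negative-binomial counts with planted fold
changes shared across species, raw small-RNA reads carrying isomiR and
tRNA/rRNA-fragment contamination, 3'-UTRs with planted seed and
nucleation-bulge sites on an otherwise seed-free background, an ortholog
map, a scored interaction table with designated anchor genes, and a flat
category map for enrichment. Every output is reproducible byte-for-byte
under a fixed seed; sub-generators derive child seeds deterministically
from one seed sequence.

The NB parameterization is mean mu, variance mu + phi * mu^2; phi = 0 is
the Poisson limit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._dna import DNA_ALPHABET, hamming, random_dna, revcomp
from .diffexpr import CountMatrix
from .mirna_annotation import MatureMiRNA, MiRNACatalog
from .target_prediction import canonical_site_scan

SPECIES = ("zebrafish", "bichir", "axolotl")
ANCHOR_SPECIES = "zebrafish"
# Illumina TruSeq small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

MATURE_LEN = 22
READ_LEN = 50
SITE_CLASSES = ("8mer", "7mer-m8", "7mer-A1", "bulge5_6")


class SimulationError(RuntimeError):
    """Raised when a configuration cannot be realized (e.g. alphabet exhaustion)."""


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic generator.

    Defaults mirror the comparative design at desk scale: a catalog-sharing
    structure dominated by triple-shared miRNAs, one species sequenced in
    triplicate per group and two without replication, library sizes of one
    million tags per sample, an effect size of |log2FC| = 2 on planted
    features and NB dispersion 0.1.
    """

    rng_seed: int = 0
    n_shared_mirnas: int = 108
    n_pairwise: int = 16  # per species pair
    n_unique_per_species: int = 16
    n_genes: int = 300
    n_anchor_genes: int = 11
    frac_planted_up: float = 0.12
    frac_planted_down: float = 0.10
    effect_log2fc: float = 2.0
    dispersion: float = 0.1
    lib_sizes: float = 1_000_000.0
    replicate_design: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"zebrafish": (3, 3), "bichir": (1, 1), "axolotl": (1, 1)}
    )
    isomir_rate: float = 0.05
    trf_rate: float = 0.01
    rrf_rate: float = 0.01
    adapter: str = DEFAULT_ADAPTER
    utr_len: int = 300
    sites_per_target: int = 1
    n_target_genes: int = 20
    n_interactions: int = 600
    frac_anchor_edges: float = 0.3
    n_categories: int = 8

    def validate(self) -> None:
        for name in ("isomir_rate", "trf_rate", "rrf_rate", "frac_planted_up",
                     "frac_planted_down", "frac_anchor_edges"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_shared_mirnas", "n_pairwise", "n_unique_per_species",
                     "n_genes", "n_anchor_genes", "utr_len", "n_target_genes",
                     "n_interactions", "n_categories"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.effect_log2fc <= 0:
            raise ValueError("effect_log2fc must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.lib_sizes <= 0:
            raise ValueError("lib_sizes must be > 0")
        if not self.adapter:
            raise ValueError("adapter must be non-empty")
        if self.sites_per_target < 1:
            raise ValueError("sites_per_target must be >= 1")
        if self.n_anchor_genes > self.n_genes:
            raise ValueError("n_anchor_genes cannot exceed n_genes")
        reps = [n for pair in self.replicate_design.values() for n in pair]
        if any(n < 1 for n in reps):
            raise ValueError("every group needs >= 1 replicate")
        if not any(min(pair) >= 2 for pair in self.replicate_design.values()):
            raise ValueError("at least one species needs >= 2 replicates per group")

    def child_rng(self, stream: int) -> np.random.Generator:
        """Deterministic per-stage generator derived from the run seed."""
        return np.random.default_rng(
            np.random.SeedSequence(self.rng_seed).spawn(stream + 1)[stream]
        )


@dataclass
class GroundTruth:
    mirna_membership: dict[str, frozenset[str]] = field(default_factory=dict)
    mirna_sequences: dict[str, str] = field(default_factory=dict)
    planted_direction: dict[str, dict[str, str]] = field(default_factory=dict)
    planted_sites: list[tuple[str, str, int, str]] = field(default_factory=list)
    anchor_genes: set[str] = field(default_factory=set)
    ortholog_map: dict[str, dict[str, str]] = field(default_factory=dict)

    def validate(self, genes: Sequence[str] | None = None) -> None:
        for mirna, _, _, _ in self.planted_sites:
            if mirna not in self.mirna_sequences:
                raise ValueError(f"planted site references unknown miRNA {mirna}")
        if genes is not None:
            universe = set(genes)
            if not self.anchor_genes <= universe:
                raise ValueError("anchor_genes must be a subset of the gene universe")
            for _, gene, _, _ in self.planted_sites:
                if gene not in universe:
                    raise ValueError(f"planted site references unknown gene {gene}")

    def to_json(self, path: str | Path) -> None:
        doc = {
            "mirna_membership": {k: sorted(v) for k, v in self.mirna_membership.items()},
            "mirna_sequences": self.mirna_sequences,
            "planted_direction": self.planted_direction,
            "planted_sites": [list(s) for s in self.planted_sites],
            "anchor_genes": sorted(self.anchor_genes),
            "ortholog_map": self.ortholog_map,
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        doc = json.loads(Path(path).read_text())
        return cls(
            mirna_membership={k: frozenset(v) for k, v in doc["mirna_membership"].items()},
            mirna_sequences=doc["mirna_sequences"],
            planted_direction=doc["planted_direction"],
            planted_sites=[tuple(s) for s in doc["planted_sites"]],
            anchor_genes=set(doc["anchor_genes"]),
            ortholog_map=doc["ortholog_map"],
        )


# ---------------------------------------------------------------------------
# miRNA catalogs

def _draw_seed_set(rng: np.random.Generator, n: int, min_dist: int = 3) -> list[str]:
    """Seeds pairwise differing in >= min_dist positions, by rejection."""
    seeds: list[str] = []
    attempts = 0
    while len(seeds) < n:
        attempts += 1
        if attempts > 200 * max(n, 1):
            raise SimulationError(
                "cannot draw enough mutually distinct seeds (alphabet exhaustion)"
            )
        cand = random_dna(rng, 7)
        if all(hamming(cand, s) >= min_dist for s in seeds):
            seeds.append(cand)
    return seeds


def simulate_catalogs(config: SimConfig) -> tuple[dict[str, MiRNACatalog], GroundTruth]:
    """Three mature-miRNA catalogs with a known sharing structure.

    Shared miRNAs carry identical mature sequences in every member species;
    all seeds differ pairwise in >= 3 positions, so no miRNA masquerades as
    an isomiR of another.
    """
    config.validate()
    rng = config.child_rng(0)
    pairs = [(a, b) for i, a in enumerate(SPECIES) for b in SPECIES[i + 1:]]
    n_total = (
        config.n_shared_mirnas
        + config.n_pairwise * len(pairs)
        + config.n_unique_per_species * len(SPECIES)
    )
    seeds = _draw_seed_set(rng, n_total)
    truth = GroundTruth()
    memberships: list[frozenset[str]] = (
        [frozenset(SPECIES)] * config.n_shared_mirnas
        + [frozenset(p) for p in pairs for _ in range(config.n_pairwise)]
        + [frozenset((sp,)) for sp in SPECIES for _ in range(config.n_unique_per_species)]
    )
    catalogs = {sp: MiRNACatalog(sp, []) for sp in SPECIES}
    for i, (seed, members) in enumerate(zip(seeds, memberships)):
        name = f"mir-s{i + 1:04d}"
        mature = random_dna(rng, 1) + seed + random_dna(rng, MATURE_LEN - 8)
        truth.mirna_membership[name] = members
        truth.mirna_sequences[name] = mature
        for sp in SPECIES:
            if sp in members:
                catalogs[sp].entries.append(MatureMiRNA(name, sp, mature))
    return catalogs, truth


# ---------------------------------------------------------------------------
# planted differential expression and NB counts

def plant_directions(
    features: Sequence[str], config: SimConfig, rng: np.random.Generator
) -> dict[str, str]:
    """Assign up / down / null to features at the configured fractions."""
    n = len(features)
    n_up = int(round(config.frac_planted_up * n))
    n_down = int(round(config.frac_planted_down * n))
    order = list(rng.permutation(n))
    directions = {f: "null" for f in features}
    for i in order[:n_up]:
        directions[features[i]] = "up"
    for i in order[n_up : n_up + n_down]:
        directions[features[i]] = "down"
    return directions


def _nb_draw(
    rng: np.random.Generator, mu: np.ndarray, phi: float
) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if phi == 0.0:
        return rng.poisson(mu)
    r = 1.0 / phi
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_counts(
    features: Sequence[str],
    config: SimConfig,
    directions: Mapping[str, str],
    species: str,
    rng: np.random.Generator | None = None,
    base_abundance: Mapping[str, float] | None = None,
) -> CountMatrix:
    """NB counts for one species' control / regenerating samples.

    Per-feature baseline abundances (lognormal unless supplied) are
    normalized to relative proportions; the case-group mean is the baseline
    scaled by 2^(+-effect_log2fc) for planted features. Expected per-sample
    totals equal the configured library size for the control group.
    """
    config.validate()
    if config.dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if rng is None:
        rng = config.child_rng(1)
    unknown = [f for f in features if f not in directions]
    if unknown:
        raise ValueError(f"features without planted direction: {unknown[:3]}")
    n_ctrl, n_case = config.replicate_design.get(species, (1, 1))
    if base_abundance is None:
        base = pd.Series(
            rng.lognormal(mean=0.0, sigma=1.5, size=len(features)), index=list(features)
        )
    else:
        base = pd.Series({f: base_abundance[f] for f in features})
    rel = base / base.sum()
    mu_ctrl = rel * config.lib_sizes
    factor = pd.Series(1.0, index=mu_ctrl.index)
    for f in features:
        if directions[f] == "up":
            factor[f] = 2.0 ** config.effect_log2fc
        elif directions[f] == "down":
            factor[f] = 2.0 ** -config.effect_log2fc
    mu_case = mu_ctrl * factor
    columns: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    for i in range(n_ctrl):
        name = f"{species}_ctrl_{i + 1}"
        columns[name] = _nb_draw(rng, mu_ctrl.to_numpy(), config.dispersion)
        groups[name] = "ctrl"
    for i in range(n_case):
        name = f"{species}_case_{i + 1}"
        columns[name] = _nb_draw(rng, mu_case.to_numpy(), config.dispersion)
        groups[name] = "case"
    counts = pd.DataFrame(columns, index=pd.Index(list(features), name="feature"))
    # library sizes are the *designed* per-sample depth: planted effects are
    # absolute expression changes, not compositional reallocation, so CPM
    # fold changes estimate the planted factors without composition bias
    libs = pd.Series(float(config.lib_sizes), index=counts.columns)
    return CountMatrix(counts, groups, libs)


# ---------------------------------------------------------------------------
# raw reads with isomiR / tRF / rRF contamination

def make_noncoding_refs(
    config: SimConfig,
    rng: np.random.Generator,
    mirna_sequences: Mapping[str, str],
    n_trna: int = 4,
    trna_len: int = 75,
    n_rrna: int = 4,
    rrna_len: int = 120,
) -> tuple[dict[str, str], dict[str, str]]:
    """Random tRNA / rRNA reference sequences free of catalog collisions."""
    matures = set(mirna_sequences.values())

    def draw(prefix: str, count: int, length: int) -> dict[str, str]:
        out = {}
        for i in range(count):
            for _ in range(100):
                seq = random_dna(rng, length)
                if not any(m in seq for m in matures):
                    break
            else:
                raise SimulationError("cannot draw contaminant references")
            out[f"{prefix}{i + 1}"] = seq
        return out

    return draw("trna-", n_trna, trna_len), draw("rrna-", n_rrna, rrna_len)


def _isomir_variant(tag: str, rng: np.random.Generator) -> str:
    """One isomiR-style variant: 5'/3' shift of 1-3 nt or a substitution at
    a uniformly chosen position (seed-window variants arise naturally)."""
    kind = rng.choice(["5p_shift", "3p_shift", "substitution"])
    if kind == "substitution":
        pos = int(rng.integers(len(tag)))
        alt = rng.choice([b for b in DNA_ALPHABET if b != tag[pos]])
        return tag[:pos] + alt + tag[pos + 1 :]
    shift = int(rng.integers(1, 4))
    extend = bool(rng.integers(2))
    if kind == "5p_shift":
        return (random_dna(rng, shift) + tag) if extend else tag[shift:]
    return (tag + random_dna(rng, shift)) if extend else tag[:-shift]


def simulate_reads(
    tag_counts: Mapping[str, Mapping[str, int]],
    config: SimConfig,
    trna_ref: Mapping[str, str],
    rrna_ref: Mapping[str, str],
    outdir: str | Path,
    rng: np.random.Generator | None = None,
) -> dict[str, Path]:
    """Write one FASTQ per sample from per-sample tag counts.

    Every tag copy is emitted exactly (so collapsing the output recovers
    the input counts); contaminant reads -- isomiR variants at
    ``isomir_rate`` and tRNA / rRNA fragments at ``trf_rate`` /
    ``rrf_rate`` -- are appended on top, per emitted tag read. Reads are
    tag + adapter + random tail, padded to a fixed read length, with
    uniform high qualities (Sanger Phred+33).
    """
    config.validate()
    if rng is None:
        rng = config.child_rng(2)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def frag(ref: Mapping[str, str]) -> str:
        name = rng.choice(sorted(ref))
        seq = ref[name]
        length = int(rng.integers(20, 26))
        start = int(rng.integers(0, len(seq) - length + 1))
        return seq[start : start + length]

    for sample in sorted(tag_counts):
        path = outdir / f"{sample}.fastq"
        with open(path, "w") as handle:
            idx = 0

            def emit(insert: str) -> None:
                nonlocal idx
                idx += 1
                read = insert + config.adapter
                if len(read) < READ_LEN:
                    read += random_dna(rng, READ_LEN - len(read))
                read = read[:READ_LEN]
                handle.write(f"@{sample}:{idx}\n{read}\n+\n{'I' * len(read)}\n")

            for tag in sorted(tag_counts[sample]):
                for _ in range(int(tag_counts[sample][tag])):
                    emit(tag)
                    if config.isomir_rate and rng.random() < config.isomir_rate:
                        emit(_isomir_variant(tag, rng))
                    if config.trf_rate and rng.random() < config.trf_rate:
                        emit(frag(trna_ref))
                    if config.rrf_rate and rng.random() < config.rrf_rate:
                        emit(frag(rrna_ref))
        paths[sample] = path
    return paths


# ---------------------------------------------------------------------------
# 3'-UTRs with planted sites

def _site_string(
    mature: str, site_class: str, rng: np.random.Generator
) -> tuple[str, int, int]:
    """Spliceable site string with guard flanks pinning the site class.

    Returns (string, offset of the class-defining site start within the
    string, site length). 7mer-m8 carries a non-A guard after the match
    (so it cannot read as an 8mer) and 7mer-A1 a guard that cannot pair
    miRNA position 8 before it.
    """
    match7 = revcomp(mature[1:8])
    m8_match = revcomp(mature[7])
    if site_class == "8mer":
        return match7 + "A", 0, 8
    if site_class == "7mer-m8":
        guard = rng.choice([b for b in DNA_ALPHABET if b != "A"])
        return match7 + guard, 0, 7
    if site_class == "7mer-A1":
        guard = rng.choice([b for b in DNA_ALPHABET if b != m8_match])
        return guard + match7[1:] + "A", 1, 7
    if site_class == "6mer":
        guard5 = rng.choice([b for b in DNA_ALPHABET if b != m8_match])
        guard3 = rng.choice([b for b in DNA_ALPHABET if b != "A"])
        return guard5 + match7[1:] + guard3, 1, 6
    if site_class == "bulge5_6":
        base = rng.choice(list(DNA_ALPHABET))
        return match7[:3] + base + match7[3:], 0, 8
    raise ValueError(f"unknown site class {site_class!r}")


def _find_all(seq: str, pattern: str) -> list[int]:
    out, p = [], seq.find(pattern)
    while p != -1:
        out.append(p)
        p = seq.find(pattern, p + 1)
    return out


def _occurrences(seq: str, forbidden: set[str]) -> set[tuple[int, str]]:
    return {(p, pat) for pat in forbidden for p in _find_all(seq, pat)}


def _pure_chunk(
    mature: str,
    site_class: str,
    forbidden: set[str],
    rng: np.random.Generator,
    tries: int = 10,
) -> tuple[str, int] | None:
    """A site chunk whose only forbidden-pattern content is the planted
    site itself -- guaranteeing the scanner reports exactly one site of the
    requested class there. None when no guard choice achieves purity
    (possible when another simulated miRNA's seed core coincides with part
    of the fixed match region)."""
    own_core = revcomp(mature[1:7])
    for _ in range(tries):
        chunk, offset, _ = _site_string(mature, site_class, rng)
        occ = _occurrences(chunk, forbidden)
        if site_class == "bulge5_6":
            if occ == {(0, chunk)}:
                return chunk, offset
        elif occ == {(1, own_core)}:
            return chunk, offset
    return None


def _forbidden_patterns(mirna_sequences: Mapping[str, str]) -> set[str]:
    """Patterns a clean background must avoid: every 6mer seed core and
    every bulge-insertion pattern of every simulated miRNA."""
    patterns: set[str] = set()
    for mature in mirna_sequences.values():
        match7 = revcomp(mature[1:8])
        patterns.add(match7[1:])  # 6mer core (positions 2-7)
        for base in DNA_ALPHABET:
            patterns.add(match7[:3] + base + match7[3:])
    return patterns


def _clean_background(
    rng: np.random.Generator, length: int, forbidden: set[str], max_tries: int = 500
) -> str:
    for _ in range(max_tries):
        seq = random_dna(rng, length)
        if not any(p in seq for p in forbidden):
            return seq
    raise SimulationError("cannot sample a seed-free background UTR")


def simulate_utrs(
    genes: Sequence[str],
    config: SimConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
    target_plan: Mapping[str, list[tuple[str, str]]] | None = None,
) -> dict[str, str]:
    """3'-UTRs with exactly the planted sites and a seed-free background.

    ``target_plan`` maps a gene to (mirna, site_class) requests; by default
    the planted-down anchor-species genes receive ``sites_per_target``
    sites of planted-up miRNAs and planted-up genes sites of planted-down
    miRNAs, cycling through site classes. Planted sites are recorded in
    ``truth.planted_sites`` as (mirna, gene, 0-based position, class).
    """
    config.validate()
    if rng is None:
        rng = config.child_rng(3)
    if target_plan is None:
        target_plan = _default_target_plan(genes, config, truth, rng)
    forbidden = _forbidden_patterns(truth.mirna_sequences)
    longest_site = 9
    utrs: dict[str, str] = {}
    for gene in genes:
        requests = target_plan.get(gene, [])
        need = len(requests) * (longest_site + 2)
        if config.utr_len < max(8, need):
            raise SimulationError(
                f"utr_len={config.utr_len} too short for {len(requests)} sites in {gene}"
            )
        for _ in range(200):
            seq = _clean_background(rng, config.utr_len, forbidden)
            placed: list[tuple[str, str, int, str]] = []
            occupied: list[tuple[int, int]] = []
            expected: set[tuple[int, str]] = set()
            ok = True
            for mirna, site_class in requests:
                pure = _pure_chunk(
                    truth.mirna_sequences[mirna], site_class, forbidden, rng
                )
                if pure is None:
                    continue  # unplaceable without spurious hits; drop request
                chunk, offset = pure
                pos = None
                for _ in range(50):
                    cand = int(rng.integers(0, config.utr_len - len(chunk) + 1))
                    if all(
                        cand + len(chunk) <= s or cand >= e for s, e in occupied
                    ):
                        pos = cand
                        break
                if pos is None:
                    ok = False
                    break
                seq = seq[:pos] + chunk + seq[pos + len(chunk) :]
                occupied.append((pos, pos + len(chunk)))
                expected |= {
                    (pos + q, pat) for (q, pat) in _occurrences(chunk, forbidden)
                }
                placed.append((mirna, gene, pos + offset, site_class))
            # exactness: the only forbidden-pattern occurrences anywhere in
            # the UTR must be those contributed by the planted chunks
            if ok and _occurrences(seq, forbidden) == expected:
                utrs[gene] = seq
                truth.planted_sites.extend(placed)
                break
        else:
            raise SimulationError(f"cannot place requested sites in {gene}")
    return utrs


def _default_target_plan(
    genes: Sequence[str],
    config: SimConfig,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> dict[str, list[tuple[str, str]]]:
    directions = truth.planted_direction.get(ANCHOR_SPECIES, {})
    up_mirnas = sorted(
        m
        for m, members in truth.mirna_membership.items()
        if members == frozenset(SPECIES)
        and truth.planted_direction.get("mirna:" + ANCHOR_SPECIES, {}).get(m) == "up"
    )
    down_mirnas = sorted(
        m
        for m, members in truth.mirna_membership.items()
        if members == frozenset(SPECIES)
        and truth.planted_direction.get("mirna:" + ANCHOR_SPECIES, {}).get(m) == "down"
    )
    down_genes = [g for g in genes if directions.get(g) == "down"]
    up_genes = [g for g in genes if directions.get(g) == "up"]
    plan: dict[str, list[tuple[str, str]]] = {}
    half = max(1, config.n_target_genes // 2)
    k = 0
    for gene_pool, mirna_pool in ((down_genes[:half], up_mirnas), (up_genes[:half], down_mirnas)):
        if not mirna_pool:
            continue
        for gene in gene_pool:
            plan[gene] = []
            for _ in range(config.sites_per_target):
                plan[gene].append(
                    (mirna_pool[k % len(mirna_pool)], SITE_CLASSES[k % len(SITE_CLASSES)])
                )
                k += 1
    return plan


# ---------------------------------------------------------------------------
# interactions, orthologs, categories

def simulate_interactions(
    genes: Sequence[str],
    anchors: Sequence[str],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Undirected scored interaction table (gene_a, gene_b, score in (0, 1000]).

    No self-edges, no duplicate unordered pairs; ``frac_anchor_edges`` of
    the edges touch at least one anchor gene.
    """
    config.validate()
    if rng is None:
        rng = config.child_rng(4)
    anchors = list(anchors)
    if not set(anchors) <= set(genes):
        raise ValueError("anchors must be a subset of genes")
    non_anchors = [g for g in genes if g not in set(anchors)]
    n_anchor_edges = int(round(config.frac_anchor_edges * config.n_interactions))
    seen: set[frozenset] = set()
    rows = []

    def add_edge(a: str, b: str) -> bool:
        key = frozenset((a, b))
        if a == b or key in seen:
            return False
        seen.add(key)
        score = float(np.round((1.0 - rng.random()) * 1000.0, 3))  # in (0, 1000]
        rows.append({"gene_a": a, "gene_b": b, "score": score})
        return True

    guard = 0
    while len(rows) < n_anchor_edges:
        guard += 1
        if guard > 100 * config.n_interactions + 1000:
            raise SimulationError("cannot place anchor-touching edges")
        a = anchors[int(rng.integers(len(anchors)))]
        b = genes[int(rng.integers(len(genes)))]
        add_edge(a, b)
    while len(rows) < config.n_interactions:
        guard += 1
        if guard > 200 * config.n_interactions + 1000:
            raise SimulationError("cannot place background edges")
        pool = non_anchors if non_anchors else list(genes)
        a = pool[int(rng.integers(len(pool)))]
        b = pool[int(rng.integers(len(pool)))]
        add_edge(a, b)
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"])


def make_ortholog_map(
    genes: Sequence[str], rng: np.random.Generator, frac_mapped: float = 0.95
) -> dict[str, dict[str, str]]:
    """Per-species transcript ids for anchor genes (1:1 for most genes)."""
    prefixes = {"bichir": "bi_t", "axolotl": "ax_t"}
    n_mapped = int(round(frac_mapped * len(genes)))
    mapped = sorted(rng.choice(list(genes), size=n_mapped, replace=False))
    out: dict[str, dict[str, str]] = {sp: {} for sp in prefixes}
    for sp, prefix in prefixes.items():
        for i, gene in enumerate(mapped):
            out[sp][f"{prefix}{i + 1:05d}"] = gene
    return out


def make_categories(
    genes: Sequence[str],
    truth: GroundTruth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, set[str]]:
    """Flat category->genes map; the first category is enriched for
    planted-up genes so enrichment has a true positive to find."""
    if rng is None:
        rng = config.child_rng(5)
    directions = truth.planted_direction.get(ANCHOR_SPECIES, {})
    up_genes = [g for g in genes if directions.get(g) == "up"]
    categories: dict[str, set[str]] = {}
    if up_genes:
        extra = rng.choice(list(genes), size=min(10, len(genes)), replace=False)
        categories["CAT:0001"] = set(up_genes) | set(extra)
    for i in range(2, config.n_categories + 1):
        size = int(rng.integers(10, max(11, len(genes) // 5)))
        members = rng.choice(list(genes), size=min(size, len(genes)), replace=False)
        categories[f"CAT:{i:04d}"] = set(members)
    return categories


# ---------------------------------------------------------------------------
# whole-study convenience

@dataclass
class SimulatedStudy:
    config: SimConfig
    truth: GroundTruth
    catalogs: dict[str, MiRNACatalog]
    mirna_counts: dict[str, CountMatrix]
    gene_counts: dict[str, CountMatrix]
    utrs: dict[str, str]
    interactions: pd.DataFrame
    categories: dict[str, set[str]]
    trna_ref: dict[str, str]
    rrna_ref: dict[str, str]
    genes: list[str]


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Generate every pipeline input (except raw reads) with shared truth.

    Planted fold-change directions are concordant across species for
    triple-shared miRNAs and for orthologous genes, mirroring conserved
    regulation during blastema formation.
    """
    config.validate()
    catalogs, truth = simulate_catalogs(config)
    rng = config.child_rng(1)
    shared = sorted(
        m for m, members in truth.mirna_membership.items() if members == frozenset(SPECIES)
    )
    shared_dirs = plant_directions(shared, config, rng)
    mirna_counts: dict[str, CountMatrix] = {}
    for sp in SPECIES:
        names = [e.name for e in catalogs[sp]]
        dirs = {n: shared_dirs.get(n, "null") for n in names}
        truth.planted_direction[f"mirna:{sp}"] = dirs
        mirna_counts[sp] = simulate_counts(names, config, dirs, sp, rng)

    genes = [f"zf_g{i + 1:05d}" for i in range(config.n_genes)]
    gene_dirs = plant_directions(genes, config, rng)
    truth.planted_direction[ANCHOR_SPECIES] = gene_dirs
    anchors = sorted(
        rng.choice(
            [g for g in genes if gene_dirs[g] != "null"] or genes,
            size=config.n_anchor_genes,
            replace=False,
        )
    )
    truth.anchor_genes = set(anchors)
    truth.ortholog_map = make_ortholog_map(genes, rng)
    gene_counts: dict[str, CountMatrix] = {}
    gene_counts[ANCHOR_SPECIES] = simulate_counts(genes, config, gene_dirs, ANCHOR_SPECIES, rng)
    for sp in SPECIES:
        if sp == ANCHOR_SPECIES:
            continue
        transcripts = sorted(truth.ortholog_map[sp])
        dirs = {t: gene_dirs[truth.ortholog_map[sp][t]] for t in transcripts}
        truth.planted_direction[sp] = dirs
        gene_counts[sp] = simulate_counts(transcripts, config, dirs, sp, rng)

    utrs = simulate_utrs(genes, config, truth)
    interactions = simulate_interactions(genes, anchors, config)
    categories = make_categories(genes, truth, config)
    trna_ref, rrna_ref = make_noncoding_refs(
        config, config.child_rng(6), truth.mirna_sequences
    )
    truth.validate(genes)
    return SimulatedStudy(
        config=config,
        truth=truth,
        catalogs=catalogs,
        mirna_counts=mirna_counts,
        gene_counts=gene_counts,
        utrs=utrs,
        interactions=interactions,
        categories=categories,
        trna_ref=trna_ref,
        rrna_ref=rrna_ref,
        genes=genes,
    )
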