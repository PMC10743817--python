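"""Self-consistent synthetic annotation world with planted ground truth.

The generator emulates the statistical structure the gene-prioritization
cascade assumes: a small set of literature-like *seed* genes that are
evolutionarily constrained, broadly expressed, mutually interacting and
co-annotated to one pathway; a block of *planted candidate* genes that
share all of those properties; four *decoy* blocks, each engineered to
fail exactly one cascade stage; and a *background* of genes drawn from
the unconstrained part of the LOEUF mixture (truncated above the seed
median, so they deterministically fail the constraint stage). Random
gene sets never sample seed, planted or stage-4-decoy genes, which makes
the planted pathway the only enriched set and the per-stage survivor
sets exact by construction.

Every random draw flows through one ``numpy.random.Generator`` stream
created from ``rng_seed``; metric values are rounded at generation time
(LOEUF/pLI to 4 decimals, TPM to 3), so the in-memory world, the emitted
files and re-loaded resources agree bit-for-bit and repeated runs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalogue import CatalogueRecord, Outcome, write_catalogue
from .resources import (
    ConstraintMap,
    DiseaseMap,
    ExpressionMatrix,
    GeneConstraint,
    GeneSetCollection,
    InteractionNetwork,
    write_constraint,
    write_disease_map,
    write_expression_matrix,
    write_gmt,
    write_network,
)

_ROUND_LOEUF = 4
_ROUND_TPM = 3


class ConfigError(ValueError):
    """The world configuration is internally inconsistent."""


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of the synthetic annotation world.

    The defaults describe the desk-scale study condition used throughout
    the test suite: a 2000-gene universe, 18 seed genes, 10 planted
    candidates and 50 decoys per cascade stage.
    """

    n_genes: int = 2000
    n_tissues: int = 30
    n_seed_genes: int = 18
    n_planted_candidates: int = 10
    n_decoys_per_stage: int = 50

    # LOEUF mixture: constrained component (seeds, planted, most decoys)
    # versus unconstrained component (background, constraint decoys).
    constrained_loeuf_mean: float = 0.35
    constrained_loeuf_sd: float = 0.12
    unconstrained_loeuf_mean: float = 1.1
    unconstrained_loeuf_sd: float = 0.25
    loeuf_floor: float = 0.02
    pli_noise_sd: float = 0.03

    # Expression model: log-normal TPM around a per-gene target median.
    seed_tpm_median: float = 25.0
    tpm_log_sd: float = 0.5
    background_expressed_tpm: float = 5.0
    background_silent_tpm: float = 0.05

    # Network and pathway models.
    network_edge_prob: float = 0.002
    n_gene_sets: int = 40
    set_size_min: int = 20
    set_size_max: int = 80
    planted_set_name: str = "DEVELOPMENTAL_CORE_SIGNALING"
    seed_membership_prob: float = 0.9
    n_background_in_planted_set: int = 20
    dev_keyword_prob: float = 0.3

    # Disease model.
    f_known: float = 0.5
    seed_disease_prob: float = 0.8
    background_disease_prob: float = 0.1

    # Seed catalogue model.
    multi_study_fraction: float = 0.4
    n_studies: int = 12
    mean_extra_records: float = 0.8
    compound_het_prob: float = 0.15
    n_catalogue_records: int | None = None
    outcome_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "miscarriage": 0.45,
            "termination": 0.25,
            "fetal_demise": 0.10,
            "stillbirth": 0.08,
            "rpl": 0.06,
            "neonatal_death": 0.04,
            "fetal_death": 0.02,
        }
    )
    origin_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "inherited": 0.50,
            "de_novo": 0.15,
            "uncertain": 0.15,
            "unknown": 0.20,
        }
    )

    rng_seed: int = 0

    def validate(self) -> None:
        planted_total = (
            self.n_seed_genes
            + self.n_planted_candidates
            + 4 * self.n_decoys_per_stage
        )
        if self.n_seed_genes < 2:
            raise ConfigError("need at least 2 seed genes")
        if self.n_planted_candidates < 0 or self.n_decoys_per_stage < 0:
            raise ConfigError("block sizes must be non-negative")
        if planted_total > self.n_genes:
            raise ConfigError(
                f"seeds + planted + decoys ({planted_total}) exceed the "
                f"universe size ({self.n_genes})"
            )
        if self.n_tissues < 1:
            raise ConfigError("need at least one tissue")
        if not 0 < self.set_size_min <= self.set_size_max:
            raise ConfigError("invalid gene-set size band")
        for name in (
            "seed_membership_prob",
            "dev_keyword_prob",
            "f_known",
            "seed_disease_prob",
            "background_disease_prob",
            "multi_study_fraction",
            "compound_het_prob",
            "network_edge_prob",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name}={value} outside [0, 1]")
        for probs_name in ("outcome_probs", "origin_probs"):
            probs = getattr(self, probs_name)
            if not probs or any(p < 0 for p in probs.values()):
                raise ConfigError(f"{probs_name} must be non-empty and non-negative")
            if sum(probs.values()) <= 0:
                raise ConfigError(f"{probs_name} must have positive mass")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, stage by stage."""

    seeds: tuple[str, ...]
    planted: tuple[str, ...]
    loeuf_max: float
    tpm_min: float
    expected_stages: tuple[tuple[str, tuple[str, ...]], ...]
    seed_overlap: tuple[str, ...]
    candidates: tuple[str, ...]
    known: tuple[str, ...]
    novel: tuple[str, ...]
    planted_set_name: str

    @property
    def expected_stage_counts(self) -> dict[str, int]:
        return {label: len(genes) for label, genes in self.expected_stages}


@dataclass(frozen=True)
class World:
    """In-memory synthetic world: all resources plus the ground truth."""

    config: WorldConfig
    genes: tuple[str, ...]
    constraint: ConstraintMap
    expression: ExpressionMatrix
    network: InteractionNetwork
    collection: GeneSetCollection
    disease_map: DiseaseMap
    catalogue: tuple[CatalogueRecord, ...]
    ground_truth: GroundTruth


@dataclass(frozen=True)
class SyntheticWorld:
    """File layout of an emitted world."""

    outdir: Path
    paths: Mapping[str, Path]
    world: World

    @property
    def ground_truth(self) -> GroundTruth:
        return self.world.ground_truth


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def _truncated_normal(
    rng: np.random.Generator,
    n: int,
    mean: float,
    sd: float,
    low: float = -np.inf,
    high: float = np.inf,
) -> np.ndarray:
    """Rejection-sample ``n`` normals restricted to (low, high)."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=max(n - filled, 16))
        keep = draw[(draw > low) & (draw < high)]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def _pli_from_loeuf(
    rng: np.random.Generator, loeuf: np.ndarray, noise_sd: float
) -> np.ndarray:
    """Monotone decreasing logistic transform of LOEUF plus noise."""
    base = 1.0 / (1.0 + np.exp((loeuf - 0.45) / 0.08))
    noisy = base + rng.normal(0.0, noise_sd, size=loeuf.shape)
    return np.clip(np.round(noisy, _ROUND_LOEUF), 0.0, 1.0)


def _scaled_profile(
    rng: np.random.Generator, n_tissues: int, target_median: float, log_sd: float
) -> np.ndarray:
    """Log-normal tissue profile rescaled to an exact target median."""
    raw = np.exp(rng.normal(0.0, log_sd, size=n_tissues))
    scaled = raw * (target_median / np.median(raw))
    return np.round(scaled, _ROUND_TPM)


def _normalized(probs: Mapping[str, float]) -> tuple[list[str], np.ndarray]:
    labels = list(probs)
    weights = np.asarray([probs[k] for k in labels], dtype=float)
    return labels, weights / weights.sum()


def _make_catalogue(
    config: WorldConfig, seeds: Sequence[str], rng: np.random.Generator
) -> list[CatalogueRecord]:
    outcome_labels, outcome_p = _normalized(config.outcome_probs)
    origin_labels, origin_p = _normalized(config.origin_probs)
    variant_counter = 0

    def next_variants() -> tuple[str, ...]:
        nonlocal variant_counter
        n = 2 if rng.random() < config.compound_het_prob else 1
        out = []
        for _ in range(n):
            variant_counter += 1
            out.append(f"c.{variant_counter * 3 + 1}A>G")
        return tuple(out)

    def make_record(gene: str, study: str) -> CatalogueRecord:
        outcome = Outcome(rng.choice(outcome_labels, p=outcome_p))
        return CatalogueRecord(
            gene=gene,
            variants=next_variants(),
            origin=str(rng.choice(origin_labels, p=origin_p)),
            outcome=outcome,
            recurrent=True if outcome is Outcome.RPL else None,
            study_id=study,
        )

    records: list[CatalogueRecord] = []
    if config.n_catalogue_records is not None:
        for _ in range(config.n_catalogue_records):
            gene = str(rng.choice(list(seeds)))
            study = f"STUDY{rng.integers(config.n_studies):03d}"
            records.append(make_record(gene, study))
        return records

    n_multi = int(round(config.multi_study_fraction * len(seeds)))
    order = rng.permutation(len(seeds))
    multi_study = {seeds[i] for i in order[:n_multi]}
    for gene in seeds:
        n_records = 1 + int(rng.poisson(config.mean_extra_records))
        studies = [f"STUDY{rng.integers(config.n_studies):03d}" for _ in range(max(n_records, 2))]
        if gene in multi_study:
            n_records = max(n_records, 2)
            while studies[1] == studies[0]:
                studies[1] = f"STUDY{rng.integers(config.n_studies):03d}"
        else:
            studies = [studies[0]] * n_records
        for i in range(n_records):
            records.append(make_record(gene, studies[i]))
    return records


# ---------------------------------------------------------------------------
# World construction
# ---------------------------------------------------------------------------

def build_world(config: WorldConfig) -> World:
    """Construct the in-memory world; fully reproducible from ``rng_seed``."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    seeds = [f"SEED{i:03d}" for i in range(config.n_seed_genes)]
    planted = [f"CAND{i:03d}" for i in range(config.n_planted_candidates)]
    dec_constraint = [f"DECC{i:03d}" for i in range(config.n_decoys_per_stage)]
    dec_expression = [f"DECE{i:03d}" for i in range(config.n_decoys_per_stage)]
    dec_ppi = [f"DECP{i:03d}" for i in range(config.n_decoys_per_stage)]
    dec_pathway = [f"DECW{i:03d}" for i in range(config.n_decoys_per_stage)]
    n_background = config.n_genes - config.n_seed_genes - len(planted) - 4 * config.n_decoys_per_stage
    background = [f"BG{i:05d}" for i in range(n_background)]
    genes = seeds + planted + dec_constraint + dec_expression + dec_ppi + dec_pathway + background

    # --- constraint -------------------------------------------------------
    seed_loeuf = np.round(
        _truncated_normal(
            rng, len(seeds), config.constrained_loeuf_mean,
            config.constrained_loeuf_sd, low=config.loeuf_floor,
        ),
        _ROUND_LOEUF,
    )
    loeuf_max = float(np.median(seed_loeuf))

    pass_genes = planted + dec_expression + dec_ppi + dec_pathway
    pass_loeuf = np.round(
        _truncated_normal(
            rng, len(pass_genes), config.constrained_loeuf_mean,
            config.constrained_loeuf_sd, low=config.loeuf_floor,
            high=loeuf_max - 10 ** (-_ROUND_LOEUF),
        ),
        _ROUND_LOEUF,
    )
    fail_genes = dec_constraint + background
    fail_loeuf = np.round(
        _truncated_normal(
            rng, len(fail_genes), config.unconstrained_loeuf_mean,
            config.unconstrained_loeuf_sd,
            low=loeuf_max + 10 ** (-_ROUND_LOEUF),
        ),
        _ROUND_LOEUF,
    )
    loeuf = dict(zip(seeds, seed_loeuf))
    loeuf.update(zip(pass_genes, pass_loeuf))
    loeuf.update(zip(fail_genes, fail_loeuf))
    loeuf_array = np.asarray([loeuf[g] for g in genes])
    pli_array = _pli_from_loeuf(rng, loeuf_array, config.pli_noise_sd)
    constraint: ConstraintMap = {
        g: GeneConstraint(gene=g, pli=float(p), loeuf=float(l))
        for g, p, l in zip(genes, pli_array, loeuf_array)
    }

    # --- expression -------------------------------------------------------
    tissues = [f"TISSUE{i:02d}" for i in range(config.n_tissues)]
    rows: dict[str, np.ndarray] = {}
    for gene in seeds:
        target = config.seed_tpm_median * float(np.exp(rng.normal(0.0, 0.4)))
        rows[gene] = _scaled_profile(rng, config.n_tissues, target, config.tpm_log_sd)
    tpm_min = float(np.median([np.median(rows[g]) for g in seeds]))

    for gene in planted + dec_constraint + dec_ppi + dec_pathway:
        target = tpm_min * float(rng.uniform(1.3, 2.5))
        rows[gene] = _scaled_profile(rng, config.n_tissues, target, 0.4)
    for gene in dec_expression:
        target = tpm_min * float(rng.uniform(0.2, 0.7))
        rows[gene] = _scaled_profile(rng, config.n_tissues, target, 0.4)
    for gene in background:
        expressed = rng.random(config.n_tissues) < rng.uniform(0.1, 0.9)
        values = np.where(
            expressed,
            config.background_expressed_tpm * np.exp(rng.normal(0, 1, config.n_tissues)),
            config.background_silent_tpm * np.exp(rng.normal(0, 0.8, config.n_tissues)),
        )
        rows[gene] = np.round(values, _ROUND_TPM)
    expression = ExpressionMatrix(
        pd.DataFrame([rows[g] for g in genes], index=genes, columns=tissues)
    )

    # --- network ----------------------------------------------------------
    edges: set[tuple[str, str]] = set()

    def add_edge(a: str, b: str) -> None:
        if a != b:
            edges.add((min(a, b), max(a, b)))

    for i, gene in enumerate(seeds):
        add_edge(gene, seeds[(i + 1) % len(seeds)])
    for gene in planted + dec_constraint + dec_expression + dec_pathway:
        add_edge(gene, seeds[int(rng.integers(len(seeds)))])
    seed_set = frozenset(seeds)
    no_seed_adjacency = frozenset(dec_ppi)
    if background:
        for gene in dec_ppi:
            for _ in range(int(rng.integers(1, 3))):
                add_edge(gene, background[int(rng.integers(len(background)))])
    n_random = int(round(config.network_edge_prob * config.n_genes * (config.n_genes - 1) / 2))
    if n_random:
        idx_a = rng.integers(0, config.n_genes, size=2 * n_random)
        idx_b = rng.integers(0, config.n_genes, size=2 * n_random)
        added = 0
        for ia, ib in zip(idx_a, idx_b):
            if added >= n_random:
                break
            a, b = genes[ia], genes[ib]
            if a == b:
                continue
            # never wire a PPI-stage decoy to a seed
            if (a in no_seed_adjacency and b in seed_set) or (
                b in no_seed_adjacency and a in seed_set
            ):
                continue
            add_edge(a, b)
            added += 1
    network = InteractionNetwork(sorted(edges))

    # --- gene sets --------------------------------------------------------
    planted_members: set[str] = set(planted)
    planted_members.update(
        g for g in seeds if rng.random() < config.seed_membership_prob
    )
    planted_members.update(dec_constraint)
    planted_members.update(dec_expression)
    planted_members.update(dec_ppi)
    if background and config.n_background_in_planted_set:
        take = min(config.n_background_in_planted_set, len(background))
        picks = rng.choice(len(background), size=take, replace=False)
        planted_members.update(background[i] for i in picks)

    dev_words = ["DEVELOPMENT", "MORPHOGENESIS", "FORMATION"]
    neutral_words = ["SIGNALING", "METABOLISM", "TRANSPORT", "BINDING", "ADHESION"]
    pool = background + dec_constraint + dec_expression + dec_ppi
    sets: dict[str, frozenset[str]] = {
        config.planted_set_name: frozenset(planted_members)
    }
    for i in range(config.n_gene_sets - 1):
        word = (
            dev_words[int(rng.integers(len(dev_words)))]
            if rng.random() < config.dev_keyword_prob
            else neutral_words[int(rng.integers(len(neutral_words)))]
        )
        size = int(rng.integers(config.set_size_min, config.set_size_max + 1))
        size = min(size, len(pool))
        picks = rng.choice(len(pool), size=size, replace=False)
        sets[f"PATHWAY_{i:03d}_{word}"] = frozenset(pool[j] for j in picks)
    collection = GeneSetCollection(name="SYNTH_SETS", sets=sets)

    # --- disease map ------------------------------------------------------
    disease_map: dict[str, frozenset[str]] = {}
    known_planted: list[str] = []
    disease_counter = 0

    def add_disease(gene: str) -> None:
        nonlocal disease_counter
        disease_counter += 1
        disease_map[gene] = frozenset({f"OMIM:6{disease_counter:05d}"})

    for gene in planted:
        if rng.random() < config.f_known:
            add_disease(gene)
            known_planted.append(gene)
    for gene in seeds:
        if rng.random() < config.seed_disease_prob:
            add_disease(gene)
    for gene in background:
        if rng.random() < config.background_disease_prob:
            add_disease(gene)

    # --- seed catalogue ---------------------------------------------------
    catalogue = _make_catalogue(config, seeds, rng)

    # --- ground truth (independent recount over the constructed arrays) ---
    adjacency: dict[str, set[str]] = {}
    for a, b in edges:
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)

    stage1 = [g for g in genes if loeuf[g] < loeuf_max]
    stage2 = [g for g in stage1 if float(np.median(rows[g])) >= tpm_min]
    stage3 = [g for g in stage2 if adjacency.get(g, set()) & (seed_set - {g})]
    stage4 = [g for g in stage3 if g in planted_members]
    seed_overlap = sorted(set(stage4) & seed_set)
    candidates = sorted(set(stage4) - seed_set)
    if set(candidates) != set(planted):
        raise AssertionError(
            "world construction broken: cascade survivors != planted candidates"
        )
    known = sorted(known_planted)
    novel = sorted(set(planted) - set(known))

    ground_truth = GroundTruth(
        seeds=tuple(seeds),
        planted=tuple(planted),
        loeuf_max=loeuf_max,
        tpm_min=tpm_min,
        expected_stages=(
            ("constraint", tuple(sorted(stage1))),
            ("expression", tuple(sorted(stage2))),
            ("ppi", tuple(sorted(stage3))),
            ("pathway", tuple(sorted(stage4))),
        ),
        seed_overlap=tuple(seed_overlap),
        candidates=tuple(candidates),
        known=tuple(known),
        novel=tuple(novel),
        planted_set_name=config.planted_set_name,
    )
    return World(
        config=config,
        genes=tuple(genes),
        constraint=constraint,
        expression=expression,
        network=network,
        collection=collection,
        disease_map=disease_map,
        catalogue=tuple(catalogue),
        ground_truth=ground_truth,
    )


def generate_world(config: WorldConfig, outdir: str | Path) -> SyntheticWorld:
    """Build a world and emit every resource file plus the ground truth."""
    world = build_world(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "constraint": outdir / "constraint.tsv",
        "expression": outdir / "expression.tsv",
        "network": outdir / "network.tsv",
        "gene_sets": outdir / "sets.gmt",
        "disease_map": outdir / "disease.tsv",
        "catalogue": outdir / "catalogue.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_constraint(world.constraint, paths["constraint"])
    write_expression_matrix(world.expression, paths["expression"])
    write_network(world.network, paths["network"])
    write_gmt(world.collection, paths["gene_sets"])
    write_disease_map(world.disease_map, paths["disease_map"])
    write_catalogue(world.catalogue, paths["catalogue"])
    gt = world.ground_truth
    payload = {
        "seeds": list(gt.seeds),
        "planted": list(gt.planted),
        "loeuf_max": gt.loeuf_max,
        "tpm_min": gt.tpm_min,
        "expected_stage_counts": gt.expected_stage_counts,
        "expected_stages": {label: list(genes) for label, genes in gt.expected_stages},
        "seed_overlap": list(gt.seed_overlap),
        "candidates": list(gt.candidates),
        "known": list(gt.known),
        "novel": list(gt.novel),
        "planted_set_name": gt.planted_set_name,
        "config": {
            k: (dict(v) if isinstance(v, Mapping) else v)
            for k, v in dataclasses.asdict(config).items()
        },
    }
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return SyntheticWorld(outdir=outdir, paths=paths, world=world)


def load_ground_truth(path: str | Path) -> dict:
    """Read back a serialized ground-truth file."""
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
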