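"""Synthetic genomes, paralog tables, expression matrices and feature tables.

The generator plants the structure the downstream analysis assumes, so every
stage is testable without external genome resources:

* ohnolog (WGD) families laid out as anchor chains of at least three linking
  pairs between paired macrosynteny segments, with inter-anchor gaps of at
  most eight genes, so the synteny-block caller can recover them exactly;
* retroduplicated pairs built by copying a multi-intron parent to a random
  location with zero introns (no surrounding microsynteny by construction);
* SSD families with duplication nodes strictly inside the vertebrate
  lineage, placed outside synteny segments;
* singletons, optionally including genes whose only paralogy predates the
  vertebrate ancestor;
* per-class feature distributions with configurable location shifts, an
  optional age confound of configurable strength, and a TPM expression
  matrix with broad/high expression for WGD genes and narrow expression for
  SSD genes.

Everything is deterministic given the config seed; the three ohnolog
replicate sets perturb only WGD membership, emulating disagreement between
independently derived ohnolog data sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .features import DEFAULT_NODE_AGES, assign_duplicate_age

# stream keys keeping the genome / replicate / feature draws independent
_GENOME_STREAM = 0
_REPLICATE_STREAM = 1
_FEATURE_STREAM = 2

WGD = "WGD"
SSD = "SSD"
SINGLETON = "SINGLETON"
RETRO_EXCLUDED = "RETRO_EXCLUDED"

_CLASSES = (WGD, SSD, SINGLETON, RETRO_EXCLUDED)


class SizingError(ValueError):
    """Requested layout does not fit the configured genome."""


@dataclass
class FeatureSpec:
    """Distribution of one feature, per true duplicate class.

    ``locations`` gives the per-class location on the latent normal scale
    (missing classes default to 0); draws are ``location + scale * z`` with
    ``z`` standard normal, optionally mixed with standardized duplicate age
    at the configured confound strength.  ``distribution`` is ``normal`` or
    ``lognormal`` (the latter exponentiates the latent draw).

    Features naming the same ``latent`` share a common standard-normal
    factor with weight ``loading`` (correlation ``loading**2`` between two
    group members); ``loading=1`` with identical locations/scale makes
    exact copies, emulating fully collinear feature groups.
    """

    distribution: str = "normal"
    locations: dict[str, float] = field(default_factory=dict)
    scale: float = 1.0
    age_confounded: bool = False
    latent: str | None = None
    loading: float = 0.9

    def validate(self, name: str) -> None:
        if self.distribution not in ("normal", "lognormal"):
            raise ValueError(
                f"feature {name!r}: unknown distribution family {self.distribution!r}"
            )
        if not all(math.isfinite(v) for v in self.locations.values()):
            raise ValueError(f"feature {name!r}: non-finite class location")
        if not (self.scale > 0 and math.isfinite(self.scale)):
            raise ValueError(f"feature {name!r}: scale must be positive and finite")
        if not (0.0 <= self.loading <= 1.0):
            raise ValueError(f"feature {name!r}: loading must lie in [0, 1]")


@dataclass
class ExpressionSpec:
    """Per-class expression profile: breadth range and log-TPM level."""

    min_tissues: int = 1
    max_tissues: int = 1
    log_mean: float = 2.0
    log_sd: float = 0.8


def default_feature_specs() -> dict[str, FeatureSpec]:
    """Feature set mirroring the reported class structure.

    WGD genes are longer, have more (unique) domains and isoforms, evolve
    more slowly and carry stronger dosage constraint (higher pLI/Phi,
    higher missense Z, lower RVIS); SSD genes sit at the other extreme with
    singletons mostly intermediate.  ``cai`` is a planted age-only feature:
    no class shift, but correlated with duplicate age at the configured
    confound strength.
    """
    L = lambda w, s, g, r=None: {  # noqa: E731 - compact per-class locations
        WGD: w, SSD: s, SINGLETON: g, RETRO_EXCLUDED: s if r is None else r
    }
    return {
        "genomic_length": FeatureSpec("lognormal", L(10.8, 9.8, 10.3), 0.8),
        "cds_length": FeatureSpec("lognormal", L(7.6, 7.1, 7.35), 0.5),
        "mean_intron_length": FeatureSpec("lognormal", L(7.8, 7.0, 7.4), 0.9),
        "intron_coverage": FeatureSpec("normal", L(0.9, 0.55, 0.7), 0.18),
        "domains": FeatureSpec("lognormal", L(1.6, 1.0, 1.3), 0.6),
        "unique_domains": FeatureSpec("lognormal", L(1.2, 0.5, 0.85), 0.5),
        "dnds": FeatureSpec("lognormal", L(-1.9, -1.2, -1.55), 0.6),
        "pli": FeatureSpec("normal", L(0.65, 0.25, 0.4), 0.3),
        "phi": FeatureSpec("normal", L(0.7, 0.4, 0.5), 0.2),
        "missense_z": FeatureSpec("normal", L(1.8, 0.4, 1.0), 1.2),
        "rvis": FeatureSpec("normal", L(-0.8, 0.3, -0.2), 1.0),
        "isoform_count": FeatureSpec("lognormal", L(1.7, 1.0, 1.4), 0.5),
        "regulatory_motifs": FeatureSpec("lognormal", L(2.4, 2.0, 2.1), 0.6),
        "ppis": FeatureSpec("lognormal", L(2.2, 1.8, 2.0), 0.9),
        "cai": FeatureSpec("normal", L(0.0, 0.0, 0.0), 1.0, age_confounded=True),
    }


def default_expression_specs() -> dict[str, ExpressionSpec]:
    return {
        WGD: ExpressionSpec(15, 20, 3.0, 0.8),
        SINGLETON: ExpressionSpec(16, 20, 2.2, 0.8),
        SSD: ExpressionSpec(2, 5, 2.0, 0.8),
        RETRO_EXCLUDED: ExpressionSpec(5, 15, 2.0, 0.8),
    }


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study design.

    Counts are genes/families; ``n_singletons`` of ``None`` means "all genes
    not used by planted families"; ``dataset_noise`` is the per-pair
    dropout/addition probability when deriving the three ohnolog replicate
    sets; ``age_confound_strength`` is the correlation injected between
    duplicate age and features flagged ``age_confounded``.
    """

    seed: int = 0
    n_chromosomes: int = 4
    genes_per_chromosome: int = 50
    n_ohnolog_families: int = 12
    n_ssd_families: int = 10
    n_retro_pairs: int = 3
    n_singletons: int | None = None
    n_prevertebrate_pairs: int = 2
    n_tissues: int = 20
    node_age_table: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NODE_AGES))
    vertebrate_root_node: str = "Vertebrata"
    wgd_nodes: tuple[str, ...] = ("Vertebrata", "Vertebrata", "Vertebrata", "Euteleostomi")
    ssd_nodes: tuple[str, ...] = (
        "Euteleostomi", "Tetrapoda", "Amniota", "Mammalia", "Primates", "Homininae"
    )
    retro_nodes: tuple[str, ...] = ("Mammalia", "Primates", "Homininae")
    prevertebrate_node: str = "Chordata"
    feature_specs: dict[str, FeatureSpec] = field(default_factory=default_feature_specs)
    expression_specs: dict[str, ExpressionSpec] = field(default_factory=default_expression_specs)
    age_confound_strength: float = 0.8
    dataset_noise: float = 0.0
    age_unit: float = 50.0
    include_cds: bool = True

    def __post_init__(self):
        for name in (
            "n_chromosomes", "genes_per_chromosome", "n_ohnolog_families",
            "n_ssd_families", "n_retro_pairs", "n_prevertebrate_pairs", "n_tissues",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_singletons is not None and self.n_singletons < 0:
            raise ValueError("n_singletons must be non-negative")
        if not (0.0 <= self.dataset_noise <= 1.0):
            raise ValueError("dataset_noise must lie in [0, 1]")
        if not (-1.0 <= self.age_confound_strength <= 1.0):
            raise ValueError("age_confound_strength must lie in [-1, 1]")
        if any(a <= 0 for a in self.node_age_table.values()):
            raise ValueError("node ages must be strictly positive")
        for name, spec in self.feature_specs.items():
            spec.validate(name)

    def to_yaml(self, path) -> None:
        payload = {
            k: v for k, v in self.__dict__.items()
            if k not in ("feature_specs", "expression_specs")
        }
        payload["wgd_nodes"] = list(self.wgd_nodes)
        payload["ssd_nodes"] = list(self.ssd_nodes)
        payload["retro_nodes"] = list(self.retro_nodes)
        payload["feature_specs"] = {
            n: {"distribution": s.distribution, "locations": s.locations,
                "scale": s.scale, "age_confounded": s.age_confounded}
            for n, s in self.feature_specs.items()
        }
        payload["expression_specs"] = {
            c: {"min_tissues": s.min_tissues, "max_tissues": s.max_tissues,
                "log_mean": s.log_mean, "log_sd": s.log_sd}
            for c, s in self.expression_specs.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if "feature_specs" in payload:
            payload["feature_specs"] = {
                n: FeatureSpec(**s) for n, s in payload["feature_specs"].items()
            }
        if "expression_specs" in payload:
            payload["expression_specs"] = {
                c: ExpressionSpec(**s) for c, s in payload["expression_specs"].items()
            }
        for key in ("wgd_nodes", "ssd_nodes", "retro_nodes"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator."""

    true_class: pd.Series  # gene_id -> WGD | SSD | SINGLETON | RETRO_EXCLUDED
    families: dict[str, list[str]]
    true_pairs: pd.DataFrame  # gene_a, gene_b, duplication_node, family, kind
    wgd_pairs: list[tuple[str, str]]
    informative_features: list[str]
    age_only_features: list[str]

    def to_frame(self) -> pd.DataFrame:
        return self.true_class.rename("true_class").rename_axis("gene_id").reset_index()


def _partition_block_sizes(n_families: int, rng: np.random.Generator) -> list[int]:
    """Split the requested family count into synteny blocks of >= 3 anchors."""
    if n_families == 0:
        return []
    if n_families < 3:
        raise SizingError(
            "an ohnolog synteny block needs at least three linking pairs; "
            f"got n_ohnolog_families={n_families}"
        )
    sizes = []
    remaining = n_families
    while remaining:
        size = int(rng.integers(3, 6))
        size = min(size, remaining)
        if remaining - size in (1, 2):  # leave no unusable remainder
            size = remaining
        if size < 3:
            size = remaining
        sizes.append(size)
        remaining -= size
    return sizes


def simulate_genome(config: SimulationConfig):
    """Generate (gene table, paralog-pair table, synteny-segment table, truth).

    Planted ohnolog families lie on paired segments as chains of >= 3
    linking pairs with inter-anchor gaps <= 8 genes; retro pairs satisfy the
    intron rules with no surrounding microsynteny; SSD families carry nodes
    strictly inside the vertebrate lineage; singletons appear in no
    vertebrate-node pair.  Deterministic given the config seed.
    """
    rng = np.random.default_rng([config.seed, _GENOME_STREAM])
    C, G = config.n_chromosomes, config.genes_per_chromosome
    chroms = [f"chr{i + 1}" for i in range(C)]
    total = C * G

    block_sizes = _partition_block_sizes(config.n_ohnolog_families, rng)
    if block_sizes and C < 2:
        raise SizingError(
            "ohnolog blocks link segments on two chromosomes; need n_chromosomes >= 2"
        )

    # role[(chrom_idx, pos)] = (role, payload)
    role: dict[tuple[int, int], tuple] = {}
    segment_of: dict[tuple[int, int], str] = {}
    cursor = [0] * C
    families: dict[str, list[str]] = {}
    planned_pairs = []  # (slotA, slotB, node, family, kind)
    seg_counter = 0
    fam_counter = 0

    for bi, k in enumerate(block_sizes):
        ca, cb = (2 * bi) % C, (2 * bi + 1) % C
        gaps_a = rng.integers(0, 4, size=k - 1)
        gaps_b = rng.integers(0, 4, size=k - 1)
        span_a = k + int(gaps_a.sum())
        span_b = k + int(gaps_b.sum())
        if cursor[ca] + span_a > G or cursor[cb] + span_b > G:
            raise SizingError(
                f"ohnolog block of {k} anchor pairs does not fit: "
                f"chromosome capacity {G} exceeded "
                f"(needs {span_a} on {chroms[ca]} and {span_b} on {chroms[cb]})"
            )
        seg_a, seg_b = f"seg{seg_counter:03d}", f"seg{seg_counter + 1:03d}"
        seg_counter += 2
        start_a, start_b = cursor[ca], cursor[cb]
        cursor[ca] += span_a + 2  # 2-gene buffer between blocks
        cursor[cb] += span_b + 2
        for off in range(span_a):
            segment_of[(ca, start_a + off)] = seg_a
        for off in range(span_b):
            segment_of[(cb, start_b + off)] = seg_b
        pa, pb = start_a, start_b
        for j in range(k):
            fam = f"fam{fam_counter:04d}"
            fam_counter += 1
            node = str(rng.choice(config.wgd_nodes))
            slot_a, slot_b = (ca, pa), (cb, pb)
            role[slot_a] = ("WGD", fam)
            role[slot_b] = ("WGD", fam)
            planned_pairs.append((slot_a, slot_b, node, fam, "WGD"))
            if j < k - 1:
                pa += 1 + int(gaps_a[j])
                pb += 1 + int(gaps_b[j])

    free = [
        (ci, p)
        for ci in range(C)
        for p in range(cursor[ci], G)
    ]
    needed = 2 * (config.n_ssd_families + config.n_retro_pairs + config.n_prevertebrate_pairs)
    if needed > len(free):
        raise SizingError(
            f"planted SSD/retro/pre-vertebrate genes need {needed} free slots "
            f"but only {len(free)} remain outside synteny blocks"
        )
    order = rng.permutation(len(free))
    free = [free[i] for i in order]

    def pop_slot():
        return free.pop()

    for _ in range(config.n_ssd_families):
        fam = f"fam{fam_counter:04d}"
        fam_counter += 1
        node = str(rng.choice(config.ssd_nodes))
        s1, s2 = pop_slot(), pop_slot()
        role[s1] = ("SSD", fam)
        role[s2] = ("SSD", fam)
        planned_pairs.append((s1, s2, node, fam, "SSD"))

    for _ in range(config.n_retro_pairs):
        fam = f"fam{fam_counter:04d}"
        fam_counter += 1
        node = str(rng.choice(config.retro_nodes))
        parent, copy = pop_slot(), pop_slot()
        role[parent] = ("RETRO_PARENT", fam)
        role[copy] = ("RETRO_COPY", fam)
        planned_pairs.append((parent, copy, node, fam, "RETRO"))

    for pi in range(config.n_prevertebrate_pairs):
        s1, s2 = pop_slot(), pop_slot()
        role[s1] = ("PREVERT", None)
        role[s2] = ("PREVERT", None)
        planned_pairs.append((s1, s2, config.prevertebrate_node, None, "PRE_VERTEBRATE"))

    n_left = len(free)
    if config.n_singletons is not None and config.n_singletons != n_left:
        raise SizingError(
            f"n_singletons={config.n_singletons} inconsistent with layout: "
            f"{n_left} slots remain after planting families "
            f"({total} genes total)"
        )

    # materialise the gene table in chromosome order
    gene_ids: dict[tuple[int, int], str] = {}
    records = []
    gid = 0
    for ci, chrom in enumerate(chroms):
        for pos in range(G):
            gene = f"G{gid:05d}"
            gid += 1
            gene_ids[(ci, pos)] = gene
            r = role.get((ci, pos), ("SINGLETON", None))[0]
            if r == "RETRO_COPY":
                introns = 0
            elif r == "RETRO_PARENT":
                introns = int(rng.integers(3, 13))
            else:
                introns = int(rng.integers(1, 15))
            cds = None
            if config.include_cds:
                n_codons = int(rng.integers(100, 401))
                cds = "".join(rng.choice(list("ACGT"), size=3 * n_codons))
            records.append(
                {
                    "gene_id": gene,
                    "chromosome": chrom,
                    "order_index": pos,
                    "intron_count": introns,
                    "segment_id": segment_of.get((ci, pos), pd.NA),
                    "cds": cds,
                }
            )
    genes = pd.DataFrame(records)
    if not config.include_cds:
        genes = genes.drop(columns=["cds"])

    pair_rows, wgd_pairs = [], []
    for slot_a, slot_b, node, fam, kind in planned_pairs:
        a, b = gene_ids[slot_a], gene_ids[slot_b]
        a, b = (a, b) if a <= b else (b, a)
        pair_rows.append(
            {"gene_a": a, "gene_b": b, "duplication_node": node, "family": fam, "kind": kind}
        )
        if kind == "WGD":
            wgd_pairs.append((a, b))
        if fam is not None:
            families.setdefault(fam, [])
            for g in (a, b):
                if g not in families[fam]:
                    families[fam].append(g)
    true_pairs = pd.DataFrame(
        pair_rows, columns=["gene_a", "gene_b", "duplication_node", "family", "kind"]
    )
    pairs = true_pairs[["gene_a", "gene_b", "duplication_node"]].copy()

    segments = (
        genes.dropna(subset=["segment_id"])
        .loc[:, ["segment_id", "chromosome", "gene_id", "order_index"]]
        .rename(columns={"order_index": "position"})
        .reset_index(drop=True)
    )

    kind_to_class = {
        "WGD": WGD, "SSD": SSD, "RETRO_PARENT": RETRO_EXCLUDED,
        "RETRO_COPY": RETRO_EXCLUDED, "PREVERT": SINGLETON, "SINGLETON": SINGLETON,
    }
    true_class = pd.Series(
        [kind_to_class[role.get((ci, p), ("SINGLETON", None))[0]]
         for ci in range(C) for p in range(G)],
        index=pd.Index(genes["gene_id"], name="gene_id"),
        name="true_class",
    )

    informative = [
        n for n, s in config.feature_specs.items()
        if len({s.locations.get(c, 0.0) for c in _CLASSES}) > 1
    ]
    age_only = [
        n for n, s in config.feature_specs.items()
        if s.age_confounded and n not in informative
    ]
    truth = SyntheticTruth(
        true_class=true_class,
        families=families,
        true_pairs=true_pairs,
        wgd_pairs=wgd_pairs,
        informative_features=informative,
        age_only_features=age_only,
    )
    return genes, pairs, segments, truth


def simulate_ohnolog_replicates(
    pairs: pd.DataFrame,
    truth: SyntheticTruth,
    config: SimulationConfig,
    n_replicates: int = 3,
) -> list[set[tuple[str, str]]]:
    """Three noisy copies of the true ohnolog pair set.

    Each replicate independently drops every true WGD pair with probability
    ``dataset_noise`` and adds every vertebrate-lineage non-WGD pair with
    the same probability, emulating disagreement between published ohnolog
    data sets.  At noise 0 all replicates equal the true set.
    """
    rng = np.random.default_rng([config.seed, _REPLICATE_STREAM])
    noise = config.dataset_noise
    true_set = [tuple(p) for p in truth.wgd_pairs]
    root_age = config.node_age_table[config.vertebrate_root_node]
    pool = [
        (a, b) if a <= b else (b, a)
        for a, b, node, kind in zip(
            truth.true_pairs["gene_a"], truth.true_pairs["gene_b"],
            truth.true_pairs["duplication_node"], truth.true_pairs["kind"],
        )
        if kind != "WGD" and config.node_age_table[node] <= root_age
    ]
    replicates = []
    for _ in range(n_replicates):
        kept = {p for p in true_set if rng.random() > noise}
        added = {p for p in pool if rng.random() < noise}
        replicates.append(kept | added)
    return replicates


def simulate_feature_table(
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the per-gene feature table and TPM expression matrix.

    Features are drawn per class from the configured specs; features
    flagged ``age_confounded`` are mixed with standardized duplicate age at
    strength ``age_confound_strength`` (genes without an age receive no
    confound term).  Returns ``(features, expression)`` indexed by gene;
    tau and maximum expression are computed downstream from the expression
    matrix.
    """
    rng = np.random.default_rng([config.seed, _FEATURE_STREAM])
    gene_index = truth.true_class.index
    n = len(gene_index)
    cls = truth.true_class

    genes_stub = pd.DataFrame({"gene_id": gene_index})
    ages = assign_duplicate_age(
        truth.true_pairs,
        genes_stub,
        node_age_table=config.node_age_table,
        vertebrate_root_node=config.vertebrate_root_node,
        age_unit=config.age_unit,
    )
    z_age = np.zeros(n)
    with_age = ages.notna().to_numpy()
    if with_age.sum() >= 2 and ages[with_age].std(ddof=0) > 0:
        vals = ages[with_age].to_numpy()
        z_age[with_age] = (vals - vals.mean()) / vals.std(ddof=0)

    c = config.age_confound_strength
    latents = {
        spec.latent: rng.standard_normal(n)
        for spec in config.feature_specs.values()
        if spec.latent is not None
    }
    cols = {}
    for name, spec in config.feature_specs.items():
        spec.validate(name)
        eps = rng.standard_normal(n)
        if spec.latent is not None:
            w = spec.loading
            eps = w * latents[spec.latent] + math.sqrt(max(0.0, 1.0 - w * w)) * eps
        if spec.age_confounded and c != 0:
            mix = math.sqrt(max(0.0, 1.0 - c * c)) * eps + c * z_age
        else:
            mix = eps
        loc = cls.map(lambda k: spec.locations.get(k, 0.0)).to_numpy(dtype=float)
        latent = loc + spec.scale * mix
        cols[name] = np.exp(latent) if spec.distribution == "lognormal" else latent
    features = pd.DataFrame(cols, index=gene_index)

    tissues = [f"tissue{t + 1:02d}" for t in range(config.n_tissues)]
    expr = np.zeros((n, config.n_tissues))
    for i, gene in enumerate(gene_index):
        spec = config.expression_specs.get(cls[gene])
        if spec is None:
            raise ValueError(f"no expression spec for class {cls[gene]!r}")
        hi = min(spec.max_tissues, config.n_tissues)
        lo = min(spec.min_tissues, hi)
        k = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(config.n_tissues, size=k, replace=False)
        expr[i, chosen] = np.exp(rng.normal(spec.log_mean, spec.log_sd, size=k))
    expression = pd.DataFrame(expr, index=gene_index, columns=tissues)
    return features, expression


def simulate_study(config: SimulationConfig):
    """One-call convenience: genome, replicates, features, expression, truth."""
    genes, pairs, segments, truth = simulate_genome(config)
    replicates = simulate_ohnolog_replicates(pairs, truth, config)
    features, expression = simulate_feature_table(truth, config)
    return {
        "genes": genes,
        "pairs": pairs,
        "segments": segments,
        "truth": truth,
        "ohnolog_sets": replicates,
        "features": features,
        "expression": expression,
    }
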