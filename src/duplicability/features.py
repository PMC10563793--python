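"""Derived per-gene features: tissue specificity, duplicate age, GC3, summaries.

Tissue specificity is the benchmarked index tau,

    tau = sum_i (1 - x_i) / (N - 1),

where x_i is a gene's expression in condition i scaled by its maximum across
the N conditions (tissues and developmental stages treated alike).  tau = 0
for uniform (housekeeping) expression and 1 for single-condition expression.

Duplicate age is the age of the oldest duplication node in a gene's
vertebrate family (the transitive closure of its vertebrate-lineage paralog
pairs), expressed in units of ``age_unit`` million years (default 50).
"""

from __future__ import annotations

import logging
import warnings

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Divergence times in MY for common duplication nodes; overridable.
DEFAULT_NODE_AGES: dict[str, float] = {
    "Chordata": 550.0,
    "Vertebrata": 530.0,
    "Euteleostomi": 430.0,
    "Tetrapoda": 350.0,
    "Amniota": 310.0,
    "Mammalia": 180.0,
    "Primates": 75.0,
    "Homininae": 9.0,
}


def tau(values) -> float:
    """Tissue-specificity index for a single expression profile.

    Returns NaN (with a log message) for an all-zero profile; raises for
    fewer than two conditions or negative values.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("tau requires at least two conditions")
    if (x < 0).any():
        raise ValueError("expression values must be non-negative")
    m = x.max()
    if m == 0:
        logger.info("all-zero expression profile: tau undefined")
        return float("nan")
    return float((1.0 - x / m).sum() / (x.size - 1))


def tissue_specificity(expression: pd.DataFrame) -> pd.Series:
    """Vectorised tau over an expression matrix (genes x conditions, TPM)."""
    if expression.shape[1] < 2:
        raise ValueError("tau requires at least two conditions")
    x = expression.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("expression values must be non-negative")
    m = x.max(axis=1)
    n_zero = int((m == 0).sum())
    if n_zero:
        logger.info("%d all-zero expression profiles: tau undefined", n_zero)
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = x / m[:, None]
    t = (1.0 - scaled).sum(axis=1) / (x.shape[1] - 1)
    t[m == 0] = np.nan
    return pd.Series(t, index=expression.index, name="tau")


def assign_duplicate_age(
    pairs: pd.DataFrame,
    genes: pd.DataFrame,
    node_age_table: dict[str, float] | None = None,
    vertebrate_root_node: str = "Vertebrata",
    age_unit: float = 50.0,
    singleton_age: float = float("nan"),
) -> pd.Series:
    """Duplicate age per gene, in ``age_unit``-MY units.

    Family membership is the transitive closure over vertebrate-lineage
    pairs (duplication node not older than ``vertebrate_root_node``); every
    member of a family shares the age of the oldest duplication node in it.
    Genes with no vertebrate-lineage pairs get ``singleton_age`` (default
    missing, so singletons never leak into age regressions).
    """
    ages = dict(DEFAULT_NODE_AGES if node_age_table is None else node_age_table)
    unknown = sorted(set(pairs["duplication_node"]) - set(ages))
    if unknown:
        raise KeyError(f"duplication nodes missing from node age table: {unknown}")
    root_age = ages[vertebrate_root_node]

    g = nx.Graph()
    for a, b, node in zip(pairs["gene_a"], pairs["gene_b"], pairs["duplication_node"]):
        if ages[node] <= root_age:
            g.add_edge(a, b, age=ages[node])

    out = pd.Series(singleton_age, index=pd.Index(genes["gene_id"], name="gene_id"), name="age")
    for family in nx.connected_components(g):
        sub = g.subgraph(family)
        oldest = max(d["age"] for _, _, d in sub.edges(data=True))
        for gene in family:
            if gene in out.index:
                out[gene] = oldest / age_unit
    return out


def per_tissue_expression_summary(
    expression: pd.DataFrame,
    labels: pd.Series,
    threshold_tpm: float = 1.0,
    classes: tuple[str, ...] = ("WGD", "SSD", "SINGLETON"),
) -> pd.DataFrame:
    """Per-tissue median expression of expressed genes, by duplicate class.

    Only genes expressed at ``threshold_tpm`` or higher in a tissue enter
    that tissue's median.  The ``wgd_gt_ssd`` column flags tissues where the
    WGD median exceeds the SSD median; tissues where a class has no
    expressed genes get a missing median (logged).
    """
    labels = labels.reindex(expression.index)
    rows = []
    for tissue in expression.columns:
        col = expression[tissue]
        row = {"tissue": tissue}
        for cls in classes:
            vals = col[(labels == cls) & (col >= threshold_tpm)]
            if vals.empty:
                logger.info("tissue %s: no expressed %s genes", tissue, cls)
                row[f"median_{cls}"] = np.nan
            else:
                row[f"median_{cls}"] = float(vals.median())
        row["wgd_gt_ssd"] = (
            row.get("median_WGD", np.nan) > row.get("median_SSD", np.nan)
            if "WGD" in classes and "SSD" in classes
            else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("tissue")


def gc3_content(cds: str) -> float:
    """Percent G+C at third codon positions of a CDS.

    A trailing partial codon is dropped with a warning; ``N`` bases at third
    positions are excluded from both numerator and denominator.
    """
    if not cds:
        raise ValueError("empty CDS sequence")
    seq = cds.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"unexpected characters in CDS: {sorted(bad)}")
    if len(seq) < 3:
        raise ValueError("CDS shorter than one codon")
    if len(seq) % 3:
        warnings.warn(
            f"CDS length {len(seq)} not a multiple of 3; trailing partial codon dropped",
            stacklevel=2,
        )
        seq = seq[: len(seq) - len(seq) % 3]
    third = seq[2::3].replace("N", "")
    if not third:
        return float("nan")
    gc = sum(1 for b in third if b in "GC")
    return 100.0 * gc / len(third)


def select_longest_transcript(
    transcripts: pd.DataFrame,
    gene_col: str = "gene_id",
    transcript_col: str = "transcript_id",
    length_col: str = "transcript_length",
) -> pd.DataFrame:
    """One row per gene: the longest transcript, ties broken by smallest id."""
    ordered = transcripts.sort_values(
        [gene_col, length_col, transcript_col], ascending=[True, False, True]
    )
    return ordered.groupby(gene_col, as_index=False).head(1).reset_index(drop=True)


def add_expression_features(
    features: pd.DataFrame,
    expression: pd.DataFrame,
) -> pd.DataFrame:
    """Append tau and maximum expression columns computed from a TPM matrix."""
    out = features.copy()
    expr = expression.reindex(out.index)
    out["tau"] = tissue_specificity(expr)
    out["max_expression"] = expr.max(axis=1)
    return out
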