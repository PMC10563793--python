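"""Duplicate-gene classification: ohnologs, SSD paralogs, retrocopies, singletons.

Pair-level rules
----------------
A paralog pair is called an **ohnolog (WGD) pair** when it links two distinct
macrosynteny segments inside a block of at least ``min_block`` linking pairs
whose consecutive anchors are separated by at most ``max_gap`` intervening
genes on both segments.  Pairs whose duplication node predates the vertebrate
ancestor are set aside as pre-vertebrate duplications.  Remaining (would-be
SSD) pairs are screened for retroduplication using intron counts and local
microsynteny.  Gene-level labels are then derived from the pairs each gene
participates in, and a majority vote across three independent ohnolog data
sets yields the consensus classification.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

# pair labels
PAIR_WGD = "WGD"
PAIR_SSD = "SSD"
PAIR_RETRO = "RETRO"
PAIR_PRE_VERTEBRATE = "PRE_VERTEBRATE"

# gene labels
WGD = "WGD"
SSD = "SSD"
SINGLETON = "SINGLETON"
EXCLUDED = "EXCLUDED"

# exclusion reasons
RETRO_PAIR = "RETRO_PAIR"
MIXED_TYPE = "MIXED_TYPE"
NO_MAJORITY = "NO_MAJORITY"

# singleton subtypes
NO_PARALOGS = "NO_PARALOGS"
PRE_VERTEBRATE_ONLY = "PRE_VERTEBRATE_ONLY"


class ReferentialIntegrityError(ValueError):
    """A pair references a gene that is absent from the gene table."""


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _check_pair_genes(pairs: pd.DataFrame, genes: pd.DataFrame) -> None:
    known = set(genes["gene_id"])
    missing = sorted(
        (set(pairs["gene_a"]) | set(pairs["gene_b"])) - known
    )
    if missing:
        raise ReferentialIntegrityError(
            f"pair table references genes missing from the gene table: {missing}"
        )


def _gene_index(genes: pd.DataFrame) -> dict[str, tuple[str, int]]:
    return {
        g: (c, int(o))
        for g, c, o in zip(genes["gene_id"], genes["chromosome"], genes["order_index"])
    }


def _segment_of(genes: pd.DataFrame) -> dict[str, str]:
    seg = {}
    for g, s in zip(genes["gene_id"], genes["segment_id"]):
        if pd.notna(s) and s != "":
            seg[g] = s
    return seg


def call_ohnolog_pairs(
    pairs: pd.DataFrame,
    genes: pd.DataFrame,
    min_block: int = 3,
    max_gap: int = 8,
) -> set[tuple[str, str]]:
    """Call WGD (ohnolog) pairs from macrosynteny segment assignments.

    Pairs linking two distinct segments are grouped by the (unordered)
    segment pair they link, sorted along one segment, and chained while the
    number of genes strictly between consecutive anchors is at most
    ``max_gap`` on *both* segments.  Chains of at least ``min_block`` pairs
    are accepted; the union of all accepted chains is returned as a set of
    canonical ``(gene_a, gene_b)`` tuples (``gene_a <= gene_b``).

    The result is independent of the row order of ``pairs``.
    """
    _check_pair_genes(pairs, genes)
    pos = _gene_index(genes)
    seg = _segment_of(genes)

    groups: dict[tuple[str, str], list[tuple[int, int, tuple[str, str]]]] = {}
    for a, b in zip(pairs["gene_a"], pairs["gene_b"]):
        sa, sb = seg.get(a), seg.get(b)
        if sa is None or sb is None or sa == sb:
            continue
        # orient the anchor so position 1 is on the lexicographically
        # smaller segment, making the grouping order-independent
        if sa <= sb:
            key, p1, p2 = (sa, sb), pos[a][1], pos[b][1]
        else:
            key, p1, p2 = (sb, sa), pos[b][1], pos[a][1]
        groups.setdefault(key, []).append((p1, p2, _canonical_pair(a, b)))

    called: set[tuple[str, str]] = set()
    for anchors in groups.values():
        anchors.sort()
        # split the sorted anchors into maximal runs with consecutive
        # inter-anchor gaps <= max_gap on both segments
        run: list[tuple[int, int, tuple[str, str]]] = []
        for anchor in anchors:
            if run:
                prev = run[-1]
                gap1 = abs(anchor[0] - prev[0]) - 1
                gap2 = abs(anchor[1] - prev[1]) - 1
                if gap1 > max_gap or gap2 > max_gap:
                    if len(run) >= min_block:
                        called.update(p for _, _, p in run)
                    run = []
            run.append(anchor)
        if len(run) >= min_block:
            called.update(p for _, _, p in run)
    return called


def check_microsynteny(
    pair: tuple[str, str],
    pairs: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 5,
) -> bool:
    """True if another paralog pair links the neighbourhoods of both members.

    A neighbour pair qualifies when one of its members lies within ``window``
    genes (either side, same chromosome) of one member of the tested pair and
    its partner lies within ``window`` genes of the other member.  The tested
    pair itself never counts; genes at chromosome ends simply use the
    truncated window.
    """
    _check_pair_genes(pairs, genes)
    a, b = pair
    pos = _gene_index(genes)
    if a not in pos or b not in pos:
        raise ReferentialIntegrityError(f"pair {pair} not in gene table")
    target = _canonical_pair(a, b)

    def near(g: str, anchor: str) -> bool:
        cg, pg = pos[g]
        ca, pa = pos[anchor]
        return cg == ca and abs(pg - pa) <= window

    for c, d in zip(pairs["gene_a"], pairs["gene_b"]):
        if _canonical_pair(c, d) == target:
            continue
        if (near(c, a) and near(d, b)) or (near(c, b) and near(d, a)):
            return True
    return False


def detect_retroduplication(
    pair: tuple[str, str],
    genes: pd.DataFrame,
    pairs: pd.DataFrame,
    window: int = 5,
) -> bool:
    """Intron-count screen for retroduplicated (retrocopy) pairs.

    True when one member has zero introns and the other three or more, or
    when one member has zero introns, the other fewer than three, and there
    is no conserved microsynteny around the pair.  Intron gain is never
    inferred.  Symmetric in member order.
    """
    introns = dict(zip(genes["gene_id"], genes["intron_count"]))
    a, b = pair
    for g in pair:
        if g not in introns or pd.isna(introns[g]):
            raise ValueError(f"intron count missing for gene {g!r}")
    lo, hi = sorted((int(introns[a]), int(introns[b])))
    if lo > 0:
        return False
    if hi >= 3:
        return True
    return not check_microsynteny(pair, pairs, genes, window=window)


def _vertebrate_nodes(node_age_table: dict[str, float], vertebrate_root_node: str) -> set[str]:
    if vertebrate_root_node not in node_age_table:
        raise KeyError(f"vertebrate root node {vertebrate_root_node!r} not in node age table")
    root_age = node_age_table[vertebrate_root_node]
    return {n for n, age in node_age_table.items() if age <= root_age}


def label_pairs(
    pairs: pd.DataFrame,
    genes: pd.DataFrame,
    node_age_table: dict[str, float],
    vertebrate_root_node: str = "Vertebrata",
    ohnolog_pairs: set[tuple[str, str]] | None = None,
    min_block: int = 3,
    max_gap: int = 8,
    window: int = 5,
) -> pd.DataFrame:
    """Assign each paralog pair exactly one label.

    Precedence: PRE_VERTEBRATE (duplication node at or older than the
    vertebrate ancestor) > WGD (pair in the ohnolog set) > RETRO
    (retroduplication screen, applied only to would-be SSD pairs) > SSD.

    ``ohnolog_pairs`` may be an externally supplied ohnolog pair set (e.g.
    one of the three cross-referencing data sets); when ``None`` it is
    called from the macrosynteny segments in ``genes``.
    """
    _check_pair_genes(pairs, genes)
    unknown = sorted(set(pairs["duplication_node"]) - set(node_age_table))
    if unknown:
        raise KeyError(f"duplication nodes missing from node age table: {unknown}")
    if ohnolog_pairs is None:
        ohnolog_pairs = call_ohnolog_pairs(pairs, genes, min_block=min_block, max_gap=max_gap)
    else:
        ohnolog_pairs = {_canonical_pair(*p) for p in ohnolog_pairs}
    vert = _vertebrate_nodes(node_age_table, vertebrate_root_node)
    # pre-vertebrate = strictly older than the vertebrate root
    labels = []
    for a, b, node in zip(pairs["gene_a"], pairs["gene_b"], pairs["duplication_node"]):
        if node not in vert:
            labels.append(PAIR_PRE_VERTEBRATE)
        elif _canonical_pair(a, b) in ohnolog_pairs:
            labels.append(PAIR_WGD)
        elif detect_retroduplication((a, b), genes, pairs, window=window):
            labels.append(PAIR_RETRO)
        else:
            labels.append(PAIR_SSD)
    out = pairs.copy()
    out["pair_label"] = labels
    return out


def assign_gene_labels(labeled_pairs: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Per-gene duplication class for one ohnolog data set.

    A gene is WGD when all of its vertebrate-lineage pairs are WGD, SSD when
    all are SSD, EXCLUDED (reason RETRO_PAIR) when any pair is a retrocopy
    pair, EXCLUDED (reason MIXED_TYPE) when it has both WGD and SSD pairs,
    and SINGLETON when it has no vertebrate-lineage pairs (subtype
    PRE_VERTEBRATE_ONLY when pre-vertebrate pairs exist, else NO_PARALOGS).
    Retro exclusion takes precedence over mixed-type exclusion.
    """
    by_gene: dict[str, Counter] = {g: Counter() for g in genes["gene_id"]}
    for a, b, lab in zip(
        labeled_pairs["gene_a"], labeled_pairs["gene_b"], labeled_pairs["pair_label"]
    ):
        by_gene[a][lab] += 1
        by_gene[b][lab] += 1

    rows = []
    for g in genes["gene_id"]:
        c = by_gene[g]
        n_vert = c[PAIR_WGD] + c[PAIR_SSD] + c[PAIR_RETRO]
        label, reason, subtype = None, None, None
        if c[PAIR_RETRO] > 0:
            label, reason = EXCLUDED, RETRO_PAIR
        elif c[PAIR_WGD] > 0 and c[PAIR_SSD] > 0:
            label, reason = EXCLUDED, MIXED_TYPE
        elif c[PAIR_WGD] > 0:
            label = WGD
        elif c[PAIR_SSD] > 0:
            label = SSD
        elif n_vert == 0:
            label = SINGLETON
            subtype = PRE_VERTEBRATE_ONLY if c[PAIR_PRE_VERTEBRATE] > 0 else NO_PARALOGS
        rows.append((g, label, reason, subtype))
    return pd.DataFrame(
        rows, columns=["gene_id", "label", "exclusion_reason", "singleton_subtype"]
    )


def majority_vote(
    label_sets: list[pd.DataFrame],
    no_majority_label: str = EXCLUDED,
) -> pd.DataFrame:
    """Consensus gene labels by majority rules across ohnolog data sets.

    The consensus is any label held by at least two of the three data sets;
    when all three disagree the gene is EXCLUDED with reason NO_MAJORITY
    (configurable via ``no_majority_label``).
    """
    if len(label_sets) < 2:
        raise ValueError("majority vote requires at least two label sets")
    universes = [tuple(sorted(ls["gene_id"])) for ls in label_sets]
    if len(set(universes)) != 1:
        raise ReferentialIntegrityError("label sets cover different gene universes")

    indexed = [ls.set_index("gene_id") for ls in label_sets]
    rows = []
    for g in label_sets[0]["gene_id"]:
        votes = [ix.loc[g] for ix in indexed]
        counts = Counter(v["label"] for v in votes)
        label, n = counts.most_common(1)[0]
        reason = subtype = None
        if n >= 2:
            support = [v for v in votes if v["label"] == label]
            if label == EXCLUDED:
                reasons = Counter(v["exclusion_reason"] for v in support)
                # retro exclusion outranks mixed-type when tied
                reason = max(
                    reasons,
                    key=lambda r: (reasons[r], r == RETRO_PAIR, r == MIXED_TYPE),
                )
            if label == SINGLETON:
                subtypes = Counter(v["singleton_subtype"] for v in support)
                subtype = subtypes.most_common(1)[0][0]
        else:
            label, reason = no_majority_label, NO_MAJORITY
        rows.append((g, label, reason, subtype))
    return pd.DataFrame(
        rows, columns=["gene_id", "label", "exclusion_reason", "singleton_subtype"]
    )


@dataclass
class ClassificationResult:
    """Full output of the three-data-set classification pipeline."""

    per_dataset_pairs: dict[str, pd.DataFrame]
    per_dataset_labels: dict[str, pd.DataFrame]
    consensus: pd.DataFrame
    summary: pd.DataFrame = field(default=None)


def classification_summary(
    per_dataset_pairs: dict[str, pd.DataFrame],
    per_dataset_labels: dict[str, pd.DataFrame],
    consensus: pd.DataFrame,
) -> pd.DataFrame:
    """Tabular report of pair and gene counts per data set plus consensus.

    Rows mirror a classification-by-data-set table: WGD / non-WGD pair
    counts, the non-WGD breakdown (retroduplicated, pre-vertebrate, presumed
    SSD), gene counts per class, and the final consensus gene counts.
    """
    rows = {}
    for name, lp in per_dataset_pairs.items():
        counts = Counter(lp["pair_label"])
        labels = per_dataset_labels[name]
        gene_counts = Counter(labels["label"])
        rows[name] = {
            "wgd_pairs": counts[PAIR_WGD],
            "non_wgd_pairs": counts[PAIR_SSD] + counts[PAIR_RETRO] + counts[PAIR_PRE_VERTEBRATE],
            "retroduplicated_pairs": counts[PAIR_RETRO],
            "prevertebrate_pairs": counts[PAIR_PRE_VERTEBRATE],
            "presumed_ssd_pairs": counts[PAIR_SSD],
            "wgd_genes": gene_counts[WGD],
            "ssd_genes": gene_counts[SSD],
            "singleton_genes": gene_counts[SINGLETON],
            "excluded_genes": gene_counts[EXCLUDED],
        }
    final = Counter(consensus["label"])
    rows["consensus"] = {
        "wgd_genes": final[WGD],
        "ssd_genes": final[SSD],
        "singleton_genes": final[SINGLETON],
        "excluded_genes": final[EXCLUDED],
    }
    out = pd.DataFrame(rows)
    return out


def run_classification(
    genes: pd.DataFrame,
    pairs: pd.DataFrame,
    ohnolog_sets: dict[str, set[tuple[str, str]] | None],
    node_age_table: dict[str, float],
    vertebrate_root_node: str = "Vertebrata",
    min_block: int = 3,
    max_gap: int = 8,
    window: int = 5,
) -> ClassificationResult:
    """End-to-end pipeline: label pairs per data set, vote, summarise.

    ``ohnolog_sets`` maps data-set name to an ohnolog pair set; a ``None``
    value means "call ohnologs from the macrosynteny segments in the gene
    table" for that data set.
    """
    per_pairs, per_labels = {}, {}
    for name, ohno in ohnolog_sets.items():
        lp = label_pairs(
            pairs,
            genes,
            node_age_table,
            vertebrate_root_node=vertebrate_root_node,
            ohnolog_pairs=ohno,
            min_block=min_block,
            max_gap=max_gap,
            window=window,
        )
        per_pairs[name] = lp
        per_labels[name] = assign_gene_labels(lp, genes)
    consensus = majority_vote(list(per_labels.values()))
    summary = classification_summary(per_pairs, per_labels, consensus)
    return ClassificationResult(per_pairs, per_labels, consensus, summary)
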