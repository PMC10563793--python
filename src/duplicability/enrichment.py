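"""Term enrichment per duplicate class and cross-class overlap analysis.

Each annotation term is tested against the whole-gene background with a
two-sided hypergeometric test (doubled smaller tail, capped at 1), so
enrichment and depletion are assessed in one pass; Benjamini-Hochberg FDR
is applied across terms within each class.  The overlap summary reports,
for every directed class pair, the fraction of the source class's
significant terms that are significant in the target class with the same
(concordant) or opposite (opposed) direction, plus UpSet-style intersection
sizes over the significant term sets.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

ENRICHED = "enriched"
DEPLETED = "depleted"


def _as_annotation_map(annotations) -> dict[str, set]:
    if isinstance(annotations, pd.DataFrame):
        return {
            term: set(sub["gene_id"])
            for term, sub in annotations.groupby("term_id")
        }
    return {t: set(g) for t, g in annotations.items()}


def term_enrichment(
    class_genes: set,
    annotations,
    universe: set,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided hypergeometric enrichment of every term in one gene class.

    ``annotations`` is either a mapping term -> gene set or a long-format
    frame with ``term_id``/``gene_id`` columns; annotated genes outside the
    universe are ignored.  Returns one row per term (with >= 1 annotated
    gene) carrying observed and expected counts, direction, raw p and BH q;
    ``significant`` flags q < alpha.
    """
    class_genes = set(class_genes)
    universe = set(universe)
    if not class_genes:
        raise ValueError("class gene set is empty")
    stray = class_genes - universe
    if stray:
        raise ValueError(f"class genes outside the universe: {sorted(stray)[:5]}")
    ann = _as_annotation_map(annotations)

    terms, K_arr, k_arr = [], [], []
    N, n = len(universe), len(class_genes)
    for term, genes in sorted(ann.items()):
        members = genes & universe
        if not members:
            continue
        terms.append(term)
        K_arr.append(len(members))
        k_arr.append(len(members & class_genes))
    if not terms:
        return pd.DataFrame(
            columns=["term", "observed", "expected", "direction", "p", "q", "significant"]
        )
    K = np.array(K_arr)
    k = np.array(k_arr)
    lower = hypergeom.cdf(k, N, K, n)
    upper = hypergeom.sf(k - 1, N, K, n)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    _, q, _, _ = multipletests(p, method="fdr_bh")
    expected = n * K / N
    out = pd.DataFrame(
        {
            "term": terms,
            "observed": k,
            "expected": expected,
            "direction": np.where(k > expected, ENRICHED, DEPLETED),
            "p": p,
            "q": q,
        }
    )
    out["significant"] = out["q"] < alpha
    return out


def _significant_directions(records: pd.DataFrame) -> dict[str, str]:
    sig = records[records["significant"]]
    return dict(zip(sig["term"], sig["direction"]))


def overlap_summary(records_by_class: dict[str, pd.DataFrame]) -> dict:
    """Concordance/opposition fractions and intersection sizes across classes.

    Returns a dict with:

    ``pairwise``
        one row per ordered class pair (source, target): the fraction of the
        source's significant terms that are significant in the target with
        the same direction (``concordant``) or the opposite direction
        (``opposed``).  Asymmetric by design: the denominator is the source
        class's significant-term count.
    ``intersections_terms`` / ``intersections_term_direction``
        UpSet-style exact-membership intersection sizes over significant
        term sets, counting terms irrespective of direction and
        term-direction pairs respectively.
    """
    sig = {cls: _significant_directions(rec) for cls, rec in records_by_class.items()}
    classes = list(records_by_class)

    rows = []
    for src, tgt in itertools.permutations(classes, 2):
        terms = sig[src]
        n_src = len(terms)
        conc = sum(1 for t, d in terms.items() if sig[tgt].get(t) == d)
        oppo = sum(1 for t, d in terms.items() if t in sig[tgt] and sig[tgt][t] != d)
        rows.append(
            {
                "source": src,
                "target": tgt,
                "n_source_terms": n_src,
                "concordant": conc / n_src if n_src else np.nan,
                "opposed": oppo / n_src if n_src else np.nan,
            }
        )
    pairwise = pd.DataFrame(rows)

    def intersections(sets: dict[str, set]) -> pd.DataFrame:
        all_items = set().union(*sets.values()) if sets else set()
        counts = []
        for r in range(1, len(classes) + 1):
            for combo in itertools.combinations(classes, r):
                inside = set(combo)
                members = all_items
                for cls in combo:
                    members = members & sets[cls]
                members = {
                    m for m in members
                    if not any(m in sets[c] for c in classes if c not in inside)
                }
                counts.append(
                    {"classes": "&".join(combo), "size": len(members)}
                )
        return pd.DataFrame(counts)

    term_sets = {cls: set(d) for cls, d in sig.items()}
    termdir_sets = {cls: {(t, d) for t, d in d_.items()} for cls, d_ in sig.items()}
    return {
        "pairwise": pairwise,
        "intersections_terms": intersections(term_sets),
        "intersections_term_direction": intersections(termdir_sets),
    }
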