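"""End-to-end validation studies for the pipeline.

Each function here sets up a planted-truth study at a fixed, documented
design, runs the relevant part of the pipeline from scratch, and returns
the measured quantities (agreement fractions, selection rates, rank
placements, calibration rates).  The designs — sample sizes, effect sizes,
confound strengths — were chosen once for statistical power and are part
of the package's validation contract; both the test suite and the
reproduction script consume these functions.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from . import classify, enrichment, importance, simulate
from .features import assign_duplicate_age, tissue_specificity
from .importance import ClassifierProtocolConfig
from .stats import fit_feature_age_model, residualize_on_age

_SEED_MAX = 2**31 - 1


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(_SEED_MAX, size=n)]


# ---------------------------------------------------------------------------
# synteny-block caller vs exhaustive enumeration

def _random_synteny_instance(rng: np.random.Generator):
    """A small random genome: <=5 single-segment chromosomes, <=30 genes each."""
    n_seg = int(rng.integers(2, 6))
    rows = []
    seg_len = {}
    for s in range(n_seg):
        L = int(rng.integers(5, 31))
        seg_len[f"s{s}"] = L
        for pos in range(L):
            rows.append((f"s{s}_g{pos}", f"chr{s}", pos, 5, f"s{s}"))
    genes = pd.DataFrame(
        rows, columns=["gene_id", "chromosome", "order_index", "intron_count", "segment_id"]
    )
    n_pairs = int(rng.integers(3, 16))
    pair_set = set()
    for _ in range(n_pairs):
        sa, sb = rng.choice(n_seg, size=2, replace=False)
        pa = int(rng.integers(0, seg_len[f"s{sa}"]))
        pb = int(rng.integers(0, seg_len[f"s{sb}"]))
        a, b = f"s{sa}_g{pa}", f"s{sb}_g{pb}"
        pair_set.add((a, b) if a <= b else (b, a))
    pairs = pd.DataFrame(sorted(pair_set), columns=["gene_a", "gene_b"])
    pairs["duplication_node"] = "Vertebrata"
    return genes, pairs


def _enumerate_blocks_bruteforce(pairs, genes, min_block=3, max_gap=8):
    """Independent oracle: check every contiguous anchor window explicitly."""
    pos = {g: int(p) for g, p in zip(genes["gene_id"], genes["order_index"])}
    seg = {g: s for g, s in zip(genes["gene_id"], genes["segment_id"]) if pd.notna(s)}
    groups = {}
    for a, b in zip(pairs["gene_a"], pairs["gene_b"]):
        sa, sb = seg.get(a), seg.get(b)
        if sa is None or sb is None or sa == sb:
            continue
        if sa <= sb:
            key, anchor = (sa, sb), (pos[a], pos[b], tuple(sorted((a, b))))
        else:
            key, anchor = (sb, sa), (pos[b], pos[a], tuple(sorted((a, b))))
        groups.setdefault(key, []).append(anchor)
    called = set()
    for anchors in groups.values():
        anchors.sort()
        k = len(anchors)
        for i, j in itertools.combinations(range(k + 1), 2):
            window = anchors[i:j]
            if len(window) < min_block:
                continue
            ok = all(
                abs(window[t + 1][0] - window[t][0]) - 1 <= max_gap
                and abs(window[t + 1][1] - window[t][1]) - 1 <= max_gap
                for t in range(len(window) - 1)
            )
            if ok:
                called.update(p for _, _, p in window)
    return called


def synteny_oracle_agreement(seed: int, n_instances: int = 200) -> dict:
    """Fraction of random instances where the caller matches the oracle."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        genes, pairs = _random_synteny_instance(rng)
        got = classify.call_ohnolog_pairs(pairs, genes)
        want = _enumerate_blocks_bruteforce(pairs, genes)
        agree += got == want
    return {"agreement": agree / n_instances, "n": n_instances}


# ---------------------------------------------------------------------------
# retroduplication rule truth table

def retro_rule_truth_table() -> dict:
    """All four rule branches, each checked in both member orders."""
    cases = [
        # (introns_a, introns_b, microsynteny, expected)
        (0, 5, False, True),
        (0, 2, True, False),
        (0, 2, False, True),
        (2, 7, False, False),
        (0, 0, False, True),
    ]
    correct = total = 0
    for ia, ib, micro, expected in cases:
        rows = [(f"A{p}", "chr1", p, 5, None) for p in range(10)]
        rows += [(f"B{p}", "chr2", p, 5, None) for p in range(10)]
        genes = pd.DataFrame(
            rows, columns=["gene_id", "chromosome", "order_index", "intron_count", "segment_id"]
        )
        genes.loc[genes.gene_id == "A5", "intron_count"] = ia
        genes.loc[genes.gene_id == "B5", "intron_count"] = ib
        pair_rows = [("A5", "B5", "Mammalia")]
        if micro:
            pair_rows.append(("A6", "B4", "Mammalia"))
        pairs = pd.DataFrame(pair_rows, columns=["gene_a", "gene_b", "duplication_node"])
        for p in (("A5", "B5"), ("B5", "A5")):
            total += 1
            correct += classify.detect_retroduplication(p, genes, pairs) == expected
    return {"correct": correct, "n": total, "agreement": correct / total}


# ---------------------------------------------------------------------------
# round-trip classification and majority-vote noise recovery

def classification_round_trip(seed: int) -> dict:
    """Noise-free synthetic genome: consensus labels vs planted truth."""
    cfg = simulate.SimulationConfig(seed=seed)
    genes, pairs, _, truth = simulate.simulate_genome(cfg)
    reps = simulate.simulate_ohnolog_replicates(pairs, truth, cfg)
    res = classify.run_classification(
        genes, pairs, {f"r{i}": s for i, s in enumerate(reps)}, cfg.node_age_table
    )
    cons = res.consensus.set_index("gene_id")["label"]
    expected = truth.true_class.map(
        lambda c: classify.EXCLUDED if c == "RETRO_EXCLUDED" else c
    )
    match = (cons.reindex(expected.index) == expected).mean()
    return {"accuracy": float(match), "n": len(expected)}


def majority_vote_recovery(seed: int, n_seeds: int = 50, noise: float = 0.1) -> dict:
    """Fraction of planted ohnolog genes recovered under replicate noise."""
    recovered = total = 0
    for s in _child_seeds(seed, n_seeds):
        cfg = simulate.SimulationConfig(
            seed=s, n_chromosomes=6, genes_per_chromosome=60,
            n_ohnolog_families=24, dataset_noise=noise, include_cds=False,
        )
        genes, pairs, _, truth = simulate.simulate_genome(cfg)
        reps = simulate.simulate_ohnolog_replicates(pairs, truth, cfg)
        res = classify.run_classification(
            genes, pairs, {f"r{i}": x for i, x in enumerate(reps)}, cfg.node_age_table
        )
        wgd = truth.true_class[truth.true_class == "WGD"].index
        cons = res.consensus.set_index("gene_id")["label"]
        recovered += int((cons[wgd] == "WGD").sum())
        total += len(wgd)
    return {"recovery": recovered / total, "n": total}


# ---------------------------------------------------------------------------
# tau against direct formula evaluation

def tau_against_direct_formula(seed: int, n_rows: int = 1000) -> dict:
    rng = np.random.default_rng(seed)
    n_cond = 12
    mat = pd.DataFrame(rng.gamma(0.6, 25.0, size=(n_rows, n_cond)))
    got = tissue_specificity(mat)
    max_err = 0.0
    for i in range(n_rows):
        x = mat.iloc[i].to_numpy()
        direct = sum(1 - xi / x.max() for xi in x) / (n_cond - 1)
        max_err = max(max_err, abs(got.iloc[i] - direct))
    uniform = tissue_specificity(pd.DataFrame([[7.0] * 5]))
    single = tissue_specificity(pd.DataFrame([[0.0, 9.0, 0.0]]))
    return {
        "max_abs_error": float(max_err),
        "uniform_tau": float(uniform.iloc[0]),
        "single_tissue_tau": float(single.iloc[0]),
        "n": n_rows,
    }


# ---------------------------------------------------------------------------
# transformation selection and interaction rule

def _regression_draw(rng, n=400, beta_int=0.0):
    age = rng.uniform(0.5, 10.6, n)
    typ = np.where(rng.random(n) < 0.5, "WGD", "SSD")
    latent = (
        0.5 + 0.25 * age + 0.5 * (typ == "WGD")
        + beta_int * age * (typ == "WGD") + rng.normal(0, 0.5, n)
    )
    return np.exp(latent), age, typ


def transformation_selection_recovery(seed: int, n_reps: int = 100) -> dict:
    """Log recovery on log-normal data; interaction kept iff planted."""
    rng = np.random.default_rng(seed)
    log_hits = int_hits = int_false = 0
    for _ in range(n_reps):
        y, age, typ = _regression_draw(rng)
        res = fit_feature_age_model(y, age, typ)
        log_hits += res.transformation == "log"
        y1, age1, typ1 = _regression_draw(rng, beta_int=0.12)
        int_hits += fit_feature_age_model(y1, age1, typ1).interaction_included
        y0, age0, typ0 = _regression_draw(rng)
        int_false += fit_feature_age_model(y0, age0, typ0).interaction_included
    return {
        "log_selected": log_hits,
        "interaction_detected": int_hits,
        "interaction_false": int_false,
        "n": n_reps,
    }


# ---------------------------------------------------------------------------
# age-confound removal in the importance protocol

def _confound_specs():
    L = lambda w, s: {"WGD": w, "SSD": s}  # noqa: E731
    sp = {
        f"len{i}": simulate.FeatureSpec(
            "normal", L(3.0, 0.0), 1.0, latent="len", loading=0.8
        )
        for i in range(5)
    }
    sp["pli"] = simulate.FeatureSpec("normal", L(1.6, 0.0), 1.0)
    sp["max_expression"] = simulate.FeatureSpec("normal", L(1.6, 0.0), 1.0)
    sp["cai"] = simulate.FeatureSpec("normal", L(0.0, 0.0), 1.0, age_confounded=True)
    sp["noise0"] = simulate.FeatureSpec("normal", {}, 1.0)
    sp["noise1"] = simulate.FeatureSpec("normal", {}, 1.0)
    return sp


def _confound_config(seed: int) -> simulate.SimulationConfig:
    return simulate.SimulationConfig(
        seed=seed, n_chromosomes=8, genes_per_chromosome=90,
        n_ohnolog_families=75, n_ssd_families=75, n_retro_pairs=0,
        n_prevertebrate_pairs=0, feature_specs=_confound_specs(),
        ssd_nodes=(
            "Euteleostomi", "Euteleostomi", "Tetrapoda", "Tetrapoda",
            "Amniota", "Mammalia", "Primates", "Homininae",
        ),
        age_confound_strength=0.99, include_cds=False,
    )


def age_confound_removal(seed: int, n_seeds: int = 100, n_iterations: int = 20) -> dict:
    """Rank of the planted age-only feature, raw vs age-controlled.

    The age-only feature (``cai``, no class shift, correlation 0.99 with
    duplicate age) should reach the top 3 of the raw ranking and drop to
    the bottom half once every feature is residualized on age.
    """
    top3 = bottom = joint = 0
    max_corr = 0.0
    for s in _child_seeds(seed, n_seeds):
        cfg = _confound_config(s)
        genes, pairs, _, truth = simulate.simulate_genome(cfg)
        feats, _ = simulate.simulate_feature_table(truth, cfg)
        ages = assign_duplicate_age(pairs, genes)
        dup = truth.true_class.isin(["WGD", "SSD"])
        X, y, a = feats.loc[dup], truth.true_class[dup], ages[dup]
        pc = ClassifierProtocolConfig(
            n_iterations=n_iterations, seed=s, n_permutation_rounds=3
        )
        raw = importance.run_protocol(X, y, pc)
        ctl = importance.run_age_controlled_protocol(X, a, y, pc)
        resid = residualize_on_age(X["cai"], a)
        max_corr = max(max_corr, abs(float(np.corrcoef(resid, a)[0, 1])))
        r_raw = list(raw.importances["feature"]).index("cai") + 1
        r_ctl = list(ctl.importances["feature"]).index("cai") + 1
        n_feat = X.shape[1]
        is_top = r_raw <= 3
        is_bottom = r_ctl > n_feat // 2
        top3 += is_top
        bottom += is_bottom
        joint += is_top and is_bottom
    return {
        "top3_raw": top3,
        "bottom_half_controlled": bottom,
        "joint": joint,
        "n": n_seeds,
        "max_residual_age_correlation": max_corr,
    }


# ---------------------------------------------------------------------------
# null calibration

def null_classifier_calibration(seed: int, n_shuffles: int = 5,
                                n_iterations: int = 20) -> dict:
    """Mean held-out accuracy under label shuffling, against chance."""
    specs = {f"noise{i}": simulate.FeatureSpec("normal", {}, 1.0) for i in range(8)}
    accs = []
    n_genes = None
    for s in _child_seeds(seed, n_shuffles):
        cfg = simulate.SimulationConfig(
            seed=s, n_chromosomes=8, genes_per_chromosome=90,
            n_ohnolog_families=75, n_ssd_families=75, n_retro_pairs=0,
            n_prevertebrate_pairs=0, feature_specs=specs, include_cds=False,
        )
        genes, pairs, _, truth = simulate.simulate_genome(cfg)
        feats, _ = simulate.simulate_feature_table(truth, cfg)
        dup = truth.true_class.isin(["WGD", "SSD"])
        X, y = feats.loc[dup], truth.true_class[dup]
        n_genes = len(y)
        y_shuf = y.sample(frac=1.0, random_state=s % _SEED_MAX).set_axis(y.index)
        pc = ClassifierProtocolConfig(n_iterations=n_iterations, seed=s)
        accs.append(importance.run_protocol(X, y_shuf, pc).accuracy_mean)
    mean = float(np.mean(accs))
    half = 2.576 * np.sqrt(0.25 / n_genes)
    return {
        "null_accuracy_mean": mean,
        "ci99_halfwidth": float(half),
        "n_genes": n_genes,
        "n_shuffles": n_shuffles,
    }


def enrichment_type_one_rate(seed: int, n_sims: int = 1000) -> dict:
    """Fraction of raw hypergeometric p-values below 0.05 under random classes."""
    rng = np.random.default_rng(seed)
    N, n_class, n_terms = 4000, 1500, 40
    universe = [f"g{i}" for i in range(N)]
    uni_set = set(universe)
    sig = tot = 0
    for _ in range(n_sims):
        ann = {
            f"t{t}": set(rng.choice(universe, size=int(rng.integers(200, 1001)),
                                    replace=False))
            for t in range(n_terms)
        }
        cls = set(rng.choice(universe, size=n_class, replace=False))
        rec = enrichment.term_enrichment(cls, ann, uni_set)
        sig += int((rec["p"] < 0.05).sum())
        tot += len(rec)
    return {"p05_rate": sig / tot, "n_tests": tot}


# ---------------------------------------------------------------------------
# correlated-feature isolation

def isolation_collinear_recheck(seed: int, n_iterations: int = 40) -> dict:
    """Exactly collinear planted pair: importance in isolation vs jointly."""
    L = lambda w, s: {"WGD": w, "SSD": s}  # noqa: E731
    specs = {
        "len_a": simulate.FeatureSpec("normal", L(2.0, 0.0), 1.0, latent="L", loading=1.0),
        "len_b": simulate.FeatureSpec("normal", L(2.0, 0.0), 1.0, latent="L", loading=1.0),
        "pli": simulate.FeatureSpec("normal", L(1.2, 0.0), 1.0),
    }
    for i in range(4):
        specs[f"noise{i}"] = simulate.FeatureSpec("normal", {}, 1.0)
    cfg = simulate.SimulationConfig(
        seed=seed, n_chromosomes=8, genes_per_chromosome=90,
        n_ohnolog_families=75, n_ssd_families=75, n_retro_pairs=0,
        n_prevertebrate_pairs=0, feature_specs=specs, include_cds=False,
    )
    genes, pairs, _, truth = simulate.simulate_genome(cfg)
    feats, _ = simulate.simulate_feature_table(truth, cfg)
    dup = truth.true_class.isin(["WGD", "SSD"])
    X, y = feats.loc[dup], truth.true_class[dup]
    pc = ClassifierProtocolConfig(n_iterations=n_iterations, seed=seed,
                                  n_permutation_rounds=3)
    out = importance.isolation_analysis(
        X, y, pc, groups={"length": ["len_a", "len_b"]}
    )
    ratios = out["isolated_importance"] / out["previous_importance"]
    acc_change = (out["new_accuracy"] - out["previous_accuracy"]).abs()
    return {
        "min_importance_ratio": float(ratios.min()),
        "max_importance_ratio": float(ratios.max()),
        "max_accuracy_change": float(acc_change.max()),
        "n_iterations": n_iterations,
    }
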