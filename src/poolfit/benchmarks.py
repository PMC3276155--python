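"""Standard validation experiments on ground-truthed synthetic data.

Each function simulates a pooled-fermentation screen under the package's
reference study conditions, runs the relevant pipeline stages, and scores
the result against the planted truth.  They back both the test suite and
the reproduction script, so the numbers they return are always recomputed
from scratch.

Reference conditions (see docs/methods.md): 4000 in-pool strains with 300
planted at s = -0.4 and 150 at s = +0.4, 200 false barcodes, 4 replicate
spots per tag, 5% dead-tag rate, 0.3 log2 multiplicative noise, cumulative
doublings [0, 1, 2, 3, 3.7, 4.2, 4.5] over days 1-14.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import calls as calls_mod
from . import enrich as enrich_mod
from . import normalize, simpool, tagstats


def _key_from_truth(truth: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "strain_id": truth["strain_id"],
            "gene": truth["gene"],
            "zygosity": truth["zygosity"],
            "in_pool": truth["in_pool"],
            "annotation_class": truth["annotation_class"],
            "has_up_tag": True,
            "has_dn_tag": True,
        }
    )


def run_reference_screen(seed: int, null: bool = False, **overrides):
    """Simulate one reference screen and run it through normalize/tagstats.

    Returns (truth, fitness matrix, TagMatrix).  ``null=True`` zeroes every
    planted effect for calibration runs.
    """
    params = dict(
        n_strains=4000,
        frac_depleted=0.0 if null else 0.075,
        frac_enriched=0.0 if null else 0.0375,
        n_false_barcodes=200,
        dead_tag_rate=0.05,
        n_replicate_spots=4,
        noise_sd_log2=0.3,
        seed=seed,
    )
    params.update(overrides)
    exp = simpool.simulate_experiment(**params)
    key = _key_from_truth(exp.truth)
    normalized = normalize.normalize_all(exp.scans, key=key)
    matrix, tag_matrix = tagstats.build_fitness_matrix(normalized, key)
    return exp.truth, matrix, tag_matrix


def recovery_metrics(seed: int) -> dict[str, float]:
    """Sensitivity/precision of planted-effect recovery for one seed."""
    truth, matrix, tag_matrix = run_reference_screen(seed)
    call_df = calls_mod.classify_matrix(matrix)
    t = truth.set_index("strain_id")
    out: dict[str, float] = {}
    for direction, sign in (("depleted", -1), ("enriched", 1)):
        planted = set(t.index[(t["in_pool"]) & (np.sign(t["fitness"]) == sign)])
        called = set(call_df.loc[call_df["direction"] == direction, "strain_id"])
        tp = len(called & planted)
        out[f"{direction}_sensitivity"] = tp / len(planted)
        out[f"{direction}_precision"] = tp / len(called) if called else float("nan")
        out[f"{direction}_called"] = len(called)
    fb = tag_matrix.prefilter_spots.loc[~tag_matrix.prefilter_spots["in_pool"]]
    out["false_barcode_significant_frac"] = float(fb["significant"].mean())
    return out


def null_call_rate(seed: int) -> float:
    """Fraction of in-pool strains called in either direction when every
    planted fitness effect is zero."""
    truth, matrix, _ = run_reference_screen(seed, null=True)
    call_df = calls_mod.classify_matrix(matrix)
    n_called = (call_df["direction"] != "none").sum()
    n_pool = int(truth["in_pool"].sum())
    return float(n_called / n_pool)


def bias_removal_residual(seed: int = 1, amplitude: float = 0.6) -> float:
    """Worst residual trend on null spots after loess, noise-free arrays
    with an injected sinusoidal dye bias of the given log2 amplitude."""
    exp = simpool.simulate_experiment(
        n_strains=4000,
        frac_depleted=0.0,
        frac_enriched=0.0,
        n_false_barcodes=200,
        dead_tag_rate=0.0,
        noise_sd_log2=0.0,
        dye_bias_amplitude=amplitude,
        seed=seed,
    )
    key = _key_from_truth(exp.truth)
    pool = set(key.loc[key["in_pool"], "strain_id"])
    worst = 0.0
    for scan in exp.scans.values():
        spots = normalize.normalize_spots(scan)
        in_pool = spots["strain_id"].isin(pool)
        out = normalize.loess_normalize(spots, in_pool=in_pool)
        worst = max(worst, float(out.loc[in_pool, "M"].abs().max()))
    return worst


def enrichment_calibration(
    seed: int = 1,
    n_draws: int = 10_000,
    universe_size: int = 3734,
    hit_size: int = 300,
    n_categories: int = 459,
    alphas: tuple[float, ...] = (0.05, 0.01),
) -> dict[float, float]:
    """Fraction of (category, random hit set) pairs with p_raw <= alpha.

    Random hit sets carry no signal, so a correct upper-tail computation
    keeps each fraction at or slightly below alpha (slightly, because the
    hypergeometric is discrete).
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(universe_size)]
    sets = simpool.simulate_gene_sets(genes, n_categories=n_categories, seed=seed)

    gene_index = {g: i for i, g in enumerate(genes)}
    membership = np.zeros((n_categories, universe_size), dtype=np.float32)
    sf_tables = []
    for row, rec in enumerate(sets.values()):
        idx = [gene_index[g] for g in rec["members"]]
        membership[row, idx] = 1.0
        K = len(idx)
        table = np.array(
            [
                enrich_mod.hypergeom_upper(k, K, hit_size, universe_size)
                for k in range(min(K, hit_size) + 1)
            ]
        )
        sf_tables.append(table)

    exceed = {a: 0 for a in alphas}
    total = 0
    chunk = 1000
    for start in range(0, n_draws, chunk):
        n_chunk = min(chunk, n_draws - start)
        masks = np.zeros((universe_size, n_chunk), dtype=np.float32)
        for c in range(n_chunk):
            masks[rng.choice(universe_size, size=hit_size, replace=False), c] = 1.0
        counts = membership @ masks  # categories x draws
        for row in range(n_categories):
            p = sf_tables[row][counts[row].astype(int)]
            for a in alphas:
                exceed[a] += int((p <= a).sum())
        total += n_chunk * n_categories
    return {a: exceed[a] / total for a in alphas}


def planted_category_enrichment(
    seed: int = 1,
    universe_size: int = 3734,
    hit_size: int = 300,
    category_size: int = 23,
    hits_in_category: int = 19,
    m: int = 459,
) -> pd.Series:
    """Score one planted category against a random background catalogue.

    Mirrors the contingency structure of a strongly enriched pathway: 19
    of 23 category genes inside a 300-gene hit set from a 3734-gene
    universe, Bonferroni-adjusted over 459 categories.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(universe_size)]
    perm = rng.permutation(universe_size)
    hits = {genes[i] for i in perm[:hit_size]}
    members = [genes[i] for i in perm[:hits_in_category]] + [
        genes[i] for i in perm[hit_size : hit_size + (category_size - hits_in_category)]
    ]
    sets = simpool.simulate_gene_sets(genes, n_categories=m - 1, seed=seed)
    sets["PLANTED"] = {"description": "planted pathway", "members": sorted(members)}
    res = enrich_mod.enrich_categories(hits, set(genes), sets, m_override=m)
    return res.set_index("category_id").loc["PLANTED"]
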