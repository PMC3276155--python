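"""Synthetic pooled-fermentation experiments with known ground truth.

The generator mimics a competitive-growth screen of a pooled deletion
collection: every strain carries molecular barcodes (UP and DN tags), the
pool ferments for two weeks, and samples taken on days 2-14 are hybridized
against the day-1 control on two-channel barcode microarrays.  Each strain
has a relative fitness coefficient ``s`` acting per population doubling, so
a strain's barcode abundance after ``D`` cumulative doublings scales as
``2**((1 + s) * D)``.  Arrays carry replicate spots, nonfunctional ("dead")
tags, false barcodes of strains absent from the pool, additive background,
multiplicative log-normal noise and an optional smooth intensity-dependent
dye bias -- the artefacts the analysis stages must remove.

Because the truth table records every planted effect, downstream stages can
be scored for recovery (sensitivity/precision) rather than eyeballed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PoolfitError

#: Sampling schedule of the fermentation: day 1 is the hybridization control,
#: days 2-14 are the experimental time points.
DEFAULT_DAYS: tuple[int, ...] = (1, 2, 4, 6, 8, 10, 14)

#: Cumulative population doublings per sampling day; saturating shape of a
#: closed fermentation (rapid early growth, near-stationary tail).
DEFAULT_DOUBLINGS: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 3.7, 4.2, 4.5)

TRUTH_COLUMNS = [
    "strain_id",
    "gene",
    "in_pool",
    "fitness",
    "up_tag_dead",
    "dn_tag_dead",
    "zygosity",
    "annotation_class",
]


@dataclass
class PoolTrajectory:
    """Per-strain relative abundances of live cells across sampling days."""

    days: tuple[int, ...]
    doublings: np.ndarray
    frequencies: pd.DataFrame  # index strain_id, one column per day

    def day_frequencies(self, day: int) -> pd.Series:
        return self.frequencies[day]


def _orf_name(i: int) -> str:
    # Systematic ORF-style names: chromosome letter, arm, position, strand.
    chrom = chr(ord("A") + (i // 640) % 16)
    arm = "LR"[(i // 320) % 2]
    strand = "WC"[i % 2]
    return f"Y{chrom}{arm}{(i % 320) + 1:03d}{strand}"


def simulate_pool(
    n_strains: int,
    frac_depleted: float = 0.0,
    frac_enriched: float = 0.0,
    effect_sizes: tuple[float, float] = (-0.4, 0.4),
    n_false_barcodes: int = 0,
    dead_tag_rate: float = 0.0,
    zygosity: str = "homozygous",
    seed: int = 0,
) -> pd.DataFrame:
    """Build a ground-truth strain table for a synthetic deletion pool.

    Exactly ``round(n_strains * frac_depleted)`` strains receive the first
    (negative) effect size and ``round(n_strains * frac_enriched)`` the
    second; everyone else is neutral (``fitness == 0``).  ``n_false_barcodes``
    extra records are appended with ``in_pool == False``: their tags are
    printed on the array but no cells carry them, so their signal
    distribution estimates the array noise floor.  Each tag of each strain
    is independently nonfunctional with probability ``dead_tag_rate``.
    """
    if n_strains < 0 or n_false_barcodes < 0:
        raise PoolfitError("strain and false-barcode counts must be nonnegative")
    if not (0.0 <= frac_depleted <= 1.0 and 0.0 <= frac_enriched <= 1.0):
        raise PoolfitError("fractions must lie in [0, 1]")
    if frac_depleted + frac_enriched > 1.0 + 1e-12:
        raise PoolfitError("frac_depleted + frac_enriched must not exceed 1")
    if zygosity not in ("homozygous", "heterozygous"):
        raise PoolfitError(f"unknown zygosity: {zygosity!r}")

    rng = np.random.default_rng(seed)
    n_dep = round(n_strains * frac_depleted)
    n_enr = round(n_strains * frac_enriched)

    fitness = np.zeros(n_strains)
    order = rng.permutation(n_strains)
    fitness[order[:n_dep]] = effect_sizes[0]
    fitness[order[n_dep : n_dep + n_enr]] = effect_sizes[1]

    n_total = n_strains + n_false_barcodes
    dead_up = rng.random(n_total) < dead_tag_rate
    dead_dn = rng.random(n_total) < dead_tag_rate
    # A strain must keep at least one functional tag to be observable at all;
    # a double-dead strain stays in the pool but yields no usable signal,
    # which is a legitimate (and tested) missing-data case -- keep it.

    # Annotation classes loosely shaped like the deletion collections: only
    # the heterozygous pool contains essential genes.
    if zygosity == "homozygous":
        classes = ["characterized", "uncharacterized", "dubious"]
        probs = [0.68, 0.20, 0.12]
    else:
        classes = ["characterized", "uncharacterized", "dubious", "essential"]
        probs = [0.50, 0.18, 0.12, 0.20]
    annot = rng.choice(classes, size=n_total, p=probs)

    truth = pd.DataFrame(
        {
            "strain_id": [f"STR{i + 1:05d}" for i in range(n_total)],
            "gene": [_orf_name(i) for i in range(n_total)],
            "in_pool": [True] * n_strains + [False] * n_false_barcodes,
            "fitness": np.concatenate([fitness, np.zeros(n_false_barcodes)]),
            "up_tag_dead": dead_up,
            "dn_tag_dead": dead_dn,
            "zygosity": zygosity,
            "annotation_class": annot,
        },
        columns=TRUTH_COLUMNS,
    )
    return truth


def simulate_growth(
    truth: pd.DataFrame,
    doublings_schedule: "np.ndarray | tuple[float, ...]" = DEFAULT_DOUBLINGS,
    days: tuple[int, ...] = DEFAULT_DAYS,
    sample_cells: int | None = None,
    seed: int = 0,
) -> PoolTrajectory:
    """Propagate the pool through the fermentation under selection.

    Each in-pool strain starts at equal frequency; abundance after D(t)
    cumulative doublings is ``2**((1 + s) * D(t))`` and per-day frequencies
    are abundances renormalized to sum to 1 (only live, in-pool cells are
    sampled).  With ``sample_cells`` set, each day's frequencies are
    additionally multinomially resampled at that depth to model genetic
    drift in the sampled aliquot.
    """
    D = np.asarray(doublings_schedule, dtype=float)
    if len(D) != len(days):
        raise PoolfitError("doublings schedule and day list differ in length")
    if D[0] != 0.0:
        raise PoolfitError("cumulative doublings must be 0 on day 1")
    if np.any(np.diff(D) < 0):
        raise PoolfitError("doublings schedule must be nondecreasing")

    pool = truth[truth["in_pool"]]
    if len(pool) == 0:
        raise PoolfitError("pool is empty")
    s = pool["fitness"].to_numpy(float)

    rng = np.random.default_rng(seed)
    freqs = {}
    for day, d in zip(days, D):
        # log-space abundances avoid overflow for large D
        log_a = (1.0 + s) * d
        a = np.exp2(log_a - log_a.max())
        f = a / a.sum()
        if sample_cells is not None and day != days[0]:
            counts = rng.multinomial(sample_cells, f)
            f = counts / counts.sum()
        freqs[day] = f
    frequencies = pd.DataFrame(freqs, index=pool["strain_id"].to_numpy())
    return PoolTrajectory(days=tuple(days), doublings=D, frequencies=frequencies)


def _dye_bias_log2(a0: np.ndarray, amplitude: float, trend: float, a_mid: float) -> np.ndarray:
    return amplitude * np.sin(a0) + trend * (a0 - a_mid)


def simulate_arrays(
    trajectory: PoolTrajectory,
    truth: pd.DataFrame,
    n_replicate_spots: int = 4,
    background_mean: float = 200.0,
    noise_sd_log2: float = 0.3,
    dye_bias_amplitude: float = 0.0,
    dye_bias_trend: float = 0.0,
    scale: float = 4.0e7,
    tag_efficiency_sd_log2: float = 0.25,
    seed: int = 0,
) -> dict[int, pd.DataFrame]:
    """Render each experimental day as a two-channel scan table.

    Every strain in the truth table (including false barcodes) contributes
    ``n_replicate_spots`` spots per existing tag.  The experimental channel
    carries ``scale * f_i(t) * efficiency`` distorted by multiplicative
    log-normal noise and a smooth dye bias in mean log-intensity; the control
    channel carries the day-1 frequencies (the two-color design hybridizes
    day t against day 1 on the same array).  Dead tags and false barcodes
    emit background-only signal in both channels.  Deterministic per seed.
    """
    if trajectory.days[0] != 1:
        raise PoolfitError("trajectory must include the day-1 control")
    if n_replicate_spots < 1:
        raise PoolfitError("need at least one replicate spot")

    rng = np.random.default_rng(seed)
    tdf = truth.reset_index(drop=True)
    n = len(tdf)

    in_pool = tdf["in_pool"].to_numpy(bool)
    f1 = np.zeros(n)
    idx = trajectory.frequencies.index.get_indexer(tdf.loc[in_pool, "strain_id"])
    if np.any(idx < 0):
        raise PoolfitError("truth strains missing from trajectory")

    # Per-tag hybridization efficiencies: log-normal, constant across days.
    eff = {
        kind: np.exp2(rng.normal(0.0, tag_efficiency_sd_log2, size=n))
        for kind in ("UP", "DN")
    }
    dead = {"UP": tdf["up_tag_dead"].to_numpy(bool), "DN": tdf["dn_tag_dead"].to_numpy(bool)}

    f_ctl = np.zeros(n)
    f_ctl[in_pool] = trajectory.frequencies[1].to_numpy()[idx]

    scans: dict[int, pd.DataFrame] = {}
    for day in trajectory.days[1:]:
        f_exp = np.zeros(n)
        f_exp[in_pool] = trajectory.frequencies[day].to_numpy()[idx]
        rows = []
        for kind in ("UP", "DN"):
            live = in_pool & ~dead[kind]
            exp0 = scale * f_exp * eff[kind]
            ctl0 = scale * f_ctl * eff[kind]
            with np.errstate(divide="ignore"):
                a0 = 0.5 * np.log2(np.maximum(exp0, 1.0) * np.maximum(ctl0, 1.0))
            a_mid = float(np.median(a0[live])) if live.any() else 0.0
            bias = np.exp2(_dye_bias_log2(a0, dye_bias_amplitude, dye_bias_trend, a_mid))
            for rep in range(1, n_replicate_spots + 1):
                noise_e = np.exp2(rng.normal(0.0, noise_sd_log2, size=n))
                noise_c = np.exp2(rng.normal(0.0, noise_sd_log2, size=n))
                fg_exp = np.where(
                    live,
                    exp0 * bias * noise_e + background_mean,
                    background_mean * noise_e,
                )
                fg_ctl = np.where(
                    live,
                    ctl0 * noise_c + background_mean,
                    background_mean * noise_c,
                )
                rows.append(
                    pd.DataFrame(
                        {
                            "array_id": f"day{day:02d}",
                            "day": day,
                            "strain_id": tdf["strain_id"],
                            "tag_kind": kind,
                            "replicate_index": rep,
                            "fg_exp": fg_exp,
                            "bg_exp": background_mean,
                            "fg_ctl": fg_ctl,
                            "bg_ctl": background_mean,
                            "flag": "ok",
                        }
                    )
                )
        scans[day] = pd.concat(rows, ignore_index=True)
    return scans


def simulate_gene_sets(
    genes,
    n_categories: int = 459,
    size_log_mean: float = 4.1,
    size_log_sd: float = 0.8,
    size_range: tuple[int, int] = (10, 300),
    seed: int = 0,
) -> dict[str, dict]:
    """Synthetic functional-category catalogue in GMT form.

    Category sizes are log-normal (median ~60 genes), clipped to
    ``size_range`` -- the span of a genome-scale functional catalogue,
    whose categories run from pathway-sized (tens of genes) to broad
    processes (hundreds).  Members are drawn uniformly without replacement
    per category; categories overlap freely, as real catalogues do.
    """
    genes = list(genes)
    if not genes:
        raise PoolfitError("need a nonempty gene universe")
    rng = np.random.default_rng(seed)
    lo, hi = size_range
    sizes = np.clip(
        np.round(np.exp(rng.normal(size_log_mean, size_log_sd, n_categories))),
        lo,
        min(hi, len(genes)),
    ).astype(int)
    sets = {}
    for j, size in enumerate(sizes):
        members = rng.choice(genes, size=size, replace=False)
        sets[f"CAT{j + 1:04d}"] = {
            "description": f"synthetic category {j + 1}",
            "members": sorted(members),
        }
    return sets


@dataclass
class SimulatedExperiment:
    """Bundle of truth, trajectory and scan tables for one synthetic run."""

    truth: pd.DataFrame
    trajectory: PoolTrajectory
    scans: dict[int, pd.DataFrame] = field(default_factory=dict)


def simulate_experiment(
    n_strains: int = 4000,
    frac_depleted: float = 0.075,
    frac_enriched: float = 0.0375,
    effect_sizes: tuple[float, float] = (-0.4, 0.4),
    n_false_barcodes: int = 200,
    dead_tag_rate: float = 0.05,
    n_replicate_spots: int = 4,
    background_mean: float = 200.0,
    noise_sd_log2: float = 0.3,
    dye_bias_amplitude: float = 0.0,
    doublings_schedule: tuple[float, ...] = DEFAULT_DOUBLINGS,
    zygosity: str = "homozygous",
    seed: int = 0,
) -> SimulatedExperiment:
    """One-call convenience wrapper chaining pool, growth and arrays.

    Defaults reproduce the package's reference study conditions: 4000
    in-pool strains with 300 depleted (s = -0.4) and 150 enriched
    (s = +0.4), 200 false barcodes, 4 replicate spots, a 5% dead-tag rate
    and 0.3 log2 multiplicative noise over a saturating 4.5-doubling
    fermentation.
    """
    truth = simulate_pool(
        n_strains,
        frac_depleted,
        frac_enriched,
        effect_sizes,
        n_false_barcodes,
        dead_tag_rate,
        zygosity,
        seed=seed,
    )
    traj = simulate_growth(truth, doublings_schedule, seed=seed + 1)
    scans = simulate_arrays(
        traj,
        truth,
        n_replicate_spots=n_replicate_spots,
        background_mean=background_mean,
        noise_sd_log2=noise_sd_log2,
        dye_bias_amplitude=dye_bias_amplitude,
        seed=seed + 2,
    )
    return SimulatedExperiment(truth=truth, trajectory=traj, scans=scans)
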