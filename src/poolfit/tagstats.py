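"""Tag-level quality control, standardization and combination.

After normalization every spot carries an (M, A) pair.  This stage decides
which spots are trustworthy (per-array, per-tag-kind intensity thresholds
on A), removes barcode tags with too little significant data, standardizes
log2 ratios to Z scores per (array, tag kind), averages replicate spots,
combines the UP and DN tags of each strain, and purges false barcodes of
strains absent from the pool.  The product is the strain x day fitness
matrix downstream calling and clustering consume.

Two thresholding regimes mirror the two pool designs: when the key lists
false barcodes (homozygous-pool mode) the threshold is set so that at most
a target fraction of false-barcode signals pass; otherwise
(heterozygous-pool mode) a two-component Gaussian mixture separates the
low-intensity peak of presumptive nonfunctional barcodes from the signal
peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .errors import ConsistencyError, PoolfitError, StandardizationError

EXPERIMENT_DAYS = (2, 4, 6, 8, 10, 14)


def select_threshold_fpr(false_barcode_A, target_fpr: float = 0.05) -> float:
    """Smallest observed A such that at most ``target_fpr`` of false-barcode
    A values lie strictly above it.

    False barcodes are printed features of strains absent from the pool, so
    their intensities sample the array's noise floor; the threshold bounds
    the false-positive rate among spots called significant.
    """
    a = np.sort(np.asarray(false_barcode_A, dtype=float))
    if a.size == 0:
        raise PoolfitError("no false-barcode A values; cannot set an FPR threshold")
    if a.size < 20:
        raise PoolfitError(
            f"need >= 20 false-barcode A values to set an FPR threshold, got {a.size}"
        )
    # fraction strictly above a[i] is (n - searchsorted_right(a[i])) / n,
    # nonincreasing in i -> take the first candidate that satisfies the bound
    n = a.size
    frac_above = (n - np.searchsorted(a, a, side="right")) / n
    ok = np.nonzero(frac_above <= target_fpr)[0]
    return float(a[ok[0]])


def select_threshold_bimodal(all_A) -> float:
    """Threshold between the two peaks of a bimodal A distribution.

    Fits a two-component 1-D Gaussian mixture and returns the equal-
    posterior crossing between the component means; falls back to the
    histogram-valley minimum if the mixture degenerates (component weight
    < 0.05 or means closer than 0.5), and to the 1st percentile, with a
    warning, if the data are effectively unimodal.
    """
    a = np.asarray(all_A, dtype=float)
    if a.size < 200:
        raise PoolfitError(f"need >= 200 A values for bimodal thresholding, got {a.size}")

    gm = GaussianMixture(n_components=2, random_state=0, n_init=3)
    gm.fit(a.reshape(-1, 1))
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    lo, hi = np.argsort(means)
    m1, m2 = means[lo], means[hi]
    degenerate = weights.min() < 0.05 or (m2 - m1) < 0.5
    if not degenerate:

        def diff(x):
            return (
                np.log(weights[lo]) + norm.logpdf(x, m1, sds[lo])
                - np.log(weights[hi]) - norm.logpdf(x, m2, sds[hi])
            )

        def mixture_pdf(x):
            return weights[lo] * norm.pdf(x, m1, sds[lo]) + weights[hi] * norm.pdf(
                x, m2, sds[hi]
            )

        if diff(m1) > 0 > diff(m2):
            crossing = float(brentq(diff, m1, m2))
            # a genuine low-intensity peak leaves a deep valley between the
            # component means; a split of one unimodal bulk does not
            if mixture_pdf(crossing) < 0.7 * min(mixture_pdf(m1), mixture_pdf(m2)):
                return crossing
        degenerate = True

    # histogram-valley fallback between the two largest modes
    counts, edges = np.histogram(a, bins=50)
    centers = 0.5 * (edges[:-1] + edges[1:])
    is_mode = np.zeros(len(counts), bool)
    for i in range(len(counts)):
        left = counts[i - 1] if i > 0 else -1
        right = counts[i + 1] if i < len(counts) - 1 else -1
        is_mode[i] = counts[i] > left and counts[i] > right
    modes = np.nonzero(is_mode)[0]
    if len(modes) >= 2:
        top2 = modes[np.argsort(counts[modes])[-2:]]
        i, j = np.sort(top2)
        if j > i + 1:
            valley = i + 1 + int(np.argmin(counts[i + 1 : j]))
            # only accept a valley clearly below both flanking peaks
            if counts[valley] < 0.5 * min(counts[i], counts[j]):
                return float(centers[valley])
    warnings.warn(
        "A distribution appears unimodal; thresholding at the 1st percentile",
        stacklevel=2,
    )
    return float(np.percentile(a, 1.0))


def zscore_per_tag_array(values) -> np.ndarray:
    """Standardize one (array, tag kind)'s significant M values.

    Centered to mean 0 and scaled to population standard deviation 1, so
    UP and DN tags become comparable before combination.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2 or np.unique(v).size < 2:
        raise StandardizationError("need >= 2 distinct values to standardize")
    sd = v.std()  # population SD (ddof=0)
    return (v - v.mean()) / sd


def combine_tags(up_z: float | None, dn_z: float | None) -> float:
    """Unweighted mean of the available tag values; NaN if both missing."""
    vals = [v for v in (up_z, dn_z) if v is not None and not np.isnan(v)]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def average_replicates(cells) -> float:
    """Arithmetic mean over significant replicates; NaN if none."""
    v = np.asarray(cells, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return float("nan")
    return float(v.mean())


@dataclass
class TagMatrix:
    """Spot-level table plus the per-(array, tag kind) thresholds applied.

    ``spots`` carries one row per replicate spot with columns M, A, usable,
    significant and (after standardization) z; ``prefilter_spots`` is the
    same table before the sparse-tag rule removed rows (the basis for QC
    such as false-barcode leakage); ``thresholds`` maps (array_id,
    tag_kind) to the A cutoff used for its significance mask.
    """

    spots: pd.DataFrame
    thresholds: dict[tuple[str, str], float]
    prefilter_spots: pd.DataFrame | None = None

    def qc_report(self) -> pd.DataFrame:
        base = self.prefilter_spots if self.prefilter_spots is not None else self.spots
        rows = []
        for (array_id, kind), thr in sorted(self.thresholds.items()):
            sel = (base["array_id"] == array_id) & (
                base["tag_kind"] == kind
            )
            sub = base[sel]
            fb = sub[~sub["in_pool"]]
            rows.append(
                {
                    "array_id": array_id,
                    "tag_kind": kind,
                    "A_threshold": thr,
                    "pct_significant": 100.0 * sub["significant"].mean(),
                    "pct_false_barcode_significant": (
                        100.0 * fb["significant"].mean() if len(fb) else float("nan")
                    ),
                }
            )
        return pd.DataFrame(rows)


def compute_thresholds(
    spots: pd.DataFrame,
    mode: str = "homozygous",
    target_fpr: float = 0.05,
) -> dict[tuple[str, str], float]:
    """One A threshold per (array, tag kind), by the mode's selector."""
    thresholds: dict[tuple[str, str], float] = {}
    for (array_id, kind), sub in spots.groupby(["array_id", "tag_kind"], sort=True):
        usable = sub[sub["usable"]]
        if mode == "homozygous":
            fb = usable.loc[~usable["in_pool"], "A"]
            thresholds[(array_id, kind)] = select_threshold_fpr(fb, target_fpr)
        elif mode == "heterozygous":
            thresholds[(array_id, kind)] = select_threshold_bimodal(usable["A"])
        else:
            raise PoolfitError(f"unknown thresholding mode: {mode!r}")
    return thresholds


def apply_significance(
    spots: pd.DataFrame, thresholds: dict[tuple[str, str], float]
) -> pd.DataFrame:
    """Mark spots significant when usable and strictly above their threshold."""
    out = spots.copy()
    thr = pd.Series(
        [thresholds[k] for k in zip(out["array_id"], out["tag_kind"])],
        index=out.index,
    )
    out["significant"] = out["usable"] & (out["A"] > thr)
    return out


def drop_sparse_tags(spots: pd.DataFrame, min_fraction: float = 0.40) -> pd.DataFrame:
    """Drop (strain, tag) rows with significant data for less than
    ``min_fraction`` of all their replicate spots across all arrays
    (strict inequality: exactly-at-threshold tags are kept)."""
    frac = spots.groupby(["strain_id", "tag_kind"])["significant"].mean()
    keep = frac[frac >= min_fraction].index
    mask = pd.MultiIndex.from_arrays(
        [spots["strain_id"], spots["tag_kind"]]
    ).isin(keep)
    return spots[mask].copy()


def standardize(spots: pd.DataFrame) -> pd.DataFrame:
    """Z-standardize significant spots per (array, tag kind).

    Location and scale are estimated from significant in-pool spots only,
    so the noise-floor signals of false barcodes cannot distort the
    standardization; z is left NaN on non-significant spots.
    """
    out = spots.copy()
    out["z"] = np.nan
    for (array_id, kind), sub in out.groupby(["array_id", "tag_kind"], sort=False):
        est = sub[sub["significant"] & sub["in_pool"]]
        if len(est) < 2 or est["M"].nunique() < 2:
            raise StandardizationError(
                f"array {array_id} tag {kind}: not enough significant in-pool "
                "spots to standardize"
            )
        mu = est["M"].mean()
        sd = est["M"].std(ddof=0)
        sig = sub.index[sub["significant"]]
        out.loc[sig, "z"] = (out.loc[sig, "M"] - mu) / sd
    return out


def purge_false_barcodes(matrix: pd.DataFrame, key: pd.DataFrame) -> pd.DataFrame:
    """Remove rows of strains not present in the pool per the key."""
    known = key.set_index("strain_id")["in_pool"]
    missing = matrix.index.difference(known.index)
    if len(missing):
        raise ConsistencyError(f"strain {missing[0]!r} not present in the key")
    keep = known.reindex(matrix.index).astype(bool)
    return matrix[keep.to_numpy()]


def build_fitness_matrix(
    normalized: dict[int, pd.DataFrame],
    key: pd.DataFrame,
    mode: str = "homozygous",
    target_fpr: float = 0.05,
    min_fraction: float = 0.40,
    value_scale: str = "z",
) -> tuple[pd.DataFrame, TagMatrix]:
    """Full tag-statistics stage: thresholds -> masks -> 40% rule -> Z ->
    replicate averaging -> UP/DN combination -> false-barcode purge.

    Returns the strain x day fitness matrix (in-pool strains only; NaN
    where a strain has no significant data on an array) together with the
    spot-level :class:`TagMatrix` for QC.  ``value_scale`` selects whether
    the matrix holds standardized values ("z", the default) or raw
    normalized log2 ratios ("m").
    """
    if value_scale not in ("z", "m"):
        raise PoolfitError(f"value_scale must be 'z' or 'm', got {value_scale!r}")
    spots = pd.concat(normalized.values(), ignore_index=True)
    pool_map = key.set_index("strain_id")["in_pool"]
    unknown = set(spots["strain_id"]) - set(pool_map.index)
    if unknown:
        raise ConsistencyError(f"strain {sorted(unknown)[0]!r} not present in the key")
    spots = spots.copy()
    spots["in_pool"] = pool_map.reindex(spots["strain_id"]).to_numpy(bool)

    thresholds = compute_thresholds(spots, mode=mode, target_fpr=target_fpr)
    spots = apply_significance(spots, thresholds)
    prefilter = spots
    spots = drop_sparse_tags(spots, min_fraction=min_fraction)
    spots = standardize(spots)

    col = "z" if value_scale == "z" else "M"
    sig = spots[spots["significant"]]
    # replicate averaging within (strain, tag, day), then unweighted mean
    # of the UP and DN tag values per (strain, day)
    tag_level = sig.groupby(["strain_id", "tag_kind", "day"])[col].mean()
    strain_level = tag_level.groupby(["strain_id", "day"]).mean()
    matrix = strain_level.unstack("day")

    days = sorted(d for d in normalized)
    matrix = matrix.reindex(columns=days)
    all_strains = pd.Index(sorted(set(spots["strain_id"])))
    matrix = matrix.reindex(all_strains)
    matrix = purge_false_barcodes(matrix, key)
    return matrix, TagMatrix(
        spots=spots, thresholds=thresholds, prefilter_spots=prefilter
    )
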