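"""Gene-category enrichment of call sets.

Given a hit set (e.g. all strains depleted during fermentation), a
universe (all genes with significant data in the pool) and a catalogue of
functional categories, each category is scored with the upper tail of the
hypergeometric distribution -- the probability of observing at least k
category members among n hits drawn without replacement from a universe of
N genes containing K category members -- and Bonferroni-adjusted over the
number of categories tested.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .errors import PoolfitError


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    Summed in log space (log-binomials via gammaln, then logsumexp) so
    extreme tails like 1e-300 survive; returns exactly 1.0 for k <= 0.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise PoolfitError(f"{name} must be a nonnegative integer, got {v!r}")
    k, K, n, N = int(k), int(K), int(n), int(N)
    if K > N or n > N:
        raise PoolfitError("require K <= N and n <= N")
    if k > min(K, n):
        raise PoolfitError("require k <= min(K, n)")
    if k <= max(0, n + K - N):
        return 1.0
    j = np.arange(k, min(K, n) + 1)
    log_pmf = _log_comb(K, j) + _log_comb(N - K, n - j) - _log_comb(N, n)
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


def bonferroni(p_raw: float, m: int) -> float:
    """Multiply a raw P by the number of categories tested, capped at 1."""
    if not (0.0 <= p_raw <= 1.0):
        raise PoolfitError(f"p_raw must lie in [0, 1], got {p_raw!r}")
    if m < 1:
        raise PoolfitError(f"m must be >= 1, got {m!r}")
    return min(1.0, m * p_raw)


def enrich_categories(
    hits,
    universe,
    genesets: dict[str, dict],
    manual_additions: dict[str, list] | None = None,
    report_cutoff: float = 0.01,
    m_override: int | None = None,
    include_manual_in_counts: bool = True,
) -> pd.DataFrame:
    """Score every category against a hit set.

    K counts category members present in the universe and k those among
    the hits; categories entirely outside the universe are excluded from
    testing and from the Bonferroni count m (overridable to a fixed
    catalogue size via ``m_override``).  ``manual_additions`` unions extra
    genes into a category before counting (they are flagged in the
    output); results are sorted by adjusted P and flagged reportable at
    ``p_adj <= report_cutoff``.
    """
    hits = set(hits)
    universe = set(universe)
    stray = hits - universe
    if stray:
        raise PoolfitError(f"hit gene {sorted(stray)[0]!r} is not in the universe")
    manual_additions = manual_additions or {}

    rows = []
    n = len(hits)
    N = len(universe)
    for cat_id, rec in genesets.items():
        members = set(rec["members"])
        added = set(manual_additions.get(cat_id, ()))
        if include_manual_in_counts:
            members = members | added
        K = len(members & universe)
        if K == 0:
            continue
        k = len(members & hits)
        rows.append(
            {
                "category_id": cat_id,
                "description": rec.get("description", ""),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "manual_added": len(added & universe),
                "genes": ",".join(sorted(members & hits)),
            }
        )

    m = m_override if m_override is not None else len(rows)
    out = pd.DataFrame(
        rows,
        columns=[
            "category_id", "description", "k", "K", "n", "N",
            "manual_added", "genes",
        ],
    )
    if len(out) == 0:
        out["p_raw"] = out["p_adj"] = out["m"] = out["reportable"] = []
        return out
    out["p_raw"] = [hypergeom_upper(r.k, r.K, n, N) for r in out.itertuples()]
    out["m"] = m
    out["p_adj"] = [bonferroni(p, m) for p in out["p_raw"]]
    out["reportable"] = out["p_adj"] <= report_cutoff
    out = out.sort_values(["p_adj", "p_raw", "category_id"], kind="stable")
    return out.reset_index(drop=True)
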