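"""Two-group comparison of per-peak intensities with the Mann-Whitney U test.

At the study's sample sizes (3 biological x 3 technical replicates per
condition) the natural test is the rank-based Mann-Whitney U with an *exact*
null distribution: the distribution of U over all C(n1+n2, n1) group
labelings of the pooled sample.  The exact distribution is computed by a
dynamic program over mid-ranks (doubled to keep them integral under ties), so
it is available for any feasible n; a tie-corrected normal approximation with
continuity correction is provided for larger samples.

Significance tiers follow the usual star convention: ns (p >= 0.05),
* (< 0.05), ** (< 0.01), *** (< 0.001), **** (< 0.0001).

A deliberate statistical caveat, surfaced here rather than hidden: with three
biological replicates per group and technical replicates averaged away
(``replicate_policy='bio_means'``), the smallest achievable exact two-sided p
is 0.1, so nothing can reach p < 0.05.  Tiers below 0.01 therefore imply
per-spectrum units, which is why ``all_spectra`` is the default policy --
technical replicates are pseudoreplicates, and ``bio_means`` remains the
statistically conservative alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .peaks import load_assignments

MW_MODES = ("exact", "normal_approx", "auto")

#: auto picks the exact distribution up to this pooled size when tie-free ...
AUTO_EXACT_MAX_N = 20
#: ... and up to this pooled size when the pooled sample contains ties.
AUTO_EXACT_MAX_N_TIES = 12

TIER_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_tier(p: float | None) -> str | None:
    if p is None:
        return None
    for threshold, stars in TIER_THRESHOLDS:
        if p < threshold:
            return stars
    return "ns"


@lru_cache(maxsize=4096)
def _rank_sum_distribution(double_ranks: tuple[int, ...], n1: int) -> dict[int, int]:
    """Counts of labelings by doubled rank-sum of the first group.

    ``double_ranks`` are the pooled mid-ranks times two (integers even under
    ties).  Returns {doubled rank-sum: number of C(n, n1) subsets attaining it}.
    """
    counts: list[dict[int, int]] = [dict() for _ in range(n1 + 1)]
    counts[0][0] = 1
    for r in double_ranks:
        for k in range(min(n1, len(double_ranks)) - 1, -1, -1):
            if not counts[k]:
                continue
            nxt = counts[k + 1]
            for s, c in counts[k].items():
                nxt[s + r] = nxt.get(s + r, 0) + c
    return counts[n1]


def _exact_p(ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Exact two-sided p of U by full enumeration over group labelings."""
    double = tuple(int(round(2 * r)) for r in ranks)
    dist = _rank_sum_distribution(double, n1)
    total = sum(dist.values())
    # doubled U = doubled rank-sum - n1 (n1 + 1)
    offset = n1 * (n1 + 1)
    u2_obs = int(round(2 * u_obs))
    le = sum(c for s, c in dist.items() if s - offset <= u2_obs)
    ge = sum(c for s, c in dist.items() if s - offset >= u2_obs)
    p_one = min(le, ge) / total
    return min(1.0, 2.0 * p_one)


def _normal_p(ranks: np.ndarray, n1: int, n2: int, u_obs: float) -> float:
    """Tie-corrected normal approximation with continuity correction."""
    n = n1 + n2
    mean = n1 * n2 / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    num = abs(u_obs - mean) - 0.5  # continuity correction toward the mean
    z = max(num, 0.0) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(z)))


def mann_whitney_u(
    a: np.ndarray, b: np.ndarray, mode: str = "auto"
) -> tuple[float, float]:
    """Mann-Whitney U statistic (for sample ``a``) and two-sided p value.

    U is computed from joint mid-ranks; ``exact`` enumerates the permutation
    distribution of U over all group labelings, ``normal_approx`` uses the
    tie-corrected normal approximation with continuity correction, and
    ``auto`` picks the exact route whenever the pooled sample is small enough
    (tie-free: n <= 20; with ties: n <= 12).
    """
    if mode not in MW_MODES:
        raise ValueError(f"mode must be one of {MW_MODES}, got {mode!r}")
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # mid-ranks under ties
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        limit = AUTO_EXACT_MAX_N_TIES if has_ties else AUTO_EXACT_MAX_N
        mode = "exact" if n1 + n2 <= limit else "normal_approx"
    if mode == "exact":
        p = _exact_p(ranks, n1, u1)
    else:
        p = _normal_p(ranks, n1, n2, u1)
    return u1, p


def exact_null_size(n1: int, n2: int, alpha: float = 0.05) -> float:
    """Achievable size of the exact two-sided test at nominal level ``alpha``.

    For tie-free data the exact test is conservative: its true rejection
    probability under the null is the largest attainable p-value mass below
    ``alpha``, not ``alpha`` itself.
    """
    ranks = np.arange(1, n1 + n2 + 1, dtype=float)
    dist = _rank_sum_distribution(tuple(int(2 * r) for r in ranks), n1)
    total = sum(dist.values())
    reject = 0
    for s, c in dist.items():
        le = sum(cc for ss, cc in dist.items() if ss <= s)
        ge = sum(cc for ss, cc in dist.items() if ss >= s)
        p = min(1.0, 2.0 * min(le, ge) / total)
        if p < alpha:
            reject += c
    return reject / total


def brute_force_exact_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Reference enumeration with :mod:`itertools` (oracle for the DP route)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    n1 = a.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    offset = n1 * (n1 + 1) / 2.0
    u_obs = float(ranks[:n1].sum() - offset)
    us = [
        float(sum(ranks[list(ix)]) - offset)
        for ix in combinations(range(pooled.size), n1)
    ]
    us = np.array(us)
    p_one = min((us <= u_obs).mean(), (us >= u_obs).mean())
    return u_obs, min(1.0, 2.0 * float(p_one))


@dataclass(frozen=True)
class ComparisonResult:
    """Group comparison of one target peak's intensities."""

    target_cm1: float
    n_control: int
    n_abeta: int
    mean_control: float
    sd_control: float
    mean_abeta: float
    sd_abeta: float
    U: float | None
    p_two_sided: float | None
    direction: str  # decrease | increase | none
    tier: str | None  # ns | * | ** | *** | **** | None when excluded
    excluded_by_shift: bool


REPLICATE_POLICIES = ("all_spectra", "bio_means")


def _group_values(sub: pd.DataFrame, policy: str) -> np.ndarray:
    if policy == "bio_means":
        return sub.groupby("bio_rep")["intensity_au"].mean().to_numpy()
    return sub["intensity_au"].to_numpy()


def compare_peaks(
    table: pd.DataFrame,
    replicate_policy: str = "all_spectra",
    mode: str = "auto",
) -> list[ComparisonResult]:
    """Per-target control-vs-abeta comparison of matched peak intensities.

    The unit of analysis is each spectrum (``all_spectra``, the default) or
    each biological replicate's mean over its technical replicates
    (``bio_means``).  Shift-flagged targets are emitted with
    ``excluded_by_shift=True`` and no test; a target with no matched spectra
    in one group is also emitted without a test (with a warning), so the
    report always carries one row per target.  Direction compares group
    means; the tier encodes the fixed p-value thresholds.
    """
    if replicate_policy not in REPLICATE_POLICIES:
        raise ValueError(
            f"replicate_policy must be one of {REPLICATE_POLICIES}, "
            f"got {replicate_policy!r}"
        )
    results: list[ComparisonResult] = []
    for target, grp in table.groupby("target_cm1", sort=True):
        matched = grp[grp["matched"]]
        ctrl = matched[matched["condition"] == "control"]
        trt = matched[matched["condition"] == "abeta"]
        shift = bool(grp["shift_flag"].any())

        if (ctrl.empty or trt.empty) and not shift:
            warnings.warn(
                f"target {target:g} cm^-1: a group has no matched spectra; "
                f"no test performed",
                stacklevel=2,
            )
        va = _group_values(ctrl, replicate_policy) if len(ctrl) else np.array([])
        vb = _group_values(trt, replicate_policy) if len(trt) else np.array([])

        def _mean_sd(v: np.ndarray) -> tuple[float, float]:
            if v.size == 0:
                return float("nan"), float("nan")
            return float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0

        mean_c, sd_c = _mean_sd(va)
        mean_t, sd_t = _mean_sd(vb)

        if shift or va.size == 0 or vb.size == 0:
            results.append(
                ComparisonResult(
                    target_cm1=float(target),
                    n_control=int(va.size),
                    n_abeta=int(vb.size),
                    mean_control=mean_c,
                    sd_control=sd_c,
                    mean_abeta=mean_t,
                    sd_abeta=sd_t,
                    U=None,
                    p_two_sided=None,
                    direction="none",
                    tier=None,
                    excluded_by_shift=shift,
                )
            )
            continue

        u, p = mann_whitney_u(va, vb, mode=mode)
        if mean_t < mean_c:
            direction = "decrease"
        elif mean_t > mean_c:
            direction = "increase"
        else:
            direction = "none"
        results.append(
            ComparisonResult(
                target_cm1=float(target),
                n_control=int(va.size),
                n_abeta=int(vb.size),
                mean_control=mean_c,
                sd_control=sd_c,
                mean_abeta=mean_t,
                sd_abeta=sd_t,
                U=u,
                p_two_sided=p,
                direction=direction,
                tier=significance_tier(p),
                excluded_by_shift=False,
            )
        )
    return results


def summarize(
    results: list[ComparisonResult],
    assignments: pd.DataFrame | None = None,
    fdr: bool = False,
) -> pd.DataFrame:
    """Tidy report table, one row per target, joined with assignment text.

    With ``fdr=True`` a ``q`` column of Benjamini-Hochberg adjusted p values
    is added (off by default: the workflow tests each peak at 0.05 without
    multiplicity correction, and the q values are provided for readers who
    want it).
    """
    columns = [
        "target_cm1", "assignment", "n_ctrl", "n_abeta", "mean_ctrl", "sd_ctrl",
        "mean_abeta", "sd_abeta", "U", "p", "tier", "direction",
        "excluded_by_shift",
    ]
    if fdr:
        columns = columns + ["q"]
    if not results:
        return pd.DataFrame(columns=columns)
    if assignments is None:
        assignments = load_assignments()
    amap = dict(zip(assignments["wavenumber"].astype(float), assignments["assignment"]))
    rows = []
    for r in sorted(results, key=lambda r: -r.target_cm1):
        rows.append(
            {
                "target_cm1": r.target_cm1,
                "assignment": amap.get(r.target_cm1, ""),
                "n_ctrl": r.n_control,
                "n_abeta": r.n_abeta,
                "mean_ctrl": r.mean_control,
                "sd_ctrl": r.sd_control,
                "mean_abeta": r.mean_abeta,
                "sd_abeta": r.sd_abeta,
                "U": r.U,
                "p": r.p_two_sided,
                "tier": r.tier,
                "direction": r.direction,
                "excluded_by_shift": r.excluded_by_shift,
            }
        )
    out = pd.DataFrame(rows, columns=columns)
    if fdr:
        from scipy.stats import false_discovery_control

        tested = out["p"].notna()
        out["q"] = np.nan
        if tested.any():
            out.loc[tested, "q"] = false_discovery_control(
                out.loc[tested, "p"].to_numpy(), method="bh"
            )
    return out
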