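"""Exact small-sample nonparametric cohort statistics.

Paired pre/post rates from a handful of subjects call for exact inference:

* Wilcoxon signed-rank with midranks for tied |differences|, zero
  differences dropped, exact two-tailed p by full enumeration of the 2^n
  sign patterns (n ≤ 25 via meet-in-the-middle subset sums), and an
  asymptotic normal statistic with tie-corrected variance and *no*
  continuity correction, signed from the smaller rank sum (SPSS
  convention, so an all-positive n = 7 sample gives Z = −2.366).
* Kendall tau-b with tie corrections; exact permutation p for n ≤ 8,
  asymptotic otherwise.
* A Monte-Carlo Kolmogorov–Smirnov normality screen with parameters
  estimated from the sample (Lilliefors-style null).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedSample",
    "TestResult",
    "wilcoxon_signed_rank",
    "kendall_tau_b",
    "ks_normality",
    "run_cohort_analysis",
    "CohortReport",
]

ZERO_TOL = 1e-12


@dataclass(frozen=True)
class PairedSample:
    """Paired pre/post measurements keyed by subject id."""

    subject_ids: tuple
    pre: np.ndarray
    post: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "pre", np.asarray(self.pre, dtype=float))
        object.__setattr__(self, "post", np.asarray(self.post, dtype=float))
        if not (len(self.subject_ids) == len(self.pre) == len(self.post)):
            raise ValueError("ids, pre and post must have equal length")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("subject ids must be unique")

    @property
    def differences(self) -> np.ndarray:
        return self.post - self.pre


@dataclass
class TestResult:
    name: str
    statistic: float
    p_two_tailed: float
    z: float | None = None
    method: str = "exact"
    n_effective: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_two_tailed <= 1.0):
            raise ValueError("p must lie in [0, 1]")


# --------------------------------------------------------------------------
# Wilcoxon signed-rank
# --------------------------------------------------------------------------

def _subset_sums(values: np.ndarray) -> np.ndarray:
    """All 2^k subset sums of ``values`` (iterative doubling)."""
    sums = np.zeros(1)
    for v in values:
        sums = np.concatenate([sums, sums + v])
    return sums


def _exact_wilcoxon_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-tailed exact p for W+ under the symmetric null.

    Enumerates the 2^n equiprobable sign patterns via meet-in-the-middle:
    p = P(W+ ≤ w_small) + P(W+ ≥ W_total − w_small) where w_small is the
    smaller of the two rank sums.
    """
    n = len(ranks)
    total = float(ranks.sum())
    w_small = min(w_plus, total - w_plus)
    lo_thresh = w_small + 1e-9
    hi_thresh = total - w_small - 1e-9

    half = n // 2
    a = np.sort(_subset_sums(ranks[:half]))
    b = np.sort(_subset_sums(ranks[half:]))
    # P(A + B <= t) via searchsorted over sorted halves
    count_le = int(np.searchsorted(b, lo_thresh - a, side="right").sum())
    count_ge = int((len(b) - np.searchsorted(b, hi_thresh - a, side="left")).sum())
    p = (count_le + count_ge) / 2.0**n
    return min(p, 1.0)


def wilcoxon_signed_rank(
    sample: PairedSample, method: str = "auto", exact_limit: int = 25
) -> TestResult:
    """Two-tailed Wilcoxon signed-rank test on post − pre.

    Zero differences (|d| ≤ 1e-12) are dropped; |d| are midranked.  The
    asymptotic Z uses mean n(n+1)/4 and tie-corrected variance
    n(n+1)(2n+1)/24 − Σ(t³−t)/48, without continuity correction, and is
    computed from the smaller rank sum (hence Z ≤ 0).  ``method='auto'``
    selects exact enumeration for n ≤ ``exact_limit``.
    """
    if method not in ("exact", "asymptotic", "auto"):
        raise ValueError("method must be exact|asymptotic|auto")
    d = sample.differences
    d = d[np.abs(d) > ZERO_TOL]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero")

    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    total = float(ranks.sum())
    w_minus = total - w_plus
    w_small = min(w_plus, w_minus)

    mean = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_small - mean) / math.sqrt(var) if var > 0 else 0.0

    use_exact = method == "exact" or (method == "auto" and n <= exact_limit)
    if method == "exact" and n > exact_limit:
        raise ValueError(f"exact enumeration limited to n <= {exact_limit}")
    if use_exact:
        p = _exact_wilcoxon_p(ranks, w_plus)
        used = "exact"
    else:
        p = min(2.0 * sps.norm.cdf(z), 1.0)
        used = "asymptotic"
    return TestResult(
        name="wilcoxon_signed_rank",
        statistic=w_small,
        p_two_tailed=p,
        z=z,
        method=used,
        n_effective=n,
        extras={"w_plus": w_plus, "w_minus": w_minus},
    )


# --------------------------------------------------------------------------
# Kendall tau-b
# --------------------------------------------------------------------------

def _tau_b_pair_counts(x: np.ndarray, y: np.ndarray) -> float:
    """O(n²) concordant/discordant count with tie corrections."""
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                ties_x += 1
                ties_y += 1
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n_pairs = n * (n - 1) / 2
    denom = math.sqrt((n_pairs - ties_x) * (n_pairs - ties_y))
    if denom == 0:
        raise ValueError("tau-b undefined: an input is constant")
    return (concordant - discordant) / denom


def kendall_tau_b(x, y, method: str = "auto", exact_limit: int = 8) -> TestResult:
    """Kendall rank correlation tau-b with exact small-sample p.

    For n ≤ ``exact_limit`` the two-tailed p is the fraction of all n!
    permutations of y whose |tau-b| is at least the observed |tau-b|;
    otherwise the tie-aware asymptotic normal approximation is used
    (delegated to scipy).
    """
    if method not in ("exact", "asymptotic", "auto"):
        raise ValueError("method must be exact|asymptotic|auto")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("tau-b undefined for constant input")

    tau = _tau_b_pair_counts(x, y)
    use_exact = method == "exact" or (method == "auto" and n <= exact_limit)
    if method == "exact" and n > exact_limit:
        raise ValueError(f"exact enumeration limited to n <= {exact_limit}")
    if use_exact:
        target = abs(tau) - 1e-12
        count = total = 0
        for perm in itertools.permutations(y):
            total += 1
            if abs(_tau_b_pair_counts(x, np.array(perm))) >= target:
                count += 1
        p = count / total
        used = "exact"
        z = None
    else:
        res = sps.kendalltau(x, y, variant="b", method="asymptotic")
        p = float(res.pvalue)
        z = float(sps.norm.isf(p / 2.0)) * (-1.0 if tau < 0 else 1.0)
        used = "asymptotic"
    return TestResult(
        name="kendall_tau_b",
        statistic=tau,
        p_two_tailed=min(p, 1.0),
        z=z,
        method=used,
        n_effective=n,
    )


# --------------------------------------------------------------------------
# KS normality (Lilliefors-style Monte-Carlo null)
# --------------------------------------------------------------------------

def ks_normality(x, n_replicates: int = 2000, seed: int = 0) -> TestResult:
    """Kolmogorov–Smirnov D against a normal with estimated mean/sd.

    Because the null parameters are estimated from the sample, the
    classical KS null distribution does not apply; the p-value is obtained
    from ``n_replicates`` Monte-Carlo draws of normal samples of the same
    size with parameters re-estimated per draw (add-one estimator).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance sample")
    d_obs = float(sps.kstest(x, "norm", args=(x.mean(), sd)).statistic)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_replicates):
        sim = rng.standard_normal(n)
        d_sim = sps.kstest(sim, "norm", args=(sim.mean(), sim.std(ddof=1))).statistic
        if d_sim >= d_obs:
            exceed += 1
    p = (exceed + 1) / (n_replicates + 1)
    return TestResult(
        name="ks_normality",
        statistic=d_obs,
        p_two_tailed=min(p, 1.0),
        method="monte_carlo",
        n_effective=n,
        extras={"n_replicates": n_replicates, "seed": seed},
    )


# --------------------------------------------------------------------------
# cohort report
# --------------------------------------------------------------------------

@dataclass
class CohortReport:
    """Cohort-level inference summary across metabolites."""

    tests: dict                 # metabolite -> TestResult | str
    n_increased: dict           # metabolite -> int
    n_pairs: int
    kendall_age: TestResult | None = None
    tables: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def encode(t):
            if isinstance(t, str):
                return t
            return {
                "statistic": t.statistic,
                "z": t.z,
                "p_two_tailed": t.p_two_tailed,
                "method": t.method,
                "n": t.n_effective,
            }

        out = {
            "n_pairs": self.n_pairs,
            "tests": {m: encode(t) for m, t in self.tests.items()},
            "n_increased": dict(self.n_increased),
        }
        if self.kendall_age is not None:
            out["kendall_age_vs_delta_kf"] = encode(self.kendall_age)
        return out


def run_cohort_analysis(results, ages: dict | None = None) -> CohortReport:
    """Paired pre/post inference from per-subject kinetic results.

    ``results`` is a list of :class:`mtmrs.exchange_kinetics.SubjectResult`;
    unpaired subjects are excluded with a warning.  Emits per-metabolite
    Wilcoxon tests, counts of subjects whose rate increased, and — when
    ages are available — the Kendall tau-b correlation between age and the
    Pi rate change.
    """
    import warnings

    import pandas as pd

    by_subject: dict = {}
    for r in results:
        by_subject.setdefault(r.subject_id, {})[r.session] = r
    paired = {
        sid: sess for sid, sess in by_subject.items()
        if "pre" in sess and "post" in sess
    }
    dropped = set(by_subject) - set(paired)
    if dropped:
        warnings.warn(f"excluding unpaired subjects: {sorted(dropped)}")
    if len(paired) < 2:
        raise ValueError("need at least 2 complete pre/post pairs")

    sids = sorted(paired)
    tests: dict = {}
    n_increased: dict = {}
    rows = []
    for metabolite, attr in (("Pi_i", "kf_pi"), ("PCr", "kf_pcr")):
        pre, post, ok_ids = [], [], []
        for sid in sids:
            fit_pre = getattr(paired[sid]["pre"], attr)
            fit_post = getattr(paired[sid]["post"], attr)
            if fit_pre is None or fit_post is None:
                continue
            pre.append(fit_pre.kf)
            post.append(fit_post.kf)
            ok_ids.append(sid)
        if len(ok_ids) < 2:
            continue
        pre = np.array(pre)
        post = np.array(post)
        n_increased[metabolite] = int(np.sum(post > pre))
        sample = PairedSample(tuple(ok_ids), pre, post)
        try:
            tests[metabolite] = wilcoxon_signed_rank(sample)
        except ValueError as exc:
            tests[metabolite] = f"no change ({exc})"
        for sid, a, b in zip(ok_ids, pre, post):
            rows.append(
                {"subject_id": sid, "metabolite": metabolite,
                 "kf_pre": a, "kf_post": b, "delta_kf": b - a}
            )

    kendall_age = None
    if ages:
        deltas, age_vals = [], []
        for sid in sids:
            fit_pre = paired[sid]["pre"].kf_pi
            fit_post = paired[sid]["post"].kf_pi
            if fit_pre is None or fit_post is None or sid not in ages:
                continue
            deltas.append(fit_post.kf - fit_pre.kf)
            age_vals.append(ages[sid])
        if len(deltas) >= 3:
            kendall_age = kendall_tau_b(age_vals, deltas)

    return CohortReport(
        tests=tests,
        n_increased=n_increased,
        n_pairs=len(sids),
        kendall_age=kendall_age,
        tables={"per_subject": pd.DataFrame(rows)},
    )
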