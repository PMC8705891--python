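"""Outcome statistics: engine comparison, agreement and responder analysis.

Implements the statistical battery used to compare the two kinematics
engines and to classify surgical outcome:

* per-variable waveform RMSD and linear-fit R^2 between engines;
* Bland-Altman agreement on changes in GPS;
* paired tests (Wilcoxon, paired t, Spearman, Pearson);
* a pointwise paired waveform comparison by a maximum-statistic permutation
  test with Bonferroni family correction across the nine variables (the
  self-contained replacement for random-field-theory SPM);
* Kruskal-Wallis + Dunn post hoc comparison of knee-axis corrections;
* responder classification at the GPS minimal clinically important
  difference (MCID, 1.6 deg) and agreement tabulation against clinical
  labels.

Change in GPS is oriented post - pre, so improvement is negative and the
responder criterion is delta <= -MCID (boundary inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ResolutionError, ValidationError
from .metrics import VARIABLES, GaitCycleWaveforms

MCID_GPS = 1.6   # degrees; minimal clinically important difference for GPS

RESPONDER, NON_RESPONDER = "responder", "non-responder"


# ---------------------------------------------------------------------------
# Responder classification and outcome records
# ---------------------------------------------------------------------------

def classify_responder(delta_gps: float, mcid: float = MCID_GPS) -> str:
    """Responder iff the GPS change satisfies delta <= -mcid (inclusive)."""
    if not math.isfinite(delta_gps):
        raise ValidationError(f"non-finite GPS change: {delta_gps}")
    if mcid < 0:
        raise ValidationError("mcid must be non-negative")
    return RESPONDER if delta_gps <= -mcid else NON_RESPONDER


@dataclass
class OutcomeRecord:
    """Per-limb pre/post GPS pair for both engines with labels."""

    subject: str
    limb: str
    operated: bool
    gps_pre: dict[str, float]          # engine ("dk"|"ik") -> degrees
    gps_post: dict[str, float]
    clinical_label: str | None = None
    mcid: float = MCID_GPS
    delta_gps: dict[str, float] = field(init=False)
    responder: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        if set(self.gps_pre) != set(self.gps_post):
            raise ValidationError("gps_pre and gps_post must cover the same engines")
        self.delta_gps = {e: self.gps_post[e] - self.gps_pre[e] for e in self.gps_pre}
        self.responder = {e: classify_responder(d, self.mcid)
                          for e, d in self.delta_gps.items()}


@dataclass
class AgreementSummary:
    n_limbs: int
    engine_vs_clinical: dict[str, int]
    engine_concordance: int
    discordant: list[dict]

    def __post_init__(self) -> None:
        if any(v > self.n_limbs for v in self.engine_vs_clinical.values()):
            raise ValidationError("agreement count exceeds limb count")
        if not 0 <= self.engine_concordance <= self.n_limbs:
            raise ValidationError("concordance count out of range")


def tabulate_agreement(records: list[OutcomeRecord]) -> AgreementSummary:
    """Engine-vs-clinical and engine-vs-engine agreement over operated limbs.

    Non-operated limbs are filtered out here (only limbs that underwent the
    surgery enter the agreement analysis).  Discordant limbs are listed with
    the between-engine difference in GPS change.
    """
    operated = [r for r in records if r.operated]
    engines = sorted(operated[0].gps_pre) if operated else ["dk", "ik"]
    agree = dict.fromkeys(engines, 0)
    concordant = 0
    discordant: list[dict] = []
    for rec in operated:
        if rec.clinical_label is None:
            raise ValidationError(
                f"missing clinical label for {rec.subject}/{rec.limb}")
        for e in engines:
            agree[e] += int(rec.responder[e] == rec.clinical_label)
        labels = {rec.responder[e] for e in engines}
        if len(labels) == 1:
            concordant += 1
        else:
            deltas = [rec.delta_gps[e] for e in engines]
            discordant.append({
                "subject": rec.subject, "limb": rec.limb,
                **{f"delta_gps_{e}": rec.delta_gps[e] for e in engines},
                "inter_engine_delta_diff": float(abs(deltas[0] - deltas[1])),
            })
    return AgreementSummary(n_limbs=len(operated), engine_vs_clinical=agree,
                            engine_concordance=concordant, discordant=discordant)


# ---------------------------------------------------------------------------
# Waveform similarity
# ---------------------------------------------------------------------------

def _paired_values(a: GaitCycleWaveforms, b: GaitCycleWaveforms):
    if a.values.shape != b.values.shape:
        raise ValidationError("waveform grids do not match")
    return a.values, b.values


def waveform_rmsd(a: GaitCycleWaveforms, b: GaitCycleWaveforms) -> dict[str, float]:
    """Per-variable RMS of pointwise differences (degrees)."""
    va, vb = _paired_values(a, b)
    rms = np.sqrt(np.mean((va - vb) ** 2, axis=1))
    return dict(zip(VARIABLES, rms.tolist()))


def waveform_r2(a: GaitCycleWaveforms, b: GaitCycleWaveforms) -> dict[str, float]:
    """Per-variable coefficient of determination of the linear fit of a on b."""
    va, vb = _paired_values(a, b)
    out = {}
    for i, var in enumerate(VARIABLES):
        x, y = vb[i], va[i]
        if np.ptp(x) < 1e-12:
            raise ValidationError(f"constant predictor waveform for {var}; R^2 undefined")
        slope, intercept = np.polyfit(x, y, 1)
        ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        out[var] = 1.0 if ss_tot == 0 and ss_res == 0 else 1.0 - ss_res / max(ss_tot, 1e-300)
    return out


# ---------------------------------------------------------------------------
# Agreement statistics
# ---------------------------------------------------------------------------

@dataclass
class BlandAltman:
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    n: int


def bland_altman(x, y) -> BlandAltman:
    """Bland-Altman agreement: bias = mean(x - y), limits bias +/- 1.96 sd
    (sample standard deviation, n-1 denominator)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("bland_altman needs two equal-length 1-D samples")
    if x.size < 2:
        raise ValidationError("bland_altman needs at least two pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias=bias, sd=sd, loa_low=bias - 1.96 * sd,
                       loa_high=bias + 1.96 * sd, n=x.size)


def paired_tests(dk_values, ik_values, kind: str):
    """Named paired statistic between the two engines' value lists.

    Returns ``(statistic, p_value, method_note)``.  Ties receive average
    ranks; Wilcoxon drops zero differences (documented policy).
    """
    x = np.asarray(dk_values, float)
    y = np.asarray(ik_values, float)
    if x.shape != y.shape:
        raise ValidationError("paired samples must have equal length")
    if x.size < 3:
        raise ValidationError("paired tests need n >= 3")
    if kind == "wilcoxon":
        if np.all(x == y):
            return 0.0, 1.0, "wilcoxon (all differences zero)"
        res = sps.wilcoxon(x, y, zero_method="wilcox")
        return float(res.statistic), float(res.pvalue), "wilcoxon, zeros dropped, average ranks"
    if kind == "paired_t":
        res = sps.ttest_rel(x, y)
        return float(res.statistic), float(res.pvalue), "paired t"
    if kind == "spearman":
        res = sps.spearmanr(x, y)
        return float(res.statistic), float(res.pvalue), "spearman, average ranks"
    if kind == "pearson":
        res = sps.pearsonr(x, y)
        return float(res.statistic), float(res.pvalue), "pearson"
    raise ValidationError(f"unknown paired test kind {kind!r}")


# ---------------------------------------------------------------------------
# Pointwise waveform comparison (permutation max-statistic test)
# ---------------------------------------------------------------------------

@dataclass
class WaveformTestResult:
    alpha_per_test: float
    masks: dict[str, np.ndarray]       # variable -> (T,) bool significance mask
    t_observed: dict[str, np.ndarray]
    thresholds: dict[str, float]
    p_values: dict[str, float]         # permutation p of the max statistic
    n_permutations: int


def _stack_groups(group) -> np.ndarray:
    """(n_subjects, 9, T) array from a list of GaitCycleWaveforms or array."""
    if isinstance(group, np.ndarray):
        return group
    arr = np.stack([w.values for w in group])
    return arr


def pointwise_waveform_test(group_a, group_b, alpha_family: float = 0.05,
                            n_comparisons: int = 9, n_permutations: int = 1000,
                            seed: int = 0) -> WaveformTestResult:
    """Paired pointwise waveform comparison with family-wise error control.

    For each variable, the paired t statistic is computed at every time
    point and compared against the permutation distribution of the
    maximum-over-time |t| under random sign flips of the subject-level
    difference waveforms — controlling the family-wise error over time
    within a variable.  Across variables the per-test level is Bonferroni
    corrected: alpha = alpha_family / n_comparisons (0.05/9 = 0.0056).
    """
    A = _stack_groups(group_a)
    B = _stack_groups(group_b)
    if A.shape != B.shape:
        raise ValidationError("paired groups must have identical shapes")
    if A.ndim == 2:
        A, B = A[:, None, :], B[:, None, :]
    n, n_var, T = A.shape
    if n < 2:
        raise ValidationError("pointwise test needs >= 2 paired subjects")
    if n_permutations < 100:
        raise ValidationError("n_permutations must be >= 100")
    alpha = alpha_family / n_comparisons
    k = int(np.floor(alpha * (n_permutations + 1)))
    if k < 1:
        raise ResolutionError(
            f"{n_permutations} permutations cannot resolve alpha = {alpha:.4g}; "
            f"need at least {int(np.ceil(1 / alpha))}")

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
    var_names = list(VARIABLES[:n_var]) if n_var <= 9 else [str(i) for i in range(n_var)]

    def tstat(D):
        mean = D.mean(axis=0)
        sd = D.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(n))
        t = np.where(sd == 0, np.where(mean == 0, 0.0, np.inf), t)
        return t

    masks, tobs_d, thresholds, pvals = {}, {}, {}, {}
    for v, name in enumerate(var_names):
        D = A[:, v, :] - B[:, v, :]
        t_obs = tstat(D)
        # permutation null of max |t| under sign flips
        null = np.empty(n_permutations)
        mean_p = signs @ D / n                         # (P, T)
        # sd of sign-flipped differences: E[x^2] unchanged by flips
        ex2 = np.mean(D ** 2, axis=0)
        sd_p = np.sqrt(np.maximum(ex2 - mean_p ** 2, 0.0) * n / (n - 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_p = mean_p / (sd_p / np.sqrt(n))
        t_p = np.where(sd_p == 0, np.where(mean_p == 0, 0.0, np.inf), t_p)
        null = np.max(np.abs(t_p), axis=1)
        thr = float(np.sort(null)[::-1][k - 1])
        obs_max = float(np.max(np.abs(t_obs)))
        pvals[name] = float((1 + np.sum(null >= obs_max)) / (n_permutations + 1))
        thresholds[name] = thr
        masks[name] = np.abs(t_obs) >= thr if obs_max > 0 else np.zeros(T, bool)
        tobs_d[name] = t_obs
    return WaveformTestResult(alpha_per_test=alpha, masks=masks, t_observed=tobs_d,
                              thresholds=thresholds, p_values=pvals,
                              n_permutations=n_permutations)


# ---------------------------------------------------------------------------
# Group comparison of knee-axis corrections
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    statistic: float
    p_omnibus: float
    pairwise: pd.DataFrame      # group_a, group_b, z, p_unadjusted, p_bonferroni


def group_axis_comparison(corrections: dict[str, np.ndarray]) -> GroupComparison:
    """Kruskal-Wallis omnibus + Dunn pairwise z tests on per-group samples.

    Dunn p-values are reported unadjusted alongside Bonferroni-adjusted
    values (adjusted over the number of pairwise comparisons).
    """
    groups = {k: np.asarray(v, float) for k, v in corrections.items()}
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    for name, vals in groups.items():
        if vals.size < 2:
            raise ValidationError(f"group {name!r} has fewer than two observations")
    H, p = sps.kruskal(*groups.values())

    pooled = np.concatenate(list(groups.values()))
    ranks = sps.rankdata(pooled)
    N = pooled.size
    idx = 0
    mean_rank, sizes = {}, {}
    for name, vals in groups.items():
        mean_rank[name] = float(ranks[idx:idx + vals.size].mean())
        sizes[name] = vals.size
        idx += vals.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12 * (N - 1))
    sigma2 = N * (N + 1) / 12.0 - tie_term

    rows = []
    pairs = list(combinations(groups, 2))
    for a, b in pairs:
        se = math.sqrt(sigma2 * (1 / sizes[a] + 1 / sizes[b]))
        z = 0.0 if se == 0 else (mean_rank[a] - mean_rank[b]) / se
        p_un = 2 * (1 - sps.norm.cdf(abs(z)))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_unadjusted": p_un,
                     "p_bonferroni": min(1.0, p_un * len(pairs))})
    return GroupComparison(statistic=float(H), p_omnibus=float(p),
                           pairwise=pd.DataFrame(rows))
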