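"""Discovery of group-enriched functions by three independent routes.

1. LEfSe-style: a Kruskal-Wallis screen across the three groups, pairwise
   Wilcoxon rank-sum consistency checks (strict = every comparison against
   the top-mean class significant; less-strict = at least one), and a
   bootstrapped linear-discriminant effect size reported on a log10 scale
   with the conventional threshold of 2.0 on per-million-scaled profiles.
2. STAMP-style: one-way ANOVA with eta-squared effect sizes, Tukey-Kramer
   post-hoc pairwise comparisons (unequal group sizes allowed), and
   Benjamini-Hochberg correction across features at q <= 0.05.
3. Importance ranking: low-count/prevalence and low-variance (IQR) filters,
   cumulative sum scaling, then mean-decrease-accuracy importances from a
   bagged decision-tree ensemble with out-of-bag evaluation.

All stochastic steps are driven by an explicit integer seed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.tree import DecisionTreeClassifier
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300


@dataclass
class SignatureRecord:
    """One function flagged as enriched in one group."""

    function_id: str
    level: str
    enriched_group: str
    kw_p: float
    pairwise_p: dict
    lda_score: float
    mode: str


@dataclass
class DiffTestResult:
    """ANOVA route result for one function."""

    function_id: str
    anova_p: float
    eta_squared: float
    tukey_pairwise: dict
    bh_q: float


@dataclass
class FilterConfig:
    """Low-count / low-variance filter settings (module defaults)."""

    min_count: float = 2
    min_prevalence: float = 0.20
    variance_drop_fraction: float = 0.10
    css_quantile: float = 0.5

    def __post_init__(self) -> None:
        for name in ("min_prevalence", "variance_drop_fraction", "css_quantile"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class ImportanceResult:
    """Ranked features with mean-decrease-accuracy scores and OOB error."""

    ranking: pd.DataFrame          # feature, importance, rank (top n)
    importances: pd.Series         # all surviving features
    oob_error: float
    oob_curve: pd.DataFrame        # n_trees, oob_error


# ---------------------------------------------------------------------------
# LEfSe-style route
# ---------------------------------------------------------------------------

def _group_arrays(values: np.ndarray, groups: pd.Series) -> dict[str, np.ndarray]:
    return {g: values[(groups == g).to_numpy()] for g in sorted(groups.unique())}


def kruskal_screen(profile: pd.DataFrame, groups: pd.Series,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Kruskal-Wallis rank test per feature; keep candidates with p < alpha.

    Uses midranks with the standard tie correction.  Features constant
    across all samples carry no rank information and get p = 1, so they are
    never candidates.  Returns a frame (function, h, p) for the candidates.
    """
    groups = groups.loc[profile.index]
    labels = sorted(groups.unique())
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    counts = groups.value_counts()
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 samples")
    rows = []
    for f in profile.columns:
        vals = profile[f].to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            continue
        arrs = [vals[(groups == g).to_numpy()] for g in labels]
        h, p = stats.kruskal(*arrs)
        if p < alpha:
            rows.append({"function": f, "h": float(h), "p": float(p)})
    return pd.DataFrame(rows, columns=["function", "h", "p"])


def pairwise_consistency(values: np.ndarray, groups: pd.Series, mode: str,
                         alpha: float = 0.05):
    """Wilcoxon rank-sum consistency of one feature across groups.

    The putatively enriched class is the one with maximal mean.  In strict
    mode every two-sided rank-sum comparison of that class against each
    other class must be significant with the enriched class's mean strictly
    larger; in less-strict mode at least one such comparison suffices.

    Returns ``(passed, enriched_group, pairwise_p)``.
    """
    if mode not in ("strict", "less-strict"):
        raise ValueError(f"unknown mode {mode!r}")
    arrs = _group_arrays(np.asarray(values, dtype=float), groups)
    means = {g: a.mean() for g, a in arrs.items()}
    top = min(means, key=lambda g: (-means[g], g))
    pvals: dict[tuple[str, str], float] = {}
    hits = 0
    ok = True
    for g, a in arrs.items():
        if g == top:
            continue
        res = stats.mannwhitneyu(arrs[top], a, alternative="two-sided",
                                 method="auto")
        pvals[(top, g)] = float(res.pvalue)
        significant = res.pvalue < alpha and means[top] > means[g]
        hits += significant
        ok = ok and significant
    passed = ok if mode == "strict" else hits >= 1
    return passed, top, pvals


def lda_effect_size(profile: pd.DataFrame, groups: pd.Series,
                    n_boot: int = 30, seed: int = 0,
                    subsample: float = 2 / 3) -> pd.Series:
    """Bootstrapped linear-discriminant effect size per feature (log10).

    The profile is expected pre-scaled to relative abundance per million.
    Each round subsamples ``subsample`` of every class without replacement,
    fits a linear discriminant on the class labels, and scores each feature
    as half the sum of (i) the largest absolute between-class difference of
    its mean and (ii) the same difference projected through the feature's
    unit-normalized first-axis discriminant coefficient.  The effect size is
    ``log10(1 + mean round score)``.  Rounds where the discriminant cannot
    be fitted (a class collapses to constants) are skipped and logged.
    """
    groups = groups.loc[profile.index]
    labels = sorted(groups.unique())
    rng = np.random.default_rng(seed)
    X = profile.to_numpy(dtype=float)
    garr = groups.to_numpy()
    idx_by_class = {g: np.flatnonzero(garr == g) for g in labels}
    scores = np.zeros((0, X.shape[1]))
    skipped = 0
    for _ in range(n_boot):
        # one global permutation per round; each class keeps its first 2/3
        # in permutation order, so renaming classes cannot change the
        # retained sample set (label-swap symmetry)
        order = rng.permutation(X.shape[0])
        rank = np.empty_like(order)
        rank[order] = np.arange(len(order))
        take = []
        for g in labels:
            idx = idx_by_class[g]
            k = min(max(2, int(round(subsample * len(idx)))), len(idx))
            take.append(idx[np.argsort(rank[idx], kind="stable")[:k]])
        sel = np.concatenate(take)
        Xs, ys = X[sel], groups.to_numpy()[sel]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lda = LinearDiscriminantAnalysis(solver="svd")
                lda.fit(Xs, ys)
            w = lda.scalings_[:, 0]
        except Exception as exc:  # singular class structure in this round
            skipped += 1
            logger.debug("lda round skipped: %s", exc)
            continue
        norm = math.sqrt(float(w @ w))
        w_unit = w / norm if norm > 0 else w
        mus = np.stack([Xs[ys == g].mean(axis=0) for g in labels])
        dmax = np.zeros(X.shape[1])
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                dmax = np.maximum(dmax, np.abs(mus[i] - mus[j]))
        round_score = 0.5 * (dmax + np.abs(w_unit) * dmax)
        scores = np.vstack([scores, round_score])
    if skipped:
        logger.warning("lda_effect_size: %d/%d bootstrap rounds skipped",
                       skipped, n_boot)
    if scores.shape[0] == 0:
        raise RuntimeError("all bootstrap rounds failed")
    return pd.Series(np.log10(1.0 + scores.mean(axis=0)),
                     index=profile.columns)


def to_per_million(profile: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample to relative abundance x 10^6 (total sum scaling)."""
    totals = profile.sum(axis=1)
    if (totals <= 0).any():
        bad = list(profile.index[totals <= 0])
        raise ValueError(f"sample(s) with zero total abundance: {bad}")
    return profile.div(totals, axis=0) * 1e6


def lefse(profile: pd.DataFrame, groups: pd.Series, *, level: str = "gene",
          alpha: float = 0.05, lda_min: float = 2.0, mode: str = "strict",
          n_boot: int = 30, seed: int = 0) -> list[SignatureRecord]:
    """LEfSe-style biomarker discovery.

    Composition: per-million rescaling -> Kruskal-Wallis screen at ``alpha``
    -> pairwise rank-sum consistency in ``mode`` -> bootstrapped LDA effect
    size, retaining features with log10 score >= ``lda_min``.
    """
    groups = groups.loc[profile.index]
    rel = to_per_million(profile)
    kw = kruskal_screen(rel, groups, alpha=alpha)
    survivors, direction, pair_p = [], {}, {}
    for _, row in kw.iterrows():
        f = row["function"]
        passed, top, pvals = pairwise_consistency(
            rel[f].to_numpy(), groups, mode=mode, alpha=alpha)
        if passed:
            survivors.append(f)
            direction[f] = top
            pair_p[f] = pvals
    if not survivors:
        return []
    scores = lda_effect_size(rel[survivors], groups, n_boot=n_boot, seed=seed)
    kw_p = kw.set_index("function")["p"]
    records = []
    for f in survivors:
        if scores[f] >= lda_min:
            records.append(SignatureRecord(
                function_id=f, level=level, enriched_group=direction[f],
                kw_p=float(kw_p[f]), pairwise_p=pair_p[f],
                lda_score=float(scores[f]), mode=mode))
    return records


def signatures_to_frame(records: list[SignatureRecord]) -> pd.DataFrame:
    cols = ["function_id", "level", "enriched_group", "kw_p", "lda_score",
            "mode"]
    return pd.DataFrame(
        [{c: getattr(r, c) for c in cols} for r in records], columns=cols)


# ---------------------------------------------------------------------------
# STAMP-style route
# ---------------------------------------------------------------------------

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone q-values)."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def _anova_one(vals: np.ndarray, groups: pd.Series) -> tuple[float, float]:
    """One-way fixed-effects ANOVA p-value and eta-squared for one feature."""
    labels = sorted(groups.unique())
    grand = vals.mean()
    ss_total = float(((vals - grand) ** 2).sum())
    ss_between = 0.0
    for g in labels:
        a = vals[(groups == g).to_numpy()]
        ss_between += len(a) * (a.mean() - grand) ** 2
    if ss_total == 0:
        return 1.0, 0.0
    eta2 = ss_between / ss_total
    ss_within = ss_total - ss_between
    df_b, df_w = len(labels) - 1, len(vals) - len(labels)
    if ss_within <= 0:
        return (P_FLOOR if ss_between > 0 else 1.0), eta2
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return max(p, P_FLOOR), eta2


def stamp_anova(profile: pd.DataFrame, groups: pd.Series,
                q_max: float = 0.05,
                return_all: bool = False) -> list[DiffTestResult]:
    """ANOVA + Tukey-Kramer + eta-squared + Benjamini-Hochberg per feature.

    BH is applied across the features of the given profile (one level at a
    time).  By default only features with q <= ``q_max`` are returned.
    """
    groups = groups.loc[profile.index]
    if groups.nunique() < 2:
        raise ValueError("need at least 2 groups")
    feats = list(profile.columns)
    pvals, etas, tukeys = [], [], []
    garr = groups.to_numpy()
    for f in feats:
        vals = profile[f].to_numpy(dtype=float)
        p, eta2 = _anova_one(vals, groups)
        pvals.append(p)
        etas.append(eta2)
        if np.ptp(vals) == 0:
            tukeys.append({})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = pairwise_tukeyhsd(vals, garr)
        pairs = {}
        for (g1, g2), pv in zip(
                [(res.groupsunique[i], res.groupsunique[j])
                 for i in range(len(res.groupsunique))
                 for j in range(i + 1, len(res.groupsunique))],
                res.pvalues):
            pairs[(str(g1), str(g2))] = float(pv)
        tukeys.append(pairs)
    qvals = bh_adjust(pvals)
    out = [DiffTestResult(function_id=f, anova_p=float(p), eta_squared=float(e),
                          tukey_pairwise=t, bh_q=float(q))
           for f, p, e, t, q in zip(feats, pvals, etas, tukeys, qvals)]
    if return_all:
        return out
    return [r for r in out if r.bh_q <= q_max]


def difftests_to_frame(results: list[DiffTestResult]) -> pd.DataFrame:
    cols = ["function_id", "anova_p", "eta_squared", "bh_q"]
    return pd.DataFrame(
        [{c: getattr(r, c) for c in cols} for r in results], columns=cols)


# ---------------------------------------------------------------------------
# Filters, CSS normalization, importance ranking
# ---------------------------------------------------------------------------

def css_normalize(profile: pd.DataFrame, quantile: float = 0.5,
                  scale: float = 1000.0) -> pd.DataFrame:
    """Cumulative sum scaling.

    Per sample, the scaling factor is the sum of counts less than or equal
    to the ``quantile``-th quantile of the sample's nonzero counts; each
    value is divided by the factor and multiplied by ``scale``.  Zeros stay
    zero; an all-zero sample is an error.
    """
    vals = profile.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("CSS expects non-negative counts")
    factors = np.empty(vals.shape[0])
    for i, row in enumerate(vals):
        nz = row[row > 0]
        if nz.size == 0:
            raise ValueError(
                f"sample {profile.index[i]!r} has no nonzero counts")
        q = np.quantile(nz, quantile)
        factors[i] = row[row <= q].sum()
    return pd.DataFrame(vals / factors[:, None] * scale,
                        index=profile.index, columns=profile.columns)


def filter_features(profile: pd.DataFrame,
                    cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Low-count/prevalence filter followed by a low-variance (IQR) drop.

    Keep features with value >= ``min_count`` in at least ``min_prevalence``
    of samples; then drop the ``variance_drop_fraction`` (floor rule) of the
    survivors with the smallest inter-quartile range, smallest first with
    lexicographic tie-breaks.  Raises if nothing survives.
    """
    cfg = cfg or FilterConfig()
    prev = (profile >= cfg.min_count).mean(axis=0)
    kept = [f for f in profile.columns if prev[f] >= cfg.min_prevalence]
    if not kept:
        raise ValueError("no features survive the count/prevalence filter")
    sub = profile[kept]
    n_drop = math.floor(cfg.variance_drop_fraction * len(kept))
    if n_drop:
        iqr = sub.quantile(0.75) - sub.quantile(0.25)
        order = sorted(kept, key=lambda f: (iqr[f], f))
        dropped = set(order[:n_drop])
        sub = sub[[f for f in kept if f not in dropped]]
    if sub.shape[1] == 0:
        raise ValueError("no features survive the variance filter")
    return sub


def importance_rank(profile: pd.DataFrame, groups: pd.Series,
                    n_top: int = 30, n_trees: int = 500,
                    seed: int = 0) -> ImportanceResult:
    """Mean-decrease-accuracy importance from a bagged tree ensemble.

    ``profile`` is expected already filtered and CSS-normalized.  Each of
    ``n_trees`` decision trees is fitted on a bootstrap resample; a
    feature's importance is the mean, over trees, of the drop in that
    tree's out-of-bag accuracy when the feature's out-of-bag column is
    permuted (trees not using the feature contribute a zero drop).  Also
    reports the running out-of-bag error as the ensemble grows.
    """
    groups = groups.loc[profile.index]
    X = profile.to_numpy(dtype=float)
    classes, y = np.unique(groups.to_numpy(), return_inverse=True)
    n, m = X.shape
    rng = np.random.default_rng(seed)
    decrease = np.zeros(m)
    votes = np.zeros((n, len(classes)))
    curve = []
    checkpoints = sorted({max(1, (n_trees * k) // 20) for k in range(1, 21)})
    for t in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeClassifier(
            max_features="sqrt",
            random_state=int(rng.integers(2 ** 31 - 1)))
        tree.fit(X[boot], y[boot])
        if oob.size:
            pred = tree.predict(X[oob])
            votes[oob, pred] += 1
            base_acc = float((pred == y[oob]).mean())
            used = np.unique(tree.tree_.feature)
            used = used[used >= 0]
            X_oob = X[oob]
            for f in used:
                Xp = X_oob.copy()
                Xp[:, f] = Xp[rng.permutation(oob.size), f]
                acc = float((tree.predict(Xp) == y[oob]).mean())
                decrease[f] += base_acc - acc
        if (t + 1) in checkpoints:
            curve.append((t + 1, _oob_error(votes, y)))
    importances = pd.Series(decrease / n_trees, index=profile.columns)
    order = sorted(profile.columns,
                   key=lambda f: (-importances[f], f))
    top = order[:min(n_top, m)]
    ranking = pd.DataFrame({
        "feature": top,
        "importance": [importances[f] for f in top],
        "rank": np.arange(1, len(top) + 1),
    })
    curve_df = pd.DataFrame(curve, columns=["n_trees", "oob_error"])
    return ImportanceResult(ranking=ranking, importances=importances,
                            oob_error=_oob_error(votes, y), oob_curve=curve_df)


def _oob_error(votes: np.ndarray, y: np.ndarray) -> float:
    voted = votes.sum(axis=1) > 0
    if not voted.any():
        return float("nan")
    pred = votes[voted].argmax(axis=1)
    return float((pred != y[voted]).mean())
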