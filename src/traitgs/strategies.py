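"""Genomic-selection strategies for a focal trait aided by correlated traits.

Five strategies are compared under a shared k-fold cross-validation scheme
(default k = 5, 30 repeats), differing only in which records enter the
training data and which predictions are scored:

==========================  =========================================  ==========================
strategy                    training records                           validation predictions
==========================  =========================================  ==========================
standard                    focal (80%)                                focal GEBV
indirect                    secondary (80%)                            secondary GEBV vs focal x-bar
multi_trait_indirect        >= 2 secondaries (80% each)                correlation-weighted index
multi_trait                 focal (80%) + secondary (80%)              focal GEBV
trait_assisted              focal (80%) + secondary (100%)             focal GEBV
==========================  =========================================  ==========================

Trait-assisted GS is the CV2-style scenario: secondary-trait phenotypes of
the *validation* genotypes are part of the fit, so focal predictions for
those genotypes use their own correlated records.

Accuracy per repeat is ONE pooled Pearson correlation between all
genotypes' out-of-fold predictions and the focal adjusted means — never an
average of per-fold correlations.  Every strategy in a comparison consumes
the identical fold assignments.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import RelationshipMatrix
from .gblup import (reml_univariate, reml_bivariate, blup_given_components)
from .spatial import AdjustedMeans

__all__ = [
    "CvScheme",
    "StrategyName",
    "AccuracyResult",
    "CoincidenceResult",
    "STRATEGY_NAMES",
    "make_folds",
    "auc_trait",
    "indirect_index",
    "run_strategy",
    "compare_strategies",
    "coincidence_index",
    "coincidence_of_result",
    "expected_selection_accuracy",
    "training_fraction_sweep",
]

STRATEGY_NAMES = ("standard", "indirect", "multi_trait_indirect",
                  "multi_trait", "trait_assisted")


class PartitionError(ValueError):
    pass


class UndefinedIndexError(ValueError):
    pass


@dataclass
class CvScheme:
    n_genotypes: int
    k: int
    n_repeats: int
    seed: int
    assignments: np.ndarray  # (n_repeats, n) fold labels 0..k-1

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.assignments, dtype=np.int64).tobytes())
        return h.hexdigest()

    @property
    def training_fraction(self) -> float:
        return 1.0 - 1.0 / self.k


def make_folds(n: int, k: int = 5, n_repeats: int = 30, seed: int = 0) -> CvScheme:
    """Balanced random k-fold partitions, identical for every strategy."""
    if k < 2:
        raise PartitionError("k must be >= 2")
    if n < k:
        raise PartitionError(f"cannot split n={n} genotypes into k={k} folds")
    rng = np.random.default_rng(seed)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    labels = np.repeat(np.arange(k), sizes)
    assignments = np.empty((n_repeats, n), dtype=np.int64)
    for rep in range(n_repeats):
        perm = rng.permutation(n)
        assignments[rep, perm] = labels
    return CvScheme(n_genotypes=n, k=k, n_repeats=n_repeats, seed=seed,
                    assignments=assignments)


@dataclass
class StrategyName:
    name: str
    focal: str
    secondary: tuple = ()

    def __post_init__(self):
        if self.name not in STRATEGY_NAMES:
            raise ValueError(f"unknown strategy {self.name!r}")
        self.secondary = tuple(self.secondary)
        ns = len(self.secondary)
        if self.name == "standard" and ns != 0:
            raise ValueError("standard GS takes no secondary trait")
        if self.name in ("indirect", "multi_trait", "trait_assisted") and ns != 1:
            raise ValueError(f"{self.name} needs exactly one secondary trait")
        if self.name == "multi_trait_indirect" and ns < 2:
            raise ValueError("multi_trait_indirect needs >= 2 secondary traits")


@dataclass
class AccuracyResult:
    strategy: StrategyName
    accuracies: np.ndarray          # pooled Pearson r per repeat
    gebv_sd: np.ndarray             # sd of pooled predictions per repeat
    predictions: np.ndarray         # (n_repeats, n) pooled out-of-fold predictions
    genotype_ids: list
    training_fraction: float
    scheme_fingerprint: str

    @property
    def mean(self) -> float:
        # failed repeats are flagged as NaN and excluded
        return float(np.nanmean(self.accuracies))

    @property
    def sd(self) -> float:
        ok = self.accuracies[~np.isnan(self.accuracies)]
        return float(np.std(ok, ddof=1)) if len(ok) > 1 else 0.0


@dataclass
class CoincidenceResult:
    direction: str
    intensity: float
    T: int
    R: int
    B: np.ndarray       # per repeat
    ci: np.ndarray      # per repeat
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self):
        self.mean = float(np.mean(self.ci))
        self.sd = float(np.std(self.ci, ddof=1)) if len(self.ci) > 1 else 0.0


def auc_trait(heights, baseline: float = 0.0) -> pd.Series:
    """Area under the growth progress curve by the trapezoidal rule.

    ``heights`` is a genotype x measurement table whose columns are
    equally spaced in time (unit spacing: one interval per measurement
    gap); ``baseline`` is h_0, height at planting.  A genotype with a
    missing measurement propagates NaN with a warning.
    """
    h = pd.DataFrame(heights).astype(float)
    if h.shape[1] < 1:
        raise ValueError("need at least one height measurement")
    hv = np.column_stack([np.full(len(h), baseline), h.to_numpy()])
    if np.isnan(hv).any():
        n_bad = int(np.isnan(hv).any(axis=1).sum())
        warnings.warn(f"{n_bad} genotypes have missing height measurements; "
                      "their AUC is NaN", stacklevel=2)
    area = 0.5 * (hv[:, :-1] + hv[:, 1:]).sum(axis=1)
    return pd.Series(area, index=h.index)


def indirect_index(gebvs: pd.DataFrame, cor_g_with_focal) -> pd.Series:
    """Correlation-weighted index over standardized secondary-trait GEBVs.

    Each GEBV vector is scaled to mean 0 and variance 1, then summed with
    weights equal to the secondary trait's genetic correlation with the
    focal trait.
    """
    g = pd.DataFrame(gebvs).astype(float)
    w = np.asarray(cor_g_with_focal, dtype=float)
    if w.shape != (g.shape[1],):
        raise ValueError("one weight per GEBV column required")
    sd = g.std(ddof=1)
    if (sd <= 0).any():
        bad = list(sd.index[sd <= 0])
        raise ValueError(f"zero-variance GEBV vector(s): {bad}")
    z = (g - g.mean()) / sd
    return pd.Series(z.to_numpy() @ w, index=g.index)


def _xbar_frame(data) -> pd.DataFrame:
    return data.values if isinstance(data, AdjustedMeans) else pd.DataFrame(data)


def _pooled_correlation(predictions: np.ndarray, truth: np.ndarray) -> float:
    """The per-repeat accuracy: a single correlation over the pooled folds."""
    ok = ~(np.isnan(predictions) | np.isnan(truth))
    return float(np.corrcoef(predictions[ok], truth[ok])[0, 1])


def _fit_fold(strategy, xbar, a, train_mask, warm):
    """Predictions for all genotypes from one fold's Table-1 training records."""
    name = strategy.name
    focal = xbar[strategy.focal]
    if name == "standard":
        fit = reml_univariate(focal.where(train_mask), a)
        return fit.gebv.to_numpy(), warm
    if name == "indirect":
        fit = reml_univariate(xbar[strategy.secondary[0]].where(train_mask), a)
        return fit.gebv.to_numpy(), warm
    if name == "multi_trait":
        yy = pd.DataFrame({strategy.focal: focal.where(train_mask),
                           strategy.secondary[0]:
                               xbar[strategy.secondary[0]].where(train_mask)})
        fit = reml_bivariate(yy, a, init=warm)
        return fit.gebv[strategy.focal].to_numpy(), (fit.G.values, fit.R.values)
    if name == "trait_assisted":
        yy = pd.DataFrame({strategy.focal: focal.where(train_mask),
                           strategy.secondary[0]: xbar[strategy.secondary[0]]})
        fit = reml_bivariate(yy, a, init=warm)
        return fit.gebv[strategy.focal].to_numpy(), (fit.G.values, fit.R.values)
    raise AssertionError(name)


def run_strategy(data, a: RelationshipMatrix, strategy: StrategyName,
                 scheme: CvScheme, *, components_mode: str = "per_fold",
                 ) -> AccuracyResult:
    """Cross-validated prediction accuracy of one strategy.

    For each repeat and fold the model defined by the strategy is fit on
    the fold's training records, out-of-fold predictions are pooled over
    the k folds, and one Pearson correlation with the focal adjusted means
    is recorded.  ``components_mode='full_data'`` estimates variance
    components once from all records and only re-solves the BLUP per fold
    (a leakage-prone shortcut kept for comparison).
    """
    xbar = _xbar_frame(data).reindex(a.genotype_ids)
    needed = (strategy.focal,) + strategy.secondary
    missing = [t for t in needed if t not in xbar.columns]
    if missing:
        raise ValueError(f"traits absent from adjusted means: {missing}")
    if xbar[list(needed)].isna().any().any():
        raise ValueError("adjusted means contain missing values for required traits")
    n = len(a.genotype_ids)
    if scheme.n_genotypes != n:
        raise ValueError("CV scheme size does not match the relationship matrix")
    if components_mode not in ("per_fold", "full_data"):
        raise ValueError("components_mode must be per_fold|full_data")

    focal_truth = xbar[strategy.focal].to_numpy()
    preds = np.full((scheme.n_repeats, n), np.nan)
    acc = np.empty(scheme.n_repeats)
    sds = np.empty(scheme.n_repeats)

    full_components = None
    if components_mode == "full_data" and strategy.name in ("multi_trait",
                                                            "trait_assisted"):
        yy = xbar[[strategy.focal, strategy.secondary[0]]]
        f = reml_bivariate(yy, a)
        full_components = (f.G.values, f.R.values)

    for rep in range(scheme.n_repeats):
        labels = scheme.assignments[rep]
        try:
            if strategy.name == "multi_trait_indirect":
                preds[rep] = _indirect_multi_repeat(strategy, xbar, a, labels,
                                                    scheme.k)
            else:
                warm = full_components
                for fold in range(scheme.k):
                    val = labels == fold
                    train = ~val
                    if full_components is not None:
                        yy = pd.DataFrame({
                            strategy.focal: xbar[strategy.focal].where(train),
                            strategy.secondary[0]: xbar[strategy.secondary[0]]
                            if strategy.name == "trait_assisted"
                            else xbar[strategy.secondary[0]].where(train)})
                        gebv = blup_given_components(yy, a, *full_components)
                        fold_pred = gebv[strategy.focal].to_numpy()
                    else:
                        fold_pred, warm = _fit_fold(strategy, xbar, a, train,
                                                    warm)
                    preds[rep, val] = fold_pred[val]
        except Exception as e:  # noqa: BLE001 - repeat flagged, not fatal
            warnings.warn(f"{strategy.name} repeat {rep} failed and was "
                          f"excluded: {type(e).__name__}: {e}", stacklevel=2)
            preds[rep] = np.nan
            acc[rep] = np.nan
            sds[rep] = np.nan
            continue
        acc[rep] = _pooled_correlation(preds[rep], focal_truth)
        sds[rep] = float(np.nanstd(preds[rep], ddof=1))

    return AccuracyResult(strategy=strategy, accuracies=acc, gebv_sd=sds,
                          predictions=preds, genotype_ids=list(a.genotype_ids),
                          training_fraction=scheme.training_fraction,
                          scheme_fingerprint=scheme.fingerprint())


def _indirect_multi_repeat(strategy, xbar, a, labels, k):
    """Pooled Eq.-5 index predictions for one repeat of multi-trait indirect GS."""
    n = len(labels)
    sec = strategy.secondary
    pooled = {t: np.full(n, np.nan) for t in sec}
    weights = {t: [] for t in sec}
    for fold in range(k):
        val = labels == fold
        train = ~val
        for t in sec:
            fit = reml_univariate(xbar[t].where(train), a)
            pooled[t][val] = fit.gebv.to_numpy()[val]
            bw = reml_bivariate(
                pd.DataFrame({strategy.focal: xbar[strategy.focal].where(train),
                              t: xbar[t].where(train)}), a)
            weights[t].append(bw.cor_g)
    gmat = pd.DataFrame(pooled)
    w = [float(np.mean(weights[t])) for t in sec]
    return indirect_index(gmat, w).to_numpy()


def compare_strategies(data, a: RelationshipMatrix, strategies, scheme: CvScheme,
                       **kwargs) -> dict:
    """Run several strategies on byte-identical fold assignments."""
    results = {}
    fp = scheme.fingerprint()
    for s in strategies:
        res = run_strategy(data, a, s, scheme, **kwargs)
        assert res.scheme_fingerprint == fp, "fold assignments drifted between strategies"
        results[s.name] = res
    return results


def coincidence_index(x_bar: pd.Series, gebv: pd.Series, intensity: float = 0.20,
                      direction: str = "top"):
    """Chance-corrected overlap CI = (B - R) / (T - R) of two selected fractions.

    T = round(intensity * n) genotypes are selected by each ranking
    (ties broken by stable input order); B is the overlap; the chance
    overlap is R = round(T^2 / n).
    """
    if direction not in ("top", "bottom"):
        raise ValueError("direction must be 'top' or 'bottom'")
    if not (0.0 < intensity < 1.0):
        raise ValueError("intensity must lie in (0, 1)")
    x = pd.Series(x_bar, dtype=float)
    g = pd.Series(gebv, dtype=float).reindex(x.index)
    if g.isna().any() or x.isna().any():
        raise ValueError("rankings must cover the same genotype set without NaN")
    n = len(x)
    t = int(np.rint(intensity * n))
    r = int(np.rint(t * t / n))
    if t <= r:
        raise UndefinedIndexError(f"T={t} <= R={r}: coincidence index undefined")
    sign = -1.0 if direction == "top" else 1.0
    sel_x = set(np.argsort(sign * x.to_numpy(), kind="stable")[:t])
    sel_g = set(np.argsort(sign * g.to_numpy(), kind="stable")[:t])
    b = len(sel_x & sel_g)
    return b, t, r, (b - r) / (t - r)


def coincidence_of_result(result: AccuracyResult, data, intensity: float = 0.20,
                          direction: str = "top") -> CoincidenceResult:
    """Per-repeat coincidence between focal adjusted means and pooled predictions."""
    xbar = _xbar_frame(data).reindex(result.genotype_ids)[result.strategy.focal]
    bs, cis = [], []
    t = r = 0
    for rep in range(result.predictions.shape[0]):
        if np.isnan(result.predictions[rep]).all():
            continue  # repeat was flagged as failed
        g = pd.Series(result.predictions[rep], index=result.genotype_ids)
        b, t, r, ci = coincidence_index(xbar, g, intensity, direction)
        bs.append(b)
        cis.append(ci)
    return CoincidenceResult(direction=direction, intensity=intensity, T=t, R=r,
                             B=np.array(bs), ci=np.array(cis))


def expected_selection_accuracy(h_focal: float, h_secondary: float,
                                cor_g: float, r_strategy: float) -> dict:
    """Expected accuracies of phenotypic and indirect phenotypic selection.

    Phenotypic selection has accuracy r = h_Y (the square root of the focal
    heritability); indirect phenotypic selection on trait x has
    r = h_x * cor_g(x, Y).  Returns both along with the strategy-to-PS and
    strategy-to-IPS ratios (NaN marks an undefined ratio).
    """
    if not (0 <= h_focal <= 1 and 0 <= h_secondary <= 1):
        raise ValueError("h values must lie in [0, 1]")
    if abs(cor_g) > 1:
        raise ValueError("|cor_g| must be <= 1")
    ps = float(h_focal)
    ips = float(h_secondary * cor_g)
    return {
        "ps": ps,
        "ips": ips,
        "ratio_ps": r_strategy / ps if ps != 0 else np.nan,
        "ratio_ips": r_strategy / ips if ips != 0 else np.nan,
    }


def training_fraction_sweep(data, a: RelationshipMatrix, strategy: StrategyName,
                            scheme: CvScheme, fractions, *,
                            min_training: int = 30) -> list:
    """Accuracy as the training population shrinks.

    For each fraction f a fresh random f-subset trains the model per
    repeat, the complement validates, and the trait-assisted convention
    (secondary records complete) is preserved.  Accuracy per repeat is the
    correlation between validation predictions and validation adjusted
    means.  Fractions leaving fewer than ``min_training`` training records
    are skipped with a warning.
    """
    xbar = _xbar_frame(data).reindex(a.genotype_ids)
    n = len(a.genotype_ids)
    focal_truth = xbar[strategy.focal].to_numpy()
    out = []
    for f in fractions:
        if not (0.0 < f < 1.0):
            raise ValueError("fractions must lie in (0, 1)")
        n_train = int(np.rint(f * n))
        if n_train < min_training:
            warnings.warn(f"fraction {f} leaves {n_train} training records "
                          f"(< {min_training}); skipped", stacklevel=2)
            continue
        rng = np.random.default_rng([scheme.seed, int(round(f * 1e6))])
        acc = np.empty(scheme.n_repeats)
        sds = np.empty(scheme.n_repeats)
        preds = np.full((scheme.n_repeats, n), np.nan)
        for rep in range(scheme.n_repeats):
            train = np.zeros(n, dtype=bool)
            train[rng.choice(n, size=n_train, replace=False)] = True
            val = ~train
            if strategy.name == "multi_trait_indirect":
                labels = np.where(val, 0, 1)  # single pseudo-fold
                pred = _indirect_multi_repeat(strategy, xbar, a,
                                              labels, 1)
            else:
                pred, _ = _fit_fold(strategy, xbar, a, train, None)
            preds[rep, val] = pred[val]
            acc[rep] = _pooled_correlation(preds[rep], focal_truth)
            sds[rep] = float(np.nanstd(preds[rep], ddof=1))
        out.append(AccuracyResult(strategy=strategy, accuracies=acc, gebv_sd=sds,
                                  predictions=preds,
                                  genotype_ids=list(a.genotype_ids),
                                  training_fraction=float(f),
                                  scheme_fingerprint=scheme.fingerprint()))
    return out
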