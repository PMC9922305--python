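"""Genomic events associated with EMT macro-states.

The core procedure is stability selection: a binomial lasso of state
membership on binary genomic events (mutations, focal and arm-level copy
number changes) is refitted over many stratified resamples, and events
selected in a large fraction of resamples are kept.  Tissue of origin
enters every fit as an unpenalised covariate so that events whose
frequency merely tracks tissue are not mistaken for state markers.  A
final model on the stable events is scored by ROC AUC on a held-out
split.

Closed-form companions: the cancer cell fraction of a mutation from
purity, copy number and VAF; a rank-based hypoxia score; and the
upper-tail hypergeometric probability used for screen-overlap
enrichment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .io import STATE_LABELS, ExpressionMatrix

logger = logging.getLogger(__name__)

# Lasso penalties are equivalent to feature rescaling: a per-feature penalty
# weight w_j equals scaling the feature by 1/w_j. Tissue indicators are
# scaled up by this factor, making their effective penalty negligible.
_UNPENALISED_SCALE = 1e3


@dataclass
class GenomicEventMatrix:
    """Binary events (samples x events) with tissue and macro-state labels."""

    events: pd.DataFrame
    tissue: pd.Series
    state: pd.Series

    def __post_init__(self) -> None:
        vals = self.events.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("event matrix entries must be 0/1")
        for name, s in (("tissue", self.tissue), ("state", self.state)):
            s = pd.Series(s)
            if not s.index.equals(self.events.index):
                s = s.reindex(self.events.index)
            if s.isna().any():
                missing = list(s.index[s.isna()][:5])
                raise ValueError(f"samples without a {name} label: {missing}")
            setattr(self, name, s)
        bad = set(self.state) - set(STATE_LABELS)
        if bad:
            raise ValueError(f"state labels must be in {STATE_LABELS}; got {sorted(bad)}")

    @property
    def event_ids(self) -> list[str]:
        return list(self.events.columns)


@dataclass
class StabilitySelectionResult:
    """Selection frequencies and coefficients over resampled lasso fits."""

    contrast: tuple[str, str]
    selection_frequency: pd.Series
    coefficient_draws: pd.DataFrame   # iterations x events
    selected_80: list[str]
    selected_50: list[str]
    holdout_auc: float

    def __post_init__(self) -> None:
        f = self.selection_frequency
        if ((f < 0) | (f > 1)).any():
            raise ValueError("selection frequencies must lie in [0, 1]")
        if not set(self.selected_80) <= set(self.selected_50):
            raise ValueError("selected_80 must be a subset of selected_50")


def _tissue_design(tissue: pd.Series) -> np.ndarray:
    """One indicator per tissue level minus one, scaled to be unpenalised."""
    dummies = pd.get_dummies(tissue.astype(str), drop_first=True, dtype=float)
    return dummies.to_numpy() * _UNPENALISED_SCALE


def stability_select(
    data: GenomicEventMatrix,
    contrast: tuple[str, str] = ("MES", "EPI"),
    n_iter: int = 1000,
    train_frac: float = 0.8,
    threshold: float = 0.8,
    seed: int = 0,
    cv_folds: int = 3,
) -> StabilitySelectionResult:
    """Stability-selection lasso for one pairwise state contrast.

    A 20% stratified holdout is split off first and never touched during
    selection.  Each iteration draws a stratified ``train_frac`` resample
    of the remaining pool, fits an L1-penalised logistic regression of
    membership in ``contrast[0]`` vs ``contrast[1]`` (penalty chosen by
    internal cross-validation; tissue covariates unpenalised) and records
    the events with non-zero coefficients.  Events passing ``threshold``
    selection frequency form ``selected_80``; 0.5 gives ``selected_50``.
    The final model refit on ``selected_80`` is scored by AUC on the
    holdout.
    """
    a, b = contrast
    if a == b:
        raise ValueError("contrast must name two distinct states")
    if not 0.5 <= threshold <= 1:
        raise ValueError("threshold must lie in [0.5, 1]")
    mask = data.state.isin([a, b]).to_numpy()
    sub_events = data.events.loc[mask]
    y = (data.state[mask] == a).to_numpy(int)
    n_a, n_b = int(y.sum()), int((1 - y).sum())
    if min(n_a, n_b) < 20:
        raise ValueError(
            f"contrast {a} vs {b} needs >= 20 samples per state; got {n_a}/{n_b}"
        )
    X_events = sub_events.to_numpy(float)
    X_tissue = _tissue_design(data.tissue[mask])
    X = np.hstack([X_events, X_tissue])
    n_ev = X_events.shape[1]

    splitter = StratifiedShuffleSplit(n_splits=1, test_size=0.2, random_state=seed)
    (pool_idx, hold_idx), = splitter.split(X, y)

    rng_seeds = np.random.SeedSequence([seed, 13]).spawn(n_iter)
    coefs = np.zeros((n_iter, n_ev))
    Cs = np.logspace(-2, 2, 10)
    for it, child in enumerate(rng_seeds):
        rs = int(child.generate_state(1)[0] % (2**31 - 1))
        sub = StratifiedShuffleSplit(
            n_splits=1, train_size=train_frac, random_state=rs
        )
        (tr, _), = sub.split(X[pool_idx], y[pool_idx])
        idx = pool_idx[tr]
        clf = LogisticRegressionCV(
            Cs=Cs, penalty="l1", solver="liblinear",
            cv=StratifiedKFold(cv_folds, shuffle=True, random_state=rs),
            max_iter=1000, random_state=rs,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X[idx], y[idx])
            # one-standard-error rule: strongest penalty whose CV score is
            # within one SE of the optimum (glmnet's lambda.1se default)
            sc = clf.scores_[1]
            mean, se = sc.mean(axis=0), sc.std(axis=0, ddof=1) / np.sqrt(sc.shape[0])
            i_best = int(np.argmax(mean))
            i_1se = int(np.flatnonzero(mean >= mean[i_best] - se[i_best]).min())
            refit = LogisticRegression(
                C=Cs[i_1se], penalty="l1", solver="liblinear",
                max_iter=1000, random_state=rs,
            )
            refit.fit(X[idx], y[idx])
        coefs[it] = refit.coef_[0, :n_ev]

    nonzero = np.abs(coefs) > 1e-8
    freq = pd.Series(nonzero.mean(axis=0), index=sub_events.columns,
                     name="selection_frequency")
    selected_80 = list(freq.index[freq >= threshold])
    selected_50 = list(freq.index[freq >= min(0.5, threshold)])

    if selected_80:
        cols = [sub_events.columns.get_loc(e) for e in selected_80]
        Xf = np.hstack([X_events[:, cols], X_tissue])
        final = LogisticRegression(penalty="l2", C=1e3, max_iter=5000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            final.fit(Xf[pool_idx], y[pool_idx])
        scores = final.predict_proba(Xf[hold_idx])[:, 1]
        auc = float(roc_auc_score(y[hold_idx], scores))
    else:
        logger.warning("no event passed the %.0f%% threshold; AUC set to 0.5",
                       100 * threshold)
        auc = 0.5

    return StabilitySelectionResult(
        contrast=(a, b),
        selection_frequency=freq,
        coefficient_draws=pd.DataFrame(coefs, columns=sub_events.columns),
        selected_80=selected_80,
        selected_50=selected_50,
        holdout_auc=auc,
    )


def pairwise_contrasts() -> list[tuple[str, str]]:
    """The three pairwise macro-state contrasts fitted by default."""
    return [("MES", "EPI"), ("hEMT", "EPI"), ("hEMT", "MES")]


# ---------------------------------------------------------------------------
# closed-form quantities


@dataclass(frozen=True)
class CCFInput:
    """Purity, segment copy number and VAF for one mutation."""

    purity: float
    CN: int
    VAF: float

    def __post_init__(self) -> None:
        if not 0 <= self.purity <= 1:
            raise ValueError("purity must lie in [0, 1]")
        if self.purity == 0:
            raise ValueError("purity must be positive")
        if self.CN <= 0 or int(self.CN) != self.CN:
            raise ValueError("CN must be a positive integer")
        if not 0 <= self.VAF <= 1:
            raise ValueError("VAF must lie in [0, 1]")


class CCFEstimate(NamedTuple):
    value: float      # capped at 1
    capped: bool
    raw_value: float


def cancer_cell_fraction(x: CCFInput, purity_scaled: bool = True) -> CCFEstimate:
    """Cancer cell fraction of a mutation.

    Default form: ``CCF = VAF * (2 + purity * (CN - 2)) / purity`` — the
    expected fraction of tumour cells carrying a heterozygous mutation
    after correcting the VAF for normal-cell dilution and local copy
    number.  ``purity_scaled=False`` gives the alternative ``CN * VAF``
    form in which purity cancels.  Values above 1 are capped and flagged.
    """
    if purity_scaled:
        raw = x.VAF * (2.0 + x.purity * (x.CN - 2.0)) / x.purity
    else:
        raw = float(x.CN) * x.VAF
    return CCFEstimate(value=min(raw, 1.0), capped=raw > 1.0, raw_value=raw)


def hypoxia_score(expr: ExpressionMatrix, hypoxia_genes: Sequence[str]) -> pd.Series:
    """Buffa-style rank score: #genes above the cohort median minus #below.

    Genes exactly at the median contribute 0; integer score per sample.
    """
    present = [g for g in hypoxia_genes if g in set(expr.gene_ids)]
    if not present:
        raise ValueError("no hypoxia gene present in the expression matrix")
    sub = expr.subset_genes(present).values
    med = np.median(sub, axis=1, keepdims=True)
    score = (sub > med).sum(axis=0) - (sub < med).sum(axis=0)
    return pd.Series(score.astype(int), index=expr.sample_ids, name="hypoxia_score")


def hypergeometric_enrichment(
    population: int, successes: int, draws: int, observed: int
) -> float:
    """P(X >= observed) for X ~ Hypergeometric(population, successes, draws).

    Computed via the log survival function so extreme tails do not
    underflow.  Symmetric in (successes, draws).
    """
    if not (0 <= successes <= population and 0 <= draws <= population):
        raise ValueError("successes and draws must lie in [0, population]")
    if not 0 <= observed <= min(successes, draws):
        raise ValueError("observed must lie in [0, min(successes, draws)]")
    if observed == 0:
        return 1.0
    logp = hypergeom.logsf(observed - 1, population, successes, draws)
    return float(np.exp(logp))
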