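"""Pattern-classification readouts.

Four readouts probe what a downstream observer could extract from the
population activity evoked by the odor subspace:

* a four-way forced-choice task solved by quadratic discriminant analysis
  (QDA) on subsets of 80 neurons,
* template matching (correlation to a randomly drawn class exemplar),
* multiple linear regression predicting the concentration of a pure odor in
  a mixture,
* a linear support vector machine classifying six 15%-wide concentration
  classes.

Concentration is defined as the percentage of an odor's 150 activated
mitral cells that are activated in the mixture (the subspace concentration
table entry).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from sklearn.svm import SVC

from .geometry import RatePatternSet
from .odors import pattern_correlation

__all__ = [
    "QDAModel", "QDAInapplicableError", "fit_qda", "qda_fourway",
    "template_match", "concentration_regress", "concentration_svm",
    "concentration_labels",
]


class QDAInapplicableError(np.linalg.LinAlgError):
    """Raised when a class covariance is singular (low intra-class
    variability, e.g. attractor dynamics in Scaled I networks)."""


@dataclass
class QDAModel:
    """Gaussian class-conditional quadratic discriminant classifier."""

    means: np.ndarray        # (n_classes, n_dim)
    covs: np.ndarray         # (n_classes, n_dim, n_dim)
    priors: np.ndarray       # (n_classes,)
    _chol: np.ndarray = None
    _logdet: np.ndarray = None

    @classmethod
    def fit(cls, x: np.ndarray, y: np.ndarray,
            priors: np.ndarray | None = None) -> "QDAModel":
        classes = np.unique(y)
        n_dim = x.shape[1]
        means, covs, counts = [], [], []
        for k in classes:
            xk = x[y == k]
            if len(xk) <= n_dim:
                raise QDAInapplicableError(
                    f"class {k}: {len(xk)} samples <= {n_dim} dimensions")
            means.append(xk.mean(axis=0))
            covs.append(np.cov(xk, rowvar=False))
            counts.append(len(xk))
        means = np.array(means)
        covs = np.array(covs)
        if priors is None:
            priors = np.array(counts, dtype=float) / np.sum(counts)
        chols, logdets = [], []
        for k, s in enumerate(covs):
            sign, logdet = np.linalg.slogdet(s)
            if sign <= 0 or not np.isfinite(logdet):
                raise QDAInapplicableError(
                    f"class {classes[k]}: singular covariance "
                    f"(rank {np.linalg.matrix_rank(s)} < {n_dim}); QDA inapplicable")
            chols.append(np.linalg.cholesky(s))
            logdets.append(logdet)
        model = cls(means=means, covs=covs, priors=priors)
        model._chol = np.array(chols)
        model._logdet = np.array(logdets)
        return model

    def discriminants(self, x: np.ndarray) -> np.ndarray:
        """delta_k(x) = -log|S_k|/2 - (x-mu_k)' S_k^-1 (x-mu_k)/2 + log pi_k."""
        x = np.atleast_2d(x)
        out = np.empty((len(x), len(self.means)))
        for k in range(len(self.means)):
            d = x - self.means[k]
            z = solve_triangular(self._chol[k], d.T, lower=True)
            maha = np.sum(z ** 2, axis=0)
            out[:, k] = -0.5 * self._logdet[k] - 0.5 * maha + np.log(self.priors[k])
        return out

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.discriminants(x), axis=1)


def fit_qda(x: np.ndarray, y: np.ndarray, priors=None) -> QDAModel:
    return QDAModel.fit(x, y, priors)


def _ob_correlation_to_pures(ob: RatePatternSet, pure_rows: np.ndarray) -> np.ndarray:
    """(n_patterns, 4) input correlation of every OB pattern to each pure odor."""
    out = np.empty((ob.n_patterns, len(pure_rows)))
    for j, pr in enumerate(pure_rows):
        out[:, j] = [pattern_correlation(pr, r) for r in ob.rates]
    return out


def qda_fourway(patterns: RatePatternSet, patterns_half: RatePatternSet,
                ob_patterns: RatePatternSet, pure_epochs: np.ndarray,
                pool: np.ndarray, seed, n_neurons: int = 80,
                n_draws: int = 50, train_threshold: float = 0.6) -> pd.DataFrame:
    """Four-way forced-choice classification of subspace mixtures.

    Training classes: for each pure odor, the half-window-averaged response
    patterns of all epochs whose OB input correlation to that pure odor
    exceeds ``train_threshold``.  Test set: full-window patterns of all
    epochs below threshold for every pure odor.  For each of ``n_draws``
    random subsets of ``n_neurons`` from ``pool`` a QDA model is fitted and
    the test patterns assigned; the result reports, per test epoch and
    class, the fraction of draws assigning the pattern to that class, along
    with the epoch's input correlation to each pure odor.

    Draws whose class covariances are singular are skipped and counted; if
    every draw fails, QDAInapplicableError propagates (expected for
    attractor networks).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cors = _ob_correlation_to_pures(ob_patterns, ob_patterns.rates[pure_epochs])
    train_class = {}
    for k in range(len(pure_epochs)):
        train_class[k] = np.nonzero(cors[:, k] > train_threshold)[0]
        if len(train_class[k]) == 0:
            raise ValueError(f"no training epochs for class {k}")
    test_epochs = np.nonzero((cors <= train_threshold).all(axis=1))[0]

    half_meta = patterns_half.meta
    x_train_rows, y_train = [], []
    for k, eps in train_class.items():
        sel = half_meta["epoch"].isin(eps).to_numpy()
        x_train_rows.append(patterns_half.rates[sel])
        y_train.extend([k] * int(sel.sum()))
    x_train = np.vstack(x_train_rows)
    y_train = np.asarray(y_train)

    test_sel = patterns.meta["epoch"].isin(test_epochs).to_numpy()
    x_test = patterns.rates[test_sel]
    test_ep_ids = patterns.meta.loc[test_sel, "epoch"].to_numpy()

    counts = np.zeros((len(x_test), len(pure_epochs)))
    n_ok = 0
    err = None
    pool = np.asarray(pool)
    for _ in range(n_draws):
        sub = rng.choice(pool, size=n_neurons, replace=False)
        try:
            model = QDAModel.fit(x_train[:, sub], y_train)
        except QDAInapplicableError as e:
            err = e
            continue
        pred = model.predict(x_test[:, sub])
        counts[np.arange(len(x_test)), pred] += 1
        n_ok += 1
    if n_ok == 0:
        raise QDAInapplicableError(f"QDA inapplicable in all draws: {err}")
    probs = counts / n_ok
    rows = []
    for i, ep in enumerate(test_ep_ids):
        for k in range(len(pure_epochs)):
            rows.append({
                "epoch": int(ep), "class": k, "p_assign": probs[i, k],
                "input_correlation": cors[ep, k], "n_draws_used": n_ok,
            })
    return pd.DataFrame(rows)


def template_match(patterns: RatePatternSet, class_epochs: dict,
                   test_epochs: np.ndarray, seed,
                   n_iter: int = 10) -> pd.DataFrame:
    """Assign test patterns to the class with the best-correlated template.

    Per iteration one random exemplar per class is drawn; each test pattern
    goes to the class whose exemplar correlates best.  Returns
    iteration-averaged assignment probabilities.  Zero-variance test
    patterns are flagged (NaN probabilities).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    classes = sorted(class_epochs)
    for k in classes:
        if len(class_epochs[k]) == 0:
            raise ValueError(f"class {k} is empty")
    ep_index = {int(e): i for i, e in enumerate(patterns.meta["epoch"].to_numpy())}
    counts = np.zeros((len(test_epochs), len(classes)))
    valid = np.ones(len(test_epochs), dtype=bool)
    for _ in range(n_iter):
        templates = {
            k: patterns.rates[ep_index[int(rng.choice(class_epochs[k]))]]
            for k in classes}
        for i, ep in enumerate(test_epochs):
            x = patterns.rates[ep_index[int(ep)]]
            if x.std() == 0:
                valid[i] = False
                continue
            cs = [pattern_correlation(x, templates[k]) for k in classes]
            counts[i, int(np.nanargmax(cs))] += 1
    probs = counts / n_iter
    probs[~valid] = np.nan
    rows = []
    for i, ep in enumerate(test_epochs):
        for j, k in enumerate(classes):
            rows.append({"epoch": int(ep), "class": k, "p_assign": probs[i, j]})
    return pd.DataFrame(rows)


def concentration_labels(meta: pd.DataFrame, odor: int) -> np.ndarray:
    """Concentration (%) of pure odor ``odor`` for every pattern row."""
    if "conc" not in meta.columns:
        raise ValueError("metadata lacks subspace concentrations")
    return np.array([c[odor] for c in meta["conc"]], dtype=float)


def _equilibrated(values: np.ndarray, trajectories: np.ndarray,
                  trials_hi: int, trials_lo: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Balance sample counts across label values.

    Samples are pixel x trajectory occurrences; label values occupying few
    subspace pixels keep more trials (trajectories) per pixel than abundant
    ones (the published "four or eight trials to equilibrate" device).
    """
    n_traj = max(1, len(np.unique(trajectories)))
    uniq, counts = np.unique(values, return_counts=True)
    pix_counts = counts / n_traj
    med = np.median(pix_counts)
    sel = []
    for v, c, npx in zip(uniq, counts, pix_counts):
        idx = np.nonzero(values == v)[0]
        per = trials_hi if npx <= med else trials_lo
        k = min(len(idx), int(round(per * npx)))
        sel.append(rng.choice(idx, size=k, replace=False))
    return np.concatenate(sel)


def concentration_regress(patterns: RatePatternSet, odor: int,
                          pool: np.ndarray, seed, n_neurons: int = 80,
                          n_draws: int = 50,
                          trials=(8, 4)) -> float:
    """Mean squared error of linear concentration prediction.

    Ordinary least squares maps the rates of ``n_neurons`` (drawn from
    ``pool``) to the concentration of ``odor``; per draw the in-sample MSE
    between actual and estimated concentration is computed and the draws
    are averaged.  Samples are equilibrated across concentration values
    (rare concentrations keep more trials).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    conc = concentration_labels(patterns.meta, odor)
    traj = patterns.meta["trajectory"].to_numpy()
    nonzero = conc > 0
    sel = _equilibrated(conc[nonzero], traj[nonzero], *trials, rng)
    idx = np.nonzero(nonzero)[0][sel]
    if len(idx) <= n_neurons:
        raise ValueError(f"{len(idx)} samples <= {n_neurons} regressors")
    y = conc[idx]
    pool = np.asarray(pool)
    errs = []
    for _ in range(n_draws):
        sub = rng.choice(pool, size=n_neurons, replace=False)
        x = np.column_stack([np.ones(len(idx)), patterns.rates[np.ix_(idx, sub)]])
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        pred = x @ beta
        errs.append(np.mean((pred - y) ** 2))
    return float(np.mean(errs))


def concentration_svm(patterns: RatePatternSet, odor: int, pool: np.ndarray,
                      seed, n_classes: int = 6, class_width: float = 15.0,
                      n_neurons: int = 80, n_draws: int = 20,
                      cv_iter: int = 20, trials=(6, 2)) -> float:
    """Linear-SVM accuracy for 15%-wide concentration classes.

    Mixtures are binned into ``n_classes`` classes of ``class_width`` %
    spanning (0, 90]; zero concentration (odor absent) is excluded.  For
    each of ``n_draws`` neuron subsets and ``cv_iter`` random twofold
    splits a linear SVM is trained and scored on the held-out half; the
    mean held-out accuracy is returned.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    conc = concentration_labels(patterns.meta, odor)
    traj = patterns.meta["trajectory"].to_numpy()
    in_range = (conc > 0) & (conc <= n_classes * class_width)
    labels = np.ceil(conc / class_width).astype(int) - 1
    sel = _equilibrated(labels[in_range].astype(float), traj[in_range], *trials, rng)
    idx = np.nonzero(in_range)[0][sel]
    y = labels[idx]
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two concentration classes")
    pool = np.asarray(pool)
    accs = []
    for _ in range(n_draws):
        sub = rng.choice(pool, size=n_neurons, replace=False)
        x = patterns.rates[np.ix_(idx, sub)]
        for _ in range(cv_iter):
            perm = rng.permutation(len(y))
            half = len(y) // 2
            for tr, te in ((perm[:half], perm[half:]), (perm[half:], perm[:half])):
                if len(np.unique(y[tr])) < 2:
                    continue
                clf = SVC(kernel="linear", C=1.0)
                clf.fit(x[tr], y[tr])
                accs.append(clf.score(x[te], y[te]))
    return float(np.mean(accs))
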