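"""Penalized maximum-entropy species distribution model.

A presence-background SDM of the maxent family, written from scratch: the
species' distribution over landscape cells is modelled as the Gibbs
distribution ``q_lambda(x) proportional to exp(lambda . f(x))`` whose feature
expectations match the presence sample, fitted as an L1-penalized
log-likelihood of presences against a background sample:

    J(lambda) = mean_presence[lambda . f]
              - log(mean_background[exp(lambda . f)])
              - rm * sum_j beta_j |lambda_j|

Feature classes follow the field's convention — linear (L), quadratic (Q),
product (P) and hinge (H) expansions of predictors scaled to [0, 1] — and
the per-feature penalties ``beta_j`` shrink with presence sample size
(1/sqrt(n) for L/Q/P, 2.5/sqrt(n) for hinge), scaled by the regularization
multiplier ``rm``.  The concave objective is maximized by accelerated
proximal gradient descent with backtracking.

Model selection mirrors the ENMeval-style protocol: a grid of
regularization multipliers and feature-class sets, each scored by AICc on
the presences with ties (delta AICc < 2) broken by cross-validated
omission rate and then test AUC.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .occurrences import OccurrenceSet
from .raster import RasterGrid

__all__ = [
    "Background", "MaxentModel", "EvalReport", "ThresholdResult",
    "sample_background", "extract_presence_values", "build_features",
    "fit_maxent", "predict_suitability", "auc_score", "cv_evaluate",
    "aicc_score", "tune_model", "compute_threshold", "binarize_map",
    "importance_suite", "response_curve",
]

VALID_CLASSES = set("LQHP")
DEFAULT_KNOTS = 20


# --------------------------------------------------------------------------- data
@dataclasses.dataclass
class Background:
    """Background (pseudo-absence) sample: cell coordinates + predictor values."""

    x: np.ndarray
    y: np.ndarray
    values: pd.DataFrame  # one column per predictor

    def __len__(self) -> int:
        return len(self.values)


def _stack_frame(stack: dict[str, RasterGrid]) -> tuple[pd.DataFrame, np.ndarray, RasterGrid]:
    """Flatten a stack to (cell table, valid mask, template grid)."""
    names = list(stack)
    template = stack[names[0]]
    for g in stack.values():
        if not g.same_grid(template):
            raise ValueError("stack layers are not co-registered")
    cols = {n: stack[n].values.ravel() for n in names}
    df = pd.DataFrame(cols)
    valid = np.isfinite(df.to_numpy()).all(axis=1)
    return df, valid, template


def sample_background(stack: dict[str, RasterGrid], n: int = 10_000,
                      bias: RasterGrid | None = None, seed: int = 0,
                      replace: bool = False) -> Background:
    """Sample background cells, with probability proportional to a bias layer.

    With no bias layer the sample is uniform over valid cells.  Sampling is
    without replacement by default, so ``n`` may not exceed the number of
    valid cells (with a bias layer, the number of positive-bias cells).
    """
    df, valid, template = _stack_frame(stack)
    gx, gy = template.cell_centers()
    idx_valid = np.flatnonzero(valid)
    if bias is not None:
        if not bias.same_grid(template):
            raise ValueError("bias layer is not on the stack grid")
        w = bias.values.ravel()[idx_valid]
        w = np.where(np.isfinite(w), w, 0.0)
        if w.sum() <= 0:
            raise ValueError("bias layer is zero over all valid cells")
        p = w / w.sum()
    else:
        p = None
    rng = np.random.default_rng(seed)
    n_avail = len(idx_valid) if p is None else int(np.count_nonzero(p))
    if not replace and n > n_avail:
        raise ValueError(f"cannot draw {n} cells without replacement from {n_avail}")
    chosen = rng.choice(idx_valid, size=n, replace=replace, p=p)
    return Background(gx.ravel()[chosen], gy.ravel()[chosen],
                      df.iloc[chosen].reset_index(drop=True))


def extract_presence_values(occ: OccurrenceSet,
                            stack: dict[str, RasterGrid]) -> pd.DataFrame:
    """Predictor values at presence points (nearest cell); NaN rows dropped."""
    out = {}
    for name, grid in stack.items():
        out[name] = grid.sample(occ.records["x"].to_numpy(float),
                                occ.records["y"].to_numpy(float))
    df = pd.DataFrame(out)
    return df.dropna().reset_index(drop=True)


# ------------------------------------------------------------------- features
def _scale01(values: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    span = np.where(hi > lo, hi - lo, 1.0)
    return np.clip((values - lo) / span, 0.0, 1.0)


def build_features(values: np.ndarray, fc: str, names: list[str] | None = None,
                   n_knots: int = DEFAULT_KNOTS) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Expand scaled-[0,1] predictors into the requested feature classes.

    Deterministic feature order: all L, then Q, then P (pairs i<j), then
    hinge features grouped per predictor (forward then reverse per knot).
    Forward hinge at knot k is ``max(0, (x-k)/(1-k))``; reverse is
    ``max(0, (k-x)/k)``.  Returns (feature matrix, feature names, owner
    index array mapping each feature to its predictor(s)).
    """
    fc = fc.upper()
    unknown = set(fc) - VALID_CLASSES
    if unknown:
        raise ValueError(f"unknown feature class letters: {sorted(unknown)}")
    if not fc:
        raise ValueError("at least one feature class is required")
    X = np.asarray(values, dtype=float)
    n, p = X.shape
    if names is None:
        names = [f"v{i}" for i in range(p)]

    feats: list[np.ndarray] = []
    fnames: list[str] = []
    owners: list[tuple[int, ...]] = []

    if "L" in fc:
        for j in range(p):
            feats.append(X[:, j]); fnames.append(f"L:{names[j]}"); owners.append((j,))
    if "Q" in fc:
        for j in range(p):
            feats.append(X[:, j] ** 2); fnames.append(f"Q:{names[j]}"); owners.append((j,))
    if "P" in fc:
        for i, j in itertools.combinations(range(p), 2):
            feats.append(X[:, i] * X[:, j])
            fnames.append(f"P:{names[i]}*{names[j]}"); owners.append((i, j))
    if "H" in fc:
        knots = np.linspace(0, 1, n_knots + 2)[1:-1]
        for j in range(p):
            for k in knots:
                feats.append(np.maximum(0.0, (X[:, j] - k) / (1.0 - k)))
                fnames.append(f"Hf:{names[j]}@{k:.3f}"); owners.append((j,))
                feats.append(np.maximum(0.0, (k - X[:, j]) / k))
                fnames.append(f"Hr:{names[j]}@{k:.3f}"); owners.append((j,))
    F = np.column_stack(feats) if feats else np.empty((n, 0))
    return F, fnames, np.array(owners, dtype=object)


@dataclasses.dataclass
class MaxentModel:
    """Fitted penalized maxent model."""

    predictor_names: list[str]
    feature_classes: str
    rm: float
    n_knots: int
    scale_min: np.ndarray           # per-predictor scaling bounds
    scale_max: np.ndarray
    weights: np.ndarray             # lambda over expanded features
    feature_names: list[str]
    log_normalizer: float           # log of background mean exp(lambda.f)
    entropy: float                  # entropy of the background Gibbs distribution
    n_background: int
    background_feature_sd: np.ndarray
    background_mean: np.ndarray     # per-predictor mean (raw units)
    converged: bool
    n_presence: int

    @property
    def n_parameters(self) -> int:
        return int(np.count_nonzero(self.weights))

    # feature pipeline shared by fit and predict
    def features(self, values: np.ndarray) -> np.ndarray:
        Z = _scale01(np.asarray(values, float), self.scale_min, self.scale_max)
        F, _, _ = build_features(Z, self.feature_classes, self.predictor_names,
                                 self.n_knots)
        return F

    def raw(self, values: np.ndarray) -> np.ndarray:
        """Raw suitability: exp score normalized to background mean 1."""
        return np.exp(self.features(values) @ self.weights - self.log_normalizer)

    def save(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for k in ("scale_min", "scale_max", "weights", "background_feature_sd",
                  "background_mean"):
            d[k] = list(map(float, d[k]))
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "MaxentModel":
        d = json.loads(Path(path).read_text())
        for k in ("scale_min", "scale_max", "weights", "background_feature_sd",
                  "background_mean"):
            d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


def _penalty_weights(feature_names: list[str], n_presence: int) -> np.ndarray:
    """Default per-feature L1 penalties: 1/sqrt(n) for L/Q/P, 2.5/sqrt(n) for hinge."""
    base = np.array([2.5 if fn.startswith(("Hf:", "Hr:")) else 1.0
                     for fn in feature_names])
    return base / np.sqrt(max(n_presence, 1))


def fit_maxent(presence: pd.DataFrame | np.ndarray,
               background: Background | pd.DataFrame | np.ndarray,
               fc: str = "L", rm: float = 1.0,
               max_iter: int = 500, tol: float = 1e-5,
               n_knots: int = DEFAULT_KNOTS) -> MaxentModel:
    """Fit the L1-penalized maxent likelihood by accelerated proximal gradient.

    Convergence is declared when the largest weight change in an iteration
    falls below ``tol``; hitting the iteration cap sets ``converged=False``
    on the model (a warning, not an exception).
    """
    if isinstance(background, Background):
        bg_df = background.values
    else:
        bg_df = pd.DataFrame(background)
    pres_df = pd.DataFrame(presence)
    if list(pres_df.columns) != list(bg_df.columns):
        pres_df.columns = bg_df.columns
    names = [str(c) for c in bg_df.columns]

    P = pres_df.to_numpy(float)
    B = bg_df.to_numpy(float)
    if len(P) < 2:
        raise ValueError("need at least 2 presences")
    if len(B) == 0:
        raise ValueError("background is empty")
    if not (np.isfinite(P).all() and np.isfinite(B).all()):
        raise ValueError("non-finite predictor values")

    lo = np.minimum(P.min(axis=0), B.min(axis=0))
    hi = np.maximum(P.max(axis=0), B.max(axis=0))
    Fp, fnames, _ = build_features(_scale01(P, lo, hi), fc, names, n_knots)
    Fb, _, _ = build_features(_scale01(B, lo, hi), fc, names, n_knots)

    beta = rm * _penalty_weights(fnames, len(P))
    mean_p = Fp.mean(axis=0)
    m = Fp.shape[1]

    def smooth_neg(lam: np.ndarray) -> tuple[float, np.ndarray]:
        s = Fb @ lam
        smax = s.max()
        w = np.exp(s - smax)
        Z = w.mean()
        grad = (Fb * w[:, None]).mean(axis=0) / Z - mean_p
        val = np.log(Z) + smax - mean_p @ lam
        return val, grad

    lam = np.zeros(m)
    ylam = lam.copy()
    t_mom = 1.0
    step = 1.0
    converged = False
    f_y, g_y = smooth_neg(ylam)
    for _ in range(max_iter):
        # backtracking on the smooth part
        while True:
            cand = ylam - step * g_y
            cand = np.sign(cand) * np.maximum(np.abs(cand) - step * beta, 0.0)
            f_c, _ = smooth_neg(cand)
            diff = cand - ylam
            quad = f_y + g_y @ diff + (diff @ diff) / (2 * step)
            if f_c <= quad + 1e-12 or step < 1e-12:
                break
            step *= 0.5
        t_next = (1 + np.sqrt(1 + 4 * t_mom**2)) / 2
        delta = cand - lam
        ylam = cand + ((t_mom - 1) / t_next) * delta
        lam_prev, lam = lam, cand
        t_mom = t_next
        # restart momentum if objective direction reverses
        if delta @ (lam_prev - ylam) > 0:
            ylam = lam.copy()
            t_mom = 1.0
        f_y, g_y = smooth_neg(ylam)
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
    if not converged:
        warnings.warn("maxent fit reached the iteration cap without convergence")

    s_b = Fb @ lam
    smax = s_b.max()
    logZ = np.log(np.mean(np.exp(s_b - smax))) + smax
    q = np.exp(s_b - smax)
    q = q / q.sum()
    entropy = float(-(q * np.log(np.where(q > 0, q, 1.0))).sum())

    return MaxentModel(
        predictor_names=names, feature_classes=fc.upper(), rm=rm,
        n_knots=n_knots, scale_min=lo, scale_max=hi, weights=lam,
        feature_names=fnames, log_normalizer=float(logZ), entropy=entropy,
        n_background=len(B), background_feature_sd=Fb.std(axis=0),
        background_mean=B.mean(axis=0), converged=converged,
        n_presence=len(P),
    )


# ------------------------------------------------------------------ prediction
def _transform(raw: np.ndarray, output: str, entropy: float, n_background: int) -> np.ndarray:
    if output == "raw":
        return raw
    if output == "logistic":
        tau = 0.5
        return tau * raw / ((1 - tau) + tau * raw)
    if output == "cloglog":
        # scale so a uniform model (raw = 1 everywhere) maps to 1 - exp(-1);
        # equals the standard entropy-based scaling on sum-normalized raw
        c = np.exp(entropy) / n_background
        return 1.0 - np.exp(-c * raw)
    raise ValueError(f"unknown output format {output!r}")


def predict_suitability(model: MaxentModel, stack: dict[str, RasterGrid],
                        output: str = "cloglog") -> RasterGrid:
    """Predict a suitability surface over a stack in raw/logistic/cloglog form."""
    if list(stack) != model.predictor_names:
        raise ValueError(
            f"stack layers {list(stack)} do not match training predictors "
            f"{model.predictor_names}")
    df, valid, template = _stack_frame(stack)
    out = np.full(len(df), np.nan)
    raw = model.raw(df.to_numpy(float)[valid])
    out[valid] = _transform(raw, output, model.entropy, model.n_background)
    return template.like(out.reshape(template.shape))


def predict_values(model: MaxentModel, values: np.ndarray | pd.DataFrame,
                   output: str = "cloglog") -> np.ndarray:
    raw = model.raw(np.asarray(pd.DataFrame(values), float))
    return _transform(raw, output, model.entropy, model.n_background)


def auc_score(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Probability a random presence outscores a random background point
    (ties count one half) — the ROC AUC of presences vs background."""
    y = np.concatenate([np.ones(len(presence_scores)), np.zeros(len(background_scores))])
    s = np.concatenate([presence_scores, background_scores])
    if np.all(s == s[0]):
        return 0.5
    return float(roc_auc_score(y, s))


# ------------------------------------------------------------------ evaluation
@dataclasses.dataclass
class ThresholdResult:
    method: str
    value: float
    sensitivity: float
    specificity: float


def compute_threshold(presence_scores: np.ndarray, background_scores: np.ndarray,
                      method: str = "MTSS") -> ThresholdResult:
    """Suitability cutoff for binarizing a continuous prediction.

    MTSS scans the unique predicted values and keeps the threshold
    maximizing sensitivity + specificity (prediction >= threshold counts
    as suitable; ties resolved toward the smallest threshold).  P10 is the
    10th percentile of presence scores with linear interpolation.
    """
    pres = np.asarray(presence_scores, float)
    bg = np.asarray(background_scores, float)
    if len(pres) == 0 or len(bg) == 0:
        raise ValueError("empty score set")
    if method == "P10":
        thr = float(np.percentile(pres, 10))
        sens = float(np.mean(pres >= thr))
        spec = float(np.mean(bg < thr))
        return ThresholdResult("P10", thr, sens, spec)
    if method != "MTSS":
        raise ValueError(f"unknown threshold method {method!r}")
    candidates = np.unique(np.concatenate([pres, bg]))
    best = None
    for thr in candidates:  # ascending, so ties keep the smallest threshold
        sens = np.mean(pres >= thr)
        spec = np.mean(bg < thr)
        if best is None or sens + spec > best[0] + 1e-15:
            best = (sens + spec, thr, sens, spec)
    _, thr, sens, spec = best
    return ThresholdResult("MTSS", float(thr), float(sens), float(spec))


def aicc_score(model: MaxentModel, presence: pd.DataFrame | np.ndarray,
               cells: pd.DataFrame | np.ndarray | None = None) -> float:
    """Small-sample AIC of the presences under the fitted Gibbs distribution.

    The landscape is discretized by ``cells`` (default: the background
    sample the model was trained on is unavailable here, so callers pass
    the stack's valid cells or the background values); raw scores are
    normalized to sum 1 over those cells.  K counts nonzero weights; when
    n <= K + 1 the correction diverges and +inf is returned with a warning.
    """
    P = np.asarray(pd.DataFrame(presence), float)
    n = len(P)
    K = model.n_parameters
    if n <= K + 1:
        warnings.warn(f"AICc undefined for n={n} presences and K={K} parameters")
        return float("inf")
    if cells is None:
        raise ValueError("aicc_score needs landscape cells for normalization")
    C = np.asarray(pd.DataFrame(cells), float)
    raw_cells = model.raw(C)
    raw_pres = model.raw(P)
    lnL = float(np.sum(np.log(raw_pres / raw_cells.sum())))
    return 2 * K - 2 * lnL + (2 * K * (K + 1)) / (n - K - 1)


@dataclasses.dataclass
class EvalReport:
    folds: pd.DataFrame          # train_auc, test_auc, omission per fold
    mean_test_auc: float
    sd_test_auc: float
    mean_train_auc: float
    sd_train_auc: float
    mean_omission: float
    sd_omission: float
    aicc: float
    n_parameters: int


def cv_evaluate(presence: pd.DataFrame | np.ndarray, background: Background,
                fc: str = "L", rm: float = 1.0, k: int = 5, seed: int = 0,
                max_iter: int = 500, tol: float = 1e-5,
                n_knots: int = DEFAULT_KNOTS) -> EvalReport:
    """k-fold cross-validation of one model configuration.

    Presences are randomly partitioned into k near-equal folds (sizes
    differ by at most one); each fold in turn is held out, the model is
    fitted on the rest, and the held-out fold is scored against the full
    background: test AUC and the omission rate at the training MTSS
    threshold.  The report also carries the AICc of the model refitted on
    all presences.
    """
    pres_df = pd.DataFrame(presence)
    n = len(pres_df)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split {n} presences into {k} folds")
    rng = np.random.default_rng(seed)
    fold_of = np.arange(n) % k
    rng.shuffle(fold_of)

    bg_scores_cache = None
    rows = []
    for fold in range(k):
        train = pres_df.iloc[fold_of != fold]
        test = pres_df.iloc[fold_of == fold]
        m = fit_maxent(train, background, fc=fc, rm=rm, max_iter=max_iter,
                       tol=tol, n_knots=n_knots)
        bg_scores = predict_values(m, background.values, "raw")
        tr_scores = predict_values(m, train, "raw")
        te_scores = predict_values(m, test, "raw")
        thr = compute_threshold(tr_scores, bg_scores, "MTSS")
        rows.append({
            "fold": fold,
            "train_auc": auc_score(tr_scores, bg_scores),
            "test_auc": auc_score(te_scores, bg_scores),
            "omission": float(np.mean(te_scores < thr.value)),
        })
        bg_scores_cache = bg_scores
    folds = pd.DataFrame(rows)

    full = fit_maxent(pres_df, background, fc=fc, rm=rm, max_iter=max_iter,
                      tol=tol, n_knots=n_knots)
    aicc = aicc_score(full, pres_df, cells=background.values)
    return EvalReport(
        folds=folds,
        mean_test_auc=float(folds["test_auc"].mean()),
        sd_test_auc=float(folds["test_auc"].std(ddof=1)),
        mean_train_auc=float(folds["train_auc"].mean()),
        sd_train_auc=float(folds["train_auc"].std(ddof=1)),
        mean_omission=float(folds["omission"].mean()),
        sd_omission=float(folds["omission"].std(ddof=1)),
        aicc=aicc,
        n_parameters=full.n_parameters,
    )


DEFAULT_RM_GRID = tuple(np.arange(0.5, 4.01, 0.5))
DEFAULT_FC_GRID = ("L", "LQ", "H", "LQH", "LQHP")


def tune_model(presence: pd.DataFrame | np.ndarray, background: Background,
               rm_grid=DEFAULT_RM_GRID, fc_grid=DEFAULT_FC_GRID,
               k: int = 5, seed: int = 0, **fit_kw) -> tuple[dict, pd.DataFrame]:
    """Grid search over regularization multiplier x feature classes.

    Every cell of the grid is fitted and cross-validated; models are ranked
    by AICc, with near-ties (delta AICc < 2) broken by lower mean test
    omission, then higher mean test AUC, then listing order.  Returns the
    winning ``{"rm": ..., "fc": ...}`` and the full selection table.
    """
    if not len(rm_grid) or not len(fc_grid):
        raise ValueError("empty tuning grid")
    rows = []
    for order, (fc, rm) in enumerate(itertools.product(fc_grid, rm_grid)):
        rep = cv_evaluate(presence, background, fc=fc, rm=rm, k=k, seed=seed,
                          **fit_kw)
        rows.append({"order": order, "fc": fc, "rm": rm, "aicc": rep.aicc,
                     "n_parameters": rep.n_parameters,
                     "mean_test_auc": rep.mean_test_auc,
                     "mean_omission": rep.mean_omission})
    table = pd.DataFrame(rows)
    finite = table[np.isfinite(table["aicc"])]
    if finite.empty:
        raise ValueError("all tuning-grid cells are degenerate (AICc undefined)")
    best_aicc = finite["aicc"].min()
    near = finite[finite["aicc"] - best_aicc < 2.0]
    near = near.sort_values(["mean_omission", "mean_test_auc", "order"],
                            ascending=[True, False, True], kind="stable")
    winner = near.iloc[0]
    table = table.drop(columns="order")
    return {"rm": float(winner["rm"]), "fc": str(winner["fc"])}, table


def binarize_map(suit: RasterGrid, threshold: float) -> RasterGrid:
    """Binary suitable (1) / unsuitable (0) map at ``value >= threshold``."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    v = suit.values
    out = np.where(np.isfinite(v), (v >= threshold).astype(float), np.nan)
    return suit.like(out)


# ------------------------------------------------------------------ diagnostics
def _gain(model: MaxentModel, presence: pd.DataFrame) -> float:
    """Unpenalized training gain: mean presence log raw score."""
    return float(np.mean(np.log(model.raw(np.asarray(pd.DataFrame(presence), float)))))


def importance_suite(model: MaxentModel, presence: pd.DataFrame,
                     background: Background, n_permutations: int = 10,
                     seed: int = 0, refit_kw: dict | None = None) -> pd.DataFrame:
    """Per-predictor importance: permutation importance, percent
    contribution, and jackknife gains.

    Permutation importance permutes one predictor's values jointly across
    presence and background rows and records the drop in training AUC
    (averaged over ``n_permutations`` shuffles), normalized to sum 100.
    Percent contribution is a path-independent surrogate — the sum of
    |weight| x background feature standard deviation over the predictor's
    features (product features split evenly between their two predictors),
    normalized to 100; it is not identical to the path-dependent tracking
    of the original maxent software.  The jackknife refits the model with
    only / without each predictor and reports the training gains.
    """
    refit_kw = refit_kw or {}
    pres_df = pd.DataFrame(presence)
    names = model.predictor_names
    P = pres_df.to_numpy(float)
    B = background.values.to_numpy(float)
    rng = np.random.default_rng(seed)

    base_auc = auc_score(model.raw(P), model.raw(B))
    n_p = len(P)
    stacked = np.vstack([P, B])

    perm_drop = np.zeros(len(names))
    for j in range(len(names)):
        drops = []
        for _ in range(n_permutations):
            shuf = stacked.copy()
            shuf[:, j] = rng.permutation(shuf[:, j])
            auc = auc_score(model.raw(shuf[:n_p]), model.raw(shuf[n_p:]))
            drops.append(max(0.0, base_auc - auc))
        perm_drop[j] = np.mean(drops)
    if perm_drop.sum() > 0:
        perm_imp = 100 * perm_drop / perm_drop.sum()
    elif len(names) == 1:
        perm_imp = np.array([100.0])
    else:
        perm_imp = np.zeros(len(names))

    # contribution surrogate from |weight| x feature spread
    _, fnames, owners = build_features(
        _scale01(B, model.scale_min, model.scale_max),
        model.feature_classes, names, model.n_knots)
    contrib = np.zeros(len(names))
    for w, sd, own in zip(model.weights, model.background_feature_sd, owners):
        share = abs(w) * sd / len(own)
        for j in own:
            contrib[j] += share
    if contrib.sum() > 0:
        contrib = 100 * contrib / contrib.sum()

    # jackknife: refit with only / without each predictor
    only_gain = np.zeros(len(names))
    without_gain = np.full(len(names), np.nan)
    fit_args = dict(fc=model.feature_classes, rm=model.rm,
                    n_knots=model.n_knots)
    fit_args.update(refit_kw)
    for j, name in enumerate(names):
        m_only = fit_maxent(pres_df[[name]],
                            background.values[[name]], **fit_args)
        only_gain[j] = _gain(m_only, pres_df[[name]])
        if len(names) > 1:
            rest = [c for c in names if c != name]
            m_wo = fit_maxent(pres_df[rest], background.values[rest], **fit_args)
            without_gain[j] = _gain(m_wo, pres_df[rest])

    return pd.DataFrame({
        "variable": names,
        "permutation_importance": perm_imp,
        "percent_contribution": contrib,
        "jackknife_only_gain": only_gain,
        "jackknife_without_gain": without_gain,
    })


def response_curve(model: MaxentModel, variable: str,
                   n_points: int = 100, output: str = "cloglog") -> pd.DataFrame:
    """Marginal response: vary one predictor over its range with the others
    held at their background means."""
    if variable not in model.predictor_names:
        raise KeyError(f"unknown variable {variable!r}")
    j = model.predictor_names.index(variable)
    grid = np.linspace(model.scale_min[j], model.scale_max[j], n_points)
    base = np.tile(model.background_mean, (n_points, 1))
    base[:, j] = grid
    return pd.DataFrame({"value": grid,
                         "suitability": predict_values(model, base, output)})
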