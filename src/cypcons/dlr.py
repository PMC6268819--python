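"""Docking-score logistic-regression (DLR) classifier.

Docking scores from several programs and binding sites are standardized and
combined in a single logistic model for the probability that a compound is a
potent CYP3A4 inhibitor.  Variables are chosen by forward/backward stepwise
Wald tests or by a "manual" procedure (keep full-model-significant columns,
then add the fewest near-significant ones until the training ROC AUC clears
a floor).  Because docking poorly resolves small ligands, the model can be
restricted to the high-molecular-weight applicability domain (TD-DLR).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .corpus import DEFAULT_BAND_THRESHOLD

DEFAULT_CUTOFF = 0.5

DOCKING_PROGRAMS = ("ehits", "fred", "surflex", "glide")
DOCKING_SITES = (
    "1TQN.catalytic",
    "1W0F.catalytic",
    "1W0F.entrance",
    "2J0D.catalytic",
    "2V0M.catalytic",
    "2V0M.secondary",
    "2V0M.full",
)


def default_score_columns() -> list[str]:
    """The 28 program-by-site docking-score column names."""
    return [f"{prog}.{site}" for prog in DOCKING_PROGRAMS for site in DOCKING_SITES]


class Selection(str, Enum):
    FORWARD = "forward"
    BACKWARD = "backward"
    MANUAL = "manual"
    FIXED = "fixed"


@dataclass
class Standardization:
    mean: pd.Series
    sd: pd.Series


def standardize(
    matrix: pd.DataFrame, training_stats: Standardization | None = None, ddof: int = 1
) -> tuple[pd.DataFrame, Standardization]:
    """Z-score a score matrix; apply-time rows reuse stored training statistics.

    Sample SD (ddof=1) by default; constant training columns are an error.
    """
    if training_stats is None:
        mean = matrix.mean()
        sd = matrix.std(ddof=ddof)
        bad = sd.index[(sd == 0) | sd.isna()].tolist()
        if bad:
            raise ValueError(f"constant score column(s): {bad}")
        training_stats = Standardization(mean=mean, sd=sd)
    missing = [c for c in training_stats.mean.index if c not in matrix.columns]
    if missing:
        raise ValueError(f"score matrix lacks trained columns: {missing}")
    cols = list(training_stats.mean.index)
    z = (matrix[cols] - training_stats.mean) / training_stats.sd
    return z, training_stats


@dataclass
class LogisticModel:
    columns: list[str]
    coef: pd.Series  # indexed by columns
    intercept: float
    se: pd.Series  # includes "intercept"
    wald_chi2: pd.Series
    p_values: pd.Series
    selection: Selection
    converged: bool = True
    flags: list[str] = field(default_factory=list)
    auc_train: float | None = None
    standardization: Standardization | None = None

    def linear_predictor(self, z: pd.DataFrame | pd.Series) -> np.ndarray:
        if isinstance(z, pd.Series):
            z = z.to_frame().T
        missing = [c for c in self.columns if c not in z.columns]
        if missing:
            raise ValueError(f"row lacks model column(s): {missing}")
        return self.intercept + z[self.columns].to_numpy(dtype=float) @ self.coef.to_numpy()

    def predict_proba(self, z: pd.DataFrame | pd.Series) -> np.ndarray:
        eta = self.linear_predictor(z)
        return 1.0 / (1.0 + np.exp(-eta))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "columns": self.columns,
            "coef": self.coef.to_dict(),
            "intercept": self.intercept,
            "se": self.se.to_dict(),
            "wald_chi2": self.wald_chi2.to_dict(),
            "p_values": self.p_values.to_dict(),
            "selection": self.selection.value,
            "converged": self.converged,
            "flags": self.flags,
            "auc_train": self.auc_train,
        }
        if self.standardization is not None:
            payload["standardization"] = {
                "mean": self.standardization.mean.to_dict(),
                "sd": self.standardization.sd.to_dict(),
            }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "LogisticModel":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        stats = None
        if "standardization" in d:
            stats = Standardization(mean=pd.Series(d["standardization"]["mean"]), sd=pd.Series(d["standardization"]["sd"]))
        return cls(
            columns=d["columns"],
            coef=pd.Series(d["coef"]).reindex(d["columns"]),
            intercept=float(d["intercept"]),
            se=pd.Series(d["se"]),
            wald_chi2=pd.Series(d["wald_chi2"]),
            p_values=pd.Series(d["p_values"]),
            selection=Selection(d["selection"]),
            converged=bool(d.get("converged", True)),
            flags=list(d.get("flags", [])),
            auc_train=d.get("auc_train"),
            standardization=stats,
        )


def _as_binary(labels) -> np.ndarray:
    y = np.asarray([1 if str(v).upper() in ("1", "P", "POTENT", "TRUE") else 0 for v in np.asarray(labels)])
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    return y


def fit_logistic(z: pd.DataFrame, labels, columns: list[str] | None = None, selection: Selection = Selection.MANUAL) -> LogisticModel:
    """Maximum-likelihood logistic fit with Wald statistics.

    Uses Newton-type iteratively reweighted least squares; standard errors
    come from the observed information.  Separation or non-convergence is
    reported on the returned model's flags.
    """
    cols = list(z.columns if columns is None else columns)
    y = _as_binary(labels)
    if len(cols) > len(y) / 2:
        warnings.warn(
            f"{len(cols)} predictors for {len(y)} compounds exceeds the 1-in-20 rule of thumb for logistic models",
            stacklevel=2,
        )
    X = sm.add_constant(z[cols].to_numpy(dtype=float), has_constant="add")
    flags: list[str] = []
    params = bse = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X)
        try:
            res = model.fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", True))
            params = np.asarray(res.params, dtype=float)
            bse = np.asarray(res.bse, dtype=float)
            if not np.all(np.isfinite(bse)):
                converged = False
        except Exception:
            converged = False
    if not converged or params is None:
        # separation or a singular information matrix: stabilize with a small
        # L2 penalty and report Wald statistics from the penalized information
        params, bse, iters = _ridge_logit(X, y, alpha=1e-2)
        flags.append(
            f"maximum-likelihood fit separated or failed to converge; "
            f"L2-stabilized fit (alpha=1e-2, {iters} Newton steps) reported instead"
        )
        converged = False
    names = ["intercept"] + cols
    se = pd.Series(bse, index=names)
    coef = pd.Series(params[1:], index=cols)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = pd.Series((params / bse) ** 2, index=names)
    from scipy import stats as sps

    p = pd.Series(sps.chi2.sf(chi2.to_numpy(), df=1), index=names)
    return LogisticModel(
        columns=cols, coef=coef, intercept=float(params[0]), se=se,
        wald_chi2=chi2, p_values=p, selection=selection, converged=converged, flags=flags,
    )


def _ridge_logit(X: np.ndarray, y: np.ndarray, alpha: float = 1e-2, maxiter: int = 100):
    """Newton solver for the L2-penalized logistic log-likelihood.

    The intercept is not penalized.  Standard errors come from the inverse
    penalized observed information; with a small alpha they are a stabilized
    approximation used only when the unpenalized fit separates.
    """
    n, p = X.shape
    beta = np.zeros(p)
    pen = np.full(p, alpha)
    pen[0] = 0.0
    it = 0
    for it in range(1, maxiter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - pen * beta
        H = X.T @ (X * w[:, None]) + np.diag(pen)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    H = X.T @ (X * w[:, None]) + np.diag(pen)
    cov = np.linalg.inv(H)
    return beta, np.sqrt(np.maximum(np.diag(cov), 0.0)), it


def _candidate_order(p_values: pd.Series, coefs: pd.Series) -> list[str]:
    # ties on p broken by larger |coefficient|, then column name
    return sorted(p_values.index, key=lambda c: (p_values[c], -abs(coefs.get(c, 0.0)), c))


def select_stepwise(z: pd.DataFrame, labels, direction: str = "forward", alpha: float = 0.05) -> LogisticModel:
    """Forward or backward stepwise selection on Wald p-values, refitting each step."""
    y = labels
    cols = list(z.columns)
    if direction == "forward":
        selected: list[str] = []
        while True:
            best = None
            for c in [c for c in cols if c not in selected]:
                m = fit_logistic(z, y, selected + [c], selection=Selection.FORWARD)
                pv = float(m.p_values[c])
                key = (pv, -abs(float(m.coef[c])), c)
                if best is None or key < best[0]:
                    best = (key, c, m)
            if best is None or best[0][0] > alpha:
                break
            selected.append(best[1])
        model = fit_logistic(z, y, selected, selection=Selection.FORWARD) if selected else _intercept_only(z, y, Selection.FORWARD)
        return model
    if direction == "backward":
        selected = list(cols)
        model = fit_logistic(z, y, selected, selection=Selection.BACKWARD)
        while selected:
            pv = model.p_values.drop("intercept")
            worst = _candidate_order(pv, model.coef)[-1]
            if float(pv[worst]) <= alpha:
                break
            selected.remove(worst)
            if not selected:
                return _intercept_only(z, y, Selection.BACKWARD)
            model = fit_logistic(z, y, selected, selection=Selection.BACKWARD)
        return model
    raise ValueError("direction must be 'forward' or 'backward'")


def _intercept_only(z: pd.DataFrame, labels, selection: Selection) -> LogisticModel:
    y = _as_binary(labels)
    p = y.mean()
    b0 = float(np.log(p / (1 - p)))
    se0 = float(1.0 / np.sqrt(len(y) * p * (1 - p)))
    from scipy import stats as sps

    chi2 = (b0 / se0) ** 2
    return LogisticModel(
        columns=[], coef=pd.Series(dtype=float), intercept=b0,
        se=pd.Series({"intercept": se0}), wald_chi2=pd.Series({"intercept": chi2}),
        p_values=pd.Series({"intercept": float(sps.chi2.sf(chi2, 1))}), selection=selection,
        flags=["intercept-only model"],
    )


def select_manual(
    z: pd.DataFrame,
    labels,
    alpha: float = 0.05,
    relaxed_alpha: float = 0.10,
    auc_floor: float = 0.8,
) -> LogisticModel:
    """Full-model-significant columns, topped up until the training AUC clears the floor.

    Columns significant at ``alpha`` in the full model are kept; if the
    resulting training ROC AUC is at or below ``auc_floor``, the fewest
    additional full-model columns with p < ``relaxed_alpha`` are added
    best-first.  An unreachable floor is flagged, not forced.
    """
    full = fit_logistic(z, labels, selection=Selection.MANUAL)
    pv = full.p_values.drop("intercept")
    keep = [c for c in z.columns if float(pv[c]) <= alpha]
    candidates = [c for c in _candidate_order(pv, full.coef) if relaxed_alpha > float(pv[c]) > alpha]

    def build(cols):
        m = fit_logistic(z, labels, cols, selection=Selection.MANUAL) if cols else _intercept_only(z, labels, Selection.MANUAL)
        m.auc_train = roc(m.predict_proba(z), labels).auc if cols else 0.5
        return m

    model = build(keep)
    while model.auc_train is not None and model.auc_train <= auc_floor and candidates:
        keep = keep + [candidates.pop(0)]
        model = build(keep)
    if model.auc_train is not None and model.auc_train <= auc_floor:
        model.flags.append(f"training ROC AUC {model.auc_train:.3f} did not clear the floor {auc_floor}")
    return model


@dataclass
class RocCurve:
    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    points: dict = field(default_factory=dict)  # named A/B/C/D cutoffs with metrics


def roc(scores, labels, cutoff_grid_step: float = 0.01) -> RocCurve:
    """ROC analysis of probability scores.

    The sens/spec table and the named cutoff points run over a fixed
    probability grid; the AUC is the exact trapezoid over all unique-score
    thresholds, which equals the Mann-Whitney rank statistic of the scores
    (ties counted half).
    """
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    cutoffs = np.round(np.arange(0.0, 1.0 + cutoff_grid_step / 2, cutoff_grid_step), 10)
    sens = np.array([(pos >= c).mean() for c in cutoffs])
    spec = np.array([(neg < c).mean() for c in cutoffs])

    # exact AUC: P(score_pos > score_neg) + 0.5 P(tie), via average ranks
    ranks = pd.Series(s).rank(method="average").to_numpy()
    auc = float((ranks[y == 1].sum() - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg)))

    accuracy = (sens * len(pos) + spec * len(neg)) / len(s)
    max_spec = spec.max()
    with_signal = (spec == max_spec) & (sens > 0)
    a_pool = np.nonzero(with_signal if with_signal.any() else spec == max_spec)[0]
    idx_a = a_pool[np.argmax(cutoffs[a_pool])]
    acc_max = accuracy.max()
    b_pool = np.nonzero(accuracy == acc_max)[0]
    idx_b = b_pool[np.argmax(cutoffs[b_pool])]
    idx_c = int(np.argmin(np.abs(sens - spec)))
    sens_max = sens.max()
    d_pool = np.nonzero(sens == sens_max)[0]
    idx_d = d_pool[np.argmin(cutoffs[d_pool])]
    points = {
        name: {
            "cutoff": float(cutoffs[i]),
            "sensitivity": float(sens[i]),
            "specificity": float(spec[i]),
            "accuracy": float(accuracy[i]),
        }
        for name, i in {"A": idx_a, "B": idx_b, "C": idx_c, "D": idx_d}.items()
    }
    return RocCurve(cutoffs=cutoffs, sensitivity=sens, specificity=spec, auc=auc, points=points)


def score_probability(model: LogisticModel, z_row: pd.Series, cutoff: float = DEFAULT_CUTOFF) -> tuple[float, str]:
    """Probability of potency for one standardized score row, with the class call."""
    p = float(model.predict_proba(z_row)[0])
    return p, ("P" if p >= cutoff else "W")


def truncate_domain(
    mws: pd.Series, band_threshold: float = DEFAULT_BAND_THRESHOLD
) -> tuple[pd.Index, pd.Index]:
    """Split compound ids into the high-MW applicability domain and exclusions."""
    inside = mws.index[mws > band_threshold]
    outside = mws.index[mws <= band_threshold]
    if len(inside) == 0:
        raise ValueError(f"no compounds above {band_threshold} Da: applicability domain is empty")
    return inside, outside


def published_model() -> LogisticModel:
    """The published seven-score docking model, shipped with fixed coefficients.

    Scoring with it needs no re-docking; the fitting path is exercised on
    synthetic score matrices instead.
    """
    rows = [
        ("surflex.1W0F.catalytic", 5.5653, 1.5783, 12.4342, 0.0004),
        ("fred.2V0M.catalytic", -2.2601, 0.8146, 7.6972, 0.0055),
        ("surflex.2J0D.catalytic", -1.7176, 0.6328, 7.3684, 0.0066),
        ("glide.2V0M.catalytic", 1.5078, 0.5545, 7.3927, 0.0065),
        ("fred.2V0M.full", 1.4618, 0.5385, 7.3740, 0.0066),
        ("glide.1W0F.catalytic", -1.2597, 0.5007, 6.3288, 0.0119),
        ("fred.1W0F.entrance", -1.0350, 0.6189, 2.7967, 0.0845),
    ]
    intercept = (-1.8088, 0.3556, 25.8789, 1e-4)
    cols = [r[0] for r in rows]
    coef = pd.Series({r[0]: r[1] for r in rows})
    se = pd.Series({**{r[0]: r[2] for r in rows}, "intercept": intercept[1]})
    chi2 = pd.Series({**{r[0]: r[3] for r in rows}, "intercept": intercept[2]})
    p = pd.Series({**{r[0]: r[4] for r in rows}, "intercept": intercept[3]})
    return LogisticModel(
        columns=cols, coef=coef, intercept=intercept[0], se=se,
        wald_chi2=chi2, p_values=p, selection=Selection.FIXED,
    )
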