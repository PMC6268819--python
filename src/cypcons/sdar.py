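"""Spectral data-activity relationship (SDAR) classifier.

Predicted 1D 13C and 15N chemical shifts are binned (1 ppm carbon, 5 ppm
nitrogen bins), sparsely populated bins are dropped, and a linear
discriminant model with equal class priors is grown by forward selection:
at each step the bin with the largest partial F (Wilks-lambda increment)
enters, provided F exceeds the F-to-enter threshold (default 4.0).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis


class Nucleus(str, Enum):
    C13 = "13C"
    N15 = "15N"

    @classmethod
    def parse(cls, text: str) -> "Nucleus":
        t = text.strip().upper().replace("^", "")
        if t in ("13C", "C13", "C"):
            return cls.C13
        if t in ("15N", "N15", "N"):
            return cls.N15
        raise ValueError(f"unknown nucleus {text!r}")


#: plausible shift ranges (ppm); violations warn but are kept
PLAUSIBLE_RANGE = {Nucleus.C13: (-20.0, 250.0), Nucleus.N15: (-50.0, 950.0)}

DEFAULT_BIN_WIDTHS = {Nucleus.C13: 1.0, Nucleus.N15: 5.0}
_PREFIX = {Nucleus.C13: "C", Nucleus.N15: "N"}


@dataclass(frozen=True)
class SpectrumPeaks:
    identifier: str
    nucleus: Nucleus
    shifts: tuple[float, ...]

    def __post_init__(self):
        lo, hi = PLAUSIBLE_RANGE[self.nucleus]
        bad = [s for s in self.shifts if not (lo <= s <= hi) or not np.isfinite(s)]
        if bad:
            warnings.warn(
                f"{self.identifier}: {self.nucleus.value} shifts outside the plausible range {lo}..{hi} ppm: {bad}",
                stacklevel=2,
            )


def bin_label(nucleus: Nucleus, shift: float, width: float) -> str:
    return f"{_PREFIX[nucleus]}{int(np.floor(shift / width))}"


def bin_spectra(
    peaks: list[SpectrumPeaks],
    widths: dict[Nucleus, float] | None = None,
    compounds: list[str] | None = None,
    binary: bool = False,
) -> pd.DataFrame:
    """Hit counts per (compound, bin); carbon and nitrogen bins are namespaced.

    Bin index is floor(shift / width).  With ``binary`` the matrix records
    presence instead of counts.
    """
    widths = dict(DEFAULT_BIN_WIDTHS if widths is None else widths)
    if any(w <= 0 for w in widths.values()):
        raise ValueError("bin widths must be positive")
    if compounds is None:
        compounds = list(dict.fromkeys(p.identifier for p in peaks))
    counts: dict[str, dict[str, int]] = {c: {} for c in compounds}
    for p in peaks:
        if p.identifier not in counts:
            counts[p.identifier] = {}
            compounds.append(p.identifier)
        row = counts[p.identifier]
        for s in p.shifts:
            lab = bin_label(p.nucleus, s, widths[p.nucleus])
            row[lab] = row.get(lab, 0) + 1
    empty = [c for c, row in counts.items() if not row]
    if empty:
        warnings.warn(f"compounds with no peaks (zero rows): {empty}", stacklevel=2)
    df = pd.DataFrame.from_dict(counts, orient="index").fillna(0).astype(int)
    df = df.reindex(index=compounds, fill_value=0)
    df = df[sorted(df.columns, key=lambda c: (c[0], int(c[1:])))]
    if binary:
        df = (df > 0).astype(int)
    df.index.name = "id"
    return df


def filter_bins(matrix: pd.DataFrame, min_compounds: int = 3) -> pd.DataFrame:
    """Keep bins hit by at least ``min_compounds`` distinct compounds."""
    populated = (matrix > 0).sum(axis=0)
    return matrix.loc[:, populated[populated >= min_compounds].index]


@dataclass
class DiscriminantModel:
    selected_bins: list[str]  # in order of entry
    entry_f: list[float]
    coef: np.ndarray  # discriminant direction over selected bins
    intercept: float
    class_means: pd.DataFrame  # classes x selected bins
    priors: tuple[float, float] = (0.5, 0.5)
    classes: tuple[str, str] = ("W", "P")
    flags: list[str] = field(default_factory=list)
    _lda: LinearDiscriminantAnalysis | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "selected_bins": self.selected_bins,
                    "entry_f": self.entry_f,
                    "coef": np.asarray(self.coef).tolist(),
                    "intercept": self.intercept,
                    "class_means": self.class_means.to_dict(),
                    "priors": list(self.priors),
                    "classes": list(self.classes),
                    "flags": self.flags,
                },
                indent=2,
            )
            + "\n",
            encoding="utf-8",
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "DiscriminantModel":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            selected_bins=d["selected_bins"],
            entry_f=d["entry_f"],
            coef=np.asarray(d["coef"], dtype=float),
            intercept=float(d["intercept"]),
            class_means=pd.DataFrame(d["class_means"]),
            priors=tuple(d["priors"]),
            classes=tuple(d["classes"]),
            flags=list(d.get("flags", [])),
        )


def _wilks_lambda(X: np.ndarray, y01: np.ndarray) -> float:
    """Wilks' Lambda det(W)/det(T) for a two-class problem on the given columns."""
    Xc = X - X.mean(axis=0)
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for g in (0, 1):
        Xg = X[y01 == g]
        Xg = Xg - Xg.mean(axis=0)
        W += Xg.T @ Xg
    sign_t, logdet_t = np.linalg.slogdet(T)
    sign_w, logdet_w = np.linalg.slogdet(W)
    if sign_t <= 0 or sign_w <= 0:
        return float("nan")  # singular: caller skips this candidate
    return float(np.exp(logdet_w - logdet_t))


def train_discriminant(
    matrix: pd.DataFrame,
    labels,
    f_enter: float = 4.0,
    max_steps: int | None = None,
) -> DiscriminantModel:
    """Forward stepwise two-class linear discriminant analysis with equal priors.

    Partial F of a candidate bin given p already-selected bins is
    ``(Lambda_p / Lambda_{p+1} - 1) * (n - 2 - p)`` (two classes).  Bins whose
    entry would make the within-class scatter singular are skipped with a
    warning.  Selection stops when no candidate reaches ``f_enter`` or when
    the selected count reaches n - 2.
    """
    y = np.asarray([1 if str(v).upper() in ("1", "P", "POTENT", "TRUE") else 0 for v in np.asarray(labels)])
    n = len(y)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least two compounds per class")
    X = matrix.to_numpy(dtype=float)
    cols = list(matrix.columns)
    selected: list[int] = []
    entry_f: list[float] = []
    flags: list[str] = []
    lambda_p = 1.0
    limit = n - 2 if max_steps is None else min(max_steps, n - 2)
    while len(selected) < limit:
        p = len(selected)
        best: tuple[float, int, float] | None = None  # (-F, col index, lambda)
        for j in range(len(cols)):
            if j in selected:
                continue
            lam = _wilks_lambda(X[:, selected + [j]], y)
            if np.isnan(lam) or lam <= 0:
                continue  # singular / collinear with already-entered bins
            F = (lambda_p / lam - 1.0) * (n - 2 - p)
            key = (-F, j)
            if best is None or key < (best[0], best[1]):
                best = (-F, j, lam)
        if best is None:
            flags.append("no admissible candidate bins remained")
            break
        F = -best[0]
        if F <= f_enter:
            break
        selected.append(best[1])
        entry_f.append(float(F))
        lambda_p = best[2]
    chosen = [cols[j] for j in selected]
    if not chosen:
        raise ValueError(f"no bin reached the F-to-enter threshold {f_enter}")
    lda = LinearDiscriminantAnalysis(priors=[0.5, 0.5])
    lda.fit(X[:, selected], y)
    means = pd.DataFrame(lda.means_, index=["W", "P"], columns=chosen)
    return DiscriminantModel(
        selected_bins=chosen,
        entry_f=entry_f,
        coef=lda.coef_.ravel().copy(),
        intercept=float(lda.intercept_[0]),
        class_means=means,
        flags=flags,
        _lda=lda,
    )


def classify_sdar(model: DiscriminantModel, matrix_row: pd.Series) -> tuple[str, float]:
    """Classify one binned spectrum; returns (category, posterior of the call).

    A row with no hits in any selected bin is classified from the intercepts
    alone and flagged low-information via a warning.
    """
    x = matrix_row.reindex(model.selected_bins, fill_value=0).to_numpy(dtype=float)
    if not np.any(x):
        warnings.warn("row has no hits in any model bin; low-information classification", stacklevel=2)
    eta = float(np.clip(x @ np.asarray(model.coef) + model.intercept, -700, 700))
    post_p = 1.0 / (1.0 + np.exp(-eta))
    return ("P", post_p) if post_p >= 0.5 else ("W", 1.0 - post_p)


def classify_matrix(model: DiscriminantModel, matrix: pd.DataFrame) -> pd.DataFrame:
    X = matrix.reindex(columns=model.selected_bins, fill_value=0).to_numpy(dtype=float)
    eta = np.clip(X @ np.asarray(model.coef) + model.intercept, -700, 700)
    post_p = 1.0 / (1.0 + np.exp(-eta))
    return pd.DataFrame({"posterior_potent": post_p, "call": np.where(post_p >= 0.5, "P", "W")}, index=matrix.index)
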