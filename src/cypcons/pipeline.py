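"""End-to-end glue: train the three classifiers and merge their votes.

Used by the command-line driver, the cross-validation harness, and the
synthetic end-to-end checks.  The docking model is trained on standardized
scores with manual variable selection (the published choice); the spectral
model by forward-F discriminant analysis on filtered bins; the descriptor
model by the entropy-filtered five-tree decision forest.  The truncated
docking model votes OUTSIDE_DOMAIN for compounds at or below the MW
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import consensus as cns
from . import dlr, sarforest, sdar
from .corpus import DEFAULT_BAND_THRESHOLD
from .sdar import DEFAULT_BIN_WIDTHS


@dataclass
class TrainedClassifiers:
    dlr_model: dlr.LogisticModel
    sdar_model: sdar.DiscriminantModel
    sdar_bins: list[str]
    forest: sarforest.ForestModel
    descriptor_columns: list[str]
    band_threshold: float
    truncated_dlr: bool


def train_classifiers(
    scores: pd.DataFrame,
    spectra,
    descriptors: pd.DataFrame,
    labels: pd.Series,
    band_threshold: float = DEFAULT_BAND_THRESHOLD,
    mws: pd.Series | None = None,
    truncated_dlr: bool = False,
    min_entropy: float = sarforest.DEFAULT_MIN_ENTROPY,
) -> TrainedClassifiers:
    ids = labels.index
    score_ids = ids
    if truncated_dlr:
        if mws is None:
            raise ValueError("truncated DLR needs molecular weights")
        score_ids, _ = dlr.truncate_domain(mws.loc[ids], band_threshold)
    z, stats = dlr.standardize(scores.loc[score_ids])
    dlr_model = dlr.select_manual(z, labels.loc[score_ids])
    dlr_model.standardization = stats

    bins = sdar.filter_bins(sdar.bin_spectra(spectra, compounds=list(ids)))
    sdar_model = sdar.train_discriminant(bins.loc[ids], labels)

    desc = sarforest.filter_descriptors(descriptors.loc[ids], min_entropy=min_entropy)
    forest = sarforest.train_forest(desc, labels)
    return TrainedClassifiers(
        dlr_model=dlr_model,
        sdar_model=sdar_model,
        sdar_bins=list(bins.columns),
        forest=forest,
        descriptor_columns=list(desc.columns),
        band_threshold=band_threshold,
        truncated_dlr=truncated_dlr,
    )


def apply_classifiers(
    models: TrainedClassifiers,
    scores: pd.DataFrame,
    spectra,
    descriptors: pd.DataFrame,
    mws: pd.Series | None = None,
    cutoff: float = dlr.DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """Per-method votes (P / W / OUTSIDE_DOMAIN) for a set of compounds."""
    ids = scores.index
    z, _ = dlr.standardize(scores, models.dlr_model.standardization)
    p = models.dlr_model.predict_proba(z)
    dlr_vote = np.where(p >= cutoff, "P", "W")
    if models.truncated_dlr:
        if mws is None:
            raise ValueError("truncated DLR needs molecular weights")
        outside = mws.loc[ids] <= models.band_threshold
        dlr_vote = np.where(outside.to_numpy(), cns.Vote.OUTSIDE_DOMAIN.value, dlr_vote)

    bins = sdar.bin_spectra(spectra, compounds=list(ids))
    sdar_calls = sdar.classify_matrix(models.sdar_model, bins)["call"].to_numpy()

    forest_calls = models.forest.predict(descriptors.reindex(index=ids)).to_numpy()
    return pd.DataFrame({"DLR": dlr_vote, "SDAR": sdar_calls, "SAR": forest_calls}, index=ids)


def consensus_calls(
    votes: pd.DataFrame,
    strategy: cns.Strategy = cns.Strategy.MAJORITY,
    allow_two_voter_probable: bool = False,
) -> list[cns.ConsensusCall]:
    return [
        cns.combine(row.to_dict(), strategy=strategy, identifier=str(ident),
                    allow_two_voter_probable=allow_two_voter_probable)
        for ident, row in votes.iterrows()
    ]
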