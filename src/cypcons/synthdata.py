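"""Synthetic inputs with the statistical structure the pipeline assumes.

None of the real model inputs (docking scores, predicted NMR spectra,
computed molecular descriptors) can be redistributed, so every stage is
exercised on generated data that reproduces the *statistical* features the
analysis relies on:

* compound libraries whose molecular weights are lognormal and whose
  activity probability follows the fitted sigmoid of activity vs MW, so the
  active subset has the reported log10 mean (2.578) and SD (0.1313) and the
  high-MW band is ~50% active;
* potency assigned band-wise (15/82 potent below 450 Da, 18/39 above);
* 28 docking-score columns sharing an MW-driven latent factor (target
  |corr| 0.35-0.75 with MW) plus a potency effect concentrated in
  catalytic-site columns;
* spectral peak lists whose peak count scales with MW/13 (a crude carbon
  count) and with a few class-informative bins;
* 777 descriptor columns of which 327 survive the entropy filter, a few of
  them class-informative.

Everything is driven by one ``numpy`` Generator; a fixed seed gives
identical output across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .corpus import Band, Category, CompoundRecord, band_of
from .dlr import default_score_columns
from .mwband import logistic_curve
from .sdar import DEFAULT_BIN_WIDTHS, Nucleus, SpectrumPeaks

#: base log10-MW distribution of the screening library, solved so that the
#: compounds accepted by the printed activity sigmoid have log10 mean 2.578
#: and SD 0.1313
BASE_LOG10_MEAN = 2.47376
BASE_LOG10_SD = 0.17161


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_compounds: int = 500
    mw_log10_mean: float = BASE_LOG10_MEAN
    mw_log10_sd: float = BASE_LOG10_SD
    band_threshold: float = 450.0
    # activity sigmoid (fraction active vs MW): a / (1 + (x0/x)^b)
    active_curve: tuple[float, float, float] = (0.5047, 285.1, 6.266)
    # potent fraction among actives, per band
    potent_fraction_low: float = 15.0 / 82.0
    potent_fraction_high: float = 18.0 / 39.0
    # docking scores
    n_score_columns: int = 28
    score_effect_size: float = 2.0
    score_affinity_loading: float = 0.6
    score_mw_correlation: tuple[float, float] = (0.35, 0.75)
    n_effect_columns: int = 7
    # spectra
    n_informative_c_bins: int = 3
    n_informative_n_bins: int = 2
    informative_hit_p_potent: float = 0.95
    informative_hit_p_weak: float = 0.03
    # descriptors
    n_descriptors: int = 777
    n_low_information: int = 450
    n_informative_descriptors: int = 25
    descriptor_effect_size: float = 2.0

    def __post_init__(self):
        lo, hi = self.score_mw_correlation
        if not (0.0 < lo < hi <= 1.0):
            raise ValueError("score_mw_correlation must be an increasing pair in (0, 1]")


@dataclass
class Library:
    records: list[CompoundRecord]
    active: pd.Series  # bool per compound id (library activity, not potency)

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.identifier for r in self.records],
                "mw": [r.mw for r in self.records],
                "category": [r.category.value for r in self.records],
                "band": [r.band.value for r in self.records],
                "active": self.active.to_numpy(),
            }
        ).set_index("id")


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,)))


def gen_library(config: GeneratorConfig) -> Library:
    """Compound library: lognormal MWs, sigmoid activity, band-wise potency."""
    rng = _rng(config, 0)
    log_mw = rng.normal(config.mw_log10_mean, config.mw_log10_sd, size=config.n_compounds)
    mw = 10.0**log_mw
    p_active = logistic_curve(mw, *config.active_curve)
    active = rng.random(config.n_compounds) < p_active
    records: list[CompoundRecord] = []
    for i in range(config.n_compounds):
        band = band_of(mw[i], config.band_threshold)
        if active[i]:
            p_pot = config.potent_fraction_high if band is Band.HIGH else config.potent_fraction_low
            cat = Category.POTENT if rng.random() < p_pot else Category.WEAK
        else:
            cat = Category.UNKNOWN
        records.append(CompoundRecord(f"cmpd{i:05d}", float(mw[i]), cat, band))
    active_s = pd.Series(active, index=[r.identifier for r in records], name="active")
    return Library(records=records, active=active_s)


#: band composition and band-wise potent fractions of the clinical training
#: cohort (82 low-MW with 15 potent, 39 high-MW with 18 potent)
HIGH_BAND_FRACTION = 39.0 / 121.0

#: log10-MW distribution of categorized inhibitors (indistinguishable from
#: the HTS actives' geometric mean; SD from the training histogram)
INHIBITOR_LOG10_MEAN = 2.578
INHIBITOR_LOG10_SD = 0.1885


def gen_inhibitor_set(config: GeneratorConfig, n_inhibitors: int, dataset: int = 0) -> list[CompoundRecord]:
    """Draw a clinical-style inhibitor set (every compound categorized P or W).

    A clinical cohort is not an HTS draw: its band composition is encoded
    directly.  Each compound falls in the high-MW band with probability
    39/121, its MW follows the inhibitor lognormal truncated to the band,
    and potency is Bernoulli with the band-wise fraction (15/82 or 18/39).
    """
    rng = _rng(config, 40 + dataset)
    records: list[CompoundRecord] = []
    log_thr = np.log10(config.band_threshold)
    for i in range(n_inhibitors):
        high = rng.random() < HIGH_BAND_FRACTION
        while True:
            lg = rng.normal(INHIBITOR_LOG10_MEAN, INHIBITOR_LOG10_SD)
            if (lg > log_thr) == high:
                break
        p_pot = config.potent_fraction_high if high else config.potent_fraction_low
        cat = Category.POTENT if rng.random() < p_pot else Category.WEAK
        mw = float(10.0**lg)
        records.append(CompoundRecord(f"inh{i:04d}", mw, cat, band_of(mw, config.band_threshold)))
    return records


def gen_scores(records: list[CompoundRecord], config: GeneratorConfig, dataset: int = 0) -> pd.DataFrame:
    """Docking-score matrix: MW latent + shared binding-affinity latent + noise.

    Every column is tied to MW with a per-column target correlation drawn
    uniformly inside ``score_mw_correlation``.  The potency signal is a
    single per-compound latent (potent compounds shifted by
    ``score_effect_size`` against unit latent noise) that loads with weight
    ``score_affinity_loading`` on the first ``n_effect_columns``
    catalytic-site columns -- the programs rescore the same binding event,
    so their class information is shared, not independent.
    """
    struct_rng = _rng(config, 1)  # column structure: shared across datasets
    rng = _rng(config, 10 + dataset)  # compound-level noise: per dataset
    cols = default_score_columns()[: config.n_score_columns]
    mw = np.array([r.mw for r in records])
    potent = np.array([r.category is Category.POTENT for r in records], dtype=float)
    mw_z = (np.log10(mw) - np.log10(mw).mean()) / max(np.log10(mw).std(), 1e-12)
    catalytic_first = sorted(cols, key=lambda c: ("catalytic" not in c, c))
    effect_cols = set(catalytic_first[: config.n_effect_columns])
    affinity = config.score_effect_size * (potent - potent.mean()) + rng.normal(size=len(records))
    aff_perp = _orthonormal_against(affinity, [mw_z])

    def unit(v):
        v = v - v.mean()
        return v / max(np.linalg.norm(v), 1e-12)

    u_mw = unit(mw_z) * np.sqrt(len(records))
    data = {}
    lo, hi = config.score_mw_correlation
    w_aff = config.score_affinity_loading
    rho_lo, rho_hi = lo + 0.05, min(hi - 0.05, np.sqrt(1 - w_aff**2) - 0.05)
    if rho_lo >= rho_hi:
        raise ValueError("correlation band too narrow for the affinity loading; reduce score_affinity_loading")
    for c in cols:
        # in-sample exact mixing: noise is orthonormalized against the
        # latents, so the realized correlation with the MW latent equals rho
        rho = struct_rng.uniform(rho_lo, rho_hi)
        sign = struct_rng.choice([-1.0, 1.0])
        e = _orthonormal_against(rng.normal(size=len(records)), [mw_z, affinity])
        if c in effect_cols:
            resid = max(1.0 - rho**2 - w_aff**2, 0.0)
            col = sign * (rho * u_mw + w_aff * aff_perp + np.sqrt(resid) * e)
        else:
            col = sign * (rho * u_mw + np.sqrt(1 - rho**2) * e)
        data[c] = col
    df = pd.DataFrame(data, index=[r.identifier for r in records])
    df.index.name = "id"
    # contract: realized correlation with log10 MW (the scale of the latent)
    # sits inside the configured band for every column
    realized = df.apply(lambda s: np.corrcoef(np.log10(mw), s)[0, 1]).abs()
    outside = realized[(realized < lo) | (realized > hi)]
    if len(records) >= 30 and not outside.empty:
        raise ValueError(
            "realized MW correlations fell outside the configured band; reduce noise or widen the band: "
            f"{outside.to_dict()}"
        )
    return df


def _orthonormal_against(v: np.ndarray, basis: list[np.ndarray]) -> np.ndarray:
    """Center, project out ``basis`` directions, and scale to unit sample SD."""
    v = np.asarray(v, dtype=float) - np.mean(v)
    for b in basis:
        b = np.asarray(b, dtype=float) - np.mean(b)
        nb = np.linalg.norm(b)
        if nb > 1e-12:
            v = v - (v @ b) / nb**2 * b
    sd = v.std()
    if sd < 1e-12:
        raise ValueError("degenerate noise vector")
    return v / sd


# synthetic informative bin centers (ppm): carbonyl-region carbons, an azole-type nitrogen
_INFORMATIVE_C_PPM = (176.5, 193.5, 127.4, 155.2)
_INFORMATIVE_N_PPM = (377.5, 212.3)


def gen_spectra(records: list[CompoundRecord], config: GeneratorConfig, dataset: int = 0) -> list[SpectrumPeaks]:
    """Per-compound peak lists; potency shows up in a few informative bins."""
    rng = _rng(config, 20 + dataset)
    peaks: list[SpectrumPeaks] = []
    c_bins = _INFORMATIVE_C_PPM[: config.n_informative_c_bins]
    n_bins = _INFORMATIVE_N_PPM[: config.n_informative_n_bins]
    cw = DEFAULT_BIN_WIDTHS[Nucleus.C13]
    nw = DEFAULT_BIN_WIDTHS[Nucleus.N15]
    for r in records:
        n_c = max(1, rng.poisson(r.mw / 13.0))
        shifts_c = list(rng.uniform(0.0, 200.0, size=n_c))
        n_n = rng.poisson(2.0)
        shifts_n = list(rng.uniform(0.0, 400.0, size=n_n))
        p_hit = config.informative_hit_p_potent if r.category is Category.POTENT else config.informative_hit_p_weak
        for ppm in c_bins:
            if rng.random() < p_hit:
                shifts_c.append(ppm + rng.uniform(-cw / 2, cw / 2) * 0.9)
        for ppm in n_bins:
            if rng.random() < p_hit:
                shifts_n.append(ppm + rng.uniform(-nw / 2, nw / 2) * 0.9)
        peaks.append(SpectrumPeaks(r.identifier, Nucleus.C13, tuple(float(s) for s in shifts_c)))
        if shifts_n:
            peaks.append(SpectrumPeaks(r.identifier, Nucleus.N15, tuple(float(s) for s in shifts_n)))
    return peaks


def gen_descriptors(records: list[CompoundRecord], config: GeneratorConfig, dataset: int = 0) -> pd.DataFrame:
    """777-column descriptor table: low-information, informative, and noise columns.

    ``n_low_information`` columns are constant or rare-indicator columns that
    the Shannon-entropy filter removes at its default threshold, leaving
    ``n_descriptors - n_low_information`` (327 by default) for modeling.
    """
    rng = _rng(config, 30 + dataset)
    n = len(records)
    potent = np.array([r.category is Category.POTENT for r in records], dtype=float)
    mw_z = np.array([r.mw for r in records])
    mw_z = (mw_z - mw_z.mean()) / max(mw_z.std(), 1e-12)
    n_low = config.n_low_information
    n_inf = config.n_informative_descriptors
    n_noise = config.n_descriptors - n_low - n_inf
    if n_noise < 0:
        raise ValueError("n_descriptors too small for the configured low-information and informative counts")
    data = {}
    for j in range(n_low):
        if j % 2 == 0:
            data[f"D{j:03d}"] = np.zeros(n)
        else:  # rare indicator, entropy well under 1 bit
            data[f"D{j:03d}"] = (rng.random(n) < 0.03).astype(float)
    for j in range(n_low, n_low + n_inf):
        eff = config.descriptor_effect_size
        loading = 0.4 if j % 3 else 0.0  # some informative columns also track MW
        data[f"D{j:03d}"] = eff * (potent - potent.mean()) + loading * mw_z + rng.normal(size=n)
    for j in range(n_low + n_inf, config.n_descriptors):
        data[f"D{j:03d}"] = rng.normal(size=n)
    df = pd.DataFrame(data, index=[r.identifier for r in records])
    df.index.name = "id"
    return df


@dataclass
class SyntheticStudy:
    """A full generated study: training inhibitors, evaluation set, all views."""

    config: GeneratorConfig
    train_records: list[CompoundRecord]
    ev_records: list[CompoundRecord]
    train_scores: pd.DataFrame = field(repr=False, default=None)
    ev_scores: pd.DataFrame = field(repr=False, default=None)
    train_spectra: list[SpectrumPeaks] = field(repr=False, default=None)
    ev_spectra: list[SpectrumPeaks] = field(repr=False, default=None)
    train_descriptors: pd.DataFrame = field(repr=False, default=None)
    ev_descriptors: pd.DataFrame = field(repr=False, default=None)

    def labels(self, which: str = "train") -> pd.Series:
        recs = self.train_records if which == "train" else self.ev_records
        return pd.Series(
            ["P" if r.category is Category.POTENT else "W" for r in recs],
            index=[r.identifier for r in recs],
            name="category",
        )


def gen_study(config: GeneratorConfig, n_train: int = 121, n_ev: int = 120) -> SyntheticStudy:
    """Generate a training set, an evaluation set, and all three data views."""
    train = gen_inhibitor_set(config, n_train, dataset=0)
    ev = [
        CompoundRecord(f"ev{i:04d}", r.mw, r.category, r.band)
        for i, r in enumerate(gen_inhibitor_set(config, n_ev, dataset=1))
    ]
    return SyntheticStudy(
        config=config,
        train_records=train,
        ev_records=ev,
        train_scores=gen_scores(train, config, dataset=0),
        ev_scores=gen_scores(ev, config, dataset=1),
        train_spectra=gen_spectra(train, config, dataset=0),
        ev_spectra=gen_spectra(ev, config, dataset=1),
        train_descriptors=gen_descriptors(train, config, dataset=0),
        ev_descriptors=gen_descriptors(ev, config, dataset=1),
    )
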