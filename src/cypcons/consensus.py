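"""Majority-rules consensus of the three classifiers, with confidence tiers.

Each compound gets three Boolean potency votes (docking LR, spectral DA,
descriptor forest); a vote can also be OUTSIDE_DOMAIN when the compound
falls outside a model's applicability domain (e.g. below the MW threshold
for the truncated docking model).  The consensus is P when more than half
of the in-domain votes are P (majority), or all (conjunction), or any
(disjunction).  Confidence in a potent call follows percent agreement:
'probable' when all three methods agree P, 'plausible' above 50% agreement,
'uncertain' otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

from .mwband import expected_count_interval

METHODS = ("DLR", "SDAR", "SAR")


class Vote(str, Enum):
    P = "P"
    W = "W"
    OUTSIDE_DOMAIN = "OUTSIDE_DOMAIN"


class Strategy(str, Enum):
    MAJORITY = "majority"
    CONJUNCTION = "conjunction"
    DISJUNCTION = "disjunction"


class Confidence(str, Enum):
    PROBABLE = "probable"
    PLAUSIBLE = "plausible"
    UNCERTAIN = "uncertain"


@dataclass(frozen=True)
class ConsensusCall:
    identifier: str
    votes: Mapping[str, Vote]
    category: str  # "P" or "W"
    confidence: Confidence
    strategy: Strategy
    flags: tuple[str, ...] = ()


def _tier(p_votes: int, in_domain: int, n_methods: int, allow_two_voter_probable: bool) -> Confidence:
    """Confidence in the potent classification, from the vote multiset alone."""
    if in_domain == 0:
        return Confidence.UNCERTAIN
    if p_votes == in_domain and (in_domain == n_methods or allow_two_voter_probable) and p_votes > 0:
        return Confidence.PROBABLE
    if p_votes / in_domain > 0.5:
        return Confidence.PLAUSIBLE
    return Confidence.UNCERTAIN


def combine(
    votes: Mapping[str, Vote | str],
    strategy: Strategy = Strategy.MAJORITY,
    identifier: str = "",
    allow_two_voter_probable: bool = False,
) -> ConsensusCall:
    """Combine per-method votes into one consensus call with a confidence tier.

    OUTSIDE_DOMAIN votes are dropped from the denominator.  With fewer than
    two in-domain votes the call is made from what remains but flagged and
    the confidence forced to 'uncertain'.  By default a 2-of-2 potent vote
    (third method out of domain) earns only 'plausible': full agreement is
    read as all three methods being able to vote.
    """
    v = {m: Vote(val) for m, val in votes.items()}
    in_domain = [m for m, val in v.items() if val is not Vote.OUTSIDE_DOMAIN]
    p_votes = sum(1 for m in in_domain if v[m] is Vote.P)
    flags: list[str] = []
    if len(in_domain) < 2:
        flags.append("fewer than two in-domain votes")
        category = "P" if (in_domain and v[in_domain[0]] is Vote.P) else "W"
        return ConsensusCall(identifier, v, category, Confidence.UNCERTAIN, strategy, tuple(flags))
    if strategy is Strategy.MAJORITY:
        potent = p_votes / len(in_domain) > 0.5
    elif strategy is Strategy.CONJUNCTION:
        potent = p_votes == len(in_domain)
    elif strategy is Strategy.DISJUNCTION:
        potent = p_votes > 0
    else:  # pragma: no cover
        raise ValueError(f"unknown strategy {strategy}")
    conf = _tier(p_votes, len(in_domain), len(v), allow_two_voter_probable)
    return ConsensusCall(identifier, v, "P" if potent else "W", conf, strategy, tuple(flags))


@dataclass
class CountAudit:
    n_calls: int
    n_potent: int
    interval: tuple[int, int]
    within: bool
    scope: str
    prior: tuple[int, int]
    notes: list[str] = field(default_factory=list)


def audit_counts(
    calls: Sequence[ConsensusCall],
    prior_k: int,
    prior_n: int,
    bands: Mapping[str, str] | None = None,
    band_priors: Mapping[str, tuple[int, int]] | None = None,
) -> list[CountAudit]:
    """Check potent-call counts against binomial expectation intervals.

    The overall count is compared with the Wilson interval of the training
    prior ``prior_k/prior_n`` scaled to the evaluated set; with ``bands``
    (compound id -> band name) and ``band_priors`` the same audit runs per
    MW band.  Out-of-range counts are flagged in the report, never hidden.
    """
    audits: list[CountAudit] = []
    if not calls:
        return audits

    def one(scope: str, subset: Sequence[ConsensusCall], k: int, n: int) -> CountAudit:
        m = len(subset)
        n_p = sum(1 for c in subset if c.category == "P")
        lo, hi = expected_count_interval(k, n, m)
        within = lo <= n_p <= hi
        notes = [] if within else [
            f"{scope}: {n_p} potent calls outside the expected range {lo}..{hi} from prior {k}/{n}"
        ]
        return CountAudit(n_calls=m, n_potent=n_p, interval=(lo, hi), within=within, scope=scope, prior=(k, n), notes=notes)

    audits.append(one("overall", calls, prior_k, prior_n))
    if bands is not None and band_priors is not None:
        for band, (k, n) in band_priors.items():
            subset = [c for c in calls if bands.get(c.identifier) == band]
            if subset:
                audits.append(one(f"band {band}", subset, k, n))
    return audits
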