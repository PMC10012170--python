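"""IF-THEN hazard-rule mining from a trained Bayesian network.

Every joint configuration of the evidence features (by default the
outcome's Markov blanket) yields one candidate rule per hazard class,
carrying the posterior probability of that class given the
configuration and a certainty factor CF = p / (1 - p), the posterior
odds for versus against the consequent.  Configurations with zero
probability are skipped; rules whose CF would be infinite (p = 1,
no counterexamples) are discarded.  Rules differing only in one free
feature (typically the exposure dose) can be merged by averaging
probabilities and certainty factors.
"""

from __future__ import annotations

import itertools
import json
import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .bayesnet import BayesNet, evidence_probability, posterior
from .preprocessing import BinnedDataset, DiscretizationMap

__all__ = [
    "HazardRule",
    "certainty_factor",
    "likelihood_ratio_cf",
    "enumerate_rules",
    "merge_over",
    "filter_rules",
    "format_rule",
    "parse_rule",
    "rules_to_json",
    "rules_to_frame",
]

#: Evidence-feature preset matching the reference example rules.
REFERENCE_RULE_EVIDENCE = [
    "crystallinity",
    "core_size",
    "spherical_surface_area",
    "ag3d_at",
    "hydro_size_t24",
    "dose",
    "assay",
    "cell_line",
]


def certainty_factor(p: float) -> float:
    """Posterior odds for versus against the consequent, p / (1 - p).

    p = 1 returns +inf to signal a rule with no counterexamples, which
    the extractor discards.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"probability outside [0, 1]: {p}")
    if p == 1.0:
        return math.inf
    return p / (1.0 - p)


def likelihood_ratio_cf(p_ev_given_t: float, p_ev_given_not_t: float) -> float:
    """Alternative reading of the certainty factor: the likelihood
    ratio P(X | T) / P(X | not T) of the evidence under the outcome
    versus its complement.  Not the default; kept for comparison."""
    if min(p_ev_given_t, p_ev_given_not_t) < 0:
        raise ValueError("likelihoods must be non-negative")
    if p_ev_given_not_t == 0.0:
        return math.inf
    return p_ev_given_t / p_ev_given_not_t


@dataclass(frozen=True)
class HazardRule:
    """Conjunction of (feature, state) conditions implying a hazard
    class, with its mean posterior probability and certainty factor."""

    antecedent: tuple[tuple[str, str], ...]
    consequent: str
    probability: float
    cf: float
    n_configs: int = 1
    support: int = 0

    def __post_init__(self):
        feats = [f for f, _ in self.antecedent]
        if len(set(feats)) != len(feats):
            raise ValueError("antecedent features must be distinct")
        if not math.isfinite(self.cf):
            raise ValueError("rules with non-finite CF must be discarded, not built")

    def condition(self, feature: str) -> str | None:
        for f, s in self.antecedent:
            if f == feature:
                return s
        return None


@dataclass
class ExtractionLog:
    """Bookkeeping of skipped configurations and discarded rules."""

    n_configs: int = 0
    zero_probability_configs: int = 0
    discarded_infinite_cf: int = 0


def enumerate_rules(
    bn: BayesNet,
    target: str = "hazard",
    evidence_features: Sequence[str] | None = None,
    data: BinnedDataset | None = None,
    log: ExtractionLog | None = None,
) -> list[HazardRule]:
    """Mine one rule per (evidence configuration, class) from the CPTs.

    ``evidence_features`` defaults to the target's Markov blanket.
    ``data`` (the training table) attaches support counts.  Rules with
    infinite CF are discarded; zero-probability configurations are
    skipped; both counts land in ``log`` when given.
    """
    if evidence_features is None:
        evidence_features = bn.markov_blanket(target)
    evidence_features = list(evidence_features)
    if not evidence_features:
        raise ValueError("evidence feature set is empty")
    for f in evidence_features:
        if f not in bn.nodes:
            raise ValueError(f"evidence feature {f!r} not in the network")

    log = log if log is not None else ExtractionLog()
    rules: list[HazardRule] = []
    state_lists = [bn.states[f] for f in evidence_features]
    for combo in itertools.product(*state_lists):
        config = dict(zip(evidence_features, combo))
        log.n_configs += 1
        p_ev = evidence_probability(bn, config)
        if p_ev <= 0.0:
            log.zero_probability_configs += 1
            continue
        post = posterior(bn, config, target)
        support = 0
        if data is not None:
            mask = pd.Series(True, index=data.frame.index)
            for f, s in config.items():
                mask &= data.frame[f] == s
            support = int(mask.sum())
        antecedent = tuple(sorted(config.items()))
        for cls, p in post.items():
            cf = certainty_factor(p)
            if not math.isfinite(cf):
                log.discarded_infinite_cf += 1
                continue
            rules.append(
                HazardRule(
                    antecedent=antecedent,
                    consequent=cls,
                    probability=p,
                    cf=cf,
                    n_configs=1,
                    support=support,
                )
            )
    return rules


def merge_over(rules: Iterable[HazardRule], free_feature: str) -> list[HazardRule]:
    """Merge rules identical except in ``free_feature``'s condition.

    The merged rule drops the free condition and carries the
    arithmetic mean of member probabilities and of member certainty
    factors (so an average-0.87 rule can carry a CF far above
    0.87/0.13 when one member is near-certain), with n_configs summed.
    """
    groups: dict[tuple, list[HazardRule]] = {}
    for r in rules:
        rest = tuple((f, s) for f, s in r.antecedent if f != free_feature)
        groups.setdefault(rest, []).append(r)
    out = []
    for rest, members in groups.items():
        consequents = {m.consequent for m in members}
        if len(consequents) > 1:
            raise ValueError(
                f"inconsistent consequents {sorted(consequents)} when merging over "
                f"{free_feature!r}; filter by class first"
            )
        p = sum(m.probability for m in members) / len(members)
        cf = sum(m.cf for m in members) / len(members)
        out.append(
            HazardRule(
                antecedent=rest,
                consequent=members[0].consequent,
                probability=p,
                cf=cf,
                n_configs=sum(m.n_configs for m in members),
                support=sum(m.support for m in members),
            )
        )
    return out


def filter_rules(
    rules: Iterable[HazardRule], hazard_class: str | None = None, top_k: int | None = None
) -> list[HazardRule]:
    """Keep rules of the requested class, sorted by CF descending
    (ties by support, then lexicographic antecedent), truncated to
    top_k."""
    kept = [r for r in rules if hazard_class is None or r.consequent == hazard_class]
    kept.sort(key=lambda r: (-r.cf, -r.support, r.antecedent))
    return kept[:top_k] if top_k is not None else kept


_LABEL_LETTER = {"low": "L", "medium": "M", "high": "H"}
_LETTER_LABEL = {v: k for k, v in _LABEL_LETTER.items()}


def format_rule(rule: HazardRule, dmap: DiscretizationMap | None = None) -> str:
    """Render a rule in IF/THEN notation.

    Binned conditions show L/M/H with their numeric ranges; the dose
    condition moves into the consequent clause ("if tested under
    ... dose"); a rule merged over dose reads "under any exposure
    range".
    """
    conds = []
    dose_part = "under any exposure range"
    for feat, state in rule.antecedent:
        if feat == "dose":
            if dmap is not None and feat in dmap.edges:
                dose_part = f"under {state} ({dmap.range_text(feat, state)}) dose"
            else:
                dose_part = f"under {state} dose"
            continue
        if dmap is not None and feat in dmap.edges and state in _LABEL_LETTER:
            conds.append(
                f"({feat}) = {_LABEL_LETTER[state]}({dmap.range_text(feat, state)})"
            )
        else:
            conds.append(f"({feat}) = {state}")
    antecedent = "^".join(conds) if conds else "(any AgNF)"
    return (
        f"IF {antecedent} THEN AgNFs are {rule.consequent} if tested {dose_part} "
        f"with an average {rule.probability:.4f} probability (CF = {rule.cf:.4g})"
    )


_RULE_RE = re.compile(
    r"^IF (?P<ante>.*) THEN AgNFs are (?P<cls>\w+) if tested "
    r"(?P<dose>under any exposure range|under (?P<dlabel>\w+)(?: \([^)]*\))? dose) "
    r"with an average (?P<p>[\d.]+) probability \(CF = (?P<cf>[\d.eE+-]+)\)$"
)
_COND_RE = re.compile(r"\((?P<feat>[^)]+)\) = (?:(?P<letter>[LMH])\([^)]*\)|(?P<state>\S+))")


def parse_rule(text: str) -> HazardRule:
    """Parse :func:`format_rule` output back into a rule (probability
    and CF at printed precision)."""
    m = _RULE_RE.match(text.strip())
    if not m:
        raise ValueError(f"unparseable rule text: {text!r}")
    conds: list[tuple[str, str]] = []
    if m.group("ante") != "(any AgNF)":
        for c in m.group("ante").split("^"):
            cm = _COND_RE.match(c.strip())
            if not cm:
                raise ValueError(f"unparseable condition: {c!r}")
            state = (
                _LETTER_LABEL[cm.group("letter")]
                if cm.group("letter")
                else cm.group("state")
            )
            conds.append((cm.group("feat"), state))
    if m.group("dlabel"):
        conds.append(("dose", m.group("dlabel")))
    return HazardRule(
        antecedent=tuple(sorted(conds)),
        consequent=m.group("cls"),
        probability=float(m.group("p")),
        cf=float(m.group("cf")),
    )


def rules_to_frame(rules: Sequence[HazardRule]) -> pd.DataFrame:
    """CSV-ready summary: antecedent, class, probability, CF, support."""
    return pd.DataFrame(
        [
            {
                "antecedent": " ^ ".join(f"{f}={s}" for f, s in r.antecedent),
                "class": r.consequent,
                "probability": r.probability,
                "cf": r.cf,
                "n_configs": r.n_configs,
                "support": r.support,
            }
            for r in rules
        ]
    )


def rules_to_json(rules: Sequence[HazardRule]) -> str:
    return json.dumps(
        [
            {
                "antecedent": [list(c) for c in r.antecedent],
                "consequent": r.consequent,
                "probability": r.probability,
                "cf": r.cf,
                "n_configs": r.n_configs,
                "support": r.support,
            }
            for r in rules
        ],
        indent=2,
    )
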