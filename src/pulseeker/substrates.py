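"""Rule-based substrate classification of called PULs.

Marine Bacteroidetes PULs surveyed at Helgoland fall into five recurring
substrate categories — beta-glucan/laminarin, alpha-glucan, alpha-mannose-rich,
sulfated xylan, and alginate — each recognisable from the CAZyme-family
composition of the locus (e.g. GH16+GH3 for the short laminarin variant,
PL6/PL7/PL17 lyases for alginate). The category patterns are distilled into
an editable YAML rule set shipped with the package; rules are tried in
priority order (most constrained first) and the first whose required family
multiset is contained in the locus wins.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .annotation import families_match, is_cazy_family

SUBSTRATE_LABELS = (
    "beta-glucan/laminarin",
    "alpha-glucan",
    "alpha-mannose-rich",
    "sulfated xylan",
    "alginate",
    "unknown",
)


@dataclass(frozen=True)
class SubstrateRule:
    name: str
    label: str
    priority: int
    required: tuple = ()          # ((family-or-role, min count), ...)
    optional: tuple = ()
    forbidden: frozenset = frozenset()
    any_of: tuple | None = None   # (families tuple, min distinct present)

    def __post_init__(self):
        if not self.required and self.any_of is None:
            raise ValueError(f"rule {self.name}: empty requirement")


@dataclass
class SubstrateCall:
    label: str = "unknown"
    variant: str | None = None
    matched_evidence: list = field(default_factory=list)
    n_matching_rules: int = 0

    def __post_init__(self):
        if (self.label == "unknown") != (self.variant is None):
            raise ValueError("label 'unknown' iff variant is None")


def default_rules_path() -> Path:
    return Path(resources.files("pulseeker").joinpath("data/substrate_rules.yaml"))


def load_rules(path: str | Path | None = None, *, include_disabled: bool = False) -> list[SubstrateRule]:
    """Load and validate the substrate rule set, sorted by priority."""
    with open(path if path is not None else default_rules_path()) as fh:
        raw = yaml.safe_load(fh)
    rules = []
    for entry in raw["rules"]:
        if not entry.get("enabled", True) and not include_disabled:
            continue
        any_of = None
        if "any_of" in entry:
            any_of = (tuple(entry["any_of"]["families"]), int(entry["any_of"]["min_distinct"]))
        rules.append(
            SubstrateRule(
                name=entry["name"],
                label=entry["label"],
                priority=int(entry["priority"]),
                required=tuple(sorted(entry.get("required", {}).items())),
                optional=tuple(sorted(entry.get("optional", {}).items())),
                forbidden=frozenset(entry.get("forbidden", ())),
                any_of=any_of,
            )
        )
    priorities = [r.priority for r in rules]
    if len(set(priorities)) != len(priorities):
        raise ValueError("substrate rule set has duplicate priorities")
    if any(r.label not in SUBSTRATE_LABELS for r in rules):
        raise ValueError("substrate rule with unknown label")
    return sorted(rules, key=lambda r: r.priority)


def _matching_keys(feature_counts: Counter, requirement: str) -> list[str]:
    """Feature keys satisfying one requirement token (role or family)."""
    if requirement == "sulfatase":
        return ["sulfatase"] if feature_counts.get("sulfatase", 0) > 0 else []
    return [
        f
        for f in feature_counts
        if f != "sulfatase" and is_cazy_family(f) and families_match(requirement, f)
    ]


def _consume(feature_counts: Counter, items: tuple, *, strict: bool) -> list[str] | None:
    """Try to consume ``items`` from a mutable feature multiset.

    Returns the consumed evidence, or None when strict and a requirement
    cannot be met. Subfamily-exact requirements are consumed before generic
    ones so that e.g. a GH30_1 requirement is not starved by a generic GH30.
    """
    evidence: list[str] = []
    ordered = sorted(items, key=lambda kv: ("_" not in kv[0], kv[0]))
    for requirement, count in ordered:
        need = count
        for key in sorted(_matching_keys(feature_counts, requirement)):
            take = min(need, feature_counts[key])
            if take > 0:
                feature_counts[key] -= take
                evidence.extend([key] * take)
                need -= take
            if need == 0:
                break
        if need > 0 and strict:
            return None
    return evidence


def rule_matches(rule: SubstrateRule, features: Counter) -> list[str] | None:
    """Evidence list if the locus composition satisfies the rule, else None."""
    for forb in rule.forbidden:
        if _matching_keys(features, forb):
            return None
    pool = Counter(features)
    evidence = _consume(pool, rule.required, strict=True)
    if evidence is None:
        return None
    if rule.any_of is not None:
        fams, min_distinct = rule.any_of
        present = [f for f in fams if _matching_keys(pool, f)]
        if len(present) < min_distinct:
            return None
        for f in present:
            for key in _matching_keys(pool, f):
                taken = pool.pop(key)
                evidence.extend([key] * taken)
    extra = _consume(pool, rule.optional, strict=False)
    evidence.extend(extra or [])
    return evidence


def classify_substrate(pul_or_features, rules: list[SubstrateRule]) -> SubstrateCall:
    """Classify one locus; accepts a PUL object or a feature Counter.

    Features are confirmed CAZy families (one count per carrying gene) plus
    a "sulfatase" count for genes with the sulfatase role. Rules fire in
    priority order; the first match wins and ``n_matching_rules`` records how
    many rules would have matched (for flagging ambiguous loci).
    """
    if isinstance(pul_or_features, Counter):
        features = pul_or_features
    else:
        features = pul_or_features.feature_counts()

    best: SubstrateCall | None = None
    n_match = 0
    for rule in rules:
        evidence = rule_matches(rule, features)
        if evidence is not None:
            n_match += 1
            if best is None:
                best = SubstrateCall(
                    label=rule.label, variant=rule.name, matched_evidence=sorted(evidence)
                )
    if best is None:
        return SubstrateCall()
    best.n_matching_rules = n_match
    return best
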