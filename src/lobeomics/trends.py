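"""Five-type trend taxonomy over gated sign patterns across comparisons.

Each gene's gated changes in (GvC, MvG, PvG, MvP) reduce to a pattern of
trits in {-1, 0, +1}. An ordered, configurable rule table maps every one
of the 3^4 = 81 patterns to one of five labels:

* NE      -- no effect (fallback; includes the all-zero pattern)
* Rein01  -- a GVHD-associated change reversed by the MSC arm AND the PBS
             vehicle arm (reversal not attributable to treatment alone)
* Rein02  -- a change reversed in MvG but not reversed in PvG (or arising
             only under treatment): the candidate treatment mediators
* SR      -- reversal only in the vehicle arm (self-recovery)
* Whip01  -- the MSC arm pushes in the same direction as the GVHD change
             (candidate exacerbation)

The default table encodes these semantics in priority order; rules are
explicit trit patterns with "*" wildcards so alternative readings can be
supplied as configuration rather than code.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .diff import ComparisonResult

COMPARISON_ORDER = ("GvC", "MvG", "PvG", "MvP")
LABELS = ("NE", "Rein01", "Rein02", "SR", "Whip01")

Trit = int  # -1, 0, +1
Pattern = tuple[Trit, Trit, Trit, Trit]

TRITS = (-1, 0, 1)
ALL_PATTERNS: tuple[Pattern, ...] = tuple(itertools.product(TRITS, repeat=4))


def _expand(pattern_spec: Sequence) -> list[Pattern]:
    """Expand a pattern with '*' wildcards into explicit trit patterns."""
    axes = []
    for x in pattern_spec:
        if x == "*":
            axes.append(TRITS)
        else:
            xi = int(x)
            if xi not in TRITS:
                raise ValueError(f"trit must be -1, 0, 1 or '*', got {x!r}")
            axes.append((xi,))
    return [tuple(p) for p in itertools.product(*axes)]


@dataclass
class TrendRuleTable:
    """Ordered (label, patterns) rules; first match wins, fallback last.

    ``rules`` maps each non-fallback label to the wildcard patterns that
    select it, evaluated in order.
    """

    rules: list[tuple[str, list[Sequence]]]
    fallback: str = "NE"

    _lookup: dict[Pattern, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        lookup: dict[Pattern, str] = {}
        for label, pattern_specs in self.rules:
            for spec in pattern_specs:
                if len(spec) != 4:
                    raise ValueError(f"rule pattern must have 4 trits: {spec!r}")
                for pat in _expand(spec):
                    lookup.setdefault(pat, label)  # priority order: keep first
        for pat in ALL_PATTERNS:
            lookup.setdefault(pat, self.fallback)
        self._lookup = lookup

    def classify(self, pattern: Sequence[int]) -> str:
        pat = tuple(int(x) for x in pattern)
        if len(pat) != 4 or any(x not in TRITS for x in pat):
            raise ValueError(f"invalid sign pattern {pattern!r}")
        return self._lookup[pat]

    @property
    def labels(self) -> tuple[str, ...]:
        seen = [lab for lab, _ in self.rules]
        if self.fallback not in seen:
            seen.append(self.fallback)
        return tuple(seen)

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "fallback": self.fallback,
            "rules": [
                {"label": lab, "patterns": [list(p) for p in pats]}
                for lab, pats in self.rules
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrendRuleTable":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        rules = [(r["label"], [tuple(p) for p in r["patterns"]]) for r in doc["rules"]]
        return cls(rules=rules, fallback=doc.get("fallback", "NE"))


def default_rule_table() -> TrendRuleTable:
    """The default 5-type table over (s1, s2, s3) = (GvC, MvG, PvG) signs.

    Priority order (s4 = MvP is stored but unused by default):

    1. Rein02: MvG reverses a GvC change while PvG does not reverse it,
       or a change appears only under comparison with the vehicle arm
       (s1 = 0) and MvG opposes PvG.
    2. Rein01: GvC change reversed by both MvG and PvG.
    3. SR:     GvC change reversed by PvG alone (MvG silent).
    4. Whip01: MvG change in the same direction as the GvC change.
    5. NE:     everything else.
    """
    return TrendRuleTable(
        rules=[
            (
                "Rein02",
                [
                    (1, -1, 0, "*"),
                    (1, -1, 1, "*"),
                    (-1, 1, 0, "*"),
                    (-1, 1, -1, "*"),
                    (0, -1, 1, "*"),
                    (0, 1, -1, "*"),
                ],
            ),
            ("Rein01", [(1, -1, -1, "*"), (-1, 1, 1, "*")]),
            ("SR", [(1, 0, -1, "*"), (-1, 0, 1, "*")]),
            ("Whip01", [(1, 1, "*", "*"), (-1, -1, "*", "*")]),
        ],
        fallback="NE",
    )


def sign_pattern(
    results: Mapping[str, ComparisonResult] | Mapping[str, pd.Series],
    gene: str,
    order: tuple[str, ...] = COMPARISON_ORDER,
) -> Pattern:
    """Sign trits of the gated change g for one gene across comparisons."""
    missing = [c for c in order if c not in results]
    if missing:
        raise ValueError(f"missing comparisons: {missing}")
    trits = []
    for comp in order:
        res = results[comp]
        g = res.g if isinstance(res, ComparisonResult) else res
        trits.append(int(np.sign(g.loc[gene])))
    return tuple(trits)


def sign_pattern_table(
    results: Mapping[str, ComparisonResult],
    order: tuple[str, ...] = COMPARISON_ORDER,
) -> pd.DataFrame:
    """Vectorized sign patterns for all genes (columns s_GvC..s_MvP)."""
    missing = [c for c in order if c not in results]
    if missing:
        raise ValueError(f"missing comparisons: {missing}")
    cols = {}
    index = None
    for comp in order:
        g = results[comp].g
        if index is None:
            index = g.index
        elif not index.equals(g.index):
            raise ValueError("comparison results have mismatched gene universes")
        cols[f"s_{comp}"] = np.sign(g.to_numpy()).astype(int)
    return pd.DataFrame(cols, index=index)


def classify(pattern: Sequence[int], rules: TrendRuleTable | None = None) -> str:
    """Label one sign pattern under the (default) rule table."""
    if rules is None:
        rules = default_rule_table()
    return rules.classify(pattern)


@dataclass
class TrendAssignment:
    """Per-gene trend labels for one lobe."""

    table: pd.DataFrame  # index gene_id; columns s_GvC..s_MvP, label
    lobe: str

    def genes_with_label(self, label: str) -> set[str]:
        return set(self.table.index[self.table["label"] == label])


def assign_trends(
    results: Mapping[str, ComparisonResult],
    lobe: str,
    rules: TrendRuleTable | None = None,
) -> TrendAssignment:
    """Classify every gene of a lobe from its four gated comparisons."""
    if rules is None:
        rules = default_rule_table()
    pats = sign_pattern_table(results)
    labels = [rules.classify(tuple(row)) for row in pats.to_numpy()]
    out = pats.copy()
    out["label"] = labels
    out.index.name = "gene_id"
    return TrendAssignment(out, lobe)


def shared_specific(
    label_sets: Mapping[str, set[str] | Iterable[str]],
) -> tuple[set[str], dict[str, set[str]], dict[frozenset, int]]:
    """Shared / lobe-specific sets and all intersection-class counts.

    Returns (shared, per-lobe specific sets, counts of every non-empty
    membership class keyed by the frozenset of lobes a gene occurs in).
    """
    lobes = list(label_sets)
    if len(lobes) < 2:
        raise ValueError("need >= 2 lobes for set intersections")
    sets = {lb: set(label_sets[lb]) for lb in lobes}
    universe = set().union(*sets.values())
    class_counts: dict[frozenset, int] = {}
    for gene in universe:
        members = frozenset(lb for lb in lobes if gene in sets[lb])
        class_counts[members] = class_counts.get(members, 0) + 1
    shared = set.intersection(*sets.values()) if sets else set()
    specific = {
        lb: {g for g in sets[lb] if all(g not in sets[o] for o in lobes if o != lb)}
        for lb in lobes
    }
    return shared, specific, class_counts


def intersection_table(class_counts: Mapping[frozenset, int], lobes: Sequence[str]) -> pd.DataFrame:
    """UpSet-style membership matrix: one row per non-empty class."""
    rows = []
    for members, count in class_counts.items():
        row = {lb: int(lb in members) for lb in lobes}
        row["n_genes"] = count
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(lobes) + ["n_genes"])
    return df.sort_values(list(lobes), kind="mergesort", ascending=False).reset_index(
        drop=True
    )
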