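"""Trajectories as (diagnosis, age-group) tuple sets and their pairwise
relations.

A disease trajectory X = {(i1, a1), (i2, a2), ...} is the tuple set of one
detected community.  Similarity is the Jaccard coefficient over tuples (the
same code in different age groups does not overlap).  Every unordered pair
of trajectories is classified:

* identical — equal tuple sets (only after imperfect dedup upstream);
* nested — one a proper subset of the other;
* diverging — they overlap at the earliest age group of either trajectory
  but their tuple sets above that earliest layer differ (for both
  trajectories' earliest layers);
* converging — the mirror image at the latest age groups;
* persistent — the overlap is confined to one trajectory's highest and the
  other's lowest age group (a hand-over across decades);
* unrelated — none of the above.

Diverging and converging can genuinely co-occur and both labels are kept;
headline frequency tables optionally apply the exclusive precedence
nested > diverging > converging > persistent.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._icd import chapter

LABELS = ("identical", "nested", "diverging", "converging", "persistent",
          "unrelated")


@dataclass(frozen=True)
class Trajectory:
    """A set of (code, age_group) tuples with derived descriptors."""

    id: str
    tuples: frozenset

    def __post_init__(self):
        if not self.tuples:
            raise ValueError("empty trajectory")
        for code, layer in self.tuples:
            if not 1 <= layer <= 8:
                raise ValueError(f"age group {layer} outside 1-8")

    @property
    def size(self) -> int:
        return len(self.tuples)

    @property
    def alpha_min(self) -> int:
        return min(a for _, a in self.tuples)

    @property
    def alpha_max(self) -> int:
        return max(a for _, a in self.tuples)

    @property
    def age_span(self) -> int:
        """Number of age groups from first to last, inclusive."""
        return self.alpha_max - self.alpha_min + 1

    @property
    def codes(self) -> frozenset:
        return frozenset(c for c, _ in self.tuples)

    @property
    def n_codes(self) -> int:
        return len(self.codes)

    @property
    def n_chapters(self) -> int:
        return len({chapter(c) for c in self.codes})

    def at_layer(self, layer: int) -> frozenset:
        return frozenset(t for t in self.tuples if t[1] == layer)

    def above(self, layer: int) -> frozenset:
        return frozenset(t for t in self.tuples if t[1] > layer)

    def below(self, layer: int) -> frozenset:
        return frozenset(t for t in self.tuples if t[1] < layer)


@dataclass(frozen=True)
class PairRelation:
    x_id: str
    y_id: str
    labels: frozenset
    shared: frozenset
    jaccard: float

    def has(self, label: str) -> bool:
        return label in self.labels


def communities_to_trajectories(communities) -> list:
    """Map communities 1:1 to trajectories, collapsing exact duplicates.

    Accepts member iterables of (code, layer) nodes (CommunityState
    objects or plain sets).
    """
    seen = {}
    for k, com in enumerate(communities):
        members = getattr(com, "members", com)
        tuples = frozenset((str(c), int(a)) for c, a in members)
        if tuples and tuples not in seen:
            seen[tuples] = Trajectory(id=f"T{len(seen):04d}", tuples=tuples)
    return list(seen.values())


def jaccard(x: Trajectory, y: Trajectory) -> float:
    inter = len(x.tuples & y.tuples)
    union = len(x.tuples | y.tuples)
    return inter / union


def classify_pair(x: Trajectory, y: Trajectory) -> PairRelation:
    """Classify one unordered trajectory pair (labels may co-occur)."""
    shared = x.tuples & y.tuples
    if x.tuples == y.tuples:
        return PairRelation(x.id, y.id, frozenset({"identical"}), shared, 1.0)

    labels = set()
    if x.tuples < y.tuples or y.tuples < x.tuples:
        labels.add("nested")

    # diverging: overlap at either trajectory's earliest layer, and the
    # remainders above each earliest layer differ
    start_overlap = (
        (x.at_layer(x.alpha_min) & y.at_layer(x.alpha_min))
        | (x.at_layer(y.alpha_min) & y.at_layer(y.alpha_min))
    )
    if (
        start_overlap
        and x.above(x.alpha_min) != y.above(x.alpha_min)
        and x.above(y.alpha_min) != y.above(y.alpha_min)
    ):
        labels.add("diverging")

    # converging: the mirror image at the latest layers
    end_overlap = (
        (x.at_layer(x.alpha_max) & y.at_layer(x.alpha_max))
        | (x.at_layer(y.alpha_max) & y.at_layer(y.alpha_max))
    )
    if (
        end_overlap
        and x.below(x.alpha_max) != y.below(x.alpha_max)
        and x.below(y.alpha_max) != y.below(y.alpha_max)
    ):
        labels.add("converging")

    # persistent: overlap confined to the highest layer of one trajectory
    # == the lowest layer of the other
    if shared:
        layers = {a for _, a in shared}
        if len(layers) == 1:
            (lay,) = layers
            if (lay == x.alpha_max == y.alpha_min and x.alpha_min < lay) or (
                lay == y.alpha_max == x.alpha_min and y.alpha_min < lay
            ):
                labels.add("persistent")

    if not labels:
        labels.add("unrelated")
    return PairRelation(x.id, y.id, frozenset(labels), shared, jaccard(x, y))


def classify_all(trajectories):
    """Classify every unordered pair.

    Returns ``(relations, counts)`` where ``counts`` is a DataFrame with
    one row per label and two counting modes: ``independent`` (a pair may
    count under several labels) and ``exclusive`` (precedence nested >
    diverging > converging > persistent).
    """
    relations = []
    independent: Counter = Counter()
    exclusive: Counter = Counter()
    precedence = ("identical", "nested", "diverging", "converging",
                  "persistent", "unrelated")
    trajs = list(trajectories)
    for i in range(len(trajs)):
        for j in range(i + 1, len(trajs)):
            rel = classify_pair(trajs[i], trajs[j])
            relations.append(rel)
            for lab in rel.labels:
                independent[lab] += 1
            for lab in precedence:
                if lab in rel.labels:
                    exclusive[lab] += 1
                    break
    counts = pd.DataFrame(
        {
            "independent": [independent.get(lab, 0) for lab in LABELS],
            "exclusive": [exclusive.get(lab, 0) for lab in LABELS],
        },
        index=pd.Index(LABELS, name="relation"),
    )
    return relations, counts


def trajectory_stats(trajectories):
    """Descriptive distributions: sizes, age spans, chapters, pairwise
    Jaccard histogram (the field's standard trajectory summaries)."""
    trajs = list(trajectories)
    if not trajs:
        raise ValueError("no trajectories")
    sizes = pd.Series([t.size for t in trajs], name="size")
    spans = pd.Series([t.age_span for t in trajs], name="age_span")
    chapters = pd.Series([t.n_chapters for t in trajs], name="n_chapters")
    jac = []
    for i in range(len(trajs)):
        for j in range(i + 1, len(trajs)):
            jac.append(jaccard(trajs[i], trajs[j]))
    return {
        "size": sizes.value_counts().sort_index(),
        "age_span": spans.value_counts().sort_index(),
        "n_chapters_by_span": chapters.groupby(spans).describe(),
        "jaccard": pd.Series(jac, name="jaccard", dtype=float),
    }


def relations_frame(relations) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "x_id": r.x_id,
                "y_id": r.y_id,
                "labels": "|".join(sorted(r.labels)),
                "n_shared": len(r.shared),
                "jaccard": r.jaccard,
            }
            for r in relations
        ]
    )
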