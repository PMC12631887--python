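"""Rule-based semantic morphotyping: dot, rod, or network.

The decision rules operate on skeleton branching and two geometric
descriptors:

* network — at least one branch point (branch count >= 1), tree-like or
  looped; branching dominates every other feature;
* dot     — unbranched, low elongation (major/minor ratio < 2) and
  relatively round (roundness > 0.25);
* rod     — unbranched, elongated (ratio >= 2) and low roundness
  (roundness <= 0.25).

The three rules do not tile the whole (ratio, roundness) plane for
unbranched objects (e.g. ratio < 2 with roundness <= 0.25 matches
neither dot nor rod).  Such objects are assigned the class whose single
violated rule has the smallest normalized margin — |ratio - 2| / 2
against |roundness - 0.25| / 0.25 — and are flagged ``rule_gap`` so the
assignment is auditable rather than silent.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from mitoscope.morphometry import RegionFeatures
from mitoscope.topology import TopologySummary

MORPHOTYPES = ("dot", "rod", "network")

#: default decision thresholds (elongation ratio, roundness)
RATIO_THRESHOLD = 2.0
ROUNDNESS_THRESHOLD = 0.25


@dataclass(frozen=True)
class Morphotype:
    """Class assignment for one object, with a rule-gap audit flag."""

    label: int
    kind: str  # dot | rod | network
    rule_gap: bool = False

    def __post_init__(self) -> None:
        if self.kind not in MORPHOTYPES:
            raise ValueError(f"unknown morphotype {self.kind!r}")


@dataclass
class MorphotypeCensus:
    image_id: str
    counts: dict[str, int]
    proportions: dict[str, float]
    branch_histogram: dict[int, int]
    loop_histogram: dict[int, int]
    n_objects: int


def classify_morphotype(
    features: RegionFeatures,
    topo: TopologySummary,
    ratio_threshold: float = RATIO_THRESHOLD,
    roundness_threshold: float = ROUNDNESS_THRESHOLD,
) -> Morphotype:
    """Apply the dot/rod/network rules to one object.

    ``features`` and ``topo`` must describe the same label.  Returns the
    assigned :class:`Morphotype`; objects falling in a rule gap carry
    ``rule_gap=True``.
    """
    if features is None or topo is None:
        raise ValueError("both region features and topology are required")
    if features.label != topo.label:
        raise ValueError(
            f"label mismatch: features {features.label} vs topology {topo.label}"
        )
    label = features.label
    if topo.branch_count >= 1:
        return Morphotype(label, "network")
    ratio, roundness = features.ratio_major_minor, features.roundness
    is_dot = ratio < ratio_threshold and roundness > roundness_threshold
    is_rod = ratio >= ratio_threshold and roundness <= roundness_threshold
    if is_dot:
        return Morphotype(label, "dot")
    if is_rod:
        return Morphotype(label, "rod")
    # rule gap: pick the class whose violated rule is nearest its boundary
    ratio_margin = abs(ratio - ratio_threshold) / ratio_threshold
    roundness_margin = abs(roundness - roundness_threshold) / roundness_threshold
    if ratio >= ratio_threshold:  # gap cell: elongated but round
        # dot violated on ratio, rod violated on roundness
        kind = "dot" if ratio_margin <= roundness_margin else "rod"
    else:  # gap cell: compact but not round
        # dot violated on roundness, rod violated on ratio
        kind = "dot" if roundness_margin <= ratio_margin else "rod"
    return Morphotype(label, kind, rule_gap=True)


def census(
    morphotypes: Iterable[Morphotype],
    topologies: Iterable[TopologySummary] = (),
    image_id: str = "",
) -> MorphotypeCensus:
    """Per-image census: class counts/proportions and branch/loop histograms."""
    kinds = [m.kind for m in morphotypes]
    n = len(kinds)
    counts = {k: 0 for k in MORPHOTYPES}
    counts.update(Counter(kinds))
    proportions = {k: (counts[k] / n if n else 0.0) for k in MORPHOTYPES}
    branch_hist: Counter = Counter(t.branch_count for t in topologies)
    loop_hist: Counter = Counter(t.loops for t in topologies)
    return MorphotypeCensus(
        image_id=image_id,
        counts=counts,
        proportions=proportions,
        branch_histogram=dict(sorted(branch_hist.items())),
        loop_histogram=dict(sorted(loop_hist.items())),
        n_objects=n,
    )
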