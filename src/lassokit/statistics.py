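"""Survey summaries over per-chain lasso classification records.

Aggregates the outputs of the detection pipeline into the census-style
quantities used to characterise a structure set: major-type counts, the
C-tail and "negative rank-1 piercing" propensities (two-sided LL/LLS
lassos excluded from both, since their piercings are not attributable to
a single tail), per-sign histograms of bridge-to-nearest-piercing
sequential distances, pierced-loops-per-chain and fingerprint counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

__all__ = ["SurveyStats", "survey"]


@dataclass
class SurveyStats:
    major_counts: Counter = field(default_factory=Counter)
    tail_fraction: float | None = None  # C-tail share among non-LL pierced loops
    negative_fraction: float | None = None  # '-' rank-1 share, non-LL loops
    distance_hist_by_sign: dict = field(default_factory=dict)
    loops_per_chain: Counter = field(default_factory=Counter)
    fingerprint_counts: Counter = field(default_factory=Counter)

    @property
    def n_pierced_loops(self) -> int:
        return sum(self.major_counts.values())


def _as_record(result) -> dict:
    if hasattr(result, "to_record"):
        return result.to_record()
    return result


def survey(results: Iterable) -> SurveyStats:
    """Aggregate per-chain classification records into survey statistics.

    Each record (dict or ChainResult) carries per-loop minor/major labels,
    sign lists and bridge-piercing distances plus the chain fingerprint.
    The result is permutation-invariant in the input order.
    """
    stats = SurveyStats(distance_hist_by_sign={"+": Counter(), "-": Counter()})
    single_tail_c = 0
    single_tail_total = 0
    negative = 0
    for result in results:
        rec = _as_record(result)
        pierced = 0
        for loop in rec.get("loops", []):
            major = loop.get("major")
            if not major or major == "L0":
                continue
            pierced += 1
            stats.major_counts[major] += 1
            ns, cs = loop.get("n_signs", []), loop.get("c_signs", [])
            two_sided = bool(ns) and bool(cs)
            if not two_sided:
                signs = list(cs) if cs else list(ns)
                single_tail_total += 1
                if cs:
                    single_tail_c += 1
                if signs[0] == "-":
                    negative += 1
                dist = loop.get("distance")
                if dist is not None:
                    stats.distance_hist_by_sign[signs[0]][int(dist)] += 1
        stats.loops_per_chain[pierced] += 1
        fp = rec.get("fingerprint", "")
        if fp:
            stats.fingerprint_counts[fp] += 1
    if single_tail_total:
        stats.tail_fraction = single_tail_c / single_tail_total
        stats.negative_fraction = negative / single_tail_total
    return stats
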