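"""Entity-level exact-match evaluation.

A predicted entity counts as a true positive only when an identical
(start, end, class) span exists in the gold annotation of the same
sentence — no partial or overlap credit.  Per class c:

    P_c = TP_c / (TP_c + FP_c),  R_c = TP_c / (TP_c + FN_c),
    F1_c = 2 P_c R_c / (P_c + R_c)

all expressed in percent; zero denominators yield 0 by convention.

Two corpus-level averages are reported, labeled distinctly:

* **macro** — unweighted arithmetic means of P_c and R_c over classes;
  Macro-F1 is the harmonic mean of Macro-P and Macro-R (not the mean of
  per-class F1 values).
* **support-weighted** — P_c and R_c averaged with weights proportional
  to gold entity counts, which approximates micro-averaging and is the
  convention some published "Average" rows actually follow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

from .corpus import TaggedSentence, TagScheme, bio_to_spans

__all__ = [
    "MatchCounts",
    "EvalReport",
    "match_entities",
    "prf_per_class",
    "harmonic_f1",
    "macro_average",
    "weighted_average",
    "evaluate_corpus",
    "round2",
]


def round2(x: float) -> float:
    """Round half-up to 2 decimal places (table convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class MatchCounts:
    """Per-class TP/FP/FN accumulated over a corpus."""

    tp: dict[str, int] = field(default_factory=dict)
    fp: dict[str, int] = field(default_factory=dict)
    fn: dict[str, int] = field(default_factory=dict)

    def classes(self) -> list[str]:
        return sorted(set(self.tp) | set(self.fp) | set(self.fn))

    def support(self, cls: str) -> int:
        return self.tp.get(cls, 0) + self.fn.get(cls, 0)


def match_entities(gold: Sequence[TaggedSentence],
                   pred: Sequence[TaggedSentence],
                   scheme: TagScheme | None = None) -> MatchCounts:
    """Exact-span matching, sentence by sentence.

    Gold and pred must be aligned: same number of sentences and same
    length at every index.  Duplicate identical spans cannot occur in BIO
    decoding, so set intersection per sentence is exact.
    """
    scheme = scheme or TagScheme()
    if len(gold) != len(pred):
        raise ValueError(
            f"corpus misalignment: {len(gold)} gold vs {len(pred)} predicted sentences")
    counts = MatchCounts(
        {c: 0 for c in scheme.classes},
        {c: 0 for c in scheme.classes},
        {c: 0 for c in scheme.classes},
    )
    for i, (g, p) in enumerate(zip(gold, pred)):
        if len(g) != len(p):
            raise ValueError(
                f"corpus misalignment at sentence {i}: lengths {len(g)} vs {len(p)}")
        gset = {(s.start, s.end, s.cls) for s in bio_to_spans(g.tags)}
        pset = {(s.start, s.end, s.cls) for s in bio_to_spans(p.tags)}
        for span in pset & gset:
            counts.tp[span[2]] = counts.tp.get(span[2], 0) + 1
        for span in pset - gset:
            counts.fp[span[2]] = counts.fp.get(span[2], 0) + 1
        for span in gset - pset:
            counts.fn[span[2]] = counts.fn.get(span[2], 0) + 1
    return counts


def harmonic_f1(p: float, r: float) -> float:
    """F1 = 2PR/(P+R) on the percent scale; 0 when both are 0."""
    if p + r == 0:
        return 0.0
    return 2.0 * p * r / (p + r)


def prf_per_class(counts: MatchCounts) -> dict[str, tuple[float, float, float]]:
    """Per-class (P, R, F1) in percent; zero denominators give 0."""
    out = {}
    for cls in counts.classes():
        tp = counts.tp.get(cls, 0)
        fp = counts.fp.get(cls, 0)
        fn = counts.fn.get(cls, 0)
        p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
        r = 100.0 * tp / (tp + fn) if tp + fn else 0.0
        out[cls] = (p, r, harmonic_f1(p, r))
    return out


def macro_average(per_class_p: Sequence[float],
                  per_class_r: Sequence[float]) -> tuple[float, float, float]:
    """Unweighted macro averages; Macro-F1 is harmonic in the two macros."""
    if len(per_class_p) == 0 or len(per_class_p) != len(per_class_r):
        raise ValueError("need one (P, R) pair per class")
    mp = sum(per_class_p) / len(per_class_p)
    mr = sum(per_class_r) / len(per_class_r)
    return mp, mr, harmonic_f1(mp, mr)


def weighted_average(per_class_p: Sequence[float], per_class_r: Sequence[float],
                     supports: Sequence[int]) -> tuple[float, float]:
    """Support-weighted means of per-class P and R."""
    if not (len(per_class_p) == len(per_class_r) == len(supports)):
        raise ValueError("P, R, supports must align")
    if any(s <= 0 for s in supports):
        raise ValueError("all supports must be positive")
    total = sum(supports)
    wp = sum(p * s for p, s in zip(per_class_p, supports)) / total
    wr = sum(r * s for r, s in zip(per_class_r, supports)) / total
    return wp, wr


@dataclass
class EvalReport:
    """Per-class and averaged precision/recall/F1, in percent."""

    per_class: dict[str, tuple[float, float, float]]
    supports: dict[str, int]
    macro_p: float
    macro_r: float
    macro_f1: float
    weighted_p: float | None
    weighted_r: float | None

    def to_table(self) -> str:
        """Console/TSV table: per-class rows, then macro and weighted rows."""
        lines = ["class\tP\tR\tF1\tsupport"]
        for cls, (p, r, f1) in self.per_class.items():
            lines.append(f"{cls}\t{round2(p):.2f}\t{round2(r):.2f}"
                         f"\t{round2(f1):.2f}\t{self.supports[cls]}")
        lines.append(f"macro\t{round2(self.macro_p):.2f}\t{round2(self.macro_r):.2f}"
                     f"\t{round2(self.macro_f1):.2f}\t{sum(self.supports.values())}")
        if self.weighted_p is not None:
            wf1 = harmonic_f1(self.weighted_p, self.weighted_r)
            lines.append(f"weighted\t{round2(self.weighted_p):.2f}"
                         f"\t{round2(self.weighted_r):.2f}\t{round2(wf1):.2f}"
                         f"\t{sum(self.supports.values())}")
        return "\n".join(lines) + "\n"


def evaluate_corpus(gold: Sequence[TaggedSentence],
                    pred: Sequence[TaggedSentence],
                    scheme: TagScheme | None = None) -> EvalReport:
    """Full entity-level report for an aligned gold/pred corpus pair."""
    scheme = scheme or TagScheme()
    counts = match_entities(gold, pred, scheme)
    per_class = prf_per_class(counts)
    ordered = {c: per_class.get(c, (0.0, 0.0, 0.0)) for c in scheme.classes}
    ps = [ordered[c][0] for c in scheme.classes]
    rs = [ordered[c][1] for c in scheme.classes]
    supports = {c: counts.support(c) for c in scheme.classes}
    mp, mr, mf1 = macro_average(ps, rs)
    pos = [c for c in scheme.classes if supports[c] > 0]
    if pos:
        wp, wr = weighted_average([ordered[c][0] for c in pos],
                                  [ordered[c][1] for c in pos],
                                  [supports[c] for c in pos])
    else:
        wp = wr = None
    return EvalReport(ordered, supports, mp, mr, mf1, wp, wr)
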