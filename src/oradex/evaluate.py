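"""Scoring pipeline output against gold labels.

Note-level scoring asks "does this note document at least one candidate
ORADE?"; pair-level scoring matches (note, generic drug, preferred term)
tuples exactly.  Metrics follow the conventional confusion-matrix formulas;
a metric whose denominator is zero is reported as ``None`` (undefined),
never silently as 0 or 1.  Internal values are exact fractions; rounding
happens only at presentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

from oradex.corpus_io import GoldLabel
from oradex.pairing import CandidateORADE


@dataclass(frozen=True)
class MetricsResult:
    tp: int
    fp: int
    fn: int
    tn: int = 0

    def _ratio(self, num: int, den: int) -> Optional[Fraction]:
        return Fraction(num, den) if den else None

    @property
    def accuracy(self) -> Optional[Fraction]:
        return self._ratio(self.tp + self.tn, self.tp + self.fp + self.fn + self.tn)

    @property
    def precision(self) -> Optional[Fraction]:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def recall(self) -> Optional[Fraction]:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def f1(self) -> Optional[Fraction]:
        p, r = self.precision, self.recall
        if p is None or r is None or p + r == 0:
            return None
        return 2 * p * r / (p + r)

    def as_dict(self, digits: int | None = 2) -> dict:
        """Presentation form; ``digits=None`` keeps exact floats."""

        def conv(x: Optional[Fraction]):
            if x is None:
                return None
            return round(float(x), digits) if digits is not None else float(x)

        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "accuracy": conv(self.accuracy),
            "precision": conv(self.precision),
            "recall": conv(self.recall),
            "f1": conv(self.f1),
        }


def _predicted_notes(pairs: Sequence[CandidateORADE], include_filtered: bool) -> set[str]:
    return {p.note_id for p in pairs if include_filtered or not p.filtered}


def evaluate_note_level(
    pairs: Sequence[CandidateORADE],
    gold: Sequence[GoldLabel],
    include_filtered: bool = False,
) -> MetricsResult:
    """Score note-level ORADE presence.

    A note is predicted positive when it carries at least one unfiltered
    candidate pair (``include_filtered=True`` also counts flagged pairs).
    Gold notes absent from the predictions count as negative predictions;
    predicted notes absent from the gold set are not scorable and ignored.
    """
    seen: set[str] = set()
    for lab in gold:
        if lab.note_id in seen:
            raise ValueError(f"duplicate gold label for note_id {lab.note_id!r}")
        seen.add(lab.note_id)
    positive = _predicted_notes(pairs, include_filtered)
    tp = fp = fn = tn = 0
    for lab in gold:
        pred = lab.note_id in positive
        if pred and lab.has_orade:
            tp += 1
        elif pred and not lab.has_orade:
            fp += 1
        elif not pred and lab.has_orade:
            fn += 1
        else:
            tn += 1
    return MetricsResult(tp=tp, fp=fp, fn=fn, tn=tn)


def evaluate_pair_level(
    pairs: Sequence[CandidateORADE],
    gold: Sequence[GoldLabel],
    include_filtered: bool = False,
    include_out_of_window: bool = False,
) -> MetricsResult:
    """Score (note_id, generic drug, preferred term) tuples exactly (after
    case folding).  True negatives are undefined at pair level and reported
    as 0.  Gold pairs planted beyond the context window are excluded unless
    ``include_out_of_window`` is set."""
    predicted = {
        (p.note_id, p.generic_drug.casefold(), p.ae_pt.casefold())
        for p in pairs
        if include_filtered or not p.filtered
    }
    gold_set = {
        (lab.note_id, gp.generic_drug.casefold(), gp.ae_preferred_term.casefold())
        for lab in gold
        for gp in lab.pairs
        if include_out_of_window or not gp.out_of_window
    }
    tp = len(predicted & gold_set)
    return MetricsResult(tp=tp, fp=len(predicted - gold_set), fn=len(gold_set - predicted), tn=0)
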