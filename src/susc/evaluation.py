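"""Evaluation of spelling corrections.

Two surfaces, mirroring how unsupervised correctors are scored in clinical
NLP:

* **Type-level correction rate** — of the distinct misspelling types, the
  fraction whose top-ranked correction equals the truth exactly.
* **Token-level metrics** — accuracy / precision / recall / F1 over an
  aligned token stream, where *accuracy* is the fraction of all tokens whose
  final form equals the truth, *precision* is the fraction of tokens the
  system changed that were changed to the truth, *recall* is the fraction of
  genuinely misspelled tokens whose final form equals the truth, and F1 is
  the harmonic mean.  A system that changes nothing gets precision 1 by
  convention (no wrong changes), which is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

__all__ = ["EvaluationReport", "GoldToken", "correction_rate", "token_metrics"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GoldToken:
    """Gold annotation for one token of the aligned stream."""

    original: str
    truth: str
    was_misspelled: bool


@dataclass(frozen=True)
class EvaluationReport:
    """Token-level scores plus supporting counts."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    n_tokens: int
    n_gold_misspelled: int
    n_changed: int
    n_changed_correctly: int
    correction_rate: Optional[float] = None

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Display form: two decimals, matching conventional reporting."""
        out = {
            "accuracy": round(self.accuracy, ndigits),
            "precision": round(self.precision, ndigits),
            "recall": round(self.recall, ndigits),
            "f1": round(self.f1, ndigits),
        }
        if self.correction_rate is not None:
            out["correction_rate"] = round(self.correction_rate, ndigits)
        return out


def correction_rate(
    predicted: Mapping[str, Optional[str]], gold: Mapping[str, str]
) -> float:
    """Type-level correction rate.

    ``gold`` maps each misspelling type to its true form; ``predicted`` maps
    types to the chosen correction (``None`` for no correction).  Returns
    the fraction of types whose prediction equals the truth exactly.  Types
    missing from ``predicted`` count as uncorrected.
    """
    if not gold:
        raise ValueError("gold mapping must be non-empty")
    hits = sum(1 for t, truth in gold.items() if predicted.get(t) == truth)
    return hits / len(gold)


def _f1(p: float, r: float) -> float:
    return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


def token_metrics(
    predictions: Sequence[str], gold: Sequence[GoldToken]
) -> EvaluationReport:
    """Token-weighted accuracy / precision / recall / F1.

    ``predictions[i]`` is the final form the system left at position ``i``;
    ``gold[i]`` carries the original form, the true form, and whether the
    token was genuinely misspelled.  The two sequences must be aligned
    one-to-one (a length mismatch is fatal).
    """
    if len(predictions) != len(gold):
        raise ValueError(
            f"predictions ({len(predictions)}) and gold ({len(gold)}) are misaligned"
        )
    if not gold:
        raise ValueError("empty evaluation set")

    n = len(gold)
    n_correct = sum(1 for p, g in zip(predictions, gold) if p == g.truth)
    changed = [(p, g) for p, g in zip(predictions, gold) if p != g.original]
    n_changed = len(changed)
    n_changed_ok = sum(1 for p, g in changed if p == g.truth)
    misspelled = [(p, g) for p, g in zip(predictions, gold) if g.was_misspelled]
    n_miss = len(misspelled)

    accuracy = n_correct / n
    if n_changed == 0:
        logger.info("system changed zero tokens; precision defined as 1.0")
        precision = 1.0
    else:
        precision = n_changed_ok / n_changed
    recall = (
        sum(1 for p, g in misspelled if p == g.truth) / n_miss if n_miss else 1.0
    )
    return EvaluationReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=_f1(precision, recall),
        n_tokens=n,
        n_gold_misspelled=n_miss,
        n_changed=n_changed,
        n_changed_correctly=n_changed_ok,
    )
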