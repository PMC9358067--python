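"""Per-protein and per-segment evaluation with cross-validation CIs.

Protein level: recall and false-positive rate for the three protein classes
(beta barrel TMP, alpha helical TMP, globular) plus a binary signal-peptide
call.  Segment level: an observed and a predicted segment match iff their
intersection is at least half of their union AND neither endpoint deviates
by more than five residues.  From the matches we report recall, precision,
the percentage of proteins with the correct segment count (Q_num), with all
segments correct (Q_ok), and the percentage of correct segments whose
membrane orientation is also correct (Q_top).  Per-segment statistics only
consider proteins that actually contain the segment kind.

Metrics are pooled over the proteins within each cross-validation split;
the mean over splits is reported with a 95% confidence interval of
1.96 x SE, and two values differ significantly iff
|A - B| > sqrt(CI_A^2 + CI_B^2).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from memtop.decoder import labels_to_segments
from memtop.io_formats import LabelSequence, Segment

__all__ = [
    "SegmentMatch",
    "protein_class",
    "match_segments",
    "segment_metrics",
    "protein_metrics",
    "confidence_interval",
    "significant_difference",
    "evaluate_split",
    "evaluate_folds",
    "report_to_json",
    "report_to_tsv",
]

MAX_ENDPOINT_SHIFT = 5


@dataclass(frozen=True)
class SegmentMatch:
    observed: Segment
    predicted: Segment | None
    correct: bool
    orientation_correct: bool


def protein_class(labels: LabelSequence | str) -> tuple[str, bool]:
    """(beta | alpha | globular, has signal peptide) for a label string.

    A protein with any TMB segment counts as beta, even if TMH segments are
    also present (beta strands are the rarer, more specific call); otherwise
    any TMH makes it alpha; otherwise globular.
    """
    kinds = {s.kind for s in labels_to_segments(labels)}
    if "TMB" in kinds:
        cls = "beta"
    elif "TMH" in kinds:
        cls = "alpha"
    else:
        cls = "globular"
    return cls, "SP" in kinds


def _is_correct(obs: Segment, pred: Segment) -> bool:
    inter = max(0, min(obs.end, pred.end) - max(obs.start, pred.start))
    union = len(obs) + len(pred) - inter
    if 2 * inter < union:
        return False
    if abs(obs.start - pred.start) > MAX_ENDPOINT_SHIFT:
        return False
    # compare last residues: identical to comparing half-open ends
    if abs(obs.end - pred.end) > MAX_ENDPOINT_SHIFT:
        return False
    return True


def match_segments(observed: Sequence[Segment], predicted: Sequence[Segment]
                   ) -> list[SegmentMatch]:
    """Pair same-kind segments greedily in sequence order (each used once).

    Segments within a protein are collinear and non-overlapping, so
    order-preserving pairing is the natural assignment.  Returns one entry
    per observed segment; unpaired observed segments get ``predicted=None``.
    """
    out: list[SegmentMatch] = []
    for kind in ("TMB", "TMH", "SP"):
        obs_k = [s for s in observed if s.kind == kind]
        pred_k = [s for s in predicted if s.kind == kind]
        for j, obs in enumerate(obs_k):
            pred = pred_k[j] if j < len(pred_k) else None
            if pred is None:
                out.append(SegmentMatch(obs, None, False, False))
            else:
                ok = _is_correct(obs, pred)
                out.append(SegmentMatch(obs, pred, ok, ok and obs.direction == pred.direction))
    return out


def segment_metrics(
    pairs: Sequence[tuple[Sequence[Segment], Sequence[Segment]]],
    kind: str,
) -> dict[str, float]:
    """Pooled per-segment metrics for one segment kind over one protein set.

    ``pairs`` holds (observed segments, predicted segments) per protein; only
    proteins with at least one observed segment of ``kind`` contribute.
    Percentages; NaN when no protein contains the kind.  Precision is NaN if
    no segment of the kind was predicted anywhere in the contributing set.
    """
    n_obs = n_pred = n_correct = n_oriented = 0
    n_prot = n_qnum = n_qok = 0
    for observed, predicted in pairs:
        obs_k = [s for s in observed if s.kind == kind]
        if not obs_k:
            continue
        pred_k = [s for s in predicted if s.kind == kind]
        matches = [m for m in match_segments(observed, predicted) if m.observed.kind == kind]
        n_prot += 1
        n_obs += len(obs_k)
        n_pred += len(pred_k)
        correct = sum(m.correct for m in matches)
        n_correct += correct
        n_oriented += sum(m.orientation_correct for m in matches)
        if len(pred_k) == len(obs_k):
            n_qnum += 1
            if correct == len(obs_k):
                n_qok += 1
    nan = float("nan")
    if n_prot == 0:
        return {k: nan for k in ("recall", "precision", "q_num", "q_ok", "q_top")}
    return {
        "recall": 100.0 * n_correct / n_obs,
        "precision": 100.0 * n_correct / n_pred if n_pred else nan,
        "q_num": 100.0 * n_qnum / n_prot,
        "q_ok": 100.0 * n_qok / n_prot,
        "q_top": 100.0 * n_oriented / n_correct if n_correct else nan,
    }


def protein_metrics(
    class_pairs: Sequence[tuple[tuple[str, bool], tuple[str, bool]]],
) -> dict[str, float]:
    """Per-class recall/FPR over (observed, predicted) protein-class pairs,
    plus binary signal-peptide recall/FPR.  Percentages; NaN when undefined."""
    out: dict[str, float] = {}
    nan = float("nan")
    for cls in ("beta", "alpha", "globular"):
        pos = [(o, p) for o, p in class_pairs if o[0] == cls]
        neg = [(o, p) for o, p in class_pairs if o[0] != cls]
        tp = sum(1 for _, p in pos if p[0] == cls)
        fp = sum(1 for _, p in neg if p[0] == cls)
        out[f"{cls}_recall"] = 100.0 * tp / len(pos) if pos else nan
        out[f"{cls}_fpr"] = 100.0 * fp / len(neg) if neg else nan
    pos = [(o, p) for o, p in class_pairs if o[1]]
    neg = [(o, p) for o, p in class_pairs if not o[1]]
    out["sp_recall"] = 100.0 * sum(1 for _, p in pos if p[1]) / len(pos) if pos else nan
    out["sp_fpr"] = 100.0 * sum(1 for _, p in neg if p[1]) / len(neg) if neg else nan
    return out


def confidence_interval(values: Sequence[float]) -> tuple[float, float]:
    """Mean and 95% CI (1.96 x sample standard error, n-1 denominator)."""
    vals = [v for v in values if not math.isnan(v)]
    if len(vals) < 2:
        raise ValueError("need at least 2 split values for a confidence interval")
    arr = np.asarray(vals, dtype=float)
    return float(arr.mean()), float(1.96 * arr.std(ddof=1) / np.sqrt(len(arr)))


def significant_difference(a: float, ci_a: float, b: float, ci_b: float) -> bool:
    """True iff |A - B| exceeds the composite CI sqrt(CI_A^2 + CI_B^2)."""
    if ci_a < 0 or ci_b < 0:
        raise ValueError("confidence intervals must be non-negative")
    return abs(a - b) > math.hypot(ci_a, ci_b)


# ---------------------------------------------------------------------------
# dataset-level reports

SEGMENT_KINDS = ("TMB", "TMH", "SP")


def evaluate_split(
    references: Mapping[str, LabelSequence],
    predictions: Mapping[str, LabelSequence],
) -> dict[str, float]:
    """All pooled metrics for one set of proteins (e.g. one CV test split)."""
    missing = sorted(set(references) - set(predictions))
    if missing:
        raise KeyError(f"predictions missing for ids: {missing[:5]}")
    seg_pairs = []
    class_pairs = []
    for pid in sorted(references):
        obs = labels_to_segments(references[pid])
        pred = labels_to_segments(predictions[pid])
        seg_pairs.append((obs, pred))
        class_pairs.append((protein_class(references[pid]), protein_class(predictions[pid])))
    report = dict(protein_metrics(class_pairs))
    for kind in SEGMENT_KINDS:
        for name, v in segment_metrics(seg_pairs, kind).items():
            report[f"{kind}_{name}"] = v
    # per-residue accuracy of the 5 observable classes (case collapsed)
    n_ok = n_tot = 0
    for pid in references:
        a = references[pid].labels
        b = predictions[pid].labels
        n_ok += sum(1 for x, y in zip(a, b) if _collapse(x) == _collapse(y))
        n_tot += len(a)
    report["residue_accuracy"] = 100.0 * n_ok / n_tot if n_tot else float("nan")
    return report


def _collapse(c: str) -> str:
    return c.upper() if c in "bh" else c


def evaluate_folds(
    references: Mapping[str, LabelSequence],
    predictions: Mapping[str, LabelSequence],
    fold_of: Mapping[str, int],
) -> dict:
    """Per-split metrics plus mean +- 95% CI across splits."""
    folds = sorted(set(fold_of.values()))
    per_split = {}
    for f in folds:
        ids = [pid for pid in references if fold_of.get(pid) == f]
        per_split[f] = evaluate_split({i: references[i] for i in ids},
                                      {i: predictions[i] for i in ids})
    metrics = sorted({m for rep in per_split.values() for m in rep})
    summary = {}
    for m in metrics:
        vals = [per_split[f].get(m, float("nan")) for f in folds]
        clean = [v for v in vals if not math.isnan(v)]
        if len(clean) >= 2:
            mean, ci = confidence_interval(clean)
        elif clean:
            mean, ci = clean[0], float("nan")
        else:
            mean, ci = float("nan"), float("nan")
        summary[m] = {"mean": mean, "ci95": ci, "per_split": vals}
    return {"splits": {str(f): per_split[f] for f in folds}, "summary": summary}


def report_to_json(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, allow_nan=True)
        fh.write("\n")


def report_to_tsv(report: dict, path: str | Path) -> None:
    """One row per metric: mean, CI and the per-split values."""
    summary = report.get("summary", report)
    with open(path, "w") as fh:
        fh.write("metric\tmean\tci95\tper_split\n")
        for m in sorted(summary):
            entry = summary[m]
            if isinstance(entry, dict):
                per = ",".join(f"{v:.4f}" for v in entry.get("per_split", []))
                fh.write(f"{m}\t{entry['mean']:.4f}\t{entry['ci95']:.4f}\t{per}\n")
            else:
                fh.write(f"{m}\t{entry:.4f}\t\t\n")
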