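"""Breed-specific SV (NSV) identification by positional subtraction.

An SV called in the focal assembly is breed-specific when its position on
the common reference overlaps no SV of the comparator assembly. Insertions
are points on the reference, so they are padded symmetrically before the
overlap test; a pad of 0 would make insertion subtraction vacuous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from intervaltree import IntervalTree

from .svcalls import StructuralVariant

DEFAULT_INS_PAD = 100


@dataclass
class OverlapPolicy:
    """How focal-vs-comparator SV overlap is judged.

    same_type_only restricts subtraction to SVs of the same type;
    reciprocal_min requires a reciprocal overlap fraction (0 = any 1-bp
    overlap); ins_pad widens insertion points by +/- pad bases.
    """

    same_type_only: bool = False
    reciprocal_min: float = 0.0
    ins_pad: int = DEFAULT_INS_PAD

    def __post_init__(self) -> None:
        if not 0.0 <= self.reciprocal_min <= 1.0:
            raise ValueError(f"reciprocal_min must be in [0,1], got {self.reciprocal_min}")
        if self.ins_pad < 0:
            raise ValueError(f"ins_pad must be >= 0, got {self.ins_pad}")


def _overlaps(a: StructuralVariant, b: StructuralVariant, policy: OverlapPolicy) -> bool:
    if a.chrom != b.chrom:
        return False
    if policy.same_type_only and a.sv_type != b.sv_type:
        return False
    a0, a1 = a.interval0(policy.ins_pad)
    b0, b1 = b.interval0(policy.ins_pad)
    inter = min(a1, b1) - max(a0, b0)
    if inter <= 0:
        return False
    if policy.reciprocal_min > 0.0:
        return (inter / (a1 - a0) >= policy.reciprocal_min
                and inter / (b1 - b0) >= policy.reciprocal_min)
    return True


def filter_breed_specific(svs_a: Sequence[StructuralVariant],
                          svs_b: Sequence[StructuralVariant],
                          policy: OverlapPolicy | None = None) -> list[StructuralVariant]:
    """Return the SVs of assembly A whose reference positions overlap no SV of B."""
    policy = policy or OverlapPolicy()
    trees: dict[str, IntervalTree] = {}
    b_by_iv: dict[str, list[StructuralVariant]] = {}
    for b in svs_b:
        s, e = b.interval0(policy.ins_pad)
        trees.setdefault(b.chrom, IntervalTree()).addi(s, e, b)
    out = []
    for a in svs_a:
        s, e = a.interval0(policy.ins_pad)
        hits = trees.get(a.chrom, IntervalTree()).overlap(s, e)
        if not any(_overlaps(a, h.data, policy) for h in hits):
            out.append(a)
    return out


def match_sv(call: StructuralVariant, truth: StructuralVariant,
             tol: int = 50, reciprocal_min: float = 0.8) -> bool:
    """Truth-matching convention: same type, breakpoints within ``tol`` bp
    or reciprocal overlap >= ``reciprocal_min``."""
    if call.chrom != truth.chrom or call.sv_type != truth.sv_type:
        return False
    if call.sv_type == "INS":
        return (abs(call.pos - truth.pos) <= tol
                and min(call.length, truth.length) / max(call.length, truth.length)
                >= reciprocal_min)
    if abs(call.pos - truth.pos) <= tol and abs(call.end - truth.end) <= tol:
        return True
    inter = min(call.end0, truth.end0) - max(call.start0, truth.start0)
    return (inter > 0 and inter / call.length >= reciprocal_min
            and inter / truth.length >= reciprocal_min)


def precision_recall(calls: Sequence[StructuralVariant],
                     truth: Sequence[StructuralVariant],
                     tol: int = 50, reciprocal_min: float = 0.8) -> dict:
    """Greedy one-to-one matching of calls against a truth set.

    Returns overall and per-type precision/recall plus the matched pairs.
    """
    unmatched_truth = list(truth)
    matches: list[tuple[StructuralVariant, StructuralVariant]] = []
    fps: list[StructuralVariant] = []
    for c in calls:
        hit = next((t for t in unmatched_truth if match_sv(c, t, tol, reciprocal_min)), None)
        if hit is None:
            fps.append(c)
        else:
            unmatched_truth.remove(hit)
            matches.append((c, hit))
    n_tp = len(matches)
    per_type = {}
    for svt in sorted({v.sv_type for v in list(calls) + list(truth)}):
        tp_t = sum(1 for c, _ in matches if c.sv_type == svt)
        n_call = sum(1 for c in calls if c.sv_type == svt)
        n_true = sum(1 for t in truth if t.sv_type == svt)
        per_type[svt] = {
            "precision": tp_t / n_call if n_call else float("nan"),
            "recall": tp_t / n_true if n_true else float("nan"),
            "n_calls": n_call, "n_truth": n_true,
        }
    return {
        "precision": n_tp / len(calls) if calls else float("nan"),
        "recall": n_tp / len(truth) if truth else float("nan"),
        "n_calls": len(calls), "n_truth": len(truth), "n_matched": n_tp,
        "per_type": per_type,
        "false_positives": fps, "false_negatives": unmatched_truth,
    }


def evaluate_specificity(nsvs: Sequence[StructuralVariant],
                         truth_private: Sequence[StructuralVariant],
                         tol: int = 50, reciprocal_min: float = 0.8) -> dict:
    """Precision/recall of private-SV recovery against simulation truth."""
    return precision_recall(nsvs, truth_private, tol, reciprocal_min)
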