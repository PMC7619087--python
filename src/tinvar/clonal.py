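"""Copy-number-corrected cancer cell fractions (CCF), clone-level CCF
trajectories, and the longitudinal coordinated-VAF quality check.

A variant observed at allele fraction ``v`` in a tumour sample of purity
``alpha_t`` on a segment with ``n_t`` tumour-cell and ``n_g`` normal-cell
copies is carried by

    CCF = v * (alpha_t * n_t + (1 - alpha_t) * n_g) / (alpha_t * m)

of the tumour cells, where the multiplicity ``m`` (mutant copies per tumour
cell) is estimated by rounding the raw mutation-copy estimate — the standard
subclonal-reconstruction convention.  Clone-level CCFs for timeline plots use
the simpler, depth-robust convention of doubling the median VAF of the
clone's diploid autosomal SNVs, which lets deep targeted timepoints and WGS
timepoints share one scale.  Clustering itself (e.g. Dirichlet-process
methods) is upstream: clone membership arrives as an assignment table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from statistics import median
from typing import Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantCcf",
    "CloneCcf",
    "CloneTrajectory",
    "CoordinationResult",
    "variant_ccf",
    "clone_ccf",
    "coordination_check",
    "export_fishplot_table",
]

CCF_HARD_CAP = 1.5


@dataclass
class VariantCcf:
    vaf: float
    multiplicity: int
    ccf: float
    capped: bool = False
    variant_id: Optional[str] = None
    timepoint: Optional[str] = None


@dataclass
class CloneCcf:
    value: float
    capped: bool = False
    source: str = "diploid_median"  # or "mean_variant_ccf" fallback


@dataclass
class CloneTrajectory:
    clone_id: str
    parent: Optional[str]
    members: list[str]
    ccf_by_timepoint: dict[str, float]
    coordination_pass: Optional[bool] = None
    coordination_score: Optional[float] = None


@dataclass
class CoordinationResult:
    status: str  # "pass" | "fail" | "unscored"
    score: Optional[float]
    informative_pairs: int


def variant_ccf(
    vaf: float,
    alpha_t: float,
    cn_normal: int = 2,
    cn_tumour: int = 2,
    variant_id: Optional[str] = None,
    timepoint: Optional[str] = None,
) -> VariantCcf:
    """CCF of one variant from its VAF, sample purity and local copy number.

    The raw mutation-copy estimate vaf * (alpha_t*cn_tumour +
    (1-alpha_t)*cn_normal) / alpha_t is rounded to the nearest integer in
    [1, cn_tumour] to give the multiplicity; the CCF divides the same
    quantity by that multiplicity.  Sampling noise can push the CCF slightly
    above 1; values above 1.5 are clamped and flagged.
    """
    if not 0.0 < alpha_t <= 1.0:
        raise ValueError("alpha_t must be in (0, 1] for a defined CCF")
    if not 0.0 <= vaf <= 1.0:
        raise ValueError("vaf must be in [0, 1]")
    raw = vaf * (alpha_t * cn_tumour + (1.0 - alpha_t) * cn_normal) / alpha_t
    m = int(min(max(round(raw), 1), max(cn_tumour, 1)))
    ccf = raw / m
    capped = ccf > CCF_HARD_CAP
    if capped:
        ccf = CCF_HARD_CAP
    return VariantCcf(
        vaf=vaf, multiplicity=m, ccf=ccf, capped=capped,
        variant_id=variant_id, timepoint=timepoint,
    )


def clone_ccf(
    diploid_vafs: Sequence[float],
    fallback_ccfs: Optional[Sequence[float]] = None,
) -> CloneCcf:
    """Clone CCF as double the median VAF of its diploid autosomal SNVs.

    With no diploid autosomal members, falls back to the mean of the members'
    copy-number-corrected variant CCFs, flagged by ``source``.  Values above
    1 are capped with a flag.
    """
    if len(diploid_vafs) >= 1:
        value = 2.0 * median(diploid_vafs)
        source = "diploid_median"
    elif fallback_ccfs:
        value = sum(fallback_ccfs) / len(fallback_ccfs)
        source = "mean_variant_ccf"
    else:
        raise ValueError("clone has no member VAFs and no fallback CCFs")
    capped = value > 1.0
    return CloneCcf(value=min(value, 1.0), capped=capped, source=source)


def coordination_check(
    member_vafs: dict[str, Sequence[float]],
    depths: dict[str, Sequence[float]] | Sequence[float],
    min_members: int = 3,
    agreement: float = 0.8,
    noise_se_mult: float = 2.0,
) -> CoordinationResult:
    """Do a clone's member variants move together over time?

    ``member_vafs`` maps variant id -> VAF at each of >= 2 timepoints (same
    order for all members); ``depths`` gives read depth per timepoint, either
    shared or per member.  For each consecutive timepoint pair the per-member
    VAF changes are compared against a binomial noise floor —
    ``noise_se_mult`` times the standard error of the median change, pooled
    across members.  A pair whose median absolute change clears the floor is
    informative and must show >= ``agreement`` of members moving in the
    majority direction; the clone passes iff all informative pairs do.  The
    score is the smallest agreeing fraction over informative pairs (1 if
    none).  Clones with too few members or timepoints are UNSCORED.
    """
    n_members = len(member_vafs)
    lengths = {len(v) for v in member_vafs.values()}
    if n_members == 0 or len(lengths) != 1:
        return CoordinationResult("unscored", None, 0)
    n_tp = lengths.pop()
    if n_members < min_members or n_tp < 2:
        return CoordinationResult("unscored", None, 0)

    per_member_depths = isinstance(depths, dict)
    score = 1.0
    informative = 0
    passed = True
    ids = sorted(member_vafs)
    for t in range(n_tp - 1):
        deltas = [member_vafs[v][t + 1] - member_vafs[v][t] for v in ids]
        # pooled binomial SE of the median change across members
        var_sum = 0.0
        for v in ids:
            d1 = (depths[v][t] if per_member_depths else depths[t])
            d2 = (depths[v][t + 1] if per_member_depths else depths[t + 1])
            p1, p2 = member_vafs[v][t], member_vafs[v][t + 1]
            var_sum += p1 * (1 - p1) / max(d1, 1) + p2 * (1 - p2) / max(d2, 1)
        pooled_se = math.sqrt(var_sum / n_members) / math.sqrt(n_members)
        floor = noise_se_mult * pooled_se
        med_abs = median([abs(d) for d in deltas])
        if med_abs <= floor:
            continue  # flat within noise: uninformative, skipped
        informative += 1
        n_up = sum(1 for d in deltas if d > 0)
        n_down = sum(1 for d in deltas if d < 0)
        frac = max(n_up, n_down) / n_members
        score = min(score, frac)
        if frac < agreement:
            passed = False
    return CoordinationResult("pass" if passed else "fail", score, informative)


def _toposort(clones: Sequence[CloneTrajectory]) -> list[CloneTrajectory]:
    by_id = {c.clone_id: c for c in clones}
    if len(by_id) != len(clones):
        raise ValueError("duplicate clone ids")
    order: list[CloneTrajectory] = []
    state: dict[str, int] = {}  # 0 in-progress, 1 done

    def visit(cid: str) -> None:
        if state.get(cid) == 1:
            return
        if state.get(cid) == 0:
            raise ValueError(f"cyclic parent relation involving clone {cid!r}")
        state[cid] = 0
        parent = by_id[cid].parent
        if parent is not None:
            if parent not in by_id:
                raise ValueError(f"clone {cid!r} has unknown parent {parent!r}")
            visit(parent)
        state[cid] = 1
        order.append(by_id[cid])

    for c in clones:
        visit(c.clone_id)
    return order


def export_fishplot_table(
    clones: Sequence[CloneTrajectory],
    timepoints: Sequence[str],
    tolerance: float = 0.05,
) -> pd.DataFrame:
    """Long-format clone/parent/timepoint/ccf table with nesting repair.

    Fishplot conventions require each clone's CCF to fit inside its parent's
    and sibling CCFs to sum to at most the parent's.  Violations are always
    repaired (children clamped to the parent, sibling groups rescaled
    proportionally onto the parent); only excesses beyond ``tolerance`` — more
    than routine sampling noise — are logged as repairs.  Clones without a
    parent nest inside an implicit root of CCF 1.  Member lists must be
    disjoint across clones; parent relations must be acyclic.
    """
    seen: set[str] = set()
    for c in clones:
        overlap = seen.intersection(c.members)
        if overlap:
            raise ValueError(f"variants assigned to multiple clones: {sorted(overlap)[:3]}")
        seen.update(c.members)

    order = _toposort(clones)
    ccf = {c.clone_id: dict(c.ccf_by_timepoint) for c in clones}
    parent_of = {c.clone_id: c.parent for c in clones}
    children: dict[Optional[str], list[str]] = {}
    for c in clones:
        children.setdefault(c.parent, []).append(c.clone_id)

    n_repairs = 0
    for tp in timepoints:
        # clamp each clone into its parent, root-first
        for c in order:
            cap = 1.0 if c.parent is None else ccf[c.parent].get(tp, 0.0)
            val = ccf[c.clone_id].get(tp, 0.0)
            if val > cap:
                if val - cap > tolerance:
                    n_repairs += 1
                    logger.info(
                        "repair: clone %s ccf %.3f clamped to parent %.3f at %s",
                        c.clone_id, val, cap, tp,
                    )
                ccf[c.clone_id][tp] = cap
        # rescale sibling groups whose sum exceeds the parent, root-first
        for parent in [None] + [c.clone_id for c in order]:
            sibs = children.get(parent, [])
            if not sibs:
                continue
            cap = 1.0 if parent is None else ccf[parent].get(tp, 0.0)
            total = sum(ccf[s].get(tp, 0.0) for s in sibs)
            if total > cap:
                if total - cap > tolerance:
                    n_repairs += 1
                    logger.info(
                        "repair: siblings of %s sum %.3f rescaled to %.3f at %s",
                        parent, total, cap, tp,
                    )
                scale = cap / total if total > 0 else 0.0
                for s in sibs:
                    ccf[s][tp] = ccf[s].get(tp, 0.0) * scale

    rows = [
        {
            "clone": c.clone_id,
            "parent": c.parent if c.parent is not None else "",
            "timepoint": tp,
            "ccf": ccf[c.clone_id].get(tp, 0.0),
        }
        for c in sorted(clones, key=lambda c: c.clone_id)
        for tp in timepoints
    ]
    df = pd.DataFrame(rows, columns=["clone", "parent", "timepoint", "ccf"])
    df.attrs["n_repairs"] = n_repairs
    return df
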