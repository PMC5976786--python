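"""Inter-rater reliability with a temporal tolerance window.

Two coders annotate the same sessions independently. Agreement is computed
on time-discretized streams: a bin agrees when coder B shows coder A's state
anywhere within +/- ``tolerance_s`` of that bin (default 3 s), mirroring the
practice of comparing event-coded video with a tolerance window. The
comparison is symmetrized by averaging the A-vs-B matrix with the transpose
of B-vs-A, so the report does not depend on which coder is called "A".
With a zero window the procedure reduces to the textbook per-bin Cohen's
kappa.

Per-behavior kappas collapse the confusion matrix to 2x2 (behavior vs. all
other). Behaviors with a mean duration below 1% of the session are excluded
from per-behavior reporting (kappa is inaccurate for very infrequent
behaviors); those below 5% are flagged for cautious interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import AlignmentError, DegeneracyError, SchemaError
from .scheme import CodingScheme
from .streams import BehaviorStream, StateSequence, discretize

__all__ = [
    "AgreementConfig",
    "ConfusionMatrix",
    "KappaResult",
    "BehaviorAgreement",
    "KappaReport",
    "tolerant_confusion",
    "cohen_kappa",
    "behavior_kappa",
    "pool_matrices",
    "irr_report",
]


@dataclass(frozen=True)
class AgreementConfig:
    tolerance_s: float = 3.0
    resolution_s: float = 0.5
    compare_modifiers: bool = False
    min_duration_report_pct: float = 1.0
    caution_pct: float = 5.0

    def __post_init__(self) -> None:
        if self.tolerance_s < 0 or self.resolution_s <= 0:
            raise ValueError("tolerance_s must be >= 0 and resolution_s > 0")

    @property
    def window_bins(self) -> int:
        return int(round(self.tolerance_s / self.resolution_s))


@dataclass
class ConfusionMatrix:
    """Square table of tolerant-match tallies over a fixed label order."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.labels), len(self.labels)):
            raise ValueError("counts must be square over labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class KappaResult:
    po: float
    pe: float
    kappa: float | None  # None flags an undefined kappa (pe == 1)

    @property
    def defined(self) -> bool:
        return self.kappa is not None


@dataclass(frozen=True)
class BehaviorAgreement:
    mean_pct: float
    min_pct: float
    max_pct: float
    result: KappaResult | None  # None when excluded
    excluded: bool
    caution: bool


@dataclass
class KappaReport:
    global_result: KappaResult
    global_po: float
    per_group: dict[str, KappaResult]
    per_behavior: dict[str, BehaviorAgreement]
    config: AgreementConfig

    def to_dict(self) -> dict:
        def kr(r: KappaResult | None):
            if r is None:
                return None
            return {"po": r.po, "pe": r.pe, "kappa": r.kappa}

        return {
            "tolerance_s": self.config.tolerance_s,
            "resolution_s": self.config.resolution_s,
            "global": kr(self.global_result),
            "per_group": {g: kr(r) for g, r in self.per_group.items()},
            "per_behavior": {
                b: {
                    "mean_pct": a.mean_pct,
                    "min_pct": a.min_pct,
                    "max_pct": a.max_pct,
                    "excluded": a.excluded,
                    "caution": a.caution,
                    **(kr(a.result) or {"po": None, "pe": None, "kappa": None}),
                }
                for b, a in self.per_behavior.items()
            },
        }


def _labels_of(seq: StateSequence, compare_modifiers: bool) -> list[str]:
    if compare_modifiers:
        return [f"{b}|{m}" for b, m in seq.labels]
    return seq.behaviors


def tolerant_confusion(
    seqA: StateSequence,
    seqB: StateSequence,
    config: AgreementConfig = AgreementConfig(),
    labels: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Windowed, symmetrized confusion matrix between two coders' sequences.

    For each bin t the counted pair is ``(A[t], A[t])`` when B shows A's
    state anywhere in ``[t-w, t+w]`` bins, else ``(A[t], B[t])``; the matrix
    is averaged with the transpose of the same construction run B-vs-A.
    """
    if seqA.resolution_s != seqB.resolution_s:
        raise AlignmentError("sequences have different resolutions")
    if len(seqA) != len(seqB):
        raise AlignmentError(
            f"sequences have different bin counts ({len(seqA)} vs {len(seqB)})"
        )
    a = _labels_of(seqA, config.compare_modifiers)
    b = _labels_of(seqB, config.compare_modifiers)
    if labels is None:
        labels = sorted(set(a) | set(b))
    labels = tuple(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    try:
        ai = np.array([index[x] for x in a])
        bi = np.array([index[x] for x in b])
    except KeyError as exc:
        raise AlignmentError(f"state {exc} not in the provided label set") from exc

    w = config.window_bins
    k, n = len(labels), len(ai)

    def directed(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        m = np.zeros((k, k))
        for t in range(n):
            lo, hi = max(0, t - w), min(n, t + w + 1)
            match = x[t] if (y[lo:hi] == x[t]).any() else y[t]
            m[x[t], match] += 1.0
        return m

    counts = (directed(ai, bi) + directed(bi, ai).T) / 2.0
    return ConfusionMatrix(labels=labels, counts=counts)


def cohen_kappa(cm: ConfusionMatrix) -> KappaResult:
    """Chance-corrected agreement kappa = (po - pe) / (1 - pe) from a confusion matrix."""
    n = cm.n
    if n == 0:
        raise DegeneracyError("empty confusion matrix")
    po = float(np.trace(cm.counts)) / n
    row = cm.counts.sum(axis=1)
    col = cm.counts.sum(axis=0)
    pe = float(row @ col) / n**2
    if pe >= 1.0 - 1e-12:
        return KappaResult(po=po, pe=pe, kappa=None)
    return KappaResult(po=po, pe=pe, kappa=(po - pe) / (1.0 - pe))


def behavior_kappa(cm: ConfusionMatrix, behavior: str) -> KappaResult:
    """Kappa of one behavior vs. the rest, via a 2x2 collapse of the matrix."""
    if behavior not in cm.labels:
        raise SchemaError(f"behavior {behavior!r} not among matrix labels")
    i = cm.labels.index(behavior)
    c = cm.counts
    a = c[i, i]
    b = c[i, :].sum() - a
    d = c[:, i].sum() - a
    rest = c.sum() - a - b - d
    collapsed = ConfusionMatrix(
        labels=(behavior, "__other__"),
        counts=np.array([[a, b], [d, rest]]),
    )
    return cohen_kappa(collapsed)


def pool_matrices(cms: Iterable[ConfusionMatrix]) -> ConfusionMatrix:
    """Sum confusion matrices over sessions; label sets must agree."""
    cms = list(cms)
    if not cms:
        raise DegeneracyError("no matrices to pool")
    labels = cms[0].labels
    for cm in cms[1:]:
        if cm.labels != labels:
            raise AlignmentError("cannot pool matrices with different label sets")
    return ConfusionMatrix(labels=labels, counts=sum(cm.counts for cm in cms))


def _duration_pcts(stream: BehaviorStream) -> dict[str, float]:
    pct: dict[str, float] = {}
    for ev in stream.events:
        pct[ev.behavior] = pct.get(ev.behavior, 0.0) + ev.duration_s
    return {b: 100.0 * t / stream.duration_s for b, t in pct.items()}


def irr_report(
    streamsA: Iterable[BehaviorStream],
    streamsB: Iterable[BehaviorStream],
    scheme: CodingScheme,
    config: AgreementConfig = AgreementConfig(),
) -> KappaReport:
    """Global, per-group, and per-behavior kappa between two coders.

    Group kappas come from the group's confusion matrix pooled across
    sessions; the global kappa pools all three groups into one
    block-diagonal label space (group label sets are disjoint), which keeps
    each group's marginals intact. Per-behavior entries carry mean/min/max
    duration percentages (averaged over the two coders) and the
    exclusion/caution flags.
    """
    byA = {(s.session_id, s.participant_id, s.group): s for s in streamsA}
    byB = {(s.session_id, s.participant_id, s.group): s for s in streamsB}
    if set(byA) != set(byB):
        only_a = sorted(set(byA) - set(byB))
        only_b = sorted(set(byB) - set(byA))
        raise AlignmentError(
            f"coders cover different keys (only A: {only_a}, only B: {only_b})"
        )
    if not byA:
        raise DegeneracyError("no streams to compare")

    group_cms: dict[str, list[ConfusionMatrix]] = {g: [] for g in scheme.groups}
    pcts: dict[str, list[float]] = {}
    for key in sorted(byA):
        _, _, group = key
        sa, sb = byA[key], byB[key]
        qa = discretize(sa, config.resolution_s)
        qb = discretize(sb, config.resolution_s)
        if len(qa) != len(qb):
            raise AlignmentError(f"bin count mismatch for key {key}")
        group_cms[group].append(
            tolerant_confusion(qa, qb, config, labels=scheme.group_codes(group))
        )
        pa, pb = _duration_pcts(sa), _duration_pcts(sb)
        for code in scheme.group_codes(group):
            pcts.setdefault(code, []).append(
                (pa.get(code, 0.0) + pb.get(code, 0.0)) / 2.0
            )

    per_group: dict[str, KappaResult] = {}
    pooled: dict[str, ConfusionMatrix] = {}
    for g, cms in group_cms.items():
        if not cms:
            continue
        pooled[g] = pool_matrices(cms)
        per_group[g] = cohen_kappa(pooled[g])

    # block-diagonal global matrix over the disjoint union of group labels
    all_labels = tuple(lab for g in scheme.groups if g in pooled for lab in pooled[g].labels)
    big = np.zeros((len(all_labels), len(all_labels)))
    off = 0
    for g in scheme.groups:
        if g not in pooled:
            continue
        k = len(pooled[g].labels)
        big[off : off + k, off : off + k] = pooled[g].counts
        off += k
    global_cm = ConfusionMatrix(labels=all_labels, counts=big)
    global_result = cohen_kappa(global_cm)

    per_behavior: dict[str, BehaviorAgreement] = {}
    for g in scheme.groups:
        if g not in pooled:
            continue
        for code in scheme.group_codes(g):
            vals = pcts.get(code, [0.0])
            mean_pct = float(np.mean(vals))
            excluded = mean_pct < config.min_duration_report_pct
            result = None if excluded else behavior_kappa(pooled[g], code)
            per_behavior[code] = BehaviorAgreement(
                mean_pct=mean_pct,
                min_pct=float(np.min(vals)),
                max_pct=float(np.max(vals)),
                result=result,
                excluded=excluded,
                caution=(not excluded) and mean_pct < config.caution_pct,
            )

    return KappaReport(
        global_result=global_result,
        global_po=global_result.po,
        per_group=per_group,
        per_behavior=per_behavior,
        config=config,
    )
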