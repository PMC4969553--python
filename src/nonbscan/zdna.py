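"""Z-DNA propensity search over alternating purine-pyrimidine tracts.

Z-DNA (left-handed duplex) is favored by strict purine/pyrimidine
alternation, strongest for GC repeats and weaker for GT/CA repeats.  The
scoring unit is the non-overlapping dinucleotide step, reflecting the
syn/anti alternation of the Z helix: steps are laid down in one of two
phases (frame 0 starts at the first base of a tract, frame 1 at the
second), and a leading or trailing unpaired base contributes nothing.

Default weights: GC/CG step = 25, GT/TG/CA/AC step = 3, AT/TA step = 0;
a segment is reported when its best-frame total reaches 75 (so (GC)3 is
the shortest qualifying GC repeat).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from nonbscan.seq_io import GenomicInterval, SequenceRecord, ValidationError

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

GC_CLASS = "GC"
GTCA_CLASS = "GT/CA"
AT_CLASS = "AT"

_STEP_CLASS = {
    "GC": GC_CLASS, "CG": GC_CLASS,
    "GT": GTCA_CLASS, "TG": GTCA_CLASS, "CA": GTCA_CLASS, "AC": GTCA_CLASS,
    "AT": AT_CLASS, "TA": AT_CLASS,
}


@dataclass(frozen=True)
class ZdnaParams:
    """Step weights and reporting threshold (defaults are the published scheme)."""

    score_gc: float = 25.0
    score_gtca: float = 3.0
    score_at: float = 0.0
    min_score: float = 75.0
    min_tract_len: int = 6
    subsegments: bool = False

    def __post_init__(self) -> None:
        if self.min_tract_len < 2:
            raise ValueError("min_tract_len must be >= 2")

    def step_score(self, step: str) -> float:
        cls = _STEP_CLASS.get(step)
        if cls is None:
            raise ValidationError(f"step {step!r} is not purine/pyrimidine alternating")
        return {GC_CLASS: self.score_gc, GTCA_CLASS: self.score_gtca,
                AT_CLASS: self.score_at}[cls]


@dataclass(frozen=True)
class ZdnaHit:
    """A scored alternating segment: the dinucleotide steps of the best frame."""

    interval: GenomicInterval
    score: float
    n_steps: int
    frame_offset: int  # 0 or 1: phase of the non-overlapping steps within the tract
    step_breakdown: dict = field(default_factory=dict, hash=False, compare=False)

    def geometry(self) -> tuple:
        return (
            self.interval.seq_id,
            self.interval.start,
            self.interval.end,
            self.score,
            self.n_steps,
        )


def _is_alternating(seq: str) -> bool:
    classes = []
    for b in seq:
        if b in _PURINES:
            classes.append(0)
        elif b in _PYRIMIDINES:
            classes.append(1)
        else:
            return False
    return all(classes[i] != classes[i + 1] for i in range(len(classes) - 1))


def find_alternating_tracts(
    record: SequenceRecord, min_len: int = 6
) -> list[GenomicInterval]:
    """Maximal runs of strict purine/pyrimidine alternation, length >= min_len.

    N breaks runs.  Alternation is about base class, not repeat identity
    ("ACGT" alternates).  Sorted by start.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    seq = record.seq
    n = len(seq)
    cls = [0 if b in _PURINES else 1 if b in _PYRIMIDINES else 2 for b in seq]
    out: list[GenomicInterval] = []
    i = 0
    while i < n:
        if cls[i] == 2:
            i += 1
            continue
        j = i
        while j + 1 < n and cls[j + 1] != 2 and cls[j + 1] != cls[j]:
            j += 1
        if j - i + 1 >= min_len:
            out.append(GenomicInterval(record.id, i, j + 1))
        i = j + 1
    return out


def _frame_score(seq: str, offset: int, params: ZdnaParams):
    """Score the non-overlapping steps of one frame; returns (score, n_steps, breakdown)."""
    score = 0.0
    n_steps = 0
    breakdown = {GC_CLASS: 0, GTCA_CLASS: 0, AT_CLASS: 0}
    for i in range(offset, len(seq) - 1, 2):
        step = seq[i : i + 2]
        breakdown[_STEP_CLASS[step]] += 1
        score += params.step_score(step)
        n_steps += 1
    return score, n_steps, breakdown


def score_fragment(seq: str, params: ZdnaParams | None = None):
    """Score a contiguous alternating purine/pyrimidine fragment.

    The fragment is partitioned into non-overlapping dinucleotide steps
    starting at offset 0 or 1 (an unpaired leading/trailing base scores 0);
    the maximum-scoring frame is returned, frame 0 on ties.

    Returns
    -------
    (score, frame_offset, breakdown)
        breakdown maps step class ('GC', 'GT/CA', 'AT') to step counts.

    Raises
    ------
    ValidationError
        If ``seq`` is not strictly alternating.
    """
    params = params or ZdnaParams()
    seq = seq.upper()
    if not _is_alternating(seq):
        raise ValidationError(f"fragment {seq!r} is not purine/pyrimidine alternating")
    s0, n0, b0 = _frame_score(seq, 0, params)
    if len(seq) < 3:
        return s0, 0, b0
    s1, n1, b1 = _frame_score(seq, 1, params)
    if s1 > s0:
        return s1, 1, b1
    return s0, 0, b0


def find_zdna(
    record: SequenceRecord, params: ZdnaParams | None = None
) -> list[ZdnaHit]:
    """Report alternating tracts whose best-frame step score meets the threshold.

    At defaults one hit is emitted per qualifying tract, covering exactly
    the dinucleotide steps of the best frame (ties go to frame 0); with
    ``params.subsegments=True`` every frame whose span reaches the
    threshold is emitted.  All step weights are non-negative, so the
    maximal-scoring segment of a frame is its whole stepped span.
    """
    params = params or ZdnaParams()
    hits: list[ZdnaHit] = []
    for tract in find_alternating_tracts(record, params.min_tract_len):
        frag = record.seq[tract.start : tract.end]
        frames = [(0, *_frame_score(frag, 0, params))]
        if len(frag) >= 3:
            frames.append((1, *_frame_score(frag, 1, params)))
        if params.subsegments:
            chosen = [f for f in frames if f[1] >= params.min_score]
        else:
            best = max(frames, key=lambda f: (f[1], -f[0]))
            chosen = [best] if best[1] >= params.min_score else []
        for offset, score, n_steps, breakdown in chosen:
            if n_steps == 0:
                continue
            start = tract.start + offset
            hits.append(
                ZdnaHit(
                    interval=GenomicInterval(record.id, start, start + 2 * n_steps),
                    score=score,
                    n_steps=n_steps,
                    frame_offset=offset,
                    step_breakdown=breakdown,
                )
            )
    hits.sort(key=lambda h: (h.interval.start, -h.score))
    return hits


def brute_force_zdna(
    record: SequenceRecord, params: ZdnaParams | None = None
) -> list[ZdnaHit]:
    """Reference search (testing oracle): literal substring enumeration.

    Within each alternating tract every even-length substring (a whole
    number of steps, covering both phases) is scored by summing its
    consecutive dinucleotide weights; the maximum-scoring substring is
    reported if it reaches the threshold, taking the longest (then
    leftmost) on ties.  Equals :func:`find_zdna` output at defaults.
    """
    params = params or ZdnaParams()
    if params.subsegments:
        raise ValueError("oracle covers default single-hit-per-tract mode only")
    hits: list[ZdnaHit] = []
    for tract in find_alternating_tracts(record, params.min_tract_len):
        frag = record.seq[tract.start : tract.end]
        best = None  # (score, length, -start, span, breakdown, n_steps)
        for i in range(len(frag)):
            for j in range(i + 2, len(frag) + 1, 2):
                sub = frag[i:j]
                score = 0.0
                breakdown = {GC_CLASS: 0, GTCA_CLASS: 0, AT_CLASS: 0}
                for k in range(0, len(sub) - 1, 2):
                    breakdown[_STEP_CLASS[sub[k : k + 2]]] += 1
                    score += params.step_score(sub[k : k + 2])
                key = (score, j - i, -i)
                if best is None or key > best[0]:
                    best = (key, (i, j), breakdown)
        if best is None:
            continue
        (score, length, neg_i), (i, j), breakdown = best
        if score < params.min_score:
            continue
        hits.append(
            ZdnaHit(
                interval=GenomicInterval(record.id, tract.start + i, tract.start + j),
                score=score,
                n_steps=length // 2,
                frame_offset=i % 2,
                step_breakdown=breakdown,
            )
        )
    hits.sort(key=lambda h: (h.interval.start, -h.score))
    return hits
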