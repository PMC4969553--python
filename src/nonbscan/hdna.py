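"""H-DNA (intramolecular triplex) candidate search.

H-DNA forms at homopurine·homopyrimidine mirror repeats: one half of the
tract folds back and binds the major groove of the remaining duplex via
Hoogsteen bonds.  A candidate is two "arms" of the same purity class
(both homopurine or both homopyrimidine) separated by a short spacer,
where the second arm is the *reversal* of the first on the same strand —
no complementation (reverse-complement logic would describe an inverted
repeat, a different structure).

Default parameters: minimum arm 6 bp, spacer 1-12 bp, and one symmetry
mismatch tolerated only when the arms are >= 10 bp (a mismatched base must
still respect the arm's purity class).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from nonbscan.seq_io import GenomicInterval, SequenceRecord

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

# class codes used by the fast scanner
_PUR, _PYR, _OTHER = 0, 1, 2
_CLASS_OF = {"A": _PUR, "G": _PUR, "C": _PYR, "T": _PYR, "N": _OTHER}
_CLASS_NAME = {_PUR: "purine", _PYR: "pyrimidine"}


@dataclass(frozen=True)
class HdnaParams:
    """Search parameters; defaults encode the published rules exactly."""

    min_arm: int = 6
    min_spacer: int = 1
    max_spacer: int = 12
    mismatch_arm_threshold: int = 10
    max_mismatches: int = 1
    require_pure_spacer: bool = False

    def __post_init__(self) -> None:
        if self.min_arm < 1:
            raise ValueError("min_arm must be >= 1")
        if self.min_spacer < 0:
            raise ValueError("min_spacer must be >= 0")
        if self.max_spacer < self.min_spacer:
            raise ValueError("max_spacer must be >= min_spacer")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")

    def mismatch_budget(self, arm_len: int) -> int:
        """Mismatches allowed for a final arm length (gate on arm length)."""
        return self.max_mismatches if arm_len >= self.mismatch_arm_threshold else 0


@dataclass(frozen=True)
class MirrorRepeatHit:
    """One H-DNA candidate: arm1 + spacer + arm2 with mirror symmetry."""

    interval: GenomicInterval
    arm_len: int
    spacer_len: int
    mismatches: int
    tract_type: str  # "purine" | "pyrimidine"
    arm1_seq: str
    spacer_seq: str
    arm2_seq: str

    def geometry(self) -> tuple:
        """Coordinate-level identity used for comparisons and tests."""
        return (
            self.interval.seq_id,
            self.interval.start,
            self.interval.end,
            self.arm_len,
            self.spacer_len,
            self.mismatches,
            self.tract_type,
        )


def _classes(seq: str) -> np.ndarray:
    out = np.full(len(seq), _OTHER, dtype=np.int8)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out[(arr == ord("A")) | (arr == ord("G"))] = _PUR
    out[(arr == ord("C")) | (arr == ord("T"))] = _PYR
    return out


def find_purity_tracts(record: SequenceRecord, min_len: int) -> list[GenomicInterval]:
    """Maximal homopurine / homopyrimidine runs of length >= min_len.

    Runs are maximal (either extension breaks purity); N breaks every run.
    Returned sorted by start.  Use :func:`find_purity_tracts_typed` to get
    each tract paired with its 'purine' / 'pyrimidine' annotation.
    """
    return [iv for iv, _ in find_purity_tracts_typed(record, min_len)]


def find_purity_tracts_typed(
    record: SequenceRecord, min_len: int
) -> list[tuple[GenomicInterval, str]]:
    """Like :func:`find_purity_tracts` but paired with 'purine'/'pyrimidine'."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    cls = _classes(record.seq)
    out: list[tuple[GenomicInterval, str]] = []
    n = len(cls)
    i = 0
    while i < n:
        c = cls[i]
        if c == _OTHER:
            i += 1
            continue
        j = i + 1
        while j < n and cls[j] == c:
            j += 1
        if j - i >= min_len:
            out.append((GenomicInterval(record.id, i, j), _CLASS_NAME[int(c)]))
        i = j
    return out


def _run_arrays(cls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """left[i] = length of the same-class run ending at i; right[i] = starting at i."""
    n = len(cls)
    left = np.zeros(n, dtype=np.int64)
    right = np.zeros(n, dtype=np.int64)
    for i in range(n):
        if cls[i] == _OTHER:
            continue
        left[i] = left[i - 1] + 1 if i > 0 and cls[i - 1] == cls[i] else 1
    for i in range(n - 1, -1, -1):
        if cls[i] == _OTHER:
            continue
        right[i] = right[i + 1] + 1 if i < n - 1 and cls[i + 1] == cls[i] else 1
    return left, right


def _best_arm_for_spacer(
    seq: str,
    cls: np.ndarray,
    q: int,
    gap: int,
    max_grow: int,
    params: HdnaParams,
) -> tuple[int, int] | None:
    """Longest admissible arm for the spacer [q, q+gap); returns (arm, mismatches).

    Symmetry pairs expand outward from the spacer: pair j compares
    seq[q-1-j] with seq[q+gap+j].  Purity bounds growth (max_grow); the
    cumulative mismatch count gates admissibility against the budget for
    the *final* arm length.
    """
    mm_prefix = [0]
    mm = 0
    grown = 0
    for j in range(max_grow):
        if seq[q - 1 - j] != seq[q + gap + j]:
            mm += 1
            if mm > params.max_mismatches:
                break
        grown = j + 1
        mm_prefix.append(mm)
    for arm in range(grown, params.min_arm - 1, -1):
        if mm_prefix[arm] <= params.mismatch_budget(arm):
            return arm, mm_prefix[arm]
    return None


def _suppress_contained(raw: list[tuple[int, int, int, int, int, int]]):
    """Drop hits wholly contained in another hit with >= arm length.

    Each raw entry is (start, end, arm, gap, mismatches, class_code).
    """
    kept = []
    for h in raw:
        s, e, a = h[0], h[1], h[2]
        suppressed = False
        for other in raw:
            if other is h:
                continue
            os, oe, oa = other[0], other[1], other[2]
            if os <= s and oe >= e and oa >= a and (os, oe, oa) != (s, e, a):
                suppressed = True
                break
        if not suppressed:
            kept.append(h)
    return kept


def _build_hits(record: SequenceRecord, raw) -> list[MirrorRepeatHit]:
    hits = []
    for s, e, arm, gap, mm, c in raw:
        q = s + arm
        hits.append(
            MirrorRepeatHit(
                interval=GenomicInterval(record.id, s, e),
                arm_len=arm,
                spacer_len=gap,
                mismatches=mm,
                tract_type=_CLASS_NAME[c],
                arm1_seq=record.seq[s:q],
                spacer_seq=record.seq[q : q + gap],
                arm2_seq=record.seq[q + gap : e],
            )
        )
    hits.sort(
        key=lambda h: (h.interval.start, -h.arm_len, h.spacer_len)
    )
    return hits


def find_mirror_repeats(
    record: SequenceRecord, params: HdnaParams | None = None
) -> list[MirrorRepeatHit]:
    """Scan a sequence for mirror-repeat H-DNA candidates.

    For every candidate spacer placement the longest admissible arm is
    reported (arms cannot be extended symmetrically without violating
    purity, the mismatch budget, or sequence bounds); hits wholly contained
    in a hit with at least their arm length are suppressed.  Output is
    sorted by (start ascending, arm length descending, spacer ascending).
    """
    params = params or HdnaParams()
    seq = record.seq
    n = len(seq)
    if n < 2 * params.min_arm + params.min_spacer:
        return []
    cls = _classes(seq)
    left, right = _run_arrays(cls)
    raw: list[tuple[int, int, int, int, int, int]] = []
    for gap in range(params.min_spacer, params.max_spacer + 1):
        # candidate spacer starts q: arm1 ends at q-1, arm2 starts at q+gap
        lo, hi = 1, n - gap  # q in [1, n-gap-1]
        if hi <= lo:
            continue
        q_all = np.arange(lo, hi)
        c_left = cls[q_all - 1]
        c_right = cls[q_all + gap]
        ok = (
            (c_left == c_right)
            & (c_left != _OTHER)
            & (left[q_all - 1] >= params.min_arm)
            & (right[q_all + gap] >= params.min_arm)
        )
        for q in q_all[ok]:
            q = int(q)
            c = int(cls[q - 1])
            if params.require_pure_spacer and gap > 0:
                if not all(int(cls[k]) == c for k in range(q, q + gap)):
                    continue
            max_grow = int(min(left[q - 1], right[q + gap]))
            best = _best_arm_for_spacer(seq, cls, q, gap, max_grow, params)
            if best is None:
                continue
            arm, mm = best
            raw.append((q - arm, q + gap + arm, arm, gap, mm, c))
    return _build_hits(record, _suppress_contained(raw))


def brute_force_mirror_repeats(
    record: SequenceRecord, params: HdnaParams | None = None
) -> list[MirrorRepeatHit]:
    """Exhaustive reference search (testing oracle; quadratic-ish, small inputs).

    Enumerates every (spacer start, spacer length, arm length) placement and
    applies each rule literally on sequence slices, then the same
    per-spacer-maximality and containment-suppression rules as the scanner.
    """
    params = params or HdnaParams()
    seq = record.seq
    n = len(seq)
    raw: list[tuple[int, int, int, int, int, int]] = []
    for gap in range(params.min_spacer, params.max_spacer + 1):
        for q in range(1, n - gap):
            spacer = seq[q : q + gap]
            best: tuple[int, int, int] | None = None  # (arm, mm, class)
            for arm in range(1, min(q, n - q - gap) + 1):
                arm1 = seq[q - arm : q]
                arm2 = seq[q + gap : q + gap + arm]
                bases = set(arm1) | set(arm2)
                if bases <= PURINES:
                    c = _PUR
                elif bases <= PYRIMIDINES:
                    c = _PYR
                else:
                    break  # purity is monotone: longer arms stay impure
                mm = sum(x != y for x, y in zip(arm1, reversed(arm2)))
                if mm > params.max_mismatches:
                    break  # mismatch count is monotone in arm length
                if arm < params.min_arm:
                    continue
                if mm > params.mismatch_budget(arm):
                    continue
                if params.require_pure_spacer and gap > 0:
                    pure = set(spacer) <= (PURINES if c == _PUR else PYRIMIDINES)
                    if not pure:
                        continue
                best = (arm, mm, c)  # keep overwriting: longest admissible arm
            if best is not None:
                arm, mm, c = best
                raw.append((q - arm, q + gap + arm, arm, gap, mm, c))
    return _build_hits(record, _suppress_contained(raw))
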