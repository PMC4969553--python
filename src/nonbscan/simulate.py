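"""Synthetic sequences with planted motifs, breakpoints and assay counts.

Everything the scanners and the enrichment test consume can be generated
here with known ground truth.  The key construction is the guard base:
each planted motif is flanked by bases that break purity (mirror repeats)
or alternation (Z tracts), so the planted geometry is provably the maximal
geometry the scanners must report — truth is exact, not approximate.

The background is i.i.d. with a chosen GC content; it carries no
higher-order structure, so incidental background hits can and do occur by
chance (scanner output is a superset of the planted truth, never compared
as an exact set against it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from nonbscan.assay import AssayCounts
from nonbscan.hdna import MirrorRepeatHit
from nonbscan.seq_io import BreakpointSet, Breakpoint, GenomicInterval, SequenceRecord
from nonbscan.zdna import AT_CLASS, GC_CLASS, GTCA_CLASS, ZdnaHit

_GUARD = 2  # guard bases on each side of a planted motif

MOTIF_KINDS = ("mirror_repeat", "zdna_gc", "zdna_ca")


@dataclass(frozen=True)
class PlantedMotif:
    """Specification of one motif to plant.

    ``position`` is the 0-based start of the motif proper (guards sit just
    outside it); ``None`` requests automatic even spacing.
    """

    kind: str
    position: int | None = None
    arm_len: int = 8
    spacer_len: int = 1
    mismatches: int = 0
    tract_type: str = "purine"
    n_steps: int = 4

    def __post_init__(self) -> None:
        if self.kind not in MOTIF_KINDS:
            raise ValueError(f"kind must be one of {MOTIF_KINDS}")
        if self.kind == "mirror_repeat":
            if self.arm_len < 1 or self.spacer_len < 0:
                raise ValueError("invalid mirror-repeat geometry")
            if self.mismatches < 0 or self.mismatches > self.arm_len:
                raise ValueError("invalid mismatch count")
            if self.tract_type not in ("purine", "pyrimidine"):
                raise ValueError("tract_type must be purine or pyrimidine")
        elif self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    @property
    def motif_len(self) -> int:
        if self.kind == "mirror_repeat":
            return 2 * self.arm_len + self.spacer_len
        return 2 * self.n_steps


@dataclass(frozen=True)
class BreakpointModel:
    """How many breakpoints and what fraction cluster near planted motifs."""

    n_points: int
    association: float = 0.0
    window: int = 100

    def __post_init__(self) -> None:
        if self.n_points < 0:
            raise ValueError("n_points must be >= 0")
        if not 0 <= self.association <= 1:
            raise ValueError("association must be in [0, 1]")
        if self.window < 0:
            raise ValueError("window must be >= 0")


@dataclass(frozen=True)
class PlantSpec:
    seq_len: int
    gc_content: float = 0.5
    motifs: tuple[PlantedMotif, ...] = ()
    breakpoint_model: BreakpointModel | None = None
    seed: int = 0
    seq_id: str = "sim"

    def __post_init__(self) -> None:
        if self.seq_len < 1:
            raise ValueError("seq_len must be >= 1")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        object.__setattr__(self, "motifs", tuple(self.motifs))


def _background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=probs)


def _mirror_plant(rng: np.random.Generator, m: PlantedMotif) -> tuple[str, str, str]:
    """Returns (left_guard + motif + right_guard, arm1, spacer)."""
    pure = "AG" if m.tract_type == "purine" else "CT"
    anti = "CT" if m.tract_type == "purine" else "AG"
    arm1 = "".join(rng.choice(list(pure), size=m.arm_len))
    arm2 = list(arm1[::-1])
    if m.mismatches:
        swap = {"A": "G", "G": "A", "C": "T", "T": "C"}
        for idx in rng.choice(m.arm_len, size=m.mismatches, replace=False):
            arm2[idx] = swap[arm2[idx]]
    spacer = "".join(rng.choice(list(anti), size=m.spacer_len))
    guard_l = "".join(rng.choice(list(anti), size=_GUARD))
    guard_r = "".join(rng.choice(list(anti), size=_GUARD))
    return guard_l + arm1 + spacer + "".join(arm2) + guard_r, arm1, spacer


def _zdna_plant(m: PlantedMotif) -> str:
    if m.kind == "zdna_gc":
        # starts G ends C: flank with same-class bases to break alternation
        return "AA" + "GC" * m.n_steps + "TT"
    return "TT" + "CA" * m.n_steps + "GG"


def _auto_positions(spec: PlantSpec) -> list[int]:
    spans = [m.motif_len + 2 * _GUARD for m in spec.motifs]
    total = sum(spans)
    free = spec.seq_len - total
    k = len(spans)
    if free < 0:
        raise ValueError(
            f"cannot pack {k} motifs ({total} bp with guards) into {spec.seq_len} bp"
        )
    gap = free // (k + 1)
    if gap < 1 and k > 0:
        raise ValueError("motifs too crowded: no background gap between plants")
    positions = []
    cursor = gap
    for span in spans:
        positions.append(cursor + _GUARD)  # position of motif proper
        cursor += span + gap
    return positions


def generate_sequence(spec: PlantSpec):
    """Generate a background sequence with guard-protected planted motifs.

    Returns
    -------
    (SequenceRecord, truth)
        ``truth`` is a list of hit objects (MirrorRepeatHit / ZdnaHit)
        describing exactly what the scanners must report for each plant
        (Z hits below the score threshold are included in truth with their
        score; the scanners will rightly omit them).  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    seq = _background(rng, spec.seq_len, spec.gc_content)

    if spec.motifs and any(m.position is None for m in spec.motifs):
        if not all(m.position is None for m in spec.motifs):
            raise ValueError("give positions for all motifs or for none")
        positions = _auto_positions(spec)
    else:
        positions = [m.position for m in spec.motifs]

    truth: list = []
    occupied: list[tuple[int, int]] = []
    for m, pos in zip(spec.motifs, positions):
        start_g = pos - _GUARD
        end_g = pos + m.motif_len + _GUARD
        if start_g < 0 or end_g > spec.seq_len:
            raise ValueError(
                f"motif at {pos} (guarded span {start_g}-{end_g}) exceeds sequence"
            )
        for s, e in occupied:
            if start_g < e and s < end_g:
                raise ValueError("planted motifs overlap (including guard zones)")
        occupied.append((start_g, end_g))

        if m.kind == "mirror_repeat":
            block, arm1, spacer = _mirror_plant(rng, m)
            arm2 = block[_GUARD + m.arm_len + m.spacer_len : -_GUARD]
            truth.append(
                MirrorRepeatHit(
                    interval=GenomicInterval(spec.seq_id, pos, pos + m.motif_len),
                    arm_len=m.arm_len,
                    spacer_len=m.spacer_len,
                    mismatches=m.mismatches,
                    tract_type=m.tract_type,
                    arm1_seq=arm1,
                    spacer_seq=spacer,
                    arm2_seq=arm2,
                )
            )
        else:
            block = _zdna_plant(m)
            if m.kind == "zdna_gc":
                score = 25.0 * m.n_steps
                breakdown = {GC_CLASS: m.n_steps, GTCA_CLASS: 0, AT_CLASS: 0}
            else:
                score = 3.0 * m.n_steps
                breakdown = {GC_CLASS: 0, GTCA_CLASS: m.n_steps, AT_CLASS: 0}
            truth.append(
                ZdnaHit(
                    interval=GenomicInterval(spec.seq_id, pos, pos + m.motif_len),
                    score=score,
                    n_steps=m.n_steps,
                    frame_offset=0,
                    step_breakdown=breakdown,
                )
            )
        block_arr = np.frombuffer(block.encode("ascii"), dtype="S1")
        seq[start_g:end_g] = block_arr

    record = SequenceRecord(spec.seq_id, seq.tobytes().decode("ascii"))
    return record, truth


def generate_breakpoints(
    record: SequenceRecord,
    truth: list,
    model: BreakpointModel,
    seed: int,
) -> BreakpointSet:
    """Breakpoints with a controlled fraction clustered near planted motifs.

    Exactly ``round(association * n_points)`` points are placed uniformly
    within +/- window bp of a randomly chosen planted motif (clipped to the
    sequence); the remainder are uniform over the whole sequence.
    Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    n_assoc = round(model.association * model.n_points)
    if n_assoc > 0 and not truth:
        raise ValueError("association > 0 requires planted motifs")
    points = []
    for i in range(model.n_points):
        if i < n_assoc:
            motif = truth[rng.integers(len(truth))]
            lo = max(0, motif.interval.start - model.window)
            hi = min(record.length, motif.interval.end + model.window)
            pos = int(rng.integers(lo, hi))
        else:
            pos = int(rng.integers(0, record.length))
        points.append(Breakpoint(record.id, pos, f"bp{i + 1}"))
    return BreakpointSet(points)


def generate_assay_counts(
    fold: float,
    base_freq: float,
    total: int,
    n_reps: int,
    seed: int,
    strain: str = "sim",
) -> list[AssayCounts]:
    """Binomial colony counts for a structure/control pair at a known fold.

    FOA-resistant counts are drawn Binomial(total, base_freq * fold) for the
    structure construct and Binomial(total, base_freq) for the control, one
    pair per replicate.
    """
    if fold < 0:
        raise ValueError("fold must be >= 0")
    if total <= 0:
        raise ValueError("total must be > 0")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    p_structure = base_freq * fold
    if not (0 <= base_freq <= 1 and 0 <= p_structure <= 1):
        raise ValueError("frequencies must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for rep in range(1, n_reps + 1):
        out.append(
            AssayCounts(
                strain=strain,
                construct="structure",
                foa_r=int(rng.binomial(total, p_structure)),
                total=total,
                replicate=rep,
            )
        )
        out.append(
            AssayCounts(
                strain=strain,
                construct="control",
                foa_r=int(rng.binomial(total, base_freq)),
                total=total,
                replicate=rep,
            )
        )
    return out
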