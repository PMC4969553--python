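"""Fluctuation-assay (YAC/FOA) summary statistics.

A yeast artificial chromosome carries a URA3 reporter distal to an inserted
structure-forming (or control B-DNA) sequence; structure-induced breakage
loses URA3 and is selected on 5-FOA.  The mutation frequency is the number
of FOA-resistant colonies divided by the total colony count, and the fold
induction of a structure is its mean frequency over the control's.  Plain
frequencies are reported — no Luria-Delbrueck mutation-rate estimation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from nonbscan.seq_io import ValidationError

CONSTRUCTS = ("structure", "control")


@dataclass(frozen=True)
class AssayCounts:
    """Colony counts for one plating of one construct."""

    strain: str
    construct: str  # "structure" | "control"
    foa_r: int
    total: int
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.construct not in CONSTRUCTS:
            raise ValidationError(f"construct must be one of {CONSTRUCTS}")
        if self.foa_r < 0:
            raise ValidationError("foa_r must be >= 0")
        if self.total <= 0:
            raise ValidationError("total colony count must be > 0")


@dataclass(frozen=True)
class FoldInduction:
    strain: str
    freq_structure: float
    freq_control: float
    fold: float  # NaN when the control frequency is 0
    se: float
    n_replicates: int


def mutation_frequency(counts: AssayCounts, dilution_factor: float = 1.0) -> float:
    """FOA-resistant colonies / total colonies, scaled by the plating dilution.

    ``dilution_factor`` accounts for differential plating volumes between the
    selective and the titer plates (> 0).
    """
    if dilution_factor <= 0:
        raise ValidationError("dilution_factor must be > 0")
    return counts.foa_r / counts.total * dilution_factor


def fold_induction(
    structure_reps: list[AssayCounts],
    control_reps: list[AssayCounts],
    dilution_factor: float = 1.0,
) -> FoldInduction:
    """Fold induction of the structure construct over the control.

    fold = mean(structure frequencies) / mean(control frequencies).  The
    standard error is the SE of per-replicate structure:control ratios when
    replicates are paired (equal count, matching replicate ids, non-zero
    control frequencies); otherwise it is propagated from the two group SEs
    by the delta method.  A zero control mean yields fold = NaN with a
    warning.
    """
    if not structure_reps or not control_reps:
        raise ValidationError("need >= 1 replicate for each construct")
    strains = {c.strain for c in structure_reps} | {c.strain for c in control_reps}
    if len(strains) != 1:
        raise ValidationError(f"mismatched strains: {sorted(strains)}")
    strain = strains.pop()
    fs = np.array([mutation_frequency(c, dilution_factor) for c in structure_reps])
    fc = np.array([mutation_frequency(c, dilution_factor) for c in control_reps])
    mean_s, mean_c = float(fs.mean()), float(fc.mean())
    if mean_c == 0:
        warnings.warn(
            f"strain {strain}: control frequency is 0; fold induction undefined",
            stacklevel=2,
        )
        fold = math.nan
    else:
        fold = mean_s / mean_c
    n = min(len(fs), len(fc))
    paired = (
        len(fs) == len(fc)
        and sorted(c.replicate for c in structure_reps)
        == sorted(c.replicate for c in control_reps)
        and np.all(fc > 0)
    )
    if paired and len(fs) > 1:
        s_sorted = sorted(structure_reps, key=lambda c: c.replicate)
        c_sorted = sorted(control_reps, key=lambda c: c.replicate)
        ratios = np.array(
            [
                mutation_frequency(s, dilution_factor)
                / mutation_frequency(c, dilution_factor)
                for s, c in zip(s_sorted, c_sorted)
            ]
        )
        se = float(ratios.std(ddof=1) / math.sqrt(len(ratios)))
    elif len(fs) > 1 and len(fc) > 1 and mean_c > 0:
        se_s = fs.std(ddof=1) / math.sqrt(len(fs))
        se_c = fc.std(ddof=1) / math.sqrt(len(fc))
        # delta method on the ratio of two independent means
        if mean_s > 0:
            se = float(
                abs(fold) * math.sqrt((se_s / mean_s) ** 2 + (se_c / mean_c) ** 2)
            )
        else:
            se = float(se_s / mean_c)
    else:
        se = math.nan
    return FoldInduction(
        strain=strain,
        freq_structure=mean_s,
        freq_control=mean_c,
        fold=fold,
        se=se,
        n_replicates=n,
    )


def summarize_screen(
    all_counts: list[AssayCounts], dilution_factor: float = 1.0
) -> pd.DataFrame:
    """Per-strain fold-induction table, sorted by fold descending.

    A strain missing one construct is kept as a row with NA fold (and a
    warning) so screens with incomplete strains still produce a full report.
    """
    strains: dict[str, dict[str, list[AssayCounts]]] = {}
    for c in all_counts:
        strains.setdefault(c.strain, {"structure": [], "control": []})[
            c.construct
        ].append(c)
    rows = []
    for strain, groups in strains.items():
        if groups["structure"] and groups["control"]:
            fi = fold_induction(groups["structure"], groups["control"], dilution_factor)
            rows.append(
                {
                    "strain": strain,
                    "freq_structure": fi.freq_structure,
                    "freq_control": fi.freq_control,
                    "fold": fi.fold,
                    "se": fi.se,
                    "n_replicates": fi.n_replicates,
                }
            )
        else:
            missing = "control" if groups["structure"] else "structure"
            warnings.warn(f"strain {strain}: no {missing} counts", stacklevel=2)
            have = groups["structure"] or groups["control"]
            freq = float(
                np.mean([mutation_frequency(c, dilution_factor) for c in have])
            )
            rows.append(
                {
                    "strain": strain,
                    "freq_structure": freq if groups["structure"] else math.nan,
                    "freq_control": freq if groups["control"] else math.nan,
                    "fold": math.nan,
                    "se": math.nan,
                    "n_replicates": 0,
                }
            )
    table = pd.DataFrame(rows)
    return table.sort_values("fold", ascending=False, na_position="last").reset_index(
        drop=True
    )


def read_counts_tsv(path) -> list[AssayCounts]:
    """Read assay counts from TSV columns strain, construct, foa_r, total[, replicate]."""
    df = pd.read_csv(path, sep="\t")
    required = {"strain", "construct", "foa_r", "total"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            AssayCounts(
                strain=str(row["strain"]),
                construct=str(row["construct"]),
                foa_r=int(row["foa_r"]),
                total=int(row["total"]),
                replicate=int(row.get("replicate", 1)) if "replicate" in df else 1,
            )
        )
    return out
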