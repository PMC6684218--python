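"""Drug–ADR association statistics: unique-user counts, PRR, calibration.

The proportional reporting ratio for a drug D and reaction group R is

    PRR(D, R) = (count[D∩R] / count[D]) / (count[!D∩R] / count[!D])

with all four counts taken over *unique users*: count(D∩R) users reporting
both D and R in a post, count(D) users reporting any ADR group with D,
count(!D∩R) users reporting R with a comparison drug other than D, and
count(!D) users reporting at least one ADR with any drug other than D.
No continuity correction is applied by default (a Haldane-style +0.5 option
exists); a zero comparator count with a non-zero target count yields an
infinite-PRR sentinel, reported rather than silently flagged.

The signal threshold is calibrated empirically: pair every comparison drug
with every target ADR group, drop pairs with known associations and manually
excluded confounds (co-prescription or syndromic), and take an upper
percentile (default 95th, linear interpolation) of the control pairs' PRRs.
A pair is flagged when its PRR strictly exceeds both the calibrated
threshold and the fixed PRR>1 rule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PairRecord",
    "ContingencyCounts",
    "SignalResult",
    "KnownAssociationTable",
    "NegativeControlSet",
    "read_pair_records",
    "write_pair_records",
    "aggregate_counts",
    "compute_prr",
    "load_known_associations",
    "build_negative_controls",
    "calibrate_threshold",
    "flag_signals",
    "write_signal_table",
]

EXCLUSION_REASONS = ("coprescription", "syndromic")


@dataclass(frozen=True)
class PairRecord:
    """One drug–ADR co-occurrence: a normalized ADR mention in a drug-corpus post."""

    drug_id: str
    group_id: str
    user_id: str
    post_id: str
    date: date


@dataclass(frozen=True)
class ContingencyCounts:
    """Unique-user counts for one (drug, group) pair."""

    n_dr: int  # users reporting both D and R
    n_d: int  # users reporting any ADR with D
    n_notd_r: int  # users reporting R with comparison drugs other than D
    n_notd: int  # users reporting any ADR with any drug other than D

    def __post_init__(self):
        if min(self.n_dr, self.n_d, self.n_notd_r, self.n_notd) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_dr > self.n_d:
            raise ValueError("count(D∩R) cannot exceed count(D)")
        if self.n_notd_r > self.n_notd:
            raise ValueError("count(!D∩R) cannot exceed count(!D)")


@dataclass(frozen=True)
class SignalResult:
    drug_id: str
    group_id: str
    counts: ContingencyCounts
    prr: float  # may be math.inf
    threshold: float
    flagged: bool  # prr > max(threshold, fixed rule), strict
    flagged_fixed: bool  # prr > fixed rule only


@dataclass
class KnownAssociationTable:
    """Known drug–condition pairs (adr or indication relation)."""

    pairs: set[tuple[str, str, str]]  # (drug_id, group_id, relation)

    def known(self, drug_id: str, group_id: str) -> bool:
        return any(p[0] == drug_id and p[1] == group_id for p in self.pairs)


@dataclass
class NegativeControlSet:
    pairs: list[tuple[str, str]]
    n_candidates: int
    n_after_known: int
    n_final: int


# ---------------------------------------------------------------------------
# pair-record I/O: drug_id \t group_id \t user_id \t post_id \t date
# ---------------------------------------------------------------------------


def read_pair_records(path: str | Path) -> list[PairRecord]:
    records = []
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise ValueError(f"pair-record line {i}: expected 5 columns, got {len(parts)}")
        records.append(
            PairRecord(
                drug_id=parts[0],
                group_id=parts[1],
                user_id=parts[2],
                post_id=parts[3],
                date=date.fromisoformat(parts[4]),
            )
        )
    return records


def write_pair_records(records: Iterable[PairRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for r in records:
            fh.write(
                f"{r.drug_id}\t{r.group_id}\t{r.user_id}\t{r.post_id}\t{r.date.isoformat()}\n"
            )


def load_known_associations(path: str | Path) -> KnownAssociationTable:
    """TSV: drug_id, group_id, relation in {adr, indication}."""
    pairs: set[tuple[str, str, str]] = set()
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"known-association line {i}: expected 3 columns")
        if parts[2] not in ("adr", "indication"):
            raise ValueError(f"known-association line {i}: bad relation {parts[2]!r}")
        pairs.add((parts[0], parts[1], parts[2]))
    return KnownAssociationTable(pairs=pairs)


# ---------------------------------------------------------------------------
# counting and PRR
# ---------------------------------------------------------------------------


def aggregate_counts(
    target_records: Sequence[PairRecord],
    comparison_records: Sequence[PairRecord],
    groups: Sequence[str] | None = None,
) -> dict[str, ContingencyCounts]:
    """Unique-user contingency counts per ADR group for one target drug.

    ``target_records`` are all pair records of the target drug over *all*
    extracted ADR groups (count(D) includes mentions outside the target
    groups); ``comparison_records`` are pair records of the comparison
    drugs and must not contain the target drug.  ``groups`` restricts the
    output to the listed groups (default: every group in the target
    records).
    """
    target_drugs = {r.drug_id for r in target_records}
    if len(target_drugs) > 1:
        raise ValueError(f"target records span several drugs: {sorted(target_drugs)}")
    overlap = target_drugs & {r.drug_id for r in comparison_records}
    if overlap:
        raise ValueError(
            f"target drug {sorted(overlap)} must not appear in the comparison set"
        )
    n_d = len({r.user_id for r in target_records})
    n_notd = len({r.user_id for r in comparison_records})
    users_dr: dict[str, set[str]] = {}
    for r in target_records:
        users_dr.setdefault(r.group_id, set()).add(r.user_id)
    users_ndr: dict[str, set[str]] = {}
    for r in comparison_records:
        users_ndr.setdefault(r.group_id, set()).add(r.user_id)
    if groups is None:
        groups = sorted(users_dr)
    return {
        g: ContingencyCounts(
            n_dr=len(users_dr.get(g, ())),
            n_d=n_d,
            n_notd_r=len(users_ndr.get(g, ())),
            n_notd=n_notd,
        )
        for g in groups
    }


def compute_prr(counts: ContingencyCounts, correction: float = 0.0) -> float:
    """PRR from a unique-user contingency table.

    ``correction`` adds a Haldane-style constant (e.g. 0.5) to all four
    counts; the default applies none.  Degenerate cases: count(D)=0 or
    count(!D)=0 is undefined and raises; a zero comparator count with a
    positive target count returns ``math.inf``; count(D∩R)=0 returns 0.0.
    """
    n_dr = counts.n_dr + correction
    n_d = counts.n_d + correction
    n_notd_r = counts.n_notd_r + correction
    n_notd = counts.n_notd + correction
    if counts.n_d == 0 and correction == 0.0 or n_d == 0:
        raise ZeroDivisionError("PRR undefined: count(D) is zero")
    if counts.n_notd == 0 and correction == 0.0 or n_notd == 0:
        raise ZeroDivisionError("PRR undefined: count(!D) is zero")
    if n_dr == 0:
        return 0.0
    if n_notd_r == 0:
        return math.inf
    return (n_dr / n_d) / (n_notd_r / n_notd)


# ---------------------------------------------------------------------------
# negative controls and calibration
# ---------------------------------------------------------------------------


def build_negative_controls(
    comparison_drugs: Sequence[str],
    target_groups: Sequence[str],
    known: KnownAssociationTable | None = None,
    manual_exclusions: Sequence[tuple[str, str, str]] = (),
) -> NegativeControlSet:
    """Drug–condition pairs with no known association.

    Starts from the cartesian product of comparison drugs and target ADR
    groups, removes pairs with a documented association (ADR or indication)
    and then manually reviewed confounds, whose reason must be
    ``coprescription`` or ``syndromic``.  The three cardinalities
    (candidates, after known removal, final) are reported alongside.
    """
    if not comparison_drugs or not target_groups:
        raise ValueError("comparison drugs and target groups must be non-empty")
    if len(set(comparison_drugs)) != len(comparison_drugs):
        raise ValueError("duplicate comparison drugs")
    candidates = [(d, g) for d in comparison_drugs for g in target_groups]
    candidate_set = set(candidates)
    for drug_id, group_id, reason in manual_exclusions:
        if reason not in EXCLUSION_REASONS:
            raise ValueError(
                f"exclusion reason must be one of {EXCLUSION_REASONS}, got {reason!r}"
            )
        if (drug_id, group_id) not in candidate_set:
            raise ValueError(
                f"manual exclusion ({drug_id}, {group_id}) is not a candidate pair"
            )
    after_known = [
        p for p in candidates if known is None or not known.known(*p)
    ]
    excluded = {(d, g) for d, g, _ in manual_exclusions}
    final = [p for p in after_known if p not in excluded]
    if not final:
        warnings.warn("negative control set is empty after exclusions")
    return NegativeControlSet(
        pairs=final,
        n_candidates=len(candidates),
        n_after_known=len(after_known),
        n_final=len(final),
    )


def calibrate_threshold(
    control_prrs: Sequence[float], percentile: float = 95.0, min_n: int = 10
) -> float:
    """Empirical percentile of the negative-control PRR distribution.

    Infinite values are excluded with a warning; at least ``min_n`` finite
    values are required.  Linear interpolation between order statistics, so
    by construction at least ``percentile`` percent of the control values
    lie at or below the returned threshold.
    """
    finite = [v for v in control_prrs if math.isfinite(v)]
    n_inf = len(control_prrs) - len(finite)
    if n_inf:
        warnings.warn(f"excluding {n_inf} non-finite control PRR value(s)")
    if len(finite) < min_n:
        raise ValueError(
            f"need at least {min_n} finite control PRR values, got {len(finite)}"
        )
    return float(np.percentile(finite, percentile, method="linear"))


def flag_signals(
    results: Sequence[tuple[str, str, ContingencyCounts]],
    threshold: float,
    fixed_rule: float = 1.0,
    correction: float = 0.0,
) -> list[SignalResult]:
    """Compute PRR per pair and flag those strictly above both criteria."""
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    out = []
    for drug_id, group_id, counts in results:
        prr = compute_prr(counts, correction=correction)
        out.append(
            SignalResult(
                drug_id=drug_id,
                group_id=group_id,
                counts=counts,
                prr=prr,
                threshold=threshold,
                flagged=prr > max(threshold, fixed_rule),
                flagged_fixed=prr > fixed_rule,
            )
        )
    return out


def write_signal_table(results: Iterable[SignalResult], path: str | Path) -> None:
    header = (
        "drug_id\tgroup_id\tn_dr\tn_d\tn_notd_r\tn_notd\tprr"
        "\tthreshold\tflagged_calibrated\tflagged_fixed\n"
    )
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(header)
        for r in results:
            c = r.counts
            prr = "inf" if math.isinf(r.prr) else f"{r.prr:.6f}"
            fh.write(
                f"{r.drug_id}\t{r.group_id}\t{c.n_dr}\t{c.n_d}\t{c.n_notd_r}\t{c.n_notd}"
                f"\t{prr}\t{r.threshold:.6f}\t{r.flagged}\t{r.flagged_fixed}\n"
            )
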