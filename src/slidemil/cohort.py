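"""Case manifests and the 21-gene recurrence-score to risk-tier mapping.

The training label is a three-tier recurrence risk (0 low / 1 medium /
2 high) derived from the 21-gene recurrence score (RS, 0-100) following the
TAILORx/RxPONDER guideline cut-offs. For premenopausal node-negative
patients the guideline prints a full three-way split (<=15 / 16-25 / >=26);
for postmenopausal and premenopausal node-positive patients it prints only
a <26 / >=26 treatment split, so the default thresholds apply the same
15/25 interior cut to give every group a three-tier label. Thresholds are
fully configurable per group.
"""

from __future__ import annotations

import csv
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

PATIENT_GROUPS = (
    "premenopausal_pN0",
    "premenopausal_pN1",
    "postmenopausal_pN0_pN1",
)

#: (low_max, med_max): tier 0 iff rs <= low_max, tier 1 iff rs <= med_max, else 2.
DEFAULT_THRESHOLDS: dict[str, tuple[int, int]] = {g: (15, 25) for g in PATIENT_GROUPS}


class ManifestError(ValueError):
    """Raised for malformed or inconsistent case manifests."""


def rs_to_tier(
    rs: int,
    group: str = "premenopausal_pN0",
    thresholds: dict[str, tuple[int, int]] | None = None,
) -> int:
    """Map a recurrence score to a risk tier (0 low, 1 medium, 2 high)."""
    if not 0 <= rs <= 100:
        raise ValueError(f"recurrence score {rs} outside [0, 100]")
    thresholds = thresholds or DEFAULT_THRESHOLDS
    if group not in thresholds:
        raise ManifestError(f"unknown patient group {group!r}")
    low_max, med_max = thresholds[group]
    if rs <= low_max:
        return 0
    if rs <= med_max:
        return 1
    return 2


@dataclass
class CaseRecord:
    case_id: str
    tier: int
    rs: int | None = None
    group: str = "premenopausal_pN0"
    slide_path: str | None = None

    def __post_init__(self):
        if self.tier not in (0, 1, 2):
            raise ManifestError(f"{self.case_id}: tier must be 0, 1 or 2, got {self.tier}")
        if self.rs is not None and not 0 <= self.rs <= 100:
            raise ManifestError(f"{self.case_id}: rs {self.rs} outside [0, 100]")

    def check_consistency(self, thresholds=None, strict: bool = False) -> bool:
        """Verify tier against rs_to_tier(rs) when both are present."""
        if self.rs is None:
            return True
        expected = rs_to_tier(self.rs, self.group, thresholds)
        if expected == self.tier:
            return True
        msg = f"{self.case_id}: tier {self.tier} inconsistent with rs={self.rs} (expected {expected})"
        if strict:
            raise ManifestError(msg)
        warnings.warn(msg, stacklevel=2)
        return False


def load_manifest(path, strict: bool = False, thresholds=None) -> list[CaseRecord]:
    """Read a case manifest CSV (case_id,tier[,rs,group,slide_path])."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        cols = set(reader.fieldnames or ())
        missing = {"case_id", "tier"} - cols
        if missing:
            raise ManifestError(f"{path}: missing required columns {sorted(missing)}")
        records: list[CaseRecord] = []
        seen: set[str] = set()
        for row in reader:
            cid = row["case_id"].strip()
            if cid in seen:
                raise ManifestError(f"{path}: duplicate case_id {cid!r}")
            seen.add(cid)
            try:
                tier = int(row["tier"])
            except (TypeError, ValueError) as exc:
                raise ManifestError(f"{path}: unparseable tier for {cid!r}") from exc
            rs = int(row["rs"]) if row.get("rs") not in (None, "") else None
            rec = CaseRecord(
                case_id=cid,
                tier=tier,
                rs=rs,
                group=row.get("group") or "premenopausal_pN0",
                slide_path=row.get("slide_path") or None,
            )
            rec.check_consistency(thresholds=thresholds, strict=strict)
            records.append(rec)
    return records


def write_manifest(records: list[CaseRecord], path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "tier", "rs", "group", "slide_path"])
        for r in records:
            writer.writerow([r.case_id, r.tier, "" if r.rs is None else r.rs, r.group, r.slide_path or ""])


def class_distribution(cohort: list[CaseRecord], n_classes: int = 3) -> dict[int, int]:
    """Per-tier case counts (zeros included for absent tiers)."""
    if not cohort:
        raise ValueError("empty cohort")
    counts = Counter(r.tier for r in cohort)
    return {tier: counts.get(tier, 0) for tier in range(n_classes)}
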