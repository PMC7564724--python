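"""Anther-size-range profiling and culture-range recommendation.

Anther length is a proxy for the developmental stage of the microspores
inside: profiling the stage mixture of cell concentrates prepared from each
of eight anther size ranges identifies the range richest in vacuolated
microspores — the stage most inducible for androgenesis — plus young-
microspore and mature-pollen ranges used as negative culture controls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .stages import DETECTABLE_STAGES, StageClass, stage_from_any

#: The eight anther size ranges of the selection experiment, in mm.
RANGE_LABELS: tuple[str, ...] = (
    "<3.5 mm",
    "3.5–4 mm",
    "4–4.5 mm",
    "4.5–5 mm",
    "5–5.5 mm",
    "5.5–6 mm",
    "6–6.5 mm",
    ">6.5 mm",
)


def parse_range_label(label: str) -> str:
    """Normalize an anther-range label to its canonical form.

    Accepts ASCII hyphens for the en dash, optional "mm", surrounding space,
    and ">6" as an alias for the open top range ">6.5 mm".
    """
    s = str(label).strip().lower().replace("mm", "").strip()
    s = s.replace("-", "–").replace("—", "–").replace(" ", "")
    alias = {">6": ">6.5"}
    s = alias.get(s, s)
    for canon in RANGE_LABELS:
        if canon.replace(" mm", "").replace(" ", "") == s:
            return canon
    raise ValueError(
        f"unknown anther range {label!r}; valid ranges: {', '.join(RANGE_LABELS)}"
    )


@dataclass
class AntherRangeCount:
    """Stage counts observed in the concentrate of one anther size range."""

    range_label: str
    counts: dict  # StageClass -> int
    n_anthers: int = 0

    def __post_init__(self):
        self.range_label = parse_range_label(self.range_label)
        self.counts = {stage_from_any(k): int(v) for k, v in self.counts.items()}
        for s in DETECTABLE_STAGES:
            self.counts.setdefault(s, 0)
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("stage counts must be non-negative")

    def __getitem__(self, stage) -> int:
        return self.counts[stage_from_any(stage)]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class Recommendation:
    """Selected culture range plus the young/mature control ranges."""

    target_stage: StageClass
    selected_range: str
    selected_count: int
    control_young_range: str
    control_mature_range: str
    profile: list = field(default_factory=list)
    tie: bool = False
    control_ties: tuple = (False, False)


def _check_profile(profile):
    profile = list(profile)
    if not profile:
        raise ValueError("profile must contain at least one range")
    labels = [p.range_label for p in profile]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate range labels in profile")
    return profile


def aggregate(detections_by_range, confidence_floor=0.0, n_anthers=None):
    """Count detections per (range, stage) at a confidence floor.

    ``detections_by_range`` maps a range label to an iterable of detections
    (anything with ``top_class`` and ``confidence``).  With floor 0 the
    counts conserve the number of detections.
    """
    out = []
    for label, dets in detections_by_range.items():
        counts = {s: 0 for s in DETECTABLE_STAGES}
        for d in dets:
            if d.confidence >= confidence_floor:
                counts[stage_from_any(d.top_class)] += 1
        out.append(
            AntherRangeCount(
                range_label=label,
                counts=counts,
                n_anthers=(n_anthers or {}).get(label, 0) if n_anthers else 0,
            )
        )
    out.sort(key=lambda r: RANGE_LABELS.index(r.range_label))
    return out


def _argmax_range(profile, stage):
    """Range with the highest count of ``stage``; ties -> earlier range."""
    best, best_count, tie = None, -1, False
    for rc in sorted(profile, key=lambda r: RANGE_LABELS.index(r.range_label)):
        c = rc[stage]
        if c > best_count:
            best, best_count, tie = rc.range_label, c, False
        elif c == best_count:
            tie = True
    return best, best_count, tie


def control_ranges(profile):
    """Young-microspore and mature-pollen control ranges (argmax per stage)."""
    profile = _check_profile(profile)
    young, _, tie_y = _argmax_range(profile, StageClass.YOUNG_MICROSPORE)
    mature, _, tie_m = _argmax_range(profile, StageClass.MATURE_POLLEN)
    return (young, mature), (tie_y, tie_m)


def recommend_range(profile, target_stage=StageClass.VACUOLATED_MICROSPORE):
    """Recommend the anther range maximizing the target stage's count.

    Ties go to the earlier (smaller) range and are flagged.  Raises if no
    cell of the target stage was detected in any range.
    """
    profile = _check_profile(profile)
    target = stage_from_any(target_stage)
    label, count, tie = _argmax_range(profile, target)
    if count <= 0:
        raise ValueError(f"no cells of target stage {target.short} detected")
    (young, mature), control_tie = control_ranges(profile)
    return Recommendation(
        target_stage=target,
        selected_range=label,
        selected_count=count,
        control_young_range=young,
        control_mature_range=mature,
        profile=profile,
        tie=tie,
        control_ties=control_tie,
    )


def culture_design(
    n_genotypes=3,
    n_protocols=2,
    n_replicates=3,
    anthers_per_replicate=15,
    n_control_ranges=2,
):
    """Anther bookkeeping of the culture experiment.

    Returns (optimal-range anthers, control anthers): each genotype gets
    ``n_replicates`` replicates of ``anthers_per_replicate`` anthers per
    protocol in the recommended range, and the same again in each control
    range.
    """
    per_condition = n_replicates * anthers_per_replicate
    optimal = n_genotypes * n_protocols * per_condition
    control = n_genotypes * n_protocols * n_control_ranges * per_condition
    return optimal, control


# ---------------------------------------------------------------------------
# CSV / JSON I/O

_CSV_COLUMNS = ["range_label", "n_anthers"] + [s.short for s in DETECTABLE_STAGES]


def profile_to_frame(profile) -> pd.DataFrame:
    rows = [
        {
            "range_label": rc.range_label,
            "n_anthers": rc.n_anthers,
            **{s.short: rc[s] for s in DETECTABLE_STAGES},
        }
        for rc in profile
    ]
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def write_profile(profile, path) -> None:
    profile_to_frame(profile).to_csv(path, index=False)


def read_profile(path):
    df = pd.read_csv(path)
    return [
        AntherRangeCount(
            range_label=row["range_label"],
            counts={s: int(row[s.short]) for s in DETECTABLE_STAGES},
            n_anthers=int(row.get("n_anthers", 0) or 0),
        )
        for _, row in df.iterrows()
    ]


def write_recommendation(rec: Recommendation, path) -> None:
    doc = {
        "target_stage": rec.target_stage.short,
        "selected_range": rec.selected_range,
        "selected_count": rec.selected_count,
        "control_young_range": rec.control_young_range,
        "control_mature_range": rec.control_mature_range,
        "tie": rec.tie,
        "control_ties": list(rec.control_ties),
        "profile": [
            {"range_label": rc.range_label, **{s.short: rc[s] for s in DETECTABLE_STAGES}}
            for rc in rec.profile
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
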