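"""Responder / partial-responder / non-responder classification.

The natural day-to-day fluctuation of an undisturbed gut microbiome is
estimated from control subjects as the pooled Bray–Curtis dissimilarity of
sample pairs taken 1-2 days apart.  Its mean + SD and mean + 2*SD become
the two cutoffs against which each intervention subject's dissimilarity to
baseline (at the first peak of the post-intervention trajectory) is
compared:

    bc <  mean + SD            -> non_responder
    mean + SD <= bc <= mean+2SD -> partial_responder
    bc >  mean + 2*SD           -> responder
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import bray_curtis
from .profiles import AbundanceTable, SampleMetadata, align

LABELS = ("non_responder", "partial_responder", "responder")


@dataclass
class FluctuationBaseline:
    """Control-cohort Bray–Curtis fluctuation summary and cutoffs."""

    mean: float
    sd: float
    n_pairs: int
    max_gap_days: int

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("degenerate fluctuation baseline: SD must be positive "
                             "(identical replicate samples only?)")
        if self.n_pairs < 2:
            raise ValueError("fluctuation baseline needs at least 2 pairs")

    @property
    def cutoff1(self) -> float:
        return self.mean + self.sd

    @property
    def cutoff2(self) -> float:
        return self.mean + 2.0 * self.sd


@dataclass
class ResponseAssessment:
    subject_id: str
    selected_day: int
    bc_value: float
    label: str


def estimate_daily_fluctuation(control_table: AbundanceTable,
                               control_metadata: SampleMetadata,
                               max_gap_days: int = 2) -> FluctuationBaseline:
    """Pooled short-interval Bray–Curtis fluctuation of control subjects.

    Every within-subject sample pair with a day gap in [1, max_gap_days]
    contributes one dissimilarity; mean and sample SD are computed over
    all pairs pooled across subjects.
    """
    table, metadata = align(control_table.relative(), control_metadata)
    dm = bray_curtis(table).to_frame()
    values = []
    for subject in metadata.subjects:
        samples = metadata.subject_samples(subject)
        ids, days = samples["sample_id"].tolist(), samples["day"].tolist()
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                gap = abs(days[j] - days[i])
                if 1 <= gap <= max_gap_days:
                    values.append(dm.loc[ids[i], ids[j]])
    if not values:
        raise ValueError(f"no within-subject pairs with a gap of 1-{max_gap_days} days")
    arr = np.asarray(values, dtype=float)
    return FluctuationBaseline(float(arr.mean()), float(arr.std(ddof=1)),
                               len(arr), max_gap_days)


def select_response_timepoint(days, bc_values) -> tuple[int, float]:
    """First peak of the Bray–Curtis-to-baseline trajectory.

    The selected point is the earliest one whose value is strictly greater
    than its successor and not smaller than its predecessor; plateaus take
    the earliest day of the plateau; a monotone non-decreasing trajectory
    yields the last time point.
    """
    days = list(days)
    vals = [float(v) for v in bc_values]
    if len(days) != len(vals) or not days:
        raise ValueError("need equal-length, non-empty day and value sequences")
    if len(vals) == 1:
        return days[0], vals[0]
    # compress runs of equal values, keeping the earliest index of each run
    comp: list[int] = [0]
    for i in range(1, len(vals)):
        if vals[i] != vals[comp[-1]]:
            comp.append(i)
    for pos, i in enumerate(comp):
        prev_ok = pos == 0 or vals[comp[pos - 1]] < vals[i]
        next_drop = pos + 1 < len(comp) and vals[comp[pos + 1]] < vals[i]
        if prev_ok and next_drop:
            return days[i], vals[i]
    return days[-1], vals[-1]  # monotone non-decreasing: last time point


def classify_response(bc_value: float, baseline: FluctuationBaseline) -> str:
    """Ordinal label from the two control-fluctuation cutoffs.

    Both cutoffs belong to the partial-responder interval (closed on both
    sides); responders are strictly above mean + 2*SD.
    """
    if not 0.0 <= bc_value <= 1.0:
        raise ValueError("Bray–Curtis value outside [0, 1]")
    if bc_value < baseline.cutoff1:
        return "non_responder"
    if bc_value <= baseline.cutoff2:
        return "partial_responder"
    return "responder"


def assess_cohort(table: AbundanceTable, metadata: SampleMetadata,
                  baseline: FluctuationBaseline) -> pd.DataFrame:
    """Per-subject response assessment of an intervention cohort.

    Each subject's earliest baseline-phase sample anchors the trajectory;
    Bray–Curtis to every post-phase sample (ordered by day) is computed,
    the first-peak time point selected and classified.
    """
    tab, metadata = align(table.relative(), metadata)
    dm = bray_curtis(tab).to_frame()
    rows = []
    for subject in metadata.subjects:
        samples = metadata.subject_samples(subject)
        base = samples[samples["phase"] == "baseline"]
        post = samples[samples["phase"] == "post"]
        if base.empty or post.empty:
            continue
        anchor = base.iloc[0]["sample_id"]
        days = post["day"].tolist()
        traj = [dm.loc[anchor, s] for s in post["sample_id"]]
        day, bc = select_response_timepoint(days, traj)
        rows.append({"subject_id": subject, "selected_day": int(day),
                     "bc_value": float(bc),
                     "label": classify_response(bc, baseline)})
    return pd.DataFrame(rows, columns=["subject_id", "selected_day", "bc_value", "label"])


def label_summary(assessments: pd.DataFrame) -> pd.Series:
    """Label proportions in canonical order (non, partial, responder)."""
    counts = assessments["label"].value_counts()
    return pd.Series({lab: counts.get(lab, 0) / max(len(assessments), 1)
                      for lab in LABELS}, name="proportion")
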