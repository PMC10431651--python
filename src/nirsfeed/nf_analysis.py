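"""Trial selection, responder classification, concordance and group statistics.

The per-subject analysis: a trial-wise GLM yields a 15×4 table of t-values
on the four DL-PFC neurofeedback channels; trials are ranked by their mean
NF-channel t; a pooled GLM is then refitted with the k best trials as the
task regressor (the unselected trials kept as a nuisance column) and a
channel is activated when its task beta is positive with p below the
ROI-wise Bonferroni threshold.  A subject is a responder when at least one
of the 4 NF channels is activated.

Group level: exact set arithmetic for the with/without short-channel
concordance, Pearson chi-square (df = 1, no continuity correction) for 2×2
comparisons, and block averages of HbO2/HbR around task onsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .glm import fit_glm, roi_activation, trial_t_table
from .preprocess import BANDS, HemoTimeSeries, preprocess_recording
from .probe_paradigm import Paradigm, ProbeLayout, RawRecording

__all__ = [
    "TrialRanking",
    "SubjectOutcome",
    "ConcordanceSummary",
    "BlockAverage",
    "rank_trials",
    "best_k_activation",
    "analyze_subject",
    "concordance",
    "block_average",
    "chi_square_2x2",
    "cohort_report",
    "read_subject_metadata",
]


# ---------------------------------------------------------------------------
# trial ranking
# ---------------------------------------------------------------------------

@dataclass
class TrialRanking:
    """Trials ordered by mean NF-channel t-value (best first)."""

    scores: pd.Series         # index: trial number (1-based), value: mean t
    order: list[int]          # trial numbers, descending score, ties → lower index

    def selected(self, k: int) -> list[int]:
        if not 1 <= k <= len(self.order):
            raise ValueError(f"k must be in 1..{len(self.order)}")
        return sorted(self.order[:k])


def rank_trials(trial_t: pd.DataFrame) -> TrialRanking:
    """Rank trials by the mean t over the 4 NF channels (rows = trials)."""
    if trial_t.isna().any().any():
        raise ValueError("trial t-value table contains missing values")
    scores = trial_t.mean(axis=1)
    # stable sort on -score keeps lower trial index first among ties
    order = list(scores.iloc[np.argsort(-scores.to_numpy(), kind="stable")].index)
    return TrialRanking(scores=scores, order=[int(t) for t in order])


# ---------------------------------------------------------------------------
# best-k activation
# ---------------------------------------------------------------------------

def best_k_activation(
    hemo: HemoTimeSeries,
    layout: ProbeLayout,
    paradigm: Paradigm,
    k: int,
    sc_on: bool = True,
    rois: Sequence[str] = ("nf_dlpfc", "other_frontal", "motor"),
    alpha: float = 0.05,
) -> dict[str, set[str]]:
    """Activated channel sets per ROI after best-k trial selection.

    Pipeline: trial-wise GLM on the NF channels → rank trials by mean NF t →
    pooled GLM (selected trials as task, unselected as nuisance) on every
    channel of the requested ROIs → Bonferroni-thresholded activation.
    """
    nf_names = [c.name for c in layout.roi_channels("nf_dlpfc")]
    trialwise = fit_glm(hemo, layout, paradigm, mode="trialwise", sc=sc_on,
                        channels=nf_names)
    ranking = rank_trials(trial_t_table(trialwise, layout))
    selected = ranking.selected(k)
    channels = [c.name for roi in rois for c in layout.roi_channels(roi)]
    pooled = fit_glm(hemo, layout, paradigm, mode="pooled",
                     selected_trials=selected, sc=sc_on, channels=channels)
    return {roi: roi_activation(pooled, layout, roi, alpha=alpha) for roi in rois}


@dataclass
class SubjectOutcome:
    """Per-subject activation summary across analysis conditions.

    `counts` maps a condition key (band_name, sc_on, k) to a dict of
    per-ROI activated-channel counts; `responder` holds the corresponding
    ≥1-NF-channel flags.  Behavioral labels come from the metadata table.
    """

    subject_id: str
    counts: dict[tuple[str, bool, int], dict[str, int]] = field(default_factory=dict)
    responder: dict[tuple[str, bool, int], bool] = field(default_factory=dict)
    control_feeling: str | None = None  # "control" | "no_control"
    gender: str | None = None
    strategy: str | None = None


def analyze_subject(
    rec: RawRecording,
    subject_id: str = "sub",
    bands: Mapping[str, tuple[float, float]] | None = None,
    ks: Sequence[int] = (15, 10, 5),
    sc_conditions: Sequence[bool] = (False, True),
    rois: Sequence[str] = ("nf_dlpfc", "other_frontal", "motor"),
) -> SubjectOutcome:
    """Run the full offline analysis grid for one subject."""
    bands = dict(bands) if bands is not None else dict(BANDS)
    outcome = SubjectOutcome(subject_id=subject_id)
    for band_name, band in bands.items():
        hemo = preprocess_recording(rec, band=band)
        for sc_on in sc_conditions:
            for k in ks:
                sets = best_k_activation(hemo, rec.layout, rec.paradigm, k,
                                         sc_on=sc_on, rois=rois)
                key = (band_name, sc_on, k)
                outcome.counts[key] = {roi: len(s) for roi, s in sets.items()}
                outcome.responder[key] = len(sets.get("nf_dlpfc", set())) >= 1
    return outcome


# ---------------------------------------------------------------------------
# concordance of with/without-SC responder calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConcordanceSummary:
    """Set decomposition of no-SC (A) vs SC (B) responder calls over n subjects."""

    n_both: int      # responders in both analyses
    n_fp: int        # no-SC only: superficial signal mimicking activation
    n_fn: int        # SC only: activation unmasked by scalp regression
    n_neither: int

    @property
    def n(self) -> int:
        return self.n_both + self.n_fp + self.n_fn + self.n_neither


def concordance(responders_no_sc: Iterable, responders_sc: Iterable, n: int) -> ConcordanceSummary:
    a, b = set(responders_no_sc), set(responders_sc)
    both = len(a & b)
    summary = ConcordanceSummary(
        n_both=both, n_fp=len(a) - both, n_fn=len(b) - both,
        n_neither=n - len(a | b))
    if summary.n != n:
        raise ValueError("responder sets are not subsets of the cohort")
    return summary


# ---------------------------------------------------------------------------
# block averages
# ---------------------------------------------------------------------------

@dataclass
class BlockAverage:
    times: np.ndarray          # s relative to task onset
    mean_hbo2: np.ndarray      # (n_channels, n_window)
    sd_hbo2: np.ndarray
    mean_hbr: np.ndarray
    sd_hbr: np.ndarray
    n_epochs: int
    channels: tuple


def block_average(
    hemo: HemoTimeSeries,
    paradigm: Paradigm,
    window: tuple[float, float] = (-5.0, 60.0),
) -> BlockAverage:
    """Epoch around each task onset, baseline-correct to the 5-s pre-onset mean."""
    fs = hemo.fs
    i_lo = int(round(window[0] * fs))
    i_hi = int(round(window[1] * fs))
    onset_idx = np.round(paradigm.onsets * fs).astype(int)
    if onset_idx[0] + i_lo < 0 or onset_idx[-1] + i_hi > hemo.n_times:
        raise ValueError("epoch window exceeds the recording")
    base_len = int(round(5.0 * fs))

    def epochs(series: np.ndarray) -> np.ndarray:
        out = np.empty((len(onset_idx), series.shape[0], i_hi - i_lo))
        for e, idx in enumerate(onset_idx):
            seg = series[:, idx + i_lo: idx + i_hi]
            base = series[:, idx - base_len: idx].mean(axis=1, keepdims=True)
            out[e] = seg - base
        return out

    eo = epochs(hemo.hbo2)
    er = epochs(hemo.hbr)
    return BlockAverage(
        times=(np.arange(i_lo, i_hi)) / fs,
        mean_hbo2=eo.mean(axis=0), sd_hbo2=eo.std(axis=0, ddof=0),
        mean_hbr=er.mean(axis=0), sd_hbr=er.std(axis=0, ddof=0),
        n_epochs=len(onset_idx), channels=hemo.channels)


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2×2 count table, df = 1, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("table must be 2x2 nonnegative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("chi-square undefined with a zero marginal")
    stat, p, dof, _ = stats.chi2_contingency(t, correction=False)
    assert dof == 1
    return float(stat), float(p)


def read_subject_metadata(path) -> pd.DataFrame:
    """Behavioral labels per subject: control_feeling, gender, strategy."""
    df = pd.read_csv(path)
    required = {"subject_id", "control_feeling"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata CSV missing columns {sorted(missing)}")
    return df.set_index("subject_id")


def cohort_report(outcomes: Sequence[SubjectOutcome]) -> dict:
    """Cohort summaries per analysis condition.

    Returns histograms of NF-channel activation counts (0..4), responder
    proportions, and — where behavioral labels are present — responder ×
    control-feeling cross-tabulations with their chi-square p-values.
    """
    if not outcomes:
        raise ValueError("need at least one subject outcome")
    conditions = sorted({key for o in outcomes for key in o.counts},
                        key=lambda key: (key[0], key[1], -key[2]))
    histograms: dict = {}
    responder_prop: dict = {}
    crosstabs: dict = {}
    for cond in conditions:
        counts = [o.counts[cond]["nf_dlpfc"] for o in outcomes if cond in o.counts]
        hist = np.bincount(counts, minlength=5)[:5]
        histograms[cond] = hist / hist.sum()
        flags = [o.responder[cond] for o in outcomes if cond in o.responder]
        responder_prop[cond] = float(np.mean(flags))
        labelled = [o for o in outcomes if cond in o.responder and o.control_feeling]
        if labelled:
            table = np.zeros((2, 2), dtype=int)
            for o in labelled:
                i = 0 if o.control_feeling == "control" else 1
                j = 0 if o.responder[cond] else 1
                table[i, j] += 1
            entry: dict = {"table": table}
            if np.all(table.sum(axis=0) > 0) and np.all(table.sum(axis=1) > 0):
                stat, p = chi_square_2x2(table)
                entry.update({"chi2": stat, "p": p})
            crosstabs[cond] = entry
    return {"histograms": histograms, "responder_proportion": responder_prop,
            "control_feeling": crosstabs, "n_subjects": len(outcomes)}
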