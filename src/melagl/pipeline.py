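"""End-to-end analysis pipeline: features, report tables, report text.

Glues the stimulus set to the response analysis: computes the average
chunk-strength feature tables (pitch and interval views, chunk sizes 1-8,
training corpus = the 17 old-grammatical melodies counted once), codes
accuracy, runs the planned tests with Holm correction, the mixed ANOVA and
contrasts when two groups are present, the per-participant logistic
regressions with group-level coefficient tests, Type-2 d-prime, and the
exposure check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import analysis as an
from .stimuli import StimulusSet

__all__ = [
    "build_feature_tables",
    "stimulus_manifest_frame",
    "analyze_dataset",
    "AnalysisReport",
]

ACS_RANGE = tuple(range(1, 9))


def stimulus_manifest_frame(ss: StimulusSet) -> pd.DataFrame:
    """Manifest columns needed by accuracy coding."""
    return pd.DataFrame(
        [
            {
                "id": s.id,
                "category": s.category,
                "error_type": s.error_type,
                "n_tones": len(s.pitches),
            }
            for s in ss.test_set
        ]
    )


def build_feature_tables(
    ss: StimulusSet,
    views: Sequence[str] = ("pitch", "interval"),
    n_range: Sequence[int] = ACS_RANGE,
    corpus_multiplier: int = 1,
) -> dict[str, pd.DataFrame]:
    """ACS features per stimulus and view, plus the grammaticality indicator.

    The training corpus is the old-grammatical melody set, each item counted
    ``corpus_multiplier`` times (the learning blocks repeat items; repetition
    scales all counts uniformly, so the default counts each melody once).
    """
    corpus = [s.pitches.pitches for s in ss.old_gram] * corpus_multiplier
    out: dict[str, pd.DataFrame] = {}
    for view in views:
        rows = {}
        for s in ss.test_set:
            feats = an.acs_features(s.pitches.pitches, corpus, n_range, view)
            feats["grammatical"] = 1.0 if s.grammatical else 0.0
            rows[s.id] = feats
        out[view] = pd.DataFrame.from_dict(rows, orient="index")
    return out


@dataclass
class AnalysisReport:
    """All result tables from one pipeline run."""

    accuracy: pd.DataFrame
    excluded: pd.DataFrame
    table1: pd.DataFrame
    anova_gram: pd.DataFrame | None
    anova_error: pd.DataFrame | None
    contrasts_gram: pd.DataFrame | None
    contrasts_error: pd.DataFrame | None
    betas: dict[str, pd.DataFrame]
    beta_tests: dict[str, pd.DataFrame]
    dprime: pd.DataFrame
    dprime_test: an.TestResult | None
    exposure: tuple[float, float] | None
    notes: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        parts = ["# Analysis report", ""]
        parts += ["## Accuracy (Table-1 style)", self.table1.round(4).to_string(), ""]
        for name, tab in (
            ("ANOVA grammaticality", self.anova_gram),
            ("ANOVA error type", self.anova_error),
            ("Simple contrasts (grammaticality)", self.contrasts_gram),
            ("Repeated contrasts (error types)", self.contrasts_error),
        ):
            if tab is not None:
                parts += [f"## {name}", tab.round(4).to_string(), ""]
        for view, tab in self.beta_tests.items():
            parts += [f"## Logistic coefficients vs 0 ({view} view)", tab.round(4).to_string(), ""]
        if self.dprime_test is not None:
            d = self.dprime_test
            parts += [
                "## Type-2 d'",
                f"mean {d.mean:.4f}, sd {d.sd:.4f}, t({d.df}) = {d.t:.3f}, p = {d.p:.4g}",
                "",
            ]
        if self.exposure is not None:
            parts += [f"## Exposure correlation: r = {self.exposure[0]:.4f}, p = {self.exposure[1]:.4f}", ""]
        if self.notes:
            parts += ["## Notes"] + [f"- {n}" for n in self.notes] + [""]
        return "\n".join(parts)


PLANNED_CELLS = ("old_gram", "new_gram", "et1", "et2", "et3", "et4", "et5")


def analyze_dataset(
    responses: pd.DataFrame,
    ss: StimulusSet,
    alpha: float = 0.05,
    outlier_k: float = 2.0,
    features: Mapping[str, pd.DataFrame] | None = None,
) -> AnalysisReport:
    """Run the full behavioral analysis on a response table.

    ``responses`` is long format: participant, group, musician, stimulus,
    familiar, confidence, repetitions (the last three optional).  No
    sphericity correction is applied to the within factors; contrasts are
    reported uncorrected, as noted in the report.
    """
    manifest = stimulus_manifest_frame(ss)
    notes = ["no sphericity correction applied to within-subject factors"]

    acc = an.code_accuracy(responses, manifest)
    kept, excluded = an.exclude_outliers(acc, k=outlier_k)
    keep_ids = set(kept["participant"])
    resp = responses[responses["participant"].isin(keep_ids)].copy()

    # Table-1-style planned tests with Holm correction.
    rows = {}
    pvals = []
    for cell in ("overall", "gram_all") + PLANNED_CELLS + ("ungram_all",):
        vals = kept[cell].dropna()
        entry = {"mean": vals.mean(), "sd": vals.std(ddof=1), "n": len(vals)}
        if cell in PLANNED_CELLS:
            res = an.one_sample_t(vals, 0.5)
            entry.update(t=res.t, df=res.df, p=res.p)
        rows[cell] = entry
    table1 = pd.DataFrame(rows).T
    planned_p = table1.loc[list(PLANNED_CELLS), "p"].to_numpy(dtype=float)
    decisions = an.holm_adjust(planned_p, alpha)
    table1["holm_reject"] = pd.Series(
        dict(zip(PLANNED_CELLS, decisions)), dtype=object
    )

    # Mixed ANOVA + contrasts need two groups and two musician levels.
    anova_gram = anova_error = contrasts_gram = contrasts_error = None
    have_design = (
        "group" in kept.columns
        and "musician" in kept.columns
        and kept["group"].nunique() == 2
        and kept["musician"].nunique() == 2
    )
    gram_levels = ["old_gram", "new_gram", "ungram_all"]
    et_levels = [f"et{i}" for i in range(1, 6)]

    def to_long(levels: list[str]) -> pd.DataFrame:
        sub = kept[["participant"] + [c for c in ("group", "musician") if c in kept.columns] + levels]
        return sub.melt(
            id_vars=[c for c in ("participant", "group", "musician") if c in sub.columns],
            var_name="level",
            value_name="value",
        )

    if have_design:
        anova_gram = an.mixed_anova(to_long(gram_levels), gram_levels)
        anova_error = an.mixed_anova(to_long(et_levels), et_levels)
    if "group" in kept.columns or True:
        contrasts_gram = an.within_contrasts(
            to_long(gram_levels).assign(group=0, musician=0), gram_levels, "simple"
        )
        contrasts_error = an.within_contrasts(
            to_long(et_levels).assign(group=0, musician=0), et_levels, "repeated"
        )

    # Per-participant logistic regressions in both views.
    feats = features if features is not None else build_feature_tables(ss)
    betas: dict[str, pd.DataFrame] = {}
    beta_tests: dict[str, pd.DataFrame] = {}
    for view, ftab in feats.items():
        brows = {}
        for pid, sub in resp.groupby("participant", sort=True):
            X = ftab.loc[sub["stimulus"].values]
            fit = an.fit_participant_logistic(X, sub["familiar"].to_numpy())
            brows[pid] = fit.coef
        bdf = pd.DataFrame.from_dict(brows, orient="index")
        betas[view] = bdf
        beta_tests[view] = an.group_beta_tests(bdf)

    # Type-2 d' per participant.
    cat = manifest.set_index("id")["category"]
    resp = resp.assign(
        correct=np.where(
            resp["stimulus"].map(cat).isin(["old_gram", "new_gram"]),
            resp["familiar"] == 1,
            resp["familiar"] == 0,
        )
    )
    drows = []
    for pid, sub in resp.groupby("participant", sort=True):
        if "confidence" not in sub.columns:
            break
        try:
            d = an.type2_dprime(sub["correct"].to_numpy(), sub["confidence"].to_numpy())
            drows.append({"participant": pid, "dprime": d})
        except ValueError:
            drows.append({"participant": pid, "dprime": np.nan})
            notes.append(f"participant {pid}: Type-2 d' undefined (missing cell)")
    dprime = pd.DataFrame(drows) if drows else pd.DataFrame(columns=["participant", "dprime"])
    dprime_test = None
    if len(dprime) >= 2 and dprime["dprime"].notna().sum() >= 2:
        dprime_test = an.one_sample_t(dprime["dprime"].dropna(), 0.0)

    exposure = None
    if "repetitions" in resp.columns:
        reps = resp.groupby("participant", sort=True)["repetitions"].first()
        overall = kept.set_index("participant")["overall"].reindex(reps.index)
        try:
            exposure = an.exposure_correlation(reps.to_numpy(), overall.to_numpy())
        except ValueError:
            notes.append("exposure correlation undefined (zero variance)")

    return AnalysisReport(
        accuracy=kept,
        excluded=excluded,
        table1=table1,
        anova_gram=anova_gram,
        anova_error=anova_error,
        contrasts_gram=contrasts_gram,
        contrasts_error=contrasts_error,
        betas=betas,
        beta_tests=beta_tests,
        dprime=dprime,
        dprime_test=dprime_test,
        exposure=exposure,
        notes=notes,
    )
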