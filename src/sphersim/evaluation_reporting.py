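"""Robustness classification, summary tables, plots, and recommendations.

Bradley's criteria judge a test robust when its empirical Type I error at
nominal alpha = 5% stays inside an interval around 5%: the liberal criterion
uses [2.5%, 7.5%], the stringent criterion [4.5%, 5.5%].  Rates above the
upper bound mark a liberal test, below the lower bound a conservative one.
Both interval endpoints count as robust.

The robustness table aggregates the null-condition grid by target epsilon
level across all K and N, excluding each K's lower-bound epsilon level
(there the Greenhouse-Geisser and Huynh-Feldt estimates coincide and the two
adjusted tests are trivially identical), and reports for each of the three
tests the percentage of conditions classified conservative / robust /
liberal.

The practical recommendation maps an observed epsilon-hat to a test: below
0.60 use the Greenhouse-Geisser correction; from 0.60 up to 0.90 use
Huynh-Feldt; above 0.90 but below 1 Huynh-Feldt remains the safer default;
at exactly 1 the unadjusted F-test is the most robust choice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .simulation_engine import (
    Condition,
    ConditionResult,
    results_to_frame,
    type1_grid,
)

__all__ = [
    "BradleyCriterion",
    "RobustnessSummary",
    "LIBERAL",
    "STRINGENT",
    "classify",
    "robustness_table",
    "recommend_procedure",
    "write_reports",
]

TESTS = ("F", "F-GG", "F-HF")
CLASSES = ("conservative", "robust", "liberal")
_RATE_COLUMNS = {"F": "rej_f", "F-GG": "rej_gg", "F-HF": "rej_hf"}


@dataclass(frozen=True)
class BradleyCriterion:
    """A robustness interval around the nominal alpha (all in percent)."""

    name: Literal["liberal", "stringent"]
    lower: float
    upper: float
    nominal_alpha: float = 5.0

    def __post_init__(self) -> None:
        if not (self.lower < self.nominal_alpha < self.upper):
            raise ValueError("criterion must bracket the nominal alpha")


LIBERAL = BradleyCriterion("liberal", 2.5, 7.5)
STRINGENT = BradleyCriterion("stringent", 4.5, 5.5)


@dataclass(frozen=True)
class RobustnessSummary:
    """Per-epsilon-level robustness percentages for the three tests.

    ``table`` is indexed by epsilon level with MultiIndex columns
    (test, class) holding percentages of conditions; ``denominators`` gives
    the number of conditions per level.
    """

    criterion: BradleyCriterion
    table: pd.DataFrame
    denominators: pd.Series


def classify(rate: float, criterion: BradleyCriterion) -> str:
    """Classify an empirical Type I error rate (percent) under a criterion."""
    if not (0.0 <= rate <= 100.0):
        raise ValueError(f"rate must be a percentage in [0, 100], got {rate}")
    if rate < criterion.lower:
        return "conservative"
    if rate > criterion.upper:
        return "liberal"
    return "robust"


def robustness_table(
    results: Sequence[ConditionResult],
    criterion: BradleyCriterion,
    require_full_grid: bool = True,
) -> RobustnessSummary:
    """Aggregate null-condition results into per-epsilon robustness
    percentages, excluding each K's lower-bound epsilon level.

    With the full 437-condition grid the denominators are 19 at the 0.30
    level (K = 6 only), 38 at 0.40 and 0.50 (K = 4 and 6), and 57 from 0.60
    on (all three K).
    """
    null_results = [r for r in results if r.condition.design == "type1"]
    if require_full_grid:
        expected = {(c.k, round(c.eps_target, 6), c.n) for c in type1_grid()}
        got = {
            (r.condition.k, round(r.condition.eps_target, 6), r.condition.n)
            for r in null_results
        }
        missing = sorted(expected - got)
        if missing:
            raise ValueError(
                f"results do not cover the Type I error grid; {len(missing)} "
                f"missing cells, first few: {missing[:5]}"
            )
    kept = [r for r in null_results if not r.condition.is_lower_bound]
    frame = results_to_frame(kept)

    levels = sorted(frame["eps_label"].unique())
    rows = {}
    denoms = {}
    for level in levels:
        sub = frame[frame["eps_label"] == level]
        denoms[level] = len(sub)
        row = {}
        for test, col in _RATE_COLUMNS.items():
            labels = [classify(rate, criterion) for rate in sub[col]]
            for cls in CLASSES:
                row[(test, cls)] = 100.0 * labels.count(cls) / len(labels)
        rows[level] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["test", "class"])
    table.index.name = "eps"
    return RobustnessSummary(
        criterion=criterion,
        table=table,
        denominators=pd.Series(denoms, name="n_conditions"),
    )


def recommend_procedure(eps_hat: float, with_note: bool = False):
    """Recommend which repeated-measures F-test to report given epsilon-hat.

    Below 0.60 the Greenhouse-Geisser-adjusted test ("F-GG"); from 0.60
    through 0.90 the Huynh-Feldt-adjusted test ("F-HF"); strictly between
    0.90 and 1 still "F-HF" (with an advisory note when ``with_note``);
    exactly 1 the unadjusted "F".
    """
    if not (0.0 < eps_hat <= 1.0):
        raise ValueError(f"epsilon-hat must be in (0, 1], got {eps_hat}")
    note = ""
    if eps_hat >= 1.0:
        proc = "F"
    elif eps_hat < 0.60:
        proc = "F-GG"
    else:
        proc = "F-HF"
        if eps_hat > 0.90:
            note = (
                "epsilon-hat above 0.90 but below 1: the unadjusted F-test is "
                "still slightly liberal here; F-HF remains the safer choice"
            )
    if with_note:
        return proc, note
    return proc


def write_reports(
    summary: RobustnessSummary,
    results: Sequence[ConditionResult],
    out_dir,
    manifest_extra: Optional[dict] = None,
) -> dict[str, Path]:
    """Write the robustness table, per-condition results, summary figures,
    and a JSON run manifest to ``out_dir``.

    Returns a mapping of artifact names to paths.  The manifest records the
    seed, replication count, grid sizes and package version, so that a run
    can be reproduced exactly from it.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    table = summary.table.round(1).copy()
    table.columns = [f"{t}_{c}" for t, c in table.columns]
    table.insert(0, "n_conditions", summary.denominators)
    paths["robustness_table"] = out / "robustness_table.csv"
    table.to_csv(paths["robustness_table"], index_label="eps")

    frame = results_to_frame(results)
    paths["conditions"] = out / "condition_results.csv"
    frame.to_csv(paths["conditions"], index=False)

    paths.update(_write_plots(frame, out))

    from . import __version__

    seeds = sorted({r.seed for r in results})
    manifest = {
        "package": "sphersim",
        "version": __version__,
        "criterion": summary.criterion.name,
        "nreps": sorted({r.nreps for r in results}),
        "n_conditions": len(results),
        "designs": sorted({r.condition.design for r in results}),
        "condition_seeds": seeds if len(seeds) <= 20 else [seeds[0], seeds[-1]],
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths


def _write_plots(frame: pd.DataFrame, out: Path) -> dict[str, Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths: dict[str, Path] = {}
    for design, ylabel, fname in [
        ("type1", "Type I error (%)", "type1_error"),
        ("power", "Empirical power (%)", "power"),
    ]:
        sub = frame[frame["design"] == design]
        if sub.empty:
            continue
        ks = sorted(sub["k"].unique())
        fig, axes = plt.subplots(1, len(ks), figsize=(4.5 * len(ks), 3.5),
                                 squeeze=False, sharey=True)
        for ax, k in zip(axes[0], ks):
            sk = sub[sub["k"] == k]
            for eps in sorted(sk["eps_label"].unique()):
                se = sk[sk["eps_label"] == eps].groupby("n")["rej_f"].mean()
                ax.plot(se.index, se.values, marker="o", ms=3, label=f"eps={eps:g}")
            if design == "type1":
                for bound in (2.5, 7.5):
                    ax.axhline(bound, color="grey", lw=0.8, ls="--")
            ax.set_title(f"K = {k} (unadjusted F)")
            ax.set_xlabel("N")
        axes[0][0].set_ylabel(ylabel)
        axes[0][-1].legend(fontsize=7)
        fig.tight_layout()
        paths[fname] = out / f"{fname}.png"
        fig.savefig(paths[fname], dpi=120)
        plt.close(fig)
    return paths
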