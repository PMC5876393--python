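"""Group-level inference and confounder checks.

One-sample t-tests of decoding accuracy against the 50% chance level
with Bonferroni correction, paired comparisons of classifier weight
maps across participants, paired tests on affective-intensity ratings,
Spearman correlations between accuracies and mood-scale changes, a
two-sample gender check, and the summary accuracy table.

All t-tests are two-sided.  Bonferroni correction is always
``min(1, p * n_tests)`` with a caller-supplied test count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as _stats

logger = logging.getLogger("fnirsdecode")

#: Chance level for two-class balanced accuracy, %.
CHANCE = 50.0

#: Default Bonferroni count for accuracy-vs-chance tests.
DEFAULT_N_CORRECTIONS = 12


def bonferroni(p: float, n_tests: int) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, float(p) * n_tests)


@dataclass
class GroupResult:
    """Across-participant summary of one decoding comparison."""

    comparison: str
    accuracies: np.ndarray
    mean: float
    sd: float
    t: float
    p_raw: float
    p_corrected: float
    n_tests: int
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p_corrected < 0.05


def test_vs_chance(accuracies, n_corrections: int = DEFAULT_N_CORRECTIONS,
                   comparison: str = "", chance: float = CHANCE) -> GroupResult:
    """Two-sided one-sample t-test of participant accuracies against 50%.

    A zero-variance sample is flagged ``degenerate``; when its mean
    equals chance exactly the test statistic is reported as t = 0,
    p = 1 (no evidence either way), otherwise as infinite t with p = 0.
    """
    acc = np.asarray(accuracies, dtype=float)
    if acc.size < 3:
        raise ValueError("need at least 3 participants")
    mean = float(acc.mean())
    sd = float(acc.std(ddof=1))
    if sd == 0.0:
        t = 0.0 if mean == chance else float(np.sign(mean - chance)) * np.inf
        p_raw = 1.0 if mean == chance else 0.0
        degenerate = True
    else:
        t, p_raw = _stats.ttest_1samp(acc, chance)
        t, p_raw = float(t), float(p_raw)
        degenerate = False
    return GroupResult(comparison=comparison, accuracies=acc, mean=mean,
                       sd=sd, t=t, p_raw=p_raw,
                       p_corrected=bonferroni(p_raw, n_corrections),
                       n_tests=n_corrections, degenerate=degenerate)


def _paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t; zero-variance zero-mean differences give t=0, p=1."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if np.all(d == d[0]):
        if d[0] == 0.0:
            return 0.0, 1.0
        return float(np.sign(d[0])) * np.inf, 0.0
    t, p = _stats.ttest_rel(x, y)
    return float(t), float(p)


def compare_weight_maps(weights1: np.ndarray, weights2: np.ndarray,
                        channel_names: list[str] | None = None,
                        n_corrections: int | None = None) -> pd.DataFrame:
    """Per-channel paired t-tests of participant weights between two
    classification procedures.

    ``weights1``/``weights2`` are (n_participants, n_channels) arrays
    of channel-level weights (same participants, same montage).  The
    correction count defaults to the channel count.
    """
    W1 = np.atleast_2d(np.asarray(weights1, dtype=float))
    W2 = np.atleast_2d(np.asarray(weights2, dtype=float))
    if W1.shape != W2.shape:
        raise ValueError("weight arrays must share (participants, channels) shape")
    n_part, n_ch = W1.shape
    if channel_names is None:
        channel_names = [f"c{i}" for i in range(n_ch)]
    if n_corrections is None:
        n_corrections = n_ch
    rows = []
    for j in range(n_ch):
        t, p = _paired_t(W1[:, j], W2[:, j])
        rows.append({"channel": channel_names[j], "t": t, "p_raw": p,
                     "p_corrected": bonferroni(p, n_corrections),
                     "significant": bonferroni(p, n_corrections) < 0.05})
    return pd.DataFrame(rows)


def intensity_contrast(ratings: pd.DataFrame,
                       n_corrections: int = 6) -> pd.DataFrame:
    """Paired t-tests on per-participant mean intensity ratings.

    ``ratings`` is long-format with columns ``participant``,
    ``condition``, ``label`` and ``rating`` (one mean rating per cell).
    All three label pairs are tested within each condition and
    Bonferroni-corrected for the six comparisons (two conditions x
    three affective experiences).
    """
    required = {"participant", "condition", "label", "rating"}
    if not required.issubset(ratings.columns):
        raise ValueError(f"ratings must have columns {sorted(required)}")
    wide = ratings.pivot_table(index="participant",
                               columns=["condition", "label"],
                               values="rating")
    rows = []
    for condition in sorted(wide.columns.get_level_values(0).unique()):
        block = wide[condition]
        for a, b in combinations(sorted(block.columns), 2):
            cell = block[[a, b]].dropna()
            if cell.empty:
                raise ValueError(f"missing cell for {condition}: {a}/{b}")
            t, p = _paired_t(cell[a].to_numpy(), cell[b].to_numpy())
            rows.append({"condition": condition, "comparison": f"{a}-vs-{b}",
                         "mean_a": float(cell[a].mean()),
                         "mean_b": float(cell[b].mean()), "t": t, "p_raw": p,
                         "p_corrected": bonferroni(p, n_corrections),
                         "significant": bonferroni(p, n_corrections) < 0.05})
    return pd.DataFrame(rows)


def confounder_scan(accuracy_table: pd.DataFrame, mood_deltas: pd.DataFrame,
                    gender: pd.Series) -> dict[str, pd.DataFrame]:
    """Confounder checks: mood-change correlations and a gender contrast.

    Parameters
    ----------
    accuracy_table
        Participants x accuracy variables (the 15 comparison
        accuracies), indexed by participant.
    mood_deltas
        Participants x mood variables (the 16 pre-to-post mood-scale
        changes), same index.
    gender
        Participant gender codes (two groups), same index.

    Returns
    -------
    dict with ``"spearman"`` (mood x accuracy grid of rho and p values,
    Bonferroni-corrected for the full grid size) and ``"gender"`` (one
    independent-samples t-test per accuracy variable, corrected for
    the number of accuracy variables).
    """
    if not accuracy_table.index.equals(mood_deltas.index) or \
            not accuracy_table.index.equals(gender.index):
        raise ValueError("participants misaligned across inputs")
    n_grid = accuracy_table.shape[1] * mood_deltas.shape[1]
    rows = []
    for mood in mood_deltas.columns:
        mv = mood_deltas[mood].to_numpy(dtype=float)
        tied = np.all(mv == mv[0])
        for acc in accuracy_table.columns:
            if tied:
                rho, p, flag = np.nan, np.nan, True
            else:
                rho, p = _stats.spearmanr(mv, accuracy_table[acc].to_numpy())
                rho, p, flag = float(rho), float(p), False
            rows.append({"mood": mood, "accuracy": acc, "rho": rho,
                         "p_raw": p,
                         "p_corrected": np.nan if flag else bonferroni(p, n_grid),
                         "undefined": flag})
    spearman = pd.DataFrame(rows)

    groups = gender.unique()
    if len(groups) != 2:
        raise ValueError("gender must have exactly two groups")
    g_rows = []
    n_acc = accuracy_table.shape[1]
    for acc in accuracy_table.columns:
        x = accuracy_table.loc[gender == groups[0], acc].to_numpy(dtype=float)
        y = accuracy_table.loc[gender == groups[1], acc].to_numpy(dtype=float)
        t, p = _stats.ttest_ind(x, y)
        g_rows.append({"accuracy": acc, "t": float(t), "p_raw": float(p),
                       "p_corrected": bonferroni(float(p), n_acc),
                       "significant": bonferroni(float(p), n_acc) < 0.05})
    return {"spearman": spearman, "gender": pd.DataFrame(g_rows)}


# --------------------------------------------------------------------------
# Summary report
# --------------------------------------------------------------------------

REPORT_COLUMNS = ["scheme", "comparison", "class_a", "class_b",
                  "acc_a_mean", "acc_a_sd", "acc_b_mean", "acc_b_sd",
                  "balanced_mean", "balanced_sd", "t", "p_raw",
                  "p_corrected", "significant"]

_SCHEME_ORDER = {"intra-LOTO": 0, "inter-cross": 1, "inter-LOTO": 2}


def build_report(per_participant: pd.DataFrame,
                 n_corrections: int = DEFAULT_N_CORRECTIONS) -> pd.DataFrame:
    """Summary accuracy table across participants.

    ``per_participant`` holds one row per participant and comparison
    with columns ``scheme``, ``comparison``, ``class_a``, ``class_b``,
    ``participant``, ``acc_a``, ``acc_b``, ``balanced``.  Rows are
    grouped by scheme (intra-LOTO, inter-cross, inter-LOTO); each row
    reports mean +/- sd of the per-class and balanced accuracies and
    the Bonferroni-corrected t-test of the balanced accuracy against
    chance, with the significance flag at corrected p < 0.05.
    """
    if per_participant.empty:
        return pd.DataFrame(columns=REPORT_COLUMNS)
    rows = []
    grouped = per_participant.groupby(["scheme", "comparison"], sort=False)
    for (scheme, comparison), g in grouped:
        res = test_vs_chance(g["balanced"].to_numpy(), n_corrections,
                             comparison=comparison)
        rows.append({
            "scheme": scheme, "comparison": comparison,
            "class_a": g["class_a"].iloc[0], "class_b": g["class_b"].iloc[0],
            "acc_a_mean": float(g["acc_a"].mean()),
            "acc_a_sd": float(g["acc_a"].std(ddof=1)),
            "acc_b_mean": float(g["acc_b"].mean()),
            "acc_b_sd": float(g["acc_b"].std(ddof=1)),
            "balanced_mean": res.mean, "balanced_sd": res.sd,
            "t": res.t, "p_raw": res.p_raw, "p_corrected": res.p_corrected,
            "significant": res.significant,
        })
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    report["_o"] = report["scheme"].map(_SCHEME_ORDER).fillna(3)
    report = report.sort_values(["_o"], kind="stable").drop(columns="_o")
    return report.reset_index(drop=True)


def report_to_markdown(report: pd.DataFrame) -> str:
    """Markdown rendering; significant rows are bolded."""
    lines = ["| Scheme | Comparison | Class A | Class B | (A+B)/2 | p |",
             "|---|---|---|---|---|---|"]
    for _, r in report.iterrows():
        def fmt(m, s):
            return f"{m:.2f} ± {s:.2f}"
        cells = [r["scheme"], r["comparison"],
                 fmt(r["acc_a_mean"], r["acc_a_sd"]),
                 fmt(r["acc_b_mean"], r["acc_b_sd"]),
                 fmt(r["balanced_mean"], r["balanced_sd"]),
                 f"{r['p_corrected']:.3g}"]
        if r["significant"]:
            cells = [f"**{c}**" for c in cells]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"
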