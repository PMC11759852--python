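"""Functional enrichment scoring by random-effects meta-analysis.

Per replicate r, a variant's enrichment score is the log ratio of
pseudocounted allele frequencies between selected and control (unselected)
pools,

    s_r = ln((c_sel + 1/2) / N_sel) - ln((c_ctrl + 1/2) / N_ctrl),

with sampling variance v_r = 1/(c_sel + 1/2) + 1/(c_ctrl + 1/2) — the
Enrich2 convention. Replicates are combined with the closed-form
DerSimonian-Laird random-effects estimator: between-replicate variance

    tau^2 = max(0, (Q - (R-1)) / (Sum w - Sum w^2 / Sum w)),  w = 1/v_r,

where Q is the fixed-effect weighted heterogeneity statistic, and

    beta = Sum w* s_r / Sum w*,  se = sqrt(1 / Sum w*),  w* = 1/(v_r + tau^2).

Variants whose unselected allele frequency falls below 0.1% are excluded
before scoring (low-abundance variants have unstable scores). Scores can be
centered per library on the neutral synonymous/BLB median and optionally
scaled by the PTC median magnitude, and truth-set separation is summarized
by rank-based AUROC.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .kmers import CountTable

logger = logging.getLogger(__name__)

PSEUDOCOUNT = 0.5


# -- allele frequencies and filtering -----------------------------------


def compute_af(table: CountTable) -> pd.DataFrame:
    """Allele frequency per variant per sample: count / total reads.

    Columns are renamed ``af_<condition>_rep<N>``.
    """
    for col, total in table.totals.items():
        if total <= 0:
            raise ValueError(f"sample {col} has zero total reads")
    af = table.df.astype(float).copy()
    for col in af.columns:
        af[col] = af[col] / table.totals[col]
    af.columns = [c.replace("counts_", "af_", 1) for c in af.columns]
    return af


def filter_low_af(
    af: pd.DataFrame,
    threshold: float = 0.001,
    mode: str = "any_replicate",
) -> pd.DataFrame:
    """Flag variants whose unselected (control) AF falls below ``threshold``.

    ``mode="any_replicate"`` excludes a variant if any control replicate is
    below the cutoff (conservative default); ``"all_replicates"`` requires
    every control replicate to be below it. Strictly below: an AF exactly at
    the threshold is retained. Returns ``af`` with ``filtered`` (bool) and
    ``filter_reason`` columns appended.
    """
    if mode not in ("any_replicate", "all_replicates"):
        raise ValueError(f"unknown filter mode {mode!r}")
    ctrl_cols = [c for c in af.columns if c.startswith("af_control_")]
    if not ctrl_cols:
        raise ValueError("no control-condition AF columns present")
    below = af[ctrl_cols] < threshold
    excluded = below.any(axis=1) if mode == "any_replicate" else below.all(axis=1)
    out = af.copy()
    out["filtered"] = excluded
    out["filter_reason"] = np.where(excluded, f"af_control_below_{threshold}", "")
    return out


# -- per-replicate scores and random effects ----------------------------


def replicate_scores(
    c_sel: np.ndarray,
    c_ctrl: np.ndarray,
    n_sel: np.ndarray,
    n_ctrl: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-replicate (s_r, v_r) from raw counts and depths."""
    c_sel = np.asarray(c_sel, dtype=float) + PSEUDOCOUNT
    c_ctrl = np.asarray(c_ctrl, dtype=float) + PSEUDOCOUNT
    s = np.log(c_sel / np.asarray(n_sel, dtype=float)) - np.log(
        c_ctrl / np.asarray(n_ctrl, dtype=float)
    )
    v = 1.0 / c_sel + 1.0 / c_ctrl
    return s, v


def random_effects(s: np.ndarray, v: np.ndarray) -> tuple[float, float, float]:
    """DerSimonian-Laird combination of per-replicate scores.

    Returns (beta, se, tau2). A single replicate collapses to
    (s_1, sqrt(v_1), 0).
    """
    s = np.asarray(s, dtype=float)
    v = np.asarray(v, dtype=float)
    if s.size == 0:
        raise ValueError("random_effects requires at least one replicate")
    if s.size == 1:
        return float(s[0]), float(np.sqrt(v[0])), 0.0
    w = 1.0 / v
    mu_fe = np.sum(w * s) / np.sum(w)
    q = np.sum(w * (s - mu_fe) ** 2)
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (s.size - 1)) / c)
    w_star = 1.0 / (v + tau2)
    beta = float(np.sum(w_star * s) / np.sum(w_star))
    se = float(np.sqrt(1.0 / np.sum(w_star)))
    return beta, se, float(tau2)


@dataclass
class ScoreResult:
    """Scored table plus bookkeeping for one library."""

    scores: pd.DataFrame  # index variant; beta, se, tau2, s_r/v_r, filtered
    replicates: int
    threshold: float


def score_table(
    table: CountTable,
    classes: dict[str, str] | None = None,
    threshold: float = 0.001,
    filter_mode: str = "any_replicate",
) -> ScoreResult:
    """Full scoring pass over a count table.

    Computes AFs, applies the unselected-AF filter, derives per-replicate
    log-enrichment scores and combines them with the random-effects model.
    ``classes`` maps variant name to class label (WT_* rows and unmapped
    rows are labeled OTHER and never enter truth-set summaries). Filtered
    variants carry no beta.
    """
    af = compute_af(table)
    af = filter_low_af(af, threshold=threshold, mode=filter_mode)
    reps = sorted(
        {
            int(c.rsplit("rep", 1)[1])
            for c in table.df.columns
            if c.startswith("counts_control_")
        }
    )
    sel_reps = {
        int(c.rsplit("rep", 1)[1])
        for c in table.df.columns
        if c.startswith("counts_selected_")
    }
    usable = [r for r in reps if r in sel_reps]
    for r in reps:
        if r not in sel_reps:
            logger.warning("replicate %d missing selected condition; dropped", r)

    rows = []
    for variant, row in table.df.iterrows():
        s_list, v_list = [], []
        for r in usable:
            c_ctrl = row[f"counts_control_rep{r}"]
            c_sel = row[f"counts_selected_rep{r}"]
            s, v = replicate_scores(
                np.array([c_sel]),
                np.array([c_ctrl]),
                np.array([table.totals[f"counts_selected_rep{r}"]]),
                np.array([table.totals[f"counts_control_rep{r}"]]),
            )
            s_list.append(float(s[0]))
            v_list.append(float(v[0]))
        filtered = bool(af.loc[variant, "filtered"])
        if filtered or not s_list:
            beta, se, tau2 = np.nan, np.nan, np.nan
        else:
            beta, se, tau2 = random_effects(np.array(s_list), np.array(v_list))
        label = (classes or {}).get(variant, "OTHER")
        rows.append(
            {
                "variant": variant,
                "class_label": label,
                "beta": beta,
                "se": se,
                "tau2": tau2,
                "filtered": filtered,
                "filter_reason": af.loc[variant, "filter_reason"],
                "s_r": s_list,
                "v_r": v_list,
            }
        )
    scores = pd.DataFrame(rows).set_index("variant")
    return ScoreResult(scores=scores, replicates=len(usable), threshold=threshold)


def write_scores_csv(table: CountTable, result: ScoreResult, path) -> None:
    """Write the input count table with exactly two appended columns, beta
    and SE (blank for filtered rows)."""
    out = table.df.copy()
    out.insert(0, "variant", out.index)
    out["beta"] = result.scores["beta"].reindex(out.index).round(6)
    out["SE"] = result.scores["se"].reindex(out.index).round(6)
    out.to_csv(path, index=False)


# -- cross-library normalization ----------------------------------------

NEUTRAL_CLASSES = ("POP_SYN", "BLB")


def normalize_scores(
    tables: dict[str, pd.DataFrame],
    min_anchors: int = 3,
    scale_by_ptc: bool = False,
) -> dict[str, pd.DataFrame]:
    """Center each library's betas on its neutral (synonymous + BLB) median.

    Libraries with fewer than ``min_anchors`` scored neutral variants are
    returned unchanged with a warning. With ``scale_by_ptc=True`` and at
    least ``min_anchors`` scored PTC variants, betas are additionally
    divided by the magnitude of the (centered) PTC median so full loss of
    function maps to -1 under depletion selection.
    """
    out = {}
    for lib, df in tables.items():
        df = df.copy()
        scored = df[~df["beta"].isna()]
        anchors = scored[scored["class_label"].isin(NEUTRAL_CLASSES)]
        if len(anchors) < min_anchors:
            logger.warning(
                "library %s: only %d neutral anchors (<%d); left unnormalized",
                lib,
                len(anchors),
                min_anchors,
            )
            out[lib] = df
            continue
        shift = float(anchors["beta"].median())
        df["beta"] = df["beta"] - shift
        if scale_by_ptc:
            ptc = df[(~df["beta"].isna()) & (df["class_label"] == "PTC_CTRL")]
            if len(ptc) >= min_anchors and abs(float(ptc["beta"].median())) > 0:
                scale = abs(float(ptc["beta"].median()))
                df["beta"] = df["beta"] / scale
                df["se"] = df["se"] / scale
        out[lib] = df
    return out


# -- truth-set separation -----------------------------------------------


def _auroc(pos: np.ndarray, neg: np.ndarray) -> float | None:
    """Rank-based AUROC: probability a ``pos`` score exceeds a ``neg``
    score (ties count 1/2)."""
    if len(pos) == 0 or len(neg) == 0:
        return None
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (len(pos) * len(neg)))


@dataclass
class SeparationReport:
    """Per-class summaries and truth-set discrimination for scored data."""

    class_stats: pd.DataFrame
    auroc_syn_vs_ptc: float | None
    auroc_blb_vs_plp: float | None
    verdict: str

    def to_dict(self) -> dict:
        return {
            "class_stats": self.class_stats.to_dict(orient="records"),
            "auroc_syn_vs_ptc": self.auroc_syn_vs_ptc,
            "auroc_blb_vs_plp": self.auroc_blb_vs_plp,
            "verdict": self.verdict,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_markdown(self) -> str:
        lines = ["# Truth-set separation", "", self.class_stats.to_string(index=False), ""]
        lines.append(
            f"AUROC synonymous vs PTC: "
            f"{self.auroc_syn_vs_ptc if self.auroc_syn_vs_ptc is not None else 'not computable'}"
        )
        lines.append(
            f"AUROC BLB vs PLP: "
            f"{self.auroc_blb_vs_plp if self.auroc_blb_vs_plp is not None else 'not computable'}"
        )
        lines += ["", self.verdict]
        return "\n".join(lines)


def evaluate_truth_sets(scores: pd.DataFrame) -> SeparationReport:
    """Summarize truth-set separation on a scored table.

    AUROCs are oriented for depletion-type selection: the probability that a
    presumed-neutral variant (POP_SYN, BLB) scores above a presumed
    loss-of-function variant (PTC_CTRL, PLP).
    """
    scored = scores[~scores["beta"].isna()]
    present = scored["class_label"].unique()
    if len(present) < 2:
        raise ValueError("need at least two classes with scores")
    rows = []
    for label, grp in scored.groupby("class_label"):
        q1, med, q3 = np.percentile(grp["beta"], [25, 50, 75])
        rows.append(
            {
                "class_label": label,
                "n": len(grp),
                "median": round(float(med), 4),
                "iqr": round(float(q3 - q1), 4),
            }
        )
    class_stats = pd.DataFrame(rows).sort_values("class_label").reset_index(drop=True)

    def betas(label):
        return scored.loc[scored["class_label"] == label, "beta"].to_numpy()

    auc_sp = _auroc(betas("POP_SYN"), betas("PTC_CTRL"))
    auc_bp = _auroc(betas("BLB"), betas("PLP"))
    parts = []
    if auc_sp is None:
        parts.append("synonymous/PTC comparison not computable")
    elif auc_sp > 0.9:
        parts.append("synonymous and PTC variants are well separated")
    else:
        parts.append("synonymous and PTC variants separate poorly")
    if auc_bp is None:
        parts.append("BLB/PLP comparison not computable")
    elif auc_bp > 0.8:
        parts.append("BLB scores sit clearly above PLP scores")
    else:
        parts.append("BLB and PLP overlap substantially")
    return SeparationReport(
        class_stats=class_stats,
        auroc_syn_vs_ptc=auc_sp,
        auroc_blb_vs_plp=auc_bp,
        verdict="; ".join(parts) + ".",
    )
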