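"""Species-resolved expression and secretion statistics.

Expression: relative mRNA levels from qPCR Ct tables by the delta-delta-Ct
convention, normalised to the species reference gene (mouse GAPDH, human
RPLP0) and rescaled so the control-group mean is 1; groups are compared with
a two-sided pooled-variance (Student's) t-test at alpha = 0.05 and reported
as means ± SE.

Secretion: a multiplex panel is first censored at the limit of detection
(an analyte counts as not detected only when every well of both biological
conditions is below LOD), screened for mouse cross-reactivity against
mouse-only conditioned media, and finally classified per analyte as
excluded_cross_reactive, not_detected, upregulated (significant EPS
increase) or detected_not_upregulated. No multiple-testing correction is
applied by default (per-analyte P < 0.05); Benjamini–Hochberg is available
behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import require
from .errors import ParameterError, SchemaError
from .simkit import REFERENCE_GENES, SecretionPanel

__all__ = [
    "TTestResult",
    "ExpressionResult",
    "PanelClassification",
    "compare_groups",
    "relative_expression",
    "expression_table",
    "censor_lod",
    "detect_cross_reactive",
    "classify_panel",
]


# ---------------------------------------------------------------------------
# group comparison


@dataclass
class TTestResult:
    t: float
    p: float
    mean_a: float
    se_a: float
    mean_b: float
    se_b: float
    n_a: int
    n_b: int


def compare_groups(
    values_a: Iterable[float],
    values_b: Iterable[float],
    welch: bool = False,
) -> TTestResult:
    """Two-sided two-sample t-test with pooled variance (Student's t).

    Welch's unequal-variance test is available behind ``welch=True``. Groups
    with zero pooled variance yield ``t = 0, p = 1`` when the means are equal
    (nothing to distinguish) and ``p = 0`` otherwise (an exact separation).
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs at least two observations")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        # degenerate: no within-group variability
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t = math.copysign(math.inf, a.mean() - b.mean())
            p = 0.0
    else:
        res = stats.ttest_ind(a, b, equal_var=not welch)
        t, p = float(res.statistic), float(res.pvalue)
        if not math.isfinite(t):
            if np.isclose(a.mean(), b.mean()):
                t, p = 0.0, 1.0
            else:
                t = math.copysign(math.inf, a.mean() - b.mean())
                p = 0.0
    return TTestResult(
        t=t,
        p=p,
        mean_a=float(a.mean()),
        se_a=float(a.std(ddof=1) / np.sqrt(a.size)),
        mean_b=float(b.mean()),
        se_b=float(b.std(ddof=1) / np.sqrt(b.size)),
        n_a=int(a.size),
        n_b=int(b.size),
    )


# ---------------------------------------------------------------------------
# relative expression (delta-delta-Ct)


@dataclass
class ExpressionResult:
    """Relative expression of one gene in one species.

    ``fold`` is the EPS-group mean relative level; the control-group mean is
    1 by construction. ``fold_ci`` is the 95 % confidence interval of the
    fold change computed on the delta-Ct (log2) scale with pooled variance.
    """

    gene: str
    species: str
    fold: float
    fold_ci: tuple
    levels_eps: np.ndarray
    levels_control: np.ndarray
    mean_eps: float
    se_eps: float
    mean_control: float
    se_control: float
    t: float | None
    p: float | None
    significant: bool
    delta_ct_eps: np.ndarray = field(repr=False, default=None)
    delta_ct_control: np.ndarray = field(repr=False, default=None)


def _fold_ci(dct_control: np.ndarray, dct_eps: np.ndarray,
             alpha: float) -> tuple:
    """95 % CI of the fold change on the delta-Ct scale (pooled variance)."""
    n1, n2 = dct_control.size, dct_eps.size
    if n1 < 2 or n2 < 2:
        return (float("nan"), float("nan"))
    ddct = dct_control.mean() - dct_eps.mean()  # log2 fold
    sp2 = (
        (n1 - 1) * dct_control.var(ddof=1) + (n2 - 1) * dct_eps.var(ddof=1)
    ) / (n1 + n2 - 2)
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    tcrit = stats.t.ppf(1 - alpha / 2, n1 + n2 - 2)
    return (float(2 ** (ddct - tcrit * se)), float(2 ** (ddct + tcrit * se)))


def relative_expression(
    ct_table: pd.DataFrame,
    reference_map: Mapping[str, str] | None = None,
    alpha: float = 0.05,
    welch: bool = False,
) -> list:
    """Delta-delta-Ct relative expression per (gene, species).

    For every sample, ``delta_Ct = Ct_gene - Ct_reference`` within the same
    species block; the per-sample relative level is ``2 ** (-delta_Ct)``
    rescaled so the control-group mean equals 1. EPS and control groups are
    compared on the rescaled levels with a pooled-variance t-test when both
    groups have at least two samples.

    Raises :class:`SchemaError` if a (sample, species) block lacks its
    reference gene or required columns are missing.
    """
    if reference_map is None:
        reference_map = REFERENCE_GENES
    needed = {"sample", "condition", "species", "gene", "ct_value"}
    missing = needed - set(ct_table.columns)
    if missing:
        raise SchemaError(f"Ct table missing columns: {sorted(missing)}")
    require(0 < alpha < 1, "alpha must lie in (0, 1)")

    results = []
    for species, block in ct_table.groupby("species", sort=True):
        if species not in reference_map:
            raise SchemaError(f"no reference gene declared for {species!r}")
        ref_gene = reference_map[species]
        ref = block[block["gene"] == ref_gene]
        ref_by_sample = ref.set_index("sample")["ct_value"]
        missing_ref = set(block["sample"]) - set(ref_by_sample.index)
        if missing_ref:
            raise SchemaError(
                f"samples missing reference gene {ref_gene} for {species}: "
                f"{sorted(missing_ref)}"
            )
        for gene, gblock in block[block["gene"] != ref_gene].groupby(
            "gene", sort=True
        ):
            dct = (
                gblock["ct_value"].to_numpy()
                - ref_by_sample.loc[gblock["sample"]].to_numpy()
            )
            rel = 2.0 ** (-dct)
            cond = gblock["condition"].to_numpy()
            ctrl = rel[cond == "control"]
            eps = rel[cond == "EPS"]
            if ctrl.size == 0 or eps.size == 0:
                raise SchemaError(
                    f"gene {gene} ({species}) lacks samples in one condition"
                )
            scale = ctrl.mean()
            ctrl_s, eps_s = ctrl / scale, eps / scale
            if ctrl.size >= 2 and eps.size >= 2:
                tt = compare_groups(eps_s, ctrl_s, welch=welch)
                t_val, p_val = tt.t, tt.p
                significant = p_val < alpha
            else:
                t_val = p_val = None
                significant = False
            dct_ctrl = dct[cond == "control"]
            dct_eps = dct[cond == "EPS"]
            results.append(
                ExpressionResult(
                    gene=str(gene),
                    species=str(species),
                    fold=float(eps_s.mean()),
                    fold_ci=_fold_ci(dct_ctrl, dct_eps, alpha),
                    levels_eps=eps_s,
                    levels_control=ctrl_s,
                    mean_eps=float(eps_s.mean()),
                    se_eps=float(eps_s.std(ddof=1) / np.sqrt(eps_s.size))
                    if eps_s.size > 1 else float("nan"),
                    mean_control=float(ctrl_s.mean()),
                    se_control=float(ctrl_s.std(ddof=1) / np.sqrt(ctrl_s.size))
                    if ctrl_s.size > 1 else float("nan"),
                    t=t_val,
                    p=p_val,
                    significant=significant,
                    delta_ct_eps=dct_eps,
                    delta_ct_control=dct_ctrl,
                )
            )
    return results


def expression_table(results: Iterable[ExpressionResult]) -> pd.DataFrame:
    """Flatten :class:`ExpressionResult` objects into one tidy DataFrame."""
    rows = [
        {
            "species": r.species,
            "gene": r.gene,
            "fold": r.fold,
            "fold_ci_low": r.fold_ci[0],
            "fold_ci_high": r.fold_ci[1],
            "mean_eps": r.mean_eps,
            "se_eps": r.se_eps,
            "mean_control": r.mean_control,
            "se_control": r.se_control,
            "t": r.t,
            "p": r.p,
            "significant": r.significant,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# secretion panel


def censor_lod(panel: SecretionPanel) -> SecretionPanel:
    """Flag below-LOD wells and per-analyte detection status.

    An analyte is *not detected* iff every well of both the EPS and control
    conditions falls below its limit of detection; a single well at or above
    LOD in either condition makes it detected. Returns a new panel whose
    ``data`` carries a ``below_lod`` column and whose ``detected`` Series
    maps analyte -> bool.
    """
    data = panel.data.copy()
    lod_per_row = panel.lod.loc[data["analyte"]].to_numpy()
    data["below_lod"] = data["concentration"].to_numpy() < lod_per_row
    bio = data[data["condition"].isin(["EPS", "control"])]
    detected = ~bio.groupby("analyte")["below_lod"].all()
    detected = detected.reindex(panel.analytes, fill_value=False)
    return SecretionPanel(data=data, lod=panel.lod, detected=detected)


def detect_cross_reactive(
    panel: SecretionPanel, k_sd: float = 3.0
) -> set:
    """Analytes whose human assay reads through from mouse media.

    An analyte is cross-reactive iff the mean signal in mouse-only
    conditioned media exceeds ``mean(blank) + k_sd * SD(blank)`` and is at
    or above the limit of detection. Requires ``mouse_only_media`` and
    ``blank`` conditions in the panel.
    """
    require(k_sd >= 0, "k_sd must be non-negative")
    present = set(panel.data["condition"])
    missing = {"mouse_only_media", "blank"} - present
    if missing:
        raise SchemaError(
            f"panel lacks conditions needed for cross-reactivity screening: "
            f"{sorted(missing)}"
        )
    out = set()
    grouped = panel.data.groupby(["analyte", "condition"])["concentration"]
    mean = grouped.mean().unstack()
    sd_blank = (
        panel.data[panel.data["condition"] == "blank"]
        .groupby("analyte")["concentration"]
        .std(ddof=1)
    )
    for analyte in panel.analytes:
        m_mouse = mean.loc[analyte, "mouse_only_media"]
        threshold = mean.loc[analyte, "blank"] + k_sd * sd_blank.loc[analyte]
        if m_mouse > threshold and m_mouse >= panel.lod.loc[analyte]:
            out.add(analyte)
    return out


@dataclass
class PanelClassification:
    """Per-analyte classes and statistics for one secretion panel.

    Classes partition the panel with precedence excluded_cross_reactive >
    not_detected > upregulated > detected_not_upregulated; excluded analytes
    carry no up/down call.
    """

    classes: dict  # analyte -> class
    stats: pd.DataFrame
    excluded: set
    alpha: float

    def class_counts(self) -> dict:
        counts: dict = {}
        for cls in self.classes.values():
            counts[cls] = counts.get(cls, 0) + 1
        return counts


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    n = pvals.size
    order = np.argsort(pvals)
    ranked = pvals[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def classify_panel(
    panel: SecretionPanel,
    cross_reactive_set: set | None = None,
    alpha: float = 0.05,
    k_sd: float = 3.0,
    bh: bool = False,
) -> PanelClassification:
    """Classify every analyte of a secretion panel.

    Order of precedence: analytes in ``cross_reactive_set`` (screened with
    :func:`detect_cross_reactive` when not supplied) are excluded; analytes
    below LOD in every biological well are not detected; remaining analytes
    are *upregulated* when the EPS mean exceeds the control mean with
    ``p < alpha`` (pooled t-test), otherwise *detected_not_upregulated*.
    There is no downregulated class. ``bh=True`` applies Benjamini–Hochberg
    correction across the tested analytes before calling significance.
    """
    require(0 < alpha < 1, "alpha must lie in (0, 1)")
    panel = censor_lod(panel)
    if cross_reactive_set is None:
        cross_reactive_set = detect_cross_reactive(panel, k_sd=k_sd)

    records = []
    for analyte in panel.analytes:
        rows = panel.data[panel.data["analyte"] == analyte]
        eps = rows.loc[rows["condition"] == "EPS", "concentration"].to_numpy()
        ctrl = rows.loc[
            rows["condition"] == "control", "concentration"
        ].to_numpy()
        tt = compare_groups(eps, ctrl)
        records.append(
            {
                "analyte": analyte,
                "mean_eps": tt.mean_a,
                "se_eps": tt.se_a,
                "mean_control": tt.mean_b,
                "se_control": tt.se_b,
                "t": tt.t,
                "p": tt.p,
                "detected": bool(panel.detected.loc[analyte]),
                "cross_reactive": analyte in cross_reactive_set,
            }
        )
    table = pd.DataFrame(records).set_index("analyte")

    testable = table.index[~table["cross_reactive"] & table["detected"]]
    table["p_used"] = table["p"]
    if bh and len(testable) > 0:
        table.loc[testable, "p_used"] = _bh_adjust(
            table.loc[testable, "p"].to_numpy()
        )

    classes = {}
    for analyte, row in table.iterrows():
        if row["cross_reactive"]:
            classes[analyte] = "excluded_cross_reactive"
        elif not row["detected"]:
            classes[analyte] = "not_detected"
        elif row["p_used"] < alpha and row["mean_eps"] > row["mean_control"]:
            classes[analyte] = "upregulated"
        else:
            classes[analyte] = "detected_not_upregulated"
    table["class"] = pd.Series(classes)
    # excluded analytes carry no up/down call
    table.loc[table["class"] == "excluded_cross_reactive",
              ["t", "p", "p_used"]] = np.nan

    return PanelClassification(
        classes=classes,
        stats=table.reset_index(),
        excluded=set(cross_reactive_set),
        alpha=alpha,
    )
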